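# Methods

This note documents the models implemented in `stai`, the defaults and
their rationale, the synthetic-data generator and the validation
experiments, including the numerical choices and known limitations.

## Codon adaptiveness and gene scores

For each sense codon `i` with bases `b1 b2 B`, the recognizing anticodons
are `X + rc(b2) + rc(b1)` where `X` (tRNA position 34) follows Crick's
wobble rules: codon-U is read by A34 (counted as inosine) and by G34;
codon-C by G34 (Watson–Crick) and A34 (I:C); codon-A by U34 (WC) and A34
(I:A); codon-G by C34 (WC) and U34 (U:G).  Genomic tRNAs with wobble base
A are assumed inosine-modified, so the A34 gene copy number feeds the I:*
interactions.  In bacteria and archaea the AUA codon is read exclusively
by the lysidine/agmatidine-modified tRNA-Ile (key `L:A`); its copy number
is carried separately (`TrnaPool.special_ile_count`, default 1) because
its genomic anticodon (CAT) is indistinguishable from tRNA-Met's.  AUG and
UGG are scored by the same generic rules (the U:G wobble term for AUG is
included; a flag on the gene scores can exclude Met/Trp codons).

Absolute adaptiveness is `W_i = Σ_j (1 − s_ij)·tGCN_j`; relative
adaptiveness `w_i = W_i / max(W)`.  Codons left with `w = 0` because the
pool contains no reader take the geometric mean of the non-zero `w`
(standard tAI practice; logged whenever triggered) so gene scores stay
defined.  A gene's score is the geometric mean of `w` over its codon
positions; stop codons are removed at parse time (the genetic-code
rationale; internal stops are additionally logged), the initiator AUG is
kept.

Three pairing modes exist: `standard` (free keys = the 4 wobble
constraints, 5 in prokaryotes), `all_pairings` (adds U:U, C:U, U:C, C:C,
C:A, G:A, I:G, G:G so every codon can pair with all four anticodons of its
box; all non-WC keys initialized at 0.5), and `free_wc` (releases the four
WC constraints, starting from the best standard-mode fit).

## Codon usage bias scores

Both scores are per gene and compare each codon's observed frequency with
the product of the gene's positional base frequencies, which controls for
base composition.  RCBS uses the signed relative excess `d = (obs −
exp)/exp ≥ −1` and aggregates as a geometric mean of `(1 + d)` minus 1;
DCBS uses `d = max(obs/exp, exp/obs) ≥ 1` and aggregates as the arithmetic
mean, so over- and under-representation both raise the score.  Sums run
over the gene's `L` codon positions (each occurrence contributes), not
over codon types; codons absent from a gene contribute nothing and no
pseudo-counts are used.  Both scores are invariant under codon-order
permutation and self-concatenation.  Under independent positional base
draws DCBS → 1 as L → ∞, with a finite-length inflation of roughly the
mean absolute multinomial fluctuation of the 64 observed/expected ratios
(about +0.06 at L = 10,000) — short genes always look somewhat biased.

## Weight inference

The objective is the Spearman correlation (midranks for ties) across genes
between the candidate-weight gene scores and a per-gene target: DCBS
(default), RCBS, or measured protein abundance over the gene-id
intersection.  The search is stochastic hill climbing with a shrinking
step: each iteration perturbs a random non-empty subset of the free keys
(each included with probability 1/2, direction ± uniform) by the current
step, clamped to [0, 1]; only strictly improving moves are accepted
(avoiding drift along the rank objective's plateaus); after 50 consecutive
rejections the step divides by 1.35, from 0.3 down to 0.001.  Starting
points: the classical weights, all-zeros, all-ones, and all 2^k
combinations of the half-region midpoints 0.25/0.75 (the deterministic
representatives of the two halves of [0, 1]), optionally plus
uniform-random extras.  The best final objective wins; ties keep the first
start.  All randomness derives from one seed (per-start child generators
from a `SeedSequence`), making results bit-reproducible.

Candidate weight sets that drive a *decodable* codon's `W` to exactly 0
(every reader at `s = 1`) are inadmissible during optimization: a
translatable codon cannot lose all decoders, and the geometric-mean
fallback would otherwise create a discontinuous spurious optimum at the
boundary (observed as a jump of the objective when a wobble weight touches
1).  The fallback still applies to codons the pool itself cannot decode.

Before optimization an exclusion screen computes the Spearman correlation
between default-weight scores and DCBS; organisms are included only when
it is positive and significant (two-sided t-approximation p < 0.05 — the
test and threshold are this package's choice).  The screen is advisory:
`optimize_weights(..., check_exclusion=True)` enforces it.

The whole procedure is also packaged as a scikit-learn estimator
(`StaiEstimator`: `fit` = multi-start climb, `transform` = per-gene
scores, `get_params`/`set_params`/`clone` compatible), which is the
recommended API.

## Synthetic genomes

`simulate_genome` draws per-gene expression `e` log-normally (sigma 1.0 by
default), gene lengths uniform in 100–400 codons, amino acids per site
from a typical proteome composition, and chooses each synonymous codon
with probability proportional to `w_c^(β·e)` under a known ("true")
weight set and tRNA pool.  Selection therefore acts multiplicatively on
adaptiveness, matching the geometric-mean form of the gene score: the
per-gene sufficient statistic of the codon distribution is `Σ log w_c`,
i.e. the log gene score itself, which is what makes planted weights
recoverable in principle from rank correlations.  (With selection linear
in `w` the correlation-optimal weights are provably not the planted ones —
the inferred vector is uniformly "sharpened"; this was measured at both
n = 1000 and n = 4000 genes.)  At β = 0 codon choice is uniform within
families; as β·e grows each family concentrates on its best codon.
Protein abundance is `e` times log-normal noise.  The default β = 1.0 was
calibrated once so that the gene-level Spearman correlation between
true-weight scores and DCBS sits in the 0.5–0.7 band typical of
codon-biased genomes at the default size.

Composition can be `multinomial` (per-site draws; realistic between-gene
variation) or `fixed` (every gene gets the same amino-acid fractions by
largest-remainder rounding).  The distinction matters: with multinomial
composition, DCBS and the adaptation score rank between-gene composition
differences differently, which biases the correlation-maximizing weights
(about +0.2 on I:C in our measurements, persisting at 800-codon genes
where the objective reaches 0.97) — a genuine limitation of the method on
real data, where composition varies.  Fixed composition isolates weight
identifiability and is used in the recovery experiment.

The default tRNA pool is a realistic mixed-decoding table: every box is
covered, but many codons are read through a single wobble channel (as in
real genomes), which is what makes each wobble weight consequential.  The
generator does not attempt GC gradients, amino-acid evolution, or tRNA
modification biology.

`synonymous_randomize` resamples every codon position from the genome-wide
synonymous distribution of its amino acid: protein content, gene count and
lengths are preserved exactly, genome-wide codon frequencies in
expectation, and the gene-level coupling between codon bias and expression
is destroyed (|Spearman(DCBS, e)| < 0.1 at 1000 genes).  Two residual
signals survive, both documented by tests: (i) genes that drift toward the
already-common (high-w) codons gain both DCBS and adaptation score, so a
randomized *biased* genome retains a weak positive gene-level correlation
and can pass the exclusion screen; (ii) the genome-average codon
frequencies still echo the original weights, so weight inference on
randomized genomes is not uniformly uninformative.  The clustering
significance study below is designed with this in mind.

## Validation experiments

**Parameter recovery** (`parameter_recovery_experiment`): 1000 genes,
fixed composition, true wobble weights {G:U 0.79, I:C 0.47, I:A 0.91,
U:G 0.63} — a stand-in for a typical eukaryote with inefficient
inosine:adenosine decoding — and β = 0.25, calibrated to put the
true-weight objective in the 0.5–0.7 band.  Reported: the objective at
truth, the best objective found, their ratio, and per-key errors.  The
optimizer reliably reaches ≥ 95% (typically > 100%) of the true-weight
objective.  Pointwise weight recovery is noisier: the rank-correlation
objective is nearly flat over ~0.2-wide moves of individual keys at this
problem size, so the sample argmax can sit 0.2–0.3 from the planted value
on one key (most often G:U or U:G, whose soft directions form a shallow
joint valley).  Recovery to within ±0.15 on every key simultaneously
would need several-fold more genes or a sharper objective; this is a
property of the method, not of the implementation, and is reproduced by
the acceptance suite as-is.

**Permutation-test calibration** (`permutation_null_study`): two groups of
8 drawn from one normal distribution, 1000 replicates, 100 permutations
each; the rejection rate at α = 0.05 stays within ±0.03 of α.  Note the
permutation p-value (fraction of relabelings with distance ≥ observed)
can never fall below 2/(number of distinct relabelings); with 2-element
groups its minimum is 1/3, so small groups cannot reach significance.

**Randomization decoupling** (`randomization_decoupling_experiment`):
proteome preservation is checked codon-list-by-codon-list, and the
DCBS-expression correlation drops from > 0.3 to |rho| < 0.1.

**Clustering significance** (`clustering_significance_experiment`): 7
organisms per domain, each with its own jittered tRNA pool (±1 gene copy)
and its own amino-acid composition (Dirichlet around the default,
concentration 200), genomes of 800 genes (80–160 codons) generated from
three planted domain corners of the shared 4-key wobble space; weights are
re-inferred per organism on a shortened climb schedule (step down to 0.01,
15 stale iterations per level) to keep the ~130 optimizations tractable,
clustered by k-means (Lloyd, 20 seeded restarts, best inertia), and
scored against the domain partition under the best cluster→domain
bijection.  Five synonymous-randomized replicates of the whole study give
the empirical p (fraction of replicates with accuracy ≥ the original).
The per-organism heterogeneity is essential: with identical pools and
compositions within a domain, the weight vectors inferred from
*randomized* genomes collapse onto a pool/frequency-determined point per
domain and cluster perfectly, voiding the null.  The planted corners
differ on at least two keys per pair of domains and avoid separating
mainly along I:A, whose genome-frequency echo survives randomization.

## Numerical choices

Spearman uses midranks and is computed as the Pearson correlation of rank
vectors; constant vectors are an error in user-facing functions and an
inadmissible (−inf) candidate inside the optimizer.  The group-distance
statistic uses sample SDs (ddof 1); a zero denominator gives distance 0
for equal means and +inf otherwise.  PCA is a mean-centered SVD with each
component signed so its largest-magnitude loading is positive; requesting
more components than the matrix rank truncates with a warning.  k-means
degeneracy (near-identical rows) is flagged when the largest row-to-mean
distance falls below 1e-6.  Jack-knife ties go to the earliest index in
the documented order (tai_default, stai_dcbs, stai_rcbs) and are logged.
Weight files are JSON with explicit mode/domain tags and round-trip
exactly.

## Known limitations

* The inferred weights are those that best reproduce the DCBS ranking,
  not consistent estimates of biophysical constraints: with between-gene
  amino-acid composition variation the optimum is systematically offset,
  and the objective's flatness leaves individual keys with sampling
  uncertainty of ~0.1–0.2 at a thousand genes.  Interpret single weights
  cautiously; ensembles (domain means, clusters) are more stable.
* The exclusion screen is not a valid null filter for synonymous-
  randomized genomes (see above).
* tGCN is a crude proxy for tRNA abundance; modification states other
  than inosine at position 34 and lysidine/agmatidine are not modelled.
* Only the standard genetic code is supported.
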