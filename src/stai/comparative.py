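"""Cross-organism analysis of inferred weight vectors.

Organism weight vectors are clustered into three groups with k-means and
compared against the domain-of-life partition (eukarya / bacteria /
archaea); a PCA projection is provided for inspection, and an empirical
significance test re-infers weights on synonymous-randomized genomes to ask
whether the domain structure could arise without gene-level codon bias.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .core import Genome, TrnaPool, WeightSet, WOBBLE_KEYS, LYSIDINE_KEY
from .optimizer import OptimizerConfig, optimize_weights
from .simulate import synonymous_randomize

#: keys shared by all three domains
SHARED_KEYS = WOBBLE_KEYS


@dataclass
class WeightMatrix:
    """Per-organism wobble weight vectors over a shared key set."""

    organisms: List[str]
    domains: List[str]
    keys: Tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, k = self.matrix.shape
        if len(self.organisms) != n or len(self.domains) != n:
            raise ValueError("organism/domain labels do not match matrix")
        if len(self.keys) != k:
            raise ValueError("key labels do not match matrix width")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class ClusterReport:
    assignments: np.ndarray
    mapping: Dict[int, str]
    per_domain_correct: Dict[str, float]
    total_correct: float
    inertia: float
    degenerate: bool = False


@dataclass
class PCAResult:
    coordinates: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


@dataclass
class SignificanceResult:
    original: ClusterReport
    randomized_accuracies: List[float]
    p_value: float
    reports: List[ClusterReport] = field(repr=False, default_factory=list)


def build_weight_matrix(
    results: Sequence[Tuple[str, str, WeightSet]],
    key_policy: str = "shared",
    impute: str = "mean",
) -> WeightMatrix:
    """Assemble per-organism weight vectors into a matrix.

    key_policy="shared" keeps the four wobble keys common to all domains;
    "padded" adds the prokaryote-only lysidine key, imputing it for eukarya
    (impute="mean": mean of the prokaryotic values).
    """
    if not results:
        raise ValueError("no weight sets given")
    if len(results) < 2:
        raise ValueError("need at least 2 organisms")
    organisms = [r[0] for r in results]
    domains = [r[1] for r in results]
    sets = [r[2] for r in results]
    if key_policy == "shared":
        keys = SHARED_KEYS
        rows = [[ws.s[k] for k in keys] for ws in sets]
    elif key_policy == "padded":
        keys = SHARED_KEYS + (LYSIDINE_KEY,)
        prok = [ws.s[LYSIDINE_KEY] for ws in sets if LYSIDINE_KEY in ws.s]
        if impute == "mean":
            if not prok:
                raise ValueError("padded policy needs >= 1 prokaryote")
            fill = float(np.mean(prok))
        else:
            raise ValueError(f"unknown impute policy {impute!r}")
        rows = [
            [ws.s[k] for k in SHARED_KEYS]
            + [ws.s.get(LYSIDINE_KEY, fill)]
            for ws in sets
        ]
    else:
        raise ValueError(f"unknown key policy {key_policy!r}")
    return WeightMatrix(
        organisms=organisms, domains=domains, keys=tuple(keys),
        matrix=np.array(rows, dtype=float),
    )


def _best_bijection(
    assignments: np.ndarray, domains: Sequence[str], k: int
) -> Tuple[Dict[int, str], Dict[str, float], float]:
    """Cluster->domain mapping maximizing the total correct fraction."""
    labels = sorted(set(domains))
    domains = np.asarray(domains)
    best = None
    for perm in itertools.permutations(range(k), len(labels)):
        mapping = {cluster: label
                   for label, cluster in zip(labels, perm)}
        correct = sum(
            mapping.get(c) == d for c, d in zip(assignments, domains)
        )
        if best is None or correct > best[0]:
            best = (correct, mapping)
    correct, mapping = best
    per_domain = {}
    for label in labels:
        mask = domains == label
        matched = sum(
            mapping.get(c) == label for c in assignments[mask]
        )
        per_domain[label] = matched / mask.sum()
    return mapping, per_domain, correct / len(domains)


def kmeans_domains(
    wm: WeightMatrix,
    k: int = 3,
    rng: Optional[np.random.Generator] = None,
    n_restarts: int = 50,
) -> ClusterReport:
    """Cluster organisms with k-means and score agreement with domains.

    Lloyd's algorithm with ``n_restarts`` seeded restarts (best
    within-cluster sum of squares kept); the cluster->domain mapping is the
    bijection maximizing the total correct fraction.
    """
    n = wm.matrix.shape[0]
    if n < k:
        raise ValueError(f"need at least {k} organisms, got {n}")
    rng = rng if rng is not None else np.random.default_rng()
    seed = int(rng.integers(2 ** 31))
    degenerate = False
    spread = np.linalg.norm(wm.matrix - wm.matrix.mean(axis=0), axis=1)
    if spread.max() < 1e-6 or len({tuple(r) for r in wm.matrix.round(12)}) < k:
        degenerate = True
    km = KMeans(
        n_clusters=k, n_init=n_restarts, algorithm="lloyd",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # duplicate-point init warnings
        assignments = km.fit_predict(wm.matrix)
    mapping, per_domain, total = _best_bijection(assignments, wm.domains, k)
    return ClusterReport(
        assignments=assignments,
        mapping=mapping,
        per_domain_correct=per_domain,
        total_correct=total,
        inertia=float(km.inertia_),
        degenerate=degenerate,
    )


def pca_project(wm: WeightMatrix, n_components: int = 3) -> PCAResult:
    """Mean-centered PCA of the weight matrix.

    Components are ordered by decreasing variance, each signed so its
    largest-magnitude loading is positive; requesting more components than
    the matrix rank truncates with a warning.
    """
    X = wm.matrix - wm.matrix.mean(axis=0)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 organisms")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(S > tol))
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; "
            "truncating", stacklevel=2,
        )
        n_components = rank
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    explained = S ** 2 / (n - 1)
    total_var = float(np.sum(np.var(wm.matrix, axis=0, ddof=1)))
    ratio = explained / total_var if total_var > 0 else explained * 0.0
    return PCAResult(
        coordinates=U * S,
        components=Vt,
        explained_variance=explained,
        explained_variance_ratio=ratio,
    )


def infer_weight_matrix(
    genomes: Sequence[Genome],
    pools: Sequence[TrnaPool],
    cfg: Optional[OptimizerConfig] = None,
    rng: Optional[np.random.Generator] = None,
    key_policy: str = "shared",
) -> WeightMatrix:
    """Optimize weights per genome and assemble the weight matrix."""
    cfg = cfg or OptimizerConfig()
    rng = rng if rng is not None else np.random.default_rng()
    results = []
    for genome, pool in zip(genomes, pools):
        run_cfg = OptimizerConfig(
            step_init=cfg.step_init, step_final=cfg.step_final,
            step_factor=cfg.step_factor,
            n_random_extra_starts=cfg.n_random_extra_starts,
            max_stale_iters_per_step=cfg.max_stale_iters_per_step,
            seed=int(rng.integers(2 ** 31)), objective=cfg.objective,
        )
        res = optimize_weights(genome, pool, cfg=run_cfg)
        results.append((genome.organism_id, genome.domain, res.best_weights))
    return build_weight_matrix(results, key_policy=key_policy)


def clustering_significance(
    genomes: Sequence[Genome],
    pools: Sequence[TrnaPool],
    cfg: Optional[OptimizerConfig] = None,
    n_randomizations: int = 20,
    rng: Optional[np.random.Generator] = None,
    k: int = 3,
    n_restarts: int = 50,
    key_policy: str = "shared",
) -> SignificanceResult:
    """Empirical significance of the domain clustering.

    For each randomization, every genome is replaced by its
    synonymous-randomized counterpart, weights are re-inferred, and the
    matrix is re-clustered; p is the fraction of randomizations whose total
    correct fraction is >= the original one.
    """
    if len(genomes) != len(pools):
        raise ValueError("genomes and pools must be matched")
    rng = rng if rng is not None else np.random.default_rng()
    wm = infer_weight_matrix(genomes, pools, cfg, rng, key_policy)
    original = kmeans_domains(wm, k=k, rng=rng, n_restarts=n_restarts)
    accuracies: List[float] = []
    reports: List[ClusterReport] = []
    for _ in range(n_randomizations):
        rand_genomes = [synonymous_randomize(g, rng) for g in genomes]
        rand_wm = infer_weight_matrix(
            rand_genomes, pools, cfg, rng, key_policy
        )
        report = kmeans_domains(rand_wm, k=k, rng=rng, n_restarts=n_restarts)
        accuracies.append(report.total_correct)
        reports.append(report)
    p = float(np.mean([a >= original.total_correct for a in accuracies])) \
        if accuracies else float("nan")
    return SignificanceResult(
        original=original,
        randomized_accuracies=accuracies,
        p_value=p,
        reports=reports,
    )
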