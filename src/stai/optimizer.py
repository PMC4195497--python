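"""Inference of species-specific wobble weights by multi-start hill climbing.

The objective is the Spearman rank correlation, over genes, between the
gene-level adaptation score (tAI under candidate weights) and a per-gene
target: a codon-usage-bias score (DCBS by default, RCBS optionally) or, in
abundance mode, measured protein abundance.

The search is a stochastic hill climb with a shrinking step: at each
iteration a random non-empty subset of the free weights is perturbed by
+/- step; the move is kept only if the objective strictly increases.  After
``max_stale_iters_per_step`` consecutive rejections the step is divided by
``step_factor``; the climb stops when the step falls below ``step_final``.
The multi-start set combines the classical tAI weights, the all-zero and
all-one extremes, every half-region combination (each of the free weights at
0.25 or 0.75), and optional uniform-random extras.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .adaptiveness import (
    adaptiveness_table,
    default_weight_set,
    genome_tai,
    recognizing_anticodons,
    uniform_weight_set,
)
from .core import (
    AbundanceTable,
    Genome,
    TrnaPool,
    WeightSet,
    free_keys,
    required_keys,
)
from .cub import genome_cub
from .genetic_code import SENSE_CODONS

logger = logging.getLogger("stai")

OBJECTIVES = ("dcbs", "rcbs", "abundance")


@dataclass
class OptimizerConfig:
    """Tunable parameters of the multi-start hill climb."""

    step_init: float = 0.3
    step_final: float = 0.001
    step_factor: float = 1.35
    n_random_extra_starts: int = 0
    max_stale_iters_per_step: int = 50
    seed: Optional[int] = None
    objective: str = "dcbs"

    def __post_init__(self) -> None:
        if not (self.step_init > self.step_final > 0):
            raise ValueError("need step_init > step_final > 0")
        if self.step_factor <= 1:
            raise ValueError("step_factor must be > 1")
        if self.max_stale_iters_per_step < 1:
            raise ValueError("max_stale_iters_per_step must be >= 1")
        if self.n_random_extra_starts < 0:
            raise ValueError("n_random_extra_starts must be >= 0")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class OptimizationResult:
    """Outcome of one multi-start optimization."""

    best_weights: WeightSet
    best_objective: float
    per_start: List[Tuple[str, float]]
    trace: Dict[str, List[float]] = field(repr=False)
    seed: Optional[int] = None


@dataclass
class ExclusionDecision:
    """Pre-optimization screen: does the CUB/tRNA-adaptation link hold?"""

    include: bool
    rho: float
    p_value: float
    reason: str


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with midranks for ties.

    Raises if either vector is constant (ranks carry no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("Spearman correlation undefined for constant vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def interaction_matrix(
    pool: TrnaPool, domain: str, mode: str
) -> Tuple[np.ndarray, Tuple[str, ...]]:
    """(61, n_keys) matrix A with A[i, k] = summed tGCN of the anticodons
    reading sense codon i through pairing key k, so W = A @ (1 - s)."""
    keys = required_keys(domain, mode)
    key_index = {k: j for j, k in enumerate(keys)}
    A = np.zeros((len(SENSE_CODONS), len(keys)))
    for i, codon in enumerate(SENSE_CODONS):
        for anticodon, key in recognizing_anticodons(codon, domain, mode):
            A[i, key_index[key]] += pool.count(anticodon)
    return A, keys


class _FastObjective:
    """Vectorized objective evaluation for one (genome, pool, target).

    Precomputes the gene x codon count matrix, the pairing matrix A and the
    midranks of the target so that each candidate weight vector costs one
    small matrix-vector product plus one ranking.
    """

    def __init__(
        self,
        genome: Genome,
        pool: TrnaPool,
        domain: str,
        mode: str,
        target: np.ndarray,
        gene_ids: Optional[Sequence[str]] = None,
    ) -> None:
        if gene_ids is not None:
            genome = genome.subset(gene_ids)
        self.counts = genome.sense_counts_matrix().astype(float)
        self.L = self.counts.sum(axis=1)
        self.A, self.keys = interaction_matrix(pool, domain, mode)
        # codons the pool can decode at all; candidates that drive the
        # weight of such a codon to exactly 0 (all its readers at s=1) are
        # inadmissible -- a translatable codon cannot lose every decoder,
        # and the zero-replacement fallback would otherwise create a
        # spurious objective discontinuity at the boundary.
        self._decodable = self.A.sum(axis=1) > 0
        target = np.asarray(target, dtype=float)
        if target.shape[0] != self.counts.shape[0]:
            raise ValueError("target length does not match gene count")
        self.target_ranks = stats.rankdata(target)
        tr = self.target_ranks - self.target_ranks.mean()
        if np.ptp(self.target_ranks) == 0:
            raise ValueError("objective target is constant across genes")
        self._tr = tr
        self._tr_norm = np.sqrt(tr @ tr)
        self.free = free_keys(domain, mode)
        self._free_idx = np.array(
            [self.keys.index(k) for k in self.free], dtype=np.intp
        )
        base = np.zeros(len(self.keys))
        self._base = base

    def stai_scores(self, s_full: np.ndarray) -> np.ndarray:
        W = self.A @ (1.0 - s_full)
        wmax = W.max()
        if wmax <= 0:
            raise FloatingPointError("all adaptiveness values are 0")
        if np.any((W <= 0) & self._decodable):
            raise FloatingPointError("candidate leaves a decodable codon "
                                     "with no reader")
        w = W / wmax
        nz = w > 0
        if not nz.all():
            w[~nz] = np.exp(np.mean(np.log(w[nz])))
        return np.exp(self.counts @ np.log(w) / self.L)

    def value(self, ws: WeightSet) -> float:
        """Objective for a candidate weight set; -inf when undefined."""
        s_full = np.array([ws.s[k] for k in self.keys])
        return self._value_full(s_full)

    def value_vec(self, free_values: np.ndarray) -> float:
        """Objective for a free-key value vector (fast path)."""
        s_full = self._base.copy()
        s_full[self._free_idx] = free_values
        return self._value_full(s_full)

    def _value_full(self, s_full: np.ndarray) -> float:
        try:
            scores = self.stai_scores(s_full)
        except FloatingPointError:
            return -np.inf
        r = stats.rankdata(scores)
        if np.ptp(r) == 0:
            return -np.inf
        r = r - r.mean()
        return float(r @ self._tr / (np.sqrt(r @ r) * self._tr_norm))


def _resolve_target(
    genome: Genome,
    objective_kind: str,
    abundance: Optional[AbundanceTable],
) -> Tuple[np.ndarray, Optional[List[str]]]:
    """Per-gene target vector and, for abundance, the covered gene ids."""
    if objective_kind in ("dcbs", "rcbs"):
        return genome_cub(genome, objective_kind), None
    if objective_kind == "abundance":
        if abundance is None:
            raise ValueError("abundance objective requires an AbundanceTable")
        ids = abundance.covered_ids(genome)
        if len(ids) < 3:
            raise ValueError(
                "fewer than 3 genes shared between genome and abundance table"
            )
        return abundance.vector_for(ids), ids
    raise ValueError(f"unknown objective {objective_kind!r}")


def objective_value(
    genome: Genome,
    pool: TrnaPool,
    ws: WeightSet,
    objective_kind: str = "dcbs",
    abundance: Optional[AbundanceTable] = None,
) -> float:
    """Spearman correlation between per-gene tAI (under ws) and the target."""
    if len(genome) < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    target, ids = _resolve_target(genome, objective_kind, abundance)
    scored = genome if ids is None else genome.subset(ids)
    scores = genome_tai(scored, adaptiveness_table(pool, ws))
    return spearman(scores, target)


def generate_starting_points(
    domain: str,
    mode: str = "standard",
    n_random_extra: int = 0,
    rng: Optional[np.random.Generator] = None,
    base: Optional[WeightSet] = None,
) -> List[WeightSet]:
    """The multi-start set for the hill climb.

    standard mode: the classical tAI defaults, all-zeros, all-ones, and every
    half-region combination (each free weight at the midpoint 0.25 or 0.75 of
    its half of [0, 1]), plus ``n_random_extra`` uniform-random vectors --
    19 starts for eukarya, 35 for prokaryotes, before extras.

    all_pairings mode: a single start with every non-WC key at 0.5.

    free_wc mode: a single start copying ``base`` (the best standard-mode
    weights) with the WC keys released at 0.
    """
    if n_random_extra and rng is None:
        raise ValueError("random extra starts require an rng")
    starts: List[WeightSet]
    if mode == "standard":
        starts = [
            default_weight_set(domain),
            uniform_weight_set(domain, mode, 0.0),
            uniform_weight_set(domain, mode, 1.0),
        ]
        k = len(free_keys(domain, mode))
        for combo in itertools.product((0.25, 0.75), repeat=k):
            starts.append(uniform_weight_set(domain, mode, 0.0)
                          .with_free_values(combo))
    elif mode == "all_pairings":
        starts = [uniform_weight_set(domain, mode, 0.5)]
    elif mode == "free_wc":
        if base is None:
            raise ValueError(
                "free_wc starting points require the best standard-mode "
                "weights as base"
            )
        s = {k: 0.0 for k in required_keys(domain, "free_wc")}
        for k in base.s:
            s[k] = base.s[k]
        starts = [WeightSet(mode="free_wc", domain=domain, s=s)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    template = starts[0]
    for _ in range(n_random_extra):
        values = rng.uniform(0.0, 1.0, size=len(template.free_keys()))
        starts.append(template.with_free_values(values))
    return starts


def start_labels(
    mode: str, n_grid: int, n_random_extra: int
) -> List[str]:
    """Human-readable labels matching generate_starting_points order."""
    if mode == "standard":
        labels = ["tai_default", "all_zero", "all_one"]
        labels += [f"grid_{i:02d}" for i in range(n_grid)]
    elif mode == "all_pairings":
        labels = ["all_half"]
    else:
        labels = ["from_standard_best"]
    labels += [f"random_{i}" for i in range(n_random_extra)]
    return labels


def _hill_climb_vec(
    eval_vec: Callable[[np.ndarray], float],
    start_vec: np.ndarray,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, float, List[float]]:
    """Core climb on a free-value vector (see :func:`hill_climb`)."""
    k = start_vec.size
    cur_vec = np.asarray(start_vec, dtype=float).copy()
    cur_val = eval_vec(cur_vec)
    if not np.isfinite(cur_val):
        cur_val = -np.inf
    trace: List[float] = [cur_val] if np.isfinite(cur_val) else []
    step = cfg.step_init
    while step >= cfg.step_final:
        stale = 0
        while stale < cfg.max_stale_iters_per_step:
            mask = rng.random(k) < 0.5
            while not mask.any():
                mask = rng.random(k) < 0.5
            directions = rng.integers(0, 2, size=k) * 2 - 1
            cand_vec = cur_vec.copy()
            cand_vec[mask] = np.clip(
                cand_vec[mask] + directions[mask] * step, 0.0, 1.0
            )
            if np.array_equal(cand_vec, cur_vec):
                stale += 1
                continue
            val = eval_vec(cand_vec)
            if np.isfinite(val) and val > cur_val:
                cur_vec, cur_val = cand_vec, val
                trace.append(val)
                stale = 0
            else:
                stale += 1
        step /= cfg.step_factor
    return cur_vec, cur_val, trace


def hill_climb(
    eval_fn: Callable[[WeightSet], float],
    start: WeightSet,
    cfg: Optional[OptimizerConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[WeightSet, float, List[float]]:
    """Variable-step stochastic hill climb from one starting weight set.

    At each iteration a random non-empty subset of the free keys is moved by
    +/- step (clamped to [0, 1]); the move is kept only on strict objective
    improvement; after ``max_stale_iters_per_step`` consecutive rejections
    the step shrinks by ``step_factor`` until it falls below ``step_final``.
    Returns (best weights, best objective, trace of accepted objective
    values); the trace is non-decreasing.
    """
    cfg = cfg or OptimizerConfig()
    rng = rng if rng is not None else np.random.default_rng()

    def eval_vec(vec: np.ndarray) -> float:
        return eval_fn(start.with_free_values(vec))

    best_vec, best_val, trace = _hill_climb_vec(
        eval_vec, start.free_values(), cfg, rng
    )
    return start.with_free_values(best_vec), best_val, trace


def exclusion_check(
    genome: Genome,
    pool: TrnaPool,
    domain: Optional[str] = None,
    alpha: float = 0.05,
    objective_kind: str = "dcbs",
) -> ExclusionDecision:
    """Screen a genome before optimization.

    An organism is included only when the Spearman correlation between tAI
    under the classical default weights and its codon usage bias is positive
    and significant at ``alpha`` (two-sided p from the t approximation);
    otherwise the assumptions linking CUB to tRNA adaptation do not hold and
    weight inference is not meaningful.
    """
    domain = domain or genome.domain
    target, _ = _resolve_target(genome, objective_kind, None)
    table = adaptiveness_table(pool, default_weight_set(domain))
    scores = genome_tai(genome, table)
    if np.ptp(scores) == 0 or np.ptp(target) == 0:
        return ExclusionDecision(
            False, float("nan"), float("nan"), "undefined correlation"
        )
    res = stats.spearmanr(scores, target)
    rho, p = float(res.statistic), float(res.pvalue)
    if rho > 0 and p < alpha:
        return ExclusionDecision(True, rho, p, "significant positive")
    if rho > 0:
        reason = "insignificant positive"
    elif p < alpha:
        reason = "significant negative"
    else:
        reason = "insignificant negative"
    return ExclusionDecision(False, rho, p, reason)


class ExclusionError(RuntimeError):
    """Raised when a genome fails the pre-optimization screen."""


def optimize_weights(
    genome: Genome,
    pool: TrnaPool,
    domain: Optional[str] = None,
    mode: str = "standard",
    cfg: Optional[OptimizerConfig] = None,
    abundance: Optional[AbundanceTable] = None,
    check_exclusion: bool = False,
) -> OptimizationResult:
    """Infer a species-specific weight set for one genome.

    Thin functional wrapper over :class:`stai.estimator.StaiEstimator`.
    """
    from .estimator import StaiEstimator

    cfg = cfg or OptimizerConfig()
    est = StaiEstimator(
        trna_pool=pool,
        domain=domain or genome.domain,
        mode=mode,
        objective=cfg.objective,
        step_init=cfg.step_init,
        step_final=cfg.step_final,
        step_factor=cfg.step_factor,
        max_stale_iters_per_step=cfg.max_stale_iters_per_step,
        n_random_starts=cfg.n_random_extra_starts,
        check_exclusion=check_exclusion,
        random_state=cfg.seed,
    )
    est.fit(genome, abundance)
    return est.result_
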