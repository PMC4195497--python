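"""Inferential procedures built on the weight-inference machinery.

* an empirical permutation test for comparing mean weights between two
  groups of organisms (distance = |mean_A - mean_B| / (sd_A + sd_B));
* a jack-knife comparison of adaptation indices against protein abundance
  (which index wins most 50% subsamples?);
* similarity of two matched collections of weight vectors (Spearman and
  Euclidean, with permutation p-values).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .adaptiveness import adaptiveness_table, default_weight_set, genome_tai
from .core import AbundanceTable, Genome, TrnaPool, WeightSet, wobble_keys
from .optimizer import OptimizerConfig, optimize_weights, spearman

logger = logging.getLogger("stai")

#: Fixed index order; earliest wins jack-knife ties.
JACKKNIFE_INDICES = ("tai_default", "stai_dcbs", "stai_rcbs")


@dataclass
class PermutationResult:
    observed_distance: float
    n_permutations: int
    p_value: float


@dataclass
class JackknifeResult:
    wins: Dict[str, int]
    rounds: int
    subsample_fraction: float
    winners: List[str] = field(repr=False, default_factory=list)


@dataclass
class SimilarityResult:
    spearman: float
    euclidean: float
    p_spearman: float
    p_euclidean: float
    n_points: int


def _group_distance(a: np.ndarray, b: np.ndarray) -> float:
    """|mean_A - mean_B| / (sd_A + sd_B); 0/0 -> 0, x/0 -> inf."""
    num = abs(a.mean() - b.mean())
    den = a.std(ddof=1) + b.std(ddof=1)
    if den == 0.0:
        return 0.0 if num == 0.0 else np.inf
    return float(num / den)


def permutation_test_means(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Empirical test for a difference between two group means.

    The p-value is the fraction of random relabelings whose distance is
    greater than or equal to the observed one.
    """
    rng = rng if rng is not None else np.random.default_rng()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    observed = _group_distance(a, b)
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _group_distance(perm[: a.size], perm[a.size:]) >= observed:
            count += 1
    return PermutationResult(
        observed_distance=observed,
        n_permutations=n_perm,
        p_value=count / n_perm,
    )


def jackknife_compare(
    genome: Genome,
    pool: TrnaPool,
    abundance: AbundanceTable,
    indices: Sequence[str] = JACKKNIFE_INDICES,
    rounds: int = 100,
    frac: float = 0.5,
    cfg: Optional[OptimizerConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> JackknifeResult:
    """Which adaptation index best predicts protein abundance?

    Per round: subsample ``frac`` of the abundance-covered genes, re-run the
    weight optimization on the subsample for each stAI variant, correlate
    every index with abundance on the subsample, and count the winner.  Ties
    go to the earliest index in ``indices`` (and are logged).
    """
    rng = rng if rng is not None else np.random.default_rng()
    unknown = [i for i in indices if i not in JACKKNIFE_INDICES]
    if unknown:
        raise ValueError(f"unknown indices {unknown}")
    cfg = cfg or OptimizerConfig()
    covered = abundance.covered_ids(genome)
    n_sub = max(3, int(round(frac * len(covered))))
    if n_sub > len(covered):
        raise ValueError("not enough abundance-covered genes to subsample")

    default_table = adaptiveness_table(
        pool, default_weight_set(genome.domain)
    )
    wins = {i: 0 for i in indices}
    winners: List[str] = []
    for r in range(rounds):
        sample_ids = [
            covered[i]
            for i in rng.choice(len(covered), size=n_sub, replace=False)
        ]
        sub = genome.subset(sample_ids)
        pa = abundance.vector_for(sub.gene_ids)
        corrs = {}
        for index in indices:
            if index == "tai_default":
                scores = genome_tai(sub, default_table)
            else:
                objective = "dcbs" if index == "stai_dcbs" else "rcbs"
                sub_cfg = OptimizerConfig(
                    step_init=cfg.step_init,
                    step_final=cfg.step_final,
                    step_factor=cfg.step_factor,
                    n_random_extra_starts=cfg.n_random_extra_starts,
                    max_stale_iters_per_step=cfg.max_stale_iters_per_step,
                    seed=int(rng.integers(2 ** 31)),
                    objective=objective,
                )
                res = optimize_weights(sub, pool, cfg=sub_cfg)
                scores = genome_tai(
                    sub, adaptiveness_table(pool, res.best_weights)
                )
            corrs[index] = spearman(scores, pa)
        best = max(corrs.values())
        tied = [i for i in indices if corrs[i] == best]
        if len(tied) > 1:
            logger.info("jackknife round %d: tie between %s", r, tied)
        winner = tied[0]
        wins[winner] += 1
        winners.append(winner)
    return JackknifeResult(
        wins=wins, rounds=rounds, subsample_fraction=frac, winners=winners
    )


def concatenate_wobble_vectors(sets: Sequence[WeightSet]) -> np.ndarray:
    """Concatenate per-organism wobble weights (domain key order)."""
    parts = [
        [ws.s[k] for k in wobble_keys(ws.domain)] for ws in sets
    ]
    return np.array([v for part in parts for v in part], dtype=float)


def weight_vector_similarity(
    sets_a: Sequence[WeightSet],
    sets_b: Sequence[WeightSet],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> SimilarityResult:
    """Similarity between two matched collections of weight sets.

    Organisms must be matched position by position (same domain, hence the
    same wobble keys).  The wobble entries are concatenated into one vector
    per collection; Spearman correlation and Euclidean distance are compared
    against shuffles of the second vector (p_spearman: fraction of shuffles
    with correlation >= observed; p_euclidean: fraction with distance <=
    observed).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if len(sets_a) != len(sets_b):
        raise ValueError("collections must have equal length")
    for wa, wb in zip(sets_a, sets_b):
        if wa.domain != wb.domain:
            raise ValueError("matched organisms must share a domain")
    va = concatenate_wobble_vectors(sets_a)
    vb = concatenate_wobble_vectors(sets_b)
    rho = spearman(va, vb)
    dist = float(np.linalg.norm(va - vb))
    ge_rho = 0
    le_dist = 0
    for _ in range(n_perm):
        perm = rng.permutation(vb)
        if spearman(va, perm) >= rho:
            ge_rho += 1
        if np.linalg.norm(va - perm) <= dist:
            le_dist += 1
    return SimilarityResult(
        spearman=rho,
        euclidean=dist,
        p_spearman=ge_rho / n_perm,
        p_euclidean=le_dist / n_perm,
        n_points=va.size,
    )
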