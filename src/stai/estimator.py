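"""Scikit-learn-style estimator for species-specific tAI weights.

``StaiEstimator.fit`` runs the multi-start hill climb on a genome;
``transform`` then scores genes (geometric-mean adaptiveness under the
fitted weights), so the estimator drops into sklearn pipelines and model
selection.  X is a :class:`~stai.core.Genome`; y is an optional
:class:`~stai.core.AbundanceTable` (required for objective="abundance").
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .adaptiveness import adaptiveness_table, genome_tai
from .core import AbundanceTable, Genome, TrnaPool
from .optimizer import (
    ExclusionError,
    OptimizationResult,
    OptimizerConfig,
    _FastObjective,
    _resolve_target,
    exclusion_check,
    generate_starting_points,
    spearman,
    start_labels,
)


class StaiEstimator(BaseEstimator, TransformerMixin):
    """Infer organism-specific wobble constraint weights from codon usage.

    Parameters
    ----------
    trna_pool:
        tRNA gene copy numbers of the organism (required at fit time).
    domain:
        "eukarya", "bacteria" or "archaea"; fixes the number of free wobble
        weights (4 / 5) and the AUA reading rule.
    mode:
        "standard" (classical wobble rules), "all_pairings" (adds the eight
        non-standard pairings, all initialized at 0.5) or "free_wc" (releases
        the four Watson-Crick weights, starting from the best standard fit).
    objective:
        "dcbs" (default), "rcbs" or "abundance" -- the per-gene target whose
        Spearman correlation with the gene scores is maximized.
    step_init, step_final, step_factor, max_stale_iters_per_step:
        hill-climb schedule: the perturbation step starts at ``step_init``
        and is divided by ``step_factor`` after ``max_stale_iters_per_step``
        consecutive rejected moves, until it falls below ``step_final``.
    n_random_starts:
        uniform-random starting points added to the deterministic set.
    check_exclusion:
        when True, raise :class:`~stai.optimizer.ExclusionError` if the
        genome fails the pre-optimization screen (no significant positive
        correlation between default-weight scores and codon usage bias).
    random_state:
        seed for every source of randomness in the fit.

    Attributes
    ----------
    weights_ : WeightSet
        The best weight set found.
    objective_ : float
        Its objective value (Spearman correlation).
    result_ : OptimizationResult
        Per-start outcomes, traces and the seed.
    adaptiveness_ : AdaptivenessTable
        Codon adaptiveness under the fitted weights.
    n_genes_ : int
        Number of genes the objective was computed on.
    """

    def __init__(
        self,
        trna_pool: Optional[TrnaPool] = None,
        domain: str = "eukarya",
        mode: str = "standard",
        objective: str = "dcbs",
        step_init: float = 0.3,
        step_final: float = 0.001,
        step_factor: float = 1.35,
        max_stale_iters_per_step: int = 50,
        n_random_starts: int = 0,
        check_exclusion: bool = False,
        exclusion_alpha: float = 0.05,
        random_state: Optional[int] = None,
    ) -> None:
        self.trna_pool = trna_pool
        self.domain = domain
        self.mode = mode
        self.objective = objective
        self.step_init = step_init
        self.step_final = step_final
        self.step_factor = step_factor
        self.max_stale_iters_per_step = max_stale_iters_per_step
        self.n_random_starts = n_random_starts
        self.check_exclusion = check_exclusion
        self.exclusion_alpha = exclusion_alpha
        self.random_state = random_state

    def _config(self) -> OptimizerConfig:
        return OptimizerConfig(
            step_init=self.step_init,
            step_final=self.step_final,
            step_factor=self.step_factor,
            n_random_extra_starts=self.n_random_starts,
            max_stale_iters_per_step=self.max_stale_iters_per_step,
            seed=self.random_state,
            objective=self.objective,
        )

    def fit(self, X: Genome, y: Optional[AbundanceTable] = None):
        """Run the multi-start hill climb on genome ``X``."""
        genome = self._validate_genome(X)
        if self.trna_pool is None:
            raise ValueError("trna_pool is required to fit")
        cfg = self._config()
        domain = self.domain

        if self.check_exclusion and self.objective != "abundance":
            decision = exclusion_check(
                genome, self.trna_pool, domain,
                alpha=self.exclusion_alpha, objective_kind=self.objective,
            )
            if not decision.include:
                raise ExclusionError(
                    f"genome {genome.organism_id!r} excluded: "
                    f"{decision.reason} correlation "
                    f"(rho={decision.rho:.4f}, p={decision.p_value:.3g})"
                )

        target, ids = _resolve_target(genome, self.objective, y)
        fobj = _FastObjective(
            genome, self.trna_pool, domain, self.mode, target, gene_ids=ids
        )
        self.n_genes_ = fobj.counts.shape[0]

        ss = np.random.SeedSequence(self.random_state)
        rng_starts = np.random.default_rng(ss.spawn(1)[0])

        if self.mode == "free_wc":
            fobj_std = _FastObjective(
                genome, self.trna_pool, domain, "standard", target,
                gene_ids=ids,
            )
            base, per_start, traces = self._run_stage(
                fobj_std, cfg, ss, rng_starts
            )
            fobj_wc = _FastObjective(
                genome, self.trna_pool, domain, "free_wc", target,
                gene_ids=ids,
            )
            starts = generate_starting_points(
                domain, "free_wc", base=base.best_weights
            )
            labels = ["free_wc_refine"]
            best, per2, tr2 = self._climb_all(
                starts, labels, fobj_wc, cfg, ss
            )
            per_start += per2
            traces.update(tr2)
            best_ws = best[0] if best[1] >= base.best_objective \
                else base.best_weights
            result = OptimizationResult(
                best_weights=best_ws,
                best_objective=max(best[1], base.best_objective),
                per_start=per_start,
                trace=traces,
                seed=self.random_state,
            )
        else:
            starts = generate_starting_points(
                domain, self.mode, cfg.n_random_extra_starts, rng_starts
            )
            n_grid = max(0, len(starts) - cfg.n_random_extra_starts - 3) \
                if self.mode == "standard" else 0
            labels = start_labels(
                self.mode, n_grid, cfg.n_random_extra_starts
            )
            best, per_start, traces = self._climb_all(
                starts, labels, fobj, cfg, ss
            )
            result = OptimizationResult(
                best_weights=best[0],
                best_objective=best[1],
                per_start=per_start,
                trace=traces,
                seed=self.random_state,
            )

        self.result_ = result
        self.weights_ = result.best_weights
        self.objective_ = result.best_objective
        self.adaptiveness_ = adaptiveness_table(self.trna_pool, self.weights_)
        return self

    def _run_stage(self, fobj, cfg, ss, rng_starts):
        """Standard-mode stage used as the base of a free_wc fit."""
        starts = generate_starting_points(
            self.domain, "standard", cfg.n_random_extra_starts, rng_starts
        )
        labels = start_labels(
            "standard", len(starts) - cfg.n_random_extra_starts - 3,
            cfg.n_random_extra_starts,
        )
        best, per_start, traces = self._climb_all(
            starts, labels, fobj, cfg, ss
        )
        stage = OptimizationResult(
            best_weights=best[0], best_objective=best[1],
            per_start=per_start, trace=traces, seed=self.random_state,
        )
        return stage, per_start, traces

    def _climb_all(self, starts, labels, fobj, cfg, ss):
        from .optimizer import _hill_climb_vec

        children = ss.spawn(len(starts) + 1)[1:]
        template = starts[0]
        best_vec, best_val = None, -np.inf
        per_start, traces = [], {}
        for label, start, child in zip(labels, starts, children):
            rng = np.random.default_rng(child)
            vec, val, trace = _hill_climb_vec(
                fobj.value_vec, start.free_values(), cfg, rng
            )
            per_start.append((label, val))
            traces[label] = trace
            if val > best_val:
                best_vec, best_val = vec, val
        if best_vec is None or not np.isfinite(best_val):
            raise RuntimeError("objective undefined at every starting point")
        best_ws = template.with_free_values(best_vec)
        return (best_ws, best_val), per_start, traces

    def transform(self, X: Genome) -> np.ndarray:
        """Per-gene stAI scores under the fitted weights."""
        self._check_fitted()
        genome = self._validate_genome(X)
        return genome_tai(genome, self.adaptiveness_)

    def score(self, X: Genome, y: Optional[AbundanceTable] = None) -> float:
        """Spearman correlation between fitted scores and the target on X."""
        self._check_fitted()
        genome = self._validate_genome(X)
        target, ids = _resolve_target(genome, self.objective, y)
        scored = genome if ids is None else genome.subset(ids)
        return spearman(genome_tai(scored, self.adaptiveness_), target)

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise NotFittedError(
                "This StaiEstimator instance is not fitted yet"
            )

    @staticmethod
    def _validate_genome(X) -> Genome:
        if not isinstance(X, Genome):
            raise TypeError(f"X must be a Genome, got {type(X).__name__}")
        if len(X) < 3:
            raise ValueError("need at least 3 genes")
        return X
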