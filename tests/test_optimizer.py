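"""Objective, starting points, hill climb and the exclusion screen."""
import numpy as np
import pytest
from scipy import stats as sps

from stai.adaptiveness import default_weight_set
from stai.cub import genome_cub
from stai.optimizer import (
    ExclusionError,
    OptimizerConfig,
    exclusion_check,
    generate_starting_points,
    hill_climb,
    objective_value,
    optimize_weights,
    spearman,
)
from stai.simulate import (
    SimulationConfig,
    simulate_genome,
    synonymous_randomize,
)


def oracle_spearman(x, y):
    """Midrank Spearman via explicit rank construction + Pearson."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks
    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx)
           * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestSpearman:
    def test_monotone_transforms(self, small_sim, default_weights):
        target = genome_cub(small_sim.genome, "dcbs")
        assert spearman(target, np.exp(target)) == pytest.approx(1.0)
        assert spearman(target, -target) == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))

    def test_oracle_agreement_with_ties(self, rng):
        for _ in range(50):
            x = rng.integers(0, 6, size=20).astype(float)
            y = rng.integers(0, 6, size=20).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(oracle_spearman(x, y),
                                                   abs=1e-12)
            ref = sps.spearmanr(x, y).statistic
            assert spearman(x, y) == pytest.approx(ref, abs=1e-12)


class TestObjectiveValue:
    def test_matches_direct_computation(self, small_sim, default_weights):
        from stai.adaptiveness import adaptiveness_table, genome_tai
        value = objective_value(small_sim.genome, small_sim.pool,
                                default_weights, "dcbs")
        table = adaptiveness_table(small_sim.pool, default_weights)
        expected = spearman(genome_tai(small_sim.genome, table),
                            genome_cub(small_sim.genome, "dcbs"))
        assert value == pytest.approx(expected, abs=1e-12)

    def test_abundance_objective_uses_intersection(self, small_sim,
                                                   default_weights):
        value = objective_value(small_sim.genome, small_sim.pool,
                                default_weights, "abundance",
                                abundance=small_sim.abundance)
        assert -1 <= value <= 1

    def test_abundance_requires_table(self, small_sim, default_weights):
        with pytest.raises(ValueError):
            objective_value(small_sim.genome, small_sim.pool,
                            default_weights, "abundance")


class TestStartingPoints:
    def test_eukarya_standard_count(self):
        starts = generate_starting_points("eukarya")
        assert len(starts) == 19          # 3 named + 2^4 half-region combos

    def test_bacteria_standard_count(self):
        assert len(generate_starting_points("bacteria")) == 35   # 3 + 2^5

    def test_contains_named_starts(self):
        starts = generate_starting_points("eukarya")
        values = [s.free_values().tolist() for s in starts]
        assert starts[0] == default_weight_set("eukarya")
        assert [0.0] * 4 in values and [1.0] * 4 in values
        assert [0.25, 0.75, 0.25, 0.75] in values

    def test_random_extras_deterministic(self):
        s1 = generate_starting_points("eukarya", n_random_extra=3,
                                      rng=np.random.default_rng(5))
        s2 = generate_starting_points("eukarya", n_random_extra=3,
                                      rng=np.random.default_rng(5))
        assert s1 == s2
        assert len(s1) == 22

    def test_all_pairings_single_half_start(self):
        starts = generate_starting_points("eukarya", mode="all_pairings")
        assert len(starts) == 1
        ws = starts[0]
        for key in ws.free_keys():
            assert ws.s[key] == 0.5
        for key in ("I:U", "G:C", "U:A", "C:G"):
            assert ws.s[key] == 0.0

    def test_free_wc_requires_base(self):
        with pytest.raises(ValueError):
            generate_starting_points("eukarya", mode="free_wc")
        base = default_weight_set("eukarya")
        starts = generate_starting_points("eukarya", mode="free_wc",
                                          base=base)
        assert starts[0].mode == "free_wc"
        assert starts[0].s["G:U"] == base.s["G:U"]
        assert starts[0].s["G:C"] == 0.0


class TestHillClimb:
    def test_recovers_1d_concave_optimum(self):
        start = default_weight_set("eukarya").with_free_values([0, 0, 0, 0])

        def f(ws):   # depends on one key only
            return -(ws.s["G:U"] - 0.37) ** 2

        best, val, trace = hill_climb(f, start,
                                      rng=np.random.default_rng(3))
        assert best.s["G:U"] == pytest.approx(0.37, abs=0.002)

    def test_monotone_objective_clamps_at_one(self):
        start = default_weight_set("eukarya").with_free_values([0, 0, 0, 0])
        best, val, _ = hill_climb(lambda ws: sum(ws.s.values()), start,
                                  rng=np.random.default_rng(0))
        assert all(best.s[k] == 1.0 for k in best.free_keys())

    def test_start_at_optimum_stays(self):
        start = default_weight_set("eukarya").with_free_values(
            [0.5, 0.5, 0.5, 0.5])

        def f(ws):
            return -sum((v - 0.5) ** 2 for v in ws.free_values())

        best, val, _ = hill_climb(f, start, rng=np.random.default_rng(1))
        assert best == start and val == 0.0

    def test_trace_monotone_nondecreasing(self):
        start = default_weight_set("eukarya")

        def f(ws):
            return -sum((v - 0.3) ** 2 for v in ws.free_values())

        _, _, trace = hill_climb(f, start, rng=np.random.default_rng(2))
        assert all(b >= a for a, b in zip(trace, trace[1:]))


@pytest.fixture(scope="module")
def opt_sim():
    return simulate_genome(SimulationConfig(n_genes=120, min_len=60,
                                            max_len=120, seed=3))


@pytest.fixture(scope="module")
def fast_cfg():
    return OptimizerConfig(step_final=0.02, max_stale_iters_per_step=10,
                           seed=0)


class TestOptimizeWeights:
    def test_deterministic_given_seed(self, opt_sim, fast_cfg):
        r1 = optimize_weights(opt_sim.genome, opt_sim.pool, cfg=fast_cfg)
        r2 = optimize_weights(opt_sim.genome, opt_sim.pool, cfg=fast_cfg)
        assert r1.best_weights == r2.best_weights
        assert r1.best_objective == r2.best_objective
        assert r1.per_start == r2.per_start

    def test_best_is_max_over_starts_and_traces_monotone(self, opt_sim,
                                                         fast_cfg):
        res = optimize_weights(opt_sim.genome, opt_sim.pool, cfg=fast_cfg)
        finals = [v for _, v in res.per_start]
        assert res.best_objective == max(finals)
        for trace in res.trace.values():
            assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_extra_starts_never_hurt(self, opt_sim):
        base_cfg = OptimizerConfig(step_final=0.05,
                                   max_stale_iters_per_step=8, seed=1)
        more_cfg = OptimizerConfig(step_final=0.05,
                                   max_stale_iters_per_step=8, seed=1,
                                   n_random_extra_starts=4)
        base = optimize_weights(opt_sim.genome, opt_sim.pool, cfg=base_cfg)
        more = optimize_weights(opt_sim.genome, opt_sim.pool, cfg=more_cfg)
        assert more.best_objective >= base.best_objective

    def test_improves_on_default_weights(self, opt_sim, fast_cfg):
        res = optimize_weights(opt_sim.genome, opt_sim.pool, cfg=fast_cfg)
        baseline = objective_value(opt_sim.genome, opt_sim.pool,
                                   default_weight_set("eukarya"), "dcbs")
        assert res.best_objective >= baseline

    def test_free_wc_refines_standard(self, opt_sim, fast_cfg):
        res = optimize_weights(opt_sim.genome, opt_sim.pool,
                               mode="free_wc", cfg=fast_cfg)
        labels = [label for label, _ in res.per_start]
        assert "free_wc_refine" in labels
        standard_best = max(v for label, v in res.per_start
                            if label != "free_wc_refine")
        assert res.best_objective >= standard_best


class TestExclusionCheck:
    def test_biased_genome_included(self, small_sim):
        decision = exclusion_check(small_sim.genome, small_sim.pool)
        assert decision.include
        assert decision.rho > 0 and decision.p_value < 0.05
        assert decision.reason == "significant positive"

    def test_unbiased_genome_excluded(self):
        # no selection (beta=0): codon usage carries no adaptation signal
        sim = simulate_genome(SimulationConfig(n_genes=150, min_len=60,
                                               max_len=120, beta=0.0,
                                               seed=11))
        decision = exclusion_check(sim.genome, sim.pool)
        assert not decision.include
        assert "insignificant" in decision.reason

    def test_randomized_biased_genome_keeps_baseline_coupling(self,
                                                              small_sim):
        # resampling every gene from the biased genome-wide codon
        # distribution leaves a weak positive DCBS/adaptation coupling
        # (genes drifting toward the already-common, high-w codons gain
        # both scores), so the screen is not a reliable null filter here
        rand = synonymous_randomize(small_sim.genome,
                                    np.random.default_rng(4))
        decision = exclusion_check(rand, small_sim.pool)
        assert decision.rho > 0

    def test_anticorrelated_construction_excluded(self, small_sim):
        # screen the biased genome against a pool favouring the codons its
        # highly-expressed genes avoid: adaptation anti-correlates with CUB
        import itertools
        from stai.core import TrnaPool
        from stai.genetic_code import revcomp
        counts = {}
        for b1, b2 in itertools.product("ACGT", repeat=2):
            tail = revcomp(b1 + b2)
            counts["C" + tail] = 8
            counts["T" + tail] = 3
        inverted = TrnaPool(counts=counts)
        decision = exclusion_check(small_sim.genome, inverted)
        assert not decision.include
        assert decision.rho < 0
        assert "negative" in decision.reason

    def test_estimator_raises_on_excluded_genome(self, fast_cfg):
        sim = simulate_genome(SimulationConfig(n_genes=150, min_len=60,
                                               max_len=120, beta=0.0,
                                               seed=11))
        with pytest.raises(ExclusionError):
            optimize_weights(sim.genome, sim.pool, cfg=fast_cfg,
                             check_exclusion=True)
        # override proceeds
        res = optimize_weights(sim.genome, sim.pool, cfg=fast_cfg,
                               check_exclusion=False)
        assert np.isfinite(res.best_objective)
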