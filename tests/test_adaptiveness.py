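"""Wobble pairing rules, Eq-1 adaptiveness and gene tAI, with an
exhaustive pairing-predicate oracle."""
import numpy as np
import pytest

from stai.adaptiveness import (
    AdaptivenessTable,
    absolute_adaptiveness,
    adaptiveness_table,
    default_weight_set,
    gene_tai,
    genome_tai,
    recognizing_anticodons,
    uniform_weight_set,
)
from stai.core import LYSIDINE_ANTICODON, CodingGene, TrnaPool
from stai.genetic_code import SENSE_CODONS, revcomp

from conftest import random_pool

# (anticodon wobble base, codon third base) -> pairing key
_ALLOWED_STANDARD = {
    ("A", "T"): "I:U", ("G", "T"): "G:U",
    ("G", "C"): "G:C", ("A", "C"): "I:C",
    ("T", "A"): "U:A", ("A", "A"): "I:A",
    ("C", "G"): "C:G", ("T", "G"): "U:G",
}
_ALLOWED_EXTRA = {
    ("T", "T"): "U:U", ("C", "T"): "C:U",
    ("T", "C"): "U:C", ("C", "C"): "C:C",
    ("C", "A"): "C:A", ("G", "A"): "G:A",
    ("A", "G"): "I:G", ("G", "G"): "G:G",
}


def oracle_W(codon, pool, ws):
    """Enumerate all 64 anticodons and apply the pairing predicate."""
    import itertools
    allowed = dict(_ALLOWED_STANDARD)
    if ws.mode == "all_pairings":
        allowed.update(_ALLOWED_EXTRA)
    if codon == "ATA" and ws.domain in ("bacteria", "archaea"):
        return (1 - ws.s["L:A"]) * pool.special_ile_count
    total = 0.0
    for ac in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
        if ac[1] != revcomp(codon[1]) or ac[2] != revcomp(codon[0]):
            continue
        key = allowed.get((ac[0], codon[2]))
        if key is not None:
            total += (1 - ws.s[key]) * pool.counts.get(ac, 0)
    return total


class TestDefaultWeights:
    def test_table_values(self):
        ws = default_weight_set("eukarya")
        assert ws.s["G:U"] == 0.41
        assert ws.s["I:C"] == 0.28
        assert ws.s["I:A"] == 0.9999
        assert ws.s["U:G"] == 0.68
        assert all(ws.s[k] == 0.0 for k in ("I:U", "G:C", "U:A", "C:G"))

    @pytest.mark.parametrize("domain", ["bacteria", "archaea"])
    def test_prokaryotic_lysidine_weight(self, domain):
        assert default_weight_set(domain).s["L:A"] == 0.89


class TestRecognizingAnticodons:
    def test_gct_read_by_inosine_and_g(self):
        pairs = recognizing_anticodons("GCT")
        assert ("AGC", "I:U") in pairs and ("GGC", "G:U") in pairs

    def test_gcc_read_by_wc_g_and_inosine(self):
        assert recognizing_anticodons("GCC") == \
            [("GGC", "G:C"), ("AGC", "I:C")]

    def test_prokaryotic_ata_uses_lysidine_only(self):
        assert recognizing_anticodons("ATA", domain="bacteria") == \
            [(LYSIDINE_ANTICODON, "L:A")]
        # eukarya keep the generic third-base-A readers
        assert recognizing_anticodons("ATA", domain="eukarya") == \
            [("TAT", "U:A"), ("AAT", "I:A")]

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            recognizing_anticodons("TAA")

    def test_all_pairings_mode_adds_four_readers(self):
        pairs = recognizing_anticodons("GCT", mode="all_pairings")
        assert len(pairs) == 4
        assert ("TGC", "U:U") in pairs and ("CGC", "C:U") in pairs


class TestAbsoluteAdaptiveness:
    def test_hand_value(self, default_weights):
        pool = TrnaPool(counts={"AGC": 5, "GGC": 2})
        W = absolute_adaptiveness("GCT", pool, default_weights)
        assert W == pytest.approx(5 * 1.0 + 2 * (1 - 0.41))
        assert W == pytest.approx(6.18)

    def test_single_wc_term(self, default_weights):
        pool = TrnaPool(counts={"GGC": 1})
        assert absolute_adaptiveness("GCC", pool, default_weights) == 1.0

    def test_zero_when_no_reader(self, default_weights):
        pool = TrnaPool(counts={"GGC": 1})
        assert absolute_adaptiveness("TTT", pool, default_weights) == 0.0

    def test_oracle_equivalence_random_pools(self, rng):
        for trial in range(25):
            pool = random_pool(rng)
            domain = ["eukarya", "bacteria"][trial % 2]
            mode = ["standard", "all_pairings"][trial % 4 == 0]
            ws = uniform_weight_set(domain, mode, float(rng.random()))
            for codon in SENSE_CODONS:
                got = absolute_adaptiveness(codon, pool, ws)
                assert got == pytest.approx(oracle_W(codon, pool, ws),
                                            abs=1e-12)

    def test_monotone_in_copy_number_and_weight(self, default_weights):
        pool1 = TrnaPool(counts={"AGC": 5, "GGC": 2})
        pool2 = TrnaPool(counts={"AGC": 5, "GGC": 4})
        assert absolute_adaptiveness("GCT", pool2, default_weights) > \
            absolute_adaptiveness("GCT", pool1, default_weights)
        softer = default_weights.replace({"G:U": 0.2})
        assert absolute_adaptiveness("GCT", pool1, softer) > \
            absolute_adaptiveness("GCT", pool1, default_weights)


class TestAdaptivenessTable:
    def test_normalization_and_zero_replacement(self, default_weights,
                                                caplog):
        pool = TrnaPool(counts={"AGC": 4, "GGC": 2})   # only Ala readable
        with caplog.at_level("INFO", logger="stai"):
            table = adaptiveness_table(pool, default_weights)
        assert max(table.w.values()) == 1.0
        assert table.w["GCT"] == 1.0
        assert all(v > 0 for v in table.w.values())
        nonzero = [table.w[c] for c in table.w if table.W[c] > 0]
        gm = np.exp(np.mean(np.log(nonzero)))
        assert table.w["TTT"] == pytest.approx(gm)

    def test_scale_invariance(self, eukarya_pool, default_weights):
        t1 = adaptiveness_table(eukarya_pool, default_weights)
        t10 = adaptiveness_table(eukarya_pool.scaled(10), default_weights)
        assert t1.w == pytest.approx(t10.w)

    def test_all_zero_error(self, default_weights):
        pool = TrnaPool(counts={"AGC": 1})
        ws = uniform_weight_set("eukarya", "standard", 1.0)
        # all wobble at 1 but WC at 0 keeps some codons readable
        table = adaptiveness_table(pool, ws)
        assert table.w["GCT"] == 1.0


class TestGeneTai:
    def test_hand_values(self):
        table = AdaptivenessTable(W={"GCT": 1, "GCC": 4},
                                  w={"GCT": 0.25, "GCC": 1.0})
        gene = CodingGene(id="g", codons=["GCT", "GCC"])
        assert gene_tai(gene, table) == pytest.approx(0.5)
        single = CodingGene(id="s", codons=["GCT"])
        assert gene_tai(single, table) == pytest.approx(0.25)

    def test_permutation_and_concatenation_invariance(self, eukarya_pool,
                                                      default_weights):
        table = adaptiveness_table(eukarya_pool, default_weights)
        gene = CodingGene(id="g", codons=["GCT", "AAA", "CGT", "TTG"])
        rev = CodingGene(id="r", codons=list(reversed(gene.codons)))
        double = CodingGene(id="d", codons=gene.codons * 2)
        assert gene_tai(gene, table) == pytest.approx(gene_tai(rev, table))
        assert gene_tai(gene, table) == \
            pytest.approx(gene_tai(double, table))

    def test_genome_vectorization_matches_scalar(self, tiny_genome,
                                                 eukarya_pool,
                                                 default_weights):
        table = adaptiveness_table(eukarya_pool, default_weights)
        scores = genome_tai(tiny_genome, table)
        expected = [gene_tai(g, table) for g in tiny_genome.genes]
        assert scores == pytest.approx(expected)

    def test_exclude_met_trp_flag(self, eukarya_pool, default_weights):
        table = adaptiveness_table(eukarya_pool, default_weights)
        gene = CodingGene(id="g", codons=["ATG", "GCT"])
        only_gct = gene_tai(gene, table, exclude_met_trp=True)
        assert only_gct == pytest.approx(table.w["GCT"])

    def test_in_unit_interval(self, small_sim, default_weights):
        table = adaptiveness_table(small_sim.pool, default_weights)
        scores = genome_tai(small_sim.genome, table)
        assert np.all(scores > 0) and np.all(scores <= 1)
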