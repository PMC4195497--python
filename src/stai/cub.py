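"""Per-gene codon usage bias scores: RCBS and DCBS.

Both scores compare, within a single gene, each codon's observed frequency
f(x,y,z) against the expectation under positional-base independence
f1(x)*f2(y)*f3(z), where f_k is the base frequency at codon position k in
that gene.  Normalizing by the independence expectation controls for the
gene's base composition (mutational bias), so only codon-level preference is
scored.

RCBS of a codon is d = (obs - exp)/exp, in [-1, inf); the gene score is the
geometric mean of (1 + d) over the gene's L codon positions, minus 1.

DCBS ("directional" codon bias) replaces d with max(obs/exp, exp/obs) >= 1 so
over- and under-represented codons both push the score up; the gene score is
the arithmetic mean of d over the L positions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .core import CodingGene, Genome
from .genetic_code import ALL_CODONS, ALL_CODON_INDEX

# base index of each codon position, aligned with the 64-codon alphabet
_B = "ACGT"
_BIDX = {b: i for i, b in enumerate(_B)}
_POS1 = np.array([_BIDX[c[0]] for c in ALL_CODONS], dtype=np.intp)
_POS2 = np.array([_BIDX[c[1]] for c in ALL_CODONS], dtype=np.intp)
_POS3 = np.array([_BIDX[c[2]] for c in ALL_CODONS], dtype=np.intp)


@dataclass
class PositionalFrequencies:
    """Base frequencies at codon positions 1-3 within one gene."""

    f1: Dict[str, float]
    f2: Dict[str, float]
    f3: Dict[str, float]

    def expected(self, codon: str) -> float:
        """Expected codon frequency under positional independence."""
        x, y, z = codon
        return (
            self.f1.get(x, 0.0) * self.f2.get(y, 0.0) * self.f3.get(z, 0.0)
        )


def _freq_arrays(gene: CodingGene):
    """(codon frequency vector over 64, expected vector over 64, L)."""
    idx = gene.codon_indices()
    L = idx.size
    counts = np.bincount(idx, minlength=64)
    f = counts / L
    f1 = np.bincount(_POS1[idx], minlength=4) / L
    f2 = np.bincount(_POS2[idx], minlength=4) / L
    f3 = np.bincount(_POS3[idx], minlength=4) / L
    expected = f1[_POS1] * f2[_POS2] * f3[_POS3]
    return f, expected, counts, L


def positional_frequencies(gene: CodingGene) -> PositionalFrequencies:
    """Observed base frequencies at the three codon positions of one gene."""
    idx = gene.codon_indices()
    L = idx.size
    maps = []
    for pos in (_POS1, _POS2, _POS3):
        freqs = np.bincount(pos[idx], minlength=4) / L
        maps.append({b: float(freqs[i]) for i, b in enumerate(_B) if freqs[i]})
    return PositionalFrequencies(*maps)


def rcbs_codon(gene: CodingGene, codon: str) -> float:
    """RCBS d_xyz = (observed - expected)/expected for one codon; >= -1."""
    f, expected, _, _ = _freq_arrays(gene)
    i = ALL_CODON_INDEX[codon.upper().replace("U", "T")]
    if expected[i] == 0.0:
        raise ValueError(
            f"codon {codon} has expected frequency 0 in gene {gene.id!r}; "
            "d is undefined"
        )
    return float((f[i] - expected[i]) / expected[i])


def dcb_codon(gene: CodingGene, codon: str) -> float:
    """DCB d_xyz = max(obs/exp, exp/obs) for one codon; >= 1."""
    f, expected, _, _ = _freq_arrays(gene)
    i = ALL_CODON_INDEX[codon.upper().replace("U", "T")]
    if f[i] == 0.0 or expected[i] == 0.0:
        raise ValueError(
            f"codon {codon} absent or expectation 0 in gene {gene.id!r}; "
            "DCB is undefined"
        )
    ratio = f[i] / expected[i]
    return float(max(ratio, 1.0 / ratio))


def rcbs_gene(gene: CodingGene) -> float:
    """Gene RCBS: geometric mean of (1+d) over the L codon positions, - 1.

    Because d is evaluated only at codons present in the gene, 1 + d =
    obs/exp > 0 always holds and the geometric mean is well defined.
    """
    f, expected, counts, L = _freq_arrays(gene)
    present = counts > 0
    ratios = f[present] / expected[present]
    log_mean = float(np.dot(counts[present], np.log(ratios)) / L)
    return float(np.exp(log_mean) - 1.0)


def dcbs_gene(gene: CodingGene) -> float:
    """Gene DCBS: arithmetic mean of d over the L codon positions; >= 1."""
    f, expected, counts, L = _freq_arrays(gene)
    present = counts > 0
    ratios = f[present] / expected[present]
    d = np.maximum(ratios, 1.0 / ratios)
    return float(np.dot(counts[present], d) / L)


def genome_cub(genome: Genome, kind: str = "dcbs") -> np.ndarray:
    """Per-gene CUB scores for a whole genome, in gene order."""
    if kind == "dcbs":
        fn = dcbs_gene
    elif kind == "rcbs":
        fn = rcbs_gene
    else:
        raise ValueError(f"unknown CUB score {kind!r}")
    return np.array([fn(g) for g in genome.genes], dtype=float)
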