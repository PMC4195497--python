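"""Codon-anticodon pairing rules and codon adaptiveness (tAI machinery).

For a sense codon b1 b2 B, the recognizing anticodons are X + rc(b2) + rc(b1)
where X (the anticodon wobble base, tRNA position 34) is allowed by Crick's
rules.  Pairing keys are written anticodon-wobble-base : codon-third-base;
genomic tRNAs with wobble base A are counted as inosine-modified (their gene
copy number feeds the I:* keys).

Absolute adaptiveness of codon i:

    W_i = sum_j (1 - s[key_ij]) * tGCN_j       over recognizing anticodons j

Relative adaptiveness w_i = W_i / max_i W_i; codons left with w = 0 (no
recognizing tRNA gene) take the geometric mean of the non-zero w values so
gene scores stay defined.  The tAI of a gene is the geometric mean of the
w values of its codons.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .core import (
    EXTRA_PAIRING_KEYS,
    LYSIDINE_ANTICODON,
    LYSIDINE_KEY,
    TrnaPool,
    WC_KEYS,
    WeightSet,
    CodingGene,
    Genome,
    is_prokaryote,
    required_keys,
    wobble_keys,
)
from .genetic_code import SENSE_CODONS, SENSE_CODON_INDEX, STOP_CODONS, revcomp

logger = logging.getLogger("stai")

#: Codon third base -> ((anticodon wobble base, pairing key), ...) under the
#: standard wobble rules.  The first entry of each pair is the WC reader.
_STANDARD_PAIRS: Dict[str, Tuple[Tuple[str, str], ...]] = {
    "T": (("A", "I:U"), ("G", "G:U")),
    "C": (("G", "G:C"), ("A", "I:C")),
    "A": (("T", "U:A"), ("A", "I:A")),
    "G": (("C", "C:G"), ("T", "U:G")),
}

#: Additional readers in all_pairings mode (non-standard pairings).
_EXTRA_PAIRS: Dict[str, Tuple[Tuple[str, str], ...]] = {
    "T": (("T", "U:U"), ("C", "C:U")),
    "C": (("T", "U:C"), ("C", "C:C")),
    "A": (("C", "C:A"), ("G", "G:A")),
    "G": (("A", "I:G"), ("G", "G:G")),
}

#: Table 2 wobble defaults (the original tAI weights).
DEFAULT_WOBBLE_WEIGHTS: Dict[str, float] = {
    "G:U": 0.41,
    "I:C": 0.28,
    "I:A": 0.9999,
    "U:G": 0.68,
    LYSIDINE_KEY: 0.89,
}


def default_weight_set(domain: str, mode: str = "standard") -> WeightSet:
    """The original tAI weights: WC keys 0, wobble keys from Table 2.

    In ``all_pairings`` mode the non-standard keys are set to 0.5, their
    initialization value (they have no classical default).
    """
    s = {k: 0.0 for k in WC_KEYS}
    for k in wobble_keys(domain):
        s[k] = DEFAULT_WOBBLE_WEIGHTS[k]
    if mode == "all_pairings":
        for k in EXTRA_PAIRING_KEYS:
            s[k] = 0.5
    return WeightSet(mode=mode, domain=domain, s=s)


def uniform_weight_set(domain: str, mode: str, value: float) -> WeightSet:
    """All free keys at ``value`` (WC keys 0 unless mode=free_wc)."""
    s = {k: 0.0 for k in required_keys(domain, mode)}
    ws = WeightSet(mode=mode, domain=domain, s=s)
    return ws.with_free_values([value] * len(ws.free_keys()))


def recognizing_anticodons(
    codon: str, domain: str = "eukarya", mode: str = "standard"
) -> List[Tuple[str, str]]:
    """(anticodon, pairing key) pairs for the tRNAs that read a sense codon.

    In prokaryotes the AUA codon is read by the lysidine/agmatidine-modified
    tRNA-Ile alone (key ``L:A``), replacing the generic third-base-A readers;
    the sentinel anticodon names :attr:`~stai.core.TrnaPool.special_ile_count`.
    """
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon")
    if codon not in SENSE_CODON_INDEX:
        raise ValueError(f"invalid codon {codon!r}")
    if codon == "ATA" and is_prokaryote(domain):
        return [(LYSIDINE_ANTICODON, LYSIDINE_KEY)]
    b1, b2, third = codon
    tail = revcomp(b1 + b2)
    pairs = list(_STANDARD_PAIRS[third])
    if mode == "all_pairings":
        pairs += list(_EXTRA_PAIRS[third])
    return [(x + tail, key) for x, key in pairs]


def absolute_adaptiveness(codon: str, pool: TrnaPool, ws: WeightSet) -> float:
    """W_i = sum over recognizing anticodons of (1 - s) * tGCN."""
    total = 0.0
    for anticodon, key in recognizing_anticodons(codon, ws.domain, ws.mode):
        total += (1.0 - ws.s[key]) * pool.count(anticodon)
    return total


@dataclass
class AdaptivenessTable:
    """Absolute (W) and max-normalized relative (w) codon adaptiveness."""

    W: Dict[str, float]
    w: Dict[str, float]

    def __post_init__(self) -> None:
        if not self.w:
            raise ValueError("empty adaptiveness table")
        values = np.array(list(self.w.values()))
        if not np.all(values > 0):
            raise ValueError("relative adaptiveness values must be > 0")
        if abs(values.max() - 1.0) > 1e-12:
            raise ValueError("max relative adaptiveness must equal 1")

    def w_vector(self) -> np.ndarray:
        """w over the 61 sense codons in canonical order."""
        try:
            return np.array([self.w[c] for c in SENSE_CODONS])
        except KeyError as exc:
            raise ValueError(f"table missing sense codon {exc}")


def adaptiveness_table(pool: TrnaPool, ws: WeightSet) -> AdaptivenessTable:
    """Build the per-codon adaptiveness table for a tRNA pool and weights."""
    W = {c: absolute_adaptiveness(c, pool, ws) for c in SENSE_CODONS}
    return _normalize_table(W)


def _normalize_table(W: Dict[str, float]) -> AdaptivenessTable:
    values = np.array([W[c] for c in W])
    wmax = values.max()
    if wmax <= 0:
        raise ValueError("all absolute adaptiveness values are 0")
    w = {c: W[c] / wmax for c in W}
    zeros = [c for c, v in w.items() if v == 0.0]
    if zeros:
        nonzero = np.array([v for v in w.values() if v > 0])
        gm = float(np.exp(np.mean(np.log(nonzero))))
        logger.info(
            "adaptiveness: %d codon(s) with w=0 replaced by geometric mean "
            "%.4g: %s", len(zeros), gm, ",".join(zeros)
        )
        for c in zeros:
            w[c] = gm
    return AdaptivenessTable(W=W, w=w)


def gene_tai(
    gene: CodingGene,
    table: AdaptivenessTable,
    exclude_met_trp: bool = False,
) -> float:
    """Geometric mean of w over a gene's codon positions, in (0, 1]."""
    codons = [c for c in gene.codons if c not in STOP_CODONS]
    if exclude_met_trp:
        codons = [c for c in codons if c not in ("ATG", "TGG")]
    if not codons:
        raise ValueError(f"gene {gene.id!r}: no scorable codons")
    try:
        logs = [np.log(table.w[c]) for c in codons]
    except KeyError as exc:
        raise ValueError(f"gene {gene.id!r}: codon {exc} not in table")
    return float(np.exp(np.mean(logs)))


def genome_tai(
    genome: Genome,
    table: AdaptivenessTable,
    exclude_met_trp: bool = False,
) -> np.ndarray:
    """Vector of gene tAI values over a genome (vectorized gene_tai)."""
    counts = genome.sense_counts_matrix().astype(float)
    if exclude_met_trp:
        counts = counts.copy()
        for c in ("ATG", "TGG"):
            counts[:, SENSE_CODON_INDEX[c]] = 0.0
    L = counts.sum(axis=1)
    if np.any(L == 0):
        bad = [genome.genes[i].id for i in np.nonzero(L == 0)[0]]
        raise ValueError(f"genes with no scorable codons: {bad}")
    logw = np.log(table.w_vector())
    return np.exp(counts @ logw / L)
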