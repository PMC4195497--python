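"""Domain types shared across the package.

The central objects are:

* :class:`CodingGene` / :class:`Genome` -- identified, in-frame codon
  sequences (the unit every score is computed on);
* :class:`TrnaPool` -- tRNA gene copy numbers (tGCN) per anticodon, the proxy
  for cellular tRNA abundance;
* :class:`WeightSet` -- the selective-constraint vector S over
  codon(3rd base) : anticodon(34) pairing keys, 0 = perfect interaction,
  1 = no interaction;
* :class:`AbundanceTable` -- optional per-gene protein abundances used as an
  alternative optimization / validation target.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

import numpy as np

from .genetic_code import ALL_CODON_INDEX, SENSE_CODONS

DOMAINS = ("eukarya", "bacteria", "archaea")
MODES = ("standard", "all_pairings", "free_wc")

#: Watson-Crick pairing keys, written anticodon-wobble-base : codon-third-base.
WC_KEYS = ("I:U", "G:C", "U:A", "C:G")
#: The four wobble keys shared by all domains.
WOBBLE_KEYS = ("G:U", "I:C", "I:A", "U:G")
#: Lysidine (bacteria) / agmatidine (archaea) reading of the AUA codon.
LYSIDINE_KEY = "L:A"
#: Non-standard pairings added in all_pairings mode.
EXTRA_PAIRING_KEYS = ("U:U", "C:U", "U:C", "C:C", "C:A", "G:A", "I:G", "G:G")

#: Sentinel "anticodon" naming the lysidine/agmatidine-modified tRNA-Ile whose
#: copy number lives in :attr:`TrnaPool.special_ile_count` (its genomic
#: anticodon, CAT, is indistinguishable from tRNA-Met's).
LYSIDINE_ANTICODON = "ILE_LYSIDINE"


def is_prokaryote(domain: str) -> bool:
    _check_domain(domain)
    return domain in ("bacteria", "archaea")


def _check_domain(domain: str) -> None:
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def wobble_keys(domain: str) -> tuple:
    """Wobble keys for a domain: 4 for eukarya, 5 for prokaryotes."""
    _check_domain(domain)
    if is_prokaryote(domain):
        return WOBBLE_KEYS + (LYSIDINE_KEY,)
    return WOBBLE_KEYS


def required_keys(domain: str, mode: str) -> tuple:
    """Every pairing key a :class:`WeightSet` of this domain/mode carries."""
    _check_mode(mode)
    keys = WC_KEYS + wobble_keys(domain)
    if mode == "all_pairings":
        keys = keys + EXTRA_PAIRING_KEYS
    return keys


def free_keys(domain: str, mode: str) -> tuple:
    """Keys the optimizer may move (WC keys join only in free_wc mode)."""
    _check_mode(mode)
    keys = wobble_keys(domain)
    if mode == "all_pairings":
        keys = keys + EXTRA_PAIRING_KEYS
    elif mode == "free_wc":
        keys = keys + WC_KEYS
    return keys


@dataclass
class WeightSet:
    """A selective-constraint vector S with mode and domain tags.

    ``s`` maps pairing keys (anticodon wobble base : codon third base, e.g.
    ``"G:U"``) to values in [0, 1].  In ``standard`` and ``all_pairings``
    modes the four WC keys are fixed at 0 (perfect interactions); ``free_wc``
    releases them into the optimized set.
    """

    mode: str
    domain: str
    s: Dict[str, float]

    def __post_init__(self) -> None:
        _check_mode(self.mode)
        _check_domain(self.domain)
        req = required_keys(self.domain, self.mode)
        missing = [k for k in req if k not in self.s]
        if missing:
            raise ValueError(
                f"weight set ({self.domain}, {self.mode}) missing keys {missing}"
            )
        unknown = [k for k in self.s if k not in req]
        if unknown:
            raise ValueError(f"unknown pairing keys {unknown} for "
                             f"({self.domain}, {self.mode})")
        for k, v in self.s.items():
            v = float(v)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValueError(f"weight {k}={v} outside [0, 1]")
            self.s[k] = v
        if self.mode != "free_wc":
            bad = [k for k in WC_KEYS if self.s[k] != 0.0]
            if bad:
                raise ValueError(
                    f"WC keys {bad} must be 0 in mode={self.mode!r}"
                )
        # canonical key order, so serialized files and vectors are stable
        self.s = {k: self.s[k] for k in req}

    def free_keys(self) -> tuple:
        return free_keys(self.domain, self.mode)

    def free_values(self) -> np.ndarray:
        return np.array([self.s[k] for k in self.free_keys()], dtype=float)

    def wobble_values(self) -> np.ndarray:
        """Values of the domain's wobble keys, in canonical order."""
        return np.array([self.s[k] for k in wobble_keys(self.domain)])

    def replace(self, updates: Dict[str, float]) -> "WeightSet":
        """A copy with some entries replaced (validates the result)."""
        s = dict(self.s)
        s.update(updates)
        return WeightSet(mode=self.mode, domain=self.domain, s=s)

    def with_free_values(self, values) -> "WeightSet":
        return self.replace(dict(zip(self.free_keys(), map(float, values))))


@dataclass
class CodingGene:
    """An identified, in-frame codon sequence (stop codons already removed)."""

    id: str
    codons: List[str]
    _indices: Optional[np.ndarray] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene id must be non-empty")
        if not self.codons:
            raise ValueError(f"gene {self.id!r} has no codons")
        for c in self.codons:
            if c not in ALL_CODON_INDEX:
                raise ValueError(f"gene {self.id!r}: invalid codon {c!r}")

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    def codon_indices(self) -> np.ndarray:
        """Codon positions as indices into the 64-codon alphabet (cached)."""
        if self._indices is None:
            self._indices = np.array(
                [ALL_CODON_INDEX[c] for c in self.codons], dtype=np.intp
            )
        return self._indices

    def sense_counts(self) -> np.ndarray:
        """Counts over the 61 sense codons (stop codons ignored)."""
        full = np.bincount(self.codon_indices(), minlength=64)
        keep = [ALL_CODON_INDEX[c] for c in SENSE_CODONS]
        return full[keep]


@dataclass
class Genome:
    """A set of coding genes with an organism id and a domain-of-life tag.

    The domain tag determines the wobble-parameter dimensionality (4 free
    wobble weights for eukarya, 5 for bacteria/archaea).
    """

    organism_id: str
    domain: str
    genes: List[CodingGene]
    _counts: Optional[np.ndarray] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        _check_domain(self.domain)
        if not self.genes:
            raise ValueError(f"genome {self.organism_id!r} has no genes")
        seen = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(
                    f"genome {self.organism_id!r}: duplicate gene id {g.id!r}"
                )
            seen.add(g.id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[CodingGene]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> List[str]:
        return [g.id for g in self.genes]

    def sense_counts_matrix(self) -> np.ndarray:
        """(n_genes, 61) matrix of sense-codon counts (cached)."""
        if self._counts is None:
            self._counts = np.vstack([g.sense_counts() for g in self.genes])
        return self._counts

    def subset(self, gene_ids, organism_id: Optional[str] = None) -> "Genome":
        wanted = set(gene_ids)
        genes = [g for g in self.genes if g.id in wanted]
        return Genome(
            organism_id=organism_id or self.organism_id,
            domain=self.domain,
            genes=genes,
        )


_VALID_ANTICODON_BASES = set("ACGT")


@dataclass
class TrnaPool:
    """tRNA gene copy numbers per anticodon (DNA alphabet, written 5'->3').

    ``special_ile_count`` is the copy number of the lysidine/agmatidine
    modified AUA-reading tRNA-Ile (prokaryotes); it defaults to 1 when a table
    does not report it, and is ignored for eukarya.
    """

    counts: Dict[str, int]
    special_ile_count: int = 1

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for ac, n in self.counts.items():
            ac = ac.upper().replace("U", "T")
            if len(ac) != 3 or not set(ac) <= _VALID_ANTICODON_BASES:
                raise ValueError(f"malformed anticodon {ac!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative copy number for anticodon {ac}")
            clean[ac] = n
        if not any(clean.values()):
            raise ValueError("tRNA pool has no positive copy number")
        if int(self.special_ile_count) < 0:
            raise ValueError("special_ile_count must be non-negative")
        self.counts = clean
        self.special_ile_count = int(self.special_ile_count)

    def count(self, anticodon: str) -> int:
        """Copy number of an anticodon (0 when absent from the table)."""
        if anticodon == LYSIDINE_ANTICODON:
            return self.special_ile_count
        return self.counts.get(anticodon, 0)

    def scaled(self, factor: int) -> "TrnaPool":
        return TrnaPool(
            counts={a: n * factor for a, n in self.counts.items()},
            special_ile_count=self.special_ile_count * factor,
        )


@dataclass
class AbundanceTable:
    """Per-gene protein abundances (strictly positive)."""

    values: Dict[str, float]

    def __post_init__(self) -> None:
        for gid, v in self.values.items():
            v = float(v)
            if not (v > 0) or not np.isfinite(v):
                raise ValueError(f"abundance for {gid!r} must be > 0, got {v}")
            self.values[gid] = v
        if not self.values:
            raise ValueError("abundance table is empty")

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def vector_for(self, gene_ids) -> np.ndarray:
        return np.array([self.values[g] for g in gene_ids], dtype=float)

    def covered_ids(self, genome: Genome) -> List[str]:
        """Gene ids present in both the genome and the table, genome order."""
        return [g for g in genome.gene_ids if g in self.values]
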