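"""Readers and writers for the package's external formats.

* CDS FASTA (nucleotide, standard dialect) -> :class:`~stai.core.Genome`
* tab-separated anticodon copy-number tables -> :class:`~stai.core.TrnaPool`
* tab-separated gene-abundance tables -> :class:`~stai.core.AbundanceTable`
* structured-text (JSON) weight-set files -> :class:`~stai.core.WeightSet`

CDS records are assumed in-frame starting at position 1; no ORF detection is
performed.  Stop codons (TAA/TAG/TGA) are removed from every gene before any
scoring; internal stops are logged.  Lowercase and RNA (U) input is accepted.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AbundanceTable, Genome, CodingGene, TrnaPool, WeightSet
from .genetic_code import STOP_CODONS, codons_of

logger = logging.getLogger("stai")

_VALID = set("ACGT")
PathLike = Union[str, Path]


def _clean_gene(record_id: str, raw_seq: str, policy: str):
    """Validate one FASTA record into a stop-free codon list (or None)."""
    seq = str(raw_seq).upper().replace("U", "T")

    def _reject(reason: str):
        if policy == "error":
            raise ValueError(f"record {record_id!r}: {reason}")
        logger.warning("skipping record %r: %s", record_id, reason)
        return None

    if len(seq) % 3:
        return _reject(f"length {len(seq)} is not a multiple of 3")
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        return _reject(f"contains non-ACGT characters {bad}")
    if not seq:
        return _reject("empty sequence")

    codons = codons_of(seq)
    n_stops = sum(c in STOP_CODONS for c in codons)
    if n_stops:
        internal = any(c in STOP_CODONS for c in codons[:-1])
        if internal:
            logger.warning("record %r: internal stop codon(s) removed",
                           record_id)
        codons = [c for c in codons if c not in STOP_CODONS]
    if not codons:
        return _reject("no sense codons left after stop removal")
    return codons


def read_cds_fasta(
    path: PathLike,
    policy: str = "skip",
    organism_id: str | None = None,
    domain: str = "eukarya",
) -> Genome:
    """Read a FASTA file of in-frame coding sequences into a Genome.

    Parameters
    ----------
    policy:
        ``"skip"`` logs and drops malformed records (wrong length, ambiguity
        codes); ``"error"`` raises on the first one.  Duplicate record ids are
        always a hard error.
    """
    if policy not in ("skip", "error"):
        raise ValueError(f"unknown policy {policy!r}")
    path = Path(path)
    genes: list[CodingGene] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"{path}: duplicate gene id {record.id!r}")
        seen.add(record.id)
        codons = _clean_gene(record.id, record.seq, policy)
        if codons is not None:
            genes.append(CodingGene(id=record.id, codons=codons))
    if not genes:
        raise ValueError(f"{path}: no valid coding sequences")
    return Genome(
        organism_id=organism_id or path.stem, domain=domain, genes=genes
    )


def write_cds_fasta(genome: Genome, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="")
        for g in genome.genes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_trna_table(path: PathLike) -> TrnaPool:
    """Read "anticodon<TAB>count" lines (optional ILE_LYSIDINE line)."""
    path = Path(path)
    counts: dict[str, int] = {}
    special: int | None = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'anticodon<TAB>count'")
        key, value = parts[0].strip(), parts[1].strip()
        try:
            n = int(value)
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer count {value!r}")
        if n < 0:
            raise ValueError(f"{path}:{ln}: negative count for {key!r}")
        if key.upper() == "ILE_LYSIDINE":
            special = n
            continue
        ac = key.upper().replace("U", "T")
        if ac in counts:
            raise ValueError(f"{path}:{ln}: duplicate anticodon {ac!r}")
        counts[ac] = n
    if not counts or not any(counts.values()):
        raise ValueError(f"{path}: no positive tRNA gene copy number")
    return TrnaPool(
        counts=counts,
        special_ile_count=1 if special is None else special,
    )


def write_trna_table(pool: TrnaPool, path: PathLike) -> None:
    lines = [f"{ac}\t{n}" for ac, n in sorted(pool.counts.items())]
    lines.append(f"ILE_LYSIDINE\t{pool.special_ile_count}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_abundance_table(path: PathLike) -> AbundanceTable:
    """Read "gene_id<TAB>abundance" lines into an AbundanceTable."""
    path = Path(path)
    values: dict[str, float] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'gene_id<TAB>abundance'")
        gid, value = parts[0].strip(), parts[1].strip()
        if gid in values:
            raise ValueError(f"{path}:{ln}: duplicate gene id {gid!r}")
        values[gid] = float(value)
    return AbundanceTable(values=values)


def write_abundance_table(table: AbundanceTable, path: PathLike) -> None:
    lines = [f"{g}\t{v:.6g}" for g, v in table.values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_weight_set(ws: WeightSet, path: PathLike) -> None:
    """Serialize a weight set (mode/domain tags + key:value map) as JSON."""
    payload = {"mode": ws.mode, "domain": ws.domain, "s": ws.s}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_weight_set(path: PathLike) -> WeightSet:
    """Read a weight-set file; round-trips :func:`write_weight_set` exactly."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid weight-set file: {exc}")
    for field_name in ("mode", "domain", "s"):
        if field_name not in payload:
            raise ValueError(f"{path}: missing field {field_name!r}")
    return WeightSet(
        mode=payload["mode"],
        domain=payload["domain"],
        s={str(k): float(v) for k, v in payload["s"].items()},
    )
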