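"""Readers and writers for every external representation the pipeline touches.

Sequence data travels as FASTA, pairwise alignments as the tab-separated
BLAST tabular dialect (the 12 standard columns, optionally extended with
query/subject lengths), taxonomies and domain hits as simple TSV tables,
and every pipeline product as a JSON report with a ``stage`` tag, an echo
of the ``parameters`` used, and a ``records`` array.

All record containers are plain frozen dataclasses so they hash, compare
and round-trip through JSON without surprises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "Contig",
    "AlignmentRecord",
    "DomainHitRecord",
    "BLAST_12_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_alignment_table",
    "write_alignment_table",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "read_domain_hits",
    "read_group_map",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Contig:
    """An assembled nucleotide sequence; the unit flowing through every stage."""

    id: str
    sequence: str
    source_dataset: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One query-subject HSP from a tabular alignment export.

    ``pident`` is percent identity over the alignment (0-100); ``qlen`` is
    the full query length in bases, needed by the ANI/coverage formulas.
    """

    qacc: str
    sacc: str
    pident: float
    align_len: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.qlen < 1:
            raise ValueError("qlen must be >= 1")


@dataclass(frozen=True)
class DomainHitRecord:
    """A conserved-domain hit: contig, CDD-style accession, E-value."""

    contig_id: str
    domain_acc: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


#: The 12 standard tabular columns, in conventional order.
BLAST_12_COLUMNS: tuple[str, ...] = (
    "qacc", "sacc", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Contig]:
    """Read contigs from a FASTA file.

    The header token up to the first whitespace becomes the id; sequences
    are uppercased. Duplicate ids and empty sequences raise ``ValueError``.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        cid = rec.id
        if not cid:
            raise ValueError(f"{path}: malformed FASTA header (empty id)")
        if cid in seen:
            raise ValueError(f"{path}: duplicate contig id {cid!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {cid!r} has an empty sequence")
        seen.add(cid)
        contigs.append(Contig(id=cid, sequence=seq))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular alignments

_NUMERIC_FIELDS = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float, "qlen": int, "slen": int,
}


def read_alignment_table(
    path: str | Path,
    columns: Sequence[str] = BLAST_12_COLUMNS,
    lengths: Mapping[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Parse a tab-separated alignment table into ``AlignmentRecord`` rows.

    ``columns`` declares the field order of the file. When ``qlen`` is not a
    declared column, ``lengths`` must resolve the query length of every
    ``qacc`` (typically derived from the contig FASTA). Rows are returned in
    file order; blank lines and ``#`` comments are skipped.
    """
    columns = list(columns)
    required = {"qacc", "sacc", "pident", "length", "evalue", "bitscore"}
    missing = required - set(columns)
    if missing:
        raise ValueError(f"column list lacks required fields: {sorted(missing)}")
    has_qlen = "qlen" in columns
    if not has_qlen and lengths is None:
        raise ValueError("qlen is not a declared column and no lengths map given")

    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
                )
            row: dict[str, object] = {}
            for name, raw in zip(columns, fields):
                conv = _NUMERIC_FIELDS.get(name)
                if conv is None:
                    row[name] = raw
                    continue
                try:
                    row[name] = conv(raw)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {raw!r} in column {name!r}"
                    ) from None
            qacc = str(row["qacc"])
            if has_qlen:
                qlen = int(row["qlen"])  # type: ignore[arg-type]
            else:
                assert lengths is not None
                if qacc not in lengths:
                    raise ValueError(
                        f"{path}:{lineno}: no query length known for {qacc!r}"
                    )
                qlen = int(lengths[qacc])
            records.append(
                AlignmentRecord(
                    qacc=qacc,
                    sacc=str(row["sacc"]),
                    pident=float(row["pident"]),  # type: ignore[arg-type]
                    align_len=int(row["length"]),  # type: ignore[arg-type]
                    evalue=float(row["evalue"]),  # type: ignore[arg-type]
                    bitscore=float(row["bitscore"]),  # type: ignore[arg-type]
                    qlen=qlen,
                    slen=int(row["slen"]) if "slen" in row else None,  # type: ignore[arg-type]
                )
            )
    return records


def write_alignment_table(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records in the 12-column dialect extended with a trailing qlen."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.qacc, r.sacc, f"{r.pident:.3f}", r.align_len,
                        0, 0, 1, r.align_len, 1, r.align_len,
                        f"{r.evalue:.6g}", f"{r.bitscore:.6g}", r.qlen,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Taxonomy, domain hits, group maps (simple TSV)


def read_taxonomy_table(path: str | Path) -> dict[int, tuple[int, str, str]]:
    """Read a 4-column TSV (taxid, parent_taxid, rank, name) into a node map."""
    nodes: dict[int, tuple[int, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            taxid, parent, rank, name = fields
            tid = int(taxid)
            if tid in nodes:
                raise ValueError(f"{path}:{lineno}: duplicate taxid {tid}")
            nodes[tid] = (int(parent), rank, name)
    return nodes


def write_taxonomy_table(
    nodes: Mapping[int, tuple[int, str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for tid in sorted(nodes):
            parent, rank, name = nodes[tid]
            fh.write(f"{tid}\t{parent}\t{rank}\t{name}\n")


def read_domain_hits(path: str | Path) -> list[DomainHitRecord]:
    """Read a 3-column TSV (contig_id, domain_acc, evalue)."""
    hits: list[DomainHitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            try:
                ev = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric evalue {fields[2]!r}"
                ) from None
            hits.append(DomainHitRecord(fields[0], fields[1], ev))
    return hits


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (domain_acc, group)."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            acc, group = fields
            if acc in entries and entries[acc] != group:
                raise ValueError(f"{path}:{lineno}: accession {acc!r} remapped")
            entries[acc] = group
    return entries


# ---------------------------------------------------------------------------
# JSON reports


def write_report(
    stage: str,
    records: Sequence[Mapping[str, object]],
    parameters: Mapping[str, object],
    path: str | Path,
) -> None:
    """Write a pipeline product as a JSON report.

    The document has a top-level object with a ``stage`` tag, a
    ``parameters`` object echoing every threshold used, and a ``records``
    array. ``read_report`` reproduces the records exactly.
    """
    doc = {
        "stage": stage,
        "parameters": dict(parameters),
        "records": [dict(r) for r in records],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("stage", "parameters", "records"):
        if key not in doc:
            raise ValueError(f"{path}: not a pipeline report (missing {key!r})")
    return doc
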