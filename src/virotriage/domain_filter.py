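"""Conserved-domain taxon voting over candidate dark-matter contigs.

Each contig's domain hits (e.g. RPSTBLASTN against the CDD) are tallied by
the taxon group of the hit accession — viral, bacterial, archaeal,
eukaryotic, or unknown — at an E-value cut-off of 1e-3. Count vectors are
then binned into three mutually exclusive fail categories and three pass
categories:

    fail 1: > 3 eukaryotic and > 3 prokaryotic hits, zero viral
    fail 2: > 3 eukaryotic hits, zero viral
    fail 3: > 3 prokaryotic hits, zero viral
    pass 1: no hits at all (dark matter)
    pass 2: at least one viral hit
    pass 3: everything else

"Prokaryotic" counts bacterial + archaeal hits by default
(``bacterial_plus_archaeal``); a ``bacterial_only`` mode is provided since
the two published phrasings of the rule differ on archaea.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHitRecord

__all__ = [
    "GROUPS",
    "GroupMap",
    "DomainVerdict",
    "count_groups",
    "apply_filter",
    "relative_counts",
    "evaluate_contig",
    "evaluate_contigs",
]

GROUPS: tuple[str, ...] = ("viral", "bacterial", "archaeal", "eukaryotic", "unknown")

PROKARYOTIC_MODES = ("bacterial_plus_archaeal", "bacterial_only")


@dataclass(frozen=True)
class GroupMap:
    """domain accession -> taxon group. Unmapped accessions count as unknown."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.entries.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown taxon groups in map: {sorted(bad)}")

    def group_of(self, domain_acc: str) -> str:
        return self.entries.get(domain_acc, "unknown")


@dataclass(frozen=True)
class DomainVerdict:
    contig_id: str
    counts: dict[str, int]
    total_hits: int
    relative: dict[str, float]
    status: str  # "pass" | "fail"
    category: int  # 1-3 within status
    dark_matter: bool


def count_groups(
    hits: Iterable[DomainHitRecord],
    gm: GroupMap,
    max_evalue: float = 1e-3,
) -> dict[str, int]:
    """Tally one contig's hits by taxon group at the E-value cut-off.

    Counting is per hit record; hits above ``max_evalue`` are excluded and
    unmapped accessions fall into the unknown group.
    """
    counts = {g: 0 for g in GROUPS}
    for hit in hits:
        if hit.evalue <= max_evalue:
            counts[gm.group_of(hit.domain_acc)] += 1
    return counts


def apply_filter(
    counts: Mapping[str, int],
    prokaryotic_mode: str = "bacterial_plus_archaeal",
) -> tuple[str, int, bool]:
    """Pass/fail categorization of one count vector.

    Returns ``(status, category, dark_matter)``. The fail rules are
    evaluated 1 -> 2 -> 3 so overlapping conditions resolve to the most
    specific category; "more than three" is strict (> 3).
    """
    if prokaryotic_mode not in PROKARYOTIC_MODES:
        raise ValueError(f"unknown prokaryotic_mode {prokaryotic_mode!r}")
    full = {g: int(counts.get(g, 0)) for g in GROUPS}
    if any(v < 0 for v in full.values()):
        raise ValueError("counts must be non-negative")
    viral = full["viral"]
    euk = full["eukaryotic"]
    prok = full["bacterial"]
    if prokaryotic_mode == "bacterial_plus_archaeal":
        prok += full["archaeal"]
    total = sum(full.values())

    if euk > 3 and prok > 3 and viral == 0:
        return "fail", 1, False
    if euk > 3 and viral == 0:
        return "fail", 2, False
    if prok > 3 and viral == 0:
        return "fail", 3, False
    if total == 0:
        return "pass", 1, True
    if viral > 0:
        return "pass", 2, False
    return "pass", 3, False


def relative_counts(counts: Mapping[str, int]) -> dict[str, float]:
    """Per-group fraction of the contig's total hits; all zeros when no hits."""
    full = {g: int(counts.get(g, 0)) for g in GROUPS}
    if any(v < 0 for v in full.values()):
        raise ValueError("counts must be non-negative")
    total = sum(full.values())
    if total == 0:
        return {g: 0.0 for g in GROUPS}
    return {g: v / total for g, v in full.items()}


def evaluate_contig(
    contig_id: str,
    hits: Iterable[DomainHitRecord],
    gm: GroupMap,
    max_evalue: float = 1e-3,
    prokaryotic_mode: str = "bacterial_plus_archaeal",
) -> DomainVerdict:
    counts = count_groups(hits, gm, max_evalue)
    status, category, dark = apply_filter(counts, prokaryotic_mode)
    return DomainVerdict(
        contig_id=contig_id,
        counts=counts,
        total_hits=sum(counts.values()),
        relative=relative_counts(counts),
        status=status,
        category=category,
        dark_matter=dark,
    )


def evaluate_contigs(
    contig_ids: Sequence[str],
    hits: Iterable[DomainHitRecord],
    gm: GroupMap,
    max_evalue: float = 1e-3,
    prokaryotic_mode: str = "bacterial_plus_archaeal",
) -> list[DomainVerdict]:
    """Verdicts for a set of contigs; contigs without hit rows are dark matter."""
    by_contig: dict[str, list[DomainHitRecord]] = {cid: [] for cid in contig_ids}
    for hit in hits:
        if hit.contig_id in by_contig:
            by_contig[hit.contig_id].append(hit)
    return [
        evaluate_contig(cid, by_contig[cid], gm, max_evalue, prokaryotic_mode)
        for cid in contig_ids
    ]
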