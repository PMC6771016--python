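"""Known/unknown contig triage from tabular alignment results.

Contigs shorter than 1 kb are removed, alignments are reduced to one HSP
per query-subject pair, and every surviving hit is scored by two
query-relative quantities:

    ani      = identities / query length
    coverage = alignment length / query length

Contigs are then binned by their best hit: ``known_known`` (ani > 0.85 and
coverage > 0.8, close matches to reference viruses), ``known_unknown_1``
(ani > 0.85 with partial 50-80% coverage), ``known_unknown_2``
(50% < ani <= 85% with coverage > 50%), and ``unknown_unknown`` (everything
else, including contigs with no qualifying hit at all — the candidate dark
matter that flows to clustering and domain scanning).

Note that with ani defined query-relative, ani can never exceed coverage,
so ``known_unknown_1`` is unreachable from real alignment records; the
region is retained because the classifier is specified over the abstract
(ani, coverage) plane. See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentRecord, Contig

__all__ = [
    "TriageThresholds",
    "TriageResult",
    "CATEGORIES",
    "length_filter",
    "hit_metrics",
    "best_hsp_per_pair",
    "hit_category",
    "classify_contig",
    "classify_all",
    "tally_known_viruses",
]

#: Category names in decreasing similarity order.
CATEGORIES: tuple[str, ...] = (
    "known_known",
    "known_unknown_1",
    "known_unknown_2",
    "unknown_unknown",
)

_RANK = {name: i for i, name in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class TriageThresholds:
    """All cut-offs of the triage stage.

    ``max_evalue`` defaults to the reference-screening cut-off 1e-3; the
    stricter all-vs-all value 1e-10 is available by configuration.
    """

    min_contig_len: int = 1000
    max_evalue: float = 1e-3
    kk_ani: float = 0.85
    kk_cov: float = 0.8
    ku_ani: float = 0.5
    ku_cov: float = 0.5
    ku1_cov_hi: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.ku_ani <= self.kk_ani <= 1:
            raise ValueError("need 0 <= ku_ani <= kk_ani <= 1")
        if not 0 <= self.ku_cov <= self.kk_cov <= 1:
            raise ValueError("need 0 <= ku_cov <= kk_cov <= 1")


@dataclass(frozen=True)
class TriageResult:
    contig_id: str
    category: str
    best_sacc: str | None = None
    ani: float | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.category not in _RANK:
            raise ValueError(f"unknown category {self.category!r}")


def length_filter(contigs: Sequence[Contig], min_len: int = 1000) -> list[Contig]:
    """Keep contigs of length >= ``min_len`` ("shorter than 1 kb" are removed)."""
    return [c for c in contigs if c.length >= min_len]


def hit_metrics(rec: AlignmentRecord) -> tuple[float, float]:
    """Query-relative (ani, coverage) of one hit.

    Identities are reconstructed as round(pident/100 * align_len) since
    tabular output carries percent identity rather than an identity count
    (exact for ungapped alignments). Coverage may exceed 1 for gapped
    alignments.
    """
    if rec.qlen < 1:
        raise ValueError("query length must be >= 1")
    identities = round(rec.pident / 100.0 * rec.align_len)
    return identities / rec.qlen, rec.align_len / rec.qlen


def best_hsp_per_pair(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """One record per (qacc, sacc) pair: highest bitscore, then lowest
    evalue, then first occurrence. Pair order follows first appearance."""
    best: dict[tuple[str, str], AlignmentRecord] = {}
    for rec in records:
        key = (rec.qacc, rec.sacc)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
        elif rec.bitscore > cur.bitscore or (
            rec.bitscore == cur.bitscore and rec.evalue < cur.evalue
        ):
            best[key] = rec
    return list(best.values())


def hit_category(ani: float, coverage: float, th: TriageThresholds) -> str | None:
    """Category of a single hit on the (ani, coverage) plane, or None.

    Thresholds are strict as printed; the interval edge between the
    known_known and known_unknown_1 coverage bands is inclusive on the
    lower category, so boundary mass falls downward deterministically.
    """
    if ani > th.kk_ani and coverage > th.kk_cov:
        return "known_known"
    if ani > th.kk_ani and th.ku_cov < coverage <= th.ku1_cov_hi:
        return "known_unknown_1"
    if th.ku_ani < ani <= th.kk_ani and coverage > th.ku_cov:
        return "known_unknown_2"
    return None


def classify_contig(
    contig_id: str,
    hits: Sequence[AlignmentRecord],
    th: TriageThresholds | None = None,
) -> TriageResult:
    """Triage one contig from its (HSP-reduced) hits.

    Hits above ``th.max_evalue`` are ignored. Each surviving hit is
    categorized on the (ani, coverage) plane; the contig takes the best
    category achieved, with the reported hit being the highest-bitscore
    one achieving it. No qualifying hit means ``unknown_unknown``.
    """
    th = th or TriageThresholds()
    surviving = [h for h in hits if h.evalue <= th.max_evalue]
    best_cat_rank = _RANK["unknown_unknown"]
    best_hit: AlignmentRecord | None = None
    best_metrics: tuple[float, float] | None = None
    for hit in surviving:
        ani, cov = hit_metrics(hit)
        cat = hit_category(ani, cov, th)
        if cat is None:
            continue
        rank = _RANK[cat]
        if rank < best_cat_rank or (
            rank == best_cat_rank
            and (best_hit is None or hit.bitscore > best_hit.bitscore)
        ):
            best_cat_rank = rank
            best_hit = hit
            best_metrics = (ani, cov)
    if best_hit is None:
        # report the top surviving hit for provenance even when unqualifying
        top = max(surviving, key=lambda h: h.bitscore, default=None)
        if top is None:
            return TriageResult(contig_id, "unknown_unknown")
        ani, cov = hit_metrics(top)
        return TriageResult(contig_id, "unknown_unknown", top.sacc, ani, cov)
    assert best_metrics is not None
    return TriageResult(
        contig_id, CATEGORIES[best_cat_rank], best_hit.sacc,
        best_metrics[0], best_metrics[1],
    )


def classify_all(
    contigs: Sequence[Contig],
    records: Sequence[AlignmentRecord],
    th: TriageThresholds | None = None,
) -> list[TriageResult]:
    """Length-filter, HSP-reduce and classify a whole contig set."""
    th = th or TriageThresholds()
    kept = length_filter(contigs, th.min_contig_len)
    kept_ids = {c.id for c in kept}
    reduced = best_hsp_per_pair([r for r in records if r.qacc in kept_ids])
    by_query: dict[str, list[AlignmentRecord]] = {}
    for rec in reduced:
        by_query.setdefault(rec.qacc, []).append(rec)
    return [classify_contig(c.id, by_query.get(c.id, []), th) for c in kept]


def tally_known_viruses(results: Iterable[TriageResult]) -> list[tuple[str, int]]:
    """Contig counts per best-matched subject among known_known results,
    sorted by descending count then subject id."""
    counts: dict[str, int] = {}
    for res in results:
        if res.category == "known_known" and res.best_sacc is not None:
            counts[res.best_sacc] = counts.get(res.best_sacc, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
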