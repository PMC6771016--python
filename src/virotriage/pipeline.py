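"""End-to-end orchestration: length filter -> triage -> clustering -> domains.

Stages run in the discovery order: contigs are length-filtered, alignments
reduced to one HSP per pair and triaged into known/unknown categories, the
filtered alignment set is clustered with MCL, and the unknown_unknown
contigs — and only those — are screened by the conserved-domain taxon
filter. One JSON report is written per executed stage plus a summary with
per-stage contig counts; every threshold used is echoed in the reports.
Stages whose inputs are absent are skipped with a logged notice.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io_formats as iof
from .domain_filter import GroupMap, evaluate_contigs
from .graph_mcl import MCLParams, build_graph, cluster_size_histogram, mcl_cluster
from .kmer_taxonomy import Taxonomy, build_index, classify_sequence
from .triage import (
    TriageThresholds,
    best_hsp_per_pair,
    classify_contig,
    length_filter,
    tally_known_viruses,
)

__all__ = ["PipelineConfig", "run_triage_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    contigs: str | Path
    alignments: str | Path | None = None
    alignment_columns: tuple[str, ...] = iof.BLAST_12_COLUMNS + ("qlen",)
    domain_hits: str | Path | None = None
    group_map: str | Path | None = None
    taxonomy: str | Path | None = None
    references: str | Path | None = None  # FASTA; enables k-mer annotation
    reference_taxids: dict[str, int] | None = None
    out_dir: str | Path = "virotriage_out"
    thresholds: TriageThresholds = field(default_factory=TriageThresholds)
    mcl: MCLParams = field(default_factory=MCLParams)
    kmer_k: int = 32
    seed: int = 0


def _echo(obj) -> dict:
    return dataclasses.asdict(obj)


def run_triage_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and return the summary report dict.

    Raises before any stage runs if a configured input path is missing.
    """
    out_dir = Path(config.out_dir)
    for name in ("contigs", "alignments", "domain_hits", "group_map",
                 "taxonomy", "references"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"configured {name} input not found: {path}")
    out_dir.mkdir(parents=True, exist_ok=True)

    th = config.thresholds
    contigs = iof.read_fasta(config.contigs)
    logger.info("loaded %d contigs", len(contigs))

    # --- length filter
    kept = length_filter(contigs, th.min_contig_len)
    logger.info("length filter (>= %d bases): %d -> %d contigs",
                th.min_contig_len, len(contigs), len(kept))
    counts = {"input": len(contigs), "length_filtered": len(kept)}
    kept_ids = {c.id for c in kept}

    # --- optional k-mer taxonomy annotation (annotates, never removes)
    kmer_calls = None
    if config.references is not None and config.taxonomy is not None:
        taxonomy = Taxonomy.from_nodes(iof.read_taxonomy_table(config.taxonomy))
        ref_contigs = iof.read_fasta(config.references)
        taxids = config.reference_taxids or {}
        refs = [(c, taxids[c.id]) for c in ref_contigs if c.id in taxids]
        index = build_index(refs, taxonomy, k=config.kmer_k)
        kmer_calls = [classify_sequence(index, taxonomy, c) for c in kept]
        iof.write_report(
            "kmer_taxonomy",
            [
                {"contig_id": tc.contig_id, "best_taxid": tc.best_taxid,
                 "probability": tc.probability,
                 "total_indexed_kmers": tc.total_indexed_kmers}
                for tc in kmer_calls
            ],
            {"k": config.kmer_k},
            out_dir / "kmer_taxonomy.json",
        )
        logger.info("k-mer screen annotated %d contigs", len(kmer_calls))

    # --- triage
    results = []
    category_counts: dict[str, int] = {}
    if config.alignments is not None:
        lengths = {c.id: c.length for c in contigs}
        records = iof.read_alignment_table(
            config.alignments, config.alignment_columns, lengths
        )
        records = [r for r in records if r.qacc in kept_ids]
        reduced = best_hsp_per_pair(records)
        by_query: dict[str, list] = {}
        for rec in reduced:
            by_query.setdefault(rec.qacc, []).append(rec)
        results = [classify_contig(c.id, by_query.get(c.id, []), th) for c in kept]
        for res in results:
            category_counts[res.category] = category_counts.get(res.category, 0) + 1
        counts["triaged"] = len(results)
        iof.write_report(
            "triage",
            [dataclasses.asdict(r) for r in results],
            _echo(th),
            out_dir / "triage.json",
        )
        top = tally_known_viruses(results)
        iof.write_report(
            "known_virus_tally",
            [{"sacc": s, "contigs": n} for s, n in top],
            _echo(th),
            out_dir / "known_virus_tally.json",
        )
        logger.info("triage categories: %s", category_counts)

        # --- clustering on the filtered alignment set
        graph = build_graph(reduced)
        clustering = mcl_cluster(graph, config.mcl)
        hist = cluster_size_histogram(clustering)
        labels = clustering.labels()
        iof.write_report(
            "clustering",
            [{"node_id": node, "cluster": cl} for node, cl in sorted(labels.items())],
            {**_echo(config.mcl), **{k: v for k, v in hist.items() if k != "histogram"},
             "histogram": {str(k): v for k, v in hist["histogram"].items()}},
            out_dir / "clustering.json",
        )
        counts["clustered_nodes"] = clustering.n_nodes
        logger.info("MCL: %d clusters over %d nodes (%d singletons)",
                    len(clustering.clusters), clustering.n_nodes,
                    clustering.singleton_count)
    else:
        logger.info("no alignment table configured; triage and clustering skipped")

    # --- domain filter on the unknown_unknowns only
    verdicts = []
    if config.domain_hits is not None and config.group_map is not None and results:
        uu_ids = [r.contig_id for r in results if r.category == "unknown_unknown"]
        hits = iof.read_domain_hits(config.domain_hits)
        gm = GroupMap(iof.read_group_map(config.group_map))
        verdicts = evaluate_contigs(uu_ids, hits, gm, max_evalue=1e-3)
        dark = sum(1 for v in verdicts if v.dark_matter)
        counts["domain_screened"] = len(verdicts)
        counts["dark_matter"] = dark
        iof.write_report(
            "domain_filter",
            [dataclasses.asdict(v) for v in verdicts],
            {"max_evalue": 1e-3, "prokaryotic_mode": "bacterial_plus_archaeal"},
            out_dir / "domain_filter.json",
        )
        status_counts: dict[str, int] = {}
        for v in verdicts:
            key = f"{v.status}_{v.category}"
            status_counts[key] = status_counts.get(key, 0) + 1
        logger.info("domain filter: %s; dark matter %d/%d",
                    status_counts, dark, len(verdicts))
    elif config.domain_hits is not None:
        logger.info("domain stage skipped (needs alignments + group map)")
    else:
        logger.info("no domain-hit table configured; domain stage skipped")

    summary = {
        "counts": counts,
        "triage_categories": category_counts,
        "parameters": {"thresholds": _echo(th), "mcl": _echo(config.mcl),
                       "kmer_k": config.kmer_k, "seed": config.seed},
    }
    iof.write_report("summary", [summary], summary["parameters"],
                     out_dir / "summary.json")
    return {
        "summary": summary,
        "triage": results,
        "verdicts": verdicts,
        "kmer_calls": kmer_calls,
    }
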