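"""Seeded synthetic fixtures with known ground truth for every stage.

The generator emulates, at desk scale, the structure of a virus-discovery
run: a small rooted taxonomy with reference genomes, contigs derived from
those references at controlled identity (point substitutions only, so
identity is exact Hamming identity), a tabular alignment table in the
12+qlen dialect, and per-contig conserved-domain hit tables drawn from
scenario distributions that cover all six pass/fail categories.

Truth records store the *realized* identity (counted by direct comparison)
alongside the designed rate, and truth categories are computed by rule
oracles local to this module — deliberately independent of the triage and
domain-filter implementations so fixtures can falsify them.

Everything is a pure function of its config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    AlignmentRecord,
    Contig,
    DomainHitRecord,
    write_alignment_table,
    write_fasta,
    write_taxonomy_table,
)
from .kmer_taxonomy import Taxonomy

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_taxonomy",
    "random_sequence",
    "mutate_contig",
    "synth_alignment_table",
    "synth_domain_table",
    "DOMAIN_SCENARIOS",
    "make_fixture",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Config and truth


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world of the standard fixture.

    Defaults: 6 species across 3 genera with one 6 kb reference genome
    each; 24 contigs cycling through the designed identity levels (0.97
    close to reference, 0.70 moderately diverged, 0.30 beyond recognition)
    and window coverages; one fifth of contigs are dark matter (pure random
    sequence, no reference parent). Domain scenarios cover all six
    pass/fail categories.
    """

    seed: int = 0
    n_species: int = 6
    n_genera: int = 3
    refs_per_species: int = 1
    ref_length: int = 6000
    n_contigs: int = 24
    identity_levels: tuple[float, ...] = (0.97, 0.70, 0.30)
    coverage_levels: tuple[float, ...] = (1.0, 0.8, 0.6)
    dark_matter_fraction: float = 0.2
    n_short_contigs: int = 2  # sub-1kb contigs exercising the length filter

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_genera, self.refs_per_species,
               self.ref_length, self.n_contigs) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.dark_matter_fraction <= 1.0:
            raise ValueError("dark_matter_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    contig_id: str
    source_taxid: int | None
    designed_identity: float
    realized_identity: float
    designed_coverage: float
    designed_category: str
    passes_length_filter: bool = True
    domain_scenario: str | None = None
    designed_domain_status: str | None = None
    designed_domain_category: int | None = None


# ---------------------------------------------------------------------------
# Taxonomy and sequences


def simulate_taxonomy(
    n_species: int,
    seed: int,
    n_genera: int = 3,
    refs_per_species: int = 1,
    ref_length: int = 6000,
) -> tuple[Taxonomy, list[tuple[Contig, int]]]:
    """Three-level tree (root -> genera -> species) plus reference genomes.

    Species are assigned round-robin to genera; references are seeded
    uniform-base sequences, ``refs_per_species`` per species leaf.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    n_genera = min(n_genera, n_species)
    nodes: dict[int, tuple[int, str, str]] = {1: (1, "root", "root")}
    genus_ids = [10 + g for g in range(n_genera)]
    for g, gid in enumerate(genus_ids):
        nodes[gid] = (1, "genus", f"genus_{g}")
    species_ids = [100 + s for s in range(n_species)]
    for s, sid in enumerate(species_ids):
        nodes[sid] = (genus_ids[s % n_genera], "species", f"species_{s}")
    taxonomy = Taxonomy.from_nodes(nodes)

    rng = np.random.default_rng(seed)
    refs: list[tuple[Contig, int]] = []
    for s, sid in enumerate(species_ids):
        for r in range(refs_per_species):
            seq = random_sequence(ref_length, rng)
            refs.append((Contig(id=f"ref_s{s}_{r}", sequence=seq), sid))
    return taxonomy, refs


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_contig(
    ref: Contig,
    designed_identity: float,
    designed_coverage: float,
    seed: int,
    contig_id: str | None = None,
) -> tuple[Contig, TruthRecord]:
    """Derive a contig from a reference window with point substitutions.

    A contiguous window of ``designed_coverage * ref.length`` bases is cut
    at a seeded random start, and each base is substituted (to one of the
    three other bases) independently with probability 1 - designed_identity.
    The truth record stores the realized identity counted by direct
    comparison against the window.
    """
    if not 0.0 <= designed_identity <= 1.0:
        raise ValueError("designed_identity must be in [0, 1]")
    if not 0.0 < designed_coverage <= 1.0:
        raise ValueError("designed_coverage must be in (0, 1]")
    win_len = int(round(designed_coverage * ref.length))
    if win_len < 1:
        raise ValueError("window length < 1")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, ref.length - win_len + 1))
    window = np.frombuffer(
        ref.sequence[start : start + win_len].encode("ascii"), dtype=np.uint8
    ).copy()
    original = window.copy()
    mutate = rng.random(win_len) < (1.0 - designed_identity)
    if mutate.any():
        # shift each mutated base by 1..3 within {A,C,G,T}: always a change
        codes = np.searchsorted(_BASES, window[mutate])  # ACGT are sorted
        shift = rng.integers(1, 4, size=int(mutate.sum()))
        window[mutate] = _BASES[(codes + shift) % 4]
    realized = float((window == original).mean())
    cid = contig_id or f"{ref.id}_m"
    contig = Contig(id=cid, sequence=window.tobytes().decode("ascii"))
    truth = TruthRecord(
        contig_id=cid,
        source_taxid=None,
        designed_identity=designed_identity,
        realized_identity=realized,
        designed_coverage=designed_coverage,
        designed_category="",
    )
    return contig, truth


# ---------------------------------------------------------------------------
# Rule oracles (independent of the triage / domain_filter implementations)


def _triage_region(ani: float, coverage: float) -> str:
    """Direct region membership on the (ani, coverage) plane at defaults."""
    if ani > 0.85 and coverage > 0.8:
        return "known_known"
    if ani > 0.85 and 0.5 < coverage <= 0.8:
        return "known_unknown_1"
    if 0.5 < ani <= 0.85 and coverage > 0.5:
        return "known_unknown_2"
    return "unknown_unknown"


def _domain_rule_oracle(counts: Mapping[str, int], archaea_prok: bool = True) -> tuple[str, int]:
    viral = counts.get("viral", 0)
    euk = counts.get("eukaryotic", 0)
    prok = counts.get("bacterial", 0) + (counts.get("archaeal", 0) if archaea_prok else 0)
    total = sum(counts.values())
    if viral == 0 and euk > 3 and prok > 3:
        return "fail", 1
    if viral == 0 and euk > 3:
        return "fail", 2
    if viral == 0 and prok > 3:
        return "fail", 3
    if total == 0:
        return "pass", 1
    if viral > 0:
        return "pass", 2
    return "pass", 3


# ---------------------------------------------------------------------------
# Alignment and domain tables


def synth_alignment_table(
    contigs_with_truth: Sequence[tuple[Contig, TruthRecord]],
    refs: Sequence[tuple[Contig, int]],
) -> list[AlignmentRecord]:
    """One alignment record per reference-derived contig.

    The record describes the (only) local alignment a search would find:
    the full mutated window against its source reference, so
    align_len = qlen = contig length and pident = realized identity. The
    E-value is a stated monotone map of the identity count,
    10^(-min(200, identities / 5)); bitscore is twice the identity count.
    Dark-matter contigs emit no records.
    """
    ref_ids = {tid: c.id for c, tid in refs}
    records: list[AlignmentRecord] = []
    for contig, truth in contigs_with_truth:
        if truth.source_taxid is None:
            continue
        qlen = contig.length
        identities = int(round(truth.realized_identity * qlen))
        evalue = 10.0 ** (-min(200.0, identities / 5.0))
        records.append(
            AlignmentRecord(
                qacc=contig.id,
                sacc=ref_ids[truth.source_taxid],
                pident=100.0 * identities / qlen,
                align_len=qlen,
                evalue=evalue,
                bitscore=2.0 * identities,
                qlen=qlen,
            )
        )
    return records


#: Group-count ranges per scenario; every draw inside a range lands in the
#: scenario's pass/fail category (verified by the rule oracle at draw time).
DOMAIN_SCENARIOS: dict[str, dict[str, tuple[int, int]]] = {
    "fail_1": {"viral": (0, 0), "bacterial": (4, 8), "eukaryotic": (4, 8), "unknown": (0, 2)},
    "fail_2": {"viral": (0, 0), "bacterial": (0, 2), "eukaryotic": (4, 8), "unknown": (0, 2)},
    "fail_3": {"viral": (0, 0), "bacterial": (4, 8), "eukaryotic": (0, 2), "unknown": (0, 2)},
    "pass_1": {},  # dark matter: no hits at all
    "pass_2": {"viral": (1, 4), "bacterial": (0, 8), "eukaryotic": (0, 8), "unknown": (0, 2)},
    "pass_3": {"viral": (0, 0), "bacterial": (0, 3), "eukaryotic": (0, 3), "unknown": (0, 3)},
}


def synth_domain_table(
    scenario_by_contig: Mapping[str, str],
    seed: int,
    scenarios: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
    max_evalue: float = 1e-3,
) -> tuple[list[DomainHitRecord], dict[str, str], dict[str, tuple[str, int]]]:
    """Draw per-contig domain hits from scenario count distributions.

    Returns (hit records, accession -> group map, contig -> truth
    (status, category)). Truth is computed by the local rule oracle on the
    drawn counts. Accessions are group-consistent synthetic CDD-style ids;
    E-values are drawn strictly below the cut-off.
    """
    scenarios = scenarios or DOMAIN_SCENARIOS
    rng = np.random.default_rng(seed)
    hits: list[DomainHitRecord] = []
    group_map: dict[str, str] = {}
    truth: dict[str, tuple[str, int]] = {}
    for contig_id in sorted(scenario_by_contig):
        tag = scenario_by_contig[contig_id]
        if tag not in scenarios:
            raise KeyError(f"unknown domain scenario {tag!r}")
        counts: dict[str, int] = {}
        for group, (lo, hi) in scenarios[tag].items():
            counts[group] = int(rng.integers(lo, hi + 1))
        for group, n in counts.items():
            for i in range(n):
                acc = f"cd_{group}_{int(rng.integers(0, 1000)):03d}"
                group_map[acc] = group
                evalue = 10.0 ** float(-rng.uniform(4.0, 30.0))
                assert evalue < max_evalue
                hits.append(DomainHitRecord(contig_id, acc, evalue))
        truth[contig_id] = _domain_rule_oracle(counts)
    return hits, group_map, truth


# ---------------------------------------------------------------------------
# Full fixture


def make_fixture(config: SimulationConfig | None = None) -> dict:
    """Generate the standard fixture: every pipeline input plus ground truth.

    Returns a dict with keys ``taxonomy``, ``refs``, ``contigs``,
    ``alignments``, ``domain_hits``, ``group_map`` and ``truth`` (a list of
    TruthRecord). Reference-derived contigs cycle through the configured
    identity and coverage levels; the leading ``dark_matter_fraction`` of
    contigs are pure random sequence. Domain scenarios are assigned
    round-robin over the contigs designed unknown_unknown (dark-matter
    contigs always take the no-hit scenario).
    """
    config = config or SimulationConfig()
    taxonomy, refs = simulate_taxonomy(
        config.n_species, config.seed, config.n_genera,
        config.refs_per_species, config.ref_length,
    )
    rng = np.random.default_rng(config.seed + 1)
    n_dark = int(round(config.dark_matter_fraction * config.n_contigs))

    contigs: list[Contig] = []
    truths: list[TruthRecord] = []
    plan_i = 0
    for i in range(config.n_contigs):
        cid = f"contig_{i:04d}"
        if i < n_dark:
            length = int(round(
                config.coverage_levels[i % len(config.coverage_levels)]
                * config.ref_length
            ))
            contigs.append(Contig(id=cid, sequence=random_sequence(length, rng)))
            truths.append(TruthRecord(
                contig_id=cid, source_taxid=None,
                designed_identity=0.0, realized_identity=0.0,
                designed_coverage=1.0, designed_category="unknown_unknown",
            ))
            continue
        identity = config.identity_levels[plan_i % len(config.identity_levels)]
        coverage = config.coverage_levels[
            (plan_i // len(config.identity_levels)) % len(config.coverage_levels)
        ]
        ref, taxid = refs[plan_i % len(refs)]
        plan_i += 1
        contig, truth = mutate_contig(
            ref, identity, coverage, seed=int(rng.integers(0, 2**31)), contig_id=cid,
        )
        # the emitted alignment spans the whole contig, so the effective
        # query-relative ani equals the realized identity and coverage is 1
        qlen = contig.length
        ani = round(truth.realized_identity * qlen) / qlen
        category = _triage_region(ani, 1.0)
        truths.append(TruthRecord(
            contig_id=cid, source_taxid=taxid,
            designed_identity=identity,
            realized_identity=truth.realized_identity,
            designed_coverage=coverage,
            designed_category=category,
        ))
        contigs.append(contig)

    # short contigs removed by the 1 kb filter
    for j in range(config.n_short_contigs):
        cid = f"short_{j:02d}"
        contigs.append(Contig(id=cid, sequence=random_sequence(500, rng)))
        truths.append(TruthRecord(
            contig_id=cid, source_taxid=None,
            designed_identity=0.0, realized_identity=0.0,
            designed_coverage=1.0, designed_category="unknown_unknown",
            passes_length_filter=False,
        ))

    alignments = synth_alignment_table(
        [(c, t) for c, t in zip(contigs, truths) if t.source_taxid is not None],
        refs,
    )

    # domain scenarios over the designed unknown_unknowns (>= 1 kb)
    scenario_tags = [t for t in DOMAIN_SCENARIOS if t != "pass_1"]
    scenario_by_contig: dict[str, str] = {}
    uu_i = 0
    for truth in truths:
        if truth.designed_category != "unknown_unknown" or not truth.passes_length_filter:
            continue
        if truth.source_taxid is None and truth.designed_identity == 0.0 and uu_i % 2 == 0:
            scenario_by_contig[truth.contig_id] = "pass_1"
        else:
            scenario_by_contig[truth.contig_id] = scenario_tags[uu_i % len(scenario_tags)]
        uu_i += 1
    domain_hits, group_map, domain_truth = synth_domain_table(
        scenario_by_contig, seed=config.seed + 2
    )
    truths = [
        t if t.contig_id not in domain_truth else TruthRecord(
            **{**asdict(t),
               "domain_scenario": scenario_by_contig[t.contig_id],
               "designed_domain_status": domain_truth[t.contig_id][0],
               "designed_domain_category": domain_truth[t.contig_id][1]}
        )
        for t in truths
    ]
    return {
        "taxonomy": taxonomy,
        "refs": refs,
        "contigs": contigs,
        "alignments": alignments,
        "domain_hits": domain_hits,
        "group_map": group_map,
        "truth": truths,
        "config": config,
    }


def write_fixture(fixture: Mapping, out_dir: str | Path) -> dict[str, Path]:
    """Write a fixture to disk in the pipeline's external formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": out / "contigs.fasta",
        "refs": out / "refs.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "alignments": out / "alignments.tsv",
        "domains": out / "domains.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(fixture["contigs"], paths["contigs"])
    write_fasta([c for c, _ in fixture["refs"]], paths["refs"])
    write_taxonomy_table(fixture["taxonomy"].nodes, paths["taxonomy"])
    write_alignment_table(fixture["alignments"], paths["alignments"])
    with open(paths["domains"], "w") as fh:
        for hit in fixture["domain_hits"]:
            fh.write(f"{hit.contig_id}\t{hit.domain_acc}\t{hit.evalue:.6g}\n")
    with open(paths["groups"], "w") as fh:
        for acc in sorted(fixture["group_map"]):
            fh.write(f"{acc}\t{fixture['group_map'][acc]}\n")
    with open(paths["truth"], "w") as fh:
        json.dump([asdict(t) for t in fixture["truth"]], fh, indent=1)
        fh.write("\n")
    return paths
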