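"""K-mer LCA taxonomic classification.

Builds a map from canonical 32-mers to taxonomy nodes: each k-mer is
assigned to the lowest common ancestor (LCA) of every reference sequence
containing it, so a k-mer shared across a genus points at the genus while a
species-private k-mer points at the species. Classification of a query then
counts the indexed k-mers it carries per node and scores each leaf by the
total count along its root-to-leaf path (Kraken-style); the best leaf's
path score over the total indexed k-mer count is reported as the call's
probability. Ties among leaves collapse to their LCA.

Also provides the reference-subsampling step used before index
construction: a seeded random sample per species for ordinary genomes, and
keep-all-then-deduplicate (by MinHash sketch distance) for segmented
genomes such as influenza.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import Contig
from .sketch import Sketch, jaccard_estimate, make_sketch, sketch_distance

__all__ = [
    "Taxonomy",
    "KmerIndex",
    "TaxonCall",
    "lca",
    "build_index",
    "classify_sequence",
    "select_references",
    "write_index",
    "read_index",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# Taxonomy


@dataclass(frozen=True)
class Taxonomy:
    """A rooted taxonomic tree: taxid -> (parent_taxid, rank, name).

    The root is its own parent; every other node's parent chain must reach
    the root without cycles.
    """

    nodes: dict[int, tuple[int, str, str]]
    root: int

    def __post_init__(self) -> None:
        if self.root not in self.nodes:
            raise ValueError(f"root {self.root} not among nodes")
        if self.nodes[self.root][0] != self.root:
            raise ValueError("root must be its own parent")
        for tid in self.nodes:
            # walk to root, guarding against cycles
            seen = {tid}
            cur = tid
            while cur != self.root:
                cur = self.nodes[cur][0]
                if cur not in self.nodes:
                    raise ValueError(f"node {tid} has parent {cur} outside the tree")
                if cur in seen:
                    raise ValueError(f"cycle through node {cur}")
                seen.add(cur)

    @classmethod
    def from_nodes(cls, nodes: Mapping[int, tuple[int, str, str]]) -> "Taxonomy":
        roots = [tid for tid, (parent, _, _) in nodes.items() if parent == tid]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one self-parented root, found {roots}")
        return cls(nodes=dict(nodes), root=roots[0])

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid][0]

    def path_to_root(self, taxid: int) -> list[int]:
        """Node list from ``taxid`` up to and including the root."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.parent(path[-1]))
        return path

    def leaves(self) -> list[int]:
        parents = {self.nodes[t][0] for t in self.nodes if t != self.root}
        return sorted(t for t in self.nodes if t not in parents)

    def children(self, taxid: int) -> list[int]:
        return [t for t, (p, _, _) in self.nodes.items() if p == taxid and t != taxid]


def lca(taxonomy: Taxonomy, a: int, b: int) -> int:
    """Deepest node that is an ancestor-or-self of both ``a`` and ``b``."""
    ancestors_a = set(taxonomy.path_to_root(a))
    for node in taxonomy.path_to_root(b):
        if node in ancestors_a:
            return node
    return taxonomy.root  # unreachable for a well-formed tree


def _lca_many(taxonomy: Taxonomy, taxids: Iterable[int]) -> int:
    it = iter(taxids)
    acc = next(it)
    for t in it:
        acc = lca(taxonomy, acc, t)
    return acc


# ---------------------------------------------------------------------------
# Index construction


@dataclass(frozen=True)
class KmerIndex:
    """Canonical k-mer -> taxid map with its word size and sampling stride."""

    k: int
    entries: dict[str, int]
    sampling_stride: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.sampling_stride < 1:
            raise ValueError("sampling_stride must be >= 1")
        bad = next((m for m in self.entries if len(m) != self.k), None)
        if bad is not None:
            raise ValueError(f"entry {bad!r} does not have length k={self.k}")


def _sampled_canonical_kmers(seq: str, k: int, stride: int) -> Iterable[str]:
    for pos in range(0, len(seq) - k + 1, stride):
        kmer = seq[pos : pos + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        yield canonical_kmer(kmer)


def build_index(
    references: Sequence[tuple[Contig, int]],
    taxonomy: Taxonomy,
    k: int = 32,
    sampling_stride: int = 1,
) -> KmerIndex:
    """Assign each sampled canonical k-mer to the LCA of the references carrying it.

    References shorter than ``k`` contribute nothing. K-mers containing
    non-ACGT characters are skipped.
    """
    for _, taxid in references:
        if taxid not in taxonomy.nodes:
            raise KeyError(f"unknown reference taxid {taxid}")
    entries: dict[str, int] = {}
    for contig, taxid in references:
        for kmer in set(_sampled_canonical_kmers(contig.sequence, k, sampling_stride)):
            if kmer in entries:
                entries[kmer] = lca(taxonomy, entries[kmer], taxid)
            else:
                entries[kmer] = taxid
    return KmerIndex(k=k, entries=entries, sampling_stride=sampling_stride)


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class TaxonCall:
    """Classification outcome for one query sequence.

    ``path_scores`` maps candidate taxids (leaves, plus the reported LCA on
    a tie) to their root-to-node k-mer count sums. ``probability`` is the
    best path score over the total number of indexed k-mers observed.
    """

    contig_id: str
    best_taxid: int | None
    probability: float
    total_indexed_kmers: int
    path_scores: dict[int, int] = field(default_factory=dict)


def classify_sequence(
    index: KmerIndex,
    taxonomy: Taxonomy,
    contig: Contig,
    min_probability: float = 0.1,
) -> TaxonCall:
    """Classify one sequence against the index.

    Every canonical k-mer found in the index adds one count to its node.
    Each leaf is scored by the summed counts along its root-to-leaf path;
    the call is the argmax leaf (ties resolve to the LCA of all tied
    leaves). Calls below ``min_probability`` are reported unclassified
    while retaining the path scores.
    """
    counts: dict[int, int] = {}
    total = 0
    seq = contig.sequence
    k = index.k
    for pos in range(0, len(seq) - k + 1):
        kmer = seq[pos : pos + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        taxid = index.entries.get(canonical_kmer(kmer))
        if taxid is not None:
            counts[taxid] = counts.get(taxid, 0) + 1
            total += 1
    if total == 0:
        return TaxonCall(contig.id, None, 0.0, 0, {})

    # score leaves below any counted node
    path_scores: dict[int, int] = {}
    for leaf in _candidate_leaves(taxonomy, counts):
        path_scores[leaf] = sum(counts.get(n, 0) for n in taxonomy.path_to_root(leaf))
    best_score = max(path_scores.values())
    tied = sorted(t for t, s in path_scores.items() if s == best_score)
    best = tied[0] if len(tied) == 1 else _lca_many(taxonomy, tied)
    path_scores.setdefault(best, best_score)
    probability = best_score / total
    if probability < min_probability:
        best = None
    return TaxonCall(contig.id, best, probability, total, path_scores)


def _candidate_leaves(taxonomy: Taxonomy, counts: Mapping[int, int]) -> set[int]:
    """Leaves of the subtrees rooted at counted nodes (incl. counted leaves)."""
    children: dict[int, list[int]] = {}
    for tid, (parent, _, _) in taxonomy.nodes.items():
        if tid != parent:
            children.setdefault(parent, []).append(tid)
    leaves: set[int] = set()
    stack = list(counts)
    seen: set[int] = set()
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        kids = children.get(node, [])
        if not kids:
            leaves.add(node)
        else:
            stack.extend(kids)
    return leaves


# ---------------------------------------------------------------------------
# Reference subsampling


def select_references(
    references: Sequence[tuple[Contig, int, bool]],
    n_per_species: int = 3,
    dedup_distance: float = 0.05,
    seed: int = 0,
    sketch_k: int = 21,
    sketch_size: int = 10000,
) -> list[tuple[Contig, int]]:
    """Subsample references per species before index construction.

    Non-segmented species: a uniform random sample of at most
    ``n_per_species`` sequences (seeded). Segmented species: all sequences
    are kept, then greedily deduplicated in input order — a sequence is
    dropped when its sketch distance to an already-kept sequence of the
    same species falls below ``dedup_distance``.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    if not 0.0 <= dedup_distance <= 1.0:
        raise ValueError("dedup_distance must be in [0, 1]")
    rng = random.Random(seed)

    by_species: dict[int, list[tuple[int, Contig, bool]]] = {}
    for order, (contig, taxid, segmented) in enumerate(references):
        by_species.setdefault(taxid, []).append((order, contig, segmented))

    kept: list[tuple[int, Contig, int]] = []  # (input order, contig, taxid)
    for taxid in sorted(by_species):
        group = by_species[taxid]
        segmented = any(seg for _, _, seg in group)
        if not segmented:
            sample = group if len(group) <= n_per_species else rng.sample(group, n_per_species)
            kept.extend((order, contig, taxid) for order, contig, _ in sample)
        else:
            retained: list[tuple[int, Contig, Sketch]] = []
            for order, contig, _ in group:  # input order within species
                sk = make_sketch(contig, k=sketch_k, size=sketch_size)
                dup = any(
                    sketch_distance(jaccard_estimate(sk, prev_sk), sketch_k)
                    < dedup_distance
                    for _, _, prev_sk in retained
                )
                if not dup:
                    retained.append((order, contig, sk))
            kept.extend((order, contig, taxid) for order, contig, _ in retained)
    kept.sort(key=lambda t: t[0])
    return [(contig, taxid) for _, contig, taxid in kept]


# ---------------------------------------------------------------------------
# Index serialization (sorted two-column text, for inspection and diffing)


def write_index(index: KmerIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={index.k}\tstride={index.sampling_stride}\n")
        for kmer in sorted(index.entries):
            fh.write(f"{kmer}\t{index.entries[kmer]}\n")


def read_index(path: str | Path) -> KmerIndex:
    entries: dict[str, int] = {}
    k = None
    stride = 1
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].split("\t"):
                    key, _, val = part.partition("=")
                    if key == "k":
                        k = int(val)
                    elif key == "stride":
                        stride = int(val)
                continue
            if not line:
                continue
            kmer, taxid = line.split("\t")
            entries[kmer] = int(taxid)
    if k is None:
        k = len(next(iter(entries))) if entries else 32
    return KmerIndex(k=k, entries=entries, sampling_stride=stride)
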