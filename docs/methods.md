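# Methods

This note documents the models and procedures implemented in `virotriage`,
the parameter defaults and why they were chosen, the numerical details that
affect results, and the limits of what the synthetic fixtures can
establish.

## K-mer MRCA index and classification

**Model.** Each reference genome is decomposed into canonical k-mers
(k = 32 by default; the canonical form is the lexicographic minimum of a
k-mer and its reverse complement, making every downstream call
strand-invariant). A k-mer found in several references is stored under the
most recent common ancestor (MRCA) of their taxa, computed by iterated
pairwise LCA over the taxonomy; a k-mer private to one reference is stored
under that reference's taxon. K-mers containing non-ACGT characters are
skipped. The invariant — every stored taxid is an ancestor-or-self of every
source reference's taxid — is brute-force checked in the tests.

**Classification.** Every canonical k-mer of a query found in the index
adds one count to its stored node. Each taxonomy leaf is scored by the sum
of counts over its root-to-leaf path (so evidence at a genus node supports
all species under it), and the query is called to the argmax leaf with
`probability = path_score / total_indexed_kmers`. Ties among leaves
collapse to the LCA of all tied leaves — in particular, counts split evenly
between two sister species yield a genus-level call. Calls below
`min_probability` (default 0.1; arbitrary but configurable) are reported
unclassified while retaining the per-leaf scores.

This leaf-path scoring is one defensible concretization of
"probability of containing a taxon given the k-mer frequencies"; the
production system it emulates is unpublished, so the exact probability
model is a design choice of this package, recorded here.

**Reference subsampling.** Because reference sets are skewed toward
well-studied viruses, only `n_per_species` (default 3 — a deliberately
small "few", configurable) genomes per species are sampled uniformly at
random (seeded) before indexing. Segmented viruses (e.g. influenza) are
exempt: all their sequences are kept and then greedily deduplicated in
input order, dropping any sequence whose MinHash sketch distance to an
already-kept same-species sequence is below `dedup_distance` (default
0.05 ≈ 95% identity; not a published value, chosen as the conventional
species-level Mash radius). Exact duplicates (distance 0) are always
removed.

## Triage

Contigs shorter than 1 kb are removed (inclusive boundary: length ≥ 1000
is kept, since the rule removes contigs *shorter than* 1 kb). Alignments
are reduced to one HSP per query–subject pair (highest bitscore, ties by
lowest E-value, then first occurrence), and hits above the E-value cut-off
are ignored. Two cut-offs are in circulation for this workflow — 1e-10 for
the all-vs-all comparison and 1e-3 for the reference screen; the default is
1e-3 and both are plain configuration, neither is hard-coded.

Each surviving hit is scored by

    ani      = round(pident/100 × align_len) / qlen
    coverage = align_len / qlen

The identity count is reconstructed from percent identity because the
tabular format does not carry it; this is exact for ungapped alignments
and a documented approximation otherwise. Coverage may exceed 1 for gapped
alignments.

Hit categories on the (ani, coverage) plane, thresholds strict as printed:

| category        | ani            | coverage       |
|-----------------|----------------|----------------|
| known_known     | > 0.85         | > 0.8          |
| known_unknown_1 | > 0.85         | (0.5, 0.8]     |
| known_unknown_2 | (0.5, 0.85]    | > 0.5          |
| unknown_unknown | everything else, including no hit |

Interval edges are inclusive on the upper edge of the lower category, so
boundary mass falls downward deterministically. A contig's category is the
best category over its hits (the aggregation rule is not published; taking
the strongest evidence matches how the known–known tallies are reported),
with the reported subject being the highest-bitscore hit achieving it.

**A structural caveat.** With ani defined query-relative,
`identities ≤ align_len` forces `ani ≤ coverage`, so the known_unknown_1
region (ani > 0.85, coverage ≤ 0.8) contains no point realizable by an
actual alignment record — a workflow computing these two formulas verbatim
would leave that bin empty, and populating it requires reading "identity"
as per-alignment identity instead. This package implements the formulas as
printed and keeps the region in the classifier (it is exercised on the
abstract grid in the tests); the synthetic fixture therefore designs
contigs only into the three reachable categories. The region-membership
oracle in the test suite is written independently from the category text
and agrees exactly on the full grid {0, 0.05, …, 1.2}².

## Similarity graph and Markov clustering

Every query and subject id becomes a node; each unordered pair with
qacc ≠ sacc becomes one edge weighted `min(−log10 E, 200)` (E = 0 takes the
cap, E ≥ 1 clamps to 0). When the two directions of a pair disagree, the
maximum weight is kept — mirroring must produce a single symmetric value
and max preserves the strongest evidence. Self-alignments contribute only
the node.

MCL runs on the column-stochastic weighted adjacency matrix with one
self-loop per node at its maximum incident edge weight (isolated nodes get
1) — loops guarantee convergence and this rule keeps them on the scale of
the node's own edges. Each iteration applies expansion (matrix power,
default 2), inflation (entrywise power 10, then column renormalization),
pruning of entries below 1e-5, and renormalization, until the maximum
entrywise change falls below 1e-8 or 100 iterations elapse (non-convergence
returns the current state with a warning, not an error). Inflation 10 is
the published operating point; pruning and convergence tolerances are
implementation necessities for a terminating sparse algorithm and are
configurable. Clusters are the connected components of the nonzero
structure of the limit matrix — a deterministic partition even when
attractor systems overlap. Column sums stay within 1e-9 of 1 after every
normalization (exposed as `max_column_dev` for auditing), and the sparse
implementation is held to *identical* partitions with an independently
written naive dense MCL on 50 seeded random graphs, plus exact recovery
(ARI = 1.0) of a planted 3×10 partition.

## Conserved-domain taxon voting

Domain hits at E ≤ 1e-3 are tallied per taxon group (viral, bacterial,
archaeal, eukaryotic, unknown); accessions missing from the group map count
as unknown, mirroring databases' unassigned-organism entries. Counting is
per hit record, not per distinct accession. The cut-off is applied at
counting time (whether the upstream search or the grouping step applied it
is not observable from the tables consumed here).

Categories are evaluated in order — fail 1: > 3 eukaryotic AND > 3
prokaryotic hits with zero viral; fail 2: > 3 eukaryotic, zero viral;
fail 3: > 3 prokaryotic, zero viral; pass 1: no hits at all (dark matter);
pass 2: any viral hit; pass 3: the rest. Evaluating fail 1 first makes the
six bins mutually exclusive (its condition is the conjunction of the other
two fail triggers). "More than three" is strict (> 3). Because the two
published phrasings of the exclusion rule differ on archaea, the
prokaryotic tally is bacterial + archaeal by default
(`bacterial_plus_archaeal`) with a `bacterial_only` mode; neither is
asserted as the original intent. Relative profiles divide each group count
by the contig's total hit count (all-zero when there are no hits). Adding
a viral hit can never move a contig from pass to fail (property-tested).

## MinHash sketching

A sketch is the 10,000 smallest distinct 64-bit hashes over a sequence's
canonical 21-mers (both parameters are the published operating point).
Hashing packs each canonical k-mer into 2 bits/base (hence k ≤ 31) and
applies the splitmix64 finalizer — a fixed, well-mixed, cross-platform
bit-stable function, chosen because the original workflow delegates hashing
to an external tool whose seed is unstated. The Jaccard estimate is the
bottom-sketch estimator: |A ∩ B ∩ bottom_s(A ∪ B)| / |bottom_s(A ∪ B)|.
The Mash-style distance is `−(1/k)·ln(2j/(1+j))`, capped at 1, with j = 0
mapped to 1 (the transform diverges there) and j = 1 to 0. Against exact
Jaccard over full canonical k-mer sets (brute force), the estimator is
within 0.02 on ≥ 95% of seeded 100 kb pairs at mutation rates 0–5%.

## Synthetic fixtures

The generator states a world at desk scale: a three-level taxonomy (root →
genera → species, species round-robin over genera) with seeded
uniform-base reference genomes (default: 6 species, 3 genera, one 6 kb
genome each; 10 species × 20 kb in the classifier-recovery tests); contigs
cut from reference windows (window length = designed coverage × reference
length) with independent point substitutions at rate 1 − designed identity.
Identity levels 0.97 / 0.70 / 0.30 place contigs firmly inside the
known_known / known_unknown_2 / unknown_unknown regions (≥ 0.03 from every
threshold at these window lengths, so binomial noise cannot cross a
boundary); a fifth of contigs are pure random sequence (dark matter), and
two sub-1-kb contigs exercise the length filter. Truth records store the
*realized* identity counted by direct comparison, and truth categories come
from rule oracles local to the generator, independent of the triage and
domain-filter implementations.

Substitutions only, no indels — identity is then exact Hamming identity and
pident/align_len are unambiguous. Synthetic E-values are a stated monotone
map of the identity count, `10^(−min(200, identities/5))`: triage uses
E-values only as a pass/fail gate, so only ordering and threshold behavior
matter, and no alignment-statistics model is implied. Emitted alignments
span the whole contig (align_len = qlen), so effective coverage is 1 and
the designed category is driven by identity; partial-coverage hits are not
emulated (see the triage caveat above). Domain-hit scenarios draw group
counts from ranges that realize all six pass/fail categories, with
accessions named for their group and E-values strictly below the cut-off.

A green end-to-end test therefore establishes that the pipeline reproduces
designed categories under clean, substitution-only, single-hit conditions.
It does not establish robustness to indels, chimeric contigs, repeat-driven
spurious alignments, multi-hit aggregation conflicts, or real E-value
statistics.

## Pipeline

Stages run in discovery order: length filter → HSP reduction → triage →
graph construction + MCL on the filtered alignment set → domain voting on
exactly the unknown_unknown set. The k-mer screen is an optional pre-stage
that annotates contigs without removing them (in the original workflow it
acted upstream, during read classification and assembly, which is out of
scope here — keeping it non-destructive preserves the downstream counts).
Each stage writes a JSON report (`stage`, `parameters` echoing every
threshold, `records`); reports are byte-reproducible across reruns given
the same inputs. Stage counts are non-increasing along the funnel.

## Known limitations

- The known_unknown_1 bin is unpopulatable under the query-relative ANI
  formula (detailed above); real partial-coverage remote homologs land in
  known_unknown_2 or unknown_unknown instead.
- The k-mer classifier's probability model is a reconstruction, not the
  unpublished original; absolute probabilities should be read as
  normalized path scores, not calibrated posteriors.
- Sparse MCL equals the dense reference on the tested scales; at very
  different scales pruning could in principle change a marginal partition
  (prune threshold is configurable down to 0 for an exact run).
- The sketch hasher supports k ≤ 31 (2-bit packing); the k-mer taxonomy
  index has no such limit.
- Desk-scale only: the cluster-scale headline numbers of the original
  study (millions of contigs, 2.3M clusters) are out of reach by design;
  correctness is established by oracles, not by reproducing those counts.
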