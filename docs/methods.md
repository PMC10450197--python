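# Methods

This note documents the models and procedures implemented in
`plasmidnet`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the design decisions taken where
the procedure was genuinely open.

## MinHash sketching and distances

All similarity decisions run on bottom-`s` MinHash sketches of
canonical k-mers (`k = 17`, `s = 3000` by default). A canonical k-mer
is the lexicographic minimum of the k-mer and its reverse complement,
so contig strand never affects a distance. k-mers containing non-ACGT
symbols are skipped rather than substituted, because draft genomes
contain N runs and substitution would fabricate sequence. Hashing is
the splitmix64 finalizer over the 2-bit k-mer code, xor-folded with a
fixed constant seed: sketches are bit-identical across runs and
platforms, and the hash is a 64-bit bijection, so distinct canonical
k-mers never collide.

The distance estimator is the Mash formula
`d = −(1/k)·ln(2j/(1+j))`, with `j` the Jaccard index estimated from
the `s` smallest hashes of the union of two sketches. When no hashes
are shared the distance is capped at exactly 1.0. Whenever
`s ≥ |union of canonical k-mer sets|` the estimate equals the exact
Jaccard, which is what the test-suite oracle exploits: brute-force set
enumeration certifies the fast path. Near identity the distance tracks
1 − ANI; sequences at a planted 99% identity land in [0.005, 0.02],
which is why 0.01 is a sound clustering cutoff for ~99%-ANI groups.
The sketch size used for the fragment-database comparison is a
configuration knob (`s` per stage); the vote only counts fragments
under a generous 0.15 cutoff, so it is insensitive to `s` well below
the default.

## Reference fragment database

Labeled replicons are tiled into non-overlapping 200 kb fragments
(most plasmids are shorter and stay whole). The windowing exists
because a 2–200 kb query against an unfragmented multi-Mb chromosome
has a tiny Jaccard even at perfect identity, which would inflate
distances for chromosome-like queries. Fragments closer than 0.02 are
clustered with MCL on the unweighted adjacency graph and reduced to
one representative per cluster — the longest member, ties broken by
id. A mixed-origin cluster (a plasmid fragment grouping with a
chromosome fragment) keeps one representative per origin, because the
downstream vote counts labels and silently erasing a label class would
bias it. MCL inflation defaults to 2.0 and is configurable; whether to
weight the graph is likewise exposed, with unweighted as the default.

## Marker selection

Gene families are scored by per-fragment presence/absence frequencies
on labeled plasmid fragments (FP) and chromosome fragments (FC) at
e-value ≤ 1e-3; a family hit twice in one fragment counts once (the
quantity is "fraction of fragments encoding the gene", not copy
number). Families with FP < 0.2% and FC < 0.2% are removed as
uninformative. PGMs are families with FP/FC > 7; CGMs are the 1400
surviving families with the smallest ratios, ties broken toward larger
FC then gene id. FC = 0 with FP above the floor yields ratio +∞ and
qualifies as a PGM: a family never observed on chromosomes is maximal
plasmid evidence. The frequency-estimation fragments are sampled with
lengths uniform on [2 kb, 200 kb] (capped at source length), seeded
and reproducible.

## PLS identification

Stage order is fixed: reference vote → marker rule on undetermined
contigs → phage screen on the union, which makes candidate I and
candidate II disjoint by construction. The vote is a raw count
comparison at distance < 0.15 with no distance weighting. Equal
nonzero hit counts are "ambiguous" and excluded from both candidacy
and the marker stage — such a contig did align to something, so it is
not "undetermined", and excluding it is the conservative-precision
choice. Zero hits is "undetermined" and goes to the marker stage,
where one PGM hit with zero CGM hits (e-value ≤ 1e-3) calls the
contig.

Keyword matching is centralized and case-insensitive over maximal
alphanumeric tokens of the product text. Phage keywords (terminase,
holin, head, tail, portal, capsid) match whole tokens only, so
"curtailed" does not trip "tail"; a single keyword hit vetoes the
contig, which also removes plasmid–phage elements. Backbone categories
(rep, rop, primase, mob, mbp, relaxase, conj, tra, trb, resolvase,
partition) match as token prefixes ("replication" → rep, "conjugal" →
conj, "partitioning" → partition), except that the short gene-symbol
stems `tra`/`trb` only match whole tokens or tokens of ≤ 5 characters
(TraG, TrbB) so that "transfer" and "transcriptional" do not fire.
`mbp` is matched literally but flagged in the decision log, since the
string is ambiguous between mobilization and maltose-binding protein.
Backbone detection uses the stricter e-value 1e-10.

## Clustering and retention

PLSs cluster into PLCs by complete linkage on the Mash distance matrix
cut at 0.01, delegated to scipy's hierarchical clustering; complete
linkage guarantees that every intra-cluster pair is within the cutoff,
which the tests assert directly on the matrix. The PLC representative
is the longest member. A candidate PLC is retained iff some member is
~100% complete or encodes backbone genes. Conjugative/mobilizable
labels are ingested from external annotation results, with conjugative
taking precedence (a PLC is mobilizable only if no member is
conjugative).

## Completeness

Two routes:

* **DTR route.** The longest terminal repeat with length ≥ 10 bp and
  ≤ 1 mismatch is found by scanning candidate lengths from the longest
  down (the scan is certified against a brute-force all-length oracle
  in the tests). The trailing repeat copy is trimmed and paired reads
  are mapped to the two 300-bp ends; a mate is an end hit when ≥ 90%
  of it aligns and ≥ 20 bp fall in the end window outside the DTR
  region. One pair anchoring both ends confirms the circle:
  completeness 1.0.
* **Graph route.** The PLS is anchored to its best-hit nodes in the
  isolate's FASTG assembly graph (orientation-aware node/edge model;
  reverse-complement records are normalised to orientation flags). The
  cycle through the anchors, in order, minimising total bp — not hop
  count, since completeness is a length ratio and the length-minimal
  cycle is the conservative gap estimate — is found by Dijkstra legs
  between consecutive anchors. Copy number per path node is
  `C = (A − min(Ap, Af))/Abase`, where `Ap`/`Af` sum the abundances of
  adjoining nodes on the two ends that are *not* on the path (on-path
  neighbours are excluded, resolving an ambiguity in the formula's
  wording); `C > 1.8` flags multi-copy, except nodes traversed in both
  orientations, which need `C > 2.8`. The path is validated by
  requiring every consecutive junction (including the closing one) to
  be bridged by a read pair with both mates mapped at ≥ 90% coverage
  to the two adjoining nodes; for a multi-copy node this enforces
  support to its specific upstream and downstream neighbours.

Completeness is `L_PLS / (L_PLS + L_G)`. `L_G` is, by default, the
summed length of path nodes not covered by the PLS (the gap the cycle
closes). The literal alternative — summing *all* path nodes — would
score a perfectly assembled single-node plasmid at ~50%, contradicting
the 100% route, so the gap reading is the default; the literal reading
remains available as `lg_mode="all_nodes"`. Fractions above 0.6 mark
comPLSs.

Read mapping throughout is a documented exact-match mini-mapper with
end soft-clipping (a junction-crossing read may clip at a contig end).
The contract is the coverage (≥ 0.9) and anchor (≥ 20 bp) thresholds,
not the mapper: the synthetic reads are error-free, and an external
mapper can replace it behind the same thresholds on real data. Cycle
search cost is polynomial (Dijkstra per anchor pair); unoriented
anchors are tried in both orientations with the combination count
capped.

## Network typing

For each complete-PLC representative the 3 nearest reference plasmids
under 0.15 are pulled in (ties at the third rank broken by smaller
distance then id), distances over the combined node set are
recomputed, and edges are drawn (unweighted) where distance < 0.15.
MCL at inflation 2.0 partitions the graph into NTGs; representatives
with no neighbour under the cutoff are reported as excluded
singletons. The MCL implementation is the standard dense
expansion/inflation iteration with self-loops, pruning, and
connected-component readout of the converged flow matrix.

## Ecology

Host range is the set of known genera over a PLC's member isolates;
"unknown" genera are excluded from the count, and ≥ 2 genera flags
broad host range. Presence of a PLC in a metagenome sample means *any*
member within 0.01 of *any* sample contig (≥ 2 kb) — all members are
compared, not just the representative, with sketches reused across
samples. Prevalence is the fraction of a population's samples with the
PLC, flagged highly prevalent strictly above 10%. Persistence is the
day span between first and last detection, where detection at a time
point counts any isolate sampled that day; the "persists ≥ N days"
summaries count spans ≥ N. Percentages are reported with half-up
rounding to one decimal.

## Haplotype networks and the transmission clock

Only members with an exact (mismatch 0) DTR ≥ 10 bp enter the
haplotype analysis — stricter than the completeness screen, because
haplotype columns must be trustworthy at single-base resolution. One
terminal repeat copy is trimmed and the sequence is canonicalised to
the lexicographically smallest string over all rotations of itself and
its reverse complement (Booth's algorithm), a deterministic,
orbit-invariant normalisation; any shared-anchor scheme would give the
same downstream distances. The multiple alignment is a center-star
progressive scheme against a median-length reference ("once a gap,
always a gap"), adequate for the > 99%-identical inputs this stage
sees; an externally computed alignment (one row per member) can be
supplied instead. Members with a gap run ≥ 2 against the reference are
removed as long-indel carriers; identical aligned rows (gap = fifth
character state) collapse into haplotypes, so haplotype distances are
plain Hamming distances over columns and reflect every difference,
including single-base indels.

The median-joining network iterates: build the minimum spanning
network (union of all tied minimum spanning trees, epsilon = 0,
uniform column weights), then for every connected node triple add the
columnwise-majority median vector if new, to a fixed point. Medians
are then pruned twice: first those lying on no shortest path between
observed haplotypes, then those whose presence does not strictly
reduce the total connection cost (the Steiner criterion); if the
surviving median set does not beat the observed-only tree it is
dropped wholesale. The emitted edge set is a deterministic minimum
spanning tree over the final vectors (ties broken by node id);
equal-cost alternative connections found during construction are not
enumerated. Consequently the network's total weight never exceeds the
MST over observed haplotypes alone, and every observed haplotype is
connected.

The transmission clock scales a per-genome mutation rate (default 30
mutations/year on a 1.67 Mb genome, a fast-evolving gut coloniser's
rate) to the plasmid: `λ = rate × L_plasmid / L_genome` per year. Zero
observed differences give the window [0, round(1/λ)] years — about 10
years for a 5.6-kb plasmid — and `n ≥ 1` differences give the point
estimate `n/λ`. The clock is linear and ignores selection and
recombination; it dates divergence, not transfer events.

## Synthetic data

The generators model unrelated replicons as independent uniform-ACGT
sequences: at k = 17 two such sequences share k-mers with vanishing
probability, so unrelated pairs sit at distance ~1 and all relatedness
is planted explicitly by copy-with-mutations, making expected
distances analytically predictable. Defaults are desk-scale: 20
plasmids of 5–30 kb and 10 chromosomes of 50–150 kb per reference set
(real chromosomes are Mb-scale; the workflow's 200 kb windowing makes
fragment-level behaviour identical), benchmark queries of 2 kb up to
the source length, assembly fixtures of ~8–12 kb plasmids in 4–6 graph
nodes with ≥ 300 bp per node so junction read pairs sit inside their
nodes, and error-free reads (read noise is outside every contract
tested). Haplotype fixtures mutate fresh, previously untouched
positions per tree edge, so planted pairwise distances are additive
along the tree.

What passing tests therefore show: the algorithms implement their
stated contracts exactly on data whose ground truth is known. What
they do not show: robustness to real-genome composition (repeats, GC
skew, shared mobile elements between plasmids and chromosomes),
sequencing error, or annotation noise — on real data the reference
vote and marker stages inherit whatever ambiguity the references and
annotations carry.

## Numerical and degenerate-input choices

* Distances are capped to [0, 1]; identical non-empty sketches give
  exactly 0, disjoint sketches exactly 1.
* Complete-linkage on a 1-element set returns the singleton; empty
  inputs return empty partitions.
* MCL that fails to converge within `max_iter` returns the current
  partition with a warning.
* DTR search requires `|seq| ≥ 2·min_len`; the search is capped (2 kb
  by default in the pipeline) since assembler-overlap repeats are
  short.
* `find_dtr` reports the *longest* qualifying repeat; the haplotype
  stage re-runs it at mismatch 0.
* Zero-abundance base nodes are rejected in copy-number estimation.
* Ratio ties at the CGM boundary and representative ties are broken
  deterministically (documented in each function).
* All generators are pure functions of (seed, parameters).

## Problem sizes

The test suite and the acceptance script run the full machinery at
reduced scale — reference sets of ~12 replicons, 40-query benchmarks
over 5 seeds, 8–9 kb assembly fixtures, haplotype populations of ≤ 12
members — sizes chosen so the whole suite completes in well under a
minute while still exercising every contract at non-trivial n. The
arithmetic checks (benchmark scoring, ratio summaries, the clock) are
scale-free.
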