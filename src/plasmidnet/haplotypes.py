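"""Haplotype collapse and median-joining networks for circular PLSs.

Members of a widespread PLC that assembled as circles (exact direct
terminal repeat >= 10 bp, zero mismatches) are trimmed of one terminal
repeat copy, rotation- and strand-normalised so cyclic permutation and
orientation cannot split a haplotype, multiply aligned, filtered for
long (>= 2 bp) indels against a median-length reference, and collapsed
into haplotypes: groups of rows identical over every alignment column,
with the gap counting as a fifth character state so single-base indels
separate haplotypes.  A median-joining network (Bandelt) connects the
haplotypes, adding inferred median (hypothetical) vectors where triples
demand them.  A linear mutation clock scaled from a reference genome
rate converts observed differences into a transmission-time window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .completeness import DTRResult, find_dtr
from .sketch import reverse_complement

HAP_MIN_DTR = 10
GENOME_RATE_PER_YEAR = 30.0
GENOME_LEN = 1_670_000
GAP = "-"


# ---------------------------------------------------------------------------
# member normalisation

@dataclass(frozen=True)
class NormalizedMember:
    member_id: str
    canonical_seq: str
    dtr_length: int
    donor: str = ""
    population: str = ""
    niche: str = ""


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    s2 = s + s
    f = [-1] * len(s2)
    k = 0
    for j in range(1, len(s2)):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(seq: str) -> str:
    """Smallest string over all rotations of ``seq`` and of its
    reverse complement; invariant on the rotation/strand orbit."""
    if not seq:
        raise ValueError("empty sequence")
    rc = reverse_complement(seq)
    i = _least_rotation(seq)
    j = _least_rotation(rc)
    return min(seq[i:] + seq[:i], rc[j:] + rc[:j])


def prepare_members(
    seqs: Mapping[str, str],
    min_dtr: int = HAP_MIN_DTR,
    origins: Mapping[str, tuple[str, str, str]] | None = None,
) -> list[NormalizedMember]:
    """Keep members with an exact (mismatch = 0) DTR >= ``min_dtr``;
    trim one terminal repeat copy and canonicalise rotation/strand."""
    out: list[NormalizedMember] = []
    for mid, seq in seqs.items():
        if len(seq) < 2 * min_dtr:
            continue
        dtr = find_dtr(seq, min_len=min_dtr, max_mismatch=0)
        if not dtr.found:
            continue
        trimmed = seq[: len(seq) - dtr.length]
        donor = population = niche = ""
        if origins and mid in origins:
            donor, population, niche = origins[mid]
        out.append(NormalizedMember(
            member_id=mid, canonical_seq=canonical_rotation(trimmed),
            dtr_length=dtr.length, donor=donor, population=population,
            niche=niche))
    return out


# ---------------------------------------------------------------------------
# multiple alignment (center-star, adequate at >99% identity)

def _pairwise_align(ref: str, other: str) -> tuple[str, str]:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(ref, other)[0]
    return str(aln[0]), str(aln[1])


def align_members(
    members: Sequence[NormalizedMember] | Mapping[str, str],
    reference_id: str | None = None,
) -> tuple[dict[str, str], str]:
    """Progressive center-star MSA against a median-length reference.

    Every member is aligned pairwise to the reference; reference gap
    patterns are merged ("once a gap, always a gap").  Returns
    (id -> aligned row, reference id).  A pre-computed alignment (one
    aligned row per member, equal lengths) can be supplied downstream
    instead of this routine.
    """
    if isinstance(members, Mapping):
        seqs = dict(members)
    else:
        seqs = {m.member_id: m.canonical_seq for m in members}
    if not seqs:
        raise ValueError("no members to align")
    ids = list(seqs)
    if reference_id is None:
        by_len = sorted(ids, key=lambda i: (len(seqs[i]), i))
        reference_id = by_len[(len(by_len) - 1) // 2]  # median length
    ref = seqs[reference_id]
    L = len(ref)
    pair: dict[str, tuple[str, str]] = {}
    ins: dict[str, list[int]] = {}
    for mid in ids:
        if mid == reference_id:
            pair[mid] = (ref, ref)
            ins[mid] = [0] * (L + 1)
            continue
        r_aln, m_aln = _pairwise_align(ref, seqs[mid])
        pair[mid] = (r_aln, m_aln)
        counts = [0] * (L + 1)
        p = 0
        for rc_ in r_aln:
            if rc_ == GAP:
                counts[p] += 1
            else:
                p += 1
        ins[mid] = counts
    master = [max(ins[mid][p] for mid in ids) for p in range(L + 1)]
    rows: dict[str, str] = {}
    for mid in ids:
        r_aln, m_aln = pair[mid]
        out: list[str] = []
        p = 0
        block: list[str] = []
        for rc_, mc in zip(r_aln, m_aln):
            if rc_ == GAP:
                block.append(mc)
            else:
                out.append("".join(block) + GAP * (master[p] - len(block)))
                out.append(mc)
                block = []
                p += 1
        out.append("".join(block) + GAP * (master[L] - len(block)))
        rows[mid] = "".join(out)
    lengths = {len(v) for v in rows.values()}
    assert len(lengths) == 1, "MSA rows of unequal length"
    return rows, reference_id


def filter_msa_members(
    msa: Mapping[str, str],
    reference_id: str,
) -> dict[str, str]:
    """Drop members with a long indel (gap run >= 2) vs the reference."""
    ref_row = msa[reference_id]
    kept: dict[str, str] = {}
    for mid, row in msa.items():
        run = 0
        long_indel = False
        for rc_, mc in zip(ref_row, row):
            if (mc == GAP) != (rc_ == GAP):
                run += 1
                if run >= 2:
                    long_indel = True
                    break
            else:
                run = 0
        if not long_indel:
            kept[mid] = row
    return kept


# ---------------------------------------------------------------------------
# haplotype collapse

@dataclass
class Haplotype:
    hap_id: str
    signature: str  # aligned characters incl. gap state
    member_ids: list[str]
    origin_tally: dict[str, int] = field(default_factory=dict)


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]
    columns: int

    def by_id(self, hap_id: str) -> Haplotype:
        return next(h for h in self.haplotypes if h.hap_id == hap_id)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def collapse_haplotypes(
    msa: Mapping[str, str],
    member_origins: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Merge identical aligned rows (gap = fifth state) into haplotypes.

    Pairwise haplotype difference counts equal the Hamming distance
    over alignment columns, so single-base indels separate haplotypes
    and the counts reflect all differences between the sequences.
    """
    if not msa:
        raise ValueError("empty alignment")
    groups: dict[str, list[str]] = {}
    for mid in sorted(msa):
        groups.setdefault(msa[mid], []).append(mid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    haps = []
    for i, (sig, mids) in enumerate(ordered, start=1):
        tally: dict[str, int] = {}
        if member_origins:
            for m in mids:
                key = member_origins.get(m, "")
                tally[key] = tally.get(key, 0) + 1
        haps.append(Haplotype(hap_id=f"Hap_{i}", signature=sig,
                              member_ids=mids, origin_tally=tally))
    return HaplotypeTable(haplotypes=haps,
                          columns=len(next(iter(msa.values()))))


# ---------------------------------------------------------------------------
# median-joining network

@dataclass
class MJNetwork:
    """Observed haplotypes plus inferred medians, with Hamming edges."""

    vectors: dict[str, str]
    observed: set[str]
    edges: list[tuple[str, str, int]]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node, vec in self.vectors.items():
            g.add_node(node, vector=vec, observed=node in self.observed)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g


def _minimum_spanning_network(vectors: dict[str, str]) -> list[tuple[str, str, int]]:
    """Union of all minimum spanning trees (epsilon = 0 MSN)."""
    ids = list(vectors)
    dist = {
        (a, b): hamming(vectors[a], vectors[b])
        for a, b in itertools.combinations(ids, 2)
    }
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[str, str, int]] = []
    for d in sorted(set(dist.values())):
        level = [(a, b) for (a, b), w in dist.items() if w == d]
        # edge joins components as they stood BEFORE this level (keeps ties)
        comp_before = {i: find(i) for i in ids}
        added = [(a, b) for a, b in level if comp_before[a] != comp_before[b]]
        for a, b in added:
            edges.append((a, b, d))
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return edges


def _majority_median(u: str, v: str, w: str) -> str:
    out = []
    for a, b, c in zip(u, v, w):
        if b == c:
            out.append(b)
        else:
            out.append(a)  # a==b, a==c, or all distinct -> first sequence
    return "".join(out)


def median_joining_network(
    haps: HaplotypeTable | Mapping[str, str],
    epsilon: int = 0,
    max_rounds: int = 20,
) -> MJNetwork:
    """Bandelt median-joining network over haplotype vectors.

    Iterates: build the minimum spanning network, then for every
    connected node triple add the columnwise-majority median vector if
    new; stops at a fixed point.  Medians not on any shortest path
    between observed haplotypes are pruned.  ``epsilon`` > 0 widens the
    connection levels (the common default 0 keeps only MST-tied edges).
    """
    if isinstance(haps, HaplotypeTable):
        vectors = {h.hap_id: h.signature for h in haps.haplotypes}
    else:
        vectors = dict(haps)
    if not vectors:
        raise ValueError("no haplotypes")
    observed = set(vectors)
    median_count = 0
    for _ in range(max_rounds):
        edges = _minimum_spanning_network(vectors)
        adj: dict[str, set[str]] = {i: set() for i in vectors}
        for a, b, _ in edges:
            adj[a].add(b)
            adj[b].add(a)
        new: list[str] = []
        seen = set(vectors.values())
        for v in vectors:
            for u, w in itertools.combinations(sorted(adj[v]), 2):
                m = _majority_median(vectors[v], vectors[u], vectors[w])
                if m not in seen:
                    seen.add(m)
                    new.append(m)
        if not new:
            break
        for m in new:
            median_count += 1
            vectors[f"Median_{median_count}"] = m

    # prune medians off every observed-to-observed shortest path
    while True:
        edges = _minimum_spanning_network(vectors)
        g = nx.Graph()
        g.add_nodes_from(vectors)
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        drop = set()
        for node in vectors:
            if node in observed:
                continue
            if not _on_shortest_path(g, node, observed):
                drop.add(node)
        if not drop:
            break
        for node in drop:
            del vectors[node]
    # utility pruning: a median earns its place only by strictly reducing
    # the total connection cost (Steiner effect); a median set that does
    # not beat the observed-only tree is dropped wholesale
    def total_weight(vs: dict[str, str]) -> int:
        return sum(w for *_, w in _kruskal_mst(vs))

    improved = True
    while improved:
        improved = False
        for m in [x for x in vectors if x not in observed]:
            without = {k: v for k, v in vectors.items() if k != m}
            if total_weight(without) <= total_weight(vectors):
                vectors = without
                improved = True
                break
    observed_only = {k: v for k, v in vectors.items() if k in observed}
    if total_weight(vectors) > total_weight(observed_only):
        vectors = observed_only
    edges = _kruskal_mst(vectors)
    return MJNetwork(vectors=vectors, observed=observed & set(vectors), edges=edges)


def _kruskal_mst(vectors: dict[str, str]) -> list[tuple[str, str, int]]:
    """Deterministic minimum spanning tree (ties by node-id pair).

    The emitted network keeps one minimum-cost connection set;
    equal-cost alternative connections found during construction are
    not enumerated.
    """
    ids = list(vectors)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cands = sorted(
        (hamming(vectors[a], vectors[b]), a, b)
        for a, b in itertools.combinations(sorted(ids), 2))
    edges: list[tuple[str, str, int]] = []
    for w, a, b in cands:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, w))
    return edges


def _on_shortest_path(g: nx.Graph, node: str, observed: set[str]) -> bool:
    try:
        dist_from = nx.single_source_dijkstra_path_length(g, node, weight="weight")
    except nx.NodeNotFound:
        return False
    obs = [o for o in observed if o in dist_from]
    for o1, o2 in itertools.combinations(obs, 2):
        try:
            d = nx.dijkstra_path_length(g, o1, o2, weight="weight")
        except nx.NetworkXNoPath:
            continue
        if dist_from[o1] + dist_from[o2] == d:
            return True
    return False


# ---------------------------------------------------------------------------
# transmission clock

def transmission_window(
    n_mut: int,
    plasmid_len: int,
    genome_rate: float = GENOME_RATE_PER_YEAR,
    genome_len: int = GENOME_LEN,
) -> tuple[float, float]:
    """Years back implied by ``n_mut`` differences on a plasmid.

    The per-genome mutation rate is scaled to the plasmid:
    lambda = genome_rate * plasmid_len / genome_len per year.  Zero
    observed mutations give the window [0, round(1/lambda)] years;
    n >= 1 gives the point estimate n/lambda (returned as a degenerate
    window).
    """
    if plasmid_len <= 0:
        raise ValueError("plasmid_len must be positive")
    lam = genome_rate * plasmid_len / genome_len
    if lam <= 0:
        raise ValueError("mutation rate scales to zero")
    if n_mut == 0:
        return 0.0, float(round(1.0 / lam))
    point = n_mut / lam
    return point, point


# ---------------------------------------------------------------------------
# output

def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("hap_id\tn_members\tmember_ids\torigin_tally\n")
        for h in table.haplotypes:
            tally = ";".join(f"{k}:{v}" for k, v in sorted(h.origin_tally.items()))
            fh.write(f"{h.hap_id}\t{len(h.member_ids)}\t"
                     f"{','.join(h.member_ids)}\t{tally}\n")


def write_network(net: MJNetwork, edge_path: str | Path,
                  graphml_path: str | Path | None = None) -> None:
    with open(edge_path, "w") as fh:
        fh.write("node_a\tnode_b\tn_diff\n")
        for a, b, w in net.edges:
            fh.write(f"{a}\t{b}\t{w}\n")
    if graphml_path is not None:
        nx.write_graphml(net.graph(), str(graphml_path))


def write_nexus_haplotypes(table: HaplotypeTable, path: str | Path) -> None:
    """Nexus-style block for population-genetics viewers."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={len(table.haplotypes)} "
                 f"NCHAR={table.columns};\n")
        fh.write("FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n")
        for h in table.haplotypes:
            fh.write(f"{h.hap_id} {h.signature}\n")
        fh.write(";\nEND;\n")
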