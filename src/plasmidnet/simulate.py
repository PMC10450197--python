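"""Seeded synthetic-data generators and the benchmark scorer.

Every input the pipeline consumes — labeled reference replicons, query
contigs, annotation tables, assembly graphs with read pairs, isolate
metadata, haplotype populations — can be fabricated here with recorded
ground truth.  Unrelated replicons are modelled as independent uniform
ACGT sequences (at k = 17 two such sequences share k-mers with
vanishing probability, so their distance is ~1); relatedness is always
planted explicitly by copy-with-mutations, which makes expected
distances analytically predictable.  All generators are pure functions
of (seed, parameters).

Simulated reads are error-free with configurable length and insert
size: read noise is not part of any contract tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .completeness import AssemblyGraph
from .ecology import fraction_summary
from .refdb import CHROMOSOME, PLASMID

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Plant exactly ``n_subs`` substitutions at distinct positions."""
    arr = bytearray(seq, "ascii")
    if n_subs == 0:
        return seq
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        old = arr[p]
        choices = [b for b in b"ACGT" if b != old]
        arr[p] = choices[rng.integers(3)]
    return arr.decode("ascii")


# ---------------------------------------------------------------------------
# reference sets and identification benchmarks

@dataclass
class ReferenceSet:
    records: dict[str, str]
    origins: dict[str, str]
    truth: dict = field(default_factory=dict)


def gen_reference_set(
    seed: int,
    n_plasmids: int = 20,
    n_chromosomes: int = 10,
    plasmid_len: tuple[int, int] = (5_000, 30_000),
    chromosome_len: tuple[int, int] = (50_000, 150_000),
    n_variants: int = 1,
    variant_divergence: float = 0.005,
) -> ReferenceSet:
    """Labeled plasmid/chromosome replicons as distinct random families.

    ``n_variants`` > 1 emits near-copies of each base replicon at
    ``variant_divergence`` (planted redundancy for dedup tests and for
    holdout splits that must stay detectable).
    """
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    origins: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for cls, n, lrange in ((PLASMID, n_plasmids, plasmid_len),
                           (CHROMOSOME, n_chromosomes, chromosome_len)):
        for i in range(n):
            base_id = f"{cls[0]}base{i}"
            length = int(rng.integers(lrange[0], lrange[1] + 1))
            base = random_sequence(rng, length)
            groups[base_id] = []
            for v in range(n_variants):
                rid = f"{cls}_{i}" if n_variants == 1 else f"{cls}_{i}_v{v}"
                n_subs = int(round(variant_divergence * length)) if v else 0
                records[rid] = mutate(rng, base, n_subs)
                origins[rid] = cls
                groups[base_id].append(rid)
    return ReferenceSet(records=records, origins=origins,
                        truth={"groups": groups, "seed": seed})


@dataclass
class Benchmark:
    """Query fragments with truth labels plus the DB-side records."""

    queries: dict[str, str]
    query_origins: dict[str, str]
    db_records: dict[str, str]
    db_origins: dict[str, str]
    truth: dict = field(default_factory=dict)


def gen_mimic_benchmark(
    seed: int,
    refs: ReferenceSet,
    n_per_class: int = 5000,
    len_range: tuple[int, int] = (2000, 200_000),
    holdout: float = 0.2,
    holdout_divergence: float = 0.02,
) -> Benchmark:
    """Held-out query fragments vs an 80% reference DB.

    Per class, ``holdout`` of the replicons are set aside; query
    fragments are cut from the held-out replicons (re-diverged by
    ``holdout_divergence`` from their family so the split is honest but
    the families remain recognisable) with near-uniform lengths capped
    at the source.  No query's parent is on the DB side.
    """
    if not 0 < holdout < 1:
        raise ValueError("holdout must be in (0, 1)")
    rng = np.random.default_rng(seed)
    db_records: dict[str, str] = {}
    db_origins: dict[str, str] = {}
    held: dict[str, list[str]] = {PLASMID: [], CHROMOSOME: []}
    for cls in (PLASMID, CHROMOSOME):
        ids = sorted(r for r, o in refs.origins.items() if o == cls)
        n_hold = max(1, int(round(holdout * len(ids))))
        perm = rng.permutation(len(ids))
        hold_ids = [ids[i] for i in perm[:n_hold]]
        for rid in ids:
            if rid in hold_ids:
                held[cls].append(rid)
            else:
                db_records[rid] = refs.records[rid]
                db_origins[rid] = cls
    queries: dict[str, str] = {}
    query_origins: dict[str, str] = {}
    lo, hi = len_range
    for cls in (PLASMID, CHROMOSOME):
        for i in range(n_per_class):
            rid = held[cls][rng.integers(len(held[cls]))]
            src = refs.records[rid]
            flen = min(int(rng.integers(lo, hi + 1)), len(src))
            start = int(rng.integers(0, len(src) - flen + 1))
            frag = src[start : start + flen]
            frag = mutate(rng, frag, int(round(holdout_divergence * flen)))
            qid = f"q_{cls}_{i}"
            queries[qid] = frag
            query_origins[qid] = cls
    return Benchmark(queries=queries, query_origins=query_origins,
                     db_records=db_records, db_origins=db_origins,
                     truth={"held_out": held, "seed": seed})


def score_benchmark(
    predicted_pls: set[str] | Sequence[str],
    query_origins: Mapping[str, str],
) -> dict:
    """Precision/recall of a PLS prediction set against truth labels."""
    if not query_origins:
        raise ValueError("empty truth")
    predicted = set(predicted_pls)
    unknown = predicted - set(query_origins)
    if unknown:
        raise ValueError(f"predictions outside the truth set: {sorted(unknown)[:5]}")
    tp = sum(1 for q in predicted if query_origins[q] == PLASMID)
    fp = len(predicted) - tp
    n_true = sum(1 for o in query_origins.values() if o == PLASMID)
    return score_benchmark_counts(len(predicted), fp, n_true)


def score_benchmark_counts(n_predicted: int, n_false_positive: int,
                           n_true_plasmid: int) -> dict:
    """Precision/recall from raw counts, as one-decimal percentages."""
    if n_true_plasmid <= 0:
        raise ValueError("empty truth")
    tp = n_predicted - n_false_positive
    precision = fraction_summary(tp, n_predicted) if n_predicted else 0.0
    recall = fraction_summary(tp, n_true_plasmid)
    return {
        "n_predicted": n_predicted,
        "n_true_positive": tp,
        "n_false_positive": n_false_positive,
        "n_true_plasmid": n_true_plasmid,
        "precision_pct": precision,
        "recall_pct": recall,
    }


# ---------------------------------------------------------------------------
# assembly-graph fixtures

@dataclass
class AssemblyFixture:
    graph: AssemblyGraph
    pls_seq: str
    read_pairs: list[tuple[str, str]]
    truth: dict


def gen_assembly_fixture(
    seed: int,
    plasmid_len: int = 12_000,
    n_nodes: int = 4,
    fraction_observed: float = 1.0,
    copy_plan: Sequence[int] | None = None,
    coverage: float = 30.0,
    abundance_noise: float = 0.0,
    read_len: int = 100,
    pairs_per_junction: int = 3,
) -> AssemblyFixture:
    """A circular plasmid fragmented into FASTG-style nodes, with a PLS
    covering a known fraction and junction-spanning read pairs.

    ``copy_plan[i]`` repeats node i that many times around the circle;
    node abundance = coverage x multiplicity, +- ``abundance_noise``
    relative noise.  The PLS covers whole nodes whose summed length is
    as close to ``fraction_observed`` as node boundaries allow; the
    realised fraction is recorded in truth.
    """
    if not 0 < fraction_observed <= 1:
        raise ValueError("fraction_observed must be in (0, 1]")
    rng = np.random.default_rng(seed)
    copy_plan = list(copy_plan) if copy_plan is not None else [1] * n_nodes
    if len(copy_plan) != n_nodes:
        raise ValueError("copy_plan length must equal n_nodes")
    # cut the circle into n_nodes * multiplicity spans; repeated nodes
    # get identical sequence, so generate per unique node then lay out
    order: list[int] = []
    for i, m in enumerate(copy_plan):
        order.extend([i] * m)
    simple = all(m == 1 for m in copy_plan)
    if not simple:
        rng.shuffle(order)
    total_steps = len(order)
    # spans >= 300 bp so junction pairs sit fully inside their nodes
    min_node = 300

    def _partition(total: int, parts: int) -> list[int]:
        extra = total - parts * min_node
        if extra < 0:
            raise ValueError("plasmid_len too short for the requested node count")
        cuts = np.sort(rng.integers(0, extra + 1, size=parts - 1))
        return [min_node + int(x) for x in np.diff([0, *cuts.tolist(), extra])]

    if simple and fraction_observed < 1.0:
        # land a node boundary exactly on the requested fraction
        target = int(round(fraction_observed * plasmid_len))
        n_pls = min(max(1, int(round(fraction_observed * total_steps))),
                    total_steps - 1)
        target = max(target, n_pls * min_node)
        target = min(target, plasmid_len - (total_steps - n_pls) * min_node)
        span_lens = _partition(target, n_pls) + _partition(
            plasmid_len - target, total_steps - n_pls)
    else:
        span_lens = _partition(plasmid_len, total_steps)
    # one span length per unique node (its first occurrence); the circle
    # length then differs from plasmid_len when nodes repeat
    node_len: dict[int, int] = {}
    for step, node in enumerate(order):
        node_len.setdefault(node, span_lens[step])
    node_seq = {i: random_sequence(rng, node_len[i]) for i in range(n_nodes)}
    circle = "".join(node_seq[i] for i in order)

    graph = AssemblyGraph()
    node_ids: dict[int, str] = {}
    for i in range(n_nodes):
        noise = 1.0 + rng.uniform(-abundance_noise, abundance_noise)
        abundance = coverage * copy_plan[i] * noise
        # SPAdes-style names so cov_ survives a FASTG round trip
        node_ids[i] = f"EDGE_{i}_length_{node_len[i]}_cov_{abundance:.6g}"
        graph.add_node(node_ids[i], node_seq[i], abundance)
    for s in range(total_steps):
        u = (node_ids[order[s]], "+")
        v = (node_ids[order[(s + 1) % total_steps]], "+")
        graph.add_edge(u, v)

    # PLS = prefix of the circle covering ~fraction_observed, on node bounds
    circle_len = len(circle)
    target = fraction_observed * circle_len
    acc = 0
    pls_steps = 0
    for s in range(total_steps):
        nxt = acc + len(node_seq[order[s]])
        if pls_steps and abs(acc - target) <= abs(nxt - target):
            break
        acc = nxt
        pls_steps = s + 1
    pls_seq = "".join(node_seq[order[s]] for s in range(pls_steps))
    realised = len(pls_seq) / circle_len

    # error-free junction-spanning pairs around the whole circle
    doubled = circle + circle
    read_pairs: list[tuple[str, str]] = []
    pos = 0
    for s in range(total_steps):
        jend = pos + len(node_seq[order[s]])  # junction after step s
        for _ in range(pairs_per_junction):
            off = int(rng.integers(10, 60))
            m1 = doubled[jend - read_len - off : jend - off]
            m2 = doubled[jend + off : jend + off + read_len]
            read_pairs.append((m1, m2))
        pos = jend
    anchors = [(node_ids[order[s]], "+") for s in range(pls_steps)]
    return AssemblyFixture(
        graph=graph, pls_seq=pls_seq, read_pairs=read_pairs,
        truth={
            "fraction": realised,
            "copy_plan": copy_plan,
            "order": [node_ids[i] for i in order],
            "anchors": anchors,
            "circle_len": circle_len,
            "coverage": coverage,
            "seed": seed,
        })


# ---------------------------------------------------------------------------
# haplotype populations

@dataclass
class HaplotypePopulation:
    members: dict[str, str]
    truth: dict


def gen_haplotype_population(
    seed: int,
    ancestor_len: int = 1200,
    mutation_tree: Sequence[tuple[int, int]] = ((0, 1), (0, 1)),
    members_per_hap: int = 3,
    rotate_and_flip: bool = True,
    dtr_len: int = 15,
) -> HaplotypePopulation:
    """Members of a clonal family with a planted mutation tree.

    ``mutation_tree`` lists (parent_index, n_mutations) for haplotypes
    1..n, parent 0 being the ancestor; each edge mutates fresh,
    previously untouched positions so pairwise distances are additive
    along the tree.  Members are emitted at random rotations (and
    strands, if ``rotate_and_flip``) with a duplicated ``dtr_len``
    terminus, as a circular assembly would present them.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_sequence(rng, ancestor_len)
    haps = [ancestor]
    used: set[int] = set()
    edges: list[tuple[int, int, int]] = []
    for parent, n_mut in mutation_tree:
        if parent >= len(haps):
            raise ValueError("tree parent precedes its child")
        if n_mut < 1:
            raise ValueError("tree edges must carry >= 1 mutation")
        free = [p for p in range(ancestor_len) if p not in used]
        pos = rng.choice(len(free), size=n_mut, replace=False)
        arr = bytearray(haps[parent], "ascii")
        for pi in pos:
            p = free[pi]
            used.add(p)
            old = arr[p]
            arr[p] = [b for b in b"ACGT" if b != old][rng.integers(3)]
        haps.append(arr.decode("ascii"))
        edges.append((parent, len(haps) - 1, n_mut))
    members: dict[str, str] = {}
    truth_assign: dict[str, int] = {}
    from .sketch import reverse_complement

    for h, hap_seq in enumerate(haps):
        for m in range(members_per_hap):
            s = hap_seq
            if rotate_and_flip:
                r = int(rng.integers(len(s)))
                s = s[r:] + s[:r]
                if rng.integers(2):
                    s = reverse_complement(s)
            mid = f"hap{h}_m{m}"
            members[mid] = s + s[:dtr_len]
            truth_assign[mid] = h
    return HaplotypePopulation(
        members=members,
        truth={"haplotypes": haps, "edges": edges,
               "assignment": truth_assign, "dtr_len": dtr_len, "seed": seed})


# ---------------------------------------------------------------------------
# annotation + metadata fabrication

def gen_marker_annotations(
    seed: int,
    n_per_class: int = 1000,
    plasmid_gene_rates: Mapping[str, float] | None = None,
    chromosome_gene_rates: Mapping[str, float] | None = None,
):
    """Bernoulli presence/absence annotation tables on labeled elements.

    Returns (annotations, plasmid_ids, chromosome_ids).  Rates are the
    per-fragment hit probabilities of each gene family on each class.
    """
    from .markers import GeneAnnotation

    rng = np.random.default_rng(seed)
    plasmid_gene_rates = plasmid_gene_rates or {}
    chromosome_gene_rates = chromosome_gene_rates or {}
    p_ids = [f"pfrag_{i}" for i in range(n_per_class)]
    c_ids = [f"cfrag_{i}" for i in range(n_per_class)]
    anns: list[GeneAnnotation] = []
    genes = sorted(set(plasmid_gene_rates) | set(chromosome_gene_rates))
    for g in genes:
        pr = plasmid_gene_rates.get(g, 0.0)
        cr = chromosome_gene_rates.get(g, 0.0)
        for eid in p_ids:
            if rng.random() < pr:
                anns.append(GeneAnnotation(eid, g, product=g, evalue=1e-6))
        for eid in c_ids:
            if rng.random() < cr:
                anns.append(GeneAnnotation(eid, g, product=g, evalue=1e-6))
    return anns, p_ids, c_ids
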