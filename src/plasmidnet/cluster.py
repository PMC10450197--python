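"""PLS -> PLC clustering, high-confidence retention, and network typing.

Plasmid-like sequences are grouped into plasmid-like clusters (PLCs) by
complete-linkage hierarchical clustering cut at Mash distance 0.01
(about 99% ANI), so every pair inside a PLC is that similar.  Candidate
PLCs are retained only when at least one member is ~100% complete or
carries plasmid backbone genes.  Typing runs Markov clustering (MCL) on
the unweighted <0.15 similarity network of complete-PLC representatives
plus their nearest reference plasmids, yielding network typing groups
(NTGs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .sketch import (
    DistanceMatrix,
    KmerSketch,
    mash_distance,
    pairwise_distance_matrix,
    sketch_collection,
)

PLC_CUTOFF = 0.01
NETWORK_CUTOFF = 0.15
MCL_INFLATION = 2.0


# ---------------------------------------------------------------------------
# complete-linkage PLC clustering

def complete_linkage_clusters(
    dm: DistanceMatrix, cutoff: float = PLC_CUTOFF
) -> list[list[str]]:
    """Flat complete-linkage clusters of a distance matrix at ``cutoff``.

    Every returned cluster has maximum pairwise distance <= cutoff.
    """
    dm.validate()
    n = len(dm.ids)
    if n == 0:
        return []
    if n == 1:
        return [[dm.ids[0]]]
    condensed = ssd.squareform(dm.d, checks=False)
    z = sch.linkage(condensed, method="complete")
    labels = sch.fcluster(z, t=cutoff, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for name, lab in zip(dm.ids, labels):
        clusters.setdefault(int(lab), []).append(name)
    # stable order: by first-appearing member
    order = {name: i for i, name in enumerate(dm.ids)}
    out = sorted(clusters.values(), key=lambda c: min(order[m] for m in c))
    for c in out:
        c.sort(key=lambda m: order[m])
    return out


# ---------------------------------------------------------------------------
# Markov clustering

def mcl_cluster(
    adjacency: Mapping[Hashable, Iterable[Hashable]] | np.ndarray,
    nodes: Sequence[Hashable] | None = None,
    inflation: float = MCL_INFLATION,
    max_iter: int = 200,
    tol: float = 1e-8,
    prune: float = 1e-7,
) -> list[list[Hashable]]:
    """Markov clustering of an (unweighted) graph.

    Alternates expansion (matrix squaring) with inflation (elementwise
    power + column renormalisation), pruning tiny entries, until the
    matrix is stable; clusters are the connected components of the
    converged flow matrix.  Self-loops are added per standard MCL
    practice.  Non-convergence returns the current partition with a
    warning.
    """
    import warnings

    if isinstance(adjacency, np.ndarray):
        a = np.asarray(adjacency, dtype=float)
        if nodes is None:
            nodes = list(range(a.shape[0]))
    else:
        if nodes is None:
            seen: dict[Hashable, None] = {}
            for u, nbrs in adjacency.items():
                seen.setdefault(u)
                for v in nbrs:
                    seen.setdefault(v)
            nodes = list(seen)
        idx = {u: i for i, u in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)))
        for u, nbrs in adjacency.items():
            for v in nbrs:
                a[idx[u], idx[v]] = 1.0
                a[idx[v], idx[u]] = 1.0
    n = a.shape[0]
    if n == 0:
        return []
    m = a.copy()
    np.fill_diagonal(m, 1.0)  # self-loops
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; returning current partition",
                      RuntimeWarning, stacklevel=2)
    # clusters = connected components of the converged flow
    support = (m + m.T) > prune
    np.fill_diagonal(support, True)
    labels = -np.ones(n, dtype=int)
    nxt = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = nxt
        while stack:
            u = stack.pop()
            for v in np.nonzero(support[u])[0]:
                if labels[v] < 0:
                    labels[v] = nxt
                    stack.append(v)
        nxt += 1
    clusters: dict[int, list[Hashable]] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), []).append(node)
    return [clusters[k] for k in sorted(clusters)]


# ---------------------------------------------------------------------------
# PLC assembly and retention

@dataclass
class PLC:
    """A plasmid-like cluster: PLSs with all pairwise distances <= 0.01."""

    plc_id: str
    members: list[str]
    representative: str = ""
    has_complete_member: bool = False
    has_backbone: bool = False
    conjugative: bool = False
    mobilizable: bool = False

    @property
    def retained(self) -> bool:
        return self.has_complete_member or self.has_backbone


def build_candidate_plcs(
    dm: DistanceMatrix,
    member_lengths: Mapping[str, int] | None = None,
    cutoff: float = PLC_CUTOFF,
    prefix: str = "Clstr",
) -> list[PLC]:
    """Cluster PLSs into candidate PLCs; representative = longest member."""
    clusters = complete_linkage_clusters(dm, cutoff=cutoff)
    plcs = []
    for i, members in enumerate(clusters, start=1):
        if member_lengths:
            rep = max(members, key=lambda m: (member_lengths.get(m, 0), m))
        else:
            rep = min(members)
        plcs.append(PLC(plc_id=f"{prefix}_{i}", members=list(members),
                        representative=rep))
    return plcs


def retain_high_confidence_plcs(
    candidates: Iterable[PLC],
    complete_members: Iterable[str] = (),
    backbone_members: Iterable[str] = (),
    conjugative_members: Iterable[str] = (),
    mobilizable_members: Iterable[str] = (),
) -> list[PLC]:
    """Keep candidate PLCs with a ~100%-complete member or a backbone gene.

    Conjugative/mobilizable flags are also set here: a PLC is conjugative
    if any member is, and mobilizable only if some member is mobilizable
    and no member is conjugative.
    """
    complete = set(complete_members)
    backbone = set(backbone_members)
    conj = set(conjugative_members)
    mob = set(mobilizable_members)
    retained = []
    for plc in candidates:
        ms = set(plc.members)
        plc.has_complete_member = bool(ms & complete)
        plc.has_backbone = bool(ms & backbone)
        plc.conjugative = bool(ms & conj)
        plc.mobilizable = bool(ms & mob) and not plc.conjugative
        if plc.retained:
            retained.append(plc)
    return retained


# ---------------------------------------------------------------------------
# network typing (NTGs)

@dataclass
class NTGAssignment:
    element_id: str
    ntg_id: str
    is_singleton_excluded: bool = False


def assign_network_types(
    complc_sketches: Mapping[str, KmerSketch],
    reference_sketches: Mapping[str, KmerSketch] | None = None,
    cutoff: float = NETWORK_CUTOFF,
    k_nearest: int = 3,
    inflation: float = MCL_INFLATION,
) -> tuple[list[NTGAssignment], list[tuple[str, str]]]:
    """Type complete-PLC representatives on a <0.15 similarity network.

    For each comPLC the ``k_nearest`` reference plasmids under the
    cutoff are pulled into the network, pairwise distances over the
    combined node set are recomputed, edges drawn where distance <
    cutoff, and MCL partitions the graph into NTGs.  comPLCs with no
    neighbour under the cutoff are excluded as singletons.

    Returns (assignments, edge list).
    """
    reference_sketches = reference_sketches or {}
    selected_refs: dict[str, KmerSketch] = {}
    for cid, cs in complc_sketches.items():
        hits = []
        for rid, rs in reference_sketches.items():
            d = mash_distance(cs, rs)
            if d < cutoff:
                hits.append((d, rid))
        hits.sort(key=lambda t: (t[0], t[1]))  # ties: smaller distance, then id
        for d, rid in hits[:k_nearest]:
            selected_refs[rid] = reference_sketches[rid]

    node_sketches = dict(complc_sketches)
    node_sketches.update(selected_refs)
    ids = list(node_sketches)
    dm = pairwise_distance_matrix(node_sketches)
    n = len(ids)
    adj = (dm.d < cutoff) & ~np.eye(n, dtype=bool)

    degree = adj.sum(axis=1)
    excluded = {ids[i] for i in range(n) if degree[i] == 0 and ids[i] in complc_sketches}
    keep = [i for i in range(n) if degree[i] > 0]
    assignments: list[NTGAssignment] = []
    edges: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                edges.append((ids[i], ids[j]))
    if keep:
        sub = adj[np.ix_(keep, keep)].astype(float)
        parts = mcl_cluster(sub, nodes=[ids[i] for i in keep], inflation=inflation)
        for gi, part in enumerate(parts, start=1):
            for el in part:
                assignments.append(NTGAssignment(element_id=el, ntg_id=f"M{gi}"))
    for el in sorted(excluded):
        assignments.append(NTGAssignment(element_id=el, ntg_id="",
                                         is_singleton_excluded=True))
    return assignments, edges
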