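"""Labeled plasmid/chromosome fragment reference database.

Known replicons are cut into 200 kb non-overlapping fragments (most
plasmids are shorter, so they stay whole; the windowing mainly stops
Mash from overestimating the distance between a 2-200 kb query contig
and a multi-Mb chromosome).  Fragments closer than 0.02 are clustered
with MCL and reduced to representatives, keeping their plasmid /
chromosome origin labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .cluster import mcl_cluster
from .sketch import (
    DEFAULT_K,
    DEFAULT_SKETCH_SIZE,
    KmerSketch,
    pairwise_distance_matrix,
    read_fasta,
    read_sketches,
    sketch_collection,
    write_fasta,
    write_sketches,
)

FRAGMENT_WINDOW = 200_000
DEDUPE_CUTOFF = 0.02

PLASMID = "plasmid"
CHROMOSOME = "chromosome"


@dataclass(frozen=True)
class ReferenceFragment:
    fragment_id: str
    parent_id: str
    origin: str  # plasmid | chromosome
    start: int  # 0-based half-open offset in parent
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


def fragment_sequences(
    records: Mapping[str, str],
    origins: Mapping[str, str],
    window: int = FRAGMENT_WINDOW,
) -> list[ReferenceFragment]:
    """Tile each labeled replicon into non-overlapping <=``window`` fragments.

    A record shorter than the window yields a single fragment equal to
    itself; the last fragment of a longer record may be short.  Empty
    sequences are skipped with a warning.
    """
    frags: list[ReferenceFragment] = []
    for rid, seq in records.items():
        if not seq:
            warnings.warn(f"empty sequence skipped: {rid}", stacklevel=2)
            continue
        origin = origins[rid]
        if origin not in (PLASMID, CHROMOSOME):
            raise ValueError(f"{rid}: unknown origin label {origin!r}")
        for idx, start in enumerate(range(0, len(seq), window)):
            piece = seq[start : start + window]
            frags.append(ReferenceFragment(
                fragment_id=f"{rid}|frag{idx}", parent_id=rid,
                origin=origin, start=start, seq=piece))
    return frags


def dedupe_fragments(
    frags: list[ReferenceFragment],
    cutoff: float = DEDUPE_CUTOFF,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    inflation: float = 2.0,
) -> tuple[list[ReferenceFragment], dict[str, KmerSketch]]:
    """Reduce redundancy by MCL over the <cutoff distance graph.

    One representative (the longest member, ties by id) is kept per MCL
    cluster — except that a mixed-origin cluster keeps one representative
    per origin, so neither label class is silently erased.
    """
    by_id = {f.fragment_id: f for f in frags}
    sketches = sketch_collection({f.fragment_id: f.seq for f in frags}, k=k, s=s)
    dm = pairwise_distance_matrix(sketches)
    n = len(dm.ids)
    adj = (dm.d < cutoff) & ~np.eye(n, dtype=bool)
    clusters = mcl_cluster(adj.astype(float), nodes=dm.ids, inflation=inflation)
    reps: list[ReferenceFragment] = []
    for members in clusters:
        per_origin: dict[str, list[ReferenceFragment]] = {}
        for m in members:
            per_origin.setdefault(by_id[m].origin, []).append(by_id[m])
        for origin in sorted(per_origin):
            group = per_origin[origin]
            rep = sorted(group, key=lambda f: (-f.length, f.fragment_id))[0]
            reps.append(rep)
    reps.sort(key=lambda f: f.fragment_id)
    return reps, {f.fragment_id: sketches[f.fragment_id] for f in reps}


@dataclass
class FragmentDB:
    """Redundancy-reduced labeled fragment database with sketches."""

    fragments: list[ReferenceFragment]
    sketches: dict[str, KmerSketch]
    provenance: dict = field(default_factory=dict)

    @property
    def origins(self) -> dict[str, str]:
        return {f.fragment_id: f.origin for f in self.fragments}

    def counts(self) -> dict[str, int]:
        out = {PLASMID: 0, CHROMOSOME: 0}
        for f in self.fragments:
            out[f.origin] += 1
        return out

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta({f.fragment_id: f.seq for f in self.fragments},
                    outdir / "fragments.fasta")
        with open(outdir / "fragments.tsv", "w") as fh:
            fh.write("fragment_id\tparent_id\torigin\tstart\tlength\n")
            for f in self.fragments:
                fh.write(f"{f.fragment_id}\t{f.parent_id}\t{f.origin}\t"
                         f"{f.start}\t{f.length}\n")
        write_sketches(self.sketches.values(), outdir / "sketches.jsonl")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2)

    @classmethod
    def load(cls, dbdir: str | Path) -> "FragmentDB":
        dbdir = Path(dbdir)
        seqs = read_fasta(dbdir / "fragments.fasta")
        frags: list[ReferenceFragment] = []
        with open(dbdir / "fragments.tsv") as fh:
            next(fh)
            for line in fh:
                fid, pid, origin, start, _len = line.rstrip("\n").split("\t")
                frags.append(ReferenceFragment(
                    fragment_id=fid, parent_id=pid, origin=origin,
                    start=int(start), seq=seqs[fid]))
        sketches = read_sketches(dbdir / "sketches.jsonl")
        with open(dbdir / "provenance.json") as fh:
            prov = json.load(fh)
        return cls(fragments=frags, sketches=sketches, provenance=prov)


def build_fragment_db(
    records: Mapping[str, str],
    origins: Mapping[str, str],
    window: int = FRAGMENT_WINDOW,
    cutoff: float = DEDUPE_CUTOFF,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
) -> FragmentDB:
    """Fragment, dedupe, sketch: the full reference-DB build."""
    frags = fragment_sequences(records, origins, window=window)
    reps, sketches = dedupe_fragments(frags, cutoff=cutoff, k=k, s=s)
    return FragmentDB(
        fragments=reps,
        sketches=sketches,
        provenance={
            "window": window,
            "dedupe_cutoff": cutoff,
            "k": k,
            "s": s,
            "n_input_records": len(records),
            "n_fragments": len(frags),
            "n_representatives": len(reps),
        },
    )


def read_origin_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (record_id, origin) -> dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rid, origin = line.split("\t")[:2]
            if rid == "record_id":
                continue
            out[rid] = origin
    return out
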