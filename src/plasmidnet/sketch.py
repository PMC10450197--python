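"""Strand-neutral k-mer MinHash sketching and Mash-style distances.

Every similarity decision in the pipeline (reference voting, PLS
clustering, network typing, metagenome presence) runs on bottom-``s``
MinHash sketches of canonical k-mers.  A canonical k-mer is the
lexicographic minimum of a k-mer and its reverse complement, so contig
strand never affects a distance.  Hashing uses a fixed, documented
64-bit mixer (splitmix64 finalizer, constant seed) so sketches are
reproducible across runs and platforms.

The distance estimator is the Mash formula

    d = -(1/k) * ln(2j / (1 + j))

where ``j`` is the Jaccard index estimated from the ``s`` smallest
hashes of the union of two sketches.  ``j = 0`` is capped at d = 1.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

DEFAULT_K = 17
DEFAULT_SKETCH_SIZE = 3000

#: Constant xor-seed folded into every hash; changing it changes every
#: sketch, so it is part of the on-disk sketch format.
HASH_SEED = np.uint64(0x2545F4914F6CDD1D)

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")


class SketchError(ValueError):
    """Raised for unsketchable input (e.g. sequence shorter than k)."""


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finalizer (a 64-bit bijection)."""
    z = (x ^ HASH_SEED) + _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit codes of canonical k-mers; windows containing non-ACGT skipped.

    With A=0 < C=1 < G=2 < T=3 the numeric order of fixed-length codes
    equals lexicographic order, so min(code, rc_code) IS the canonical
    k-mer.
    """
    vals = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = vals.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    invalid = vals == 4
    # windows with any non-ACGT symbol are skipped, not substituted
    bad = np.cumsum(np.concatenate(([0], invalid.astype(np.int64))))
    valid_win = (bad[k:] - bad[:-k]) == 0
    v = np.where(invalid, 0, vals).astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    windows = np.lib.stride_tricks.sliding_window_view(v, k)
    fwd = windows @ powers
    rc_vals = (np.uint64(3) - v)[::-1]
    rc_windows = np.lib.stride_tricks.sliding_window_view(rc_vals, k)
    rc = (rc_windows @ powers)[::-1]
    canon = np.minimum(fwd, rc)[valid_win]
    return np.unique(canon)


@dataclass(frozen=True)
class KmerSketch:
    """Bottom-``s`` MinHash sketch of one sequence.

    ``hashes`` holds the ``min(s, n_kmers)`` smallest splitmix64 hashes
    of the distinct canonical k-mers, sorted ascending.
    """

    source_id: str
    k: int
    s: int
    hashes: np.ndarray
    n_kmers: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "hashes", np.asarray(self.hashes, dtype=np.uint64))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerSketch):
            return NotImplemented
        return (
            self.source_id == other.source_id
            and self.k == other.k
            and self.s == other.s
            and self.n_kmers == other.n_kmers
            and np.array_equal(self.hashes, other.hashes)
        )


def build_sketch(
    seq: str,
    source_id: str = "",
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
) -> KmerSketch:
    """Sketch one nucleotide sequence.

    Raises :class:`SketchError` when the sequence is too short to sketch
    (shorter than ``k``, or no valid k-mer window).
    """
    if len(seq) < k:
        raise SketchError(
            f"{source_id or 'sequence'}: too short to sketch ({len(seq)} bp < k={k})"
        )
    codes = _canonical_kmer_codes(seq, k)
    if codes.size == 0:
        raise SketchError(f"{source_id or 'sequence'}: too short to sketch "
                          "(no ACGT-only k-mer window)")
    hashes = splitmix64(codes)
    hashes.sort()
    return KmerSketch(source_id=source_id, k=k, s=s,
                      hashes=hashes[:s].copy(), n_kmers=int(codes.size))


def mash_distance(a: KmerSketch, b: KmerSketch) -> float:
    """Mash distance between two sketches, in [0, 1]."""
    if a.k != b.k:
        raise SketchError(f"mismatched k: {a.k} != {b.k}")
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)[:s]
    if union.size == 0:
        raise SketchError("empty sketches")
    shared = np.intersect1d(union, a.hashes, assume_unique=True)
    shared = np.intersect1d(shared, b.hashes, assume_unique=True)
    j = shared.size / union.size
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -math.log(2.0 * j / (1.0 + j)) / a.k
    return min(max(d, 0.0), 1.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with element ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} ids")

    def validate(self) -> None:
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix has nonzero diagonal")
        if np.any(self.d < 0) or np.any(self.d > 1):
            raise ValueError("distances outside [0, 1]")

    def get(self, i: str, j: str) -> float:
        return float(self.d[self.ids.index(i), self.ids.index(j)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for name, row in zip(self.ids, self.d):
                fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        d = np.array([[float(x) for x in r[1:]] for r in rows])
        return cls(ids=header, d=d)


def sketch_collection(
    seqs: Mapping[str, str] | Iterable[tuple[str, str]],
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
) -> dict[str, KmerSketch]:
    """Sketch many sequences; unsketchable members are reported together."""
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    sketches: dict[str, KmerSketch] = {}
    failures: list[str] = []
    for name, seq in items:
        try:
            sketches[name] = build_sketch(seq, source_id=name, k=k, s=s)
        except SketchError:
            failures.append(name)
    if failures:
        raise SketchError("unsketchable sequences: " + ", ".join(failures))
    return sketches


def pairwise_distance_matrix(
    seqs: Mapping[str, str] | Iterable[tuple[str, str]] | Mapping[str, KmerSketch],
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
) -> DistanceMatrix:
    """All-vs-all Mash distance matrix over a sequence (or sketch) collection."""
    if isinstance(seqs, Mapping) and seqs and all(
        isinstance(v, KmerSketch) for v in seqs.values()
    ):
        sketches = dict(seqs)
    else:
        sketches = sketch_collection(seqs, k=k, s=s)
    ids = list(sketches)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mash_distance(sketches[ids[i]], sketches[ids[j]])
    return DistanceMatrix(ids=ids, d=d)


def cross_distances(
    queries: Mapping[str, KmerSketch],
    refs: Mapping[str, KmerSketch],
) -> dict[tuple[str, str], float]:
    """Query-vs-reference Mash distances (no self pairs)."""
    out: dict[tuple[str, str], float] = {}
    for qid, qs in queries.items():
        for rid, rs in refs.items():
            out[(qid, rid)] = mash_distance(qs, rs)
    return out


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (gzip allowed) as an ordered id -> sequence dict."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sketches(sketches: Iterable[KmerSketch], path: str | Path) -> None:
    """JSON-lines sketch file: one object per sketch."""
    with open(path, "w") as fh:
        for sk in sketches:
            fh.write(json.dumps({
                "source_id": sk.source_id,
                "k": sk.k,
                "s": sk.s,
                "n_kmers": sk.n_kmers,
                "hashes": [int(h) for h in sk.hashes],
            }) + "\n")


def read_sketches(path: str | Path) -> dict[str, KmerSketch]:
    out: dict[str, KmerSketch] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out[obj["source_id"]] = KmerSketch(
                source_id=obj["source_id"], k=obj["k"], s=obj["s"],
                hashes=np.array(obj["hashes"], dtype=np.uint64),
                n_kmers=obj["n_kmers"],
            )
    return out
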