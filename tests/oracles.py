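"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised implementations:
k-mer sets are enumerated by string slicing, Jaccard by Python set
algebra, DTRs by an all-length scan, and cycles by exhaustive
enumeration, so they can certify the fast paths.
"""

from __future__ import annotations

import math

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_canonical_kmers(seq: str, k: int = 17) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if set(km) <= set("ACGT"):
            out.add(min(km, revcomp(km)))
    return out


def brute_jaccard(a: str, b: str, k: int = 17) -> float:
    sa, sb = brute_canonical_kmers(a, k), brute_canonical_kmers(b, k)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


def mash_formula(j: float, k: int = 17) -> float:
    if j <= 0:
        return 1.0
    if j >= 1:
        return 0.0
    return min(1.0, -math.log(2 * j / (1 + j)) / k)


def brute_dtr(seq: str, min_len: int = 10, max_mismatch: int = 1):
    """All-length terminal-repeat scan; returns (found, length, mismatches)."""
    n = len(seq)
    for L in range(n // 2, min_len - 1, -1):
        mism = sum(x != y for x, y in zip(seq[:L], seq[n - L :]))
        if mism <= max_mismatch:
            return True, L, mism
    return False, 0, 0


def brute_rotations(seq: str) -> list[str]:
    cands = []
    for base in (seq, revcomp(seq)):
        for r in range(len(base)):
            cands.append(base[r:] + base[:r])
    return cands
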