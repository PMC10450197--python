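"""Plasmid / chromosome gene-marker selection from fragment annotations.

Gene families are scored by their per-fragment occurrence frequency on
labeled plasmid fragments (FP) and chromosome fragments (FC).  Families
rare on both (FP and FC below 0.2%) are removed; plasmid-like gene
markers (PGMs) are the families with FP/FC above 7, chromosome-like
gene markers (CGMs) the 1400 families with the smallest ratios.  A
family never seen on chromosomes but present on plasmids has ratio
+inf and qualifies as a PGM: absence from chromosomes is maximal
plasmid evidence.

Counting is presence/absence per fragment, not copy number: a family
hit twice inside one fragment counts once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RATIO_MIN = 7.0
LOW_FREQ = 0.002
N_CGM = 1400
EVALUE_MAX = 1e-3

CLS_PGM = "PGM"
CLS_CGM = "CGM"
CLS_NEITHER = "neither"
CLS_REMOVED = "removed"


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene-family hit on one element (contig or fragment)."""

    element_id: str
    gene_id: str
    product: str = ""
    evalue: float = 0.0


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """TSV (element_id, gene_id, product, evalue), with optional header."""
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "element_id":
                continue
            out.append(GeneAnnotation(
                element_id=parts[0], gene_id=parts[1],
                product=parts[2] if len(parts) > 2 else "",
                evalue=float(parts[3]) if len(parts) > 3 else 0.0))
    return out


def write_annotations(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tgene_id\tproduct\tevalue\n")
        for a in annotations:
            fh.write(f"{a.element_id}\t{a.gene_id}\t{a.product}\t{a.evalue:g}\n")


def sample_random_fragments(
    records: Mapping[str, str],
    origins: Mapping[str, str],
    n: int,
    len_range: tuple[int, int] = (2000, 200_000),
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Cut ``n`` random fragments with near-uniform lengths from replicons.

    Returns (fragment_id, origin, seq) triples.  Fragment length is drawn
    uniform over ``len_range`` and capped at the source length; source
    records are drawn uniformly.  Seeded and reproducible.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ids = [rid for rid, seq in records.items() if len(seq) >= 2000]
    if not ids:
        raise ValueError("no usable source records (>= 2 kb)")
    rng = np.random.default_rng(seed)
    lo, hi = len_range
    out: list[tuple[str, str, str]] = []
    for i in range(n):
        rid = ids[rng.integers(len(ids))]
        seq = records[rid]
        frag_len = min(int(rng.integers(lo, hi + 1)), len(seq))
        start = int(rng.integers(0, len(seq) - frag_len + 1))
        out.append((f"{rid}|rand{i}", origins[rid], seq[start : start + frag_len]))
    return out


def compute_marker_frequencies(
    annotations: Iterable[GeneAnnotation],
    plasmid_ids: Iterable[str],
    chromosome_ids: Iterable[str],
    evalue_max: float = EVALUE_MAX,
) -> pd.DataFrame:
    """Per-gene FP / FC frequencies and their ratio.

    FP(g) = fraction of plasmid elements with at least one hit to g at
    evalue <= evalue_max; FC analogous.  Ratio is FP/FC, +inf when
    FC = 0 and FP > 0.
    """
    pset, cset = set(plasmid_ids), set(chromosome_ids)
    if not pset or not cset:
        raise ValueError("both element id sets must be non-empty")
    if pset & cset:
        raise ValueError("plasmid and chromosome id sets overlap")
    phits: dict[str, set[str]] = {}
    chits: dict[str, set[str]] = {}
    for a in annotations:
        if a.evalue > evalue_max:
            continue
        if a.element_id in pset:
            phits.setdefault(a.gene_id, set()).add(a.element_id)
        elif a.element_id in cset:
            chits.setdefault(a.gene_id, set()).add(a.element_id)
        else:
            raise ValueError(f"annotated element {a.element_id} in neither id set")
    genes = sorted(set(phits) | set(chits))
    fp = np.array([len(phits.get(g, ())) / len(pset) for g in genes])
    fc = np.array([len(chits.get(g, ())) / len(cset) for g in genes])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fc > 0, fp / np.where(fc > 0, fc, 1.0),
                         np.where(fp > 0, np.inf, np.nan))
    return pd.DataFrame({"gene_id": genes, "FP": fp, "FC": fc, "ratio": ratio})


def select_markers(
    table: pd.DataFrame,
    ratio_min: float = RATIO_MIN,
    low_freq: float = LOW_FREQ,
    n_cgm: int = N_CGM,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Classify gene families into PGMs / CGMs.

    Families rare on both replicon classes are removed first; of the
    survivors, PGMs have ratio > ratio_min and CGMs are the ``n_cgm``
    smallest ratios (ties broken toward larger FC, then gene id).
    Returns (pgms, cgms, classified table).
    """
    t = table.copy()
    removed = (t["FP"] < low_freq) & (t["FC"] < low_freq)
    t["cls"] = CLS_NEITHER
    t.loc[removed, "cls"] = CLS_REMOVED
    surv = t.loc[~removed].copy()
    pgm_mask = surv["ratio"] > ratio_min
    pgms = set(surv.loc[pgm_mask, "gene_id"])
    pool = surv.loc[~pgm_mask].copy()
    if n_cgm > len(pool):
        warnings.warn(
            f"requested {n_cgm} CGMs but only {len(pool)} surviving genes; taking all",
            stacklevel=2)
    pool = pool.sort_values(["ratio", "FC", "gene_id"],
                            ascending=[True, False, True])
    cgms = set(pool["gene_id"].head(n_cgm))
    t.loc[t["gene_id"].isin(pgms), "cls"] = CLS_PGM
    t.loc[t["gene_id"].isin(cgms), "cls"] = CLS_CGM
    return pgms, cgms, t


def write_marker_set(markers: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(markers):
            fh.write(g + "\n")


def read_marker_set(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
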