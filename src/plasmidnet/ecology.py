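"""Host range, prevalence and persistence of plasmid-like clusters.

A PLC's host range is the set of known bacterial genera of the
isolates its member PLSs came from; isolates of unknown genus are
excluded, and a PLC spanning at least two genera is broad-host-range
(BHR).  A PLC is present in a metagenome sample when any member is
within Mash distance 0.01 of any sample contig (>= 2 kb); prevalence
in a population is the fraction of that population's samples with the
PLC, "highly prevalent" above 10%.  Persistence in a longitudinally
sampled host is the day span between the first and last time point at
which any member is detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sketch import KmerSketch, mash_distance

PRESENCE_CUTOFF = 0.01
HIGH_PREVALENCE = 0.10
UNKNOWN_GENUS = "unknown"


@dataclass(frozen=True)
class IsolateMeta:
    isolate_id: str
    genus: str = UNKNOWN_GENUS
    donor_id: str = ""
    population: str = ""
    sampling_day: int | None = None


def read_isolate_metadata(path: str | Path) -> dict[str, IsolateMeta]:
    """TSV: isolate_id, genus, donor_id, population, sampling_day ('' allowed)."""
    out: dict[str, IsolateMeta] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("isolate_id"):
                continue
            parts = (line.split("\t") + [""] * 5)[:5]
            day = int(parts[4]) if parts[4] not in ("", "NA") else None
            out[parts[0]] = IsolateMeta(
                isolate_id=parts[0], genus=parts[1] or UNKNOWN_GENUS,
                donor_id=parts[2], population=parts[3], sampling_day=day)
    return out


def host_range(
    member_isolates: Iterable[str],
    meta: Mapping[str, IsolateMeta],
) -> tuple[set[str], bool]:
    """Known-genus set of a PLC's members and the BHR flag (>= 2 genera)."""
    genera: set[str] = set()
    for iso in member_isolates:
        if iso not in meta:
            raise KeyError(f"isolate without metadata: {iso}")
        g = meta[iso].genus
        if g and g.lower() != UNKNOWN_GENUS:
            genera.add(g)
    return genera, len(genera) >= 2


def sample_presence(
    member_sketches: Iterable[KmerSketch],
    contig_sketches: Iterable[KmerSketch],
    cutoff: float = PRESENCE_CUTOFF,
) -> bool:
    """True iff any member-vs-contig Mash distance is under the cutoff."""
    contig_sketches = list(contig_sketches)
    for m in member_sketches:
        for c in contig_sketches:
            if mash_distance(m, c) < cutoff:
                return True
    return False


def presence_matrix(
    plc_members: Mapping[str, Mapping[str, KmerSketch]],
    samples: Mapping[str, Mapping[str, KmerSketch]],
    cutoff: float = PRESENCE_CUTOFF,
) -> pd.DataFrame:
    """PLC x sample boolean presence matrix."""
    data = {
        sid: {
            plc: sample_presence(members.values(), contigs.values(), cutoff)
            for plc, members in plc_members.items()
        }
        for sid, contigs in samples.items()
    }
    df = pd.DataFrame(data, dtype=bool)
    return df.reindex(index=list(plc_members), columns=list(samples))


def prevalence_by_population(
    presence: pd.DataFrame,
    sample_populations: Mapping[str, str],
    high: float = HIGH_PREVALENCE,
) -> pd.DataFrame:
    """Per-(PLC, population) prevalence fractions with a high-prevalence flag.

    Prevalence = samples carrying the PLC / samples in the population;
    highly prevalent means strictly above ``high`` in >= 1 population.
    """
    missing = [s for s in presence.columns if s not in sample_populations]
    if missing:
        raise KeyError(f"samples without population label: {missing}")
    pops = sorted(set(sample_populations[s] for s in presence.columns))
    rows = []
    for plc in presence.index:
        row = {}
        for pop in pops:
            cols = [s for s in presence.columns if sample_populations[s] == pop]
            row[pop] = float(presence.loc[plc, cols].sum()) / len(cols)
        row["highly_prevalent"] = any(row[p] > high for p in pops)
        rows.append(row)
    return pd.DataFrame(rows, index=presence.index)


def persistence_span(
    member_isolates: Iterable[str],
    detected_isolates: Iterable[str],
    meta: Mapping[str, IsolateMeta],
) -> int | None:
    """Day span between first and last detection of a PLC in a host.

    Detection at a time point counts if any member is found in any
    isolate sampled that day.  One time point -> span 0; never detected
    -> None.
    """
    days = set()
    detected = set(detected_isolates)
    for iso in member_isolates:
        if iso in detected and iso in meta and meta[iso].sampling_day is not None:
            days.add(meta[iso].sampling_day)
    if not days:
        return None
    return max(days) - min(days)


def persistence_table(
    plc_members: Mapping[str, Sequence[str]],
    meta: Mapping[str, IsolateMeta],
    thresholds: Sequence[int] = (50, 150),
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Spans for all PLCs plus counts persisting >= each threshold."""
    rows = []
    for plc, members in plc_members.items():
        span = persistence_span(members, members, meta)
        if span is not None:
            rows.append({"plc_id": plc, "span_days": span})
    df = pd.DataFrame(rows, columns=["plc_id", "span_days"])
    counts = {t: int((df["span_days"] >= t).sum()) for t in thresholds}
    return df, counts


def genus_sharing_edges(
    plc_members: Mapping[str, Sequence[str]],
    meta: Mapping[str, IsolateMeta],
) -> list[tuple[str, str, str]]:
    """Edges (genus_a, genus_b, plc_id) for genera sharing a PLC.

    The genus network connected by shared PLCs, for external viewers;
    unknown genera are excluded as in host_range.
    """
    edges: list[tuple[str, str, str]] = []
    for plc, members in plc_members.items():
        genera, _ = host_range(members, meta)
        for a, b in ((a, b) for a in sorted(genera) for b in sorted(genera)
                     if a < b):
            edges.append((a, b, plc))
    return edges


def fraction_summary(numerator: int, denominator: int) -> float:
    """Percentage 100*num/den, half-up rounded to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
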