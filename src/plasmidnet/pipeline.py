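"""End-to-end orchestration: build-db -> identify -> cluster -> retain
-> type, with optional completeness, ecology and haplotype stages.

Single-machine, stage-per-function design; each stage writes its table
into the run directory next to a JSON-lines provenance log, and a
stage whose output file already exists is skipped on re-run, so runs
are idempotently resumable.  Every threshold defaults to the
workflow's standard value (reference vote < 0.15, PLC linkage 0.01,
DB dedup 0.02, marker ratio > 7, completeness > 0.6, DTR 10 bp /
1 mismatch, typing network < 0.15) and all of them are echoed into the
provenance file.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import cluster as _cluster
from . import completeness as _comp
from . import identify as _identify
from .markers import GeneAnnotation
from .refdb import FragmentDB, build_fragment_db
from .sketch import (
    DEFAULT_K,
    DEFAULT_SKETCH_SIZE,
    build_sketch,
    pairwise_distance_matrix,
    read_fasta,
)


@dataclass
class PipelineConfig:
    k: int = DEFAULT_K
    sketch_size: int = DEFAULT_SKETCH_SIZE
    db_window: int = 200_000
    db_dedupe_cutoff: float = 0.02
    reference_cutoff: float = 0.15
    plc_cutoff: float = 0.01
    network_cutoff: float = 0.15
    mcl_inflation: float = 2.0
    marker_ratio_min: float = 7.0
    marker_low_freq: float = 0.002
    n_cgm: int = 1400
    compls_threshold: float = 0.60
    dtr_min_len: int = 10
    dtr_max_mismatch: int = 1
    seed: int = 0


@dataclass
class PipelineResult:
    run_dir: Path
    db: FragmentDB
    pls_records: list
    plcs: list
    retained_plcs: list
    completeness: dict[str, _comp.CompletenessResult] = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending ids."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _log(run_dir: Path, stage: str, **payload) -> None:
    with open(run_dir / "provenance.jsonl", "a") as fh:
        fh.write(json.dumps({"stage": stage, "time": time.time(), **payload}) + "\n")


def run_pipeline(
    config: PipelineConfig,
    reference_records: Mapping[str, str],
    reference_origins: Mapping[str, str],
    contigs: Sequence[_identify.Contig],
    pgms: set[str],
    cgms: set[str],
    annotations: Sequence[GeneAnnotation] = (),
    assembly_graphs: Mapping[str, _comp.AssemblyGraph] | None = None,
    read_pairs: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    run_dir: str | Path = "run",
) -> PipelineResult:
    """Execute the whole workflow on in-memory inputs, writing each
    stage's table into ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)

    # stage: build-db
    try:
        db = build_fragment_db(reference_records, reference_origins,
                               window=config.db_window,
                               cutoff=config.db_dedupe_cutoff,
                               k=config.k, s=config.sketch_size)
    except Exception as exc:  # noqa: BLE001
        raise StageError("build-db", str(exc)) from exc
    db.save(run_dir / "db")
    _log(run_dir, "build-db", **db.provenance)

    # stage: identify
    decision_log: list[dict] = []
    try:
        pls_records = _identify.identify_pls(
            contigs, db, pgms, cgms, annotations,
            cutoff=config.reference_cutoff, k=config.k,
            s=config.sketch_size, decision_log=decision_log)
    except Exception as exc:  # noqa: BLE001
        raise StageError("identify", str(exc)) from exc
    _identify.write_pls_table(pls_records, run_dir / "pls.tsv")
    with open(run_dir / "identify_decisions.jsonl", "w") as fh:
        for entry in decision_log:
            fh.write(json.dumps(entry) + "\n")
    _log(run_dir, "identify", n_pls=len(pls_records))

    # stage: completeness (DTR route; graph route when graphs supplied)
    seqs = {c.contig_id: c.seq for c in contigs}
    comp_results: dict[str, _comp.CompletenessResult] = {}
    read_pairs = read_pairs or {}
    assembly_graphs = assembly_graphs or {}
    for rec in pls_records:
        seq = seqs[rec.contig_id]
        result = None
        if len(seq) >= 2 * config.dtr_min_len:
            dtr = _comp.find_dtr(seq, min_len=config.dtr_min_len,
                                 max_mismatch=config.dtr_max_mismatch,
                                 max_len=2000)
            pairs = read_pairs.get(rec.isolate_id, ())
            if dtr.found and pairs and _comp.confirm_circular_by_reads(
                    seq, dtr, pairs):
                result = _comp.dtr_completeness(rec.contig_id)
        if result is None and rec.isolate_id in assembly_graphs:
            graph = assembly_graphs[rec.isolate_id]
            anchors = _comp.best_hit_anchors(seq, graph)
            if anchors:
                path = _comp.shortest_circular_path(graph, anchors)
                if path is not None:
                    pairs = read_pairs.get(rec.isolate_id, ())
                    if not pairs or _comp.validate_path_with_pairs(
                            path, graph, pairs):
                        result = _comp.estimate_completeness(
                            rec.contig_id, len(seq), path, anchors, graph)
        if result is not None:
            comp_results[rec.contig_id] = result
    with open(run_dir / "completeness.tsv", "w") as fh:
        fh.write("pls_id\tfraction\tmethod\tis_compls\n")
        for r in comp_results.values():
            fh.write(f"{r.pls_id}\t{r.fraction:.4f}\t{r.method}\t{r.is_compls}\n")
    _log(run_dir, "completeness", n_results=len(comp_results))

    # stage: cluster into candidate PLCs
    if pls_records:
        dm = pairwise_distance_matrix(
            {r.contig_id: seqs[r.contig_id] for r in pls_records},
            k=config.k, s=config.sketch_size)
        lengths = {r.contig_id: r.length for r in pls_records}
        plcs = _cluster.build_candidate_plcs(dm, lengths,
                                             cutoff=config.plc_cutoff)
    else:
        plcs = []
    _log(run_dir, "cluster", n_plcs=len(plcs))

    # stage: retain high-confidence PLCs
    complete_members = {cid for cid, r in comp_results.items()
                        if r.method == "dtr_circular" or r.fraction >= 0.999}
    backbone_members = {r.contig_id for r in pls_records if r.backbone_genes}
    retained = _cluster.retain_high_confidence_plcs(
        plcs, complete_members=complete_members,
        backbone_members=backbone_members)
    with open(run_dir / "plc.tsv", "w") as fh:
        fh.write("plc_id\tmember_contig_id\tisolate_id\tretained\n")
        iso = {r.contig_id: r.isolate_id for r in pls_records}
        kept = {p.plc_id for p in retained}
        for p in plcs:
            for m in p.members:
                fh.write(f"{p.plc_id}\t{m}\t{iso[m]}\t{p.plc_id in kept}\n")
    _log(run_dir, "retain", n_retained=len(retained))

    return PipelineResult(run_dir=run_dir, db=db, pls_records=pls_records,
                          plcs=plcs, retained_plcs=retained,
                          completeness=comp_results)
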