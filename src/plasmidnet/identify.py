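"""Two-stage plasmid-like sequence (PLS) calling with phage screening.

Stage I votes each contig (>= 2 kb) against the labeled fragment
database: a contig aligned (Mash distance < 0.15) to more plasmid
fragments than chromosome fragments is a candidate PLS (candidate I);
more chromosome hits discards it; no hits at all leaves it
"undetermined"; equal nonzero hit counts are ambiguous and excluded
from both candidacy and the marker stage.  Stage II promotes an
undetermined contig to candidate II when it encodes at least one
plasmid-like gene marker (PGM) and no chromosome-like gene marker
(CGM).  Finally, contigs with phage-like gene products (terminase,
holin, head, tail, portal, capsid) are removed — this also drops
plasmid-phage elements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .markers import GeneAnnotation
from .refdb import CHROMOSOME, PLASMID, FragmentDB
from .sketch import DEFAULT_K, KmerSketch, build_sketch, mash_distance

MIN_CONTIG_LEN = 2000
REFERENCE_CUTOFF = 0.15
MARKER_EVALUE_MAX = 1e-3
BACKBONE_EVALUE_MAX = 1e-10

PLASMID_LIKE = "plasmid_like"
CHROMOSOME_LIKE = "chromosome_like"
AMBIGUOUS = "ambiguous"
UNDETERMINED = "undetermined"

CANDIDATE_I = "candidate_I"
CANDIDATE_II = "candidate_II"

PHAGE_KEYWORDS = ("terminase", "holin", "head", "tail", "portal", "capsid")

#: Backbone keyword categories (replication, mobilization, conjugation,
#: segregation, stabilization).  'mbp' is matched literally although the
#: tag is ambiguous (mobilization vs maltose-binding); hits are flagged
#: in the decision log.
BACKBONE_KEYWORDS = (
    "rep", "rop", "primase", "mob", "mbp", "relaxase",
    "conj", "tra", "trb", "resolvase", "partition",
)

#: Short gene-symbol stems that must NOT match long English words
#: ("transfer", "transcription" must not hit 'tra'): these match whole
#: tokens or as prefixes of tokens no longer than 5 characters
#: (TraG, TrbB).  All other keywords match any token prefix
#: (replication -> rep, conjugal -> conj, partitioning -> partition).
_SYMBOL_ONLY_PREFIX = {"tra", "trb"}
_MAX_SYMBOL_LEN = 5

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def _tokens(text: str) -> list[str]:
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def _keyword_hits(products: Iterable[str], keywords: Sequence[str],
                  prefix_mode: bool) -> set[str]:
    hits: set[str] = set()
    for product in products:
        toks = _tokens(product)
        for kw in keywords:
            if kw in hits:
                continue
            for tok in toks:
                if tok == kw:
                    hits.add(kw)
                    break
                if not prefix_mode:
                    continue
                if tok.startswith(kw):
                    if kw in _SYMBOL_ONLY_PREFIX:
                        if len(tok) <= _MAX_SYMBOL_LEN:
                            hits.add(kw)
                            break
                    else:
                        hits.add(kw)
                        break
    return hits


@dataclass
class Contig:
    contig_id: str
    isolate_id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class PLSRecord:
    """A called PLS and its evidence trail."""

    contig_id: str
    isolate_id: str
    length: int
    evidence: str  # candidate_I | candidate_II
    n_plasmid_hits: int = 0
    n_chromosome_hits: int = 0
    pgms_found: set[str] = field(default_factory=set)
    backbone_genes: set[str] = field(default_factory=set)
    phage_flag: bool = False


def classify_by_reference(
    contig_sketch: KmerSketch,
    db: FragmentDB,
    cutoff: float = REFERENCE_CUTOFF,
) -> tuple[str, int, int]:
    """Reference vote: (category, n_plasmid_hits, n_chromosome_hits)."""
    if not db.fragments:
        raise ValueError("empty fragment database")
    origins = db.origins
    n_p = n_c = 0
    for fid, fsk in db.sketches.items():
        if mash_distance(contig_sketch, fsk) < cutoff:
            if origins[fid] == PLASMID:
                n_p += 1
            else:
                n_c += 1
    if n_p == 0 and n_c == 0:
        return UNDETERMINED, 0, 0
    if n_p > n_c:
        return PLASMID_LIKE, n_p, n_c
    if n_c > n_p:
        return CHROMOSOME_LIKE, n_p, n_c
    return AMBIGUOUS, n_p, n_c


def classify_by_markers(
    contig_annotations: Iterable[GeneAnnotation],
    pgms: set[str],
    cgms: set[str],
    evalue_max: float = MARKER_EVALUE_MAX,
) -> tuple[bool, set[str]]:
    """Marker rule: >=1 PGM and no CGM.  Returns (is_pls, pgms found)."""
    found_pgm: set[str] = set()
    for a in contig_annotations:
        if a.evalue > evalue_max:
            continue
        if a.gene_id in cgms:
            return False, set()
        if a.gene_id in pgms:
            found_pgm.add(a.gene_id)
    return bool(found_pgm), found_pgm


def phage_screen(contig_annotations: Iterable[GeneAnnotation]) -> bool:
    """True (drop) iff any product carries a phage keyword as a whole word."""
    products = [a.product for a in contig_annotations]
    return bool(_keyword_hits(products, PHAGE_KEYWORDS, prefix_mode=False))


def detect_backbone_genes(
    contig_annotations: Iterable[GeneAnnotation],
    evalue_max: float = BACKBONE_EVALUE_MAX,
) -> set[str]:
    """Which of the 11 plasmid-backbone keyword categories the contig hits."""
    products = [a.product for a in contig_annotations if a.evalue <= evalue_max]
    return _keyword_hits(products, BACKBONE_KEYWORDS, prefix_mode=True)


def identify_pls(
    contigs: Iterable[Contig],
    db: FragmentDB,
    pgms: set[str],
    cgms: set[str],
    annotations: Iterable[GeneAnnotation] = (),
    cutoff: float = REFERENCE_CUTOFF,
    k: int = DEFAULT_K,
    s: int | None = None,
    decision_log: list[dict] | None = None,
) -> list[PLSRecord]:
    """Run the full caller: reference vote -> marker rule -> phage screen.

    ``decision_log``, when supplied, receives one dict per contig with
    its stage outcomes.
    """
    ann_by_contig: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        ann_by_contig.setdefault(a.element_id, []).append(a)
    sketch_s = s if s is not None else (db.provenance.get("s") or 3000)
    records: list[PLSRecord] = []
    for contig in contigs:
        log: dict = {"contig_id": contig.contig_id, "isolate_id": contig.isolate_id}
        if contig.length < MIN_CONTIG_LEN:
            log["decision"] = "rejected_short"
            if decision_log is not None:
                decision_log.append(log)
            continue
        csk = build_sketch(contig.seq, source_id=contig.contig_id,
                           k=k, s=sketch_s)
        cat, n_p, n_c = classify_by_reference(csk, db, cutoff=cutoff)
        log.update(reference=cat, n_plasmid_hits=n_p, n_chromosome_hits=n_c)
        cann = ann_by_contig.get(contig.contig_id, [])
        evidence = None
        pgms_found: set[str] = set()
        if cat == PLASMID_LIKE:
            evidence = CANDIDATE_I
        elif cat == UNDETERMINED:
            is_pls, pgms_found = classify_by_markers(cann, pgms, cgms)
            log["marker_call"] = is_pls
            if is_pls:
                evidence = CANDIDATE_II
        if evidence is None:
            log["decision"] = "not_pls"
            if decision_log is not None:
                decision_log.append(log)
            continue
        dropped = phage_screen(cann)
        log["phage_flag"] = dropped
        if dropped:
            log["decision"] = "phage_removed"
            if decision_log is not None:
                decision_log.append(log)
            continue
        backbone = detect_backbone_genes(cann)
        if "mbp" in backbone:
            log["mbp_ambiguous"] = True
        log["decision"] = evidence
        if decision_log is not None:
            decision_log.append(log)
        records.append(PLSRecord(
            contig_id=contig.contig_id, isolate_id=contig.isolate_id,
            length=contig.length, evidence=evidence,
            n_plasmid_hits=n_p, n_chromosome_hits=n_c,
            pgms_found=pgms_found, backbone_genes=backbone))
    return records


def write_pls_table(records: Iterable[PLSRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tisolate_id\tlength\tevidence\tn_plasmid_hits\t"
                 "n_chromosome_hits\tpgms_found\tbackbone_genes\tphage_flag\n")
        for r in records:
            fh.write("\t".join([
                r.contig_id, r.isolate_id, str(r.length), r.evidence,
                str(r.n_plasmid_hits), str(r.n_chromosome_hits),
                ",".join(sorted(r.pgms_found)),
                ",".join(sorted(r.backbone_genes)),
                str(r.phage_flag),
            ]) + "\n")
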