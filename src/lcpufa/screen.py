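"""Candidate classification: combine ORF, motif, hydropathy and
conserved-residue evidence into Fad/Elovl calls.

A contig passes through, in order: a length pre-filter (>= 200 nt), ORF
extraction, and per-family structural checks on the translated protein.
Desaturase (Fad) candidates must carry the haeme-binding HPGG motif in the
N-terminal region (a proxy for the cytochrome b5-like domain that contains
it), the three histidine boxes HXXXH, HXXHH and QXXHH in that N-to-C
order, and 3-4 predicted membrane-spanning segments.  Elongase (Elovl)
candidates must carry the diagnostic HXXHH box, 5-7 membrane-spanning
segments, and the 17-residue conserved checklist transferred from the
annotated reference Elovl5 protein by global alignment, allowing
conservative substitutions.

Full-length proteins failing one or more structural filters are classified
as putative pseudogenes; ORFs below the family length window (or truncated
by the contig end) with residual family evidence are partial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import tm
from .align import PROTEIN_SCHEME, ScoringScheme, global_align, map_reference_positions
from .motif import MotifHit, ResidueAnnotation, scan
from .orfs import ELOVL_LEN_WINDOW, FAD_LEN_WINDOW, Orf, find_orfs, is_full_length
from .profiles import ProfileSet, load_builtin_profiles
from .seqio import SeqRecord, read_fasta

#: Conservative substitution groups accepted at checklist positions; the
#: observed T<->S, L<->V and L<->A pairs generalised to standard classes.
CONSERVATIVE_GROUPS = (
    frozenset("ST"),
    frozenset("LVIA"),
    frozenset("FY"),
    frozenset("KR"),
    frozenset("DE"),
    frozenset("NQ"),
)

FilterResult = Tuple[str, bool, str]


@dataclass
class ScreenConfig:
    min_contig_nt: int = 200
    min_scan_aa: int = 100  # minimum ORF length considered at all
    fad_len_window: Tuple[int, int] = FAD_LEN_WINDOW
    elovl_len_window: Tuple[int, int] = ELOVL_LEN_WINDOW
    haeme_nterm_limit: int = 80
    tm_window: int = tm.DEFAULT_WINDOW
    tm_threshold: float = tm.DEFAULT_THRESHOLD
    tm_min_len: int = tm.DEFAULT_MIN_LEN
    tm_min_gap: int = tm.DEFAULT_MIN_GAP
    max_residue_mismatches: int = 1
    #: minimum count of passing *motif* filters for a non-functional ORF to
    #: be reported as a family member (pseudogene/partial) at all
    min_motif_passes: int = 1
    #: alternatively, minimum fractional identity to a family reference
    #: protein (the homology-annotation stand-in) for family membership
    min_reference_identity: float = 0.4
    scheme: ScoringScheme = field(default_factory=lambda: PROTEIN_SCHEME)

    def __post_init__(self) -> None:
        for name in ("min_contig_nt", "min_scan_aa", "haeme_nterm_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for win in (self.fad_len_window, self.elovl_len_window):
            if win[0] > win[1]:
                raise ValueError(f"empty length window {win}")

    def tm_kwargs(self) -> Dict:
        return dict(
            window=self.tm_window,
            threshold=self.tm_threshold,
            min_len=self.tm_min_len,
            min_gap=self.tm_min_gap,
        )


@dataclass
class References:
    """Reference material consumed by the screen.

    ``elovl_reference`` carries the conserved-residue checklist;
    ``fad_reference`` is used, together with ``elovl_reference``, to assign
    a family to non-functional (pseudogene/partial) candidates by global
    alignment similarity — the stand-in for homology-search annotation.
    """

    elovl_reference: SeqRecord
    elovl_annotation: ResidueAnnotation
    fad_reference: Optional[SeqRecord] = None
    profiles: ProfileSet = field(default_factory=load_builtin_profiles)


@dataclass
class CandidateCall:
    record_id: str
    family: str  # 'Fad', 'Elovl' or 'none'
    status: str  # 'functional', 'putative_pseudogene', 'partial', 'rejected'
    evidence: List[FilterResult]
    orf: Optional[Orf] = None
    tm_count: Optional[int] = None
    detail: str = ""


def _fmt_hits(hits: List[MotifHit]) -> str:
    return ",".join(str(h.start) for h in hits) if hits else "absent"


def check_fad_structure(
    protein: str, cfg: ScreenConfig, profiles: Optional[ProfileSet] = None
) -> List[FilterResult]:
    """Evaluate the desaturase structural filters on a protein.

    Filters, in order: HPGG within the first ``haeme_nterm_limit`` residues
    (cytochrome b5-like domain proxy); presence of each of HXXXH, HXXHH,
    QXXHH; strict N-to-C ordering HPGG < HXXXH < HXXHH < QXXHH; predicted
    membrane-spanning segment count in 3-4.
    """
    profiles = profiles or load_builtin_profiles()
    p = profiles.patterns
    haeme_hits = [
        h for h in scan(protein, p["haeme"])
        if h.start < cfg.haeme_nterm_limit
    ]
    box_hits = {name: scan(protein, p[name]) for name in
                ("fad_box1", "fad_box2", "fad_box3")}
    results: List[FilterResult] = [
        (
            "haeme_hpgg_nterm",
            bool(haeme_hits),
            f"HPGG within first {cfg.haeme_nterm_limit} aa: {_fmt_hits(haeme_hits)}",
        )
    ]
    for name, label in (
        ("fad_box1", "HXXXH"), ("fad_box2", "HXXHH"), ("fad_box3", "QXXHH")
    ):
        results.append(
            (name, bool(box_hits[name]), f"{label} at {_fmt_hits(box_hits[name])}")
        )
    # ordering: the motifs that ARE present must admit a strictly
    # increasing chain HPGG < HXXXH < HXXHH < QXXHH (absent motifs are
    # skipped so a single deletion flips only its own presence filter);
    # greedy earliest-feasible choice decides chain existence
    ordered = True
    last = -1
    for hits in (haeme_hits, box_hits["fad_box1"], box_hits["fad_box2"],
                 box_hits["fad_box3"]):
        if not hits:
            continue
        nxt = next((h.start for h in hits if h.start > last), None)
        if nxt is None:
            ordered = False
            break
        last = nxt
    results.append(("box_order", ordered, "HPGG < HXXXH < HXXHH < QXXHH"))
    if len(protein) >= cfg.tm_window:
        count = tm.tm_count(protein, **cfg.tm_kwargs())
    else:
        count = 0
    results.append(
        ("tm_count", tm.tm_count_ok(count, "Fad"), f"{count} segments (need 3-4)")
    )
    return results


def classify_residue(candidate_res: Optional[str], expected: str) -> str:
    """'match', 'conservative' or 'mismatch' for a checklist position."""
    if candidate_res == expected:
        return "match"
    if candidate_res is not None:
        for group in CONSERVATIVE_GROUPS:
            if candidate_res in group and expected in group:
                return "conservative"
    return "mismatch"


def check_elovl_structure(
    protein: str,
    reference: SeqRecord,
    cfg: ScreenConfig,
    annotation: Optional[ResidueAnnotation] = None,
    profiles: Optional[ProfileSet] = None,
) -> List[FilterResult]:
    """Evaluate the elongase structural filters on a protein.

    Filters: the diagnostic HXXHH box; membrane-spanning segment count in
    5-7; the conserved-residue checklist transferred from the reference by
    global alignment (pass iff non-conservative mismatches, including
    unaligned positions, do not exceed ``max_residue_mismatches``).
    """
    profiles = profiles or load_builtin_profiles()
    annotation = annotation or profiles.annotations["elovl_checklist"]
    hits = scan(protein, profiles.patterns["elovl_box"])
    results: List[FilterResult] = [
        ("elovl_box", bool(hits), f"HXXHH at {_fmt_hits(hits)}")
    ]
    if len(protein) >= cfg.tm_window:
        count = tm.tm_count(protein, **cfg.tm_kwargs())
    else:
        count = 0
    results.append(
        ("tm_count", tm.tm_count_ok(count, "Elovl"), f"{count} segments (need 5-7)")
    )
    cand = SeqRecord(id="candidate", residues=protein, alphabet="protein")
    mapping = map_reference_positions(reference, cand, annotation, cfg.scheme)
    tallies = {"match": 0, "conservative": 0, "mismatch": 0}
    for (pos, expected), (_, _, cand_res, _) in zip(annotation.positions, mapping):
        tallies[classify_residue(cand_res, expected)] += 1
    ok = tallies["mismatch"] <= cfg.max_residue_mismatches
    results.append(
        (
            "residue_checklist",
            ok,
            f"{tallies['match']} match, {tallies['conservative']} conservative, "
            f"{tallies['mismatch']} mismatch (max {cfg.max_residue_mismatches})",
        )
    )
    return results


#: Filters whose pass signals family-diagnostic motif content.
MOTIF_FILTERS = frozenset(
    {"haeme_hpgg_nterm", "fad_box1", "fad_box2", "fad_box3", "elovl_box"}
)


def _passes(evidence: List[FilterResult]) -> int:
    return sum(ok for _, ok, _ in evidence)


def _motif_passes(evidence: List[FilterResult]) -> int:
    return sum(ok for name, ok, _ in evidence if name in MOTIF_FILTERS)


def _reference_identity(
    protein: str, refs: References, scheme: ScoringScheme
) -> Dict[str, float]:
    """Fractional identity (matching columns / alignment length) of the
    candidate against each family reference — the homology-annotation
    stand-in used for family assignment of non-functional candidates."""
    cand = SeqRecord(id="query", residues=protein, alphabet="protein")
    pairs = [("Elovl", refs.elovl_reference)]
    if refs.fad_reference is not None:
        pairs.append(("Fad", refs.fad_reference))
    out = {}
    for fam, ref in pairs:
        al, _ = global_align(cand, ref, scheme)
        (_, row_a), (_, row_b) = al.rows
        matches = sum(x == y for x, y in zip(row_a, row_b) if x != "-")
        out[fam] = matches / al.ncol if al.ncol else 0.0
    return out


def _best_orf(orfs: List[Orf], window: Tuple[int, int]) -> Optional[Orf]:
    """Best ORF for a family window: prefer full-length in-window, else the
    longest candidate."""
    for orf in orfs:  # orfs are sorted by descending length
        if is_full_length(orf, window):
            return orf
    return orfs[0] if orfs else None


def classify_candidate(
    contig: SeqRecord, cfg: ScreenConfig, refs: References
) -> CandidateCall:
    """Classify one contig as a Fad/Elovl functional gene, putative
    pseudogene, partial gene, or reject it."""
    if len(contig) < cfg.min_contig_nt:
        return CandidateCall(
            record_id=contig.id, family="none", status="rejected",
            evidence=[], detail=f"below {cfg.min_contig_nt} nt",
        )
    orfs = find_orfs(contig, min_aa=cfg.min_scan_aa)
    if not orfs:
        return CandidateCall(
            record_id=contig.id, family="none", status="rejected",
            evidence=[], detail=f"no ORF of >= {cfg.min_scan_aa} aa",
        )

    assessments = {}
    for family, window in (
        ("Fad", cfg.fad_len_window), ("Elovl", cfg.elovl_len_window)
    ):
        orf = _best_orf(orfs, window)
        if family == "Fad":
            evidence = check_fad_structure(orf.aa, cfg, refs.profiles)
        else:
            evidence = check_elovl_structure(
                orf.aa, refs.elovl_reference, cfg,
                refs.elovl_annotation, refs.profiles,
            )
        assessments[family] = (orf, evidence, is_full_length(orf, window))

    full_pass = {
        fam: all(ok for _, ok, _ in ev)
        for fam, (orf, ev, full) in assessments.items()
    }
    functional = {
        fam for fam, (orf, ev, full) in assessments.items()
        if full and full_pass[fam]
    }
    if len(functional) == 2:
        scores = {fam: _passes(assessments[fam][1]) for fam in functional}
        if scores["Fad"] == scores["Elovl"]:
            return CandidateCall(
                record_id=contig.id, family="none", status="rejected",
                evidence=assessments["Fad"][1] + assessments["Elovl"][1],
                detail="ambiguous: both family checks passed",
            )
        functional = {max(scores, key=scores.get)}
    if functional:
        fam = next(iter(functional))
        orf, ev, _ = assessments[fam]
        return CandidateCall(
            record_id=contig.id, family=fam, status="functional",
            evidence=ev, orf=orf, tm_count=_tm_from_evidence(ev),
        )

    # No functional call.  Assign the family first (reference identity,
    # falling back on motif content), then judge full-length within that
    # family's window: full-length with failing filters -> pseudogene,
    # sub-full-length -> partial; no family evidence at all -> rejected.
    identity = _reference_identity(orfs[0].aa, refs, cfg.scheme)
    best_fam = max(sorted(identity), key=lambda f: identity[f])
    total_motifs = max(
        _motif_passes(ev) for _, (orf, ev, full) in assessments.items()
    )
    has_evidence = (
        identity[best_fam] >= cfg.min_reference_identity
        or total_motifs >= cfg.min_motif_passes
    )
    if not has_evidence:
        orf, ev, _ = assessments["Fad"]
        return CandidateCall(
            record_id=contig.id, family="none", status="rejected",
            evidence=ev, orf=orf, detail="no family evidence",
        )
    if identity[best_fam] < cfg.min_reference_identity:
        # motif evidence only: pick the family with more motif passes
        best_fam = max(
            sorted(assessments),
            key=lambda f: _motif_passes(assessments[f][1]),
        )
    orf, ev, full = assessments[best_fam]
    if full:
        return CandidateCall(
            record_id=contig.id, family=best_fam, status="putative_pseudogene",
            evidence=ev, orf=orf, tm_count=_tm_from_evidence(ev),
            detail="full-length but failing structural filters: "
            + ";".join(name for name, ok, _ in ev if not ok),
        )
    return CandidateCall(
        record_id=contig.id, family=best_fam, status="partial",
        evidence=ev, orf=orf, tm_count=_tm_from_evidence(ev),
        detail="sub-full-length ORF with family evidence",
    )


def _tm_from_evidence(evidence: List[FilterResult]) -> Optional[int]:
    for name, _, det in evidence:
        if name == "tm_count":
            return int(det.split()[0])
    return None


def screen_transcriptome(
    fasta_path, cfg: ScreenConfig, refs: References, out_dir=None
) -> pd.DataFrame:
    """Classify every contig in a FASTA file.

    Returns a calls table; when ``out_dir`` is given, writes ``calls.tsv``
    and ``summary.json`` (counts per family and status) there.
    """
    records = read_fasta(fasta_path, alphabet="nucleotide")
    calls = [classify_candidate(rec, cfg, refs) for rec in records]
    rows = []
    for call in calls:
        rows.append(
            {
                "record_id": call.record_id,
                "family": call.family,
                "status": call.status,
                "aa_len": len(call.orf.aa) if call.orf else 0,
                "tm_count": call.tm_count if call.tm_count is not None else "",
                "filters_failed": ";".join(
                    name for name, ok, _ in call.evidence if not ok
                ),
                "detail": call.detail,
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "calls.tsv", sep="\t", index=False)
        summary = {
            "n_records": len(calls),
            "counts": table.groupby(["family", "status"])
            .size()
            .reset_index(name="n")
            .to_dict(orient="records"),
            "note": "membrane-segment counts from hydropathy profile scanning",
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return table
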