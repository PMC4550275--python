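"""Pairwise global alignment, progressive multiple alignment, conserved
columns, and reference-position mapping.

Pairwise alignment is optimal Needleman-Wunsch with affine gaps (a gap of
length k costs ``gap_open + k * gap_extend``; both penalties are <= 0),
BLOSUM62 for proteins and +5/-4 for nucleotides, with an optional
free-end-gaps variant used when aligning Sanger clones against assembled
ORFs.  Multiple alignment is progressive: a neighbor-joining guide tree
from pairwise alignment distances, profile-profile merges in guide-tree
order, and one round of leave-one-out refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices as _submat

from .motif import ResidueAnnotation
from .seqio import SeqRecord

GAP = "-"

_PROTEIN_ORDER = "ACDEFGHIKLMNPQRSTVWYX*"
_NUC_ORDER = "ACGTN"


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring for global alignment.

    ``matrix_name`` is ``"BLOSUM62"`` for proteins or ``"NUC"`` for the
    match/mismatch nucleotide scheme.  Gap convention: a gap of length k
    costs ``gap_open + k * gap_extend`` (both values <= 0).
    """

    matrix_name: str = "BLOSUM62"
    match: int = 5
    mismatch: int = -4
    gap_open: float = -10.0
    gap_extend: float = -1.0
    end_gaps_free: bool = False

    @property
    def alphabet(self) -> str:
        return "protein" if self.matrix_name == "BLOSUM62" else "nucleotide"


#: Default protein scheme used for structural screens and protein MSAs.
PROTEIN_SCHEME = ScoringScheme()

#: Nucleotide scheme for ORF-scale alignments.
NUCLEOTIDE_SCHEME = ScoringScheme(matrix_name="NUC")

#: Preset used for clone-vs-assembly validation: global nucleotide
#: alignment with free end gaps so UTR overhang is not penalised.
CLONE_VALIDATION_SCHEME = ScoringScheme(matrix_name="NUC", end_gaps_free=True)


@dataclass
class Alignment:
    """A gapped alignment; all rows have equal length ``ncol``."""

    rows: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> List[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")


def _as_parts(x: Union[SeqRecord, str], default_id: str) -> Tuple[str, str]:
    if isinstance(x, SeqRecord):
        return x.id, x.residues
    return default_id, str(x).upper()


def _make_aligner(s: ScoringScheme) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "global"
    if s.matrix_name == "NUC":
        aligner.match_score = s.match
        aligner.mismatch_score = s.mismatch
    else:
        aligner.substitution_matrix = _submat.load(s.matrix_name)
    aligner.open_internal_gap_score = s.gap_open + s.gap_extend
    aligner.extend_internal_gap_score = s.gap_extend
    if s.end_gaps_free:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    else:
        aligner.open_end_gap_score = s.gap_open + s.gap_extend
        aligner.extend_end_gap_score = s.gap_extend
    return aligner


def global_align(
    a: Union[SeqRecord, str],
    b: Union[SeqRecord, str],
    s: ScoringScheme = PROTEIN_SCHEME,
) -> Tuple[Alignment, float]:
    """Optimal global alignment of two sequences under ``s``.

    Returns the alignment and its score.  Ties between co-optimal
    alignments are broken deterministically (first traceback).
    """
    id_a, seq_a = _as_parts(a, "a")
    id_b, seq_b = _as_parts(b, "b")
    for rec in (a, b):
        if isinstance(rec, SeqRecord) and rec.alphabet != s.alphabet:
            raise ValueError(
                f"record {rec.id!r} alphabet {rec.alphabet!r} does not match "
                f"scheme alphabet {s.alphabet!r}"
            )
    if not seq_a or not seq_b:
        n = max(len(seq_a), len(seq_b))
        score = 0.0 if (s.end_gaps_free or n == 0) else s.gap_open + n * s.gap_extend
        return (
            Alignment(rows=[(id_a, seq_a or GAP * n), (id_b, seq_b or GAP * n)]),
            score,
        )
    aligner = _make_aligner(s)
    result = aligner.align(seq_a, seq_b)
    best = result[0]
    return Alignment(rows=[(id_a, str(best[0])), (id_b, str(best[1]))]), best.score


# ---------------------------------------------------------------------------
# Profile machinery for progressive MSA
# ---------------------------------------------------------------------------

def _score_matrix(s: ScoringScheme) -> Tuple[str, np.ndarray]:
    """Dense substitution matrix over alphabet+gap; gap scores 0."""
    if s.matrix_name == "NUC":
        order = _NUC_ORDER
        m = np.full((len(order), len(order)), float(s.mismatch))
        np.fill_diagonal(m, float(s.match))
        n_idx = order.index("N")
        m[n_idx, :] = 0.0
        m[:, n_idx] = 0.0
    else:
        blosum = _submat.load(s.matrix_name)
        order = _PROTEIN_ORDER
        m = np.zeros((len(order), len(order)))
        for i, x in enumerate(order):
            for j, y in enumerate(order):
                m[i, j] = blosum[x, y]
    full = np.zeros((len(order) + 1, len(order) + 1))
    full[: len(order), : len(order)] = m
    return order + GAP, full


def _profile_freqs(rows: List[str], order: str) -> np.ndarray:
    index = {c: i for i, c in enumerate(order)}
    ncol = len(rows[0])
    freq = np.zeros((ncol, len(order)))
    for row in rows:
        for j, c in enumerate(row):
            freq[j, index[c]] += 1.0
    return freq / len(rows)


def _profile_align(
    rows_a: List[str], rows_b: List[str], s: ScoringScheme
) -> Tuple[List[str], List[str]]:
    """Affine-gap NW on two profiles; returns gapped row groups."""
    order, smat = _score_matrix(s)
    fa = _profile_freqs(rows_a, order)
    fb = _profile_freqs(rows_b, order)
    pair = fa @ smat @ fb.T  # column-vs-column expected score
    la, lb = pair.shape
    go, ge = s.gap_open + s.gap_extend, s.gap_extend
    neg = -1e30
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, lb + 1):
        Y[0, j] = go + (j - 1) * ge
    tb_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        cur_m, cur_x = M[i], X[i]
        # X: gap in B, move down. Vectorised over j.
        cand = np.stack([prev_m + go, prev_x + ge, prev_y + go])
        tb_x[i] = np.argmax(cand, axis=0)
        X[i] = cand[tb_x[i], np.arange(lb + 1)]
        # M and Y need left neighbours: loop over j.
        scores_i = pair[i - 1]
        for j in range(1, lb + 1):
            cand_m = (prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            k = int(np.argmax(cand_m))
            tb_m[i, j] = k
            M[i, j] = cand_m[k] + scores_i[j - 1]
            cand_y = (cur_m[j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
            k = int(np.argmax(cand_y))
            tb_y[i, j] = k
            Y[i, j] = cand_y[k]
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    out_a: List[str] = []
    out_b: List[str] = []
    ga = GAP * len(rows_a)
    gb = GAP * len(rows_b)
    while i > 0 or j > 0:
        if state == 0:
            prev = tb_m[i, j]
            out_a.append("".join(r[i - 1] for r in rows_a))
            out_b.append("".join(r[j - 1] for r in rows_b))
            i, j = i - 1, j - 1
        elif state == 1:
            prev = tb_x[i, j]
            out_a.append("".join(r[i - 1] for r in rows_a))
            out_b.append(gb)
            i -= 1
        else:
            prev = tb_y[i, j]
            out_a.append(ga)
            out_b.append("".join(r[j - 1] for r in rows_b))
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
        else:
            state = int(prev)
    cols_a = out_a[::-1]
    cols_b = out_b[::-1]
    new_a = ["".join(col[k] for col in cols_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in cols_b) for k in range(len(rows_b))]
    return new_a, new_b


def sp_score(al: Alignment, s: ScoringScheme = PROTEIN_SCHEME) -> float:
    """Sum-of-pairs score with affine gap penalties per pairwise projection."""
    total = 0.0
    order, smat = _score_matrix(s)
    index = {c: i for i, c in enumerate(order)}
    rows = [seq for _, seq in al.rows]
    go, ge = s.gap_open, s.gap_extend
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            in_gap = False
            for x, y in zip(a, b):
                if x == GAP and y == GAP:
                    continue
                if x == GAP or y == GAP:
                    total += (go + ge) if not in_gap else ge
                    in_gap = True
                else:
                    total += smat[index[x], index[y]]
                    in_gap = False
    return total


def _drop_all_gap_columns(rows: List[str]) -> List[str]:
    keep = [j for j in range(len(rows[0])) if any(r[j] != GAP for r in rows)]
    return ["".join(r[j] for j in keep) for r in rows]


def progressive_msa(
    seqs: Sequence[SeqRecord],
    s: ScoringScheme = PROTEIN_SCHEME,
    refine: bool = True,
) -> Alignment:
    """Progressive multiple alignment guided by a neighbor-joining tree.

    Pairwise alignment distances (1 - fractional identity) feed NJ; profiles
    are merged following the midpoint-rooted guide tree; one round of
    leave-one-out refinement re-aligns each sequence against the remaining
    profile and keeps the result when the sum-of-pairs score improves.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires >= 2 sequences")
    if len({rec.id for rec in seqs}) != len(seqs):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 2:
        al, _ = global_align(seqs[0], seqs[1], s)
        return al

    from . import phylo  # deferred: phylo depends on this module

    ids = [rec.id for rec in seqs]
    by_id = {rec.id: rec for rec in seqs}
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            al, _ = global_align(seqs[i], seqs[j], s)
            (_, ra), (_, rb) = al.rows
            pairs = [
                (x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP
            ]
            ident = sum(x == y for x, y in pairs) / max(len(pairs), 1)
            dist[i, j] = dist[j, i] = 1.0 - ident
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels=ids, d=dist))

    def merge(node) -> Dict[str, str]:
        if node.is_leaf():
            rec = by_id[node.taxon.label]
            return {rec.id: rec.residues}
        groups = [merge(ch) for ch in node.child_nodes()]
        if node.taxon is not None:  # degenerate rooting: leaf with children
            rec = by_id[node.taxon.label]
            groups.append({rec.id: rec.residues})
        children = sorted(groups, key=lambda grp: min(grp))
        group = children[0]
        for other in children[1:]:
            ids_a, rows_a = list(group), list(group.values())
            ids_b, rows_b = list(other), list(other.values())
            new_a, new_b = _profile_align(rows_a, rows_b, s)
            group = dict(zip(ids_a, new_a)) | dict(zip(ids_b, new_b))
        return group

    aligned = merge(tree.seed_node)
    rows = [(rid, aligned[rid]) for rid in ids]
    al = Alignment(rows=rows)

    if refine:
        best = sp_score(al, s)
        for rid in ids:
            others = [(r, seq) for r, seq in al.rows if r != rid]
            other_rows = _drop_all_gap_columns([seq for _, seq in others])
            new_o, new_s = _profile_align(
                other_rows, [al.ungapped(rid)], s
            )
            cand_rows = list(zip([r for r, _ in others], new_o)) + [
                (rid, new_s[0])
            ]
            cand_rows = [(r, q) for r, q in cand_rows]
            cand = Alignment(
                rows=[(r, q) for r, q in sorted(
                    cand_rows, key=lambda t: ids.index(t[0])
                )]
            )
            cand_score = sp_score(cand, s)
            if cand_score > best:
                al, best = cand, cand_score
    return al


def conserved_columns(al: Alignment, include_gapped: bool = False) -> int:
    """Number of columns where every row carries the identical residue.

    Columns containing a gap are not conserved unless ``include_gapped``,
    in which case gaps are ignored and the remaining residues must agree
    (with at least one residue present).
    """
    count = 0
    for j in range(al.ncol):
        col = [seq[j] for _, seq in al.rows]
        residues = [c for c in col if c != GAP]
        if not residues:
            continue
        if not include_gapped and len(residues) != len(col):
            continue
        if len(set(residues)) == 1:
            count += 1
    return count


def map_reference_positions(
    reference: SeqRecord,
    candidate: SeqRecord,
    ann: ResidueAnnotation,
    s: ScoringScheme = PROTEIN_SCHEME,
) -> List[Tuple[int, Optional[int], Optional[str], Optional[str]]]:
    """Map annotated reference positions onto a candidate via global alignment.

    Returns, for each annotated (1-based) reference position, a tuple
    ``(ref_pos, cand_pos or None, cand_residue or None, warning or None)``
    where ``cand_pos`` is 1-based on the candidate and ``None`` marks a gap
    in the candidate at that column.  A warning string is attached when the
    reference residue at the stated position differs from the annotation's
    expectation; the mapping still proceeds.
    """
    for pos, _ in ann.positions:
        if pos > len(reference.residues):
            raise ValueError(
                f"annotation position {pos} beyond reference length "
                f"{len(reference.residues)}"
            )
    al, _ = global_align(reference, candidate, s)
    (_, ref_row), (_, cand_row) = al.rows
    ref_pos_at_col: Dict[int, int] = {}
    rp = 0
    cand_pos_at_col: Dict[int, int] = {}
    cp = 0
    for col in range(al.ncol):
        if ref_row[col] != GAP:
            rp += 1
            ref_pos_at_col[rp] = col
        if cand_row[col] != GAP:
            cp += 1
            cand_pos_at_col[col] = cp
    out = []
    for pos, expected in ann.positions:
        warning = None
        if reference.residues[pos - 1] != expected:
            warning = (
                f"reference residue {reference.residues[pos - 1]} at {pos} "
                f"differs from annotation {expected}"
            )
        col = ref_pos_at_col[pos]
        if cand_row[col] == GAP:
            out.append((pos, None, None, warning))
        else:
            out.append((pos, cand_pos_at_col[col], cand_row[col], warning))
    return out
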