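"""Clone-vs-assembly comparison: percent nucleotide identity and
synonymous/nonsynonymous SNP classification.

Sanger-sequenced clones are aligned against the assembled ORF they were
amplified from (global nucleotide alignment, free end gaps, so UTR
overhang is trimmed rather than penalised).  Mismatch columns inside the
ORF span are classified by translating both codons in the assembled
reading frame; percent identity is computed over the ORF span and rounded
half-up to one decimal to match the convention of reported validation
figures (e.g. five synonymous SNPs over a 1293-nt ORF -> 99.6%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Tuple, Union

from .align import CLONE_VALIDATION_SCHEME, GAP, ScoringScheme, global_align
from .orfs import Orf
from .seqio import translate


@dataclass
class CloneComparison:
    orf_len_nt: int
    n_mismatch: int
    n_synonymous: int
    n_nonsynonymous: int
    n_indel_cols: int
    pct_identity: float
    snps: List[Tuple[int, str, str, str]] = None  # (orf pos, from, to, class)


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def classify_snp(codon_a: str, codon_b: str) -> str:
    """'identical', 'synonymous' or 'nonsynonymous' for two codons."""
    if len(codon_a) != 3 or len(codon_b) != 3:
        raise ValueError("codons must be 3 nt")
    if codon_a == codon_b:
        return "identical"
    return "synonymous" if translate(codon_a) == translate(codon_b) else "nonsynonymous"


def compare_orfs(
    assembled_orf: Union[Orf, str],
    clone_nt: str,
    scheme: ScoringScheme = CLONE_VALIDATION_SCHEME,
) -> CloneComparison:
    """Compare a clone sequence against an assembled ORF.

    The clone is aligned with free end gaps; mismatch columns within the
    ORF span are counted and classified codon-wise (synonymous iff the
    substituted codon translates identically).  Internal indels are
    reported via ``n_indel_cols`` and flag the identity as computed over
    aligned columns only.
    """
    orf_nt = assembled_orf.nt if isinstance(assembled_orf, Orf) else str(assembled_orf)
    orf_nt = orf_nt.upper()
    al, _ = global_align(orf_nt, clone_nt.upper(), scheme)
    (_, orf_row), (_, clone_row) = al.rows

    orf_pos = -1
    n_mismatch = n_syn = n_nonsyn = n_indel = 0
    aligned_cols = 0
    snps: List[Tuple[int, str, str, str]] = []
    # clone residues aligned to each ORF position (None at indels)
    clone_at: List[Union[str, None]] = [None] * len(orf_nt)
    for o, c in zip(orf_row, clone_row):
        if o != GAP:
            orf_pos += 1
            if c == GAP:
                n_indel += 1
            else:
                clone_at[orf_pos] = c
                aligned_cols += 1
        else:
            # insertion in the clone; only counts inside the ORF span
            if 0 <= orf_pos < len(orf_nt) - 1:
                n_indel += 1
    for pos, (ref, obs) in enumerate(zip(orf_nt, clone_at)):
        if obs is None or obs == ref:
            continue
        n_mismatch += 1
        codon_start = 3 * (pos // 3)
        codon_ref = orf_nt[codon_start : codon_start + 3]
        codon_obs = "".join(
            clone_at[codon_start + k] or codon_ref[k] for k in range(3)
        )
        kind = classify_snp(codon_ref, codon_obs)
        if kind == "synonymous":
            n_syn += 1
        else:
            n_nonsyn += 1
        snps.append((pos, ref, obs, kind))
    if n_indel == 0:
        pct = round_half_up(100.0 * (len(orf_nt) - n_mismatch) / len(orf_nt))
    else:
        pct = round_half_up(
            100.0 * (aligned_cols - n_mismatch) / max(aligned_cols, 1)
        )
    return CloneComparison(
        orf_len_nt=len(orf_nt),
        n_mismatch=n_mismatch,
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
        n_indel_cols=n_indel,
        pct_identity=pct,
        snps=snps,
    )
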