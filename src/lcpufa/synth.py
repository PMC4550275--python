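"""Synthetic transcriptomes with planted Fad/Elovl genes and known truth.

The generator emulates the inputs the screening pipeline was designed for:
assembled transcript contigs containing full-length desaturase and
elongase ORFs with correct motif architecture and membrane topology,
full-length pseudogenised copies (a structural motif knocked out),
partial/truncated copies, allelic clone pairs with planted synonymous
SNPs, random decoy contigs, and gap-free nucleotide alignments evolved on
known trees under K2P-type models.

Each gene family is derived from a fixed family template so that members
share ~85-90% protein identity (as homologous family members do); motif
boxes, the haeme-binding tetrapeptide, checklist residues and hydrophobic
membrane stretches are stamped at fixed template coordinates and
per-member substitution noise is class-preserving, so planted structure
survives in every lesion-free member.  Every generated record carries a
truth entry sufficient to decide each screening filter without running
the screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from . import phylo
from .align import Alignment
from .motif import ResidueAnnotation
from .phylo import DistanceModelParams, mixture_rates, stationary_freqs, transition_matrix
from .profiles import load_builtin_profiles
from .seqio import CODON_TO_AA, SeqRecord, revcomp, translate, write_fasta

#: Residue pools.  Hydrophobic stretches avoid H so no spurious histidine
#: boxes can arise; linkers avoid H and P so neither boxes nor HPGG can.
#: Guard bands flanking each membrane stretch use only the strongly
#: hydrophilic subset so hydropathy windows cannot bridge two stretches.
HYDROPHOBIC = "LIVF"
LINKER = "EKRDNQSG"
STRONG_LINKER = "EKRDNQ"
GUARD = 10  # guard-band width on each side of a membrane stretch

_AA_TO_CODONS: Dict[str, List[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)

STOP_CHOICES = ("TAA", "TAG", "TGA")

# Template geometry (0-based).  Desaturase: haeme motif near the N
# terminus, three histidine boxes in canonical order, four candidate
# membrane-stretch slots.  Elongase: diagnostic box and the 17 checklist
# residues at the coordinates of the reference annotation, five or six
# stretch slots.
FAD_TEMPLATE_LEN = 480
FAD_HPGG_POS = 29
FAD_BOX1_POS = 119
FAD_BOX2_POS = 154
FAD_BOX3_POS = 349
FAD_TM_SLOTS = (45, 165, 220, 280)

ELOVL_TEMPLATE_LEN = 340
ELOVL_BOX_POS = 147
ELOVL_TM_SLOTS = (5, 48, 91, 154, 213)
ELOVL_TM_SLOT_TAIL = 256  # used only when the member is long enough

TM_LEN = 21

_FAD_TEMPLATE_SEED = 20150826
_ELOVL_TEMPLATE_SEED = 20150827

#: Protein length of the synthetic annotated elongase reference.
ELOVL_REFERENCE_LEN = 294


@dataclass
class SynthParams:
    """Generator configuration; the defaults are the study conditions.

    Family protein-length ranges follow the lengths observed across the
    surveyed molluscs (desaturases 428-445 aa, elongases 261-324 aa).
    """

    n_fad: int = 5
    n_elovl: int = 5
    n_pseudo: int = 3
    n_partial: int = 3
    n_decoys: int = 100
    fad_len: Tuple[int, int] = (428, 445)
    elovl_len: Tuple[int, int] = (261, 324)
    utr_len: Tuple[int, int] = (30, 150)
    noise_rate: float = 0.08
    truncate_frac: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fad", "n_elovl", "n_pseudo", "n_partial", "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fad_len[1] > FAD_TEMPLATE_LEN or self.elovl_len[1] > ELOVL_TEMPLATE_LEN:
            raise ValueError("requested length exceeds family template")
        if self.fad_len[0] < FAD_BOX3_POS + 5 + 1:
            raise ValueError("desaturase length window below final box position")
        if self.elovl_len[0] < 255:
            raise ValueError("elongase length window below last checklist residue")


@dataclass
class PlantedGene:
    """A generated transcript plus the ledger entry describing it."""

    record: SeqRecord
    family: str
    category: str  # functional / pseudogene / partial
    expected_status: str
    lesion: str
    strand: str
    orf_start: int
    orf_end: int
    aa_len: int
    protein: str
    cds: str  # coding sequence in ORF orientation, stop excluded
    mrna_forward: str  # transcript in ORF orientation (before strand flip)
    utr5_len: int
    utr3_len: int
    motif_positions: Dict[str, int] = field(default_factory=dict)
    tm_planted: int = 0
    snps: List[Tuple[int, str, str, bool]] = field(default_factory=list)


def _template(length: int, seed: int, tm_slots: Sequence[int]) -> List[str]:
    rng = np.random.default_rng(seed)
    residues = [LINKER[i] for i in rng.integers(0, len(LINKER), size=length)]
    for slot in tm_slots:
        for k in range(max(0, slot - GUARD), min(length, slot + TM_LEN + GUARD)):
            residues[k] = STRONG_LINKER[rng.integers(0, len(STRONG_LINKER))]
        for k in range(TM_LEN):
            residues[slot + k] = HYDROPHOBIC[rng.integers(0, len(HYDROPHOBIC))]
    return residues


def _fad_anchor_map(rng: np.random.Generator) -> Dict[int, str]:
    """Anchor residues for one desaturase member; degenerate box positions
    drawn from the observed consensus variants."""
    anchors: Dict[int, str] = {}
    for offset, ch in enumerate("HPGG"):
        anchors[FAD_HPGG_POS + offset] = ch
    box1 = "HD" + ("F" if rng.random() < 0.5 else "Y") + "GH"
    box2 = ("H" + ("Y" if rng.random() < 0.5 else "F")
            + ("Q" if rng.random() < 0.5 else "L") + "HH")
    box3 = "Q" + ("I" if rng.random() < 0.5 else "V") + "EHH"
    for pos, box in ((FAD_BOX1_POS, box1), (FAD_BOX2_POS, box2), (FAD_BOX3_POS, box3)):
        for offset, ch in enumerate(box):
            anchors[pos + offset] = ch
    return anchors


def elovl_annotation() -> ResidueAnnotation:
    return load_builtin_profiles().annotations["elovl_checklist"]


def _elovl_anchor_map(rng: np.random.Generator) -> Dict[int, str]:
    anchors: Dict[int, str] = {}
    box = "HV" + ("F" if rng.random() < 0.5 else "Y") + "HH"
    for offset, ch in enumerate(box):
        anchors[ELOVL_BOX_POS + offset] = ch
    for pos, res in elovl_annotation().positions:  # 1-based positions
        anchors[pos - 1] = res
    return anchors


def _elovl_tm_slots(length: int) -> Tuple[int, ...]:
    slots = ELOVL_TM_SLOTS
    if length >= ELOVL_TM_SLOT_TAIL + TM_LEN + 1:
        slots = slots + (ELOVL_TM_SLOT_TAIL,)
    return slots


def _member_protein(
    family: str, length: int, rng: np.random.Generator, noise_rate: float
) -> Tuple[str, Dict[int, str], Tuple[int, ...]]:
    """A family member protein: truncated template + anchors + noise."""
    if family == "Fad":
        template = _template(FAD_TEMPLATE_LEN, _FAD_TEMPLATE_SEED, FAD_TM_SLOTS)
        anchors = _fad_anchor_map(rng)
        slots = FAD_TM_SLOTS
    else:
        template = _template(
            ELOVL_TEMPLATE_LEN, _ELOVL_TEMPLATE_SEED,
            ELOVL_TM_SLOTS + (ELOVL_TM_SLOT_TAIL,),
        )
        anchors = _elovl_anchor_map(rng)
        slots = _elovl_tm_slots(length)
        if ELOVL_TM_SLOT_TAIL not in slots:
            # short member: neutralise the (possibly clipped) tail stretch
            filler_rng = np.random.default_rng(_ELOVL_TEMPLATE_SEED + 1)
            for k in range(ELOVL_TM_SLOT_TAIL, min(ELOVL_TM_SLOT_TAIL + TM_LEN, length)):
                template[k] = LINKER[filler_rng.integers(0, len(LINKER))]
    residues = template[:length]
    reserved = set(anchors)
    for pos in range(length):
        if pos in reserved:
            residues[pos] = anchors[pos]
            continue
        if rng.random() < noise_rate:
            pool = HYDROPHOBIC if residues[pos] in HYDROPHOBIC else LINKER
            choices = [c for c in pool if c != residues[pos]]
            residues[pos] = choices[rng.integers(0, len(choices))]
    residues[0] = "M"
    return "".join(residues), anchors, slots


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous-codon back-translation."""
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))]
        for aa in protein
    )


def _random_utr(length: int, rng: np.random.Generator, atg_free: bool) -> str:
    utr = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    if atg_free:
        while "ATG" in utr:
            utr = utr.replace("ATG", "ATC", 1)
    return utr


def _expected_status_from_mrna(
    mrna: str, utr5_len: int, family: str, len_window: Tuple[int, int],
    lesioned: bool,
) -> Tuple[str, int]:
    """Decide the planted record's expected screening status from its own
    coding arithmetic: full-length iff the ORF starting at the planted ATG
    reaches an in-frame stop inside the record with a protein length in
    the family window."""
    aa = translate(mrna[utr5_len:])
    stop_pos = utr5_len + 3 * len(aa)
    has_stop = stop_pos + 3 <= len(mrna) and mrna[stop_pos : stop_pos + 3] in STOP_CHOICES
    lo, hi = len_window
    if has_stop and lo <= len(aa) <= hi:
        return ("putative_pseudogene" if lesioned else "functional"), len(aa)
    return "partial", len(aa)


def _assemble(
    protein: str,
    family: str,
    params: SynthParams,
    rng: np.random.Generator,
    lesion: str,
    category: str,
    record_id: str,
    stop: bool = True,
) -> PlantedGene:
    cds = back_translate(protein, rng)
    utr5 = _random_utr(
        int(rng.integers(params.utr_len[0], params.utr_len[1] + 1)), rng, atg_free=True
    )
    utr3 = (
        _random_utr(
            int(rng.integers(params.utr_len[0], params.utr_len[1] + 1)), rng,
            atg_free=False,
        )
        if stop
        else ""
    )
    stop_codon = STOP_CHOICES[rng.integers(0, 3)] if stop else ""
    mrna = utr5 + cds + stop_codon + utr3
    window = params.fad_len if family == "Fad" else params.elovl_len
    expected, aa_len = _expected_status_from_mrna(
        mrna, len(utr5), family, window, lesioned=lesion not in ("", "truncate", "frameshift")
    )
    strand = "+" if rng.random() < 0.5 else "-"
    residues = mrna if strand == "+" else revcomp(mrna)
    # forward-strand ORF coordinates (start codon through stop when present)
    aa_full = translate(mrna[len(utr5):])
    stop_present = (
        len(utr5) + 3 * len(aa_full) + 3 <= len(mrna)
        and mrna[len(utr5) + 3 * len(aa_full):][:3] in STOP_CHOICES
    )
    span = 3 * len(aa_full) + (3 if stop_present else 0)
    if strand == "+":
        orf_start, orf_end = len(utr5), len(utr5) + span
    else:
        orf_start = len(mrna) - (len(utr5) + span)
        orf_end = len(mrna) - len(utr5)
    record = SeqRecord(id=record_id, residues=residues, alphabet="nucleotide")
    gene = PlantedGene(
        record=record,
        family=family,
        category=category,
        expected_status=expected,
        lesion=lesion,
        strand=strand,
        orf_start=orf_start,
        orf_end=orf_end,
        aa_len=aa_len,
        protein=aa_full,
        cds=mrna[len(utr5) : len(utr5) + 3 * len(aa_full)],
        mrna_forward=mrna,
        utr5_len=len(utr5),
        utr3_len=len(utr3),
    )
    return gene


def _note_motifs(gene: PlantedGene, anchors: Dict[int, str], slots) -> None:
    """Record which planted motifs survive the lesion, and the surviving
    membrane-stretch count."""
    if gene.family == "Fad":
        positions = {
            "haeme": FAD_HPGG_POS, "fad_box1": FAD_BOX1_POS,
            "fad_box2": FAD_BOX2_POS, "fad_box3": FAD_BOX3_POS,
        }
    else:
        positions = {"elovl_box": ELOVL_BOX_POS}
    if gene.lesion == "drop_hpgg":
        positions.pop("haeme", None)
    elif gene.lesion == "scramble_box":
        positions.pop("fad_box3", None)
        positions.pop("elovl_box", None)
    alive = len(gene.protein)
    gene.motif_positions = {
        name: pos for name, pos in positions.items() if pos + 5 <= alive
    }
    gene.tm_planted = sum(1 for s in slots if s + TM_LEN <= alive)


def make_fad_gene(
    rng: np.random.Generator,
    params: SynthParams,
    lesion: str = "",
    record_id: str = "fad",
) -> PlantedGene:
    """A desaturase transcript; ``lesion`` in {'', 'drop_hpgg',
    'scramble_box', 'truncate', 'frameshift'}."""
    length = int(rng.integers(params.fad_len[0], params.fad_len[1] + 1))
    protein, anchors, slots = _member_protein("Fad", length, rng, params.noise_rate)
    protein, category, stop = _apply_protein_lesion(
        protein, "Fad", lesion, params, rng
    )
    gene = _assemble(protein, "Fad", params, rng, lesion, category, record_id,
                     stop=stop)
    if lesion == "frameshift":
        gene = _apply_frameshift(gene, params, rng, record_id)
    _note_motifs(gene, anchors, slots)
    return gene


def make_elovl_gene(
    rng: np.random.Generator,
    params: SynthParams,
    lesion: str = "",
    record_id: str = "elovl",
) -> PlantedGene:
    """An elongase transcript; lesions as for :func:`make_fad_gene`
    (``drop_hpgg`` is meaningless here and maps to ``scramble_box``)."""
    if lesion == "drop_hpgg":
        lesion = "scramble_box"
    length = int(rng.integers(params.elovl_len[0], params.elovl_len[1] + 1))
    protein, anchors, slots = _member_protein("Elovl", length, rng, params.noise_rate)
    protein, category, stop = _apply_protein_lesion(
        protein, "Elovl", lesion, params, rng
    )
    gene = _assemble(protein, "Elovl", params, rng, lesion, category, record_id,
                     stop=stop)
    if lesion == "frameshift":
        gene = _apply_frameshift(gene, params, rng, record_id)
    _note_motifs(gene, anchors, slots)
    return gene


def _apply_protein_lesion(
    protein: str, family: str, lesion: str, params: SynthParams,
    rng: np.random.Generator,
) -> Tuple[str, str, bool]:
    """Apply a protein-level lesion; returns (protein, category, has_stop)."""
    residues = list(protein)
    if lesion == "":
        return protein, "functional", True
    if lesion == "drop_hpgg":
        for k in range(4):
            residues[FAD_HPGG_POS + k] = LINKER[rng.integers(0, len(LINKER))]
        return "".join(residues), "pseudogene", True
    if lesion == "scramble_box":
        pos = FAD_BOX3_POS if family == "Fad" else ELOVL_BOX_POS
        for k in range(5):
            residues[pos + k] = LINKER[rng.integers(0, len(LINKER))]
        return "".join(residues), "pseudogene", True
    if lesion == "truncate":
        cut = int(len(protein) * params.truncate_frac)
        return protein[:cut], "partial", False
    if lesion == "frameshift":
        return protein, "partial", True
    raise ValueError(f"unknown lesion {lesion!r}")


def _apply_frameshift(
    gene: PlantedGene, params: SynthParams, rng: np.random.Generator,
    record_id: str,
) -> PlantedGene:
    """Delete one nucleotide midway through the coding sequence and
    re-derive the truth entry from the shifted transcript."""
    mrna = gene.mrna_forward
    cut = gene.utr5_len + (3 * (gene.aa_len // 2))
    mrna = mrna[:cut] + mrna[cut + 1 :]
    window = params.fad_len if gene.family == "Fad" else params.elovl_len
    # a frameshifted ORF that happens to stay full-length would be a
    # structurally broken full-length sequence, i.e. a pseudogene
    expected, aa_len = _expected_status_from_mrna(
        mrna, gene.utr5_len, gene.family, window, lesioned=True
    )
    aa_full = translate(mrna[gene.utr5_len:])
    stop_present = (
        gene.utr5_len + 3 * len(aa_full) + 3 <= len(mrna)
        and mrna[gene.utr5_len + 3 * len(aa_full):][:3] in STOP_CHOICES
    )
    span = 3 * len(aa_full) + (3 if stop_present else 0)
    if gene.strand == "+":
        residues = mrna
        orf_start, orf_end = gene.utr5_len, gene.utr5_len + span
    else:
        residues = revcomp(mrna)
        orf_start = len(mrna) - (gene.utr5_len + span)
        orf_end = len(mrna) - gene.utr5_len
    record = SeqRecord(id=record_id, residues=residues, alphabet="nucleotide")
    gene.record = record
    gene.expected_status = expected
    gene.aa_len = aa_len
    gene.protein = aa_full
    gene.cds = mrna[gene.utr5_len : gene.utr5_len + 3 * len(aa_full)]
    gene.mrna_forward = mrna
    gene.orf_start = orf_start
    gene.orf_end = orf_end
    return gene


# ---------------------------------------------------------------------------
# Clone pairs
# ---------------------------------------------------------------------------

def synonymous_third_position_choices(codon: str) -> List[str]:
    """Alternative codons differing only at the third position with the
    same translation."""
    return [
        codon[:2] + b
        for b in "ACGT"
        if b != codon[2]
        and CODON_TO_AA.get(codon[:2] + b) == CODON_TO_AA.get(codon)
        and codon in CODON_TO_AA
    ]


def make_clone_pair(
    gene: PlantedGene,
    n_snps: int,
    synonymous_only: bool,
    rng: np.random.Generator,
) -> Tuple[SeqRecord, List[Tuple[int, str, str, bool]]]:
    """An allelic Sanger-style clone of a planted gene.

    Plants exactly ``n_snps`` substitutions inside the ORF (third-position
    degenerate changes when ``synonymous_only``), trims the UTRs randomly,
    and returns the clone with the planted-SNP ledger
    (ORF position, from, to, synonymous flag).
    """
    cds = list(gene.cds)
    n_codons = len(cds) // 3
    snps: List[Tuple[int, str, str, bool]] = []
    if synonymous_only:
        degenerate = [
            i for i in range(n_codons)
            if synonymous_third_position_choices("".join(cds[3 * i : 3 * i + 3]))
        ]
        if len(degenerate) < n_snps:
            raise ValueError(
                f"only {len(degenerate)} degenerate codons available for "
                f"{n_snps} synonymous SNPs"
            )
        picks = rng.choice(len(degenerate), size=n_snps, replace=False)
        for p in sorted(int(x) for x in picks):
            i = degenerate[p]
            codon = "".join(cds[3 * i : 3 * i + 3])
            alts = synonymous_third_position_choices(codon)
            new = alts[rng.integers(0, len(alts))]
            cds[3 * i + 2] = new[2]
            snps.append((3 * i + 2, codon[2], new[2], True))
    else:
        positions = sorted(
            int(x) for x in rng.choice(len(cds), size=n_snps, replace=False)
        )
        for pos in positions:
            i = pos // 3
            codon = "".join(cds[3 * i : 3 * i + 3])
            while True:
                b = "ACGT"[rng.integers(0, 4)]
                cand = codon[: pos % 3] + b + codon[pos % 3 + 1 :]
                if cand != codon and cand in CODON_TO_AA:
                    break
            syn = CODON_TO_AA[cand] == CODON_TO_AA[codon]
            cds[3 * i : 3 * i + 3] = list(cand)
            snps.append((pos, codon[pos % 3], b, syn))
    mrna = gene.mrna_forward
    utr5 = mrna[: gene.utr5_len]
    tail = mrna[gene.utr5_len + len(gene.cds) :]
    keep5 = int(rng.integers(0, gene.utr5_len + 1))
    keep3 = int(rng.integers(0, len(tail) + 1))
    clone_seq = utr5[gene.utr5_len - keep5 :] + "".join(cds) + tail[:keep3]
    clone = SeqRecord(
        id=f"{gene.record.id}_clone", residues=clone_seq, alphabet="nucleotide"
    )
    return clone, snps


# ---------------------------------------------------------------------------
# Alignment simulation on known trees
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: dendropy.Tree,
    m: DistanceModelParams,
    n_sites: int,
    rng: np.random.Generator,
    ncat: int = 1,
    use_rate_mixture: bool = False,
) -> Alignment:
    """Gap-free leaf alignment evolved along ``tree`` under the model.

    The root sequence is drawn from the stationary frequencies and evolved
    along each branch with the model's transition probabilities; when
    ``use_rate_mixture`` each site carries an invariant/discrete-gamma rate
    drawn from the model's mixture.
    """
    pi = stationary_freqs(m)
    bases = np.array(list("ACGT"))
    if use_rate_mixture:
        rates, weights = mixture_rates(m, ncat)
        site_rates = rates[rng.choice(len(rates), size=n_sites, p=weights)]
    else:
        site_rates = np.ones(n_sites)
    unique_rates = np.unique(site_rates)

    root_states = rng.choice(4, size=n_sites, p=pi)
    states: Dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    rows: List[Tuple[str, str]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_states = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = np.empty(n_sites, dtype=int)
        for rate in unique_rates:
            mask = site_rates == rate
            P = transition_matrix(m, t * rate)
            cum = np.cumsum(P, axis=1)
            u = rng.random(int(mask.sum()))
            rowsum = cum[parent_states[mask]]
            child[mask] = (u[:, None] > rowsum).sum(axis=1)
        states[id(node)] = child
        if node.is_leaf():
            rows.append((node.taxon.label, "".join(bases[child])))
    return Alignment(rows=rows)


# ---------------------------------------------------------------------------
# Whole transcriptomes
# ---------------------------------------------------------------------------

_PSEUDO_LESIONS = (("Fad", "drop_hpgg"), ("Fad", "scramble_box"),
                   ("Elovl", "scramble_box"))
_PARTIAL_LESIONS = (("Fad", "truncate"), ("Elovl", "truncate"),
                    ("Fad", "frameshift"))


def make_transcriptome(
    params: SynthParams, out_dir=None
) -> Tuple[List[SeqRecord], pd.DataFrame, List[PlantedGene]]:
    """All planted categories plus decoys, with the truth table.

    Deterministic under ``params.seed``.  When ``out_dir`` is given,
    writes ``contigs.fasta``, ``truth.tsv`` and ``params.json``.
    """
    rng = np.random.default_rng(params.seed)
    genes: List[PlantedGene] = []
    for i in range(params.n_fad):
        genes.append(make_fad_gene(rng, params, record_id=f"fad_{i:02d}"))
    for i in range(params.n_elovl):
        genes.append(make_elovl_gene(rng, params, record_id=f"elovl_{i:02d}"))
    for i in range(params.n_pseudo):
        family, lesion = _PSEUDO_LESIONS[i % len(_PSEUDO_LESIONS)]
        maker = make_fad_gene if family == "Fad" else make_elovl_gene
        genes.append(maker(rng, params, lesion=lesion, record_id=f"pseudo_{i:02d}"))
    for i in range(params.n_partial):
        family, lesion = _PARTIAL_LESIONS[i % len(_PARTIAL_LESIONS)]
        maker = make_fad_gene if family == "Fad" else make_elovl_gene
        genes.append(maker(rng, params, lesion=lesion, record_id=f"partial_{i:02d}"))

    records = [g.record for g in genes]
    planted_lens = [len(r) for r in records] or [800]
    lo, hi = min(planted_lens), max(planted_lens)
    for i in range(params.n_decoys):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        records.append(
            SeqRecord(id=f"decoy_{i:03d}", residues=seq, alphabet="nucleotide")
        )

    truth_rows = []
    for g in genes:
        truth_rows.append(
            {
                "record_id": g.record.id,
                "family": g.family,
                "category": g.category,
                "expected_status": g.expected_status,
                "lesion": g.lesion,
                "strand": g.strand,
                "orf_start": g.orf_start,
                "orf_end": g.orf_end,
                "aa_len": g.aa_len,
                "tm_planted": g.tm_planted,
                "motif_positions": json.dumps(g.motif_positions),
            }
        )
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "contigs.fasta")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        (out_dir / "params.json").write_text(json.dumps(asdict(params), indent=2))
    return records, truth, genes


def elovl_reference() -> SeqRecord:
    """The synthetic annotated elongase reference protein.

    A deterministic, noise-free member of the synthetic elongase family at
    the reference length, carrying the 17 checklist residues at exactly
    the annotated coordinates.  It stands in for the annotated Elovl5
    reference protein, which is not redistributed here.
    """
    rng = np.random.default_rng(_ELOVL_TEMPLATE_SEED)
    protein, _, _ = _member_protein("Elovl", ELOVL_REFERENCE_LEN, rng, 0.0)
    return SeqRecord(id="elovl5_reference_synthetic", residues=protein,
                     alphabet="protein")


def fad_reference() -> SeqRecord:
    """Synthetic noise-free desaturase family member used for
    similarity-based family assignment."""
    rng = np.random.default_rng(_FAD_TEMPLATE_SEED)
    protein, _, _ = _member_protein("Fad", 436, rng, 0.0)
    return SeqRecord(id="fad_reference_synthetic", residues=protein,
                     alphabet="protein")


def default_references():
    """Screening references built from the synthetic family templates."""
    from .screen import References

    return References(
        elovl_reference=elovl_reference(),
        elovl_annotation=elovl_annotation(),
        fad_reference=fad_reference(),
    )
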