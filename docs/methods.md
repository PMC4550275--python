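# Methods

This note documents the models, filters, numerical choices and known
limitations of the `lcpufa` pipeline, and states what the synthetic-data
generator does and does not emulate.

## Sequence handling

Sequences are upper-cased on construction and validated against a
nucleotide ({A,C,G,T,N}) or protein (20 amino acids + X, *) alphabet.
Translation uses the standard genetic code only — the target taxa are
molluscs and the screened sequences are nuclear transcripts — stops
terminate translation and never appear in output proteins, and any codon
containing N translates to X. FASTA is written wrapped at 70 columns;
read∘write is a bijection on (id, residues).

Contig merging accepts only exact terminal overlaps (default minimum
15 nt, the overlap at which the split desaturase transcript that motivated
the feature was joined). Fuzzy merging is deliberately not offered: allowing
mismatches in the overlap risks chimeric transcripts, and a screen built on
structural motifs is particularly sensitive to chimeras.

ORF extraction reports ATG-initiated frames on both strands; ORFs sharing a
stop codon keep only the longest (first ATG after the previous stop), which
matches common ORF-finder behaviour and reflects the one-protein-per-
transcript assumption of the screen. "Full-length" means: stop codon inside
the contig *and* protein length inside the family window. The windows
default to 380–480 aa for desaturases and 230–340 aa for elongases, padding
the observed family ranges (428–445 aa and 261–324 aa across surveyed
molluscs) enough to admit unusual members without admitting fragments.

## Motif grammar

Patterns are position lists: a literal residue, `X` (any), or a binary
alternative `A/B`. Alternatives are capped at two residues because every
consensus the screen uses is binary (HDF/YGH, HY/FQ/LHH, QI/VEHH, HVF/YHH);
longer groups are rejected as probable typos. Multi-letter runs in residue
annotations ("131DT", "151HH") denote *consecutive* positions — the only
reading under which the reference Elovl5 checklist totals its stated
17 residues. Scans report every window, including overlapping ones;
downstream filters impose order constraints.

One structural consequence of the grammar: any HXXHH window (H at
positions 1, 4, 5) also satisfies HXXXH (H at 1 and 5). A desaturase that
loses its first histidine box therefore still has HXXXH *presence*
satisfied by the second box; the loss is caught by the ordering filter,
which then finds no HXXXH hit strictly upstream of an HXXHH hit. The
ordering filter skips motifs that are absent, so a single motif knockout
flips exactly one filter (its own presence filter, or the order filter in
the HXXXH case).

## Transmembrane-segment counting

Membrane topology enters the screen only as a segment count (3–4 for
desaturases, 5–7 for elongases), so a deterministic hydropathy scanner is
used: a centred Kyte–Doolittle moving average (window 19 residues, the
canonical helix-spanning width), runs of windows with mean ≥ 1.6 extended
to window extents, merged when separated by < 5 residues, kept when
≥ 19 residues. The 1.6 threshold is the classical cut-off for candidate
transmembrane helices on a 19-residue window. The scanner predicts no
in/out topology and no signal peptides — none of that is consumed
downstream. Counts on real proteins will not always equal an HMM
predictor's; the family windows are wide enough that the distinction
rarely matters for classification, but this is the main caveat when
running the screen on real data.

## Alignment

Pairwise global alignment is Needleman–Wunsch with affine gaps under the
convention that a gap of length k costs `gap_open + k·gap_extend`
(defaults −10 and −1), BLOSUM62 for proteins, +5/−4 for nucleotides.
The clone-validation preset uses the nucleotide scheme with free end gaps,
so clone UTR overhang is trimmed instead of penalised; this preset is this
package's interpretation of the "93% similarity" aligner preset named in
transcript-validation workflows — the preset's exact parameters are not
published, so the free-end-gap +5/−4 scheme is documented here rather than
asserted equivalent. Optimal scores are verified in the test suite against
exhaustive alignment enumeration on short inputs.

Multiple alignment is progressive: pairwise alignment identities give
distances, neighbor joining gives the guide tree, profiles are merged in
guide-tree order by profile–profile Needleman–Wunsch (expected
column-vs-column substitution score over residue frequencies), followed by
one leave-one-out refinement pass that re-aligns each sequence to the
remaining profile and keeps the result if the sum-of-pairs score improves.
This replaces meta-aligners deliberately: the package's analysis surface is
synthetic homolog families at 85–90% identity, where progressive alignment
is ample, and a dependency-free aligner keeps the pipeline deterministic.
Conserved-column counts on alignments of *external* reference accessions
(which involve manual curation) are not reproduced and are treated as
directional properties only: adding a divergent row never increases the
conserved count; removing the most divergent row never decreases it.

## Distances, trees, likelihood

Observed transition (P) and transversion (Q) proportions skip columns with
a gap or N in either row. K2P: d = −½·ln((1−2P−Q)·√(1−2Q)). Tamura
3-parameter: h = 2θ(1−θ) with θ the mean G+C of the pair (or supplied),
d = −h·ln(1−P/h−Q) − ½(1−h)·ln(1−2Q); θ = ½ reduces exactly to K2P.
Saturated pairs yield NaN rather than an exception; neighbor joining
refuses matrices containing them (conservative: the caller drops taxa
rather than silently imputing). NJ uses the standard Q-criterion with a
deterministic lexicographic tie-break and clamps negative branch lengths
to zero; it is exact on additive matrices, which the tests exploit.

The likelihood engine is nucleotide-only: K2P (uniform frequencies,
closed-form P(t)) or a Tamura-style matrix (G+C-parameterised frequencies,
matrix exponential), with a rate mixture of an invariant-sites class
(probability `p_inv`, rate 0) and `ncat` equal-probability discrete-gamma
categories (per-category mean rates, normalised so the overall mean rate
is 1; variable-class rates scaled by 1/(1−p_inv)). Gamma shape and `p_inv`
are free configuration — no published values exist for the motivating
analyses, so none are baked in. Site patterns are compressed before
pruning. Pruning equals brute-force state enumeration on small trees
(tested) and is invariant under re-rooting (reversible models).

Topology search is nearest-neighbour-interchange hill climbing from the NJ
tree, optionally re-optimising branch lengths (bounded scalar minimisation
per edge) when scoring each neighbour; the accepted-move likelihood trace
is non-decreasing by construction. This replaces a full ML search on
purpose: at the problem sizes this package targets (tens of taxa,
kilobase alignments) NJ + NNI with strong signal recovers the generating
topology, and the scientific conclusions consumed downstream are clade
memberships, not likelihood values.

Bootstrap support resamples alignment columns with replacement, rebuilds
each replicate with the supplied builder (NJ on K2P distances by default),
and annotates each point-estimate bipartition with its replicate
percentage. Replicates whose distance matrices saturate are skipped and
count against support (conservative). Reports suppress values below 75%,
the conventional reporting floor; the values themselves are retained on
the tree object.

Clade assignment roots at the designated outgroup leaf when one is given
(as a sea-anemone sequence served in the motivating analyses), else at the
midpoint, then walks from the candidate leaf rootward to the smallest
clade containing a labelled reference. The label is returned only if all
labelled references in that clade agree and the clade's support meets the
threshold; nodes without recorded support pass only a zero threshold.

## Clone validation

Percent identity uses the ORF alignment span as denominator — matching the
convention in which "five SNPs across the 1293-bp ORF" corresponds to
99.6% — and rounds half-up to one decimal. Mismatches are classified by
translating the assembled codon and the codon with the clone's aligned
residues substituted in: synonymous iff the amino acid is unchanged.
Internal indels are flagged (`n_indel_cols`) and identity falls back to
aligned columns only. A 293-codon ORF is 879 nt with the stop excluded;
including the stop (882 nt) changes nothing at one-decimal precision.

## The synthetic-data generator

The generator is the package's stand-in for real assembled transcriptomes,
and its defaults are the study conditions the tests run under: 5 desaturase
and 5 elongase genes, 3 pseudogenes, 3 partials, 100 random decoy contigs,
family length ranges 428–445 aa (Fad) and 261–324 aa (Elovl), UTRs of
30–150 nt, and ~8% per-residue substitution noise between family members.

Each family derives from a fixed template (seeded independently of the
user's master seed, so every run shares the same two "gene families"):
hydrophilic background, hydrophobic 21-residue membrane stretches at fixed
slots, and anchored motifs — HPGG at position 30 and the three boxes in
canonical order for desaturases; the diagnostic box at 148 and the 17
checklist residues at their annotated coordinates for elongases. Members
are template prefixes of the drawn length with class-preserving noise
(hydrophobic↔hydrophobic, hydrophilic↔hydrophilic) outside anchored
positions, giving realistic within-family identity while guaranteeing the
planted structure. Hydrophobic stretches draw from {L,I,V,F} and the
10-residue guard bands flanking them from strongly hydrophilic residues
only, so hydropathy windows cannot bridge two stretches; background
residues exclude H and P, so no spurious histidine boxes or HPGG can
arise by chance. Back-translation picks synonymous codons uniformly (no
codon-usage table — the simplest defensible choice; a usage table could be
slotted into `back_translate`). 5' UTRs are generated ATG-free so the
planted start codon is the ORF start; about half of all transcripts are
emitted reverse-complemented to exercise minus-strand handling.

Lesions define the non-functional categories: `drop_hpgg` and
`scramble_box` leave the protein full-length but erase one motif
(pseudogenes); `truncate` cuts the protein at 60% with no stop codon and
`frameshift` deletes one nucleotide mid-CDS (partials). Frameshift partials
are planted in desaturases, whose diagnostic motifs precede the shift
point; a frameshifted elongase would lose its only box and become
indistinguishable from a decoy, which is a property of the screen, not a
defect of the generator. Expected statuses in the truth table are derived
from the generated sequence's own coding arithmetic (where the planted ATG
reaches a stop, and whether the length lands in the family window), so
truth is exact even for the rare frameshift whose random tail runs long.

Decoy contigs are i.i.d. uniform nucleotides with lengths drawn from the
planted-record range, so length alone cannot separate decoys from genes.

What the generator does **not** emulate: sequencing error, coverage
variation, assembly artefacts beyond truncation/frameshift, alternative
splicing, codon-usage bias, and realistic background homology (decoys are
random, not low-similarity paralogs). Passing the recovery tests therefore
demonstrates the pipeline's internal consistency — filters detect exactly
what is planted, at the planted coordinates — not its error rates on real
assemblies, where motif degeneracy and hydropathy-count disagreements with
HMM predictors will matter.

## Family assignment for non-functional candidates

The structure checks decide the family of functional calls (in the
pathological case where both family checks pass at full length, the family
with more passing filters wins and a tie is rejected as ambiguous).
Pseudogenes and partials cannot be assigned that way — their filters fail
by definition — so the screen assigns them by fractional identity to
built-in family reference proteins (global alignment, matches over
columns; threshold 0.4), falling back on motif content when identity is
below threshold. This mirrors the homology-search annotation step that
precedes structural screening in practice. The shipped references are
synthetic, noise-free members of the generator's families (their ids say
so); real screens should substitute curated references via
`References(...)` or `lcpufa screen --refs`.

## Numerical and reproducibility choices

Alignment traceback, NJ joins and NNI move selection are deterministic
(first-optimal traceback, lexicographic tie-breaks). Every stochastic
operation takes an explicit seed or `numpy` Generator; the CLI refuses to
run without a seed and records seeds, thresholds and a config hash in a
provenance block. Identical inputs and configuration produce byte-identical
reports, which the tests assert.

Test and demonstration problem sizes — 116-contig transcriptomes, 6-taxon
trees, 2,000-site alignments, 200 bootstrap replicates, 10,000 sites for
estimator-recovery checks — were chosen as the smallest sizes at which the
statistical assertions have comfortable margins (e.g. all true bipartitions
at ≥ 75% support; K2P estimates within 3 standard errors of truth).

## Known limitations

- Protein-model likelihood (LG) is not implemented; protein trees are
  supported through NJ on alignment-derived distances only.
- The hydropathy scanner is a stand-in for HMM topology prediction; output
  reports note this substitution.
- Exact reproduction of published alignments/trees built from external
  database accessions and manual curation is out of scope; those results
  are covered by directional invariants instead.
- BLAST-style database pre-screening is replaced by exhaustive screening of
  all contigs; at transcriptome scale (10⁵ contigs) the per-contig
  reference alignments dominate runtime, and a k-mer pre-filter would be
  the first optimisation to add.
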