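"""Degenerate protein motifs and conserved-residue annotations.

Desaturases carry a haeme-binding HPGG tetrapeptide inside their N-terminal
cytochrome b5-like domain and three histidine boxes (HXXXH, HXXHH, QXXHH)
that coordinate the catalytic iron; elongases carry a single diagnostic
HXXHH box plus a checklist of 17 conserved residues annotated on a
reference Elovl5 protein.  This module provides the small pattern grammar
those filters are written in, an exhaustive scanner, and the parser for the
residue-checklist annotation strings.

Pattern grammar: each position is a literal residue, ``X`` (any residue),
or a two-way alternative written ``A/B`` (either residue).  ``HDF/YGH``
therefore has five positions with F-or-Y at the third.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


class MotifGrammarError(ValueError):
    """Malformed motif pattern specification."""


class AnnotationError(ValueError):
    """Malformed conserved-residue annotation string."""


@dataclass(frozen=True)
class MotifPattern:
    name: str
    spec: str
    positions: Tuple[frozenset, ...]  # allowed residues per position; empty = any

    @property
    def length(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    start: int  # 0-based position in the protein
    matched: str


@dataclass(frozen=True)
class ResidueAnnotation:
    """Ordered (1-based reference position, expected residue) checklist."""

    source_ref_id: str
    positions: Tuple[Tuple[int, str], ...]

    def __len__(self) -> int:
        return len(self.positions)

    def to_text(self) -> str:
        """Re-serialise, collapsing runs of consecutive positions."""
        tokens: List[str] = []
        i = 0
        pos = self.positions
        while i < len(pos):
            j = i
            while (
                j + 1 < len(pos) and pos[j + 1][0] == pos[j][0] + 1
            ):
                j += 1
            tokens.append(f"{pos[i][0]}{''.join(r for _, r in pos[i:j + 1])}")
            i = j + 1
        return ", ".join(tokens)


def compile_pattern(name: str, spec: str) -> MotifPattern:
    """Compile a pattern string into a :class:`MotifPattern`.

    Alternatives groups are limited to two residues; anything longer is
    rejected to catch typos.
    """
    if not spec:
        raise MotifGrammarError(f"{name}: empty pattern")
    positions: List[frozenset] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "/":
            raise MotifGrammarError(f"{name}: '/' at position {i} has no left residue")
        if ch == "X":
            positions.append(frozenset())
            i += 1
            continue
        if ch not in PROTEIN_LETTERS:
            raise MotifGrammarError(f"{name}: illegal character {ch!r} at position {i}")
        if i + 1 < len(spec) and spec[i + 1] == "/":
            if i + 2 >= len(spec):
                raise MotifGrammarError(f"{name}: dangling '/' at position {i + 1}")
            alt = spec[i + 2]
            if alt == "X" or alt not in PROTEIN_LETTERS:
                raise MotifGrammarError(
                    f"{name}: illegal alternative {alt!r} at position {i + 2}"
                )
            if i + 3 < len(spec) and spec[i + 3] == "/":
                raise MotifGrammarError(
                    f"{name}: alternatives groups are limited to 2 residues "
                    f"(position {i + 3})"
                )
            positions.append(frozenset({ch, alt}))
            i += 3
            continue
        positions.append(frozenset({ch}))
        i += 1
    return MotifPattern(name=name, spec=spec, positions=tuple(positions))


def matches_at(protein: str, pattern: MotifPattern, start: int) -> bool:
    """Does the window at ``start`` satisfy the pattern?"""
    if start < 0 or start + pattern.length > len(protein):
        return False
    for offset, allowed in enumerate(pattern.positions):
        if allowed and protein[start + offset] not in allowed:
            return False
    return True


def scan(protein: str, pattern: MotifPattern) -> List[MotifHit]:
    """All (possibly overlapping) windows satisfying ``pattern``, in
    ascending start order."""
    hits = []
    for start in range(len(protein) - pattern.length + 1):
        if matches_at(protein, pattern, start):
            hits.append(
                MotifHit(
                    pattern_name=pattern.name,
                    start=start,
                    matched=protein[start : start + pattern.length],
                )
            )
    return hits


def parse_residue_annotation(
    text: str, source_ref_id: str = "", run_rule: str = "consecutive"
) -> ResidueAnnotation:
    """Parse a checklist like ``"125K, 128E, 131DT"``.

    A token ``pRS...`` with k residue letters expands to k *consecutive*
    positions p, p+1, ..., p+k-1 — the only reading under which the
    reference Elovl5 checklist totals its stated 17 residues.
    """
    if run_rule != "consecutive":
        raise ValueError(f"unknown run_rule {run_rule!r}")
    positions: List[Tuple[int, str]] = []
    for raw in text.split(","):
        token = raw.strip()
        if not token:
            continue
        i = 0
        while i < len(token) and token[i].isdigit():
            i += 1
        if i == 0 or i == len(token):
            raise AnnotationError(f"bad token {token!r}: expected <int><residues>")
        pos = int(token[:i])
        for k, res in enumerate(token[i:]):
            if not ("A" <= res <= "Z"):
                raise AnnotationError(f"bad residue {res!r} in token {token!r}")
            positions.append((pos + k, res))
    for (p1, _), (p2, _) in zip(positions, positions[1:]):
        if p2 <= p1:
            raise AnnotationError(
                f"positions not strictly increasing after expansion: {p1} -> {p2}"
            )
    return ResidueAnnotation(source_ref_id=source_ref_id, positions=tuple(positions))
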