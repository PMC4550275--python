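"""Built-in motif profiles: the patterns and annotations the screen uses.

The shipped plain-text profile file carries the haeme-binding motif, the
three desaturase histidine boxes and their consensus variants, the
diagnostic elongase box, the 17-residue Elovl5 checklist, and the conserved
elongase alignment region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Tuple

from .motif import MotifPattern, ResidueAnnotation, compile_pattern, parse_residue_annotation


@dataclass
class ProfileSet:
    patterns: Dict[str, MotifPattern] = field(default_factory=dict)
    annotations: Dict[str, ResidueAnnotation] = field(default_factory=dict)
    regions: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def region_span(self, name: str) -> int:
        """Residue count of a 1-based inclusive region."""
        start, end = self.regions[name]
        return end - start + 1


def parse_profiles(text: str) -> ProfileSet:
    out = ProfileSet()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, rest = line.split(None, 1)
        if kind == "pattern":
            name, spec = rest.split(None, 1)
            out.patterns[name] = compile_pattern(name, spec.strip())
        elif kind == "annotation":
            name, ref_id, checklist = rest.split(None, 2)
            out.annotations[name] = parse_residue_annotation(
                checklist, source_ref_id=ref_id
            )
        elif kind == "region":
            name, start, end = rest.split()
            out.regions[name] = (int(start), int(end))
        else:
            raise ValueError(f"unknown profile line kind {kind!r}")
    return out


def load_builtin_profiles() -> ProfileSet:
    text = (
        resources.files("lcpufa").joinpath("data/profiles.txt").read_text()
    )
    return parse_profiles(text)


#: Names of the three desaturase histidine-box patterns, in their required
#: N-to-C order along the protein.
FAD_HISTIDINE_BOXES = ("fad_box1", "fad_box2", "fad_box3")
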