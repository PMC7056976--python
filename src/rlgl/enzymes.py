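"""Bundled restriction-enzyme table.

Loaded once from ``data/enzymes.yaml`` (a small versioned asset) so that
both the cloning simulator and the motif scrubber agree on recognition
sequences and cut chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .seqcore import DegeneratePattern, SequenceError

__all__ = ["RestrictionEnzyme", "ENZYMES", "get_enzyme", "ENZYME_TABLE_VERSION"]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition site plus top/bottom-strand cut offsets.

    Offsets are measured from the recognition start on the top strand;
    ``cut_top < cut_bottom`` leaves a 5' overhang, ``>`` a 3' overhang,
    ``==`` a blunt end.
    """

    name: str
    recognition: DegeneratePattern
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        m = len(self.recognition)
        for off in (self.cut_top, self.cut_bottom):
            if not 0 <= off <= m:
                raise SequenceError(
                    f"{self.name}: cut offset {off} outside recognition length {m}"
                )

    @property
    def overhang_kind(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "5p"
        if self.cut_top > self.cut_bottom:
            return "3p"
        return "blunt"

    @property
    def overhang_len(self) -> int:
        return abs(self.cut_top - self.cut_bottom)

    @property
    def site(self) -> str:
        return self.recognition.code


def _load_table() -> tuple[int, dict[str, RestrictionEnzyme]]:
    text = resources.files("rlgl.data").joinpath("enzymes.yaml").read_text()
    raw = yaml.safe_load(text)
    table = {}
    for name, spec in raw["enzymes"].items():
        table[name] = RestrictionEnzyme(
            name=name,
            recognition=DegeneratePattern(spec["site"], label=name),
            cut_top=int(spec["cut_top"]),
            cut_bottom=int(spec["cut_bottom"]),
        )
    return int(raw["version"]), table


ENZYME_TABLE_VERSION, ENZYMES = _load_table()


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return ENZYMES[name]
    except KeyError:
        raise SequenceError(
            f"unknown enzyme {name!r}; bundled: {', '.join(sorted(ENZYMES))}"
        ) from None
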