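"""Comparison designs: which samples are compared, and how.

The study makes three comparisons: donor vs paired recipient without GvHD
(D vs Rs, paired), donor vs paired recipient with GvHD (D vs Ra, paired),
and recipient-without vs recipient-with GvHD (Rs vs Ra, unpaired).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .tables import SampleInfo

__all__ = ["PairedDesign", "UnpairedDesign", "build_design", "COMPARISONS"]

COMPARISONS = ("D_vs_Rs", "D_vs_Ra", "Rs_vs_Ra")


@dataclass(frozen=True)
class PairedDesign:
    """Paired two-group design. ``pairs[i] = (sample in group 1, sample in
    group 2)``; the test statistic acts on within-pair differences
    (group 1 minus group 2)."""

    pairs: tuple[tuple[str, str], ...]
    labels: tuple[str, str] = ("g1", "g2")

    @property
    def group1(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def group2(self) -> list[str]:
        return [p[1] for p in self.pairs]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    kind = "paired"


@dataclass(frozen=True)
class UnpairedDesign:
    """Independent two-group design."""

    group1: tuple[str, ...]
    group2: tuple[str, ...]
    labels: tuple[str, str] = ("g1", "g2")

    kind = "unpaired"


def build_design(info: Sequence[SampleInfo], comparison: str):
    """Construct the design for one of the three study comparisons.

    ``D_vs_Rs`` / ``D_vs_Ra`` pair each donor with their recipient via
    ``pair_id`` (group 1 = recipient, group 2 = donor, so positive effects
    read as increases in recipients).  ``Rs_vs_Ra`` is unpaired with
    group 1 = Ra (cases) and group 2 = Rs (controls).
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; pick from {COMPARISONS}")
    by_id = {s.sample_id: s for s in info}
    if len(by_id) != len(list(info)):
        raise ValueError("duplicate sample ids in metadata")

    if comparison == "Rs_vs_Ra":
        ra = tuple(s.sample_id for s in info if s.group == "Ra")
        rs = tuple(s.sample_id for s in info if s.group == "Rs")
        if not ra or not rs:
            raise ValueError("Rs_vs_Ra needs samples in both Ra and Rs")
        return UnpairedDesign(group1=ra, group2=rs, labels=("Ra", "Rs"))

    recip_group = "Rs" if comparison == "D_vs_Rs" else "Ra"
    donors = {s.pair_id: s.sample_id for s in info
              if s.subject_role == "donor" and s.pair_id}
    pairs = []
    for s in info:
        if s.group == recip_group and s.pair_id and s.pair_id in donors:
            pairs.append((s.sample_id, donors[s.pair_id]))
    if not pairs:
        raise ValueError(f"no donor/{recip_group} pairs found for {comparison}")
    return PairedDesign(pairs=tuple(sorted(pairs)), labels=(recip_group, "D"))
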