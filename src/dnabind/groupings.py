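"""Physicochemical groupings of the amino-acid alphabet.

Each property partitions the 20 standard amino acids into three
disjoint groups (for example hydrophobicity: polar / neutral /
hydrophobic). The content, distribution and dipeptide descriptors are
computed per group against one of these partitions.

The published hydrophobicity row contains a typographical slip: its
second group is printed with a duplicated T and the row covers only 19
distinct letters, leaving Y unassigned. Completing the partition forces
Y into the second group, so the shipped table uses ``GASTPHY``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from os import PathLike
from typing import IO, Union

import numpy as np
import yaml

from dnabind.sequence_io import STANDARD_AA

logger = logging.getLogger("dnabind")

_ALPHABET_SET = frozenset(STANDARD_AA)
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass(frozen=True)
class PropertyGrouping:
    """A named three-way partition of the 20 standard amino acids."""

    name: str
    groups: tuple[frozenset, frozenset, frozenset]

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) != 3:
            raise ValueError(f"{self.name}: need exactly three groups")
        union = groups[0] | groups[1] | groups[2]
        total = sum(len(g) for g in groups)
        if union != _ALPHABET_SET or total != 20:
            raise ValueError(
                f"{self.name}: groups must be disjoint and cover the 20 "
                f"standard amino acids exactly (got union of {len(union)} "
                f"letters, {total} assignments)"
            )

    @cached_property
    def membership(self) -> np.ndarray:
        """Lookup table: alphabet index (A..Y) -> group index 0, 1 or 2."""
        table = np.empty(20, dtype=np.int8)
        for gi, group in enumerate(self.groups):
            for aa in group:
                table[AA_INDEX[aa]] = gi
        return table

    def group_of(self, aa: str) -> int:
        """1-based group index of a residue letter."""
        return int(self.membership[AA_INDEX[aa]]) + 1


# Property rows in published order. Hydrophobicity's 2nd group is the
# corrected GASTPHY (see module docstring).
_STANDARD_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("hydrophobicity", "RKEDQN", "GASTPHY", "CVLIMFW"),
    ("normalized_vdw_volume", "GASCTPD", "NVEQIL", "MHKFRYW"),
    ("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    ("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    ("charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
    ("surface_tension", "GQDNAHR", "KTSEC", "ILMFPWYV"),
    ("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
    ("solvent_accessibility", "ALFCGIVW", "RKQEND", "MPSTHY"),
)


def standard_groupings() -> list[PropertyGrouping]:
    """The eight standard physicochemical groupings, in table order.

    Order: hydrophobicity, normalized van der Waals volume, polarity,
    polarizability, charge, surface tension, secondary structure,
    solvent accessibility.
    """
    return [
        PropertyGrouping(name, (frozenset(g1), frozenset(g2), frozenset(g3)))
        for name, g1, g2, g3 in _STANDARD_ROWS
    ]


def load_groupings(source: Union[str, PathLike, IO[str]]) -> list[PropertyGrouping]:
    """Load groupings from a YAML file mapping property name to three letter-strings.

    Example::

        hydrophobicity: [RKEDQN, GASTPHY, CVLIMFW]

    Each row must partition the 20-letter alphabet; order of properties
    in the file is preserved and defines the feature-block order.
    """
    if isinstance(source, (str, PathLike)):
        with open(source) as handle:
            spec = yaml.safe_load(handle)
    else:
        spec = yaml.safe_load(source)
    if not isinstance(spec, dict) or not spec:
        raise ValueError("groupings file must map property names to three groups")
    groupings = []
    for name, rows in spec.items():
        if not isinstance(rows, (list, tuple)) or len(rows) != 3:
            raise ValueError(f"{name}: expected a list of three letter-strings")
        groupings.append(
            PropertyGrouping(str(name), tuple(frozenset(str(r).upper()) for r in rows))
        )
    return groupings
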