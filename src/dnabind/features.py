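"""The 188-dimensional sequence feature vector.

Layout: 20 amino-acid composition values (alphabetical A..Y), followed
by one 21-value block per physicochemical grouping in table order. Each
property block is: 3 content values, 15 distribution values (5 position
quantiles per group), 3 cross-group dipeptide values.

All values are normalized by the sequence length L and lie in [0, 1].

Definitions, for a sequence of length L and a grouping with groups
1, 2, 3:

* composition: per-letter occurrence count / L.
* content:     per-group residue count / L (the triple sums to 1).
* distribution: for group i with n_i occurrences at 1-based positions
  p_1 < ... < p_{n_i}, the positions of the first, 25%, 50%, 75% and
  100%-th occurrence, each divided by L. The quantile index is
  k = ceil(q * n_i) (1-based), which degenerates correctly to the single
  position when n_i = 1. A group with no occurrences contributes five
  zeros.
* dipeptide composition: among the L-1 adjacent residue pairs, the
  counts of pairs spanning groups (1,2), (1,3) and (2,3) in either
  order, each divided by L by default (``normalizer="L-1"`` switches
  the denominator to L-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from dnabind.groupings import AA_INDEX, PropertyGrouping, standard_groupings
from dnabind.sequence_io import STANDARD_AA, ProteinRecord

_QUANTILES = (0.25, 0.50, 0.75)
_PAIR_LABELS = ("g1g2", "g1g3", "g2g3")
_DIST_LABELS = ("first", "q25", "q50", "q75", "last")


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter(
        (AA_INDEX[c] for c in sequence), dtype=np.int8, count=len(sequence)
    )


@dataclass(frozen=True)
class FeatureVector:
    """An ordered feature vector with names aligned to values."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.names):
            raise ValueError("values and names must align one-to-one")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, key):
        return self.values[key]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def composition(record: ProteinRecord) -> np.ndarray:
    """Amino-acid composition: occurrence count / L, alphabetical A..Y order."""
    counts = np.bincount(_encode(record.sequence), minlength=20)
    return counts / record.length


def content(record: ProteinRecord, grouping: PropertyGrouping) -> np.ndarray:
    """Per-group residue fraction (3 values summing to 1)."""
    gidx = grouping.membership[_encode(record.sequence)]
    counts = np.bincount(gidx, minlength=3)
    return counts / record.length


def distribution(record: ProteinRecord, grouping: PropertyGrouping) -> np.ndarray:
    """Normalized positions of the first/25/50/75/100%-th residue per group.

    15 values: group 1's five, then group 2's, then group 3's. Within a
    group the values are non-decreasing; an absent group yields zeros.
    """
    gidx = grouping.membership[_encode(record.sequence)]
    L = record.length
    out = np.zeros(15)
    for gi in range(3):
        positions = np.flatnonzero(gidx == gi) + 1  # 1-based
        n = len(positions)
        if n == 0:
            continue
        picks = [positions[0]]
        picks += [positions[ceil(q * n) - 1] for q in _QUANTILES]
        picks.append(positions[-1])
        out[gi * 5 : gi * 5 + 5] = np.asarray(picks) / L
    return out


def dipeptide_composition(
    record: ProteinRecord, grouping: PropertyGrouping, normalizer: str = "L"
) -> np.ndarray:
    """Cross-group adjacent-pair fractions for pairs (1,2), (1,3), (2,3).

    A pair counts regardless of residue order. The default denominator
    is L; ``normalizer="L-1"`` divides by the number of dipeptides L-1
    instead (undefined at L = 1, where the result is all zeros either
    way).
    """
    if normalizer not in ("L", "L-1"):
        raise ValueError(f"normalizer must be 'L' or 'L-1', got {normalizer!r}")
    gidx = grouping.membership[_encode(record.sequence)]
    L = record.length
    if L == 1:
        return np.zeros(3)
    a, b = gidx[:-1], gidx[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    counts = np.array(
        [
            int(np.sum((lo == 0) & (hi == 1))),
            int(np.sum((lo == 0) & (hi == 2))),
            int(np.sum((lo == 1) & (hi == 2))),
        ],
        dtype=float,
    )
    denom = L if normalizer == "L" else L - 1
    return counts / denom


def feature_names(
    groupings: Optional[Sequence[PropertyGrouping]] = None,
) -> tuple[str, ...]:
    """Column names aligned with :func:`extract_features` output."""
    if groupings is None:
        groupings = standard_groupings()
    names = [f"comp_{aa}" for aa in STANDARD_AA]
    for grouping in groupings:
        p = grouping.name
        names += [f"{p}_content_g{i}" for i in (1, 2, 3)]
        names += [
            f"{p}_dist_g{i}_{lab}" for i in (1, 2, 3) for lab in _DIST_LABELS
        ]
        names += [f"{p}_dipep_{lab}" for lab in _PAIR_LABELS]
    return tuple(names)


def extract_features(
    record: ProteinRecord,
    groupings: Optional[Sequence[PropertyGrouping]] = None,
    normalizer: str = "L",
) -> FeatureVector:
    """Full feature vector for one sequence.

    With the eight standard groupings the result has 20 + 8*21 = 188
    values; a caller-supplied grouping list yields 20 + 21*len(groupings).
    """
    if groupings is None:
        groupings = standard_groupings()
    blocks = [composition(record)]
    for grouping in groupings:
        blocks.append(content(record, grouping))
        blocks.append(distribution(record, grouping))
        blocks.append(dipeptide_composition(record, grouping, normalizer=normalizer))
    return FeatureVector(np.concatenate(blocks), feature_names(groupings))


def feature_matrix(
    records: Iterable[ProteinRecord],
    groupings: Optional[Sequence[PropertyGrouping]] = None,
    normalizer: str = "L",
) -> np.ndarray:
    """Stack feature vectors for many records into an (m, d) matrix."""
    if groupings is None:
        groupings = standard_groupings()
    rows = [extract_features(r, groupings, normalizer=normalizer).values for r in records]
    if not rows:
        return np.empty((0, len(feature_names(groupings))))
    return np.vstack(rows)


def features_to_table(
    records: Sequence[ProteinRecord],
    labels: Optional[Sequence[int]] = None,
    groupings: Optional[Sequence[PropertyGrouping]] = None,
    normalizer: str = "L",
) -> pd.DataFrame:
    """One row per record: id, optional label, named feature columns.

    Write with ``df.to_csv(path, sep="\\t", index=False)`` for the
    tab-separated interchange format.
    """
    if groupings is None:
        groupings = standard_groupings()
    if labels is not None:
        labels = list(labels)
        if len(labels) != len(records):
            raise ValueError(
                f"{len(labels)} labels for {len(records)} records"
            )
        if any(l not in (1, -1) for l in labels):
            raise ValueError("labels must take values in {1, -1}")
    matrix = feature_matrix(records, groupings, normalizer=normalizer)
    table = pd.DataFrame(matrix, columns=list(feature_names(groupings)))
    if labels is not None:
        table.insert(0, "label", labels)
    table.insert(0, "id", [r.id for r in records])
    return table
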