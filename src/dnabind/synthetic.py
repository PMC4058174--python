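"""Synthetic labelled protein sequences for end-to-end testing.

The generator emulates a DNA-binding-protein benchmark in shape only:
two sequence classes over the 20-letter alphabet with a controllable
class-conditional compositional shift and class imbalance. Negatives
draw every residue from the uniform composition (1/20 per letter);
positives shift total probability mass ``delta`` onto a small set of
enriched letters — by default arginine and lysine, mirroring the
positive-charge bias of real DNA-binding proteins — with the remaining
letters rescaled uniformly. Residues are sampled independently, so
composition and content features carry the class signal while
distribution and dipeptide blocks stay near-uninformative.

Defaults mirror the expanded-benchmark shape (146 positives against
2,125 negatives) with lengths uniform on 100..300 and delta = 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Union

import numpy as np

from dnabind.sequence_io import STANDARD_AA, ProteinRecord, write_fasta


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; see the module docstring for semantics."""

    n_pos: int = 146
    n_neg: int = 2125
    length_range: tuple[int, int] = (100, 300)
    enriched_letters: tuple[str, ...] = ("R", "K")
    delta: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class counts must be non-negative")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(
                f"length_range must satisfy 1 <= min <= max, got {self.length_range}"
            )
        if not 0.0 <= self.delta <= 0.5:
            raise ValueError(f"delta must lie in [0, 0.5], got {self.delta}")
        letters = tuple(str(c).upper() for c in self.enriched_letters)
        object.__setattr__(self, "enriched_letters", letters)
        unknown = set(letters) - set(STANDARD_AA)
        if unknown or not letters:
            raise ValueError(f"enriched_letters must be standard amino acids, got {letters}")


def class_compositions(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-letter sampling probabilities (positive class, negative class)."""
    negative = np.full(20, 1.0 / 20)
    positive = negative.copy()
    enriched = [STANDARD_AA.index(c) for c in config.enriched_letters]
    k = len(enriched)
    positive[:] = (1.0 - k / 20.0 - config.delta) / (20 - k)
    positive[enriched] = 1.0 / 20 + config.delta / k
    return positive, negative


def generate(config: SyntheticConfig) -> tuple[list[ProteinRecord], np.ndarray]:
    """Generate records (positives first, then negatives) and aligned labels.

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p_pos, p_neg = class_compositions(config)
    letters = np.array(list(STANDARD_AA))
    lo, hi = config.length_range

    records: list[ProteinRecord] = []
    labels: list[int] = []
    for label, count, probs, prefix in (
        (1, config.n_pos, p_pos, "pos"),
        (-1, config.n_neg, p_neg, "neg"),
    ):
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=length, p=probs))
            records.append(ProteinRecord(f"{prefix}_{i + 1:05d}", seq))
            labels.append(label)
    return records, np.asarray(labels, dtype=int)


def write_dataset(
    records: list[ProteinRecord],
    labels: np.ndarray,
    positives_path: Union[str, PathLike],
    negatives_path: Union[str, PathLike],
    labels_path: Union[str, PathLike, None] = None,
) -> None:
    """Write the two-FASTA convention plus an optional id/label table."""
    labels = np.asarray(labels)
    write_fasta([r for r, y in zip(records, labels) if y == 1], positives_path)
    write_fasta([r for r, y in zip(records, labels) if y == -1], negatives_path)
    if labels_path is not None:
        with open(labels_path, "w") as handle:
            for rec, y in zip(records, labels):
                handle.write(f"{rec.id}\t{int(y)}\n")
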