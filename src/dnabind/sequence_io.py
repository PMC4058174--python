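"""FASTA input/output and sequence validation.

Every downstream computation is defined only over the 20 standard
amino-acid letters, so parsing normalizes case and either rejects
(``strict``) or strips (``lenient``) non-standard residue codes such as
X, B, Z, U and O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger("dnabind")

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

Source = Union[str, PathLike, IO[str]]


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class SequenceValidationError(ValueError):
    """A sequence violates the 20-letter amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein sequence over the standard amino-acid alphabet.

    Parameters
    ----------
    id :
        Non-empty identifier token.
    sequence :
        Uppercase string over the 20 standard amino-acid letters; at
        least one residue.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise ValueError("record id must be a non-empty token")
        if len(self.sequence) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        """Number of residues, L."""
        return len(self.sequence)


def _open_maybe(source: Source, mode: str):
    if isinstance(source, (str, PathLike)):
        return open(source, mode), True
    return source, False


def parse_fasta(source: Source, mode: str = "strict") -> list[ProteinRecord]:
    """Read protein records from a FASTA file or text stream.

    Sequences are uppercased. In ``strict`` mode any letter outside the
    20-letter alphabet raises :class:`SequenceValidationError`; in
    ``lenient`` mode such letters are removed with a logged warning, and
    records that become empty are dropped (also with a warning).

    Returns records in file order. Duplicate ids are allowed but warned
    about, since identifiers play no role in the feature mathematics.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    handle, close = _open_maybe(source, "r")
    try:
        first = handle.read(1)
        rest = handle.read()
    finally:
        if close:
            handle.close()
    text = first + rest
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        offending = stripped.splitlines()[0]
        raise FastaParseError(
            f"sequence data before any FASTA header: {offending[:40]!r}"
        )

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    import io as _io

    for title, seq in SimpleFastaParser(_io.StringIO(text)):
        rec_id = title.split()[0] if title.split() else title
        if not rec_id:
            raise FastaParseError("FASTA entry with empty header line")
        seq = seq.upper().replace(" ", "")
        nonstd = [c for c in seq if c not in _STANDARD_SET]
        if nonstd:
            if mode == "strict":
                raise SequenceValidationError(
                    f"record {rec_id!r}: non-standard residue {nonstd[0]!r} "
                    "(use mode='lenient' to strip such residues)"
                )
            logger.warning(
                "record %r: removed %d non-standard residue(s) %s",
                rec_id,
                len(nonstd),
                sorted(set(nonstd)),
            )
            seq = "".join(c for c in seq if c in _STANDARD_SET)
        if not seq:
            logger.warning("record %r: empty after normalization, dropped", rec_id)
            continue
        if rec_id in seen:
            logger.warning("duplicate FASTA id %r", rec_id)
        seen.add(rec_id)
        records.append(ProteinRecord(rec_id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], sink: Source, width: int = 60) -> None:
    """Write records as plain FASTA with sequences wrapped at ``width`` columns.

    ``parse_fasta`` applied to the output reproduces the input records.
    """
    handle, close = _open_maybe(sink, "w")
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
    except OSError as exc:
        raise OSError(f"failed writing FASTA to {sink!r}: {exc}") from exc
    finally:
        if close:
            handle.close()


def read_label_table(source: Source) -> dict[str, int]:
    """Read a two-column tab-separated ``id<TAB>label`` table, label in {1, -1}."""
    handle, close = _open_maybe(source, "r")
    try:
        labels: dict[str, int] = {}
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"label table line {lineno}: expected 2 columns")
            rec_id, raw = parts
            value = int(raw)
            if value not in (1, -1):
                raise ValueError(
                    f"label table line {lineno}: label must be 1 or -1, got {value}"
                )
            labels[rec_id] = value
        return labels
    finally:
        if close:
            handle.close()


def records_from_fasta_pair(
    positives: Source, negatives: Source, mode: str = "strict"
) -> tuple[list[ProteinRecord], list[int]]:
    """Load the two-FASTA convention: one positives file, one negatives file.

    Returns all records (positives first, file order preserved) and
    aligned labels (+1 / -1).
    """
    pos = parse_fasta(positives, mode=mode)
    neg = parse_fasta(negatives, mode=mode)
    return pos + neg, [1] * len(pos) + [-1] * len(neg)
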