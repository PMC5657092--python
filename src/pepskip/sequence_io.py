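"""Peptide FASTA input/output with amino-acid alphabet validation.

Peptides are short sequences (typically 5-50 residues) over the 20 standard
one-letter amino-acid codes. Sequences containing ambiguity or non-natural
codes (B, J, O, U, X, Z, gaps, stops) cannot be featurized by the dipeptide
models downstream, so validation is strict by default; a lenient mode skips
offending records with a warning instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically ordered.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

PathOrStream = Union[str, Path, IO[str]]


class FastaError(ValueError):
    """Malformed FASTA input."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the 20-letter alphabet."""


@dataclass(frozen=True)
class Peptide:
    """An identified amino-acid sequence.

    Attributes
    ----------
    id : str
        FASTA header token (text up to the first whitespace).
    sequence : str
        Uppercase residues over the 20-letter alphabet.
    """

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> "Peptide":
        """Raise :class:`AlphabetError` unless every residue is standard."""
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise AlphabetError(
                f"peptide {self.id!r}: non-standard residue(s) "
                f"{', '.join(sorted(bad))}"
            )
        if not self.sequence:
            raise AlphabetError(f"peptide {self.id!r}: empty sequence")
        return self


def _as_handle(source: PathOrStream, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_fasta(source: PathOrStream, strict: bool = True) -> list[Peptide]:
    """Read peptides from FASTA text.

    Sequences are uppercased and wrapped lines concatenated. In strict mode
    (default) a non-standard residue raises :class:`AlphabetError` naming the
    peptide and the character; in lenient mode the record is skipped with a
    logged warning.
    """
    handle, owned = _as_handle(source)
    try:
        first = handle.read(1)
        if first and first not in (">", ";") and not first.isspace():
            raise FastaError(
                "malformed FASTA: sequence data before the first '>' header "
                "(line 1)"
            )
        text = first + handle.read()
    finally:
        if owned:
            handle.close()

    peptides: list[Peptide] = []
    seen: set[str] = set()
    for record in SeqIO.parse(StringIO(text), "fasta"):
        pep = Peptide(id=record.id, sequence=str(record.seq).upper())
        if pep.id in seen:
            raise FastaError(f"duplicate FASTA id {pep.id!r}")
        try:
            pep.validate()
        except AlphabetError as exc:
            if strict:
                raise
            logger.warning("skipping %s", exc)
            continue
        seen.add(pep.id)
        peptides.append(pep)
    return peptides


def write_fasta(peptides: Iterable[Peptide], sink: PathOrStream) -> None:
    """Write peptides as unwrapped FASTA records (``>id`` then one line)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    handle, owned = _as_handle(sink, "w")
    try:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(records)
    finally:
        if owned:
            handle.close()


def read_labels(source: PathOrStream) -> dict[str, int]:
    """Read a two-column TSV mapping peptide id to a {1, 0} class label.

    1 marks a cell-penetrating peptide, 0 a non-CPP. Lines starting with '#'
    are comments.
    """
    handle, owned = _as_handle(source)
    labels: dict[str, int] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"label TSV line {lineno}: expected 2 tab-separated "
                    f"columns, got {len(parts)}"
                )
            pid, raw = parts
            if raw not in ("0", "1"):
                raise ValueError(
                    f"label TSV line {lineno}: label must be 0 or 1, got "
                    f"{raw!r}"
                )
            if pid in labels:
                raise ValueError(f"label TSV line {lineno}: duplicate id {pid!r}")
            labels[pid] = int(raw)
    finally:
        if owned:
            handle.close()
    return labels


def write_labels(labels: dict[str, int], sink: PathOrStream) -> None:
    handle, owned = _as_handle(sink, "w")
    try:
        for pid, lab in labels.items():
            handle.write(f"{pid}\t{lab}\n")
    finally:
        if owned:
            handle.close()
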