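"""Reading, validation and canonicalization of transcript sequences.

Transcripts arrive as DNA or RNA FASTA; downstream code works on a single
uppercase DNA alphabet {A,C,G,T}. Class labels (lncRNA / pcRNA) may come from
a two-column TSV or be embedded in FASTA headers as an ``|label`` suffix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CANONICAL_BASES = "ACGT"
LABELS = ("lncRNA", "pcRNA", "unknown")

#: IUPAC ambiguity codes and the canonical bases each may stand for.
AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Transcripts shorter than this are accepted with a warning (the usual
#: lncRNA definition starts above 200 bp).
MIN_TYPICAL_LENGTH = 200


class FastaFormatError(ValueError):
    """Malformed FASTA input (empty record, invalid character, ...)."""


class SequenceValidationError(ValueError):
    """A sequence violates a contract (empty, ambiguous under error policy, ...)."""


@dataclass
class NucleotideSequence:
    """A validated transcript: identifier, canonical residues, optional label."""

    seq_id: str
    residues: str
    label: Optional[str] = None
    n_altered: int = 0

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise SequenceValidationError("seq_id must be non-empty")
        if not self.residues:
            raise SequenceValidationError(f"sequence {self.seq_id!r} is empty")
        bad = set(self.residues) - set(CANONICAL_BASES)
        if bad:
            raise SequenceValidationError(
                f"sequence {self.seq_id!r} contains non-canonical residues {sorted(bad)}"
            )
        if self.label is not None and self.label not in LABELS:
            raise SequenceValidationError(
                f"label {self.label!r} not in {LABELS}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


def canonicalize(
    raw: str,
    seq_id: str = "seq",
    n_policy: str = "drop",
    label: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> NucleotideSequence:
    """Map raw sequence text onto the canonical DNA alphabet.

    Lowercase is uppercased, U becomes T, and IUPAC ambiguity codes are handled
    per ``n_policy``: ``drop`` removes them, ``random_seeded`` replaces each by
    a seeded random choice among its compatible bases (length preserving), and
    ``error`` raises. Non-IUPAC characters always raise ``FastaFormatError``.
    The number of altered (dropped or replaced) positions is recorded.
    """
    if n_policy not in ("drop", "random_seeded", "error"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    if n_policy == "random_seeded" and rng is None:
        rng = np.random.default_rng(0)

    text = raw.upper().replace("U", "T")
    out = []
    altered = 0
    for pos, ch in enumerate(text):
        if ch in CANONICAL_BASES:
            out.append(ch)
        elif ch in AMBIGUITY:
            if n_policy == "error":
                raise SequenceValidationError(
                    f"{seq_id!r}: ambiguity code {ch!r} at position {pos} "
                    "(n_policy=error)"
                )
            altered += 1
            if n_policy == "random_seeded":
                out.append(AMBIGUITY[ch][rng.integers(len(AMBIGUITY[ch]))])
            # drop: skip
        else:
            raise FastaFormatError(
                f"{seq_id!r}: invalid character {ch!r} at position {pos}"
            )
    if not out:
        raise SequenceValidationError(
            f"sequence {seq_id!r} is empty after canonicalization"
        )
    seq = NucleotideSequence(seq_id, "".join(out), label=label, n_altered=altered)
    if seq.length < MIN_TYPICAL_LENGTH:
        logger.warning(
            "sequence %s is %d bp (< %d bp, shorter than a typical lncRNA)",
            seq_id, seq.length, MIN_TYPICAL_LENGTH,
        )
    return seq


def _split_header_label(seq_id: str) -> tuple[str, Optional[str]]:
    """Peel an ``|lncRNA`` / ``|pcRNA`` suffix off a FASTA identifier."""
    if "|" in seq_id:
        head, _, tail = seq_id.rpartition("|")
        if tail in LABELS:
            return head, tail
    return seq_id, None


def read_fasta(
    path: str | Path,
    n_policy: str = "drop",
    rng: Optional[np.random.Generator] = None,
    parse_header_labels: bool = True,
) -> list[NucleotideSequence]:
    """Read a FASTA file into canonicalized transcripts, order preserved.

    Headers are parsed up to the first whitespace as ``seq_id``. An empty file
    or a record with an empty body raises :class:`FastaFormatError` naming the
    record; duplicate identifiers raise :class:`SequenceValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    seqs: list[NucleotideSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if len(record.seq) == 0:
            raise FastaFormatError(f"record {record.id!r} has an empty sequence")
        seq_id, label = (record.id, None)
        if parse_header_labels:
            seq_id, label = _split_header_label(record.id)
        if seq_id in seen:
            raise SequenceValidationError(f"duplicate seq_id {seq_id!r}")
        seen.add(seq_id)
        seqs.append(
            canonicalize(str(record.seq), seq_id=seq_id, n_policy=n_policy,
                         label=label, rng=rng)
        )
    if not seqs:
        raise FastaFormatError(f"{path} contains no FASTA records")
    return seqs


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path,
                embed_labels: bool = False) -> None:
    """Write transcripts as FASTA, wrapped at 60 columns."""
    records = []
    for s in seqs:
        seq_id = f"{s.seq_id}|{s.label}" if embed_labels and s.label else s.seq_id
        records.append(SeqRecord(Seq(s.residues), id=seq_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a ``seq_id<TAB>label`` TSV (header row optional)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FastaFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            seq_id, label = parts
            if lineno == 1 and label not in LABELS:
                continue  # header row
            if label not in LABELS:
                raise SequenceValidationError(
                    f"{path}:{lineno}: unknown label {label!r}"
                )
            labels[seq_id] = label
    return labels


def write_labels(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tlabel\n")
        for s in seqs:
            fh.write(f"{s.seq_id}\t{s.label or 'unknown'}\n")


def attach_labels(seqs: list[NucleotideSequence],
                  labels: dict[str, str]) -> list[NucleotideSequence]:
    """Return copies of ``seqs`` with labels from a mapping attached."""
    out = []
    for s in seqs:
        out.append(NucleotideSequence(s.seq_id, s.residues,
                                      label=labels.get(s.seq_id, s.label),
                                      n_altered=s.n_altered))
    return out
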