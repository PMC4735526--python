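"""Nucleotide sequences, tag sets and FASTA I/O.

Sequences are stored in the RNA alphabet {A, C, G, U, N} after normalization;
CLIP tags map to a DNA genome but every binding motif in this package is
written as RNA, so conversion happens once, at ingest.  Coordinates are
0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")
DNA_ALPHABET = frozenset("ACGTN")

__all__ = [
    "NucleotideSequence",
    "TagSet",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "normalize_alphabet",
]


class FastaFormatError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence.

    Attributes
    ----------
    id:
        Text label (non-empty when read from FASTA).
    residues:
        Uppercase residues; after :func:`normalize_alphabet` these are over
        {A, C, G, U, N}.
    """

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass
class TagSet:
    """An ordered, named collection of nucleotide sequences.

    Member ids need not be unique; positions are stable.
    """

    name: str
    sequences: list[NucleotideSequence] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[NucleotideSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> NucleotideSequence:
        return self.sequences[i]


def normalize_alphabet(
    seq: NucleotideSequence, target: Literal["RNA", "DNA"] = "RNA"
) -> tuple[NucleotideSequence, int]:
    """Uppercase ``seq`` and convert it to the target alphabet.

    T<->U are interconverted according to ``target``; any other character
    outside the alphabet is mapped to N.  Lossy replacements are counted and
    reported, never fatal.

    Returns
    -------
    (normalized sequence, number of characters replaced by N)

    Idempotent: applying it twice equals applying it once.
    """
    if target not in ("RNA", "DNA"):
        raise ValueError(f"unknown target alphabet: {target!r}")
    alphabet = RNA_ALPHABET if target == "RNA" else DNA_ALPHABET
    swap = {"RNA": ("T", "U"), "DNA": ("U", "T")}[target]
    out = []
    n_replaced = 0
    for ch in seq.residues.upper():
        if ch == swap[0]:
            ch = swap[1]
        if ch not in alphabet:
            ch = "N"
            n_replaced += 1
        out.append(ch)
    if n_replaced:
        logger.warning(
            "sequence %s: replaced %d unexpected character(s) with N", seq.id, n_replaced
        )
    return NucleotideSequence(seq.id, "".join(out)), n_replaced


def read_fasta(
    path: str | Path,
    name: str | None = None,
    normalize: Literal["RNA", "DNA", None] = "RNA",
) -> TagSet:
    """Read a FASTA file into a :class:`TagSet`.

    One :class:`NucleotideSequence` per record, multi-line records
    concatenated, record order preserved.  By default residues are normalized
    to RNA (uppercase, T->U, unknown characters -> N).

    Raises
    ------
    FastaFormatError
        If sequence data precedes the first ``>`` header (the offending line
        number is named).
    """
    path = Path(path)
    # Bio.SeqIO silently ignores leading junk; enforce the format contract
    # (no sequence data before a header) with an explicit pre-check.
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break

    tags = TagSet(name=name if name is not None else path.stem)
    for record in SeqIO.parse(str(path), "fasta"):
        seq = NucleotideSequence(record.id, str(record.seq))
        if normalize is not None:
            seq, _ = normalize_alphabet(seq, normalize)
        tags.sequences.append(seq)
    if not tags.sequences:
        logger.warning("%s: no FASTA records found (empty tag set)", path)
    return tags


def write_fasta(tags: TagSet | Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences as plain FASTA, one (unwrapped) sequence line per record.

    Round-trip property: ``read_fasta(write_fasta(x))`` reproduces ids and
    residues exactly (up to alphabet normalization options).
    """
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in tags
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)
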