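"""Sequence and coordinate primitives shared by every pipeline stage.

Coordinates are 0-based half-open everywhere; anything 1-based exists only
at the formatting layer of reports. ``N`` in a reference sequence never
matches a concrete pattern base and is never a callable cytosine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

#: IUPAC nucleotide codes and the set of concrete bases each stands for.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Complement table over the full IUPAC alphabet (R<->Y, K<->M, W<->W, B<->V, ...).
IUPAC_COMPLEMENT = str.maketrans("ACGTRYKMWSBDHVN", "TGCAYRMKWSVHDBN")


class AlphabetError(ValueError):
    """A sequence contains a character outside the permitted alphabet."""


class FastaFormatError(ValueError):
    """A FASTA file is empty or structurally malformed."""


@dataclass(frozen=True)
class ReferenceLocus:
    """A named DNA sequence (promoter plus gene body) used as the assay substrate.

    Parameters
    ----------
    id :
        Text label, e.g. an accession or a synthetic-locus name.
    sequence :
        Uppercase DNA over ``{A, C, G, T, N}``.
    source :
        Free-text provenance (accession string, simulator parameters, ...).
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"locus {self.id!r}: empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"locus {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open interval ``[start, end)`` with a strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


def read_fasta(path: str | Path) -> list[ReferenceLocus]:
    """Read a (multi-record) FASTA file into :class:`ReferenceLocus` objects.

    Sequences are uppercased and ``U`` is mapped to ``T``; record order is
    preserved. Raises :class:`FastaFormatError` on empty input or when the
    first non-blank line is not a header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno} is not a FASTA header"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty file")
    loci = [
        ReferenceLocus(id=rec.id, sequence=str(rec.seq), source=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not loci:
        raise FastaFormatError(f"{path}: no FASTA records")
    return loci


def write_fasta(path: str | Path, loci: Iterable[ReferenceLocus]) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            header = locus.id if not locus.source else f"{locus.id} {locus.source}"
            fh.write(f">{header}\n")
            for i in range(0, len(locus.sequence), 70):
                fh.write(locus.sequence[i : i + 70] + "\n")


def _validate_iupac(seq: str, *, what: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in IUPAC_EXPANSION:
            raise AlphabetError(f"invalid character {ch!r} at position {i} in {what}")


def revcomp(seq: str) -> str:
    """Reverse complement honouring the full IUPAC alphabet."""
    seq = seq.upper()
    _validate_iupac(seq)
    return seq.translate(IUPAC_COMPLEMENT)[::-1]


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every window base is covered by the matching IUPAC pattern code.

    Degenerate window characters match only if their expansion is a subset of
    the pattern code's expansion, so a reference ``N`` matches only a pattern
    ``N`` — ambiguity in the reference is treated conservatively.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    pattern = pattern.upper()
    window = window.upper()
    _validate_iupac(pattern, what="pattern")
    _validate_iupac(window, what="window")
    return all(
        IUPAC_EXPANSION[w] <= IUPAC_EXPANSION[p] for p, w in zip(pattern, window)
    )


def hamming_iupac(pattern: str, window: str) -> int:
    """Number of positions where the window base is not covered by the pattern."""
    if len(pattern) != len(window):
        raise ValueError("length mismatch")
    return sum(
        not IUPAC_EXPANSION[w] <= IUPAC_EXPANSION[p]
        for p, w in zip(pattern.upper(), window.upper())
    )


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "+"

    def to_line(self) -> str:
        return "\t".join(
            [self.chrom, str(self.start), str(self.end), self.name, str(self.score), self.strand]
        )


def write_bed(path: str | Path, records: Iterable[BedRecord]) -> None:
    """Write BED6 records (0-based half-open, matching internal coordinates)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
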