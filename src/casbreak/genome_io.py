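"""Sequence and coordinate primitives shared by every stage of the pipeline.

All coordinates are stored 0-based half-open internally.  Everything a user
ever sees (reports, VCF, TSV, log lines) is 1-based inclusive — the single
conversion point is :func:`to_report_coords` / :func:`from_report_coords`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

#: characters kept verbatim after normalization
_CANONICAL = frozenset("ACGTN")
#: IUPAC ambiguity codes that are degraded to N (with a warning)
_AMBIGUOUS = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


def normalize_sequence(raw: str, *, name: str = "?") -> str:
    """Uppercase a nucleotide string and restrict it to {A,C,G,T,N}.

    Lowercase (soft-masked) bases are uppercased.  IUPAC ambiguity codes
    other than N are converted to N with a logged warning; anything outside
    the IUPAC nucleotide alphabet is an error.
    """
    seq = raw.upper()
    bad = set(seq) - _CANONICAL
    if not bad:
        return seq
    illegal = bad - _AMBIGUOUS
    if illegal:
        raise FastaError(
            f"sequence {name!r}: illegal character(s) {sorted(illegal)!r}"
        )
    n_converted = sum(seq.count(c) for c in bad)
    log.warning(
        "sequence %s: %d ambiguous IUPAC base(s) (%s) converted to N",
        name, n_converted, ",".join(sorted(bad)),
    )
    table = str.maketrans({c: "N" for c in bad})
    return seq.translate(table)


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        if not self.seq:
            raise FastaError(f"sequence {self.name!r} is empty")
        object.__setattr__(self, "seq", normalize_sequence(self.seq, name=self.name))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def to_report_coords(interval: GenomicInterval) -> tuple[str, int, int]:
    """Convert an internal interval to (chrom, 1-based start, 1-based end), inclusive."""
    return interval.chrom, interval.start + 1, interval.end


def from_report_coords(chrom: str, start_1: int, end_1: int) -> GenomicInterval:
    """Inverse of :func:`to_report_coords`."""
    return GenomicInterval(chrom, start_1 - 1, end_1)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - _CANONICAL
    if bad:
        raise ValueError(f"illegal character(s) in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def load_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a (multi-record, possibly CRLF) FASTA file.

    Every record is normalized to uppercase {A,C,G,T,N}.  Duplicate record
    names and empty records are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: dict[str, GenomeSequence] = {}
    name: str | None = None
    chunks: list[str] = []

    def _commit() -> None:
        if name is None:
            return
        if name in records:
            raise FastaError(f"duplicate sequence name {name!r} in {path}")
        records[name] = GenomeSequence(name, "".join(chunks))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                _commit()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FastaError(f"unnamed FASTA record in {path}")
                chunks = []
            else:
                if name is None:
                    raise FastaError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    _commit()
    if not records:
        raise FastaError(f"{path}: no FASTA records")
    return records


def write_fasta(
    records: Mapping[str, GenomeSequence | str] | Iterable[GenomeSequence],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records as LF-terminated FASTA wrapped at ``width`` columns."""
    if isinstance(records, Mapping):
        items = [(k, v.seq if isinstance(v, GenomeSequence) else str(v))
                 for k, v in records.items()]
    else:
        items = [(r.name, r.seq) for r in records]
    if not items:
        raise ValueError("no records to write")
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w", newline="\n") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
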