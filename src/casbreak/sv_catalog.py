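"""Optical-mapping SV call catalog: parsing, filtering, summarization.

Optical (Bionano-style) genome mapping reports structural variants as
labelled intervals with a type and, sometimes, zygosity — but without
base-level breakpoints.  This module reads those calls from either plain
BED (0-based half-open, type/zygosity in columns 7-8) or a documented
minimal tab dialect ``smap_min`` (1-based inclusive, header-tagged) and
turns them into the records that seed guide design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .genome_io import GenomicInterval, from_report_coords, to_report_coords

SV_TYPES = frozenset({"deletion", "insertion", "inversion", "duplication", "translocation"})
ZYGOSITIES = frozenset({"het", "hom", "unknown"})

SMAP_MIN_HEADER = "#chrom\tstart\tend\ttype\tsize\tzygosity\tid"


class SVTableError(ValueError):
    """Malformed SV table input (carries the offending line number)."""


@dataclass(frozen=True)
class SVRecord:
    """One optical-mapping SV call.

    ``interval`` is the locus on the reference; for insertions it is where
    the extra material maps on the contig, while ``size_estimate`` is the
    estimated number of inserted bases — the two are distinct quantities.
    For deletions and inversions ``size_estimate`` defaults to the interval
    length.
    """

    sv_id: str
    interval: GenomicInterval
    sv_type: str
    size_estimate: int = 0
    zygosity: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.size_estimate <= 0:
            if self.sv_type in ("deletion", "inversion", "duplication"):
                object.__setattr__(self, "size_estimate", self.interval.length())
            else:
                raise ValueError(
                    f"{self.sv_id}: size_estimate required for {self.sv_type}"
                )


@dataclass
class SVCatalog:
    records: list[SVRecord] = field(default_factory=list)
    reference_name: str = ""

    def __post_init__(self) -> None:
        ids = [r.sv_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sv_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _parse_bed_row(fields: list[str], lineno: int) -> SVRecord:
    if len(fields) < 8:
        raise SVTableError(f"line {lineno}: BED dialect needs 8 columns, got {len(fields)}")
    chrom, start, end, name, _score, _strand, sv_type, zyg = fields[:8]
    try:
        iv = GenomicInterval(chrom, int(start), int(end))
    except ValueError as e:
        raise SVTableError(f"line {lineno}: {e}") from e
    if sv_type not in SV_TYPES:
        raise SVTableError(f"line {lineno}: unknown sv_type {sv_type!r}")
    zygosity = "unknown" if zyg == "." else zyg
    if zygosity not in ZYGOSITIES:
        raise SVTableError(f"line {lineno}: unknown zygosity {zyg!r}")
    size = int(fields[8]) if len(fields) > 8 and fields[8] not in (".", "") else 0
    try:
        return SVRecord(name, iv, sv_type, size, zygosity)
    except ValueError as e:
        raise SVTableError(f"line {lineno}: {e}") from e


def _parse_smap_row(fields: list[str], lineno: int) -> SVRecord:
    if len(fields) != 7:
        raise SVTableError(f"line {lineno}: smap_min needs 7 columns, got {len(fields)}")
    chrom, start, end, sv_type, size, zyg, sv_id = fields
    try:
        if int(start) > int(end):
            raise SVTableError(f"line {lineno}: start > end")
        iv = from_report_coords(chrom, int(start), int(end))
    except SVTableError:
        raise
    except ValueError as e:
        raise SVTableError(f"line {lineno}: {e}") from e
    if sv_type not in SV_TYPES:
        raise SVTableError(f"line {lineno}: unknown sv_type {sv_type!r}")
    if zyg not in ZYGOSITIES:
        raise SVTableError(f"line {lineno}: unknown zygosity {zyg!r}")
    try:
        return SVRecord(sv_id, iv, sv_type, int(size), zyg)
    except ValueError as e:
        raise SVTableError(f"line {lineno}: {e}") from e


def parse_sv_table(path: str | Path, dialect: str, reference_name: str = "") -> SVCatalog:
    """Parse SV calls from ``bed`` or ``smap_min`` dialect (see module docs)."""
    if dialect not in ("bed", "smap_min"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                if dialect == "smap_min" and line != SMAP_MIN_HEADER:
                    raise SVTableError(f"line {lineno}: unexpected smap_min header {line!r}")
                continue
            fields = line.split("\t")
            if dialect == "bed":
                records.append(_parse_bed_row(fields, lineno))
            else:
                records.append(_parse_smap_row(fields, lineno))
    return SVCatalog(records, reference_name=reference_name)


def write_sv_table(catalog: SVCatalog, path: str | Path, dialect: str) -> None:
    """Serialize a catalog; inverse of :func:`parse_sv_table` for both dialects."""
    if dialect not in ("bed", "smap_min"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="\n") as fh:
        if dialect == "smap_min":
            fh.write(SMAP_MIN_HEADER + "\n")
        for r in catalog:
            if dialect == "bed":
                zyg = r.zygosity
                fh.write(
                    f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                    f"{r.sv_id}\t0\t+\t{r.sv_type}\t{zyg}\t{r.size_estimate}\n"
                )
            else:
                chrom, s1, e1 = to_report_coords(r.interval)
                fh.write(
                    f"{chrom}\t{s1}\t{e1}\t{r.sv_type}\t{r.size_estimate}\t"
                    f"{r.zygosity}\t{r.sv_id}\n"
                )


def filter_catalog(
    catalog: SVCatalog, min_size: int = 2000, types: Iterable[str] | None = None
) -> SVCatalog:
    """Keep records with size_estimate >= min_size (inclusive) and sv_type in ``types``.

    ``types`` defaults to all known SV types; an explicitly empty set is an error.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if types is None:
        types = SV_TYPES
    types = set(types)
    if not types:
        raise ValueError("types must be non-empty")
    unknown = types - SV_TYPES
    if unknown:
        raise ValueError(f"unknown sv_type(s) in filter: {sorted(unknown)}")
    kept = [r for r in catalog.records if r.size_estimate >= min_size and r.sv_type in types]
    return SVCatalog(kept, reference_name=catalog.reference_name)


def summarize_catalog(catalog: SVCatalog) -> dict[str, int]:
    """Per-type counts plus ``total``; every known type is reported (0 if absent)."""
    counts = {t: 0 for t in sorted(SV_TYPES)}
    for r in catalog:
        counts[r.sv_type] += 1
    counts["total"] = len(catalog.records)
    return counts
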