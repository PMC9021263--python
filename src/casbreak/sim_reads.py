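"""Synthetic-data engine for Cas9-targeted nanopore enrichment.

Builds SV-bearing diploid haplotypes from a reference, simulates the
targeted assay's output — whole-amplicon reads between designed cut sites
with nanopore-like iid errors plus off-target ("blocking leakage")
background reads — and emits exact truth alignments in SAM so the
breakpoint caller can be tested without any external aligner or download.

The amplicon model reflects the wet protocol: Cas9 cleavage exposes
ligatable ends, adapters attach at the fresh cuts, and PCR amplifies the
fragment between two cuts of the same target, so reads are full fragments
(optionally jittered), not random shears.  Fragments longer than
``amplicon_max`` drop out, as PCR enrichment caps usable target sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .digest_model import CutSite
from .genome_io import GenomeSequence, GenomicInterval, reverse_complement

DEFAULT_ERROR_RATES = (0.03, 0.02, 0.04)  # substitution, insertion, deletion
PHRED_STUB = "5"  # constant Q20 placeholder quality


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class AppliedSV:
    """Ground-truth SV applied to a haplotype.

    For insertions ``ref_interval`` is the single-base locus whose start is
    the inter-base insertion point; ``truth_breakpoints`` are 1-based
    positions (last reference base before the junction).
    """

    sv_id: str
    sv_type: str
    ref_interval: GenomicInterval
    inserted_seq: str | None = None
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if self.sv_type not in ("deletion", "insertion", "inversion"):
            raise ValueError(f"{self.sv_id}: unsupported sv_type {self.sv_type!r}")
        if (self.inserted_seq is not None) != (self.sv_type == "insertion"):
            raise ValueError(f"{self.sv_id}: inserted_seq required iff insertion")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"{self.sv_id}: zygosity must be het or hom")

    @property
    def truth_breakpoints(self) -> list[int]:
        """1-based truth junction positions (deletion/inversion: 2; insertion: 1)."""
        iv = self.ref_interval
        if self.sv_type == "deletion":
            # last retained base before the gap / position of first base after
            return [iv.start, iv.end + 1]
        if self.sv_type == "inversion":
            # last base before the inverted block, last base of it
            return [iv.start, iv.end]
        return [iv.start]


@dataclass(frozen=True)
class Block:
    """One colinear piece of a haplotype in haplotype coordinates."""

    hap_start: int
    hap_end: int
    kind: str  # "match" | "inserted"
    chrom: str | None = None
    ref_start: int | None = None
    ref_end: int | None = None
    strand: str = "+"
    sv_id: str = ""


@dataclass(frozen=True)
class Part:
    """A block restricted to a fragment, in fragment-local clean coordinates."""

    clean_start: int
    clean_end: int
    kind: str
    chrom: str | None
    ref_start: int | None
    ref_end: int | None
    strand: str
    sv_id: str


@dataclass
class Haplotype:
    """One chromosome copy: edited sequence plus an exact block liftover."""

    name: str
    chrom: str
    seq: GenomeSequence
    blocks: list[Block]

    def ref_to_hap(self, ref_coord: int) -> int | None:
        """Map a reference inter-base coordinate; None if it fell in a deletion."""
        for b in self.blocks:
            if b.kind != "match":
                continue
            if b.ref_start <= ref_coord <= b.ref_end:
                if b.strand == "+":
                    return b.hap_start + (ref_coord - b.ref_start)
                return b.hap_start + (b.ref_end - ref_coord)
        return None

    def hap_to_ref(self, hap_coord: int) -> int | None:
        """Inverse mapping; None inside inserted material."""
        for b in self.blocks:
            if b.hap_start <= hap_coord <= b.hap_end:
                if b.kind != "match":
                    return None
                if b.strand == "+":
                    return b.ref_start + (hap_coord - b.hap_start)
                return b.ref_end - (hap_coord - b.hap_start)
        return None

    def decompose(self, s: int, e: int) -> list[Part]:
        """Split haplotype interval [s, e) into reference-space parts."""
        if not 0 <= s < e <= len(self.seq):
            raise ValueError(f"{self.name}: interval [{s},{e}) out of range")
        parts: list[Part] = []
        for b in self.blocks:
            lo, hi = max(s, b.hap_start), min(e, b.hap_end)
            if lo >= hi:
                continue
            if b.kind == "inserted":
                parts.append(Part(lo - s, hi - s, "inserted", None, None, None, "+", b.sv_id))
                continue
            if b.strand == "+":
                rs = b.ref_start + (lo - b.hap_start)
                re_ = b.ref_start + (hi - b.hap_start)
            else:
                rs = b.ref_end - (hi - b.hap_start)
                re_ = b.ref_end - (lo - b.hap_start)
            parts.append(Part(lo - s, hi - s, "match", self.chrom, rs, re_, b.strand, b.sv_id))
        return parts


@dataclass
class HaplotypePair:
    """Both haplotypes of the simulated sample, keyed 'hap1'/'hap2'."""

    haplotypes: dict[str, dict[str, Haplotype]]  # hap_name -> chrom -> Haplotype
    svs: list[AppliedSV]

    def sequences(self) -> dict[str, GenomeSequence]:
        out = {}
        for hap_name, chroms in self.haplotypes.items():
            for h in chroms.values():
                out[h.seq.name] = h.seq
        return out


def _build_haplotype(
    ref: GenomeSequence, svs: Sequence[AppliedSV], hap_name: str
) -> Haplotype:
    svs = sorted(svs, key=lambda s: s.ref_interval.start)
    pieces: list[str] = []
    blocks: list[Block] = []
    cursor = 0  # ref coordinate
    hap_pos = 0

    def add_match(r0: int, r1: int, strand: str = "+", sv_id: str = "") -> None:
        nonlocal hap_pos
        if r1 <= r0:
            return
        sub = ref.seq[r0:r1]
        if strand == "-":
            sub = reverse_complement(sub)
        pieces.append(sub)
        blocks.append(Block(hap_pos, hap_pos + len(sub), "match", ref.name, r0, r1, strand, sv_id))
        hap_pos += len(sub)

    for sv in svs:
        iv = sv.ref_interval
        if iv.end > len(ref):
            raise SimulationError(f"{sv.sv_id}: interval outside reference")
        if sv.sv_type == "insertion":
            # inserted_seq enters at inter-base coordinate iv.start
            add_match(cursor, iv.start)
            ins = sv.inserted_seq
            pieces.append(ins)
            blocks.append(Block(hap_pos, hap_pos + len(ins), "inserted", sv_id=sv.sv_id))
            hap_pos += len(ins)
            cursor = iv.start
        elif sv.sv_type == "deletion":
            add_match(cursor, iv.start)
            cursor = iv.end
        else:  # inversion
            add_match(cursor, iv.start)
            add_match(iv.start, iv.end, strand="-", sv_id=sv.sv_id)
            cursor = iv.end
    add_match(cursor, len(ref))
    seq = GenomeSequence(f"{ref.name}_{hap_name}", "".join(pieces))
    return Haplotype(f"{ref.name}_{hap_name}", ref.name, seq, blocks)


def apply_svs_to_reference(
    reference: Mapping[str, GenomeSequence], svs: Sequence[AppliedSV]
) -> HaplotypePair:
    """Apply SVs to build both haplotypes (het -> hap2 only, hom -> both).

    SV intervals must be non-overlapping per chromosome; the returned
    liftover blocks are exact and invertible outside edited bases.
    """
    by_chrom: dict[str, list[AppliedSV]] = {}
    for sv in svs:
        chrom = sv.ref_interval.chrom
        if chrom not in reference:
            raise SimulationError(f"{sv.sv_id}: unknown chrom {chrom!r}")
        by_chrom.setdefault(chrom, []).append(sv)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: s.ref_interval.start)
        for a, b in zip(group, group[1:]):
            if a.ref_interval.end > b.ref_interval.start:
                raise SimulationError(
                    f"overlapping SVs {a.sv_id} and {b.sv_id} on {chrom}"
                )
    haps: dict[str, dict[str, Haplotype]] = {"hap1": {}, "hap2": {}}
    for chrom, ref in reference.items():
        group = by_chrom.get(chrom, [])
        hom = [s for s in group if s.zygosity == "hom"]
        haps["hap1"][chrom] = _build_haplotype(ref, hom, "hap1")
        haps["hap2"][chrom] = _build_haplotype(ref, group, "hap2")
    return HaplotypePair(haps, list(svs))


# ---------------------------------------------------------------------------
# error model


def mutate_sequence(
    seq: str, rates: tuple[float, float, float], rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Apply iid substitution/insertion/deletion errors to a clean sequence.

    Returns the read sequence and an op list along the clean axis:
    ``M`` copy, ``X`` substitution, ``D`` clean base dropped, ``I`` read
    bases inserted (consume no clean base).  Adjacent same ops are merged.
    """
    sub, ins, dele = rates
    L = len(seq)
    if L == 0:
        return "", []
    u = rng.random(L)
    cat = np.zeros(L, dtype=np.int8)  # 0 M, 1 X, 2 D
    cat[u < dele] = 2
    cat[(u >= dele) & (u < dele + sub)] = 1
    ins_after = rng.random(L + 1) < ins  # insertion before clean position i
    events = np.flatnonzero((cat != 0) | ins_after[:L])
    bases = "ACGT"
    out: list[str] = []
    ops: list[tuple[str, int]] = []

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + ln)
        else:
            ops.append((op, ln))

    prev = 0
    for i in map(int, events):
        if i > prev:
            out.append(seq[prev:i])
            push("M", i - prev)
        if ins_after[i]:
            out.append(bases[int(rng.integers(4))])
            push("I", 1)
        c = cat[i]
        if c == 0:
            out.append(seq[i])
            push("M", 1)
        elif c == 1:
            orig = seq[i]
            alts = bases.replace(orig, "") if orig in bases else bases
            out.append(alts[int(rng.integers(len(alts)))])
            push("X", 1)
        else:
            push("D", 1)
        prev = i + 1
    if prev < L:
        out.append(seq[prev:])
        push("M", L - prev)
    if ins_after[L]:
        out.append(bases[int(rng.integers(4))])
        push("I", 1)
    return "".join(out), ops


def edit_count(ops: Sequence[tuple[str, int]]) -> int:
    return sum(ln for op, ln in ops if op in "XID")


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    hap_name: str  # "hap1" | "hap2"
    chrom: str
    sv_id: str  # sv_id or "background"
    frag_start: int  # haplotype coordinates
    frag_end: int
    strand: str  # orientation the molecule was read in
    ops: tuple[tuple[str, int], ...]  # error ops on the clean fragment axis


@dataclass
class ReadSet:
    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    truth: dict[str, ReadTruth]
    seed: int
    haplotypes: HaplotypePair

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.reads]
        if len(ids) != len(set(ids)) or set(ids) != set(self.truth):
            raise ValueError("read ids and truth records must correspond 1:1")


def _map_cut(hap: Haplotype, cut: CutSite, reference: Mapping[str, GenomeSequence]) -> int | None:
    """Map a designed cut to haplotype coordinates.

    Reference-space cuts go through the liftover (None when deleted on this
    haplotype).  Element-consensus cuts (seq_name not a reference chrom)
    land at their consensus offset inside the matching inserted block,
    assuming the inserted sequence begins with the consensus — true for
    the bundled synthetic worlds.
    """
    if cut.seq_name in reference:
        if cut.seq_name != hap.chrom:
            return None
        return hap.ref_to_hap(cut.coord)
    for b in hap.blocks:
        if b.kind == "inserted" and b.sv_id == cut.sv_id:
            if cut.coord < b.hap_end - b.hap_start:
                return b.hap_start + cut.coord
    return None


def simulate_reads(
    haplotypes: HaplotypePair,
    cut_sites: Sequence[CutSite],
    reference: Mapping[str, GenomeSequence],
    n_reads_per_target: int = 30,
    error_rates: tuple[float, float, float] = DEFAULT_ERROR_RATES,
    on_target_fraction: float = 0.7,
    seed: int = 0,
    amplicon_max: int = 30000,
    length_jitter: float = 0.0,
    background_median: int = 2000,
    allele_weights: Mapping[tuple[str, str], float] | None = None,
) -> ReadSet:
    """Simulate targeted amplicon reads plus background leakage.

    On-target reads are whole fragments between two same-target cut sites
    on the sampled haplotype; background reads are uniform random
    haplotype fragments with log-normal length (median
    ``background_median``) making up ``1 - on_target_fraction`` of the
    total.  Deterministic for a fixed seed.
    """
    if not cut_sites:
        raise SimulationError("no cut sites supplied")
    if not 0.0 < on_target_fraction <= 1.0:
        raise SimulationError("on_target_fraction must be in (0, 1]")
    for r in error_rates:
        if not 0.0 <= r <= 0.2:
            raise SimulationError(f"error rate {r} outside [0, 0.2]")
    rng = np.random.default_rng(seed)
    weights = dict(allele_weights or {})
    reads: list[tuple[str, str, str]] = []
    truth: dict[str, ReadTruth] = {}
    counter = 0

    def emit(hap_name: str, hap: Haplotype, s: int, e: int, sv_id: str) -> None:
        nonlocal counter
        frag = hap.seq.seq[s:e]
        read_seq, ops = mutate_sequence(frag, error_rates, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            read_seq = reverse_complement(read_seq)
        rid = f"r{counter:06d}"
        counter += 1
        reads.append((rid, read_seq, PHRED_STUB * len(read_seq)))
        truth[rid] = ReadTruth(
            rid, hap_name, hap.chrom, sv_id, s, e, strand, tuple(ops)
        )

    # --- on-target amplicons
    for hap_name in ("hap1", "hap2"):
        for chrom, hap in sorted(haplotypes.haplotypes[hap_name].items()):
            mapped: list[tuple[int, str]] = []
            for cut in cut_sites:
                pos = _map_cut(hap, cut, reference)
                if pos is not None and 0 < pos < len(hap.seq):
                    mapped.append((pos, cut.sv_id))
            mapped.sort()
            for (p0, sv0), (p1, sv1) in zip(mapped, mapped[1:]):
                if sv0 != sv1 or p1 - p0 > amplicon_max or p1 == p0:
                    continue
                weight = weights.get((sv0, hap_name), 1.0)
                n = int(round(n_reads_per_target * weight))
                for _ in range(n):
                    s, e = p0, p1
                    if length_jitter > 0:
                        trim = int(length_jitter * (e - s))
                        s += int(rng.integers(0, trim + 1))
                        e -= int(rng.integers(0, trim + 1))
                    emit(hap_name, hap, s, e, sv0)

    n_on = counter
    if n_on == 0:
        raise SimulationError("no on-target fragments under amplicon_max; check cuts")

    # --- background leakage
    n_bg = int(round(n_on * (1.0 - on_target_fraction) / on_target_fraction))
    all_haps = [
        (hap_name, hap)
        for hap_name in ("hap1", "hap2")
        for _, hap in sorted(haplotypes.haplotypes[hap_name].items())
    ]
    lengths = np.array([len(h.seq) for _, h in all_haps], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(n_bg):
        idx = int(rng.choice(len(all_haps), p=probs))
        hap_name, hap = all_haps[idx]
        L = int(rng.lognormal(mean=float(np.log(background_median)), sigma=0.6))
        L = max(200, min(L, len(hap.seq) - 1))
        s = int(rng.integers(0, len(hap.seq) - L))
        emit(hap_name, hap, s, s + L, "background")

    return ReadSet(reads, truth, seed, haplotypes)


def write_fastq(read_set: ReadSet, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rid, seq, qual in read_set.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth_table(read_set: ReadSet, path: str | Path) -> None:
    """Per-read truth TSV (haplotype, target, fragment interval, strand)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("read_id\thaplotype\tchrom\tsv_id\tfrag_start\tfrag_end\tstrand\tedits\n")
        for rid, _, _ in read_set.reads:
            t = read_set.truth[rid]
            fh.write(
                f"{rid}\t{t.hap_name}\t{t.chrom}\t{t.sv_id}\t{t.frag_start}\t"
                f"{t.frag_end}\t{t.strand}\t{edit_count(t.ops)}\n"
            )


# ---------------------------------------------------------------------------
# truth alignments


@dataclass
class SAMRecord:
    qname: str
    flag: int
    rname: str
    pos: int  # 0-based leftmost
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    qual: str
    tags: dict[str, tuple[str, object]] = field(default_factory=dict)

    def cigar_string(self) -> str:
        return "".join(f"{ln}{op}" for op, ln in self.cigar)

    def to_line(self) -> str:
        tags = "\t".join(
            f"{k}:{t}:{v}" for k, (t, v) in sorted(self.tags.items())
        )
        base = (
            f"{self.qname}\t{self.flag}\t{self.rname}\t{self.pos + 1}\t{self.mapq}\t"
            f"{self.cigar_string()}\t*\t0\t0\t{self.seq}\t{self.qual}"
        )
        return base + ("\t" + tags if tags else "")


def _slice_ops(
    ops: Sequence[tuple[str, int]], c0: int, c1: int
) -> tuple[int, int, list[tuple[str, int]]]:
    """Restrict clean-axis error ops to clean interval [c0, c1).

    Returns (read_start, read_end, ops_within) where read coordinates are
    on the error-bearing fragment.  Insertions at an interior boundary
    attach to the left side.
    """
    clean = read = 0
    read_start = read_end = None
    within: list[tuple[str, int]] = []

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if within and within[-1][0] == op:
            within[-1] = (op, within[-1][1] + ln)
        else:
            within.append((op, ln))

    for op, ln in ops:
        if op in "MXD":
            lo, hi = max(clean, c0), min(clean + ln, c1)
            if lo < hi:
                push(op, hi - lo)
                if op in "MX":
                    if read_start is None:
                        read_start = read + (lo - clean)
                    read_end = read + (hi - clean)
            clean += ln
            if op in "MX":
                read += ln
        else:  # insertion at inter-base clean position `clean`; attach left
            if c0 < clean <= c1:
                if read_start is None:
                    read_start = read
                push(op, ln)
                read_end = read + ln
            read += ln
    if read_start is None:
        # entire slice deleted by errors (or empty): anchor at mapped point
        read_start = read_end = _clean_to_read(ops, c0)
    return read_start, read_end, within


def _clean_to_read(ops: Sequence[tuple[str, int]], c: int) -> int:
    clean = read = 0
    for op, ln in ops:
        if op in "MX":
            if clean + ln >= c:
                return read + (c - clean)
            clean += ln
            read += ln
        elif op == "D":
            if clean + ln >= c:
                return read
            clean += ln
        else:
            read += ln
    return read


def _normalize(pos: int, ops: list[tuple[str, int]]) -> tuple[int, list[tuple[str, int]], int, int]:
    """Strip boundary D, turn boundary I into extra clips.

    Returns (pos, ops, extra_left_clip, extra_right_clip).
    """
    left = right = 0
    while ops and ops[0][0] in "DI":
        op, ln = ops.pop(0)
        if op == "D":
            pos += ln
        else:
            left += ln
    while ops and ops[-1][0] in "DI":
        op, ln = ops.pop()
        if op == "I":
            right += ln
    return pos, ops, left, right


def _merge_mx(ops: Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        op = "M" if op == "X" else op
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def _records_for_read(
    truth: ReadTruth,
    hap: Haplotype,
    read_seq: str,
    qual: str,
    split_threshold: int,
) -> list[SAMRecord]:
    parts = hap.decompose(truth.frag_start, truth.frag_end)
    ops = list(truth.ops) or [("M", truth.frag_end - truth.frag_start)]
    frag_read_len = sum(ln for op, ln in ops if op in "MXI")

    # annotate each part with read-space coordinates and sliced ops
    sliced = []
    for p in parts:
        r0, r1, within = _slice_ops(ops, p.clean_start, p.clean_end)
        sliced.append((p, r0, r1, within))

    # group colinear same-strand match parts (with small deletion gaps and
    # interior inserted parts) into single records
    groups: list[list[tuple]] = []
    for item in sliced:
        p = item[0]
        if p.kind == "inserted":
            if groups and groups[-1]:
                groups[-1].append(item)  # may become an I op or trailing clip
            else:
                groups.append([item])
            continue
        if groups:
            prev_matches = [it for it in groups[-1] if it[0].kind == "match"]
            if prev_matches:
                q = prev_matches[-1][0]
                colinear = (
                    q.strand == p.strand
                    and q.chrom == p.chrom
                    and (
                        (p.strand == "+" and 0 <= p.ref_start - q.ref_end <= split_threshold)
                        or (p.strand == "-" and 0 <= q.ref_start - p.ref_end <= split_threshold)
                    )
                )
                if colinear:
                    groups[-1].append(item)
                    continue
        groups.append([item])

    records: list[SAMRecord] = []
    for group in groups:
        matches = [it for it in group if it[0].kind == "match"]
        if not matches:
            continue  # purely inserted content: soft-clipped in neighbours
        strand = matches[0][0].strand
        # ref-forward part order
        ordered = group if strand == "+" else list(reversed(group))
        ref_ops: list[tuple[str, int]] = []
        pos = None
        prev_ref_end = None
        match_idx = [i for i, it in enumerate(ordered) if it[0].kind == "match"]
        for i, it in enumerate(ordered):
            p, r0, r1, within = it
            if p.kind == "inserted":
                # I op only when flanked by match parts; terminal inserted
                # content becomes soft clip via the read-space margins
                if ref_ops and any(j > i for j in match_idx):
                    ref_ops.append(("I", r1 - r0))
                continue
            p_ops = within if strand == "+" else list(reversed(within))
            p_start = p.ref_start
            if pos is None:
                pos = p_start
            if prev_ref_end is not None and p_start > prev_ref_end:
                ref_ops.append(("D", p_start - prev_ref_end))
            ref_ops.extend(p_ops)
            prev_ref_end = p.ref_end
        pos, ref_ops, extra_l, extra_r = _normalize(pos, list(ref_ops))
        if not ref_ops:
            continue
        # read-space extent of the group's aligned portion (fragment coords)
        r_lo = min(it[1] for it in group if it[0].kind == "match")
        r_hi = max(it[2] for it in group if it[0].kind == "match")
        # clips in ref-forward read orientation
        if strand == "+":
            left_clip = r_lo + extra_l
            right_clip = frag_read_len - r_hi + extra_r
            stored = read_seq if truth.strand == "+" else reverse_complement(read_seq)
        else:
            left_clip = frag_read_len - r_hi + extra_l
            right_clip = r_lo + extra_r
            stored = (
                reverse_complement(read_seq) if truth.strand == "+" else read_seq
            )
        cigar = _merge_mx(ref_ops)
        if left_clip:
            cigar.insert(0, ("S", left_clip))
        if right_clip:
            cigar.append(("S", right_clip))
        flag = 16 if (strand == "-") != (truth.strand == "-") else 0
        nm = sum(ln for op, ln in ref_ops if op in "XID")
        rec = SAMRecord(
            truth.read_id, flag, matches[0][0].chrom, pos, 60, cigar,
            stored, qual if len(qual) == len(stored) else PHRED_STUB * len(stored),
            {"NM": ("i", nm)},
        )
        records.append(rec)

    if not records:
        return []
    records.sort(key=lambda r: -sum(ln for op, ln in r.cigar if op in "MDI"))
    for i, rec in enumerate(records):
        if i > 0:
            rec.flag |= 2048
    if len(records) > 1:
        for rec in records:
            others = [r for r in records if r is not rec]
            sa = "".join(
                f"{o.rname},{o.pos + 1},{'-' if o.flag & 16 else '+'},"
                f"{o.cigar_string()},{o.mapq},{o.tags['NM'][1]};"
                for o in others
            )
            rec.tags["SA"] = ("Z", sa)
    return records


def emit_truth_alignments(
    read_set: ReadSet,
    reference: Mapping[str, GenomeSequence],
    split_threshold: int = 10000,
) -> list[SAMRecord]:
    """Reference-space truth alignments computed through the known liftover.

    Deletion-spanning reads yield one record with a D op, or a
    primary+supplementary split pair when the deleted span exceeds
    ``split_threshold``; inserted material is soft-clipped (terminal) or an
    I op (interior); inverted segments become opposite-strand records with
    SA cross-links.  CIGARs include the simulated errors, so NM equals the
    simulated edit count within each aligned portion.
    """
    seqs = {rid: (seq, qual) for rid, seq, qual in read_set.reads}
    records: list[SAMRecord] = []
    for rid, _, _ in read_set.reads:
        truth = read_set.truth[rid]
        hap = read_set.haplotypes.haplotypes[truth.hap_name][truth.chrom]
        seq, qual = seqs[rid]
        records.extend(_records_for_read(truth, hap, seq, qual, split_threshold))
    order = {name: i for i, name in enumerate(reference)}
    records.sort(key=lambda r: (order.get(r.rname, 1 << 30), r.pos, r.qname))
    return records


def write_sam(
    records: Sequence[SAMRecord],
    reference: Mapping[str, GenomeSequence],
    path: str | Path,
) -> None:
    """Write coordinate-sorted SAM with full headers."""
    with open(path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, rec in reference.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(rec)}\n")
        fh.write("@PG\tID:casbreak\tPN:casbreak\n")
        for r in records:
            fh.write(r.to_line() + "\n")
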