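"""Base-level SV breakpoint and genotype resolution from targeted reads.

Consumes standard alignment records (SAM/BAM, or PAF with CIGAR) of
Cas9-enriched nanopore reads, groups them per read, assigns read groups to
designed targets by cut-site proximity, and resolves each SV class from
its alignment signature:

* deletions — a large in-read deletion op or a split primary/supplementary
  pair with a reference gap; breakpoints are the junction-adjacent aligned
  bases, aggregated as medians across supporting reads.
* insertions — reads aligned up to the breakpoint with the inserted
  sequence soft-clipped; a plurality consensus of the clipped tails is
  built and, when a mobile-element consensus is supplied, confirmed by
  local alignment.
* inversions — reads with opposite-orientation segments anchored at the
  two junctions; both breakpoints are read off the junction-side segment
  boundaries, and dual placements from inverted-repeat similarity are
  flagged, never silently resolved.

Genotypes come from per-allele-class support counts only: the assay's
per-allele cut efficiency varies too much for allele-balance tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .config import CallConfig
from .genome_io import GenomeSequence, GenomicInterval, reverse_complement
from .guide_design import GuideSet


class AlignmentInputError(ValueError):
    pass


@dataclass
class AlignedSegment:
    """One alignment record in a strand-normalized view.

    ``read_interval`` is in original-read coordinates (the orientation the
    molecule was sequenced in), so segments of one read can be ordered
    along the read regardless of mapping strand.  Clips are in stored
    (reference-forward) orientation.
    """

    read_id: str
    ref_interval: GenomicInterval
    read_interval: tuple[int, int]
    strand: str
    cigar: tuple[tuple[str, int], ...]
    left_clip: int
    right_clip: int
    is_supplementary: bool
    seq: str | None = None  # stored orientation, with clipped bases
    supplementary_links: tuple[tuple[str, int, str], ...] = ()

    def clip_at_read_start(self) -> int:
        return self.left_clip if self.strand == "+" else self.right_clip

    def clip_at_read_end(self) -> int:
        return self.right_clip if self.strand == "+" else self.left_clip


@dataclass
class ReadAlignmentGroup:
    read_id: str
    segments: list[AlignedSegment]
    assigned_sv: str | None = None
    allele_class: str = "unassigned"

    def sorted_by_read(self) -> list[AlignedSegment]:
        return sorted(self.segments, key=lambda s: s.read_interval[0])


@dataclass
class BreakpointCall:
    sv_id: str
    sv_type: str
    breakpoints: list[tuple[str, int, str]]  # (chrom, 1-based pos, confidence)
    sv_length: int | None
    genotype: str
    support: dict[str, int]
    inserted_consensus: str | None = None
    flags: list[str] = field(default_factory=list)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(text: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if not ops or "".join(f"{l}{o}" for o, l in ops) != text:
        raise AlignmentInputError(f"malformed CIGAR {text!r}")
    return ops


def _segment_from_fields(
    read_id: str,
    flag_reverse: bool,
    is_supp: bool,
    rname: str,
    pos0: int,
    cigar: Sequence[tuple[str, int]],
    seq: str | None,
    sa: str | None,
) -> AlignedSegment:
    left = cigar[0][1] if cigar and cigar[0][0] in "SH" else 0
    right = cigar[-1][1] if cigar and cigar[-1][0] in "SH" else 0
    read_len = sum(l for op, l in cigar if op in "MIS=XH")
    ref_len = sum(l for op, l in cigar if op in "MD=XN")
    strand = "-" if flag_reverse else "+"
    if strand == "+":
        read_iv = (left, read_len - right)
    else:
        read_iv = (right, read_len - left)
    links = []
    if sa:
        for chunk in sa.rstrip(";").split(";"):
            f = chunk.split(",")
            if len(f) >= 3:
                links.append((f[0], int(f[1]) - 1, f[2]))
    return AlignedSegment(
        read_id=read_id,
        ref_interval=GenomicInterval(rname, pos0, pos0 + ref_len),
        read_interval=read_iv,
        strand=strand,
        cigar=tuple(cigar),
        left_clip=left,
        right_clip=right,
        is_supplementary=is_supp,
        seq=seq,
        supplementary_links=tuple(links),
    )


def load_alignments(path: str | Path, dialect: str = "sam_bam") -> list[ReadAlignmentGroup]:
    """Load SAM/BAM (via pysam) or CIGAR-bearing PAF into per-read groups."""
    if dialect not in ("sam_bam", "paf"):
        raise AlignmentInputError(f"unknown dialect {dialect!r}")
    segments: dict[str, list[AlignedSegment]] = {}
    n_unmapped = 0
    if dialect == "sam_bam":
        import pysam

        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    n_unmapped += 1
                    continue
                cigar = parse_cigar(rec.cigarstring)
                sa = rec.get_tag("SA") if rec.has_tag("SA") else None
                seg = _segment_from_fields(
                    rec.query_name, rec.is_reverse, rec.is_supplementary,
                    rec.reference_name, rec.reference_start, cigar,
                    rec.query_sequence, sa,
                )
                segments.setdefault(rec.query_name, []).append(seg)
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise AlignmentInputError(f"line {lineno}: short PAF record")
                cg = next((x[5:] for x in f[12:] if x.startswith("cg:Z:")), None)
                if cg is None:
                    raise AlignmentInputError(f"line {lineno}: PAF record lacks cg tag")
                if f[5] == "*":
                    n_unmapped += 1
                    continue
                cigar = parse_cigar(cg)
                qlen, qstart, qend = int(f[1]), int(f[2]), int(f[3])
                strand = f[4]
                # reconstruct clips so the segment view matches SAM semantics
                if strand == "+":
                    cigar = [("S", qstart)] * (qstart > 0) + cigar + [("S", qlen - qend)] * (qlen - qend > 0)
                else:
                    cigar = [("S", qlen - qend)] * (qlen - qend > 0) + cigar + [("S", qstart)] * (qstart > 0)
                seg = _segment_from_fields(
                    f[0], strand == "-", False, f[5], int(f[7]), cigar, None, None
                )
                segments.setdefault(f[0], []).append(seg)
    groups = [ReadAlignmentGroup(rid, segs) for rid, segs in segments.items()]
    return groups


def assign_reads_to_targets(
    groups: Iterable[ReadAlignmentGroup],
    guide_sets: Mapping[str, GuideSet] | Sequence[GuideSet],
    tol: int = 100,
) -> list[ReadAlignmentGroup]:
    """Assign each read group to the SV whose designed cut it starts/ends at.

    A group is assigned when any segment boundary lies within ``tol`` of a
    designed cut coordinate; ties break by smallest boundary distance.
    Unassigned groups get ``assigned_sv=None`` (background).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if not isinstance(guide_sets, Mapping):
        guide_sets = {gs.sv_id: gs for gs in guide_sets}
    cuts = [
        (gs.sv_id, g.interval.chrom, g.cut_coord)
        for gs in guide_sets.values()
        for _, g in gs.guides
    ]
    out = []
    for group in groups:
        best: tuple[int, str] | None = None
        for seg in group.segments:
            for bound in (seg.ref_interval.start, seg.ref_interval.end):
                for sv_id, chrom, cut in cuts:
                    if chrom != seg.ref_interval.chrom:
                        continue
                    d = abs(bound - cut)
                    if d <= tol and (best is None or d < best[0]):
                        best = (d, sv_id)
        group.assigned_sv = best[1] if best else None
        out.append(group)
    return out


def _median_pos(values: Sequence[int]) -> int:
    """Median position, ties toward the smaller coordinate (lower median)."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _walk_cigar_deletions(seg: AlignedSegment, min_del: int) -> list[tuple[int, int]]:
    """(last aligned base, first aligned base after) 1-based, per D >= min_del."""
    pos = seg.ref_interval.start
    hits = []
    for op, ln in seg.cigar:
        if op in "M=X":
            pos += ln
        elif op in "DN":
            if ln >= min_del:
                hits.append((pos, pos + ln + 1))
            pos += ln
    return hits


def genotype_target(support: Mapping[str, int], config: CallConfig | None = None) -> str:
    """Presence/absence genotype from per-class read support (no allele balance)."""
    cfg = config or CallConfig()
    ref_ok = support.get("ref", 0) >= cfg.min_support
    alt_ok = support.get("alt", 0) >= cfg.min_support
    if ref_ok and alt_ok:
        return "het"
    if alt_ok:
        return "hom_alt"
    if ref_ok:
        return "hom_ref"
    return "no_call"


def _contiguous_ref_like(
    group: ReadAlignmentGroup, cut_lo: int, cut_hi: int, cfg: CallConfig
) -> bool:
    """Single contiguous segment matching the cutA..cutB reference expectation."""
    if len(group.segments) != 1:
        return False
    seg = group.segments[0]
    if any(op in "DN" and ln >= cfg.min_del for op, ln in seg.cigar):
        return False
    return (
        abs(seg.ref_interval.start - cut_lo) <= cfg.tol
        and abs(seg.ref_interval.end - cut_hi) <= cfg.tol
    )


def _n_run_in(reference: Mapping[str, GenomeSequence] | None, chrom: str,
              lo: int, hi: int, n_run: int) -> bool:
    if reference is None or chrom not in reference or hi <= lo:
        return False
    return "N" * n_run in reference[chrom].seq[max(0, lo):hi]


def call_deletion(
    groups: Sequence[ReadAlignmentGroup],
    sv,
    guide_set: GuideSet,
    config: CallConfig | None = None,
    reference: Mapping[str, GenomeSequence] | None = None,
) -> BreakpointCall:
    """Resolve a deletion: gapped/split alt reads vs contiguous ref reads."""
    cfg = config or CallConfig()
    mine = [g for g in groups if g.assigned_sv == guide_set.sv_id]
    cut_a = guide_set.by_role("flank_5p").cut_coord
    cut_b = guide_set.by_role("internal").cut_coord
    chrom = guide_set.by_role("flank_5p").interval.chrom
    bp5: list[int] = []
    bp3: list[int] = []
    low5 = low3 = 0
    n_alt = n_ref = 0
    for g in mine:
        evidence = False
        for seg in g.segments:
            for b5, b3 in _walk_cigar_deletions(seg, cfg.min_del):
                bp5.append(b5)
                bp3.append(b3)
                evidence = True
        if not evidence and len(g.segments) >= 2:
            segs = g.sorted_by_read()
            for s1, s2 in zip(segs, segs[1:]):
                if s1.strand != s2.strand or s1.ref_interval.chrom != s2.ref_interval.chrom:
                    continue
                # reference-space order is independent of sequencing orientation
                lo, hi = sorted((s1, s2), key=lambda s: s.ref_interval.start)
                gap = hi.ref_interval.start - lo.ref_interval.end
                # read bases between the aligned segments (aligned nowhere):
                # tolerated, but they blur the junction -> low confidence
                read_gap = s2.read_interval[0] - s1.read_interval[1]
                if gap - max(read_gap, 0) >= cfg.min_del:
                    bp5.append(lo.ref_interval.end)
                    bp3.append(hi.ref_interval.start + 1)
                    if read_gap > cfg.clip_tol:
                        low5 += 1
                        low3 += 1
                    elif read_gap > cfg.adj_tol:
                        low3 += 1
                    evidence = True
        if evidence:
            n_alt += 1
            g.allele_class = "alt-like"
        elif _contiguous_ref_like(g, cut_a, cut_b, cfg):
            n_ref += 1
            g.allele_class = "ref-like"
    support = {"ref": n_ref, "alt": n_alt}
    if n_alt < cfg.min_support and n_ref < cfg.min_support:
        return BreakpointCall(
            guide_set.sv_id, "deletion", [], None, "no_call", support
        )
    flags: list[str] = []
    breakpoints: list[tuple[str, int, str]] = []
    sv_length = None
    genotype = genotype_target(support, cfg)
    if n_alt >= cfg.min_support:
        p5, p3 = _median_pos(bp5), _median_pos(bp3)
        conf5 = "high" if low5 * 2 <= len(bp5) else "low"
        conf3 = "high" if low3 * 2 <= len(bp3) else "low"
        if _n_run_in(reference, chrom, p5, p3 - 1, cfg.n_run):
            flags.append("reference_N_gap")
            conf3 = "low" if low3 else conf3
        breakpoints = [(chrom, p5, conf5), (chrom, p3, conf3)]
        if conf5 == conf3 == "high":
            sv_length = p3 - p5 - 1
    return BreakpointCall(
        guide_set.sv_id, "deletion", breakpoints, sv_length, genotype, support,
        flags=flags,
    )


def clipped_consensus(
    tails: Sequence[str], cons_min: int = 2
) -> tuple[str, list[int]]:
    """Plurality consensus of clip-anchored tails with per-column support.

    Consensus length is the median tail length; per column the plurality
    base wins (ties lexicographic); columns covered by fewer than
    ``cons_min`` tails are emitted as N.  Returns (consensus, support).
    """
    if not tails:
        raise ValueError("no tails to build a consensus from")
    length = _median_pos([len(t) for t in tails])
    out = []
    support = []
    for i in range(length):
        counts: dict[str, int] = {}
        for t in tails:
            if i < len(t):
                counts[t[i]] = counts.get(t[i], 0) + 1
        coverage = sum(counts.values())
        if coverage < cons_min:
            out.append("N")
            support.append(coverage)
            continue
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out.append(best[0])
        support.append(best[1])
    return "".join(out), support


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    cigar: tuple[tuple[str, int], ...]
    identity: float


def local_align(
    query: str,
    target: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -4,
    gap_extend: int = -2,
) -> LocalAlignment:
    """Optimal local alignment with affine gaps (gap of length k costs
    ``|gap_open| + k*|gap_extend|``).  Returns score, the aligned
    intervals, a CIGAR, and identity = matches / alignment columns."""
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython charges open on the first gap base: open' = open + extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    score = aligner.score(query, target)
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), (), 0.0)
    aln = aligner.align(query, target)[0]
    q_blocks, t_blocks = aln.aligned
    matches = 0
    columns = 0
    cigar: list[tuple[str, int]] = []

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        if prev_q is not None:
            push("I", qs - prev_q)
            push("D", ts - prev_t)
            columns += (qs - prev_q) + (ts - prev_t)
        push("M", qe - qs)
        columns += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b)
        prev_q, prev_t = qe, te
    q_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    t_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    identity = matches / columns if columns else 0.0
    return LocalAlignment(float(score), q_iv, t_iv, tuple(cigar), identity)


def call_insertion(
    groups: Sequence[ReadAlignmentGroup],
    sv,
    guide_set: GuideSet,
    element_consensus: GenomeSequence | None = None,
    config: CallConfig | None = None,
) -> BreakpointCall:
    """Resolve an insertion from soft-clipped read tails.

    The breakpoint is the last aligned reference base before the clip
    (median over reads; the insertion is placed after it).  Right-clip
    tails (stored orientation = inserted sequence 5'->3') feed the
    consensus; when an element consensus is given the call is annotated
    ``element_confirmed`` if the tail consensus aligns locally at >=
    ``id_min`` identity over >= ``len_min`` bp (either orientation).
    """
    cfg = config or CallConfig()
    mine = [g for g in groups if g.assigned_sv == guide_set.sv_id]
    chrom = guide_set.by_role("flank_5p").interval.chrom
    positions: list[int] = []
    tails: list[str] = []
    n_alt = n_ref = 0
    cut_a = guide_set.by_role("flank_5p").cut_coord
    flank_cuts = sorted(
        g.cut_coord for role, g in guide_set.guides if role.startswith("flank")
    )
    for g in mine:
        clipped = False
        for seg in g.segments:
            if seg.ref_interval.chrom != chrom:
                continue
            if seg.right_clip >= cfg.min_clip:
                positions.append(seg.ref_interval.end)
                if seg.seq is not None:
                    tails.append(seg.seq[len(seg.seq) - seg.right_clip:])
                clipped = True
            elif seg.left_clip >= cfg.min_clip:
                positions.append(seg.ref_interval.start)
                clipped = True
        if clipped:
            n_alt += 1
            g.allele_class = "alt-like"
        elif len(flank_cuts) == 2 and _contiguous_ref_like(
            g, flank_cuts[0], flank_cuts[1], cfg
        ):
            n_ref += 1
            g.allele_class = "ref-like"
    support = {"ref": n_ref, "alt": n_alt}
    if n_alt < cfg.min_support:
        return BreakpointCall(guide_set.sv_id, "insertion", [], None, "no_call", support)
    bp = _median_pos(positions)
    consensus = None
    flags: list[str] = []
    if tails:
        consensus, _ = clipped_consensus(tails, cfg.cons_min)
    if consensus and element_consensus is not None:
        best = None
        probe = consensus.replace("N", "A") if consensus else ""
        for cand in (probe, reverse_complement(probe)):
            aln = local_align(cand, element_consensus.seq)
            if best is None or aln.score > best.score:
                best = aln
        span = best.query_interval[1] - best.query_interval[0]
        if best.identity >= cfg.id_min and span >= cfg.len_min:
            flags.append("element_confirmed")
    genotype = genotype_target(support, cfg)
    return BreakpointCall(
        guide_set.sv_id, "insertion", [(chrom, bp, "high")], None, genotype,
        support, inserted_consensus=consensus, flags=flags,
    )


def _junction_positions(s1: AlignedSegment, s2: AlignedSegment) -> tuple[int, int]:
    """1-based junction-side aligned-base positions of a read-ordered pair."""

    def at_read_end(seg: AlignedSegment) -> int:
        return seg.ref_interval.end if seg.strand == "+" else seg.ref_interval.start + 1

    def at_read_start(seg: AlignedSegment) -> int:
        return seg.ref_interval.start + 1 if seg.strand == "+" else seg.ref_interval.end

    return at_read_end(s1), at_read_start(s2)


def call_inversion(
    groups: Sequence[ReadAlignmentGroup],
    sv,
    guide_set: GuideSet,
    config: CallConfig | None = None,
) -> BreakpointCall:
    """Resolve an inversion from opposite-orientation dual alignments.

    Each supporting read carries a reference-orientation segment and an
    inverted-orientation segment; the two breakpoints are the
    junction-side boundaries of those segments (medians across reads).
    Extra opposite-strand placements — the signature of inverted-repeat
    similarity at the two junctions — raise ``inverted_repeat_ambiguity``
    and all placements are reported.
    """
    cfg = config or CallConfig()
    mine = [g for g in groups if g.assigned_sv == guide_set.sv_id]
    chrom = guide_set.by_role("flank_5p").interval.chrom
    bps_low: list[int] = []
    bps_high: list[int] = []
    extra_placements: list[tuple[str, int, str]] = []
    ambiguous = False
    n_alt = n_ref = 0
    for g in mine:
        segs = [s for s in g.sorted_by_read() if s.ref_interval.chrom == chrom]
        strands = {s.strand for s in segs}
        if len(segs) >= 2 and strands == {"+", "-"}:
            pair = None
            for s1, s2 in zip(segs, segs[1:]):
                if s1.strand != s2.strand:
                    gap = abs(s2.read_interval[0] - s1.read_interval[1])
                    if pair is None or gap < pair[0]:
                        pair = (gap, s1, s2)
            if pair is None:
                continue
            _, s1, s2 = pair
            b1, b2 = _junction_positions(s1, s2)
            bps_low.append(min(b1, b2))
            bps_high.append(max(b1, b2))
            n_alt += 1
            g.allele_class = "alt-like"
            leftover = [s for s in segs if s is not s1 and s is not s2]
            for s in leftover:
                if s.strand != s1.strand or s.strand != s2.strand:
                    ambiguous = True
                    pos = s.ref_interval.end if s.strand == "-" else s.ref_interval.start + 1
                    extra_placements.append((chrom, pos, "ambiguous"))
        elif len(segs) == 1 and segs[0].strand == "+":
            seg = segs[0]
            if (
                seg.left_clip <= cfg.clip_tol
                and seg.right_clip <= cfg.clip_tol
                and not any(op in "DN" and ln >= cfg.min_del for op, ln in seg.cigar)
            ):
                n_ref += 1
                g.allele_class = "ref-like"
    support = {"ref": n_ref, "alt": n_alt}
    if n_alt < cfg.min_support:
        return BreakpointCall(guide_set.sv_id, "inversion", [], None, "no_call", support)
    b_lo = _median_pos(bps_low)
    b_hi = _median_pos(bps_high)
    conf = "ambiguous" if ambiguous else "high"
    breakpoints = [(chrom, b_lo, conf), (chrom, b_hi, conf)]
    seen = set()
    for p in extra_placements:
        if p not in seen:
            breakpoints.append(p)
            seen.add(p)
    flags = ["inverted_repeat_ambiguity"] if ambiguous else []
    sv_length = (b_hi - b_lo) if not ambiguous else None
    return BreakpointCall(
        guide_set.sv_id, "inversion", breakpoints, sv_length,
        genotype_target(support, cfg), support, flags=flags,
    )


@dataclass
class InsertionLiftover:
    """Exact coordinate map between an original and an insertion-bearing sequence."""

    breakpoint: int  # 0-based inter-base insertion point
    insert_len: int

    def orig_to_mod(self, pos: int) -> int:
        return pos if pos <= self.breakpoint else pos + self.insert_len

    def mod_to_orig(self, pos: int) -> int | None:
        if pos <= self.breakpoint:
            return pos
        if pos < self.breakpoint + self.insert_len:
            return None  # inside inserted material
        return pos - self.insert_len


def build_custom_reference(
    reference: Mapping[str, GenomeSequence],
    chrom: str,
    breakpoint: int,
    insert_seq: str,
) -> tuple[dict[str, GenomeSequence], InsertionLiftover]:
    """Splice ``insert_seq`` immediately after 1-based ``breakpoint`` on ``chrom``.

    Returns the modified reference (other chromosomes unchanged) and an
    exact, invertible liftover.  Re-aligning insertion-supporting reads to
    this reference should yield contiguous signatures.
    """
    if chrom not in reference:
        raise KeyError(chrom)
    seq = reference[chrom].seq
    if not 0 < breakpoint <= len(seq):
        raise ValueError(f"breakpoint {breakpoint} outside [1, {len(seq)}]")
    modified = dict(reference)
    new_seq = seq[:breakpoint] + insert_seq + seq[breakpoint:]
    modified[chrom] = GenomeSequence(chrom, new_seq)
    return modified, InsertionLiftover(breakpoint, len(insert_seq))


def compute_target_coverage(
    groups: Sequence[ReadAlignmentGroup],
    guide_sets: Mapping[str, GuideSet] | Sequence[GuideSet],
) -> dict[str, dict[str, float]]:
    """Per-base depth over each target span (min cut .. max cut per SV).

    Returns per-target median/mean depth plus an overall ``_median`` entry
    (median of per-target medians).
    """
    import numpy as np

    if not isinstance(guide_sets, Mapping):
        guide_sets = {gs.sv_id: gs for gs in guide_sets}
    out: dict[str, dict[str, float]] = {}
    medians = []
    for sv_id, gs in guide_sets.items():
        ref_guides = [g for _, g in gs.guides if g.interval.chrom]
        chroms = {g.interval.chrom for _, g in gs.guides}
        chrom = gs.by_role("flank_5p").interval.chrom
        cuts = [g.cut_coord for role, g in gs.guides if g.interval.chrom == chrom]
        lo, hi = min(cuts), max(cuts)
        depth = np.zeros(hi - lo, dtype=np.int32)
        for g in groups:
            if g.assigned_sv != sv_id:
                continue
            for seg in g.segments:
                if seg.ref_interval.chrom != chrom:
                    continue
                a = max(lo, seg.ref_interval.start) - lo
                b = min(hi, seg.ref_interval.end) - lo
                if b > a:
                    depth[a:b] += 1
        med = float(np.median(depth)) if len(depth) else 0.0
        out[sv_id] = {"median": med, "mean": float(depth.mean()) if len(depth) else 0.0}
        medians.append(med)
    out["_median"] = {"median": float(np.median(medians)) if medians else 0.0,
                      "mean": float(np.mean(medians)) if medians else 0.0}
    return out
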