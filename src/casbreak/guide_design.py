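"""SpCas9 guide design for structural-variant targets.

Finds NGG protospacers, screens them for desk-scale usability (GC content,
homopolymers, exact-match uniqueness in the supplied reference), and
assembles the SV-class-specific guide geometries used by the targeted
enrichment assay:

* deletion — three guides acting as two pairs.  A 5'-anchor guide (A) is
  shared; with an internal guide (B) it produces a reference-allele
  fragment of known length, and with a 3'-flank guide (C) it spans the
  whole deletion so the deleted allele yields a shorter fragment carrying
  both breakpoints.
* insertion — either a 5'-flank guide plus a guide designed on a
  mobile-element consensus (cuts only inside element insertions), or a
  flank-flank pair when no consensus is available.
* inversion — a flank guide outside the 5' breakpoint and an internal
  guide near the 3' end; inversion relocates the internal cut next to the
  flank cut, producing a short diagnostic fragment only in the sample.

Also emits T7 in-vitro-transcription synthesis oligos for each guide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .config import DesignConfig
from .genome_io import GenomeSequence, GenomicInterval, reverse_complement
from .sv_catalog import SVRecord

SPACER_LEN = 20
PAM_LEN = 3
#: blunt SpCas9 cut, 3 nt 5' of the PAM (inter-base coordinate)
CUT_OFFSET = 3

T7_PROMOTER = "TTCTAATACGACTCACTATAG"
OVERLAP = "GTTTTAGAGCTAGA"
#: constant scaffold oligo shared by all guides (single sgRNA mix); the
#: literal ordered sequence is 79 nt long
SCAFFOLD_OLIGO = (
    "AAAGCACCGACTCGGTGCCACTTTTTCAAGTTGATAACGGACTAGCCTTATTTTAACTTGCTATTTCTAGCTCTAAAAC"
)

ROLES = ("flank_5p", "flank_3p", "internal", "element")


class DesignError(ValueError):
    """Raised when a guide set cannot be assembled for an SV."""


@dataclass(frozen=True)
class Protospacer:
    """One candidate SpCas9 target site.

    ``interval`` is the 20-bp protospacer footprint on the forward
    reference strand; ``spacer_seq`` is given in protospacer orientation
    (equal to the reference slice on '+', its reverse complement on '-').
    ``cut_coord`` is the 0-based inter-base blunt-cut position on the
    forward strand.
    """

    interval: GenomicInterval
    strand: str
    spacer_seq: str
    pam_seq: str
    cut_coord: int
    uniqueness_count: int = 0

    def __post_init__(self) -> None:
        if len(self.spacer_seq) != SPACER_LEN:
            raise ValueError("spacer must be 20 nt")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if len(self.pam_seq) != PAM_LEN or self.pam_seq[1:] != "GG":
            raise ValueError(f"PAM {self.pam_seq!r} does not match NGG")
        if "N" in self.spacer_seq:
            raise ValueError("spacer contains N")


@dataclass
class GuideSet:
    """Designed guides for one SV, keyed by role."""

    sv_id: str
    guides: list[tuple[str, Protospacer]]
    element_name: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        for role, _ in self.guides:
            if role not in ROLES:
                raise ValueError(f"invalid guide role {role!r}")
        cuts = [(g.interval.chrom, g.cut_coord) for _, g in self.guides]
        if len(cuts) != len(set(cuts)):
            raise ValueError(f"{self.sv_id}: duplicate cut coordinates in guide set")

    def by_role(self, role: str) -> Protospacer:
        for r, g in self.guides:
            if r == role:
                return g
        raise KeyError(f"{self.sv_id}: no guide with role {role!r}")

    def roles(self) -> list[str]:
        return [r for r, _ in self.guides]


@dataclass(frozen=True)
class OligoSet:
    """T7 synthesis oligos for one guide: 55-nt template + constant scaffold."""

    template_oligo: str
    scaffold_oligo: str = SCAFFOLD_OLIGO

    def __post_init__(self) -> None:
        if len(self.template_oligo) != 55:
            raise ValueError("template oligo must be exactly 55 nt")


def find_protospacers(seq: GenomeSequence, window: GenomicInterval) -> list[Protospacer]:
    """All SpCas9 sites (20-mer + NGG) on both strands within ``window``.

    Coordinates are absolute on ``seq``.  Spacers containing N are
    excluded; results are sorted by cut coordinate.
    """
    if window.chrom != seq.name:
        raise ValueError(f"window chrom {window.chrom!r} != sequence {seq.name!r}")
    if window.start < 0 or window.end > len(seq):
        raise ValueError(f"window {window} outside sequence of length {len(seq)}")
    if window.length() < SPACER_LEN + PAM_LEN:
        raise ValueError("window shorter than 23 nt")
    s = seq.seq
    hits: list[Protospacer] = []
    # forward: [i, i+20) spacer, PAM at [i+20, i+23) == NGG; cut at i+17
    for i in range(window.start, window.end - 22):
        if s[i + 21 : i + 23] == "GG":
            spacer = s[i : i + 20]
            if "N" in spacer:
                continue
            hits.append(
                Protospacer(
                    GenomicInterval(seq.name, i, i + 20), "+",
                    spacer, s[i + 20 : i + 23], cut_coord=i + 17,
                )
            )
    # reverse: forward context CCN at [j, j+3), spacer footprint [j+3, j+23);
    # protospacer-orientation cut 3 nt from the PAM-proximal end -> j+6
    for j in range(window.start, window.end - 22):
        if s[j : j + 2] == "CC":
            fwd_spacer = s[j + 3 : j + 23]
            if "N" in fwd_spacer:
                continue
            hits.append(
                Protospacer(
                    GenomicInterval(seq.name, j + 3, j + 23), "-",
                    reverse_complement(fwd_spacer),
                    reverse_complement(s[j : j + 3]),
                    cut_coord=j + 6,
                )
            )
    hits.sort(key=lambda p: (p.cut_coord, p.strand))
    return hits


def _count_occurrences(text: str, pattern: str) -> int:
    n = start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return n
        n += 1
        start = idx + 1


# one-entry cache of the 23-mer occurrence index, keyed by reference identity
_KMER_INDEX: dict = {}


def _reference_key(reference: Mapping[str, GenomeSequence]) -> tuple:
    return tuple((name, len(rec.seq), hash(rec.seq)) for name, rec in reference.items())


def _kmer_counts(reference: Mapping[str, GenomeSequence], k: int = SPACER_LEN + PAM_LEN) -> dict[str, int]:
    key = (_reference_key(reference), k)
    if key in _KMER_INDEX:
        return _KMER_INDEX[key]
    counts: dict[str, int] = {}
    for rec in reference.values():
        s = rec.seq
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            counts[km] = counts.get(km, 0) + 1
    _KMER_INDEX.clear()
    _KMER_INDEX[key] = counts
    return counts


def count_exact_matches(spacer_plus_pam: str, reference: Mapping[str, GenomeSequence]) -> int:
    """Exact occurrences of a 23-nt protospacer+PAM in the reference, both strands.

    Forward occurrences plus occurrences of the reverse complement (a
    '-'-strand site seen from the forward sequence); overlaps count.
    """
    if len(spacer_plus_pam) == SPACER_LEN + PAM_LEN:
        counts = _kmer_counts(reference)
        return counts.get(spacer_plus_pam, 0) + counts.get(
            reverse_complement(spacer_plus_pam), 0
        )
    rc = reverse_complement(spacer_plus_pam)
    total = 0
    for rec in reference.values():
        total += _count_occurrences(rec.seq, spacer_plus_pam)
        total += _count_occurrences(rec.seq, rc)
    return total


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def screen_guides(
    candidates: Sequence[Protospacer],
    reference: Mapping[str, GenomeSequence],
    config: DesignConfig | None = None,
) -> list[Protospacer]:
    """Keep unique, sequence-sane candidates (stable order).

    Filters: GC fraction within [gc_min, gc_max]; homopolymer run <=
    max_homopolymer; exactly one exact spacer+PAM match in the reference
    (both strands).  Mismatch-tolerant off-target scoring is out of scope.
    """
    if not candidates:
        raise ValueError("no candidates to screen")
    cfg = config or DesignConfig()
    kept = []
    for p in candidates:
        if not cfg.gc_min <= gc_fraction(p.spacer_seq) <= cfg.gc_max:
            continue
        if max_homopolymer_run(p.spacer_seq) > cfg.max_homopolymer:
            continue
        count = count_exact_matches(p.spacer_seq + p.pam_seq, reference)
        if count != 1:
            continue
        kept.append(replace(p, uniqueness_count=count))
    return kept


_N_POS_CACHE: dict = {}


def _n_positions(seq: str) -> list[int]:
    key = (len(seq), hash(seq))
    if key not in _N_POS_CACHE:
        _N_POS_CACHE.clear()
        _N_POS_CACHE[key] = [i for i, c in enumerate(seq) if c == "N"]
    return _N_POS_CACHE[key]


def _distance_to_n(seq: str, cut: int) -> int:
    import bisect

    npos = _n_positions(seq)
    if not npos:
        return len(seq)
    i = bisect.bisect_left(npos, cut)
    best = len(seq)
    if i > 0:
        best = min(best, cut - npos[i - 1])
    if i < len(npos):
        best = min(best, npos[i] - cut)
    return best


def _pick(
    candidates: Sequence[Protospacer],
    objective,
    seq: GenomeSequence,
) -> Protospacer:
    """Minimize ``objective(cut)``; ties -> larger distance-to-N, then leftmost."""
    return min(
        candidates,
        key=lambda p: (
            objective(p.cut_coord),
            -_distance_to_n(seq.seq, p.cut_coord),
            p.cut_coord,
        ),
    )


def _best_pair(
    first: Sequence[Protospacer],
    second: Sequence[Protospacer],
    target: int,
    seq: GenomeSequence,
    length_of,
) -> tuple[Protospacer | None, Protospacer | None]:
    """Pair minimizing |length_of(a, b) - target| over valid orderings.

    Ties break by larger distance-to-N of both cuts, then leftmost cuts.
    Only pairs with b downstream of a (positive length) are considered.
    """
    import bisect

    second_sorted = sorted(second, key=lambda p: p.cut_coord)
    cuts = [p.cut_coord for p in second_sorted]
    best = None
    for a in first:
        # only the few b's whose implied length brackets the target matter
        ideal = a.cut_coord + target
        i = bisect.bisect_left(cuts, ideal)
        for b in second_sorted[max(0, i - 2) : i + 2]:
            ln = length_of(a, b)
            if ln <= 0:
                continue
            key = (
                abs(ln - target),
                -min(
                    _distance_to_n(seq.seq, a.cut_coord),
                    _distance_to_n(seq.seq, b.cut_coord),
                ),
                a.cut_coord,
                b.cut_coord,
            )
            if best is None or key < best[0]:
                best = (key, a, b)
    if best is None:
        return None, None
    return best[1], best[2]


def _window_candidates(
    seq: GenomeSequence,
    reference: Mapping[str, GenomeSequence],
    lo: int,
    hi: int,
    cfg: DesignConfig,
    role: str,
    sv_id: str,
) -> list[Protospacer]:
    lo = max(0, lo)
    hi = min(len(seq), hi)
    if hi - lo < SPACER_LEN + PAM_LEN:
        raise DesignError(f"{sv_id}/{role}: anchor window [{lo},{hi}) too small")
    sites = find_protospacers(seq, GenomicInterval(seq.name, lo, hi))
    sites = [p for p in sites if lo <= p.cut_coord <= hi]
    if not sites:
        raise DesignError(f"{sv_id}/{role}: no protospacer in window [{lo},{hi})")
    screened = screen_guides(sites, reference, cfg)
    if not screened:
        raise DesignError(f"{sv_id}/{role}: all candidates in [{lo},{hi}) failed screening")
    return screened


def design_deletion_guides(
    sv: SVRecord,
    reference: Mapping[str, GenomeSequence],
    config: DesignConfig | None = None,
) -> GuideSet:
    """Three guides, two pairs, for a deletion call.

    Guide A (flank_5p) anchors in [start - w_out, start + w_in]; guide B
    (internal) cuts inside the SV interval so that the A-B reference-allele
    fragment is closest to ``ref_fragment_target``; guide C (flank_3p)
    cuts in [end, end + w_out] with the A-C span within ``max_fragment``
    when PCR mode is on.  A is shared by both pairs.
    """
    if sv.sv_type != "deletion":
        raise ValueError(f"{sv.sv_id}: not a deletion")
    cfg = config or DesignConfig()
    seq = reference[sv.interval.chrom]
    start, end = sv.interval.start, sv.interval.end

    cand_a = _window_candidates(
        seq, reference, start - cfg.w_out, start + cfg.w_in, cfg, "flank_5p", sv.sv_id
    )
    # joint choice of (A, B): reference-allele fragment closest to target
    # the internal cut must sit clear of the optical interval's edge
    # uncertainty so it falls inside the truly deleted span (only then does
    # the deleted allele escape it and yield the spanning A-C fragment)
    b_margin = min(cfg.w_in, (end - start) // 2)
    cand_b = _window_candidates(
        seq, reference, start + b_margin, end, cfg, "internal", sv.sv_id
    )
    guide_a, guide_b = _best_pair(
        cand_a, cand_b, cfg.ref_fragment_target, seq,
        lambda a, b: b.cut_coord - a.cut_coord,
    )
    if guide_a is None:
        raise DesignError(f"{sv.sv_id}/internal: no feasible A-B pair")

    cand_c = _window_candidates(seq, reference, end, end + cfg.w_out, cfg, "flank_3p", sv.sv_id)
    if cfg.pcr_mode:
        max_span = cfg.max_fragment
        cand_c = [c for c in cand_c if c.cut_coord - guide_a.cut_coord <= max_span]
        if not cand_c:
            raise DesignError(
                f"{sv.sv_id}/flank_3p: spanning fragment exceeds max_fragment "
                f"{cfg.max_fragment} under PCR mode"
            )
    guide_c = _pick(cand_c, lambda c: c, seq)  # leftmost feasible: smallest span
    ref_frag = guide_b.cut_coord - guide_a.cut_coord
    span = guide_c.cut_coord - guide_a.cut_coord
    if cfg.pcr_mode and ref_frag < cfg.min_fragment:
        raise DesignError(f"{sv.sv_id}: reference-allele fragment {ref_frag} < min_fragment")
    return GuideSet(
        sv.sv_id,
        [("flank_5p", guide_a), ("internal", guide_b), ("flank_3p", guide_c)],
        notes=f"ref_pair={ref_frag}bp span_pair={span}bp",
    )


def design_insertion_guides(
    sv: SVRecord,
    reference: Mapping[str, GenomeSequence],
    element_consensus: GenomeSequence | None = None,
    config: DesignConfig | None = None,
) -> GuideSet:
    """Flank + element-consensus guides, or a flank pair without consensus.

    With a consensus, the element guide's cut position on the reference is
    undefined; its recorded coordinates are offsets on the consensus
    sequence.  Without a consensus, the expected mutant fragment is the
    reference span plus the estimated inserted length and must respect
    ``max_fragment`` in PCR mode.
    """
    if sv.sv_type != "insertion":
        raise ValueError(f"{sv.sv_id}: not an insertion")
    cfg = config or DesignConfig()
    seq = reference[sv.interval.chrom]
    start, end = sv.interval.start, sv.interval.end

    if element_consensus is not None:
        if len(element_consensus) < SPACER_LEN + PAM_LEN:
            raise DesignError(f"{sv.sv_id}: element consensus shorter than 23 nt")
        flank = _window_candidates(
            seq, reference, start - cfg.w_out, start, cfg, "flank_5p", sv.sv_id
        )
        guide_a = _pick(flank, lambda c: start - c, seq)  # closest upstream cut
        elem_sites = find_protospacers(
            element_consensus,
            GenomicInterval(element_consensus.name, 0, len(element_consensus)),
        )
        elem_sites = [
            p for p in elem_sites
            if cfg.gc_min <= gc_fraction(p.spacer_seq) <= cfg.gc_max
            and max_homopolymer_run(p.spacer_seq) <= cfg.max_homopolymer
            # must not cut the reference itself: element-only specificity
            and count_exact_matches(p.spacer_seq + p.pam_seq, reference) == 0
        ]
        if not elem_sites:
            raise DesignError(f"{sv.sv_id}/element: no usable site on consensus")
        budget = cfg.max_fragment - (start - guide_a.cut_coord) if cfg.pcr_mode else None
        if budget is not None:
            elem_sites = [p for p in elem_sites if p.cut_coord <= budget]
            if not elem_sites:
                raise DesignError(f"{sv.sv_id}/element: fragment exceeds max_fragment")
        # deepest cut into the element maximizes recovered inserted sequence
        guide_e = max(elem_sites, key=lambda p: p.cut_coord)
        return GuideSet(
            sv.sv_id,
            [("flank_5p", guide_a), ("element", guide_e)],
            element_name=element_consensus.name,
            notes=f"element_cut_offset={guide_e.cut_coord}bp",
        )

    # flank-only mode
    expected_min = sv.size_estimate
    if cfg.pcr_mode and expected_min > cfg.max_fragment:
        raise DesignError(
            f"{sv.sv_id}: insertion of ~{sv.size_estimate} bp cannot fit a "
            f"{cfg.max_fragment} bp PCR fragment in flank-only mode"
        )
    cand_a = _window_candidates(seq, reference, start - cfg.w_out, start, cfg, "flank_5p", sv.sv_id)
    cand_c = _window_candidates(seq, reference, end, end + cfg.w_out, cfg, "flank_3p", sv.sv_id)
    guide_a = _pick(cand_a, lambda c: start - c, seq)
    guide_c = _pick(cand_c, lambda c: c - end, seq)
    mutant = (guide_c.cut_coord - guide_a.cut_coord) + sv.size_estimate
    if cfg.pcr_mode and mutant > cfg.max_fragment:
        raise DesignError(f"{sv.sv_id}: expected mutant fragment {mutant} > max_fragment")
    return GuideSet(
        sv.sv_id,
        [("flank_5p", guide_a), ("flank_3p", guide_c)],
        notes=f"expected_mutant={mutant}bp",
    )


def design_inversion_guides(
    sv: SVRecord,
    reference: Mapping[str, GenomeSequence],
    config: DesignConfig | None = None,
) -> GuideSet:
    """Flank guide before the inversion + internal guide near its 3' end.

    In the inverted sample the internal cut moves next to the flank cut,
    so the diagnostic fragment length is (start - f) + (end - p); the pair
    is chosen to bring it closest to ``inv_fragment_target``.
    """
    if sv.sv_type != "inversion":
        raise ValueError(f"{sv.sv_id}: not an inversion")
    cfg = config or DesignConfig()
    seq = reference[sv.interval.chrom]
    start, end = sv.interval.start, sv.interval.end

    cand_f = _window_candidates(seq, reference, start - cfg.w_out, start, cfg, "flank_5p", sv.sv_id)
    # keep the internal cut clear of the 3' optical-edge uncertainty so it
    # truly lies inside the inverted span
    p_margin = min(cfg.w_in, (end - start) // 2, cfg.internal_window - 1)
    cand_p = _window_candidates(
        seq, reference, max(start, end - cfg.internal_window), end - p_margin,
        cfg, "internal", sv.sv_id,
    )
    best: tuple | None = None
    for f in cand_f:
        flank_part = start - f.cut_coord
        p = _pick(
            cand_p,
            lambda c, fp=flank_part: abs((fp + (end - c)) - cfg.inv_fragment_target),
            seq,
        )
        frag = flank_part + (end - p.cut_coord)
        if cfg.pcr_mode and not (cfg.min_fragment <= frag <= cfg.max_fragment):
            continue
        score = abs(frag - cfg.inv_fragment_target)
        if best is None or score < best[0]:
            best = (score, f, p, frag)
    if best is None:
        raise DesignError(f"{sv.sv_id}: no feasible flank/internal pair under fragment bounds")
    _, guide_f, guide_p, frag = best
    return GuideSet(
        sv.sv_id,
        [("flank_5p", guide_f), ("internal", guide_p)],
        notes=f"expected_fragment={frag}bp",
    )


def emit_synthesis_oligos(guide: Protospacer | str) -> OligoSet:
    """55-nt T7 template oligo (promoter + spacer + overlap) for one guide.

    The scaffold oligo is a single constant shared by every guide in the
    one-pot sgRNA transcription mix; its 3' end is the reverse complement
    of the template overlap so the two hybridize for Klenow extension.
    """
    spacer = guide.spacer_seq if isinstance(guide, Protospacer) else guide
    if len(spacer) != SPACER_LEN:
        raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(spacer)}")
    return OligoSet(template_oligo=T7_PROMOTER + spacer + OVERLAP)


def write_guide_panel(
    guide_sets: Iterable[GuideSet], path: str | Path
) -> None:
    """Guide panel TSV: one row per guide, cut coordinates 1-based."""
    with open(path, "w", newline="\n") as fh:
        fh.write("sv_id\trole\tchrom\tcut_1based\tstrand\tspacer\tpam\tuniqueness\n")
        for gs in guide_sets:
            for role, g in gs.guides:
                fh.write(
                    f"{gs.sv_id}\t{role}\t{g.interval.chrom}\t{g.cut_coord + 1}\t"
                    f"{g.strand}\t{g.spacer_seq}\t{g.pam_seq}\t{g.uniqueness_count}\n"
                )


def write_oligo_sheet(guide_sets: Iterable[GuideSet], path: str | Path) -> None:
    """Synthesis-oligo TSV (template per guide + one shared scaffold row)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("name\tsequence\tlength\n")
        for gs in guide_sets:
            for role, g in gs.guides:
                o = emit_synthesis_oligos(g)
                fh.write(f"{gs.sv_id}_{role}_template\t{o.template_oligo}\t55\n")
        fh.write(f"scaffold_shared\t{SCAFFOLD_OLIGO}\t{len(SCAFFOLD_OLIGO)}\n")
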