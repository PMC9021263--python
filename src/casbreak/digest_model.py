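"""In-silico Cas9 digestion and per-allele expected-fragment prediction.

Given a guide set for one SV, predicts the fragments the single-tube
cleavage reaction should release from each allele, the alignment signature
those fragments must show once sequenced and mapped back to the reference
(contiguous / gapped / clipped-tail / inverted-dual), and the fraction of
the genome the whole panel targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .config import DigestConfig
from .genome_io import GenomeSequence, GenomicInterval
from .guide_design import GuideSet
from .sv_catalog import SVRecord

SIGNATURES = ("contiguous", "gapped_two_segment", "clipped_tail", "inverted_dual")


@dataclass(frozen=True)
class CutSite:
    """One designed blunt cut (0-based inter-base coordinate)."""

    seq_name: str
    coord: int
    guide_role: str = ""
    sv_id: str = ""

    def validate_against(self, seq: GenomeSequence) -> None:
        if not 0 < self.coord < len(seq):
            raise ValueError(
                f"cut {self.seq_name}:{self.coord} outside (0, {len(seq)})"
            )


@dataclass(frozen=True)
class ExpectedFragment:
    """Predicted Cas9 fragment for one allele of one SV.

    ``length`` is None when the fragment length cannot be known before
    sequencing (deleted allele with unknown true deletion length);
    ``length_bound`` then carries the spanning upper bound.
    """

    sv_id: str
    allele: str  # "ref" | "alt"
    length: int | None
    segments: tuple[tuple[str, int], ...]
    signature: str
    length_bound: int | None = None

    def __post_init__(self) -> None:
        if self.allele not in ("ref", "alt"):
            raise ValueError("allele must be ref or alt")
        if self.signature not in SIGNATURES:
            raise ValueError(f"unknown signature {self.signature!r}")
        if self.length is not None:
            seg_sum = sum(l for _, l in self.segments)
            if seg_sum != self.length:
                raise ValueError(
                    f"{self.sv_id}/{self.allele}: segments sum {seg_sum} != length {self.length}"
                )

    def effective_length(self) -> int:
        """Numeric length when known, else the spanning upper bound."""
        if self.length is not None:
            return self.length
        if self.length_bound is not None:
            return self.length_bound
        raise ValueError(f"{self.sv_id}/{self.allele}: no length information")


def cut_sites_from_guides(guide_set: GuideSet) -> list[CutSite]:
    """Designed cut sites of one guide set as :class:`CutSite` records."""
    return [
        CutSite(g.interval.chrom, g.cut_coord, guide_role=role, sv_id=guide_set.sv_id)
        for role, g in guide_set.guides
    ]


def digest_sequence(
    seq: GenomeSequence, cuts: Sequence[CutSite | int]
) -> list[tuple[GenomicInterval, str]]:
    """Cut a sequence at blunt inter-base coordinates: n cuts -> n+1 fragments.

    Duplicate coordinates collapse; cuts at 0 or at the sequence end are
    rejected (no zero-length fragments; circular molecules unsupported).
    Fragment sequences concatenate exactly to the input.
    """
    coords = sorted({c.coord if isinstance(c, CutSite) else int(c) for c in cuts})
    for c in coords:
        if not 0 < c < len(seq):
            raise ValueError(f"cut at {c} outside (0, {len(seq)})")
    bounds = [0, *coords, len(seq)]
    return [
        (GenomicInterval(seq.name, a, b), seq.seq[a:b])
        for a, b in zip(bounds, bounds[1:])
    ]


def predict_fragments(
    sv: SVRecord, guides: GuideSet, config: DigestConfig | None = None
) -> list[ExpectedFragment]:
    """Per-allele expected fragments and alignment signatures for one SV."""
    cfg = config or DigestConfig()
    roles = set(guides.roles())
    out: list[ExpectedFragment] = []

    if sv.sv_type == "deletion":
        if not {"flank_5p", "internal", "flank_3p"} <= roles:
            raise ValueError(f"{sv.sv_id}: deletion needs flank_5p/internal/flank_3p")
        cut_a = guides.by_role("flank_5p").cut_coord
        cut_b = guides.by_role("internal").cut_coord
        cut_c = guides.by_role("flank_3p").cut_coord
        ref_len = cut_b - cut_a
        out.append(
            ExpectedFragment(
                sv.sv_id, "ref", ref_len, (("flank", ref_len),), "contiguous"
            )
        )
        # true deleted length unknown pre-sequencing: bounded symbolic value
        span = cut_c - cut_a
        out.append(
            ExpectedFragment(
                sv.sv_id, "alt", None,
                (("flank", max(0, sv.interval.start - cut_a)),
                 ("flank", max(0, cut_c - sv.interval.end))),
                "gapped_two_segment",
                length_bound=span - cfg.min_del,
            )
        )
        return out

    if sv.sv_type == "insertion":
        cut_a = guides.by_role("flank_5p").cut_coord
        breakpoint = sv.interval.start
        if "element" in roles:
            elem = guides.by_role("element")
            flank_len = breakpoint - cut_a
            alt_len = flank_len + elem.cut_coord
            out.append(
                ExpectedFragment(
                    sv.sv_id, "alt", alt_len,
                    (("flank", flank_len), ("inserted", elem.cut_coord)),
                    "clipped_tail",
                )
            )
            return out
        if "flank_3p" not in roles:
            raise ValueError(f"{sv.sv_id}: insertion needs element or flank_3p guide")
        cut_c = guides.by_role("flank_3p").cut_coord
        span = cut_c - cut_a
        out.append(
            ExpectedFragment(sv.sv_id, "ref", span, (("flank", span),), "contiguous")
        )
        alt_len = span + sv.size_estimate
        out.append(
            ExpectedFragment(
                sv.sv_id, "alt", alt_len,
                (("flank", breakpoint - cut_a),
                 ("inserted", sv.size_estimate),
                 ("flank", cut_c - breakpoint)),
                "clipped_tail",
            )
        )
        return out

    if sv.sv_type == "inversion":
        if not {"flank_5p", "internal"} <= roles:
            raise ValueError(f"{sv.sv_id}: inversion needs flank_5p and internal guides")
        f = guides.by_role("flank_5p").cut_coord
        p = guides.by_role("internal").cut_coord
        flank_len = sv.interval.start - f
        inv_len = sv.interval.end - p
        out.append(
            ExpectedFragment(
                sv.sv_id, "alt", flank_len + inv_len,
                (("flank", flank_len), ("inverted", inv_len)),
                "inverted_dual",
            )
        )
        return out

    raise ValueError(f"{sv.sv_id}: no fragment model for sv_type {sv.sv_type!r}")


def guide_pair_extent(sv: SVRecord, guides: GuideSet) -> int:
    """Largest physical fragment (bp) any pair of the guide set can release.

    This is the quantity the PCR-enrichment limit constrains: for
    deletions the spanning A-C distance, for flank-pair insertions the
    span plus the estimated inserted length, for element-mode insertions
    and inversions the predicted sample fragment.
    """
    roles = set(guides.roles())
    if sv.sv_type == "deletion":
        a = guides.by_role("flank_5p").cut_coord
        return max(
            guides.by_role("internal").cut_coord - a,
            guides.by_role("flank_3p").cut_coord - a,
        )
    if sv.sv_type == "insertion":
        a = guides.by_role("flank_5p").cut_coord
        if "element" in roles:
            return (sv.interval.start - a) + guides.by_role("element").cut_coord
        return (guides.by_role("flank_3p").cut_coord - a) + sv.size_estimate
    if sv.sv_type == "inversion":
        f = guides.by_role("flank_5p").cut_coord
        p = guides.by_role("internal").cut_coord
        return (sv.interval.start - f) + (sv.interval.end - p)
    raise ValueError(f"{sv.sv_id}: no extent model for {sv.sv_type!r}")


def target_fraction(fragments: Iterable[ExpectedFragment], genome_size: int) -> float:
    """Fraction of the genome covered by the targeted fragment panel."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return sum(f.effective_length() for f in fragments) / genome_size


@dataclass(frozen=True)
class SignatureExpectation:
    """What the aligned reads of one expected fragment must look like."""

    signature: str
    #: (kind, length) where kind in {aligned, gap, clipped, inverted_aligned}
    parts: tuple[tuple[str, int | None], ...]
    description: str


def alignment_signature(fragment: ExpectedFragment) -> SignatureExpectation:
    """Expand a fragment's signature into per-segment alignment expectations."""
    segs = fragment.segments
    if fragment.signature == "contiguous":
        return SignatureExpectation(
            "contiguous",
            ((("aligned"), fragment.length),),
            "single full-length reference match between the two cut sites",
        )
    if fragment.signature == "gapped_two_segment":
        five = segs[0][1] if segs else None
        three = segs[1][1] if len(segs) > 1 else None
        return SignatureExpectation(
            "gapped_two_segment",
            (("aligned", five), ("gap", None), ("aligned", three)),
            "5'-aligned segment, reference gap over the deleted span, 3'-aligned segment",
        )
    if fragment.signature == "clipped_tail":
        aligned = segs[0][1] if segs else None
        clipped = sum(l for label, l in segs[1:]) if len(segs) > 1 else None
        return SignatureExpectation(
            "clipped_tail",
            (("aligned", aligned), ("clipped", clipped)),
            "aligned prefix ending at the insertion breakpoint, soft-clipped inserted tail",
        )
    if fragment.signature == "inverted_dual":
        flank = segs[0][1] if segs else None
        inv = segs[1][1] if len(segs) > 1 else None
        return SignatureExpectation(
            "inverted_dual",
            (("aligned", flank), ("inverted_aligned", inv)),
            "reference-orientation flank segment plus inverted-orientation segment "
            "anchored at the opposite breakpoint",
        )
    raise ValueError(f"unknown signature {fragment.signature!r}")


def write_fragment_table(
    fragments: Iterable[ExpectedFragment], path: str | Path
) -> None:
    """Expected-fragment TSV (lengths in bp; symbolic lengths as <=bound)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("sv_id\tallele\tlength\tsignature\tsegments\n")
        for f in fragments:
            length = str(f.length) if f.length is not None else f"<={f.length_bound}"
            segs = ",".join(f"{label}:{l}" for label, l in f.segments)
            fh.write(f"{f.sv_id}\t{f.allele}\t{length}\t{f.signature}\t{segs}\n")
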