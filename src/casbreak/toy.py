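"""Bundled synthetic test world: a 200 kbp genome with one SV of each class.

Everything is generated programmatically from a seed — no data files.  The
world mirrors the situations the assay is designed for:

* a heterozygous 13.2 kbp deletion whose optical-map interval over-extends
  the true breakpoints by 3 kbp on each side (label-resolution error, the
  reason flanking guides may legitimately sit inside the optical interval);
* a homozygous 6 kbp mobile-element insertion described in the catalog
  only as a locus plus an estimated inserted length, with a synthetic
  element consensus supplied separately (the consensus-guide situation);
* a homozygous 40 kbp inversion with +-500 bp optical edge error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeSequence, GenomicInterval
from .sim_reads import AppliedSV
from .sv_catalog import SVCatalog, SVRecord

TOY_CHROM = "chr_t"
TOY_LENGTH = 200_000

# truth geometry (0-based internal coordinates)
DEL_TRUTH = (30_000, 43_200)      # het, 13.2 kbp
INS_TRUTH_BP = 95_000             # hom, 6 kbp element inserted at this point
INS_LEN = 6_000
INV_TRUTH = (120_000, 160_000)    # hom, 40 kbp

# optical-map view (edges deliberately offset from truth)
DEL_OPTICAL = (27_000, 46_200)
INS_OPTICAL = (94_400, 95_600)
INV_OPTICAL = (119_500, 160_500)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@dataclass
class ToyWorld:
    reference: dict[str, GenomeSequence]
    element: GenomeSequence
    catalog: SVCatalog
    truth_svs: list[AppliedSV]


def make_feasibility_world(seed: int = 7) -> tuple[dict[str, GenomeSequence], SVCatalog]:
    """A 200 kbp reference with candidate SVs spanning 1-60 kbp.

    Used to probe the PCR-mode feasibility filter: targets whose guide-pair
    fragments would exceed the enrichment limit must be rejected at the
    design stage.  Catalog intervals may overlap; each record is designed
    independently.
    """
    rng = np.random.default_rng(seed)
    reference = {TOY_CHROM: GenomeSequence(TOY_CHROM, random_sequence(TOY_LENGTH, rng))}
    spans_kb = [1, 2, 5, 8, 12, 16, 20, 24, 28, 35, 45, 60]
    records: list[SVRecord] = []
    for i, kb in enumerate(spans_kb):
        span = kb * 1000
        start = int(rng.integers(10_000, TOY_LENGTH - span - 10_000))
        records.append(
            SVRecord(f"del_{kb}k", GenomicInterval(TOY_CHROM, start, start + span),
                     "deletion")
        )
        start = int(rng.integers(10_000, TOY_LENGTH - span - 10_000))
        records.append(
            SVRecord(f"inv_{kb}k", GenomicInterval(TOY_CHROM, start, start + span),
                     "inversion")
        )
        pos = int(rng.integers(10_000, TOY_LENGTH - 10_000))
        records.append(
            SVRecord(f"ins_{kb}k", GenomicInterval(TOY_CHROM, pos, pos + 1),
                     "insertion", size_estimate=span)
        )
    return reference, SVCatalog(records, reference_name=TOY_CHROM)


def make_toy_world(seed: int = 1234) -> ToyWorld:
    """Build the bundled toy reference, SV catalog, truth SVs and element."""
    rng = np.random.default_rng(seed)
    ref_seq = random_sequence(TOY_LENGTH, rng)
    reference = {TOY_CHROM: GenomeSequence(TOY_CHROM, ref_seq)}
    element = GenomeSequence("EL1_consensus", random_sequence(INS_LEN, rng))

    catalog = SVCatalog(
        [
            SVRecord("del1", GenomicInterval(TOY_CHROM, *DEL_OPTICAL), "deletion",
                     zygosity="het"),
            SVRecord("ins1", GenomicInterval(TOY_CHROM, *INS_OPTICAL), "insertion",
                     size_estimate=INS_LEN, zygosity="hom"),
            SVRecord("inv1", GenomicInterval(TOY_CHROM, *INV_OPTICAL), "inversion",
                     zygosity="hom"),
        ],
        reference_name=TOY_CHROM,
    )
    truth = [
        AppliedSV("del1", "deletion", GenomicInterval(TOY_CHROM, *DEL_TRUTH),
                  zygosity="het"),
        AppliedSV("ins1", "insertion",
                  GenomicInterval(TOY_CHROM, INS_TRUTH_BP, INS_TRUTH_BP + 1),
                  inserted_seq=element.seq, zygosity="hom"),
        AppliedSV("inv1", "inversion", GenomicInterval(TOY_CHROM, *INV_TRUTH),
                  zygosity="hom"),
    ]
    return ToyWorld(reference, element, catalog, truth)
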