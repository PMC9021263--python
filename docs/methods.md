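# Methods

## Problem and model

Optical genome mapping reports structural variants as intervals with a
type and sometimes a zygosity, at label resolution (kilobases). To resolve
a *chosen subset* of those SVs to base precision, a Cas9-targeted
enrichment assay is modelled: guide RNAs direct Cas9 to cut just outside
(and, where informative, inside) each SV locus; the freshly cut ends are
the only ones competent for adapter ligation after end blocking; the
ligated fragments are PCR-amplified and nanopore-sequenced; breakpoints
are then read off the alignment signatures of the targeted reads.

`casbreak` implements the desk side of this assay end to end — design,
prediction, simulation, and calling — with the wet-lab chemistry reduced
to simulator parameters (on-target fraction, per-target read counts,
error rates).

### Coordinate conventions

Internally every interval is 0-based half-open; every user-facing number
is 1-based inclusive, converted at exactly one point
(`genome_io.to_report_coords`). Cut sites are 0-based *inter-base*
coordinates: the blunt SpCas9 cut 3 nt 5′ of the NGG PAM in protospacer
orientation (forward-strand PAM at `p`: cut `p-3`; reverse site with
forward CCN context at `j`: cut `j+6`).

Breakpoint conventions (all 1-based):

- deletion: 5′ breakpoint = last retained base before the gap, 3′
  breakpoint = first retained base after it;
- insertion: the last reference base before the inserted sequence
  (VCF-compatible; the insertion is placed after it);
- inversion: last base before the inverted block, and last base of the
  inverted block.

## Guide design

Protospacer search is exhaustive (every 20-mer + NGG on both strands,
N-containing spacers excluded) and is cross-checked against a brute-force
scan in the tests. Screening keeps guides with GC in [0.25, 0.75],
homopolymer runs ≤ 5, and exactly one exact spacer+PAM match in the
supplied reference (both strands, counted via a cached 23-mer index).
Mismatch-tolerant off-target scoring is deliberately out of scope: the
screen is exact-match uniqueness at desk scale, a documented limitation.

Class geometries and the parameters that matter (defaults in
`config.DesignConfig`):

- `w_out` = 5000 bp: how far outside the optical interval flanking guides
  may sit; `w_in` = 4000 bp: how far *inside* the optical interval a
  "flanking" cut may sit, because optical intervals over-extend past true
  breakpoints by up to the label resolution. For the same reason the
  deletion-internal and inversion-internal guides are required to sit at
  least `min(w_in, span/2)` inside the optical edge, so they fall within
  the truly rearranged span.
- `ref_fragment_target` = 3500 bp and `inv_fragment_target` = 6500 bp:
  the preferred diagnostic fragment lengths; among feasible candidates the
  pair minimizing |achieved − target| is chosen, ties broken by larger
  distance-to-N, then leftmost coordinate. The targets are sized for
  efficient PCR and unambiguous length readout.
- `min_fragment` = 1000, `max_fragment` = 30000 bp, enforced only in PCR
  mode: PCR enrichment caps usable fragment sizes at under ~30 kbp;
  without PCR the bounds are lifted and larger SVs become targetable at
  higher input-DNA cost.

For deletions the spanning constraint applies to the A–C cut distance; an
SV whose geometry cannot satisfy it raises a design error naming the
failing role, and the pipeline records the SV as skipped rather than
silently shrinking windows.

Synthesis oligos follow the one-pot T7 transcription scheme: a 55-nt
template (21-nt T7 promoter + 20-nt spacer + 14-nt overlap) per guide and
one constant scaffold oligo whose 3′ end is the reverse complement of the
overlap. The scaffold constant is stored verbatim as printed in the
protocol source; its literal length is 79 nt even though it is described
as an 80-mer there, and the discrepancy is preserved, not resolved.

## Expected fragments

`digest_model` predicts per-allele fragments from the cut geometry. For
deletions the reference-allele fragment (A–B) has known length; the
deleted-allele fragment length is unknowable before sequencing (the true
deleted length is what the assay measures), so it is reported as a bound:
≤ span − `min_del`. Signatures map each fragment to the read-alignment
pattern it must produce: `contiguous`, `gapped_two_segment`,
`clipped_tail`, or `inverted_dual`. The target-fraction operation sums
fragment lengths over the genome size; no published value is asserted for
it because the underlying fragment panel is not fully enumerable.

## Synthetic data

`sim_reads` generates the stated world the caller is validated against:

- Haplotypes: het SVs are applied to haplotype 2 only, hom SVs to both;
  the liftover between reference and haplotype coordinates is exact and
  block-based (match / inserted, with strand for inverted blocks).
- Amplicon model: reads are whole fragments between two same-target cut
  sites on the sampled haplotype — the protocol sequences PCR amplicons,
  so no fragmentation model is used. Fragments longer than `amplicon_max`
  (30 kbp, matching the PCR limit) drop out; a consequence is that
  reference-allele fragments of inversion and element-mode insertion
  targets are never sequenced, so genotypes for those classes rest on alt
  support alone — matching the real assay's information content.
- Errors: iid substitution/insertion/deletion at 0.03/0.02/0.04 per base
  (a nanopore-like profile; chosen once, not tuned). Error events are
  tracked as an op list per read so truth alignments carry exact CIGARs
  and NM tags.
- Background: off-target "blocking leakage" reads are uniform random
  haplotype fragments with log-normal length (median 2 kbp), 30% of the
  total by default. Per-(SV, haplotype) weights can reproduce extreme
  allele imbalance (the assay's per-allele cut efficiency varies by
  orders of magnitude).
- Truth alignments: reference-space records computed through the
  liftover — deletion gaps become CIGAR `D` ops or, above
  `split_threshold` = 10 kbp, primary+supplementary split pairs with SA
  tags; inserted material is soft-clipped (terminal) or an `I` op
  (interior); inverted segments become opposite-strand records. The
  emitter replaces an external aligner for testing; production inputs are
  minimap2-style SAM/BAM or CIGAR-bearing PAF.

What a green synthetic test does *not* establish: real nanopore errors
are not iid (homopolymer-biased), real off-target reads are not uniform,
chimeric PCR products are not modelled, and real breakpoints can sit in
repeats that defeat unique guide placement. The simulator validates the
geometry and logic of the method, not basecaller behaviour.

## Breakpoint calling

Reads are grouped by name (supplementaries attached via SA), assigned to
the SV whose designed cut lies within `tol` = 100 bp of a segment
boundary, and classified per class:

- **Deletion**: alt evidence is an in-read deletion ≥ `min_del` = 1000 bp
  or a same-strand split pair whose reference gap minus any unaligned
  read bases between the segments is ≥ `min_del` (segments are compared
  in reference order, so sequencing orientation is irrelevant).
  Breakpoints are medians across reads (ties toward the smaller
  coordinate). Unaligned bases between the segments above `adj_tol` =
  50 bp downgrade the 3′ side to low confidence, above `clip_tol` =
  200 bp both sides — this is the reference-N situation, and N runs ≥ 10
  inside the called gap additionally set the `reference_N_gap` flag.
  `sv_length` is reported only when both sides are high-confidence.
- **Insertion**: supporting reads carry terminal soft clips ≥ `min_clip`
  = 200 bp at the locus; the breakpoint is the median last-aligned base.
  Right-clip tails (stored orientation = inserted sequence 5′→3′) feed a
  per-column plurality consensus (`cons_min` = 2 minimum coverage, ties
  lexicographic, length = median tail length); when an element consensus
  is supplied the call is `element_confirmed` if the tail consensus
  locally aligns at ≥ 0.80 identity over ≥ 200 bp in either orientation.
  Known limitation: a column-wise consensus loses register under indel
  noise, so at full nanopore error rates the consensus identity can fall
  below the confirmation threshold even for true element insertions
  (breakpoints are unaffected); confirmation is reliable at low error or
  high coverage.
- **Inversion**: supporting reads contain opposite-orientation segments;
  both breakpoints are the junction-side segment boundaries (for a
  forward segment the junction at its read end is its reference end; for
  an inverted segment the junction at its read start is also its
  reference end — which is exactly how the two true junctions surface).
  Additional opposite-strand placements of the same read (inverted-repeat
  similarity at the two junctions) raise `inverted_repeat_ambiguity`; all
  placements are reported and never silently resolved.

Genotypes use support counts only (`min_support` = 3 per class): het =
both classes present, hom_alt / hom_ref = one class, no_call = neither.
Allele balance is deliberately ignored — per-allele cut efficiency in
this assay varies enormously, and a 5-read alt class against a 171-read
ref class is still a confident het.

Local alignment (element confirmation) is affine-gap Smith–Waterman with
match 2, mismatch −4, and gap cost 4 + 2k for a gap of length k,
delegated to Biopython's `PairwiseAligner` (C implementation) and
cross-checked in the tests against an independent quadratic Gotoh DP.

## Numerical and degenerate-input choices

- Circular sequences are unsupported; cuts at coordinate 0 or L are
  rejected (no zero-length fragments); duplicate cut coordinates collapse.
- Median aggregation uses the lower median (ties toward the smaller
  coordinate).
- IUPAC ambiguity codes other than N are degraded to N on FASTA ingest
  with a warning; characters outside IUPAC are errors.
- All randomness flows from a single integer seed per run; FASTQ/SAM
  outputs are byte-identical across runs with the same seed and config.

## Scale of the bundled validation

The toy world is one 200 kbp chromosome with a het 13.2 kbp deletion
(optical interval over-extended by 3 kbp per side), a hom 6 kbp element
insertion (locus ±600 bp), and a hom 40 kbp inversion (edges ±500 bp).
The recovery experiment in the acceptance tests runs 50 seeded replicates
at the default error rates with 12 reads per target — read depth is the
only scaled-down quantity, chosen to keep the suite within its time
budget; error rates and SV sizes are not scaled.
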