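"""Standard-format outputs: VCF 4.2 with symbolic SV alleles, per-SV TSV."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .breakpoint_caller import BreakpointCall
from .digest_model import ExpectedFragment
from .genome_io import GenomeSequence
from .guide_design import GuideSet

_ALT = {"deletion": "<DEL>", "insertion": "<INS>", "inversion": "<INV>"}
_SVTYPE = {"deletion": "DEL", "insertion": "INS", "inversion": "INV"}
_GT = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0", "no_call": "./."}

VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant (negative for deletions)">',
    '##INFO=<ID=SUPPORT,Number=2,Type=Integer,Description="Reads supporting ref,alt allele classes">',
    '##INFO=<ID=BPCONF,Number=.,Type=String,Description="Per-breakpoint confidence">',
    '##INFO=<ID=FLAGS,Number=.,Type=String,Description="Caller flags">',
    '##FILTER=<ID=LowConf,Description="Low-confidence or ambiguous breakpoint">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Supporting read depth (all classes)">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
]


def write_vcf(
    calls: Sequence[BreakpointCall],
    reference: Mapping[str, GenomeSequence],
    path: str | Path,
    sample: str = "sample",
) -> None:
    """VCF 4.2 with symbolic ALTs; POS is the last reference base before the event."""
    lines = ["##fileformat=VCFv4.2", "##source=casbreak"]
    for name, rec in reference.items():
        lines.append(f"##contig=<ID={name},length={len(rec)}>")
    lines.extend(VCF_HEADER_LINES)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    body = []
    for call in calls:
        if call.genotype == "no_call" or not call.breakpoints:
            continue
        if call.sv_type not in _ALT:
            raise ValueError(f"{call.sv_id}: cannot encode sv_type {call.sv_type!r}")
        chrom, pos, _ = call.breakpoints[0]
        confs = [c for _, _, c in call.breakpoints]
        low = any(c != "high" for c in confs)
        if call.sv_type == "deletion" and len(call.breakpoints) >= 2:
            end = call.breakpoints[1][1] - 1  # last deleted base
            svlen = -(call.sv_length or (end - pos))
        elif call.sv_type == "inversion" and len(call.breakpoints) >= 2:
            end = call.breakpoints[1][1]
            svlen = call.sv_length or (end - pos)
        else:
            end = pos
            svlen = len(call.inserted_consensus or "")
        ref_base = (
            reference[chrom].seq[pos - 1] if chrom in reference and pos <= len(reference[chrom]) else "N"
        )
        info = (
            f"SVTYPE={_SVTYPE[call.sv_type]};END={end};SVLEN={svlen};"
            f"SUPPORT={call.support.get('ref', 0)},{call.support.get('alt', 0)};"
            f"BPCONF={','.join(confs)}"
        )
        if call.flags:
            info += f";FLAGS={','.join(call.flags)}"
        filt = "LowConf" if low else "PASS"
        dp = sum(call.support.values())
        body.append(
            (chrom, pos,
             f"{chrom}\t{pos}\t{call.sv_id}\t{ref_base}\t{_ALT[call.sv_type]}\t.\t"
             f"{filt}\t{info}\tGT:DP\t{_GT[call.genotype]}:{dp}")
        )
    order = {name: i for i, name in enumerate(reference)}
    body.sort(key=lambda t: (order.get(t[0], 1 << 30), t[1]))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
        for _, _, line in body:
            fh.write(line + "\n")


def write_report_tsv(
    calls: Sequence[BreakpointCall],
    guide_sets: Mapping[str, GuideSet],
    fragments: Sequence[ExpectedFragment],
    coverage: Mapping[str, Mapping[str, float]] | None,
    path: str | Path,
) -> None:
    """One row per SV: design geometry, expected fragments, resolved call."""
    frags_by_sv: dict[str, list[ExpectedFragment]] = {}
    for f in fragments:
        frags_by_sv.setdefault(f.sv_id, []).append(f)
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "sv_id\tsv_type\tchrom\tcuts_1based\texpected_fragments\t"
            "breakpoints_1based\tgenotype\tsupport_ref\tsupport_alt\t"
            "flags\tmedian_coverage\n"
        )
        for call in calls:
            if call.sv_id not in guide_sets:
                raise ValueError(f"no guide set for call {call.sv_id!r}")
            gs = guide_sets[call.sv_id]
            chrom = gs.by_role("flank_5p").interval.chrom
            cuts = ",".join(
                f"{role}:{g.cut_coord + 1}" for role, g in gs.guides
            )
            exp = ";".join(
                f"{f.allele}:{f.length if f.length is not None else f'<={f.length_bound}'}"
                for f in frags_by_sv.get(call.sv_id, [])
            ) or "NA"
            bps = ",".join(f"{p}({c})" for _, p, c in call.breakpoints) or "NA"
            cov = "NA"
            if coverage and call.sv_id in coverage:
                cov = f"{coverage[call.sv_id]['median']:g}"
            fh.write(
                f"{call.sv_id}\t{call.sv_type}\t{chrom}\t{cuts}\t{exp}\t{bps}\t"
                f"{call.genotype}\t{call.support.get('ref', 0)}\t"
                f"{call.support.get('alt', 0)}\t"
                f"{','.join(call.flags) or '.'}\t{cov}\n"
            )
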