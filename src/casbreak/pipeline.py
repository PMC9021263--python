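"""Stage orchestration shared by the CLI and the test suite.

Chains catalog -> guide design -> fragment prediction -> (optionally)
simulation -> calling, with per-stage counters, without any file I/O of
its own; the CLI layers argument parsing and artifact writing on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .breakpoint_caller import (
    BreakpointCall,
    ReadAlignmentGroup,
    assign_reads_to_targets,
    call_deletion,
    call_insertion,
    call_inversion,
    compute_target_coverage,
)
from .config import PipelineConfig
from .digest_model import ExpectedFragment, predict_fragments
from .genome_io import GenomeSequence
from .guide_design import (
    DesignError,
    GuideSet,
    design_deletion_guides,
    design_insertion_guides,
    design_inversion_guides,
)
from .sv_catalog import SVCatalog

log = logging.getLogger(__name__)


@dataclass
class DesignResult:
    guide_sets: dict[str, GuideSet]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (sv_id, reason)


def design_all(
    catalog: SVCatalog,
    reference: Mapping[str, GenomeSequence],
    element_consensus: GenomeSequence | None = None,
    config: PipelineConfig | None = None,
) -> DesignResult:
    """Design guide sets for every targetable record; collect failures."""
    cfg = (config or PipelineConfig()).design
    result = DesignResult({})
    for sv in catalog:
        try:
            if sv.sv_type == "deletion":
                gs = design_deletion_guides(sv, reference, cfg)
            elif sv.sv_type == "insertion":
                gs = design_insertion_guides(sv, reference, element_consensus, cfg)
            elif sv.sv_type == "inversion":
                gs = design_inversion_guides(sv, reference, cfg)
            else:
                result.skipped.append((sv.sv_id, f"unsupported class {sv.sv_type}"))
                continue
        except DesignError as e:
            log.info("design skipped %s: %s", sv.sv_id, e)
            result.skipped.append((sv.sv_id, str(e)))
            continue
        result.guide_sets[sv.sv_id] = gs
    log.info(
        "design: %d guide sets, %d skipped",
        len(result.guide_sets), len(result.skipped),
    )
    return result


def predict_all(
    catalog: SVCatalog,
    guide_sets: Mapping[str, GuideSet],
    config: PipelineConfig | None = None,
) -> list[ExpectedFragment]:
    cfg = (config or PipelineConfig()).digest
    fragments: list[ExpectedFragment] = []
    for sv in catalog:
        if sv.sv_id in guide_sets:
            fragments.extend(predict_fragments(sv, guide_sets[sv.sv_id], cfg))
    return fragments


def call_all(
    groups: Sequence[ReadAlignmentGroup],
    catalog: SVCatalog,
    guide_sets: Mapping[str, GuideSet],
    element_consensus: GenomeSequence | None = None,
    reference: Mapping[str, GenomeSequence] | None = None,
    config: PipelineConfig | None = None,
) -> list[BreakpointCall]:
    """Assign read groups to targets and resolve every designed SV."""
    cfg = (config or PipelineConfig()).call
    groups = assign_reads_to_targets(groups, guide_sets, tol=cfg.tol)
    n_bg = sum(1 for g in groups if g.assigned_sv is None)
    log.info("assigned %d/%d read groups (%d background)",
             len(groups) - n_bg, len(groups), n_bg)
    calls: list[BreakpointCall] = []
    by_id = {sv.sv_id: sv for sv in catalog}
    for sv_id, gs in guide_sets.items():
        sv = by_id.get(sv_id)
        if sv is None:
            continue
        if sv.sv_type == "deletion":
            call = call_deletion(groups, sv, gs, cfg, reference)
        elif sv.sv_type == "insertion":
            call = call_insertion(groups, sv, gs, element_consensus, cfg)
        elif sv.sv_type == "inversion":
            call = call_inversion(groups, sv, gs, cfg)
        else:
            continue
        log.info(
            "call %s (%s): genotype=%s support=%s breakpoints=%s",
            sv_id, sv.sv_type, call.genotype, call.support,
            [(c, p) for c, p, _ in call.breakpoints],
        )
        calls.append(call)
    return calls


def coverage_all(
    groups: Sequence[ReadAlignmentGroup], guide_sets: Mapping[str, GuideSet]
) -> dict[str, dict[str, float]]:
    return compute_target_coverage(groups, guide_sets)
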