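"""Pipeline configuration: dataclasses with documented defaults + TOML loading.

Every threshold that shapes a result lives here so a run is fully described
by one TOML file (sections [design], [digest], [simulate], [call],
[report]) plus a seed.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib


class ConfigError(ValueError):
    pass


@dataclass
class DesignConfig:
    """Guide-design geometry and screening thresholds (all lengths in bp)."""

    #: anchor window extension outside the optical SV interval
    w_out: int = 5000
    #: allowed interior placement past the optical interval edge
    #: (optical breakpoints over-extend; a "flanking" cut may sit inside)
    w_in: int = 4000
    #: target length of the reference-allele fragment for deletions
    ref_fragment_target: int = 3500
    #: target sample-fragment length for inversions
    inv_fragment_target: int = 6500
    #: inversion internal guide must cut within this distance of the 3' edge
    internal_window: int = 5000
    gc_min: float = 0.25
    gc_max: float = 0.75
    max_homopolymer: int = 5
    #: fragment-length bounds enforced when PCR enrichment is on
    min_fragment: int = 1000
    max_fragment: int = 30000
    pcr_mode: bool = True


@dataclass
class DigestConfig:
    #: deletions below this are not treated as SV evidence (shared with caller)
    min_del: int = 1000


@dataclass
class SimulateConfig:
    """Targeted-amplicon read simulation parameters."""

    seed: int = 0
    n_reads_per_target: int = 30
    #: nanopore-like per-base error rates (substitution, insertion, deletion)
    error_sub: float = 0.03
    error_ins: float = 0.02
    error_del: float = 0.04
    #: fraction of reads that are on-target amplicons (blocking leakage = rest)
    on_target_fraction: float = 0.7
    #: digest fragments longer than this are not amplified (PCR dropout)
    amplicon_max: int = 30000
    #: reference gaps larger than this are emitted as split records, not CIGAR D
    split_threshold: int = 10000
    #: uniform amplicon length jitter as a fraction (0 disables)
    length_jitter: float = 0.0
    #: median background fragment length (log-normal)
    background_median: int = 2000
    #: optional per-(sv_id, haplotype) read-count multipliers
    allele_weights: dict = field(default_factory=dict)

    def validate(self) -> None:
        for r in (self.error_sub, self.error_ins, self.error_del):
            if not 0.0 <= r <= 0.2:
                raise ConfigError(f"error rate {r} outside [0, 0.2]")
        if not 0.0 < self.on_target_fraction <= 1.0:
            raise ConfigError("on_target_fraction must be in (0, 1]")


@dataclass
class CallConfig:
    """Breakpoint-caller thresholds."""

    #: read-boundary-to-cut-site distance for target assignment
    tol: int = 100
    #: minimum deletion span treated as alt evidence
    min_del: int = 1000
    #: minimum reads per allele class to call that class present
    min_support: int = 3
    #: element-confirmation identity / length thresholds for insertions
    id_min: float = 0.80
    len_min: int = 200
    #: minimum tail coverage per consensus column (below -> N)
    cons_min: int = 2
    #: inner-end soft clips above this downgrade a breakpoint to low confidence
    clip_tol: int = 200
    #: maximum read-coordinate gap between split segments of one junction
    adj_tol: int = 50
    #: minimum terminal clip length counted as insertion evidence
    min_clip: int = 200
    #: N-runs at least this long inside a called gap set the reference_N_gap flag
    n_run: int = 10


@dataclass
class ReportConfig:
    pass


@dataclass
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    digest: DigestConfig = field(default_factory=DigestConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    call: CallConfig = field(default_factory=CallConfig)
    report: ReportConfig = field(default_factory=ReportConfig)


_SECTIONS = {
    "design": DesignConfig,
    "digest": DigestConfig,
    "simulate": SimulateConfig,
    "call": CallConfig,
    "report": ReportConfig,
}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a TOML config; missing sections/keys take defaults, unknown keys fail."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    for section, cls in _SECTIONS.items():
        if section not in data:
            continue
        block = data[section]
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(block) - names
        if bad:
            raise ConfigError(f"[{section}]: unknown key(s) {sorted(bad)}")
        setattr(cfg, section, dataclasses.replace(getattr(cfg, section), **block))
    cfg.simulate.validate()
    return cfg
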