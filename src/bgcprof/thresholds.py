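"""Analysis cutoffs shared across the pipeline stages.

All thresholds the procedures use live in one dataclass so that a run is
fully described by a single configuration object. Defaults are the
conventions of the strain-characterisation workflow this package
implements: an RPKM silence floor, a capped log2 fold change for genes
silent on exactly one side, z-score bands for the cross-platform
comparison, and detection-limit conventions for targeted metabolomics.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class AnalysisThresholds:
    """Cutoffs for every decision rule in the pipeline.

    Attributes
    ----------
    silent_rpkm : float
        Genes below this RPKM are treated as silent (default 0.3).
    fc_cap : float
        Magnitude of the log2 fold change assigned when a gene is silent
        in exactly one strain, and the clamp for extreme ratios
        (default 7 log2 units).
    de_min_abs_fc : float
        Minimum |log2 FC| for a gene to be called differentially
        expressed (strict inequality, default 0.25).
    alpha : float
        Significance level for t-tests and enrichment FDR (default 0.05).
    trend_alpha : float
        Upper p-value bound for a non-significant trend marker,
        "(+)" / "(-)" (default 0.10).
    screen_min_silent_conditions : int
        A BGC core gene is called silent when it is not expressed in at
        least this many compendium conditions (default 22).
    screen_n_conditions : int
        Number of compendium conditions the screen expects (default 26).
    actin_rel_silent : float
        Actin-relative expression below which a gene counts as "not
        expressed" in one screen condition (default 0.02).
    actin_rel_low : float
        Actin-relative level below which qPCR expression is reported as
        low (default 0.05).
    z_similar : float
        |z| below this is "similar" expression behaviour (default 0.2).
    z_divergent : float
        |z| above this is divergent (default 1.25).
    coverage_min : float
        Minimum fraction of compendium datasets a gene must be present
        in to enter the z analysis (default 0.5).
    lod_floor : float
        Magnitude of the log2 fold change assigned to a metabolite
        detected in exactly one condition (default 5 log2 units).
    feature_min_fc : float
        Untargeted m/z features are kept when log2 FC exceeds this
        (strict, default 2).
    feature_min_area : float
        ... and their larger normalized peak area exceeds this
        (strict, default 1e6).
    """

    silent_rpkm: float = 0.3
    fc_cap: float = 7.0
    de_min_abs_fc: float = 0.25
    alpha: float = 0.05
    trend_alpha: float = 0.10
    screen_min_silent_conditions: int = 22
    screen_n_conditions: int = 26
    actin_rel_silent: float = 0.02
    actin_rel_low: float = 0.05
    z_similar: float = 0.2
    z_divergent: float = 1.25
    coverage_min: float = 0.5
    lod_floor: float = 5.0
    feature_min_fc: float = 2.0
    feature_min_area: float = 1.0e6

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value <= 0:
                raise ValueError(f"threshold {f.name} must be positive, got {value!r}")
        if not self.z_similar < self.z_divergent:
            raise ValueError("z_similar must be below z_divergent")
        if self.screen_min_silent_conditions > self.screen_n_conditions:
            raise ValueError(
                "screen_min_silent_conditions cannot exceed screen_n_conditions"
            )


DEFAULT_THRESHOLDS = AnalysisThresholds()
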