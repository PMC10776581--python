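"""Configuration objects for the cohort generator and the analysis pipeline.

All defaults encode the study conditions the analyses assume: a cohort of
very preterm babies (gestational age 23-29 weeks) sampled roughly weekly
over their neonatal-unit stay, 105 flow-derived immune parameters of which
a small signature responds to sepsis, plasma amphiregulin (AREG) with a low
stable baseline, and C-reactive protein (CRP) that rises in only about
three quarters of sepsis episodes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "ConfigError",
    "CohortConfig",
    "PipelineConfig",
    "SIGNATURE_PARAMETERS",
    "CYTOKINES",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


#: The ten cellular traits that carry the sepsis effect by default: T-cell
#: lymphopenia (counts and frequency), reduced dendritic-cell frequencies and
#: counts, and diminished HLA-DR expression on DC and monocyte subsets.
SIGNATURE_PARAMETERS = [
    "CD4_T_cells_per_uL",
    "CD8_T_cells_per_uL",
    "T_cell_freq_pct",
    "mDC_freq_pct",
    "pDC_freq_pct",
    "mDC_per_uL",
    "DC_HLA_DR_MFI",
    "classical_monocyte_HLA_DR_MFI",
    "intermediate_monocyte_HLA_DR_MFI",
    "T_cells_per_uL",
]

#: Plasma cytokines measured alongside AREG, with baseline medians (pg/mL)
#: and the fold-elevation applied at sepsis onset. Only IL-6 and IL-10 are
#: sepsis-responsive by default; CXCL8, TNF-a and IFN-g are null analytes.
CYTOKINES = {
    "IL6": (5.0, 3.0),
    "CXCL8": (20.0, 1.0),
    "TNFa": (3.0, 1.0),
    "IL10": (2.0, 2.5),
    "IFNg": (1.0, 1.0),
}

_Z75 = 0.6744897501960817  # upper-quartile z of the standard normal


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass
class CohortConfig:
    """Parameters of the synthetic longitudinal cohort generator.

    The defaults are the study conditions: 19 babies sampled weekly (median
    9 samples/baby), 105 immune parameters of which 10 carry a one-log2
    suppression at sepsis onset with a ~7-day rebound, AREG baseline
    calibrated to median 19 and IQR 14-27.9 pg/mL, and CRP remaining low
    (<=10 mg/L) in a quarter of sepsis episodes.
    """

    n_babies: int = 19
    ga_range_weeks: tuple[int, int] = (23, 29)
    sampling_interval_days: float = 7.0
    sampling_jitter_days: float = 2.0
    # Routine (scheduled) draws per baby; episode-onset suspicion draws are
    # added on top, so the realized per-baby total has median ~9.
    samples_per_baby_median: int = 7
    samples_per_baby_sd: float = 2.5
    samples_per_baby_range: tuple[int, int] = (2, 14)

    n_parameters: int = 105
    n_true_effects: int = 10
    effect_size_log2: float = 1.0
    rebound_days: float = 7.0
    # Developmental ramp saturates early in the second 15-day bracket, so
    # neighbouring-bracket tests detect only the first transition.
    age_trend_log2_per_day: float = 0.03
    age_trend_plateau_day: int = 21
    within_baby_sd_log2: float = 0.3
    assay_cv: float = 0.2

    episode_rate_per_baby: float = 2.4
    p_mcs_given_sepsis: float = 0.55
    p_cons_given_mcs: float = 0.6
    p_cons_supported: float = 1.0
    nsc_rate_per_baby: float = 2.0
    nec_rate_per_baby: float = 0.08
    episode_followup_days: float = 5.0
    min_episode_separation_days: float = 10.0

    crp_low_fraction: float = 0.25
    crp_baseline_range: tuple[float, float] = (1.0, 5.0)
    crp_sepsis_median: float = 40.0
    crp_sepsis_sigma_log: float = 0.5

    areg_median: float = 19.0
    areg_iqr: tuple[float, float] = (14.0, 27.9)
    areg_sepsis_multiplier: float = 4.0
    nsc_areg_multiplier: float = 1.3

    qc_dropout_rate: float = 0.02
    qc_parent_mean: float = 400.0
    qc_low_mean: float = 15.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require(self.n_babies >= 1, "n_babies", "must be >= 1")
        _require(
            self.ga_range_weeks[0] <= self.ga_range_weeks[1],
            "ga_range_weeks",
            "must be an (low, high) interval",
        )
        _require(self.sampling_interval_days > 0, "sampling_interval_days", "must be > 0")
        _require(self.n_parameters >= 1, "n_parameters", "must be >= 1")
        _require(
            0 <= self.n_true_effects <= self.n_parameters,
            "n_true_effects",
            "must satisfy 0 <= n_true_effects <= n_parameters",
        )
        _require(self.rebound_days > 0, "rebound_days", "must be > 0")
        _require(
            0.0 <= self.crp_low_fraction <= 1.0,
            "crp_low_fraction",
            "must lie in [0, 1]",
        )
        _require(self.areg_median > 0, "areg_median", "must be > 0")
        q1, q3 = self.areg_iqr
        _require(0 < q1 < q3, "areg_iqr", "must satisfy 0 < Q1 < Q3")
        _require(self.areg_sepsis_multiplier > 0, "areg_sepsis_multiplier", "must be > 0")
        _require(self.assay_cv >= 0, "assay_cv", "must be >= 0")
        _require(self.within_baby_sd_log2 >= 0, "within_baby_sd_log2", "must be >= 0")
        _require(self.effect_size_log2 >= 0, "effect_size_log2", "must be >= 0")
        _require(
            0.0 <= self.p_mcs_given_sepsis <= 1.0,
            "p_mcs_given_sepsis",
            "must lie in [0, 1]",
        )
        lo, hi = self.samples_per_baby_range
        _require(1 <= lo <= hi, "samples_per_baby_range", "must be a positive interval")

    @property
    def areg_sigma_log(self) -> float:
        """Log-scale SD of the AREG baseline implied by the target IQR."""
        q1, q3 = self.areg_iqr
        return math.log(q3 / q1) / (2.0 * _Z75)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("ga_range_weeks", "samples_per_baby_range", "crp_baseline_range", "areg_iqr"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineConfig:
    """All downstream thresholds in one declarative document.

    Every default equals the study's printed value: volcano |log2FC| > 0.6
    at BH p < 0.01, DEG thresholds BH < 0.05 / |log2FC| > 0.95, CRP cut
    10 mg/L, AREG cut 38.7 pg/mL, 15-day age brackets, 48-h suspected-sepsis
    window, 30-event flow QC floor and an external prior of 0.22.
    """

    fc_threshold: float = 0.6
    alpha: float = 0.01
    deg_alpha: float = 0.05
    deg_lfc: float = 0.95
    crp_cut_mg_per_L: float = 10.0
    areg_cut_pg_per_mL: float = 38.7
    bracket_days: int = 15
    window_hours: float = 48.0
    qc_min_events: int = 30
    external_prior: float = 0.22
    max_gap_days: int = 14
    age_strata_boundary_day: int = 30
    min_pairs: int = 5
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require(self.fc_threshold >= 0, "fc_threshold", "must be >= 0")
        _require(0 < self.alpha < 1, "alpha", "must lie in (0, 1)")
        _require(0 < self.deg_alpha < 1, "deg_alpha", "must lie in (0, 1)")
        _require(self.crp_cut_mg_per_L >= 0, "crp_cut_mg_per_L", "must be >= 0")
        _require(self.areg_cut_pg_per_mL >= 0, "areg_cut_pg_per_mL", "must be >= 0")
        _require(self.bracket_days >= 1, "bracket_days", "must be >= 1")
        _require(self.window_hours > 0, "window_hours", "must be > 0")
        _require(self.qc_min_events >= 0, "qc_min_events", "must be >= 0")
        _require(0 <= self.external_prior <= 1, "external_prior", "must lie in [0, 1]")
        _require(self.max_gap_days >= 1, "max_gap_days", "must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)


def parameter_names(n_parameters: int, n_true_effects: int) -> tuple[list[str], list[str]]:
    """Return (all parameter names, true-effect parameter names).

    The first ``n_true_effects`` names are drawn from the named signature
    traits (extended with generic names if more than ten effects are
    requested); the remainder are anonymous null parameters.
    """
    true_names = list(SIGNATURE_PARAMETERS[:n_true_effects])
    k = len(true_names)
    while len(true_names) < n_true_effects:
        true_names.append(f"effect_param_{len(true_names) + 1:03d}")
    fillers = [f"param_{i + 1:03d}" for i in range(n_parameters - n_true_effects)]
    return true_names + fillers, true_names
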