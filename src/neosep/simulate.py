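"""Synthetic longitudinal cohort generator.

Emulates the data structure of a prospective neonatal-unit study of very
preterm babies: weekly blood draws over the first weeks of life, sepsis
episodes (culture-positive or culture-negative) that acutely suppress a
signature of cellular immune traits with a roughly one-week rebound,
suspected-but-ruled-out episodes, rare necrotising enterocolitis, and plasma
analytes (CRP, amphiregulin, cytokines) with episode-contemporaneous spikes.

Everything is driven by a single seeded :class:`numpy.random.Generator`, so a
fixed :class:`~neosep.config.CohortConfig` reproduces the cohort byte for
byte. A ground-truth sidecar (true-effect parameter names, episode onsets)
accompanies every cohort for recovery tests.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .config import CYTOKINES, CohortConfig, parameter_names

__all__ = [
    "generate_cohort",
    "inject_episode",
    "generate_baseline_plasma",
    "generate_deg_table",
    "PARAM_PREFIX",
    "EVENTS_PREFIX",
    "CYT_PREFIX",
]

PARAM_PREFIX = "param."
EVENTS_PREFIX = "events."
CYT_PREFIX = "cyt."

AREG_COL = "areg_pg_per_mL"
CRP_COL = "crp_mg_per_L"

_ORGANISMS = ["E. coli", "E. cloacae", "E. faecalis", "GBS", "S. anginosus"]

_SEPSIS_KINDS = ("MCS", "ClinSep")


def _recovery_weight(days: np.ndarray, onset_day: float, rebound_days: float) -> np.ndarray:
    """Fraction of the full acute effect remaining on each day.

    1 at onset, linearly decaying (on the log scale of the affected trait)
    to 0 at ``onset + rebound_days``; 0 before onset.
    """
    days = np.asarray(days, dtype=float)
    w = 1.0 - (days - onset_day) / float(rebound_days)
    w = np.clip(w, 0.0, 1.0)
    w[days < onset_day] = 0.0
    return w


def inject_episode(
    trajectory: pd.DataFrame,
    onset_day: int,
    kind: str,
    *,
    affected: list[str],
    effect_size_log2: float,
    rebound_days: float,
    areg_multiplier: float = 1.0,
    crp_elevated: bool = False,
    crp_peak: float | None = None,
    cytokine_multipliers: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Overlay one clinical episode on a day-indexed trajectory.

    ``trajectory`` is indexed by postnatal day and holds parameter columns
    (linear scale) plus, optionally, ``areg_pg_per_mL``, ``crp_mg_per_L``
    and ``cyt.*`` columns. Affected parameters are multiplied by
    ``2**(-effect_size_log2)`` at onset, recovering to baseline by
    ``onset + rebound_days``; plasma analytes spike at onset and decay on
    the same schedule. NEC and NSC episodes perturb plasma analytes only.

    An onset outside the observed window skips the episode with a warning
    and returns the trajectory unchanged.
    """
    days = trajectory.index.to_numpy(dtype=float)
    if len(days) == 0 or onset_day < days.min() or onset_day > days.max():
        warnings.warn(
            f"episode onset day {onset_day} outside observation window; episode skipped",
            stacklevel=2,
        )
        return trajectory
    out = trajectory.copy()
    w = _recovery_weight(days, onset_day, rebound_days)

    if kind in _SEPSIS_KINDS:
        cols = [c for c in affected if c in out.columns]
        if cols:
            out[cols] = out[cols].to_numpy() * np.power(2.0, -effect_size_log2 * w)[:, None]

    if AREG_COL in out.columns and areg_multiplier != 1.0:
        out[AREG_COL] = out[AREG_COL].to_numpy() * np.power(areg_multiplier, w)

    if crp_elevated and CRP_COL in out.columns and crp_peak is not None:
        onset_pos = int(np.argmin(np.abs(days - onset_day)))
        base = float(out[CRP_COL].iloc[onset_pos])
        ratio = max(1.0, crp_peak / max(base, 1e-9))
        out[CRP_COL] = out[CRP_COL].to_numpy() * np.power(ratio, w)

    for name, mult in (cytokine_multipliers or {}).items():
        col = CYT_PREFIX + name
        if col in out.columns and mult != 1.0:
            out[col] = out[col].to_numpy() * np.power(mult, w)

    return out


def generate_baseline_plasma(
    n: int,
    config: CohortConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Draw ``n`` baseline plasma amphiregulin values (pg/mL).

    Log-normal, calibrated so the large-sample median equals
    ``config.areg_median`` and the quartiles approach ``config.areg_iqr``
    (a single log-scale SD is fitted to the IQR width, so each quartile
    lands within a few percent of its target).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config if config is not None else CohortConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    return rng.lognormal(math.log(config.areg_median), config.areg_sigma_log, size=n)


def _sample_days(rng: np.random.Generator, config: CohortConfig) -> list[int]:
    lo, hi = config.samples_per_baby_range
    k = int(np.clip(round(rng.normal(config.samples_per_baby_median, config.samples_per_baby_sd)), lo, hi))
    first = int(rng.integers(1, 9))
    jitter = rng.uniform(-config.sampling_jitter_days, config.sampling_jitter_days, k)
    raw = first + config.sampling_interval_days * np.arange(k) + jitter
    days: list[int] = []
    prev = 0
    for d in np.sort(raw):
        di = max(prev + 1, int(round(d)), 1)
        days.append(di)
        prev = di
    return days


def _draw_events(
    rng: np.random.Generator, config: CohortConfig, window: tuple[int, int]
) -> list[tuple[int, str]]:
    """Choose episode onsets/kinds within a baby's observation window."""
    lo = window[0] + 3
    hi = window[1]
    if hi - lo < 1:
        return []
    kinds: list[str] = []
    for _ in range(rng.poisson(config.episode_rate_per_baby)):
        kinds.append("MCS" if rng.random() < config.p_mcs_given_sepsis else "ClinSep")
    kinds.extend("NSC" for _ in range(rng.poisson(config.nsc_rate_per_baby)))
    if rng.random() < config.nec_rate_per_baby:
        kinds.append("NEC")
    rng.shuffle(kinds)
    events: list[tuple[int, str]] = []
    for kind in kinds:
        for _ in range(10):  # rejection sampling for separation
            onset = int(rng.integers(lo, hi + 1))
            if all(abs(onset - o) >= config.min_episode_separation_days for o, _ in events):
                events.append((onset, kind))
                break
    events.sort()
    return events


def _episode_metadata(rng: np.random.Generator, config: CohortConfig, kind: str) -> dict:
    meta = {
        "culture_result": "negative",
        "organism": "",
        "organism_is_cons": False,
        "cons_supporting_evidence": False,
        "antibiotic_course_days": 0.0,
        "antibiotics_stopped_within_72h": False,
        "clinical_criteria_met": 0,
        "nec_stage": "none",
    }
    if kind == "MCS":
        is_cons = rng.random() < config.p_cons_given_mcs
        meta.update(
            culture_result="positive",
            organism="CoNS" if is_cons else str(rng.choice(_ORGANISMS)),
            organism_is_cons=is_cons,
            cons_supporting_evidence=bool(is_cons and rng.random() < config.p_cons_supported),
            clinical_criteria_met=int(rng.integers(3, 8)),
            antibiotic_course_days=float(np.round(rng.uniform(5, 10), 1)),
        )
    elif kind == "ClinSep":
        meta.update(
            clinical_criteria_met=int(rng.integers(3, 8)),
            antibiotic_course_days=float(np.round(rng.uniform(5, 10), 1)),
        )
    elif kind == "NSC":
        meta.update(
            clinical_criteria_met=int(rng.integers(0, 3)),
            antibiotic_course_days=float(np.round(rng.uniform(1, 3), 1)),
            antibiotics_stopped_within_72h=True,
        )
    elif kind == "NEC":
        meta.update(
            nec_stage="II" if rng.random() < 0.6 else "III",
            clinical_criteria_met=int(rng.integers(0, 6)),
            antibiotic_course_days=float(np.round(rng.uniform(3, 10), 1)),
        )
    else:  # pragma: no cover - guarded by _draw_events
        raise ValueError(f"unknown episode kind: {kind}")
    return meta


def generate_cohort(config: CohortConfig | None = None, **overrides) -> tuple[pd.DataFrame, dict]:
    """Generate a seeded synthetic cohort.

    Returns a tidy per-sample table (one row per blood draw; parameter
    columns prefixed ``param.``, parent event counts ``events.``, cytokines
    ``cyt.``) together with a ground-truth sidecar dict recording the
    true-effect parameter names and every injected episode.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a CohortConfig or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)

    names, true_names = parameter_names(config.n_parameters, config.n_true_effects)
    n_par = config.n_parameters
    true_set = set(true_names)
    is_true = np.array([nm in true_set for nm in names])
    base_log2 = rng.uniform(2.0, 10.0, n_par)
    slopes = np.where(is_true, config.age_trend_log2_per_day, 0.0)
    sigma_noise_log2 = math.sqrt(math.log1p(config.assay_cv**2)) / math.log(2.0)
    cyt_mults = {name: mult for name, (_, mult) in CYTOKINES.items()}

    frames: list[pd.DataFrame] = []
    truth_episodes: list[dict] = []

    for b in range(config.n_babies):
        baby_id = f"B{b + 1:03d}"
        ga = int(rng.integers(config.ga_range_weeks[0], config.ga_range_weeks[1] + 1))
        sex = "F" if rng.random() < 0.5 else "M"
        bw_z = float(np.round(rng.normal(0.0, 1.0), 3))
        resp = bool(rng.random() < 0.5)
        steroids = bool(rng.random() < 0.8)

        routine_days = _sample_days(rng, config)
        window = (routine_days[0], routine_days[-1])
        events = _draw_events(rng, config, window)
        day_arr = np.array(sorted(set(routine_days) | {o for o, _ in events}))
        nd = len(day_arr)

        intercept = rng.normal(0.0, config.within_baby_sd_log2, n_par)
        age = np.minimum(day_arr, config.age_trend_plateau_day).astype(float)
        logs = (
            base_log2[None, :]
            + intercept[None, :]
            + slopes[None, :] * age[:, None]
            + rng.normal(0.0, sigma_noise_log2, (nd, n_par))
        )
        traj = pd.DataFrame(np.power(2.0, logs), index=day_arr, columns=names)
        traj[AREG_COL] = generate_baseline_plasma(nd, config, rng=rng)
        traj[CRP_COL] = rng.uniform(*config.crp_baseline_range, nd)
        for cname, (med, _) in CYTOKINES.items():
            traj[CYT_PREFIX + cname] = rng.lognormal(math.log(med), 0.5, nd)

        episode_info = []
        for j, (onset, kind) in enumerate(events, start=1):
            ep_id = f"{baby_id}-E{j}"
            inflammatory = kind in ("MCS", "ClinSep", "NEC")
            crp_elev = bool(inflammatory and rng.random() > config.crp_low_fraction)
            crp_peak = float(
                rng.lognormal(math.log(config.crp_sepsis_median), config.crp_sepsis_sigma_log)
            )
            if crp_elev:
                crp_peak = max(crp_peak, 12.0)  # an "elevated" episode must cross 10 mg/L
            areg_mult = (
                config.areg_sepsis_multiplier if inflammatory else config.nsc_areg_multiplier
            )
            culture_offset_h = float(rng.uniform(0.0, 36.0))
            meta = _episode_metadata(rng, config, kind)
            traj = inject_episode(
                traj,
                onset,
                kind,
                affected=true_names,
                effect_size_log2=config.effect_size_log2,
                rebound_days=config.rebound_days,
                areg_multiplier=areg_mult,
                crp_elevated=crp_elev,
                crp_peak=crp_peak,
                cytokine_multipliers=cyt_mults if inflammatory else None,
            )
            episode_info.append((onset, kind, ep_id, meta, culture_offset_h))
            truth_episodes.append(
                {
                    "episode_id": ep_id,
                    "baby_id": baby_id,
                    "onset_day": int(onset),
                    "kind": kind,
                    "crp_elevated": crp_elev,
                    "areg_multiplier": areg_mult,
                }
            )

        events_ok = rng.random((nd, n_par)) >= config.qc_dropout_rate
        parent_counts = np.where(
            events_ok,
            rng.poisson(config.qc_parent_mean, (nd, n_par)),
            rng.poisson(config.qc_low_mean, (nd, n_par)),
        )

        meta_rows = []
        for day in day_arr:
            row = {
                "baby_id": baby_id,
                "ga_weeks": ga,
                "sex": sex,
                "birthweight_z": bw_z,
                "resp_support": resp,
                "antenatal_steroids": steroids,
                "postnatal_day": int(day),
                "draw_reason": "routine",
                "culture_result": "none",
                "organism": "",
                "organism_is_cons": False,
                "cons_supporting_evidence": False,
                "antibiotic_course_days": 0.0,
                "antibiotics_stopped_within_72h": False,
                "clinical_criteria_met": 0,
                "nec_stage": "none",
                "episode_id": "",
                "hours_from_culture": np.nan,
            }
            for onset, kind, ep_id, meta, offset_h in episode_info:
                if onset <= day <= onset + config.episode_followup_days:
                    row.update(meta)
                    row["draw_reason"] = "suspected_sepsis"
                    row["episode_id"] = ep_id
                    row["hours_from_culture"] = float((day - onset) * 24.0 + offset_h)
                    break
            meta_rows.append(row)

        measured = {
            CRP_COL: np.round(traj[CRP_COL].to_numpy(), 3),
            AREG_COL: np.round(traj[AREG_COL].to_numpy(), 3),
        }
        for cname in CYTOKINES:
            measured[CYT_PREFIX + cname] = np.round(traj[CYT_PREFIX + cname].to_numpy(), 3)
        for i, nm in enumerate(names):
            measured[PARAM_PREFIX + nm] = np.round(traj[nm].to_numpy(), 4)
        for i, nm in enumerate(names):
            measured[EVENTS_PREFIX + nm] = parent_counts[:, i]
        frames.append(pd.concat([pd.DataFrame(meta_rows), pd.DataFrame(measured)], axis=1))

    samples = pd.concat(frames, ignore_index=True)
    truth = {
        "seed": config.seed,
        "config": config.to_dict(),
        "true_effect_parameters": true_names,
        "episodes": truth_episodes,
    }
    return samples, truth


def generate_deg_table(
    n_genes: int = 2000,
    n_true: int = 150,
    seed: int = 0,
    condition: str = "condition1",
    true_start: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Fabricate a per-gene differential-expression table.

    ``n_true`` genes receive |log2FC| > 0.95 with very small p-values; the
    rest are null. The ten haemoglobin genes are always appended as
    high-fold-change nuisance rows (they are removed by the fixed filter
    downstream). Adjusted p-values are Benjamini-Hochberg over the whole
    table. Returns the table and the list of true DEG names.

    ``true_start`` shifts the window of gene indices that carry the effect,
    so tables for different conditions can share a controlled subset of
    true DEGs (overlapping windows) against condition-specific noise.
    """
    from statsmodels.stats.multitest import multipletests

    from .degsets import HEMOGLOBIN_GENES

    if true_start + n_true > n_genes:
        raise ValueError("true_start + n_true must be <= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    sl = slice(true_start, true_start + n_true)
    true_genes = genes[sl]
    lfc = rng.normal(0.0, 0.3, n_genes)
    p = rng.uniform(0.0, 1.0, n_genes)
    if n_true:
        signs = rng.choice([-1.0, 1.0], n_true)
        lfc[sl] = signs * rng.uniform(1.0, 3.0, n_true)
        p[sl] = np.power(10.0, rng.uniform(-12.0, -4.0, n_true))
    hb_lfc = rng.choice([-1.0, 1.0], len(HEMOGLOBIN_GENES)) * rng.uniform(1.0, 4.0, len(HEMOGLOBIN_GENES))
    hb_p = np.power(10.0, rng.uniform(-8.0, -3.0, len(HEMOGLOBIN_GENES)))
    table = pd.DataFrame(
        {
            "gene": genes + list(HEMOGLOBIN_GENES),
            "log2fc": np.concatenate([lfc, hb_lfc]),
            "p_raw": np.concatenate([p, hb_p]),
        }
    )
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    table["condition"] = condition
    return table, true_genes
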