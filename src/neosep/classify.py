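"""Clinical classification of blood samples.

Each blood draw is assigned to exactly one of five categories from
contemporaneous clinical and microbiological metadata, in precedence order:

1. **NEC** — Bell's stage II or III necrotising enterocolitis.
2. **MCS** (microbiologically confirmed sepsis) — a contemporaneous positive
   culture; coagulase-negative staphylococci (CoNS), being common
   contaminants, additionally require supporting clinical evidence.
3. **ClinSep** (clinical sepsis) — suspected sepsis with negative cultures,
   at least three clinical criteria for invasive infection, and a treated or
   intended antibiotic course of at least five days.
4. **NSC** (no sepsis confirmed) — suspected sepsis with negative cultures
   and antibiotics discontinued within 72 h.
5. **Stable** — a routine draw with no clinical suspicion.

MCS and ClinSep form the composite "Sepsis" group, NSC and Stable the
composite "No-Sepsis" group; NEC samples are excluded from the cellular
screen. Repeat samples within one sepsis episode are deduplicated to the
earliest draw, and flow-derived parameters whose parent gate holds fewer
than 30 events are set to missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import EVENTS_PREFIX, PARAM_PREFIX

__all__ = [
    "CategoryLabel",
    "ClassificationError",
    "classify_sample",
    "classify_samples",
    "dedup_episodes",
    "composite_groups",
    "qc_filter",
    "COMPOSITE_OF",
]

CATEGORIES = ("MCS", "ClinSep", "NSC", "Stable", "NEC")

#: Composite group of each category ("excluded" marks NEC, which is left out
#: of the cellular screen).
COMPOSITE_OF = {
    "MCS": "Sepsis",
    "ClinSep": "Sepsis",
    "NSC": "NoSepsis",
    "Stable": "NoSepsis",
    "NEC": "excluded",
}


class ClassificationError(ValueError):
    """Raised when sample metadata is contradictory or rule coverage fails."""


@dataclass
class CategoryLabel:
    category: str
    composite: str
    rationale: list[str] = field(default_factory=list)


def classify_sample(sample, *, min_criteria: int = 3, min_course_days: float = 5.0) -> CategoryLabel:
    """Assign one clinical category to a single sample (mapping or Series).

    Raises :class:`ClassificationError` on contradictory metadata (an
    organism named without a positive culture) or when no rule fires.
    """
    s = dict(sample)
    trail: list[str] = []

    culture = str(s.get("culture_result", "none"))
    organism = str(s.get("organism", "") or "")
    positive = culture.startswith("positive")
    suspected = str(s.get("draw_reason", "routine")) == "suspected_sepsis"

    conflicts = []
    if organism and organism != "-" and not positive:
        conflicts.append(f"organism {organism!r} named but culture_result={culture!r}")
    if positive and not (organism and organism != "-"):
        conflicts.append("positive culture without an organism")
    if conflicts:
        raise ClassificationError("; ".join(conflicts))

    nec_stage = str(s.get("nec_stage", "none"))
    if nec_stage in ("II", "III"):
        trail.append(f"NEC: Bell's stage {nec_stage}")
        return CategoryLabel("NEC", COMPOSITE_OF["NEC"], trail)

    is_cons = bool(s.get("organism_is_cons", False))
    cons_ok = bool(s.get("cons_supporting_evidence", False))
    if positive:
        if not is_cons:
            trail.append(f"MCS: contemporaneous positive culture ({organism})")
            return CategoryLabel("MCS", COMPOSITE_OF["MCS"], trail)
        if cons_ok:
            trail.append("MCS: CoNS culture with supporting clinical evidence")
            return CategoryLabel("MCS", COMPOSITE_OF["MCS"], trail)
        trail.append("CoNS culture without supporting evidence: treated as contaminant")

    # A CoNS contaminant is treated as an effectively negative culture below.
    criteria = int(s.get("clinical_criteria_met", 0))
    course = float(s.get("antibiotic_course_days", 0.0))
    stopped = bool(s.get("antibiotics_stopped_within_72h", False))

    if suspected:
        if criteria >= min_criteria and course >= min_course_days:
            trail.append(
                f"ClinSep: suspicion, negative cultures, {criteria} criteria, "
                f"{course:g}-day antibiotic course"
            )
            return CategoryLabel("ClinSep", COMPOSITE_OF["ClinSep"], trail)
        if stopped:
            trail.append("NSC: suspicion, negative cultures, antibiotics stopped within 72 h")
            return CategoryLabel("NSC", COMPOSITE_OF["NSC"], trail)
        raise ClassificationError(
            "suspected sample matches neither ClinSep (needs >=3 criteria and >=5-day course: "
            f"got {criteria} criteria, {course:g} days) nor NSC (antibiotics not stopped within 72 h)"
        )

    trail.append("Stable: routine draw, no clinical suspicion")
    return CategoryLabel("Stable", COMPOSITE_OF["Stable"], trail)


def classify_samples(samples: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Classify every row; returns a copy with ``category``, ``composite``
    and ``rationale`` columns appended."""
    labels = [classify_sample(row, **kwargs) for _, row in samples.iterrows()]
    out = samples.copy()
    out["category"] = [lab.category for lab in labels]
    out["composite"] = [lab.composite for lab in labels]
    out["rationale"] = ["; ".join(lab.rationale) for lab in labels]
    return out


def dedup_episodes(samples: pd.DataFrame) -> pd.DataFrame:
    """Keep only the earliest sample of each episode.

    Rows without an episode id are untouched. Two samples of one episode on
    the same day keep the first in input order (with a warning).
    """
    has_ep = samples["episode_id"].fillna("").astype(str) != ""
    keep = pd.Series(True, index=samples.index)
    for ep_id, grp in samples.loc[has_ep].groupby("episode_id", sort=False):
        first_day = grp["postnatal_day"].min()
        winners = grp.index[grp["postnatal_day"] == first_day]
        if len(winners) > 1:
            warnings.warn(
                f"episode {ep_id}: {len(winners)} samples on day {first_day}; "
                "keeping the first in input order",
                stacklevel=2,
            )
        keep.loc[grp.index] = False
        keep.loc[winners[0]] = True
    return samples.loc[keep].copy()


def composite_groups(labeled: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition classified samples into composite groups.

    Returns ``{"Sepsis": ..., "NoSepsis": ..., "excluded": ...}`` — a
    partition of the input (NEC rows land in ``excluded``).
    """
    if "category" not in labeled.columns:
        raise ValueError("samples must be classified first (missing 'category' column)")
    comp = labeled["category"].map(COMPOSITE_OF)
    if comp.isna().any():
        bad = sorted(labeled.loc[comp.isna(), "category"].unique())
        raise ClassificationError(f"unknown categories: {bad}")
    return {
        "Sepsis": labeled.loc[comp == "Sepsis"].copy(),
        "NoSepsis": labeled.loc[comp == "NoSepsis"].copy(),
        "excluded": labeled.loc[comp == "excluded"].copy(),
    }


def qc_filter(samples: pd.DataFrame, min_events: int = 30) -> pd.DataFrame:
    """Blank flow parameters whose parent gate held fewer than ``min_events``.

    Missingness is per parameter per sample (pairwise): a blanked value is
    simply absent from any later test using that parameter, while the
    sample's other parameters survive.
    """
    out = samples.copy()
    for col in out.columns:
        if not col.startswith(PARAM_PREFIX):
            continue
        events_col = EVENTS_PREFIX + col[len(PARAM_PREFIX):]
        if events_col in out.columns:
            low = out[events_col] < min_events
            out.loc[low, col] = np.nan
    return out
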