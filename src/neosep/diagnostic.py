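"""Rule-out diagnostics combining CRP and plasma amphiregulin.

The evaluation set is every sample drawn within 48 h of a blood culture
taken for suspected sepsis (categories NSC, ClinSep, MCS). The combined
test calls a sample negative only when CRP <= 10 mg/L AND amphiregulin
<= 38.7 pg/mL, positive when either analyte is raised; the amphiregulin
cutoff derives from the maximal Youden index on the ROC curve. Confusion
metrics are kept as exact rationals (truth positive = ClinSep or MCS,
negative = NSC) and predictive values can be re-projected to an external
prevalence by Bayes' rule — the clinical question being how safely the
test rules sepsis out in less-preterm populations where prevalence is
lower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticReport",
    "window_filter",
    "roc_points",
    "youden_threshold",
    "combined_test",
    "confusion_metrics",
    "adjust_prevalence",
    "single_analyte_report",
    "solve_confusion_from_printed",
    "round2",
]

POSITIVE_CATEGORIES = ("ClinSep", "MCS")
NEGATIVE_CATEGORIES = ("NSC",)


def round2(x: float) -> float:
    """Presentation rounding: two decimals, half away from zero."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class DiagnosticReport:
    """Confusion counts and derived accuracy measures for one test rule."""

    tp: int
    fp: int
    tn: int
    fn: int
    crp_cut: float | None = None
    areg_cut: float | None = None
    n_not_evaluable: int = 0
    adjusted_prior: float | None = None
    adjusted_ppv: float | None = None
    adjusted_npv: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def _frac(self, num: int, den: int) -> Fraction | None:
        return None if den == 0 else Fraction(num, den)

    @property
    def sensitivity(self) -> Fraction | None:
        return self._frac(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Fraction | None:
        return self._frac(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Fraction | None:
        return self._frac(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Fraction | None:
        return self._frac(self.tn, self.tn + self.fn)

    @property
    def prevalence(self) -> Fraction | None:
        return self._frac(self.tp + self.fn, self.n)

    def to_dict(self, rounded: bool = True) -> dict:
        conv = (lambda v: None if v is None else round2(float(v))) if rounded else (
            lambda v: None if v is None else float(v)
        )
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "n_not_evaluable": self.n_not_evaluable,
            "crp_cut": self.crp_cut,
            "areg_cut": self.areg_cut,
            "sensitivity": conv(self.sensitivity),
            "specificity": conv(self.specificity),
            "ppv": conv(self.ppv),
            "npv": conv(self.npv),
            "prevalence": conv(self.prevalence),
            "adjusted_prior": self.adjusted_prior,
            "adjusted_ppv": None if self.adjusted_ppv is None else conv(self.adjusted_ppv),
            "adjusted_npv": None if self.adjusted_npv is None else conv(self.adjusted_npv),
        }


def window_filter(labeled: pd.DataFrame, hours: float = 48.0) -> pd.DataFrame:
    """Restrict to suspected-sepsis samples within the review window.

    Keeps NSC/ClinSep/MCS samples whose draw lies within ``hours`` of the
    blood culture; samples without a culture timestamp are excluded.
    """
    if "category" not in labeled.columns:
        raise ValueError("samples must be classified first")
    cat_ok = labeled["category"].isin(POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES)
    delta = pd.to_numeric(labeled["hours_from_culture"], errors="coerce")
    return labeled.loc[cat_ok & delta.notna() & (delta.abs() <= hours)].copy()


def roc_points(values, labels) -> pd.DataFrame:
    """ROC coordinates over the observed candidate thresholds.

    ``labels`` are booleans (True = diseased); a sample is called positive
    when its value is strictly greater than the threshold, so higher values
    are more disease-like. The unique observed values serve as candidate
    thresholds, with -inf/+inf sentinels supplying the (1, 0) and (0, 1)
    endpoints.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    thresholds = np.concatenate([[-np.inf], np.unique(values)])
    rows = []
    for t in thresholds:
        call_pos = values > t
        sens = float(np.sum(call_pos & labels)) / n_pos
        spec = float(np.sum(~call_pos & ~labels)) / n_neg
        rows.append((t, sens, spec))
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


def roc_auc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under the curve in (1-specificity, sensitivity)."""
    fpr = (1.0 - roc["specificity"].to_numpy())[::-1]
    tpr = roc["sensitivity"].to_numpy()[::-1]
    return float(np.trapezoid(tpr, fpr))


def youden_threshold(roc: pd.DataFrame) -> tuple[float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Only finite (observed) candidate thresholds compete; ties are broken
    toward the lowest threshold, favouring sensitivity — the natural choice
    for a rule-out test.
    """
    finite = roc.loc[np.isfinite(roc["threshold"])]
    if len(finite) == 0:
        raise ValueError("ROC has no finite candidate thresholds")
    j = finite["sensitivity"] + finite["specificity"] - 1.0
    j_max = float(j.max())
    winners = finite.loc[j >= j_max - 1e-12, "threshold"]
    return float(winners.min()), j_max


def combined_test(
    crp, areg, crp_cut: float = 10.0, areg_cut: float = 38.7
) -> np.ndarray:
    """Apply the combined CRP/amphiregulin rule elementwise.

    Negative iff CRP <= ``crp_cut`` AND AREG <= ``areg_cut``; positive when
    either analyte exceeds its cutoff. A missing analyte yields
    "not_evaluable" — never a silent negative.
    """
    crp = np.asarray(crp, dtype=float)
    areg = np.asarray(areg, dtype=float)
    if crp.shape != areg.shape:
        raise ValueError("crp and areg must align")
    out = np.where(
        np.isnan(crp) | np.isnan(areg),
        "not_evaluable",
        np.where((crp > crp_cut) | (areg > areg_cut), "positive", "negative"),
    )
    return out


def confusion_metrics(
    calls, truth_labels, crp_cut: float | None = None, areg_cut: float | None = None
) -> DiagnosticReport:
    """Tally calls against clinical truth into a :class:`DiagnosticReport`.

    Truth positive = ClinSep or MCS, negative = NSC. Not-evaluable calls
    are excluded from the 2x2 but counted.
    """
    calls = np.asarray(calls, dtype=object)
    truth_labels = np.asarray(truth_labels, dtype=object)
    if calls.shape != truth_labels.shape:
        raise ValueError("calls and truth labels must align")
    if calls.size == 0:
        raise ValueError("empty input")
    unexpected = set(truth_labels) - set(POSITIVE_CATEGORIES) - set(NEGATIVE_CATEGORIES)
    if unexpected:
        raise ValueError(f"unexpected truth labels: {sorted(map(str, unexpected))}")
    truth_pos = np.isin(truth_labels, POSITIVE_CATEGORIES)
    ne = calls == "not_evaluable"
    pos = calls == "positive"
    tp = int(np.sum(pos & truth_pos & ~ne))
    fp = int(np.sum(pos & ~truth_pos & ~ne))
    fn = int(np.sum(~pos & truth_pos & ~ne))
    tn = int(np.sum(~pos & ~truth_pos & ~ne))
    return DiagnosticReport(
        tp=tp, fp=fp, tn=tn, fn=fn, crp_cut=crp_cut, areg_cut=areg_cut,
        n_not_evaluable=int(ne.sum()),
    )


def adjust_prevalence(sens: float, spec: float, prior: float) -> tuple[float, float]:
    """Project PPV and NPV to an external pre-test probability (Bayes).

    Returns ``(ppv, npv)``. Degenerate denominators (a prior of 0 or 1
    combined with perfect error rates) resolve to their defined limits.
    """
    for name, v in (("sens", sens), ("spec", spec), ("prior", prior)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    ppv_den = sens * prior + (1.0 - spec) * (1.0 - prior)
    npv_den = spec * (1.0 - prior) + (1.0 - sens) * prior
    ppv = sens * prior / ppv_den if ppv_den > 0 else 1.0
    npv = spec * (1.0 - prior) / npv_den if npv_den > 0 else 1.0
    return float(ppv), float(npv)


def single_analyte_report(
    values, truth_labels, cutoff: float, direction: str = ">"
) -> DiagnosticReport:
    """Diagnostic report for one analyte with a single cutoff.

    ``direction=">"`` calls a sample positive when the value exceeds the
    cutoff (CRP, AREG); ``"<"`` when it falls below. Missing values are
    not-evaluable.
    """
    values = np.asarray(values, dtype=float)
    if direction == ">":
        pos = values > cutoff
    elif direction == "<":
        pos = values < cutoff
    else:
        raise ValueError("direction must be '>' or '<'")
    calls = np.where(np.isnan(values), "not_evaluable", np.where(pos, "positive", "negative"))
    return confusion_metrics(calls, truth_labels)


def solve_confusion_from_printed(
    sensitivity_2dp: float, npv_2dp: float, n_pos: int, n_neg: int
) -> DiagnosticReport:
    """Recover the integer 2x2 table behind printed accuracy figures.

    Searches TP in 0..n_pos and TN in 0..n_neg for tables whose rounded
    sensitivity and NPV reproduce the printed two-decimal values; when
    rounding admits several tables, the one whose unrounded metrics lie
    closest to the printed figures wins.
    """
    best = None
    best_err = math.inf
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        sens = tp / n_pos
        if round2(sens) != round2(sensitivity_2dp):
            continue
        for tn in range(n_neg + 1):
            if tn + fn == 0:
                continue
            npv = tn / (tn + fn)
            if round2(npv) != round2(npv_2dp):
                continue
            err = abs(sens - sensitivity_2dp) + abs(npv - npv_2dp)
            if err < best_err:
                best_err = err
                best = (tp, fn, tn, n_neg - tn)
    if best is None:
        raise ValueError("no integer confusion matrix reproduces the printed values")
    tp, fn, tn, fp = best
    return DiagnosticReport(tp=tp, fp=fp, tn=tn, fn=fn)
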