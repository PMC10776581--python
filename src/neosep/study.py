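"""Published cohort-level figures used as fixed inputs.

These are transcribed printed values — per-baby clinical characteristics
(``data/table1.tsv``) and the cohort-level counts and accuracy figures the
analyses reproduce arithmetically. The per-baby assay columns of the
printed table could not all be transcribed unambiguously; the
``flow_cohort`` flag marks the babies whose samples feed the
flow-cytometry analyses (the A-series cohort plus the one B-series baby
contributing NEC samples).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "FLOW_CATEGORY_COUNTS",
    "PLASMA_CATEGORY_COUNTS",
    "COMBINED_TEST_PRINTED",
    "CRP_ALONE_PRINTED",
    "AREG_ALONE_PRINTED",
    "AREG_BASELINE",
    "CRP_CUTOFF_MG_PER_L",
    "AREG_CUTOFF_PG_PER_ML",
    "EXTERNAL_PRIOR_GT28W",
    "PRINTED_ADJUSTED_NPV",
    "load_table1",
    "flow_cohort_table",
]

#: Per-category flow-cytometry sample counts (PBMC immunophenotyping).
FLOW_CATEGORY_COUNTS = {"MCS": 26, "ClinSep": 21, "NSC": 22, "Stable": 82, "NEC": 6}

#: Per-category plasma (soluble-analyte) sample counts.
PLASMA_CATEGORY_COUNTS = {"MCS": 26, "ClinSep": 48, "NSC": 28, "Stable": 111, "NEC": 6}

#: Printed accuracy of the combined CRP/amphiregulin rule on the 48-h
#: suspected-sepsis window set (33 sepsis, 28 ruled-out samples).
COMBINED_TEST_PRINTED = {"sensitivity": 0.97, "npv": 0.94, "n_pos": 33, "n_neg": 28}
CRP_ALONE_PRINTED = {"sensitivity": 0.55, "npv": 0.65}
AREG_ALONE_PRINTED = {"sensitivity": 0.88, "npv": 0.79}

#: Stable-baby plasma amphiregulin baseline (pg/mL).
AREG_BASELINE = {"median": 19.0, "q1": 14.0, "q3": 27.9}

CRP_CUTOFF_MG_PER_L = 10.0
AREG_CUTOFF_PG_PER_ML = 38.7

#: Estimated prevalence of late-onset suspected/confirmed infection in
#: babies born after 28 weeks, and the NPV the combined test projects to
#: at that prior.
EXTERNAL_PRIOR_GT28W = 0.22
PRINTED_ADJUSTED_NPV = 0.99

MEDIAN_GA_FLOW_COHORT_WEEKS = 24


def load_table1() -> pd.DataFrame:
    """Per-baby clinical characteristics table."""
    with resources.files("neosep.data").joinpath("table1.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def flow_cohort_table() -> pd.DataFrame:
    """Rows of babies contributing to the flow-cytometry analyses."""
    t = load_table1()
    return t.loc[t["flow_cohort"] == 1].copy()
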