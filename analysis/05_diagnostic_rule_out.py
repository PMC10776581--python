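#!/usr/bin/env python
"""Evaluate the combined CRP/amphiregulin rule-out test.

Restricts to samples within 48 h of a blood culture for suspected sepsis,
derives the amphiregulin threshold from the maximal Youden index on the ROC
curve, applies the combined rule (negative only when CRP <= 10 mg/L AND
AREG <= cutoff), and reports confusion metrics with the NPV re-projected to
an external prevalence of 0.22 (babies born after 28 weeks).
"""

import argparse
import json
from pathlib import Path

from neosep.diagnostic import (
    adjust_prevalence,
    combined_test,
    confusion_metrics,
    roc_points,
    single_analyte_report,
    window_filter,
    youden_threshold,
)
from neosep.io import read_samples


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--prior", type=float, default=0.22)
    args = ap.parse_args()

    deduped = read_samples(args.out / "classified_dedup.tsv")
    window = window_filter(deduped, hours=48.0)
    truth_pos = window["category"].isin(["MCS", "ClinSep"]).to_numpy()
    print(
        f"48-h window set: n={len(window)} "
        f"(sepsis={int(truth_pos.sum())}, ruled-out={int((~truth_pos).sum())})"
    )

    roc = roc_points(window["areg_pg_per_mL"].to_numpy(), truth_pos)
    roc.to_csv(args.out / "roc_areg.tsv", sep="\t", index=False)
    areg_cut, j = youden_threshold(roc)
    print(f"amphiregulin threshold at maximal Youden J={j:.2f}: {areg_cut:.1f} pg/mL")

    calls = combined_test(window["crp_mg_per_L"], window["areg_pg_per_mL"], areg_cut=areg_cut)
    report = confusion_metrics(calls, window["category"], crp_cut=10.0, areg_cut=areg_cut)
    report.adjusted_prior = args.prior
    report.adjusted_ppv, report.adjusted_npv = adjust_prevalence(
        float(report.sensitivity), float(report.specificity), args.prior
    )
    crp_only = single_analyte_report(window["crp_mg_per_L"].to_numpy(), window["category"], 10.0)
    areg_only = single_analyte_report(
        window["areg_pg_per_mL"].to_numpy(), window["category"], areg_cut
    )
    out = {
        "combined": report.to_dict(),
        "crp_alone": crp_only.to_dict(),
        "areg_alone": areg_only.to_dict(),
    }
    with open(args.out / "diagnostic_report.json", "w") as fh:
        json.dump(out, fh, indent=1)
    d = report.to_dict()
    print(
        f"combined rule: sens={d['sensitivity']} spec={d['specificity']} "
        f"ppv={d['ppv']} npv={d['npv']}; NPV at prior {args.prior} = {d['adjusted_npv']}"
    )
    print(
        f"single analytes: CRP sens={crp_only.to_dict()['sensitivity']} "
        f"npv={crp_only.to_dict()['npv']}; AREG sens={areg_only.to_dict()['sensitivity']} "
        f"npv={areg_only.to_dict()['npv']}"
    )


if __name__ == "__main__":
    main()
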