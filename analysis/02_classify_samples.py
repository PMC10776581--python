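#!/usr/bin/env python
"""Assign each blood sample to its clinical category and build the
composite analysis groups.

Applies the five-category rule table (NEC > MCS > ClinSep > NSC > Stable,
with CoNS validity), the 30-event flow QC floor, and first-sample-per-
episode deduplication; then reports the composite Sepsis / No-Sepsis split
entering the cellular screen.
"""

import argparse
from pathlib import Path

from neosep.classify import classify_samples, composite_groups, dedup_episodes, qc_filter
from neosep.io import read_samples, write_samples


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    samples = read_samples(args.out / "samples.tsv")
    labeled = qc_filter(classify_samples(samples))
    deduped = dedup_episodes(labeled)
    write_samples(deduped, args.out / "classified_dedup.tsv")
    labeled[["baby_id", "postnatal_day", "category", "composite", "rationale"]].to_csv(
        args.out / "rules_report.tsv", sep="\t", index=False
    )

    counts = deduped["category"].value_counts().to_dict()
    groups = composite_groups(deduped)
    print(f"categories (post-dedup): {counts}")
    print(
        f"composite groups: Sepsis={len(groups['Sepsis'])}, "
        f"NoSepsis={len(groups['NoSepsis'])}, NEC excluded={len(groups['excluded'])} "
        f"({len(labeled) - len(deduped)} repeat-episode samples removed)"
    )


if __name__ == "__main__":
    main()
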