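"""End-to-end orchestration: simulate -> classify -> screen -> pair ->
diagnose -> degsets, with provenance logging.

Every stage writes delimited-text tables into the artifact directory; a
``provenance.json`` records the configuration, its hash, the seed and the
package version, so each reported number is reproducible from config+seed
alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_samples, composite_groups, dedup_episodes, qc_filter
from .config import PipelineConfig
from .degsets import filter_hemoglobin, set_partition, threshold_degs
from .diagnostic import (
    adjust_prevalence,
    combined_test,
    confusion_metrics,
    roc_points,
    single_analyte_report,
    window_filter,
    youden_threshold,
)
from .io import config_hash, write_samples, write_truth
from .pairing import match_triplets, rebound_report, triplet_table
from .screen import age_bracket_analysis, stratified_screen, volcano_screen
from .simulate import generate_cohort, generate_deg_table

__all__ = ["run_pipeline", "ALL_STAGES", "StageError"]

ALL_STAGES = ("simulate", "classify", "screen", "pair", "diagnose", "degsets")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path = "artifacts",
    stages: tuple[str, ...] = ALL_STAGES,
    samples: pd.DataFrame | None = None,
) -> Path:
    """Run the requested stages and return the artifact directory.

    ``samples`` may supply a pre-existing sample table instead of the
    ``simulate`` stage. Later stages require the outputs of earlier ones
    within the same call.
    """
    config = config or PipelineConfig()
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    truth = None
    labeled = deduped = None
    try:
        if "simulate" in stages:
            cohort_cfg = config.cohort
            if config.seed != cohort_cfg.seed:
                d = cohort_cfg.to_dict()
                d["seed"] = config.seed
                from .config import CohortConfig

                cohort_cfg = CohortConfig.from_dict(d)
            samples, truth = generate_cohort(cohort_cfg)
            write_samples(samples, out / "samples.tsv")
            write_truth(truth, out / "ground_truth.json")
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'simulate' failed: {e}") from e

    if samples is None and set(stages) - {"degsets"}:
        raise StageError("no sample table: run the simulate stage or pass samples=")

    try:
        if "classify" in stages:
            labeled = classify_samples(samples)
            labeled = qc_filter(labeled, min_events=config.qc_min_events)
            write_samples(labeled, out / "classified.tsv")
            labeled[["baby_id", "postnatal_day", "category", "composite", "rationale"]].to_csv(
                out / "rules_report.tsv", sep="\t", index=False
            )
            deduped = dedup_episodes(labeled)
            write_samples(deduped, out / "classified_dedup.tsv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'classify' failed: {e}") from e

    try:
        if "screen" in stages:
            if deduped is None:
                raise ValueError("screen requires the classify stage")
            analysed = composite_groups(deduped)
            flow_set = pd.concat([analysed["Sepsis"], analysed["NoSepsis"]])
            volcano = volcano_screen(
                flow_set, fc_threshold=config.fc_threshold, alpha=config.alpha
            )
            volcano.to_csv(out / "volcano_screen.tsv", sep="\t", index=False)
            brackets = age_bracket_analysis(flow_set, bracket_days=config.bracket_days)
            brackets.to_csv(out / "age_brackets.tsv", sep="\t", index=False)
            for name, res in stratified_screen(
                flow_set,
                boundary_day=config.age_strata_boundary_day,
                fc_threshold=config.fc_threshold,
                alpha=config.alpha,
            ).items():
                safe = name.replace(">", "gt").replace("-", "_")
                res.to_csv(out / f"screen_stratum_{safe}.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'screen' failed: {e}") from e

    try:
        if "pair" in stages:
            if deduped is None:
                raise ValueError("pair requires the classify stage")
            triplets = match_triplets(deduped, max_gap_days=config.max_gap_days)
            triplet_table(triplets).to_csv(out / "triplets.tsv", sep="\t", index=False)
            rebound = rebound_report(triplets, deduped, min_pairs=config.min_pairs)
            rebound.to_csv(out / "rebound_report.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'pair' failed: {e}") from e

    try:
        if "diagnose" in stages:
            if deduped is None:
                raise ValueError("diagnose requires the classify stage")
            window = window_filter(deduped, hours=config.window_hours)
            calls = combined_test(
                window["crp_mg_per_L"],
                window["areg_pg_per_mL"],
                crp_cut=config.crp_cut_mg_per_L,
                areg_cut=config.areg_cut_pg_per_mL,
            )
            report = confusion_metrics(
                calls,
                window["category"],
                crp_cut=config.crp_cut_mg_per_L,
                areg_cut=config.areg_cut_pg_per_mL,
            )
            if report.sensitivity is not None and report.specificity is not None:
                ppv, npv = adjust_prevalence(
                    float(report.sensitivity), float(report.specificity), config.external_prior
                )
                report.adjusted_prior = config.external_prior
                report.adjusted_ppv, report.adjusted_npv = ppv, npv
            truth_pos = window["category"].isin(["MCS", "ClinSep"]).to_numpy()
            roc = roc_points(window["areg_pg_per_mL"].to_numpy(), truth_pos)
            roc.to_csv(out / "roc_areg.tsv", sep="\t", index=False)
            t_star, j_star = youden_threshold(roc)
            crp_only = single_analyte_report(
                window["crp_mg_per_L"].to_numpy(), window["category"], config.crp_cut_mg_per_L
            )
            areg_only = single_analyte_report(
                window["areg_pg_per_mL"].to_numpy(), window["category"], config.areg_cut_pg_per_mL
            )
            with open(out / "diagnostic_report.json", "w") as fh:
                json.dump(
                    {
                        "combined": report.to_dict(),
                        "crp_alone": crp_only.to_dict(),
                        "areg_alone": areg_only.to_dict(),
                        "areg_youden_threshold": t_star,
                        "areg_youden_J": j_star,
                        "n_window_samples": int(len(window)),
                    },
                    fh,
                    indent=1,
                )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'diagnose' failed: {e}") from e

    try:
        if "degsets" in stages:
            tables = {}
            for i, cond in enumerate(["MCS_enterobacter", "NEC_stage_II", "NEC_stage_III"]):
                tab, _ = generate_deg_table(
                    n_genes=800, n_true=80, seed=config.seed + i, condition=cond
                )
                tab.to_csv(out / f"deg_{cond}.tsv", sep="\t", index=False)
                tables[cond] = threshold_degs(
                    filter_hemoglobin(tab), alpha=config.deg_alpha, lfc=config.deg_lfc
                )
            regions = set_partition(tables)
            regions.assign(genes=regions["genes"].map(",".join)).to_csv(
                out / "deg_regions.tsv", sep="\t", index=False
            )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'degsets' failed: {e}") from e

    cfg = config.to_dict()
    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {
                "config": cfg,
                "config_hash": config_hash(cfg),
                "seed": config.seed,
                "stages": list(stages),
                "version": __version__,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return out
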