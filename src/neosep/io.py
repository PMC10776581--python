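"""Delimited-text IO for sample tables and ground-truth sidecars.

All artefacts are UTF-8 TSV with header rows (the study inputs are derived
feature tables, not instrument files) plus JSON for ground truth and
provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["write_samples", "read_samples", "write_truth", "read_truth", "config_hash"]

_BOOL_COLUMNS = (
    "resp_support",
    "antenatal_steroids",
    "organism_is_cons",
    "cons_supporting_evidence",
    "antibiotics_stopped_within_72h",
)
_STR_COLUMNS = ("organism", "episode_id", "culture_result", "nec_stage", "draw_reason")

REQUIRED_COLUMNS = (
    "baby_id",
    "postnatal_day",
    "draw_reason",
    "culture_result",
    "nec_stage",
    "episode_id",
)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    samples.to_csv(path, sep="\t", index=False)


def _parse_bool(v: str) -> bool:
    return str(v).strip().lower() in ("true", "1", "yes")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        converters={c: _parse_bool for c in _BOOL_COLUMNS},
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing required columns: {missing}")
    for c in _STR_COLUMNS:
        if c in df.columns:
            df[c] = df[c].fillna("").astype(str)
    return df


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def config_hash(config_dict: dict) -> str:
    """Stable digest of a configuration document (for provenance logs)."""
    doc = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]
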