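"""Cohort readers/writers and pipeline configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .labels import DEMOGRAPHICS, GROUPS, METRICS, VOLUMES

__all__ = ["PipelineConfig", "SchemaError", "read_table", "read_cohort_tables",
           "write_table"]

log = logging.getLogger("rptfusion")

RESPONSE_COLUMNS = ("participant_id", "category", "picture", "valence", "keypresses")
PARTICIPANT_REQUIRED = ("participant_id", "group")


class SchemaError(ValueError):
    """An input table is missing required structure; message names it."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline switches.

    Defaults follow the analysis design this package implements: alpha=.05
    throughout, Cook's-distance outlier removal at the Cook-Weisberg
    F-median cutoff (single worst point at a time), BH q-values per (group, volume)
    family, k=5 Mahalanobis kNN with training-fold priors.
    """

    responses_path: str | None = None
    participants_path: str | None = None
    output_dir: str = "rptfusion_output"
    volumes: tuple[str, ...] = VOLUMES
    metrics: tuple[str, ...] = METRICS
    alpha: float = 0.05
    cooks: bool = True
    cooks_rule: str = "classical"
    bh_method: str = "bh"
    include_zeros: bool = False
    value_form: str = "log"
    heatmap_significant_only: bool = False
    exact_proportion_test: bool = False
    knn_k: int = 5
    knn_refit_transform: bool = True
    seed: int = 0
    log_level: str = "INFO"
    simulate: bool = False

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.volumes or len(set(self.volumes)) != len(self.volumes):
            raise ValueError("volumes must be non-empty and unique")
        if not self.metrics or len(set(self.metrics)) != len(self.metrics):
            raise ValueError("metrics must be non-empty and unique")
        if self.cooks_rule not in ("classical", "4/n"):
            raise ValueError("cooks_rule must be 'classical' or '4/n'")
        if self.bh_method not in ("bh", "holm"):
            raise ValueError("bh_method must be 'bh' or 'holm'")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV or XLSX table by extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def _require(df: pd.DataFrame, cols, filename: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{filename}: missing required column(s) {missing}"
        )


def read_cohort_tables(
    responses_path: str | Path,
    participants_path: str | Path,
    *,
    volumes=VOLUMES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and schema-validate the raw cohort tables.

    The response table needs columns participant_id / category / picture /
    valence (inc|dec) / keypresses; the participant table needs
    participant_id, group (CTRL|MDD|CD), the demographics and the volume
    columns.  Categorical levels are whitespace-normalized.  Raises
    :class:`SchemaError` naming the offending file and column.
    """
    responses = read_table(responses_path)
    participants = read_table(participants_path)
    _require(responses, RESPONSE_COLUMNS, str(responses_path))
    _require(participants, PARTICIPANT_REQUIRED + DEMOGRAPHICS, str(participants_path))
    _require(participants, volumes, str(participants_path))

    responses = responses.copy()
    responses["valence"] = responses["valence"].astype(str).str.strip().str.lower()
    bad = set(responses["valence"]) - {"inc", "dec"}
    if bad:
        raise SchemaError(
            f"{responses_path}: valence must be 'inc' or 'dec', found {sorted(bad)}"
        )
    if (responses["keypresses"] < 0).any():
        raise SchemaError(f"{responses_path}: keypresses must be >= 0")

    participants = participants.copy()
    participants["group"] = participants["group"].astype(str).str.strip()
    bad = set(participants["group"]) - set(GROUPS)
    if bad:
        raise SchemaError(
            f"{participants_path}: group must be one of {GROUPS}, found {sorted(bad)}"
        )
    rp = set(responses["participant_id"])
    pp = set(participants["participant_id"])
    if rp != pp:
        raise SchemaError(
            "participant ids differ between tables: "
            f"{sorted(rp ^ pp)[:5]}{'...' if len(rp ^ pp) > 5 else ''}"
        )
    return responses, participants
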