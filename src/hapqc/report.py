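"""Batch survey reports: per-genome completeness model columns and verdicts.

Input schema (TSV): genome, r_percent, s_percent, observed_percent, and
optionally assembly_size_mb and haploid_size_mb. Output adds
maximum_percent, expected_percent, deviation_pp, size_ratio and verdict.
Model columns are formatted at 2 decimal places; the observed column is
echoed at its input precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .completeness import (
    DEFAULT_SIZE_BAND,
    DEFAULT_TOLERANCE_PP,
    CompletenessInputs,
    purging_verdict,
)

__all__ = ["REQUIRED_COLUMNS", "load_batch", "batch_report", "render_tsv", "render_json"]

REQUIRED_COLUMNS = ["genome", "r_percent", "s_percent", "observed_percent"]
OPTIONAL_COLUMNS = ["assembly_size_mb", "haploid_size_mb"]


def load_batch(path: str | Path) -> pd.DataFrame:
    """Read a batch TSV, keeping original string forms for echoing."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _parse_percent(df: pd.DataFrame, row: int, col: str) -> float:
    raw = df.at[row, col]
    genome = df.at[row, "genome"]
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValueError(f"row {row + 1} ({genome}): {col}={raw!r} is not a number") from None
    return value / 100.0


def _parse_optional_mb(df: pd.DataFrame, row: int, col: str) -> float | None:
    if col not in df.columns:
        return None
    raw = df.at[row, col]
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        return float(raw) * 1e6
    except ValueError:
        genome = df.at[row, "genome"]
        raise ValueError(f"row {row + 1} ({genome}): {col}={raw!r} is not a number") from None


def batch_report(
    df: pd.DataFrame,
    k: int = 21,
    tolerance_pp: float = DEFAULT_TOLERANCE_PP,
    size_band: tuple[float, float] = DEFAULT_SIZE_BAND,
) -> pd.DataFrame:
    """Compute model columns and verdicts for every row of a batch table."""
    out = df.copy()
    maxima, expecteds, deviations, ratios, verdicts = [], [], [], [], []
    for i in range(len(df)):
        inputs = CompletenessInputs(
            heterozygosity_r=_parse_percent(df, i, "r_percent"),
            prepurge_completeness_s=_parse_percent(df, i, "s_percent"),
            observed_completeness=_parse_percent(df, i, "observed_percent"),
            k=k,
            assembly_size_bp=_parse_optional_mb(df, i, "assembly_size_mb"),
            haploid_size_bp=_parse_optional_mb(df, i, "haploid_size_mb"),
        )
        try:
            rep = purging_verdict(inputs, tolerance_pp=tolerance_pp, size_band=size_band)
        except ValueError as exc:
            raise ValueError(f"row {i + 1} ({df.at[i, 'genome']}): {exc}") from None
        maxima.append(rep.maximum * 100.0)
        expecteds.append(rep.expected * 100.0)
        deviations.append(rep.deviation_pp)
        ratios.append(rep.size_ratio)
        verdicts.append(rep.verdict)
    out["maximum_percent"] = maxima
    out["expected_percent"] = expecteds
    out["deviation_pp"] = deviations
    out["size_ratio"] = ratios
    out["verdict"] = verdicts
    return out


def render_tsv(report: pd.DataFrame) -> str:
    """Stable TSV rendering: model columns at 2 d.p., observed echoed as-is."""
    df = report.copy()
    for col in ("maximum_percent", "expected_percent", "deviation_pp"):
        df[col] = df[col].map(lambda v: f"{v:.2f}")
    df["size_ratio"] = df["size_ratio"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.2f}"
    )
    return df.to_csv(sep="\t", index=False)


def render_json(report: pd.DataFrame) -> str:
    records = []
    for rec in report.to_dict(orient="records"):
        clean = {
            key: (None if isinstance(val, float) and math.isnan(val) else val)
            for key, val in rec.items()
        }
        records.append(clean)
    return json.dumps(records, indent=2)
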