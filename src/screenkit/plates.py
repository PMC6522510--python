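"""Plate data model, IO, normalization, percent-inhibition scoring, and QC.

Raw luminescence from 384-well viability plates is log10-transformed, then
anchored to the per-plate controls:

    percent inhibition = 100 * (sample - neg_mean) / (pos_mean - neg_mean)

where the negative controls are DMSO-only wells (no effect, inhibition 0) and
the positive controls are cycloheximide-treated wells (full kill, inhibition
100).  Values outside [0, 100] are retained, never clipped.  Percent activity
is the complementary scale, ``100 - inhibition``.  Plate quality is gated by
the Z'-factor computed on the same (log10 by default) scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._errors import DataError, DegeneratePlateError

__all__ = [
    "PLATE_COLUMNS",
    "ROLES",
    "ControlStats",
    "QCReport",
    "read_plate_table",
    "write_plate_table",
    "log10_normalize",
    "percent_inhibition",
    "percent_activity",
    "control_stats",
    "normalize_plates",
    "plate_qc",
]

PLATE_COLUMNS = [
    "plate_id", "well", "row", "col", "cell_line", "compound_id",
    "concentration_M", "replicate", "luminescence", "role",
]
ROLES = ("sample", "neg_control", "pos_control")


@dataclass(frozen=True)
class ControlStats:
    """Per-plate control summary on the normalization scale."""

    plate_id: str
    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float
    n_neg: int
    n_pos: int


@dataclass(frozen=True)
class QCReport:
    """Plate-level assay diagnostics (Z'-factor gate)."""

    plate_id: str
    z_prime: float
    signal_window: float
    passed: bool


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _validate_plate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"plate table is missing columns: {missing}")
    bad_role = df.loc[~df["role"].isin(ROLES)]
    if len(bad_role):
        rows = bad_role.index[:5].tolist()
        raise DataError(
            f"invalid role values {sorted(bad_role['role'].unique())} at rows {rows}; "
            f"allowed roles are {ROLES}"
        )
    lum = pd.to_numeric(df["luminescence"], errors="coerce")
    if lum.isna().any():
        rows = df.index[lum.isna()][:5].tolist()
        raise DataError(f"non-numeric luminescence at rows {rows}")
    nonpos = df.loc[lum <= 0]
    if len(nonpos):
        wells = nonpos[["plate_id", "well"]].astype(str).agg("/".join, axis=1).tolist()[:5]
        raise DataError(f"luminescence must be positive for normalization; offending wells: {wells}")
    dup = df.duplicated(subset=["plate_id", "well", "replicate"])
    if dup.any():
        keys = df.loc[dup, ["plate_id", "well"]].astype(str).agg("/".join, axis=1).tolist()[:5]
        raise DataError(f"duplicate (plate, well, replicate) keys: {keys}")
    samp = df["role"] == "sample"
    conc = pd.to_numeric(df["concentration_M"], errors="coerce")
    if (samp & ~(conc > 0)).any():
        raise DataError("sample wells must carry a positive concentration_M")
    out = df.copy()
    out["luminescence"] = lum
    return out


def read_plate_table(path) -> pd.DataFrame:
    """Read and validate a long-format plate CSV (one row per well)."""
    df = pd.read_csv(path)
    if "compound_id" in df.columns:
        df["compound_id"] = df["compound_id"].fillna("").astype(str)
    if df.empty and set(PLATE_COLUMNS) <= set(df.columns):
        return df
    return _validate_plate_frame(df)


def write_plate_table(measurements: pd.DataFrame, path) -> None:
    """Write a validated long-format plate CSV; round-trips with
    :func:`read_plate_table`."""
    _validate_plate_frame(measurements)[PLATE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# normalization and scoring
# ---------------------------------------------------------------------------


def log10_normalize(luminescence, well: str | None = None):
    """log10-transform raw luminescence; rejects non-positive values."""
    lum = np.asarray(luminescence, dtype=float)
    if np.any(lum <= 0):
        where = f" (well {well})" if well else ""
        raise DataError(f"cannot log10-normalize non-positive luminescence{where}")
    out = np.log10(lum)
    return out if out.ndim else float(out)


def percent_inhibition(sample, controls: ControlStats):
    """Control-anchored inhibition score on the normalization scale.

    Exactly 0 at the negative-control mean and 100 at the positive-control
    mean; out-of-range values are retained."""
    span = controls.pos_mean - controls.neg_mean
    if span == 0:
        raise DegeneratePlateError(
            f"plate {controls.plate_id}: positive and negative control means coincide"
        )
    sample = np.asarray(sample, dtype=float)
    out = 100.0 * (sample - controls.neg_mean) / span
    return out if out.ndim else float(out)


def percent_activity(inhibition):
    """Percent of negative-control activity: ``100 - inhibition``."""
    arr = 100.0 - np.asarray(inhibition, dtype=float)
    return arr if arr.ndim else float(arr)


def control_stats(
    plate: pd.DataFrame, scale: Literal["log10", "raw"] = "log10"
) -> ControlStats:
    """Per-plate control means/SDs on the chosen scale (log10 by default)."""
    (plate_id,) = plate["plate_id"].unique()
    vals = plate["luminescence"].to_numpy(dtype=float)
    if scale == "log10":
        vals = log10_normalize(vals)
    elif scale != "raw":
        raise ValueError(f"unknown scale: {scale!r}")
    neg = vals[(plate["role"] == "neg_control").to_numpy()]
    pos = vals[(plate["role"] == "pos_control").to_numpy()]
    if len(neg) < 2 or len(pos) < 2:
        raise DataError(
            f"plate {plate_id}: need >=2 wells of each control role "
            f"(got {len(neg)} negative, {len(pos)} positive)"
        )
    return ControlStats(
        plate_id=str(plate_id),
        neg_mean=float(np.mean(neg)), neg_sd=float(np.std(neg, ddof=1)),
        pos_mean=float(np.mean(pos)), pos_sd=float(np.std(pos, ddof=1)),
        n_neg=len(neg), n_pos=len(pos),
    )


def normalize_plates(
    df: pd.DataFrame, scale: Literal["log10", "raw"] = "log10"
) -> pd.DataFrame:
    """Score every well against its own plate's controls.

    Adds ``log10_lum``, ``pct_inhibition`` and ``pct_activity`` columns.
    Control means are per-plate (plates may drift between runs)."""
    df = _validate_plate_frame(df)
    out = []
    for _, plate in df.groupby("plate_id", sort=False):
        stats = control_stats(plate, scale=scale)
        block = plate.copy()
        block["log10_lum"] = log10_normalize(block["luminescence"].to_numpy())
        basis = block["log10_lum"] if scale == "log10" else block["luminescence"]
        block["pct_inhibition"] = percent_inhibition(basis.to_numpy(dtype=float), stats)
        block["pct_activity"] = percent_activity(block["pct_inhibition"].to_numpy())
        out.append(block)
    return pd.concat(out, ignore_index=True)


def plate_qc(
    plate: pd.DataFrame,
    threshold: float = 0.5,
    scale: Literal["log10", "raw"] = "log10",
) -> QCReport:
    """Z'-factor assay diagnostic for one plate:

        Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|

    computed on the normalization scale; the plate passes at a configurable
    threshold (default 0.5, the conventional excellent-assay gate)."""
    stats = control_stats(plate, scale=scale)
    window = abs(stats.pos_mean - stats.neg_mean)
    if window == 0:
        raise DegeneratePlateError(
            f"plate {stats.plate_id}: zero signal window between controls"
        )
    z_prime = 1.0 - 3.0 * (stats.pos_sd + stats.neg_sd) / window
    return QCReport(
        plate_id=stats.plate_id,
        z_prime=float(z_prime),
        signal_window=float(window),
        passed=bool(z_prime >= threshold),
    )
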