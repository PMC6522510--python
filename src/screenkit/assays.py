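"""Deterministic calculations for the validation assays.

Radiotracer uptake (DPM -> pmol per mg protein via specific activity),
clearance-style transport efficiency, HPLC metabolite fractionation, and
delta-Ct relative expression / percent knockdown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._errors import DataError

__all__ = [
    "DPM_PER_CURIE",
    "TracerAssay",
    "MetabolitePanel",
    "protein_normalized_uptake",
    "uptake_rate",
    "transport_efficiency",
    "metabolite_fractions",
    "delta_ct_expression",
]

DPM_PER_CURIE = 2.22e12  # disintegrations per minute in one curie


@dataclass(frozen=True)
class TracerAssay:
    """One radiotracer uptake measurement.

    dpm: disintegrations per minute; specific_activity: Ci/mmol;
    protein: mg; exposure_time: minutes; concentration: uM.
    """

    dpm: float
    specific_activity: float
    protein: float
    exposure_time: float = np.nan
    concentration: float = np.nan

    def __post_init__(self) -> None:
        if self.dpm < 0:
            raise DataError("dpm must be >= 0")
        if self.specific_activity <= 0:
            raise DataError("specific activity must be positive")
        if self.protein <= 0:
            raise DataError("protein mass must be positive")


@dataclass(frozen=True)
class MetabolitePanel:
    """HPLC-fractionated species (parent, mono-, di-, tri-phosphate) with
    per-species DPM counts."""

    species: tuple[str, ...]
    dpm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.species) != len(self.dpm):
            raise DataError("species and dpm must have equal length")
        if any(v < 0 for v in self.dpm):
            raise DataError("dpm must be >= 0")


def protein_normalized_uptake(assay: TracerAssay) -> float:
    """Tracer uptake in pmol per mg protein.

    pmol = dpm / (2.22e12 dpm/Ci * specific_activity Ci/mmol * 1e-9 mmol/pmol),
    then normalized to total protein content."""
    pmol = assay.dpm / (DPM_PER_CURIE * assay.specific_activity * 1e-9)
    return pmol / assay.protein


def uptake_rate(
    times_min: Sequence[float], amounts_pmol_per_mg: Sequence[float]
) -> float:
    """Uptake rate (pmol mg^-1 min^-1) over the linear window: the slope of
    the least-squares line through the origin."""
    t = np.asarray(times_min, dtype=float)
    a = np.asarray(amounts_pmol_per_mg, dtype=float)
    if t.size < 2 or np.all(t == 0):
        raise DataError("uptake rate needs at least 2 nonzero time points")
    return float((t @ a) / (t @ t))


def transport_efficiency(uptake_rate_pmol_mg_min: float, concentration_um: float) -> float:
    """Clearance-form transport efficiency, uL min^-1 mg^-1.

    efficiency = uptake rate / extracellular concentration; 1 pmol mg^-1
    min^-1 per uM equals 1 uL min^-1 mg^-1.  For a saturable carrier the
    efficiency falls as the dose escalates, so a low-efficiency substrate
    cannot be rescued by concentration alone."""
    if concentration_um <= 0:
        raise DataError("concentration must be positive")
    return uptake_rate_pmol_mg_min / concentration_um


def metabolite_fractions(panel: MetabolitePanel) -> dict[str, float]:
    """Per-species fraction of total intracellular radioactivity (sums to 1)."""
    total = float(sum(panel.dpm))
    if total <= 0:
        raise DataError("total dpm must be positive for fraction computation")
    return {s: v / total for s, v in zip(panel.species, panel.dpm)}


def delta_ct_expression(
    ct_target: float,
    ct_reference: float,
    calibrator_delta: float | None = None,
) -> dict[str, float]:
    """Relative expression by the delta-Ct method.

    relative = 2^-(Ct_target - Ct_reference).  With a calibrator delta-Ct,
    fold = 2^-ddCt and knockdown% = 100 * (1 - fold): expression halves per
    threshold cycle."""
    for v in (ct_target, ct_reference):
        if not np.isfinite(v):
            raise DataError("Ct values must be finite")
    delta = ct_target - ct_reference
    out = {"delta_ct": delta, "relative_expression": 2.0 ** (-delta)}
    if calibrator_delta is not None:
        if not np.isfinite(calibrator_delta):
            raise DataError("calibrator delta-Ct must be finite")
        ddct = delta - calibrator_delta
        fold = 2.0 ** (-ddct)
        out.update(ddct=ddct, fold_change=fold, knockdown_pct=100.0 * (1.0 - fold))
    return out
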