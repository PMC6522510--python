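"""Synthetic screen generator with known ground truth.

Emulates the data-generating process the analysis assumes: 384-well viability
plates with DMSO-only negative controls and cycloheximide positive controls,
compound wells whose expected luminescence follows a per-(compound, cell
line) four-parameter log-logistic viability curve, and multiplicative
lognormal measurement noise (plate readers show roughly constant CV, so noise
is applied as ``exp(eps)`` with ``eps ~ Normal(0, sigma)`` on luminescence).

The positive-control floor defaults to 2% of the negative-control mean rather
than zero so the log10 transform is always defined.  Ground truth is written
to a sidecar table, never into the plate table the pipeline consumes.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import DataError
from .doseresponse import DoseDesign, eval_4pl
from .plates import PLATE_COLUMNS

__all__ = [
    "GroundTruthCompound",
    "SimulationConfig",
    "simulate_plate_set",
    "simulate_dose_response",
    "simulate_expression",
    "truth_table",
]


@dataclass(frozen=True)
class GroundTruthCompound:
    """Simulator truth record: per-cell-line 4PL parameters plus annotation.

    ``per_cell_line_params`` maps a cell line to ``(b, c, d, e)``: hill slope
    (<= 0), low- and high-dose asymptotes in % activity (``c >= d`` for
    viability-style decreasing curves), and EC50 in molar.
    """

    compound_id: str
    per_cell_line_params: Mapping[str, tuple[float, float, float, float]]
    mechanism_class: str = "unknown"
    fda_approved: bool | None = None
    pediatric_dose: bool | None = None
    used_in_aml: bool | None = None

    def __post_init__(self) -> None:
        for line, (b, c, d, e) in self.per_cell_line_params.items():
            if e <= 0:
                raise DataError(f"{self.compound_id}/{line}: EC50 must be positive")
            if c < d:
                raise DataError(f"{self.compound_id}/{line}: need c >= d for decreasing curves")
            if b > 0:
                raise DataError(f"{self.compound_id}/{line}: hill slope must be <= 0")

    def viability(self, cell_line: str, x) -> np.ndarray:
        """Noise-free % activity at concentration(s) x."""
        b, c, d, e = self.per_cell_line_params[cell_line]
        return eval_4pl(b, c, d, e, x)


@dataclass(frozen=True)
class SimulationConfig:
    """Plate-set simulation settings."""

    n_plates: int | None = None  # derived from well demand when None
    wells_per_plate: int = 384
    control_fraction: float = 0.1
    negative_mean_luminescence: float = 1e6
    positive_floor_fraction: float = 0.02
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.positive_floor_fraction < 1):
            raise DataError("positive_floor_fraction must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise DataError("noise_sigma must be >= 0")
        if self.negative_mean_luminescence <= 0:
            raise DataError("negative_mean_luminescence must be positive")
        if not (0 < self.control_fraction < 1):
            raise DataError("control_fraction must lie in (0, 1)")


_ROWS = string.ascii_uppercase


def _well_name(i: int, n_cols: int = 24) -> tuple[str, str, int]:
    r, c = divmod(i, n_cols)
    return f"{_ROWS[r]}{c + 1:02d}", _ROWS[r], c + 1


def simulate_plate_set(
    truths: list[GroundTruthCompound],
    config: SimulationConfig,
    design: DoseDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a plate set for every cell line named in the truth records.

    One plate block per cell line per replicate; control wells occupy the
    first (negative) and last (positive) layout positions of each plate by
    default.  Expected luminescence: ``neg_mean * noise`` for negative
    controls, ``neg_mean * floor * noise`` for positive controls, and
    ``neg_mean * V(x)/100 * noise`` for compound wells, where ``V`` is the
    truth 4PL % activity.

    Returns ``(plate_table, truth_sidecar)``; the plate table carries no
    truth columns.
    """
    if not truths:
        raise DataError("need at least one ground-truth compound")
    rng = np.random.default_rng(config.seed)
    conc = design.as_array()

    cell_lines: list[str] = []
    for t in truths:
        for line in t.per_cell_line_params:
            if line not in cell_lines:
                cell_lines.append(line)

    n_controls = max(2, int(round(config.control_fraction * config.wells_per_plate / 2)))
    capacity = config.wells_per_plate - 2 * n_controls
    if capacity < 1:
        raise DataError("wells_per_plate too small for the control layout")

    rows = []
    for line in cell_lines:
        jobs = [
            (t, x, rep)
            for t in truths
            if line in t.per_cell_line_params
            for x in conc
            for rep in range(1, design.replicates + 1)
        ]
        n_plates = int(np.ceil(len(jobs) / capacity))
        for p in range(n_plates):
            plate_id = f"{line}_P{p + 1:03d}"
            chunk = jobs[p * capacity : (p + 1) * capacity]
            layout = 0

            def emit(role, compound_id="", x=np.nan, rep=0, mean=None):
                nonlocal layout
                well, wrow, wcol = _well_name(layout)
                layout += 1
                noise = float(np.exp(rng.normal(0.0, config.noise_sigma))) if config.noise_sigma > 0 else 1.0
                rows.append({
                    "plate_id": plate_id, "well": well, "row": wrow, "col": wcol,
                    "cell_line": line, "compound_id": compound_id,
                    "concentration_M": x, "replicate": rep,
                    "luminescence": mean * noise, "role": role,
                })

            for _ in range(n_controls):
                emit("neg_control", mean=config.negative_mean_luminescence)
            for t, x, rep in chunk:
                v = float(t.viability(line, x))
                emit("sample", t.compound_id, x, rep,
                     mean=config.negative_mean_luminescence * max(v, 0.0) / 100.0)
            for _ in range(n_controls):
                emit("pos_control",
                     mean=config.negative_mean_luminescence * config.positive_floor_fraction)

    plate_table = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    return plate_table, truth_table(truths)


def truth_table(truths: list[GroundTruthCompound]) -> pd.DataFrame:
    """Sidecar ground-truth table (one row per compound x cell line)."""
    recs = []
    for t in truths:
        for line, (b, c, d, e) in t.per_cell_line_params.items():
            recs.append({
                "compound_id": t.compound_id, "cell_line": line,
                "b": b, "c": c, "d": d, "ec50_M": e,
                "mechanism_class": t.mechanism_class,
            })
    return pd.DataFrame(recs)


def simulate_dose_response(
    truth: GroundTruthCompound,
    cell_line: str,
    design: DoseDesign,
    replicates: int = 3,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a (concentration, % activity) dose-response table.

    Response = truth 4PL * exp(eps), eps ~ Normal(0, noise_sigma), floored at
    zero.  Row count is ``n_points * replicates``.
    """
    if replicates < 1:
        raise DataError("replicates must be >= 1")
    conc = design.as_array()
    if np.unique(conc).size < 2:
        raise DataError("dose design needs at least 2 distinct concentrations")
    rng = np.random.default_rng(seed)
    x = np.repeat(conc, replicates)
    v = truth.viability(cell_line, x)
    if noise_sigma > 0:
        v = v * np.exp(rng.normal(0.0, noise_sigma, size=x.size))
    v = np.clip(v, 0.0, None)
    return pd.DataFrame({
        "compound_id": truth.compound_id,
        "cell_line": cell_line,
        "concentration_M": x,
        "response_pct": v,
        "replicate": np.tile(np.arange(1, replicates + 1), conc.size),
    })


def simulate_expression(
    n_genes: int,
    groups: Mapping[str, str],
    elevated_gene: str,
    fold_change: float,
    seed: int = 0,
    elevated_group: str | None = None,
    noise_sigma: float = 0.3,
    true_correlation: float = -0.9,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a gene x sample expression table with one group-elevated gene
    plus a per-sample drug-sensitivity vector correlated with that gene.

    The elevated gene's mean is multiplied by ``fold_change`` in
    ``elevated_group`` (defaults to the first group label in sorted order);
    multiplicative lognormal noise affects both groups identically, so the
    group-mean ratio equals ``fold_change`` in expectation.  Sensitivity
    (log10 IC50-like) is constructed with population correlation
    ``true_correlation`` to the elevated gene's expression values.
    """
    if fold_change <= 0:
        raise DataError("fold_change must be positive")
    labels = set(groups.values())
    if len(labels) < 2:
        raise DataError("need at least two sample groups")
    counts = pd.Series(list(groups.values())).value_counts()
    if (counts < 2).any():
        raise DataError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    samples = list(groups)
    if elevated_group is None:
        elevated_group = sorted(labels)[0]

    genes = [f"G{i:04d}" for i in range(n_genes)]
    if elevated_gene not in genes:
        genes[0] = elevated_gene
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n_genes)
    mat = np.empty((n_genes, len(samples)))
    for j, s in enumerate(samples):
        mean = base.copy()
        gi = genes.index(elevated_gene)
        if groups[s] == elevated_group:
            mean[gi] = base[gi] * fold_change
        noise = np.exp(rng.normal(0.0, noise_sigma, size=n_genes)) if noise_sigma > 0 else 1.0
        mat[:, j] = mean * noise
    expr = pd.DataFrame(mat, index=genes, columns=samples)

    # sensitivity with the requested population correlation to the elevated gene
    x = expr.loc[elevated_gene].to_numpy()
    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    z = rng.normal(size=len(samples))
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    # orthogonalise so the *sample* correlation concentrates near the target
    z = z - (z @ xs) / (xs @ xs) * xs
    z = z / (z.std() if z.std() > 0 else 1.0)
    rho = float(np.clip(true_correlation, -1.0, 1.0))
    y = rho * xs + np.sqrt(1.0 - rho**2) * z
    sensitivity = pd.Series(-7.0 + 0.5 * y, index=samples, name="log10_ic50_M")
    return expr, sensitivity
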