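"""Constrained four-parameter log-logistic dose-response fitting.

The response model is the decreasing-viability log-logistic ("4PL")

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with hill slope ``b`` (constrained non-positive), low-dose asymptote ``c``
(percent of negative-control activity near dose zero), high-dose asymptote
``d``, and midpoint ``e`` — the relative EC50, the concentration at which the
curve crosses halfway between its own asymptotes: ``f(e) = (c + d) / 2``.

Fitting is weighted bounded nonlinear least squares in ``(b, c, d, log10 e)``
with box constraints ``-10 <= b <= 0``, ``0 <= c, d <= A_max`` and
``1e-10 <= e <= 1e-4`` molar; replicate rows at the single highest tested
concentration are down-weighted to 10% to reduce curve-fitting artifacts from
off-target/solubility effects at the top dose. When no acceptable sigmoid can
be fitted, a smoothing-spline fallback summarises the curve by its mean
activity over the tested log-concentration range (the AUC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

from ._errors import DataError, FitError, IC50UndefinedError

__all__ = [
    "DoseDesign",
    "FourPLFit",
    "HillBindingFit",
    "eval_4pl",
    "fit_4pl",
    "fit_curve",
    "curve_auc",
    "relative_ic50",
    "fit_hill_kd",
    "grid_oracle_sse",
]

SLOPE_BOUNDS = (-10.0, 0.0)
LOG10_E_BOUNDS = (-10.0, -4.0)  # molar; the tested range spans ~0.5 nM-10 uM
TOP_DOSE_WEIGHT = 0.1


# ---------------------------------------------------------------------------
# dose designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseDesign:
    """A dose-escalation design: strictly increasing molar concentrations."""

    concentrations: tuple[float, ...]
    replicates: int = 1

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 2:
            raise DataError("a dose design needs at least 2 concentrations")
        if np.any(conc <= 0):
            raise DataError("dose design concentrations must be positive")
        if np.any(np.diff(conc) <= 0):
            raise DataError("dose design concentrations must be strictly increasing")
        if self.replicates < 1:
            raise DataError("replicates must be >= 1")

    @classmethod
    def ten_point(
        cls, low: float = 1e-9, high: float = 1e-5, replicates: int = 1
    ) -> "DoseDesign":
        """The standard secondary-screen design: 10 log-spaced points, 1 nM-10 uM."""
        return cls(tuple(np.geomspace(low, high, 10)), replicates=replicates)

    @property
    def n_points(self) -> int:
        return len(self.concentrations)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)


# ---------------------------------------------------------------------------
# the 4PL model
# ---------------------------------------------------------------------------


def eval_4pl(b: float, c: float, d: float, e: float, x) -> np.ndarray | float:
    """Evaluate the four-parameter log-logistic at concentration(s) ``x`` (molar).

    ``f(e) = (c + d) / 2`` for any parameters; with ``b < 0`` the curve runs
    from ``c`` at vanishing dose to ``d`` at saturating dose.
    """
    x_arr = np.asarray(x, dtype=float)
    if e <= 0:
        raise DataError("midpoint e must be positive")
    if np.any(x_arr <= 0):
        raise DataError("concentrations must be positive")
    with np.errstate(over="ignore"):
        out = c + (d - c) / (1.0 + np.exp(b * (np.log(x_arr) - np.log(e))))
    return out if out.ndim else float(out)


@dataclass
class FourPLFit:
    """Result of a constrained sigmoid fit (or its spline fallback).

    ``mode == "spline_fallback"`` means no acceptable sigmoid exists:
    parameters are ``None`` and only ``auc`` (mean % activity over the tested
    log-concentration range) is reported.
    """

    mode: Literal["sigmoid", "spline_fallback"]
    converged: bool
    auc: float
    b: float | None = None
    c: float | None = None
    d: float | None = None
    e: float | None = None
    log10_e: float | None = None
    weighted_sse: float | None = None
    a_max: float | None = None

    def __call__(self, x):
        if self.mode != "sigmoid":
            raise FitError("spline-fallback fits are not evaluable as a sigmoid")
        return eval_4pl(self.b, self.c, self.d, self.e, x)


@dataclass
class HillBindingFit:
    """Equilibrium-binding fit with the hill slope fixed at -1.

    signal(x) = bottom + (top - bottom) / (1 + x / kd)
    """

    kd: float
    top: float
    bottom: float
    residual_sse: float
    slope: float = -1.0

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + x / self.kd)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _prepare(concentration, response) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("concentration and response must be equal-length 1-D arrays")
    if np.any(x <= 0):
        raise DataError("concentrations must be positive")
    if not np.all(np.isfinite(y)):
        raise DataError("responses must be finite")
    return x, y


def _per_concentration_medians(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq = np.unique(x)
    med = np.array([np.median(y[x == u]) for u in uniq])
    return uniq, med


def response_cap(
    concentration, response, rule: Literal["anchored", "data"] = "anchored"
) -> float:
    """Upper bound for the fitted asymptotes.

    The data-driven component is the maximum over tested concentrations of the
    per-concentration median response ("max median normalized % activity").
    The default ``"anchored"`` rule never lets the cap fall below 100 — the
    activity scale is anchored at 100% of the negative control, and a finite
    lowest tested dose always samples the curve slightly below its true
    low-dose asymptote.  ``"data"`` uses the observed maximum alone.
    """
    x, y = _prepare(concentration, response)
    _, med = _per_concentration_medians(x, y)
    a_max = float(np.max(med))
    if rule == "anchored":
        return max(100.0, a_max)
    if rule == "data":
        return a_max
    raise ValueError(f"unknown asymptote cap rule: {rule!r}")


def top_dose_weights(concentration, rule: Literal["top10pct", "uniform"] = "top10pct",
                     n_top: int = 1) -> np.ndarray:
    """Per-row fit weights: all replicate rows at the highest tested
    concentration(s) carry weight 0.1, all others 1.0."""
    x = np.asarray(concentration, dtype=float)
    w = np.ones_like(x)
    if rule == "uniform":
        return w
    if rule != "top10pct":
        raise ValueError(f"unknown weights rule: {rule!r}")
    top = np.sort(np.unique(x))[-n_top:]
    w[np.isin(x, top)] = TOP_DOSE_WEIGHT
    return w


# ---------------------------------------------------------------------------
# grid oracle: brute-force profile over (b, log10 e)
# ---------------------------------------------------------------------------


def _profiled_cd_sse(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    cap: float,
    b_nodes: np.ndarray,
    log10e_nodes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted SSE at each (b, log10 e) node with (c, d) solved by
    box-constrained weighted linear least squares (exact active-set
    enumeration for the 2-variable box problem).

    Returns (sse, c, d), each of shape (len(b_nodes), len(log10e_nodes)).
    """
    lnx = np.log(x)
    B = b_nodes[:, None, None]
    lnE = (log10e_nodes * np.log(10.0))[None, :, None]
    with np.errstate(over="ignore"):
        g = 1.0 / (1.0 + np.exp(B * (lnx[None, None, :] - lnE)))  # weight on d
    u = 1.0 - g

    wv = w[None, None, :]
    yv = y[None, None, :]
    Suu = np.sum(wv * u * u, axis=-1)
    Svv = np.sum(wv * g * g, axis=-1)
    Suv = np.sum(wv * u * g, axis=-1)
    Suy = np.sum(wv * u * yv, axis=-1)
    Svy = np.sum(wv * g * yv, axis=-1)
    Syy = float(np.sum(w * y * y))

    def sse(c, d):
        return (
            Syy
            - 2.0 * (c * Suy + d * Svy)
            + c * c * Suu
            + 2.0 * c * d * Suv
            + d * d * Svv
        )

    eps = 1e-300
    det = Suu * Svv - Suv * Suv
    # interior (unconstrained) candidate; invalid where the system is singular
    c0 = (Svv * Suy - Suv * Svy) / np.where(np.abs(det) < eps, np.nan, det)
    d0 = (Suu * Svy - Suv * Suy) / np.where(np.abs(det) < eps, np.nan, det)
    interior_ok = np.isfinite(c0) & np.isfinite(d0) & (c0 >= 0) & (c0 <= cap) & (d0 >= 0) & (d0 <= cap)

    candidates = []
    c_int = np.where(interior_ok, c0, 0.0)
    d_int = np.where(interior_ok, d0, 0.0)
    candidates.append((c_int, d_int, np.where(interior_ok, sse(c_int, d_int), np.inf)))

    # four edges: fix one variable, solve the 1-D problem, clip into the box
    def edge(c_fixed=None, d_fixed=None):
        if c_fixed is not None:
            cc = np.full_like(Suu, c_fixed)
            dd = np.clip((Svy - c_fixed * Suv) / np.where(Svv < eps, np.nan, Svv), 0.0, cap)
            dd = np.where(np.isfinite(dd), dd, 0.0)
        else:
            dd = np.full_like(Suu, d_fixed)
            cc = np.clip((Suy - d_fixed * Suv) / np.where(Suu < eps, np.nan, Suu), 0.0, cap)
            cc = np.where(np.isfinite(cc), cc, 0.0)
        return cc, dd, sse(cc, dd)

    for kwargs in ({"c_fixed": 0.0}, {"c_fixed": cap}, {"d_fixed": 0.0}, {"d_fixed": cap}):
        candidates.append(edge(**kwargs))

    all_sse = np.stack([s for _, _, s in candidates])
    all_c = np.stack([c for c, _, _ in candidates])
    all_d = np.stack([d for _, d, _ in candidates])
    pick = np.argmin(all_sse, axis=0)
    idx = np.indices(pick.shape)
    return (
        all_sse[pick, idx[0], idx[1]],
        all_c[pick, idx[0], idx[1]],
        all_d[pick, idx[0], idx[1]],
    )


def grid_oracle_sse(
    concentration,
    response,
    weights_rule: Literal["top10pct", "uniform"] = "top10pct",
    asymptote_cap: Literal["anchored", "data"] = "anchored",
    b_step: float = 0.1,
    log10e_step: float = 0.05,
) -> float:
    """Brute-force lower-envelope weighted SSE over a (b, log10 e) lattice.

    At every lattice node the asymptotes (c, d) are solved exactly by
    box-constrained weighted linear least squares.  Serves as an independent
    check that the nonlinear optimizer is not stuck in a poor local minimum:
    any acceptable converged fit must achieve a weighted SSE no larger than
    this grid minimum (the grid fixes b and e, the optimizer does not).
    """
    x, y = _prepare(concentration, response)
    w = top_dose_weights(x, weights_rule)
    cap = response_cap(x, y, asymptote_cap)
    b_nodes = np.arange(SLOPE_BOUNDS[0], SLOPE_BOUNDS[1] + b_step / 2, b_step)
    e_nodes = np.arange(LOG10_E_BOUNDS[0], LOG10_E_BOUNDS[1] + log10e_step / 2, log10e_step)
    sse, _, _ = _profiled_cd_sse(x, y, w, cap, b_nodes, e_nodes)
    return float(np.min(sse))


# ---------------------------------------------------------------------------
# sigmoid fitting
# ---------------------------------------------------------------------------


def _starts(x: np.ndarray, y: np.ndarray, w: np.ndarray, cap: float) -> list[np.ndarray]:
    """Deterministic multi-start points: a coarse lattice over (b, log10 e)
    plus the two best nodes of a coarse profiled grid."""
    _, med = _per_concentration_medians(x, y)
    c0 = float(np.clip(np.max(med), 0.0, cap))
    d0 = float(np.clip(np.min(med), 0.0, cap))
    lo, hi = np.log10(x.min()), np.log10(x.max())
    lattice_e = np.linspace(max(lo, LOG10_E_BOUNDS[0]), min(hi, LOG10_E_BOUNDS[1]), 4)
    starts = [np.array([b, c0, d0, le]) for b in (-0.5, -2.0) for le in lattice_e]

    b_nodes = np.array([-8.0, -4.0, -2.0, -1.0, -0.5])
    e_nodes = np.linspace(LOG10_E_BOUNDS[0], LOG10_E_BOUNDS[1], 31)
    sse, cg, dg = _profiled_cd_sse(x, y, w, cap, b_nodes, e_nodes)
    flat = np.argsort(sse, axis=None)[:2]
    for k in flat:
        i, j = np.unravel_index(k, sse.shape)
        starts.append(np.array([b_nodes[i], cg[i, j], dg[i, j], e_nodes[j]]))
    return starts


def fit_4pl(
    concentration,
    response,
    weights_rule: Literal["top10pct", "uniform"] = "top10pct",
    asymptote_cap: Literal["anchored", "data"] = "anchored",
    min_r_squared: float = 0.3,
) -> FourPLFit:
    """Fit the constrained 4PL by multi-start bounded weighted least squares.

    ``converged`` is False — signalling the spline fallback in
    :func:`fit_curve` — when the data are constant, when the fitted curve
    explains too little of the weighted variance (weighted R^2 below
    ``min_r_squared``), or when the midpoint is pinned at a box bound outside
    the tested concentration range.
    """
    x, y = _prepare(concentration, response)
    if np.unique(x).size < 4:
        raise FitError("sigmoid fitting needs at least 4 distinct concentrations")
    w = top_dose_weights(x, weights_rule)
    cap = response_cap(x, y, asymptote_cap)

    wmean = float(np.sum(w * y) / np.sum(w))
    sst = float(np.sum(w * (y - wmean) ** 2))
    if sst <= 1e-12:  # identical responses: no dose effect to model
        auc = _trapezoid_auc(lambda t: np.full_like(np.asarray(t, float), y[0]), x.min(), x.max())
        return FourPLFit(mode="sigmoid", converged=False, auc=auc,
                         weighted_sse=0.0, a_max=cap)

    lnx = np.log(x)
    ln10 = np.log(10.0)
    sqw = np.sqrt(w)

    def residuals(theta):
        b, c, d, log10e = theta
        with np.errstate(over="ignore"):
            g = 1.0 / (1.0 + np.exp(b * (lnx - log10e * ln10)))
        return sqw * (c + (d - c) * g - y)

    def jac(theta):
        b, c, d, log10e = theta
        z = b * (lnx - log10e * ln10)
        with np.errstate(over="ignore"):
            ez = np.exp(z)
            g = 1.0 / (1.0 + ez)
            dg_dz = -ez / (1.0 + ez) ** 2
        dg_dz = np.where(np.isfinite(dg_dz), dg_dz, 0.0)
        df_db = (d - c) * dg_dz * (lnx - log10e * ln10)
        df_dc = 1.0 - g
        df_dd = g
        df_dle = (d - c) * dg_dz * (-b * ln10)
        return (sqw[:, None] * np.column_stack([df_db, df_dc, df_dd, df_dle]))

    lower = np.array([SLOPE_BOUNDS[0], 0.0, 0.0, LOG10_E_BOUNDS[0]])
    upper = np.array([SLOPE_BOUNDS[1], cap, cap, LOG10_E_BOUNDS[1]])

    # multi-start, pruned to the most promising starts by initial cost,
    # with a cheap first pass and a tight polish from the best solution
    starts = [np.clip(t, lower + 1e-12, upper - 1e-12) for t in _starts(x, y, w, cap)]
    start_cost = [float(np.sum(residuals(t) ** 2)) for t in starts]
    keep = np.argsort(start_cost, kind="stable")[:4]
    best = None
    for theta0 in (starts[k] for k in keep):
        try:
            sol = least_squares(
                residuals, theta0, jac=jac, bounds=(lower, upper),
                xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=60,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FourPLFit(mode="sigmoid", converged=False, auc=np.nan, a_max=cap)
    # tight polish is only worthwhile when a usable sigmoid is in reach
    if 1.0 - 2.0 * best.cost / sst >= 0.5 * min_r_squared:
        best = least_squares(
            residuals, best.x, jac=jac, bounds=(lower, upper),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300,
        )

    b, c, d, log10e = best.x
    sse = float(2.0 * best.cost)
    r2 = 1.0 - sse / sst

    pin_tol = 1e-6
    e = 10.0 ** log10e
    pinned_e = (abs(log10e - LOG10_E_BOUNDS[0]) < pin_tol
                or abs(log10e - LOG10_E_BOUNDS[1]) < pin_tol)
    outside = not (x.min() <= e <= x.max())
    # a slope pinned at the steep bound is a step the design cannot resolve
    pinned_b = abs(b - SLOPE_BOUNDS[0]) < pin_tol
    converged = (bool(best.success) and r2 >= min_r_squared
                 and not (pinned_e and outside) and not pinned_b)

    auc = _trapezoid_auc(lambda t: eval_4pl(b, c, d, e, t), x.min(), x.max())
    return FourPLFit(
        mode="sigmoid", converged=converged, auc=auc,
        b=float(b), c=float(c), d=float(d), e=float(e), log10_e=float(log10e),
        weighted_sse=sse, a_max=cap,
    )


# ---------------------------------------------------------------------------
# AUC and the spline fallback
# ---------------------------------------------------------------------------


def _trapezoid_auc(curve: Callable, xmin: float, xmax: float, n_grid: int = 512) -> float:
    lo, hi = np.log10(xmin), np.log10(xmax)
    if not hi > lo:
        raise DataError("AUC needs a non-degenerate concentration range")
    grid = np.linspace(lo, hi, n_grid)
    vals = np.asarray(curve(10.0 ** grid), dtype=float)
    return float(np.trapezoid(vals, grid) / (hi - lo))


def curve_auc(curve: Callable, design: DoseDesign | Sequence[float], n_grid: int = 512) -> float:
    """Mean value of ``curve`` (a callable of molar concentration) over the
    tested log10-concentration range, so a 0-100 activity curve maps to a
    0-100 AUC.  Trapezoid rule on a uniform log-spaced grid."""
    conc = design.as_array() if isinstance(design, DoseDesign) else np.asarray(design, float)
    if np.unique(conc).size < 2:
        raise DataError("AUC needs at least two distinct concentrations")
    return _trapezoid_auc(curve, conc.min(), conc.max(), n_grid)


def fit_spline_auc(concentration, response) -> FourPLFit:
    """Smoothing-spline summary of a dose-response curve.

    Fits a cubic smoothing spline to (log10 concentration, mean response per
    concentration) with GCV-selected smoothing, evaluated only within the
    tested range, and reports the mean activity (AUC).  Used as the fallback
    when no acceptable sigmoid fits."""
    x, y = _prepare(concentration, response)
    uniq, _ = _per_concentration_medians(x, y)
    if uniq.size < 4:
        raise FitError("spline fallback needs at least 4 distinct concentrations")
    means = np.array([np.mean(y[x == u]) for u in uniq])
    lx = np.log10(uniq)
    if uniq.size >= 5 and np.ptp(means) > 1e-12:
        spline = make_smoothing_spline(lx, means)
        curve = lambda t: spline(np.log10(np.asarray(t, float)))
    else:
        curve = lambda t: np.interp(np.log10(np.asarray(t, float)), lx, means)
    auc = _trapezoid_auc(curve, x.min(), x.max())
    return FourPLFit(mode="spline_fallback", converged=False, auc=auc)


def fit_curve(
    concentration,
    response,
    weights_rule: Literal["top10pct", "uniform"] = "top10pct",
    asymptote_cap: Literal["anchored", "data"] = "anchored",
) -> FourPLFit:
    """Fit a dose-response curve: constrained sigmoid first, smoothing-spline
    AUC fallback when the sigmoid fails (non-convergence, flat response, or a
    midpoint pinned at a bound outside the tested range)."""
    x, y = _prepare(concentration, response)
    if np.unique(x).size < 4:
        raise FitError("curve fitting needs at least 4 distinct concentrations")
    fit = fit_4pl(x, y, weights_rule=weights_rule, asymptote_cap=asymptote_cap)
    if fit.converged:
        return fit
    return fit_spline_auc(x, y)


def relative_ic50(fit: FourPLFit) -> float:
    """The relative IC50: the fitted midpoint ``e`` (molar), where the curve
    crosses halfway between its own asymptotes."""
    if fit.mode != "sigmoid" or fit.e is None or not fit.converged:
        raise IC50UndefinedError("IC50 is undefined without a converged sigmoid fit")
    return fit.e


# ---------------------------------------------------------------------------
# fixed-slope Hill binding
# ---------------------------------------------------------------------------


def fit_hill_kd(ligand_concentration, signal) -> HillBindingFit:
    """Fit an equilibrium-binding curve with the hill slope fixed at -1:

        signal(x) = bottom + (top - bottom) / (1 + x / kd)

    by least squares over (kd, top, bottom); only the dissociation constant
    and the two plateaus are estimated."""
    x, y = _prepare(ligand_concentration, signal)
    if np.unique(x).size < 3:
        raise FitError("Kd fitting needs at least 3 distinct concentrations")
    if np.ptp(y) <= 1e-12:
        raise FitError("constant signal: Kd is not identifiable")

    def residuals(theta):
        log_kd, top, bottom = theta
        return bottom + (top - bottom) / (1.0 + x / np.exp(log_kd)) - y

    best = None
    for log_kd0 in np.log(np.geomspace(x.min(), x.max(), 5)):
        sol = least_squares(
            residuals, np.array([log_kd0, float(y.max()), float(y.min())]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    log_kd, top, bottom = best.x
    return HillBindingFit(
        kd=float(np.exp(log_kd)), top=float(top), bottom=float(bottom),
        residual_sse=float(2.0 * best.cost),
    )
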