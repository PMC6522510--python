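"""EC50 potency/selectivity profiling and expression quantification.

Assembles the compounds x cell-lines EC50 matrix (uM) from dose-response
fits, flags broadly potent compounds, orders cell lines by agglomerative
clustering of their log10 EC50 profiles, quantifies subtype selectivity, and
implements the RNA-seq expression rules used alongside the screen:
best-covered-exon gene expression with a >=10 retention filter, FPKM, and
quantile normalization, plus expression-sensitivity correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

from ._errors import DataError
from .doseresponse import FourPLFit

__all__ = [
    "assemble_ec50_matrix",
    "flag_broad_potency",
    "cluster_cell_lines",
    "subtype_selectivity",
    "best_exon_expression",
    "fpkm",
    "quantile_normalize",
    "fpkm_quantile_normalize",
    "correlate_expression_sensitivity",
    "CorrelationResult",
]

ASSAY_CEILING_UM = 10.0  # top tested concentration of the dose-response screen


# ---------------------------------------------------------------------------
# EC50 matrix
# ---------------------------------------------------------------------------


def assemble_ec50_matrix(
    fits: Mapping[tuple[str, str], FourPLFit]
) -> pd.DataFrame:
    """Build the compounds x cell-lines EC50 matrix in uM from keyed fits.

    Spline-fallback (or non-converged) fits become missing entries ("NE" in
    report output, NaN in memory).  Row/column order is stable on first
    appearance in the input."""
    compounds: list[str] = []
    lines: list[str] = []
    seen = set()
    for key in fits:
        if key in seen:
            raise DataError(f"duplicate fit key: {key}")
        seen.add(key)
        comp, line = key
        if comp not in compounds:
            compounds.append(comp)
        if line not in lines:
            lines.append(line)
    matrix = pd.DataFrame(np.nan, index=compounds, columns=lines)
    for (comp, line), fit in fits.items():
        if fit.mode == "sigmoid" and fit.converged and fit.e is not None:
            matrix.loc[comp, line] = fit.e * 1e6  # molar -> uM
    return matrix


def flag_broad_potency(matrix: pd.DataFrame, cut: float = 1.0) -> list[str]:
    """Compounds with EC50 strictly below ``cut`` (uM) in *all* cell lines.

    A missing (not-evaluable) entry disqualifies a compound: potency in every
    line cannot be verified."""
    matrix = matrix.astype(float)
    flagged = [
        comp for comp, row in matrix.iterrows()
        if row.notna().all() and (row < cut).all()
    ]
    return flagged


def cluster_cell_lines(
    matrix: pd.DataFrame,
    method: str = "average",
) -> tuple[list[str], np.ndarray]:
    """Order cell lines by agglomerative clustering of their potency profiles.

    Clustering operates on log10(EC50 uM) columns with pairwise-complete
    Euclidean distance (missing entries ignored pair by pair), average
    linkage, and scipy's deterministic leaf ordering (ties broken by input
    order).  Returns ``(ordered_cell_lines, linkage_matrix)``."""
    if matrix.shape[1] < 2:
        raise DataError("clustering needs at least 2 cell lines")
    logm = np.log10(matrix.astype(float).to_numpy())
    profiles = logm.T  # one row per cell line
    empty = np.all(np.isnan(profiles), axis=1)
    if empty.any():
        bad = matrix.columns[empty].tolist()
        raise DataError(f"cell lines without any numeric EC50: {bad}")
    dist = nan_euclidean_distances(profiles)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(linkage)
    return [matrix.columns[i] for i in order], linkage


def subtype_selectivity(
    matrix: pd.DataFrame,
    subtypes: Mapping[str, str] | pd.Series,
    target_subtype: str,
    ceiling_um: float = ASSAY_CEILING_UM,
) -> pd.DataFrame:
    """Per-compound selectivity for a cell-line subtype.

    ratio = median EC50 of non-target lines / median EC50 of target lines,
    with missing (not-evaluable) entries censored at the assay ceiling
    (default 10 uM, the top tested concentration).  Ratios > 1 indicate
    preferential potency in the target subtype; the result is sorted by
    descending ratio."""
    subtypes = pd.Series(dict(subtypes))
    labels = subtypes.reindex(matrix.columns)
    if labels.isna().any():
        raise DataError(f"missing subtype labels for: {labels.index[labels.isna()].tolist()}")
    in_target = labels == target_subtype
    if not in_target.any():
        raise DataError(f"subtype {target_subtype!r} absent from labels")
    if in_target.all():
        raise DataError("need at least one cell line outside the target subtype")
    filled = matrix.astype(float).fillna(ceiling_um)
    target_med = filled.loc[:, in_target.to_numpy()].median(axis=1)
    other_med = filled.loc[:, (~in_target).to_numpy()].median(axis=1)
    out = pd.DataFrame({
        "target_median_um": target_med,
        "other_median_um": other_med,
        "selectivity_ratio": other_med / target_med,
    })
    return out.sort_values("selectivity_ratio", ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# expression quantification
# ---------------------------------------------------------------------------


def best_exon_expression(
    exon_coverage: pd.DataFrame,
    min_expression: float = 10.0,
) -> pd.DataFrame:
    """Best-covered-exon gene expression with a retention filter.

    ``exon_coverage`` is a long-by-gene table with columns ``gene``, ``exon``
    and one numeric column per sample (average coverage of that exon).  A
    gene's expression in a sample is the maximum over its exons; genes are
    retained iff expression >= ``min_expression`` (inclusive) in at least one
    sample."""
    if "gene" not in exon_coverage.columns or "exon" not in exon_coverage.columns:
        raise DataError("exon coverage table needs 'gene' and 'exon' columns")
    samples = [c for c in exon_coverage.columns if c not in ("gene", "exon")]
    if not samples:
        raise DataError("exon coverage table has no sample columns")
    expr = exon_coverage.groupby("gene", sort=False)[samples].max()
    keep = (expr >= min_expression).any(axis=1)
    return expr.loc[keep]


def fpkm(
    counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    total_mapped_reads: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of gene per million mapped reads.

    ``total_mapped_reads`` defaults to each sample's column sum."""
    counts = counts.astype(float)
    lengths = pd.Series(gene_lengths_bp).reindex(counts.index).astype(float)
    if lengths.isna().any() or (lengths <= 0).any():
        raise DataError("every gene needs a positive length for FPKM")
    if total_mapped_reads is None:
        total_mapped_reads = counts.sum(axis=0)
    totals = pd.Series(total_mapped_reads).reindex(counts.columns).astype(float)
    if totals.isna().any() or (totals <= 0).any():
        raise DataError("every sample needs a positive total mapped-read count")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common empirical distribution.

    The rank-r value in each sample is replaced by the mean across samples of
    the r-th order statistics; tied values receive the mean of the target
    quantiles their ranks span.  After normalization the sorted value vector
    is identical in every column."""
    mat = values.astype(float).to_numpy()
    n, m = mat.shape
    targets = np.mean(np.sort(mat, axis=0), axis=1)
    out = np.empty_like(mat)
    for j in range(m):
        col = mat[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n)
        ranked[order] = targets
        # ties: average the targets spanned by each tied block
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranked[order[i : k + 1]] = targets[i : k + 1].mean()
            i = k + 1
        out[:, j] = ranked
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def fpkm_quantile_normalize(
    counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    total_mapped_reads: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM normalization followed by quantile normalization across samples
    (the depth-adjustment used for cross-sample expression comparison)."""
    return quantile_normalize(fpkm(counts, gene_lengths_bp, total_mapped_reads))


# ---------------------------------------------------------------------------
# expression-sensitivity correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate_expression_sensitivity(
    expression,
    ic50,
    ic50_scale: Literal["log10", "linear"] = "log10",
) -> CorrelationResult:
    """Pearson correlation and OLS regression of drug sensitivity on gene
    expression.

    IC50 values are log10-transformed by default (potency spans orders of
    magnitude); pass ``ic50_scale="linear"`` for the raw scale, or supply
    already-logged values with ``"linear"``.  The two-sided p-value comes
    from the t distribution with n - 2 degrees of freedom."""
    x = np.asarray(expression, dtype=float)
    y = np.asarray(ic50, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("expression and IC50 must be equal-length 1-D vectors")
    if x.size < 3:
        raise DataError("correlation needs at least 3 paired samples")
    if ic50_scale == "log10":
        if np.any(y <= 0):
            raise DataError("IC50 values must be positive for the log10 scale")
        y = np.log10(y)
    elif ic50_scale != "linear":
        raise ValueError(f"unknown ic50 scale: {ic50_scale!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation is undefined for a constant vector")
    lr = sps.linregress(x, y)
    return CorrelationResult(
        pearson_r=float(lr.rvalue),
        r_squared=float(lr.rvalue**2),
        p_value=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=int(x.size),
    )
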