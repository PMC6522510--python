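"""Primary-screen hit calling and compound advancement rules.

All thresholds are strict inequalities, exactly as the screening rules are
stated: a total hit requires activity > 50% inhibition in a cell line; a
selective hit requires > 80% inhibition in one line and < 20% in every other
line with data; boundary values fail.  Annotation flags are tri-state
(True / False / None for unknown) and an unknown flag can never satisfy an
advancement criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError

__all__ = [
    "CompoundAnnotation",
    "AdvancementDecision",
    "call_total_hits",
    "call_selective_hits",
    "select_secondary_candidates",
    "advancement_flags",
    "primary_screen_statistics",
]


@dataclass(frozen=True)
class CompoundAnnotation:
    """Clinical/mechanistic annotation; ``None`` means unknown."""

    compound_id: str
    fda_approved: bool | None = None
    pediatric_dose_or_phase1: bool | None = None
    used_or_investigated_in_aml: bool | None = None
    clinical_phase: str = ""
    analog_of: str = ""
    class_of_interest: bool | None = None


@dataclass(frozen=True)
class AdvancementDecision:
    compound_id: str
    advance: bool
    failed_criteria: tuple[str, ...]


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.empty:
        raise DataError("empty response matrix")
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise DataError("duplicated compound or cell-line ids in response matrix")
    return matrix.astype(float)


def call_total_hits(
    matrix: pd.DataFrame, threshold: float = 50.0
) -> tuple[dict[str, set[str]], pd.Series]:
    """Per-cell-line total hits: compounds with inhibition strictly above
    ``threshold``.  Missing cells are never hits.

    Returns ``(hits_by_line, counts_by_line)``.
    """
    matrix = _check_matrix(matrix)
    if not 0 <= threshold <= 100:
        warnings.warn(f"hit threshold {threshold} lies outside [0, 100]", stacklevel=2)
    hits = {
        line: set(matrix.index[matrix[line] > threshold].tolist())
        for line in matrix.columns
    }
    counts = pd.Series({line: len(s) for line, s in hits.items()}, name="n_hits")
    return hits, counts


def call_selective_hits(
    matrix: pd.DataFrame, high: float = 80.0, low: float = 20.0
) -> tuple[list[tuple[str, str]], list[str]]:
    """Selective hits: inhibition > ``high`` in one line AND < ``low`` in all
    other lines with data.  A compound missing data in any other line cannot
    be verified selective and is excluded (returned in the skip log)."""
    matrix = _check_matrix(matrix)
    if matrix.shape[1] < 2:
        raise DataError("selectivity calls need at least 2 cell lines")
    selective: list[tuple[str, str]] = []
    skipped: list[str] = []
    for compound, row in matrix.iterrows():
        for line in matrix.columns:
            v = row[line]
            if pd.isna(v) or not v > high:
                continue
            others = row.drop(line)
            if others.isna().any():
                skipped.append(compound)
                continue
            if (others < low).all():
                selective.append((compound, line))
    return selective, sorted(set(skipped))


def select_secondary_candidates(
    matrix: pd.DataFrame,
    annotations: list[CompoundAnnotation],
    threshold: float = 50.0,
) -> pd.DataFrame:
    """Secondary-screen candidate selection with reason codes.

    A compound is selected if it is (a) a hit in more than one cell line,
    (b) an analog of a selected compound, or (c) a member of a compound class
    of interest.  Clinical phase is recorded alongside.  Annotated compounds
    absent from the matrix can still enter via (b)/(c)."""
    matrix = _check_matrix(matrix)
    ann = {a.compound_id: a for a in annotations}
    hits, _ = call_total_hits(matrix, threshold)
    n_hit_lines = {
        comp: sum(comp in hits[line] for line in matrix.columns)
        for comp in matrix.index
    }

    reasons: dict[str, set[str]] = {}
    for comp, n in n_hit_lines.items():
        if n >= 2:
            reasons.setdefault(comp, set()).add("multi_line_hit")
    for comp, a in ann.items():
        if a.class_of_interest is True:
            reasons.setdefault(comp, set()).add("class_of_interest")
    # analog closure: analogs of already-selected compounds, to a fixed point
    changed = True
    while changed:
        changed = False
        for comp, a in ann.items():
            if a.analog_of and a.analog_of in reasons and comp not in reasons:
                reasons.setdefault(comp, set()).add("analog_of_selected")
                changed = True

    recs = []
    for comp in sorted(set(matrix.index) | set(ann)):
        a = ann.get(comp, CompoundAnnotation(comp))
        recs.append({
            "compound_id": comp,
            "selected": comp in reasons,
            "reasons": ";".join(sorted(reasons.get(comp, ()))),
            "n_hit_lines": n_hit_lines.get(comp, 0),
            "clinical_phase": a.clinical_phase,
        })
    return pd.DataFrame(recs).set_index("compound_id")


def advancement_flags(
    ec50_row: pd.Series,
    annotation: CompoundAnnotation,
    potency_cut: float = 1.0,
) -> AdvancementDecision:
    """Advancement decision for one compound given its per-cell-line EC50 row
    (in uM).

    Advance iff the compound is potent in every line (max EC50 < potency_cut),
    FDA-approved, has an established pediatric dose (or phase-1 pediatric
    testing), and is NOT already used or under investigation for AML.  An
    unknown flag blocks advancement and is reported as "<criterion>:unknown".
    """
    row = pd.Series(ec50_row).astype(float)
    if row.empty:
        raise DataError("EC50 row is empty")
    failed: list[str] = []
    if row.isna().any() or not (row.max() < potency_cut):
        failed.append(f"potency(max_ec50<{potency_cut}uM)")
    for name, value, want in (
        ("fda_approved", annotation.fda_approved, True),
        ("pediatric_dose_or_phase1", annotation.pediatric_dose_or_phase1, True),
        ("used_or_investigated_in_aml", annotation.used_or_investigated_in_aml, False),
    ):
        if value is None:
            failed.append(f"{name}:unknown")
        elif value is not want:
            failed.append(name)
    return AdvancementDecision(
        compound_id=annotation.compound_id,
        advance=not failed,
        failed_criteria=tuple(failed),
    )


def primary_screen_statistics(
    matrix: pd.DataFrame, threshold: float = 50.0, high: float = 80.0, low: float = 20.0
) -> pd.DataFrame:
    """Per-cell-line summary of a primary screen: total and selective hit
    counts.  Intended for full screen-scale inhibition matrices."""
    _, counts = call_total_hits(matrix, threshold)
    selective, _ = call_selective_hits(matrix, high, low)
    sel_counts = pd.Series(0, index=matrix.columns, dtype=int)
    for _, line in selective:
        sel_counts[line] += 1
    return pd.DataFrame({"total_hits": counts, "selective_hits": sel_counts})
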