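"""Bundled reference tables for the pediatric-AML secondary-screen panel."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .hits import CompoundAnnotation

__all__ = [
    "secondary_screen_ec50",
    "secondary_screen_annotations",
    "cell_line_subtypes",
    "MECHANISM_CLASSES",
]

MECHANISM_CLASSES = {
    "a": "anti-metabolite",
    "c": "complex",
    "d": "DNA",
    "e": "epigenetic",
    "k": "kinase",
    "m": "mitotic",
    "o": "other",
    "p": "proteasome",
}


def _data(name: str) -> pd.DataFrame:
    with resources.files("screenkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def secondary_screen_ec50() -> pd.DataFrame:
    """The 17-compound x 8-cell-line secondary-screen EC50 matrix (uM):
    every compound with sub-micromolar potency across the whole panel."""
    return _data("secondary_screen_ec50_um.csv").set_index("compound")


def secondary_screen_annotations() -> tuple[pd.DataFrame, list[CompoundAnnotation]]:
    """Mechanism codes and tri-state clinical flags for the panel compounds.

    Blank flags mean unknown and map to ``None``."""
    df = _data("secondary_screen_annotations.csv").set_index("compound")

    def tri(v):
        if pd.isna(v):
            return None
        return str(v).strip().lower() == "true"

    anns = [
        CompoundAnnotation(
            compound_id=comp,
            fda_approved=tri(row["fda_approved"]),
            pediatric_dose_or_phase1=tri(row["pediatric_dose_or_phase1"]),
            used_or_investigated_in_aml=tri(row["used_or_investigated_in_aml"]),
        )
        for comp, row in df.iterrows()
    ]
    return df, anns


def cell_line_subtypes() -> pd.Series:
    """Subtype label per panel cell line (MLLr, MLLr+FLT3-ITD,
    PICALM/MLLT10, AMKL)."""
    df = _data("cell_line_subtypes.csv")
    return df.set_index("cell_line")["subtype"]
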