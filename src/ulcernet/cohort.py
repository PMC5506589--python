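"""Cohort table schema shared across the pipeline.

A cohort is a :class:`pandas.DataFrame` with one row per ICU patient and the
following column conventions:

``patient_id``
    opaque unique identifier.
``pu``
    binary pressure-ulcer outcome (0/1).
``braden_*``
    ordinal Braden scale columns.  The six subscales (``sensory``,
    ``moisture``, ``activity``, ``mobility``, ``nutrition`` on 1-4 and
    ``friction_shear`` on 1-3), the raw ``braden_total`` (6-23, the sum of
    the subscales) and ``braden_total_band`` (0-4, the total binned at
    9/12/14/18, so the clinical operating threshold of 13 is a band edge).
``med_*`` / ``dx_*`` / ``noise_*``
    binary medication-category, three-digit-diagnosis and synthetic noise
    flags (0/1).

``braden_total`` is carried for the threshold baseline but is never used as
a network node; the banded version stands in for it (an 18-state node would
be hopelessly data starved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PU_COLUMN = "pu"
ID_COLUMN = "patient_id"

#: Braden subscale name -> (minimum value, cardinality)
BRADEN_SUBSCALES: dict[str, tuple[int, int]] = {
    "braden_sensory": (1, 4),
    "braden_moisture": (1, 4),
    "braden_activity": (1, 4),
    "braden_mobility": (1, 4),
    "braden_nutrition": (1, 4),
    "braden_friction_shear": (1, 3),
}

BRADEN_TOTAL = "braden_total"
BRADEN_BAND = "braden_total_band"
#: right-inclusive upper edges of the first four Braden-total bands
#: (<=9, 10-12, 13-14, 15-18, >=19); 13 -- the threshold used by the
#: single-score clinical baseline -- falls on a band boundary.
BRADEN_BAND_EDGES = (9, 12, 14, 18)

#: columns that may enter a Bayesian network as nodes, with cardinality/offset
_NETWORK_BRADEN = dict(BRADEN_SUBSCALES) | {BRADEN_BAND: (0, 5)}


@dataclass(frozen=True)
class Variable:
    """A discrete variable: ``cardinality`` states, raw values start at ``offset``."""

    name: str
    cardinality: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.cardinality < 2:
            raise ValueError(f"{self.name}: cardinality must be >= 2")


def braden_band(total: np.ndarray | pd.Series) -> np.ndarray:
    """Bin raw Braden totals into the five ordinal bands."""
    return np.digitize(np.asarray(total), BRADEN_BAND_EDGES, right=True)


def _base_name(column: str) -> str:
    """Strip the ``_d<k>`` suffix added by the feature-duplication benchmark."""
    import re

    return re.sub(r"_d\d+$", "", column)


def feature_class(column: str) -> str | None:
    """Classify a cohort column as ``braden``/``medication``/``diagnosis``/``noise``."""
    if _base_name(column) in _NETWORK_BRADEN or column == BRADEN_TOTAL:
        return "braden"
    if column.startswith("med_"):
        return "medication"
    if column.startswith("dx_"):
        return "diagnosis"
    if column.startswith("noise_"):
        return "noise"
    return None


def binary_feature_columns(df: pd.DataFrame) -> list[str]:
    """Medication, diagnosis and noise flag columns present in ``df``."""
    return [c for c in df.columns if feature_class(c) in ("medication", "diagnosis", "noise")]


def column_variable(column: str) -> Variable:
    """Declared state space of a cohort column usable as a network node."""
    base = _base_name(column)
    if base in _NETWORK_BRADEN:
        offset, card = _NETWORK_BRADEN[base]
        return Variable(column, card, offset)
    if column == PU_COLUMN or feature_class(column) in ("medication", "diagnosis", "noise"):
        return Variable(column, 2, 0)
    raise ValueError(f"column {column!r} has no declared state space")


def network_feature_columns(df: pd.DataFrame, classes: Iterable[str]) -> list[str]:
    """Columns of the requested feature classes that can serve as network nodes.

    ``classes`` uses the study's letters: ``B`` Braden, ``M`` medication,
    ``D`` diagnosis, plus ``N`` for synthetic noise flags.
    """
    wanted = {
        {"B": "braden", "M": "medication", "D": "diagnosis", "N": "noise"}[c]
        for c in classes
    }
    cols: list[str] = []
    for c in df.columns:
        if c in (PU_COLUMN, ID_COLUMN, BRADEN_TOTAL):
            continue
        cls = feature_class(c)
        if cls in wanted:
            cols.append(c)
    return cols


def validate_cohort(df: pd.DataFrame) -> None:
    """Check the cohort invariants: unique patients, values in declared spaces."""
    if ID_COLUMN in df.columns and df[ID_COLUMN].duplicated().any():
        raise ValueError("cohort has duplicated patient_id values")
    if PU_COLUMN not in df.columns:
        raise ValueError("cohort lacks the pu outcome column")
    for col in [PU_COLUMN, *binary_feature_columns(df)]:
        vals = df[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"column {col!r} is not binary")
    for col, (lo, card) in BRADEN_SUBSCALES.items():
        if col in df.columns:
            vals = df[col].to_numpy()
            if vals.min() < lo or vals.max() >= lo + card:
                raise ValueError(f"column {col!r} outside its declared range")


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
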