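"""Cohort preparation and univariate variable selection.

Implements the data-preparation stage of the pipeline: ICD-9 truncation with
the 707-family special case, pressure-ulcer labelling from discharge codes,
the admission-level cohort filters (age, PU at admission, 36-hour ICU stay,
first hospitalization, first ICU admission), the frequency filter, and the
chi-square / Fisher univariate screen with the class-specific retention
rules (medications at alpha = 0.1; diagnoses at chi-square statistic > 20,
i.e. alpha = 0.001).  No multiple-testing correction is applied at this
stage -- screening is deliberately inclusive.

Boundary conventions (documented, literal readings): an ICU stay of exactly
36.0 hours is kept; a feature with exactly ``min_count`` positives is kept.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    BRADEN_BAND,
    BRADEN_SUBSCALES,
    BRADEN_TOTAL,
    ID_COLUMN,
    PU_COLUMN,
    binary_feature_columns,
    braden_band,
    feature_class,
)

__all__ = [
    "PU_CATEGORY",
    "NONPU_707",
    "truncate_icd9",
    "label_pu",
    "filter_cohort",
    "frequency_filter",
    "contingency_2x2",
    "choose_test",
    "pearson_chi2",
    "lr_chi2",
    "fisher_exact",
    "univariate_screen",
    "demographics_table",
]

log = logging.getLogger(__name__)

#: sentinel category for PU-qualifying 707.x codes; consumed by
#: :func:`label_pu`, never emitted as a predictor feature
PU_CATEGORY = "707"
#: chronic-ulcer 707 codes (707.1, 707.8, 707.9) that do *not* indicate a
#: pressure ulcer; kept as their own diagnosis category
NONPU_707 = "707-nonPU"

_ICD9_RE = re.compile(r"^(V|E)?(\d+)(?:\.(\d{1,2}))?$")


def truncate_icd9(code: str) -> str:
    """Collapse a full ICD-9 code to its three-digit disease category.

    ``"428.0" -> "428"``; E/V-prefixed codes keep their prefix
    (``"E812.0" -> "E812"``).  The 707 family is special-cased: 707.1,
    707.8 and 707.9 (chronic ulcers that are not pressure ulcers) map to
    ``"707-nonPU"``, every other 707.x to the PU indicator category.
    """
    code = str(code).strip()
    m = _ICD9_RE.match(code)
    if m is None:
        raise ValueError(f"malformed ICD-9 code: {code!r}")
    prefix, digits, decimal = m.group(1) or "", m.group(2), m.group(3)
    want = {"": 3, "V": 2, "E": 3}[prefix]
    if len(digits) != want:
        raise ValueError(f"malformed ICD-9 code: {code!r}")
    category = prefix + digits
    if category == "707":
        if decimal is not None and decimal[0] in "189":
            return NONPU_707
        return PU_CATEGORY
    return category


def label_pu(codes: Iterable[str]) -> int:
    """1 iff any code truncates to the PU indicator category."""
    return int(any(truncate_icd9(c) == PU_CATEGORY for c in codes))


def _parse_codes(cell) -> list[str]:
    if isinstance(cell, str):
        return [c for c in cell.split(";") if c]
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return list(cell)


def filter_cohort(
    raw: pd.DataFrame, min_age: int = 18, min_icu_hours: float = 36.0
) -> pd.DataFrame:
    """Apply the admission-level inclusion rules, in order, and build the
    patient-level cohort table.

    Rules: age >= 18; no PU at admission; ICU stay >= 36 hours; first
    hospitalization only; first ICU admission within it; one row per
    patient.  Per-rule exclusion counts are logged and stored in
    ``result.attrs["exclusion_counts"]``.  Diagnosis features are rebuilt
    from ``icd9_codes`` (truncated categories, PU indicator removed) and the
    outcome label from :func:`label_pu`.
    """
    if raw.empty:
        raise ValueError("raw admission table is empty")
    df = raw
    counts: dict[str, int] = {}

    def drop(mask: pd.Series, rule: str, frame: pd.DataFrame) -> pd.DataFrame:
        counts[rule] = int(mask.sum())
        return frame.loc[~mask]

    df = drop(df["age"] < min_age, "underage", df)
    df = drop(df["pu_at_admission"] == 1, "pu_at_admission", df)
    df = drop(df["icu_hours"] < min_icu_hours, "short_stay", df)
    df = drop(df["hosp_seq"] != 1, "repeat_hospitalization", df)
    df = drop(df["icu_seq"] != 1, "repeat_icu", df)
    dup = df.duplicated(subset=ID_COLUMN, keep="first")
    df = drop(dup, "duplicate_patient", df)
    for rule, n in counts.items():
        log.info("filter_cohort: excluded %d records (%s)", n, rule)
    if df.empty:
        log.warning("filter_cohort: no records remain after filtering")

    code_lists = [
        [truncate_icd9(c) for c in _parse_codes(cell)] for cell in df["icd9_codes"]
    ]
    pu = np.array([int(PU_CATEGORY in codes) for codes in code_lists])
    categories = sorted({c for codes in code_lists for c in codes if c != PU_CATEGORY})

    out = pd.DataFrame({ID_COLUMN: df[ID_COLUMN].to_numpy(), PU_COLUMN: pu})
    braden_cols = [c for c in BRADEN_SUBSCALES if c in df.columns]
    for c in braden_cols:
        out[c] = df[c].to_numpy()
    if braden_cols:
        total = out[braden_cols].sum(axis=1)
        out[BRADEN_TOTAL] = total
        out[BRADEN_BAND] = braden_band(total)
    for c in df.columns:
        if c.startswith(("med_", "noise_")):
            out[c] = df[c].to_numpy()
    for cat in categories:
        out[f"dx_{cat}"] = np.array([int(cat in codes) for codes in code_lists])
    out = out.reset_index(drop=True)
    out.attrs["exclusion_counts"] = counts
    return out


def frequency_filter(
    cohort: pd.DataFrame, min_count: int = 10
) -> pd.DataFrame:
    """Drop binary features with fewer than ``min_count`` positive records
    (a feature with exactly ``min_count`` is kept).  Braden columns are never
    dropped.  Dropped names are recorded in ``attrs["frequency_dropped"]``."""
    dropped = [
        c for c in binary_feature_columns(cohort) if int(cohort[c].sum()) < min_count
    ]
    out = cohort.drop(columns=dropped)
    out.attrs = dict(cohort.attrs)
    out.attrs["frequency_dropped"] = dropped
    if dropped:
        log.info("frequency_filter: dropped %d features below %d positives", len(dropped), min_count)
    return out


def contingency_2x2(feature: Sequence[int], labels: Sequence[int]) -> np.ndarray:
    """2x2 cross-tabulation; rows are feature 0/1, columns label 0/1."""
    f = np.asarray(feature)
    y = np.asarray(labels)
    if f.shape != y.shape:
        raise ValueError("feature and labels have different lengths")
    table = np.zeros((2, 2), dtype=np.int64)
    np.add.at(table, (f, y), 1)
    return table


def _expected(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / n


def choose_test(table: np.ndarray) -> str:
    """``"chi-square"`` iff every expected cell count is >= 20, else
    ``"fisher-exact"`` (which also covers degenerate zero margins)."""
    table = np.asarray(table)
    if (table < 0).any():
        raise ValueError("negative counts")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return "fisher-exact"
    return "chi-square" if _expected(table).min() >= 20 else "fisher-exact"


def pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction; 1 df."""
    exp = _expected(table)
    if (exp == 0).any():
        raise ValueError("chi-square undefined: zero margin")
    stat = float((((np.asarray(table) - exp) ** 2) / exp).sum())
    return stat, float(stats.chi2.sf(stat, 1))


def lr_chi2(table: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio (G) chi-square ``2 sum O ln(O/E)``; empty cells
    contribute 0; 1 df."""
    obs = np.asarray(table, dtype=float)
    exp = _expected(table)
    if (exp == 0).any():
        raise ValueError("chi-square undefined: zero margin")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = obs * np.log(obs / exp)
    stat = float(2.0 * np.where(obs > 0, terms, 0.0).sum())
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, 1))


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value by the point-probability method: sum
    the hypergeometric probabilities of all same-margin tables whose
    probability does not exceed the observed table's."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


@dataclass(frozen=True)
class _Rule:
    """Retention rule of one feature class."""

    alpha: float | None  # p-value threshold (medications)
    stat_threshold: float | None  # chi-square statistic bound (diagnoses)
    fisher_alpha: float | None  # fallback when Fisher is chosen for diagnoses


_RULES = {
    "medication": _Rule(alpha=0.1, stat_threshold=None, fisher_alpha=None),
    "diagnosis": _Rule(alpha=None, stat_threshold=20.0, fisher_alpha=0.001),
    "noise": _Rule(alpha=0.1, stat_threshold=None, fisher_alpha=None),
}


def univariate_screen(
    cohort: pd.DataFrame,
    feature_class_name: str = "medication",
    min_count: int | None = None,
    chi2_variant: str = "pearson",
    alpha: float | None = None,
    stat_threshold: float | None = None,
) -> pd.DataFrame:
    """Univariate association screen of one feature class against PU.

    Medications (and noise features, screened like medications) are retained
    when the chosen test's p-value is below 0.1; diagnoses when the
    chi-square statistic exceeds 20 (p < 0.001 when Fisher is the chosen
    test).  Braden features always pass.  When ``min_count`` is given the
    frequency filter is applied first and its casualties reported with
    reason ``frequency-filtered``.

    Returns a frame with columns ``feature, test, statistic, p, retained,
    reason``.
    """
    if feature_class_name == "braden":
        feats = [c for c in cohort.columns if feature_class(c) == "braden" and c != BRADEN_TOTAL]
        return pd.DataFrame(
            {
                "feature": feats,
                "test": "none",
                "statistic": np.nan,
                "p": np.nan,
                "retained": True,
                "reason": "retained",
            }
        )
    rule = _RULES[feature_class_name]
    if alpha is not None:
        rule = _Rule(alpha, rule.stat_threshold, rule.fisher_alpha)
    if stat_threshold is not None:
        rule = _Rule(rule.alpha, stat_threshold, 0.001)
    chi2_fn = {"pearson": pearson_chi2, "lr": lr_chi2}[chi2_variant]

    frame = cohort
    freq_dropped: list[str] = []
    if min_count is not None:
        frame = frequency_filter(cohort, min_count)
        freq_dropped = [
            c for c in frame.attrs.get("frequency_dropped", [])
            if feature_class(c) == feature_class_name
        ]

    y = frame[PU_COLUMN].to_numpy()
    rows: list[dict] = []
    for c in freq_dropped:
        rows.append(
            dict(feature=c, test="none", statistic=np.nan, p=np.nan,
                 retained=False, reason="frequency-filtered")
        )
    for c in binary_feature_columns(frame):
        if feature_class(c) != feature_class_name:
            continue
        table = contingency_2x2(frame[c].to_numpy(), y)
        test = choose_test(table)
        if test == "chi-square":
            stat, p = chi2_fn(table)
        else:
            stat, p = np.nan, fisher_exact(table)
        if rule.stat_threshold is not None:
            if test == "chi-square":
                retained = stat > rule.stat_threshold
            else:
                retained = p < rule.fisher_alpha
        else:
            retained = p < rule.alpha
        rows.append(
            dict(feature=c, test=test, statistic=stat, p=p,
                 retained=bool(retained), reason="retained" if retained else "not-significant")
        )
    return pd.DataFrame(rows, columns=["feature", "test", "statistic", "p", "retained", "reason"])


def write_screening(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False)


def demographics_table(
    cohort: pd.DataFrame,
    categorical: Sequence[str] = (),
    continuous: Sequence[str] = (),
    chi2_variant: str = "lr",
) -> pd.DataFrame:
    """Group-comparison summary in the style of a clinical Table 1.

    One row per variable level: totals, PU-group and non-PU-group counts
    (percent) for categorical variables, mean (SD) for continuous ones, with
    a 2x2 chi-square statistic (likelihood-ratio by default) for categorical
    rows and a pooled-variance two-sample t statistic for continuous rows.
    """
    chi2_fn = {"pearson": pearson_chi2, "lr": lr_chi2}[chi2_variant]
    pu = cohort[PU_COLUMN] == 1
    rows: list[dict] = [
        dict(variable="N", level="", total=len(cohort),
             pu_group=int(pu.sum()), non_pu_group=int((~pu).sum()),
             statistic=np.nan, p=np.nan)
    ]
    for var in categorical:
        levels = sorted(cohort[var].unique())
        for i, lev in enumerate(levels):
            mask = cohort[var] == lev
            stat = p = np.nan
            if i == 0 and len(levels) == 2:
                table = contingency_2x2(mask.astype(int), pu.astype(int))
                stat, p = chi2_fn(table)
            n_pu, n_non = int((mask & pu).sum()), int((mask & ~pu).sum())
            rows.append(
                dict(variable=var, level=str(lev), total=int(mask.sum()),
                     pu_group=n_pu, non_pu_group=n_non, statistic=stat, p=p)
            )
    for var in continuous:
        a = cohort.loc[pu, var].to_numpy(dtype=float)
        b = cohort.loc[~pu, var].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            dict(variable=var, level="mean (SD)",
                 total=f"{cohort[var].mean():.1f} ({cohort[var].std(ddof=1):.1f})",
                 pu_group=f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                 non_pu_group=f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                 statistic=float(t), p=float(p))
        )
    return pd.DataFrame(rows)
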