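"""Train/validate evaluation harness.

Reproduces the study protocol around the Bayesian-network classifier:
repeated random 67/33 train/validation splits, per-trial sensitivity,
specificity, predictive values and rank AUC with mean (sample SD)
aggregation, the Braden-total threshold baseline, a maximum-likelihood
logistic-regression comparator, feature-set comparisons (B / M / D / BD /
BMD) and the feature- and record-duplication scalability benchmarks.

Screening runs *inside* the trial loop on the training fold only, so no
validation label ever influences variable selection.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .cohort import (
    BRADEN_TOTAL,
    ID_COLUMN,
    PU_COLUMN,
    feature_class,
    network_feature_columns,
)
from .network import DiscreteDataset, estimate_parameters, pu_posterior
from .screening import univariate_screen
from .search import SearchConfig, hill_climb, learn_structure, tabu_search

__all__ = [
    "TrialPlan",
    "EvaluationReport",
    "split_data",
    "confusion_metrics",
    "auc",
    "run_trials",
    "braden_baseline",
    "scan_braden_threshold",
    "logistic_baseline",
    "feature_set_experiment",
    "side_by_side",
    "scalability_bench",
    "permute_labels",
    "trial_seed",
]

log = logging.getLogger(__name__)

_METRICS = ("sens", "spec", "ppv", "npv", "auc")


@dataclass
class TrialPlan:
    """Protocol of one repeated-split experiment.

    ``feature_set`` uses the study letters (``B`` Braden, ``M`` medication,
    ``D`` diagnosis, ``N`` synthetic noise); ``threshold`` is the posterior
    cutoff for a positive call (most-probable-class 0.5 by default);
    ``prior`` the CPT pseudo-count.
    """

    n_trials: int = 100
    train_fraction: float = 0.67
    feature_set: str = "BD"
    search: SearchConfig = field(
        default_factory=lambda: SearchConfig(algorithm="tabu", score="bdeu", init="naive_bayes")
    )
    prior: float = 1.0
    threshold: float = 0.5
    screen: bool = True
    min_count: int = 10
    stratify: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class EvaluationReport:
    """Per-trial metrics plus their mean / sample-SD aggregation."""

    label: str
    trials: pd.DataFrame
    summary: pd.DataFrame
    failures: int = 0

    def mean(self, metric: str) -> float:
        return float(self.summary.loc[self.summary.metric == metric, "mean"].iloc[0])


def trial_seed(plan_seed: int, trial: int) -> int:
    """Deterministic per-trial seed (kept below 2**31)."""
    return int(np.random.SeedSequence((plan_seed, trial)).generate_state(1)[0] % (2**31))


def split_data(
    cohort: pd.DataFrame,
    fraction: float = 0.67,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random partition into training (``floor(fraction * n)`` records) and
    validation sets; optionally stratified by the outcome."""
    n = len(cohort)
    if n < 2:
        raise ValueError("cohort must have at least 2 records")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[np.ndarray] = []
        for _, grp in cohort.groupby(PU_COLUMN):
            perm = grp.index.to_numpy()[rng.permutation(len(grp))]
            train_idx.append(perm[: int(len(perm) * fraction)])
        tr = np.concatenate(train_idx)
    else:
        perm = cohort.index.to_numpy()[rng.permutation(n)]
        tr = perm[: int(n * fraction)]
    mask = cohort.index.isin(tr)
    train, val = cohort.loc[mask], cohort.loc[~mask]
    if train.empty or val.empty:
        log.warning("degenerate split: train=%d validate=%d", len(train), len(val))
    return train, val


def confusion_metrics(labels, predicted) -> dict[str, float | None]:
    """SENS/SPEC/PPV/NPV from a confusion table; zero-denominator metrics
    are ``None`` (excluded from aggregation, with a count)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predicted).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions have different lengths")
    tp = int(((y == 1) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())

    def ratio(a: int, b: int) -> float | None:
        return a / b if b > 0 else None

    return {
        "sens": ratio(tp, tp + fn),
        "spec": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def auc(labels, scores) -> float | None:
    """Rank (Mann-Whitney) AUC with half-credit for ties; ``None`` when only
    one class is present."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def screen_features(
    train: pd.DataFrame, features: Sequence[str], min_count: int = 10
) -> list[str]:
    """Training-fold univariate screen: Braden features pass, medications
    (and noise, screened the same way) at alpha = 0.1, diagnoses at
    chi-square > 20, after the frequency filter."""
    sub = train[[PU_COLUMN, *features]]
    keep = {c for c in features if feature_class(c) == "braden"}
    for cls in ("medication", "diagnosis", "noise"):
        if any(feature_class(c) == cls for c in features):
            res = univariate_screen(sub, cls, min_count=min_count)
            keep.update(res.loc[res["retained"], "feature"])
    return [c for c in features if c in keep]


def _aggregate(trials: pd.DataFrame, label: str, failures: int = 0) -> EvaluationReport:
    rows = []
    for m in _METRICS:
        vals = trials[m].dropna()
        rows.append(
            dict(metric=m, mean=vals.mean() if len(vals) else np.nan,
                 sd=vals.std(ddof=1) if len(vals) > 1 else np.nan,
                 n_defined=int(len(vals)), n_undefined=int(trials[m].isna().sum()))
        )
    return EvaluationReport(label, trials, pd.DataFrame(rows), failures)


def run_trials(cohort: pd.DataFrame, plan: TrialPlan, label: str = "BN") -> EvaluationReport:
    """The full protocol: per trial, split; screen on the training fold;
    learn structure and CPTs on the training fold; score the validation fold
    with the PU posterior; report threshold metrics and AUC."""
    features_all = network_feature_columns(cohort, set(plan.feature_set))
    if not features_all:
        raise ValueError(f"feature set {plan.feature_set!r} selects no columns")
    records: list[dict] = []
    failures = 0
    for t in range(plan.n_trials):
        seed = trial_seed(plan.seed, t)
        train, val = split_data(cohort, plan.train_fraction, seed, plan.stratify)
        feats = screen_features(train, features_all, plan.min_count) if plan.screen else list(features_all)
        if not feats:
            # degenerate but well-defined: an outcome-only network scores
            # every record with the training prevalence
            log.warning("trial %d: no features retained; falling back to the prior model", t)
            failures += 1
        cols = [PU_COLUMN, *feats]
        ds_train = DiscreteDataset.from_frame(train, cols)
        cfg = replace(plan.search, seed=seed)
        structure, _ = learn_structure(ds_train, cfg, pu_node=PU_COLUMN)
        params = estimate_parameters(ds_train, structure, plan.prior)
        ds_val = DiscreteDataset.from_frame(val, cols)
        post = pu_posterior(structure, params, ds_val)
        y = val[PU_COLUMN].to_numpy()
        rec = confusion_metrics(y, post >= plan.threshold)
        rec["auc"] = auc(y, post)
        rec["trial"] = t
        rec["n_features"] = len(feats)
        records.append(rec)
    if not records:
        raise ValueError("every trial failed; nothing to aggregate")
    return _aggregate(pd.DataFrame(records), label, failures)


def braden_baseline(
    cohort: pd.DataFrame,
    threshold: int = 13,
    plan: TrialPlan | None = None,
    label: str = "Braden",
) -> EvaluationReport:
    """Threshold baseline: call PU-positive iff Braden total <= ``threshold``
    (lower Braden = higher risk); the continuous risk score for AUC is the
    negated total.  With a ``plan`` the metrics are computed on the same
    validation folds as :func:`run_trials`; otherwise on the full cohort."""
    if BRADEN_TOTAL not in cohort.columns:
        raise ValueError("cohort lacks the braden_total column")
    records = []
    n_trials = plan.n_trials if plan is not None else 1
    for t in range(n_trials):
        if plan is not None:
            seed = trial_seed(plan.seed, t)
            _, val = split_data(cohort, plan.train_fraction, seed, plan.stratify)
        else:
            val = cohort
        y = val[PU_COLUMN].to_numpy()
        total = val[BRADEN_TOTAL].to_numpy()
        rec = confusion_metrics(y, total <= threshold)
        rec["auc"] = auc(y, -total.astype(float))
        rec["trial"] = t
        rec["n_features"] = 1
        records.append(rec)
    return _aggregate(pd.DataFrame(records), label)


def scan_braden_threshold(cohort: pd.DataFrame) -> tuple[int, pd.DataFrame]:
    """Exhaustive scan of the Braden-total cutoff, maximizing the one-point
    ROC area ``(sens + spec) / 2``; ties go to the lower cutoff."""
    y = cohort[PU_COLUMN].to_numpy()
    total = cohort[BRADEN_TOTAL].to_numpy()
    rows = []
    for t in range(int(total.min()), int(total.max()) + 1):
        m = confusion_metrics(y, total <= t)
        point_auc = ((m["sens"] or 0.0) + (m["spec"] or 0.0)) / 2
        rows.append(dict(threshold=t, sens=m["sens"], spec=m["spec"], point_auc=point_auc))
    table = pd.DataFrame(rows)
    best = int(table.loc[table["point_auc"].idxmax(), "threshold"])
    return best, table


def logistic_baseline(
    cohort: pd.DataFrame, plan: TrialPlan, label: str = "LR"
) -> EvaluationReport:
    """Maximum-likelihood main-effects logistic regression on the same
    splits, screening and feature set as the network model: the off-the-shelf
    comparator, not a contribution."""
    features_all = network_feature_columns(cohort, set(plan.feature_set))
    records: list[dict] = []
    failures = 0
    for t in range(plan.n_trials):
        seed = trial_seed(plan.seed, t)
        train, val = split_data(cohort, plan.train_fraction, seed, plan.stratify)
        feats = screen_features(train, features_all, plan.min_count) if plan.screen else list(features_all)
        if not feats:
            failures += 1
            continue
        model = LogisticRegression(penalty=None, max_iter=2000, solver="lbfgs")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model.fit(train[feats].to_numpy(float), train[PU_COLUMN].to_numpy())
        if caught:
            log.info("trial %d: logistic fit warned (%s)", t, caught[0].category.__name__)
        post = model.predict_proba(val[feats].to_numpy(float))[:, 1]
        y = val[PU_COLUMN].to_numpy()
        rec = confusion_metrics(y, post >= plan.threshold)
        rec["auc"] = auc(y, post)
        rec["trial"] = t
        rec["n_features"] = len(feats)
        records.append(rec)
    return _aggregate(pd.DataFrame(records), label, failures)


def feature_set_experiment(
    cohort: pd.DataFrame,
    plan: TrialPlan,
    sets: Sequence[str] = ("B", "M", "D", "BD", "BMD"),
) -> tuple[dict[str, EvaluationReport], pd.DataFrame]:
    """Run the protocol once per feature set and lay the results out as a
    metrics x feature-sets grid of ``mean (sd)`` strings."""
    if not sets:
        raise ValueError("no feature sets given")
    reports = {
        s: run_trials(cohort, replace(plan, feature_set=s), label=s) for s in sets
    }
    grid = pd.DataFrame(
        {
            s: {
                row.metric: f"{row.mean:.3f} ({row.sd:.3f})"
                for row in rep.summary.itertuples()
            }
            for s, rep in reports.items()
        }
    )
    grid.index.name = "metric"
    return reports, grid


def side_by_side(
    cohort: pd.DataFrame,
    plan: TrialPlan,
    braden_threshold: int = 13,
) -> pd.DataFrame:
    """Bayesian network vs logistic regression vs the Braden-threshold
    baseline on identical splits; one row per model with mean sensitivity,
    specificity and AUC.  The comparison is reported, not asserted."""
    bn = run_trials(cohort, plan, label="BN")
    lr = logistic_baseline(cohort, plan, label="LR")
    br = braden_baseline(cohort, braden_threshold, plan, label="Braden")
    rows = []
    for rep in (br, lr, bn):
        rows.append(
            dict(model=rep.label,
                 sens=rep.mean("sens"), spec=rep.mean("spec"), auc=rep.mean("auc"),
                 n_trials=len(rep.trials))
        )
    return pd.DataFrame(rows)


def plot_metric_boxes(reports: Sequence[EvaluationReport], path,
                      metrics: Sequence[str] = ("sens", "spec", "auc")) -> None:
    """Box plot of per-trial metrics across models (SVG/PNG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(metrics), figsize=(3.2 * len(metrics), 3.4),
                             sharey=True)
    for ax, metric in zip(np.atleast_1d(axes), metrics):
        data = [rep.trials[metric].dropna() for rep in reports]
        ax.boxplot(data, tick_labels=[rep.label for rep in reports])
        ax.set_title(metric.upper())
        ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def permute_labels(cohort: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Copy of the cohort with the outcome column randomly permuted -- the
    null cohort used for calibration checks."""
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    out[PU_COLUMN] = out[PU_COLUMN].to_numpy()[rng.permutation(len(out))]
    return out


def scalability_bench(
    cohort: pd.DataFrame,
    mode: str = "duplicate_features",
    factors: Sequence[int] = (1, 2, 3),
    config: SearchConfig | None = None,
    feature_set: str = "BD",
) -> pd.DataFrame:
    """Runtime of structure learning as columns or rows are duplicated.

    ``duplicate_features`` suffixes copied columns; ``duplicate_records``
    stacks copies of every row.  Wall time and accepted-step counts are a
    report artifact, never an assertion.
    """
    if mode not in ("duplicate_features", "duplicate_records"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or SearchConfig(algorithm="hill_climb", score="mdl", init="naive_bayes")
    features = network_feature_columns(cohort, set(feature_set))
    rows = []
    for factor in factors:
        if factor < 1:
            raise ValueError("factor must be >= 1")
        df = cohort[[PU_COLUMN, *features]]
        if mode == "duplicate_features":
            extra = {
                f"{c}_d{k}": df[c].to_numpy()
                for k in range(2, factor + 1)
                for c in features
            }
            df = pd.concat([df, pd.DataFrame(extra, index=df.index)], axis=1)
        else:
            df = pd.concat([df] * factor, ignore_index=True)
        ds = DiscreteDataset.from_frame(df)
        t0 = time.perf_counter()
        if config.algorithm == "tabu":
            _, _, trace = tabu_search(ds, config, pu_node=PU_COLUMN)
        else:
            _, _, trace = hill_climb(ds, config, pu_node=PU_COLUMN)
        rows.append(
            dict(mode=mode, factor=factor, n_features=ds.matrix.shape[1] - 1,
                 n_records=ds.n, seconds=time.perf_counter() - t0, steps=len(trace))
        )
    return pd.DataFrame(rows)
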