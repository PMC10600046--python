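"""Behavioral response analysis: filtering, aggregation, ranking, and tests.

A trial table is a DataFrame with one row per response and columns
``observer_id, observer_type, condition_id, true_class, predicted_class,
confidence, response_time, is_catch`` (``response_time`` optional).  Humans
report confidence on a 1–5 scale; network confidence is any per-trial score in
[0, 1] treated as an opaque column.

The statistical comparisons mirror a human-vs-network study design: paired
t-tests on matched per-condition accuracies, Pearson product-moment
correlation, OLS regression of one observer type's per-condition accuracy on
the other's, and the confidence–accuracy correlation that separates human-like
observers (confidence tracks accuracy) from network-like ones (it does not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    FilteringError,
    PairingError,
    ParameterError,
)
from .grid import TransformSpec

__all__ = [
    "TRIAL_COLUMNS",
    "ComparisonResult",
    "filter_participants",
    "condition_accuracy",
    "transform_ranking",
    "paired_comparison",
    "pearson_r",
    "ols_fit",
    "confidence_accuracy_correlation",
]

TRIAL_COLUMNS = [
    "observer_id", "observer_type", "condition_id", "true_class",
    "predicted_class", "confidence", "response_time", "is_catch",
]

#: consistency constant making MAD estimate the SD under normality
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one statistical comparison."""

    name: str
    statistic: float
    df: float
    p_value: float
    estimate: float
    details: dict = field(default_factory=dict)

    def __str__(self):
        extra = "".join(f", {k}={v:.4g}" for k, v in self.details.items())
        return (f"{self.name}: statistic={self.statistic:.4g}, df={self.df:g}, "
                f"p={self.p_value:.4g}, estimate={self.estimate:.4g}{extra}")


def _correct(trials: pd.DataFrame) -> pd.Series:
    return trials["true_class"] == trials["predicted_class"]


def filter_participants(trials: pd.DataFrame, catch_min: float = 2 / 3,
                        mad_c: float = 3.0):
    """Two-stage observer exclusion: catch trials, then MAD outliers.

    Stage 1 drops observers whose accuracy on catch trials (rows with
    ``is_catch``) falls below ``catch_min``; observers with no catch trials
    pass by default.  Stage 2 computes each surviving observer's accuracy on
    non-catch trials and drops those deviating from the cohort median by more
    than ``mad_c`` x MAD, with the MAD scaled by 1.4826 so it estimates the
    SD under normality.  When the cohort is perfectly homogeneous the MAD is
    zero and a zero deviation still passes.

    Returns ``(kept_trials, exclusion_report)`` where the report is a
    DataFrame with one row per excluded observer (``observer_id, reason,
    value, threshold``).
    """
    if len(trials) == 0:
        raise FilteringError("trial table is empty")
    trials = trials.copy()
    trials["_correct"] = _correct(trials)
    exclusions = []

    catch = trials[trials["is_catch"].astype(bool)]
    catch_acc = catch.groupby("observer_id")["_correct"].mean()
    for obs, acc in catch_acc.items():
        if acc < catch_min:
            exclusions.append({"observer_id": obs, "reason": "catch",
                               "value": acc, "threshold": catch_min})
    failed_catch = {e["observer_id"] for e in exclusions}

    main = trials[~trials["is_catch"].astype(bool)]
    main = main[~main["observer_id"].isin(failed_catch)]
    overall = main.groupby("observer_id")["_correct"].mean()
    if len(overall):
        median = overall.median()
        mad = MAD_SCALE * (overall - median).abs().median()
        threshold = mad_c * mad
        for obs, acc in overall.items():
            if abs(acc - median) > threshold:
                exclusions.append({"observer_id": obs, "reason": "mad",
                                   "value": acc, "threshold": threshold})

    excluded = {e["observer_id"] for e in exclusions}
    kept = trials[~trials["observer_id"].isin(excluded)].drop(columns="_correct")
    if kept["observer_id"].nunique() == 0:
        raise FilteringError("filtering excluded every observer")
    report = pd.DataFrame(
        exclusions, columns=["observer_id", "reason", "value", "threshold"]
    )
    return kept, report


def _family_of(condition_id: str) -> str:
    return TransformSpec.from_condition_id(condition_id).family


def condition_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (observer_type, condition_id) accuracy, mean confidence, and n.

    Catch trials are excluded from the aggregates.  The result carries one
    row per condition summary with the transform family attached.
    """
    main = trials[~trials["is_catch"].astype(bool)].copy()
    main["_correct"] = _correct(main)
    grouped = main.groupby(["observer_type", "condition_id"], sort=True)
    summary = grouped.agg(
        n_trials=("_correct", "size"),
        accuracy=("_correct", "mean"),
        mean_confidence=("confidence", "mean"),
    ).reset_index()
    summary["family"] = summary["condition_id"].map(_family_of)
    return summary[["observer_type", "condition_id", "family", "n_trials",
                    "accuracy", "mean_confidence"]]


def transform_ranking(summaries: pd.DataFrame,
                      observer_type: str | None = None) -> pd.DataFrame:
    """Transform families ranked by mean accuracy, descending.

    The family mean averages its condition summaries (one value per parameter
    setting, unweighted, so every parameter setting counts equally).  Ties are
    broken alphabetically and flagged in the ``tied`` column.
    """
    if observer_type is not None:
        summaries = summaries[summaries["observer_type"] == observer_type]
    if len(summaries) == 0:
        raise ParameterError("no summaries to rank")
    means = (summaries.groupby("family")["accuracy"].mean()
             .rename("mean_accuracy").reset_index())
    means = means.sort_values(["mean_accuracy", "family"],
                              ascending=[False, True], ignore_index=True)
    means["tied"] = means["mean_accuracy"].duplicated(keep=False)
    means["rank"] = np.arange(1, len(means) + 1)
    return means


def _paired_arrays(a, b):
    a = pd.Series(a).astype(float)
    b = pd.Series(b).astype(float)
    if len(a) != len(b):
        raise PairingError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise PairingError("need at least 2 pairs")
    if not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        if len(common) != len(a):
            raise PairingError("indices (condition ids) do not match")
        b = b.reindex(a.index)
    return a.to_numpy(), b.to_numpy()


def paired_comparison(a, b, df: float | None = None) -> ComparisonResult:
    """Paired t-test on matched per-condition values.

    ``a`` and ``b`` may be arrays or Series indexed by condition id (indices
    must then match).  The statistic is the classical paired t on the
    differences with ``df = n - 1``; pass ``df`` explicitly to evaluate the
    p-value at another convention (e.g. the number of independent transform
    variables) while keeping the same statistic.  Identical inputs give
    t = 0; nonzero differences with zero variance are flagged as degenerate
    rather than reported as an infinite t.
    """
    x, y = _paired_arrays(a, b)
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            t = 0.0
        else:
            raise DegenerateVarianceError(
                "paired differences are constant and nonzero; t is undefined"
            )
    else:
        t = mean / (sd / np.sqrt(n))
    used_df = float(df) if df is not None else float(n - 1)
    p = float(2 * sps.t.sf(abs(t), used_df))
    return ComparisonResult("paired_t", float(t), used_df, p, float(mean),
                            details={"n": n})


def pearson_r(x, y) -> ComparisonResult:
    """Pearson product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise PairingError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise PairingError("need at least 3 observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DegenerateVarianceError(
            "correlation undefined for a zero-variance sample"
        )
    res = sps.pearsonr(x, y)
    return ComparisonResult("pearson_r", float(res.statistic), float(len(x) - 2),
                            float(res.pvalue), float(res.statistic))


def ols_fit(response, predictor) -> ComparisonResult:
    """Simple OLS regression of ``response`` on ``predictor``.

    Reports the slope as the estimate together with the intercept and R²; the
    statistic and p-value refer to the two-sided slope t-test.  In this simple
    regression R² equals the squared Pearson correlation.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(x) != len(y):
        raise PairingError(f"length mismatch: {len(y)} vs {len(x)}")
    if len(x) < 3:
        raise PairingError("need at least 3 observations")
    if np.std(x) == 0.0:
        raise DegenerateVarianceError("constant predictor: singular fit")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    return ComparisonResult(
        "ols_slope", float(model.tvalues[1]), float(model.df_resid),
        float(model.pvalues[1]), slope,
        details={"intercept": float(model.params[0]),
                 "r_squared": float(model.rsquared)},
    )


def confidence_accuracy_correlation(trials: pd.DataFrame,
                                    observer_type: str) -> ComparisonResult:
    """Pearson r between per-condition mean confidence and accuracy.

    Human observers typically show a strong positive correlation — they know
    when a transform is hard — whereas networks' confidence scores are
    largely unrelated to their per-condition accuracy.
    """
    summaries = condition_accuracy(trials)
    rows = summaries[summaries["observer_type"] == observer_type]
    if len(rows) < 3:
        raise PairingError("need at least 3 conditions")
    return pearson_r(rows["mean_confidence"].to_numpy(),
                     rows["accuracy"].to_numpy())
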