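"""Prediction metrics, fold aggregation and model comparison tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "accuracy_pearson",
    "accuracy_spearman",
    "rmse",
    "slope_bias",
    "relative_difference",
    "aggregate_folds",
    "accuracy_vs_h2_fit",
    "fold_metrics",
    "comparison_table",
]


def _paired(y_true, y_pred, min_n=1):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("paired vectors must have equal length")
    if len(y_true) < min_n:
        raise ValueError(f"need at least {min_n} paired values")
    return y_true, y_pred


def accuracy_pearson(y_true, y_pred) -> float:
    """Pearson correlation r = cor(y*, y-hat*)."""
    y_true, y_pred = _paired(y_true, y_pred, 3)
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(stats.pearsonr(y_true, y_pred)[0])


def accuracy_spearman(y_true, y_pred) -> float:
    """Spearman rank correlation."""
    y_true, y_pred = _paired(y_true, y_pred, 3)
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(stats.spearmanr(y_true, y_pred)[0])


def rmse(y_true, y_pred) -> float:
    """Root mean squared prediction error."""
    y_true, y_pred = _paired(y_true, y_pred, 1)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def slope_bias(y_true, y_pred) -> float:
    """OLS slope of y* regressed on y-hat*; 1 = empirically unbiased."""
    y_true, y_pred = _paired(y_true, y_pred, 2)
    v = np.var(y_pred)
    if v == 0:
        raise ValueError("zero-variance predictions: slope undefined")
    return float(np.cov(y_true, y_pred, ddof=0)[0, 1] / v)


def relative_difference(r_model: float, r_baseline: float) -> float:
    """RD% = (r_model - r_baseline) / r_baseline * 100 (baseline: GBLUP)."""
    if r_baseline == 0:
        raise ValueError("zero baseline accuracy")
    return float((r_model - r_baseline) / r_baseline * 100.0)


def fold_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-(design, repeat, fold) metrics from a raw prediction table."""
    rows = []
    for (design, rep, fold), grp in predictions.groupby(["design", "repeat", "fold"]):
        ok = grp[~grp["failed"]] if "failed" in grp else grp
        if len(ok) < 3:
            continue
        yt, yp = ok["y_true"].to_numpy(), ok["y_pred"].to_numpy()
        constant = np.std(yp) == 0  # no-signal model: zero predictive ability
        rows.append(
            {
                "design": design,
                "repeat": rep,
                "fold": fold,
                "n": len(ok),
                "pearson": 0.0 if constant else accuracy_pearson(yt, yp),
                "spearman": 0.0 if constant else accuracy_spearman(yt, yp),
                "rmse": rmse(yt, yp),
                "slope": np.nan if constant else slope_bias(yt, yp),
            }
        )
    return pd.DataFrame(rows)


def aggregate_folds(per_fold: pd.DataFrame, by=("design",)) -> pd.DataFrame:
    """Mean and standard error of each metric across folds/repeats."""
    if len(per_fold) < 2:
        raise ValueError("need metrics from at least 2 folds")
    metrics = [c for c in ("pearson", "spearman", "rmse", "slope") if c in per_fold]
    out = []
    for key, grp in per_fold.groupby(list(by)):
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n_folds"] = len(grp)
        for mcol in metrics:
            vals = grp[mcol].dropna().to_numpy()
            row[f"{mcol}_mean"] = vals.mean()
            row[f"{mcol}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
        out.append(row)
    return pd.DataFrame(out)


def comparison_table(
    results: dict[str, pd.DataFrame], baseline: str = "GBLUP"
) -> pd.DataFrame:
    """Per-model mean metrics and RD vs the baseline model.

    ``results`` maps model name -> raw prediction table.
    """
    if baseline not in results:
        raise ValueError(f"baseline {baseline!r} missing from results")
    rows = {}
    for name, preds in results.items():
        pf = fold_metrics(preds)
        rows[name] = {
            "model": name,
            "pearson": pf["pearson"].mean(),
            "pearson_se": pf["pearson"].std(ddof=1) / np.sqrt(len(pf)),
            "spearman": pf["spearman"].mean(),
            "rmse": pf["rmse"].mean(),
            "slope": pf["slope"].mean(),
        }
    r_base = rows[baseline]["pearson"]
    for name in rows:
        rows[name]["rd_vs_baseline"] = relative_difference(rows[name]["pearson"], r_base)
    return pd.DataFrame(list(rows.values()))


def accuracy_vs_h2_fit(accuracies, heritabilities) -> float:
    """R^2 of the least-squares line of accuracy on heritability."""
    acc = np.asarray(accuracies, dtype=float)
    h2 = np.asarray(heritabilities, dtype=float)
    if len(acc) < 3 or len(acc) != len(h2):
        raise ValueError("need >= 3 paired (accuracy, h2) points")
    res = stats.linregress(h2, acc)
    return float(res.rvalue**2)
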