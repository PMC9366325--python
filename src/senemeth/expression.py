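"""Relative expression (delta-delta-Ct) and chlorophyll-from-colour tools.

``delta_delta_ct`` implements the Livak relative-quantification scheme for
qRT-PCR: per technical replicate, the target Ct is normalized to the mean
reference-gene Ct of the same (time point, biological replicate), then to
the gene's own mean delta-Ct at the reference time point (flowering by
default), and expression is ``2**-ddCt``. Technical replicates are averaged
on the log (ddCt) scale before exponentiation, so the mean normalized
value at the reference time point equals 1 exactly, per biological
replicate and hence also across replicates.

``fit_chlorophyll_model`` fits the leaf-colour regression

    Chl/DW ~ percent_green + percent_green:g_norm + percent_green:percent_gy

by ordinary least squares, where percent_green and percent_gy are the
green and green-yellow pixel fractions of the leaf image and g_norm is the
leaf's green-pixel deficit relative to the maximum green count of its leaf
position, ``(max_green - leaf_green) / max_green``. Model quality is
summarised by repeated stratified k-fold cross-validation (k=5, 10
repeats) on the held-out R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "delta_delta_ct",
    "g_norm",
    "chlorophyll_design",
    "fit_chlorophyll_model",
    "predict_chlorophyll",
    "ChlorophyllFit",
]


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str,
    reference_timepoint: str = "Flwr",
    log_scale_averaging: bool = True,
) -> pd.DataFrame:
    """Normalized expression 2^-ddCt per (gene, time point, biological replicate).

    ``table`` needs columns gene, time_point, biological_replicate,
    technical_replicate, Ct. The reference gene must be measured at every
    (time point, biological replicate) that carries target measurements,
    and every (gene, biological replicate) needs the reference time point;
    gaps raise a ``ValueError`` listing them. With ``log_scale_averaging``
    (default) technical replicates are averaged on the ddCt scale, which
    pins the reference-time-point mean at exactly 1.
    """
    req = {"gene", "time_point", "biological_replicate", "technical_replicate", "Ct"}
    missing_cols = req - set(table.columns)
    if missing_cols:
        raise ValueError(f"Ct table lacks columns {sorted(missing_cols)}")
    df = table.copy()
    ref = df[df["gene"] == reference_gene]
    targets = df[df["gene"] != reference_gene]
    if targets.empty:
        raise ValueError("no target genes in table")

    ref_mean = ref.groupby(["time_point", "biological_replicate"])["Ct"].mean()
    need = targets[["time_point", "biological_replicate"]].drop_duplicates()
    gaps = [
        (tp, br)
        for tp, br in need.itertuples(index=False)
        if (tp, br) not in ref_mean.index
    ]
    if gaps:
        raise ValueError(f"reference gene {reference_gene!r} missing at {gaps}")

    t = targets.copy()
    t["dct"] = t["Ct"] - ref_mean.loc[
        pd.MultiIndex.from_frame(t[["time_point", "biological_replicate"]])
    ].to_numpy()

    # technical-replicate mean dCt per (gene, time point, bio replicate);
    # subtracting the reference-time-point entry of the *same* aggregate
    # makes the reference ddCt an exact floating-point zero
    mean_dct = (
        t.groupby(["gene", "time_point", "biological_replicate"])["dct"]
        .mean()
        .rename("mean_dct")
        .reset_index()
    )
    base = (
        mean_dct[mean_dct["time_point"] == reference_timepoint]
        .set_index(["gene", "biological_replicate"])["mean_dct"]
    )
    gaps = [
        (g, br)
        for g, br in t[["gene", "biological_replicate"]].drop_duplicates().itertuples(index=False)
        if (g, br) not in base.index
    ]
    if gaps:
        raise ValueError(
            f"reference time point {reference_timepoint!r} missing for {gaps}"
        )
    if log_scale_averaging:
        out = mean_dct.copy()
        ddct = out["mean_dct"] - base.loc[
            pd.MultiIndex.from_frame(out[["gene", "biological_replicate"]])
        ].to_numpy()
        out["expression"] = 2.0 ** (-ddct)
        return out[["gene", "time_point", "biological_replicate", "expression"]]
    t["ddct"] = t["dct"] - base.loc[
        pd.MultiIndex.from_frame(t[["gene", "biological_replicate"]])
    ].to_numpy()
    t["expr_tech"] = 2.0 ** (-t["ddct"])
    return (
        t.groupby(["gene", "time_point", "biological_replicate"])["expr_tech"]
        .mean()
        .rename("expression")
        .reset_index()
    )


def g_norm(leaf_green: float | np.ndarray, max_green: float | np.ndarray) -> np.ndarray:
    """Green-pixel deficit ``(max_green - leaf_green) / max_green`` in [0, 1]."""
    leaf_green = np.asarray(leaf_green, dtype=float)
    max_green = np.asarray(max_green, dtype=float)
    if np.any(max_green <= 0):
        raise ValueError("max_green must be positive")
    if np.any(leaf_green < 0) or np.any(leaf_green > max_green):
        raise ValueError("leaf_green must lie in [0, max_green]")
    return (max_green - leaf_green) / max_green


def chlorophyll_design(features: pd.DataFrame) -> np.ndarray:
    """Design matrix [1, pg, pg*g_norm, pg*pgy] from leaf pixel counts.

    ``features`` needs columns green, green_yellow, total and either a
    precomputed g_norm column or (leaf_position, from which the per-position
    maximum green count defines g_norm).
    """
    pg = features["green"] / features["total"]
    pgy = features["green_yellow"] / features["total"]
    if "g_norm" in features:
        gn = features["g_norm"].to_numpy(dtype=float)
    else:
        max_green = features.groupby("leaf_position")["green"].transform("max")
        gn = g_norm(features["green"].to_numpy(), max_green.to_numpy())
    return np.column_stack([np.ones(len(features)), pg, pg * gn, pg * pgy])


_TERMS = ["intercept", "percent_green", "percent_green:g_norm", "percent_green:percent_gy"]


@dataclass
class ChlorophyllFit:
    """OLS coefficients with the repeated-CV quality summary."""

    coef: np.ndarray
    r2_train: float
    cv_r2_mean: float
    cv_r2_sd: float
    cv_r2: np.ndarray


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        keep: list[int] = []
        bad = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                bad.append(_TERMS[j])
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_chlorophyll_model(
    features: pd.DataFrame,
    chl_dw: np.ndarray | pd.Series,
    k: int = 5,
    times: int = 10,
    seed: int = 0,
) -> ChlorophyllFit:
    """Fit the colour regression and report repeated stratified k-fold CV R2.

    Folds are stratified on outcome quantile bins so each fold spans the
    chlorophyll range; the partition is deterministic given ``seed`` and
    fold sizes differ by at most one. Requires at least ``3 * k``
    observations.
    """
    y = np.asarray(chl_dw, dtype=float)
    X = chlorophyll_design(features)
    n = len(y)
    if n < 3 * k:
        raise ValueError(f"need at least {3 * k} observations, got {n}")
    beta = _ols(X, y)
    resid = y - X @ beta
    r2_train = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    strata = pd.qcut(pd.Series(y).rank(method="first"), q=min(k, n // k), labels=False)
    scores = []
    for rep in range(times):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for train, test in skf.split(X, strata):
            b = _ols(X[train], y[train])
            pred = X[test] @ b
            sse = np.sum((y[test] - pred) ** 2)
            sst = np.sum((y[test] - y[test].mean()) ** 2)
            scores.append(1.0 - sse / sst if sst > 0 else np.nan)
    scores = np.asarray(scores)
    return ChlorophyllFit(
        coef=beta,
        r2_train=float(r2_train),
        cv_r2_mean=float(np.nanmean(scores)),
        cv_r2_sd=float(np.nanstd(scores)),
        cv_r2=scores,
    )


def predict_chlorophyll(coef: np.ndarray, features: pd.DataFrame) -> np.ndarray:
    """mg chlorophyll per g dry weight from the fitted linear combination."""
    return chlorophyll_design(features) @ np.asarray(coef, dtype=float)
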