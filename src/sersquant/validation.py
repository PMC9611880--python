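"""Model validation engines.

Two schemes mirror the two experimental designs:

* **double (nested) cross-validation** for single-dye dilution series —
  the outer k folds are the k concentration levels (each fold holds all
  technical replicates of one level); an inner (k-1)-fold CV on each outer
  training set picks the component count; held-out predictions are pooled
  into one Q²/RMSECV per run.
* **bootstrap out-of-bag validation** for the multiplexed mixtures — each
  iteration resamples sample ids with replacement (training multiset,
  duplicates enter the fit with their multiplicity), the out-of-bag ids
  form the test set, and an inner k-fold CV on the training set selects
  the component count.

Splits always operate on sample ids, never on individual spectra, so
technical replicates of a sample can never leak between training and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import MAX_COMPONENTS, PLSNipals, regression_metrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Nested-CV settings.

    ``k`` should equal the number of distinct concentration levels for a
    dilution series (7 in the reference design). ``a_max`` bounds the
    component search; the effective ceiling is further limited by the
    training-set rank. ``pool`` selects pooled outer-fold metrics (default)
    versus per-fold averaging.
    """

    k: int = 7
    a_max: int = 10
    pool: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 1 <= self.a_max <= MAX_COMPONENTS:
            raise ValueError(f"a_max must be in [1, {MAX_COMPONENTS}]")


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap-validation settings.

    Defaults follow the reference protocol: 1000 iterations for PLS1 and
    10,000 for PLS2; the inner-CV fold count is the number of distinct
    sample ids in the training set capped at ``inner_k_cap`` (= 7, keeping
    mixture inner folds comparable to the simplex k)."""

    n_boot: int = 1000
    seed: int = 0
    a_max: int = 10
    inner_k_cap: int = 7

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 1 <= self.a_max <= MAX_COMPONENTS:
            raise ValueError(f"a_max must be in [1, {MAX_COMPONENTS}]")
        if self.inner_k_cap < 2:
            raise ValueError("inner_k_cap must be >= 2")


@dataclass
class ValidationSummary:
    """Aggregated validation output.

    ``stats``: per-response mean/SD of R², Q², RMSECV, RMSEP across
    resamples (SD columns are NaN for pooled double-CV, which yields one
    number per run). ``predictions``: per-sample held-out predictions
    (mean, SD, count) for predicted-vs-known plots. ``component_counts``:
    histogram of selected component numbers. ``records``: raw per-resample
    (or per-outer-fold) figures of merit.
    """

    scheme: str
    responses: list[str]
    stats: pd.DataFrame
    predictions: pd.DataFrame
    component_counts: pd.Series
    records: pd.DataFrame


def make_grouped_folds(
    metadata: pd.DataFrame, k: int, seed: int | None = None
) -> dict[str, int]:
    """Assign each sample id to one of ``k`` folds.

    If the metadata shows exactly ``k`` distinct concentration profiles
    (the dilution-series layout), each fold is one level — all technical
    replicates of a level validate together. Otherwise sample ids are
    partitioned as evenly as possible at random. Returns a mapping
    sample_id -> fold index; every replicate of an id shares its fold.
    """
    if "sample_id" not in metadata.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    conc_cols = [c for c in metadata.columns if c.startswith("conc_")]
    per_id = metadata.drop_duplicates("sample_id")
    ids = per_id["sample_id"].to_numpy()
    if k > ids.size:
        raise ValueError(f"k={k} exceeds the {ids.size} distinct sample ids")
    if conc_cols:
        profiles = per_id[conc_cols].apply(tuple, axis=1)
        levels = sorted(set(profiles))
        if len(levels) == k:
            level_index = {lev: i for i, lev in enumerate(levels)}
            return {
                sid: level_index[prof] for sid, prof in zip(ids, profiles)
            }
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(ids)
    return {sid: i % k for i, sid in enumerate(shuffled)}


def bootstrap_draw(
    rng: np.random.Generator, unique_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap resample of sample ids.

    Draws ``len(unique_ids)`` ids with replacement; the ids never drawn form
    the out-of-bag set. A draw with an empty out-of-bag set is rejected and
    redrawn (logged), so the returned test set is never empty.
    """
    while True:
        draw = rng.choice(unique_ids, size=unique_ids.size, replace=True)
        drawn = set(draw)
        oob = np.array([sid for sid in unique_ids if sid not in drawn])
        if oob.size:
            return draw, oob
        logger.info("bootstrap draw produced an empty out-of-bag set; redrawn")


def _rank_cap(n_rows: int, n_channels: int, a_max: int) -> int:
    return max(1, min(a_max, MAX_COMPONENTS, n_rows - 1, n_channels))


def _inner_select(
    X: np.ndarray,
    Y: np.ndarray,
    ids: np.ndarray,
    fold_of: dict[str, int],
    n_folds: int,
    a_max: int,
) -> tuple[int, float]:
    """Pick the component count minimizing pooled inner-CV RMSE.

    Rows arrive with bootstrap multiplicity already expanded, so duplicated
    draws weight both the fit and the pooled error. Ties break to the
    smaller count (parsimony). Returns (selected_a, rmsecv_at_selected).
    """
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    n, p = X.shape
    preds: list[np.ndarray] = []  # per fold: (a_achieved, n_test, q)
    trues: list[np.ndarray] = []
    for f in range(n_folds):
        test_mask = np.array([fold_of[s] == f for s in ids])
        if not test_mask.any() or test_mask.all():
            continue
        train_idx = np.flatnonzero(~test_mask)
        a_fit = _rank_cap(train_idx.size, p, a_max)
        model = PLSNipals(n_components=a_fit).fit(X[train_idx], Y2[train_idx])
        preds.append(model.predict_path(X[test_mask]))
        trues.append(Y2[test_mask])
    if not preds:
        raise ValueError("inner CV produced no usable splits")
    a_common = min(pp.shape[0] for pp in preds)
    rmse = np.empty(a_common)
    y_all = np.vstack(trues)
    for a in range(a_common):
        p_all = np.vstack([pp[a] for pp in preds])
        rmse[a] = np.sqrt(np.mean((y_all - p_all) ** 2))
    best = int(np.argmin(rmse))  # argmin takes the first = smallest a on ties
    return best + 1, float(rmse[best])


def double_cv(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: np.ndarray,
    cv: CVConfig | None = None,
    seed: int | None = None,
    response: str = "response",
) -> ValidationSummary:
    """k-fold double (nested) cross-validation of a PLS1 calibration.

    The outer loop leaves out one concentration level at a time; the inner
    (k-1)-fold CV on the remaining levels selects the component count that
    minimizes inner RMSECV (ties to fewer components); the outer model is
    refit at that count and its held-out predictions are pooled. Q² uses
    the grand mean of ``y`` as center.
    """
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sample_ids = np.asarray(sample_ids)
    if y.ndim != 1 or X.shape[0] != y.size or sample_ids.size != y.size:
        raise ValueError("X, y and sample_ids must be row-aligned")
    meta = pd.DataFrame({"sample_id": sample_ids, "conc_y_M": y})
    n_groups = meta["sample_id"].nunique()
    if n_groups < 3:
        raise ValueError("nested CV needs at least 3 sample groups")
    fold_of = make_grouped_folds(meta, cv.k, seed)

    pooled_pred = np.full(y.size, np.nan)
    fold_records = []
    selected = []
    for f in range(cv.k):
        test_mask = np.array([fold_of[s] == f for s in sample_ids])
        train_mask = ~test_mask
        ids_tr = sample_ids[train_mask]
        inner_meta = meta[train_mask]
        inner_folds = make_grouped_folds(inner_meta, cv.k - 1, seed)
        a_sel, inner_rmse = _inner_select(
            X[train_mask], y[train_mask], ids_tr, inner_folds, cv.k - 1, cv.a_max
        )
        model = PLSNipals(n_components=a_sel).fit(X[train_mask], y[train_mask])
        yhat = model.predict(X[test_mask])
        pooled_pred[test_mask] = yhat
        m = regression_metrics(y[test_mask], yhat, float(y[train_mask].mean()))
        fold_records.append(
            {
                "fold": f,
                "n_components": model.n_components_,
                "inner_rmsecv": inner_rmse,
                "q2": m.q2,
                "rmsecv": m.rmse,
            }
        )
        selected.append(model.n_components_)

    assert not np.isnan(pooled_pred).any(), "every sample must be predicted once"
    if cv.pool:
        pooled = regression_metrics(y, pooled_pred, float(y.mean()))
        q2, rmsecv = pooled.q2, pooled.rmse
    else:
        q2 = float(np.mean([r["q2"] for r in fold_records]))
        rmsecv = float(np.mean([r["rmsecv"] for r in fold_records]))

    pred_df = (
        pd.DataFrame(
            {"sample_id": sample_ids, "y_true": y, "y_pred": pooled_pred}
        )
        .groupby("sample_id", sort=False)
        .agg(
            y_true=("y_true", "mean"),
            pred_mean=("y_pred", "mean"),
            pred_sd=("y_pred", "std"),
            n_pred=("y_pred", "size"),
        )
        .reset_index()
    )
    stats = pd.DataFrame(
        {
            "q2_mean": [q2],
            "q2_sd": [np.nan],
            "rmsecv_mean": [rmsecv],
            "rmsecv_sd": [np.nan],
        },
        index=pd.Index([response], name="response"),
    )
    return ValidationSummary(
        scheme="double_cv",
        responses=[response],
        stats=stats,
        predictions=pred_df,
        component_counts=pd.Series(selected).value_counts().sort_index(),
        records=pd.DataFrame(fold_records),
    )


def double_cv_predictions(summary: ValidationSummary) -> pd.DataFrame:
    """Held-out (pooled) predictions table from a double-CV summary."""
    return summary.predictions


def bootstrap_validate(
    X: np.ndarray,
    Y: np.ndarray,
    sample_ids: np.ndarray,
    mode: str = "pls1",
    config: BootstrapConfig | None = None,
    responses: list[str] | None = None,
) -> ValidationSummary:
    """Bootstrap out-of-bag validation with inner component selection.

    Each iteration draws n sample ids with replacement; drawn ids form the
    training multiset (duplicates weighted by copy count), out-of-bag ids
    the test set (iterations with an empty bag are redrawn and logged). An
    inner k-fold CV on the training ids — k = min(distinct training ids,
    ``inner_k_cap``) — selects the component count; the refit model is
    scored on the training set (R², with the inner RMSECV) and on the
    out-of-bag set (Q², RMSEP).

    ``mode="pls1"`` requires a single-response ``Y``; ``mode="pls2"``
    models all columns simultaneously.
    """
    config = config or BootstrapConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    y2 = Y if Y.ndim == 2 else Y[:, None]
    sample_ids = np.asarray(sample_ids)
    if X.shape[0] != y2.shape[0] or sample_ids.size != X.shape[0]:
        raise ValueError("X, Y and sample_ids must be row-aligned")
    if mode not in ("pls1", "pls2"):
        raise ValueError("mode must be 'pls1' or 'pls2'")
    if mode == "pls1" and y2.shape[1] != 1:
        raise ValueError("pls1 mode takes one response at a time")
    if responses is None:
        responses = [f"y{j + 1}" for j in range(y2.shape[1])]
    if len(responses) != y2.shape[1]:
        raise ValueError("one response name per Y column required")

    unique_ids = pd.unique(sample_ids)
    rows_of = {sid: np.flatnonzero(sample_ids == sid) for sid in unique_ids}
    rng = np.random.default_rng(config.seed)

    records = []
    sel_counts: list[int] = []
    oob_pred_acc: dict[object, list[np.ndarray]] = {sid: [] for sid in unique_ids}
    for it in range(config.n_boot):
        draw, oob = bootstrap_draw(rng, unique_ids)
        multiplicity = pd.Series(draw).value_counts().to_dict()
        train_ids = np.array(list(multiplicity))
        train_rows = np.concatenate(
            [np.repeat(rows_of[sid], multiplicity[sid]) for sid in train_ids]
        )
        oob_rows = np.concatenate([rows_of[sid] for sid in oob])

        k_inner = min(config.inner_k_cap, train_ids.size)
        inner_meta = pd.DataFrame({"sample_id": train_ids})
        inner_folds = make_grouped_folds(
            inner_meta, k_inner, seed=rng.integers(0, 2**31 - 1)
        )
        id_per_row = sample_ids[train_rows]
        a_sel, inner_rmse = _inner_select(
            X[train_rows],
            y2[train_rows],
            id_per_row,
            inner_folds,
            k_inner,
            config.a_max,
        )
        model = PLSNipals(n_components=a_sel).fit(X[train_rows], y2[train_rows])
        sel_counts.append(model.n_components_)

        fit_train = model.predict(X[train_rows])
        pred_oob = model.predict(X[oob_rows])
        y_center = y2[train_rows].mean(axis=0)
        rec = {"iteration": it, "n_components": model.n_components_, "n_oob": oob.size}
        for j, name in enumerate(responses):
            m_tr = regression_metrics(y2[train_rows, j], fit_train[:, j], y_center[j])
            m_te = regression_metrics(y2[oob_rows, j], pred_oob[:, j], y_center[j])
            rec[f"r2_{name}"] = m_tr.q2
            rec[f"rmsecv_{name}"] = inner_rmse
            rec[f"q2_{name}"] = m_te.q2
            rec[f"rmsep_{name}"] = m_te.rmse
        records.append(rec)
        for sid in oob:
            rows = rows_of[sid]
            mask = np.isin(oob_rows, rows)
            oob_pred_acc[sid].append(pred_oob[mask].mean(axis=0))

    rec_df = pd.DataFrame(records)
    stats_rows = {}
    for name in responses:
        stats_rows[name] = {
            "r2_mean": rec_df[f"r2_{name}"].mean(),
            "r2_sd": rec_df[f"r2_{name}"].std(),
            "q2_mean": rec_df[f"q2_{name}"].mean(),
            "q2_sd": rec_df[f"q2_{name}"].std(),
            "rmsecv_mean": rec_df[f"rmsecv_{name}"].mean(),
            "rmsecv_sd": rec_df[f"rmsecv_{name}"].std(),
            "rmsep_mean": rec_df[f"rmsep_{name}"].mean(),
            "rmsep_sd": rec_df[f"rmsep_{name}"].std(),
        }
    stats = pd.DataFrame.from_dict(stats_rows, orient="index")
    stats.index.name = "response"

    pred_records = []
    y_true_of = {
        sid: y2[rows_of[sid]].mean(axis=0) for sid in unique_ids
    }
    for sid in unique_ids:
        stack = np.array(oob_pred_acc[sid])
        rec = {"sample_id": sid, "n_pred": len(stack)}
        for j, name in enumerate(responses):
            rec[f"y_true_{name}"] = y_true_of[sid][j]
            rec[f"pred_mean_{name}"] = stack[:, j].mean() if len(stack) else np.nan
            rec[f"pred_sd_{name}"] = stack[:, j].std(ddof=1) if len(stack) > 1 else np.nan
        pred_records.append(rec)

    return ValidationSummary(
        scheme=f"bootstrap_{mode}",
        responses=list(responses),
        stats=stats,
        predictions=pd.DataFrame(pred_records),
        component_counts=pd.Series(sel_counts).value_counts().sort_index(),
        records=rec_df,
    )
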