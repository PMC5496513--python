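"""Predictive accuracy of the abundance SDM.

Leave-one-out (LOOCV) and stratified k-fold cross-validation score the model
by AUC (probability that a randomly chosen presence quadrat receives a
higher predicted cover than a randomly chosen absence quadrat, ties counting
one half) and by prediction error (RMSE of held-out predicted cover against
observed k/m; MAE also reported).  Abundance counts are binarized for AUC as
presence = k > 0 by default.  The learning curve refits the model on
increasingly large random training subsets, scoring each by LOOCV within the
subset, to locate the training-data volume beyond which accuracy stops
improving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from kelpscape._seeds import as_rng, rng_for, stage_seed_int
from kelpscape.errors import FitError, UndefinedAUCError
from kelpscape.sdm import DEFAULT_COVARIATES, fit_binomial_glm, predict_records

DEFAULT_PRESENCE_RULE = "any"
DEFAULT_COVER_THRESHOLD = 0.1


def presence_labels(
    records: pd.DataFrame,
    rule: str = DEFAULT_PRESENCE_RULE,
    threshold: float = DEFAULT_COVER_THRESHOLD,
) -> np.ndarray:
    """Binary presence from point counts: ``any`` -> k > 0 (minimal
    assumption), ``cover`` -> k/m >= threshold."""
    if rule == "any":
        return (records["k"] > 0).to_numpy()
    if rule == "cover":
        return ((records["k"] / records["m"]) >= threshold).to_numpy()
    raise ValueError(f"unknown presence rule {rule!r}")


def auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation with tie correction.

    AUC = (R_1 - n_1(n_1+1)/2) / (n_1 n_0), where R_1 is the rank sum of the
    positive class under midranks; equivalent to counting concordant pairs
    with ties worth one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    r1 = ranks[labels].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CVResult:
    strategy: str
    fold_auc: list[float]
    mean_auc: float
    heldout: pd.DataFrame = field(repr=False)  # index, p_hat, observed, presence
    rmse: float = float("nan")
    mae: float = float("nan")
    k: int | None = None
    n_skipped: int = 0
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "k": self.k,
            "mean_auc": self.mean_auc,
            "rmse": self.rmse,
            "mae": self.mae,
            "n_heldout": len(self.heldout),
            "n_skipped": self.n_skipped,
        }


def _errors(heldout: pd.DataFrame) -> tuple[float, float]:
    resid = heldout["p_hat"].to_numpy() - heldout["observed"].to_numpy()
    return float(np.sqrt(np.mean(resid**2))), float(np.mean(np.abs(resid)))


def loocv(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    max_n: int | None = None,
    seed: int | None = None,
    presence_rule: str = DEFAULT_PRESENCE_RULE,
    **fit_kwargs,
) -> CVResult:
    """Leave-one-out cross-validation of the binomial GLM.

    With ``max_n`` set, a seeded random subset of records is held out one at
    a time (every fit still uses all remaining n-1 records) — the standard
    cost cap for LOOCV at survey scale.  Non-convergent folds are skipped
    with a warning and counted.
    """
    records = records.reset_index(drop=True)
    n = len(records)
    idx = np.arange(n)
    if max_n is not None and max_n < n:
        idx = np.sort(as_rng(seed).choice(n, size=max_n, replace=False))
    rows = []
    skipped = 0
    labels = presence_labels(records, presence_rule)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-subset fit warnings
        for i in idx:
            train = records.drop(index=i)
            try:
                model = fit_binomial_glm(train, covariates, **fit_kwargs)
            except FitError:
                skipped += 1
                continue
            p, _ = predict_records(model, records.iloc[[i]])
            rows.append(
                {
                    "index": int(i),
                    "p_hat": float(p[0]),
                    "observed": float(records.at[i, "k"] / records.at[i, "m"]),
                    "presence": bool(labels[i]),
                }
            )
    if skipped:
        warnings.warn(f"LOOCV: {skipped} fold(s) skipped (non-convergent)", stacklevel=2)
    heldout = pd.DataFrame(rows)
    if heldout.empty:
        raise FitError("LOOCV: every fold failed to fit")
    try:
        a = auc(heldout["p_hat"], heldout["presence"])
    except UndefinedAUCError:
        a = float("nan")
    rmse, mae = _errors(heldout)
    return CVResult(
        strategy="loocv",
        fold_auc=[a],
        mean_auc=a,
        heldout=heldout,
        rmse=rmse,
        mae=mae,
        n_skipped=skipped,
        seed=seed,
    )


def kfold_cv(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    k: int = 10,
    seed: int | None = None,
    presence_rule: str = DEFAULT_PRESENCE_RULE,
    **fit_kwargs,
) -> CVResult:
    """Stratified k-fold cross-validation: per-fold AUC, mean AUC and pooled
    prediction error.  Folds are stratified on presence/absence; a fold
    lacking both classes triggers one refold, then an error."""
    records = records.reset_index(drop=True)
    n = len(records)
    if n < 2 * k:
        raise FitError(f"need >= {2 * k} records for {k}-fold CV, got {n}")
    labels = presence_labels(records, presence_rule)

    def _folds(rs: int):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        return list(skf.split(np.zeros(n), labels.astype(int)))

    base = stage_seed_int(seed if seed is not None else 0, "kfold")
    splits = _folds(base)
    if any(len(np.unique(labels[test])) < 2 for _, test in splits):
        splits = _folds(base + 1)
        if any(len(np.unique(labels[test])) < 2 for _, test in splits):
            raise UndefinedAUCError(
                "a fold lacks both presence and absence even after refolding"
            )
    fold_auc = []
    rows = []
    skipped = 0
    for fold, (train_idx, test_idx) in enumerate(splits):
        try:
            model = fit_binomial_glm(records.iloc[train_idx], covariates, **fit_kwargs)
        except FitError:
            skipped += 1
            continue
        p, _ = predict_records(model, records.iloc[test_idx])
        fold_auc.append(auc(p, labels[test_idx]))
        for j, i in enumerate(test_idx):
            rows.append(
                {
                    "index": int(i),
                    "fold": fold,
                    "p_hat": float(p[j]),
                    "observed": float(records.at[i, "k"] / records.at[i, "m"]),
                    "presence": bool(labels[i]),
                }
            )
    heldout = pd.DataFrame(rows)
    rmse, mae = _errors(heldout)
    return CVResult(
        strategy="kfold",
        k=k,
        fold_auc=fold_auc,
        mean_auc=float(np.mean(fold_auc)),
        heldout=heldout,
        rmse=rmse,
        mae=mae,
        n_skipped=skipped,
        seed=seed,
    )


def resubstitution_error(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    **fit_kwargs,
) -> float:
    """Training (resubstitution) RMSE of predicted vs observed cover."""
    model = fit_binomial_glm(records, covariates, **fit_kwargs)
    p, _ = predict_records(model, records)
    obs = (records["k"] / records["m"]).to_numpy(float)
    return float(np.sqrt(np.mean((p - obs) ** 2)))


@dataclass
class LearningCurveResult:
    table: pd.DataFrame  # n_train, repeat, error, auc, converged
    full_error: float
    asymptote_n: int | None
    eps: float

    def mean_error(self) -> pd.Series:
        ok = self.table[self.table["converged"]]
        return ok.groupby("n_train")["error"].mean()


def learning_curve(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_grid=range(10, 451, 20),
    repeats: int = 5,
    seed: int = 0,
    loocv_cap: int | None = None,
    full_cap: int = 1000,
    eps: float = 0.005,
    full_error: float | None = None,
    evaluator: str = "within",
    **fit_kwargs,
) -> LearningCurveResult:
    """Training-data-volume learning curve.

    Per (n, repeat): fit on n randomly chosen quadrats and score prediction
    error by LOOCV *within* that training subset (optionally capped at
    ``loocv_cap`` held-out records for cost; ``evaluator='holdout'`` instead
    scores against all remaining records).  The full-data reference error is
    LOOCV on the complete table, capped at ``full_cap`` held-out records.
    The asymptote estimate is the smallest grid n whose mean error — and
    that of every larger grid n — is within ``eps`` of the full-data error.
    """
    records = records.reset_index(drop=True)
    n_grid = sorted(set(int(n) for n in n_grid))
    if not n_grid:
        raise ValueError("empty n_grid")
    if n_grid[-1] > len(records):
        raise ValueError(f"max(n_grid)={n_grid[-1]} exceeds {len(records)} records")
    if n_grid[0] < 10:
        warnings.warn("training sizes below 10 give unstable fits", stacklevel=2)
    if full_error is None:
        full_error = loocv(
            records, covariates, max_n=full_cap, seed=stage_seed_int(seed, "full-loocv"),
            **fit_kwargs,
        ).rmse
    rows = []
    for n in n_grid:
        for rep in range(repeats):
            rng = rng_for(seed, "learning", n, rep)
            sub = records.iloc[np.sort(rng.choice(len(records), size=n, replace=False))]
            sub = sub.reset_index(drop=True)
            try:
                if evaluator == "within":
                    res = loocv(
                        sub, covariates, max_n=loocv_cap,
                        seed=stage_seed_int(seed, "lc-loocv", n, rep), **fit_kwargs,
                    )
                    err, a = res.rmse, res.mean_auc
                elif evaluator == "holdout":
                    rest = records.drop(index=records.index[np.isin(records.index, sub.index)])
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model = fit_binomial_glm(sub, covariates, **fit_kwargs)
                    p, _ = predict_records(model, rest)
                    obs = (rest["k"] / rest["m"]).to_numpy(float)
                    err = float(np.sqrt(np.mean((p - obs) ** 2)))
                    a = float("nan")
                else:
                    raise ValueError(f"unknown evaluator {evaluator!r}")
                converged = True
            except FitError:
                err, a, converged = float("nan"), float("nan"), False
            rows.append(
                {"n_train": n, "repeat": rep, "error": err, "auc": a, "converged": converged}
            )
    table = pd.DataFrame(rows)
    mean_err = table[table["converged"]].groupby("n_train")["error"].mean()
    asymptote = None
    close = (mean_err - full_error) <= eps
    # stable asymptote: all larger grid sizes must also stay within eps
    suffix = np.logical_and.accumulate(close.to_numpy()[::-1])[::-1]
    hits = mean_err.index.to_numpy()[suffix]
    if len(hits):
        asymptote = int(hits[0])
    return LearningCurveResult(table=table, full_error=float(full_error), asymptote_n=asymptote, eps=eps)
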