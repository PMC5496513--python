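"""Fine-scale abundance species-distribution model for kelp cover.

The model is a binomial GLM of the point counts: cover, as k successes of m
classification points, regressed on latitude, longitude, bathymetry and a
rocky-reef indicator with a logit link,

    (k, m - k) ~ LAT + LONG + BATH + REEF.

Covariates are standardized internally for numerical conditioning and the
coefficients (and their covariance) reported back on the original scale.
Prediction onto an aligned 5 m raster grid yields a cover surface and a
delta-method standard-error surface, se_p = p(1-p) * se_eta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from kelpscape.errors import FitError
from kelpscape.raster import EnvironmentRasters, Raster

DEFAULT_COVARIATES = ("lat", "long", "bath", "reef")

#: quadrat-table column behind each covariate, in planar-meters mode and in
#: raw-degrees mode
_COLUMN_FOR = {
    "meters": {"lat": "y", "long": "x", "bath": "depth_m", "reef": "reef"},
    "degrees": {"lat": "lat", "long": "lon", "bath": "depth_m", "reef": "reef"},
}


@dataclass
class SDMModel:
    """Fitted binomial GLM: coefficients, covariance and fit diagnostics."""

    covariates: tuple[str, ...]
    coef: np.ndarray  # original-scale: intercept first
    cov: np.ndarray  # original-scale coefficient covariance
    deviance: float
    null_deviance: float
    df_resid: int
    n_obs: int
    converged: bool
    dispersion: float  # Pearson chi^2 / df, quasi-binomial diagnostic only
    coords_mode: str = "meters"
    standardization: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return ["intercept", *self.covariates]

    def coef_series(self) -> pd.Series:
        return pd.Series(self.coef, index=self.names)

    def wald_intervals(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame(
            {"coef": self.coef, "se": se, "lo": self.coef - z * se, "hi": self.coef + z * se},
            index=self.names,
        )

    def to_json(self, path) -> None:
        payload = {
            "covariates": list(self.covariates),
            "coef": self.coef.tolist(),
            "cov": self.cov.tolist(),
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "dispersion": self.dispersion,
            "coords_mode": self.coords_mode,
            "standardization": self.standardization,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "SDMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            covariates=tuple(d["covariates"]),
            coef=np.array(d["coef"]),
            cov=np.array(d["cov"]),
            deviance=d["deviance"],
            null_deviance=d["null_deviance"],
            df_resid=d["df_resid"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            dispersion=d["dispersion"],
            coords_mode=d.get("coords_mode", "meters"),
            standardization=d.get("standardization", {}),
        )


def design_matrix(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    coords_mode: str = "meters",
) -> np.ndarray:
    """Covariate matrix (no intercept column) in model order."""
    colmap = _COLUMN_FOR[coords_mode]
    cols = []
    for cov in covariates:
        col = colmap.get(cov, cov)
        if col not in records.columns:
            raise FitError(f"missing covariate column {col!r} for {cov!r}")
        v = records[col]
        cols.append(v.astype(float).to_numpy())
    if not cols:
        return np.empty((len(records), 0))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise FitError("non-finite covariate values")
    return X


def fit_binomial_glm(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    coords_mode: str = "meters",
    standardize: bool = True,
    maxiter: int = 50,
    tol: float = 1e-8,
    min_records: int = 25,
) -> SDMModel:
    """Maximum-likelihood binomial GLM (logit link, IRLS) of k of m counts.

    Raises :class:`FitError` on rank deficiency (naming the collinear or
    constant columns), non-convergence, or apparent separation.  Fits with
    fewer than ``min_records`` rows are allowed but warned about as unstable.
    """
    import warnings

    n = len(records)
    p = len(covariates)
    if n < p + 2:
        raise FitError(f"need at least {p + 2} records to fit {p} covariates, got {n}")
    if n < min_records:
        warnings.warn(f"fitting on only {n} records; estimates may be unstable", stacklevel=2)
    k = records["k"].to_numpy(float)
    m = records["m"].to_numpy(float)
    X = design_matrix(records, covariates, coords_mode)

    means = X.mean(axis=0) if p else np.empty(0)
    scales = X.std(axis=0) if p else np.empty(0)
    constant = [covariates[j] for j in range(p) if scales[j] == 0]
    if constant:
        raise FitError(f"constant (rank-deficient) covariate(s): {', '.join(constant)}")
    Xs = (X - means) / scales if standardize else X
    exog = np.column_stack([np.ones(n), Xs])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise FitError(f"rank-deficient design among covariates {covariates}")

    model = sm.GLM(np.column_stack([k, m - k]), exog, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=maxiter, tol=tol)
    except Exception as err:  # statsmodels raises PerfectSeparationError etc.
        raise FitError(f"GLM fit failed: {err}") from err
    if not getattr(res, "converged", True):
        raise FitError(f"IRLS did not converge in {maxiter} iterations")
    b = np.asarray(res.params)
    V = np.asarray(res.cov_params())
    if np.abs(b).max() > 50:
        raise FitError(
            "apparent separation: standardized coefficients exploded "
            f"(max |b| = {np.abs(b).max():.1f})"
        )

    if standardize and p:
        # eta = b0 + sum_j b_j (x_j - mu_j)/s_j  =>  beta_j = b_j / s_j,
        # beta_0 = b0 - sum_j b_j mu_j / s_j; covariance transforms linearly.
        A = np.eye(p + 1)
        A[0, 1:] = -means / scales
        A[np.arange(1, p + 1), np.arange(1, p + 1)] = 1.0 / scales
        coef = A @ b
        cov = A @ V @ A.T
    else:
        coef, cov = b, V

    null_dev = float(
        sm.GLM(np.column_stack([k, m - k]), np.ones((n, 1)), family=sm.families.Binomial())
        .fit()
        .deviance
    )
    return SDMModel(
        covariates=tuple(covariates),
        coef=coef,
        cov=cov,
        deviance=float(res.deviance),
        null_deviance=null_dev,
        df_resid=int(res.df_resid),
        n_obs=n,
        converged=bool(getattr(res, "converged", True)),
        dispersion=float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan"),
        coords_mode=coords_mode,
        standardization={"means": means.tolist(), "scales": scales.tolist()}
        if standardize
        else {},
    )


def linear_predictor(model: SDMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """eta = x'beta and se_eta = sqrt(x' Sigma x) per row of X (no intercept
    column; it is added here)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.covariates):
        raise FitError(
            f"expected {len(model.covariates)} covariate columns, got {X.shape[1]}"
        )
    Xd = np.column_stack([np.ones(len(X)), X])
    eta = Xd @ model.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xd, model.cov, Xd))
    return eta, se


def predict_records(model: SDMModel, records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(p_hat, se_p) for quadrat records, delta method on the response scale."""
    X = design_matrix(records, model.covariates, model.coords_mode)
    eta, se_eta = linear_predictor(model, X)
    p = expit(eta)
    return p, p * (1 - p) * se_eta


@dataclass
class PredictionSurface:
    """Predicted cover and its standard error on the raster grid; cells
    outside the reef mask carry no-data."""

    p_hat: Raster
    se: Raster
    masked_fraction: float

    def write(self, directory, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.p_hat.write_ascii(directory / f"{prefix}prediction.asc")
        self.se.write_ascii(directory / f"{prefix}prediction_se.asc")


def predict_surface(
    model: SDMModel,
    env: EnvironmentRasters,
    mask_outside_reef: bool = True,
) -> PredictionSurface:
    """Project the fitted model onto the environment grid.

    Requires a meters-mode model (cell centers are planar).  REEF is 1 inside
    the mask; off-reef cells are either masked (default) or predicted with
    REEF = 0.
    """
    if not model.converged:
        raise FitError("refusing to predict from a non-converged model")
    if model.coords_mode != "meters":
        raise FitError("raster prediction requires a meters-mode model")
    bath = env.bathymetry
    Xg, Yg = bath.cell_centers()
    reef = env.reef_bool()
    cols = {
        "lat": Yg.ravel(),
        "long": Xg.ravel(),
        "bath": bath.data.ravel(),
        "reef": reef.ravel().astype(float),
    }
    try:
        X = np.column_stack([cols[c] for c in model.covariates])
    except KeyError as err:
        raise FitError(f"covariate {err} not available on the raster grid") from err
    eta, se_eta = linear_predictor(model, X)
    p = expit(eta).reshape(bath.data.shape)
    se = (expit(eta) * (1 - expit(eta)) * se_eta).reshape(bath.data.shape)
    if mask_outside_reef:
        p = np.where(reef, p, bath.nodata)
        se = np.where(reef, se, bath.nodata)
        masked_fraction = float(1 - reef.mean())
    else:
        masked_fraction = 0.0
    return PredictionSurface(
        p_hat=bath.copy_with(p),
        se=bath.copy_with(se),
        masked_fraction=masked_fraction,
    )
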