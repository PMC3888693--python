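"""Feature–thickness statistics: rank correlations and the quadratic model.

Two analyses quantify how first-order fundus texture relates to OCT-derived
RNFL thickness:

1. **Spearman rank correlation**, computed per eye (each eye's set of ROIs
   is one sample) and pooled over all ROIs of all eyes, between every
   feature/channel combination and the matching tROI thickness.

2. **A second-order multivariate regression** predicting thickness from the
   GB-channel mean and standard deviation,

       y = β1 + β2·µ_GB + β3·σ_GB + β4·µ_GB·σ_GB + β5·µ_GB² + β6·σ_GB²,

   fitted by least squares on normalized predictors so the β magnitudes are
   comparable.  The model is linear in β, so the exact linear solve and an
   iterative nonlinear-least-squares routine reach the same optimum; both
   are available.  Reported diagnostics: MAE (mean absolute error, µm), MCI
   (mean half-width of the confidence interval of the predicted mean
   response) and R².

Per-feature p-values are reported raw — no multiple-testing correction is
applied, so treat borderline p-values accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_X_y

__all__ = [
    "RnflRegressor",
    "spearman_by_image",
    "spearman_pooled",
    "fit_eq4",
    "predict_eq4",
    "within_eye_error",
    "TABLE_COLUMNS",
]

#: tidy PairedDataset columns: eye, roi, 5 features × 4 channels, thickness
TABLE_COLUMNS = (
    ["eye_id", "roi_id"]
    + [
        f"{feat}_{ch}"
        for ch in ("R", "G", "B", "GB")
        for feat in ("mu", "sigma", "entropy", "skewness", "kurtosis")
    ]
    + ["thickness_um"]
)


# --------------------------------------------------------------------------
# Spearman correlation analyses
# --------------------------------------------------------------------------

def spearman_by_image(
    data: pd.DataFrame, feature: str, min_rows: int = 5
) -> tuple[pd.DataFrame, dict, list]:
    """Per-eye Spearman correlation of ``feature`` against thickness.

    Eyes with fewer than ``min_rows`` ROIs, or with a constant feature or
    constant thickness (undefined rank correlation), are skipped and listed.
    Returns ``(per_eye table, summary, skipped)`` where the summary holds the
    across-eye mean/sd/min/max of R_S and the mean p-value.
    """
    per_eye = []
    skipped = []
    for eye, grp in data.groupby("eye_id", sort=True):
        if len(grp) < min_rows:
            skipped.append((eye, f"only {len(grp)} rows (< {min_rows})"))
            continue
        x = grp[feature].to_numpy(float)
        y = grp["thickness_um"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            skipped.append((eye, "constant feature or thickness"))
            continue
        r, p = stats.spearmanr(x, y)
        per_eye.append({"eye_id": eye, "n": len(grp), "r_s": r, "p": p})
    table = pd.DataFrame(per_eye, columns=["eye_id", "n", "r_s", "p"])
    if len(table):
        summary = {
            "mean": float(table.r_s.mean()),
            "sd": float(table.r_s.std(ddof=1)) if len(table) > 1 else 0.0,
            "min": float(table.r_s.min()),
            "max": float(table.r_s.max()),
            "mean_p": float(table.p.mean()),
        }
    else:
        summary = {k: float("nan") for k in ("mean", "sd", "min", "max", "mean_p")}
    return table, summary, skipped


def spearman_pooled(
    data: pd.DataFrame, feature: str, min_rows: int = 10
) -> tuple[float, float]:
    """Spearman correlation over all ROIs of all eyes at once (midrank ties)."""
    if len(data) < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {len(data)}")
    x = data[feature].to_numpy(float)
    y = data["thickness_um"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant column")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


# --------------------------------------------------------------------------
# second-order regression model
# --------------------------------------------------------------------------

def _eq4_design(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Design matrix [1, µ, σ, µσ, µ², σ²] matching the β1..β6 layout."""
    one = np.ones_like(mu)
    return np.column_stack([one, mu, sigma, mu * sigma, mu**2, sigma**2])


def predict_eq4(beta, mu_gb, sigma_gb):
    """Evaluate the six-term polynomial at (already normalized) predictors.

    Pure function of its arguments: y = β1 + β2µ + β3σ + β4µσ + β5µ² + β6σ².
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (6,):
        raise ValueError("beta must hold exactly six coefficients")
    mu = np.asarray(mu_gb, dtype=float)
    sigma = np.asarray(sigma_gb, dtype=float)
    out = (
        beta[0]
        + beta[1] * mu
        + beta[2] * sigma
        + beta[3] * mu * sigma
        + beta[4] * mu**2
        + beta[5] * sigma**2
    )
    return out if out.ndim else float(out)


class RnflRegressor(RegressorMixin, BaseEstimator):
    """Second-order polynomial regression of RNFL thickness on (µ_GB, σ_GB).

    Parameters
    ----------
    normalization : {"zscore", "minmax", "none"}
        Predictor normalization applied before fitting; the fitted constants
        are stored so prediction uses the same mapping.  z-scoring makes the
        β magnitudes comparable across terms.
    ci_level : float
        Confidence level for the MCI diagnostic.
    ci_type : {"mean", "prediction"}
        Whether MCI averages half-widths of the mean-response or the
        prediction interval.
    method : {"linear", "iterative"}
        "linear" solves the least-squares problem exactly (the model is
        linear in β); "iterative" runs Levenberg–Marquardt on the same
        residuals and converges to the identical optimum.

    Attributes
    ----------
    beta_ : ndarray (6,)
        β1..β6 for the design [1, µ, σ, µσ, µ², σ²] on normalized predictors.
    beta_se_ : ndarray (6,)
        OLS standard errors of the coefficients.
    norm_center_, norm_scale_ : ndarray (2,)
        Normalization constants for (µ_GB, σ_GB).
    mae_, mci_, r2_ : float
        In-sample diagnostics (µm, µm, dimensionless).
    """

    def __init__(
        self,
        normalization: str = "zscore",
        ci_level: float = 0.95,
        ci_type: str = "mean",
        method: str = "linear",
    ):
        self.normalization = normalization
        self.ci_level = ci_level
        self.ci_type = ci_type
        self.method = method

    # -- normalization ------------------------------------------------------
    def _fit_norm(self, X: np.ndarray) -> None:
        if self.normalization == "zscore":
            self.norm_center_ = X.mean(axis=0)
            scale = X.std(axis=0, ddof=0)
        elif self.normalization == "minmax":
            self.norm_center_ = X.min(axis=0)
            scale = X.max(axis=0) - X.min(axis=0)
        elif self.normalization == "none":
            self.norm_center_ = np.zeros(X.shape[1])
            scale = np.ones(X.shape[1])
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if np.any(scale == 0):
            raise ValueError("a predictor is constant; design would be singular")
        self.norm_scale_ = scale

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.norm_center_) / self.norm_scale_

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (mu_GB, sigma_GB)")
        if len(y) < 12:
            raise ValueError("need at least 12 samples to fit six coefficients")
        if not np.all(np.isfinite(X)):
            raise ValueError("predictors must be finite")
        self._fit_norm(X)
        Z = self._normalize(X)
        D = _eq4_design(Z[:, 0], Z[:, 1])
        if np.linalg.matrix_rank(D) < 6:
            raise ValueError("rank-deficient design (degenerate predictors)")

        ols = sm.OLS(y, D).fit()
        if self.method == "iterative":
            from scipy.optimize import least_squares

            sol = least_squares(
                lambda b: D @ b - y, x0=np.zeros(6), method="lm", xtol=1e-14, ftol=1e-14
            )
            self.beta_ = sol.x
        elif self.method == "linear":
            self.beta_ = ols.params
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.beta_se_ = ols.bse
        self._ols_results_ = ols

        yhat = D @ self.beta_
        self.mae_ = float(np.mean(np.abs(yhat - y)))
        self.r2_ = float(ols.rsquared)
        alpha = 1.0 - self.ci_level
        pred = ols.get_prediction(D)
        frame = pred.summary_frame(alpha=alpha)
        if self.ci_type == "mean":
            half = (frame["mean_ci_upper"] - frame["mean_ci_lower"]) / 2.0
        elif self.ci_type == "prediction":
            half = (frame["obs_ci_upper"] - frame["obs_ci_lower"]) / 2.0
        else:
            raise ValueError(f"unknown ci_type {self.ci_type!r}")
        self.mci_ = float(half.mean())
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        if not hasattr(self, "beta_"):
            raise AttributeError("model is not fitted; call fit or from_coefficients")
        X = check_array(np.asarray(X, dtype=float))
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (mu_GB, sigma_GB)")
        Z = self._normalize(X)
        return predict_eq4(self.beta_, Z[:, 0], Z[:, 1])

    @classmethod
    def from_coefficients(cls, beta, norm_center=(0.0, 0.0), norm_scale=(1.0, 1.0)):
        """Wire a model from externally supplied β (e.g. published values).

        Without the original normalization constants, predictions are only
        interpretable at the normalized origin and for wiring checks.
        """
        m = cls()
        m.beta_ = np.asarray(beta, dtype=float)
        if m.beta_.shape != (6,):
            raise ValueError("beta must hold exactly six coefficients")
        m.norm_center_ = np.asarray(norm_center, dtype=float)
        m.norm_scale_ = np.asarray(norm_scale, dtype=float)
        m.n_features_in_ = 2
        return m

    def to_dict(self) -> dict:
        d = {
            "beta": self.beta_.tolist(),
            "normalization": self.normalization,
            "norm_center": self.norm_center_.tolist(),
            "norm_scale": self.norm_scale_.tolist(),
        }
        for attr in ("mae_", "mci_", "r2_"):
            if hasattr(self, attr):
                d[attr.rstrip("_")] = getattr(self, attr)
        return d


def fit_eq4(data: pd.DataFrame, **kwargs) -> RnflRegressor:
    """Fit the quadratic thickness model on a PairedDataset table."""
    X = data[["mu_GB", "sigma_GB"]].to_numpy(float)
    y = data["thickness_um"].to_numpy(float)
    return RnflRegressor(**kwargs).fit(X, y)


def within_eye_error(
    data: pd.DataFrame, model: RnflRegressor
) -> tuple[pd.DataFrame, float, float]:
    """Median relative prediction error per eye, and its across-eye mean/sd.

    For each ROI the relative error |ŷ − y| / y is computed (rows with y = 0
    are excluded — relative error is undefined there); each eye contributes
    the median over its ROIs.  Returns ``(per_eye table, mean, sd)``.
    """
    rows = []
    for eye, grp in data.groupby("eye_id", sort=True):
        if len(grp) < 2:
            raise ValueError(f"eye {eye!r} has fewer than 2 ROIs")
        y = grp["thickness_um"].to_numpy(float)
        keep = y != 0
        if not keep.all():
            import warnings

            warnings.warn(f"eye {eye!r}: excluded {int((~keep).sum())} rows with zero thickness")
        X = grp[["mu_GB", "sigma_GB"]].to_numpy(float)[keep]
        y = y[keep]
        rel = np.abs(model.predict(X) - y) / y
        rows.append({"eye_id": eye, "n": int(keep.sum()), "median_rel_error": float(np.median(rel))})
    table = pd.DataFrame(rows)
    med = table["median_rel_error"]
    sd = float(med.std(ddof=1)) if len(table) > 1 else 0.0
    return table, float(med.mean()), sd
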