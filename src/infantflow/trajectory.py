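"""Developmental trajectory models of CBF against age.

Five candidate families (linear, logarithmic, exponential, Poisson and
quadratic polynomial) are fitted to CBF-versus-age data and ranked by
AIC through Akaike weights, interpretable as the probability that a
family is the best of the candidate set.  The logarithmic family -
``y ~ beta * ln(age) + covariates`` - is then applied voxel-wise to
produce age-effect Z maps, Bonferroni thresholds, fitted map stacks
across 1-28 months, and growth-rate maps (the first derivative of the
fitted logarithmic curves, ``beta / age``).

All logarithms of age are natural logarithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelFit",
    "TrajectoryModelSet",
    "TrajectoryModelSetResults",
    "EffectMap",
    "FittedMapStack",
    "FAMILIES",
    "fit_candidate_models",
    "akaike_weights",
    "fit_log_model",
    "voxelwise_age_effects",
    "bonferroni_threshold",
    "predict_map_stack",
    "rate_maps",
]

FAMILIES = ("linear", "logarithmic", "exponential", "poisson", "quadratic")

#: covariate settings used when constructing fitted maps: the cohort
#: mean head motion, and the sex effect averaged over both sexes
PREDICTION_MOTION_MM = 0.22


@dataclass
class ModelFit:
    """One fitted candidate family."""

    family: str
    params: pd.Series
    llf: float
    k: int                      # estimated parameters incl. residual variance
    nobs: int
    fitted: np.ndarray
    r: float                    # Pearson r between fitted and observed
    p_age: float | None = None  # two-tailed p of the age term
    z: float | None = None      # signed probit transform of p_age
    beta_age: float | None = None
    se_age: float | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k * np.log(self.nobs)


def _gaussian_llf(resid: np.ndarray) -> float:
    n = resid.size
    rss = float(resid @ resid)
    sigma2 = rss / n
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def signed_z_from_p(p: float, beta: float) -> float:
    """Two-tailed p mapped through the standard normal quantile, signed."""
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return float(np.sign(beta) * stats.norm.isf(p / 2.0))


def _design(age, covariates, age_cols):
    n = len(age)
    cols = [np.ones(n)] + age_cols
    names = ["intercept"] + [f"age_term_{i}" for i in range(len(age_cols))]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    return X, names


def _ols_fit(age, y, covariates, family, age_transform, age_names):
    X, names = _design(age, covariates, age_transform)
    names = ["intercept"] + age_names + names[1 + len(age_names):]
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("collinear design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    llf = _gaussian_llf(resid)
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov_beta))
    # the age term of interest is the first non-intercept column
    b_age, se_age = beta[1], se[1]
    if se_age > 0 and dof > 0:
        t = b_age / se_age
        p_age = 2.0 * stats.t.sf(abs(t), dof)
    else:
        p_age = 1.0
    r = _fit_r(y, fitted)
    return ModelFit(family=family, params=pd.Series(beta, index=names),
                    llf=llf, k=p + 1, nobs=n, fitted=fitted, r=r,
                    p_age=p_age, z=signed_z_from_p(p_age, b_age),
                    beta_age=float(b_age), se_age=float(se_age))


def _fit_r(y, fitted) -> float:
    if np.std(fitted) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(y, fitted)[0, 1])


def _fit_linear(age, y, covariates):
    return _ols_fit(age, y, covariates, "linear", [np.asarray(age)], ["age"])


def _fit_logarithmic(age, y, covariates):
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("logarithmic family requires positive ages")
    return _ols_fit(age, y, covariates, "logarithmic", [np.log(age)], ["log_age"])


def _fit_quadratic(age, y, covariates):
    age = np.asarray(age, dtype=float)
    return _ols_fit(age, y, covariates, "quadratic", [age, age**2],
                    ["age", "age_sq"])


def _fit_exponential(age, y, covariates):
    """y = a * exp(b * age) + linear covariate terms, by nonlinear LS."""
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    n = age.size
    if covariates is not None:
        C = pd.DataFrame(covariates).to_numpy(dtype=float)
        cov_names = [str(c) for c in pd.DataFrame(covariates).columns]
    else:
        C = np.empty((n, 0))
        cov_names = []
    # log-linear initialisation on the positive part of y
    ypos = np.maximum(y, 1e-3)
    b0 = np.polyfit(age, np.log(ypos), 1)
    theta0 = np.concatenate([[np.exp(b0[1]), b0[0]], np.zeros(C.shape[1])])

    def model(theta):
        a, b = theta[0], theta[1]
        return a * np.exp(np.clip(b * age, -50, 50)) + C @ theta[2:]

    res = optimize.least_squares(lambda th: model(th) - y, theta0,
                                 method="lm", max_nfev=20000)
    fitted = model(res.x)
    resid = y - fitted
    llf = _gaussian_llf(resid)
    p = res.x.size
    names = ["a", "b_age"] + cov_names
    # delta-method SE of b from the Jacobian at the solution
    J = res.jac
    dof = n - p
    try:
        cov = np.linalg.inv(J.T @ J) * (resid @ resid) / max(dof, 1)
        se_b = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se_b = np.nan
    if np.isfinite(se_b) and se_b > 0 and dof > 0:
        p_age = 2.0 * stats.t.sf(abs(res.x[1] / se_b), dof)
    else:
        p_age = 1.0
    return ModelFit(family="exponential", params=pd.Series(res.x, index=names),
                    llf=llf, k=p + 1, nobs=n, fitted=fitted,
                    r=_fit_r(y, fitted), p_age=p_age,
                    z=signed_z_from_p(p_age, res.x[1]),
                    beta_age=float(res.x[1]), se_age=se_b)


def _fit_poisson(age, y, covariates):
    """Poisson GLM with log link on age.

    CBF is continuous, so the Poisson log-likelihood is evaluated at the
    continuous response (gamma-function factorial), the standard way R's
    ``glm`` scores such fits; the family is retained purely for the AIC
    comparison of candidate shapes.
    """
    import statsmodels.api as sm

    X, names = _design(age, covariates, [np.asarray(age, dtype=float)])
    names[1] = "age"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(np.asarray(y, dtype=float), X,
                       family=sm.families.Poisson())
        res = model.fit()
    fitted = np.asarray(res.fittedvalues)
    b_age = float(res.params[1])
    se_age = float(res.bse[1])
    p_age = float(res.pvalues[1])
    return ModelFit(family="poisson", params=pd.Series(res.params, index=names),
                    llf=float(res.llf), k=X.shape[1], nobs=len(age),
                    fitted=fitted, r=_fit_r(np.asarray(y, float), fitted),
                    p_age=p_age, z=signed_z_from_p(p_age, b_age),
                    beta_age=b_age, se_age=se_age)


_FITTERS = {
    "linear": _fit_linear,
    "logarithmic": _fit_logarithmic,
    "exponential": _fit_exponential,
    "poisson": _fit_poisson,
    "quadratic": _fit_quadratic,
}


def akaike_weights(aic_values) -> np.ndarray:
    """Akaike weights from a set of AIC values.

    delta_i = AIC_i - min(AIC); weight_i = exp(-delta_i/2) normalised to
    sum to 1.  Invariant to adding a constant to every AIC.
    """
    aic = np.asarray(aic_values, dtype=float)
    if aic.size == 0:
        raise ValueError("empty AIC set")
    delta = aic - aic.min()
    lik = np.exp(-delta / 2.0)
    return lik / lik.sum()


class TrajectoryModelSet:
    """Candidate developmental models of a CBF series against age.

    Parameters
    ----------
    age : array-like
        Ages in months (positive).
    y : array-like
        CBF in ml/100g/min.
    covariates : DataFrame or dict, optional
        Linear adjustment terms (sex, head motion, cohort, ...).
    families : sequence of str
        Candidate families to fit (default: all five).
    """

    def __init__(self, age, y, covariates=None, families=FAMILIES):
        self.age = np.asarray(age, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.covariates = covariates
        self.families = tuple(families)
        if self.age.size != self.y.size:
            raise ValueError("age and y lengths differ")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")

    def fit(self) -> "TrajectoryModelSetResults":
        fits = {fam: _FITTERS[fam](self.age, self.y, self.covariates)
                for fam in self.families}
        return TrajectoryModelSetResults(self, fits)


@dataclass
class TrajectoryModelSetResults:
    """AIC comparison of the fitted candidate families."""

    model: TrajectoryModelSet
    fits: dict

    @property
    def aic(self) -> pd.Series:
        return pd.Series({f: m.aic for f, m in self.fits.items()})

    @property
    def bic(self) -> pd.Series:
        return pd.Series({f: m.bic for f, m in self.fits.items()})

    @property
    def delta_aic(self) -> pd.Series:
        aic = self.aic
        return aic - aic.min()

    @property
    def weights(self) -> pd.Series:
        """Akaike weight per family."""
        aic = self.aic
        return pd.Series(akaike_weights(aic.to_numpy()), index=aic.index)

    @property
    def best_family(self) -> str:
        return self.aic.idxmin()

    def summary(self) -> pd.DataFrame:
        rows = []
        for fam, fit in self.fits.items():
            rows.append({
                "family": fam, "loglik": fit.llf, "k": fit.k,
                "AIC": fit.aic, "BIC": fit.bic, "r": fit.r,
            })
        out = pd.DataFrame(rows).set_index("family")
        out["dAIC"] = out["AIC"] - out["AIC"].min()
        out["wAIC"] = akaike_weights(out["AIC"].to_numpy())
        return out.sort_values("AIC")


def fit_candidate_models(age, y, covariates=None,
                         families=FAMILIES) -> TrajectoryModelSetResults:
    """Fit all candidate families and rank them by Akaike weight."""
    return TrajectoryModelSet(age, y, covariates, families).fit()


def fit_log_model(age, y, covariates=None) -> ModelFit:
    """OLS of y on ln(age) plus covariates; the workhorse regional model."""
    return _fit_logarithmic(np.asarray(age, dtype=float),
                            np.asarray(y, dtype=float), covariates)


@dataclass
class EffectMap:
    """Voxel-wise age-effect statistics on a shared mask.

    ``beta``, ``z``, ``r`` and ``coef`` are indexed by in-mask voxel
    order (C order); ``coef`` holds the full coefficient vector per
    voxel for prediction.
    """

    mask: np.ndarray
    beta: np.ndarray
    z: np.ndarray
    r: np.ndarray
    coef: np.ndarray            # (n_voxels, p)
    coef_names: list
    degenerate: np.ndarray      # voxels with constant data, Z forced to 0
    voxel_size_mm: float = 2.0

    def to_volume(self, stat: str = "z") -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = getattr(self, stat)
        return vol


def voxelwise_age_effects(data: np.ndarray, age, covariates=None,
                          mask: np.ndarray | None = None,
                          voxel_size_mm: float = 2.0) -> EffectMap:
    """Fit the logarithmic age model at every voxel (vectorised OLS).

    ``data`` is a voxel x subject matrix whose columns match ``age``.
    """
    data = np.asarray(data, dtype=float)
    age = np.asarray(age, dtype=float)
    if data.shape[1] != age.size:
        raise ValueError("data columns must match the number of subjects")
    if np.any(age <= 0):
        raise ValueError("ages must be positive")
    X, names = _design(age, covariates, [np.log(age)])
    names[1] = "log_age"
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = data @ (xtx_inv @ X.T).T            # (voxels, p)
    fitted = coef @ X.T
    resid = data - fitted
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    se_b = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = coef[:, 1]
    degenerate = data.std(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_b > 0, beta / se_b, 0.0)
    p_two = 2.0 * stats.t.sf(np.abs(t), dof)
    p_two = np.clip(p_two, np.finfo(float).tiny, 1.0)
    z = np.sign(beta) * stats.norm.isf(p_two / 2.0)
    z[degenerate] = 0.0
    # r between observed and fitted per voxel
    yc = data - data.mean(axis=1, keepdims=True)
    fc = fitted - fitted.mean(axis=1, keepdims=True)
    denom = np.sqrt((yc**2).sum(axis=1) * (fc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (yc * fc).sum(axis=1) / denom, 0.0)
    if mask is None:
        mask = np.ones(data.shape[0], dtype=bool)
    return EffectMap(mask=np.asarray(mask, dtype=bool), beta=beta, z=z, r=r,
                     coef=coef, coef_names=names, degenerate=degenerate,
                     voxel_size_mm=voxel_size_mm)


def bonferroni_threshold(alpha: float, n_tests: int) -> dict:
    """Per-test p and two-tailed Z thresholds under Bonferroni correction."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p_threshold = alpha / n_tests
    return {"p_threshold": p_threshold,
            "z_threshold": float(stats.norm.isf(p_threshold / 2.0))}


@dataclass
class FittedMapStack:
    """Predicted CBF maps over a grid of ages (default 1-28 by 0.5)."""

    ages: np.ndarray
    maps: np.ndarray            # (n_ages, n_voxels), in-mask values
    mask: np.ndarray
    covariate_settings: dict
    voxel_size_mm: float = 2.0

    def __len__(self) -> int:
        return self.ages.size

    def volume_at(self, index: int) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.maps[index]
        return vol


def default_age_grid() -> np.ndarray:
    return np.arange(1.0, 28.0 + 0.25, 0.5)


def predict_map_stack(effects: EffectMap, ages=None,
                      motion_mm: float = PREDICTION_MOTION_MM) -> FittedMapStack:
    """Fitted rCBF maps at each age on the grid.

    Head motion is fixed at the cohort-average MRD and the sex effect is
    averaged over both sexes (prediction at sex 0 and 1, then averaged,
    i.e. sex = 0.5 for a 0/1 coding).
    """
    if ages is None:
        ages = default_age_grid()
    ages = np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("requested ages must be positive")
    settings = {"motion_mm": motion_mm, "sex": 0.5}
    preds = np.empty((ages.size, effects.coef.shape[0]))
    for j, a in enumerate(ages):
        row = np.zeros(len(effects.coef_names))
        for i, name in enumerate(effects.coef_names):
            low = name.lower()
            if name == "intercept":
                row[i] = 1.0
            elif name == "log_age":
                row[i] = np.log(a)
            elif "sex" in low:
                row[i] = settings["sex"]
            elif "motion" in low or "mrd" in low:
                row[i] = motion_mm
            else:
                row[i] = 0.0
        preds[j] = effects.coef @ row
    return FittedMapStack(ages=ages, maps=preds, mask=effects.mask,
                          covariate_settings=settings,
                          voxel_size_mm=effects.voxel_size_mm)


def rate_maps(effects: EffectMap, ages) -> np.ndarray:
    """Growth rate maps: d/dage of beta*ln(age) = beta/age per voxel.

    Returns an (n_ages, n_voxels) array in ml/100g/min per month.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    return effects.beta[None, :] / ages[:, None]
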