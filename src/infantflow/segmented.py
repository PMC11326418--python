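"""Segmented (breakpoint) regression of CBF against age.

Fits continuous piecewise-linear models with 0-3 breakpoints by the
iterative linearisation scheme of Muggeo: the model is locally
re-expressed through the hinge term (x - psi)+ and an indicator
correction term whose coefficient measures the gap at the current
breakpoint guess; the breakpoint is updated by gamma/beta_hinge until
the step vanishes.  Breakpoint standard errors follow from the delta
method; nested models are compared with extra-sum-of-squares F tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SegmentedModel",
    "SegmentedResults",
    "fit_segmented",
    "compare_segmented",
    "select_n_breakpoints",
    "voxelwise_breakpoints",
    "grid_search_breakpoint",
]


def _hinge(x, psi):
    return np.maximum(x - psi, 0.0)


def _segmented_design(x, psis):
    cols = [np.ones_like(x), x] + [_hinge(x, p) for p in psis]
    return np.column_stack(cols)


def _ols(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


@dataclass
class SegmentedResults:
    """A fitted continuous piecewise-linear model."""

    n_breakpoints: int
    psi: np.ndarray             # breakpoint estimates, months
    psi_se: np.ndarray
    slopes: np.ndarray          # one slope per phase
    slope_se: np.ndarray
    intercept: float
    rss: float
    nobs: int
    n_params: int
    adj_r2: float
    converged: bool = True
    used_grid_fallback: bool = False

    @property
    def df_resid(self) -> int:
        return self.nobs - self.n_params

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Delta-method CIs for the breakpoints (t quantiles)."""
        zq = stats.t.isf((1.0 - level) / 2.0, max(self.df_resid, 1))
        return np.column_stack([self.psi - zq * self.psi_se,
                                self.psi + zq * self.psi_se])

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        out = self.intercept + self.slopes[0] * age
        for j, p in enumerate(self.psi):
            out = out + (self.slopes[j + 1] - self.slopes[j]) * _hinge(age, p)
        return out

    def compare(self, simpler: "SegmentedResults") -> dict:
        return compare_segmented(simpler, self)

    def summary(self) -> str:
        lines = [f"Segmented regression: {self.n_breakpoints} breakpoint(s), "
                 f"n={self.nobs}, adj R2={self.adj_r2:.4f}"]
        ci = self.conf_int() if self.n_breakpoints else np.empty((0, 2))
        for j, p in enumerate(self.psi):
            lines.append(f"  psi_{j + 1} = {p:.2f} months "
                         f"(SE {self.psi_se[j]:.2f}, 95% CI {ci[j, 0]:.2f}, {ci[j, 1]:.2f})")
        for j, s in enumerate(self.slopes):
            lines.append(f"  phase {j + 1} slope = {s:.3f} "
                         f"+/- {self.slope_se[j]:.3f} ml/100g/min per month")
        return "\n".join(lines)


class SegmentedModel:
    """Piecewise-linear model of y against age with unknown breakpoints.

    Covariates, when supplied, are partialled out of y by OLS
    residualisation (adding back the mean) before the segmented fit.
    """

    def __init__(self, age, y, n_breakpoints: int = 1, covariates=None,
                 min_phase_points: int = 3):
        age = np.asarray(age, dtype=float)
        y = np.asarray(y, dtype=float)
        order = np.argsort(age, kind="stable")
        self.age = age[order]
        self.n_breakpoints = int(n_breakpoints)
        self.min_phase_points = min_phase_points
        if covariates is not None:
            import pandas as pd
            C = pd.DataFrame(covariates).to_numpy(dtype=float)[order]
            X = np.column_stack([np.ones(len(y)), C])
            beta, _ = _ols(X, y[order])
            y = y[order] - X @ beta + (X @ beta).mean()
            self.y = y
        else:
            self.y = y[order]
        n_min = 2 * (self.n_breakpoints + 1) + 1
        if self.age.size < n_min:
            raise ValueError(f"need at least {n_min} points for "
                             f"{self.n_breakpoints} breakpoint(s)")

    # -- fitting ---------------------------------------------------------

    def fit(self, init_psi=None, max_iter: int = 100,
            tol: float = 1e-9) -> SegmentedResults:
        if self.n_breakpoints == 0:
            return self._linear_fit()
        starts = self._starting_points(init_psi)
        last_err = None
        best = None
        for psi0 in starts:
            try:
                res = self._muggeo(np.asarray(psi0, dtype=float), max_iter, tol)
            except (FloatingPointError, np.linalg.LinAlgError, ValueError) as e:
                last_err = e
                continue
            if best is None or res.rss < best.rss:
                best = res
        if best is not None:
            if self.n_breakpoints == 1:
                best = self._polish_single(best)
            return best
        if self.n_breakpoints == 1:
            # profile grid-search fallback
            import warnings
            warnings.warn("iterative breakpoint estimation failed; "
                          "falling back to profile grid search")
            psi = grid_search_breakpoint(self.age, self.y)
            return self._finalize(np.array([psi]), converged=False,
                                  used_grid=True)
        raise ValueError(f"segmented fit failed: {last_err}")

    def _starting_points(self, init_psi):
        m = self.n_breakpoints
        qs = np.linspace(0, 100, m + 2)[1:-1]
        median_start = np.percentile(self.age, qs)
        starts = []
        if init_psi is not None:
            starts.append(np.atleast_1d(np.asarray(init_psi, dtype=float)))
        starts.append(median_start)
        # multi-start from shifted quantile grids
        for lo, hi in ((10, 60), (40, 90)):
            starts.append(np.percentile(self.age, np.linspace(lo, hi, m + 2)[1:-1]))
        if m == 1:
            # coarse profile scan: start the iteration in the global basin
            lo_b, hi_b = self._psi_bounds()
            best_psi, best_rss = None, np.inf
            for psi in np.linspace(lo_b, hi_b, 41)[1:-1]:
                _, rss = _ols(_segmented_design(self.age, [psi]), self.y)
                if rss < best_rss:
                    best_psi, best_rss = psi, rss
            starts.insert(0 if init_psi is None else 1, np.array([best_psi]))
        return starts

    def _polish_single(self, res: SegmentedResults) -> SegmentedResults:
        """Local profile scan around the iterative solution.

        The profile residual surface can hold several narrow basins under
        noise; a fine scan near the solution guards against settling in
        an adjacent one.
        """
        lo_b, hi_b = self._psi_bounds()
        psi0 = res.psi[0]
        grid = np.arange(max(lo_b, psi0 - 0.75), min(hi_b, psi0 + 0.75), 0.025)
        best_psi, best_rss = psi0, res.rss
        for psi in grid:
            _, rss = _ols(_segmented_design(self.age, [psi]), self.y)
            if rss < best_rss - 1e-12:
                best_psi, best_rss = psi, rss
        if best_psi != psi0:
            cand = None
            try:
                cand = self._muggeo(np.array([best_psi]), 30, 1e-9)
            except (ValueError, np.linalg.LinAlgError):
                pass
            if cand is None or cand.rss > best_rss + 1e-9:
                try:
                    cand = self._finalize(np.array([best_psi]),
                                          converged=res.converged,
                                          used_grid=True)
                except ValueError:
                    cand = None
            if cand is not None and cand.rss < res.rss:
                return cand
        return res

    def _psi_bounds(self):
        lo = self.age[self.min_phase_points - 1]
        hi = self.age[-self.min_phase_points]
        return lo + 1e-8, hi - 1e-8

    def _muggeo(self, psi, max_iter, tol):
        x, y = self.age, self.y
        lo, hi = self._psi_bounds()
        psi = np.clip(np.sort(psi), lo, hi)
        m = psi.size
        for _ in range(max_iter):
            U = np.column_stack([_hinge(x, p) for p in psi])
            V = np.column_stack([-(x > p).astype(float) for p in psi])
            X = np.column_stack([np.ones_like(x), x, U, V])
            beta, _ = _ols(X, y)
            b_u = beta[2:2 + m]
            gamma = beta[2 + m:]
            if np.any(np.abs(b_u) < 1e-12):
                raise ValueError("vanishing slope change at a breakpoint")
            step = gamma / b_u
            psi_new = np.sort(psi + step)
            if np.any(psi_new <= lo) or np.any(psi_new >= hi):
                psi_new = np.clip(psi_new, lo, hi)
            if np.max(np.abs(psi_new - psi)) < tol:
                psi = psi_new
                break
            psi = psi_new
        else:
            # accept the last iterate; flagged as not fully converged
            return self._finalize(psi, converged=False)
        return self._finalize(psi, converged=True)

    def _finalize(self, psi, converged=True, used_grid=False) -> SegmentedResults:
        x, y = self.age, self.y
        psi = np.sort(psi)
        m = psi.size
        # degenerate-phase guard
        edges = np.concatenate([[-np.inf], psi, [np.inf]])
        for j in range(m + 1):
            in_phase = (x > edges[j]) & (x <= edges[j + 1])
            if in_phase.sum() < self.min_phase_points:
                raise ValueError(f"phase {j + 1} contains fewer than "
                                 f"{self.min_phase_points} points")
        # final fit with the correction terms (gamma ~ 0 at the solution)
        U = np.column_stack([_hinge(x, p) for p in psi])
        V = np.column_stack([-(x > p).astype(float) for p in psi])
        Xfull = np.column_stack([np.ones_like(x), x, U, V])
        beta_full, _ = _ols(Xfull, y)
        n = x.size
        p_full = Xfull.shape[1]
        resid = y - Xfull @ beta_full
        rss = float(resid @ resid)
        dof = n - p_full
        sigma2 = rss / dof if dof > 0 else np.nan
        cov = sigma2 * np.linalg.pinv(Xfull.T @ Xfull)
        se = np.sqrt(np.abs(np.diag(cov)))
        b_u = beta_full[2:2 + m]
        se_gamma = se[2 + m:]
        psi_se = se_gamma / np.abs(b_u)
        # continuous piecewise model for reporting (drop the V terms)
        Xseg = _segmented_design(x, psi)
        beta_seg, rss_seg = _ols(Xseg, y)
        slopes = np.concatenate([[beta_seg[1]], beta_seg[1] + np.cumsum(beta_seg[2:])])
        # slope SEs from the covariance of (b1, b_u1, ...)
        p_seg = Xseg.shape[1]
        dof_seg = n - p_seg - m  # psi estimates consume df as well
        sigma2_seg = rss_seg / max(dof_seg, 1)
        cov_seg = sigma2_seg * np.linalg.pinv(Xseg.T @ Xseg)
        slope_se = np.empty(m + 1)
        for j in range(m + 1):
            w = np.zeros(p_seg)
            w[1] = 1.0
            w[2:2 + j] = 1.0
            slope_se[j] = np.sqrt(max(w @ cov_seg @ w, 0.0))
        n_params = p_seg + m + 1  # coefficients + breakpoints + residual sd
        tss = float(((y - y.mean())**2).sum())
        df_model = p_seg + m
        adj_r2 = 1.0 - (rss_seg / max(n - df_model, 1)) / (tss / (n - 1))
        return SegmentedResults(
            n_breakpoints=m, psi=psi, psi_se=psi_se, slopes=slopes,
            slope_se=slope_se, intercept=float(beta_seg[0]), rss=rss_seg,
            nobs=n, n_params=df_model + 1, adj_r2=adj_r2,
            converged=converged, used_grid_fallback=used_grid)

    def _linear_fit(self) -> SegmentedResults:
        x, y = self.age, self.y
        X = np.column_stack([np.ones_like(x), x])
        beta, rss = _ols(X, y)
        n = x.size
        dof = n - 2
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        tss = float(((y - y.mean())**2).sum())
        adj_r2 = 1.0 - (rss / dof) / (tss / (n - 1))
        return SegmentedResults(
            n_breakpoints=0, psi=np.empty(0), psi_se=np.empty(0),
            slopes=np.array([beta[1]]), slope_se=np.array([np.sqrt(cov[1, 1])]),
            intercept=float(beta[0]), rss=rss, nobs=n, n_params=3,
            adj_r2=adj_r2)


def grid_search_breakpoint(age, y, step: float = 0.05) -> float:
    """Brute-force profile search for a single breakpoint (oracle-grade)."""
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(age)
    age, y = age[order], y[order]
    lo, hi = age[2], age[-3]
    best_psi, best_rss = None, np.inf
    for psi in np.arange(lo + step, hi - step / 2, step):
        X = _segmented_design(age, [psi])
        _, rss = _ols(X, y)
        if rss < best_rss:
            best_rss, best_psi = rss, psi
    return float(best_psi)


def fit_segmented(age, y, n_breakpoints: int = 1, init_psi=None,
                  covariates=None) -> SegmentedResults:
    """Fit a continuous piecewise-linear model with the given breakpoints."""
    return SegmentedModel(age, y, n_breakpoints, covariates).fit(init_psi=init_psi)


def compare_segmented(fit_simple: SegmentedResults,
                      fit_complex: SegmentedResults) -> dict:
    """Extra-sum-of-squares ANOVA between nested segmented fits."""
    if fit_simple.nobs != fit_complex.nobs:
        raise ValueError("fits are not on the same data")
    if fit_complex.n_params <= fit_simple.n_params:
        raise ValueError("fit_complex must have more parameters than fit_simple")
    df1 = fit_complex.n_params - fit_simple.n_params
    df2 = fit_complex.nobs - (fit_complex.n_params - 1)
    num = (fit_simple.rss - fit_complex.rss) / df1
    den = fit_complex.rss / df2
    if den == 0:
        f = 0.0 if num <= 0 else np.inf
    else:
        f = max(num / den, 0.0)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return {"F": float(f), "df1": df1, "df2": df2, "p": p}


def select_n_breakpoints(age, y, max_breakpoints: int = 3,
                         alpha: float = 0.05, covariates=None) -> SegmentedResults:
    """Add breakpoints while the F test improves the fit at level alpha.

    Starting from the plain linear model, each extra breakpoint is
    accepted only when the extra-sum-of-squares test is significant and
    the adjusted R-squared increases; the last accepted model returns.
    """
    current = SegmentedModel(age, y, 0, covariates).fit()
    for m in range(1, max_breakpoints + 1):
        try:
            candidate = SegmentedModel(age, y, m, covariates).fit()
        except ValueError:
            break
        test = compare_segmented(current, candidate)
        if test["p"] < alpha and candidate.adj_r2 > current.adj_r2:
            current = candidate
        else:
            break
    return current


def voxelwise_breakpoints(data: np.ndarray, age, labels=None,
                          covariates=None) -> dict:
    """Single-breakpoint fit per voxel; per-cluster breakpoint histograms.

    ``data`` is voxel x subject; ``labels`` an optional per-voxel
    cluster label vector.  Voxels whose fit fails are flagged and left
    out of the histograms.
    """
    data = np.asarray(data, dtype=float)
    n_vox = data.shape[0]
    psi = np.full(n_vox, np.nan)
    failed = np.zeros(n_vox, dtype=bool)
    for v in range(n_vox):
        try:
            res = SegmentedModel(age, data[v], 1, covariates).fit()
            psi[v] = res.psi[0]
        except (ValueError, np.linalg.LinAlgError):
            failed[v] = True
    out = {"psi": psi, "failed": failed, "n_failed": int(failed.sum())}
    if labels is not None:
        labels = np.asarray(labels)
        hists = {}
        for lab in np.unique(labels):
            sel = (labels == lab) & ~failed
            hists[lab] = psi[sel]
        out["per_cluster"] = hists
    return out
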