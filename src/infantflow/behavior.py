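"""Brain-behaviour association with penalized-spline GAMs.

Regional CBF is regressed on a behaviour score with a penalized cubic
regression spline for age (so linear and nonlinear age effects are
absorbed without committing to a functional form) and linear terms for
sex, head motion and family socioeconomic status:

    rCBF ~ behaviour + s(age) + sex + motion + SES

The t statistic of the behaviour term is the quantity of interest.
Voxel-wise t maps are thresholded (default t > 2.02) and cleaned by a
minimum cluster extent (default 100 contiguous voxels, 26-connectivity,
800 mm^3 at 2 mm isotropic); cluster-level tests over the three Bayley
domains use a Bonferroni-corrected threshold 0.05/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GAMFit",
    "VoxelCluster",
    "fit_gam_behavior",
    "voxelwise_behavior_tmap",
    "extract_clusters",
    "cluster_level_assoc",
    "behavior_river_summary",
    "complete_cases",
]

T_THRESHOLD_DEFAULT = 2.02
MIN_EXTENT_DEFAULT = 100

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class GAMFit:
    """Behaviour-term inference from one penalized-spline GAM."""

    coef_score: float
    t_score: float
    p_score: float
    spline_df: int
    alpha: float                # smoothing penalty weight
    edf_age: float              # effective degrees of freedom of s(age)
    df_resid: float
    nobs: int


def _gam_design(score, sex, motion, ses):
    cols = {"score": score}
    for name, vec in (("sex", sex), ("motion", motion), ("ses", ses)):
        if vec is not None:
            cols[name] = vec
    X = pd.DataFrame(cols).astype(float)
    X.insert(0, "const", 1.0)
    return X


def fit_gam_behavior(rcbf, score, age, sex=None, motion=None, ses=None,
                     spline_df: int = 5, alpha: float | None = None) -> GAMFit:
    """GAM of regional CBF on a behaviour score with s(age) adjustment.

    ``alpha`` is the smoothing penalty weight; when omitted it is chosen
    by generalized cross-validation.  Subjects with missing values must
    be removed beforehand (see :func:`complete_cases`).
    """
    from statsmodels.gam.api import BSplines, GLMGam

    y = np.asarray(rcbf, dtype=float)
    age = np.asarray(age, dtype=float)
    n = y.size
    if n < 15:
        raise ValueError("GAM requires at least 15 subjects")
    X = _gam_design(np.asarray(score, dtype=float), sex, motion, ses)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design")
    smoother = BSplines(age, df=[spline_df], degree=[3])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GLMGam(y, exog=X, smoother=smoother)
        if alpha is None:
            model.fit()  # establishes the scale select_penweight starts from
            alpha = float(np.atleast_1d(model.select_penweight(criterion="gcv")[0])[0])
        model = GLMGam(y, exog=X, smoother=smoother, alpha=alpha)
        res = model.fit()
    idx = list(X.columns).index("score")
    # effective df of the spline block from the penalized hat matrix
    try:
        edf_age = float(np.sum(res.edf[X.shape[1]:]))
    except Exception:
        edf_age = float(spline_df)
    df_resid = float(res.df_resid)
    from scipy import stats as sps

    t = float(np.asarray(res.tvalues)[idx])
    p = float(2.0 * sps.t.sf(abs(t), df_resid))
    return GAMFit(coef_score=float(np.asarray(res.params)[idx]), t_score=t, p_score=p,
                  spline_df=spline_df, alpha=float(alpha),
                  edf_age=max(edf_age, 1.0), df_resid=df_resid, nobs=n)


def voxelwise_behavior_tmap(data, score, age, sex=None, motion=None, ses=None,
                            spline_df: int = 5,
                            alpha: float | None = None) -> dict:
    """Behaviour-term t statistic at every voxel.

    ``data`` is voxel x subject.  The smoothing weight is selected once
    on the mask-mean signal by GCV and reused across voxels (a single
    age smooth is shared by construction of the study design); voxels
    whose fit fails are flagged with NaN.
    """
    data = np.asarray(data, dtype=float)
    if alpha is None:
        mean_fit = fit_gam_behavior(data.mean(axis=0), score, age, sex,
                                    motion, ses, spline_df=spline_df)
        alpha = mean_fit.alpha
    t = np.full(data.shape[0], np.nan)
    failed = np.zeros(data.shape[0], dtype=bool)
    for v in range(data.shape[0]):
        try:
            t[v] = fit_gam_behavior(data[v], score, age, sex, motion, ses,
                                    spline_df=spline_df, alpha=alpha).t_score
        except (ValueError, np.linalg.LinAlgError):
            failed[v] = True
    return {"t": t, "failed": failed, "alpha": alpha}


@dataclass
class VoxelCluster:
    """A contiguous suprathreshold voxel cluster."""

    indices: np.ndarray          # (n, 3) 0-based voxel indices
    size: int
    volume_mm3: float
    peak_t: float
    parcel_label: int | None = None
    t_cluster: float | None = None
    p_cluster: float | None = None
    significant: bool | None = None


def extract_clusters(t_map: np.ndarray, t_threshold: float = T_THRESHOLD_DEFAULT,
                     min_extent: int = MIN_EXTENT_DEFAULT, connectivity: int = 26,
                     voxel_size_mm: float = 2.0, parcel_labels=None,
                     two_sided: bool = False) -> list:
    """Connected suprathreshold components above a minimum extent.

    Default keeps the positive tail only (t > threshold); each cluster
    is annotated with its dominant parcellation label when given.
    """
    t_map = np.asarray(t_map, dtype=float)
    if t_map.ndim != 3 or t_map.size == 0:
        raise ValueError("t map must be a non-empty 3-D grid")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    supra = np.abs(t_map) > t_threshold if two_sided else t_map > t_threshold
    labeled, n_comp = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    voxel_volume = voxel_size_mm**3
    clusters = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labeled == comp)
        if idx.shape[0] < min_extent:
            continue
        tvals = t_map[tuple(idx.T)]
        peak = float(tvals[np.argmax(np.abs(tvals))])
        parcel = None
        if parcel_labels is not None:
            labs = np.asarray(parcel_labels)[tuple(idx.T)]
            labs = labs[labs >= 0]
            if labs.size:
                parcel = int(np.bincount(labs).argmax())
        clusters.append(VoxelCluster(indices=idx, size=idx.shape[0],
                                     volume_mm3=idx.shape[0] * voxel_volume,
                                     peak_t=peak, parcel_label=parcel))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


def cluster_level_assoc(cluster_mean_rcbf, score, age, sex=None, motion=None,
                        ses=None, n_domains: int = 3,
                        alpha_family: float = 0.05, **gam_kw) -> dict:
    """Cluster-level GAM with Bonferroni control over behaviour domains.

    Significance threshold is ``alpha_family / n_domains`` (0.0167 for
    the three Bayley domains).
    """
    fit = fit_gam_behavior(cluster_mean_rcbf, score, age, sex, motion, ses,
                           **gam_kw)
    threshold = alpha_family / n_domains
    return {"t": fit.t_score, "p": fit.p_score,
            "threshold": threshold,
            "significant": fit.p_score < threshold, "fit": fit}


def behavior_river_summary(domain_clusters: dict, parcel_labels,
                           parcel_names=None) -> pd.DataFrame:
    """Domain x parcel table of significant-voxel fractions.

    ``domain_clusters`` maps a domain name to its list of significant
    :class:`VoxelCluster`; each row (domain) is normalised by that
    domain's total significant voxel count.  Domains without any
    significant voxel keep a NaN row rather than an unnormalisable one.
    """
    parcel_labels = np.asarray(parcel_labels)
    parcels = np.unique(parcel_labels[parcel_labels >= 0])
    columns = ([parcel_names[p] for p in parcels]
               if parcel_names is not None else list(parcels))
    rows = {}
    for domain, clusters in domain_clusters.items():
        counts = np.zeros(parcels.size)
        for cl in clusters:
            labs = parcel_labels[tuple(cl.indices.T)]
            for j, p in enumerate(parcels):
                counts[j] += np.count_nonzero(labs == p)
        total = counts.sum()
        rows[domain] = counts / total if total > 0 else np.full(parcels.size, np.nan)
    return pd.DataFrame(rows, index=columns).T


def complete_cases(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Listwise deletion of subjects missing any of the given columns."""
    return table.dropna(subset=list(columns))
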