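"""Orthonormal projective NMF parcellation of voxel x subject matrices.

Factorises a non-negative matrix X (voxels x subjects) as X ~ W H with
H = W^T X, minimising ||X - W W^T X||_F^2 subject to W >= 0 and
approximately orthonormal columns.  The projective multiplicative
update W <- W * (X X^T W) / (W W^T X X^T W), followed by column
renormalisation, drives W toward an orthonormal non-negative basis
without enforcing W^T W = I as a hard constraint.  Soft voxel weights
are hardened by assigning each voxel to its highest-weight component;
the number of components is selected by scanning K with the
Davies-Bouldin (lower is better) and Calinski-Harabasz (higher is
better) cluster-validity indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

__all__ = [
    "OPNMF",
    "ParcellationResult",
    "opnmf_fit",
    "hard_assignment",
    "davies_bouldin",
    "calinski_harabasz",
    "select_k",
    "KSelectionReport",
]


def _nndsvd_init(x: np.ndarray, k: int, eps: float = 1e-9) -> np.ndarray:
    """Deterministic non-negative double-SVD initialisation of W."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    m = x.shape[0]
    w = np.zeros((m, k))
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    for j in range(1, min(k, s.size)):
        uj, vj = u[:, j], vt[j]
        up, un = np.maximum(uj, 0), np.maximum(-uj, 0)
        vp, vn = np.maximum(vj, 0), np.maximum(-vj, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            w[:, j] = np.sqrt(s[j] * n_up * n_vp) * up / max(n_up, eps)
        else:
            w[:, j] = np.sqrt(s[j] * n_un * n_vn) * un / max(n_un, eps)
    if k > s.size:
        w[:, s.size:] = np.abs(x.mean()) / 100.0
    # NNDSVDa-style fill of zeros with the matrix mean to avoid dead entries
    w[w < eps] = np.abs(x).mean() / 100.0
    return w


@dataclass
class ParcellationResult:
    """Result of one opNMF factorisation."""

    w: np.ndarray               # (voxels, K), non-negative, unit columns
    k: int
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    x_norm_sq: float
    _x: np.ndarray | None = field(default=None, repr=False)

    @property
    def h(self) -> np.ndarray:
        """Coefficients H = W^T X."""
        return self.w.T @ self._x

    @property
    def labels(self) -> np.ndarray:
        return hard_assignment(self.w)

    @property
    def reconstruction_error(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def orthonormality_residual(self) -> float:
        """Largest off-diagonal |W^T W| entry (0 for exact orthogonality)."""
        g = self.w.T @ self.w
        off = np.abs(g - np.diag(np.diag(g)))
        return float(off.max()) if self.k > 1 else 0.0


class OPNMF:
    """Orthonormal projective NMF of a non-negative voxel x subject matrix."""

    def __init__(self, x: np.ndarray, k: int, init: str = "nndsvd",
                 tol: float = 1e-7, max_iter: int = 5000, seed: int | None = None):
        x = np.asarray(x, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if np.any(x < 0):
            raise ValueError("X must be non-negative")
        if not np.any(x > 0):
            raise ValueError("X must not be all zero")
        if not 1 <= k <= min(x.shape):
            raise ValueError("K must lie in [1, min(M, N)]")
        self.x = x
        self.k = int(k)
        self.init = init
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def _init_w(self) -> np.ndarray:
        if self.init == "nndsvd":
            w = _nndsvd_init(self.x, self.k)
        elif self.init == "random":
            rng = np.random.default_rng(self.seed)
            w = rng.uniform(0.1, 1.0, (self.x.shape[0], self.k))
        else:
            raise ValueError(f"unknown init {self.init!r}")
        return w / np.linalg.norm(w, axis=0, keepdims=True)

    def fit(self) -> ParcellationResult:
        x = self.x
        # X X^T is only ever applied to W; factorising X = U S V^T lets
        # every product run through the thin (M, r) factor A = U S,
        # which is much cheaper than the (M, M) Gram matrix for M >> N.
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        a = u * s
        x_norm_sq = float((s**2).sum())
        w = self._init_w()
        eps = 1e-12

        def objective(w):
            # ||X - W W^T X||^2 = ||X||^2 - 2 tr(W^T C W) + tr((W^T C W)(W^T W))
            atw = a.T @ w
            wtcw = atw.T @ atw
            return x_norm_sq - 2.0 * np.trace(wtcw) + float(
                np.einsum("ij,ji->", wtcw, w.T @ w))

        obj = objective(w)
        trace = [obj]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            cw = a @ (a.T @ w)
            denom = w @ (w.T @ cw)
            w_new = w * cw / np.maximum(denom, eps)
            # overall-norm renormalisation (the projective-NMF convention;
            # the returned W is column-normalised at the end)
            w_new /= max(np.linalg.norm(w_new, 2), eps)
            new_obj = objective(w_new)
            if new_obj > obj * (1 + 1e-10):
                # multiplicative step overshot: damp toward the previous iterate
                w_new = 0.5 * (w + w_new)
                w_new /= max(np.linalg.norm(w_new, 2), eps)
                new_obj = objective(w_new)
                if new_obj > obj * (1 + 1e-10):
                    converged = True
                    break
            rel_change = abs(obj - new_obj) / max(abs(obj), eps)
            w, obj = w_new, new_obj
            trace.append(obj)
            if rel_change < self.tol:
                converged = True
                break
        w = w / np.maximum(np.linalg.norm(w, axis=0, keepdims=True), eps)
        return ParcellationResult(w=w, k=self.k,
                                  objective_trace=np.asarray(trace),
                                  converged=converged, n_iter=it,
                                  x_norm_sq=x_norm_sq, _x=x)


def opnmf_fit(x: np.ndarray, k: int, **kw) -> ParcellationResult:
    """Fit orthonormal projective NMF with K components."""
    return OPNMF(x, k, **kw).fit()


def hard_assignment(w: np.ndarray) -> np.ndarray:
    """Hard labels: per-voxel argmax component (ties -> lowest index).

    All-zero rows cannot be assigned; they receive label 0 as well and
    are reported through the returned array's companion count when
    needed (argmax of a zero row is 0 by the same tie rule).
    """
    w = np.asarray(w)
    return np.argmax(w, axis=1)


def davies_bouldin(features: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index (lower = better separated clusters)."""
    _check_clustering(features, labels)
    return float(davies_bouldin_score(features, labels))


def calinski_harabasz(features: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index (higher = denser, better separated)."""
    _check_clustering(features, labels)
    return float(calinski_harabasz_score(features, labels))


def _check_clustering(features, labels):
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("validity indices require at least 2 clusters")
    if np.allclose(np.asarray(features).std(axis=0), 0):
        raise ValueError("degenerate features: all rows identical")


@dataclass
class KSelectionReport:
    """Validity-index scan over a contiguous K range."""

    table: pd.DataFrame         # per-K DB, CH, reconstruction error
    chosen_k: int
    rule: str

    def summary(self) -> pd.DataFrame:
        return self.table


def select_k(x: np.ndarray, k_range=range(2, 21), init: str = "nndsvd",
             tol: float = 1e-7, max_iter: int = 1500,
             seed: int | None = None) -> KSelectionReport:
    """Scan K, scoring each opNMF hard parcellation with DB and CH.

    Features for the indices are the voxel rows of X (each voxel's
    subject profile).  The chosen K optimises the summed rank of the
    two indices (DB ascending, CH descending); ties go to the smaller K.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty K range")
    rows = []
    for k in ks:
        res = OPNMF(x, k, init=init, tol=tol, max_iter=max_iter, seed=seed).fit()
        labels = res.labels
        if np.unique(labels).size < 2:
            db, ch = np.inf, 0.0
        else:
            db = davies_bouldin(x, labels)
            ch = calinski_harabasz(x, labels)
        rows.append({"K": k, "davies_bouldin": db, "calinski_harabasz": ch,
                     "reconstruction_error": res.reconstruction_error,
                     "n_iter": res.n_iter})
    table = pd.DataFrame(rows).set_index("K")
    if len(ks) == 1:
        return KSelectionReport(table=table, chosen_k=ks[0],
                                rule="single candidate")
    db_rank = table["davies_bouldin"].rank(method="min")
    ch_rank = table["calinski_harabasz"].rank(method="min", ascending=False)
    total = db_rank + ch_rank
    chosen = int(total.idxmin())  # idxmin returns the first (smallest K) on ties
    table["rank_sum"] = total
    return KSelectionReport(table=table, chosen_k=chosen,
                            rule="min(DB rank + CH rank), ties to smaller K")
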