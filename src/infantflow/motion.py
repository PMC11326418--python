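"""In-scanner motion quality control for ASL time series.

Rigid realignment parameters (three rotations, three translations per
volume, MCFLIRT column order) are condensed to a per-volume RMS
displacement relative to the preceding volume, averaged into the mean
relative displacement (MRD) motion summary.  Volumes moving more than a
threshold are scrubbed; subjects whose MRD exceeds the threshold are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MotionSeries",
    "rigid_matrix",
    "relative_rms_displacement",
    "mean_relative_displacement",
    "scrub_volumes",
    "exclude_subject",
    "motion_qc_report",
]

#: default radius (mm) of the sphere over which displacement is averaged
BRAIN_RADIUS_MM = 50.0
#: scrubbing / exclusion threshold, mm
MOTION_THRESHOLD_MM = 0.5

MOTION_COLUMNS = ["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"]


def rigid_matrix(params) -> np.ndarray:
    """4x4 rigid transform from (rx, ry, rz, tx, ty, tz).

    Rotations in radians applied in Rz @ Ry @ Rx order about the sphere
    centre, then translation in mm (the FSL convention for small-angle
    realignment parameters; the displacement metric is insensitive to
    the composition order at realistic amplitudes).
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (6,):
        raise ValueError("a motion row must have exactly 6 parameters")
    rx, ry, rz, tx, ty, tz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    out = np.eye(4)
    out[:3, :3] = Rz @ Ry @ Rx
    out[:3, 3] = (tx, ty, tz)
    return out


def _rms_of_transform_pair(t_a: np.ndarray, t_b: np.ndarray, radius: float) -> float:
    # Jenkinson's RMS deviation between two rigid transforms: the root
    # mean square displacement of points in a ball of the given radius
    # under M = T_a T_b^{-1}.  With A = M[:3,:3] - I and t = M[:3,3],
    # RMS^2 = (R^2/5) tr(A^T A) + t^T t.
    m = t_a @ np.linalg.inv(t_b)
    a = m[:3, :3] - np.eye(3)
    t = m[:3, 3]
    return float(np.sqrt(radius**2 / 5.0 * np.trace(a.T @ a) + t @ t))


@dataclass
class MotionSeries:
    """A rigid-body motion parameter table for one acquisition."""

    params: pd.DataFrame

    def __post_init__(self):
        arr = np.asarray(self.params, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError("motion table must have 6 columns "
                             "(3 rotations rad, 3 translations mm)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite motion parameters")
        self.params = pd.DataFrame(arr, columns=MOTION_COLUMNS)

    @classmethod
    def from_file(cls, path) -> "MotionSeries":
        return cls(pd.read_csv(path, sep=r"\s+", header=None))

    @property
    def n_volumes(self) -> int:
        return len(self.params)


def relative_rms_displacement(series: MotionSeries,
                              brain_radius_mm: float = BRAIN_RADIUS_MM) -> np.ndarray:
    """Per-volume RMS displacement relative to the preceding volume (mm).

    Volume 0 has no predecessor and is assigned 0.  A pure translation
    displaces every voxel equally, so its entry is the translation
    magnitude regardless of radius; rotations contribute through the
    sphere-averaged term and grow with the radius.
    """
    if series.n_volumes < 1:
        raise ValueError("motion series is empty")
    mats = [rigid_matrix(row) for row in series.params.to_numpy()]
    rel = np.zeros(series.n_volumes)
    for i in range(1, series.n_volumes):
        rel[i] = _rms_of_transform_pair(mats[i], mats[i - 1], brain_radius_mm)
    return rel


def mean_relative_displacement(rel: np.ndarray) -> float:
    """MRD: the arithmetic mean of the relative displacement vector."""
    rel = np.asarray(rel, dtype=float)
    if rel.size == 0:
        raise ValueError("empty displacement vector")
    if np.any(np.isnan(rel)):
        raise ValueError("NaN in displacement vector")
    return float(rel.mean())


def scrub_volumes(rel: np.ndarray, threshold: float = MOTION_THRESHOLD_MM) -> np.ndarray:
    """Indices of volumes with relative displacement <= threshold.

    The inequality is strict for removal: a volume exactly at the
    threshold is retained.
    """
    rel = np.asarray(rel, dtype=float)
    return np.flatnonzero(~(rel > threshold))


def exclude_subject(mrd: float, threshold: float = MOTION_THRESHOLD_MM) -> bool:
    """True when a subject's MRD exceeds the exclusion threshold."""
    if np.isnan(mrd):
        raise ValueError("MRD is NaN")
    return bool(mrd > threshold)


def motion_qc_report(series: MotionSeries,
                     brain_radius_mm: float = BRAIN_RADIUS_MM,
                     threshold: float = MOTION_THRESHOLD_MM) -> dict:
    """Full motion QC for one subject.

    MRD is computed on the full series before scrubbing (the covariate
    used downstream); the retained index set reflects volume scrubbing.
    """
    rel = relative_rms_displacement(series, brain_radius_mm)
    mrd = mean_relative_displacement(rel)
    retained = scrub_volumes(rel, threshold)
    return {
        "relative_displacement": rel,
        "mrd": mrd,
        "retained_volumes": retained,
        "excluded": exclude_subject(mrd, threshold),
    }


def retained_pairs_from_volumes(retained_volumes: np.ndarray, n_pairs: int) -> np.ndarray:
    """Map volume-level scrubbing to control/label pair indices.

    Volumes are interleaved control, label, control, label, ...; a pair
    survives only if both of its members do.
    """
    retained = set(np.asarray(retained_volumes, dtype=int).tolist())
    keep = [p for p in range(n_pairs)
            if 2 * p in retained and 2 * p + 1 in retained]
    return np.asarray(keep, dtype=int)
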