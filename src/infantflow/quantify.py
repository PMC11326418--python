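"""Cerebral blood flow quantification from phase-contrast and pCASL MRI.

Global CBF comes from the summed flow flux through the four feeding
arteries (bilateral internal carotid and vertebral arteries) divided by
brain parenchyma mass.  Regional CBF comes from the single-compartment
pCASL kinetic model of the ASL consensus recommendations, and is then
calibrated so that its mask mean equals the phase-contrast global CBF,
absorbing subject-wise variation in labelling efficiency and arterial T1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCMeasurement",
    "ASLConstants",
    "ASLAcquisition",
    "CBFMap",
    "global_cbf_from_pc",
    "compute_delta_m",
    "rcbf_from_asl",
    "calibrate_rcbf",
    "icc_test_retest",
]

#: brain tissue density, g/mL
RHO_DEFAULT = 1.06


@dataclass(frozen=True)
class PCMeasurement:
    """Phase-contrast flux measurement for one subject.

    Parameters
    ----------
    fluxes : array-like of float
        Flow flux (integral of velocity over the vessel cross-section)
        for each feeding artery, ml/min.  Conventionally ordered as
        [left ICA, right ICA, left VA, right VA].
    brain_volume : float
        Parenchyma (GM+WM) volume in mL.
    rho : float
        Brain tissue density in g/mL.
    """

    fluxes: np.ndarray
    brain_volume: float
    rho: float = RHO_DEFAULT

    def __post_init__(self):
        object.__setattr__(self, "fluxes", np.asarray(self.fluxes, dtype=float))
        if np.any(self.fluxes < 0):
            raise ValueError("artery fluxes must be non-negative")
        if not self.brain_volume > 0:
            raise ValueError("brain volume must be positive")
        if not self.rho > 0:
            raise ValueError("tissue density must be positive")


@dataclass(frozen=True)
class ASLConstants:
    """Constants of the pCASL single-compartment quantification model.

    All times are stored in seconds; configuration files quoting
    milliseconds must convert at the boundary.
    """

    lambda_coeff: float = 0.9  # blood-brain partition coefficient, ml/g
    alpha: float = 0.86        # labelling efficiency
    t1a: float = 1.8           # T1 of arterial blood, s
    pld: float = 1.8           # post-labelling delay, s
    label_dur: float = 1.6     # labelling duration, s

    def __post_init__(self):
        for name in ("lambda_coeff", "alpha", "t1a", "pld", "label_dur"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha > 1:
            raise ValueError("labelling efficiency cannot exceed 1")

    @property
    def scale(self) -> float:
        """Scalar mapping dM/M0 to CBF in ml/100g/min."""
        num = 6000.0 * self.lambda_coeff * np.exp(self.pld / self.t1a)
        den = 2.0 * self.alpha * self.t1a * (1.0 - np.exp(-self.label_dur / self.t1a))
        return num / den


@dataclass
class ASLAcquisition:
    """A pCASL control/label series with its M0 image and motion table.

    ``control`` and ``label`` are (n_pairs, *grid) arrays; ``m0`` is a
    single volume (mean of the acquired M0 pair); ``mask`` is boolean.
    ``motion_params`` is the 6-column rigid realignment table, one row
    per acquired volume (controls and labels interleaved).
    """

    control: np.ndarray
    label: np.ndarray
    m0: np.ndarray
    mask: np.ndarray
    motion_params: pd.DataFrame | None = None

    def __post_init__(self):
        self.control = np.asarray(self.control, dtype=float)
        self.label = np.asarray(self.label, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.control.shape != self.label.shape:
            raise ValueError("control and label series must be paired volumes")
        if self.control.shape[1:] != self.m0.shape or self.m0.shape != self.mask.shape:
            raise ValueError("all ASL volumes must share one grid")

    @property
    def n_pairs(self) -> int:
        return self.control.shape[0]


@dataclass
class CBFMap:
    """A masked voxel-wise CBF map in ml/100g/min."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float = 2.0
    calibrated: bool = False
    calibration_scale: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite CBF values inside mask")

    @property
    def masked(self) -> np.ndarray:
        """1-D vector of in-mask values (fixed C-order voxel ordering)."""
        return self.values[self.mask]

    def mean(self) -> float:
        return float(self.masked.mean())


def global_cbf_from_pc(pc: PCMeasurement) -> float:
    """Global CBF in ml/100g/min from a phase-contrast measurement.

    CBF = total arterial flux / (rho * brain volume), rescaled to
    ml/100g/min.  Flux in ml/min and volume in mL give mass in grams via
    the tissue density, hence the factor 100.
    """
    total_flux = float(np.sum(pc.fluxes))
    return 100.0 * total_flux / (pc.rho * pc.brain_volume)


def compute_delta_m(acq: ASLAcquisition, retained_pairs=None) -> np.ndarray:
    """Dynamic-averaged control-minus-label difference image.

    Parameters
    ----------
    retained_pairs : sequence of int, optional
        Indices of control/label pairs surviving motion scrubbing.  A
        pair is retained only as a whole; volume-level scrubbing must be
        reconciled to pairs upstream (see :func:`infantflow.motion.scrub_volumes`).
    """
    if retained_pairs is None:
        retained_pairs = np.arange(acq.n_pairs)
    retained_pairs = np.asarray(retained_pairs, dtype=int)
    if retained_pairs.size == 0:
        raise ValueError("QC failure: no control/label pairs retained after scrubbing")
    diff = acq.control[retained_pairs] - acq.label[retained_pairs]
    return diff.mean(axis=0)


def rcbf_from_asl(delta_m: np.ndarray, m0: np.ndarray, constants: ASLConstants,
                  mask: np.ndarray | None = None,
                  voxel_size_mm: float = 2.0) -> CBFMap:
    """Regional CBF from the pCASL difference image.

    rCBF = 6000 * lambda * (dM/M0) * exp(PLD/T1a)
           / (2 * alpha * T1a * (1 - exp(-LabelDur/T1a)))

    Voxels whose M0 is non-positive cannot be quantified and are dropped
    from the mask (a count is emitted as a warning).
    """
    delta_m = np.asarray(delta_m, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if mask is None:
        mask = np.ones(delta_m.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    bad = mask & ~(m0 > 0)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"excluding {n_bad} voxels with non-positive M0 from the mask")
        mask = mask & ~bad
    values = np.zeros_like(delta_m)
    values[mask] = constants.scale * delta_m[mask] / m0[mask]
    return CBFMap(values=values, mask=mask, voxel_size_mm=voxel_size_mm)


def calibrate_rcbf(cbf_map: CBFMap, global_cbf: float) -> CBFMap:
    """Scale an rCBF map so its mask mean equals the PC global CBF.

    The single scalar factor absorbs subject-specific deviations of the
    labelling efficiency and arterial T1 from their assumed values; the
    spatial pattern is untouched (Pearson r with the input is 1).
    """
    mean = cbf_map.mean()
    if not mean > 0:
        raise ValueError("cannot calibrate a map with non-positive mask mean")
    scale = global_cbf / mean
    values = cbf_map.values * scale
    return CBFMap(values=values, mask=cbf_map.mask,
                  voxel_size_mm=cbf_map.voxel_size_mm,
                  calibrated=True,
                  calibration_scale=cbf_map.calibration_scale * scale)


def icc_test_retest(map1: CBFMap, map2: CBFMap) -> dict:
    """Test-retest ICC of two CBF maps over their shared mask.

    Uses the two-way random-effects, absolute-agreement, single-rater
    form ICC(2,1), treating voxels as targets and the two scans as
    repeated measurements, with the F-distribution-based 95% CI.
    """
    if not np.array_equal(map1.mask, map2.mask):
        raise ValueError("maps must share a mask")
    v1 = map1.masked
    v2 = map2.masked
    n = v1.size
    if n < 2:
        raise ValueError("ICC requires at least 2 voxels")
    import pingouin as pg

    long = pd.DataFrame({
        "voxel": np.tile(np.arange(n), 2),
        "scan": np.repeat(["scan1", "scan2"], n),
        "value": np.concatenate([v1, v2]),
    })
    if np.allclose(v1, v2):
        return {"icc": 1.0, "ci_low": 1.0, "ci_high": 1.0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(data=long, targets="voxel", raters="scan",
                                   ratings="value")
    row = table.set_index("Type").loc["ICC(A,1)"]  # two-way random, absolute
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci_low, ci_high = row[ci_col]
    return {"icc": float(row["ICC"]), "ci_low": float(ci_low),
            "ci_high": float(ci_high)}
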