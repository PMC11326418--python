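"""Synthetic infant perfusion cohort generator.

Emulates the statistical structure of an infant CBF developmental study:
ages spanning roughly 1.4-28 months, a global CBF trajectory that rises
logarithmically (or biphasically with a break near 10.75 months), and a
regional hierarchy of three voxel clusters - limbic, sensorimotor and
frontoparietal association - whose biphasic trajectories break at
progressively older ages (6.71, 7.69 and 10.36 months).  Each subject
additionally carries phase-contrast artery fluxes and a pCASL
control/label series constructed to be exactly consistent with the
quantification equations, a rigid-motion parameter table realising a
target mean relative displacement, and Bayley-like behaviour scores
(mean 100, SD 15) correlated with age-adjusted regional CBF.

The generator is deliberately simple where the real data are not: voxel
noise is i.i.d. Gaussian (optionally smoothed), head size enters only
through a deterministic brain-volume curve, and there is no MR physics
beyond the kinetic model itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .motion import MOTION_COLUMNS
from .quantify import ASLAcquisition, ASLConstants, CBFMap, PCMeasurement, RHO_DEFAULT

__all__ = [
    "TrajectoryParams",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_pc_measurement",
    "generate_asl_series",
    "generate_behavior_scores",
    "generate_reference_map",
    "GLOBAL_LOG_PARAMS",
    "GLOBAL_BIPHASIC_PARAMS",
    "DEFAULT_CLUSTER_PARAMS",
]

CLUSTER_NAMES = ("limbic", "sensorimotor", "frontoparietal")

#: global logarithmic trajectory: CBF = 16.38 ln(age) + 16.85
GLOBAL_LOG_PARAMS = {"beta": 16.38, "intercept": 16.85}


@dataclass(frozen=True)
class TrajectoryParams:
    """A continuous two-phase (biphasic) linear trajectory.

    ``level_at_break`` anchors the curve: value at the breakpoint age.
    Phase slopes are in ml/100g/min per month.
    """

    breakpoint: float
    slope1: float
    slope2: float
    level_at_break: float

    def curve(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        below = np.minimum(age, self.breakpoint) - self.breakpoint
        above = np.maximum(age, self.breakpoint) - self.breakpoint
        return self.level_at_break + self.slope1 * below + self.slope2 * above


def _log_curve(age):
    return GLOBAL_LOG_PARAMS["beta"] * np.log(age) + GLOBAL_LOG_PARAMS["intercept"]


#: global biphasic trajectory anchored to the logarithmic curve at the break
GLOBAL_BIPHASIC_PARAMS = TrajectoryParams(
    breakpoint=10.75, slope1=3.52, slope2=0.43,
    level_at_break=float(_log_curve(10.75)),
)

#: per-cluster biphasic trajectories.  Breakpoints follow the
#: limbic < sensorimotor < frontoparietal ordering; phase slopes and
#: levels are physiological choices (sensorimotor cortex is the most
#: perfused in infancy, limbic the least, association cortex rises the
#: latest), documented in the methods note.
DEFAULT_CLUSTER_PARAMS = {
    "limbic": TrajectoryParams(6.71, 3.0, 0.35, 44.0),
    "sensorimotor": TrajectoryParams(7.69, 3.8, 0.50, 62.0),
    "frontoparietal": TrajectoryParams(10.36, 3.3, 0.55, 53.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n_subjects: int = 76
    age_mean: float = 12.5
    age_sd: float = 7.1
    age_range: tuple = (1.4, 28.0)
    age_sampling: str = "truncnorm"  # or "uniform"
    grid_shape: tuple = (20, 24, 20)
    voxel_size_mm: float = 2.0
    cluster_fractions: tuple = (0.20, 0.35, 0.45)
    trajectory_family: str = "biphasic"  # global trajectory: or "logarithmic"
    cluster_params: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_PARAMS))
    residual_sd_global: float = 6.5   # ml/100g/min, subject-level; calibrated
                                      # so the logarithmic fit at n=119 gives
                                      # an age-CBF correlation near r=0.823
    residual_sd_voxel: float = 10.0   # ml/100g/min, marginal per-voxel SD
    # Decomposition of the voxel residual: subject-level global fluctuation
    # shared by every voxel (so the regional cohort's mask-mean CBF scatters
    # like the global cohort's), a subject-x-cluster regional fluctuation,
    # and an independent voxel component absorbing the remainder of the
    # marginal SD.  Real perfusion varies between subjects mostly through
    # such shared physiological state, not voxel-independent noise.
    sd_subject_global: float = 6.5
    sd_subject_regional: float = 4.0
    smoothing_fwhm_mm: float = 0.0    # optional spatial smoothing of the noise
    behavior_effect: float = 0.5
    behavior_effect_map: dict = field(default_factory=lambda: {
        "motor": "sensorimotor",
        "language": "frontoparietal",
        "cognitive": "limbic",
    })
    n_behavior: int = 49
    mrd_mean: float = 0.22
    mrd_sd: float = 0.13
    n_pairs: int = 10
    asl_noise_sd: float = 0.0
    asl_constants: ASLConstants = field(default_factory=ASLConstants)
    include_maps: bool = True
    include_asl: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if abs(sum(self.cluster_fractions) - 1.0) > 1e-9:
            raise ValueError("cluster fractions must sum to 1")
        if self.trajectory_family not in ("logarithmic", "biphasic"):
            raise ValueError(f"unknown trajectory family {self.trajectory_family!r}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        shared = self.sd_subject_global**2 + self.sd_subject_regional**2
        if shared > self.residual_sd_voxel**2:
            raise ValueError("shared noise components exceed the marginal "
                             "voxel SD")

    @classmethod
    def global_cohort(cls, **kw) -> "GeneratorConfig":
        """Conditions of the global-CBF analyses: n=119, no maps."""
        kw.setdefault("n_subjects", 119)
        kw.setdefault("include_maps", False)
        kw.setdefault("include_asl", False)
        return cls(**kw)


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    config: GeneratorConfig
    cohort_table: pd.DataFrame
    mask: np.ndarray | None = None
    truth_labels: np.ndarray | None = None   # 0-based cluster index, -1 outside mask
    truth_params: dict | None = None
    rcbf_maps: list | None = None            # per-subject CBFMap
    truth_maps: list | None = None           # noiseless per-subject CBFMap
    pc_fluxes: pd.DataFrame | None = None
    asl_series: list | None = None           # per-subject ASLAcquisition

    @property
    def ages(self) -> np.ndarray:
        return self.cohort_table["age_months"].to_numpy()

    def cluster_mask(self, name: str) -> np.ndarray:
        idx = CLUSTER_NAMES.index(name)
        return self.truth_labels == idx

    def cluster_mean_rcbf(self, name: str) -> np.ndarray:
        """Per-subject mean rCBF over a ground-truth cluster's voxels."""
        cmask = self.cluster_mask(name)
        return np.array([m.values[cmask].mean() for m in self.rcbf_maps])

    def data_matrix(self) -> np.ndarray:
        """Voxel x subject matrix of in-mask rCBF values (C order)."""
        return np.column_stack([m.masked for m in self.rcbf_maps])


def _sample_ages(cfg: GeneratorConfig, rng) -> np.ndarray:
    lo, hi = cfg.age_range
    if cfg.age_sampling == "uniform":
        return rng.uniform(lo, hi, cfg.n_subjects)
    a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    return stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                               size=cfg.n_subjects, random_state=rng)


def _brain_volume_ml(age) -> np.ndarray:
    # parenchyma volume growth: ~500 mL at 1 month to ~1090 mL at 28 months
    return 350.0 + 220.0 * np.log(np.asarray(age, dtype=float) + 1.0)


def make_brain_mask(grid_shape, gm_fraction_radii=(0.72, 0.78, 0.72)) -> np.ndarray:
    """Ellipsoidal gray-matter mask (~2,000 voxels on the default grid)."""
    nx, ny, nz = grid_shape
    radii = np.array(gm_fraction_radii) * np.array([nx, ny, nz]) / 2.0
    center = (np.array(grid_shape) - 1) / 2.0
    coords = np.indices(grid_shape).astype(float)
    r2 = sum(((coords[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def make_cluster_labels(mask: np.ndarray, fractions) -> np.ndarray:
    """Partition the mask into three radial shells by voxel count.

    Innermost shell = limbic (deep/medial), middle = sensorimotor,
    outer = frontoparietal association; shells give spatially contiguous
    clusters with exactly the requested voxel fractions (up to rounding).
    """
    center = (np.array(mask.shape) - 1) / 2.0
    coords = np.indices(mask.shape).astype(float)
    extent = np.array(mask.shape) / 2.0
    r2 = sum(((coords[i] - center[i]) / extent[i]) ** 2 for i in range(3))
    labels = np.full(mask.shape, -1, dtype=int)
    rv = r2[mask]
    order = np.argsort(rv, kind="stable")
    n = rv.size
    bounds = np.cumsum(np.round(np.asarray(fractions) * n).astype(int))
    bounds[-1] = n
    shell = np.empty(n, dtype=int)
    start = 0
    for k, b in enumerate(bounds):
        shell[order[start:b]] = k
        start = b
    labels[mask] = shell
    return labels


def _smooth_noise(noise: np.ndarray, mask: np.ndarray, fwhm_mm: float,
                  voxel_size_mm: float) -> np.ndarray:
    if fwhm_mm <= 0:
        return noise
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    sm = ndimage.gaussian_filter(noise, sigma)
    # restore the marginal SD so residual_sd keeps its meaning
    inside = sm[mask]
    if inside.std() > 0:
        sm = sm * (noise[mask].std() / inside.std())
    return sm


def generate_pc_measurement(target_global_cbf: float, brain_volume: float,
                            rng=None, rho: float = RHO_DEFAULT) -> PCMeasurement:
    """Four-artery flux table whose quantification returns the target.

    Total flux = target * rho * volume / 100, split across bilateral
    ICAs (~38% each) and VAs (~12% each) with mild seeded jitter.
    """
    if target_global_cbf < 0:
        raise ValueError("target global CBF must be non-negative")
    if not brain_volume > 0:
        raise ValueError("brain volume must be positive")
    total = target_global_cbf * rho * brain_volume / 100.0
    base = np.array([0.38, 0.38, 0.12, 0.12])
    if rng is not None:
        base = base * np.exp(rng.normal(0.0, 0.05, 4))
    shares = base / base.sum()
    return PCMeasurement(fluxes=total * shares, brain_volume=brain_volume, rho=rho)


def generate_asl_series(truth_map: CBFMap, constants: ASLConstants | None = None,
                        n_pairs: int = 10, m0_value: float = 1000.0,
                        noise_sd: float = 0.0, motion_profile=None,
                        rng=None) -> ASLAcquisition:
    """Control/label series consistent with the pCASL kinetic model.

    The mean control-minus-label difference equals the dM implied by the
    truth map; at zero noise quantification recovers the map exactly.
    ``motion_profile`` is an optional (2*n_pairs, 6) rigid-parameter
    array recorded in the acquisition's motion table.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    constants = constants or ASLConstants()
    mask = truth_map.mask
    if np.any(truth_map.values[mask] < 0):
        raise ValueError("truth map must be non-negative inside the mask")
    m0 = np.zeros(truth_map.values.shape)
    m0[mask] = m0_value
    delta_m = np.zeros_like(m0)
    delta_m[mask] = truth_map.values[mask] * m0_value / constants.scale
    control = np.broadcast_to(m0 + delta_m / 2.0, (n_pairs,) + m0.shape).copy()
    label = np.broadcast_to(m0 - delta_m / 2.0, (n_pairs,) + m0.shape).copy()
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        control += rng.normal(0.0, noise_sd, control.shape)
        label += rng.normal(0.0, noise_sd, label.shape)
    if motion_profile is None:
        motion_profile = np.zeros((2 * n_pairs, 6))
    motion = pd.DataFrame(np.asarray(motion_profile, dtype=float),
                          columns=MOTION_COLUMNS)
    return ASLAcquisition(control=control, label=label, m0=m0, mask=mask,
                          motion_params=motion)


def _motion_profile_for_mrd(target_mrd: float, n_volumes: int, rng) -> np.ndarray:
    """Random-walk translation table whose MRD equals the target exactly.

    Relative displacements of a pure translation are radius-independent,
    so the per-step translation magnitudes fully determine the MRD
    (volume 0 contributes 0 by convention).
    """
    steps = rng.gamma(shape=2.0, scale=1.0, size=n_volumes - 1)
    if n_volumes > 1:
        steps *= target_mrd * n_volumes / steps.sum()
    dirs = rng.normal(size=(n_volumes - 1, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    rel_t = dirs * steps[:, None]
    table = np.zeros((n_volumes, 6))
    table[1:, 3:] = np.cumsum(rel_t, axis=0)
    return table


def generate_behavior_scores(cohort_table: pd.DataFrame, rcbf_maps, truth_labels,
                             effect_map: dict, effect: float, n_behavior: int,
                             rng) -> pd.DataFrame:
    """Bayley-like standard scores (mean 100, SD 15) per domain.

    Each domain's score correlates (partially, given age) with the
    age-adjusted mean rCBF of its loaded cluster at the configured
    effect size.  Only ``n_behavior`` randomly chosen subjects receive
    scores; the rest are missing, mirroring incomplete assessment.
    """
    table = cohort_table.copy()
    n = len(table)
    ages = table["age_months"].to_numpy()
    design = np.column_stack([np.ones(n), np.log(ages)])
    have = np.sort(rng.choice(n, size=min(n_behavior, n), replace=False))
    for domain, cluster in effect_map.items():
        if cluster not in CLUSTER_NAMES:
            raise ValueError(f"unknown cluster {cluster!r} for domain {domain!r}")
        cmask = truth_labels == CLUSTER_NAMES.index(cluster)
        region = np.array([m.values[cmask].mean() for m in rcbf_maps])
        beta, *_ = np.linalg.lstsq(design, region, rcond=None)
        resid = region - design @ beta
        z = (resid - resid.mean()) / resid.std() if resid.std() > 0 else np.zeros(n)
        noise = rng.normal(size=n)
        latent = effect * z + np.sqrt(max(0.0, 1.0 - effect**2)) * noise
        scores = np.full(n, np.nan)
        scores[have] = 100.0 + 15.0 * latent[have]
        table[f"bayley_{domain}"] = scores
    return table


def generate_reference_map(truth_params: dict, labels: np.ndarray, mask: np.ndarray,
                           age: float = 28.0, noise_sd: float = 0.0,
                           voxel_size_mm: float = 2.0, rng=None) -> CBFMap:
    """Noiseless cluster-trajectory pattern at an adult-like age.

    Serves as a metabolism-like (CMRglc) reference topography for the
    spatial alignment analyses; units are irrelevant for correlation.
    """
    values = np.zeros(mask.shape)
    for k, name in enumerate(CLUSTER_NAMES):
        values[labels == k] = truth_params[name].curve(age)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise_sd, values.shape)
    values[~mask] = 0.0
    return CBFMap(values=values, mask=mask, voxel_size_mm=voxel_size_mm)


def generate_cohort(config: GeneratorConfig | None = None, **kw) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given the seed."""
    if config is None:
        config = GeneratorConfig(**kw)
    # independent child streams per component: toggling one component
    # (e.g. the ASL series) never perturbs the draws of another
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    rng, rng_maps, rng_flux, rng_asl, rng_beh = map(np.random.default_rng, seeds)
    n = config.n_subjects
    ages = np.sort(_sample_ages(config, rng))
    sex = rng.integers(0, 2, n)
    ses = np.clip(rng.normal(45.0, 12.0, n), 8.0, 66.0)
    a, b = (0.02 - config.mrd_mean) / config.mrd_sd, (0.5 - config.mrd_mean) / config.mrd_sd
    mrd_target = stats.truncnorm.rvs(a, b, loc=config.mrd_mean, scale=config.mrd_sd,
                                     size=n, random_state=rng)
    table = pd.DataFrame({
        "subject": [f"sub-{i:03d}" for i in range(n)],
        "age_months": ages,
        "sex": sex,
        "ses": ses,
        "mrd_mm": mrd_target,
    })

    mask = truth_labels = None
    rcbf_maps = truth_maps = asl_series = None
    truth_params = dict(config.cluster_params)

    if config.include_maps:
        mask = make_brain_mask(config.grid_shape)
        truth_labels = make_cluster_labels(mask, config.cluster_fractions)
        cluster_curves = np.column_stack([
            truth_params[name].curve(ages) for name in CLUSTER_NAMES])
        if config.residual_sd_voxel > 0:
            sd_g, sd_r = config.sd_subject_global, config.sd_subject_regional
            sd_eps = np.sqrt(config.residual_sd_voxel**2 - sd_g**2 - sd_r**2)
        else:
            sd_g = sd_r = sd_eps = 0.0
        n_clusters = len(CLUSTER_NAMES)
        subj_global = rng_maps.normal(0.0, sd_g, n) if sd_g > 0 else np.zeros(n)
        subj_regional = (rng_maps.normal(0.0, sd_r, (n, n_clusters))
                         if sd_r > 0 else np.zeros((n, n_clusters)))
        rcbf_maps, truth_maps = [], []
        for i in range(n):
            values = np.zeros(config.grid_shape)
            shared = np.zeros(config.grid_shape)
            for k in range(n_clusters):
                sel = truth_labels == k
                values[sel] = cluster_curves[i, k]
                shared[sel] = subj_global[i] + subj_regional[i, k]
            truth_maps.append(CBFMap(values=values.copy(), mask=mask,
                                     voxel_size_mm=config.voxel_size_mm))
            if sd_eps > 0:
                noise = rng_maps.normal(0.0, sd_eps, config.grid_shape)
                noise = _smooth_noise(noise, mask, config.smoothing_fwhm_mm,
                                      config.voxel_size_mm)
            else:
                noise = 0.0
            noisy = np.maximum(values + shared + noise, 0.1)
            noisy[~mask] = 0.0
            rcbf_maps.append(CBFMap(values=noisy, mask=mask,
                                    voxel_size_mm=config.voxel_size_mm))
        global_cbf = np.array([m.mean() for m in rcbf_maps])
    else:
        if config.trajectory_family == "logarithmic":
            mean = _log_curve(ages)
        else:
            mean = GLOBAL_BIPHASIC_PARAMS.curve(ages)
        global_cbf = mean + rng_maps.normal(0.0, config.residual_sd_global, n)

    table["global_cbf"] = global_cbf

    volumes = _brain_volume_ml(ages)
    flux_rows = []
    for i in range(n):
        pc = generate_pc_measurement(global_cbf[i], volumes[i], rng=rng_flux)
        flux_rows.append(list(pc.fluxes) + [pc.brain_volume])
    pc_fluxes = pd.DataFrame(
        flux_rows,
        columns=["flux_ica_l", "flux_ica_r", "flux_va_l", "flux_va_r",
                 "brain_volume_ml"])
    pc_fluxes.insert(0, "subject", table["subject"])

    if config.include_maps and config.include_asl:
        asl_series = []
        for i in range(n):
            profile = _motion_profile_for_mrd(mrd_target[i], 2 * config.n_pairs, rng_asl)
            asl_series.append(generate_asl_series(
                rcbf_maps[i], constants=config.asl_constants,
                n_pairs=config.n_pairs, noise_sd=config.asl_noise_sd,
                motion_profile=profile, rng=rng_asl))

    if config.include_maps:
        table = generate_behavior_scores(
            table, rcbf_maps, truth_labels, config.behavior_effect_map,
            config.behavior_effect, config.n_behavior, rng_beh)

    return SyntheticCohort(config=config, cohort_table=table, mask=mask,
                           truth_labels=truth_labels, truth_params=truth_params,
                           rcbf_maps=rcbf_maps, truth_maps=truth_maps,
                           pc_fluxes=pc_fluxes, asl_series=asl_series)
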