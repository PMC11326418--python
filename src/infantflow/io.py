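"""Standard-format I/O and pipeline orchestration.

NIfTI volumes for maps, masks and label images (affines carry the voxel
size; masks are uint8), TSV for tabular outputs, YAML for configuration
and JSON for reports.  ``run_pipeline`` chains the analysis stages on a
synthetic cohort: quantification consistency, motion QC, trajectory
modelling, segmented regression, parcellation, spatial alignment and
behaviour association, writing a provenance manifest with the seed and
configuration used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import behavior, cohort, motion, parcellation, quantify, segmented, spatial, trajectory

__all__ = [
    "save_map",
    "load_map",
    "save_labels",
    "save_table",
    "load_table",
    "save_config",
    "load_config",
    "run_pipeline",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_map(cbf_map: quantify.CBFMap, path, dtype=np.float64) -> None:
    img = nib.Nifti1Image(cbf_map.values.astype(dtype),
                          _affine(cbf_map.voxel_size_mm))
    nib.save(img, str(path))
    mask_img = nib.Nifti1Image(cbf_map.mask.astype(np.uint8),
                               _affine(cbf_map.voxel_size_mm))
    nib.save(mask_img, str(Path(path).with_suffix("").with_suffix("")) + "_mask.nii.gz")


def load_map(path, mask_path=None) -> quantify.CBFMap:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    voxel = float(img.header.get_zooms()[0])
    if mask_path is None:
        guess = str(Path(path).with_suffix("").with_suffix("")) + "_mask.nii.gz"
        mask_path = guess if Path(guess).exists() else None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != values.shape:
            raise ValueError("map/mask grid mismatch")
    else:
        mask = np.ones(values.shape, dtype=bool)
    return quantify.CBFMap(values=values, mask=mask, voxel_size_mm=voxel)


def save_labels(labels: np.ndarray, voxel_size_mm: float, path) -> None:
    img = nib.Nifti1Image(labels.astype(np.int16), _affine(voxel_size_mm))
    nib.save(img, str(path))


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _config_dict(cfg) -> dict:
    out = dataclasses.asdict(cfg)
    # dataclass values that YAML cannot hold directly
    out["cluster_params"] = {k: dataclasses.asdict(v)
                             for k, v in cfg.cluster_params.items()}
    out["asl_constants"] = dataclasses.asdict(cfg.asl_constants)
    return out


def save_config(cfg: cohort.GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=True)


def load_config(path) -> cohort.GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["cluster_params"] = {k: cohort.TrajectoryParams(**v)
                             for k, v in raw["cluster_params"].items()}
    raw["asl_constants"] = quantify.ASLConstants(**raw["asl_constants"])
    for key in ("age_range", "grid_shape", "cluster_fractions"):
        raw[key] = tuple(raw[key])
    return cohort.GeneratorConfig(**raw)


def _manifest_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: cohort.GeneratorConfig | None = None,
                 out_dir=None, seed: int | None = None,
                 n_perm: int = 1000, k_range=range(2, 8)) -> dict:
    """End-to-end analysis of a synthetic cohort.

    Generates the cohort, verifies quantification consistency, runs
    motion QC, voxel-wise trajectory models, segmented regression on
    global and per-cluster CBF, opNMF parcellation with K selection,
    spatial alignment against the reference topography, and the
    behaviour association, returning a result bundle (and writing
    outputs plus a provenance manifest when ``out_dir`` is given).
    """
    if config is None:
        config = cohort.GeneratorConfig(seed=seed if seed is not None else 0)
    elif seed is not None:
        config = dataclasses.replace(config, seed=seed)
    syn = cohort.generate_cohort(config)
    table = syn.cohort_table
    ages = syn.ages
    results: dict = {"config": config, "cohort": syn}

    # quantification round trip on the first subject
    pc_row = syn.pc_fluxes.iloc[0]
    pc = quantify.PCMeasurement(
        fluxes=pc_row[["flux_ica_l", "flux_ica_r", "flux_va_l", "flux_va_r"]].to_numpy(),
        brain_volume=float(pc_row["brain_volume_ml"]))
    results["global_cbf_check"] = abs(
        quantify.global_cbf_from_pc(pc) - table["global_cbf"].iloc[0])

    # motion QC
    qc_rows = []
    if syn.asl_series is not None:
        for sid, acq in zip(table["subject"], syn.asl_series):
            rep = motion.motion_qc_report(motion.MotionSeries(acq.motion_params))
            qc_rows.append({"subject": sid, "mrd_mm": rep["mrd"],
                            "n_retained": len(rep["retained_volumes"]),
                            "excluded": rep["excluded"]})
    qc = pd.DataFrame(qc_rows)
    results["motion_qc"] = qc

    # global trajectory model selection + segmented regression
    model_set = trajectory.fit_candidate_models(ages, table["global_cbf"].to_numpy())
    results["model_selection"] = model_set.summary()
    results["global_segmented"] = segmented.select_n_breakpoints(
        ages, table["global_cbf"].to_numpy())

    # voxel-wise age effects and fitted stack
    covars = pd.DataFrame({"sex": table["sex"], "motion": table["mrd_mm"]})
    data = syn.data_matrix()
    effects = trajectory.voxelwise_age_effects(
        data, ages, covariates=covars, mask=syn.mask,
        voxel_size_mm=config.voxel_size_mm)
    results["effects"] = effects
    thr = trajectory.bonferroni_threshold(0.05, data.shape[0])
    results["bonferroni"] = thr
    stack = trajectory.predict_map_stack(effects)
    results["stack"] = stack

    # per-cluster segmented fits
    cluster_fits = {}
    for name in cohort.CLUSTER_NAMES:
        cluster_fits[name] = segmented.fit_segmented(
            ages, syn.cluster_mean_rcbf(name), n_breakpoints=1)
    results["cluster_segmented"] = cluster_fits

    # parcellation
    ksel = parcellation.select_k(data, k_range=k_range)
    results["k_selection"] = ksel
    parcel = parcellation.opnmf_fit(data, ksel.chosen_k)
    results["parcellation"] = parcel

    # spatial alignment against the adult-like reference
    ref = cohort.generate_reference_map(syn.truth_params, syn.truth_labels,
                                        syn.mask, age=28.0)
    ages_grid, r_curve = spatial.alignment_trajectory(stack, ref)
    results["alignment"] = (ages_grid, r_curve)
    results["alignment_p_final"] = spatial.permutation_pvalue(
        stack.maps[-1], ref.masked, n_perm=n_perm, seed=config.seed).p_value

    # behaviour association on complete cases
    comp = behavior.complete_cases(
        table.assign(row=np.arange(len(table))),
        ["bayley_motor", "ses"])
    rows = comp["row"].to_numpy()
    assoc = behavior.cluster_level_assoc(
        syn.cluster_mean_rcbf("sensorimotor")[rows],
        comp["bayley_motor"].to_numpy(), comp["age_months"].to_numpy(),
        sex=comp["sex"].to_numpy(), motion=comp["mrd_mm"].to_numpy(),
        ses=comp["ses"].to_numpy())
    results["behavior_motor_sensorimotor"] = {
        k: assoc[k] for k in ("t", "p", "threshold", "significant")}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_table(table, out / "cohort.tsv")
        save_table(syn.pc_fluxes, out / "pc_fluxes.tsv")
        if len(qc):
            save_table(qc, out / "motion_qc.tsv")
        save_config(config, out / "config.yaml")
        save_labels(syn.truth_labels, config.voxel_size_mm,
                    out / "truth_labels.nii.gz")
        zmap = quantify.CBFMap(values=effects.to_volume("z"), mask=syn.mask,
                               voxel_size_mm=config.voxel_size_mm)
        save_map(zmap, out / "age_effect_z.nii.gz")
        results["model_selection"].to_csv(out / "model_selection.tsv", sep="\t")
        ksel.table.to_csv(out / "k_selection.tsv", sep="\t")
        manifest = {
            "seed": config.seed,
            "config_hash": _manifest_hash(_config_dict(config)),
            "n_subjects": config.n_subjects,
            "chosen_k": ksel.chosen_k,
            "best_family": str(results["model_selection"].index[0]),
            "global_breakpoints": results["global_segmented"].psi.tolist(),
        }
        manifest["manifest_hash"] = _manifest_hash(manifest)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        results["manifest"] = manifest
    return results
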