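"""Brain-behaviour GAM association, cluster-extent thresholding and the
domain-by-parcel river summary."""

import numpy as np
import pytest

from infantflow import behavior
from infantflow.behavior import (VoxelCluster, behavior_river_summary,
                                 cluster_level_assoc, complete_cases,
                                 extract_clusters, fit_gam_behavior,
                                 voxelwise_behavior_tmap)


def sim_dataset(rng, n=49, effect=0.0):
    age = np.sort(rng.uniform(1.4, 28, n))
    sex = rng.integers(0, 2, n)
    mot = rng.uniform(0.05, 0.5, n)
    ses = rng.normal(45, 12, n)
    resid = rng.normal(0, 1, n)
    score = 100 + 15 * (effect * resid
                        + np.sqrt(1 - effect**2) * rng.normal(0, 1, n))
    y = 15 * np.log(age) + 20 + 6 * resid
    return y, score, age, sex, mot, ses


class TestGAMFit:
    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(0)
        # select the smoothing weight once; reuse across simulations
        y, s, a, sx, m, se = sim_dataset(rng)
        alpha = fit_gam_behavior(y, s, a, sx, m, se).alpha
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            y, s, a, sx, m, se = sim_dataset(rng)
            fit = fit_gam_behavior(y, s, a, sx, m, se, alpha=alpha)
            hits += abs(fit.t_score) > 2.02
        assert 0.02 <= hits / n_sim <= 0.09

    def test_loaded_effect_t_magnitude(self):
        # r = 0.5 at ~43 residual df implies |t| around 3.7 on average
        rng = np.random.default_rng(1)
        ts = []
        for _ in range(25):
            y, s, a, sx, m, se = sim_dataset(rng, effect=0.5)
            ts.append(abs(fit_gam_behavior(y, s, a, sx, m, se,
                                           alpha=20.0).t_score))
        assert 2.8 < np.mean(ts) < 4.8

    def test_spline_absorbs_log_age(self):
        # with a purely logarithmic age effect and a null score, the GAM
        # score t should track the oracle that knows the log form
        rng = np.random.default_rng(2)
        gam_ts, oracle_ts = [], []
        for _ in range(25):
            y, s, a, sx, m, se = sim_dataset(rng)
            gam_ts.append(fit_gam_behavior(y, s, a, sx, m, se).t_score)
            X = np.column_stack([np.ones(len(a)), s, np.log(a), sx, m, se])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = len(a) - X.shape[1]
            cov = (resid @ resid) / dof * np.linalg.inv(X.T @ X)
            oracle_ts.append(beta[1] / np.sqrt(cov[1, 1]))
        gam_ts, oracle_ts = np.asarray(gam_ts), np.asarray(oracle_ts)
        # the data-driven smooth costs a little efficiency, so the two t
        # series agree closely but not to arbitrary precision
        assert np.mean(np.abs(gam_ts - oracle_ts)) < 0.5
        assert np.corrcoef(gam_ts, oracle_ts)[0, 1] > 0.9

    def test_large_penalty_approaches_linear_age_model(self):
        rng = np.random.default_rng(3)
        y, s, a, sx, m, se = sim_dataset(rng)
        gam_t = fit_gam_behavior(y, s, a, sx, m, se, alpha=1e9).t_score
        X = np.column_stack([np.ones(len(a)), s, a, sx, m, se])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        cov = (resid @ resid) / (len(a) - 6) * np.linalg.inv(X.T @ X)
        lin_t = beta[1] / np.sqrt(cov[1, 1])
        assert gam_t == pytest.approx(lin_t, abs=0.3)

    def test_preconditions(self):
        rng = np.random.default_rng(4)
        y, s, a, sx, m, se = sim_dataset(rng, n=10)
        with pytest.raises(ValueError, match="at least 15"):
            fit_gam_behavior(y, s, a, sx, m, se)
        y, s, a, sx, m, se = sim_dataset(rng, n=30)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_gam_behavior(y, s, a, sex=s, motion=m, ses=se)


class TestVoxelwiseTmap:
    def test_loaded_cluster_enriched(self, regional_cohort):
        syn = regional_cohort
        t = syn.cohort_table
        comp = complete_cases(t.assign(row=np.arange(len(t))),
                              ["bayley_motor", "ses"])
        rows = comp["row"].to_numpy()
        labels = syn.truth_labels[syn.mask]
        data = syn.data_matrix()[:, rows]
        # subsample voxels for runtime; keep the cluster identity
        keep = np.sort(np.concatenate([
            np.flatnonzero(labels == k)[::8] for k in range(3)]))
        out = voxelwise_behavior_tmap(
            data[keep], comp["bayley_motor"].to_numpy(),
            comp["age_months"].to_numpy(), sex=comp["sex"].to_numpy(),
            motion=comp["mrd_mm"].to_numpy(), ses=comp["ses"].to_numpy())
        tvals = out["t"]
        in_loaded = labels[keep] == 1      # motor loads the sensorimotor cluster
        assert np.nanmean(tvals[in_loaded]) > np.nanmean(tvals[~in_loaded])

    def test_null_scores_rarely_suprathreshold(self):
        rng = np.random.default_rng(5)
        n = 40
        age = np.sort(rng.uniform(1.4, 28, n))
        data = rng.normal(60, 8, (60, n)) + 10 * np.log(age)
        score = rng.normal(100, 15, n)
        out = voxelwise_behavior_tmap(data, score, age)
        rate = np.mean(np.abs(out["t"]) > 2.02)
        assert rate < 0.15


def flood_fill_oracle(mask3d):
    """Brute-force 26-connected component labelling."""
    visited = np.zeros(mask3d.shape, bool)
    comps = []
    idx = np.argwhere(mask3d)
    for start in map(tuple, idx):
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        q = (p[0] + dx, p[1] + dy, p[2] + dz)
                        if (0 <= q[0] < mask3d.shape[0]
                                and 0 <= q[1] < mask3d.shape[1]
                                and 0 <= q[2] < mask3d.shape[2]
                                and mask3d[q] and not visited[q]):
                            visited[q] = True
                            stack.append(q)
        comps.append(set(comp))
    return comps


class TestExtractClusters:
    def test_extent_threshold_separates_blobs(self):
        t = np.zeros((10, 10, 10))
        t[0:5, 0:5, 0:5] = 3.0        # 125 voxels
        t[7:10, 7:10, 7:10] = 3.0     # 27 voxels
        out = extract_clusters(t, t_threshold=2.02, min_extent=100)
        assert len(out) == 1
        assert out[0].size == 125
        assert out[0].volume_mm3 == 125 * 8.0

    def test_minimum_extent_boundary(self):
        t = np.zeros((12, 12, 12))
        blob = np.argwhere(np.ones((5, 5, 5)))[:101]
        t[tuple(blob.T)] = 5.0
        t[10, 10, 10] = 5.0           # singleton, below extent
        out = extract_clusters(t, min_extent=101)
        assert len(out) == 1 and out[0].size == 101

    def test_all_zero_map_gives_empty_list(self):
        assert extract_clusters(np.zeros((5, 5, 5))) == []

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(6)
        t = rng.normal(0, 1.5, (8, 8, 8))
        got = extract_clusters(t, t_threshold=1.0, min_extent=1)
        oracle = flood_fill_oracle(t > 1.0)
        got_sets = sorted((frozenset(map(tuple, c.indices)) for c in got),
                          key=len)
        oracle_sets = sorted(map(frozenset, oracle), key=len)
        assert got_sets == oracle_sets

    def test_connectivity_matters(self):
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = t[1, 1, 1] = 3.0   # diagonal neighbours
        assert len(extract_clusters(t, min_extent=1, connectivity=26)) == 1
        assert len(extract_clusters(t, min_extent=1, connectivity=6)) == 2

    def test_parcel_annotation_and_errors(self):
        t = np.zeros((4, 4, 4))
        t[:2] = 3.0
        labels = np.zeros((4, 4, 4), int)
        labels[:2] = 2
        out = extract_clusters(t, min_extent=1, parcel_labels=labels)
        assert out[0].parcel_label == 2
        with pytest.raises(ValueError):
            extract_clusters(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            extract_clusters(t, connectivity=10)


class TestClusterLevel:
    def test_threshold_is_bonferroni_over_domains(self):
        rng = np.random.default_rng(7)
        y, s, a, sx, m, se = sim_dataset(rng, effect=0.6)
        out = cluster_level_assoc(y + 0.4 * (s - 100), s, a, sx, m, se)
        assert out["threshold"] == pytest.approx(0.05 / 3)
        assert out["significant"] == (out["p"] < 0.0167)

    def test_loaded_cluster_power(self, regional_cohort):
        syn = regional_cohort
        t = syn.cohort_table
        comp = complete_cases(t.assign(row=np.arange(len(t))),
                              ["bayley_motor", "ses"])
        rows = comp["row"].to_numpy()
        out = cluster_level_assoc(
            syn.cluster_mean_rcbf("sensorimotor")[rows],
            comp["bayley_motor"].to_numpy(), comp["age_months"].to_numpy(),
            sex=comp["sex"].to_numpy(), motion=comp["mrd_mm"].to_numpy(),
            ses=comp["ses"].to_numpy())
        assert out["significant"]


class TestRiverSummary:
    def _cluster(self, indices):
        idx = np.asarray(indices)
        return VoxelCluster(indices=idx, size=len(idx),
                            volume_mm3=8.0 * len(idx), peak_t=3.0)

    def test_single_domain_single_parcel(self):
        labels = np.zeros((4, 4, 4), int)
        cl = self._cluster([[0, 0, 0], [1, 1, 1]])
        table = behavior_river_summary({"motor": [cl]}, labels)
        assert table.loc["motor"].tolist() == [1.0]

    def test_split_between_parcels(self):
        labels = np.zeros((4, 4, 4), int)
        labels[2:] = 1
        idx = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0]]   # 3 vs 1
        table = behavior_river_summary({"motor": [self._cluster(idx)]}, labels)
        assert table.loc["motor"].tolist() == pytest.approx([0.75, 0.25])
        assert table.sum(axis=1).tolist() == pytest.approx([1.0])

    def test_empty_domain_flagged_not_normalised(self):
        labels = np.zeros((2, 2, 2), int)
        table = behavior_river_summary({"cognitive": []}, labels)
        assert np.isnan(table.loc["cognitive"]).all()


class TestCompleteCases:
    def test_listwise_deletion(self, regional_cohort):
        t = regional_cohort.cohort_table
        comp = complete_cases(t, ["bayley_motor", "bayley_language", "ses"])
        assert len(comp) == 49
        assert comp["bayley_motor"].notna().all()
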