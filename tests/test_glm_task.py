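"""Design construction, OLS, contrasts, and cluster-extent inference."""

import numpy as np
import pandas as pd
import pytest

from avihrf.behavior import GO, NOGO, TrialOutcome
from avihrf.glm_task import (
    build_design_matrix,
    cluster_threshold,
    contrast_vector,
    contrast_z,
    convolve_to_tr,
    first_level_clusters,
    fit_glm,
    group_level,
    task_condition_events,
)
from avihrf.hrf_core import canonical_params, hrf_response
from avihrf.preprocess_qc import BOLDSeries, MotionTrace


def _trials(labels, spacing=24.0, start=20.0):
    rows, outcomes = [], []
    for i, lab in enumerate(labels):
        onset = start + i * spacing
        tt = GO if lab in ("hit", "miss") else NOGO
        rows.append((onset, 2.0, tt))
        rt = 0.8 if lab in ("hit", "fa") else None
        outcomes.append(TrialOutcome(i, onset, tt, lab, rt, int(rt is not None)))
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]), outcomes


def _motion(n, seed=0):
    rng = np.random.default_rng(seed)
    return MotionTrace(rotations=rng.normal(0, 1e-4, (n, 3)),
                       translations=rng.normal(0, 1e-3, (n, 3)))


class TestConditionEvents:
    def test_hit_trial_epochs(self):
        ev, out = _trials(["hit"])
        cond = task_condition_events(ev, out, [])
        d = {r.trial_type: (r.onset, r.duration) for r in cond.itertuples()}
        assert d["hit"] == (20.0, 2.0)
        assert d["reward"] == (22.8, 1.0)  # 0.8 s after stimulus offset
        assert d["post_reward"] == (23.8, 4.0)  # 4 s after reward offset
    def test_nogo_post_window(self):
        ev, out = _trials(["cr"])
        cond = task_condition_events(ev, out, [])
        d = {r.trial_type: (r.onset, r.duration) for r in cond.itertuples()}
        assert d["post_reward"] == (22.0, 5.0)  # 5 s after NoGo offset

    def test_mandibulation_restricted_to_rest_and_iti(self):
        ev, out = _trials(["hit", "cr"])
        # events: inside stimulus, inside post-reward, in ITI, in rest
        cond = task_condition_events(ev, out, [20.5, 25.0, 35.0, 5.0])
        mandib = cond[cond["trial_type"] == "mandibulation"]["onset"].tolist()
        assert mandib == [5.0, 35.0]


class TestDesignMatrix:
    def test_column_count_with_all_types_present(self):
        ev, out = _trials(["hit", "miss", "cr", "fa"])
        X = build_design_matrix(ev, out, [5.0], _motion(60), canonical_params("pigeon"),
                                TR=2.0, n_volumes=60)
        assert X.matrix.shape == (60, 7 + 6 + 1)
        assert X.dropped == []

    def test_absent_types_dropped_and_flagged(self):
        ev, out = _trials(["hit", "hit"])
        X = build_design_matrix(ev, out, [], _motion(50), canonical_params("pigeon"),
                                TR=2.0, n_volumes=50)
        assert set(X.dropped) == {"miss", "cr", "fa", "mandibulation"}
        assert np.linalg.matrix_rank(X.matrix) == X.matrix.shape[1]

    def test_single_event_regressor_matches_response(self):
        p = canonical_params("pigeon")
        reg = convolve_to_tr([8.0], [2.0], p, TR=2.0, n_volumes=30, dt=0.01)
        ref = hrf_response(p, stim_duration=2.0, dt=0.01, t_max=44.0)
        expected = np.interp(2.0 * np.arange(30) - 8.0, ref.times, ref.values,
                             left=0.0)
        np.testing.assert_allclose(reg, expected, atol=1e-3)

    def test_motion_columns_demeaned(self):
        ev, out = _trials(["hit", "cr"])
        X = build_design_matrix(ev, out, [], _motion(40), canonical_params("pigeon"),
                                TR=2.0, n_volumes=40)
        for name in ("rot_x", "trans_z"):
            assert X.column(name).mean() == pytest.approx(0.0, abs=1e-12)

    def test_motion_length_mismatch_rejected(self):
        ev, out = _trials(["hit"])
        with pytest.raises(ValueError):
            build_design_matrix(ev, out, [], _motion(10), canonical_params("pigeon"),
                                TR=2.0, n_volumes=40)


class TestOLS:
    def _design(self, n=60):
        ev, out = _trials(["hit", "miss", "cr", "fa"])
        return build_design_matrix(ev, out, [5.0], _motion(n),
                                   canonical_params("pigeon"), TR=2.0, n_volumes=n)

    def test_noiseless_beta_recovery(self):
        X = self._design()
        rng = np.random.default_rng(1)
        true_beta = rng.normal(0, 2, X.matrix.shape[1])
        y = X.matrix @ true_beta
        series = BOLDSeries(data=np.tile(y, (2, 2, 1, 1)), TR=2.0)
        fit = fit_glm(series, X)
        np.testing.assert_allclose(fit.betas[0, 0, 0], true_beta, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        X = self._design()
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, (5, X.n_volumes))
        series = BOLDSeries(data=Y.reshape(5, 1, 1, -1), TR=2.0)
        fit = fit_glm(series, X)
        M = X.matrix
        oracle = np.linalg.solve(M.T @ M, M.T @ Y.T).T
        np.testing.assert_allclose(fit.betas.reshape(5, -1), oracle, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        X = self._design()
        rng = np.random.default_rng(3)
        series = BOLDSeries(data=rng.normal(0, 1, (3, 3, 1, X.n_volumes)), TR=2.0)
        fit = fit_glm(series, X)
        assert np.abs(X.matrix.T @ fit.residuals).max() < 1e-6

    def test_matches_nilearn_first_level_oracle(self):
        """Betas and t statistics agree with nilearn's OLS on the same
        design matrix and data (independent reference implementation)."""
        from nilearn.glm.first_level import run_glm

        X = self._design()
        rng = np.random.default_rng(17)
        Y = rng.normal(100, 2, (6, X.n_volumes))
        series = BOLDSeries(data=Y.reshape(6, 1, 1, -1), TR=2.0)
        fit = fit_glm(series, X)
        labels, results = run_glm(Y.T, X.matrix, noise_model="ols")
        res = results[labels[0]]
        np.testing.assert_allclose(fit.betas.reshape(6, -1).T, res.theta, atol=1e-8)
        c = contrast_vector(X, "nogo_gt_go")
        t_mine = (fit.betas.reshape(6, -1) @ c) / np.sqrt(
            (c @ fit.xtx_inv @ c) * fit.sigma2.ravel()
        )
        t_ref = res.Tcontrast(c).t.ravel()
        np.testing.assert_allclose(t_mine, t_ref, atol=1e-8)

    def test_collinear_design_names_columns(self):
        X = self._design()
        M = np.column_stack([X.matrix, X.matrix[:, 0]])
        from avihrf.glm_task import DesignMatrix

        bad = DesignMatrix(matrix=M, names=X.names + ["dup"], TR=2.0, hrf=X.hrf)
        series = BOLDSeries(
            data=np.zeros((2, 1, 1, X.n_volumes)) + np.arange(X.n_volumes), TR=2.0
        )
        with pytest.raises(ValueError, match="rank"):
            fit_glm(series, bad)


class TestContrasts:
    def _fit(self, seed=0, n=80):
        ev, out = _trials(["hit", "miss", "cr", "fa"])
        X = build_design_matrix(ev, out, [5.0], _motion(n),
                                canonical_params("pigeon"), TR=2.0, n_volumes=n)
        rng = np.random.default_rng(seed)
        series = BOLDSeries(data=rng.normal(100, 1, (4, 4, 2, n)), TR=2.0)
        return fit_glm(series, X), X

    def test_zero_contrast_gives_zero_z(self):
        fit, X = self._fit()
        z = contrast_z(fit, np.zeros(len(X.names)))
        np.testing.assert_allclose(z, 0.0)

    def test_presets_resolve_to_expected_weights(self):
        _, X = self._fit()
        c = contrast_vector(X, "go_gt_nogo_plus_mandibulation")
        d = dict(zip(X.names, c))
        assert d["hit"] == d["miss"] == 0.5
        assert d["cr"] == d["fa"] == d["mandibulation"] == pytest.approx(-1 / 3)
        assert d["reward"] == d["post_reward"] == 0.0
        assert contrast_vector(X, "nogo_gt_go")[X.names.index("cr")] == 0.5
        assert contrast_vector(X, "mandibulation_gt_rest")[
            X.names.index("mandibulation")
        ] == 1.0

    def test_unknown_preset_rejected(self):
        _, X = self._fit()
        with pytest.raises(ValueError, match="unknown contrast"):
            contrast_vector(X, "reward_gt_everything")

    def test_null_tail_calibrated(self):
        # P(z > 3.1) under the null ~ 0.001; Monte-Carlo over 20 seeds
        count, total = 0, 0
        for seed in range(20):
            fit, X = self._fit(seed=seed)
            z = contrast_z(fit, "go_gt_nogo_plus_mandibulation")
            count += (z > 3.1).sum()
            total += z.size
        rate = count / total
        assert rate < 0.01  # loose binomial bound around 0.001 at n = 640

    def test_invariant_to_grand_mean_scaling(self):
        fit, X = self._fit(seed=7)
        from dataclasses import replace

        rng = np.random.default_rng(7)
        data = rng.normal(100, 1, (4, 4, 2, X.n_volumes))
        s1 = BOLDSeries(data=data, TR=2.0)
        s2 = BOLDSeries(data=3.0 * data, TR=2.0)
        z1 = contrast_z(fit_glm(s1, X), "nogo_gt_go")
        z2 = contrast_z(fit_glm(s2, X), "nogo_gt_go")
        np.testing.assert_allclose(z1, z2, atol=1e-8)


class TestClusterInference:
    def test_subthreshold_map_yields_no_clusters(self, rng):
        zmap = rng.normal(0, 1, (8, 8, 2))
        res = cluster_threshold(zmap, z_min=3.1, null_max_sizes=np.array([1, 2, 3]))
        assert res.clusters == []

    def test_critical_extent_monotone_in_alpha(self, rng):
        null = rng.integers(1, 40, size=999)
        zmap = np.zeros((4, 4, 2))
        prev = None
        for alpha in (0.01, 0.05, 0.2):
            res = cluster_threshold(zmap, 3.1, alpha=alpha, null_max_sizes=null)
            if prev is not None:
                assert res.critical_extent <= prev
            prev = res.critical_extent

    def test_blob_survives_single_voxel_spikes_do_not(self, small_session):
        from avihrf.behavior import classify_trials, detect_mandibulations
        from avihrf.preprocess_qc import (
            gaussian_smooth,
            grand_mean_scale,
            highpass_filter,
        )

        b = small_session
        det = detect_mandibulations(b.piezo)
        out = classify_trials(b.events, det)
        s = gaussian_smooth(b.bold, 0.8)
        s = grand_mean_scale(s)
        s = highpass_filter(s, 60.0)
        X = build_design_matrix(b.events, out, det, b.motion, b.truth["hrf"],
                                s.TR, s.n_volumes)
        fit = fit_glm(s, X)
        res = first_level_clusters(fit, "task_gt_rest", n_permutations=500, seed=4)
        assert len(res.clusters) >= 1
        truth = b.truth["active_mask"]
        detected = np.zeros_like(truth)
        for cl in res.clusters:
            detected[tuple(cl.voxels.T)] = True
        jaccard = (detected & truth).sum() / (detected | truth).sum()
        assert jaccard >= 0.5
        # isolated suprathreshold noise voxels are below the critical extent
        assert res.critical_extent > 1

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_threshold(rng.normal(size=(4, 4, 2)), 3.1,
                              n_permutations=100, null_source=lambda r: None)


class TestGroupLevel:
    def test_identical_subject_maps_cap_z(self):
        base = np.zeros((6, 6, 2))
        base[2:4, 2:4, :] = 1.0
        maps = np.stack([base] * 5)
        res = group_level(maps, n_permutations=500, seed=0)
        from avihrf.glm_task import Z_CAP

        assert res.zmap.max() == Z_CAP

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_level(np.zeros((2, 4, 4, 2)))

    def test_power_at_cohort_size(self):
        # subject maps = truth effect + independent noise at n = 8:
        # active-region detection in >= 80% of replicates
        truth = np.zeros((10, 10, 2))
        truth[3:7, 3:7, :] = 1.0
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            maps = truth + rng.normal(0, 0.45, (8, 10, 10, 2))
            res = group_level(maps, n_permutations=500, seed=1)
            detected = np.zeros_like(truth, dtype=bool)
            for cl in res.clusters:
                detected[tuple(cl.voxels.T)] = True
            if (detected & (truth > 0)).sum() >= 0.5 * (truth > 0).sum():
                hits += 1
        assert hits / n_rep >= 0.8

    def test_signflip_null_fwe_calibrated(self):
        """200 pure-null group datasets: fraction with any surviving cluster
        stays within the 3-sigma binomial band around alpha = 0.05.

        A cluster-forming threshold of z = 2.0 is used so the null
        max-cluster-size distribution is non-degenerate on this grid; the
        integer-valued cluster sizes make the test mildly conservative
        (achieved FWE below alpha), which the band accommodates.
        """
        rng = np.random.default_rng(5)
        n_datasets, rejections = 200, 0
        for i in range(n_datasets):
            maps = rng.normal(0, 1, (8, 12, 12, 3))
            res = group_level(maps, z_min=2.0, n_permutations=500, seed=i)
            if res.clusters:
                rejections += 1
        rate = rejections / n_datasets
        assert 0.004 <= rate <= 0.096


class TestOrthogonalAugmentation:
    def test_adding_orthogonal_column_preserves_contrast_effect(self):
        ev, out = _trials(["hit", "miss", "cr", "fa"])
        n = 80
        X = build_design_matrix(ev, out, [5.0], _motion(n),
                                canonical_params("pigeon"), TR=2.0, n_volumes=n)
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, n)
        # column orthogonal to the design and to the data
        q, _ = np.linalg.qr(np.column_stack([X.matrix, y]))
        extra = rng.normal(0, 1, n)
        extra -= q @ (q.T @ extra)
        from avihrf.glm_task import DesignMatrix

        X2 = DesignMatrix(matrix=np.column_stack([X.matrix, extra]),
                          names=X.names + ["orth"], TR=2.0, hrf=X.hrf)
        series = BOLDSeries(data=y.reshape(1, 1, 1, -1), TR=2.0)
        c1 = np.zeros(len(X.names)); c1[0] = 1.0
        c2 = np.zeros(len(X2.names)); c2[0] = 1.0
        e1 = fit_glm(series, X).betas[0, 0, 0] @ c1
        e2 = fit_glm(series, X2).betas[0, 0, 0] @ c2
        assert e1 == pytest.approx(e2, abs=1e-8)
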