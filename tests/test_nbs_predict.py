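"""Residualization, edgewise F tests, component selection, model fitting,
thresholding, transfer, and the discovery loop's contracts."""

import numpy as np
import pytest
from scipy import stats

import cycleconn as cc
from cycleconn.core import edge_index, n_edges
from cycleconn.nbs_predict import (
    _lcc_indices,
    _run_fold,
    fit_component_model,
)

from conftest import union_find_components


class TestResidualizeConfounds:
    def test_zero_covariates_mean_center(self, rng):
        X = rng.normal(size=(20, 3))
        train = np.arange(10)
        with pytest.warns(UserWarning, match="constant"):
            resid, _ = cc.residualize_confounds(X, np.zeros((20, 1)), train)
        np.testing.assert_allclose(resid, X - X[train].mean(0), atol=1e-10)

    def test_motion_coupled_edge_decorrelated(self, rng):
        n = 60
        fd = rng.uniform(0.05, 0.3, n)
        edge = 2.0 * fd + rng.normal(0, 0.05, n)
        train = np.arange(n)
        resid, _ = cc.residualize_confounds(edge, fd, train)
        r = np.corrcoef(resid, fd)[0, 1]
        assert abs(r) < 0.05

    def test_held_out_rows_use_training_coefficients(self, rng):
        # predictions on held-out rows must match a normal-equations oracle
        S = 30
        C = rng.normal(size=(S, 2))
        X = C @ rng.normal(size=(2, 4)) + rng.normal(size=(S, 4))
        train = np.arange(20)
        resid, coef = cc.residualize_confounds(X, C, train)
        D = np.column_stack([np.ones(S), C])
        beta = np.linalg.solve(
            D[train].T @ D[train], D[train].T @ X[train]
        )
        np.testing.assert_allclose(resid, X - D @ beta, atol=1e-8)

    def test_no_leakage_from_held_out_rows(self, rng):
        S = 30
        C = rng.normal(size=(S, 2))
        X = rng.normal(size=(S, 4))
        train = np.arange(20)
        _, coef1 = cc.residualize_confounds(X, C, train)
        X2 = X.copy()
        X2[20:] += 100.0  # perturb only held-out rows
        _, coef2 = cc.residualize_confounds(X2, C, train)
        np.testing.assert_array_equal(coef1, coef2)


class TestEdgewiseAssociation:
    def test_perfect_association_machine_level_p(self, rng):
        y = rng.normal(size=20)
        F, p = cc.edgewise_association(y[:, None], y)
        assert p[0] < 1e-12

    def test_identity_with_pearson_oracle(self, rng):
        S, E = 40, 12
        edges = rng.normal(size=(S, E))
        y = rng.normal(size=S)
        F, p = cc.edgewise_association(edges, y)
        for k in range(E):
            r = np.corrcoef(edges[:, k], y)[0, 1]
            expected = r**2 * (S - 2) / (1 - r**2)
            assert F[k] == pytest.approx(expected, rel=1e-9)

    def test_two_group_anova_by_hand(self):
        # groups {1,2,3} and {6,7,8}: SSB = 37.5, SSW = 4, df = (1, 4),
        # so F = 37.5 / (4/4) = 37.5
        edge = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 8.0])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        F, p = cc.edgewise_association(edge[:, None], y)
        assert F[0] == pytest.approx(37.5, rel=1e-12)
        assert p[0] == pytest.approx(stats.f.sf(37.5, 1, 4), rel=1e-12)

    def test_constant_edge_gets_unit_p(self, rng):
        edges = np.column_stack([np.ones(20), rng.normal(size=20)])
        F, p = cc.edgewise_association(edges, rng.normal(size=20))
        assert F[0] == 0.0 and p[0] == 1.0

    def test_constant_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cc.edgewise_association(rng.normal(size=(10, 2)), np.ones(10))


def _pvals_for_edges(hits, n_regions):
    iu, ju = edge_index(n_regions)
    p = np.ones(n_edges(n_regions))
    lookup = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    for e in hits:
        p[lookup[e]] = 0.001
    return p


class TestLargestConnectedComponent:
    def test_no_suprathreshold_edges(self):
        assert cc.largest_connected_component(np.ones(45), 0.05, 10) == []

    def test_all_edges_suprathreshold(self):
        iu, ju = edge_index(6)
        out = cc.largest_connected_component(np.zeros(15), 0.05, 6)
        assert out == list(zip(iu.tolist(), ju.tolist()))

    def test_toy_graph_drops_disconnected_edge(self):
        p = _pvals_for_edges([(0, 1), (1, 2), (5, 6)], 10)
        out = cc.largest_connected_component(p, 0.05, 10)
        assert out == [(0, 1), (1, 2)]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        p = rng.uniform(size=n_edges(n))
        thr = float(rng.uniform(0.02, 0.3))
        ours = cc.largest_connected_component(p, thr, n)
        iu, ju = edge_index(n)
        hits = [(int(i), int(j)) for i, j, pv in zip(iu, ju, p) if pv < thr]
        comps = union_find_components(hits, n)
        if not comps:
            assert ours == []
            return
        best = max(len(c) for c in comps)
        assert len(ours) == best
        assert set(ours) <= set(hits)
        # the returned edges form a single component
        sub = union_find_components(ours, n)
        assert len(sub) == 1


class TestFitComponentModel:
    def test_ridge_zero_limit_matches_ols(self, rng):
        S = 40
        X = rng.normal(size=(S, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.1, S)
        beta, icpt, alpha, mean, std = fit_component_model(
            X, y, "linear", alpha_grid=(1e-10,), inner_folds=3, seed=0
        )
        Xs = (X - mean) / std
        D = np.column_stack([np.ones(S), Xs])
        ols = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(beta, ols[1:], atol=1e-6)
        assert icpt == pytest.approx(ols[0], abs=1e-6)

    def test_huge_penalty_shrinks_to_mean(self, rng):
        S = 30
        X = rng.normal(size=(S, 3))
        y = rng.normal(size=S)
        beta, icpt, *_ = fit_component_model(
            X, y, "linear", alpha_grid=(1e12,), inner_folds=2, seed=0
        )
        assert np.abs(beta).max() < 1e-6
        assert icpt == pytest.approx(y.mean(), abs=1e-6)

    def test_separable_binary_perfect_in_sample(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (15, 2)), rng.normal(3, 0.3, (15, 2))])
        y = np.r_[np.zeros(15), np.ones(15)]
        beta, icpt, alpha, mean, std = fit_component_model(
            X, y, "logistic", alpha_grid=(1e-3, 1e-2), inner_folds=3, seed=0
        )
        from cycleconn.nbs_predict import _predict_logistic_prob

        pred = _predict_logistic_prob(beta, icpt, (X - mean) / std) > 0.5
        assert (pred == y.astype(bool)).all()


class TestThresholdNetwork:
    def _network(self, weights, n=10):
        w = np.zeros(n_edges(n))
        w[: len(weights)] = weights
        return cc.WeightedNetwork(
            outcome="hc", labels=[f"r{k}" for k in range(n)],
            edge_weights=w, performance=np.array([1.0, 1.0]), n_iterations=2,
        )

    def test_half_of_ten(self):
        net = self._network([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.15, 0.1])
        kept = cc.threshold_network(net, 0.5)
        assert kept.tolist() == [0, 1, 2, 3, 4]

    def test_fraction_one_keeps_all_positive(self):
        net = self._network([0.5, -0.2, 0.1, 0.0, 0.3])
        kept = cc.threshold_network(net, 1.0)
        assert kept.tolist() == [0, 2, 4]

    def test_tie_break_by_edge_index(self):
        net = self._network([0.3, 0.3, 0.1])
        kept = cc.threshold_network(net, 0.5)
        assert kept.tolist() == [0, 1]

    def test_all_zero_warns_and_returns_empty(self):
        net = self._network([0.0])
        with pytest.warns(UserWarning, match="no positive"):
            kept = cc.threshold_network(net, 0.5)
        assert kept.size == 0


@pytest.fixture(scope="module")
def planted_hc_setup():
    """Small discovery study with a strong planted HC component."""
    design = cc.StudyDesignSpec(
        subjects=[
            cc.SubjectPlan("s1", "A", False, 15, 1, 28),
            cc.SubjectPlan("s1", "B", True, 15, 1, 28),
            cc.SubjectPlan("s2", "C", False, 3, 7, 28),
            cc.SubjectPlan("s3", "C", True, 3, 7, 28),
            cc.SubjectPlan("s4", "C", True, 3, 7, 28),
        ],
        n_regions=20,
        seed=31,
    )
    truth = cc.GroundTruthSpec(
        hc_edges=8, hc_effect=1.2, e2_effect=0.0, p4_effect=0.0,
        motion_effect=0.0, noise_scale=0.08, dataset_scale=0.0, seed=31,
    )
    study, record = cc.generate_study(design, truth)
    dense = study.subset(study.sessions["dataset_id"].isin(["A", "B"]).to_numpy())
    weekly = study.subset((study.sessions["dataset_id"] == "C").to_numpy())
    config = cc.CVConfig.for_outcome("hc", n_iterations=10, seed=31)
    return dense, weekly, record, config


class TestDiscoveryLoop:
    def test_deterministic_given_config(self, planted_hc_setup):
        dense, _, _, config = planted_hc_setup
        net1 = cc.run_discovery(dense, config)
        net2 = cc.run_discovery(dense, config)
        np.testing.assert_array_equal(net1.edge_weights, net2.edge_weights)
        np.testing.assert_array_equal(net1.performance, net2.performance)

    def test_never_selected_edges_are_exactly_zero(self, planted_hc_setup):
        dense, _, record, config = planted_hc_setup
        net = cc.run_discovery(dense, config)
        assert (net.edge_weights == 0).any()
        # planted edges are selected and carry the highest weights
        iu, ju = edge_index(20)
        flat = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
        planted = [flat[tuple(e)] for e in record["masks"]["hc"]]
        assert net.edge_weights[planted].min() > 0

    def test_fold_selection_ignores_held_out_values(self, planted_hc_setup):
        dense, _, _, config = planted_hc_setup
        E = dense.edge_matrix()
        y = dense.sessions["hc_use"].to_numpy(dtype=float)
        C = dense.sessions["mean_fd"].to_numpy(dtype=float)[:, None]
        train = np.arange(24)
        test = np.arange(24, 30)
        sel1, _ = _run_fold(E, y, C, train, test, config, "logistic", 20, seed=5)
        E2 = E.copy()
        E2[test] = 100.0
        sel2, _ = _run_fold(E2, y, C, train, test, config, "logistic", 20, seed=5)
        assert sel1 == sel2

    def test_final_model_round_trip_and_transfer(self, tmp_path, planted_hc_setup):
        dense, weekly, _, config = planted_hc_setup
        net = cc.run_discovery(dense, config)
        kept = cc.threshold_network(net, config.retain_fraction)
        model = cc.train_final_model(dense, kept, config)
        assert len(model.beta) == kept.size
        model.to_json(tmp_path / "model.json")
        reloaded = cc.FittedModel.from_json(tmp_path / "model.json")
        r1 = cc.transfer_predict(model, weekly)
        r2 = cc.transfer_predict(reloaded, weekly)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        assert 0.0 <= r1.performance <= 1.0
        assert r1.mse >= 0.0

    def test_self_transfer_matches_in_sample(self, planted_hc_setup):
        dense, _, _, config = planted_hc_setup
        net = cc.run_discovery(dense, config)
        kept = cc.threshold_network(net, config.retain_fraction)
        model = cc.train_final_model(dense, kept, config)
        res = cc.transfer_predict(model, dense)
        # refit on the full study should at least track the CV mean
        assert res.performance >= net.performance_mean - 0.05

    def test_single_edge_model(self, planted_hc_setup):
        dense, _, _, config = planted_hc_setup
        model = cc.train_final_model(dense, np.array([0]), config)
        assert len(model.beta) == 1

    def test_region_set_mismatch_rejected(self, planted_hc_setup):
        dense, _, _, config = planted_hc_setup
        model = cc.train_final_model(dense, np.array([0, 1]), config)
        other, _ = cc.generate_study(
            cc.default_design(n_regions=12, seed=1), cc.default_truth(seed=1)
        )
        with pytest.raises(ValueError, match="region"):
            cc.transfer_predict(model, other)


class TestDropCycleWindow:
    def test_window_counts_on_dense_study(self, default_study):
        study, _ = default_study
        dense = study.subset(study.sessions["dataset_id"].str.startswith("dense").to_numpy())
        trimmed = cc.drop_cycle_window(dense, 12, 16)
        # five ovulatory-window days per 30-day block, two blocks
        assert trimmed.n_sessions == 60 - 10
        days = trimmed.sessions["cycle_day"]
        assert not ((days >= 12) & (days <= 16)).any()

    def test_empty_window_is_identity(self, default_study):
        study, _ = default_study
        out = cc.drop_cycle_window(study, 16, 12)
        assert out.n_sessions == study.n_sessions

    def test_missing_cycle_day_retained_with_warning(self, default_study):
        study, _ = default_study
        sess = study.sessions.copy()
        sess.loc[0, "cycle_day"] = np.nan
        modified = cc.Study(sessions=sess, connectomes=study.connectomes,
                            regions=study.regions)
        with pytest.warns(UserWarning, match="cycle day"):
            out = cc.drop_cycle_window(modified, 0, 27)
        assert out.n_sessions == 1
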