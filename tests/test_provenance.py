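"""Distance matrices, Mantel test, calibration, placement and LOO."""

import itertools

import numpy as np
import pandas as pd
import pytest

from _util import dirichlet_q
from whogem.containers import QMatrix
from whogem.provenance import (
    PAPER_CALIBRATION,
    CalibrationModel,
    LooSummary,
    ReferencePanel,
    admixture_distance_matrix,
    calibrate,
    geographic_distance_matrix,
    loo_cross_validate,
    mantel_test,
    panel_from_populations,
    predict_location,
    select_k,
)
from whogem.synthetic_data import LandscapeConfig, make_landscape


class TestDistances:
    def test_admixture_distance_cases(self):
        Q = QMatrix(["a", "b", "c", "d"],
                    np.array([[1, 0], [0, 1], [0.5, 0.5], [0.2, 0.8]]))
        D = admixture_distance_matrix(Q)
        assert D[0, 0] == 0.0
        assert np.isclose(D[0, 1], np.sqrt(2))
        assert np.isclose(D[2, 3], np.sqrt(0.18))
        assert np.allclose(D, D.T)
        assert D.max() <= np.sqrt(2) + 1e-12

    def test_geographic_euclidean_345(self):
        geo = pd.DataFrame({"sample_id": ["a", "b"], "latitude": [0.0, 3.0],
                            "longitude": [0.0, 4.0]})
        D = geographic_distance_matrix(geo)
        assert np.isclose(D[0, 1], 5.0)

    def test_geographic_great_circle_one_degree(self):
        geo = pd.DataFrame({"sample_id": ["a", "b"], "latitude": [0.0, 0.0],
                            "longitude": [0.0, 1.0]})
        D = geographic_distance_matrix(geo, metric="great-circle-km")
        assert np.isclose(D[0, 1], 111.19, atol=0.01)


class TestMantel:
    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(0)
        A = rng.random((6, 6))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        r, p = mantel_test(D, D, n_perm=199, seed=0)
        assert np.isclose(r, 1.0)
        assert p == pytest.approx(1 / 200, abs=1e-12)

    def test_matches_exhaustive_permutation_oracle(self):
        D1 = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0.]])
        rng = np.random.default_rng(5)
        A = rng.random((4, 4))
        D2 = (A + A.T) / 2
        np.fill_diagonal(D2, 0)
        il = np.tril_indices(4, -1)
        r, _ = mantel_test(D1, D2, n_perm=99, seed=1)
        assert np.isclose(r, np.corrcoef(D1[il], D2[il])[0, 1])
        # the permutation distribution over all 24 relabelings brackets
        # the estimated p value
        rs = [np.corrcoef(D1[il], D2[np.ix_(p, p)][il])[0, 1]
              for p in itertools.permutations(range(4))]
        p_exact = np.mean([x >= r - 1e-12 for x in rs])
        _, p_est = mantel_test(D1, D2, n_perm=4999, seed=2)
        assert abs(p_est - p_exact) < 0.05

    def test_zero_variance_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            mantel_test(D, D, n_perm=9)

    def test_null_type_one_error_calibrated(self):
        hits = 0
        n_null = 100
        for seed in range(n_null):
            rng = np.random.default_rng(seed)
            A, B = rng.random((2, 12, 12))
            D1, D2 = (A + A.transpose(1, 0)) / 2, (B + B.transpose(1, 0)) / 2
            np.fill_diagonal(D1, 0)
            np.fill_diagonal(D2, 0)
            _, p = mantel_test(D1, D2, n_perm=199, seed=seed + 1)
            hits += p <= 0.05
        assert 0.01 <= hits / n_null <= 0.10


class TestCalibrate:
    def test_noiseless_line_recovered(self):
        rng = np.random.default_rng(1)
        n = 12
        gen = rng.random((n, n))
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        geo = 5.0 * gen
        cal = calibrate(gen, geo, cutoff=geo.max() + 1, n_perm=99, seed=0)
        assert np.isclose(cal.slope, 5.0) and np.isclose(cal.intercept, 0.0, atol=1e-9)
        assert cal.adj_r2 > 0.999

    def test_packaged_study_constants(self):
        assert PAPER_CALIBRATION.intercept == 0.204
        assert PAPER_CALIBRATION.slope == 4.973
        assert np.isclose(PAPER_CALIBRATION.cutoff * PAPER_CALIBRATION.deg_to_km, 950.0)
        assert PAPER_CALIBRATION.mantel_r_filtered == 0.78

    def test_cutoff_below_all_distances_rejected(self):
        gen = np.array([[0, 1.0], [1.0, 0]])
        geo = np.array([[0, 5.0], [5.0, 0]])
        with pytest.raises(ValueError):
            calibrate(np.pad(gen, (0, 1)), np.pad(geo, (0, 1)), cutoff=0.1, n_perm=9)


def _toy_panel():
    q = np.array([0.4, 0.4, 0.1, 0.1])
    deltas = np.array([0.1, 0.2, 0.4])
    direction = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2)
    theta = q[None, :] + deltas[:, None] * direction[None, :]
    panel = ReferencePanel(["u1", "u2", "u3"], theta,
                           np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]),
                           ["x", "y", "z"], ["x", "y", "z"])
    return q, panel


class TestPredictLocation:
    def test_exact_match_returns_unit(self):
        q, panel = _toy_panel()
        cal = CalibrationModel(0.0, 5.0, 100.0)
        res = predict_location(panel.theta[1], panel, cal, M=3)
        assert res.tie_ids == ["u2"]
        assert np.isclose(res.latitude, 0.0) and np.isclose(res.longitude, 1.0)

    def test_zero_distance_tie_centroid(self):
        theta = np.array([[0.5, 0.5], [0.5, 0.5]])
        panel = ReferencePanel(["a", "b"], theta, np.array([0.0, 0.0]),
                               np.array([0.0, 2.0]), ["x", "y"], ["x", "y"])
        cal = CalibrationModel(0.0, 5.0, 100.0)
        res = predict_location(np.array([0.5, 0.5]), panel, cal)
        assert np.isclose(res.latitude, 0.0) and np.isclose(res.longitude, 1.0)
        assert set(res.tie_ids) == {"a", "b"}

    def test_hand_worked_weighted_displacement(self):
        # deltas (0.1, 0.2, 0.4), cal Geo = 5 Gen: radius 0.5,
        # weights (1, 1/2, 1/4), displacement (0.25, 0.5) clipped to 0.5
        q, panel = _toy_panel()
        cal = CalibrationModel(0.0, 5.0, 100.0)
        res = predict_location(q, panel, cal, M=3)
        assert np.allclose(res.weights, [1.0, 0.5, 0.25], atol=1e-9)
        assert np.isclose(res.radius, 0.5, atol=1e-12)
        assert np.isclose(res.latitude, 0.22360679, atol=1e-6)
        assert np.isclose(res.longitude, 0.44721359, atol=1e-6)

    def test_weight_bounds_and_radius_invariant(self):
        rng = np.random.default_rng(2)
        Q = dirichlet_q(15, 4, seed=2)
        panel = ReferencePanel([f"u{i}" for i in range(15)], Q.theta,
                               rng.uniform(30, 45, 15), rng.uniform(-10, 25, 15),
                               ["c"] * 15, ["p"] * 15)
        cal = CalibrationModel(0.2, 5.0, 8.0)
        for _ in range(10):
            q = rng.dirichlet(np.ones(4))
            res = predict_location(q, panel, cal)
            assert (res.weights > 0).all() and (res.weights <= 1 + 1e-12).all()
            tie_lat = panel.latitude[[panel.unit_ids.index(t) for t in res.tie_ids]].mean()
            tie_lon = panel.longitude[[panel.unit_ids.index(t) for t in res.tie_ids]].mean()
            d = np.hypot(res.latitude - tie_lat, res.longitude - tie_lon)
            assert d <= res.radius + 1e-9

    def test_panel_order_and_component_relabel_invariance(self):
        q, panel = _toy_panel()
        cal = CalibrationModel(0.0, 5.0, 100.0)
        base = predict_location(q, panel, cal, M=3)
        order = [2, 0, 1]
        shuffled = ReferencePanel([panel.unit_ids[i] for i in order], panel.theta[order],
                                  panel.latitude[order], panel.longitude[order],
                                  [panel.country[i] for i in order],
                                  [panel.population[i] for i in order])
        res = predict_location(q, shuffled, cal, M=3)
        assert np.isclose(res.latitude, base.latitude)
        assert np.isclose(res.longitude, base.longitude)
        relab = [3, 1, 0, 2]
        relabeled = ReferencePanel(panel.unit_ids, panel.theta[:, relab],
                                   panel.latitude, panel.longitude,
                                   panel.country, panel.population)
        res2 = predict_location(q[relab], relabeled, cal, M=3)
        assert np.isclose(res2.latitude, base.latitude)
        assert np.isclose(res2.longitude, base.longitude)

    def test_k_mismatch_rejected(self):
        q, panel = _toy_panel()
        with pytest.raises(ValueError):
            predict_location(np.array([0.5, 0.5]), panel, CalibrationModel(0, 5, 10))


class TestLoo:
    def test_degenerate_panel_perfect(self):
        # every member of a population shares one Q row and one location
        theta = np.repeat(np.eye(3), 4, axis=0)
        ids = [f"s{i}" for i in range(12)]
        Q = QMatrix(ids, theta)
        geo = pd.DataFrame({
            "sample_id": ids,
            "latitude": np.repeat([35.0, 40.0, 45.0], 4),
            "longitude": np.repeat([0.0, 10.0, 20.0], 4),
            "country": np.repeat(["A", "B", "C"], 4),
            "population": np.repeat(["P1", "P2", "P3"], 4),
        })
        cal = CalibrationModel(0.0, 5.0, 50.0)
        out = loo_cross_validate(geo, Q, cal)
        assert out.median_error < 1e-9
        assert out.country_accuracy == 1.0

    def test_shuffled_structure_is_uninformative(self):
        cfg = LandscapeConfig(K=4, n_per_pop=25, decay_rho=1.0, seed=3)
        geo, q = make_landscape(cfg)
        rng = np.random.default_rng(4)
        shuffled = QMatrix(q.sample_ids, q.theta[rng.permutation(q.n_samples)])
        cal = CalibrationModel(0.5, 5.0, 20.0)
        out = loo_cross_validate(geo, shuffled, cal)
        n_countries = geo["country"].nunique()
        # binomial CI around chance level
        se = np.sqrt(out.country_accuracy * (1 - out.country_accuracy) / len(out.per_sample))
        assert out.country_accuracy < 1 / n_countries + 4 * max(se, 0.05)
        assert out.median_error > 1.0

    def test_all_singletons_rejected(self):
        Q = dirichlet_q(3, 2, seed=0)
        geo = pd.DataFrame({"sample_id": Q.sample_ids, "latitude": [1.0, 2.0, 3.0],
                            "longitude": [1.0, 2.0, 3.0], "country": list("abc"),
                            "population": list("xyz")})
        with pytest.raises(ValueError):
            loo_cross_validate(geo, Q, CalibrationModel(0, 5, 10))


def _summary(median, acc):
    df = pd.DataFrame({"sample_id": ["s"], "population": ["p"],
                       "error": [median], "correct_country": [acc > 0.5]})
    return LooSummary(df, median, acc, df.groupby("population")["correct_country"].mean())


class TestSelectK:
    def test_dominating_k(self):
        out, table = select_k({2: _summary(10, 0.5), 3: _summary(2, 0.9),
                               4: _summary(5, 0.7)})
        assert out == 3

    def test_parsimony_on_ties(self):
        out, _ = select_k({6: _summary(2.01, 0.89), 8: _summary(2.0, 0.9)})
        assert out == 6

    def test_fallback_when_no_k_satisfies_both(self):
        with pytest.warns(UserWarning):
            out, _ = select_k({2: _summary(1.0, 0.2), 3: _summary(5.0, 0.9)})
        assert out == 2
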