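"""Cluster assignment ensemble, kNN sampling, and the microsimulation loop."""

import numpy as np
import pandas as pd
import pytest

from vlab import (ClusterSimulationContext, assign_cluster, assign_dose,
                  hierarchical_cluster, knn_neighbors, predict_pain,
                  sample_next_covariates, simulate)
from vlab.equations import coeffs_by_column
from vlab.regression import FittedClusterModel
from vlab.simulate import fuzzy_memberships, sqrt_k


class TestAssignment:
    def test_k_square_root_convention(self):
        assert sqrt_k(431) == 21
        assert sqrt_k(100) == 10
        assert sqrt_k(2) == 1

    def test_equidistant_memberships_are_uniform(self):
        u = fuzzy_memberships(np.full(6, 0.37))
        np.testing.assert_allclose(u, np.full(6, 1 / 6))

    def test_zero_distance_dominates(self):
        u = fuzzy_memberships(np.array([0.4, 0.0, 0.2]))
        np.testing.assert_allclose(u, [0, 1, 0])

    def test_separated_patient_assigned_to_true_cluster(self, separated_cohort):
        patients, _ = separated_cohort
        os_patients = patients[patients["source"] == "OS"].reset_index(drop=True)
        model = hierarchical_cluster(os_patients, n_clusters=6)
        novel = os_patients.iloc[17]
        c, conf, detail = assign_cluster(novel, model, os_patients)
        assert detail["knn"][0] == detail["fuzzy"][0] == c
        assert c == int(model.labels[novel["patient_id"]])
        assert conf > 0.5

    def test_centroid_patient_gets_full_membership(self, separated_cohort):
        patients, _ = separated_cohort
        os_patients = patients[patients["source"] == "OS"].reset_index(drop=True)
        model = hierarchical_cluster(os_patients, n_clusters=6)
        novel = model.centroids.loc[3].to_dict() | {"patient_id": "C3"}
        c, conf, detail = assign_cluster(novel, model, os_patients)
        assert detail["fuzzy"][0] == 3

    def test_unseen_level_errors(self, separated_cohort):
        patients, _ = separated_cohort
        os_patients = patients[patients["source"] == "OS"].reset_index(drop=True)
        model = hierarchical_cluster(os_patients, n_clusters=6)
        novel = os_patients.iloc[0].copy()
        novel["gender"] = "X"
        with pytest.raises(ValueError, match="gender"):
            assign_cluster(novel, model, os_patients)


class TestKnn:
    def test_identical_member_ranked_first(self):
        states = np.array([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]])
        ids = ["a", "b", "c"]
        assert knn_neighbors(states, ids, np.array([5.0, 5.0]), 2)[0] == "b"

    def test_line_ordering(self):
        states = np.array([[float(i)] for i in range(5)])
        ids = list("abcde")
        assert knn_neighbors(states, ids, np.array([0.0]), 5) == list("abcde")

    def test_k_clamped_with_warning(self):
        states = np.array([[0.0], [1.0]])
        with pytest.warns(UserWarning, match="clamped"):
            out = knn_neighbors(states, ["a", "b"], np.array([0.0]), 5)
        assert out == ["a", "b"]


class TestSampling:
    def test_degenerate_pdf(self):
        rng = np.random.default_rng(0)
        out = sample_next_covariates({"prsi": np.array([4.0, 4.0, 4.0])}, rng)
        assert out["prsi"] == 4.0

    def test_empirical_mean_converges(self):
        rng = np.random.default_rng(1)
        draws = [sample_next_covariates({"v": np.array([2.0, 2.0, 6.0, 6.0])},
                                        rng)["v"] for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(4.0, abs=0.15)

    def test_seeded_draws_reproducible(self):
        vals = {"v": np.array([1.0, 2.0, 3.0])}
        d1 = [sample_next_covariates(vals, np.random.default_rng(9))["v"]
              for _ in range(5)]
        d2 = [sample_next_covariates(vals, np.random.default_rng(9))["v"]
              for _ in range(5)]
        assert d1 == d2

    def test_dose_from_unanimous_responders(self):
        doses = np.full((4, 7), 300.0)
        rng = np.random.default_rng(2)
        assert assign_dose(doses, 2, rng) == 300.0

    def test_dose_split_frequencies(self):
        doses = np.array([[150.0] * 7, [150.0] * 7, [300.0] * 7, [300.0] * 7])
        rng = np.random.default_rng(3)
        draws = [assign_dose(doses, 3, rng) for _ in range(4000)]
        assert np.mean(np.array(draws) == 150.0) == pytest.approx(0.5, abs=0.05)


def degenerate_context(cluster=1, n_members=9):
    """All members share one declining trajectory and one dose schedule."""
    pain = np.array([8.0, 6.0, 5.0, 4.0, 3.5, 3.2, 3.0])
    prsi = np.array([6.0, 5.0, 4.5, 4.0, 3.8, 3.6, 3.4])
    dose = np.array([150.0, 300.0, 300.0, 300.0, 300.0, 300.0, 300.0])
    rows = []
    for i in range(n_members):
        for w in range(7):
            rows.append({"patient_id": f"M{i}", "week": w, "pain": pain[w],
                         "prsi": prsi[w], "dose_mg": dose[w], "observed": True})
    series = pd.DataFrame(rows)
    members = pd.DataFrame([{"patient_id": f"M{i}"} for i in range(n_members)])
    return ClusterSimulationContext.build(cluster, members, series), prsi, dose


def novel_patient(**kw):
    base = dict(patient_id="N0", gender="M", age_years=50, age_group="45-64",
                bmi=27.0, insulin=0, depression=0, gabapentin=0, monotherapy=1,
                baseline_pain=8.0, baseline_prsi=6.0, feel_calm=3,
                feel_energy=4, feel_sad=4)
    base.update(kw)
    return pd.Series(base)


class TestSimulate:
    def make_model(self, cluster=1):
        return FittedClusterModel(cluster, "ref", coeffs_by_column(cluster),
                                  1.0, 0.0)

    def test_degenerate_setting_collapses_to_recursion(self):
        """With identical neighbors and a single dose schedule, all instances
        coincide with the deterministic recursion of the cluster equation."""
        context, prsi, dose = degenerate_context()
        model = self.make_model(1)
        res = simulate(novel_patient(), model, context, n_instances=50, seed=0)
        assert np.ptp(res.trajectories, axis=0).max() == 0.0
        expected = np.empty(7)
        expected[0] = 8.0
        for t in range(1, 7):
            values = {"pain_lag1": expected[t - 1], "prsi_lag0": prsi[t],
                      "dose_lag3": dose[max(t - 3, 0)], "feel_calm_t0": 3.0}
            expected[t] = np.clip(predict_pain(model, values), 0, 10)
        np.testing.assert_allclose(res.trajectories[0], expected, atol=1e-12)

    def test_same_seed_identical_result(self, separated_cohort):
        patients, series = separated_cohort
        members = patients[patients["true_cluster"] == 2]
        context = ClusterSimulationContext.build(2, members, series)
        model = self.make_model(2)
        r1 = simulate(novel_patient(), model, context, n_instances=40, seed=4)
        r2 = simulate(novel_patient(), model, context, n_instances=40, seed=4)
        np.testing.assert_array_equal(r1.trajectories, r2.trajectories)
        assert r1.summary() == r2.summary()

    def test_threshold_monotonicity_and_median_bounds(self, separated_cohort):
        patients, series = separated_cohort
        members = patients[patients["true_cluster"] == 1]
        context = ClusterSimulationContext.build(1, members, series)
        model = self.make_model(1)
        res = simulate(novel_patient(), model, context, n_instances=60, seed=5)
        assert res.responder_fraction_30 >= res.responder_fraction_50
        finals = res.trajectories[:, -1]
        assert finals.min() <= res.median_final_pain <= finals.max()
        assert np.all((res.trajectories >= 0) & (res.trajectories <= 10))

    def test_missing_model_errors(self):
        context, *_ = degenerate_context()
        with pytest.raises(ValueError, match="model"):
            simulate(novel_patient(), None, context, n_instances=5, seed=0)
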