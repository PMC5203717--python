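"""Transition tables, dependence/agreement/stability tests and the
within- vs between-subject distance-ratio machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix

from pneumotyper.trajectory import (
    _loo_medians,
    agreement_comparison,
    dependence_test,
    distance_ratio,
    ratio_permutation_test,
    stability_test,
    transition_counts,
)


def assignments_from_wide(wide: pd.DataFrame) -> pd.DataFrame:
    out = wide.rename_axis("subject_id").reset_index().melt(
        id_vars="subject_id", var_name="timepoint", value_name="pneumotype"
    )
    return out.dropna(subset=["pneumotype"])


class TestTransitionCounts:
    def test_identity_labels_give_diagonal(self):
        wide = pd.DataFrame({"W1": [1, 2, 2], "M1": [1, 2, 2]},
                            index=["a", "b", "c"])
        tab = transition_counts(assignments_from_wide(wide), "W1", "M1")
        assert tab.loc[1, 1] == 1 and tab.loc[2, 2] == 2
        assert tab.to_numpy().sum() == 3

    def test_direct_counting(self):
        wide = pd.DataFrame({"W1": [1, 1, 2], "M1": [2, 2, 2]},
                            index=["a", "b", "c"])
        tab = transition_counts(assignments_from_wide(wide), "W1", "M1")
        assert tab.loc[1, 2] == 2 and tab.loc[2, 2] == 1

    def test_markov_rows_recover_truth(self):
        rng = np.random.default_rng(0)
        T = np.array([[0.7, 0.3], [0.2, 0.8]])
        w1 = rng.integers(0, 2, size=400)
        m1 = np.array([rng.choice(2, p=T[i]) for i in w1])
        wide = pd.DataFrame({"W1": w1 + 1, "M1": m1 + 1},
                            index=[f"S{i}" for i in range(400)])
        tab = transition_counts(assignments_from_wide(wide), "W1", "M1")
        emp = tab.div(tab.sum(axis=1), axis=0).to_numpy()
        n_rows = tab.sum(axis=1).to_numpy()
        for i in range(2):
            se = np.sqrt(T[i] * (1 - T[i]) / n_rows[i])
            assert (np.abs(emp[i] - T[i]) < 4 * se).all()


class TestDependence:
    def test_hand_computed_2x2(self):
        tab = pd.DataFrame([[10, 0], [0, 10]])
        res = dependence_test(tab)
        assert res["yates"] is True
        raw = stats.chi2_contingency(tab.to_numpy(), correction=False)
        assert raw.statistic == pytest.approx(20.0)
        assert res["p_value"] < 0.01

    def test_block_diagonal_is_overwhelming(self):
        tab = pd.DataFrame(np.diag([40, 40, 40]))
        res = dependence_test(tab)
        assert res["p_value"] < 1e-6

    def test_independent_table_null_calibration(self):
        rng = np.random.default_rng(3)
        rej = 0
        reps = 150
        p_row = np.array([0.5, 0.3, 0.2])
        p_col = np.array([0.4, 0.4, 0.2])
        probs = np.outer(p_row, p_col).ravel()
        for _ in range(reps):
            tab = rng.multinomial(500, probs).reshape(3, 3)
            res = dependence_test(pd.DataFrame(tab))
            rej += res["p_value"] < 0.05
        assert 0.0 < rej / reps < 0.12

    def test_zero_margin_dropped_with_warning(self):
        tab = pd.DataFrame([[10, 5, 0], [5, 10, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero-margin"):
            res = dependence_test(tab)
        assert res["dof"] == 1


class TestAgreement:
    def test_identical_agreement_in_both_spans_gives_p_one(self):
        # both spans agree for exactly 2 of 4 subjects
        wide = pd.DataFrame({"W1": [1, 2, 1, 2], "M1": [1, 2, 2, 1],
                             "M3": [1, 2, 1, 2]})
        wide.index = [f"S{i}" for i in range(4)]
        res = agreement_comparison(assignments_from_wide(wide))
        assert res["per_pair"]["agreement"].tolist() == [0.5, 0.5]
        assert res["p_value"] == 1.0

    def test_all_stable_agreements_are_one(self):
        wide = pd.DataFrame({"W1": [1, 2], "M1": [1, 2], "M3": [1, 2]},
                            index=["a", "b"])
        res = agreement_comparison(assignments_from_wide(wide))
        assert res["per_pair"]["agreement"].tolist() == [1.0, 1.0]

    def test_stickier_second_span_detected(self):
        rng = np.random.default_rng(1)
        detected = 0
        reps = 25
        for _ in range(reps):
            n = 430
            same1 = rng.random(n) < 0.28
            same2 = rng.random(n) < 0.40
            w1 = rng.integers(1, 6, size=n)
            m1 = np.where(same1, w1, w1 % 5 + 1)
            m3 = np.where(same2, m1, m1 % 5 + 1)
            wide = pd.DataFrame({"W1": w1, "M1": m1, "M3": m3},
                                index=[f"S{i}" for i in range(n)])
            res = agreement_comparison(assignments_from_wide(wide))
            detected += res["p_value"] < 0.05
        assert detected / reps >= 0.6


class TestStability:
    def test_uniform_closed_form_expectation(self):
        # 5 equifrequent pneumotypes at each visit: expected = 5 * (1/5)^3
        labels = np.repeat(np.arange(1, 6), 20)
        rng = np.random.default_rng(2)
        wide = pd.DataFrame(
            {t: rng.permutation(labels) for t in ("W1", "M1", "M3")},
            index=[f"S{i}" for i in range(100)],
        )
        res = stability_test(assignments_from_wide(wide))
        assert res["expected_proportion"] == pytest.approx(0.04, abs=1e-12)

    def test_identity_transitions_observed_one(self):
        wide = pd.DataFrame({"W1": [1, 2, 3] * 10, "M1": [1, 2, 3] * 10,
                             "M3": [1, 2, 3] * 10})
        wide.index = [f"S{i}" for i in range(30)]
        res = stability_test(assignments_from_wide(wide))
        assert res["observed_proportion"] == 1.0
        assert res["p_value"] < 1e-10

    def test_per_pneumotype_table_present(self):
        rng = np.random.default_rng(8)
        wide = pd.DataFrame(
            {t: rng.integers(1, 4, size=60) for t in ("W1", "M1", "M3")},
            index=[f"S{i}" for i in range(60)],
        )
        res = stability_test(assignments_from_wide(wide))
        assert set(res["per_pneumotype"]["pneumotype"]) == {1, 2, 3}


class TestLooMedians:
    def test_matches_naive_exclusion(self):
        rng = np.random.default_rng(9)
        for m in (5, 6, 11, 12):
            C = rng.random((4, m))
            loo = _loo_medians(C)
            for i in range(4):
                for j in range(m):
                    naive = np.median(np.delete(C[i], j))
                    assert loo[i, j] == pytest.approx(naive, abs=1e-12)


def ratio_inputs(n, cross, own=None):
    """Full distance matrix + metadata for n subjects x 2 visits with a
    constant cross-subject block and optional own-distance overrides."""
    ids = [f"S{i}_W1" for i in range(n)] + [f"S{i}_M1" for i in range(n)]
    D = np.full((2 * n, 2 * n), cross, dtype=float)
    np.fill_diagonal(D, 0.0)
    if own is not None:
        for i, v in own.items():
            D[i, n + i] = D[n + i, i] = v
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "subject_id": [f"S{i}" for i in range(n)] * 2,
            "timepoint": ["W1"] * n + ["M1"] * n,
        }
    )
    return DistanceMatrix(D, ids=ids), meta


class TestDistanceRatio:
    def test_symmetric_world_gives_ratio_one(self):
        dm, meta = ratio_inputs(12, cross=1.0)
        res = distance_ratio(dm, meta, "W1", "M1")
        assert res["median_ratio"] == pytest.approx(1.0)

    def test_single_close_subject(self):
        dm, meta = ratio_inputs(12, cross=1.0, own={0: 0.5})
        res = distance_ratio(dm, meta, "W1", "M1")
        ratios = dict(zip(res["subjects"], res["ratios"]))
        assert ratios["S0"] == pytest.approx(0.5)

    def test_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(4)
        n = 15
        pts = rng.normal(size=(2 * n, 3))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        ids = [f"S{i}_W1" for i in range(n)] + [f"S{i}_M1" for i in range(n)]
        meta = pd.DataFrame(
            {"sample_id": ids, "subject_id": [f"S{i}" for i in range(n)] * 2,
             "timepoint": ["W1"] * n + ["M1"] * n}
        )
        r1 = distance_ratio(DistanceMatrix(D, ids=ids), meta, "W1", "M1")
        r2 = distance_ratio(DistanceMatrix(D * 7.5, ids=ids), meta, "W1", "M1")
        assert r1["median_ratio"] == pytest.approx(r2["median_ratio"], abs=1e-12)

    def test_minimum_attainable_p(self):
        dm, meta = ratio_inputs(20, cross=1.0, own={i: 1e-6 for i in range(20)})
        res = ratio_permutation_test(dm, meta, "W1", "M1", n_perm=999, seed=0,
                                     tail="one")
        assert res["p_value"] == pytest.approx(1 / 1000)

    def test_subject_persistence_in_synthetic_cohort(self, recovery_bundle):
        """The persistent per-subject genus tilt and core OTU choices make
        each infant's later sample closer to its own earlier sample than to
        other infants' samples (median ratio < 1); the second span, with its
        stickier pneumotypes, is individually significant."""
        dm = recovery_bundle["dm"]
        meta = recovery_bundle["cohort"].metadata
        meta = meta[meta["sample_id"].isin(dm.ids)]
        for pair in (("W1", "M1"), ("M1", "M3")):
            res = distance_ratio(dm, meta, *pair)
            assert res["median_ratio"] < 1.0
        res = ratio_permutation_test(dm, meta, "M1", "M3", n_perm=500, seed=1)
        assert res["p_value"] < 0.05

    def test_too_few_permutations_rejected(self):
        dm, meta = ratio_inputs(12, cross=1.0)
        with pytest.raises(ValueError):
            ratio_permutation_test(dm, meta, "W1", "M1", n_perm=50)
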