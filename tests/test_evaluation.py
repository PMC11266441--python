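"""Cross-validation schemes and metrics: partition properties, scheme
definitions, hand-computed metric values, and the dependent-correlation test."""

import numpy as np
import pandas as pd
import pytest

from metboost import evaluation as ev, trials
from metboost.errors import KeyMismatchError, SplitError, UndefinedMetricError
from metboost.evaluation import (
    CVPlan,
    coincidence_index,
    meng_test,
    pearson_accuracy,
    split_cv0,
    split_cv1,
    split_cv2,
)


@pytest.fixture(scope="module")
def blues(small_study):
    return trials.plot_mean_blues(small_study.plot_table)


class TestCV2:
    def test_folds_partition_all_combinations(self, blues):
        plan = split_cv2(blues, seed=4, repetitions=2)
        n = len(plan.records)
        for rep in (1, 2):
            valid_sets = [set(plan.assignments[(rep, f)][1]) for f in range(1, 6)]
            assert set().union(*valid_sets) == set(range(n))
            assert sum(len(s) for s in valid_sets) == n
            for f in range(1, 6):
                tr, va = plan.assignments[(rep, f)]
                assert set(tr) & set(va) == set()
                assert abs(len(va) - 0.2 * n) < 1  # within one record of 20%

    def test_restricted_to_last_two_years(self, blues):
        plan = split_cv2(blues, seed=4, repetitions=1)
        years = set(plan.records["Year"])
        assert years == {2020, 2021}

    def test_sparse_testing_property(self, blues):
        # every validation Env appears in training, and essentially every
        # validation Hybrid does too (a hybrid with few records can by chance
        # land entirely in one fold, so the hybrid check is statistical)
        plan = split_cv2(blues, seed=4, repetitions=2)
        for (rep, fold), _ in plan.assignments.items():
            tr, va = plan.split(rep, fold)
            assert set(va["Env"]) <= set(tr["Env"])
            known = set(va["Hybrid"]) & set(tr["Hybrid"])
            assert len(known) >= 0.97 * va["Hybrid"].nunique()

    def test_too_few_combinations_rejected(self):
        tiny = pd.DataFrame(
            {"Env": ["L1_2021"] * 3, "Hybrid": list("abc"), "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(SplitError):
            split_cv2(tiny, seed=0)

    def test_seeded_determinism(self, blues):
        a = split_cv2(blues, seed=9, repetitions=2)
        b = split_cv2(blues, seed=9, repetitions=2)
        for key in a.assignments:
            assert np.array_equal(a.assignments[key][1], b.assignments[key][1])


class TestCV1:
    def test_validation_hybrids_absent_from_training(self, blues):
        plan = split_cv1(blues, seed=5, repetitions=2)
        for (rep, fold), _ in plan.assignments.items():
            tr, va = plan.split(rep, fold)
            assert set(tr["Hybrid"]) & set(va["Hybrid"]) == set()

    def test_validation_is_final_year_only(self, blues):
        plan = split_cv1(blues, seed=5, repetitions=1)
        for (rep, fold), _ in plan.assignments.items():
            _, va = plan.split(rep, fold)
            assert set(va["Year"]) <= {2021}

    def test_folds_partition_final_year_hybrids(self, blues):
        plan = split_cv1(blues, seed=5, repetitions=2)
        final_hybrids = set(
            plan.records.loc[plan.records["Year"] == 2021, "Hybrid"]
        )
        for rep in (1, 2):
            held = [
                set(plan.split(rep, f)[1]["Hybrid"]) for f in range(1, 6)
            ]
            assert set().union(*held) == final_hybrids
            sizes = sorted(len(h) for h in held)
            assert sizes[-1] - sizes[0] <= 1  # 20% groups up to rounding


class TestCV0:
    def test_no_final_year_record_in_training(self, blues):
        plan = split_cv0(blues, seed=6, repetitions=2)
        for (rep, fold), _ in plan.assignments.items():
            tr, va = plan.split(rep, fold)
            assert (tr["Year"] < 2021).all()
            assert (va["Year"] == 2021).all()

    def test_every_validation_hybrid_known_from_earlier_years(self, blues):
        plan = split_cv0(blues, seed=6, repetitions=2)
        for (rep, fold), _ in plan.assignments.items():
            tr, va = plan.split(rep, fold)
            assert set(va["Hybrid"]) <= set(tr["Hybrid"])

    def test_three_years_required(self, blues):
        two_years = blues[~blues["Env"].str.endswith("2019")]
        with pytest.raises(SplitError):
            split_cv0(two_years, seed=0)


class TestPearson:
    def test_perfect_and_inverted_predictions(self):
        df = pd.DataFrame({"y_observed": [1.0, 2, 3, 4], "y_predicted": [1.0, 2, 3, 4]})
        assert pearson_accuracy(df) == pytest.approx(1.0)
        df["y_predicted"] = -df["y_observed"]
        assert pearson_accuracy(df) == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        df = pd.DataFrame(
            {"y_observed": [1.0, 2, 3, 4], "y_predicted": [2.0, 1, 4, 3]}
        )
        assert pearson_accuracy(df) == pytest.approx(0.6)

    def test_degenerate_inputs_raise(self):
        flat = pd.DataFrame({"y_observed": [1.0, 1, 1, 1], "y_predicted": [1.0, 2, 3, 4]})
        with pytest.raises(UndefinedMetricError):
            pearson_accuracy(flat)
        with pytest.raises(UndefinedMetricError):
            pearson_accuracy(flat.iloc[:2])


class TestCoincidenceIndex:
    def test_identical_rankings_give_one(self):
        v = np.arange(20.0)
        assert coincidence_index(v, v) == pytest.approx(1.0)

    def test_chance_level_gives_zero(self):
        # N=25, T=5, R=1; predictions place exactly one true top-5 in the top 5
        obs = np.arange(25.0)
        pred = np.concatenate([obs[:4][::-1] + 100, obs[4:]])  # bottom 4 promoted
        # top-5 observed: ids 20..24; top-5 predicted: ids 0,1,2,3 and 24
        assert coincidence_index(obs, pred) == pytest.approx(0.0)

    def test_printed_fraction_example(self):
        # N=10, T=2, B=1 -> (1 - 0.4) / (2 - 0.4) = 0.375
        obs = np.arange(10.0)
        pred = obs.copy()
        pred[[9, 0]] = pred[[0, 9]]  # keep 8, swap out 9
        assert coincidence_index(obs, pred) == pytest.approx(0.375)

    def test_random_permutations_average_to_zero(self):
        rng = np.random.default_rng(12)
        obs = np.arange(50.0)
        vals = [
            coincidence_index(obs, rng.permutation(obs)) for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            coincidence_index([1.0, 2], [1.0])
        with pytest.raises(ValueError):
            coincidence_index([1.0, 2], [1.0, 2], top_frac=1.5)


class TestTesterOverlap:
    @staticmethod
    def _plan(train_hybrids, valid_hybrids):
        hybrids = sorted(set(train_hybrids) | set(valid_hybrids))
        records = pd.DataFrame(
            {"Env": "L1_2021", "Hybrid": hybrids, "y": 0.0, "Year": 2021}
        )
        pos = {h: i for i, h in enumerate(hybrids)}
        return CVPlan(
            "CV2", 1, 1, 0, records,
            {
                (1, 1): (
                    np.array([pos[h] for h in train_hybrids]),
                    np.array([pos[h] for h in valid_hybrids]),
                )
            },
        )

    def test_identical_and_disjoint_tester_sets(self):
        tester_of = {f"h{i}": f"T{i % 2}" for i in range(8)}
        plan = self._plan([f"h{i}" for i in range(4)], [f"h{i}" for i in range(4, 8)])
        assert ev.tester_overlap(plan, tester_of) == 1.0
        tester_of = {f"h{i}": f"T{i}" for i in range(8)}
        assert ev.tester_overlap(plan, tester_of) == 0.0

    def test_hand_computed_jaccard(self):
        tester_of = {"h1": "a", "h2": "b", "h3": "c", "h4": "b", "h5": "c", "h6": "d"}
        plan = self._plan(["h1", "h2", "h3"], ["h4", "h5", "h6"])
        # W={a,b,c}, Z={b,c,d} -> 2/4
        assert ev.tester_overlap(plan, tester_of) == 0.5

    def test_unmapped_hybrid_raises(self):
        plan = self._plan(["h1"], ["h2"])
        with pytest.raises(KeyMismatchError):
            ev.tester_overlap(plan, {"h1": "a"})


class TestMengTest:
    def test_equal_correlations_give_null_result(self):
        z, p = meng_test(0.6, 0.6, 0.5, 200)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetry_in_swapped_correlations(self):
        z1, _ = meng_test(0.7, 0.5, 0.4, 150)
        z2, _ = meng_test(0.5, 0.7, 0.4, 150)
        assert z1 == pytest.approx(-z2)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(UndefinedMetricError):
            meng_test(1.0, 0.5, 0.3, 100)

    def test_larger_r1_gives_positive_z(self):
        z, p = meng_test(0.8, 0.4, 0.5, 200)
        assert z > 0
        assert p < 0.05


def test_fold_metrics_and_comparisons_roundtrip():
    from metboost.prediction import PredictionSet

    rng = np.random.default_rng(3)
    obs = rng.normal(size=60)
    preds = []
    for model, noise in (("G(A)", 0.5), ("G(A)+E", 0.2)):
        for rep in (1, 2):
            records = pd.DataFrame(
                {
                    "Env": "L1_2021",
                    "Hybrid": [f"h{i}" for i in range(60)],
                    "y_observed": obs,
                    "y_predicted": obs + rng.normal(0, noise, 60),
                }
            )
            preds.append(PredictionSet(records, model, fold=1, repetition=rep))
    fm = ev.fold_metrics(preds)
    assert len(fm) == 4
    assert fm["pearson_r"].between(-1, 1).all()
    cmp = ev.model_comparisons(preds)
    assert len(cmp) == 1
    assert 0 <= cmp["p_raw"].iloc[0] <= 1
    assert cmp["p_bonferroni"].iloc[0] >= cmp["p_raw"].iloc[0]
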