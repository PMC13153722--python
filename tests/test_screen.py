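"""Robustness screen: trajectories, features, clustering, selection, density."""

import numpy as np
import pandas as pd
import pytest

from promscreen.landscape import plant_cohort
from promscreen.mutation import MutationConfig, simulate_cohort
from promscreen.predictor import external_predictor_adapter, oracle_predictor
from promscreen.screen import (
    TrajectoryMatrix,
    build_report,
    cluster_trajectories,
    expression_trajectories,
    select_resistant,
    top_n_by_prediction,
    trajectory_density_summary,
    trajectory_features,
)


def _matrix(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"f{i}" for i in range(rows.shape[0])]
    return TrajectoryMatrix(values=rows, founder_ids=tuple(ids))


class TestExpressionTrajectories:
    def test_matrix_shape_and_founder_column(self, simple_landscape):
        founders = ["ACGTACGTAA", "TTTTTTTTTT"]
        cohort = simulate_cohort(founders, MutationConfig(generations=4, seed=1))
        tm = expression_trajectories(oracle_predictor(simple_landscape), cohort)
        assert tm.values.shape == (2, 5)
        assert tm.values[0, 0] == simple_landscape.score(founders[0])

    def test_zero_generation_cohort(self, simple_landscape):
        cohort = simulate_cohort(["ACGTACGTAA"], MutationConfig(generations=0, seed=1))
        tm = expression_trajectories(oracle_predictor(simple_landscape), cohort)
        assert tm.values.shape == (1, 1)

    def test_block_structure_under_concatenation(self, simple_landscape):
        cfg = MutationConfig(generations=3, seed=5)
        a = simulate_cohort(["ACGTACGTAA"], cfg)
        b = simulate_cohort(["TTTTTTTTTT"], cfg)
        model = oracle_predictor(simple_landscape)
        tm_a = expression_trajectories(model, a)
        tm_b = expression_trajectories(model, b)
        tm_ab = expression_trajectories(model, a + b)
        assert np.array_equal(tm_ab.values, np.vstack([tm_a.values, tm_b.values]))

    def test_ragged_cohort_rejected(self, simple_landscape):
        a = simulate_cohort(["ACGTACGTAA"], MutationConfig(generations=2, seed=1))
        b = simulate_cohort(["ACGTACGTAA"], MutationConfig(generations=3, seed=1))
        with pytest.raises(ValueError):
            expression_trajectories(oracle_predictor(simple_landscape), a + b)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[1.0, np.nan]])


class TestTrajectoryFeatures:
    def test_constant_row(self):
        f = trajectory_features(_matrix([[5, 5, 5]]))[0]
        assert f.sd == 0 and f.net_drop == 0 and f.volatility == 0
        assert f.max_rise == 0 and f.max_drop_step == 0

    def test_monotone_decay_row(self):
        f = trajectory_features(_matrix([[10, 6, 2]]))[0]
        assert f.start == 10 and f.final == 2
        assert f.net_drop == 8 and f.volatility == 4

    def test_oscillating_row(self):
        f = trajectory_features(_matrix([[5, 9, 1]]))[0]
        assert f.min == 1 and f.max == 9
        assert f.volatility == pytest.approx((4 + 8) / 2)
        assert f.max_rise == 4 and f.max_drop_step == 8

    def test_large_step_balance_invariant_to_rebuild(self):
        # destroy (-8), rebuild (+8), destroy again (-8): net loss 8
        f = trajectory_features(_matrix([[9, 1, 1, 9, 9, 1]]))[0]
        assert f.large_step_balance == 8.0
        # balanced up/down traffic nets to zero
        g = trajectory_features(_matrix([[9, 1, 9, 1, 9]]))[0]
        assert g.large_step_balance == 0.0

    def test_min_le_mean_le_max(self, rng):
        rows = rng.normal(size=(20, 30))
        for f in trajectory_features(_matrix(rows)):
            assert f.min <= f.mean <= f.max and f.sd >= 0 and f.volatility >= 0


class TestClustering:
    def test_archetype_recovery(self, rng):
        # flat-high rows, collapsing rows, oscillating rows
        flat = 9 + 0.1 * rng.normal(size=(5, 21))
        collapse = np.concatenate(
            [np.full((5, 3), 9.0), np.full((5, 18), 1.0)], axis=1
        ) + 0.1 * rng.normal(size=(5, 21))
        osc = np.tile([9.0, 1.0], 11)[:21] + 0.1 * rng.normal(size=(5, 21))
        tm = _matrix(np.vstack([flat, collapse, osc]))
        result = cluster_trajectories(trajectory_features(tm), seed=0)
        labels = list(result.labels)
        assert labels[:5] == ["resistant"] * 5
        assert labels[5:10] == ["declining"] * 5
        assert labels[10:] == ["volatile"] * 5

    def test_duplicate_rows_same_label(self):
        rows = np.vstack([
            np.full((3, 11), 9.0),
            np.r_[[9.0] * 1, [1.0] * 10][None, :].repeat(3, 0),
            np.tile([9.0, 1.0], 6)[:11][None, :].repeat(3, 0),
        ])
        rows = rows + np.linspace(0, 0.01, 11)  # break exact feature ties mildly
        result = cluster_trajectories(trajectory_features(_matrix(rows)), seed=1)
        for block in (slice(0, 3), slice(3, 6), slice(6, 9)):
            assert len(set(result.labels[block])) == 1

    def test_deterministic(self, rng):
        rows = rng.normal(size=(12, 21)).cumsum(axis=1)
        feats = trajectory_features(_matrix(rows))
        a = cluster_trajectories(feats, seed=7)
        b = cluster_trajectories(feats, seed=7)
        assert a == b

    def test_too_few_founders(self):
        feats = trajectory_features(_matrix([[1, 2], [3, 4]]))
        with pytest.raises(ValueError):
            cluster_trajectories(feats, n_clusters=3)

    def test_unknown_feature_name(self):
        feats = trajectory_features(_matrix(np.random.default_rng(0).normal(size=(5, 4))))
        with pytest.raises(ValueError, match="unknown clustering features"):
            cluster_trajectories(feats, feature_names=("no_such",))


class TestSelection:
    def test_identical_resistant_ranked_by_id(self):
        rows = np.full((4, 5), 7.0)
        feats = trajectory_features(_matrix(rows, ids=["d", "b", "a", "c"]))
        selected = select_resistant(feats, ["resistant"] * 4)
        assert selected == ["a", "b", "c", "d"]

    def test_low_final_excluded(self):
        rows = np.array([[9.0] * 5, [9.0] * 5, [9, 9, 9, 9, 1.0], [9.0] * 5])
        feats = trajectory_features(_matrix(rows))
        selected = select_resistant(feats, ["resistant"] * 4, min_final_quantile=0.5)
        assert "f2" not in selected

    def test_only_resistant_labels_selected(self):
        rows = np.full((3, 4), 5.0)
        feats = trajectory_features(_matrix(rows))
        selected = select_resistant(feats, ["resistant", "declining", "volatile"])
        assert selected == ["f0"]

    def test_order_invariance(self, rng):
        rows = rng.normal(8, 1, size=(8, 6))
        ids = [f"f{i}" for i in range(8)]
        feats = trajectory_features(_matrix(rows, ids=ids))
        labels = ["resistant"] * 8
        sel_a = select_resistant(feats, labels)
        perm = rng.permutation(8)
        sel_b = select_resistant([feats[i] for i in perm], [labels[i] for i in perm])
        assert sel_a == sel_b

    def test_empty_selection_is_not_error(self):
        rows = np.full((3, 4), 5.0)
        feats = trajectory_features(_matrix(rows))
        assert select_resistant(feats, ["declining"] * 3) == []

    def test_invalid_quantile(self):
        feats = trajectory_features(_matrix([[1, 2]]))
        with pytest.raises(ValueError):
            select_resistant(feats, ["resistant"], min_final_quantile=1.5)


class TestTopN:
    def test_matches_brute_force_sort(self, simple_landscape, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(50)]
        model = oracle_predictor(simple_landscape)
        top = top_n_by_prediction(model, seqs, n=10)
        scores = {s: simple_landscape.score(s) for s in seqs}
        brute = sorted(seqs, key=lambda s: -scores[s])
        assert sorted(scores[s] for s in top) == sorted(scores[s] for s in brute[:10])

    def test_n_equals_pool_and_argmax(self, simple_landscape):
        seqs = ["ACGTACGT", "TTTTTTTT", "ACGTTTTT"]
        model = oracle_predictor(simple_landscape)
        assert len(top_n_by_prediction(model, seqs, n=3)) == 3
        assert top_n_by_prediction(model, seqs, n=1) == ["ACGTACGT"]

    def test_ties_by_input_order(self):
        model = external_predictor_adapter(lambda seqs: [1.0] * len(seqs))
        assert top_n_by_prediction(model, ["AAAA", "CCCC", "GGGG"], n=2) == ["AAAA", "CCCC"]

    def test_n_exceeds_pool(self, simple_landscape):
        with pytest.raises(ValueError):
            top_n_by_prediction(oracle_predictor(simple_landscape), ["ACGT"], n=2)


class TestDensitySummary:
    def test_column_sums_equal_founders(self, rng):
        tm = _matrix(rng.normal(size=(7, 11)))
        table = trajectory_density_summary(tm, n_bins=5)
        sums = table.groupby("generation")["count"].sum()
        assert (sums == 7).all()

    def test_single_constant_trajectory(self):
        tm = _matrix([[2.0, 2.0, 3.0]])
        table = trajectory_density_summary(tm, n_bins=4)
        per_gen = table.groupby("generation")["count"].sum()
        assert (per_gen == 1).all()

    def test_duplicating_rows_doubles_counts(self, rng):
        rows = rng.normal(size=(4, 6))
        t1 = trajectory_density_summary(_matrix(rows), n_bins=5)
        t2 = trajectory_density_summary(_matrix(np.vstack([rows, rows])), n_bins=5)
        assert (t2["count"] == 2 * t1["count"]).all()

    def test_degenerate_range(self):
        with pytest.raises(ValueError):
            trajectory_density_summary(_matrix([[1.0, 1.0]]), n_bins=3)

    def test_min_bins(self, rng):
        with pytest.raises(ValueError):
            trajectory_density_summary(_matrix(rng.normal(size=(2, 3))), n_bins=1)


class TestEndToEndReport:
    def test_planted_cohort_report(self, tmp_path):
        ls, cohort = plant_cohort(n_per_class=6, seed=3)
        trajs = simulate_cohort(cohort.sequences, MutationConfig(generations=40, seed=4))
        tm = expression_trajectories(oracle_predictor(ls), trajs)
        report = build_report(tm, seed=0)
        frame = report.to_frame()
        assert len(frame) == 18
        assert set(frame["cluster"]) == {"resistant", "declining", "volatile"}
        out = tmp_path / "report.tsv"
        report.write_tsv(out)
        back = pd.read_csv(out, sep="\t")
        assert list(back.columns) == list(frame.columns)
        assert (back["founder_id"] == frame["founder_id"]).all()
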