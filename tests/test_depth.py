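"""Depth-robustness statistics and the rarefaction-replicate experiment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sinktrack.depth import (
    DepthEvalConfig,
    compare_depths_stats,
    dunn_test,
    hit_ratio,
    mean_squared_difference,
    run_depth_evaluation,
    spearman_vs_reference,
    unknown_rate_difference,
)
from sinktrack.feature_table import from_arrays
from sinktrack.gibbs import UNKNOWN, GibbsConfig
from sinktrack.metadata import SampleMetadata
from statsmodels.stats.multitest import multipletests

ENVS = ["EnvA", "EnvB", UNKNOWN]


def mat(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=ENVS)


class TestMSD:
    def test_identical_matrices_give_zero(self):
        m = mat({"m1": [0.5, 0.3, 0.2]})
        assert mean_squared_difference(m, m)[0] == 0.0

    def test_hand_arithmetic_one_by_two(self):
        est = pd.DataFrame([[0.6, 0.4]], index=["m1"], columns=["A", "B"])
        ref = pd.DataFrame([[0.4, 0.6]], index=["m1"], columns=["A", "B"])
        msd, cells = mean_squared_difference(est, ref)
        assert msd == pytest.approx(0.04)
        assert np.allclose(cells.to_numpy(), [[0.04, 0.04]])

    def test_invariant_to_consistent_permutation(self):
        est = mat({"m1": [0.6, 0.3, 0.1], "m2": [0.2, 0.3, 0.5]})
        ref = mat({"m1": [0.5, 0.4, 0.1], "m2": [0.3, 0.3, 0.4]})
        perm = [ENVS[2], ENVS[0], ENVS[1]]
        a = mean_squared_difference(est, ref)[0]
        b = mean_squared_difference(est[perm], ref[perm])[0]
        assert a == pytest.approx(b)

    def test_misalignment_is_hard_error(self):
        est = mat({"m1": [0.6, 0.3, 0.1]})
        ref = mat({"other": [0.6, 0.3, 0.1]})
        with pytest.raises(ValueError, match="not aligned"):
            mean_squared_difference(est, ref)


class TestSpearman:
    def test_identity_and_reversal(self):
        ref = mat({"m1": [0.5, 0.3, 0.2], "m2": [0.1, 0.2, 0.7]})
        assert spearman_vs_reference(ref, ref) == pytest.approx(1.0)
        # any strictly decreasing transform reverses every rank
        rev = 1.0 - ref
        assert spearman_vs_reference(rev, ref) == pytest.approx(-1.0)

    def test_tied_cells_match_manual_average_ranks(self):
        est = pd.DataFrame([[0.1, 0.2, 0.2, 0.3, 0.2]], index=["m"],
                           columns=list("abcde"))
        ref = pd.DataFrame([[0.05, 0.15, 0.25, 0.45, 0.10]], index=["m"],
                           columns=list("abcde"))
        # manual average ranks: est -> (1, 3, 3, 5, 3); ref -> (1, 3, 4, 5, 2)
        ra = np.array([1.0, 3.0, 3.0, 5.0, 3.0])
        rb = np.array([1.0, 3.0, 4.0, 5.0, 2.0])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert spearman_vs_reference(est, ref) == pytest.approx(expected)

    def test_constant_vector_returns_nan_with_warning(self):
        est = mat({"m1": [1 / 3, 1 / 3, 1 / 3]})
        ref = mat({"m1": [0.5, 0.3, 0.2]})
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman_vs_reference(est, ref))


class TestHitRatio:
    def test_identity_is_100(self):
        m = mat({"m1": [0.5, 0.3, 0.2], "m2": [0.1, 0.2, 0.7]})
        assert hit_ratio(m, m) == 100.0

    def test_three_of_five_matching(self):
        ref = mat({f"m{i}": [0.6, 0.3, 0.1] for i in range(5)})
        est_rows = {f"m{i}": [0.6, 0.3, 0.1] for i in range(3)}
        est_rows.update({f"m{i}": [0.1, 0.8, 0.1] for i in range(3, 5)})
        assert hit_ratio(mat(est_rows), ref) == pytest.approx(60.0)

    def test_tie_breaks_to_lexicographically_smallest(self):
        ref = mat({"m1": [0.6, 0.3, 0.1]})  # argmax EnvA
        est = mat({"m1": [0.45, 0.45, 0.1]})  # tie EnvA/EnvB -> EnvA
        assert hit_ratio(est, ref) == 100.0

    def test_topk_rule(self):
        ref = mat({"m1": [0.6, 0.3, 0.1]})
        est = mat({"m1": [0.3, 0.5, 0.2]})  # EnvA only second
        assert hit_ratio(est, ref, "top1") == 0.0
        assert hit_ratio(est, ref, ("topk", 2)) == 100.0

    def test_zero_sinks_is_error(self):
        empty = pd.DataFrame(columns=ENVS)
        with pytest.raises(ValueError, match="at least one sink"):
            hit_ratio(empty, empty)


class TestUnknownRateDifference:
    def test_identity_gives_zeros(self):
        m = mat({"m1": [0.5, 0.3, 0.2]})
        diffs, mean = unknown_rate_difference(m, m)
        assert mean == 0.0 and (diffs == 0).all()

    def test_hand_arithmetic_at_reported_scale(self):
        est = mat({"m1": [0.4, 0.3, 0.30]})
        ref = mat({"m1": [0.416, 0.3, 0.284]})
        _, mean = unknown_rate_difference(est, ref)
        assert mean == pytest.approx(1.6, abs=1e-9)

    def test_symmetric_in_arguments(self):
        a = mat({"m1": [0.5, 0.2, 0.3]})
        b = mat({"m1": [0.45, 0.25, 0.3]})
        assert unknown_rate_difference(a, b)[1] == unknown_rate_difference(b, a)[1]

    def test_missing_unknown_column_is_error(self):
        est = pd.DataFrame([[1.0]], index=["m1"], columns=["EnvA"])
        with pytest.raises(ValueError, match="Unknown"):
            unknown_rate_difference(est, est)


class TestGroupStats:
    def test_kruskal_h_matches_hand_ranked_value(self):
        # {1,2,3} vs {10,11,12}: rank sums 6 and 15 ->
        # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7
        h, _ = sps.kruskal([1, 2, 3], [10, 11, 12])
        assert h == pytest.approx(27 / 7)

    def test_dunn_z_matches_hand_arithmetic(self):
        # mean ranks 2 and 5, variance 3.5*(2/3) -> z = -3/sqrt(7/3)
        df = dunn_test({200: np.array([1.0, 2.0, 3.0]),
                        5000: np.array([10.0, 11.0, 12.0])})
        assert df.loc[0, "z"] == pytest.approx(-3 / np.sqrt(7 / 3))
        assert df.loc[0, "p"] == pytest.approx(
            2 * sps.norm.sf(3 / np.sqrt(7 / 3))
        )

    def test_bh_step_up_worked_example(self):
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_dunn_tie_correction_changes_variance(self):
        no_tie = dunn_test({1: np.array([1.0, 2.0]), 2: np.array([3.0, 4.0])})
        tied = dunn_test({1: np.array([1.0, 2.0]), 2: np.array([2.0, 4.0])})
        assert abs(tied.loc[0, "z"]) != abs(no_tie.loc[0, "z"])


def _facility_table():
    """3 source envs, 4 sinks, equal 600-read libraries, 12 taxa."""
    rng = np.random.default_rng(21)
    taxa = [f"t{i:02d}" for i in range(12)]
    profiles = rng.dirichlet(np.full(12, 0.3), size=3)
    cols, meta_rows = {}, []
    for v in range(3):
        sid = f"sw{v}"
        cols[sid] = rng.multinomial(600, profiles[v])
        meta_rows.append((sid, "source", f"Env{v}", pd.NA, "surface"))
    for i in range(4):
        sid = f"m{i}"
        w = rng.dirichlet([1, 1, 1])
        comp = w @ profiles
        cols[sid] = rng.multinomial(600, comp)
        meta_rows.append((sid, "sink", "Meat", "Truck", "meat"))
    table = from_arrays(
        np.column_stack([cols[s] for s in cols]), taxa, list(cols)
    )
    meta = SampleMetadata(
        pd.DataFrame(
            [r[1:] for r in meta_rows],
            index=[r[0] for r in meta_rows],
            columns=["role", "env", "position", "sample_type"],
        )
    )
    return table, meta


class TestRunDepthEvaluation:
    def test_full_depth_self_comparison_is_exact(self):
        table, meta = _facility_table()
        gibbs = GibbsConfig(seed=5, restarts=2, burnin_passes=20,
                            draws_per_restart=3, delay_passes=2)
        config = DepthEvalConfig(depths=(600,), replicates_default=1,
                                 replicates_smallest=1, seed=3)
        res = run_depth_evaluation(table, meta, gibbs, config)
        row = res.records.iloc[0]
        assert row["msd"] == 0.0
        assert row["spearman_rho"] == pytest.approx(1.0)
        assert row["hit_ratio"] == 100.0
        assert row["unknown_diff_mean"] == 0.0

    def test_experiment_is_deterministic_and_reports_all_cells(self):
        table, meta = _facility_table()
        gibbs = GibbsConfig(seed=5, restarts=2, burnin_passes=20,
                            draws_per_restart=3, delay_passes=2)
        config = DepthEvalConfig(depths=(400, 100), replicates_default=2,
                                 replicates_smallest=3, seed=3)
        r1 = run_depth_evaluation(table, meta, gibbs, config)
        r2 = run_depth_evaluation(table, meta, gibbs, config)
        assert r1.records.equals(r2.records)
        # 2 replicates at 400, 3 at the smallest depth 100
        assert list(r1.records.groupby("depth").size().loc[[400, 100]]) == [2, 3]
        report = compare_depths_stats(r1, "msd")
        assert set(report) >= {"kruskal_h", "kruskal_p", "shapiro", "levene"}

    def test_ascending_ladder_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            DepthEvalConfig(depths=(100, 600))

    def test_constant_metric_reports_trivial_null(self):
        from sinktrack.depth import DepthEvalResult

        records = pd.DataFrame(
            {
                "depth": [500, 500, 200, 200],
                "replicate": [0, 1, 0, 1],
                "msd": [0.0, 0.0, 0.0, 0.0],
                "spearman_rho": [1.0] * 4,
                "hit_ratio": [100.0] * 4,
                "unknown_diff_mean": [0.0] * 4,
                "unknown_rate": [10.0] * 4,
                "n_sinks": [4] * 4,
            }
        )
        res = DepthEvalResult(reference=None, records=records, proportions={})
        report = compare_depths_stats(res, "msd")
        assert report["kruskal_p"] == 1.0
        assert any("identical" in n for n in report["notes"])
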