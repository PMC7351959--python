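"""Gibbs source attribution: conditional formula, oracle agreement, contracts.

The central correctness check compares the sampler's posterior-mean mixing
proportions against exact enumeration of the joint over all assignment
vectors on tiny instances.
"""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sinktrack.feature_table import from_arrays
from sinktrack.gibbs import (
    UNKNOWN,
    GibbsConfig,
    conditional_assignment_distribution,
    enumerate_posterior_oracle,
    fit_sink,
    source_profiles,
    track_all_sinks,
)
from sinktrack.metadata import SampleMetadata

ORACLE_CFG = GibbsConfig(
    alpha1=0.5, alpha2=0.5, beta=1.0,
    restarts=5, burnin_passes=100, draws_per_restart=10_000, delay_passes=1,
    seed=42,
)


def small_instances():
    """Tiny fixtures (V <= 2, T <= 4, n <= 6) for sampler/oracle agreement."""
    yield (
        from_arrays(np.array([[8, 0], [0, 8], [1, 1]]), list("abc"), ["A", "B"]),
        [3, 1, 0],
    )
    yield (
        from_arrays(np.array([[5], [2], [1], [0]]), list("abcd"), ["A"]),
        [2, 1, 0, 3],
    )
    yield (
        from_arrays(np.array([[4, 1], [1, 4]]), list("ab"), ["A", "B"]),
        [3, 3],
    )
    yield (
        from_arrays(np.array([[10, 0], [0, 10], [0, 0]]), list("abc"), ["A", "B"]),
        [1, 1, 4],
    )


class TestConditional:
    def test_hand_computed_two_source_case(self):
        """V=2, T=2, n=2, all hyperparameters 1: exact pencil-and-paper value.

        Sources m_A=(3,1), m_B=(0,2); current read carries taxon 0; the other
        read sits on source A; Unknown is empty.  The three unnormalized
        terms are (2/3)(2/4), (1/4)(1/4), (1/2)(1/4) -> (16, 3, 6)/25.
        """
        cfg = GibbsConfig(alpha1=1.0, alpha2=1.0, beta=1.0)
        phi = source_profiles(np.array([[3.0, 1.0], [0.0, 2.0]]), cfg.alpha1)
        p = conditional_assignment_distribution(
            taxon=0,
            counts_excluding_current=np.array([1.0, 0.0, 0.0]),
            source_profiles_matrix=phi,
            unknown_counts_excluding_current=np.zeros(2),
            config=cfg,
            n=2,
            T=2,
        )
        expected = [Fraction(16, 25), Fraction(3, 25), Fraction(6, 25)]
        assert np.allclose(p, [float(f) for f in expected], atol=1e-12)

    def test_dominant_source_limit(self):
        # empty Unknown keeps a floor of 1/T on its taxon factor, so the
        # source probability approaches 1 only as its assigned mass grows
        cfg = GibbsConfig(alpha1=1e-6, alpha2=1e-6, beta=1.0)
        phi = source_profiles(np.array([[1000.0, 0.0]]), cfg.alpha1)
        p = conditional_assignment_distribution(
            0, np.array([500.0, 0.0]), phi, np.zeros(2), cfg, n=501, T=2
        )
        assert p[0] > 0.999

    def test_unknown_mechanism_dominates_for_foreign_taxon(self):
        cfg = GibbsConfig()
        phi = source_profiles(np.array([[100.0, 0.0]]), cfg.alpha1)
        unk = np.array([0.0, 40.0])  # many reads of taxon 1 already on Unknown
        p = conditional_assignment_distribution(
            1, np.array([5.0, 40.0]), phi, unk, cfg, n=46, T=2
        )
        assert p[1] > 0.99

    def test_strictly_positive_and_normalized(self):
        cfg = GibbsConfig()
        phi = source_profiles(np.array([[3.0, 0.0, 1.0], [0.0, 2.0, 0.0]]), cfg.alpha1)
        p = conditional_assignment_distribution(
            2, np.array([1.0, 2.0, 3.0]), phi, np.zeros(3), cfg, n=7, T=3
        )
        assert (p > 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch_raises(self):
        cfg = GibbsConfig()
        phi = source_profiles(np.array([[1.0, 1.0]]), cfg.alpha1)
        with pytest.raises(ValueError, match="dimension"):
            conditional_assignment_distribution(
                0, np.array([1.0]), phi, np.zeros(2), cfg, n=2, T=2
            )


class TestOracle:
    def test_single_read_equals_conditional_closed_form(self):
        src = from_arrays(np.array([[6, 0], [2, 4]]), ["a", "b"], ["A", "B"])
        cfg = GibbsConfig(alpha1=0.5, alpha2=0.5, beta=2.0)
        oracle = enumerate_posterior_oracle(src, [1, 0], cfg)
        phi = source_profiles(src.counts.T.astype(float), cfg.alpha1)
        cond = conditional_assignment_distribution(
            0, np.zeros(3), phi, np.zeros(2), cfg, n=1, T=2
        )
        assert np.allclose(oracle.to_numpy(), cond, atol=1e-12)

    def test_symmetric_sources_give_equal_proportions(self):
        src = from_arrays(np.array([[3, 3], [3, 3]]), ["a", "b"], ["A", "B"])
        oracle = enumerate_posterior_oracle(src, [2, 2], GibbsConfig())
        assert oracle["A"] == pytest.approx(oracle["B"], abs=1e-12)

    def test_instance_too_large_names_bound(self):
        src = from_arrays(np.ones((2, 2), dtype=int), ["a", "b"], ["A", "B"])
        with pytest.raises(ValueError, match="2000000"):
            enumerate_posterior_oracle(src, [20, 20], GibbsConfig())

    @pytest.mark.parametrize("idx", range(4))
    def test_gibbs_matches_enumeration(self, idx):
        """Sampler vs exact posterior mean within 0.02 per component."""
        src, sink = list(small_instances())[idx]
        oracle = enumerate_posterior_oracle(src, np.array(sink), ORACLE_CFG)
        mean, _, _ = fit_sink(src, np.array(sink), ORACLE_CFG)
        assert np.abs(mean - oracle).max() < 0.02


class TestFitSink:
    def test_self_tracking_recovers_single_source(self):
        rng = np.random.default_rng(5)
        profile = rng.dirichlet(np.full(30, 0.3))
        src_counts = rng.multinomial(20_000, profile)[:, None]
        src = from_arrays(src_counts, [f"t{i}" for i in range(30)], ["A"])
        sink = rng.multinomial(2_000, profile)
        cfg = GibbsConfig(seed=1, restarts=3, draws_per_restart=5)
        mean, _, _ = fit_sink(src, sink, cfg)
        assert mean["A"] > 0.9

    def test_foreign_sink_goes_to_unknown(self):
        src = from_arrays(
            np.array([[500], [500], [0], [0]]), list("abcd"), ["A"]
        )
        sink = np.array([0, 0, 600, 400])
        mean, _, _ = fit_sink(src, sink, GibbsConfig(seed=2, restarts=3,
                                                     draws_per_restart=5))
        assert mean[UNKNOWN] > 0.9

    def test_identical_sources_are_exchangeable(self):
        counts = np.array([[300, 300], [200, 200], [100, 100]])
        src = from_arrays(counts, list("abc"), ["A", "B"])
        sink = np.array([30, 20, 10])
        mean, _, _ = fit_sink(src, sink, GibbsConfig(seed=3))
        assert abs(mean["A"] - mean["B"]) < 0.05

    def test_result_invariants(self):
        src = from_arrays(np.array([[40, 5], [5, 40], [10, 10]]),
                          list("abc"), ["A", "B"])
        sink = np.array([25, 10, 15])
        mean, sd, assign = fit_sink(src, sink, GibbsConfig(seed=4))
        assert mean.sum() == pytest.approx(1.0, abs=1e-9)
        assert (sd >= 0).all()
        assert assign.to_numpy().sum() == pytest.approx(50.0, abs=1e-9)
        # proportions are assignment column sums over depth
        assert np.allclose(assign.sum(axis=0) / 50.0, mean, atol=1e-9)

    def test_seed_fixes_every_bit(self):
        src = from_arrays(np.array([[40, 5], [5, 40]]), list("ab"), ["A", "B"])
        sink = np.array([12, 8])
        cfg = GibbsConfig(seed=11, restarts=2, draws_per_restart=3)
        r1 = fit_sink(src, sink, cfg, sink_id="m1")
        r2 = fit_sink(src, sink, cfg, sink_id="m1")
        assert r1[0].equals(r2[0]) and r1[1].equals(r2[1]) and r1[2].equals(r2[2])

    def test_label_equivariance(self):
        # permuting source columns permutes result columns; checked on a tiny
        # instance where both runs sit within 0.01 of the exact posterior
        src = from_arrays(np.array([[6, 1], [1, 5], [2, 2]]),
                          list("abc"), ["A", "B"])
        perm = from_arrays(src.counts[:, ::-1], list("abc"), ["B", "A"])
        sink = np.array([3, 2, 1])
        m1, _, _ = fit_sink(src, sink, ORACLE_CFG)
        m2, _, _ = fit_sink(perm, sink, ORACLE_CFG)
        assert np.allclose(m1[["A", "B", UNKNOWN]], m2[["A", "B", UNKNOWN]],
                           atol=0.02)

    def test_empty_source_set_and_zero_sink_error(self):
        src = from_arrays(np.array([[3]]), ["a"], ["A"])
        with pytest.raises(ValueError, match="zero analyzed reads"):
            fit_sink(src, np.array([0]), GibbsConfig())


class TestTrackAllSinks:
    def _setup(self):
        src = np.array([[80, 2], [2, 80], [10, 10]])
        sinks = np.array([[30, 30], [30, 30], [5, 5]])
        table = from_arrays(np.hstack([src, sinks]), list("abc"),
                            ["sw1", "sw2", "m1", "m2"])
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "role": ["source", "source", "sink", "sink"],
                    "env": ["EnvA", "EnvB", "Meat", "Meat"],
                    "position": [pd.NA, pd.NA, "Truck", "Truck"],
                    "sample_type": ["surface", "surface", "meat", "meat"],
                },
                index=["sw1", "sw2", "m1", "m2"],
            )
        )
        return table, meta

    def test_rows_independent_of_cohort(self):
        table, meta = self._setup()
        cfg = GibbsConfig(seed=9, restarts=2, draws_per_restart=3)
        full = track_all_sinks(table, meta, cfg)
        solo = track_all_sinks(table.select_samples(["sw1", "sw2", "m2"]), meta, cfg)
        assert full.proportions.loc["m2"].equals(solo.proportions.loc["m2"])

    def test_proportions_rows_sum_to_one(self):
        table, meta = self._setup()
        res = track_all_sinks(table, meta, GibbsConfig(seed=1, restarts=2,
                                                       draws_per_restart=3))
        assert np.allclose(res.proportions.sum(axis=1), 1.0, atol=1e-9)
        assert list(res.proportions.columns) == ["EnvA", "EnvB", UNKNOWN]

    def test_empty_sink_set_warns(self):
        table, meta = self._setup()
        sub = table.select_samples(["sw1", "sw2"])  # sources only
        with pytest.warns(UserWarning, match="no sink"):
            res = track_all_sinks(sub, meta, GibbsConfig(seed=0))
        assert len(res.proportions) == 0

    def test_no_sources_is_error(self):
        table, meta = self._setup()
        sub = table.select_samples(["m1", "m2"])
        with pytest.raises(ValueError, match="no source"):
            track_all_sinks(sub, meta, GibbsConfig(seed=0))
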