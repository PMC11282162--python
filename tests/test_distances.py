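import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn
from scipy import stats

from glut4queue import (
    AggregationSpec,
    SampleTable,
    build_ecdf,
    combined_distance,
    experiment_distance,
    extended_point_distance,
    hierarchical_distance,
    ks_distance,
    point_distance,
    wasserstein1_distance,
)

samples = stn.lists(
    stn.floats(-50, 50).map(lambda x: round(x, 3)), min_size=1, max_size=10
)


def riemann_area(a, b, power, refine=64):
    """Independent midpoint-rule oracle for the integrated metrics.

    Every interval between consecutive distinct combined sample values is
    subdivided ``refine`` times and the integrand evaluated at midpoints, so
    no evaluation node ever coincides with an ECDF jump.
    """
    F, G = build_ecdf(a), build_ecdf(b)
    knots = np.union1d(a, b)
    total = 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        x = np.linspace(lo, hi, refine + 1)
        mid = (x[:-1] + x[1:]) / 2
        total += np.sum(np.abs(F(mid) - G(mid)) ** power) * (x[1] - x[0])
    return float(total)


class TestEmpiricalCDF:
    def test_single_point_right_continuity(self):
        P = build_ecdf([5.0])
        assert P(4.9) == 0.0
        assert P(5.0) == 1.0
        assert P(5.1) == 1.0

    def test_counting_and_ties(self):
        P = build_ecdf([1, 2, 3])
        assert P(2) == pytest.approx(2 / 3)
        Q = build_ecdf([2, 2, 4])
        assert Q(2) == pytest.approx(2 / 3)  # jump of 2/3 at the tie
        assert Q(1.999) == 0.0

    def test_rejects_bad_samples(self):
        with pytest.raises(ValueError):
            build_ecdf([])
        with pytest.raises(ValueError):
            build_ecdf([1.0, np.nan])

    @settings(derandomize=True, max_examples=50)
    @given(xs=samples)
    def test_monotone_and_bounded(self, xs):
        P = build_ecdf(xs)
        grid = np.linspace(min(xs) - 1, max(xs) + 1, 101)
        v = P(grid)
        assert np.all(np.diff(v) >= 0)
        assert v[0] == 0.0 or min(xs) <= grid[0]
        assert v[-1] == 1.0


class TestPointMetrics:
    def test_hand_worked_examples(self):
        F, G = build_ecdf([1, 2]), build_ecdf([1, 3])
        assert ks_distance(F, G) == pytest.approx(0.5)
        assert wasserstein1_distance(F, G) == pytest.approx(0.5)
        assert extended_point_distance(F, G, "squared_area") == pytest.approx(0.25)

    def test_identical_samples_give_zero(self):
        F = build_ecdf([0.3, 1.7, 2.2])
        for m in ("ks", "wasserstein1", "kuiper", "cramer_von_mises",
                  "anderson_darling", "signed_area", "squared_area"):
            assert point_distance(F, F, m) == pytest.approx(0.0)

    def test_disjoint_supports_saturate_ks(self):
        F, G = build_ecdf([0, 0, 0]), build_ecdf([10, 10, 10])
        assert ks_distance(F, G) == 1.0
        assert extended_point_distance(F, G, "kuiper") == 1.0

    def test_point_mass_translation(self):
        F, G = build_ecdf([2.0, 2.0]), build_ecdf([5.5, 5.5])
        assert wasserstein1_distance(F, G) == pytest.approx(3.5)

    def test_unknown_metric_rejected(self):
        F = build_ecdf([1.0])
        with pytest.raises(ValueError, match="unknown metric"):
            point_distance(F, F, "hellinger")

    @settings(derandomize=True, max_examples=100)
    @given(a=samples, b=samples)
    def test_against_scipy_and_riemann_oracles(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        F, G = build_ecdf(a), build_ecdf(b)
        assert ks_distance(F, G) == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)
        assert wasserstein1_distance(F, G) == pytest.approx(
            stats.wasserstein_distance(a, b), abs=1e-9
        )
        pooled = np.concatenate([a, b])
        tie_free = len(np.unique(pooled)) == len(pooled)
        if min(len(a), len(b)) >= 2 and tie_free:
            # scipy's rank-based form agrees with the ECDF-sum definition
            # only for tie-free pools (it midranks ties)
            assert extended_point_distance(F, G, "cramer_von_mises") == pytest.approx(
                stats.cramervonmises_2samp(a, b).statistic, abs=1e-9
            )

    @settings(derandomize=True, max_examples=25)
    @given(a=samples, b=samples)
    def test_integrated_metrics_match_fine_grid(self, a, b):
        F, G = build_ecdf(a), build_ecdf(b)
        w1 = wasserstein1_distance(F, G)
        sq = extended_point_distance(F, G, "squared_area")
        assert w1 == pytest.approx(riemann_area(a, b, 1), abs=1e-9)
        assert sq == pytest.approx(riemann_area(a, b, 2), abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(a=samples, b=samples, c=samples)
    def test_metric_axioms(self, a, b, c):
        F, G, H = build_ecdf(a), build_ecdf(b), build_ecdf(c)
        for m in ("ks", "wasserstein1", "kuiper", "cramer_von_mises",
                  "anderson_darling", "squared_area"):
            dFG = point_distance(F, G, m)
            assert dFG >= 0
            assert dFG == pytest.approx(point_distance(G, F, m), abs=1e-9)
        s = extended_point_distance(F, G, "signed_area")
        assert s == pytest.approx(-extended_point_distance(G, F, "signed_area"), abs=1e-12)
        # triangle inequality for the two headline metrics
        for m in ("ks", "wasserstein1"):
            assert point_distance(F, H, m) <= (
                point_distance(F, G, m) + point_distance(G, H, m) + 1e-9
            )

    @settings(derandomize=True, max_examples=40)
    @given(a=samples, b=samples, c=stn.floats(0.1, 10))
    def test_scale_behaviour(self, a, b, c):
        """Scaling both samples by c scales W1 by c and leaves KS unchanged."""
        F, G = build_ecdf(a), build_ecdf(b)
        Fc, Gc = build_ecdf(np.asarray(a) * c), build_ecdf(np.asarray(b) * c)
        assert ks_distance(Fc, Gc) == pytest.approx(ks_distance(F, G), abs=1e-12)
        assert wasserstein1_distance(Fc, Gc) == pytest.approx(
            c * wasserstein1_distance(F, G), rel=1e-9
        )

    def test_kuiper_dominates_ks_and_is_bounded(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(1, 8))
            b = rng.normal(size=rng.integers(1, 8))
            F, G = build_ecdf(a), build_ecdf(b)
            ks, ku = ks_distance(F, G), extended_point_distance(F, G, "kuiper")
            assert ks <= ku <= min(2.0, 2 * ks) + 1e-12

    def test_anderson_darling_matches_direct_formula(self, rng):
        """Independent re-derivation from pooled order statistics."""
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 8)))
            b = rng.normal(size=int(rng.integers(2, 8)))
            n, m = len(a), len(b)
            N = n + m
            z = np.sort(np.concatenate([a, b]))
            total = 0.0
            for i in range(N - 1):
                Fz = np.sum(a <= z[i]) / n
                Gz = np.sum(b <= z[i]) / m
                H = (i + 1) / N
                if 0 < H < 1:
                    total += (Fz - Gz) ** 2 / (H * (1 - H))
            expected = n * m / N * total
            got = extended_point_distance(build_ecdf(a), build_ecdf(b), "anderson_darling")
            assert got == pytest.approx(expected, abs=1e-9)

    def test_ks_attains_at_most_n_times_m_values(self, rng):
        """Discreteness: the KS distance between samples of sizes (n, m) is
        |i/n - j/m|, so at most n*m distinct values are attainable."""
        for n, m in itertools.product(range(1, 6), range(1, 6)):
            seen = set()
            for _ in range(300):
                a, b = rng.normal(size=n), rng.normal(size=m)
                d = ks_distance(build_ecdf(a), build_ecdf(b))
                seen.add(round(d, 9))
                attainable = any(
                    abs(d - abs(i / n - j / m)) < 1e-9
                    for i in range(n + 1)
                    for j in range(m + 1)
                )
                assert attainable
            assert len(seen) <= n * m


class TestAggregation:
    def test_examples(self):
        assert experiment_distance([0.1, 0.3, 0.5], AggregationSpec("mean")) == pytest.approx(0.3)
        assert experiment_distance([3, 4], AggregationSpec("l2")) == pytest.approx(5.0)
        assert experiment_distance([0.2, 0.4], AggregationSpec("max")) == pytest.approx(0.4)
        assert experiment_distance([0.2, 0.4], AggregationSpec("min")) == pytest.approx(0.2)

    def test_weights(self):
        spec = AggregationSpec("mean", weights=[2.0, 0.0])
        assert experiment_distance([0.5, 9.0], spec) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            AggregationSpec("mean", weights=[-1.0])
        with pytest.raises(ValueError):
            experiment_distance([1.0], AggregationSpec("mean", weights=[1.0, 1.0]))
        with pytest.raises(ValueError):
            AggregationSpec("median")

    def test_combined_examples(self):
        assert combined_distance([3, 4]) == pytest.approx(5.0)
        assert combined_distance([0.7]) == pytest.approx(0.7)
        assert combined_distance([1, 1, 1], [4, 0, 0]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            combined_distance([1, 2], [1.0])
        with pytest.raises(ValueError):
            combined_distance([1.0], [-1.0])


def _table_from_values(values_by_exp_time, role="data"):
    rows = [
        (e, t, k, v)
        for (e, t), vals in values_by_exp_time.items()
        for k, v in enumerate(vals)
    ]
    return SampleTable(frame=pd.DataFrame(rows, columns=SampleTable.COLUMNS), role=role)


class TestHierarchical:
    def test_identical_tables_give_zero(self, synthetic_dataset):
        hd = hierarchical_distance(synthetic_dataset.table, synthetic_dataset.table)
        assert hd.combined == 0.0
        for d in hd.point_distances.values():
            assert np.all(d == 0.0)

    def test_single_shared_time_point_reduces_to_point_distance(self):
        a = _table_from_values({("transition", 30.0): [1.0, 2.0]})
        b = _table_from_values({("transition", 30.0): [1.0, 3.0]}, role="model")
        hd = hierarchical_distance(a, b, metric="wasserstein1")
        assert hd.combined == pytest.approx(0.5)
        assert hd.experiment_distances["transition"] == pytest.approx(0.5)

    def test_time_grid_mismatch_is_an_error(self):
        a = _table_from_values({("transition", 30.0): [1.0]})
        b = _table_from_values({("transition", 31.0): [1.0]}, role="model")
        with pytest.raises(ValueError, match="time grids differ"):
            hierarchical_distance(a, b)

    def test_experiment_set_mismatch_is_an_error(self):
        a = _table_from_values({("transition", 30.0): [1.0]})
        b = _table_from_values({("basal_uptake", 30.0): [1.0]}, role="model")
        with pytest.raises(ValueError, match="experiment sets differ"):
            hierarchical_distance(a, b)

    def test_real_tables_nonnegative_and_consistent(self, synthetic_dataset, model_table):
        hd = hierarchical_distance(synthetic_dataset.table, model_table)
        assert hd.combined >= 0
        D = [hd.experiment_distances[e] for e in sorted(hd.experiment_distances)]
        assert hd.combined == pytest.approx(np.sqrt(np.sum(np.square(D))))
        report = hd.to_dict()
        assert set(report["experiment_distances"]) == set(hd.point_distances)

    def test_unequal_replicate_counts_allowed(self):
        a = _table_from_values({("transition", 0.0): [1.0, 2.0, 3.0]})
        b = _table_from_values({("transition", 0.0): [1.5, 2.5]}, role="model")
        hd = hierarchical_distance(a, b, metric="ks")
        assert 0 < hd.combined <= 1
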