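import numpy as np
import pytest

from crabmap import prioritization as pz
from crabmap.pipeline import random_ranking
from conftest import binary_range, km_template


class TestAssignWeights:
    def test_median_rule_and_zero_sum(self):
        t = km_template(8, 8)
        ranges = {}
        for name, n in zip("abcd", (10, 20, 30, 40)):
            g = np.zeros(64)
            g[:n] = 1
            ranges[name] = binary_range(name, t, g.reshape(8, 8))
        w = pz.assign_weights(ranges)
        assert list(w.species_weights[list("abcd")]) == [1, 1, 2, 2]
        assert w.built_weight == -6

    def test_single_species_is_at_its_own_median(self):
        t = km_template(4, 4)
        g = np.zeros((4, 4))
        g[0, 0] = 1
        w = pz.assign_weights({"only": binary_range("only", t, g)})
        assert w.species_weights["only"] == 2
        assert w.built_weight == -2

    @pytest.mark.parametrize("seed", range(100))
    def test_weights_always_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        t = km_template(6, 6)
        ranges = {}
        for i in range(int(rng.integers(1, 12))):
            g = np.zeros(36)
            g[: int(rng.integers(1, 36))] = 1
            ranges[f"s{i}"] = binary_range(f"s{i}", t, rng.permutation(g).reshape(6, 6))
        w = pz.assign_weights(ranges)
        assert float(w.species_weights.sum()) + w.built_weight == 0


class TestCazRank:
    def test_toy_removal_order(self):
        # species A in cells 0,1 (w=1); B in cell 2 (w=1): the shared-cell
        # species loses half a range cheaply, so 0 then 1 go first and the
        # single-cell endemic's cell is ranked top
        t = km_template(1, 3)
        ranges = {"A": binary_range("A", t, [[1, 1, 0]]),
                  "B": binary_range("B", t, [[0, 0, 1]])}
        w = pz.FeatureWeights(ranges_weights(ranges), -2.0, 1.5)
        rk = pz.caz_rank(ranges, w, warp=1)
        assert list(rk.removal_order) == [0, 1, 2]
        assert rk.rank_fraction.values[0, 2] == 1.0

    def test_toy_curve_value(self):
        t = km_template(1, 3)
        ranges = {"A": binary_range("A", t, [[1, 1, 0]]),
                  "B": binary_range("B", t, [[0, 0, 1]])}
        w = pz.FeatureWeights(ranges_weights(ranges), -2.0, 1.5)
        rk = pz.caz_rank(ranges, w, warp=1)
        curve = pz.performance_curve(rk, ranges, fractions=[0, 1 / 3, 1])
        assert curve.mean_retained[0] == 0.0
        assert curve.mean_retained[1] == pytest.approx(0.5)  # B kept, A lost
        assert curve.mean_retained[2] == 1.0

    def test_masked_cell_removed_last(self):
        t = km_template(1, 3)
        ranges = {"A": binary_range("A", t, [[1, 1, 0]]),
                  "B": binary_range("B", t, [[0, 0, 1]])}
        mask = t.like([[1, 0, 0]])
        rk = pz.caz_rank(ranges, mask=mask, warp=1)
        assert rk.removal_order[-1] == 0

    def test_full_warp_is_single_batch_of_initial_deltas(self):
        rng = np.random.default_rng(2)
        t = km_template(4, 4)
        ranges = {}
        for i in range(3):
            g = (rng.random((4, 4)) < 0.4).astype(float)
            if g.sum() == 0:
                g[0, 0] = 1
            ranges[f"s{i}"] = binary_range(f"s{i}", t, g)
        rk = pz.caz_rank(ranges, warp=16)
        # single batch: order equals ascending initial delta with index ties
        sizes = {sp: ranges[sp].presence.values.sum() for sp in ranges}
        w = pz.assign_weights(ranges).species_weights
        delta = np.zeros(16)
        for j in range(16):
            delta[j] = max(w[sp] * ranges[sp].presence.values.ravel()[j] / sizes[sp]
                           for sp in ranges)
        expect = np.lexsort((np.arange(16), delta))
        assert np.array_equal(rk.removal_order, expect)

    @pytest.mark.parametrize("seed", range(8))
    def test_warp1_matches_exhaustive_simulator(self, seed):
        rng = np.random.default_rng(seed)
        nr, nc = rng.integers(2, 5, 2)
        t = km_template(int(nr), int(nc))
        n_sp = int(rng.integers(1, 5))
        ranges = {}
        for i in range(n_sp):
            g = (rng.random((nr, nc)) < 0.5).astype(float)
            if g.sum() == 0:
                g[0, 0] = 1
            ranges[f"s{i}"] = binary_range(f"s{i}", t, g)
        built = t.like(rng.random((nr, nc))) if seed % 2 else None
        rk = pz.caz_rank(ranges, built=built, warp=1)
        brute = pz.caz_rank_bruteforce(ranges, built=built)
        assert np.array_equal(rk.removal_order, brute)

    def test_invalid_warp(self):
        t = km_template(2, 2)
        ranges = {"a": binary_range("a", t, [[1, 0], [0, 0]])}
        with pytest.raises(ValueError, match="warp"):
            pz.caz_rank(ranges, warp=0)


def ranges_weights(ranges):
    import pandas as pd
    return pd.Series({sp: 1.0 for sp in ranges})


class TestPerformanceCurve:
    def test_fixed_points(self, pipeline_result):
        curve = pipeline_result.curve
        assert curve.at(0.0) == 0.0
        assert curve.at(1.0) == 1.0

    def test_per_species_monotone(self, pipeline_result):
        per = pipeline_result.curve.per_species.to_numpy()
        assert (np.diff(per, axis=1) >= -1e-12).all()

    def test_fraction_bounds_enforced(self, pipeline_result):
        with pytest.raises(ValueError):
            pipeline_result.curve.at(1.5)
        with pytest.raises(ValueError):
            pz.performance_curve(pipeline_result.ranking, pipeline_result.ranges,
                                 fractions=[-0.1])

    def test_coverage_table_monotone(self, pipeline_result):
        cov = pz.coverage_at_fraction(pipeline_result.curve)
        vals = cov["mean_retained"].to_numpy()
        assert vals[0] <= vals[1] <= vals[2]

    def test_caz_dominates_random_over_seeds(self):
        # small landscapes, 10 random seeds: CAZ mean curve ≥ random at all f
        fractions = np.linspace(0, 1, 21)
        diffs = np.zeros(len(fractions))
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = km_template(20, 20)
            ranges = {}
            for i in range(8):
                g = np.zeros(400)
                k = int(rng.integers(5, 80))
                start = int(rng.integers(0, 400 - k))
                g[start:start + k] = 1
                ranges[f"s{i}"] = binary_range(f"s{i}", t, g.reshape(20, 20))
            rk = pz.caz_rank(ranges, warp=1)
            cz = pz.performance_curve(rk, ranges, fractions)
            rr = random_ranking(t, seed)
            rc = pz.performance_curve(rr, ranges, fractions)
            diffs += cz.mean_retained - rc.mean_retained
        assert (diffs >= -1e-9).all()
        assert diffs[1:-1].mean() > 0
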