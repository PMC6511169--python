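import itertools
import json
import math

import numpy as np
import pytest

from raospace import (
    AngleSample,
    OffGridWarning,
    PerturbationScaleWarning,
    RandomizationConfig,
    normalize_angles,
    p_from_counts,
    perturb,
    rao_u,
    round_to_bins,
    runiform_circular,
    test_continuous as run_continuous,
    test_discrete as run_discrete,
)
from raospace.angles import TWO_PI, rao_u_rows

pytestmark = pytest.mark.filterwarnings(
    "ignore::raospace.PerturbationScaleWarning")


class TestPFromCounts:
    @pytest.mark.parametrize(
        "ne, nr, expected",
        [(0, 10_000, 1 / 10_001), (10_000, 10_000, 1.0),
         (499, 9_999, 0.05), (0, 1, 0.5)],
    )
    def test_formula(self, ne, nr, expected):
        assert p_from_counts(ne, nr) == pytest.approx(expected)

    @pytest.mark.parametrize("ne, nr", [(-1, 10), (11, 10)])
    def test_counts_out_of_range(self, ne, nr):
        with pytest.raises(ValueError):
            p_from_counts(ne, nr)


class TestPerturb:
    def test_spread_matches_large_kappa_approximation(self):
        # circular SD of von Mises(0, kappa) ~ kappa**-0.5 for large kappa
        rng = np.random.default_rng(1)
        base = AngleSample(values=np.full(200_000, math.pi))
        jittered = perturb(base, 1000.0, rng)
        sd = np.std(jittered.values - math.pi)
        assert sd == pytest.approx(1000.0 ** -0.5, rel=0.02)

    def test_wraps_past_two_pi(self):
        rng = np.random.default_rng(2)
        base = AngleSample(values=np.full(500, TWO_PI - 1e-9))
        out = perturb(base, 1000.0, rng)
        assert np.all(out.values >= 0) and np.all(out.values < TWO_PI)
        # roughly half the jitter pushes past the 0/2pi seam
        assert np.sum(out.values < 1.0) > 100

    def test_huge_kappa_converges_to_original(self):
        rng = np.random.default_rng(3)
        base = runiform_circular(50, rng)
        out = perturb(base, 1e12, rng)
        assert out.values == pytest.approx(base.values, abs=1e-4)


class TestRoundToBins:
    @pytest.mark.parametrize(
        "deg, bins, expected_deg",
        [(123.4, 36, 120.0), (355.1, 36, 0.0),
         (0.4, 360, 0.0), (359.6, 360, 0.0)],
    )
    def test_nearest_multiple_with_wrap(self, deg, bins, expected_deg):
        s = normalize_angles([deg, deg], unit="degrees")
        out = round_to_bins(s, bins)
        assert out.values == pytest.approx(
            [math.radians(expected_deg)] * 2, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        s = round_to_bins(runiform_circular(100, rng), 36)
        again = round_to_bins(s, 36)
        assert np.array_equal(s.values, again.values)

    def test_output_on_grid(self):
        rng = np.random.default_rng(5)
        out = round_to_bins(runiform_circular(500, rng), 7)
        ratio = out.values / (TWO_PI / 7)
        assert np.allclose(ratio, np.round(ratio), atol=1e-9)


class TestContinuous:
    def test_equal_spacing_gives_p_one(self):
        n = 12
        s = normalize_angles([i * TWO_PI / n for i in range(n)],
                             unit="radians")
        res = run_continuous(s, RandomizationConfig(n_resamples=500, seed=0))
        assert res.p_value == 1.0
        assert res.n_exceed == 500

    def test_coincident_gives_minimum_p(self):
        s = AngleSample(values=np.full(10, 2.0))
        res = run_continuous(s, RandomizationConfig(n_resamples=500, seed=0))
        assert res.p_value == pytest.approx(1 / 501)
        assert res.n_exceed == 0

    def test_p_value_bounds(self):
        rng = np.random.default_rng(6)
        for i in range(20):
            s = runiform_circular(15, rng)
            res = run_continuous(
                s, RandomizationConfig(n_resamples=99, seed=i))
            assert 1 / 100 <= res.p_value <= 1.0
            assert 0 <= res.n_exceed <= 99

    def test_bit_reproducible(self):
        rng = np.random.default_rng(7)
        s = runiform_circular(30, rng)
        cfg = RandomizationConfig(n_resamples=3000, seed=123)
        a, b = run_continuous(s, cfg), run_continuous(s, cfg)
        assert a == b
        assert a.to_json() == b.to_json()

    def test_batching_invariance(self):
        # results must not depend on the internal batch layout
        from raospace import randomization

        rng = np.random.default_rng(8)
        s = runiform_circular(20, rng)
        cfg = RandomizationConfig(n_resamples=5000, seed=9)
        base = run_continuous(s, cfg)
        assert base.n_resamples == 5000
        # a resample count not divisible by the batch size still works
        cfg2 = RandomizationConfig(n_resamples=randomization._BATCH_ROWS + 7,
                                   seed=9)
        res2 = run_continuous(s, cfg2)
        assert res2.n_exceed <= cfg2.n_resamples

    def test_rejects_discrete_config(self):
        s = runiform_circular(10, 1)
        with pytest.raises(ValueError, match="test_discrete"):
            run_continuous(s, RandomizationConfig(n_bins=36))

    def test_null_p_distribution_sub_uniform(self):
        """Under a continuous uniform null, P(p <= a) must not exceed
        a + 3 SE for a in {0.01, 0.05, 0.1}."""
        rng = np.random.default_rng(10)
        reps, nr = 2000, 400
        pvals = np.empty(reps)
        for i in range(reps):
            s = runiform_circular(20, rng)
            pvals[i] = run_continuous(
                s, RandomizationConfig(n_resamples=nr, seed=50_000 + i)
            ).p_value
        for a in (0.01, 0.05, 0.1):
            se = math.sqrt(a * (1 - a) / reps)
            assert (pvals <= a).mean() <= a + 3 * se


class TestDiscrete:
    def test_bit_reproducible(self):
        s = round_to_bins(runiform_circular(40, 11), 36)
        cfg = RandomizationConfig(n_resamples=1000, seed=5, n_bins=36)
        assert run_discrete(s, cfg) == run_discrete(s, cfg)

    def test_off_grid_strict_raises(self):
        s = runiform_circular(20, 12)  # continuous, not on any grid
        cfg = RandomizationConfig(n_resamples=50, seed=1, n_bins=36)
        with pytest.raises(ValueError, match="grid"):
            run_discrete(s, cfg, strict=True)

    def test_off_grid_permissive_rounds_with_warning(self):
        s = runiform_circular(20, 12)
        cfg = RandomizationConfig(n_resamples=200, seed=1, n_bins=36)
        with pytest.warns(OffGridWarning):
            res = run_discrete(s, cfg, strict=False)
        ref = run_discrete(round_to_bins(s, 36), cfg)
        assert res == ref

    def test_perturbation_scale_warning(self):
        s = round_to_bins(runiform_circular(20, 13), 360)
        cfg = RandomizationConfig(n_resamples=10, seed=1, n_bins=360,
                                  kappa=1000.0)
        with pytest.warns(PerturbationScaleWarning):
            run_discrete(s, cfg)

    def test_no_warning_when_kappa_large_enough(self):
        import warnings

        s = round_to_bins(runiform_circular(20, 13), 36)
        cfg = RandomizationConfig(n_resamples=10, seed=1, n_bins=36,
                                  kappa=5000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerturbationScaleWarning)
            run_discrete(s, cfg)

    def test_rejects_continuous_config(self):
        s = runiform_circular(10, 1)
        with pytest.raises(ValueError, match="test_continuous"):
            run_discrete(s, RandomizationConfig())

    def test_single_occupied_bin_extreme_p(self):
        # all mass in one of two bins with large n: maximal clustering
        s = AngleSample(values=np.zeros(40) + 0.0)
        cfg = RandomizationConfig(n_resamples=400, seed=3, n_bins=2,
                                  kappa=5000.0)
        res = run_discrete(s, cfg)
        assert res.p_value <= 5 / 401

    def test_monotone_severity(self):
        """Concentrating the sample into fewer bins should not raise the
        average p-value."""
        n, bins = 36, 36
        width = TWO_PI / bins
        spread = AngleSample(values=np.sort(np.arange(n) % bins * width))
        clumped = AngleSample(values=np.sort(np.arange(n) % 6 * width))
        p_spread, p_clump = [], []
        for seed in range(15):
            cfg = RandomizationConfig(n_resamples=300, seed=seed,
                                      n_bins=bins)
            p_spread.append(run_discrete(spread, cfg).p_value)
            p_clump.append(run_discrete(clumped, cfg).p_value)
        assert np.mean(p_clump) <= np.mean(p_spread)

    def test_json_round_trip(self):
        s = round_to_bins(runiform_circular(20, 14), 36)
        cfg = RandomizationConfig(n_resamples=100, seed=21, n_bins=36)
        res = run_discrete(s, cfg)
        d = json.loads(res.to_json())
        assert d["p_value"] == res.p_value
        assert d["n_exceed"] == res.n_exceed
        assert d["method"] == "discrete-simulation"
        assert d["kappa"] == 1000.0


class TestDiscreteEnumerationOracle:
    """For tiny n and few bins the null distribution of the unperturbed U
    over rounded uniform samples can be enumerated exactly; Monte-Carlo
    exceedance frequencies must agree."""

    @pytest.mark.parametrize("n, bins", [(4, 6), (5, 8), (3, 4)])
    def test_mc_matches_enumeration(self, n, bins):
        width = TWO_PI / bins
        u_all = np.array([
            rao_u(AngleSample(values=np.sort(np.array(combo) * width))
                  ).u_radians
            for combo in itertools.product(range(bins), repeat=n)
        ])
        rng = np.random.default_rng(1234)
        draws = rng.integers(0, bins, size=(20_000, n)) * width
        draws.sort(axis=1)
        u_mc = rao_u_rows(draws)
        for q in (0.25, 0.5, 0.75):
            u0 = np.quantile(u_all, q)
            exact = (u_all >= u0 - 1e-12).mean()
            mc = (u_mc >= u0 - 1e-12).mean()
            se = math.sqrt(exact * (1 - exact) / 20_000)
            assert abs(mc - exact) <= 3 * se + 1e-12, (n, bins, q)

    def test_null_p_distribution_sub_uniform_discrete(self):
        """Rounded-uniform null: the discrete test's P(p <= a) <= a + 3 SE."""
        rng = np.random.default_rng(20)
        reps, nr, bins = 2000, 300, 36
        pvals = np.empty(reps)
        for i in range(reps):
            s = round_to_bins(runiform_circular(25, rng), bins)
            pvals[i] = run_discrete(
                s, RandomizationConfig(n_resamples=nr, seed=80_000 + i,
                                       n_bins=bins)).p_value
        for a in (0.01, 0.05, 0.1):
            se = math.sqrt(a * (1 - a) / reps)
            assert (pvals <= a).mean() <= a + 3 * se
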