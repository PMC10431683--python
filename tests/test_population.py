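import numpy as np
import pytest
from scipy import stats

from ceqpbpk import (
    DosingRegimen,
    ParameterDistribution,
    percentiles,
    sample_parameters,
    simulate,
    simulate_population,
    truncation_bounds,
)
from ceqpbpk.population import DEFAULT_DISTRIBUTIONS

# Published truncation bounds for each sampled parameter:
# (name, family, mean, CV, lower, upper)
BOUND_TABLE = [
    ("QCC", "normal", 4.944, 0.30, 2.04, 7.85),
    ("QKC", "normal", 0.1398, 0.30, 0.06, 0.22),
    ("PL", "lognormal", 6.00, 0.20, 3.99, 8.67),
    ("PK", "lognormal", 15.2, 0.20, 10.11, 21.97),
    ("PM", "lognormal", 0.10, 0.20, 0.07, 0.14),
    ("PR", "lognormal", 0.10, 0.20, 0.07, 0.14),
    ("PLU", "lognormal", 1.50, 0.20, 1.00, 2.17),
    ("KIT", "lognormal", 3.56, 0.30, 1.92, 6.06),
    ("KTI", "lognormal", 2.60, 0.30, 1.40, 4.43),
    ("KurineC", "lognormal", 0.30, 0.30, 0.16, 0.51),
    ("PT", "lognormal", 0.30, 0.30, 0.16, 0.51),
]


class TestTruncationBounds:
    @pytest.mark.parametrize("name,family,mean,cv,lower,upper", BOUND_TABLE)
    def test_bounds_match_reference_table(self, name, family, mean, cv, lower, upper):
        lo, hi = truncation_bounds(family, mean, cv)
        assert lo == pytest.approx(lower, abs=0.01), name
        assert hi == pytest.approx(upper, abs=0.01), name

    def test_zero_cv_collapses_to_point(self):
        assert truncation_bounds("normal", 5.0, 0.0) == (5.0, 5.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            truncation_bounds("normal", -1.0, 0.3)
        with pytest.raises(ValueError):
            truncation_bounds("gamma", 1.0, 0.3)

    def test_default_distributions_cover_the_influential_set(self):
        names = {d.name for d in DEFAULT_DISTRIBUTIONS}
        assert names == {"QCC", "QKC", "PL", "PK", "PM", "PR", "PLU",
                         "KIT", "KTI", "KurineC", "PT"}


class TestSampling:
    def test_large_sample_mean_and_bounds(self):
        d = ParameterDistribution("QCC", "normal", 4.944, 0.30)
        x = d.sample(100_000, np.random.default_rng(0))
        assert x.mean() == pytest.approx(4.944, rel=0.01)
        lo, hi = d.bounds
        assert x.min() >= lo and x.max() <= hi

    def test_same_seed_reproduces_matrix(self):
        a = sample_parameters(DEFAULT_DISTRIBUTIONS, 50, seed=123)
        b = sample_parameters(DEFAULT_DISTRIBUTIONS, 50, seed=123)
        assert a.equals(b)

    def test_zero_cv_gives_constant_draws(self):
        d = ParameterDistribution("PT", "lognormal", 0.30, 0.0)
        assert np.all(d.sample(10, np.random.default_rng(1)) == 0.30)

    def test_rejection_preserves_truncated_lognormal_density(self):
        """KS test of draws against the analytic truncated CDF."""
        d = ParameterDistribution("KurineC", "lognormal", 0.30, 0.30)
        x = d.sample(100_000, np.random.default_rng(5))
        sigma = np.sqrt(np.log1p(0.3**2))
        mu = np.log(0.3) - sigma**2 / 2
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        lo, hi = d.bounds
        p_lo, p_hi = dist.cdf(lo), dist.cdf(hi)

        def trunc_cdf(v):
            return (dist.cdf(v) - p_lo) / (p_hi - p_lo)

        ks = stats.kstest(x, trunc_cdf)
        assert ks.pvalue > 0.01


class TestPopulationSimulation:
    def test_degenerate_population_equals_deterministic(self, phys, chem, single_dose):
        point = tuple(ParameterDistribution(d.name, d.family, d.mean, 0.0)
                      for d in DEFAULT_DISTRIBUTIONS)
        ens = simulate_population(phys, chem, single_dose, 12.0,
                                  distributions=point, n=5, seed=0,
                                  compartments=("plasma",))
        det = simulate(phys, chem, single_dose, 12.0)
        for i in range(5):
            assert np.allclose(ens.traces["plasma"][i], det.trace("plasma"))

    def test_median_tracks_deterministic_within_mc_error(self, phys, chem, single_dose):
        ens = simulate_population(phys, chem, single_dose, 24.0, n=200, seed=4,
                                  compartments=("plasma",))
        det = simulate(phys, chem, single_dose, 24.0)
        med = percentiles(ens, "plasma", 50.0)[0]
        peak = det.trace("plasma").max()
        mask = det.trace("plasma") > 0.05 * peak
        rel = np.abs(med[mask] - det.trace("plasma")[mask]) / det.trace("plasma")[mask]
        # The population median sits slightly below the mean-parameter run
        # (lognormal medians are below their means); 20% covers that shift
        # plus Monte Carlo error at n=200.
        assert np.median(rel) < 0.20

    def test_bands_widen_with_cv(self, phys, chem, single_dose):
        widths = []
        for scale in (0.5, 1.0, 2.0):
            dists = tuple(ParameterDistribution(d.name, d.family, d.mean, d.cv * scale)
                          for d in DEFAULT_DISTRIBUTIONS)
            ens = simulate_population(phys, chem, single_dose, 12.0,
                                      distributions=dists, n=150, seed=9,
                                      compartments=("plasma",))
            p10, p90 = percentiles(ens, "plasma", (10.0, 90.0))
            widths.append(np.trapezoid(p90 - p10, ens.time))
        assert widths[0] < widths[1] < widths[2]

    def test_single_individual_percentiles_equal_trace(self, phys, chem, single_dose):
        ens = simulate_population(phys, chem, single_dose, 6.0, n=1, seed=2,
                                  compartments=("plasma",))
        for p in (5.0, 50.0, 95.0):
            assert np.allclose(percentiles(ens, "plasma", p)[0],
                               ens.traces["plasma"][0])

    def test_percentile_traces_are_ordered(self, phys, chem, single_dose):
        ens = simulate_population(phys, chem, single_dose, 12.0, n=100, seed=3,
                                  compartments=("plasma",))
        p10, p50, p90 = percentiles(ens, "plasma", (10.0, 50.0, 90.0))
        assert np.all(p10 <= p50 + 1e-12) and np.all(p50 <= p90 + 1e-12)

    def test_sampled_parameters_respect_bounds(self, phys, chem, single_dose):
        ens = simulate_population(phys, chem, single_dose, 6.0, n=100, seed=8,
                                  compartments=("plasma",))
        for d in DEFAULT_DISTRIBUTIONS:
            lo, hi = d.bounds
            col = ens.parameters[d.name]
            assert col.min() >= lo and col.max() <= hi

    def test_ensemble_reproducible_end_to_end(self, phys, chem, single_dose):
        a = simulate_population(phys, chem, single_dose, 6.0, n=20, seed=77,
                                compartments=("plasma",))
        b = simulate_population(phys, chem, single_dose, 6.0, n=20, seed=77,
                                compartments=("plasma",))
        assert np.array_equal(a.traces["plasma"], b.traces["plasma"])
        assert a.parameters.equals(b.parameters)

    def test_invalid_percentile_probs_rejected(self, phys, chem, single_dose):
        ens = simulate_population(phys, chem, single_dose, 6.0, n=3, seed=1,
                                  compartments=("plasma",))
        with pytest.raises(ValueError):
            percentiles(ens, "plasma", (0.0,))
        with pytest.raises(KeyError):
            percentiles(ens, "liver", (50.0,))
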