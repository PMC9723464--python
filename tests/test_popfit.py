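"""Distribution building, two-Gaussian decomposition and replicate statistics."""
import numpy as np
import pytest
from scipy.stats import norm

from nucfret import (
    ConditionSpec,
    EprDistribution,
    GaussianPeak,
    build_distribution,
    compute_epr,
    estimate_fractions,
    fit_two_gaussians,
    simulate_bursts,
    summarize_replicates,
    two_state_species,
)

SQRT_2PI = np.sqrt(2 * np.pi)


def analytic_two_gaussian_distribution(
    mu=(0.15, 0.70), sigma=(0.08, 0.08), areas=(0.3, 0.7), bin_width=0.05, rng=(-0.25, 1.25)
):
    """Exact bin probabilities of a two-Gaussian mixture (via the normal CDF)."""
    edges = rng[0] + bin_width * np.arange(round((rng[1] - rng[0]) / bin_width) + 1)
    probs = np.zeros(len(edges) - 1)
    for m, s, a in zip(mu, sigma, areas):
        probs += a * np.diff(norm.cdf(edges, loc=m, scale=s))
    probs /= probs.sum()
    return EprDistribution(bin_edges=edges, frequencies=probs, n_bursts=10_000)


class TestBuildDistribution:
    def test_single_value_single_bin(self):
        dist = build_distribution([0.5] * 100, bin_width=0.05, value_range=(0.0, 1.0))
        assert dist.frequencies.max() == pytest.approx(1.0)
        assert np.count_nonzero(dist.frequencies) == 1

    def test_frequencies_sum_to_one_with_outliers_clipped(self):
        values = np.concatenate([np.linspace(-1.0, 2.0, 50), [0.5] * 50])
        dist = build_distribution(values, value_range=(-0.25, 1.25))
        assert dist.frequencies.sum() == pytest.approx(1.0)
        assert dist.n_bursts == 100

    def test_modal_mass_of_gaussian_sample(self):
        """For Normal(0.7, 0.05) the 0.05-wide modal bin holds ~38% of mass."""
        rng = np.random.default_rng(3)
        dist = build_distribution(rng.normal(0.7, 0.05, size=1000), bin_width=0.05)
        assert dist.frequencies.max() == pytest.approx(0.38, abs=0.05)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_distribution([])


class TestFitTwoGaussians:
    def test_recovers_analytic_mixture(self):
        """Self-consistency: exact two-Gaussian input returns its parameters."""
        dist = analytic_two_gaussian_distribution()
        fit = fit_two_gaussians(dist)
        assert fit.converged and not fit.degenerate
        assert fit.peak_lf.mean == pytest.approx(0.15, abs=1e-3)
        assert fit.peak_hf.mean == pytest.approx(0.70, abs=1e-3)
        assert fit.peak_lf.sigma == pytest.approx(0.08, abs=2e-3)
        assert fit.fraction_lf == pytest.approx(0.3, abs=1e-3)
        assert fit.fraction_hf == pytest.approx(0.7, abs=1e-3)

    def test_single_species_sample_is_nearly_pure_hf(self):
        spec = ConditionSpec("t", two_state_species(0.0), n_bursts=4000, seed=9)
        bursts = simulate_bursts(spec)
        epr = compute_epr(
            bursts["intensity_acceptor"].to_numpy(), bursts["intensity_donor"].to_numpy()
        )
        fit = fit_two_gaussians(build_distribution(epr))
        assert fit.fraction_hf >= 0.95

    def test_mirror_symmetry_of_weights(self):
        """Swapping species weights swaps the LF and HF fractions."""
        fits = []
        for weight_lf in (0.3, 0.7):
            spec = ConditionSpec("t", two_state_species(weight_lf), n_bursts=6000, seed=21)
            bursts = simulate_bursts(spec)
            epr = compute_epr(
                bursts["intensity_acceptor"].to_numpy(),
                bursts["intensity_donor"].to_numpy(),
            )
            fits.append(fit_two_gaussians(build_distribution(epr)))
        assert fits[0].fraction_lf == pytest.approx(fits[1].fraction_hf, abs=0.03)

    def test_fractions_sum_to_one_by_construction(self):
        fit = fit_two_gaussians(analytic_two_gaussian_distribution(areas=(0.45, 0.55)))
        assert fit.fraction_lf + fit.fraction_hf == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_range_padding(self):
        """Padding the histogram range with empty bins leaves the fit unchanged."""
        narrow = analytic_two_gaussian_distribution(rng=(-0.25, 1.25))
        wide = analytic_two_gaussian_distribution(rng=(-0.75, 1.75))
        fit_narrow = fit_two_gaussians(narrow)
        fit_wide = fit_two_gaussians(wide)
        assert fit_wide.fraction_lf == pytest.approx(fit_narrow.fraction_lf, abs=1e-4)
        assert fit_wide.peak_hf.mean == pytest.approx(fit_narrow.peak_hf.mean, abs=1e-4)

    def test_too_few_bins_rejected(self):
        dist = build_distribution([0.5] * 100, bin_width=0.05, value_range=(0.0, 1.0))
        with pytest.raises(ValueError, match="nonempty bins"):
            fit_two_gaussians(dist)

    def test_init_override_honored(self):
        dist = analytic_two_gaussian_distribution()
        fit = fit_two_gaussians(dist, init={"mu_1": 0.1, "mu_2": 0.8})
        assert fit.fraction_lf == pytest.approx(0.3, abs=1e-3)


class TestEstimateFractions:
    def test_equal_peaks_split_evenly(self):
        peak = GaussianPeak(1.0, 0.2, 0.05)
        other = GaussianPeak(1.0, 0.7, 0.05)
        assert estimate_fractions(peak, other) == pytest.approx((0.5, 0.5))

    def test_amplitude_proportionality(self):
        lf = GaussianPeak(2.0, 0.2, 0.05)
        hf = GaussianPeak(1.0, 0.7, 0.05)
        assert estimate_fractions(lf, hf) == pytest.approx((2 / 3, 1 / 3))

    def test_sigma_weighting(self):
        lf = GaussianPeak(1.0, 0.2, 0.05)
        hf = GaussianPeak(1.0, 0.7, 0.10)
        assert estimate_fractions(lf, hf) == pytest.approx((1 / 3, 2 / 3))

    def test_zero_areas_rejected(self):
        with pytest.raises(ValueError):
            estimate_fractions(GaussianPeak(0.0, 0.2, 0.05), GaussianPeak(0.0, 0.7, 0.05))


class TestSummarizeReplicates:
    def test_mean_and_sem(self):
        summary = summarize_replicates("c", [0.4, 0.5, 0.6])
        assert summary.mean_fraction_lf == pytest.approx(0.5)
        assert summary.sem_fraction_lf == pytest.approx(0.1 / np.sqrt(3), abs=1e-4)
        assert summary.n_replicates == 3

    def test_identical_replicates_zero_sem(self):
        assert summarize_replicates("c", [0.4, 0.4, 0.4]).sem_fraction_lf == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_replicate_sem_undefined(self):
        summary = summarize_replicates("c", [0.4])
        assert summary.mean_fraction_lf == 0.4
        assert np.isnan(summary.sem_fraction_lf)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates("c", [])
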