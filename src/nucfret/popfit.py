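"""Proximity-ratio distributions, two-Gaussian fits, state fractions.

The per-burst proximity ratios of a sample are binned into a relative
frequency distribution and fitted with the sum of two Gaussians describing
the two conformational states of the nucleosome: a low-FRET (LF, unfolded)
and a high-FRET (HF, folded) sub-population. State fractions are the areas
under the two peaks normalized to their sum,

    area_k = amplitude_k * sigma_k * sqrt(2*pi),
    fraction_k = area_k / (area_LF + area_HF),

and replicate experiments are summarized as mean +/- SEM of the LF fraction.

The fit is unweighted nonlinear least squares on the binned curve evaluated
at bin centers (a per-bin Poisson weighting is available as a flag); peaks
are relabeled after fitting so that mean_LF < mean_HF.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit import Model
from scipy.signal import find_peaks

log = logging.getLogger("nucfret")

DEFAULT_BIN_WIDTH = 0.05
DEFAULT_RANGE = (-0.25, 1.25)
DEFAULT_SIGMA_INIT = 0.08
MAX_RESTARTS = 5

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


class FitError(RuntimeError):
    """The two-Gaussian fit failed to converge after all restarts."""


@dataclass(frozen=True)
class EprDistribution:
    """Binned relative-frequency distribution of proximity ratios."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_bursts: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "frequencies", freq)
        if len(edges) != len(freq) + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing, one more than frequencies")
        if np.any(freq < 0) or abs(freq.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def build_distribution(
    epr_values: Sequence[float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    value_range: tuple[float, float] = DEFAULT_RANGE,
) -> EprDistribution:
    """Histogram proximity ratios into a relative frequency distribution.

    Values outside ``value_range`` are clipped into the end bins (and
    logged), so every burst contributes to the normalization.
    """
    values = np.asarray(epr_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input: no proximity ratios to histogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    low, high = value_range
    if high <= low:
        raise ValueError("value_range must be increasing")
    n_outside = int(np.sum((values < low) | (values > high)))
    if n_outside:
        log.info("clipping %d of %d E_PR values into the end bins", n_outside, values.size)
    n_bins = int(np.ceil((high - low) / bin_width - 1e-9))
    edges = low + bin_width * np.arange(n_bins + 1)
    clipped = np.clip(values, low, edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return EprDistribution(
        bin_edges=edges,
        frequencies=counts / values.size,
        n_bursts=int(values.size),
    )


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted peak: height (relative-frequency units), center, width (E_PR)."""

    amplitude: float
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.sigma <= 0:
            raise ValueError("amplitude must be >= 0 and sigma > 0")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * SQRT_2PI


@dataclass(frozen=True)
class TwoGaussianFit:
    """LF and HF peaks with derived state fractions and fit diagnostics."""

    peak_lf: GaussianPeak
    peak_hf: GaussianPeak
    fraction_lf: float
    fraction_hf: float
    residual_norm: float
    converged: bool = True
    degenerate: bool = False
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "peak_lf": vars(self.peak_lf) | {"area": self.peak_lf.area},
            "peak_hf": vars(self.peak_hf) | {"area": self.peak_hf.area},
            "fraction_lf": self.fraction_lf,
            "fraction_hf": self.fraction_hf,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "message": self.message,
        }


def _two_gaussians(x, amp_1, mu_1, sig_1, amp_2, mu_2, sig_2):
    return amp_1 * np.exp(-0.5 * ((x - mu_1) / sig_1) ** 2) + amp_2 * np.exp(
        -0.5 * ((x - mu_2) / sig_2) ** 2
    )


_MODEL = Model(_two_gaussians)


def _initial_means(dist: EprDistribution) -> tuple[float, float]:
    """Means at the two most separated prominent maxima of the smoothed curve."""
    freq = dist.frequencies
    smoothed = np.convolve(freq, [0.25, 0.5, 0.25], mode="same")
    centers = dist.bin_centers
    peaks, _ = find_peaks(smoothed, prominence=0.02 * smoothed.max())
    if smoothed.argmax() not in peaks:  # plateau or edge maximum
        peaks = np.append(peaks, smoothed.argmax())
    if len(peaks) >= 2:
        order = np.argsort(centers[peaks])
        return float(centers[peaks[order[0]]]), float(centers[peaks[order[-1]]])
    # single mode: put one component on it and one on the far mass quantile
    mode = float(centers[smoothed.argmax()])
    cdf = np.cumsum(freq)
    q15 = float(centers[np.searchsorted(cdf, 0.15)])
    q85 = float(centers[np.searchsorted(cdf, min(0.85, cdf[-1]))])
    partner = q15 if abs(mode - q15) > abs(mode - q85) else q85
    if abs(partner - mode) < dist.bin_width:
        partner = mode + 2 * dist.bin_width
    return (mode, partner) if mode < partner else (partner, mode)


def _amplitude_near(dist: EprDistribution, mean: float) -> float:
    idx = int(np.clip(np.searchsorted(dist.bin_edges, mean) - 1, 0, len(dist.frequencies) - 1))
    return max(float(dist.frequencies[idx]), 1e-3 * float(dist.frequencies.max()))


def fit_two_gaussians(
    dist: EprDistribution,
    init: dict | None = None,
    seed: int = 0,
    max_restarts: int = MAX_RESTARTS,
    poisson_weights: bool = False,
) -> TwoGaussianFit:
    """Fit the sum of two Gaussians to a relative-frequency distribution.

    ``init`` may override any of ``amp_1, mu_1, sig_1, amp_2, mu_2, sig_2``.
    On failure the fit is restarted up to ``max_restarts`` times from
    seeded, jittered initial values; persistent non-convergence raises
    :class:`FitError` (never silent garbage). A fit whose two means collapse
    within one bin width, or whose width sticks at a bound, is flagged
    ``degenerate``.

    With ``poisson_weights=True`` the residuals are weighted by the inverse
    shot-noise standard deviation of each bin frequency.
    """
    freq = dist.frequencies
    if int(np.count_nonzero(freq)) < 6:
        raise ValueError("need at least 6 nonempty bins to fit two Gaussians")
    x = dist.bin_centers
    span = float(dist.bin_edges[-1] - dist.bin_edges[0])
    sigma_min = dist.bin_width / 2.0
    mu_lo, mu_hi = float(dist.bin_edges[0]), float(dist.bin_edges[-1])
    amp_max = 2.0 * float(freq.max())

    mu1, mu2 = _initial_means(dist)
    defaults = {
        "amp_1": _amplitude_near(dist, mu1),
        "mu_1": mu1,
        "sig_1": DEFAULT_SIGMA_INIT,
        "amp_2": _amplitude_near(dist, mu2),
        "mu_2": mu2,
        "sig_2": DEFAULT_SIGMA_INIT,
    }
    if init:
        defaults.update(init)

    weights = None
    if poisson_weights:
        expected_sd = np.sqrt(np.maximum(freq, 1.0 / dist.n_bursts) / dist.n_bursts)
        weights = 1.0 / expected_sd

    rng = np.random.default_rng(seed)
    last_message = ""
    for attempt in range(max_restarts + 1):
        start = dict(defaults)
        if attempt > 0:
            start["mu_1"] = float(np.clip(start["mu_1"] + rng.uniform(-0.1, 0.1), mu_lo, mu_hi))
            start["mu_2"] = float(np.clip(start["mu_2"] + rng.uniform(-0.1, 0.1), mu_lo, mu_hi))
            start["sig_1"] = float(np.clip(start["sig_1"] * rng.uniform(0.5, 2.0), sigma_min, span))
            start["sig_2"] = float(np.clip(start["sig_2"] * rng.uniform(0.5, 2.0), sigma_min, span))
        params = _MODEL.make_params()
        for k in ("amp_1", "amp_2"):
            params[k].set(value=start[k], min=0.0, max=amp_max)
        for k in ("mu_1", "mu_2"):
            params[k].set(value=start[k], min=mu_lo, max=mu_hi)
        for k in ("sig_1", "sig_2"):
            params[k].set(value=start[k], min=sigma_min, max=span)
        result = _MODEL.fit(freq, params, x=x, weights=weights)
        if result.success and np.isfinite(result.residual).all():
            return _build_fit(result, dist, sigma_min, span)
        last_message = result.message
    raise FitError(
        f"two-Gaussian fit did not converge after {max_restarts} restarts: {last_message}"
    )


def _build_fit(result, dist: EprDistribution, sigma_min: float, sigma_max: float) -> TwoGaussianFit:
    p = {name: float(par.value) for name, par in result.params.items()}
    peaks = sorted(
        (
            GaussianPeak(p["amp_1"], p["mu_1"], p["sig_1"]),
            GaussianPeak(p["amp_2"], p["mu_2"], p["sig_2"]),
        ),
        key=lambda peak: peak.mean,
    )
    peak_lf, peak_hf = peaks
    residual_norm = float(np.sqrt(np.sum(np.asarray(result.residual) ** 2)))

    degenerate = False
    message = ""
    means_collapsed = abs(peak_hf.mean - peak_lf.mean) < dist.bin_width
    at_bound = any(
        s < sigma_min * (1 + 1e-6) or s > sigma_max * (1 - 1e-6)
        for s in (peak_lf.sigma, peak_hf.sigma)
    )
    if means_collapsed:
        degenerate = True
        midpoint = 0.5 * (dist.bin_edges[0] + dist.bin_edges[-1])
        if peak_hf.mean > midpoint:
            fraction_lf, fraction_hf = 0.0, 1.0
            message = "means collapsed; single peak above midpoint reported as HF"
        else:
            fraction_lf, fraction_hf = 1.0, 0.0
            message = "means collapsed; single peak below midpoint reported as LF"
    else:
        fraction_lf, fraction_hf = estimate_fractions(peak_lf, peak_hf)
        if at_bound:
            degenerate = True
            message = "a peak width converged at its bound"
    return TwoGaussianFit(
        peak_lf=peak_lf,
        peak_hf=peak_hf,
        fraction_lf=fraction_lf,
        fraction_hf=fraction_hf,
        residual_norm=residual_norm,
        converged=True,
        degenerate=degenerate,
        message=message,
    )


def estimate_fractions(peak_lf: GaussianPeak, peak_hf: GaussianPeak) -> tuple[float, float]:
    """State fractions as Gaussian areas normalized to their sum."""
    area_lf, area_hf = peak_lf.area, peak_hf.area
    total = area_lf + area_hf
    if total <= 0:
        raise ValueError("both peak areas are zero; fractions undefined")
    return area_lf / total, area_hf / total


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SEM of the LF (unfolded) fraction over replicate experiments."""

    condition: str
    mean_fraction_lf: float
    sem_fraction_lf: float   # NaN when only one replicate (undefined, not zero)
    n_replicates: int


def summarize_replicates(condition: str, fractions_lf: Sequence[float]) -> ReplicateSummary:
    """Mean and SEM (sample sd / sqrt(n)) of per-replicate LF fractions."""
    values = np.asarray(fractions_lf, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate")
    n = int(values.size)
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return ReplicateSummary(
        condition=condition,
        mean_fraction_lf=float(values.mean()),
        sem_fraction_lf=sem,
        n_replicates=n,
    )
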