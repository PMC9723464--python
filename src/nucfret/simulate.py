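"""Forward simulation of single-particle FRET photon bursts.

Emulates a two-channel confocal measurement of freely diffusing,
doubly-labeled nucleosomes: each burst is one particle transit. A species is
characterized by its true FRET efficiency E, its mean total signal photon
count (brightness), and its mixture weight. Per burst:

1. draw the species by weight (multinomial or stratified allocation);
2. draw total signal photons N from a lognormal around the brightness
   (diffusion-path variability), rounded to an integer;
3. split ideally: acceptor A* = E*N, donor D* = (1-E)*N;
4. leak a fraction of donor signal into the acceptor channel and add
   per-channel background, then apply shot noise:
   I_a = Poisson(A* + crosstalk*D* + background_acceptor),
   I_d = Poisson(D* + background_donor).

The crosstalk is applied exactly in the form that the proximity-ratio
correction inverts, so in the noiseless limit the analysis recovers E to
machine precision — the central simulator/analyzer oracle.

Not modeled: photon-by-photon time traces, diffusion optics, photobleaching,
gamma-factor calibration, acceptor direct excitation.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import largest_remainder_apportion

DEFAULT_CROSSTALK = 0.19
DEFAULT_EFFICIENCY_LF = 0.15
DEFAULT_EFFICIENCY_HF = 0.70
DEFAULT_BRIGHTNESS = 100.0
DEFAULT_N_BURSTS = 4000
DEFAULT_SIGMA_LOG = 0.4
DEFAULT_BACKGROUND = 2.0

#: Folded-state (high-FRET) weight for each condition of the unfolding ladder:
#: intact nucleosomes, the chaperone alone (no structural change), the curaxin
#: alone (minor unfolding), chaperone + curaxin (profound unfolding), and the
#: competitor-DNA chase (largely reversed). These encode the qualitative
#: ordering of the conditions, not measured values.
LADDER_FOLDED_WEIGHT = {
    "nucleosome": 0.85,
    "FACT": 0.85,
    "CBL0137": 0.75,
    "FACT+CBL0137": 0.25,
    "FACT+CBL0137+competitorDNA": 0.75,
}


class ConfigurationError(ValueError):
    """A simulation specification violates its invariants."""


@dataclass(frozen=True)
class SpeciesParams:
    """One conformational species: true FRET efficiency, brightness, weight."""

    name: str
    efficiency: float
    brightness: float = DEFAULT_BRIGHTNESS
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ConfigurationError(f"efficiency must be in [0,1], got {self.efficiency}")
        if self.brightness <= 0:
            raise ConfigurationError(f"brightness must be positive, got {self.brightness}")
        if self.weight < 0:
            raise ConfigurationError(f"weight must be non-negative, got {self.weight}")


@dataclass(frozen=True)
class ConditionSpec:
    """Generative truth for one measured sample."""

    condition: str
    species: tuple[SpeciesParams, ...]
    n_bursts: int = DEFAULT_N_BURSTS
    background_donor: float = DEFAULT_BACKGROUND
    background_acceptor: float = DEFAULT_BACKGROUND
    crosstalk: float = DEFAULT_CROSSTALK
    seed: int = 0
    allocation: str = "multinomial"   # or "stratified"
    sigma_log: float = DEFAULT_SIGMA_LOG

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        total = sum(s.weight for s in self.species)
        if not self.species or abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"species weights must sum to 1, got {total}")
        if self.n_bursts < 1:
            raise ConfigurationError(f"n_bursts must be >= 1, got {self.n_bursts}")
        if not 0.0 <= self.crosstalk < 1.0:
            raise ConfigurationError(f"crosstalk must be in [0,1), got {self.crosstalk}")
        if self.background_donor < 0 or self.background_acceptor < 0:
            raise ConfigurationError("background means must be non-negative")
        if self.allocation not in ("multinomial", "stratified"):
            raise ConfigurationError(f"unknown allocation {self.allocation!r}")

    def replace(self, **kwargs) -> "ConditionSpec":
        return dataclasses.replace(self, **kwargs)


def two_state_species(
    weight_lf: float,
    efficiency_lf: float = DEFAULT_EFFICIENCY_LF,
    efficiency_hf: float = DEFAULT_EFFICIENCY_HF,
    brightness: float = DEFAULT_BRIGHTNESS,
) -> tuple[SpeciesParams, SpeciesParams]:
    """LF (unfolded) / HF (folded) species pair with LF mixture weight."""
    if not 0.0 <= weight_lf <= 1.0:
        raise ConfigurationError(f"weight_lf must be in [0,1], got {weight_lf}")
    return (
        SpeciesParams("LF", efficiency_lf, brightness, weight_lf),
        SpeciesParams("HF", efficiency_hf, brightness, 1.0 - weight_lf),
    )


def ladder_condition_spec(condition: str, **kwargs) -> ConditionSpec:
    """ConditionSpec for one rung of the default unfolding ladder."""
    try:
        folded = LADDER_FOLDED_WEIGHT[condition]
    except KeyError:
        raise ConfigurationError(
            f"unknown ladder condition {condition!r}; choose from "
            f"{sorted(LADDER_FOLDED_WEIGHT)}"
        ) from None
    species_kwargs = {
        k: kwargs.pop(k)
        for k in ("efficiency_lf", "efficiency_hf", "brightness")
        if k in kwargs
    }
    species = two_state_species(1.0 - folded, **species_kwargs)
    return ConditionSpec(condition=condition, species=species, **kwargs)


def _allocate_species(spec: ConditionSpec, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([s.weight for s in spec.species], dtype=float)
    weights = weights / weights.sum()
    if spec.allocation == "stratified":
        counts = largest_remainder_apportion(weights, spec.n_bursts)
        index = np.repeat(np.arange(len(weights)), counts)
        rng.shuffle(index)
        return index
    return rng.choice(len(weights), size=spec.n_bursts, p=weights)


def _burst_frame(
    spec: ConditionSpec,
    replicate: int,
    donor: np.ndarray,
    acceptor: np.ndarray,
    species_index: np.ndarray,
) -> pd.DataFrame:
    names = np.array([s.name for s in spec.species])
    return pd.DataFrame(
        {
            "burst_id": np.arange(spec.n_bursts, dtype=int),
            "condition": spec.condition,
            "replicate": int(replicate),
            "intensity_donor": donor,
            "intensity_acceptor": acceptor,
            "true_species": names[species_index],
        }
    )


def simulate_bursts(spec: ConditionSpec, replicate: int = 1) -> pd.DataFrame:
    """Simulate a burst table for one sample; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    index = _allocate_species(spec, rng)
    efficiency = np.array([s.efficiency for s in spec.species])[index]
    brightness = np.array([s.brightness for s in spec.species])[index]
    # lognormal with mean equal to the species brightness
    mu = np.log(brightness) - spec.sigma_log**2 / 2.0
    total = np.round(rng.lognormal(mean=mu, sigma=spec.sigma_log)).astype(float)
    acceptor_ideal = efficiency * total
    donor_ideal = (1.0 - efficiency) * total
    acceptor = rng.poisson(
        acceptor_ideal + spec.crosstalk * donor_ideal + spec.background_acceptor
    ).astype(float)
    donor = rng.poisson(donor_ideal + spec.background_donor).astype(float)
    return _burst_frame(spec, replicate, donor, acceptor, index)


def noiseless_mode(spec: ConditionSpec, replicate: int = 1) -> pd.DataFrame:
    """The identical forward model with every random draw replaced by its mean.

    Burst sizes equal the species brightness exactly and the Poisson detection
    step returns its mean, so intensities are noise-free expectations. Species
    allocation still follows ``spec.allocation`` (use ``"stratified"`` for
    exact per-species counts). Used by the crosstalk-inversion oracle tests.
    """
    rng = np.random.default_rng(spec.seed)
    index = _allocate_species(spec, rng)
    efficiency = np.array([s.efficiency for s in spec.species])[index]
    brightness = np.array([s.brightness for s in spec.species])[index]
    acceptor_ideal = efficiency * brightness
    donor_ideal = (1.0 - efficiency) * brightness
    acceptor = acceptor_ideal + spec.crosstalk * donor_ideal + spec.background_acceptor
    donor = donor_ideal + spec.background_donor
    return _burst_frame(spec, replicate, donor, acceptor, index)
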