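"""Census statistics for conformational class counts.

Electron microscopy of the FACT histone chaperone classifies particles into a
small set of conformations (compact, closed, open). This module turns such
class counts into fractions, printed-style integer percentages that always
total 100, normalized ratio strings, bootstrap (or Wilson) confidence
intervals, and replicate averages.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


def largest_remainder_apportion(values: Sequence[float], total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``values``.

    Hamilton (largest-remainder) rounding: floor the proportional shares,
    then hand the leftover units to the largest fractional remainders, ties
    broken by position. The result always sums to exactly ``total``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError("values must be finite and non-negative")
    if values.sum() <= 0:
        raise ValueError("at least one value must be positive")
    shares = values / values.sum() * total
    base = np.floor(shares).astype(int)
    leftover = int(total - base.sum())
    # stable sort keeps earlier categories first on remainder ties
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:leftover]] += 1
    return base


def ratio_to_percent(ratio: Sequence[float]) -> tuple[int, ...]:
    """Normalize a ratio (e.g. 2:1:1.6) to integer percentages summing to 100."""
    return tuple(int(p) for p in largest_remainder_apportion(ratio, 100))


@dataclass(frozen=True)
class ClassTally:
    """Particle counts per conformational category for one sample."""

    categories: tuple[str, ...]
    counts: tuple[int, ...]
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.counts):
            raise ValueError("categories and counts must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.total


@dataclass(frozen=True)
class CensusResult:
    """Fractions, integer percentages, CIs and ratio string for one tally."""

    categories: tuple[str, ...]
    counts: tuple[int, ...]
    fractions: tuple[float, ...]
    percentages: tuple[int, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    ratio_string: str
    ci_method: str

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def as_dict(self) -> dict:
        return {
            "categories": list(self.categories),
            "counts": list(self.counts),
            "fractions": [float(f) for f in self.fractions],
            "percentages": list(self.percentages),
            "ci_low": [float(v) for v in self.ci_low],
            "ci_high": [float(v) for v in self.ci_high],
            "ratio_string": self.ratio_string,
            "ci_method": self.ci_method,
        }


def _ratio_string(counts: Sequence[int]) -> str:
    """Normalize counts against the smallest positive component, 2 decimals."""
    counts = np.asarray(counts, dtype=float)
    reference = counts[counts > 0].min()
    parts = []
    for value in counts / reference:
        parts.append("1" if abs(value - 1.0) < 5e-3 else f"{value:.2f}")
    return ":".join(parts)


def tally_fractions(
    tally: ClassTally,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
    method: str = "bootstrap",
) -> CensusResult:
    """Fractions, percentages and per-category confidence intervals.

    The default CI is a seeded percentile bootstrap that resamples particles
    with replacement (``n_boot`` multinomial resamples of the observed
    fractions). ``method="wilson"`` is available for two-category tallies.
    """
    fractions = tally.fractions
    percentages = ratio_to_percent(tally.counts)
    alpha = 1.0 - ci_level
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        resampled = rng.multinomial(tally.total, fractions, size=n_boot) / tally.total
        low = np.quantile(resampled, alpha / 2, axis=0)
        high = np.quantile(resampled, 1 - alpha / 2, axis=0)
    elif method == "wilson":
        if len(tally.counts) != 2:
            raise ValueError("Wilson intervals are defined for 2-category tallies")
        bounds = [
            proportion_confint(c, tally.total, alpha=alpha, method="wilson")
            for c in tally.counts
        ]
        low = np.array([b[0] for b in bounds])
        high = np.array([b[1] for b in bounds])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return CensusResult(
        categories=tally.categories,
        counts=tuple(int(c) for c in tally.counts),
        fractions=tuple(float(f) for f in fractions),
        percentages=percentages,
        ci_low=tuple(float(v) for v in low),
        ci_high=tuple(float(v) for v in high),
        ratio_string=_ratio_string(tally.counts),
        ci_method=method,
    )


def pool_categories(
    tally: ClassTally | CensusResult,
    groups: Mapping[str, Iterable[str]],
    **census_kwargs,
) -> CensusResult:
    """Merge categories into groups and recompute the census.

    ``groups`` maps new labels to the original categories; it must partition
    the category set exactly. The pooled total equals the original total, so
    pooling counts first and recomputing fractions commute.
    """
    categories = tuple(tally.categories)
    counts = dict(zip(categories, tally.counts))
    assigned: list[str] = []
    pooled: dict[str, int] = {}
    for label, members in groups.items():
        members = list(members)
        unknown = [m for m in members if m not in counts]
        if unknown:
            raise ValueError(f"unknown categories in group {label!r}: {unknown}")
        assigned.extend(members)
        pooled[label] = sum(counts[m] for m in members)
    if sorted(assigned) != sorted(categories):
        raise ValueError("groups must partition the categories exactly once each")
    condition = getattr(tally, "condition", "")
    replicate = getattr(tally, "replicate", 1)
    pooled_tally = ClassTally(
        categories=tuple(pooled),
        counts=tuple(pooled.values()),
        condition=condition,
        replicate=replicate,
    )
    return tally_fractions(pooled_tally, **census_kwargs)


def average_replicates(tallies: Sequence[ClassTally]) -> pd.DataFrame:
    """Unweighted mean fraction and SEM per category across replicate tallies.

    SEM uses the sample (n-1) standard deviation over sqrt(n) and is NaN for a
    single replicate (undefined, never reported as zero).
    """
    if not tallies:
        raise ValueError("need at least one tally")
    categories = tallies[0].categories
    for tally in tallies[1:]:
        if tally.categories != categories:
            raise ValueError(
                f"replicate category sets differ: {tally.categories} vs {categories}"
            )
    fractions = np.vstack([t.fractions for t in tallies])
    n = len(tallies)
    mean = fractions.mean(axis=0)
    sem = fractions.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(categories), np.nan)
    return pd.DataFrame(
        {"category": categories, "mean_fraction": mean, "sem_fraction": sem, "n_replicates": n}
    )
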