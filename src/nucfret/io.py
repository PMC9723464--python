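"""Readers, writers and run configuration for burst and class-count tables.

All tables are plain CSV (comma-separated, UTF-8, ``.`` decimal). Data tables
keep full float precision; report files round to 6 significant digits.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger("nucfret")

#: Exact burst-table header. ``true_species`` is simulation provenance and may
#: be empty for real data.
BURST_COLUMNS = (
    "burst_id",
    "condition",
    "replicate",
    "intensity_donor",
    "intensity_acceptor",
    "true_species",
)

#: Exact class-count table header.
TALLY_COLUMNS = ("condition", "replicate", "category", "count")

_BURST_NUMERIC = ("burst_id", "replicate", "intensity_donor", "intensity_acceptor")
_BURST_INT = ("burst_id", "replicate")


class ParseError(ValueError):
    """A table failed validation; the message names the offending line."""


def read_burst_table(path: str | Path) -> pd.DataFrame:
    """Read a burst CSV, validating the header and every numeric field.

    Unknown extra columns are preserved with a warning. Malformed numeric
    fields raise :class:`ParseError` naming the 1-based file line.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in BURST_COLUMNS if c != "true_species"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in raw.columns if c not in BURST_COLUMNS]
    if extra:
        log.warning("%s: preserving unknown column(s): %s", path, ", ".join(extra))
    if raw.empty:
        raise ParseError(f"{path}: empty input")
    out = raw.copy()
    for col in _BURST_NUMERIC:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(bad.idxmax())
            # +2: one for the header line, one for 1-based numbering
            raise ParseError(
                f"{path}: non-numeric value {raw[col][row]!r} in column "
                f"{col!r} on line {row + 2}"
            )
        out[col] = values.astype(int) if col in _BURST_INT else values.astype(float)
    if "true_species" not in out.columns:
        out["true_species"] = ""
    return out


def write_burst_table(bursts: pd.DataFrame, path: str | Path) -> Path:
    """Write a burst table with the canonical column order; returns the path."""
    path = Path(path)
    ordered = [c for c in BURST_COLUMNS if c in bursts.columns]
    ordered += [c for c in bursts.columns if c not in BURST_COLUMNS]
    bursts.loc[:, ordered].to_csv(path, index=False)
    return path


def read_tally_table(path: str | Path) -> pd.DataFrame:
    """Read a class-count CSV (``condition,replicate,category,count``)."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TALLY_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    if raw.empty:
        raise ParseError(f"{path}: empty input")
    out = raw.copy()
    for col in ("replicate", "count"):
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {raw[col][row]!r} in column "
                f"{col!r} on line {row + 2}"
            )
        out[col] = values.astype(int)
    return out


def write_tally_table(tallies: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    tallies.loc[:, list(TALLY_COLUMNS)].to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """All tunable analysis and simulation parameters with their defaults.

    Defaults mirror the per-module defaults documented in ``docs/methods.md``;
    a config file only needs to list the keys it overrides.
    """

    # analysis
    leakage: float = 0.19          # donor->acceptor spectral crosstalk fraction
    bin_width: float = 0.05        # E_PR histogram bin width
    epr_min: float = -0.25         # histogram lower edge (crosstalk bound)
    epr_max: float = 1.25          # histogram upper edge
    min_total: float = 30.0        # burst-selection threshold, photons
    n_boot: int = 2000             # bootstrap resamples for census CIs
    # simulation
    condition: str = "nucleosome"
    n_bursts: int = 4000
    replicates: int = 3
    background_donor: float = 2.0  # mean background photons/burst, donor channel
    background_acceptor: float = 2.0
    brightness: float = 100.0      # mean total signal photons per burst
    sigma_log: float = 0.4         # lognormal spread of burst size
    efficiency_lf: float = 0.15    # unfolded-state FRET efficiency
    efficiency_hf: float = 0.70    # folded-state FRET efficiency
    weight_lf: float = 0.15        # unfolded-state mixture weight
    allocation: str = "multinomial"
    seed: int = 0
    verbosity: str = "INFO"

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key-value config file (``key: value`` per line).

    Unknown keys raise :class:`ParseError`; every key left at its default is
    logged so a run records the parameters it actually used.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    if data is None:
        data = {}
    if not isinstance(data, dict) or any(isinstance(v, (dict, list)) for v in data.values()):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    unknown = [k for k in data if k not in fields]
    if unknown:
        raise ParseError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    config = RunConfig(**data)
    for name, field in fields.items():
        if name not in data:
            log.info("config %s: using default %s=%r", path, name, field.default)
    return config


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Write a config as flat ``key: value`` lines; round-trips losslessly."""
    path = Path(path)
    lines = [
        f"{field.name}: {getattr(config, field.name)!r}"
        if isinstance(getattr(config, field.name), str)
        else f"{field.name}: {getattr(config, field.name)}"
        for field in dataclasses.fields(config)
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
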