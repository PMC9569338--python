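"""Synthetic peptide-array data with known ground truth.

Generates kinase->peptide maps and kinetic exposure series that mimic a
144-peptide serine/threonine chip run across replicate chips: intensity grows
linearly with camera exposure time, group-specific kinase activity raises the
slopes of mapped peptides, and measurement noise is multiplicative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from kinoscope.errors import ConfigError

DEFAULT_GROUPS = ("nuclear", "cytosolic", "synaptosomal", "total")
DEFAULT_EXPOSURES = (10.0, 20.0, 50.0, 100.0, 200.0)

# independent random streams derived from the same user seed
_STREAM_MAP = 0
_STREAM_SIGNAL = 1


@dataclass
class SimulationConfig:
    """Parameters of the synthetic chip experiment.

    ``active_kinases`` maps group label -> {kinase -> activity multiplier};
    a multiplier of 1 is neutral, >1 raises the slope of mapped peptides,
    <1 lowers it. Kinases absent from a group's map are neutral there.
    """

    n_peptides: int = 144
    n_kinases: int = 20
    peptides_per_kinase: tuple[int, int] = (5, 15)
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_chips: int = 3
    exposure_times: tuple[float, ...] = DEFAULT_EXPOSURES
    active_kinases: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_slope: float = 1.0
    noise_cv: float = 0.05
    intercept: float = 0.0
    seed: int = 0
    n_low_signal_peptides: int = 3
    low_signal_slope: float = 0.005

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ConfigError("n_peptides must be >= 1")
        if self.n_kinases < 1:
            raise ConfigError("n_kinases must be >= 1")
        lo, hi = self.peptides_per_kinase
        if not (1 <= lo <= hi):
            raise ConfigError("peptides_per_kinase must satisfy 1 <= lo <= hi")
        if hi > self.n_peptides:
            raise ConfigError(
                f"peptides_per_kinase upper bound {hi} exceeds n_peptides {self.n_peptides}"
            )
        if len(self.groups) < 1 or len(set(self.groups)) != len(self.groups):
            raise ConfigError("groups must be nonempty and unique")
        if self.n_chips < 1:
            raise ConfigError("n_chips must be >= 1")
        times = tuple(float(t) for t in self.exposure_times)
        if len(times) < 2:
            raise ConfigError("need at least 2 exposure times")
        if any(t <= 0 for t in times):
            raise ConfigError("exposure times must be strictly positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError("exposure times must be strictly increasing")
        object.__setattr__(self, "exposure_times", times)
        for g, kmap in self.active_kinases.items():
            if g not in self.groups:
                raise ConfigError(f"active_kinases group {g!r} not in groups")
            for k, mult in kmap.items():
                if mult < 0:
                    raise ConfigError(f"activity multiplier for {k!r} must be >= 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.baseline_slope < 0:
            raise ConfigError("baseline_slope must be >= 0")
        if self.intercept < 0:
            raise ConfigError("intercept must be >= 0")
        if not (0 <= self.n_low_signal_peptides <= self.n_peptides):
            raise ConfigError("n_low_signal_peptides must be within [0, n_peptides]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("peptides_per_kinase", "groups", "exposure_times"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["active_kinases"] = {g: dict(m) for g, m in self.active_kinases.items()}
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run.

    ``slopes`` is a peptides x groups frame of noise-free kinetic slopes;
    ``active_kinases`` records the injected elevations; ``low_signal_peptides``
    lists peptides forced to a near-zero slope to exercise the QC filter.
    """

    slopes: pd.DataFrame
    active_kinases: dict[str, dict[str, float]]
    low_signal_peptides: list[str]
    seed: int

    def slopes_long(self) -> pd.DataFrame:
        out = self.slopes.stack().rename("true_slope").reset_index()
        out.columns = ["peptide_id", "group", "true_slope"]
        return out


def peptide_ids(n: int) -> list[str]:
    return [f"pep_{i + 1:03d}" for i in range(n)]


def kinase_ids(n: int) -> list[str]:
    return [f"KIN{i + 1:02d}" for i in range(n)]


def generate_kinase_map(config: SimulationConfig) -> pd.DataFrame:
    """Draw a kinase->peptide map: each kinase gets a uniformly sized peptide
    set drawn without replacement; peptides may be shared between kinases.

    Deterministic given ``config.seed``. Returns a tidy frame with columns
    ``kinase`` and ``peptide_id``.
    """
    rng = np.random.default_rng([_STREAM_MAP, config.seed])
    peptides = np.array(peptide_ids(config.n_peptides))
    lo, hi = config.peptides_per_kinase
    rows = []
    for kinase in kinase_ids(config.n_kinases):
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(peptides, size=size, replace=False)
        rows.extend((kinase, p) for p in sorted(chosen))
    return pd.DataFrame(rows, columns=["kinase", "peptide_id"])


def expected_slopes(config: SimulationConfig, kinase_map: pd.DataFrame) -> pd.DataFrame:
    """Noise-free slope per (peptide, group).

    slope(p, g) = baseline * (1 + sum over active kinases k mapped to p of
    (multiplier_gk - 1)), floored at 0. Low-signal peptides are overridden.
    """
    peptides = peptide_ids(config.n_peptides)
    mapped = kinase_map.groupby("kinase")["peptide_id"].apply(set).to_dict()
    for g, acts in config.active_kinases.items():
        missing = set(acts) - set(mapped)
        if missing:
            raise ConfigError(
                f"active kinases {sorted(missing)} for group {g!r} not in kinase map"
            )
    slopes = pd.DataFrame(
        config.baseline_slope, index=pd.Index(peptides, name="peptide_id"),
        columns=pd.Index(config.groups, name="group"), dtype=float,
    )
    for g, acts in config.active_kinases.items():
        for kinase, mult in acts.items():
            targets = sorted(mapped[kinase])
            slopes.loc[targets, g] += config.baseline_slope * (mult - 1.0)
    slopes = slopes.clip(lower=0.0)
    low = peptides[-config.n_low_signal_peptides:] if config.n_low_signal_peptides else []
    slopes.loc[list(low), :] = config.low_signal_slope
    return slopes


def simulate_exposure_series(
    config: SimulationConfig, kinase_map: pd.DataFrame
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the exposure series for one run (one sample per group x chip).

    intensity(p, g, c, t) = (intercept + slope_pg * t) * eps with eps
    log-normal, mean 1, CV = noise_cv. Intensities are floored at 0.
    """
    slopes = expected_slopes(config, kinase_map)
    rng = np.random.default_rng([_STREAM_SIGNAL, config.seed])
    times = np.asarray(config.exposure_times)
    chips = [f"chip{c + 1}" for c in range(config.n_chips)]

    # clean signal: peptides x groups x exposures
    clean = config.intercept + slopes.to_numpy()[:, :, None] * times[None, None, :]
    n_p, n_g, n_t = clean.shape
    shape = (n_p, n_g, config.n_chips, n_t)
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        eps = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=shape)
    else:
        eps = np.ones(shape)
    intensity = np.maximum(clean[:, :, None, :] * eps, 0.0)

    idx = pd.MultiIndex.from_product(
        [slopes.index, slopes.columns, chips, times],
        names=["peptide_id", "group", "chip", "exposure_ms"],
    )
    series = pd.DataFrame({"intensity": intensity.ravel()}, index=idx).reset_index()

    low = (
        peptide_ids(config.n_peptides)[-config.n_low_signal_peptides:]
        if config.n_low_signal_peptides
        else []
    )
    truth = SyntheticTruth(
        slopes=slopes,
        active_kinases={g: dict(m) for g, m in config.active_kinases.items()},
        low_signal_peptides=list(low),
        seed=config.seed,
    )
    return series, truth
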