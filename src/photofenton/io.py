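"""File formats and run configuration.

All tabular exchange is UTF-8 delimited text with a header row:

* measured / synthetic series: ``experiment_id, time_min, kind, value,
  units`` (target and H2O2 in mmol/L, TOC in mg C/L);
* trajectories: ``time_min, compartment, species,
  concentration_mmol_per_L``.

Rate constants travel as YAML mirroring the staged structure: a ``core``
block (k0, k1, k2, k_elim) and one block per compound (k_target,
k_fragment).  The run configuration is YAML validated against a small
schema; its defaults reproduce the reference pilot-plant setup.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from typing import Mapping

import pandas as pd
import yaml

from .kinetics import CoreRateConstants, TargetRateConstants
from .reactor import Trajectory

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_series",
    "write_series",
    "write_trajectory",
    "read_trajectory",
    "species_names",
    "read_params",
    "write_params",
]

SERIES_COLUMNS = ["experiment_id", "time_min", "kind", "value", "units"]


class ConfigError(ValueError):
    """A run-configuration file violates the schema."""


@dataclass
class RunConfig:
    """Run-level settings; the defaults reproduce the reference setup."""

    dt_s: float = 0.05
    feed_duration_s: float = 30.0
    record_interval_s: float = 1.0
    normalization: str = "literal"
    sampling_compartment: int = 0
    seed: int = 0
    noise_sigma: float = 0.05
    detection_limit: float = 1e-3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ConfigError("dt_s: must be positive")
        if self.feed_duration_s <= 0:
            raise ConfigError("feed_duration_s: must be positive")
        if self.record_interval_s < self.dt_s:
            raise ConfigError("record_interval_s: must be >= dt_s")
        if self.normalization not in ("literal", "proportional"):
            raise ConfigError(
                "normalization: must be 'literal' or 'proportional'"
            )
        if not 0 <= self.sampling_compartment <= 3:
            raise ConfigError("sampling_compartment: must be in 0..3")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma: must be non-negative")
        if self.detection_limit < 0:
            raise ConfigError("detection_limit: must be non-negative")

    def simulate_kwargs(self) -> dict:
        return {
            "dt": self.dt_s,
            "feed_duration_s": self.feed_duration_s,
            "record_interval_s": self.record_interval_s,
            "normalization": self.normalization,
            "sampling_compartment": self.sampling_compartment,
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys and invalid values raise :class:`ConfigError` naming
    the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**raw)


def read_series(path) -> pd.DataFrame:
    """Read a measured/synthetic observable series file."""
    df = pd.read_csv(path)
    missing = set(SERIES_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_series(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def species_names(mech) -> list[str]:
    """Column order of the raw state vector, matching the integrator."""
    names = ["fe2", "fe3", "h2o2", "r_ho", "ho2_sink"]
    if mech is not None:
        names.append("target")
        names.extend(f"f{b}" for b in range(1, mech.chain.n_fragments + 1))
    names.append("mineralized_c")
    return names


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the full per-compartment history as long-format text."""
    names = species_names(traj.mechanism)
    nt, ncomp, nspec = traj.states.shape
    frames = []
    for c in range(ncomp):
        df = pd.DataFrame(traj.states[:, c, :] * 1e3, columns=names)
        df.insert(0, "time_min", traj.times_min)
        df.insert(1, "compartment", c + 1)
        frames.append(
            df.melt(
                id_vars=["time_min", "compartment"],
                var_name="species",
                value_name="concentration_mmol_per_L",
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_min", "compartment", "species", "concentration_mmol_per_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_params(
    path,
    core: CoreRateConstants | None = None,
    targets: Mapping[str, TargetRateConstants] | None = None,
) -> None:
    doc: dict = {}
    if core is not None:
        doc["core"] = {k: float(v) for k, v in asdict(core).items()}
    for name, kt in (targets or {}).items():
        doc[name] = {k: float(v) for k, v in asdict(kt).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_params(path) -> tuple[CoreRateConstants | None, dict[str, TargetRateConstants]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    core = None
    if "core" in doc:
        core = CoreRateConstants(**doc["core"])
    targets = {
        name: TargetRateConstants(**block)
        for name, block in doc.items()
        if name != "core"
    }
    return core, targets
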