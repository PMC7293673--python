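"""Derived observables: TOC, conversions, and the RMSE fit metric.

TOC is a lumped carbon balance over the fictitious fragments: the
target and every fragment contribute their fictitious carbon number
times their concentration; mineralized carbon has left the pool and is
excluded.  The RMSE compares normalized measured and simulated series
point-by-point (root of the mean squared residual, not normalized by
the mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import SpeciesState
from .mechanism import FragmentChain

__all__ = [
    "CARBON_MOLAR_MASS",
    "ObservableSeries",
    "toc",
    "toc_mg_per_l",
    "conversion",
    "rmse",
    "summary_rmse",
]

CARBON_MOLAR_MASS = 12.011  # g/mol, converts mmol C/L to mg C/L


@dataclass
class ObservableSeries:
    """A time series of one observable kind (target, TOC, or H2O2).

    Values are concentrations (mmol/L; mmol C/L for TOC) unless
    ``normalized`` is set, in which case they are value/initial.
    """

    times_min: np.ndarray
    values: np.ndarray
    kind: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("target", "TOC", "H2O2"):
            raise ValueError(f"unknown observable kind {self.kind!r}")
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if len(self.times_min) and np.any(np.diff(self.times_min) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(self.values < 0):
            raise ValueError("observable values must be non-negative")

    def normalize(self, initial: float | None = None) -> "ObservableSeries":
        """Divide by the initial value (first point unless given)."""
        if self.normalized:
            return self
        v0 = self.values[0] if initial is None else initial
        if v0 <= 0:
            raise ValueError("cannot normalize a series with zero initial value")
        return ObservableSeries(
            times_min=self.times_min.copy(),
            values=self.values / v0,
            kind=self.kind,
            normalized=True,
        )

    def at(self, t_min: float, atol: float = 1e-9) -> float:
        idx = np.flatnonzero(np.isclose(self.times_min, t_min, atol=atol))
        if not len(idx):
            raise ValueError(f"no sample at t = {t_min} min")
        return float(self.values[idx[0]])


def toc(organics, chain: FragmentChain) -> float:
    """TOC (same concentration unit as the inputs, times carbon atoms).

    ``organics`` is a concentration vector over target + fragments, or a
    :class:`SpeciesState`.  All organic species contribute with their
    fictitious carbon numbers; cumulative mineralized carbon does not.
    """
    if isinstance(organics, SpeciesState):
        organics = organics.organics
    organics = np.asarray(organics, dtype=float)
    fncs = np.asarray(chain.fncs)
    if organics.shape != fncs.shape:
        raise ValueError(
            f"got {organics.shape[0]} organic species, chain has {fncs.shape[0]}"
        )
    return float(organics @ fncs)


def toc_mg_per_l(organics, chain: FragmentChain) -> float:
    """TOC in mg C/L from concentrations in mmol/L."""
    return toc(organics, chain) * CARBON_MOLAR_MASS


def conversion(series: ObservableSeries, t_min: float) -> float:
    """Fractional conversion ``1 - value(t)/value(0)``."""
    v0 = series.values[0]
    if v0 <= 0:
        raise ValueError("conversion undefined for zero initial value")
    idx = int(np.argmin(np.abs(series.times_min - t_min)))
    return 1.0 - float(series.values[idx]) / float(v0)


def rmse(measured: ObservableSeries, simulated: ObservableSeries) -> float:
    """Root mean squared residual over the common sampling grid.

    Both series must be on the same time grid (the simulation is sampled
    at the measurement times beforehand).  The sum of squares is divided
    by the number of points only.
    """
    if measured.times_min.shape != simulated.times_min.shape or not np.allclose(
        measured.times_min, simulated.times_min
    ):
        raise ValueError("series are not on the same time grid")
    if len(measured.values) < 1:
        raise ValueError("need at least one point")
    resid = measured.values - simulated.values
    return float(np.sqrt(np.mean(resid**2)))


def summary_rmse(values) -> float:
    """Per-compound summary: arithmetic mean of per-experiment RMSEs."""
    values = np.asarray(list(values), dtype=float)
    if len(values) == 0:
        raise ValueError("no RMSE values to average")
    return float(values.mean())
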