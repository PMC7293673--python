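"""Staged parameter estimation and the synthetic-data generator.

Calibration follows the two-stage protocol of the pilot-plant study:

1. :class:`CoreKineticsModel` — the target-independent constants
   (k0, k1, k2, k_elim) are estimated from blank assays (iron + oxidant,
   no organics) against the measured H2O2 series.  Dark blanks constrain
   the Fenton cycle (k1, k2); irradiated blanks are required to estimate
   the photo constant k0.  The elimination constant has no influence on
   radical-free observables (the radicals feed nothing back), so it is
   structurally unidentifiable at this stage and simply retains its
   starting value; it is exposed for interface completeness and can be
   fixed explicitly.
2. :class:`TargetKineticsModel` — with the core fixed, the two
   compound-specific constants (k_target, k_fragment) are estimated from
   the target / TOC / H2O2 series of the compound's assays, weighted
   TOC > target > H2O2 (3:2:1 by default) to prioritize the lumped
   water-quality variable.

Both models expose a ``fit`` returning a results object with the
estimates, asymptotic standard errors, per-experiment RMSEs of the
normalized series, and a ``summary()`` table.  The search is bounded
multistart least squares on log10-transformed constants; the historical
trial-and-error search is replaced by this reproducible procedure.

The synthetic-data generator replays the assay structure of the study
(per-observable sampling grids, multiplicative measurement noise,
detection limit on the target) so the whole pipeline can be exercised
without any deposited measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .experiments import get_experiment
from .kinetics import (
    DEFAULT_CORE,
    TARGET_CONSTANTS,
    CoreRateConstants,
    TargetRateConstants,
)
from .observables import CARBON_MOLAR_MASS
from .reactor import ExperimentSpec, Trajectory, simulate
from .compounds import get_compound

__all__ = [
    "IdentifiabilityError",
    "DegenerateDataError",
    "SAMPLING_GRIDS",
    "SyntheticDataset",
    "generate_synthetic",
    "CoreKineticsModel",
    "CoreFitResults",
    "TargetKineticsModel",
    "TargetFitResults",
    "nominal_initial",
]


class IdentifiabilityError(ValueError):
    """A free parameter has no leverage on the available data."""


class DegenerateDataError(ValueError):
    """The measured series carry no usable signal."""


_TOC_GRID = tuple(float(t) for t in range(0, 121, 15))
_H2O2_GRID = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0, 120.0)

#: Per-compound measurement grids (minutes).  TOC comes every 15 min
#: (the analyzer's cycle time); H2O2 every 5 min up to 30 min and every
#: 15 min afterwards; the target grid follows each compound's HPLC
#: protocol (formic acid was followed through TOC only).
SAMPLING_GRIDS: dict[str, dict[str, tuple[float, ...]]] = {
    "PCT": {
        "target": (0.0, 1.5, 2.5, 5.0, 7.5, 10.0, 15.0),
        "TOC": _TOC_GRID,
        "H2O2": _H2O2_GRID,
    },
    "SQX": {
        "target": (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 45.0, 60.0, 75.0, 90.0, 120.0),
        "TOC": _TOC_GRID,
        "H2O2": _H2O2_GRID,
    },
    "FA": {
        "TOC": _TOC_GRID,
        "H2O2": _H2O2_GRID,
    },
    None: {"H2O2": _H2O2_GRID},
}

_UNITS = {"target": "mmol/L", "TOC": "mgC/L", "H2O2": "mmol/L"}


def nominal_initial(experiment: ExperimentSpec, kind: str) -> float:
    """Nominal initial value of an observable, in its measurement unit.

    Used to normalize series robustly (independent of noise on the t=0
    sample): the dosed concentrations for target and H2O2, and the
    carbon content of the dosed target for TOC (mg C/L).
    """
    if kind == "target":
        return experiment.target0
    if kind == "H2O2":
        return experiment.h2o2_0
    if kind == "TOC":
        if experiment.compound is None:
            raise ValueError("blank assay has no TOC")
        nc = get_compound(experiment.compound).nc
        return experiment.target0 * nc * CARBON_MOLAR_MASS
    raise ValueError(f"unknown observable kind {kind!r}")


def _series_value(traj: Trajectory, kind: str, times: Sequence[float]) -> np.ndarray:
    vals = traj.sample(kind, times)
    if kind == "TOC":
        vals = vals * CARBON_MOLAR_MASS  # mmol C/L -> mg C/L
    return vals


@dataclass
class SyntheticDataset:
    """Noisy observation series plus their generating ground truth."""

    data: pd.DataFrame  # experiment_id, time_min, kind, value, units
    truth: dict
    noise_sigma: float
    seed: int
    detection_limit: float

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def series(self, exp_id: str, kind: str) -> pd.DataFrame:
        mask = (self.data["experiment_id"] == exp_id) & (self.data["kind"] == kind)
        return self.data.loc[mask].sort_values("time_min")


def generate_synthetic(
    experiments: Iterable[ExperimentSpec | str],
    core: CoreRateConstants = DEFAULT_CORE,
    target_constants: Mapping[str, TargetRateConstants] | None = None,
    noise_sigma: float = 0.05,
    seed: int = 0,
    detection_limit: float = 1e-3,
    dt: float = 0.05,
    **simulate_kwargs,
) -> SyntheticDataset:
    """Simulate assays and sample them like the laboratory would.

    Each observable is sampled on its compound's measurement grid and
    perturbed with multiplicative Gaussian noise of relative standard
    deviation ``noise_sigma``; negative draws are truncated to zero and
    target values below ``detection_limit`` (mmol/L) are dropped, as a
    real HPLC series would simply lack those rows.  Each experiment gets
    an independent child stream of the master ``seed``; regenerating
    with the same seed reproduces the dataset exactly.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if target_constants is None:
        target_constants = TARGET_CONSTANTS
    specs = [
        get_experiment(e) if isinstance(e, str) else e for e in experiments
    ]
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(specs))
    rows = []
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        kt = (
            target_constants[spec.compound]
            if spec.compound is not None
            else None
        )
        traj = simulate(
            spec, core=core, target_constants=kt, dt=dt, **simulate_kwargs
        )
        grids = SAMPLING_GRIDS.get(spec.compound, SAMPLING_GRIDS[None])
        for kind, times in grids.items():
            if kind == "target" and spec.target0 <= 0:
                continue
            if kind == "H2O2" and spec.h2o2_0 <= 0:
                continue
            times = [t for t in times if t <= spec.duration_min]
            clean = _series_value(traj, kind, times)
            noisy = clean * (1.0 + noise_sigma * rng.standard_normal(len(clean)))
            noisy = np.clip(noisy, 0.0, None)
            for t, v in zip(times, noisy):
                if kind == "target" and v < detection_limit and t > 0:
                    continue
                rows.append(
                    {
                        "experiment_id": spec.id,
                        "time_min": t,
                        "kind": kind,
                        "value": v,
                        "units": _UNITS[kind],
                    }
                )
    data = pd.DataFrame(rows, columns=["experiment_id", "time_min", "kind", "value", "units"])
    truth = {
        "core": core,
        "target_constants": {
            s.compound: target_constants[s.compound]
            for s in specs
            if s.compound is not None
        },
    }
    return SyntheticDataset(
        data=data,
        truth=truth,
        noise_sigma=noise_sigma,
        seed=seed,
        detection_limit=detection_limit,
    )


# ---------------------------------------------------------------------------
# Fitting machinery shared by both stages.
# ---------------------------------------------------------------------------


def _decade_bounds(center: float) -> tuple[float, float]:
    return center / 10.0, center * 10.0


@dataclass
class _FitProblem:
    names: list[str]
    start: np.ndarray  # log10
    lo: np.ndarray  # log10
    hi: np.ndarray  # log10


def _multistart_points(
    problem: _FitProblem, n_starts: int, seed: int
) -> list[np.ndarray]:
    points = [problem.start]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        span = problem.hi - problem.lo
        for _ in range(n_starts - 1):
            points.append(problem.lo + rng.random(len(problem.lo)) * span)
    return points


def _run_multistart(residual_fn, problem: _FitProblem, n_starts: int, seed: int, xtol: float):
    best = None
    starts = []
    for x0 in _multistart_points(problem, n_starts, seed):
        r0 = residual_fn(x0)
        cost0 = 0.5 * float(r0 @ r0)
        sol = least_squares(
            residual_fn,
            x0,
            bounds=(problem.lo, problem.hi),
            method="trf",
            xtol=xtol,
            ftol=xtol,
            gtol=None,
        )
        starts.append({"x0": x0.copy(), "cost0": cost0, "cost": sol.cost})
        if best is None or sol.cost < best.cost:
            best = sol
    return best, starts


def _standard_errors(sol, n_resid: int) -> np.ndarray:
    """Asymptotic standard errors of the log10 parameters.

    From the Gauss-Newton covariance ``s2 (J'J)^-1`` with the pseudo-
    inverse; flat (unidentified) directions yield very large values.
    """
    n_par = sol.x.size
    dof = max(n_resid - n_par, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    cov = np.linalg.pinv(jtj) * s2
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


def _summary_table(title: str, rows: list[tuple], extra: list[str]) -> str:
    lines = [title, "=" * len(title)]
    lines.append(f"{'parameter':<12}{'estimate':>14}{'std err':>14}")
    for name, est, se in rows:
        se_s = f"{se:.3g}" if np.isfinite(se) else "n/a"
        lines.append(f"{name:<12}{est:>14.5g}{se_s:>14}")
    lines.extend(extra)
    return "\n".join(lines)


def _rmse_table(rmses: dict) -> pd.DataFrame:
    rows = [
        {"experiment_id": e, "kind": k, "rmse": v}
        for (e, k), v in sorted(rmses.items())
    ]
    return pd.DataFrame(rows, columns=["experiment_id", "kind", "rmse"])


class _StagedModel:
    """Shared plumbing: measured-series access and simulation sampling."""

    def __init__(
        self,
        data: pd.DataFrame,
        experiments: Sequence[ExperimentSpec | str] | None,
        dt: float,
        feed_duration_s: float,
        normalization: str,
    ):
        required = {"experiment_id", "time_min", "kind", "value"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        self.data = data.copy()
        if experiments is None:
            experiments = sorted(self.data["experiment_id"].unique())
        self.experiments = [
            get_experiment(e) if isinstance(e, str) else e for e in experiments
        ]
        self.dt = dt
        self.feed_duration_s = feed_duration_s
        self.normalization = normalization

    def _measured(self, exp_id: str, kind: str) -> tuple[np.ndarray, np.ndarray]:
        mask = (self.data["experiment_id"] == exp_id) & (self.data["kind"] == kind)
        sub = self.data.loc[mask].sort_values("time_min")
        return sub["time_min"].to_numpy(float), sub["value"].to_numpy(float)

    def _simulate(self, spec: ExperimentSpec, core, kt) -> Trajectory:
        return simulate(
            spec,
            core=core,
            target_constants=kt,
            dt=self.dt,
            feed_duration_s=self.feed_duration_s,
            normalization=self.normalization,
        )


# ---------------------------------------------------------------------------
# Stage 1: core constants from blank assays.
# ---------------------------------------------------------------------------


class CoreKineticsModel(_StagedModel):
    """Estimate the radical-core constants from blank H2O2 series.

    Parameters
    ----------
    data : DataFrame with columns experiment_id, time_min, kind, value;
        only the ``H2O2`` rows are used (mmol/L).
    experiments : the blank assay specs or registry IDs; resolved from
        the data's experiment IDs when omitted.  All must be free of
        organics.
    start, bounds : optional overrides per constant name; k1 and k2
        default to their literature ranges (0.1-11.7 and 63.0-76.0
        L mol^-1 s^-1), k0 and k_elim to one decade around the
        irradiance-derived and reference values.
    """

    PARAM_NAMES = ("k0", "k1", "k2", "k_elim")

    #: Literature-anchored default search ranges.
    DEFAULT_BOUNDS = {
        "k0": _decade_bounds(DEFAULT_CORE.k0),
        "k1": (0.1, 11.7),
        "k2": (63.0, 76.0),
        "k_elim": _decade_bounds(DEFAULT_CORE.k_elim),
    }

    def __init__(
        self,
        data: pd.DataFrame,
        experiments: Sequence[ExperimentSpec | str] | None = None,
        *,
        start: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        fixed: Mapping[str, float] | None = None,
        dt: float = 0.25,
        feed_duration_s: float = 30.0,
        normalization: str = "literal",
    ):
        super().__init__(data, experiments, dt, feed_duration_s, normalization)
        for spec in self.experiments:
            if spec.compound is not None:
                raise ValueError(
                    f"{spec.id}: core stage requires blank assays "
                    "(no target compound)"
                )
        self.fixed = dict(fixed or {})
        defaults = {
            "k0": DEFAULT_CORE.k0,
            "k1": DEFAULT_CORE.k1,
            "k2": DEFAULT_CORE.k2,
            "k_elim": DEFAULT_CORE.k_elim,
        }
        start = {**defaults, **(start or {})}
        self.free_names = [n for n in self.PARAM_NAMES if n not in self.fixed]
        if "k0" in self.free_names and not any(
            s.irradiated for s in self.experiments
        ):
            raise IdentifiabilityError(
                "k0 is free but no irradiated blank assay is available; "
                "fix k0 or add irradiated data"
            )
        lo, hi, x0 = [], [], []
        for name in self.free_names:
            b = (bounds or {}).get(name, self.DEFAULT_BOUNDS[name])
            lo.append(np.log10(b[0]))
            hi.append(np.log10(b[1]))
            x0.append(np.log10(np.clip(start[name], b[0], b[1])))
        self.problem = _FitProblem(
            names=self.free_names,
            start=np.array(x0),
            lo=np.array(lo),
            hi=np.array(hi),
        )
        self._targets = []
        for spec in self.experiments:
            times, values = self._measured(spec.id, "H2O2")
            if len(times) == 0:
                raise DegenerateDataError(f"{spec.id}: no H2O2 series in data")
            v0 = nominal_initial(spec, "H2O2")
            if v0 <= 0 or not values.any():
                raise DegenerateDataError(f"{spec.id}: degenerate H2O2 series")
            self._targets.append((spec, times, values / v0))

    def _constants(self, x: np.ndarray) -> CoreRateConstants:
        vals = dict(zip(self.free_names, 10.0**x))
        vals.update(self.fixed)
        return CoreRateConstants(**vals)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        core = self._constants(x)
        out = []
        for spec, times, obs_norm in self._targets:
            traj = self._simulate(spec, core, None)
            sim_norm = traj.sample("H2O2", times) / nominal_initial(spec, "H2O2")
            out.append(sim_norm - obs_norm)
        return np.concatenate(out)

    def fit(
        self, n_starts: int = 1, seed: int = 0, xtol: float = 1e-10
    ) -> "CoreFitResults":
        sol, starts = _run_multistart(
            self._residuals, self.problem, n_starts, seed, xtol
        )
        core = self._constants(sol.x)
        se_log = _standard_errors(sol, len(sol.fun))
        se = {
            n: 10.0 ** x * np.log(10.0) * s
            for n, x, s in zip(self.free_names, sol.x, se_log)
        }
        rmses = {}
        for spec, times, obs_norm in self._targets:
            traj = self._simulate(spec, core, None)
            sim = traj.sample("H2O2", times) / nominal_initial(spec, "H2O2")
            rmses[(spec.id, "H2O2")] = float(np.sqrt(np.mean((obs_norm - sim) ** 2)))
        return CoreFitResults(
            model=self,
            params=core,
            stderr=se,
            cost=float(sol.cost),
            rmse=_rmse_table(rmses),
            success=bool(sol.success),
            n_starts=n_starts,
            seed=seed,
            starts=starts,
            nfev=int(sol.nfev),
        )


@dataclass
class CoreFitResults:
    """Estimates and diagnostics of the core-stage fit."""

    model: CoreKineticsModel
    params: CoreRateConstants
    stderr: dict
    cost: float
    rmse: pd.DataFrame
    success: bool
    n_starts: int
    seed: int
    starts: list
    nfev: int

    def summary(self) -> str:
        rows = [
            (n, getattr(self.params, n), self.stderr.get(n, np.nan))
            for n in self.model.PARAM_NAMES
            if n in self.model.free_names
        ]
        extra = [
            f"fixed: {self.model.fixed}" if self.model.fixed else "fixed: none",
            f"experiments: {[s.id for s in self.model.experiments]}",
            f"cost: {self.cost:.6g}   nfev: {self.nfev}   "
            f"starts: {self.n_starts}   seed: {self.seed}",
            "mean H2O2 RMSE (normalized): "
            f"{self.rmse['rmse'].mean():.4f}",
        ]
        return _summary_table("Core kinetics fit", rows, extra)

    def simulate(self, experiment: ExperimentSpec | str, **kw) -> Trajectory:
        spec = get_experiment(experiment) if isinstance(experiment, str) else experiment
        return simulate(spec, core=self.params, **kw)


# ---------------------------------------------------------------------------
# Stage 2: compound-specific constants with the core fixed.
# ---------------------------------------------------------------------------

#: Objective weights encoding the TOC > target > H2O2 fitting priority.
DEFAULT_WEIGHTS = {"TOC": 3.0, "target": 2.0, "H2O2": 1.0}


class TargetKineticsModel(_StagedModel):
    """Estimate (k_target, k_fragment) for one compound, core fixed."""

    PARAM_NAMES = ("k_target", "k_fragment")

    def __init__(
        self,
        compound: str,
        data: pd.DataFrame,
        core: CoreRateConstants,
        experiments: Sequence[ExperimentSpec | str] | None = None,
        *,
        weights: Mapping[str, float] | None = None,
        start: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        dt: float = 0.25,
        feed_duration_s: float = 30.0,
        normalization: str = "literal",
    ):
        self.compound = compound.upper()
        if experiments is None and "experiment_id" in data.columns:
            ids = sorted(data["experiment_id"].unique())
            experiments = [
                i for i in ids if get_experiment(i).compound == self.compound
            ]
        super().__init__(data, experiments, dt, feed_duration_s, normalization)
        if not self.experiments:
            raise ValueError(f"no experiments for compound {self.compound}")
        for spec in self.experiments:
            if spec.compound != self.compound:
                raise ValueError(
                    f"{spec.id} is not a {self.compound} experiment"
                )
        self.core = core
        self.weights = dict(DEFAULT_WEIGHTS, **(weights or {}))
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("objective weights must be positive")
        ref = TARGET_CONSTANTS.get(self.compound)
        defaults = {
            "k_target": ref.k_target if ref else 1e2,
            "k_fragment": ref.k_fragment if ref else 1e1,
        }
        start = {**defaults, **(start or {})}
        lo, hi, x0 = [], [], []
        for name in self.PARAM_NAMES:
            b = (bounds or {}).get(name, _decade_bounds(defaults[name]))
            lo.append(np.log10(b[0]))
            hi.append(np.log10(b[1]))
            x0.append(np.log10(start[name]))
        self.problem = _FitProblem(
            names=list(self.PARAM_NAMES),
            start=np.array(x0),
            lo=np.array(lo),
            hi=np.array(hi),
        )
        self._targets = []
        any_signal = False
        for spec in self.experiments:
            kinds = []
            for kind in ("target", "TOC", "H2O2"):
                times, values = self._measured(spec.id, kind)
                if len(times) == 0:
                    continue
                v0 = nominal_initial(spec, kind)
                if v0 <= 0:
                    continue
                if values.any():
                    any_signal = True
                kinds.append((kind, times, values / v0))
            if not kinds:
                raise DegenerateDataError(f"{spec.id}: no usable series")
            self._targets.append((spec, kinds))
        if not any_signal:
            raise DegenerateDataError("all measured series are zero")

    def _constants(self, x: np.ndarray) -> TargetRateConstants:
        return TargetRateConstants(k_target=10.0 ** x[0], k_fragment=10.0 ** x[1])

    def _sim_norm(self, spec, kt, kind, times) -> np.ndarray:
        traj = self._traj_cache.get(spec.id)
        if traj is None:
            traj = self._simulate(spec, self.core, kt)
            self._traj_cache[spec.id] = traj
        vals = _series_value(traj, kind, times)
        return vals / nominal_initial(spec, kind)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        kt = self._constants(x)
        self._traj_cache: dict = {}
        out = []
        for spec, kinds in self._targets:
            for kind, times, obs_norm in kinds:
                sim_norm = self._sim_norm(spec, kt, kind, times)
                w = np.sqrt(self.weights[kind])
                out.append(w * (sim_norm - obs_norm))
        return np.concatenate(out)

    def fit(
        self, n_starts: int = 1, seed: int = 0, xtol: float = 1e-10
    ) -> "TargetFitResults":
        sol, starts = _run_multistart(
            self._residuals, self.problem, n_starts, seed, xtol
        )
        kt = self._constants(sol.x)
        se_log = _standard_errors(sol, len(sol.fun))
        se = {
            n: 10.0 ** x * np.log(10.0) * s
            for n, x, s in zip(self.PARAM_NAMES, sol.x, se_log)
        }
        rmses = {}
        self._traj_cache = {}
        for spec, kinds in self._targets:
            for kind, times, obs_norm in kinds:
                sim_norm = self._sim_norm(spec, kt, kind, times)
                rmses[(spec.id, kind)] = float(
                    np.sqrt(np.mean((obs_norm - sim_norm) ** 2))
                )
        return TargetFitResults(
            model=self,
            params=kt,
            stderr=se,
            cost=float(sol.cost),
            rmse=_rmse_table(rmses),
            success=bool(sol.success),
            n_starts=n_starts,
            seed=seed,
            starts=starts,
            nfev=int(sol.nfev),
        )


@dataclass
class TargetFitResults:
    """Estimates and diagnostics of the compound-stage fit."""

    model: TargetKineticsModel
    params: TargetRateConstants
    stderr: dict
    cost: float
    rmse: pd.DataFrame
    success: bool
    n_starts: int
    seed: int
    starts: list
    nfev: int

    def summary(self) -> str:
        rows = [
            (n, getattr(self.params, n), self.stderr.get(n, np.nan))
            for n in self.model.PARAM_NAMES
        ]
        kind_means = self.rmse.groupby("kind")["rmse"].mean()
        extra = [
            f"compound: {self.model.compound}",
            f"experiments: {[s.id for s in self.model.experiments]}",
            f"weights: {self.model.weights}",
            f"cost: {self.cost:.6g}   nfev: {self.nfev}   "
            f"starts: {self.n_starts}   seed: {self.seed}",
            "mean RMSE by kind (normalized, x100 = %): "
            + ", ".join(f"{k}={100 * v:.1f}%" for k, v in kind_means.items()),
        ]
        return _summary_table(
            f"{self.model.compound} degradation-mechanism fit", rows, extra
        )

    def simulate(self, experiment: ExperimentSpec | str, **kw) -> Trajectory:
        spec = get_experiment(experiment) if isinstance(experiment, str) else experiment
        return simulate(
            spec, core=self.model.core, target_constants=self.params, **kw
        )
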