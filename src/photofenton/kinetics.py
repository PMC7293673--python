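"""Reaction rates and species derivatives for one well-mixed volume.

The core radical chemistry is the H2O2-driven iron cycle

    Fe3+ + H2O2 -> Fe2+ + H+  + HO2.      (k1)
    Fe2+ + H2O2 -> Fe3+ + OH- + HO.       (k2)
    Fe3+ + H2O --light--> Fe2+ + H+ + HO. (k0, irradiance folded in)

plus a fictitious first-order inefficient elimination of HO.
(``k_elim``).  The organic cascade consists of second-order attacks of
HO. on the target and its fragments (see :mod:`photofenton.mechanism`).

All processes competing for HO. (elimination and every breakage step)
are damped by the competitive normalization

    r_i,mod = r_i**2 / (r_elim + sum_b r_b)

which keeps the fastest competitors from generating infeasible stiffness
while preserving their ordering.  The alternative "proportional" reading
leaves each competitor at its mass-action rate (each then receives the
share ``r_i / S`` of the total radical demand); it is available as a
switch but the squared form is the default.

pH is controlled experimentally, so [H+], [OH-] and [H2O] are clamped;
HO2. has no consuming reaction in the scheme and is routed to an inert
cumulative sink; dissolved O2 is carried as an inert constant.

Internal units are mol/L and seconds throughout; conversion from the
external mmol/L-and-minutes convention happens once at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mechanism import DegradationMechanism

__all__ = [
    "CoreRateConstants",
    "TargetRateConstants",
    "DEFAULT_CORE",
    "TARGET_CONSTANTS",
    "SpeciesState",
    "RateSet",
    "core_rates",
    "competing_rates",
    "normalize_competition",
    "assemble_derivatives",
    "WATER_MOLARITY",
    "KW",
    "DEFAULT_PH",
]

#: Clamped water molarity (mol/L) and ion product at 25 C.
WATER_MOLARITY = 55.5
KW = 1e-14
#: Operating pH of the pilot plant (controlled to 2.8 +/- 0.2).
DEFAULT_PH = 2.8


@dataclass(frozen=True)
class CoreRateConstants:
    """Target-independent rate constants of the radical core.

    k0 : photo-reduction of Fe3+, s^-1 (the lamp irradiance is folded in)
    k1 : Fe3+ + H2O2, L mol^-1 s^-1
    k2 : Fe2+ + H2O2, L mol^-1 s^-1
    k_elim : inefficient HO. elimination, s^-1
    """

    k0: float
    k1: float
    k2: float
    k_elim: float

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "k2", "k_elim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "CoreRateConstants":
        return replace(self, **kw)


@dataclass(frozen=True)
class TargetRateConstants:
    """The two compound-specific constants of the fragmentation cascade.

    k_target : first attack on the parent compound, L mol^-1 s^-1
    k_fragment : all subsequent fragment attacks, L mol^-1 s^-1
    """

    k_target: float
    k_fragment: float

    def __post_init__(self) -> None:
        if self.k_target < 0 or self.k_fragment < 0:
            raise ValueError("rate constants must be non-negative")


#: Reference estimates of the core constants for the 15-L pilot plant
#: (36 W/m2 lamp irradiance folded into k0).
DEFAULT_CORE = CoreRateConstants(k0=5.6e-2, k1=5.0, k2=63.0, k_elim=7.5e-2)

#: Reference compound-specific constants (L mol^-1 s^-1).
TARGET_CONSTANTS: dict[str, TargetRateConstants] = {
    "PCT": TargetRateConstants(k_target=15.0e2, k_fragment=1.5e2),
    "SQX": TargetRateConstants(k_target=4.5e2, k_fragment=3.5e2),
    "FA": TargetRateConstants(k_target=65.0e-2, k_fragment=7.5e-2),
}


@dataclass
class SpeciesState:
    """Concentrations (mol/L) of one well-mixed volume.

    ``organics`` holds the target (index 0) and its fragments;
    ``mineral_c`` is the cumulative mineralized carbon (mol C / L).
    [H+], [OH-], [H2O] are derived from the clamped pH, and ``o2`` and
    ``ho2_sink`` are inert.
    """

    fe2: float = 0.0
    fe3: float = 0.0
    h2o2: float = 0.0
    ho: float = 0.0
    organics: np.ndarray = None  # type: ignore[assignment]
    mineral_c: float = 0.0
    ho2_sink: float = 0.0
    o2: float = 2.5e-4
    ph: float = DEFAULT_PH

    def __post_init__(self) -> None:
        if self.organics is None:
            self.organics = np.zeros(0)
        self.organics = np.asarray(self.organics, dtype=float)
        if (
            min(self.fe2, self.fe3, self.h2o2, self.ho, self.mineral_c) < 0
            or (self.organics < 0).any()
        ):
            raise ValueError("concentrations must be non-negative")

    @property
    def hp(self) -> float:
        """[H+] clamped by the controlled pH (1.58e-3 mol/L at pH 2.8)."""
        return 10.0 ** (-self.ph)

    @property
    def ohn(self) -> float:
        """[OH-] from the water ion product at the clamped pH."""
        return KW / self.hp

    @property
    def h2o(self) -> float:
        return WATER_MOLARITY


@dataclass
class RateSet:
    """All reaction rates (mol L^-1 s^-1) at one state.

    ``r_b[j]`` is the attack on organic species ``j`` (the last entry is
    the terminal mineralization step).  ``normalized`` flags whether the
    competitive normalization has been applied to the HO.-consuming set.
    """

    r0: float = 0.0
    r1: float = 0.0
    r2: float = 0.0
    r_elim: float = 0.0
    r_b: np.ndarray = None  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.r_b is None:
            self.r_b = np.zeros(0)
        self.r_b = np.asarray(self.r_b, dtype=float)


def core_rates(
    state: SpeciesState, k: CoreRateConstants, irradiated: bool
) -> RateSet:
    """Mass-action rates of the iron/peroxide core.

    The photo step runs only in irradiated volumes; its rate is first
    order in Fe3+ with the irradiance folded into ``k0``.
    """
    r1 = k.k1 * state.fe3 * state.h2o2
    r2 = k.k2 * state.fe2 * state.h2o2
    r0 = k.k0 * state.fe3 if irradiated else 0.0
    return RateSet(r0=r0, r1=r1, r2=r2)


def competing_rates(
    state: SpeciesState,
    mech: DegradationMechanism | None,
    kt: TargetRateConstants | None,
    k_elim: float,
) -> tuple[float, np.ndarray]:
    """Raw rates of all processes competing for HO.

    Returns ``(r_elim, r_b)`` where ``r_b[j] = k_j [species_j] [HO.]``
    with ``k_0 = k_target`` and ``k_j = k_fragment`` for ``j >= 1``.
    """
    r_elim = k_elim * state.ho
    if mech is None or kt is None:
        return r_elim, np.zeros(0)
    if len(state.organics) != mech.n_species:
        raise ValueError(
            f"state has {len(state.organics)} organic species, "
            f"mechanism expects {mech.n_species}"
        )
    k_org = np.full(mech.n_species, kt.k_fragment)
    k_org[0] = kt.k_target
    r_b = k_org * state.organics * state.ho
    return r_elim, r_b


def normalize_competition(
    r_elim: float, r_b: np.ndarray, mode: str = "literal"
) -> tuple[float, np.ndarray]:
    """Apply the competitive normalization to the HO.-consuming rates.

    In ``"literal"`` mode every competitor i is replaced by
    ``r_i**2 / S`` with ``S = r_elim + sum(r_b)``; in ``"proportional"``
    mode the raw mass-action rates are kept (each competitor then takes
    the proportional share ``r_i / S`` of the total demand).  ``S = 0``
    maps everything to zero.
    """
    if mode == "proportional":
        return r_elim, np.asarray(r_b, dtype=float).copy()
    if mode != "literal":
        raise ValueError(f"unknown normalization mode {mode!r}")
    r_b = np.asarray(r_b, dtype=float)
    total = r_elim + r_b.sum()
    if total <= 0.0:
        return 0.0, np.zeros_like(r_b)
    return r_elim**2 / total, r_b**2 / total


def assemble_derivatives(
    state: SpeciesState, rates: RateSet, mech: DegradationMechanism | None
) -> SpeciesState:
    """Species time derivatives (mol L^-1 s^-1) from a normalized RateSet.

    Returned as a :class:`SpeciesState`-shaped object whose fields hold
    d/dt values.  The clamped species (H+, OH-, H2O) have no dynamics by
    construction; HO2. production (one per Fe3+ + H2O2 event) goes to
    the inert sink.
    """
    r_b = rates.r_b
    if mech is None:
        if len(r_b) or len(state.organics):
            raise ValueError("organic rates given without a mechanism")
        d_org = np.zeros(0)
        d_min = 0.0
    else:
        if len(r_b) != mech.n_species or len(state.organics) != mech.n_species:
            raise ValueError("rate/state/mechanism dimensions disagree")
        d_org = np.zeros(mech.n_species)
        d_org[0] = -r_b[0]
        mult = mech.chain.doubling
        for j in range(1, mech.n_species):
            d_org[j] = mult * r_b[j - 1] - r_b[j]
        d_min = mech.chain.fncs[-1] * r_b[-1]
    d_fe3 = rates.r2 - rates.r1 - rates.r0
    deriv = SpeciesState.__new__(SpeciesState)
    deriv.fe2 = -d_fe3
    deriv.fe3 = d_fe3
    deriv.h2o2 = -rates.r1 - rates.r2
    deriv.ho = rates.r2 + rates.r0 - rates.r_elim - r_b.sum()
    deriv.organics = d_org
    deriv.mineral_c = d_min
    deriv.ho2_sink = rates.r1
    deriv.o2 = 0.0
    deriv.ph = state.ph
    return deriv
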