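"""Algorithmic generation of a compound's degradation mechanism.

The degradation of a target with ``NC`` carbon atoms is modeled as a
cascade of hydroxyl-radical attacks on fictitious fragments.  Each
breakage step halves the fictitious carbon number and doubles the molar
amount::

    FR_{b-1} + HO.  ->  2 FR_b        FNC_b = NC / 2**b

The chain has ``F = ceil(log2 NC)`` fragments (so ``2**(F-1) < NC <=
2**F``) and ``F + 1`` reactions: the first attack on the target itself
(rate constant ``k_target``), the intermediate fragment attacks
(``k_fragment``), and a terminal attack on the last fragment whose carbon
leaves the organic pool as mineralized carbon.  Without that terminal
carbon-removing step the cascade would conserve organic carbon exactly
and TOC could never decrease.

A single-carbon target is the degenerate case: one 1:1 attack producing
a one-carbon intermediate, followed by the terminal mineralization of
that intermediate (two reactions, no doubling).

The fragments are explicitly fictitious bookkeeping species; non-integer
fictitious carbon numbers (e.g. 14 -> 7 -> 3.5 -> ...) carry no
structural meaning and simply weight each species' contribution to TOC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .compounds import Compound, InvalidCompoundError

__all__ = [
    "MINERALIZED",
    "FragmentChain",
    "Reaction",
    "DegradationMechanism",
    "build_fragment_chain",
    "build_mechanism",
]

#: Sentinel product for the terminal carbon-removing reaction.
MINERALIZED = "MINERALIZED"


@dataclass(frozen=True)
class FragmentChain:
    """Fictitious carbon numbers of the target (index 0) and its fragments.

    ``fncs[b]`` is the fictitious carbon number of species ``b``;
    ``doubling`` is the product multiplicity of each breakage step
    (2 for the halving cascade, 1 for the single-carbon special case).
    """

    fncs: tuple[float, ...]
    doubling: int = 2

    def __post_init__(self) -> None:
        if len(self.fncs) < 2:
            raise ValueError("chain needs the target and at least one fragment")
        if any(v <= 0 for v in self.fncs):
            raise ValueError("all fictitious carbon numbers must be positive")

    @property
    def n_fragments(self) -> int:
        """Number of fragment species F (chain length minus the target)."""
        return len(self.fncs) - 1

    @property
    def nc(self) -> float:
        return self.fncs[0]


class Reaction(NamedTuple):
    """One attack step: species ``reactant`` + HO. -> products."""

    reactant: int
    role: str  # "target" for the first attack, "fragment" afterwards
    product: int | str  # fragment index or MINERALIZED
    multiplicity: int


@dataclass(frozen=True)
class DegradationMechanism:
    """The ordered reaction list of one compound's degradation cascade."""

    chain: FragmentChain
    reactions: tuple[Reaction, ...]

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_species(self) -> int:
        """Organic species count (target + fragments)."""
        return len(self.chain.fncs)


def build_fragment_chain(nc: int | float) -> FragmentChain:
    """Build the halving chain for a target with ``nc`` carbon atoms.

    For ``nc >= 2`` the chain is ``nc / 2**b`` for ``b = 0..F`` with
    ``F = ceil(log2 nc)``; for ``nc = 1`` it is the 1 -> 1 chain with a
    single non-doubling intermediate.
    """
    if isinstance(nc, float) and not nc.is_integer():
        raise InvalidCompoundError(f"carbon count must be an integer, got {nc}")
    nc = int(nc)
    if nc < 1:
        raise InvalidCompoundError(f"carbon count must be >= 1, got {nc}")
    if nc == 1:
        return FragmentChain(fncs=(1.0, 1.0), doubling=1)
    n_frag = math.ceil(math.log2(nc))
    fncs = tuple(nc / 2.0**b for b in range(n_frag + 1))
    return FragmentChain(fncs=fncs, doubling=2)


def build_mechanism(compound: Compound) -> DegradationMechanism:
    """Generate the full reaction list for ``compound``.

    Every reaction is second order in (organic species, HO.).  The first
    attack carries the ``target`` rate constant, all subsequent attacks
    the ``fragment`` one; the final reaction removes the last fragment's
    carbon from the organic pool.
    """
    chain = build_fragment_chain(compound.nc)
    n_frag = chain.n_fragments
    reactions = [Reaction(0, "target", 1, chain.doubling)]
    for b in range(1, n_frag):
        reactions.append(Reaction(b, "fragment", b + 1, chain.doubling))
    reactions.append(Reaction(n_frag, "fragment", MINERALIZED, 1))
    return DegradationMechanism(chain=chain, reactions=tuple(reactions))
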