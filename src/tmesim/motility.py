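"""Immune-cell motility: Levy walks before activation, Brownian after.

Inactive cells draw a direction and a power-law run length
``z ~ F(z) = 1 - z^-l`` and persist in that direction for ``z`` steps;
activated cells hop to one of the 8 Moore neighbors chosen uniformly.
Moves succeed only onto empty in-grid sites.  A Levy walker that draws an
out-of-grid target stays put and its stored direction is mirrored away
from the offending edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import _kernels as kn
from .core_types import LEVY_KINDS, AgentKind, Lattice

__all__ = ["MotilityMode", "MotilityState", "sample_levy_run_length",
           "levy_step", "brownian_step"]


class MotilityMode(Enum):
    LEVY = "levy"
    BROWNIAN = "brownian"


@dataclass(frozen=True)
class MotilityState:
    mode: MotilityMode
    direction: int          # Moore direction index 0..7, or -1 if unset
    steps_remaining: int


def motility_state(lattice: Lattice, agent_index: int) -> MotilityState:
    """Current motility state of one immune agent."""
    kind = AgentKind(lattice.kind[agent_index])
    mode = MotilityMode.LEVY if kind in LEVY_KINDS else MotilityMode.BROWNIAN
    return MotilityState(
        mode=mode,
        direction=int(lattice.direction[agent_index]),
        steps_remaining=int(lattice.steps_remaining[agent_index]),
    )


def sample_levy_run_length(u: float, l: float) -> int:
    """Run length by inverse CDF: the smallest z >= 1 with 1 - z^-l >= u.

    Closed form ``z = ceil((1-u)^(-1/l))``; the pmf is
    ``P(Z=z) = (z-1)^-l - z^-l`` for z >= 2 (z = 1 only on the draw u = 0).
    """
    if not 0.0 <= u < 1.0:
        raise ValueError(f"u={u} must lie in [0, 1)")
    if l <= 1.0:
        raise ValueError(f"walk exponent l={l} must exceed 1")
    return int(kn.levy_run_length(u, l))


def levy_step(lattice: Lattice, agent_index: int, rng: np.random.Generator,
              l: float = 1.15) -> None:
    """Advance one Levy walker by one step (in place).

    If its run is exhausted, a new direction is drawn uniformly among empty
    Moore neighbors (deferred when none is empty) together with a fresh run
    length, and the cell moves immediately.  Blocked moves are forfeited
    but still consume a step of the run.
    """
    kn.levy_move(lattice.grid, lattice.kind, lattice.row, lattice.col,
                 lattice.direction, lattice.steps_remaining,
                 agent_index, l, rng)


def brownian_step(lattice: Lattice, agent_index: int,
                  rng: np.random.Generator) -> None:
    """Advance one Brownian walker: uniform over 8 directions, move if legal."""
    kn.brownian_move(lattice.grid, lattice.kind, lattice.row, lattice.col,
                     agent_index, rng)
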