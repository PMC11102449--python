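"""Lattice-wide stochastic interaction rules, one rule per operation.

Each operation sweeps the relevant agents in a freshly shuffled order and
applies a single interaction rule; the engine instead runs a single fused
shuffled phase in which every agent performs its interaction rule followed
by its movement.  Both paths share the per-agent rule kernels, so a rule
behaves identically whichever way it is invoked.

The rules (all per step of 2 min):

* a tumor cell with an empty Moore neighbor divides with probability
  P̄_tumor(U at its site, Ad), the daughter filling a random empty neighbor;
* an inactive DC adjacent to tumor activates with probability ``D_act``;
* an inactive T cell adjacent to an active DC activates with probability
  ``C_act`` and polarizes to Treg with probability P̄_Treg(U at the
  activating DC's site, Ad), else becomes an effector;
* an effector adjacent to tumor removes one uniformly chosen tumor
  neighbor with probability µ̄(U at its site, Ad) and survives (serial
  killing, at most one kill per step);
* an active DC adjacent to a Treg deactivates with probability ``D_inact``
  and resumes Levy motion with a fresh run.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as kn
from .core_types import AgentKind, Lattice, ParameterSet
from .oxygen_field import OxygenField

__all__ = ["tumor_division_step", "dc_activation_step", "t_activation_step",
           "effector_kill_step", "dc_inactivation_step"]


def tumor_division_step(lattice: Lattice, field: OxygenField, Ad: float,
                        params: ParameterSet, rng: np.random.Generator) -> int:
    """Apply the rim-only division rule to every tumor cell; returns births."""
    pk = params.kernel_array()
    n0 = lattice.n_tumor
    n = n0
    for slot in rng.permutation(n0):
        n = kn.try_divide(lattice.grid, lattice.tumor_row, lattice.tumor_col,
                          lattice.tumor_slot, lattice.blk_tumor, n, slot,
                          field.U, Ad, pk, rng)
    lattice.n_tumor = n
    return n - n0


def dc_activation_step(lattice: Lattice, params: ParameterSet,
                       rng: np.random.Generator) -> int:
    """Activate tumor-adjacent inactive DCs; returns number activated."""
    pk = params.kernel_array()
    idx = lattice.agent_indices(AgentKind.DC_INACTIVE)
    activated = 0
    for i in rng.permutation(idx):
        kn.try_dc_activation(lattice.grid, lattice.kind,
                             lattice.steps_remaining, lattice.row,
                             lattice.col, i, pk, rng)
        activated += lattice.kind[i] == AgentKind.DC_ACTIVE
    return int(activated)


def t_activation_step(lattice: Lattice, field: OxygenField, Ad: float,
                      params: ParameterSet, rng: np.random.Generator) -> int:
    """Activate T cells adjacent to active DCs; returns number activated."""
    pk = params.kernel_array()
    idx = lattice.agent_indices(AgentKind.T_INACTIVE)
    activated = 0
    for i in rng.permutation(idx):
        kn.try_t_activation(lattice.grid, lattice.kind,
                            lattice.steps_remaining, lattice.row,
                            lattice.col, i, field.U, Ad, pk, rng)
        activated += lattice.kind[i] != AgentKind.T_INACTIVE
    return int(activated)


def effector_kill_step(lattice: Lattice, field: OxygenField, Ad: float,
                       params: ParameterSet, rng: np.random.Generator) -> int:
    """Serial-killing sweep over all effectors; returns the kill count."""
    pk = params.kernel_array()
    idx = lattice.agent_indices(AgentKind.EFFECTOR)
    kills = 0
    for i in rng.permutation(idx):
        kills += kn.try_kill(lattice.grid, lattice.tumor_row,
                             lattice.tumor_col, lattice.tumor_slot,
                             lattice.blk_tumor, lattice.row[i], lattice.col[i],
                             field.U, Ad, pk, rng)
    lattice.n_tumor = kn.compact_tumor(lattice.tumor_row, lattice.tumor_col,
                                       lattice.tumor_slot, lattice.n_tumor)
    return int(kills)


def dc_inactivation_step(lattice: Lattice, params: ParameterSet,
                         rng: np.random.Generator) -> int:
    """Deactivate Treg-adjacent active DCs; returns number deactivated."""
    pk = params.kernel_array()
    idx = lattice.agent_indices(AgentKind.DC_ACTIVE)
    deactivated = 0
    for i in rng.permutation(idx):
        kn.try_dc_inactivation(lattice.grid, lattice.kind,
                               lattice.steps_remaining, lattice.row,
                               lattice.col, i, pk, rng)
        deactivated += lattice.kind[i] == AgentKind.DC_INACTIVE
    return int(deactivated)
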