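"""Domain types shared by every part of the simulator.

The model lives on an ``N x N`` square lattice with Moore (8-neighbor)
connectivity and hard walls.  Each site holds at most one agent: a tumor
cell, a dendritic cell (inactive or active), an inactive T lymphocyte, a
regulatory T cell, or an effector cell.  All model rates are expressed per
simulation step of ``dt_minutes`` (2 min) and are used directly as per-step
Bernoulli probabilities or forward-Euler increments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "AgentKind",
    "ParameterSet",
    "Lattice",
    "make_default_parameters",
    "moore_neighbors",
    "empty_moore_neighbors",
]


class AgentKind(IntEnum):
    """Occupancy codes for lattice sites; ``EMPTY`` marks a vacant site."""

    EMPTY = 0
    TUMOR = 1
    DC_INACTIVE = 2
    DC_ACTIVE = 3
    T_INACTIVE = 4
    TREG = 5
    EFFECTOR = 6


#: Kinds that move with a Levy walk (not yet activated by antigen).
LEVY_KINDS = (AgentKind.DC_INACTIVE, AgentKind.T_INACTIVE)

_PROBABILITY_FIELDS = ("D_act", "C_act", "D_inact", "mu", "P_Treg", "P_tumor")


@dataclass
class ParameterSet:
    """All model parameters; defaults are the calibrated murine 4T1 values.

    Rates carry the unit "per step" (one step = ``dt_minutes``).  The
    humoral parameters (``gamma`` .. ``k``) drive the adenosine / vaccine
    ODEs, the ``r_*`` pairs couple hypoxia ``1/(U+c)`` and adenosine ``Ad``
    into the tumor-division, Treg-polarization and cytotoxicity
    probabilities, and the remaining fields configure the lattice, the
    oxygen field and the initial cell inventory.
    """

    # humoral dynamics
    gamma: float = 0.000038   # vaccine (adenosine-inhibitor) effect on Ad
    a: float = 0.9412         # hypoxia -> adenosine production strength
    r: float = 0.07           # adenosine elimination rate
    beta: float = 12.0        # basal adenosine production rate
    lambda_s: float = 0.002   # adenosine-inhibitor elimination rate
    eta: float = 0.014        # hypoxia-inhibitor elimination rate
    k: float = 0.00004        # hypoxia-inhibitor -> oxygen source coefficient
    # hypoxia/adenosine couplings into per-step probabilities
    r_At: float = 0.000025    # adenosine effect on tumor division
    r_Ht: float = 0.0021      # hypoxia effect on tumor division
    r_Ar: float = 0.0015      # adenosine effect on Treg polarization
    r_Hr: float = 0.0047      # hypoxia effect on Treg polarization
    r_Ae: float = 0.001       # adenosine effect on cytotoxicity
    r_He: float = 0.014       # hypoxia effect on cytotoxicity
    # base per-step probabilities
    D_act: float = 0.003      # DC activation by adjacent tumor
    C_act: float = 0.24       # T-lymphocyte activation by adjacent active DC
    D_inact: float = 0.01     # DC inactivation by adjacent Treg
    mu: float = 0.45          # base effector cytotoxicity
    P_Treg: float = 0.3       # base Treg polarization probability
    P_tumor: float = 0.001    # base tumor division probability
    # Reference levels subtracted inside the tumor-division modulation: the
    # base division probability P_tumor is calibrated at the in-vivo
    # baseline, where the standing adenosine steady state
    # (beta + a/(U_b+c))/r = 188.03 is already present, so the adenosine
    # term drives division through the EXCESS over that baseline.  Setting
    # both references to 0 recovers the raw absolute-level form.  The Treg
    # and cytotoxicity modulations always use absolute levels.
    hypoxia_ref: float = 0.0
    adenosine_ref: float = 188.02821869488534  # (beta + a/(U_boundary+c)) / r
    # oxygen field
    f_bar: float = 0.0023     # oxygen consumption per tumor site per step
    c: float = 0.01           # denominator offset in 1/(U+c)
    alpha: float = 0.5        # diffusion coefficient, in (0, 1)
    diffusion_substeps: int = 10  # relaxation sub-iterations per 2-min step
    U_boundary: float = 0.8   # boundary (vessel) oxygen, mMol
    # start the field at the perfused (tumor-free) steady state; False gives
    # a zero interior that must fill in from the boundary vessels
    oxygen_equilibrated: bool = True
    # motility
    l: float = 1.15           # Levy walk exponent
    # inventory / geometry
    N_T: int = 750            # initial inactive T lymphocytes
    N_D: int = 100            # initial inactive DCs
    V_DC: int = 70            # active DCs per vaccine injection
    M: int = 800              # moving-average window for the siRNA drug
    N: int = 210              # lattice side length (divisible by 3)
    chi: float = 10.0         # site spacing, micrometers
    dt_minutes: float = 2.0
    # dosing and unit conversion
    dose_px: float = 40.0     # hypoxia-inhibitor bolus magnitude
    dose_s: float = 4200.0    # adenosine-inhibitor bolus magnitude
    volume_factor: float = 2200.0  # 2D area -> 3D volume factor
    site_area_mm2: float = 1e-4

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} must lie in (0, 1)")
        if self.l <= 1.0:
            raise ValueError(f"Levy exponent l={self.l} must exceed 1")
        if self.M < 1:
            raise ValueError("moving-average window M must be >= 1")
        if self.N < 9 or self.N % 3 != 0:
            raise ValueError("grid side N must be >= 9 and divisible by 3")
        if self.c <= 0:
            raise ValueError("offset c must be positive")
        if self.diffusion_substeps < 1:
            raise ValueError("diffusion_substeps must be >= 1")

    # -- config round trip ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def kernel_array(self) -> np.ndarray:
        """Pack the fields the agent-update kernels need into a flat array."""
        from . import _kernels as kn

        pk = np.zeros(kn.N_KERNEL_PARAMS, dtype=np.float64)
        pk[kn.K_PTUMOR] = self.P_tumor
        pk[kn.K_RHT] = self.r_Ht
        pk[kn.K_RAT] = self.r_At
        pk[kn.K_C] = self.c
        pk[kn.K_PTREG] = self.P_Treg
        pk[kn.K_RHR] = self.r_Hr
        pk[kn.K_RAR] = self.r_Ar
        pk[kn.K_MU] = self.mu
        pk[kn.K_RHE] = self.r_He
        pk[kn.K_RAE] = self.r_Ae
        pk[kn.K_DACT] = self.D_act
        pk[kn.K_CACT] = self.C_act
        pk[kn.K_DINACT] = self.D_inact
        pk[kn.K_LEXP] = self.l
        pk[kn.K_HREF] = self.hypoxia_ref
        pk[kn.K_ADREF] = self.adenosine_ref
        return pk


def make_default_parameters() -> ParameterSet:
    """Return the full calibrated default parameter set."""
    return ParameterSet()


# Moore-neighborhood offsets; index 7-d is the opposite direction of d.
MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


class Lattice:
    """Single-occupancy agent grid with flat per-agent state arrays.

    Immune agents (DCs and T-lineage cells) are stored in parallel arrays
    ``kind / row / col / direction / steps_remaining``; tumor cells, which
    never move, are stored as a coordinate list with a reverse-lookup grid
    ``tumor_slot`` so an effector kill can delete a site in O(1).
    """

    def __init__(self, n: int):
        if n < 3:
            raise ValueError("lattice side must be >= 3")
        self.n = int(n)
        self.grid = np.zeros((n, n), dtype=np.int8)
        self.kind = np.zeros(0, dtype=np.int8)
        self.row = np.zeros(0, dtype=np.int32)
        self.col = np.zeros(0, dtype=np.int32)
        self.direction = np.zeros(0, dtype=np.int8)
        self.steps_remaining = np.zeros(0, dtype=np.int32)
        self.tumor_row = np.zeros(n * n, dtype=np.int32)
        self.tumor_col = np.zeros(n * n, dtype=np.int32)
        self.n_tumor = 0
        self.tumor_slot = np.full((n, n), -1, dtype=np.int32)
        # per-block tumor counts (3x3 partition), kept incrementally
        nb = (n + 2) // 3
        self.blk_tumor = np.zeros((nb, nb), dtype=np.int32)

    # -- queries -----------------------------------------------------------
    def in_grid(self, site: tuple[int, int]) -> bool:
        r, c = site
        return 0 <= r < self.n and 0 <= c < self.n

    def is_empty(self, site: tuple[int, int]) -> bool:
        return self.grid[site] == AgentKind.EMPTY

    def tumor_mask(self) -> np.ndarray:
        return self.grid == AgentKind.TUMOR

    def counts(self) -> dict[AgentKind, int]:
        out = {k: 0 for k in AgentKind if k != AgentKind.EMPTY}
        out[AgentKind.TUMOR] = self.n_tumor
        for k in (AgentKind.DC_INACTIVE, AgentKind.DC_ACTIVE,
                  AgentKind.T_INACTIVE, AgentKind.TREG, AgentKind.EFFECTOR):
            out[k] = int(np.count_nonzero(self.kind == k))
        return out

    def agent_indices(self, kind: AgentKind) -> np.ndarray:
        return np.flatnonzero(self.kind == kind)

    def iter_tumor_sites(self) -> Iterator[tuple[int, int]]:
        for j in range(self.n_tumor):
            yield int(self.tumor_row[j]), int(self.tumor_col[j])

    # -- mutation ----------------------------------------------------------
    def add_immune(self, kind: AgentKind, site: tuple[int, int]) -> int:
        if not self.in_grid(site):
            raise ValueError(f"site {site} outside the grid")
        if not self.is_empty(site):
            raise ValueError(f"site {site} already occupied")
        self.kind = np.append(self.kind, np.int8(kind))
        self.row = np.append(self.row, np.int32(site[0]))
        self.col = np.append(self.col, np.int32(site[1]))
        self.direction = np.append(self.direction, np.int8(-1))
        self.steps_remaining = np.append(self.steps_remaining, np.int32(0))
        self.grid[site] = kind
        return self.kind.size - 1

    def add_tumor(self, site: tuple[int, int]) -> None:
        if not self.in_grid(site):
            raise ValueError(f"site {site} outside the grid")
        if not self.is_empty(site):
            raise ValueError(f"site {site} already occupied")
        j = self.n_tumor
        self.tumor_row[j] = site[0]
        self.tumor_col[j] = site[1]
        self.tumor_slot[site] = j
        self.grid[site] = AgentKind.TUMOR
        self.blk_tumor[site[0] // 3, site[1] // 3] += 1
        self.n_tumor += 1

    def remove_tumor(self, site: tuple[int, int]) -> None:
        j = int(self.tumor_slot[site])
        if j < 0:
            raise ValueError(f"no tumor cell at {site}")
        last = self.n_tumor - 1
        if j != last:
            lr, lc = self.tumor_row[last], self.tumor_col[last]
            self.tumor_row[j], self.tumor_col[j] = lr, lc
            self.tumor_slot[lr, lc] = j
        self.n_tumor = last
        self.tumor_slot[site] = -1
        self.grid[site] = AgentKind.EMPTY
        self.blk_tumor[site[0] // 3, site[1] // 3] -= 1

    # -- audits ------------------------------------------------------------
    def audit(self) -> None:
        """Full-grid consistency check; raises AssertionError on violation.

        Verifies single occupancy: every occupied grid site corresponds to
        exactly one stored agent of the matching kind, and vice versa.
        """
        rebuilt = np.zeros_like(self.grid)
        for j in range(self.n_tumor):
            r, c = self.tumor_row[j], self.tumor_col[j]
            assert rebuilt[r, c] == 0, f"double occupancy at {(r, c)}"
            assert self.tumor_slot[r, c] == j
            rebuilt[r, c] = AgentKind.TUMOR
        for i in range(self.kind.size):
            r, c = self.row[i], self.col[i]
            assert 0 <= r < self.n and 0 <= c < self.n, "agent out of grid"
            assert rebuilt[r, c] == 0, f"double occupancy at {(r, c)}"
            rebuilt[r, c] = self.kind[i]
            if AgentKind(self.kind[i]) not in LEVY_KINDS:
                assert self.steps_remaining[i] == 0, "Brownian agent with run"
        assert np.array_equal(rebuilt, self.grid), "grid/bookkeeping mismatch"
        blk = np.zeros_like(self.blk_tumor)
        for j in range(self.n_tumor):
            blk[self.tumor_row[j] // 3, self.tumor_col[j] // 3] += 1
        assert np.array_equal(blk, self.blk_tumor), "block tumor counts stale"

    def tumor_bbox(self) -> tuple[int, int, int, int] | None:
        """Inclusive (rmin, rmax, cmin, cmax) of tumor sites, or None."""
        if self.n_tumor == 0:
            return None
        rows = self.tumor_row[:self.n_tumor]
        cols = self.tumor_col[:self.n_tumor]
        return int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())


def moore_neighbors(lattice: Lattice, site: tuple[int, int]) -> list[tuple[int, int]]:
    """In-grid Moore neighbors of ``site`` (no wrap-around)."""
    if not lattice.in_grid(site):
        raise ValueError(f"site {site} outside the grid")
    r, c = site
    out = []
    for dr, dc in MOORE_OFFSETS:
        nr, nc = r + int(dr), c + int(dc)
        if 0 <= nr < lattice.n and 0 <= nc < lattice.n:
            out.append((nr, nc))
    return out


def empty_moore_neighbors(lattice: Lattice, site: tuple[int, int]) -> list[tuple[int, int]]:
    """Subset of :func:`moore_neighbors` whose sites are vacant."""
    return [s for s in moore_neighbors(lattice, site) if lattice.is_empty(s)]
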