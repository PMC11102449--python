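"""Block-coarsened oxygen diffusion with Dirichlet (vessel) boundaries.

The ``N x N`` grid is partitioned into fixed, non-overlapping 3x3 blocks
anchored at (0, 0).  Each step the block value is relaxed toward the mean
of its 3x3 Moore neighborhood of blocks at rate ``alpha``, tumor sites in
the block consume ``f_bar`` oxygen apiece (spread over the block's 9
sites), a spatially uniform hypoxia-inhibitor source ``k * px`` is added,
and the new block value is redistributed to all 9 sites.  Boundary sites
are pinned at ``U_boundary`` (blood vessels at the grid border), which is
how oxygen enters: border blocks contain pinned sites, so their block
means feel the boundary and the neighborhood coupling carries it inward.
Negative concentrations are clamped to zero.

To keep the uniform boundary value an exactly idempotent fixed point, the
update is computed on the residual ``U - U_boundary``.
"""

from __future__ import annotations

import json
from functools import lru_cache
from pathlib import Path

import numpy as np

from . import _kernels as kn
from .core_types import ParameterSet

__all__ = ["OxygenField", "block_average", "diffuse_step",
           "diffuse_step_blocks", "hypoxia_at", "dilate_mask",
           "tumor_neighborhood_mean"]


class OxygenField:
    """Oxygen concentration grid (mMol) with a fixed boundary value."""

    def __init__(self, n: int, U_boundary: float = 0.8,
                 equilibrated: bool = True):
        """``equilibrated=True`` starts the field at the tumor-free steady
        state (uniform vessel oxygen, as in perfused tissue before
        implantation); ``equilibrated=False`` starts the interior at zero
        so the field has to fill in from the boundary vessels."""
        if n % 3 != 0:
            raise ValueError("grid side must be divisible by 3")
        self.n = int(n)
        self.U_boundary = float(U_boundary)
        if equilibrated:
            self.U = np.full((n, n), self.U_boundary, dtype=np.float64)
        else:
            self.U = np.zeros((n, n), dtype=np.float64)
        self._impose_boundary()

    def _impose_boundary(self) -> None:
        self.U[0, :] = self.U_boundary
        self.U[-1, :] = self.U_boundary
        self.U[:, 0] = self.U_boundary
        self.U[:, -1] = self.U_boundary

    def copy(self) -> "OxygenField":
        out = OxygenField(self.n, self.U_boundary)
        out.U = self.U.copy()
        return out

    def save_snapshot(self, path: str | Path, day: float | None = None) -> None:
        """Dump the grid as CSV with a JSON sidecar holding metadata."""
        path = Path(path)
        np.savetxt(path, self.U, delimiter=",")
        meta = {"units": "mMol", "day": day, "n": self.n,
                "U_boundary": self.U_boundary}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def block_average(U: np.ndarray, block_center: tuple[int, int]) -> float:
    """Arithmetic mean of the 9 sites of one block of the fixed partition.

    ``block_center`` must be the middle site of a 3x3 block anchored at
    (0, 0), i.e. both coordinates are congruent to 1 modulo 3.
    """
    r, c = block_center
    if r % 3 != 1 or c % 3 != 1 or not (0 <= r < U.shape[0] and 0 <= c < U.shape[1]):
        raise ValueError(f"{block_center} is not a block center of the fixed partition")
    return float(U[r - 1:r + 2, c - 1:c + 2].mean())


@lru_cache(maxsize=8)
def _boundary_weight(nb: int) -> np.ndarray:
    """Fraction of non-boundary sites per block: (9 - pinned sites) / 9."""
    w = np.ones((nb, nb))
    w[0, :] = w[-1, :] = w[:, 0] = w[:, -1] = 6.0 / 9.0
    w[0, 0] = w[0, -1] = w[-1, 0] = w[-1, -1] = 4.0 / 9.0
    return w


def diffuse_step(field: OxygenField, tumor_mask: np.ndarray, px: float,
                 params: ParameterSet) -> None:
    """Advance the oxygen field by one simulation step (in place).

    Elementary block update: ``B <- B + alpha * (mean of 3x3 block
    neighborhood - B) - f_bar * (tumor sites in block) / 9 + k * px``, then
    redistribution of the block value to all 9 sites, clamping at 0 and
    re-imposition of the boundary.  Because oxygen transport relaxes much
    faster than the 2-min cell-dynamics step, the elementary update is
    applied ``diffusion_substeps`` times per step with the consumption and
    source terms split evenly across sub-iterations (total per step is
    still ``f_bar`` per tumor site and ``k * px``).  Computed on the
    residual from ``U_boundary`` so the uniform boundary value is an
    exactly idempotent fixed point.
    """
    nb = field.n // 3
    tumor_frac = tumor_mask.reshape(nb, 3, nb, 3).mean(axis=(1, 3))
    diffuse_step_blocks(field, tumor_frac, px, params)


def diffuse_step_blocks(field: OxygenField, tumor_frac: np.ndarray,
                        px: float, params: ParameterSet) -> None:
    """Same update as :func:`diffuse_step`, taking per-block tumor fractions
    directly (the engine maintains block tumor counts incrementally)."""
    nb = field.n // 3
    ks = params.diffusion_substeps
    S = kn.block_residual_means(field.U, field.U_boundary)
    sink = (params.f_bar / ks) * tumor_frac - (params.k / ks) * px
    sink = np.ascontiguousarray(sink, dtype=np.float64)
    kn.coarse_diffusion(S, sink, params.alpha, _boundary_weight(nb), ks,
                        field.U_boundary)
    kn.reconstruct_fine(field.U, S, field.U_boundary)


def hypoxia_at(field: OxygenField, site: tuple[int, int], c: float) -> float:
    """Local hypoxia level ``1 / (U(site) + c)``."""
    if c <= 0:
        raise ValueError("offset c must be positive")
    return float(1.0 / (field.U[site] + c))


def _dilate_chebyshev(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation of ``mask`` by a Chebyshev ball via shifted ORs."""
    out = mask.copy()
    for _ in range(radius):
        rows = out.copy()
        rows[1:, :] |= out[:-1, :]
        rows[:-1, :] |= out[1:, :]
        full = rows.copy()
        full[:, 1:] |= rows[:, :-1]
        full[:, :-1] |= rows[:, 1:]
        out = full
    return out


def dilate_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Sites within Chebyshev distance ``radius`` of any set site."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    return _dilate_chebyshev(mask, radius)


def tumor_neighborhood_mean(field: OxygenField, tumor_mask: np.ndarray) -> float:
    """Mean oxygen over tumor sites and their Moore neighbors.

    This is the spatial summary of ``U`` fed to the global adenosine ODE;
    with no tumor present it falls back to the grid mean.
    """
    if not tumor_mask.any():
        return float(field.U.mean())
    region = dilate_mask(tumor_mask, 1)
    return float(field.U[region].mean())
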