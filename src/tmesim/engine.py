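"""Simulation orchestration: initialization, the step loop, recorders and
replicate aggregation.

One step (2 min of biological time) applies, in order: protocol doses,
the two drug ODEs, oxygen diffusion, the global adenosine ODE, and a
shuffled agent phase in which every immune agent runs its interaction rule
followed by its movement and every tumor cell attempts rim division.
Tumor burden converts to volume as ``sites x 1e-4 mm^2 x 2200`` = 0.22
mm^3 per occupied site.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import _kernels as kn
from .core_types import AgentKind, Lattice, ParameterSet
from .humoral import HumoralState, step_adenosine, step_px, step_s
from .oxygen_field import OxygenField, dilate_mask, diffuse_step_blocks
from .protocols import ProtocolSpec, inject_dc_vaccine, to_step_schedule

__all__ = ["TrajectoryRecord", "ReplicateSummary", "initialize", "run",
           "run_replicates", "tumor_volume_mm3"]

#: Chebyshev radius defining "around the tumor" for the rim-effector metric.
RIM_RADIUS = 2

_SERIES = ("tumor_sites", "tumor_volume", "n_dc_inactive", "n_dc_active",
           "n_t_inactive", "n_treg", "n_effector", "Ad", "px", "s_raw",
           "S_t", "mean_mu_effectors", "mean_U_tumor", "rim_effectors",
           "cum_births", "cum_kills")


@dataclass
class TrajectoryRecord:
    """Time series recorded during one replicate."""

    step: np.ndarray
    day: np.ndarray
    series: dict[str, np.ndarray]
    params: ParameterSet
    protocol_name: str = "Untreated"
    seed: int | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"step": self.step, "day": self.day, **self.series})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def daily(self, name: str, horizon_days: int | None = None) -> np.ndarray:
        """Series value at (the recording closest to) each integer day."""
        horizon = int(self.day[-1]) if horizon_days is None else horizon_days
        days = np.arange(horizon + 1)
        idx = np.argmin(np.abs(self.day[None, :] - days[:, None]), axis=1)
        return self.series[name][idx]

    # scalar summaries used by the dose/timing experiments
    @property
    def mean_tumor_volume(self) -> float:
        return float(self.series["tumor_volume"].mean())

    @property
    def final_tumor_volume(self) -> float:
        return float(self.series["tumor_volume"][-1])

    @property
    def mean_rim_effectors(self) -> float:
        return float(self.series["rim_effectors"].mean())


def tumor_volume_mm3(n_sites: int | np.ndarray, params: ParameterSet):
    """Tumor volume in mm^3 from the occupied-site count."""
    return n_sites * params.site_area_mm2 * params.volume_factor


def initialize(params: ParameterSet, seed: int | np.random.Generator = 0
               ) -> tuple[Lattice, OxygenField, HumoralState, np.random.Generator]:
    """Day-0 state: one central tumor cell, scattered inactive DCs and T
    cells, zero interior oxygen, vessels at the boundary, all drugs zero."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = params.N
    if params.N_D + params.N_T + 1 > n * n:
        raise ValueError("initial cell inventory exceeds the lattice capacity")
    lattice = Lattice(n)
    center = (n // 2, n // 2)
    lattice.add_tumor(center)
    flat = rng.choice(n * n - 1, size=params.N_D + params.N_T, replace=False)
    # skip the occupied center when unflattening
    center_flat = center[0] * n + center[1]
    flat = np.where(flat >= center_flat, flat + 1, flat)
    kinds = [AgentKind.DC_INACTIVE] * params.N_D + [AgentKind.T_INACTIVE] * params.N_T
    for pos, kind in zip(flat, kinds):
        lattice.add_immune(kind, (int(pos) // n, int(pos) % n))
    field = OxygenField(n, params.U_boundary,
                        equilibrated=params.oxygen_equilibrated)
    hum = HumoralState(params.M)
    return lattice, field, hum, rng


def _u_effective(field: OxygenField, lattice: Lattice) -> float:
    """Mean oxygen over tumor sites + Moore neighbors, bbox-accelerated.

    Bit-identical to :func:`tmesim.oxygen_field.tumor_neighborhood_mean`
    on the full grid; falls back to the grid mean with no tumor present.
    """
    bbox = lattice.tumor_bbox()
    if bbox is None:
        return float(field.U.mean())
    r0, r1, c0, c1 = bbox
    r0 = max(r0 - 1, 0)
    c0 = max(c0 - 1, 0)
    r1 = min(r1 + 1, lattice.n - 1)
    c1 = min(c1 + 1, lattice.n - 1)
    sub = lattice.tumor_slot[r0:r1 + 1, c0:c1 + 1] >= 0
    region = dilate_mask(sub, 1)
    return float(field.U[r0:r1 + 1, c0:c1 + 1][region].mean())


def _record(rec: dict, step: int, day: float, lattice: Lattice,
            field: OxygenField, hum: HumoralState, params: ParameterSet,
            pk: np.ndarray, u_eff: float, births: int, kills: int) -> None:
    counts = lattice.counts()
    eff_idx = lattice.agent_indices(AgentKind.EFFECTOR)
    if eff_idx.size:
        u_eff_sites = field.U[lattice.row[eff_idx], lattice.col[eff_idx]]
        mean_mu = float(np.mean([kn.cytotoxicity_rate_kernel(u, hum.Ad, pk)
                                 for u in u_eff_sites]))
    else:
        mean_mu = float(kn.cytotoxicity_rate_kernel(u_eff, hum.Ad, pk))
    mask = lattice.tumor_mask()
    if mask.any() and eff_idx.size:
        rim = dilate_mask(mask, RIM_RADIUS)
        rim_eff = int(np.count_nonzero(
            rim[lattice.row[eff_idx], lattice.col[eff_idx]]))
    else:
        rim_eff = 0
    rec["step"].append(step)
    rec["day"].append(day)
    rec["tumor_sites"].append(lattice.n_tumor)
    rec["tumor_volume"].append(tumor_volume_mm3(lattice.n_tumor, params))
    rec["n_dc_inactive"].append(counts[AgentKind.DC_INACTIVE])
    rec["n_dc_active"].append(counts[AgentKind.DC_ACTIVE])
    rec["n_t_inactive"].append(counts[AgentKind.T_INACTIVE])
    rec["n_treg"].append(counts[AgentKind.TREG])
    rec["n_effector"].append(counts[AgentKind.EFFECTOR])
    rec["Ad"].append(hum.Ad)
    rec["px"].append(hum.px)
    rec["s_raw"].append(hum.s_raw)
    rec["S_t"].append(hum.S_t)
    rec["mean_mu_effectors"].append(mean_mu)
    rec["mean_U_tumor"].append(u_eff)
    rec["rim_effectors"].append(rim_eff)
    rec["cum_births"].append(births)
    rec["cum_kills"].append(kills)


def run(params: ParameterSet, protocol: ProtocolSpec | None = None,
        seed: int = 0, horizon_days: int = 18, record_every: int = 60,
        audit_every: int | None = None) -> TrajectoryRecord:
    """Run one replicate and return its trajectory.

    The run is fully determined by ``(params, protocol, seed)``; replays
    are bit-identical.  ``record_every`` sets the recording interval in
    steps (default 60, i.e. every 2 h); ``audit_every`` optionally runs a
    full single-occupancy/bookkeeping audit at that step interval.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    protocol = protocol or ProtocolSpec("Untreated")
    lattice, field, hum, rng = initialize(params, seed)
    sched = to_step_schedule(protocol, params, horizon_days)
    n_steps = sched.px_bolus.size
    pk = params.kernel_array()
    rec: dict[str, list] = {k: [] for k in ("step", "day", *_SERIES)}
    births_total = 0
    kills_total = 0
    rim_buf = np.empty(lattice.grid.size, dtype=np.int64)
    _record(rec, 0, 0.0, lattice, field, hum, params, pk,
            _u_effective(field, lattice), 0, 0)
    for step in range(n_steps):
        if sched.dc_counts[step]:
            inject_dc_vaccine(lattice, int(sched.dc_counts[step]), rng)
        pxb = sched.px_bolus[step]
        sb = sched.s_bolus[step]
        step_px(hum, pxb > 0, params,
                dose_scale=pxb / params.dose_px if pxb > 0 else 1.0)
        step_s(hum, sb > 0, params,
               dose_scale=sb / params.dose_s if sb > 0 else 1.0)
        diffuse_step_blocks(field, lattice.blk_tumor / 9.0, hum.px, params)
        u_eff = _u_effective(field, lattice)
        step_adenosine(hum, u_eff, params)
        n_rim = kn.find_rim_slots(lattice.grid, lattice.tumor_row,
                                  lattice.tumor_col, lattice.n_tumor, rim_buf)
        perm = rng.permutation(lattice.kind.size + n_rim)
        n_tumor, births, kills = kn.agent_phase(
            lattice.grid, lattice.kind, lattice.row, lattice.col,
            lattice.direction, lattice.steps_remaining,
            lattice.tumor_row, lattice.tumor_col, lattice.tumor_slot,
            lattice.blk_tumor, lattice.n_tumor, rim_buf,
            field.U, hum.Ad, pk, perm, rng)
        lattice.n_tumor = n_tumor
        births_total += births
        kills_total += kills
        if audit_every and (step + 1) % audit_every == 0:
            lattice.audit()
        if (step + 1) % record_every == 0 or step == n_steps - 1:
            _record(rec, step + 1, (step + 1) / sched.steps_per_day,
                    lattice, field, hum, params, pk, u_eff,
                    births_total, kills_total)
    arrays = {k: np.asarray(v) for k, v in rec.items()}
    return TrajectoryRecord(
        step=arrays.pop("step"), day=arrays.pop("day"), series=arrays,
        params=params, protocol_name=protocol.name, seed=seed)


@dataclass
class ReplicateSummary:
    """Per-day mean and 95% CI over replicates, plus scalar summaries."""

    protocol_name: str
    n_replicates: int
    days: np.ndarray
    mean: dict[str, np.ndarray]
    ci_halfwidth: dict[str, np.ndarray]
    per_replicate: pd.DataFrame
    replicates: list[TrajectoryRecord] = dc_field(default_factory=list, repr=False)

    @property
    def mean_tumor_volume(self) -> float:
        """Average tumor volume over the horizon, averaged over replicates."""
        return float(self.per_replicate["mean_tumor_volume"].mean())

    @property
    def final_tumor_volume(self) -> float:
        """Tumor volume on the final day, averaged over replicates."""
        return float(self.per_replicate["final_tumor_volume"].mean())

    @property
    def mean_rim_effectors(self) -> float:
        return float(self.per_replicate["mean_rim_effectors"].mean())

    def ci_of(self, column: str) -> float:
        vals = self.per_replicate[column].to_numpy()
        if vals.size < 2:
            return 0.0
        return float(1.96 * vals.std(ddof=1) / np.sqrt(vals.size))

    def to_json_dict(self) -> dict:
        return {
            "protocol": self.protocol_name,
            "n_replicates": self.n_replicates,
            "days": self.days.tolist(),
            "mean": {k: v.tolist() for k, v in self.mean.items()},
            "ci_halfwidth": {k: v.tolist() for k, v in self.ci_halfwidth.items()},
            "mean_tumor_volume": self.mean_tumor_volume,
            "final_tumor_volume": self.final_tumor_volume,
            "mean_rim_effectors": self.mean_rim_effectors,
        }


def _ci_halfwidth(stack: np.ndarray) -> np.ndarray:
    n = stack.shape[0]
    if n < 2:
        return np.zeros(stack.shape[1])
    return 1.96 * stack.std(axis=0, ddof=1) / np.sqrt(n)


def run_replicates(params: ParameterSet, protocol: ProtocolSpec | None,
                   seeds, horizon_days: int = 18, record_every: int = 60,
                   keep_trajectories: bool = False) -> ReplicateSummary:
    """Run independent replicates and aggregate daily means and 95% CIs.

    ``seeds`` may be an integer replicate count (seeds ``0..n-1``) or an
    explicit sequence of seeds.
    """
    if isinstance(seeds, (int, np.integer)):
        seeds = list(range(int(seeds)))
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed is required")
    protocol = protocol or ProtocolSpec("Untreated")
    trajs = [run(params, protocol, seed=s, horizon_days=horizon_days,
                 record_every=record_every) for s in seeds]
    days = np.arange(horizon_days + 1)
    mean: dict[str, np.ndarray] = {}
    ci: dict[str, np.ndarray] = {}
    for name in _SERIES:
        stack = np.stack([t.daily(name, horizon_days) for t in trajs])
        mean[name] = stack.mean(axis=0)
        ci[name] = _ci_halfwidth(stack)
    per_rep = pd.DataFrame({
        "seed": seeds,
        "mean_tumor_volume": [t.mean_tumor_volume for t in trajs],
        "final_tumor_volume": [t.final_tumor_volume for t in trajs],
        "mean_rim_effectors": [t.mean_rim_effectors for t in trajs],
    })
    return ReplicateSummary(
        protocol_name=protocol.name, n_replicates=len(seeds), days=days,
        mean=mean, ci_halfwidth=ci, per_replicate=per_rep,
        replicates=trajs if keep_trajectories else [])
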