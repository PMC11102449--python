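"""Treatment schedules: experimental groups and dose/timing variants.

The eight experimental groups combine three interventions: the hypoxia
inhibitor Px-478 (days 6, 8, 10, 13, 15), the adenosine-inhibitor siRNA
nanoparticle (days 6, 9, 12, 15) and a DC vaccine (70 active DCs on day
7).  Variants modify the best-performing triple-therapy group: shifting or
repeating the DC injection, scaling doses, or re-spacing the drug
schedules.  A protocol is converted to per-step boluses before a run
("day d" is the first step of day d, i.e. step d * 720 at 2-min steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .core_types import AgentKind, Lattice

__all__ = ["ProtocolSpec", "StepSchedule", "GROUP_NAMES", "group_protocol",
           "variant_protocol", "dose_timing_variants", "to_step_schedule",
           "schedule_to_protocol", "inject_dc_vaccine"]

HORIZON_DAYS = 18
DEFAULT_DC_COUNT = 70


@dataclass(frozen=True)
class ProtocolSpec:
    """One treatment schedule; dose scales of 1.0 mean the standard dose."""

    name: str = "custom"
    px_days: tuple[int, ...] = ()
    s_days: tuple[int, ...] = ()
    dc_events: tuple[tuple[int, int], ...] = ()  # (day, active-DC count)
    px_dose_scale: float = 1.0
    s_dose_scale: float = 1.0

    def __post_init__(self):
        for d in (*self.px_days, *self.s_days, *(e[0] for e in self.dc_events)):
            if not 0 <= d <= HORIZON_DAYS:
                raise ValueError(f"day {d} outside [0, {HORIZON_DAYS}]")
        if self.px_dose_scale <= 0 or self.s_dose_scale <= 0:
            raise ValueError("dose scales must be positive")
        if any(count < 0 for _, count in self.dc_events):
            raise ValueError("DC cell counts must be >= 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "px_days": list(self.px_days),
            "s_days": list(self.s_days),
            "dc_events": [list(e) for e in self.dc_events],
            "px_dose_scale": self.px_dose_scale,
            "s_dose_scale": self.s_dose_scale,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ProtocolSpec":
        return cls(
            name=data.get("name", "custom"),
            px_days=tuple(data.get("px_days", ())),
            s_days=tuple(data.get("s_days", ())),
            dc_events=tuple((int(d), int(c)) for d, c in data.get("dc_events", ())),
            px_dose_scale=float(data.get("px_dose_scale", 1.0)),
            s_dose_scale=float(data.get("s_dose_scale", 1.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ProtocolSpec":
        from pathlib import Path
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_PX_DAYS = (6, 8, 10, 13, 15)
_S_DAYS = (6, 9, 12, 15)
_DC = ((7, DEFAULT_DC_COUNT),)

_GROUPS = {
    "Untreated": ProtocolSpec("Untreated"),
    "Px-478": ProtocolSpec("Px-478", px_days=_PX_DAYS),
    "siRNA": ProtocolSpec("siRNA", s_days=_S_DAYS),
    "DC": ProtocolSpec("DC", dc_events=_DC),
    "Px-478+DC": ProtocolSpec("Px-478+DC", px_days=_PX_DAYS, dc_events=_DC),
    "siRNA+DC": ProtocolSpec("siRNA+DC", s_days=_S_DAYS, dc_events=_DC),
    "siRNA+Px-478": ProtocolSpec("siRNA+Px-478", px_days=_PX_DAYS, s_days=_S_DAYS),
    "siRNA+Px-478+DC": ProtocolSpec("siRNA+Px-478+DC", px_days=_PX_DAYS,
                                    s_days=_S_DAYS, dc_events=_DC),
}

GROUP_NAMES = tuple(_GROUPS)


def group_protocol(name: str) -> ProtocolSpec:
    """Schedule for one of the eight experimental groups, unit dose scales."""
    try:
        return _GROUPS[name]
    except KeyError:
        raise ValueError(
            f"unknown group {name!r}; valid names: {', '.join(GROUP_NAMES)}"
        ) from None


def _every(k: int) -> tuple[int, ...]:
    if k < 1:
        raise ValueError("injection interval must be >= 1 day")
    return tuple(range(6, HORIZON_DAYS, k))


def variant_protocol(base: ProtocolSpec, modification: dict) -> ProtocolSpec:
    """Apply dose/timing modifications to ``base``; other fields untouched.

    Supported keys: ``dc_day`` (single injection day), ``dc_scale``
    (multiply cell counts, rounded), ``dc_repeat`` = (n, interval_days)
    (n injections from day 7), ``px_every`` / ``s_every`` (re-space from
    day 6), ``px_scale`` / ``s_scale`` (dose multipliers),
    ``alternate_start`` ("Px-478" or "siRNA": daily alternation, days
    6..17).
    """
    spec = base
    mod = dict(modification)
    base_count = base.dc_events[0][1] if base.dc_events else DEFAULT_DC_COUNT
    if "dc_day" in mod:
        spec = replace(spec, dc_events=((int(mod.pop("dc_day")), base_count),))
    if "dc_repeat" in mod:
        n, interval = mod.pop("dc_repeat")
        if n < 1 or interval < 1:
            raise ValueError("dc_repeat needs n >= 1 and interval >= 1")
        days = [7 + i * interval for i in range(n)]
        spec = replace(spec, dc_events=tuple((d, base_count) for d in days))
    if "dc_scale" in mod:
        sc = float(mod.pop("dc_scale"))
        if sc < 0:
            raise ValueError("dc_scale must be >= 0")
        spec = replace(spec, dc_events=tuple(
            (d, int(round(c * sc))) for d, c in spec.dc_events))
    if "px_every" in mod:
        spec = replace(spec, px_days=_every(int(mod.pop("px_every"))))
    if "s_every" in mod:
        spec = replace(spec, s_days=_every(int(mod.pop("s_every"))))
    if "px_scale" in mod:
        sc = float(mod.pop("px_scale"))
        if sc <= 0:
            raise ValueError("px_scale must be positive")
        spec = replace(spec, px_dose_scale=spec.px_dose_scale * sc)
    if "s_scale" in mod:
        sc = float(mod.pop("s_scale"))
        if sc <= 0:
            raise ValueError("s_scale must be positive")
        spec = replace(spec, s_dose_scale=spec.s_dose_scale * sc)
    if "alternate_start" in mod:
        first = mod.pop("alternate_start")
        odd = tuple(range(6, HORIZON_DAYS, 2))
        even = tuple(range(7, HORIZON_DAYS, 2))
        if first == "Px-478":
            spec = replace(spec, px_days=odd, s_days=even)
        elif first == "siRNA":
            spec = replace(spec, s_days=odd, px_days=even)
        else:
            raise ValueError("alternate_start must be 'Px-478' or 'siRNA'")
    if mod:
        raise ValueError(f"unknown modification keys: {sorted(mod)}")
    if "name" not in modification:
        spec = replace(spec, name=f"{base.name} [{modification}]")
    return spec


def dose_timing_variants() -> dict[str, ProtocolSpec]:
    """The full battery of dose/timing variants of the triple therapy."""
    base = group_protocol("siRNA+Px-478+DC")
    out: dict[str, ProtocolSpec] = {}

    def add(label, mod):
        out[label] = replace(variant_protocol(base, mod), name=label)

    for day in (6, 7, 8):
        add(f"dc_day{day}", {"dc_day": day})
    for sc in (0.7, 1.3, 1.5):
        add(f"dc_dose_x{sc}", {"dc_scale": sc})
    for n in (2, 4, 6):
        add(f"dc_{n}x_interval1", {"dc_repeat": (n, 1)})
        add(f"dc_{n}x_interval2", {"dc_repeat": (n, 2)})
    for k, word in ((1, "everyday"), (2, "every2days"), (3, "every3days")):
        add(f"sirna_{word}", {"s_every": k})
        add(f"px_{word}", {"px_every": k})
    for sc in (0.7, 1.3, 1.5):
        add(f"sirna_dose_x{sc}", {"s_scale": sc})
        add(f"px_dose_x{sc}", {"px_scale": sc})
    for sc in (1.3, 1.5, 1.7):
        for k in (1, 2, 3):
            add(f"both_x{sc}_every{k}",
                {"px_scale": sc, "s_scale": sc, "px_every": k, "s_every": k})
    add("alternate_start_px", {"alternate_start": "Px-478"})
    add("alternate_start_sirna", {"alternate_start": "siRNA"})
    return out


@dataclass
class StepSchedule:
    """Per-step dose events for one run."""

    px_bolus: np.ndarray   # float, bolus magnitude added at each step
    s_bolus: np.ndarray
    dc_counts: np.ndarray  # int, active DCs injected at each step
    steps_per_day: int


def to_step_schedule(protocol: ProtocolSpec, params, horizon_days: int) -> StepSchedule:
    """Expand day-based schedules into per-step bolus/injection arrays."""
    spd = int(round(24 * 60 / params.dt_minutes))
    n_steps = horizon_days * spd
    px = np.zeros(n_steps)
    s = np.zeros(n_steps)
    dc = np.zeros(n_steps, dtype=np.int64)
    for d in protocol.px_days:
        if d * spd < n_steps:
            px[d * spd] += params.dose_px * protocol.px_dose_scale
    for d in protocol.s_days:
        if d * spd < n_steps:
            s[d * spd] += params.dose_s * protocol.s_dose_scale
    for d, count in protocol.dc_events:
        if d * spd < n_steps:
            dc[d * spd] += count
    return StepSchedule(px, s, dc, spd)


def schedule_to_protocol(schedule: StepSchedule, params,
                         name: str = "custom") -> ProtocolSpec:
    """Inverse of :func:`to_step_schedule` (uniform dose scales assumed)."""
    spd = schedule.steps_per_day
    px_steps = np.flatnonzero(schedule.px_bolus)
    s_steps = np.flatnonzero(schedule.s_bolus)
    dc_steps = np.flatnonzero(schedule.dc_counts)
    px_scales = schedule.px_bolus[px_steps] / params.dose_px
    s_scales = schedule.s_bolus[s_steps] / params.dose_s
    for arr, what in ((px_scales, "px"), (s_scales, "s")):
        if arr.size and not np.allclose(arr, arr[0]):
            raise ValueError(f"non-uniform {what} dose scales cannot round-trip")
    return ProtocolSpec(
        name=name,
        px_days=tuple(int(t) // spd for t in px_steps),
        s_days=tuple(int(t) // spd for t in s_steps),
        dc_events=tuple((int(t) // spd, int(schedule.dc_counts[t]))
                        for t in dc_steps),
        px_dose_scale=float(px_scales[0]) if px_scales.size else 1.0,
        s_dose_scale=float(s_scales[0]) if s_scales.size else 1.0,
    )


def inject_dc_vaccine(lattice: Lattice, count: int,
                      rng: np.random.Generator) -> int:
    """Scatter ``count`` active DCs uniformly over empty sites.

    If fewer empty sites exist, all of them are filled and a warning is
    issued.  Returns the number actually placed.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return 0
    empties = np.argwhere(lattice.grid == AgentKind.EMPTY)
    if count > len(empties):
        warnings.warn(
            f"DC vaccine of {count} cells exceeds the {len(empties)} empty "
            "sites; filling all of them", RuntimeWarning, stacklevel=2)
        count = len(empties)
    chosen = empties[rng.choice(len(empties), size=count, replace=False)]
    for r, c in chosen:
        lattice.add_immune(AgentKind.DC_ACTIVE, (int(r), int(c)))
    return count
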