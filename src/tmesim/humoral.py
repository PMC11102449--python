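"""Global humoral state: adenosine and the two inhibitor vaccines.

Adenosine ``Ad`` is a single grid-wide scalar produced at a basal rate
``beta`` plus a hypoxia-driven term ``a / (U_eff + c)``, eliminated at rate
``r`` and additionally degraded by the adenosine-inhibitor drug at rate
``gamma * S_t * Ad``.  The two drugs follow bolus-decay kinetics
(``px' = v(t) - eta*px`` for the hypoxia inhibitor, ``s' = v_s(t) -
lambda*s`` for the adenosine inhibitor); because the adenosine inhibitor is
adhesive and accumulates in the tumor area, the level that acts on ``Ad``
is a length-``M`` moving average ``S_t`` of ``s``, zero-padded before ``M``
samples exist.  All updates are forward Euler with the time unit equal to
one simulation step.
"""

from __future__ import annotations

import numpy as np

from .core_types import ParameterSet

__all__ = ["HumoralState", "step_px", "step_s", "step_adenosine",
           "adenosine_steady_state"]


class HumoralState:
    """Adenosine level, drug levels and the moving-average buffer."""

    def __init__(self, M: int):
        if M < 1:
            raise ValueError("moving-average window M must be >= 1")
        self.Ad = 0.0
        self.px = 0.0
        self.s_raw = 0.0
        self._buf = np.zeros(M, dtype=np.float64)
        self._pos = 0
        self._sum = 0.0

    @property
    def M(self) -> int:
        return self._buf.size

    @property
    def S_t(self) -> float:
        """Moving average of the last M values of ``s`` (zero-padded)."""
        return self._sum / self._buf.size

    def _push(self, value: float) -> None:
        self._sum += value - self._buf[self._pos]
        self._buf[self._pos] = value
        self._pos = (self._pos + 1) % self._buf.size
        # periodic exact recompute to keep the running sum drift-free
        if self._pos == 0:
            self._sum = float(self._buf.sum())


def step_px(state: HumoralState, is_dose_step: bool, params: ParameterSet,
            dose_scale: float = 1.0) -> float:
    """One Euler step of the hypoxia inhibitor; bolus applied before decay."""
    if is_dose_step:
        state.px += params.dose_px * dose_scale
    state.px *= (1.0 - params.eta)
    if state.px < 0.0:
        state.px = 0.0
    return state.px


def step_s(state: HumoralState, is_dose_step: bool, params: ParameterSet,
           dose_scale: float = 1.0) -> tuple[float, float]:
    """One Euler step of the adenosine inhibitor plus the adhesion filter.

    Returns ``(s_raw, S_t)`` after the update.
    """
    if is_dose_step:
        state.s_raw += params.dose_s * dose_scale
    state.s_raw *= (1.0 - params.lambda_s)
    if state.s_raw < 0.0:
        state.s_raw = 0.0
    state._push(state.s_raw)
    return state.s_raw, state.S_t


def step_adenosine(state: HumoralState, U_eff: float,
                   params: ParameterSet) -> float:
    """One Euler step of Ad' = beta + a/(U_eff+c) - r*Ad - gamma*S_t*Ad.

    ``U_eff`` is the spatial oxygen summary over the tumor neighborhood;
    the drug level entering the gamma term is the filtered ``S_t``.
    """
    if U_eff < 0.0:
        raise ValueError("effective oxygen must be non-negative")
    ad = state.Ad
    ad += params.beta + params.a / (U_eff + params.c) \
        - params.r * ad - params.gamma * state.S_t * ad
    state.Ad = max(ad, 0.0)
    return state.Ad


def adenosine_steady_state(U_eff: float, S_t: float,
                           params: ParameterSet) -> float:
    """Closed-form fixed point Ad* = (beta + a/(U+c)) / (r + gamma*S_t)."""
    return (params.beta + params.a / (U_eff + params.c)) \
        / (params.r + params.gamma * S_t)
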