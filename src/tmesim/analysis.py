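"""Model assessment: goodness of fit, global sensitivity, identifiability.

Global sensitivity uses Latin-hypercube sampling of the parameters within a
relative range around their defaults and ranks them by the partial rank
correlation coefficient (PRCC) between each parameter and a scalar model
output (by default the tumor volume averaged over the horizon).
Identifiability screens parameter pairs by correlating their
finite-difference sensitivity trajectories across several model outputs; a
pair whose |correlation| reaches the threshold in *every* output cannot be
distinguished by those outputs and is flagged non-identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .core_types import ParameterSet
from .engine import run

__all__ = ["rsq", "prcc", "global_sensitivity", "identifiability",
           "IdentifiabilityResult", "mean_volume_model", "trajectory_model",
           "synthetic_reference_curve"]


def rsq(sim_series, ref_series) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot.

    Values below 0 (model worse than the reference mean) are returned as
    computed, with a warning.  A constant reference series has no variance
    to explain and raises ``ValueError``.
    """
    sim = np.asarray(sim_series, dtype=float)
    ref = np.asarray(ref_series, dtype=float)
    if sim.shape != ref.shape:
        raise ValueError("series must have matching shapes")
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference series is constant (SS_tot = 0)")
    r2 = 1.0 - float(np.sum((sim - ref) ** 2)) / ss_tot
    if r2 < 0.0:
        warnings.warn(f"R^2 = {r2:.4g} is negative: the model fits worse "
                      "than the reference mean", RuntimeWarning, stacklevel=2)
    return r2


def prcc(samples: np.ndarray, output: np.ndarray) -> np.ndarray:
    """Partial rank correlation of each input column with the output.

    Both inputs and output are rank-transformed; for each input column the
    linear effect of all other columns is regressed out of it and out of
    the output, and the residuals are correlated.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(output, dtype=float).ravel()
    n, k = X.shape
    if y.size != n:
        raise ValueError("output length must match the number of samples")
    Xr = np.column_stack([rankdata(X[:, j]) for j in range(k)])
    yr = rankdata(y)
    out = np.empty(k)
    for j in range(k):
        others = np.column_stack(
            [np.ones(n), np.delete(Xr, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, Xr[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, yr, rcond=None)
        rx = Xr[:, j] - others @ beta_x
        ry = yr - others @ beta_y
        denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        out[j] = float(rx @ ry / denom) if denom > 0 else np.nan
    return out


def mean_volume_model(base_params: ParameterSet, horizon_days: int = 3,
                      replicates_per_sample: int = 3,
                      record_every: int = 60) -> Callable[[Mapping, int], float]:
    """Scalar model for sensitivity analysis: untreated mean tumor volume.

    Returns ``model(overrides, seed) -> mean tumor volume (mm^3)`` averaged
    over ``replicates_per_sample`` untreated runs.
    """

    def model(overrides: Mapping[str, float], seed: int) -> float:
        p = base_params.replace(**dict(overrides))
        vols = [run(p, None, seed=seed + i, horizon_days=horizon_days,
                    record_every=record_every).mean_tumor_volume
                for i in range(replicates_per_sample)]
        return float(np.mean(vols))

    return model


def global_sensitivity(params: ParameterSet | Mapping[str, float],
                       param_names: Sequence[str], rel_range: float = 0.5,
                       n_samples: int = 200, seed: int = 0,
                       replicates_per_sample: int = 3,
                       model: Callable[[Mapping, int], float] | None = None,
                       horizon_days: int = 3) -> pd.DataFrame:
    """Latin-hypercube PRCC sensitivity ranking of ``param_names``.

    Each named parameter is sampled uniformly within ``±rel_range`` of its
    default; ``model(overrides, seed)`` maps one sample to a scalar output
    (defaults to the untreated mean tumor volume).  Returns a DataFrame
    sorted by |PRCC| with columns ``parameter, prcc, abs_prcc, rank``.
    """
    k = len(param_names)
    if n_samples < 10 * k:
        raise ValueError(f"n_samples={n_samples} < 10 x {k} parameters")
    if rel_range <= 0:
        raise ValueError("rel_range must be positive (degenerate sampling)")
    defaults = params if isinstance(params, Mapping) else params.to_dict()
    centers = np.array([float(defaults[p]) for p in param_names])
    if np.any(centers == 0):
        zero = [p for p, v in zip(param_names, centers) if v == 0]
        raise ValueError(f"zero-valued defaults give a degenerate range: {zero}")
    if model is None:
        base = params if isinstance(params, ParameterSet) else ParameterSet(**defaults)
        model = mean_volume_model(base, horizon_days=horizon_days,
                                  replicates_per_sample=replicates_per_sample)
    sampler = qmc.LatinHypercube(d=k, seed=seed)
    unit = sampler.random(n_samples)
    lo = centers * (1.0 - rel_range)
    hi = centers * (1.0 + rel_range)
    X = qmc.scale(unit, np.minimum(lo, hi), np.maximum(lo, hi))
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2 ** 31 - 1, size=n_samples)
    y = np.array([model(dict(zip(param_names, row)), int(s))
                  for row, s in zip(X, run_seeds)])
    vals = prcc(X, y)
    df = pd.DataFrame({"parameter": list(param_names), "prcc": vals,
                       "abs_prcc": np.abs(vals)})
    df = df.sort_values("abs_prcc", ascending=False, ignore_index=True)
    df["rank"] = np.arange(1, k + 1)
    return df


DEFAULT_OUTPUTS = ("tumor_volume", "Ad", "hypoxia", "mean_mu_effectors",
                   "n_effector", "n_treg", "n_dc_active")


def trajectory_model(base_params: ParameterSet, horizon_days: int = 3,
                     replicates: int = 3, record_every: int = 60,
                     outputs: Sequence[str] = DEFAULT_OUTPUTS,
                     ) -> Callable[[Mapping, int], dict[str, np.ndarray]]:
    """Trajectory-valued model for identifiability analysis.

    ``model(overrides, seed)`` returns replicate-averaged untreated time
    series for each requested output; ``hypoxia`` is derived as
    ``1 / (mean tumor-neighborhood oxygen + c)``.
    """

    def model(overrides: Mapping[str, float], seed: int) -> dict[str, np.ndarray]:
        p = base_params.replace(**dict(overrides))
        acc: dict[str, np.ndarray] | None = None
        for i in range(replicates):
            t = run(p, None, seed=seed + i, horizon_days=horizon_days,
                    record_every=record_every)
            cur = {}
            for name in outputs:
                if name == "hypoxia":
                    cur[name] = 1.0 / (t["mean_U_tumor"] + p.c)
                else:
                    cur[name] = t[name].astype(float)
            acc = cur if acc is None else {k: acc[k] + cur[k] for k in cur}
        return {k: v / replicates for k, v in acc.items()}

    return model


@dataclass
class IdentifiabilityResult:
    """Pairwise sensitivity-correlation screen over several outputs."""

    param_names: list[str]
    output_names: list[str]
    #: |corr| per output: array (n_outputs, k, k)
    abs_corr: np.ndarray
    #: flagging statistic: min over outputs of |corr| (symmetric, unit diag)
    min_abs_corr: np.ndarray
    non_identifiable_pairs: list[tuple[str, str]]
    inert_params: list[str]
    threshold: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.min_abs_corr, index=self.param_names,
                            columns=self.param_names)


def identifiability(params: ParameterSet | Mapping[str, float],
                    param_names: Sequence[str],
                    outputs: Sequence[str] = DEFAULT_OUTPUTS,
                    delta: float = 0.1, seed: int = 0,
                    model: Callable[[Mapping, int], dict] | None = None,
                    threshold: float = 0.9, horizon_days: int = 3,
                    replicates: int = 3) -> IdentifiabilityResult:
    """Screen parameter pairs for non-identifiability.

    For each parameter a central finite-difference sensitivity trajectory
    of every output is computed with common random numbers (the same seed
    for the + and - perturbations).  A pair is flagged non-identifiable iff
    the |Pearson correlation| of their sensitivity trajectories reaches
    ``threshold`` in every output.  Parameters whose sensitivity is zero in
    all outputs are reported inert and excluded with a warning.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    defaults = params if isinstance(params, Mapping) else params.to_dict()
    if model is None:
        base = params if isinstance(params, ParameterSet) else ParameterSet(**defaults)
        model = trajectory_model(base, horizon_days=horizon_days,
                                 replicates=replicates, outputs=outputs)
    param_names = list(param_names)
    outputs = list(outputs)
    k = len(param_names)
    sens: dict[str, dict[str, np.ndarray]] = {}
    for p in param_names:
        v = float(defaults[p])
        plus = model({p: v * (1 + delta)}, seed)
        minus = model({p: v * (1 - delta)}, seed)
        denom = 2.0 * delta * v if v != 0 else 2.0 * delta
        sens[p] = {o: (plus[o] - minus[o]) / denom for o in outputs}
    def _flat(s: np.ndarray) -> bool:
        # zero or constant sensitivity carries no trajectory-shape signal
        return np.std(s) <= 1e-10 * (1.0 + np.abs(s).max(initial=0.0))

    inert = [p for p in param_names if all(_flat(sens[p][o]) for o in outputs)]
    if inert:
        warnings.warn(f"parameters with zero/constant sensitivity in all "
                      f"outputs excluded from the screen: {inert}",
                      RuntimeWarning, stacklevel=2)
    abs_corr = np.full((len(outputs), k, k), np.nan)
    for oi, o in enumerate(outputs):
        for i in range(k):
            abs_corr[oi, i, i] = 1.0
        for i, j in combinations(range(k), 2):
            si, sj = sens[param_names[i]][o], sens[param_names[j]][o]
            if _flat(si) or _flat(sj):
                continue
            c = abs(float(np.corrcoef(si, sj)[0, 1]))
            abs_corr[oi, i, j] = abs_corr[oi, j, i] = c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        min_abs = np.nanmin(abs_corr, axis=0)
    flagged = []
    for i, j in combinations(range(k), 2):
        pi, pj = param_names[i], param_names[j]
        if pi in inert or pj in inert:
            min_abs[i, j] = min_abs[j, i] = np.nan
            continue
        if np.isfinite(min_abs[i, j]) and min_abs[i, j] >= threshold:
            flagged.append((pi, pj))
    np.fill_diagonal(min_abs, 1.0)
    return IdentifiabilityResult(
        param_names=param_names, output_names=outputs, abs_corr=abs_corr,
        min_abs_corr=min_abs, non_identifiable_pairs=flagged,
        inert_params=inert, threshold=threshold)


def synthetic_reference_curve(days, final_volume: float = 900.0,
                              onset_day: float = 9.0,
                              steepness: float = 0.45) -> np.ndarray:
    """Synthetic logistic tumor-volume curve (mm^3) for goodness-of-fit demos.

    A stand-in reference time series shaped like a murine 4T1 growth curve;
    it is generated, not measured.
    """
    d = np.asarray(days, dtype=float)
    return final_volume / (1.0 + np.exp(-steepness * (d - onset_day)))
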