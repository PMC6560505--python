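"""Deterministic concentration predictions for the two structural PK models.

Two structures are provided:

* a one-compartment model with first-order oral absorption and first-order
  elimination (closed-form superposition over doses), and
* a two-compartment model with parallel linear and saturable
  (Michaelis–Menten) elimination from the central compartment, dosed as an
  intravenous bolus, integrated numerically.

Both expose a scalar, per-subject API and a batched API used by the
likelihood engine, where each parameter is an array over subjects and a
common sampling-time grid is shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .datamodel import ResidualSpec, ROUTE_BOLUS, ROUTE_ORAL

__all__ = [
    "StructuralParams1Cmt",
    "StructuralParams2CmtParallel",
    "conc_1cmt_oral",
    "conc_2cmt_parallel",
    "predict_1cmt_oral_batch",
    "predict_2cmt_parallel_batch",
    "apply_residual",
    "scale_by_weight",
    "WEIGHT_SCALED_PARAMS",
    "WEIGHT_REFERENCE_KG",
]

# Disposition parameters scaled linearly with body weight (reference 70 kg).
WEIGHT_SCALED_PARAMS = ("CLlin", "Vmax", "V1", "V2")
WEIGHT_REFERENCE_KG = 70.0

# Relative ka≈ke window where the closed form degenerates and the limit
# form D·ka·t·e^{−ka t}/V is used instead (avoids catastrophic cancellation).
_EQUAL_RATE_RTOL = 1e-8


@dataclass(frozen=True)
class StructuralParams1Cmt:
    ka: float  # 1/h
    CL: float  # L/h
    V: float   # L

    def __post_init__(self):
        if not (self.ka > 0 and self.CL > 0 and self.V > 0):
            raise ValueError("one-compartment parameters must all be > 0")


@dataclass(frozen=True)
class StructuralParams2CmtParallel:
    Vmax: float   # mg/h
    Km: float     # mg/L
    CLlin: float  # L/h
    V1: float     # L
    V2: float     # L
    Q: float      # L/h
    WT: float = WEIGHT_REFERENCE_KG  # kg

    def __post_init__(self):
        if not all(v > 0 for v in (self.Km, self.CLlin, self.V1, self.V2, self.Q, self.WT)):
            raise ValueError("two-compartment parameters must be > 0")
        if self.Vmax < 0:
            raise ValueError("Vmax must be >= 0")


def _onecmt_single_dose(dose_amt, ka, ke, V, dt):
    """Vectorized single oral dose contribution; dt may be any shape.

    Handles the ka→ke degenerate case by the analytic limit.
    """
    dt = np.asarray(dt, dtype=float)
    ka = np.asarray(ka, dtype=float)
    ke = np.asarray(ke, dtype=float)
    V = np.asarray(V, dtype=float)
    pos = dt > 0
    dtp = np.where(pos, dt, 0.0)
    denom = ka - ke
    degenerate = np.abs(denom) < _EQUAL_RATE_RTOL * np.abs(ka)
    safe_denom = np.where(degenerate, 1.0, denom)
    general = dose_amt * ka / (V * safe_denom) * (np.exp(-ke * dtp) - np.exp(-ka * dtp))
    limit = dose_amt * ka * dtp * np.exp(-ka * dtp) / V
    out = np.where(degenerate, limit, general)
    return np.where(pos, out, 0.0)


def conc_1cmt_oral(params: StructuralParams1Cmt, doses: list, t: float) -> float:
    """Concentration (mg/L) at time ``t`` for first-order oral absorption.

    Superposition over doses of
    ``D·ka/(V·(ka−ke))·(e^{−ke(t−td)} − e^{−ka(t−td)})`` with ``ke = CL/V``;
    doses with ``td >= t`` contribute nothing.
    """
    for d in doses:
        if d.route != ROUTE_ORAL:
            raise ValueError(f"conc_1cmt_oral expects {ROUTE_ORAL} doses, got {d.route}")
    if t < 0:
        raise ValueError("t must be >= 0")
    ke = params.CL / params.V
    total = 0.0
    for d in doses:
        total += float(_onecmt_single_dose(d.amount, params.ka, ke, params.V, t - d.time))
    return total


def predict_1cmt_oral_batch(theta: dict, times: np.ndarray, doses: list) -> np.ndarray:
    """Batched one-compartment predictions.

    theta: maps 'ka', 'CL', 'V' to (n,) arrays; times: (T,) or (n, T);
    returns an (n, T) concentration matrix.
    """
    ka = np.atleast_1d(np.asarray(theta["ka"], dtype=float))[:, None]
    CL = np.atleast_1d(np.asarray(theta["CL"], dtype=float))[:, None]
    V = np.atleast_1d(np.asarray(theta["V"], dtype=float))[:, None]
    times = np.asarray(times, dtype=float)
    if times.ndim == 1:
        times = times[None, :]
    ke = CL / V
    conc = np.zeros(np.broadcast_shapes(ka.shape, times.shape), dtype=float)
    for d in doses:
        conc = conc + _onecmt_single_dose(d.amount, ka, ke, V, times - d.time)
    return conc


# ---------------------------------------------------------------------------
# two-compartment model with parallel linear + Michaelis–Menten elimination

_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-10


def _integrate_parallel(CLlin, Vmax, Km, V1, V2, Q, doses, times, rtol=_ODE_RTOL, atol=_ODE_ATOL):
    """Integrate the parallel-elimination system for a batch of subjects.

    All parameters are (n,) arrays; ``times`` is a common sorted (T,) grid.
    Returns an (n, T) central-compartment concentration matrix.  The system
    is integrated piecewise between bolus dose instants, stacking the 2n
    amounts into one state vector.
    """
    CLlin, Vmax, Km, V1, V2, Q = (np.atleast_1d(np.asarray(a, dtype=float))
                                  for a in (CLlin, Vmax, Km, V1, V2, Q))
    n = max(a.size for a in (CLlin, Vmax, Km, V1, V2, Q))
    CLlin, Vmax, Km, V1, V2, Q = (np.broadcast_to(a, (n,)).copy()
                                  for a in (CLlin, Vmax, Km, V1, V2, Q))
    times = np.asarray(times, dtype=float)
    for d in doses:
        if d.route != ROUTE_BOLUS:
            raise ValueError(f"parallel-elimination model expects {ROUTE_BOLUS} doses")

    def rhs(t, y):
        A1 = y[:n]
        A2 = y[n:]
        C = A1 / V1
        dA1 = -(CLlin / V1) * A1 - Vmax * C / (Km + C) - (Q / V1) * A1 + (Q / V2) * A2
        dA2 = (Q / V1) * A1 - (Q / V2) * A2
        return np.concatenate([dA1, dA2])

    dose_times = sorted({d.time for d in doses})
    dose_amt = {t0: sum(d.amount for d in doses if d.time == t0) for t0 in dose_times}
    breakpoints = sorted(set(dose_times) | {0.0, float(times.max()) if times.size else 0.0})

    conc = np.zeros((n, times.size), dtype=float)
    y = np.zeros(2 * n)
    t_cur = 0.0
    # observations at/before the first dose see an empty system
    for i, t0 in enumerate(breakpoints):
        if t0 > t_cur:
            seg_mask = (times > t_cur) & (times <= t0)
            t_eval = times[seg_mask]
            span_pts = np.unique(np.concatenate([t_eval, [t0]]))
            if np.any(y != 0.0):
                sol = solve_ivp(
                    rhs, (t_cur, t0), y, method="LSODA", t_eval=span_pts,
                    rtol=rtol, atol=atol,
                )
                if not sol.success:
                    raise RuntimeError(
                        f"ODE integration failed on [{t_cur}, {t0}]: {sol.message}"
                    )
                if t_eval.size:
                    idx = np.searchsorted(span_pts, t_eval)
                    conc[:, seg_mask] = sol.y[:n, :][:, idx] / V1[:, None]
                y = sol.y[:, -1].copy()
            t_cur = t0
        if t0 in dose_amt:
            y[:n] += dose_amt[t0]
    np.maximum(conc, 0.0, out=conc)
    return conc


def conc_2cmt_parallel(params: StructuralParams2CmtParallel, doses: list, t: float) -> float:
    """Concentration (mg/L) at ``t`` for the parallel-elimination model.

    Disposition parameters (CLlin, Vmax, V1, V2) are scaled linearly with
    body weight relative to 70 kg before integration.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    w = params.WT / WEIGHT_REFERENCE_KG
    conc = _integrate_parallel(
        params.CLlin * w, params.Vmax * w, params.Km,
        params.V1 * w, params.V2 * w, params.Q,
        doses, np.array([t]),
    )
    return float(conc[0, 0])


def predict_2cmt_parallel_batch(theta: dict, times: np.ndarray, doses: list,
                                rtol=_ODE_RTOL, atol=_ODE_ATOL) -> np.ndarray:
    """Batched parallel-elimination predictions on a common time grid.

    theta maps 'CLlin', 'Vmax', 'Km', 'V1', 'V2', 'Q' to (n,) arrays already
    on the individual scale (weight scaling applied by the caller).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("the ODE batch path requires a common 1-D time grid")
    order = np.argsort(times)
    conc_sorted = _integrate_parallel(
        theta["CLlin"], theta["Vmax"], theta["Km"],
        theta["V1"], theta["V2"], theta["Q"],
        doses, times[order], rtol=rtol, atol=atol,
    )
    out = np.empty_like(conc_sorted)
    out[:, order] = conc_sorted
    return out


def scale_by_weight(theta: dict, wt, reference: float = WEIGHT_REFERENCE_KG) -> dict:
    """Apply linear body-weight scaling to the disposition parameters."""
    wt = np.asarray(wt, dtype=float)
    scaled = dict(theta)
    for name in WEIGHT_SCALED_PARAMS:
        if name in scaled:
            scaled[name] = np.asarray(scaled[name], dtype=float) * (wt / reference)
    return scaled


def apply_residual(conc, sigma: ResidualSpec, eps):
    """Map model predictions to observed values given standard-normal draws.

    proportional: ``conc·(1 + sqrt(prop_var)·eps)``;
    additive: ``conc + sqrt(add_var)·eps``; combined: both terms with
    independent draws stacked along the first axis of ``eps``.
    """
    conc = np.asarray(conc, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(conc < 0):
        raise ValueError("model predictions must be non-negative")
    if sigma.kind == "proportional":
        return conc * (1.0 + math.sqrt(sigma.prop_var) * eps)
    if sigma.kind == "additive":
        return conc + math.sqrt(sigma.add_var) * eps
    eps_p, eps_a = eps[0], eps[1]
    return conc * (1.0 + math.sqrt(sigma.prop_var) * eps_p) + math.sqrt(sigma.add_var) * eps_a
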