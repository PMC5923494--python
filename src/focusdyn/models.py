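"""Population-level virus dynamics models.

The model family couples target cells ``T``, infected cells ``I`` and
extracellular virus ``V``:

    dT/dt = -beta_f V T - g(I) beta_c I T
    dI/dt = +beta_f V T + g(I) beta_c I T
    dV/dt = rho I - c V

with ``g(I) = 1`` for the classical mass-action variants and
``g(I) = fc(I)`` (the perimeter-fraction adjustment) for the adjusted
ones.  Cell death and proliferation are outside the scope of this
package (``delta_T = delta_I = 0``), so ``T + I`` is conserved.  Delay
variants replace ``I(t)`` in the infection term by ``I(t - tau)``,
modelling the time a newly infected cell needs to become infectious.

Registry of named variants (``ModelSpec.from_name``):

========  =========  ==========  ========  =======
name      cell-free  cell-cell   adjusted  delayed
========  =========  ==========  ========  =======
CF        yes        no          --        no
CC        no         yes         no        no
CC-dI     no         yes         no        yes
CCF       yes        yes         no        no
aCC       no         yes         yes       no
aCC-dI    no         yes         yes       yes
aCCF      yes        yes         yes       no
========  =========  ==========  ========  =======
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .adjustment import AdjustmentParams, fc_full

__all__ = ["ModelSpec", "ODEParams", "MODEL_NAMES", "rhs", "simulate",
           "predicted_contributors", "ode_increment"]

#: delays below this (hours, = 3 min) are dynamically indistinguishable
#: from zero and routed to the non-delayed integrator
TAU_EPS = 0.05


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant is active."""

    name: str
    cell_free: bool
    cell_to_cell: bool
    adjusted: bool
    delayed: bool

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            flags = _REGISTRY[name]
        except KeyError:
            raise ValueError(
                f"unknown model {name!r}; one of {sorted(_REGISTRY)}") from None
        return cls(name=name, **flags)


_REGISTRY = {
    "CF": dict(cell_free=True, cell_to_cell=False, adjusted=False, delayed=False),
    "CC": dict(cell_free=False, cell_to_cell=True, adjusted=False, delayed=False),
    "CC-dI": dict(cell_free=False, cell_to_cell=True, adjusted=False, delayed=True),
    "CCF": dict(cell_free=True, cell_to_cell=True, adjusted=False, delayed=False),
    "aCC": dict(cell_free=False, cell_to_cell=True, adjusted=True, delayed=False),
    "aCC-dI": dict(cell_free=False, cell_to_cell=True, adjusted=True, delayed=True),
    "aCCF": dict(cell_free=True, cell_to_cell=True, adjusted=True, delayed=False),
}
MODEL_NAMES = tuple(_REGISTRY)


@dataclass(frozen=True)
class ODEParams:
    """Rates, delay, adjustment and initial conditions of one model run.

    Rates are per hour.  ``T0, I0, V0`` are the state at the first
    requested time point.  ``adjustment`` must be set for adjusted
    variants and is ignored otherwise.
    """

    T0: float
    I0: float
    V0: float = 0.0
    beta_f: float = 0.0        # CF transmission rate (/virus /h)
    beta_c: float = 0.0        # CC transmission rate (/cell /h)
    rho: float = 0.0           # per-cell virion production (/h)
    c: float = 0.0             # virion clearance (/h)
    tau: float = 0.0           # infection-to-infectiousness delay (h)
    delta_T: float = 0.0       # fixed 0 in scope
    delta_I: float = 0.0       # fixed 0 in scope
    adjustment: Optional[AdjustmentParams] = None

    def __post_init__(self):
        for name in ("beta_f", "beta_c", "rho", "c", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.T0 <= 0:
            raise ValueError("T0 must be > 0")


def _g(I: float, params: ODEParams, spec: ModelSpec) -> float:
    if not spec.adjusted:
        return 1.0
    if params.adjustment is None:
        raise ValueError(f"model {spec.name} requires adjustment parameters")
    g = params.adjustment.fc_scalar(I) if np.ndim(I) == 0 else fc_full(
        I, params.adjustment)
    if np.any(np.isnan(g)):
        raise FloatingPointError(
            f"fc evaluation returned NaN at I={I!r} with {params.adjustment}")
    return g


def rhs(t: float, y: np.ndarray, params: ODEParams, spec: ModelSpec) -> list:
    """Time derivatives (dT, dI, dV) of the non-delayed model."""
    T, I, V = y
    inf_cc = _g(I, params, spec) * params.beta_c * I * T if spec.cell_to_cell else 0.0
    inf_cf = params.beta_f * V * T if spec.cell_free else 0.0
    dT = -inf_cf - inf_cc
    dI = inf_cf + inf_cc
    dV = params.rho * I - params.c * V
    return [dT, dI, dV]


def _simulate_delay(spec: ModelSpec, params: ODEParams,
                    times: np.ndarray, h_max: float = 1.0) -> dict:
    """Method-of-steps integration of the delayed CC-only models.

    With beta_f = 0 and delta = 0 the system reduces to the scalar
    equation dI/dt = g(I) beta_c I(t - tau) (N - I) with N = T0 + I0;
    the history is constant, I(s) = I0 for s <= t0.  Integration uses a
    fixed-step RK4 with the step chosen as an exact divisor of tau
    (h <= 1 h, well below the ~10 h dynamics timescale); the delayed
    argument then falls on stored grid points (half-step stages use the
    midpoint of the two bracketing values).  The correction term is
    inlined for speed — this integrator runs inside optimizer loops.
    """
    if spec.cell_free:
        raise NotImplementedError(
            "delay variants are defined for cell-to-cell-only models")
    t0, tf = float(times[0]), float(times[-1])
    tau = params.tau
    N = params.T0 + params.I0
    h = tau / math.ceil(tau / h_max)
    n_steps = max(1, math.ceil((tf - t0) / h - 1e-12))
    m = round(tau / h)
    I_grid = np.zeros(n_steps + 1)
    I_grid[0] = params.I0

    beta_c = params.beta_c
    adjusted = spec.adjusted and params.adjustment is not None
    if adjusted:
        adj = params.adjustment
        k, z, phi = float(adj.k), adj.z, adj.phi
        ca, cb = adj.coeffs.a, adj.coeffs.b
        kk8 = k * k - 8.0 * k
    half = 0.5 * h
    sixth = h / 6.0
    sqrt = math.sqrt

    def g_of(I: float) -> float:
        if not adjusted:
            return 1.0
        x = I / phi
        if x <= k:
            return 1.0
        d = x - k
        if d < z:
            return (ca * d + cb) * d * d + 1.0
        return (sqrt(kk8 + 8.0 * k * x) - k) / (2.0 * x)

    Ig = I_grid
    for i in range(n_steps):
        jm = i - m
        d0 = Ig[jm] if jm > 0 else Ig[0]
        d1 = Ig[jm + 1] if jm + 1 > 0 else Ig[0]
        dh = 0.5 * (d0 + d1)
        I = Ig[i]
        k1 = g_of(I) * beta_c * d0 * (N - I)
        y = I + half * k1
        k2 = g_of(y) * beta_c * dh * (N - y)
        y = I + half * k2
        k3 = g_of(y) * beta_c * dh * (N - y)
        y = I + h * k3
        k4 = g_of(y) * beta_c * d1 * (N - y)
        Ig[i + 1] = I + sixth * (k1 + 2.0 * (k2 + k3) + k4)
    grid = t0 + h * np.arange(n_steps + 1)
    I_out = np.interp(times, grid, I_grid)
    return {"times": np.asarray(times, dtype=float),
            "T": N - I_out, "I": I_out, "V": np.zeros_like(I_out)}


def _simulate_cc_scalar(spec: ModelSpec, params: ODEParams,
                        times: np.ndarray) -> dict:
    """Fast fixed-step RK4 for the scalar CC-only system (rho = c = 0).

    With no cell-free route and no viral turnover the dynamics reduce to
    dI/dt = g(I) beta_c I (N - I), N = T0 + I0.  The step is capped so
    that h * beta_c * N <= 0.03, keeping the local truncation error far
    below the 1e-8 relative scale (verified by a convergence test).
    """
    t0, tf = float(times[0]), float(times[-1])
    N = params.T0 + params.I0
    h = min(1.0, 0.03 / max(params.beta_c * N, 1e-12))
    n_steps = max(1, math.ceil((tf - t0) / h - 1e-12))
    h = (tf - t0) / n_steps if tf > t0 else h
    beta_c = params.beta_c
    adjusted = spec.adjusted and params.adjustment is not None
    if adjusted:
        adj = params.adjustment
        k, z, phi = float(adj.k), adj.z, adj.phi
        ca, cb = adj.coeffs.a, adj.coeffs.b
        kk8 = k * k - 8.0 * k
    sqrt = math.sqrt

    def f(I: float) -> float:
        if adjusted:
            x = I / phi
            if x <= k:
                g = 1.0
            elif x - k < z:
                d = x - k
                g = (ca * d + cb) * d * d + 1.0
            else:
                g = (sqrt(kk8 + 8.0 * k * x) - k) / (2.0 * x)
        else:
            g = 1.0
        return g * beta_c * I * (N - I)

    I_grid = np.zeros(n_steps + 1)
    I_grid[0] = params.I0
    half, sixth = 0.5 * h, h / 6.0
    I = params.I0
    for i in range(n_steps):
        k1 = f(I)
        k2 = f(I + half * k1)
        k3 = f(I + half * k2)
        k4 = f(I + h * k3)
        I = I + sixth * (k1 + 2.0 * (k2 + k3) + k4)
        I_grid[i + 1] = I
    grid = t0 + h * np.arange(n_steps + 1)
    I_out = np.interp(times, grid, I_grid)
    return {"times": np.asarray(times, dtype=float),
            "T": N - I_out, "I": I_out, "V": np.zeros_like(I_out)}


def simulate(spec: ModelSpec, params: ODEParams, times) -> dict:
    """Integrate the model and return ``{"times", "T", "I", "V"}``.

    ``times`` must be sorted ascending; the initial conditions in
    ``params`` apply at ``times[0]``.  Non-delayed variants use an
    adaptive stiffness-switching integrator (LSODA, rtol = atol = 1e-8),
    except for the scalar cell-to-cell-only reduction which has a
    dedicated fixed-step path of matching accuracy; delayed variants
    use the method of steps (see ``_simulate_delay``).
    """
    times = np.asarray(times, dtype=float)
    if times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-empty and strictly increasing")
    if spec.delayed and params.tau >= (times[-1] - times[0]):
        raise ValueError("delay tau must be smaller than the time span")
    if spec.delayed and params.tau > TAU_EPS:
        return _simulate_delay(spec, params, times)
    if (not spec.cell_free and spec.cell_to_cell and params.rho == 0.0
            and params.c == 0.0 and params.V0 == 0.0 and times.size > 1
            and params.beta_c * (params.T0 + params.I0)
            * (times[-1] - times[0]) < 2e4):
        return _simulate_cc_scalar(spec, params, times)
    y0 = [params.T0, params.I0, params.V0]
    if times.size == 1:
        return {"times": times, "T": np.array([params.T0]),
                "I": np.array([params.I0]), "V": np.array([params.V0])}
    sol = solve_ivp(rhs, (times[0], times[-1]), y0, t_eval=times,
                    args=(params, spec), method="LSODA",
                    rtol=1e-8, atol=1e-8)
    if not sol.success:
        raise RuntimeError(
            f"integration of {spec.name} failed: {sol.message}; "
            f"last state {sol.y[:, -1] if sol.y.size else y0}")
    return {"times": times, "T": sol.y[0], "I": sol.y[1], "V": sol.y[2]}


def predicted_contributors(traj: dict, params: ODEParams) -> dict:
    """Model-side contributor fractions along a trajectory.

    Returns ``fc`` — the raw adjustment term fc(I(t)) — and
    ``fc_corrected`` — fc(I(t)) * T(t)/T_total with T_total the total
    cell count at the trajectory start, which is the quantity comparable
    to the contributor fraction measured in the lattice simulation
    (an enclosed cell needs an *uninfected* neighbor to transmit).
    """
    if params.adjustment is None:
        raise ValueError("predicted_contributors requires adjustment parameters")
    fc_vals = fc_full(traj["I"], params.adjustment)
    t_total = traj["T"][0] + traj["I"][0]
    return {"times": traj["times"], "fc": np.atleast_1d(fc_vals),
            "fc_corrected": np.atleast_1d(fc_vals) * traj["T"] / t_total}


def ode_increment(traj: dict, params: ODEParams, spec: ModelSpec) -> np.ndarray:
    """Instantaneous CC increment g(I) beta_c I T along a trajectory (/h)."""
    g = fc_full(traj["I"], params.adjustment) if spec.adjusted else 1.0
    return g * params.beta_c * traj["I"] * traj["T"]
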