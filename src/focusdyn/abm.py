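"""Agent-based simulation of viral spread in a cell monolayer.

Each lattice site holds one stationary cell that is either uninfected or
infected.  Infected cells replicate positive-strand viral RNA ``R``
logistically (maximal rate ``alpha``, carrying capacity ``Rcap``), lose
it to degradation (``gamma``) and export (``rho``); the exported,
infectious fraction ``finf`` feeds the local extracellular virus ``V``,
which is cleared at rate ``c`` and diffuses to neighboring sites by a
conservative neighbor-exchange scheme (fraction ``m`` per step).

Two transmission routes are simulated per time step ``dt``:

* cell-free (CF): an uninfected cell is infected with probability
  ``min(1, sf * V_local * dt)``;
* cell-to-cell (CC): each infected neighbor independently transmits with
  probability ``min(1, sc * finf * R_donor * dt)``; on success the donor
  loses one RNA copy and the recipient starts replication at ``R = 1``.

Infection is optionally initiated by an inoculum: during the first
``t_init`` hours cells are infected at a density that decays at rate
``lam`` and integrates to an expected total of ``I0hat`` cells; at
``t_init`` the medium is changed (all extracellular virus removed) and
CF transmission can be blocked from then on.

The full infection lineage (mode, infector, time) is tracked so that the
fraction of cells infected by each route can be reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .lattice import HexLattice

__all__ = [
    "ABMParams",
    "ABMState",
    "ABMTimeSeries",
    "MODE_NONE",
    "MODE_INOCULUM",
    "MODE_CF",
    "MODE_CC",
    "M_SLOW",
    "M_FAST",
    "SC_MIXED",
    "SCENARIOS",
    "new_state",
    "step_intracellular",
    "step_diffusion",
    "attempt_infections",
    "inoculate",
    "media_change",
    "run_simulation",
    "replicate_runs",
    "contributor_fraction",
    "abm_increment_rate",
    "aggregate_replicates",
]

MODE_NONE = 0
MODE_INOCULUM = 1
MODE_CF = 2
MODE_CC = 3

#: diffusing fraction per step for the slow-diffusion scenarios
M_SLOW = 0.004
#: fast diffusion, 165x the slow flux (HIV-sized virions in water scale)
M_FAST = 0.66
#: CC scaling used by the scenarios where both routes compete; the
#: transmission probabilities differ between study designs so that both
#: routes contribute appreciably when simulated together
SC_MIXED = 5e-5

SCENARIOS = (
    "single_focus_cc",
    "multifocus_cc",
    "mixed_slow_diffusion",
    "mixed_fast_diffusion",
    "cf_only_slow",
    "cf_only_fast",
)


@dataclass(frozen=True)
class ABMParams:
    """All per-simulation rates, probabilities and protocol settings.

    Rates are per minute; times (``t_init``, ``t_end``, ``sample_every``)
    are in hours; ``dt`` is the step length in minutes.
    """

    alpha: float = 2e-3        # maximal intracellular replication rate (/min)
    Rcap: float = 170.0        # intracellular carrying capacity (RNA copies)
    gamma: float = 2e-4        # RNA degradation rate (/min)
    rho: float = 6e-4          # RNA export rate (/min)
    c: float = 1.67e-3         # extracellular clearance rate (/min)
    finf: float = 0.5          # infectious fraction of RNA
    m: float = M_SLOW          # diffusing fraction per step
    sf: float = 1e-4           # CF infection scaling (/min /virus)
    sc: float = 1e-4           # CC infection scaling (/min /RNA)
    I0hat: float = 8.0         # expected inoculated cells
    lam: float = 0.1           # inoculum decay rate (/h)
    t_init: float = 17.0       # inoculation window (h)
    dt: float = 1.0            # time step (min)
    t_end: float = 240.0       # simulation horizon (h)
    sample_every: float = 24.0  # sampling interval (h)
    cf_blocked_after_init: bool = False
    cc_enabled: bool = True
    cf_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha", "Rcap", "gamma", "rho", "c", "sf", "sc",
                     "I0hat", "lam"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("diffusing fraction m must lie in [0, 1]")
        if not 0.0 <= self.finf <= 1.0:
            raise ValueError("finf must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        # explicit-Euler safety for the intracellular update
        if self.alpha * self.dt >= 0.5 or (self.gamma + self.rho) * self.dt >= 1.0:
            raise ValueError("dt too large for the intracellular rates")
        if self.c * self.dt >= 1.0:
            raise ValueError("dt too large for clearance rate c")

    @property
    def r_net(self) -> float:
        """Net early replication rate alpha - gamma - rho (/min)."""
        return self.alpha - self.gamma - self.rho

    @property
    def r_star(self) -> float:
        """Stationary intracellular RNA level Rcap*(alpha-gamma-rho)/alpha."""
        return self.Rcap * self.r_net / self.alpha

    @property
    def beta_c_tilde(self) -> float:
        """Per-intracellular-RNA infectivity sc*finf (/min /RNA)."""
        return self.sc * self.finf

    def ode_rho_eff(self) -> float:
        """Effective per-cell infectious-virion production rate (/h).

        Matches the export term of a saturated cell, finf*rho*R*; used as
        the fixed production rate in population-level fits that do not
        observe the viral load.
        """
        return self.finf * self.rho * self.r_star * 60.0

    def ode_c_eff(self) -> float:
        """Clearance rate on the hourly scale used by the ODE layer."""
        return self.c * 60.0

    def diffusion_coefficient(self, dx: float = 20.0) -> float:
        """Physical diffusion coefficient D = m*dx^2/(4*dt) (um^2/min).

        ``dx`` is the lattice constant in micrometers.  Informational
        helper only; the simulation works directly with ``m``.
        """
        return self.m * dx * dx / (4.0 * self.dt)


@dataclass
class ABMState:
    """Evolving per-cell state of one simulation replicate."""

    t: float                     # current time (min)
    status: np.ndarray           # bool, infected?
    R: np.ndarray                # intracellular RNA per site
    V: np.ndarray                # extracellular virus per site
    infected_at: np.ndarray      # infection time (h); nan if uninfected
    mode: np.ndarray             # MODE_* code per site
    infector: np.ndarray         # source site index; -1 if none
    inf_sites: np.ndarray        # indices of infected sites (first n_infected)
    n_infected: int
    v_total: float = 0.0         # lattice-total virus when V is not spatial
    spatial_v: bool = True

    def infected_indices(self) -> np.ndarray:
        return self.inf_sites[: self.n_infected]

    def total_virus(self) -> float:
        return float(self.V.sum()) if self.spatial_v else self.v_total


def new_state(lattice: HexLattice, spatial_v: bool = True) -> ABMState:
    n = lattice.n_sites
    return ABMState(
        t=0.0,
        status=np.zeros(n, dtype=bool),
        R=np.zeros(n),
        V=np.zeros(n),
        infected_at=np.full(n, np.nan),
        mode=np.zeros(n, dtype=np.int8),
        infector=np.full(n, -1, dtype=np.int64),
        inf_sites=np.zeros(n, dtype=np.int64),
        n_infected=0,
        spatial_v=spatial_v,
    )


def _infect(state: ABMState, sites: np.ndarray, mode: int,
            infectors: Optional[np.ndarray] = None) -> None:
    """Mark ``sites`` infected with one RNA copy and record lineage."""
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size == 0:
        return
    state.status[sites] = True
    state.R[sites] = 1.0
    state.infected_at[sites] = state.t / 60.0
    state.mode[sites] = mode
    if infectors is not None:
        state.infector[sites] = infectors
    state.inf_sites[state.n_infected: state.n_infected + sites.size] = sites
    state.n_infected += sites.size


def step_intracellular(state: ABMState, params: ABMParams) -> ABMState:
    """Advance R and local V one explicit-Euler step of the cell ODEs.

    dR/dt = alpha R (1 - R/Rcap) - (gamma + rho) R
    dV/dt = finf rho R - c V
    Uninfected sites are untouched.
    """
    dt = params.dt
    idx = state.infected_indices()
    r = state.R[idx]
    r_new = r + dt * (params.alpha * r * (1.0 - r / params.Rcap)
                      - (params.gamma + params.rho) * r)
    if r_new.size and r_new.min() < 0.0:
        raise FloatingPointError(
            "intracellular step produced negative RNA; decrease dt "
            f"(dt={dt} min, alpha={params.alpha}/min)")
    state.R[idx] = r_new
    export = params.finf * params.rho * r * dt
    if state.spatial_v:
        state.V *= 1.0 - params.c * dt
        state.V[idx] += export
    else:
        state.v_total = state.v_total * (1.0 - params.c * dt) + float(export.sum())
    return state


def step_diffusion(state: ABMState, params: ABMParams,
                   lattice: HexLattice) -> ABMState:
    """Synchronous neighbor-exchange diffusion V <- V + (m/k) sum(V_nbr - V).

    Applied from the pre-step field through a sparse one-step operator;
    conserves the lattice total exactly (no-flux boundary).
    """
    if state.spatial_v and params.m > 0.0:
        state.V = lattice.exchange_matrix(params.m).dot(state.V)
    return state


def attempt_infections(state: ABMState, params: ABMParams,
                       lattice: HexLattice, rng: np.random.Generator) -> ABMState:
    """Draw this step's CF and CC infection events and apply the winners.

    Both routes are evaluated against the pre-step state.  When several
    events target the same cell (multiple CC donors, or CF and CC
    together), the candidate list is randomly permuted and the first
    event per site wins.  Successful CC donors lose one RNA copy each
    (floored at zero).
    """
    dt = params.dt
    cand_sites = []
    cand_modes = []
    cand_donors = []

    if params.cf_enabled and state.spatial_v and params.sf > 0.0:
        pf = np.minimum(1.0, params.sf * state.V * dt)
        u = rng.random(state.status.size)
        hit = (~state.status) & (u < pf)
        cf_sites = np.nonzero(hit)[0]
        if cf_sites.size:
            cand_sites.append(cf_sites)
            cand_modes.append(np.full(cf_sites.size, MODE_CF, dtype=np.int8))
            cand_donors.append(np.full(cf_sites.size, -1, dtype=np.int64))

    if params.cc_enabled and state.n_infected > 0 and params.sc > 0.0:
        donors = state.infected_indices()
        nb = lattice.adjacency[donors]                      # (n_inf, 6)
        valid = nb >= 0
        nb_safe = np.where(valid, nb, 0)
        open_edge = valid & ~state.status[nb_safe]
        rows, cols = np.nonzero(open_edge)
        if rows.size:
            pc = np.minimum(1.0, params.sc * params.finf * state.R[donors] * dt)
            u = rng.random(rows.size)
            hit = u < pc[rows]
            if np.any(hit):
                rec = nb[rows[hit], cols[hit]]
                don = donors[rows[hit]]
                cand_sites.append(rec)
                cand_modes.append(np.full(rec.size, MODE_CC, dtype=np.int8))
                cand_donors.append(don)

    if not cand_sites:
        return state
    sites = np.concatenate(cand_sites)
    modes = np.concatenate(cand_modes)
    donors = np.concatenate(cand_donors)
    perm = rng.permutation(sites.size)
    sites, modes, donors = sites[perm], modes[perm], donors[perm]
    uniq, first = np.unique(sites, return_index=True)
    modes, donors = modes[first], donors[first]

    cc = modes == MODE_CC
    if np.any(cc):
        # transfer cost: the donor loses half its RNA per transmission
        halvings = np.zeros(state.R.size)
        np.add.at(halvings, donors[cc], 1.0)
        hit = halvings > 0
        state.R[hit] *= 0.5 ** halvings[hit]
    for mode in (MODE_CF, MODE_CC):
        sel = modes == mode
        if np.any(sel):
            _infect(state, uniq[sel], mode,
                    donors[sel] if mode == MODE_CC else None)
    return state


def _inoculum_step_mass(params: ABMParams, t_h: float) -> float:
    """Expected inoculations in [t, t+dt): exact integral of the density.

    The inoculation density I0hat * lam * exp(-lam t) / (1 - exp(-lam*t_init))
    integrates to I0hat over the window by construction; integrating it
    exactly over each step keeps the normalization free of O(dt) bias.
    In the lam -> 0 limit the density is uniform, I0hat / t_init.
    """
    dt_h = params.dt / 60.0
    hi = min(t_h + dt_h, params.t_init)
    if hi <= t_h:
        return 0.0
    lam = params.lam
    if lam < 1e-12:
        return params.I0hat * (hi - t_h) / params.t_init
    norm = 1.0 - math.exp(-lam * params.t_init)
    return params.I0hat * (math.exp(-lam * t_h) - math.exp(-lam * hi)) / norm


def inoculate(state: ABMState, params: ABMParams,
              rng: np.random.Generator) -> ABMState:
    """Seed new infections for the current step of the inoculation window.

    The number of inoculated cells is Poisson with the step's exact
    density mass, assigned to uniformly random uninfected sites.
    """
    t_h = state.t / 60.0
    if t_h >= params.t_init:
        return state
    mean = _inoculum_step_mass(params, t_h)
    n_new = rng.poisson(mean)
    if n_new == 0:
        return state
    free = np.nonzero(~state.status)[0]
    n_new = min(n_new, free.size)
    sites = rng.choice(free, size=n_new, replace=False)
    _infect(state, sites, MODE_INOCULUM)
    return state


def media_change(state: ABMState) -> ABMState:
    """Remove all extracellular virus (change of media at t_init)."""
    state.V[:] = 0.0
    state.v_total = 0.0
    return state


def contributor_fraction(state: ABMState, lattice: HexLattice) -> float:
    """Fraction of infected cells with at least one uninfected neighbor."""
    if state.n_infected == 0:
        raise ValueError("contributor_fraction undefined without infected cells")
    idx = state.infected_indices()
    nb = lattice.adjacency[idx]
    valid = nb >= 0
    nb_safe = np.where(valid, nb, 0)
    has_target = np.any(valid & ~state.status[nb_safe], axis=1)
    return float(has_target.mean())


@dataclass
class ABMTimeSeries:
    """Sampled observables of one replicate."""

    times: np.ndarray            # sampling times (h)
    I_count: np.ndarray          # infected cells
    V_total: np.ndarray          # lattice-total extracellular virus
    contrib_fraction: np.ndarray  # fraction of infected with >=1 open neighbor
    n_inoculum: np.ndarray
    n_cf: np.ndarray
    n_cc: np.ndarray

    @property
    def cf_fraction(self) -> np.ndarray:
        """CF share of post-inoculum infections (nan while none occurred)."""
        denom = self.n_cf + self.n_cc
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.n_cf / np.maximum(denom, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times,
            "I_count": self.I_count,
            "V_total": self.V_total,
            "contrib_fraction": self.contrib_fraction,
            "cf_fraction": self.cf_fraction,
            "n_inoculum": self.n_inoculum,
            "n_cf": self.n_cf,
            "n_cc": self.n_cc,
        })


def apply_scenario(params: ABMParams, scenario: str) -> tuple[ABMParams, bool]:
    """Return (params with scenario flags applied, use_inoculum)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    if scenario == "single_focus_cc":
        return replace(params, cc_enabled=True, cf_enabled=False,
                       cf_blocked_after_init=False), False
    if scenario == "multifocus_cc":
        return replace(params, cc_enabled=True, cf_enabled=True,
                       cf_blocked_after_init=True, m=M_SLOW), True
    if scenario == "mixed_slow_diffusion":
        return replace(params, cc_enabled=True, cf_enabled=True,
                       cf_blocked_after_init=False, m=M_SLOW, sc=SC_MIXED), True
    if scenario == "mixed_fast_diffusion":
        return replace(params, cc_enabled=True, cf_enabled=True,
                       cf_blocked_after_init=False, m=M_FAST, sc=SC_MIXED), True
    if scenario == "cf_only_slow":
        return replace(params, cc_enabled=False, cf_enabled=True,
                       cf_blocked_after_init=False, m=M_SLOW), True
    return replace(params, cc_enabled=False, cf_enabled=True,
                   cf_blocked_after_init=False, m=M_FAST), True


def run_simulation(params: ABMParams, lattice: HexLattice, scenario: str,
                   seed: Optional[int] = None) -> ABMTimeSeries:
    """Run one replicate of a named scenario and sample its observables.

    The per-step loop is: inoculation (while within the window) ->
    intracellular replication/export -> virion diffusion -> infection
    attempts.  At ``t_init`` the media change removes all extracellular
    virus and, in scenarios with ``cf_blocked_after_init``, disables CF
    transmission for the remainder of the run.  Observables are recorded
    every ``sample_every`` hours (plus at ``t_init`` for inoculated
    scenarios).  A warning is emitted if infection saturates the lattice
    before ``t_end``.
    """
    params, use_inoculum = apply_scenario(params, scenario)
    if use_inoculum and params.I0hat > lattice.n_sites:
        raise ValueError("expected inoculum exceeds the number of lattice sites")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = params.dt
    n_steps = int(round(params.t_end * 60.0 / dt))
    init_step = int(round(params.t_init * 60.0 / dt))

    # spatial virus is only needed while CF infection can still occur
    cf_active = params.cf_enabled
    spatial = cf_active and params.sf > 0.0
    state = new_state(lattice, spatial_v=spatial)

    sample_times = list(np.arange(0.0, params.t_end + 1e-9, params.sample_every))
    if use_inoculum and params.t_init not in sample_times:
        sample_times.append(params.t_init)
    sample_steps = sorted({int(round(t * 60.0 / dt)) for t in sample_times})

    if not use_inoculum:
        _infect(state, np.array([lattice.center_index]), MODE_INOCULUM)

    rec: dict[str, list] = {key: [] for key in
                            ("t", "I", "V", "fc", "ninoc", "ncf", "ncc")}

    def record():
        rec["t"].append(state.t / 60.0)
        rec["I"].append(state.n_infected)
        rec["V"].append(state.total_virus())
        rec["fc"].append(contributor_fraction(state, lattice)
                         if state.n_infected else np.nan)
        modes = state.mode[state.infected_indices()]
        rec["ninoc"].append(int(np.sum(modes == MODE_INOCULUM)))
        rec["ncf"].append(int(np.sum(modes == MODE_CF)))
        rec["ncc"].append(int(np.sum(modes == MODE_CC)))

    sample_set = set(sample_steps)
    if 0 in sample_set:
        record()
    saturated_warned = False
    params_run = params
    for n in range(1, n_steps + 1):
        if use_inoculum and (n - 1) < init_step:
            inoculate(state, params_run, rng)
        if use_inoculum and (n - 1) == init_step:
            media_change(state)
            if params.cf_blocked_after_init:
                cf_active = False
                state.spatial_v = False
                params_run = replace(params_run, cf_enabled=False)
        step_intracellular(state, params_run)
        if cf_active:
            step_diffusion(state, params_run, lattice)
        attempt_infections(state, params_run, lattice, rng)
        state.t = n * dt
        if n in sample_set:
            record()
        if not saturated_warned and state.n_infected == lattice.n_sites:
            warnings.warn(
                f"infection saturated the lattice at t={state.t / 60.0:.1f} h "
                "(boundary effects likely)", RuntimeWarning, stacklevel=2)
            saturated_warned = True

    return ABMTimeSeries(
        times=np.array(rec["t"]),
        I_count=np.array(rec["I"], dtype=np.int64),
        V_total=np.array(rec["V"]),
        contrib_fraction=np.array(rec["fc"]),
        n_inoculum=np.array(rec["ninoc"], dtype=np.int64),
        n_cf=np.array(rec["ncf"], dtype=np.int64),
        n_cc=np.array(rec["ncc"], dtype=np.int64),
    )


def replicate_runs(params: ABMParams, lattice: HexLattice, scenario: str,
                   n_replicates: int, base_seed: int = 0) -> list[ABMTimeSeries]:
    """Run ``n_replicates`` independent replicates; replicate r uses seed
    ``base_seed + r``."""
    return [run_simulation(params, lattice, scenario, seed=base_seed + r)
            for r in range(n_replicates)]


def aggregate_replicates(runs: list[ABMTimeSeries]) -> pd.DataFrame:
    """Per-time-point mean, SD (ddof=1) and replicate count of observables.

    This is the population-level summary the inference layer consumes:
    columns ``time_h, I_mean, I_sd, V_mean, V_sd, fc_mean, cf_mean, n``.
    """
    times = runs[0].times
    for run in runs[1:]:
        if not np.array_equal(run.times, times):
            raise ValueError("replicates were sampled at different times")
    I = np.stack([r.I_count for r in runs]).astype(float)
    V = np.stack([r.V_total for r in runs])
    fc = np.stack([r.contrib_fraction for r in runs])
    cf = np.stack([r.cf_fraction for r in runs])
    n = len(runs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan slices
        frame = pd.DataFrame({
            "time_h": times,
            "I_mean": I.mean(axis=0),
            "I_sd": I.std(axis=0, ddof=1) if n > 1 else np.zeros_like(times),
            "V_mean": V.mean(axis=0),
            "V_sd": V.std(axis=0, ddof=1) if n > 1 else np.zeros_like(times),
            "fc_mean": np.nanmean(fc, axis=0),
            "cf_mean": np.nanmean(cf, axis=0),
            "n": n,
        })
    return frame


def abm_increment_rate(series: ABMTimeSeries, beta_c_tilde: float):
    """Empirical infected-cell increments and the mean transmitting load.

    For a CC-only trajectory sampled densely enough that ``I`` and the
    contributor fraction are smooth between samples, returns

    * ``times`` (midpoints, h) and ``dI_dt`` — the empirical per-hour
      increments of the infected-cell count,
    * ``v_cc`` — the average infectious load per transmitting cell,
      defined so that ``beta_c_tilde * v_cc * integral(I * fc) dt``
      reproduces the total growth over the run exactly:
      v_cc = (I_end - I_start) / (beta_c_tilde * trapz(I * fc, t)).

    ``beta_c_tilde`` is the per-RNA infectivity on the hourly scale,
    sc * finf * 60.
    """
    t, I, fc = series.times, series.I_count.astype(float), series.contrib_fraction
    integral = float(np.trapezoid(I * fc, t))
    if integral <= 0.0:
        raise ValueError("contributor-weighted integral of I vanishes")
    v_cc = (I[-1] - I[0]) / (beta_c_tilde * integral)
    dI_dt = np.diff(I) / np.diff(t)
    mid = 0.5 * (t[1:] + t[:-1])
    return mid, dI_dt, v_cc
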