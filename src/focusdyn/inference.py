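"""Likelihood-based fitting, model comparison and profile-likelihood CIs.

Replicate time series are summarized per sampling time by their mean
``xbar(t)`` and empirical SD ``sigma_t`` across ``n`` replicates.  The
Gaussian log-likelihood of a model prediction ``f(theta, t)`` is

    l(theta) = -1/2 sum_t (xbar(t) - f(theta, t))^2 / sigma^2(t)
               -1/2 sum_t ln sigma^2(t),
    sigma^2(t) = sigma_t^2 / n + sigma_me^2,

with a constant measurement error ``sigma_me`` estimated alongside the
kinetic parameters.  Channels carrying the viral load (or any channel
flagged ``relative``) use relative residuals ``(xbar - f)/f`` with the
empirical SD rescaled by the mean.  Models are ranked by the
small-sample-corrected Akaike criterion

    AICc = 2k - 2L + 2k(k+1)/(n - k - 1),

and confidence intervals come from profile likelihood: the 95% interval
is the set of parameter values whose profile log-likelihood stays
within chi2_1(0.95)/2 = 1.9207 of the maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .models import ModelSpec, ODEParams, simulate

__all__ = [
    "Channel", "Dataset", "ParamBound", "FitProblem", "FitResult",
    "ProfileCI", "log_likelihood", "fit", "joint_fit", "aicc",
    "delta_aicc", "profile_ci", "reduced_chisq", "CHI2_95_DROP",
]

#: chi-squared(1 dof) 95% quantile / 2 — profile-likelihood drop
CHI2_95_DROP = 1.9207


@dataclass(frozen=True)
class Channel:
    """One observable channel of a dataset."""

    kind: str                  # 'infected_cells' | 'viral_load'
    times: np.ndarray          # sampling times (h), strictly increasing
    xbar: np.ndarray           # per-time replicate mean
    sd: np.ndarray             # per-time replicate SD (ddof=1)
    n_reps: int
    error_model: str = "absolute"   # 'absolute' | 'relative'

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "xbar", np.asarray(self.xbar, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if np.any(np.diff(times) <= 0):
            raise ValueError("channel times must be strictly increasing")
        if not (self.times.size == self.xbar.size == self.sd.size):
            raise ValueError("channel arrays must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be >= 0")
        if self.error_model not in ("absolute", "relative"):
            raise ValueError("error_model must be 'absolute' or 'relative'")


@dataclass(frozen=True)
class Dataset:
    """Observed time series: one or more channels sharing an experiment."""

    channels: tuple

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        if not self.channels:
            raise ValueError("dataset needs at least one channel")

    @property
    def n_points(self) -> int:
        return sum(ch.times.size for ch in self.channels)


def log_likelihood(predictions: Sequence[np.ndarray], dataset: Dataset,
                   sigma_me: float) -> float:
    """Gaussian log-likelihood of per-channel predictions.

    ``predictions[i]`` must be aligned with ``dataset.channels[i].times``.
    For relative channels both the residual and the empirical SD are
    scaled (residual by the prediction, SD by the observed mean), and
    ``sigma_me`` acts on the relative scale.
    """
    total = 0.0
    for ch, f in zip(dataset.channels, predictions):
        f = np.asarray(f, dtype=float)
        if ch.error_model == "relative":
            if np.any(f <= 0.0) or np.any(ch.xbar <= 0.0):
                return -np.inf
            resid = (ch.xbar - f) / f
            var = (ch.sd / ch.xbar) ** 2 / ch.n_reps + sigma_me**2
        else:
            resid = ch.xbar - f
            var = ch.sd**2 / ch.n_reps + sigma_me**2
        if np.any(var <= 0.0):
            raise ValueError(
                "zero combined variance; require sigma_me > 0 or positive sd")
        total += float(-0.5 * np.sum(resid**2 / var) - 0.5 * np.sum(np.log(var)))
    return total


@dataclass(frozen=True)
class ParamBound:
    """Box bound and optimizer scale for one free parameter."""

    lo: float
    hi: float
    scale: str = "log"        # 'log' | 'linear'
    init: Optional[float] = None

    def transform(self, x: float) -> float:
        return math.log(x) if self.scale == "log" else x

    def inverse(self, y: float) -> float:
        return math.exp(y) if self.scale == "log" else y

    @property
    def box(self) -> tuple:
        return (self.transform(self.lo), self.transform(self.hi))

    def default_init(self) -> float:
        if self.init is not None:
            return self.init
        lo, hi = self.box
        return self.inverse(0.5 * (lo + hi))


@dataclass
class FitProblem:
    """Binds a model variant to a dataset with fixed and free parameters.

    ``base`` supplies the initial conditions and every fixed rate;
    ``free`` maps parameter names (``beta_c``, ``beta_f``, ``theta``,
    ``z``, ``tau``, ``rho``, ``c``, ``sigma_me``) to bounds.  ``theta``
    and ``z`` rebuild the adjustment term around the fixed ``k`` and
    ``psi`` of ``base.adjustment``.
    """

    spec: ModelSpec
    dataset: Dataset
    base: ODEParams
    free: dict
    name: str = ""
    t0: Optional[float] = None    # time of the initial conditions

    @property
    def n_points(self) -> int:
        return self.dataset.n_points

    def make_params(self, values: dict) -> ODEParams:
        ode_updates = {k: v for k, v in values.items()
                       if k in ("beta_c", "beta_f", "rho", "c", "tau")}
        params = replace(self.base, **ode_updates) if ode_updates else self.base
        adj_updates = {k: v for k, v in values.items() if k in ("theta", "z")}
        if adj_updates:
            if self.base.adjustment is None:
                raise ValueError("theta/z free but base has no adjustment")
            params = replace(params, adjustment=replace(
                self.base.adjustment, **adj_updates))
        return params

    def predict(self, values: dict) -> list:
        params = self.make_params(values)
        t0 = self.t0 if self.t0 is not None else min(
            ch.times[0] for ch in self.dataset.channels)
        if t0 > min(ch.times[0] for ch in self.dataset.channels):
            raise ValueError("t0 must not exceed the first observation time")
        all_times = np.unique(np.concatenate(
            [[t0]] + [ch.times for ch in self.dataset.channels]))
        traj = simulate(self.spec, params, all_times)
        cols = {"infected_cells": traj["I"], "viral_load": traj["V"]}
        out = []
        for ch in self.dataset.channels:
            idx = np.searchsorted(all_times, ch.times)
            out.append(cols[ch.kind][idx])
        return out

    def loglik(self, values: dict) -> float:
        try:
            preds = self.predict(values)
        except (RuntimeError, FloatingPointError, OverflowError):
            return -np.inf
        return log_likelihood(preds, self.dataset, values.get("sigma_me", 0.0))


@dataclass
class ProfileCI:
    """Profile-likelihood confidence interval for one parameter."""

    lower: float
    upper: float
    lower_open: bool           # bound hit without crossing the drop
    upper_open: bool
    identifiable: bool         # crossed the drop on both sides
    grid: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_loglik: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class FitResult:
    """Maximum-likelihood estimates and model-comparison bookkeeping."""

    estimates: dict
    loglik: float
    k: int
    n: int
    aicc: Optional[float]
    converged: bool
    n_restarts: int
    profiles: dict = field(default_factory=dict)


class _VectorObjective:
    """Maps a flat optimizer vector onto named parameters of >=1 problems.

    Shared names occupy one slot; problem-specific names are suffixed
    with ``@<problem name>`` when several problems are fitted jointly.
    """

    def __init__(self, problems: Sequence, shared: Sequence[str] = (),
                 fixed: Optional[dict] = None):
        self.problems = list(problems)
        self.shared = tuple(shared)
        self.fixed = dict(fixed or {})
        self.labels: list[str] = []
        self.bounds: list[ParamBound] = []
        self._slots: list[list[tuple[str, str]]] = []  # per-problem (name, label)
        seen = set()
        for i, prob in enumerate(self.problems):
            slots = []
            for pname, bound in prob.free.items():
                label = (pname if (pname in self.shared or len(self.problems) == 1)
                         else f"{pname}@{prob.name or i}")
                slots.append((pname, label))
                if label in seen:
                    continue
                seen.add(label)
                if label not in self.fixed:
                    self.labels.append(label)
                    self.bounds.append(bound)
            self._slots.append(slots)
        for label in self.fixed:
            if not any(label == lab for slots in self._slots for _, lab in slots):
                raise KeyError(f"fixed parameter {label!r} is not a free label")
        self._bound_by_label = {}
        for prob, slots in zip(self.problems, self._slots):
            for pname, label in slots:
                self._bound_by_label.setdefault(label, prob.free[pname])

    @property
    def dim(self) -> int:
        return len(self.labels)

    def decode(self, x: np.ndarray) -> tuple[dict, float]:
        """Vector -> {label: value}; returns box-violation penalty too."""
        values, penalty = {}, 0.0
        for label, bound, y in zip(self.labels, self.bounds, x):
            lo, hi = bound.box
            y_c = min(max(y, lo), hi)
            penalty += (y - y_c) ** 2
            values[label] = bound.inverse(y_c)
        values.update(self.fixed)
        return values, penalty

    def encode(self, values: dict) -> np.ndarray:
        return np.array([b.transform(values[lab])
                         for lab, b in zip(self.labels, self.bounds)])

    def loglik(self, values: dict) -> float:
        total = 0.0
        for prob, slots in zip(self.problems, self._slots):
            total += prob.loglik({p: values[lab] for p, lab in slots})
            if not np.isfinite(total):
                return -np.inf
        return total

    def negative(self, x: np.ndarray) -> float:
        values, penalty = self.decode(x)
        ll = self.loglik(values)
        if not np.isfinite(ll):
            return 1e12 + 1e3 * penalty
        return -ll + 1e3 * penalty


def _default_inits(obj: _VectorObjective) -> np.ndarray:
    return np.array([b.transform(b.default_init()) for b in obj.bounds])


def _minimize(obj: _VectorObjective, x0: np.ndarray, maxiter: int):
    return optimize.minimize(
        obj.negative, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8,
                 "adaptive": obj.dim > 4})


def joint_fit(problems: Sequence, shared: Sequence[str] = (),
              n_restarts: int = 50, seed: int = 0,
              fixed: Optional[dict] = None,
              x0: Optional[np.ndarray] = None,
              maxiter_per_dim: int = 250) -> FitResult:
    """Maximize the summed log-likelihood over one or more problems.

    Nelder-Mead in transformed (log where declared) parameter space with
    Latin-hypercube restarts; deterministic for a given ``seed``.  The
    first start is the declared initial guess (or ``x0`` when supplied,
    e.g. for warm-started profile refits).
    """
    obj = _VectorObjective(problems, shared, fixed)
    if obj.dim == 0:
        values, _ = obj.decode(np.array([]))
        ll = obj.loglik(values)
        n = sum(p.n_points for p in problems)
        return FitResult(estimates=dict(values), loglik=ll, k=0, n=n,
                         aicc=aicc(ll, 0, n) if n > 1 else None,
                         converged=True, n_restarts=0)
    starts = [np.asarray(x0, dtype=float) if x0 is not None
              else _default_inits(obj)]
    if n_restarts > 1:
        sampler = qmc.LatinHypercube(d=obj.dim, seed=seed)
        unit = sampler.random(n_restarts - 1)
        los = np.array([b.box[0] for b in obj.bounds])
        his = np.array([b.box[1] for b in obj.bounds])
        # sample the central 90% of the box to avoid starting on the edge
        span = his - los
        starts.extend(los + span * (0.05 + 0.9 * unit))
    best, best_fun, any_ok = None, np.inf, False
    maxiter = maxiter_per_dim * obj.dim
    for s in starts:
        res = _minimize(obj, s, maxiter)
        if np.isfinite(res.fun):
            any_ok = True
        if res.fun < best_fun:
            best, best_fun = res, res.fun
    if best is None or not any_ok:
        raise RuntimeError("no optimizer restart produced a finite likelihood")
    values, _ = obj.decode(best.x)
    ll = obj.loglik(values)
    k = obj.dim
    n = sum(p.n_points for p in problems)
    return FitResult(
        estimates=dict(values), loglik=ll, k=k, n=n,
        aicc=aicc(ll, k, n) if n > k + 1 else None,
        converged=bool(best.success or best_fun < np.inf),
        n_restarts=len(starts))


def fit(problem: FitProblem, n_restarts: int = 50, seed: int = 0,
        **kwargs) -> FitResult:
    """Fit a single model/dataset problem (see ``joint_fit``)."""
    return joint_fit([problem], shared=(), n_restarts=n_restarts, seed=seed,
                     **kwargs)


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion 2k - 2L + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def delta_aicc(fits: Sequence[FitResult]) -> list:
    """AICc differences relative to the best (lowest-AICc) fit."""
    vals = [f.aicc for f in fits]
    if any(v is None for v in vals):
        raise ValueError("all fits need a defined AICc")
    best = min(vals)
    return [v - best for v in vals]


def reduced_chisq(problem: FitProblem, values: dict) -> float:
    """Goodness-of-fit sum((xbar - f)^2 / (sd^2/n)) / (n_pts - k).

    Uses the data's empirical standard error scale; sampling times where
    the replicate SD vanishes (e.g. a saturated lattice) carry no
    information about misfit on that scale and are excluded from both
    the sum and the degrees of freedom.
    """
    preds = problem.predict(values)
    chi, used = 0.0, 0
    for ch, f in zip(problem.dataset.channels, preds):
        se2 = ch.sd**2 / ch.n_reps
        mask = se2 > 0
        chi += float(np.sum((ch.xbar[mask] - f[mask]) ** 2 / se2[mask]))
        used += int(mask.sum())
    dof = used - len(problem.free)
    if dof <= 0:
        raise ValueError("no degrees of freedom left for reduced chi-square")
    return chi / dof


def profile_ci(problems: Sequence, fit_result: FitResult, label: str,
               shared: Sequence[str] = (), n_grid: int = 12,
               drop: float = CHI2_95_DROP, seed: int = 0,
               n_restarts: int = 1, max_refit_failures: float = 0.2,
               maxiter_per_dim: int = 150) -> ProfileCI:
    """Profile-likelihood 95% confidence interval for one parameter.

    The parameter is scanned from its estimate toward each bound
    (log-spaced for log-scale parameters), re-optimizing all remaining
    parameters at every grid value with a warm start from the previous
    point.  The interval edge is the interpolated crossing of the
    ``drop`` level; a side that reaches its bound without crossing is
    reported open (unbounded within the box).  ``identifiable`` is True
    only if both sides cross — a profile flat to both bounds flags a
    non-identifiable parameter.
    """
    obj_full = _VectorObjective(problems, shared)
    if label not in obj_full.labels:
        raise KeyError(f"{label!r} is not a free parameter of this fit")
    bound = obj_full._bound_by_label[label]
    est = fit_result.estimates[label]
    ll_max = fit_result.loglik
    grid_vals, grid_lls = [est], [ll_max]
    edges = {}
    failures, attempts = 0, 0
    for side in (-1, +1):
        target = bound.lo if side < 0 else bound.hi
        y_est = bound.transform(min(max(est, bound.lo), bound.hi))
        ys = np.linspace(y_est, bound.transform(target), n_grid + 1)[1:]
        prev_ll, prev_val = ll_max, est
        prev2 = None                      # (y, ll) two steps back
        # warm-start the first refit from the MLE itself
        sub0 = _VectorObjective(problems, shared, fixed={label: est})
        x_warm = sub0.encode(fit_result.estimates)
        crossing = None
        for y in ys:
            val = bound.inverse(y)
            attempts += 1
            try:
                refit = joint_fit(problems, shared=shared,
                                  n_restarts=n_restarts, seed=seed,
                                  fixed={label: val}, x0=x_warm,
                                  maxiter_per_dim=maxiter_per_dim)
            except RuntimeError:
                failures += 1
                continue
            sub_obj = _VectorObjective(problems, shared, fixed={label: val})
            x_warm = sub_obj.encode(refit.estimates)
            ll = refit.loglik
            ll_max = max(ll_max, ll)
            grid_vals.append(val)
            grid_lls.append(ll)
            if ll < ll_max - drop:
                y_prev = bound.transform(prev_val)
                level = ll_max - drop
                y_cross = None
                if prev2 is not None:
                    # quadratic through the last three profile points —
                    # exact for locally parabolic log-likelihoods
                    coef = np.polyfit([prev2[0], y_prev, y],
                                      [prev2[1], prev_ll, ll], 2)
                    roots = np.roots(np.array([coef[0], coef[1],
                                               coef[2] - level]))
                    roots = roots[np.isreal(roots)].real
                    inside = [r for r in roots
                              if min(y_prev, y) - 1e-12 <= r
                              <= max(y_prev, y) + 1e-12]
                    if inside:
                        y_cross = float(inside[0])
                if y_cross is None:
                    frac = (level - prev_ll) / (ll - prev_ll)
                    frac = min(max(frac, 0.0), 1.0)
                    y_cross = y_prev + frac * (y - y_prev)
                crossing = bound.inverse(y_cross)
                break
            prev2 = (bound.transform(min(max(prev_val, bound.lo), bound.hi)),
                     prev_ll)
            prev_ll, prev_val = ll, val
            if ll < ll_max - drop - 5.0:   # pragma: no cover - safety stop
                break
        edges[side] = crossing
    if attempts and failures / attempts > max_refit_failures:
        raise RuntimeError(
            f"profile refits failed at {failures}/{attempts} grid points")
    lower = edges[-1] if edges[-1] is not None else bound.lo
    upper = edges[+1] if edges[+1] is not None else bound.hi
    order = np.argsort(grid_vals)
    return ProfileCI(
        lower=lower, upper=upper,
        lower_open=edges[-1] is None, upper_open=edges[+1] is None,
        identifiable=(edges[-1] is not None and edges[+1] is not None),
        grid=np.asarray(grid_vals)[order],
        grid_loglik=np.asarray(grid_lls)[order])
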