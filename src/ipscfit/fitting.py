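"""Multi-start derivative-free fitting of single-event traces.

Each fit attempt draws a random initial parameter vector uniformly within
the configured bounds (rejecting vectors that violate the exclusion rules),
applies the dependency rules, and locally minimizes the root-mean-squared
error between the model current and the recorded event with a bounded
principal-axis (direction-set) method.  A result is accepted when its RMSE
is below 10% of the event's peak amplitude; the accepted results form the
event's parameter ensemble, whose internal spread exposes the model's
degeneracies.  Warnings are emitted for unfittable traces and for accepted
results with a parameter pinned at a bound (an outlier value).

Seeding is per (trace, start): ``seed + 10^4 * trace_index + start_index``,
so results are reproducible and independent of how work is distributed
across processes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, minimize

from .configdsl import (
    BIEXP_REGISTRY,
    GEPHYRIN_REGISTRY,
    FitConfig,
    apply_dependencies,
    eval_exclusion,
    serialize_config,
)
from .models import (
    BiexpParams,
    ClampContext,
    GephyrinParams,
    ParameterDomainError,
    eval_biexp_current,
    eval_current_analytic,
)
from .preprocess import EventStatus, EventTrace, moving_window_samples

__all__ = [
    "FitResult",
    "FitEnsemble",
    "MinimizeOutcome",
    "GephyrinModel",
    "BiexpModel",
    "StartError",
    "compute_cost",
    "praxis_minimize",
    "fit_trace",
    "fit_events",
    "flag_outliers",
    "ensembles_frame",
    "best_fits_frame",
    "write_warnings_log",
    "write_run_report",
    "RMSE_THRESHOLD",
]

#: default acceptance threshold: RMSE below 10% of the event's peak amplitude
RMSE_THRESHOLD = 0.10
#: default multi-start budget
DEFAULT_N_STARTS = 100
DEFAULT_MAX_ITER = 3000
#: outlier warning: parameter within 1% of the bound range of either bound
OUTLIER_BOUND_TOL = 0.01
#: half-width of the onset-parameter bound window around the detected onset (ms)
ONSET_WINDOW_MS = 2.0

_PENALTY = 1e9


class StartError(ValueError):
    """The objective was non-finite at the requested start point."""


@dataclass(frozen=True)
class FitResult:
    values: np.ndarray
    names: tuple[str, ...]
    rmse: float
    rmse_frac: float
    n_eval: int
    init_id: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


@dataclass(frozen=True)
class FitEnsemble:
    trace_id: str
    results: tuple[FitResult, ...]
    best: FitResult | None
    warnings: tuple[tuple[int, str], ...] = ()
    n_starts: int = 0
    status: EventStatus = EventStatus.ACCEPTED
    peak_amplitude: float = float("nan")
    experiment: str = ""
    cell: str = ""

    @property
    def unfittable(self) -> bool:
        return self.status is EventStatus.ACCEPTED and self.best is None


# ---------------------------------------------------------------------------
# Model adapters: map canonical config names onto the kinetic models

@dataclass(frozen=True)
class GephyrinModel:
    """Gephyrin transsynaptic scheme as a fit target (magnitude in pA)."""

    ctx: ClampContext = field(default_factory=ClampContext)
    defaults: GephyrinParams = field(default_factory=GephyrinParams)
    registry = GEPHYRIN_REGISTRY

    def evaluate(self, values: dict[str, float], t: np.ndarray) -> np.ndarray:
        fields = {k: v for k, v in values.items()
                  if k in GEPHYRIN_REGISTRY.parameters}
        params = replace(self.defaults, **fields)
        cur = eval_current_analytic(params, self.ctx, t)
        return cur if self.ctx.driving_force > 0 else -cur


@dataclass(frozen=True)
class BiexpModel:
    """Peak-normalized bi-exponential conductance as a fit target."""

    ctx: ClampContext = field(default_factory=ClampContext)
    registry = BIEXP_REGISTRY

    def evaluate(self, values: dict[str, float], t: np.ndarray) -> np.ndarray:
        params = BiexpParams(
            tau1=values["tau1"], tau2=values["tau2"],
            t_start=values["t_start"], weight=values["weight"],
        )
        cur = eval_biexp_current(params, self.ctx, t)
        return cur if self.ctx.driving_force > 0 else -cur


# ---------------------------------------------------------------------------
# Cost

def compute_cost(model_current: np.ndarray, event: EventTrace,
                 mode: str = "raw") -> float:
    """RMSE (pA) between a model current and the event's retained samples.

    ``mode="running_mean"`` replaces the data by its centered running mean
    (window = the preprocessing moving-window width) before the residual.
    """
    model_current = np.asarray(model_current, dtype=float)
    data = event.samples
    if model_current.shape != data.shape:
        raise ValueError(
            f"grid mismatch: model has {model_current.shape}, "
            f"event has {data.shape}"
        )
    if mode == "running_mean":
        n_w = moving_window_samples(event.dt, data.size * event.dt)
        data = (
            pd.Series(data)
            .rolling(n_w, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    elif mode != "raw":
        raise ValueError(f"unknown cost mode {mode!r}")
    return float(np.sqrt(np.mean((model_current - data) ** 2)))


# ---------------------------------------------------------------------------
# Bounded principal-axis local minimization

@dataclass(frozen=True)
class MinimizeOutcome:
    x: np.ndarray
    fun: float
    n_eval: int
    converged: bool


class _BudgetExceeded(Exception):
    pass


def praxis_minimize(objective, x0, bounds, max_iter: int = DEFAULT_MAX_ITER,
                    xtol: float = 1e-6, ftol: float = 1e-14) -> MinimizeOutcome:
    """Bounded derivative-free local minimization (principal-axis family).

    Uses the Powell direction-set method with truncated line searches inside
    the box, restarted from the incumbent (which resets the direction set to
    the coordinate axes) until the evaluation budget ``max_iter`` is spent or
    a restart no longer improves the objective.  The restarts matter: a
    single direction-set pass can stall along a soft, curved valley of the
    objective — exactly what the amplitude/rate trade-offs of kinetic models
    produce.  The best point seen is always returned.  Deterministic given
    (x0, bounds, tolerances).
    """
    x0 = np.asarray(x0, dtype=float)
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise StartError(f"start point {x0} outside bounds")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    state = {"n": 0, "best_x": x0.copy(), "best_f": math.inf}

    def wrapped(x: np.ndarray) -> float:
        if state["n"] >= max_iter:
            raise _BudgetExceeded
        state["n"] += 1
        f = float(objective(np.clip(x, lo, hi)))
        if math.isfinite(f) and f < state["best_f"]:
            state["best_f"] = f
            state["best_x"] = np.clip(np.asarray(x, dtype=float), lo, hi)
        return f

    f0 = wrapped(x0)
    if not math.isfinite(f0):
        raise StartError(f"objective non-finite at start point: {f0}")

    converged = False
    try:
        prev_best = math.inf
        while state["n"] < max_iter:
            res = minimize(
                wrapped, state["best_x"], method="Powell",
                bounds=Bounds(lo, hi),
                options={"maxfev": max_iter - state["n"],
                         "xtol": xtol, "ftol": ftol, "disp": False},
            )
            improved = prev_best - state["best_f"] > 1e-12 * (1.0 + abs(state["best_f"]))
            if bool(res.success) and not improved:
                converged = True
                break
            prev_best = state["best_f"]
    except _BudgetExceeded:
        pass
    return MinimizeOutcome(
        x=state["best_x"], fun=state["best_f"], n_eval=state["n"],
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Outlier warnings

def flag_outliers(result: FitResult, config: FitConfig,
                  rel_tol: float = OUTLIER_BOUND_TOL) -> list[tuple[int, str]]:
    """Flag warned parameters whose value is pinned near a bound.

    A value within ``rel_tol`` of the bound range of either bound indicates
    a non-identifiable or misspecified fit.
    """
    flags: list[tuple[int, str]] = []
    warn = set(config.warn_set)
    vals = result.as_dict()
    for spec in config.params:
        if spec.name not in warn:
            continue
        v = vals[spec.name]
        margin = rel_tol * (spec.hi - spec.lo)
        if v - spec.lo <= margin or spec.hi - v <= margin:
            flags.append((result.init_id, spec.name))
    return flags


# ---------------------------------------------------------------------------
# Multi-start fitting

def _canonical_values(config: FitConfig, x: np.ndarray) -> dict[str, float]:
    return {config.canonical(n): float(v) for n, v in zip(config.names, x)}


def _start_seed(seed: int, trace_index: int, start_index: int) -> int:
    return int(seed) + 10_000 * int(trace_index) + int(start_index)


def fit_trace(event: EventTrace, config: FitConfig, model,
              n_starts: int = DEFAULT_N_STARTS,
              max_iter: int = DEFAULT_MAX_ITER,
              seed: int = 0, trace_index: int = 0,
              rmse_threshold: float = RMSE_THRESHOLD,
              cost_mode: str = "raw",
              onset_window_ms: float = ONSET_WINDOW_MS) -> FitEnsemble:
    """Fit one accepted event with randomized multi-start local optimization.

    Returns the ensemble of accepted results (rmse/peak below threshold),
    the best result, and (init_id, parameter) outlier warnings.  Rejected
    events pass through with an empty ensemble and their rejection status.
    Failures are recorded states, never exceptions.
    """
    trace_id = event.meta.trace_id
    meta_kwargs = dict(peak_amplitude=event.peak_amplitude,
                       experiment=event.meta.experiment, cell=event.meta.cell)
    if not event.accepted:
        return FitEnsemble(trace_id=trace_id, results=(), best=None,
                           n_starts=0, status=event.status, **meta_kwargs)

    t = event.times()
    names = config.names
    lo = np.array([p.lo for p in config.params])
    hi = np.array([p.hi for p in config.params])

    # the onset is fitted, but only within a window around the detected onset
    onset_names = {"t0", "t_start"}
    for i, p in enumerate(config.params):
        if config.canonical(p.name) in onset_names:
            onset = event.onset_time
            lo[i] = max(lo[i], onset - onset_window_ms)
            hi[i] = min(hi[i], onset + onset_window_ms)
            if lo[i] >= hi[i]:  # detected onset outside configured bounds
                lo[i], hi[i] = max(0.0, onset - onset_window_ms), onset + onset_window_ms

    def objective(x: np.ndarray) -> float:
        values = _canonical_values(config, x)
        try:
            values = apply_dependencies(config, values)
            if config.exclusions and eval_exclusion(config, values):
                return _PENALTY
            cur = model.evaluate(values, t)
        except ParameterDomainError:
            return _PENALTY
        return compute_cost(cur, event, mode=cost_mode)

    results: list[FitResult] = []
    warnings: list[tuple[int, str]] = []
    for j in range(n_starts):
        rng = np.random.default_rng(_start_seed(seed, trace_index, j))
        x0 = None
        for _ in range(100):
            cand = rng.uniform(lo, hi)
            values = apply_dependencies(config, _canonical_values(config, cand))
            if not (config.exclusions and eval_exclusion(config, values)):
                x0 = cand
                break
        if x0 is None:
            continue  # exclusion rules reject the whole box: skip this start
        try:
            out = praxis_minimize(objective, x0, list(zip(lo, hi)),
                                  max_iter=max_iter)
        except StartError:
            continue
        values = apply_dependencies(config, _canonical_values(config, out.x))
        if config.exclusions and eval_exclusion(config, values):
            continue
        rmse = out.fun
        rmse_frac = rmse / event.peak_amplitude
        if rmse_frac < rmse_threshold:
            result = FitResult(
                values=np.asarray(out.x, dtype=float), names=names,
                rmse=rmse, rmse_frac=rmse_frac, n_eval=out.n_eval,
                init_id=j, converged=out.converged,
            )
            results.append(result)
            warnings.extend(flag_outliers(result, config))

    best = min(results, key=lambda r: r.rmse) if results else None
    return FitEnsemble(
        trace_id=trace_id, results=tuple(results), best=best,
        warnings=tuple(warnings), n_starts=n_starts, status=event.status,
        **meta_kwargs,
    )


def _fit_one(args) -> FitEnsemble:
    event, config, model, kwargs = args
    return fit_trace(event, config, model, **kwargs)


def fit_events(events: list[EventTrace], config: FitConfig, model,
               n_starts: int = DEFAULT_N_STARTS,
               max_iter: int = DEFAULT_MAX_ITER,
               seed: int = 0, rmse_threshold: float = RMSE_THRESHOLD,
               cost_mode: str = "raw", workers: int = 1) -> list[FitEnsemble]:
    """Fit a list of events; per-(trace, start) seeding makes the result
    independent of ``workers``. Results are returned in input order."""
    jobs = [
        (ev, config, model, dict(
            n_starts=n_starts, max_iter=max_iter, seed=seed, trace_index=i,
            rmse_threshold=rmse_threshold, cost_mode=cost_mode,
        ))
        for i, ev in enumerate(events)
    ]
    if workers <= 1:
        return [_fit_one(job) for job in jobs]
    import multiprocessing as mp

    with mp.get_context("spawn").Pool(workers) as pool:
        return list(pool.map(_fit_one, jobs))


# ---------------------------------------------------------------------------
# Tabular outputs

def ensembles_frame(ensembles: list[FitEnsemble]) -> pd.DataFrame:
    """Long table: one row per accepted fit (trace, init, params, rmse)."""
    rows = []
    for ens in ensembles:
        for res in ens.results:
            row = {"trace": ens.trace_id, "experiment": ens.experiment,
                   "cell": ens.cell, "init": res.init_id}
            row.update(res.as_dict())
            row["rmse"] = res.rmse
            row["rmse_frac"] = res.rmse_frac
            row["peak_pA"] = ens.peak_amplitude
            rows.append(row)
    return pd.DataFrame(rows)


def best_fits_frame(ensembles: list[FitEnsemble]) -> pd.DataFrame:
    rows = []
    for ens in ensembles:
        if ens.best is None:
            continue
        row = {"trace": ens.trace_id, "experiment": ens.experiment,
               "cell": ens.cell, "init": ens.best.init_id}
        row.update(ens.best.as_dict())
        row["rmse"] = ens.best.rmse
        row["rmse_frac"] = ens.best.rmse_frac
        row["peak_pA"] = ens.peak_amplitude
        rows.append(row)
    return pd.DataFrame(rows)


def write_warnings_log(ensembles: list[FitEnsemble], path: str) -> None:
    """One line per problem: trace id and reason
    (unfittable | too-short | overlap | outlier:<name>)."""
    with open(path, "w") as fh:
        for ens in ensembles:
            if ens.status is EventStatus.REJECTED_SHORT:
                fh.write(f"{ens.trace_id}\ttoo-short\n")
            elif ens.status is EventStatus.REJECTED_OVERLAP:
                fh.write(f"{ens.trace_id}\toverlap\n")
            elif ens.unfittable:
                fh.write(f"{ens.trace_id}\tunfittable\n")
            for init_id, name in ens.warnings:
                fh.write(f"{ens.trace_id}\toutlier:{name}\t{init_id}\n")


def write_run_report(ensembles: list[FitEnsemble], config: FitConfig,
                     path: str, *, seed: int, n_starts: int, max_iter: int,
                     rmse_threshold: float = RMSE_THRESHOLD) -> None:
    config_hash = hashlib.sha256(serialize_config(config).encode()).hexdigest()
    n_accepted_traces = sum(1 for e in ensembles if e.best is not None)
    report = {
        "n_traces": len(ensembles),
        "n_fitted": n_accepted_traces,
        "n_unfittable": sum(1 for e in ensembles if e.unfittable),
        "n_rejected_short": sum(
            1 for e in ensembles if e.status is EventStatus.REJECTED_SHORT),
        "n_rejected_overlap": sum(
            1 for e in ensembles if e.status is EventStatus.REJECTED_OVERLAP),
        "n_accepted_fits": sum(len(e.results) for e in ensembles),
        "n_outlier_warnings": sum(len(e.warnings) for e in ensembles),
        "seed": seed,
        "n_starts": n_starts,
        "max_iter": max_iter,
        "rmse_threshold": rmse_threshold,
        "config_sha256": config_hash,
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
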