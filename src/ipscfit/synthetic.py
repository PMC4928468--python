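"""Synthetic sIPSC datasets with known ground truth.

Emulates the statistical character of spontaneous inhibitory events
recorded from CA1 pyramidal neurons under somatic voltage clamp: inward
currents of roughly 10-100 pA peak, rise time constants 0.05-0.5 ms, decay
time constants 3-20 ms, peak amplitudes drawn from a 4-parameter
pseudo-Voigt distribution, additive Gaussian background noise, a
holding/baseline offset, and occasional overlapping second events during
the decay.

The target peak amplitude of each trace is realized by solving for the
current-scale constant ``c1`` given the sampled kinetics, so amplitude and
kinetics are statistically independent by construction — which is also what
makes downstream identifiability and time-to-peak analyses meaningful.

Every dataset regenerates bit-identically from (spec, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .models import (
    ClampContext,
    GephyrinParams,
    TimeGrid,
    current_shape,
    eval_current_analytic,
    peak_time,
    steady_states,
)
from .preprocess import RawTrace, TraceMeta, write_trace_csv

__all__ = [
    "PseudoVoigtParams",
    "NoiseModel",
    "DatasetSpec",
    "TraceTruth",
    "SyntheticDataset",
    "PSEUDO_VOIGT_EXPERIMENTS",
    "pseudo_voigt",
    "pseudo_voigt_mass_fraction",
    "sample_peaks",
    "analytic_peak",
    "calibrate_c1",
    "generate_trace",
    "generate_dataset",
    "write_dataset",
    "truth_frame",
]


@dataclass(frozen=True)
class PseudoVoigtParams:
    """4-parameter pseudo-Voigt: height ``a``, width ``b`` (pA), Lorentzian
    fraction ``c`` in [0, 1], mode location ``x0`` (pA)."""

    a: float = 0.2785
    b: float = 13.3410
    c: float = 0.4665
    x0: float = 36.9253

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("pseudo-Voigt height and width must be > 0")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"Lorentzian fraction must be in [0, 1], got {self.c}")


#: per-experiment peak-amplitude distributions of the five recording sets
PSEUDO_VOIGT_EXPERIMENTS = {
    "expA": PseudoVoigtParams(a=0.2069, b=18.7436, c=0.8087, x0=40.2020),
    "expB": PseudoVoigtParams(a=0.4024, b=9.0292, c=1.0000, x0=24.8492),
    "expC": PseudoVoigtParams(a=0.2785, b=13.3410, c=0.4665, x0=36.9253),
    "expD": PseudoVoigtParams(a=0.2998, b=11.5380, c=1.0000, x0=34.6231),
    "expE": PseudoVoigtParams(a=0.3193, b=11.7930, c=1.0000, x0=26.8240),
}


def pseudo_voigt(x, p: PseudoVoigtParams):
    """f(x) = a*[c/(1+((x-x0)/b)^2) + (1-c)*exp(-0.5*((x-x0)/b)^2)].

    A weighted sum of a Lorentzian and a Gaussian of common width ``b``;
    symmetric about ``x0`` with f(x0) = a.
    """
    z = (np.asarray(x, dtype=float) - p.x0) / p.b
    return p.a * (p.c / (1.0 + z * z) + (1.0 - p.c) * np.exp(-0.5 * z * z))


def pseudo_voigt_mass_fraction(p: PseudoVoigtParams,
                               interval: tuple[float, float],
                               support: tuple[float, float]) -> float:
    """Probability mass of ``interval`` under the density normalized on ``support``."""
    num, _ = quad(lambda x: float(pseudo_voigt(x, p)), *interval)
    den, _ = quad(lambda x: float(pseudo_voigt(x, p)), *support)
    return num / den


def sample_peaks(n: int, p: PseudoVoigtParams,
                 amp_range: tuple[float, float] = (10.0, 100.0),
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` peak amplitudes (pA) from the pseudo-Voigt restricted to
    ``amp_range``, by rejection sampling."""
    lo, hi = amp_range
    if not (0.0 < lo < hi):
        raise ValueError(f"degenerate amplitude range {amp_range!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # density is unimodal at x0: its max over [lo, hi] is at the clipped mode
    fmax = float(pseudo_voigt(np.clip(p.x0, lo, hi), p))
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        x = rng.uniform(lo, hi, size=m)
        u = rng.uniform(0.0, fmax, size=m)
        keep = x[u < pseudo_voigt(x, p)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


@dataclass(frozen=True)
class NoiseModel:
    """Additive distortions of a recorded sweep.

    ``sigma`` white-noise SD (pA); ``offset`` holding/baseline current (pA);
    ``drift`` linear drift (pA/ms); ``p_overlap`` probability that a second
    event lands in the decay of the first.
    """

    sigma: float = 2.0
    offset: float = 0.0
    drift: float = 0.0
    p_overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.p_overlap <= 1.0:
            raise ValueError("p_overlap must be in [0, 1]")


def analytic_peak(params: GephyrinParams, ctx: ClampContext) -> float:
    """Peak magnitude (pA) of the noiseless analytic current."""
    tstar = peak_time(params)
    shape = float(current_shape(params.alpha_b, params.tau_r, params.tau_d,
                                np.array([tstar]))[0])
    return abs(steady_states(params).i_fact * shape * ctx.driving_force)


def calibrate_c1(params: GephyrinParams, ctx: ClampContext,
                 target_peak: float) -> GephyrinParams:
    """Scale ``c1`` so the noiseless current peaks at ``target_peak`` pA."""
    base = analytic_peak(params, ctx)
    return replace(params, c1=params.c1 * target_peak / base)


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth of one generated trace."""

    trace_id: str
    params: GephyrinParams
    ctx: ClampContext
    noise: NoiseModel
    peak: float
    experiment: str = ""
    cell: str = ""
    overlap: bool = False
    overlap_lag: float = 0.0
    overlap_params: GephyrinParams | None = None


@dataclass(frozen=True)
class DatasetSpec:
    """Study conditions of a generated dataset.

    Defaults emulate the recordings the package targets: 20 kHz-like
    sampling (dt = 0.05 ms) over 80 ms with the event onset at 20 ms,
    amplitudes from the pseudo-Voigt restricted to 10-100 pA, rise/decay
    time constants in the experimentally plausible 0.05-0.5 / 3-20 ms
    ranges, clearance rates in the 0.4-1.8 /ms band between the rise and
    decay rate bands (which keeps all three rates attributable), 2 pA
    background noise, a
    holding offset uniform in [-60, -20] pA, and a 10% chance of an
    overlapping second event 1-20 ms into the decay.
    """

    n_traces: int = 50
    amplitude: PseudoVoigtParams = field(default_factory=PseudoVoigtParams)
    amp_range: tuple[float, float] = (10.0, 100.0)
    tau_r_range: tuple[float, float] = (0.05, 0.5)
    tau_d_range: tuple[float, float] = (3.0, 20.0)
    alpha_b_range: tuple[float, float] = (0.4, 1.8)
    sigma: float = 2.0
    sigma_frac: float = 0.0
    offset_range: tuple[float, float] = (-60.0, -20.0)
    drift: float = 0.0
    p_overlap: float = 0.1
    overlap_lag_range: tuple[float, float] = (1.0, 20.0)
    t0: float = 20.0
    grid: TimeGrid = field(default_factory=lambda: TimeGrid(dt=0.05, n=1600))
    ctx: ClampContext = field(default_factory=ClampContext)
    n_experiments: int = 1
    cells_per_experiment: int = 1

    def __post_init__(self) -> None:
        for name in ("tau_r_range", "tau_d_range", "alpha_b_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if self.tau_r_range[1] >= self.tau_d_range[0]:
            raise ValueError("rise range must lie entirely below decay range")


@dataclass(frozen=True)
class SyntheticDataset:
    traces: tuple[RawTrace, ...]
    truth: tuple[TraceTruth, ...]
    seed: int


#: keep sampled kinetics away from the removable singularities alpha_b = 1/tau
_SINGULARITY_MARGIN = 0.05


def _sample_kinetics(spec: DatasetSpec, rng: np.random.Generator) -> GephyrinParams:
    for _ in range(1000):
        tau_r = rng.uniform(*spec.tau_r_range)
        tau_d = rng.uniform(*spec.tau_d_range)
        alpha_b = rng.uniform(*spec.alpha_b_range)
        if (abs(1.0 - alpha_b * tau_d) > _SINGULARITY_MARGIN
                and abs(1.0 - alpha_b * tau_r) > _SINGULARITY_MARGIN):
            return GephyrinParams(tau_r=tau_r, tau_d=tau_d, alpha_b=alpha_b,
                                  t0=spec.t0)
    raise RuntimeError("could not sample kinetics away from singularities")


def generate_trace(truth: GephyrinParams, ctx: ClampContext, noise: NoiseModel,
                   grid: TimeGrid, seed: int | np.random.Generator = 0,
                   overlap_params: GephyrinParams | None = None) -> RawTrace:
    """One synthetic sweep: analytic current + offset + drift + white noise.

    ``overlap_params`` adds a second event with its own parameters (its
    onset time ``t0`` is absolute on the grid).  When it is None and
    ``noise.p_overlap > 0``, the second event is drawn at random: lag
    uniform in (1, 20) ms after the first peak, amplitude 30-100% of the
    first, kinetics from the default plausible ranges.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = grid.times()
    cur = eval_current_analytic(truth, ctx, t)
    if overlap_params is None and noise.p_overlap > 0.0:
        if rng.uniform() < noise.p_overlap:
            overlap_params = _draw_overlap(truth, ctx, DatasetSpec(), rng)
    if overlap_params is not None:
        cur = cur + eval_current_analytic(overlap_params, ctx, t)
    samples = (cur + noise.offset + noise.drift * t
               + rng.normal(0.0, noise.sigma, size=t.size))
    return RawTrace(samples=samples, dt=grid.dt)


def _draw_overlap(first: GephyrinParams, ctx: ClampContext, spec: DatasetSpec,
                  rng: np.random.Generator) -> GephyrinParams:
    lag = rng.uniform(*spec.overlap_lag_range)
    second = _sample_kinetics(spec, rng)
    second = replace(second, t0=first.t0 + peak_time(first) + lag)
    frac = rng.uniform(0.3, 1.0)
    return calibrate_c1(second, ctx, frac * analytic_peak(first, ctx))


def generate_dataset(spec: DatasetSpec, seed: int = 0) -> SyntheticDataset:
    """Generate ``spec.n_traces`` sweeps with a full ground-truth manifest."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(spec.n_traces)
    traces: list[RawTrace] = []
    truths: list[TraceTruth] = []
    n_cells = spec.n_experiments * spec.cells_per_experiment
    per_cell = max(1, -(-spec.n_traces // n_cells)) if n_cells else 1
    for i in range(spec.n_traces):
        rng = np.random.default_rng(children[i])
        params = _sample_kinetics(spec, rng)
        target = float(sample_peaks(1, spec.amplitude, spec.amp_range, rng)[0])
        params = calibrate_c1(params, spec.ctx, target)
        offset = rng.uniform(*spec.offset_range)
        # sigma_frac scales the noise to each trace's target peak amplitude
        sigma = spec.sigma_frac * target if spec.sigma_frac > 0 else spec.sigma
        noise = NoiseModel(sigma=sigma, offset=offset, drift=spec.drift,
                           p_overlap=spec.p_overlap)
        overlap_params = None
        if rng.uniform() < spec.p_overlap:
            overlap_params = _draw_overlap(params, spec.ctx, spec, rng)
        # the overlap decision is materialized here, so the trace generator
        # must not draw a second one of its own
        trace = generate_trace(params, spec.ctx,
                               replace(noise, p_overlap=0.0), spec.grid, rng,
                               overlap_params=overlap_params)
        cell_idx = i // per_cell
        exp_idx = cell_idx // spec.cells_per_experiment
        exp = f"exp{chr(ord('A') + exp_idx % 26)}"
        cell = f"{exp}-c{cell_idx % spec.cells_per_experiment}"
        tid = f"trace_{i:04d}"
        trace = replace(trace, meta=TraceMeta(
            trace_id=tid, experiment=exp, cell=cell, holding_mv=spec.ctx.v))
        traces.append(trace)
        truths.append(TraceTruth(
            trace_id=tid, params=params, ctx=spec.ctx, noise=noise,
            peak=target, experiment=exp, cell=cell,
            overlap=overlap_params is not None,
            overlap_lag=(overlap_params.t0 - params.t0 - peak_time(params)
                         if overlap_params is not None else 0.0),
            overlap_params=overlap_params,
        ))
    return SyntheticDataset(traces=tuple(traces), truth=tuple(truths), seed=seed)


def truth_frame(dataset: SyntheticDataset) -> pd.DataFrame:
    rows = []
    for tr in dataset.truth:
        p = tr.params
        rows.append({
            "trace": tr.trace_id, "experiment": tr.experiment, "cell": tr.cell,
            "peak_pA": tr.peak, "w": p.w, "tau_r": p.tau_r, "tau_d": p.tau_d,
            "beta": p.beta, "alpha_f": p.alpha_f, "alpha_b": p.alpha_b,
            "geph": p.geph, "phi": p.phi, "h": p.h, "h1": p.h1, "c1": p.c1,
            "t0": p.t0, "i_fact": steady_states(p).i_fact,
            "sigma": tr.noise.sigma, "offset": tr.noise.offset,
            "overlap": tr.overlap,
        })
    return pd.DataFrame(rows)


def write_dataset(dataset: SyntheticDataset, outdir: str) -> None:
    """Write per-trace CSVs (the format the preprocessing reader consumes)
    plus a ground-truth manifest TSV."""
    os.makedirs(outdir, exist_ok=True)
    for trace in dataset.traces:
        write_trace_csv(trace, os.path.join(outdir, f"{trace.meta.trace_id}.csv"))
    truth_frame(dataset).to_csv(os.path.join(outdir, "truth.tsv"),
                                sep="\t", index=False)
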