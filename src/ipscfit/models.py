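"""Kinetic models of the inhibitory synaptic current.

The central model is a minimal transsynaptic signaling scheme for a
GABAergic synapse in which the postsynaptic scaffold protein gephyrin
(GEPH) clusters receptors and, through the neuroligin-2/neurexin adhesion
pair (NLG2/NRXN), feeds back on presynaptic drive.  The state variables
are the neurotransmitter level in the cleft ``N``, the adhesion-pair level
``NLG2`` and the postsynaptic receptor level ``Ry``:

    dN/dt    = beta * alpha_f * g(t) * NLG2 - alpha_b * N
    dNLG2/dt = Nlmax * F(GEPH) / (1 + Nhalf / NLG2) - phi * NLG2
    dRy/dt   = h * GEPH - h1 * Ry

with ``g(t) = w * (exp(-t/tau_d) - exp(-t/tau_r))`` the basic conductance
waveform and the recorded current ``I = c1 * N * Ry * (v - e_rev)``.
GEPH is held constant during a single event, ``F(GEPH) = 1``, and with
``Nlmax = GEPH`` and ``Nhalf = GEPH / 2`` the NLG2 and Ry equations have the
steady states

    NLG2_ss = GEPH * (2 - phi) / (2 * phi),    Ry_ss = (h / h1) * GEPH.

Holding NLG2 and Ry at steady state, the N equation is linear and driven
by the double exponential, so the current has a closed form::

    I(t') = I_FACT * [(tau_d - tau_r) * exp(-alpha_b*t')
                      - tau_d*(1 - alpha_b*tau_r) * exp(-t'/tau_d)
                      + tau_r*(1 - alpha_b*tau_d) * exp(-t'/tau_r)]
            / [(1 - alpha_b*tau_d) * (1 - alpha_b*tau_r)] * (v - e_rev)

for t' = t - t0 >= 0 (zero before onset), where the time-independent
amplitude factor is

    I_FACT = c1 * (h/h1) * GEPH^2 * (2 - phi) / (2*phi) * beta * alpha_f * w.

Only the combination (I_FACT, alpha_b, tau_r, tau_d, t0) is identifiable
from a recorded current: the amplitude factor lumps every other parameter.
The amplitude is quadratic in GEPH and hyperbolic in phi, which is what
makes the scaffold level the dominant lever on the synaptic response.

A peak-normalized bi-exponential conductance model is included as the
conventional alternative kinetic scheme.

Rates and levels other than the time constants are in arbitrary units per
ms; ``c1`` carries the scaling to pA; potentials are in mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ClampContext",
    "GephyrinParams",
    "DerivedSynapse",
    "BiexpParams",
    "TimeGrid",
    "ParameterDomainError",
    "ExcludedParameterError",
    "SingularParameterError",
    "NumericError",
    "GUARD_EPS",
    "eval_g",
    "steady_states",
    "current_shape",
    "eval_current_analytic",
    "integrate_ode",
    "eval_biexp_current",
    "biexp_peak_time",
    "peak_time",
    "nernst_potential",
    "chloride_concentration",
    "PIPETTE_SOLUTION_MM",
    "ACSF_SOLUTION_MM",
]


class ParameterDomainError(ValueError):
    """A parameter vector violates the model's domain (positivity, ordering)."""


class ExcludedParameterError(ParameterDomainError):
    """Parameters land in an excluded region (e.g. phi >= 2 makes NLG2_ss <= 0)."""


class SingularParameterError(ParameterDomainError):
    """Parameters sit on a removable singularity of the closed-form current."""


class NumericError(RuntimeError):
    """Numerical integration failed."""


#: half-width of the guard band around the removable singularities
#: alpha_b = 1/tau_r and alpha_b = 1/tau_d of the closed-form current
GUARD_EPS = 1e-6


@dataclass(frozen=True)
class ClampContext:
    """Voltage-clamp context: holding potential and synaptic reversal potential (mV)."""

    v: float = -70.0
    erev: float = -16.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v) and math.isfinite(self.erev)):
            raise ParameterDomainError("holding and reversal potentials must be finite")
        if self.v == self.erev:
            raise ParameterDomainError("zero driving force: v == erev")

    @property
    def driving_force(self) -> float:
        return self.v - self.erev


@dataclass(frozen=True)
class GephyrinParams:
    """Free parameters of the gephyrin transsynaptic kinetic scheme.

    ``w`` peak synaptic conductance; ``tau_r``/``tau_d`` rise and decay time
    constants (ms); ``beta``/``alpha_f`` forward neurotransmitter-drive rates;
    ``alpha_b`` neurotransmitter clearance rate (1/ms); ``geph`` gephyrin
    cluster level; ``phi`` NLG2/NRXN turnover rate; ``h``/``h1`` receptor
    insertion/removal rates; ``c1`` current scale (to pA); ``t0`` onset (ms).
    """

    w: float = 1.0
    tau_r: float = 0.2
    tau_d: float = 8.0
    beta: float = 1.0
    alpha_f: float = 1.0
    alpha_b: float = 1.0
    geph: float = 1.0
    phi: float = 1.0
    h: float = 1.0
    h1: float = 1.0
    c1: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("w", "tau_r", "tau_d", "beta", "alpha_f", "alpha_b",
                     "geph", "phi", "h", "h1", "c1"):
            val = getattr(self, name)
            if not math.isfinite(val) or val <= 0.0:
                raise ParameterDomainError(f"{name} must be finite and > 0, got {val!r}")
        if not math.isfinite(self.t0) or self.t0 < 0.0:
            raise ParameterDomainError(f"t0 must be finite and >= 0, got {self.t0!r}")
        if self.tau_r >= self.tau_d:
            raise ParameterDomainError(
                f"rise must be faster than decay: tau_r={self.tau_r} >= tau_d={self.tau_d}"
            )

    def check_singularity(self, eps: float = GUARD_EPS) -> None:
        """Reject parameter vectors inside the removable-singularity guard band."""
        for tau in (self.tau_r, self.tau_d):
            if abs(1.0 - self.alpha_b * tau) < eps:
                raise SingularParameterError(
                    f"alpha_b={self.alpha_b} within {eps} of 1/tau={1.0 / tau}"
                )


@dataclass(frozen=True)
class DerivedSynapse:
    """Steady-state levels and the lumped amplitude factor of the current."""

    nlmax: float
    nhalf: float
    nlg2_ss: float
    ry_ss: float
    i_fact: float


@dataclass(frozen=True)
class BiexpParams:
    """Peak-normalized bi-exponential conductance: the conventional alternative model."""

    tau1: float = 1.6
    tau2: float = 7.7
    t_start: float = 0.2
    weight: float = 1.2e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.tau1 < self.tau2):
            raise ParameterDomainError(
                f"need 0 < tau1 < tau2, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.weight <= 0.0:
            raise ParameterDomainError(f"weight must be > 0, got {self.weight!r}")
        if self.t_start < 0.0:
            raise ParameterDomainError(f"t_start must be >= 0, got {self.t_start!r}")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid: interval ``dt`` (ms), ``n`` samples, first-sample time."""

    dt: float
    n: int
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ParameterDomainError(f"dt must be > 0, got {self.dt!r}")
        if self.n < 2:
            raise ParameterDomainError(f"need at least 2 samples, got {self.n!r}")

    def times(self) -> np.ndarray:
        return self.origin + self.dt * np.arange(self.n)


def eval_g(params: GephyrinParams, t: np.ndarray) -> np.ndarray:
    """Conductance waveform g(t) = w*(exp(-t'/tau_d) - exp(-t'/tau_r)), t' = t - t0."""
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t - params.t0, 0.0)
    g = params.w * (np.exp(-tp / params.tau_d) - np.exp(-tp / params.tau_r))
    return np.where(t >= params.t0, g, 0.0)


def steady_states(params: GephyrinParams) -> DerivedSynapse:
    """Steady-state NLG2 and Ry levels and the amplitude factor I_FACT.

    Raises :class:`ExcludedParameterError` when ``phi >= 2``, where the NLG2
    steady state is non-positive (the excluded region the configuration-file
    exclusion rule ``geph < nhalf*phi`` encodes).
    """
    if params.phi >= 2.0:
        raise ExcludedParameterError(
            f"phi={params.phi} >= 2 gives non-positive steady-state NLG2"
        )
    nlg2_ss = params.geph * (2.0 - params.phi) / (2.0 * params.phi)
    ry_ss = params.h / params.h1 * params.geph
    i_fact = (
        params.c1 * ry_ss * nlg2_ss * params.beta * params.alpha_f * params.w
    )
    return DerivedSynapse(
        nlmax=params.geph,
        nhalf=params.geph / 2.0,
        nlg2_ss=nlg2_ss,
        ry_ss=ry_ss,
        i_fact=i_fact,
    )


def current_shape(alpha_b: float, tau_r: float, tau_d: float,
                  tp: np.ndarray) -> np.ndarray:
    """Amplitude-free time course of the current for t' >= 0.

    This is the exact response of the linear neurotransmitter equation,
    started at N(0) = 0 and driven by the unit double exponential with NLG2
    and Ry held at steady state; the full current is
    ``I_FACT * current_shape * (v - erev)``.  It has units of ms (a filtered
    integral of the dimensionless waveform) and is non-negative.
    """
    tp = np.asarray(tp, dtype=float)
    a = 1.0 - alpha_b * tau_d
    b = 1.0 - alpha_b * tau_r
    num = (
        (tau_d - tau_r) * np.exp(-alpha_b * tp)
        - tau_d * b * np.exp(-tp / tau_d)
        + tau_r * a * np.exp(-tp / tau_r)
    )
    return num / (a * b)


def eval_current_analytic(params: GephyrinParams, ctx: ClampContext,
                          t: np.ndarray) -> np.ndarray:
    """Closed-form synaptic current (pA) on the time grid ``t`` (ms).

    Zero before onset ``t0``; thereafter ``I_FACT * shape(t - t0) * (v - erev)``.
    With v < erev the driving force is negative and the current inward
    (negative); the event magnitude is |I|.
    """
    params.check_singularity()
    der = steady_states(params)
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t - params.t0, 0.0)
    shape = current_shape(params.alpha_b, params.tau_r, params.tau_d, tp)
    cur = der.i_fact * shape * ctx.driving_force
    return np.where(t >= params.t0, cur, 0.0)


def integrate_ode(params: GephyrinParams, ctx: ClampContext, grid: TimeGrid,
                  rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
    """Numerically integrated current on ``grid``; oracle for the closed form.

    Integrates the full three-variable system with NLG2 and Ry initialized at
    their steady states and N(0) = 0, so NLG2 and Ry remain at their fixed
    points and the current must agree with :func:`eval_current_analytic`.
    """
    der = steady_states(params)
    t = grid.times()
    t0 = params.t0
    ba = params.beta * params.alpha_f

    def rhs(time: float, y: np.ndarray) -> list[float]:
        n, nlg2, ry = y
        g = 0.0
        if time >= t0:
            tp = time - t0
            g = params.w * (math.exp(-tp / params.tau_d) - math.exp(-tp / params.tau_r))
        dn = ba * g * nlg2 - params.alpha_b * n
        # Michaelis-Menten production with Nlmax = GEPH, Nhalf = GEPH/2, F(GEPH) = 1
        dnlg2 = der.nlmax / (1.0 + der.nhalf / nlg2) - params.phi * nlg2
        dry = params.h * params.geph - params.h1 * ry
        return [dn, dnlg2, dry]

    y0 = [0.0, der.nlg2_ss, der.ry_ss]
    sol = solve_ivp(
        rhs, (float(t[0]), float(t[-1])), y0, t_eval=t,
        method="LSODA", rtol=rtol, atol=atol, max_step=max(params.tau_r / 4.0, grid.dt),
    )
    if not sol.success:
        raise NumericError(f"ODE integration failed: {sol.message}")
    n, _, ry = sol.y
    return params.c1 * n * ry * ctx.driving_force


def biexp_peak_time(tau1: float, tau2: float) -> float:
    """Time from onset to the conductance peak of the bi-exponential waveform."""
    return math.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1)


def eval_biexp_current(params: BiexpParams, ctx: ClampContext,
                       t: np.ndarray) -> np.ndarray:
    """Current (pA) of the peak-normalized bi-exponential conductance model.

    The normalization factor is chosen so the conductance peak equals
    ``weight`` (the common built-in convention for this scheme).
    """
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t - params.t_start, 0.0)
    tstar = biexp_peak_time(params.tau1, params.tau2)
    factor = 1.0 / (math.exp(-tstar / params.tau2) - math.exp(-tstar / params.tau1))
    g = factor * params.weight * (np.exp(-tp / params.tau2) - np.exp(-tp / params.tau1))
    cur = g * ctx.driving_force
    return np.where(t >= params.t_start, cur, 0.0)


def peak_time(params: GephyrinParams) -> float:
    """Time from onset to the peak of |I|, by bracketed root-finding on dI/dt.

    Depends only on the shape parameters (alpha_b, tau_r, tau_d); invariant to
    any rescaling of the amplitude factor.
    """
    params.check_singularity()
    ab, tr, td = params.alpha_b, params.tau_r, params.tau_d

    def dshape(tp: float) -> float:
        # d/dt of current_shape numerator (the 1/(a*b) factor does not move the root,
        # but it does carry the sign, so divide it back in)
        a = 1.0 - ab * td
        b = 1.0 - ab * tr
        num = (
            -ab * (td - tr) * math.exp(-ab * tp)
            + b * math.exp(-tp / td)
            - a * math.exp(-tp / tr)
        )
        return num / (a * b)

    # dI/dt(0) = 0 because the drive vanishes at onset; bracket strictly inside
    lo = 1e-9 * tr
    hi = tr
    limit = 200.0 * (td + 1.0 / ab)
    while dshape(hi) > 0.0:
        hi *= 2.0
        if hi > limit:  # pragma: no cover - valid params always peak
            raise NumericError("failed to bracket the current peak")
    if dshape(lo) <= 0.0:  # pragma: no cover - shape rises from onset
        raise NumericError("shape not rising at onset")
    return float(brentq(dshape, lo, hi, xtol=1e-12, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# Reversal potential

GAS_CONSTANT = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212331001  # C / mol

#: chloride ions contributed per formula unit of the salts used in the
#: recording solutions
_CL_PER_SALT = {
    "NaCl": 1, "KCl": 1, "MgCl2": 2, "CaCl2": 2, "CholineCl": 1,
}

#: chloride-bearing salts of the pipette (intracellular) solution, mM
PIPETTE_SOLUTION_MM = {"KCl": 70.0, "MgCl2": 1.0}
#: chloride-bearing salts of the bath ACSF, mM
ACSF_SOLUTION_MM = {"NaCl": 126.0, "KCl": 2.5, "CaCl2": 2.0}


def chloride_concentration(salts_mm: dict[str, float]) -> float:
    """Total chloride concentration (mM) contributed by a salt composition."""
    total = 0.0
    for salt, conc in salts_mm.items():
        try:
            stoich = _CL_PER_SALT[salt]
        except KeyError:
            raise ValueError(f"unknown chloride stoichiometry for salt {salt!r}") from None
        total += stoich * conc
    return total


def nernst_potential(conc_out_mm: float, conc_in_mm: float,
                     temperature_c: float = 32.0, charge: int = -1) -> float:
    """Nernst equilibrium potential (mV) for an ion of the given charge.

    E = (R*T)/(z*F) * ln([out]/[in]), in mV.  For chloride (z = -1) with the
    pipette and bath compositions used for sIPSC recordings this evaluates to
    about -16 mV.
    """
    if conc_out_mm <= 0.0 or conc_in_mm <= 0.0:
        raise ValueError("concentrations must be > 0")
    if charge == 0:
        raise ValueError("charge must be nonzero")
    t_kelvin = temperature_c + 273.15
    return (
        1000.0 * GAS_CONSTANT * t_kelvin / (charge * FARADAY)
        * math.log(conc_out_mm / conc_in_mm)
    )
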