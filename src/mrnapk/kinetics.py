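"""Mechanistic cross-species model of mRNA-LNP-encoded antibody kinetics.

The model has three processes:

1. mRNA-LNP elimination — the dose enters an mRNA-LNP amount M (µg) that is
   cleared first-order:  dM/dt = input(t) − k_elim·M.
2. Translation — circulating antibody is produced first-order per unit of
   remaining mRNA-LNP without consuming it:  production = k_translate·M.
3. Antibody disposition — a standard 2-compartment model (central amount A1,
   peripheral A2, clearance CL, volumes V1/V2, intercompartmental clearance
   Q) with first-order elimination from the central compartment; a
   1-compartment variant drops A2/Q entirely.

Every structural parameter is a power law of body weight W (kg):
``effective = base·W^α`` — the base value is the parameter of a 1 kg
reference animal.  Observed concentration is A1/(V1·W^α_V1) in µg/mL.

The system is linear with piecewise-constant input, so the default
propagator advances the state exactly with matrix exponentials between dose
events; an adaptive LSODA route (``method="ivp"``) and an independent
eigendecomposition closed form for single boluses are provided as
cross-checks of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, linalg

from .data import DoseEvent
from .errors import ConfigurationError, DegenerateSystemError, ValidationError

__all__ = [
    "TranslationalParams",
    "EffectiveParams",
    "ScalingConfig",
    "SimulatedProfile",
    "scale_params",
    "simulate",
    "simulate_population",
    "closed_form_dauc",
    "closed_form_profile",
    "project_params_cross_species",
]

#: Structural parameter names, in canonical order.
STRUCTURAL = ("k_elim_mrna", "k_translate", "cl_ab", "v1", "v2", "q_ab")


@dataclass(frozen=True)
class TranslationalParams:
    """Structural parameters (1 kg reference values) with allometric exponents.

    Units at W = 1 kg: rates 1/h, clearances mL/h, volumes mL.  ``v2`` and
    ``q_ab`` must be both present (2-compartment disposition) or both absent.
    ``omega`` holds log-normal between-subject SDs per parameter name and
    ``sigma_prop`` the proportional residual error SD; both are used by the
    synthetic-data generator and population simulation, not by the
    structural equations.
    """

    k_elim_mrna: float
    alpha_k_elim: float
    k_translate: float
    alpha_k_translate: float
    cl_ab: float
    alpha_cl: float
    v1: float
    alpha_v1: float
    v2: float | None = None
    alpha_v2: float | None = None
    q_ab: float | None = None
    alpha_q: float | None = None
    omega: Mapping[str, float] = field(default_factory=dict)
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_elim_mrna", "k_translate", "cl_ab", "v1"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if (self.v2 is None) != (self.q_ab is None):
            raise ValidationError("v2 and q_ab must both be present or both absent")
        if self.v2 is not None and (self.v2 <= 0 or self.q_ab <= 0):
            raise ValidationError("v2 and q_ab must be > 0 when present")
        if any(v < 0 for v in self.omega.values()) or self.sigma_prop < 0:
            raise ValidationError("omega and sigma_prop must be >= 0")

    @property
    def n_compartments(self) -> int:
        return 2 if self.v2 is not None else 1

    def with_multipliers(self, mult: Mapping[str, float]) -> "TranslationalParams":
        """Multiply structural base values (e.g. by exp(η) IIV draws)."""
        changes = {}
        for name, m in mult.items():
            if name not in STRUCTURAL:
                raise ValidationError(f"unknown structural parameter {name!r}")
            cur = getattr(self, name)
            if cur is not None:
                changes[name] = cur * m
        return replace(self, **changes)

    def structural_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in STRUCTURAL if getattr(self, n) is not None}


@dataclass(frozen=True)
class EffectiveParams:
    """Parameter values for one animal of weight ``w`` (after W^α scaling)."""

    w: float
    k_elim: float
    k_translate: float
    cl: float
    v1: float
    v2: float | None = None
    q: float | None = None

    @property
    def n_compartments(self) -> int:
        return 2 if self.v2 is not None else 1


def scale_params(p: TranslationalParams, w: float) -> EffectiveParams:
    """Apply the allometric factors: effective = base·w^α for every parameter."""
    if not w > 0:
        raise ValidationError(f"body weight must be > 0, got {w}")
    two = p.n_compartments == 2
    return EffectiveParams(
        w=w,
        k_elim=p.k_elim_mrna * w**p.alpha_k_elim,
        k_translate=p.k_translate * w**p.alpha_k_translate,
        cl=p.cl_ab * w**p.alpha_cl,
        v1=p.v1 * w**p.alpha_v1,
        v2=p.v2 * w**p.alpha_v2 if two else None,
        q=p.q_ab * w**p.alpha_q if two else None,
    )


def _system_matrix(e: EffectiveParams) -> np.ndarray:
    """State matrix for x = [M, A1(, A2)] (amounts, µg)."""
    ke, kt = e.k_elim, e.k_translate
    if e.n_compartments == 2:
        return np.array(
            [
                [-ke, 0.0, 0.0],
                [kt, -(e.cl + e.q) / e.v1, e.q / e.v2],
                [0.0, e.q / e.v1, -e.q / e.v2],
            ]
        )
    return np.array([[-ke, 0.0], [kt, -e.cl / e.v1]])


@dataclass(frozen=True)
class SimulatedProfile:
    """Concentration-time output of one simulation."""

    times: np.ndarray  # h
    concentration: np.ndarray  # µg/mL, = A1/V1_eff
    states: np.ndarray  # (n_times, n_states) amounts µg
    regimen: tuple[DoseEvent, ...]
    body_weight: float

    @property
    def total_dose(self) -> float:
        return float(sum(d.amount for d in self.regimen))

    def dcmax(self) -> float:
        """Max simulated concentration / total administered dose (1/mL)."""
        return float(np.max(self.concentration)) / self.total_dose

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "concentration": self.concentration})


def _dose_breaks(regimen: Sequence[DoseEvent]):
    """Bolus jumps and piecewise-constant infusion-rate change points."""
    boluses: dict[float, float] = {}
    rate_changes: dict[float, float] = {}
    for d in regimen:
        if d.duration == 0:
            boluses[d.time] = boluses.get(d.time, 0.0) + d.amount
        else:
            r = d.amount / d.duration
            rate_changes[d.time] = rate_changes.get(d.time, 0.0) + r
            end = d.time + d.duration
            rate_changes[end] = rate_changes.get(end, 0.0) - r
    return boluses, rate_changes


def simulate(
    p: TranslationalParams,
    w: float,
    regimen: Sequence[DoseEvent],
    times: Sequence[float],
    method: str = "expm",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulatedProfile:
    """Simulate the model under an arbitrary bolus/infusion regimen.

    ``times`` must be sorted and non-negative.  The state is restarted at
    every dose event so discontinuities are never stepped over; infusions
    are zero-order inputs into M over their duration, duration 0 is an
    instantaneous bolus.  ``method="expm"`` (default) is the exact
    piecewise matrix-exponential propagator; ``method="ivp"`` integrates
    with adaptive LSODA at the given tolerances.
    """
    t_out = np.asarray(times, dtype=float)
    if np.any(np.diff(t_out) < 0):
        raise ValidationError("output times must be sorted ascending")
    if len(t_out) and t_out[0] < 0:
        raise ValidationError("output times must be >= 0")
    if method not in ("expm", "ivp"):
        raise ValidationError(f"unknown method {method!r}")
    e = scale_params(p, w)
    A = _system_matrix(e)
    nstate = A.shape[0]
    boluses, rate_changes = _dose_breaks(regimen)

    breaks = sorted({0.0, *boluses, *rate_changes, *t_out.tolist()})
    x = np.zeros(nstate)
    rate = 0.0
    out = np.zeros((len(t_out), nstate))
    t_prev = breaks[0]
    # map each requested time to its position(s) in t_out
    from collections import defaultdict

    where = defaultdict(list)
    for i, t in enumerate(t_out):
        where[float(t)].append(i)

    def _advance(x, dt, rate):
        if dt == 0:
            return x
        u = np.zeros(nstate)
        u[0] = rate
        if method == "expm":
            E = linalg.expm(A * dt)
            xn = E @ x
            if rate != 0.0:
                xn = xn + np.linalg.solve(A, (E - np.eye(nstate)) @ u)
            return xn
        sol = integrate.solve_ivp(
            lambda t, y: A @ y + u, (0.0, dt), x, method="LSODA",
            rtol=rtol, atol=atol, t_eval=[dt],
        )
        if not sol.success:
            raise DegenerateSystemError(
                f"ODE solver failed: {sol.message}; state={x}, dt={dt}"
            )
        return sol.y[:, -1]

    for t in breaks:
        x = _advance(x, t - t_prev, rate)
        t_prev = t
        if t in boluses:
            x = x.copy()
            x[0] += boluses[t]
        if t in rate_changes:
            rate += rate_changes[t]
        for i in where.get(t, ()):
            out[i] = x

    conc = out[:, 1] / e.v1
    return SimulatedProfile(
        times=t_out, concentration=conc, states=out,
        regimen=tuple(regimen), body_weight=w,
    )


def closed_form_profile(
    p: TranslationalParams,
    w: float,
    bolus_amount: float,
    times: Sequence[float] | None = None,
):
    """Exact multi-exponential solution for a single bolus into M at t=0.

    Returns a vectorized ``conc(t)`` callable, or the evaluated array when
    ``times`` is given.  Built from the eigendecomposition of the
    disposition block with a particular solution ∝ e^(−k_elim·t); refuses
    (``DegenerateSystemError``) when system eigenvalues are closer than a
    relative gap of 1e-8, in which case callers fall back to ``simulate``.
    """
    if bolus_amount < 0:
        raise ValidationError("bolus_amount must be >= 0")
    e = scale_params(p, w)
    if e.n_compartments == 2:
        K = np.array(
            [[-(e.cl + e.q) / e.v1, e.q / e.v2], [e.q / e.v1, -e.q / e.v2]]
        )
    else:
        K = np.array([[-e.cl / e.v1]])
    lam, U = np.linalg.eig(K)
    lam = lam.real
    U = U.real
    all_eigs = np.concatenate([lam, [-e.k_elim]])
    scale = np.max(np.abs(all_eigs))
    for i in range(len(all_eigs)):
        for j in range(i + 1, len(all_eigs)):
            if abs(all_eigs[i] - all_eigs[j]) < 1e-8 * scale:
                raise DegenerateSystemError(
                    f"eigenvalues too close: {all_eigs[i]} vs {all_eigs[j]}"
                )
    b = np.zeros(K.shape[0])
    b[0] = e.k_translate * bolus_amount
    # particular solution v·e^(−ke·t):  (−ke·I − K)·v = b
    v = np.linalg.solve(-e.k_elim * np.eye(K.shape[0]) - K, b)
    c = np.linalg.solve(U, -v)  # homogeneous coefficients so that A(0) = 0
    row = U[0, :]  # central compartment amount

    def conc(t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        a1 = np.exp(tt[:, None] * lam[None, :]) @ (row * c)
        a1 = a1 + v[0] * np.exp(-e.k_elim * tt)
        a1 = np.where(tt >= 0, a1, 0.0)
        out = a1 / e.v1
        return float(out[0]) if scalar else out

    if times is not None:
        return conc(np.asarray(times, dtype=float))
    return conc


def closed_form_dauc(p: TranslationalParams, w: float) -> float:
    """Dose-normalized AUC_0-inf in h/mL: k_translate_eff/(k_elim_eff·CL_eff).

    Total antibody production per unit dose is ∫k_t·M dt = k_t/k_elim and
    AUC is production/CL; volumes and Q do not enter.
    """
    e = scale_params(p, w)
    return e.k_translate / (e.k_elim * e.cl)


@dataclass(frozen=True)
class ScalingConfig:
    """Projection exponents for single-species cross-species scaling."""

    exponents: Mapping[str, float]
    source_species: str | None = None

    def exponent_for(self, name: str) -> float:
        if name not in self.exponents:
            raise ConfigurationError(f"no projection exponent configured for {name!r}")
        x = self.exponents[name]
        if not math.isfinite(x):
            raise ConfigurationError(f"projection exponent for {name!r} is not finite")
        return x


def project_params_cross_species(
    p_fit: TranslationalParams,
    w_source: float,
    w_target: float,
    scaling: ScalingConfig,
) -> TranslationalParams:
    """Project a single-species fit to another body weight.

    The parameters effective at ``w_source`` are each multiplied by
    ``(w_target/w_source)^exponent`` from ``scaling``.  The result is a
    parameter set whose base values are the target-species effective values
    (all α = 0), ready for :func:`simulate` at ``w_target``.
    """
    if w_source <= 0 or w_target <= 0:
        raise ValidationError("weights must be > 0")
    e = scale_params(p_fit, w_source)
    ratio = w_target / w_source
    eff = {
        "k_elim_mrna": e.k_elim,
        "k_translate": e.k_translate,
        "cl_ab": e.cl,
        "v1": e.v1,
        "v2": e.v2,
        "q_ab": e.q,
    }
    projected = {
        name: val * ratio ** scaling.exponent_for(name)
        for name, val in eff.items()
        if val is not None
    }
    return TranslationalParams(
        k_elim_mrna=projected["k_elim_mrna"],
        alpha_k_elim=0.0,
        k_translate=projected["k_translate"],
        alpha_k_translate=0.0,
        cl_ab=projected["cl_ab"],
        alpha_cl=0.0,
        v1=projected["v1"],
        alpha_v1=0.0,
        v2=projected.get("v2"),
        alpha_v2=0.0 if "v2" in projected else None,
        q_ab=projected.get("q_ab"),
        alpha_q=0.0 if "q_ab" in projected else None,
        omega=dict(p_fit.omega),
        sigma_prop=p_fit.sigma_prop,
    )


def simulate_population(
    p: TranslationalParams,
    w: float,
    regimen: Sequence[DoseEvent],
    times: Sequence[float],
    n_replicates: int = 500,
    seed: int | None = None,
    percentiles: Sequence[float] = (10.0, 50.0, 90.0),
) -> dict:
    """Monte-Carlo percentile bands over log-normal between-subject variability.

    Each replicate multiplies the structural base values by exp(η),
    η ~ N(0, ω²) per parameter named in ``p.omega``; residual error is not
    added.  Returns times, the percentile matrix and the typical profile.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    typical = simulate(p, w, regimen, t)
    if not p.omega or all(v == 0 for v in p.omega.values()):
        bands = np.tile(typical.concentration, (len(percentiles), 1))
        return dict(times=t, percentiles=np.asarray(percentiles), bands=bands,
                    typical=typical.concentration)
    sims = np.empty((n_replicates, len(t)))
    for i in range(n_replicates):
        mult = {
            name: float(np.exp(rng.normal(0.0, sd))) for name, sd in p.omega.items()
        }
        sims[i] = simulate(p.with_multipliers(mult), w, regimen, t).concentration
    bands = np.percentile(sims, percentiles, axis=0)
    return dict(times=t, percentiles=np.asarray(percentiles), bands=bands,
                typical=typical.concentration)
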