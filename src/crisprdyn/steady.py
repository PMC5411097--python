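"""Analytic steady states, coexistence theory and regime classification.

At a coexistence fixed point the bacteria stop short of carrying capacity; the
shortfall is summarized by the fraction of unused capacity ``F = 1 - n/K``.
For equal growth rates the closed form is

    F = (kappa/f) * (b(1-alpha) - 1) / ((b-1)(1 - b*eta))

with the spacer/wild-type ratio n1/n0 = (b(1-alpha)-1)/(1-b*eta).  Coexistence
requires spacer loss (kappa > 0) and a failure probability below a critical
value eta_c ~ 1/b; above it CRISPR cannot stop viral growth.

With N spacer types the same form holds with eta replaced by the abundance-
weighted mean failure probability eta_bar, which itself depends on the steady
spacer distribution:

    g v = b f F
    n_i/n0 = alpha_i * b f F / (kappa - f F (1 - eta_i b))
    sum_i n_i/n0 = (b(1-alpha) - 1)/(1 - b*eta_bar)

making the solution an implicit (self-consistent) equation in eta_bar, solved
here by bracketed 1-d root finding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import optimize

from .model import (
    MultiSpacerParams,
    MultiState,
    SingleSpacerParams,
    SingleState,
    multi_rhs_array,
    single_rhs_array,
)

__all__ = [
    "RegimeLabel",
    "CoexistenceSolution",
    "SteadyStateError",
    "unused_capacity_single",
    "critical_failure_probability",
    "spacer_ratio_single",
    "unused_capacity_multi",
    "mean_failure_probability",
    "solve_coexistence_multi",
    "coexistence_state_single",
    "steady_state_numeric",
    "classify_regime",
]


class SteadyStateError(RuntimeError):
    """Raised when a steady-state computation is invalid or fails to converge."""


class RegimeLabel(str, Enum):
    """Asymptotic outcome of the dynamics."""

    coexistence = "coexistence"
    phage_extinction = "phage_extinction"
    bacterial_extinction = "bacterial_extinction"


def _no_extensions(p, what: str) -> None:
    if p.dilution != 0.0 or p.phage_decay != 0.0:
        raise SteadyStateError(
            f"{what} assumes no dilution and no phage decay; "
            "use steady_state_numeric for the extended system"
        )


def unused_capacity_single(params: SingleSpacerParams) -> float:
    """Fraction of unused capacity F at the single-spacer coexistence state.

    Valid only for equal growth rates (r = 1) and an effective spacer
    (b*eta < 1).  The caller must check F < 1 for a physical coexistence
    state; F >= 1 means the bacteria cannot sustain the phage pressure.
    """
    p = params
    _no_extensions(p, "the closed-form F")
    if p.r != 1.0:
        raise SteadyStateError(
            "closed-form F requires equal growth rates (r = 1); "
            "use steady_state_numeric for r != 1"
        )
    denom = 1.0 - p.b * p.eta
    if denom <= 0.0:
        raise SteadyStateError(
            f"b*eta = {p.b * p.eta:g} >= 1: CRISPR immunity cannot stop viral "
            "growth and no coexistence state exists"
        )
    return (p.kappa / p.f0) * (p.b * (1.0 - p.alpha) - 1.0) / ((p.b - 1.0) * denom)


def critical_failure_probability(params: SingleSpacerParams) -> float:
    """Critical failure probability eta_c below which coexistence is possible.

    eta_c = (1/b) * (1 - (kappa/f0) * (b(1-alpha)-1)/(b-1)).  The correction
    of order (r-1)/b^2 for unequal growth rates is dropped.
    """
    p = params
    if p.b <= 1.0:
        raise SteadyStateError("critical failure probability requires b > 1")
    return (1.0 / p.b) * (
        1.0 - (p.kappa / p.f0) * (p.b * (1.0 - p.alpha) - 1.0) / (p.b - 1.0)
    )


def spacer_ratio_single(params: SingleSpacerParams) -> float:
    """Steady-state ratio n1/n0 of spacer-enhanced to wild-type bacteria.

    Equal to (b(1-alpha)-1)/(1-b*eta); independent of the growth rates, so it
    can be used to infer spacer effectiveness from population ratios.
    """
    p = params
    denom = 1.0 - p.b * p.eta
    if denom <= 0.0:
        raise SteadyStateError(
            f"b*eta = {p.b * p.eta:g} >= 1: spacer ratio undefined (no coexistence)"
        )
    return (p.b * (1.0 - p.alpha) - 1.0) / denom


def unused_capacity_multi(eta_bar: float, params: MultiSpacerParams) -> float:
    """F for the N-spacer model at a given mean failure probability eta_bar."""
    p = params
    _no_extensions(p, "the closed-form F")
    denom = 1.0 - p.b * eta_bar
    if denom <= 0.0:
        raise SteadyStateError(
            f"b*eta_bar = {p.b * eta_bar:g} >= 1: no coexistence state exists"
        )
    return (p.kappa / p.f) * (p.b * (1.0 - p.alpha_total) - 1.0) / (denom * (p.b - 1.0))


def mean_failure_probability(n_vec: np.ndarray, eta_vec: np.ndarray) -> float:
    """Abundance-weighted mean failure probability sum(eta_i n_i)/sum(n_i)."""
    n_vec = np.asarray(n_vec, dtype=float)
    eta_vec = np.asarray(eta_vec, dtype=float)
    if n_vec.shape != eta_vec.shape:
        raise ValueError("n_vec and eta_vec must have equal length")
    if np.any(n_vec < 0):
        raise ValueError("n_vec must be non-negative")
    total = n_vec.sum()
    if total <= 0.0:
        raise ValueError("mean failure probability undefined: sum(n_vec) must be positive")
    return float(np.dot(eta_vec, n_vec) / total)


@dataclass(frozen=True)
class CoexistenceSolution:
    """Assembled analytic coexistence fixed point of the N-spacer model.

    ``valid`` is False when the positivity conditions fail (some ratio
    denominator non-positive, or F outside (0, 1)); the numeric fields are
    still populated where they are defined so callers can inspect why.
    """

    F: float
    eta_bar: float
    v_star: float
    n0_star: float
    n_vec_star: np.ndarray
    I0_star: float
    I_vec_star: np.ndarray
    n_total: float
    valid: bool
    residual_norm: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def state(self) -> MultiState:
        return MultiState(
            n0=self.n0_star,
            n_vec=self.n_vec_star,
            I0=self.I0_star,
            I_vec=self.I_vec_star,
            v=self.v_star,
        )

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "eta_bar": self.eta_bar,
            "v_star": self.v_star,
            "n0_star": self.n0_star,
            "n_vec_star": [float(x) for x in np.atleast_1d(self.n_vec_star)],
            "I0_star": self.I0_star,
            "I_vec_star": [float(x) for x in np.atleast_1d(self.I_vec_star)],
            "n_total": self.n_total,
            "valid": self.valid,
            "residual_norm": self.residual_norm,
        }


def _ratio_vec(eta_bar: float, p: MultiSpacerParams) -> np.ndarray:
    """Per-spacer abundance ratios n_i/n0 at a trial eta_bar."""
    fF = p.f * unused_capacity_multi(eta_bar, p)
    denom = p.kappa - fF * (1.0 - p.eta_vec * p.b)
    return p.alpha_vec * p.b * fF / denom


def _eta_bar_residual(eta_bar: float, p: MultiSpacerParams) -> float:
    rho = _ratio_vec(eta_bar, p)
    return eta_bar - float(np.dot(p.eta_vec, rho) / rho.sum())


def _assemble(eta_bar: float, p: MultiSpacerParams) -> CoexistenceSolution:
    F = unused_capacity_multi(eta_bar, p)
    fF = p.f * F
    denom = p.kappa - fF * (1.0 - p.eta_vec * p.b)
    rho = p.alpha_vec * p.b * fF / denom
    v = p.b * p.f * F / p.g
    # I0 = g v n0 / mu and I_i = eta_i g v n_i / mu from stationarity of the
    # infected equations; the absolute scale comes from n_total = K(1-F).
    gv_mu = p.g * v / p.mu
    n0 = p.K * (1.0 - F) / (1.0 + rho.sum() + gv_mu * (1.0 + float(np.dot(p.eta_vec, rho))))
    n_vec = rho * n0
    I0 = gv_mu * n0
    I_vec = p.eta_vec * gv_mu * n_vec
    state = MultiState(n0=n0, n_vec=n_vec, I0=I0, I_vec=I_vec, v=v)
    residual = float(np.linalg.norm(multi_rhs_array(state.to_array(), p)))
    valid = bool(np.all(denom > 0) and 0.0 < F < 1.0 and np.all(n_vec >= 0) and n0 > 0)
    # third closed-form relation: sum_i n_i/n0 = (b(1-alpha)-1)/(1-b*eta_bar)
    ratio_sum_closed = (p.b * (1.0 - p.alpha_total) - 1.0) / (1.0 - p.b * eta_bar)
    return CoexistenceSolution(
        F=F,
        eta_bar=eta_bar,
        v_star=v,
        n0_star=n0,
        n_vec_star=n_vec,
        I0_star=I0,
        I_vec_star=I_vec,
        n_total=state.n_total,
        valid=valid,
        residual_norm=residual,
        diagnostics={
            "ratio_sum": float(rho.sum()),
            "ratio_sum_closed_form": ratio_sum_closed,
            "min_denominator": float(denom.min()),
        },
    )


def solve_coexistence_multi(
    params: MultiSpacerParams,
    *,
    scan_points: int = 100,
) -> CoexistenceSolution:
    """Solve the implicit coexistence equation of the N-spacer model.

    Finds eta_bar such that the abundance-weighted mean failure probability of
    the resulting spacer distribution reproduces eta_bar itself, then
    assembles the full fixed point (healthy, infected and phage compartments).
    The mean must lie between min(eta_i) and max(eta_i); positivity of every
    ratio denominator kappa - f F (1 - eta_i b) restricts the bracket further
    from above, and the root is located with Brent's method at machine
    precision.  A sign scan over ``scan_points`` points flags (via a warning
    and the diagnostics dict) any additional sign change, i.e. a potentially
    non-unique fixed point.
    """
    p = params
    _no_extensions(p, "the analytic coexistence solution")
    if p.kappa == 0.0:
        raise SteadyStateError(
            "coexistence requires spacer loss (kappa > 0); with kappa = 0 the "
            "stable outcomes are phage or bacterial extinction"
        )
    if p.alpha_vec.sum() == 0.0:
        raise SteadyStateError("coexistence requires at least one alpha_i > 0")

    active = p.alpha_vec > 0
    eta_lo = float(p.eta_vec[active].min())
    eta_hi = float(p.eta_vec[active].max())

    if eta_hi - eta_lo < 1e-15:
        # all (acquirable) spacers share one failure probability: eta_bar is it
        return _assemble(eta_lo, p)

    # upper bound from positivity of the smallest-eta denominator:
    # kappa - f F(eta_bar) (1 - b eta_min) > 0
    c = p.b * (1.0 - p.alpha_total) - 1.0
    if c <= 0.0:
        return _assemble(eta_lo, p)  # b(1-alpha) <= 1: phage cannot grow; invalid
    hi = eta_hi
    if eta_lo < 1.0 / p.b:
        eta_up = (1.0 / p.b) * (1.0 - c * (1.0 - p.b * eta_lo) / (p.b - 1.0))
        hi = min(hi, eta_up)
    hi = min(hi, 1.0 / p.b)
    if hi <= eta_lo:
        sol = _assemble(eta_lo + 0.0, p) if eta_lo < 1.0 / p.b else None
        if sol is not None:
            return CoexistenceSolution(**{**sol.__dict__, "valid": False})
        raise SteadyStateError("no admissible bracket for eta_bar: coexistence impossible")

    span = hi - eta_lo
    lo_b = eta_lo + 1e-14 * max(span, eta_lo)
    hi_b = hi - 1e-12 * span
    f_lo = _eta_bar_residual(lo_b, p)
    f_hi = _eta_bar_residual(hi_b, p)
    while f_hi < 0 and hi_b - lo_b > 1e-15 * span:
        # denominator not yet binding at hi; tighten toward the singular edge
        hi_b = hi - (hi - hi_b) * 0.1
        f_hi = _eta_bar_residual(hi_b, p)
    if f_lo > 0 or f_hi < 0:
        sol = _assemble(0.5 * (lo_b + hi_b), p)
        return CoexistenceSolution(**{**sol.__dict__, "valid": False})

    grid = np.linspace(lo_b, hi_b, scan_points)
    signs = np.sign([_eta_bar_residual(x, p) for x in grid])
    crossings = int(np.sum(np.abs(np.diff(signs)) > 0))
    if crossings > 1:
        warnings.warn(
            f"eta_bar self-consistency has {crossings} sign changes in the bracket; "
            "the coexistence fixed point may not be unique",
            RuntimeWarning,
            stacklevel=2,
        )

    root = optimize.brentq(_eta_bar_residual, lo_b, hi_b, args=(p,), xtol=1e-15, rtol=8.9e-16)
    sol = _assemble(float(root), p)
    sol.diagnostics["sign_changes"] = crossings
    sol.diagnostics["self_consistency"] = _eta_bar_residual(float(root), p)
    return sol


def coexistence_state_single(params: SingleSpacerParams) -> SingleState:
    """Assemble the full single-spacer coexistence fixed point (r = 1).

    Combines the closed forms for F and n1/n0 with g v = b f0 F and the
    stationarity of the infected compartments (I0 = g v n0/mu,
    I1 = eta g v n1/mu), fixing the scale by n_total = K(1-F).
    """
    p = params
    F = unused_capacity_single(p)
    if not 0.0 < F < 1.0:
        raise SteadyStateError(f"F = {F:g} outside (0, 1): no physical coexistence state")
    rho = spacer_ratio_single(p)
    v = p.b * p.f0 * F / p.g
    gv_mu = p.g * v / p.mu
    n0 = p.K * (1.0 - F) / (1.0 + rho + gv_mu * (1.0 + p.eta * rho))
    return SingleState(n0=n0, n1=rho * n0, I0=gv_mu * n0, I1=p.eta * gv_mu * rho * n0, v=v)


def steady_state_numeric(
    params,
    guess_state,
    *,
    tol: float = 1e-9,
):
    """Find a fixed point of the full ODE system by root finding.

    Works for either model (dispatch on the parameter type) and therefore also
    covers cases outside the analytic theory, e.g. unequal growth rates or
    nonzero dilution.  Uses scipy's modified-Powell (hybrid) solver; the
    scaled residual ||rhs|| / (||x|| + 1) must fall below ``tol`` or a
    SteadyStateError with the residual is raised.
    """
    if isinstance(params, SingleSpacerParams):
        rhs = lambda y: single_rhs_array(y, params)  # noqa: E731
        unpack = SingleState.from_array
    elif isinstance(params, MultiSpacerParams):
        rhs = lambda y: multi_rhs_array(y, params)  # noqa: E731
        unpack = lambda y: MultiState.from_array(y, params.N)  # noqa: E731
    else:
        raise TypeError(f"unsupported params type: {type(params)!r}")

    y0 = guess_state.to_array()
    if np.any(y0 < 0):
        raise ValueError("guess_state must be non-negative")
    result = optimize.root(rhs, y0, method="hybr", tol=1e-14)
    resid = float(np.linalg.norm(rhs(result.x)) / (np.linalg.norm(result.x) + 1.0))
    if resid > tol:
        raise SteadyStateError(
            f"numeric steady state did not converge: scaled residual {resid:.3e} > {tol:g} "
            f"(solver message: {result.message})"
        )
    return unpack(result.x)


def _coexistence_attainable_numeric(params: SingleSpacerParams) -> bool:
    """Check numerically whether an interior (all-positive) fixed point exists."""
    guess_params = SingleSpacerParams(**{**params.to_dict(), "r": 1.0})
    try:
        guess = coexistence_state_single(guess_params)
    except SteadyStateError:
        return False
    try:
        st = steady_state_numeric(params, guess, tol=1e-8)
    except SteadyStateError:
        return False
    y = st.to_array()
    return bool(np.all(y > 0) and st.v > 1e-12 * params.K and st.n_total < params.K)


def classify_regime(params: SingleSpacerParams) -> RegimeLabel:
    """Predicted asymptotic regime from the parameters alone.

    With spacer loss (kappa > 0) and eta below the critical value, bacteria
    and phage coexist.  Without spacer loss the phage go extinct and bacteria
    reach capacity provided the spacer is effective enough (eta < 1/b);
    otherwise viral growth cannot be stopped and the bacteria die out.
    Boundary cases (eta exactly at threshold) are labelled
    bacterial_extinction since the coexistence formulas diverge there.
    """
    p = params
    if p.kappa == 0.0:
        if p.eta < 1.0 / p.b:
            return RegimeLabel.phage_extinction
        return RegimeLabel.bacterial_extinction
    if p.r == 1.0:
        eta_c = critical_failure_probability(p)
        if p.eta < eta_c:
            return RegimeLabel.coexistence
        return RegimeLabel.bacterial_extinction
    # unequal growth rates: no closed form; probe the fixed point numerically
    if _coexistence_attainable_numeric(p):
        return RegimeLabel.coexistence
    return RegimeLabel.bacterial_extinction
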