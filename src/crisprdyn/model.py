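"""Parameter/state containers and ODE right-hand sides for the bacteria-phage model.

The model tracks healthy wild-type bacteria (``n0``), healthy spacer-enhanced
bacteria (``n1`` or a per-spacer vector ``n_i``), the corresponding infected
compartments (``I0``, ``I1`` / ``I_i``) and free phage (``v``).  Bacteria grow
logistically toward a carrying capacity ``K``; the total population ``n``
counts both healthy and infected cells.  Phage adsorb onto healthy bacteria at
rate ``g`` per phage; a spacer lets its carrier evade infection except with
failure probability ``eta``.  Infected cells do not divide and lyse at rate
``mu``, releasing ``b`` phage, unless a wild-type cell survives the infection
and integrates a spacer (probability ``alpha``).  Spacers are lost at rate
``kappa``, reverting the carrier to wild type.

All rates are conventionally expressed in units of the wild-type growth rate
(``f0 = 1``); the equations are written for arbitrary ``f0`` so raw rates work
too.  Optional ``dilution`` removes every population at a common rate, and
``phage_decay`` adds a free-phage specific loss term; both default to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "SingleSpacerParams",
    "MultiSpacerParams",
    "SingleState",
    "MultiState",
    "single_rhs",
    "multi_rhs",
    "single_rhs_array",
    "multi_rhs_array",
    "total_derivative_single",
    "total_derivative_multi",
    "embed_single_as_multi",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SingleSpacerParams:
    """Rates and probabilities of the single-spacer model.

    f0 : wild-type maximum growth rate (1/time)
    r : growth-rate ratio f1/f0 of spacer-enhanced to wild-type bacteria
    K : carrying capacity (cells)
    kappa : spacer loss rate (1/time)
    g : phage adsorption/encounter rate (1/(phage*time))
    eta : spacer failure probability in [0, 1]
    alpha : spacer acquisition probability in [0, 1)
    mu : lysis rate of infected cells (1/time)
    b : burst size (phage released per lysis)
    dilution : optional removal rate applied to every population (1/time)
    phage_decay : optional extra decay rate of free phage (1/time)
    """

    f0: float = 1.0
    r: float = 1.0
    K: float = 1e5
    kappa: float = 0.0
    g: float = 1e-5
    eta: float = 0.0
    alpha: float = 0.0
    mu: float = 1.0
    b: float = 100.0
    dilution: float = 0.0
    phage_decay: float = 0.0

    def __post_init__(self) -> None:
        _require(self.f0 > 0, "f0 must be positive")
        _require(self.K > 0, "K must be positive")
        _require(self.g > 0, "g must be positive")
        _require(self.mu > 0, "mu must be positive")
        _require(self.r > 0, "r must be positive")
        _require(self.kappa >= 0, "kappa must be non-negative")
        _require(self.dilution >= 0, "dilution must be non-negative")
        _require(self.phage_decay >= 0, "phage_decay must be non-negative")
        _require(0.0 <= self.eta <= 1.0, "eta must lie in [0, 1]")
        _require(0.0 <= self.alpha < 1.0, "alpha must lie in [0, 1)")
        _require(self.b >= 1, "burst size b must be >= 1")

    @property
    def f1(self) -> float:
        """Growth rate of spacer-enhanced bacteria."""
        return self.r * self.f0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class MultiSpacerParams:
    """Rates and probabilities of the N-spacer-type model.

    All bacteria grow at a common rate ``f`` regardless of spacer content.
    ``alpha_vec[i]`` is the probability that an infected wild-type cell
    survives and acquires spacer ``i``; acquisitions of distinct spacers are
    disjoint events, so the total acquisition probability sum(alpha_vec) must
    stay below 1.  ``eta_vec[i]`` is the failure probability of spacer ``i``.
    """

    alpha_vec: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    eta_vec: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    f: float = 1.0
    K: float = 1e5
    kappa: float = 0.0
    g: float = 1e-5
    mu: float = 1.0
    b: float = 100.0
    dilution: float = 0.0
    phage_decay: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha_vec", np.atleast_1d(np.asarray(self.alpha_vec, dtype=float)))
        object.__setattr__(self, "eta_vec", np.atleast_1d(np.asarray(self.eta_vec, dtype=float)))
        _require(self.f > 0, "f must be positive")
        _require(self.K > 0, "K must be positive")
        _require(self.g > 0, "g must be positive")
        _require(self.mu > 0, "mu must be positive")
        _require(self.kappa >= 0, "kappa must be non-negative")
        _require(self.dilution >= 0, "dilution must be non-negative")
        _require(self.phage_decay >= 0, "phage_decay must be non-negative")
        _require(self.b >= 1, "burst size b must be >= 1")
        _require(
            self.alpha_vec.shape == self.eta_vec.shape and self.alpha_vec.ndim == 1,
            "alpha_vec and eta_vec must be 1-d vectors of equal length",
        )
        _require(bool(np.all(self.alpha_vec >= 0)), "each alpha_i must be non-negative")
        _require(
            float(np.sum(self.alpha_vec)) < 1.0,
            "sum(alpha_vec) must be < 1 (disjoint acquisition events)",
        )
        _require(
            bool(np.all((self.eta_vec >= 0) & (self.eta_vec <= 1))),
            "each eta_i must lie in [0, 1]",
        )

    @property
    def N(self) -> int:
        return self.alpha_vec.size

    @property
    def alpha_total(self) -> float:
        return float(np.sum(self.alpha_vec))

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["alpha_vec"] = [float(x) for x in self.alpha_vec]
        d["eta_vec"] = [float(x) for x in self.eta_vec]
        return d


@dataclass(frozen=True)
class SingleState:
    """Population vector of the single-spacer model (all non-negative counts)."""

    n0: float = 0.0
    n1: float = 0.0
    I0: float = 0.0
    I1: float = 0.0
    v: float = 0.0

    @property
    def n_total(self) -> float:
        """Total bacteria, healthy plus infected."""
        return self.n0 + self.n1 + self.I0 + self.I1

    def to_array(self) -> np.ndarray:
        return np.array([self.n0, self.n1, self.I0, self.I1, self.v], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SingleState":
        n0, n1, I0, I1, v = (float(x) for x in y)
        return cls(n0=n0, n1=n1, I0=I0, I1=I1, v=v)


@dataclass(frozen=True)
class MultiState:
    """Population vector of the N-spacer model.

    Array layout (used by the solver): ``[n0, n_1..n_N, I0, I_1..I_N, v]``.
    """

    n0: float
    n_vec: np.ndarray
    I0: float
    I_vec: np.ndarray
    v: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_vec", np.atleast_1d(np.asarray(self.n_vec, dtype=float)))
        object.__setattr__(self, "I_vec", np.atleast_1d(np.asarray(self.I_vec, dtype=float)))
        _require(self.n_vec.shape == self.I_vec.shape, "n_vec and I_vec must have equal length")

    @property
    def N(self) -> int:
        return self.n_vec.size

    @property
    def n_total(self) -> float:
        return float(self.n0 + self.n_vec.sum() + self.I0 + self.I_vec.sum())

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.n0], self.n_vec, [self.I0], self.I_vec, [self.v]))

    @classmethod
    def from_array(cls, y: np.ndarray, N: int) -> "MultiState":
        y = np.asarray(y, dtype=float)
        if y.size != 2 * N + 3:
            raise ValueError(f"state vector has length {y.size}, expected {2 * N + 3}")
        return cls(
            n0=float(y[0]),
            n_vec=y[1 : N + 1].copy(),
            I0=float(y[N + 1]),
            I_vec=y[N + 2 : 2 * N + 2].copy(),
            v=float(y[2 * N + 2]),
        )


def _check_finite(y: np.ndarray) -> None:
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state encountered: {y!r} (solver blow-up?)")


def single_rhs_array(y: np.ndarray, p: SingleSpacerParams) -> np.ndarray:
    """Time derivatives for the state vector ``[n0, n1, I0, I1, v]``.

    Phage are lost by adsorption onto healthy bacteria only (n0 + n1), as the
    model equations are written; infected cells occupy carrying capacity but
    do not adsorb further phage.
    """
    _check_finite(y)
    n0, n1, I0, I1, v = y
    n = n0 + n1 + I0 + I1
    growth = p.f0 * (1.0 - n / p.K)
    gv = p.g * v
    dn0 = growth * n0 + p.kappa * n1 - gv * n0
    dn1 = p.r * growth * n1 - p.kappa * n1 - p.eta * gv * n1 + p.alpha * p.mu * I0
    dI0 = gv * n0 - p.mu * I0
    dI1 = p.eta * gv * n1 - p.mu * I1
    dv = p.b * (1.0 - p.alpha) * p.mu * I0 + p.b * p.mu * I1 - gv * (n0 + n1)
    out = np.array([dn0, dn1, dI0, dI1, dv])
    if p.dilution:
        out -= p.dilution * y
    if p.phage_decay:
        out[4] -= p.phage_decay * v
    return out


def single_rhs(state: SingleState, params: SingleSpacerParams) -> np.ndarray:
    """Right-hand side of the single-spacer ODE system at ``state``."""
    return single_rhs_array(state.to_array(), params)


def multi_rhs_array(y: np.ndarray, p: MultiSpacerParams) -> np.ndarray:
    """Time derivatives for ``[n0, n_1..n_N, I0, I_1..I_N, v]``."""
    _check_finite(y)
    N = p.N
    if y.size != 2 * N + 3:
        raise ValueError(f"state vector has length {y.size}, expected {2 * N + 3} for N={N}")
    n0 = y[0]
    n_vec = y[1 : N + 1]
    I0 = y[N + 1]
    I_vec = y[N + 2 : 2 * N + 2]
    v = y[2 * N + 2]

    n = n0 + n_vec.sum() + I0 + I_vec.sum()
    growth = p.f * (1.0 - n / p.K)
    gv = p.g * v
    dn0 = growth * n0 + p.kappa * n_vec.sum() - gv * n0
    dn_vec = growth * n_vec - p.kappa * n_vec - p.eta_vec * gv * n_vec + p.alpha_vec * p.mu * I0
    dI0 = gv * n0 - p.mu * I0
    dI_vec = p.eta_vec * gv * n_vec - p.mu * I_vec
    dv = (
        p.b * (1.0 - p.alpha_vec.sum()) * p.mu * I0
        + p.b * p.mu * I_vec.sum()
        - gv * (n0 + n_vec.sum())
    )
    out = np.concatenate(([dn0], dn_vec, [dI0], dI_vec, [dv]))
    if p.dilution:
        out -= p.dilution * y
    if p.phage_decay:
        out[-1] -= p.phage_decay * v
    return out


def multi_rhs(state: MultiState, params: MultiSpacerParams) -> np.ndarray:
    """Right-hand side of the N-spacer ODE system at ``state``."""
    if state.N != params.N:
        raise ValueError(f"state has N={state.N} but params have N={params.N}")
    return multi_rhs_array(state.to_array(), params)


def total_derivative_single(state: SingleState, params: SingleSpacerParams) -> float:
    """dn/dt for the total bacterial count of the single-spacer model.

    Equals f0*(n0 + r*n1)*(1 - n/K) - mu*(1-alpha)*I0 - mu*I1, minus dilution;
    identical to the sum of the four bacterial components of the full system.
    """
    p = params
    n = state.n_total
    out = (
        p.f0 * (state.n0 + p.r * state.n1) * (1.0 - n / p.K)
        - p.mu * (1.0 - p.alpha) * state.I0
        - p.mu * state.I1
    )
    if p.dilution:
        out -= p.dilution * n
    return out


def total_derivative_multi(state: MultiState, params: MultiSpacerParams) -> float:
    """dn/dt for the total bacterial count of the N-spacer model.

    Only healthy cells divide, so the logistic term applies to n minus all
    infected compartments: f*(1-n/K)*(n - I0 - sum(I_i)).
    """
    p = params
    n = state.n_total
    infected = state.I0 + state.I_vec.sum()
    out = (
        p.f * (1.0 - n / p.K) * (n - infected)
        - p.mu * (1.0 - p.alpha_total) * state.I0
        - p.mu * state.I_vec.sum()
    )
    if p.dilution:
        out -= p.dilution * n
    return out


def embed_single_as_multi(params: SingleSpacerParams) -> MultiSpacerParams:
    """Express a single-spacer parameter set as an N=1 multi-spacer set.

    The N-spacer model assumes all bacteria grow at the same rate, so this
    embedding is only defined for r = 1.
    """
    if params.r != 1.0:
        raise ValueError(
            "the multi-spacer model assumes equal growth rates for all bacteria; "
            f"cannot embed single-spacer params with r={params.r} != 1"
        )
    return MultiSpacerParams(
        alpha_vec=np.array([params.alpha]),
        eta_vec=np.array([params.eta]),
        f=params.f0,
        K=params.K,
        kappa=params.kappa,
        g=params.g,
        mu=params.mu,
        b=params.b,
        dilution=params.dilution,
        phage_decay=params.phage_decay,
    )
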