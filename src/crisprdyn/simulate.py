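"""Time integration, steady-state detection and trajectory analytics.

Populations span many orders of magnitude during near-extinction transients,
so integration uses a stiff-capable solver (LSODA) with tight default
tolerances.  Output is recorded on a logarithmic time grid by default,
matching how these dynamics are usually inspected (the interesting structure
— lysis peak, bottleneck, recovery — plays out across decades in time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    MultiSpacerParams,
    MultiState,
    SingleSpacerParams,
    SingleState,
    multi_rhs_array,
    single_rhs_array,
)
from .steady import RegimeLabel

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "TransientSummary",
    "IntegrationError",
    "UndeterminedOutcomeError",
    "integrate",
    "detect_steady_state",
    "classify_outcome",
    "transient_summary",
]


class IntegrationError(RuntimeError):
    """Solver failure or trajectory leaving the admissible region."""


class UndeterminedOutcomeError(RuntimeError):
    """Trajectory cannot be classified (non-finite or empty endpoint)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical controls for a single integration run.

    t_max : end time, in units of 1/f0 (default 1e4, long enough for damped
        oscillations to settle at spacer-loss rates kappa/f0 >= 1e-3)
    n_outputs : number of output grid points
    rel_tol, abs_tol : solver tolerances
    steady_tol : scaled RHS-norm threshold for declaring a steady state
    extinction_threshold : population level below which a compartment counts
        as extinct when classifying the outcome; ``None`` means 1e-6 * K
        (the deterministic flow never reaches exactly zero)
    grid : "log" (default) or "linear" output spacing
    """

    t_max: float = 1e4
    n_outputs: int = 2000
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    steady_tol: float = 1e-6
    extinction_threshold: float | None = None
    grid: str = "log"

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.rel_tol <= 0 or self.abs_tol <= 0 or self.steady_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.extinction_threshold is not None and self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be non-negative")
        if self.grid not in ("log", "linear"):
            raise ValueError("grid must be 'log' or 'linear'")
        if self.n_outputs < 2:
            raise ValueError("n_outputs must be at least 2")

    def time_grid(self) -> np.ndarray:
        if self.grid == "linear":
            return np.linspace(0.0, self.t_max, self.n_outputs)
        # log grid spanning ~7 decades up to t_max, with t=0 prepended
        t = np.geomspace(self.t_max * 1e-7, self.t_max, self.n_outputs - 1)
        return np.concatenate(([0.0], t))

    def to_dict(self) -> dict:
        return {
            "t_max": self.t_max,
            "n_outputs": self.n_outputs,
            "rel_tol": self.rel_tol,
            "abs_tol": self.abs_tol,
            "steady_tol": self.steady_tol,
            "extinction_threshold": self.extinction_threshold,
            "grid": self.grid,
        }


@dataclass(frozen=True)
class Trajectory:
    """Integrated states on an increasing time grid, plus run metadata."""

    times: np.ndarray
    states: np.ndarray  # shape (n_points, dim)
    params: SingleSpacerParams | MultiSpacerParams
    config: SimulationConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_multi(self) -> bool:
        return isinstance(self.params, MultiSpacerParams)

    @property
    def N(self) -> int:
        return self.params.N if self.is_multi else 1

    def state_at(self, i: int):
        if self.is_multi:
            return MultiState.from_array(self.states[i], self.params.N)
        return SingleState.from_array(self.states[i])

    @property
    def final_state(self):
        return self.state_at(-1)

    @property
    def v(self) -> np.ndarray:
        """Free-phage count along the trajectory."""
        return self.states[:, -1]

    @property
    def n_total(self) -> np.ndarray:
        """Total bacteria (healthy + infected) along the trajectory."""
        return self.states[:, :-1].sum(axis=1)

    def rhs(self, y: np.ndarray) -> np.ndarray:
        if self.is_multi:
            return multi_rhs_array(y, self.params)
        return single_rhs_array(y, self.params)

    def to_dataframe(self) -> pd.DataFrame:
        N = self.N
        cols = (
            ["time", "n0"]
            + [f"n_{i}" for i in range(1, N + 1)]
            + ["I0"]
            + [f"I_{i}" for i in range(1, N + 1)]
            + ["v"]
        )
        data = np.column_stack([self.times, self.states])
        df = pd.DataFrame(data, columns=cols)
        df["n_total"] = self.n_total
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rhs_for(params):
    if isinstance(params, MultiSpacerParams):
        return lambda t, y: multi_rhs_array(y, params)
    if isinstance(params, SingleSpacerParams):
        return lambda t, y: single_rhs_array(y, params)
    raise TypeError(f"unsupported params type: {type(params)!r}")


def integrate(params, initial_state, config: SimulationConfig | None = None) -> Trajectory:
    """Integrate the model ODEs from ``initial_state`` over [0, t_max].

    The right-hand sides are evaluated as written, without clamping; the flow
    preserves the non-negative orthant analytically, so any negativity beyond
    100x the absolute tolerance indicates solver failure and raises.
    """
    if config is None:
        config = SimulationConfig()
    y0 = initial_state.to_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    if isinstance(params, MultiSpacerParams) and y0.size != 2 * params.N + 3:
        raise ValueError("initial state dimension inconsistent with params N")

    t_eval = config.time_grid()
    sol = solve_ivp(
        _rhs_for(params),
        (0.0, config.t_max),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=config.rel_tol,
        atol=config.abs_tol,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    states = sol.y.T
    floor = states.min()
    if floor < -100.0 * config.abs_tol:
        raise IntegrationError(
            f"trajectory left the non-negative orthant (min component {floor:.3e}); "
            "tighten tolerances"
        )
    return Trajectory(
        times=sol.t,
        states=states,
        params=params,
        config=config,
        diagnostics={"nfev": sol.nfev, "njev": sol.njev, "message": sol.message},
    )


def detect_steady_state(traj: Trajectory, steady_tol: float | None = None):
    """Return the final state if the tail of the trajectory is stationary.

    Stationarity means the scaled derivative norm ||rhs|| / (||y|| + 1) stays
    below ``steady_tol`` over the last 5% of the output grid; otherwise None.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    if steady_tol is None:
        steady_tol = traj.config.steady_tol
    tail = max(1, traj.times.size // 20)
    for y in traj.states[-tail:]:
        scaled = np.linalg.norm(traj.rhs(y)) / (np.linalg.norm(y) + 1.0)
        if scaled >= steady_tol:
            return None
    return traj.final_state


def classify_outcome(traj: Trajectory, extinction_threshold: float | None = None) -> RegimeLabel:
    """Classify the asymptotic outcome of an integrated run.

    Compares the endpoint phage and total-bacteria counts against the
    extinction threshold (default 1e-6 * K): below-threshold phage means
    phage extinction, below-threshold bacteria means bacterial extinction,
    both above means coexistence.
    """
    if traj.times.size == 0:
        raise UndeterminedOutcomeError("empty trajectory")
    if extinction_threshold is None:
        extinction_threshold = traj.config.extinction_threshold
    if extinction_threshold is None:
        extinction_threshold = 1e-6 * traj.params.K
    end = traj.states[-1]
    if not np.all(np.isfinite(end)):
        raise UndeterminedOutcomeError("non-finite endpoint state")
    v_end = float(traj.v[-1])
    n_end = float(traj.n_total[-1])
    if n_end < extinction_threshold:
        return RegimeLabel.bacterial_extinction
    if v_end < extinction_threshold:
        return RegimeLabel.phage_extinction
    return RegimeLabel.coexistence


@dataclass(frozen=True)
class TransientSummary:
    """Shape statistics of the transient phase of a run.

    The phage load typically peaks when the first infected cells burst, then
    falls as immunity spreads; spacer loss re-seeds the susceptible pool and
    can drive damped oscillations, counted here as strict local maxima of the
    phage curve after the main peak (on the raw output grid, no smoothing).
    """

    v_peak: float
    t_peak: float
    v_min_post_peak: float
    n_bottleneck: float
    oscillation_count: int


def transient_summary(traj: Trajectory) -> TransientSummary:
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    v = traj.v
    i_peak = int(np.argmax(v))
    v_peak = float(v[i_peak])
    t_peak = float(traj.times[i_peak])
    post = v[i_peak:]
    v_min_post = float(post.min())
    n_bottleneck = float(traj.n_total.min())
    osc = 0
    if post.size >= 3:
        interior = post[1:-1]
        osc = int(np.sum((interior > post[:-2]) & (interior > post[2:])))
    return TransientSummary(
        v_peak=v_peak,
        t_peak=t_peak,
        v_min_post_peak=v_min_post,
        n_bottleneck=n_bottleneck,
        oscillation_count=osc,
    )
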