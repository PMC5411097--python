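"""Reference scenarios: parameter regimes the model is meant to probe.

Every other module is testable against these generated fixtures, so no
external data is needed.  The baseline single-spacer scenario describes a
lytic-phage invasion of a small naive culture: n(0) = 1000 wild-type cells,
v(0) = 1e4 phage, carrying capacity K = 1e5, burst size b = 100, and rates
(in units of the wild-type growth rate) g = 1e-5, mu = 1, kappa = 2e-3, with
acquisition probability alpha = 1e-4 — a regime with coexistence and damped
oscillations for effective spacers.  The multi-spacer scenarios use N = 20
spacer types with kappa = 1e-2, g = 1e-4 and a total acquisition probability
of 0.0972, split across spacers in several documented ways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MultiSpacerParams, MultiState, SingleSpacerParams, SingleState
from .simulate import SimulationConfig
from .steady import classify_regime

__all__ = [
    "ScenarioSpec",
    "single_invasion_scenario",
    "unused_capacity_sweep",
    "multi_spacer_scenario",
    "MULTI_MODES",
    "scenario_catalog",
]

MULTI_MODES = (
    "acquisition_varying",
    "effectiveness_varying",
    "correlated",
    "anticorrelated",
    "constant",
)

# default per-spacer failure-probability grid: linear, kept below 1/b = 0.01
# so that coexistence stays attainable for every spacer type
DEFAULT_ETA_MIN = 0.0005
DEFAULT_ETA_MAX = 0.0095
DEFAULT_ETA_CONST = 0.005
DEFAULT_ALPHA_TOTAL = 0.0972


@dataclass(frozen=True)
class ScenarioSpec:
    """A named parameter set with initial condition and expected behavior."""

    name: str
    params: SingleSpacerParams | MultiSpacerParams
    initial_state: SingleState | MultiState
    config: SimulationConfig = field(default_factory=SimulationConfig)
    expectation: dict = field(default_factory=dict)


def single_invasion_scenario(
    eta: float = 0.0,
    r: float = 1.0,
    *,
    b: float = 100.0,
    kappa: float = 2e-3,
    config: SimulationConfig | None = None,
) -> ScenarioSpec:
    """Phage invasion of a naive wild-type culture (single spacer type).

    eta and r are free (the regime depends on them); the remaining parameters
    are the reference values of the coexistence/oscillation regime.
    """
    params = SingleSpacerParams(
        f0=1.0,
        r=r,
        K=1e5,
        kappa=kappa,
        g=1e-5,
        eta=eta,
        alpha=1e-4,
        mu=1.0,
        b=b,
    )
    state = SingleState(n0=1000.0, n1=0.0, I0=0.0, I1=0.0, v=1e4)
    regime = classify_regime(params)
    expectation = {
        "regime": regime.value,
        "bottleneck": regime.value != "phage_extinction",
        "oscillations": regime.value == "coexistence" and kappa > 0,
    }
    return ScenarioSpec(
        name="single-invasion",
        params=params,
        initial_state=state,
        config=config or SimulationConfig(),
        expectation=expectation,
    )


def unused_capacity_sweep(
    eta_b_grid: np.ndarray | None = None,
    alphas: tuple = (0.0, 1e-4, 1e-2),
) -> list[ScenarioSpec]:
    """Grid of single-spacer scenarios for the unused-capacity curve F(eta*b).

    b = 100, r = 1, kappa/f0 = 1e-2; eta*b runs over [0, 1) and each alpha
    gives one curve.  F diverges as eta*b approaches 1, so the grid stays
    strictly below it.
    """
    if eta_b_grid is None:
        eta_b_grid = np.linspace(0.0, 0.95, 20)
    specs = []
    for alpha in alphas:
        for eta_b in np.asarray(eta_b_grid, dtype=float):
            params = SingleSpacerParams(
                f0=1.0,
                r=1.0,
                K=1e5,
                kappa=1e-2,
                g=1e-5,
                eta=eta_b / 100.0,
                alpha=alpha,
                mu=1.0,
                b=100.0,
            )
            specs.append(
                ScenarioSpec(
                    name=f"capacity-sweep-alpha{alpha:g}-etab{eta_b:g}",
                    params=params,
                    initial_state=SingleState(n0=1000.0, v=1e4),
                    expectation={"regime": classify_regime(params).value},
                )
            )
    return specs


def _alpha_grid(N: int, alpha_total: float) -> np.ndarray:
    """Increasing linear ramp (proportional to 1..N) normalized to alpha_total."""
    ramp = np.arange(1, N + 1, dtype=float)
    return alpha_total * ramp / ramp.sum()


def multi_spacer_scenario(
    mode: str,
    N: int = 20,
    alpha_total: float = DEFAULT_ALPHA_TOTAL,
    *,
    eta_min: float = DEFAULT_ETA_MIN,
    eta_max: float = DEFAULT_ETA_MAX,
    eta_const: float = DEFAULT_ETA_CONST,
    config: SimulationConfig | None = None,
) -> ScenarioSpec:
    """N-spacer-type scenario in one of five documented modes.

    acquisition_varying : alpha_i on an increasing ramp, eta_i all equal
        (abundances should scale linearly with alpha_i)
    effectiveness_varying : alpha_i = alpha_total/N, eta_i on a linear grid
        (the lowest-eta spacer should win)
    correlated : alpha ramp and eta grid sorted in the same order
        (hardest-to-acquire spacers are also the least effective)
    anticorrelated : alpha ramp paired against the reversed eta grid
        (effective spacers are also easy to acquire; skews the distribution)
    constant : alpha_i and eta_i all equal (fully symmetric control)

    The pairing between the two grids in the correlated/anticorrelated modes
    is by rank.
    """
    if N < 2:
        raise ValueError("multi-spacer scenarios require N >= 2")
    if not 0.0 < alpha_total < 1.0:
        raise ValueError("alpha_total must lie in (0, 1)")
    if mode not in MULTI_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose one of {MULTI_MODES}")

    eta_grid = np.linspace(eta_min, eta_max, N)
    if mode == "acquisition_varying":
        alpha_vec = _alpha_grid(N, alpha_total)
        eta_vec = np.full(N, eta_const)
    elif mode == "effectiveness_varying":
        alpha_vec = np.full(N, alpha_total / N)
        eta_vec = eta_grid
    elif mode == "correlated":
        alpha_vec = _alpha_grid(N, alpha_total)
        eta_vec = eta_grid
    elif mode == "anticorrelated":
        alpha_vec = _alpha_grid(N, alpha_total)
        eta_vec = eta_grid[::-1].copy()
    else:  # constant
        alpha_vec = np.full(N, alpha_total / N)
        eta_vec = np.full(N, eta_const)

    params = MultiSpacerParams(
        alpha_vec=alpha_vec,
        eta_vec=eta_vec,
        f=1.0,
        K=1e5,
        kappa=1e-2,
        g=1e-4,
        mu=1.0,
        b=100.0,
    )
    state = MultiState(n0=1000.0, n_vec=np.zeros(N), I0=0.0, I_vec=np.zeros(N), v=1e4)
    return ScenarioSpec(
        name=f"multi-{mode.replace('_', '-')}",
        params=params,
        initial_state=state,
        config=config or SimulationConfig(),
        expectation={"regime": "coexistence", "mode": mode},
    )


def scenario_catalog() -> dict:
    """Named scenario factories exposed to the CLI."""
    catalog = {"single-invasion": single_invasion_scenario}
    for mode in MULTI_MODES:
        catalog[f"multi-{mode.replace('_', '-')}"] = (
            lambda m=mode, **kw: multi_spacer_scenario(m, **kw)
        )
    return catalog
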