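"""Summaries of the steady-state spacer distribution.

The fraction of bacteria carrying each spacer type is the model's observable
for acquisition-vs-effectiveness questions: acquisition differences move
abundances linearly, effectiveness differences enter a denominator and can
produce winner-take-all distributions.  Entropy and winner share make those
qualitative regimes quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MultiState
from .steady import CoexistenceSolution

__all__ = [
    "SpacerDistribution",
    "spacer_fractions",
    "shannon_entropy",
    "winner_share",
    "winner_index",
    "distribution_summary",
]


@dataclass(frozen=True)
class SpacerDistribution:
    """Normalized fractions f_i = n_i / sum_j n_j of healthy spacer carriers."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        fr = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        object.__setattr__(self, "fractions", fr)
        if np.any(fr < 0):
            raise ValueError("fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError(f"fractions must sum to 1 (got {fr.sum()!r})")

    @property
    def N(self) -> int:
        return self.fractions.size


def spacer_fractions(state: MultiState | CoexistenceSolution) -> SpacerDistribution:
    """Spacer-type distribution among healthy spacer-enhanced bacteria.

    Infected cells are excluded: the distribution describes which immunity
    the standing healthy population actually carries.
    """
    n_vec = state.n_vec_star if isinstance(state, CoexistenceSolution) else state.n_vec
    n_vec = np.asarray(n_vec, dtype=float)
    total = n_vec.sum()
    if total <= 0.0:
        raise ValueError("no spacer-enhanced bacteria: fractions undefined")
    return SpacerDistribution(fractions=n_vec / total)


def shannon_entropy(dist: SpacerDistribution) -> float:
    """Shannon entropy -sum f_i ln f_i in nats; 0 for a single-type population,
    ln N for a uniform one."""
    f = dist.fractions
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum())


def winner_share(dist: SpacerDistribution) -> float:
    """Population fraction of the most abundant spacer type."""
    return float(dist.fractions.max())


def winner_index(dist: SpacerDistribution) -> int:
    """Index (0-based) of the most abundant spacer type."""
    return int(np.argmax(dist.fractions))


def distribution_summary(dist: SpacerDistribution) -> dict:
    """JSON-ready summary of a spacer distribution."""
    return {
        "fractions": [float(x) for x in dist.fractions],
        "entropy": shannon_entropy(dist),
        "winner_index": winner_index(dist),
        "winner_share": winner_share(dist),
    }
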