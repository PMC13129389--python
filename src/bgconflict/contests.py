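"""Two-group contest resolution, model thresholds, and the winner phase diagram.

Contest success depends on the realized fighting-group size S of each side,
not on census size.  Two structural thresholds organise the outcome space at
a given ecology: the satiation threshold v/s (the census size at which the
contested patch stops feeding everyone, the "gray line") and the maximum
viable group size (the census size at which net gain crosses zero so nobody
joins a fight, the "black arrow").  Between the two, smaller census groups
can field larger fighting parties and win.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    DEFAULT_COST,
    DEFAULT_MOTIVATION,
    DEFAULT_RESOURCE,
    CostProfile,
    Motivation,
    ResourceProfile,
    fighting_group_size,
    group_coordination_cost,
    group_gain,
)

__all__ = [
    "ContestOutcome",
    "ThresholdReport",
    "PhaseDiagram",
    "resolve_contest",
    "satiation_threshold",
    "max_viable_group_size",
    "phase_diagram",
    "tabulate_figure4",
]

WinnerCode = Literal["group1", "group2", "draw"]


@dataclass(frozen=True)
class ContestOutcome:
    """Result of a single two-group contest."""

    n1: float
    n2: float
    S1: float
    S2: float
    winner: WinnerCode
    win_prob_1: Optional[float] = None


@dataclass(frozen=True)
class ThresholdReport:
    """The two structural group-size thresholds of the model."""

    satiation_threshold: float
    max_viable_size: Optional[float]
    zero_crossing_tol: float


@dataclass(frozen=True)
class PhaseDiagram:
    """Winner matrix over a grid of census-size pairs.

    ``winner_matrix[i, j]`` codes the winner of (n1_grid[i] vs n2_grid[j]):
    1 = group 1, 2 = group 2, 0 = draw / no contest.
    ``smaller_wins_fraction`` is the share of off-diagonal unequal-size cells
    in which the smaller census group wins.
    """

    n1_grid: np.ndarray
    n2_grid: np.ndarray
    winner_matrix: np.ndarray
    smaller_wins_fraction: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: n1, n2, S1, S2 omitted, winner code."""
        i, j = np.meshgrid(
            np.arange(len(self.n1_grid)), np.arange(len(self.n2_grid)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "n1": self.n1_grid[i.ravel()],
                "n2": self.n2_grid[j.ravel()],
                "winner": self.winner_matrix.ravel(),
            }
        )


def resolve_contest(
    n1: float,
    n2: float,
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
    motivation: Motivation = DEFAULT_MOTIVATION,
    rule: Literal["deterministic", "smooth"] = "deterministic",
    beta: float = 1.0,
) -> ContestOutcome:
    """Resolve a contest between census sizes ``n1`` and ``n2``.

    Both groups share one ecology (cost, resource, motivation).  Under the
    ``deterministic`` rule the side with the larger realized fighting size S
    wins and exact ties (including S1 = S2 = 0, "no contest") are draws.
    The ``smooth`` rule additionally reports a Tullock-style win probability
    ``S1**beta / (S1**beta + S2**beta)`` (0.5 when both S vanish).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("census sizes must be >= 1")
    S1 = fighting_group_size(n1, cost, resource, motivation)
    S2 = fighting_group_size(n2, cost, resource, motivation)
    if S1 > S2:
        winner: WinnerCode = "group1"
    elif S2 > S1:
        winner = "group2"
    else:
        winner = "draw"
    win_prob_1 = None
    if rule == "smooth":
        if S1 == 0.0 and S2 == 0.0:
            win_prob_1 = 0.5
        else:
            a, b = S1**beta, S2**beta
            win_prob_1 = float(a / (a + b))
    elif rule != "deterministic":
        raise ValueError(f"unknown rule {rule!r}")
    return ContestOutcome(n1=n1, n2=n2, S1=S1, S2=S2, winner=winner, win_prob_1=win_prob_1)


def satiation_threshold(resource: ResourceProfile = DEFAULT_RESOURCE) -> float:
    """Census size v/s at which the contested patch stops satiating everyone."""
    return resource.v / resource.s


def max_viable_group_size(
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
    tol: float = 1e-6,
    scan_cap: Optional[float] = None,
) -> Optional[float]:
    """Largest census size with positive net gain — beyond it no one fights.

    Above the satiation threshold the sign of the net gain equals the sign of
    ``v - c_g(n)``, which is independent of alpha (alpha only scales positive
    gains).  The function scans ``(v/s, scan_cap]`` on a unit grid for the
    last positive-to-nonpositive sign change and polishes the crossing by
    Brent root finding to within ``tol`` individuals.  Returns ``None`` when
    net gain never turns negative on the scanned range (no upper limit in
    range, e.g. when ``sum(C) < v``).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if scan_cap is None:
        scan_cap = 10.0 * max(cost.n_centers)
    lo = satiation_threshold(resource)
    if scan_cap <= lo:
        raise ValueError("scan_cap must exceed the satiation threshold v/s")

    def net(n: float) -> float:
        return group_gain(n, resource) - group_coordination_cost(n, cost)

    grid = np.linspace(lo, scan_cap, max(int(np.ceil(scan_cap - lo)), 2) + 1)
    vals = group_gain(grid, resource) - group_coordination_cost(grid, cost)
    # when c_g only approaches v from below, the tail underflows to exactly 0
    # at machine precision; require a genuinely negative excursion
    neg_eps = 1e-9 * resource.v
    if vals.min() >= -neg_eps or vals[0] <= 0:
        return None
    pos_idx = np.nonzero(vals > 0)[0]
    i = pos_idx[-1]
    if i == len(vals) - 1:
        return None  # still viable at the scan cap
    j = i + 1 + np.argmax(vals[i + 1 :] < -neg_eps)  # first strictly negative point
    return float(brentq(net, grid[i], grid[j], xtol=tol))


def thresholds(
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
    tol: float = 1e-6,
    scan_cap: Optional[float] = None,
) -> ThresholdReport:
    """Bundle both structural thresholds into one report."""
    return ThresholdReport(
        satiation_threshold=satiation_threshold(resource),
        max_viable_size=max_viable_group_size(cost, resource, tol=tol, scan_cap=scan_cap),
        zero_crossing_tol=tol,
    )


def phase_diagram(
    n1_grid: Sequence[int],
    n2_grid: Sequence[int],
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
    motivation: Motivation = DEFAULT_MOTIVATION,
) -> PhaseDiagram:
    """Winner map over all (n1, n2) pairs of two integer census-size grids."""
    g1 = np.asarray(n1_grid, dtype=int)
    g2 = np.asarray(n2_grid, dtype=int)
    if np.any(g1 < 1) or np.any(g2 < 1):
        raise ValueError("census sizes must be >= 1")
    sizes = np.unique(np.concatenate([g1, g2]))
    S = dict(
        zip(
            sizes.tolist(),
            np.atleast_1d(fighting_group_size(sizes.astype(float), cost, resource, motivation)),
        )
    )
    winner = np.zeros((len(g1), len(g2)), dtype=int)
    smaller_wins = 0
    unequal = 0
    for i, a in enumerate(g1):
        for j, b in enumerate(g2):
            sa, sb = S[int(a)], S[int(b)]
            code = 1 if sa > sb else (2 if sb > sa else 0)
            winner[i, j] = code
            if a != b:
                unequal += 1
                if (code == 1 and a < b) or (code == 2 and b < a):
                    smaller_wins += 1
    frac = smaller_wins / unequal if unequal else float("nan")
    return PhaseDiagram(
        n1_grid=g1, n2_grid=g2, winner_matrix=winner, smaller_wins_fraction=frac
    )


def tabulate_figure4(
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
    alphas: Sequence[float] = (0.4, 0.7, 1.0),
    n_grid: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Tabulate every model curve over an n-grid for a list of alpha values.

    Long format (alpha, n, c_g, c_a, g_a, g, p, S): one block per alpha, the
    alpha-free columns repeating identically.  Suitable for re-plotting the
    cost, gain, participation, and fighting-size curves.
    """
    if len(alphas) == 0:
        raise ValueError("alphas must be non-empty")
    if n_grid is None:
        n_grid = np.linspace(0.5, 10.0 * max(cost.n_centers) / 8.0, 400)
    n = np.asarray(n_grid, dtype=float)
    if np.any(n <= 0):
        raise ValueError("n_grid entries must be positive")
    c_g = group_coordination_cost(n, cost)
    c_a = c_g / n
    g_a = group_gain(n, resource) / n
    g = g_a - c_a
    blocks = []
    for a in alphas:
        mot = Motivation(alpha=a)
        p = np.clip(mot.alpha * g, 0.0, 1.0)
        blocks.append(
            pd.DataFrame(
                {
                    "alpha": a,
                    "n": n,
                    "c_g": c_g,
                    "c_a": c_a,
                    "g_a": g_a,
                    "g": g,
                    "p": p,
                    "S": n * p,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)
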