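"""Mean-field model of coordination costs in between-group conflicts (BGCs).

A social group of census size ``n`` forages over a set of discrete food
patches ("fruit trees").  Assembling the whole group at a contested patch
incurs a coordination cost that rises with group size in a staircase of
sigmoid steps — one step per occupied patch.  The value of the contested
patch is finite, so per-capita gains fall once the group outgrows the patch's
carrying capacity.  Individuals join a fight with probability proportional to
their expected net gain; the product of census size and that probability is
the realized fighting-group size ``S`` on which contest outcomes depend.

Quantities, for a group of census size ``n``:

* ``c_g(n) = sum_i C_i / (1 + exp(-k_i (n - n_i)))``  — group coordination cost
* ``c_a = c_g / n``                                   — per-capita cost
* ``g_g = min(s * n, v)``                             — group gross gain
* ``g_a = g_g / n``                                   — individual gross gain
* ``g = g_a - c_a``                                   — individual net gain
* ``p = clamp(alpha * g, 0, 1)``                      — participation probability
* ``S = n * p``                                       — realized fighting size
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "CostProfile",
    "ResourceProfile",
    "Motivation",
    "GroupEvaluation",
    "DEFAULT_COST",
    "DEFAULT_RESOURCE",
    "DEFAULT_MOTIVATION",
    "group_coordination_cost",
    "per_capita_cost",
    "group_gain",
    "individual_gross_gain",
    "individual_net_gain",
    "participation_probability",
    "fighting_group_size",
    "evaluate_group",
]

ArrayLike = Union[float, Sequence[float], np.ndarray]


class ProfileError(ValueError):
    """Raised for structurally invalid model parameter profiles."""


@dataclass(frozen=True)
class CostProfile:
    """Parameters of the staircase (multi-phase sigmoid) coordination cost.

    Each of the ``m`` steps corresponds to one food patch over which the
    group spreads: ``C[i]`` is the magnitude of the cost increase at
    transition ``i`` (cost units), ``k[i]`` its steepness (per individual)
    and ``n_centers[i]`` the group size at the middle of the step.
    """

    C: tuple[float, ...]
    k: tuple[float, ...]
    n_centers: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "C", tuple(float(x) for x in self.C))
        object.__setattr__(self, "k", tuple(float(x) for x in self.k))
        object.__setattr__(self, "n_centers", tuple(float(x) for x in self.n_centers))
        m = len(self.C)
        if m == 0:
            raise ProfileError("CostProfile needs at least one step")
        if len(self.k) != m or len(self.n_centers) != m:
            raise ProfileError(
                f"length mismatch: C has {m} entries, k has {len(self.k)}, "
                f"n_centers has {len(self.n_centers)}"
            )
        if any(c <= 0 for c in self.C) or any(x <= 0 for x in self.k):
            raise ProfileError("all C_i and k_i must be positive")
        if any(x <= 0 for x in self.n_centers):
            raise ProfileError("all transition centers must be positive")
        if any(b <= a for a, b in zip(self.n_centers, self.n_centers[1:])):
            raise ProfileError("n_centers must be strictly increasing")

    @property
    def m(self) -> int:
        """Number of sigmoid steps (occupied food patches)."""
        return len(self.C)

    @property
    def total_cost(self) -> float:
        """Asymptotic group cost as n -> infinity: sum of all step heights."""
        return float(sum(self.C))


@dataclass(frozen=True)
class ResourceProfile:
    """Contested-resource ecology: consumption capacity and patch value.

    ``s`` is the mean per-individual consumption capacity (food units) and
    ``v`` the total value of the contested patch (food units); ``v / s`` is
    the census size at which the patch stops satiating every member.
    """

    s: float = 1.0
    v: float = 10.0

    def __post_init__(self) -> None:
        if self.s <= 0 or self.v <= 0:
            raise ProfileError("s and v must be positive")


@dataclass(frozen=True)
class Motivation:
    """Dimensionless scaling ``alpha`` of the willingness to fight, in (0, 1]."""

    alpha: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ProfileError(f"alpha must lie in (0, 1], got {self.alpha}")


#: Default parameter set: four equal steps C_i = 5, k_i = 1 centered at
#: n_i = 10 i, patch value v = 10 at unit consumption capacity, alpha = 0.7.
DEFAULT_COST = CostProfile(C=(5, 5, 5, 5), k=(1, 1, 1, 1), n_centers=(10, 20, 30, 40))
DEFAULT_RESOURCE = ResourceProfile(s=1.0, v=10.0)
DEFAULT_MOTIVATION = Motivation(alpha=0.7)


@dataclass(frozen=True)
class GroupEvaluation:
    """All per-group model quantities at a single census size ``n``."""

    n: float
    c_g: float
    c_a: float
    g_g: float
    g_a: float
    g: float
    p: float
    S: float


def _as_array(n: ArrayLike) -> tuple[np.ndarray, bool]:
    arr = np.asarray(n, dtype=float)
    return arr, arr.ndim == 0


def group_coordination_cost(n: ArrayLike, cost: CostProfile = DEFAULT_COST) -> ArrayLike:
    """Group-level coordination cost ``c_g(n)``: a sum of sigmoid steps.

    Strictly increasing in ``n`` and bounded in ``(0, sum(C))``.  Accepts a
    scalar or an array of census sizes.  Uses ``expit`` so large
    ``|k (n - n_i)|`` never overflows.
    """
    arr, scalar = _as_array(n)
    if np.any(arr < 0):
        raise ValueError("census size must be non-negative")
    C = np.asarray(cost.C)
    k = np.asarray(cost.k)
    centers = np.asarray(cost.n_centers)
    out = (C * expit(k * (arr[..., None] - centers))).sum(axis=-1)
    return float(out) if scalar else out


def per_capita_cost(n: ArrayLike, cost: CostProfile = DEFAULT_COST) -> ArrayLike:
    """Expected coordination cost per group member, ``c_a = c_g / n`` (n > 0)."""
    arr, scalar = _as_array(n)
    if np.any(arr <= 0):
        raise ValueError("per-capita cost is undefined at n = 0")
    out = group_coordination_cost(arr, cost) / arr
    return float(out) if scalar else out


def group_gain(n: ArrayLike, resource: ResourceProfile = DEFAULT_RESOURCE) -> ArrayLike:
    """Expected group gross gain ``g_g = min(s n, v)``: linear then saturated."""
    arr, scalar = _as_array(n)
    if np.any(arr < 0):
        raise ValueError("census size must be non-negative")
    out = np.minimum(resource.s * arr, resource.v)
    return float(out) if scalar else out


def individual_gross_gain(
    n: ArrayLike, resource: ResourceProfile = DEFAULT_RESOURCE
) -> ArrayLike:
    """Per-member gross gain ``g_a = g_g / n`` (n > 0): flat at ``s`` below
    the satiation threshold ``v/s``, declining as ``v/n`` above it."""
    arr, scalar = _as_array(n)
    if np.any(arr <= 0):
        raise ValueError("individual gain is undefined at n = 0")
    out = group_gain(arr, resource) / arr
    return float(out) if scalar else out


def individual_net_gain(
    n: ArrayLike,
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
) -> ArrayLike:
    """Per-member net gain ``g = g_a - c_a``; may be negative."""
    arr, scalar = _as_array(n)
    out = individual_gross_gain(arr, resource) - per_capita_cost(arr, cost)
    return float(out) if scalar else out


def participation_probability(
    n: ArrayLike,
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
    motivation: Motivation = DEFAULT_MOTIVATION,
) -> ArrayLike:
    """Probability an individual joins the fight: ``clamp(alpha * g, 0, 1)``.

    The lower clamp is part of the model (no participation at non-positive
    net gain); the upper clamp at 1 keeps ``p`` a probability for arbitrary
    parameter combinations and never binds at the defaults (g <= s = 1).
    """
    arr, scalar = _as_array(n)
    g = individual_net_gain(arr, cost, resource)
    out = np.clip(motivation.alpha * g, 0.0, 1.0)
    return float(out) if scalar else out


def fighting_group_size(
    n: ArrayLike,
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
    motivation: Motivation = DEFAULT_MOTIVATION,
) -> ArrayLike:
    """Realized fighting-group size ``S = n p``, the expected participant count.

    Contest outcomes depend on ``S``, not census size; ``S = 0`` whenever the
    net gain is non-positive (no one joins).  Defined for all ``n >= 0``
    (vacuously 0 at n = 0).
    """
    arr, scalar = _as_array(n)
    if np.any(arr < 0):
        raise ValueError("census size must be non-negative")
    out = np.where(
        arr > 0,
        arr * participation_probability(np.maximum(arr, 1e-300), cost, resource, motivation),
        0.0,
    )
    return float(out) if scalar else out


def evaluate_group(
    n: float,
    cost: CostProfile = DEFAULT_COST,
    resource: ResourceProfile = DEFAULT_RESOURCE,
    motivation: Motivation = DEFAULT_MOTIVATION,
) -> GroupEvaluation:
    """Evaluate every model quantity at one census size and bundle the record."""
    if n <= 0:
        raise ValueError("evaluate_group requires n > 0")
    c_g = group_coordination_cost(n, cost)
    c_a = c_g / n
    g_g = group_gain(n, resource)
    g_a = g_g / n
    g = g_a - c_a
    p = float(np.clip(motivation.alpha * g, 0.0, 1.0))
    return GroupEvaluation(n=float(n), c_g=c_g, c_a=c_a, g_g=g_g, g_a=g_a, g=g, p=p, S=n * p)
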