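"""YAML parameter files for the contest model.

Schema (all keys optional; omitted sections fall back to the defaults):

.. code-block:: yaml

    cost:
      C: [5, 5, 5, 5]
      k: [1, 1, 1, 1]
      n_centers: [10, 20, 30, 40]
    resource:
      s: 1.0
      v: 10.0
    motivation:
      alpha: 0.7
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import yaml

from .model import (
    DEFAULT_COST,
    DEFAULT_MOTIVATION,
    DEFAULT_RESOURCE,
    CostProfile,
    Motivation,
    ResourceProfile,
)

__all__ = ["load_params", "dump_params"]


def load_params(
    path: Optional[Union[str, Path]] = None,
) -> tuple[CostProfile, ResourceProfile, Motivation]:
    """Load (cost, resource, motivation) from a YAML file; None -> defaults."""
    if path is None:
        return DEFAULT_COST, DEFAULT_RESOURCE, DEFAULT_MOTIVATION
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cost_raw = raw.get("cost", {})
    cost = CostProfile(
        C=tuple(cost_raw.get("C", DEFAULT_COST.C)),
        k=tuple(cost_raw.get("k", DEFAULT_COST.k)),
        n_centers=tuple(cost_raw.get("n_centers", DEFAULT_COST.n_centers)),
    )
    res_raw = raw.get("resource", {})
    resource = ResourceProfile(
        s=float(res_raw.get("s", DEFAULT_RESOURCE.s)),
        v=float(res_raw.get("v", DEFAULT_RESOURCE.v)),
    )
    mot_raw = raw.get("motivation", {})
    motivation = Motivation(alpha=float(mot_raw.get("alpha", DEFAULT_MOTIVATION.alpha)))
    return cost, resource, motivation


def dump_params(
    cost: CostProfile, resource: ResourceProfile, motivation: Motivation,
    path: Union[str, Path],
) -> None:
    """Write a parameter set back to YAML (round-trips with load_params)."""
    payload = {
        "cost": {
            "C": list(cost.C),
            "k": list(cost.k),
            "n_centers": list(cost.n_centers),
        },
        "resource": {"s": resource.s, "v": resource.v},
        "motivation": {"alpha": motivation.alpha},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
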