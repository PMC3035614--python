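"""Random parameter sets for property tests and sweeps.

Fixtures perturb every rate of a scenario's baseline multiplicatively,
uniformly within a relative range (default +/-50%), through one seeded
generator so sweeps are reproducible.  Conversion efficiencies stay capped
at 1 and structural fields (resource/habitat counts) are left at their
baseline values.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .models import (
    AdditionalResourcesParams,
    InterstageSharingParams,
    MultipleHabitatsParams,
    ScenarioParams,
    default_params,
)

__all__ = ["generate_fixtures"]

# fields perturbed per scenario; counts and flags stay fixed
_PERTURBED = {
    "additional": ("r_J", "K_J", "a_J", "b_J", "r_A", "K_A", "a_A", "b_A", "d_J", "d_A"),
    "multiple": ("r_J", "K_J", "a_J", "b_J", "r_A", "K_A", "a_A", "b_A", "d_J", "d_A"),
    "sharing": (
        "r_J", "K_J", "r_A", "K_A",
        "a_JJ", "a_JA", "a_AJ", "a_AA",
        "b_JJ", "b_JA", "b_AJ", "b_AA",
        "d_J", "d_A",
    ),
}


def _perturb(value, factor):
    if isinstance(value, np.ndarray):
        return value * factor
    return float(value) * float(factor)


def generate_fixtures(
    scenario: str,
    n: int,
    seed: int,
    rel_range: float = 0.5,
    base: ScenarioParams | None = None,
) -> list[ScenarioParams]:
    """``n`` valid random parameter sets around the scenario baseline.

    Each perturbed field is scaled by an independent uniform factor in
    ``[1 - rel_range, 1 + rel_range]`` (entry-wise for per-resource
    arrays).  The same ``seed`` always yields the same list.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= rel_range < 1:
        raise ValueError("rel_range must lie in [0, 1)")
    if base is None:
        base = default_params(scenario)
    if base.scenario != scenario:
        raise ValueError("base parameter set does not match the requested scenario")
    rng = np.random.default_rng(seed)
    fields = _PERTURBED[scenario]
    out = []
    for _ in range(n):
        updates = {}
        for name in fields:
            value = getattr(base, name)
            size = value.size if isinstance(value, np.ndarray) else None
            factor = rng.uniform(1.0 - rel_range, 1.0 + rel_range, size=size)
            new = _perturb(value, factor)
            if name.startswith("b"):
                new = np.minimum(new, 1.0) if isinstance(new, np.ndarray) else min(new, 1.0)
            updates[name] = new
        out.append(dataclasses.replace(base, **updates))
    return out
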