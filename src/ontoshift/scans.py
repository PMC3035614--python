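"""Parameter-plane maps of alternative stable states and multistability searches.

A scan evaluates the ASS test on a rectangular grid in two parameters,
either analytically (reduced cubic + discriminant + positivity) or by brute
force (attractor census over a grid of initial conditions).  The
heterogeneous-habitat search sweeps a productivity difference between two
juvenile habitats, holding total juvenile productivity fixed, and counts
attractors of the full system.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .dynamics import count_attractors, default_initial_grid
from .equilibria import ass_condition
from .models import MultipleHabitatsParams, ScenarioParams

__all__ = [
    "AxisSpec",
    "ScanSpec",
    "ScanResult",
    "HeterogeneousSearchResult",
    "with_param",
    "scan_ass_region",
    "subsidy_variant_scan",
    "heterogeneous_multistability_search",
]

_PATH_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*?)(?:\[(\d+)\])?$")


def with_param(params: ScenarioParams, path: str, value: float) -> ScenarioParams:
    """Return a copy of ``params`` with one field (or array entry) replaced.

    ``path`` is a field name, optionally indexed: ``"n_J"``, ``"a_JA"``,
    ``"K_J[1]"`` (the second juvenile resource's carrying capacity).
    """
    m = _PATH_RE.match(path)
    if m is None:
        raise ValueError(f"cannot parse parameter path {path!r}")
    name, idx = m.group(1), m.group(2)
    if not hasattr(params, name):
        raise ValueError(f"{type(params).__name__} has no parameter {name!r}")
    current = getattr(params, name)
    if idx is not None:
        arr = np.array(current, dtype=float)
        i = int(idx)
        if arr.ndim != 1 or i >= arr.size:
            raise ValueError(f"index {i} out of range for parameter {name!r}")
        arr[i] = value
        value = arr
    return dataclasses.replace(params, **{name: value})


@dataclass(frozen=True)
class AxisSpec:
    """One scan axis: a parameter path and an inclusive linear range."""

    path: str
    start: float
    stop: float
    num: int

    def __post_init__(self):
        if self.num < 2:
            raise ValueError("each axis needs at least 2 grid points")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.num)


@dataclass(frozen=True)
class ScanSpec:
    """Specification of a two-parameter ASS map."""

    base: ScenarioParams
    axis1: AxisSpec
    axis2: AxisSpec
    mode: str = "analytic"  # "analytic" | "simulation"
    #: keyword options forwarded to the analytic cell test (ass_condition),
    #: e.g. {"depletion": "own-stage"} for the sharing model
    analytic_options: dict = field(default_factory=dict)
    #: initial-condition grid edge for simulation mode (grid is n x n)
    sim_initials: int = 4
    sim_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("analytic", "simulation"):
            raise ValueError("mode must be 'analytic' or 'simulation'")


@dataclass(frozen=True)
class ScanResult:
    """Boolean ASS map over a parameter plane, with per-cell diagnostics."""

    x: np.ndarray  # axis1 values
    y: np.ndarray  # axis2 values
    ass: np.ndarray  # bool, shape (len(x), len(y))
    boundary: np.ndarray  # bool mask of near-degenerate cells
    n_equilibria: np.ndarray  # interior equilibrium / attractor count
    failures: tuple  # ((i, j, message), ...)
    provenance: dict

    @property
    def ass_fraction(self) -> float:
        """Fraction of non-boundary cells where ASS exist."""
        ok = ~self.boundary
        return float(np.mean(self.ass[ok])) if np.any(ok) else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        xs, ys = np.meshgrid(self.x, self.y, indexing="ij")
        return pd.DataFrame(
            {
                "x": xs.ravel(),
                "y": ys.ravel(),
                "ass": self.ass.ravel().astype(int),
                "boundary": self.boundary.ravel().astype(int),
                "n_equilibria": self.n_equilibria.ravel(),
            }
        )

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.csv`` (grid) and ``<prefix>.json`` (provenance)."""
        import json
        from pathlib import Path

        self.to_dataframe().to_csv(f"{prefix}.csv", index=False)
        sidecar = dict(self.provenance)
        sidecar["failures"] = [list(f) for f in self.failures]
        Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def _cell_analytic(params: ScenarioParams, spec: ScanSpec) -> tuple[bool, bool, int]:
    diag = ass_condition(params, **spec.analytic_options)
    return diag.ass_exists, diag.boundary, diag.n_interior


def _cell_simulation(params: ScenarioParams, spec: ScanSpec) -> tuple[bool, bool, int]:
    initials = default_initial_grid(params, n_per_axis=spec.sim_initials)
    _, reps, _ = count_attractors(params, initials, **spec.sim_options)
    interior = sum(1 for r in reps if r.kind != "boundary")
    return interior >= 2, False, interior


def scan_ass_region(spec: ScanSpec) -> ScanResult:
    """Evaluate the ASS test on the full grid defined by ``spec``.

    Per-cell failures are recorded in ``ScanResult.failures`` (with the cell
    marked as boundary) rather than aborting the scan.
    """
    xs = spec.axis1.values
    ys = spec.axis2.values
    ass = np.zeros((xs.size, ys.size), dtype=bool)
    boundary = np.zeros_like(ass)
    n_eq = np.zeros(ass.shape, dtype=int)
    failures = []
    for i, xv in enumerate(xs):
        for j, yv in enumerate(ys):
            try:
                params = with_param(spec.base, spec.axis1.path, xv)
                params = with_param(params, spec.axis2.path, yv)
                if spec.mode == "analytic":
                    a, b, n = _cell_analytic(params, spec)
                else:
                    a, b, n = _cell_simulation(params, spec)
                ass[i, j], boundary[i, j], n_eq[i, j] = a, b, n
            except Exception as exc:  # noqa: BLE001 - per-cell diagnostics
                boundary[i, j] = True
                failures.append((i, j, f"{type(exc).__name__}: {exc}"))
    provenance = {
        "version": _pkg_version,
        "scenario": spec.base.scenario,
        "mode": spec.mode,
        "axis1": dataclasses.asdict(spec.axis1),
        "axis2": dataclasses.asdict(spec.axis2),
        "sim_initials": spec.sim_initials if spec.mode == "simulation" else None,
    }
    return ScanResult(
        x=xs, y=ys, ass=ass, boundary=boundary, n_equilibria=n_eq,
        failures=tuple(failures), provenance=provenance,
    )


def subsidy_variant_scan(spec: ScanSpec) -> ScanResult:
    """ASS map with allochthonous subsidy inputs on the axes.

    Identical machinery to :func:`scan_ass_region`; requires the base
    parameter set to flag at least one subsidized resource (the analytic
    cell test then falls back to dense ZNGI intersection).
    """
    base = spec.base
    if not getattr(base, "has_subsidy", False):
        raise ValueError("subsidy scan requires at least one subsidized resource")
    return scan_ass_region(spec)


@dataclass(frozen=True)
class HeterogeneousSearchResult:
    """Outcome of the juvenile-productivity heterogeneity sweep."""

    offsets: np.ndarray
    counts: np.ndarray  # interior attractor count per offset
    descriptors: tuple  # tuple (per offset) of attractor representatives
    provenance: dict

    @property
    def max_count(self) -> int:
        return int(np.max(self.counts))

    @property
    def best_offset(self) -> float:
        return float(self.offsets[int(np.argmax(self.counts))])


def _heterogeneity_probe_set(
    params: MultipleHabitatsParams, base_records
) -> list[np.ndarray]:
    """Initial conditions aimed at each plausible basin of a 2+2 habitat system.

    Seeds sit near the homogeneous system's interior equilibria (consumer
    abundances nudged by 1% so unstable equilibria shed rather than
    masquerade as attractors) plus two "depleted habitat" states in which
    one juvenile habitat's resource is grazed out and its juvenile class
    piles up — the configuration behind the mirrored juvenile-dominated
    states.
    """
    K_J = params.effective_K("J")
    K_A = params.effective_K("A")
    c_hi = params.r_J / params.a_J  # juvenile abundance that fully depletes R_J
    probes = []
    consumers = params.consumer_slice()
    for rec in (base_records[0], base_records[-1]) if base_records else ():
        s = rec.state.copy()
        s[consumers] *= 1.01
        probes.append(s)
    template = base_records[-1].state if base_records else params.pack_state(
        K_J.copy(), K_A.copy(), np.full(2, 0.05), np.full(2, 0.05)
    )
    for k in (0, 1):
        s = template.copy()
        s[k] = 0.02 * K_J[k]
        s[1 - k] = 0.9 * K_J[1 - k]
        s[4 + k] = 0.95 * c_hi
        s[5 - k] = 0.05 * c_hi
        probes.append(s)
    # one consumer-poor start to probe the adult-dominated / boundary basin
    probes.append(
        params.pack_state(K_J.copy(), K_A.copy(), np.full(2, 0.05), np.full(2, 0.05))
    )
    return probes


def heterogeneous_multistability_search(
    base: MultipleHabitatsParams,
    productivity_offsets,
    initial_set=None,
    *,
    cluster_rtol: float = 1e-2,
    cluster_atol: float = 1e-6,
    **find_kwargs,
) -> HeterogeneousSearchResult:
    """Sweep a productivity difference between the two juvenile habitats.

    For each offset ``delta`` the juvenile carrying capacities become
    ``(K_J + delta, K_J - delta)`` — total juvenile productivity is
    preserved so heterogeneity is isolated from total availability — and
    the attractors of the full system are censused from ``initial_set``
    (default: a probe set aimed at adult-dominated and habitat-1/2
    juvenile-dominated basins).  Counts exclude consumer-free states.
    """
    if not base.is_integer or round(base.n_J) != 2 or round(base.n_A) != 2:
        raise ValueError("the heterogeneity search is defined for n_J = n_A = 2")
    if not base.is_homogeneous:
        raise ValueError("the search base must be homogeneous; offsets supply heterogeneity")
    offsets = np.asarray(productivity_offsets, dtype=float)
    if np.any(np.abs(offsets) >= base.K_J):
        raise ValueError("offsets must keep both juvenile carrying capacities positive")
    from .equilibria import coexistence_equilibria

    base_records = coexistence_equilibria(base, classify=False)
    counts = np.zeros(offsets.size, dtype=int)
    all_reps = []
    for k, delta in enumerate(offsets):
        params = dataclasses.replace(
            base, K_J_override=np.array([base.K_J + delta, base.K_J - delta])
        )
        initials = (
            initial_set
            if initial_set is not None
            else _heterogeneity_probe_set(params, base_records)
        )
        _, reps, _ = count_attractors(
            params, initials, cluster_rtol=cluster_rtol, cluster_atol=cluster_atol,
            **find_kwargs,
        )
        interior = [r for r in reps if r.kind != "boundary"]
        counts[k] = len(interior)
        all_reps.append(tuple(interior))
    provenance = {
        "version": _pkg_version,
        "scenario": "multiple",
        "K_J": base.K_J,
        "K_A": base.K_A,
        "offsets": list(map(float, offsets)),
        "n_initials": len(initial_set) if initial_set is not None else 6,
    }
    return HeterogeneousSearchResult(
        offsets=offsets, counts=counts, descriptors=tuple(all_reps), provenance=provenance
    )
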