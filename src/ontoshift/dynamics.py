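"""Forward integration and attractor census.

Alternative stable states are diagnosed dynamically by integrating past a
transient window, measuring the system over a terminal window, and
clustering the time-averaged states reached from many initial conditions.
Time averages (not phases) identify attractors, because alternative states
are distinguished by which stage or habitat dominates on average, whether
the attractor is a point or a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models import MultipleHabitatsParams, ScenarioParams, resource_equilibrium, rhs

__all__ = [
    "Trajectory",
    "AttractorDescriptor",
    "IntegrationError",
    "integrate",
    "find_attractor",
    "count_attractors",
    "default_initial_grid",
]

#: components averaging below this level count as extinct
EXTINCTION_FLOOR = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last accepted state."""

    def __init__(self, message: str, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


@dataclass(frozen=True)
class Trajectory:
    """One integrated orbit: strictly increasing times, states row-per-time."""

    t: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]


@dataclass(frozen=True)
class AttractorDescriptor:
    """Long-run state summary used to distinguish alternative states."""

    kind: str  # "fixed-point" | "periodic-orbit" | "boundary"
    mean: np.ndarray
    amplitude: np.ndarray
    extinct: tuple
    converged: bool
    final_state: np.ndarray

    @property
    def consumer_free(self) -> bool:
        return self.kind == "boundary"


def integrate(
    params: ScenarioParams,
    initial,
    horizon: float,
    *,
    t_eval=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the scenario ODEs from ``initial`` for ``horizon`` time units.

    Output abundances are clipped at zero (adaptive steppers may undershoot
    by up to the local tolerance).
    """
    y0 = np.asarray(initial, dtype=float)
    if y0.size != params.state_size or y0.ndim != 1:
        raise ValueError(f"initial state must have length {params.state_size}")
    if np.any(y0 < 0):
        raise ValueError("initial abundances must be non-negative")
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    def fun(t, y):
        # negative excursions of the logistic term are dynamically explosive;
        # evaluate fluxes on the clipped state and relax undershoots back to 0
        yc = np.clip(y, 0.0, None)
        dy = rhs(params, yc, validate=False)
        neg = y < 0.0
        if np.any(neg):
            dy[neg] -= y[neg]
        return dy

    sol = solve_ivp(
        fun, (0.0, float(horizon)), y0, t_eval=t_eval, rtol=rtol, atol=atol, method=method
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed: {sol.message}",
            last_state=sol.y[:, -1] if sol.y.size else y0,
            last_time=sol.t[-1] if sol.t.size else 0.0,
        )
    return Trajectory(
        t=sol.t,
        y=np.clip(sol.y.T, 0.0, None),
        meta={"rtol": rtol, "atol": atol, "method": method, "nfev": sol.nfev},
    )


def _cycle_average(t: np.ndarray, y: np.ndarray, amplitude: np.ndarray):
    """Mean state over an integer number of oscillation periods.

    The period is read off the dominant (largest-amplitude) component as the
    average spacing of its upward mean-crossings; averaging between the
    first and last upward crossing removes the partial-period bias that a
    fixed-length window would leave on every component's mean.  Returns
    ``(mean, n_crossings)``; falls back to the plain window mean when fewer
    than three crossings are seen.
    """
    k = int(np.argmax(amplitude))
    s = y[:, k] - y[:, k].mean()
    up = np.nonzero((s[:-1] < 0) & (s[1:] >= 0))[0]
    if up.size < 3:
        return y.mean(axis=0), int(up.size)
    i0, i1 = up[0], up[-1]
    return y[i0:i1].mean(axis=0), int(up.size)


def find_attractor(
    params: ScenarioParams,
    initial,
    *,
    transient: float = 2000.0,
    window: float = 500.0,
    n_sample: int = 1001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    amplitude_tol: float = 1e-4,
    drift_tol: float = 1e-3,
    max_extensions: int = 2,
    extinction_floor: float = EXTINCTION_FLOOR,
) -> AttractorDescriptor:
    """Classify the long-run state reached from one initial condition.

    Integrates a transient window, then measures means and oscillation
    amplitudes over a terminal window.  Near-steady runs count as converged
    when the first- and second-half window means agree to ``drift_tol``
    (relative); oscillatory runs when the oscillation amplitude is
    stationary across the two half-windows and the mean is taken over an
    integer number of periods (see :func:`_cycle_average`).  Otherwise the
    transient is doubled up to ``max_extensions`` times and the descriptor
    is flagged non-converged if drift persists.  Kinds: ``boundary``
    (consumers extinct), ``fixed-point`` (amplitude below ``amplitude_tol``
    relative to the mean scale), else ``periodic-orbit``.
    """
    state = np.asarray(initial, dtype=float)
    span = transient
    converged = False
    for _ in range(max_extensions + 1):
        state = integrate(params, state, span, rtol=rtol, atol=atol).final_state
        t_eval = np.linspace(0.0, window, n_sample)
        traj = integrate(params, state, window, t_eval=t_eval, rtol=rtol, atol=atol)
        y = traj.y
        mean = y.mean(axis=0)
        amplitude = y.max(axis=0) - y.min(axis=0)
        scale = 1.0 + np.abs(mean)
        half = n_sample // 2
        if np.max(amplitude / scale) < amplitude_tol:
            drift = np.max(
                np.abs(y[:half].mean(axis=0) - y[half:].mean(axis=0)) / scale
            )
            if drift < drift_tol:
                converged = True
                break
        else:
            amp1 = y[:half].max(axis=0) - y[:half].min(axis=0)
            amp2 = y[half:].max(axis=0) - y[half:].min(axis=0)
            amp_drift = np.max(np.abs(amp1 - amp2) / scale)
            mean, n_cross = _cycle_average(t_eval, y, amplitude)
            if amp_drift < 0.05 * np.max(amplitude / scale) and n_cross >= 3:
                converged = True
                break
        state = traj.final_state
        span = transient

    mean = np.where(mean < extinction_floor, 0.0, mean)
    extinct = tuple(int(i) for i in np.nonzero(mean <= max(extinction_floor, 1e-6))[0])
    consumers = params.consumer_slice()
    consumer_mass = float(np.sum(mean[consumers]))
    if consumer_mass <= 1e-6:
        kind = "boundary"
    elif np.max(amplitude / (1.0 + np.abs(mean))) < amplitude_tol:
        kind = "fixed-point"
    else:
        kind = "periodic-orbit"
    return AttractorDescriptor(
        kind=kind,
        mean=mean,
        amplitude=amplitude,
        extinct=extinct,
        converged=converged,
        final_state=traj.final_state,
    )


def _same_attractor(a: np.ndarray, b: np.ndarray, rtol: float, atol: float) -> bool:
    return bool(np.all(np.abs(a - b) <= atol + rtol * np.maximum(np.abs(a), np.abs(b))))


def count_attractors(
    params: ScenarioParams,
    initial_set,
    *,
    cluster_rtol: float = 1e-2,
    cluster_atol: float = 1e-6,
    **find_kwargs,
):
    """Number of distinct attractors reached from a set of initial states.

    Descriptors are clustered greedily on their time-averaged states
    (per-component relative tolerance ``cluster_rtol`` with absolute floor
    ``cluster_atol``); non-converged runs are excluded from the count.

    Returns ``(count, representatives, labels)`` where ``labels[i]`` is the
    cluster index of initial ``i`` (-1 for non-converged runs) and
    ``representatives`` holds one descriptor per cluster.
    """
    initial_set = list(initial_set)
    if len(initial_set) < 2:
        raise ValueError("need at least two initial states to census attractors")
    descriptors = [find_attractor(params, y0, **find_kwargs) for y0 in initial_set]
    if not any(d.converged for d in descriptors):
        raise RuntimeError("no run converged; extend the transient window")
    representatives: list[AttractorDescriptor] = []
    labels = []
    for desc in descriptors:
        if not desc.converged:
            labels.append(-1)
            continue
        for k, rep in enumerate(representatives):
            if _same_attractor(desc.mean, rep.mean, cluster_rtol, cluster_atol):
                labels.append(k)
                break
        else:
            labels.append(len(representatives))
            representatives.append(desc)
    return len(representatives), representatives, labels


def default_initial_grid(
    params: ScenarioParams,
    n_per_axis: int = 10,
    c_min: float = 1e-2,
    c_max: float | None = None,
) -> list[np.ndarray]:
    """Log-spaced grid of initial conditions probing both basins.

    Resources start at their consumer-free equilibrium (carrying capacity,
    or ``I/l`` for a subsidized resource); total juvenile and adult
    abundances take every combination from a log-spaced grid on
    ``[c_min, c_max]`` (default upper end: twice the largest carrying
    capacity).  In the multiple-habitats model consumers are split evenly
    across habitats.
    """
    R_J0, R_A0 = resource_equilibrium(params, 0.0, 0.0)
    if c_max is None:
        c_max = 2.0 * float(max(np.max(R_J0), np.max(R_A0), 1.0))
    levels = np.geomspace(c_min, c_max, n_per_axis)
    grid = []
    for cj in levels:
        for ca in levels:
            if isinstance(params, MultipleHabitatsParams):
                nJ, nA = params._int_counts()
                state = params.pack_state(
                    R_J0, R_A0, np.full(nJ, cj / nJ), np.full(nA, ca / nA)
                )
            else:
                state = params.pack_state(R_J0, R_A0, cj, ca)
            grid.append(state)
    return grid
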