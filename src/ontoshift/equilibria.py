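"""Coexistence equilibria and the alternative-stable-states condition.

At a coexistence equilibrium the resources sit at their consumer-dependent
equilibria, so the whole system collapses onto the ``(C_J*, C_A*)`` plane.
Setting ``dC_A/dt = 0`` there gives the adult zero-net-growth isocline
(ZNGI_A, ``C_A*`` as a function of ``C_J*``) and ``d(C_J + C_A)/dt = 0``
gives the juvenile one (ZNGI_J, ``C_J*`` as a function of ``C_A*``).  For
purely logistic resources both isoclines are upward-convex quadratics
through the origin (quadratic-over-linear rational functions in the
resource-sharing model), so after removing the trivial intersection at the
origin the coexistence equilibria are the positive roots of a cubic

    F(C_J*) = L1 C_J*^3 + L2 C_J*^2 + L3 C_J* + L4 = 0.

Alternative stable states require three distinct real roots of ``F`` (cubic
discriminant > 0) that all map to strictly positive consumer and resource
abundances; when three interior equilibria exist, the middle one is a saddle
separating a juvenile-dominated from an adult-dominated attractor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq

from .models import (
    AdditionalResourcesParams,
    InterstageSharingParams,
    MultipleHabitatsParams,
    ScenarioParams,
    resource_equilibrium,
    rhs,
)

__all__ = [
    "ReducedPolynomial",
    "EquilibriumRecord",
    "AssDiagnostics",
    "zngi_adult",
    "zngi_juvenile",
    "reduced_cubic",
    "coexistence_equilibria",
    "ass_condition",
    "classify_stability",
    "stability_spectrum",
    "zngi_intersections",
]

#: default tolerance below which an eigenvalue real part counts as zero
STABILITY_TOL = 1e-6


# ---------------------------------------------------------------------------
# reduced cubic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReducedPolynomial:
    """Cubic ``F`` whose positive roots are the interior ``C_J*`` values.

    Coefficients are stored highest degree first:
    ``F(x) = lam1 x^3 + lam2 x^2 + lam3 x + lam4``.
    """

    lam1: float
    lam2: float
    lam3: float
    lam4: float
    scenario: str

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return ((self.lam1 * x + self.lam2) * x + self.lam3) * x + self.lam4

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in ascending order (numpy polynomial convention)."""
        return np.array([self.lam4, self.lam3, self.lam2, self.lam1])

    @property
    def scale(self) -> float:
        return float(np.max(np.abs(self.coefficients)))

    @property
    def degree(self) -> int:
        """Effective degree after stripping numerically-zero leading terms."""
        c = self.coefficients
        scale = self.scale
        if scale == 0.0:
            return 0
        nz = np.nonzero(np.abs(c) > 1e-14 * scale)[0]
        return int(nz[-1]) if nz.size else 0

    def discriminant(self) -> float:
        """Standard cubic discriminant; positive iff three distinct real roots."""
        l1, l2, l3, l4 = self.lam1, self.lam2, self.lam3, self.lam4
        return (
            18.0 * l1 * l2 * l3 * l4
            - 4.0 * l2**3 * l4
            + l2**2 * l3**2
            - 4.0 * l1 * l3**3
            - 27.0 * l1**2 * l4**2
        )

    def real_roots(self, merge_tol: float = 1e-7) -> list[tuple[float, int]]:
        """Real roots as ``(root, multiplicity)``, ascending.

        Degenerate leading coefficients (quadratic/linear cases) are handled
        by degree reduction; roots closer than ``merge_tol`` (relative) are
        merged and reported with multiplicity > 1.  The tolerance sits above
        the ~sqrt(machine epsilon) splitting that an exact double root picks
        up in floating point, so genuine folds are flagged rather than
        reported as two distinct equilibria.
        """
        deg = self.degree
        if deg == 0:
            return []
        c = self.coefficients[: deg + 1]
        roots = Polynomial(c).roots()
        real = sorted(
            float(r.real) for r in roots if abs(r.imag) <= 1e-7 * (1.0 + abs(r.real))
        )
        merged: list[tuple[float, int]] = []
        for r in real:
            if merged and abs(r - merged[-1][0]) <= merge_tol * (1.0 + abs(r)):
                prev, mult = merged[-1]
                merged[-1] = ((prev * mult + r) / (mult + 1), mult + 1)
            else:
                merged.append((r, 1))
        return merged


def _quad_zngi_coeffs(params) -> tuple[float, float, float, float]:
    """Coefficients (p, q, sigma, tau) of the two quadratic ZNGIs.

    ZNGI_A: ``d_A C_A = C_J (p - q C_J)``;
    ZNGI_J: ``d_J C_J = C_A (sigma - tau C_A)``.
    """
    if isinstance(params, AdditionalResourcesParams):
        if params.has_subsidy:
            raise ValueError(
                "subsidized resources make the ZNGIs non-polynomial; "
                "use the numeric intersection path"
            )
        w_J = params.b_J * params.a_J * params.K_J
        w_A = params.b_A * params.a_A * params.K_A
        p = float(np.sum(w_J))
        q = float(np.sum(w_J * params.a_J / params.r_J))
        sigma = float(np.sum(w_A)) - params.d_A
        tau = float(np.sum(w_A * params.a_A / params.r_A))
        return p, q, sigma, tau
    if isinstance(params, MultipleHabitatsParams):
        if not params.is_homogeneous:
            raise ValueError(
                "the symmetric ZNGI reduction requires homogeneous habitats"
            )
        ratio = params.n_J / params.n_A
        w_J = params.b_J * params.a_J * params.K_J
        w_A = params.b_A * params.a_A * params.K_A
        p = ratio * w_J
        q = p * params.a_J / params.r_J
        sigma = (w_A - params.d_A) / ratio
        tau = (w_A * params.a_A / params.r_A) / ratio
        return p, q, sigma, tau
    raise TypeError(f"no quadratic ZNGI form for {type(params).__name__}")


#: resource-depletion conventions for the sharing-model analysis.
#: "joint" solves the resource rows with both consumer stages grazing (exactly
#: consistent with the ODEs); "own-stage" is the classical approximation in
#: which each resource's equilibrium reflects only its major consumer stage,
#: i.e. R_J* = K_J (1 - a_JJ C_J / r_J) and R_A* = K_A (1 - a_AA C_A / r_A).
DEPLETION_MODES = ("joint", "own-stage")


def _check_depletion(params, depletion: str) -> None:
    if depletion not in DEPLETION_MODES:
        raise ValueError(f"depletion must be one of {DEPLETION_MODES}")
    if depletion != "joint" and not isinstance(params, InterstageSharingParams):
        raise ValueError("the own-stage depletion convention only applies to the sharing model")


def _sharing_alpha(
    params: InterstageSharingParams, depletion: str = "joint"
) -> tuple[float, float, float]:
    """Juvenile intake at resource equilibrium: ``alpha0 + aJ*C_J + aA*C_A``."""
    wJJ = params.b_JJ * params.a_JJ * params.K_J
    wJA = params.b_JA * params.a_JA * params.K_A
    alpha0 = wJJ + wJA
    if depletion == "joint":
        alpha_J = -(wJJ * params.a_JJ / params.r_J + wJA * params.a_JA / params.r_A)
        alpha_A = -(wJJ * params.a_AJ / params.r_J + wJA * params.a_AA / params.r_A)
    else:
        alpha_J = -wJJ * params.a_JJ / params.r_J
        alpha_A = -wJA * params.a_AA / params.r_A
    return alpha0, alpha_J, alpha_A


def _sharing_beta(
    params: InterstageSharingParams, depletion: str = "joint"
) -> tuple[float, float, float]:
    """Adult intake at resource equilibrium: ``beta0 + bJ*C_J + bA*C_A``."""
    wAA = params.b_AA * params.a_AA * params.K_A
    wAJ = params.b_AJ * params.a_AJ * params.K_J
    beta0 = wAA + wAJ
    if depletion == "joint":
        beta_J = -(wAA * params.a_JA / params.r_A + wAJ * params.a_JJ / params.r_J)
        beta_A = -(wAA * params.a_AA / params.r_A + wAJ * params.a_AJ / params.r_J)
    else:
        beta_J = -wAJ * params.a_JJ / params.r_J
        beta_A = -wAA * params.a_AA / params.r_A
    return beta0, beta_J, beta_A


def _sharing_resources(
    params: InterstageSharingParams, C_J: float, C_A: float, depletion: str
):
    """Sharing-model resource equilibria under either depletion convention."""
    if depletion == "joint":
        return resource_equilibrium(params, C_J, C_A)
    R_J = params.K_J * (1.0 - params.a_JJ * C_J / params.r_J)
    R_A = params.K_A * (1.0 - params.a_AA * C_A / params.r_A)
    return np.array([R_J]), np.array([R_A])


def zngi_adult(params: ScenarioParams, C_J, depletion: str = "joint"):
    """Adult isocline: ``C_A*`` such that ``dC_A/dt = 0`` at resource equilibrium.

    For stage-specific diets this is an upward-convex quadratic through the
    origin; for the sharing model it is a rational function whose numerator
    is an upward-convex quadratic and whose denominator increases linearly.
    Accepts scalars or arrays.
    """
    C_J = np.asarray(C_J, dtype=float)
    scalar = C_J.ndim == 0
    c = np.atleast_1d(C_J)
    if np.any(c < 0):
        raise ValueError("C_J must be non-negative")
    _check_depletion(params, depletion)
    if isinstance(params, InterstageSharingParams):
        alpha0, alpha_J, alpha_A = _sharing_alpha(params, depletion)
        denom = params.d_A - alpha_A * c
        if np.any(denom <= 0):
            raise ValueError("outside the feasible region: ZNGI_A denominator <= 0")
        out = c * (alpha0 + alpha_J * c) / denom
    elif isinstance(params, AdditionalResourcesParams) and params.has_subsidy:
        cc = c[:, None]
        logistic = params.K_J * (1.0 - params.a_J * cc / params.r_J)
        denom = params.loss_J + params.a_J * cc
        with np.errstate(divide="ignore", invalid="ignore"):
            donor = np.where(denom > 0, params.input_J / np.where(denom > 0, denom, 1.0), 0.0)
        donor = np.where(params.input_J == 0.0, 0.0, donor)
        R_J = np.where(params.subsidized_J, donor, logistic)
        out = c * np.sum(params.b_J * params.a_J * R_J, axis=1) / params.d_A
    else:
        p, q, _, _ = _quad_zngi_coeffs(params)
        d_A = params.d_A
        out = c * (p - q * c) / d_A
    return float(out[0]) if scalar else out


def zngi_juvenile(params: ScenarioParams, C_A, depletion: str = "joint"):
    """Juvenile isocline: ``C_J*`` from ``d(C_J + C_A)/dt = 0`` at resource equilibrium."""
    C_A = np.asarray(C_A, dtype=float)
    scalar = C_A.ndim == 0
    c = np.atleast_1d(C_A)
    if np.any(c < 0):
        raise ValueError("C_A must be non-negative")
    _check_depletion(params, depletion)
    if isinstance(params, InterstageSharingParams):
        beta0, beta_J, beta_A = _sharing_beta(params, depletion)
        denom = params.d_J - beta_J * c
        if np.any(denom <= 0):
            raise ValueError("outside the feasible region: ZNGI_J denominator <= 0")
        out = c * (beta0 - params.d_A + beta_A * c) / denom
    elif isinstance(params, AdditionalResourcesParams) and params.has_subsidy:
        cc = c[:, None]
        logistic = params.K_A * (1.0 - params.a_A * cc / params.r_A)
        denom = params.loss_A + params.a_A * cc
        with np.errstate(divide="ignore", invalid="ignore"):
            donor = np.where(denom > 0, params.input_A / np.where(denom > 0, denom, 1.0), 0.0)
        donor = np.where(params.input_A == 0.0, 0.0, donor)
        R_A = np.where(params.subsidized_A, donor, logistic)
        intake = np.sum(params.b_A * params.a_A * R_A, axis=1)
        out = c * (intake - params.d_A) / params.d_J
    else:
        _, _, sigma, tau = _quad_zngi_coeffs(params)
        out = c * (sigma - tau * c) / params.d_J
    return float(out[0]) if scalar else out


def reduced_cubic(params: ScenarioParams, depletion: str = "joint") -> ReducedPolynomial:
    """Cubic obtained by composing ZNGI_A into ZNGI_J and removing the trivial root.

    For quadratic ZNGIs (``d_A C_A = C_J (p - q C_J)`` and
    ``d_J C_J = C_A (sigma - tau C_A)``) the coefficients are closed-form::

        L1 = -tau q^2,  L2 = 2 tau p q,
        L3 = -(tau p^2 + q sigma d_A),  L4 = p sigma d_A - d_J d_A^2.

    For the sharing model the rational isoclines are cleared of their
    denominators and composed by polynomial arithmetic, then the trivial
    factor ``C_J`` is removed.
    """
    _check_depletion(params, depletion)
    if isinstance(params, InterstageSharingParams):
        alpha0, alpha_J, alpha_A = _sharing_alpha(params, depletion)
        beta0, beta_J, beta_A = _sharing_beta(params, depletion)
        w = Polynomial([alpha0, alpha_J])  # ZNGI_A numerator / C_J
        v = Polynomial([params.d_A, -alpha_A])  # ZNGI_A denominator
        x = Polynomial([0.0, 1.0])
        cubic = (
            w * v * (beta0 - params.d_A + beta_J * x)
            + beta_A * x * w**2
            - params.d_J * v**2
        )
        c = np.zeros(4)
        c[: cubic.coef.size] = cubic.coef
        return ReducedPolynomial(
            lam1=float(c[3]), lam2=float(c[2]), lam3=float(c[1]), lam4=float(c[0]),
            scenario=params.scenario,
        )
    p, q, sigma, tau = _quad_zngi_coeffs(params)
    d_A, d_J = params.d_A, params.d_J
    return ReducedPolynomial(
        lam1=-tau * q**2,
        lam2=2.0 * tau * p * q,
        lam3=-(tau * p**2 + q * sigma * d_A),
        lam4=p * sigma * d_A - d_J * d_A**2,
        scenario=params.scenario,
    )


# ---------------------------------------------------------------------------
# numeric ZNGI intersection (oracle / subsidy path)
# ---------------------------------------------------------------------------


def _cj_upper_bound(params: ScenarioParams) -> float:
    """Upper end of the ``C_J`` search interval for isocline intersections.

    Intersections with positive consumer abundances require the adult
    isocline to stay positive, which bounds ``C_J`` by the isocline's
    nontrivial zero; subsidized systems (positive isocline everywhere) are
    instead bounded by resource feasibility.
    """
    bounds = []
    if isinstance(params, AdditionalResourcesParams):
        if params.has_subsidy:
            logistic = ~params.subsidized_J
            if np.any(logistic):
                bounds.append(
                    float(np.min(params.r_J[logistic] / params.a_J[logistic]))
                )
        else:
            p, q, _, _ = _quad_zngi_coeffs(params)
            if q > 0:
                bounds.append(p / q)
    elif isinstance(params, MultipleHabitatsParams):
        p, q, _, _ = _quad_zngi_coeffs(params)
        if q > 0:
            bounds.append(p / q)
    elif isinstance(params, InterstageSharingParams):
        alpha0, alpha_J, _ = _sharing_alpha(params)
        if alpha_J < 0:
            bounds.append(-alpha0 / alpha_J)
    if not bounds:
        bounds.append(1e3)
    return min(bounds)


def zngi_intersections(
    params: ScenarioParams,
    n_grid: int = 4001,
    merge_tol: float = 1e-8,
) -> list[float]:
    """Positive ``C_J*`` values where the two ZNGI curves intersect.

    Brute-force alternative to :func:`reduced_cubic`: evaluates the fixed
    point residual ``zngi_juvenile(zngi_adult(C_J)) - C_J`` on a dense grid
    over the feasible interval and polishes each sign change by bisection.
    Also the only equilibrium path available when subsidized resources make
    the isoclines non-polynomial.
    """
    c_max = _cj_upper_bound(params)
    lo = 1e-8 * c_max

    def residual(c: float) -> float:
        ca = zngi_adult(params, c)
        if not np.isfinite(ca) or ca <= 0:
            # no feasible adult abundance here; signed surrogate keeps
            # bracketing sane near the boundary C_A -> 0+
            return -c
        return zngi_juvenile(params, ca) - c

    grid = np.linspace(lo, c_max * (1.0 - 1e-12), n_grid)
    ca = zngi_adult(params, grid)
    ok = np.isfinite(ca) & (ca > 0)
    vals = np.where(ok, np.nan, -grid)
    if np.any(ok):
        vals[ok] = zngi_juvenile(params, ca[ok]) - grid[ok]
    roots: list[float] = []
    for i in range(len(grid) - 1):
        f0, f1 = vals[i], vals[i + 1]
        if f0 == 0.0:
            roots.append(float(grid[i]))
        elif f0 * f1 < 0:
            roots.append(float(brentq(residual, grid[i], grid[i + 1], xtol=1e-13)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or abs(r - merged[-1]) > merge_tol * (1.0 + abs(r)):
            merged.append(r)
    return merged


# ---------------------------------------------------------------------------
# equilibrium records and stability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EquilibriumRecord:
    """One interior (coexistence) equilibrium."""

    C_J: float
    C_A: float
    R_J: np.ndarray
    R_A: np.ndarray
    state: np.ndarray
    residual: float
    stability: str | None = None
    leading_eigenvalue: float | None = None

    def to_dict(self) -> dict:
        return {
            "C_J": self.C_J,
            "C_A": self.C_A,
            "R_J": list(np.atleast_1d(self.R_J)),
            "R_A": list(np.atleast_1d(self.R_A)),
            "residual": self.residual,
            "stability": self.stability,
            "leading_eigenvalue": self.leading_eigenvalue,
        }


def _symmetric_multiple_rhs(params: MultipleHabitatsParams) -> Callable:
    """Mean-field 4-component system exact on the symmetric subspace.

    Valid for non-integer habitat counts; state is
    ``[R_J, R_A, C_J, C_A]`` with per-habitat abundances.
    """
    ratio = params.n_J / params.n_A

    def fn(y: np.ndarray) -> np.ndarray:
        R_J, R_A, C_J, C_A = y
        dR_J = params.r_J * R_J * (1 - R_J / params.K_J) - params.a_J * R_J * C_J
        dR_A = params.r_A * R_A * (1 - R_A / params.K_A) - params.a_A * R_A * C_A
        mat = params.b_J * params.a_J * R_J * C_J
        rep = params.b_A * params.a_A * R_A * C_A
        dC_J = rep / ratio - mat - params.d_J * C_J
        dC_A = ratio * mat - params.d_A * C_A
        return np.array([dR_J, dR_A, dC_J, dC_A])

    return fn


def _equilibrium_rhs(params: ScenarioParams) -> Callable:
    """Right-hand side used for residuals/Jacobians of equilibrium states."""
    if isinstance(params, MultipleHabitatsParams) and not params.is_integer:
        return _symmetric_multiple_rhs(params)
    return lambda y: rhs(params, y, validate=False)


def _full_state(params: ScenarioParams, c_J: float, c_A: float, R_J, R_A) -> np.ndarray:
    if isinstance(params, MultipleHabitatsParams):
        if params.is_integer:
            nJ, nA = int(round(params.n_J)), int(round(params.n_A))
            return params.pack_state(
                np.broadcast_to(R_J, (nJ,)).copy(),
                np.broadcast_to(R_A, (nA,)).copy(),
                np.full(nJ, c_J),
                np.full(nA, c_A),
            )
        return np.array([float(np.atleast_1d(R_J)[0]), float(np.atleast_1d(R_A)[0]), c_J, c_A])
    return params.pack_state(R_J, R_A, c_J, c_A)


def _numerical_jacobian(fn: Callable, y: np.ndarray, rel_step: float = 1e-7) -> np.ndarray:
    n = y.size
    J = np.empty((n, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(y[i]))
        e = np.zeros(n)
        e[i] = h
        J[:, i] = (fn(y + e) - fn(y - e)) / (2.0 * h)
    return J


def stability_spectrum(params: ScenarioParams, state: np.ndarray) -> np.ndarray:
    """Jacobian eigenvalues of the scenario dynamics at ``state``.

    The Jacobian is formed by central finite differences; for non-integer
    habitat counts the symmetric mean-field system is used (transverse
    habitat modes are then not represented).
    """
    fn = _equilibrium_rhs(params)
    y = np.asarray(state, dtype=float)
    return np.linalg.eigvals(_numerical_jacobian(fn, y))


def classify_stability(
    params: ScenarioParams, record, tol: float = STABILITY_TOL
) -> str:
    """Local stability label from the sign of the leading eigenvalue real part.

    ``record`` may be an :class:`EquilibriumRecord` or a bare state vector.
    Labels: ``stable-node``/``stable-focus``, ``unstable``,
    ``non-hyperbolic`` (|max Re| below ``tol``).
    """
    state = record.state if isinstance(record, EquilibriumRecord) else np.asarray(record, float)
    eig = stability_spectrum(params, state)
    leading = eig[np.argmax(eig.real)]
    if leading.real > tol:
        return "unstable"
    if leading.real < -tol:
        return "stable-focus" if abs(leading.imag) > tol else "stable-node"
    return "non-hyperbolic"


def coexistence_equilibria(
    params: ScenarioParams,
    *,
    classify: bool = True,
    residual_tol: float = 1e-8,
    positive_tol: float = 1e-9,
    merge_tol: float = 1e-9,
) -> list[EquilibriumRecord]:
    """All interior equilibria (0-3), sorted by ``C_J*``.

    Candidates come from the reduced cubic (or, with subsidized resources,
    from dense numeric ZNGI intersection); each is mapped through the adult
    isocline and the resource equilibria, kept only if every abundance is
    strictly positive, and verified against the full right-hand side.
    """
    if isinstance(params, MultipleHabitatsParams) and not params.is_homogeneous:
        raise ValueError(
            "heterogeneous habitats have no symmetric reduction; "
            "use the dynamics module to enumerate attractors"
        )
    use_numeric = isinstance(params, AdditionalResourcesParams) and params.has_subsidy
    if use_numeric:
        candidates: list[tuple[float, int]] = [(c, 1) for c in zngi_intersections(params)]
    else:
        candidates = reduced_cubic(params).real_roots(merge_tol=merge_tol)

    fn = _equilibrium_rhs(params)
    records: list[EquilibriumRecord] = []
    for c_J, mult in candidates:
        if not np.isfinite(c_J) or c_J <= positive_tol:
            continue
        try:
            c_A = zngi_adult(params, c_J)
        except ValueError:
            continue
        if not np.isfinite(c_A) or c_A <= positive_tol:
            continue
        R_J, R_A = resource_equilibrium(params, c_J, c_A)
        if not _resources_positive(params, R_J, R_A, positive_tol):
            continue
        state = _full_state(params, c_J, c_A, R_J, R_A)
        residual = float(np.max(np.abs(fn(state))))
        if residual > residual_tol * max(1.0, float(np.max(np.abs(state)))):
            continue
        stability = None
        leading = None
        if classify:
            eig = stability_spectrum(params, state)
            lead = eig[np.argmax(eig.real)]
            leading = float(lead.real)
            if mult > 1:
                stability = "non-hyperbolic"
            elif lead.real > STABILITY_TOL:
                stability = "unstable"
            elif lead.real < -STABILITY_TOL:
                stability = "stable-focus" if abs(lead.imag) > STABILITY_TOL else "stable-node"
            else:
                stability = "non-hyperbolic"
        records.append(
            EquilibriumRecord(
                C_J=float(c_J),
                C_A=float(c_A),
                R_J=np.atleast_1d(R_J),
                R_A=np.atleast_1d(R_A),
                state=state,
                residual=residual,
                stability=stability,
                leading_eigenvalue=leading,
            )
        )
    records.sort(key=lambda r: r.C_J)
    return records


# ---------------------------------------------------------------------------
# ASS condition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssDiagnostics:
    """Outcome of the alternative-stable-states test at one parameter point."""

    ass_exists: bool
    boundary: bool
    discriminant: float
    lam1: float
    n_interior: int
    root_flags: tuple
    #: interior C_J* values (positive, feasible); length == n_interior
    interior_C_J: tuple

    @property
    def lam1_sign(self) -> int:
        if np.isnan(self.lam1):
            return 0
        return int(np.sign(self.lam1))



def _positive_resource_masks(params: ScenarioParams):
    """Which resources must be strictly positive at a coexistence equilibrium.

    A subsidized resource with zero input is structurally absent (it sits at
    exactly zero) and is excluded from the requirement.
    """
    if isinstance(params, AdditionalResourcesParams):
        m_J = ~(params.subsidized_J & (params.input_J == 0.0))
        m_A = ~(params.subsidized_A & (params.input_A == 0.0))
        return m_J, m_A
    return None, None


def _resources_positive(params, R_J, R_A, tol: float) -> bool:
    m_J, m_A = _positive_resource_masks(params)
    R_J = np.atleast_1d(R_J)
    R_A = np.atleast_1d(R_A)
    ok_J = np.all(R_J[m_J] > tol) if m_J is not None else np.all(R_J > tol)
    ok_A = np.all(R_A[m_A] > tol) if m_A is not None else np.all(R_A > tol)
    neg_J = np.any(R_J < -tol) if m_J is not None else False
    neg_A = np.any(R_A < -tol) if m_A is not None else False
    return bool(ok_J and ok_A and not neg_J and not neg_A)


def _root_feasibility(params: ScenarioParams, c_J: float, depletion: str) -> dict:
    """Positivity flags for one candidate root of the reduced cubic."""
    entry = {"C_J": float(c_J), "C_J_pos": c_J > 0, "C_A_pos": False, "R_pos": False}
    if c_J <= 0:
        return entry
    try:
        c_A = zngi_adult(params, c_J, depletion=depletion)
    except ValueError:
        return entry
    entry["C_A_pos"] = bool(np.isfinite(c_A) and c_A > 0)
    if entry["C_A_pos"]:
        if isinstance(params, InterstageSharingParams):
            R_J, R_A = _sharing_resources(params, c_J, c_A, depletion)
        else:
            R_J, R_A = resource_equilibrium(params, c_J, c_A)
        entry["R_pos"] = _resources_positive(params, R_J, R_A, 0.0)
    return entry


def ass_condition(
    params: ScenarioParams,
    *,
    boundary_tol: float = 1e-12,
    depletion: str = "joint",
    require_resource_positivity: bool = True,
) -> AssDiagnostics:
    """Do alternative stable states exist at this parameter point?

    True iff the reduced cubic has three distinct real roots (discriminant
    > 0) that all map to strictly positive juvenile, adult and resource
    abundances.  This counts candidate equilibria; it is a necessary, not
    sufficient, condition for dynamical bistability (the outer equilibria
    may shed their stability to surrounding or remote attractors, which
    only the dynamics module can decide).

    Near-degenerate discriminants (|disc| below ``boundary_tol`` times the
    fourth power of the coefficient scale) raise the ``boundary`` flag so
    region maps can exclude ambiguous cells.  ``depletion`` selects the
    resource-equilibrium convention for the sharing model (see
    :data:`DEPLETION_MODES`).

    With ``require_resource_positivity=False`` a candidate counts as long
    as its consumer abundances are positive, even if a mapped resource
    abundance is negative.  Such candidates are not coexistence equilibria
    of the full system — they shadow states in which a resource has been
    excluded by apparent competition — but counting them reproduces the
    classical sign-condition treatment of the cubic, which in the sharing
    model is what restores the three-candidate region when both
    cross-feeding rates are very large.
    """
    _check_depletion(params, depletion)
    use_numeric = isinstance(params, AdditionalResourcesParams) and params.has_subsidy
    if use_numeric:
        disc = float("nan")
        lam1 = float("nan")
        boundary = False
        candidates = [(c, 1) for c in zngi_intersections(params)]
        three_real = None  # decided by the feasible-root count below
    else:
        poly = reduced_cubic(params, depletion=depletion)
        disc = poly.discriminant()
        lam1 = poly.lam1
        scale = poly.scale
        boundary = bool(scale > 0 and abs(disc) < boundary_tol * scale**4)
        three_real = poly.degree == 3 and disc > 0
        candidates = poly.real_roots()

    flags = []
    interior = []
    for c_J, mult in candidates:
        entry = _root_feasibility(params, c_J, depletion)
        flags.append(entry)
        feasible = entry["C_J_pos"] and entry["C_A_pos"]
        if require_resource_positivity:
            feasible = feasible and entry["R_pos"]
        if feasible:
            interior.append(c_J)  # merged multiple roots count once
    if three_real is None:
        three_real = len(interior) == 3

    ass = bool(three_real and len(interior) == 3)
    return AssDiagnostics(
        ass_exists=ass,
        boundary=boundary,
        discriminant=disc,
        lam1=lam1,
        n_interior=len(interior),
        root_flags=tuple(flags),
        interior_C_J=tuple(interior),
    )
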