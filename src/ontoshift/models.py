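"""Stage-structured consumer-resource models coupled by an ontogenetic niche shift.

A single consumer population is split into juveniles (``C_J``) and adults
(``C_A``).  Resources grow logistically, all trophic interactions are linear
(mass action), and both maturation (juvenile -> adult) and reproduction
(adult -> juvenile) are proportional to food intake.  Three variants of
multiple resource use are provided:

``additional``
    Juveniles and adults each feed on several resources in their own habitat
    (:class:`AdditionalResourcesParams`).  Any resource may optionally be an
    allochthonous subsidy with donor-controlled dynamics ``dR/dt = I - l R``
    instead of logistic self-renewal.
``multiple``
    Juveniles and adults each colonize several identical habitats, one
    resource per habitat; colonization is random, so each maturation or
    reproduction flow is split evenly across the destination habitats
    (:class:`MultipleHabitatsParams`).
``sharing``
    One juvenile and one adult resource, but each stage can also exploit the
    major resource of the other stage (:class:`InterstageSharingParams`).

State vectors follow a fixed ordering convention so that serialized
trajectories are comparable across runs: all juvenile-habitat resources (by
index), then all adult-habitat resources, then juvenile consumer classes,
then adult consumer classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "SCENARIOS",
    "PANELS",
    "AdditionalResourcesParams",
    "MultipleHabitatsParams",
    "InterstageSharingParams",
    "ScenarioParams",
    "rhs",
    "rhs_additional",
    "rhs_multiple",
    "rhs_sharing",
    "resource_equilibrium",
    "default_params",
]

SCENARIOS = ("additional", "multiple", "sharing")
PANELS = ("left", "center", "right")


def _as_vector(x, n: int | None, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float)).copy()
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if n is not None and arr.size != n:
        raise ValueError(f"{name} must have length {n}, got {arr.size}")
    return arr


def _check_positive(arr: np.ndarray, name: str) -> None:
    if not np.all(arr > 0):
        raise ValueError(f"all entries of {name} must be strictly positive")


def _check_unit(arr: np.ndarray, name: str) -> None:
    if not np.all((arr > 0) & (arr <= 1.0)):
        raise ValueError(f"all entries of {name} must lie in (0, 1]")


def _freeze(obj, **arrays) -> None:
    for key, val in arrays.items():
        val.setflags(write=False)
        object.__setattr__(obj, key, val)


@dataclass(frozen=True)
class AdditionalResourcesParams:
    """Parameters for the additional-resources model.

    Each stage ``h`` (juvenile ``J`` or adult ``A``) feeds on ``n_h``
    resources ``R_h,i`` with intrinsic growth rate ``r_h[i]``, carrying
    capacity ``K_h[i]``, consumption rate ``a_h[i]`` and conversion
    efficiency ``b_h[i]``; ``d_J``/``d_A`` are stage death rates.

    Setting ``subsidized_J[i]`` (or ``_A``) turns resource ``i`` into an
    allochthonous subsidy with input rate ``input_*[i]`` and loss rate
    ``loss_*[i]``; its logistic term is replaced by ``I - l R``.
    """

    r_J: np.ndarray
    K_J: np.ndarray
    a_J: np.ndarray
    b_J: np.ndarray
    r_A: np.ndarray
    K_A: np.ndarray
    a_A: np.ndarray
    b_A: np.ndarray
    d_J: float = 0.1
    d_A: float = 0.1
    subsidized_J: np.ndarray = None
    input_J: np.ndarray = None
    loss_J: np.ndarray = None
    subsidized_A: np.ndarray = None
    input_A: np.ndarray = None
    loss_A: np.ndarray = None

    def __post_init__(self) -> None:
        r_J = _as_vector(self.r_J, None, "r_J")
        n_J = r_J.size
        r_A = _as_vector(self.r_A, None, "r_A")
        n_A = r_A.size
        arrays = {"r_J": r_J, "r_A": r_A}
        for stage, n in (("J", n_J), ("A", n_A)):
            for key in ("K", "a", "b"):
                name = f"{key}_{stage}"
                arrays[name] = _as_vector(getattr(self, name), n, name)
            for key, default in (
                ("subsidized", False),
                ("input", 0.0),
                ("loss", 0.0),
            ):
                name = f"{key}_{stage}"
                val = getattr(self, name)
                if val is None:
                    val = np.full(n, default)
                name_arr = _as_vector(val, n, name)
                arrays[name] = name_arr
        arrays["subsidized_J"] = arrays["subsidized_J"].astype(bool)
        arrays["subsidized_A"] = arrays["subsidized_A"].astype(bool)
        for stage in ("J", "A"):
            for key in ("r", "K", "a"):
                _check_positive(arrays[f"{key}_{stage}"], f"{key}_{stage}")
            _check_unit(arrays[f"b_{stage}"], f"b_{stage}")
            sub = arrays[f"subsidized_{stage}"]
            inp = arrays[f"input_{stage}"]
            loss = arrays[f"loss_{stage}"]
            if np.any(inp < 0) or np.any(loss < 0):
                raise ValueError("subsidy input and loss rates must be non-negative")
            if np.any(sub & (inp > 0) & (loss <= 0)):
                raise ValueError(
                    "a subsidized resource with positive input needs a positive loss rate"
                )
        if self.d_J <= 0 or self.d_A <= 0:
            raise ValueError("death rates d_J, d_A must be strictly positive")
        _freeze(self, **arrays)

    @property
    def scenario(self) -> str:
        return "additional"

    @property
    def n_J(self) -> int:
        return self.r_J.size

    @property
    def n_A(self) -> int:
        return self.r_A.size

    @property
    def has_subsidy(self) -> bool:
        return bool(np.any(self.subsidized_J) or np.any(self.subsidized_A))

    @property
    def state_size(self) -> int:
        return self.n_J + self.n_A + 2

    def split_state(self, y: np.ndarray):
        """Split a state vector into (R_J, R_A, C_J, C_A)."""
        y = np.asarray(y, dtype=float)
        nJ, nA = self.n_J, self.n_A
        return y[:nJ], y[nJ : nJ + nA], y[nJ + nA], y[nJ + nA + 1]

    def pack_state(self, R_J, R_A, C_J, C_A) -> np.ndarray:
        return np.concatenate(
            [np.atleast_1d(R_J), np.atleast_1d(R_A), [float(C_J)], [float(C_A)]]
        )

    def consumer_slice(self) -> slice:
        return slice(self.n_J + self.n_A, self.state_size)


@dataclass(frozen=True)
class MultipleHabitatsParams:
    """Parameters for the multiple-habitats model.

    ``n_J`` and ``n_A`` juvenile/adult habitats each hold one resource; all
    juvenile (or adult) habitats share identical rates ``r_h, K_h, a_h, b_h``.
    Maturation out of each juvenile habitat is split evenly across the
    ``n_A`` adult habitats and reproduction evenly across the ``n_J``
    juvenile habitats (random colonization).  ``n_J``/``n_A`` may be
    non-integer for the analytic (symmetric, mean-field) branch; simulation
    requires integers.  ``K_J_override``/``K_A_override`` introduce
    per-habitat productivity heterogeneity.
    """

    n_J: float = 2
    n_A: float = 2
    r_J: float = 1.0
    K_J: float = 10.0
    a_J: float = 0.1
    b_J: float = 0.5
    r_A: float = 1.0
    K_A: float = 10.0
    a_A: float = 0.1
    b_A: float = 0.5
    d_J: float = 0.1
    d_A: float = 0.1
    K_J_override: np.ndarray = None
    K_A_override: np.ndarray = None

    def __post_init__(self) -> None:
        for name in ("n_J", "n_A", "r_J", "K_J", "a_J", "r_A", "K_A", "a_A", "d_J", "d_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("b_J", "b_A"):
            val = getattr(self, name)
            if not 0 < val <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        arrays = {}
        for stage in ("J", "A"):
            name = f"K_{stage}_override"
            val = getattr(self, name)
            if val is not None:
                n = getattr(self, f"n_{stage}")
                if abs(n - round(n)) > 1e-9:
                    raise ValueError(
                        f"{name} requires an integer habitat count n_{stage}"
                    )
                arr = _as_vector(val, int(round(n)), name)
                _check_positive(arr, name)
                arrays[name] = arr
        _freeze(self, **arrays)

    @property
    def scenario(self) -> str:
        return "multiple"

    @property
    def is_integer(self) -> bool:
        return (
            abs(self.n_J - round(self.n_J)) < 1e-9
            and abs(self.n_A - round(self.n_A)) < 1e-9
        )

    def _int_counts(self) -> tuple[int, int]:
        if not self.is_integer:
            raise ValueError(
                "habitat counts must be integers for the full dynamical system; "
                f"got n_J={self.n_J}, n_A={self.n_A}"
            )
        return int(round(self.n_J)), int(round(self.n_A))

    def effective_K(self, stage: str) -> np.ndarray:
        """Per-habitat carrying capacities (overrides applied)."""
        nJ, nA = self._int_counts()
        n = nJ if stage == "J" else nA
        override = getattr(self, f"K_{stage}_override")
        if override is not None:
            return override
        return np.full(n, getattr(self, f"K_{stage}"))

    @property
    def is_homogeneous(self) -> bool:
        return self.K_J_override is None and self.K_A_override is None

    @property
    def state_size(self) -> int:
        nJ, nA = self._int_counts()
        return 2 * (nJ + nA)

    def split_state(self, y: np.ndarray):
        """Split a state vector into (R_J, R_A, C_J, C_A) habitat arrays."""
        y = np.asarray(y, dtype=float)
        nJ, nA = self._int_counts()
        return (
            y[:nJ],
            y[nJ : nJ + nA],
            y[nJ + nA : 2 * nJ + nA],
            y[2 * nJ + nA :],
        )

    def pack_state(self, R_J, R_A, C_J, C_A) -> np.ndarray:
        return np.concatenate(
            [np.atleast_1d(R_J), np.atleast_1d(R_A), np.atleast_1d(C_J), np.atleast_1d(C_A)]
        )

    def consumer_slice(self) -> slice:
        nJ, nA = self._int_counts()
        return slice(nJ + nA, 2 * (nJ + nA))


@dataclass(frozen=True)
class InterstageSharingParams:
    """Parameters for the interstage resource-sharing model.

    One juvenile resource ``R_J`` and one adult resource ``R_A``; stage
    ``h`` consumes resource ``i`` at rate ``a_hi`` with conversion ``b_hi``.
    Own-resource rates ``a_JJ``/``a_AA`` are required positive; cross rates
    ``a_JA`` (juveniles on the adult resource) and ``a_AJ`` (adults on the
    juvenile resource) may be zero, recovering fully stage-specific diets.
    """

    r_J: float = 1.0
    K_J: float = 15.0
    r_A: float = 1.0
    K_A: float = 15.0
    a_JJ: float = 0.1
    a_JA: float = 0.0
    a_AJ: float = 0.0
    a_AA: float = 0.1
    b_JJ: float = 0.5
    b_JA: float = 0.5
    b_AJ: float = 0.5
    b_AA: float = 0.5
    d_J: float = 0.1
    d_A: float = 0.1

    def __post_init__(self) -> None:
        for name in ("r_J", "K_J", "r_A", "K_A", "a_JJ", "a_AA", "d_J", "d_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("a_JA", "a_AJ"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("b_JJ", "b_JA", "b_AJ", "b_AA"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @property
    def scenario(self) -> str:
        return "sharing"

    @property
    def state_size(self) -> int:
        return 4

    def split_state(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        return y[0], y[1], y[2], y[3]

    def pack_state(self, R_J, R_A, C_J, C_A) -> np.ndarray:
        return np.array(
            [np.ravel(R_J)[0], np.ravel(R_A)[0], float(C_J), float(C_A)], dtype=float
        )

    def consumer_slice(self) -> slice:
        return slice(2, 4)

    def swap_resource_roles(self) -> "InterstageSharingParams":
        """Relabel the two resources (juvenile <-> adult major resource).

        Exchanges carrying capacities and growth rates together with the
        matching rows of the consumption/conversion matrices, so the
        relabelled system is the same food web with the resource identities
        swapped.
        """
        return InterstageSharingParams(
            r_J=self.r_A,
            K_J=self.K_A,
            r_A=self.r_J,
            K_A=self.K_J,
            a_JJ=self.a_JA,
            a_JA=self.a_JJ,
            a_AJ=self.a_AA,
            a_AA=self.a_AJ,
            b_JJ=self.b_JA,
            b_JA=self.b_JJ,
            b_AJ=self.b_AA,
            b_AA=self.b_AJ,
            d_J=self.d_J,
            d_A=self.d_A,
        )


ScenarioParams = Union[
    AdditionalResourcesParams, MultipleHabitatsParams, InterstageSharingParams
]


def _validate_state(params: ScenarioParams, state: np.ndarray) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.ndim != 1 or y.size != params.state_size:
        raise ValueError(
            f"state must be a vector of length {params.state_size}, got shape {y.shape}"
        )
    if np.any(y < 0):
        raise ValueError("state abundances must be non-negative")
    return y


def _logistic_or_subsidy(r, K, sub, inp, loss, R):
    """Self-renewal term: logistic by default, donor control ``I - l R`` if subsidized."""
    return np.where(sub, inp - loss * R, r * R * (1.0 - R / K))


def _rhs_additional(params: AdditionalResourcesParams, y: np.ndarray) -> np.ndarray:
    R_J, R_A, C_J, C_A = params.split_state(y)
    dR_J = (
        _logistic_or_subsidy(
            params.r_J, params.K_J, params.subsidized_J, params.input_J, params.loss_J, R_J
        )
        - params.a_J * R_J * C_J
    )
    dR_A = (
        _logistic_or_subsidy(
            params.r_A, params.K_A, params.subsidized_A, params.input_A, params.loss_A, R_A
        )
        - params.a_A * R_A * C_A
    )
    juv_intake = float(np.sum(params.b_J * params.a_J * R_J))
    ad_intake = float(np.sum(params.b_A * params.a_A * R_A))
    dC_J = ad_intake * C_A - juv_intake * C_J - params.d_J * C_J
    dC_A = juv_intake * C_J - params.d_A * C_A
    return np.concatenate([dR_J, dR_A, [dC_J], [dC_A]])


def _rhs_multiple(params: MultipleHabitatsParams, y: np.ndarray) -> np.ndarray:
    nJ, nA = params._int_counts()
    R_J, R_A, C_J, C_A = params.split_state(y)
    K_J = params.effective_K("J")
    K_A = params.effective_K("A")
    dR_J = params.r_J * R_J * (1.0 - R_J / K_J) - params.a_J * R_J * C_J
    dR_A = params.r_A * R_A * (1.0 - R_A / K_A) - params.a_A * R_A * C_A
    maturation = params.b_J * params.a_J * R_J * C_J  # per juvenile habitat
    reproduction = params.b_A * params.a_A * R_A * C_A  # per adult habitat
    dC_J = np.sum(reproduction) / nJ - maturation - params.d_J * C_J
    dC_A = np.sum(maturation) / nA - params.d_A * C_A
    return np.concatenate([dR_J, dR_A, dC_J, dC_A])


def _rhs_sharing(params: InterstageSharingParams, y: np.ndarray) -> np.ndarray:
    R_J, R_A, C_J, C_A = params.split_state(y)
    dR_J = (
        params.r_J * R_J * (1.0 - R_J / params.K_J)
        - params.a_JJ * R_J * C_J
        - params.a_AJ * R_J * C_A
    )
    dR_A = (
        params.r_A * R_A * (1.0 - R_A / params.K_A)
        - params.a_AA * R_A * C_A
        - params.a_JA * R_A * C_J
    )
    juv_intake = params.b_JJ * params.a_JJ * R_J + params.b_JA * params.a_JA * R_A
    ad_intake = params.b_AA * params.a_AA * R_A + params.b_AJ * params.a_AJ * R_J
    dC_J = ad_intake * C_A - juv_intake * C_J - params.d_J * C_J
    dC_A = juv_intake * C_J - params.d_A * C_A
    return np.array([dR_J, dR_A, dC_J, dC_A])


_RHS_DISPATCH = {
    AdditionalResourcesParams: _rhs_additional,
    MultipleHabitatsParams: _rhs_multiple,
    InterstageSharingParams: _rhs_sharing,
}


def rhs(params: ScenarioParams, state, *, validate: bool = True) -> np.ndarray:
    """Time derivative of the state vector for any scenario.

    With ``validate=True`` (default) the state is checked for the right
    dimension and non-negativity; integrators may pass ``validate=False`` to
    tolerate the tiny negative excursions adaptive steppers produce.
    """
    fn = _RHS_DISPATCH.get(type(params))
    if fn is None:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    y = _validate_state(params, state) if validate else np.asarray(state, dtype=float)
    return fn(params, y)


def rhs_additional(params: AdditionalResourcesParams, state, *, validate=True):
    return rhs(params, state, validate=validate)


def rhs_multiple(params: MultipleHabitatsParams, state, *, validate=True):
    return rhs(params, state, validate=validate)


def rhs_sharing(params: InterstageSharingParams, state, *, validate=True):
    return rhs(params, state, validate=validate)


def resource_equilibrium(params: ScenarioParams, C_J: float, C_A: float):
    """Resource abundances at which every resource derivative vanishes.

    Solves the resource rows for fixed consumer abundances:
    ``R* = K (1 - a C / r)`` for a logistic resource (joint-consumption form
    for the sharing model) and ``R* = I / (l + a C)`` for a subsidized one.
    Values may be negative; callers filter for feasibility.

    Returns a pair of arrays ``(R_J, R_A)`` (scalars packed in length-1
    arrays for the sharing model).
    """
    C_J = float(C_J)
    C_A = float(C_A)
    if C_J < 0 or C_A < 0:
        raise ValueError("consumer abundances must be non-negative")
    if isinstance(params, AdditionalResourcesParams):
        R = []
        for stage, C in (("J", C_J), ("A", C_A)):
            r = getattr(params, f"r_{stage}")
            K = getattr(params, f"K_{stage}")
            a = getattr(params, f"a_{stage}")
            sub = getattr(params, f"subsidized_{stage}")
            inp = getattr(params, f"input_{stage}")
            loss = getattr(params, f"loss_{stage}")
            logistic = K * (1.0 - a * C / r)
            denom = loss + a * C
            with np.errstate(divide="ignore", invalid="ignore"):
                donor = np.where(denom > 0, inp / np.where(denom > 0, denom, 1.0), 0.0)
            donor = np.where(inp == 0.0, 0.0, donor)
            R.append(np.where(sub, donor, logistic))
        return R[0], R[1]
    if isinstance(params, MultipleHabitatsParams):
        # symmetric per-habitat abundances; heterogeneity enters through K overrides
        if params.is_integer:
            K_J = params.effective_K("J")
            K_A = params.effective_K("A")
        else:
            K_J = np.atleast_1d(params.K_J)
            K_A = np.atleast_1d(params.K_A)
        return (
            K_J * (1.0 - params.a_J * C_J / params.r_J),
            K_A * (1.0 - params.a_A * C_A / params.r_A),
        )
    if isinstance(params, InterstageSharingParams):
        R_J = params.K_J * (1.0 - (params.a_JJ * C_J + params.a_AJ * C_A) / params.r_J)
        R_A = params.K_A * (1.0 - (params.a_AA * C_A + params.a_JA * C_J) / params.r_A)
        return np.array([R_J]), np.array([R_A])
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def default_params(scenario: str, panel: str = "right") -> ScenarioParams:
    """Baseline parameter set for one scenario.

    All scenarios share ``r = 1``, ``a = 0.1``, ``b = 0.5`` and ``d = 0.1``
    per rate; carrying capacities are 10 for the additional-resources and
    multiple-habitats baselines and 15 for the sharing baseline, with two
    resources/habitats per stage and small cross-feeding rates (0.01) in the
    sharing model.  ``panel`` selects one of the three standard views
    (``left``/``center``/``right``); the baseline point is the same for all
    three, the panel choice matters to scan axis conventions.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}; expected one of {PANELS}")
    if scenario == "additional":
        n = 2
        ones = np.ones(n)
        return AdditionalResourcesParams(
            r_J=ones,
            K_J=10.0 * ones,
            a_J=0.1 * ones,
            b_J=0.5 * ones,
            r_A=ones.copy(),
            K_A=10.0 * ones,
            a_A=0.1 * ones,
            b_A=0.5 * ones,
            d_J=0.1,
            d_A=0.1,
        )
    if scenario == "multiple":
        return MultipleHabitatsParams(
            n_J=2, n_A=2, r_J=1.0, K_J=10.0, a_J=0.1, b_J=0.5,
            r_A=1.0, K_A=10.0, a_A=0.1, b_A=0.5, d_J=0.1, d_A=0.1,
        )
    return InterstageSharingParams(
        r_J=1.0, K_J=15.0, r_A=1.0, K_A=15.0,
        a_JJ=0.1, a_JA=0.01, a_AJ=0.01, a_AA=0.1,
        b_JJ=0.5, b_JA=0.5, b_AJ=0.5, b_AA=0.5,
        d_J=0.1, d_A=0.1,
    )
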