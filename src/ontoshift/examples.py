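"""Reference parameter sets with verified dynamical behaviour.

The plotting baselines (``default_params``) sit in a weakly-damped part of
parameter space where the juvenile-dominated branch is an unstable focus,
so three candidate equilibria do not guarantee two coexisting attractors
there.  The sets below are chosen at higher stage mortalities / stronger
asymmetries where the saddle structure is clean: stability margins are
O(0.1) and forward simulation from coarse initial grids reproducibly finds
every attractor.  They anchor the worked examples, the test suite and the
acceptance script.
"""

from __future__ import annotations

from .models import (
    AdditionalResourcesParams,
    InterstageSharingParams,
    MultipleHabitatsParams,
)

__all__ = ["bistable_additional", "bistable_sharing", "heterogeneous_search_base"]


def bistable_additional() -> AdditionalResourcesParams:
    """One resource per stage, two stable interior states separated by a saddle.

    The three interior equilibria are (ordered by ``C_J*``): a stable
    adult-dominated focus, an unstable middle equilibrium, and a stable
    juvenile-dominated focus; basins are broad enough that a log-spaced
    4 x 4 grid of initial consumer abundances reaches both attractors.
    """
    return AdditionalResourcesParams(
        r_J=[2.4], K_J=[10.0], a_J=[0.05], b_J=[0.9],
        r_A=[2.8], K_A=[28.0], a_A=[0.1], b_A=[1.0],
        d_J=0.4, d_A=0.23,
    )


def bistable_sharing() -> InterstageSharingParams:
    """Sharing-model counterpart of :func:`bistable_additional`.

    Cross-feeding rates sit at 0.0005 — well below the own-resource rates
    and just inside the fold at which interstage resource sharing destroys
    the alternative stable states (at these rates the fold lies near
    0.001, i.e. about 1-2% of the own-resource consumption rates).
    """
    return InterstageSharingParams(
        r_J=2.4, K_J=10.0, r_A=2.8, K_A=28.0,
        a_JJ=0.05, a_JA=0.0005, a_AJ=0.0005, a_AA=0.1,
        b_JJ=0.9, b_JA=0.9, b_AJ=1.0, b_AA=1.0,
        d_J=0.4, d_A=0.23,
    )


def heterogeneous_search_base() -> MultipleHabitatsParams:
    """Two juvenile + two adult habitats supporting three alternative states.

    With a juvenile-productivity difference between the two juvenile
    habitats (see
    :func:`ontoshift.scans.heterogeneous_multistability_search`) the system
    holds one adult-dominated state and two mirrored juvenile-dominated
    states in which one habitat's resource is grazed out and its juvenile
    class dominates; all three are stable fixed points.
    """
    return MultipleHabitatsParams(
        n_J=2, n_A=2,
        r_J=2.0, K_J=37.0, a_J=0.16, b_J=0.67,
        r_A=2.1, K_A=43.0, a_A=0.043, b_A=0.24,
        d_J=0.1, d_A=0.15,
    )
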