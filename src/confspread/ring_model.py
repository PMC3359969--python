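"""State space, free energies and rate constants of the conformational-spread ring.

The switch complex is modelled as a closed ring of ``N`` identical protomers
(FliM subunits).  Each protomer has two degrees of freedom:

* a mechanical conformation, *inactive* (CCW) or *active* (CW), and
* a chemical state, *unbound* or *bound* to one ligand molecule (CheY-P).

A protomer therefore cycles through the four states ``AB <-> AN <-> IN <-> IB``.
Site free energies (in units of k_B T, relative to the inactive/unbound state)
are::

    g(I, N) = 0              g(A, N) = ea0
    g(I, B) = E_C + ea0      g(A, B) = E_C + ea0 - ea1

where ``E_C = -ln(c / c_0.5)`` is the chemical free energy of ligand binding at
relative concentration ``c_rel = c / c_0.5``, ``ea0`` is the activation energy
of an unliganded protomer and ``ea1`` that of a liganded protomer (the
symmetric model has ``ea0 == ea1``).  The activity difference is ``+ea0`` for
an unliganded protomer and ``-ea1`` for a liganded one; binding to the
*inactive* conformation costs ``ea0`` more than binding to the active one, so
that in the symmetric model at ``c_rel = 1`` (``E_C = 0``) the landscape is
invariant under the joint exchange (active, bound) <-> (inactive, unbound):
``c_0.5`` is simultaneously the concentration of half occupancy and of neutral
bias.  In addition the free energy of a protomer is lowered by the coupling
energy ``ej`` for each nearest neighbour sharing its mechanical conformation,
which drives conformational spread around the ring.

Rate constants follow the standard load-sharing construction: a conformational
flip with free-energy change ``dG`` (site term plus coupling term) proceeds at

    k(I->A) = omega_a * exp(-lambda_a * dG_IA)
    k(A->I) = omega_a * exp(+(1 - lambda_a) * dG_IA)

so that detailed balance ``k_f / k_r = exp(-dG)`` holds for every
``lambda_a``; at the default ``lambda_a = 0.5`` both directions reduce to the
single formula ``omega_a * exp(-dG/2)``.  Ligand binding is conformation
independent (``lambda_b = 0``): ``k_on = omega_b * c_rel`` for both
conformations, with the conformation dependence carried entirely by the
off-rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "INACTIVE",
    "ACTIVE",
    "UNBOUND",
    "BOUND",
    "ModelParams",
    "RingState",
    "site_energy",
    "site_energies",
    "delta_g_flip",
    "flip_rate",
    "binding_rates",
    "total_free_energy",
]

# Mechanical conformation codes (active <=> CW, inactive <=> CCW).
INACTIVE: int = 0
ACTIVE: int = 1
# Chemical occupancy codes.
UNBOUND: int = 0
BOUND: int = 1


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of one simulation condition.

    Energies are in units of k_B T, rates in 1/s.  ``c_rel`` is the ligand
    (CheY-P) concentration expressed in units of ``c_0.5``, the concentration
    of half occupancy in the symmetric model.
    """

    ea0: float = 0.65  #: activation energy of an unliganded protomer (k_B T)
    ea1: float = 0.65  #: activation energy of a liganded protomer (k_B T)
    ej: float = 4.15  #: nearest-neighbour coupling energy (k_B T)
    c_rel: float = 1.0  #: ligand concentration in units of c_0.5
    n_protomers: int = 34  #: ring size N
    omega_a: float = 1.0e4  #: fundamental flipping frequency (1/s)
    omega_b: float = 10.0  #: characteristic binding rate (1/s)
    lambda_a: float = 0.5  #: load-sharing factor for conformational flips
    lambda_b: float = 0.0  #: load-sharing factor for binding (only 0 supported)

    def __post_init__(self) -> None:
        if self.n_protomers < 3:
            raise ValueError("n_protomers must be >= 3")
        if not (self.omega_a > 0 and self.omega_b > 0):
            raise ValueError("omega_a and omega_b must be positive")
        if not 0.0 <= self.lambda_a <= 1.0:
            raise ValueError("lambda_a must lie in [0, 1]")
        if self.lambda_b != 0.0:
            raise ValueError("only lambda_b = 0 (conformation-independent binding) is supported")
        if self.c_rel < 0:
            raise ValueError("c_rel must be non-negative")
        for name in ("ea0", "ea1", "ej"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def e_c(self) -> float:
        """Ligand chemical free energy E_C = -ln(c_rel), in k_B T."""
        if self.c_rel == 0.0:
            return math.inf
        return -math.log(self.c_rel)

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class RingState:
    """Circular array of per-protomer (activity, occupancy) states.

    ``activity`` and ``occupancy`` are uint8 arrays of equal length N; index
    arithmetic is modulo N (the neighbour of protomer N-1 is protomer 0).
    """

    activity: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=np.uint8)
        self.occupancy = np.asarray(self.occupancy, dtype=np.uint8)
        if self.activity.shape != self.occupancy.shape or self.activity.ndim != 1:
            raise ValueError("activity and occupancy must be 1-D arrays of equal length")
        if self.activity.size < 3:
            raise ValueError("ring must have at least 3 protomers")
        for arr in (self.activity, self.occupancy):
            if np.any(arr > 1):
                raise ValueError("state codes must be 0 or 1")

    @classmethod
    def all_active_bound(cls, n: int) -> "RingState":
        """The canonical initial condition: every protomer active and bound."""
        return cls(np.ones(n, dtype=np.uint8), np.ones(n, dtype=np.uint8))

    @classmethod
    def uniform(cls, n: int, activity: int, occupancy: int) -> "RingState":
        return cls(
            np.full(n, activity, dtype=np.uint8),
            np.full(n, occupancy, dtype=np.uint8),
        )

    def __len__(self) -> int:
        return self.activity.size

    @property
    def n_active(self) -> int:
        return int(self.activity.sum())

    @property
    def n_bound(self) -> int:
        return int(self.occupancy.sum())

    def copy(self) -> "RingState":
        return RingState(self.activity.copy(), self.occupancy.copy())


def site_energy(activity: int, occupancy: int, params: ModelParams) -> float:
    """Free energy of a single protomer state, in k_B T (coupling excluded).

    Reference: g(inactive, unbound) = 0.
    """
    g = 0.0
    if occupancy == BOUND:
        g += params.e_c + params.ea0
    if activity == ACTIVE:
        g += params.ea0 if occupancy == UNBOUND else -params.ea1
    return g


def site_energies(params: ModelParams) -> dict:
    """All four site energies keyed by two-letter state code (IN/AN/IB/AB)."""
    return {
        "IN": site_energy(INACTIVE, UNBOUND, params),
        "AN": site_energy(ACTIVE, UNBOUND, params),
        "IB": site_energy(INACTIVE, BOUND, params),
        "AB": site_energy(ACTIVE, BOUND, params),
    }


def _check_index(state: RingState, i: int) -> None:
    if not 0 <= i < len(state):
        raise IndexError(f"protomer index {i} out of range for ring of {len(state)}")


def delta_g_flip(state: RingState, i: int, params: ModelParams) -> float:
    """Free-energy change of toggling protomer ``i``'s conformation (k_B T).

    The occupancy is held fixed.  The change is the site term (+-ea0 if
    unbound, -+ea1 if bound) plus the coupling term ``ej * (2*n_alike - 2)``,
    where ``n_alike`` counts the neighbours currently sharing protomer ``i``'s
    conformation: flipping breaks those bonds and forms bonds with the others.
    """
    _check_index(state, i)
    n = len(state)
    a = int(state.activity[i])
    b = int(state.occupancy[i])
    if a == INACTIVE:
        dg_site = params.ea0 if b == UNBOUND else -params.ea1
    else:
        dg_site = -params.ea0 if b == UNBOUND else params.ea1
    left = int(state.activity[(i - 1) % n])
    right = int(state.activity[(i + 1) % n])
    n_alike = (left == a) + (right == a)
    return dg_site + params.ej * (2 * n_alike - 2)


def flip_rate(state: RingState, i: int, params: ModelParams) -> float:
    """Rate constant (1/s) of the conformational flip of protomer ``i``.

    The load-sharing factor lambda_a applies to the I->A direction and
    (1 - lambda_a) to A->I, which keeps detailed balance exact for every
    lambda_a; at lambda_a = 0.5 this is omega_a * exp(-dG/2) in both
    directions.
    """
    dg = delta_g_flip(state, i, params)
    lam = params.lambda_a if state.activity[i] == INACTIVE else 1.0 - params.lambda_a
    return params.omega_a * math.exp(-lam * dg)


def binding_rates(state: RingState, i: int, params: ModelParams) -> Tuple[float, float]:
    """(k_on, k_off) in 1/s for ligand exchange at protomer ``i``.

    With lambda_b = 0 the mass-action on-rate ``omega_b * c_rel`` is
    independent of conformation; the conformation dependence of the binding
    free energy sits entirely in the off-rates,
    ``k_off(inactive) = omega_b * exp(+ea0)`` and
    ``k_off(active) = omega_b * exp(-ea1)`` (ligand leaves the active
    conformation more slowly).  Both satisfy detailed balance against the
    site energies: ``k_on / k_off = exp(-(g(., B) - g(., N)))``.
    """
    _check_index(state, i)
    if params.c_rel < 0:
        raise ValueError("c_rel must be non-negative")
    k_on = params.omega_b * params.c_rel
    if state.activity[i] == ACTIVE:
        k_off = params.omega_b * math.exp(-params.ea1)
    else:
        k_off = params.omega_b * math.exp(params.ea0)
    return k_on, k_off


def total_free_energy(state: RingState, params: ModelParams) -> float:
    """Total free energy of a ring configuration, in k_B T.

    Sum of site energies minus ``ej`` for every adjacent pair sharing a
    conformation.  The difference of this quantity across a single flip equals
    :func:`delta_g_flip` exactly, which is the invariant the tests rely on.
    """
    act = state.activity
    occ = state.occupancy
    g = 0.0
    for a, b in zip(act, occ):
        g += site_energy(int(a), int(b), params)
    alike = int(np.sum(act == np.roll(act, -1)))
    return g - params.ej * alike
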