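"""Exact equilibrium reference calculations for the ring.

Because every rate in the model satisfies detailed balance against the total
free energy, the stationary distribution of the kinetic Monte Carlo process is
the Boltzmann distribution ``P(config) ∝ exp(-G(config))``.  That makes two
independent exact calculations possible:

* :func:`enumerate_equilibrium` — brute-force summation over all ``4**N`` ring
  configurations (small N).  Also yields the equilibrium distribution of the
  domain count.
* :func:`transfer_matrix_summary` — a 2x2 activity transfer matrix, after
  summing the two occupancy states of each site into the per-conformation
  weight ``w(a) = sum_b exp(-g_site(a, b))``.  Scales to any N; eigenvalues
  are handled in scaled form so N = 100 is numerically safe.

These serve as oracles for the simulator (long-run time averages must match)
and to solve for the neutral-bias concentration ``c_0.5(asymmetric)`` when
``ea0 != ea1``, by root-finding mean activity = 1/2 on log concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .ring_model import ModelParams

__all__ = [
    "EquilibriumSummary",
    "enumerate_equilibrium",
    "transfer_matrix_summary",
    "solve_c05_asymmetric",
    "exact_domain_count_dist",
]

_ENUM_MAX_N = 12


@dataclass
class EquilibriumSummary:
    """Exact equilibrium marginals of a ring condition."""

    mean_activity: float  #: expected fraction of active protomers
    mean_occupancy: float  #: expected fraction of ligand-bound protomers
    partition_log: float  #: log partition function
    domain_count_dist: Optional[Dict[int, float]] = None  #: P(domain count), enumeration only


def _site_weights(params: ModelParams):
    """Per-conformation weights w(a) = sum_b exp(-g_site(a, b)) and P(bound | a).

    Written in terms of c_rel directly (exp(-E_C) = c_rel) so that c_rel = 0
    is handled without infinities.
    """
    c = params.c_rel
    # site energies: IN 0, AN ea0, IB e_c + ea0, AB e_c + ea0 - ea1,
    # and exp(-e_c) = c_rel.
    w_i = 1.0 + c * math.exp(-params.ea0)
    w_a = math.exp(-params.ea0) + c * math.exp(params.ea1 - params.ea0)
    pb_i = c * math.exp(-params.ea0) / w_i
    pb_a = c * math.exp(params.ea1) / (1.0 + c * math.exp(params.ea1))
    return w_i, w_a, pb_i, pb_a


def enumerate_equilibrium(params: ModelParams) -> EquilibriumSummary:
    """Exact Boltzmann average over all 4**N configurations (N <= 12).

    Configurations are enumerated as base-4 integers, two bits per site
    (activity bit, occupancy bit); weights are ``exp(-G)`` with ``G`` the
    total free energy including the nearest-neighbour coupling.
    """
    n = params.n_protomers
    if n > _ENUM_MAX_N:
        raise ValueError(f"enumeration is limited to N <= {_ENUM_MAX_N} (got {n})")

    # site free energies indexed by digit d = 2*activity + occupancy
    # d: 0 = IN, 1 = IB, 2 = AN, 3 = AB
    c = params.c_rel
    with np.errstate(divide="ignore"):
        e_c = np.inf if c == 0.0 else -math.log(c)
    g_site = np.array(
        [0.0, e_c + params.ea0, params.ea0, e_c + params.ea0 - params.ea1]
    )

    cfg = np.arange(4**n, dtype=np.int64)
    g = np.zeros(cfg.size)
    n_act = np.zeros(cfg.size, dtype=np.int16)
    n_bnd = np.zeros(cfg.size, dtype=np.int16)
    n_edges = np.zeros(cfg.size, dtype=np.int16)
    first_act = prev_act = None
    for k in range(n):
        d = (cfg >> (2 * k)) & 3
        act = (d >> 1).astype(np.int8)
        g += g_site[d]
        n_act += act
        n_bnd += (d & 1).astype(np.int8)
        if k == 0:
            first_act = act
        else:
            same = act == prev_act
            g -= params.ej * same
            n_edges += ~same
        prev_act = act
    same = prev_act == first_act  # closing bond of the ring
    g -= params.ej * same
    n_edges += ~same

    logw = -g
    log_z = float(logsumexp(logw))
    p = np.exp(logw - log_z)
    dom = np.where(n_edges == 0, 1, n_edges)
    counts = np.unique(dom)
    dist = {int(k): float(p[dom == k].sum()) for k in counts}
    return EquilibriumSummary(
        mean_activity=float((p * n_act).sum()) / n,
        mean_occupancy=float((p * n_bnd).sum()) / n,
        partition_log=log_z,
        domain_count_dist=dist,
    )


def transfer_matrix_summary(params: ModelParams) -> EquilibriumSummary:
    """Equilibrium marginals from the 2x2 activity transfer matrix (any N).

    With occupancy summed per site, ``Z = tr(T^N)`` for the symmetric matrix
    ``T[a, b] = sqrt(w(a) w(b)) * exp(ej * [a == b])`` and the one-site
    activity marginal is ``(T^N)_{AA} / Z``.  Eigenvalues are rescaled by
    their largest magnitude before taking the N-th power, so large rings never
    overflow.
    """
    n = params.n_protomers
    w_i, w_a, pb_i, pb_a = _site_weights(params)
    if w_a == 0.0 and w_i == 0.0:
        raise ValueError("degenerate weights")
    s = np.sqrt([w_i, w_a])
    ej = params.ej
    t_mat = np.outer(s, s) * np.exp(ej * np.eye(2))
    lam, vec = np.linalg.eigh(t_mat)
    scale = np.max(np.abs(lam))
    r = lam / scale
    rn = np.sign(r) ** n * np.abs(r) ** n
    z_scaled = float(np.sum(rn))
    p_active = float(np.sum(rn * vec[1, :] ** 2)) / z_scaled
    p_inactive = 1.0 - p_active
    return EquilibriumSummary(
        mean_activity=p_active,
        mean_occupancy=p_inactive * pb_i + p_active * pb_a,
        partition_log=n * math.log(scale) + math.log(z_scaled),
        domain_count_dist=None,
    )


def exact_domain_count_dist(params: ModelParams) -> Dict[int, float]:
    """Exact equilibrium distribution of the domain count, any N.

    Because every transition satisfies detailed balance, the fraction of time
    the ring holds a given number of domains (maximal circular runs of equal
    conformation) equals its Boltzmann probability.  With occupancy summed
    into the per-conformation weight ``w(a)``, the number of ring
    configurations with ``m`` active sites and ``b = 2j`` domain boundaries
    is ``(N/j) * C(m-1, j-1) * C(N-m-1, j-1)``, each weighted by
    ``exp(ej * (N - b)) * w_A**m * w_I**(N-m)``.  Run counts are computed in
    log space, so N = 100 is safe.

    This is the reference the simulated domain occupancy is validated
    against.
    """
    n = params.n_protomers
    w_i, w_a, _, _ = _site_weights(params)
    log_wi, log_wa = math.log(w_i), math.log(w_a)
    ej = params.ej

    log_terms = {1: ej * n + logsumexp([n * log_wi, n * log_wa])}
    for j in range(1, n // 2 + 1):
        b = 2 * j
        parts = []
        for m in range(j, n - j + 1):
            log_cnt = (
                math.log(n) - math.log(j)
                + math.lgamma(m) - math.lgamma(j) - math.lgamma(m - j + 1)
                + math.lgamma(n - m) - math.lgamma(j) - math.lgamma(n - m - j + 1)
            )
            parts.append(log_cnt + m * log_wa + (n - m) * log_wi)
        log_terms[b] = ej * (n - b) + logsumexp(parts)
    log_z = logsumexp(list(log_terms.values()))
    return {k: math.exp(v - log_z) for k, v in sorted(log_terms.items())}


def solve_c05_asymmetric(
    ea0: float,
    ea1: float,
    ej: float,
    n_protomers: int = 34,
    rtol: float = 1e-6,
) -> float:
    """Relative concentration giving equilibrium mean activity 1/2.

    In the symmetric model (``ea0 == ea1``) the energy landscape at
    ``c_rel = 1`` is symmetric under the joint exchange of conformations and
    occupancies, so neutral bias needs no correction and 1.0 is returned
    exactly.  Otherwise the root of ``mean_activity(c) - 1/2`` is bracketed
    and solved on log concentration with the transfer matrix; mean activity is
    monotone increasing in concentration, so the root is unique.
    """
    if ea0 == ea1:
        return 1.0

    def f(logc: float) -> float:
        p = ModelParams(ea0=ea0, ea1=ea1, ej=ej, c_rel=math.exp(logc), n_protomers=n_protomers)
        return transfer_matrix_summary(p).mean_activity - 0.5

    lo, hi = -1.0, 1.0
    limit = math.log(1e6)
    while f(lo) > 0:
        lo *= 2
        if lo < -limit:
            raise ValueError("no neutral-bias concentration in c_rel in [1e-6, 1e6]")
    while f(hi) < 0:
        hi *= 2
        if hi > limit:
            raise ValueError("no neutral-bias concentration in c_rel in [1e-6, 1e6]")
    logc = brentq(f, lo, hi, xtol=rtol / 2)
    return math.exp(logc)
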