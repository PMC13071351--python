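"""Core nutrient-producer-consumer model of a meta-ecosystem.

Each local ecosystem ("patch") tracks three stocks: inorganic nutrients
``N``, primary producers ``P`` and consumers ``C``.  Producers take up
nutrients and consumers graze producers following saturating (Monod)
functional responses

.. math::

    f_P(N) = a_P N / (b_P + N), \\qquad f_C(P) = a_C P / (b_C + P).

A fraction ``r_P`` (``r_C``) of producer (consumer) mortality is recycled
into the local nutrient pool; the remainder leaves the meta-ecosystem,
together with hydrological export ``e_N * N``.  Each patch receives a
constant external nutrient input ``I_N``.  Patches are coupled by passive
resource flows (rate ``d_N``, connectivity matrix ``S_N``) and by consumer
dispersal (per-patch rates ``d_C[i]``, connectivity ``S_C``).  The per-patch
dynamics are

.. math::

    dN_i/dt &= I_N - e_N N_i + m_P r_P P_i + m_C r_C C_i - P_i f_P(N_i)
               + d_N \\sum_j s^N_{ij} N_j \\\\
    dP_i/dt &= P_i f_P(N_i) - m_P P_i - C_i f_C(P_i) \\\\
    dC_i/dt &= C_i f_C(P_i) - m_C C_i + d_{C,i} \\sum_j s^C_{ij} C_j

Producers do not disperse between patches by default (their dispersal is
assumed to act within a patch); an optional ``S_P`` hook with rate ``d_P``
exists for generalizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .topology import MetaTopology

__all__ = [
    "ModelParams",
    "MetaState",
    "EquilibriumError",
    "uptake_producer",
    "uptake_consumer",
    "derivative",
    "closed_ecosystem_equilibrium",
    "BASELINE",
]

#: Parameter names accepted in flat config sections (see ``to_dict``).
_SCALAR_FIELDS = (
    "I_N", "e_N", "m_P", "m_C", "a_P", "b_P", "a_C", "b_C", "r_P", "r_C",
    "d_N", "d_P",
)


@dataclass
class ModelParams:
    """Rate constants of the meta-ecosystem model.

    All rates are per unit time; ``b_P``/``b_C`` are half-saturation stocks
    and ``r_P``/``r_C`` dimensionless recycled fractions in [0, 1].
    Defaults are the baseline parameterization used throughout the state
    diagrams (spatial rates default to zero, i.e. uncoupled patches).

    ``d_C`` is stored as one dispersal rate per patch so that type-specific
    and fully patch-specific rates are expressible; the ``d_CA``/``d_CB``
    accessors implement the two-type convention under the standard patch
    ordering (A1, B1, A2, B2, ...), where type A occupies even indices.
    """

    I_N: float = 0.05
    e_N: float = 0.01
    m_P: float = 0.05
    m_C: float = 0.24
    a_P: float = 1.0
    b_P: float = 10.0
    a_C: float = 0.6
    b_C: float = 6.0
    r_P: float = 0.8
    r_C: float = 0.8
    d_N: float = 0.0
    d_C: np.ndarray = field(default_factory=lambda: np.zeros(4))
    d_P: float = 0.0

    def __post_init__(self) -> None:
        self.d_C = np.atleast_1d(np.asarray(self.d_C, dtype=float)).copy()
        for name in _SCALAR_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if np.any(self.d_C < 0):
            raise ValueError("all d_C entries must be >= 0")
        for name in ("r_P", "r_C"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.a_C <= self.m_C:
            warnings.warn(
                "a_C <= m_C: consumers cannot persist at a positive "
                "equilibrium",
                stacklevel=2,
            )

    # -- two-type convenience accessors (patch order A1, B1, A2, B2, ...) --
    @property
    def d_CA(self) -> float:
        """Dispersal rate of type-A consumers (even patch indices)."""
        return float(self.d_C[0])

    @property
    def d_CB(self) -> float:
        """Dispersal rate of type-B consumers (odd patch indices)."""
        return float(self.d_C[1]) if self.d_C.size > 1 else float(self.d_C[0])

    @classmethod
    def with_dispersal(
        cls,
        d_N: float = 0.0,
        d_CA: float = 0.0,
        d_CB: float | None = None,
        n_locations: int = 2,
        **kwargs,
    ) -> "ModelParams":
        """Baseline parameters with the given spatial rates.

        Builds the per-patch ``d_C`` vector for ``n_locations`` locations of
        alternating types (A, B, A, B, ...).
        """
        if d_CB is None:
            d_CB = d_CA
        d_C = np.tile([d_CA, d_CB], n_locations)
        return cls(d_N=d_N, d_C=d_C, **kwargs)

    @property
    def n_patches(self) -> int:
        return self.d_C.size

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    # ------------------------- config round-trip -------------------------
    def to_dict(self) -> dict:
        """Flat key-value mapping suitable for a config file section."""
        d = {name: float(getattr(self, name)) for name in _SCALAR_FIELDS}
        d["d_C"] = [float(v) for v in self.d_C]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        """Parse a flat config section; unknown keys are an error."""
        allowed = set(_SCALAR_FIELDS) | {"d_C", "d_CA", "d_CB"}
        unknown = set(data) - allowed
        if unknown:
            raise KeyError(
                f"unknown parameter name(s) in config: {sorted(unknown)}"
            )
        data = dict(data)
        if "d_CA" in data or "d_CB" in data:
            if "d_C" in data:
                raise KeyError("give either d_C or d_CA/d_CB, not both")
            d_CA = data.pop("d_CA", 0.0)
            d_CB = data.pop("d_CB", d_CA)
            data["d_C"] = [d_CA, d_CB, d_CA, d_CB]
        return cls(**data)


#: Baseline parameter set of the published state diagrams.
BASELINE = ModelParams()


@dataclass
class MetaState:
    """Stocks of every patch: vectors ``N``, ``P``, ``C`` of equal length."""

    N: np.ndarray
    P: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.atleast_1d(np.asarray(self.N, dtype=float))
        self.P = np.atleast_1d(np.asarray(self.P, dtype=float))
        self.C = np.atleast_1d(np.asarray(self.C, dtype=float))
        if not (self.N.shape == self.P.shape == self.C.shape):
            raise ValueError("N, P, C must have equal lengths")

    @property
    def n_patches(self) -> int:
        return self.N.size

    def require_nonnegative(self) -> None:
        if min(self.N.min(), self.P.min(), self.C.min()) < 0:
            raise ValueError("stocks must be nonnegative")

    def to_vector(self) -> np.ndarray:
        """Flat layout [N_1..N_n, P_1..P_n, C_1..C_n]."""
        return np.concatenate([self.N, self.P, self.C])

    @classmethod
    def from_vector(cls, y: np.ndarray, n: int) -> "MetaState":
        y = np.asarray(y, dtype=float)
        if y.size != 3 * n:
            raise ValueError(f"state vector has size {y.size}, expected {3 * n}")
        return cls(y[:n], y[n : 2 * n], y[2 * n :])

    @classmethod
    def uniform(cls, N: float, P: float, C: float, n: int) -> "MetaState":
        return cls(np.full(n, N), np.full(n, P), np.full(n, C))


def uptake_producer(N, params: ModelParams):
    """Per-capita producer uptake rate f_P(N) = a_P N / (b_P + N)."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("nutrient stock must be nonnegative")
    return params.a_P * N / (params.b_P + N)


def uptake_consumer(P, params: ModelParams):
    """Per-capita consumer uptake rate f_C(P) = a_C P / (b_C + P)."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("producer stock must be nonnegative")
    return params.a_C * P / (params.b_C + P)


def derivative(
    state: MetaState, params: ModelParams, topo: "MetaTopology"
) -> MetaState:
    """Time derivative of the full meta-ecosystem.

    Pure-numpy reference implementation; the integrator uses an equivalent
    compiled kernel (see :mod:`metaecosim._kernels`), and the two are held
    to agreement by the test suite.
    """
    n = topo.n
    if state.n_patches != n:
        raise ValueError(
            f"state has {state.n_patches} patches, topology has {n}"
        )
    if params.n_patches != n:
        raise ValueError(
            f"params.d_C has {params.n_patches} entries, topology has {n} patches"
        )
    N, P, C = state.N, state.P, state.C
    fP = uptake_producer(N, params)
    fC = uptake_consumer(P, params)
    dN = (
        params.I_N
        - params.e_N * N
        + params.m_P * params.r_P * P
        + params.m_C * params.r_C * C
        - P * fP
        + params.d_N * (topo.S_N @ N)
    )
    dP = P * fP - params.m_P * P - C * fC + params.d_P * (topo.S_P @ P)
    dC = C * fC - params.m_C * C + params.d_C * (topo.S_C @ C)
    return MetaState(dN, dP, dC)


class EquilibriumError(ValueError):
    """No positive interior fixed point exists for the given parameters."""


def closed_ecosystem_equilibrium(
    params: ModelParams,
) -> tuple[float, float, float]:
    """Interior fixed point (N*, P*, C*) of one isolated patch.

    With all spatial rates zero the consumer equation pins the producer
    stock at ``P* = b_C m_C / (a_C - m_C)`` (where grazing balances
    consumer loss).  Substituting into the producer equation gives the
    required uptake ``f_P(N*) = m_P + (m_C / P*) C*`` and hence one
    expression for ``N*`` as a function of ``C*``; the nutrient balance
    gives a second, linear one,
    ``N* = [I_N - (1 - r_P) m_P P* - (1 - r_C) m_C C*] / e_N``.
    Equating the two yields a quadratic in ``C*``; the root giving
    ``N* > 0`` is returned (the other root is unphysical: it implies a
    negative nutrient stock for any baseline-like parameterization with a
    single interior fixed point).
    """
    if params.a_C <= params.m_C:
        raise EquilibriumError(
            "a_C <= m_C: consumers cannot persist (no interior equilibrium)"
        )
    P_star = params.b_C * params.m_C / (params.a_C - params.m_C)

    # u(C) = f_P(N*) = m_P + k C with k = m_C / P*
    k = params.m_C / P_star
    A = params.a_P - params.m_P  # must exceed u - m_P at the root
    lP = (1.0 - params.r_P) * params.m_P * P_star
    lC = (1.0 - params.r_C) * params.m_C
    B0 = params.I_N - lP
    # e_N b_P u(C) = (a_P - u(C)) (B0 - lC C)  ->  a2 C^2 + a1 C + a0 = 0
    a2 = k * lC
    a1 = -(A * lC + k * B0 + params.e_N * params.b_P * k)
    a0 = A * B0 - params.e_N * params.b_P * params.m_P

    if a2 == 0.0:  # fully recycled consumer mortality: linear case
        roots = np.array([-a0 / a1]) if a1 != 0 else np.array([])
    else:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc < 0:
            raise EquilibriumError("no real root for the consumer stock")
        sq = np.sqrt(disc)
        roots = np.array([(-a1 - sq) / (2 * a2), (-a1 + sq) / (2 * a2)])

    for C_star in sorted(float(r) for r in roots if r > 0):
        u = params.m_P + k * C_star
        if u >= params.a_P:
            continue
        N_star = (params.I_N - lP - lC * C_star) / params.e_N
        if N_star > 0:
            return N_star, P_star, C_star
    raise EquilibriumError(
        "no positive interior fixed point for these parameters"
    )
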