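"""Parameter and state types plus the right-hand sides of both population models.

The system lives in a chemostat: fresh monomers flow in at concentration
``m0`` and everything is diluted at rate ``delta``.  Chains grow by
templated polymerization at rate ``r * m`` per hybridized primer end
(``m`` is the free-monomer concentration) and break either spontaneously
at rate ``beta0`` per internal bond (random-cleavage model) or, in the
catalytic model, site-specifically when a substrate chain is hybridized
with a catalyst of the complementary family (rates ``beta``,
``beta_bar``).  Every scission creates a fresh primer, so cleavage drives
proliferation.

All lengths and monomer-type concentrations are renormalized so that the
minimal hybridization (primer) length l0 equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ChemostatParams",
    "CatalyticParams",
    "RandomState",
    "CatalyticState",
    "Derived",
    "free_monomer",
    "primer_fate",
    "duplex_fractions",
    "derived_quantities",
    "random_rhs",
    "random_rhs_array",
    "catalytic_rhs",
    "catalytic_rhs_array",
    "symmetric_rhs_array",
    "DegenerateStateError",
]


class DegenerateStateError(ValueError):
    """Raised when a state is too degenerate for a quantity to be defined."""


@dataclass(frozen=True)
class ChemostatParams:
    """Shared environment and kinetics constants.

    Parameters
    ----------
    m0 : float
        Feed monomer concentration (renormalized, units of l0-mers).
    delta : float
        Dilution rate of the chemostat (1/time).
    r : float
        Elongation rate constant (1/(concentration * time)); the primer
        elongation rate is ``r * m``.
    beta0 : float
        Random (spontaneous) cleavage rate per breakable bond (1/time).
    """

    m0: float = 100.0
    delta: float = 1.0
    r: float = 1.0
    beta0: float = 0.015

    def __post_init__(self) -> None:
        for name in ("m0", "delta", "r", "beta0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CatalyticParams:
    """Chemostat constants plus the catalytic-cleavage constants.

    ``beta`` is the rate at which b-bar catalysts cleave a-chains inside
    b-bar/a duplexes; ``beta_bar`` the rate at which b catalysts cleave
    a-bar chains.  ``lam`` (λ >= 1) is the elongation asymmetry: maturation
    of a right fragment into a catalyst chain is slower than into a
    substrate chain by this factor (extra insert length, hairpin
    unzipping).  ``beta_bar`` defaults to ``beta``.
    """

    chemostat: ChemostatParams = field(default_factory=ChemostatParams)
    beta: float = 10.0
    beta_bar: float | None = None
    lam: float = 2.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.beta_bar is None:
            object.__setattr__(self, "beta_bar", self.beta)
        if self.beta_bar < 0:
            raise ValueError("beta_bar must be >= 0")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")

    # convenience pass-through accessors
    @property
    def m0(self) -> float:
        return self.chemostat.m0

    @property
    def delta(self) -> float:
        return self.chemostat.delta

    @property
    def r(self) -> float:
        return self.chemostat.r

    @property
    def beta0(self) -> float:
        return self.chemostat.beta0

    def with_beta(self, beta: float, beta_bar: float | None = None) -> "CatalyticParams":
        return replace(self, beta=beta, beta_bar=beta_bar if beta_bar is not None else beta)


@dataclass(frozen=True)
class RandomState:
    """State of the random-cleavage model.

    ``c`` / ``c_bar`` are total fragment concentrations of the master
    sequence and its complement; ``M`` / ``M_bar`` the monomers
    incorporated into each subpopulation's chains.
    """

    c: float
    c_bar: float
    M: float
    M_bar: float

    def to_array(self) -> np.ndarray:
        return np.array([self.c, self.c_bar, self.M, self.M_bar], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "RandomState":
        return cls(*map(float, y))

    def validate(self, params: ChemostatParams) -> None:
        arr = self.to_array()
        if np.any(arr < 0):
            raise ValueError("all RandomState fields must be >= 0")
        if self.M + self.M_bar > params.m0 + 1e-12 * params.m0:
            raise ValueError("M + M_bar exceeds m0 (negative free monomer)")


# index layout of the flattened 10-variable catalytic state
_FIELDS = ("a", "b", "aL", "aR", "a_bar", "b_bar", "aL_bar", "aR_bar", "M", "M_bar")


@dataclass(frozen=True)
class CatalyticState:
    """State of the catalyzed-cleavage model: ten concentrations.

    Unbarred fields describe the master-sequence family — uncleaved
    substrate chains ``a``, catalyst chains ``b``, and the left/right
    cleavage-fragment primers ``aL``, ``aR`` — barred fields the
    complementary family.  ``M`` / ``M_bar`` are monomer-in-chain
    densities per family.
    """

    a: float
    b: float
    aL: float
    aR: float
    a_bar: float
    b_bar: float
    aL_bar: float
    aR_bar: float
    M: float
    M_bar: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CatalyticState":
        return cls(*map(float, y))

    @classmethod
    def symmetric(cls, a: float, b: float, aL: float, aR: float, M: float) -> "CatalyticState":
        """Embed a point of the mirror-symmetric subspace (a=ā, b=b̄, ...)."""
        return cls(a, b, aL, aR, a, b, aL, aR, M, M)

    @property
    def c(self) -> float:
        return self.a + self.b + self.aL + self.aR

    @property
    def c_bar(self) -> float:
        return self.a_bar + self.b_bar + self.aL_bar + self.aR_bar

    def clamped(self) -> "CatalyticState":
        """Non-negative copy (physical-state validation of reported states)."""
        return CatalyticState.from_array(np.maximum(self.to_array(), 0.0))

    def validate(self, params: ChemostatParams | CatalyticParams) -> None:
        arr = self.to_array()
        if np.any(arr < 0):
            raise ValueError("all CatalyticState fields must be >= 0")
        m0 = params.m0 if isinstance(params, CatalyticParams) else params.m0
        if self.M + self.M_bar > m0 * (1 + 1e-12):
            raise ValueError("M + M_bar exceeds m0 (negative free monomer)")


@dataclass(frozen=True)
class Derived:
    """Quantities derived from a catalytic state.

    ``phi`` is the probability that a freshly cleaved right fragment aR
    first hybridizes with a catalyst-family template b̄ (rather than ā)
    and hence matures into a catalyst; ``phi_bar`` its mirror.  ``chi``
    and ``chi_bar`` are the fractions of each strand family that find
    complementary partners when family concentrations are unbalanced.
    """

    m: float
    phi: float
    phi_bar: float
    chi: float
    chi_bar: float


def free_monomer(params: ChemostatParams, M: float, M_bar: float) -> float:
    """Free monomer concentration m = m0 - M - M_bar.

    May be transiently negative inside a solver step; callers enforcing
    physicality clamp at zero.
    """
    return params.m0 - M - M_bar


def primer_fate(a: float, b: float, a_bar: float, b_bar: float) -> Tuple[float, float]:
    """Primer-fate probabilities (phi, phi_bar).

    phi = b_bar/(a_bar + b_bar) is the probability that an aR fragment
    first meets a catalyst-family template; phi_bar = b/(a + b) its
    mirror.  A probability whose template family is empty is 0 — no
    templates of that family exist, so no conversion occurs.
    """
    denom = a_bar + b_bar
    denom_bar = a + b
    if denom <= 0 and denom_bar <= 0:
        raise DegenerateStateError("both strand families are empty; primer fate undefined")
    phi = b_bar / denom if denom > 0 else 0.0
    phi_bar = b / denom_bar if denom_bar > 0 else 0.0
    return phi, phi_bar


def duplex_fractions(a: float, b: float, a_bar: float, b_bar: float) -> Tuple[float, float]:
    """Duplex-availability factors (chi, chi_bar).

    chi = min(a+b, ā+b̄)/(a+b) <= 1 is the fraction of the unbarred family
    that finds complementary partners; chi_bar its mirror.  A factor with
    an empty family in the denominator is vacuously 1.
    """
    s = a + b
    s_bar = a_bar + b_bar
    lo = min(s, s_bar)
    chi = lo / s if s > 0 else 1.0
    chi_bar = lo / s_bar if s_bar > 0 else 1.0
    return chi, chi_bar


def derived_quantities(state: CatalyticState, params: CatalyticParams) -> Derived:
    """All derived quantities (m, phi, phi_bar, chi, chi_bar) for a state."""
    m = free_monomer(params.chemostat, state.M, state.M_bar)
    phi, phi_bar = primer_fate(state.a, state.b, state.a_bar, state.b_bar)
    chi, chi_bar = duplex_fractions(state.a, state.b, state.a_bar, state.b_bar)
    return Derived(m=m, phi=phi, phi_bar=phi_bar, chi=chi, chi_bar=chi_bar)


def random_rhs_array(y: np.ndarray, params: ChemostatParams) -> np.ndarray:
    """Time derivatives of (c, c_bar, M, M_bar) for the random-cleavage model.

    dc/dt    = beta0*M - delta*c
    dM/dt    = r*m*min(c, c_bar) - delta*M,   m = m0 - M - M_bar
    and the barred twins with (c, M) <-> (c_bar, M_bar).
    """
    c, c_bar, M, M_bar = y
    m = params.m0 - M - M_bar
    paired = min(c, c_bar)
    dc = params.beta0 * M - params.delta * c
    dc_bar = params.beta0 * M_bar - params.delta * c_bar
    dM = params.r * m * paired - params.delta * M
    dM_bar = params.r * m * paired - params.delta * M_bar
    return np.array([dc, dc_bar, dM, dM_bar])


def random_rhs(state: RandomState, params: ChemostatParams) -> RandomState:
    return RandomState.from_array(random_rhs_array(state.to_array(), params))


def catalytic_rhs_array(y: np.ndarray, params: CatalyticParams) -> np.ndarray:
    """Time derivatives of the ten catalytic-model concentrations.

    Implements the elongation/cleavage/dilution balance for both strand
    families; the barred family's equations are the unbarred ones with
    every barred/unbarred symbol pair swapped and (beta, phi, chi)
    replaced by (beta_bar, phi_bar, chi_bar).
    """
    a, b, aL, aR, a_bar, b_bar, aL_bar, aR_bar, M, M_bar = y
    p = params
    m = p.m0 - M - M_bar

    s = a + b
    s_bar = a_bar + b_bar
    phi = b_bar / s_bar if s_bar > 0 else 0.0
    phi_bar = b / s if s > 0 else 0.0
    lo = min(s, s_bar)
    chi = lo / s if s > 0 else 1.0
    chi_bar = lo / s_bar if s_bar > 0 else 1.0

    rm = p.r * m
    c = a + b + aL + aR
    c_bar = a_bar + b_bar + aL_bar + aR_bar

    # unbarred family
    daL = p.beta * phi * a - rm * chi * aL - p.delta * aL
    daR = p.beta * phi * a - rm * chi * (1 - phi) * aR - rm * chi * (phi / p.lam) * aR - p.delta * aR
    db = p.beta0 * M * phi_bar + rm * chi * (phi / p.lam) * aR - p.delta * b
    da = (
        p.beta0 * M * (1 - phi_bar)
        + rm * chi * aL
        + rm * chi * (1 - phi) * aR
        - p.beta * phi * a
        - p.delta * a
    )
    dM = rm * chi * c - p.delta * M

    # barred family (substitution rule)
    daL_bar = p.beta_bar * phi_bar * a_bar - rm * chi_bar * aL_bar - p.delta * aL_bar
    daR_bar = (
        p.beta_bar * phi_bar * a_bar
        - rm * chi_bar * (1 - phi_bar) * aR_bar
        - rm * chi_bar * (phi_bar / p.lam) * aR_bar
        - p.delta * aR_bar
    )
    db_bar = p.beta0 * M_bar * phi + rm * chi_bar * (phi_bar / p.lam) * aR_bar - p.delta * b_bar
    da_bar = (
        p.beta0 * M_bar * (1 - phi)
        + rm * chi_bar * aL_bar
        + rm * chi_bar * (1 - phi_bar) * aR_bar
        - p.beta_bar * phi_bar * a_bar
        - p.delta * a_bar
    )
    dM_bar = rm * chi_bar * c_bar - p.delta * M_bar

    return np.array([da, db, daL, daR, da_bar, db_bar, daL_bar, daR_bar, dM, dM_bar])


def catalytic_rhs(state: CatalyticState, params: CatalyticParams) -> CatalyticState:
    return CatalyticState.from_array(catalytic_rhs_array(state.to_array(), params))


def symmetric_rhs_array(x: np.ndarray, params: CatalyticParams) -> np.ndarray:
    """RHS restricted to the mirror-symmetric subspace (a=ā, ..., M=M̄).

    Coordinates are (a, b, aL, aR, M); requires beta == beta_bar for the
    subspace to be forward-invariant.  There phi = phi_bar = b/(a+b) and
    chi = chi_bar = 1, so the kink of the min() is inactive.
    """
    a, b, aL, aR, M = x
    p = params
    m = p.m0 - 2 * M
    s = a + b
    phi = b / s if s > 0 else 0.0
    rm = p.r * m
    c = a + b + aL + aR

    daL = p.beta * phi * a - rm * aL - p.delta * aL
    daR = p.beta * phi * a - rm * (1 - phi) * aR - rm * (phi / p.lam) * aR - p.delta * aR
    db = p.beta0 * M * phi + rm * (phi / p.lam) * aR - p.delta * b
    da = (
        p.beta0 * M * (1 - phi)
        + rm * aL
        + rm * (1 - phi) * aR
        - p.beta * phi * a
        - p.delta * a
    )
    dM = rm * c - p.delta * M
    return np.array([da, db, daL, daR, dM])
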