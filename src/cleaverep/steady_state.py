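"""Steady states of both models and the phase-diagram machinery.

The random-cleavage model has a closed-form symmetric steady state; the
catalytic model's fixed points are found numerically.  The mirror
symmetry (a=ā, b=b̄, aL=āL, aR=āR, M=M̄, with β=β̄) makes all the fixed
points of interest live on a 5-dimensional invariant subspace, so the
root-finding, natural-parameter continuation in β, existence-window
bisection and the β0/δ disappearance threshold all operate on the
reduced system and the resulting points are then embedded in the full
10-variable state.

Interior (all-subpopulations-positive) fixed points are enumerated by a
further semi-analytic reduction: at a symmetric steady state every
concentration fraction is an explicit function of the catalyst fraction
φ = b/(a+b) and the scaled free-monomer level u = r·m/δ, leaving two
scalar consistency equations in (φ, u).  A scan over φ with per-φ
bracketing in u finds every branch, and each candidate is polished by
Newton iteration on the reduced 5-variable system.

Stability is judged from the Jacobian of the reduced system (numeric,
central differences).  The non-cooperative (single-chain-type) points
sit at a transcritical-marginal configuration — the invasion eigenvalue
of the absent type is exactly zero and decay is nonlinear — so the
stability flag treats spectra within a small band of zero as
non-positive for boundary points, while interior points must be
strictly hyperbolic to count as stable.  The spectrum of the full
10-variable Jacobian (stability against symmetry-breaking
perturbations) is computed alongside and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import (
    CatalyticParams,
    CatalyticState,
    ChemostatParams,
    RandomState,
    catalytic_rhs_array,
    symmetric_rhs_array,
)

__all__ = [
    "FixedPoint",
    "ExistenceWindow",
    "ApproxBounds",
    "random_steady_state",
    "survival_condition",
    "monomer_steady_state",
    "noncooperative_fixed_points",
    "cooperative_fixed_point",
    "interior_fixed_points",
    "fixed_point_census",
    "continuation_in_beta",
    "existence_window",
    "disappearance_threshold",
    "approx_bounds",
]

#: half-width of the spectral band around zero treated as marginal
ZERO_TOL = 1e-5
#: residual norm required of a converged fixed point
RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class FixedPoint:
    """A fixed point of one of the models with its linear stability.

    ``kind`` is one of ``extinct``, ``pure_a``, ``pure_b``, ``surviving``
    (random model), ``cooperative``, ``saddle``.  ``eigenvalues`` is the
    spectrum of the Jacobian restricted to the symmetric subspace;
    ``full_eigenvalues`` that of the full 10-variable Jacobian (None for
    random-model points).
    """

    state: CatalyticState | RandomState
    kind: str
    eigenvalues: np.ndarray
    stable: bool
    residual: float = 0.0
    full_eigenvalues: np.ndarray | None = None
    full_stable: bool | None = None

    def monomer(self, params: ChemostatParams | CatalyticParams) -> float:
        """Free monomer concentration at the fixed point."""
        return params.m0 - self.state.M - self.state.M_bar


@dataclass(frozen=True)
class ExistenceWindow:
    """Range of β with a stable cooperative fixed point (other params fixed)."""

    beta_min: float = np.nan
    beta_max: float = np.nan
    empty: bool = True
    # interior sample reused as a continuation seed by callers
    beta_interior: float | None = None
    interior: np.ndarray | None = None

    def __contains__(self, beta: float) -> bool:
        return (not self.empty) and self.beta_min <= beta <= self.beta_max


@dataclass(frozen=True)
class ApproxBounds:
    """Asymptotic (β0/δ ≪ 1/λ) existence bounds and fitness-ratio cap.

    beta_lo = 4λδ, beta_hi = (λ−1)δ/(4β0); ratio_max = 1/2 bounds
    m*coop/m* from above.  Degenerate (empty) when beta_lo >= beta_hi.
    """

    beta_lo: float
    beta_hi: float
    ratio_max: float
    empty: bool


# ----------------------------------------------------------------- random model


def monomer_steady_state(params: ChemostatParams) -> float:
    """Surviving-state free monomer concentration m* = δ²/(β0·r)."""
    return params.delta**2 / (params.beta0 * params.r)


def survival_condition(params: ChemostatParams) -> bool:
    """Whether mutually templating chains survive: β0·m0·r > δ² (strict)."""
    return params.beta0 * params.m0 * params.r > params.delta**2


def random_steady_state(params: ChemostatParams) -> FixedPoint:
    """Analytic steady state of the random-cleavage model.

    In the surviving regime (m0 > m*) the state is the symmetric mixture
    with mean chain length ⟨L⟩ = M/c = δ/β0 = r·m*/δ and

        m* = δ²/(β0·r),    c = c̄ = (β0·m0/δ − δ/r)/2,    M = c·δ/β0.

    Below the survival threshold the extinct state is returned.
    """
    d = params.delta
    if not survival_condition(params):
        return FixedPoint(
            state=RandomState(0.0, 0.0, 0.0, 0.0),
            kind="extinct",
            eigenvalues=np.array([]),
            stable=True,
        )
    c = 0.5 * (params.beta0 * params.m0 / d - d / params.r)
    M = c * d / params.beta0
    return FixedPoint(
        state=RandomState(c, c, M, M),
        kind="surviving",
        eigenvalues=np.array([]),
        stable=True,
    )


# ------------------------------------------------------------ numeric Jacobians


def _numeric_jacobian(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian with step h = 1e-7·max(1, |x_i|)."""
    n = x.size
    J = np.empty((n, n))
    for i in range(n):
        h = 1e-7 * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (fun(xp) - fun(xm)) / (2 * h)
    return J


def _reduced_jacobian(x: np.ndarray, params: CatalyticParams) -> np.ndarray:
    return _numeric_jacobian(lambda z: symmetric_rhs_array(z, params), x)


def _full_jacobian(y: np.ndarray, params: CatalyticParams) -> np.ndarray:
    return _numeric_jacobian(lambda z: catalytic_rhs_array(z, params), y)


def _is_interior(x: np.ndarray) -> bool:
    a, b, aL, aR, M = x
    tot = a + b + aL + aR
    return tot > 0 and min(a, b, aL, aR) > 1e-8 * tot


def _classify(x: np.ndarray, max_re: float, delta: float) -> tuple[str, bool]:
    """(kind, stable) of a symmetric-subspace root from its spectrum."""
    a, b, aL, aR, M = x
    tot = a + b + aL + aR
    tol = ZERO_TOL * delta
    if tot < 1e-12 and M < 1e-12:
        return "extinct", max_re < tol
    if _is_interior(x):
        # interior points must be strictly hyperbolic to count as stable
        if max_re < -tol:
            return "cooperative", True
        return "saddle", False
    # boundary (single-type) points: the invasion eigenvalue of the absent
    # type is exactly zero (transcritical-marginal); treat |Re| < tol as 0
    kind = "pure_a" if b <= 1e-8 * tot else "pure_b"
    return kind, max_re < tol


def _make_fixed_point(
    x: np.ndarray, params: CatalyticParams, kind: str | None = None
) -> FixedPoint:
    """Classify and package a symmetric-subspace root."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    res = float(np.linalg.norm(symmetric_rhs_array(x, params)))
    eig = np.linalg.eigvals(_reduced_jacobian(x, params))
    max_re = float(eig.real.max())
    auto_kind, stable = _classify(x, max_re, params.delta)
    state = CatalyticState.symmetric(*x)
    full_eig = np.linalg.eigvals(_full_jacobian(state.to_array(), params))
    full_stable = bool(np.all(full_eig.real < ZERO_TOL * params.delta))
    return FixedPoint(
        state=state,
        kind=kind if kind is not None else auto_kind,
        eigenvalues=eig,
        stable=stable,
        residual=res,
        full_eigenvalues=full_eig,
        full_stable=full_stable,
    )


# ------------------------------------------- semi-analytic interior enumeration


def _fraction_system(phi: float, u: np.ndarray, params: CatalyticParams):
    """Concentration fractions (of c) at a symmetric steady state.

    With ε = β0/δ, B = β/δ and rates measured in units of δ, a symmetric
    steady state with catalyst fraction φ and scaled monomer u = r·m/δ has

        a/c  = (1 − εu)/(Bφ)                    (chain-number balance)
        aL/c = Bφ (a/c)/(u + 1)
        aR/c = Bφ (a/c)/(u(1−φ+φ/λ) + 1)
        b/c  = εuφ + (uφ/λ)(aR/c)

    and must satisfy the two consistency conditions
    a/c + b/c + aL/c + aR/c = 1 and φ = (b/c)/((a+b)/c).
    """
    d = params.delta
    eps = params.beta0 / d
    B = params.beta / d
    a_c = (1.0 - eps * u) / (B * phi)
    aL_c = B * phi * a_c / (u + 1.0)
    aR_c = B * phi * a_c / (u * (1.0 - phi + phi / params.lam) + 1.0)
    b_c = eps * u * phi + (u * phi / params.lam) * aR_c
    return a_c, b_c, aL_c, aR_c


def _residuals_phi_u(phi: float, u: float, params: CatalyticParams) -> tuple[float, float]:
    a_c, b_c, aL_c, aR_c = _fraction_system(phi, np.asarray(u), params)
    g1 = float(a_c + b_c + aL_c + aR_c - 1.0)
    s = a_c + b_c
    g2 = float(phi - b_c / s) if s > 0 else np.inf
    return g1, g2


def _embed_phi_u(phi: float, u: float, params: CatalyticParams) -> np.ndarray | None:
    """Map a (φ, u) solution to the 5-variable state; None if unphysical."""
    d = params.delta
    m = u * d / params.r
    if not 0 < m < params.m0:
        return None
    M = 0.5 * (params.m0 - m)
    c = M * d / (params.r * m)  # from M-balance r·m·c = δ·M
    a_c, b_c, aL_c, aR_c = _fraction_system(phi, np.asarray(u), params)
    x = np.array([a_c * c, b_c * c, aL_c * c, aR_c * c, M], dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        return None
    return x


def _newton_polish(x: np.ndarray, params: CatalyticParams) -> np.ndarray | None:
    """Polish a near-root of the reduced system.

    Accepts the root when the residual norm is below RESIDUAL_TOL
    relative to the fastest rate in the balance (δ times the largest
    concentration, floored at 1): at large concentrations the absolute
    residual is limited by floating-point cancellation between the
    production and dilution terms.
    """
    sol = optimize.root(
        lambda z: symmetric_rhs_array(z, params), x, method="hybr", tol=1e-13
    )
    z = sol.x
    if not np.all(np.isfinite(z)):
        return None
    scale = max(1.0, float(np.max(np.abs(z))))
    if np.any(z < -1e-9 * scale):
        return None
    z = np.maximum(z, 0.0)
    # the largest cancelling term pair is r·m·c against δ·M, both of size
    # δ·M at a root, so δ·max|x| sets the floating-point residual floor
    rate_scale = max(1.0, params.delta * scale)
    if np.linalg.norm(symmetric_rhs_array(z, params)) > RESIDUAL_TOL * rate_scale:
        return None
    return z


def interior_fixed_points(
    params: CatalyticParams, n_phi: int = 240, n_u: int = 360
) -> list[FixedPoint]:
    """All interior symmetric fixed points (cooperative point and saddles).

    Scans the catalyst fraction φ ∈ (0, 1); for each φ the chain-number
    balance is bracketed and solved in u, and sign changes of the
    remaining consistency residual between neighbouring φ (branches
    matched by proximity in log u) seed two-dimensional refinement plus
    Newton polishing on the reduced system.  Requires β = β̄ (the
    symmetric subspace is only invariant then).
    """
    if params.beta <= 0 or params.beta != params.beta_bar:
        return []
    d = params.delta
    eps = params.beta0 / d
    u_max = min(1.0 / eps, params.r * params.m0 / d) * (1.0 - 1e-9)
    u_grid = np.geomspace(max(1e-3, 1e-5 * u_max), u_max, n_u)
    # the catalyst fraction of the cooperative branch approaches 1 as β0/δ
    # shrinks, so the grid is enriched logarithmically near φ = 1
    phis = np.unique(
        np.concatenate(
            [
                np.linspace(2e-3, 0.9, n_phi),
                1.0 - np.geomspace(1e-8, 0.1, max(60, n_phi // 3)),
            ]
        )
    )

    per_phi: list[list[tuple[float, float]]] = []  # [(u, g2), ...] per phi
    for phi in phis:
        a_c, b_c, aL_c, aR_c = _fraction_system(phi, u_grid, params)
        g1 = a_c + b_c + aL_c + aR_c - 1.0
        roots: list[tuple[float, float]] = []
        sign = np.sign(g1)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        for i in idx:
            try:
                u = optimize.brentq(
                    lambda uu: _residuals_phi_u(phi, uu, params)[0],
                    u_grid[i],
                    u_grid[i + 1],
                    xtol=1e-12,
                    rtol=1e-14,
                )
            except ValueError:
                continue
            roots.append((u, _residuals_phi_u(phi, u, params)[1]))
        per_phi.append(roots)

    # branch-match consecutive φ and collect sign changes of g2
    candidates: list[tuple[float, float]] = []
    for k in range(len(phis) - 1):
        for u1, g1v in per_phi[k]:
            best = None
            for u2, g2v in per_phi[k + 1]:
                dlog = abs(np.log(u2 / u1))
                if dlog < 1.5 and (best is None or dlog < best[0]):
                    best = (dlog, u2, g2v)
            if best is not None and g1v * best[2] < 0:
                candidates.append((0.5 * (phis[k] + phis[k + 1]), float(np.sqrt(u1 * best[1]))))

    points: list[FixedPoint] = []
    seen: list[np.ndarray] = []
    for phi0, u0 in candidates:
        sol = optimize.root(
            lambda z: _residuals_phi_u(z[0], z[1], params),
            np.array([phi0, u0]),
            method="hybr",
            tol=1e-13,
        )
        phi, u = sol.x
        if not (0 < phi < 1 and 0 < u < u_max / (1.0 - 1e-9)):
            continue
        x = _embed_phi_u(phi, u, params)
        if x is None:
            continue
        x = _newton_polish(x, params)
        if x is None or not _is_interior(x):
            continue
        scale = max(1.0, float(np.max(np.abs(x))))
        if any(np.max(np.abs(x - s)) < 1e-6 * scale for s in seen):
            continue
        seen.append(x)
        points.append(_make_fixed_point(x, params))
    return points


# -------------------------------------------------------- catalytic fixed points


def noncooperative_fixed_points(params: CatalyticParams) -> tuple[FixedPoint, FixedPoint]:
    """The pure a/ā and pure b/b̄ fixed points of the catalytic model.

    Both reduce to the random-cleavage steady state (catalytic terms
    vanish when only one of the two chain types is present).  In the
    extinct regime the extinct point is returned twice.
    """
    rs = random_steady_state(params.chemostat)
    if rs.kind == "extinct":
        fp = _make_fixed_point(np.zeros(5), params, kind="extinct")
        return fp, fp
    c = rs.state.c
    M = rs.state.M
    pure_a = _make_fixed_point(np.array([c, 0.0, 0.0, 0.0, M]), params, kind="pure_a")
    pure_b = _make_fixed_point(np.array([0.0, c, 0.0, 0.0, M]), params, kind="pure_b")
    return pure_a, pure_b


def cooperative_fixed_point(
    params: CatalyticParams,
    guess: np.ndarray | CatalyticState | None = None,
) -> FixedPoint | None:
    """Stable cooperative fixed point on the symmetric subspace, or None.

    With a ``guess`` (e.g. the solution at a neighbouring parameter
    value during continuation) a direct Newton solve is tried first;
    otherwise — or when the fast path does not land on a stable interior
    root — the semi-analytic enumeration is used.  Returns None when no
    stable all-positive fixed point exists (not an exception: absence is
    an ordinary regime of the model).

    Does not require the non-cooperative survival condition: the
    cooperative network can persist on catalytic cleavage alone in
    regimes where mutually templating chains relying on random cleavage
    would die out.
    """
    if guess is not None:
        if isinstance(guess, CatalyticState):
            g = np.array([guess.a, guess.b, guess.aL, guess.aR, guess.M])
        else:
            g = np.asarray(guess, dtype=float)
        x = _newton_polish(g, params)
        if x is not None and _is_interior(x):
            fp = _make_fixed_point(x, params)
            if fp.kind == "cooperative":
                return fp
    for fp in interior_fixed_points(params):
        if fp.kind == "cooperative":
            return fp
    return None


def fixed_point_census(params: CatalyticParams) -> list[FixedPoint]:
    """All distinct symmetric-subspace fixed points.

    Contains the extinct point, the two non-cooperative points (in the
    surviving regime) and every interior root (stable cooperative point
    and saddles) found by the semi-analytic enumeration.
    """
    points = [_make_fixed_point(np.zeros(5), params, kind="extinct")]
    pa, pb = noncooperative_fixed_points(params)
    if pa.kind != "extinct":
        points.extend([pa, pb])
        points.extend(interior_fixed_points(params))
    return points


# --------------------------------------------------------------- continuation


def continuation_in_beta(
    params: CatalyticParams,
    beta_grid: Sequence[float],
) -> pd.DataFrame:
    """Natural-parameter continuation of the interior branches along β.

    For each β in the sorted grid every interior fixed point is located
    (fast-path seeding from the previous β, backed by the semi-analytic
    enumeration) and reported with its scaled monomer level
    m*coop/m* and stability.  Branch loss at a fold simply ends the
    corresponding branch; no error is raised.
    """
    m_star = monomer_steady_state(params.chemostat)
    rows = []
    for beta in sorted(beta_grid):
        p = params.with_beta(beta)
        pts = interior_fixed_points(p)
        if not pts:
            rows.append(
                dict(beta=beta, branch="none", found=False, m_coop=np.nan,
                     ratio=np.nan, stable=False, max_eig_re=np.nan)
            )
            continue
        for fp in pts:
            m_coop = fp.monomer(p)
            rows.append(
                dict(
                    beta=beta,
                    branch="stable" if fp.kind == "cooperative" else "saddle",
                    found=True,
                    m_coop=m_coop,
                    ratio=m_coop / m_star,
                    stable=fp.stable,
                    max_eig_re=float(fp.eigenvalues.real.max()),
                )
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ existence window


def _stable_coop_at(
    params: CatalyticParams, beta: float, seed: np.ndarray | None
) -> FixedPoint | None:
    return cooperative_fixed_point(params.with_beta(beta), guess=seed)


def _coop_guess_only(
    params: CatalyticParams, beta: float, seed: np.ndarray
) -> FixedPoint | None:
    """Fast path: Newton from a seed, no enumeration fallback."""
    p = params.with_beta(beta)
    x = _newton_polish(seed, p)
    if x is None or not _is_interior(x):
        return None
    fp = _make_fixed_point(x, p)
    return fp if fp.kind == "cooperative" else None


def _as_seed(fp: FixedPoint) -> np.ndarray:
    st = fp.state
    return np.array([st.a, st.b, st.aL, st.aR, st.M])


def _march_edge(
    params: CatalyticParams,
    beta_in: float,
    x_in: np.ndarray,
    direction: int,
    beta_limit: float,
    tol: float,
) -> float:
    """Walk β outward from an interior point until the stable cooperative
    root is lost, then bisect the edge to absolute precision ``tol``."""
    factor = 1.05 if direction > 0 else 1 / 1.05
    beta_ok, x_ok = beta_in, x_in
    beta_bad = None
    beta = beta_in
    while True:
        beta = beta * factor
        if (direction > 0 and beta > beta_limit) or (direction < 0 and beta < beta_limit):
            beta = beta_limit
        fp = _stable_coop_at(params, beta, x_ok)
        if fp is not None:
            beta_ok, x_ok = beta, _as_seed(fp)
            if beta == beta_limit:
                return beta_ok  # window runs to the search limit
        else:
            beta_bad = beta
            break
    while abs(beta_bad - beta_ok) > tol:
        mid = 0.5 * (beta_bad + beta_ok)
        fp = _stable_coop_at(params, mid, x_ok)
        if fp is not None:
            beta_ok, x_ok = mid, _as_seed(fp)
        else:
            beta_bad = mid
    return beta_ok


def existence_window(
    params: CatalyticParams,
    beta_search_range: tuple[float, float] | None = None,
    hint: ExistenceWindow | None = None,
    edge_tol: float | None = None,
) -> ExistenceWindow:
    """β-range with a stable cooperative fixed point, by edge bisection.

    An interior β is located first (a hint window from a previous call,
    asymptotic-bound candidates, then a log-grid scan of the search
    range); the two edges are then marched to and bisected with
    continuation seeding.  Edge precision defaults to 1e-4·δ.
    """
    d = params.delta
    if beta_search_range is None:
        beta_search_range = (d, 100.0 * d)
    if edge_tol is None:
        edge_tol = 1e-4 * d
    lo_lim, hi_lim = beta_search_range
    candidates: list[tuple[float, np.ndarray | None]] = []
    have_hint = hint is not None and not hint.empty and hint.beta_interior is not None
    if have_hint:
        candidates.append((hint.beta_interior, hint.interior))
        candidates.append((float(np.sqrt(hint.beta_min * hint.beta_max)), hint.interior))
        lo_lim = min(lo_lim, 0.5 * hint.beta_min)
        hi_lim = max(hi_lim, 2.0 * hint.beta_max)
    ab = approx_bounds(params)
    if not ab.empty:
        candidates.append((float(np.sqrt(ab.beta_lo * ab.beta_hi)), None))
    found = None
    for beta, seed in candidates:
        if not lo_lim <= beta <= hi_lim:
            continue
        fp = _stable_coop_at(params, beta, seed)
        if fp is not None:
            found = (beta, _as_seed(fp))
            break
    if found is None and have_hint:
        # the window can drift and narrow between calls: fine guess-chained
        # sweep across (and slightly beyond) the hinted range
        for beta in np.geomspace(0.75 * hint.beta_min, 1.3 * hint.beta_max, 240):
            fp = _coop_guess_only(params, float(beta), hint.interior)
            if fp is not None:
                found = (float(beta), _as_seed(fp))
                break
    if found is None:
        for beta in np.geomspace(lo_lim, hi_lim, 40):
            fp = _stable_coop_at(params, float(beta), None)
            if fp is not None:
                found = (float(beta), _as_seed(fp))
                break
    if found is None:
        return ExistenceWindow(empty=True)
    beta_in, x_in = found
    lo = _march_edge(params, beta_in, x_in, -1, min(lo_lim, beta_in), edge_tol)
    hi = _march_edge(params, beta_in, x_in, +1, max(hi_lim, beta_in), edge_tol)
    # refresh the interior sample at the window midpoint so that callers
    # chaining this window as a hint get a non-stale seed
    beta_mid = float(np.sqrt(lo * hi))
    fp_mid = _stable_coop_at(params, beta_mid, x_in)
    if fp_mid is not None:
        beta_in, x_in = beta_mid, _as_seed(fp_mid)
    return ExistenceWindow(
        beta_min=lo, beta_max=hi, empty=False, beta_interior=beta_in, interior=x_in
    )


def disappearance_threshold(
    lam: float,
    delta: float = 1.0,
    r: float = 1.0,
    m0: float = 100.0,
    rel_tol: float = 1e-3,
    beta0_over_delta_max: float = 0.5,
) -> float:
    """Critical β0/δ above which no stable cooperative state exists (any β).

    Marches β0/δ upward from deep inside the cooperative region with the
    existence-window predicate (hint-chained for robustness near the
    fold where the window closes), then bisects to relative precision
    ``rel_tol``.  The result depends only on λ and β0/δ — the feed m0
    and elongation constant r drop out of the reduced consistency
    equations as long as the feed is far above the survival threshold.
    """
    if not lam > 1:
        raise ValueError("lam must exceed 1 for a cooperative window to exist")
    # start where the asymptotic bounds are comfortably open
    x_lo = 0.25 * (lam - 1) / (16 * lam)

    def window_at(b0d: float, hint: ExistenceWindow | None) -> ExistenceWindow:
        chem = ChemostatParams(m0=m0, delta=delta, r=r, beta0=b0d * delta)
        p = CatalyticParams(chemostat=chem, beta=10.0 * delta, lam=lam)
        return existence_window(p, hint=hint, edge_tol=1e-3 * delta)

    hint = window_at(x_lo, None)
    if hint.empty:
        raise RuntimeError("no cooperative window at the lower end of the search range")
    b0d = x_lo
    last_true = x_lo
    first_false = None
    while b0d < beta0_over_delta_max:
        b0d = min(b0d * 1.3, beta0_over_delta_max)
        w = window_at(b0d, hint)
        if w.empty:
            first_false = b0d
            break
        hint = w
        last_true = b0d
    if first_false is None:
        raise RuntimeError("cooperative window still open at the top of the search range")
    while first_false - last_true > rel_tol * last_true:
        mid = 0.5 * (last_true + first_false)
        w = window_at(mid, hint)
        if w.empty:
            first_false = mid
        else:
            hint = w
            last_true = mid
    return 0.5 * (last_true + first_false)


def approx_bounds(params: CatalyticParams) -> ApproxBounds:
    """Asymptotic existence bounds 4λ < β/δ < (λ−1)δ/(4β0) and the 1/2 cap.

    Valid in the limit β0/δ ≪ 1/λ; degenerate (empty) when the bounds
    cross or λ ≤ 1.
    """
    d = params.delta
    lo = 4.0 * params.lam * d
    hi = (params.lam - 1.0) * d * d / (4.0 * params.beta0)
    return ApproxBounds(beta_lo=lo, beta_hi=hi, ratio_max=0.5, empty=not (lo < hi))
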