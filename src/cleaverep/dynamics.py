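"""Time integration, phase portraits, basin classification and seeding thresholds.

All trajectories integrate the full 10-variable catalytic system with a
stiff-capable solver (LSODA, rtol 1e-9 / atol 1e-12 by default) and an
early-exit event once the vector field norm drops below 1e-8 — fixed
points are approached exponentially at a rate of order the dilution
rate δ, so a horizon of 200/δ is ample in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    CatalyticParams,
    CatalyticState,
    ChemostatParams,
    RandomState,
    catalytic_rhs_array,
    random_rhs_array,
)
from .steady_state import FixedPoint, fixed_point_census

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "integrate_random",
    "classify_endpoint",
    "settle_and_classify",
    "phase_portrait",
    "minimal_seeding_ratio",
]

#: endpoint is matched to a fixed point within this scale-aware relative distance
MATCH_RTOL = 1e-3
#: and only if the vector field there is this quiet
MATCH_RHS_NORM = 1e-6


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid state."""

    def __init__(self, message: str, last_state: CatalyticState):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class Trajectory:
    """A solved trajectory of the catalytic model."""

    times: np.ndarray
    states: np.ndarray  # shape (n_samples, 10), clamped to >= 0
    params: CatalyticParams
    terminal_label: str = "undecided"

    @property
    def terminal_state(self) -> CatalyticState:
        return CatalyticState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        cols = ["a", "b", "aL", "aR", "a_bar", "b_bar", "aL_bar", "aR_bar", "M", "M_bar"]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        df["m"] = self.params.m0 - df["M"] - df["M_bar"]
        return df


def integrate(
    state0: CatalyticState,
    params: CatalyticParams,
    t_end: float | None = None,
    n_samples: int = 201,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    fixed_points: list[FixedPoint] | None = None,
    classify: bool = False,
) -> Trajectory:
    """Integrate the full catalytic system from ``state0``.

    Reported states are clamped to the physical (non-negative) orthant;
    solver internals are not, which keeps the vector field smooth for
    the stiff solver.  With ``classify=True`` the terminal state is
    labelled against ``fixed_points`` (computed on demand).
    """
    if t_end is None:
        t_end = 200.0 / params.delta
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = state0.to_array()

    def rhs(t, y):
        return catalytic_rhs_array(y, params)

    def settled(t, y):
        return float(np.linalg.norm(catalytic_rhs_array(y, params))) - 1e-8

    settled.terminal = True
    settled.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_samples),
        rtol=rtol,
        atol=atol,
        events=settled,
        dense_output=False,
    )
    if not sol.success and sol.status != 1:
        last = CatalyticState.from_array(np.maximum(sol.y[:, -1], 0.0)) if sol.y.size else state0
        raise IntegrationError(f"solver failed: {sol.message}", last)
    times = sol.t
    states = sol.y.T
    if sol.status == 1 and sol.t_events[0].size:  # settled early
        times = np.append(times, sol.t_events[0][-1])
        states = np.vstack([states, sol.y_events[0][-1]])
    traj = Trajectory(times=times, states=np.maximum(states, 0.0), params=params)
    if classify:
        if fixed_points is None:
            fixed_points = fixed_point_census(params)
        traj.terminal_label = classify_endpoint(traj, fixed_points)
    return traj


def integrate_random(
    state0: RandomState,
    params: ChemostatParams,
    t_end: float | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> RandomState:
    """Long-time endpoint of the random-cleavage (4-variable) model."""
    if t_end is None:
        t_end = 400.0 / params.delta

    def settled(t, y):
        return float(np.linalg.norm(random_rhs_array(y, params))) - 1e-10

    settled.terminal = True
    settled.direction = -1
    sol = solve_ivp(
        lambda t, y: random_rhs_array(y, params),
        (0.0, t_end),
        state0.to_array(),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=settled,
    )
    if not sol.success and sol.status != 1:
        raise IntegrationError(
            f"solver failed: {sol.message}",
            CatalyticState.from_array(np.zeros(10)),
        )
    return RandomState.from_array(np.maximum(sol.y[:, -1], 0.0))


def classify_endpoint(traj: Trajectory, fixed_points: list[FixedPoint]) -> str:
    """Label of the fixed point the trajectory terminated at, or "undecided".

    The terminal state must lie within a scale-aware per-coordinate
    relative distance of 1e-3 of some fixed point and the vector field
    norm there must be below 1e-6.
    """
    y = traj.states[-1]
    if np.linalg.norm(catalytic_rhs_array(y, traj.params)) > MATCH_RHS_NORM:
        return "undecided"
    m0 = traj.params.m0
    best = ("undecided", np.inf)
    for fp in fixed_points:
        target = fp.state.to_array() if isinstance(fp.state, CatalyticState) else None
        if target is None:
            continue
        scale = np.maximum(np.abs(target), 1e-3 * m0)
        dist = float(np.max(np.abs(y - target) / scale))
        if dist < best[1]:
            best = (fp.kind, dist)
    return best[0] if best[1] < MATCH_RTOL else "undecided"


def settle_and_classify(
    state0: CatalyticState,
    params: CatalyticParams,
    fixed_points: list[FixedPoint],
    t_end: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    max_doublings: int = 5,
) -> str:
    """Integrate until the endpoint classifies, doubling the horizon as needed.

    The non-cooperative fixed points are approached algebraically (their
    invasion eigenvalue is exactly zero), so a fixed horizon can leave a
    trajectory recognisably en route but outside the match tolerance;
    extending from the reached state is cheap because the solver takes
    long steps on the quiet tail.
    """
    if t_end is None:
        t_end = 200.0 / params.delta
    state = state0
    horizon = t_end
    for _ in range(max_doublings + 1):
        traj = integrate(
            state, params, t_end=horizon, n_samples=2,
            rtol=rtol, atol=atol, fixed_points=fixed_points, classify=True,
        )
        if traj.terminal_label != "undecided":
            return traj.terminal_label
        state = traj.terminal_state
        horizon *= 2.0
    return "undecided"


def phase_portrait(
    params: CatalyticParams,
    a_grid: np.ndarray,
    b_grid: np.ndarray,
    t_end: float | None = None,
    chain_length_init: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Basin-classification grid over symmetric initial conditions.

    Each grid point (a0, b0) seeds the mirror-symmetric state with
    aL = aR = 0 and M = M̄ = (a0 + b0)·L_init, where the initial mean
    chain length L_init defaults to the random-model steady-state value
    δ/β0 (chains start on the physically reached slow manifold; pass
    ``chain_length_init`` to override).  Returns a tidy frame with one
    row per grid point and the basin label of its endpoint.
    """
    if np.any(np.asarray(a_grid) <= 0) or np.any(np.asarray(b_grid) <= 0):
        raise ValueError("grids must be strictly positive")
    L0 = params.delta / params.beta0 if chain_length_init is None else chain_length_init
    fps = fixed_point_census(params)
    rows = []
    for a0 in a_grid:
        for b0 in b_grid:
            M0 = (a0 + b0) * L0
            # keep the initial state physical: both families' chains cannot
            # hold more monomer than the feed supplies
            M0 = min(M0, 0.45 * params.m0)
            state0 = CatalyticState.symmetric(a0, b0, 0.0, 0.0, M0)
            label = settle_and_classify(
                state0, params, fps, t_end=t_end, rtol=rtol, atol=atol
            )
            rows.append(dict(a0=a0, b0=b0, label=label))
    return pd.DataFrame(rows)


def _seeded_state(eps: float, base: FixedPoint, direction: str) -> CatalyticState:
    st = base.state
    if direction == "a_into_b":
        return CatalyticState.symmetric(eps * st.b, st.b, st.aL, st.aR, st.M)
    return CatalyticState.symmetric(st.a, eps * st.a, st.aL, st.aR, st.M)


def minimal_seeding_ratio(
    params: CatalyticParams,
    direction: str = "a_into_b",
    bracket: tuple[float, float] = (1e-6, 0.1),
    t_end: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> float:
    """Smallest symmetric seed ratio that reaches the cooperative basin.

    Starting from the pure b/b̄ steady state, a substrate subpopulation
    a = ā = ε·b is added (direction ``a_into_b``; ``b_into_a`` seeds
    catalysts into the pure a/ā state — the two emergence pathways) and
    the trajectory endpoint is classified.  Bisection in log ε locates
    the cooperative/non-cooperative boundary to two significant figures.
    """
    if direction not in ("a_into_b", "b_into_a"):
        raise ValueError("direction must be 'a_into_b' or 'b_into_a'")
    fps = fixed_point_census(params)
    if not any(fp.kind == "cooperative" for fp in fps):
        raise ValueError("no stable cooperative fixed point at these parameters")
    base_kind = "pure_b" if direction == "a_into_b" else "pure_a"
    base = next(fp for fp in fps if fp.kind == base_kind)
    if t_end is None:
        t_end = 400.0 / params.delta

    def is_coop(eps: float) -> bool:
        label = settle_and_classify(
            _seeded_state(eps, base, direction), params, fps,
            t_end=t_end, rtol=rtol, atol=atol,
        )
        return label == "cooperative"

    lo, hi = bracket
    if is_coop(lo):
        raise ValueError("lower bracket already cooperative; decrease it")
    if not is_coop(hi):
        raise ValueError("upper bracket not cooperative; no threshold in bracket")
    # bisect in log space to two significant figures
    while hi / lo > 1.02:
        mid = float(np.sqrt(lo * hi))
        if is_coop(mid):
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))
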