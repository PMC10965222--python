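"""Fitness of the cooperative state and evolutionary Monte Carlo over (λ, β).

Competition for monomers is the selection mechanism: the steady state
that depresses the free-monomer level furthest excludes everything that
needs more monomer to break even.  Fitness is therefore quantified as
m*/m*coop — the free-monomer level of the non-cooperative (random
cleavage) steady state divided by that of the stable cooperative state.
Without a cooperative state the fitness is exactly 1; with one it
exceeds 2, because the cooperative monomer level is always below m*/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import CatalyticParams, ChemostatParams
from .steady_state import (
    cooperative_fixed_point,
    monomer_steady_state,
    survival_condition,
)

__all__ = ["EvolutionStep", "fitness", "fitness_landscape", "metropolis_evolve"]


@dataclass(frozen=True)
class EvolutionStep:
    """One Metropolis record of the (λ, β) co-evolution walk."""

    step_index: int
    lam: float
    beta: float
    fitness: float
    accepted: bool
    rng_state_tag: str


class _FitnessEvaluator:
    """Fitness with continuation seeding: reuses the last cooperative
    solution as the Newton seed for nearby (λ, β) to avoid re-scanning."""

    def __init__(self, base: ChemostatParams):
        self.base = base
        self._seed: np.ndarray | None = None

    def __call__(self, lam: float, beta: float) -> float:
        p = CatalyticParams(chemostat=self.base, beta=beta, lam=lam)
        fp = cooperative_fixed_point(p, guess=self._seed)
        if fp is None:
            return 1.0
        st = fp.state
        self._seed = np.array([st.a, st.b, st.aL, st.aR, st.M])
        return monomer_steady_state(self.base) / fp.monomer(p)


def fitness(params: CatalyticParams) -> float:
    """m*/m*coop at the stable cooperative point, or exactly 1.0 without one.

    Requires the survival condition β0·m0·r > δ² — outside it the
    reference non-cooperative state is extinct and the ratio loses its
    meaning as a competitive-exclusion measure.
    """
    if not survival_condition(params.chemostat):
        raise ValueError("extinct regime: survival condition violated")
    fp = cooperative_fixed_point(params)
    if fp is None:
        return 1.0
    return monomer_steady_state(params.chemostat) / fp.monomer(params)


def fitness_landscape(
    beta_over_beta0_grid: np.ndarray,
    lam_grid: np.ndarray,
    base: ChemostatParams,
) -> pd.DataFrame:
    """Fitness matrix over catalytic enhancement β/β0 and asymmetry λ.

    Returns a tidy frame (lam, beta_over_beta0, beta, fitness); fitness
    is 1.0 outside the cooperative region.  Rows are swept in ascending
    β with continuation seeding per λ.
    """
    b_grid = np.asarray(beta_over_beta0_grid, dtype=float)
    l_grid = np.asarray(lam_grid, dtype=float)
    if np.any(b_grid <= 0) or np.any(l_grid < 1):
        raise ValueError("grids must be positive and lam >= 1")
    rows = []
    for lam in l_grid:
        ev = _FitnessEvaluator(base)
        for bb0 in np.sort(b_grid):
            beta = bb0 * base.beta0
            rows.append(
                dict(lam=lam, beta_over_beta0=bb0, beta=beta, fitness=ev(lam, beta))
            )
    return pd.DataFrame(rows)


def metropolis_evolve(
    start: tuple[float, float],
    n_steps: int,
    temperature: float = 0.05,
    proposal_scale: float = 0.1,
    seed: int = 0,
    base: ChemostatParams | None = None,
) -> list[EvolutionStep]:
    """Metropolis walk of (λ, β) with fitness as negative energy.

    Proposals are independent multiplicative kicks λ' = λ·exp(η1),
    β' = β·exp(η2) with η ~ U(−scale, +scale); λ is reflected at its
    floor of 1 (in log space).  A proposal is accepted with probability
    min(1, exp((F'−F)/T)).  Leaving the cooperative region is allowed —
    fitness simply drops to 1 there (the population persists by random
    cleavage) — so the walk can cross barren patches.  Deterministic
    given ``seed``.
    """
    lam, beta = start
    if base is None:
        base = ChemostatParams()
    rng = np.random.default_rng(seed)
    ev = _FitnessEvaluator(base)
    current = ev(lam, beta)
    steps: list[EvolutionStep] = []
    for k in range(n_steps):
        eta1, eta2 = rng.uniform(-proposal_scale, proposal_scale, size=2)
        lam_new = lam * float(np.exp(eta1))
        if lam_new < 1.0:
            lam_new = 1.0 / lam_new  # reflect at the lam = 1 boundary
        beta_new = beta * float(np.exp(eta2))
        proposed = ev(lam_new, beta_new)
        accept = proposed >= current or rng.random() < np.exp(
            (proposed - current) / temperature
        )
        if accept:
            lam, beta, current = lam_new, beta_new, proposed
        steps.append(
            EvolutionStep(
                step_index=k,
                lam=lam,
                beta=beta,
                fitness=current,
                accepted=bool(accept),
                rng_state_tag=f"seed={seed},step={k}",
            )
        )
    return steps
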