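"""Stochastic maintenance / de-novo methylation model (Riggs model).

Regional methylation is the equilibrium of two per-division
probabilities acting independently at every site of every cell: a
methylated site stays methylated with maintenance probability ``mu``
and an unmethylated site gains methylation with de-novo probability
``delta``. The population mean then follows the linear recursion

    p_{t+1} = delta + p_t (mu - delta),

which for mu > delta contracts geometrically (ratio mu - delta) to the
equilibrium p* = delta / (delta + 1 - mu). With symmetric rates
(delta = 1 - mu) the equilibrium is exactly 1/2: a population seeded
from equal fully-methylated and fully-unmethylated clones stays at 50%
in expectation, and two populations seeded at 0% and 100% converge to
50% — after roughly 30 divisions for rates near mu = 0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RiggsParams",
    "MethylomeState",
    "NonContractiveError",
    "step_generation",
    "simulate_population",
    "deterministic_recursion",
    "equilibrium_closed_form",
]


class NonContractiveError(ValueError):
    """mu <= delta: the recursion does not contract to an equilibrium."""


@dataclass(frozen=True)
class RiggsParams:
    """Per-division rates and population dimensions."""

    mu: float  # maintenance probability
    delta: float  # de novo probability
    n_cells: int = 1000
    n_sites: int = 100
    n_generations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu", "delta"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 0 or self.n_sites < 0 or self.n_generations < 0:
            raise ValueError("n_cells, n_sites and n_generations must be >= 0")


@dataclass
class MethylomeState:
    """Binary per-cell per-site methylation states at one generation."""

    generation: int
    states: np.ndarray  # (n_cells, n_sites) bool

    @property
    def mean_methylation(self) -> float:
        return float(self.states.mean()) if self.states.size else float("nan")


def step_generation(
    state: MethylomeState, params: RiggsParams, rng: np.random.Generator
) -> MethylomeState:
    """One cell division: every methylated site survives independently
    with probability mu; every unmethylated site converts with
    probability delta."""
    u = rng.random(state.states.shape)
    new = np.where(state.states, u < params.mu, u < params.delta)
    return MethylomeState(generation=state.generation + 1, states=new)


def simulate_population(
    params: RiggsParams, init_fraction_fully_methylated: float = 0.5
) -> pd.DataFrame:
    """Simulate the population and record the mean-methylation
    trajectory alongside the deterministic recursion.

    The stated fraction of cells starts fully methylated and the rest
    fully unmethylated. Returns columns ``generation,
    mean_methylation, closed_form_mean`` for generations
    0..n_generations; deterministic under ``params.seed``.
    """
    if not (0 <= init_fraction_fully_methylated <= 1):
        raise ValueError("init_fraction_fully_methylated must be in [0, 1]")
    if params.n_cells * params.n_sites == 0:
        raise ValueError("n_cells * n_sites must be positive")
    rng = np.random.default_rng(params.seed)
    n_meth = round(init_fraction_fully_methylated * params.n_cells)
    states = np.zeros((params.n_cells, params.n_sites), dtype=bool)
    states[:n_meth] = True
    state = MethylomeState(generation=0, states=states)
    p0 = n_meth / params.n_cells
    closed = deterministic_recursion(params.mu, params.delta, p0, params.n_generations)
    rows = [(0, state.mean_methylation, closed[0])]
    for t in range(1, params.n_generations + 1):
        state = step_generation(state, params, rng)
        rows.append((t, state.mean_methylation, closed[t]))
    return pd.DataFrame(rows, columns=["generation", "mean_methylation", "closed_form_mean"])


def deterministic_recursion(mu: float, delta: float, p0: float, n_generations: int) -> np.ndarray:
    """Expected mean-methylation trajectory p_{t+1} = delta + p_t (mu - delta)."""
    out = np.empty(n_generations + 1)
    out[0] = p0
    for t in range(n_generations):
        out[t + 1] = delta + out[t] * (mu - delta)
    return out


def equilibrium_closed_form(
    mu: float, delta: float, p0: float | None = None, eps: float = 0.01
) -> dict:
    """Equilibrium p* = delta/(delta + 1 - mu) and convergence analytics.

    The deviation decays geometrically with ratio mu - delta; from p0,
    the first generation within eps of p* is
    t = ceil(ln(eps / |p0 - p*|) / ln(mu - delta)). Requires mu > delta.
    """
    if mu <= delta:
        raise NonContractiveError(f"need mu > delta, got mu={mu}, delta={delta}")
    p_star = delta / (delta + 1 - mu)
    ratio = mu - delta
    out = {"p_star": p_star, "contraction_ratio": ratio}
    if p0 is not None:
        gap = abs(p0 - p_star)
        if gap <= eps:
            out["generations_to_eps"] = 0
            out["generations_to_eps_exact"] = 0.0
        else:
            exact = math.log(eps / gap) / math.log(ratio)
            out["generations_to_eps"] = math.ceil(exact)
            out["generations_to_eps_exact"] = exact
    return out
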