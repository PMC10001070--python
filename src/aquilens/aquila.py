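"""Adaptive Aquila Optimizer (AAO).

A population metaheuristic for minimising a black-box objective over box
bounds.  It mimics four hunting behaviours of the Aquila eagle:

1. expanded exploration — high soar: move between the current best and the
   population mean, X1 = X_best·(1 − t/T) + (X_M − X_best)·rand;
2. narrowed exploration — contour flight with Lévy steps around a random
   flock member, X2 = X_best·levy(D) + X_R + (y − x)·rand, where (y, x)
   trace a logarithmic-spiral scan of the search region;
3. expanded exploitation — low descent,
   X3 = (X_best − X_M)·α − rand + ((UB − LB)·rand + LB)·δ;
4. narrowed exploitation — swoop,
   X4 = QF·X_best − G1·X·rand − G2·levy(D), with quality function
   QF = t^((2·rand−1)/(1−T)²), escape factor G1 = 2·rand − 1 and chase
   slope G2 = 2·(1 − t/T) decaying linearly from 2 to 0.

The adaptive variant adds niche sharing: individuals crowded within radius
ρ of others are penalised by the sharing sum S_i = Σ_j sh(d_ij), with
sh(d) = 1 − d/ρ for d < ρ and 0 otherwise; the adjusted fitness
F_i' = F_i·S_i (F_i/S_i for negative fitness, so the penalty always
worsens) relaxes the greedy acceptance threshold for crowded individuals,
pushing them to update and search elsewhere.  The current best keeps its
raw fitness and is therefore never outranked by the adjustment.  Proposals
are clamped to the bounds and accepted greedily against the adjusted
fitness, while the global best is tracked on raw fitness, so the
best-so-far trace is non-increasing (elitism).

Strategy schedule: exploration while t ≤ (2/3)·T, exploitation afterwards,
picking within each pair with probability 1/2 — the original Aquila
Optimizer convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

__all__ = [
    "Bounds",
    "Candidate",
    "AAOConfig",
    "OptimizationTrace",
    "levy_sigma",
    "levy_flight",
    "expanded_exploration",
    "narrowed_exploration",
    "expanded_exploitation",
    "narrowed_exploitation",
    "niche_sharing",
    "initialize",
    "optimize",
]

STRATEGY_NAMES = ("expanded_exploration", "narrowed_exploration",
                  "expanded_exploitation", "narrowed_exploitation")


@dataclass(frozen=True)
class Bounds:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape:
            raise ValueError("lower and upper must have equal length")
        if (lo > hi).any():
            raise ValueError("lower bound exceeds upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        return bool((x >= self.lower - atol).all()
                    and (x <= self.upper + atol).all())


@dataclass
class Candidate:
    position: np.ndarray
    fitness: float = np.inf


@dataclass(frozen=True)
class AAOConfig:
    """Optimizer settings.

    alpha, delta   exploitation adjustment parameters in (0, 1)
    levy_beta      stability index β of the Lévy step, in (0, 2]
    levy_scale     step scale s (the classical small-step convention 0.01)
    niche_radius   sharing radius ρ; if None, 0.1·‖UB − LB‖ at run time
    r1             spiral base radius index in [1, 20]
    """

    population_size: int = 20
    max_iterations: int = 100
    alpha: float = 0.1
    delta: float = 0.1
    levy_beta: float = 1.5
    levy_scale: float = 0.01
    niche_radius: float | None = None
    r1: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if not 0.0 < self.levy_beta <= 2.0:
            raise ValueError("levy_beta must lie in (0, 2]")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.delta < 1.0):
            raise ValueError("alpha and delta must lie in (0, 1)")
        if self.niche_radius is not None and self.niche_radius <= 0:
            raise ValueError("niche_radius must be positive")
        if not 1.0 <= self.r1 <= 20.0:
            raise ValueError("r1 must lie in [1, 20]")


@dataclass
class OptimizationTrace:
    best_fitness: list[float] = field(default_factory=list)
    best_position: list[np.ndarray] = field(default_factory=list)
    strategies: list[list[str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.best_fitness)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, (bf, strats) in enumerate(zip(self.best_fitness,
                                             self.strategies), start=1):
            row = {"iteration": t, "best_fitness": bf}
            for name in STRATEGY_NAMES:
                row[f"n_{name}"] = strats.count(name)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def levy_sigma(beta: float) -> float:
    """σ of the Mantegna Lévy-step construction.

    σ = [Γ(1+β)·sin(πβ/2) / (Γ((1+β)/2)·β·2^((β−1)/2))]^(1/β);
    σ(1.5) ≈ 0.6966.
    """
    num = _gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_flight(D: int, beta: float, scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step s·u·σ/|v|^(1/β), u and v standard normal D-vectors.

    Draw order: u first, then v.
    """
    u = rng.standard_normal(D)
    v = rng.standard_normal(D)
    return scale * u * levy_sigma(beta) / np.abs(v) ** (1.0 / beta)


def population_mean(positions: np.ndarray) -> np.ndarray:
    return np.asarray(positions, dtype=float).mean(axis=0)


def expanded_exploration(position: np.ndarray, best: np.ndarray,
                         pop_mean: np.ndarray, t: int, T: int,
                         rng: np.random.Generator) -> np.ndarray:
    """High-soar move (one uniform scalar draw)."""
    r = rng.uniform()
    return best * (1.0 - t / T) + (pop_mean - best) * r


def _spiral(D: int, r1: float) -> tuple[np.ndarray, np.ndarray]:
    """Spiral scan coordinates: y = r·cosθ, x = r·sinθ with
    r = r1 + 0.00565·D1 and θ = −0.005·D1 + 3π/2, D1 = 1..D."""
    d1 = np.arange(1, D + 1, dtype=float)
    r = r1 + 0.00565 * d1
    theta = -0.005 * d1 + 3.0 * np.pi / 2.0
    return r * np.cos(theta), r * np.sin(theta)


def narrowed_exploration(position: np.ndarray, best: np.ndarray,
                         random_other: np.ndarray, r1: float,
                         levy_beta: float, levy_scale: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Contour-flight move (draw order: Lévy u, v, then one uniform scalar)."""
    D = position.size
    step = levy_flight(D, levy_beta, levy_scale, rng)
    y, x = _spiral(D, r1)
    r = rng.uniform()
    return best * step + random_other + (y - x) * r


def expanded_exploitation(position: np.ndarray, best: np.ndarray,
                          pop_mean: np.ndarray, bounds: Bounds,
                          alpha: float, delta: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Low-descent move (draw order: two uniform scalars).

    The update reads (X_best − X_M)·α − rand + ((UB − LB)·rand + LB)·δ,
    i.e. the first random draw is subtracted, not an exponent on α.
    """
    r_sub = rng.uniform()
    r_box = rng.uniform()
    box = (bounds.upper - bounds.lower) * r_box + bounds.lower
    return (best - pop_mean) * alpha - r_sub + box * delta


def narrowed_exploitation(position: np.ndarray, best: np.ndarray,
                          t: int, T: int, levy_beta: float, levy_scale: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Swoop move (draw order: QF uniform, G1 uniform, Lévy u, v, then a
    per-dimension uniform vector multiplying the current position).

    QF = t^((2·rand−1)/(1−T)²) balances the search; G1 = 2·rand − 1 models
    prey escape; G2 = 2·(1 − t/T) decays linearly from 2 to 0.  The random
    factor on X(t) is drawn per dimension so coordinates can be refined
    independently near the optimum.
    """
    D = position.size
    r_qf = rng.uniform()
    if T > 1:
        qf = float(t) ** ((2.0 * r_qf - 1.0) / (1.0 - T) ** 2)
    else:  # degenerate single-iteration run: exponent denominator vanishes
        qf = 1.0
    g1 = 2.0 * rng.uniform() - 1.0
    g2 = 2.0 * (1.0 - t / T)
    step = levy_flight(D, levy_beta, levy_scale, rng)
    r = rng.uniform(size=D)
    return qf * best - (g1 * position * r) - g2 * step


def niche_sharing(positions: np.ndarray, fitnesses: np.ndarray,
                  rho: float, best_index: int | None = None) -> np.ndarray:
    """Crowding penalty via fitness sharing over Euclidean distances.

    sh(d) = 1 − d/ρ for d < ρ, else 0 (self-distance contributes 1).  For
    minimisation the penalty must worsen the adjusted value, so
    F_i' = F_i·S_i with S_i = Σ_j sh(d_ij) ≥ 1 (and F_i/S_i when F_i < 0).
    Isolated individuals (S_i = 1) are unchanged.  The incumbent best keeps
    its raw fitness; since every adjusted value is ≥ its raw value, the
    best individual's rank is never worsened by the adjustment.
    """
    if rho <= 0:
        raise ValueError("niche radius must be positive")
    X = np.atleast_2d(np.asarray(positions, dtype=float))
    F = np.asarray(fitnesses, dtype=float)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    sh = np.where(d < rho, 1.0 - d / rho, 0.0)
    S = sh.sum(axis=1)
    adjusted = np.where(F >= 0, F * S, F / S)
    if best_index is None:
        best_index = int(np.argmin(F))
    adjusted[best_index] = F[best_index]
    return adjusted


def initialize(bounds: Bounds, N: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions X_ij = rand·(UB_j − LB_j) + LB_j."""
    if N < 2:
        raise ValueError("population size must be at least 2")
    span = bounds.upper - bounds.lower
    return rng.uniform(size=(N, bounds.dim)) * span + bounds.lower


def _evaluate(objective, x: np.ndarray) -> float:
    f = float(objective(x))
    return f


def optimize(objective, bounds: Bounds,
             config: AAOConfig) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Minimise ``objective`` over ``bounds``; returns (x_best, f_best, trace)."""
    rng = np.random.default_rng(config.seed)
    N, T = config.population_size, config.max_iterations
    rho = config.niche_radius
    if rho is None:
        rho = 0.1 * float(np.linalg.norm(bounds.upper - bounds.lower))
        rho = max(rho, np.finfo(float).tiny)

    X = initialize(bounds, N, rng)
    F = np.array([_evaluate(objective, x) for x in X])
    if not np.isfinite(F).all():
        bad = ~np.isfinite(F)
        warnings.warn(f"{bad.sum()} non-finite initial fitness value(s); "
                      "treated as +inf", stacklevel=2)
        F[bad] = np.inf
    best_i = int(np.argmin(F))
    best_x, best_f = X[best_i].copy(), float(F[best_i])

    trace = OptimizationTrace()
    for t in range(1, T + 1):
        pop_mean = population_mean(X)
        adjusted = niche_sharing(X, F, rho, best_index=int(np.argmin(F)))
        strategies: list[str] = []
        explore = t <= (2.0 / 3.0) * T
        for i in range(N):
            pick = rng.uniform() < 0.5
            if explore:
                if pick:
                    prop = expanded_exploration(X[i], best_x, pop_mean, t, T, rng)
                    strategies.append("expanded_exploration")
                else:
                    j = int(rng.integers(N))
                    prop = narrowed_exploration(
                        X[i], best_x, X[j], config.r1,
                        config.levy_beta, config.levy_scale, rng)
                    strategies.append("narrowed_exploration")
            else:
                if pick:
                    prop = expanded_exploitation(
                        X[i], best_x, pop_mean, bounds,
                        config.alpha, config.delta, rng)
                    strategies.append("expanded_exploitation")
                else:
                    prop = narrowed_exploitation(
                        X[i], best_x, t, T,
                        config.levy_beta, config.levy_scale, rng)
                    strategies.append("narrowed_exploitation")
            prop = bounds.clamp(prop)
            f_new = _evaluate(objective, prop)
            if not np.isfinite(f_new):
                warnings.warn(
                    f"objective returned non-finite value at iteration {t}; "
                    "candidate rejected", stacklevel=2)
                continue
            if f_new < adjusted[i]:
                X[i] = prop
                F[i] = f_new
                if f_new < best_f:
                    best_f = f_new
                    best_x = prop.copy()
        trace.best_fitness.append(best_f)
        trace.best_position.append(best_x.copy())
        trace.strategies.append(strategies)
    return best_x, best_f, trace
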