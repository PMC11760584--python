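"""Escape Coati Optimization Algorithm (eCOA) for bound-constrained minimisation.

The coati optimisation metaphor runs a population of N candidate solutions
through two phases per iteration:

* exploration ("hunting the iguana"): a prey position is chosen per coati
  — the global best for the upper half of the population, a fresh uniform
  random point in the box otherwise — and the coati moves towards it. The
  escape variant draws an escape probability per coati: with probability
  1/2 a soft encirclement move is tried first and, if it does not improve,
  retried with an added Levy-flight step (heavy-tailed, Mantegna's
  algorithm, beta = 1.5); otherwise a hard encirclement move contracts the
  coati straight towards the prey. Moves are accepted greedily.
* exploitation ("fleeing to a nearby safe spot"): each coati is perturbed
  inside a local box whose bounds shrink as lb/t, ub/t with the iteration
  counter t, again with greedy acceptance.

Greedy acceptance in both phases makes the best-so-far trajectory
monotone non-increasing; candidates are clipped to the box at every step.
A plain-COA baseline (``variant="coa"``) drops the escape-probability /
Levy branch and always uses the hard encirclement move in exploration.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np

__all__ = ["SearchSpace", "OptResult", "levy_flight", "minimize",
           "OBJECTIVES"]


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    """Box constraints with an optional integer-dimension mask.

    Masked dimensions are optimised in continuous space and rounded to the
    nearest integer before each objective evaluation (and in the reported
    best position).
    """

    lower: np.ndarray
    upper: np.ndarray
    integer: np.ndarray | None = None

    def __post_init__(self) -> None:
        lb = np.asarray(self.lower, dtype=float)
        ub = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lb)
        object.__setattr__(self, "upper", ub)
        if lb.shape != ub.shape or lb.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if np.any(lb >= ub):
            raise ValueError("need lower < upper in every dimension")
        mask = (np.zeros(len(lb), dtype=bool) if self.integer is None
                else np.asarray(self.integer, dtype=bool))
        object.__setattr__(self, "integer", mask)

    @property
    def ndim(self) -> int:
        return len(self.lower)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def round_integers(self, x: np.ndarray) -> np.ndarray:
        out = np.array(x, dtype=float)
        out[..., self.integer] = np.rint(out[..., self.integer])
        return out


@dataclasses.dataclass
class OptResult:
    best_position: np.ndarray
    best_fitness: float
    trajectory: np.ndarray  # best-so-far after each iteration, length T
    n_evaluations: int
    variant: str


def levy_flight(rng: np.random.Generator, size, beta: float = 1.5,
                scale: float = 0.01) -> np.ndarray:
    """Heavy-tailed step lengths via Mantegna's algorithm."""
    sigma_u = (
        math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
        / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, size)
    v = rng.normal(0.0, 1.0, size)
    return scale * u / np.abs(v) ** (1 / beta)


def _safe_eval(objective: Callable, space: SearchSpace, x: np.ndarray,
               counter: list[int]) -> float:
    counter[0] += 1
    val = objective(space.round_integers(x))
    return float(val) if np.isfinite(val) else math.inf


def minimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    n_coatis: int = 50,
    n_iterations: int = 10,
    seed: int = 0,
    variant: str = "ecoa",
    coa_convention: bool = False,
) -> OptResult:
    """Run eCOA (or the plain-COA baseline) on a bound-constrained objective.

    ``coa_convention`` swaps which half of the population targets the best
    position when choosing the prey: the printed rule sends coatis with
    index i >= N/2 towards the best; the original description sends the
    first half. Both are exposed because the intended split is ambiguous.
    """
    if n_coatis < 2:
        raise ValueError("need at least 2 coatis")
    if n_iterations < 1:
        raise ValueError("need at least 1 iteration")
    if variant not in ("ecoa", "coa"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    m = space.ndim
    counter = [0]
    X = space.lower + rng.random((n_coatis, m)) * (space.upper - space.lower)
    F = np.array([_safe_eval(objective, space, x, counter) for x in X])
    best_i = int(np.argmin(F))
    best_x = X[best_i].copy()
    best_f = float(F[best_i])
    trajectory = np.empty(n_iterations)

    for t in range(1, n_iterations + 1):
        # -- exploration -------------------------------------------------
        for i in range(n_coatis):
            # prey position: global best for one half, random otherwise
            # (1-based index convention of the printed rule)
            takes_best = (i + 1) >= n_coatis / 2
            if coa_convention:
                takes_best = not takes_best
            if takes_best:
                iguana = best_x
            else:
                iguana = space.lower + rng.random(m) * (space.upper - space.lower)
            if variant == "ecoa" and rng.random() < 0.5:
                # soft encirclement, with a Levy-flight retry on failure
                r = rng.random(m)
                cand = iguana - r * np.abs(2.0 * (1.0 - r) * iguana - X[i])
                cand = space.clip(cand)
                f_cand = _safe_eval(objective, space, cand, counter)
                if f_cand >= F[i]:
                    cand = space.clip(cand + rng.random(m) * levy_flight(rng, m))
                    f_cand = _safe_eval(objective, space, cand, counter)
            else:
                r = rng.random(m)
                cand = space.clip(iguana - r * np.abs(iguana - X[i]))
                f_cand = _safe_eval(objective, space, cand, counter)
            if f_cand < F[i]:
                X[i] = cand
                F[i] = f_cand
                if f_cand < best_f:
                    best_f = f_cand
                    best_x = cand.copy()
        # -- exploitation ------------------------------------------------
        lb_loc = space.lower / t
        ub_loc = space.upper / t
        for i in range(n_coatis):
            r = rng.random(m)
            step = (1.0 - 2.0 * rng.random(m)) * (lb_loc + r * (ub_loc - lb_loc))
            cand = space.clip(X[i] + step)
            f_cand = _safe_eval(objective, space, cand, counter)
            if f_cand < F[i]:
                X[i] = cand
                F[i] = f_cand
                if f_cand < best_f:
                    best_f = f_cand
                    best_x = cand.copy()
        trajectory[t - 1] = best_f

    return OptResult(
        best_position=space.round_integers(best_x),
        best_fitness=best_f,
        trajectory=trajectory,
        n_evaluations=counter[0],
        variant=variant,
    )


# small registry of analytic objectives for testing and the CLI
def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x**2))


def _rastrigin(x: np.ndarray) -> float:
    return float(10 * len(x) + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


def _absdev(c: float) -> Callable[[np.ndarray], float]:
    return lambda x: float(np.sum(np.abs(x - c)))


OBJECTIVES: dict[str, Callable[[np.ndarray], float]] = {
    "sphere": _sphere,
    "rastrigin": _rastrigin,
    "absdev2": _absdev(2.0),
}
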