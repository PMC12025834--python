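"""Genetic search for constraint boxes in the six-dimensional train space.

A chromosome is 12 real genes — a lower and upper bound per characteristic,
with "unbounded" encoded as the characteristic's observed range endpoints.
Fitness is the most extreme frequency-diagram cell reachable under the box:
``max_cell (AUC - 0.5)`` for a red search (trains typical of the first
group), ``max_cell (0.5 - AUC)`` for blue.  Boxes selecting fewer than
``min_support`` trains per fragment on average are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diagrams import FragmentTrains, frequency_auc_diagram
from .types import CHARACTERISTICS, ConstraintBox

__all__ = ["SearchConfig", "SearchResult", "fitness", "evolve"]


@dataclass(frozen=True)
class SearchConfig:
    """Genetic-algorithm hyperparameters.

    direction : "red" maximizes AUC, "blue" minimizes.
    mutation_sigma : Gaussian mutation scale as a fraction of each
        characteristic's observed range.
    min_support : minimum mean wave trains per fragment a box must keep.
    coarse_step : frequency-grid step (Hz) used during fitness evaluation;
        the winning box is re-evaluated on the full 0.1 Hz grid.
    """

    direction: str = "red"
    population: int = 64
    generations: int = 100
    tournament_size: int = 3
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    mutation_sigma: float = 0.1
    min_support: float = 1.0
    coarse_step: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("red", "blue"):
            raise ValueError("direction must be 'red' or 'blue'")
        if self.population < 2:
            raise ValueError("population must be at least 2")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_support <= 0:
            raise ValueError("min_support must be positive")


@dataclass
class SearchResult:
    """Winning box with the diagram cell and AUC that justify it."""

    box: ConstraintBox
    best_cell: tuple[float, float]
    best_auc: float
    fitness_history: list[float] = field(default_factory=list)


def _char_ranges(groups: list[list[FragmentTrains]]) -> np.ndarray:
    vals = [[] for _ in CHARACTERISTICS]
    for group in groups:
        for ft in group:
            for t in ft.trains:
                for k, c in enumerate(CHARACTERISTICS):
                    vals[k].append(t.characteristic(c))
    if not vals[0]:
        raise ValueError("no wave trains to search over")
    return np.array([[min(v), max(v)] for v in vals])


def _genes_to_box(genes: np.ndarray, ranges: np.ndarray,
                  simplify_frac: float = 0.0) -> ConstraintBox:
    """Decode 12 genes into a box; bounds at/near range endpoints become open.

    ``simplify_frac`` > 0 additionally reports bounds within that fraction
    of the data range of an endpoint as unbounded (post-hoc simplification
    mirroring how discovered criteria are quoted with most cells open).
    """
    bounds = {}
    for k, name in enumerate(CHARACTERISTICS):
        lo, hi = sorted((genes[2 * k], genes[2 * k + 1]))
        rlo, rhi = ranges[k]
        span = rhi - rlo
        tol = simplify_frac * span
        blo = None if lo <= rlo + tol else float(lo)
        bhi = None if hi >= rhi - tol else float(hi)
        if name == "phase":
            if blo is not None:
                blo = max(blo, -np.pi)
            if bhi is not None:
                bhi = min(bhi, np.pi)
        if blo is not None or bhi is not None:
            bounds[name] = (blo, bhi)
    return ConstraintBox(**bounds)


def _signed_score(auc_extreme: float, direction: str) -> float:
    return auc_extreme - 0.5 if direction == "red" else 0.5 - auc_extreme


def fitness(
    box: ConstraintBox,
    group_a: list[FragmentTrains],
    group_b: list[FragmentTrains],
    direction: str = "red",
    min_support: float = 1.0,
    grid: np.ndarray | None = None,
) -> float:
    """Best signed diagram-cell score of *box*; -inf if support is too low."""
    n_frag = len(group_a) + len(group_b)
    kept = sum(sum(1 for t in ft.trains if box.contains(t)) for ft in group_a + group_b)
    if n_frag == 0 or kept / n_frag < min_support:
        return -np.inf
    if grid is None:
        grid = np.arange(0.5, 50.0 + 1e-9, 0.5)
    diagram = frequency_auc_diagram(group_a, group_b, box, grid=grid)
    _, _, extreme = diagram.best_cell(direction)
    return _signed_score(extreme, direction)


def evolve(
    group_a: list[FragmentTrains],
    group_b: list[FragmentTrains],
    cfg: SearchConfig = SearchConfig(),
) -> SearchResult:
    """Run the genetic search and return the best box on the full grid.

    Tournament selection, uniform crossover, Gaussian mutation clipped to
    the observed characteristic ranges, elitism of one.  Deterministic for
    a fixed config seed.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 fragments per group")
    rng = np.random.default_rng(cfg.seed)
    ranges = _char_ranges([group_a, group_b])
    span = ranges[:, 1] - ranges[:, 0]
    span[span == 0] = 1.0

    coarse = np.arange(cfg.coarse_step, 50.0 + 1e-9, cfg.coarse_step)

    def decode(genes):
        return _genes_to_box(genes, ranges)

    def evaluate(genes):
        return fitness(decode(genes), group_a, group_b, cfg.direction,
                       cfg.min_support, grid=coarse)

    n_genes = 2 * len(CHARACTERISTICS)
    lo = np.repeat(ranges[:, 0], 2)
    hi = np.repeat(ranges[:, 1], 2)
    pop = rng.uniform(lo, hi, size=(cfg.population, n_genes))
    # Seed one fully open box so the search starts from a feasible point.
    pop[0] = np.column_stack([ranges[:, 0], ranges[:, 1]]).ravel()
    fit = np.array([evaluate(g) for g in pop])

    history = []
    sigma = cfg.mutation_sigma * np.repeat(span, 2)
    for _ in range(cfg.generations):
        best_idx = int(np.argmax(fit))
        history.append(float(fit[best_idx]))
        new_pop = [pop[best_idx].copy()]                       # elitism
        while len(new_pop) < cfg.population:
            # Tournament selection of two parents.
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, cfg.tournament_size)
                parents.append(pop[contenders[np.argmax(fit[contenders])]])
            child = parents[0].copy()
            if rng.random() < cfg.crossover_rate:
                take = rng.random(n_genes) < 0.5
                child[take] = parents[1][take]
            mutate = rng.random(n_genes) < cfg.mutation_rate
            child[mutate] += sigma[mutate] * rng.standard_normal(int(mutate.sum()))
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fit = np.array([evaluate(g) for g in pop])

    best_idx = int(np.argmax(fit))
    history.append(float(fit[best_idx]))
    box = _genes_to_box(pop[best_idx], ranges, simplify_frac=0.02)

    # Re-evaluate the winner on the full-resolution grid.
    diagram = frequency_auc_diagram(group_a, group_b, box)
    blo, bhi, extreme = diagram.best_cell(cfg.direction)
    return SearchResult(box=box, best_cell=(blo, bhi), best_auc=extreme,
                        fitness_history=history)
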