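"""Elitist NSGA-II over the discrete cultivation design grid.

The feasible space is tiny but mixed: 11 spacing levels (30–80 cm, step 5)
× 4 pruning codes = 44 designs.  Objectives are (total growth period,
−yield, −quality closeness), all minimized, evaluated through the trained
surrogate.  The algorithm is the standard elitist scheme: fast
non-dominated sorting, crowding-distance diversity, binary tournament
selection, uniform per-gene crossover and random-reset mutation, with a
(μ+λ) truncation each generation.  Because the grid is exhaustive at desk
scale, a brute-force Pareto oracle over all 44 designs is provided and
used to certify the evolved front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surrogate import SurrogateModel, predict_batch
from .trial_data import (
    PRUNING_LABELS,
    SPACING_MAX_CM,
    SPACING_MIN_CM,
    SPACING_STEP_CM,
    TreatmentSpec,
)

__all__ = [
    "N_SPACING_LEVELS",
    "Genome",
    "Individual",
    "GAParams",
    "ParetoSolution",
    "ParetoFront",
    "decode_genome",
    "feasible_genomes",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "make_offspring",
    "evolve",
    "brute_force_pareto",
]

N_SPACING_LEVELS = (SPACING_MAX_CM - SPACING_MIN_CM) // SPACING_STEP_CM + 1  # 11


@dataclass(frozen=True)
class Genome:
    """Feasible-by-construction design: spacing index 0..10, pruning 1..4."""

    spacing_index: int
    pruning_code: int

    def __post_init__(self):
        if not 0 <= self.spacing_index < N_SPACING_LEVELS:
            raise ValueError(f"spacing index {self.spacing_index} outside grid")
        if self.pruning_code not in PRUNING_LABELS:
            raise ValueError(f"pruning code {self.pruning_code} not in 1..4")

    @property
    def spacing_cm(self) -> int:
        return SPACING_MIN_CM + SPACING_STEP_CM * self.spacing_index


def decode_genome(g: Genome) -> TreatmentSpec:
    return TreatmentSpec(
        label=f"S{g.spacing_cm}-{PRUNING_LABELS[g.pruning_code]}",
        spacing_cm=g.spacing_cm,
        pruning_code=g.pruning_code,
    )


def feasible_genomes() -> list[Genome]:
    """All 44 designs on the feasible grid, in (spacing, pruning) order."""
    return [
        Genome(spacing_index=i, pruning_code=c)
        for i in range(N_SPACING_LEVELS)
        for c in sorted(PRUNING_LABELS)
    ]


@dataclass
class Individual:
    genome: Genome
    objectives: np.ndarray  # (duration, -yield, -ci), minimized
    rank: int = -1
    crowding: float = 0.0


@dataclass(frozen=True)
class GAParams:
    population_size: int = 100
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population and generations must be positive")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ParetoSolution:
    design: TreatmentSpec
    duration_days: float
    yield_t_hm2: float
    ci: float

    @property
    def objectives_min(self) -> np.ndarray:
        """Internal minimization-sense objective vector."""
        return np.array([self.duration_days, -self.yield_t_hm2, -self.ci])


@dataclass
class ParetoFront:
    """Deduplicated non-dominated designs in physical units, plus run
    provenance (GA parameters, seed, surrogate identity)."""

    solutions: list[ParetoSolution]
    provenance: dict = field(default_factory=dict)

    def genomes(self) -> set[tuple[int, int]]:
        return {
            (s.design.spacing_cm, s.design.pruning_code) for s in self.solutions
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ParetoFront":
        from .trial_data import PRUNING_CODES

        sols = [
            ParetoSolution(
                design=TreatmentSpec(
                    label=f"S{s['spacing_cm']}-{s['pruning']}",
                    spacing_cm=int(s["spacing_cm"]),
                    pruning_code=PRUNING_CODES[s["pruning"]],
                ),
                duration_days=float(s["duration_days"]),
                yield_t_hm2=float(s["yield_t_hm2"]),
                ci=float(s["ci"]),
            )
            for s in d["solutions"]
        ]
        return cls(solutions=sols, provenance=dict(d.get("provenance", {})))

    def to_json_dict(self) -> dict:
        return {
            "solutions": [
                {
                    "spacing_cm": s.design.spacing_cm,
                    "pruning": s.design.pruning_label,
                    "duration_days": s.duration_days,
                    "yield_t_hm2": s.yield_t_hm2,
                    "ci": s.ci,
                }
                for s in self.solutions
            ],
            "objective_directions": {
                "duration_days": "min",
                "yield_t_hm2": "max",
                "ci": "max",
            },
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# Core relations
# ---------------------------------------------------------------------------


def dominates(a, b) -> bool:
    """Pareto dominance, minimization sense: a no worse everywhere and
    strictly better somewhere."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"objective length mismatch: {av.shape} vs {bv.shape}")
    return bool(np.all(av <= bv) and np.any(av < bv))


def fast_nondominated_sort(pop: list[Individual]) -> list[list[int]]:
    """Deb's fast non-dominated sort; writes ranks back onto individuals."""
    n = len(pop)
    if n == 0:
        return []
    objs = np.stack([ind.objectives for ind in pop])
    # full pairwise domination matrix (n small here)
    le = np.all(objs[:, None, :] <= objs[None, :, :], axis=2)
    lt = np.any(objs[:, None, :] < objs[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts: list[list[int]] = []
    current = list(np.flatnonzero(n_dominators == 0))
    counts = n_dominators.copy()
    while current:
        fronts.append(current)
        for i in current:
            pop[i].rank = len(fronts) - 1
        nxt: list[int] = []
        for i in current:
            dominated = np.flatnonzero(dom[i])
            counts[dominated] -= 1
            nxt.extend(j for j in dominated if counts[j] == 0)
        current = sorted(set(nxt))
    return fronts


def crowding_distance(front_objectives) -> np.ndarray:
    """Crowding distances for one front: boundary solutions infinite,
    interior ones accumulate normalized neighbour gaps per objective.
    Objectives with zero range contribute nothing."""
    objs = np.asarray(front_objectives, dtype=float)
    if objs.ndim != 2 or objs.shape[0] == 0:
        raise ValueError("front must be a non-empty 2-D objective array")
    n, m = objs.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(objs[:, j], kind="stable")
        lo, hi = objs[order[0], j], objs[order[-1], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        rng = hi - lo
        if rng == 0:
            continue
        gaps = (objs[order[2:], j] - objs[order[:-2], j]) / rng
        dist[order[1:-1]] += gaps
    return dist


# ---------------------------------------------------------------------------
# Variation and selection
# ---------------------------------------------------------------------------


def _tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    i, j = rng.integers(0, len(pop), size=2)
    a, b = pop[i], pop[j]
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a


def _random_genome(rng: np.random.Generator) -> Genome:
    return Genome(
        spacing_index=int(rng.integers(0, N_SPACING_LEVELS)),
        pruning_code=int(rng.integers(1, 5)),
    )


def make_offspring(
    pop: list[Individual], params: GAParams, rng: np.random.Generator
) -> list[Genome]:
    """One generation of variation: binary tournament on (rank, crowding),
    uniform per-gene crossover, per-gene random-reset mutation.  Offspring
    genomes are feasible by construction."""
    out: list[Genome] = []
    while len(out) < params.population_size:
        p1 = _tournament(pop, rng).genome
        p2 = _tournament(pop, rng).genome
        g1 = [p1.spacing_index, p1.pruning_code]
        g2 = [p2.spacing_index, p2.pruning_code]
        if rng.random() < params.crossover_prob:
            for k in range(2):
                if rng.random() < 0.5:
                    g1[k], g2[k] = g2[k], g1[k]
        for g in (g1, g2):
            if rng.random() < params.mutation_prob:
                g[0] = int(rng.integers(0, N_SPACING_LEVELS))
            if rng.random() < params.mutation_prob:
                g[1] = int(rng.integers(1, 5))
        out.append(Genome(spacing_index=g1[0], pruning_code=g1[1]))
        if len(out) < params.population_size:
            out.append(Genome(spacing_index=g2[0], pruning_code=g2[1]))
    return out


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


def _evaluate(model: SurrogateModel, genomes: list[Genome]) -> list[Individual]:
    specs = [decode_genome(g) for g in genomes]
    phys = predict_batch(model, specs)  # (n, 3): duration, yield, ci
    objs = phys.copy()
    objs[:, 1] *= -1.0
    objs[:, 2] *= -1.0
    return [Individual(genome=g, objectives=objs[i]) for i, g in enumerate(genomes)]


def _assign_crowding(pop: list[Individual], fronts: list[list[int]]) -> None:
    for front in fronts:
        dists = crowding_distance(np.stack([pop[i].objectives for i in front]))
        for i, d in zip(front, dists):
            pop[i].crowding = float(d)


def _truncate(pop: list[Individual], size: int) -> list[Individual]:
    fronts = fast_nondominated_sort(pop)
    _assign_crowding(pop, fronts)
    kept: list[Individual] = []
    for front in fronts:
        members = [pop[i] for i in front]
        if len(kept) + len(members) <= size:
            kept.extend(members)
        else:
            members.sort(key=lambda ind: -ind.crowding)
            kept.extend(members[: size - len(kept)])
            break
    return kept


def _front_from_individuals(
    model: SurrogateModel, individuals: list[Individual], provenance: dict
) -> ParetoFront:
    # deduplicate genotypes, then keep the exact non-dominated subset
    seen: dict[tuple[int, int], Individual] = {}
    for ind in individuals:
        seen.setdefault((ind.genome.spacing_index, ind.genome.pruning_code), ind)
    unique = list(seen.values())
    objs = np.stack([ind.objectives for ind in unique])
    keep = []
    for i in range(len(unique)):
        if not any(
            dominates(objs[j], objs[i]) for j in range(len(unique)) if j != i
        ):
            keep.append(unique[i])
    keep.sort(
        key=lambda ind: (ind.genome.spacing_index, ind.genome.pruning_code)
    )
    sols = []
    for ind in keep:
        spec = decode_genome(ind.genome)
        sols.append(
            ParetoSolution(
                design=spec,
                duration_days=float(ind.objectives[0]),
                yield_t_hm2=float(-ind.objectives[1]),
                ci=float(-ind.objectives[2]),
            )
        )
    return ParetoFront(solutions=sols, provenance=provenance)


def evolve(model: SurrogateModel, params: GAParams | None = None) -> ParetoFront:
    """Run elitist NSGA-II and return the deduplicated rank-0 front.

    Each generation evaluates offspring through the surrogate, pools them
    with the parents (μ+λ) and truncates by (rank, crowding).  The returned
    front is in physical units with stated objective directions.
    """
    params = params or GAParams()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 31]))
    genomes = [_random_genome(rng) for _ in range(params.population_size)]
    pop = _evaluate(model, genomes)
    pop = _truncate(pop, params.population_size)  # assigns rank/crowding
    for _ in range(params.generations):
        children = make_offspring(pop, params, rng)
        pop = _truncate(pop + _evaluate(model, children), params.population_size)
    final_front = [ind for ind in pop if ind.rank == 0]
    provenance = {
        "algorithm": "nsga2",
        "population_size": params.population_size,
        "generations": params.generations,
        "crossover_prob": params.crossover_prob,
        "mutation_prob": params.mutation_prob,
        "seed": params.seed,
        "surrogate_seed": model.seed,
    }
    return _front_from_individuals(model, final_front, provenance)


def brute_force_pareto(model: SurrogateModel) -> ParetoFront:
    """Exact non-dominated set over the exhaustive 44-design grid, by
    pairwise comparison; the oracle the evolved front is checked against."""
    individuals = _evaluate(model, feasible_genomes())
    return _front_from_individuals(
        model,
        individuals,
        {"algorithm": "exhaustive", "surrogate_seed": model.seed},
    )
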