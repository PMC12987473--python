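import numpy as np
import pytest

import melonopt as m
from melonopt.nsga2 import Individual, decode_genome

from conftest import FAST_GA


# ---------------------------------------------------------------------------
# Independent oracles: plain double loops, no shared code with the module.
# ---------------------------------------------------------------------------

def oracle_dominates(a, b):
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def oracle_fronts(objectives):
    """Peel non-dominated layers by repeated O(n^2 m) scans."""
    remaining = list(range(len(objectives)))
    fronts = []
    while remaining:
        layer = [
            i for i in remaining
            if not any(
                oracle_dominates(objectives[j], objectives[i])
                for j in remaining if j != i
            )
        ]
        fronts.append(sorted(layer))
        remaining = [i for i in remaining if i not in set(layer)]
    return fronts


def oracle_crowding(objs):
    n, mdim = objs.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(mdim):
        order = sorted(range(n), key=lambda i: objs[i, j])
        dist[order[0]] = dist[order[-1]] = np.inf
        rng = objs[order[-1], j] - objs[order[0], j]
        if rng == 0:
            continue
        for pos in range(1, n - 1):
            if np.isinf(dist[order[pos]]):
                continue
            dist[order[pos]] += (
                objs[order[pos + 1], j] - objs[order[pos - 1], j]
            ) / rng
    return dist


def individuals_from(objs):
    g = m.Genome(spacing_index=0, pruning_code=1)
    return [Individual(genome=g, objectives=np.asarray(o, float)) for o in objs]


def constant_surrogate():
    """A surrogate whose forward pass is identically zero in scaled space:
    every design maps to the same physical triple."""
    return m.SurrogateModel(
        weights=[np.zeros((12, 2)), np.zeros(12), np.zeros((8, 12)), np.zeros(8),
                 np.zeros((3, 8)), np.zeros(3)],
        hidden_sizes=(12, 8),
        out_min=np.array([100.0, 30.0, 0.2]),
        out_range=np.array([20.0, 20.0, 0.6]),
        train_labels=[], seed=0,
    )


class TestDominates:
    def test_strict_domination(self):
        assert m.dominates((1, 2, 3), (2, 3, 4))

    def test_incomparable_both_ways(self):
        assert not m.dominates((1, 2), (2, 1))
        assert not m.dominates((2, 1), (1, 2))

    def test_irreflexive(self):
        assert not m.dominates((1.5, 2.5), (1.5, 2.5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            m.dominates((1, 2), (1, 2, 3))


class TestSorting:
    def test_single_individual(self):
        pop = individuals_from([[1.0, 2.0, 3.0]])
        assert m.fast_nondominated_sort(pop) == [[0]]
        assert pop[0].rank == 0

    def test_chain_gives_singleton_fronts(self):
        pop = individuals_from([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
        assert m.fast_nondominated_sort(pop) == [[0], [1], [2]]

    def test_matches_oracle_on_random_populations(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(1, 51))
            objs = rng.integers(0, 6, size=(n, 3)).astype(float)  # forces ties
            pop = individuals_from(objs)
            got = [sorted(f) for f in m.fast_nondominated_sort(pop)]
            assert got == oracle_fronts(objs.tolist())
            for rank, front in enumerate(got):
                for i in front:
                    assert pop[i].rank == rank


class TestCrowding:
    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(m.crowding_distance([[1.0, 2.0]])))
        assert np.all(np.isinf(m.crowding_distance([[1.0, 2.0], [2.0, 1.0]])))

    def test_collinear_equally_spaced(self):
        d = m.crowding_distance([[0.0], [1.0], [2.0]])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(1.0)

    def test_matches_oracle_on_random_fronts(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            objs = rng.uniform(0, 1, size=(n, 3))
            np.testing.assert_allclose(
                m.crowding_distance(objs), oracle_crowding(objs)
            )

    def test_zero_range_objective_contributes_nothing(self):
        objs = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0]])
        d = m.crowding_distance(objs)
        assert d[1] == pytest.approx(1.0)  # only the varying objective counts


class TestOffspring:
    def _ranked_population(self, rng, n=20):
        genomes = [
            m.Genome(int(rng.integers(0, 11)), int(rng.integers(1, 5)))
            for _ in range(n)
        ]
        pop = [
            Individual(genome=g, objectives=rng.uniform(0, 1, 3)) for g in genomes
        ]
        fronts = m.fast_nondominated_sort(pop)
        from melonopt.nsga2 import _assign_crowding

        _assign_crowding(pop, fronts)
        return pop

    def test_no_variation_copies_parents(self):
        rng = np.random.default_rng(1)
        pop = self._ranked_population(rng)
        params = m.GAParams(population_size=10, crossover_prob=0.0,
                            mutation_prob=0.0, seed=1)
        children = m.make_offspring(pop, params, np.random.default_rng(2))
        parent_genomes = {(i.genome.spacing_index, i.genome.pruning_code)
                          for i in pop}
        assert all(
            (c.spacing_index, c.pruning_code) in parent_genomes for c in children
        )

    def test_full_mutation_resamples_domain(self):
        rng = np.random.default_rng(3)
        pop = self._ranked_population(rng)
        params = m.GAParams(population_size=200, mutation_prob=1.0, seed=3)
        children = m.make_offspring(pop, params, np.random.default_rng(4))
        spacings = {c.spacing_index for c in children}
        codes = {c.pruning_code for c in children}
        assert spacings == set(range(11))  # uniform resampling covers the grid
        assert codes == {1, 2, 3, 4}

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        pop = self._ranked_population(rng)
        params = m.GAParams(population_size=30, seed=5)
        c1 = m.make_offspring(pop, params, np.random.default_rng(9))
        c2 = m.make_offspring(pop, params, np.random.default_rng(9))
        assert c1 == c2


class TestEvolve:
    def test_front_equals_exhaustive_oracle(self, grid_model):
        front = m.evolve(grid_model, m.GAParams(seed=2, **FAST_GA))
        oracle = m.brute_force_pareto(grid_model)
        assert front.genomes() == oracle.genomes()

    def test_constant_surrogate_returns_all_44(self):
        front = m.brute_force_pareto(constant_surrogate())
        assert len(front.solutions) == 44
        evolved = m.evolve(constant_surrogate(),
                           m.GAParams(seed=0, generations=20))
        assert evolved.genomes() <= front.genomes()

    def test_front_members_pairwise_nondominated(self, grid_model):
        front = m.evolve(grid_model, m.GAParams(seed=3, **FAST_GA))
        objs = [s.objectives_min for s in front.solutions]
        for i in range(len(objs)):
            for j in range(len(objs)):
                if i != j:
                    assert not oracle_dominates(objs[j], objs[i])

    def test_seeded_determinism(self, grid_model):
        p = m.GAParams(seed=8, **FAST_GA)
        f1 = m.evolve(grid_model, p)
        f2 = m.evolve(grid_model, p)
        assert f1.to_json_dict() == f2.to_json_dict()

    def test_elitist_truncation_preserves_objective_minima(self):
        """(mu+lambda) truncation never loses the best value of any
        objective: extremes carry infinite crowding in front 0."""
        from melonopt.nsga2 import _truncate

        rng = np.random.default_rng(11)
        for _ in range(20):
            pool = individuals_from(rng.uniform(0, 1, size=(40, 3)))
            kept = _truncate(pool, 20)
            pool_objs = np.stack([i.objectives for i in pool])
            kept_objs = np.stack([i.objectives for i in kept])
            np.testing.assert_allclose(
                kept_objs.min(axis=0), pool_objs.min(axis=0)
            )

    def test_monotone_surrogate_single_solution(self):
        """If every objective improves in the same grid direction the
        exhaustive front collapses to that corner."""
        model = constant_surrogate()
        # linear forward: duration rises with spacing, yield and ci fall
        model.weights[0][0, 0] = 1.0  # first hidden unit tracks spacing
        model.weights[2][0, 0] = 1.0  # passed through the second layer
        model.weights[4][:, 0] = [1.0, -1.0, -1.0]
        front = m.brute_force_pareto(model)
        assert len(front.solutions) == 4  # one per pruning code at 30 cm
        assert all(s.design.spacing_cm == 30 for s in front.solutions)
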