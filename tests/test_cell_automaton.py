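"""Cellular automaton: neighborhoods, motion weights, lineage draws,
lifecycle rules, and whole-population stepping invariants."""

import random

import numpy as np
import pytest

from stemca.cell_automaton import (
    CSC,
    DEAD,
    NECROTIC,
    PC,
    QUIESCENT,
    TC,
    VIABLE,
    CellPopulation,
    LineageKinetics,
    draw_division_outcome,
    free_neighbors,
    motion_probabilities,
    sample_self_renewal,
    select_option,
    step_population,
    update_lifecycle,
)
from stemca.lattice import Lattice
from stemca.params import ParameterSet


@pytest.fixture
def kinetics(params):
    return LineageKinetics.from_params(params, base_cycle_time=1.0)


class _FixedRng:
    """Stub RNG returning a preset uniform value."""

    def __init__(self, r):
        self.r = r

    def random(self):
        return self.r


# ---------------------------------------------------------------------------
# Neighborhoods
# ---------------------------------------------------------------------------

class TestFreeNeighbors:
    def test_isolated_interior_cell_has_six(self, lat7):
        pop = CellPopulation(lat7)
        i = pop.add_cell(CSC, lat7.center_node)
        assert len(free_neighbors(pop, i)) == 6

    def test_corner_cell_has_three(self, lat7):
        pop = CellPopulation(lat7)
        i = pop.add_cell(TC, 0)
        assert len(free_neighbors(pop, i)) == 3

    def test_fully_enclosed_cell_has_none(self, lat7):
        pop = CellPopulation(lat7)
        center = lat7.center_node
        i = pop.add_cell(CSC, center)
        for nb in lat7.neighbor_table()[center]:
            pop.add_cell(TC, nb)
        assert free_neighbors(pop, i) == []


# ---------------------------------------------------------------------------
# Motion probabilities and selection
# ---------------------------------------------------------------------------

class TestMotion:
    def test_symmetric_fields_give_uniform_options(self, lat7):
        pop = CellPopulation(lat7)
        center = lat7.center_node
        pop.add_cell(CSC, center)
        n = [1.0] * lat7.n_nodes
        f = [1.0] * lat7.n_nodes
        free = free_neighbors(pop, 0)
        probs = motion_probabilities(center, free, n, f)
        assert len(probs) == 7
        assert np.allclose(probs, 1.0 / 7.0)

    def test_direct_arithmetic_two_options(self):
        # stay weight 1, single neighbor weight 2 -> (1/3, 2/3)
        n = {0: 1.0, 1: 2.0}
        f = {0: 1.0, 1: 1.0}
        probs = motion_probabilities(0, [1], n, f)
        assert probs == pytest.approx([1 / 3, 2 / 3])

    def test_normalization_and_ordering_random_fields(self, lat7, rng):
        """Probabilities sum to 1 and preserve the raw n/f ordering."""
        nprng = np.random.default_rng(5)
        n = nprng.random(lat7.n_nodes).tolist()
        f = (nprng.random(lat7.n_nodes) + 0.05).tolist()
        pop = CellPopulation(lat7)
        pop.add_cell(PC, lat7.center_node)
        for _ in range(50):
            free = free_neighbors(pop, 0)[: rng.randint(1, 6)]
            probs = motion_probabilities(lat7.center_node, free, n, f)
            assert abs(sum(probs) - 1.0) < 1e-12
            raw = [n[lat7.center_node] / f[lat7.center_node]] + [
                n[nb] / f[nb] for nb in free
            ]
            assert np.argsort(raw).tolist() == np.argsort(probs).tolist()

    def test_no_free_neighbors_means_stay(self):
        assert motion_probabilities(0, [], [1.0], [1.0]) == [1.0]

    def test_select_degenerate_and_interval_rule(self):
        assert select_option([1.0, 0.0], random.Random(1)) == 0
        # r = 0.99 with (0.5, 0.5): falls in the second cumulative interval
        assert select_option([0.5, 0.5], _FixedRng(0.99)) == 1

    def test_select_monte_carlo_frequencies(self):
        rng = random.Random(123)
        probs = [1 / 3, 2 / 3]
        n_draws = 100_000
        hits = sum(select_option(probs, rng) for _ in range(n_draws))
        p = 2 / 3
        se = np.sqrt(p * (1 - p) / n_draws)
        assert abs(hits / n_draws - p) < 4 * se


# ---------------------------------------------------------------------------
# Division outcomes and self-renewal
# ---------------------------------------------------------------------------

class TestLineageDraws:
    def test_csc_outcome_frequencies(self, kinetics):
        """CSC outcomes follow {0.6, 0.25, 0.1, 0.05} within 4 SE."""
        rng = random.Random(42)
        n_draws = 100_000
        counts = [0, 0, 0, 0]
        for _ in range(n_draws):
            counts[draw_division_outcome(CSC, kinetics, rng)] += 1
        for freq, p in zip(counts, (0.6, 0.25, 0.1, 0.05)):
            se = np.sqrt(p * (1 - p) / n_draws)
            assert abs(freq / n_draws - p) < 4 * se

    def test_heritable_renewal_rescales_remaining_outcomes(self, kinetics):
        """Heterogeneity mode: mass 1-p covers the CSC-preserving
        asymmetric outcomes in the K_CCP:K_CT ratio; the stem lineage
        is never lost through a PC+PC conversion."""
        rng = random.Random(9)
        n_draws = 50_000
        p_self = 0.8
        counts = [0, 0, 0, 0]
        for _ in range(n_draws):
            counts[
                draw_division_outcome(CSC, kinetics, rng, renewal_p=p_self)
            ] += 1
        assert counts[2] == 0  # no CSC-eliminating outcome
        expected = [0.8, 0.2 * 0.25 / 0.3, 0.2 * 0.05 / 0.3]
        for freq, p in zip([counts[0], counts[1], counts[3]], expected):
            se = np.sqrt(p * (1 - p) / n_draws)
            assert abs(freq / n_draws - p) < 4 * se

    def test_sample_self_renewal_degenerate_and_mc_mean(self):
        rng = random.Random(7)
        assert sample_self_renewal(0.42, 0.0, rng) == 0.42
        draws = [sample_self_renewal(0.5, 0.1, rng) for _ in range(100_000)]
        se = 0.1 / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 0.5) < 4 * se
        assert all(0.0 <= d <= 1.0 for d in draws)

    def test_high_cohort_mean_used_directly(self):
        """sigma = 0 passes the cohort mean 0.75 through unchanged."""
        assert sample_self_renewal(0.75, 0.0, random.Random(0)) == 0.75


# ---------------------------------------------------------------------------
# Lifecycle
# ---------------------------------------------------------------------------

class TestLifecycle:
    def _pop_with(self, lat7, ctype):
        pop = CellPopulation(lat7)
        pop.add_cell(ctype, lat7.center_node)
        return pop

    def test_survival_thresholds_are_type_specific(self, lat7, params):
        # TC survives at n = 0.3 > 0.25
        pop = self._pop_with(lat7, TC)
        for _ in range(40):
            update_lifecycle(pop, 0, 0.3, params, 0.1)
        assert pop.state[0] == VIABLE
        # at n = 0.12 a CSC (theta 0.1) survives where a TC would die
        pop_csc = self._pop_with(lat7, CSC)
        pop_tc = self._pop_with(lat7, TC)
        for _ in range(40):
            update_lifecycle(pop_csc, 0, 0.12, params, 0.1)
            update_lifecycle(pop_tc, 0, 0.12, params, 0.1)
        assert pop_csc.state[0] == VIABLE
        assert pop_tc.state[0] == NECROTIC

    def test_anoxia_kills_every_type_after_window(self, lat7, params):
        for ctype in (CSC, PC, TC):
            pop = self._pop_with(lat7, ctype)
            for _ in range(25):
                update_lifecycle(pop, 0, 0.0, params, 0.1)
            assert pop.state[0] == NECROTIC

    def test_recovery_resets_the_hypoxia_clock(self, lat7, params):
        pop = self._pop_with(lat7, TC)
        for _ in range(15):
            update_lifecycle(pop, 0, 0.0, params, 0.1)  # 1.5 of 2 days
        update_lifecycle(pop, 0, 0.9, params, 0.1)      # recovers
        for _ in range(15):
            update_lifecycle(pop, 0, 0.0, params, 0.1)
        assert pop.state[0] == VIABLE


# ---------------------------------------------------------------------------
# Population stepping
# ---------------------------------------------------------------------------

def _uniform_fields(lattice):
    return np.ones(lattice.shape), np.ones(lattice.shape)


class TestStepPopulation:
    def test_single_immature_cell_stays_single(self, lat7, params, kinetics):
        pop = CellPopulation(lat7)
        pop.add_cell(CSC, lat7.center_node)
        n, f = _uniform_fields(lat7)
        sample = step_population(
            pop, n, f, kinetics, params, random.Random(1), 0.1
        )
        assert sample.n_live == 1 and sample.births == 0

    def test_motion_only_conserves_cells(self, lat7, params, kinetics):
        pop = CellPopulation(lat7)
        rng = random.Random(3)
        nodes = rng.sample(range(lat7.n_nodes), 40)
        for node in nodes:
            pop.add_cell(rng.choice([CSC, PC, TC]), node)
        n = np.random.default_rng(0).random(lat7.shape)
        f = np.random.default_rng(1).random(lat7.shape) + 0.1
        for _ in range(30):
            sample = step_population(
                pop, n, f, kinetics, params, rng, 0.1,
                enable_division=False, enable_death=False,
            )
            assert sample.n_live == 40
            pop.check_occupancy()

    def test_unbiased_motion_has_zero_mean_drift(self, params, kinetics):
        """Symmetric weights: single-cell displacement has no net drift."""
        lat = Lattice((15, 15, 15))
        n, f = _uniform_fields(lat)
        rng = random.Random(99)
        trials, steps = 300, 6
        disp = np.zeros(3)
        start = np.array(lat.unravel_index(lat.center_node))
        for _ in range(trials):
            pop = CellPopulation(lat)
            pop.add_cell(TC, lat.center_node)
            for _ in range(steps):
                step_population(
                    pop, n, f, kinetics, params, rng, 0.01,
                    enable_division=False, enable_death=False,
                )
            disp += np.array(lat.unravel_index(pop.node[0])) - start
        mean = disp / trials
        # per-axis variance per step ~ 2/7; 4 SE bound on the mean
        se = np.sqrt(steps * (2 / 7) / trials)
        assert np.all(np.abs(mean) < 4 * se)

    def test_population_growth_from_csc_cluster(self, params):
        """A compact CSC cluster only gains cells before any death."""
        lat = Lattice((15, 15, 15))
        kinetics = LineageKinetics.from_params(params, base_cycle_time=1.0)
        pop = CellPopulation(lat)
        center = lat.center_node
        pop.add_cell(CSC, center, mu=0.6)
        for nb in lat.neighbor_table()[center][:4]:
            pop.add_cell(CSC, nb, mu=0.6)
        n, f = _uniform_fields(lat)
        rng = random.Random(17)
        counts = []
        for _ in range(40):
            sample = step_population(pop, n, f, kinetics, params, rng, 0.1)
            counts.append(sample.n_live)
            assert sample.deaths == 0 or sample.n_live >= counts[0]
        assert counts == sorted(counts)  # non-decreasing
        assert counts[-1] > 5

    def test_bookkeeping_identity_births_minus_deaths(self, params, kinetics):
        lat = Lattice((9, 9, 9))
        pop = CellPopulation(lat)
        for nb in [lat.center_node] + list(lat.neighbor_table()[lat.center_node]):
            pop.add_cell(CSC, nb, mu=0.6)
        n, f = _uniform_fields(lat)
        rng = random.Random(2)
        prev = pop.n_live()
        for _ in range(30):
            sample = step_population(pop, n, f, kinetics, params, rng, 0.2)
            assert sample.n_live - prev == sample.births - sample.deaths
            prev = sample.n_live

    def test_generation_limit_stops_division(self, lat7, params):
        kinetics = LineageKinetics.from_params(params, base_cycle_time=0.1)
        pop = CellPopulation(lat7)
        pop.add_cell(PC, lat7.center_node, gen=params.G_m[PC])
        n, f = _uniform_fields(lat7)
        rng = random.Random(4)
        for _ in range(50):
            sample = step_population(pop, n, f, kinetics, params, rng, 0.5)
            assert sample.births == 0
        assert pop.n_live() == 1

    def test_hierarchy_is_one_way(self, params):
        """No PC or TC ever becomes a CSC across many division steps."""
        lat = Lattice((13, 13, 13))
        kinetics = LineageKinetics.from_params(params, base_cycle_time=0.5)
        pop = CellPopulation(lat)
        pop.add_cell(CSC, lat.center_node, mu=0.6)
        n, f = _uniform_fields(lat)
        rng = random.Random(8)
        prev_types = list(pop.ctype)
        for _ in range(40):
            step_population(pop, n, f, kinetics, params, rng, 0.25,
                            heterogeneity=True)
            for i, old in enumerate(prev_types):
                new = pop.ctype[i]
                if old != new:
                    # the only legal switch is CSC differentiating to PC
                    assert (old, new) == (CSC, PC)
            prev_types = list(pop.ctype)

    def test_quiescent_cell_resumes_when_space_frees(self, lat7, params):
        kinetics = LineageKinetics.from_params(params, base_cycle_time=0.1)
        pop = CellPopulation(lat7)
        center = lat7.center_node
        i = pop.add_cell(TC, center, age=5.0)
        blockers = [
            pop.add_cell(TC, nb, gen=params.G_m[TC])
            for nb in lat7.neighbor_table()[center]
        ]
        n, f = _uniform_fields(lat7)
        rng = random.Random(5)
        step_population(pop, n, f, kinetics, params, rng, 0.05,
                        enable_motion=False)
        assert pop.state[i] == QUIESCENT
        # free one neighbor: the crowded cell divides again
        freed = blockers[0]
        pop.state[freed] = DEAD
        pop.occupancy[pop.node[freed]] = -1
        grew = False
        for _ in range(20):
            sample = step_population(pop, n, f, kinetics, params, rng, 0.05,
                                     enable_motion=False)
            if sample.births:
                grew = True
                break
        assert grew
        assert pop.state[i] == VIABLE

    def test_full_step_determinism(self, params, kinetics):
        """Identical seeds reproduce identical cell tables."""
        def run():
            lat = Lattice((11, 11, 11))
            pop = CellPopulation(lat)
            pop.add_cell(CSC, lat.center_node, mu=0.7)
            n, f = _uniform_fields(lat)
            rng = random.Random(42)
            for _ in range(30):
                step_population(pop, n, f, kinetics, params, rng, 0.2,
                                heterogeneity=True)
            return pop.to_dataframe()

        a, b = run(), run()
        assert a.equals(b)

    def test_occupancy_conflict_detected(self, lat7):
        pop = CellPopulation(lat7)
        pop.add_cell(CSC, 10)
        pop.add_cell(PC, 11)
        pop.node[1] = 10  # corrupt
        with pytest.raises(RuntimeError, match="occupancy conflict"):
            pop.check_occupancy()


def test_csc_fraction_stabilizes_in_long_run(params):
    """Untreated growth keeps the CSC fraction inside (0, 1) and roughly
    steady over the last third of the run (regression-style check)."""
    lat = Lattice((13, 13, 13))
    kinetics = LineageKinetics.from_params(params, base_cycle_time=1.0)
    pop = CellPopulation(lat)
    center = lat.center_node
    pop.add_cell(CSC, center, mu=0.6)
    for nb in lat.neighbor_table()[center]:
        pop.add_cell(CSC, nb, mu=0.6)
    n, f = _uniform_fields(lat)
    rng = random.Random(31)
    fracs = []
    for _ in range(240):  # 60 days at dt = 0.25
        sample = step_population(pop, n, f, kinetics, params, rng, 0.25)
        fracs.append(sample.csc_fraction)
    tail = np.asarray(fracs[-80:])
    assert np.all((tail > 0) & (tail < 1))
    assert (tail.max() - tail.min()) / tail.mean() < 0.2
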