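import dataclasses

import numpy as np
import pytest

from hitchsim.dynamics import (
    EstablishmentFlags,
    Fixation,
    Outcome,
    PopulationState,
    Winner,
    apply_mutations,
    bottleneck,
    check_fixation,
    grow_to_threshold,
    reproduce,
    run_trial,
    update_establishment,
)
from hitchsim.model import ClassTable, GenotypeClass, Origin, SimulationParams

WT = GenotypeClass(0, 0, 0)
ADAPTED_WT = GenotypeClass(1, 0, 0, Origin.WT)


def no_mutation_params(**overrides):
    return SimulationParams(mu_b=0, mu_d=0, mu_m=0, mu_l=0, **overrides)


class TestReproduce:
    def test_wild_type_doubles(self, rng):
        p = SimulationParams()
        st = PopulationState.from_counts(ClassTable(p), {WT: 1.0})
        reproduce(st, p, rng)
        assert st.total == pytest.approx(2.0)
        assert st.generation == 1

    def test_geometric_growth_closed_form(self, rng):
        p = no_mutation_params()
        t = ClassTable(p)
        st = PopulationState.from_counts(t, {WT: 1.0})
        for _ in range(12):
            reproduce(st, p, rng)
            apply_mutations(st, p, rng)
        assert st.total == pytest.approx(2.0 ** 12)

    def test_adapted_class_gains_ten_percent_per_generation(self, rng):
        p = SimulationParams()
        t = ClassTable(p)
        st = PopulationState.from_counts(t, {WT: 1.0, ADAPTED_WT: 1.0})
        reproduce(st, p, rng)
        ratio = st.counts[t.index[ADAPTED_WT]] / st.counts[t.index[WT]]
        assert ratio == pytest.approx(1.1)


class TestMutations:
    def test_zero_rates_leave_state_unchanged(self, rng):
        p = no_mutation_params()
        t = ClassTable(p)
        st = PopulationState.from_counts(t, {WT: 123.0, ADAPTED_WT: 7.0})
        before = st.counts.copy()
        apply_mutations(st, p, rng)
        np.testing.assert_array_equal(st.counts, before)

    def test_poisson_mean_matches_rate_times_abundance(self):
        """1e8 cells at a beneficial rate of 1e-7 yield on average 10
        mutants per generation (Monte-Carlo over 1e4 draws)."""
        p = SimulationParams(mu_b=1e-7, mu_d=0, mu_m=0, mu_l=0)
        t = ClassTable(p)
        rng = np.random.default_rng(7)
        adapted_idx = t.index[ADAPTED_WT]
        total = 0.0
        reps = 10_000
        for _ in range(reps):
            st = PopulationState.from_counts(t, {WT: 1e8})
            apply_mutations(st, p, rng)
            total += st.counts[adapted_idx]
        mean = total / reps
        se = np.sqrt(10.0 / reps)
        assert mean == pytest.approx(10.0, abs=4 * se)

    def test_mutator_background_rates_are_amplified(self):
        """Mean beneficial output from an m=1 class is mutator_fold larger."""
        p = SimulationParams(mu_d=0, mu_m=0, mu_l=0)
        t = ClassTable(p)
        rng = np.random.default_rng(8)
        mut = GenotypeClass(0, 0, 1)
        dest = t.index[GenotypeClass(1, 0, 1, Origin.MUT)]
        total = 0.0
        reps = 4_000
        for _ in range(reps):
            st = PopulationState.from_counts(t, {mut: 1e8})
            apply_mutations(st, p, rng)
            total += st.counts[dest]
        assert total / reps == pytest.approx(1000.0, rel=0.05)

    def test_no_mutator_rate_means_no_mutator_classes(self):
        p = SimulationParams(mu_m=0.0, max_generations=400)
        result = run_trial(p, seed=5)
        assert result.winner is Winner.WT
        assert not result.established_mut

    def test_extinction_flagged_when_population_lost(self):
        p = SimulationParams(mu_b=0, mu_d=0, mu_m=0, mu_l=0.9)
        t = ClassTable(p)
        rng = np.random.default_rng(3)
        st = PopulationState.from_counts(t, {WT: 1.0})
        for _ in range(200):
            apply_mutations(st, p, rng)
            if st.extinct:
                break
        assert st.extinct
        assert st.total == 0.0

    def test_provenance_preserved_when_adapted_wt_acquires_mutator(self):
        """(1,d,0,WT) -> (1,d,1,WT): the driver's origin never changes, so
        sigma will not apply to these classes."""
        p = SimulationParams(mu_b=0, mu_d=0, mu_l=0, mu_m=0.01)
        t = ClassTable(p)
        rng = np.random.default_rng(11)
        st = PopulationState.from_counts(t, {ADAPTED_WT: 1e6})
        apply_mutations(st, p, rng)
        wt_origin_mut = t.index[GenotypeClass(1, 0, 1, Origin.WT)]
        mut_origin = t.index[GenotypeClass(1, 0, 1, Origin.MUT)]
        assert st.counts[wt_origin_mut] > 0
        assert st.counts[mut_origin] == 0


class TestGrowthPhase:
    def test_ten_generations_from_bottleneck_to_threshold(self, rng):
        p = no_mutation_params()
        st = PopulationState.from_counts(ClassTable(p), {WT: 1e5})
        grow_to_threshold(st, p, rng)
        assert st.generation == 10          # 1e5 * 2^10 = 1.024e8 > 1e8
        assert st.total == pytest.approx(1.024e8)

    def test_twentyseven_generations_from_single_cell(self, rng):
        p = no_mutation_params()
        st = PopulationState.from_single_cell(ClassTable(p))
        grow_to_threshold(st, p, rng)
        assert st.generation == 27          # 2^27 ~ 1.34e8 is the first > 1e8

    def test_already_above_threshold_returns_unchanged(self, rng):
        p = no_mutation_params()
        st = PopulationState.from_counts(ClassTable(p), {WT: 2e8})
        grow_to_threshold(st, p, rng)
        assert st.generation == 0
        assert st.total == pytest.approx(2e8)


class TestBottleneck:
    def test_single_class_population_sampled_exactly(self, rng):
        p = SimulationParams()
        st = PopulationState.from_counts(ClassTable(p), {WT: 1.3e8})
        bottleneck(st, p, rng)
        assert st.total == p.n_bottleneck
        assert st.cycle == 1

    def test_total_is_exactly_bottleneck_size(self, rng):
        p = SimulationParams()
        t = ClassTable(p)
        for trial in range(20):
            st = PopulationState.from_counts(
                t, {WT: 9e7, ADAPTED_WT: 1e7, GenotypeClass(0, 1, 0): 3e7})
            bottleneck(st, p, rng)
            assert st.counts.sum() == p.n_bottleneck
            assert (st.counts >= 0).all()

    def test_rare_class_survival_probability(self):
        """A class at frequency 1e-5 has ~1 expected copy in a 1e5 sample,
        so it survives the bottleneck with probability ~1 - 1/e."""
        p = SimulationParams()
        t = ClassTable(p)
        rng = np.random.default_rng(42)
        idx = t.index[ADAPTED_WT]
        reps, survived = 2_000, 0
        for _ in range(reps):
            st = PopulationState.from_counts(
                t, {WT: 1e8 - 1e3, ADAPTED_WT: 1e3})
            bottleneck(st, p, rng)
            survived += st.counts[idx] >= 1
        expected = 1 - np.exp(-1)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert survived / reps == pytest.approx(expected, abs=4 * se)


class TestEstablishmentAndFixation:
    def test_flag_boundary_is_inclusive_and_sticky(self):
        p = SimulationParams(est_threshold=100)
        t = ClassTable(p)
        flags = EstablishmentFlags()
        st = PopulationState.from_counts(t, {ADAPTED_WT: 99.0, WT: 1e5})
        update_establishment(st, p, flags)
        assert not flags.wt
        st.counts[t.index[ADAPTED_WT]] = 100.0
        update_establishment(st, p, flags)
        assert flags.wt
        st.counts[t.index[ADAPTED_WT]] = 0.0
        update_establishment(st, p, flags)
        assert flags.wt                      # sticky

    def test_mutator_flag_counts_only_mutator_origin_classes(self):
        p = SimulationParams(est_threshold=100)
        t = ClassTable(p)
        flags = EstablishmentFlags()
        st = PopulationState.from_counts(
            t, {GenotypeClass(1, 0, 1, Origin.WT): 500.0, WT: 1e5})
        update_establishment(st, p, flags)
        assert not flags.mut
        st = PopulationState.from_counts(
            t, {GenotypeClass(1, 0, 1, Origin.MUT): 100.0, WT: 1e5})
        update_establishment(st, p, flags)
        assert flags.mut

    def test_fixation_ignores_deleterious_load(self):
        p = SimulationParams()
        t = ClassTable(p)
        st = PopulationState.from_counts(t, {
            GenotypeClass(1, 0, 0, Origin.WT): 5e4,
            GenotypeClass(1, 3, 0, Origin.WT): 5e4,
        })
        assert check_fixation(st) is Fixation.WT

    def test_single_unadapted_individual_blocks_fixation(self):
        p = SimulationParams()
        t = ClassTable(p)
        st = PopulationState.from_counts(
            t, {ADAPTED_WT: 99_999.0, WT: 1.0})
        assert check_fixation(st) is Fixation.NOT_FIXED

    def test_pure_mutator_origin_population_is_mutator_fixed(self):
        p = SimulationParams()
        t = ClassTable(p)
        st = PopulationState.from_counts(t, {
            GenotypeClass(1, 1, 1, Origin.MUT): 6e4,
            GenotypeClass(1, 2, 1, Origin.MUT): 4e4,
        })
        assert check_fixation(st) is Fixation.MUTATOR

    def test_wt_fixation_tolerates_wt_origin_mutator_satellites(self):
        """Recurrent mutator acquisition keeps WT-origin adapted mutators at
        mutation-selection balance; they cannot win and do not block the
        wild-type fixation call."""
        p = SimulationParams()
        t = ClassTable(p)
        st = PopulationState.from_counts(t, {
            ADAPTED_WT: 99_950.0,
            GenotypeClass(1, 0, 1, Origin.WT): 50.0,
        })
        assert check_fixation(st) is Fixation.WT

    def test_live_mutator_origin_lineage_blocks_wt_fixation(self):
        p = SimulationParams()
        t = ClassTable(p)
        st = PopulationState.from_counts(t, {
            ADAPTED_WT: 99_900.0,
            GenotypeClass(1, 0, 1, Origin.MUT): 100.0,
        })
        assert check_fixation(st) is Fixation.NOT_FIXED


class TestRunTrial:
    def test_same_seed_reproduces_result_exactly(self, fast_params):
        r1 = run_trial(fast_params, seed=99)
        r2 = run_trial(fast_params, seed=99)
        assert dataclasses.asdict(r1) == dataclasses.asdict(r2)

    def test_no_beneficial_mutation_never_fixes(self):
        p = SimulationParams(mu_b=0.0, max_generations=300)
        r = run_trial(p, seed=1)
        assert r.outcome is Outcome.NONE_WITHIN_CAP
        assert r.winner is Winner.NONE
        assert r.generations >= 300

    def test_fast_regime_trial_completes_with_wt_winner(self, fast_params):
        r = run_trial(fast_params, seed=11)
        assert r.winner in (Winner.WT, Winner.MUTATOR)
        assert r.cycles > 0
        assert r.generations > 0
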