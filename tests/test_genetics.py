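"""Unit and property tests for the four-allele drive genetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssedrive import (
    ALLELE_PAIRS,
    Allele,
    DriveParams,
    EmptyPopulationError,
    Genotype,
    Population,
    Sex,
    SexStructuredState,
    all_genotypes,
    allele_frequencies,
    gamete_distribution,
    offspring_distribution,
    recursion_step,
    run_recursion,
)

probs = st.floats(0.0, 1.0, allow_nan=False)
params_st = st.builds(DriveParams, c=probs, h=probs, phi=probs)


def male(a1, a2):
    return Genotype.of(a1, a2, Sex.MALE)


def female(a1, a2):
    return Genotype.of(a1, a2, Sex.FEMALE)


class TestTypes:
    def test_allele_marker_flags(self):
        assert [a for a in Allele if a.gfp_positive] == [Allele.T]
        assert [a for a in Allele if a.cleavable] == [Allele.T]
        assert [a for a in Allele if a.drive_capable] == [Allele.D]

    def test_genotype_is_unordered(self):
        assert male(Allele.D, Allele.T) == male(Allele.T, Allele.D)
        assert hash(male(Allele.D, Allele.T)) == hash(male(Allele.T, Allele.D))

    def test_twenty_genotypes_exist(self):
        genos = all_genotypes()
        assert len(genos) == len(set(genos)) == 20

    @pytest.mark.parametrize("bad", [dict(c=-0.1), dict(h=1.5), dict(phi=2.0)])
    def test_out_of_range_params_rejected(self, bad):
        kwargs = dict(c=0.5, h=0.5, phi=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            DriveParams(**kwargs)


class TestGameteDistribution:
    def test_homozygote_emits_single_class(self, talelat_params):
        dist = gamete_distribution(male(Allele.T, Allele.T), talelat_params)
        assert dist[Allele.T] == 1.0

    def test_female_trans_heterozygote_is_mendelian(self, talelat_params):
        dist = gamete_distribution(female(Allele.D, Allele.T), talelat_params)
        assert dist[Allele.D] == 0.5
        assert dist[Allele.T] == 0.5

    def test_male_trans_heterozygote_drives(self, talelat_params):
        dist = gamete_distribution(male(Allele.D, Allele.T), talelat_params)
        expected = {
            Allele.D: 0.5980,
            Allele.DN: 0.1470,
            Allele.N: 0.1060,
            Allele.T: 0.1490,
        }
        for allele, value in expected.items():
            assert dist[allele] == pytest.approx(value, abs=1e-4)

    def test_perfect_drive_limit(self):
        dist = gamete_distribution(
            male(Allele.D, Allele.T), DriveParams(c=1, h=1, phi=1)
        )
        assert dist[Allele.D] == 1.0

    def test_no_cleavage_reduces_to_mendelian(self):
        dist = gamete_distribution(
            male(Allele.D, Allele.T), DriveParams(c=0, h=0.7, phi=0.4)
        )
        assert dist[Allele.D] == 0.5
        assert dist[Allele.T] == 0.5

    @pytest.mark.parametrize(
        "geno",
        [male(Allele.DN, Allele.T), male(Allele.D, Allele.N), male(Allele.D, Allele.D)],
    )
    def test_non_driving_genotypes_are_mendelian(self, geno, talelat_params):
        dist = gamete_distribution(geno, talelat_params)
        for allele in geno.alleles:
            assert dist[allele] >= 0.5 - 1e-12

    @settings(deadline=None)
    @given(params=params_st)
    def test_distributions_are_normalized_for_all_genotypes(self, params):
        for geno in all_genotypes():
            arr = gamete_distribution(geno, params).as_array()
            assert np.all(arr >= 0)
            assert abs(arr.sum() - 1.0) < 1e-12

    @settings(deadline=None)
    @given(params=params_st, delta=st.floats(0.0, 1.0))
    def test_drive_transmission_monotone_in_each_parameter(self, params, delta):
        geno = male(Allele.D, Allele.T)
        base = gamete_distribution(geno, params)[Allele.D]
        for name in ("c", "h", "phi"):
            raised = min(1.0, getattr(params, name) + delta)
            bumped = DriveParams(**{**params.__dict__, name: raised})
            assert gamete_distribution(geno, bumped)[Allele.D] >= base - 1e-12


class TestOffspringDistribution:
    def test_double_homozygote_cross(self, talelat_params):
        dist = offspring_distribution(
            female(Allele.T, Allele.T), male(Allele.T, Allele.T), talelat_params
        )
        assert dist[(Allele.T, Allele.T)] == 1.0

    def test_mendelian_limit(self):
        dist = offspring_distribution(
            female(Allele.T, Allele.T),
            male(Allele.D, Allele.T),
            DriveParams(c=0, h=0.7, phi=0.4),
        )
        assert dist[(Allele.T, Allele.D)] == pytest.approx(0.5)
        assert dist[(Allele.T, Allele.T)] == pytest.approx(0.5)

    def test_drive_cross_offspring(self, talelat_params):
        dist = offspring_distribution(
            female(Allele.T, Allele.T), male(Allele.D, Allele.T), talelat_params
        )
        expected = {
            (Allele.T, Allele.D): 0.5980,
            (Allele.T, Allele.DN): 0.1470,
            (Allele.T, Allele.N): 0.1060,
            (Allele.T, Allele.T): 0.1490,
        }
        for pair, value in expected.items():
            assert dist[tuple(sorted(pair, key=list(Allele).index))] == pytest.approx(
                value, abs=1e-4
            )

    def test_swapped_sexes_rejected(self, talelat_params):
        with pytest.raises(ValueError):
            offspring_distribution(
                male(Allele.T, Allele.T), male(Allele.T, Allele.T), talelat_params
            )

    @settings(deadline=None)
    @given(params=params_st)
    def test_offspring_distribution_normalized(self, params):
        for mother_pair in ALLELE_PAIRS:
            dist = offspring_distribution(
                Genotype(mother_pair, Sex.FEMALE),
                male(Allele.D, Allele.T),
                params,
            )
            values = np.array(list(dist.values()))
            assert np.all(values >= 0)
            assert abs(values.sum() - 1.0) < 1e-12


def release_state(fraction_dt_males: float, target: Allele = Allele.T):
    """Males a mixture of D/target and target/target, all females target/target."""
    return SexStructuredState(
        male_freqs={
            male(Allele.D, target): fraction_dt_males,
            male(target, target): 1.0 - fraction_dt_males,
        },
        female_freqs={female(target, target): 1.0},
    )


class TestRecursion:
    def test_all_wild_type_is_fixed_point(self, talelat_params):
        state = release_state(0.0)
        nxt = recursion_step(state, talelat_params)
        assert nxt.generation == 1
        assert nxt.female_freqs[female(Allele.T, Allele.T)] == pytest.approx(1.0)

    def test_perfect_drive_produces_only_trans_heterozygotes(self):
        nxt = recursion_step(release_state(1.0), DriveParams(c=1, h=1, phi=1))
        assert nxt.male_freqs[male(Allele.D, Allele.T)] == pytest.approx(1.0)

    def test_single_cross_matches_offspring_distribution(self, talelat_params):
        nxt = recursion_step(release_state(1.0), talelat_params)
        expected = {
            male(Allele.D, Allele.T): 0.5980,
            male(Allele.DN, Allele.T): 0.1470,
            male(Allele.N, Allele.T): 0.1060,
            male(Allele.T, Allele.T): 0.1490,
        }
        for geno, value in expected.items():
            assert nxt.male_freqs[geno] == pytest.approx(value, abs=1e-4)

    def test_sexes_identical_after_step(self, zfn_params):
        nxt = recursion_step(release_state(0.3), zfn_params)
        for g, v in nxt.male_freqs.items():
            assert nxt.female_freqs[Genotype(g.alleles, Sex.FEMALE)] == pytest.approx(v)

    def test_zero_generations_returns_initial_only(self, talelat_params):
        traj = run_recursion(release_state(0.5), talelat_params, 0)
        assert len(traj) == 1
        assert traj.states[0].generation == 0

    def test_negative_generations_rejected(self, talelat_params):
        with pytest.raises(ValueError):
            run_recursion(release_state(0.5), talelat_params, -1)

    def test_no_cleavage_conserves_allele_frequencies(self):
        params = DriveParams(c=0, h=0.7, phi=0.4)
        traj = run_recursion(release_state(0.4), params, 6)
        after_mixing = traj.frequencies[1].as_array()
        for freqs in traj.frequencies[2:]:
            np.testing.assert_allclose(freqs.as_array(), after_mixing, atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(params=params_st, frac=st.floats(0.0, 1.0))
    def test_mass_conserved_and_gfp_negative_monotone(self, params, frac):
        traj = run_recursion(release_state(frac), params, 8)
        for state in traj.states:
            assert abs(sum(state.male_freqs.values()) - 1.0) < 1e-9
        series = traj.gfp_negative_series()
        assert np.all(np.diff(series) >= -1e-12)


class TestAlleleFrequencies:
    def test_finite_population_counts(self):
        pop = Population(
            counts={
                male(Allele.D, Allele.T): 25,
                male(Allele.T, Allele.T): 50,
                female(Allele.T, Allele.T): 50,
            }
        )
        freqs = allele_frequencies(pop)
        assert freqs[Allele.D] == pytest.approx(25 / 250)

    def test_all_wild_type_has_no_gfp_negative_alleles(self):
        pop = Population(counts={male(Allele.T, Allele.T): 10})
        assert allele_frequencies(pop).gfp_negative == 0.0

    def test_drive_fixation(self):
        pop = Population(counts={female(Allele.D, Allele.D): 7})
        assert allele_frequencies(pop)[Allele.D] == 1.0

    def test_empty_population_rejected(self):
        with pytest.raises(EmptyPopulationError):
            allele_frequencies(Population(counts={}))

    def test_state_frequencies_sum_to_one(self, zfn_params):
        state = recursion_step(release_state(0.25), zfn_params)
        freqs = allele_frequencies(state)
        assert freqs.as_array().sum() == pytest.approx(1.0)
        assert freqs.gfp_negative == pytest.approx(1.0 - freqs[Allele.T])
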