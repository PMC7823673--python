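import math

import numpy as np
import pytest

from twinhap import (
    POPULATION,
    EvidenceLocus,
    FrequencyTable,
    Genotype,
    GenotypeProfile,
    Hypothesis,
    MixtureParams,
    ValidationError,
    child_genotype_prior,
    compute_lr,
    default_grid,
    locus_likelihood,
    mixture_likelihood,
    specificity_screen,
)
from twinhap.kinship import HypothesisSpec, cross_grid

from _oracles import (
    all_evidence_sets,
    oracle_locus_likelihood,
    oracle_mixture_likelihood,
)


def ev(alleles, locus="L1"):
    return EvidenceLocus(locus, frozenset(alleles))


def gt(*alleles, locus="L1"):
    return Genotype(locus, tuple(alleles))


class TestChildGenotypePrior:
    def test_mendelian_cross(self, small_freqs):
        prior = child_genotype_prior(gt("A", "B"), gt("C", "C"), small_freqs, r=0)
        assert prior == {
            gt("A", "C"): pytest.approx(0.5),
            gt("B", "C"): pytest.approx(0.5),
        }

    def test_population_father_hardy_weinberg(self):
        freqs = FrequencyTable({"L1": {"A": 0.4, "B": 0.6}})
        prior = child_genotype_prior(gt("A", "A"), POPULATION, freqs, r=0)
        assert prior[gt("A", "A")] == pytest.approx(0.4)
        assert prior[gt("A", "B")] == pytest.approx(0.6)

    @pytest.mark.parametrize("father", ["AF", POPULATION])
    @pytest.mark.parametrize("r", [0.0, 1e-8, 0.01])
    def test_normalised(self, small_freqs, father, r):
        father_gt = gt("C", "D") if father == "AF" else POPULATION
        prior = child_genotype_prior(gt("A", "B"), father_gt, small_freqs, r=r)
        assert sum(prior.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mutation_spreads_mass_beyond_parental_alleles(self, small_freqs):
        prior = child_genotype_prior(gt("A", "A"), gt("B", "B"), small_freqs, r=0.01)
        assert prior[gt("A", "B")] < 1
        assert gt("A", "C") in prior

    def test_theta_changes_population_sampling(self, small_freqs):
        base = child_genotype_prior(
            gt("A", "B"), POPULATION, small_freqs, r=0,
            conditioning=("A", "A", "B", "B"),
        )
        adjusted = child_genotype_prior(
            gt("A", "B"), POPULATION, small_freqs, r=0, theta=0.05,
            conditioning=("A", "A", "B", "B"),
        )
        assert sum(adjusted.values()) == pytest.approx(1.0, abs=1e-12)
        # coancestry pushes the random man's allele toward the observed ones
        assert adjusted[gt("A", "A")] > base[gt("A", "A")]


class TestMixtureLikelihood:
    def test_maternal_copies_explain_everything(self, small_freqs, mother_ab):
        p = mixture_likelihood(
            ev("AB"), mother_ab, gt("A", "B"), gt("A", "B"),
            MixtureParams(d1=0.3, d2=0.7, drop_in=0.0), small_freqs,
        )
        assert p == pytest.approx(1.0)

    def test_single_fetal_copy_must_drop(self, small_freqs, mother_ab):
        p = mixture_likelihood(
            ev("AB"), mother_ab, gt("A", "C"), gt("A", "B"),
            MixtureParams(d1=0.2, d2=0.5, drop_in=0.0), small_freqs,
        )
        assert p == pytest.approx(0.2)

    def test_unexplained_allele_needs_drop_in(self, small_freqs, mother_ab):
        p = mixture_likelihood(
            ev("ABC"), mother_ab, gt("A", "A"), gt("A", "B"),
            MixtureParams(d1=0.1, d2=0.1, drop_in=0.01), small_freqs,
        )
        assert p == pytest.approx(0.01 * 0.2)

    def test_missing_maternal_allele_impossible(self, small_freqs, mother_ab):
        p = mixture_likelihood(
            ev("A"), mother_ab, gt("A", "A"), gt("A", "A"),
            MixtureParams(drop_in=0.01), small_freqs,
        )
        assert p == 0.0

    def test_homozygous_fetal_dropout_is_squared(self, small_freqs, mother_ab):
        p = mixture_likelihood(
            ev("AB"), mother_ab, gt("C", "C"), gt("A", "B"),
            MixtureParams(d1=0.3, d2=0.2, drop_in=0.0), small_freqs,
        )
        assert p == pytest.approx(0.3**2)

    def test_matches_enumeration_oracle_random_instances(self, small_freqs, rng):
        alleles = ["A", "B", "C", "D"]
        params_pool = [
            MixtureParams(d1=0.1, d2=0.3, drop_in=0.01),
            MixtureParams(d1=0.001, d2=0.001, drop_in=0.05),
            MixtureParams(d1=0.5, d2=0.5, drop_in=0.0),
        ]
        mother = gt("A", "B")
        for _ in range(200):
            g1 = gt(*rng.choice(alleles, 2))
            g2 = gt(*rng.choice(alleles, 2))
            evidence = ev(
                set(mother.alleles)
                | set(rng.choice(alleles, rng.integers(0, 3), replace=False))
            )
            params = params_pool[rng.integers(len(params_pool))]
            expected = oracle_mixture_likelihood(
                evidence, mother, g1, g2, params, small_freqs
            )
            actual = mixture_likelihood(evidence, mother, g1, g2, params, small_freqs)
            assert actual == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_evidence_sets_sum_to_one(self, small_freqs, mother_ab):
        params = MixtureParams(d1=0.2, d2=0.4, drop_in=0.01)
        total = sum(
            mixture_likelihood(
                EvidenceLocus("L1", s), mother_ab, gt("A", "C"), gt("C", "D"),
                params, small_freqs,
            )
            for s in all_evidence_sets("ABCD")
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLocusLikelihood:
    def test_matches_double_loop_oracle(self, small_freqs, rng):
        params = MixtureParams(d1=0.05, d2=0.2, drop_in=0.01)
        mother = gt("A", "B")
        for _ in range(30):
            af = gt(*rng.choice(["A", "B", "C", "D"], 2))
            evidence = ev(
                set(mother.alleles)
                | set(rng.choice(["C", "D"], rng.integers(0, 2), replace=False))
            )
            for hyp in Hypothesis:
                expected = oracle_locus_likelihood(
                    evidence, mother, af, hyp, params, small_freqs
                )
                actual = locus_likelihood(
                    evidence, mother, af, hyp, params, small_freqs
                )
                assert actual == pytest.approx(expected, rel=1e-11)

    def test_h2_labelings_symmetric_when_dropouts_equal(self, small_freqs):
        params = MixtureParams(d1=0.1, d2=0.1, drop_in=0.01)
        evidence = ev("ABC")
        spec = HypothesisSpec.standard(Hypothesis.H2)
        assert spec.father_of_twin1 != spec.father_of_twin2
        # averaging the two labelings equals either one at d1 == d2
        l_h2 = locus_likelihood(
            evidence, gt("A", "B"), gt("C", "C"), Hypothesis.H2, params, small_freqs
        )
        from twinhap.kinship import _LocusEngine

        engine = _LocusEngine(evidence, gt("A", "B"), gt("C", "C"), small_freqs, params)
        _, l_a, l_b, _ = engine.likelihoods(0.1, 0.1)
        assert l_a == pytest.approx(l_b, rel=1e-12)
        assert l_h2 == pytest.approx(l_a, rel=1e-12)

    def test_apparent_exclusion_favours_h3(self, small_freqs):
        """An AF homozygous for an unobserved allele is penalised relative
        to random paternity when that allele is rare."""
        params = MixtureParams(d1=0.001, d2=0.001, drop_in=0.0)
        evidence = ev("AB")
        l_h1 = locus_likelihood(
            evidence, gt("A", "B"), gt("D", "D"), Hypothesis.H1, params, small_freqs
        )
        l_h3 = locus_likelihood(
            evidence, gt("A", "B"), gt("D", "D"), Hypothesis.H3, params, small_freqs
        )
        assert l_h1 < l_h3


class TestComputeLR:
    @pytest.fixture
    def single_locus_inputs(self, small_freqs):
        mother = GenotypeProfile("m", {"L1": gt("A", "B")})
        af = GenotypeProfile("af", {"L1": gt("C", "C")})
        return [ev("ABC")], mother, af, small_freqs

    def test_lr_identity_holds_everywhere(self, single_locus_inputs):
        evidence, mother, af, freqs = single_locus_inputs
        result = compute_lr(evidence, mother, af, freqs, cross_grid((0.001, 0.1, 0.5)))
        for triples in list(result.per_locus_log10.values()) + [
            result.cumulative_log10
        ]:
            for lr13, lr23, lr12 in triples:
                assert lr13 == pytest.approx(lr23 + lr12, abs=1e-9)

    def test_single_locus_cumulative_equals_per_locus(self, single_locus_inputs):
        evidence, mother, af, freqs = single_locus_inputs
        result = compute_lr(evidence, mother, af, freqs, default_grid((0.01, 0.1)))
        assert result.cumulative_log10 == result.per_locus_log10["L1"]

    def test_true_father_locus_supports_h1(self, small_freqs):
        mother = GenotypeProfile("m", {"L1": gt("A", "B")})
        af = GenotypeProfile("af", {"L1": gt("C", "D")})
        result = compute_lr(
            [ev("ABCD")], mother, af, small_freqs, default_grid((0.01, 0.1))
        )
        assert result.min_cumulative(0) > 0

    def test_added_shared_pa_locus_never_decreases_lr(self, small_freqs):
        mother = GenotypeProfile("m", {"L1": gt("A", "B"), "L2": gt("A", "A")})
        af = GenotypeProfile("af", {"L1": gt("C", "C"), "L2": gt("B", "B")})
        grid = default_grid((0.01, 0.1, 0.3))
        one = compute_lr([ev("ABC")], mother, af, small_freqs, grid)
        two = compute_lr(
            [ev("ABC"), ev("AB", locus="L2")], mother, af, small_freqs, grid
        )
        for t1, t2 in zip(one.cumulative_log10, two.cumulative_log10):
            assert t2[0] >= t1[0] - 1e-12

    def test_all_loci_skipped_is_error(self, small_freqs):
        mother = GenotypeProfile("m", {"L1": gt("A", "B")})
        af = GenotypeProfile("af", {})
        with pytest.raises(ValidationError):
            compute_lr([ev("AB")], mother, af, small_freqs)

    def test_simulated_true_father_and_unrelated(self, panel_freqs, dz_case):
        from twinhap import evidence_from_plasma

        truth, plasma = dz_case
        evidence = evidence_from_plasma(plasma)
        grid = default_grid((0.001, 0.05, 0.2))
        related = compute_lr(evidence, truth.mother, truth.af, panel_freqs, grid)
        unrelated = compute_lr(
            evidence, truth.mother, truth.random_men[0], panel_freqs, grid
        )
        assert related.min_cumulative(0) > 2
        assert unrelated.max_cumulative(0) < 0
        assert unrelated.max_cumulative(1) < 0


class TestSpecificityScreen:
    def test_flags_true_father_not_unrelated(self, panel_freqs, dz_case):
        from twinhap import evidence_from_plasma

        truth, plasma = dz_case
        evidence = evidence_from_plasma(plasma)
        rows = specificity_screen(
            evidence,
            truth.mother,
            [truth.af, truth.random_men[0], truth.random_men[1]],
            panel_freqs,
            default_grid((0.01, 0.1, 0.3)),
        )
        assert rows[0].min_log10_lr_h1h3 > 0
        assert rows[0].lr_h2h3_crosses_one
        for row in rows[1:]:
            assert row.max_log10_lr_h1h3 < 0
            assert not row.lr_h2h3_crosses_one

    def test_empty_candidate_list_rejected(self, small_freqs):
        mother = GenotypeProfile("m", {"L1": gt("A", "B")})
        with pytest.raises(ValidationError):
            specificity_screen([ev("AB")], mother, [], small_freqs)


class TestParams:
    def test_silent_alleles_rejected(self):
        with pytest.raises(ValidationError):
            MixtureParams(silent=0.1)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValidationError):
            MixtureParams(d1=1.0)
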