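import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popstrat import (
    SimulationParams,
    TraitArchitecture,
    FrequencyModel,
    assign_architecture,
    build_phenotype,
    decouple_environment,
    draw_admixture,
    draw_ancestral_freqs,
    draw_population_freqs,
    make_cohort,
    sample_genotypes,
    synth_sharing_matrix,
)
from popstrat.simulate import ParameterError, combine_phenotype


class TestSimulationParams:
    def test_defaults_match_published_operating_point(self):
        p = SimulationParams()
        assert (p.h, p.e) == (0.5, 0.5)
        assert (p.n_individuals, p.n_snps) == (2000, 4000)
        assert (p.l_eff, p.a0, p.beta0, p.s) == (20, 0.4, 1.0, 0.2)

    def test_sigma_a2_derivation(self):
        p = SimulationParams(a0=0.4, l_eff=20)
        assert p.sigma_a2 == pytest.approx(0.4 * 0.6 / 20)
        assert p.sigma_a2 >= 0 and np.isfinite(p.sigma_a2)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("a0", 1.5),
            ("a0", -0.1),
            ("l_eff", 0),
            ("sigma_p2", -1e-9),
            ("h", 2.0),
            ("e", -0.5),
            ("causal_fraction", 0.0),
            ("causal_fraction", 1.5),
            ("n_individuals", 0),
            ("s", -2.0),
        ],
    )
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ParameterError):
            SimulationParams(**{field: value})

    def test_round_trip_dict(self):
        p = SimulationParams(seed=9, sigma_p2=0.3)
        assert SimulationParams.from_dict(p.to_dict()) == p


class TestDrawAdmixture:
    def test_variance_zero_limit(self):
        p = SimulationParams(a0=0.5, l_eff=1e12)
        a = draw_admixture(p, 100)
        assert np.allclose(a, 0.5, atol=1e-4)

    def test_boundary_a0_zero(self):
        a = draw_admixture(SimulationParams(a0=0.0), 50)
        assert np.all(a == 0.0)

    def test_large_sample_variance_matches_binomial_analogue(self):
        # oracle: a0(1-a0)/l_eff = 0.012; clamping at >3.6 sd is negligible
        p = SimulationParams(a0=0.4, l_eff=20, seed=7)
        a = draw_admixture(p, 100_000)
        assert a.var(ddof=1) == pytest.approx(0.012, abs=5e-4)
        assert a.mean() == pytest.approx(0.4, abs=3e-3)

    def test_bounds_and_reproducibility(self):
        p = SimulationParams(a0=0.1, l_eff=0.5, seed=3)  # heavy clamping regime
        a1 = draw_admixture(p, 1000)
        a2 = draw_admixture(p, 1000)
        assert np.array_equal(a1, a2)
        assert a1.min() >= 0.0 and a1.max() <= 1.0
        assert np.any(a1 == 0.0)  # clamping, not rejection: mass at the bound

    def test_invalid_n(self):
        with pytest.raises(ParameterError):
            draw_admixture(SimulationParams(), 0)


class TestAncestralFreqs:
    def test_bounds(self):
        p = SimulationParams(n_snps=5000, seed=1)
        f = draw_ancestral_freqs(p)
        assert f.min() >= 0.05 and f.max() <= 0.5

    def test_seeded_repeatability(self):
        p = SimulationParams(n_snps=1, seed=5)
        assert draw_ancestral_freqs(p) == draw_ancestral_freqs(p)

    def test_uniform_mean(self):
        p = SimulationParams(n_snps=100_000, seed=2)
        f = draw_ancestral_freqs(p)
        # oracle: mean of Uniform(0.05, 0.5) = 0.275, SE ~ 0.13/sqrt(1e5)
        assert f.mean() == pytest.approx(0.275, abs=1.5e-3)


class TestAssignArchitecture:
    def test_degenerate_zero_causal_errors(self):
        p = SimulationParams(n_snps=3, causal_fraction=0.1)
        with pytest.raises(ParameterError, match="causal"):
            assign_architecture(p, np.full(3, 0.3))

    def test_noncausal_effects_exactly_zero(self, small_params):
        anc = draw_ancestral_freqs(small_params)
        arch = assign_architecture(small_params, anc)
        assert np.all(arch.effect_sizes[arch.causal_indicator == 0] == 0.0)
        assert arch.causal_indicator.sum() == round(
            small_params.causal_fraction * small_params.n_snps
        )

    def test_effect_size_distribution(self):
        # oracle: Uniform(0, beta0*p(1-p)) at p=0.5 has support [0, .25], mean .125
        p = SimulationParams(n_snps=20_000, causal_fraction=1.0, beta0=1.0, seed=8)
        arch = assign_architecture(p, np.full(20_000, 0.5))
        assert arch.effect_sizes.max() <= 0.25
        assert arch.effect_sizes.min() >= 0.0
        assert arch.effect_sizes.mean() == pytest.approx(0.125, abs=2e-3)

    def test_effect_bounded_by_beta0_p_1mp(self, small_params):
        anc = draw_ancestral_freqs(small_params)
        arch = assign_architecture(small_params, anc)
        cap = small_params.beta0 * anc * (1 - anc)
        assert np.all(arch.effect_sizes <= cap + 1e-12)


class TestPopulationFreqs:
    def _arch(self, L, causal_idx=()):
        c = np.zeros(L, dtype=np.int8)
        c[list(causal_idx)] = 1
        beta = np.where(c == 1, 0.1, 0.0)
        return TraitArchitecture(causal_indicator=c, effect_sizes=beta)

    def test_no_drift_no_selection_identity(self):
        p = SimulationParams(n_snps=10, sigma_p2=0.0, s=0.0)
        anc = np.full(10, 0.3)
        fm = draw_population_freqs(anc, self._arch(10), p)
        assert np.array_equal(fm.pop1, anc)
        assert np.array_equal(fm.pop2, anc)

    def test_selection_shift_population1_only(self):
        p = SimulationParams(n_snps=2, sigma_p2=0.0, s=0.2)
        anc = np.array([0.3, 0.3])
        fm = draw_population_freqs(anc, self._arch(2, [0]), p)
        assert fm.pop1[0] == pytest.approx(0.36)  # causal: p*(1+s)
        assert fm.pop1[1] == pytest.approx(0.30)  # non-causal untouched
        assert np.array_equal(fm.pop2, anc)

    def test_large_drift_hits_bounds_exactly(self):
        p = SimulationParams(n_snps=2000, sigma_p2=5.0, s=0.0, seed=3)
        anc = draw_ancestral_freqs(p)
        fm = draw_population_freqs(anc, self._arch(2000), p)
        assert np.any(fm.pop1 == 0.0) and np.any(fm.pop1 == 1.0)
        assert fm.pop1.min() >= 0.0 and fm.pop1.max() <= 1.0


class TestSampleGenotypes:
    def test_zero_probability(self):
        fm = FrequencyModel(ancestral=[0.05], pop1=[0.0], pop2=[0.5])
        X = sample_genotypes(np.ones(20), fm, np.random.default_rng(0))
        assert np.all(X == 0)

    def test_sure_event(self):
        fm = FrequencyModel(ancestral=[0.5], pop1=[1.0], pop2=[0.0])
        X = sample_genotypes(np.ones(20), fm, np.random.default_rng(0))
        assert np.all(X == 1)

    def test_mixture_probability(self):
        fm = FrequencyModel(ancestral=[0.3], pop1=[0.2], pop2=[0.4])
        X = sample_genotypes(
            np.full(100_000, 0.5), fm, np.random.default_rng(1)
        )
        # oracle: 0.5*0.2 + 0.5*0.4 = 0.3
        assert X.mean() == pytest.approx(0.3, abs=5e-3)

    def test_diploid_option(self):
        fm = FrequencyModel(ancestral=[0.5], pop1=[0.6], pop2=[0.6])
        X = sample_genotypes(np.full(500, 0.5), fm, np.random.default_rng(1), ploidy=2)
        assert set(np.unique(X)) <= {0, 1, 2}


class TestBuildPhenotype:
    def test_h_one_gives_pure_genetic(self, small_cohort):
        p = small_cohort.params.with_overrides(h=1.0)
        yg, env, eps, y = build_phenotype(
            small_cohort.genotypes, small_cohort.arch, small_cohort.admixture, p
        )
        assert np.array_equal(y, yg)

    def test_h_zero_e_one_gives_pure_environment(self, small_cohort):
        p = small_cohort.params.with_overrides(h=0.0, e=1.0)
        yg, env, eps, y = build_phenotype(
            small_cohort.genotypes, small_cohort.arch, small_cohort.admixture, p
        )
        assert np.array_equal(y, env)

    def test_environment_variance_near_one_at_defaults(self):
        c = make_cohort(SimulationParams(n_snps=100, seed=6))
        # E = (a - a0)/sigma_a has expected variance 1 (N=2000 here)
        assert c.environment.var(ddof=1) == pytest.approx(1.0, abs=0.1)

    def test_genetic_component_standardized(self, small_cohort):
        assert small_cohort.genetic_component.mean() == pytest.approx(0.0, abs=1e-12)
        assert small_cohort.genetic_component.var(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_genetic_variance_share_no_structure(self):
        # oracle (variance algebra, YG orthogonal to E when s=0, sigma_p2=0):
        # var share = h^2 / (h^2 + (1-h)^2 e^2 + (1-h)^2 (1-e)^2) = 2/3
        p = SimulationParams(
            n_individuals=20_000, n_snps=400, sigma_p2=0.0, s=0.0, seed=10
        )
        c = make_cohort(p)
        share = np.var(p.h * c.genetic_component) / np.var(c.phenotype)
        assert share == pytest.approx(2.0 / 3.0, abs=0.03)

    def test_sigma_a_zero_with_e_positive_errors(self, small_cohort):
        p = small_cohort.params.with_overrides(a0=0.0, e=0.5)
        with pytest.raises(ParameterError, match="sigma_a"):
            build_phenotype(
                small_cohort.genotypes, small_cohort.arch,
                np.zeros(small_cohort.n_individuals), p,
            )

    def test_no_segregating_causal_snp_errors(self, small_params):
        arch = TraitArchitecture(
            causal_indicator=np.zeros(small_params.n_snps, dtype=np.int8),
            effect_sizes=np.zeros(small_params.n_snps),
        )
        X = np.zeros((10, small_params.n_snps))
        with pytest.raises(ValueError, match="variance"):
            build_phenotype(X, arch, np.full(10, 0.4), small_params)


class TestMakeCohort:
    def test_determinism(self, small_params):
        c1 = make_cohort(small_params)
        c2 = make_cohort(small_params)
        assert np.array_equal(c1.genotypes, c2.genotypes)
        assert np.array_equal(c1.phenotype, c2.phenotype)

    def test_test_cohort_reuses_architecture(self, small_cohort, small_params):
        test = make_cohort(small_params, freqs=small_cohort.freqs,
                           arch=small_cohort.arch, salt=1)
        assert np.array_equal(test.arch.effect_sizes, small_cohort.arch.effect_sizes)
        assert not np.array_equal(test.genotypes, small_cohort.genotypes)

    def test_shared_freqs_agree_within_binomial_error(self):
        p = SimulationParams(n_individuals=2000, n_snps=300, seed=77)
        c1 = make_cohort(p)
        c2 = make_cohort(p, freqs=c1.freqs, arch=c1.arch, salt=9)
        diff = np.abs(c1.genotypes.mean(0) - c2.genotypes.mean(0))
        # 6-sigma bound on the difference of two binomial frequencies
        assert diff.max() < 6 * np.sqrt(2 * 0.25 / 2000)

    def test_phenotype_identity_exact(self, small_cohort):
        p = small_cohort.params
        expected = combine_phenotype(
            small_cohort.genetic_component, small_cohort.environment,
            small_cohort.noise, p,
        )
        assert np.array_equal(small_cohort.phenotype, expected)

    def test_mismatched_supplied_model_errors(self, small_cohort):
        p = small_cohort.params.with_overrides(n_snps=7)
        with pytest.raises(ValueError, match="SNPs"):
            make_cohort(p, freqs=small_cohort.freqs, arch=small_cohort.arch)

    def test_freqs_without_arch_errors(self, small_cohort, small_params):
        with pytest.raises(ValueError):
            make_cohort(small_params, freqs=small_cohort.freqs)


class TestDecoupleEnvironment:
    def test_zero_mode_formula(self, small_cohort):
        dec = decouple_environment(small_cohort, mode="zero")
        expected = 0.5 * small_cohort.genetic_component + 0.25 * small_cohort.noise
        assert np.allclose(dec.phenotype, expected)
        assert np.array_equal(dec.genotypes, small_cohort.genotypes)

    def test_permute_breaks_ancestry_link(self):
        c = make_cohort(SimulationParams(n_snps=100, seed=15))
        dec = decouple_environment(c, mode="permute")
        r = np.corrcoef(dec.admixture, dec.environment)[0, 1]
        assert abs(r) < 4 / np.sqrt(c.n_individuals)

    def test_permute_preserves_marginal(self, small_cohort):
        dec = decouple_environment(small_cohort, mode="permute")
        assert np.array_equal(np.sort(dec.environment), np.sort(small_cohort.environment))

    def test_e_zero_warns_and_noops(self, small_params):
        c = make_cohort(small_params.with_overrides(e=0.0))
        with pytest.warns(UserWarning, match="no-op"):
            dec = decouple_environment(c)
        assert dec is c

    def test_bad_mode(self, small_cohort):
        with pytest.raises(ValueError):
            decouple_environment(small_cohort, mode="shuffle")


class TestSynthSharingMatrix:
    def test_rows_sum_to_fixed_total(self):
        sm = synth_sharing_matrix(50, 5, concentration=10.0, row_total=100.0, seed=1)
        assert np.allclose(sm.values.sum(axis=1), 100.0)
        assert sm.values.min() >= 0

    def test_infinite_concentration_collapses_to_group_means(self):
        sm = synth_sharing_matrix(30, 4, concentration=np.inf, seed=2)
        for g in np.unique(sm.group):
            rows = sm.values[sm.group == g]
            assert np.allclose(rows, rows[0])

    def test_two_group_separation_first_axis(self):
        from popstrat import fit_reference_basis, project_cohort
        means = np.array([[0.9, 0.1], [0.1, 0.9]])
        sm = synth_sharing_matrix(80, 2, concentration=200.0, group_means=means, seed=3)
        basis = fit_reference_basis(sm)
        scores = project_cohort(basis, sm)
        side = scores[:, 0] > 0.0
        agreement = max(np.mean(side == (sm.group == 0)), np.mean(side == (sm.group == 1)))
        assert agreement == 1.0

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ParameterError):
            synth_sharing_matrix(10, 1, concentration=5.0)
        with pytest.raises(ParameterError):
            synth_sharing_matrix(10, 3, concentration=0.0)


class TestProperties:
    @given(
        a0=st.floats(0.0, 1.0),
        l_eff=st.floats(0.1, 1000.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_admixture_always_in_bounds(self, a0, l_eff, seed):
        p = SimulationParams(a0=a0, l_eff=l_eff, seed=seed)
        a = draw_admixture(p, 200)
        assert a.min() >= 0.0 and a.max() <= 1.0

    @given(
        sigma_p2=st.floats(0.0, 10.0),
        s=st.floats(-1.0, 2.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_population_freqs_always_in_bounds(self, sigma_p2, s, seed):
        p = SimulationParams(n_snps=50, sigma_p2=sigma_p2, s=s, seed=seed)
        anc = draw_ancestral_freqs(p)
        arch = assign_architecture(p, anc)
        fm = draw_population_freqs(anc, arch, p)
        for v in (fm.pop1, fm.pop2):
            assert v.min() >= 0.0 and v.max() <= 1.0

    @given(
        h=st.floats(0.0, 1.0),
        e=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=20, deadline=None)
    def test_phenotype_mixing_identity(self, h, e, seed):
        p = SimulationParams(n_individuals=50, n_snps=40, h=h, e=e, seed=seed)
        c = make_cohort(p)
        expected = (
            h * c.genetic_component
            + (1 - h) * e * c.environment
            + (1 - h) * (1 - e) * c.noise
        )
        assert np.allclose(c.phenotype, expected, atol=1e-12)

    def test_no_structure_means_identical_group_distributions(self):
        # with sigma_p2=0 and s=0 the genotype distribution does not depend
        # on ancestry: two-sample frequency z-scores behave like nulls
        p = SimulationParams(
            n_individuals=2000, n_snps=300, sigma_p2=0.0, s=0.0, seed=21
        )
        c = make_cohort(p)
        lo = c.admixture < np.median(c.admixture)
        p1, p2 = c.genotypes[lo].mean(0), c.genotypes[~lo].mean(0)
        n1, n2 = lo.sum(), (~lo).sum()
        pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        # nominal rate of |z|>1.96 is 5%
        assert np.mean(np.abs(z) > 1.96) < 0.10
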