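"""Selfing-age cohort recursions: one-generation steps, equilibria and
derived statistics, checked against hand evaluations and independent
single-locus / neutral oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfest import (
    ArchitectureParams,
    CohortState,
    ConvergenceError,
    ILECSolverParams,
    ParameterError,
    SelectionRegime,
    cohort_mutation,
    cohort_reproduction,
    cohort_selection,
    ilec_equilibrium,
    initial_state,
    load_distribution,
    neutral_id_reference,
    pairwise_identity_disequilibrium,
    population_summaries,
)
from selfest.ilec import cohort_log_mean_fitness


def _one_cohort_state(pA, pR, f=None):
    pA, pR = np.atleast_2d(pA).astype(float), np.atleast_2d(pR).astype(float)
    n = pA.shape[0]
    f = np.full(n, 1.0 / n) if f is None else np.asarray(f, float)
    return CohortState(f, pA, pR)


# ---------------------------------------------------------------------------
# Independent oracle: single-cohort (random-mating) deterministic recursion
# ---------------------------------------------------------------------------


def _single_locus_equilibrium(mu, weights, tol=1e-14, max_iter=2_000_000):
    """Allele-frequency fixed point of the textbook deterministic
    mutation-selection recursion for one locus in a random-mating population
    (Hardy-Weinberg genotypes, genotype weights (w00, w01, w11))."""
    w00, w01, w11 = weights
    q = 0.0
    for _ in range(max_iter):
        qm = q * (1 - mu) + (1 - q) * mu
        num = qm * qm * w11 + qm * (1 - qm) * w01
        den = qm * qm * w11 + 2 * qm * (1 - qm) * w01 + (1 - qm) ** 2 * w00
        q_new = num / den
        if abs(q_new - q) < tol:
            return q_new
        q = q_new
    raise RuntimeError("oracle did not converge")


class TestCohortMutation:
    def test_zero_rate_is_identity(self):
        st_ = _one_cohort_state([0.3, 0.5, 0.2], [0.6, 0.3, 0.1])
        arch = ArchitectureParams(L_A=1, L_R=1, mu_A=0.0, mu_R=0.0)
        out = cohort_mutation(st_, arch)
        np.testing.assert_allclose(out.pA, st_.pA)
        np.testing.assert_allclose(out.pR, st_.pR)

    def test_fair_flip_randomizes_homozygote(self):
        st_ = _one_cohort_state([1, 0, 0], [1, 0, 0])
        arch = ArchitectureParams(L_A=1, L_R=1, mu_A=0.5, mu_R=0.5)
        out = cohort_mutation(st_, arch)
        np.testing.assert_allclose(out.pA[0], [0.25, 0.5, 0.25])

    @pytest.mark.parametrize("mu", [0.01, 0.2, 0.5])
    def test_heterozygote_persistence(self, mu):
        # both-flip or no-flip keeps the heterozygote: (1-mu)^2 + mu^2
        st_ = _one_cohort_state([0, 1, 0], [0, 1, 0])
        arch = ArchitectureParams(L_A=1, L_R=1, mu_A=mu, mu_R=mu)
        out = cohort_mutation(st_, arch)
        assert out.pA[0, 1] == pytest.approx((1 - mu) ** 2 + mu**2)
        assert out.pA[0].sum() == pytest.approx(1.0)


class TestCohortSelection:
    def test_recessive_reweighting_hand_value(self):
        st_ = _one_cohort_state([1, 0, 0], [0.8, 0.2, 0.0])
        arch = ArchitectureParams(L_A=0, L_R=1, s=0.05, h=0.1)
        out, logw = cohort_selection(st_, arch, SelectionRegime.source(0.0))
        nu = 0.8 + 0.2 * math.exp(-0.005)
        assert out.pR[0, 1] == pytest.approx(0.2 * math.exp(-0.005) / nu)
        assert out.pR[0, 1] == pytest.approx(0.19920, abs=5e-6)
        assert math.exp(logw[0]) == pytest.approx(0.99900, abs=5e-6)

    def test_neutral_selection_is_identity(self):
        st_ = _one_cohort_state([0.3, 0.5, 0.2], [0.6, 0.3, 0.1])
        arch = ArchitectureParams(L_A=2, L_R=3, s=0.0, h=0.0, s0_tilde=0.0)
        out, logw = cohort_selection(st_, arch, SelectionRegime.source(0.0))
        np.testing.assert_allclose(out.pR, st_.pR)
        np.testing.assert_allclose(out.pA, st_.pA)
        np.testing.assert_allclose(logw, 0.0, atol=1e-14)

    def test_monomorphic_cohort_unchanged(self):
        st_ = _one_cohort_state([1, 0, 0], [1, 0, 0])
        arch = ArchitectureParams(L_A=5, L_R=5, s=0.1, h=0.2, s0_tilde=0.01)
        out, logw = cohort_selection(st_, arch, SelectionRegime.source(0.01))
        np.testing.assert_allclose(out.pR[0], [1, 0, 0])
        np.testing.assert_allclose(logw, 0.0)


class TestCohortReproduction:
    def test_mendelian_selfing_of_heterozygotes(self):
        # selfing (0.5, 0.5, 0) gives (0.625, 0.25, 0.125) in the age-1 class
        st_ = _one_cohort_state([0.5, 0.5, 0], [0.5, 0.5, 0], f=[1.0])
        st_ = CohortState(
            np.array([1.0, 0.0, 0.0]),
            np.tile([0.5, 0.5, 0.0], (3, 1)),
            np.tile([0.5, 0.5, 0.0], (3, 1)),
        )
        out = cohort_reproduction(st_, np.zeros(3), r_s=1.0)
        np.testing.assert_allclose(out.pA[1], [0.625, 0.25, 0.125])
        np.testing.assert_allclose(out.f, [0.0, 1.0, 0.0])

    def test_fitness_weighted_cohort_contributions(self):
        # two cohorts, equal mass, wbar ratio 2:1 -> parental weights 2/3, 1/3
        st_ = CohortState(
            np.array([0.5, 0.5, 0.0]),
            np.tile([1.0, 0, 0], (3, 1)),
            np.array([[1.0, 0, 0], [0.0, 0, 1.0], [1.0, 0, 0]]),
        )
        logw = np.log(np.array([1.0, 0.5, 1.0]))
        out = cohort_reproduction(st_, logw, r_s=0.6)
        # selfed mass: cohort 1 gets 0.6 * g0, absorbing class 0.6 * (g1 + g2)
        np.testing.assert_allclose(out.f, [0.4, 0.6 * 2 / 3, 0.6 * 1 / 3])

    def test_pure_outcrossing_gives_hardy_weinberg(self):
        st_ = CohortState(
            np.array([0.7, 0.3]),
            np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]]),
            np.tile([1.0, 0, 0], (2, 1)),
        )
        out = cohort_reproduction(st_, np.zeros(2), r_s=0.0)
        q = 0.7 * 0.25 + 0.3 * 0.75
        np.testing.assert_allclose(out.f, [1.0, 0.0])
        np.testing.assert_allclose(
            out.pA[0], [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        )

    def test_invalid_selfing_fraction_rejected(self):
        st_ = initial_state(0.5, ILECSolverParams(I_max=3))
        with pytest.raises(ParameterError):
            cohort_reproduction(st_, np.zeros(4), r_s=1.2)


class TestEquilibrium:
    def test_mutation_free_monomorphic_state_is_absorbing(self):
        arch = ArchitectureParams(L_A=10, L_R=10, s=0.05, h=0.1, s0_tilde=0.005)
        reg = SelectionRegime.source(arch.s0_tilde)
        st_ = ilec_equilibrium(arch, reg, 0.5, ILECSolverParams(I_max=10))
        assert st_.converged
        np.testing.assert_allclose(st_.pR[:, 0], 1.0)
        assert population_summaries(st_, arch, reg).wbar == pytest.approx(1.0)

    @pytest.mark.parametrize("rs", [0.0, 0.3, 0.6, 0.9])
    def test_additive_only_matches_printed_formula(self, rs):
        """Equilibrium unfavourable-allele frequency ~ (mu/2s~)(2 - rs)
        for mu << s~ (within 5%)."""
        arch = ArchitectureParams(L_A=1000, L_R=0, mu_A=1e-4, s0_tilde=0.005)
        st_ = ilec_equilibrium(arch, SelectionRegime.source(0.005), rs)
        q = st_.allele_frequency("A")
        q_formula = (1e-4 / (2 * 0.005)) * (2 - rs)
        assert q == pytest.approx(q_formula, rel=0.05)

    @pytest.mark.parametrize("locus_type", ["A", "R"])
    def test_rs0_reduces_to_single_cohort_recursion(self, locus_type):
        """At rs=0 the cohort model collapses to the textbook single-locus
        deterministic mutation-selection recursion (tolerance 1e-10)."""
        if locus_type == "A":
            arch = ArchitectureParams(L_A=500, L_R=0, mu_A=2e-4, s0_tilde=0.004)
            weights = SelectionRegime.source(0.004).additive_weights()
            mu = arch.mu_A
        else:
            arch = ArchitectureParams(L_A=0, L_R=500, mu_R=2e-4, s=0.05, h=0.1)
            weights = np.exp(-arch.s * np.array([0.0, arch.h, 1.0]))
            mu = arch.mu_R
        reg = SelectionRegime.source(arch.s0_tilde)
        st_ = ilec_equilibrium(
            arch, reg, 0.0, ILECSolverParams(tol=1e-14, max_iter=2_000_000)
        )
        q_oracle = _single_locus_equilibrium(mu, weights)
        assert abs(st_.allele_frequency(locus_type) - q_oracle) < 1e-10

    def test_equilibrium_independent_of_initialization(self):
        arch = ArchitectureParams(
            L_A=100, L_R=200, mu_A=1e-4, mu_R=1e-4, s=0.05, h=0.1, s0_tilde=0.005
        )
        reg = SelectionRegime.source(arch.s0_tilde)
        solver = ILECSolverParams(tol=1e-13)
        a = ilec_equilibrium(arch, reg, 0.5, solver)
        b = ilec_equilibrium(
            arch, reg, 0.5, solver, init=initial_state(0.5, solver, p1_init=0.9)
        )
        assert np.abs(a.pR - b.pR).max() < 1e-7
        assert np.abs(a.pA - b.pA).max() < 1e-7
        assert np.abs(a.f - b.f).max() < 1e-7

    def test_nonconvergence_reports_last_state(self):
        arch = ArchitectureParams(L_A=0, L_R=100, mu_R=1e-4, s=0.05, h=0.02)
        with pytest.raises(ConvergenceError) as exc:
            ilec_equilibrium(
                arch,
                SelectionRegime.source(0.0),
                0.5,
                ILECSolverParams(tol=1e-12, max_iter=5),
            )
        assert isinstance(exc.value.state, CohortState)

    def test_recessive_interference_inflates_additive_alleles(self):
        """Unlinked recessives raise the unfavourable additive allele
        frequency at intermediate selfing."""
        reg = SelectionRegime.source(0.005)
        base = ArchitectureParams(L_A=1000, L_R=0, mu_A=1e-4, s0_tilde=0.005)
        both = ArchitectureParams(
            L_A=1000, L_R=5000, mu_A=1e-4, mu_R=1e-4, s=0.05, h=0.02, s0_tilde=0.005
        )
        q0 = ilec_equilibrium(base, reg, 0.5).allele_frequency("A")
        q1 = ilec_equilibrium(both, reg, 0.5).allele_frequency("A")
        assert q1 > q0

    @given(rs=st.floats(0.0, 0.95), seed=st.integers(0, 2**16))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_mass_conservation_through_generations(self, rs, seed):
        """sum f = 1 and all frequencies in [0,1] after every step."""
        from selfest.ilec import generation

        rng = np.random.default_rng(seed)
        solver = ILECSolverParams(I_max=12)
        arch = ArchitectureParams(
            L_A=50, L_R=50, mu_A=1e-3, mu_R=1e-3, s=0.1, h=0.1, s0_tilde=0.01
        )
        state = initial_state(rs, solver, p1_init=float(rng.uniform(0, 1)))
        reg = SelectionRegime.source(arch.s0_tilde)
        for _ in range(5):
            state = generation(state, arch, reg, rs)
            state.validate()


class TestIdentityDisequilibrium:
    def test_single_cohort_has_no_id(self):
        st_ = _one_cohort_state([0.5, 0.3, 0.2], [0.6, 0.3, 0.1])
        assert pairwise_identity_disequilibrium(st_, "AA") == pytest.approx(0.0)

    def test_hand_evaluated_two_cohort_value(self):
        # f=(0.5,0.5); p11 = (0, 0.2); pooled p = 0.15
        st_ = CohortState(
            np.array([0.5, 0.5]),
            np.array([[0.8, 0.2, 0.0], [0.8, 0.0, 0.2]]),
            np.array([[0.8, 0.2, 0.0], [0.8, 0.0, 0.2]]),
        )
        expected = 0.25 * 0.2**2 / (0.15**2 * 0.85**2)
        for pair in ("AA", "RR", "AR"):
            assert pairwise_identity_disequilibrium(st_, pair) == pytest.approx(
                expected, rel=1e-12
            )
        assert expected == pytest.approx(0.6152, abs=1e-4)

    def test_identical_cohort_homozygosity_gives_zero(self):
        st_ = CohortState(
            np.array([0.4, 0.6]),
            np.tile([0.5, 0.3, 0.2], (2, 1)),
            np.tile([0.6, 0.2, 0.2], (2, 1)),
        )
        assert pairwise_identity_disequilibrium(st_, "AA") == pytest.approx(0.0)

    def test_monomorphic_type_is_undefined(self):
        st_ = CohortState(
            np.array([0.5, 0.5]),
            np.tile([1.0, 0, 0], (2, 1)),
            np.array([[0.8, 0.2, 0.0], [0.8, 0.0, 0.2]]),
        )
        assert math.isnan(pairwise_identity_disequilibrium(st_, "AA"))

    def test_selection_lowers_id_below_neutral(self):
        """With selection, genotypes homozygous at many loci are culled, so
        ID at intermediate selfing sits below the neutral expectation."""
        arch = ArchitectureParams(
            L_A=1000, L_R=5000, mu_A=1e-4, mu_R=1e-4, s=0.05, h=0.02, s0_tilde=0.005
        )
        st_ = ilec_equilibrium(arch, SelectionRegime.source(arch.s0_tilde), 0.5)
        for pair in ("AA", "RR", "AR"):
            assert pairwise_identity_disequilibrium(st_, pair) < neutral_id_reference(
                0.5
            )


class TestNeutralIDReference:
    def test_boundary_selfing_fractions_vanish(self):
        assert neutral_id_reference(0.0) == pytest.approx(0.0, abs=1e-12)
        assert neutral_id_reference(1.0) == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_identity_coefficients(self):
        """Fixed point equals phi - F^2 with F = rs/(2-rs) and
        phi = rs (1 + 2F) / (4 - rs) (equilibrium of the recursions)."""
        for rs in (0.2, 0.5, 0.8, 0.95):
            F = rs / (2 - rs)
            phi = rs * (1 + 2 * F) / (4 - rs)
            assert neutral_id_reference(rs) == pytest.approx(phi - F * F, abs=1e-12)

    def test_maximal_at_intermediate_selfing(self):
        grid = np.linspace(0, 1, 21)
        vals = [neutral_id_reference(r) for r in grid]
        k = int(np.argmax(vals))
        assert 0 < k < 20

    def test_neutral_cohort_model_reproduces_reference(self):
        """Dual route: the mutation-free, selection-free cohort recursion
        (which conserves allele frequency) yields the same between-cohort ID
        as the identity-coefficient recursions."""
        arch = ArchitectureParams(L_A=10, L_R=10)
        reg = SelectionRegime.source(0.0)
        solver = ILECSolverParams(I_max=80)
        for rs in (0.3, 0.7):
            st_ = ilec_equilibrium(
                arch, reg, rs, solver, init=initial_state(rs, solver, p1_init=0.25)
            )
            assert pairwise_identity_disequilibrium(st_, "RR") == pytest.approx(
                neutral_id_reference(rs), abs=1e-8
            )


class TestPopulationSummaries:
    def test_single_cohort_wbar_and_undefined_delta(self):
        arch = ArchitectureParams(L_A=0, L_R=100, mu_R=1e-4, s=0.05, h=0.1)
        reg = SelectionRegime.source(0.0)
        st_ = ilec_equilibrium(arch, reg, 0.0)
        summ = population_summaries(st_, arch, reg)
        lw = cohort_log_mean_fitness(st_, arch, reg)
        assert summ.wbar == pytest.approx(math.exp(lw[0]))
        assert math.isnan(summ.delta)

    def test_no_heterozygosity_means_no_inbreeding_depression(self):
        # identical fully homozygous cohorts: selfed and outcrossed classes
        # have equal fitness
        solver = ILECSolverParams(I_max=4)
        p = np.tile([0.9, 0.0, 0.1], (5, 1))
        st_ = CohortState(np.array([0.5, 0.3, 0.1, 0.05, 0.05]), p.copy(), p.copy())
        arch = ArchitectureParams(L_A=0, L_R=50, s=0.05, h=0.1)
        summ = population_summaries(st_, arch, SelectionRegime.source(0.0))
        assert summ.delta == pytest.approx(0.0, abs=1e-12)

    def test_ushaped_mean_fitness_for_nearly_recessive_load(self):
        """Population fitness is minimal at intermediate selfing when load is
        nearly recessive and mutation rate high."""
        arch = ArchitectureParams(
            L_A=1000, L_R=5000, mu_A=1e-4, mu_R=1e-4, s=0.05, h=0.02, s0_tilde=0.005
        )
        reg = SelectionRegime.source(arch.s0_tilde)
        w = {
            rs: population_summaries(ilec_equilibrium(arch, reg, rs), arch, reg).wbar
            for rs in (0.0, 0.4, 0.9)
        }
        assert w[0.4] < w[0.0] and w[0.4] < w[0.9]


class TestLoadDistribution:
    def test_single_locus_pmf(self):
        st_ = _one_cohort_state([1, 0, 0], [0.7, 0.2, 0.1])
        arch = ArchitectureParams(L_A=0, L_R=1, s=0.05, h=0.1)
        dist = load_distribution(st_, arch, SelectionRegime.source(0.0))
        assert dist.method == "exact"
        support = {round(v, 10): p for v, p in zip(dist.values, dist.pmf) if p > 1e-12}
        assert support == pytest.approx({0.0: 0.7, 0.005: 0.2, 0.05: 0.1})

    def test_mean_matches_genotype_frequency_moment(self):
        """E[G] = sum_i f_i [L_R s (p11 + h p01) + L_A s~ (2 p11 + p01)]."""
        arch = ArchitectureParams(
            L_A=100, L_R=300, mu_A=1e-3, mu_R=1e-3, s=0.05, h=0.1, s0_tilde=0.005
        )
        reg = SelectionRegime.source(arch.s0_tilde)
        st_ = ilec_equilibrium(arch, reg, 0.6)
        dist = load_distribution(st_, arch, reg)
        summ = population_summaries(st_, arch, reg)
        assert dist.method == "exact"
        assert dist.mean() == pytest.approx(summ.mean_load, rel=1e-8)

    def test_monte_carlo_fallback_agrees_with_moment(self, rng):
        # irrational dominance ratio -> no common grid -> multinomial sampling
        arch = ArchitectureParams(
            L_A=0, L_R=200, mu_R=1e-3, s=0.05, h=1 / math.pi, s0_tilde=0.0
        )
        reg = SelectionRegime.source(0.0)
        st_ = ilec_equilibrium(arch, reg, 0.5)
        dist = load_distribution(st_, arch, reg, mc_draws=200_000, rng=rng)
        summ = population_summaries(st_, arch, reg)
        assert dist.method == "monte-carlo"
        se = math.sqrt(dist.var() / 200_000)
        assert abs(dist.mean() - summ.mean_load) < 5 * se + 1e-3

    def test_bimodal_load_for_nearly_recessive_alleles(self):
        """Outcrossed individuals carry much lower recessive load than any
        selfed cohort, so the population load density is bimodal."""
        arch = ArchitectureParams(
            L_A=1000, L_R=5000, mu_A=1e-4, mu_R=1e-4, s=0.05, h=0.02, s0_tilde=0.005
        )
        reg = SelectionRegime.source(arch.s0_tilde)
        st_ = ilec_equilibrium(arch, reg, 0.5)
        dist = load_distribution(st_, arch, reg)
        # coarse-grain to a density and look for two separated peaks
        nbin = 400
        edges = np.linspace(0, dist.values[-1], nbin + 1)
        idx = np.clip(np.digitize(dist.values, edges) - 1, 0, nbin - 1)
        density = np.bincount(idx, weights=dist.pmf, minlength=nbin)
        peak1 = int(np.argmax(density))
        # second peak: best bin at least 10 bins away from the first
        away = np.abs(np.arange(nbin) - peak1) > 10
        peak2 = int(np.arange(nbin)[away][np.argmax(density[away])])
        lo, hi = sorted((peak1, peak2))
        valley = density[lo : hi + 1].min()
        assert valley < 0.5 * min(density[peak1], density[peak2])
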