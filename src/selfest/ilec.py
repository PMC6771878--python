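"""Deterministic selfing-age-cohort recursions for a large partially selfing
population (the ILEC approximation: Identity and Linkage Equilibrium within
Cohorts).

The population is partitioned into cohorts by *selfing age* — the number of
consecutive generations of selfing in the lineage back to the most recent
outcrossed ancestor.  The state of the population is the vector of cohort
masses ``f_i`` together with per-cohort genotype frequencies at an
exchangeable additive locus and an exchangeable recessive locus
(p00, p01, p11 each).  All within-cohort associations between loci (linkage
and identity disequilibria) are neglected; population-wide disequilibria then
arise purely from between-cohort differences in homozygosity.

One generation is mutation -> selection -> partial-selfing reproduction:

* mutation flips each allele independently with probability mu;
* selection reweights genotype frequencies by the marginal genotype fitness
  weights, and cohort mean fitness is the product of per-locus normalizers
  (accumulated in log space, ``L * ln(nu)``, to avoid underflow at large L);
* reproduction selects parents with weights ``g_i = f_i wbar_i / sum f wbar``.
  Outcrossed offspring (mass ``1 - r_s``) form cohort 0 at Hardy-Weinberg
  proportions of the pooled gamete allele frequency; selfed offspring of a
  cohort-i parent form cohort i+1 with Mendelian selfing per locus
  (p11 -> p11 + p01/4, p01 -> p01/2).  Ages at or beyond the absorbing cap
  ``I_max`` are pooled by g-weighted averaging.

Iterating to a fixed point yields the mutation-selection-drift-free
equilibrium, from which allele frequencies, mean fitness, inbreeding
depression, pairwise identity disequilibria and the full distribution of
genetic load follow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .core import (
    ArchitectureParams,
    ParameterError,
    SelectionRegime,
    recessive_weights,
)

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Equilibrium iteration failed to converge; carries the last state."""

    def __init__(self, message: str, state: "CohortState"):
        super().__init__(message)
        self.state = state


@dataclass
class CohortState:
    """Selfing-age cohort masses and per-cohort genotype frequencies.

    ``pA`` and ``pR`` have shape (I_max + 1, 3) holding (p00, p01, p11) for an
    exchangeable additive / recessive locus in each cohort.  The final class
    (age I_max) is absorbing.
    """

    f: np.ndarray
    pA: np.ndarray
    pR: np.ndarray
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.pA = np.asarray(self.pA, dtype=float)
        self.pR = np.asarray(self.pR, dtype=float)
        n = self.f.size
        if self.pA.shape != (n, 3) or self.pR.shape != (n, 3):
            raise ParameterError("genotype frequency arrays must be (I_max+1, 3)")

    @property
    def I_max(self) -> int:
        return self.f.size - 1

    def copy(self) -> "CohortState":
        return CohortState(
            self.f.copy(), self.pA.copy(), self.pR.copy(), self.converged, self.n_iter
        )

    def validate(self, atol: float = 1e-9) -> None:
        """Mass conservation and frequency bounds (asserted each iteration)."""
        if abs(self.f.sum() - 1.0) > atol:
            raise ParameterError(f"cohort masses sum to {self.f.sum()}, not 1")
        if (self.f < -atol).any():
            raise ParameterError("negative cohort mass")
        for p in (self.pA, self.pR):
            if (p < -atol).any() or (p > 1 + atol).any():
                raise ParameterError("genotype frequency outside [0, 1]")
            if np.abs(p.sum(axis=1) - 1.0).max() > atol:
                raise ParameterError("genotype frequencies do not sum to 1")

    def allele_frequency(self, locus_type: str) -> float:
        """Population-wide frequency of the "1" allele for a locus type."""
        p = self.pA if locus_type == "A" else self.pR
        return float(self.f @ (p[:, 2] + 0.5 * p[:, 1]))


@dataclass(frozen=True)
class ILECSolverParams:
    """Iteration controls for the equilibrium solver."""

    I_max: int = 50
    tol: float = 1e-12
    max_iter: int = 1_000_000

    def __post_init__(self) -> None:
        if self.I_max < 1:
            raise ParameterError("I_max must be >= 1")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")


def initial_state(
    r_s: float, solver: ILECSolverParams, p1_init: float = 0.0
) -> CohortState:
    """Monomorphic-"0" start (overridable via p1_init) with geometric cohort
    masses f_i ~ (1-r_s) r_s^i, tail mass pooled in the absorbing class."""
    I = solver.I_max
    i = np.arange(I + 1, dtype=float)
    if r_s >= 1.0:
        f = np.zeros(I + 1)
        f[-1] = 1.0
    else:
        f = (1.0 - r_s) * r_s**i
        f[-1] = r_s**I
    q = p1_init
    hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    p = np.tile(hw, (I + 1, 1))
    return CohortState(f, p.copy(), p.copy())


# ---------------------------------------------------------------------------
# One-generation steps
# ---------------------------------------------------------------------------


def _mutation_matrix(mu: float) -> np.ndarray:
    """Genotype transition from flipping each of the two alleles
    independently with probability mu (columns: source genotype 00, 01, 11)."""
    a, b = 1.0 - mu, mu
    return np.array(
        [
            [a * a, a * b, b * b],
            [2 * a * b, a * a + b * b, 2 * a * b],
            [b * b, a * b, a * a],
        ]
    )


def cohort_mutation(state: CohortState, arch: ArchitectureParams) -> CohortState:
    """Symmetric allele flips at rates mu_A / mu_R; cohort masses unchanged."""
    out = state.copy()
    out.pA = state.pA @ _mutation_matrix(arch.mu_A).T
    out.pR = state.pR @ _mutation_matrix(arch.mu_R).T
    return out


def cohort_log_mean_fitness(
    state: CohortState, arch: ArchitectureParams, regime: SelectionRegime
) -> np.ndarray:
    """ln(wbar_i): per-cohort mean fitness under within-cohort independence,
    i.e. L_A ln(nu_A) + L_R ln(nu_R) with nu the per-locus normalizers."""
    lw = np.zeros(state.f.size)
    if arch.L_A > 0:
        nuA = state.pA @ regime.additive_weights()
        lw += arch.L_A * np.log(nuA)
    if arch.L_R > 0:
        nuR = state.pR @ recessive_weights(arch)
        lw += arch.L_R * np.log(nuR)
    return lw


def cohort_selection(
    state: CohortState, arch: ArchitectureParams, regime: SelectionRegime
) -> tuple[CohortState, np.ndarray]:
    """Reweight per-locus genotype frequencies by marginal genotype fitness.

    Returns the post-selection state and ln(wbar_i) per cohort.  Cohort masses
    are unchanged here; fitness-weighting of cohorts happens in reproduction.
    """
    out = state.copy()
    logw = np.zeros(state.f.size)
    if arch.L_A > 0:
        wA = regime.additive_weights()
        num = state.pA * wA
        nu = num.sum(axis=1)
        out.pA = num / nu[:, None]
        logw += arch.L_A * np.log(nu)
    if arch.L_R > 0:
        wR = recessive_weights(arch)
        num = state.pR * wR
        nu = num.sum(axis=1)
        out.pR = num / nu[:, None]
        logw += arch.L_R * np.log(nu)
    return out, logw


def _mendelian_selfing(p: np.ndarray) -> np.ndarray:
    """Per-locus genotype frequencies among selfed offspring."""
    p00, p01, p11 = p[:, 0], p[:, 1], p[:, 2]
    return np.stack(
        [p00 + 0.25 * p01, 0.5 * p01, p11 + 0.25 * p01], axis=1
    )


def cohort_reproduction(
    state: CohortState, logwbar: np.ndarray, r_s: float
) -> CohortState:
    """Partial-selfing reproduction from a post-selection state.

    Outcrossed offspring (mass 1-r_s) form cohort 0 at Hardy-Weinberg
    proportions of the pooled gamete allele frequency — the defining ILEC
    approximation (within-cohort LD of outcrossed offspring is neglected).
    Selfed offspring of cohort i form cohort i+1; the absorbing class pools
    ages >= I_max by g-weighted averaging.
    """
    if not 0.0 <= r_s <= 1.0:
        raise ParameterError(f"r_s={r_s} outside [0, 1]")
    I = state.I_max
    lw = logwbar - logwbar.max()
    g = state.f * np.exp(lw)
    g /= g.sum()

    new_f = np.zeros(I + 1)
    new_f[0] = 1.0 - r_s
    new_f[1:I] = r_s * g[0 : I - 1]
    new_f[I] = r_s * (g[I - 1] + g[I])

    out = state.copy()
    for name in ("pA", "pR"):
        p = getattr(state, name)
        q = float(g @ (p[:, 2] + 0.5 * p[:, 1]))
        selfed = _mendelian_selfing(p)
        new_p = np.empty_like(p)
        new_p[0] = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        new_p[1:I] = selfed[0 : I - 1]
        wsum = g[I - 1] + g[I]
        if wsum > 0:
            new_p[I] = (g[I - 1] * selfed[I - 1] + g[I] * selfed[I]) / wsum
        else:
            new_p[I] = selfed[I]
        setattr(out, name, new_p)
    out.f = new_f
    return out


def generation(
    state: CohortState,
    arch: ArchitectureParams,
    regime: SelectionRegime,
    r_s: float,
) -> CohortState:
    """One full mutation -> selection -> reproduction cycle (census to census)."""
    st = cohort_mutation(state, arch)
    st, logw = cohort_selection(st, arch, regime)
    return cohort_reproduction(st, logw, r_s)


def ilec_equilibrium(
    arch: ArchitectureParams,
    regime: SelectionRegime,
    r_s: float,
    solver: ILECSolverParams = ILECSolverParams(),
    init: CohortState | None = None,
) -> CohortState:
    """Iterate the cohort recursions to a fixed point.

    Convergence is the sup-norm change of (f, pA, pR) between successive
    censuses falling below ``solver.tol``.  Non-convergence raises
    :class:`ConvergenceError` carrying the last state.
    """
    if not 0.0 <= r_s <= 1.0:
        raise ParameterError(f"r_s={r_s} outside [0, 1]")
    state = init.copy() if init is not None else initial_state(r_s, solver)
    state.validate()
    for it in range(1, solver.max_iter + 1):
        new = generation(state, arch, regime, r_s)
        delta = max(
            np.abs(new.f - state.f).max(),
            np.abs(new.pA - state.pA).max(),
            np.abs(new.pR - state.pR).max(),
        )
        state = new
        if delta < solver.tol:
            state.converged = True
            state.n_iter = it
            state.validate()
            logger.debug("ILEC converged in %d iterations (r_s=%.3g)", it, r_s)
            return state
    state.n_iter = solver.max_iter
    raise ConvergenceError(
        f"no convergence within {solver.max_iter} iterations (last delta={delta:.3g})",
        state,
    )


# ---------------------------------------------------------------------------
# Equilibrium summaries
# ---------------------------------------------------------------------------


@dataclass
class ILECSummary:
    """Population-wide statistics of a census-state (post-reproduction)."""

    p_A: float
    p_R: float
    wbar: float
    wbar_oc: float
    wbar_self: float
    delta: float  # nan when undefined (r_s = 0 or 1)
    het_A: float
    het_R: float
    mean_load: float


def population_summaries(
    state: CohortState, arch: ArchitectureParams, regime: SelectionRegime
) -> ILECSummary:
    """Allele frequencies, mean fitness, inbreeding depression, heterozygosity.

    Inbreeding depression is delta = 1 - Wbar_self / Wbar_oc where the selfed
    class is every cohort with age >= 1 at the census and the outcrossed class
    is cohort 0, weighted by census masses f_i.  Returned as NaN when either
    class is empty (pure outcrossing or pure selfing).
    """
    f = state.f
    lw = cohort_log_mean_fitness(state, arch, regime)
    w = np.exp(lw)
    wbar = float(f @ w)
    f_self = f[1:].sum()
    wbar_oc = float(w[0])
    wbar_self = float(f[1:] @ w[1:] / f_self) if f_self > 0 else math.nan
    if f[0] > 0 and f_self > 0:
        delta = 1.0 - wbar_self / wbar_oc
    else:
        delta = math.nan
    mean_load = 0.0
    if arch.L_R > 0:
        mean_load += arch.s * arch.L_R * float(
            f @ (state.pR[:, 2] + arch.h * state.pR[:, 1])
        )
    if arch.L_A > 0:
        atoms = regime.additive_exponent_atoms()
        mean_load += arch.L_A * float(f @ (state.pA @ atoms))
    return ILECSummary(
        p_A=state.allele_frequency("A"),
        p_R=state.allele_frequency("R"),
        wbar=wbar,
        wbar_oc=wbar_oc,
        wbar_self=wbar_self,
        delta=delta,
        het_A=float(f @ state.pA[:, 1]),
        het_R=float(f @ state.pR[:, 1]),
        mean_load=mean_load,
    )


def pairwise_identity_disequilibrium(state: CohortState, type_pair: str) -> float:
    """Normalized identity disequilibrium between two unlinked loci.

    For a pair of same-type loci this is the between-cohort variance of the
    homozygote frequency p11 divided by p^2 (1-p)^2:

        ID = sum_i sum_{j<i} f_i f_j (p11(i) - p11(j))^2 / p^2(1-p)^2

    For a mixed additive/recessive pair ("AR") the numerator is the
    between-cohort covariance of the two p11 vectors and the normalizer is
    the natural generalization p_A(1-p_A) p_R(1-p_R).  Returns NaN when a
    participating locus type is monomorphic.
    """
    if type_pair not in ("AA", "RR", "AR"):
        raise ParameterError(f"unknown type pair {type_pair!r}")
    f = state.f

    def moments(t: str) -> tuple[np.ndarray, float]:
        p = state.pA if t == "A" else state.pR
        return p[:, 2], state.allele_frequency(t)

    a, pa = moments(type_pair[0])
    b, pb = moments(type_pair[1])
    norm = pa * (1 - pa) * pb * (1 - pb)
    if norm <= 0:
        return math.nan
    cov = float(f @ (a * b) - (f @ a) * (f @ b))
    return cov / norm


def neutral_id_reference(r_s: float, tol: float = 1e-14) -> float:
    """Neutral identity disequilibrium between two unlinked loci at
    equilibrium under partial selfing.

    Iterates the exact one- and two-locus identity-by-descent recursions of a
    large neutral population (F' = r_s (1 + F) / 2 and
    phi' = r_s (1 + 2F + phi) / 4 for unlinked loci) to their fixed point and
    returns phi - F^2, which equals the normalized homozygosity covariance.
    Vanishes at r_s = 0 and in the fully selfing limit; maximal at
    intermediate selfing.
    """
    if not 0.0 <= r_s <= 1.0:
        raise ParameterError(f"r_s={r_s} outside [0, 1]")
    F = phi = 0.0
    for _ in range(100_000):
        F_new = 0.5 * r_s * (1.0 + F)
        phi_new = 0.25 * r_s * (1.0 + 2.0 * F + phi)
        if abs(F_new - F) < tol and abs(phi_new - phi) < tol:
            F, phi = F_new, phi_new
            break
        F, phi = F_new, phi_new
    return phi - F * F


# ---------------------------------------------------------------------------
# Load distribution
# ---------------------------------------------------------------------------


@dataclass
class LoadDistribution:
    """Probability distribution of genetic load G = -ln W at equilibrium.

    ``values`` is a grid of load values and ``pmf`` the corresponding
    probabilities (summing to 1).  ``method`` records whether the exact
    integer-grid convolution or the Monte-Carlo fallback produced it.
    """

    values: np.ndarray
    pmf: np.ndarray
    method: str

    def mean(self) -> float:
        return float(self.values @ self.pmf)

    def var(self) -> float:
        m = self.mean()
        return float(((self.values - m) ** 2) @ self.pmf)


def _commensurate_step(
    atoms: np.ndarray, rtol: float = 1e-9, max_den: int = 1000
) -> float | None:
    """Common grid step for which every atom is an integer multiple, or None.

    Ratios of atoms to the smallest positive atom are approximated by small
    rationals; the step is the smallest atom divided by the lcm of their
    denominators.  Returns None (triggering the Monte-Carlo fallback) when no
    such small-denominator structure exists.
    """
    from fractions import Fraction

    pos = np.unique(atoms[atoms > 0])
    if pos.size == 0:
        return None
    base = pos[0]
    lcm = 1
    for a in pos:
        frac = Fraction(a / base).limit_denominator(max_den)
        if abs(float(frac) - a / base) > rtol * (a / base):
            return None
        lcm = lcm * frac.denominator // math.gcd(lcm, frac.denominator)
        if lcm > 100_000:
            return None
    return base / lcm


def _pmf_power(atom_idx: np.ndarray, atom_p: np.ndarray, L: int) -> np.ndarray:
    """PMF of the sum of L iid integer-valued atoms, via FFT power."""
    base = np.zeros(int(atom_idx.max()) + 1)
    np.add.at(base, atom_idx, atom_p)
    n_out = int(atom_idx.max()) * L + 1
    n_fft = next_fast_len(n_out)
    spec = rfft(base, n=n_fft) ** L
    pmf = irfft(spec, n=n_fft)[:n_out]
    pmf = np.clip(pmf, 0.0, None)
    return pmf / pmf.sum()


def load_distribution(
    state: CohortState,
    arch: ArchitectureParams,
    regime: SelectionRegime,
    step: float | None = None,
    mc_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
    f_cutoff: float = 1e-10,
) -> LoadDistribution:
    """Distribution of G across the population at a census state.

    Within cohort i, per-locus genotypes are independent, so the per-type
    counts of heterozygous/homozygous loci are multinomial; the load is the
    cohort mixture of the convolution of the per-type count distributions.
    When the per-locus load atoms (0, hs, s) and (0, s~, 2s~) are commensurate
    on a common grid the convolution is computed exactly by FFT on that grid;
    otherwise the distribution is estimated by Monte-Carlo multinomial
    sampling (``mc_draws`` draws).
    """
    atoms_all = []
    if arch.L_R > 0:
        atoms_all.append(arch.s * np.array([0.0, arch.h, 1.0]))
    if arch.L_A > 0:
        atoms_all.append(regime.additive_exponent_atoms())
    if not atoms_all:
        return LoadDistribution(np.array([0.0]), np.array([1.0]), "exact")

    step_found = step if step is not None else _commensurate_step(
        np.concatenate(atoms_all)
    )
    f = state.f
    keep = f > f_cutoff
    fk = f[keep] / f[keep].sum()

    if step_found is not None:
        pmfs = []
        for i in np.flatnonzero(keep):
            parts = []
            if arch.L_R > 0:
                idx = np.round(arch.s * np.array([0.0, arch.h, 1.0]) / step_found)
                parts.append(_pmf_power(idx.astype(int), state.pR[i], arch.L_R))
            if arch.L_A > 0:
                idx = np.round(regime.additive_exponent_atoms() / step_found)
                parts.append(_pmf_power(idx.astype(int), state.pA[i], arch.L_A))
            pmf = parts[0]
            if len(parts) == 2:
                n_out = parts[0].size + parts[1].size - 1
                n_fft = next_fast_len(n_out)
                pmf = irfft(
                    rfft(parts[0], n=n_fft) * rfft(parts[1], n=n_fft), n=n_fft
                )[:n_out]
                pmf = np.clip(pmf, 0.0, None)
                pmf /= pmf.sum()
            pmfs.append(pmf)
        n = max(p.size for p in pmfs)
        mix = np.zeros(n)
        for w, p in zip(fk, pmfs):
            mix[: p.size] += w * p
        values = np.arange(n) * step_found
        return LoadDistribution(values, mix / mix.sum(), "exact")

    # Monte-Carlo fallback on incommensurate grids
    rng = np.random.default_rng(0) if rng is None else rng
    cohorts = rng.choice(np.flatnonzero(keep), size=mc_draws, p=fk)
    G = np.zeros(mc_draws)
    for i in np.flatnonzero(keep):
        m = cohorts == i
        nm = int(m.sum())
        if nm == 0:
            continue
        if arch.L_R > 0:
            counts = rng.multinomial(arch.L_R, state.pR[i], size=nm)
            G[m] += arch.s * (counts[:, 2] + arch.h * counts[:, 1])
        if arch.L_A > 0:
            counts = rng.multinomial(arch.L_A, state.pA[i], size=nm)
            G[m] += counts @ regime.additive_exponent_atoms()
    hist, edges = np.histogram(G, bins=200)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return LoadDistribution(centers, hist / hist.sum(), "monte-carlo")
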