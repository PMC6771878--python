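"""Colonization of a new habitat by founders drawn from a partially selfing
source population, under hard selection.

Founders are sampled from the deterministic cohort-structured source
equilibrium (:func:`selfest.ilec.ilec_equilibrium`): each founder gets a
selfing age i with probability f_i and independent per-locus genotypes drawn
from that cohort's frequencies (the within-cohort independence assumption).
On the island the direction of selection on the additive trait is reversed;
recessive alleles remain unconditionally deleterious.  Demography is hard
selection in Ricker form: the next census size is Poisson with mean

    N_t * exp[r_0 (1 - N_t / K)] * Wbar_t,

so mean fitness multiplies the growth rate and genetics and demography are
coupled.  Establishment succeeds when the population numbers at least
``success_fraction * K`` individuals exactly ``T`` generations after the
founder event; extinction (N = 0) is absorbing.

A Poisson branching-process approximation for the establishment probability
(each founder line survives independently; extinction probability per line is
the fixed point of q = exp[m (q - 1)] with m = e^{r_0} W) is provided as an
independent check valid for highly fit founders and large K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import ArchitectureParams, ParameterError, SelectionRegime
from .ilec import CohortState
from .simulate import DiploidPopulation, pack_bits

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IslandParams:
    """New-habitat selection and demographic parameters.

    ``s1_tilde`` is the per-allele selection strength favouring the additive
    "1" allele on the island (beta_1 * alpha); ``r_0`` the intrinsic growth
    rate; ``K`` the carrying capacity; ``N_0`` founder count; ``T`` the
    census horizon (generations); success requires N_T >= success_fraction*K.
    ``r_s`` is the selfing probability, the same as in the source.
    """

    s1_tilde: float
    r_0: float
    K: int
    N_0: int
    r_s: float
    T: int = 100
    success_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.K < 1 or self.N_0 < 1 or self.T < 1:
            raise ParameterError("K, N_0 and T must be >= 1")
        if not 0.0 < self.success_fraction <= 1.0:
            raise ParameterError("success_fraction must be in (0, 1]")
        if not 0.0 <= self.r_s <= 1.0:
            raise ParameterError("r_s must be in [0, 1]")
        if self.s1_tilde < 0:
            raise ParameterError("s1_tilde must be nonnegative")

    @property
    def regime(self) -> SelectionRegime:
        return SelectionRegime.island(self.s1_tilde)

    @property
    def success_threshold(self) -> float:
        return self.success_fraction * self.K


@dataclass
class ReplicateTrajectory:
    """Per-generation census sizes and mean fitnesses of one replicate."""

    N: np.ndarray
    wbar: np.ndarray
    success: bool
    extinct_at: int | None


@dataclass
class EstablishmentResult:
    """Monte-Carlo estimate of the establishment probability."""

    successes: np.ndarray
    p_est: float
    se: float
    n_replicates: int
    trajectories: list[ReplicateTrajectory] = field(default_factory=list)
    sfs_snapshots: list[np.ndarray] = field(default_factory=list)


def sample_founders(
    eq_state: CohortState,
    arch: ArchitectureParams,
    N_0: int,
    rng: np.random.Generator,
) -> DiploidPopulation:
    """Draw N_0 independent founder genomes from the source equilibrium.

    Each founder is assigned a selfing age with probability f_i, then each
    locus independently receives genotype 00/01/11 from that cohort's
    frequencies; heterozygote phase is randomized.  Refuses non-converged
    states.
    """
    if not eq_state.converged:
        raise ParameterError("refusing to sample founders from a non-converged state")
    if N_0 < 1:
        raise ParameterError("N_0 must be >= 1")
    f = np.clip(eq_state.f, 0.0, None)
    ages = rng.choice(f.size, size=N_0, p=f / f.sum())

    def block(p: np.ndarray, L: int) -> np.ndarray:
        if L == 0:
            return np.zeros((2, N_0, 0), dtype=np.uint64)
        u = rng.random((N_0, L))
        probs = p[ages]  # (N_0, 3)
        geno = (u > probs[:, [0]]).astype(np.uint8) + (
            u > (probs[:, 0] + probs[:, 1])[:, None]
        ).astype(np.uint8)
        het = geno == 1
        phase = rng.integers(0, 2, size=(N_0, L), dtype=np.uint8)
        h0 = np.where(het, phase, (geno == 2).astype(np.uint8))
        h1 = np.where(het, 1 - phase, (geno == 2).astype(np.uint8))
        return pack_bits(np.stack([h0, h1]))

    return DiploidPopulation(
        block(eq_state.pA, arch.L_A),
        block(eq_state.pR, arch.L_R),
        arch.L_A,
        arch.L_R,
        ages.astype(np.int64),
    )


def demographic_update(
    N_t: int, wbar_t: float, island: IslandParams, rng: np.random.Generator
) -> int:
    """Next census size: Poisson(N_t e^{r_0 (1 - N_t/K)} Wbar_t); 0 absorbing."""
    if N_t <= 0:
        return 0
    mean = N_t * math.exp(island.r_0 * (1.0 - N_t / island.K)) * wbar_t
    return int(rng.poisson(mean))


def establishment_replicate(
    founders: DiploidPopulation,
    arch: ArchitectureParams,
    island: IslandParams,
    rng: np.random.Generator,
    sfs_at: int | None = None,
) -> tuple[ReplicateTrajectory, np.ndarray | None]:
    """Simulate one colonization attempt from a founder cohort.

    Per generation: mutation, island fitness evaluation, Poisson/Ricker draw
    of the offspring number from the mean fitness of all current individuals,
    then per-offspring selfing decisions and fitness-weighted parent sampling
    (outcross partners drawn independently, so a lone individual necessarily
    selfs).  All-zero fitness with N > 0 counts as extinction that generation.
    Optionally returns the adaptive-allele SFS at generation ``sfs_at``.
    """
    if founders.N == 0:
        raise ParameterError("founder population is empty")
    pop = founders.copy()
    regime = island.regime
    sizes = [pop.N]
    wbars = []
    sfs = None
    extinct_at = None
    for t in range(1, island.T + 1):
        pop.mutate(arch, rng)
        W = pop.fitnesses(arch, regime)
        wbar = float(W.mean())
        wbars.append(wbar)
        n_next = demographic_update(pop.N, wbar, island, rng)
        if n_next == 0 or not W.sum() > 0:
            extinct_at = t
            sizes.append(0)
            break
        pop = pop.reproduce(n_next, W, island.r_s, rng)
        sizes.append(pop.N)
        if sfs_at is not None and t == sfs_at:
            sfs = adaptive_allele_frequencies(pop)
    N_arr = np.array(sizes)
    success = extinct_at is None and N_arr[-1] >= island.success_threshold
    traj = ReplicateTrajectory(
        N=N_arr, wbar=np.array(wbars), success=bool(success), extinct_at=extinct_at
    )
    return traj, sfs


def estimate_establishment_probability(
    eq_state: CohortState,
    arch: ArchitectureParams,
    island: IslandParams,
    R: int,
    rng: np.random.Generator,
    keep_trajectories: bool = False,
    sfs_at: int | None = None,
    sfs_established_only: bool = True,
) -> EstablishmentResult:
    """R independent colonization events, each with fresh founders.

    Replicates are independent given sub-generators spawned from ``rng`` by a
    fixed splitting rule, so results are reproducible and order-independent.
    Returns the success fraction with its binomial standard error.
    """
    if R < 1:
        raise ParameterError("R must be >= 1")
    child_rngs = rng.spawn(R)
    successes = np.zeros(R, dtype=bool)
    trajectories: list[ReplicateTrajectory] = []
    snapshots: list[np.ndarray] = []
    for r, sub in enumerate(child_rngs):
        founders = sample_founders(eq_state, arch, island.N_0, sub)
        traj, sfs = establishment_replicate(founders, arch, island, sub, sfs_at)
        successes[r] = traj.success
        if keep_trajectories:
            trajectories.append(traj)
        if sfs is not None and (traj.success or not sfs_established_only):
            snapshots.append(sfs)
    p = float(successes.mean())
    se = math.sqrt(p * (1.0 - p) / R)
    return EstablishmentResult(
        successes=successes,
        p_est=p,
        se=se,
        n_replicates=R,
        trajectories=trajectories,
        sfs_snapshots=snapshots,
    )


# ---------------------------------------------------------------------------
# Branching-process approximation
# ---------------------------------------------------------------------------


def _poisson_extinction_prob(m: float, tol: float = 1e-12, max_iter: int = 100_000) -> float:
    """Smallest root of q = exp[m (q - 1)] (Poisson offspring, mean m)."""
    if m <= 1.0:
        return 1.0
    q = 0.0
    for _ in range(max_iter):
        q_new = math.exp(m * (q - 1.0))
        if abs(q_new - q) < tol:
            return q_new
        q = q_new
    raise RuntimeError("extinction-probability fixed point did not converge")


def branching_process_pest(
    founder_fitnesses: np.ndarray | float, r_0: float, N_0: int | None = None
) -> float:
    """Establishment probability from independent Poisson branching lines.

    Each founder k initiates a line with offspring mean m_k = e^{r_0} W_k;
    the line dies out with probability q_k solving q = exp[m_k (q - 1)], and
    P_est = 1 - prod_k q_k.  With a scalar pooled fitness, pass ``N_0`` and
    P_est = 1 - q^{N_0}.
    """
    growth = math.exp(r_0)
    if np.isscalar(founder_fitnesses):
        if N_0 is None:
            raise ParameterError("N_0 required with a pooled scalar fitness")
        q = _poisson_extinction_prob(growth * float(founder_fitnesses))
        return 1.0 - q**N_0
    W = np.asarray(founder_fitnesses, dtype=float)
    if (W < 0).any() or (W > 1).any():
        raise ParameterError("fitnesses must lie in [0, 1]")
    log_q = sum(math.log(_poisson_extinction_prob(growth * w)) for w in W)
    return 1.0 - math.exp(log_q)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def viability_check(
    eq_state: CohortState,
    arch: ArchitectureParams,
    source_regime: SelectionRegime,
    r_s: float,
    r_0: float,
    rng: np.random.Generator,
    n_replicates: int = 100,
    N_0: int = 100,
    T: int = 100,
    threshold: float = 0.95,
) -> tuple[bool, float]:
    """Pre-check that a large source population is demographically viable.

    Simulates N_0 = 100 individuals under source-habitat fitness with
    effectively infinite K (density factor e^{r_0}) and asks whether the
    population doubles within T generations in more than ``threshold`` of
    replicates.  Returns (viable, doubling fraction).
    """
    big_K = 10**9
    island = IslandParams(
        s1_tilde=0.0, r_0=r_0, K=big_K, N_0=N_0, r_s=r_s, T=T, success_fraction=1e-9
    )
    doubled = 0
    for sub in rng.spawn(n_replicates):
        founders = sample_founders(eq_state, arch, N_0, sub)
        pop = founders.copy()
        ok = False
        for _ in range(T):
            pop.mutate(arch, sub)
            W = pop.fitnesses(arch, source_regime)
            n_next = demographic_update(pop.N, float(W.mean()), island, sub)
            if n_next == 0 or not W.sum() > 0:
                break
            pop = pop.reproduce(n_next, W, r_s, sub)
            if pop.N >= 2 * N_0:
                ok = True
                break
        doubled += ok
    frac = doubled / n_replicates
    return frac > threshold, frac


def adaptive_allele_frequencies(pop: DiploidPopulation) -> np.ndarray:
    """Per-additive-locus frequency of the island-favoured "1" allele."""
    genoA, _ = pop.genotypes()
    if genoA.shape[1] == 0:
        return np.empty(0)
    return genoA.mean(axis=0) / 2.0


@dataclass
class SFS:
    """Site frequency spectrum of island-adaptive alleles at additive loci."""

    bin_edges: np.ndarray
    counts: np.ndarray
    fixed_low: int  # loci with the adaptive allele lost (frequency 0)
    fixed_high: int  # loci with the adaptive allele fixed (frequency 1)


def adaptive_allele_sfs(
    pop: DiploidPopulation, arch: ArchitectureParams, bins: int = 20
) -> SFS:
    """Histogram of adaptive-allele frequencies with explicit fixed classes.

    The interior histogram covers (0, 1) exclusive; loci at exactly 0 or 1
    are reported separately.  Total counts sum to L_A.
    """
    freqs = adaptive_allele_frequencies(pop)
    fixed_low = int(np.count_nonzero(freqs == 0.0))
    fixed_high = int(np.count_nonzero(freqs == 1.0))
    interior = freqs[(freqs > 0) & (freqs < 1)]
    counts, edges = np.histogram(interior, bins=bins, range=(0.0, 1.0))
    return SFS(edges, counts, fixed_low, fixed_high)
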