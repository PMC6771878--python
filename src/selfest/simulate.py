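"""Individual-based forward simulation of the partially selfing source
population.

This is the stochastic counterpart of the deterministic cohort recursions in
:mod:`selfest.ilec` and exists to validate them.  The life cycle per
generation matches the deterministic model: symmetric mutation at every
locus, fitness-weighted sampling of parents with replacement, selfing with
probability ``r_s`` per offspring, and gamete formation by free recombination
(an independent fair coin at every locus).

Haplotypes are stored bit-packed in uint64 words (one bit per locus, additive
and recessive blocks in separate arrays), which makes mutation (sparse XOR),
recombination (random 64-bit masks) and genotype counting (popcount) cheap
enough to run thousands of generations at N of a few thousand in seconds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .core import ArchitectureParams, ParameterError, SelectionRegime

logger = logging.getLogger(__name__)


class PopulationCollapseError(RuntimeError):
    """Total fitness is zero: no parent can be sampled."""


# ---------------------------------------------------------------------------
# Bit-packing helpers
# ---------------------------------------------------------------------------


def _n_words(L: int) -> int:
    return (L + 63) >> 6


def pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack a (..., L) binary array into (..., ceil(L/64)) uint64 words."""
    bits = np.asarray(bits, dtype=np.uint64)
    L = bits.shape[-1]
    W = _n_words(L)
    words = np.zeros(bits.shape[:-1] + (W,), dtype=np.uint64)
    idx = np.arange(L)
    w, b = idx >> 6, (idx & 63).astype(np.uint64)
    np.add.at(words, (..., w), bits << b)
    return words


def unpack_bits(words: np.ndarray, L: int) -> np.ndarray:
    """Unpack (..., W) uint64 words into a (..., L) uint8 binary array."""
    idx = np.arange(L)
    w, b = idx >> 6, (idx & 63).astype(np.uint64)
    return ((words[..., w] >> b) & np.uint64(1)).astype(np.uint8)


def _sample_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct uniform integers from range(n), k << n."""
    pos = np.unique(rng.integers(0, n, size=k))
    while pos.size < k:
        extra = rng.integers(0, n, size=k - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def _flip_sites(
    hap: np.ndarray, L: int, mu: float, rng: np.random.Generator
) -> None:
    """Flip each allele independently with probability mu (in place).

    The number of flipped sites is Binomial(2 N L, mu); a uniform distinct
    subset of that size is then XOR-ed in.
    """
    if mu <= 0 or L == 0:
        return
    n = hap.shape[1]
    n_sites = 2 * n * L
    k = rng.binomial(n_sites, mu)
    if k == 0:
        return
    pos = _sample_distinct(rng, n_sites, k)
    h = pos // (n * L)
    rem = pos - h * n * L
    i = rem // L
    l = rem - i * L
    np.bitwise_xor.at(
        hap, (h, i, l >> 6), np.uint64(1) << (l & 63).astype(np.uint64)
    )


def _gametes(
    hap: np.ndarray, parents: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One free-recombination gamete per listed parent (uint64 words)."""
    W = hap.shape[2]
    if W == 0:
        return np.zeros((parents.size, 0), dtype=np.uint64)
    mask = rng.integers(0, 1 << 64, size=(parents.size, W), dtype=np.uint64)
    return (hap[0, parents] & mask) | (hap[1, parents] & ~mask)


# ---------------------------------------------------------------------------
# Population container
# ---------------------------------------------------------------------------


class DiploidPopulation:
    """N diploid genomes with phased, bit-packed haplotypes.

    ``hapA``/``hapR`` have shape (2, N, words) for the additive and recessive
    blocks.  ``selfing_age`` holds the per-individual count of consecutive
    selfed generations (0 = outcrossed this generation); it is exact for
    every individual because the simulator assigns it at birth.
    """

    def __init__(
        self,
        hapA: np.ndarray,
        hapR: np.ndarray,
        L_A: int,
        L_R: int,
        selfing_age: np.ndarray,
        generation: int = 0,
    ):
        self.hapA = hapA
        self.hapR = hapR
        self.L_A = L_A
        self.L_R = L_R
        self.selfing_age = selfing_age
        self.generation = generation
        if hapA.shape[0] != 2 or hapR.shape[0] != 2:
            raise ParameterError("haplotype arrays must have leading axis 2")
        if hapA.shape[1] != hapR.shape[1] or hapA.shape[1] != selfing_age.size:
            raise ParameterError("inconsistent individual counts")

    @property
    def N(self) -> int:
        return self.hapA.shape[1]

    def copy(self) -> "DiploidPopulation":
        return DiploidPopulation(
            self.hapA.copy(),
            self.hapR.copy(),
            self.L_A,
            self.L_R,
            self.selfing_age.copy(),
            self.generation,
        )

    @classmethod
    def from_haplotypes(
        cls,
        bitsA: np.ndarray,
        bitsR: np.ndarray,
        selfing_age: np.ndarray | None = None,
    ) -> "DiploidPopulation":
        """Build from unpacked (2, N, L) binary arrays."""
        bitsA = np.asarray(bitsA, dtype=np.uint8)
        bitsR = np.asarray(bitsR, dtype=np.uint8)
        N = bitsA.shape[1]
        age = (
            np.zeros(N, dtype=np.int64)
            if selfing_age is None
            else np.asarray(selfing_age, dtype=np.int64)
        )
        return cls(
            pack_bits(bitsA), pack_bits(bitsR), bitsA.shape[2], bitsR.shape[2], age
        )

    def haplotype_bits(self) -> tuple[np.ndarray, np.ndarray]:
        """Unpacked (2, N, L) binary haplotype arrays (additive, recessive)."""
        return unpack_bits(self.hapA, self.L_A), unpack_bits(self.hapR, self.L_R)

    def genotypes(self) -> tuple[np.ndarray, np.ndarray]:
        """(N, L) per-locus counts of "1" alleles for each block."""
        bA, bR = self.haplotype_bits()
        return bA[0] + bA[1], bR[0] + bR[1]

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-individual (n1 additive alleles, het additive loci,
        homozygous recessive loci, heterozygous recessive loci)."""
        homA = np.bitwise_count(self.hapA[0] & self.hapA[1]).sum(axis=1)
        hetA = np.bitwise_count(self.hapA[0] ^ self.hapA[1]).sum(axis=1)
        homR = np.bitwise_count(self.hapR[0] & self.hapR[1]).sum(axis=1)
        hetR = np.bitwise_count(self.hapR[0] ^ self.hapR[1]).sum(axis=1)
        return 2 * homA + hetA, hetA, homR, hetR

    def trait_values(self, arch: ArchitectureParams) -> np.ndarray:
        n1 = self.counts()[0]
        return arch.alpha * (n1.astype(float) - arch.L_A)

    def fitnesses(
        self, arch: ArchitectureParams, regime: SelectionRegime
    ) -> np.ndarray:
        """Vector of absolute fitness W in (0, 1] for every individual."""
        n1, _, n11, n01 = self.counts()
        if regime.habitat == "source":
            g_add = regime.s_tilde * n1
        else:
            g_add = regime.s_tilde * (2 * self.L_A - n1)
        return np.exp(-(g_add + arch.s * (n11 + arch.h * n01)))

    def mutate(self, arch: ArchitectureParams, rng: np.random.Generator) -> None:
        """Symmetric allele flips at mu_A / mu_R per locus (in place)."""
        _flip_sites(self.hapA, self.L_A, arch.mu_A, rng)
        _flip_sites(self.hapR, self.L_R, arch.mu_R, rng)

    def reproduce(
        self,
        n_offspring: int,
        weights: np.ndarray,
        r_s: float,
        rng: np.random.Generator,
    ) -> "DiploidPopulation":
        """Produce offspring by fitness-weighted parent sampling.

        Each offspring selfs with probability ``r_s``; outcross partners are
        drawn independently with replacement and may coincide with the first
        parent (so the realized selfing fraction exceeds ``r_s`` at small N).
        """
        if not 0.0 <= r_s <= 1.0:
            raise ParameterError(f"r_s={r_s} outside [0, 1]")
        total = weights.sum()
        if not total > 0:
            raise PopulationCollapseError("total fitness is zero")
        cum = np.cumsum(weights)
        cum /= cum[-1]

        def draw(k: int) -> np.ndarray:
            return np.searchsorted(cum, rng.random(k), side="right")

        p1 = draw(n_offspring)
        selfed = rng.random(n_offspring) < r_s
        p2 = np.where(selfed, p1, draw(n_offspring))
        hapA = np.stack([_gametes(self.hapA, p1, rng), _gametes(self.hapA, p2, rng)])
        hapR = np.stack([_gametes(self.hapR, p1, rng), _gametes(self.hapR, p2, rng)])
        age = np.where(selfed, self.selfing_age[p1] + 1, 0)
        return DiploidPopulation(
            hapA, hapR, self.L_A, self.L_R, age, self.generation + 1
        )


def initialize_population(
    N: int,
    arch: ArchitectureParams,
    rng: np.random.Generator,
    p_init: float = 0.0,
) -> DiploidPopulation:
    """Independent Bernoulli(p_init) alleles at every locus of N individuals.

    The default monomorphic-"0" start is a free choice (the stationary state
    is initialization-independent); override ``p_init`` to start elsewhere.
    """
    if N < 1:
        raise ParameterError("N must be >= 1")

    def block(L: int) -> np.ndarray:
        bits = (rng.random((2, N, L)) < p_init).astype(np.uint8)
        return pack_bits(bits)

    return DiploidPopulation(
        block(arch.L_A), block(arch.L_R), arch.L_A, arch.L_R, np.zeros(N, np.int64)
    )


def generation_step(
    pop: DiploidPopulation,
    arch: ArchitectureParams,
    regime: SelectionRegime,
    r_s: float,
    rng: np.random.Generator,
    mutate_in_place: bool = False,
) -> DiploidPopulation:
    """One life cycle: mutation, selection (as sampling weights), reproduction.

    Returns a new population of the same size N.  Unless ``mutate_in_place``
    the input population is left untouched (the in-place path avoids a copy
    in long stationary runs).
    """
    parent = pop if mutate_in_place else pop.copy()
    parent.mutate(arch, rng)
    W = parent.fitnesses(arch, regime)
    return parent.reproduce(pop.N, W, r_s, rng)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """Census-time summaries of a simulated population.

    Identity disequilibrium (ID) and gametic LD are averaged over a seeded
    random subsample of locus pairs; monomorphic pairs are excluded and
    counted in ``excluded_pairs``.
    """

    p_A: float
    p_R: float
    het_A: float
    het_R: float
    wbar: float
    delta: float
    id_AA: float
    id_RR: float
    id_AR: float
    ld_r: float
    mean_load: float
    excluded_pairs: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _pair_indices(
    rng: np.random.Generator, L1: int, L2: int, k: int, cross: bool
) -> tuple[np.ndarray, np.ndarray]:
    if cross:
        return rng.integers(0, L1, k), rng.integers(0, L2, k)
    jj = rng.integers(0, L1, k)
    kk = rng.integers(0, L1 - 1, k)
    kk += kk >= jj  # distinct within-type pairs
    return jj, kk


def _id_over_pairs(
    X1: np.ndarray,
    X2: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    jj: np.ndarray,
    kk: np.ndarray,
) -> tuple[float, int]:
    """Mean over pairs of cov(X_j, X_k) / [p_j(1-p_j) p_k(1-p_k)]."""
    norm = p1[jj] * (1 - p1[jj]) * p2[kk] * (1 - p2[kk])
    ok = norm > 0
    if not ok.any():
        return math.nan, int(jj.size)
    a, b = X1[:, jj[ok]], X2[:, kk[ok]]
    cov = (a * b).mean(axis=0) - a.mean(axis=0) * b.mean(axis=0)
    return float(np.mean(cov / norm[ok])), int(jj.size - ok.sum())


def estimate_statistics(
    pop: DiploidPopulation,
    arch: ArchitectureParams,
    regime: SelectionRegime,
    pair_subsample: int = 2000,
    rng: np.random.Generator | None = None,
) -> SummaryStats:
    """All census statistics of one population snapshot.

    delta uses the offspring generation's realized selfing labels: selfed
    individuals are those with selfing_age >= 1 at the census.  NaN when one
    of the classes is empty.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    genoA, genoR = pop.genotypes()
    N = pop.N
    W = pop.fitnesses(arch, regime)
    wbar = float(W.mean())

    selfed = pop.selfing_age >= 1
    if 0 < selfed.sum() < N:
        delta = 1.0 - float(W[selfed].mean()) / float(W[~selfed].mean())
    else:
        delta = math.nan

    out: dict[str, float] = {}
    excluded = 0
    freqA = genoA.mean(axis=0) / 2.0 if pop.L_A else np.empty(0)
    freqR = genoR.mean(axis=0) / 2.0 if pop.L_R else np.empty(0)
    XA = (genoA == 2).astype(np.float64)
    XR = (genoR == 2).astype(np.float64)
    specs = {
        "id_AA": (XA, XA, freqA, freqA, False),
        "id_RR": (XR, XR, freqR, freqR, False),
        "id_AR": (XA, XR, freqA, freqR, True),
    }
    for name, (X1, X2, q1, q2, cross) in specs.items():
        if X1.shape[1] < 2 or X2.shape[1] < (1 if cross else 2):
            out[name] = math.nan
            continue
        jj, kk = _pair_indices(rng, X1.shape[1], X2.shape[1], pair_subsample, cross)
        out[name], nex = _id_over_pairs(X1, X2, q1, q2, jj, kk)
        excluded += nex

    # gametic LD: correlation of allelic states over the 2N haplotypes,
    # averaged over a pair subsample spanning both blocks
    bitsA, bitsR = pop.haplotype_bits()
    H = np.concatenate(
        [bitsA.reshape(2 * N, pop.L_A), bitsR.reshape(2 * N, pop.L_R)], axis=1
    ).astype(np.float64)
    L = H.shape[1]
    if L >= 2:
        jj, kk = _pair_indices(rng, L, L, pair_subsample, False)
        hp = H.mean(axis=0)
        v = hp * (1 - hp)
        ok = (v[jj] > 0) & (v[kk] > 0)
        if ok.any():
            a, b = H[:, jj[ok]], H[:, kk[ok]]
            cov = (a * b).mean(axis=0) - a.mean(axis=0) * b.mean(axis=0)
            ld = float(np.mean(cov / np.sqrt(v[jj[ok]] * v[kk[ok]])))
        else:
            ld = math.nan
        excluded += int(jj.size - ok.sum())
    else:
        ld = math.nan

    return SummaryStats(
        p_A=float(freqA.mean()) if pop.L_A else math.nan,
        p_R=float(freqR.mean()) if pop.L_R else math.nan,
        het_A=float((genoA == 1).mean()) if pop.L_A else math.nan,
        het_R=float((genoR == 1).mean()) if pop.L_R else math.nan,
        wbar=wbar,
        delta=delta,
        id_AA=out["id_AA"],
        id_RR=out["id_RR"],
        id_AR=out["id_AR"],
        ld_r=ld,
        mean_load=float(-np.log(W).mean()),
        excluded_pairs=excluded,
    )


@dataclass
class StationaryResult:
    """Stationary averages with between-sample standard errors."""

    mean: pd.Series
    se: pd.Series
    samples: pd.DataFrame
    final_population: DiploidPopulation

    def halves_agree(self, n_se: float = 4.0, fields=("p_R", "p_A", "wbar")) -> bool:
        """Stationarity diagnostic: first- and second-half sample means of the
        listed fields agree within n_se combined standard errors."""
        n = len(self.samples)
        a, b = self.samples.iloc[: n // 2], self.samples.iloc[n // 2 :]
        for f in fields:
            if self.samples[f].isna().all():
                continue
            se = math.sqrt(a[f].var() / len(a) + b[f].var() / len(b))
            if se > 0 and abs(a[f].mean() - b[f].mean()) > n_se * se:
                return False
        return True


def run_to_stationarity(
    pop: DiploidPopulation,
    arch: ArchitectureParams,
    regime: SelectionRegime,
    r_s: float,
    rng: np.random.Generator,
    burn_in: int = 5000,
    n_samples: int = 20,
    thin: int = 25,
    pair_subsample: int = 2000,
) -> StationaryResult:
    """Evolve through burn-in, then record summaries every ``thin``
    generations ``n_samples`` times; return averages with between-sample SE."""
    if burn_in < 0 or thin < 1 or n_samples < 1:
        raise ParameterError("burn_in >= 0, thin >= 1, n_samples >= 1 required")
    pop = pop.copy()
    for _ in range(burn_in):
        pop = generation_step(pop, arch, regime, r_s, rng, mutate_in_place=True)
    rows = []
    for k in range(n_samples):
        if k > 0:
            for _ in range(thin):
                pop = generation_step(
                    pop, arch, regime, r_s, rng, mutate_in_place=True
                )
        stats = estimate_statistics(pop, arch, regime, pair_subsample, rng)
        rows.append(stats.as_dict())
    df = pd.DataFrame(rows)
    mean = df.mean()
    se = df.std(ddof=1) / math.sqrt(len(df)) if len(df) > 1 else df.std(ddof=0)
    return StationaryResult(mean=mean, se=se, samples=df, final_population=pop)
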