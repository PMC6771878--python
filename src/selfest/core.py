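"""Shared parameter types and fitness functions.

The model world: a diploid, partially selfing population whose genome carries
two kinds of unlinked biallelic loci.

* ``L_A`` *additive* loci: the two alleles contribute -alpha/2 or +alpha/2 to a
  quantitative trait ``z`` under directional selection.  Allele "1" is the
  trait-increasing allele; it is disfavoured in the source habitat and favoured
  on the island (the direction of selection on the trait is reversed there).
* ``L_R`` *recessive* loci: allele "1" is unconditionally deleterious with
  selective disadvantage ``s`` when homozygous and dominance coefficient
  ``h`` (< 1/2) when heterozygous.

Fitness is multiplicative across loci::

    source:  W = exp[-beta0 (z - z_min) - s * sum_i (X_i + h Y_i)]
    island:  W = exp[-beta1 (z_max - z) - s * sum_i (X_i + h Y_i)]

where X_i / Y_i indicate a recessive homozygote / heterozygote at locus i, and
z ranges over [z_min, z_max] = [-alpha L_A, +alpha L_A] with alpha = 1/L_A.
The per-allele selection strengths are s0_tilde = beta0 * alpha in the source
and s1_tilde = beta1 * alpha on the island.  Genetic load is G = -ln W.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np


class ParameterError(ValueError):
    """Invalid or inconsistent model parameters."""


@dataclass(frozen=True)
class ArchitectureParams:
    """Genome layout and per-locus selection/mutation/dominance constants.

    Parameters
    ----------
    L_A, L_R
        Numbers of additive and recessive loci (either may be 0).
    mu_A, mu_R
        Per-locus, per-generation symmetric allele flip probabilities.
    s
        Homozygous selective disadvantage at recessive loci.
    h
        Dominance coefficient of the recessive allele, 0 <= h < 1/2.
    s0_tilde
        Per-allele selection strength against the "1" allele at additive loci
        in the source habitat (= beta_0 * alpha).
    """

    L_A: int
    L_R: int
    mu_A: float = 0.0
    mu_R: float = 0.0
    s: float = 0.0
    h: float = 0.0
    s0_tilde: float = 0.0

    def __post_init__(self) -> None:
        if self.L_A < 0 or self.L_R < 0:
            raise ParameterError("locus counts must be nonnegative")
        for name in ("mu_A", "mu_R"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ParameterError(f"{name}={v} outside [0, 0.5]")
        if self.s < 0:
            raise ParameterError("s must be nonnegative")
        if not 0.0 <= self.h < 0.5:
            raise ParameterError("h must satisfy 0 <= h < 1/2")
        if self.s0_tilde < 0:
            raise ParameterError("s0_tilde must be nonnegative")

    # ---- derived quantities -------------------------------------------------

    @property
    def L(self) -> int:
        return self.L_A + self.L_R

    @property
    def alpha(self) -> float:
        """Per-allele trait effect magnitude, fixed to 1/L_A (0 if L_A=0)."""
        return 1.0 / self.L_A if self.L_A > 0 else 0.0

    @property
    def beta_0(self) -> float:
        """Directional selection gradient in the source (= s0_tilde / alpha)."""
        return self.s0_tilde * self.L_A

    @property
    def z_min(self) -> float:
        return -self.alpha * self.L_A if self.L_A > 0 else 0.0

    @property
    def z_max(self) -> float:
        return self.alpha * self.L_A if self.L_A > 0 else 0.0

    @property
    def U_A(self) -> float:
        """Genome-wide mutation rate at additive loci (2 mu_A L_A)."""
        return 2.0 * self.mu_A * self.L_A

    @property
    def U_R(self) -> float:
        """Genome-wide mutation rate at recessive loci (2 mu_R L_R)."""
        return 2.0 * self.mu_R * self.L_R


@dataclass(frozen=True)
class SelectionRegime:
    """Habitat-specific direction and strength of selection on the trait.

    The source habitat penalizes trait excess above z_min with per-allele
    strength ``s_tilde``; the island penalizes the shortfall below z_max.
    Recessive loci are selected identically in both habitats.
    """

    habitat: Literal["source", "island"]
    s_tilde: float = 0.0

    def __post_init__(self) -> None:
        if self.habitat not in ("source", "island"):
            raise ParameterError(f"unknown habitat {self.habitat!r}")
        if self.s_tilde < 0:
            raise ParameterError("s_tilde must be nonnegative")

    @classmethod
    def source(cls, s0_tilde: float) -> "SelectionRegime":
        return cls("source", s0_tilde)

    @classmethod
    def island(cls, s1_tilde: float) -> "SelectionRegime":
        return cls("island", s1_tilde)

    def additive_weights(self) -> np.ndarray:
        """Relative fitness of additive genotypes by count of "1" alleles.

        Source: (1, e^-s~, e^-2s~) for (00, 01, 11); island is the mirror
        image, since the "1" allele is favoured there.
        """
        g = np.arange(3)
        if self.habitat == "source":
            return np.exp(-self.s_tilde * g)
        return np.exp(-self.s_tilde * (2 - g))

    def additive_exponent_atoms(self) -> np.ndarray:
        """Per-locus contribution to load G by count of "1" alleles."""
        g = np.arange(3)
        if self.habitat == "source":
            return self.s_tilde * g
        return self.s_tilde * (2.0 - g)


def recessive_weights(arch: ArchitectureParams) -> np.ndarray:
    """Relative fitness (1, e^{-hs}, e^{-s}) of recessive-locus genotypes."""
    return np.exp(-arch.s * np.array([0.0, arch.h, 1.0]))


def recessive_exponent_atoms(arch: ArchitectureParams) -> np.ndarray:
    """Per-locus load contribution (0, hs, s) of recessive-locus genotypes."""
    return arch.s * np.array([0.0, arch.h, 1.0])


@dataclass
class DiploidGenome:
    """Two phased haplotypes over L_A + L_R loci (additive block first).

    Allele "1" is the allele disfavoured in the source at both locus types.
    ``selfing_age`` counts consecutive generations of selfing back to the most
    recent outcrossed ancestor; None when unknown (simulation-bred after the
    founding generation does not track it through outcrossing pedigrees).
    """

    hap0: np.ndarray
    hap1: np.ndarray
    selfing_age: int | None = None

    def __post_init__(self) -> None:
        self.hap0 = np.asarray(self.hap0, dtype=np.uint8)
        self.hap1 = np.asarray(self.hap1, dtype=np.uint8)
        if self.hap0.shape != self.hap1.shape or self.hap0.ndim != 1:
            raise ParameterError("haplotypes must be 1-D vectors of equal length")
        if np.any(self.hap0 > 1) or np.any(self.hap1 > 1):
            raise ParameterError("haplotypes must be binary")

    def genotype(self) -> np.ndarray:
        """Per-locus count of "1" alleles (0, 1 or 2)."""
        return self.hap0 + self.hap1


def _check_length(genome: DiploidGenome, arch: ArchitectureParams) -> None:
    if genome.hap0.size != arch.L:
        raise ParameterError(
            f"genome length {genome.hap0.size} does not match architecture L={arch.L}"
        )


def trait_value(genome: DiploidGenome, arch: ArchitectureParams) -> float:
    """Additive trait z = sum of allelic contributions +/- alpha/2.

    Equivalently z = alpha * (n1 - L_A) where n1 counts "1" alleles over the
    additive block.  Recessive loci do not contribute.
    """
    _check_length(genome, arch)
    if arch.L_A == 0:
        return 0.0
    n1 = int(genome.genotype()[: arch.L_A].sum())
    return arch.alpha * (n1 - arch.L_A)


def fitness(
    genome: DiploidGenome, arch: ArchitectureParams, regime: SelectionRegime
) -> float:
    """Multiplicative fitness of a single genome in the given habitat."""
    return float(np.exp(-genetic_load(genome, arch, regime)))


def genetic_load(
    genome: DiploidGenome, arch: ArchitectureParams, regime: SelectionRegime
) -> float:
    """Load G = -ln W; sum of the trait-maladaptation and recessive parts."""
    return genetic_load_components(genome, arch, regime).sum()


def genetic_load_components(
    genome: DiploidGenome, arch: ArchitectureParams, regime: SelectionRegime
) -> np.ndarray:
    """(additive-trait load, recessive load) for one genome."""
    _check_length(genome, arch)
    geno = genome.genotype()
    if arch.L_A > 0:
        n1 = int(geno[: arch.L_A].sum())
        if regime.habitat == "source":
            g_add = regime.s_tilde * n1
        else:
            g_add = regime.s_tilde * (2 * arch.L_A - n1)
    else:
        g_add = 0.0
    gR = geno[arch.L_A :]
    n11 = int(np.count_nonzero(gR == 2))
    n01 = int(np.count_nonzero(gR == 1))
    g_rec = arch.s * (n11 + arch.h * n01)
    return np.array([g_add, g_rec])
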