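# Methods

`selfest` models a large, partially selfing, hermaphroditic diploid
population at mutation–selection balance and asks how the genetic composition
of such a population shapes the probability that a handful of emigrant
founders establish a colony in a new habitat under hard selection.

## The model

Each genome carries two kinds of unlinked biallelic loci.

* **Additive loci** (`L_A` of them). The two alleles contribute −α/2 and
  +α/2 to a quantitative trait z, with α = 1/L_A, so z ∈ [−1, 1]. The trait
  is under directional selection: in the source habitat fitness contains a
  factor exp[−β₀(z − z_min)], in the new habitat exp[−β₁(z_max − z)] — the
  direction of selection is reversed. The per-allele selection strengths are
  s̃₀ = β₀α and s̃₁ = β₁α; per-locus genotype weights are (1, e^{−s̃}, e^{−2s̃})
  with the order reversed between habitats.
* **Recessive loci** (`L_R`). Allele "1" is unconditionally deleterious in
  both habitats, with genotype weights (1, e^{−hs}, e^{−s}), 0 ≤ h < 1/2.

Fitness is multiplicative across loci (no epistasis, no linkage). Every
locus flips its allelic state symmetrically with probability μ per
generation. The per-generation life cycle is mutation → selection →
reproduction, where a fraction r_s of offspring are produced by selfing and
the rest by outcrossing with fitness-weighted parents.

## The selfing-age cohort (ILEC) recursion

Partial selfing generates identity disequilibrium (ID): individuals differ
in how many consecutive generations of selfing their lineage has just
experienced, hence in genome-wide homozygosity, which correlates
homozygosity across loci. The deterministic solver exploits exactly this
structure. The population is described by cohorts of *selfing age* i (number
of generations since the last outcrossing event in the lineage): masses f_i
and, per cohort, genotype frequencies (p00, p01, p11) of one exchangeable
locus of each type. The defining approximation is that loci are
statistically independent *within* a cohort (identity and linkage
equilibrium within cohorts); all population-level disequilibria then arise
from between-cohort differences.

Under that assumption each step factorizes per locus:

* mutation: genotype frequencies are premultiplied by the two-independent-
  flips transition matrix;
* selection: (p00, p01, p11) → (p00 w00, p01 w01, p11 w11)/ν, and the cohort
  mean fitness is the product of per-locus normalizers,
  ln w̄_i = L_A ln ν_A(i) + L_R ln ν_R(i) (accumulated in log space — at
  L = 5000 the product underflows otherwise);
* reproduction: parents are weighted g_i ∝ f_i w̄_i. Outcrossed offspring
  (mass 1 − r_s) form cohort 0 at Hardy–Weinberg proportions of the pooled
  gamete frequency q = Σ g_i (p11 + p01/2); selfed offspring of cohort i
  form cohort i+1 with p11 → p11 + p01/4, p01 → p01/2.

Ages accumulate in an absorbing class at `I_max` (default 50; the mass
beyond it is ≤ r_s^50, far below the convergence tolerance for r_s ≤ 0.95),
pooled by g-weighted averaging. Iteration stops when the sup-norm
census-to-census change falls below `tol` (default 1e−12, cap 1e6
iterations); non-convergence raises an error carrying the last state rather
than returning silently. The solver starts monomorphic for the favoured
allele with geometric cohort masses. The fixed point is
initialization-independent; note that two runs converged to step-size `tol`
can still sit ~`tol`/(1−λ) apart along the slowest mode (λ the contraction
factor), so the initialization-independence test compares states at 1e−7,
not at 10·`tol`.

Derived statistics:

* ID between two same-type loci is the between-cohort variance of p11
  divided by p²(1−p)². For an additive–recessive pair there is no single
  standard normalization; we use the natural generalization
  cov_f(p11_A, p11_R) / [p_A(1−p_A) p_R(1−p_R)].
* Inbreeding depression δ = 1 − W̄_self/W̄_oc, where "selfed" is every census
  cohort with age ≥ 1 weighted by census masses and "outcrossed" is
  cohort 0. δ is NaN (not 0) at r_s ∈ {0, 1} where one class is empty.
* The neutral ID reference iterates the exact one- and two-locus
  identity-by-descent recursions for unlinked loci under partial selfing,
  F′ = r_s(1 + F)/2 and φ′ = r_s(1 + 2F + φ)/4, and returns φ − F², which
  equals the normalized homozygosity covariance. The selection-free cohort
  recursion reproduces this value — a useful dual-route consistency check.
* The load distribution G = −ln W is, per cohort, the distribution of a sum
  of L iid three-atom variables (atoms (0, hs, s) and (0, s̃, 2s̃)); when the
  atoms are commensurate on a common grid the exact pmf is computed by an
  FFT power (one transform per cohort and type), otherwise by Monte-Carlo
  multinomial sampling (1e6 draws). A caveat discovered while testing: the
  mixture mean of G equals Σ_i f_i Σ_types L (expected per-locus exponent),
  *not* −Σ f_i ln w̄_i — per-cohort E[−ln W] ≠ −ln E[W] (Jensen). The moment
  test asserts the correct identity.

## The individual-based simulator

The stochastic counterpart keeps N diploid genomes with phased haplotypes,
bit-packed into uint64 words. Mutation draws a Binomial(2NL, μ) number of
flipped sites and XORs a uniform distinct subset; gametes are formed with
random 64-bit crossover masks (free recombination); homozygote/heterozygote
counts use popcounts. This runs thousands of generations at N of a few
thousand in seconds, which is what makes the reduced-scale solver-vs-
simulation validation affordable inside a test suite. Selfing ages are
assigned at birth, so the simulator's δ uses the realized selfed/outcrossed
labels of the census generation, matching the solver's convention.

ID/LD estimators average over a seeded random subsample of ≤ 2000 locus
pairs; the per-pair statistic is cov(X_j, X_k)/[p_j(1−p_j)p_k(1−p_k)] with X
the "11"-homozygote indicator; monomorphic pairs are excluded and counted.
LD is the gametic correlation r over the 2N phased haplotypes (phase is
known in the simulation, so no composite measure is needed).

Defaults: burn-in 5000 generations ("a few thousand" suffices at the rates
used here; the slowest mode relaxes at ~hs per generation), then 20 samples
25 generations apart. Initial genotypes are monomorphic favourable —
equilibrium is initialization-independent, verified by test.

## Founders and establishment

Founders are drawn from the converged cohort state: a selfing age with
probability f_i, then independent per-locus genotypes from that cohort
(heterozygote phase randomized). Island demography is hard selection in
Ricker form: N_{t+1} ~ Poisson(N_t · exp[r₀(1 − N_t/K)] · W̄_t), the form
under which the per-capita growth criterion is e^{r₀}W̄ ≷ 1 and K acts as a
carrying capacity. Parents are sampled
with replacement proportionally to fitness; the outcross partner may
coincide with the first parent, so realized selfing exceeds r_s in small
populations (a lone survivor necessarily selfs). Establishment succeeds
when N_T ≥ K/10 exactly at the horizon T = 100; extinction short-circuits.

The branching-process check treats each founder as an independent Poisson
line with offspring mean m_k = e^{r₀} W_k; line-extinction probabilities
solve q = exp[m(q − 1)] by fixed-point iteration and
P_est = 1 − Π_k q_k. It is accurate for clearly supercritical founders and
large K, and is used as an oracle against the full simulation, never as its
replacement.

The viability pre-check runs the same machinery with source-habitat fitness
and effectively infinite K and asks whether 100 individuals double within
100 generations in > 95% of replicates.

## Parameter choices where the source is silent

* Figure-level establishment scans fix r₀ = 1.1, K = 1000, N₀ = 10, T = 100
  and 1000 replicates (reduced to 300 in the test suite, which roughly
  triples the binomial SE — the qualitative shape assertions use explicit
  SE margins).
* For the recessive-only establishment shapes, the dominance/selection
  pairs are (s = 0.05, h = 0.02) for the "weakly selected, nearly
  recessive" regime with U_R/hs = 800 and (s = 0.02, h = 0.15) for the
  "moderately recessive" regime; at (s = 0.02, h = 0.02) the inbreeding
  load at low selfing is so large that no colony ever establishes, which
  masks the interior minimum.
* "Intermediate" island selection for the additive-only decline means
  2s̃₁L_A comparable to r₀; the scan uses 2s̃₁L_A = 1.1 with r₀ = 1.1.

## What the tests do and do not establish

The generator *is* the model: synthetic populations obey exactly the stated
life cycle, so green tests establish internal consistency (solver vs
independent simulator, simulator vs branching process and identity-
coefficient theory) and reproduction of the qualitative regime structure.
They do not establish anything about real populations — no linkage, no
epistasis, no distribution of effect sizes, equal effects within a locus
type, one-shot migration only.

Known limitations, all visible in the validation output:

* The cohort approximation neglects within-cohort associations; it slightly
  overestimates deleterious allele frequencies and δ in the nearly recessive
  interference regime (U_R/hs ≫ 1) at low r_s.
* The deterministic solver ignores drift. Finite simulated populations
  purge somewhat more than it predicts; the bias shrinks visibly from
  N = 2000 to N = 10,000 in the checks we run.
* Selfing fractions very close to 1 are outside the supported regime
  (strong Hill–Robertson interference; the solver's assumptions fail there).
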