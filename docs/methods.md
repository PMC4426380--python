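# Methods

## Model

`matsel` iterates a deterministic single-locus model of *maternal selection*:
the viability of an individual depends jointly on its own genotype and its
mother's genotype.  For `n` alleles A_1...A_n every compatible offspring-mother
combination (the mother must carry at least one of the offspring's alleles)
has a relative fitness w_ijkl in [0, 1].  Counting combinations gives

    C(n) = n^2 + n(n-1)(2n-1)/2

distinct parameters (1, 7, 24, 58, 115 for n = 1..5): each of the n
homozygotes has n possible mothers; each of the n(n-1)/2 heterozygotes A_iA_j
has two homozygous mothers, one identical heterozygous mother and 2(n-2)
non-identical heterozygous mothers.  These five structural classes
(C_iiii, C_iiij, C_ijii, C_ijij, C_ijik) partition the parameters.

The population is effectively infinite, randomly mating and dioecious, but a
single genotype-frequency matrix x_ij suffices (no sex-specific frequencies
are tracked: the recursion uses one x).  With allele frequencies
p_i = x_ii + (1/2)Σ_{j≠i} x_ij, the next generation is

    wbar x'_ii = p_i ( w_iiii x_ii + (1/2) Σ_{k≠i} w_iiik x_ik )
    wbar x'_ij = p_i ( w_ijjj x_jj + (1/2) Σ_{k≠j} w_ijjk x_jk )
             + p_j ( w_ijii x_ii + (1/2) Σ_{k≠i} w_ijik x_ik ),  i ≠ j,

with wbar (the population mean fitness) the sum of all right-hand sides.
Internally the update is expressed through a maternal-transmission tensor
V[i,j,k] = w({i,j},{j,k}) and the matrix T[j,k] = (probability a random
mother has genotype {j,k} *and* transmits allele j), giving
M = Σ_k V[i,j,k] T[j,k] and unnormalized frequencies A_ij = p_i M_ij; this
formulation turns one generation into a batched matrix-vector product, so
tens of thousands of independent populations advance per numpy call.
Correctness of the algebra is checked in the test suite against a brute-force
mating-table enumeration (mother genotype x transmitted allele x paternal
allele) to 1e-12, and two reductions are verified: all-equal fitnesses give
Hardy-Weinberg proportions in one generation with stationary allele
frequencies, and mother-independent fitnesses reproduce classical constant-
viability selection (including the overdominant fixed point
p̂ = (v12-v22)/(2 v12 - v11 - v22)).

Numerical guards: the genotype frequencies are renormalized when rounding
drift exceeds 1e-12 and an error is raised beyond 1e-8 (drift that large
indicates a logic bug, not rounding).  A state in which the unnormalized
update has wbar = 0 (possible only if every surviving combination has zero
fitness) raises a `DegenerateStateError`; the model's behaviour there is
undefined and we prefer an error to a guess.

## Random inputs

Fitness sets draw one independent U[0,1] value per canonical combination, in
a fixed enumeration order (offspring lexicographic, then mother), so a seeded
draw is reproducible.  U[0,1] is not a claim about natural fitnesses; it
makes parameter space a C(n)-dimensional unit cube that can be sampled
uniformly.  Initial allele frequencies use the broken-stick construction:
spacings of n-1 independent U[0,1] points on the unit interval, i.e. the
uniform (flat Dirichlet) distribution on the simplex.  We use *unranked*
spacings; a ranked variant would change nothing in retention statistics
(the model is exchangeable in allele labels) but would shift the broken-stick
baseline distribution of the evenness statistic slightly.  Genotype
frequencies are Hardy-Weinberg expansions of these allele frequencies.

All randomness derives from numpy's PCG64 seeded by SeedSequence with a
per-replicate spawn key, so replicate r of any experiment is a pure function
of (seed, r).  The generator's name is recorded in all output metadata.

## Parameter-space protocol

For fixed n, `estimate_potential` draws `n_sets` random fitness sets and
iterates each from `n_starts` random initial conditions.  A run *retains* its
n alleles if no allele frequency falls below the loss threshold (default
1e-5, the same threshold the constructionist protocol uses for extinction)
before the run terminates.  Termination rules — the original study does not
state its stopping rule, so these substitutes are explicit, configurable and
echoed in output metadata:

- convergence: max-norm allele-frequency change < 1e-9 for 100 consecutive
  generations (conservative: doubling the 1e4-generation horizon changes the
  n=2 classification counts by under 0.3%);
- horizon: 10,000 generations; a run unconverged at the horizon with all
  alleles above threshold counts as retaining them (this includes cycling);
- cycling: an unconverged run is iterated 1000 further generations and
  flagged cycling if its final allele-frequency vector recurs within 1e-6
  (max-norm, lag >= 2) in that window *and* the window's per-coordinate
  amplitude exceeds 1e-4.  The amplitude floor separates genuine cycles from
  slow monotone transients whose successive states trivially "recur".
  Cycling is reported per fitness set; non-converged non-cycling runs are
  counted separately in the summary.

A fitness set is "always" if every start retained all n alleles, "never" if
none did, "sometimes" otherwise; the potential for polymorphism is the pooled
proportion of retaining runs and decomposes exactly as
P(always) + P(sometimes) x retention-among-sometimes.  Because runs sharing a
fitness set are correlated, the summary attaches a cluster (between-set)
standard error to the potential — at n=2 it is roughly four times the naive
pooled-binomial standard error — and set-level binomial standard errors to
the category proportions.

Retirement on first allele loss is an optimization, not a semantic choice:
an experiment comparing retire-on-loss against evaluating retention only at
termination found 1 differing run in 60,000 (transient dips below 1e-5 that
later recover are essentially absent), and the distribution of the final
minimum allele frequency is sharply bimodal (below 1e-9 or above 1e-4), so
the exact threshold value is immaterial over several orders of magnitude.

Default problem sizes in the acceptance runs are 1e4 sets x 20 starts for
n = 2 and 3 and 2e4 sets x 20 starts for n = 4 (the n=4 potential is rare, so
more sets control its binomial error); the reference study used 1e5 sets x
100 starts.  The pooled potential is an unbiased estimator at any number of
starts; the always/sometimes *classification* is start-count dependent
(fewer starts inflate "always": a set with retention fraction f is
misclassified with probability f^20 versus f^100).

## Constructionist protocol

Each replicate starts monomorphic with w_1111 = 0.5.  Every generation, in
this order: (1) a new mutant allele enters at frequency 1e-5, the fitness set
gaining 3n^2 + 2n + 1 fresh U[0,1] entries (existing entries are untouched);
(2) one generation of selection; (3) every allele strictly below 1e-5 is
removed, iterating the sweep because a removal can drag a second allele's
frequency below threshold; (4) allele count and (post-selection) mean fitness
are recorded.  The study does not state the within-generation order; this
choice is declared in output metadata.  One mutant enters every generation
even while the previous one still segregates, per the protocol's literal
description.  Runs always go the full horizon (default 1e4 generations).

Mutant bookkeeping: the donor allele d is chosen uniformly among alleles with
p_d strictly above the mutant frequency δ (an allele at or below δ cannot
donate without going negative).  The mutation converts a fraction u = δ/p_d
of the donor's copies: x_dk -> (1-u) x_dk with u x_dk moved to the
{k, mutant} heterozygote, and x_dd splitting into (1-u)^2 / 2u(1-u) / u^2.
This is the unique genotype-level apportionment that gives the mutant exactly
δ, takes exactly δ from the donor, and leaves every other allele frequency
unchanged to the last bit; the mutant lands (up to a negligible u^2 homozygote
term) in heterozygotes whose partner alleles follow the donor's genotype
composition, i.e. approximately the resident allele frequencies under
Hardy-Weinberg.  Because introduction is *at* the threshold and extinction is
*strictly below* it, a fresh mutant is never pruned in its introduction
generation: it must survive one round of selection.

## Summaries

Evenness uses I = Σ(p_i - 1/n)^2, the squared distance from the simplex
centroid (0 for equal frequencies, 1 - 1/n at a vertex).  Class means average
the fitness entries within each of the five combination classes; classes that
do not exist at small n (all but C_iiii at n=1, C_ijik at n=2) are flagged
empty rather than zero.  Constructionist reports include a broken-stick
baseline distribution of I, generated internally with the same unranked-
spacings construction used for initial conditions.

## What the synthetic inputs do and do not emulate

All inputs are synthetic by design — the study object is the model itself
under uniform random fitnesses, not data from any organism.  Passing tests
therefore demonstrate properties of the model and protocols (combinatorics,
dynamics, retention statistics), not claims about natural populations:
U[0,1] fitnesses are a measure on parameter space, the population is
infinite (no drift), mutation supplies one brand-new allele per generation
regardless of population composition, and viability is the only selection
component (no fertility, paternal or sex-specific effects).

## Known limitations and reproduction notes

- The reference study's classification counts are not exactly recoverable
  from its stated methods.  At 1e4 sets x 20 starts this implementation gives
  potential 0.358 at n=2 (reference 0.36697, within 2 cluster s.e.) but an
  always-set proportion of 0.286 versus 0.31154 — a systematic difference
  robust to every unstated protocol knob we varied (horizon 1e2..3e4,
  retention floor 1e-12..1e-4, loss semantics, convergence tolerance) while
  the same engine reproduces the exact closed-form benchmark for
  mother-independent fitnesses (potential 1/3, per-set agreement 99.95%).
  The residual difference plausibly traces to the study's legacy random
  number generator or unstated details of its code.  The corresponding
  acceptance assertion is kept at its stated tolerance and fails honestly.
- Cycling detection is a heuristic; counts of cycling sets are reported but
  are detection-rule dependent and too rare for quantitative comparison at
  desk scale.
- At 200 replicates the constructionist final-allele-number mode is a noisy
  statistic: the underlying probabilities of ending with 1 or 2 alleles are
  close, so the sample mode can flip between seeds.
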