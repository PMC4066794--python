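# Methods

## Model

`ssedrive` models a homing-based synthetic selfish element segregating at a
single autosomal locus with four allele classes: the cleavable, GFP-tagged
wild-type target site `T`; the functional drive donor `D`; the
non-functionally homed donor `DN`; and the out-of-frame end-joining product
`N`. `D`, `DN` and `N` all lack the intact GFP-tagged site and are resistant
to further cleavage; only `D` can home, and only into `T`.

Drive acts exclusively in the male `D/T` trans-heterozygote germline, where
the target chromosome is cleaved with probability `c`; a cleaved chromosome
is resolved by homologous recombination with probability `h` (yielding a
functional copy with probability `phi`, otherwise `DN`) or by end-joining
(yielding `N`). This gives the driving gamete distribution

    P(D) = 1/2 + c·h·phi/2,  P(DN) = c·h·(1−phi)/2,
    P(N) = c·(1−h)/2,        P(T) = (1−c)/2.

All other genotypes, and all females, segregate Mendelianly. Genotypes are
unordered allele pairs (no parent-of-origin effects); homed functional
copies are pooled with the original donor class, since nothing downstream
distinguishes them. Female nuclease activity, which the assay detects at a
low level for some constructs, is deliberately excluded from the population
model: transmission through females is always Mendelian. `c` is the
observed GFP-loss rate, which understates true cleavage by the invisible
fraction of perfectly repaired chromosomes (in-frame end-joining,
sister-chromatid repair); the model consumes the observable rate as-is.

### Assumptions of the population simulator

Discrete, non-overlapping generations; random mating in which each female
mates exactly one male drawn uniformly with replacement (males may sire
several broods); a fixed brood size (`eggs_per_female`, default 40); equal
survival and fertility for all genotypes; offspring sex assigned by a fair
Bernoulli draw (the sex model is otherwise unspecified in this experimental
design, and a fair coin is the simplest choice consistent with the
male/female initialisation); and a hard population cap applied as a uniform
random subsample without replacement to exactly `cap` offspring. The
experimental re-sampling tolerances around the census size (±10–20%) are not
modelled; the cap is exact. If either sex disappears, the iteration ends:
the population is flagged extinct and the trajectory repeats its terminal
record so all trajectories keep `generations + 1` rows. Not modelled:
overlapping generations, fitness costs, density dependence, mate choice,
age or spatial structure, marker co-conversion.

The deterministic recursion iterates the exact one-generation expectation of
this process over sex-structured genotype frequencies (female frequency x
male frequency mixture of per-cross offspring distributions; offspring sex
is genotype-independent, so both sexes share the offspring distribution).
It is the oracle against which the stochastic simulator is tested.

One consequence worth noting: because each sex contributes half the gene
pool, the conserved neutral expectation of an allele frequency is the
sex-averaged frequency, not the census frequency. A release of 25 `D/T`
males into 50 + 50 wild-type flies has census `D` frequency 0.10, but from
generation 1 onward the expectation is (1/6 + 0)/2 = 1/12 ≈ 0.083 — the
males are over-represented in the census (75:50) relative to their genetic
contribution. The martingale and refractory-control tests therefore compare
simulated means with the recursion's generation-1 value rather than the
census release frequency.

## Parameters

| parameter | meaning | default | notes |
|-----------|---------|---------|-------|
| `c` | cleavage rate (GFP-loss fraction), per target chromosome | — | in [0,1]; TALEN line 0.702, ZFN line 0.861 |
| `h` | homing fraction of cleaved chromosomes | — | TALEN 0.698, ZFN 0.395 |
| `phi` | functional fraction of homing events | — | TALEN 0.40, ZFN 0.75 (from F2 significance counts) |
| `eggs_per_female` | brood size per mated female | 40 | |
| `cap` | post-reproduction census ceiling | — | 100 (TALEN regime) or 400 (ZFN regime) |
| `alpha` | significance level of the F2 chi-square test | 0.05 | two-sided test; significance scored directionally |

Packaged constants `TALELAT_PARAMS`, `ZFN_AAVS1_PARAMS` and
`ZFN_AAVS1_LONG_PARAMS` carry the exact count ratios rather than the rounded
percentages (e.g. `c = 998/1422`). The long-construct `phi` is set to the
short-construct value 15/20, its own F2 assay not having been done.

## Estimation

Rates are exact count ratios: `c_hat = n_gfp_loss / n_target_total`,
`h_hat = n_homed / n_homing_assayed`, `total_homed = c_hat·h_hat`,
`nhej = c_hat·(1−h_hat)`. The homing denominator may be an explicit
molecularly-assayed subset of the GFP-loss flies (e.g. 117/296 scored by
junction PCR out of 366 GFP-negative flies); when zero, the homing estimate
is flagged undefined rather than reported as zero. Confidence intervals are
95% Wilson score intervals (statsmodels), clamped to contain the point
estimate against floating-point round-off at the boundaries. Percentages
are reported to one decimal, round-half-even, always alongside the raw
fraction.

The F2 segregation test is a df-1 goodness-of-fit chi-square against 1:1
with no continuity correction (the plain test matches the assay's sample
sizes; a correction would only make the functional-homing call more
conservative). Because the biological readout is loss of GFP, a cross
counts toward the functional-homing fraction only when the significant
deviation is a GFP deficit; a symmetric count is available via
`require_deficit=False`.

## Synthetic data

`simulate_assay_progeny` draws the fates of the target chromosomes
transmitted by one assayed male as a single multinomial over
(unmodified, homed-functional, homed-non-functional, misrepair) with
probabilities `(1−c, c·h·phi, c·h·(1−phi), c·(1−h))`, per-chromosome
independent — mass matings provide no brood structure to emulate.
`simulate_f2_crosses` draws each cross functional with probability `phi`;
functional crosses are `Binomial(n, 1 − active_gfp_loss_rate)` GFP-positive
(default GFP-positive fraction 0.138, matching the observed strongly-driven
regime) and non-functional crosses are `Binomial(n, 1/2)`.

What the generators emulate: the sampling noise of multinomial progeny
classification and binomial F2 segregation under the stated model. What
they do not: PCR dropout, scoring error, marker co-conversion, brood-level
correlation, or female drive activity. Passing parameter-recovery tests
therefore demonstrates the estimators are consistent under the model's own
assumptions, not that real assays are free of those artefacts.

## Numerical and design choices

- Gamete/offspring distributions are exact closed forms; distributions are
  validated to sum to 1 within 1e-12, state frequency maps within 1e-9.
- Stochastic reproduction is drawn hierarchically with exact distributions:
  father assignment per female genotype is multinomial over male genotype
  frequencies; offspring genotypes per mating class are multinomial over the
  cross's offspring distribution; capping is multivariate hypergeometric;
  sex assignment is binomial. This is equivalent to per-individual
  simulation but runs in time proportional to the number of genotype
  combinations, not the population size.
- Seeding: iteration `i` of a run with master seed `s` uses
  `numpy.random.default_rng([s, i])`, so results are bit-reproducible and
  independent of how many iterations are requested.
- Per-cross offspring distributions are memoised on (mother pair, father
  pair, parameters); parameters are frozen dataclasses, so the cache is
  sound.
- Degenerate inputs raise rather than guess: empty populations for frequency
  queries, zero-progeny chi-square tests, zero assay denominators, invalid
  probabilities, sexes swapped in a cross.

## Problem sizes used in the checks

The packaged checks run the invasion regime at its experimental scale
(30 iterations, 15 generations, cap 400) and the distributional property
checks at Monte-Carlo sizes chosen so that a 3-standard-error band is
decisively narrower than the effects under test: 500 replicate single
generations for simulator/recursion agreement, 200 iterations for the
neutral-martingale and refractory-control checks, and 500 seeds for
interval-coverage and parameter-recovery checks.

## Known limitations

- The four-class model folds in-frame end-joining and sister-chromatid
  repair into "unmodified", so `c` is a lower bound on true cleavage.
- No fitness costs: invasion forecasts are optimistic for constructs with
  load.
- The refractory control uses a single resistant background allele; real
  refractory lines are a family of distinct end-joining products.
- The F2 functional-homing fraction inherits the chi-square test's power
  profile: with few progeny per cross, weakly active cassettes are scored
  non-functional, and ~2.5% of truly inactive crosses are called active by
  the directional test at `alpha = 0.05`.
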