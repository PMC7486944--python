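# Methods

## Model

The trait model for an animal with record `y_i`, housed in a group of
`n_i` animals, is

    y = X b + Z_D a_D + Z_S a_S + W c + V g + T pe + U l + Q k + e

* `b` — fixed effects: birth year-month, sex, group-size class (one level
  per distinct observed size), and age at target weight as a covariate.
  Treatment coding with an intercept keeps the fixed block full rank; the
  age covariate is centred so the intercept/covariate equations stay well
  conditioned (this matters for both the direct solver and the Gibbs
  sweep, whose Gauss–Seidel core converges slowly on near-collinear
  columns).
* `a_D`, `a_S` — direct and social genetic effect vectors over the whole
  pedigree, jointly `MVN(0, C ⊗ K)` with `C` the 2×2 genetic (co)variance
  matrix and `K` the relationship kernel: the pedigree matrix `A` when no
  genotypes are supplied, the single-step `H` otherwise.  Only `K⁻¹` is
  ever used.
* `c`, `g`, `pe` — iid pen, group and maternal-permanent-environment
  effects.
* `(l, k)` — birth-litter and early-life effects sharing litter levels,
  `MVN(0, Σ_lk ⊗ I)`; `k` enters through the birth litters of an animal's
  group mates.
* Dilution: each nonzero entry of `Z_S` and `Q` for record `i` equals
  `d_i = (n̄ − 1)/(n_i − 1)`, so row sums of `Z_S` are exactly `n̄ − 1`
  regardless of group size.  Entry-level weighting (rather than a shared
  row scalar on unweighted incidences) is the only reading that treats
  each group mate symmetrically.
* `n̄` is the unweighted mean of realised group sizes.

Derived parameters (`genetic_parameters`) follow the standard
total-breeding-value arithmetic: `TBV = a_D + (n̄−1) a_S`,
`σ²_TBV = σ²_aD + 2(n̄−1)σ_aDaS + (n̄−1)²σ²_aS`,
`σ²_P = σ²_aD + (n̄−1)σ²_aS + σ²_c + σ²_g + σ²_pe + σ²_l + (n̄−1)σ²_k + σ²_e`,
`h² = σ²_aD/σ²_P`, `T² = σ²_TBV/σ²_P`.  Reported point estimates of
ratios (h², T², correlations) are posterior means of per-draw ratios, so
each carries its own posterior SD.

## Relationship kernels

`A` is built by the tabular method with inbreeding; `A⁻¹` by Henderson's
rules using Mendelian-sampling variances `0.5 − 0.25(F_s + F_d)` (one
parent: `0.75 − 0.25 F_p`; none: 1).  Unknown parents are unrelated,
non-inbred founders; no genetic groups.

`G = Z D Z' q` uses gene content centred at allele frequencies observed in
the genotyped sample (the usual convention when base-generation frequencies
are unavailable), diagonal marker weights `D` (identity unless the ssGWAS
iteration supplies weights), and `q = mean(diag(A22))/mean(diag(Z D Z'))`
so the genomic and pedigree kernels agree on the average self-relationship.
With observed-frequency centring the rows of `Z` sum to zero, so `Z D Z'`
(and hence `G`) is structurally singular; before inversion `G` is blended
as `(1−ε)G + εA22` with default `ε = 0.05` (configurable; `ε = 0` restores
the pure VanRaden matrix for callers that guarantee invertibility).
`H⁻¹ = A⁻¹ + [[0,0],[0, G⁻¹ − A22⁻¹]]` exactly, added at the genotyped
animals' pedigree positions.  `A⁻¹` and `H⁻¹` are held sparse (CSR); `A`,
`A22`, `G` dense — the implementation targets herds up to a few thousand
animals.

## Gibbs sampler

Single-site Gibbs in the GIBBS2F90 style: one sweep per round draws every
location effect from its scalar Gaussian full conditional; the coefficient
matrix is never assembled (the `W'W` cross-product and `K⁻¹` are read
directly in a numba kernel, with penalties applied on the fly).  Variance
updates per round:

* residual and scalar variances (`c`, `g`, `pe`): scaled inverse
  chi-square full conditionals under flat (bounded-improper) priors,
  `σ² = u'u / χ²_{q−2}`;
* the 2×2 genetic and litter blocks: inverse Wishart
  `IW(ν₀ + q, S₀ + S)` with `S` the kernel-weighted cross-product of the
  current effect draws.  The default prior is flat on the block
  (`ν₀ = −(p+1) = −3`, `S₀ = 0`, giving posterior `IW(q−3, S)`), matching
  the common default of animal-breeding Gibbs software.  A proper
  low-degree-of-freedom inverse Wishart (`ν₀ = 3`, small diagonal scale)
  is available in `GibbsPriors` but is **not** the default: its marginal
  behaves like `x⁻²` near the origin, and for components whose likelihood
  is nearly flat at moderate herd sizes (a social variance of ~16 against
  a residual of ~3300, or a litter variance observed through ~4 records
  per litter) that prior mass dominates and pins the chain at zero.

Chain defaults are 55,000 rounds / 5,000 burn-in / thinning 5 — a 10×
reduction of the full-scale schedule (550,000 / 50,000 / 50, which retains
exactly 10,000 samples and is available as `ChainConfig.reference()`).
The whole chain is driven by one PCG64 generator seeded from the config
(default seed 20191709); identical seeds give bitwise-identical output
tables.  Non-finite effect draws abort with a diagnostic.  Starting
values: effects at zero, variances at fixed fractions of `var(y)`.

`solve_mme` provides the matching BLUE/BLUP point solutions by sparse LU
on the mixed-model equations; it is validated against a dense GLS oracle
on the equivalent marginal covariance, and the Gibbs sweep with the noise
vector zeroed is exactly Gauss–Seidel on the same equations (used as a
convergence test).

## ssGWAS

For the chosen effect vector (DGE or SGE), starting from `D = I`: build
`G(D)` and `H⁻¹`, solve the MME at fixed components (posterior means —
re-running the chain inside the weight loop is not part of the printed
procedure), take the genotyped animals' breeding values `â_g`, back-solve
`û = D Z' [Z D Z']⁻¹ â_g`, update `d_i = û_i² 2p_i(1−p_i)` rescaled by a
single constant so `Σ d_i 2p_i(1−p_i)` is conserved, and repeat; two
iterations by default.  The back-solve gram matrix inherits the same
ε-blend as `G` (`(1−ε) Z D Z' + (ε/q) A22`) because it shares the
structural singularity; the projection identity `Z û = â_g` is exact at
`ε = 0` and holds to O(ε) otherwise.  Weights are effect-kind-specific:
the DGE and SGE runs each build their own weighted `G`.

Window decomposition: non-overlapping 1-Mb tiles anchored at position 0 on
each chromosome (1-based MAP coordinates; positions 1..10⁶ form the first
tile; reported labels are 1-based inclusive).  Each window's genomic value
`Σ_{j∈w} Z_j û_j` is computed across genotyped animals and its variance
(ddof = 1) expressed as a percentage of `σ²_a` — by default the model's
additive variance estimate for the effect kind; a self-normalised mode
(denominator = variance of the total genomic value) is provided for
scale-free testing.  Windows at or above 0.5% (inclusive) are QTL.  An
alternative fixed-10-SNP windowing is deliberately not implemented; the
1-Mb reading is used throughout.  A decomposition audit confirms that
window variances plus twice the between-window covariances reproduce the
total genomic-value variance exactly.

## Synthetic data

The generator emulates a closed nucleus herd on performance test:

* **Pedigree** — discrete generations (default 3, all phenotyped);
  founders (default 260) plus litters of `1 + Poisson(3.12)` piglets
  (mean 4.12).  Each generation breeds from pools sized so dams average
  ~3.2 litters and sires ~8, reproducing the litter/dam ratio of a
  nucleus population; repeated-dam litters are what separate the maternal
  permanent environment from the litter effect.  With a single phenotyped
  generation the direct genetic variance is confounded with litter +
  maternal environment (no phenotyped parent–offspring links) and no
  sampler can recover it — multi-generation phenotyping is a structural
  requirement, not a tuning choice.
* **Groups** — sizes drawn from a discretised normal (mean 6.8, SD 1.9)
  truncated to 4–13, within (generation, sex); groups are filled from a
  litter-ordered queue so pens hold littermates and a handful of
  contemporaneous litters, as when test pens are stocked from the
  farrowing batch.  This cohort structure also gives the early-life
  effect (`Q`) repeated observations per litter level.  Pens are recycled
  (~32 groups per pen).
* **Genotypes** — founders Hardy–Weinberg at frequencies uniform on
  (0.1, 0.9) (recorded per marker as `founder_freq` for validation);
  descendants by Mendelian gene dropping, unlinked by default, optional
  per-chromosome recombination (Haldane, 1 cM/Mb).  Planted QTL assign a
  marker the effect size that yields a requested fraction of `σ²_aD`; the
  polygenic remainder is scaled down to keep the total.
* **Phenotypes** — `(a_D, a_S)` simulated down the pedigree with exact
  Mendelian-sampling variances, so their joint distribution is
  `MVN(0, C ⊗ A)`; all environmental terms drawn at their levels; the
  record assembled exactly by the model equation, with social and
  early-life contributions delivered individually through the same
  dilution weights the design matrices use.  Default (co)variances are
  the growth-trait magnitudes the package is tested against (direct 2235,
  social 16, covariance 43, pen 43, group 227, maternal 48, litter 218,
  early-life 17, covariance 36, residual 3299 (g/day)²; phenotypic
  variance ≈ 6260 at n̄ = 6.8).  Fixed-effect levels get `N(0, spread)`
  values (year-month 25, sex 20, size class 10 g/day; 12 year-month
  levels by default, scaling the records-per-level ratio of the target
  population down to desk-size herds); age is uniform on 135–175 days
  with slope −2 (g/day)/day.

What the generator does **not** emulate: realistic porcine LD maps,
selection across generations, genotyping error, missing pedigree links,
heterogeneous residual variance.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated generative model,
not robustness to those real-data features.

## Validation designs and problem sizes

* Parameter recovery: five herds of 1,500 phenotyped animals, default
  chain; every generating component must lie inside the central 95%
  posterior interval in ≥ 4/5 replicates.  Posterior-mean `h²` is within
  0.1 of truth per replicate; `T²`'s own posterior SD at this herd size
  is ~0.15 (it inherits the poorly determined `σ_aDaS`), so the 0.1 bound
  is asserted on the replicate-averaged estimate.
* Planted-QTL detection: ten herds of 1,500 genotyped animals, 2,500
  markers on five 10-Mb chromosomes, one marker carrying 10% of `σ²_aD`;
  the window holding it must be top-ranked and flagged in ≥ 9/10 seeds,
  and its self-normalised share averages within ±5 points of 10%.
  Detection at this marker density needs the full herd genotyped: the
  back-solve spreads polygenic (pedigree-borne) variance lumpily across
  windows, and small genotyped subsets let background windows outrank the
  QTL.
* Oracles: exact-rational kinship recursion (pedigrees ≤ 12), gene-drop
  IBD Monte Carlo (200,000 replicates), dense GLS, enumeration-based
  Hardy–Weinberg exact test, brute-force `Z D Z'` products.

## Quality control

Rules apply in a fixed order (order is part of the contract): animal call
rate ≥ 0.90, marker call rate ≥ 0.90, monomorphic markers, MAF ≥ 0.05,
Hardy–Weinberg exact-test p ≥ 1e-6, sex-chromosome markers; survivors are
mean-imputed per marker.  Thresholds are explicit and configurable — the
defaults are conventional values, chosen because the source material's
printed thresholds are not interpretable as written.  A segregation-
distortion filter is not implemented (no defined rule exists for it).

## Known limitations

* Dense `A`/`G` construction caps practical herd size at a few thousand
  animals; the MME and sweep remain sparse.
* Single-site Gibbs mixes slowly along the `σ²_aD`/`σ²_e` ridge; the
  reduced default chain is adequate at the validated sizes but full-scale
  schedules are advisable for weakly structured pedigrees.
* Whether dams with own records should share levels between their animal
  effect and their maternal permanent environment is ambiguous; they are
  kept distinct (pe is purely dam-indexed).
* With observed-frequency centring the projection identity of the
  back-solve holds only up to the blending ε.
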