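# Methods

## The model

`bnkqtl` implements single-marker QTL mapping through linkage
disequilibrium (LD) rather than recombination fractions.  For each
bi-allelic marker (alleles M/m, frequency `p` of M) a hidden bi-allelic QTL
(alleles A/a, frequency `q` of A) is postulated at LD `D` with the marker.
Marker and QTL haplotypes MA, Ma, mA, ma then have frequencies

    p11 = pq + D,   p10 = p(1-q) - D,   p01 = (1-p)q - D,   p00 = (1-p)(1-q) + D,

and `D` is feasible exactly when all four are non-negative:
`max(-pq, -(1-p)(1-q)) <= D <= min(p(1-q), (1-p)q)`.

Three nested models describe a quantitative phenotype Y:

1. **linked QTL** — a 3-component normal mixture with common variance whose
   weights are the QTL-genotype probabilities conditional on each
   individual's marker genotype.  The conditional weights are built by
   random union of gametes: an M-bearing gamete carries A with probability
   `p11/p`, an m-bearing gamete with probability `p01/(1-p)`, and an
   individual's two gametes are independent.
2. **unlinked QTL** — the same mixture with marginal Hardy–Weinberg weights
   `((1-q)^2, 2q(1-q), q^2)` (the `D = 0` limit of model 1).
3. **no QTL** — a single normal.

Two statistics are produced per marker:

* `T_L = 2 (log L_linked - log L_null)`, the likelihood-ratio statistic for
  QTL existence.  The classical reference for this statistic is a
  chi-square with 5 degrees of freedom (the difference in free parameter
  counts), but the regularity conditions fail — `p`, `q`, `D` are
  unidentified under the null — so the reference is unreliable and `T_L` is
  never converted to a p-value through it.  A `convention="lnL"` flag
  exposes the un-doubled log-ratio.
* `T_D = n D^2 / (p(1-p) q(1-q)) = n r^2`, the LD-strength statistic, with
  `r` the marker–QTL haplotype correlation.  With a hidden QTL its null
  distribution is wildly non-chi-square: `q` is weakly identified and the
  fitted `D` can be large on pure-noise data, so `T_D` under the no-QTL
  null has a mean orders of magnitude above the two-observed-loci
  chi-square(1) folklore.  This is precisely why the joint test below is
  simulation-based.

A marker is declared interesting only when *both* nulls are implausible,
i.e. the joint statistic pair is extreme.

## Estimation

The no-QTL model has closed-form normal MLEs (divide-by-`n` variance).  The
linked model is fit by a generalized EM over `(q, D, mu1, mu2, mu3, sigma)`
with `p` fixed at the allele-count estimate `sum(M) / 2n`, whose MLE under
HWE does not involve the phenotype model.  Per iteration:

* E-step: posterior QTL-genotype probabilities per individual;
* M-step: posterior-weighted closed forms for the means and the common
  sigma; `(q, D)` by maximizing the expected complete-data log-likelihood —
  a function of a 3x3 posterior count table only — over a grid refined
  around the incumbent, with `D` parameterized linearly over its feasible
  range so every candidate is valid.  The incumbent is kept unless
  improved, so the observed-data log-likelihood never decreases.

The likelihood surface is genuinely multimodal.  Recurring mode families on
null data include boundary-`q` solutions whose vanishing-weight component
absorbs a phenotype tail, and sign-flipped `(q, D)` pairs.  The fit
therefore runs 12 restarts: a null-collapsed start (all means equal,
`D = 0`, which guarantees the returned optimum nests the no-QTL fit),
quantile-spread mean starts crossed with `D` signs, two boundary-`q`
tail-component starts, and random-jitter fill-up.  All restarts run a cheap
exploration stage (40 sweeps); the best four continue to convergence
(|delta log L| < 1e-8, cap 500 sweeps) and are polished with box-constrained
L-BFGS-B on the observed-data log-likelihood.  On benchmark null datasets
this two-stage scheme reproduces the optima found by exhaustive
differential-evolution global search at a fraction of the cost.  sigma is
floored at `1e-6 * sd(Y)`; missing genotypes are handled complete-case per
marker; all restart randomness is driven by an explicit seed.

## The bivariate null kernel (BNK) test

The joint null distribution of `(T_L, T_D)` is unknown, strongly
correlated, and far from any chi-square product, so it is estimated
directly:

1. simulate `k` null datasets (default 1000): phenotype
   `Normal(Ybar, sigma_Y^2)` and an independent HWE marker at the observed
   allele frequency, and compute the statistic pair of each with the same
   estimation settings as the observed data — calibration only requires
   internal consistency between the null pairs and the observed statistic,
   not absolute optimizer thoroughness;
2. fit a Gaussian product-kernel density on a 256x256 grid padded by 3
   bandwidths per axis (axis-wise bandwidths, since the two statistics live
   on very different scales);
3. choose the bandwidth from `{0.5, 0.75, 1, 1.5, 2, 3}` x the
   normal-reference (Scott) bandwidth: the in-sample size of the test —
   the fraction of null pairs whose own highest-density-region p-value
   falls below alpha — is computed per candidate, and the candidate
   maximizing the size subject to size <= alpha wins, ties breaking toward
   the larger bandwidth.  In-sample scoring is chosen for determinism; the
   conservative tie-break compensates its optimism.  Note the in-sample
   size is *not* monotone in bandwidth at extreme undersmoothing (every
   point becomes its own near-maximal spike), which is why candidates are
   anchored at the normal-reference scale;
4. tabulate the level-set CDF `F(c)` = grid mass of `{f >= c}` (ties
   inclusive);
5. report `p = 1 - F(f(t*, u*))` with `f` evaluated by bilinear
   interpolation, zero outside the padded grid.  A point outside the grid
   gets `p = 0` exactly; the grid's ~1% mass deficit is not allowed to leak
   into it.

Genome-wide, markers are grouped into 20 right-closed allele-frequency
packets of width 0.05; one kernel is simulated per occupied packet at the
packet's mean frequency and shared by its members, and the per-marker joint
p-values are Holm-adjusted (family size = markers actually tested;
monomorphic markers are flagged and given adjusted p 1).  Packets receive
independent child seed streams, so results do not depend on processing
order.  A `per_marker=True` flag builds one kernel per marker instead.

## What the simulators emulate

* `simulate_null_dataset` / `simulate_linked_qtl_dataset` — the
  single-marker study: null data at `(n, p)` with phenotype moments
  `(mu, sigma)`, and linked-QTL data where the hidden QTL genotype is drawn
  conditionally on the marker through `(p, q, D)` and the phenotype from
  the genotype means.  The default linked configuration is
  `p = 0.5, q = 0.7, D = 0.08, sigma = 1`.  The type-I-error study uses
  `Y ~ Normal(10, 1)`; genotype means for power runs default to
  `(mu - 0.5, mu, mu + 0.5)` — an additive effect of 0.5, a medium effect
  for this design, chosen once as the documented default since power is
  checked only as a monotone-in-`n` property.
* `simulate_f2_cross` — an F2 intercross: two independent gametes per
  chromosome, each a Markov chain along the ordered loci with switch
  probability given by the Haldane map function `r = (1 - e^(-2d/100))/2`
  (no interference); phenotype = sum of additive QTL effects
  `a (g - 1)` plus unit-variance noise.  The default design is four 100-cM
  chromosomes with 50/10/50/10 equally spaced markers, QTL at chr1 44.4 cM
  (a = 0.75) and chr2 61.6 cM (a = 1.0), n = 100.
* `hotelling_t2` / `simulate_bivariate_normal_pairs` — the general
  (non-genetic) bivariate mean test: `T^2 = n (Xbar - mu0)' S^{-1}
  (Xbar - mu0)` with the scaled-F null `2(n-1)/(n-2) F(2, n-2)`, and the
  marginal statistics `sqrt(n)(Xbar_j - mu0_j)/S_jj` (dividing by the
  diagonal *variance* entries as the default convention; a `marginal="sd"`
  variant divides by standard deviations).  The BNK consumes the marginal
  pair in place of `(T_L, T_D)`; one null kernel is shared across
  replications, which is exact here because the null distribution of the
  marginal statistics does not depend on the simulated alternative.

What the generators do **not** emulate: population structure or relatedness
(all individuals are unrelated random-mating draws), genotyping error,
non-normal phenotypes, dominance or epistatic QTL effects, crossover
interference, and linked *pairs* of causal loci on one chromosome beyond
the stated designs.  Passing tests therefore show correctness of the
machinery under the stated generative assumptions, not robustness to their
violation.

## Numerical choices and degenerate inputs

* Feasibility of `D` is enforced through the linear `t in [0, 1]`
  reparameterization during fitting and validated with explicit bounds
  elsewhere; infeasible user input is rejected naming the violated
  haplotype frequency.
* Monomorphic markers raise a structured `MonomorphicMarkerError` (T_D is
  undefined); genome scans record the status and continue.
* Monomorphic *simulated* null markers are redrawn.
* Level-set CDF ties are inclusive (`f >= c`).
* Holm: stable sort, running maximum, cap at 1.
* Packet bin edges are right-closed; the frequency binned is that of the
  counted allele, not folded MAF.
* `q` is kept in `[1e-6, 1 - 1e-6]` during fitting; boundary optima are
  reported at the clamp.

## Replication-study problem sizes

The null-distribution study runs 1000 replicates at `n = 500` in the
acceptance script (about 7 minutes on one core).  The test suite exercises
the same studies at reduced replication counts and kernel sizes
(250 null replicates; `k` of 300–500; 40–50 replicates per sample size)
with Monte-Carlo-aware tolerances; the study conditions themselves (sample
sizes, frequencies, effect sizes, covariance) are never scaled.

## Known limitations

* The null sampling distribution of `T_L` produced by this implementation
  is empirically indistinguishable from chi-square(5) (mean ~5, 95th
  percentile ~11) at `n = 500`.  Cross-checks with global optimization
  confirm this is a property of the common-variance likelihood itself, not
  of optimizer laziness.  Heavier-tailed nulls reported elsewhere for
  related models appear to require additional model freedom (for example
  component-specific variances), which the likelihood implemented here
  deliberately does not have.  The BNK calibration is unaffected: it never
  assumes a chi-square reference.
* The per-packet kernel approximates each member marker's null by the
  packet-mean frequency; markers at a packet edge inherit a kernel built up
  to 0.05 away in allele frequency.  `per_marker=True` removes the
  approximation at ~`k` times the cost per marker.
* p-values are lower-bounded only by the kernel tails: a marker far outside
  the null cloud gets exactly 0, which is the intended highest-density
  -region semantics but means -log10(p) is unbounded for plotting.
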