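# Methods

This document states the model assumptions, parameter conventions and
numerical choices behind `cryptdrift`. Everything quantitative below is
computed by the package itself; no empirical claims are made beyond what the
code produces from its own synthetic data.

## 1. Biological picture

Colonic crypts are maintained by a small pool of effective stem cells at the
crypt base. Somatic mtDNA mutations arise in individual stem cells, drift to
high heteroplasmy through random segregation of mitochondria at cell
division, and render a cell OXPHOS-deficient once mutant molecules dominate.
A deficient stem cell founds a clone that then drifts neutrally within the
niche: it is either lost or takes over the whole ring of stem cells (niche
succession), at which point the crypt becomes fully deficient. Histological
sections read out the deficient fraction of the crypt circumference.

The package implements this picture at three coupled levels, plus an
observation layer and cohort machinery.

## 2. Within-cell mtDNA dynamics (`cryptdrift.mtdna`)

- Each stem cell carries a fixed copy number `M = 200` mtDNA molecules,
  partitioned into wild type and mutant lineages (each new mutation gets a
  fresh lineage id; there is no back-mutation).
- **Replication ("binary" scheme, default):** at division every molecule is
  copied exactly once, doubling the pool to `2M`. Each newly synthesised
  wild-type copy mutates independently with probability `mu(t)`. A
  "resample" scheme (draw `2M` copies with replacement) is provided as a
  sensitivity switch.
- **Mutation rate schedule:** `mu(t) = mu0 * (mu_end/mu0)^(t/80)` rises
  exponentially from `1e-5` at birth to `6e-5` per molecule per division at
  age 80 years, and extrapolates beyond 80 if asked.
- **Segregation:** the doubled pool is split multivariate-hypergeometrically
  into two daughters of exactly `M` molecules each (strict conservation; the
  daughter heteroplasmy is a martingale).
- **Deficiency threshold:** a cell is OXPHOS-deficient when its mutant
  fraction reaches `theta = 0.75` (inclusive: `ceil(theta*M)` = 150 of 200
  molecules, with a `1e-9` epsilon guarding the ceiling against
  floating-point representation error).

## 3. Niche dynamics (`cryptdrift.niche`)

- The niche is an ordered ring of `N = 5` stem cells dividing synchronously
  once per `7` days; an 80-year (365-day years) lifespan is
  `floor(80*365/7) = 4171` division rounds.
- At each round every cell divides. With probability `p_asym = 0.99` the
  outcome is asymmetric (one daughter stays; the ring configuration is
  unchanged). Otherwise both daughters are retained and one ring neighbour
  (left/right with equal probability; optionally any other position) is
  expunged with all its contents. Positions are visited in random order; a
  cell expunged before its turn does not divide that round (its division is
  pre-empted). Because of this pre-emption the realised loss/replacement
  rate is very slightly below the nominal `p_sym * divisions/year`.
- A crypt is classified by the number `k` of deficient stem cells: normal
  (`k = 0`), partial (`0 < k < N`), full (`k = N`).
- Single-crypt routines are plain Python; `simulate_ensemble` runs the
  identical update rule in compiled (numba) kernels with an exact sequential
  Bernoulli implementation of hypergeometric sampling, validated against
  `scipy.stats.hypergeom` in the test suite. A labelled-cell engine
  (`simulate_induction_ensemble`) runs the same niche rules without the
  mtDNA layer: cells are irreversibly labelled by a Poisson induction
  process, which is the stochastic counterpart of the analytic model below.

## 4. Analytic clone model (`cryptdrift.drift`)

Clone size `n` in `{0..N}` performs a continuous-time birth-death walk with
absorbing boundaries and rates

    n -> n+1 at lambda * (1 + delta),    n -> n-1 at lambda * (1 - delta).

**Rate convention.** `lambda` is exactly the per-stem-cell loss/replacement
rate, so `p_sym` per weekly division corresponds to
`lambda = p_sym * 365/7` (0.01 -> 0.521/yr; the package default rounds this
to 0.6/yr, the fitted value scale). `delta = 0` is strict neutrality.

Closed forms and solvers:

- transition probabilities by eigendecomposition of the `(N+1)x(N+1)`
  generator, validated against `scipy.linalg.expm` at the largest requested
  time and falling back to `expm` when ill-conditioned;
- fixation probability by the biased gambler's-ruin formula, reducing to
  `n0/N` when neutral (including biases below float resolution);
- the quasi-steady size distribution of surviving partial clones under
  constant injection at `n = 1` by a linear solve; in the neutral case it is
  proportional to `N - n` and independent of `lambda`, so the modal clone
  occupies a fraction `1/N` of the circumference.

**Induction law and units.** New clones are seeded at size 1 at rate
`R(t) = R0 * exp(eta * t)` with defaults `R0 = 0.05`, `eta = 0.05/yr`.
`R0` is expressed in *percent of crypts per year* — the scale on which crypt
prevalences are reported — so the absolute per-crypt rate is `R(t)/100`.
Read as absolute rates the same constants would accumulate tens of clones
per crypt by age 80, contradicting the late, few-percent prevalence the
model is meant to describe; the percent convention keeps all printed
constants intact and reproduces data-like prevalences.

**Class probabilities.** Expected clone-size masses are
`m_n(a) = ∫ R_abs(t) P_{1->n}(a-t) dt`, evaluated by 48-node Gauss-Legendre
quadrature. Clones are treated as independent Poisson arrivals:
`P(full) = 1 - exp(-m_N)`, and the partial-size distribution is the
Poisson-compound convolution of clone sizes capped at `N - 1`. The
independence approximation is accurate while cumulative induction per crypt
is modest (about 0.5 events by age 80 at the defaults); a `RuntimeWarning`
is emitted when it exceeds one event.

**Fitting.** `CryptDriftModel` / `CryptDriftResults` provide a
model/results fitting interface: patient-count-weighted nonlinear least
squares (`scipy.optimize.least_squares`) on decade-binned partial/full
percentages, with any subset of `(lambda, delta, R0, eta)` free, plus
profile curves and a text summary.

## 5. Observation model (`cryptdrift.observation`)

- A crypt with `k` of `N` deficient stem cells shows a section fraction
  `k/N` blurred by zero-mean Gaussian jitter of scale `sigma = 0.03`,
  truncated to `(0, 1)` by rejection; `k = 0` and `k = N` map exactly to 0
  and 1.
- Observed fractions at or below the detection floor `0.05` are recorded as
  normal (thin patches are unresolvable). The floor must stay below `1/N`.
- Fractions are binned back to stem-cell counts in increments of `1/N` with
  inclusive upper edges (so an unbiased jitter around `k/N` splits between
  bins `k` and `k+1`).
- `scan_sc_number` scores candidate `N = 3..8` against an observed
  partial-fraction histogram by the sum of squared differences between
  observed frequencies and the analytically blurred quasi-steady size law,
  over bins above the floor; exact ties are reported, never broken silently.

## 6. Synthetic cohorts (`cryptdrift.cohort`)

The default cohort reproduces the study composition: 148 patients in age
brackets 17-20 (2), 21-30 (10), 31-40 (25), 41-50 (44), 51-60 (37),
61-70 (21), 71-80 (9), with 1,000 crypts per biopsy. Patient ages are
uniform over the bracket's integer years. Patient-to-patient variability is
a mean-one gamma multiplier (shape 4) on the mutation or induction rate.
Crypt states come either from the multiscale simulator or from the analytic
clone model (Poisson clone sampling), and both engines push stem-cell counts
through the same observation pipeline. Crypt fission is not simulated, so
collapsing adjacent fully deficient crypts into single clonal events is a
no-op here.

## 7. What the synthetic data do and do not show

The synthetic cohorts demonstrate *internal consistency*: parameters used to
generate data are recovered by the package's own inference (the stem-cell
number scan, the analytic drift fit, the induction-law refit, and the
asymmetry grid fit), and the two stochastic engines agree with the analytic
model within Monte-Carlo error. They do not constitute evidence about real
tissue: no patient data ship with the package, measured-data quantities such
as goodness-of-fit statistics of published cohorts cannot be reproduced
here, and the defaults are modelling conventions, not estimates derived from
data in this repository.

## 8. Numerical and reproducibility choices

- All stochastic entry points accept either a `numpy.random.Generator` or a
  seed; compiled kernels receive a single sub-seed drawn from that stream,
  so identical seeds give bit-identical outputs.
- CSV output uses fixed `%.6g` formatting and sorted JSON keys so repeated
  runs are byte-stable; every CLI run writes a `metadata.json` with the full
  configuration and package version.
- Default experiment sizes (for example 7,000 crypts for the stem-cell-number
  scan, chosen to pool at least 2,000 partial observations; 20 synthetic
  patients per decade in the grid-fit recovery so gamma patient
  heterogeneity does not drown the grid signal) are package choices that
  balance Monte-Carlo error against a single-CPU time budget.

## 9. Limitations

- The niche is a fixed-size ring with synchronous weekly divisions; niche
  size fluctuations, asynchronous division and crypt fission/fusion are out
  of scope.
- OXPHOS deficiency is a sharp threshold on a single mutant fraction;
  heteroplasmy of multiple interacting mutations is not modelled beyond
  lineage bookkeeping.
- The analytic model treats clones as independent; at high induction rates
  the Poisson overlap correction caps, rather than resolves, clone
  competition.
- The observation model is a one-parameter Gaussian blur with a hard
  detection floor; real section geometry, patch contiguity and scoring
  error are richer than this.
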