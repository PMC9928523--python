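# Methods

`tipchron` implements Bayesian tip-dating for serially sampled sequence
data: radiocarbon-dated and modern samples calibrate a strict molecular
clock, which in turn dates the specimens without direct dates. This note
describes the model, the algorithms, the synthetic data the package is
validated on, and the design choices made where more than one defensible
option existed.

## The model

The joint posterior over genealogy `G` (a rooted binary time tree with node
ages in calendar years BP), clock rate `r` (substitutions/site/year),
effective population size `Ne` (years; Ne multiplied by generation time),
and the unknown tip ages `a` is

    p(G, r, Ne, a | D) ∝ P(D | G, r) · p(G | Ne, a) · p(r) p(Ne) p(a)

* **Sequence likelihood** `P(D | G, r)`: Felsenstein pruning under
  HKY+Γ. The HKY rate matrix is normalized to one expected substitution per
  unit branch length, so a branch spanning `Δt` years contributes `Δt · r`
  substitutions/site. Among-site rate variation uses k = 4 equiprobable
  discrete-gamma categories whose rates are band conditional means,
  renormalized to average exactly 1. Transition probabilities use the
  closed-form HKY solution rather than matrix exponentials. Gaps and `N`
  are missing data; IUPAC codes contribute partial likelihood 1 over their
  compatible states. Site patterns are compressed and per-pattern partials
  are rescaled, keeping the computation stable for ≥ 10 kb alignments.
* **Tree prior** `p(G | Ne, a)`: the heterochronous (serial-sampling)
  Kingman coalescent with constant `Ne`. Lineages activate at their
  sampling ages; with k active lineages each pair coalesces at rate
  `1/Ne`, and each coalescent event contributes a `1/Ne` factor.
* **Parameter priors**: clock rate log-uniform on [1e-10, 1e-4]
  substitutions/site/year and pop size log-uniform on [1e2, 1e9] years by
  default (weakly informative and configurable); tip-age priors per tip —
  fixed (dated samples), Gamma(shape 2, scale 50 000 years; mean 100 kyr)
  for a specimen dated in its own single run, or a lognormal matched to a
  previous posterior in the joint analysis.

The substitution model is fixed to HKY+Γ on a single partition and the
clock is strict. These are deliberate minimal choices: they are the
standard mitogenome defaults, they keep the engine exhaustively testable
(every likelihood is checked against brute-force enumeration on small
trees), and nothing in the architecture prevents swapping richer site or
clock models later.

## MCMC sampler

A Metropolis–Hastings sampler draws one operator per iteration with
probability proportional to its weight:

| operator | move | Hastings |
|---|---|---|
| `clock_rate`, `pop_size` | multiplier `x' = x·exp(λ(u−½))` | `x'/x` |
| `node_ages` | redraw one internal age uniformly between its oldest child and its parent | 1 |
| `root_age` | multiplier on the root's offset above its older child | factor |
| `rate_height` | scale all internal ages by m, rate by 1/m | `m^(n_tips−2)` |
| `narrow_exchange` | swap a child with its uncle (validity-checked) | 1 |
| `tip_ages` | reflected random walk on [0, parent age) | 1 |
| `tip_ages_prior` | independence redraw from the tip's prior | prior ratio |

Proposal widths adapt toward 23.4% acceptance during burn-in only
(Robbins–Monro step sizes), then freeze, so the retained chain satisfies
detailed balance. All randomness flows from a single integer seed; the same
seed reproduces the trace bit-for-bit. When a single undated tip is
estimated, its tip-age operator weight is raised to 5 — the boost a
one-specimen-at-a-time dating run needs because every other operator
targets global parameters. The independence redraw (a quarter of the
tip-age weight) lets the chain jump between data-supported and
prior-supported modes of a tip's age rather than diffusing between them.

The likelihood enters the target as `P(D|·)^β`. β = 1 is ordinary
sampling; the β ladder (8 steps at quantiles of Beta(0.3, 1), concentrated
near 0) feeds the stepping-stone marginal-likelihood estimator
`log ML = Σ_k log E_{β_k}[exp((β_{k+1}−β_k)·log L)]`, stabilized by
max-shifting before exponentiation.

**Prior-only mode.** With `prior_only=True` both the sequence likelihood
and the coalescent density are dropped and the tree is frozen; clock rate,
pop size and estimated tip ages are then sampled from their marginal
parameter priors. This is a deliberate definition: the coalescent couples
tip ages to internal-node ages, so a mode that kept it would not reproduce
the analytic gamma/lognormal prior moments that make the mode useful as a
Geweke-style validation of the proposal machinery (correct Hastings ratios,
reflection, adaptation freezing).

## Diagnostics

ESS uses the initial-monotone-sequence estimator on pair sums of the
autocorrelation function; estimates are capped at n and a zero-variance
column is flagged degenerate with ESS 0. Per-tip convergence is flagged at
ESS ≥ 200, the conventional BEAST-community threshold. HPD intervals are
the shortest contiguous interval containing ⌈mass·n⌉ sorted samples.

## Radiocarbon calibration

A determination `age ± error` (14C yr BP) is calibrated on a 1-year
calendar grid: the curve is linearly interpolated, the likelihood at
calendar year θ is Gaussian in `age − μ(θ)` with variance
`error² + σ(θ)²`, and the normalized density is summarized by its median
and 95.4% highest-density regions (grid cells accumulated in decreasing
density order and merged into intervals — multi-modal ranges arise
naturally on wiggly curves). No reservoir corrections or outlier models.
Calibrated tips enter the MCMC as fixed point ages at the calibrated
median; full-density tip priors would be a natural extension but point
calibration keeps the validation loop (where calibrated medians equal
simulated truth by construction) free of calibration error.

## Consensus calling

Per reference position with read counts over {A,C,G,T}: coverage < 3 masks
to `N`; a base supported by ≥ 75% of reads is called; otherwise all bases
with ≥ 25% support form the IUPAC ambiguity call. The boundary is
deliberate: "less than 75%" triggers ambiguity coding, so exactly 75%
calls the plain base, and 25% is the complement of the majority threshold.
Ties for the top base fall through to the ambiguity path automatically.
Indels are outside the rule's scope.

## The specimen-dating workflow

1. **Temporal signal.** The date-randomization test re-runs the analysis
   with tip dates permuted among tips (default 10 permutations) and claims
   signal only if the real-data clock-rate 95% HPD overlaps none of the
   permuted HPDs — the strict variant of the published criterion. BETS
   compares stepping-stone marginal likelihoods of the model with true
   sampling dates against all-contemporaneous tips; the verdict threshold
   is log BF > 1.1 (≈ BF 3, "strong" on the natural-log scale),
   configurable and recorded in the report.
2. **Leave-one-out.** Each dated tip is re-estimated with its date hidden
   (Gamma(2, 50 000) prior, operator weight 5) and scored by the percent
   difference of the posterior median from the radiocarbon age (the
   radiocarbon age is the denominator) and by 95% HPD coverage.
3. **Single-specimen dating.** Undated tips are dated one at a time
   against all dated tips. These runs condition on a fixed topology built
   once from the data (average-linkage clustering of JC-corrected
   distances, node heights converted through the initial clock rate) —
   conditioning keeps a run with one free age cheap, and the choice is
   recorded in the trace metadata; topology estimation can be switched on
   per run.
4. **Joint analysis.** Each single-run posterior is summarized as a
   lognormal by moment matching in log space (mean/SD of log samples) and
   used as that tip's prior in one joint MCMC over all specimens, with
   per-tip ESS ≥ 200 convergence flags.

## Synthetic data

The generator produces study-shaped data with known truth so every stage
is testable without downloads. Defaults — the conditions used throughout
the tests — are 20 tips (one-sixth modern at age 0, the rest spread evenly
to 50 kyr BP), constant `Ne` = 100 kyr, strict clock 2e-7
substitutions/site/year, 2 kb of HKY+Γ sequence (κ = 10, mitochondrial-like
base frequencies [0.34, 0.26, 0.13, 0.27], Γ shape 0.5), and pileups with
Poisson coverage mean 8, 0.5% uniform sequencing error and 5% uniform
C→T damage. Pseudo-radiocarbon dates are generated through an *identity*
calibration curve with ±200 yr errors, so calibrated medians equal true
ages by construction and clock-inference error is isolated from
calibration error.

What the generator deliberately does not emulate: positional deamination
profiles (damage is uniform — the consensus caller only needs mixed-base
sites), fragment-length structure, recombination, population structure or
non-constant demography, and rate variation across lineages. Passing tests
therefore demonstrate the correctness of the inference machinery under its
own model assumptions, not robustness to their violation in real data.

## Numerical choices and problem sizes

* Pattern compression plus a JIT-compiled pruning kernel give ~0.15 ms per
  likelihood evaluation at 20 tips × 2 kb; validation chains are 25k–60k
  iterations, thinned to ~2 000 samples with 10% burn-in. These lengths
  give clock-rate ESS of roughly 10–60 on the default datasets — enough
  for calibrated-coverage checks across replicates, while individual runs
  flag themselves unconverged by the ESS ≥ 200 rule, mirroring how the
  convergence flag is meant to be used.
* Recovery checks: across 20 replicate default datasets the clock-rate
  95% HPD covers the generating rate in ≥ 17, and held-out tip-age
  coverage lies in [80%, 100%]. Leave-one-out accuracy is asserted on a
  12-tip, 4 kb dataset with dated tips spanning 12–48 kyr (the
  "strong-signal" configuration); the spread of per-tip errors is wide
  at the oldest tip, which sits beyond the calibrators and is genuinely
  an extrapolation.
* Degenerate inputs: zero-length internal newick branches are resolved by
  an infinitesimal age nudge on parsing; a tree proposal that violates an
  age ordering is rejected rather than repaired; JC distances cap the
  observed difference fraction at 0.70 before the log correction.

## Known limitations

Strict clock and single partition only; no relaxed clocks, skyline
demographics or BEAST XML interchange. Single-tip runs conditioned on a
fixed data-derived topology inherit that topology's errors (the clock-rate
HPDs of such runs are less reliable than those of full runs with topology
sampling — the validation suite measures rate coverage on the latter).
Marginal-likelihood estimates at short chain lengths carry Monte-Carlo
error of a few log units; BETS verdicts near the threshold should be
re-run with longer ladders.
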