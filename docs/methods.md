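# Methods

## Count adjustment

Observed bait–prey read counts are assumed sparse: only pairs with at
least one read pair are stored, so the null count model is a
**zero-truncated NB2** (variance μ + αμ², log link), fitted by maximum
likelihood independently within **ten distance bins**. Bins are deciles of
log10 midpoint distance; quantile bins keep per-bin sample sizes balanced.
A record lying exactly on an internal bin edge is assigned to the lower
(right-closed) bin, deterministically.

Covariates enter as log distance, log bait length, log prey length, a
both-baited indicator, and standardized **transchromosomal bait
activity** — the residual of a bait's summed cross-chromosome counts after
regressing on its chromosome (with a categorical regressor this is exactly
per-chromosome mean subtraction). Under the assumption that true
transchromosomal contacts are equally rare everywhere, this covariate
proxies capture/enrichment efficiency. The transforms (logs for
heavy-tailed positive covariates, z-scoring for activity) are this
package's choices. A Poisson technical-noise convolution is deliberately
omitted; NB regression alone is applied to the raw counts.

Fitting goes through statsmodels' zero-truncated NB likelihood with
Poisson-GLM starting values; if the optimizer diverges, the dispersion is
profiled on a geometric grid with coefficients re-optimized at each value,
and the best candidate by truncated likelihood wins (flagged
unconverged). Covariates with zero variance inside a bin are dropped and
recorded on the fit object.

Adjusted signals are **normalized randomized quantile residuals**: for
count y with fitted truncated CDF F, draw u ~ Uniform(F(y−1), F(y)] and
return z = Φ⁻¹(u). The truncated CDF is evaluated through survival
functions, F(y) = 1 − S(y)/S(0), which stays accurate when the untruncated
model puts nearly all its mass on zero; u is clamped one machine epsilon
away from {0, 1}. The randomization uses one dedicated RNG stream keyed by
the run seed, so residuals are bit-reproducible. Under a correctly
specified null these residuals are exactly standard normal — the test
suite verifies this by simulation (KS p > 0.01 at n ≈ 10⁴).

## Joint spatial model

Within a window of ±5 Mb around each bait (only preys with observed
counts; residuals exist only for recorded pairs), residuals are modelled
as

    Y_p ~ N(μ_p, 1),   μ_p = Σ_{q: γ_q = 1} β_q · exp(−ω·|m_p − m_q|)

with m the fragment midpoints. ω is a single global constant, default
10⁻⁴·⁷ per bp (≈ e-folding every 50 kb), exposed as a configuration
parameter. Contributions from multiple contacts add on the residual scale
with no saturation. The sum runs over the full window; no neighbourhood
cutoff is applied (a cutoff radius could be added to the design matrix,
but the kernel itself already localizes contributions).

Priors: β_q | γ_q = 1 ~ N(0, σ_β²); σ_β ~ Uniform(0.01, 2) — a weakly
informative hyper-prior whose median σ_β = 1 supports strengths up to
about 1.96 at 95% central mass; γ_q i.i.d. Bernoulli(θ) with
θ ~ Beta(1, F). Marginalizing θ gives the configuration prior
P(γ) = B(1 + k, 2F − k)/B(1, F) with k = Σγ: exactly 1/2 on the empty
configuration for every F, and marginal inclusion odds 1/F per fragment,
so multiplicity is corrected intrinsically and the null is comparable
across baits.

## Inference

The posterior over (γ, β, σ_β) is sampled per bait by reversible-jump
Metropolis–Hastings with four move types — add (β drawn from its
conditional prior, so prior and proposal densities cancel in the
acceptance ratio), delete, single-site Gaussian random walk on an included
β, and a reflected random walk on σ_β inside its bounds — selected with
weights 0.3/0.3/0.3/0.1, renormalized over the moves available in the
current state. The β walk scale is tuned toward ~30% acceptance during a
discarded 10⁴-iteration adaptation phase and frozen before retained
sampling so the kernel is valid. Chains start at the empty model with
σ_β = 1 (the hyper-prior median).

The production protocol retains 5000 samples per chain at a density of one
per 1000 iterations with no burn-in, runs two chains per bait, and extends
both by further 5000-sample blocks while the Pearson correlation between
the chains' per-fragment MPPC is ≤ 0.75, up to a cap of 2×10⁷ iterations
per chain (non-convergence is flagged, never raised). For a single-prey
window the correlation is undefined and the criterion falls back to
|ΔMPPC| < 0.05. Inference uses the union of samples from both chains.
Baits are independent, so seeds are derived deterministically per
(base seed, bait, chain, extension segment) via `SeedSequence` spawning;
chain extensions continue the Markov state under a fresh per-segment
stream, which preserves both determinism and the stationary distribution.

Per prey, **MPPC** is the proportion of retained samples with β > 0 (not
β ≠ 0: contacts are expected to raise counts), and `beta.post` is the
posterior mean of β including zeros. The per-bait sum of MPPC estimates
the expected number of direct contacts.

The long-run inner loop is compiled with numba; the same transition is
also implemented explicitly in Python (`propose`/`mh_ratio`), used by the
tests to verify the acceptance-ratio algebra (prior/proposal cancellation,
reversibility) term by term.

## Exact oracle

For windows with F ≤ 20 and fixed σ_β the model is conditionally
linear-Gaussian: the evidence of each of the 2^F configurations is
available in closed form (Y ~ N(0, I + σ_β² X_γ X_γᵀ), evaluated through
the k×k information matrix), and P(β_q > 0 | Y, γ) is a univariate normal
tail of the conditional Gaussian posterior of β. Enumeration therefore
yields the exact MPPC, against which the sampler is validated (max
absolute difference < 0.05 over randomized windows). σ_β is fixed in the
oracle to keep it closed-form; the hyper-prior path is validated
separately by prior-sampling tests.

## Synthetic data generator

The generator emulates the data features the method relies on: contiguous
restriction fragments with log-normal lengths (median 4 kb), background
counts decaying exponentially with distance (log mean = intercept −
slope·log d), NB2 overdispersion, a sparse transchromosomal background per
bait, and planted direct contacts with collateral spillover at
neighbours. Signal is injected on the latent residual scale and mapped
back through the NB quantile function, so the generative model matches the
inferential model exactly and oracle tests apply; a deliberately
mismatched `multiplier` mode (signal scales the NB mean) exists for
robustness checks. Zero counts are dropped, matching the sparse-storage
convention.

Default study conditions are a 50-bait dataset with ≈300 observed preys
per window. Two design points matter:

- **Window geometry.** F ≈ 300 is reached by a ±600 kb simulation window
  over 4 kb fragments with background deep enough (intercept 10.4,
  slope 0.75, dispersion 0.3) that nearly all window fragments are
  observed. Reaching F ≈ 300 instead by thinning a ±5 Mb window through
  shallow counts creates a selection effect — distant pairs are observed
  mainly *because* they carry signal — which badly inflates fitted
  dispersions in the far bins and is not how a well-powered capture
  experiment behaves.
- **Contamination of the null fit.** The null regression assumes most
  pairs carry no contact. Planted contacts with β ∈ [2, 6] spill over tens
  of fragments, so small simulations with one or two baits contaminate a
  large fraction of the fit data, inflate the dispersion estimate and
  compress all residuals. At 50 baits with 1–5 contacts each the
  contaminated fraction is small and the compression mild — the same
  dilution that real capture designs with thousands of baits provide.

What passing tests on these simulations do **not** show: robustness to
replicate structure, ligation artefacts, TAD-boundary asymmetries in the
count decay, or misspecified ω — real-data features the generator does not
emulate (the `multiplier` mode probes one kind of misspecification).

## Problem sizes and numerical choices

Simulation-backed checks run at desk scale as this package's own choice:
the 50-bait recovery and convergence analyses use 2500 retained samples
per chain at a thinning of 1 per 400 (10⁶ iterations per chain, two
chains), a scaled-down surrogate for the production protocol whose
defaults remain 5000 × 1000. Sampler-versus-oracle comparisons use 10⁴
retained samples per chain at thinning 20 on windows of 5–10 fragments.

Identifiability at fragment resolution is intrinsically limited: adjacent
4 kb fragments have decay-design columns correlated at exp(−ω·4000) ≈
0.92, so a contact and its immediate neighbour are nearly exchangeable and
the posterior legitimately splits mass between them. Accuracy statements
are therefore made at the level of ranking (MPPC-vs-truth AUC ≥ 0.9 under
the default conditions) and paired planted-versus-neighbour comparisons,
not exact argmax recovery.

Other numerical details: the truncated-NB quantile-residual CDF uses
survival-function ratios; randomized residual draws clamp u away from
{0, 1} by machine epsilon; non-finite MH ratios reject the proposal and
log an incident; duplicate fragment midpoints make design columns
identical and are flagged; an all-identical-MPPC degenerate pair of chains
(e.g. both all-zero) counts as converged when the vectors match within
0.05, since the undefined correlation there reflects agreement, not
disagreement.

## Known limitations

- ω is global and fixed; data generated with a different decay rate will
  smear or shrink MPPC peaks.
- The NB null is fitted on all pairs, so extremely contact-dense designs
  bias it upward (see contamination above).
- The oracle cannot marginalize σ_β (covered instead by Monte-Carlo
  agreement tests).
- Windows are capped at the chromosome; baits near assembly edges have
  asymmetric windows, which the model tolerates but the generator does not
  specifically exercise.
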