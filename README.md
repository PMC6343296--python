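# chicfine

Bayesian fine-mapping of direct chromatin contacts in capture Hi-C (CHi-C)
data.

## The problem

CHi-C enriches sequencing reads for contacts between selected *bait*
restriction fragments (typically gene promoters) and all other fragments
(*preys*). Per-fragment callers score each bait–prey pair independently,
which often produces long runs of adjacent "significant" prey fragments.
Because a genuine contact at one fragment pulls physically linked
neighbours along with it, many fragments in such a run carry only
*collateral* signal. `chicfine` asks the fine-mapping question: which small
subset of fragments, if directly contacting the bait, explains the whole
local pattern of enrichment?

## The model

Counts N for each observed bait–prey pair are first adjusted by
zero-truncated negative-binomial (NB2, log link) regressions fitted within
ten distance bins, with log distance, log fragment lengths, a both-baited
indicator and transchromosomal bait activity as covariates. Normalized
randomized quantile residuals of these fits — *NB residuals* Y_bp — are
standard normal under the null.

For one bait b with F_b observed preys the residuals follow

    Y_bp ~ N(mu_bp, 1),    mu_bp = Σ_{q: γ_bq=1} β_bq · exp(−ω·d(p,q))

where γ_bq indicates a direct contact at fragment q, β_bq its strength,
d(p,q) the distance between fragment midpoints, and ω (fixed at 10⁻⁴·⁷ per
bp) the rate at which a contact's signal decays across its neighbours.
Priors: β_bq | γ_bq=1 ~ N(0, σ_β²) with σ_β ~ Uniform(0.01, 2), and
γ_bq i.i.d. Bernoulli(θ_b) with θ_b ~ Beta(1, F_b). The model-space prior
puts probability 1/2 on "no contacts" for every window size and marginal
prior odds 1/F_b on each fragment — an intrinsic multiplicity correction.

The posterior over (γ, β, σ_β) is sampled by reversible-jump MCMC (two
chains per bait, 5000 retained samples each at one per 1000 iterations, no
burn-in, extended until the inter-chain correlation of summaries exceeds
0.75). The headline statistic per prey is the **MPPC** — the marginal
posterior probability of contact, the proportion of retained samples in
which β_bp > 0.

## Worked example

```python
from chicfine import (
    SimConfig, simulate_fragment_map, simulate_counts,
    NegativeBinomialAdjuster, ContactFineMapper,
)
from chicfine.io import annotate_counts

cfg = SimConfig(n_baits=10, n_fragments=5000, n_chromosomes=2,
                window_bp=400_000, n_contacts_range=(1, 2), seed=5)
fragments = simulate_fragment_map(cfg)
counts, truth = simulate_counts(cfg, fragments)

residuals = NegativeBinomialAdjuster(n_bins=5, random_state=5).fit_transform(
    annotate_counts(counts, fragments))
mapper = ContactFineMapper(n_retained=1000, thin=100, random_state=5)
mapper.fit(residuals, fragment_map=fragments)

top = mapper.results_.sort_values("mppc", ascending=False).head(5)
print(top.to_string(index=False))
print(f"{mapper.percent_converged_:.0f}% of baits converged")
```

prints

```
 bait  prey     mppc  beta.post
 2973  2971 0.459167   0.926903
 3861  3912 0.414625   0.995591
 3861  3911 0.340750   0.827898
 2973  2970 0.300500   0.583920
 2028  1994 0.257500   0.417700
100% of baits converged
```

Checking against the simulation's truth table: fragment 2971 carries a
planted contact of bait 2973 (β_true = 4.9), and 3911 one of bait 3861
(β_true = 5.8). The remaining high-MPPC preys (3912, 2970, 1994) are
immediate neighbours of planted fragments: at 4 kb spacing the decay
kernel makes adjacent fragments nearly exchangeable, so the posterior
honestly splits contact probability across them instead of committing to
one — the fine-mapping uncertainty the MPPC is designed to express. Per
bait, `sum(mppc)` estimates the expected number of direct contacts.

The same pipeline is available from the shell:

```sh
chicfine simulate --config sim.yaml --out-dir data/
chicfine adjust --counts data/counts.csv --fragments data/fragments.csv \
    --bins 10 --seed 5 --out data/residuals.csv
chicfine fit --residuals data/residuals.csv --fragments data/fragments.csv \
    --samples 5000 --thin 1000 --seed 5 --out data/results.csv
chicfine run --config pipeline.yaml --out-dir run/   # end-to-end
```

`results.csv` has columns `bait, prey, N, residual, mppc, beta.post`;
`chicfine fit` also writes a per-bait convergence log (bait_id, rho,
iterations, converged).

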