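# Methods

## Model

Each reported soil biodegradation half-life is treated as one experiment.
For substance *i* with reported half-lives DT50_ij (days), the model is

    x_ij = log10(DT50_ij) ~ Normal(mu_i, sigma_min + sigma_i)

- `mu_i` — average log10 half-life of the substance, log(d).
- `sigma_i` — substance-specific experimental noise, log(d). It captures
  soil-to-soil variability, kinetic-model choice, and analytical error.
- `sigma_min` — minimal experimental variability shared by all
  substances, default **0.2 log(d)**. The effective likelihood sd is the
  *sum* `sigma_i + sigma_min`, not a quadrature combination; `sigma_min`
  acts as a floor that prevents overconfident fits when the few reported
  values happen to agree closely. The floor is informed by reference
  compounds with many observations (see `estimate_sigma_min`): compounds
  with more than 20 uncensored values have a mean log10 sd around
  0.4 log(d) in both real exports and prior-drawn synthetic cohorts, with
  individual compounds down to about 0.2, hence a conservative floor of
  0.2.

Substances are fitted independently; there is no hierarchical pooling and
no covariate model of experimental conditions (reported metadata are too
sparse to support one).

### Censoring

An incubation study of ~120 days with ~daily initial sampling cannot
reliably quantify half-lives below ~0.1 d or above ~1000 d (more than one
log unit of extrapolation). Observations are therefore classified as:

- LEFT at 0.1 d when the value is ≤ 0.1 d; RIGHT at 1000 d when ≥ 1000 d
  (boundary values count as censored — this convention matches how
  published counts of censored records are tallied);
- censored at a *local* threshold when the report comment states a bound
  (">365 days", "< 0.5 d", "≥ 40", ...). Bounds outside the global range
  are clipped to it. When the value and the comment both imply censoring
  in the same direction, the more informative bound wins (the larger one
  for RIGHT, the smaller for LEFT); contradictory directions fall back to
  the value-based rule with a logged warning.

A censored observation contributes `Phi((t - mu)/s)` (LEFT) or
`1 - Phi((t - mu)/s)` (RIGHT) to the likelihood, with
`s = sigma_i + sigma_min` and t the log10 threshold; its point value, if
any, is never used. Both terms are computed through the log-CDF
(`scipy.special.log_ndtr`) so deep tails stay finite. Interval censoring
is not modeled.

### Priors

| parameter | distribution | mean | sd | units |
|-----------|--------------|------|----|-------|
| `mu_i`    | normal       | 1    | 2  | log(d) |
| `sigma_i` | log-normal   | 0.4  | 0.4 | log(d) |

The `mu` prior is centered in the measurable range (−1 to 3 log(d)) with
an sd wide enough to cover it. The log-normal parameters are the mean and
sd of `sigma_i` *itself* (their units match sigma's); they are converted
to the underlying normal's location/scale by moment matching:
`s_ln² = ln(1 + (sd/mean)²)`, `m_ln = ln(mean) − s_ln²/2`, giving
`s_ln ≈ 0.8326`, `m_ln ≈ −1.2629` for the defaults. The alternative
reading — parameters of the underlying normal — is available via
`PriorSpec(sigma_params_are_log_scale=True)`.

### Sampling

The 2-D posterior is sampled with the Goodman–Weare affine-invariant
ensemble sampler, implemented in this package: proposal
`y = x_k + z (x_j − x_k)` with `z ~ g(z) ∝ 1/√z` on `[1/a, a]`, accepted
with probability `min(1, z^(d−1) exp(Δ log p))`, d = 2, stretch scale
a = 2.0 (the sampler family's standard default). The ensemble is updated
in two half-batches per iteration (each walker stretches toward a walker
of the complementary half), which preserves detailed balance and allows
vectorized density evaluation. Defaults: **10 walkers, 2000 iterations,
burn-in 100 iterations per walker** (so 19 000 pooled draws). "Burn-in of
100" is read as iterations, the conventional ensemble-sampler usage.
Walkers initialize from independent prior draws, redrawn (bounded
retries) if the density is −inf.

Reproducibility: every substance gets its own seed derived as a SHA-256
hash of `(global seed, canonical SMILES)` truncated to 31 bits, so results
are bit-reproducible and independent of processing order.

Posterior summaries: `mu_mean`, `mu_std`, `sigma_mean`, `sigma_std` are
the mean/sd of the pooled post-burn-in draws. `mu_std` is the uncertainty
of the inferred mean and always shrinks with added data; `sigma_mean`
estimates the spread of repeated experiments and does not.

### Persistence classification

Against a user-supplied regulatory threshold T (days; none is baked in —
thresholds differ by compartment, e.g. 40 d for water):

- `p_mean_exceeds` = fraction of mu draws above log10 T. A substance is
  nonpersistent at level 0.95 if this is ≤ 0.05 (the average half-life is
  below T with 95% probability).
- `p_experiment_exceeds` = posterior-predictive probability that one new
  experiment exceeds T, i.e. the draw-average of
  `Phi((mu − log10 T)/(sigma + sigma_min))`. Nonpersistent at level 0.95
  means 95% of experiments would indicate nonpersistence.

The decision level (default 0.95) is a parameter.

## Curation

- **Salt stripping.** Multi-component SMILES are split; components on the
  counterion list (alkali/alkaline-earth cations, ammonium, halides,
  hydroxide, water, sulfate/nitrate/phosphate/carbonate species,
  configurable) are removed and logged. If more than one *distinct*
  active component remains, the entry is a mixture and is dropped
  (mixtures are out of scope). The surviving component keeps its charge
  state — no neutralization is applied, so e.g. an acetate salt merges
  with free acetate but not with acetic acid. The counterion list
  replaces a manual per-entry judgement, which is why it is configurable
  and every stripped component is logged for audit.
- **Merging.** Records merge on canonical SMILES computed after removing
  stereochemistry (RDKit), so stereoisomers and duplicates collapse into
  one compound; observation lists concatenate, all names are kept as
  synonyms, and the lexicographically first name becomes the display name
  (a determinism choice). Compounds are annotated with InChIKeys.
- **Robustness.** Record-level failures (unparseable SMILES, nonpositive
  half-life, no value and no bound) skip the record with a logged reason
  and never abort a run; the curation report carries in/kept/dropped
  counts (with a conservation identity checked in tests), per-reason
  tallies, and the audit trails.

## Synthetic data generator

The generator emulates the statistical structure of a regulatory-report
export, with ground-truth labels the pipeline never reads:

- `mu_i ~ Normal(1, 2)`, `sigma_i ~ LogNormal(mean 0.4, sd 0.4)` — the
  same distributions the model uses as priors, so prior-drawn cohorts are
  exactly calibrated and credible-interval coverage is a sharp test.
- Per-substance sample sizes span 1–60: 45% of substances have 1–2
  values, 45% have 3–15, 10% have 16–60. This mirrors an export dominated
  by data-poor substances with a small reference-grade tail (and yields
  ~8 records per substance on average).
- Values beyond 0.1/1000 d are written verbatim; catching them is the
  censoring module's job.
- A fraction of records (default attempt rate 5%) passes through a
  simulated assay window: a record-local reporting limit is drawn
  independently of the value (lower limits 0.2–5 d with 85% probability,
  mirroring exports in which most comment bounds are lower bounds; upper
  limits ~30–900 d otherwise), and when the drawn value falls beyond the
  limit the record carries only a comment bound in one of several
  dialects (">x", "> x days", "≥ x", ...). Because the limit is
  independent of the value this is proper censoring, and the realized
  comment-bound rate (roughly 1–2% of records) is of the order seen in
  real exports.
- Optional decoy records exercise curation: a sodium-acetate salt, an
  enantiomer pair that must merge, a two-active-component mixture that
  must be dropped, and an unparseable SMILES.

What the generator does **not** emulate: experimental covariates (soil
properties, temperature), kinetic-model heterogeneity, non-normal
residuals, or correlated studies. Passing tests therefore demonstrate the
statistical machinery is correct under the model's own assumptions, not
that real half-life data follow a log-normal law.

## Numerical choices and problem sizes

- Densities are computed in natural log; all half-life quantities are
  base-10.
- The quadrature oracle used in tests integrates the unnormalized
  posterior on a 1001 × 1200 grid over mu ∈ [−9, 11], sigma ∈ (0, 10];
  truncation and discretization errors are ~10⁻³, far below the 0.05
  comparison tolerance.
- Validation problem sizes: oracle comparisons use 10 substance cases
  with ≤3 observations and 20 000-iteration chains (Monte Carlo error
  ≲0.01); calibration uses a 300-compound prior-drawn cohort at the
  default 2000-iteration setting; moment checks on the standard-normal
  target use ≥10⁴ iterations so Monte Carlo error stays well inside the
  0.05 band.
- Degenerate inputs: empty observation lists are an error at fit time;
  empty input tables produce empty outputs with a warning; all-invalid
  tables are an error.

## Known limitations

- Each substance is fitted independently; information is not shared
  across substances beyond the common prior and `sigma_min`.
- The censored likelihood treats local comment bounds as exact
  thresholds; vague comments ("slow degradation") are ignored.
- The counterion list approximates a curator's judgement; unusual salts
  with an unlisted counterion will be classified as mixtures and dropped
  (visible in the audit log).
- With a single censored observation the posterior is strongly
  prior-driven; `mu_std` honestly reports this, but the estimate should
  not be over-interpreted.
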