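# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Age transformations (`agetx`)

All clocks regress a transform f(age) on methylation and report DNAm
age by applying f⁻¹ to the linear predictor.

* **identity** — f(a) = a. Used for single-species clocks.
* **relative** — f(a) = a / L with L the species' maximum recorded
  lifespan (human 122.5 yr, naked mole-rat 37 yr, from the anAge
  compilation). Puts species with very different lifespans on a common
  [0, 1] scale.
* **loglinear** — f(a) = ln((a+k)/(m+k)) for a ≤ m and (a−m)/(m+k) for
  a > m, with m the species' age of sexual maturity and k > 0 an offset
  (default 1 yr) that keeps f finite at birth. Value and first
  derivative match at a = m (both branches have slope 1/(m+k) there),
  so f is C¹, strictly increasing, and exactly invertible; the inverse
  of a negative transformed value is a negative, prenatal-equivalent
  age, which is how reprogrammed samples can legitimately receive
  DNAm age < 0. This log-below-maturity / linear-above form is the
  standard construction for multi-species clocks; m and k are exposed
  as per-species configuration rather than hard-coded.

Inverses are exact to < 1e−9 over [0, 2L] (property-tested).

## Clock fitting (`clockfit`)

Elastic-net regression (scikit-learn coordinate descent) of f(age) on
raw, unstandardized beta values; mixing parameter α = 0.5 — the
conventional midpoint between ridge and lasso for methylation clocks —
is fixed, not tuned. The penalty strength λ is selected by tenfold
internal cross-validation minimizing mean squared error (minimum-MSE
rule, not 1-SE). Defaults that matter:

* `n_lambdas=20`, path stopping at λ_min = 0.01·λ_max, coordinate
  descent tolerance 1e−3, max 2,000 iterations. These give fits
  indistinguishable in CV accuracy from long paths at tight tolerance
  on studies of this size while keeping a 120-fold LOO under two
  minutes on one core.
* Only nonzero coefficients are stored, with per-CpG training medians
  for imputing missing betas at prediction time. A CpG entirely absent
  from a prediction matrix is an error, not silently imputed.
* iPSC samples are excluded from training by default (override flag),
  so reprogrammed samples are always out-of-sample.
* Outer CV (LOO, or tenfold balanced by species — each fold gets
  ~1/10 of every stratum) re-selects λ inside every outer fold; a
  held-out sample can never influence its own model, and a test
  verifies the held-out *label* has bit-zero influence on the held-out
  prediction. Fold assignment is seeded and recorded.

**A note on null-permutation LOO.** Under permuted labels, LOO
predictions collapse toward the training mean, and the training mean of
n−1 samples moves *against* the held-out value; LOO correlation under
the null is therefore negatively biased (down to r = −1 when the model
is intercept-only). This is a property of leave-one-out itself, not an
implementation artifact; the null test accordingly checks the absence
of *positive* skill and that the error is no better than mean-age
guessing.

## Aging EWAS (`ewas`)

Per CpG: Pearson r of beta with (transformed) age, pairwise-complete
when values are missing; Fisher z = atanh(r)·√(n−3) (sign = aging
direction); two-sided p from the correlation t-test on n−2 df. Both
framings are reported because downstream consumers use both. |r| is
clipped at 1−1e−15 so a perfectly linear CpG yields a large finite z
and a p at the numerical floor rather than infinities. Constant CpGs
(or < 4 complete pairs) are flagged invalid rather than dropped.

Meta-analysis is Stouffer's Z = Σwᵢzᵢ/√(Σwᵢ²), equal weights by
default (√n weights optional); a CpG missing in a stratum omits that
stratum. Top-CpG selection at p < 10⁻⁵ keeps up to 500 per direction,
ranked by smallest p with ties broken by |z| then CpG id
(deterministic). Set overlap is the exact upper-tail hypergeometric
probability; BH-FDR is available alongside the fixed thresholds. The
divergence screen takes two long-lived-species tables and one
short-lived table: a hit is significant (p < p_sig, default 10⁻⁵,
10⁻⁴ also in use) with the same sign in both long-lived species and,
in the short-lived species, either non-significant (p > 0.05; an
undefined statistic counts as flat) or — default rule — of opposite
sign (`flat_only` variant selectable, recorded in the output).

Calibration: under 200 replicate global-null studies of 10,000 CpGs,
the mean fraction of p < 10⁻⁵ is ≤ 2×10⁻⁵ (measured by the acceptance
script each run).

## Breeding-status analyses (`strata`)

* **Interaction test** — OLS of DNAm age on age, group and age×group;
  classical Wald t on the interaction, n−4 df. The estimated rate ratio
  is (β_age + β_interaction)/β_age. A numerically perfect fit (residual
  mean square < 1e−24 × scale) is resolved exactly: interaction ~0 →
  p = 1, otherwise p = 0. The DNAm ages fed in are LOO estimates by
  default; because a clock trained on queens may partially absorb their
  slower aging, the **male-trained / female-tested** design is also
  implemented (training strictly on males, then predicted age ~ age +
  queen in females, Wald test on the queen main effect, optional
  age-< 15 yr restriction).
* **Status EWAS** — per-CpG OLS beta ~ group + age, vectorized in
  closed form across CpGs (hat matrix computed once); Wald p on n−3 df.
  Near-collinearity of group and age (|r| > 0.999) warns but returns.
* **Sector classification** — stratified EWAS against ln(age) (samples
  with age ≤ 0 excluded and counted; no offset is added because the
  youngest usable animals are ≥ a few months old); a CpG is
  group-specific iff p < 10⁻⁴ in that group and p > 0.05 (or
  undefined) in the other, shared iff significant in both. The
  classification is exactly symmetric under label swap (tested).

Calibration at the study's blood design (n = 92 with 18 queens, DNAm
noise 1.5 yr): type-I error of the interaction test is inside the
binomial 99% CI of 0.05 over 500 null replicates; at a queen rate
factor of 0.6 the power at α = 0.01 exceeds 0.8 and the mean estimated
rate ratio recovers 0.6. These replicates simulate at the DNAm-age
level (age × factor + Gaussian noise): re-fitting an elastic net
hundreds of times would only add Monte-Carlo cost, not change the
distribution of the statistic being calibrated.

## QC classifiers (`qc`)

Random forest (500 trees by default, √p feature subsampling — the
conventional settings) on CpG features with out-of-bag error; OOB
predictions come from trees whose bootstrap excluded the sample.
Hierarchical clustering uses distance 1 − Pearson correlation between
sample profiles, average linkage, cut at height 0.04 by default; a
constant profile has no defined correlation and is rejected by sample
name. Note the inter-array correlation is itself an estimate over the
probe panel: on panels of only a few hundred CpGs its sampling noise
can exceed the 0.04 cut, so the QC validation runs on 1,500-CpG panels
(the real array has 37,492 probes).

## Synthetic studies (`simdata`)

The generator emulates the statistical structure of a multi-tissue
mammalian methylation-array aging study:

* Per-CpG baselines on the logit scale: islands low (N(−1.5, 0.5²)),
  non-island CpGs high (N(1.0, 0.8²)), matching the bimodal beta
  landscape with hypomethylated islands.
* A fraction of CpGs (default 10%) drift linearly with f(age) on the
  logit scale. `effect_scale` (default 2.0) is the typical *total*
  logit drift across the configured age range — internally divided by
  the transformed-age span so it means the same thing under any
  transform; per-CpG magnitudes are effect_scale × U(0.5, 1.5) (the
  effect-size distribution is a convention; nothing in the emulated
  design pins it down). Promoter/5'UTR/island age-CpGs gain methylation
  with probability `promoter_hyper_bias` (default 0.8), others 50/50.
* Tissue and sex effects are constant logit offsets (tissue: N(0,
  `tissue_offset_sd`²) per tissue × CpG; sex: ±2 logit on
  `n_sex_cpgs` marker CpGs, no age interaction).
* Queens (a configurable fraction of adult females) have their aging
  *slope* multiplied by `queen_rate_factor` on age CpGs — a rate
  effect, not a level shift — plus optional constant-offset queen
  marker CpGs for the status EWAS.
* Multi-species mode: species-specific baseline offsets over a shared
  conserved probe set; `frac_shared_probes` of age CpGs share one slope
  across species on the relative-age scale (these carry the promoter
  sign bias); the rest get independent per-species slopes with
  *unbiased* signs (half null) so unshared aging directions are
  uncorrelated between species. With ≥ 3 species, `frac_divergent` of
  the shared age CpGs are silenced in the shortest-lived species — the
  planted target of the divergence screen.
* Ages are uniform on the configured range (right-skew Beta(1,3)
  option, since breeding females in real colonies skew young); other
  species sample the same *relative*-age window.
* Noise is Gaussian on the logit scale (default sd 0.15), then
  inverse-logit, then clipped to [1e−6, 1−1e−6] — betas stay bounded
  with age-stable variance.
* Identical config + seed → byte-identical outputs (tested via file
  checksums).

Because the mean function passes through the inverse logit, a noiseless
age CpG is *monotone* but not exactly linear in f(age); its Pearson
correlation with f(age) is ~0.99+, not 1, and saturation near the clip
boundaries attenuates extreme effects. What passing tests show is that
the estimators recover planted logit-linear structure at realistic
effect/noise ratios; what they do not show is robustness to real-array
features the generator omits: batch/chip effects, probe cross-
hybridization, cell-composition shifts, non-Gaussian heteroscedastic
noise, and spatial correlation along the genome.

`synthesize_at_transformed_age` builds new samples from a study's
generative parameters at arbitrary transformed ages; passing a value
below f(0) emulates reprogrammed cells, which a clock trained on the
ordinary samples then places at negative DNAm age.

## Problem sizes used by the validation runs

Chosen as compact study conditions that still separate signal from
artifact: clock recovery at n = 120 samples × 2,000 CpGs (200
age-related, noise sd 0.15); dual-species LOFO10 at 2 × 60 noiseless
samples × 1,000 CpGs; EWAS null calibration at 200 replicates × 10,000
CpGs × 50 samples; planted-effect recall at 50 five-sigma CpGs among
1,950 nulls, n = 100; queen calibration at 500 null + 200 alternative
replicates of the n = 92 / 18-queen blood design; QC at 10 seeds × 60
samples × 1,500 CpGs.

## Known limitations

* The generator's logit-linear drift is the simplest monotone aging
  model; real aging trajectories can be nonlinear in age beyond what
  the transform captures.
* The status EWAS uses classical (homoscedastic) standard errors;
  beta-value variance shrinks near 0/1, so p-values at extreme
  baselines are mildly misspecified under heavy planted effects.
* LOFO10 stratifies only on one label (species by default); joint
  tissue × species balancing is not implemented.
* The hypergeometric overlap treats gene sets as exchangeable draws;
  no background correction for gene length or probe density (pathway
  enrichment is deliberately out of scope).
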