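# Methods

This note documents the models implemented in `fosnet`, the synthetic-data
generator that stands in for raw study data, the numerical choices, and the
limits of what the validation suite demonstrates.

## Density aggregation

Raw records are per-slide, per-hemisphere c-Fos⁺ counts with ROI areas.
For each (subject, region, slide) the hemisphere counts and areas are pooled
— density = (count_L + count_R)/(area_L + area_R) — and slide densities are
then **averaged** (not pooled counts over pooled area): the mean-of-slides
rule weights each slide equally regardless of its sectioned area.  Midline
nuclei may carry a single hemisphere record, which is used as-is.  A subject
missing a region is an explicit missing value; downstream correlations use
pairwise-complete observations with per-pair degrees of freedom.

## Negative-binomial mixed model

Counts aggregated per subject and region are modeled as

    y ~ NB(mean μ, size k),           Var(y) = μ + μ²/k
    log μ = x'β + u_litter [+ v_subject] + log(area)

with Normal random intercepts.  The NB size parameterization above is used
consistently in the generator and the fitter.  Design choices:

* **Per-region model** — fixed effects: intercept + treatment; random:
  litter only.  With a single aggregated observation per subject, a subject
  intercept is not identifiable separately from NB overdispersion and is
  absorbed by `k`.  The same logic is applied automatically in the pooled
  model when every subject contributes one observation.
* **Network (pooled) model** — fixed effects: intercept + treatment +
  region; random: litter and subject (subjects contribute one observation
  per member region).
* **Inference** — likelihood-ratio χ² with 1 df on the treatment term,
  comparing full and reduced fits.  Wald statistics are not used.

Fitting maximizes the Laplace-approximated marginal likelihood.  Random
effects are integrated litter-block by litter-block (blocks are scalar for
the per-region model and small dense systems — one litter plus its subjects
— for the pooled model); the inner mode is found by Newton iterations to a
step tolerance of 1e-11, and the outer parameters (β, log k, log σ) by
L-BFGS-B (ftol 1e-12) started from a short Poisson IRLS fit with a
moment-based dispersion estimate, with a Nelder-Mead polish on non-success.
σ is bounded below at e⁻⁶ ≈ 0.0025, where the model is numerically
indistinguishable from a no-random-effect NB regression; this makes the
boundary case smooth rather than special-cased.  The fit agrees with
statsmodels' `NegativeBinomial` ML estimate in that limit and with
`glmmTMB` (which uses the same Laplace approximation) to ~1e-4 on
coefficients, dispersion, litter SD and log-likelihood; both checks are in
the test suite.

Multiplicity over the region family uses Holm's step-down procedure
(family-wise error control); Benjamini–Hochberg is available by config.  The
family is all analyzed regions, as one family.  For regions with raw
0.05 < p < 0.1, Cohen's d — (mean₁ − mean₂)/pooled SD with (n−1) weights,
magnitude reported — is computed on densities as an effect-size screen.
A Wilcoxon signed-rank helper (normal approximation, zero differences
dropped, signed Z) covers paired behavioral comparisons.

## Connectome reconstruction

Within a group, Pearson r between all region pairs of the density matrix;
two-sided p from the t transform t = r·√((n−2)/(1−r²)).  The working
quantity is the signed determination coefficient sign(r)·r², so strong
negative couplings survive magnitude thresholding while remaining
distinguishable.  Zero-variance regions are excluded with a logged warning.

The anatomical adjacency (square 0/1 matrix over the same labels) is
validated for zero diagonal, symmetrized by logical OR if directed, and
applied as a mask: non-adjacent pairs become undefined.  Edges require
|sign(r)·r²| > 0.7 **and** p < 0.05, both strict, evaluated on unmasked
entries; edge sign is the sign of r and the weight is |sign(r)·r²|.  By
construction, masking-then-thresholding equals thresholding-then-
intersecting with the adjacency, and tightening either threshold can only
remove edges.  No multiplicity correction is applied across the 630 pair
tests at this stage (the thresholds themselves are the filter); this is
deliberate and logged.

The connected-vs-unconnected comparison is a Welch two-sample t-test on the
upper-triangle correlation values split by adjacency, using r by default
(|r| or signed r² by config), two-sided by default.

## Centralities and hubs

The functional graph is treated as unweighted and undirected; edge signs are
display attributes only.  Degree is the incident-edge count.  Betweenness is
B(v) = Σ_{u<w} σ_uw(v)/σ_uw over unordered distinct pairs, endpoints
excluded, unreachable pairs contributing zero (unnormalized; the
normalization is irrelevant to quantile-based hub calls but fixed for
reproducibility).  Hubs are regions **strictly** above the 0.8 quantile —
linear interpolation between order statistics, numpy's default — of both
degree and betweenness; the alternative sum rule (min-max rescaled degree +
betweenness, same quantile) is config-selectable.  With 36 regions the 0.8
quantile sits exactly on the 29th order statistic, so ties at the cutoff are
excluded, and an all-equal centrality vector yields an empty hub set.
Group degree distributions are compared with the Mann–Whitney U test
(two-sided, tie-corrected normal approximation).

## Synthetic generator

Per subject s (group g, litter ℓ) and region r:

    b_ℓ ~ N(0, litter_sd²)                     (one per litter)
    z_s ~ MVN(0, C_g)                          (one vector per subject)
    log μ_sr = baseline_r + lfc_r·[treated] + b_ℓ + latent_scale·z_sr
    total_sr ~ NB(μ_sr·area_r, size k)
    hemisphere/slide counts: equal-probability multinomial split of total_sr

Latent correlation enters on the log-mean (Gaussian-copula-like), keeping
counts marginally NB while inducing controllable cross-region correlation.
Litters are treatment-specific (the exposure is prenatal, applied to dams)
and subjects are assigned round-robin within their group's litters.

Defaults emulate the study design: 10 + 11 subjects, 14 litters, 36 regions
with nominal ROI areas (0.08–2.5 mm²) and baseline densities (50–250
cells/mm²), `litter_sd = 0.15` (≈15% between-litter variation on the log
scale), `nb_dispersion = 8` (counts ~35% overdispersed CV beyond Poisson),
`latent_scale = 0.3`, identity latent correlation, 2 slides for regions ≥
1 mm² else 1.  No variance components are published for the emulated study,
so these are design defaults judged realistic for immediate-early-gene
counts, fixed once; they are not calibrated to any dataset.  The default
treatment scenario reduces activation in treated animals by lfc −0.5 in six
strongly affected regions and −0.25 in nine marginal ones.

Helper correlation structures: `hub_factor_corr` (one-factor: hub loading
1.0, others 0.9, hence indirect 0.81 correlation between non-hub pairs —
forced by positive semidefiniteness once corr(hub, ·) = 0.9) and
`adjacency_supported_corr` (I + wA with w = 0.9/|λ_min(A)|, the near-maximal
strength for which support exactly on the adjacency stays PSD).

## Validation scenarios (`fosnet.scenarios`, `scripts/acceptance.py`)

* **Type-I / recovery** — single-region studies at full design scale with
  true lfc 0 or −0.7; 1000 and 500 replicates respectively.
* **Planted hub** — one-factor latent correlation 0.9 through IPN with
  latent scale 2.5, chosen so the *observed* density correlations match the
  planted 0.9 (at the default scale, NB noise attenuates hub-pair
  correlations below the R² threshold); anatomy is the pure star around the
  hub ("wired to all others", zero background), under which the anatomical
  mask removes all indirect (0.81) pairs — the configuration the masking
  step is designed for.  Recovery = the planted region is the *unique* hub
  of the control-group graph (n = 10).  With an Erdős–Rényi background
  anatomy instead, indirect edges survive the mask and several distractor
  regions share the top-quintile of both centralities, so unique recovery is
  rare; the analysis scripts demonstrate that harder regime.
* **Anatomically supported coupling** — latent correlation exactly on a
  random ER(0.3) adjacency at near-maximal support strength, null treatment
  effect; the Welch test runs on the full-cohort (n = 21) correlation
  matrix, which is coherent here because the latent structure is
  group-shared.  Shuffling the adjacency labels yields uniform p (a
  randomization null, robust to the dependence among the 630 pair
  correlations).

## Known limitations

* **Mild type-I liberality of the treatment LRT.**  The treatment effect is
  a between-litter contrast with only 14 litters; the χ²(1) reference for
  the likelihood ratio is slightly liberal in that regime, and the latent
  log-normal noise is not exactly the gamma mixing the NB assumes.  Across
  3000 null replicates the empirical rate at α = 0.05 was ≈0.065 (seed-block
  range 0.05–0.08).  This matches the reference implementation (glmmTMB
  agrees per replicate to ~1e-4), i.e. it is a property of the test at this
  design size, not of the optimizer.
* The generator emulates the *statistical* structure of bilateral count
  data, not images, section loss, or counting error; all slides share one
  rostrocaudal mean, hemispheres are exchangeable, and areas are fixed
  constants.  Passing tests therefore validate the inference machinery
  under the stated generative model, not robustness to histological
  artifacts or atlas misregistration.
* Betweenness-based hub calls on n ≈ 10 correlation graphs are noisy:
  single-replicate hub sets (as in the analysis scripts) can include
  distractors or miss the planted hub in one group; only the replicated
  recovery rate is a stable quantity.
* The NB mixed model assumes litter effects act identically on all regions
  of a pooled network model; region-by-treatment interactions are not
  modeled.
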