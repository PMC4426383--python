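# Methods

## Measurement model and scoring pipeline

The pipeline assumes background-subtracted per-colony GFP and tdTomato
intensities from a fluorescence scanner, arrayed on fixed-layout plates
(default 1536 format, 32 × 48). The per-colony reporter metric is
`m = log2(GFP/tdTomato)`; dividing by the constitutive channel cancels
colony-size-dependent intensity effects, so `m` tracks reporter
abundance per unit of cell material.

**Filtering.** Four rules, applied in order, each colony attributed to
the first rule that removes it:

| rule | definition | default |
|---|---|---|
| border | within `border_depth` of any plate edge | depth 1 |
| small_area | `area_px < area_min_px`, strict | 500 px |
| nonpositive | gfp or tdtomato ≤ `positive_floor` | 1e-9 |
| low_tdtomato | `ceil(q·n)` smallest tdTomato among prior survivors | q = 0.0005 |

The low-tdTomato cut is rank-based (deterministic, ties broken by input
order) and applied per condition/replicate across plates by default
(`tdtomato_scope`), since the quantile is defined per replicate
experiment; per-plate and global scopes are selectable. Note that
`ceil` removes at least one colony per group whenever the group is
non-empty.

**LOESS.** Degree-1 local regression with tricube weights
(statsmodels `lowess`), span 0.3, no robustness iterations, fitted
within each plate × replicate × condition group (minimum 20 colonies,
otherwise pass-through with a warning). The default covariate is log2
tdTomato (MA-style), which removes intensity-dependent trends; `spatial`
mode applies separable row-then-column passes for plate-surface
gradients. Residuals are re-centered to median 0 per group. Two
numerical facts the tests rely on: a local *linear* fit reproduces a
globally linear signal exactly (residuals at machine precision), and the
span bounds the spatial frequency that can be removed — a surface is
only removed well when the span window is small relative to its period
(for a full-period sinusoid across a 32-row plate, span ≈ 0.1; the 0.3
default targets the gentler monotone trends typical of intensity bias).
Span, mode and group minimum are configurable.

**Averaging and Z-scores.** The per-strain score is the arithmetic mean
of normalized values over all surviving colonies across replicates
(duplicate pinnings count as extra replicates); strains losing every
colony are reported missing, never imputed. Z-scores are computed per
condition against the mean and sample SD (n−1; population SD
selectable) of all scored strains, so they are location-invariant and
have mean 0, SD 1 by construction. Hits use strict inequalities at
z_hi = +2 / z_lo = −2.

**Enrichment.** Upper-tail hypergeometric p per GO term (scipy's
log-space survival function; verified against exact integer enumeration
for every universe N ≤ 25), term size counted as annotated *background*
genes, with strict size filters: > 2000 omitted in all aspects, < 10
omitted for BP only. BH step-up is applied within each aspect
separately (a pooled mode exists); significance is q < 0.05. The
background defaults to the screened universe restricted to annotated
genes; whole-annotated-genome is selectable. Annotations are taken as
given in the GAF — no ontology-graph propagation.

**Comparative subtraction.** A hit is *novel* when it belongs to none
of the catalog's yeast reference sets; membership is tested at gene
level on upper-cased systematic names. Conservation percentages use the
column's own gene count as denominator and round half-away-from-zero
(so 42.5% prints as 43%); empty columns report a dash rather than 0.

## Synthetic screen generator

The generator emulates the screen's statistical structure, not its
biology or imaging:

```
log2(GFP/td) = baseline + strain_dev + effect + spatial + bias + noise
```

with tdTomato log-normal (log2 mean 10, SD 0.5), per-colony Gaussian
noise σ0 = 0.25 log2 units (the dominant within-replicate variance; the
"calibration" tests check the per-replicate log-ratio SD reproduces σ0
within 5%), planted hits as independent Bernoulli(5%) per
strain × condition with effect +0.75 log2 units (3σ0), smooth spatial
surfaces (random low-order polynomial plus two Gaussian bumps, unit
variance × amplitude 0.1, drawn fresh per physical plate — each
replicate is a separate plate, so surfaces decorrelate across
replicates while the strain layout stays fixed), a bounded tanh
intensity bias (amplitude 0.1), and 1% dead colonies. Dead colonies get
tdTomato ~6 log2 units low, an extra 1.0 log2 units of ratio noise
(background subtraction dominates near zero signal) and small areas, so
the area and low-tdTomato filters have true positives.

Deliberate simplifications, and what passing tests therefore do and do
not show: hits are condition-independent draws (real screens share most
hits across conditions); effects are one-sided and fixed-size;
`strain_baseline_sd` — strain-to-strain biological spread fixed across
replicates — defaults to 0 so that planted effects are the only
between-strain signal and the global-null Z > 2 tail is exactly the
standard-normal 2.28%. Real screens have large biological spread: with
`strain_baseline_sd = 0.5` the simulated replicate correlations land in
the 0.73–0.95 band reported for real reporter screens (tested), at the
price of burying 3σ0 effects; recovery benchmarks and realism studies
are therefore run with different configurations, and a high planted-hit
recall on the default configuration does not certify recall under
realistic biological spread. Areas are truncated normals (clipped at
1 px); no growth kinetics, morphology or image artifacts are modeled.

The fixture bundle writer also emits *synthetic* stand-ins for the
external resources (toy GAF, toy prior-screen gene lists enriched for
planted hits, toy yeast→human ortholog map and human gene lists); they
exercise the interfaces and carry no real biology.

## Design choices and degenerate inputs

* Published screen protocols typically state only that log-ratios were
  LOESS normalized per replicate, leaving the covariate open; the
  package defaults to intensity mode because the ratio already corrects
  size effects and residual trends in practice track intensity.
* Z-scores use all scored strains (including any neutral controls) —
  with ≥ 3 strains required and a degenerate-distribution error on zero
  SD; constant groups and constant covariates in LOESS fall back to
  mean-fitting.
* Overlap significance between hit lists is a one-sided hypergeometric
  on a user-supplied universe (default: strains screened in both
  conditions); the choice of universe materially changes p and is
  always recorded in the output.
* Percent rounding is half-away-from-zero everywhere, at the caller's
  precision (0 decimals for summary tables, 1 for hit percentages).
* Readers never silently drop data: structural violations raise typed
  errors (configuration / integrity / format, mapped to CLI exit codes
  2/3/4), and empty-but-valid inputs warn.

## Problem sizes

The full-scale analyses and acceptance computations use 5000 mutants ×
4 replicates × 2 conditions (≈ 49k colonies, four 1536-format plates
per replicate), which runs in seconds; unit tests use 96-format toys.
The exact hypergeometric cross-check enumerates all ~44k valid
(N ≤ 25, K, n, k) tuples.

## Known limitations

* No ontology-aware enrichment (no term propagation, no DAG collapse);
  term lists are as annotated.
* Spatial LOESS is separable (row pass then column pass); strongly
  non-separable surfaces (e.g. diagonal gradients with interaction
  structure beyond row+col) are only partially removed.
* The generator's noise model is Gaussian on the log-ratio scale;
  heavy-tailed measurement error would make the fixed ±2 Z thresholds
  anticonservative.
* Essential-allele vs deletion matching in comparative analysis is by
  gene name only.
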