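# Methods

## Pipeline overview

Five small case/control expression cohorts → per-cohort moderated-t
differential expression → gene-wise Fisher inverse-chi-square combination →
FDR + median-fold-change signature selection → over-representation of the
signature against knockout consensus gene sets → per-receptor
consensual/opposite concordance classification.

## Per-cohort differential expression

Each cohort is a two-group comparison on the log2 scale. For gene g:
β̂_g = mean(case) − mean(control); s²_g is the pooled within-group variance
on d_g = n₁+n₂−2 df; v_g = 1/n₁+1/n₂. A zero sample variance is legal (it is
handled by moderation, never a division error).

The variance prior (d₀, s₀²) is fitted by the closed-form moment method on
log variances: e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2) is unbiased for
ln σ²_g; the mean of (e_g−ē)²·G/(G−1) − ψ′(d_g/2) identifies ψ′(d₀/2), which
is inverted by Newton iteration on the trigamma function (relative tolerance
1e-8, start 0.5 + 1/target, with 1/x and 1/√y asymptotic guards). When the
observed spread does not exceed sampling noise the prior df is capped at
d₀ = 1e6 — a numerically safe stand-in for infinity that avoids
special-casing the t CDF — and s₀² = exp(ē). Note exp(ē) carries the
finite-df bias correction exp(ln(d/2) − ψ(d/2)) relative to the raw variance
scale (≈1.31 at d = 4); this is the estimator's intended behaviour, not an
error. No array weights, trend, or robust variants are fitted; the plain
moderated t is the model.

Moderation: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g), t̃ = β̂/√(s̃²v), two-sided p
from Student t on d₀+d_g df (capped at 1e6). As d₀→0 this reduces to the
classical pooled t; the test suite asserts that limit at 1e-9 and
cross-checks the whole path against the Bioconductor reference
implementation on a small matrix.

## Meta-analysis

Probe-level tables are collapsed to genes by keeping each gene's lowest-p
probe verbatim; ties on p are broken by larger |β̂|, then lexicographically
smallest probe ID (determinism). Per gene measured in ≥2 cohorts
(single-cohort genes would be mislabeled "meta" results), the per-cohort
two-sided p-values combine as S = −2Σ ln pᵢ (pᵢ floored at 1e-300) referred
to χ²_{2k}. Fisher's method is direction-blind; per-study log2FCs are
reported so discordance stays visible, and direction comes solely from the
median log2FC (even counts: mean of the two middle values). BH FDR is
computed over all retained genes; the signature takes q < 0.05 and
|median log2FC| > 0.5, both strict.

## Enrichment

For query size C against a set of size B on a universe of N genes with
overlap a: one-sided hypergeometric upper tail P(X ≥ a); sample odds ratio
a·d/(b·c) with b = B−a, c = C−a, d = N−B−C+a (0 when a = 0, +∞ when a
margin is exhausted). N defaults to 20 000 because that background
reproduces published receptor-knockout odds ratios exactly from their
printed contingency inputs. The effective query size C is exposed as an
explicit parameter since published down-signature rows imply C = 287 while
the reported down-gene count is 267; the package takes C = |query| by
default and lets the caller override.

The z-score calibration draws n_random (default 100, seeded) uniform random
query lists of size C, ranks all terms by p on each list (ascending, ties by
term name, ordinal ranks), and records the per-term mean and SD of ranks;
z = (observed rank − mean)/SD (0 when SD = 0), so better-than-expected ranks
give negative z and positive combined score ln(p)·z. Since only the library's
own genes can overlap a term, the sampler draws the number of query genes
landing inside the library's gene union from the correct hypergeometric, then
samples those members uniformly — preserving between-term rank correlations
without materialising the unnamed remainder of the universe. The calibration
set of the original web service is unpublished, so z and combined scores are
a documented stand-in and are not expected to match published values
numerically; p, q and OR are exact. BH family = all terms of one library for
one query list.

## Concordance

A receptor's knockout Up/Down sets cross the disease Up/Down signature in
four cells, each tested as above with BH over exactly those four tests
(mirroring per-receptor reporting). Consensual = disease-up ∩ knockout-down
plus disease-down ∩ knockout-up: a gene that falls when the receptor is
removed and rises in disease is consistent with receptor-driven expression.
A receptor is "specific" when at least one consensual cell is significant
and no opposite cell is; "non-specific" when significant cells appear in
both orientations (significance *only* in opposite cells is also reported
as non-specific, the conservative reading of a gap in the definition);
"none" otherwise.

## Synthetic data: the stated world

The generator emulates the five-cohort design: group sizes (7,6), (2,2),
(5,5), (5,5), (16,3); 5 000 genes; 5% truly differential with |log2 effect|
~ |Normal(0.8, 0.2)| and random sign, identical across cohorts by default
(Fisher's method is direction-blind, so a shared sign keeps the median-lfc
selection interpretable; a heterogeneity_sd knob exists); gene variances
from s₀²·d₀/χ²_{d₀} with d₀ = 4, s₀² = 0.05 (typical microarray moderation
regime); baselines Normal(7, 1.5²) on the log2 scale (typical intensity
range, immaterial to tests); 10% of genes dropped per cohort to emulate
platform differences. Identical seed ⇒ bit-identical output.

What it does **not** emulate: probe-level structure with multiple probes per
gene, array-specific noise or batch effects, correlated genes,
normalisation artefacts, or real platform annotation. A green recovery test
therefore establishes that the statistics are implemented correctly and are
well calibrated under the assumed model — not that the pipeline is robust to
real microarray pathologies.

The companion knockout-library generator draws term gene sets (default size
245, matching the published set-size range) uniformly from the simulated
universe, planting round(frac × size) genes from the truly up-regulated
disease genes into one receptor's Down set — the consensual orientation — so
enrichment and concordance recovery are testable against ground truth. For
small simulated universes the pipeline scales the set size to ≤ a tenth of
the universe and the planted fraction to the available up genes.

## Numerical and design choices

- Log-scale heuristic on input: matrices with max > 50 are treated as linear
  intensities and log2(x+1)-transformed (cohort series mix scales; per-series
  preprocessing of the original sources is unspecified and deliberately not
  emulated beyond this).
- Gene symbols are uppercased and trimmed at every boundary; cross-source
  overlaps depend on symbol normalisation.
- One global pipeline seed fans out to stage seeds via a fixed offset table
  (simulate +0, KO library +101, enrichment +211, mod 2³¹−1).
- BH adjustment and the hypergeometric tail are delegated to statsmodels and
  scipy respectively, each verified against brute-force oracles in the test
  suite; the moderated-t, prior-estimation, Fisher-combination and
  rank-calibration code is authored here.
- Degenerate inputs: all-zero variances raise; empty signatures and empty
  GMT libraries are legal (logged); a missing knockout direction raises.

## Limitations

Only two-group, unpaired designs; no RNA-seq count models; no
effect-size (inverse-variance) meta-analysis or heterogeneity statistics;
no curated pathway library content is shipped — any GMT can be supplied.
The headline disease-signature gene counts of the motivating analysis depend
on the original cohorts and are not reproducible from synthetic data; the
package instead reproduces the arithmetic of every published worked example
and the statistical calibration of the method.
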