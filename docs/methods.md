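# Methods

## Model and assumptions

The package scores pathway activation in single samples and relates it to
drug sensitivity across a panel of cell lines.

**PAS.** The pathway activation strength of pathway *p* in case sample *s*
is `PAS_p(s) = Σ_n ARR_np · BTIF_n(s) · lg(CNR_n(s))` over member genes
*n*. The score assumes linear-scale, strictly positive expression
intensities (microarray-style), a panel of ≥2 normal control samples per
normalization, and that a gene's role in a pathway can be summarized by a
discrete signed weight. It deliberately ignores within-pathway topology:
every flagged member contributes additively.

**ARR alphabet.** The activator/repressor role takes values in
{−1, −0.5, 0, +0.5, +1} — repressor, weak repressor, neutral, weak
activator, activator. Five levels follow the established pathway-scoring
convention; a ternary restriction {−1, 0, +1} can be enforced at parse
time (`allowed_arr=ARR_TERNARY`). Gene identity is the upper-cased gene
symbol so that matrices from different array platforms join on a common
key.

**CNR and BTIF.** CNR is the case intensity over the arithmetic mean of
the control panel for that gene. BTIF gates each gene's contribution and
requires *both* criteria for "significantly perturbed": (i) the case value
lies outside the control tolerance interval — implemented as a two-sided
p-value of the single-observation z-score `(x − m̄)/(s·√(1+1/n))` referred
to a t distribution with n−1 degrees of freedom — and (ii) CNR < 0.66 or
CNR > 1.5. We resolve the flag's polarity as 1-when-perturbed: the score
exists to accumulate evidence from perturbed genes, and the opposite
reading would let only unperturbed genes (with log-ratios pinned near
zero) contribute. The literal inverted reading remains available as
`btif_polarity="literal"`; the two polarities partition the unfiltered
signed sum, which is also the limit of the default polarity when the
normal band shrinks to {1} and `alpha_gene` → 1 (with the band *widened*
instead, no gene is ever flagged and PAS is identically zero — the
gate is conjunctive, so only the shrinking-band limit recovers the plain
signed sum).

**Degenerate inputs.** Zero-variance control vectors make the tolerance
test undecidable; p is set to 1 (the statistical criterion never fires)
with a warning. Member genes absent from the matrix contribute 0 and are
counted in a per-pathway coverage fraction; a configurable minimum global
coverage aborts the run when the matrix and the database barely overlap.
Intensities are floored at 1e−6 so log-ratios stay finite. No per-pathway
size normalization is applied by default (the score is a plain sum);
`normalize_by_size=True` divides by member count.

**Multi-control normalization.** Results depend on the control panel, so
PAS is computed independently against each of several control datasets.
Case and control samples are quantile-normalized *jointly* per panel, on
the linear scale (a `log_before_quantile` switch normalizes log10 values
instead); joint normalization keeps CNR free of per-sample scale effects.
Ties in quantile normalization receive the mean of the reference values at
their tied ranks, making the transform idempotent.

## Dose–response and IC50

Viability is `(OD_t − OD_b)/(mean OD_c − OD_b) × 100 %`, raw (not
clipped). The mean viability per nonzero concentration is fitted with the
four-parameter logistic on log10 dose by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective). Initialization
is a fixed deterministic multi-start grid — hill ∈ {0.5, 1, 2} crossed
with the inflection at each interior dose — and the lowest residual sum of
squares wins, so fits are reproducible and invariant to replicate order.
The zero-dose wells only anchor the viability normalization.

Two IC50 readouts are produced: the fitted inflection (`IC50Result.ic50`,
the "relative" IC50) and the dose where the fitted curve crosses 50 %
viability (`ic50_absolute`). The tabulated `ic50_uM` used downstream is
the absolute IC50: when a drug never reaches its lower plateau inside the
ladder, the inflection trades off against the poorly determined bottom
parameter (errors of 2× are easy to produce), while the 50 % crossing
stays pinned by the observed data. Curves that never cross 50 % in range,
or whose inflection exceeds the top dose, are censored and reported as
"> max dose"; censored values are excluded pairwise from correlations
rather than imputed.

## Correlation screen and consensus

Pearson's product-moment r with the two-sided p from
`t = r·√((n−2)/(1−r²))`, df = n−2 (via `scipy.stats.pearsonr`), computed
on IC50 as provided; `log10_ic50=True` is available and usually advisable
for lognormally spread IC50s, but the default stays on the raw scale.
Raw p < 0.05 filters records (no multiple-testing correction by default;
Benjamini–Hochberg is a flag). Constant-PAS pathways have undefined r and
are skipped. n ≥ 3 complete pairs are required.

Within a dataset, support = number of control panels with a significant
record, tallied by sign; a pathway significant with both signs across
panels is *sign-discordant* and excluded from consensus but written to a
diagnostics table. Consensus requires support ≥ `min_support` (default 1)
in each dataset and, by default, a concordant sign across datasets. Note
the discordance rule makes consensus not strictly monotone in alpha: a
larger alpha can newly admit an opposite-signed record and knock a pathway
out; with signs fixed, monotonicity holds.

## Synthetic data generator

The generator emulates a two-dataset cell-line study at desk scale; its
defaults are the study conditions all simulation tests run under.

- 50 pathways with 5–15 member genes each (disjoint across pathways so a
  planted effect cannot leak), plus 400 pathway-free background genes;
  ARR drawn with weights (0.15, 0.10, 0.05, 0.10, 0.60) over
  (−1, −0.5, 0, +0.5, +1) — activator-dominated, as curated pathway
  databases are; 40 % metabolic.
- Expression: per-gene log10 baselines uniform on [1.5, 3.5] (linear
  30–3000), within-gene noise sd 0.05 log10 (~12 % CV). Control panels:
  11 sets of 4–33 samples for the first dataset, 3 sets of 2–10 for the
  second, each with a small systematic per-gene tissue shift
  (sd 0.02 log10) so panels genuinely differ.
- Planting: each case line has a latent activation a ~ N(0,1) of the
  planted pathway; member gene g is multiplied by `effect^(ARR_g · a)`
  with effect = 4, so activators rise and repressors fall, clearing the
  BTIF thresholds for |a| of order one.
- IC50 link: `log10(IC50) = 0.796 + 0.2·(r·z_a + √(1−r²)·z_e)` with the
  latent standardized in-sample and the noise orthogonalized against it,
  so the planted correlation r is exact in the sample, not just in
  expectation. The slope keeps true IC50s within the 0.8–50 μM ladder
  (~16-fold spread between extreme lines). Negative r plants
  activation→sensitivity and must surface as a "−" consensus sign.
- Plates: 4PL forward model (top 100, bottom 0, hill 1) on the standard
  ladder, quadruplicate, Gaussian OD noise with sd 5 % of the control OD
  (blanks a tenth of that).

Everything is a pure function of (scenario, seed) via seeded
`numpy.random.default_rng` streams; written bundles are byte-identical
across runs and round-trip losslessly through the package's readers.

What the generator does **not** emulate: probe-level chemistry, batch and
platform effects, correlated pathways sharing genes, heavy-tailed
expression outliers, or partial-inhibition drugs (bottom plateau above
zero). Passing tests therefore demonstrate that the pipeline's logic and
statistics are correct under its own assumptions, not that real
cross-platform datasets will behave as cleanly.

## Problem sizes in the test and acceptance runs

Simulation-based checks use the default scenario (50 pathways, 11 lines
per dataset, 11 + 3 control panels) over 50 seeds for end-to-end
recovery, 200 plates for noisy IC50 recovery, 1000 pathways × 12 lines
for null-screen calibration, and 441-point sweeps for the BTIF boundary —
sizes chosen so each stage's statistics are informative while a full run
of the suite plus the acceptance script completes in a few minutes on a
single CPU.

## Known limitations

- The tolerance-interval test treats the control panel as the reference
  distribution with estimated mean and sd; for panels of 2–4 samples the
  t-based p is crude, which mirrors how small real control sets behave.
- Consensus intersects exactly the datasets given; with more than two,
  a pathway must pass in all of them.
- Censored IC50s are dropped, not modeled; heavy censoring shrinks n and
  power.
- The screen's raw p < 0.05 threshold, chosen for fidelity to the
  published procedure, is anti-conservative across ~600 pathways × 4
  drugs; the BH flag exists for users who want error control.
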