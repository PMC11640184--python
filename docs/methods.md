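# Methods

## Calling model

A sample's methylation state at a CpG probe is summarized by the beta
value β ∈ [0, 1], the fraction of methylated signal. The probe call is

    methylated      if β ≥ c        (c = 0.30 by default)
    unmethylated    if β < c
    undetermined    if β is missing

and a panel of probes is **positive** when at least one probe call is
methylated, **negative** when no probe is methylated and at least one
call is determined, and **undetermined** only when every probe call is
undetermined. The 30% cutoff mirrors the 30%-methylated control DNA
used in melt-curve assays and the conventional 0.3 beta threshold on
HM450/EPIC arrays; the comparison is inclusive (≥) because the
operational rule labels a sample methylated when its profile is *equal
to or higher than* the 30% control. With continuous beta values the
boundary has probability zero, so the choice is immaterial in practice;
a strict-greater mode is exposed for completeness
(`strict=True` / `--strict-greater`).

Undetermined panel calls are an extension beyond the original
count-only data (which has no missing calls): they are excluded from
both the numerator and the denominator of every metric and reported in
a separate column, which is the conservative treatment.

## Comparison framings

The positive class is always the target diagnosis's primary tumors
(TP). Three negative classes are evaluated:

| framing         | negatives                                                  |
|-----------------|------------------------------------------------------------|
| `target_vs_nat` | the target's own normal adjacent tissues (NAT) only        |
| `all_tumors`    | TP samples of every other diagnosis (no normals)           |
| `all_samples`   | all other TP samples plus *all* NATs, including the target's |

## Metrics and intervals

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n,
PPV TP/(TP+FP), NPV TN/(TN+FN). Each is a binomial proportion and gets
an exact Clopper–Pearson 95% CI (beta-quantile form, via statsmodels);
the exact interval is conservative, with coverage ≥ the nominal level.
A metric with a zero denominator is reported as undefined (`NA`), never
as 0 — an empty class has no performance to fabricate. Percentages are
rendered with one decimal using round-half-up (81.25 → 81.3%), the
convention that matches the published cells; full-precision values are
kept alongside.

## ROC analysis

Scores default to the binary panel call (0/1), matching the published
analysis; `probe-count` (0–3 methylated probes) and `max-beta` scores
are documented extensions. The AUC is the midrank Mann–Whitney
statistic (ties counted half, O(n log n)); its variance is the DeLong
structural-components estimator from placement values V₁₀ and V₀₁,
Var = S₁₀/m + S₀₁/n. The CI is the normal approximation
AUC ± z·√Var truncated to [0, 1] (no bootstrap), and the p-value is a
two-sided Z-test of AUC ≠ 0.5. Zero variance (constant or perfectly
separating scores) is flagged `degenerate`: the CI collapses to the
point and the p-value is indeterminate rather than silently clamped.
For binary scores the AUC identity (sensitivity + specificity)/2 holds
exactly and is asserted in the tests; the variance is invariant under
strictly monotone score transforms.

## Embedded fixtures

The published per-group tallies (methylated/unmethylated per cohort ×
diagnosis × tissue) for both panels on the MS-HRM, GEO and TCGA cohorts
are embedded as constants, and `fixture_from_counts` materializes them
into per-sample panel calls: per group, exactly n_methylated positive
samples then n_unmethylated negative ones, zero-padded ids so
lexicographic order is construction order. A positive sample carries a
methylated call on the panel's first probe only — the fixtures encode
the *panel-level* call; per-probe patterns are not recoverable from
published counts. Where a diagnosis's tumor and normal blocks are the
same size (all of MS-HRM), pair ids link the k-th tumor with the k-th
normal, giving the 89 pairs of the experimental cohort. Tabulating any
fixture recovers its input counts exactly (an identity asserted over
all six cohorts).

One transcription quirk: the published LUAD count-table header repeats
the GAC probe ids; the primer table defines the LUAD panel
unambiguously as cg00907427/cg09590094/cg21929771, which the fixtures
carry.

## Known inconsistencies in the published percent tables

`methpanel reproduce` compares all 90 printed percent cells with their
recomputation from the published counts. 70 agree exactly; 20 cannot be
derived from the counts and are flagged (`match = False`), with the
recomputed value asserted in the tests instead:

- **GAC panel, MS-HRM, 5 cells.** "All tumor samples" specificity
  (printed 86.6%, recomputed 65/75 = 86.7%), accuracy (89.9% vs
  76/89 = 85.4%) and NPV (98.0% vs 65/68 = 95.6%); "All samples"
  accuracy (90.2% vs 160/178 = 89.9%) and NPV (98.1% vs
  149/152 = 98.0%). The printed all-tumors accuracy/NPV equal the
  recomputed all-samples values, suggesting a column shift.
- **LUAD panel, TCGA, all 15 cells.** The printed column is not
  reproducible from the TCGA counts (TP 358 methylated / 96
  unmethylated, NAT 32/0): e.g. sensitivity prints 88.1% but
  358/454 = 78.9%, and specificity prints 35.0% where the counts give
  0/32 = 0.0%. The printed cells are also mutually inconsistent with
  any single 2×2 at those class sizes; they were presumably computed
  on a different sample subset that the counts do not describe.

The pipeline reports recomputed values and does not chase the printed
ones. Both headline AUCs (0.8471 GAC, 0.8562 LUAD) and every other
printed cell reproduce exactly.

## Synthetic cohorts

`generate_cohort` draws each beta value from a two-component mixture:
with per-probe probability π the high-methylation component, else the
low one. Components are beta distributions parameterized by (mean m,
concentration κ) ↦ Beta(mκ, (1−m)κ), the natural reading for
methylation levels. Defaults, chosen once to look like normalized
array data: low component m = 0.08, κ = 30 (unmethylated loci sit near
zero with little spread); high component m = 0.70, κ = 15 (tumor
hypermethylation, broadened by cellularity and partial methylation).
Validation requires the component means to straddle the cutoff. The
continuous components never emit the exact cutoff value, so the
inclusive-≥ rule is exercised separately with handcrafted betas.

What the generator emulates: group-structured exceedance rates at the
cutoff, missing values, reproducibility under a single seed (NumPy
`default_rng`). What it does not: probe–probe correlation (probes are
independent, whereas neighboring CpGs co-methylate), array batch
effects, bimodality induced by tumor purity gradients, or melt-curve
noise. Passing calibration tests therefore validates the calling and
statistics machinery, not the biological realism of any particular
panel.

Calibration is checked against closed-form mixture tail masses
(`exceedance_probability`, verified against numeric quadrature of the
component densities) and against the analytic OR-panel positivity
1 − ∏(1 − q_p) under independence, at 10,000 samples per group within
3 binomial standard errors — a problem size that keeps the whole suite
in seconds while leaving Monte Carlo error far below the tolerances.

## Numerical choices

- Percent formatting: round-half-up at one decimal after snapping away
  float noise below 1e-9 of a percent; internal values full precision.
- Clopper–Pearson at boundary counts (0 or n): the undefined beta
  quantile is replaced by the exact endpoint 0 or 1.
- DeLong variance ≤ 1e-300 is treated as exactly degenerate.
- Tabulation row order: cohort, then the canonical diagnosis order
  (HCC, CCA, CRC, PDAC, GAC, LUAD), tumors before normals; count
  equality is order-insensitive.
- All randomness flows from one integer seed; identical configuration
  and seed give byte-identical pipeline outputs.

## Limitations

- Only one-vs-rest evaluation; no paired comparison of two correlated
  ROC curves, no partial AUC, no cross-validation.
- Inputs begin at beta values or binary calls; deriving calls from raw
  melt curves or IDAT files is out of scope, as is array
  normalization.
- The diagnosis vocabulary is an extensible registry seeded with the
  six entities above, so the pipeline applies beyond these two panels,
  but the embedded fixtures cover only the published panels/cohorts.
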