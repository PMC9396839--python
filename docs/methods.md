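# Methods

## Scope and model of the problem

`qsarval` validates a *finished* QSAR model: its inputs are the paired
experimental and model-calculated activities for a training split and a
test split, nothing upstream (descriptors, fitting) is touched.
Activities are treated as unitless log-scale quantities (pIC50 and the
like); no unit handling is attempted. The package computes the scalar
agreement metrics, applies five published criterion families, and can do
so either from raw per-compound data ("raw mode") or from a published
summary row ("summary mode").

## Metric definitions and conventions

**r².** The squared Pearson correlation between experimental and
calculated activity — symmetric in its arguments and invariant to affine
rescaling. A perfectly anti-correlated prediction therefore also scores
r² = 1; since every criterion implicitly assumes positive association,
the metric set carries the correlation's sign as a separate flag rather
than folding it into r².

**Through-origin statistics.** K and K′ are the closed-form
least-squares slopes through the origin,
`K = ΣYY′/ΣY′²` and `K′ = ΣYY′/ΣY²`. The forward coefficient of
determination is `r₀² = 1 − Σ(Y − K·Y′)² / Σ(Y − Ȳ)²`; it can never
exceed r², because the origin constraint only adds residual error
relative to the intercept model. For the reverse direction the
literature is inconsistent, so `r0prime_sq_eq4` takes a convention tag:

* `printed` — the residual `Y − K′·Y′` against the centered total sum of
  squares of Y, exactly as some papers typeset it. Since K′ is the
  wrong-direction slope for that residual, this form goes strongly
  negative for biased or rescaled predictions.
* `swapped_centered` (default) — the standard reverse-axis form,
  `1 − Σ(Y′ − K′·Y)²/Σ(Y′ − Ȳ′)²`. This is the default because the
  printed form is mathematically bounded above by the forward `r₀²`,
  yet published reverse-direction values exceed it for several models —
  so the printed equation cannot be what produced those values.
* `uncentered` — same residual over `ΣY′²`; algebraically identical to
  the textbook uncentered form below.

The textbook uncentered through-origin statistic
`r₀² = (ΣYY′)²/(ΣY²·ΣY′²)` is direction-symmetric and satisfies the
exact identity `K·K′ = r₀²`, which the test suite asserts to 1e−12
relative tolerance. For log-activity data far from zero it is close to 1
regardless of model quality, which is precisely why r²m computed from it
is so often undefined.

**r²m.** `r²m = r²(1 − √(r² − r₀²))` with the forward centered `r₀²`.
When `r² < r₀²` the metric is undefined and the function returns a typed
`ND` sentinel — a value, not an error and not NaN — so downstream
verdicts can distinguish "undefined" (fails the criterion, reported as
ND) from "computed and failed".

**CCC.** Lin's concordance correlation coefficient in its summation
form, `2·S_xy / (S_xx + S_yy + n(x̄ − ȳ)²)` with centered sums. One
published rendering of the denominator's last term is dimensionally
inconsistent (it subtracts a mean from a single observation inside a
term multiplied by n); the standard Lin form is used, which reproduces
the published per-model CCC values where they can be checked.

**Error statistics.** Absolute errors are `|Y − Y′|` per compound. The
summary SD uses the sample (n−1) denominator by default (`ddof=0`
selectable) — the convention of mainstream statistics software; the
frequency bins are `[0, 0.1)`, `[0.1, 0.2]`, `(0.2, ∞)` with boundary
values in the closed middle bin. The train-vs-test comparison is a
two-sided independent two-sample t-test on the absolute-error sequences,
Student (pooled) by default with Welch behind a flag, because the source
comparisons specify only "independent t-test". Degenerate case: both
groups zero-variance with equal means gives p = 1 by convention, with
unequal means p = 0.

## Criterion application

All threshold comparisons are strict exactly as published
(`>`, `<`, `≤`): r² > 0.6; 0.85 < K (or K′) < 1.15; ratio < 0.1 with
negative ratios passing (they arise legitimately when r₀′² > r²,
and are never clipped); r²m > 0.5 with ND failing; CCC > 0.8;
p > 0.05. The method-5 classifier uses only AAE, SD and the training
range — the empirical observation that low-r² models also classify BAD
is not made a rule. GOOD and BAD are mutually exclusive by construction
(0.1 < 0.15, 0.2 < 0.25). No composite overall score is produced; the
five verdicts are reported side by side because their disagreements are
the scientifically interesting output.

Summary mode computes everything derivable from a summary row (r²,
ratios, r²m, method 5) and marks sub-checks that need raw data (slopes,
CCC, p-value) *unavailable* rather than guessing; published reference
values can be supplied to fill them, which is how the embedded 44-model
comparison evaluates methods 1, 3 and 4.

## The embedded 44-model tables

The package embeds two transcriptions: the summary-input table
(split sizes, r², the three r₀² variants, AAE ± SD per split, training
range) and the published derived-value table (K/K′, ratio terms, r²m,
CCC, p-values, method-5 thresholds and letters). A SHA-256 checksum test
freezes both against silent drift. A numerical audit found eleven
derived cells in the published table inconsistent with the table's own
inputs beyond what input rounding can explain (e.g. a 0.15×range cell of
0.58 where the same range yields 0.56 in another row; range-multiple
cells consistent with a range of 13.48 where the input table prints
14.46). These are enumerated in `tables.TABLE2_PRINT_ERRATA` with the
values the inputs imply and excluded from the cell-level agreement test;
none of them affects any verdict, letter or headline count. One model
(row 30) sits exactly on the `AAE + 3·SD = 0.2·range` boundary where the
strict `≤` gives GOOD but the published letter is MODERATE; it is the
single documented letter exception. The published claim that every
CCC-valid model also passes the slope/ratio rules holds with one
exception (model 27, ratios 0.278/0.101 against the strict 0.1
threshold), which the agreement test documents explicitly.

Comparisons of recomputed against published cells use ±0.01 plus
first-order propagation of the inputs' printed quantisation (±0.0005 for
3-decimal cells, ±0.005 for the 2-decimal range): ratios with small r²
denominators (one model has r² = 0.088) amplify input rounding far
beyond ±0.01, and the comparison can only be as precise as its inputs.

## Synthetic data generator

The generator emulates the (experimental, calculated) pair structure the
criteria consume. Experimental activities are uniform on a stated range;
calculated values are truth + constant bias + noise, with an optional
`floor(fraction·n)` subset shifted by a fixed amount to emulate outlier
compounds. Defaults (50 train / 15 test compounds, a 4-log-unit activity
range, noise SD 0.3, no bias, no outliers) mirror a typical model in the
44-model collection, where training sets run ~20–90 compounds, test sets
~4–22 and training ranges cluster near 4 log units. Noise is Gaussian by
default; a scaled Student-t (3 df) option emulates the outlier-inflated
error SDs seen in several published models. A single integer seed fully
determines a dataset; parameter grids derive the dataset at linear index
i from `seed + i`.

What the generator does *not* emulate: descriptor-driven error
correlation, heteroscedasticity across the activity range,
activity-cliff structure, or the selection effects of real
train/test splitting. Passing the synthetic tests therefore shows the
criteria respond correctly to bias, spread and contamination — not that
any particular real model is valid.

Known calibration used in tests: with Gaussian noise of SD σ and no
outliers the expected AAE is σ√(2/π) (mean of a half-normal), checked at
n = 10,000 within three standard errors.

## Numerical choices

Internal computation is double precision throughout; rounding to the
published 2–3 decimals happens only at render time, half-away-from-zero
(matching the published tables rather than banker's rounding). Degenerate
inputs (constant vectors, all-zero vectors, non-positive ranges, r² = 0
in the ratio rule) raise typed errors rather than returning NaN; ND is
reserved for the one case where "undefined" is itself a reportable
result. Centered metrics require n ≥ 3, slopes and the uncentered form
n ≥ 2.

## Problem sizes

The default test suite and the reproduction script run at desk scale: the
44-row summary tables, synthetic datasets of ≤ 10,000 compounds for the
calibration checks, 1,000-vector oracle sweeps, and 100–200 replicate
Monte-Carlo property runs. The whole suite completes in a few seconds on
one CPU.

## Known limitations

* The raw per-compound data behind the 44 published models are not
  redistributable with the package; raw-mode reproduction of the
  per-model CCC/AAE/p-value columns requires placing that archive under
  `data/additional_file_1/` (standard CSV schema, one file per model).
  Until then those checks fail loudly rather than being silently skipped.
* Only two-split (train/test) designs are supported; cross-validation
  statistics and applicability-domain analysis are out of scope.
* The criteria are applied to point predictions; prediction uncertainty
  is not modelled.
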