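# qsarval

External-validation criteria for QSAR regression models.

A QSAR (quantitative structure–activity relationship) model is only
useful if it predicts the activity of compounds it has never seen, so a
trained model is judged on a held-out test set. The literature offers
several competing criteria for that judgement, and they frequently
disagree about the same model. `qsarval` implements the five most widely
used criterion families side by side, renders per-model verdicts with the
exact numeric comparison behind every sub-rule, and reproduces a published
comparison of 44 literature models from summary tables embedded in the
package. It is aimed at QSAR practitioners validating their own models and
at methodologists studying the criteria themselves.

## The five criterion families

Let `Y_i` be the experimental and `Y'_i` the calculated activity of test
compound `i` (log scale), `r²` their squared Pearson correlation, and
`K = Σ Y Y′ / Σ Y′²`, `K′ = Σ Y Y′ / Σ Y²` the slopes of the least-squares
regressions through the origin in the two directions.

1. **Golbraikh–Tropsha rules.** Valid iff `r² > 0.6`, *and*
   `0.85 < K < 1.15` or `0.85 < K′ < 1.15`, *and*
   `(r² − r₀²)/r² < 0.1` or `(r² − r₀′²)/r² < 0.1`, where `r₀²`/`r₀′²`
   are the coefficients of determination of the through-origin fits.
   Negative ratios satisfy the strict `< 0.1` comparison.
2. **Roy's r²m.** `r²m = r²(1 − √(r² − r₀²))`, valid iff `r²m > 0.5`.
   When `r₀² > r²` the square root is undefined and the metric is
   reported as the typed sentinel `ND` (which fails the criterion).
   Because several computational conventions for `r₀′²` circulate, the
   reverse-direction form is an explicit parameter
   (`printed` / `swapped_centered` / `uncentered`).
3. **Concordance correlation coefficient.** Lin's
   `CCC = 2 S_xy / (S_xx + S_yy + n (x̄ − ȳ)²)`; valid iff `CCC > 0.8`.
   Unlike `r²`, CCC is driven toward 0 by constant bias.
4. **Training-vs-test error comparison.** Two-sided independent t-test
   (Student pooled by default, Welch optional) on the per-compound
   absolute errors `|Y − Y′|` of the two splits; valid iff `r² > 0.6`
   and `p > 0.05`.
5. **MAE / training-range classification.** With `AAE` and `SD` the mean
   and standard deviation of the test-set absolute errors and `R` the
   training-set activity range: GOOD iff `AAE ≤ 0.1·R` and
   `AAE + 3·SD ≤ 0.2·R`; BAD iff `AAE > 0.15·R` or `AAE + 3·SD > 0.25·R`;
   MODERATE otherwise.

## Worked example

`python examples/reproduce_comparison.py` recomputes the 44-model
comparison from the embedded summary tables and prints:

```
models evaluated:                 44
r2 below 0.6:                     7
invalid under slope/ratio rules:  11
rm2 above 0.5:                    26
published CCC above 0.8:          28
error t-test criterion passed:    26
MAE/range classes (published):    {'G': 17, 'M': 7, 'B': 20}
  as percentages:                 {'G': 39, 'M': 16, 'B': 45}
```

Reading: 7 of the 44 published models fail the basic `r² > 0.6` screen;
the full Golbraikh–Tropsha rule set rejects 11; 26 clear the `r²m`
threshold and 26 the error t-test; and the range-scaled error classifier
calls 45 % of the models BAD and 39 % GOOD. The other examples evaluate a
single model end to end (`evaluate_one_model.py`), show how the `r₀′²`
conventions diverge on biased predictions (`metric_conventions.py`), and
sweep bias/outlier grids to show which criteria respond to which error
structure (`error_structure_tour.py`).

From Python, a single model is three lines:

```python
from qsarval import SyntheticSpec, generate_dataset, evaluate_model
report = evaluate_model(generate_dataset(SyntheticSpec(bias=0.5, seed=42)))
print({m: v.outcome for m, v in report.verdicts.items()})
# {'m1_golbraikh_tropsha': 'valid', 'm2_rm2': 'valid', 'm3_ccc': 'valid',
#  'm4_error_ttest': 'valid', 'm5_mae_range': 'bad'}
```

Real data goes through the same pipeline via a per-model CSV with columns
`compound_id,split,y_exp,y_calc` (`split` ∈ {train, test}):

```sh
qsarval evaluate --data model.csv --out report.json
qsarval batch --dir models/ --out table.tsv
qsarval reproduce --fixture table1 --out table2_repro.tsv
qsarval synth --spec spec.json --out model.csv
```

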