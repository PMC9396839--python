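"""Evaluate a single model's external validity end to end.

Generates a synthetic model with realistic noise plus a constant
calibration bias, then runs all five criterion families and prints the
verdicts. The bias leaves r² untouched but drags down the agreement
metrics — exactly the disagreement pattern the criteria exist to expose.
"""

from qsarval import SyntheticSpec, evaluate_model, generate_dataset, table2_row

spec = SyntheticSpec(n_train=50, n_test=15, noise_sd=0.3, bias=0.5, seed=42)
dataset = generate_dataset(spec)
report = evaluate_model(dataset)
row = table2_row(report)

print(f"model: {report.model_id}  (train n={dataset.train.n}, test n={dataset.test.n})")
print(f"r2={row['r2']}  K={row['k']}  K'={row['k_prime']}  "
      f"rm2={row['rm2']}  CCC={row['ccc']}  p={row['p_value']}")
print(f"test AAE={row['aae_test']} +- {row['sd_test']}  "
      f"training range={row['training_range']}")
for mid, verdict in report.verdicts.items():
    print(f"  {mid:22s} -> {verdict.outcome}")
print()
print("The 0.5-log-unit bias barely moves r2 (scatter is unchanged), and the")
print("correlation-based rules still pass the model; but it inflates every")
print("absolute error, so the range-scaled error classifier calls the same")
print("model BAD and the concordance coefficient drops well below its")
print("unbiased value.")
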