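"""How the through-origin r0'^2 conventions diverge.

The reverse-direction through-origin coefficient of determination has
several published computational conventions that agree for well-behaved
models but diverge wildly once predictions are biased — the root of the
ND (undefined) entries that plague the rm2 metric.
"""

from qsarval import (
    ActivityPairs,
    Eq4Convention,
    ND,
    r0prime_sq_eq4,
    r0sq_eq3,
    r0sq_eq5,
    rm_squared,
    squared_correlation,
)

# a model with good rank order, mild scatter and a systematic +0.8 shift
y_exp = [5.0, 5.6, 6.1, 6.7, 7.2, 7.9, 8.4]
y_pred = [5.9, 6.3, 7.1, 7.4, 8.1, 8.6, 9.3]
pairs = ActivityPairs(y_exp, y_pred)

r2 = squared_correlation(pairs)
print(f"r2                = {r2:.3f}   (blind to the bias)")
print(f"r0^2 (centered)   = {r0sq_eq3(pairs):.3f}   (through-origin fit, forward)")
for conv in Eq4Convention:
    print(f"r0'^2 [{conv.value:16s}] = {r0prime_sq_eq4(pairs, conv):8.3f}")
print(f"r0^2 (uncentered) = {r0sq_eq5(pairs):.3f}   (equals K*K'; near 1 for any "
      "log-scale data)")

rm_centered = rm_squared(r2, r0sq_eq3(pairs))
rm_uncentered = rm_squared(r2, r0sq_eq5(pairs))
print()
print(f"rm2 from centered r0^2:   {rm_centered if rm_centered is ND else round(rm_centered, 3)}")
print(f"rm2 from uncentered r0^2: {rm_uncentered if rm_uncentered is ND else round(rm_uncentered, 3)}")
print()
print("With the uncentered convention r0^2 routinely exceeds r2, making")
print("rm2 undefined (ND) — which is why the convention choice matters and")
print("is an explicit, recorded parameter here rather than a silent default.")
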