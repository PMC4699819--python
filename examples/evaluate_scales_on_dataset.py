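"""Compare propensity scales on an observed-Rh benchmark.

Evaluates every built-in scale (plus the context-dependent composite) on a
synthetic benchmark: mean absolute error, predicted-vs-observed R², and the
correlation of length-normalized error with net charge density.
"""

import ppiirh

records, observed = ppiirh.synthetic_idp_dataset(rng_seed=7)

print(f"{'scale':<12} {'mean|err| (Å)':>14} {'R²(pred,obs)':>13} {'R²(nerr,ncd)':>13}")
for name in ("null", "kallenbach", "creamer", "hilser", "static"):
    ev = ppiirh.evaluate_dataset(records, observed, ppiirh.load_builtin_scale(name))
    print(f"{name:<12} {ev.mean_abs_error:>8.1f} ± {ev.sd_abs_error:<4.1f}"
          f"{ev.r2_pred_obs:>12.3f} {ev.r2_nerr_ncd:>13.3f}")
ev = ppiirh.evaluate_dataset(records, observed, "composite")
print(f"{'composite':<12} {ev.mean_abs_error:>8.1f} ± {ev.sd_abs_error:<4.1f}"
      f"{ev.r2_pred_obs:>12.3f} {ev.r2_nerr_ncd:>13.3f}")

print(
    "\nLow mean error with high R² marks a scale whose propensities match the "
    "hydrodynamic data;\nthe null (random-coil) scale underpredicts every Rh. "
    "R²(nerr,ncd) flags error structure\nexplained by net charge, which the "
    "PPII-only model does not capture."
)
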