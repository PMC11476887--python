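"""Two-sample MR for one gene: instrument selection to sensitivity cascade.

Simulates a gene with 10 cis-eQTL instruments and a true causal effect of
0.3 (per exposure SD) on a continuous outcome, harmonises corrupted
summary statistics, and runs every estimator plus the sensitivity checks.
"""

import dataclasses

from exmr import calibration, ivselect, mrcore

hset = calibration.simulate_instrumented_gene(
    seed=1, theta=0.3, n_exp=5000, n_out=50_000, k=10, flip_fraction=0.1)
print(f"{len(hset)} instruments retained after harmonisation "
      f"(audit actions: "
      f"{sorted({a['action'] for a in hset.audit})})")

steiger = ivselect.steiger_filter(hset)
results, sens = mrcore.run_gene(hset, steiger=steiger, n_boot=500, seed=1)
for r in results:
    lo, hi = r.ci95
    print(f"{r.method:16s} estimate={r.estimate:+.3f} "
          f"[{lo:+.3f}, {hi:+.3f}] p={r.p:.2e}")
print(f"pve (exposure variance explained by IVs): {results[0].pve:.3f}")
print(f"Egger intercept p={sens.egger_intercept_p:.2f} "
      f"(pleiotropy; should not reject)")
print(f"Cochran Q p={sens.q_ivw_p:.2f} (heterogeneity; should not reject)")
print(f"Steiger: direction_ok={steiger.direction_ok} p={steiger.p:.1e}")
# All estimators should bracket the true effect 0.3; the sensitivity
# statistics should stay quiet because the instruments are valid.
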