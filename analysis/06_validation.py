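#!/usr/bin/env python
"""Monte-Carlo validation of the estimators and specification tests.

Runs scaled-down versions of the replicate studies: recovery of a known
effect under unmeasured confounding (IV vs. OLS, depth 7 vs. depth 1), the
2SLS/Wald-ratio oracle agreement, DWH size under the null, and LM
calibration for pure-noise added instruments.  The full-size studies run in
scripts/acceptance.py.
"""

import json
from pathlib import Path

from prefiv.experiments import (
    confounding_recovery_study,
    dwh_calibration_study,
    lm_noise_study,
    wald_oracle_check,
)

RESULTS = Path("results/analysis")
RESULTS.mkdir(parents=True, exist_ok=True)

r = confounding_recovery_study(n_reps=40, seed=1)
d = dwh_calibration_study(n_reps=200, seed=1)
l = lm_noise_study(n_reps=200, seed=1)
w = wald_oracle_check(n_datasets=300, seed=1)

out = {
    "recovery": {k: round(v, 4) for k, v in r.items() if isinstance(v, (int, float))},
    "dwh_null_rejection_rate": round(d["rejection_rate"], 4),
    "lm_noise_mean": round(l["mean_statistic"], 3),
    "wald_oracle_max_abs_diff": w["max_abs_diff"],
}
(RESULTS / "validation.json").write_text(json.dumps(out, indent=2))

print(f"true effect {r['true_effect']}: IV mean {r['mean_iv1']:.2f} "
      f"(MC SE {r['mc_se_iv1']:.2f}), OLS mean {r['mean_ols']:.2f} — the "
      "instrument removes the confounding the naive contrast absorbs")
print(f"depth-7 SE <= depth-1 SE in {100*r['share_iv7_se_le_iv1']:.0f}% of replicates")
print(f"DWH null rejection rate {d['rejection_rate']:.3f} (nominal 0.05)")
print(f"LM mean for 6 noise instruments {l['mean_statistic']:.2f} (df 6)")
print(f"2SLS vs Wald ratio max |diff| {w['max_abs_diff']:.2e}")
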