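#!/usr/bin/env python
"""Generate the synthetic physician-clustered prescribing population.

Writes the three raw tables (prescriptions, patients, outcome events) plus
the latent ground truth to scratch/data/ for the downstream analysis steps,
and prints the headline features of the simulated world.
"""

import json
from pathlib import Path

from prefiv.simulate import SimulationConfig, generate_population, write_tables

OUT = Path("scratch/data")
RESULTS = Path("results/analysis")

config = SimulationConfig(seed=20260928)  # defaults: 500 physicians x 100 patients

prescriptions, patients, outcomes, truth = generate_population(config)
write_tables(OUT, prescriptions, patients, outcomes, truth)

idx = prescriptions[prescriptions["patient_id"] > 0]
share_tca = float((idx["drug_class"] == "TCA").mean())
summary = {
    "n_physicians": config.n_physicians,
    "n_patients": len(patients),
    "n_prescription_rows": len(prescriptions),
    "n_outcome_events": len(outcomes),
    "comparator_share_tca": round(share_tca, 4),
    "true_risk_difference_per_100": truth.true_effect,
    "seed": config.seed,
}
RESULTS.mkdir(parents=True, exist_ok=True)
(RESULTS / "simulation.json").write_text(json.dumps(summary, indent=2))

print(f"wrote {len(prescriptions)} prescription rows for {len(patients)} patients "
      f"({config.n_physicians} physicians) to {OUT}/")
print(f"TCA share {share_tca:.1%}; {len(outcomes)} outcome events; "
      f"true effect {truth.true_effect} per 100")
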