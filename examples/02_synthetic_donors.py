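"""Generate a synthetic PAS cohort, train one surrogate, calibrate.

Shows the raw generator traces, the trained network's closed-loop
rollout fidelity, and the cohort-wide release-threshold calibration.
"""

import numpy as np

from thrombosim import (CohortConfig, calibrate_thresholds, generate_cohort,
                        rollout, simulate_pas_traces, train_donor_nn)
from thrombosim.donors import apply_hill, default_conditions, simulate_response

cfg = CohortConfig()
donors = generate_cohort(cfg, seed=1)
print(f"cohort of {len(donors)} synthetic donors; collagen response span "
      f"{max(d.agonists['convulxin'].response(10.0) for d in donors) / min(d.agonists['convulxin'].response(10.0) for d in donors):.1f}x")

d = donors[-1]
pas = simulate_pas_traces(d, default_conditions(cfg), config=cfg)
print(f"PAS dataset: {len(pas.conditions)} conditions x {pas.traces.shape[1]} s")

model = train_donor_nn(pas, training_seed=d.seed)
print(f"trained surrogate: held-out rollout NRMSE "
      f"{model.provenance['holdout_nrmse']:.3f} (of the PAS dynamic range)")

ref = simulate_response(d, {"convulxin": 10.0}, 256)
pred = rollout(model, {"convulxin": 10.0}, 256)
print(f"collagen-contact trace: generator peak {ref.max():.2f} uM, "
      f"network rollout peak {pred.max():.2f} uM")

# full-cohort calibration (trains the remaining donors; a few minutes)
cohort = [model if dd is d else
          train_donor_nn(simulate_pas_traces(dd, default_conditions(cfg),
                                             config=cfg),
                         training_seed=dd.seed)
          for dd in donors]
xi50, xi_crit, taus = calibrate_thresholds(cohort)
cohort = apply_hill(cohort, xi50, xi_crit)
print(f"calibrated xi50 = {xi50:.1f}, xi_crit = {xi_crit:.1f} uM*s")
print("collagen release times (s), weakest to strongest donor:",
      np.sort(taus)[::-1])
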