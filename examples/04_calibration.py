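"""Calibrate the model against a synthetic cohort (reduced scale).

Generates "observed" islet statistics by simulating a small cohort at
known parameters theta*, then fits theta with CMA-ES by minimising the
weighted Kolmogorov loss between simulated and observed distributions.
A reduced population/generation budget keeps this demo around a minute;
the loss is stochastic, so success means reaching the Monte-Carlo noise
floor of the objective, not recovering theta* digit by digit.
"""

import numpy as np

from isletsim import ModelParams
from isletsim.calibration import CalibrationConfig, calibrate, loss_samples
from isletsim.geometry import make_cohort, small_cohort_spec

theta_star = ModelParams(kBT=0.8, tau_jump=3.7, tau_dup=0.6, tau_die=0.5,
                         tend=20.0, dx=0.5)
cohort = make_cohort(6, theta_star, seed=11, base_spec=small_cohort_spec())
print("observed (count, median diameter):")
for p in cohort.patients:
    med = "-" if p.observed_median_mm is None else f"{p.observed_median_mm:.2f}"
    print(f"  {p.patient_id}: {p.observed_count}, {med}")

config = CalibrationConfig(
    lambda_n=2.0, samples_per_patient=3, tend=20.0, dx=0.5,
    popsize=8, generations=4, base_seed=11, max_events_per_sim=200_000,
)
floor = loss_samples(
    (theta_star.kBT, theta_star.tau_jump, theta_star.tau_dup, theta_star.tau_die),
    cohort, config, n_eval=8,
)
print(f"\nloss at theta* (noise floor): median {np.median(floor):.3f}, "
      f"90th pct {np.percentile(floor, 90):.3f}")

result = calibrate(cohort, config)
print(result.trace.to_string(index=False))
t = result.theta
print(f"\nbest loss {result.loss:.3f} at kBT={t.kBT:.3f} "
      f"tau_jump={t.tau_jump:.3f} tau_dup={t.tau_dup:.3f} tau_die={t.tau_die:.3f}")
print("calibration succeeded" if result.loss <= np.percentile(floor, 90)
      else "loss above the noise floor -- increase the budget")
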