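"""Plan under several isocenter limits and pick the subjective best plan.

Limits I0/I1/I2 are 60%/100%/140% of the reference plan's isocenter count;
Ipred comes from a cubic regression on prescription dose and target volume.
A challenger beats the incumbent if it improves conformity by >= 3% without
costing more than 3 extra minutes, or saves >= 3 minutes without losing more
than 3% conformity.
"""
import numpy as np

import gkplan as gk

spec = gk.PhantomSpec(
    targets=[gk.TargetSpec(volume_cc=0.4, prescription_dose=18.0)],
    grid_shape=(32, 32, 32),
    spacing_mm=(1.5, 1.5, 1.5),
    skull_semi_axes_mm=(18.0, 18.0, 18.0),
)
phantom = gk.build_phantom(spec)
candidates = gk.generate_candidates(phantom, reference_count=4)
central = gk.make_central_kernel(phantom.grid, dose_rate_scale=2.5)
positions, target_idx = candidates.positions_and_targets()
kernels = gk.KernelSet.from_candidates(central, phantom.skull_mask, positions, target_idx)

weights = gk.ObjectiveWeights(np.array([[0.45, 0.05, 0.25, 0.25, 0.002]]))
target = phantom.targets[0]
ipred = gk.predict_isocenter_limit(target.prescription_dose, target.volume_cc(phantom.grid))
print(f"regression-predicted isocenter limit: {ipred}")

result = gk.run_limit_sweep(
    phantom, kernels, lambda h: weights, reference_count=4, include_ipred=True,
)
for name, record in result.plans.items():
    report = record["report"]
    print(
        f"{name} (H={record['limit']}): objective {record['objective']:.5f}, "
        f"CI {report.mean_conformity:.3f}, time {report.treatment_time_min:.1f} min, "
        f"{report.isocenter_count} isocenters"
    )
print(f"best plan across I0/I1/I2: {result.best}")
# The objective can only improve (decrease) as the isocenter limit rises;
# the best-plan rule trades that improvement against treatment time.
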