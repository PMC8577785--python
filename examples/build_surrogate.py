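"""Build a surrogate from scratch with the two-iteration pipeline.

Runs uniform sampling + linear fit (iteration 1), transition-domain
resampling (iteration 2), and criterion-based quadratic feature selection
against the toy simulator, then scores the result on an independent
test set.
"""

import numpy as np

from eblrm import (
    MMISpace,
    PipelineConfig,
    reference_surface_config,
    run_two_iteration_pipeline,
    sample_roi,
    simulate_batch,
    validate,
)

simulator = reference_surface_config()
config = PipelineConfig(space=MMISpace.ectopic_beat_roi(),
                        sets_per_iteration=100, realizations_per_set=100, seed=42)
result = run_two_iteration_pipeline(config, simulator)

it1, it2 = result.iterations
print(f"iteration 1: {len(it1.observations)} uniform MMI sets, "
      f"linear-only fit ({len(it1.model.spec)} features)")
print(f"iteration 2: {len(it2.observations)} transition-domain sets "
      f"(band {config.transition_band})")
print(f"selected features ({len(result.model.spec)}): {result.model.spec.names}")

# independent test set, as in the published design
test_pts = sample_roi(config.space, 100, np.random.default_rng(777))
test_obs = [simulate_batch(simulator, pt, 100, ss)
            for pt, ss in zip(test_pts, np.random.SeedSequence(778).spawn(100))]

final = validate(result.model, test_obs)
prelim = validate(it1.model, test_obs)
print(f"\ntest-set performance   (final): error {final.mean_abs_error:.4f} "
      f"+- {final.sd_abs_error:.4f}, transition R^2 {final.r2_transition:.3f}")
print(f"test-set performance (linear-only iteration 1): error {prelim.mean_abs_error:.4f} "
      f"+- {prelim.sd_abs_error:.4f}, transition R^2 {prelim.r2_transition:.3f}")
print("\nTransition-domain resampling plus quadratic features cuts the"
      "\nprediction error several-fold relative to the preliminary model.")
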