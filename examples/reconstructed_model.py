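"""Evaluate the reconstructed published ectopic-beat surrogate.

Loads the 10-feature logistic model rebuilt from published weights (with
the intercept derived from the P(EB) = 0.5 anchor set), predicts the
published scenario points, and sweeps the G_K1 scaling factor to show its
model-characteristic curve.
"""

import numpy as np

from eblrm import load_reference_model, mc_curve

model = load_reference_model()
print(f"intercept (anchor-derived): {model.intercept:.3f}")
print("features by importance:", [name for name, _, _ in model.rank_features()][:3], "...")

scenarios = {
    "set 2  (G_K1_sf = 0.638)": dict(ca_i_ini=150, ca_sr_ini=500, g_k1_sf=0.638, k_ryr_sf=1),
    "set 3  (G_K1_sf = 0.0)  ": dict(ca_i_ini=150, ca_sr_ini=500, g_k1_sf=0.0, k_ryr_sf=1),
    "default diastolic set    ": dict(ca_i_ini=100, ca_sr_ini=700, g_k1_sf=1.0, k_ryr_sf=1),
}
print("\npredicted ectopic-beat probabilities:")
for label, point in scenarios.items():
    p = model.predict_probability(model.space.point(**point))
    print(f"  {label} P(EB) = {p:.3f}")

# 1-D sweep: suppressing the inward-rectifier current raises P(EB)
anchor = model.space.point(ca_i_ini=150, ca_sr_ini=500, g_k1_sf=0.338, k_ryr_sf=1)
curve = mc_curve(model, "g_k1_sf", anchor, grid_size=5)
print("\nG_K1_sf sweep (other inputs at the anchor set):")
for g, p in zip(curve.grid, curve.probabilities):
    print(f"  G_K1_sf = {g:.2f} -> P(EB) = {p:.3f}")
print("\nP(EB) falls monotonically as G_K1 conductance grows: the inward-"
      "\nrectifier current stabilises the resting membrane against ectopy.")
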