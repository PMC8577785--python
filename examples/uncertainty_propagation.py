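"""Propagate MMI measurement uncertainty through the surrogate.

Reproduces the two published uncertainty studies: (1) SR Ca2+ load
uncertainty at the anchor set, where P(EB) uncertainty first grows and
then collapses onto the plateaus as sigma increases; (2) G_K1 uncertainty
in normal vs heart-failure myocytes.
"""

from eblrm import (
    UncertaintySpec,
    classify_modality,
    entropy,
    load_reference_model,
    propagate_mc,
)

model = load_reference_model()
axes = model.space.names

# -- SR-load uncertainty at the anchor set (P(EB) = 0.5) ---------------
anchor = dict(ca_i_ini=150, ca_sr_ini=500, g_k1_sf=0.338, k_ryr_sf=1)
print("SR Ca2+ load uncertainty at the anchor set:")
for sigma in (5.0, 15.0, 30.0):
    uspec = UncertaintySpec(anchor, {a: (sigma if a == "ca_sr_ini" else 0.0) for a in axes})
    d = propagate_mc(model, uspec, n_samples=1_000_000, seed=1)
    print(f"  sigma = {sigma:4.0f} uM: mean {d.mean:.3f}, sd {d.sd:.3f}, "
          f"entropy {entropy(d):.2f} nats, {classify_modality(d)}")
print("Entropy peaks at the intermediate sigma: uncertainty in P(EB) first"
      "\nrises (toward a uniform distribution) and then falls as probability"
      "\nmass concentrates on the 0/1 plateaus (bimodal).\n")

# -- G_K1 uncertainty: normal vs heart-failure myocytes ----------------
fixed = dict(ca_i_ini=150, ca_sr_ini=550, k_ryr_sf=1)
print("G_K1 scaling-factor uncertainty (150 nM, 550 uM, k_RyR_sf = 1):")
for label, (mean, sd) in {"normal": (1.0000, 0.1108), "heart failure": (0.5100, 0.0852)}.items():
    uspec = UncertaintySpec({**fixed, "g_k1_sf": mean},
                            {a: (sd if a == "g_k1_sf" else 0.0) for a in axes})
    d = propagate_mc(model, uspec, n_samples=1_000_000, seed=2)
    print(f"  {label:>13}: P(EB) = {d.mean:.4f} +- {d.sd:.4f}")
print("Even with measurement uncertainty, the heart-failure G_K1 level"
      "\ncarries a far higher ectopic-beat probability than normal.")
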