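"""Extract the handcrafted feature battery from pen recordings.

Simulates one PD and one HC spiral, preprocesses them (unit-normalised,
already uniformly sampled), and prints a few clinically interpretable
features side by side: the PD subject should show lower median velocity
(bradykinesia), higher spiral severity (tremor), and lower pressure.
"""

from graphomotor import (
    EffectProfile,
    NEUTRAL_PROFILE,
    extract_feature_vector,
    simulate_spiral,
)

pd_profile = EffectProfile(velocity_scale=0.6, tremor_amp=1.0,
                           pressure_scale=0.8)
pd_rec = simulate_spiral(pd_profile, seed=1)
hc_rec = simulate_spiral(NEUTRAL_PROFILE, seed=2)

pd_fv = extract_feature_vector(pd_rec)
hc_fv = extract_feature_vector(hc_rec)

print(f"{'feature':28s} {'PD':>10s} {'HC':>10s}")
for name in ("ON:VEL(median)", "ON:AVEL(median)", "DoS", "SPI",
             "PRESS(median)", "MDS", "RNCV"):
    print(f"{name:28s} {pd_fv[name]:10.3f} {hc_fv[name]:10.3f}")
print(f"\n{len(pd_fv.values)} named features per spiral recording.")
# ON:VEL(median) is the median on-surface pen speed in mm/s; DoS is the
# RMS deviation from the ideally fitted spiral relative to its radial
# range (0 = perfect); SPI is the spiral precision index (1 = perfect).
# Note how 1 mm of 5 Hz tremor adds ~30 mm/s of oscillatory speed, so
# raw median velocity barely separates the groups here — the spiral
# residual (DoS, SPI) and angular velocity carry the tremor signature.
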