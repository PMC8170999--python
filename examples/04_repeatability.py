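"""Instrument repeatability at three concentration levels.

Ten full-pipeline replicate measurements at low/medium/high concentration
with 1% relative source jitter; prints the per-level coefficient of
variation of the retrieved concentration.
"""

import cholspec as cs

study = cs.simulate_repeatability_study(
    levels=(0.25, 1.0, 4.0),
    replicates=10,
    noise=cs.NoiseModel(jitter=0.01, seed=1),
    seed=1,
)
for level, values in study.items():
    cv = cs.coefficient_of_variation(values)
    print(f"level {level:4}: mean {values.mean():.4f}, CV {cv:.2f}%")
print("\nCV stays within 5% at every level: the additive retrieval error from")
print("source jitter matters most, relatively, at the lowest concentration.")
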