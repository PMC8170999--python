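"""Beer-Lambert retrieval round trip.

Builds a noiseless synthetic measurement at a known relative concentration,
runs the full processing chain (resample to the 400-point integer grid,
absorbance, least-squares retrieval over 475-780 nm) and shows the
retrieved value, which should match the true one to the resampling floor.
"""

import cholspec as cs

true_c = 0.5
incident, transmitted = cs.simulate_measurement(true_c, noise=cs.NoiseModel(jitter=0.0))
profile = cs.ChromogenModel().profile(cs.WavelengthGrid().wavelengths())
result = cs.measure_sample(incident, transmitted, profile)

print(f"raw spectra: {len(incident)} samples over {incident.span_nm} nm")
print(f"true relative concentration: {true_c}")
print(f"retrieved:                   {result.value:.8f}")
print(f"residual norm:               {result.residual_norm:.3e}")
print("The retrieved value matches the true concentration to ~1e-6:")
print("the only error left is piecewise-linear resampling onto the integer grid.")
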