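"""Simulate one cough recording and turn it into an RDM sequence.

Builds a 3 s scene containing a breathing subject who coughs once, renders
the raw complex IF cube a 60 GHz FMCW radar would record, and runs the full
range-Doppler preprocessing chain.
"""

import numpy as np

from radarcough import (RadarConfig, preprocess, sample_motion_profile,
                        synthesize_cube)

rng = np.random.default_rng(0)
radar = RadarConfig()

profile = sample_motion_profile("cough", "sitting", rng)
torso = profile.scatterers[0]
print(f"subject at {torso.base_range:.2f} m, breathing "
      f"{torso.breathing_amplitude * 1e3:.1f} mm at "
      f"{torso.breathing_frequency:.2f} Hz")
for ev in profile.transient_events:
    print(f"cough transient: onset {ev.onset:.2f} s, duration "
          f"{ev.duration:.2f} s, peak speed {ev.peak_speed:.2f} m/s")

cube = synthesize_cube(profile, radar, snr_db=20, rng=rng)
print(f"\nraw cube shape {cube.data.shape}  (chirps, TX, RX, ADC samples)")

seq = preprocess(cube)
print(f"RDM sequence shape {seq.data.shape}  (frames, channel, range bins, "
      f"Doppler bins)")
print(f"primary range bin {seq.primary_bin} "
      f"(~{seq.primary_bin * radar.range_bin_spacing:.2f} m)")

# the cough shows up as a transient Doppler broadening: report the frame
# with the widest spectrum
mag = np.exp(seq.data[:, 0]) - 1e-6
doppler_marginal = mag.sum(axis=1)
bins = np.arange(doppler_marginal.shape[1])
spread = [
    float(np.sqrt(np.sum(w * (bins - w.argmax()) ** 2) / w.sum()))
    for w in doppler_marginal
]
peak_frame = int(np.argmax(spread))
print(f"\nwidest Doppler spread at frame {peak_frame} "
      f"(t = {seq.frame_times[peak_frame]:.2f} s): {spread[peak_frame]:.1f} bins")
print("frames near the cough transient carry a broadband Doppler stripe; "
      "quiet breathing frames stay near the zero-velocity column.")
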