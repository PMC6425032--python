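"""Track an actin wave and recover its speed-intensity coupling.

Generates a noiseless synthetic wave whose boundary expands at a different
programmed speed at every angle (from -0.5 to +1.5 um/min), tracks the
boundary at all 360 degrees, normalizes the band intensity to 1 at null
speed, and tabulates the binned speed-intensity relation.
"""

import numpy as np

from phagokit import synthgen as sg
from phagokit import waves as wv

cfg = sg.SynthConfig(seed=3, image_shape=(256, 256))  # 0.133 um/px, 10 s/frame
speeds = 0.5 + 1.0 * np.sin(np.deg2rad(np.arange(360)))
radii = sg.expanding_wave_radii(r0_um=8.0, speed_um_min=speeds, n_frames=12,
                                frame_interval_s=cfg.frame_interval_s)
actin, membrane, truth = sg.gen_wave_movie(cfg, radii, intensity0=100.0,
                                           coupling_beta=0.1)

df = wv.track_movie(actin, threshold=50.0, center_px=truth.center_px)
v_hat = df["v_um_min"].dropna().to_numpy()
err = np.abs(v_hat - truth.v_true_um_min.reshape(-1))
print(f"tracked {len(v_hat)} (angle, frame) boundary samples")
print(f"median |v_hat - v_true| = {np.median(err):.4f} um/min "
      "(subpixel ray-casting accuracy)")

dfn = wv.normalize_at_null_speed(df)
rel = wv.speed_intensity_relation(dfn, bin_width=0.2)
slope = np.polyfit(rel["speed_bin_center"], rel["mean_intensity"], 1,
                   w=np.sqrt(rel["n"]))[0]
print(f"binned speed-intensity slope = {slope:.4f} per (um/min); "
      f"programmed coupling = {-truth.coupling_beta}")
print("(negative slope: bright, stalled boundary segments vs dim, fast ones)")
print(rel.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
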