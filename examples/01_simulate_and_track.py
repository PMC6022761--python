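"""Simulate a dynamic microtubule, render a TIRF movie, and track it back.

The round trip — stochastic two-state trace -> rendered two-channel movie ->
seed detection -> drift registration -> kymograph -> threshold tracking —
should reproduce the simulated length at every frame to about one pixel.
"""

import numpy as np

from mtdynamics import (
    DIParams,
    ImagingParams,
    render_movie,
    simulate_length_trace,
)
from mtdynamics.kymo import build_kymograph, detect_seeds, register_frames, track_length

params = DIParams(v_grow=2.0, v_shrink=2.0, f_cat=0.5, f_res=2.0, seed_length_um=1.0)
trace = simulate_length_trace(params, duration_s=180.0, dt_s=3.0, rng_seed=7)
imaging = ImagingParams(noise_model="none", background_level=5.0)

movie, truth = render_movie(trace, imaging, seed_length_um=1.0, shape=(32, 160))
registered = register_frames(movie["seed"], apply_to=movie["dynamic"])
seed = detect_seeds(movie["seed"][0])[0]
kymo = build_kymograph(registered.frames, seed, 65.0, 3.0)
tracked = track_length(kymo, direction="right")

err_px = (tracked.lengths_um - (trace.lengths_um - 1.0)) * 1000.0 / 65.0
print(f"simulated {len(trace)} frames; final extension "
      f"{trace.lengths_um[-1] - 1.0:.2f} um beyond the 1.0-um seed")
print(f"tracking RMS error: {np.sqrt(np.mean(err_px**2)):.2f} px "
      f"(<= 1 px means the pipeline reads back the simulation faithfully)")
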