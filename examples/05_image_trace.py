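"""Measure filament length from rendered frames and recover the speed.

Renders a synthetic trace as grayscale frames (bright filament, dark
background, nozzle tip at a known row), measures each frame by thresholding,
reassembles the trace and estimates the extrusion speed — a closed loop that
validates the whole image path to within one pixel.
"""

import numpy as np

import extruflow as xf
from extruflow.synthetic import GeneratorConfig, synth_trace

config = GeneratorConfig(trace_noise_sd=0.0, seed=3)
trace = synth_trace(config, pressure=100e3)

render = xf.FrameRenderConfig(pixel_size=0.05e-3, background_noise_sd=0.02, seed=3)
frames = xf.synth_frames(trace, render)
print(f"rendered {len(frames)} frames of {render.height_px}x{render.width_px} px "
      f"at {render.pixel_size * 1e3:.3f} mm/px")

recovered = xf.trace_from_frames(frames, pressure=trace.pressure)
err_px = np.abs(recovered.lengths - trace.lengths) / render.pixel_size
print(f"max length error: {err_px.max():.2f} px "
      f"({err_px.max() * render.pixel_size * 1e3:.4f} mm)")

estimate = xf.extrusion_speed(recovered)
vex_true = xf.predict_extrusion_speed(
    config.rheology, config.swell_law, config.nozzle, trace.pressure
)
print(f"speed from frames : {estimate.extrusion_speed_mean * 1e3:.3f} mm/s "
      f"(model: {vex_true * 1e3:.3f} mm/s, {estimate.points_used} points)")
print("Lengths survive rendering to within a pixel, so frame-based measurement")
print("adds ~1 px of quantization noise and no bias to the speed estimate.")
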