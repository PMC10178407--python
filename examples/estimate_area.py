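"""Calibrate a height->pixel curve and convert a wound mask to cm².

Renders a prior-graphic ladder (a 4 cm² square photographed at 100-500 mm),
fits λ = f(h), renders one wound scene with a known area, and converts its
ground-truth mask's pixel count to physical area.  The printed error is the
percentage deviation from the scene's exact analytic area — it reflects only
rasterisation and calibration-fit error, since the mask is perfect.
"""

from woundseg import (
    SCALED_CAMERA,
    CalibrationSeriesSpec,
    SceneSpec,
    count_mask_pixels,
    estimate_area,
    fit_calibration,
    relative_error,
    render_calibration_series,
    render_scene,
)

records = render_calibration_series(CalibrationSeriesSpec(camera=SCALED_CAMERA))
curve = fit_calibration(records)  # degree-4 polynomial in powers of 1/h
print(f"calibrated over [{curve.h1:.0f}, {curve.hn:.0f}] mm, "
      f"max fit residual {curve.max_rel_residual * 100:.2f}%")

scene = render_scene(SceneSpec(true_area_cm2=12.0, height_mm=250.0,
                               camera=SCALED_CAMERA, seed=5))
est = estimate_area(curve, count_mask_pixels(scene.mask), scene.height_mm)
print(f"true {scene.true_area_cm2:.2f} cm2  estimated {est.s_w_est:.2f} cm2  "
      f"error {relative_error(scene.true_area_cm2, est.s_w_est):.2f}%")
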