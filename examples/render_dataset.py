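"""Render a small synthetic wound dataset to disk.

Writes images/, masks/ and manifest.csv under ./scratch_dataset.  The
manifest records each scene's shooting height, exact physical area and
rasterised wound pixel count; reruns with the same seed are bit-identical.
"""

from woundseg.synthetic import SCALED_CAMERA, make_dataset

manifest = make_dataset(6, "scratch_dataset", seed=4, camera=SCALED_CAMERA,
                        area_range_cm2=(10, 30), height_range_mm=(150, 300))
print(manifest.to_string(index=False))
print("each row's lambda_true equals the saved mask's exact pixel count")
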