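# File formats and CLI reference

## Masks

Single-channel 8-bit PNG, values {0, 255} (0 = background, 255 = wound);
{0, 1} uint8 in memory. `read_mask` is strict by default; `--coerce` (CLI)
or `coerce=True` converts any input to grayscale and thresholds at 128.
Write→read round-trips are bit-exact.

## Probability maps

16-bit PNG; stored value = round(p · 65535).

## Dataset directories

```
<root>/
  images/<name>.png     # RGB
  masks/<name>.png      # matching basenames, 0/255 single-channel
  manifest.csv          # optional: filename, height_mm, true_area_cm2, lambda_true
```

## Calibration tables

CSV with a header row and columns `height_mm, pixel_count`. The prior
graphic's area (cm²) is passed separately (`--prior-area`). Pixel counts may
be fractional (sub-pixel coverage counting).

## Checkpoints

One `.npz` file holding the JSON-encoded network config plus every parameter
and batch-norm running statistic; parameter round-trips are bit-exact.

## Training history

CSV with columns `epoch, train_loss, val_loss, val_dice`.

## Area reports

`estimate-area` prints JSON:
`{"S_wEst", "lambda_w", "lambda_i", "h_i", "S_pi", "S_wReal"?, "S_wMbr"?, "E"?}`
(areas cm², heights mm, λ in pixels).

## CLI

Subcommands: `synth`, `train`, `segment`, `evaluate`, `calibrate`,
`estimate-area`. Run configs are YAML with sections `network`, `training`,
`augmentation`, `calibration`, `synthetic`; unknown sections or keys are
rejected, and the fully resolved config is logged per run.

Exit codes: 0 ok, 2 usage error, 3 data error (including out-of-range
shooting heights).
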