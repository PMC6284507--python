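# recruitkit

Quantification of protein recruitment kinetics at laser-microirradiated
DNA damage stripes, for simultaneous dual-channel ("split-view")
time-lapse fluorescence movies.

Laser microirradiation draws a stripe of DNA damage across a cell
nucleus; fluorescently tagged repair proteins then accumulate at the
stripe, and their accumulation curves encode recruitment kinetics.
With a split-view setup the two emission colours land on two halves of
one camera chip in the same exposure, so two proteins are imaged truly
simultaneously in the same cell — which is what makes relative
kinetics (who arrives first, who dissociates faster) measurable for
fast recruiters. `recruitkit` implements the image-processing and
analysis side of that experiment:

- split-view channel splitting with integer-pixel registration,
- difference-of-Gaussians bandpass prefiltering (σ = 0.065 µm / 13 µm),
- damage-site quantification by **medMax** — the median of the 20
  brightest damage-ROI pixels,
- photobleaching correction by the whole-nucleus mean,
  3-point smoothing, and normalization to
  **RFI** = I_t/I₀ (fold change), **ΔI** = I_t − I₀, and
  **FMR** = (RFI − 1)/(max RFI − 1) (amplitude-free kinetics, 0 before
  damage, 1 at the maximum),
- per-cell scalars (max RFI, t_max, **t50** — first time FMR ≥ 0.5),
- population analyses: intensity-range QC, rank clustering by final
  FMR, FMR heatmaps, intensity/size/cross-channel regressions,
  red/green FMR-ratio series, mean ± SEM curves,
- a synthetic movie generator with exact ground truth (two-rate
  kinetics `f(t) = A(1 − e^(−k_on t))e^(−k_off t)`, bleaching,
  bleed-through, drift, camera noise) so every stage has a
  parameter-recovery test.

See `docs/methods.md` for the full model and the design rationale.

## Worked example

Simulate one cell under the standard acquisition (0.5 s interval,
damage after 10 frames, SNR 10) and run the full pipeline:

```python
import numpy as np
from recruitkit import NucleusMask, simulate_movie
from recruitkit.synth import standard_config
from recruitkit.pipeline import process_cell_pair

cfg = standard_config(n_frames=310)   # 150 s of imaging after damage
green, red, truth = simulate_movie(cfg, np.random.default_rng(0))
nucleus = NucleusMask.from_ellipse(cfg.shape, cfg.nucleus_center, cfg.nucleus_axes)
cell = process_cell_pair("cell000", green, red, cfg.damage_roi, nucleus)

for channel in ("green", "red"):
    curve = cell.curve(channel)
    true = truth.channel(channel)
    print(f"{channel}: i0_raw={cell.i0_raw_green if channel=='green' else cell.i0_raw_red:6.1f}"
          f"  max_RFI={curve.max_rfi:5.2f}  t_max={curve.t_max:6.1f} s"
          f"  t50={curve.t50:5.1f} s (true {true.t50:5.1f} s)")
```

prints

```
green: i0_raw= 178.1  max_RFI= 1.65  t_max=  94.0 s  t50= 25.5 s (true  20.2 s)
red: i0_raw= 255.5  max_RFI= 2.11  t_max= 146.0 s  t50= 39.0 s (true  37.7 s)
```

Reading this: the cell's raw initial intensities (178/255 counts) fall
inside the QC selection ranges; the green protein peaks near 94 s with
a 1.65-fold intensity increase, the red near 146 s with a larger fold
change — the fast-recruiter/slow-recruiter pair the defaults emulate.
t50 is quantized to the 0.5 s frame grid and its threshold (half of
the observed maximum) sits on a noisy estimate, so slow curves at SNR
10 read a few seconds high; over the faster kinetics regime
(k_on ≥ 0.05/s) recovery is within ±1 s for ≥ 18/20 cells (see the
validation battery).

## Command-line workflow

```bash
recruitkit simulate --config config.yaml --out run/ --seed 1
recruitkit extract  --config config.yaml --out run/
recruitkit analyze  --config config.yaml --out run/
```

`simulate` writes per-cell TIFF pairs (or one split-view stack per
cell), a ground-truth table and a manifest; `extract` reads the
manifest (or a hand-written `input:` section pointing at real movies
plus ROIs), runs the pipeline and writes `traces.csv` / `cells.csv`;
`analyze` writes every population table as CSV (mean ± SEM curves,
clusters, ordered FMR heatmap, scatters, FMR ratio, t50 pairs), PNG
figures for convenience, and a JSON provenance log. Re-running
`analyze` on the same traces reproduces the tables bit-identically.
`--mode fast` switches to the fast-imaging preset (0.1 s interval,
3 pre-damage frames, no smoothing).

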