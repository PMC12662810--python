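# octmargin

Quantitative optical coherence tomography (OCT) analytics for **neural
tumor margin delineation**: depth-resolved attenuation-coefficient
estimation on swept-source B-scans, A-line/trendline metrics, grid-based
gray-value statistics, ROC tissue discrimination, and interleaved 3D
reconstruction with attenuation-based color classification — plus a
seeded speckle phantom generator calibrated to published ex vivo
brain-tissue statistics.

## Who this is for

Researchers developing or validating intraoperative OCT pipelines for
brain tumor surgery. Glioma tissue attenuates near-infrared light less
than peritumoral brain, so a per-A-line attenuation estimate separates
tumor from margin tissue. The package implements the full measurement
chain as a tested library with a thin `octm` CLI. Since raw clinical OCT
scans of this kind are not publicly deposited, a first-class synthetic
phantom module stands in for the instrument and the specimens, with
generator-side ground truth for every pixel.

## The core estimator

For each image column (A-line), the two-point attenuation coefficient is

```
mu_t = (10 / L) * log10(P_i / P_L)   [dB/mm],   L = n_rows * 0.024445 mm
```

where `P_i` is the gray value at the starting row (fourth-largest value
of the column, robust to specular spikes), `P_L` the gray level at the
ending row (first five-pixel running-mean window below 45, evaluated at
the window centre), and `L` the distance between them. Estimates above
11 or below 0 indicate noise-corrupted endpoints and are discarded.
Accepted values live on the same numeric scale as the published tissue
tables (glioma ≈ 4.8, peritumoral brain ≈ 6.4).

Around the estimator the package provides:

- `octmargin.phantom` — seeded A-line/B-scan/volume generator with tissue
  presets (attenuation mean ± SD per tissue class, probe standoff
  distributions, speckle and background noise);
- `octmargin.profiles` — ROI depth profiles, 10-row trendline, peak and
  4:3-aspect descending-angle metric;
- `octmargin.gridstats` — threshold-band pixel counting (70–140 / 70–110
  in 55×100 grids; 100–140 in 55×80) and 16-color pseudocolor rendering;
- `octmargin.volume3d` — bidirectional-pass interleaving (e.g. ten passes:
  0.187 mm → 0.0187 mm slice spacing), surface extraction (binarize > 70,
  open/close, first foreground row), attenuation volumes, and the
  red/yellow/green/white classified surface mesh (red 0–5 = tumor-probable,
  yellow 5–6 = boundary, green 6–11 = peritumoral, white = undefined);
- `octmargin.stats` / `octmargin.pipeline` — Welch comparisons, ROC/AUC
  (Mann–Whitney identity, Youden operating point), and the end-to-end
  seeded report workflow.

## Worked example

Simulate the published group sizes (60 glioma vs 21 peritumoral
specimens), estimate per-specimen attenuation from each B-scan's central
A-line, and compare the groups:

```python
from octmargin.pipeline import run_pipeline

report = run_pipeline({
    "groups": [{"name": "glioma", "preset": "all_glioma", "n": 60},
               {"name": "peritumoral", "preset": "peritumoral_all", "n": 21}],
    "seed": 7,
})
print(report["summaries"]["attenuation"].to_string(index=False))
for metric in ("attenuation", "angle"):
    r = report["roc"][metric]
    print(f"{metric}: AUC={r['auc']:.3f} direction={r['direction']} "
          f"Youden threshold={r['youden_threshold']:.2f} Welch p={r['welch_p']:.2e}")
```

prints

```
      group  n     mean       sd     p_vs_ref
     glioma 60 4.814994 1.686291 2.074058e-08
peritumoral 21 6.333611 0.496003          NaN

attenuation: AUC=0.814 direction=lower Youden threshold=5.33 Welch p=2.07e-08
angle: AUC=0.890 direction=higher Youden threshold=18.62 Welch p=1.47e-10
```

The simulated cohorts reproduce the preset tissue statistics
(4.81 ± 1.51 vs 6.40 ± 0.53 across specimens), the classifier direction
is auto-detected as *lower-is-tumor* (gliomas attenuate less), and the
discrimination quality lands in the range reported for real margin
specimens. The same workflow is available from the shell:

```sh
$ octm simulate --preset all_glioma --n-specimens 1 --seed 5 --out demo
wrote 1 specimen(s) to demo
$ octm attenuation demo/specimen_000.tif --out est.csv
{"accepted_fraction": 1.0, "counts": {"accepted": 512}}
$ octm trend demo/specimen_000.tif --cols 250:261 --out trend.csv
peak=98.5 angle=31.76 deg
```

(`demo/specimen_000.truth.json` records the generator truth for this
specimen — attenuation 3.51 dB/mm, standoff 2.03 mm — so every estimate
can be checked against it.) Other subcommands: `octm gridcount`,
`octm render2d`, `octm volume`, `octm report`, `octm roc`.

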