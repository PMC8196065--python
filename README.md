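# droptubes

Quantifying dynamic DNA-nanotube self-assembly inside water-in-oil
droplets.

Synthetic cells need cytoskeleton-like scaffolds that assemble and
disassemble on command.  DNA tiles (five-strand DAE-E double-crossover
motifs) polymerize isothermally into micrometer-long nanotubes; inside
cell-sized droplets, assembly can be switched on by a transcribed RNA
"trigger" that completes an inactive tile's sticky end, and switched off
by RNase H, which degrades the RNA half of the hybrid sticky end on free
tiles.  Watching this happen in an epifluorescence microscope poses a
quantification problem: nanotubes inside droplets cannot be segmented or
measured individually.  The tractable readout is statistical — as
fluorescently labeled tiles condense from a uniform background into a few
bright filaments, the *shape* of each droplet's pixel-intensity
distribution changes, and its skewness and excess kurtosis rise.

`droptubes` implements that analysis end to end, plus the kinetic model
that explains the dynamics:

| module | what it does |
|---|---|
| `droptubes.synthetic` | seeded ground-truth generator: droplet populations (log-uniform radii 1–20 µm), worm-like-chain nanotube bundles (persistence 4.5 µm), chord-depth sphere projection with defocus, Poisson+read noise, 16-bit TIFF output |
| `droptubes.detection` | multi-scale matched-filter droplet detector (projected-sphere templates, filament-suppressing grayscale opening, NMS) with interior pixel extraction away from the rim |
| `droptubes.stats` | per-droplet bias-corrected skewness G1 / excess kurtosis G2 (plain-pixel and unique-binned-value modes), population mean ± SD timecourses, CSV export |
| `droptubes.model` | stiff ODE model of transcription (with RNAP activity decay), RNA-triggered tile activation, cooperative nucleation + elongation, and RNase H deactivation with waste; pulse metrics and parameter sweeps |
| `droptubes.cli` / `droptubes.pipeline` | `droptubes synthesize / analyze / simulate` commands tying the stages into reproducible, provenance-stamped runs |

The central quantities: per droplet, skewness
`G1 = n²/((n−1)(n−2)) · m₃/s³` and excess kurtosis
`G2 = ((n+1)(m₄/m₂²−3)+6)(n−1)/((n−2)(n−3))` of the interior pixel
values — exactly invariant under exposure changes while no pixel
saturates.  In the model, the observable is the fraction of assembled
tiles `f = P/T_total`; with transcription decaying and RNase H present,
`f(t)` is a pulse whose height falls and whose onset delays as RNase H
increases.

## Worked example

Simulate the transcription + degradation pulse, render a droplet movie
from it, and analyze the movie blind:

```python
import numpy as np
from droptubes import model, synthetic, pipeline

res = model.simulate(model.pulse_params(H=0.1), t_end=600.0)
print(model.pulse_metrics(res))

pop = synthetic.sample_droplet_population(
    30, (384, 384), radius_range_um=(6, 18), seed=42, border_margin_px=5)
frames = synthetic.render_timeseries(
    res, pop, synthetic.ImagingParams(rng_seed=42),
    np.linspace(0, 600, 6), (384, 384), seed=42)
_, tc = pipeline.analyze_frames(
    [(fr.time_min, fr.image) for fr in frames], mode="pixels")
for p in tc.points:
    print(f"t={p.time_min:5.0f} min  n={p.n_droplets:2d}  "
          f"skewness {p.mean_skewness:5.2f} ± {p.sd_skewness:.2f}")
```

prints (seed 42):

```
PulseMetrics(peak_height=0.5733597860481151, t_peak=158.54895379406233,
             duration_above=583.0304983687413, t_half_rise=37.81854463923904,
             threshold=0.1, right_censored=True)
t=    0 min  n=30  skewness -0.06 ± 0.04
t=  120 min  n=25  skewness  1.67 ± 0.90
t=  240 min  n=27  skewness  1.60 ± 0.67
t=  360 min  n=29  skewness  1.60 ± 0.63
t=  480 min  n=30  skewness  1.51 ± 0.52
t=  600 min  n=30  skewness  1.17 ± 0.41
```

The simulated assembly fraction peaks around 160 min (between frames 1
and 2); the recovered mean skewness rises from ≈0 to ≈1.7 and falls again
as RNase H disassembles the nanotubes — the blind image analysis recovers
the pulse the kinetics produced.

The same stages are scriptable from the shell:

```bash
droptubes simulate --outdir runs/pulse --t-end 600        # trajectory + metrics
droptubes synthesize --seed 7 --outdir runs/frames        # TIFFs + ground truth
droptubes analyze --indir runs/frames --outdir runs/stats --mode pixels
```

The numbered drivers under `analysis/` run the headline studies and write
tables to `results/`: `01_simulate_regimes.py` (two-tile concentration
series, gene titration, RNase H pulse sweep), `02_detection_benchmark.py`
(recall/precision against ground truth), `03_condensation_curve.py`
(mean skewness/kurtosis vs true assembled fraction, both estimator
modes), `04_closed_loop_pulse.py` (the loop above, from disk).

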