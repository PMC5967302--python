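# myoquant

Quantification toolkit for myotube-formation experiments: during myogenic
differentiation, myoblasts fuse into multinucleated MyHC⁺ syncytia that
elongate into bipolar myotubes, assemble cortical actomyosin, and signal
through mechanosensitive Ca²⁺ channels. This package implements the
measurements such a study runs on its imaging, optical-trap and cytometry
data — as a tested, reusable library with a config-driven CLI — together
with synthetic-data generators that provide ground truth for every stage.

It is written for cell biologists and biophysicists who have segmentation
masks, bead/stage tracks, or trace tables and want reproducible numbers.

## What it computes

**Syncytium morphometry** (label mask + nuclei centroids → per-field %):

- fusion index = 100 · (nuclei in MyHC⁺ cells with ≥ *N* nuclei) / (nuclei
  in all MyHC⁺ cells), *N* ∈ {16, 26, 50} by dataset;
- polarized elongation index = 100 · (area of MyHC⁺ cells with best-fit
  ellipse aspect ratio ≥ 3) / (total MyHC⁺ area);
- differentiation index = 100 · (nuclei in MyHC⁺ cells) / (all nuclei).

**Cortical actomyosin enrichment** (intensity image + mask → ratio): the
cell edge is divided into rectangles orthogonal to the periphery; per
rectangle, the peak intensity 0–5 μm from the edge is divided by the mean
intensity 2–7 μm inward of that peak; the cortex/cytoplasm ratio is the
average over rectangles.

**Optical-trap mechanics** (bead/stage tracks → stiffness, force, slope):
equipartition calibration k = k_B·T/⟨x²⟩ with the variance from a
Gaussian fit to the position histogram; trap force F = k·Δx; tether
force-extension curves and a first-linear-region fit.

**Trace statistics**: Fura2 Δratio (trace maximum minus the ratio at
1 min), basal level, relative peak currents, median-intensity time
courses, positive-fraction gating, and 2^−ΔΔCt fold changes.

**Synthetic data**: exact-discretization Ornstein–Uhlenbeck trapped-bead
tracks, series-spring tether pulls, rasterized syncytium fields with
nuclei, cortical-ring images, agonist-response traces, and bimodal
intensity populations — each shipping the ground truth its analysis
should recover.

## Worked example

```python
import myoquant as mq

# calibrate a trap from a simulated 10-s, 1000 frames/s equilibrium track
track = mq.simulate_trapped_bead(mq.TrapSimParams(seed=1))  # k = 7.29 pN/um
calib = mq.stiffness_equipartition(track, temperature=296.15)

# pull a tether and fit the first linear part of the force-extension curve
bead, stage = mq.simulate_tether_pull(
    mq.TetherSimParams(stiffness=7.29, tether_stiffness=20.0,
                       noise_sd=0.002, seed=1))
fit = mq.linear_region_fit(mq.force_extension_curve(bead, stage, calib))

# morphometry on a random synthetic field with known ground truth
spec = mq.sample_field_spec(seed=21, n_cells=5)
field = mq.generate_syncytium_field(spec)
cfg = mq.MorphometryConfig(fusion_nuclei_threshold=16, pixel_size=spec.pixel_size)
records, summary = mq.analyze_field(
    field.label_mask, field.nuclei[["x_px", "y_px"]], cfg,
    myhc_image=field.myhc, myhc_threshold=55.0)
```

This prints, via the obvious f-strings:

```
recovered stiffness: 7.509 pN/um (variance 5.445e-04 um^2, n = 10000)
tether slope: 5.504 pN/um over samples [0, 501) , R^2 = 1.0000
fusion 60.4%  elongation 87.1%  differentiation 98.0%  (truth: 60.4 / 87.1 / 98.0)
```

The recovered stiffness differs from the generating 7.29 pN/μm by
Monte-Carlo error (a 10⁴-frame track at a 2-ms correlation time carries a
~3% standard error); the tether slope equals k̂·k_t/(k̂+k_t) for the
*estimated* k̂, i.e. the series-spring value propagated through the
calibration; and the field indices reproduce the generator's
direct-counting ground truth.

The same analyses run from the shell:

```sh
myoquant simulate --config sim.yaml --out simout          # task: simulate
myoquant trap --config trap.yaml --out trapout            # equipartition calibration
myoquant morphometry --config morph.yaml --out morphout   # field indices
```

Each run writes its tables/JSON plus a `manifest.json` with parameters,
seed and SHA-256 checksums; identical config + seed reproduce
byte-identical outputs.

## Layout

```
src/myoquant/
  synthetic_data.py    generators + ground truth
  morphometry.py       ellipse metrics, nucleus assignment, indices
  cortical_profile.py  boundary rectangles, edge profiles, ratio
  trap_mechanics.py    equipartition calibration, force-extension, linear fit
  signal_traces.py     dratio, peaks, medians, gating, 2^-ddCt
  pipeline.py / cli.py config-driven tasks, manifests, CLI
docs/methods.md        models, defaults, numerical choices, limitations
```
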