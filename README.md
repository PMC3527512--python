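# thickfil

Sphere-bead modelling of the resting skeletal-muscle thick (myosin)
filament and its x-ray fiber diffraction.

X-ray diffraction from intact resting muscle is one of the few probes of
the *native* crossbridge array, but interpreting it requires forward
modelling: the myosin filaments are packed in a statistical "no
three-alike" hexagonal superlattice that partially samples the layer
lines, and the crossbridge crowns are helically regular in one part of the
filament but axially and azimuthally perturbed in the part carrying
myosin-binding protein C (MyBP-C). `thickfil` implements the complete
analysis pipeline for this problem, for structural muscle biophysicists:

- **filament builders** — regular-region (three-stranded 9/1 helix, crown
  rise c/3 = 14.3 nm, 40° twist), perturbed-region (42.9-nm triplets with
  crown azimuths φ₁..φ₃), and the three-fold MyBP-C array (11-domain bead
  chains, 45.33-nm repeat); heads are rigid 68-sphere clouds, either
  synthetic or coarse-grained from PDB Cα coordinates;
- **Fourier–Bessel transform** — cylindrically averaged layer-line
  intensities I_l(R) = Σ_n |G_n(R)|² with uniform-sphere form factors and
  axial-disorder temperature factors, the myosin/C-protein/cross-term
  decomposition, and coherent superlattice-cell sampling;
- **difference-Patterson desampling** — ΔQ(r,z) from the non-equatorial
  layer lines, cut-off of inter-filament vectors outside a borderline, and
  back-transformation to single-filament intensities; the helical-radius
  relation r = 2 r_h sin[π(z/C + 1/3)];
- **model fitting** — the RDI statistic (normalized L1 intensity residual
  with optimal scale factor, meridional region excluded) and a
  deterministic constrained grid search over crossbridge orientations
  (ε per head, φ per crown, r_h per region), statsmodels-style:
  `OrientationSearch(...).fit()` returns a results object with the score
  table, sensitivity traces and `summary()`;
- **meridional analysis** — internal calibration against the 14.34-nm M3
  reflection, Gaussian deconvolution of reflection clusters, intensity-
  weighted axial periodicities and two-zone interference distances;
- **synthetic data** — generators for every input, with truth records, at
  the study's default geometry (C-protein repeat 45.33 nm, myosin repeat
  42.96 nm, C-zone interference distance 660 nm, 1% multiplicative noise).

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

```python
import numpy as np
from thickfil import (default_filament, RadialGrid, cylindrical_intensity,
                      delta_q, estimate_crossbridge_radius,
                      MeridionalSpacing, default_windows, SynthConfig,
                      synth_meridional)

# full default half filament: regular + perturbed regions + MyBP-C array
fil = default_filament()
print("beads:", len(fil.all_spheres()),
      " perturbed fraction: %.2f" % fil.perturbed_fraction())

# forward transform and its difference-Patterson map
pattern = cylindrical_intensity(fil, RadialGrid())
pm = delta_q(pattern)
sel = (pm.r >= 15) & (pm.r <= 32)
peak_r = pm.r[sel][np.argmax(pm.values[0][sel])]
print("dQ(z=0) peak at r = %.1f nm -> r_h = %.1f nm"
      % (peak_r, estimate_crossbridge_radius(peak_r, 0.0)))

# meridional periodicity pipeline on a synthetic profile
profile, truth = synth_meridional(SynthConfig(seed=1, noise=0.01))
windows = default_windows(45.33, range(2, 6), other_period=42.96, prefix="C")
print(MeridionalSpacing(profile, windows).fit().summary())
```

prints

```
beads: 21171  perturbed fraction: 0.71
dQ(z=0) peak at r = 18.0 nm -> r_h = 10.4 nm
Meridional cluster analysis
==============================================
label    order  spacing (nm)  peaks    D (nm)
C2           2        47.499      3       667
C3           3        45.469      3       654
C4           4        45.366      3       658
C5           5        45.309      3       658
----------------------------------------------
period = 45.91 +/- 1.06 nm
interference distance D = 659 +/- 5 nm
```

The z = 0 Patterson peak is the same-crown inter-strand crossbridge
vector; dividing by 2 sin(60°) = √3 returns a crossbridge helical radius
between the regular- and perturbed-region values (9.8 and 12.7 nm).  The
meridional summary recovers the generating C-protein repeat (45.33 nm; the
C2 entry is biased high because at order 2 the C-protein and myosin
clusters physically overlap — higher orders are the reliable ones) and the
two-C-zone interference distance (660 nm) from the ~1/660 nm⁻¹ fringe
splitting of every cluster.

## Command line

```sh
thickfil build    --out model/                        # bead model from config
thickfil simulate --out sim/ --seed 1                 # synthetic data
thickfil desample --out des/ --pattern sim/layer_lines.txt
thickfil fit      --out fit/ --pattern des/corrected_layer_lines.txt
thickfil meridional --out mer/ --profile sim/meridional.txt
thickfil report   --out rep/                          # tables + plots
```

Every run writes a `manifest.json` (inputs, config hash, versions, seed).
The packaged default config (`thickfil/data/default_model.yaml`) holds the
full-filament-overlap parameter set; pass `--config your.yaml` to overlay
any field.

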