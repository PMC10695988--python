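# tensionmap

Quantitative analysis of intracellular molecular-tension microscopy with a
FRET-based actin crosslinker sensor, for labs combining live-cell
three-cube FRET imaging with traction force microscopy and substrate
stretching. The package turns raw multi-channel image stacks into
pixel-wise FRET-efficiency maps, cytoskeletal structure statistics,
traction and internal-force fields, and strain-response regressions — and
ships a synthetic-data generator with exact ground truth so every stage of
the analysis is verifiable without microscope data.

## What it computes

**Three-cube FRET efficiency.** From donor (I_DD), acceptor (I_AA) and
FRET (I_DA) channel images, after background subtraction:

    FRET_c = I_DA − a·I_AA − d·I_DD            (bleed-through correction)
    index  = FRET_c / I_AA                     (sensor-amount-normalised)
    E      = (FRET_c/G) / (I_DD + FRET_c/G)    (FRET efficiency)

with cross-excitation fraction *a*, donor bleed-through *d* (defaults
0.045, both estimable from single-label stacks) and instrument factor *G*
(sensitized acceptor emission per unit quenched donor emission, estimated
from a high-/low-efficiency construct pair). For paired relaxed/stretched
states, ΔFRET E = (⟨E_s⟩ − ⟨E_r⟩)/⟨E_r⟩ — negative for net molecular
tension, positive for relaxation/compression.

**Spatial statistics on micropatterned cells.** Pearson colocalization,
sensor/actin enrichment ratio ρ (whole-cell mean normalised to 1, pixels
below 30% of mean sensor intensity excluded), radial profiles in r/R0 with
a central/peripheral split at 0.6, and angular profiles with profile–profile
correlation.

**Cytoskeletal structure.** Per-window orientation angles from the axis of
least second moment of the windowed 2D FFT power spectrum (16-px windows,
50% overlap), the nematic alignment order ⟨φ⟩ = 2⟨cos²δθ − ½⟩ over all
window pairs within a neighbourhood r (local r = 5 µm, global r = 10 µm),
and stress-fiber / cortical-actin segmentation by multi-scale ridge
filtering.

**Mechanics.** Drift registration, two-pass PIV with subpixel Gaussian peak
fitting, Fourier-transform traction cytometry (FTTC: regularized spectral
inversion of the Boussinesq half-space operator; 2.8 kPa gel, ν = 0.5
defaults) with the forward solution available as an independent oracle,
and an internal-force map |F̃| from the plane-stress force balance
∇·σ + t = 0 over the cell domain (homogeneous isotropic elasticity,
traction-free boundary), solved by finite elements on the traction grid.

**Strain response.** Per-compartment ΔFRET for stress fibers vs cortical
actin, the load-sharing slope m (OLS of SF ΔFRET on cortical ΔFRET per
stretch direction), and slope-equality testing across directions by the
ANCOVA interaction F-test — the statistic that carries the anisotropy
conclusion.

## Worked example

```python
import numpy as np
from tensionmap import synthetic as syn, fret
from tensionmap.types import SceneSpec, FretTruth
from tensionmap.stretch import LoadSharingModel

# a circular micropatterned cell (R0 = 12.5 µm) expressing a load-free
# sensor at uniform E = 0.22, imaged with 1% camera noise
spec = SceneSpec(shape="circle", R0=12.5, pixel_size=0.1, image_size=(300, 300))
masks = syn.make_mask(spec)
rng = np.random.default_rng(0)
truth = FretTruth(E_field=np.where(masks.cell, 0.22, 0.0),
                  S_field=syn.smooth_field(masks.cell.shape, rng),
                  a=0.045, d=0.045, G=2.0, noise="gaussian", noise_scale=0.01)
stack = syn.simulate_three_cube(masks, truth, seed=1)
maps = fret.compute_fret_maps(stack, fret.CalibrationConstants(a=0.045, d=0.045, G=2.0))
m, sd, n = fret.mean_fret(maps.E, masks.cell)
print(f"<FRET E> = {m:.4f} +/- {sd:.4f}  (n = {n} pixels)")

# load-sharing regression on a synthetic stretch series
recs = (syn.simulate_stretch_records(1.22, n_cells=13, orientation="parallel", seed=2)
        + syn.simulate_stretch_records(-0.77, n_cells=15, orientation="orthogonal", seed=3))
print(LoadSharingModel.from_records(recs).fit().summary())
```

prints

```
<FRET E> = 0.2200 +/- 0.0016  (n = 49080 pixels)
Load-sharing regression: SF dFRET ~ cortex dFRET
  orthogonal  m = -0.7630 +/- 0.0266  (intercept -0.0009, n = 60)
  parallel    m = +1.2278 +/- 0.0242  (intercept -0.0011, n = 52)
  slope equality: F = 3009, p = 1.084e-80
```

The recovered mean efficiency equals the prescribed 0.22 within the noise
floor; the two load-sharing slopes recover their generating values
(m > 1: stress fibers accumulate tension faster than the cortex when
stretched along the fiber axis; m < 0: they relax while the cortex loads
when stretched across it), and the interaction F-test flags the slopes as
different — the signature of an anisotropic strain response.

A command-line interface mirrors the library:
`tensionmap simulate|fret|profile|structure|tfm|balance|stretch|run`.

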