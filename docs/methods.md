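# Methods

This note documents the models behind each analysis stage, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## Three-cube FRET model

The sensor is a dimeric construct carrying one donor (GFP) and one
acceptor (RFP) per monomer, so donor and acceptor are present at molar
parity. The imaging model assumes a linear camera with a single gain per
channel. With sensor density S and efficiency E, the clean channels are

    I_DD = k·S·(1−E),   I_AA = k·S,   FRET_c = G·k·S·E,
    I_DA = FRET_c + a·I_AA + d·I_DD,

the generative inverse of the correction/efficiency equations, which is
why noise-free round trips recover E to machine precision — the identity
the first acceptance check asserts.

Parameters:

- **a, d** — acceptor cross-excitation and donor bleed-through fractions,
  default 0.045 each (typical for GFP/RFP filter sets; used as fallback
  when no calibration stacks are supplied, with a logged warning).
  Estimated from single-label stacks as the Theil–Sen slope through the
  origin of the pixel-wise I_DA-vs-reference scatter, averaged over cells.
  The robust slope guards against saturated or clipped pixels; the median
  of ratios is the exact through-origin Theil–Sen estimator.
- **G** — sensitized-emission/quenched-donor ratio, default 2.0. Estimated
  from two constructs of distinct efficiency via the line
  FRET_c/I_AA = const − G·(I_DD/I_AA). Because each construct occupies a
  single point of the abscissa up to noise, pooled pixel-wise OLS is an
  errors-in-variables regression whose slope attenuates under ratio noise;
  the implementation therefore takes the slope between the two construct
  centroids (the consistent limit of that regression) with a delta-method
  SE, and rejects construct pairs whose centroids are indistinguishable.
  Dim pixels (acceptor below 20% of its mean) are dropped first.
- **Validity mask** — pixels with I_AA or I_DD below 3× the background SD
  are NaN in the index and E maps; this prevents ratio blow-up in dim
  regions. Negative FRET_c values are retained (clipping would bias means)
  and counted in QC.
- **Background** — a scalar per channel, the median of an off-cell region
  (or the darkest-decile median when no region is given). Whether the
  original analysis subtracted per frame or per experiment is unknown;
  per-frame is the safer default.

ΔFRET E uses relative changes because they cancel the per-cell expression
level; the sign convention (negative = net tension) follows the sensor's
inverse distance–efficiency relation.

### FRAP

Recovery traces are fitted to I(t) = a + b·exp(−t/τ) by bounded
Levenberg–Marquardt with data-derived initial values (plateau from the
trace tail, amplitude from the bleach dip, τ from a third of the time
span). A trace whose amplitude is within 3× the point-to-point noise, or
whose fitted b is within 2 SE of zero, is flagged unidentifiable rather
than returning a meaningless τ. The default synthetic τ of 20 s matches
the sensor turnover timescale the strain protocol is designed around
(strain ramps shorter than turnover).

## Spatial statistics

The colocalization statistic is the standard 2D Pearson coefficient; a
zero-variance channel raises rather than silently returning NaN. The
enrichment ratio ρ = RFP/actin is normalised so its whole-cell mean is 1,
making ρ directly readable as fold-enrichment (the normalisation constant
is a free choice; this one is self-calibrating per cell). Pixels below
30% of the mean sensor intensity are excluded — the same low-expression
guard used when the ratio was introduced — as are pixels with effectively
no actin signal (ratio undefined), with the count reported.

Radial profiles run over r/R0 ∈ (0, 1] (R0 = 12.5 µm default, the
micropattern outer radius) in 20 bins; the central/peripheral split at
r/R0 = 0.6 is closed on the left (a pixel exactly at 0.6 is central).
Angular profiles average radially within 36 wedges and interpolate
(periodically) across empty wedges so downstream profile correlations are
NaN-free; correlations are reported both signed and as |C|.

Profile correlation operates on the θ-profiles; a 2D-field variant is
also provided because either reading is defensible for map-vs-map
comparisons (order vs FRET). Both are exposed so users can choose.

## Orientation and nematic order

Each 16×16-px window (50% overlap) is mean-subtracted, Hann-windowed and
FFT'd; the orientation is the axis of least second moment of the power
spectrum, rotated 90° back to real space. The DC bin and a 2-px
low-frequency disk are zeroed first — without this the DC term dominates
the moment tensor and the axis is meaningless. Windows with under 50% of
pixels inside the cell are NaN; partially inside windows have their
outside pixels replaced by the window mean (zero after mean subtraction).
Stripe fixtures at 0°/30°/45°/60° are recovered within ±2° per window;
isotropic noise gives near-uniform angles.

The order parameter ⟨φ⟩ = ⟨cos 2δθ⟩ is averaged over all distinct ordered
pairs of valid windows within the r×r square neighbourhood of each grid
point, using |Σe^{2iθ}|² = n + Σ_{i≠j} cos 2δθ for O(n) evaluation — an
identity, not an approximation, so it matches the literal double loop to
floating-point precision (asserted against a brute-force oracle). The
frequently used "tensor" form (squared mean resultant length) includes
the i=j terms and is biased upward by 1/n at small n; it is provided as
`method="tensor"` but the pair form is canonical here. Perpendicular
pairs contribute −1, so the raw pair average is negative for strongly
bimodal fields; because the order is often quoted on a 0–1 scale, a
clipped summary (`mean_clipped`) is reported alongside the raw mean.
Defaults r = 5 µm (local) and r = 10 µm (global): a radial stress-fiber
arrangement is locally aligned but globally disordered, so local > global
for such cells — the discriminating pattern between pattern shapes.

### Stress-fiber segmentation

Multi-scale Sato ridge enhancement (σ ∈ {1, 2} px), hysteresis threshold
at the (80th, 95th) in-cell ridge-response percentiles, then a
component filter: keep components at least 2 µm long whose peak
underlying intensity exceeds the robust in-cell background
(median + 5·MAD). The brightness test is what separates true fibers from
the crest lines of smooth cortex texture, which pass any pure
ridge-response threshold; with it, fiber-free synthetic cortex yields an
essentially empty SF mask while fixture fibers are recovered at
IoU 0.70–0.82. These defaults were calibrated on the synthetic fixtures;
the cortex mask is defined as the in-cell complement, so SF ∪ cortex =
cell exactly by construction.

## Traction force microscopy

Drift is removed by upsampled phase correlation (reported as the image's
drift relative to the reference). PIV correlates 32-px interrogation
windows by zero-padded linear cross-correlation with overlap
normalisation — circular correlation biases the peak toward zero lag by
the triangular overlap weighting — followed by a three-point Gaussian
subpixel fit, and a second pass with integer window offsets so the peak
sits in the best subpixel regime. Vectors failing the normalized-median
universal outlier test (threshold 2, ε = 0.1 px) are replaced by the
local median and flagged. At bead density 0.02/px² this yields ≤ 0.01 px
mean error on rigid motion and ≈ 0.12–0.15 px RMS on smooth fields. Both
grid-spacing presets used in practice (6.4 µm and 35 µm) are accepted;
the spacing is a free parameter.

Traction reconstruction is FTTC: the Boussinesq surface Green's tensor in
Fourier space, inverted per wavevector with zeroth-order Tikhonov
regularization. λ defaults to 0 (synthetic, noise-free data needs none);
an L-curve helper scans λ and picks the maximum-curvature corner. The DC
mode is zeroed, which enforces zero net reconstructed force exactly; the
residual is still measured and reported. ν = 0.5 (incompressible
polyacrylamide limit) and E_gel = 2800 Pa are defaults, both
configurable. The forward solution uses the same kernel and serves as the
oracle for round-trip testing (relative L2 error ~1e−10 at λ→0 on a
64×64 grid; the acceptance bound of 10% leaves room for noisy, regularized
use).

## Internal force balance

Internal forces are inferred from tractions under homogeneous isotropic
elasticity: 2D plane-stress equilibrium ∇·σ + t = 0 over the cell domain,
where t = −T is the substrate reaction to the cell's traction field, the
cell boundary is traction-free, ν_cell = 0.5 and thickness is 1 (|F̃| is
then a force per unit length). The solver assembles bilinear
quadrilateral finite elements on the traction grid, removes the
three-dimensional rigid-body null space by Lagrange constraints, and
evaluates stresses at element centres (averaged to nodes).
|F̃| = |(σ₁+σ₂)/2| — the magnitude of the mean principal (hydrostatic
in-plane) stress. The reported map is independent of the assumed cell
Young's modulus (stress = E·K⁻¹f and K ∝ E), linear in T, and exactly
equivariant under quarter-turn rotations of the grid.

Small net-force residuals in the input are subtracted uniformly over the
cell before solving (reported); imbalances above 20% of the total
traction magnitude are an error. The independent oracle is the
axisymmetric closed form: for a radial body force t_r(r) on a free disk,
Navier's equation collapses to d/dr[(1/r)(ru)′] = −t_r/E′, giving mean
stress = E/(2(1−ν))·(A − (1/E′)∫₀ʳ t_r ds) by quadrature. The FEM matches
this to <1% on a 64×64 disk, and reproduces the qualitative pattern that
inward peripheral traction yields the largest internal force at the cell
centre. The exact stress invariant and thickness convention used in the
original force-balance analysis are not published; the mean principal
stress at unit thickness is the standard monolayer-stress choice and is
parameterised so an alternative invariant can be swapped in.

## Stretch response

Uniaxial substrate stretch is modelled as the affine map
(1+ε_x, 1−ν_film·ε_x) with ν_film = 0.5, applied to masks and maps about
the image centre with nearest-neighbour resampling — compartment means are
then exactly preserved and the prescribed per-compartment ΔE is recovered
identically. Compartment masks are segmented in the relaxed frame and
warped to the stretched frame, keeping each pixel's compartment identity
fixed across the pair (re-segmenting the stretched frame could swap
identities and mix compartments).

The load-sharing model regresses SF ΔFRET on cortical ΔFRET by OLS per
stretch direction, and tests slope equality across directions with the
nested-model (interaction) F-test; a permutation oracle agrees with its
p-values on small synthetic sets, and its type-I error is ≈5% under
equal-slope simulation. Records flagged as detached are excluded before
fitting (the QC route for cells that release from the substrate at high
strain under myosin inhibition). Summary-level record generation draws
one relaxed/stretched pair per cell per strain level (5–20%), i.e. the
stretch-cycle protocol pooled across strains, with 13–15 cells per
direction as the default study size; cortical ΔE is uniform on ±0.1 and
SF scatter is 0.01 SD about the prescribed slope. The ±2·SE interval of
the fitted slope then covers the truth at the exact t(n−2) rate (~95.3%);
the acceptance test checks this calibration by a one-sided exact binomial
test rather than a sharp ≥95% cut, which a perfectly calibrated estimator
would fail on ~45% of finite seed panels.

## What the synthetic data does and does not emulate

Emulated: micropattern geometries (circle/square/triangle), three-cube
channel mixing with realistic bleed-through, sensor-density texture,
Gaussian (sCMOS-like, σ = 1% of channel mean) or Poisson noise, fiber/
cortex actin texture with known orientations and masks, subpixel bead
displacements consistent with the elastic forward model, film-kinematics
stretching, exponential FRAP recovery.

Not emulated: photobleaching and fluorophore maturation, 3D PSF and
optical sectioning, inter/intradimeric FRET between neighbouring sensors
(an optional additive per-compartment FRET offset exists, but no
generative model for its functional form is published), focal-plane
drift, segmentation-confounding organelles. Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
stated image model — not robustness to every real-microscope artifact.

## Numerical choices and limitations

- All simulations are seeded (numpy `default_rng`); the demo pipeline is
  byte-deterministic under a fixed seed, and provenance JSON records the
  config hash, seed and output hashes.
- Problem sizes used in tests and the acceptance script (300² px FRET
  scenes, 10⁵-px calibration stacks, 256² bead images, 64² mechanics
  grids, 200-seed regression panels) were chosen to make every check
  sharp at desk scale while keeping the whole suite in the minutes range.
- The FEM force balance requires the mask to be reasonably resolved on
  the traction grid (≥ ~10 nodes across) for the 2% oracle agreement;
  multi-component or holed masks are warned about, not rejected.
- FTTC assumes an infinite elastic half-space sampled periodically;
  fields approaching the grid boundary wrap around. Keep tractions inside
  ~2/3 of the field of view.
- The angular-profile interpolation fills empty wedges linearly in θ;
  profiles from very sparse maps are smooth by construction, which can
  understate angular heterogeneity.
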