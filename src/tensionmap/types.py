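"""Shared data containers for the tension-map pipeline.

These are deliberately thin: plain dataclasses around numpy arrays with the
metadata (pixel size, grid spacing, calibration constants) that downstream
stages need.  Images are ``float64`` internally; I/O converts to 16-bit
integer TIFF at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SceneSpec",
    "FretTruth",
    "MechTruth",
    "StretchTruth",
    "ChannelStack",
    "CalibrationConstants",
    "FretMaps",
    "RegionMasks",
    "CompartmentMasks",
    "OrientationField",
    "OrderMap",
    "DisplacementField",
    "TractionField",
    "InternalForceMap",
    "RadialProfile",
    "AngularProfile",
    "StretchRecord",
]

_SHAPES = ("circle", "square", "triangle")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of a micropatterned scene.

    Parameters
    ----------
    shape : {"circle", "square", "triangle"}
        Micropattern shape.
    R0 : float
        Outer radius (circle) or half-size (square/triangle), in µm.
    pixel_size : float
        µm per pixel.
    image_size : tuple of int
        (rows, cols) of the rendered image.
    seed : int
        Seed for every random element of the scene.
    """

    shape: str = "circle"
    R0: float = 12.5
    pixel_size: float = 0.1
    image_size: tuple = (300, 300)
    seed: int = 0

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        r_px = self.R0 / self.pixel_size
        if 2 * r_px > min(self.image_size):
            raise ValueError(
                f"pattern (diameter {2 * r_px:.0f} px) exceeds image bounds {self.image_size}"
            )

    @property
    def center(self) -> tuple:
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)

    @property
    def R0_px(self) -> float:
        return self.R0 / self.pixel_size


@dataclass
class FretTruth:
    """Ground truth for a synthetic three-cube FRET scene.

    ``E_field`` is the FRET-efficiency map (donor excitations transferred to
    the acceptor), ``S_field`` the sensor density.  ``a`` is the acceptor
    cross-excitation fraction, ``d`` the donor bleed-through fraction, ``G``
    the ratio of sensitized acceptor emission to quenched donor emission.
    """

    E_field: np.ndarray
    S_field: np.ndarray
    a: float = 0.045
    d: float = 0.045
    G: float = 2.0
    noise: str = "none"          # none | gaussian | poisson
    noise_scale: float = 0.01    # gaussian: fraction of channel mean
    background: float = 0.0
    gain: float = 1000.0         # photons per unit sensor density per channel

    def __post_init__(self):
        if not (0 <= self.a < 1 and 0 <= self.d < 1):
            raise ValueError("bleed-through fractions must lie in [0, 1)")
        if self.G <= 0:
            raise ValueError("G must be positive")
        if np.any(np.asarray(self.E_field) >= 1):
            raise ValueError("E_field must be < 1 everywhere")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class MechTruth:
    """Ground truth for a synthetic traction-force scene."""

    traction_field: np.ndarray          # (ny, nx, 2) Pa
    grid_spacing: float                 # µm between traction grid nodes
    E_gel: float = 2800.0               # Pa
    nu: float = 0.5
    bead_density: float = 0.02          # beads / px²
    bead_sigma: float = 1.5             # px
    pixel_size: float = 0.1             # µm / px

    def __post_init__(self):
        if not (0 <= self.nu <= 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.E_gel <= 0:
            raise ValueError("E_gel must be positive")
        if self.bead_density <= 0:
            raise ValueError("bead_density must be positive")


@dataclass
class StretchTruth:
    """Ground truth for a synthetic uniaxial stretch series."""

    strains: tuple = (0.05, 0.10, 0.15, 0.20)
    delta_E_sf: float = -0.05
    delta_E_cortex: float = -0.04
    slope: Optional[float] = None       # if set, SF ΔE = slope · cortex ΔE
    nu_film: float = 0.5                # transverse contraction of the film
    E_baseline: float = 0.22

    def __post_init__(self):
        if any(s < 0 for s in self.strains):
            raise ValueError("strains must be nonnegative")


@dataclass
class ChannelStack:
    """Co-registered three-cube FRET channels plus optional extras.

    Channels follow the three-cube convention: ``I_DD`` donor excitation /
    donor emission, ``I_AA`` acceptor excitation / acceptor emission,
    ``I_DA`` donor excitation / acceptor emission (the FRET channel).
    """

    I_DD: np.ndarray
    I_AA: np.ndarray
    I_DA: np.ndarray
    actin: Optional[np.ndarray] = None
    beads: Optional[np.ndarray] = None
    pixel_size: float = 0.1
    label: str = ""

    def __post_init__(self):
        if not (self.I_DD.shape == self.I_AA.shape == self.I_DA.shape):
            raise ValueError("FRET channels must share one shape")

    @property
    def shape(self):
        return self.I_DD.shape


@dataclass
class CalibrationConstants:
    """Three-cube calibration: bleed-through fractions and the G factor."""

    a: float = 0.045
    d: float = 0.045
    G: float = 2.0
    a_se: float = float("nan")
    d_se: float = float("nan")
    G_se: float = float("nan")
    n_pixels: int = 0

    def __post_init__(self):
        if not (0 <= self.a < 1 and 0 <= self.d < 1):
            raise ValueError("bleed-through fractions must lie in [0, 1)")
        if self.G <= 0:
            raise ValueError("G must be positive")


@dataclass
class FretMaps:
    """Pixel-wise FRET quantification products."""

    fret_c: np.ndarray
    index: np.ndarray
    E: np.ndarray
    valid: np.ndarray
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    n_negative_fret_c: int = 0


@dataclass
class RegionMasks:
    """Cell mask plus the micropattern geometry that generated it."""

    cell: np.ndarray
    center: tuple
    R0: float                 # µm
    pixel_size: float
    shape: str = "circle"


@dataclass
class CompartmentMasks:
    """Stress-fiber / cortical-actin partition of the cell mask.

    Invariant: ``sf | cortex == cell`` and ``sf & cortex == ∅``.
    """

    sf: np.ndarray
    cortex: np.ndarray
    cell: np.ndarray

    def __post_init__(self):
        if np.any(self.sf & self.cortex):
            raise ValueError("SF and cortex masks overlap")
        if not np.array_equal(self.sf | self.cortex, self.cell.astype(bool)):
            raise ValueError("SF and cortex masks must partition the cell mask")


@dataclass
class OrientationField:
    """Per-window actin orientation angles on a regular window grid.

    ``theta`` is in degrees, nematic convention (θ ≡ θ + 180°), folded into
    (−90, 90].  ``rows``/``cols`` are window-centre pixel coordinates.
    """

    theta: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    window: int = 16
    overlap: float = 0.5
    pixel_size: float = 0.1

    @property
    def grid_step_px(self) -> float:
        return self.window * (1.0 - self.overlap)


@dataclass
class OrderMap:
    """Nematic order ⟨φ⟩ evaluated per window over a neighbourhood of size r."""

    phi: np.ndarray
    r_um: float
    mean: float
    mean_clipped: float
    method: str = "pairs"


@dataclass
class DisplacementField:
    """Gridded substrate displacement from PIV."""

    x: np.ndarray             # µm, grid columns
    y: np.ndarray             # µm, grid rows
    u: np.ndarray             # (ny, nx, 2) µm, (ux, uy)
    quality: np.ndarray       # correlation peak quality in [0,1]
    replaced: np.ndarray      # bool, outlier-replaced vectors
    grid_spacing: float       # µm


@dataclass
class TractionField:
    """Gridded traction stress reconstructed on the gel surface."""

    x: np.ndarray
    y: np.ndarray
    T: np.ndarray             # (ny, nx, 2) Pa
    grid_spacing: float       # µm
    E_gel: float = 2800.0
    nu: float = 0.5
    lam: float = 0.0
    net_force: tuple = (0.0, 0.0)   # N, residual after reconstruction

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.T[..., 0], self.T[..., 1])


@dataclass
class InternalForceMap:
    """Internal force magnitude |F̃| from the plane-stress force balance."""

    F: np.ndarray             # |F̃| per grid node, zero outside cell
    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_xy: np.ndarray
    grid_spacing: float
    thickness: float = 1.0


@dataclass
class RadialProfile:
    """Radial intensity profile on the (0, 1] r/R0 axis."""

    r_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    central_mean: float       # r/R0 <= 0.6 (closed-left split)
    peripheral_mean: float    # r/R0 > 0.6


@dataclass
class AngularProfile:
    """Radially-averaged value as a function of the angle from the centre."""

    theta_deg: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        if np.any(np.isnan(self.value)):
            raise ValueError("angular profile must be NaN-free after interpolation")


@dataclass
class StretchRecord:
    """Paired relaxed/stretched measurements for one cell at one strain."""

    cell_id: str
    orientation: str                    # parallel | orthogonal
    strain: float                       # applied strain (fraction)
    condition: str = "none"
    E_relaxed: float = float("nan")     # whole-cell ⟨E⟩
    E_stretched: float = float("nan")
    E_sf_relaxed: float = float("nan")
    E_sf_stretched: float = float("nan")
    E_cortex_relaxed: float = float("nan")
    E_cortex_stretched: float = float("nan")
    rfp_total_relaxed: float = float("nan")
    rfp_total_stretched: float = float("nan")
    area_relaxed: float = float("nan")  # µm²
    area_stretched: float = float("nan")
    detached: bool = False              # QC flag; dropped from regressions

    def __post_init__(self):
        if self.orientation not in ("parallel", "orthogonal"):
            raise ValueError("orientation must be 'parallel' or 'orthogonal'")
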