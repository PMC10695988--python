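"""Synthetic microscopy scenes with known ground truth.

Every input the analysis pipeline consumes can be generated here: three-cube
FRET channel stacks with a prescribed efficiency field, fiber-textured actin
images with prescribed orientations, bead-image pairs with prescribed
substrate displacements, uniaxial stretch series with prescribed compartment
responses, and FRAP recovery traces.  The generators are the exact inverse
of the corresponding quantification steps, so noise-free round trips recover
the truth to machine precision.

Default study conditions: circular micropatterns of outer radius
R0 = 12.5 µm, bleed-through fractions a = d = 0.045, 2.8 kPa gel substrate,
film Poisson ratio 0.5, applied strains {5, 10, 15, 20}%, sensor turnover
time 20 s.  Noise defaults to Gaussian with SD 1% of the channel mean
(sCMOS regime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import (
    ChannelStack,
    CompartmentMasks,
    FretTruth,
    MechTruth,
    RegionMasks,
    SceneSpec,
    StretchRecord,
    StretchTruth,
)

__all__ = [
    "make_mask",
    "smooth_field",
    "simulate_three_cube",
    "simulate_donor_only",
    "simulate_acceptor_only",
    "simulate_g_pair",
    "simulate_fiber_image",
    "stripe_image",
    "FiberScene",
    "BeadPair",
    "simulate_bead_pair",
    "gaussian_traction_patch",
    "inward_traction_ring",
    "StretchScene",
    "simulate_stretch_experiment",
    "simulate_stretch_records",
    "simulate_frap_trace",
]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_mask(spec: SceneSpec) -> RegionMasks:
    """Binary micropattern mask (circle, square, or equilateral triangle).

    The pattern is centred in the image; circles use ``R0`` as the outer
    radius, squares as the half-size, triangles as the circumradius.
    """
    ny, nx = spec.image_size
    cy, cx = spec.center
    r_px = spec.R0_px
    yy, xx = np.mgrid[0:ny, 0:nx]
    if spec.shape == "circle":
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2
    elif spec.shape == "square":
        mask = (np.abs(yy - cy) <= r_px) & (np.abs(xx - cx) <= r_px)
    else:  # equilateral triangle, apex up, circumradius R0
        verts = []
        for k in range(3):
            ang = -math.pi / 2 + 2 * math.pi * k / 3
            verts.append((cy + r_px * math.sin(ang), cx + r_px * math.cos(ang)))
        mask = np.ones((ny, nx), bool)
        for k in range(3):
            (y1, x1), (y2, x2) = verts[k], verts[(k + 1) % 3]
            # half-plane test: interior lies on the same side as the centroid
            s = (xx - x1) * (y2 - y1) - (yy - y1) * (x2 - x1)
            sc = (cx - x1) * (y2 - y1) - (cy - y1) * (x2 - x1)
            mask &= (s * sc) >= 0
    return RegionMasks(cell=mask, center=(cy, cx), R0=spec.R0,
                       pixel_size=spec.pixel_size, shape=spec.shape)


def smooth_field(shape, rng, mean=1.0, rel_sd=0.2, sigma_px=10.0, low=0.1):
    """Positive smooth random field: gaussian-filtered white noise.

    Used for sensor-density and efficiency textures; clipped below at
    ``low * mean`` so intensities stay positive.
    """
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, sigma_px)
    f = f / max(np.std(f), 1e-12)
    return np.clip(mean * (1.0 + rel_sd * f), low * mean, None)


# ---------------------------------------------------------------------------
# Three-cube FRET stacks
# ---------------------------------------------------------------------------

def _apply_noise(channels, truth, rng):
    out = []
    for c in channels:
        if truth.noise == "none":
            out.append(c)
        elif truth.noise == "gaussian":
            sd = truth.noise_scale * max(float(np.mean(c)), 1e-12)
            out.append(c + rng.normal(0.0, sd, c.shape))
        else:  # poisson on photon counts
            out.append(rng.poisson(np.clip(c, 0, None)).astype(float))
    return out


def simulate_three_cube(masks: RegionMasks, truth: FretTruth, seed=0,
                        label="") -> ChannelStack:
    """Generate a three-cube stack that inverts exactly under quantification.

    Clean-channel model (donor/acceptor molar parity, single gain ``k``)::

        I_DD  = k·S·(1−E)
        I_AA  = k·S
        FRET_c = G·I_DD·E/(1−E) = G·k·S·E
        I_DA  = FRET_c + a·I_AA + d·I_DD

    Background is added to every channel after the bleed-through mixing and
    noise is applied last, so background-subtracted noise-free stacks invert
    to ``E`` at machine precision.
    """
    E = np.asarray(truth.E_field, float)
    S = np.asarray(truth.S_field, float)
    cell = np.asarray(masks.cell, bool)
    if E.shape != cell.shape or S.shape != cell.shape:
        raise ValueError("E_field/S_field must match the mask shape")
    if np.any(E >= 1):
        raise ValueError("E_field must be < 1 everywhere")
    S = np.where(cell, S, 0.0)
    k = truth.gain
    I_DD = k * S * (1.0 - E)
    I_AA = k * S
    fret_c = truth.G * k * S * E
    I_DA = fret_c + truth.a * I_AA + truth.d * I_DD
    rng = np.random.default_rng(seed)
    I_DD, I_AA, I_DA = _apply_noise([I_DD, I_AA, I_DA], truth, rng)
    bg = truth.background
    return ChannelStack(I_DD=I_DD + bg, I_AA=I_AA + bg, I_DA=I_DA + bg,
                        pixel_size=masks.pixel_size, label=label)


def simulate_donor_only(shape, d=0.045, gain=1000.0, seed=0, noise="none",
                        noise_scale=0.01, pixel_size=0.1) -> ChannelStack:
    """Donor-only (GFP) calibration stack: I_DA = d·I_DD, I_AA ≈ 0."""
    rng = np.random.default_rng(seed)
    S = smooth_field(shape, rng, mean=1.0, rel_sd=0.5, sigma_px=5.0)
    I_DD = gain * S
    I_DA = d * I_DD
    I_AA = np.zeros(shape)
    truth = FretTruth(E_field=np.zeros(shape), S_field=S, noise=noise,
                      noise_scale=noise_scale)
    I_DD, I_AA, I_DA = _apply_noise([I_DD, I_AA, I_DA], truth, rng)
    return ChannelStack(I_DD=I_DD, I_AA=I_AA, I_DA=I_DA, pixel_size=pixel_size,
                        label="donor-only")


def simulate_acceptor_only(shape, a=0.045, gain=1000.0, seed=0, noise="none",
                           noise_scale=0.01, pixel_size=0.1) -> ChannelStack:
    """Acceptor-only (RFP) calibration stack: I_DA = a·I_AA, I_DD ≈ 0."""
    rng = np.random.default_rng(seed)
    S = smooth_field(shape, rng, mean=1.0, rel_sd=0.5, sigma_px=5.0)
    I_AA = gain * S
    I_DA = a * I_AA
    I_DD = np.zeros(shape)
    truth = FretTruth(E_field=np.zeros(shape), S_field=S, noise=noise,
                      noise_scale=noise_scale)
    I_DD, I_AA, I_DA = _apply_noise([I_DD, I_AA, I_DA], truth, rng)
    return ChannelStack(I_DD=I_DD, I_AA=I_AA, I_DA=I_DA, pixel_size=pixel_size,
                        label="acceptor-only")


def simulate_g_pair(shape, G=2.0, E_high=0.33, E_low=0.12, a=0.045, d=0.045,
                    seed=0, noise="none", noise_scale=0.01):
    """High/low-efficiency construct pair for G-factor calibration.

    Emulates short-linker (high-E) vs long-linker (low-E) constructs with
    1:1 donor:acceptor stoichiometry and spatially varying expression.
    """
    rng = np.random.default_rng(seed)
    stacks = []
    for E0, sub in ((E_high, 1), (E_low, 2)):
        S = smooth_field(shape, rng, mean=1.0, rel_sd=0.5, sigma_px=5.0)
        masks = RegionMasks(cell=np.ones(shape, bool), center=(0, 0), R0=1.0,
                            pixel_size=0.1)
        truth = FretTruth(E_field=np.full(shape, E0), S_field=S, a=a, d=d,
                          G=G, noise=noise, noise_scale=noise_scale)
        stacks.append(simulate_three_cube(masks, truth, seed=seed * 1000 + sub))
    return stacks[0], stacks[1]


# ---------------------------------------------------------------------------
# Fiber-textured actin
# ---------------------------------------------------------------------------

@dataclass
class FiberScene:
    """A synthetic actin image and its ground truth."""

    image: np.ndarray
    angle_map: np.ndarray     # degrees in (-90, 90]; NaN off-fiber
    sf_mask: np.ndarray       # true stress-fiber mask
    cell: np.ndarray


def fold_angle(theta_deg):
    """Fold angles to the nematic range (−90, 90]."""
    t = (np.asarray(theta_deg, float) + 90.0) % 180.0 - 90.0
    return np.where(t == -90.0, 90.0, t)


def simulate_fiber_image(masks: RegionMasks, orientation=0.0, n_fibers=25,
                         fiber_length_um=(6.0, 14.0), fiber_sigma_px=1.5,
                         fiber_amp=4.0, cortex_amp=1.0, cortex_sigma_px=2.0,
                         seed=0) -> FiberScene:
    """Bright anisotropic ridges over an isotropic cortex texture.

    ``orientation`` may be a constant angle (degrees), the string
    ``"radial"`` (fibers point away from the pattern centre), or a callable
    ``(y_px, x_px) -> degrees``.  The returned ``angle_map`` carries the true
    fiber angle on fiber pixels and NaN elsewhere; ``sf_mask`` is the true
    stress-fiber footprint (rendered ridge above half its peak profile).
    """
    if n_fibers < 0:
        raise ValueError("n_fibers must be nonnegative")
    rng = np.random.default_rng(seed)
    cell = np.asarray(masks.cell, bool)
    ny, nx = cell.shape
    px = masks.pixel_size
    canvas = np.zeros((ny, nx))
    angle_map = np.full((ny, nx), np.nan)

    if callable(orientation):
        angle_at = orientation
    elif orientation == "radial":
        cy, cx = masks.center

        def angle_at(y, x):
            return math.degrees(math.atan2(-(y - cy), x - cx))
    else:
        ang0 = float(orientation)

        def angle_at(y, x):
            return ang0

    inside = np.argwhere(cell)
    for _ in range(n_fibers):
        y0, x0 = inside[rng.integers(len(inside))]
        theta = fold_angle(angle_at(y0, x0))
        L = rng.uniform(*fiber_length_um) / px
        # image rows increase downward: angle θ means direction (cosθ, −sinθ)
        dx, dy = math.cos(math.radians(theta)), -math.sin(math.radians(theta))
        n_steps = max(int(L), 2)
        t = np.linspace(-L / 2, L / 2, n_steps)
        ys, xs = y0 + t * dy, x0 + t * dx
        sel = (ys >= 0) & (ys <= ny - 1) & (xs >= 0) & (xs <= nx - 1)
        ys, xs = ys[sel], xs[sel]
        line = np.zeros((ny, nx))
        line[np.clip(np.round(ys).astype(int), 0, ny - 1),
             np.clip(np.round(xs).astype(int), 0, nx - 1)] = 1.0
        line = ndimage.gaussian_filter(line, fiber_sigma_px)
        if line.max() > 0:
            line /= line.max()
        on = line > 0.5
        canvas += fiber_amp * line
        angle_map[on & cell] = theta

    cortex = ndimage.gaussian_filter(rng.standard_normal((ny, nx)),
                                     cortex_sigma_px)
    cortex = cortex_amp * (1.0 + 0.5 * cortex / max(np.std(cortex), 1e-12))
    image = np.where(cell, np.clip(cortex, 0, None) + canvas, 0.0)
    sf_mask = np.isfinite(angle_map) & cell
    return FiberScene(image=image, angle_map=angle_map, sf_mask=sf_mask,
                      cell=cell)


def stripe_image(shape, angle_deg, period_px=8.0, phase=0.0):
    """Sinusoidal stripe texture at a given real-space orientation.

    Stripes *run along* ``angle_deg`` (their intensity gradient is
    perpendicular to it) — the fixture for orientation-field accuracy.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    th = math.radians(angle_deg)
    # coordinate perpendicular to the stripe direction (y axis points down)
    u = xx * (-math.sin(th)) + (-yy) * math.cos(th)
    return 0.5 + 0.5 * np.cos(2 * math.pi * u / period_px + phase)


# ---------------------------------------------------------------------------
# Bead pairs for TFM
# ---------------------------------------------------------------------------

@dataclass
class BeadPair:
    """Reference/deformed bead images with the prescribed displacement."""

    reference: np.ndarray
    deformed: np.ndarray
    positions: np.ndarray     # (n, 2) px (row, col) reference positions
    u_fn: Callable            # (y_px, x_px) -> (uy_px, ux_px)
    pixel_size: float

    def true_displacement(self, rows_px, cols_px):
        """Evaluate the true displacement (px) at pixel coordinates."""
        uy, ux = self.u_fn(np.asarray(rows_px, float), np.asarray(cols_px, float))
        return np.asarray(uy, float), np.asarray(ux, float)


def _render_beads(shape, positions, sigma, amplitude=1000.0):
    """Sum of Gaussian spots at subpixel positions (vectorised, windowed)."""
    ny, nx = shape
    img = np.zeros((ny, nx))
    w = int(math.ceil(4 * sigma))
    for y0, x0 in positions:
        iy, ix = int(round(y0)), int(round(x0))
        y1, y2 = max(iy - w, 0), min(iy + w + 1, ny)
        x1, x2 = max(ix - w, 0), min(ix + w + 1, nx)
        if y1 >= y2 or x1 >= x2:
            continue
        yy, xx = np.mgrid[y1:y2, x1:x2]
        img[y1:y2, x1:x2] += amplitude * np.exp(
            -((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma ** 2))
    return img


def simulate_bead_pair(mech: MechTruth, image_shape=(256, 256), seed=0,
                       displacement=None, noise_sd=0.0,
                       search_window_px=32) -> BeadPair:
    """Bead-image pair whose deformed frame is the reference warped by u.

    The displacement field is either prescribed directly (``displacement``:
    a callable ``(y_px, x_px) -> (uy_px, ux_px)``) or computed from the
    traction field in ``mech`` through the elastic half-space (Boussinesq)
    forward solution.  Beads are rendered analytically at displaced subpixel
    positions, so the warp is exact; the same beads appear in both frames.
    """
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    n_beads = int(mech.bead_density * ny * nx)
    pos = rng.uniform([0, 0], [ny, nx], size=(n_beads, 2))

    if displacement is None:
        from .mechanics import forward_boussinesq
        from .types import TractionField
        T = np.asarray(mech.traction_field, float)
        gny, gnx = T.shape[:2]
        h = mech.grid_spacing
        tf = TractionField(
            x=np.arange(gnx) * h, y=np.arange(gny) * h, T=T,
            grid_spacing=h, E_gel=mech.E_gel, nu=mech.nu)
        disp = forward_boussinesq(tf, mech.E_gel, mech.nu)
        # interpolate the µm-grid displacement onto pixel coordinates
        from scipy.interpolate import RegularGridInterpolator
        pts_y = disp.y / mech.pixel_size
        pts_x = disp.x / mech.pixel_size
        f_uy = RegularGridInterpolator((pts_y, pts_x),
                                       disp.u[..., 1] / mech.pixel_size,
                                       bounds_error=False, fill_value=0.0)
        f_ux = RegularGridInterpolator((pts_y, pts_x),
                                       disp.u[..., 0] / mech.pixel_size,
                                       bounds_error=False, fill_value=0.0)

        def displacement(y, x):
            pts = np.stack([np.atleast_1d(y), np.atleast_1d(x)], axis=-1)
            return f_uy(pts), f_ux(pts)

    uy, ux = displacement(pos[:, 0], pos[:, 1])
    umax = float(np.max(np.hypot(np.ravel(uy), np.ravel(ux)))) if n_beads else 0.0
    if umax > search_window_px / 2:
        import warnings
        warnings.warn(
            f"max displacement {umax:.1f} px exceeds half the PIV search "
            f"window ({search_window_px} px); PIV may lose correlation")
    ref = _render_beads(image_shape, pos, mech.bead_sigma)
    moved = pos + np.stack([np.ravel(uy), np.ravel(ux)], axis=1)
    deformed = _render_beads(image_shape, moved, mech.bead_sigma)
    if noise_sd > 0:
        ref = ref + rng.normal(0, noise_sd, ref.shape)
        deformed = deformed + rng.normal(0, noise_sd, deformed.shape)
    return BeadPair(reference=ref, deformed=deformed, positions=pos,
                    u_fn=displacement, pixel_size=mech.pixel_size)


def gaussian_traction_patch(grid_shape, grid_spacing, magnitude=200.0,
                            sigma_um=8.0, separation_um=20.0):
    """Balanced pair of opposing Gaussian traction patches (Pa).

    Two equal-and-opposite x-directed patches along the grid midline, so the
    net force is zero by construction — the canonical contractile dipole.
    """
    ny, nx = grid_shape
    h = grid_spacing
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float) * h
    cy, cx = (ny - 1) * h / 2, (nx - 1) * h / 2
    T = np.zeros((ny, nx, 2))
    for sgn in (+1, -1):
        x0 = cx + sgn * separation_um / 2
        g = np.exp(-((yy - cy) ** 2 + (xx - x0) ** 2) / (2 * sigma_um ** 2))
        T[..., 0] += -sgn * magnitude * g    # patches pull inward
    return T


def inward_traction_ring(grid_shape, grid_spacing, magnitude=100.0,
                         r0_um=None, width_um=4.0, center=None):
    """Axisymmetric inward radial traction ring (Pa) — auto-balanced."""
    ny, nx = grid_shape
    h = grid_spacing
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float) * h
    if center is None:
        cy, cx = (ny - 1) * h / 2, (nx - 1) * h / 2
    else:
        cy, cx = center
    r = np.hypot(yy - cy, xx - cx)
    prof = np.exp(-((r - (r0_um if r0_um else 0.35 * min(ny, nx) * h)) ** 2)
                  / (2 * width_um ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        ery = np.where(r > 0, (yy - cy) / r, 0.0)
        erx = np.where(r > 0, (xx - cx) / r, 0.0)
    T = np.zeros((ny, nx, 2))
    T[..., 0] = -magnitude * prof * erx
    T[..., 1] = -magnitude * prof * ery
    return T


# ---------------------------------------------------------------------------
# Stretch series
# ---------------------------------------------------------------------------

@dataclass
class StretchScene:
    """Paired relaxed/stretched efficiency maps with compartment masks."""

    E_relaxed: np.ndarray
    E_stretched: np.ndarray
    masks_relaxed: CompartmentMasks
    masks_stretched: CompartmentMasks
    rfp_relaxed: np.ndarray
    rfp_stretched: np.ndarray
    strain: float
    truth: StretchTruth


def _affine_stretch(arr, strain, nu_film, order=0):
    """Apply the film kinematics (1+ε_x, 1−ν·ε_x) about the image centre."""
    ny, nx = arr.shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    # output -> input mapping: divide by the stretch factors
    mat = np.array([[1.0 / (1.0 - nu_film * strain), 0.0],
                    [0.0, 1.0 / (1.0 + strain)]])
    offset = np.array([cy, cx]) - mat @ np.array([cy, cx])
    return ndimage.affine_transform(arr.astype(float), mat, offset=offset,
                                    order=order, mode="constant", cval=0.0)


def simulate_stretch_experiment(masks: RegionMasks, truth: StretchTruth,
                                strain=0.10, seed=0, noise_sd=0.0,
                                sf_fraction=0.25) -> StretchScene:
    """One relaxed/stretched pair with prescribed compartment ΔE.

    The relaxed cell carries uniform efficiencies per compartment
    (baseline ``E_baseline`` on the cortex, slightly lower on stress
    fibers); stretching multiplies each compartment by ``1 + ΔE`` and warps
    all masks and maps by the affine film kinematics (ε_x, −ν_film·ε_x).
    Per-compartment mean ΔFRET therefore equals the prescribed ΔE exactly
    in the noise-free case.
    """
    rng = np.random.default_rng(seed)
    cell = np.asarray(masks.cell, bool)
    ny, nx = cell.shape
    # deterministic horizontal SF band pattern inside the cell
    yy = np.mgrid[0:ny, 0:nx][0]
    band = (yy // max(int(sf_fraction * 20), 2)) % 4 == 0
    sf = band & cell
    cortex = cell & ~sf
    comp_r = CompartmentMasks(sf=sf, cortex=cortex, cell=cell)

    E_sf_r = truth.E_baseline * 0.9
    E_cx_r = truth.E_baseline
    E_r = np.where(sf, E_sf_r, np.where(cortex, E_cx_r, np.nan))
    E_s_vals = np.where(sf, E_sf_r * (1.0 + truth.delta_E_sf),
                        np.where(cortex, E_cx_r * (1.0 + truth.delta_E_cortex),
                                 np.nan))
    rfp_r = np.where(cell, 1000.0, 0.0)

    warp = lambda a, order=0: _affine_stretch(np.nan_to_num(a), strain,
                                              truth.nu_film, order)
    cell_s = warp(cell.astype(float)) > 0.5
    sf_s = (warp(sf.astype(float)) > 0.5) & cell_s
    cortex_s = cell_s & ~sf_s
    E_s = warp(E_s_vals)
    E_s = np.where(cell_s, E_s, np.nan)
    rfp_s = warp(rfp_r)
    if noise_sd > 0:
        E_r = E_r + rng.normal(0, noise_sd, E_r.shape)
        E_s = E_s + rng.normal(0, noise_sd, E_s.shape)
    comp_s = CompartmentMasks(sf=sf_s, cortex=cortex_s, cell=cell_s)
    return StretchScene(E_relaxed=E_r, E_stretched=E_s, masks_relaxed=comp_r,
                        masks_stretched=comp_s, rfp_relaxed=rfp_r,
                        rfp_stretched=rfp_s, strain=strain, truth=truth)


def simulate_stretch_records(slope, n_cells=15, orientation="parallel",
                             condition="none", seed=0, E_baseline=0.22,
                             cortex_delta_range=(-0.10, 0.10),
                             noise_sd=0.01, strains=(0.05, 0.10, 0.15, 0.20)):
    """Summary-level stretch records with a prescribed load-sharing slope.

    Each cell is measured through the whole strain series (one relaxed/
    stretched pair per applied strain, as in a stretch-cycle protocol), so
    the regression pools cells × strains.  Per pair, the cortical ΔE is
    drawn uniformly from ``cortex_delta_range`` and the stress-fiber ΔE is
    ``slope · cortex ΔE`` plus Gaussian scatter of SD ``noise_sd``.
    Compartment means are back-computed so the records invert exactly under
    the ΔFRET definition.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_cells):
        for strain in strains:
            d_cx = rng.uniform(*cortex_delta_range)
            d_sf = slope * d_cx + rng.normal(0, noise_sd)
            E_cx_r = E_baseline
            E_sf_r = E_baseline * 0.9
            w_sf = 0.3   # SF area fraction for the whole-cell mean
            E_cell_r = w_sf * E_sf_r + (1 - w_sf) * E_cx_r
            E_cell_s = (w_sf * E_sf_r * (1 + d_sf)
                        + (1 - w_sf) * E_cx_r * (1 + d_cx))
            records.append(StretchRecord(
                cell_id=f"{orientation[:4]}-{i:03d}", orientation=orientation,
                strain=strain, condition=condition,
                E_relaxed=E_cell_r, E_stretched=E_cell_s,
                E_sf_relaxed=E_sf_r, E_sf_stretched=E_sf_r * (1 + d_sf),
                E_cortex_relaxed=E_cx_r, E_cortex_stretched=E_cx_r * (1 + d_cx),
                rfp_total_relaxed=1e6, rfp_total_stretched=1e6,
                area_relaxed=490.0,
                area_stretched=490.0 * (1 + strain) * (1 - 0.5 * strain),
            ))
    return records


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def simulate_frap_trace(tau=20.0, a=1.0, b=-0.6, dt=1.0, T=100.0,
                        noise_sd=0.0, seed=0):
    """Exponential recovery trace ``I(t) = a + b·exp(−t/τ)`` (+ noise).

    ``b < 0`` gives recovery from a bleached dip toward the plateau ``a``.
    Returns ``(t, intensity)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.arange(0.0, T + dt / 2, dt)
    y = a + b * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise_sd, y.shape)
    return t, y
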