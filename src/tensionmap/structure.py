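"""Actin orientation fields, nematic order, and stress-fiber segmentation.

The orientation field is extracted per image window (default 16 px with 50%
overlap) from the axis of least second moment of the window's DC-suppressed
2D FFT power spectrum; stripes at real-space angle θ concentrate spectral
energy along the perpendicular axis, so the real-space orientation is the
spectral axis rotated by 90°.  Angles are nematic: θ and θ+180° are the same
director, folded into (−90°, 90°].

The alignment order parameter over a neighbourhood of size r is

    ⟨φ⟩ = 2⟨cos²δθ − 1/2⟩ = ⟨cos 2δθ⟩,   δθ = θ_i − θ_j,

averaged over all distinct pairs of valid windows whose centres fall in the
r×r square around each grid point (NaN windows outside the cell are
skipped).  φ = 1 for perfectly aligned directors; the pair average tends to
0 for uniformly random directors.  Perpendicular pairs contribute −1, so the
raw pair average can be negative; a clipped-to-[0,1] summary is also
reported.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .types import CompartmentMasks, OrderMap, OrientationField

__all__ = [
    "orientation_field",
    "order_parameter",
    "order_parameter_brute_force",
    "segment_fibers",
]


def _window_angle(patch, lowfreq_radius=2.0):
    """Orientation (deg, real space) of one image window via its spectrum.

    Returns NaN if the spectrum carries no anisotropic energy.
    """
    p = patch - patch.mean()
    w = p.shape[0]
    han = np.hanning(w)
    p = p * np.outer(han, han)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(p))) ** 2
    cy = cx = w // 2
    yy, xx = np.mgrid[0:w, 0:w].astype(float)
    fy = -(yy - cy)   # up-positive frequency coordinate
    fx = xx - cx
    r2 = fx ** 2 + fy ** 2
    spec = np.where(r2 <= lowfreq_radius ** 2, 0.0, spec)  # DC + low-f disk
    total = spec.sum()
    if total <= 0:
        return float("nan")
    mu20 = float(np.sum(spec * fx * fx) / total)
    mu02 = float(np.sum(spec * fy * fy) / total)
    mu11 = float(np.sum(spec * fx * fy) / total)
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        return float("nan")   # isotropic spectrum: no defined axis
    alpha = 0.5 * math.degrees(math.atan2(2 * mu11, mu20 - mu02))
    theta = alpha + 90.0      # spectral axis -> real-space orientation
    theta = (theta + 90.0) % 180.0 - 90.0
    return 90.0 if theta == -90.0 else theta


def orientation_field(image, cell_mask=None, window=16, overlap=0.5,
                      pixel_size=0.1, presmooth_sigma=1.0,
                      min_inside=0.5) -> OrientationField:
    """Per-window orientation angles from the windowed-FFT spectrum.

    Windows tile the image with the given overlap; a window is analysed if
    at least ``min_inside`` of its pixels lie inside the cell mask (pixels
    outside contribute their NaN-ignored mean, i.e. zero after mean
    subtraction), and NaN otherwise.
    """
    image = np.asarray(image, float)
    if window < 8:
        raise ValueError("window must be at least 8 px")
    if min(image.shape) < window:
        raise ValueError("image smaller than one window")
    if cell_mask is None:
        cell_mask = np.ones(image.shape, bool)
    cell_mask = np.asarray(cell_mask, bool)
    img = ndimage.gaussian_filter(image, presmooth_sigma)
    step = max(int(round(window * (1.0 - overlap))), 1)
    rows = np.arange(window // 2, image.shape[0] - window // 2 + 1, step)
    cols = np.arange(window // 2, image.shape[1] - window // 2 + 1, step)
    theta = np.full((rows.size, cols.size), np.nan)
    half = window // 2
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            sl = (slice(r - half, r + half), slice(c - half, c + half))
            inside = cell_mask[sl]
            if inside.mean() < min_inside:
                continue
            patch = img[sl].copy()
            if not inside.all():
                m = patch[inside].mean()
                patch[~inside] = m
            theta[i, j] = _window_angle(patch)
    return OrientationField(theta=theta, rows=rows, cols=cols, window=window,
                            overlap=overlap, pixel_size=pixel_size)


def _pair_phi(angles_deg):
    """All-distinct-pairs mean of cos 2δθ via the resultant identity.

    |Σ e^{2iθ}|² = n + Σ_{i≠j} cos 2(θ_i−θ_j), so the mean over the
    n(n−1) ordered distinct pairs is (|Σe^{2iθ}|² − n) / (n(n−1)).
    """
    t = np.radians(angles_deg)
    n = t.size
    if n < 2:
        return float("nan")
    c = np.cos(2 * t).sum()
    s = np.sin(2 * t).sum()
    return float((c * c + s * s - n) / (n * (n - 1)))


def _tensor_phi(angles_deg):
    """Squared mean resultant length of the director field (O(n) form).

    Equals the mean of cos 2δθ over *all* ordered pairs including i=j, i.e.
    the nematic order of each director against the neighbourhood mean
    director; coincides with the all-pairs form only as n → ∞.
    """
    t = np.radians(angles_deg)
    if t.size == 0:
        return float("nan")
    return float(np.mean(np.cos(2 * t)) ** 2 + np.mean(np.sin(2 * t)) ** 2)


def order_parameter(field: OrientationField, r_um, pixel_size=None,
                    method="pairs") -> OrderMap:
    """Nematic order map ⟨φ⟩ at neighbourhood size ``r_um`` (µm).

    For each window-grid point, all valid windows whose centres lie within
    the r×r square around it contribute; ``method='pairs'`` (canonical)
    averages cos 2δθ over all distinct pairs, ``method='tensor'`` uses the
    squared mean resultant length.  The scalar ⟨φ⟩ is the mean of the map
    over grid points with a defined value; ``mean_clipped`` clips the map to
    [0, 1] first (perpendicular pairs give negative φ; a 0–1 convention
    treats them as unaligned).
    """
    if method not in ("pairs", "tensor"):
        raise ValueError("method must be 'pairs' or 'tensor'")
    px = pixel_size if pixel_size is not None else field.pixel_size
    step_um = field.grid_step_px * px
    half = int(math.floor((r_um / 2.0) / step_um))
    th = field.theta
    ny, nx = th.shape
    phi = np.full((ny, nx), np.nan)
    fn = _pair_phi if method == "pairs" else _tensor_phi
    any_ok = False
    for i in range(ny):
        for j in range(nx):
            if not np.isfinite(th[i, j]):
                continue
            nb = th[max(i - half, 0):i + half + 1,
                    max(j - half, 0):j + half + 1]
            vals = nb[np.isfinite(nb)]
            if vals.size < 2:
                continue
            phi[i, j] = fn(vals)
            any_ok = True
    if not any_ok:
        raise ValueError("fewer than 2 valid windows in every neighbourhood")
    valid = np.isfinite(phi)
    mean = float(np.mean(phi[valid]))
    mean_clipped = float(np.mean(np.clip(phi[valid], 0.0, 1.0)))
    return OrderMap(phi=phi, r_um=r_um, mean=mean, mean_clipped=mean_clipped,
                    method=method)


def order_parameter_brute_force(angles_deg):
    """Literal double loop over all distinct ordered pairs (test oracle)."""
    t = [a for a in np.ravel(angles_deg) if np.isfinite(a)]
    n = len(t)
    if n < 2:
        return float("nan")
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d = math.radians(t[i] - t[j])
                acc += 2.0 * (math.cos(d) ** 2 - 0.5)
    return acc / (n * (n - 1))


def segment_fibers(image, cell_mask, ridge_sigmas=(1, 2),
                   hysteresis_pct=(80.0, 95.0), min_length_um=2.0,
                   intensity_k=5.0, pixel_size=0.1) -> CompartmentMasks:
    """Stress-fiber / cortex partition of the cell by ridge enhancement.

    Multi-scale line (Sato) filtering enhances bright ridges; hysteresis
    thresholding at the given in-cell ridge-response percentiles keeps
    connected ridge runs; components are kept only if longer than
    ``min_length_um`` AND genuinely bright (peak intensity above the robust
    in-cell background, median + ``intensity_k``·MAD — smooth-texture crest
    lines pass the ridge filter but fail this contrast test, so a fiber-free
    cortex yields an essentially empty SF mask).  The cortex mask is the
    in-cell complement, so the two always partition the cell exactly.
    """
    image = np.asarray(image, float)
    cell = np.asarray(cell_mask, bool)
    if not cell.any():
        raise ValueError("empty cell mask")
    vals = image[cell]
    if vals.max() <= vals.min():
        raise ValueError("image has no contrast inside the cell")
    ridge = filters.sato(image, sigmas=ridge_sigmas, black_ridges=False)
    ridge = np.where(cell, ridge, 0.0)
    lo, hi = np.percentile(ridge[cell], hysteresis_pct)
    if hi <= lo:
        hi = lo * 1.0001 + 1e-12
    sf = filters.apply_hysteresis_threshold(ridge, lo, hi) & cell
    min_len_px = min_length_um / pixel_size
    med = float(np.median(vals))
    mad = 1.4826 * float(np.median(np.abs(vals - med)))
    bright = med + intensity_k * mad
    if sf.any():
        lbl = measure.label(sf)
        keep = np.zeros(lbl.max() + 1, bool)
        for p in measure.regionprops(lbl, intensity_image=image):
            if p.axis_major_length >= min_len_px and p.intensity_max > bright:
                keep[p.label] = True
        sf = keep[lbl]
    cortex = cell & ~sf
    return CompartmentMasks(sf=sf, cortex=cortex, cell=cell)
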