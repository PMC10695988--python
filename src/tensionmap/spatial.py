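"""Colocalization, enrichment, and radial/angular profiling.

Works on micropatterned cells: the pattern centre and outer radius ``R0``
define a normalised radial coordinate ``r/R0`` used to split the cell into a
central zone (r/R0 ≤ 0.6, cortical actin and stress fibers) and a
peripheral zone (r/R0 > 0.6, lamellipodial actin).
"""

from __future__ import annotations

import numpy as np

from .types import AngularProfile, RadialProfile

__all__ = [
    "pearson_colocalization",
    "enrichment_map",
    "radial_profile",
    "angular_profile",
    "profile_correlation",
    "field_correlation",
]

CENTRAL_SPLIT = 0.6
DEFAULT_EXCLUSION = 0.30


def pearson_colocalization(A, B, mask=None):
    """Two-dimensional Pearson correlation coefficient between two channels.

    ``C = Σ(A−Ā)(B−B̄) / sqrt(Σ(A−Ā)² · Σ(B−B̄)²)`` over the mask,
    NaN-aware.  Positive values indicate direct correlation, negative
    anti-correlation.

    Raises
    ------
    ValueError
        On shape mismatch, fewer than 2 valid pixels, or zero variance in
        either channel (undefined correlation is an error, never silent NaN).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("images must share a shape")
    sel = np.isfinite(A) & np.isfinite(B)
    if mask is not None:
        sel &= np.asarray(mask, bool)
    a, b = A[sel], B[sel]
    if a.size < 2:
        raise ValueError("fewer than 2 valid pixels")
    da, db = a - a.mean(), b - b.mean()
    va, vb = np.dot(da, da), np.dot(db, db)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in one channel; correlation undefined")
    return float(np.dot(da, db) / np.sqrt(va * vb))


def enrichment_map(rfp, actin, mask, exclusion=DEFAULT_EXCLUSION,
                   actin_rel_threshold=0.01):
    """Sensor enrichment ratio ρ = RFP/actin, normalised to whole-cell mean 1.

    Pixels with RFP below ``exclusion`` × mean in-cell RFP are excluded
    (guards against low-expression artifacts), as are pixels whose actin
    signal is below ``actin_rel_threshold`` × its in-cell mean (ratio
    undefined); the count of actin-excluded pixels is reported.

    Returns
    -------
    (rho, included, n_actin_excluded)
        ``rho`` is NaN outside the included set; the normalisation makes the
        mean of ρ over included pixels exactly 1, so ρ reads as
        fold-enrichment relative to the cell average.
    """
    rfp = np.asarray(rfp, float)
    actin = np.asarray(actin, float)
    mask = np.asarray(mask, bool)
    mean_rfp = float(np.nanmean(rfp[mask]))
    mean_act = float(np.nanmean(actin[mask]))
    included = mask & (rfp >= exclusion * mean_rfp)
    actin_ok = actin > actin_rel_threshold * mean_act
    n_actin_excluded = int(np.sum(included & ~actin_ok))
    included &= actin_ok
    rho = np.full(rfp.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rfp / actin
    rho[included] = ratio[included]
    norm = float(np.nanmean(rho[included]))
    rho /= norm
    return rho, included, n_actin_excluded


def _radial_coords(shape, center):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return np.hypot(yy - center[0], xx - center[1])


def radial_profile(map_, center, R0_px, n_bins=20, mask=None) -> RadialProfile:
    """NaN-aware radial mean profile over annuli of r/R0 ∈ (0, 1].

    The central/peripheral split is at r/R0 = 0.6, closed on the left:
    a pixel exactly at 0.6 counts as central.
    """
    map_ = np.asarray(map_, float)
    if mask is not None:
        mask = np.asarray(mask, bool)
        if not mask[int(round(center[0])), int(round(center[1]))]:
            raise ValueError("center lies outside the mask")
        map_ = np.where(mask, map_, np.nan)
    rr = _radial_coords(map_.shape, center) / float(R0_px)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    valid = np.isfinite(map_) & (rr <= 1.0)
    idx = np.clip(np.searchsorted(edges, rr[valid], side="left") - 1, 0, n_bins - 1)
    vals = map_[valid]
    for b in range(n_bins):
        v = vals[idx == b]
        n[b] = v.size
        if v.size:
            mean[b] = v.mean()
            sd[b] = v.std(ddof=1) if v.size > 1 else 0.0
    central = vals[rr[valid] <= CENTRAL_SPLIT]
    peripheral = vals[rr[valid] > CENTRAL_SPLIT]
    return RadialProfile(
        r_centers=centers, mean=mean, sd=sd, n=n,
        central_mean=float(central.mean()) if central.size else float("nan"),
        peripheral_mean=float(peripheral.mean()) if peripheral.size else float("nan"),
    )


def angular_profile(map_, center, n_bins=36, mask=None, r_max_px=None,
                    interpolate=True) -> AngularProfile:
    """Per-wedge radial mean as a function of the angle θ from the centre.

    The map is averaged over radius within each angular wedge, then (by
    default) linearly interpolated onto the wedge-centre grid so the profile
    is NaN-free; interpolation wraps periodically in 360°.
    """
    map_ = np.asarray(map_, float)
    if mask is not None:
        map_ = np.where(np.asarray(mask, bool), map_, np.nan)
    yy, xx = np.mgrid[0:map_.shape[0], 0:map_.shape[1]].astype(float)
    theta = np.degrees(np.arctan2(-(yy - center[0]), xx - center[1])) % 360.0
    rr = np.hypot(yy - center[0], xx - center[1])
    valid = np.isfinite(map_)
    if r_max_px is not None:
        valid &= rr <= r_max_px
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    vals = np.full(n_bins, np.nan)
    idx = np.clip(np.digitize(theta[valid], edges) - 1, 0, n_bins - 1)
    mv = map_[valid]
    for b in range(n_bins):
        v = mv[idx == b]
        if v.size:
            vals[b] = v.mean()
    if np.all(np.isnan(vals)):
        raise ValueError("no valid pixels in any wedge")
    if np.any(np.isnan(vals)):
        if not interpolate:
            raise ValueError("empty wedge(s) and interpolation disabled")
        good = np.isfinite(vals)
        # periodic linear interpolation across empty wedges
        vals = np.interp(centers, centers[good], vals[good],
                         period=360.0)
    return AngularProfile(theta_deg=centers, value=vals)


def profile_correlation(p: AngularProfile, q: AngularProfile):
    """Pearson correlation of two angular profiles on a shared θ grid.

    Returns ``(abs_C, C)`` — figures report |C|, the signed value is kept
    for interpretation (e.g. the inverse force/FRET correlation in circular
    cells).
    """
    if p.theta_deg.shape != q.theta_deg.shape or not np.allclose(p.theta_deg, q.theta_deg):
        raise ValueError("profiles must share a θ grid; interpolate first")
    c = pearson_colocalization(p.value, q.value)
    return abs(c), c


def field_correlation(A, B, mask=None):
    """2D-field variant of the spatial correlation (e.g. order vs FRET maps).

    Returns ``(abs_C, C)`` like :func:`profile_correlation`.
    """
    c = pearson_colocalization(A, B, mask)
    return abs(c), c
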