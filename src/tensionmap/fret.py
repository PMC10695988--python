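"""Pixel-wise three-cube FRET quantification.

The three-cube (sensitized-emission) method images a FRET construct in three
channels: donor excitation/donor emission ``I_DD``, acceptor excitation/
acceptor emission ``I_AA``, and donor excitation/acceptor emission ``I_DA``.
After background subtraction, the FRET channel is corrected for donor
bleed-through (fraction ``d`` of donor emission leaking into the acceptor
filter) and acceptor cross-excitation (fraction ``a`` of acceptor directly
excited at the donor wavelength)::

    FRET_c = I_DA - a * I_AA - d * I_DD

The FRET index normalises ``FRET_c`` by the acceptor channel (proportional
to sensor amount), and the FRET efficiency converts ``FRET_c`` to the
fraction of donor excitations transferred, via the instrument factor ``G``
(sensitized acceptor emission per unit quenched donor emission)::

    index = FRET_c / I_AA
    E     = (FRET_c / G) / (I_DD + FRET_c / G)

ΔFRET E for paired relaxed/stretched states is the relative change
``(<E_s> - <E_r>) / <E_r>`` — negative for net tension, positive for net
relaxation/compression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .types import CalibrationConstants, ChannelStack, FretMaps

__all__ = [
    "subtract_background",
    "estimate_bleedthrough",
    "corrected_fret",
    "fret_index",
    "estimate_g_factor",
    "fret_efficiency",
    "compute_fret_maps",
    "mean_fret",
    "delta_fret",
    "FrapModel",
    "FrapResults",
    "fit_frap",
]

DEFAULT_A = 0.045
DEFAULT_D = 0.045


def subtract_background(image, background=None, mask=None):
    """Subtract a scalar background estimated from an off-cell region.

    If ``background`` is given it is used directly; otherwise the median over
    ``~mask`` (off-cell pixels) is used; with neither, the median of the
    darkest decile of the image is a robust fallback.
    """
    image = np.asarray(image, dtype=float)
    if background is None:
        if mask is not None:
            off = image[~np.asarray(mask, bool)]
            if off.size == 0:
                raise ValueError("mask covers the whole image; no off-cell region")
            background = float(np.median(off))
        else:
            q = np.quantile(image, 0.10)
            background = float(np.median(image[image <= q]))
    return image - background, background


def estimate_bleedthrough(stacks, mode):
    """Estimate a bleed-through fraction from single-label calibration cells.

    ``mode='donor'`` estimates the donor bleed-through ``d`` as the slope of
    the pixel-wise I_DA-vs-I_DD scatter from donor-only (GFP) cells;
    ``mode='acceptor'`` estimates the cross-excitation ``a`` from I_DA vs
    I_AA of acceptor-only (RFP) cells.  The slope is the Theil–Sen robust
    slope through the origin (median of per-pixel ratios), averaged over
    cells; channels must be background-subtracted.

    Parameters
    ----------
    stacks : ChannelStack or sequence of ChannelStack
        One stack per calibration cell.
    mode : {"donor", "acceptor"}

    Returns
    -------
    (fraction, se) : tuple of float
        Mean slope across cells and its standard error (SD/√n across cells;
        for a single cell, the SE of the median ratio).
    """
    if isinstance(stacks, ChannelStack):
        stacks = [stacks]
    if mode not in ("donor", "acceptor"):
        raise ValueError("mode must be 'donor' or 'acceptor'")
    slopes = []
    for st in stacks:
        x = st.I_DD if mode == "donor" else st.I_AA
        y = st.I_DA
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        # keep pixels with usable signal in the reference channel
        lim = 0.05 * np.nanmax(x)
        sel = np.isfinite(x) & np.isfinite(y) & (x > max(lim, 0.0))
        x, y = x[sel], y[sel]
        if x.size < 10:
            raise ValueError("too few valid pixels for bleed-through regression")
        if np.max(x) / max(np.min(x), 1e-12) < 2:
            raise ValueError("dynamic range too small (max/min < 2)")
        ratios = y / x
        slope = float(np.median(ratios))
        slopes.append(slope)
    slopes = np.asarray(slopes)
    frac = float(np.mean(slopes))
    if len(slopes) > 1:
        se = float(np.std(slopes, ddof=1) / math.sqrt(len(slopes)))
    else:
        # single cell: SE of the median via the asymptotic normal formula
        ratios = np.sort(ratios)
        se = float(1.2533 * np.std(ratios, ddof=1) / math.sqrt(ratios.size))
    if frac < 0:
        warnings.warn(f"negative bleed-through slope ({frac:.4g}); check background subtraction")
    return frac, se


def corrected_fret(I_DD, I_AA, I_DA, a=DEFAULT_A, d=DEFAULT_D):
    """Bleed-through-corrected FRET image: ``I_DA - a*I_AA - d*I_DD``.

    Negative values are retained (clipping would bias downstream means);
    callers can count them for QC.
    """
    I_DD, I_AA, I_DA = (np.asarray(c, float) for c in (I_DD, I_AA, I_DA))
    if not (I_DD.shape == I_AA.shape == I_DA.shape):
        raise ValueError("channel shapes differ")
    return I_DA - a * I_AA - d * I_DD


def fret_index(fret_c, I_AA, valid=None):
    """FRET index ``FRET_c / I_AA`` with NaN where invalid.

    ``valid`` marks pixels with sufficient acceptor signal; elsewhere the
    index is NaN (NaN propagation is the contract — no exceptions raised).
    """
    fret_c = np.asarray(fret_c, float)
    I_AA = np.asarray(I_AA, float)
    out = np.full(fret_c.shape, np.nan)
    if valid is None:
        valid = I_AA > 0
    valid = np.asarray(valid, bool) & (I_AA != 0)
    out[valid] = fret_c[valid] / I_AA[valid]
    return out


def estimate_g_factor(stack_high, stack_low, a=DEFAULT_A, d=DEFAULT_D, mask_high=None, mask_low=None):
    """Estimate the G factor from two constructs of distinct FRET efficiency.

    For donor:acceptor 1:1 constructs, ``FRET_c/I_AA`` is linear in
    ``I_DD/I_AA`` with slope ``-G`` (pixels of both constructs fall on the
    same line because both axes are sensor-amount-normalised).  Pooling the
    pixel scatters of a high-efficiency and a low-efficiency construct (e.g.
    short-linker vs TRAF-linker analogues) spreads the abscissa so the slope
    is identifiable; the estimate needs no assumed efficiency values.

    The slope is taken between the two construct centroids (per-construct
    means of x and y) rather than by pooled pixel-wise least squares:
    within one construct x is constant up to noise, so pooled OLS is an
    errors-in-variables regression whose slope is attenuated by the ratio
    noise, whereas the centroid slope averages that noise out and stays
    consistent.  Dim pixels (acceptor signal below 20% of its mean) are
    dropped before averaging to tame the ratio noise.

    Returns
    -------
    (G, se) : tuple of float
        SE propagated from the per-construct centroid standard errors.

    Raises
    ------
    ValueError
        If the two constructs are indistinguishable (degenerate abscissa,
        detected via the spread of the centroids relative to their scale).
    """
    cents = []
    for st, mask in ((stack_high, mask_high), (stack_low, mask_low)):
        fc = corrected_fret(st.I_DD, st.I_AA, st.I_DA, a, d)
        iaa = np.asarray(st.I_AA, float)
        idd = np.asarray(st.I_DD, float)
        sel = np.isfinite(fc) & (iaa > 0)
        if mask is not None:
            sel &= np.asarray(mask, bool)
        sel &= iaa > 0.2 * np.mean(iaa[sel]) if sel.any() else sel
        if sel.sum() < 10:
            raise ValueError("too few valid pixels for G calibration")
        x = idd[sel] / iaa[sel]
        y = fc[sel] / iaa[sel]
        n = x.size
        cents.append((float(np.mean(x)), float(np.mean(y)),
                      float(np.std(x, ddof=1) / math.sqrt(n)),
                      float(np.std(y, ddof=1) / math.sqrt(n))))
    (x1, y1, sx1, sy1), (x2, y2, sx2, sy2) = cents
    dx = x1 - x2
    spread = abs(dx) / max(abs(x1), abs(x2), 1e-12)
    if spread < 1e-3:
        raise ValueError(
            "constructs indistinguishable: I_DD/I_AA centroids differ by "
            f"{spread:.2e} relative — G calibration is degenerate"
        )
    G = -(y1 - y2) / dx
    # delta-method SE from the four centroid SEMs
    var = ((sy1 ** 2 + sy2 ** 2) / dx ** 2
           + (y1 - y2) ** 2 * (sx1 ** 2 + sx2 ** 2) / dx ** 4)
    if G <= 0:
        raise ValueError(f"non-positive G estimate ({G:.4g}); check inputs")
    return float(G), float(math.sqrt(var))


def fret_efficiency(fret_c, I_DD, G):
    """FRET efficiency ``E = (FRET_c/G) / (I_DD + FRET_c/G)`` pixel-wise.

    NaN where the denominator is ≤ 0 (no exceptions beyond the NaN contract).
    """
    if G <= 0:
        raise ValueError("G must be positive")
    fret_c = np.asarray(fret_c, float)
    I_DD = np.asarray(I_DD, float)
    q = fret_c / G
    denom = I_DD + q
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(denom > 0, q / denom, np.nan)
    return E


def compute_fret_maps(stack, calibration=None, validity_k=3.0, background_sd=0.0):
    """Full FRET quantification of one background-subtracted channel stack.

    Pixels where ``I_AA`` or ``I_DD`` fall below ``validity_k`` times the
    background SD are marked invalid (NaN in index and E) to prevent ratio
    blow-up in dim regions.

    Returns a :class:`~tensionmap.types.FretMaps`.
    """
    cal = calibration or CalibrationConstants()
    fc = corrected_fret(stack.I_DD, stack.I_AA, stack.I_DA, cal.a, cal.d)
    thr = validity_k * background_sd
    valid = (np.asarray(stack.I_AA, float) > thr) & (np.asarray(stack.I_DD, float) > thr)
    idx = fret_index(fc, stack.I_AA, valid)
    E = fret_efficiency(fc, stack.I_DD, cal.G)
    E = np.where(valid, E, np.nan)
    return FretMaps(
        fret_c=fc,
        index=idx,
        E=E,
        valid=valid,
        calibration=cal,
        n_negative_fret_c=int(np.sum(fc[valid] < 0)),
    )


def mean_fret(E, mask=None):
    """NaN-aware mean FRET efficiency ⟨E⟩ over a mask.

    Returns ``(mean, sd, n)`` where ``n`` counts valid (non-NaN) pixels.
    """
    E = np.asarray(E, float)
    if mask is not None:
        E = E[np.asarray(mask, bool)]
    E = E[np.isfinite(E)]
    if E.size == 0:
        return float("nan"), float("nan"), 0
    return float(np.mean(E)), float(np.std(E, ddof=1) if E.size > 1 else 0.0), int(E.size)


def delta_fret(E_stretched_mean, E_relaxed_mean):
    """Relative FRET change ``(⟨E_s⟩ − ⟨E_r⟩) / ⟨E_r⟩`` for a paired cell.

    Negative for net tension, positive for net relaxation/compression.
    """
    if not E_relaxed_mean > 0:
        raise ValueError("relaxed-state mean efficiency must be positive")
    return (E_stretched_mean - E_relaxed_mean) / E_relaxed_mean


# ---------------------------------------------------------------------------
# FRAP recovery
# ---------------------------------------------------------------------------

@dataclass
class FrapResults:
    """Fitted exponential recovery ``I(t) = a + b·exp(−t/τ)``.

    ``tau`` is the sensor turnover time (s): the timescale on which bound
    sensors unbind and diffuse sensors rebind.  ``identifiable`` is False
    when the amplitude ``b`` is indistinguishable from zero (flat trace), in
    which case ``tau`` is meaningless.
    """

    tau: float
    a: float
    b: float
    tau_se: float
    a_se: float
    b_se: float
    cov: np.ndarray
    rss: float
    r_squared: float
    n: int
    identifiable: bool
    t: np.ndarray = None
    intensity: np.ndarray = None

    def plot(self, ax=None):
        """Recovery trace with the fitted exponential overlaid."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.intensity, "o", ms=3, alpha=0.6, label="data")
        if self.identifiable:
            tt = np.linspace(self.t.min(), self.t.max(), 200)
            ax.plot(tt, self.a + self.b * np.exp(-tt / self.tau), "-",
                    label=f"fit: tau = {self.tau:.1f} s")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend()
        return ax

    def summary(self):
        lines = [
            "FRAP exponential recovery fit: I(t) = a + b*exp(-t/tau)",
            f"  n points      : {self.n}",
            f"  tau (s)       : {self.tau:.4g} +/- {self.tau_se:.2g}",
            f"  plateau a     : {self.a:.4g} +/- {self.a_se:.2g}",
            f"  amplitude b   : {self.b:.4g} +/- {self.b_se:.2g}",
            f"  R^2           : {self.r_squared:.4f}",
            f"  identifiable  : {self.identifiable}",
        ]
        return "\n".join(lines)


class FrapModel:
    """Nonlinear least-squares model for FRAP recovery traces.

    Parameters
    ----------
    t : array
        Time points (s), ≥ 5 of them, ideally spanning at least one τ.
    intensity : array
        Fluorescence recovery trace (a.u.).
    """

    def __init__(self, t, intensity):
        t = np.asarray(t, float)
        y = np.asarray(intensity, float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and intensity must be 1-D arrays of equal length")
        if t.size < 5:
            raise ValueError("need at least 5 time points")
        self.t = t
        self.y = y

    @staticmethod
    def _model(t, a, b, tau):
        return a + b * np.exp(-t / tau)

    def fit(self):
        t, y = self.t, self.y
        span = np.ptp(y)
        noise_sd = float(np.std(np.diff(y)) / math.sqrt(2)) if y.size > 2 else 0.0
        # amplitude indistinguishable from trace noise -> tau unidentifiable
        if span < 1e-12 or (noise_sd > 0 and span < 3 * noise_sd):
            a0 = float(np.mean(y))
            return FrapResults(
                tau=float("nan"), a=a0, b=0.0,
                tau_se=float("nan"), a_se=float(np.std(y) / math.sqrt(y.size)),
                b_se=float("nan"), cov=np.full((3, 3), np.nan),
                rss=float(np.sum((y - a0) ** 2)), r_squared=0.0,
                n=y.size, identifiable=False, t=t, intensity=y,
            )
        a0 = y[np.argmax(t)]
        b0 = y[np.argmin(t)] - a0
        tau0 = max((t.max() - t.min()) / 3.0, 1e-6)
        popt, pcov = optimize.curve_fit(
            self._model, t, y, p0=[a0, b0, tau0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        resid = y - self._model(t, *popt)
        rss = float(np.sum(resid ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        identifiable = abs(popt[1]) > 2 * se[1] if np.isfinite(se[1]) else True
        return FrapResults(
            tau=float(popt[2]), a=float(popt[0]), b=float(popt[1]),
            tau_se=float(se[2]), a_se=float(se[0]), b_se=float(se[1]),
            cov=pcov, rss=rss,
            r_squared=1.0 - rss / tss if tss > 0 else 1.0,
            n=y.size, identifiable=bool(identifiable), t=t, intensity=y,
        )


def fit_frap(t, intensity):
    """Fit ``a + b·exp(−t/τ)`` to a recovery trace; returns :class:`FrapResults`."""
    return FrapModel(t, intensity).fit()
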