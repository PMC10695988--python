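"""Strain-series ΔFRET analysis: compartment responses and load sharing.

For each cell, ΔFRET E = (⟨E_stretched⟩ − ⟨E_relaxed⟩)/⟨E_relaxed⟩ is
computed for the whole cell and for the stress-fiber and cortical-actin
compartments (masks segmented in the relaxed frame and warped by the strain
map onto the stretched frame, keeping compartment identity fixed).

The load-sharing slope m is the OLS slope of stress-fiber ΔFRET on cortical
ΔFRET across cells of one stretch direction: m > 1 means stress fibers
accumulate molecular tension faster than the cortex, m < 0 that they relax
while the cortex loads.  Equality of slopes between directions is tested by
the interaction F-test of the nested common-slope vs separate-slopes linear
models (ANCOVA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .fret import delta_fret, mean_fret
from .types import CompartmentMasks, StretchRecord

__all__ = [
    "compartment_delta",
    "records_to_dataframe",
    "LoadSharingModel",
    "LoadSharingResults",
    "load_sharing_slope",
    "sensor_binding_metrics",
]


def compartment_delta(E_relaxed, E_stretched, masks_relaxed: CompartmentMasks,
                      masks_stretched: CompartmentMasks):
    """Per-compartment ΔFRET for one relaxed/stretched pair.

    Returns ``(ΔFRET_cell, ΔFRET_SF, ΔFRET_cortex)``.  Compartment means are
    NaN-aware; an empty compartment raises.
    """
    out = []
    for m_r, m_s in ((masks_relaxed.cell, masks_stretched.cell),
                     (masks_relaxed.sf, masks_stretched.sf),
                     (masks_relaxed.cortex, masks_stretched.cortex)):
        if not np.any(m_r) or not np.any(m_s):
            raise ValueError("empty compartment mask")
        mr, _, nr = mean_fret(E_relaxed, m_r)
        ms, _, ns = mean_fret(E_stretched, m_s)
        if nr == 0 or ns == 0:
            raise ValueError("compartment contains no valid pixels")
        out.append(delta_fret(ms, mr))
    return tuple(out)


def records_to_dataframe(records: Sequence[StretchRecord]) -> pd.DataFrame:
    """Tidy frame (one row per cell × strain) with derived ΔFRET columns."""
    rows = []
    for r in records:
        rows.append({
            "cell_id": r.cell_id,
            "orientation": r.orientation,
            "strain": r.strain,
            "condition": r.condition,
            "delta_cell": delta_fret(r.E_stretched, r.E_relaxed)
            if r.E_relaxed > 0 else np.nan,
            "delta_sf": delta_fret(r.E_sf_stretched, r.E_sf_relaxed)
            if r.E_sf_relaxed > 0 else np.nan,
            "delta_cortex": delta_fret(r.E_cortex_stretched, r.E_cortex_relaxed)
            if r.E_cortex_relaxed > 0 else np.nan,
            "detached": r.detached,
        })
    return pd.DataFrame(rows)


@dataclass
class LoadSharingResults:
    """Per-direction load-sharing slopes and the slope-equality test."""

    slopes: dict                 # direction -> slope
    slope_ses: dict
    intercepts: dict
    n: dict
    f_stat: Optional[float]      # interaction F (slope equality), if 2 groups
    f_pvalue: Optional[float]
    per_direction: dict          # direction -> statsmodels results
    data: Optional[pd.DataFrame] = None

    def plot(self, ax=None):
        """SF ΔFRET vs cortical ΔFRET with per-direction fit lines."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for d in self.slopes:
            sub = self.data[self.data["orientation"] == d]
            ax.plot(sub["delta_cortex"], sub["delta_sf"], "o", ms=4,
                    alpha=0.6, label=f"{d} (m = {self.slopes[d]:+.2f})")
            xx = np.linspace(sub["delta_cortex"].min(),
                             sub["delta_cortex"].max(), 50)
            ax.plot(xx, self.intercepts[d] + self.slopes[d] * xx, "-")
        ax.set_xlabel("cortical actin " + r"$\Delta$FRET E")
        ax.set_ylabel("stress fiber " + r"$\Delta$FRET E")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = ["Load-sharing regression: SF dFRET ~ cortex dFRET"]
        for d in self.slopes:
            lines.append(
                f"  {d:<11} m = {self.slopes[d]:+.4f} +/- {self.slope_ses[d]:.4f}"
                f"  (intercept {self.intercepts[d]:+.4f}, n = {self.n[d]})")
        if self.f_stat is not None:
            lines.append(
                f"  slope equality: F = {self.f_stat:.4g}, p = {self.f_pvalue:.4g}")
        return "\n".join(lines)


class LoadSharingModel:
    """OLS model of stress-fiber ΔFRET on cortical ΔFRET, by direction.

    Parameters
    ----------
    data : DataFrame or sequence of StretchRecord
        Must provide columns ``delta_sf``, ``delta_cortex``, ``orientation``
        (records are converted via :func:`records_to_dataframe`).  Rows
        flagged ``detached`` are dropped (QC exclusion).
    """

    def __init__(self, data):
        if not isinstance(data, pd.DataFrame):
            data = records_to_dataframe(data)
        df = data.copy()
        if "detached" in df:
            df = df[~df["detached"].astype(bool)]
        df = df.dropna(subset=["delta_sf", "delta_cortex"])
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records):
        return cls(records_to_dataframe(records))

    def fit(self) -> LoadSharingResults:
        df = self.data
        directions = sorted(df["orientation"].unique())
        slopes, ses, icpts, ns, per = {}, {}, {}, {}, {}
        for d in directions:
            sub = df[df["orientation"] == d]
            if len(sub) < 3:
                raise ValueError(f"need >= 3 pairs per direction, got {len(sub)} for {d!r}")
            if np.std(sub["delta_cortex"]) == 0:
                raise ValueError("degenerate regression: cortex dFRET has zero variance")
            X = sm.add_constant(sub["delta_cortex"].to_numpy())
            res = sm.OLS(sub["delta_sf"].to_numpy(), X).fit()
            icpts[d], slopes[d] = map(float, res.params)
            ses[d] = float(res.bse[1])
            ns[d] = int(len(sub))
            per[d] = res
        f_stat = f_p = None
        if len(directions) == 2:
            full = smf.ols("delta_sf ~ delta_cortex * C(orientation)", data=df).fit()
            reduced = smf.ols("delta_sf ~ delta_cortex + C(orientation)", data=df).fit()
            cmp_ = sm.stats.anova_lm(reduced, full)
            f_stat = float(cmp_["F"].iloc[1])
            f_p = float(cmp_["Pr(>F)"].iloc[1])
        return LoadSharingResults(slopes=slopes, slope_ses=ses,
                                  intercepts=icpts, n=ns,
                                  f_stat=f_stat, f_pvalue=f_p,
                                  per_direction=per, data=df)


def load_sharing_slope(records, direction=None) -> LoadSharingResults:
    """Fit the load-sharing regression; optionally restrict to one direction."""
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    if direction is not None:
        df = df[df["orientation"] == direction]
    return LoadSharingModel(df).fit()


def sensor_binding_metrics(record: StretchRecord):
    """Relative sensor-binding changes (ΔRFP, ΔRFP/A) for one cell.

    ΔX = (X_stretched − X_relaxed)/X_relaxed for the total RFP signal and
    the RFP density (total / cell area); near-zero ΔRFP with shrinking
    density indicates the bound sensor pool is conserved while the cell
    area changes.
    """
    if not record.rfp_total_relaxed > 0:
        raise ValueError("relaxed-state RFP total must be positive")
    if not record.area_relaxed > 0 or not record.area_stretched > 0:
        raise ValueError("cell areas must be positive")
    d_rfp = (record.rfp_total_stretched - record.rfp_total_relaxed) / record.rfp_total_relaxed
    dens_r = record.rfp_total_relaxed / record.area_relaxed
    dens_s = record.rfp_total_stretched / record.area_stretched
    d_dens = (dens_s - dens_r) / dens_r
    return d_rfp, d_dens
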