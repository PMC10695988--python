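"""Configuration, image I/O, and end-to-end pipeline wiring.

The demo pipeline generates a fully synthetic experiment (micropatterned
cell, three-cube FRET stack, fiber-textured actin, bead pair, stretch
series, FRAP trace), runs every analysis stage on it, and writes
CSV/TIFF/JSON outputs plus a provenance record.  With a fixed seed the
whole run is deterministic: identical bytes on every invocation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fret, mechanics, spatial, stretch, structure, synthetic
from .types import ChannelStack, MechTruth, SceneSpec, StretchTruth, TractionField

__all__ = ["PipelineConfig", "load_channel_stack", "save_channel_stack",
           "run_pipeline"]

log = logging.getLogger("tensionmap")

CHANNEL_ORDER = ("DD", "AA", "DA", "actin", "beads")


@dataclass
class PipelineConfig:
    """All tunable parameters of the demo pipeline (YAML round-trippable)."""

    out_dir: str = "tensionmap_out"
    seed: int = 0
    # scene
    shape: str = "circle"
    R0_um: float = 12.5
    pixel_size_um: float = 0.1
    image_size: int = 300
    # fret
    a: float = 0.045
    d: float = 0.045
    G: float = 2.0
    validity_multiplier: float = 3.0
    exclusion: float = 0.30
    # structure
    window_px: int = 16
    overlap: float = 0.5
    r_local_um: float = 5.0
    r_global_um: float = 10.0
    # mechanics
    E_gel_pa: float = 2800.0
    nu_gel: float = 0.5
    tfm_grid_um: float = 6.4
    piv_window_px: int = 32
    lam: float = 0.0
    # stretch
    strains: tuple = (0.05, 0.10, 0.15, 0.20)
    slope_parallel: float = 1.22
    slope_orthogonal: float = -0.77
    n_cells_per_direction: int = 15
    # frap
    frap_tau_s: float = 20.0

    def __post_init__(self):
        for name in ("R0_um", "pixel_size_um", "G", "E_gel_pa", "tfm_grid_um",
                     "r_local_um", "r_global_um", "frap_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text())
        if "strains" in raw:
            raw["strains"] = tuple(raw["strains"])
        if "image_size" in raw and isinstance(raw["image_size"], list):
            raw["image_size"] = tuple(raw["image_size"])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_channel_stack(path, stack: ChannelStack, truth=None):
    """Write a multi-page 16-bit TIFF (+ JSON sidecar with metadata).

    Channels are scaled into the 16-bit range per stack (one global factor,
    recorded in the sidecar so loading restores the original values).
    """
    path = Path(path)
    channels = {"DD": stack.I_DD, "AA": stack.I_AA, "DA": stack.I_DA}
    if stack.actin is not None:
        channels["actin"] = stack.actin
    if stack.beads is not None:
        channels["beads"] = stack.beads
    names = [n for n in CHANNEL_ORDER if n in channels]
    arr = np.stack([channels[n] for n in names])
    peak = float(arr.max()) if arr.max() > 0 else 1.0
    scale = 60000.0 / peak
    data = np.clip(np.round(arr * scale), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"axes": "CYX"},
                     photometric="minisblack")
    sidecar = {"channels": names, "pixel_size_um": stack.pixel_size,
               "scale": scale, "label": stack.label}
    if truth is not None:
        sidecar["truth"] = truth
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_channel_stack(path, channel_map=None, pixel_size=None) -> ChannelStack:
    """Read a stack written by :func:`save_channel_stack` (or any TIFF).

    ``channel_map`` maps channel names to page indices for foreign TIFFs;
    pixel size comes from the JSON sidecar unless overridden.  Missing pixel
    size without an override is an error.
    """
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    sidecar = {}
    sc_path = path.with_suffix(".json")
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
        data = data / sidecar.get("scale", 1.0)
    if channel_map is None:
        names = sidecar.get("channels")
        if names is None:
            if data.shape[0] < 3:
                raise ValueError("channel count mismatch: need >= 3 pages (DD, AA, DA)")
            names = list(CHANNEL_ORDER[: data.shape[0]])
        channel_map = {n: i for i, n in enumerate(names)}
    for required in ("DD", "AA", "DA"):
        if required not in channel_map:
            raise ValueError(f"channel map lacks {required!r}")
        if channel_map[required] >= data.shape[0]:
            raise ValueError("channel count mismatch")
    px = pixel_size if pixel_size is not None else sidecar.get("pixel_size_um")
    if px is None:
        raise ValueError("pixel size missing from metadata; supply pixel_size")
    extras = {}
    for opt in ("actin", "beads"):
        if opt in channel_map and channel_map[opt] < data.shape[0]:
            extras[opt] = data[channel_map[opt]]
    return ChannelStack(I_DD=data[channel_map["DD"]],
                        I_AA=data[channel_map["AA"]],
                        I_DA=data[channel_map["DA"]],
                        pixel_size=float(px),
                        label=sidecar.get("label", ""),
                        **extras)


def _write_map(path, arr):
    tifffile.imwrite(path, np.asarray(arr, np.float32))


def _hash_file(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-experiment pipeline.

    Returns a report dict with the key per-stage numbers, the output file
    hashes, and the provenance record (also written to ``provenance.json``).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.default_rng(config.seed)
    report = {"stages": {}, "qc": {}}

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return time.time()

    # --- simulate -----------------------------------------------------
    ts = stage("simulate")
    spec = SceneSpec(shape=config.shape, R0=config.R0_um,
                     pixel_size=config.pixel_size_um,
                     image_size=(config.image_size, config.image_size),
                     seed=config.seed)
    masks = synthetic.make_mask(spec)
    rng = np.random.default_rng(config.seed)
    E_true = np.where(masks.cell,
                      synthetic.smooth_field(masks.cell.shape, rng, mean=0.22,
                                             rel_sd=0.15, sigma_px=15.0),
                      0.0)
    E_true = np.clip(E_true, 0.0, 0.5)
    S = synthetic.smooth_field(masks.cell.shape, rng, mean=1.0, rel_sd=0.3,
                               sigma_px=10.0)
    truth = synthetic.FretTruth(E_field=E_true, S_field=S, a=config.a,
                                d=config.d, G=config.G, noise="gaussian",
                                noise_scale=0.01)
    stack = synthetic.simulate_three_cube(masks, truth,
                                          seed=int(rng_root.integers(2 ** 31)))
    fibers = synthetic.simulate_fiber_image(masks, orientation="radial",
                                            n_fibers=30,
                                            seed=int(rng_root.integers(2 ** 31)))
    stack.actin = fibers.image
    save_channel_stack(out / "stack.tif", stack)
    report["stages"]["simulate"]["dt"] = round(time.time() - ts, 2)

    # --- fret ---------------------------------------------------------
    ts = stage("fret")
    cal = fret.CalibrationConstants(a=config.a, d=config.d, G=config.G)
    maps = fret.compute_fret_maps(stack, cal, config.validity_multiplier,
                                  background_sd=0.0)
    E = np.where(masks.cell, maps.E, np.nan)
    mE, sdE, nE = fret.mean_fret(E, masks.cell)
    _write_map(out / "fret_E.tif", np.nan_to_num(E))
    pd.DataFrame([{"cell_id": "demo", "mean_E": mE, "sd_E": sdE,
                   "n_px": nE}]).to_csv(out / "fret_per_cell.csv", index=False)
    report["fret"] = {"mean_E": mE, "sd_E": sdE, "n_px": nE}
    report["qc"]["fret_mean_E_in_range"] = bool(0.0 < mE < 0.5)
    report["stages"]["fret"]["dt"] = round(time.time() - ts, 2)

    # --- structure ----------------------------------------------------
    ts = stage("structure")
    field_ = structure.orientation_field(fibers.image, masks.cell,
                                         window=config.window_px,
                                         overlap=config.overlap,
                                         pixel_size=config.pixel_size_um)
    om_local = structure.order_parameter(field_, config.r_local_um)
    om_global = structure.order_parameter(field_, config.r_global_um)
    comp = structure.segment_fibers(fibers.image, masks.cell,
                                    pixel_size=config.pixel_size_um)
    tifffile.imwrite(out / "sf_mask.tif", comp.sf.astype(np.uint8) * 255)
    _write_map(out / "order_local.tif", np.nan_to_num(om_local.phi))
    report["structure"] = {"order_local": om_local.mean,
                           "order_global": om_global.mean,
                           "sf_area_fraction": float(comp.sf.sum() / comp.cell.sum())}
    report["qc"]["order_local_ge_global"] = bool(om_local.mean >= om_global.mean - 0.05)
    report["stages"]["structure"]["dt"] = round(time.time() - ts, 2)

    # --- profile ------------------------------------------------------
    ts = stage("profile")
    rprof = spatial.radial_profile(E, masks.center, spec.R0_px, mask=masks.cell)
    aprof = spatial.angular_profile(E, masks.center, mask=masks.cell)
    rho, included, n_excl = spatial.enrichment_map(
        1000.0 * S * masks.cell, fibers.image + 1e-6, masks.cell,
        exclusion=config.exclusion)
    pd.DataFrame({"r_over_R0": rprof.r_centers, "mean": rprof.mean,
                  "sd": rprof.sd, "n": rprof.n}).to_csv(
        out / "radial_profile.csv", index=False)
    pd.DataFrame({"theta_deg": aprof.theta_deg, "value": aprof.value}).to_csv(
        out / "angular_profile.csv", index=False)
    report["profile"] = {"central_mean": rprof.central_mean,
                         "peripheral_mean": rprof.peripheral_mean,
                         "enrichment_excluded_px": n_excl}
    report["stages"]["profile"]["dt"] = round(time.time() - ts, 2)

    # --- tfm ----------------------------------------------------------
    ts = stage("tfm")
    gh = config.tfm_grid_um
    gn = 48
    T_true = synthetic.inward_traction_ring((gn, gn), gh, magnitude=100.0,
                                            r0_um=0.3 * gn * gh)
    mech = MechTruth(traction_field=T_true, grid_spacing=gh,
                     E_gel=config.E_gel_pa, nu=config.nu_gel,
                     bead_density=0.02, pixel_size=config.pixel_size_um)
    tf_true = TractionField(x=np.arange(gn) * gh, y=np.arange(gn) * gh,
                            T=T_true, grid_spacing=gh, E_gel=config.E_gel_pa,
                            nu=config.nu_gel)
    disp = mechanics.forward_boussinesq(tf_true)
    tf_rec = mechanics.fttc_tractions(disp, config.E_gel_pa, config.nu_gel,
                                      lam=config.lam)
    rel_err = float(np.linalg.norm(tf_rec.T - T_true) / np.linalg.norm(T_true))
    yy, xx = np.mgrid[0:gn, 0:gn].astype(float) * gh
    cy = cx = (gn - 1) * gh / 2
    cell_grid = np.hypot(yy - cy, xx - cx) <= 0.38 * gn * gh
    fmap = mechanics.internal_force_balance(tf_rec, cell_grid)
    pd.DataFrame({
        "x_um": np.repeat(tf_rec.x, gn), "y_um": np.tile(tf_rec.y, gn),
        "Tx_pa": tf_rec.T[..., 0].T.ravel(), "Ty_pa": tf_rec.T[..., 1].T.ravel(),
    }).to_csv(out / "tractions.csv", index=False)
    _write_map(out / "internal_force.tif", fmap.F)
    report["tfm"] = {"traction_rel_err": rel_err,
                     "net_force_N": list(tf_rec.net_force),
                     "mean_T_pa": float(tf_rec.magnitude[cell_grid].mean()),
                     "F_center_over_edge": float(
                         fmap.F[gn // 2, gn // 2] /
                         max(fmap.F[cell_grid].mean(), 1e-12))}
    report["qc"]["tfm_roundtrip_ok"] = bool(rel_err < 0.10)
    report["stages"]["tfm"]["dt"] = round(time.time() - ts, 2)

    # --- stretch ------------------------------------------------------
    ts = stage("stretch")
    recs = []
    recs += synthetic.simulate_stretch_records(
        config.slope_parallel, n_cells=config.n_cells_per_direction,
        orientation="parallel", seed=int(rng_root.integers(2 ** 31)),
        strains=config.strains)
    recs += synthetic.simulate_stretch_records(
        config.slope_orthogonal, n_cells=config.n_cells_per_direction,
        orientation="orthogonal", seed=int(rng_root.integers(2 ** 31)),
        strains=config.strains)
    df = stretch.records_to_dataframe(recs)
    df.to_csv(out / "stretch_records.csv", index=False)
    fit = stretch.LoadSharingModel(df).fit()
    report["stretch"] = {"slopes": fit.slopes, "slope_ses": fit.slope_ses,
                         "slope_equality_F": fit.f_stat,
                         "slope_equality_p": fit.f_pvalue}
    report["qc"]["slopes_differ"] = bool(fit.f_pvalue is not None
                                         and fit.f_pvalue < 0.05)
    report["stages"]["stretch"]["dt"] = round(time.time() - ts, 2)

    # --- frap ---------------------------------------------------------
    ts = stage("frap")
    t, y = synthetic.simulate_frap_trace(tau=config.frap_tau_s, noise_sd=0.01,
                                         seed=int(rng_root.integers(2 ** 31)))
    frap_fit = fret.fit_frap(t, y)
    report["frap"] = {"tau_s": frap_fit.tau, "tau_se": frap_fit.tau_se,
                      "identifiable": frap_fit.identifiable}
    report["qc"]["frap_tau_close"] = bool(
        abs(frap_fit.tau - config.frap_tau_s) < 0.2 * config.frap_tau_s)
    report["stages"]["frap"]["dt"] = round(time.time() - ts, 2)

    # --- provenance ---------------------------------------------------
    files = sorted(p for p in out.iterdir()
                   if p.is_file() and p.name != "provenance.json")
    hashes = {p.name: _hash_file(p) for p in files}
    with open(out / "fit_summary.json", "w") as fh:
        json.dump({"stretch": report["stretch"], "frap": report["frap"],
                   "tfm": report["tfm"]}, fh, indent=1, default=float)
    hashes["fit_summary.json"] = _hash_file(out / "fit_summary.json")
    provenance = {"config": asdict(config), "config_hash": config.hash(),
                  "seed": config.seed, "file_hashes": hashes}
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=1, default=list))
    report["provenance"] = provenance
    report["qc"]["all_pass"] = all(report["qc"].values())
    report["runtime_s"] = round(time.time() - t0, 2)
    return report
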