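"""Pipeline orchestration: generate -> WHAM -> decompose -> surface -> report.

Each stage consumes only on-disk artifacts of earlier stages so stages can
be rerun independently; one seeded run writes a complete, reproducible
report bundle (windows manifest + series, PMF CSV, decomposition CSV,
minimum-record JSON, structure CSVs, run-metadata JSON with a QC block).
Identical config and seed give identical numerical outputs; wall-clock
timings live only in the run metadata.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import decomposition as dec
from . import structure as struct
from . import synthetic as syn
from . import wham as whammod
from .config import PipelineConfig
from .errors import SurfpropError
from .windows import EnergyComponents, UmbrellaWindow

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_wham",
    "stage_decompose",
    "stage_surface",
    "stage_report",
]

log = logging.getLogger(__name__)

STAGES = ("simulate", "wham", "decompose", "surface", "report")


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise SurfpropError(f"cannot create output_dir {out}: {exc}") from exc
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise SurfpropError(f"output_dir {out} is not writable: {exc}") from exc
    return out


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def stage_simulate(config: PipelineConfig) -> dict:
    """Generate all umbrella windows and write series, energies and manifest."""
    out = _outdir(config)
    windir = out / "windows"
    windir.mkdir(exist_ok=True)
    dyn = config.dynamics
    entries = []
    for i, center in enumerate(config.window_centers):
        seed = (config.master_seed + i) % 2**31
        window = syn.sample_window(
            config.potential, dyn, float(center), config.spring, config.n_steps, seed
        )
        series = windir / f"win_{i:03d}.xvg"
        energies = windir / f"win_{i:03d}_energies.csv"
        syn.write_window_xvg(window, series)
        syn.write_window_energies(window, energies)
        entries.append(
            {
                "label": window.label,
                "center": float(center),
                "spring": config.spring,
                "seed": seed,
                "series": str(series.relative_to(out)),
                "energies": str(energies.relative_to(out)),
            }
        )
    syn.write_windows_manifest(entries, out / "windows_manifest.json")
    meta = {
        "n_windows": len(entries),
        "n_frames_per_window": config.n_steps // config.stride,
        "spacing_nm": float(config.window_spacing),
        "spring_kJmolnm2": config.spring,
    }
    _write_json(out / "simulate_meta.json", meta)
    return meta


def _load_manifest(out: Path) -> list[dict]:
    manifest_path = out / "windows_manifest.json"
    if not manifest_path.exists():
        raise SurfpropError(f"missing windows manifest {manifest_path}; run simulate first")
    return json.loads(manifest_path.read_text())["windows"]


def _load_windows(out: Path, with_energies: bool) -> list[UmbrellaWindow]:
    windows = []
    for entry in _load_manifest(out):
        series = out / entry["series"]
        if not series.exists():
            raise SurfpropError(f"window {entry['label']!r}: series file missing: {series}")
        times, coords = whammod.read_pull_series(series)
        energies = None
        if with_energies:
            epath = out / entry["energies"]
            if not epath.exists():
                raise SurfpropError(f"window {entry['label']!r}: energy file missing: {epath}")
            df = pd.read_csv(epath, float_precision="round_trip")
            energies = EnergyComponents(
                e_ww=df["e_ww"].to_numpy(),
                e_aaw=df["e_aaw"].to_numpy(),
                e_aaaa=df["e_aaaa"].to_numpy(),
            )
        windows.append(
            UmbrellaWindow(
                center=entry["center"],
                spring=entry["spring"],
                samples=coords,
                energies=energies,
                times=times,
                label=entry["label"],
            )
        )
    return windows


def stage_wham(config: PipelineConfig) -> dict:
    """Run WHAM over the on-disk windows and write the referenced PMF."""
    out = _outdir(config)
    windows = _load_windows(out, with_energies=False)
    profile = whammod.wham(
        windows,
        n_bins=config.wham.n_bins,
        temperature=config.temperature,
        tol=config.wham.tol,
        max_iter=config.wham.max_iter,
    )
    profile = whammod.set_reference(profile, config.wham.r_ref)
    whammod.write_pmf(profile, out / "pmf.csv")
    ref_bin = profile.bin_index(config.wham.r_ref)
    meta = {
        "n_bins": config.wham.n_bins,
        "n_windows": len(windows),
        "window_spacing_nm": float(np.round(np.min(np.diff(sorted(w.center for w in windows))), 12)),
        "r_ref_nm": config.wham.r_ref,
        "reference_bin_value": float(profile.values[ref_bin]),
        "n_iterations": profile.n_iterations,
        "final_residual_kJmol": profile.final_residual,
        "tolerance_kJmol": config.wham.tol,
        "window_overlap_counts": whammod.window_overlap_counts(windows, config.wham.n_bins),
    }
    _write_json(out / "wham_meta.json", meta)
    return meta


def stage_decompose(config: PipelineConfig) -> dict:
    """Enthalpy/entropy decomposition along the profile and at the minimum."""
    out = _outdir(config)
    windows = _load_windows(out, with_energies=True)
    pmf_path = out / "pmf.csv"
    if not pmf_path.exists():
        raise SurfpropError(f"missing PMF {pmf_path}; run wham first")
    profile = whammod.read_pmf(pmf_path, temperature=config.temperature)
    # windows whose center the sampling never reached (e.g. behind the vacuum
    # wall) have no defined PMF value to pair with; drop them with a notice
    defined_centers = profile.centers[profile.defined]
    lo, hi = float(defined_centers.min()), float(defined_centers.max())
    usable = [w for w in windows if lo <= w.center <= hi]
    usable_ids = {id(w) for w in usable}
    for w in windows:
        if id(w) not in usable_ids:
            log.warning(
                "window %s (center %.3f nm) outside defined PMF range [%.3f, %.3f]; "
                "excluded from decomposition", w.label, w.center, lo, hi,
            )
    table = dec.decomposition_profile(profile, usable, config.wham.r_ref)
    # %.17g round-trips float64 exactly, preserving the decomposition
    # identities for any consumer of the CSV
    table.to_csv(out / "decomposition.csv", index=False, float_format="%.17g")
    minimum = dec.find_surface_minimum(profile, config.region)
    record = dec.decomposition_at_minimum(profile, windows, config.wham.r_ref, config.region)
    payload = {
        "region_nm": list(config.region),
        "interior_minimum": minimum.interior,
        "record": asdict(record),
    }
    _write_json(out / "minimum_record.json", payload)
    meta = {
        "r_min_nm": minimum.r_min,
        "dG_min_kJmol": minimum.dG_min,
        "interior_minimum": minimum.interior,
    }
    _write_json(out / "decompose_meta.json", meta)
    return meta


def _planted_hbond_count(r: float, config: PipelineConfig) -> int:
    """Planted bonds per frame: ~8 in bulk falling toward ~4 at the surface."""
    return int(round(8.0 - 4.0 * syn.switch(r, config.potential)))


def stage_surface(config: PipelineConfig) -> dict:
    """Slab density / GDS, hydrogen-bond series and orientation histograms."""
    out = _outdir(config)
    sdir = out / "structure"
    sdir.mkdir(exist_ok=True)
    slab = config.slab
    snaps = syn.make_density_snapshots(
        slab.slab_center,
        slab.gds_position,
        slab.interface_width,
        slab.bulk_density,
        slab.box,
        slab.n_frames,
        seed=(config.master_seed + 1000) % 2**31,
    )
    struct.write_gro(snaps[0], sdir / "slab_frame0.gro", title="synthetic slab frame")
    profile = struct.density_profile(
        snaps, "SOL", bin_width=slab.profile_bin_width
    )
    pd.DataFrame(
        {"z_nm": profile.z_centers, "density_nm3": profile.density}
    ).to_csv(sdir / "density_profile.csv", index=False, float_format="%.10g")
    gds = struct.gibbs_dividing_surface(profile)
    region_from_gds = struct.interphase_region(gds, config.region_halfwidth)

    # hydrogen-bond series: planted fixtures per window, read back per frame
    rng = np.random.default_rng((config.master_seed + 2000) % 2**31)
    per_window = {}
    planted = {}
    for center in config.window_centers:
        k = _planted_hbond_count(float(center), config)
        planted[float(center)] = k
        frames = []
        for _ in range(3):
            geoms = [
                (rng.uniform(0.26, 0.33), rng.uniform(0.0, 25.0)) for _ in range(k)
            ] + [(0.45, rng.uniform(0.0, 25.0)), (0.30, rng.uniform(50.0, 90.0))]
            frames.append(
                syn.make_hbond_fixture(
                    geoms,
                    seed=int(rng.integers(2**31)),
                    angle_vertex=config.criteria.angle_vertex,
                )
            )
        per_window[float(center)] = frames
    series = struct.hbond_vs_r(per_window, config.criteria)
    pd.DataFrame(
        {
            "r_nm": [r for r, _ in series],
            "mean_hbonds": [m for _, m in series],
            "planted": [planted[r] for r, _ in series],
        }
    ).to_csv(sdir / "hbond_vs_r.csv", index=False, float_format="%.10g")

    # orientation distributions for the three reference modes
    orient_rows = {}
    for mode in ("aligned", "planar", "isotropic"):
        vecs = syn.make_orientation_fixture(
            mode, 20000, seed=(config.master_seed + 3000) % 2**31
        )
        hist = struct.orientation_distribution(vecs, n_bins=20)
        orient_rows["cos_theta"] = hist.centers
        orient_rows[mode] = hist.density
    pd.DataFrame(orient_rows).to_csv(
        sdir / "orientation_hist.csv", index=False, float_format="%.10g"
    )

    meta = {
        "gds_nm": float(gds),
        "gds_true_nm": slab.gds_position,
        "bulk_density_nm3": profile.bulk_density,
        "interphase_region_nm": [float(x) for x in region_from_gds],
        "hbond_criteria": {
            "max_da_distance_nm": config.criteria.max_da_distance,
            "max_angle_dev_deg": config.criteria.max_angle_dev,
            "angle_vertex": config.criteria.angle_vertex,
        },
        "hbond_series_matches_planted": bool(
            all(abs(m - planted[r]) < 1e-12 for r, m in series)
        ),
    }
    _write_json(sdir / "summary.json", meta)
    return meta


def stage_report(config: PipelineConfig, timings: dict | None = None) -> dict:
    """Aggregate stage metadata into run_metadata.json (with a QC block)."""
    out = _outdir(config)
    meta = {}
    for name, fname in (
        ("simulate", "simulate_meta.json"),
        ("wham", "wham_meta.json"),
        ("decompose", "decompose_meta.json"),
        ("surface", "structure/summary.json"),
    ):
        path = out / fname
        if path.exists():
            meta[name] = json.loads(path.read_text())
    wham_meta = meta.get("wham", {})
    qc = {
        "wham_converged": wham_meta.get("final_residual_kJmol", np.inf)
        < wham_meta.get("tolerance_kJmol", 0.0),
        "wham_residual_kJmol": wham_meta.get("final_residual_kJmol"),
        "min_window_overlap_bins": (
            min(wham_meta["window_overlap_counts"])
            if wham_meta.get("window_overlap_counts")
            else None
        ),
        "interior_minimum": meta.get("decompose", {}).get("interior_minimum"),
        "reference_bin_zero": wham_meta.get("reference_bin_value") == 0.0,
    }
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "versions": {"surfprop": _pkg_version, "numpy": np.__version__},
        "protocol": {
            "window_spacing_nm": float(config.window_spacing),
            "n_wham_bins": config.wham.n_bins,
            "r_ref_nm": config.wham.r_ref,
            "hbond_max_da_distance_nm": config.criteria.max_da_distance,
            "hbond_max_angle_dev_deg": config.criteria.max_angle_dev,
            "reference_bin_value": wham_meta.get("reference_bin_value"),
        },
        "stages": meta,
        "qc": qc,
        "timings_s": timings or {},
    }
    _write_json(out / "run_metadata.json", report)
    if config.make_plots:
        _make_plots(config, out)
    return report


def _make_plots(config: PipelineConfig, out: Path) -> None:
    """Cosmetic PMF curve and decomposition bars; numbers in CSV are the contract."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profile = whammod.read_pmf(out / "pmf.csv", temperature=config.temperature)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    mask = profile.defined
    ax.plot(profile.centers[mask], profile.values[mask], "-o", ms=2.5)
    ax.set_xlabel("r (nm)")
    ax.set_ylabel(r"$\Delta G$ (kJ/mol)")
    fig.tight_layout()
    fig.savefig(out / "pmf.png", dpi=150)
    plt.close(fig)

    rec = json.loads((out / "minimum_record.json").read_text())["record"]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    labels = ["dG", "dH", "-TdS", "dE_ww", "dE_aaw", "dE_aaaa"]
    vals = [rec["dG"], rec["dH"], rec["minus_TdS"], rec["dE_ww"], rec["dE_aaw"], rec["dE_aaaa"]]
    ax.bar(labels, vals)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("kJ/mol")
    fig.tight_layout()
    fig.savefig(out / "decomposition.png", dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the final report dict.

    Any stage error aborts with a stage-labeled message; a ``FAILED`` marker
    file naming the stage is left next to any partial outputs.
    """
    out = _outdir(config)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    timings: dict[str, float] = {}
    stage_fns = {
        "simulate": stage_simulate,
        "wham": stage_wham,
        "decompose": stage_decompose,
        "surface": stage_surface,
    }
    for name in STAGES[:-1]:
        t0 = time.perf_counter()
        try:
            stage_fns[name](config)
        except Exception as exc:
            failed_marker.write_text(f"stage {name} failed: {exc}\n")
            raise SurfpropError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
    t0 = time.perf_counter()
    report = stage_report(config, timings={**timings})
    timings["report"] = time.perf_counter() - t0
    return report
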