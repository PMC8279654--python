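"""Pipeline configuration: a strict, round-trippable YAML surface.

All protocol constants surface as named defaults - 0.1 nm window spacing,
41 WHAM bins, bulk reference at r = 1.0 nm, hydrogen-bond cutoffs
3.5 angstrom / 30 degrees - so the published-protocol run is
a single flag. Unknown keys are rejected; load -> dump -> load yields an
identical run plan.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import DEFAULT_TEMPERATURE
from .errors import InputError
from .structure import HBondCriteria
from .synthetic import LangevinParams, TruePotentialParams

__all__ = ["PipelineConfig", "WhamOptions", "SlabOptions", "load_config", "dump_config"]


@dataclass
class WhamOptions:
    n_bins: int = 41
    tol: float = 1e-6
    max_iter: int = 100000
    r_ref: float = 1.0


@dataclass
class SlabOptions:
    """Synthetic slab used by the surface-structure stage."""

    slab_center: float = 3.0
    gds_position: float = 2.2
    interface_width: float = 0.3
    bulk_density: float = 33.0
    box: tuple[float, float, float] = (3.0, 3.0, 6.0)
    n_frames: int = 50
    profile_bin_width: float = 0.05


@dataclass
class PipelineConfig:
    master_seed: int = 1
    temperature: float = DEFAULT_TEMPERATURE
    published_protocol: bool = False
    window_start: float = 1.0
    window_stop: float = 3.0
    window_spacing: float = 0.1
    spring: float = 1000.0
    n_steps: int = 20_000_000
    stride: int = 100
    n_equil: int = 5000
    diffusion_coeff: float = 0.001
    timestep: float = 0.01
    domain_min: float = 0.8
    domain_max: float = 3.2
    region_lo: float = 1.6
    region_hi: float = 2.8
    region_halfwidth: float = 0.6
    make_plots: bool = False
    output_dir: str = "surfprop_out"
    potential: TruePotentialParams = field(default_factory=TruePotentialParams)
    wham: WhamOptions = field(default_factory=WhamOptions)
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    slab: SlabOptions = field(default_factory=SlabOptions)

    def __post_init__(self):
        if self.published_protocol:
            # published protocol: 41 windows at 0.1 nm spacing from the bulk
            # reference; the vacuum wall moves out so the wider ladder is
            # physically reachable.
            self.window_start, self.window_stop, self.window_spacing = 1.0, 5.0, 0.1
            self.domain_max = max(self.domain_max, 5.2)
            self.potential.wall_position = max(self.potential.wall_position, 4.6)
            self.wham.n_bins = 41
            self.wham.r_ref = 1.0
        centers = self.window_centers
        if centers.size < 1 or np.any(np.diff(centers) <= 0):
            raise InputError("window centers must be strictly increasing")
        if not centers[0] <= self.wham.r_ref <= centers[-1]:
            raise InputError(
                f"wham.r_ref={self.wham.r_ref} outside the window range "
                f"[{centers[0]}, {centers[-1]}]"
            )
        if self.spring < 0:
            raise InputError("spring must be >= 0")
        if self.n_steps < 1:
            raise InputError("n_steps must be >= 1")

    @property
    def window_centers(self) -> np.ndarray:
        n = int(round((self.window_stop - self.window_start) / self.window_spacing)) + 1
        return self.window_start + self.window_spacing * np.arange(n)

    @property
    def dynamics(self) -> LangevinParams:
        return LangevinParams(
            temperature=self.temperature,
            diffusion_coeff=self.diffusion_coeff,
            timestep=self.timestep,
            domain_min=self.domain_min,
            domain_max=self.domain_max,
            stride=self.stride,
            n_equil=self.n_equil,
        )

    @property
    def region(self) -> tuple[float, float]:
        return (self.region_lo, self.region_hi)

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "temperature": self.temperature,
            "published_protocol": self.published_protocol,
            "windows": {
                "start": self.window_start,
                "stop": self.window_stop,
                "spacing": self.window_spacing,
                "spring": self.spring,
                "n_steps": self.n_steps,
                "stride": self.stride,
                "n_equil": self.n_equil,
            },
            "dynamics": {
                "diffusion_coeff": self.diffusion_coeff,
                "timestep": self.timestep,
                "domain_min": self.domain_min,
                "domain_max": self.domain_max,
            },
            "potential": {
                k: getattr(self.potential, k)
                for k in (
                    "well_depth", "well_center", "well_width", "wall_position",
                    "wall_scale", "switch_center", "switch_width",
                    "amp_ww", "amp_aaw", "amp_aaaa", "noise_sd",
                )
            },
            "wham": {
                "n_bins": self.wham.n_bins,
                "tol": self.wham.tol,
                "max_iter": self.wham.max_iter,
                "r_ref": self.wham.r_ref,
            },
            "criteria": {
                "max_da_distance_angstrom": self.criteria.max_da_distance * 10.0,
                "max_angle_dev": self.criteria.max_angle_dev,
                "angle_vertex": self.criteria.angle_vertex,
            },
            "region": {
                "lo": self.region_lo,
                "hi": self.region_hi,
                "halfwidth": self.region_halfwidth,
            },
            "slab": {
                "slab_center": self.slab.slab_center,
                "gds_position": self.slab.gds_position,
                "interface_width": self.slab.interface_width,
                "bulk_density": self.slab.bulk_density,
                "box": list(self.slab.box),
                "n_frames": self.slab.n_frames,
                "profile_bin_width": self.slab.profile_bin_width,
            },
            "make_plots": self.make_plots,
            "output_dir": self.output_dir,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _take(mapping: dict, section: str, allowed: set[str]) -> dict:
    unknown = set(mapping) - allowed
    if unknown:
        raise InputError(f"unknown config key(s) in {section}: {sorted(unknown)}")
    return mapping


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated config from a nested plain dict (strict keys)."""
    data = dict(data or {})
    _take(
        data,
        "top level",
        {
            "master_seed", "temperature", "published_protocol", "windows", "dynamics",
            "potential", "wham", "criteria", "region", "slab", "make_plots",
            "output_dir",
        },
    )
    kwargs: dict = {}
    for key in ("master_seed", "temperature", "published_protocol", "make_plots", "output_dir"):
        if key in data:
            kwargs[key] = data[key]
    win = _take(
        dict(data.get("windows") or {}),
        "windows",
        {"start", "stop", "spacing", "spring", "n_steps", "stride", "n_equil"},
    )
    rename = {"start": "window_start", "stop": "window_stop", "spacing": "window_spacing"}
    for k, v in win.items():
        kwargs[rename.get(k, k)] = v
    dyn = _take(
        dict(data.get("dynamics") or {}),
        "dynamics",
        {"diffusion_coeff", "timestep", "domain_min", "domain_max"},
    )
    kwargs.update(dyn)
    pot = _take(
        dict(data.get("potential") or {}),
        "potential",
        {
            "well_depth", "well_center", "well_width", "wall_position", "wall_scale",
            "switch_center", "switch_width", "amp_ww", "amp_aaw", "amp_aaaa", "noise_sd",
        },
    )
    kwargs["potential"] = TruePotentialParams(**pot)
    wham_opts = _take(
        dict(data.get("wham") or {}), "wham", {"n_bins", "tol", "max_iter", "r_ref"}
    )
    kwargs["wham"] = WhamOptions(**wham_opts)
    crit = _take(
        dict(data.get("criteria") or {}),
        "criteria",
        {"max_da_distance_angstrom", "max_da_distance_nm", "max_angle_dev", "angle_vertex"},
    )
    crit_kwargs: dict = {}
    if "max_da_distance_angstrom" in crit:
        crit_kwargs["max_da_distance"] = float(crit["max_da_distance_angstrom"]) / 10.0
    if "max_da_distance_nm" in crit:
        crit_kwargs["max_da_distance"] = float(crit["max_da_distance_nm"])
    for k in ("max_angle_dev", "angle_vertex"):
        if k in crit:
            crit_kwargs[k] = crit[k]
    kwargs["criteria"] = HBondCriteria(**crit_kwargs)
    region = _take(dict(data.get("region") or {}), "region", {"lo", "hi", "halfwidth"})
    if "halfwidth" in region:
        kwargs["region_halfwidth"] = float(region["halfwidth"])
    if "lo" in region:
        kwargs["region_lo"] = float(region["lo"])
    if "hi" in region:
        kwargs["region_hi"] = float(region["hi"])
    slab = _take(
        dict(data.get("slab") or {}),
        "slab",
        {
            "slab_center", "gds_position", "interface_width", "bulk_density",
            "box", "n_frames", "profile_bin_width",
        },
    )
    if "box" in slab:
        slab["box"] = tuple(float(x) for x in slab["box"])
    kwargs["slab"] = SlabOptions(**slab)
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:
        raise InputError(f"invalid configuration: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    An empty file yields the documented defaults; unknown keys and invalid
    values raise :class:`~surfprop.errors.InputError` naming the key.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise InputError("config file must contain a mapping")
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path) -> None:
    """Serialize the full (default-expanded) run plan back to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
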