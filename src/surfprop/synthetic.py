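"""Synthetic slab system with a fully known free-energy landscape.

Everything the analysis pipeline consumes can be generated here with ground
truth in hand: harmonically biased reaction-coordinate trajectories sampled
by overdamped Langevin dynamics on a prescribed potential of mean force
(PMF), per-frame interaction-energy components, slab-like density snapshots,
hydrogen-bond geometry fixtures, and orientation-vector fixtures. Recovery
tests compare pipeline output against the closed forms below.

The true PMF is a single Gaussian surface well plus an exponential vacuum
wall,

    G(r) = -D exp(-(r - r_w)^2 / (2 w^2)) + exp((r - r_v) / s),

flat in bulk (small r), with a minimum just below the Gibbs dividing surface
and a steep rise toward vacuum. Component enthalpy means switch on smoothly
across the interface through a logistic S(r), vanishing at the bulk
reference by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels
from .constants import DEFAULT_TEMPERATURE, KB
from .errors import ConfigurationError, InputError
from .structure import Snapshot, _angle_deviation
from .windows import EnergyComponents, UmbrellaWindow

__all__ = [
    "TruePotentialParams",
    "LangevinParams",
    "true_pmf",
    "true_pmf_grad",
    "switch",
    "true_enthalpy_components",
    "true_enthalpy",
    "true_minus_t_delta_s",
    "check_stability",
    "sample_window",
    "make_density_snapshots",
    "make_hbond_fixture",
    "measure_hbond_geometries",
    "hbond_fixture_selections",
    "make_orientation_fixture",
    "write_window_xvg",
    "write_window_energies",
    "write_windows_manifest",
]


@dataclass
class TruePotentialParams:
    """Ground-truth landscape and component-enthalpy parameters.

    Energies in kJ/mol, lengths in nm. ``well_depth`` is the depth of the
    Gaussian surface minimum at ``well_center``; the exponential wall at
    ``wall_position`` models the cost of detaching into vacuum. The logistic
    switch (``switch_center``, ``switch_width``) carries the component
    enthalpy means from zero in bulk to their interface amplitudes
    ``amp_ww``/``amp_aaw``/``amp_aaaa`` (water-water, solute-water,
    solute-solute); ``noise_sd`` is the per-frame Gaussian noise on each
    component.
    """

    well_depth: float = 5.0
    well_center: float = 2.05
    well_width: float = 0.15
    wall_position: float = 2.6
    wall_scale: float = 0.1
    switch_center: float = 2.0
    switch_width: float = 0.15
    amp_ww: float = -20.0
    amp_aaw: float = 15.0
    amp_aaaa: float = -2.0
    noise_sd: float = 5.0

    def __post_init__(self):
        if self.well_depth < 0:
            raise InputError("well_depth must be >= 0")
        for name in ("well_width", "wall_scale", "switch_width"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


@dataclass
class LangevinParams:
    """Overdamped (Brownian) dynamics configuration.

    Only the stationary distribution matters for PMF recovery, so a simple
    Euler-Maruyama integrator with reflecting domain boundaries stands in
    for a full thermostatted integrator. ``stride`` controls how many
    integration steps separate stored frames; the default (100) is about
    half the relaxation time of a window restrained at the default spring
    constant (kT / (D k) = 250 steps), so stored frames are approximately
    independent - the downstream estimators weight every stored frame
    equally and apply no autocorrelation correction. ``n_equil`` steps are
    discarded before storage begins.
    """

    temperature: float = DEFAULT_TEMPERATURE
    diffusion_coeff: float = 0.001  # nm^2/ps
    timestep: float = 0.01  # ps
    domain_min: float = 0.8
    domain_max: float = 3.2
    stride: int = 100
    n_equil: int = 5000

    def __post_init__(self):
        if self.temperature <= 0 or self.diffusion_coeff <= 0 or self.timestep <= 0:
            raise InputError("temperature, diffusion_coeff and timestep must be positive")
        if self.domain_min >= self.domain_max:
            raise InputError("domain_min must be below domain_max")
        if self.stride < 1:
            raise InputError("stride must be >= 1")

    @property
    def kT(self) -> float:
        return KB * self.temperature


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def true_pmf(r, params: TruePotentialParams):
    """Ground-truth PMF G(r) in kJ/mol (zero in bulk by construction)."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise InputError("reaction coordinate must be finite")
    well = -params.well_depth * np.exp(
        -((r - params.well_center) ** 2) / (2.0 * params.well_width**2)
    )
    wall = np.exp((r - params.wall_position) / params.wall_scale)
    out = well + wall
    return float(out) if out.ndim == 0 else out


def true_pmf_grad(r, params: TruePotentialParams):
    """dG/dr in kJ/mol/nm."""
    r = np.asarray(r, dtype=float)
    dr = r - params.well_center
    w2 = params.well_width**2
    grad = params.well_depth * dr / w2 * np.exp(-0.5 * dr * dr / w2)
    grad += np.exp((r - params.wall_position) / params.wall_scale) / params.wall_scale
    return float(grad) if grad.ndim == 0 else grad


def switch(r, params: TruePotentialParams):
    """Logistic interface switch S(r) in [0, 1]; 0 in bulk, 1 past the interface."""
    r = np.asarray(r, dtype=float)
    s = 1.0 / (1.0 + np.exp(-(r - params.switch_center) / params.switch_width))
    return float(s) if s.ndim == 0 else s


def true_enthalpy_components(r, params: TruePotentialParams):
    """Noise-free component-energy means (ww, aaw, aaaa) at r, kJ/mol."""
    s = switch(r, params)
    return (params.amp_ww * s, params.amp_aaw * s, params.amp_aaaa * s)


def true_enthalpy(r, params: TruePotentialParams):
    """Total ground-truth enthalpy change relative to bulk, kJ/mol."""
    ww, aaw, aaaa = true_enthalpy_components(r, params)
    return ww + aaw + aaaa


def true_minus_t_delta_s(r, params: TruePotentialParams):
    """-T dS implied by the ground truth: G(r) - dH(r) identically."""
    return true_pmf(r, params) - true_enthalpy(r, params)


# ---------------------------------------------------------------------------
# Langevin sampling
# ---------------------------------------------------------------------------

def check_stability(
    pot: TruePotentialParams,
    dyn: LangevinParams,
    spring: float = 0.0,
    center: float = 0.0,
    n_grid: int = 2001,
    limit: float = 0.1,
) -> float:
    """Scan the domain for the Euler-Maruyama drift-step criterion.

    The dimensionless drift step ``D * dt * |U'(r)| / kT`` must stay below
    ``limit`` everywhere on the domain for the configured total potential
    (landscape plus bias); returns the maximum encountered and raises
    :class:`ConfigurationError` if it exceeds the limit.
    """
    grid = np.linspace(dyn.domain_min, dyn.domain_max, n_grid)
    grad = np.abs(true_pmf_grad(grid, pot) + spring * (grid - center))
    drift = dyn.diffusion_coeff * dyn.timestep * grad / dyn.kT
    worst = float(drift.max())
    if worst >= limit:
        r_bad = float(grid[int(np.argmax(drift))])
        raise ConfigurationError(
            f"drift step {worst:.3g} at r={r_bad:.3f} nm exceeds the stability "
            f"limit {limit}; reduce the timestep or shrink the domain"
        )
    return worst


def sample_window(
    pot: TruePotentialParams,
    dyn: LangevinParams,
    center: float,
    spring: float,
    n_steps: int,
    seed: int,
    with_energies: bool = True,
) -> UmbrellaWindow:
    """Sample one umbrella window on the true landscape.

    Integrates Euler-Maruyama overdamped Langevin dynamics on
    ``U(r) = G(r) + 1/2 spring (r - center)^2`` with reflecting boundaries at
    the domain edges, stores every ``stride``-th coordinate and attaches
    per-frame component energies (true mean at the frame's r plus independent
    Gaussian noise). Identical ``seed`` gives bitwise-identical output.
    """
    if n_steps < 1:
        raise InputError("n_steps must be >= 1")
    if spring < 0:
        raise InputError("spring must be >= 0")
    check_stability(pot, dyn, spring=spring, center=center)
    margin = 1e-6 * (dyn.domain_max - dyn.domain_min)
    r0 = float(np.clip(center, dyn.domain_min + margin, dyn.domain_max - margin))
    samples = _kernels.langevin_trajectory(
        int(seed) % 2**31,
        int(n_steps),
        int(dyn.n_equil),
        int(dyn.stride),
        dyn.timestep,
        dyn.diffusion_coeff,
        dyn.kT,
        dyn.domain_min,
        dyn.domain_max,
        r0,
        pot.well_depth,
        pot.well_center,
        pot.well_width,
        pot.wall_position,
        pot.wall_scale,
        float(spring),
        float(center),
    )
    times = (np.arange(samples.size) + 1.0) * dyn.stride * dyn.timestep
    energies = None
    if with_energies:
        rng = np.random.default_rng([int(seed) % 2**31, 0xE])
        ww, aaw, aaaa = true_enthalpy_components(samples, pot)
        noise = rng.normal(0.0, pot.noise_sd, size=(3, samples.size))
        energies = EnergyComponents(
            e_ww=ww + noise[0], e_aaw=aaw + noise[1], e_aaaa=aaaa + noise[2]
        )
    return UmbrellaWindow(
        center=float(center),
        spring=float(spring),
        samples=samples,
        energies=energies,
        times=times,
        label=f"win_{center:.3f}",
    )


# ---------------------------------------------------------------------------
# Slab density snapshots
# ---------------------------------------------------------------------------

def make_density_snapshots(
    slab_center: float,
    gds_position: float,
    interface_width: float,
    bulk_density: float,
    box,
    n_frames: int,
    seed: int,
    placement_bin: float = 0.02,
) -> list[Snapshot]:
    """Single-site particle snapshots whose expected z-density is a tanh slab.

    The expected number density is
    ``rho(z) = bulk * 1/2 (1 - tanh((|z - slab_center| - gds_position) / width))``;
    per-z-bin occupation is Poisson with that mean, particles are placed
    uniformly within their bin and uniformly in x/y.
    """
    if gds_position <= 0 or interface_width <= 0:
        raise InputError("gds_position and interface_width must be positive")
    box = np.asarray(box, dtype=float)
    lz = box[2]
    if slab_center - gds_position < 0 or slab_center + gds_position > lz:
        raise ConfigurationError(
            f"box z-length {lz} nm too small for a slab of half-width "
            f"{gds_position} nm centered at {slab_center} nm"
        )
    rng = np.random.default_rng(int(seed) % 2**31)
    edges = np.arange(0.0, lz + 0.5 * placement_bin, placement_bin)
    z_lo = edges[:-1]
    widths = np.diff(edges)
    z_mid = z_lo + 0.5 * widths
    rho = bulk_density * 0.5 * (
        1.0 - np.tanh((np.abs(z_mid - slab_center) - gds_position) / interface_width)
    )
    lam = rho * box[0] * box[1] * widths
    snapshots = []
    for _ in range(n_frames):
        counts = rng.poisson(lam)
        total = int(counts.sum())
        z = np.repeat(z_lo, counts) + rng.random(total) * np.repeat(widths, counts)
        xy = rng.random((total, 2)) * box[:2]
        positions = np.column_stack([xy, z])
        snapshots.append(
            Snapshot(
                box=box,
                names=np.array(["OW"] * total, dtype=object),
                resids=np.arange(1, total + 1),
                resnames=np.array(["SOL"] * total, dtype=object),
                positions=positions,
            )
        )
    return snapshots


# ---------------------------------------------------------------------------
# Hydrogen-bond geometry fixtures
# ---------------------------------------------------------------------------

_DH_BOND = 0.1  # donor-hydrogen covalent bond length, nm


def _triplet_local(distance: float, deviation_deg: float, vertex: str) -> np.ndarray:
    """Local-frame D/H/A coordinates realizing the requested geometry."""
    dev = math.radians(deviation_deg)
    d_pos = np.zeros(3)
    a_pos = np.array([distance, 0.0, 0.0])
    if vertex == "hydrogen":
        # law of sines in the D-H-A triangle: angle at H is 180 - dev
        theta_a = math.asin(_DH_BOND * math.sin(dev) / distance)
        alpha = dev - theta_a  # angle at the donor vertex
    else:
        alpha = dev
    h_pos = d_pos + _DH_BOND * np.array([math.cos(alpha), math.sin(alpha), 0.0])
    return np.vstack([d_pos, h_pos, a_pos])


def make_hbond_fixture(
    geometries,
    seed: int,
    angle_vertex: str = "hydrogen",
) -> Snapshot:
    """Snapshot with one donor-hydrogen-acceptor triplet per requested geometry.

    ``geometries`` is a list of ``(donor_acceptor_distance_nm,
    angular_deviation_deg)``. Triplets are laid out on a grid coarse enough
    that cross-triplet contacts stay beyond any sensible hydrogen-bond
    cutoff, then randomly rotated and jittered; the requested geometry of
    each triplet is preserved exactly (to rotation round-off).
    """
    if angle_vertex not in ("hydrogen", "donor"):
        raise InputError(f"unknown angle vertex {angle_vertex!r}")
    geometries = list(geometries)
    if not geometries:
        raise InputError("need at least one geometry")
    for dist, dev in geometries:
        if dist <= 0.1:
            raise InputError("donor-acceptor distance must exceed 0.1 nm")
        if not 0 <= dev <= 180:
            raise InputError("angular deviation must lie in [0, 180] degrees")
    rng = np.random.default_rng(int(seed) % 2**31)
    n = len(geometries)
    cells_per_side = max(2, math.ceil(n ** (1.0 / 3.0)))
    spacing = 1.2
    box = np.full(3, cells_per_side * spacing)
    names, resids, resnames, positions = [], [], [], []
    rotations = Rotation.random(n, random_state=np.random.RandomState(int(seed) % 2**31))
    for t, (dist, dev) in enumerate(geometries):
        local = _triplet_local(dist, dev, angle_vertex)
        cell = np.array(
            [
                t % cells_per_side,
                (t // cells_per_side) % cells_per_side,
                t // cells_per_side**2,
            ]
        )
        origin = (cell + 0.5) * spacing + rng.uniform(-0.05, 0.05, size=3)
        rotated = rotations[t].apply(local) + origin
        positions.append(rotated)
        names.extend(["OD", "HD", "OA"])
        resids.extend([t + 1] * 3)
        resnames.extend(["HBX"] * 3)
    return Snapshot(
        box=box,
        names=np.array(names, dtype=object),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        positions=np.vstack(positions),
    )


def hbond_fixture_selections(snapshot: Snapshot):
    """Donor/hydrogen/acceptor selections for fixtures built here."""
    from .structure import select_hbond_atoms

    return select_hbond_atoms(snapshot)


def measure_hbond_geometries(snapshot: Snapshot, angle_vertex: str = "hydrogen"):
    """Read back (distance, deviation) per triplet of a fixture snapshot."""
    out = []
    for rid in sorted(set(snapshot.resids.tolist())):
        idx = snapshot.select_resid(rid)
        by_name = {snapshot.names[i]: i for i in idx}
        d, h, a = by_name["OD"], by_name["HD"], by_name["OA"]
        vec = snapshot.positions[a] - snapshot.positions[d]
        vec -= snapshot.box * np.round(vec / snapshot.box)
        dist = float(np.linalg.norm(vec))
        dev = _angle_deviation(
            snapshot.positions[d],
            snapshot.positions[h],
            snapshot.positions[a],
            snapshot.box,
            angle_vertex,
        )
        out.append((dist, float(dev)))
    return out


# ---------------------------------------------------------------------------
# Orientation fixtures
# ---------------------------------------------------------------------------

def make_orientation_fixture(mode: str, n: int, seed: int) -> np.ndarray:
    """Unit vectors: all +z (aligned), in-plane (planar), or uniform on the sphere."""
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(int(seed) % 2**31)
    if mode == "aligned":
        return np.tile([0.0, 0.0, 1.0], (n, 1))
    if mode == "planar":
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    if mode == "isotropic":
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1)[:, None]
    raise InputError(f"unknown orientation mode {mode!r}")


# ---------------------------------------------------------------------------
# On-disk window interchange (xvg dialect + energy CSV + manifest)
# ---------------------------------------------------------------------------

def write_window_xvg(window: UmbrellaWindow, path) -> None:
    """Two-column pull-style series: time (ps), coordinate (nm)."""
    times = (
        window.times
        if window.times is not None
        else np.arange(window.n_frames, dtype=float)
    )
    with open(path, "w") as fh:
        fh.write("# surfprop umbrella window pull coordinate\n")
        fh.write(f"# center {window.center!r} nm, spring {window.spring!r} kJ/mol/nm^2\n")
        fh.write('@    xaxis  label "Time (ps)"\n')
        fh.write('@    yaxis  label "Position (nm)"\n')
        for t, r in zip(times, window.samples):
            fh.write(f"{t:.6f}\t{r:.12g}\n")


def write_window_energies(window: UmbrellaWindow, path) -> None:
    """Four-column CSV: time_ps, e_ww, e_aaw, e_aaaa (kJ/mol)."""
    if window.energies is None:
        raise InputError("window carries no energies")
    times = (
        window.times
        if window.times is not None
        else np.arange(window.n_frames, dtype=float)
    )
    e = window.energies
    with open(path, "w") as fh:
        fh.write("time_ps,e_ww,e_aaw,e_aaaa\n")
        for t, a, b, c in zip(times, e.e_ww, e.e_aaw, e.e_aaaa):
            fh.write(f"{t:.6f},{a:.12g},{b:.12g},{c:.12g}\n")


def write_windows_manifest(entries, path) -> None:
    """JSON manifest: per-window center, spring, seed and file paths."""
    with open(path, "w") as fh:
        json.dump({"windows": list(entries)}, fh, indent=2)
        fh.write("\n")


def potential_to_dict(params: TruePotentialParams) -> dict:
    return asdict(params)
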