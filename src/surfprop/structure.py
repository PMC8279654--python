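"""Structural analyses for slab geometries.

Density profiles and the Gibbs dividing surface (GDS), geometric
hydrogen-bond counting, side-chain orientation statistics, and
intramolecular close-pair searches. All coordinates are in nm; boxes are
orthorhombic and minimum-image conventions apply throughout.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from MDAnalysis.lib.distances import distance_array

from .errors import GeometryError, InputError, ParseError

__all__ = [
    "Snapshot",
    "HBondCriteria",
    "DensityProfile",
    "OrientationHistogram",
    "AngleDistribution",
    "read_gro",
    "write_gro",
    "density_profile",
    "gibbs_dividing_surface",
    "interphase_region",
    "select_hbond_atoms",
    "count_hbonds",
    "hbond_vs_r",
    "orientation_distribution",
    "close_pairs",
    "hda_angle_distribution",
]


@dataclass(eq=False)
class Snapshot:
    """A molecular configuration: names, residues, positions (nm) and box (nm)."""

    box: np.ndarray
    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.names)
        if self.positions.shape != (n, 3):
            raise InputError("positions must be (n_atoms, 3)")
        if len(self.resids) != n or len(self.resnames) != n:
            raise InputError("per-atom arrays must share one length")
        if not np.all(np.isfinite(self.positions)):
            raise InputError("positions must be finite")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise InputError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def select_resname(self, resname: str) -> np.ndarray:
        return np.flatnonzero(self.resnames == resname)

    def select_resid(self, resid: int) -> np.ndarray:
        return np.flatnonzero(self.resids == resid)

    def select_names(self, names: Iterable[str]) -> np.ndarray:
        names = set(names)
        return np.flatnonzero([n in names for n in self.names])


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``max_da_distance`` (nm) bounds the donor-acceptor separation;
    ``max_angle_dev`` (degrees) bounds the angular deviation from an ideal
    bond under the chosen vertex convention:

    * ``"hydrogen"`` - deviation from linearity of the donor-hydrogen-acceptor
      angle (180 deg is ideal); this is the common trajectory-analysis choice.
    * ``"donor"`` - the hydrogen-donor-acceptor angle itself (0 deg is ideal).
    """

    max_da_distance: float = 0.35
    max_angle_dev: float = 30.0
    angle_vertex: str = "hydrogen"

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise InputError("max_da_distance must be positive")
        if not 0 < self.max_angle_dev <= 180:
            raise InputError("max_angle_dev must be in (0, 180]")
        if self.angle_vertex not in ("hydrogen", "donor"):
            raise InputError(f"unknown angle vertex {self.angle_vertex!r}")


@dataclass(eq=False)
class DensityProfile:
    """Binned number-density profile along the slab normal (nm^-3 vs nm)."""

    z_centers: np.ndarray
    density: np.ndarray
    bulk_density: float
    bin_width: float
    slab_center: float
    n_frames: int = 1

    def __post_init__(self):
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise InputError("density must be non-negative")
        if self.bulk_density <= 0:
            raise InputError("bulk density must be positive")


@dataclass(eq=False)
class OrientationHistogram:
    """Probability density of cos(theta) over [-1, 1]."""

    edges: np.ndarray
    density: np.ndarray
    count: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(eq=False)
class AngleDistribution:
    """Raw angular deviations (degrees) plus their normalized histogram."""

    angles_deg: np.ndarray
    edges: np.ndarray
    density: np.ndarray

    @property
    def count(self) -> int:
        return self.angles_deg.size


# ---------------------------------------------------------------------------
# GRO I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _precheck_gro(path) -> int:
    """Structural scan producing line-numbered errors MDAnalysis would swallow."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ParseError("file too short for a GRO snapshot", line=len(lines) + 1)
    try:
        natoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(f"expected atom count, got {lines[1]!r}", line=2) from None
    if len(lines) < natoms + 3:
        raise ParseError(
            f"declared {natoms} atoms but file truncated", line=len(lines) + 1
        )
    for i in range(2, 2 + natoms):
        ln = lines[i]
        if len(ln) < 44:
            raise ParseError("atom record shorter than fixed-column layout", line=i + 1)
        for lo, hi in ((20, 28), (28, 36), (36, 44)):
            try:
                float(ln[lo:hi])
            except ValueError:
                raise ParseError(
                    f"malformed coordinate field {ln[lo:hi]!r}", line=i + 1
                ) from None
    return natoms


def read_gro(path) -> Snapshot:
    """Read a GRO-format snapshot; positions returned in nm.

    Raises :class:`ParseError` (with a line number where determinable) on
    truncation, count mismatch or malformed fixed-column fields.
    """
    import MDAnalysis as mda

    natoms = _precheck_gro(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), topology_format="GRO", format="GRO")
    except Exception as exc:  # pragma: no cover - precheck catches common cases
        raise ParseError(f"GRO parse failed: {exc}") from exc
    if len(u.atoms) != natoms:
        raise ParseError(f"declared {natoms} atoms, parsed {len(u.atoms)}", line=2)
    return Snapshot(
        box=u.dimensions[:3] / 10.0,
        names=np.array([a.name for a in u.atoms], dtype=object),
        resids=np.array([a.resid for a in u.atoms], dtype=int),
        resnames=np.array([a.resname for a in u.atoms], dtype=object),
        positions=u.atoms.positions.astype(float) / 10.0,
    )


def write_gro(snapshot: Snapshot, path, title: str = "surfprop snapshot") -> None:
    """Write a snapshot in GRO format (3-decimal nm precision)."""
    import MDAnalysis as mda

    # consecutive-residue factorization preserving appearance order
    keys = list(zip(snapshot.resids.tolist(), snapshot.resnames.tolist()))
    res_index = np.empty(snapshot.n_atoms, dtype=int)
    seen: dict[tuple, int] = {}
    for i, k in enumerate(keys):
        if k not in seen:
            seen[k] = len(seen)
        res_index[i] = seen[k]
    n_res = len(seen)
    u = mda.Universe.empty(
        snapshot.n_atoms,
        n_residues=n_res,
        atom_resindex=res_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", snapshot.names.astype(str))
    u.add_TopologyAttr("resids", [k[0] for k in seen])
    u.add_TopologyAttr("resnames", [str(k[1]) for k in seen])
    u.atoms.positions = snapshot.positions * 10.0
    u.dimensions = [*(snapshot.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# Density profile and Gibbs dividing surface
# ---------------------------------------------------------------------------

def density_profile(
    snapshots: Sequence[Snapshot],
    selection: str,
    axis: str = "z",
    n_bins: int | None = None,
    bin_width: float = 0.05,
    bulk_halfwidth: float = 1.0,
) -> DensityProfile:
    """Frame-averaged number density of ``selection`` (a residue name) along z.

    The bulk density is the mean over bins whose centers lie within
    ``bulk_halfwidth`` of the slab center of mass (default: the central 2 nm).
    """
    if axis != "z":
        raise InputError("only the z axis is supported for slab profiles")
    if not snapshots:
        raise InputError("need at least one snapshot")
    box = snapshots[0].box
    lz = box[2]
    if n_bins is not None:
        bin_width = lz / n_bins
    edges = np.arange(0.0, lz + 0.5 * bin_width, bin_width)
    if edges[-1] < lz:
        edges = np.append(edges, lz)
    zs = []
    for snap in snapshots:
        idx = snap.select_resname(selection)
        zs.append(snap.positions[idx, 2])
    zs = np.concatenate(zs)
    if zs.size == 0:
        raise InputError(f"selection {selection!r} matches no atoms")
    counts, edges = np.histogram(zs, bins=edges)
    widths = np.diff(edges)
    volume = widths * box[0] * box[1] * len(snapshots)
    density = counts / volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    slab_center = float(zs.mean())
    bulk_mask = np.abs(centers - slab_center) <= bulk_halfwidth
    bulk = float(density[bulk_mask].mean()) if bulk_mask.any() else float(density.max())
    return DensityProfile(
        z_centers=centers,
        density=density,
        bulk_density=bulk,
        bin_width=float(widths[0]),
        slab_center=slab_center,
        n_frames=len(snapshots),
    )


def gibbs_dividing_surface(profile: DensityProfile) -> float:
    """Locate the GDS: where density falls to half its bulk value.

    Scans the outward (+z) flank away from the slab center, takes the
    outermost bin still at or above half-bulk followed by one below, and
    linearly interpolates the crossing. Returns the crossing as a distance
    from the slab center (the reaction-coordinate convention).
    """
    half = 0.5 * profile.bulk_density
    z = profile.z_centers
    d = profile.density
    outward = z >= profile.slab_center
    zo, do = z[outward], d[outward]
    cross = None
    for i in range(len(do) - 1):
        if do[i] >= half > do[i + 1]:
            cross = i
    if cross is None:
        raise GeometryError("density profile never crosses half of bulk on the +z flank")
    i = cross
    frac = (do[i] - half) / (do[i] - do[i + 1])
    z_cross = zo[i] + frac * (zo[i + 1] - zo[i])
    return float(z_cross - profile.slab_center)


def interphase_region(gds: float, halfwidth: float) -> tuple[float, float]:
    """Interval of width ``2*halfwidth`` centered at the GDS (nm)."""
    if halfwidth <= 0:
        raise InputError("halfwidth must be positive")
    return (gds - halfwidth, gds + halfwidth)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _mi_vector(v: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement for an orthorhombic box."""
    return v - box * np.round(v / box)


def _mda_box(box: np.ndarray) -> np.ndarray:
    return np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float64)


def _angle_deviation(
    d_pos: np.ndarray,
    h_pos: np.ndarray,
    a_pos: np.ndarray,
    box: np.ndarray,
    vertex: str,
) -> float:
    """Angular deviation (deg) from an ideal hydrogen bond."""
    if vertex == "hydrogen":
        v1 = _mi_vector(d_pos - h_pos, box)
        v2 = _mi_vector(a_pos - h_pos, box)
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    v1 = _mi_vector(h_pos - d_pos, box)
    v2 = _mi_vector(a_pos - d_pos, box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _validate_hbond_inputs(donors, hydrogens, acceptors):
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    seen_h: set[int] = set()
    for d in donors:
        if int(d) not in hydrogens:
            raise InputError(f"donor atom {int(d)} has no hydrogen mapping")
        for h in hydrogens[int(d)]:
            if int(h) in seen_h:
                raise InputError(f"hydrogen atom {int(h)} mapped to more than one donor")
            seen_h.add(int(h))
    for d, hs in hydrogens.items():
        if int(d) not in set(donors.tolist()):
            raise InputError(f"hydrogen mapping references non-donor atom {int(d)}")
    return donors, acceptors


def select_hbond_atoms(
    snapshot: Snapshot,
    donor_names: Sequence[str] = ("OD",),
    hydrogen_names: Sequence[str] = ("HD",),
    acceptor_names: Sequence[str] = ("OA",),
):
    """Name-based donor/hydrogen/acceptor selection.

    Hydrogens are attached to the donor within the same residue; returns
    ``(donor_indices, {donor: [hydrogens]}, acceptor_indices)``.
    """
    donors = snapshot.select_names(donor_names)
    acceptors = snapshot.select_names(acceptor_names)
    hydrogens: dict[int, list[int]] = {int(d): [] for d in donors}
    for h in snapshot.select_names(hydrogen_names):
        rid = snapshot.resids[h]
        owner = [int(d) for d in donors if snapshot.resids[d] == rid]
        if len(owner) != 1:
            raise InputError(f"hydrogen atom {int(h)} has no unique donor in residue {rid}")
        hydrogens[owner[0]].append(int(h))
    return donors, hydrogens, acceptors


def count_hbonds(
    snapshot: Snapshot,
    donors,
    hydrogens: Mapping[int, Sequence[int]],
    acceptors,
    criteria: HBondCriteria = HBondCriteria(),
) -> int:
    """Count donor-hydrogen-acceptor triples satisfying ``criteria``.

    A triple counts when the minimum-image donor-acceptor distance is at most
    ``max_da_distance`` and the angular deviation (under the configured vertex
    convention) is at most ``max_angle_dev``; the donor and acceptor must be
    distinct atoms.
    """
    donors, acceptors = _validate_hbond_inputs(donors, hydrogens, acceptors)
    if donors.size == 0 or acceptors.size == 0:
        return 0
    pos = snapshot.positions
    dmat = distance_array(pos[donors], pos[acceptors], box=_mda_box(snapshot.box))
    count = 0
    for di, d in enumerate(donors):
        for ai, a in enumerate(acceptors):
            if int(d) == int(a) or dmat[di, ai] > criteria.max_da_distance:
                continue
            for h in hydrogens[int(d)]:
                dev = _angle_deviation(
                    pos[d], pos[h], pos[a], snapshot.box, criteria.angle_vertex
                )
                if dev <= criteria.max_angle_dev:
                    count += 1
    return count


def hbond_vs_r(
    per_window_snapshots: Mapping[float, Sequence[Snapshot]],
    criteria: HBondCriteria = HBondCriteria(),
    selector: Callable[[Snapshot], tuple] = select_hbond_atoms,
) -> list[tuple[float, float]]:
    """Frame-averaged hydrogen-bond count per umbrella window, ordered by r.

    Windows with no snapshots are excluded with a warning rather than failing
    the whole series.
    """
    series = []
    for r in sorted(per_window_snapshots):
        snaps = per_window_snapshots[r]
        if not snaps:
            warnings.warn(f"window r={r}: no snapshots, excluded from H-bond series")
            continue
        counts = []
        for snap in snaps:
            donors, hyd, acceptors = selector(snap)
            counts.append(count_hbonds(snap, donors, hyd, acceptors, criteria))
        series.append((float(r), float(np.mean(counts))))
    return series


# ---------------------------------------------------------------------------
# Orientations
# ---------------------------------------------------------------------------

def orientation_distribution(vectors, n_bins: int = 20) -> OrientationHistogram:
    """Histogram of cos(theta) between each vector and the surface normal (+z).

    Vectors are normalized first; the returned histogram is a probability
    density over [-1, 1] (it integrates to one).
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0) or not np.all(np.isfinite(norms)):
        raise InputError("orientation vectors must be nonzero and finite")
    cos_theta = vectors[:, 2] / norms
    density, edges = np.histogram(cos_theta, bins=n_bins, range=(-1.0, 1.0), density=True)
    return OrientationHistogram(edges=edges, density=density, count=len(cos_theta))


# ---------------------------------------------------------------------------
# Close pairs and HDA angle distribution
# ---------------------------------------------------------------------------

def _graph_distance_within(adjacency: Mapping[int, set], start: int, limit: int) -> dict:
    """BFS distances from ``start`` up to ``limit`` bonds."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        if dist[u] >= limit:
            continue
        for v in adjacency.get(u, ()):  # noqa: B909
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def close_pairs(
    snapshot: Snapshot,
    residue_id: int,
    cutoff: float,
    min_bond_separation: int = 0,
    bonds: Sequence[tuple[int, int]] | None = None,
) -> list[tuple[int, int, float]]:
    """All intra-residue atom pairs within ``cutoff`` (nm), sorted by distance.

    With a bonded topology (``bonds``, global index pairs) pairs fewer than
    ``min_bond_separation`` bonds apart are excluded; without one, all pairs
    are eligible.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    idx = snapshot.select_resid(residue_id)
    if idx.size == 0:
        raise InputError(f"no atoms with residue id {residue_id}")
    pos = snapshot.positions[idx]
    dmat = distance_array(pos, pos, box=_mda_box(snapshot.box))
    excluded: set[tuple[int, int]] = set()
    if bonds is not None and min_bond_separation > 0:
        adjacency: dict[int, set] = {}
        for a, b in bonds:
            adjacency.setdefault(int(a), set()).add(int(b))
            adjacency.setdefault(int(b), set()).add(int(a))
        for gi in idx:
            dists = _graph_distance_within(adjacency, int(gi), min_bond_separation - 1)
            for gj, nd in dists.items():
                if gj != gi and nd < min_bond_separation:
                    excluded.add((min(int(gi), gj), max(int(gi), gj)))
    pairs = []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            gi, gj = int(idx[i]), int(idx[j])
            if (gi, gj) in excluded:
                continue
            if dmat[i, j] <= cutoff:
                pairs.append((gi, gj, float(dmat[i, j])))
    pairs.sort(key=lambda t: t[2])
    return pairs


def hda_angle_distribution(
    snapshot: Snapshot,
    donors,
    hydrogens: Mapping[int, Sequence[int]],
    acceptors,
    max_da_distance: float = 0.35,
    n_bins: int = 36,
    angle_vertex: str = "hydrogen",
) -> AngleDistribution:
    """Angular deviations for every in-range donor-acceptor pair.

    Records the deviation for each donor hydrogen against each acceptor whose
    minimum-image D-A distance is within ``max_da_distance``; histograms the
    deviations over [0, 180] degrees. An empty result is returned (not an
    error) when no pair is in range.
    """
    donors, acceptors = _validate_hbond_inputs(donors, hydrogens, acceptors)
    angles: list[float] = []
    if donors.size and acceptors.size:
        pos = snapshot.positions
        dmat = distance_array(pos[donors], pos[acceptors], box=_mda_box(snapshot.box))
        for di, d in enumerate(donors):
            for ai, a in enumerate(acceptors):
                if int(d) == int(a) or dmat[di, ai] > max_da_distance:
                    continue
                for h in hydrogens[int(d)]:
                    angles.append(
                        _angle_deviation(pos[d], pos[h], pos[a], snapshot.box, angle_vertex)
                    )
    angles_arr = np.array(sorted(angles), dtype=float)
    if angles_arr.size:
        density, edges = np.histogram(angles_arr, bins=n_bins, range=(0.0, 180.0), density=True)
    else:
        edges = np.linspace(0.0, 180.0, n_bins + 1)
        density = np.zeros(n_bins)
    return AngleDistribution(angles_deg=angles_arr, edges=edges, density=density)
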