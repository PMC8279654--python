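"""Enthalpy-entropy decomposition of the PMF and its group-wise split.

The free energy along the reaction coordinate decomposes as
``dG = dH - T dS``. The enthalpy at each umbrella window is the difference
in time-averaged potential energy between that window and the bulk
reference window; the entropy term is obtained by subtraction,
``-T dS = dG - dH``. The enthalpy further splits into water-water,
solute-water and solute-solute interaction contributions, which sum to dH
exactly (dH is assembled from the component means, and each frame's total
is stored as the exact component sum).

Standard errors treat frames as independent; with correlated data they are
optimistic in variance but unbiased in the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ReferencingError, RegionSearchError
from .wham import PMFProfile
from .windows import UmbrellaWindow

__all__ = [
    "DecompositionRecord",
    "SurfaceMinimum",
    "enthalpy_profile",
    "enthalpy_components_profile",
    "entropy_profile",
    "decomposition_profile",
    "find_surface_minimum",
    "decomposition_at_minimum",
]


@dataclass
class DecompositionRecord:
    """Free-energy decomposition at one point of the profile (kJ/mol).

    Identities enforced by construction: ``dG = dH + minus_TdS`` (the
    entropy term is defined by this difference) and
    ``dH = dE_ww + dE_aaw + dE_aaaa``.
    """

    r: float
    dG: float
    dH: float
    minus_TdS: float
    dE_ww: float
    dE_aaw: float
    dE_aaaa: float
    se_dH: float


@dataclass
class SurfaceMinimum:
    """Location and depth of the PMF minimum inside a search region."""

    r_min: float
    dG_min: float
    interior: bool


def _require_energies(windows):
    for w in windows:
        if w.energies is None:
            raise InputError(f"window {w.label!r} carries no per-frame energies")


def _reference_window(windows, ref_center):
    centers = np.array(sorted({w.center for w in windows}))
    if centers.size > 1:
        tol = 0.5 * float(np.min(np.diff(centers)))
    else:
        tol = 1e-9 + 1e-9 * abs(ref_center)
    dists = np.array([abs(w.center - ref_center) for w in windows])
    i = int(np.argmin(dists))
    if dists[i] > tol:
        raise ReferencingError(
            f"no window within {tol:.4g} nm of the reference center {ref_center} nm"
        )
    return windows[i]


def enthalpy_components_profile(
    windows: list[UmbrellaWindow], ref_center: float
) -> pd.DataFrame:
    """Component-energy differences per window relative to the bulk reference.

    Returns a DataFrame ordered by window center with columns
    ``r, dE_ww, dE_aaw, dE_aaaa, dH, se_dH`` where ``dH`` is the exact sum of
    the three components and ``se_dH`` combines the two windows' standard
    errors of the per-frame total in quadrature (zero for the reference row,
    whose difference is identically zero).
    """
    _require_energies(windows)
    ref = _reference_window(windows, ref_center)
    ref_means = {
        "ww": float(np.mean(ref.energies.e_ww)),
        "aaw": float(np.mean(ref.energies.e_aaw)),
        "aaaa": float(np.mean(ref.energies.e_aaaa)),
    }
    ref_se2 = np.var(ref.energies.e_total, ddof=1) / ref.n_frames if ref.n_frames > 1 else 0.0
    rows = []
    for w in sorted(windows, key=lambda w: w.center):
        if w is ref:
            rows.append(
                {"r": w.center, "dE_ww": 0.0, "dE_aaw": 0.0, "dE_aaaa": 0.0,
                 "dH": 0.0, "se_dH": 0.0}
            )
            continue
        de_ww = float(np.mean(w.energies.e_ww)) - ref_means["ww"]
        de_aaw = float(np.mean(w.energies.e_aaw)) - ref_means["aaw"]
        de_aaaa = float(np.mean(w.energies.e_aaaa)) - ref_means["aaaa"]
        se2 = np.var(w.energies.e_total, ddof=1) / w.n_frames if w.n_frames > 1 else 0.0
        rows.append(
            {
                "r": w.center,
                "dE_ww": de_ww,
                "dE_aaw": de_aaw,
                "dE_aaaa": de_aaaa,
                "dH": de_ww + de_aaw + de_aaaa,
                "se_dH": float(np.sqrt(se2 + ref_se2)),
            }
        )
    return pd.DataFrame(rows)


def enthalpy_profile(windows: list[UmbrellaWindow], ref_center: float) -> pd.DataFrame:
    """Per-window enthalpy difference to the reference window.

    Columns ``r, dH, se_dH``; see :func:`enthalpy_components_profile` for the
    component-resolved version (``dH`` here is the same exact component sum).
    """
    return enthalpy_components_profile(windows, ref_center)[["r", "dH", "se_dH"]]


def entropy_profile(pmf: PMFProfile, enthalpy: pd.DataFrame) -> pd.DataFrame:
    """Entropy term by subtraction: ``-T dS(r) = dG(r) - dH(r)``.

    ``dG`` is interpolated linearly from PMF bin centers to each window
    center; the PMF must be referenced at the same coordinate used for the
    enthalpy reference.
    """
    if pmf.reference is None:
        raise InputError("PMF must be referenced before the entropy subtraction")
    r = enthalpy["r"].to_numpy(dtype=float)
    dG = np.asarray(pmf.value_at(r), dtype=float)
    out = enthalpy.copy()
    dH = out["dH"].to_numpy()
    minus_TdS = dG - dH
    # re-emit dG as the sum so dG = dH + minus_TdS holds bitwise (the
    # adjustment is at most one ulp of the interpolated value)
    out["dG"] = dH + minus_TdS
    out["minus_TdS"] = minus_TdS
    return out[["r", "dG", "dH", "minus_TdS", *(c for c in out.columns if c == "se_dH")]]


def decomposition_profile(
    pmf: PMFProfile, windows: list[UmbrellaWindow], ref_center: float
) -> pd.DataFrame:
    """Full per-window table: r, dG, dH, minus_TdS, dE_ww, dE_aaw, dE_aaaa, se_dH."""
    comp = enthalpy_components_profile(windows, ref_center)
    r = comp["r"].to_numpy(dtype=float)
    dG = np.asarray(pmf.value_at(r), dtype=float)
    dH = comp["dH"].to_numpy()
    minus_TdS = dG - dH
    comp.insert(1, "dG", dH + minus_TdS)  # bitwise dG = dH + minus_TdS
    comp.insert(3, "minus_TdS", minus_TdS)
    return comp[["r", "dG", "dH", "minus_TdS", "dE_ww", "dE_aaw", "dE_aaaa", "se_dH"]]


def find_surface_minimum(pmf: PMFProfile, region: tuple[float, float]) -> SurfaceMinimum:
    """Deepest defined bin inside ``region``; ties break toward smaller r.

    ``interior`` is False when the minimum sits at an edge bin of the
    in-region defined set (a boundary minimum does not indicate surface
    propensity).
    """
    lo, hi = region
    mask = pmf.defined & (pmf.centers >= lo) & (pmf.centers <= hi)
    if not mask.any():
        raise RegionSearchError(f"no defined PMF bins inside [{lo}, {hi}] nm")
    idx = np.flatnonzero(mask)
    vals = pmf.values[idx]
    best = idx[int(np.argmin(vals))]  # argmin takes the first (smallest r) tie
    interior = best != idx[0] and best != idx[-1]
    return SurfaceMinimum(
        r_min=float(pmf.centers[best]), dG_min=float(pmf.values[best]), interior=bool(interior)
    )


def decomposition_at_minimum(
    pmf: PMFProfile,
    windows: list[UmbrellaWindow],
    ref_center: float,
    region: tuple[float, float],
) -> DecompositionRecord:
    """Assemble the decomposition record at the PMF's surface minimum.

    Locates the minimum in ``region``, takes the window nearest to it for
    the enthalpy terms, and interpolates dG at the minimum. When the nearest
    window is the reference window itself (degenerate request) the record is
    identically zero.
    """
    minimum = find_surface_minimum(pmf, region)
    ref = _reference_window(windows, ref_center)
    nearest = min(windows, key=lambda w: abs(w.center - minimum.r_min))
    if nearest is ref:
        return DecompositionRecord(
            r=minimum.r_min, dG=0.0, dH=0.0, minus_TdS=0.0,
            dE_ww=0.0, dE_aaw=0.0, dE_aaaa=0.0, se_dH=0.0,
        )
    comp = enthalpy_components_profile([ref, nearest], ref_center)
    row = comp[comp["r"] == nearest.center].iloc[0]
    dG = float(pmf.value_at(minimum.r_min))
    dH = float(row["dH"])
    minus_TdS = dG - dH
    return DecompositionRecord(
        r=minimum.r_min,
        dG=dH + minus_TdS,
        dH=dH,
        minus_TdS=minus_TdS,
        dE_ww=float(row["dE_ww"]),
        dE_aaw=float(row["dE_aaw"]),
        dE_aaaa=float(row["dE_aaaa"]),
        se_dH=float(row["se_dH"]),
    )
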