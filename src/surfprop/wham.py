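"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Solves the standard self-consistent WHAM equations over equal-width bins:

    P_j = ( sum_i n_ij ) / ( sum_i N_i exp[(f_i - c_ij)/kT] )
    f_i = -kT ln sum_j P_j exp(-c_ij / kT)

with harmonic bias c_ij = 1/2 k_i (x_j - r_i)^2 evaluated at bin centers,
iterated in log space until the window free energies f_i stop moving. The
PMF is -kT ln P_j on bins that received samples; empty bins stay undefined
rather than being interpolated. A simple Boltzmann-inversion estimator is
provided as the independent single-window oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB
from .errors import (
    ConvergenceError,
    InputError,
    ParseError,
    ReferencingError,
    WindowOverlapError,
)
from .windows import UmbrellaWindow

__all__ = [
    "PMFProfile",
    "read_pull_series",
    "wham",
    "set_reference",
    "boltzmann_invert",
    "write_pmf",
    "read_pmf",
    "window_overlap_counts",
]


@dataclass(eq=False)
class PMFProfile:
    """Binned free-energy profile.

    ``values`` hold the PMF (kJ/mol) at bin centers, NaN where undefined
    (zero samples); ``reference`` records the coordinate whose bin was
    pinned to zero. WHAM diagnostics (iteration count, final residual and
    residual history) ride along when the profile came from :func:`wham`.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    temperature: float
    reference: float | None = None
    n_iterations: int | None = None
    final_residual: float | None = None
    residual_history: np.ndarray | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise InputError("bin edges must be strictly increasing")
        n = self.bin_edges.size - 1
        if self.values.size != n or self.counts.size != n:
            raise InputError("values/counts must have one entry per bin")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_index(self, r: float) -> int:
        """Index of the bin containing r (right-inclusive last bin)."""
        if r < self.bin_edges[0] or r > self.bin_edges[-1]:
            raise ReferencingError(
                f"coordinate {r} nm outside the binned range "
                f"[{self.bin_edges[0]:.4f}, {self.bin_edges[-1]:.4f}]"
            )
        idx = int(np.searchsorted(self.bin_edges, r, side="right") - 1)
        return min(idx, self.n_bins - 1)

    def value_at(self, r) -> np.ndarray | float:
        """PMF linearly interpolated between defined bin centers."""
        from .errors import ProfileRangeError

        mask = self.defined
        xs, ys = self.centers[mask], self.values[mask]
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        if np.any(r_arr < xs[0]) or np.any(r_arr > xs[-1]):
            raise ProfileRangeError(
                f"coordinate outside the defined profile range [{xs[0]:.4f}, {xs[-1]:.4f}]"
            )
        out = np.interp(r_arr, xs, ys)
        return float(out[0]) if np.isscalar(r) or np.asarray(r).ndim == 0 else out


def read_pull_series(path, dialect: str = "xvg"):
    """Parse a GROMACS-pull-style two-column series (time ps, coordinate nm).

    Lines starting with ``#`` or ``@`` are comments. Returns
    ``(times, coords)`` as float arrays.
    """
    if dialect != "xvg":
        raise InputError(f"unknown dialect {dialect!r}")
    times, coords = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError("expected two numeric columns", line=lineno)
            try:
                t, x = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"malformed numeric line {line!r}", line=lineno) from None
            times.append(t)
            coords.append(x)
    if not coords:
        raise InputError(f"{path}: no data rows")
    return np.array(times), np.array(coords)


def _bin_setup(windows, n_bins, bin_range):
    allsamp = np.concatenate([w.samples for w in windows])
    if bin_range is None:
        lo, hi = float(allsamp.min()), float(allsamp.max())
    else:
        lo, hi = map(float, bin_range)
    if hi <= lo:
        raise InputError("degenerate bin range (all samples identical?)")
    edges = np.linspace(lo, hi, n_bins + 1)
    return edges


def _histogram_windows(windows, edges):
    n_ij = np.empty((len(windows), edges.size - 1))
    for i, w in enumerate(windows):
        n_ij[i], _ = np.histogram(w.samples, bins=edges)
    return n_ij


def wham(
    windows: list[UmbrellaWindow],
    n_bins: int = 41,
    temperature: float = 300.0,
    tol: float = 1e-6,
    max_iter: int = 100000,
    bin_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Reconstruct the unbiased PMF from umbrella windows.

    Bins span the observed sample range (or ``bin_range``) with equal
    widths; convergence is declared when ``max_i |Delta f_i| < tol``
    (kJ/mol). Raises :class:`WindowOverlapError` when a window contributes no
    in-range samples and :class:`ConvergenceError` after ``max_iter``
    sweeps.
    """
    if not windows:
        raise InputError("need at least one window")
    if tol <= 0:
        raise InputError("tol must be positive")
    kT = KB * temperature
    edges = _bin_setup(windows, n_bins, bin_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_ij = _histogram_windows(windows, edges)
    N_i = n_ij.sum(axis=1)
    for i, w in enumerate(windows):
        if N_i[i] == 0:
            raise WindowOverlapError(
                f"window {w.label!r} (center {w.center} nm) has no samples in the "
                "binned range - check window overlap"
            )
    M_j = n_ij.sum(axis=0)
    defined = M_j > 0
    with np.errstate(divide="ignore"):
        logM = np.where(defined, np.log(np.maximum(M_j, 1e-300)), -np.inf)
        logN = np.log(N_i)

    # log bias Boltzmann factor, shape (n_windows, n_bins)
    k = np.array([w.spring for w in windows])[:, None]
    r0 = np.array([w.center for w in windows])[:, None]
    c = 0.5 * k * (centers[None, :] - r0) ** 2
    g = -c / kT

    f = np.zeros(len(windows))
    history = []
    converged = False
    n_done = 0
    for n_done in range(1, max_iter + 1):
        log_denom = logsumexp(logN[:, None] + f[:, None] / kT + g, axis=0)
        logP = np.where(defined, logM - log_denom, -np.inf)
        f_new = -kT * logsumexp(logP[None, :] + g, axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        history.append(residual)
        f = f_new
        if residual < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {history[-1]:.3g} kJ/mol)",
            residual=history[-1],
        )
    values = np.where(defined, -kT * logP, np.nan)
    return PMFProfile(
        bin_edges=edges,
        values=values,
        counts=M_j,
        temperature=temperature,
        n_iterations=n_done,
        final_residual=history[-1],
        residual_history=np.array(history),
    )


def set_reference(pmf: PMFProfile, r_ref: float) -> PMFProfile:
    """Shift the profile so the bin containing ``r_ref`` is exactly zero."""
    idx = pmf.bin_index(r_ref)
    if not pmf.defined[idx]:
        raise ReferencingError(f"reference coordinate {r_ref} nm falls in an undefined bin")
    shifted = pmf.values - pmf.values[idx]
    return dataclasses.replace(pmf, values=shifted, reference=float(r_ref))


def boltzmann_invert(
    samples,
    n_bins: int = 41,
    temperature: float = 300.0,
    bin_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Direct histogram inversion: PMF_j = -kT ln(count_j / N).

    Valid only for unbiased samples; serves as the independent oracle for
    :func:`wham` on zero-spring data.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise InputError("need at least one sample")
    kT = KB * temperature
    if bin_range is None:
        lo, hi = float(samples.min()), float(samples.max())
    else:
        lo, hi = map(float, bin_range)
    if hi <= lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    with np.errstate(divide="ignore"):
        values = np.where(counts > 0, -kT * np.log(counts / samples.size), np.nan)
    return PMFProfile(bin_edges=edges, values=values, counts=counts, temperature=temperature)


def write_pmf(pmf: PMFProfile, path) -> None:
    """CSV with columns center_nm, dG_kJmol, count, defined.

    Undefined bins keep their row with an empty free-energy field. Requires
    a referenced profile so the file states energies relative to a declared
    zero.
    """
    if pmf.reference is None:
        raise InputError("profile must be referenced before writing")
    with open(path, "w") as fh:
        fh.write(f"# reference_nm={pmf.reference!r} temperature_K={pmf.temperature!r}\n")
        fh.write("center_nm,dG_kJmol,count,defined\n")
        for c, v, n, ok in zip(pmf.centers, pmf.values, pmf.counts, pmf.defined):
            val = f"{v:.12g}" if ok else ""
            fh.write(f"{c:.12g},{val},{int(n)},{str(bool(ok)).lower()}\n")


def read_pmf(path, temperature: float = 300.0) -> PMFProfile:
    """Read a profile written by :func:`write_pmf`."""
    reference = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                key, _, val = tok.partition("=")
                if key == "reference_nm":
                    reference = float(val)
                elif key == "temperature_K":
                    temperature = float(val)
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    centers = df["center_nm"].to_numpy(dtype=float)
    if centers.size < 2:
        raise ParseError("profile needs at least two bins")
    width = centers[1] - centers[0]
    edges = np.append(centers - 0.5 * width, centers[-1] + 0.5 * width)
    values = df["dG_kJmol"].to_numpy(dtype=float)
    values = np.where(df["defined"].to_numpy(), values, np.nan)
    return PMFProfile(
        bin_edges=edges,
        values=values,
        counts=df["count"].to_numpy(),
        temperature=temperature,
        reference=reference,
    )


def window_overlap_counts(windows: list[UmbrellaWindow], n_bins: int = 41) -> list[int]:
    """Shared-sample diagnostic: for each adjacent window pair, the number of
    bins populated by both windows. Zero signals a broken ladder."""
    edges = _bin_setup(windows, n_bins, None)
    n_ij = _histogram_windows(windows, edges)
    order = np.argsort([w.center for w in windows])
    overlaps = []
    for a, b in zip(order[:-1], order[1:]):
        overlaps.append(int(np.sum((n_ij[a] > 0) & (n_ij[b] > 0))))
    return overlaps
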