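"""Containers for umbrella-sampling windows and their per-frame energies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass(eq=False)
class EnergyComponents:
    """Per-frame interaction-energy components, kJ/mol.

    ``e_total`` is stored as the exact per-frame sum of the three components
    (water-water, solute-water, solute-solute) so downstream bookkeeping
    identities hold in floating point.
    """

    e_ww: np.ndarray
    e_aaw: np.ndarray
    e_aaaa: np.ndarray
    e_total: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.e_ww = np.asarray(self.e_ww, dtype=float)
        self.e_aaw = np.asarray(self.e_aaw, dtype=float)
        self.e_aaaa = np.asarray(self.e_aaaa, dtype=float)
        n = len(self.e_ww)
        if len(self.e_aaw) != n or len(self.e_aaaa) != n:
            raise InputError("energy component series must have equal length")
        if self.e_total is None:
            self.e_total = self.e_ww + self.e_aaw + self.e_aaaa
        else:
            self.e_total = np.asarray(self.e_total, dtype=float)
            if len(self.e_total) != n:
                raise InputError("e_total length mismatch")
            if not np.array_equal(self.e_total, self.e_ww + self.e_aaw + self.e_aaaa):
                raise InputError("e_total must equal the exact component sum per frame")

    def __len__(self) -> int:
        return len(self.e_ww)


@dataclass(eq=False)
class UmbrellaWindow:
    """One harmonically biased sampling window along the reaction coordinate.

    Parameters
    ----------
    center : float
        Bias (restraint) center, nm.
    spring : float
        Harmonic spring constant of the bias ``1/2 k (r - center)^2``,
        kJ mol^-1 nm^-2.
    samples : ndarray
        Stored reaction-coordinate frames, nm.
    energies : EnergyComponents, optional
        Per-frame component energies, same length as ``samples``.
    times : ndarray, optional
        Frame times, ps.
    label : str
        Human-readable window name (used in diagnostics).
    """

    center: float
    spring: float
    samples: np.ndarray
    energies: EnergyComponents | None = None
    times: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise InputError("window must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("window samples must be finite")
        if self.spring < 0:
            raise InputError("spring constant must be >= 0")
        if self.energies is not None and len(self.energies) != self.samples.size:
            raise InputError("energies length must match samples length")
        if not self.label:
            self.label = f"win_{self.center:.3f}"

    @property
    def n_frames(self) -> int:
        return self.samples.size
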