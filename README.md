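# surfprop

Free-energy analysis of solute surface propensity at a liquid slab
interface, exercised end to end on a synthetic system with a known answer.

Small solutes such as free amino acids can prefer the water/vapor interface
over the bulk; the thermodynamic signature is a minimum of the potential of
mean force (PMF) ΔG(r) near the Gibbs dividing surface (GDS), where r is
the distance between the solute and the slab center of mass along the
surface normal. `surfprop` implements the full inference chain used in
such studies:

* **Umbrella sampling** of r in harmonically restrained windows
  (here by overdamped Langevin dynamics on a configurable ground-truth
  landscape G(r) — a Gaussian surface well plus an exponential vacuum
  wall — so every later stage can be validated by parameter recovery);
* **WHAM** (weighted histogram analysis method): the self-consistent
  estimator P_j = Σᵢn_ij / Σᵢ Nᵢ exp[(fᵢ − c_ij)/k_BT],
  fᵢ = −k_BT ln Σ_j P_j exp(−c_ij/k_BT), iterated in log space, with the
  PMF anchored to zero at the bulk reference r = 1.0 nm;
* **Enthalpy–entropy decomposition** ΔG = ΔH − TΔS, with ΔH the difference
  in time-averaged potential energy between a window and the bulk
  reference and −TΔS obtained by subtraction, plus the split of ΔH into
  water–water, solute–water and solute–solute contributions;
* **Interface structure**: slab density profiles and the GDS (half-bulk
  crossing), geometric hydrogen bonds (D–A ≤ 3.5 Å, angular deviation
  ≤ 30°), side-chain orientation distributions over cos θ, and
  intramolecular close-pair searches.

The intended audience is molecular-simulation practitioners who want a
tested, self-contained reference implementation of this workflow whose
statistical behavior is verifiable without a cluster.

## Worked example

```python
import numpy as np
from surfprop import (TruePotentialParams, LangevinParams, sample_window,
                      wham, set_reference, find_surface_minimum, true_pmf)

pot, dyn = TruePotentialParams(), LangevinParams()   # 5 kJ/mol well at 2.05 nm
windows = [sample_window(pot, dyn, c, spring=1000.0, n_steps=2_000_000, seed=10+i)
           for i, c in enumerate(np.arange(1.0, 3.01, 0.1))]
profile = set_reference(wham(windows, n_bins=41, temperature=300.0), r_ref=1.0)
m = find_surface_minimum(profile, region=(1.6, 2.8))
mask = profile.defined & (profile.centers >= 1.6) & (profile.centers <= 2.8)
rms = np.sqrt(np.mean((profile.values[mask] - true_pmf(profile.centers[mask], pot))**2))
print(f"minimum at r = {m.r_min:.3f} nm, dG = {m.dG_min:.2f} kJ/mol (interior: {m.interior})")
print(f"RMS(PMF - truth) over the interphase region: {rms:.3f} kJ/mol")
```

Output:

```
minimum at r = 2.051 nm, dG = -4.67 kJ/mol (interior: True)
RMS(PMF - truth) over the interphase region: 0.261 kJ/mol
```

The minimum sits at the configured well center (2.05 nm) and its depth
recovers the configured 5 kJ/mol well to within the statistical error of
this short demonstration run (2×10⁴ stored frames per window; at the
default production length of 2×10⁵ frames the RMS drops below 0.1 kJ/mol
and the depth error below 0.1 kJ/mol). The RMS line quantifies how closely
the WHAM profile tracks the known landscape across the interphase region
(1.6–2.8 nm, the ±0.6 nm band around the GDS). A negative interior minimum
of this kind is exactly the surface-propensity signature the workflow is
designed to detect.

The same chain runs as one seeded command producing a reproducible bundle
(windows, PMF CSV, decomposition CSV, minimum-record JSON, structure CSVs,
run metadata with a QC block):

```bash
surfprop all --seed 7 --out run_out          # defaults: 21 windows, 41 bins
surfprop all --config examples/published_protocol.yaml --seed 7 --out protocol_out
```

`examples/` contains short narrative scripts, one per capability
(`01_sample_and_wham.py`, `02_decomposition.py`, `03_surface_structure.py`,
`04_full_pipeline.py`).

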