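"""Sample an umbrella ladder and reconstruct the PMF with WHAM.

Builds 21 harmonically biased windows on the synthetic slab landscape,
runs the self-consistent WHAM iteration, anchors the profile at the bulk
reference (r = 1.0 nm) and compares against the known ground truth.
"""

import numpy as np

from surfprop import (
    LangevinParams,
    TruePotentialParams,
    find_surface_minimum,
    sample_window,
    set_reference,
    true_pmf,
    wham,
)

pot = TruePotentialParams()  # 5 kJ/mol Gaussian well at 2.05 nm, wall at 2.6 nm
dyn = LangevinParams()       # 300 K overdamped Langevin, stored every 100 steps

centers = np.round(np.arange(1.0, 3.01, 0.1), 10)
windows = [
    sample_window(pot, dyn, float(c), spring=1000.0, n_steps=2_000_000, seed=40 + i)
    for i, c in enumerate(centers)
]
profile = set_reference(wham(windows, n_bins=41, temperature=300.0), r_ref=1.0)

print(f"WHAM converged in {profile.n_iterations} iterations "
      f"(residual {profile.final_residual:.2e} kJ/mol)")
minimum = find_surface_minimum(profile, region=(1.6, 2.8))
print(f"surface minimum: r = {minimum.r_min:.3f} nm, "
      f"dG = {minimum.dG_min:.2f} kJ/mol, interior = {minimum.interior}")

mask = profile.defined & (profile.centers >= 1.6) & (profile.centers <= 2.8)
truth = true_pmf(profile.centers[mask], pot) - true_pmf(1.0, pot)
rms = np.sqrt(np.mean((profile.values[mask] - truth) ** 2))
print(f"RMS deviation from the true landscape over 1.6-2.8 nm: {rms:.3f} kJ/mol")
print("A negative interior minimum near the Gibbs dividing surface is the")
print("thermodynamic signature of surface propensity; the RMS shows how well")
print("the estimator recovers the landscape it sampled.")
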