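# Methods

`surfprop` implements the free-energy workflow used to quantify the surface
propensity of a small solute (e.g. an amino acid) at a water/vacuum slab
interface: umbrella sampling along the solute–slab center-of-mass distance
*r*, WHAM reconstruction of the potential of mean force (PMF),
enthalpy–entropy decomposition with a group-wise enthalpy split, and
structural statistics of the interface. Because the all-atom simulations
behind such studies are cluster-scale, the package ships a synthetic slab
system with a fully known landscape; every stage of the analysis chain is
validated by parameter recovery against that ground truth rather than
against any particular force field.

## The synthetic landscape

The true PMF is a Gaussian surface well plus an exponential vacuum wall,

    G(r) = −D · exp(−(r − r_w)² / (2 w²)) + exp((r − r_v) / s),

with defaults D = 5 kJ/mol, r_w = 2.05 nm, w = 0.15 nm, r_v = 2.6 nm,
s = 0.1 nm. This reproduces the qualitative shape of a surface-propensity
PMF: flat in bulk (small r), a minimum just below the Gibbs dividing
surface, and a steep rise as the solute detaches into vacuum. G(1.0 nm) ≈ 0
by construction, so the conventional bulk reference at r = 1.0 nm is exact.

Per-frame interaction energies (water–water, solute–water, solute–solute)
have means amp_X · S(r) with a logistic switch
S(r) = 1/(1 + exp(−(r − 2.0)/0.15)), so all components vanish at the bulk
reference, plus independent Gaussian noise (default sd 5 kJ/mol per
component and frame). Defaults amp_ww = −20, amp_aaw = +15, amp_aaaa = −2
kJ/mol give a decomposition with partially cancelling terms of realistic
magnitude. The implied entropy term −TΔS(r) = G(r) − ΔH(r) holds as an
identity, which is what the decomposition-recovery tests exploit.

Real MD energies are strongly autocorrelated and correlated across
components; the generator draws them independently. This is sufficient for
mean-recovery tests (the estimators only use means and standard errors) but
means the quoted standard errors would be optimistic on real trajectories.

## Sampling

Windows are sampled with Euler–Maruyama overdamped Langevin dynamics on
U(r) = G(r) + ½k(r − r₀)² with reflecting boundaries at the domain edges
(defaults: T = 300 K with k_B = 0.0083144621 kJ/mol/K, D = 0.001 nm²/ps,
dt = 0.01 ps, domain [0.8, 3.2] nm). Only the stationary distribution
matters for PMF recovery, so a Brownian integrator is an adequate stand-in
for a thermostatted MD integrator. A construction-time grid scan enforces
the drift-step stability criterion D·dt·|U′|/k_BT < 0.1 over the whole
domain, including the bias; unstable configurations are rejected rather
than silently integrated.

Stored frames are every 100th step by default. This matters: the restrained
relaxation time at the default spring constant (1000 kJ/mol/nm²) is
k_BT/(D·k) ≈ 250 steps, and the downstream WHAM weights every stored frame
once with no autocorrelation correction. Storing every ~half relaxation
time keeps stored frames approximately independent, so the estimator's
independence assumption actually holds for the data fed to it. With heavily
correlated frames (e.g. storage every 10 steps) the window free energies
acquire a ladder random walk of several tenths of kJ/mol at 2×10⁵ frames
per window — a variance, not a bias, but large enough to defeat
parameter-recovery checks at the 0.3 kJ/mol level.

Each window derives its seed deterministically from the master seed
(master + window index), and identical seeds give bitwise-identical
trajectories.

## WHAM

The estimator solves the standard self-consistent equations over equal-width
bins spanning the observed sample range (default 41 bins, mirroring the
published protocol):

    P_j = Σ_i n_ij / Σ_i N_i exp[(f_i − c_ij)/k_BT],
    f_i = −k_BT ln Σ_j P_j exp(−c_ij/k_BT),

with the harmonic bias c_ij evaluated at bin centers. Iteration is in log
space (log-sum-exp) for stability; the gauge is fixed by pinning f of the
first window, and convergence is declared when max_i |Δf_i| falls below the
tolerance (default 1e-6 kJ/mol, max 10⁵ sweeps). Empty bins are flagged
undefined, never interpolated; referencing (`set_reference`) pins the bin
containing the reference coordinate to exactly zero. With a single
zero-spring window the equations collapse to direct Boltzmann inversion,
which the test suite exploits as a bin-for-bin oracle (agreement to
1e-10 kJ/mol).

No autocorrelation correction is applied (each stored frame counts once);
see the sampling section for why the generator's storage interval makes
that assumption hold. Uncertainty estimation beyond the per-window standard
errors (e.g. block bootstrap) is not implemented.

## Decomposition

ΔH per window is the difference in time-averaged potential energy between
that window and the bulk reference window (the window at r = 1.0 nm), and
−TΔS = ΔG − ΔH with ΔG interpolated linearly from PMF bin centers to window
centers (window spacing, 0.1 nm, is fine relative to PMF curvature).
Standard errors treat frames as independent and combine the two windows in
quadrature; the reference row is identically zero with zero error.

Two bookkeeping identities hold exactly (bitwise) on every emitted record:
ΔG = ΔH + (−TΔS) and ΔH = ΔE_ww + ΔE_aaw + ΔE_aaaa. The first is arranged
by emitting ΔG as the recomputed sum ΔH + (ΔG_interp − ΔH) — an adjustment
of at most one ulp — and the second by defining ΔH as the sum of component
means, with each frame's total energy stored as the exact component sum.
The decomposition CSV is written at 17 significant digits and read back
with correctly-rounded parsing so the identities survive the file round
trip.

Recovery tests compare each recovered component against its *noise-free
window average*, amp_X · mean_t S(r_t), not against the point value
amp_X · S(r_well): the window observable is the restrained ensemble average,
which differs from the point value by restraint smearing and the
bias-induced shift of the mean position (up to ~1 kJ/mol at the default
spring constant) — a property of the observable, not an estimator error.

The surface minimum is the deepest defined bin inside the interphase region
(default [GDS − 0.6, GDS + 0.6] nm, i.e. 1.6–2.8 nm for the default slab),
ties broken toward smaller r, with an "interior" flag distinguishing a true
minimum from a region-edge artifact. A solvent–solvent
enthalpy/entropy-cancellation decomposition is deliberately not
implemented; the plain ΔG = ΔH − TΔS split is the supported analysis.

## Surface structure

* **Density / GDS.** Number-density profiles along z are frame-averaged
  histograms (default bin width 0.05 nm); the bulk density is the mean over
  the central 2 nm around the slab center of mass. The Gibbs dividing
  surface is the half-bulk crossing on the outward flank, linearly
  interpolated between the outermost bin still ≥ half-bulk and its
  neighbor, reported as a distance from the slab center (the reaction
  coordinate convention).
* **Hydrogen bonds.** Geometric criterion: donor–acceptor distance
  ≤ 0.35 nm and angular deviation ≤ 30°. Two vertex conventions are
  supported because the field uses both: deviation from linearity of the
  donor–hydrogen–acceptor angle (vertex at H, the default) or the
  hydrogen–donor–acceptor angle itself (vertex at D). All distances use the
  orthorhombic minimum image. Criteria given in Å in configuration files
  are converted to nm on load.
* **Orientations.** cos θ between a direction vector and the surface
  normal (+z), histogrammed as a probability density over [−1, 1]; an
  isotropic ensemble is flat in cos θ, which the fixtures and tests use.
* **Close pairs.** All intra-residue pairs within a cutoff, optionally
  excluding pairs closer than a bond-count threshold in a supplied bonded
  graph; results are sorted by distance and validated against an O(n²)
  recount.

## Pipeline and protocol constants

One seeded command runs generate → WHAM → decompose → surface → report into
a bundle of CSV/JSON artifacts plus run metadata (config hash, versions,
QC: WHAM residual, window-overlap counts, interior-minimum flag,
reference-bin value). Stages communicate only through files so each can be
rerun independently. The published-protocol constants — 0.1 nm window
spacing, 41 WHAM bins, bulk reference r = 1.0 nm, 3.5 Å / 30° hydrogen-bond
cutoffs — are named defaults; `published_protocol: true` switches to the 41-window
ladder (1.0–5.0 nm). In published-protocol mode the vacuum wall moves from 2.6 to 4.6 nm
(and the Langevin domain widens accordingly) so the wider ladder remains
physically reachable; the well region is unchanged.

The default problem sizes are 21 windows × 2×10⁵ stored frames, chosen so a
full run completes in well under five minutes on one CPU while leaving the
headline recovery checks (PMF RMS < 0.3 kJ/mol over the interphase region,
well depth within 0.3 kJ/mol) with comfortable statistical margin.

## Statistical conventions in the tests

Chi-square goodness-of-fit tests require approximately independent samples;
the Boltzmann-consistency check therefore uses a faster-diffusing
configuration (D = 0.1 nm²/ps on [1.0, 2.75] nm, storage every 1000 steps ≈
three relaxation times) so the stored-frame histogram is a valid multinomial.
The harmonic-variance check instead keeps the default D = 0.001, because the
Euler–Maruyama stationary variance is biased by a factor 1/(1 − θ·dt/2) with
θ = D·k/k_BT, and that bias (0.2% at defaults) must stay well below the 2%
tolerance. Per-bin "3 standard error" profile checks allow the standard
finite-sample exceedance (≥99% of bins within 3σ, all within 5σ) rather than
demanding a simultaneous 3σ band across hundreds of bins.

## Known limitations

* 1D reaction coordinate, harmonic bias, non-periodic coordinate only; no
  MBAR/umbrella-integration variants.
* Component energies are synthetic and uncorrelated; nothing here validates
  force-field-specific energetics, and the package makes no attempt to
  reproduce published per-residue adsorption free energies.
* Standard errors assume independent frames; on correlated real data they
  understate the uncertainty.
* The slab generator produces ideal-gas (Poisson) configurations with a
  tanh mean profile — adequate for density/GDS estimators, with none of the
  layering or capillary-wave structure of real interfaces.
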