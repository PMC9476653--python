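# Methods

`gpwater` implements a machine-learnt force field for flexible water in which
all intramolecular physics comes from Gaussian-process regression (GPR)
models of per-atom properties, and all intermolecular physics from classical
long-range terms: point traceless Cartesian multipoles (up to quadrupole)
whose values are themselves GPR predictions that follow the molecular
geometry, plus a 12-6 Lennard-Jones potential. This note records the model,
the numerical choices, and what the synthetic test bed does and does not
establish.

## The model

**Energy decomposition.** The potential energy of a box of water is

```
U = sum_molecules sum_atoms E_A(f)  +  U_multipole({r, Q(r)})  +  U_LJ
```

`E_A(f)` is the GPR-predicted energy share of atom A, a function of the
monomer's internal-coordinate feature vector `f` (below). The model boundary
is the molecule (monomeric modelling): every intramolecular interaction is
inside the GPR term, so no bond/angle force-field terms and no intramolecular
electrostatics exist; every intermolecular interaction is multipolar
electrostatics plus Lennard-Jones.

**Features and frames.** A 3-atom environment has `3N - 6 = 3` internal
coordinates. Each atom's models see `(d(centre, a), d(centre, b),
angle a-centre-b)` with partners ordered oxygen-first: for O that is
`(r_OH1, r_OH2, theta_HOH)`; for a hydrogen, its bonded O-H distance, the
H..H distance and the angle at that hydrogen. Distances are in angstrom,
angles in radians. The feature Jacobian is analytic, so the chain rule gives
exact Cartesian gradients of any predicted quantity. Multipole moments are
learnt in a local right-handed frame per atom (x towards the first partner,
second partner in the x-y half-plane) and rotated to the global frame at
prediction time; the rotation matrix's analytic coordinate derivative enters
the force chain rule.

**GPR.** One model per atom per property (energy; charge; 3 local dipole
components; 5 independent traceless-quadrupole components). Kernel:
squared-exponential with per-feature lengthscales (Matern-5/2 available).
Hyperparameters maximise the log marginal likelihood (L-BFGS in log space,
analytic gradients, 5 seeded restarts, tolerance 1e-8). Lengthscales are
bounded to [0.05, 20] times the per-feature data spread and the signal
variance to 50x the target variance: unbounded maximisation on very smooth
targets runs to enormous signal variances whose dual weights put the
predictions at the mercy of round-off. Zero noise (exact interpolation) is
the default, with a jitter escalated from 1e-12 only as far as the Cholesky
factorisation requires.

**Training sets.** The compact-training protocol selects 100 points: 50
uniformly at random (seeded), then 50 one at a time, each the pool point
with maximum posterior variance under the current model (ties broken by
lowest index), refitting dual weights after every addition and re-optimising
hyperparameters every 10 additions and at the end. Moment models in the
bundled training helper use a plain random subset of the same size; at the
surrogate's smoothness both protocols reach far sub-kJ/mol accuracy, and the
active protocol is exercised where the benchmark demands it.

**Electrostatics.** Sites carry charge `q`, dipole `mu` and traceless
quadrupole `Theta` (convention `Theta = 1/2 sum q (3rr - r^2 I)`, quadrupole
contraction prefactor 1/3). Everything is built from per-site potential
derivatives `P0..P3 = phi, grad phi, grad^2 phi, grad^3 phi`: the energy is
`1/2 sum_i [q P0 + mu.P1 + (1/3) Theta:P2]`, the fixed-moment force is
`-[q P1 + mu.P2 + (1/3) Theta:P3]`, and the moment derivatives `dE/dq = P0`,
`dE/dmu = P1`, `dE/dTheta = P2/3` feed the flexible-moment force terms
`-(dE/dQ)(dQ/dr)` that arise because the moments are functions of the
molecular geometry. Interaction tensors up to rank 5 come from the pairing
expansion `grad^n g = sum_m D_{n-m} Sym[delta^m u^(n-2m)]` with
`D_n = (1/r d/dr)^n g`, which serves the bare kernel (`1/r`, open boundary),
the Ewald real-space kernel (`erfc(alpha r)/r`), the exclusion/self kernel
(`erf(alpha r)/r`, with its analytic `r -> 0` series for the self terms) with
one code path.

Periodic systems use plain (non-mesh) Ewald summation in a cubic box —
identical physics to mesh Ewald at desk scale — with parameters chosen from
a precision target: `alpha = sqrt(-ln eps)/r_cut`,
`kmax = 2 alpha sqrt(-ln eps) (1 + 0.15 L')`. The L'-dependent margin covers
the `k^2`/`k^4` factors that dipole and quadrupole structure factors put in
front of the Gaussian tail; without it the reciprocal sum meets the target
only for charges. The surface term uses the tin-foil convention by default
(what the dipole-fluctuation permittivity formula assumes); a vacuum
(`epsilon = 1`) boundary is available and is used when comparing a periodic
box against an isolated cluster. Intramolecular pairs are excluded
exactly. Predicted charges are shifted by the per-molecule mean (a smooth,
symmetric correction of order of the model's charge error) so each molecule
is exactly neutral, as the Ewald neutrality check requires.

Truncation `L'` enables all pair interactions between moments of rank
<= L': 0 = charges only, 1 = +dipoles, 2 = +quadrupoles
(quadrupole-quadrupole included). Simulations default to L' = 2.

**Lennard-Jones.** 12-6 on intermolecular O-O and O-H pairs only (H-H
carries no term), with the liquid-water parameter set
(eps_OO = 0.763 kJ/mol, sigma_OO = 3.17 A, eps_OH = 0.106 kJ/mol,
sigma_OH = 1.902 A). The potential is cut-and-shifted at the cutoff by
default: at desk-scale cutoffs (4-6 A) a plainly truncated LJ leaves an
energy discontinuity of order 0.1 kJ/mol per crossing, which alone would
dominate the NVE drift budget; the shift removes it at the cost of a
constant offset in the pair energy. Plain truncation remains available
(`shift=False`). No long-range tail correction is applied.

## Dynamics

Velocity Verlet with a 1 fs default timestep. NVT uses Nose-Hoover chains
(length 3, coupling time 0.1 ps); NPT adds isotropic Martyna-Tobias-Klein
cell dynamics (barostat time 1.0 ps, cell momentum thermostatted by the
first chain element, `sinh(x)/x` factors in the position/velocity updates).
Each ensemble tracks its conserved quantity. The instantaneous pressure uses
a central-difference virial `W = -3V dU/dV` obtained by rescaling all atomic
coordinates with the box (exact for every term, including reciprocal-space
electrostatics, at the cost of two extra energy evaluations — accepted
because NPT is used for toy validation, not production, here). Initial
velocities are Maxwell-Boltzmann with the centre-of-mass drift removed; an
optional velocity-scale factor reproduces the replica-decorrelation trick of
scaling initial velocities. Positions are kept unwrapped (molecules stay
whole; minimum image is applied inside force evaluations), which is also
what the mean-squared-displacement analysis requires.

Energy drift is measured as the least-squares slope of the conserved
quantity against time: velocity Verlet at `omega dt ~ 0.7` (O-H stretch at
1 fs) shows a bounded O(dt^2) energy oscillation that is not drift, and the
slope separates the two. The oscillation amplitude is the quantity checked
for O(dt^2) scaling.

## Bulk-property estimators

* **RDF** — shell-normalised histogram, minimum image; intramolecular pairs
  included by default (matching how simulated RDFs are usually compared to
  scattering data), with an exclusion flag.
* **Diffusion** — Einstein relation, least-squares slope of the
  centre-of-mass MSD over a configurable lag window, divided by 6; a
  two-half-window slope-ratio diagnostic flags ballistic or arrested motion;
  wrapped input (jumps > L/2) is rejected. Finite-size correction
  `D_inf = D(L) + kB T xi/(6 pi eta L)` with `xi = 2.837297` (reproduced
  independently by an Ewald lattice summation of the cubic periodic
  self-interaction) and tabulated experimental viscosity.
* **Density maximum / thermal expansion** — cubic least-squares fit of
  rho(T) or V(T), analytically differentiated; an interior maximum is
  reported only if the derivative root lies inside the data range with the
  right curvature, otherwise a "none" diagnostic (never a silent
  extrapolation). `alpha = (dV/dT)/V_fit` may be negative.
* **Vaporisation enthalpy** — per-molecule `H_gas - H_liq` on a shared
  temperature grid; the gas phase comes from isolated-monomer runs, the
  ideal-gas `pV = kB T` and the liquid `PV/N` bookkeeping are the caller's
  convention and documented at the call sites.
* **Heat capacity** — derivative of a quadratic fit of H_liq(T).
* **IR spectrum** — FFT autocorrelation of the total system dipole
  (unbiased, mean-removed, unwindowed by default with a Hann option),
  discrete Fourier transform, multiplied by a quantum correction factor
  (harmonic `x/(1-e^-x)` default; "standard" and Schofield variants
  implemented since the choice is known to matter little), normalised to a
  unit maximum. Total dipole `M = sum q r + sum mu` is logged every step
  for this purpose.
* **Permittivity** — fluctuation formula
  `eps_r = 1 + 4 pi ke (<M^2> - <M>^2)/(3 V kB T)`, reported both with and
  without the `<M>` subtraction; short series carry a warning in the result
  metadata. Assumes tin-foil Ewald boundaries, which is the simulation
  default.
* **Uncertainties** — leave-one-out RMS shift of the ensemble mean; plus
  the RMS deviation between an ensemble-average estimate and per-box values
  (the convention used for diffusion).

## Dimer probe

Close dimers (O-O <= 3.5 A, inclusive, minimum image) are parameterised by
12 coordinates: two bonds + angle per molecule, spherical polars of the
second oxygen in the first molecule's O-centred local frame, and ZYZ Euler
angles (gimbal limit resolved by setting the third angle to zero) for the
second molecule's orientation; the lower molecule index owns the frame. The
reconstruction is exact up to rigid motion (RMSD < 1e-8 A verified).
Representative sets are drawn by bootstrapping each of the 12 marginals
independently; since independent marginals can compose invalid joints, any
sample with an intermolecular pair closer than 1.2 A is rejected and
redrawn (counted and reported). The electrostatic error of a dimer is the
sum over the nine intermolecular atom pairs of |E_pair(reference) -
E_pair(predicted)| at L' = 0, 1, 2, with reference moments computed
monomer-wise (each molecule in isolation) — the correct comparison for
monomeric models, which contain no intermolecular polarisation.

## The synthetic oracle

The oracle stands in for the quantum-chemistry pipeline (wavefunction +
atomic-basin partitioning) that labels training geometries in production
use. Its constants are non-physical stand-ins on water-like scales, fixed in
one config block:

* **PES** — two Morse bonds (D_e = 450 kJ/mol, a = 2.2 1/A, r0 = 0.96 A), a
  harmonic bend (k = 300 kJ/mol/rad^2 about 104.5 deg), bond-bond (30
  kJ/mol/A^2) and bond-angle (-20 kJ/mol/(A rad)) couplings, offset -250
  kJ/mol. The minimum is exactly at (r0, r0, 104.5 deg). Per-atom shares use
  fixed fractions plus a smooth geometry-dependent O<->H transfer term that
  sums to zero, so the shares reproduce the molecular total identically;
  since nothing downstream consumes the partition itself, any smooth
  partition is equally valid.
* **Moments** — an explicit auxiliary point-charge construction:
  geometry-dependent site charges (oxygen carries the exact negative sum of
  the hydrogens') plus one satellite charge pair per atom at fixed
  local-frame positions with geometry-dependent strength. Atomic dipole and
  traceless quadrupole are the exact moments of the atom's satellites, so
  electroneutrality and tracelessness are identities, moments transform
  covariantly by construction, and the molecular dipole equals the dipole of
  the explicit array (a brute-force cross-check). One overall charge scale
  is calibrated once so the equilibrium molecular dipole is exactly 2.15 D,
  emulating a monomer pre-polarised by an implicit solvent.
* **Sampling** — independent truncated normals in the three internal
  coordinates (not normal modes; only the coverage envelope matters). At the
  default spread, bonds cover ~0.90-1.10 A (mean 1.00, sd 0.035) and the
  angle ~95-115 deg (mean 105 deg, sd 3.5 deg) — a liquid-like envelope with
  bonds stretched relative to the gas-phase minimum; the magnitudes are this
  package's choice of a realistic liquid-water distortion range, not a
  measured distribution. Spread 0 collapses to the equilibrium geometry.

**What passing tests show.** The oracle is smooth, low-dimensional and
noise-free, so GPR accuracies here (max held-out energy errors ~1e-4 kJ/mol
with 100 training points) are far better than models trained on real
quantum-chemistry labels, where sub-kJ/mol maximum errors are the realistic
outcome; tests against the oracle validate the machinery (features,
gradients, electrostatics, dynamics, estimators), not the attainable
chemical accuracy. Likewise the desk-scale simulations (8-64 molecules,
picoseconds) validate conservation, thermostats and estimator plumbing; they
are far too small and short for converged liquid properties, so no bulk
number from them should be read as a prediction.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale defaults: 8-molecule boxes (9 A, 4 A
cutoff, Ewald precision 1e-6) for conservation and FD checks, 10 ps NVE for
the drift bound, ~3 ps NVT for temperature sampling, a 32-particle LJ fluid
for the decoupled barostat check, 600-geometry pools for the model
benchmark, and 100-dimer samples for the probe. Larger boxes (216+) are
supported through the same interfaces.

## Known limitations

* Monomeric modelling only: no intermolecular polarisation beyond what the
  oracle's implicit-solvent-style dipole calibration bakes in; dimeric or
  N-meric model boundaries are out of scope.
* Multipoles stop at quadrupole (L' = 2); no octupole/hexadecapole
  interaction scheme.
* No nuclear quantum effects; the IR quantum correction factors adjust the
  lineshape, not the dynamics.
* Plain Ewald scales as O(N^(3/2))-ish at desk scale; no mesh acceleration
  or parallel decomposition.
* The NPT virial is numerical (two extra energy evaluations per step).
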