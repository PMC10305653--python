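# Methods

Units are fixed package-wide: Å for lengths, kcal/mol for energies,
elementary charges, amu, K, ns.  Atom and residue indices are 0-based
internally; PDB serial numbers are mapped on I/O.

## Data model and trajectory assembly

A `Topology` is an ordered atom list carrying the per-atom physics the
energy terms consume — partial charge, Lennard-Jones r_min/2 and ε,
intrinsic Born radius, HCT screening factor, mass — plus residue, segment
(receptor/ligand), region (backbone/sidechain/ligand) and hydrogen-bond
role annotations.  It travels as a JSON sidecar next to the structure:
deriving these quantities from real force-field files is a non-goal, which
keeps the package self-contained and every input auditable.  The protein
backbone set is {N, H, CA, HA, C, O}; everything else is sidechain, the
convention under which published sidechain/backbone decomposition tables
are produced.

Coordinate ensembles are lists of replicas (frames + times).  Analyses act
on the *merged trajectory*: the frames of every replica with time ≥ that
replica's burn-in threshold, concatenated in replica order.  Burn-in
defaults to half of each replica — typical practice when production runs
double the observed equilibration time — and is configurable per replica
because equilibration points are system-specific and cannot be derived
from the data model.

Structures are read and written as (multi-model) PDB via biotite; reading
compressed binary trajectory formats is out of scope for this version —
any ensemble must be converted to multi-model PDB first.

## Structural statistics

Superposition is the Kabsch SVD solution, mass-unweighted over the fit
selection (the common trajectory-analysis convention), with the reflection
branch removed so the rotation is always proper.  RMSD uses separate fit
and measure selections, so pocket RMSD fits on the backbone and measures
on pocket heavy atoms.  Pocket membership — receptor residues with at
least one heavy atom within the cutoff (default 7 Å) of the ligand mass
center — is decided once in the reference frame and frozen; a per-frame
pocket would make the series discontinuous.  RMSF is computed about the
ensemble-average structure after a two-pass fit (fit to the first frame,
average, refit to the average).  Distribution peak detection smooths the
normalized histogram with a Gaussian kernel of one bin width before taking
local maxima, which stabilizes two-peak reporting on noisy bimodal series.

## Collective dynamics

PCA diagonalizes the mass-unweighted 3N×3N covariance of the superposed
Cα coordinates.  The DCCM normalizes the displacement inner products to
[−1, 1]; atoms with zero variance get zero off-diagonal entries and are
flagged rather than producing NaNs.  Superposition is applied internally
(it can be disabled for pre-aligned frames).  Note that removing the six
rigid-body degrees of freedom induces a small systematic anti-correlation
of order 1/N between otherwise independent atoms, and absorbs the
rigid-body share of any planted direction — planted modes used for
validation are therefore projected onto the internal-motion subspace
(`internal_mode_direction`).

The free-energy landscape bins the first two principal projections
(default 60×60 over the data range padded 5%) and sets
F = −k_B T ln(P/P_max) at the simulation temperature (default 300 K), so
the occupied minimum is exactly zero and empty bins are masked.  Valleys
are found by persistence watershed: occupied bins are flooded in order of
increasing F; when a basin first touches a deeper one, its persistence is
the merge level minus its bottom, and basins with persistence below
`depth_cut` (default 0.5 kcal/mol) are merged away.  This makes the valley
count non-increasing in `depth_cut` and reproduces the textbook
calibration that two point clusters with population ratio e are separated
by exactly k_B T.  Each surviving valley reports its bottom free energy,
persistence, member frames and the member frame nearest the bottom-bin
center as representative.  Isolated occupied bins form basins that never
touch a neighbor and thus can never be merged; on sparsely sampled
landscapes the `min_frames` filter (pipeline default: 2% of frames) is the
effective guard against such spurious substates.

## Binding energetics

All binding quantities use the single-trajectory end-point protocol:
complex, receptor and ligand conformations share frames, so internal
energies cancel — ΔE_ele and ΔE_vdW are pure receptor–ligand cross terms
(Coulomb with k = 332.0636 kcal·Å/(mol·e²); 12-6 Lennard-Jones with
Lorentz–Berthelot combination) and the solvation terms are
complex − receptor − ligand differences per frame.  Snapshots are an
evenly spaced subsample of the merged trajectory; component means carry
standard errors over snapshots.

Effective Born radii subtract the 0.09 Å dielectric offset from the
intrinsic radii and support four backends: the HCT pairwise-descreening
integral; OBC-I and OBC-II, which pass the same integral through the tanh
rescaling with (α, β, γ) = (0.8, 0, 2.909125) and (1.0, 0.8, 4.85); and a
numerical R6 backend that integrates |r − r_i|⁻⁶ over the union-of-spheres
volume on a cubic grid (0.45 Å spacing, sized for toy systems of a few
hundred atoms).  The GB energy uses the canonical interpolation
f_GB = [r² + R_i R_j exp(−r²/(4 R_i R_j))]^½ with ε_in = 1 and
ε_out = 78.5 (the standard continuum-water convention; the study the
package reproduces does not state its dielectrics).  Radii are recomputed
per scope, since descreening differs between the complex and the isolated
partners.  The four GB model presets pair these backends with the surface
coefficients γ = 0.0072 (GB1) or 0.005 (GB2/GB5/GB66) kcal/mol/Å² and
β = 0, and with the mbondi/mbondi2/bondi radii families; in this package
the intrinsic radii live on the topology, so the radii-set label is
metadata rather than a lookup.

SASA is Shrake–Rupley quadrature on deterministic golden-spiral points
(default 240 per atom; 960 recovers an isolated sphere to <1%), over
spheres of intrinsic radius + probe (default 1.4 Å).  The same intrinsic
radii feed the GB and SASA terms; the SIE route instead uses ρ-scaled
Lennard-Jones radii for both its reaction-field surrogate and its surface
term, following that method's ρ convention.

The SIE composition is linear in its four components, so it is exact
whenever the components are supplied (that is how the published tables are
reproduced).  When components are derived from an ensemble, two documented
surrogates apply: the reaction-field term ΔG_R is computed with the GB
model at interior dielectric D_in = 2.25 on ρ-scaled radii instead of a
boundary-element Poisson solver, and ΔMSA uses solvent-accessible rather
than molecular (Connolly) surface area.  Both preserve the signs and
qualitative behavior (desolvation penalty upon binding) but not the
calibration of the original solver, so trajectory-derived SIE scores from
this package are comparative, not absolute.  The entropy term −TΔS of the
MM-GBSA composition is an external input (normal-mode analysis is out of
scope).

Per-residue decomposition attributes the cross terms to each receptor
residue in full (they are strictly pairwise), splits every GB pair term
half to each partner atom with self-terms kept on their own atom, and
assigns per-atom SASA differences times γ.  Each term is split by the
backbone/sidechain region flag, so T = S + B holds identically and the
residue sums reproduce the complex totals to rounding; a trailing LIG row
carries the ligand-side GB/surface attribution so column sums conserve.

Experimental affinities convert as ΔG = RT ln Ki (R = 1.98720425×10⁻³
kcal/(mol·K)) at 298.15 K — the temperature under which the published 1 nM
and 45 nM entries round to −12.3 and −10.0 kcal/mol.  A consistency flag
compares a reported ΔG against the conversion (tolerance 0.2 kcal/mol);
the published 60X entry (−11.4 at Ki = 48 nM) fails it and is excluded
from quantitative checks.

## Hydrogen bonds

A candidate is every (donor, bonded hydrogen, acceptor) triple in scope
(receptor–ligand keeps cross-segment pairs only).  A bond exists in a
frame iff the acceptor···donor distance is strictly below 3.5 Å and the
angle at the hydrogen between the H→D and H→A vectors strictly exceeds
120° — the near-linear D–H···A reading of the standard criteria.  Mean
distance and angle are averaged over present frames only; occupancy is the
percentage of frames in which the bond exists.

## Synthetic ensembles

`make_toy_complex` builds a helical receptor (2.3 Å radius, 1.5 Å rise,
100°/residue) with N/CA/C/O plus radially extending sidechain beads, and a
ring ligand (C/N/O cycle plus one polar hydrogen on the first ring
nitrogen) standing 2.8 Å off the sidechain tips — far enough that Gaussian
sampling does not cross the Lennard-Jones repulsive wall, close enough
that at least three residues fall inside the 7 Å pocket.  Charges, LJ
parameters, Born radii and screening factors come from fixed element-keyed
palettes; the backbone palette sums to zero per residue so toy receptors
stay near-neutral, as real proteins are.  Every third/fourth residue
(SER/THR-like) carries a hydroxyl donor pair when enough beads are
available; backbone and ligand oxygens are acceptors.

`simulate_ensemble` draws frames as reference + Gaussian displacements:
per-residue isotropic σ (default 0.5 Å), damped by `pocket_damping` for
pocket residues in the bound variant; signed correlated blocks replace a
fraction `strength` of the variance with a shared latent 3-vector, giving
DCCM entries of exactly sign×strength in expectation (blocks must not
overlap, which would break positive-definiteness); planted modes add
amplitude²·uuᵀ.  Non-Cα receptor atoms ride with their residue's Cα plus
0.2σ local jitter; ligand atoms get 0.15σ.  Every frame receives a random
rigid-body rotation (0.2 rad) and translation (2 Å) so superposition is
always exercised.  Sampling is Gaussian, not dynamical — the analyses
consume ensembles, not kinetics; an AR(1) time-correlation option
(`ou_tau`) exists and is off by default.  All outputs are bit-reproducible
under a fixed seed.

What the generator does *not* emulate: anharmonicity, conformational
transitions with barriers, excluded volume, explicit solvent, and realistic
force-field couplings.  Passing tests therefore certify the estimators and
kernels — parameter recovery, conservation laws, closed forms — not the
ability to reproduce trajectory-scale magnitudes of a real 400-residue
protease, which would require microsecond simulations far outside a test
suite.  The published component tables are used as inputs where absolute
published energetics are asserted.

## Pipeline and problem sizes

`run_study` isolates stage failures per system (recorded in
`manifest.json`, other stages proceed) and hashes the configuration for
reproducibility audits.  The bundled `demo` builds four systems — apo with
three planted conformational clusters and a strong anti-correlated block,
three bound variants with damped pockets, weakened blocks and two or three
clusters — at 30 residues, 2–3 replicas × 150 frames (60 in `--fast`
mode), 16 energy snapshots and 120 SASA points per atom; this completes in
well under a minute on one CPU while exhibiting every qualitative
signature the analyses are designed to detect (reduced pocket RMSD,
weakened anti-correlations, fewer substates upon binding).

## Known limitations

- The GB surrogate for the SIE reaction field and the SASA-for-MSA
  substitution change absolute trajectory-derived SIE values; composition
  from externally computed components is exact.
- The numerical R6 backend is quadrature-limited (≲2000 atoms) and
  intended for validation, not production.
- DCD/XTC readers, DSSP secondary structure, normal-mode entropy and
  Poisson–Boltzmann solvers are deliberately out of scope.
- Persistence-based valley detection needs adequately sampled landscapes;
  isolated occupied bins are controlled only by the `min_frames` filter.
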