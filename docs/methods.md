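# Methods

This note documents the models, conventions and numerical choices behind
fepkit, and what its validation does and does not demonstrate.

## Staged transformation plans

A transformation is described by a `FragmentGraph`: a connected bond graph of
atoms with partial charges and force-field-style charge-group labels,
anchored at the attachment atom (Cα for sidechains, the ring-attachment atom
for ligand fragments).  Group membership is taken from the input labels —
the tool does not infer charge groups, since in practice they come from
topology files.  Hydrogens with an empty group label inherit the group of
their bonded heavy atom.  Each group's net charge must be an integer within
1e-6 e (configurable off) so that decharging a group never leaves a
fractional net charge behind.

Annihilation proceeds group by group in order of decreasing maximum
topological (bond-count) distance from the anchor; ties are broken by
decreasing mean distance and then by ascending group label.  The tie rules
are fepkit's own — they exist purely so that identical inputs always produce
byte-identical plans.  For each removed group the plan emits decharge →
softcore → annihilate steps (strictly sequential per group), and one final
recharge step restores the partial charges of the whole end-state species in
a single stage; a per-group recharge would be equally defensible, but a
single step keeps plans shorter and the bookkeeping simpler.  λ runs 0 → 1
in the direction of annihilation, so "forward" always means initial →
target.  Every stage carries a uniform λ schedule: 21 windows per stage for
sidechain plans and 51 for ligand plans by default.

A mutation is specified as WT fragment → target fragment, where the target
must map into the WT atoms (subfragment by atom id, or an explicit
common-fragment mapping).  A group is annihilated when none of its atoms
survives into the target.  The embedded sidechain templates for the 20
standard residues use schematic neutral-group partial charges, not values
from any published force field: only the graph topology, group membership
and integer group charges matter to the planner.  The alanine common
fragment lists only the atoms shared with every other sidechain (CA, CB,
HB1); the remaining β-hydrogens of the real end state appear implicitly with
the recharge stage.  The proline template omits the CD–N ring closure, since
the backbone nitrogen lies outside the sidechain fragment.

## Estimators

`zwanzig_window` implements exponential averaging,
ΔG = −kT·ln⟨exp(−ΔU/kT)⟩, with a log-sum-exp guard; no clipping or
subsampling of large |ΔU| is applied.  The gas constant is fixed at
R = 1.987204259·10⁻³ kcal/(mol·K), default temperature 298 K.

Per replica, the forward free energy is the EXP sum over forward window
samples and the backward free energy the EXP sum for the reverse path, so a
converged pair satisfies ΔG_fwd ≈ −ΔG_bwd.  The reported replica value is
the antisymmetrized mean (ΔG_fwd − ΔG_bwd)/2, which cancels the
leading-order EXP bias of the two directions; both one-directional estimates
are also reported.  Hysteresis is defined per leg as |ΔG_fwd + ΔG_bwd| and
averaged over replicas — a per-window hysteresis table can be derived from
the same data, but the leg-level number is the convergence diagnostic used
throughout.  The s.e.m. uses the sample standard deviation (n−1) over
replicas divided by √n, and is 0 for a single replica.

`bar_window` solves the Bennett acceptance-ratio self-consistency equation
by bracketing and Brent root finding (default tolerance 1e-8 kcal/mol).  It
exists as an independent cross-check of the Zwanzig route in the tests, not
as the production estimator.

## Thermodynamic cycles

Legs combine by simple differences with fixed sign conventions, recorded in
each result's interpretation string: ΔΔG = ΔG_bound − ΔG_solvent for ligand
perturbations, ΔG_complex − ΔG_apo for mutations (positive = mutant binds
worse), ΔΔG_active − ΔΔG_inactive for conformational selectivity (positive =
the unperturbed ligand prefers the active conformation).  Non-alanine
mutations join two reduction cycles: ΔΔG(WT→Mut) = ΔΔG(WT→common) −
ΔΔG(Mut→common).  Errors propagate in quadrature of the replica s.e.m.
values; the underlying replicas of different legs are independent, so
quadrature is exact for the variance of the difference.  Affinity
conversions use ΔΔG = RT·ln(K_D ratio) at a default 298.15 K.
`cycle_closure` checks that the signed ΔG sum around any declared loop
vanishes within statistical error.

## The analytic sampler

Metropolis Monte Carlo replaces MD: the estimators consume ensemble averages
of ΔU, which are sampler-agnostic, and MC sampling of analytic potentials is
exact and fast at desk scale.  Supported families are harmonic wells (the
main validation system — ΔG = Σ_dims (kT/2)·ln(k_B/k_A), a closed form
independent of the well centers), 1-D double wells, and a soft-core pair
potential U = 4ε(1−λ)[(αλ + (r/σ)⁶)⁻² − (αλ + (r/σ)⁶)⁻¹], the common
α-shifted-r⁶ form, which reduces to Lennard-Jones at λ = 0, vanishes at
λ = 1, and stays finite at r = 0 for αλ > 0.

Endpoints couple either linearly in energy or by parameter interpolation
("staged"); both agree on harmonic systems within statistical error, which
the tests verify.  Each window runs a fixed number of Metropolis steps
(default 10 000, matching the per-window protocol size), discards a 10 %
burn-in, and starts from the previous window's endpoint, mirroring the
sequential λ protocol.  The per-window equilibration/collection split is
exposed as `burn_in_fraction` since no single convention is canonical.
Replica r uses seed + r, so fixtures are bit-reproducible.  The default
step size of 1 Å gives ~50–70 % acceptance for the validation systems.
Constant-temperature sampling only; no warm-up ramp is emulated.  1-D
harmonic endpoint pairs take a specialized scalar code path (the coupled
Hamiltonian stays quadratic), which is ~20× faster than the generic
callable path; both paths are exact.

The Gaussian fixture generator draws forward ΔU ~ N(μ, σ²), for which EXP
has the closed form ΔG = μ − σ²/(2kT); backward samples are drawn as
N(σ²/kT − μ, σ²) so both directions share the same true ΔG.

## Hydration mapping

Occupancy is binary per frame: the fraction of frames in which at least one
water oxygen falls inside the half-open 1 Å voxel.  An averaged-density
metric (as volumetric tools often report) is a noted alternative; the
frame-fraction reading is implemented because an "80 % occupancy" threshold
is most naturally a fraction of simulation time, and the metric is recorded
in the DX output header.  Only water oxygens are counted; replica
trajectories are pooled frame-wise before binning; no kernel smoothing is
applied.  The grid origin snaps down to integer Å of the region's lower
corner; spherical regions mask voxels whose centers fall outside.  Sites are
26-connected components of above-threshold voxels, positioned at the
occupancy-weighted centroid, sorted by descending peak occupancy with
centroid-lexicographic tie-break.

The synthetic trajectory generator plants tethered waters with a presence
probability and isotropic Gaussian jitter; a site's jitter σ is the total
3-D RMS displacement (per-axis σ/√3), the RMSF convention for a tethered
atom.  With the per-axis convention a 0.3 Å jitter would spread ~26 % of the
density outside a 1 Å voxel even when centered, making an 80 % single-voxel
occupancy unreachable — a useful reminder that voxel occupancy convolves
positional spread with grid placement.  What passing tests show is that the
binning, clustering and centroid bookkeeping are exact (verified against a
brute-force recount) and that well-localized waters are recovered without
false positives at low bulk density; they say nothing about force-field or
sampling realism of real MD water distributions.

## Pipeline and determinism

The manifest-driven pipeline realizes legs from Gaussian fixtures, the MC
sampler, or energy CSVs, combines them into cycles, and writes a results
JSON plus a comparison table (label, ΔΔG in vitro, ΔΔG in silico, s.e.m.,
flag, with `ND` for missing experimental values and a detection-threshold
flag for lower-bound experiments).  All randomness derives deterministically
from the run seed (per-cycle and per-leg offsets), so reruns with the same
seed are byte-identical.  Energies are serialized in kcal/mol, temperatures
in K, coordinates in Å, with unit strings embedded in the JSON outputs.

## Validation scope and problem sizes

The validation suite runs the full protocol shape (21 windows × 10 000 MC
steps × 10 replicas) on 1-D harmonic systems, where the exact answer is
known; hysteresis convergence compares 5- vs 21-window schedules over 10
independent runs; pipeline bookkeeping is validated by planting per-leg
truths and recovering the combined ΔΔG within 3 s.e.m.  These checks
demonstrate correctness of the estimators and bookkeeping, not the accuracy
of any force field or the adequacy of MD sampling for real receptor–ligand
systems, which are outside this toolkit's scope.

## Known limitations

* No MBAR across more than two states, no autocorrelation or equilibration
  detection, and no readers for native MD-engine energy formats.
* Charge groups must be supplied; there is no perception of groups from
  geometry or charges.
* The sampler has no explicit solvent, boundary models, or constraints — it
  is a validation harness, not a simulation engine.
* Hydration analysis assumes rectilinear grids and water oxygens only; no
  thermodynamic scoring of sites.
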