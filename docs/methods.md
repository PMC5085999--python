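# Methods

This note records the models, conventions and numerical choices behind
each analysis, what the synthetic generators do and do not emulate, and
the known limitations.

## Structures, trajectories and selections

Structures are read from fixed-column PDB; trajectories from multi-model
PDB (one MODEL per frame) with an optional 2-column CSV of frame times in
ns (default 0, 1, 2, …). Coordinates are Ångström throughout; nothing
downstream converts units. Residue identity is `(chain_id, res_seq)`.
Insertion codes are rejected with an explicit error rather than silently
renumbered; alternate locations are resolved to the highest-occupancy
conformer, ties broken toward altloc `A`. Elements come from PDB columns
77–78 when present, else from the atom name after stripping leading
digits — MD-written PDBs frequently omit the element column. Selections
(chains, residue ranges, atom names, heavy-only, backbone-only with
backbone = N/CA/C/O) resolve to deterministic, topology-ordered index
lists, and a selection that matches nothing is an error: no metric ever
silently operates on an empty atom set.

## Superposition and displacement

Rigid-body alignment is a Kabsch least-squares fit (SVD route) restricted
to proper rotations by determinant correction; point sets with fewer than
three points, or collinear geometry (second singular value below 1e-8 of
the first), are rejected. The fit is computed on a fit selection only —
conventionally the transmembrane-helix backbones — and then applied to
all atoms. The TM residue ranges are a required configuration item
because they depend on the structures being compared; the synthetic
topologies declare their own (`tm_ranges = 80–99, 150–179`).

Per-residue displacement between two conformations is the Euclidean
distance between the residue's heavy-atom centers after alignment. The
"heavy-atom center" is the unweighted geometric mean of non-hydrogen
atom coordinates, not a mass-weighted centroid. Residues present in only
one structure are skipped and reported, never silently dropped.

## Distance and angle metrics

Site centers are unweighted means over named atoms (e.g. the NH1/NH2
center of an arginine). Cross-subunit metrics use an explicit ring order
of chains plus a signed chain offset interpreted cyclically; the package
deliberately does not hard-code whether "the next subunit" is clockwise
or anticlockwise — the adjacency direction is an input, because the two
conventions give different neighbours and published definitions are easy
to mirror. The membrane normal defaults to the +Z axis of the input
frame (the usual convention for membrane-embedded simulation systems)
and is overridable as a 3-vector. Side-chain orientation angles are
arccos of the normalised dot product, reported in degrees on [0, 180]
without folding at 90°: the Ile and Leu orientation distributions have
distinct lobes on both sides of 90° that folding would merge.

## Hydrogen bonds

A hydrogen bond is a (donor heavy atom, hydrogen, acceptor heavy atom)
triple with donor–acceptor distance strictly below 3.5 Å and deviation
from linearity 180° − ∠(D,H,A) strictly below 45°. A literal "D–H–A
angle < 45°" cutoff would be geometrically impossible for a hydrogen
bond (∠DHA ≈ 180°), so the threshold is applied to the deviation, the
common trajectory-analysis convention; the raw ∠DHA is stored on every
detection. Donors are N/O/S heavy atoms with a hydrogen of the same
residue within 1.25 Å (covers N–H, O–H and S–H without capturing
nonbonded contacts); acceptors are all N/O/S heavy atoms; an atom may be
both. Intra-residue bonds are excluded. Counts are per triple, not per
residue pair, so one pair can contribute more than one bond per frame —
this is what makes mean "H-bond numbers" above 1 possible. Detection is
a vectorised distance prefilter over donors × acceptors followed by the
angle test; results are independent of that acceleration and are checked
exactly against exhaustive enumeration in the test suite. Structures
without hydrogens yield an empty donor list with a warning (acceptors
are still reported); the package does not place hydrogens.

## Interaction energy

Ligand–protein interaction energy is pairwise Coulomb plus
Lennard-Jones:

    elec = s(r) · 332.0636 · qᵢqⱼ / r        [kcal/mol, q in e, r in Å]
    vdw  = s(r) · ε_ij · [(rmin_ij/r)¹² − 2(rmin_ij/r)⁶]

with CHARMM combining rules (ε_ij = √(εᵢεⱼ), rmin_ij = rmin_half_i +
rmin_half_j), dielectric fixed at 1, no 1–4 scaling (the groups share no
bonds), and the CHARMM switching polynomial

    s(r) = (r_off²−r²)²(r_off²+2r²−3r_on²)/(r_off²−r_on²)³

between r_on = 10 Å and r_off = 12 Å (1 below, 0 beyond; continuous and
once-differentiable at both knots). Switching is applied to both the
electrostatic and van der Waals terms — one consistent scheme — and can
be disabled in favour of a hard cutoff at r_off. This is a
pair-interaction analysis, not an Ewald decomposition: per-residue
attribution (each pair booked to the protein atom's residue) is exact by
construction, and the numbers are meant for relative comparisons between
systems and sites, not absolute binding free energies. Parameter tables
(res_name, atom_name, charge_e, epsilon_kcal, rmin_half_A) are
user-supplied CSV; a missing parameter is an error naming the atom,
never a silent zero. No force-field parameters are shipped.

## Windowed statistics

The reporting protocol is: time-average each subunit's series over the
analysis window, then mean and sample SD (ddof = 1) across the subunit
averages — four subunits are a sample, not a population. Windows are
inclusive on both ends and select frames by time stamp, not index.
Histograms use fixed bin sizes (15° for orientation angles over
[0°, 180°], giving 12 bins), left-closed/right-open bins with the last
bin closed, frequencies normalised to sum to 1; values outside the range
are clipped into the edge bins and flagged. Two-sample comparisons use
Welch's unequal-variance t test (two-sided, Welch–Satterthwaite degrees
of freedom), delegated to scipy with the degenerate both-constant case
returning p = 1.

## Kinetics

Dose-response curves are fitted with I(c) = I_max·cⁿ/(EC₅₀ⁿ + cⁿ) by
nonlinear least squares (EC₅₀ parameterised on a log scale; tight
xtol/ftol so noiseless data refits to machine precision). The starting
point is the linearly interpolated half-max concentration with n = 1.
Fits require at least 4 points with responses on both sides of half-max;
otherwise EC₅₀ is not identifiable and the fit refuses to run. The Hill
coefficient is free by default and can be fixed. Fitting always uses raw
responses; I/I_max normalisation is display-only.

Half-amplitude times are read directly off the trace — no exponential
fitting — with the crossing linearly interpolated between bracketing
samples. For inhibition (τ_off) the reference amplitude is the mean of
the first three samples, damping single-sample noise at the trace start.
For activation (τ_on) the reference is the steady-state amplitude: on a
finite recording the raw trace maximum systematically underestimates the
plateau while the current is still rising (a 300-s recording of a
τ_on ≈ 58 s channel reaches only ~97% of steady state, which would bias
τ_on early by ~4%), so the plateau is estimated by Aitken Δ²
extrapolation on three equally spaced tail samples — exact for a
single-exponential approach — with a fallback to the observed maximum
when the extrapolation is ill-conditioned (flat or noisy tails).

## Synthetic data

The generators exist to give every analysis a test surface with exact,
planted ground truth:

- `build_tetramer` places four chains C4-symmetrically about Z, each a
  helical path of reduced residues (backbone N/CA/C/O plus only the
  side-chain atoms the metrics touch: Arg NE/NH1/NH2 with guanidinium
  hydrogens, Ile CG1/CG2 and Leu CD1/CD2 with a configurable branch
  orientation angle, Lys NZ/HZ, Thr OG1/HG1, His/Trp/Ser donors,
  Asp/Glu carboxylates, Met SD). The shipped demo topology uses
  Kir2.2-style numbering (E55, D76, R78, W79, R80, K183, R186, K188,
  K189, T193, L219, K220, H222, I/L223, V224, E225, H227, M302, V303,
  E304, M308) with declared TM ranges, the CTD blocks at lower Z than
  the TM blocks so that a shrinking TMD–CTD distance means "upward"
  motion, and ~2,700 atoms. Any two atoms closer than 0.8 Å abort
  generation.
- `simulate_trajectory` builds frames as reference + iid Gaussian jitter
  (no temporal correlation — sufficient for window statistics, not a
  physical model) + planted signals. Drift plans translate the residue
  holding one site along the line toward the other site, which changes
  the distance metric by exactly the planned amount per frame when the
  jitter is zero (linear or sigmoid time profiles, any subset of
  subunits). H-bond schedules place the acceptor atom 3.0 Å from the
  donor along the donor's N/O–H direction on bonded frames (zero
  deviation) and 4.5 Å out otherwise (violating the distance
  criterion), so detection recovers the schedule exactly. Plans that
  would move the same residue twice are an error.
- `gen_dose_response` and `gen_trace` produce Hill curves and
  single-exponential traces, noiseless or with seeded Gaussian noise.
  The off-trace crosses half its initial amplitude at exactly τ½; the
  on-trace crosses half its asymptotic amplitude at exactly τ½.

Passing round-trip tests on these data shows the estimators are correct
on their own generating models; it does not show robustness to the
features of real recordings and trajectories the generators omit
(temporally correlated fluctuations, baseline drift, rundown,
multi-exponential kinetics, real protein geometry).

## Problem sizes and determinism

The shipped analyses run at desk scale: the demo tetramer has ~2,700
atoms (with ligands ~2,710), integration trajectories use 50 frames at
1 ns spacing, dose-response fits use 8–10 concentrations, and traces use
2,401–3,001 samples. Every stochastic generator takes an explicit seed
(numpy `default_rng`), and two runs with identical configuration and
seed produce identical outputs.

## Limitations

- No mmCIF or binary trajectory formats (DCD/XTC), no PSF topologies,
  no periodic-image handling: trajectories are assumed whole and
  unwrapped.
- No secondary-structure assignment or automatic TM-helix detection:
  alignment ranges are inputs.
- The energy model is a switched pairwise approximation with vacuum
  dielectric; it is not comparable in absolute terms to Ewald-based
  simulation energies.
- Hydrogen placement is out of scope; structures intended to donate must
  carry explicit hydrogens.
- Statistical comparisons apply no multiple-testing correction and treat
  window averages as independent samples, ignoring time-series
  autocorrelation.
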