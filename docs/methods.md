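# Methods

This note records the models implemented in `phosbind`, the conventions and
defaults chosen where several were defensible, and what the synthetic-data
tier does and does not establish about real data.

## Structure model

Coordinate files (PDB and mmCIF, parsed with gemmi) are flattened to an
ordered atom list. Only the first model is read; where an atom has
alternate conformers, the one labelled `A` (or blank) is kept — a
deterministic rule adequate for single-conformer analysis of crystal
structures. Author residue numbering is the sole addressing scheme, because
binding-site residues are conventionally cited that way (Y208, H160, W52).
Elements come from the element column when present, otherwise from the
atom-name prefix with a two-letter-element table; deuterium is treated as
hydrogen; waters are retained but flagged. No symmetry expansion, bond
perception or chemical-component-dictionary lookup is attempted.

## Hydrogen placement on phosphorus oxyanions

Crystallographic models of phosphite and hypophosphite complexes do not
include the P–H hydrogens, yet those hydrogens carry the interaction of
interest, so they are modelled geometrically at a P–H bond length of
1.42 Å (the standard phosphine/phosphonate value):

- **Phosphite (P + 3 O):** one hydrogen along −Σ unit(P→Oᵢ), normalised —
  the direction completing the tetrahedron. For ideal tetrahedral oxygens
  this reproduces 109.47° to every P–O bond exactly.
- **Hypophosphite (P + 2 O):** two hydrogens in the plane through P spanned
  by the negated O–P–O bisector and the O–P–O plane normal, at half the
  tetrahedral angle either side of the negated bisector. This fixes
  H–P–H = 109.47° exactly and gives 109.47° to each P–O bond when the
  oxygens are ideal.
- **Methylphosphonate (P + 3 O + 1 C):** no P–H; the methyl carbon takes
  the position the phosphite hydrogen would occupy, which is exactly why
  the molecule is sterically disfavoured.

The hydroxyl proton of mono-anionic phosphite is deliberately not placed:
its position is dictated by the hydrogen-bond network, not by P geometry,
and it does not enter the π criterion.

## The P–H…π criterion

For each placed hydrogen and each perceived aromatic ring (PHE/TYR
six-rings, TRP five- and six-rings, HIS five-rings, by canonical atom
names, with a 0.1 Å planarity gate):

- `d` — unsigned perpendicular distance from H to the least-squares ring
  plane; accepted up to 2.9 Å, the Bondi van der Waals sum for hydrogen
  (1.20 Å) over aromatic carbon (1.70 Å). A contact at d ≈ 2.6 Å is well
  inside the vdW sum.
- centroid offset — in-plane distance of H's projection from the ring
  centroid; accepted up to 1.6 Å, keeping the hydrogen over the π face
  rather than the ring edge.
- approach angle θ — measured **at the hydrogen**, between the H→donor and
  H→centroid directions; accepted in 120–180°. The literature quotes the
  angle of approach without fixing a convention; the donor–H–centroid angle
  is adopted here because it reproduces the quoted ~140° for a
  near-perpendicular approach with a short offset, and the convention is
  echoed in report metadata. Comparisons against deposited structures
  should therefore carry ±0.2 Å / ±10° tolerances for the combined
  H-placement and angle-convention freedom.

Hydrogen bonds from ligand oxygens use a heavy-atom distance-only criterion
(default 3.5 Å, to protein N/O and water O): the crystallographic models
carry no protein hydrogens, so a donor–H–acceptor angle term would be
spurious precision. Waters are allowed partners (a single buried water is a
conserved feature of these pockets).

## Pocket volume

The buried cavity is estimated on a Cartesian grid (default 0.5 Å spacing)
over the ligand bounding box plus 8 Å padding: a voxel is occupied when its
centre lies within (Bondi vdW + probe) of a protein heavy atom, with a
water-sized 1.4 Å probe; free voxels 6-connected to the box boundary are
bulk solvent; the cavity is the free, non-bulk component containing the
ligand centroid; volume = voxel count × spacing³. Ligand atoms are excluded
from the occupying set (the cavity is what the ligand occupies), and waters
are excluded by default (the buried water belongs to the cavity), with a
flag to include them.

This is a deliberately self-contained estimator, not an alpha-shape pocket
decomposition as used by CASTp-style servers; absolute volumes will differ
from such tools. Analyses should therefore compare **percent changes**
between structures computed at identical settings. Grid-orientation
discretisation keeps rigid-motion variation under ~10% at default spacing;
degenerate cases (seed voxel occupied, unenclosed pocket) are flagged
rather than silently returning numbers.

## Domain motion

Lobe closure is decomposed in two stages: the closed structure is
superposed on the open one using the reference-lobe (lobe 2) Cα pairs,
then the residual rigid motion of lobe 1 is extracted as a screw — rotation
angle (the closure angle), unit axis, the axis point nearest the lobe-1
centroid, and the translation along the axis. Correspondence is by author
residue number, not secondary-structure matching, so cross-structure RMSDs
are "paired-residue" values and may differ slightly from SSM-based tools;
hinge-residue identification (as in full DynDom) is out of scope. The
default lobe definition is lobe 1 = residues 1–84 ∪ 202–255, lobe 2 =
96–196, the standard split for the Ps PtxB open/closed pair. Rotation
angles are extracted with the atan2 form (well conditioned near 0° and
180°); superposition uses SVD Kabsch with the determinant correction.

## Binding models

**MST.** The measured signal against total ligand follows the
ligand-depletion quadratic isotherm (protein at 50 nM is comparable to the
nanomolar K_d values, so the hyperbola is wrong by construction). Final
labelled-protein concentration defaults to 50 nM — 100 nM labelled protein
mixed 1:1 with the ligand series. Each replicate is fitted independently by
least squares over (log K_d, Bound, Unbound) — log-space enforces
positivity — with a deterministic multistart at {0.1, 1, 10}× the geometric
mean of the concentration series. The reported K_d is the arithmetic mean
over replicates and its uncertainty the sample standard deviation (n−1),
matching the "± esd over three independent experiments" convention of
affinity tables. "No binding detected" (NBD) is called when the pooled
amplitude is below 3× the residual noise sd or the fitted K_d exceeds the
top tested concentration; the result is then the bound
"> top concentration" (10 mM in the standard series).

**ITC.** The forward model updates total cell concentrations per injection
with the standard displaced-volume correction (contents diluted by
1 − ΔV/V₀, ligand delivered at syringe concentration), solves the
single-site depletion quadratic, and reports per-injection heats
dH·V₀·(B_i − B_{i−1}(1 − ΔV/V₀)). The fit runs over (log K_d, dH, n_sites)
with the first injection excluded (syringe-tip diffusion makes it
unreliable), standard errors from the Jacobian covariance. Heat-of-dilution
subtraction is the caller's responsibility. The default geometry —
32 × 1.49 µl of 2 mM ligand into 160 µl of 200 µM protein — is the standard
protocol for these proteins.

**Selectivity and redox.** Fold selectivity is a K_d ratio with first-order
error propagation; ratios against NBD fits are refused (they are bounds,
not numbers). Redox-coupled free energy is ΔG°′ = −nF(E°′_acceptor −
E°′_donor), F = 96.485 kJ mol⁻¹ V⁻¹; the phosphate/phosphite couple
(−650 mV) against NAD⁺/NADH (−320 mV) with n = 2 gives −63.7 kJ mol⁻¹,
the driving force that makes phosphite a usable phosphorus and electron
source.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their spec, including the seed (named
substreams per replicate/lobe give reproducibility with independence).

- `make_pi_site` solves the **inverse** placement problem analytically: the
  ring is ideal (regular hexagon, C–C 1.39 Å), and the oxygens are arranged
  so the forward hydrogen construction lands exactly at the requested
  (d, θ, offset). Detection is therefore tested as an exact round trip.
  Fixture ligands use local hetero codes PHS (phosphite) and HPS
  (hypophosphite), since deposited component IDs vary between entries.
- `make_two_lobe` builds self-avoiding Cα walks (3.8 Å steps) and applies
  an exact rigid rotation to lobe 1, so closure recovery can be asserted to
  1e-6 degrees.
- `make_cavity` places carbon pseudo-atoms on layered Fibonacci spheres
  starting at void radius + r_vdW(C) + probe, so the probe-inflated
  occupancy begins exactly at the void radius; the analytic reference
  applies the same voxel rule to the ideal sphere.
- `simulate_mst` / `simulate_itc` add Gaussian noise (2% of amplitude and
  1% of peak heat by default — typical instrument noise floors) to the
  exact forward models.

These fixtures validate the algorithms, not the biology: idealised rings
are perfectly planar, toy lobes are exactly rigid, simulated noise is
homoscedastic and Gaussian, and the simulators share the forward models
with the fitters (parameter-recovery tests demonstrate estimator
correctness and precision, not robustness to model misspecification such
as thermophoresis artefacts, heats of dilution, or active-fraction error).
Checks against deposited crystal structures (the ~2.6 Å / ~140° tyrosine
contact, the ~60° closure, the −36% pocket contraction in the
hypophosphite binder) require the entries to be fetched and are run through
the CLI, not the test suite.

## Problem sizes and numerical defaults

The test suite and acceptance script run entirely from generated data:
MST recovery uses 16-point triplicates (the bias sweep: 200 triplicates at
each of four K_d values spanning 0.05–50 µM, with the top concentration at
300× K_d so the series brackets the transition); ITC recovery uses the
32-injection geometry; pocket checks use a 5 Å void at 0.25–0.5 Å grid
spacing. Exact geometric constructions are asserted at 1e-6–1e-9;
floating-point comparisons against independent oracles at 1e-9 relative;
statistical recoveries at 3× the estimated error. Degenerate geometry
(collinear point sets, non-rotation matrices, open pockets, all-zero
heats) raises typed errors rather than returning silent numbers.

## Known limitations

- Hydrogen placement is idealised geometry; real P–H vectors tilt with the
  electronic environment by a few degrees.
- The pocket estimator's absolute volumes are method-dependent; only
  like-for-like percent changes are meaningful.
- The closure decomposition assumes exactly two quasi-rigid lobes and
  reports a single screw; flexible hinges are absorbed into the lobe-1
  residual RMSD.
- MST fitting assumes the replicates share true parameters but fits them
  independently; systematic inter-replicate drift inflates the esd rather
  than biasing the mean.
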