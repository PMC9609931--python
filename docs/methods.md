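# Methods

This package asks a residue-centric structural question: does a point
substitution at one interface residue redirect a protein domain's
dimerization preference?  The motivating case is the ALS2/alsin VPS9
domain, where replacing an exposed arginine by a tryptophan (R1611W)
plausibly turns a charged surface site into a hydrophobic one that seeks
burial, shifting the domain from homodimerization toward association
with the hydrophobic face of the RLD β-propeller.  Because the relevant
homology models are not publicly deposited and the original quantitative
outputs came from external engines, every stage here is exercised on
synthetic structures whose statistical ground truth is programmed, and
only relative, between-condition comparisons are claimed.

## Structure model and geometry

Structures are arrays of heavy atoms (hydrogens are read and written but
excluded from every analysis) with author residue numbering preserved.
Van der Waals radii come from an element-keyed NACCESS-compatible table
(C 1.76, N 1.65, O 1.40, S 1.85 Å; unknown elements default to 1.8 Å).
PDB I/O goes through biotite behind the module surface, with a
pre-validation pass that reports malformed ATOM records by line number.
Superposition is closed-form Kabsch (SVD with a determinant correction,
so reflections are never returned).  Backbone dihedrals follow the IUPAC
sign convention; the "allowed" Ramachandran classification uses coarse
rectangular boxes per residue class (general / Gly / Pro) because the
aim is counting gross violations, not reproducing a validation server.
Residue substitution is identity-level: the residue name changes, side
chains are truncated beyond CB, and no rotamer is rebuilt — descriptor
analyses see the new identity while geometry stays honest about what is
actually known.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic Fibonacci sphere lattice (default 960
points, probe 1.4 Å).  The lattice is expressed in the molecule's
principal-axis frame with third-moment sign fixing, which makes the
estimate invariant (to lattice resolution, ≲0.5%) under rigid motion
without introducing randomness.  Buried fraction of a residue is
(SASA_monomer − SASA_complex)/SASA_monomer, clipped to [0, 1]; small
negative deltas can only arise from lattice re-orientation between the
monomer and complex frames and are clipped to zero.  A single-residue
fast path computes areas only for the atoms of interest while occluding
against everything, which is what makes ensemble scoring cheap.

## Elastic-network flexibility

CA-node GNM (cutoff 10 Å) and ANM (15 Å) with eigendecomposition of the
Kirchhoff/Hessian; RMSF is the pseudo-inverse diagonal with zero modes
excluded (1 for GNM, 6 for ANM on connected networks — asserted, not
assumed).  The mutation cannot be represented structurally without
rebuilding side chains, so it enters as a contact-weight proxy: springs
are scaled by the geometric mean of side-chain heavy-atom counts of
their endpoints ("sidechain" weighting).  An Arg→Trp substitution makes
the local network stiffer, which is the qualitative behaviour the
comparison needs.  Profiles are median-normalised before differencing;
sites are flagged beyond a z-threshold on the robust (MAD) scale.

## Pose ensembles and the externalization score

A pose ensemble is a ranked set of two-chain rigid poses with
lower-is-better energies.  For each pose the tagged residue is classified
external if its buried fraction is below `f_min` (default 0.25; since any
such threshold is a modelling choice, the score is also reported at 0.15
and 0.40).  The score is the weighted fraction of external poses with
weights proportional to −energy (rank-linear fallback when energies are
missing, uniform available for calibration studies); weights renormalise
over non-excluded poses.  The contact-density map bins ligand centres of
mass on a grid in the receptor frame and reports connected clusters.

## Interaction energy and descriptor ΔΔG

The nonbonded potential is deliberately simple and declared: united
heavy-atom Lennard-Jones (element-level parameters, Lorentz–Berthelot
combining), plus Coulomb terms between coarse per-residue net charges
(Arg/Lys +1, Asp/Glu −1, His +0.1) placed at side-chain centroids,
screened by a relative permittivity of 80, hard 12 Å cutoff, no
switching function (the discontinuity is irrelevant for between-condition
comparison, which is the only claimed use).  Because monomers are rigid,
the complex energy is assembled as intra-A + intra-B + inter, making
Δ = E(complex) − E(A) − E(B) exactly the inter-chain pair sum; pair terms
are accumulated with an exactly rounded sum so Δ is bitwise symmetric
under chain relabeling and identically zero beyond the cutoff.

The mutation ΔΔG is a three-descriptor linear model
`c0 + cV·Vdiff + cH·Hdiff + cS·SASA_rel`: volume difference of the
substitution, enthalpy-term difference, and the site's relative solvent
accessibility (Gly-X-Gly normalisation).  The shipped tables are package
defaults — consensus average residue volumes for Vdiff and the
Kyte–Doolittle hydropathy scale as the enthalpy term — and the default
coefficients (0, 0.005, 0.8, 2.0) are conventions validated for shape
only; all of it is editable configuration, and no absolute free-energy
claim is made.

## Unbinding trajectories

Each frame is superposed on frame 0 using the anchored chain only; every
non-anchored residue's heavy-atom RMSD from its bound position forms a
time series.  The detachment lag is the first frame where that RMSD
exceeds a threshold (default 3 Å) for a persistence window (3 frames);
residues that never do are "attached".  Both numbers are declared
parameters, since published unbinding curves rarely state a criterion.
Any residue grouping (core, linker) can be averaged into group curves;
conditions are compared by one-way ANOVA on replicate summary RMSDs, with
lower mean RMSD of the pulled domain labelled — explicitly as an
interpretation label — "stronger residual association".

## Pocket detection

The shell is every residue with a heavy atom within 5 Å of the target
(heavy-atom criterion).  Cavity detection is LIGSITE-family: grid voxels
outside all probe-inflated atoms count as cavity when at least 9 of 14
scan directions (6 axial + 8 diagonal) hit protein.  Buriedness is always
evaluated on a fixed-resolution scan grid (0.8 Å) so whether a point in
space counts as enclosed is independent of the output voxel size; the
output grid then only discretizes the volume integral, which is what
makes volumes converge as the spacing shrinks.  Clusters below 10 Å³ are
discarded as surface dimples; the cluster nearest the target is the
pocket (all clusters are still reported).  The docking box is the cluster
extent plus a 4 Å margin per side, falling back to the target centroid
when no pocket exists.

## Screening triage

Descriptors (logBB, solubility, logP in two solvents) are ingested, never
computed; an optional logBB surrogate from logP and TPSA is labelled as
such.  Filters are conjunctive with a per-candidate × per-rule audit
table and an explicit missing-value policy.  The mutant-specificity
differential is Δ = score_mut − score_wt with the score orientation
declared per engine (fitness: positive Δ = mutant-specific; affinity:
negative Δ = mutant-specific).  The default BBB rule (lgBB ≥ −1) is a
documented placeholder, not a literature threshold.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their arguments, seed included.
Monomers are ideal-geometry backbones (α-helix φ=−57°, ψ=−47°, NeRF
construction, CB at tetrahedral positions), poly-alanine with one
taggable site residue so wild-type and mutant runs differ only at the
tag.  Pose ensembles place a randomly oriented ligand along an approach
axis using a closed-form first-contact solution (minimum heavy-atom
separation exactly 4.0 Å, hence clash-free by construction); with
programmed probability the axis aims at the tagged residue and the
placement is accepted only if the tag truly carries the contact (≤4.3 Å,
≥7 ligand atoms within 6 Å) — otherwise the approach targets the far
hemisphere and the tag stays ≥8 Å from the ligand.  That separation is
what makes the burial Bernoulli draw recoverable by the SASA classifier
with essentially no confusion.  The default ensemble size is 30 poses
per condition, the study's stated docking-ensemble size.  Trajectories
move pulled residues at constant speed (default 10 Å/ns, 0.1 ns/frame)
after their scheduled frame, with optional Gaussian noise.  Candidate
tables draw descriptors from normal distributions and plant a
mutant-specific subset whose score advantage is expressed in units of
the paired-score noise SD.

None of this emulates real energetics, real docking funnels, chemically
realistic ligand poses, conformational change, or correlated noise.
Passing tests therefore demonstrate that the *statistical machinery*
recovers programmed contrasts at the stated sizes — not that the
biological conclusion would survive on real structures.

## The preference verdict

The comparative question is operationalised as an explicit 2-of-3 rule:
a variant "prefers" partner X when at least two of {tagged-residue
buried fraction, tagged-residue SASA, mean interaction energy} favour X
in direction with Holm-adjusted Welch p < α (default 0.05).  Raw and
adjusted p-values are both reported so the rule can be audited; burial
and SASA are correlated lines of evidence, which the Holm family
adjustment partially compensates.  No verdict is emitted without the
dimer-metrics stage.  Multi-variant comparison flattens per-partner
metrics into a matrix and ranks variants by absolute distance from the
wild-type value per metric.

## Problem sizes and numerical choices

Analyses and tests run on 16-residue receptors, 10-residue ligands,
30-pose ensembles (200 for score-calibration studies), 50-frame
trajectories and ~600-atom lattice fixtures — sizes chosen so the whole
analysis chain, including its 100-seed calibration studies, completes on
a laptop-class single core in minutes while keeping every statistical
contrast overpowered rather than marginal.  Degenerate inputs follow
fixed conventions: zero-variance equal-mean tests return p = 1;
zero-monomer-SASA burial is 0; collinear superposition selections raise
rather than silently produce a rank-deficient fit.

## Known limitations

The energy model has no bonded terms, no polarisation and a hard cutoff;
its absolute numbers are meaningless by design.  The ΔΔG coefficients
are uncalibrated defaults.  The ENM mutation proxy changes stiffness,
not geometry.  Pocket volumes depend on the declared buriedness
threshold (9/14) and probe convention.  The verdict rule treats two
correlated metrics as separate votes.  All statistical guarantees are
demonstrated on the synthetic generators' assumptions (independent
poses, Gaussian noise) and sizes stated above.
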