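# Methods

This note documents the models implemented in `tailscape`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## NMR titration analysis (`cspfit`)

**Model.** A two-state, fast-exchange, single-site binding equilibrium.
The observed peak of each residue sits at the population-weighted average
of its apo and bound positions; the bound fraction is the exact quadratic
("ligand-depleted") solution of the 1:1 equilibrium, valid when ligand and
receptor concentrations are comparable. Composite shifts weight ¹⁵N by
0.154, the conventional gyromagnetic scaling for amide HSQC work.

**Pipeline.** Δδ per residue per point relative to apo → significance
call → independent per-residue (K_d, Δδ_max) fits → aggregation.

* *Significance rule*: Δδ > mean + k·sd over all observable residues at
  the evaluation point, strict inequality, k = 0.5 by default. The low
  cutoff is appropriate when the binding surface is a large fraction of a
  small domain; k is a parameter. The evaluation point defaults to the
  final (highest-ligand) titration point, where contrast is largest; it is
  configurable because the rule could equally be applied at any point.
* *Standard deviations*: population (1/n) normalisation for both the
  significance rule and the outlier rule; switchable to sample sd. The
  choice only matters at these small n and is documented because neither
  convention is canonical.
* *Per-residue fits*: nonlinear least squares (`scipy.optimize.
  least_squares`) of Δδ = Δδ_max·f_B(P_i, L_i, K_d) with per-point protein
  and ligand totals, so dilution across the series enters the model
  exactly rather than as a correction. Initialisation K_d⁰ = median L,
  Δδ_max⁰ = 1.2 × max Δδ; bounds K_d ∈ (0, 10⁶] μM, Δδ_max ∈ (0, 10] ppm;
  tolerances 10⁻¹². Flat or non-convergent series are flagged, never
  silently dropped or imputed. Residues broadened beyond detection at the
  evaluation point are excluded from statistics.
* *Aggregation*: a single pass — mean and sd over all converged fits,
  removal of values outside mean ± 2·sd, then mean and sd over the
  retained set. The pass is not iterated (with well-behaved data at most
  one residue is ever removed, and iterating a 2·sd rule on small n can
  cascade). A tiny relative slack (10⁻⁸) keeps numerically identical fits
  from being evicted when sd ≈ 0.
* Each residue is fit with its own Δδ_max (no sharing across residues);
  a global shared-K_d fit would be a reasonable extension but is not what
  the per-residue aggregation scheme assumes.

## BLI equilibrium analysis (`blieq`)

Processing order: reference subtraction → baseline alignment → smoothing
→ r_eq extraction → hyperbolic fit. Kinetic (k_on/k_off) fitting is out of
scope: when kinetics are fast relative to the phase lengths the transients
carry little information and the equilibrium route is the robust one.

* *Referencing*: "single" subtracts the loaded-sensor-vs-buffer channel;
  "double" additionally subtracts the unloaded-sensor-vs-analyte channel
  matched by concentration. Time grids must agree to within one sample
  period (traces are interpolated onto the sample grid).
* *Baseline alignment*: subtract the mean of the last 10 s of baseline
  (parameter, sensible range 5–10 s).
* *Smoothing*: Savitzky–Golay, window 15 points (1.5 s at 10 Hz), order 2,
  via `scipy.signal.savgol_filter`. Window and order are parameters.
* *r_eq*: arithmetic mean of the last 20 s of the association phase.
  Channels whose association has visibly not plateaued (last two 20-s
  windows differing by more than ~3% of the response, or 10 standard
  errors) are flagged in the report but not dropped.
* *Fit*: r_eq = r_0 + (r_max − r_0)·x/(K_d + x) by least squares;
  uncertainties are asymptotic (Jacobian-based) standard errors, the
  default when no replicate-based error model is available.

## Trajectory metrics (`traj`)

* *Selections*: a small predicate language ("chain T resid 1-10
  backbone"); residue indices are 1-based within a chain and ranges are
  closed.
* *Superposition*: Kabsch SVD with the determinant correction, so only
  proper rotations are returned. The fit selection and the RMSD selection
  are independent — the protocol for "fit the structured core, measure the
  tail spread". Tests cross-check against an independent quaternion
  (Horn) implementation to 10⁻⁶ Å.
* *Secondary structure*: a Kabsch–Sander implementation — geometric amide
  H placement (1 Å from N, parallel to the preceding C=O), electrostatic
  H-bond energy with bond call at −0.5 kcal/mol — collapsed to four
  categories: helix (G/H/I), sheet (E/B), turn (T), coil. Priority when
  elements overlap follows the original program (4-helix > sheet >
  3₁₀ > π > turn). Donor/acceptor pairs within the same peptide unit are
  excluded; an N–O gate at 5.2 Å prunes the pair search. Chain breaks end
  ladders because bonds are only evaluated within one contiguous chain;
  residues with incomplete backbones are reported coil and flagged.
  Ensemble summaries report per-residue percent-of-frames per category,
  and overall values as the mean of per-residue percentages.
* *Occupancy maps*: frames are rigid-fit to a reference (first frame, or
  an external structure) on a fit selection; occupancy is the fraction of
  frames in which ≥ 1 selected atom falls in a 1 Å³ voxel. "Average
  occupancy" is ambiguous between frame fraction and mean atom count, so
  both modes exist ("fraction" is the default). Grids auto-size with a
  2 Å margin and export to OpenDX.
* *SASA*: Shrake–Rupley with 960 deterministic golden-spiral sphere
  points and a 1.4 Å probe, occluding against **all** atoms in the frame.
  Shrake–Rupley was chosen over LCPO because LCPO requires a force-field-
  specific atom-type parameterisation, whereas Shrake–Rupley is fully
  specified by the per-atom radii the topology already carries.
* *Interaction energies*: screened Coulomb,
  E = Σ 332.0636·q_i·q_j/(ε(r)·r) with ε(r) = 4r by default (a constant
  dielectric or a callable can be substituted), optional Lennard-Jones.
  This is a deliberately simple surrogate for solvated per-residue
  decompositions: absolute values are qualitative only. What is exact is
  the aggregation: each tail copy in each simulation is one sample, group
  means and SEMs are taken across samples (SEM reported as absent when
  n = 1), and chemistry totals are sums of per-residue means.

## Sequence calculators (`seqcalc`)

Protein ε₂₈₀ = 5500·nTrp + 1490·nTyr + 125·nCystine; cysteines are
reduced by default (correct for DTT-containing or Zn-coordinating preps).
Single-strand DNA ε₂₆₀ uses the Cantor–Warshaw–Shapiro nearest-neighbor
table (pair sums minus internal monomers); duplex ε₂₆₀ applies
hypochromicity h = 0.287·f_AT + 0.059·f_GC to the sum of both strands.
This dialect reproduces the printed 21-bp reference value exactly
(computed 333,804.47 vs printed 333,804.5). For the printed 147-bp
nucleosome-positioning duplex the package computes 2,346,044.9 M⁻¹cm⁻¹;
the value printed alongside that sequence in the source study
(2,312,300.9) is about 1.5% lower and is not reproduced by this formula
from that sequence under any variant we tested (alternative monomer
corrections, strand-handling variants, subsequence windows), so we report
the formula's value and note the discrepancy rather than adjust constants
to match one number.

## Synthetic-data generators (`synth`)

The generators produce data with the statistical structure the analyses
assume, with ground truth known, so pipelines can be validated end to end.

* *Titrations*: fast-exchange population-weighted peaks with Gaussian
  shift noise (defaults 0.002 ppm ¹H, 0.01 ppm ¹⁵N — typical peak-picking
  precision; real instruments do not publish a single number). Schedules
  are given as receptor:ligand molar ratios (default ladder
  0, 0.1, 0.25, 0.5, 1, 2, 5, 10 at 50 μM receptor); dilution is modelled
  by decreasing P_i across points. A slow-exchange mode emits two peaks
  per residue with intensities linear in the bound fraction.
* *Sensorgrams*: 1:1 kinetics with k_off = k_on·K_d; k_on defaults to
  0.1 μM⁻¹s⁻¹ so 300 s association plateaus at every tested
  concentration. Artifacts are a linear drift common to loaded sensors
  (removed by single referencing) and an analyte-proportional optical
  offset common to everything dipped in analyte (removed by double
  referencing), plus white noise (0.01 response units).
* *Backbones*: ideal-geometry chains grown from (φ, ψ) by
  internal-to-Cartesian placement (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å,
  ω = 180°, carbonyl O in-plane anti to the next N). Dihedral round trips
  are exact to < 10⁻³ degrees, so secondary-structure fixtures are fully
  determined by their dihedral lists.
* *Tail/pseudo-DNA ensembles*: each frame is an independent self-avoiding
  bead chain (one 1.9 Å bead per residue, 3.8 Å bonds) anchored near a
  charged cylinder (radius 10 Å, 40 pseudo-phosphate sites of charge −1
  and contact radius 1 Å on a helical path). Growth directions of
  positively charged beads are tilted toward the nearest site with weight
  1.5·collapse·q; neutral beads consume the same random draws but take
  the unbiased direction, so a fully neutralised tail reproduces the
  collapse = 0 ensemble draw for draw. Blocked approaches decay the bias
  over retries so self-avoidance is never violated. The steering weight
  is kept moderate deliberately: if steering saturates at contact, bead
  packing rather than charge becomes the limit on surface proximity and
  charge-pattern comparisons lose their meaning. This is Metropolis-style
  resampling, not dynamics — only ensemble statistics are meaningful.

**What the generators do not emulate.** No lineshapes, relaxation or
intermediate exchange on the NMR side; no mass-transport limitation,
sensor heterogeneity or nonspecific binding beyond a linear artifact on
the BLI side; no solvent, force field, kinetics or realistic DNA geometry
on the trajectory side. Passing tests therefore demonstrate that the
*analysis pipelines* are correct and unbiased under their stated model
assumptions — not that those assumptions hold for any particular real
dataset.

## Problem sizes

Recovery studies use 20 replicate seeds (NMR: 44 residues, 8 points;
BLI: 7 concentrations at 10 Hz over 780 s) and report medians; trajectory
ensembles in tests use 40–200 frames of 10–12 beads. These sizes give
stable medians and sharp property checks while keeping the whole suite in
the tens of seconds.

## Known limitations

* The CSP pipeline assumes fast exchange; intermediate-exchange peak
  positions would bias fitted K_d values and are not modelled.
* The screened-Coulomb energy is not a solvation model; only orderings
  and aggregation statistics should be interpreted.
* The secondary-structure implementation handles single contiguous
  chains; inter-chain β-bridges are not assigned.
* SASA uses hard-sphere radii from the topology; no implicit hydrogens
  beyond what the radii encode.
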