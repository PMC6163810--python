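# Methods

## Scope and model

`protongate` implements the desk-scale analysis layer of a proton-transport
account of voltage-sensor gating. The expensive inputs — per-atom partial
charges of a ~10³-atom sensor cluster and protonation-state energies on a
voltage grid, as produced by quantum-chemistry calculations — are consumed
as plain tables; the package never performs electronic-structure work.
What it does compute:

1. **Slab/center-of-charge analysis** of a charged structure along the
   membrane normal, and the displacement of that center between two
   states, as a surrogate for gating charge.
2. **Protonation-state energetics**: minimum-energy state per voltage,
   crossing points of two state curves, decomposition-term differences.
3. **Thermal/kinetic arithmetic**: Q10 ↔ activation energy, k_BT unit
   conversions, mode-cutoff frequency k_BT/h, 3N−6 mode counting,
   gating-cycle counting.
4. **Gating-curve models**: the two-state Boltzmann fit, the
   Gaussian-threshold (probit) alternative, and the single-barrier
   log-log conductance analysis.
5. **Hydrogen-bond graph analysis**: donor/acceptor site typing (with the
   amphoteric-arginine rule), candidate-bond edges, Y-R-E / R-E-R triad
   detection, and residue-level simple-path enumeration.
6. **Synthetic data** for all of the above, with planted, exactly
   recoverable truths.

## Coordinate frame and slab partition

z is the membrane normal, increasing toward the extracellular side; the
frame origin defaults to the minimum z of the selection, which makes slab
indices reproducible without external membrane annotation. Slabs are
half-open intervals [z₀ + k·t, z₀ + (k+1)·t), so a boundary atom belongs to
the upper slab deterministically and no atom is double-counted. The default
partition is eleven 3 Å slices. An atom outside the partition is an error,
never a silent truncation, so per-slab sums always conserve the total
charge.

The center of charge is defined on the *signed* net charge: the systems of
interest carry net +2 e, so the centroid is well defined, and zero-net
inputs raise an error rather than silently splitting positive and negative
clouds.

### Accuracy of the slabwise center

Writing z_mid(i) for the midpoint of atom i's slab,
|Σqᵢ·z_mid(i) − Σqᵢzᵢ| ≤ (t/2)·Σ|qᵢ|, so the center error is bounded by
(t/2)·Σ|qᵢ|/|Σqᵢ|. For sign-definite charges this is exactly t/2 — half a
slab — but for a signed distribution with a small net total the
amplification factor Σ|q|/|Q| can be large: the default synthetic cluster
(Σ|q| ≈ 230 e, Q = +2 e, t = 3 Å) shows slabwise and atomwise centers tens
of ångströms apart. Both centers are therefore always reported; the
property tests assert the t/2 bound on sign-definite fixtures and the
amplified bound (plus linear-in-t refinement convergence) on signed ones.
The *displacement* between two states whose charge distribution shifts
rigidly is unaffected: with each state's partition anchored at its own
minimum z, the slabwise center is exactly translation-equivariant, so the
shift is recovered exactly.

`effective_gating_charge` exposes the field-drop distance as an explicit
parameter (default none — the caller must choose), because the implied
per-sensor gating charge depends on how far the membrane field is assumed
to fall, which is not derivable from the structure alone.

## State energetics

Energies are relative (absolute quantum totals are meaningless here);
tables may arrive already shifted, and every operation is invariant under
adding a constant per voltage. Interpolation between the five grid
voltages (−70, −35, 0, +35, +70 mV by convention) is linear — no
functional form beyond the grid is assumed. The crossing height is
measured above the grid minimum of a reference state; the default
reference is whichever of the two compared states reaches the lower grid
minimum, which keeps the default symmetric under swapping the states. A
difference curve that never changes sign returns a distinguished
"no crossing" result (None), not an error; fewer than two common voltages
is an error. Ties for the minimum-energy state (within 10⁻⁹ kJ/mol) are
reported as errors listing the tied states rather than broken arbitrarily.

kJ/mol ↔ k_BT conversions use R·T per mole at a declared temperature
(default 300 K, consistent with the 290–300 K decade convention and with
k_BT/h ≈ 6.25 × 10¹² Hz at room temperature). "Q10 at T °C" means the
decade [T−10 °C, T °C]; this convention reproduces the ≈50 kJ/mol (Q10
2.2, decade ending 10 °C) and ≈20 kJ/mol (Q10 1.3, decade ending 40 °C)
activation energies of proton-channel conduction.

## Gating curves

The Boltzmann model is extended with a midpoint parameter V½ because real
datasets are not centered at 0 mV; the textbook single-Boltzmann form is
the V½ = 0 case. The fit is nonlinear least squares on probabilities (not
logits), so saturated points at 0/1 remain usable; initialization uses the
interpolated 0.5-crossing and the steepest central finite-difference slope.
The two-state assumption is knowingly wrong for real channels — the fit is
a descriptive tool, and "slope" for mutant comparisons means dP/dV at the
midpoint, q·e/(4k_BT), which is proportional to q.

**Uncertainty.** Observation noise on probabilities is clipped to [0, 1],
which makes the error variance voltage-dependent (smaller where the curve
saturates). The homoscedastic covariance from ordinary least squares then
understates the uncertainty in q (Monte Carlo: reported SE 0.32 vs true
spread 0.41 under the default synthetic conditions). `fit_boltzmann`
therefore reports an HC3 sandwich covariance, whose SEs match the
Monte-Carlo spread (0.40); the true 2-SE coverage under clipped noise is
about 92% rather than the nominal 95%, and the recovery tests are
calibrated to that.

**Threshold model.** The alternative model opens the channel when the
voltage-coupled energy drive q·e·V/k_BT crosses a Gaussian threshold of
width ≈ 1 k_BT (probit curve). For comparison with the Boltzmann, the
midpoint is matched exactly and the width is chosen numerically to
minimize the sup deviation over a dense grid; the familiar probit/logit
scale factor ≈ 1.702 emerges from that minimization (it is not
hard-coded), and the resulting maximum deviation is ≈ 0.0095 — below 0.01,
i.e. the two models are experimentally indistinguishable. Matching the
midpoint *slope* instead (width 4/√(2π) ≈ 1.596) leaves a larger sup
deviation of ≈ 0.018 and is available as an option.

**Conductance barrier.** Relative conductance proportional to ln[K⁺] is
equivalent, through ΔΔG = −RT ln(c/c_ref), to linearity of conductance in
the solution free energy of the ion — the single-barrier picture. The
diagnostic is ordinary least squares of ln g on ln c with R² reported;
constant conductance is returned as slope 0 exactly.

## Hydrogen-bond graph

Site typing is a residue/atom table switched by nominal side-chain charge:
Tyr OH both (acceptor-only when ionized); Arg NH1/NH2 always donors, NE
acceptor when neutral and donor when protonated — the amphoteric rule that
lets arginine relay a proton; Glu/Asp carboxylate oxygens acceptors when
charged, with one oxygen donor-capable when neutral; His ring nitrogens,
Ser/Thr/Cys hydroxyl-or-thiol, and water oxygens both. Defaults are the
solution states (Arg/Lys +, Glu/Asp −, Tyr/His 0), overridable by a
protonation state — the scientific point being precisely that the
overrides matter. Unknown residues are skipped with a warning.

Edges are candidate hydrogen bonds: donor-capable to acceptor-capable,
different residues, heavy-atom distance ≤ 3.5 Å. No donor–H–acceptor
angle term is used: the path reasoning is distance-level and input
structures may lack hydrogens. Waters are ordinary nodes (one hop per
water). Triads use a 6 Å pairwise window on functional-group atoms
(minimum over atom pairs), chosen to admit the ~5.1–5.4 Å
arginine-N-to-carboxylate-O separations seen in sensor and
bacteriorhodopsin proton-wire triads with margin; the window is monotone
(enlarging it never removes a triad). Paths are reported residue-collapsed
(all sites of a residue merge into one node), as simple paths up to a hop
limit, in lexicographic order; path enumeration is independently checked
against a brute-force depth-first search in the tests.

## Synthetic data

The generators define the study conditions; their defaults are fixed, not
tuning knobs.

* **Cluster**: 976 atoms = 904 protein + 24 × 3-atom waters; net charge
  +2 e; planted atomwise center of charge 8.3 Å (the open-state value;
  the rigid-shift pair generator plants an 11.3 Å displacement). The
  proton-wire motif is five minimal side-chain proxies (Tyr266 OH,
  Arg300 NE/NH1/NH2, Glu183 OE1/OE2, Arg303, Glu226) on a 2.8 Å
  hydrogen-bond lattice in the z = 20 Å plane, with intra-residue atoms
  offset along z only so the minimum inter-residue functional distance is
  the in-plane spacing exactly. The resulting hydrogen-bond graph has
  exactly the edges R303–Y266, Y266–R300, R303–E226, E226–R300, R300–E183
  (Arg–Arg and Glu–Glu pairs are role-incompatible; Y266–E183 at 5.6 Å and
  Y266–E226 at 3.96 Å exceed the 3.5 Å cutoff) and hence exactly two
  residue paths R303 → E183. Geometry note: any layout realizing those
  five contacts at ≤ 3.5 Å forces Y266, R300, R303, E226 pairwise within
  ≈ 2 × 3.5 Å by the triangle inequality, so besides the designed
  Y266/R300/E183 triad and the R300/E226/R303 triad, the triples
  Y266/R300/E226 and Y266/R303/E226 also fall inside the 6 Å window —
  four triads total, enumerated in the manifest by an independent brute
  force inside the generator. Filler is apolar carbon; filler charges are
  random with two atoms adjusted (on the PDB-precision coordinates) so the
  charge sum and charge-weighted centroid are exact to 10⁻⁶.
* **Energy tables**: closed (all-neutral) and open (Tyr⁻/Arg⁺/Glu⁰)
  states are straight lines in voltage crossing exactly at the planted
  point (default −20 mV, 60 kJ/mol above the closed minimum ≈ 24 k_BT);
  the open-state slope is kept shallow enough that the closed state is
  the global reference minimum across the grid. Decoy states sit strictly
  above both. Because the truth is piecewise-linear, recovery by the
  piecewise-linear crossing finder is exact. Exchange–correlation values
  96.0 / 25.2 kJ/mol are planted at 0 mV for the decomposition check.
* **Gating curves**: Boltzmann evaluations (default q = 13 e, the
  canonical *Shaker* gating charge; V½ = 0; 41 voltages spanning ±10 k_BT
  of drive) plus N(0, 0.02) noise clipped to [0, 1].
* **Conductance**: log-log-linear data over 1–1000 mM with 5%
  multiplicative noise.

One integer seed governs each generator (no global random state);
identical seeds give byte-identical files, which is asserted by hashing in
the tests. What the generators deliberately do **not** emulate: realistic
force-field geometry, charge distributions beyond the sum/centroid
constraints, multi-state gating kinetics, or rundown/drift in recordings —
so passing tests demonstrate correctness of the analysis arithmetic and
graph logic under the stated conditions, not robustness to every artifact
of real recordings or real electron densities.

## Numerical choices and degenerate inputs

* Constants are CODATA via scipy; energies per mole use R·T for k_BT.
* Altloc conformers: highest occupancy wins, ties go to the first
  encountered — deterministic.
* Boundary atoms belong to the upper slab; zero-total-charge profiles,
  empty selections, missing charge-table ids, duplicate (state, voltage)
  rows, tied minima, single-voltage crossings, non-identifiable gating
  data, and nonpositive cutoffs/windows/concentrations all raise typed
  errors rather than returning silent values.
* The Boltzmann evaluator uses the numerically stable logistic (expit), so
  extreme voltages saturate without overflow.
* Problem sizes in the test suite and acceptance script (976-atom
  clusters, 41-point curves, ≤ 12-node random graphs, 50–200 replicate
  sweeps) were chosen so each suite completes in seconds while still
  exercising the documented properties at realistic scale.

## Known limitations

* The slabwise center of charge is a faithful re-implementation of the
  slice-and-sum procedure, but as shown above its discretization error is
  amplified for signed densities with small net charge; the atomwise
  center is the quantitatively reliable one and both are reported.
* Crossing analysis is piecewise-linear on a five-point grid; curvature
  between grid voltages is invisible by construction.
* Hydrogen-bond edges ignore geometry beyond heavy-atom distance; triad
  patterns are limited to Y-R-E/D and R-E/D-R.
* The Boltzmann fit is descriptive: real activation involves multiple
  states, and q from a single-Boltzmann fit is an effective parameter.
* No pKa prediction, no water placement, no energy ranking of paths, and
  no kinetic-scheme fitting.
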