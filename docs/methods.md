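# Methods

## Scope and model

`rcvkit` analyses ensembles of protein conformations (MD trajectory frames)
against a reference structure to quantify how far named functional elements
have deformed, and couples that structural readout to companion enzyme
kinetics and thermal-stability analysis. The motivating use case is a
calcium-activated homodimeric decarboxylase in which deformation of a
lid-loop/rim-helix unit capping the active pocket marks deactivation, and a
metal site at the interface between the catalytic domain and an appendage
C-terminal domain controls that deformation. Nothing in the package is
specific to that enzyme: components, binding sites and cutoffs are all
declared in a config.

## RMSD with align/measure semantics

All deformation measures start from least-squares rigid superposition
(Kabsch, SVD with the determinant correction that excludes reflections).
`rmsd_series` superposes every frame onto the reference using an *alignment*
selection — by default each monomer's rigid core, or a dimer-wide core for
whole-dimer analyses — and then evaluates RMSD over a separate *measure*
selection without refitting. This makes the RMSD of a lid loop report its
displacement relative to the core rather than its internal flexibility.
Selections are residue ranges with an atom filter; the backbone filter
(N, CA, C, O, unweighted) is the default, configurable to Cα-only, heavy or
explicit atom lists. No mass weighting is applied.

Summaries pool frames over both monomers and all replicas and report the
median with the interquartile range. Quartiles use numpy's default linear
interpolation (Hyndman–Fan type 7), fixed so test values are exact.

## RCV scoring

The relative conformational variation score affinely rescales a component's
RMSD distribution between two reference ensembles:

    RCV(v) = (v − median_active) / (median_inactive − median_active)

so the active reference's median maps to 0 and the inactive reference's to 1.
The map is applied framewise; because a monotone affine map commutes with
order statistics, the score median is identical to normalizing the summary
median directly, and the transformed IQR is also reportable. Scores are not
clamped: a median ≥ 1 means the component is at least as deformed as the
inactive reference and is labelled *severe*; 0.5–1 *perturbed*; below 0.5
*native-like*. These labels grade conformational deviation only — RCV is
explicitly not a quantitative predictor of enzymatic activity. References
closer than 1e-9 Å cannot define a scale and are rejected.

## GROMOS clustering

Conformational clustering uses the greedy maximum-neighbour rule: repeatedly
take the frame with the most neighbours within the RMSD cutoff as a cluster
centroid, remove it and its neighbours, and continue; clusters are relabelled
by descending population. Ties in neighbour count go to the lowest frame
index, making the procedure fully deterministic (the classic algorithm leaves
this unstated). Neighbourhoods use strict `distance < cutoff`. The default
mode computes raw pairwise RMSD between frames already superposed on the core
("prealigned"), matching the convention of aligning all structures on the
dimeric core before analysis; a `pairwise_fit` mode refits every pair for
compatibility with the classic tool. Clustering is run per subunit, pooling
all replicas. Per-component cutoffs calibrated on an active wild-type
ensemble (catalytic domain 2.4 Å, active pocket 1.4 Å, catalytic loop 3.0 Å,
lid-rim 1.8 Å) ship as defaults and are config-overridable.

## Ion residence and occupancy

A binding site is declared as coordinating residues with named atoms, split
into primary and backup residues; the residence test always uses their
union, reflecting the observation that neighbouring carboxylates take over
coordination when the primary shell distorts. A frame is bound when an ion
of the site's species has at least `min_contacts` (default 1) coordinating
atoms within `distance_cutoff` (default 3.5 Å — a generous first shell given
~2.4 Å crystallographic Ca–O distances). These defaults are declared package
choices, not values inferred from any particular study. Residence
probability is the pooled bound-frame fraction over monomers and replicas,
with per-source fractions retained for dispersion. Occupancy grids bin ion
positions into voxels (default 1 Å); counts outside the region go to an
overflow tally so total observations are conserved, and grids export as
OpenDX text.

## Contacts and SASA

Contact frequency between residues i and j is the fraction of frames in
which their minimum heavy-atom distance falls below the cutoff (default
4.5 Å; the definition is a declared choice since no single field standard
exists). Differential maps are plain subtraction, antisymmetric under
operand swap. SASA uses Shrake–Rupley sphere-point sampling with a 1.4 Å
probe and 960 points per atom placed on a deterministic golden-section
spiral, so results contain no RNG and are bit-reproducible; the van der
Waals radii table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, Ca 2.31,
Na 2.27 Å) is fixed in code. Selection SASA is always evaluated in the
context of all atoms. At 960 points an isolated sphere's area is accurate to
well under 0.5%.

## Kinetics and melt curves

Rates are consumed on the kcat scale (v/[E], s⁻¹); a helper converts
product-formation rates plus enzyme concentration. The Michaelis–Menten
hyperbola is fit by nonlinear least squares with relative (1/v) weighting by
default, the standard choice when measurement error scales with the rate;
with multiplicative noise this keeps the linearized t-quantile confidence
intervals calibrated (~95% coverage in the package's own simulation test),
where unweighted least squares under-covers. Uniform weighting and a seeded
residual-resampling bootstrap (resampling relative residuals) are options;
the CI method is stamped in the output. Fold activation is
kcat(Ca)/kcat(Na) and fold catalytic efficiency (kcat/Km)(Ca)/(kcat/Km)(Na),
reported at one decimal with full precision retained.

Melting temperatures come from the smoothed numerical derivative of a
fluorescence melt curve: all local extrema of dF/dT ("wells") are returned
sorted by depth and the deepest defines the primary Tm, accommodating
multi-domain proteins with several transitions. Raw dye traces gain
fluorescence on unfolding while exported derivative curves are often
negated, so the well sign is configurable (`auto` picks the deeper side).
Extrema shallower than 1e-9 of the curve's slope scale are discarded as
numerical jitter; a flat curve therefore raises a no-well error. Smoothing
is a 5-point moving average by default; Tm resolution equals the temperature
grid spacing.

## Synthetic data

The generators produce every input with analytic ground truth:

- **Toy dimer** — two 40-residue chains of idealized helical backbone
  (4 atoms/residue, chain B mirrored so the dimer is not a translation
  copy), with named core (res 1–20), lid (25–32), rim (35–38) and binding
  sites. Downstream analyses depend only on coordinates and labels, so an
  idealized backbone suffices; the helical parametrization guarantees
  non-degenerate 3D geometry for fitting.
- **State mixtures** — frames sample rigid per-component translations by
  weight plus isotropic Gaussian thermal noise (default σ = 0.05 Å). For a
  pure translation Δ of a component whose alignment core is unmoved, the
  noiseless component RMSD is exactly |Δ|, giving closed-form expectations
  for RMSD series, clustering populations and RCV scores. The default
  study (``simulate_study``) builds an active system (no offsets), an
  inactive system (lid +3 Å, rim +2 Å) and a midway system at half offsets,
  two replicas each.
- **Ion binding** — a two-state Markov chain started at stationarity with
  per-frame probabilities p_on, p_off; the stationary bound fraction is
  p_on/(p_on+p_off) and the lag-1 autocorrelation 1−p_on−p_off, so the
  standard error of the residence estimate over n frames is
  sqrt(p(1−p)/n · (1+λ)/(1−λ)). Bound frames place the ion 2.4 Å from a
  coordinating atom; unbound frames are uniform in a diffusion box excluding
  the cutoff shell.
- **Kinetics / melt** — Michaelis–Menten values with multiplicative
  Gaussian noise (default 5% relative, 8 log-spaced concentrations spanning
  1 µM–2 mM, 3 replicates), and sums of logistic transitions with a linear
  baseline for melt curves.

What the generators deliberately do not emulate: real protein internal
flexibility (noise is isotropic and stateless), correlated frame-to-frame
conformational dynamics, solvent, multiple interacting ions, or any
force-field physics. Passing tests therefore demonstrate that the
*estimators* are correct and calibrated on data with known truth — not that
any particular real system's microsecond-simulation numbers are reproduced,
which would require the original trajectories.

## Problem sizes and numerical choices

The test suite and the reproduction script run the toy dimer at 320 atoms
with 40–150 frames per replica, 20,000-frame ion chains, 200-fit coverage
simulations and 100 randomized clustering matrices — sizes chosen so every
ground truth is statistically resolvable while the whole suite completes in
well under a minute of CPU per module. Rigid fits require ≥ 3 non-collinear
points; degenerate references, empty selections, NaN distance matrices,
insertion codes and mismatched atom counts all raise typed errors naming the
offending input. PDB coordinates round-trip at the format's 0.001 Å
precision; altloc conformers resolve to highest occupancy.

## Known limitations

- The PDB reader covers ATOM/HETATM/MODEL records only — no insertion
  codes, SEQRES or symmetry; binary trajectory formats (XTC/DCD) are out of
  scope, with multi-model PDB and a frames-csv text dialect as the supported
  interchange.
- Contact maps are O(atoms log atoms) per frame via a k-d tree but still
  per-frame Python loops; very long trajectories should be strided.
- SASA is sphere-point sampling, not an exact power-diagram area; accuracy
  is set by the point count.
- The RCV calibration inherits whatever sampling error the reference
  ensembles carry; references should pool enough frames that their medians
  are stable (the calibration file records the provenance hash).
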