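# Methods

This note records the models and procedures implemented by `turnprop`,
the assumptions behind them, the parameters that matter, and the
choices made where the design was genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Angles and circular arithmetic

All angles are degrees wrapped into the half-open interval
(−180, 180]; −180 normalizes to +180. The signed circular deviation of
two angles is wrap(a − b), which is antisymmetric except at exactly
180°, where both signs denote the same separation. Dihedrals are
computed with the atan2 formulation (stable near ±90°) under the IUPAC
sign convention; an atom triple whose cross product has norm below
1e-8 makes the dihedral undefined (NaN, with a warning) rather than
raising.

## Turn classification

A four-residue window *i*..*i*+3 is a turn candidate when
|Cα(*i*) − Cα(*i*+3)| < 7.0 Å (strict inequality) and the two central
residues are not both helical. The helix test is dihedral-only: a
residue is helix-like when both φ and ψ are within 40° (circular) of
(−60, −47), and counts as helical only inside a run of at least four
consecutive helix-like residues. The run-length requirement reflects
the convention that a turn may overlap the end of a helix by up to
three residues; a dihedral-only criterion keeps classification usable
when only torsions (no hydrogen-bond geometry) are available.

A candidate window is assigned the classical type — I, II, I', II' or
VIII, whose ideal central quadruples the package ships as versioned
JSON — whose four circular deviations are all ≤ 30°, with at most one
angle allowed in (30°, 45°]. The one-angle relaxation matches the
assignment convention of the PROMOTIF program; a `strict=True` flag
disables it, since published analyses do not always state which
convention they used. If several types match (possible only through
the relaxation), the one with the smallest total |deviation| wins;
exact ties fall back to the fixed priority I, II, I', II', VIII.
Candidates matching no classical type are the miscellaneous type IV.
Type VIII's ideal angles (−60, −30, −120, 120) follow Thornton's
standard values; the Pro-dependent types VIa1/VIa2/VIb are out of
scope. Population tables report, per central-residue pair, the % of
all frames carrying each type, with a Total row summing the six types.

## Synthetic ensembles

The generator emulates what downstream statistics care about in a
folding trajectory of a capped peptide — a mixture of conformers with
stationary weights, angular noise around each conformer's central
angles, optional temporal correlation, and per-frame temperatures —
while making no claim of physical realism (no force field, no solvent,
no energies, no side chains beyond an optional Cβ placeholder).

* **Labels.** iid draws reproduce the weights exactly in expectation.
  Markov switching stays with probability *p* and otherwise draws a
  *different* conformer with probability proportional to weight, so
  dwell times are exactly Geometric(1 − *p*) with mean 1/(1 − *p*);
  the stationary distribution then equals the weights exactly for
  equal weights and approximately otherwise (the two desiderata —
  weight-matched stationarity and weight-independent dwell — cannot
  hold simultaneously for unequal weights under any single kernel, and
  the dwell contract was kept).
* **Noise.** Angular noise is von Mises with concentration κ rather
  than wrapped Gaussian: correct circular topology with one parameter,
  converging at large κ to a Gaussian of σ ≈ 1/√κ radians. The default
  κ = 50 (σ ≈ 8°) is a realistic within-conformer basin width for a
  short peptide; recovery tests that need point-like conformers use
  κ = 400 (σ ≈ 2.9°) and the degenerate-noise contract uses κ = 1e8.
* **Flanks.** Non-central angles are either coil-random (uniform on
  the circle — deliberately harsher than a Ramachandran-weighted coil,
  since uniform angles maximize accidental type-IV background) or
  fixed at an extended-strand center (−120, 140) plus the same noise.
* **Coordinates.** Backbones are built by sequential NeRF-style
  placement from idealized bond lengths/angles (N–Cα 1.458 Å,
  Cα–C 1.525 Å, C–N 1.329 Å; trans ω = 180° by default), with acetyl
  and N-methylamide caps contributing the atoms that define φ of
  residue 1 and ψ of residue N. Rebuilt bond lengths equal the input
  geometry to machine precision and recomputed torsions equal the
  inputs to ≪ 1e-3°, which the round-trip tests assert.
* **Temperatures.** An optional sinusoidal series (base ± amplitude,
  clipped to [280, 480] K, default period 500 frames) stands in for an
  adaptive-tempering temperature trace; only the ≤ *T* filtering
  behavior matters downstream.
* **Seeding.** One integer seed drives a single PCG64 generator for
  the whole ensemble; identical specs give byte-identical output.

What passing tests on these ensembles shows: the analysis operations
recover programmed statistical structure at realistic noise and sample
sizes. What they do not show: force-field adequacy, solvent effects,
or kinetics of real peptides — the generator has none of those.

## Dihedral PCA and clustering

φ/ψ of the selected residues (typically the four central ones) enter
as (cos θ, sin θ) pairs — residue-major, φ before ψ, cos before sin —
so every frame has squared row norm 2 × n_angles and periodicity never
splits a compact conformer. PCA is the eigendecomposition of the
column-centered covariance; each component's sign is fixed by making
its largest-magnitude loading positive.

Clustering is a deterministic grid-density flood fill in the top-3 PC
space: 32 bins per axis spanning ±3 SD per component (frames outside
are clipped into edge bins, so a zero cutoff clusters every frame);
bins with counts above the cutoff are kept and merged by face
adjacency. When no cutoff is given it is chosen so the kept
high-density bins hold ≈35% of frames, echoing the clustered fractions
typical of disordered-peptide trajectory analyses; both the cutoff and
the grid are explicit parameters because anisotropic PC scales make
the right resolution problem-dependent (two-conformer recovery tests
use a coarse 8-bin grid with cutoff 0). Cluster representatives: the
member with the lowest backbone (N/Cα/C) RMSD to the average structure
obtained from two passes of Kabsch superposition onto the running
mean; ties go to the lowest frame index.

## Deviation statistics and peak fitting

For each tracked angle the per-frame deviation from a reference value
is histogrammed in 5° bins over (−180, 180] (fine enough to resolve
~10°-wide modes at n ~ 10⁴–10⁵ without drowning in count noise). The
density is modeled as a sum of Gaussian components: local maxima of a
3-bin circular moving average seed one component each (tallest first,
at most five — the expected number of Ramachandran-region modes is
small), and all components are jointly least-squares fitted with each
Gaussian summed over its ±360° periodic images, so modes near the ±180
seam are handled without special-casing. σ is bounded to [1°, 120°].
Maxima (and fitted components) below 2% of the tallest are treated as
count noise, not modes: without that floor, Poisson fluctuations in
the tails can seed spurious components near d = 0 and steal the
nearest-peak selection. The returned peak is the component whose
fitted mean is circularly closest to zero; exact ties break toward the
negative mean. Fitting a Gaussian to 5°-binned data inflates σ by
about w²/12 ≈ 2 deg² (≤ 0.21° at σ = 5°), well inside the ±1° recovery
tolerance. At least 50 defined deviations are required; a flat
histogram raises "no peak" rather than fitting nonsense.

The Z-score is Z = (0 − μ)/σ — the distance of the reference from the
nearest simulated mode, in mode widths — with a two-sided standard
normal tail probability 2(1 − Φ(|Z|)). Reference analyses report the
deviation-of-the-mode reading rather than a per-frame statistic; both
per-reference and whole-series fits are supported since published
tables are ambiguous about whether one global peak per angle was
reused across turn types. Reports: angles with |μ| > 30° (reported as
|μ|), and |wrap(reference + μ) − ideal| for the central residues of
each classical type (type IV, having no ideal angles, is rejected).

## Good-Turing convergence

The estimator asks how much structural variability a trajectory has
*not* shown. From `n_samples` frames (default 500, drawn without
replacement with a stated seed — keeping the O(n²) RMSD matrix at
~125k pairs, seconds of work via batched 3×3 SVD Kabsch), species at
radius r are single-linkage clusters of the pairwise minimum backbone
RMSD matrix, each pair superposed independently to avoid reference
bias. p_unobserved(r) = N₁/N, the classical Good-Turing mass of
singleton species, evaluated on an ascending grid (default 0.05–4.0 Å
in 0.05 Å steps) and made monotone non-increasing by a running
minimum. This implements the published output interface (the
p_unobserved-vs-RMSD curve) with the textbook estimator and a stated
species definition; it is a documented variant, not a claim of
bit-compatibility with any specific prior implementation, whose
calibration details (linkage choice, frame-correlation correction)
are not public. Temperature filtering simply restricts frames to
T ≤ t_max before sampling.

## Degenerate inputs and tie-breaks (summary)

* Undefined angles propagate as NaN and disqualify a window (reason
  recorded) rather than raising mid-scan.
* Colinear dihedral geometry → NaN with warning.
* All-identical frames: PCA returns ~0 eigenvalues and projections;
  Good-Turing returns p ≡ 0; the cluster representative is frame 0.
* −180 is normalized to +180 everywhere; classification is invariant
  under adding multiples of 360° to any input angle.
* Reported TSVs use 1-based frame numbers (0-based internally) and
  full-precision floats so read/write round trips are exact.

## Known limitations

* The helix exclusion is dihedral-only; DSSP-style hydrogen-bond
  assignment could disagree near helix termini.
* The grid-density clustering is resolution-dependent by design; it
  reproduces the *structure* of published cluster statistics
  (% clustered, dominant-cluster share), not any specific program's
  partition.
* The coil model is uniform on the circle, which overestimates the
  type-IV background relative to a Ramachandran-weighted coil; recovery
  tolerances account for it.
* Published headline numbers that depend on multi-microsecond MD
  trajectories are not reproducible from synthetic ensembles and are
  not targets of this package's checks; the package validates the
  *operations* on inputs with known ground truth, including the
  printed DFT geometries.
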