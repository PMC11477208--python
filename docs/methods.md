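# Methods

This note documents the models, conventions, and numerical choices behind
`myolever`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinate system and tail angles

The crossbridge frame is constructed from a weakly-bound actomyosin
reference geometry. The origin is the (unweighted) centroid of the
actin-pentamer selection. Axis **e₂** is the dominant principal axis of the
actin coordinates (eigenvector of the coordinate covariance with the largest
eigenvalue), oriented from the first toward the last selected atom so the
sign is deterministic. Axis **e₁** is the component, orthogonal to e₂, of
the vector from the origin to the centroid of the myosin anchor selection
(the converter region in the reference-aligned pose). **e₃ = e₁ × e₂**
completes a right-handed orthonormal triad. Construction fails loudly for
coincident actin atoms, for an axis-degenerate covariance, and for an anchor
on the e₂ line.

The tail vector **v** joins the backbone (N, Cα, C) centroids of the
proximal (residues 769–771) and distal (784–787) tail groups, the region
N-terminal of the light-chain binding site that stays straight during
simulations. Angles, in degrees:

* elevation = 90° − ∠(v, e₁) ∈ [−90, 90] — rise toward e₁ out of the
  e₂–e₃ plane;
* azimuth = atan2(v·e₃, v·e₂) ∈ (−180, 180] — position around e₁ from +e₂
  toward +e₃;
* tilt = ∠(v, e₃) ∈ [0, 180].

For a single unit vector these three are redundant:
cos(tilt) = cos(elevation)·sin(azimuth). Published angle triples for this
system (e.g. an X-ray pose quoted at 35°/43°/142°) do not satisfy that
identity, so they cannot all be reproduced by any single-vector convention
in an orthonormal frame; the likely cause is that the original tooling
evaluated the three angles as independent measurements. We therefore fix
conventions by the axis-aligned cases (v = e₂ ⇒ (0, 0, 90); v = −e₃ ⇒
(0, −90, 180); v = e₁ ⇒ elevation 90 with azimuth reported as 0 and flagged
degenerate) and treat tilt as a derived diagnostic throughout, including in
the synthetic generator. This is a documented limitation, not a free
parameter.

Angle statistics use ordinary (non-circular) moments: observed tail angles
sit tens of degrees from the ±180° wrap, where circular corrections are
negligible. Data near the wrap would need circular statistics.

Probability densities use uniform bins (2° default, 2°×2° in 2-D) anchored
at `width · floor(min/width)`, normalized so density × bin width (or area)
sums to one exactly.

## Superposition and LOVO core selection

All rigid-body fits are least-squares Kabsch superpositions via SVD with the
reflection branch excluded (determinant correction), erroring on fewer than
three points or rank < 2 configurations. An independent Kearsley
quaternion-eigenvalue implementation serves as the test oracle.

The LOVO (low-order-value-optimization) fit separates a rigid core from
mobile subdomains. Starting from all Cα atoms: (1) align every frame on the
current subset to the current average structure (inner loop iterated until
the average drifts less than `tol`); (2) recompute the average; (3) rank
atoms by time-averaged deviation from the average; (4) keep the
round(φ·N) lowest. Convergence is subset-membership fixed point; ties at the
boundary go to the lower atom index (stable sort). The internal reference is
the evolving average structure. Default φ = 0.35; inputs are subsampled at
1 ns by default before fitting. Non-convergence at `max_iter` flags the
result instead of raising.

RMSD series take separate alignment and measurement masks, so "align on the
rigid core, measure everything" tables are first-class. RMSF is the
root-mean-square deviation of each Cα from its time-averaged position in a
pre-aligned trajectory; a single frame yields zeros with a warning.

## Replicate statistics

Replicates — not frames — are the statistical units: each replicate
contributes one time-averaged observation per quantity. Conditions are
compared with the classic pooled-variance two-tailed Student's *t*
(df = n₁ + n₂ − 2), matching the three-per-condition design; Welch's
correction is deliberately not used. Degenerate inputs follow a fixed
convention: zero pooled variance gives p = 1 for equal means and p = 0
otherwise. No multiple-testing correction is applied across residues or
contact pairs by default (raw p < α counts are the reported quantity); a
Benjamini–Hochberg switch exists for the residue map and is off by default.

## Contacts

Two residues are in contact in a frame when any heavy-atom pair is within
5.0 Å, boundary inclusive. Neighbor searches use a k-d tree
(`scipy.spatial.cKDTree`), which is exact — no cutoff approximation — and
near-linear per frame; randomized tests pin it to an all-pairs brute force.
Residue–residue tables are evaluated at 100 ps stride by default;
sequence-adjacent pairs are included (no published exclusion rule exists for
this analysis), and solvent/ions are outside scope. Ligand–protein occupancy
averages across replicates and drops residues below 5 % average occupancy;
persistence tiers count the replicates in which a residue reaches that
threshold, and novel contacts are those absent from a supplied reference
pose. Differential contacts union pairs across replicates (occupancy 0 where
absent), test 3-vs-3 occupancies per pair, and keep p ≤ α with
|Δ| ≥ threshold (0.05/0.10/0.20 give nested sets). Salt bridges reuse the
distance criterion restricted to side-chain N/O atoms of the named charged
residues, stratified by lever-arm elevation.

## Conformer clustering

Ligand poses are superposed on the conformationally homogeneous central
moiety of the first pose, then scored by plain all-heavy-atom RMSD (no
second fit), so rigid motions that leave the moiety fixed score zero. The
merge sequence is average-linkage (scipy); at each cut level the penalty is
the normalized average intra-cluster spread — the mean over multi-member
clusters of their mean pairwise distance, rescaled onto [1, N−1] across
levels (all-equal spreads map to 1) — plus the cluster count. The
minimizing level is returned; ties go to the earliest level. The penalty is
invariant under uniform scaling of the matrix. Representatives are medoids
(minimal mean distance to co-members); cluster "variance share" is reported
as population share, the only reading computable from frame assignments.
Whether the original clustering used all heavy atoms or ring atoms only is
unrecoverable; all-heavy-atom RMSD is used and stated.

## Elevation morphs

Frames are re-aligned on a motor-domain/lever-arm junction selection
(default residues 704–723; the published range is unstated, so this is a
configuration input), assigned to twenty 5° elevation bins anchored at
5°·floor(min/5°) with half-open [lo, hi) intervals (edge values go right),
and averaged per bin. Morphs interpolate atom coordinates linearly between
consecutive occupied bin averages; endpoints equal the averages exactly, so
B bins with s steps give (B−1)s + B frames. Cartesian interpolation is
deliberately nonphysical — it visualizes range of motion, not a pathway.

## Synthetic generator: what it emulates and what it does not

The generator builds a deterministic pseudo-protein: a 151-residue motor
blob on a 5 Å lattice, a relay segment (492–503), a converter (712–766) and
tail helix (769–810) rigidly hinged at the motor–tail junction, a
40-residue pseudo-ELC riding the tail, an actin-pentamer surrogate
(anisotropy ratio > 10), isolated switch-residue pairs for planting contact
occupancies, and, in the holo condition, a multi-moiety pseudo-ligand with
a rigid 7-atom central ring and two 3-atom terminal groups drawn from a
discrete pose mixture.

Study conditions: apo-like elevation ~ N(23°, 6°), azimuth ~ N(34°, 8°);
holo-like elevation ~ N(33°, 2.5°), azimuth ~ N(45°, 4°). Means follow the
reported condition averages; standard deviations are not published, so they
were chosen once to reproduce the qualitative broad-vs-narrow contrast of
the reported distributions and are part of the fixed study conditions.
Per-atom isotropic thermal noise defaults to σ = 0.5 Å (a typical
sub-Ångström heavy-atom jitter), giving a closed-form backbone RMSF of
σ√3 ≈ 0.87 Å. Three replicates of 4000 frames at 100 ps emulate 400 ns of
production analysis per replicate; tests and the acceptance script use
shorter runs (150–1200 frames) chosen for desk-scale runtimes, with the
problem size always reported alongside the result. Angles are sampled
independently per frame by default; an AR(1) option exists because real MD
frames are autocorrelated, which matters when calibrating statistics against
real ensembles. Planted features: differential contact pairs at
(0.90/0.40, 0.60/0.10, 0.75/0.25) plus a null pair, apo-only RMSF inflation
of residues 240–250 sized to produce a +2 Å ΔRMSF, an elevation-gated salt
bridge (break at 30°), and pose-mixture weights (0.4, 0.3, 0.2, 0.1).

The generator realizes sampled (elevation, azimuth) *exactly*: tail-residue
backbone centroids lie on the tail axis by construction, and the lever-arm
body is rotated about the hinge by the minimal rotation taking the base
direction to the target, expressed in the same crossbridge frame the
measurement pipeline later computes — so the zero-noise round trip is
machine-precision identity. Planted contact occupancies are realized by
Bernoulli-gated repositioning of dedicated switch residues; the gated
salt-bridge atom tracks its partner as a planted mechanism rather than a
physical side chain.

What passing these benchmarks shows: the geometry, alignment, statistics,
and clustering machinery recover known truths exactly or within stated
sampling bounds. What they do not show: anything about force fields,
sampling convergence, solvent effects, or correlated protein motions — the
generator has no physics, and real-ensemble conclusions still require real
trajectories.

## Pipeline defaults and reproducibility

The orchestrated run discards 100 ns of equilibration for file inputs
(time-based, converted via the trajectory timestep); the synthetic scenario
represents post-equilibration production, so its discard defaults to zero.
Other defaults: 100 ps contact stride, 1 ns LOVO subsampling, φ = 0.35,
5 Å cutoff, α = 0.05, 10 % difference threshold, 2° angle bins, 5° morph
bins. Every stage is a pure function of (inputs, config, seed); the manifest
records the config hash, seed, and package versions, and reruns with the
same config are byte-identical. Selections are validated before any stage
runs; a mid-run failure leaves partial outputs next to a `FAILED` marker
naming the stage.

## Known limitations

* The crystallographic calibration (reference-pose angle triple and the
  21-residue ligand contact count) requires PDB entries 5N69 and 8EFE on
  disk; they are not redistributed with the package.
* The helix-loop-helix alignment range and the morph junction range are
  required configuration inputs with documented defaults, not published
  values.
* Tilt is derived, not independent (see the coordinate-system section).
* Altloc handling keeps the highest-occupancy conformer (ties → 'A');
  residue numbering is taken from the source file without renumbering.
* No mmCIF output, no binary trajectory writers, no torsion-space morphing
  or clustering, and no plotting — outputs are CSV/JSON/PDB for downstream
  tools.
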