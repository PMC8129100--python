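# Methods

`neuroaggsim` simulates the aggregation, contraction and cell sorting of
confined 3D neuron–astrocyte cultures with a phenomenological point-cell
model, and implements the morphometric and activity-analysis procedures
used to characterize such cultures.  This note records the model, its
parameters, the numerical choices, and what the synthetic data (and hence
a green test) does and does not establish.

## The aggregation model

Each cell is a point in 3D.  Cells interact through three exponentially
decaying forces, each defined by a strength and a length constant; the
length constant τ is the distance at which the force has decayed to 1% of
its maximum:

    F(d) = strength · 0.01^(d/τ)

* **Attraction** (strength `A`, length `tau_a`), scaled per ordered
  cell-type pair by a constant `AS`: the attraction *felt by* a neuron due
  to a neuron (N-N), by a neuron due to an astrocyte (N-A), by an
  astrocyte due to a neuron (A-N), and by an astrocyte due to an astrocyte
  (A-A).  The asymmetry (N-A ≠ A-N allowed) models differential adhesion.
* **Repulsion** (`R`, `tau_r`), identical for all type pairs.  Attraction
  and repulsion cancel at the *force equilibrium point*
  d\* = ln(R/A·AS) / (ln 0.01 · (1/τa − 1/τr)), the model's characteristic
  cell-to-cell distance.
* **Surface adhesion** (`S`, `tau_s`) toward fixed anchor points scattered
  on the substrate plane (z = 0), modeling adhesion to the coated floor.

Forces act along the 3D unit separation vector with Euclidean-distance
magnitudes (see *Design choices*).  Displacement per step is `k(t)·F`
minus a constant gravity `g` on z, where the *movement freedom*

    k(t) = 1 − σ((t − delay)/constant),   σ the logistic function,

decays from 1 toward 0 around a stiffening delay, freezing the culture as
it matures.  Cells are clamped to the confinement walls (slit: per-axis
clamp; disk: radial projection) and to z ≥ 0; there is no ceiling.

### Parameters (defaults)

| parameter | value | unit | meaning |
|---|---|---|---|
| `A`, `tau_a` | 1, 320 | –, μm | attraction strength / length |
| `R`, `tau_r` | 2.27, 200 (140 in the `initial` preset) | –, μm | repulsion strength / length |
| `S`, `tau_s` | 0.01, 30 | –, μm | surface adhesion |
| `AS` (N-N, N-A, A-N, A-A) | 1, 0.9, 0.8, 0.7 | – | type-pair attraction constants |
| `g` | 1e-4 | μm/step | gravity displacement |
| schedule | 350 / 300 / 20 | steps | total time / stiffening delay / constant |
| cell density | 1e-4 | cells/μm³ | seeding concentration |
| astrocyte fraction | 0.2 | – | fraction labeled astrocyte |
| anchor density | 2e-3 | points/μm² | substrate anchors |
| min spacings | 10 | μm | cell–cell and anchor–anchor at seeding |

The two shipped presets (`initial`, `optimized`) differ only in `tau_r`
(140 vs 200 μm).  The standard slit is 4000 × 200 μm with 100 μm seeding
height (8000 cells: 6400 neurons + 1600 astrocytes, 1600 anchors).

### Design choices

* **Isotropic force reading.**  A per-axis force form (each component
  decaying with that axis' coordinate separation alone) was prototyped and
  rejected: its one-dimensional bulk integrals make repulsion dominate
  (R·τr > A·τa for the optimized constants) and cultures explode
  vertically.  The isotropic Euclidean form is rotation invariant and
  produces aggregation, clustering and sorting.  Its bulk balance is
  attraction-dominated, so aggregation is vigorous: cultures fragment into
  dense well-separated clusters rather than staying connected.  This has
  measurable consequences listed under *Known limitations*.
* **Engine.**  All-pairs force evaluation uses a numba kernel over cells
  sorted by x with a cutoff radius at 1e-4 of each strength (= 2τ); the
  shared pair exponential is computed once and applied to both members.
  The kernel is validated against a per-cell reference implementation to
  float precision on sub-cutoff systems.
* **Coincident cells** (distance 0) receive the full repulsion magnitude
  along a pseudo-random direction so they separate; attraction and
  adhesion contribute nothing there.
* **Movement freedom** uses the current step t in the logistic argument;
  a literal reading of the printed schedule formula would be constant in
  time, contradicting its described role.
* **Seeding** is rejection sampling with a grid hash (min-spacing
  enforced), capped at 10,000 attempts per point with an explicit failure
  naming the achieved fraction.  Replicate seeds in sweeps are
  `base + 1000·replicate`.

## Morphometrics

* **CCDP** — probability-normalized histogram of pairwise distances, 5 μm
  bins; the peak is the center of the maximal bin, ties toward smaller
  distance.
* **Cluster segmentation** — neurons binned at 10 μm along the slit axis,
  3-bin moving average; culture extent spans the occupied bins (≥ 5% of
  the maximum smoothed count); cluster edges are local minima with dip
  prominence ≥ max(5% of max, 2·√max).  The shot-noise floor (2·√max, a
  two-sigma Poisson fluctuation of the modal bin) suppresses spurious
  minima; candidate intervals that never rise above that floor are valley
  territory and are split at their center between the flanking clusters.
* **Cluster CCDP** — within each cluster, planar (x–y) pairwise distances
  among neurons sharing a 10 μm z-slab, pooled per cluster; the mean CCDP
  averages per-cluster probability profiles on a common grid.
* **Contraction** — 100·(L0 − Lf)/L0 with L the 0.5–99.5 percentile
  x-extent of *all* cells (culture size as seen in phase contrast; a
  neuron-only extent confounds contraction with neuron count when
  comparing compositions).  `normalized_contraction` divides by a
  reference condition's mean.
* **Depth profile** — per 10 μm (x, y) column, the local surface is the
  maximum cell z over the column's 3×3 neighborhood; depth = surface − z.
  Cells on the aggregate's lateral faces are excluded, because a column
  through the side shell has no meaningful "top"; a lateral face is a
  column whose coarse footprint cell (3× pitch, so sparse fields don't
  create spurious holes) borders empty space.  Scalars:
  superficial astrocyte ratio (depth ≤ 10 μm), overall deep ratio, and
  the maximum per-bin deep ratio over bins with ≥ 10 cells.  The surface
  estimate sits below the true top by roughly (cell volume density ×
  neighborhood area)⁻¹ μm, so superficial fractions of sparse fields are
  diluted; recovery tests use dense fields where the bias is ~1 μm.
* **Force–morphology correlation** — Pearson correlation (zero-lag) of
  each AS column against the superficial astrocyte ratio across a sweep.

## Image analysis

ROI directionality: binarize at gray value 55, autocorrelate (full 2D
cross-correlation with zero padding), threshold the surface at 70% of its
own maximum, take the central blob; major axis = maximum pairwise distance
between blob edge pixels, minor axis = shortest chord through the major
axis midpoint (1° direction scan, 0.25 px steps, ties to the shorter
chord).  Directional iff major/minor ≥ 2 and major ≥ 5 px; the angle is
the major-axis angle against the image x-axis (culture long axis), CCW
positive, in (−90°, 90°].  Default pixel pitch 0.25 μm/px (40 px per
10 μm ROI); the acquisition pixel size is configurable.

Nucleus morphometry: binarize at the intensity midpoint (recorded;
configurable), remove components touching the lateral borders, erode each
z-plane with a 3×3 cross, take per-plane outlines; the maximal 3D distance
between outline voxels is the major axis (convex-hull pruning above 400
points), its XY-projected angle the alignment, the outline z-range the
height.  One erosion shell trims the apex planes of an ellipsoid, so the
measured height of an ideal ellipsoid of height 2c lands about 1–2 voxel
layers short.

## Activity analysis

ΔF/F = (R − F0)/F0 with F0 an asymmetric-least-squares baseline
(smoothness λ = 1e7, asymmetry p = 0.01, 10 reweighting iterations;
recorded in output metadata).  The AsLS penalty has natural boundary
conditions, so the first/last few seconds of a drifting trace fit slightly
worse.  Bursts are maximal runs of ΔF/F above 3× a robust std
(1.4826·MAD of the whole series; the plain std is inflated by the bursts
themselves) lasting at least 1 s — a 3σ threshold on a noise floor is
crossed by isolated frames ~0.1% of the time, while network bursts last
tens of seconds, so sub-second runs are treated as noise.  Per burst:
duration, peak ΔF/F, trapezoidal AUC; plus total active-time fraction.
Segment baseline profiles average raw fluorescence over burst-mask
complements and normalize by the brightest segment.

LFP: 100 Hz–3 kHz band pass (4th-order Butterworth, zero phase) plus
narrow notches (Q = 60) at 60 Hz and harmonics.  Initiation: a sample
counts when the trace stays at/above threshold for the whole 10 ms
persistence window; re-arming requires a drop below threshold.  The
threshold is the std of the quietest 100 ms window (automating the
paper-style manual silent-segment choice).  Center/edge initiations are
matched greedily within a 5 s window; delay = edge − center (positive =
center leads); exact ties count for neither side of the center-leading
fraction.

## Synthetic data

Generators are seeded and bit-reproducible, and return the construction
ground truth for parameter-recovery tests.  They emulate: post-sorting
cell fields (uniform, Gaussian clusters, astrocyte shell over a core at
the published shell/deep fractions 39.3%/5.8%), fiber patches (blurred
3 px lines with angular jitter; 1 px unblurred lines autocorrelate only at
lattice angles, which is a rendering artifact, not fiber physics),
ellipsoid nucleus stacks, calcium traces (drifting baseline, 50 ms-edge
burst envelopes tens of seconds long, 0.2 s frames), and 6 kHz LFP channel
pairs with per-burst center/edge leads (trapezoidal envelopes with a 2 ms
attack so threshold crossings pin to onsets; noise σ = 0.5 vs burst
amplitude 60).  None of these is a biophysical forward model: a green
parameter-recovery test establishes that the analysis inverts the
generator's stated construction, not that it is unbiased on real
microscopy or electrophysiology.

## Known limitations

* Under the isotropic force reading the model aggregates more violently
  than the published reference behavior for these cultures: per-step
  displacements at seeding are ~10 μm, clusters are tall separated balls,
  and consequently (a) contraction across the 24 attraction-order
  configurations spreads by ~20 percentage points rather than ≤ 1.5, (b)
  at 50–60 μm equilibrium points cultures stay single aggregates only up
  to ~1600 μm of slit length and fragment beyond it, (c) the full-scale
  cluster count at a 70 μm equilibrium is 4–5 rather than ~8, and (d)
  disk cultures collapse centrally instead of forming rim rings.  The linear CCDP-peak/equilibrium-point relationship,
  the N-N and A-N force–shell correlations, the astrocyte-shell sorting
  and the contraction–composition trend are all reproduced; the weaker
  N-A correlation is not (measured near zero instead of moderately
  negative).  The
  corresponding tests assert the published values and are expected to
  fail under this engine; they document the discrepancy rather than hide
  it.
* Gravity (1e-4 μm/step) and surface adhesion (S = 0.01) are retained at
  their stated values but are dynamically negligible against cell–cell
  force sums in this reading.
* The depth profile is column-based; fully overhanging surfaces are
  attributed to the column's top cell.
* `segment_baseline_profile` defines "inactive" via the 3σ burst-mask
  complement; manual inactive-period selection is not reproduced.
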