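# Methods

This note records the models, the numerical choices, and the reasoning
behind the design decisions in `mesochrom`. It is the authoritative
description of what the package computes; the README shows how to run it.

## 1. Confined two-type chromatin polymer

### Model

Chromatin is represented as a single bead-spring chain of `N` beads inside
a rigid spherical cavity (the nucleus or a dense sub-nuclear region). Each
bead is either euchromatin (EC/A, diameter `sigma_AA` = 18 nm ~ 6
nucleosomes ~ 1.2 kbp) or heterochromatin (HC/B, diameter `sigma_BB` =
25 nm ~ 16 nucleosomes ~ 3 kbp; the 25 nm figure follows from reading the
smallest ~50 nm observed domain as a tetrahedron of four equidistant
beads). Composition is 55:45 A:B.

Reduced units: length `sigma_AA`, energy `e = k_B T` (4.28 pN nm at
310 K), viscosity `eta* = 1` (1.5 cP physical), and the derived time unit
`tau = eta sigma_AA^3 / (eta* e)` (~2.0e-3 ms at the defaults; the unit
system accepts an explicit override because the literature also quotes a
~14x smaller value whose underlying length scale is unclear).

Four interactions:

* **Soft blob exclusion** between all pairs within `3 sigma_ab`:
  `eps_vex exp(-alpha_vex r^2 / sigma_ab^2)`, defaults `eps_vex = 10 e`,
  `alpha_vex = 4`. Coarse-grained chromatin blobs may interpenetrate, so
  there are no hard cores; overlaps are penalised, not forbidden.
* **FENE springs** between chain neighbours:
  `-12 k r0^2 ln[1 - (r/r0)^2]`, defaults `k = 1 e/sigma^2`,
  `r0 = 1.5 sigma_ab`. Together with the exclusion this sets a bond rest
  separation below `sigma_ab` (soft blobs interpenetrate).
* **Heterochromatin affinity** between HC/B pairs:

      h_HC(r) = -eps_HC (r/d_B)^2 exp(-alpha_HC (r - d_B)^2),

  truncated at `3 sigma_BB`. The quadratic prefactor makes the attraction
  vanish at zero separation (paired with the soft core, this avoids a
  spurious bound state at full overlap); the well minimum sits just
  outside the optimal separation `d_B = sigma_BB` with depth ~`eps_HC`;
  `1/sqrt(alpha_HC)` is an independent range parameter. `eps_HC` is the
  biological control knob: 3 e maps to the control condition, 2.5 e to
  G9a-inhibition-like disruption, 2 e to ROS-like disruption.
* **Wall**: repulsive truncated-shifted Lennard-Jones (WCA) on the
  bead-wall distance, zero beyond `2^(1/6) sigma_i`, `eps_wall = 1 e`.

The affinity functional form deserves a note. The attraction must (i)
vanish at the origin, (ii) have an interior minimum at an optimal HC-HC
separation, and (iii) be short-ranged. Requirement (iii) is not cosmetic:
a well whose range is tied to its position (as in a pure
`r^2 exp(-alpha r^2)` family, where the minimum *is* the range) produces,
at any depth that clusters at all, complete condensation of every HC bead
into a single droplet — verified directly at N = 500 across exclusion
strengths 10-100 e and both sequence models. A single condensate
contradicts the defining phenomenology of this system: many mesoscale
domains with a size distribution, slow (logarithmic) energy relaxation,
and a cluster-connectivity network near the 3D isostatic point. The
Gaussian well of width `1/sqrt(alpha_HC)` centred at `d_B` decouples range
from position and, at sub-bead widths, produces the arrested multi-domain
regime.

### Sequence model

`build_initial_chain` supports two type assignments: an exact-count
seeded shuffle (i.i.d.-like), and alternating geometric blocks with mean
B-block length `mean_block_B` (A blocks scaled to preserve 55:45).
Contiguity matters: each HC/B bead is only ~3 kbp, while heterochromatin
is contiguous over tens of kbp, so runs of consecutive B beads are the
faithful reading. With i.i.d. assignment the A spacers between B runs are
1-2 beads long, which tethers all clusters into one interdigitated
aggregate; with blocks, the long A spacers separate the clusters in
space, reproducing domain-to-domain separations in the experimental
range. The scaled study conditions use geometric B blocks of mean 8 beads
(~24 kbp heterochromatin stretches).

### Integration

Overdamped Langevin dynamics, Euler-Maruyama, timestep `1e-4 tau`:

    x <- x + F/gamma_i dt + sqrt(2 k_B T dt / gamma_i) xi,

with Stokes drag `gamma_i = 6 pi eta (sigma_i/2)` (the noise coefficient
is the standard Euler-Maruyama discretisation with per-step variance
`2 k_B T dt / gamma_i`; dimensional consistency requires the `sqrt(dt)`).
Forces come from an exact Verlet-list evaluation (list cutoff = pair
cutoff + 0.4 sigma skin, rebuilt when any bead has moved half a skin;
list-based energies match an all-pairs evaluation to 1e-10). A FENE bond
at or beyond `r0` aborts the run with the offending bead index.

Steady state is declared by a sliding-window linear fit of the per-bead
potential energy vs time: the earliest window spanning >= 20% of the
trace whose least-squares slope is below `plateau_tol` marks the start of
the steady snapshots. The default tolerance is a strict 1e-4 e/tau,
appropriate for fast-relaxing weak-affinity runs; the control-affinity
relaxation is logarithmic and nowhere strictly flat, so the scaled
cluster analyses pass 5e-2 e/tau — the fluctuation scale of the N = 500
energy trace — to mark the quasi-stationary window (the measured cluster
statistics are constant across it).

### Observables

* **MSD** per bead type, averaged over beads and all steady-state time
  origins (time-origin averaging is a statistics improvement over a
  single origin; the curve metadata flags it).
* **Overlap function** `Q(t)`: fraction of beads displaced less than one
  (type-specific) bead diameter over a lag; the step function is strict
  (`theta(0) = 0`), so a displacement exactly one diameter counts as
  moved.
* **Confined g(r)**: pair-distance histogram normalised by
  `rho x V_shell`, with `V_shell` the *exact* (closed-form) volume of the
  intersection between each spherical shell around each reference bead
  and the cavity. There are no periodic images; the naive unbounded-shell
  normalisation underestimates g(r) at large r by 2x and more.
* **Clusters**: HC/B pairs within a bond cutoff are bonded; the cutoff
  defaults to the first minimum of the pooled steady-state g_BB(r)
  restricted to r >= 0.5 sigma_BB (the soft cores allow a small
  population of fully-overlapped pairs whose g(r) spike would otherwise
  masquerade as the first peak), with fallback 1.5 sigma_BB. Beads with
  >= 3 bonded HC neighbours are core; clusters are connected components
  of core beads; bonded non-core B beads join their nearest component as
  halo members. Size statistics are reported for core+halo (default) and
  core-only membership. Reported clusters have >= 4 members (the
  smallest-domain/tetrahedron argument). The volume-equivalent diameter
  is `(sum_i sigma_i,nm^3)^(1/3)` — the same volume-based definition as
  the experimental `D_eff`.
* **Coordination number z_c**: two clusters are neighbours when at least
  one chain segment runs from a member of one to a member of the other
  without passing through a third cluster (walking the chain in index
  order); multiple connecting segments count once. A cluster whose
  nearest member is within `sigma_BB` of the wall gains exactly one
  contact. `z_iso = 6` is the isostatic reference in 3D.

### Scaled study conditions and calibration

Desk-scale runs use N = 500 beads (scaled down from 3000) at reduced
number density N/V = 0.2 (the density and the "~1 um cavity" statement
in the source literature are mutually inconsistent at N = 3000; the
density is the binding choice, making the N = 500 cavity radius 8.42
sigma ~ 151 nm). The supplementary parameter table of the source study
is not public, so the free shape parameters were calibrated *once*
against the qualitative control-condition phenomenology (spatially
separated mesoscale clusters at domain-scale sizes, slow relaxation) and
then frozen: `alpha_HC = 16` (well width ~ sigma_BB/4), geometric B
blocks of mean 8. The affinity ladder eps_HC = 2, 2.5, 3 and every other
constant above are fixed by the study design, not by calibration.

Finite-size caveat — read before interpreting scaled results. With only
~225 HC beads the system holds 1-4 clusters at its quasi-stationary
state, and seeds differ qualitatively: some arrest with 2-4 separated
clusters at domain-scale sizes (~80-115 nm volume-equivalent diameter,
centroid separations ~100-130 nm), others coarsen into a single
condensate (~155 nm). Per-cluster means pooled over seeds therefore sit
above the full-scale typical domain size, and connectivity-derived
quantities are bounded by the cluster count: the coordination number
z_c, which counts distinct chain-linked neighbour clusters (plus a wall
contact), cannot approach the isostatic value 6 with fewer than seven
clusters in the cavity. Likewise the measured MSD mixes internal
dynamics with rigid-body motion of the few large structures (effective
intermediate-lag exponents ~0.6-0.7 for EC/A rather than the asymptotic
polymeric 1/2). These are properties of the N = 500 scale, not of the
method: the package reports what the scaled system actually produces.

## 2. Tomographic quantification

* **Threshold**: `theta = min(LAC) + 0.6 (max(LAC) - min(LAC))` over the
  raw voxels of the heterochromatin mask (no pre-smoothing; the min/max
  are taken on raw values).
* **Watershed**: Euclidean distance transform of the thresholded
  foreground; markers at its local maxima with minimum separation 2
  voxels; basins merged when the deepest point of their shared boundary
  reaches 0.8x the smaller peak value — candidate merges are processed
  in descending boundary depth with the group maximum tracked, so a
  shallow saddle basin joins its deeper side without transitively
  bridging two genuine domains. Domains under 8 voxels are discarded.
* **Missing wedge**: `f_mw = D_rec / D_fid` from fiducial spheres;
  applied as an isotropic volume factor inside
  `D_eff = (6 f_mw V_seg / pi)^(1/3)` and as a z-rescaling of centroids
  before distance computations.
* **Pair correlation / coordination number** of domain centroids: the
  same confinement-corrected estimator as the polymer g(r) (bounding
  sphere from the region radius or volume); `r2` is the first local
  minimum of the 3-bin-smoothed g(r) beyond its first maximum; `z = 4 pi
  rho integral r^2 g dr` from `r1` (mean domain radius) to `r2` by
  bin-sum quadrature (robust to single-bin lattice peaks; empty shells
  count zero). On an FCC lattice sampled to a sphere this recovers
  z = 12 within a few percent.
* **Size-distribution fit**: maximum-likelihood skew-normal with a
  bootstrap CI on the shape parameter alpha.
* Voxels are 13 nm (2197 nm^3); centroids are voxel centres
  `(index + 0.5) x 13 nm`. Volume I/O is TIFF stacks.

## 3. Tilt series, SIRT, FSC

The forward model is parallel-beam line integration about the y (tilt)
axis, implemented as a per-angle sparse matrix with bilinear weights in
[0, 1] (0.5-voxel ray sampling); its transpose is the exact adjoint.
Default angles -65..+65 degrees in 1-degree steps (the experimental
missing wedge). SIRT iterates `x <- x + C A^T R (b - Ax)` with inverse
row/column-sum normalisation, 20 iterations by default, non-negativity
clamp, and a divergence guard (abort after 3 consecutive residual
increases). The missing wedge elongates reconstructed spheres along z,
which is what the fiducial-based `f_mw` measures.

FSC: even/odd split of the tilt series by index, shell-wise normalised
cross-correlation of the two reconstructions' Fourier transforms in
unit-width shells to Nyquist, correction `FSC' = 2 FSC/(FSC+1)` for
half-series noise, resolution = half-pitch at the first crossing of the
criterion (default 0.5 on FSC'; 0.143/half-bit available). The
experimental 31 nm half-pitch figure requires the beamline tomograms and
is out of scope here.

## 4. Registration

Boundary-based similarity registration (isotropic scale, rotation,
translation): ordered contours of each mask (sub-pixel marching squares,
dominant component), coarse initialisation from centroids and
second-moment principal axes (both axis polarities tried), Nelder-Mead
refinement of the symmetric mean nearest-neighbour distance between
boundary point sets (log-scale parameterisation keeps scale positive).
The residual after alignment is reported in pixels and physical units;
residuals above 5 px flag a low-confidence result.

## 5. Classification

Features are z-scored, PCA is fit on the training split only (first 12
components by default), LDA runs on the PC scores with a stratified 60%
training split (resplit until every class is present; singular scatter
triggers lsqr+shrinkage, reported). Per-class 95% confidence ellipses in
the first two LDs use the small-sample multivariate-t (Hotelling)
radius `r^2 = p(n-1)/(n-p) F_{p,n-p}(0.95)`. The Random-Forest
validation tunes the tree count on out-of-bag accuracy over
{50, 100, 200, 400} and keeps features whose permutation importance
(impurity importance available as an alternative) exceeds 40% of the
maximum. Mann-Whitney U tests use scipy's exact small-sample
distribution.

## 6. Synthetic data

The phantom generator emulates the two-phase heterochromatin volumes:
dense spherical domains (per-domain LAC uniform in 0.15-0.27 1/um) with
truncated skew-normal diameters (location 55 nm, scale 35 nm, alpha 4,
truncated to 30-250 nm; mean ~80 nm) placed without overlap inside a
spherical heterochromatin region whose surround is uniform 0.10-0.15;
the euchromatin background outside is a low-skewed triangular draw over
0.05-0.22 so compartment medians order dense > surround > background.
Optional additive Gaussian noise and an ellipsoidal z-stretch (for
missing-wedge tests). Ground truth (centres, diameters, LACs) ships with
every realisation.

What the phantoms do *not* emulate: reconstruction artefacts (streaks,
rings), correlated noise, nucleoli and membranes, partial-volume blur,
and irregular (non-spherical) domain shapes. Pipeline-recovery results
on phantoms therefore validate the measurement chain, not the biology.

Labelled feature tables plant class-mean shifts of `effect_size` pooled
SDs along a class-specific random direction (4 conditions: control, TSA,
G9a, ROS); mask pairs warp a harmonic nucleus-like blob through a known
similarity transform with anti-aliased re-binarisation.

## 7. Known limitations

* The scaled polymer system (N = 500) cannot reproduce connectivity
  statistics that require tens of clusters; see the finite-size caveat
  above.
* The affinity functional form is this package's own (documented above);
  absolute energies are not comparable to other implementations of the
  same ideas, though the eps_HC ladder and all trend results are.
* SIRT accuracy on hard-edged phantoms is limited by the bilinear
  projector's model mismatch (~6% RMSE at 50 iterations); band-limited
  phantoms reconstruct to <1%.
* The registration cost is a local optimisation; rotations near 180
  degrees rely on the two-polarity initialisation and may need the
  low-confidence flag consulted.

* A dynamics caveat at desk scale: with single-digit cluster counts, the
  measured MSD mixes internal (Rouse-like) motion with rigid-body
  diffusion and rotation of the arrested clusters and with residual
  coarsening advection; effective intermediate-lag exponents come out
  ~0.6-0.7 for EC/A beads (and above 1 for HC/B) rather than the clean
  polymeric 1/2 expected — and reported by the full-scale system — once
  many clusters average the collective modes away. The A-below-B
  mobility ordering and its disappearance at vanishing affinity are
  scale-robust and are what the tests assert quantitatively.
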