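# Methods

## Problem and model

A 3D Cartesian MRI acquisition phase-encodes along two axes (`k_y`, `k_z`)
and can be accelerated by sampling only every `R_y`-th and `R_z`-th line of
each, leaving `R_y·R_z − 1` missing samples in every block of the acquired
lattice. GRAPPA-type reconstruction estimates each missing sample
`S_i(k + r)` as a linear combination of acquired neighbouring samples over
all `J` coil channels,

    S_i(k_x + r_x Δk_x, k_y + r_y Δk_y, k_z + r_z Δk_z)
      = Σ_j Σ_{(s,p,q) ∈ Ω} W_{i,r}(j, s, p, q) ·
        S_j(k_x + s Δk_x, k_y + p R_y Δk_y, k_z + q R_z Δk_z),

where Ω is the kernel's source-offset set and the weights `W` are fitted on
a centred, fully sampled autocalibration (ACS) block by linear least
squares: target and source samples are gathered into matrices and
`S_tgt = S_src W` solved for `W`. Synthesis slides the fitted weights
across the acquired lattice.

## Kernel families

Four kernel families are implemented, differing only in Ω and in how many
block targets one application serves:

* **LK** (lowest-dimensional): two 1D kernels whose two sources bracket the
  target along `k_y` or `k_z`, plus a 2D kernel using the four lattice
  corners of the block cell. One weight fit per target offset.
* **EX** (extended): the 1D kernels widened to three lattice columns in the
  orthogonal phase-encoding direction (2×3 and 3×2 in-plane footprints);
  the plane kernel is unchanged. One fit per target offset.
* **SK** (square): the intersection of the EX footprints over all block
  targets — the 2×2 lattice square containing the block — fitted jointly
  for all `R_y·R_z − 1` targets at once.
* **BK** (boomerang): the union of the EX footprints — the 3×3 lattice
  neighbourhood minus the one corner no EX kernel touches — also fitted
  jointly for the whole block. It sees the most acquired data per fit,
  which is why it resolves aliasing best, while joint-block synthesis keeps
  its memory footprint below EX's.

Every family can be *expanded* along the fully sampled readout axis
(`n_x = 3`), replicating the in-plane sources at readout offsets −1, 0, +1.

### Orientation (`type_index`)

The square and boomerang kernels admit four orientations, corresponding to
the four quadrants around the central acquired point in which the
reconstructed block can sit. We define type 4 as the canonical geometry —
the block extends toward +`k_y`, +`k_z`, and the excluded boomerang corner
is (−1, −1) in lattice units — and types 1–3 as its reflections about the
block anchor (type 1 flips both axes, type 2 flips `k_y`, type 3 flips
`k_z`). Reflections are applied to sources and targets together, so sliding
coverage of the missing lattice is complete for every type. The four types
are algebraically equivalent up to reflection; type 4 is the default.

## Numerical choices

* **Solver.** Weights are obtained with an SVD-based least-squares solve
  rather than by inverting the normal equations; the two agree for
  full-rank systems (asserted in the tests against an explicit
  normal-equations oracle) and the factorised solve is numerically safer.
  Rank-deficient systems return the minimum-norm solution with a warning.
  No regularisation is applied by default; a relative Tikhonov damping
  (`ridge`, as a fraction of the largest singular value) is available for
  ill-conditioned user data.
* **Calibration anchors** step by one sample along the readout and by
  `R_y` / `R_z` along the phase-encoding axes, aligned with the acquired
  lattice (the ACS block is centred on DC, which itself lies on the
  lattice). This makes the calibration geometry congruent with the
  synthesis geometry; a kernel relation that holds exactly on the lattice
  is then recovered exactly (the planted-weight tests rely on this).
* **Column ordering** in all gathered matrices is source-offset-major,
  channel-minor, fixed by the geometry's sorted offset list, and identical
  in calibration and synthesis.
* **Grid borders.** Synthesis processes anchors one block beyond each grid
  edge so that border samples receive estimates. Border sources are
  gathered *periodically* by default: the container stores centred DFT
  spectra, which are periodic by construction, so wrap-around gathering is
  exact for simulated data and measurably better at small grid sizes,
  where the object's spectral tail still carries energy at the band edges.
  `boundary="zero"` switches to zero-filled reads, the usual convention
  for windowed (non-periodic) scanner acquisitions.
* **Degenerate inputs.** `R_y = R_z = 1` reconstructs nothing and returns
  the input; an ACS smaller than a kernel footprint raises an error naming
  the minimal extent; an empty ACS is rejected at extraction.

## Coil and phantom simulation

The simulator emulates a clustered loop head array: four clusters at 90°
intervals on the cylinder circumscribing a 28 cm cubic volume of interest,
each cluster holding loops of 7.2 cm diameter stacked 1 mm apart along the
cylinder axis, normals pointing at the centre. The defaults give the
12-channel (4 × 3) configuration; the desk-scale profile uses 8 channels
(4 × 2). Per-channel sensitivities come from the Biot–Savart law with each
loop discretised into 128 straight segments (centre and on-axis fields
match the analytic circular-loop formulas to 0.1 % at this resolution);
the complex sensitivity is `B_x + i·B_y`, the transverse receive-field
convention, which provides the nontrivial phase that calibration needs.
Voxel–conductor distances are floored at half a voxel to regularise
near-singular contributions.

The numerical phantom is a sum of constant-intensity ellipsoids (a
head-like nested arrangement by default) rasterised on the image grid.
Fully sampled k-space is the centred unitary FFT of the
sensitivity-weighted phantom. Optional complex white Gaussian noise is
calibrated so that `10·log10(signal power / noise power)` equals the
requested SNR, with signal power averaged over the nonzero support
(sensitivity maps) or all samples (k-space); the full-scale profile uses
30 dB, applied to the sensitivity map before the forward transform.

What the simulation does *not* model: coil coupling and loading, field
inhomogeneity, relaxation and sequence weighting, and the non-periodic
windowing of real acquisitions. Passing trend tests on this generator
therefore demonstrates correct algorithm behaviour under the linear
multi-coil model, not performance on scanner data.

## Sampling and evaluation

Undersampling masks are the union of a DC-anchored lattice and a centred
ACS block; "excluding the reference lines" replaces ACS-only samples with
their kernel estimates in the final k-space (grids stay congruent), so
comparisons reflect kernel performance alone. Reconstruction quality is
the per-channel complex nRMSE

    nRMSE = sqrt( Σ |I_full − I_recon|² / Σ |I_full|² ),

averaged over channels, over the whole volume and over an "undersampled
edge" region: the Laplacian-of-Gaussian edge set (σ = 2 voxels, threshold
0.1 of the peak response by default; both configurable) of the
root-sum-of-squares reference image, decimated along the two
phase-encoding axes by `(R_y, R_z)` through the DC-anchored lattice. Mask
decimation — rather than edge detection on a decimated image — is our
reading of "undersampled edges"; both interpretations agree on which
algorithm ranks where in our experiments.

## Problem sizes and defaults

The shipped desk-scale profile runs a 64³ grid with 8 channels, R = 2×2
and a 16×16 ACS; the sweep sizes used in the tests are ACS 16/24/32 with
basis and expanded kernels. These sizes keep a full four-algorithm sweep
in the tens of seconds while preserving every qualitative result of the
full-scale protocol (192³, 12 channels, ACS 24–48), which remains
available through the `full` profile. At desk scale with 30 dB
sensitivity noise under the support-wide SNR convention, noise rather
than model error dominates the scores and the kernel ordering is no
longer resolved; the noise-free desk-scale comparison isolates model
error and reproduces the expected ordering (BK best, then EX, SK, LK).

## Cost model

The complexity module implements the closed-form memory-allocation and
arithmetic-operation counts per kernel (see the module docstring for the
formulas), with the target multiplicity entering the second calibration
term and the synthesis-arithmetic term for the block-simultaneous SK/BK
kernels. `N_f` and `N_rec` are free parameters of the model; kernel
source/target counts are derived from the actual geometries.

## Known limitations

* Lattice sampling only: no CAIPIRINHA shifts, partial Fourier or
  variable-density patterns.
* The coil placement is a documented approximation of a clustered head
  array; exact cluster coordinates of any particular commercial coil are
  not reproduced.
* LK/EX weight granularity is one fit per target offset; a joint fit per
  class is conceivable but not implemented.
* Acceleration factors beyond 8 and kernels wider than three lattice
  columns are out of scope.
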