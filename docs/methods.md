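# Methods

## Signal model

A saturation-recovery readout at delay *t* (ms) with repetition time *TR*
(ms) is modelled as

    S(t) = S0 · [ 1 − (1 − B) e^(−t/T1) − B e^(−t/TR) / (1 − B·C·e^(−t/TR)) ]

with S0 the net equilibrium magnetization (arbitrary units), T1 the
longitudinal relaxation time (ms), B the cosine of the effective saturation
flip angle and C the cosine of the excitation pulse. C is fixed to 1
throughout, which removes one degree of freedom; B = 0 (perfect saturation)
reduces the model exactly to the textbook form S0·(1 − e^(−t/T1)), and this
identity is enforced by test. Rates are R1 [s⁻¹] = 1000 / T1 [ms], the
contrast effect is ΔR1 = R1_post − R1_pre, and a contrast agent at tissue
concentration C_Gd (mmol/L) with longitudinal relaxivity r1
(L·mmol⁻¹·s⁻¹) raises the rate by exactly r1·C_Gd.

An important regime restriction follows from the model itself: the fitting
layer works on magnitude images and assumes the recovery signal is
non-negative (no polarity restoration). For the canonical delay scheme
(77, 200, 350, 500, 1200 ms at TR 1500 ms) and physiological T1 of
1000–2000 ms, S(77 ms) dips below zero once B exceeds roughly 0.15. All
defaults therefore keep B ≤ 0.15; pushing the B1 field beyond that both
violates the model assumption and injects a strong Rician-folding bias into
the fit.

## Pixel-wise fitting

Per-voxel parameters are estimated by bounded Levenberg–Marquardt least
squares with analytic Jacobians, vectorised over voxels: the damped normal
equations of every active voxel are assembled and solved in one batched
3×3 (or 2×2) linear solve per iteration, with an individual damping
parameter per voxel. Implementation choices that matter:

- **Bounds**: S0 ≥ 0, T1 ∈ [1, 10000] ms, B ∈ [0, 0.99], enforced by step
  projection.
- **log-T1 parameterisation**: steps in T1 are multiplicative (capped at a
  factor e per iteration), so the solver cannot tunnel through the flat
  e^(−t/T1) plateau at tiny T1 in a single overshooting Gauss–Newton step.
- **Multi-start**: the (S0, T1, B) landscape has a curved T1–B trade-off
  valley; the solver is restarted from a small fixed set of initial points
  (default init S0 = max signal, T1 = 1000 ms, B = 0.1; alternates at
  (400 ms, 0.05), (1500 ms, 0.35), (1000 ms, 0)) and the per-voxel
  minimum-cost solution is kept.
- **Active-set polish**: a solution grazing a B bound zigzags under
  projected steps; such voxels are refit with B pinned at the bound.
- **Convergence**: relative cost decrease ≤ 1e−8 on an accepted step, or a
  vanishing step; at most 200 iterations, after which the voxel is flagged
  unconverged rather than raising.

On noiseless curves the solver recovers its generator to machine precision
and matches an exhaustive (T1 × B) grid search; on noisy curves its
residual is never worse than scipy's bounded trust-region solver started
from the same points (both checked in the test suite).

### Multi-pass B smoothing

Because B reflects the B1 transmit field, it varies slowly in space. Map
fitting therefore proceeds in passes: pass 1 fits (S0, T1, B) freely per
voxel; each later pass (default 3 passes total) replaces B by a mask-aware
mean over the 3×3×3 neighbourhood (radius and in-plane restriction
configurable) and refits only (S0, T1) with B held fixed. Smoothing a
constant B map is a no-op, and on smooth-B1 phantoms the three-pass fit has
lower plaque T1 RMSE than the single-pass fit (paired over seeds, enforced
by test).

### Attainable precision

With five delay points and sigma = S0/50 (SNR 50), the Cramér–Rao bound for
T1 with S0 free and B known exactly is already 7–18% (sd) across
T1 = 350–1000 ms; the free-B fit is considerably worse, and no optimizer
can beat the bound. Voxelwise T1 at this SNR is therefore a ~5–20%
measurement, and quantitative conclusions ride on ROI averages: the mean
plaque ΔR1 over a ~100–500-voxel ROI recovers the ground truth with
relative RMSE around 6% and estimate-vs-truth correlation above 0.99 across
the default cohort. A residual systematic remains at low signal levels —
the Rician noise floor inflates the shortest-delay point, biasing B
slightly low and long T1 high — which shrinks with SNR and largely cancels
in ΔR1.

## Synthetic phantom

The generator emulates one vessel cross-section per animal on a
32×32×16 grid at 0.14×0.14×0.22 mm (the in vivo mapping resolution; the
anatomical volume may be simulated at an integer multiple of that
resolution with a shifted field of view). Geometry is a straight vessel
along the slice axis (lumen radius 0.45 mm, wall 0.16 mm) with ellipsoidal
plaque blobs attached to the wall. Tissue parameters are piecewise constant
per compartment: T1 of 2000 (blood), 1200 (wall), 1000 (plaque), 1400 ms
(background), S0 of 1.0 / 0.8 / 0.9 / 0.25, with ~3% lognormal
between-animal T1 variation in wall and plaque. The B field is a constant
plus one long-wavelength Gaussian bump (B ∈ [0.08, 0.15] by default, length
scale 2.5 mm). Magnitude noise is Rician: the modulus of a complex Gaussian
perturbation with per-channel sigma = noise_sigma · max(S0); the default
noise_sigma = 0.02 corresponds to SNR 50 at full recovery. The agent is
static (a single post-injection state, no kinetics), confined to plaque,
with r1 = 18 L·mmol⁻¹·s⁻¹.

The longitudinal presets place each animal on calibrated ladders: plaque
geometry grows so group-mean total plaque volume follows
0.44 / 0.63 / 1.36 / 1.91 mm³ (progression weeks 9–21) and
1.04 / 1.30 / 1.58 mm³ (regression weeks 13–25; the middle point is
interpolated, the end point scaled from the reported end-stage ratio
between the reversal and progression arms), and the plaque agent
concentration follows ΔR1 targets of 0.28 / 0.5 / 1.06 / 3.29 s⁻¹
(progression) and 0.49 / 0.58 / 1.33 s⁻¹ (regression). Per-animal
variability is a mean-one lognormal pair of latent factors (sd 0.12 on
linear size, 0.5 on uptake) correlated at ρ = 0.6 — advanced plaques carry
more binding matrix, so concentration co-varies with extent; without that
coupling the pooled ΔR1-versus-size correlations collapse well below the
substantial range the cohort is meant to exhibit.

What the generator does **not** emulate: motion, partial-volume mixing
beyond voxelization, coil sensitivity profiles, flow effects in blood,
plaque heterogeneity, or the optics of a stained-surface preparation (the
2D/3D surface-preparation measures are derived from ground-truth geometry
with a 0.25 volume scale for the higher segmentation threshold of that
technique, plus lognormal measurement noise). Passing tests therefore
demonstrate the correctness and internal consistency of the analysis chain
under the stated model, not performance on scanner data.

## Volumetry and ROI transfer

Total plaque volume is the sum of per-slice ROI areas times slice
thickness (equivalently voxel count × voxel volume). Threshold segmentation
keeps voxels at or above a global intensity threshold and discards
connected components (26-connectivity in 3D, 8 in 2D) below a minimum size.
ROI masks carry their grid (voxel size + field-of-view origin in a shared
world frame) and move between acquisitions by exact axis-aligned box
overlap: a target voxel is included when at least 50% of its volume is
covered (a nearest-neighbour mode exists). Transfer on matched grids is the
identity, and round trips lose at most the boundary-voxel layer.

Synthetic readers perturb a reference outline per slice by one voxel of
erosion or dilation (each with probability p/2, default p = 0.7), emulating
manual delineation variability. On the default cohort two such readers
correlate at r ≈ 0.9; this ±1-voxel model cannot produce arbitrarily poor
agreement, so lower interobserver correlations seen in animal studies are
outside its range — a known limitation.

## Statistics

Group summaries are mean ± SEM (sample SD/√n). Between-group comparisons
use the unpaired two-tailed Mann–Whitney U test, with the exact enumerated
null distribution whenever the smaller group has ≤ 8 observations and no
ties (the study's group size is n = 5, where exact inference matters) and
the tie-corrected normal approximation otherwise. Correlations are Pearson
product-moment with the t-transform p-value (n − 2 df) and conventional
strength bands on |r|: strong (0.8, 1], substantial (0.6, 0.8], moderate
(0.4, 0.6], fair (0.2, 0.4], almost non-existent [0, 0.2]. The bands are
half-open at the top of each lower band, so a boundary value such as 0.4
belongs to the weaker category — matching how such values are labelled in
practice.

## Pipeline

One study run simulates every animal (paired pre/post saturation-recovery
series plus anatomical volumes), fits both T1 maps (foreground mask from
the longest-delay volume at 45% of its 99th percentile), forms the ΔR1 map,
outlines the plaque on the anatomy grid, measures TPV there, transfers the
ROI to the map grid for the mean plaque ΔR1, derives the
surface-preparation analogues, and finally computes trajectories, pooled
correlations and interobserver agreement. A single global seed fans out to
per-case seeds via counter-based SeedSequence spawning, so enlarging the
cohort never changes existing animals, and a rerun under the same config is
hash-identical. The default cohort (20 progression + 15 regression
animals) runs in about half a minute on one core; the recovery benchmark
reports per-case and aggregate bias, relative RMSE and estimate-vs-truth
correlations for plaque T1, ΔR1 and TPV.
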