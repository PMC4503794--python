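# Methods

## The two-pool bSSFP signal model

Tissue is modeled as a binary spin bath: a liquid pool (equilibrium
magnetization M0, relaxation times T1f, T2f) and a semisolid pool whose
transverse magnetization decays too fast to observe (T2b ~ 10 µs), carried
as a longitudinal component only. The pools exchange longitudinal
magnetization with forward pseudo-first-order rate k_f (free→bound) and
reverse rate k_b = k_f / F, where F = M0b/M0f is the bound-to-free pool-size
ratio ("bound proton fraction"); detailed balance fixes k_b given F. During
each balanced-SSFP RF pulse the bound pool is saturated at the mean rate

    W = π · ω1rms² · G(0),

where ω1rms is the RMS on-resonance RF amplitude delivering the flip angle
α in the pulse duration t_rf (rectangular envelope: ω1 = α/t_rf) and G is
the absorption lineshape of the semisolid pool evaluated on resonance.

Model conventions, fixed throughout:

- **Instantaneous rotation.** The RF rotation of the free pool is applied as
  a discrete ±α event at the center of the pulse window; bound-pool
  saturation acts over the full pulse duration. Finite-pulse transverse
  relaxation effects (which elevate the true bSSFP signal by up to ~10% at
  the duty cycles used here) are deliberately outside the model for both
  the closed form and the simulator, so that the F = 0 limit reduces
  exactly to the textbook single-pool formula
  S = M0 sin α (1−E1) / (1 − (E1−E2) cos α − E1E2).
- **Signal convention.** Reported signal is the transverse magnitude
  immediately after the rotation.
- **On-resonance, uniform B1.** No off-resonance or B1 error is modeled
  (appropriate for 1.5 T body-coil transmission and flip angles ≤ 40°).
- **Transverse exchange neglected.** The free pool's transverse decay is
  pure T2f; magnetization transferred while transverse is not tracked.
- **Bound-pool constants.** T1b = 1.0 s and T2b = 12 µs by convention (the
  protocol does not constrain them); both overridable.
- **Lineshape.** Super-Lorentzian by default (appropriate for brain tissue),
  Gaussian available. The super-Lorentzian on-resonance value diverges
  logarithmically; it is obtained by quadratic extrapolation from a 1 kHz
  cutoff (nodes at 1.0/1.5/2.0 kHz), giving G(0) ≈ 1.4e-5 s at T2b = 12 µs.

### Two routes to the steady state

The **closed form** treats one TR as a piecewise-constant affine flow:
half-pulse saturation → free interval → half-pulse saturation, with exact
2×2 matrix exponentials for the longitudinal (free, bound) pair, full-TR T2f
decay for the transverse component, and the alternating ±α phase absorbed
as a per-period sign flip. The periodic steady state is the solution of one
3×3 linear system per protocol row, vectorized over voxels.

The **Bloch–McConnell simulator** integrates the same physics by RK4 time
stepping (dt ≤ t_rf/20 in the pulse window) through successive TRs from an
arbitrary initial state until the state change over two periods falls below
1e-9 relative. It shares no algebra with the closed form beyond the
physical model, and serves as the in-repo ground truth: the two agree to
~1e-7 relative over the physiological grid, far inside the 1% acceptance
band. The simulator's step-halving (Richardson) consistency and initial-
state invariance are tested separately.

## T1 mapping and the observed-T1 correction

The 3-point VFA SPGR series (5°/15°/25°, TR 30 ms) is inverted with the
linearized DESPOT1 transform (y = S/sin α against x = S/tan α; slope = E1).
Degenerate voxels (slope outside (0,1), constant signals) are flagged, not
raised. A nonlinear polish is available but off by default — with three
points the closed form is standard and exact on clean data.

A VFA measurement on two-pool tissue sees the *apparent* T1 — the slowest
eigenmode of the longitudinal exchange-relaxation matrix — not the intrinsic
free-pool T1f. The synthetic generator therefore produces SPGR volumes from
the apparent T1, and the qMT fit (default mode `eigen_corrected`) inverts
the relation in closed form at each iterate:

    R1f = R1obs − k_f + k_f·k_b / (R1b + k_b − R1obs).

Self-consistency (slow eigenvalue equals 1/T1obs) is verified to 1e-10.
The alternative mode `observed_as_t1f` uses the measured T1 directly.

## Voxel-wise qMT fit

Bounded nonlinear least squares over (M0, F, k_f, T2f) with an analytic-free
finite-difference Jacobian, fit per masked voxel; deterministic given the
(single, fixed) initialization F = 0.1, k_f = 2 s⁻¹, T2f = 80 ms, M0 from
the peak signal. Bounds: F ∈ [0.001, 0.5], k_f ∈ [0.1, 20] s⁻¹, T2f ∈
[10, 300] ms — physiological brain ranges. scipy's trust-region-reflective
`least_squares` provides the damped (Levenberg–Marquardt-type) step within
box bounds. Non-convergent or degenerate voxels are retained and flagged so
downstream statistics can exclude them explicitly. Noiseless inverse-crime
recovery is exact to ≲1e-10 relative; at protocol SNR 100 the k_f RMSE is
~10% (500-replicate Monte Carlo), improving monotonically with SNR.

## The synthetic study

The phantom is a three-shell ellipsoid (CSF rim, gray ribbon, white core)
on a 32×32×8 grid at 3 mm isotropic (16×16×4 for the raw-signal demos) —
small enough that every calibration study runs in minutes on one CPU while
leaving the cluster geometry non-trivial. Tissue parameters (typical 1.5 T
brain values): gray M0 820, F 0.10, k_f 2.4 s⁻¹, T1f 1.2 s, T2f 90 ms;
white 700/0.16/3.8/0.65/70; CSF 1000/0.01/0.5/3.5/250. Insula-like
ellipsoidal ROIs sit in the lateral gray ribbon of each hemisphere
(~108 voxels each); basal-ganglia-like gray islands sit inside the white
core. Noise is Rician (magnitude of complex Gaussian), σ = mean gray-matter
bSSFP signal / SNR, default SNR 100.

The vaccine condition adds a per-subject Δk_f ~ N(0.3, 0.1²) s⁻¹ uniformly
inside the left insular ROI — a ~12% regional increase, chosen as a
realistic low-grade neuroinflammatory effect detectable but not trivial at
n = 20. The crossover session order is randomized per subject.

**Behavioral generator.** IL-6 is lognormal per condition and timepoint
with means/SDs 1.29/1.70 → 3.74/1.21 pmol/L (vaccine) and 0.97/1.03 →
0.90/0.80 (placebo) — an approximately threefold vaccine response. Fatigue
(VAS): vaccine baseline N(16.18, 12.57²), vaccine change
b0 + b1·Δk_f,i + ε with b1 set by the target explained-variance fraction
(default 0.24 of a 19.4² change variance) and ε rescaled against the
realized sample variance of the signal component — this keeps the
finite-sample mean of the cohort R² close to the target (measured 0.26 over
200 cohorts of n = 20) instead of inheriting the ~+0.02 upward bias of
sample R². Placebo baseline N(22.08, 17.72²), change N(7.52, 17.4²). With
zero noise (target fraction 1) the fatigue change is an exact line in Δk_f.

**Two fidelity levels.** Raw-signal cohorts (forward model + Rician noise,
then VFA + qMT fitting) exercise the full chain and are used end-to-end at
small size (5 subjects, 16×16×4). Replicate-heavy calibration studies
(hundreds of cohorts through the group pipeline) instead use map-level
cohorts: ground-truth k_f maps plus white per-voxel noise (default SD
0.25 s⁻¹ per session) emulating fit error; `calibrate_kf_map_noise`
reproduces this number (~0.23 s⁻¹ at SNR 100) from actual voxel fits.
What the map-level studies do *not* probe: fit-error spatial structure,
Rician bias at low SNR, or any fitting failure mode — those are covered by
the raw-route tests.

## Group inference

Per-subject parameter maps are smoothed (8 mm FWHM Gaussian,
σ = FWHM/(2√(2 ln 2)), mask-renormalized so in-mask constants are
preserved), then compared by voxel-wise paired t (df = n−1; identically
zero differences give t = 0, constant nonzero differences are flagged
invalid). Clusters form one-sided (vaccine > placebo, matching the planned
contrast; two-sided available) at p_voxel = .001 with 26-connectivity.

**Cluster-extent correction.** The null maximum-extent distribution comes
from Monte Carlo simulation (1000 iterations): smoothed unit Gaussian noise
in the mask, re-standardized, thresholded at the z quantile. Because a
smoothed z field slightly overestimates the cluster extents of a t field
with df ~ 19 (measured pipeline FPR 0.027 at nominal 0.05), the pipeline
uses the df-matched variant (each iteration simulates df+1 fields and
thresholds their one-sample t map), which calibrates to FPR ≈ 0.045 over
300 null cohorts; the z-field form remains available and is the default of
the low-level function. The critical extent k* is the smallest extent whose
null exceedance probability is below α = .05 (k* = 9 voxels at the default
geometry; at the ~6× larger voxel count and finer grid of a whole-brain
analysis this threshold scales into the tens-to-hundreds range).

**ROI small-volume FWE** uses sign-flip permutation of the paired
differences (exact enumeration when 2^n fits the budget) against the null
max |t| over the ROI — distribution-free and exactly testable, a deliberate
substitution for parametric random-field FWE. ROI means are taken from the
*unsmoothed* difference maps so the ROI-mean Δk_f estimate is unbiased by
kernel leakage; its 95% CI covers the generative effect at nominal rate.

**Behavioral statistics.** The 2×2 within-subject interaction is computed
exactly as F = t² of the per-subject difference-of-differences (df 1, n−1);
a full repeated-measures ANOVA serves as the test oracle only. Regression
of fatigue change on ROI Δk_f is OLS with the two-sided t-based p.

**Uptake-map contrast logic.** Uptake-like maps (smoothed Gaussian fields
plus an ROI offset — a deliberately simple synthetic stand-in, no tracer
physics) are grand-mean scaled to exactly 50 within the mask, and the
vaccine time contrast is exclusively masked by the placebo contrast at
p < .005 before cluster extraction.

## Numerical choices and degenerate inputs

- Matrix exponentials of the 2×2 exchange blocks use the spectral closed
  form with a series-protected sinh(x)/x near coincident eigenvalues.
- The simulator refuses dt > t_rf/20 and raises after 200k periods without
  convergence.
- All-zero or non-finite voxel signals, invalid T1, and empty masks are
  flagged/warned, never raised mid-volume.
- Ties in cluster peak location resolve to the first maximum in C order;
  cluster lists sort by extent descending.
- All randomness flows through numpy Generators seeded explicitly; every
  pipeline stage is bit-deterministic given its seed, and dataset
  directories written twice with the same seed are byte-identical.

## Known limitations

- The phantom is geometric, not anatomical: no registration error, motion,
  B0/B1 inhomogeneity, or partial-volume mixing at class boundaries.
- Finite-pulse transverse effects and MT exchange of transverse
  magnetization are outside the signal model (see above); absolute signal
  levels therefore differ from scanner data at large t_rf/TR.
- The acquisition protocol's exact 22 (flip, TR, t_rf) combinations are a
  declared package default spanning the stated ranges, not a calibrated
  scanner protocol.
- Map-level cohort noise is white; real fit-error fields have mild spatial
  correlation, which would lower the effective cluster threshold slightly.
- T1b and T2b are fixed, not fitted; errors in these conventions bias F and
  k_f in known, smooth ways and do not affect the within-subject contrast.
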