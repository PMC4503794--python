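# qmtpipe

Quantitative magnetization transfer (qMT) imaging pipeline for studying
inflammation effects on brain microstructure — as a fully synthetic,
testable re-implementation.

Low-grade systemic inflammation (e.g. after typhoid vaccination) produces
fatigue and measurable changes in brain tissue. qMT imaging probes the
exchange of magnetization between free water protons and macromolecular-bound
protons; its forward exchange rate constant k_f (= R·M0^B, the
pseudo-first-order free→bound rate) is sensitive to glial/macromolecular
changes that conventional imaging misses. This package implements the whole
analysis chain for a two-session (vaccine vs. placebo) crossover study of
20 subjects, driven entirely by a synthetic data generator, so every stage —
from the Bloch–McConnell physics to the family-wise-error-corrected cluster
statistics — is quantitatively testable without any scanner data.

## What is implemented

**Signal models** (`qmtpipe.signal_models`) — the binary spin bath (two-pool)
model for balanced SSFP: a free water pool (M0, T1f, T2f) exchanging with a
semisolid bound pool (fraction F = M0b/M0f, rates k_f and k_b = k_f/F) that
is saturated by the RF pulse train at rate W = π·ω1rms²·G(0), with Gaussian
or super-Lorentzian absorption lineshape G. Two independent routes: an exact
closed form (piecewise matrix-exponential periodic steady state) and a
brute-force RK4 Bloch–McConnell time-stepping simulator used as numerical
ground truth (they agree to ~1e-7; acceptance demands < 1%). Plus the
spoiled gradient echo (SPGR) signal for variable-flip-angle T1 mapping.

**Relaxometry** (`qmtpipe.relaxometry`) — linearized DESPOT1 inversion of
the 3-point VFA series (S/sin α vs. S/tan α), and the correction from the
observed (apparent) T1 to the free-pool T1 via the slowest eigenmode of the
2×2 longitudinal exchange-relaxation matrix.

**qMT fitting** (`qmtpipe.qmt_fit`) — voxel-wise bounded nonlinear least
squares for (M0, F, k_f, T2f) from the 22-volume bSSFP protocol (flip angles
5–40°, TR 3.66–5.96 ms, varied RF pulse duration), with the free-pool T1
constrained by the voxel's measured T1.

**Synthetic cohort** (`qmtpipe.synthetic_cohort`) — digital phantom
(CSF/gray/white shells, insula-like and basal-ganglia-like ROIs),
per-subject Δk_f effect injected in the left insular ROI under the vaccine
condition, Rician magnitude noise, and a behavioral table: IL-6 rising
roughly threefold after vaccine and a fatigue change linearly coupled to
each subject's ROI Δk_f (target R² = 0.24).

**Group inference** (`qmtpipe.group_inference`) — 8 mm FWHM masked Gaussian
smoothing, voxel-wise paired t maps, Monte Carlo cluster-extent correction
(1000 iterations), sign-flip permutation small-volume FWE within ROIs,
ROI-mean extraction, OLS regression of fatigue change on ROI Δk_f, the 2×2
within-subject interaction F test, and grand-mean scaling / exclusive
masking for uptake-like maps.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale and
write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py   # phantom + 5-subject raw cohort
python analysis/02_fit_maps.py          # VFA T1 + voxel-wise qMT fits
python analysis/03_group_inference.py   # 20-subject cluster + ROI statistics
python analysis/04_behavioral.py        # IL-6 / fatigue statistics
python analysis/05_uptake_contrast.py   # grand-mean scaling + exclusive masking
```

`03_group_inference.py` prints, for the 20-subject map-level cohort with the
default injected effect (Δk_f = 0.3 ± 0.1 s⁻¹ in the left insula ROI):

```
Monte Carlo cluster-extent threshold (1000 iterations, p_voxel=.001, alpha=.05, df-matched): k* = 9 voxels

Clusters (vaccine > placebo, cluster-forming p < .001):
 label  extent  peak_t  x_mm  y_mm  z_mm  corrected_p  survives
     1     238  12.109  18.0  39.0  12.0        0.001      True

ROI small-volume FWE (sign-flip permutation, max |t|):
  insula_L         peak t =   6.34, FWE p = 0.0010, mean delta-kf = 0.276 s^-1
  insula_R         peak t =  -3.16, FWE p = 0.4407, mean delta-kf = 0.001 s^-1
```

One cluster of 238 voxels (peak t = 12.1) survives the 9-voxel extent
threshold, centered on the left insular ROI; the ROI-mean Δk_f estimate
(0.276 s⁻¹) recovers the realized cohort effect (0.285 s⁻¹), and the
contralateral/deep-gray control ROIs stay null. `04_behavioral.py` reports
the coupled behavioral structure, e.g. IL-6 1.32 → 3.52 pmol/L under vaccine
(interaction F(1,19) = 58.1) and fatigue change regressing on ROI Δk_f with
R² = 0.231 against the 0.24 generator target.

A command-line interface mirrors the stages for file-based use
(`qmtpipe simulate | fit-t1 | fit-qmt | group | behave | report`).

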