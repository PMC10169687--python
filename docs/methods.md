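# Methods

This note documents the analysis model implemented by `eegspatcorr`, the
synthetic data generator used to exercise it, the main parameter choices,
and known limitations.

## 1. Scientific question

Resting-state EEG oscillations (theta 3–7 Hz, alpha 8–12 Hz, beta 17–25 Hz)
have amplitude envelopes that fluctuate on much slower time scales. The
*infraslow* (0.05–0.1 Hz) component of these envelope fluctuations is
spatially correlated across the scalp in healthy participants. The package
quantifies that long-range spatial correlation with a phase-difference
statistic and screens for *region pairs* where the correlation breaks down
in participants with depressive symptoms, then evaluates the best channel
pair as a single-value biomarker with leave-one-subject-out (LOSO)
discrimination.

## 2. Pipeline

For each participant and condition (eyes closed / eyes open, alternating
30 s segments):

1. **Edge trimming.** The first and last 10 s of the recording are dropped;
   condition intervals are shifted and cropped accordingly.
2. **Optional surface Laplacian.** A spherical-spline current source
   density (CSD) transform (Perrin-style; spline flexibility m = 4,
   regularization λ = 1e−5, 50 Legendre terms) reduces volume-conduction
   blur. It is applied by default to file-based input and skipped for
   synthetic input (the generator emulates source-level coupling with no
   volume-conduction forward model).
3. **Carrier band-pass.** Hamming-window linear-phase FIR filters with the
   order rule `7 · floor(fs / f_lo)` (1163 coefficients for theta at
   500 Hz), applied forward–backward for zero phase. The convolutions run
   in the FFT domain; equivalence with direct `filtfilt` is asserted in
   tests to ~1e−15.
4. **Envelope.** The amplitude envelope is the modulus of the Hilbert
   analytic signal of the band-passed data.
5. **Envelope-fluctuation phase.** The envelope is anti-alias decimated to
   10 Hz and band-passed into the infraslow (0.05–0.1 Hz) or slow
   (0.1–1 Hz) fluctuation band with the same FIR rule at the decimated
   rate (1401 taps for infraslow at 10 Hz); the instantaneous phase is the
   Hilbert angle. Decimation is a design necessity: at 500 Hz the rule
   yields a 70 001-tap filter whose padding requirement (three filter
   lengths) no realistic record can satisfy. When a record is still too
   short for the rule-length filter, the tap count is capped at
   `(n − 1) // 3` with a warning (strict mode raises instead). Filter
   transients (half the filter length at each end) are masked out of all
   downstream statistics.
6. **Spatial correlation ψ.** For channels 1 and 2 with envelope-fluctuation
   phases θ1(t), θ2(t):

       ψ(t) = 1 − |θ1(t) − θ2(t)| / π,

   with the difference wrapped into [0, π]. ψ = 1 for identical phases,
   0 for antiphase, and averages 0.5 for independent uniform phases. The
   per-pair summary **Mψ** is the median of ψ(t) over the valid samples of
   one condition's intervals.
7. **Region-pair screen.** Channels are grouped into 8 scalp regions
   (left/right frontal 9+9, temporal 3+3, parietal 7+7, occipital 4+4;
   46 channels of the 60-channel montage take part, 28 region pairs). For
   every (region pair × carrier band × condition) cell, each cross-region
   channel pair's Mψ values are compared between the experimental group and
   controls with a one-tailed Wilcoxon rank-sum test (exact when the
   smaller group has ≤ 8 participants and there are no ties), separately
   for the decrease and increase directions. Benjamini–Hochberg FDR at
   q = 0.05 is applied within each (region pair × direction) family. The
   cell with the largest fraction of significant pairs wins (ties broken by
   smaller minimum p); within it, the channel pair with the smallest
   uncorrected p becomes the biomarker.
8. **LOSO discrimination.** Each held-out subject is assigned to the group
   whose median biomarker Mψ (recomputed without that subject) is closer;
   ties go to the non-target group. Accuracy, sensitivity and specificity
   are reported; two-class chance level is 0.5.

Participants are grouped by Beck Depression Inventory score and clinical
interview: BDI ≤ 7 → Control; BDI ≥ 13 → depressive, split into cMDD
(current MDD), pMDD (past MDD) or None; BDI 8–12 → Unclassified (excluded).

## 3. Synthetic data model

Each channel c of a synthetic recording is

    x_c(t) = Σ_bands [1 + m·cos(2π f_env t + η_c(t))] · cos(2π f_center t + φ_c)
             + σ_n · n_c(t)

with modulation depth m = 0.5, envelope-modulation frequency
f_env = 0.07 Hz (inside the infraslow band), band-center carriers, uniform
random carrier phases φ_c, and unit-variance 1/f noise n_c (flat below
0.1 Hz, σ_n = 0.5). The envelope-modulation phase η_c(t) carries the
ground-truth spatial structure:

    η_c(t) = L(t) + δ_c(t) + s_r(c) · w_pair(t)

* **L(t)** — a latent free phase walk shared by all channels (τ = 120 s),
  giving every envelope a drifting common rhythm.
* **δ_c(t)** — a per-channel Ornstein–Uhlenbeck offset (τ = 30 s) whose
  stationary variance is 1/(2κ), so any two channels' phase difference has
  variance 1/κ — the wrapped-Gaussian match of a von Mises concentration
  κ. The base coupling is κ = 10. κ = 0 is realized as an unbounded slow
  walk (circularly uniform), giving Mψ ≈ 0.5.
* **w_pair(t)** — planted *pair deficits*. A coupling override
  (region_a, region_b, band, condition) → κ_eff adds one shared OU process
  w with variance 1/(4 κ_eff), with sign s = +1 on all channels of
  region_a and s = −1 on those of region_b. The target pair's difference
  then has the full deficit variance 1/κ_eff while pairs joining one target
  region to the rest of the scalp pick up only a quarter of it. Because
  phase differences are transitive, a deficit confined *exactly* to one
  region pair is impossible when both regions stay coupled to everything
  else; the antisymmetric construction is the most pair-specific
  realization available (collateral is half that of independent per-region
  offsets).

Per-band, per-condition phase processes are generated independently and
stitched over the alternating condition schedule, so a deficit can be
specific to one band and one condition.

The default cohort is 10 Control, 5 cMDD and 5 pMDD participants, 300 s
each (10 × 30 s alternating segments). Planted effects: cMDD — left
frontal–left temporal, theta, eyes closed, κ_eff = 2 (vs base κ = 10);
pMDD — left–right occipital, alpha, eyes open, κ_eff = 2. Per-participant
seeds derive from the master seed via `numpy.random.SeedSequence`, making
cohorts bit-reproducible.

## 4. Design choices

* **Wrapped difference.** |θ1 − θ2| is wrapped into [0, π] before the
  linear map, so ψ is symmetric, invariant to a common phase shift, and
  continuous across ±π.
* **Montage.** Electrode positions come from the standard 10-05 template,
  least-squares sphere-fitted and projected to the unit sphere. Only the
  angular configuration matters (the spherical-spline Laplacian); head
  size does not.
* **Partial deficit (κ_eff = 2, not 0).** With κ_eff = 0 both target
  regions decouple from everything, making the winning-cell ranking among
  all cells containing either region ambiguous; a partial deficit keeps
  the disruption preferentially on the target pair.
* **Statistics are bought, oracles are owned.** Rank-sum p-values come from
  `scipy.stats.mannwhitneyu`, FDR from `statsmodels`; the test suite checks
  both against independent brute-force oracles (full rank-set enumeration;
  literal step-up definition).
* **Envelope zero-mean.** The band-passed fluctuation is DC-suppressed by
  the filter, but its finite-window mean is dominated by the partial-cycle
  residue of the narrowband content, O(1/(T·f_lo)) of its s.d.; tests
  assert strong DC suppression rather than an unattainable exact zero.

## 5. Limitations

* The synthetic generator models envelope-phase coupling directly at the
  "source" level; it has no volume-conduction forward model, no artifacts
  (blinks, muscle), and stationary band power. It validates the analysis
  machinery, not the physiology.
* The wrapped-Gaussian ≈ von Mises correspondence is exact only in the
  large-κ limit; for moderate κ the pair-difference concentration deviates
  slightly from the nominal value. Monotonicity of Mψ in κ is what the
  analysis relies on, and that is tested.
* Collateral coupling loss on pairs adjacent to a planted deficit is
  unavoidable (transitivity); screens on small cohorts can flag such
  neighboring cells, as real-data screens would.
* The exact rank-sum path requires tie-free data; tied Mψ values fall back
  to the tie-corrected normal approximation, which is approximate for very
  small groups.
* LOSO with the median-closeness rule uses a single biomarker value per
  subject; no multivariate classifier is fitted, by design.
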