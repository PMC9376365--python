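# Methods

This note documents the models, estimators and design choices behind
`alphaconn`: what the synthetic generators emulate, how the EEG and fMRI
features are computed, how the inferential machinery is defined, and where
the genuinely open choices were resolved.

## Synthetic cohort

Each subject carries a genotype (E4+/E4−), an age drawn uniformly on
[26, 79] years (the study population's range; no age distribution beyond the
range is known, so uniform maximizes coverage of the regression tests), a
sex drawn with P(male) ≈ 0.33 (the study's 45:92 ratio), and two ground-truth
generative parameters:

* **true IAPF** = 10.2 Hz + slope(genotype)·(age − 40) + ε,
  ε ~ N(0, 0.8²), clipped to [7, 14] Hz, with slopes −0.010 Hz/yr (E4−) and
  −0.030 Hz/yr (E4+). These defaults reproduce the *sign and ordering* of
  the reported age–IAPF correlations (weaker in non-carriers, stronger and
  more negative in carriers), not their exact magnitudes — no effect sizes
  for the underlying generative process are available.
* **true alpha power**, a dimensionless log-normal amplitude factor
  (log-sd 0.2) multiplying the alpha component.

Age group is a pure function of age with threshold 50 years. Randomness is
drawn from one `SeedSequence` stream per (master seed, subject id, purpose),
so enlarging one group never changes any other subject's data, and every
generator is bit-reproducible.

## Synthetic EEG

Channels are synthesized in the frequency domain: complex Gaussian Fourier
coefficients shaped by

* a 1/f^β background (β = 1 by default) of scale `noise_sd`, and
* a Gaussian alpha profile centred at the subject's true IAPF.

The inverse FFT of such coefficients is a stationary Gaussian process whose
alpha component waxes and wanes with a Rayleigh envelope — an
amplitude-modulated burst process rather than a sinusoid — so IAPF
estimation faces realistic spectral leakage. Alpha amplitude is scaled by a
10–20 topography gain (occipital 1.0 tapering to 0.5 frontally), and
`alpha_peak_snr` is defined as the peak-bin power of the alpha component
over the background power at that bin for a unit-gain channel (default 16,
i.e. per-channel peak SNR between 4 and 16).

**Alpha bandwidth.** The spectral FWHM of the alpha peak defaults to
0.6 Hz. This is the one parameter calibrated against the package's own
recovery requirement: the IAPF estimator works at the native 0.25 Hz bin
resolution without interpolation, and a single 150-s recording carries
irreducible realization noise in each bin (the epoch-averaged periodogram
converges to the *realization's* spectrum, not the ensemble spectrum).
With a 1.0-Hz-wide peak the argmax therefore wanders more than one bin in
~15% of channels regardless of SNR; at 0.6 Hz — still a physiologically
plausible sharp resting alpha peak — at least 95% of channels recover the
true IAPF to within 0.25 Hz at peak SNR ≥ 3, which is the recovery property
the test suite enforces.

What the generator does **not** emulate: eye-blink/EMG artifacts, line
noise, non-stationarity across the session, volume conduction between
channels (channels are statistically independent), and any direct genotype
effect on alpha *power*. The reduced 11–13 Hz relative power in E4+
emerges indirectly, from the genotype-dependent IAPF shift moving spectral
mass out of the high-alpha bins; at the default effect sizes this
reproduces the sign of the group difference but is deliberately not tuned
to reach significance. Passing tests therefore show correctness of the
estimators and inference under a clean generative model, not robustness to
real-world EEG artifacts.

## EEG spectral analysis

1. Zero-phase band-limit to 2–35 Hz (Butterworth order 4, forward–backward).
2. Consecutive non-overlapping 4-s epochs (trailing remainder dropped);
   optional amplitude-threshold epoch rejection at ±100 µV stands in for
   visual artifact editing and is logged.
3. Per epoch and channel, Hann-tapered periodogram (0.25 Hz resolution).
   Bands are half-open [f₁, f₂), so the 33 one-Hz bins of 2–35 Hz partition
   total power exactly; relative powers sum to 1 to machine precision.
4. Logit transform log[x/(1−x)] in natural log — the log base is a free
   scale choice that cancels from every F statistic and p-value computed on
   the transformed values. Inputs outside (0, 1) are clamped to
   [10⁻⁶, 1−10⁻⁶] with a counted warning.
5. Mean over epochs per channel × subband.

IAPF is the argmax of the epoch-averaged spectrum restricted to [8, 13] Hz,
ties broken toward the lower frequency, reported at bin resolution with no
parabolic interpolation (keeps the estimator exactly reproducible); a
maximum on the band edge is flagged as a boundary solution (no interior
alpha peak). Per-channel estimation is the default; topographic averaging
happens downstream in the ANOVA layer.

## Synthetic BOLD and denoising

ROI series are multivariate normal with correlation I + C(genotype); the
sparse symmetric coupling matrix C plants, by default, the positive
interhemispheric visual/parietal/salience edges (+0.20…+0.29) in E4+ and
the negative hippocampus-L ↔ PPC-R (−0.25), parahippocampal–frontal
(−0.17…−0.24) edges in E4− only. Both default matrices are verified
positive definite. Sessions default to 400 volumes at TR 1.5 s (the volume
count is a package choice; it is not part of the published acquisition
description). Shared slowly-varying nuisance components (Gaussian-smoothed
white noise, kernel 8 volumes) load onto both the ROI and the WM/CSF
noise-ROI series; motion is a mean-reverting random walk with occasional
spikes whose standardized traces leak into the ROI signal. There is no
hemodynamic forward model and no image-space processing — the artifact
starts from extracted time series, as the analysis it feeds does.

Denoising regresses each ROI series on an intercept plus the 24-parameter
motion expansion, 10 aCompCor components (top-5 unit-variance principal
component time courses of each column-centred tissue block, ordered by
explained variance), and spike regressors. Framewise displacement is the
Power-style sum of absolute backward differences with rotations scaled by a
50 mm head radius (the displacement formula itself is not specified by the
source analysis and had to be chosen). Volumes with FD strictly above the
within-session 97th percentile are censored — realized as spike regressors
rather than row deletion so the subsequent 0.01–0.1 Hz band-pass
(Butterworth order 2, forward–backward) operates on a regular temporal
grid; connectivity is then computed over uncensored rows only, which makes
censored volumes exactly leverage-free. Residuals are orthogonal to every
design column before filtering (enforced to |r| < 10⁻¹⁰ by one step of
iterative refinement; the motion block's squared terms make a single
projection marginally imprecise). Regression precedes filtering; the
alternative orderings are not equivalent, and regress-then-filter was
chosen as the convention. Fisher z = atanh r is capped at ±6; zero-variance
ROIs yield flagged undefined entries.

A calibration caveat: the variance of null edge z values follows the
textbook 1/(n−3) law only *before* band-pass filtering; filtering reduces
the effective degrees of freedom (roughly threefold at these settings), so
the null-calibration property is tested on unfiltered sessions, while group
inference — which only compares z values across subjects — remains exact
either way.

## Statistical inference

**Split-plot repeated-measures ANOVA.** Univariate mixed-model partitioned
sums of squares: between-subject effects (and covariates, which enter the
between stratum only) are tested against the subjects-within-groups mean
square; each within-subject effect and its interactions with the between
factors are tested against their own effect-by-subject mean square,
computed in a collapsed stratum (data averaged over the other within
factors). Sums of squares are Type III via sum-to-zero coding, so
unbalanced between cells are handled; the within design must be complete.
No sphericity correction is applied — reported degrees of freedom are the
uncorrected univariate ones, consistent with the analysis being mirrored.
Exact reproduction of that analysis' printed error df under the covariate
is not guaranteed, because the original error-term bookkeeping for
covariate-adjusted between effects is not documented; the fitted design
governs here. Constant-data degenerate strata return F = 0.

**Duncan's multiple range test.** Means are ranked; a pair spanning p ranks
is significant iff its difference exceeds
q(1−(1−α)^(p−1); p, df_err)·√(MS_err/ñ), with ñ the harmonic mean of the
two cell sizes and q the studentized range quantile (computed numerically);
standard multiple-range protection applies — a pair can only be declared
significant if every enclosing range is.

**Correlations.** Pearson or Spearman with p from t = r√(n−2)/√(1−r²) on
n−2 df; method selection by a Shapiro–Wilk gate at α = 0.05 on both
margins. Two correlations are compared by Fisher's
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3)) against the standard
normal, one- or two-sided as requested.

**Edge contrasts.** The "paired t-test between genotype groups" wording of
the mirrored analysis is internally inconsistent (the groups are
independent); the implementation is the CONN-style second-level GLM
two-sample contrast on Fisher-z edges — equivalent to the pooled-variance
two-sample t — with beta reported as the raw mean z difference. FDR control
is Benjamini–Hochberg (the specific FDR procedure is unnamed in the
mirrored analysis; BH is the CONN default), applied separately to the
contrast family and to each within-group one-sample family. Bivariate
regression coefficients are not implemented; correlation-based z is the
sole edge measure.

## Pipeline

`alphaconn.pipeline.run` chains cohort → EEG features → EEG inference →
BOLD connectivity → edge inference → EEG–fMRI linkage from a single
validated `RunConfig` (unknown keys rejected; all defaults serialized into
the manifest). The EEG–fMRI linkage correlates each subject's
channel-averaged IAPF with edge z values of the same synthetic individual —
the mirrored study likewise used non-simultaneous EEG and fMRI sessions on
the same subjects. The fMRI subgroup defaults to the first 23 E4− and 14
E4+ cohort members. The IAPF topographic ANOVA uses the 10–20 pairing into
eight scalp regions (occipital O2/O1 … temporal3 F8/F7) crossed with
hemisphere. Stage failures abort with a stage-named error; tables are
written atomically, and the manifest's run hash (SHA-256 over the config
hash and all table hashes) is identical across reruns of the same
seed/config.

ROI identity is a label list only — no atlas files are shipped; the
default label set covers the regions named by the planted couplings and
can be reconfigured freely.

## Problem sizes in the test suite

The acceptance-level checks run at the sizes their properties need:
50 full-length recordings for IAPF recovery; a 20-subject batch for the
spectral partition identity; 100 random balanced toys against the
cell-mean ANOVA oracle and 1000 null replicates for type-I calibration
(16 subjects × 5 bands each); 200 coupling-free and 100 planted-edge
connectome simulations at the study's 23 + 14 subgroup size with the full
default generation and denoising chain; determinism on a reduced cohort
(32 subjects, 40-s EEG, 160 volumes). These sizes are the package's own
balance of statistical resolution against a desk-scale run.

## Known limitations

* The generators produce Gaussian, stationary, artifact-free signals;
  robustness to real EEG/BOLD pathology is untested by construction.
* Subband power differences between genotypes arise only via the IAPF
  shift and are sign-calibrated, not magnitude-calibrated.
* The split-plot ANOVA requires a complete, balanced within design; missing
  cells are rejected rather than imputed.
* Duncan critical values rely on `scipy`'s studentized range distribution,
  which is slow for extreme parameter combinations.
* EDF files can be read (via `mne`) but not written; the text matrix +
  JSON sidecar format is the native interchange format.
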