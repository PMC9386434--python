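# Methods

This note documents the models, defaults, and design choices behind
`infantfmri`, and what the synthetic-data validation does and does not
establish about real infant data.

## Paradigm and design matrices

The block schedule alternates 21 s stimulation blocks with 9 s rests: 8
blocks per category × 4 categories (neutral, positive/laughter,
negative/crying, environmental) = 32 blocks, 960 s.  Category order is a
seeded shuffle constrained to no immediate repeats.  Each block packs 7–11
sounds with inter-sound gaps drawn uniformly from 0.47–0.75 s; per-sound
durations are drawn from 0.9–1.8 s and shrunk proportionally when a draw
would overflow the block.  Sound onsets are recorded (and serialized) but
regressors are block-level boxcars: in a block design the sustained
response, not individual sound events, carries the signal.  Rest is the
implicit baseline; the GLM adds its own intercept.

γ-variate kernels are parameterized as `f(t) = (t/p)^a · exp(a(1 − t/p))`,
which peaks at exactly `t = p` with value 1.  Only peak latencies (4 s and
8 s) are externally specified; the shape default `a = 6p/8` (a = 3 at 4 s)
is a single-knob choice that keeps kernel width roughly proportional to
latency.  Kernels are normalized to unit **peak** amplitude, not unit
integral, so β has the interpretation of peak signal change per unit
regressor.

Design columns are plain discrete convolutions of the category boxcar with
the kernel samples, truncated to the acquisition window.  This keeps two
algebraic contracts exact: a unit-impulse kernel returns the sampled boxcar
itself, and scaling a kernel by α scales its columns by α.  The consequence
— a regressor plateau equal to the kernel sample sum rather than 1 — is
handled by an explicit conversion factor (`plateau_scale`), applied when βs
are reported in percent signal change at block plateau.

## Synthetic cohorts

Ground-truth effect amplitudes are **synthetic choices**, not estimates
from any study (none are published for this design); they were fixed once
for adequate power at 29 subjects/group and are documented here:

| quantity | default | units |
| --- | --- | --- |
| baseline intensity | 1000 | a.u. |
| auditory response, all categories, both groups | 1.0 | % signal change |
| frontal-limbic positive / negative, control | 0.9 / 0.3 | % |
| frontal-limbic positive / negative, PMD | 0.3 / 0.7 | % |
| neutral & environmental in frontal-limbic ROIs | 0.2 | % |
| between-subject amplitude SD | 0.15 | % |
| HRF peak jitter (SD around 4 s) | 0.5 | s |
| AR(1) lag-1 autocorrelation ρ | 0.3 | – |
| thermal (stationary AR(1)) SD | 5 (0.5% of baseline) | a.u. |
| linear drift amplitude over session | up to 10 (1%) | a.u. |

Sessions are simulated as
`y = B·(1 + Σ_c β_c/100 · r_c(t)) + drift + AR(1)` where `r_c` is the
design regressor under the subject's true HRF divided by its plateau, so
`β_c` is exactly the percent block-plateau response.  The AR(1) process is
generated with stationary SD `sigma_thermal` and 50 burn-in frames.  Drift
is a per-voxel linear ramp with random amplitude.  The simulation grid
defaults to 24³ voxels (12³ in most tests) — statistics are per-voxel, so
grid size trades runtime against cluster geometry only; the geometry
metadata still records the protocol voxel sizes (3.5 × 3.5 × 4.0 mm, 2 mm
gap, giving 3.5/3.5/6.0 mm centre-to-centre spacing).

Six box ROIs (auditory, amygdala/parahippocampal, superior temporal,
putamen, orbitofrontal, inferior frontal) are placed at fixed fractional
positions; grids smaller than 12³ are rejected because the boxes would
collide.  Motion defaults to **zero** — the emulated infants sleep — and is
injected explicitly (per-volume rigid resampling, trilinear) where the
realignment stage is under test.  "Corrupted" sessions (infant woke, moved
excessively) get a large mid-session translation and are flagged for the
exclusion logic.

One global seed expands into per-subject seeds through
`numpy.random.SeedSequence`; every stochastic operation takes an explicit
seed and the whole pipeline is bitwise reproducible from its config.

What passing these simulations does **not** show: robustness to real
infant data's unmodelled structure — slice timing, susceptibility and
spin-history artefacts, physiological (cardiac/respiratory) noise,
arousal-state changes, spatially correlated noise, or template
normalization error (the synthetic cohort shares one voxel space by
construction).

## Preprocessing

Realignment maximizes the Pearson correlation of each rigid-transformed
volume with the voxelwise session-mean image, via derivative-free Powell
search over the 6 rigid parameters, with two outer passes (re-average,
re-fit) and a 0.01 mm/° parameter tolerance; a step is accepted only if it
does not lower the objective.  Detrending removes the per-voxel OLS line,
preserving the mean.  Smoothing is Gaussian, 7.2 mm isotropic FWHM by
default, with per-axis sigmas in voxel units (so anisotropic voxels get an
isotropic smooth in mm) and reflective boundaries (preserves local means
on small grids).  Slow spin-history intensity effects are approximated by
realignment + detrending; no explicit spin-history regression is fitted.

The exclusion rule — maximum translation above one in-plane voxel
(3.5 mm, configurable) — is an artifact default, not a literature value.

## HRF estimation and GLM

FIR deconvolution regresses the auditory ROI-mean series on lagged copies
of the all-sounds boxcar (lags 0–24 s at TR spacing) plus an intercept,
with a ridge penalty of `0.01 × mean diag(XᵀX)` (intercept unpenalized;
`ridge=0` gives plain least squares and raises on singular designs).  The
input function is category-agnostic by default — an auditory experiment
produces a dominant auditory response regardless of category — with a
per-category option.  A per-lag FIR coefficient is the response to a
TR-long stimulus bin; comparisons against a known fine-grid kernel
therefore go through `fir_reference` (TR-bin averaging), otherwise a
half-TR phase offset masquerades as error.

The leave-one-out mean HRF peak-normalizes each kernel before averaging
(subjects contribute shape, not amplitude) and renormalizes the mean.  Its
defining property — invariance to arbitrary mutation of the held-out
subject's kernel — is tested directly.

The GLM is voxel-wise OLS with an internally added intercept; percent
scaling divides coefficients by the fitted intercept rather than the
temporal mean, because the temporal mean contains task signal and would
bias β multiplicatively.  With two basis kernels per condition the
per-condition β defaults to the first-basis (4 s) coefficient
(sign-preserving, as needed for signed contrasts); a root-sum-square
alternative exists.  Residual dof is `n_vols − rank(X)`.  The default
pipeline mode fits the single LOO kernel; a two-γ-basis mode is kept for
comparison runs.

## Group inference

Permutation conventions: add-one p values `(b+1)/(B+1)`, two-sided on |t|;
when the requested permutation count covers the full group (2ⁿ sign
patterns, or C(n,k) relabelings) the test switches to exhaustive
enumeration and p is exact.  One set of flips/relabelings per permutation
is shared across voxels, preserving the spatial structure of permuted maps
(required for valid cluster-level nulls).  Zero-variance voxels are
flagged and excluded from FDR input rather than silently assigned p = 1.

Cluster extraction thresholds voxel p at 0.005 (uncorrected), labels
connected components (6-connectivity default; 18/26 available), and drops
components below 3 voxels.  Benjamini–Yekutieli q values (the Σ1/i
variant, valid under arbitrary dependence) are computed over voxel-wise p
within the analysis mask and annotate each cluster; an optional `q_alpha`
additionally gates clustering on q.  Gating is off by default because at
desk-scale permutation counts the p-value floor (1/(B+1)) places a hard
q-gate on a knife edge, and the operating point actually specified by the
emulated analysis is the voxel threshold plus minimum cluster extent.  The
alternative correction path calibrates a cluster-size threshold so that
the expected number of false-positive clusters per null image stays below
a target (default < 1), using null cluster sizes from the same permutation
stream.

Post-hoc ANOVAs (group × sex on cluster-mean interaction contrasts;
SSRI exposure × valence within the PMD group) use classical type-II F
statistics computed by QR projection (verified against
`statsmodels.anova_lm` in the tests), with permutation p values:
Freedman–Lane residual permutation for the interaction, within-stratum
permutation for main effects (exhaustive enumeration available for
two-level factors).

Interaction summaries report per-cluster group × condition cell means of
in-cluster mean β with 95% percentile bootstrap bounds (resampling
subjects within group), plus a direction flag describing the valence
preference ordering; the flag is scale-invariant.

## Problem sizes used in validation

The shipped tests and the acceptance script run at reduced but fully
specified sizes, chosen as the package's own desk-scale defaults: 12³
simulation grids, 320-volume sessions, 500–2000 permutations (with the
exhaustive-enumeration oracle guarding correctness at small n), 20
replicate cohorts of 29 + 29 subjects for the interaction-recovery check,
and 2000 null voxels for the false-positive-rate check.  The production
default for permutations is 40 000.

## Known limitations

- The realignment objective is optimized per volume against the mean
  image; very large motion (several voxels) can fall into local optima —
  the exclusion rule is the guard, as in practice.
- FIR deconvolution at TR = 3 s resolves the HRF only to 3 s bins; peak
  latency differences below the TR are not recoverable per subject (the
  LOO average mitigates, not removes, this).
- BY FDR over permutation p values inherits the p-value floor; with B
  permutations no q can fall below m·c(m)/(B+1)/rank.
- The two-way ANOVA permutation schemes assume exchangeability within
  strata (main effects) and under the additive model (interaction).
- The synthetic effect pattern is a stylized planted truth; power numbers
  transfer to real cohorts only insofar as the noise model does.
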