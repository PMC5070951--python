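# Methods

`crossfreq` analyzes n:m cross-frequency phase synchrony (CFS) between
cortical parcel time series, together with the couplings it must be
distinguished from — within-frequency (1:1) phase synchrony,
phase-amplitude coupling (PAC), and cross-frequency amplitude
correlation — and the confounds that can mimic it (signal-to-noise
changes, linear mixing from source reconstruction).  Because no public
source-space recording accompanies the analysis design, the package
ships a synthetic-study generator whose planted ground truth lets every
statistical claim be checked end to end.

## Spectral decomposition

Broadband trials are filtered with complex Morlet wavelets

    w(t, f) = A · exp(−t² / 2σ_t²) · exp(2iπf t),   σ_f = f/m,  σ_t = 1/(2π σ_f)

with the time-frequency parameter m = 5 (five carrier cycles under the
Gaussian).  The default analysis grid holds 25 log-spaced frequencies
from 3 to 90 Hz (consecutive ratio 30^{1/24} ≈ 1.152); scaled-down
analyses pick the low frequencies they need.  Kernels are truncated at
±5σ_t (Gaussian tail loss < 10⁻⁵), normalized to unit energy so band
amplitudes are comparable across frequencies, and applied by
FFT convolution.  Samples within one kernel half-width of a trial edge
are flagged invalid rather than padded — fabricating phase at trial
edges would leak into the synchrony estimates — and every windowed
statistic excludes them.  Consequence: at 600 Hz a 3 Hz wavelet has a
1.3 s half-width, so the lowest grid frequencies cannot be estimated on
short trials; the shipped trial layout (−1.25 … 1.45 s around stimulus
onset) keeps all four analysis windows fully valid for f ≥ 9 Hz.

## Coupling estimators

For parcels p (slow) and q (fast) with phases θ_p(t, f_low),
θ_q(t, f_high) and n·f_high = m·f_low:

* **CFS**: PLV = |mean over trials×samples of exp(i(m·θ_p − n·θ_q))|,
  unit phasors (amplitude discarded).  n = 1, m ∈ {2…9} for CFS;
  m = n = 1 gives 1:1 phase synchrony.
* **PAC**: the fast band's amplitude envelope is re-filtered at f_low
  and its phase enters a 1:1 PLV against the slow phase.  The envelope
  inherits both bands' edge margins.
* **Amplitude correlation**: Pearson correlation of the two amplitude
  envelopes over the pooled valid observations.

Windows are kept separate through estimation; the group stage decides
how to combine them.  Estimator code is vectorized as phasor matrix
products; unit tests pin every estimator to literal loop-based
evaluations at 10⁻¹⁰.

### Time-shift surrogates

Single-estimate significance uses surrogates in which the fast series
is shifted by a random lag of 0–300 ms, preserving all local features
(spectra, autocorrelation, amplitude distribution) while destroying the
inter-parcel alignment.  Two properties matter in practice and are
measured by `experiments.surrogate_calibration`:

* A 300 ms range spans only ~10 phase-coherence times of one narrow
  band, so a single-series surrogate family is too small for a stable
  99th percentile.  The across-trials estimator shifts **each trial by
  its own lag** (`timeshift_null_plv_trials`), which concentrates the
  surrogate distribution correctly; the threshold's conditional
  coverage still depends on the trial count (~1.7 % empirical FPR at
  10–20 trials, 1.0–1.15 % at ≥ 40), so calibration is assessed at the
  studies' own scale (60 trials, 1 s windows).
* Shifts are linear within a trial that carries the 300 ms margin —
  what shifting a window over a longer recording does.  A circular
  variant (`circular=True`) is kept; its wrap seam slightly
  underdisperses the null.  Thresholds use the non-interpolated upper
  order statistic of the surrogate values.

## Group statistics

Per edge and (f_low, ratio): the **Mean condition** averages coupling
over the six memory loads and the two retention windows (0.4–0.7 and
0.7–1.0 s) and tests it against the first pre-stimulus baseline with a
paired two-sided t-test; the effect size is the mean difference divided
by the SD of the difference.  The **Load condition** is the Spearman
rank correlation of retention coupling with memory load over pooled
subject × load observations.  Trials are equalized across loads (PLV is
biased by observation count) before estimation.

Two multiple-comparison rules are implemented.  The expected-FP removal
rule drops, among edges with p < α, the ⌈α·N⌉ with the largest p — it
controls the expected count of false positives and suits dense
10⁴-edge matrices, but on desk-scale graphs it deletes true discoveries
unconditionally and does not control the false-discovery proportion
(measured FDP 0.39 under the global null at 100 edges).  All shipped
analyses therefore use Benjamini–Hochberg (measured null FDP 0.05–0.06
at α = 0.05); the removal rule remains available as
`fdr_method="expected_fp"`.

Robustness masks retain edges that stay significant in every
leave-one-out cohort and whose effect sizes clear the minimum
detectable effect for the cohort size.  The latter comes from the
noncentral-t power analysis: a two-sided one-sample design with n = 12,
α = 0.05 and power 0.8 requires d ≈ 0.89 (0.9 to one decimal);
the analogous Fisher-z calculation for a correlation over 72 pooled
observations gives r ≈ 0.33.

Connection density K is the fraction of significant edges among the
possible edges (directed low→high pairs for cross-frequency graphs,
unordered pairs for 1:1), per tail.

## Harmonic consistency

C = K̄ · exp(−Σ_m |K_m − K̄| / (N·K̄)) over the N analyzed ratios, with
C = 0 when K̄ = 0.  C equals the mean density when all ratios agree and
decays with dispersion, so isolated single-ratio effects score low.
Significance comes from shuffling K values across low frequencies
independently per ratio column (2000 shuffles, 95th percentile).  With
only three analyzed low frequencies (the demonstration scale) the
shuffle null is coarse and ties with the observed values are common;
the measure needs the full 12-frequency, 8-ratio grid to have
resolution.

## Networks, mixing and hyperedges

Significant edges are pooled across ratios into summary graphs with
per-edge ratio provenance.  Because source-space mixing smears one true
interaction into a cloud of nearby edges, edges are bundled by
average-linkage clustering on the affinity
crosstalk(low₁, low₂) · crosstalk(high₁, high₂) (pairwise parcel
cross-talk, unit self-affinity; dendrogram cut at distance 0.5).
Bundles smaller than 4 edges are dropped, edges below the bundle-median
end-vertex degree are trimmed, and bundles attributable to a single
ratio (permutation test on ratio labels, p < 0.05) are excluded — the
pooled representation should reflect sharing across ratios.  System
structure is summarized as directed system-pair densities against 5000
randomized graphs with the edge count held fixed; hub structure as
Pearson correlations between CFS low/high-end degrees and the 1:1
network degrees at the corresponding frequencies (BH-corrected).

Parcel metadata carries fidelity (reconstruction accuracy), cross-talk
(contamination received) and spread (contamination emitted); parcels
are excluded by the quality score f/(c·s), defaulting to the worst 10 %.
In synthetic studies all three derive analytically from the planted
mixing matrix (row-normalized exponential decay over parcel index
distance).

## Behavior

Capacity is C(l) = HR(l)·l.  A subject's network strength sums their
coupling over the positive-tail Mean-condition edges and the two
retention windows.  Strength and capacity are detrended identically —
subtract the subject's mean over loads, subtract the load-wise
population mean of the centered values, divide by the population mean
absolute centered value — leaving the subject-by-load interaction,
whose Pearson correlation over pooled subject × load points is tested
per low frequency (ratio groups 1:2–1:5 and 1:6–1:9, BH across
frequencies).  Note the detrending removes subject-*level*
associations by construction; only interaction structure (e.g. coupling
load-slopes covarying with hit-rate decline) is detectable.

## SNR-confound audit

Amplitude gains improve phase estimation and inflate PLV without any
change in coupling.  The audit quantifies the expected size of that
artifact per edge:

1. tabulate PLV_sim(c, SNR_x, SNR_y) from simulated coupled pairs
   (10⁵ samples; geometric SNR grid, factor 1.3; common random numbers
   across cells).  The simulated series pass through the same Morlet
   re-filtering as the data — the wavelet narrows the noise band, and
   omitting it makes the surface sit systematically below the data at
   equal nominal SNR;
2. estimate apparent SNR, aSNR = (A_exp − A_noise)/A_noise, from band
   amplitudes against a matched noise-only reference, and map it to
   simulation SNR through the numerically estimated monotone
   aSNR(SNR) relation (PCHIP interpolation in log-SNR);
3. map surface values onto the finite-sample estimator scale with the
   Rice mean at N_eff implied by the measured chance level of off-focus
   edges (asymptotic surfaces cannot be compared to biased estimates
   directly);
4. invert the surface at the initial-condition SNRs for the coupling
   factor c_in, and predict ΔPLV_pred as the (observed-scale) surface
   difference between modulated and initial SNRs at fixed c_in.

On studies with constant coupling and a retention-only amplitude gain,
observed and predicted changes agree (mean excess ≈ 0 within ± 0.08 on
observed ≈ 0.2; the residual tracks the ± 15 % accuracy of the aSNR
estimate itself).  With genuine retention-only coupling and constant
amplitude, the prediction is ≈ 0 and the observed change exceeds it for
every planted edge.

## Synthetic studies

`generate_study` assembles broadband real trials per (subject, load,
trial, parcel): one narrow-band oscillation (Morlet-filtered uniform
white noise, unit mean amplitude) per analysis band, band-matched noise
at amplitude 1/SNR per component, a pink-noise floor (0.2), then linear
mixing.  Planted structure replaces the independent components of the
endpoint parcels:

* **CFS / 1:1** injection is a directional convex additive mixture,
  Y′ = (1−c)·Y + c·A_x·exp(i·n·φ_x): c = 0 leaves the fast series
  untouched, c = 1 locks its phase exactly to n·φ_x, and PLV rises
  monotonically between.  Injection must be directional: the phase of
  a sum of two phasors is a circular midpoint, which breaks the n:m
  ratio relation, and any slow-side phase mixture is amplified m-fold
  by the comparison — no two-sided additive scheme can produce strong
  n:m locking (verified numerically, PLV ≈ 0.14 at c = 1 for a
  symmetric mixture vs 1.0 for the directional form).
* **PAC** multiplies the fast amplitude by 1 + c·cos(φ_slow) with no
  phase injection; **amplitude correlation** modulates both envelopes
  by a shared slow signal.
* `load_slope` raises the effective coupling with memory load
  (clipped to [0, 1]); `retention_only` gates the injection with a
  100 ms-ramped window after stimulus onset, so retention-vs-baseline
  contrasts can detect it.  A per-subject lognormal gain (sd 0.2)
  scales all planted couplings and can shift the behavioral hit-rate
  midpoint (`behavior_coupling_link`).

Hit rates decline logistically from ≈ 0.93 at load 1 to ≈ 0.60 at load
6, above the 0.5 chance level of a same/different response.  One master
seed drives fixed per-(subject, load, parcel, component) spawn keys, so
a fixed seed reproduces a bit-identical study.

**What the generator does not emulate**: anatomically realistic lead
fields (mixing decays with parcel index, not cortical geometry),
non-stationary oscillatory bursts, 1/f slope changes with task, eye or
muscle artifacts, or evoked responses.  Passing tests therefore show
that the estimators and statistics behave as claimed under the assumed
generative structure — not that real recordings satisfy that structure.

### Detectability depends on SNR and ratio

In-band noise jitters the slow phase, and the n:m comparison multiplies
that jitter by m.  At in-band SNR 1 this annihilates CFS for every
m ≥ 2 (measured PLV ≈ 0.01–0.1 at c = 0.8); at SNR 2, ratios 2–3 yield
PLV 0.4–0.7.  Linear mixing dilutes further (at mixing width 0.45,
1:4 edges fall below the detection threshold of a 12-subject, 60-trial
study).  This interaction between amplitude and measurable phase
locking is precisely the confound the SNR audit quantifies.

## Problem sizes

Full-scale defaults mirror the target study design (12 subjects, 6
loads, 300 trials per load, 400 parcels at 600 Hz; 25 frequencies,
ratios 1:2–1:9, 1000 surrogates, 2000 consistency shuffles, 5000 graph
randomizations).  The shipped analyses run scaled-down versions chosen
to keep each full chain in minutes on one CPU: the demonstration study
uses 12 subjects × 6 loads × 60 trials × 10 parcels with low
frequencies {10, 13, 16} Hz and ratios {2, 3, 4}; the validation
experiments use 8–12 subjects, 50–80 trials and 6–8 parcels; surrogate
calibration uses 500–1000 repetitions of 60 × 1 s trials; SNR surfaces
use 10⁵-sample simulations.  All counts are parameters of the
respective functions.
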