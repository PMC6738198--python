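# Methods

This note documents the models, estimators, defaults and design choices
behind `modespec`, and what the synthetic tests do and do not establish
about real data.

## Variational mode decomposition

The solver works on the one-sided spectrum of the mirror-extended
series (half the series length reflected onto each side, cropped after
inversion) to suppress edge ringing. Per iteration, modes are updated
Gauss–Seidel style:

* mode update: û_k ← (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²),
* center update: ω_k ← Σ ω |û_k(ω)|² / Σ |û_k(ω)|²,
* dual update: λ̂ ← λ̂ + τ (Σ û_k − f̂),

until the summed relative change of all modes falls below `tol` or
`max_iter` is reached (the result is then returned flagged
`converged=False` with a warning, never silently). Modes are reported
sorted by ascending center-of-mass frequency of their own demeaned
periodogram, together with `residual = input − Σ modes`, so the
reconstruction identity holds to floating-point roundoff.

Defaults and their reasons:

* `tau = 0` — no exact-reconstruction enforcement. BOLD data carry a
  broadband noise floor that should stay in the residual, not be forced
  into band-limited modes.
* `tol = 1e-7`, `max_iter = 500` — on noiseless tones convergence takes
  well under 10 iterations; noisy 230-sample voxels at large α may hit
  the cap, which in practice changes the modes negligibly (the
  convergence functional is monotone at that point).
* `init_scheme = "peaks"` — initial ω_k at the K most prominent peaks of
  the series' own periodogram (padded with uniformly spaced values when
  fewer exist). Uniform spacing is also available but measurably worse:
  on phantom voxels whose lowest oscillation (≈0.028 Hz) is weaker than
  the neighboring 0.080 Hz content, a uniformly initialized lowest mode
  is captured by the stronger basin in roughly one voxel in ten, merging
  two clusters into one mode and biasing every downstream fraction.
  Peak seeding removes this failure mode without biasing the solution:
  the update equations are unchanged and the noiseless recoveries are
  identical under both schemes.
* α grid logarithmic over 10¹…10⁴ (13 points), reconstruction cap 0.25
  relative squared error. `select_alpha` runs the decomposition per
  candidate, scores the mean fractional overlap between the modes'
  spectra (bands built by midpoint partition of the mode centers) and
  returns the smallest candidate among those minimizing overlap subject
  to the cap — larger α gives cleaner separation but sheds edge and
  leakage power into the residual.
* Duplicate converged centers are kept (K is a user contract), flagged
  in diagnostics.

For whole volumes the identical kernel runs vectorized across voxels
with per-voxel convergence masks; batch results match single-series
calls to ~1e-14 (summation order), with identical iteration counts.
The pipeline selects one α per dataset as the median of `select_alpha`
over a seeded random sample of 12 in-mask voxel series — selecting on
the voxels actually being decomposed rather than on a global mean
series, whose averaging suppresses exactly the voxel-private
oscillations that matter.

## EMD and CEEMD baselines

Classic sifting: natural cubic-spline envelopes through local extrema
(two end extrema mirrored across each boundary), envelope-mean
subtraction until the Cauchy criterion Σ(h−h')²/Σh² < 0.2 (cap 100
sifts), repeated on the remainder until it is monotone, the IMF cap is
hit, or the extracted energy is numerical residue. CEEMD averages EMD
runs over 100 complementary pairs (signal ± white noise at 0.2 of the
signal sd), aligned by extraction index and zero-padded; with one pair
and zero noise it reduces to EMD exactly. These are canonical settings;
the baselines exist to be compared against, not tuned.

A structural caveat the benchmark quantifies: sifting cannot separate
tones closer than about a factor of two in frequency, so EMD/CEEMD mix
the 0.15 and 0.23 Hz tones even without noise. They still *reconstruct*
the signal; they just cannot attribute it to distinct modes.

## Spectral conventions

Spectra are demeaned full-length one-sided periodograms normalized so
that integrated power equals time-domain variance (no Welch averaging —
segmenting would blur modal peaks on 230-sample series). Band power
sums bins whose centers fall in the half-open [lo, hi), so adjacent
bands partition without double counting. The band-pass filter is an
explicit zero-phase frequency-domain mask: unit gain in band, Gaussian
roll-off of scale `edge_sigma` (default 0.005 Hz) outside, DC removed.
SNR is signal power over noise power (demeaned mean squares).
Fractional overlap assigns each mode to the truth band containing its
center-of-mass frequency (nearest band, flagged, if outside all) and
reports the out-of-band share of its power.

## Synthetic data

**Tone mixtures.** The benchmark signal sums four equal-amplitude
cosines at 0.03, 0.08, 0.15 and 0.23 Hz with seed-fixed random phases,
sampled at TR = 2 s for 230 retained frames. Each of 200 realizations
adds fresh white noise scaled for a signal-power/noise-power ratio of
1.2 — the harsh end of realistic rs-fMRI, which is the point of the
benchmark. Truth bands for overlap scoring are midpoints between
adjacent tones with outer edges at 0.01 Hz and Nyquist (0.25 Hz).

**Brain phantom.** A 16×16×8 grid with concentric-shell tissue labels
(CSF core, WM shell, GM rind — geometry only supplies labels) and 12
azimuthal GM ROIs named from the packaged AAL-116 list. Each in-brain
voxel's signal is Σ_c √(frac_c) · x_c(t) + ε, where x_c is a
unit-variance cosine at a frequency drawn from cluster c's Gaussian
(centers 0.028/0.080/0.15/0.22 Hz; sds 0.004/0.009/0.010/0.010,
chosen so ±1.96σ matches typically reported cluster ranges). Per-voxel
fractions are Dirichlet draws around tissue means (concentration 100).
Within a network block, x_c is mixed with a block-shared component as
√(1−s²)·private + s·shared, giving within-block correlation s² before
noise; the shared component is unit-variance noise with cluster c's
Gaussian *power spectrum*, not a shared cosine — a shared single
frequency would put a delta spike into the pooled frequency histogram
that the peak fitter correctly (but unhelpfully) detects as an extra
cluster. Default sharing (0.8, 0.6, 0, 0) plants connectivity only in
the two lowest-frequency clusters, so frequency-dependent network
recovery is a falsifiable prediction; set it to zeros for a null
phantom. Acquisition defaults are 240 frames at TR = 2 s with the first
10 discarded (230 analyzed); a short-TR variant (TR = 323 ms, 1486
analyzed frames) is configured the same way.

`noise_sd` defaults to 0.35 against unit signal variance (power SNR
≈ 8, an ordinary in-band fluctuation SNR for 3T rs-fMRI). This choice
matters for one estimator: modal power includes whatever noise the
mode's Wiener lobe absorbs, so fractional amplitudes are biased toward
uniformity as noise grows (≈0.03 absolute at the default, growing to
≈0.06–0.09 at SNR 2). The bias is a property of the measure itself —
on real data the modal power cannot be separated from in-band noise —
and is the main caveat when reading fractional amplitude maps.

What the phantom does **not** emulate: hemodynamic-response
convolution, scanner drift, motion, physiological waveform shapes,
spatial autocorrelation, and non-stationarity. Passing recovery tests
therefore shows the estimators are correct and well-calibrated for
quasi-stationary narrowband mixtures, not that real rs-fMRI obeys the
four-cluster model.

## Clustering, amplitude, connectivity

Histograms pool per-mode center frequencies over voxels, weighted by
each mode's share of its voxel's total modal power (total mass equals
the contributing voxel count). Bin width defaults to 0.005 Hz over
0–0.25 Hz, fine enough to resolve the narrowest cluster. Peaks with
prominence above 5% of the tallest bin seed a multi-Gaussian
least-squares fit (moment-based seeds, bounded parameters); components
below 2% of total mass are dropped; on failure the seeded moments are
used and flagged. Cluster ranges are central 95% intervals
(center ± 1.96σ), labels run IMF1 (highest frequency) downward, and the
number of detected clusters is independent of the K used at
decomposition — model order is instead chosen by `order_selection`,
which scores candidate K by group sd of matched cluster centers and
widths, the percentage of runs manifesting each cluster, and
between-run center correlation (greedy center matching with a 0.02 Hz
gate; recommendation by rank sum). Reproducibility uses ICC(2,1) —
two-way random effects, absolute agreement, single measure — computed
from ANOVA mean squares and cross-checked against pingouin in the
tests.

Mode assignment: nearest cluster center among the clusters whose range
contains the mode's frequency; outside all ranges the mode stays
unassigned and is excluded from cluster statistics. Fractional
amplitude normalizes over *labeled* modes only, reporting the
unassigned power share separately. Connectivity averages the mode time
courses of all cluster-labeled modes across each ROI's voxels and
correlates ROI pairs (Pearson); empty ROIs become NaN sentinel
rows. Band-passed reference matrices apply the Gaussian band-pass to
ROI-mean raw series (0.01–0.08 Hz by default). Matrix similarity is the
Pearson correlation of strict upper triangles (the constant diagonal
would inflate it); group averaging is plain element-wise mean of r,
with a Fisher-z variant behind a flag.

## Numerical and interface choices

* Analysis band 0.01–0.25 Hz; short-TR data are first low-pass filtered
  at the band's upper edge to emulate the conventional bandwidth.
* Tissue labels follow the FAST convention (1 = CSF, 2 = GM, 3 = WM);
  voxel indices are 0-based internally, ROI indices 1-based externally.
* NIfTI I/O via nibabel with TR in the time-axis header field; an
  absent or implausible TR (≤0 or >30 s) is rejected unless overridden.
* Every pipeline run writes a manifest (config hash, seed, versions,
  stage wall times) sufficient to reproduce it.
* All stochastic components take explicit seeds; fixed seeds give
  bit-identical generator output and CEEMD results.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the benchmark at 50 noise
realizations (the generator default is 200), phantom pipelines on the
default 16×16×8 grid across 10 seeds, and order selection on
10×10×6 phantoms with 2 subjects × 2 runs — sizes at which every
recovery property above is comfortably resolved on a single CPU.

## Known limitations

* Fractional amplitude inherits in-band noise power (see above).
* VMD center frequencies of noisy modes are pulled a few mHz toward
  their Wiener-lobe centers at large α; the α-selection rule and peak
  initialization keep this below the histogram bin width at the
  defaults.
* EMD/CEEMD envelope handling at the series ends uses mirrored extrema;
  other boundary rules change IMFs near the edges.
* The phantom's connectivity ground truth is block-diagonal by
  construction; graph-theoretic network measures beyond mean block
  correlation are out of scope.
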