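# Methods

## Observable and conventions

The raw observable is the bead centroid (x, y) in nm at a fixed frame rate
(30 Hz by default).  Within a sliding window of `window_frames` frames
(default 20, i.e. 0.66 s truncated to two decimals) the per-axis
mean-squared displacement is the within-window variance, MSD = ⟨x²⟩−⟨x⟩²
(population form, divide by n; the 1/20 relative difference from the
unbiased form is absorbed by the calibration).  The scalar Brownian-motion
amplitude is the per-axis RMS excursion

    BM = sqrt((MSD_x + MSD_y) / 2)   [nm]

so an isotropic bead with per-axis standard deviation σ has BM = σ.  Windows
advance by `stride` frames (default 1, maximally overlapping); any window
touching an unrecorded frame is dropped.  Population measurements use one
block of 1000 consecutive recorded frames per bead; the population is
summarized by the sample mean and sd of the per-bead values, the unbinned
equivalent of fitting a Gaussian to the histogram.

Units throughout: lengths nm, times s, velocities bp/s, ATP mM, ATPase
rates µM/min.

## Substrate model

Substrates are described by oligo lengths and 1-based inclusive anneal
intervals on the scaffold; all derived geometry (duplex bp, 5′ overhang,
nicks, single-stranded content) follows from interval arithmetic.  A partner
may pair over an interval shorter than its own length; the excess is an
unpaired partner overhang counted as single-stranded tether (this is how the
mimicked-unwound control carries its 71 nt bead-proximal tail).  Sequences
are optional because nothing downstream depends on them; when present they
are verified as exact reverse complements over the paired interval.  Per
base pair unwound, duplex decreases by 1 bp and single strand increases by
2 nt (both strands of the opened pair stay in the surface-to-bead path), and
the bead detaches exactly when the unwindable duplex (the paired length of
the biotinylated partner, 90 bp for the fork) is fully open.

## Synthetic recordings

No polymer model of the tether is attempted.  Each axis is a stationary
mean-reverting (AR(1)/Ornstein–Uhlenbeck) process with relaxation time `tau`
and instantaneous per-axis standard deviation

    σ(t) = sigma0 + c_true · u(t)

where u(t) is the base pairs unwound: 0 before the onset time, then
v_true·(t−t_start) capped at the unwindable duplex length, with an optional
plateau (pause) inserted before release.  By construction the scalar BM
defined above equals sigma0 + c_true·u(t), so calibration and velocity
estimation can be validated independently of tether physics.  The AR(1)
recursion is exact (no discretization error), driven by one seeded
generator; cohorts spawn per-bead substreams from a `SeedSequence`, making
every output bit-reproducible.

Simulated nuisance features: a recording dead time (default 20 s; frames
present, flagged unrecorded), linear stage drift (default 0.1 nm/s per
axis), a 2:1 axis-variance anisotropy for a configurable minority of beads
(default 10%; emulates multiply-tethered beads, exercises the symmetry
filter), per-bead baseline spread (default sd 2.18 nm), stochastic onset
times (uniform over [dead_time+100 s, dead_time+300 s], reflecting the long
pre-unwinding baseline of real recordings), a pause probability (default
0.08, duration 30 s at 50–85% completion) and bead disappearance at
completion, after which the trajectory simply ends.

Defaults represent the study conditions: sigma0 = 9.90 nm and spread
2.18 nm (intact fork population), c_true = 0.0718 nm/bp, v_true = 3.58 bp/s,
90 bp unwindable duplex, 17% of tethers unwinding in a field of view.
`tau` is a free parameter (the bead-position autocorrelation time is not
constrained by the data the analysis consumes); the default is 0.05 s, and
analyses that compare windowed BM with σ quantitatively use tau = 0.01 s so
that windows are long relative to tau — the windowed variance of a
mean-reverting process underestimates σ² by approximately
(2/n)·a/(1−a) with a = exp(−dt/tau), about 8% at tau = 0.05 s and 3% at
tau = 0.01 s for 20-frame windows at 30 Hz.

Not modelled: hydrodynamic or excluded-volume tether physics, force
dependence (the assay is nearly force-free), motion blur, backstepping.
Passing tests on these synthetics therefore demonstrate estimator
correctness under the affine BM↔bp model, not robustness to tether-physics
effects absent from the generator.

## Drift correction and QC

Drift is removed by subtracting a centred moving average per axis
(default 10 s — long against the 0.66 s BM window, short against drift).
Bead symmetry QC computes the x/y MSD ratio over 1000 recorded frames and
keeps beads with ratio in the closed interval [0.9, 1.1].  Note the
sampling noise of a 1000-frame variance ratio is about 6% (1 sd), so even
perfectly isotropic beads pass only ~89% of the time; 2:1 anisotropic beads
essentially never pass.

## Calibration

c = (mean BM of mimicked-unwound − mean BM of fork) / Δduplex, with
Δduplex = 108 − 37 = 71 bp derived by the substrate model.  With the
published population means (15.00 and 9.90 nm) this gives 0.0718 nm/bp.
A negative factor warns rather than errors (it indicates swapped inputs).
No uncertainty is propagated onto c by default: the published ±0.0257 nm/bp
does not follow from simple propagation of the population sds, so the
derivation is left configurable rather than asserted.

## Onset detection

Performed on the BM series decimated to non-overlapping windows (nearly
independent samples).  The first derivative is a sliding least-squares slope
over `deriv_span_s` (default 20 s).  The baseline band is the empirical
2.5/97.5 percentile interval of the derivative over the initial flat segment
(default first 100 s of data), robust to heavy tails.  Unwinding is declared
at the first run of at least `persistence` consecutive above-band samples
(default 30 decimated points = 20 s, capped at span−1 samples so that an
instantaneous step remains detectable).  Two refinements handle release
truncation: a run reaching the final derivative sample of a disappeared bead
is accepted at `end_persistence` (default 8 points), and if no run is found
at all, the terminal `end_span_s` (15 s) least-squares slope is tested
directly against the band — fast events (≈10 bp/s unwinds 90 bp in under
9 s) otherwise leave too short an evidence window.  These defaults were set
by Monte-Carlo on stationary synthetic traces at the study noise level to
hold the per-trace false-positive rate at or below a few percent while
detecting all cohort velocities of interest.

The reported onset is then refined by a least-squares changepoint fit in a
±40 s neighbourhood of the band crossing: a flat-baseline-plus-ramp (hinge)
and a flat-plus-step model are both fitted on a grid of candidate
changepoints and the better SSE wins.  Unlike the raw band-crossing time,
this estimate is unbiased in the onset regardless of the unwinding speed.

## Velocity estimators and exclusions

* `v_slope` — ordinary least-squares slope of the dense BM series over
  [t_start, t_max], divided by c.
* `v_dwell` — unwindable_bp / (t_max − t_start), where t_max is the last
  frame of the last fully recorded window (maximum BM is achieved at
  release).
* Pause flag — a sliding span of at least `plateau_min_s` (15 s) between
  onset and release with |local slope| ≤ `slope_tol` (0.08 nm/s) at a BM
  level strictly between baseline and final (margin 0.5 nm).  Paused
  molecules are excluded from velocity statistics.
* Qualification — only beads that disappear with a significantly rising
  (one-sided test, α = 0.05) pre-disappearance BM section enter cohorts.

On clean ramps the two estimators coincide up to the half-window
discretization of t_max; on noisy synthetic cohorts at the study conditions
their cohort means agree to within a few percent.

## Ensemble statistics

* Bootstrap: ordinary nonparametric, resampling n velocities with
  replacement (default 100 resamples); summary is the mean and sd of the
  resample means, with percentile intervals available.  The bootstrap sd
  approaches sd/√n for large resample counts.
* Michaelis–Menten: `scipy` nonlinear least squares of v = Vmax·S/(Km+S),
  initialized at Vmax₀ = max v, Km₀ = median S, both bounded positive;
  unweighted by default (per-condition means), optional 1/sd² weights.  The
  fit recovers exact model data to better than 4 significant figures.
* ATPase: rate = |least-squares A340 slope| × 9820 µM/min; the constant
  embeds the NADH extinction coefficient and path length and is a named
  configuration constant, not recomputed.  An increasing A340 yields rate 0
  with a warning.
* Gel shift: %Unwound = (U_S − U_0)/(U_100 − U_0)·100; affine-invariant in
  its three inputs; values outside [0, 100] are flagged, not silently
  clipped.
* Disappearance curves: the empirical cumulative percent of lost tethers is
  fitted with y = y0 + A·(1 − exp(−t/t_c)) with the amplitude bounded by the
  percent axis (A ≤ 100).  The fixed-amplitude variant with a 1/t_c
  prefactor is available behind `model="unit"` for comparison, but it is
  dimensionally awkward on a percent axis and parameter recovery is only
  well-posed under the amplitude form, which is therefore the default.

## Problem sizes and numerical choices

Validation suites use cohorts of 15–60 molecules of 600 s recordings at
30 Hz, population cohorts of 57–66 beads, 200 stationary traces for the
false-positive rate, and 10⁴ bootstrap resamples — sizes at which the
estimator means are determined to a few percent while the whole suite runs
in well under a minute of simulation time.  Ties and degenerate inputs:
equal population means give c = 0 (no error); an all-identical velocity
cohort gives bootstrap sd 0 and is flagged degenerate at the population
level; traces whose bead never disappears have no dwell velocity and are
disqualified rather than assigned infinity.

## Known limitations

* The affine BM↔bp relation is assumed exact in the generator; real tethers
  approach it only empirically, and window-bias corrections depend on the
  unknown bead relaxation time.
* The onset detector's band and persistence defaults are tuned to the study
  noise regime (baseline BM ≈ 10 nm, c·v between 0.2 and 0.8 nm/s); far
  outside it, `deriv_span_s` and `persistence` should be rescaled.
* Pause detection cannot see pauses shorter than `plateau_min_s` or pauses
  at extreme completion levels (within the level margins of baseline or
  final BM), and at high velocities the pre-pause rise may be too short to
  detect at all.
* The calibration uncertainty is not propagated; velocity errors quoted from
  cohorts are sampling errors only.
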