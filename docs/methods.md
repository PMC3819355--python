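# Methods

## Signal model

An fMRI time series is modelled as `y(t) = S(t) + N(t)`: a noise-free
activation signal riding on a constant baseline, plus zero-mean white
Gaussian noise. The quantities entering the six SNR/CNR definitions
are the baseline `b`, the activation amplitude `a` (peak minus
baseline), the activation fluctuation SD `σ_S` (population SD of the
baseline-subtracted samples, hence invariant to `b`), and the noise SD
`σ_N`. Percent signal change `p` fixes the amplitude through
`a = p·b/100`.

## Design templates and signal construction

All signals are sampled at the repetition time (TR, default 2 s) over
200 s (100 samples) with baseline 100, and are built by convolving a
binary stimulus function with the canonical HRF **on the sampling
grid** (no microtime upsampling), truncating to the run length, and
**peak-anchoring**: the convolved response is rescaled so its maximum
equals `a`, then the baseline is added. Peak-anchoring makes
Definition 2 exactly `p·b/(100·σ_N)` for every design, which is the
convention under which the amplitude-based columns of the reference
tables are closed-form.

- **Block**: 20 s task / 20 s rest, task first. At the defaults this
  gives `σ_S = 0.4451·p` (temporal mean `b + 0.328·p`).
- **Event-related (ER)**: 25 single-sample impulse events placed
  uniformly at random on the TR grid without overlap (seeded). `σ_S`
  depends on the placement; across placements it averages `0.2959·p`
  with SD `0.024·p`. The amplitude is that of the highest peak (the
  anchor), so Definition 2 is placement-independent.
- **Contrast**: repeating 20 s condition-1 / condition-2 / rest
  epochs. Condition 1's response is anchored to `a` and condition 2's
  to `a/2` ("condition 1's effect twice condition 2's"). The contrast
  signal is the difference of the two condition signals; its amplitude
  is max minus min of the difference course (1.844·p/100·b at the
  defaults) and its `σ_S` is `0.5296·p`.

### Canonical HRF

The kernel is a mode-parameterised double gamma,

    h(t) = (t/d1)^(d1/b1) exp(−(t−d1)/b1) − c·(t/d2)^(d2/b2) exp(−(t−d2)/b2),

with peak delay `d1 = 5.4` s, undershoot delay `d2 = 10.8` s,
dispersions `b1 = b2 = 0.9` and undershoot ratio `c = 0.35` — the
parameterisation used by the established fMRI simulation toolchain in
R. `h(0) = 0`, the positive lobe peaks at `d1` with unit height, and
the undershoot dips to about −7% of the peak. The widely used
SPM-style variant (gamma densities peaking at 6 s and 16 s, ratio 1/6)
is also expressible through `HRFParams` but yields `σ_S = 0.4554·p`
for the block design, ~2% higher; the default parameterisation is the
one that reproduces the reference tables.

## Detection power

Per grid cell (design, `p`, `σ_N`), `n_reps` independent series are
simulated (signal plus white Gaussian noise) and each is fitted by OLS
with an intercept and one convolved regressor per condition — the same
regressors that generated the data, so the model is correctly
specified and the resulting power is *maximal*; real data with
structured noise detect less. Detection is a t-test (default
two-sided, α = 0.05, residual df n − rank) on the task coefficient, or
on the coefficient difference (contrast vector [0, 1, −1]) for the
contrast design. The implementation applies the projection matrix to
all replications at once; this is algebraically identical to fitting
each series separately and keeps the full 21-cell table with 1000
replications per cell under a second.

`analytic_power_oracle` computes the same power in closed form: under
the correctly specified model the t statistic is noncentral-t with
noncentrality `|c'β| / (σ_N·sqrt(c'(X'X)⁻¹c))`; for a single-condition
design this reduces to `σ_S·sqrt(n)/σ_N` up to centering. For very
large noncentrality, where scipy's noncentral-t underflows, the normal
approximation is used (exact to double precision there). The oracle is
used in tests to validate the Monte-Carlo machinery; it never replaces
it.

Two-sided α = 0.05 was chosen as the community default; it is the main
tolerance source for mid-range power cells. The per-cell random stream
is derived deterministically from the simulation seed and the cell's
(p, σ_N), so any cell is reproducible in isolation.

### Internal-consistency caution on published power values

For a given Definition-4 value, white noise and a correctly specified
single-regressor GLM, the noncentral-t formula is a *hard ceiling and
floor*: power at `σ_N = 1`, n = 100, two-sided α = 0.05 is determined
by `σ_S` alone. An ER cell with Definition 4 ≈ 0.31 therefore has
power ≈ 0.86; published values near 0.67 for the same cell cannot be
produced by any event-placement convention that also yields
Definition 4 ≈ 0.31 (overlap-allowed placements lower both together:
σ_S ≈ 0.26–0.27 and power ≈ 0.72–0.74). This package keeps the
convention consistent with the Definition-4 column (non-overlapping
events) and reports the power its own model implies. Similarly, in a
two-condition contrast the power of the coefficient-difference test is
*not* a function of the contrast signal's Definition 4 alone (the
regressor correlation enters), so matched Definition-4 values across
designs do not imply matched power; power/CNR monotonicity checks are
restricted to the single-condition designs.

## Conversions

Within the amplitude family (p, Def 2, Def 3) and within the SD family
(Defs 4–6) conversions are closed-form (`a = p·b/100`,
`dB = 20·log10(linear)`, `Def 5 = Def 4²`). Cross-family conversions
(and anything involving Definition 1) are resolved by constructing the
design's signal at the implied percent signal change and reading the
target metric off it; without a design context they are refused, since
`σ_S` is not derivable from `p` alone.

dB is the amplitude-ratio convention `20·log10` throughout (0 dB means
signal equals noise; negative values mean less signal than noise). A
zero-amplitude signal yields 0 for the linear CNRs and NaN (not −∞)
for the dB ones. Sample SDs use the population (1/n) denominator; at
n = 100 the difference from 1/(n−1) is below the tables' printed
resolution.

## Volume procedures

- **tSNR**: per-voxel temporal mean over temporal SD on the raw,
  undetrended series; zero-variance voxels (padded background) map to
  NaN.
- **ROI CNR**: the region's activation signal is the spatial average
  course of the mask (separately for the complement); each voxel's
  noise is the residual after subtracting its region's average course,
  giving a per-voxel `σ_N` (per-voxel rather than region-pooled, so
  the in-mask CNR range reflects voxel-level noise heterogeneity).
  The region CNR uses the region signal's `a` (Definition 2) or `σ_S`
  (Definition 4) over the voxel's residual SD, summarised by mean and
  range per region.
- **Amplitude of an estimated course**: the raw maximum of a noisy
  average course is upward-biased by extreme-value selection. The
  amplitude is therefore estimated by cross-fitted quartile bands: the
  peak and trough quartile time points are selected on the average of
  one half of the region's voxels and the band means are read off the
  other half (both directions, averaged). Selection bias under noise
  is removed by the independence of the two halves; the remaining
  static bias (~+9% for a block paradigm, from the undershoot in the
  trough band) is below the 15% recovery tolerance the synthetic
  fixtures are tested at. For a single-voxel region the estimator
  degenerates to plain quartile-band means.

## Synthetic-volume generator

`synth_volume` emulates the two real-data situations the procedures
target: a task acquisition (planted design signal at a chosen percent
signal change inside a box mask, baseline 100 elsewhere) and a
resting acquisition (baseline only), with i.i.d. Gaussian noise
everywhere and full seeding. Default geometry is 10×10×10 voxels ×
100 time points (125-voxel mask), large enough for parameter-recovery
tests at the 15% level and small enough for second-scale test runs.
It does **not** emulate spatial noise correlation, temporal
autocorrelation, drift, motion or physiological noise — so passing
recovery tests demonstrate correctness of the estimators under the
stated model, not robustness on real scanner data, where tSNR/CNR
values are additionally mask- and preprocessing-dependent.

## Known limitations

- Noise is white Gaussian by construction; empirical power values are
  upper bounds for real data.
- The contrast-design scale conventions in circulation are not unique;
  this package's choice (per-condition peak anchoring at `a` and
  `a/2`) makes Definition 2 closed-form per condition and is
  internally consistent between the metric and power machinery, but
  other published tabulations of contrast-signal CNR differ by a
  constant factor.
- ER designs use single-sample impulse events on the TR grid; event
  durations can be specified, but sub-TR event timing is out of scope.
- No preprocessing (motion correction, slice timing, detrending) is
  applied or modelled; volume inputs are taken as-is.
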