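# Methods

## The detection problem

A peri-event recording is a matrix of aligned dF traces (one row per
subject or trial) around an event. An event-related transient (ERT) is a
phasic, event-locked deviation of the population mean from baseline.
`ertwave` flags ERTs by testing every timepoint of the mean waveform and
then demanding a minimum period of *continuous* significance.

## Pointwise tests

**t interval.** `mean ± SEM · t_crit` per timepoint, df = n−1,
two-sided critical value. Requires n ≥ 2.

**Expanded percentile bootstrap interval.** Whole rows are resampled
with replacement (default 1,000 replicates; percentiles 2.5/97.5 at the
95% level, 0.5/99.5 at 99%, linear interpolation between order
statistics). Resampling rows rather than individual cells preserves
within-trace autocorrelation. The raw percentile interval is too narrow
at small n — on average by a factor (n−1)/n — so both endpoints are
moved away from the sample mean by n/(n−1):
`bound' = mean + (bound − mean) · n/(n−1)`. This printed factor is a
partial correction: the classical small-sample width correction is
`sqrt(n/(n−1)) · t_crit/z_crit` (≈ 1.22 at n = 10 vs 1.11), so the
expanded interval still under-covers somewhat at small n; the Monte
Carlo section below quantifies the consequence.

**Permutation test.** Two groups of whole traces are pooled and
reassigned; the statistic is the per-timepoint group mean difference.
All `C(n_a+n_b, n_a)` assignments are enumerated when that count is
within the permutation budget (default 1,000), making p exact; otherwise
the budget's worth of random reassignments is drawn and the observed
statistic is added to the set, `p = (b+1)/(m+1)`, so p is never 0. Ties
count as extreme, with a relative tolerance of 1e−9 on the comparison so
that exactly mirrored assignments are counted symmetrically. The default
tail for the public API is two-sided on |mean difference|; the Monte
Carlo harness instead counts one-sided (see below). The smallest
attainable p is `1/C(n_a+n_b, n_a)` — 1/70 ≈ 0.014 at n = 4 per group —
which is the granularity bound on α for small samples.

**Significance rules.** An interval flags a timepoint when it excludes
the null value; endpoints are closed, so an interval touching the null
exactly is *not* significant (conservative tie-break). A permutation
timepoint flags when p < α strictly.

## Consecutive thresholds

The run length is `ceil(fraction · fs / lowpass_hz)` samples: at 10 Hz
sampling with a 2 Hz low-pass, the full-window threshold (fraction 1) is
5 samples and the half-window threshold (fraction 0.5) is 3; fraction 0
resolves to 1 sample (no filtering). Runs are maximal stretches of
significant timepoints regardless of effect direction (a strict
direction-consistent mode is available via the `signs` argument — in
practice mixed-direction runs essentially never occur because the mean
waveform is smooth at the filter timescale); runs touching the window
edge count with their in-window length. Thresholding is idempotent,
monotone in the run length, and never adds flags.

## Synthetic generative model

Defaults emulate subject-averaged fiber photometry:

| parameter | default | meaning |
|---|---|---|
| `n_points`, `fs` | 100, 10 Hz | 10-s peri-event window |
| `noise_power` | 0.1 dF² | white-noise variance before filtering |
| `lowpass_hz` | 2 Hz | zero-phase 2nd-order Butterworth cutoff |
| `transient_duration` | 1 s | parabolic transient support |
| `null_transient_prob` | 0.5 | chance of an unrelated transient per null line |
| `lines_per_subject_range` | [1, 31] | lines averaged per subject (uniform) |
| `population_lines`, `population_subjects` | 10,000 / 1,000 | per condition |
| `magnitude_scale` | 1.0 | scale of the half-normal magnitude |

A *line* is filtered noise plus, depending on condition, a transient:
ERT lines get one starting at the halfway sample (indices 50–59,
t = 0 at the event by the file convention); null lines get one with 50%
probability at a uniform start that fits wholly inside the window.
Transient magnitudes are half-normal (|z|, mean ≈ 0.798). *Subjects*
average k lines, k uniform on [1, 31], drawn without replacement from
the 10,000-line pool.

Numerical choices worth stating:

- The parabola `m·(1 − (2t/T − 1)²)` is sampled at the midpoints of the
  k = round(T·fs) sample intervals and rescaled so the sampled maximum
  equals the drawn magnitude exactly. This keeps the vector symmetric
  under reversal, every sample strictly positive (edge samples ≈ 0.19 m),
  and the peak exact — an even k has no sample at the apex, so an
  edge-anchored grid would either zero the support's outermost samples
  (capping the correct-reject rate at 80%) or break symmetry.
- Noise is filtered first; the transient is added afterwards, unfiltered.
  The filter is zero-phase (forward–backward), so it introduces no group
  delay that would shift transient timing.
- "Noise power" is the variance of the white noise *before* filtering;
  filtering reduces the realized trace variance by roughly four-fold at
  the default cutoff.
- **Unrelated null transients are sign-symmetric** (half-normal magnitude
  times a random ±1), unlike the event-locked ERT transient, which is
  always positive. Event-unrelated fluctuations have no preferred
  direction relative to the event, and this choice is what keeps the
  null ensemble zero-mean. A positively biased null (mean ≈ +0.027 dF
  everywhere) would make the family-wise error of any interval tested
  against dF = 0 grow without bound in n, and no noise level can then
  reconcile threshold-controlled FWER with high small-sample detection.

What the model does *not* emulate: biosensor kinetics (GCaMP decay makes
real transients asymmetric and duration-dependent on spike count),
bleaching and slow drift, isosbestic/motion artifacts, dF/F computation
from raw fluorescence, and trial-to-trial latency jitter. Passing Monte
Carlo results therefore speak to the statistical machinery under a
stylized signal, not to preprocessing quality on real recordings.

## Monte Carlo harness

Per simulation, n subjects are sampled without replacement from each
condition's 1,000-subject population. CI methods test each sample
against dF = 0; the permutation test compares each sample against a
fresh n-subject baseline drawn from the null population (disjoint from
the null analysis sample) each simulation. The harness counts p-values
one-sided (`perm_tail="one"`), matching the counting convention implied
by the minimum-p granularity above: under two-sided counting the n = 5
cell at α = 0.01 is reachable only by the single most extreme
assignment, which would misrepresent the method as far less sensitive
than reported.

Scores per simulation: a null-condition *false positive* is any flag
anywhere in the window after thresholding; the ERT *correct-reject
fraction* is the fraction of the 10 transient-support samples flagged
(thresholding is applied to the whole window first, then intersected
with the support, so a run straddling the support boundary contributes
its in-support samples); a *miss* is an ERT simulation with no
in-support flag. All threshold fractions are scored on the same
per-simulation raw mask — thresholding is deterministic post-processing,
so this is identical to rerunning per threshold. Every trial draws its
RNG stream from a spawn tree keyed on the master seed, so any cell is
reproducible in isolation and results are independent of execution
order.

Default problem sizes: the bundled studies use 500 simulations for the
n = 10 / 95% detection cell and 1,000 for the n = 5 / 99% sensitivity
cell; cells complete in seconds-to-minutes on one CPU, and the full
n = 5–100 grid is available by listing more sample sizes in the config.

## Known limitations and honest numbers

- Under this model the full 5-sample threshold brings FWER near, but not
  reliably below, α for every method at n = 10, 95%: tCI is conservative
  (per-point rate ~2–3% due to the heavy-tailed subject mixture), but
  the expanded bCI runs a ~7.7% per-point rate (the n/(n−1) expansion
  under-corrects; see above) and lands at 0.08–0.14 FWER, and the
  permutation test — exactly valid per point — measures 0.03–0.11
  depending on the drawn population. Null-condition unrelated transients
  are 10-sample smooth bumps identical in shape to the ERT, so a sample
  containing a single-line subject can carry a genuine extended
  deviation that no run-length filter can reject.
- At the hardest sensitivity cell (n = 5, 99%, full threshold) the
  expanded bCI misses the transient in well under 1% of simulations and
  the permutation test misses most often, with tCI in between — the
  ordering expected from the methods' small-sample granularity.
- Percentile interpolation, the Welch (rather than pooled) two-sample t,
  closed interval endpoints, and the tie-counting tolerance are all
  documented conventions; switching any of them changes results at the
  margin only, but exact reproduction requires matching them.
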