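# Methods

## Population model

The simulator draws a fixed-cell snapshot of an asynchronously proliferating
population in steady-state exponential growth.  With doubling time `T_d`
(hours) and growth rate `α = ln2/T_d`, cell age `a` has density
`2α·e^(−αa)` on `[0, T_d]`; sampling is by inverse CDF,
`a = −ln(1 − u/2)/α`.  The factor of two encodes that each division replaces
one old cell with two newborns, so young cells are over-represented relative
to a uniform age distribution.

Phases are deterministic age windows G1 → S → G2/M whose scheduled durations
sum to `T_d`.  Per-cell trajectories:

* **G1**: loaded MCM rises linearly, `m(a) = min(r·a, M_max)`, DNA = 1
  (relative, 2N), EdU = 0.  `r` is the loading rate (MCM-units/h) and
  `M_max` the licensing target at S entry.  Loading starts at age 0 (no
  telophase loading burst).
* **S**: with progress `s ∈ [0,1)`, MCM unloads linearly from the amount
  held at S entry, `m = m0·(1−s)`; DNA = 1 + s; EdU = `edu_scale ·
  min(m0/M_max, 1)` — DNA synthesis scales with how fully licensed the cell
  was, the minimal mechanism that couples underlicensing to slow S-phase
  progression.
* **G2/M**: MCM = 0, DNA = 2, EdU = 0.

**Licensing checkpoint.** With `checkpoint_active` (default), S entry waits
until `r·T_G1 ≥ M_max`: the effective G1 is `max(g1_hours, M_max/r)` and S
and G2/M are rescaled proportionally to keep the cycle at `T_d`.  The
checkpoint only ever *extends* G1; a cell loading faster than needed parks
at `M_max` until its scheduled transition.  With the checkpoint off, S entry
occurs at `g1_hours` regardless, producing underlicensed S cells
(`m0 < M_max`) — the Cyclin-E-overproduction scenario.  That scenario is
modelled as a 70/30 mixture of shortened-G1/checkpoint-off cells and
control-like cells, reflecting incompletely penetrant induction; a fully
homogeneous perturbed population would make the within-sample MCM-high/low
comparison degenerate, since every cell would share the same `m0`.

Both the linear G1 loading law and the linear S unloading law are modelling
choices — the data motivating this package constrain only the qualitative
rise-and-fall shape — and they are the main place simulated samples differ
from real ones (see *Limitations*).

## Measurement model

Measured channel = truth × LogNormal(unit mean, CV) + background, where the
additive antibody background (log-normal, median 5 AU, CV 0.5) applies to
the antibody channels (EdU, MCM) and defines what a no-primary-antibody
negative control measures.  Defaults, chosen once as typical for linear-scale
immunofluorescence flow data: CV 0.06 for DAPI area (DNA-content resolution),
0.03 for DAPI height, 0.18 for MCM, 0.25 for EdU and scatter; `M_max` = 200
AU, G1 DAPI level 100 AU, `edu_scale` 500 AU.  Doublets (default 3%) are
formed by merging random pairs: area channels add, DAPI height takes the
pair maximum — exactly the asymmetry the DAPI area-vs-height singlet gate
exploits.  A `NoiseModel.noiseless()` identity model is used where exact
truth accounting is needed.

## Gating

Hierarchy: optional scatter gate → singlet gate (band 0.75–1.25 around the
mode of the DAPI height/area ratio) → antibody thresholds (empirical 0.995
quantile of the matched negative control, per channel) → taxonomy.
Non-excluded cells partition as: MCM ≤ threshold → MCM⁻ G1/G2/M; else EdU⁺ →
S-MCM⁺; else DNA within 0.85–1.15 of the G1 DAPI peak → G1-MCM⁺; remaining
MCM⁺ anomalies fold into the MCM⁻ class and are counted.  The G1 peak is the
dominant mode of a kernel-smoothed (256-bin, σ = 2 bins) DAPI histogram with
a consistency check for a secondary mode near 2×.  "Early S" = EdU⁺ with
G1-window DNA.  All window parameters are configurable; results downstream
should be read with their sensitivity to gate geometry in mind.

**MCM-high/low S split.** The boundary is the 10th percentile of the
*control* sample's early-S MCM.  Whether a cell *began* S underlicensed is
only decidable near S entry on a 1-D MCM axis — later in S, normal unloading
carries every cell below any fixed boundary — so the headline fraction-low
uses the early-S denominator (which calibrates to ~10% in the control by
construction); the all-S fraction is reported alongside.

## Growth

Doubling time is the inverse slope of an ordinary least-squares fit of
log2(count) against time, replicates pooled as points; exactly invertible
and exact on noiseless geometric series.  Phase durations from fractions use
the linear convention `fraction × T_d` by default; an `exponential` option
inverts the age-structure occupancy `2(1 − e^(−αt))` for birth-anchored
phases and always gives shorter durations for fractions below one.

## Ergodic rate analysis

Per sample: `w_n = α(2 − F)/f_n` over 10 equal-width bins spanning the
G1-MCM⁺ intensities' own min–max range, no bin-width division, mean of the
ten `w_n` as the sample statistic.  `F` is the G1-MCM⁺ fraction of all
non-excluded cells (post-scatter, post-singlet).  Empty bins are an error by
default (`drop_empty` averages over non-empty bins and records the choice in
provenance).  Ties at the maximum fall in the last bin.  No outlier trimming
is applied by default.

Consequences of these conventions, verified analytically and by simulation:

* The statistic is invariant under positive affine transforms of the
  intensity axis, so a pure k-fold rate change that merely rescales the MCM
  axis is invisible; rate differences register through *shape* — cells that
  finish loading early park at `M_max` and pile into the top bin, thinning
  the others.  For the hESC-like geometry the expected recovered ratio for a
  true k-fold difference is ≈1.77 (k = 2) and ≈3.48 (k = 4): within ±15% of
  truth, with the deficit coming from the parked top bin and the exponential
  age tilt.
* The min–max range makes the statistic sensitive to sparse outlying bins
  under measurement noise (the mean over bins is dominated by the smallest
  `f_n`), which is why the rate-recovery validation runs on noiseless
  samples and why replicate means, not single samples, are the unit of
  inference.  With the default 18% MCM CV at n = 20,000, empty bins can
  occur and group ratios inherit substantial variance.

The validation experiments use n = 20,000 events per sample and eight
replicate samples per group, sized to keep the Monte-Carlo error of the
recovered ratio well inside the ±15% acceptance band.  `cumulative_era`
implements the flux-conservation form `v(x) = α(2 − Φ(x))/p(x)` with
bin-width-normalised density and the cumulative trajectory fraction Φ; on a
constant-speed population it returns the true loading speed (intensity/h),
flat across bins, and serves as the independent cross-check of the
binned statistic.

`run_era` refuses samples flagged as actively differentiating: a population
whose cell-cycle distribution is shifting violates the steady-state
assumption underneath the ergodic argument.

Group comparisons are two-tailed unpaired t-tests on replicate-level mean
rates (equal-variance by default, Welch optional), with the group-mean ratio
as the effect size; rates are relative, so only samples from a matched
staining/instrument batch should be compared.

## Differentiation score

Per-cell score = Cdx2 / Oct4 mean fluorescence.  Cells with Oct4 below 1% of
the table median are excluded (unbounded ratios) and counted.  Histograms
cover [0, 3.5] with a final overflow bin for all larger scores; box stats
use the 25th/75th box and 1st/99th whiskers convention.  Condition
comparisons use the two-tailed Mann-Whitney U: exact enumeration when both
groups have ≤50 tie-free observations, otherwise the tie-corrected normal
approximation.  A threshold-fraction helper (same negative-control quantile
rule as the flow gates) covers single-marker positive fractions.

## Numerical choices

* Quantiles are linear-interpolation order statistics (numpy default),
  matched exactly by the brute-force oracles in the tests.
* Histogram bins are right-open with a closed last bin.
* Mode finding degenerates gracefully: point masses and numerically
  collapsed spreads return the midpoint.
* All simulation randomness flows from one `numpy` Generator per sample;
  seeds are recorded in sample metadata and outputs.  Analysis stages are
  seed-free and deterministic.

## Problem sizes

Simulation-based tests use 10⁴–2×10⁵ cells per sample — enough that
binomial error on phase fractions is ≲1% and the age-distribution
goodness-of-fit test has power, while the full suite stays fast.  The
validation scripts use 20,000 events per sample, a realistic per-tube event
count after gating.

## Limitations

* Linear loading/unloading trajectories; real licensing kinetics may
  saturate or accelerate, changing bin-occupancy shapes.  The trajectory is
  a single place to swap (`assign_phase_and_signals`).
* Deterministic phase durations — no cell-to-cell variability in G1 length
  apart from the checkpoint rule, and no lineage correlation.
* The rate statistic is relative; absolute calibration (MCM molecules per
  cell) and cross-batch comparison are out of scope.
* Gating reproduces hand-drawn-gate logic with fixed relative windows;
  sensitivity to gate geometry should be assessed per dataset.
* Passing simulation tests demonstrates correctness of the computations
  under the generative assumptions above, not the biology of any particular
  cell line.
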