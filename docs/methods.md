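# Methods

## Signal model

A long-term rate series (events/hour, time in days) is assumed to be the
sum of a small number of stationary narrowband oscillations, a low-order
polynomial trend, and noise. The observed data are m sparse, irregular
samples of an underlying dense grid of N points spaced dt days apart:

    y = Φ Ψ x + Φ T z + ε = A x + B z + ε.

`Ψ` is an oscillation dictionary, `T` a Vandermonde trend dictionary, and
`Φ` a row-selection operator (never materialized; rows of `Ψ` and `T` are
evaluated directly at the sample positions, fractional positions allowed).
Stationarity in the frequency domain is assumed throughout: phase drift and
oscillations that appear or disappear mid-record are outside the model.

## Oscillation dictionary

The base dictionary is the orthonormal DCT-II synthesis matrix with
1-based column index k and the 1/√2 DC correction,

    Ψ[n, k] = √(2/N) · (1+[k=1])^(−1/2) · cos(π (2n−1)(k−1) / (2N)).

Its native frequency grid is sparse at long periods (near 100 days the
integer grid resolves only ~10% steps), so the grid is remapped: column k
carries a real frequency index f(k) ≥ 1, and a target period P contributes
the fractional index f = 1 + 2·N·dt/P. Default targets are 2–150 days in
0.5-day steps (capped at the record length; thinned evenly when a short
record lacks the high-frequency budget to absorb them). For each inserted
column, one identity column with period below a removal ceiling — 0.25 days,
or 3·dt when the dense grid is coarser — is removed uniformly at random
(seeded), keeping the dictionary square (n = N). The retained integer-index
columns remain exactly orthonormal; the inserted columns are locally
coherent by construction (two cosines 0.5 days apart in period at ~140 days
differ by less than 0.01 cycles over a one-year record, so their coherence
is near 1 for any dictionary of this density). Columns separated by ≥1.5×
in period have coherence < 0.2.

The trend dictionary has p = max_degree + 1 columns, `T[:, j] = t̃^j`, with
time affinely normalized to [−1, 1] before exponentiation (raw day counts
raised to powers destroy conditioning). Default max_degree = 1, matching
the simulator's first-order trend.

## Estimation

The joint problem `min ‖y − Ax − Bz‖² s.t. ‖x‖₁ ≤ δ` is reduced by variable
projection: `P = I − B B⁺` (applied through an SVD-derived orthonormal
basis of range(B); rank tolerance 1e-10 of the leading singular value, no
m×m matrix formed), then

    min_x ‖P(y − A x)‖²  s.t. ‖x‖₁ ≤ δ,      ẑ = B⁺(y − A x̂).

The constrained (L1-ball) form is solved directly — δ is the method's
tuning parameter — by FISTA with the exact sort-based Euclidean projection
onto the L1 ball, per-column adaptive restart, and a power-iteration
Lipschitz bound. Multiple right-hand sides or budgets (the shuffle null,
the CV delta path) run as batched columns of one solver call; converged
columns are frozen and dropped from the batch. Convergence is declared
when the relative objective change between checks (every 10 iterations)
falls below the tolerance: 1e-8 for small exact work, 1e-6 for full-scale
fits, 1e-4 inside cross-validation where only the MSE ranking matters.
Iteration caps: 50,000 (default), 5,000 (full-scale fits), 2,000 (CV).
The variable-projection route is certified in the tests against an
independent joint solve (split x = u − v, smooth QP via SLSQP) and the
constrained solver against the exact piecewise-linear LARS/lasso path.

## Choosing δ

"10-fold 75/25 cross-validation" is implemented as Monte-Carlo CV: ten
independent random 75/25 splits of the fixed sample set (a partitioned
10-fold scheme cannot produce 75/25 splits). Held-out MSE is averaged per
δ; the reported confidence half-width is 1.96·sd/√folds; ties break toward
the smaller (sparser) δ. The automatic grid brackets 20 log-spaced points
from 1e-2 to 1e2·‖y‖₂·√m — spanning inactive to saturated constraint —
and is followed by one refinement pass of 10 log-spaced points between the
neighbors of the bracket minimizer. The refinement matters: the bracket's
~3× spacing can overshoot the minimum by enough that the surplus budget
fits in-sample noise and seeds small spurious sidelobes in the spectrum.
User-supplied grids are scored exactly as given, without refinement.

## Significance

The noise floor is nonparametric: the observed values are permuted over
the fixed sample times (inter-sample intervals preserved), the model is
refit with the same δ and dictionaries, and |x| recorded — 100 iterations
by default (25 in the scaled-down experiments). A coefficient is
significant when its amplitude is ≥ the 99th percentile of the noise floor
for its period, with equality counting and exact zeros never flagged.

The floor for a period is estimated from the null amplitudes of all grid
bins within ±10% of that period (widened to the nearest 25 bins in
log-period where the grid is sparser than that), not from the bin alone,
and is bounded below by the 99th percentile of the entire finite-period
shuffle distribution. Both safeguards address the same artifact of an
exact-sparse solver: null fits concentrate their L1 budget on a small set
of columns, so individual bins — and, at the isolated long-period end of
the grid, whole period regions — are zero in every shuffle, and a per-bin
percentile of zero would flag arbitrarily small leaked amplitudes (e.g.
windowing leakage of a strong 100-day component onto the 182.5-day
column). The resulting thresholds are period-specific wherever the null is
informative and fall back to the noise-floor envelope where it is empty;
an interior-point solver, whose noise floor is strictly positive
everywhere, needs neither safeguard. `pool_halfwidth=0` with
`global_floor=False` recovers the strict bin-by-bin rule.

## Simulator

`simulate_ied_series` emulates a year of hourly IED counts updated every
20 minutes (26,280 points): baseline 60 events/h, stationary cosines at
1, 7, 15, 21, 30, 50 and 100 days of 10 events/h each (phases 0), a
first-order trend rising 20 events/h across the year, Gaussian noise of
sd 8 events/h, clipped at zero (clipping touches <1% of points under these
defaults). Amplitudes, baseline and noise are not prescribed anywhere
beyond "comparable to long-term IED rates"; these defaults sit in the
visual range of real hippocampal recordings and are fully configurable. A
Poisson count mode replaces the Gaussian noise when integer counts are
wanted. The single-cycle generator for the detection grid uses amplitude
5/15 events/h (low/high variance) and noise sd set so the realized SNR
(a²/2σ²) is 1 or 10 (low/high).

What the simulator does not emulate: frequency-domain non-stationarity,
bursty or autocorrelated noise, device telemetry artifacts, and the
detector chain that produces real IED rates. Passing tests therefore
demonstrate recovery under the stated stationary conditions, not
performance on any particular device record.

## Evaluation experiments

- Dense reference spectrum: continuous wavelet transform with a
  generalized Morse wavelet, γ = 3 and time-bandwidth product γβ = 60
  (β = 20), built as a frequency-domain filter bank with unit peak gain,
  power averaged over time per scale; scales span 0.5–150 days (truncated
  to half the record when shorter). The conventional "Morlet" label for
  this symmetry/time-bandwidth parameterization belongs to the Morse
  family, which is what is implemented.
- Peaks are local maxima above a prominence floor of 5% of the global
  maximum. Agreement between a reference peak and the model spectrum is
  the offset to the nearest significant model peak divided by the
  reference period; sweeps average this over 10 resamplings per condition.
- Data drops: contiguous blocks (12/30/60 days, 120 days total) placed
  uniformly at random without overlap; sampling then draws a fixed count
  (default 1307) from the remaining days.
- Frequency-specific agreement: both series are zero-phase filtered in
  bands [0.9P, 1.1P] for central periods 1–120 days, the original is
  interpolated onto the reconstruction's time vector, and Pearson r with
  its two-sided p is reported per band. Bands longer than a third of the
  record are skipped.
- Detection grid: a single simulated cycle (1–120 days) per
  variance/SNR/sampling-rate cell; a repeat counts as detected when a
  significant peak lies within 10% of the true period; the rate is the
  percentage over 10 repeats.

## Phase analysis

Reconstructions are filtered with least-squares FIR bandpass filters
applied forward-backward (zero net phase) in the conserved cycle bands
0.9–1.1, 5–10, 15–25 and 25–35 days. The tap count spans three cycles of
the slowest passband period, capped at a third of the record and forced
odd; transition bands are 15% of each edge frequency. Instantaneous phase
is the angle of the analytic (Hilbert) signal with phase 0 at the cycle
peak, increasing through the cycle; events take the phase of the nearest
grid sample. Non-uniformity of event phases uses the Hodges–Ajne omnibus
statistic m (minimum count in any closed half-circle): the exact tail
2^(1−n)·(n−2m)·C(n,m) for n ≤ 50 and the standard large-sample
approximation beyond (the exact binomial coefficient overflows well past
that boundary).

## Problem sizes used in tests and the acceptance script

The full-scale study conditions (20-minute updates, N = 26,280) are kept
for the generator defaults. The end-to-end recovery experiment runs on an
hourly variant of the same year (N = 8,760, identical periods, trend and
noise), sampled at 5/day over 360 days (m = 1,800), with a 25-iteration
null; the sampling-density sweep runs on a 6-hourly variant (N = 1,460)
with a compact explicit CV grid and 10-iteration nulls. These grids
preserve every study condition that matters to the claims (periods,
amplitudes, noise, sampling rates) while keeping a full pipeline run in
minutes on a single core.

## Known limitations

- Long-period columns are mutually coherent on a one-year record, so a
  single oscillation appears as a small cluster of significant bins rather
  than one; peak matching uses the 10% tolerance accordingly.
- The null preserves the value multiset but not any autocorrelation of the
  noise; heavy-tailed or strongly autocorrelated residuals would make the
  floor optimistic.
- Regularly spaced samples alias: the method requires irregular sampling,
  and the samplers here draw uniformly at random by design.
- δ selection dominates runtime (two CV passes ≈ 10–20 solver calls per
  fold); the solver is exact-sparse, so spectra are cleaner than an
  interior-point solve but per-bin nulls degenerate without the local
  pooling described above.
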