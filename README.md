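# bpwp — basis pursuit denoising with polynomial detrending

Long-term neurophysiological monitoring rarely yields the dense, regular
timeseries that Fourier methods need. Implanted devices that log features
such as the hourly rate of inter-ictal epileptiform discharges (IEDs) drop
data to battery, storage and connectivity limits, and a deliberately sparse
sampling schedule can extend device life — if the underlying circadian and
multidien cycles can still be recovered from a few irregular samples per
day. `bpwp` recovers narrowband oscillations and a slow polynomial trend
from exactly such sparse, irregularly sampled series.

## Model

The observed samples `y` (length m) are modeled as

    y = A x + B z + ε,     A = Φ Ψ,   B = Φ T

where `Ψ` is an N×N orthonormal DCT-II dictionary whose frequency axis has
been remapped to densify long periods (a target period `P` enters at the
fractional frequency index `f = 1 + 2·N·dt/P`), `T` is an N×p Vandermonde
trend dictionary in normalized time, and `Φ` selects the m observed rows.
The coefficients are estimated by the L1-ball-constrained least squares

    min_{x,z} ‖y − A x − B z‖²   s.t.  ‖x‖₁ ≤ δ,

reduced by variable projection to a one-variable problem: with
`P = I − B B⁺`, solve `min_x ‖P(y − A x)‖²` under the same constraint
(FISTA with exact projection onto the L1 ball), then `z = B⁺(y − A x)`.
The budget δ is chosen by 10-fold Monte-Carlo 75/25 cross-validation
(minimum held-out MSE). Significance of each spectral coefficient is
assessed against a noise floor built by shuffling the observed values over
their fixed sample times and refitting (default 100 times); a coefficient
is significant when its amplitude reaches the 99th percentile of the null
amplitudes for its period. Reconstructions `ŝ = Ψ x + T z` can be
band-pass filtered (zero-phase least-squares FIR), Hilbert-transformed,
and tested for event-phase preference with the Hodges–Ajne omnibus test.

## Worked example

Simulate a year of IED rates (baseline 60 events/h, oscillations at
1/7/15/21/30/50/100 days, first-order trend, Gaussian noise) on an hourly
grid, keep 5 random samples per day, and recover the spectrum:

```python
import numpy as np
from bpwp import SimulationSpec, simulate_ied_series, random_sample
from bpwp.basis import build_frequency_mapping
from bpwp.workflow import analyze

dense = simulate_ied_series(SimulationSpec(update_minutes=60.0, seed=42))
sampled = random_sample(dense, 5.0, window_days=(0.0, 360.0), seed=7)   # 1800 samples
grid = build_frequency_mapping(dense.N, dense.dt, seed=0)
result = analyze(sampled, grid, n_shuffles=25, seed=11)

sig = result.spectrum.significant_periods()
print(f"delta = {result.delta:.0f}")
print("significant periods (d):", np.round(np.sort(sig)[::-1], 2))
print("trend z:", np.round(result.fit.z, 2))
```

Output from this exact run:

```
delta = 5063
significant periods (d): [1.015e+02 1.010e+02 1.005e+02 1.000e+02 9.950e+01 9.900e+01 5.000e+01
 3.000e+01 2.100e+01 1.500e+01 7.020e+00 7.000e+00 1.000e+00 3.100e-01
 2.800e-01 2.000e-01 1.300e-01 1.300e-01 1.100e-01 9.000e-02]
trend z: [70.19 10.39]
```

Every generator period (1, 7, 15, 21, 30, 50, 100 days) appears as a
significant peak; the small cluster around 100 days reflects the 0.5-day
grid spacing at long periods, and the handful of tiny sub-daily flags is
the expected ~1% tail of the 99th-percentile rule over several thousand
short-period bins. The selected budget δ≈5000 matches the total
coefficient mass of the seven amplitude-10 components (each
≈ 10·√(N/2) ≈ 660). The trend coefficients are in normalized time over
[−1, 1]: a mean level of ~70 events/h and a slope of 2·10.4 ≈ 21 events/h
across the year, recovering the simulated +20 events/h drift.

The `bpwp` command line exposes the pipeline stages
(`simulate`, `sample`, `cv`, `fit`, `significance`, `reconstruct`,
`evaluate-density`, `evaluate-drops`, `evaluate-bands`, `phase`,
`detect-experiment`); run `bpwp --help`.

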