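"""Simulated inter-ictal discharge (IED) rate timeseries.

The default simulation emulates a year of hourly IED counts updated every
20 minutes (26,280 points): a baseline rate, stationary oscillations at
periods of 1, 7, 15, 21, 30, 50 and 100 days, a first-order polynomial
trend, and additive Gaussian noise, clipped at zero (rates cannot be
negative). A Poisson count mode is available as an alternative noise model.

Amplitudes, baseline and noise level are tunable; the defaults (baseline 60
events/h, 10 events/h per component, noise sd 8 events/h, +20 events/h trend
over the year) put the series in the visual range of real hippocampal IED
rate recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sampling import DenseSeries

__all__ = ["SimulationSpec", "simulate_ied_series", "simulate_single_cycle"]

DEFAULT_PERIODS = (1.0, 7.0, 15.0, 21.0, 30.0, 50.0, 100.0)

#: Oscillation amplitudes (events/h) for the variance conditions of the
#: single-cycle grid, and noise scaling for the SNR conditions. SNR is the
#: oscillation power (a^2/2) over the noise variance.
VARIANCE_LEVELS = {"low": 5.0, "high": 15.0}
SNR_LEVELS = {"low": 1.0, "high": 10.0}


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth description of a simulated rate series."""

    duration_days: float = 365.0
    update_minutes: float = 20.0
    window_hours: float = 1.0
    periods_days: tuple[float, ...] = DEFAULT_PERIODS
    amplitudes: tuple[float, ...] = (10.0,) * 7
    phases: tuple[float, ...] = (0.0,) * 7
    trend: tuple[float, ...] = (0.0, 20.0)  # polynomial in t/duration
    baseline: float = 60.0
    noise_sd: float = 8.0
    poisson: bool = False
    seed: int | None = 0

    def __post_init__(self) -> None:
        if min(self.periods_days, default=1.0) <= 0:
            raise ValueError("periods must be positive")
        if len(self.amplitudes) != len(self.periods_days):
            raise ValueError("need one amplitude per period")
        if len(self.phases) != len(self.periods_days):
            raise ValueError("need one phase per period")

    @property
    def dt_days(self) -> float:
        return self.update_minutes / 1440.0

    @property
    def n_points(self) -> int:
        return int(round(self.duration_days / self.dt_days))


def _mean_rate(spec: SimulationSpec, t: np.ndarray) -> np.ndarray:
    rate = np.full(t.size, spec.baseline)
    for P, a, ph in zip(spec.periods_days, spec.amplitudes, spec.phases):
        rate += a * np.cos(2.0 * np.pi * t / P + ph)
    if spec.trend:
        rate += np.polynomial.polynomial.polyval(t / spec.duration_days, spec.trend)
    return rate


def simulate_ied_series(spec: SimulationSpec | None = None) -> DenseSeries:
    """Generate the dense simulated rate series described by ``spec``."""
    spec = spec or SimulationSpec()
    t = spec.dt_days * np.arange(spec.n_points)
    mean = _mean_rate(spec, t)
    if np.mean(mean) < 0:
        raise ValueError("configuration yields a negative mean rate")
    rng = np.random.default_rng(spec.seed)
    if spec.poisson:
        values = rng.poisson(np.clip(mean, 0.0, None)).astype(float)
    else:
        values = mean + (rng.standard_normal(spec.n_points) * spec.noise_sd
                         if spec.noise_sd > 0 else 0.0)
        np.clip(values, 0.0, None, out=values)
    return DenseSeries(t0=0.0, dt=spec.dt_days, values=values)


def simulate_single_cycle(
    period_days: float,
    variance_level: str = "high",
    snr_level: str = "high",
    base_spec: SimulationSpec | None = None,
) -> tuple[DenseSeries, SimulationSpec]:
    """One oscillation plus noise, for the detection-rate grid.

    ``variance_level`` sets the oscillation amplitude; ``snr_level`` sets the
    noise standard deviation so the realized SNR (a^2/2 over sigma^2) matches
    the named condition. Returns the series and the resolved spec.
    """
    if not 0 < period_days:
        raise ValueError("period must be positive")
    base = base_spec or SimulationSpec()
    try:
        amp = VARIANCE_LEVELS[variance_level]
        snr = SNR_LEVELS[snr_level]
    except KeyError as e:
        raise ValueError(f"unknown level {e.args[0]!r}; use 'low' or 'high'") from None
    noise_sd = float(np.sqrt(amp**2 / 2.0 / snr))
    spec = replace(
        base,
        periods_days=(float(period_days),),
        amplitudes=(amp,),
        phases=(0.0,),
        trend=(),
        noise_sd=noise_sd,
    )
    return simulate_ied_series(spec), spec
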