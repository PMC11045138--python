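"""Delimited-text and JSON file formats.

Timeseries are plain CSV with a ``time_days,value`` header; dense series
additionally carry ``# t0=...`` and ``# dt=...`` metadata lines before the
header. Events are one ``event_time_days`` column. Grids, fits and configs
are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import FrequencyGrid
from .sampling import DenseSeries, EventSeries, SampledSeries, SamplingMask
from .solver import BPWPFit, Spectrum

__all__ = [
    "read_series",
    "write_series",
    "read_events",
    "write_events",
    "read_spectrum",
    "write_spectrum",
    "write_fit",
    "write_cv_report",
]


def write_series(path: str | Path, series: SampledSeries | DenseSeries) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if isinstance(series, DenseSeries):
            fh.write(f"# t0={series.t0!r}\n# dt={series.dt!r}\n")
        fh.write("time_days,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_series(path: str | Path) -> SampledSeries | DenseSeries:
    """Read a timeseries file; ``#`` metadata lines make it a dense series."""
    path = Path(path)
    meta: dict[str, float] = {}
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = float(val)
                continue
            if line.lower().startswith("time_days"):
                continue
            t_str, _, v_str = line.partition(",")
            rows.append((float(t_str), float(v_str) if v_str.strip() else np.nan))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    if "t0" in meta and "dt" in meta:
        return DenseSeries(t0=meta["t0"], dt=meta["dt"], values=v)
    return SampledSeries(times=t, values=v)


def write_events(path: str | Path, events: EventSeries) -> None:
    Path(path).write_text(
        "event_time_days\n" + "".join(f"{float(t)!r}\n" for t in events.event_times)
    )


def read_events(path: str | Path) -> EventSeries:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    vals = [float(ln) for ln in lines if not ln.lower().startswith("event_time")]
    return EventSeries(event_times=np.asarray(vals))


def write_mask(path: str | Path, mask: SamplingMask) -> None:
    Path(path).write_text(json.dumps(mask.indices.tolist()))


def read_mask(path: str | Path) -> SamplingMask:
    return SamplingMask(np.asarray(json.loads(Path(path).read_text()), dtype=np.int64))


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    df = pd.DataFrame({
        "period_days": spectrum.period_days,
        "amplitude": spectrum.amplitude,
        "significant": spectrum.significant
        if spectrum.significant is not None
        else np.zeros(spectrum.amplitude.size, dtype=bool),
        "threshold": spectrum.threshold
        if spectrum.threshold is not None
        else np.full(spectrum.amplitude.size, np.nan),
    })
    df.to_csv(path, index=False)


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        period_days=df["period_days"].to_numpy(),
        amplitude=df["amplitude"].to_numpy(),
        significant=df["significant"].to_numpy(dtype=bool),
        threshold=df["threshold"].to_numpy(),
    )


def write_fit(path: str | Path, fit: BPWPFit, grid: FrequencyGrid, grid_ref: str = "") -> None:
    nz = np.flatnonzero(fit.x)
    periods = grid.period_days
    payload = {
        "delta": fit.delta,
        "objective": fit.objective,
        "p": int(fit.z.size),
        "z": fit.z.tolist(),
        "grid_ref": grid_ref,
        "x_nonzero": [
            {
                "index": int(i),
                "f": float(grid.f_values[i]),
                "period_days": float(periods[i]) if np.isfinite(periods[i]) else None,
                "amplitude": float(abs(fit.x[i])),
                "sign": int(np.sign(fit.x[i])),
            }
            for i in nz
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_cv_report(path: str | Path, cv) -> None:
    pd.DataFrame({
        "delta": cv.delta_grid,
        "mean_mse": cv.mean_mse,
        "ci95": cv.ci95,
    }).to_csv(path, index=False)
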