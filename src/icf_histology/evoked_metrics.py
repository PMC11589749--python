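"""Sensor-level evoked metrics: TEP averaging, ICF contrasts, LMFP.

The intracortical-facilitation (ICF) contrast is always the paired-pulse
response minus the single-pulse response; summary indices are means over the
50-120 ms post-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import ROI_ELECTRODES
from .preprocess import EpochSet


@dataclass
class Evoked:
    """Trial-averaged waveform (channels x time, microvolts)."""

    data: np.ndarray
    ch_names: list[str]
    times: np.ndarray
    n_trials: int
    condition: str = ""

    def ch_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None


@dataclass(frozen=True)
class WindowSpec:
    """Post-stimulus analysis window in milliseconds (inclusive ends)."""

    start: float = 50.0
    end: float = 120.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")


def average_tep(epochs: EpochSet, condition: str = "") -> Evoked:
    """TMS-evoked potential: element-wise mean over retained trials."""
    if epochs.n_trials < 1:
        raise ValueError("cannot average an empty epoch set")
    return Evoked(
        data=epochs.data.mean(axis=0),
        ch_names=list(epochs.ch_names),
        times=epochs.times.copy(),
        n_trials=epochs.n_trials,
        condition=condition,
    )


def roi_series(
    evoked: Evoked, electrodes: tuple[str, ...] = ROI_ELECTRODES
) -> np.ndarray:
    """Unweighted mean waveform across the named electrodes."""
    idx = [evoked.ch_index(e) for e in electrodes]
    return evoked.data[idx].mean(axis=0)


def icf_contrast(series_paired: np.ndarray, series_single: np.ndarray) -> np.ndarray:
    """Point-wise paired-pulse minus single-pulse difference."""
    a = np.asarray(series_paired, dtype=float)
    b = np.asarray(series_single, dtype=float)
    if a.shape != b.shape:
        raise ValueError("time axes of the two conditions do not match")
    return a - b


def lmfp(
    evoked: Evoked,
    electrodes: tuple[str, ...] = ROI_ELECTRODES,
    mode: str = "rms",
) -> np.ndarray:
    """Local mean field power over an electrode cluster.

    ``rms`` (default): root of the mean squared voltage across the cluster
    at each time point.  ``mean_abs``: mean absolute voltage, offered as an
    alternative reading of the field-power definition.
    """
    idx = [evoked.ch_index(e) for e in electrodes]
    x = evoked.data[idx]
    if mode == "rms":
        return np.sqrt((x**2).mean(axis=0))
    if mode == "mean_abs":
        return np.abs(x).mean(axis=0)
    raise ValueError(f"unknown LMFP mode {mode!r}")


def window_mean(
    series: np.ndarray, times: np.ndarray, window: WindowSpec = WindowSpec()
) -> float | np.ndarray:
    """Mean over the analysis window (ends inclusive), along the last axis.

    Returns a scalar for a single series; for stacked series (e.g. regions x
    time) the window mean of each row.
    """
    times = np.asarray(times)
    mask = (times >= window.start) & (times <= window.end)
    if not mask.any():
        raise ValueError("analysis window contains no samples")
    out = np.asarray(series, dtype=float)[..., mask].mean(axis=-1)
    return float(out) if out.ndim == 0 else out
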