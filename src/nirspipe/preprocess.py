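"""Per-channel preprocessing: median filter, polynomial detrend, Z-score,
zero-phase Butterworth low-pass — applied in exactly that order.

Conventions fixed for reproducibility:

* median-filter edges shrink the window symmetrically (the first and last
  samples are returned unchanged for window 3);
* Z-score uses the population standard deviation (divide by N);
* the low-pass is a 2nd-order Butterworth run forward and backward
  (zero phase, 4th-order magnitude), scipy's default odd-extension padding.

Z-scoring makes every downstream quantity invariant to the unknown
per-channel pathlength factor multiplying the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import DegenerateChannelError, ParameterError


@dataclass
class PreprocessConfig:
    median_window: int = 3
    detrend_order: int = 2
    lowpass_cutoff_hz: float = 0.08
    filter_order: int = 2
    zero_phase: bool = True
    zscore: bool = True  # disable only for calibration experiments

    def validate(self, fs: float) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ParameterError("median_window must be an odd integer >= 1")
        if self.detrend_order < 0:
            raise ParameterError("detrend_order must be >= 0")
        if not 0.0 < self.lowpass_cutoff_hz < fs / 2.0:
            raise ParameterError(
                f"lowpass cutoff must lie in (0, fs/2) = (0, {fs / 2.0}), "
                f"got {self.lowpass_cutoff_hz}"
            )
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")


def median_filter(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered sliding median; window shrinks symmetrically at the edges."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ParameterError("series must be one-dimensional")
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ParameterError(f"window {window} exceeds series length {x.size}")
    if window == 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    core = np.lib.stride_tricks.sliding_window_view(x, window)
    out[half : x.size - half] = np.median(core, axis=1)
    for i in range(half):
        out[i] = np.median(x[: 2 * i + 1])
        out[x.size - 1 - i] = np.median(x[x.size - 2 * i - 1 :])
    return out


def detrend_poly(series: np.ndarray, order: int = 2) -> np.ndarray:
    """Subtract the least-squares polynomial of the given order."""
    x = np.asarray(series, dtype=float)
    if x.size <= order + 1:
        raise ParameterError(
            f"series of length {x.size} too short for order-{order} detrend"
        )
    t = np.arange(x.size, dtype=float)
    poly = np.polynomial.Polynomial.fit(t, x, deg=order)
    return x - poly(t)


def zscore(series: np.ndarray, ddof: int = 0) -> np.ndarray:
    """(x - mean) / std with population SD by default.

    Raises :class:`DegenerateChannelError` on a constant series; callers
    flag such channels and drop them from regressors and statistics.
    """
    x = np.asarray(series, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0.0 or not np.isfinite(sd) or np.ptp(x) == 0.0:
        raise DegenerateChannelError("constant series cannot be Z-scored")
    return (x - x.mean()) / sd


def lowpass(
    series: np.ndarray,
    fs: float,
    cutoff: float = 0.08,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth low-pass; forward-backward (zero phase) by default."""
    x = np.asarray(series, dtype=float)
    if not 0.0 < cutoff < fs / 2.0:
        raise ParameterError(f"cutoff must lie in (0, {fs / 2.0}), got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def preprocess_series(series: np.ndarray, fs: float, config: PreprocessConfig | None = None) -> np.ndarray:
    """Run the four-step chain on one channel."""
    cfg = config or PreprocessConfig()
    cfg.validate(fs)
    raw = np.asarray(series, dtype=float)
    if np.ptp(raw) == 0.0:  # dead channel: flag before detrend turns it
        raise DegenerateChannelError("constant channel")  # into numeric dust
    x = median_filter(raw, cfg.median_window)
    x = detrend_poly(x, cfg.detrend_order)
    if cfg.zscore:
        x = zscore(x)
    x = lowpass(x, fs, cfg.lowpass_cutoff_hz, cfg.filter_order, cfg.zero_phase)
    return x


def preprocess_recording(recording, config: PreprocessConfig | None = None):
    """Preprocess every channel of a Recording.

    Returns ``(recording', degenerate_flags)`` where flagged (constant)
    channels are zeroed in the output and must be excluded downstream.
    """
    cfg = config or PreprocessConfig()
    cfg.validate(recording.fs)
    out = np.empty_like(np.asarray(recording.data, dtype=float))
    flags: list[int] = []
    for i, ch_id in enumerate(recording.channel_ids):
        try:
            out[i] = preprocess_series(recording.data[i], recording.fs, cfg)
        except DegenerateChannelError:
            out[i] = 0.0
            flags.append(ch_id)
    return replace(recording, data=out), flags
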