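"""Task-unrelated channel regression, applied per hemisphere.

Channels whose Pearson correlation with the raw task boxcar is below the
threshold (|r| < 0.2 by default, strict) are averaged into one regressor
per hemisphere; that regressor is regressed out (OLS with intercept) of
every channel on the same hemisphere only.  The report carries the
before/after channel-correlation matrices as the standard diagnostic.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptySelectionError, ParameterError
from .probe_geometry import ProbeLayout

logger = logging.getLogger(__name__)

SIDES = ("left", "right")


@dataclass
class RegressionReport:
    """Diagnostics from one hemispheric-regression pass."""

    task_r: dict[int, float]
    selected: dict[str, set[int]]
    regressors: dict[str, np.ndarray | None]
    coefficients: dict[int, float]
    residual_variance: dict[int, float]
    corr_before: np.ndarray
    corr_after: np.ndarray
    channel_ids: list[int]
    degenerate: set[int] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def mean_offdiag_abs(self, which: str = "before", channel_ids=None) -> float:
        """Mean |r| over off-diagonal entries of a correlation matrix."""
        mat = self.corr_before if which == "before" else self.corr_after
        idx = np.arange(len(self.channel_ids))
        if channel_ids is not None:
            pos = {c: i for i, c in enumerate(self.channel_ids)}
            idx = np.array([pos[c] for c in channel_ids])
        sub = mat[np.ix_(idx, idx)]
        mask = ~np.eye(len(idx), dtype=bool)
        return float(np.nanmean(np.abs(sub[mask])))


def task_correlation(series: np.ndarray, boxcar: np.ndarray) -> float:
    """Pearson correlation between one channel and the 0/1 task function.

    Returns NaN for a constant (degenerate) series — such channels are
    treated as task-unrelated but never enter regressor construction.
    """
    x = np.asarray(series, dtype=float)
    b = np.asarray(boxcar, dtype=float)
    if x.shape != b.shape:
        raise ParameterError(f"length mismatch: series {x.shape}, boxcar {b.shape}")
    if b.std() == 0.0:
        raise ParameterError("task function is constant")
    if x.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, b)[0, 1])


def select_task_unrelated(
    r_by_channel: dict[int, float],
    side_channels: set[int],
    threshold: float = 0.2,
) -> set[int]:
    """Channels on one side with |r| strictly below the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    return {
        ch
        for ch in side_channels
        if ch in r_by_channel
        and np.isfinite(r_by_channel[ch])
        and abs(r_by_channel[ch]) < threshold
    }


def build_regressor(data: np.ndarray, channel_ids: list[int], selected: set[int]) -> np.ndarray:
    """Pointwise mean of the selected channels' (preprocessed) series."""
    if not selected:
        raise EmptySelectionError("no task-unrelated channels to average")
    pos = {c: i for i, c in enumerate(channel_ids)}
    rows = [pos[c] for c in sorted(selected)]
    return np.asarray(data, dtype=float)[rows].mean(axis=0)


def regress_out(series: np.ndarray, regressor: np.ndarray):
    """OLS fit of series on {intercept, regressor}; returns the residual.

    Returns ``(residual, slope)``.  A constant regressor degrades to an
    intercept-only fit (mean removal), with slope 0.
    """
    y = np.asarray(series, dtype=float)
    r = np.asarray(regressor, dtype=float)
    if y.shape != r.shape:
        raise ParameterError("series and regressor lengths differ")
    if r.std() == 0.0:
        logger.warning("constant regressor: intercept-only fit")
        return y - y.mean(), 0.0
    X = np.column_stack([np.ones_like(r), r])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta, float(beta[1])


def _corr_matrix(data: np.ndarray) -> np.ndarray:
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # constant rows -> NaN
        return np.corrcoef(data)


def apply_hemispheric_regression(
    data: np.ndarray,
    channel_ids: list[int],
    layout: ProbeLayout,
    boxcar: np.ndarray,
    threshold: float = 0.2,
    degenerate: set[int] | None = None,
    leave_one_out: bool = False,
) -> tuple[np.ndarray, RegressionReport]:
    """Regress each hemisphere's task-unrelated average out of that side.

    Parameters
    ----------
    data
        (n_channels, n_samples) preprocessed matrix.
    channel_ids
        Channel id per row of ``data``.
    leave_one_out
        If true, each channel's own series is excluded from the regressor
        applied to it (off by default; the standard method averages over
        all selected channels including the target).

    Returns the cleaned matrix and a :class:`RegressionReport`.  If a
    hemisphere yields an empty selection, regression is skipped for that
    side and a warning recorded — the threshold is never adjusted.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] != len(channel_ids):
        raise ParameterError("data row count does not match channel_ids")
    degenerate = set(degenerate or ())
    pos = {c: i for i, c in enumerate(channel_ids)}

    task_r = {c: task_correlation(data[pos[c]], boxcar) for c in channel_ids}
    degenerate |= {c for c, r in task_r.items() if not np.isfinite(r)}

    out = data.copy()
    selected: dict[str, set[int]] = {}
    regressors: dict[str, np.ndarray | None] = {}
    coefficients: dict[int, float] = {}
    warnings: list[str] = []

    for side in SIDES:
        side_ids = layout.hemisphere_channels(side) & set(channel_ids)
        sel = select_task_unrelated(task_r, side_ids, threshold) - degenerate
        selected[side] = sel
        if not sel:
            regressors[side] = None
            msg = f"{side} hemisphere: no task-unrelated channels; regression skipped"
            warnings.append(msg)
            logger.warning(msg)
            continue
        reg = build_regressor(data, channel_ids, sel)
        regressors[side] = reg
        for c in sorted(side_ids):
            if leave_one_out and c in sel and len(sel) > 1:
                reg_c = build_regressor(data, channel_ids, sel - {c})
            else:
                reg_c = reg
            out[pos[c]], coefficients[c] = regress_out(data[pos[c]], reg_c)

    resid_var = {c: float(out[pos[c]].var()) for c in channel_ids}
    report = RegressionReport(
        task_r=task_r,
        selected=selected,
        regressors=regressors,
        coefficients=coefficients,
        residual_variance=resid_var,
        corr_before=_corr_matrix(data),
        corr_after=_corr_matrix(out),
        channel_ids=list(channel_ids),
        degenerate=degenerate,
        warnings=warnings,
    )
    return out, report


def regress_recording(recording, layout, boxcar, threshold: float = 0.2, degenerate=None, **kw):
    """Recording-level wrapper around :func:`apply_hemispheric_regression`."""
    cleaned, report = apply_hemispheric_regression(
        recording.data, recording.channel_ids, layout, boxcar,
        threshold=threshold, degenerate=degenerate, **kw,
    )
    return replace(recording, data=cleaned), report


def plot_correlation_maps(report: RegressionReport, path) -> None:
    """Before/after correlation heat maps (the standard visual diagnostic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.4))
    for ax, mat, title in (
        (axes[0], report.corr_before, "before regression"),
        (axes[1], report.corr_after, "after regression"),
    ):
        im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(title)
        ax.set_xlabel("channel")
        ax.set_ylabel("channel")
    fig.colorbar(im, ax=axes, shrink=0.8, label="r")
    fig.savefig(path, dpi=120)
    plt.close(fig)
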