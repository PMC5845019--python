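"""Per-trial GLM activation estimates.

Each trial's boxcar is convolved with a canonical double-gamma
hemodynamic response function to form one design column; ordinary least
squares gives one beta per trial, and the per-condition activation
magnitude is the arithmetic mean of the trial betas.  No prewhitening or
precoloring is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, RankDeficiencyError


def double_gamma_hrf(
    fs: float,
    duration_s: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma impulse response, normalized to unit peak.

    Difference of two gamma densities (response peaking near ``peak_s``
    seconds, undershoot near ``undershoot_s``), sampled at ``fs``.
    """
    if fs <= 0 or duration_s <= 0:
        raise ParameterError("fs and duration must be positive")
    t = np.arange(0.0, duration_s, 1.0 / fs)
    h = sps.gamma.pdf(t, peak_s) - sps.gamma.pdf(t, undershoot_s) / undershoot_ratio
    peak = np.abs(h).max()
    if peak == 0.0:
        raise ParameterError("degenerate HRF parameters")
    return h / peak


def delta_hrf(fs: float) -> np.ndarray:
    """Unit impulse 'HRF' — convolution identity, useful for testing."""
    return np.array([1.0])


@dataclass
class DesignMatrix:
    """Trial-wise design: one HRF-convolved boxcar per trial + intercept."""

    matrix: np.ndarray  # (n_samples, n_columns)
    labels: list[str]
    trial_columns: list[int]

    @property
    def n_trials(self) -> int:
        return len(self.trial_columns)


def build_design(design, hrf: np.ndarray | None = None, drift: bool = False) -> DesignMatrix:
    """Build the trial-wise design matrix for a sampled task design.

    Parameters
    ----------
    design
        A TaskDesign (onsets, durations, boxcar sampled at design.fs).
    hrf
        Impulse response sampled at the same rate; defaults to the
        canonical double-gamma.
    drift
        Append a linear-drift column (off by default; slow drift is
        removed upstream by the polynomial detrend).
    """
    if hrf is None:
        hrf = double_gamma_hrf(design.fs)
    hrf = np.asarray(hrf, dtype=float)
    n = design.n_samples
    t = np.arange(n) / design.fs

    cols = []
    labels = []
    for k, onset in enumerate(design.onsets):
        box = ((t >= onset) & (t < onset + design.task_s)).astype(float)
        cols.append(np.convolve(box, hrf)[:n])
        labels.append(f"trial{k + 1}")
    trial_columns = list(range(len(cols)))
    cols.append(np.ones(n))
    labels.append("intercept")
    if drift:
        cols.append(np.linspace(-1.0, 1.0, n))
        labels.append("drift")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            "design matrix is rank deficient (overlapping trials or degenerate HRF)"
        )
    return DesignMatrix(matrix=X, labels=labels, trial_columns=trial_columns)


@dataclass
class GLMFit:
    betas: np.ndarray          # all columns, design order
    trial_betas: np.ndarray    # trial columns only
    residual_variance: float


def fit_glm(series: np.ndarray, X: DesignMatrix) -> GLMFit:
    """Ordinary least squares: beta-hat = (X'X)^-1 X'y."""
    y = np.asarray(series, dtype=float)
    M = X.matrix
    if y.shape[0] != M.shape[0]:
        raise ParameterError(
            f"series length {y.shape[0]} != design rows {M.shape[0]}"
        )
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    dof = max(M.shape[0] - M.shape[1], 1)
    return GLMFit(
        betas=beta,
        trial_betas=beta[X.trial_columns],
        residual_variance=float(resid @ resid / dof),
    )


def average_betas(trial_betas: np.ndarray) -> float:
    """Arithmetic mean of the per-trial betas."""
    b = np.asarray(trial_betas, dtype=float)
    if b.size < 1:
        raise ParameterError("need at least one trial beta")
    return float(b.mean())


# ---------------------------------------------------------------------------
# BetaTable

@dataclass
class BetaTable:
    """Tidy per-trial betas: subject, condition, channel, trial, beta."""

    trials: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["subject", "condition", "channel", "trial", "beta"]
        )
    )

    def means(self) -> pd.DataFrame:
        """Per (subject, condition, channel) arithmetic mean beta."""
        return (
            self.trials.groupby(["subject", "condition", "channel"], as_index=False)[
                "beta"
            ]
            .mean()
            .rename(columns={"beta": "mean_beta"})
        )

    def write(self, path) -> None:
        self.trials.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "BetaTable":
        return cls(trials=pd.read_csv(path, sep="\t"))


def glm_recording(recording, design, hrf: np.ndarray | None = None, drift: bool = False,
                  exclude: set[int] | None = None) -> BetaTable:
    """Fit the trial-wise GLM to every channel of one recording."""
    X = build_design(design, hrf=hrf, drift=drift)
    exclude = exclude or set()
    rows = []
    for i, ch in enumerate(recording.channel_ids):
        if ch in exclude:
            continue
        fit = fit_glm(recording.data[i], X)
        for k, b in enumerate(fit.trial_betas):
            rows.append(
                {
                    "subject": recording.subject_id,
                    "condition": recording.condition,
                    "channel": ch,
                    "trial": k + 1,
                    "beta": b,
                }
            )
    return BetaTable(trials=pd.DataFrame(rows))


def concat_beta_tables(tables) -> BetaTable:
    frames = [t.trials for t in tables if len(t.trials)]
    if not frames:
        return BetaTable()
    return BetaTable(trials=pd.concat(frames, ignore_index=True))
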