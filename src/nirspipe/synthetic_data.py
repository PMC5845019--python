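"""Synthetic block-design fNIRS generator with known ground truth.

Each channel is built as

    L_c * [ A_c * (HRF * boxcar) + g_c * shared_systemic + drift_c + noise ]

where the shared systemic term sums sinusoids in the cardiac (1-2 Hz),
respiratory (0.2-0.4 Hz), Mayer-wave (~0.1 Hz) and very-low-frequency
(0.01-0.05 Hz) bands with randomized frequencies and phases, plus a slow
polynomial drift.  L_c is an unknown positive per-channel scale factor
(photon pathlength); g_c a per-channel coupling gain.  The "stress"
scenarios narrow the VLF band onto the 0.04 Hz block frequency, the
hardest interference case for a 10 s task / 15 s rest design.

Everything is deterministic under a seed; group simulations derive one
child seed per subject from the master seed via numpy's SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import ParameterError
from .glm_activation import double_gamma_hrf
from .probe_geometry import ProbeLayout

CONDITIONS = ("ME_left", "ME_right", "MI_left", "MI_right")


# ---------------------------------------------------------------------------
# task design

@dataclass
class TaskDesign:
    """Block design: n_trials of task_s seconds followed by rest_s rest."""

    n_trials: int
    task_s: float
    rest_s: float
    fs: float
    lead_in_s: float
    onsets: np.ndarray
    n_samples: int

    @property
    def period_s(self) -> float:
        return self.task_s + self.rest_s

    @property
    def fundamental_freq_hz(self) -> float:
        """Expected response frequency: one cycle per trial period."""
        return 1.0 / self.period_s

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + self.n_trials * self.period_s

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def boxcar(self) -> np.ndarray:
        """0/1 task function: 1 exactly during [onset, onset + task_s)."""
        t = self.times
        box = np.zeros(self.n_samples)
        for onset in self.onsets:
            box[(t >= onset) & (t < onset + self.task_s)] = 1.0
        return box


def make_design(
    n_trials: int = 20,
    task_s: float = 10.0,
    rest_s: float = 15.0,
    fs: float = 7.14,
    lead_in_s: float | None = None,
) -> TaskDesign:
    """Build the block design; lead-in rest defaults to one rest period.

    Onsets fall at lead_in + k*(task_s + rest_s); the record ends after
    the last trial's rest.  Sample count is floor(duration * fs).
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if task_s <= 0 or rest_s <= 0 or fs <= 0:
        raise ParameterError("durations and sampling rate must be positive")
    lead = rest_s if lead_in_s is None else float(lead_in_s)
    if lead < 0:
        raise ParameterError("lead_in_s must be >= 0")
    onsets = lead + np.arange(n_trials) * (task_s + rest_s)
    duration = lead + n_trials * (task_s + rest_s)
    return TaskDesign(
        n_trials=n_trials,
        task_s=task_s,
        rest_s=rest_s,
        fs=fs,
        lead_in_s=lead,
        onsets=onsets,
        n_samples=int(np.floor(duration * fs)),
    )


# ---------------------------------------------------------------------------
# systemic interference

@dataclass(frozen=True)
class SystemicComponent:
    band_hz: tuple[float, float]
    amplitude: float


@dataclass
class SystemicParams:
    """Bands and amplitudes of the shared physiological components."""

    cardiac: SystemicComponent = SystemicComponent((1.0, 2.0), 0.4)
    respiration: SystemicComponent = SystemicComponent((0.2, 0.4), 0.4)
    mayer: SystemicComponent = SystemicComponent((0.095, 0.105), 0.6)
    vlf: SystemicComponent = SystemicComponent((0.01, 0.05), 1.0)
    drift_amplitude: float = 0.5
    gain_mean: float = 1.0
    gain_sd: float = 0.2
    # Task-evoked global physiology (blood pressure / arousal responses
    # phase-locked to the blocks): amplitude of a shared component built
    # by convolving the boxcar with a slow kernel peaking task_locked_peak_s
    # seconds after onset.  Zero by default.
    task_locked_amplitude: float = 0.0
    task_locked_peak_s: float = 8.0

    def components(self) -> dict[str, SystemicComponent]:
        return {
            "cardiac": self.cardiac,
            "respiration": self.respiration,
            "mayer": self.mayer,
            "vlf": self.vlf,
        }


def stress_systemic_params(
    vlf_amplitude: float = 1.5, task_locked_amplitude: float = 0.5
) -> SystemicParams:
    """The hardest interference case for a 10 s task / 15 s rest design:
    a VLF sinusoid confined to 0.033-0.045 Hz (overlapping the 0.04 Hz
    block frequency, which defeats plain band-pass filtering) plus a
    task-evoked global component that biases every channel's beta in the
    same direction across subjects.  Coupling gains spread widely so some
    channels stay weakly coupled."""
    return SystemicParams(
        vlf=SystemicComponent((0.033, 0.045), vlf_amplitude),
        task_locked_amplitude=task_locked_amplitude,
        gain_sd=0.5,
    )


def simulate_systemic(
    params: SystemicParams, n_samples: int, fs: float, seed, design: "TaskDesign | None" = None
) -> np.ndarray:
    """One shared interference series: band sinusoids, polynomial drift,
    and (when configured and a design is given) a task-locked component."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    out = np.zeros(n_samples)
    for comp in params.components().values():
        lo, hi = comp.band_hz
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += comp.amplitude * np.sin(2.0 * np.pi * f * t + phase)
    if params.drift_amplitude:
        u = np.linspace(-1.0, 1.0, n_samples)
        coeffs = rng.normal(0.0, params.drift_amplitude, size=3)
        out += coeffs[0] * u + coeffs[1] * u**2 + coeffs[2] * u**3
    if params.task_locked_amplitude and design is not None:
        from scipy import stats as _sps

        peak = rng.normal(params.task_locked_peak_s, 1.0)
        peak = max(2.0, float(peak))
        tk = np.arange(0.0, 30.0, 1.0 / fs)
        kernel = _sps.gamma.pdf(tk, peak)
        tl = np.convolve(design.boxcar[:n_samples], kernel)[:n_samples]
        sd = tl.std()
        if sd > 0:
            out += params.task_locked_amplitude * (tl - tl.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# ground truth and recordings

@dataclass
class GroundTruth:
    """Known generative parameters of one simulated recording."""

    active_channels: set[int]
    response_amplitude: dict[int, float]
    pathlength_factors: dict[int, float]
    coupling_gains: dict[int, float]
    noise_sd: float
    hrf: np.ndarray | None = None


@dataclass
class Recording:
    """One subject x condition multichannel time series."""

    subject_id: str
    condition: str
    fs: float
    data: np.ndarray  # (n_channels, n_samples)
    channel_ids: list[int]
    species: str = "HbO2"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_ids):
            raise ParameterError(
                f"data must be (n_channels={len(self.channel_ids)}, n_samples), "
                f"got {self.data.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def simulate_recording(
    layout: ProbeLayout,
    design: TaskDesign,
    truth: GroundTruth,
    params: SystemicParams,
    seed,
    subject_id: str = "S01",
    condition: str = "ME_left",
    fs: float | None = None,
) -> tuple[Recording, GroundTruth]:
    """Simulate one recording; ground truth (with drawn L/gains) returned.

    Pathlength factors and coupling gains not supplied in ``truth`` are
    drawn here (log-uniform L in [0.5, 2], normal gains) so that the
    returned GroundTruth is always fully populated.
    """
    if fs is not None and fs != design.fs:
        raise ParameterError(
            f"requested fs {fs} does not match design fs {design.fs}"
        )
    rng = np.random.default_rng(seed)
    n = design.n_samples
    ids = layout.channel_ids
    bad = truth.active_channels - set(ids)
    if bad:
        raise ParameterError(f"active channels not in layout: {sorted(bad)}")

    hrf = truth.hrf if truth.hrf is not None else double_gamma_hrf(design.fs)
    response = np.convolve(design.boxcar, hrf)[:n]

    shared = simulate_systemic(params, n, design.fs, rng, design=design)

    L = dict(truth.pathlength_factors)
    gains = dict(truth.coupling_gains)
    for ch in ids:
        if ch not in L:
            L[ch] = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        if ch not in gains:
            gains[ch] = float(rng.normal(params.gain_mean, params.gain_sd))

    data = np.zeros((len(ids), n))
    for i, ch in enumerate(ids):
        amp = truth.response_amplitude.get(ch, 0.0)
        if ch not in truth.active_channels:
            amp = 0.0
        chan = amp * response + gains[ch] * shared
        if truth.noise_sd:
            chan = chan + rng.normal(0.0, truth.noise_sd, size=n)
        data[i] = L[ch] * chan

    rec = Recording(
        subject_id=subject_id,
        condition=condition,
        fs=design.fs,
        data=data,
        channel_ids=list(ids),
    )
    full_truth = replace(
        truth,
        response_amplitude={
            ch: (truth.response_amplitude.get(ch, 0.0) if ch in truth.active_channels else 0.0)
            for ch in ids
        },
        pathlength_factors=L,
        coupling_gains=gains,
        hrf=hrf,
    )
    return rec, full_truth


# ---------------------------------------------------------------------------
# scenarios and group simulation

def _contralateral_m1(layout: ProbeLayout, condition: str) -> set[int]:
    hand = condition.rsplit("_", 1)[-1]
    side = "right" if hand == "left" else "left"
    return layout.roi_channels("M1", side)


def _bilateral_smc(layout: ProbeLayout, condition: str) -> set[int]:
    return layout.roi_channels("SMC")


@dataclass(frozen=True)
class Scenario:
    name: str
    active_fn: Callable[[ProbeLayout, str], set[int]] | None
    amplitude: float
    amplitude_sd: float
    noise_sd: float
    params_fn: Callable[[], SystemicParams]


SCENARIOS: dict[str, Scenario] = {
    "null": Scenario("null", None, 0.0, 0.0, 0.5, SystemicParams),
    # noise_sd 1.0 keeps measurement noise comparable to the shared
    # interference, so the task-unrelated selection stays viable even when
    # the VLF component aligns with the task
    "stress-null": Scenario("stress-null", None, 0.0, 0.0, 1.0, stress_systemic_params),
    "contralateral-M1": Scenario(
        "contralateral-M1", _contralateral_m1, 1.0, 0.2, 0.5, SystemicParams
    ),
    "bilateral-SMC": Scenario(
        "bilateral-SMC", _bilateral_smc, 1.0, 0.2, 0.5, SystemicParams
    ),
}


def simulate_group(
    n_subjects: int,
    layout: ProbeLayout,
    scenario: str,
    seed,
    condition: str = "ME_left",
    design: TaskDesign | None = None,
) -> tuple[list[Recording], list[GroundTruth]]:
    """Simulate independent subjects under a named scenario.

    Per-subject seeds are spawned from the master seed, so the full group
    is bit-reproducible and any prefix of subjects is stable as well.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    sc = SCENARIOS[scenario]
    design = design or make_design()
    active = sc.active_fn(layout, condition) if sc.active_fn else set()

    children = np.random.SeedSequence(seed).spawn(n_subjects)
    recordings: list[Recording] = []
    truths: list[GroundTruth] = []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        amp = {
            ch: max(0.0, float(rng.normal(sc.amplitude, sc.amplitude_sd)))
            for ch in active
        }
        truth = GroundTruth(
            active_channels=set(active),
            response_amplitude=amp,
            pathlength_factors={},
            coupling_gains={},
            noise_sd=sc.noise_sd,
        )
        rec, full = simulate_recording(
            layout,
            design,
            truth,
            sc.params_fn(),
            rng,
            subject_id=f"S{s + 1:02d}",
            condition=condition,
        )
        recordings.append(rec)
        truths.append(full)
    return recordings, truths
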