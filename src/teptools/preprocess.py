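"""Sensor-space preprocessing: epochs -> averaged, cleaned TEP.

The chain mirrors standard TMS-EEG practice: epochs recorded at 1450 Hz
are down-sampled to 725 Hz, trials with ocular or muscle artifacts are
rejected by deterministic thresholds (replacing manual inspection), the
remaining trials are averaged and band-pass filtered 2-40 Hz, bad channels
are reconstructed by spherical-spline interpolation, the average reference
is applied, and the result is baseline-corrected over -300..-50 ms.

Stage order is enforced through the ``processing_log`` carried by
:class:`Evoked`: calling a step out of order raises
:class:`PipelineOrderError`.  All time windows are half-open ``[a, b)`` in
milliseconds, with time zero at the pulse sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .montage import Montage
from .simulate import CLEAN, EpochSet

__all__ = [
    "RejectionCriteria",
    "Evoked",
    "PipelineOrderError",
    "downsample",
    "reject_artifacts",
    "average_and_filter",
    "interpolate_bad",
    "average_reference",
    "baseline_correct",
    "preprocess_evoked",
    "write_evoked_csv",
    "read_evoked_csv",
]


class PreprocessingError(ValueError):
    """Raised for invalid preprocessing parameters."""


class PipelineOrderError(RuntimeError):
    """Raised when preprocessing steps are applied out of order."""


#: Default EOG proxy channels (frontal row nearest the eyes).
DEFAULT_EOG_CHANNELS: tuple[str, ...] = ("Fp1", "Fpz", "Fp2", "AF7", "AF8")


@dataclass(frozen=True)
class RejectionCriteria:
    """Deterministic thresholds replacing semi-automatic trial screening.

    ``abs_amplitude_limit``: any sample beyond this (uV) rejects the trial.
    ``eog_limit``: threshold (uV) on the frontal EOG-proxy channels.
    ``hf_power_limit``: maximal per-channel ratio of >40 Hz power to total
    power (muscle activity detector).
    """

    abs_amplitude_limit: float = 100.0
    eog_limit: float = 70.0
    hf_power_limit: float = 0.5
    eog_channels: tuple[str, ...] = DEFAULT_EOG_CHANNELS

    def __post_init__(self) -> None:
        if min(self.abs_amplitude_limit, self.eog_limit, self.hf_power_limit) <= 0:
            raise PreprocessingError("all rejection limits must be positive")


@dataclass(frozen=True)
class Evoked:
    """Trial-averaged TEP with a complete processing audit trail."""

    data: np.ndarray  # channels x samples, uV
    fs: float
    t0_index: int
    channels: tuple[str, ...]
    n_trials_used: int
    processing_log: tuple[str, ...]
    subject_id: str = ""
    condition: str = ""

    @property
    def times(self) -> np.ndarray:
        idx = np.arange(self.data.shape[1])
        return (idx - self.t0_index) * 1000.0 / self.fs

    def has_step(self, step: str) -> bool:
        return step in self.processing_log


def _require_order(evoked: Evoked, step: str, after: tuple[str, ...],
                   before: tuple[str, ...]) -> None:
    for prereq in after:
        if not evoked.has_step(prereq):
            raise PipelineOrderError(
                f"{step} requires {prereq} to have been applied first "
                f"(log: {evoked.processing_log})"
            )
    for later in before + (step,):
        if evoked.has_step(later):
            raise PipelineOrderError(
                f"{step} cannot follow {later} (log: {evoked.processing_log})"
            )


# ---------------------------------------------------------------------------
# trial-level steps
# ---------------------------------------------------------------------------

def downsample(epochs: EpochSet, target_fs: float = 725.0) -> EpochSet:
    """Anti-alias low-pass (0.45 x target, zero-phase) then decimate.

    The sampling rate must be an integer multiple of ``target_fs``; the
    pulse sample is preserved exactly (``t0_index`` maps to a kept sample).
    """
    if target_fs > epochs.fs:
        raise PreprocessingError("target_fs exceeds the sampling rate")
    ratio = epochs.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise PreprocessingError(
            f"fs {epochs.fs} not divisible by target {target_fs}"
        )
    if factor == 1:
        return epochs
    b, a = butter(8, 0.45 * target_fs, btype="low", fs=epochs.fs)
    filtered = filtfilt(b, a, epochs.data, axis=-1)
    start = epochs.t0_index % factor
    out = filtered[:, :, start::factor]
    return replace(
        epochs,
        data=out,
        fs=float(target_fs),
        t0_index=epochs.t0_index // factor,
    )


def _hf_power_ratio(trial: np.ndarray, fs: float, cutoff_hz: float = 40.0) -> np.ndarray:
    """Per-channel ratio of power above ``cutoff_hz`` to total power."""
    spec = np.abs(np.fft.rfft(trial - trial.mean(axis=-1, keepdims=True), axis=-1)) ** 2
    freqs = np.fft.rfftfreq(trial.shape[-1], 1.0 / fs)
    total = spec.sum(axis=-1)
    total[total == 0] = 1.0
    return spec[:, freqs > cutoff_hz].sum(axis=-1) / total


def reject_artifacts(
    epochs: EpochSet, criteria: RejectionCriteria | None = None
) -> tuple[EpochSet, pd.DataFrame]:
    """Remove trials failing any amplitude/EOG/high-frequency criterion.

    Returns the cleaned epochs and a per-trial report with the triggering
    rule(s).  Rejection is fully deterministic.
    """
    criteria = criteria or RejectionCriteria()
    eog_idx = [
        epochs.channels.index(ch)
        for ch in criteria.eog_channels
        if ch in epochs.channels
    ]
    rows = []
    keep = np.ones(epochs.n_trials, dtype=bool)
    for i in range(epochs.n_trials):
        trial = epochs.data[i]
        rules = []
        if np.abs(trial).max() > criteria.abs_amplitude_limit:
            rules.append("abs_amplitude")
        if eog_idx and np.abs(trial[eog_idx]).max() > criteria.eog_limit:
            rules.append("eog")
        if _hf_power_ratio(trial, epochs.fs).max() > criteria.hf_power_limit:
            rules.append("hf_power")
        keep[i] = not rules
        rows.append(
            {
                "trial": i,
                "kept": not rules,
                "rule": "+".join(rules) if rules else "",
                "true_flag": int(epochs.trial_flags[i]),
            }
        )
    if not keep.any():
        raise PreprocessingError(
            "all trials rejected; review the rejection thresholds"
        )
    cleaned = replace(
        epochs, data=epochs.data[keep], trial_flags=epochs.trial_flags[keep]
    )
    return cleaned, pd.DataFrame(rows)


def rejection_sensitivity(report: pd.DataFrame) -> float:
    """Fraction of ground-truth artifact trials that were rejected."""
    artifacts = report[report["true_flag"] != CLEAN]
    if len(artifacts) == 0:
        return float("nan")
    return float((~artifacts["kept"]).mean())


# ---------------------------------------------------------------------------
# evoked-level steps
# ---------------------------------------------------------------------------

def bandpass_evoked(data: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass along the last axis."""
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise PreprocessingError(f"band {band} outside (0, fs/2)")
    b, a = butter(3, [lo, hi], btype="bandpass", fs=fs)
    return filtfilt(b, a, data, axis=-1)


def average_and_filter(
    epochs: EpochSet, band: tuple[float, float] = (2.0, 40.0)
) -> Evoked:
    """Arithmetic trial mean followed by the 2-40 Hz zero-phase band-pass."""
    if epochs.n_trials < 1:
        raise PreprocessingError("no trials to average")
    mean = epochs.data.mean(axis=0)
    return Evoked(
        data=bandpass_evoked(mean, epochs.fs, band),
        fs=epochs.fs,
        t0_index=epochs.t0_index,
        channels=tuple(epochs.channels),
        n_trials_used=epochs.n_trials,
        processing_log=("average", "filter"),
        subject_id=epochs.subject_id,
        condition=epochs.condition,
    )


def _spline_g(cosang: np.ndarray, stiffness: int, n_terms: int) -> np.ndarray:
    """Spherical-spline kernel g(cos gamma) (Perrin-style basis)."""
    cosang = np.asarray(cosang, dtype=float)
    res = np.zeros_like(cosang)
    Pnm1 = np.ones_like(cosang)
    Pn = cosang.copy()
    for n in range(1, n_terms + 1):
        res += (2 * n + 1) / (n**stiffness * (n + 1) ** stiffness) * Pn
        Pnp1 = ((2 * n + 1) * cosang * Pn - n * Pnm1) / (n + 1)
        Pnm1, Pn = Pn, Pnp1
    return res / (4.0 * np.pi)


def spline_interpolate(
    good_pos: np.ndarray,
    good_data: np.ndarray,
    target_pos: np.ndarray,
    stiffness: int = 4,
    n_terms: int = 50,
    regularization: float = 1e-8,
) -> np.ndarray:
    """Spherical-spline interpolation of scalp values.

    ``good_data`` is (n_good, n_samples); returns (n_targets, n_samples).
    The spline exactly reproduces constants for any regularization.
    """
    ng = len(good_pos)
    G = _spline_g(good_pos @ good_pos.T, stiffness, n_terms)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + regularization * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    rhs = np.vstack([np.atleast_2d(good_data), np.zeros((1, np.atleast_2d(good_data).shape[1]))])
    sol = np.linalg.solve(A, rhs)
    coefs, c0 = sol[:ng], sol[ng]
    Gt = _spline_g(np.atleast_2d(target_pos) @ good_pos.T, stiffness, n_terms)
    return c0[None, :] + Gt @ coefs


def interpolate_bad(
    evoked: Evoked,
    montage: Montage,
    stiffness: int = 4,
    n_terms: int = 50,
    regularization: float = 1e-8,
) -> Evoked:
    """Rewrite bad channels by spherical-spline interpolation.

    Refuses when more than 20% of channels are bad.  Channel count and
    order are unchanged; only the bad rows are replaced.
    """
    _require_order(evoked, "interpolate_bad", after=("filter",),
                   before=("average_reference", "baseline_correct"))
    bad = sorted(montage.bad_channels)
    if not bad:
        raise PreprocessingError("montage has no bad channels to interpolate")
    if len(bad) >= len(evoked.channels):
        raise PreprocessingError("bad channels must be a proper subset")
    if len(bad) > 0.2 * len(evoked.channels):
        raise PreprocessingError(
            f"{len(bad)} bad of {len(evoked.channels)} channels exceeds the "
            "20% interpolation limit"
        )
    bad_idx = [evoked.channels.index(ch) for ch in bad]
    good_idx = [i for i in range(len(evoked.channels)) if i not in bad_idx]
    montage_order = [montage.index(ch) for ch in evoked.channels]
    pos = montage.positions[montage_order]
    interp = spline_interpolate(
        pos[good_idx], evoked.data[good_idx], pos[bad_idx],
        stiffness=stiffness, n_terms=n_terms, regularization=regularization,
    )
    data = evoked.data.copy()
    data[bad_idx] = interp
    return replace(
        evoked, data=data,
        processing_log=evoked.processing_log + ("interpolate_bad",),
    )


def average_reference(evoked: Evoked) -> Evoked:
    """Subtract the per-sample mean across channels.

    Idempotent: re-referencing an already average-referenced TEP leaves it
    unchanged (and does not duplicate the log entry).
    """
    if evoked.has_step("average_reference"):
        if evoked.has_step("baseline_correct"):
            raise PipelineOrderError("average_reference cannot follow baseline_correct")
        return replace(evoked, data=evoked.data - evoked.data.mean(axis=0, keepdims=True))
    _require_order(evoked, "average_reference", after=("filter",),
                   before=("baseline_correct",))
    data = evoked.data - evoked.data.mean(axis=0, keepdims=True)
    return replace(
        evoked, data=data,
        processing_log=evoked.processing_log + ("average_reference",),
    )


def baseline_correct(
    evoked: Evoked, window: tuple[float, float] = (-300.0, -50.0)
) -> Evoked:
    """Subtract the per-channel mean over the pre-pulse window ``[a, b)``."""
    _require_order(evoked, "baseline_correct", after=("average_reference",),
                   before=())
    a, b = window
    if b > 0:
        raise PreprocessingError("baseline window must precede the pulse")
    t = evoked.times
    sel = (t >= a) & (t < b)
    if not sel.any():
        raise PreprocessingError(f"baseline window {window} outside the epoch")
    data = evoked.data - evoked.data[:, sel].mean(axis=1, keepdims=True)
    return replace(
        evoked, data=data,
        processing_log=evoked.processing_log + ("baseline_correct",),
    )


def preprocess_evoked(
    epochs: EpochSet,
    montage: Montage,
    target_fs: float = 725.0,
    criteria: RejectionCriteria | None = None,
    band: tuple[float, float] = (2.0, 40.0),
    baseline: tuple[float, float] = (-300.0, -50.0),
    interpolate: bool = True,
) -> tuple[Evoked, pd.DataFrame]:
    """Full chain: downsample, reject, average+filter, interpolate,
    re-reference, baseline-correct.  Returns the TEP and the trial report."""
    epochs = downsample(epochs, target_fs)
    epochs, report = reject_artifacts(epochs, criteria)
    evoked = average_and_filter(epochs, band)
    if interpolate and montage.bad_channels:
        evoked = interpolate_bad(evoked, montage)
    evoked = average_reference(evoked)
    evoked = baseline_correct(evoked, baseline)
    return evoked, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_evoked_csv(evoked: Evoked, path) -> None:
    df = pd.DataFrame(evoked.data.T, columns=list(evoked.channels))
    df.insert(0, "time_ms", evoked.times)
    df.to_csv(path, index=False, float_format="%.12g")


def read_evoked_csv(path, fs: float, n_trials_used: int = 0,
                    processing_log: tuple[str, ...] = ("average", "filter")) -> Evoked:
    df = pd.read_csv(path)
    times = df["time_ms"].to_numpy()
    data = df.drop(columns="time_ms").to_numpy().T
    dt = np.median(np.diff(times))
    t0_index = int(np.argmin(np.abs(times)))
    return Evoked(
        data=data,
        fs=float(fs if fs else 1000.0 / dt),
        t0_index=t0_index,
        channels=tuple(df.columns[1:]),
        n_trials_used=n_trials_used,
        processing_log=processing_log,
    )


def epochs_from_edf(path, n_samples_per_trial: int, t0_index: int,
                    subject_id: str = "", condition: str = "pre") -> EpochSet:
    """Import epochs from an EDF file holding concatenated fixed-length trials."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    n_ch, total = data.shape
    n_trials = total // n_samples_per_trial
    if n_trials < 1:
        raise PreprocessingError("EDF shorter than one trial")
    data = data[:, : n_trials * n_samples_per_trial]
    trials = data.reshape(n_ch, n_trials, n_samples_per_trial).transpose(1, 0, 2)
    return EpochSet(
        data=trials,
        fs=float(raw.info["sfreq"]),
        t0_index=t0_index,
        channels=tuple(raw.ch_names),
        subject_id=subject_id,
        condition=condition,
        trial_flags=np.zeros(n_trials, dtype=np.int8),
    )
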