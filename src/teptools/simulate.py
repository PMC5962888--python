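"""Synthetic multi-subject TMS-EEG sessions with known ground truth.

Each simulated session mirrors the emulated experiment: per subject, three
blocks of single-pulse TMS-EEG (pre / during / post neuromodulation), each
block ~180 trials of 60-channel epochs spanning -800..+800 ms around the
pulse at 1450 Hz.  The evoked response is produced by a small set of
cortical source patches (Gaussian-windowed pulses at fixed latencies)
passed through the spherical-shell lead field; trials add per-channel 1/f
("pink") noise, and a configurable fraction of trials carries an ocular or
muscle artifact.  A condition-dependent gain multiplies all source
amplitudes: gain 1 in every block reproduces a null (no-modulation)
scenario; gain > 1 during/post emulates an excitability increase.

Amplitudes are in nA*mm of total patch moment; with the default head model
they yield evoked scalp peaks of a few microvolts, the conventional scale
of TMS-evoked potentials.  The TMS pulse/decay artifact itself is not
simulated: the emulated amplifier gates it, so epochs are artifact-free at
the pulse sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .forward import LeadField

__all__ = [
    "ComponentParams",
    "SubjectParams",
    "ConditionGain",
    "EpochSet",
    "DEFAULT_TEMPLATE",
    "CONDITIONS",
    "sample_subject",
    "simulate_block",
    "simulate_experiment",
    "pink_noise",
    "save_epochs",
    "load_epochs",
]

CONDITIONS: tuple[str, str, str] = ("pre", "during", "post")

#: Trial artifact codes.
CLEAN, OCULAR, MUSCLE = 0, 1, 2

#: Between-subject priors for the evoked components.  Three components
#: populate all four analysis clusters/parcels: an early patch under the
#: (left parietal) TMS hotspot, a middle-latency contralateral parietal
#: patch, and a late bilateral frontal patch.  Values are simulator
#: conventions chosen to give 2-5 uV evoked peaks.
DEFAULT_TEMPLATE: dict = {
    "components": [
        {
            "name": "p25_left_parietal",
            "centers": [(-0.45, -0.55, 0.70)],
            "patch_radius_mm": 15.0,
            "latency_mean_ms": 25.0,
            "latency_sd_ms": 3.0,
            "width_ms": 8.0,
            "amplitude_mean": 20000.0,
            "amplitude_sd": 4000.0,
        },
        {
            "name": "p60_right_parietal",
            "centers": [(0.45, -0.55, 0.70)],
            "patch_radius_mm": 15.0,
            "latency_mean_ms": 60.0,
            "latency_sd_ms": 5.0,
            "width_ms": 12.0,
            "amplitude_mean": 16000.0,
            "amplitude_sd": 3000.0,
        },
        {
            "name": "p100_bilateral_frontal",
            "centers": [(-0.45, 0.45, 0.77), (0.45, 0.45, 0.77)],
            "patch_radius_mm": 15.0,
            "latency_mean_ms": 100.0,
            "latency_sd_ms": 8.0,
            "width_ms": 15.0,
            # the ~100 ms component is the dominant TEP deflection
            "amplitude_mean": 24000.0,
            "amplitude_sd": 5000.0,
        },
    ],
    "noise_sd": 12.0,       # uV, per-channel pink-noise std per trial
    "artifact_rate": 0.3,   # probability a trial carries an artifact
    "ocular_amplitude": 150.0,   # uV, mean frontal deflection
    "muscle_amplitude": 60.0,    # uV, std of the high-frequency burst
}


class SimulationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class ComponentParams:
    """One evoked component: source patch(es) sharing a time course."""

    name: str
    centers: tuple[tuple[float, float, float], ...]
    patch_radius_mm: float
    latency_ms: float
    width_ms: float
    amplitude: float  # total patch moment, nA*mm

    def __post_init__(self) -> None:
        if not (0.0 <= self.latency_ms <= 300.0):
            raise SimulationError(
                f"component latency {self.latency_ms} ms outside 0-300 ms"
            )
        if self.amplitude < 0:
            raise SimulationError("component amplitude must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters, fully determined by a seed."""

    seed: int
    components: tuple[ComponentParams, ...]
    noise_sd: float
    artifact_rate: float
    ocular_amplitude: float = 150.0
    muscle_amplitude: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise SimulationError("artifact_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ConditionGain:
    """Source-amplitude multipliers per condition; pre is 1 by convention."""

    g_pre: float = 1.0
    g_during: float = 1.0
    g_post: float = 1.0

    def __post_init__(self) -> None:
        if self.g_pre != 1.0:
            raise SimulationError("g_pre must be 1 (pre-block is the reference)")
        if self.g_during < 0 or self.g_post < 0:
            raise SimulationError("gains must be nonnegative")

    def for_condition(self, condition: str) -> float:
        return {"pre": self.g_pre, "during": self.g_during,
                "post": self.g_post}[condition]


@dataclass
class EpochSet:
    """Single-block trial data: trials x channels x samples, in uV."""

    data: np.ndarray
    fs: float
    t0_index: int
    channels: tuple[str, ...]
    subject_id: str
    condition: str
    trial_flags: np.ndarray  # 0 clean, 1 ocular, 2 muscle (ground truth)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise SimulationError("EpochSet data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channels):
            raise SimulationError("channel count mismatch")
        if len(self.trial_flags) != self.data.shape[0]:
            raise SimulationError("one flag per trial required")
        if self.condition not in CONDITIONS:
            raise SimulationError(f"condition must be one of {CONDITIONS}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms, 0 at the pulse sample."""
        idx = np.arange(self.data.shape[2])
        return (idx - self.t0_index) * 1000.0 / self.fs


def sample_subject(seed: int, template: dict | None = None) -> SubjectParams:
    """Draw one subject's generative parameters from the template priors.

    Deterministic given ``seed``: the same seed always returns identical
    parameters.  Latencies are normal draws clipped to 0-300 ms, amplitudes
    clipped at zero.
    """
    template = DEFAULT_TEMPLATE if template is None else template
    rng = np.random.default_rng(seed)
    comps = []
    for spec in template["components"]:
        lat = float(
            np.clip(
                rng.normal(spec["latency_mean_ms"], spec["latency_sd_ms"]),
                0.0,
                300.0,
            )
        )
        amp = float(
            max(0.0, rng.normal(spec["amplitude_mean"], spec["amplitude_sd"]))
        )
        comps.append(
            ComponentParams(
                name=spec["name"],
                centers=tuple(tuple(c) for c in spec["centers"]),
                patch_radius_mm=float(spec["patch_radius_mm"]),
                latency_ms=lat,
                width_ms=float(spec["width_ms"]),
                amplitude=amp,
            )
        )
    return SubjectParams(
        seed=int(seed),
        components=tuple(comps),
        noise_sd=float(template["noise_sd"]),
        artifact_rate=float(template["artifact_rate"]),
        ocular_amplitude=float(template.get("ocular_amplitude", 150.0)),
        muscle_amplitude=float(template.get("muscle_amplitude", 60.0)),
    )


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               fs: float) -> np.ndarray:
    """Per-channel independent 1/f noise, unit standard deviation.

    Spectral amplitude ~ f^(-1/2), flattened below 1 Hz to keep the very
    low frequencies finite.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.empty_like(freqs)
    shape[0] = 0.0  # no DC
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 1.0))
    spec = (
        rng.standard_normal((n_channels, len(freqs)))
        + 1j * rng.standard_normal((n_channels, len(freqs)))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _patch_weights(component: ComponentParams, leadfield: LeadField) -> np.ndarray:
    """Per-vertex moment weights; Gaussian taper, total moment = 1."""
    pos = leadfield.source_space.positions
    radius = leadfield.source_space.radius
    w = np.zeros(len(pos))
    for center in component.centers:
        c = np.asarray(center, dtype=float)
        c = radius * c / np.linalg.norm(c)
        d = np.linalg.norm(pos - c, axis=1)
        inside = d <= component.patch_radius_mm
        if not inside.any():  # degenerate patch: snap to nearest vertex
            inside = np.zeros(len(pos), bool)
            inside[np.argmin(d)] = True
        taper = np.exp(-(d**2) / (2.0 * (component.patch_radius_mm / 2.0) ** 2))
        w += np.where(inside, taper, 0.0)
    return w / w.sum()


def component_truth(
    subject: SubjectParams, leadfield: LeadField
) -> list[dict]:
    """Ground-truth description of each component for oracle checks:
    vertex weights, the index of the dominant vertex, sensor pattern."""
    out = []
    for comp in subject.components:
        w = _patch_weights(comp, leadfield)
        out.append(
            {
                "name": comp.name,
                "weights": w,
                "peak_vertex": int(np.argmax(w)),
                "pattern": leadfield.matrix @ w,
                "latency_ms": comp.latency_ms,
                "width_ms": comp.width_ms,
                "amplitude": comp.amplitude,
            }
        )
    return out


def evoked_signal(
    subject: SubjectParams,
    gain: float,
    leadfield: LeadField,
    times_ms: np.ndarray,
) -> np.ndarray:
    """Noise-free evoked sensor signal (channels x samples, uV)."""
    n_ch = leadfield.n_channels
    out = np.zeros((n_ch, len(times_ms)))
    for comp in subject.components:
        w = _patch_weights(comp, leadfield)
        pattern = leadfield.matrix @ w
        course = comp.amplitude * np.exp(
            -((times_ms - comp.latency_ms) ** 2) / (2.0 * comp.width_ms**2)
        )
        out += np.outer(pattern, course)
    return gain * out


def _frontal_profile(channels: tuple[str, ...], positions: np.ndarray) -> np.ndarray:
    """Spatial weighting of ocular artifacts: strongest at the frontal pole."""
    y = positions[:, 1]
    return np.clip(y, 0.0, None) ** 2


_MUSCLE_SETS = (
    ("T7", "FT7", "TP7", "C5", "F7"),
    ("T8", "FT8", "TP8", "C6", "F8"),
)


def _muscle_profile(channels: tuple[str, ...], side: int) -> np.ndarray:
    w = np.zeros(len(channels))
    for lab in _MUSCLE_SETS[side]:
        if lab in channels:
            w[channels.index(lab)] = 1.0
    return w


def simulate_block(
    subject: SubjectParams,
    gain: float,
    leadfield: LeadField,
    n_trials: int = 180,
    fs: float = 1450.0,
    condition: str = "pre",
    subject_id: str = "S00",
    rng: np.random.Generator | None = None,
    epoch_span_ms: tuple[float, float] = (-800.0, 800.0),
) -> EpochSet:
    """Simulate one recording block of TMS-evoked epochs.

    Every trial is ``gain * (leadfield @ source time courses)`` plus pink
    noise; trials flagged as artifactual additionally receive a
    low-frequency frontal deflection (ocular) or a high-frequency lateral
    burst (muscle).
    """
    if gain < 0:
        raise SimulationError("gain must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    n_pre = int(round(-epoch_span_ms[0] * fs / 1000.0))
    n_post = int(round(epoch_span_ms[1] * fs / 1000.0))
    n_samples = n_pre + n_post
    t0_index = n_pre
    times = (np.arange(n_samples) - t0_index) * 1000.0 / fs
    channels = tuple(leadfield.montage.channels)
    n_ch = len(channels)

    evoked = evoked_signal(subject, gain, leadfield, times)

    flags = np.zeros(n_trials, dtype=np.int8)
    art = rng.random(n_trials) < subject.artifact_rate
    kinds = rng.integers(0, 2, size=n_trials)  # 0 ocular, 1 muscle
    flags[art] = np.where(kinds[art] == 0, OCULAR, MUSCLE)

    data = np.empty((n_trials, n_ch, n_samples))
    frontal = _frontal_profile(channels, leadfield.montage.positions)
    for i in range(n_trials):
        trial = evoked.copy()
        if subject.noise_sd > 0:
            trial = trial + subject.noise_sd * pink_noise(rng, n_ch, n_samples, fs)
        if flags[i] == OCULAR:
            amp = max(100.0, rng.normal(subject.ocular_amplitude, 20.0))
            center = rng.uniform(times[0] + 200.0, times[-1] - 200.0)
            pulse = amp * np.exp(-((times - center) ** 2) / (2.0 * 80.0**2))
            trial = trial + np.outer(frontal, pulse)
        elif flags[i] == MUSCLE:
            side = int(rng.integers(0, 2))
            profile = _muscle_profile(channels, side)
            dur = rng.uniform(100.0, 300.0)
            start = rng.uniform(times[0] + 50.0, times[-1] - dur - 50.0)
            window = (times >= start) & (times < start + dur)
            burst = np.zeros(n_samples)
            raw = rng.standard_normal(int(window.sum()))
            from scipy.signal import butter, filtfilt

            b, a = butter(4, [60.0, min(300.0, 0.45 * fs)], "bandpass", fs=fs)
            if window.sum() > 30:
                raw = filtfilt(b, a, raw)
            sd = raw.std() or 1.0
            burst[window] = subject.muscle_amplitude * raw / sd
            trial = trial + np.outer(profile, burst)
        data[i] = trial

    return EpochSet(
        data=data,
        fs=float(fs),
        t0_index=t0_index,
        channels=channels,
        subject_id=subject_id,
        condition=condition,
        trial_flags=flags,
    )


def simulate_experiment(
    n_subjects: int,
    gains: ConditionGain,
    seed: int,
    leadfield: LeadField,
    template: dict | None = None,
    n_trials: int = 180,
    fs: float = 1450.0,
):
    """Yield pre/during/post blocks for each subject (lazy generator).

    Per subject, the three blocks share the same generative component
    amplitudes; only the per-condition gain and the noise realizations
    differ.  Fully deterministic given ``(seed, config)``.
    """
    if n_subjects < 1:
        raise SimulationError("need at least one subject")
    base = np.random.SeedSequence(seed)
    subject_seqs = base.spawn(n_subjects)
    for i, seq in enumerate(subject_seqs):
        params_seed = int(seq.generate_state(1)[0] & 0x7FFFFFFF)
        subject = sample_subject(params_seed, template)
        subject = replace(subject, seed=params_seed)
        block_seqs = seq.spawn(3)
        for condition, bseq in zip(CONDITIONS, block_seqs):
            yield simulate_block(
                subject,
                gains.for_condition(condition),
                leadfield,
                n_trials=n_trials,
                fs=fs,
                condition=condition,
                subject_id=f"S{i:02d}",
                rng=np.random.default_rng(bseq),
            )


# ---------------------------------------------------------------------------
# persistence: raw little-endian float32 + JSON sidecar
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(epochs.data, dtype="<f4")
    (d / "data.bin").write_bytes(arr.tobytes())
    meta = {
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "fs": epochs.fs,
        "t0_index": epochs.t0_index,
        "channels": list(epochs.channels),
        "subject_id": epochs.subject_id,
        "condition": epochs.condition,
        "trial_flags": [int(f) for f in epochs.trial_flags],
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_epochs(directory) -> EpochSet:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    data = np.frombuffer((d / "data.bin").read_bytes(), dtype=meta["dtype"])
    data = data.reshape(meta["shape"]).astype(float)
    return EpochSet(
        data=data,
        fs=meta["fs"],
        t0_index=meta["t0_index"],
        channels=tuple(meta["channels"]),
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        trial_flags=np.array(meta["trial_flags"], dtype=np.int8),
    )
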