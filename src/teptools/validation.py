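"""Calibration harnesses for the source-imaging stage.

These routines measure operating characteristics of the inverse and of the
permutation threshold on synthetic data with known ground truth: peak
localization error for noiseless single sources, and the family-wise error
rate of the max-statistic threshold on pure-noise recordings.  They are
used by the test suite and by the reproduction script; the statistical
harness for the mixed-model stage lives in :mod:`teptools.stats`.
"""

from __future__ import annotations

import warnings

import numpy as np

from .forward import LeadField
from .inverse import make_inverse, permutation_threshold
from .simulate import EpochSet, pink_noise

__all__ = ["localization_errors", "permutation_fwer"]


def localization_errors(
    leadfield: LeadField,
    n_runs: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Peak-localization error (mm) for noiseless single-source topographies.

    For each run one source vertex is drawn, its noise-free topography is
    projected through the minimum-norm kernel, and the distance between the
    |current| peak and the true vertex is recorded.
    """
    inv = make_inverse(leadfield, np.eye(leadfield.n_channels))
    rng = np.random.default_rng(seed)
    pos = leadfield.source_space.positions
    errors = np.empty(n_runs)
    for i in range(n_runs):
        s = int(rng.integers(0, leadfield.n_sources))
        currents = inv.kernel @ leadfield.matrix[:, s]
        peak = int(np.argmax(np.abs(currents)))
        errors[i] = np.linalg.norm(pos[peak] - pos[s])
    return errors


def permutation_fwer(
    leadfield: LeadField,
    n_simulations: int = 200,
    n_permutations: int = 100,
    n_trials: int = 40,
    noise_sd: float = 12.0,
    fs: float = 725.0,
    epoch_span_ms: tuple[float, float] = (-400.0, 400.0),
    test_window_ms: tuple[float, float] = (0.0, 150.0),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of pure-noise simulations with any significant post-pulse
    source sample inside ``test_window_ms`` (family-wise error rate)."""
    montage = leadfield.montage
    n_pre = int(round(-epoch_span_ms[0] * fs / 1000.0))
    n_post = int(round(epoch_span_ms[1] * fs / 1000.0))
    n_samples = n_pre + n_post
    inv = None
    base = np.random.SeedSequence(seed)
    hits = 0
    for sim_seq in base.spawn(n_simulations):
        rng = np.random.default_rng(sim_seq)
        data = noise_sd * np.stack(
            [pink_noise(rng, montage.n_channels, n_samples, fs)
             for _ in range(n_trials)]
        )
        epochs = EpochSet(
            data=data, fs=fs, t0_index=n_pre, channels=montage.channels,
            subject_id="null", condition="pre",
            trial_flags=np.zeros(n_trials, dtype=np.int8),
        )
        if inv is None:
            from .inverse import baseline_noise_cov

            inv = make_inverse(leadfield, baseline_noise_cov(epochs))
        perm_seed = int(sim_seq.generate_state(1)[0] & 0x7FFFFFFF)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est, mask = permutation_threshold(
                epochs, inv, n_permutations=n_permutations, alpha=alpha,
                seed=perm_seed,
            )
        t = est.times
        sel = (t >= test_window_ms[0]) & (t < test_window_ms[1])
        hits += bool(mask.mask[:, sel].any())
    return hits / n_simulations
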