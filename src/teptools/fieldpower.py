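"""Global and local mean field power of the averaged TEP.

GMFP(t) is the spatial standard deviation of the average-referenced TEP
across the K channels at sample t (population convention, 1/K):

    GMFP(t) = sqrt( (1/K) sum_k (V_k(t) - Vbar(t))^2 )

LMFP applies the same formula restricted to a 4-electrode cluster, with
deviations taken from the cluster-local mean (a flag switches to the
global mean for sensitivity analyses).  Both are cumulated over the three
post-pulse analysis windows 0-50, 50-100 and 100-150 ms as rectangular
sums (value x sample spacing, in uV*ms), and the natural log of the
cumulated value feeds the mixed-model inference downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Evoked

__all__ = [
    "FieldPowerTrace",
    "DEFAULT_WINDOWS",
    "WINDOW_LABELS",
    "gmfp",
    "lmfp",
    "cumulate",
    "build_table",
    "write_table_csv",
    "read_table_csv",
]

#: The three post-pulse analysis windows, half-open, in ms.
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = (
    (0.0, 50.0),
    (50.0, 100.0),
    (100.0, 150.0),
)
WINDOW_LABELS: tuple[str, ...] = ("w1", "w2", "w3")


class FieldPowerError(ValueError):
    """Raised for invalid field-power computations."""


@dataclass(frozen=True)
class FieldPowerTrace:
    """Per-sample field power (uV); ``scope`` is 'global' or a cluster name."""

    values: np.ndarray
    fs: float
    t0_index: int
    scope: str

    @property
    def times(self) -> np.ndarray:
        idx = np.arange(len(self.values))
        return (idx - self.t0_index) * 1000.0 / self.fs


def _spatial_sd(data: np.ndarray) -> np.ndarray:
    return np.sqrt(((data - data.mean(axis=0, keepdims=True)) ** 2).mean(axis=0))


def gmfp(evoked: Evoked) -> FieldPowerTrace:
    """Global mean field power over all channels.

    The spatial-deviation form makes the result independent of any common
    per-sample offset, so an explicit average reference is not required
    for correctness (it is still enforced upstream by the pipeline).
    """
    if evoked.data.shape[0] < 2:
        raise FieldPowerError("GMFP needs at least 2 channels")
    return FieldPowerTrace(
        values=_spatial_sd(evoked.data),
        fs=evoked.fs,
        t0_index=evoked.t0_index,
        scope="global",
    )


def lmfp(evoked: Evoked, cluster, scope: str | None = None,
         local_mean: bool = True) -> FieldPowerTrace:
    """Local mean field power over a cluster of channels.

    ``local_mean=True`` (default) takes deviations from the cluster mean;
    ``False`` uses the global (all-channel) mean instead.
    """
    cluster = sorted(cluster)
    missing = [c for c in cluster if c not in evoked.channels]
    if missing:
        raise FieldPowerError(f"cluster channels not in evoked: {missing}")
    if len(cluster) < 2:
        raise FieldPowerError("LMFP needs at least 2 channels")
    idx = [evoked.channels.index(c) for c in cluster]
    sub = evoked.data[idx]
    if local_mean:
        values = _spatial_sd(sub)
    else:
        dev = sub - evoked.data.mean(axis=0, keepdims=True)
        values = np.sqrt((dev**2).mean(axis=0))
    return FieldPowerTrace(
        values=values,
        fs=evoked.fs,
        t0_index=evoked.t0_index,
        scope=scope or "+".join(cluster),
    )


def cumulate(trace: FieldPowerTrace, window: tuple[float, float]) -> float:
    """Rectangular cumulation over a half-open window: sum(value) * dt (ms)."""
    a, b = window
    t = trace.times
    sel = (t >= a) & (t < b)
    if not sel.any():
        raise FieldPowerError(f"window {window} contains no samples")
    dt_ms = 1000.0 / trace.fs
    return float(trace.values[sel].sum() * dt_ms)


def build_table(
    evokeds,
    clusters: dict,
    windows=DEFAULT_WINDOWS,
    session: str = "active",
) -> pd.DataFrame:
    """Tidy per-subject field-power table for the mixed-model stage.

    One row per subject x condition x window x scope, scopes being
    'global' plus each cluster.  ``log_value`` is the natural log of the
    cumulated value.
    """
    rows = []
    seen = set()
    for evoked in evokeds:
        key = (evoked.subject_id, evoked.condition)
        if key in seen:
            raise FieldPowerError(f"duplicate subject-condition {key}")
        seen.add(key)
        traces = {"global": gmfp(evoked)}
        for name, labels in clusters.items():
            traces[name] = lmfp(evoked, labels, scope=name)
        for label, window in zip(WINDOW_LABELS, windows):
            for scope, trace in traces.items():
                val = cumulate(trace, window)
                rows.append(
                    {
                        "subject": evoked.subject_id,
                        "session": session,
                        "condition": evoked.condition,
                        "window": label,
                        "scope": scope,
                        "cumulated_value": val,
                        "log_value": np.log(val) if val > 0 else -np.inf,
                    }
                )
    return pd.DataFrame(rows)


def write_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
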