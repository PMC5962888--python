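"""End-to-end orchestration: simulate -> preprocess -> analyze -> infer.

``run_all`` executes the full workflow described by a :class:`RunConfig`:
synthetic pre/during/post TMS-EEG sessions for every subject, the sensor
preprocessing chain, global/local field power, minimum-norm source
imaging with permutation-thresholded significant current density, and the
mixed-model condition tests.  All tables are written as CSV with a fixed
float format, plus a JSON manifest (config hash, seed, package versions)
and a plain-text log, so a run is bit-reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .fieldpower import DEFAULT_WINDOWS, WINDOW_LABELS, build_table, write_table_csv
from .forward import lead_field
from .headmodel import build_source_space, build_sphere_model, define_parcels
from .inverse import (
    baseline_noise_cov,
    make_inverse,
    permutation_threshold,
    significant_current_density,
)
from .montage import build_montage, cluster_map
from .preprocess import (
    RejectionCriteria,
    average_and_filter,
    average_reference,
    baseline_correct,
    downsample,
    interpolate_bad,
    reject_artifacts,
)
from .simulate import ConditionGain, simulate_experiment
from .stats import fit_condition_lrt, results_to_frame

__all__ = ["run_all"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage."""


def _log(lines: list, message: str) -> None:
    lines.append(f"[{time.strftime('%H:%M:%S')}] {message}")


def run_all(config: RunConfig, outdir=None, seed: int | None = None) -> dict:
    """Run the complete pipeline; returns a small report dictionary."""
    config = config.validated()
    out = Path(outdir if outdir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    run_seed = sim.seed if seed is None else int(seed)
    log: list[str] = []

    stage = "setup"
    try:
        montage = build_montage()
        clusters = cluster_map(montage)
        geo = config.effective_geometry()
        sphere = build_sphere_model(tuple(geo.radii_mm), tuple(geo.conductivities))
        space = build_source_space(
            n_sources=geo.n_sources,
            radius=geo.source_radius_mm,
            inner_skull_radius=geo.radii_mm[2],
        )
        parcels = define_parcels(space)
        L = lead_field(sphere, montage, space, n_terms=geo.n_terms)
        _log(log, f"setup: {montage.n_channels} channels, {space.n_sources} sources")

        stage = "simulate+preprocess"
        gains = ConditionGain(1.0, sim.g_during, sim.g_post)
        pre = config.preprocessing
        criteria = RejectionCriteria(
            abs_amplitude_limit=pre.abs_amplitude_limit,
            eog_limit=pre.eog_limit,
            hf_power_limit=pre.hf_power_limit,
        )
        band = (pre.band_low, pre.band_high)
        baseline = tuple(pre.baseline_ms)
        n_perm = config.effective_n_permutations()
        srccfg = config.source

        evokeds = []
        scd_rows = []
        retained = []
        for epochs in simulate_experiment(
            sim.n_subjects, gains, run_seed, L,
            n_trials=sim.n_trials, fs=sim.fs,
        ):
            epochs = downsample(epochs, pre.target_fs)
            epochs, report = reject_artifacts(epochs, criteria)
            retained.append(
                {
                    "subject": epochs.subject_id,
                    "condition": epochs.condition,
                    "n_retained": epochs.n_trials,
                }
            )
            evoked = average_and_filter(epochs, band)
            if montage.bad_channels:
                evoked = interpolate_bad(evoked, montage)
            evoked = average_reference(evoked)
            evoked = baseline_correct(evoked, baseline)
            evokeds.append(evoked)

            stage = "source"
            cov = baseline_noise_cov(epochs, baseline)
            inv = make_inverse(
                L, cov, snr=srccfg.snr,
                smoothing_sigma=srccfg.smoothing_sigma_mm,
                depth_exponent=srccfg.depth_exponent,
            )
            est, mask = permutation_threshold(
                epochs, inv, baseline=baseline,
                n_permutations=n_perm, alpha=srccfg.alpha,
                seed=run_seed + 7919 * len(evokeds),
            )
            for label, window in zip(WINDOW_LABELS, DEFAULT_WINDOWS):
                scopes = {"global": "global", **{k: v for k, v in parcels.items()}}
                for scope_name, parcel in scopes.items():
                    val = significant_current_density(est, mask, window, parcel)
                    scd_rows.append(
                        {
                            "subject": epochs.subject_id,
                            "session": "active",
                            "condition": epochs.condition,
                            "window": label,
                            "scope": scope_name,
                            "cumulated_value": val,
                            "log_value": float(np.log(val)) if val > 0 else -np.inf,
                        }
                    )
            stage = "simulate+preprocess"
            _log(log, f"{epochs.subject_id}/{epochs.condition}: "
                      f"{epochs.n_trials} trials retained")

        stage = "fieldpower"
        fp_table = build_table(evokeds, clusters)
        write_table_csv(fp_table, out / "fieldpower.csv")
        scd_table = pd.DataFrame(scd_rows)
        write_table_csv(scd_table, out / "scd.csv")
        pd.DataFrame(retained).to_csv(out / "retained_trials.csv", index=False)

        stage = "stats"
        # field power is analyzed on the log scale; SCD on the raw scale
        # (sub-threshold blocks give exact zeros, where the log is undefined)
        all_results = []
        for measure, table, col in (
            ("fieldpower", fp_table, "log_value"),
            ("scd", scd_table, "cumulated_value"),
        ):
            if sim.n_subjects < 2:
                continue
            for window in WINDOW_LABELS:
                for scope in sorted(table["scope"].unique()):
                    res = fit_condition_lrt(table, window, scope, value_col=col)
                    all_results.append((measure, res))
        stats_df = results_to_frame([r for _, r in all_results])
        if not stats_df.empty:
            stats_df.insert(0, "measure", [m for m, _ in all_results])
        stats_df.to_csv(out / "stats.csv", index=False, float_format="%.12g")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    config_path = out / "config.toml"
    dump_config(config, config_path)
    config_hash = hashlib.sha256(config_path.read_bytes()).hexdigest()
    manifest = {
        "config_sha256": config_hash,
        "seed": run_seed,
        "n_subjects": sim.n_subjects,
        "versions": {
            "teptools": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return {
        "outdir": str(out),
        "n_blocks": len(evokeds),
        "n_stat_tests": len(stats_df),
        "manifest": manifest,
    }
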