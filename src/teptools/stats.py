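"""Mixed-model inference on excitability indices, and a simulation harness.

For every time window and scope (global GMFP, cluster LMFP, or parcel SCD)
the package fits two linear mixed models to the log-cumulated values by
maximum likelihood (not REML):

    M0:  log_value ~ 1 + (1 | subject)
    M1:  log_value ~ condition + (1 | subject)

and tests the three-level condition factor (pre/during/post) with the
likelihood-ratio statistic chi2 = 2 (l1 - l0) on 2 degrees of freedom.
Evidence for the null is summarized with the BIC approximation to the
Bayes factor, BF01 = exp((BIC1 - BIC0) / 2); BF01 > 3 is read as moderate
support for no condition effect.

``run_operating_characteristics`` closes the loop: it simulates whole
experiments under a known condition gain, runs them through the analysis
chain, and reports rejection rates and Bayes-factor summaries, so both the
type-I error of the LRT and its power against a given excitability change
can be measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .fieldpower import WINDOW_LABELS, build_table
from .montage import ANALYSIS_CLUSTERS
from .simulate import (
    CONDITIONS,
    ConditionGain,
    DEFAULT_TEMPLATE,
    sample_subject,
    simulate_experiment,
    pink_noise,
)

__all__ = [
    "ModelFit",
    "StatResult",
    "OperatingCharacteristics",
    "fit_condition_lrt",
    "bf01",
    "run_operating_characteristics",
    "results_to_frame",
]


class StatsError(ValueError):
    """Raised for invalid inference inputs."""


@dataclass(frozen=True)
class ModelFit:
    """Minimal fit summary needed for LRT/BIC arithmetic."""

    llf: float
    n_params: int
    n_obs: int

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.n_params * np.log(self.n_obs)


@dataclass(frozen=True)
class StatResult:
    """LRT + Bayes-factor result for one window x scope analysis."""

    window: str
    scope: str
    chi2: float
    df: int
    p_value: float
    bf01: float
    n_subjects: int
    converged: bool
    fit_null: ModelFit | None = None
    fit_alt: ModelFit | None = None


def bf01(fit0: ModelFit, fit1: ModelFit) -> float:
    """BIC approximation of the Bayes factor favouring the null model."""
    return float(np.exp((fit1.bic - fit0.bic) / 2.0))


def _fit_mixed(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> tuple[float, bool]:
    """ML fit of a random-intercept model; returns (llf, converged).

    Near-zero between-subject variance puts the optimum on the boundary,
    where a single optimizer can fail; the best log-likelihood over a
    small fallback chain is kept.
    """
    best_llf, best_conv = -np.inf, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        for method in ("bfgs", "powell", "nm"):
            try:
                res = model.fit(reml=False, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                continue
            if np.isfinite(res.llf) and res.llf > best_llf:
                best_llf, best_conv = float(res.llf), bool(res.converged)
            if best_conv:
                break
    if not np.isfinite(best_llf):
        raise StatsError("mixed-model fit failed with every optimizer")
    return best_llf, best_conv


def fit_condition_lrt(
    table: pd.DataFrame,
    window: str,
    scope: str,
    value_col: str = "log_value",
) -> StatResult:
    """Likelihood-ratio test for the condition effect in one window/scope.

    The table must hold one value per subject x condition for the given
    window and scope (the tidy format written by the field-power and SCD
    stages).  Values are analyzed on the (natural) log scale by default;
    pass ``value_col='cumulated_value'`` for the raw scale.
    """
    sub = table[(table["window"] == window) & (table["scope"] == scope)]
    if sub.empty:
        raise StatsError(f"no rows for window={window!r} scope={scope!r}")
    pivot = sub.pivot_table(
        index="subject", columns="condition", values=value_col, aggfunc="size"
    )
    if pivot.isna().any().any() or not set(CONDITIONS) <= set(pivot.columns):
        raise StatsError("every subject needs all three conditions")
    if (pivot > 1).any().any():
        raise StatsError("duplicate subject-condition rows")
    subjects = sorted(sub["subject"].unique())
    if len(subjects) < 2:
        raise StatsError("need at least 2 subjects")

    sub = sub.sort_values(["subject", "condition"])
    y = sub[value_col].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise StatsError("non-finite values (zero cumulated power?)")
    if np.var(y) < 1e-24:
        # constant response (e.g. SCD all zero): both models fit exactly,
        # the LRT is null and the Bayes factor reduces to the BIC penalty
        n_ = len(y)
        fit0 = ModelFit(llf=0.0, n_params=3, n_obs=n_)
        fit1 = ModelFit(llf=0.0, n_params=5, n_obs=n_)
        return StatResult(
            window=window, scope=scope, chi2=0.0, df=2, p_value=1.0,
            bf01=bf01(fit0, fit1), n_subjects=len(sub["subject"].unique()),
            converged=True, fit_null=fit0, fit_alt=fit1,
        )
    groups = sub["subject"].to_numpy()
    n = len(y)
    X0 = np.ones((n, 1))
    cond = sub["condition"].to_numpy()
    X1 = np.column_stack(
        [np.ones(n), (cond == "during").astype(float), (cond == "post").astype(float)]
    )
    llf0, conv0 = _fit_mixed(y, X0, groups)
    llf1, conv1 = _fit_mixed(y, X1, groups)
    chi2_stat = max(0.0, 2.0 * (llf1 - llf0))
    # parameters: fixed effects + random-intercept variance + residual variance
    fit0 = ModelFit(llf=llf0, n_params=3, n_obs=n)
    fit1 = ModelFit(llf=llf1, n_params=5, n_obs=n)
    return StatResult(
        window=window,
        scope=scope,
        chi2=chi2_stat,
        df=2,
        p_value=float(sps.chi2.sf(chi2_stat, 2)),
        bf01=bf01(fit0, fit1),
        n_subjects=len(subjects),
        converged=conv0 and conv1,
        fit_null=fit0,
        fit_alt=fit1,
    )


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "window": r.window,
                "scope": r.scope,
                "chi2": r.chi2,
                "df": r.df,
                "p_value": r.p_value,
                "bf01": r.bf01,
                "n_subjects": r.n_subjects,
                "converged": r.converged,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# operating characteristics
# ---------------------------------------------------------------------------

@dataclass
class OperatingCharacteristics:
    """Aggregated simulation results for one gain scenario."""

    gains: ConditionGain
    n_subjects: int
    n_reps: int
    seed: int
    alpha: float
    rejection_rate: dict[str, float]
    median_bf01: dict[str, float]
    fraction_bf01_gt_3: dict[str, float]
    overall_rejection_rate: float
    overall_median_bf01: float
    overall_fraction_bf01_gt_3: float
    n_failed: int
    results: pd.DataFrame = field(repr=False)


def _fast_fieldpower_table(
    rep_seq: np.random.SeedSequence,
    gains: ConditionGain,
    n_subjects: int,
    leadfield,
    template: dict,
    n_trials: int,
    fs: float,
    epoch_span_ms: tuple[float, float],
    band: tuple[float, float],
    baseline: tuple[float, float],
    clusters: dict,
) -> pd.DataFrame:
    """Evoked-level shortcut through the analysis chain.

    Instead of generating every trial, the trial average is simulated
    directly: noise-free evoked + pink noise scaled by 1/sqrt(n_retained),
    with n_retained the expected artifact-free trial count.  Filtering,
    referencing, baseline correction and field power then run through the
    same code paths as the trial-level pipeline.
    """
    from .preprocess import (
        Evoked,
        average_reference,
        bandpass_evoked,
        baseline_correct,
    )
    from .simulate import evoked_signal

    n_pre = int(round(-epoch_span_ms[0] * fs / 1000.0))
    n_post = int(round(epoch_span_ms[1] * fs / 1000.0))
    n_samples = n_pre + n_post
    t0 = n_pre
    times = (np.arange(n_samples) - t0) * 1000.0 / fs
    channels = tuple(leadfield.montage.channels)
    n_retained = max(1, int(round(n_trials * (1.0 - template["artifact_rate"]))))

    evokeds = []
    for i, seq in enumerate(rep_seq.spawn(n_subjects)):
        params_seed = int(seq.generate_state(1)[0] & 0x7FFFFFFF)
        subject = sample_subject(params_seed, template)
        for condition, bseq in zip(CONDITIONS, seq.spawn(3)):
            rng = np.random.default_rng(bseq)
            clean = evoked_signal(
                subject, gains.for_condition(condition), leadfield, times
            )
            noise = pink_noise(rng, len(channels), n_samples, fs)
            data = clean + subject.noise_sd / np.sqrt(n_retained) * noise
            ev = Evoked(
                data=bandpass_evoked(data, fs, band),
                fs=fs,
                t0_index=t0,
                channels=channels,
                n_trials_used=n_retained,
                processing_log=("average", "filter"),
                subject_id=f"S{i:02d}",
                condition=condition,
            )
            ev = average_reference(ev)
            ev = baseline_correct(ev, baseline)
            evokeds.append(ev)
    return build_table(evokeds, clusters)


def run_operating_characteristics(
    gains: ConditionGain,
    n_subjects: int = 15,
    n_reps: int = 200,
    seed: int = 0,
    leadfield=None,
    template: dict | None = None,
    scope: str = "global",
    windows=WINDOW_LABELS,
    alpha: float = 0.05,
    mode: str = "fast",
    n_trials: int = 180,
    min_reps: int = 1,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the condition LRT.

    ``mode='fast'`` simulates trial averages directly (field-power path
    only); ``mode='full'`` generates every trial and runs the complete
    preprocessing chain (much slower; use few reps).  Results are fully
    deterministic given ``seed``.
    """
    if n_reps < min_reps:
        raise StatsError(f"need at least {min_reps} repetitions")
    template = DEFAULT_TEMPLATE if template is None else template
    if leadfield is None:
        leadfield = _default_reduced_leadfield()
    # only the clusters actually analyzed are cumulated in fast mode
    if scope == "global":
        clusters = {}
    elif scope in ANALYSIS_CLUSTERS:
        clusters = {scope: ANALYSIS_CLUSTERS[scope]}
    else:
        clusters = dict(ANALYSIS_CLUSTERS)
    base = np.random.SeedSequence(seed)
    rep_seqs = base.spawn(n_reps)
    rows = []
    n_failed = 0
    for rep, rep_seq in enumerate(rep_seqs):
        try:
            if mode == "fast":
                table = _fast_fieldpower_table(
                    rep_seq,
                    gains,
                    n_subjects,
                    leadfield,
                    template,
                    n_trials,
                    fs=725.0,
                    epoch_span_ms=(-400.0, 400.0),
                    band=(2.0, 40.0),
                    baseline=(-300.0, -50.0),
                    clusters=clusters,
                )
            elif mode == "full":
                from .preprocess import preprocess_evoked

                rep_seed = int(rep_seq.generate_state(1)[0] & 0x7FFFFFFF)
                evokeds = [
                    preprocess_evoked(ep, leadfield.montage)[0]
                    for ep in simulate_experiment(
                        n_subjects, gains, rep_seed, leadfield,
                        template=template, n_trials=n_trials,
                    )
                ]
                table = build_table(evokeds, clusters)
            else:
                raise StatsError(f"unknown mode {mode!r}")
            for window in windows:
                res = fit_condition_lrt(table, window, scope)
                rows.append(
                    {
                        "rep": rep,
                        "window": window,
                        "chi2": res.chi2,
                        "p_value": res.p_value,
                        "bf01": res.bf01,
                        "converged": res.converged,
                    }
                )
        except StatsError:
            raise
        except Exception as exc:  # noqa: BLE001 - harness keeps going
            n_failed += 1
            warnings.warn(f"repetition {rep} failed: {exc}", stacklevel=2)
    results = pd.DataFrame(rows)
    rejection, med_bf, frac_bf = {}, {}, {}
    for window in windows:
        w = results[results["window"] == window]
        rejection[window] = float((w["p_value"] < alpha).mean())
        med_bf[window] = float(w["bf01"].median())
        frac_bf[window] = float((w["bf01"] > 3.0).mean())
    return OperatingCharacteristics(
        gains=gains,
        n_subjects=n_subjects,
        n_reps=n_reps,
        seed=seed,
        alpha=alpha,
        rejection_rate=rejection,
        median_bf01=med_bf,
        fraction_bf01_gt_3=frac_bf,
        overall_rejection_rate=float((results["p_value"] < alpha).mean()),
        overall_median_bf01=float(results["bf01"].median()),
        overall_fraction_bf01_gt_3=float((results["bf01"] > 3.0).mean()),
        n_failed=n_failed,
        results=results,
    )


def _default_reduced_leadfield():
    """Reduced-geometry lead field (812 sources) for simulation harnesses."""
    from .forward import lead_field
    from .headmodel import build_source_space, build_sphere_model
    from .montage import build_montage

    montage = build_montage()
    sphere = build_sphere_model()
    space = build_source_space(n_sources=812)
    return lead_field(sphere, montage, space)
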