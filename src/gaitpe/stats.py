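"""Group comparisons and linear mixed models for entropy features.

Three layers:

* Per-channel two-sided t-tests (Welch by default) comparing control and
  patient entropy, with a Šidák familywise correction over the 15
  channels: per-test level 1 - (1 - alpha)^(1/15).
* Three families of linear mixed models, all with a random intercept per
  subject: (1) per-cycle entropy on GMFCS stage indicators (control as
  reference); (2) per-cycle entropy on normalized walking speed,
  condition and their interaction; (3) a gait index (GDI, GPS or a MAP
  item) on entropy, patients only.
* Bias-corrected and accelerated (BCa) bootstrap confidence intervals
  for the fixed effects, resampling whole subjects (clusters) with
  replacement — a subject's cycles are never split across replicates —
  with jackknife-over-subjects acceleration.

Mixed models are fitted by REML through statsmodels; fixed-effect
p-values use the normal approximation to the t-contrast (the small-sample
degrees-of-freedom convention is deliberately left to the bootstrap
intervals, which are the primary uncertainty statement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .channels import CHANNEL_LABELS, MAP_CHANNEL_PAIRING, MAP_ITEMS
from .data import Cohort

GMFCS_MODEL_LEVELS = ("I", "II", "III", "IV")

#: Exceptions treated as a non-convergent bootstrap replicate.
_FIT_FAILURES = (ValueError, ZeroDivisionError, np.linalg.LinAlgError, KeyError)


def sidak_threshold(alpha_family: float, m: int) -> float:
    """Per-test significance level controlling familywise error at
    ``alpha_family`` over ``m`` independent tests: 1 - (1 - alpha)^(1/m)."""
    if not 0.0 < alpha_family < 1.0:
        raise ValueError(f"alpha_family must be in (0, 1), got {alpha_family}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return 1.0 - (1.0 - alpha_family) ** (1.0 / m)


# ---------------------------------------------------------------------------
# Channel-wise t-tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelTestResult:
    channel: str
    mean_control: float
    mean_cp: float
    t_statistic: float
    p_value: float
    significant: bool


def _subject_frame(subjects) -> pd.DataFrame:
    if isinstance(subjects, Cohort):
        return subjects.subject_frame()
    if isinstance(subjects, pd.DataFrame):
        return subjects
    raise TypeError(f"expected Cohort or DataFrame, got {type(subjects)!r}")


def channel_t_tests(
    table: pd.DataFrame,
    subjects,
    unit: str = "subject_mean",
    alpha_family: float = 0.01,
    equal_var: bool = False,
) -> list[ChannelTestResult]:
    """Two-sided t-tests of control vs patient entropy, per channel.

    ``unit="subject_mean"`` (default) compares per-subject mean entropy,
    avoiding pseudo-replication from repeated cycles of the same subject;
    ``unit="cycle"`` compares raw per-cycle values.  Welch's
    unequal-variance statistic is used unless ``equal_var``.  The
    significance flag applies the Šidák-corrected per-test level for the
    15-channel family.
    """
    if unit not in ("subject_mean", "cycle"):
        raise ValueError(f"unknown unit {unit!r}")
    subj = _subject_frame(subjects)[["subject_id", "condition"]]
    df = table.merge(subj, on="subject_id", how="left")
    if df["condition"].isna().any():
        missing = sorted(df.loc[df["condition"].isna(), "subject_id"].unique())
        raise ValueError(f"subjects missing from metadata: {missing}")
    if unit == "subject_mean":
        df = (
            df.groupby(["subject_id", "channel", "condition"], sort=True)["pe"]
            .mean()
            .reset_index()
        )
    channels = [c for c in CHANNEL_LABELS if c in set(df["channel"])]
    alpha = sidak_threshold(alpha_family, len(channels))
    results = []
    for ch in channels:
        sub = df[df["channel"] == ch]
        ctrl = sub.loc[sub["condition"] == "control", "pe"].to_numpy()
        cp = sub.loc[sub["condition"] == "cp", "pe"].to_numpy()
        if len(ctrl) < 2 or len(cp) < 2:
            raise ValueError(
                f"channel {ch}: each group needs >= 2 units "
                f"(control {len(ctrl)}, cp {len(cp)})"
            )
        t, p = sps.ttest_ind(cp, ctrl, equal_var=equal_var)
        results.append(
            ChannelTestResult(
                channel=ch,
                mean_control=float(ctrl.mean()),
                mean_cp=float(cp.mean()),
                t_statistic=float(t),
                p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    return results


def t_test_frame(results: Sequence[ChannelTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedEffect:
    beta: float
    ci_lo: float
    ci_hi: float
    p_value: float


@dataclass
class MixedModelFit:
    """One fitted mixed model: fixed effects with CIs, variance components."""

    model_family: str
    response: str
    channel: str | None
    fixed_effects: dict[str, FixedEffect]
    random_intercept_variance: float
    residual_variance: float
    n_replicates: int

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "model_family": self.model_family,
                "response": self.response,
                "channel": self.channel,
                "effect": name,
                "beta": fe.beta,
                "ci_lo": fe.ci_lo,
                "ci_hi": fe.ci_hi,
                "p_value": fe.p_value,
            }
            for name, fe in self.fixed_effects.items()
        ]
        return pd.DataFrame(rows)


def _fit_mixedlm(endog: np.ndarray, exog: pd.DataFrame, groups: np.ndarray,
                 start_params=None, fast: bool = False):
    # fast mode (bootstrap/jackknife refits): warm-started with a loose
    # gradient tolerance on the variance profile — fixed effects are the
    # GLS solution given the variance parameters and are insensitive to
    # the residual imprecision
    for col in exog.columns[1:]:
        if np.ptp(exog[col].to_numpy()) == 0.0:
            raise ValueError(f"design column {col!r} is constant (rank deficient)")
    opts = dict(gtol=0.05, maxiter=50) if fast else dict(maxiter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        return model.fit(reml=True, method="bfgs", start_params=start_params, **opts)


def bca_bootstrap_ci(
    fit_procedure: Callable[[pd.DataFrame], np.ndarray],
    data: pd.DataFrame,
    n_replicates: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    max_dropped_frac: float = 0.2,
) -> np.ndarray:
    """BCa confidence intervals by subject-level (cluster) bootstrap.

    ``fit_procedure`` maps a data frame (with a ``subject_id`` column) to
    a vector of statistics.  Whole subjects are resampled with
    replacement, duplicated subjects receiving fresh ids so a random
    intercept treats each draw as a distinct cluster.  Bias correction
    comes from the fraction of replicates below the full-data estimate;
    acceleration from a jackknife over subjects.  Non-convergent
    replicates are dropped; more than ``max_dropped_frac`` dropped is an
    error.  Returns an ``(n_statistics, 2)`` array of (lo, hi) bounds.
    """
    if "subject_id" not in data.columns:
        raise ValueError("data must carry a subject_id column")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids = np.array(sorted(data["subject_id"].unique()))
    if len(ids) < 10:
        raise ValueError(f"cluster bootstrap needs >= 10 subjects, got {len(ids)}")

    theta_hat = np.atleast_1d(np.asarray(fit_procedure(data), dtype=float))
    by_subject = {sid: grp for sid, grp in data.groupby("subject_id", sort=True)}

    reps = []
    dropped = 0
    for _ in range(n_replicates):
        draw = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for k, sid in enumerate(draw):
            part = by_subject[sid].copy()
            part["subject_id"] = f"boot_{k:03d}"
            parts.append(part)
        sample = pd.concat(parts, ignore_index=True)
        try:
            reps.append(np.atleast_1d(np.asarray(fit_procedure(sample), dtype=float)))
        except _FIT_FAILURES:
            dropped += 1
    if dropped > max_dropped_frac * n_replicates:
        raise RuntimeError(
            f"{dropped}/{n_replicates} bootstrap replicates failed to converge"
        )
    theta_star = np.vstack(reps)

    # jackknife over subjects for the acceleration constant
    jack = []
    for sid in ids:
        sample = data[data["subject_id"] != sid]
        try:
            jack.append(np.atleast_1d(np.asarray(fit_procedure(sample), dtype=float)))
        except _FIT_FAILURES:
            continue
    jack = np.vstack(jack) if jack else theta_hat[None, :]

    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = sps.norm.ppf(alpha), sps.norm.ppf(1.0 - alpha)
    out = np.empty((theta_hat.shape[0], 2))
    B = theta_star.shape[0]
    for j in range(theta_hat.shape[0]):
        ts = theta_star[:, j]
        if np.ptp(ts) == 0.0 and ts[0] == theta_hat[j]:
            out[j] = (theta_hat[j], theta_hat[j])
            continue
        prop = np.clip(np.mean(ts < theta_hat[j]), 1.0 / (B + 1), B / (B + 1.0))
        z0 = sps.norm.ppf(prop)
        d = jack[:, j].mean() - jack[:, j]
        denom = np.sum(d**2) ** 1.5
        a = np.sum(d**3) / (6.0 * denom) if denom > 0 else 0.0
        qs = []
        for z in (z_lo, z_hi):
            adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
            qs.append(sps.norm.cdf(adj))
        out[j] = np.quantile(ts, qs)
    return out


def _merged_channel_frame(
    table: pd.DataFrame, subjects, channel: str
) -> pd.DataFrame:
    subj = _subject_frame(subjects)
    df = table[table["channel"] == channel].merge(
        subj, on="subject_id", how="left", suffixes=("", "_subj")
    )
    if df.empty:
        raise ValueError(f"no rows for channel {channel!r}")
    return df.reset_index(drop=True)


def _family_fit(
    df: pd.DataFrame,
    design: Callable[[pd.DataFrame], tuple[np.ndarray, pd.DataFrame]],
    family: str,
    response: str,
    channel: str | None,
    n_replicates: int,
    level: float,
    rng,
) -> MixedModelFit:
    endog, exog = design(df)
    res = _fit_mixedlm(endog, exog, df["subject_id"].to_numpy())
    names = list(exog.columns)
    betas = np.asarray(res.fe_params)
    pvals = np.asarray(res.pvalues)[: len(names)]
    if n_replicates > 0:
        start = res.params_object  # warm start: replicate fits begin at the
        # full-data optimum, which they stay close to

        def proc(d: pd.DataFrame) -> np.ndarray:
            e, x = design(d)
            return np.asarray(
                _fit_mixedlm(
                    e, x, d["subject_id"].to_numpy(), start_params=start,
                    fast=True,
                ).fe_params
            )

        cis = bca_bootstrap_ci(proc, df, n_replicates=n_replicates, level=level, rng=rng)
    else:  # Wald fallback when bootstrap is disabled
        se = np.asarray(res.bse)[: len(names)]
        z = sps.norm.ppf(1.0 - (1.0 - level) / 2.0)
        cis = np.column_stack([betas - z * se, betas + z * se])
    effects = {
        name: FixedEffect(float(b), float(lo), float(hi), float(p))
        for name, b, (lo, hi), p in zip(names, betas, cis, pvals)
    }
    return MixedModelFit(
        model_family=family,
        response=response,
        channel=channel,
        fixed_effects=effects,
        random_intercept_variance=float(np.asarray(res.cov_re)[0, 0]),
        residual_variance=float(res.scale),
        n_replicates=n_replicates,
    )


def fit_lmm_gmfcs(
    table: pd.DataFrame,
    subjects,
    channels: Sequence[str] | None = None,
    n_replicates: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> dict[str, MixedModelFit]:
    """Per-cycle entropy on GMFCS stage, one model per channel.

    Fixed effects: intercept plus an indicator slope for each GMFCS level
    I-IV, the control group being the reference — a positive slope means
    that stage's mean entropy exceeds the control mean.  Random intercept
    per subject; BCa cluster-bootstrap CIs.
    """
    subj = _subject_frame(subjects)
    counts = subj.groupby("gmfcs", observed=True)["subject_id"].nunique()
    for level_name in ("none",) + GMFCS_MODEL_LEVELS:
        if counts.get(level_name, 0) == 1:
            raise ValueError(
                f"GMFCS level {level_name!r} has a single subject; "
                f">= 2 required per modelled level"
            )

    def design(d: pd.DataFrame):
        exog = pd.DataFrame({"intercept": np.ones(len(d))})
        for lv in GMFCS_MODEL_LEVELS:
            if counts.get(lv, 0) > 0:
                exog[f"gmfcs_{lv}"] = (d["gmfcs"] == lv).astype(float).to_numpy()
        return d["pe"].to_numpy(), exog

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fits = {}
    for ch in channels or sorted(set(table["channel"])):
        df = _merged_channel_frame(table, subj, ch)
        fits[ch] = _family_fit(
            df, design, "gmfcs", "pe", ch, n_replicates, level, rng
        )
    return fits


def fit_lmm_speed_condition(
    table: pd.DataFrame,
    subjects,
    channels: Sequence[str] | None = None,
    n_replicates: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> dict[str, MixedModelFit]:
    """Per-cycle entropy on normalized speed, condition and interaction.

    Fixed effects: intercept; normalized walking speed (1/s); condition
    (cp = 1, healthy reference); speed x condition.  Random intercept per
    subject; BCa cluster-bootstrap CIs.
    """
    subj = _subject_frame(subjects)
    if np.ptp(subj["normalized_speed"].to_numpy()) == 0.0:
        raise ValueError("normalized speed is constant across subjects (rank deficient)")
    if subj["normalized_speed"].isna().any():
        missing = sorted(subj.loc[subj["normalized_speed"].isna(), "subject_id"])
        raise ValueError(f"subjects missing speed data: {missing}")

    def design(d: pd.DataFrame):
        speed = d["normalized_speed"].to_numpy(dtype=float)
        cp = (d["condition"] == "cp").astype(float).to_numpy()
        exog = pd.DataFrame(
            {
                "intercept": np.ones(len(d)),
                "speed": speed,
                "condition_cp": cp,
                "speed_x_condition": speed * cp,
            }
        )
        return d["pe"].to_numpy(), exog

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fits = {}
    for ch in channels or sorted(set(table["channel"])):
        df = _merged_channel_frame(table, subj, ch)
        fits[ch] = _family_fit(
            df, design, "speed_condition", "pe", ch, n_replicates, level, rng
        )
    return fits


def fit_lmm_gait_index(
    table: pd.DataFrame,
    subjects,
    response: str = "gdi",
    channels: Sequence[str] | None = None,
    pairing: Mapping[str, object] | None = None,
    n_replicates: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> dict[str, MixedModelFit] | MixedModelFit:
    """A gait index regressed on entropy, patients only.

    For ``response`` "gdi" or "gps": one model per channel, that
    channel's per-cycle entropy as the fixed slope.  For a MAP item the
    predictor is its paired channel (pelvic tilt with pelvis
    flexion-extension and so on, configurable via ``pairing``) and a
    single fit is returned.  Random intercept per subject; BCa CIs.
    """
    subj = _subject_frame(subjects)
    subj = subj[subj["condition"] == "cp"]
    if subj.empty:
        raise ValueError("no patient (cp) subjects available")
    if response in MAP_ITEMS:
        pairing = pairing or MAP_CHANNEL_PAIRING
        channel_list = [pairing[response].label]
        single = True
    elif response in ("gdi", "gps"):
        channel_list = list(channels or sorted(set(table["channel"])))
        single = False
    else:
        raise ValueError(f"unknown response {response!r}")
    if subj[response].isna().any():
        missing = sorted(subj.loc[subj[response].isna(), "subject_id"])
        raise ValueError(f"subjects missing {response}: {missing}")

    def design(d: pd.DataFrame):
        exog = pd.DataFrame(
            {"intercept": np.ones(len(d)), "pe": d["pe"].to_numpy(dtype=float)}
        )
        return d[response].to_numpy(dtype=float), exog

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fits = {}
    cp_table = table[table["subject_id"].isin(subj["subject_id"])]
    for ch in channel_list:
        df = _merged_channel_frame(cp_table, subj, ch)
        fits[ch] = _family_fit(
            df, design, "gait_index", response, ch, n_replicates, level, rng
        )
    return fits[channel_list[0]] if single else fits
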