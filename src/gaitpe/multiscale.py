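"""Multi-scale permutation entropy and the ΔMSE attenuation ratio.

The series is coarse-grained at scale factor ``v``: consecutive
non-overlapping windows of ``v`` samples are replaced by their mean, so
the coarse series has ``floor(N / v)`` points and high-frequency content
attenuated roughly as 1/sqrt(v).  Permutation entropy as a function of
``v`` separates complexity living at short time scales (washed out by
coarse-graining) from complexity of the macroscopic envelope.

For two groups, the attenuation of their entropy gap is summarized per
channel by

    dMSE = [MSE_cp(v_max) - MSE_control(v_max)] / [MSE_cp(1) - MSE_control(1)]

A ratio near 0 means the groups differ only in high-frequency structure;
near 1, the gap persists at every scale.  ``v_max`` defaults to 22, the
largest scale at which a 201-sample cycle still leaves a usable coarse
series; note that 201/22 = 9 points is below the (d+1)! rule-of-thumb for
reliable pattern statistics, which is why pooled-counts group curves are
offered alongside per-cycle means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .channels import CHANNELS, Channel
from .data import Cohort
from .entropy import EmbeddingConfig, _pattern_codes, permutation_entropy

#: Default largest coarse-graining factor for 201-sample cycles.
DEFAULT_MAX_SCALE = 22


def recommended_min_length(d: int) -> int:
    """Rule-of-thumb minimum series length for stable pattern statistics.

    For embedding dimension ``d`` this is (d+1)! samples — 24 for the
    default d=3.  Shorter series still yield a defined entropy but the
    pattern frequencies are undersampled.
    """
    if d < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {d}")
    return math.factorial(d + 1)


def coarse_grain(series, scale: int) -> np.ndarray:
    """Average non-overlapping windows of ``scale`` consecutive samples.

    Output length is ``floor(N / scale)``; trailing remainder samples are
    discarded.  ``scale=1`` returns the series unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    if scale < 1:
        raise ValueError(f"scale factor must be >= 1, got {scale}")
    n = x.shape[0]
    if scale > n:
        raise ValueError(
            f"scale factor {scale} exceeds series length {n}"
        )
    if scale == 1:
        return x.copy()
    m = n // scale
    return x[: m * scale].reshape(m, scale).mean(axis=1)


def multiscale_pe(
    series,
    cfg: EmbeddingConfig = EmbeddingConfig(),
    max_scale: int = DEFAULT_MAX_SCALE,
) -> dict[int, float]:
    """Permutation entropy of the coarse-grained series at scales 1..max_scale.

    The value at scale 1 is exactly the single-scale entropy.  Scales whose
    coarse series is too short to embed are reported as NaN rather than
    raised — they are flagged, not errors.
    """
    x = np.asarray(series, dtype=float)
    out: dict[int, float] = {}
    for v in range(1, max_scale + 1):
        if v > x.shape[0]:
            out[v] = math.nan
            continue
        y = coarse_grain(x, v)
        if y.shape[0] < cfg.span:
            out[v] = math.nan
        else:
            out[v] = permutation_entropy(y, cfg)
    return out


class MultiscaleEntropy:
    """Batch multi-scale entropy over equal-length series.

    ``transform(X)`` with ``X`` of shape ``(n_series, n_samples)`` returns
    ``(n_series, max_scale)`` entropies, column ``j`` holding scale
    ``j + 1`` (NaN where the coarse series cannot be embedded).
    """

    def __init__(self, d: int = 3, tau: int = 1, max_scale: int = DEFAULT_MAX_SCALE):
        self.d = d
        self.tau = tau
        self.max_scale = max_scale

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cfg = EmbeddingConfig(d=self.d, tau=self.tau)
        norm = math.log2(cfg.n_patterns)
        out = np.full((X.shape[0], self.max_scale), math.nan)
        for v in range(1, self.max_scale + 1):
            m = X.shape[1] // v
            if m < cfg.span:
                continue
            Y = X[:, : m * v].reshape(X.shape[0], m, v).mean(axis=2)
            windows = sliding_window_view(Y, cfg.span, axis=1)[:, :, :: cfg.tau]
            codes = _pattern_codes(windows, cfg.d)
            for i, row in enumerate(codes):
                counts = np.unique(row, return_counts=True)[1]
                p = counts / row.shape[0]
                out[i, v - 1] = min(max(-np.sum(p * np.log2(p)) / norm, 0.0), 1.0)
        return out


@dataclass(frozen=True)
class MultiscaleCurve:
    """Group-level entropy as a function of scale, for one channel."""

    channel: Channel
    group: str  # "control" | "cp"
    values: dict[int, float]


def group_ms_curves(
    cohort: Cohort,
    cfg: EmbeddingConfig = EmbeddingConfig(),
    max_scale: int = DEFAULT_MAX_SCALE,
    pooling: str = "mean",
) -> list[MultiscaleCurve]:
    """Per-channel, per-group multi-scale entropy curves.

    pooling="mean"
        At each scale, the mean over the group's per-cycle entropies
        (cycles with an undefined scale are skipped at that scale).
    pooling="pooled"
        At each scale, ordinal-pattern counts are pooled over all the
        group's cycles and a single entropy is computed from the pooled
        distribution — robust at large scales where individual coarse
        cycles are very short.
    """
    if pooling not in ("mean", "pooled"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    groups: dict[str, list] = {"control": [], "cp": []}
    for cyc in cohort.cycles:
        groups[cohort.subjects[cyc.subject_id].condition].append(cyc)
    for name, cycs in groups.items():
        if not cycs:
            raise ValueError(f"cohort has no cycles in group {name!r}")

    norm = math.log2(cfg.n_patterns)
    curves: list[MultiscaleCurve] = []
    for group, cycs in groups.items():
        for ch in CHANNELS:
            X = np.stack([c.samples[ch] for c in cycs])
            values: dict[int, float] = {}
            for v in range(1, max_scale + 1):
                m = X.shape[1] // v
                if m < cfg.span:
                    values[v] = math.nan
                    continue
                Y = X[:, : m * v].reshape(X.shape[0], m, v).mean(axis=2)
                windows = sliding_window_view(Y, cfg.span, axis=1)[:, :, :: cfg.tau]
                codes = _pattern_codes(windows, cfg.d)
                if pooling == "pooled":
                    counts = np.unique(codes.ravel(), return_counts=True)[1]
                    p = counts / codes.size
                    values[v] = float(
                        np.clip(-np.sum(p * np.log2(p)) / norm, 0.0, 1.0)
                    )
                else:
                    pes = np.empty(codes.shape[0])
                    for i, row in enumerate(codes):
                        counts = np.unique(row, return_counts=True)[1]
                        p = counts / row.shape[0]
                        pes[i] = -np.sum(p * np.log2(p)) / norm
                    values[v] = float(np.clip(pes.mean(), 0.0, 1.0))
            curves.append(MultiscaleCurve(channel=ch, group=group, values=values))
    return curves


def curves_to_frame(curves: list[MultiscaleCurve]) -> pd.DataFrame:
    """Tidy (channel, group, scale, pe) frame from a list of curves."""
    rows = [
        (c.channel.label, c.group, v, pe)
        for c in curves
        for v, pe in sorted(c.values.items())
    ]
    return pd.DataFrame(rows, columns=["channel", "group", "scale", "pe"])


def delta_mse(
    cp_curve: MultiscaleCurve,
    control_curve: MultiscaleCurve,
    scale: int = DEFAULT_MAX_SCALE,
) -> float:
    """Entropy-gap attenuation ratio for one channel.

    ``[MSE_cp(scale) - MSE_control(scale)] / [MSE_cp(1) - MSE_control(1)]``.
    Undefined (raises) when the scale-1 gap is zero.  Swapping which group
    is called cp negates numerator and denominator alike, leaving the
    ratio unchanged.
    """
    if cp_curve.channel != control_curve.channel:
        raise ValueError(
            f"channel mismatch: {cp_curve.channel.label} vs "
            f"{control_curve.channel.label}"
        )
    for curve in (cp_curve, control_curve):
        for v in (1, scale):
            if v not in curve.values or math.isnan(curve.values[v]):
                raise ValueError(
                    f"curve for {curve.channel.label}/{curve.group} does not "
                    f"define scale {v}"
                )
    num = cp_curve.values[scale] - control_curve.values[scale]
    den = cp_curve.values[1] - control_curve.values[1]
    if den == 0.0:
        raise ZeroDivisionError(
            f"channel {cp_curve.channel.label}: zero entropy gap at scale 1, "
            f"attenuation ratio undefined"
        )
    return num / den


def delta_mse_table(
    curves: list[MultiscaleCurve], scale: int = DEFAULT_MAX_SCALE
) -> pd.DataFrame:
    """Per-channel ΔMSE from a list of group curves (NaN where undefined)."""
    by_key = {(c.channel, c.group): c for c in curves}
    rows = []
    for ch in CHANNELS:
        try:
            val = delta_mse(by_key[(ch, "cp")], by_key[(ch, "control")], scale)
        except (KeyError, ValueError, ZeroDivisionError):
            val = math.nan
        rows.append((ch.label, val))
    return pd.DataFrame(rows, columns=["channel", "delta_mse"])
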