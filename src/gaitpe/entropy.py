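"""Single-scale Bandt-Pompe permutation entropy.

A scalar series is split into maximally overlapping regions of length
``D`` (samples ``tau`` apart); each region is reduced to its ordinal
pattern — the permutation that sorts its values in increasing order, ties
broken by time index.  The normalized Shannon entropy of the pattern
frequencies,

    PE = -(1 / log2 D!) * sum_i p_i log2 p_i,

is 0 for a fully ordered series (a single pattern, e.g. any monotone
series) and 1 when all D! patterns are equally frequent (e.g. long i.i.d.
noise).  PE depends only on the rank structure, so it is invariant to any
positive affine rescaling of the series — angle units never matter.

``D`` defaults to 3 and ``tau`` to 1: with only 201 samples per gait
cycle, higher dimensions leave too few regions per pattern for stable
frequency estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .channels import CHANNEL_LABELS, CHANNELS
from .data import Cohort


@dataclass(frozen=True)
class EmbeddingConfig:
    """Ordinal-embedding parameters: dimension ``d`` (>= 2), delay ``tau`` (>= 1)."""

    d: int = 3
    tau: int = 1

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError(f"embedding dimension must be >= 2, got {self.d}")
        if self.tau < 1:
            raise ValueError(f"embedding delay must be >= 1, got {self.tau}")

    @property
    def span(self) -> int:
        """Number of samples one region stretches over: (d-1)*tau + 1."""
        return (self.d - 1) * self.tau + 1

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.d)


@dataclass(frozen=True)
class PatternDistribution:
    """Relative frequencies over the D! ordinal patterns of one series."""

    freq: dict[tuple[int, ...], float]
    n_regions: int

    def entropy(self) -> float:
        """Normalized permutation entropy of this distribution."""
        d = len(next(iter(self.freq)))
        p = np.array([v for v in self.freq.values() if v > 0.0])
        h = -np.sum(p * np.log2(p))
        return float(np.clip(h / math.log2(math.factorial(d)), 0.0, 1.0))


def _check_series(series: Sequence[float] | np.ndarray, cfg: EmbeddingConfig) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    if x.shape[0] < cfg.span:
        raise ValueError(
            f"series of length {x.shape[0]} too short for d={cfg.d}, "
            f"tau={cfg.tau}: at least {cfg.span} samples required"
        )
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    return x


def embed_regions(
    series: Sequence[float] | np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig()
) -> np.ndarray:
    """Split a series into its N - (d-1)*tau maximally overlapping regions.

    Region ``k`` is ``(x[k], x[k+tau], ..., x[k + tau*(d-1)])``; returned
    as an array of shape ``(n_regions, d)``.
    """
    x = _check_series(series, cfg)
    return sliding_window_view(x, cfg.span)[:, :: cfg.tau]


def ordinal_pattern_of(region: Sequence[float] | np.ndarray) -> tuple[int, ...]:
    """The permutation that sorts a region's values in increasing order.

    Ties are broken by original position (stable sort), so e.g. a
    constant region maps to the identity pattern.
    """
    r = np.asarray(region, dtype=float)
    if r.ndim != 1:
        raise ValueError(f"expected a 1-D region, got shape {r.shape}")
    if not np.isfinite(r).all():
        raise ValueError("region contains non-finite values")
    return tuple(int(i) for i in np.argsort(r, kind="stable"))


def _pattern_codes(regions: np.ndarray, d: int) -> np.ndarray:
    """Integer code of each region's ordinal pattern (injective over S_d)."""
    ranks = np.argsort(regions, axis=-1, kind="stable")
    base = d ** np.arange(d)
    return ranks @ base


def pattern_frequencies(
    series: Sequence[float] | np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig()
) -> PatternDistribution:
    """Relative frequency of each ordinal pattern occurring in the series."""
    regions = embed_regions(series, cfg)
    ranks = np.argsort(regions, axis=1, kind="stable")
    patterns, counts = np.unique(ranks, axis=0, return_counts=True)
    n = regions.shape[0]
    freq = {
        tuple(int(i) for i in pat): int(c) / n
        for pat, c in zip(patterns, counts)
    }
    return PatternDistribution(freq=freq, n_regions=n)


def permutation_entropy(
    series: Sequence[float] | np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig()
) -> float:
    """Normalized permutation entropy of one series, in [0, 1].

    Patterns that never occur contribute nothing to the sum (the
    0*log 0 = 0 limit convention); no pseudo-counts are added.
    """
    regions = embed_regions(series, cfg)
    codes = _pattern_codes(regions, cfg.d)
    counts = np.unique(codes, return_counts=True)[1]
    p = counts / codes.shape[0]
    h = -np.sum(p * np.log2(p))
    return float(np.clip(h / math.log2(cfg.n_patterns), 0.0, 1.0))


class PermutationEntropy(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping series to their permutation entropy.

    ``X`` is ``(n_series, n_samples)`` — one series per row, all the same
    length — and ``transform`` returns an ``(n_series, 1)`` column of
    normalized entropies.  Stateless: ``fit`` only records and validates
    the input width, so the transformer composes with sklearn pipelines
    feeding entropy features into a downstream classifier.

    Parameters
    ----------
    d : int, default 3
        Embedding dimension (region length).
    tau : int, default 1
        Embedding delay (spacing between region samples).
    """

    def __init__(self, d: int = 3, tau: int = 1):
        self.d = d
        self.tau = tau

    def _cfg(self) -> EmbeddingConfig:
        return EmbeddingConfig(d=self.d, tau=self.tau)

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        cfg = self._cfg()
        if X.shape[1] < cfg.span:
            raise ValueError(
                f"series length {X.shape[1]} < minimum {cfg.span} for "
                f"d={self.d}, tau={self.tau}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        cfg = self._cfg()
        windows = sliding_window_view(X, cfg.span, axis=1)[:, :, :: cfg.tau]
        codes = _pattern_codes(windows, cfg.d)
        norm = math.log2(cfg.n_patterns)
        out = np.empty(X.shape[0])
        for i, row in enumerate(codes):
            counts = np.unique(row, return_counts=True)[1]
            p = counts / row.shape[0]
            out[i] = -np.sum(p * np.log2(p)) / norm
        return np.clip(out, 0.0, 1.0)[:, None]


def pe_feature_table(
    cohort: Cohort, cfg: EmbeddingConfig = EmbeddingConfig()
) -> pd.DataFrame:
    """Per-cycle, per-channel permutation entropy for a whole cohort.

    Returns a tidy frame with one row per (cycle, channel):
    columns ``subject_id, side, cycle_id, channel, pe``.  Entropy is
    computed channel-wise on each cycle's 201-sample angular series.
    """
    order = {ch: i for i, ch in enumerate(CHANNELS)}
    rows = []
    for cyc in sorted(
        cohort.cycles, key=lambda c: (c.subject_id, c.cycle_id, c.side)
    ):
        for ch in sorted(cyc.samples, key=lambda c: order[c]):
            try:
                pe = permutation_entropy(cyc.samples[ch], cfg)
            except ValueError as err:
                raise ValueError(
                    f"cycle {cyc.subject_id}/{cyc.side}/{cyc.cycle_id}, "
                    f"channel {ch.label}: {err}"
                ) from err
            rows.append(
                (cyc.subject_id, cyc.side, cyc.cycle_id, ch.label, pe)
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "side", "cycle_id", "channel", "pe"]
    )


def subject_mean_pe(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean entropy vector: the 15-channel classifier features.

    Averages ``pe`` over each subject's cycles, per channel.  Returns a
    frame indexed by ``subject_id`` with one column per channel, in
    canonical channel order.
    """
    if table.empty:
        raise ValueError("feature table is empty")
    wide = (
        table.groupby(["subject_id", "channel"], sort=True)["pe"]
        .mean()
        .unstack("channel")
    )
    present = [c for c in CHANNEL_LABELS if c in wide.columns]
    return wide[present]
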