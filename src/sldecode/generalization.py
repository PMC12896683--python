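"""Temporal generalization and label-transfer analyses.

A classifier trained at time t is scored at other times t': above-chance
off-diagonal AUC indicates that the same discriminative pattern is present
at both times.  Three flavors are provided:

* :func:`temporal_generalization` — the full train-time x test-time matrix;
* :func:`cross_epoch_curves` — lag-aligned curves linking the presearch
  interval (after placeholder onset) with the postsearch interval (after
  search onset): a model trained tau seconds into one interval is tested
  tau seconds into the other, in both directions;
* :func:`label_transfer` — train on one label column, test on another
  (e.g. train on the previous trial's distractor hemifield, test on the
  current trial's).

Generalization analyses default to logistic regression; the pseudotrial,
standardization, and cross-validation discipline is identical to plain
time-resolved decoding, and held-out pseudotrials are reused across test
times so no trial serves in both roles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import EpochSet
from .decoding import (
    DecodingConfig,
    DecodingResult,
    _decode_pairs,
    valid_centers,
)

__all__ = [
    "TGMatrix",
    "LagCurve",
    "temporal_generalization",
    "cross_epoch_curves",
    "label_transfer",
]


def _default_config(config: DecodingConfig | None) -> DecodingConfig:
    return config if config is not None else DecodingConfig(classifier="logistic")


@dataclass
class TGMatrix:
    """Temporal generalization matrix: train-time x test-time AUC."""

    train_times: np.ndarray
    test_times: np.ndarray
    auc: np.ndarray  # (..., train, test); leading axis = subjects if stacked
    config: DecodingConfig
    label_column: str
    chance: float = 0.5

    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.auc, axis1=-2, axis2=-1)

    @staticmethod
    def stack(matrices: "list[TGMatrix]") -> "TGMatrix":
        first = matrices[0]
        return replace(first, auc=np.stack([m.auc for m in matrices]))


@dataclass
class LagCurve:
    """Cross-epoch generalization at matched lags from interval onsets."""

    lags: np.ndarray  # seconds from each interval's start
    auc: np.ndarray  # (..., lag)
    direction: str  # "pre_to_post" or "post_to_pre"
    pre_interval: tuple[float, float]
    post_interval: tuple[float, float]
    config: DecodingConfig | None = None
    chance: float = 0.5

    @staticmethod
    def stack(curves: "list[LagCurve]") -> "LagCurve":
        first = curves[0]
        return replace(first, auc=np.stack([c.auc for c in curves]))


def temporal_generalization(
    epochs: EpochSet, label_column: str, config: DecodingConfig | None = None
) -> TGMatrix:
    """Train at every time center, test at every other, for one subject."""
    config = _default_config(config)
    config.validate()
    centers = valid_centers(
        epochs.n_samples, config.window_samples, config.time_step
    )
    pairs = [(int(c), centers.copy()) for c in centers]
    out = _decode_pairs(epochs, label_column, label_column, pairs, config)
    times = epochs.times[centers].copy()
    return TGMatrix(
        train_times=times,
        test_times=times.copy(),
        auc=np.stack(out),
        config=config,
        label_column=label_column,
    )


def cross_epoch_curves(
    epochs: EpochSet,
    label_column: str,
    pre_interval: tuple[float, float] = (0.0, 1.0),
    post_interval: tuple[float, float] = (1.5, 2.5),
    config: DecodingConfig | None = None,
    max_lag: float | None = None,
) -> tuple[LagCurve, LagCurve]:
    """Lag-aligned cross-epoch generalization, both directions.

    For each lag tau (in steps of ``config.time_step`` samples), the
    pre-to-post curve trains at ``pre_start + tau`` and tests at
    ``post_start + tau``; the post-to-pre curve swaps roles.  Lags whose
    sliding window would leave the epoch are dropped.  ``max_lag``
    optionally restricts the lag axis (e.g. to the windows a statistical
    test will use).
    """
    config = _default_config(config)
    config.validate()
    if not np.isclose(
        pre_interval[1] - pre_interval[0], post_interval[1] - post_interval[0]
    ):
        raise ValueError("pre and post intervals must have equal length")
    sfreq = epochs.sfreq
    half = (config.window_samples - 1) // 2
    i_pre = epochs.time_index(pre_interval[0])
    i_post = epochs.time_index(post_interval[0])
    n_lags = int(np.rint((pre_interval[1] - pre_interval[0]) * sfreq))
    if max_lag is not None:
        n_lags = min(n_lags, int(np.rint(max_lag * sfreq)) + 1)
    lag_steps = []
    for k in range(0, n_lags, config.time_step):
        lo = min(i_pre, i_post) + k
        hi = max(i_pre, i_post) + k
        if lo - half >= 0 and hi + half < epochs.n_samples:
            lag_steps.append(k)
    if not lag_steps:
        raise ValueError("no valid lags for the requested intervals")
    pairs_fwd = [(i_pre + k, np.array([i_post + k])) for k in lag_steps]
    pairs_bwd = [(i_post + k, np.array([i_pre + k])) for k in lag_steps]
    out_fwd = _decode_pairs(epochs, label_column, label_column, pairs_fwd, config)
    out_bwd = _decode_pairs(epochs, label_column, label_column, pairs_bwd, config)
    lags = np.array(lag_steps) / sfreq
    common = dict(
        lags=lags,
        pre_interval=pre_interval,
        post_interval=post_interval,
        config=config,
    )
    return (
        LagCurve(auc=np.array([a[0] for a in out_fwd]),
                 direction="pre_to_post", **common),
        LagCurve(auc=np.array([a[0] for a in out_bwd]),
                 direction="post_to_pre", **common),
    )


def label_transfer(
    epochs: EpochSet,
    train_label: str,
    test_label: str,
    config: DecodingConfig | None = None,
) -> DecodingResult:
    """Train on one label column, score held-out pseudotrials on another.

    Trials are restricted to rows where both labels are left/right (NA and
    'absent' dropped); class balancing uses the training label.  With
    ``train_label == test_label`` this reduces exactly to
    :func:`sldecode.decoding.decode_timecourse`.
    """
    config = config if config is not None else DecodingConfig()
    config.validate()
    centers = valid_centers(
        epochs.n_samples, config.window_samples, config.time_step
    )
    pairs = [(int(c), np.array([int(c)])) for c in centers]
    out = _decode_pairs(epochs, train_label, test_label, pairs, config)
    return DecodingResult(
        times=epochs.times[centers].copy(),
        auc=np.array([a[0] for a in out]),
        config=config,
        label_column=train_label,
        test_label_column=test_label,
    )
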