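"""Time-resolved linear decoding of condition labels from epoched data.

The pipeline mirrors standard sensor-level MVPA practice: at each time
point, sensor data within a short sliding window (default 5 samples = 25 ms
at 200 Hz) form the feature vector; the majority class is subsampled to the
minority count; trials are split into stratified cross-validation folds;
*pseudotrials* (averages of ``m`` same-class trials, drawn without
replacement) are formed separately within the training and test partitions;
features are z-scored with training-set statistics; an optional univariate
F-test keeps the top-k features; a linear classifier (SVM or logistic) is
fit; and performance is summarized as the ROC AUC of the held-out decision
scores.  Sessions are decoded independently and averaged within subject.

The same machinery generalizes across time: a model fit at one time center
can be scored at any other, which is what the temporal-generalization
module builds on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import EpochSet

__all__ = [
    "DecodingConfig",
    "DecodingResult",
    "LinearModel",
    "extract_features",
    "balance_classes",
    "make_pseudotrials",
    "standardize",
    "select_features_f",
    "train_linear_classifier",
    "auc_score",
    "decode_timecourse",
    "haufe_patterns",
    "valid_centers",
]

_SD_FLOOR = 1e-12


@dataclass
class DecodingConfig:
    """Decoding hyperparameters.

    ``window_samples`` is the (odd) sliding-window length; with 200 Hz data
    the default of 5 spans 25 ms.  ``pseudotrial_size`` is the number of
    trials averaged per pseudotrial.  ``time_step`` strides over time
    centers (1 = every sample); larger strides trade temporal resolution
    for speed without touching the per-time computation.
    """

    window_samples: int = 5
    pseudotrial_size: int = 5
    n_folds: int = 5
    classifier: str = "linear_svm"  # or "logistic"
    regularization: float = 1.0
    feature_select_k: int | None = None
    balance: bool = True
    n_repeats: int = 1
    time_step: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.window_samples < 1 or self.window_samples % 2 == 0:
            raise ValueError("window_samples must be odd and >= 1")
        if self.pseudotrial_size < 1:
            raise ValueError("pseudotrial_size must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.classifier not in ("linear_svm", "logistic"):
            raise ValueError("classifier must be 'linear_svm' or 'logistic'")
        if self.time_step < 1:
            raise ValueError("time_step must be >= 1")


@dataclass
class LinearModel:
    """A linear decision rule ``s(x) = <w, x> + b``."""

    weights: np.ndarray
    bias: float

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


@dataclass
class DecodingResult:
    """Per-time AUC with configuration provenance.

    ``auc`` has time as the last axis; a leading axis indexes subjects when
    results from several subjects are stacked.
    """

    times: np.ndarray
    auc: np.ndarray
    config: DecodingConfig
    label_column: str
    test_label_column: str | None = None
    chance: float = 0.5

    @staticmethod
    def stack(results: "list[DecodingResult]") -> "DecodingResult":
        """Stack single-subject results into a subjects x time result."""
        first = results[0]
        for r in results[1:]:
            if not np.allclose(r.times, first.times):
                raise ValueError("results have mismatched time axes")
        return replace(first, auc=np.stack([r.auc for r in results]))


def valid_centers(n_samples: int, window_samples: int, time_step: int = 1) -> np.ndarray:
    """Indices of window centers that keep the full window inside the epoch."""
    half = (window_samples - 1) // 2
    return np.arange(half, n_samples - half, time_step)


def extract_features(
    epochs: EpochSet, t_center: float, window_samples: int
) -> np.ndarray:
    """Features at one time center: sensors x window values, concatenated.

    Row i is trial i's sensor data over the centered window, flattened
    sensor-major; feature length = ``n_sensors * window_samples``.
    """
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError("window_samples must be odd and >= 1")
    idx = epochs.time_index(t_center)
    half = (window_samples - 1) // 2
    if idx - half < 0 or idx + half >= epochs.n_samples:
        raise ValueError(
            f"window of {window_samples} samples centered at {t_center} s "
            "extends beyond the epoch"
        )
    block = epochs.data[:, :, idx - half : idx + half + 1]
    return block.reshape(epochs.n_trials, -1)


def balance_classes(labels: np.ndarray, seed: int) -> np.ndarray:
    """Subsample the majority class to the minority count.

    Returns the sorted indices of retained trials; the minority class is
    kept in full.  With equal counts all indices are returned.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() == 0:
        raise ValueError("balance_classes requires two non-empty classes")
    n_keep = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _partition_groups(
    labels: np.ndarray, m: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random within-class partition into groups of exactly m (remainder
    dropped); each index appears in at most one group."""
    groups: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if m > 1:
            idx = rng.permutation(idx)
        for k in range(len(idx) // m):
            groups.append(idx[k * m : (k + 1) * m])
    return groups


def make_pseudotrials(
    features: np.ndarray, labels: np.ndarray, m: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average random same-class groups of ``m`` trials into pseudotrials.

    Per class, ``floor(n/m)`` pseudotrials are formed from a random
    partition; leftover trials are dropped.  ``m = 1`` returns the input
    unchanged (up to class ordering).
    """
    if m < 1:
        raise ValueError("pseudotrial size m must be >= 1")
    features = np.asarray(features)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    groups = _partition_groups(labels, m, rng)
    if not groups:
        raise ValueError(f"no class has at least m={m} trials")
    pseudo = np.stack([features[g].mean(axis=0) for g in groups])
    pseudo_labels = np.array([labels[g[0]] for g in groups])
    return pseudo, pseudo_labels


def standardize(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """z-score both sets with per-feature mean/SD estimated on train only.

    The SD uses the population convention (denominator n); features with
    (near-)zero training SD are mapped to 0 in both sets.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    dead = sd <= _SD_FLOOR
    sd_safe = np.where(dead, 1.0, sd)
    train_z = (train - mu) / sd_safe
    test_z = (test - mu) / sd_safe
    train_z[:, dead] = 0.0
    test_z[:, dead] = 0.0
    return train_z, test_z


def select_features_f(
    train: np.ndarray, labels: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the k features with the largest one-way ANOVA F statistic.

    Computed on the training set only.  ``k`` larger than the feature count
    is clamped (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    train = np.asarray(train)
    if k >= train.shape[1]:
        if k > train.shape[1]:
            warnings.warn(
                f"feature_select_k={k} exceeds {train.shape[1]} features; "
                "keeping all",
                stacklevel=2,
            )
        return np.arange(train.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield 0/0 -> nan
        f_stats, _ = f_classif(train, labels)
    f_stats = np.nan_to_num(f_stats, nan=-np.inf)
    top = np.argpartition(f_stats, -k)[-k:]
    return np.sort(top)


def train_linear_classifier(
    X: np.ndarray, y: np.ndarray, config: DecodingConfig
) -> LinearModel:
    """Fit the configured linear classifier and return its decision rule.

    Decision scores are oriented toward the lexicographically larger class
    (e.g. positive scores favor 'right' over 'left').
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("training labels must contain exactly two classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y_bin = (y == classes[1]).astype(int)
    if config.classifier == "linear_svm":
        est = SVC(kernel="linear", C=config.regularization)
    else:
        est = LogisticRegression(
            C=config.regularization, solver="lbfgs", max_iter=1000
        )
    est.fit(X, y_bin)
    return LinearModel(weights=est.coef_.ravel().copy(), bias=float(est.intercept_[0]))


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of decision scores against two-class labels.

    Equals the Mann-Whitney statistic: the fraction of (positive, negative)
    pairs whose positive score is larger, with ties counted 0.5.  The
    positive class is the lexicographically larger label.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score((labels == classes[1]).astype(int), scores))


def _auc_columns(scores: np.ndarray, y_bin: np.ndarray) -> np.ndarray:
    """Tie-aware Mann-Whitney AUC for each column of a scores matrix."""
    n_pos = int(y_bin.sum())
    n_neg = len(y_bin) - n_pos
    ranks = rankdata(scores, axis=0)
    rank_sum = ranks[y_bin == 1].sum(axis=0)
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def haufe_patterns(X: np.ndarray, model: LinearModel) -> np.ndarray:
    """Activation pattern of a linear decoder: ``A = Cov(X) w``.

    Converts backward-model weights into a forward (encoding) pattern by
    multiplying with the data covariance; the result is normalized to unit
    norm with its sign fixed so that ``<A, w> >= 0``.  A small ridge is
    added to the covariance diagonal for numerical safety.
    """
    X = np.asarray(X, dtype=float)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    ridge = 1e-12 * max(np.trace(cov) / cov.shape[0], 1.0)
    cov = cov + ridge * np.eye(cov.shape[0])
    a = cov @ model.weights
    norm = np.linalg.norm(a)
    if norm > 0:
        a = a / norm
    if a @ model.weights < 0:
        a = -a
    return a


# ---------------------------------------------------------------------------
# session engine


def _filter_two_class(values: pd.Series) -> np.ndarray:
    """Row mask keeping left/right trials; NA and 'absent' are dropped."""
    vals = values.to_numpy(dtype=object)
    return (vals == "left") | (vals == "right")


def _effective_model(
    model: LinearModel,
    mu: np.ndarray,
    sd_safe: np.ndarray,
    dead: np.ndarray,
    sel: np.ndarray | None,
    n_features: int,
) -> LinearModel:
    """Fold standardization + selection into raw-feature-space weights."""
    w_sel = model.weights
    w_std = np.zeros(n_features)
    if sel is None:
        sel = np.arange(n_features)
    w_std[sel] = w_sel
    w_std[dead] = 0.0
    w_raw = w_std / sd_safe
    b_raw = model.bias - float((w_std * mu / sd_safe).sum())
    return LinearModel(weights=w_raw, bias=b_raw)


def _session_pairs_auc(
    data: np.ndarray,
    y_train: np.ndarray,
    y_test: np.ndarray,
    pairs: list[tuple[int, np.ndarray]],
    config: DecodingConfig,
    session_seed: int,
) -> list[np.ndarray]:
    """Cross-validated generalization AUC for one session.

    ``pairs`` maps each training time-center index to the test time-center
    indices to score.  Per fold, pseudotrials are formed separately in the
    training and test partitions (grouped by their respective label
    columns) and reused across all time centers, so that the model trained
    at one time is evaluated on the *same* held-out pseudotrials at every
    other time.  Returns one AUC vector per pair, averaged over folds and
    repeats.
    """
    config.validate()
    m = config.pseudotrial_size
    half = (config.window_samples - 1) // 2
    n_trials, n_sensors, _ = data.shape
    classes_tr = np.unique(y_train)
    classes_te = np.unique(y_test)
    if len(classes_tr) != 2 or len(classes_te) != 2:
        raise ValueError("both label vectors must contain exactly two classes")
    counts = np.array([(y_train == c).sum() for c in classes_tr])
    if counts.min() < config.n_folds * m:
        raise ValueError(
            f"need at least n_folds*m = {config.n_folds * m} trials per class, "
            f"got {counts.min()}"
        )
    rng = np.random.default_rng(session_seed)
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True,
        random_state=int(rng.integers(2**31)),
    )
    # stratify on the joint label so label-transfer folds keep both test
    # classes; identical to stratifying on y_train when the labels coincide
    y_strat = np.char.add(np.char.add(y_train.astype(str), "|"), y_test.astype(str))
    if np.unique(y_strat, return_counts=True)[1].min() < config.n_folds:
        y_strat = y_train
    sums = [np.zeros(len(tjs), dtype=float) for _, tjs in pairs]
    n_eval = 0
    for train_idx, test_idx in skf.split(np.zeros(n_trials), y_strat):
        for _ in range(config.n_repeats):
            g_tr = _partition_groups(y_train[train_idx], m, rng)
            g_te = _partition_groups(y_test[test_idx], m, rng)
            if not g_tr or not g_te:
                raise ValueError("a fold produced no pseudotrials")
            yp_tr = np.array([y_train[train_idx[g[0]]] for g in g_tr])
            yp_te = np.array([y_test[test_idx[g[0]]] for g in g_te])
            yb_te = (yp_te == classes_te[1]).astype(int)
            if len(np.unique(yp_tr)) < 2:
                raise ValueError("training fold lost one class after pseudotrials")
            if yb_te.sum() == 0 or yb_te.sum() == len(yb_te):
                # can happen when test pseudotrials are grouped by a different
                # label than the one stratifying the folds (label transfer
                # with scarce trials); skip the draw rather than fail
                warnings.warn(
                    "test fold lost one class after pseudotrial grouping; "
                    "skipping this fold/repeat",
                    stacklevel=3,
                )
                continue
            ep_tr = np.stack([data[train_idx[g]].mean(axis=0) for g in g_tr])
            ep_te = np.stack([data[test_idx[g]].mean(axis=0) for g in g_te])
            # sliding windows over test pseudotrials: (P, S, T-w+1, w)
            win_te = np.lib.stride_tricks.sliding_window_view(
                ep_te, config.window_samples, axis=2
            )
            for k, (ti, tjs) in enumerate(pairs):
                X_tr = ep_tr[:, :, ti - half : ti + half + 1].reshape(
                    len(ep_tr), -1
                )
                mu = X_tr.mean(axis=0)
                sd = X_tr.std(axis=0)
                dead = sd <= _SD_FLOOR
                sd_safe = np.where(dead, 1.0, sd)
                X_trz = (X_tr - mu) / sd_safe
                X_trz[:, dead] = 0.0
                sel = None
                if config.feature_select_k is not None:
                    sel = select_features_f(
                        X_trz, yp_tr, config.feature_select_k
                    )
                    X_fit = X_trz[:, sel]
                else:
                    X_fit = X_trz
                model = train_linear_classifier(X_fit, yp_tr, config)
                eff = _effective_model(
                    model, mu, sd_safe, dead, sel, X_tr.shape[1]
                )
                w_sw = eff.weights.reshape(n_sensors, config.window_samples)
                scores = (
                    np.einsum(
                        "pstw,sw->pt",
                        win_te[:, :, np.asarray(tjs) - half, :],
                        w_sw,
                        optimize=True,
                    )
                    + eff.bias
                )
                sums[k] += _auc_columns(scores, yb_te)
            n_eval += 1
    if n_eval == 0:
        raise ValueError(
            "every fold lost a test class after pseudotrial grouping; "
            "reduce pseudotrial_size or n_folds"
        )
    return [s / n_eval for s in sums]


def _prepare_session(
    epochs: EpochSet,
    session: int,
    train_col: str,
    test_col: str,
    config: DecodingConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filter one session to two-class rows and apply class balancing."""
    table = epochs.trial_table
    mask = (
        (table["session"] == session).to_numpy()
        & _filter_two_class(table[train_col])
        & _filter_two_class(table[test_col])
    )
    rows = np.flatnonzero(mask)
    if len(rows) == 0:
        raise ValueError(f"session {session}: no usable trials for '{train_col}'")
    y_train = table[train_col].to_numpy(dtype=object)[rows].astype(str)
    y_test = table[test_col].to_numpy(dtype=object)[rows].astype(str)
    if config.balance:
        counts = np.unique(y_train, return_counts=True)[1]
        if len(counts) == 2 and counts[0] != counts[1]:
            keep = balance_classes(
                y_train, seed=int(np.random.default_rng(
                    (config.seed, int(session), 0xBA1A)
                ).integers(2**31))
            )
            rows = rows[keep]
            y_train = y_train[keep]
            y_test = y_test[keep]
    return epochs.data[rows], y_train, y_test


def _decode_pairs(
    epochs: EpochSet,
    train_col: str,
    test_col: str,
    pairs: list[tuple[int, np.ndarray]],
    config: DecodingConfig,
) -> list[np.ndarray]:
    """Run the session engine on every session and average the AUC."""
    sessions = sorted(epochs.trial_table["session"].unique())
    acc = None
    for session in sessions:
        data, y_tr, y_te = _prepare_session(
            epochs, session, train_col, test_col, config
        )
        session_seed = int(
            np.random.default_rng((config.seed, int(session))).integers(2**31)
        )
        out = _session_pairs_auc(data, y_tr, y_te, pairs, config, session_seed)
        if acc is None:
            acc = out
        else:
            acc = [a + o for a, o in zip(acc, out)]
    return [a / len(sessions) for a in acc]


def decode_timecourse(
    epochs: EpochSet, label_column: str, config: DecodingConfig | None = None
) -> DecodingResult:
    """Time-resolved decoding of a two-class label for one subject.

    Sessions are decoded independently (balancing, CV, pseudotrials, and
    standardization all within session) and the per-time AUC is averaged
    across sessions to give the subject-level estimate.
    """
    config = config if config is not None else DecodingConfig()
    config.validate()
    centers = valid_centers(
        epochs.n_samples, config.window_samples, config.time_step
    )
    pairs = [(int(c), np.array([int(c)])) for c in centers]
    out = _decode_pairs(epochs, label_column, label_column, pairs, config)
    auc = np.array([a[0] for a in out])
    return DecodingResult(
        times=epochs.times[centers].copy(),
        auc=auc,
        config=config,
        label_column=label_column,
    )
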