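"""Group-level inference for decoding time courses and generalization
matrices.

Implements the standard nonparametric toolkit for time-resolved decoding
results: point-wise one-sample t tests against chance, cluster-mass
permutation tests (1D temporal adjacency or 2D 4-connectivity on the
train x test lattice) with a sign-flip null, Benjamini-Hochberg FDR over a
small family of a-priori windows, and the one-sample JZS Bayes factor.

The permutation unit is the subject: under the null that every subject's
deviation from chance is symmetric about zero, the signs of subject-level
deviation curves are exchangeable, so the null distribution of the maximum
|cluster mass| is built from random (or, when feasible, exhaustive)
sign-flips.  Monte-Carlo p-values use the (k+1)/(B+1) convention and are
therefore never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterTestConfig",
    "Cluster",
    "ClusterResult",
    "WindowedTestResult",
    "one_sample_t",
    "cluster_permutation_1d",
    "cluster_permutation_2d",
    "windowed_tests",
    "fdr_bh",
    "bf10_jzs",
]


@dataclass
class ClusterTestConfig:
    """Cluster-permutation settings.

    ``alpha_forming`` is the two-tailed point-wise threshold used to form
    clusters; ``n_permutations`` is the Monte-Carlo sample size (when it
    reaches ``2**n_subjects`` the test enumerates all sign patterns
    exhaustively instead).
    """

    alpha_forming: float = 0.05
    n_permutations: int = 1024
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha_forming < 1:
            raise ValueError("alpha_forming must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class Cluster:
    """One supra-threshold cluster: member flat indices, summed t, sign."""

    indices: np.ndarray
    mass: float
    sign: int


@dataclass
class ClusterResult:
    """Clusters with Monte-Carlo p-values and the max-|mass| null."""

    clusters: list[Cluster]
    p_values: np.ndarray
    null_distribution: np.ndarray
    t_map: np.ndarray
    threshold: float
    exhaustive: bool = False

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c, p in zip(self.clusters, self.p_values) if p < alpha]


def one_sample_t(values: np.ndarray, mu: float = 0.0) -> tuple[float, int, float]:
    """Two-tailed one-sample t test: returns ``(t, df, p)``.

    ``t = (mean - mu) / (sd / sqrt(n))`` with the n-1 SD.  A zero-variance
    sample returns ``t = +/-inf`` with ``p = 0`` and a warning.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two observations")
    df = n - 1
    delta = values.mean() - mu
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance in one_sample_t; t is infinite", stacklevel=2)
        t = np.inf * np.sign(delta) if delta != 0 else 0.0
        return float(t), df, 0.0 if delta != 0 else 1.0
    t = delta / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def _t_maps(deviations: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Point-wise t maps for many sign-flip patterns at once.

    ``deviations``: subjects x points; ``signs``: B x subjects (+/-1).
    Flipping a subject's sign leaves per-point second moments unchanged,
    so each permutation's t map follows from the flipped mean alone.
    """
    n = deviations.shape[0]
    mean = signs @ deviations / n
    msq = (deviations**2).mean(axis=0)
    var = (msq - mean**2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def _clusters_from_tmap(
    t_map: np.ndarray, threshold: float, structure: np.ndarray | None
) -> list[Cluster]:
    """Group supra-threshold points by adjacency, separately per sign."""
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t_map) > threshold
        if not mask.any():
            continue
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            idx = np.flatnonzero(labels.ravel() == lab)
            mass = float(t_map.ravel()[idx].sum())
            clusters.append(Cluster(indices=idx, mass=mass, sign=sign))
    return clusters


def _max_cluster_mass(
    t_map: np.ndarray, threshold: float, structure: np.ndarray | None
) -> float:
    clusters = _clusters_from_tmap(t_map, threshold, structure)
    if not clusters:
        return 0.0
    return max(abs(c.mass) for c in clusters)


def _sign_patterns(n: int) -> np.ndarray:
    """All 2**n sign patterns, identity first."""
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    return 1.0 - 2.0 * bits


def _cluster_permutation(
    data: np.ndarray, chance: float, config: ClusterTestConfig, ndim: int
) -> ClusterResult:
    config.validate()
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    shape = data.shape[1:]
    deviations = (data - chance).reshape(n, -1)
    structure = None
    if ndim == 2:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    threshold = float(stats.t.ppf(1 - config.alpha_forming / 2, n - 1))

    obs_t = _t_maps(deviations, np.ones((1, n)))[0].reshape(shape)
    clusters = _clusters_from_tmap(obs_t, threshold, structure)

    exhaustive = 2**n <= config.n_permutations
    if exhaustive:
        signs = _sign_patterns(n)
    else:
        rng = np.random.default_rng(config.seed)
        signs = 1.0 - 2.0 * rng.integers(
            0, 2, size=(config.n_permutations, n)
        ).astype(float)
    t_perm = _t_maps(deviations, signs)
    null = np.array(
        [
            _max_cluster_mass(t_perm[b].reshape(shape), threshold, structure)
            for b in range(t_perm.shape[0])
        ]
    )
    p_values = np.empty(len(clusters))
    for i, cl in enumerate(clusters):
        k = int((null >= abs(cl.mass)).sum())
        if exhaustive:
            # identity pattern is included in the enumeration, so k >= 1
            p_values[i] = k / len(null)
        else:
            p_values[i] = (k + 1) / (len(null) + 1)
    return ClusterResult(
        clusters=clusters,
        p_values=p_values,
        null_distribution=null,
        t_map=obs_t,
        threshold=threshold,
        exhaustive=exhaustive,
    )


def cluster_permutation_1d(
    subject_by_time: np.ndarray,
    chance: float = 0.5,
    config: ClusterTestConfig | None = None,
) -> ClusterResult:
    """Cluster-mass permutation test on subject x time curves.

    Point-wise two-tailed t tests against ``chance`` are thresholded at
    ``alpha_forming``; temporally adjacent supra-threshold points of the
    same sign form clusters whose mass is the summed t; the null is the
    maximum |mass| over subject sign-flips.
    """
    config = config if config is not None else ClusterTestConfig()
    data = np.asarray(subject_by_time, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a subjects x time matrix")
    return _cluster_permutation(data, chance, config, ndim=1)


def cluster_permutation_2d(
    subject_by_traintest: np.ndarray,
    chance: float = 0.5,
    config: ClusterTestConfig | None = None,
) -> ClusterResult:
    """Cluster-mass permutation test on subject x train x test matrices.

    As the 1D test, with 4-connectivity on the train x test lattice (cells
    touching only diagonally belong to different clusters).
    """
    config = config if config is not None else ClusterTestConfig()
    data = np.asarray(subject_by_traintest, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a subjects x train x test array")
    return _cluster_permutation(data, chance, config, ndim=2)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: ``(reject mask, adjusted p)``."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class WindowedTestResult:
    """Per-window t tests against chance with FDR and Bayes factors."""

    labels: list[str]
    centers: np.ndarray
    half_width: float
    t: np.ndarray
    df: int
    p_uncorrected: np.ndarray
    p_fdr: np.ndarray
    reject: np.ndarray
    bf10: np.ndarray
    window_means: np.ndarray = field(repr=False, default=None)


def windowed_tests(
    curves,
    times: np.ndarray | None = None,
    centers=(0.1, 0.2),
    half_width: float = 0.025,
    chance: float = 0.5,
    q: float = 0.05,
) -> WindowedTestResult:
    """A-priori-window t tests with BH-FDR across the tested family.

    ``curves`` is either a subjects x time matrix (with ``times``) or a
    dict mapping a direction/condition name to ``(matrix, times)`` pairs;
    in the latter case the FDR family spans all windows x conditions
    tested in this call.  Per window, subject curves are averaged over
    samples in the closed interval ``[center - half_width,
    center + half_width]`` before a two-tailed one-sample t test against
    ``chance``; the JZS Bayes factor is reported alongside.
    """
    if isinstance(curves, dict):
        items = [(name, np.asarray(m, dtype=float), np.asarray(t, dtype=float))
                 for name, (m, t) in curves.items()]
    else:
        if times is None:
            raise ValueError("times is required when curves is a matrix")
        items = [("", np.asarray(curves, dtype=float), np.asarray(times, dtype=float))]
    labels, cs, ts, ps, means = [], [], [], [], []
    df = None
    tol = 1e-9
    for name, mat, tax in items:
        if mat.ndim != 2 or mat.shape[1] != len(tax):
            raise ValueError("curve matrix must be subjects x time")
        for center in np.atleast_1d(centers):
            mask = (tax >= center - half_width - tol) & (
                tax <= center + half_width + tol
            )
            if not mask.any():
                raise ValueError(
                    f"window centered at {center} s contains no samples"
                )
            vals = mat[:, mask].mean(axis=1)
            t_stat, df_i, p = one_sample_t(vals, chance)
            if df is None:
                df = df_i
            labels.append(f"{name}@{center:g}s" if name else f"@{center:g}s")
            cs.append(center)
            ts.append(t_stat)
            ps.append(p)
            means.append(vals)
    reject, p_adj = fdr_bh(np.array(ps), q)
    bf = np.array([bf10_jzs(t, df + 1) for t in ts])
    return WindowedTestResult(
        labels=labels,
        centers=np.array(cs),
        half_width=half_width,
        t=np.array(ts),
        df=df,
        p_uncorrected=np.array(ps),
        p_fdr=p_adj,
        reject=reject,
        bf10=bf,
        window_means=np.array(means),
    )


def bf10_jzs(
    t: float, n: int, r: float = np.sqrt(2) / 2, n_quad: int = 201
) -> float:
    """One-sample JZS Bayes factor (alternative over null).

    The effect size carries a Cauchy(0, r) prior; the marginal likelihood
    under H1 is the noncentral-t density integrated over the prior, and
    BF10 is its ratio to the central-t density.  The integral is evaluated
    by Gauss-Legendre quadrature after the substitution ``delta =
    r * tan(theta)``, which maps the Cauchy prior to the uniform measure
    ``dtheta / pi`` on (-pi/2, pi/2); ``n_quad`` nodes are used.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("n must be >= 2")
    if r <= 0:
        raise ValueError("prior scale r must be > 0")
    nu = n - 1
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    theta = nodes * (np.pi / 2)
    delta = r * np.tan(theta)
    dens = stats.nct.pdf(t, nu, delta * np.sqrt(n))
    numerator = float(np.sum(weights * (np.pi / 2) * dens) / np.pi)
    denominator = float(stats.t.pdf(t, nu))
    return numerator / denominator
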