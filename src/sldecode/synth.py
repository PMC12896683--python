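"""Synthetic epoch generator emulating a statistical-learning visual-search
MEG session.

The generator has two halves:

* :func:`generate_design` builds a trial table with the study's design
  statistics realized as *exact counts* (rounded, then shuffled), rather than
  Bernoulli draws: per session, 66% of trials carry a color-singleton
  distractor, 75% of those fall in the session's high-probability hemifield
  (roles swapped between the two sessions), and targets are split 50/50
  across hemifields.

* :func:`simulate_epochs` plants condition-locked spatial activity patterns
  into spatiotemporally correlated Gaussian sensor noise.  Each effect is a
  unit-norm sensor pattern whose polarity encodes the relevant left/right
  label, multiplied by a windowed envelope: a presearch pattern tied to the
  upcoming distractor hemifield, early and late reactive patterns after
  search onset, a post-search target pattern, and an intertrial carryover
  pattern tied to the previous trial's distractor hemifield.  The
  correlation between the presearch and the late reactive pattern is
  constructed exactly, so cross-epoch generalization strength is under
  direct experimental control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .data import EpochSet, attach_previous_labels, validate_trial_table

__all__ = [
    "DesignConfig",
    "PatternSet",
    "EffectSpec",
    "PlantedEffectSpec",
    "NoiseSpec",
    "generate_design",
    "make_effect_patterns",
    "simulate_epochs",
    "simulate_subject",
]


@dataclass
class DesignConfig:
    """Trial-design parameters (defaults reproduce the study's session plan)."""

    n_sessions: int = 2
    blocks_per_session: int = 6
    trials_per_block: int = 120
    p_distractor_present: float = 0.66
    p_high_hemifield: float = 0.75
    high_prob_hemifield_session1: str = "left"
    swap_between_sessions: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_sessions, self.blocks_per_session, self.trials_per_block) < 1:
            raise ValueError("session/block/trial counts must be >= 1")
        if self.trials_per_block < 2:
            raise ValueError("trials_per_block must be >= 2 for exact balancing")
        for name in ("p_distractor_present", "p_high_hemifield"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.high_prob_hemifield_session1 not in ("left", "right"):
            raise ValueError("high_prob_hemifield_session1 must be 'left' or 'right'")


def _split_even(n: int, rng: np.random.Generator) -> tuple[int, int]:
    """Split n into two counts as evenly as possible; odd remainder random."""
    half = n // 2
    if n % 2 == 0:
        return half, half
    extra = int(rng.integers(2))
    return half + extra, half + 1 - extra


def generate_design(config: DesignConfig) -> pd.DataFrame:
    """Generate a trial table with exact design counts per session.

    Per session of ``blocks_per_session * trials_per_block`` trials:
    ``round(p_distractor_present * n)`` trials are distractor-present, of
    which ``round(p_high_hemifield * n_present)`` fall in that session's
    high-probability hemifield; within each hemifield the two distractor
    positions are split as evenly as possible.  Targets are assigned
    independently: hemifields split exactly 50/50 and positions balanced
    within hemifield.  Trial order is shuffled by the seed, previous-trial
    labels are attached, and the table is validated before return.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.blocks_per_session * config.trials_per_block
    frames = []
    for session in range(1, config.n_sessions + 1):
        high = config.high_prob_hemifield_session1
        if config.swap_between_sessions and session % 2 == 0:
            high = "right" if high == "left" else "left"
        low = "right" if high == "left" else "left"

        n_present = int(np.rint(config.p_distractor_present * n))
        n_high = int(np.rint(config.p_high_hemifield * n_present))
        n_low = n_present - n_high

        d_hemi = np.array(
            [high] * n_high + [low] * n_low + ["absent"] * (n - n_present),
            dtype=object,
        )
        d_pos = np.empty(n, dtype=object)
        d_pos[:] = "absent"
        off = 0
        for count in (n_high, n_low):
            up, lo = _split_even(count, rng)
            d_pos[off : off + count] = ["upper"] * up + ["lower"] * lo
            off += count

        t_left, t_right = _split_even(n, rng)
        t_hemi = np.array(["left"] * t_left + ["right"] * t_right, dtype=object)
        t_pos = np.empty(n, dtype=object)
        off = 0
        for count in (t_left, t_right):
            up, lo = _split_even(count, rng)
            t_pos[off : off + count] = ["upper"] * up + ["lower"] * lo
            off += count

        order_d = rng.permutation(n)
        order_t = rng.permutation(n)
        frame = pd.DataFrame(
            {
                "session": session,
                "block": np.arange(n) // config.trials_per_block + 1,
                "trial": np.arange(n) + 1,
                "distractor_present": (d_hemi[order_d] != "absent"),
                "distractor_hemifield": d_hemi[order_d],
                "distractor_position": d_pos[order_d],
                "target_hemifield": t_hemi[order_t],
                "target_position": t_pos[order_t],
                "high_prob_hemifield": high,
                "prev_distractor_hemifield": np.nan,
                "prev_target_hemifield": np.nan,
            }
        )
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table = attach_previous_labels(table)
    return validate_trial_table(table)


@dataclass
class PatternSet:
    """Unit-norm, zero-mean sensor patterns for each planted effect.

    Patterns live in the zero-mean subspace of sensor space, so the Pearson
    correlation between two patterns equals their inner product; the
    requested correlations are realized exactly by construction.
    """

    p_pre: np.ndarray
    p_early: np.ndarray
    p_late: np.ndarray
    p_target: np.ndarray
    p_carryover: np.ndarray
    rho_pre_late: float = 0.8
    rho_pre_early: float = 0.0
    rho_pre_carryover: float = 0.5


def make_effect_patterns(
    n_sensors: int,
    rho_pre_late: float = 0.8,
    rho_pre_early: float = 0.0,
    rho_pre_carryover: float = 0.5,
    seed: int = 0,
) -> PatternSet:
    """Construct the five effect patterns with exact pairwise correlations.

    Five orthonormal zero-mean basis vectors are drawn (Gram-Schmidt via QR
    on random Gaussians); ``p_early``, ``p_late`` and ``p_carryover`` are
    rotated mixtures of the presearch pattern and an orthogonal complement
    realizing the requested correlations exactly.  ``p_target`` is
    orthogonal to ``p_pre``.

    The nonzero default for ``rho_pre_carryover`` encodes the
    shared-mechanism hypothesis: the intertrial carryover trace and the
    proactive presearch bias occupy overlapping sensor patterns, which is
    what lets a classifier trained on the previous trial's distractor
    location transfer to the current trial's.
    """
    for name, rho in (
        ("rho_pre_late", rho_pre_late),
        ("rho_pre_early", rho_pre_early),
        ("rho_pre_carryover", rho_pre_carryover),
    ):
        if abs(rho) > 1:
            raise ValueError(f"{name} must lie in [-1, 1]")
    if n_sensors < 6:
        raise ValueError("need n_sensors >= 6 for five orthogonal zero-mean patterns")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_sensors, 5))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    # fix signs for reproducibility across LAPACK implementations
    q *= np.sign(q[0] + (q[0] == 0))
    b = [q[:, i] for i in range(5)]
    p_pre = b[0]
    p_early = rho_pre_early * p_pre + np.sqrt(1 - rho_pre_early**2) * b[1]
    p_late = rho_pre_late * p_pre + np.sqrt(1 - rho_pre_late**2) * b[2]
    p_carry = (
        rho_pre_carryover * p_pre + np.sqrt(1 - rho_pre_carryover**2) * b[4]
    )
    return PatternSet(
        p_pre=p_pre,
        p_early=p_early,
        p_late=p_late,
        p_target=b[3],
        p_carryover=p_carry,
        rho_pre_late=rho_pre_late,
        rho_pre_early=rho_pre_early,
        rho_pre_carryover=rho_pre_carryover,
    )


@dataclass
class EffectSpec:
    """One planted effect: amplitude, active window, and onset/offset ramp."""

    amplitude: float
    window: tuple[float, float]
    ramp: float = 0.025  # full half-Gaussian transition width (~2 sigma), s

    def envelope(self, times: np.ndarray) -> np.ndarray:
        """Boxcar over ``window`` with half-Gaussian ramps.

        ``ramp`` is the full transition width; the Gaussian sigma is half
        of it, so the envelope decays to ~13.5% at one ramp width outside
        the window and adjacent windows 50 ms apart stay distinct.
        """
        t_on, t_off = self.window
        env = np.ones_like(times)
        if self.ramp > 0:
            sigma = self.ramp / 2.0
            pre = times < t_on
            post = times > t_off
            env[pre] = np.exp(-0.5 * ((times[pre] - t_on) / sigma) ** 2)
            env[post] = np.exp(-0.5 * ((times[post] - t_off) / sigma) ** 2)
        else:
            env = ((times >= t_on) & (times <= t_off)).astype(float)
        return env


@dataclass
class PlantedEffectSpec:
    """The set of planted effects and their defaults.

    Windows are on the epoch time axis (0 = placeholder onset, 1.5 = search
    onset).  The presearch window covers roughly 100-700 ms after placeholder
    onset; early/late reactive windows sit ~100 ms and ~200 ms after search
    onset; amplitudes are in units of the noise SD.
    """

    presearch: EffectSpec = field(
        default_factory=lambda: EffectSpec(0.4, (0.1, 0.7))
    )
    early_reactive: EffectSpec = field(
        default_factory=lambda: EffectSpec(0.8, (1.575, 1.625))
    )
    late_reactive: EffectSpec = field(
        default_factory=lambda: EffectSpec(0.8, (1.675, 1.725))
    )
    target_post: EffectSpec = field(
        default_factory=lambda: EffectSpec(0.8, (1.675, 1.725))
    )
    carryover: EffectSpec = field(
        default_factory=lambda: EffectSpec(0.3, (0.1, 0.7))
    )

    def items(self):
        return {
            "presearch": self.presearch,
            "early_reactive": self.early_reactive,
            "late_reactive": self.late_reactive,
            "target_post": self.target_post,
            "carryover": self.carryover,
        }.items()

    def validate(self, span: tuple[float, float]) -> None:
        for name, eff in self.items():
            if eff.amplitude < 0:
                raise ValueError(f"{name}: amplitude must be >= 0")
            if eff.amplitude > 0 and not (
                span[0] <= eff.window[0] <= eff.window[1] <= span[1]
            ):
                raise ValueError(f"{name}: window {eff.window} outside span {span}")

    @classmethod
    def silent(cls) -> "PlantedEffectSpec":
        """All amplitudes zero (pure-noise data)."""
        spec = cls()
        for _, eff in spec.items():
            eff.amplitude = 0.0
        return spec


@dataclass
class NoiseSpec:
    """Gaussian sensor noise with optional spatial correlation and temporal
    smoothing.

    ``spatial_correlation`` mixes a random full-rank correlation matrix R
    with the identity: C = (1 - c) I + c R.  Temporal smoothing applies a
    moving average of the given width, rescaled so the marginal SD stays
    ``sensor_sd`` (the smoothing then only introduces autocorrelation).
    """

    sensor_sd: float = 1.0
    spatial_correlation: float = 0.2
    temporal_smoothing_ms: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.sensor_sd <= 0:
            raise ValueError("sensor_sd must be > 0")
        if not 0.0 <= self.spatial_correlation < 1.0:
            raise ValueError("spatial_correlation must lie in [0, 1)")


# label columns driving each effect's per-trial sign
_EFFECT_LABEL = {
    "presearch": "distractor_hemifield",
    "early_reactive": "distractor_hemifield",
    "late_reactive": "distractor_hemifield",
    "target_post": "target_hemifield",
    "carryover": "prev_distractor_hemifield",
}

_EFFECT_PATTERN = {
    "presearch": "p_pre",
    "early_reactive": "p_early",
    "late_reactive": "p_late",
    "target_post": "p_target",
    "carryover": "p_carryover",
}


def _label_signs(values: pd.Series) -> np.ndarray:
    """+1 for left, -1 for right, 0 for absent/NA."""
    signs = np.zeros(len(values))
    vals = values.to_numpy(dtype=object)
    signs[vals == "left"] = 1.0
    signs[vals == "right"] = -1.0
    return signs


def simulate_epochs(
    table: pd.DataFrame,
    patterns: PatternSet,
    effects: PlantedEffectSpec | None = None,
    noise: NoiseSpec | None = None,
    epoch_span: tuple[float, float] = (-0.5, 2.5),
    sfreq: float = 200.0,
) -> EpochSet:
    """Simulate an EpochSet for the given trial table.

    ``data[trial] = sum_effects sign(label) * amplitude * envelope(t) *
    pattern + noise``; distractor-absent trials carry zero distractor signal
    but full noise, and carryover contributes nothing when the previous
    trial's label is NA or absent.
    """
    effects = effects if effects is not None else PlantedEffectSpec()
    noise = noise if noise is not None else NoiseSpec()
    table = validate_trial_table(table)
    effects.validate(epoch_span)
    noise.validate()

    n_trials = len(table)
    n_sensors = len(patterns.p_pre)
    n_samples = int(np.rint((epoch_span[1] - epoch_span[0]) * sfreq))
    times = epoch_span[0] + np.arange(n_samples) / sfreq

    rng = np.random.default_rng(noise.seed)
    # spatial covariance: (1-c) I + c R, R a random unit-diagonal correlation
    c = noise.spatial_correlation
    if c > 0:
        a = rng.standard_normal((n_sensors, max(n_sensors, 2)))
        w = a @ a.T
        d = np.sqrt(np.diag(w))
        r = w / np.outer(d, d)
        cov = (1 - c) * np.eye(n_sensors) + c * r
        chol = np.linalg.cholesky(cov)
    else:
        chol = None

    eps = rng.standard_normal((n_trials, n_sensors, n_samples))
    if chol is not None:
        eps = np.einsum("st,nto->nso", chol, eps)
    k = int(np.rint(noise.temporal_smoothing_ms / 1000.0 * sfreq))
    if k > 1:
        eps = uniform_filter1d(eps, size=k, axis=2, mode="nearest")
        eps *= np.sqrt(k)  # restore marginal SD
    data = noise.sensor_sd * eps

    for name, eff in effects.items():
        if eff.amplitude == 0:
            continue
        col = _EFFECT_LABEL[name]
        if col not in table.columns:
            raise ValueError(f"effect '{name}' requires label column '{col}'")
        signs = _label_signs(table[col])
        if not np.any(signs):
            continue
        pattern = getattr(patterns, _EFFECT_PATTERN[name])
        env = eff.envelope(times)
        data += (
            eff.amplitude
            * signs[:, None, None]
            * pattern[None, :, None]
            * env[None, None, :]
        )

    return EpochSet(data=data, times=times, sfreq=sfreq, trial_table=table)


def simulate_subject(
    seed: int,
    n_sensors: int = 64,
    design: DesignConfig | None = None,
    effects: PlantedEffectSpec | None = None,
    noise_sd: float = 1.0,
    rho_pre_late: float = 0.8,
    rho_pre_early: float = 0.0,
    rho_pre_carryover: float = 0.5,
    epoch_span: tuple[float, float] = (-0.5, 2.5),
    sfreq: float = 200.0,
) -> EpochSet:
    """Convenience: one simulated subject with subject-specific patterns.

    Derives design, pattern, and noise seeds from ``seed`` so each subject
    has an independent trial order, its own spatial patterns (decoding is
    within-subject, so patterns need not be shared), and independent noise.
    """
    if design is None:
        design = DesignConfig(seed=seed)
    else:
        design = DesignConfig(**{**design.__dict__, "seed": seed})
    table = generate_design(design)
    patterns = make_effect_patterns(
        n_sensors, rho_pre_late=rho_pre_late, rho_pre_early=rho_pre_early,
        rho_pre_carryover=rho_pre_carryover, seed=seed + 1_000_003,
    )
    noise = NoiseSpec(sensor_sd=noise_sd, seed=seed + 2_000_003)
    return simulate_epochs(
        table, patterns, effects=effects, noise=noise,
        epoch_span=epoch_span, sfreq=sfreq,
    )
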