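"""Synthetic EEG cohorts with the statistical structure the pipeline assumes.

The signal model is additive: a 1/f background, lateralized mu (~10 Hz) and
beta (~20 Hz) sensorimotor sources over C3/C4, and band-limited beta/gamma
noise whose power scales with the induced frustration state.  Motor imagery
attenuates the source contralateral to the imagined hand (event-related
desynchronization); the attenuation depth and the source topography both
depend on the frustration state, so decoding degrades with frustration and
the optimal spatial filter is state-specific — which is exactly the regime
the state-aware fusion strategies are meant to exploit.

The protocol generator reproduces the feedback manipulation (80/65/50%
success rates for low/medium/high frustration) and 7-point Likert block
ratings.

Everything derives from one seed; subjects get independent child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import Epoch, TrialTable
from .preprocess import WindowSet, segment_epochs

__all__ = [
    "SyntheticConfig",
    "ProtocolLog",
    "simulate_trial",
    "simulate_subject",
    "simulate_cohort",
    "simulate_protocol",
]

STATES = ("low", "mid", "high")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the study conditions.

    Power/amplitude units are microvolts.  ``mi_erd_depth`` is the
    fractional mu/beta power reduction contralateral to the imagined hand in
    the low-frustration state; ``erd_state_scale`` scales it per state so
    motor-imagery decodability falls with frustration.
    ``erd_contra_weight`` sets, per state, how much of the attenuation
    falls on the contralateral vs the ipsilateral source (1 = strictly
    contralateral); ``topo_angle`` rotates each sensorimotor source away
    from its home electrode per state (radians).  Together they make the
    discriminative spatial pattern state-dependent.  ``beta_gain`` and
    ``gamma_gain`` are per-state multiplicative band-power factors
    (low < mid, low < high).
    """

    n_subjects: int = 12
    channels: tuple[str, ...] = ("C3", "Cz", "C4", "Oz")
    rate: float = 1000.0
    trial_len_s: float = 4.0
    trials_per_state_per_class: int = 30  # stage 2, per (state x MI class)
    stage1_trials_per_class: int = 100
    mi_erd_depth: float = 0.5
    erd_state_scale: tuple[float, float, float] = (1.0, 0.75, 0.6)
    erd_contra_weight: tuple[float, float, float] = (1.0, 0.0, 0.0)
    topo_angle: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beta_gain: tuple[float, float, float] = (1.0, 1.2, 1.35)
    gamma_gain: tuple[float, float, float] = (1.0, 1.3, 1.6)
    noise_exponent: float = 1.0
    bg_rms: float = 5.0
    mu_amp: float = 6.0
    beta_amp: float = 2.5
    state_beta_amp: float = 2.0
    state_gamma_amp: float = 1.5
    # spatial profiles of the state components, one per state (channel
    # order follows ``channels``).  The shapes differ across states — the
    # beta component shifts centrally with moderate frustration, the gamma
    # component becomes occipital-dominant with high frustration — so the
    # state signature survives per-window covariance normalization.
    state_beta_topo: tuple[tuple[float, ...], ...] = (
        (1.0, 1.0, 1.0, 0.7),
        (0.8, 1.4, 0.8, 0.7),
        (1.2, 0.9, 1.2, 0.8),
    )
    state_gamma_topo: tuple[tuple[float, ...], ...] = (
        (0.8, 0.9, 0.8, 1.0),
        (0.7, 1.2, 0.7, 1.0),
        (0.7, 0.8, 0.7, 1.6),
    )
    success_rates: tuple[float, float, float] = (0.80, 0.65, 0.50)
    likert_means: tuple[float, float, float] = (2.1, 3.5, 4.8)
    likert_sds: tuple[float, float, float] = (0.8, 1.4, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < r <= 1 for r in self.success_rates):
            raise ValueError("success rates must lie in (0, 1]")
        if not (0 <= self.mi_erd_depth <= 1):
            raise ValueError("mi_erd_depth must lie in [0, 1]")
        if not all(0 <= w <= 1 for w in self.erd_contra_weight):
            raise ValueError("erd_contra_weight entries must lie in [0, 1]")
        if min(self.beta_gain) <= 0 or min(self.gamma_gain) <= 0:
            raise ValueError("state gains must be positive")
        if self.rate <= 0 or self.trial_len_s <= 0:
            raise ValueError("rate and trial length must be positive")
        if self.trials_per_state_per_class < 1 or self.stage1_trials_per_class < 0:
            raise ValueError("trial counts must be positive")
        for name in ("C3", "C4"):
            if name not in self.channels:
                raise ValueError("channels must include C3 and C4")


def _one_over_f(rng: np.random.Generator, shape: tuple[int, int], rate: float, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise along the last axis."""
    n = shape[-1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    freqs[0] = freqs[1]
    spec *= freqs ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _band_noise(rng: np.random.Generator, shape: tuple[int, int], rate: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _state_index(state: str) -> int:
    if state == "none":
        return 0  # calibration behaves like the unmodulated low state
    return STATES.index(state)


def simulate_trial(
    state: str,
    mi_class: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One trial epoch (channels x samples), in microvolts.

    ``state`` in {"low", "mid", "high", "none"}; "none" is the calibration
    stage: no state-dependent band gains and the baseline topography.
    """
    if mi_class not in ("left", "right"):
        raise ValueError(f"unknown MI class {mi_class!r}")
    n = int(round(cfg.trial_len_s * cfg.rate))
    n_ch = len(cfg.channels)
    t = np.arange(n) / cfg.rate
    ch = {name: i for i, name in enumerate(cfg.channels)}
    s = _state_index(state)
    theta = cfg.topo_angle[s]
    erd = cfg.mi_erd_depth * cfg.erd_state_scale[s]

    x = cfg.bg_rms * _one_over_f(rng, (n_ch, n), cfg.rate, cfg.noise_exponent)

    # Lateralized sensorimotor sources.  In the low state imagery attenuates
    # the hemisphere contralateral to the imagined hand (left hand -> C4,
    # right hand -> C3); with rising frustration the attenuation's
    # hemispheric balance shifts (erd_contra_weight) until it is
    # ipsilateral-dominant, and each source topography also rotates away
    # from its home electrode (C3 toward Cz, C4 toward Oz).  Both make the
    # discriminative MI signature state-dependent, which is what defeats a
    # state-agnostic pooled decoder.
    w_contra = cfg.erd_contra_weight[s]
    for hemi_ch, lean_ch, contra_of in (("C3", "Cz", "right"), ("C4", "Oz", "left")):
        balance = w_contra if mi_class == contra_of else 1.0 - w_contra
        depth = erd * balance
        scale = np.sqrt(1.0 - depth)
        topo = np.zeros(n_ch)
        topo[ch[hemi_ch]] = np.cos(theta)
        if lean_ch in ch:
            topo[ch[lean_ch]] = np.sin(theta)
        for amp, freq in ((cfg.mu_amp, 10.0), (cfg.beta_amp, 20.0)):
            jitter = 1.0 + 0.1 * rng.standard_normal()
            phase = rng.uniform(0, 2 * np.pi)
            osc = amp * scale * abs(jitter) * np.sin(2 * np.pi * freq * t + phase)
            x += topo[:, None] * osc[None, :]

    if state != "none":
        # anisotropic spatial profiles keep the state signature visible to
        # spatial filtering (a purely isotropic gain would vanish under
        # per-window covariance normalization)
        beta_topo = np.asarray(cfg.state_beta_topo[s][:n_ch], dtype=float)
        gamma_topo = np.asarray(cfg.state_gamma_topo[s][:n_ch], dtype=float)
        x += (cfg.state_beta_amp * np.sqrt(cfg.beta_gain[s]) * beta_topo[:, None]
              * _band_noise(rng, (n_ch, n), cfg.rate, (12.0, 30.0)))
        x += (cfg.state_gamma_amp * np.sqrt(cfg.gamma_gain[s]) * gamma_topo[:, None]
              * _band_noise(rng, (n_ch, n), cfg.rate, (30.0, 45.0)))
    return x


def _subject_rng(cfg: SyntheticConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_index]))


def simulate_subject(
    cfg: SyntheticConfig,
    subject_index: int,
) -> tuple[list[Epoch], TrialTable]:
    """All trials for one subject (stage 1 then stage 2), deterministically
    derived from ``cfg.seed`` and the subject index."""
    rng = _subject_rng(cfg, subject_index)
    subject_id = f"S{subject_index + 1:02d}"
    n = int(round(cfg.trial_len_s * cfg.rate))
    gap = int(round(cfg.rate))  # nominal inter-trial gap for the table
    epochs: list[Epoch] = []
    rows = []
    onset = 0
    counter = 0

    def add(state: str, mi: str, stage: int) -> None:
        nonlocal onset, counter
        trial_id = f"{subject_id}_t{counter:04d}"
        data = simulate_trial(state, mi, cfg, rng)
        epochs.append(
            Epoch(
                data=data, rate=cfg.rate, channel_names=list(cfg.channels),
                subject_id=subject_id, trial_id=trial_id,
                mi_label=mi, state_label=state, stage=stage,
            )
        )
        rows.append(
            {
                "subject_id": subject_id, "trial_id": trial_id,
                "onset_sample": onset, "duration_samples": n,
                "mi_label": mi, "state_label": state, "stage": stage,
            }
        )
        onset += n + gap
        counter += 1

    stage1_order = ["left", "right"] * cfg.stage1_trials_per_class
    rng.shuffle(stage1_order)
    for mi in stage1_order:
        add("none", mi, stage=1)
    for state in STATES:
        block = ["left", "right"] * cfg.trials_per_state_per_class
        rng.shuffle(block)
        for mi in block:
            add(state, mi, stage=2)
    return epochs, TrialTable(pd.DataFrame(rows))


def simulate_cohort(cfg: SyntheticConfig) -> tuple[list[Epoch], TrialTable]:
    """All subjects' trials plus the combined trial table."""
    all_epochs: list[Epoch] = []
    tables = []
    for i in range(cfg.n_subjects):
        epochs, table = simulate_subject(cfg, i)
        all_epochs.extend(epochs)
        tables.append(table.frame)
    return all_epochs, TrialTable(pd.concat(tables, ignore_index=True))


def subject_windows(
    cfg: SyntheticConfig,
    subject_index: int,
    window_len: int = 3000,
    step: int = 100,
) -> tuple[WindowSet, WindowSet]:
    """Convenience: one subject's (stage2, stage1) window sets."""
    epochs, _ = simulate_subject(cfg, subject_index)
    s1 = [e for e in epochs if e.stage == 1]
    s2 = [e for e in epochs if e.stage == 2]
    return (
        segment_epochs(s2, window_len=window_len, step=step),
        segment_epochs(s1, window_len=window_len, step=step),
    )


@dataclass
class ProtocolLog:
    """Feedback outcomes per trial and Likert ratings per block."""

    trials: pd.DataFrame  # subject, condition, intended_direction, feedback_outcome
    blocks: pd.DataFrame  # subject, condition, likert_rating


def simulate_protocol(cfg: SyntheticConfig) -> ProtocolLog:
    """Simulate the feedback protocol and subjective ratings.

    Feedback outcomes are Bernoulli draws at the condition's success rate;
    each subject rates each condition block once on a 7-point Likert scale
    (normal draw, rounded and clipped to 1..7).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 987654321]))
    trial_rows = []
    block_rows = []
    n_trials = 2 * cfg.trials_per_state_per_class
    for i in range(cfg.n_subjects):
        subject_id = f"S{i + 1:02d}"
        for s, state in enumerate(STATES):
            outcomes = rng.random(n_trials) < cfg.success_rates[s]
            directions = rng.choice(["left", "right"], size=n_trials)
            for d, ok in zip(directions, outcomes):
                trial_rows.append(
                    {
                        "subject": subject_id,
                        "condition": state,
                        "intended_direction": d,
                        "feedback_outcome": "success" if ok else "failure",
                    }
                )
            rating = int(np.clip(np.round(
                rng.normal(cfg.likert_means[s], cfg.likert_sds[s])), 1, 7))
            block_rows.append(
                {"subject": subject_id, "condition": state, "likert_rating": rating}
            )
    return ProtocolLog(pd.DataFrame(trial_rows), pd.DataFrame(block_rows))
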