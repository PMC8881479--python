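"""Synthetic 60-channel evoked / resting EEG cohorts.

The generator emulates the statistical structure the classifier relies on,
so the whole pipeline is testable without clinical recordings:

* low-awareness states (NREM sleep, propofol, xenon, UWS) respond to the
  pulse with a single high-amplitude slow (1-4 Hz) damped transient confined
  to the first 300 ms;
* high-awareness states (wakefulness, REM, ketamine, MCS) show a sustained
  low-amplitude 8-40 Hz oscillation persisting past 300 ms;
* a second, independent time-frequency signature separates high from low
  arousal, so the same trials support both component classifiers;
* the class effect is parietal-dominant (``parietal_gain``), mirroring the
  posterior hot zone;
* every channel carries 1/f Gaussian background noise, and every participant
  carries a random amplitude/latency offset.

Effect amplitudes are in microvolts at ``effect_size = 1``; the defaults are
the cohort used throughout the package's recovery analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet, META_COLUMNS
from .labels import HIGH, domain_for_state, label_for_state
from .montage import DEFAULT_60, REGIONS


@dataclass
class SimConfig:
    """Cohort design and signal parameters for :func:`generate_cohort`."""

    n_participants_per_domain: int = 6
    trials_per_session: int = 40
    states: tuple[str, ...] = ("nrem", "rem", "wake")
    modality: str = "tms"               # "tms" (evoked) or "resting"
    srate_hz: float = 1450.0
    effect_size: float = 3.0            # >= 0; scales every class kernel
    parietal_gain: float = 4.0          # >= 1; spatial localization of the effect
    noise_exponent: float = 1.0         # 1/f^a background slope
    noise_rms_uv: float = 9.0           # per-channel background RMS, microvolts
    participant_sd: float = 0.3         # lognormal amplitude SD between participants
    participant_latency_sd_ms: float = 15.0
    trial_amp_sd: float = 0.6           # lognormal amplitude SD between trials
    trial_latency_sd_ms: float = 20.0   # per-trial latency jitter
    seed: int = 0
    channels: tuple[str, ...] = field(default=DEFAULT_60)

    @property
    def epoch_window_ms(self) -> tuple[float, float]:
        return (-400.0, 1000.0) if self.modality == "tms" else (0.0, 1000.0)

    def validate(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.parietal_gain < 1:
            raise ValueError("parietal_gain must be >= 1")
        if self.srate_hz <= 90:
            raise ValueError("srate_hz must exceed 90 Hz (Nyquist above the 45 Hz band edge)")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if self.modality not in ("tms", "resting"):
            raise ValueError(f"modality must be 'tms' or 'resting', got {self.modality!r}")
        for s in self.states:
            label_for_state(s)  # raises naming an unknown code


def _gabor(t: np.ndarray, freq: float, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2) * np.cos(2 * np.pi * freq * (t - center))


def _evoked_kernel(t: np.ndarray, aro: str, awa: str) -> np.ndarray:
    """State kernel on the post-pulse time axis ``t`` (seconds), unit effect."""
    k = np.zeros_like(t)
    post = t >= 0
    if awa == HIGH:
        # sustained low-amplitude fast activity persisting past 300 ms
        k += 1.5 * _gabor(t, 10.0, 0.25, 0.12) + 1.2 * _gabor(t, 25.0, 0.30, 0.12)
    else:
        # single high-amplitude slow transient confined to 0-300 ms
        conf = post & (t <= 0.3)
        env = np.zeros_like(t)
        env[conf] = 0.5 * (1 - np.cos(2 * np.pi * t[conf] / 0.3)) * np.exp(-t[conf] / 0.12)
        k += 7.0 * env * np.cos(2 * np.pi * 2.5 * t)
    if aro == HIGH:
        k += 1.25 * _gabor(t, 18.0, 0.33, 0.06)
    else:
        k += 2.0 * _gabor(t, 5.0, 0.30, 0.09)
    return np.where(t >= -1e-12, k, 0.0)


def _resting_kernel(t: np.ndarray, aro: str, awa: str, rng: np.random.Generator) -> np.ndarray:
    """Stationary oscillatory mixture with state-dependent spectral content."""
    ph = rng.uniform(0, 2 * np.pi, size=4)
    if awa == HIGH:
        k = 1.2 * np.cos(2 * np.pi * 10.0 * t + ph[0]) + 1.0 * np.cos(2 * np.pi * 25.0 * t + ph[1])
    else:
        k = 2.5 * np.cos(2 * np.pi * 2.5 * t + ph[0])
    if aro == HIGH:
        k = k + 0.8 * np.cos(2 * np.pi * 18.0 * t + ph[2])
    else:
        k = k + 1.5 * np.cos(2 * np.pi * 5.0 * t + ph[3])
    return k


def _one_over_f(rng: np.random.Generator, n_ch: int, n_sm: int,
                exponent: float, rms: float, srate: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_sm, d=1.0 / srate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_sm, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def generate_cohort(config: SimConfig) -> EpochSet:
    """Simulate a labeled cohort; bit-reproducible for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    lo_ms, hi_ms = config.epoch_window_ms
    n_sm = int(round((hi_ms - lo_ms) / 1000.0 * config.srate_hz))
    times_ms = lo_ms + np.arange(n_sm) / config.srate_hz * 1000.0
    t = times_ms / 1000.0

    channels = list(config.channels)
    n_ch = len(channels)
    parietal = set(REGIONS["parietal"])
    weights = np.array([config.parietal_gain if c in parietal else 1.0 for c in channels])

    domains = sorted({domain_for_state(s) for s in config.states})
    participants = {
        d: [f"{d}{i + 1:02d}" for i in range(config.n_participants_per_domain)] for d in domains
    }

    rows: list[dict] = []
    chunks: list[np.ndarray] = []
    for domain in domains:
        dom_states = [s for s in config.states if domain_for_state(s) == domain]
        for pid in participants[domain]:
            amp = float(np.exp(rng.normal(0.0, config.participant_sd)))
            lat = float(rng.normal(0.0, config.participant_latency_sd_ms)) / 1000.0
            for state in dom_states:
                lab = label_for_state(state)
                block = np.empty((config.trials_per_session, n_ch, n_sm), dtype=np.float32)
                for i in range(config.trials_per_session):
                    trial_amp = float(np.exp(rng.normal(0.0, config.trial_amp_sd)))
                    if config.modality == "tms":
                        jit = float(rng.normal(0.0, config.trial_latency_sd_ms)) / 1000.0
                        kern = _evoked_kernel(t - lat - jit, lab.arousal, lab.awareness)
                    else:
                        kern = _resting_kernel(t, lab.arousal, lab.awareness, rng)
                    sig = (config.effect_size * amp * trial_amp) * np.outer(weights, kern)
                    sig += _one_over_f(rng, n_ch, n_sm, config.noise_exponent,
                                       config.noise_rms_uv, config.srate_hz)
                    block[i] = sig
                    rows.append({
                        "participant_id": pid,
                        "session_id": state,
                        "domain": domain,
                        "state": state,
                        "modality": config.modality,
                    })
                chunks.append(block)

    if not rows:
        raise ValueError("configuration produced zero trials")
    meta = pd.DataFrame(rows, columns=list(META_COLUMNS))
    return EpochSet(
        data=np.concatenate(chunks, axis=0),
        srate_hz=config.srate_hz,
        channel_labels=channels,
        times_ms=times_ms,
        trial_meta=meta,
    )


def inject_outliers(epochs: EpochSet, trial_indices, amplitude_uv: float = 150.0,
                    width_ms: float = 0.0) -> EpochSet:
    """Return a copy with an artifact added to the given trials.

    ``width_ms = 0`` adds a single-sample spike (exercises the amplitude
    threshold directly); a positive width adds a raised-cosine bump of that
    duration, which survives band-pass filtering and decimation and therefore
    exercises the rejection stage of the full preprocessing chain.  The
    generator itself simulates no artifacts.
    """
    data = epochs.data.copy()
    n_sm = data.shape[2]
    mid = n_sm // 2
    if width_ms > 0:
        half = max(1, int(round(width_ms / 2000.0 * epochs.srate_hz)))
        lo, hi = max(0, mid - half), min(n_sm, mid + half)
        bump = amplitude_uv * 0.5 * (1 - np.cos(2 * np.pi * np.arange(hi - lo) / max(hi - lo - 1, 1)))
    for idx in np.atleast_1d(trial_indices):
        if width_ms > 0:
            data[int(idx), 0, lo:hi] += bump
        else:
            data[int(idx), 0, mid] += amplitude_uv
    out = EpochSet(
        data=data,
        srate_hz=epochs.srate_hz,
        channel_labels=list(epochs.channel_labels),
        times_ms=epochs.times_ms.copy(),
        trial_meta=epochs.trial_meta.copy(),
    )
    return out
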