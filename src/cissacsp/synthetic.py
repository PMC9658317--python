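"""Synthetic two-class motor-imagery EEG with known ground truth.

Each trial is a sum of narrowband "rhythm" sources — white noise shaped by
a Gaussian amplitude mask in the frequency domain, so spectral content is
controlled exactly and there are no filter transients — projected onto
fixed spatial mixing patterns, plus independent 1/f^a background noise per
channel.  The class difference is event-related desynchronization (ERD):
the source amplitude of designated rhythms is multiplied by
``1 - erd_depth`` for class 2 inside a configurable time window, so the
class-2/class-1 band-power ratio inside that window is ``(1-erd_depth)^2``.

The default configuration mirrors the public-dataset recording conditions:
fs = 100 Hz, 3.5 s trials, 140 trials per class (280 total), 17
sensorimotor channels, mu (10 Hz) and beta (20 Hz) rhythms with ERD in
0.5-2.5 s — the window where motor imagery is most discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trial_store import SENSORIMOTOR_17, TrialSet

__all__ = ["Rhythm", "SynthConfig", "GroundTruth", "generate", "default_public_like"]


@dataclass
class Rhythm:
    """One narrowband source: centre/width (Hz), mixing pattern, ERD flag.

    ``pattern`` is the forward-model channel vector; when None a unit-norm
    vector is drawn (deterministically from the config seed).  ``erd=True``
    marks the rhythm as class-modulated: its class-2 envelope is attenuated
    inside the ERD window.
    """

    center_hz: float
    bandwidth_hz: float = 2.0
    pattern: np.ndarray | None = None
    erd: bool = True


@dataclass
class SynthConfig:
    n_trials_per_class: int = 140
    n_channels: int = 17
    fs: float = 100.0
    trial_length: float = 3.5
    rhythms: list[Rhythm] = field(
        default_factory=lambda: [Rhythm(10.0, 2.0), Rhythm(20.0, 2.0)]
    )
    erd_depth: float = 0.7
    erd_window: tuple[float, float] = (0.5, 2.5)
    noise_exponent: float = 1.0
    snr: float = 1.0
    seed: int = 7

    def validate(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if not 0 <= self.erd_depth < 1:
            raise ValueError(f"erd_depth must lie in [0, 1), got {self.erd_depth}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.fs <= 0 or self.trial_length <= 0 or self.n_channels < 1:
            raise ValueError("fs, trial_length and n_channels must be positive")
        for r in self.rhythms:
            if not 0 < r.center_hz < self.fs / 2:
                raise ValueError(
                    f"rhythm centre {r.center_hz} Hz must lie below fs/2 = {self.fs / 2}"
                )


@dataclass
class GroundTruth:
    """What the generator actually realized, for oracle-based testing."""

    patterns: list[np.ndarray]  # one channel vector per rhythm
    envelopes: dict[int, list[np.ndarray]]  # class -> per-rhythm envelope
    source_band_powers: np.ndarray  # (n_trials, n_rhythms) whole-trial variance
    erd_window_powers: np.ndarray  # (n_trials, n_rhythms) variance inside the ERD window
    noise_scale: float


def default_public_like() -> SynthConfig:
    """Conditions matching the public recording: 100 Hz, 3.5 s, 140/class, 17 ch."""
    return SynthConfig()


def _narrowband_source(rng: np.random.Generator, N: int, fs: float,
                       center: float, bandwidth: float) -> np.ndarray:
    """Unit-variance narrowband noise via a frequency-domain Gaussian mask.

    The amplitude mask is exp(-(f-fc)^2 / (2 sigma^2)) with
    sigma = bandwidth/4, which puts >99% of the power inside
    [fc - bandwidth/2, fc + bandwidth/2].
    """
    white = rng.standard_normal(N)
    freqs = np.fft.rfftfreq(N, 1.0 / fs)
    sigma = bandwidth / 4.0
    mask = np.exp(-((freqs - center) ** 2) / (2.0 * sigma**2))
    src = np.fft.irfft(np.fft.rfft(white) * mask, n=N)
    sd = src.std()
    return src / sd if sd > 0 else src


def _pink_noise(rng: np.random.Generator, N: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance noise with amplitude spectrum 1/f^(exponent/2)."""
    white = rng.standard_normal(N)
    freqs = np.fft.rfftfreq(N, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    noise = np.fft.irfft(np.fft.rfft(white) * amp, n=N)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def generate(config: SynthConfig) -> tuple[TrialSet, GroundTruth]:
    """Generate a two-class :class:`TrialSet` plus its ground truth.

    Deterministic given ``config.seed``.  Trials are ordered class 1 first,
    then class 2.  Background-noise amplitude is set so that the
    channel-average noise variance equals the channel-average (class-1)
    rhythm-signal variance divided by ``snr``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    N = int(round(config.trial_length * config.fs))
    C = config.n_channels
    times = np.arange(N) / config.fs

    patterns = []
    for r in config.rhythms:
        if r.pattern is not None:
            p = np.asarray(r.pattern, dtype=np.float64)
            if p.shape != (C,):
                raise ValueError(
                    f"rhythm pattern must have {C} entries, got {p.shape}"
                )
        else:
            p = rng.standard_normal(C)
            p /= np.linalg.norm(p)
        patterns.append(p)

    in_window = (times >= config.erd_window[0]) & (times < config.erd_window[1])
    envelopes: dict[int, list[np.ndarray]] = {1: [], 2: []}
    for r in config.rhythms:
        env1 = np.ones(N)
        env2 = np.ones(N)
        if r.erd:
            env2 = env2.copy()
            env2[in_window] = 1.0 - config.erd_depth
        envelopes[1].append(env1)
        envelopes[2].append(env2)

    # class-1 signal variance averaged over channels, from the analytic
    # forward model (unit-variance sources, unit-norm default patterns)
    sig_var = sum(
        (p @ p) / C * float(np.mean(env**2))
        for p, env in zip(patterns, envelopes[1])
    )
    noise_scale = np.sqrt(sig_var / config.snr)

    n_per = config.n_trials_per_class
    n_total = 2 * n_per
    data = np.empty((n_total, C, N))
    labels = np.concatenate([np.ones(n_per, int), np.full(n_per, 2)])
    source_powers = np.empty((n_total, len(config.rhythms)))
    window_powers = np.empty((n_total, len(config.rhythms)))
    for i, label in enumerate(labels):
        trial = np.zeros((C, N))
        for j, r in enumerate(config.rhythms):
            src = _narrowband_source(rng, N, config.fs, r.center_hz, r.bandwidth_hz)
            modulated = envelopes[int(label)][j] * src
            source_powers[i, j] = modulated.var()
            window_powers[i, j] = modulated[in_window].var()
            trial += np.outer(patterns[j], modulated)
        for ch in range(C):
            trial[ch] += noise_scale * _pink_noise(
                rng, N, config.fs, config.noise_exponent
            )
        data[i] = trial

    if C == len(SENSORIMOTOR_17):
        names = list(SENSORIMOTOR_17)
    else:
        names = [f"ch{i:02d}" for i in range(C)]
    ts = TrialSet(data=data, labels=labels, fs=config.fs, channel_names=names, t0=0.0)
    gt = GroundTruth(
        patterns=patterns,
        envelopes=envelopes,
        source_band_powers=source_powers,
        erd_window_powers=window_powers,
        noise_scale=float(noise_scale),
    )
    return ts, gt
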