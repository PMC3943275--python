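"""Synthetic surrogate surface-EMG signals.

Surface EMG during steady contraction is well approximated, for codec
purposes, by band-limited Gaussian noise: the interference pattern of many
asynchronous motor-unit action potential trains has near-Gaussian amplitude
statistics with power concentrated between roughly 20 and 450 Hz.  Two
activity regimes are generated:

* ``isometric`` — constant-envelope band-passed noise, emulating a held
  contraction at a fixed fraction of maximum voluntary force;
* ``dynamic``  — the same carrier modulated by periodic activation bursts
  with raised-cosine ramps separated by near-silent gaps, emulating cyclic
  exercise such as pedaling, plus a small instrumentation noise floor.

Signals are scaled to a target RMS (as a fraction of 16-bit full scale),
rounded to integers, and returned as :class:`~semgcodec.signal_io.SignalRecord`
at 2 kHz / 16 bits by default.  These surrogates reproduce the spectral
and amplitude structure the codec exploits, not the physiology: there are
no motor-unit firings, no fatigue drift, and no movement artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .signal_io import SignalRecord

__all__ = ["SyntheticConfig", "generate", "generate_bank"]

_FULL_SCALE = 1 << 15   # 16-bit signed full scale


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the surrogate generator.

    ``rms_level`` is the target RMS as a fraction of full scale; the default
    0.1 leaves the Gaussian amplitude peaks (about 4.5 sigma) comfortably
    inside the 16-bit range, matching the gain headroom of real acquisition
    chains.  ``burst_rate_hz`` and ``duty_cycle`` shape the
    activation pattern of the dynamic regime and are ignored for isometric.
    """

    protocol: str = "isometric"
    sample_rate: float = 2000.0
    duration_s: float = 10.0
    rms_level: float = 0.1
    low_hz: float = 20.0
    high_hz: float = 450.0
    burst_rate_hz: float = 1.0
    duty_cycle: float = 0.5
    ramp_s: float = 0.05
    noise_floor: float = 0.01   # off-interval RMS, fraction of full scale
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.protocol not in ("isometric", "dynamic"):
            raise ParameterError("protocol must be 'isometric' or 'dynamic'")
        if not 0 < self.low_hz < self.high_hz < self.sample_rate / 2:
            raise ParameterError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) "
                f"< Nyquist ({self.sample_rate / 2})"
            )
        if not 0 < self.rms_level < 1:
            raise ParameterError("rms_level must be in (0, 1)")
        if not 0 < self.duty_cycle <= 1:
            raise ParameterError("duty_cycle must be in (0, 1]")
        if self.duration_s <= 0 or self.burst_rate_hz <= 0:
            raise ParameterError("duration and burst rate must be positive")
        return self


def _bandpassed_noise(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian carrier (4th-order zero-phase filter)."""
    sos = sps.butter(4, [cfg.low_hz, cfg.high_hz], btype="bandpass",
                     fs=cfg.sample_rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x * x))


def _burst_envelope(n: int, cfg: SyntheticConfig) -> np.ndarray:
    """Periodic on/off gate with raised-cosine ramps, in [0, 1]."""
    t = np.arange(n) / cfg.sample_rate
    period = 1.0 / cfg.burst_rate_hz
    phase = np.mod(t, period)
    on_len = cfg.duty_cycle * period
    ramp = min(cfg.ramp_s, on_len / 2)
    env = np.zeros(n)
    core = (phase >= ramp) & (phase <= on_len - ramp)
    env[core] = 1.0
    rising = phase < ramp
    env[rising] = 0.5 * (1 - np.cos(np.pi * phase[rising] / ramp))
    falling = (phase > on_len - ramp) & (phase < on_len)
    env[falling] = 0.5 * (1 - np.cos(np.pi * (on_len - phase[falling]) / ramp))
    return env


def generate(config: SyntheticConfig | None = None, **overrides) -> SignalRecord:
    """Generate one surrogate S-EMG record; deterministic for a fixed seed."""
    cfg = replace(config or SyntheticConfig(), **overrides).validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate))
    carrier = _bandpassed_noise(n, cfg, rng)
    if cfg.protocol == "isometric":
        x = carrier * cfg.rms_level * _FULL_SCALE
    else:
        env = _burst_envelope(n, cfg)
        floor_carrier = _bandpassed_noise(n, cfg, rng)
        x = (carrier * env * cfg.rms_level
             + floor_carrier * (1 - env) * cfg.noise_floor) * _FULL_SCALE
    x = np.clip(np.round(x), -_FULL_SCALE, _FULL_SCALE - 1)
    return SignalRecord(x.astype(np.int64), cfg.sample_rate, 16)


def generate_bank(n_signals: int, protocol: str = "isometric", seed: int = 0,
                  duration_s: float = 10.0,
                  base_config: SyntheticConfig | None = None) -> list[SignalRecord]:
    """A bank of independent surrogate subjects.

    Per-signal RMS level is jittered by +/-20% around the base level and the
    per-signal seeds are spawned from the master seed, so changing ``seed``
    changes every signal.
    """
    if n_signals < 1:
        raise ParameterError("n_signals must be >= 1")
    base = base_config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    bank = []
    for i in range(n_signals):
        level = base.rms_level * (1 + rng.uniform(-0.2, 0.2))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(base, protocol=protocol, duration_s=duration_s,
                      rms_level=float(level), seed=sub_seed)
        bank.append(generate(cfg))
    return bank
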