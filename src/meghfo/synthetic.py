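"""Synthetic MEG-like signal simulator.

Generates ground-truthed segments and continuous multi-channel recordings that
emulate the statistical structure of a clinical high-frequency-oscillation
(HFO) gold standard: two balanced classes of fixed-length single-channel
windows (default 2000 samples at 2400 Hz), where the positive class contains a
transient oscillatory burst inside the 80-500 Hz band riding on 1/f-plus-white
background noise, and the negative (normal control, NC) class is background
only.

Amplitude convention: the background is calibrated so that its 80-500 Hz
band-limited RMS is 1.0 in expectation; an event's ``amplitude`` is the RMS
of the burst over its own duration expressed in units of background in-band
RMS — i.e. a dimensionless SNR on the usual RMS-ratio scale. ``amplitude=3``
means the oscillation runs at three times the background level while it
lasts.

This is a statistical emulator, not a biophysical one: no dipole forward
model, sensor geometry or physiological artifacts (eye blink, cardiac).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import HFO, NC, Segment, SegmentDataset

#: The HFO frequency band (Hz) the simulator and the pipeline agree on.
HFO_BAND = (80.0, 500.0)

_ENVELOPES = ("gaussian", "hann")


@dataclass
class HFOEventParams:
    """Morphology of one oscillatory burst.

    center_freq : Hz, must lie inside the 80-500 Hz HFO band.
    duration    : s; ``duration * center_freq >= 4`` so the event contains at
                  least four cycles and is a genuine oscillation rather than a
                  transient.
    amplitude   : burst RMS (over its duration) in units of background
                  in-band RMS (dimensionless SNR scale).
    envelope    : "gaussian" (sigma = duration/6) or "hann".
    onset       : s, used only when placing events into recordings.
    """

    center_freq: float = 150.0
    duration: float = 0.08
    amplitude: float = 3.0
    envelope: str = "gaussian"
    onset: float = 0.0

    def __post_init__(self) -> None:
        if not (HFO_BAND[0] <= self.center_freq <= HFO_BAND[1]):
            raise ValueError(
                f"center_freq {self.center_freq} Hz outside HFO band {HFO_BAND}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.duration * self.center_freq < 4:
            raise ValueError(
                "duration * center_freq must be >= 4 (at least four cycles)"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.envelope not in _ENVELOPES:
            raise ValueError(f"envelope must be one of {_ENVELOPES}")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")


@dataclass
class BackgroundParams:
    """Background noise model: 1/f^alpha component plus white noise.

    ``pink_sd`` and ``white_sd`` set the relative weight of the two
    components; when ``normalize`` is true the mixture is rescaled by a
    deterministic factor so the expected 80-500 Hz band RMS equals 1.0,
    which defines the SNR scale used by :class:`HFOEventParams.amplitude`.
    """

    pink_exponent: float = 1.0
    pink_sd: float = 1.0
    white_sd: float = 0.5
    seed: int = 0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.pink_exponent < 0:
            raise ValueError("pink_exponent must be >= 0")
        if self.pink_sd < 0 or self.white_sd < 0:
            raise ValueError("component amplitudes must be >= 0")


@dataclass
class ParamJitter:
    """Per-segment multiplicative jitter ranges for dataset generation.

    Each burst in a simulated dataset draws its frequency, duration and
    amplitude uniformly from ``base * [1 - frac, 1 + frac]`` (frequency
    clipped back into the HFO band)."""

    freq_frac: float = 0.2
    duration_frac: float = 0.2
    amplitude_frac: float = 0.2


@dataclass
class Recording:
    """Continuous multi-channel recording with its ground-truth event list."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    event_truth: list[tuple[str, float, HFOEventParams]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 2 * HFO_BAND[1]:
            raise ValueError(
                f"fs={self.fs} Hz cannot represent the {HFO_BAND[1]} Hz band edge"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def simulate_hfo_burst(
    params: HFOEventParams, fs: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Envelope-windowed sinusoid at ``center_freq`` with random phase.

    Returns ``round(duration * fs)`` samples, scaled so the burst's RMS over
    its duration equals ``params.amplitude`` (the RMS-ratio SNR convention of
    this simulator). The phase is the only random quantity; identical seeds
    give bit-identical waveforms.
    """
    if fs <= 2 * params.center_freq:
        raise ValueError(
            f"fs={fs} Hz violates Nyquist for a {params.center_freq} Hz burst"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    if params.envelope == "gaussian":
        sigma = params.duration / 6.0
        env = np.exp(-0.5 * ((t - params.duration / 2.0) / sigma) ** 2)
    else:  # hann
        env = np.hanning(n)
    # unit-envelope burst RMS (cos^2 averages to 1/2 over >= 4 cycles)
    unit_rms = np.sqrt(np.mean(env**2) / 2.0)
    return (params.amplitude / unit_rms) * env * np.cos(
        2.0 * np.pi * params.center_freq * t + phase
    )


def _band_calibration_scale(
    n_samples: int, fs: float, params: BackgroundParams
) -> float:
    """Deterministic factor making the expected 80-500 Hz band RMS equal 1.

    Computed analytically from the prescribed amplitude spectrum of the pink
    component plus the flat white spectrum (not per-realization, so segment
    energies keep their natural variability)."""
    lo, hi = HFO_BAND[0], min(HFO_BAND[1], fs / 2.0)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    # synthesis is x_t = sum_k C_k e^{2 pi i k t / n} with E|C_k|^2 = amp_k^2,
    # so per-sample variance = sum_k w_k amp_k^2, w_k = 1 for DC/Nyquist else 2.
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    band = (freqs >= lo) & (freqs <= hi)
    pink_band_var = 0.0
    if params.pink_sd > 0:
        amp = np.zeros(freqs.size)
        amp[1:] = freqs[1:] ** (-params.pink_exponent / 2.0)
        amp *= params.pink_sd
        pink_band_var = float(np.sum(w[band] * amp[band] ** 2))
    white_band_var = params.white_sd**2 * max(hi - lo, 0.0) / (fs / 2.0)
    total = pink_band_var + white_band_var
    return 1.0 / np.sqrt(total) if total > 0 else 1.0


def _background(
    n_samples: int, fs: float, params: BackgroundParams, rng: np.random.Generator
) -> np.ndarray:
    x = np.zeros(n_samples)
    if params.pink_sd > 0:
        freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
        amp = np.zeros(freqs.size)
        amp[1:] = freqs[1:] ** (-params.pink_exponent / 2.0)
        amp *= params.pink_sd
        # complex gaussian coefficients with E|C_k|^2 = amp_k^2
        coeffs = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
        coeffs *= amp / np.sqrt(2.0)
        coeffs[0] = 0.0
        if n_samples % 2 == 0:
            coeffs[-1] = coeffs[-1].real * np.sqrt(2.0)
        x = x + np.fft.irfft(coeffs, n_samples) * n_samples
    if params.white_sd > 0:
        x = x + rng.normal(0.0, params.white_sd, n_samples)
    if params.normalize and (params.pink_sd > 0 or params.white_sd > 0):
        x = x * _band_calibration_scale(n_samples, fs, params)
    return x


def simulate_background(
    n_samples: int, fs: float, params: BackgroundParams | None = None
) -> np.ndarray:
    """1/f^alpha + white background noise of length ``n_samples``."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    params = params or BackgroundParams()
    return _background(n_samples, fs, params, np.random.default_rng(params.seed))


# ---------------------------------------------------------------------------
# segments and datasets
# ---------------------------------------------------------------------------

def simulate_segment(
    kind: int | str,
    hfo: HFOEventParams | None = None,
    bg: BackgroundParams | None = None,
    T: int = 2000,
    fs: float = 2400.0,
    seed: int = 0,
) -> Segment:
    """One labeled segment: background only (NC) or background + burst (HFO).

    The background and the event placement use independent substreams derived
    from ``seed``, so an HFO segment with ``amplitude=0`` is sample-identical
    to the NC segment generated from the same seed.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    kind = {"HFO": HFO, "NC": NC}.get(kind, kind)
    if kind not in (HFO, NC):
        raise ValueError("kind must be HFO or NC")
    hfo = hfo or HFOEventParams()
    bg = bg or BackgroundParams()
    bg_rng = np.random.default_rng([int(seed), 0])
    ev_rng = np.random.default_rng([int(seed), 1])
    x = _background(T, fs, bg, bg_rng)
    if kind == HFO:
        burst = simulate_hfo_burst(hfo, fs, ev_rng)
        if burst.size > T:
            raise ValueError(
                f"burst of {burst.size} samples does not fit a {T}-sample segment"
            )
        start = int(ev_rng.integers(0, T - burst.size + 1))
        x[start : start + burst.size] += burst
    return Segment(x, kind, fs, source="synthetic")


def simulate_dataset(
    n_hfo: int,
    n_nc: int,
    hfo: HFOEventParams | None = None,
    bg: BackgroundParams | None = None,
    T: int = 2000,
    fs: float = 2400.0,
    seed: int = 0,
    jitter: ParamJitter | None = None,
) -> SegmentDataset:
    """Balanced (or arbitrary-count) labeled dataset of simulated segments.

    Burst parameters are re-drawn per HFO segment within the multiplicative
    jitter ranges of ``jitter`` (default +/-20%), emulating the event-to-event
    variability of an expert-marked gold standard.
    """
    if n_hfo < 0 or n_nc < 0:
        raise ValueError("segment counts must be non-negative")
    hfo = hfo or HFOEventParams()
    bg = bg or BackgroundParams()
    jit = jitter or ParamJitter()
    master = np.random.default_rng(seed)
    segs: list[Segment] = []

    def _u(frac: float) -> float:
        return float(master.uniform(1.0 - frac, 1.0 + frac)) if frac > 0 else 1.0

    for _ in range(n_hfo):
        cf = float(np.clip(hfo.center_freq * _u(jit.freq_frac), *HFO_BAND))
        dur = hfo.duration * _u(jit.duration_frac)
        dur = max(dur, 4.0 / cf)  # keep the four-cycle invariant
        amp = hfo.amplitude * _u(jit.amplitude_frac)
        p = replace(hfo, center_freq=cf, duration=dur, amplitude=amp)
        segs.append(
            simulate_segment(HFO, p, bg, T, fs, int(master.integers(0, 2**31 - 1)))
        )
    for _ in range(n_nc):
        segs.append(
            simulate_segment(NC, hfo, bg, T, fs, int(master.integers(0, 2**31 - 1)))
        )
    if not segs:
        return SegmentDataset(np.empty((0, T)), np.empty(0, dtype=int), fs)
    return SegmentDataset.from_segments(segs, fs)


# ---------------------------------------------------------------------------
# continuous recordings
# ---------------------------------------------------------------------------

def simulate_recording(
    duration: float,
    events: Sequence[tuple] = (),
    bg: BackgroundParams | None = None,
    fs: float = 2400.0,
    n_channels: int = 1,
    seed: int = 0,
) -> Recording:
    """Continuous multi-channel background with bursts at stated onsets.

    ``events`` entries are ``(onset_s, HFOEventParams)`` (placed on channel 0)
    or ``(channel, onset_s, HFOEventParams)``. Overlapping events sum
    linearly. The ground-truth list is stored on the returned recording.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    bg = bg or BackgroundParams()
    n = int(round(duration * fs))
    names = [f"ch{i:03d}" for i in range(n_channels)]
    rng = np.random.default_rng(seed)
    data = np.stack([_background(n, fs, bg, np.random.default_rng(s)) for s in
                     rng.integers(0, 2**31 - 1, size=n_channels)])
    truth: list[tuple[str, float, HFOEventParams]] = []
    for ev in events:
        if len(ev) == 2:
            ch, onset, params = 0, ev[0], ev[1]
        else:
            ch, onset, params = ev
        ch_idx = names.index(ch) if isinstance(ch, str) else int(ch)
        if onset < 0 or onset + params.duration > duration:
            raise ValueError(
                f"event at {onset}s (+{params.duration}s) exceeds the "
                f"{duration}s recording"
            )
        burst = simulate_hfo_burst(
            params, fs, int(rng.integers(0, 2**31 - 1))
        )
        start = int(round(onset * fs))
        stop = min(start + burst.size, n)
        data[ch_idx, start:stop] += burst[: stop - start]
        truth.append((names[ch_idx], float(onset), replace(params, onset=float(onset))))
    return Recording(data, fs, names, truth)
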