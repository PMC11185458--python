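"""Synthetic multichannel EEG: 1/f background noise plus event-locked kernels.

The chunk-rate spectral peak is induced structurally — by a gain applied to
the kernel of each chunk's first syllable — rather than by injecting a
sinusoid at the analysis frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft

__all__ = [
    "NadEffect",
    "SynthParams",
    "Recording",
    "grid_adjacency",
    "one_over_f_noise",
    "render_recording",
]


@dataclass(frozen=True)
class NadEffect:
    """Additive deflection (uV, kernel-shaped) at second-dependency onsets."""

    amp_match: float
    amp_violation: float


def _default_nad_effect() -> dict[str, NadEffect]:
    # Amplitude difference present within chunks only, absent across chunks.
    return {
        "within": NadEffect(amp_match=2.0, amp_violation=0.0),
        "across": NadEffect(amp_match=1.0, amp_violation=1.0),
    }


@dataclass
class SynthParams:
    """Parameters of the synthetic EEG generator.

    Defaults are calibrated so that, at the default design scale (72 learning
    epochs per condition, 36 test trials per cell, 31 subjects), the chunk- and
    syllable-rate peaks and the within-condition ERP difference are reliably
    detectable while the across-condition difference is null.
    """

    srate: float = 500.0
    n_channels: int = 32
    kernel_dur_s: float = 0.2
    kernel_amp: float = 1.0
    chunk_initial_gain: float = 2.0
    nad_effect: dict[str, NadEffect] = field(default_factory=_default_nad_effect)
    noise_alpha: float = 1.0
    noise_sd: float = 2.0
    topography: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.chunk_initial_gain < 1:
            raise ValueError("chunk_initial_gain must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_alpha < 0:
            raise ValueError("noise_alpha must be >= 0")

    def channel_weights(self) -> np.ndarray:
        if self.topography is None:
            return np.ones(self.n_channels)
        w = np.asarray(self.topography, dtype=float)
        if w.shape != (self.n_channels,):
            raise ValueError("topography must have one weight per channel")
        return w


def grid_adjacency(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Labels and rook (4-neighbour) adjacency for channels on a near-square grid.

    Returns ``(labels, adjacency)`` where adjacency is a symmetric, irreflexive
    boolean matrix. Prime channel counts degenerate to a 1xN chain.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rows = int(np.sqrt(n_channels))
    while rows > 1 and n_channels % rows != 0:
        rows -= 1
    cols = n_channels // rows
    labels = [f"E{i + 1:02d}" for i in range(n_channels)]
    adj = np.zeros((n_channels, n_channels), dtype=bool)
    for i in range(n_channels):
        r, c = divmod(i, cols)
        for dr, dc in ((0, 1), (1, 0)):
            rr, cc = r + dr, c + dc
            if rr < rows and cc < cols:
                j = rr * cols + cc
                adj[i, j] = adj[j, i] = True
    return labels, adj


@dataclass
class Recording:
    """Multichannel time series (uV) with rate, labels and channel adjacency."""

    data: np.ndarray  # channels x samples
    srate: float
    channel_labels: list[str]
    adjacency: np.ndarray  # boolean channels x channels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (self.data.shape[0],) * 2:
            raise ValueError("adjacency shape must match channel count")
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj)):
            raise ValueError("adjacency must be symmetric and irreflexive")
        self.adjacency = adj

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate


def one_over_f_noise(
    params: SynthParams,
    n_samples: int,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Per-channel-independent noise with amplitude spectrum ~ f^(-alpha/2).

    Each channel is rescaled to sample standard deviation ``noise_sd``.
    Returns a ``(n_channels, n_samples)`` array.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if params.noise_alpha < 0:
        raise ValueError("noise_alpha must be >= 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    white = rng.standard_normal((params.n_channels, n_samples))
    if params.noise_sd == 0:
        return np.zeros((params.n_channels, n_samples))
    if params.noise_alpha == 0:
        x = white
    else:
        # pad to a fast transform length; the tail is discarded
        n_fft = scipy.fft.next_fast_len(n_samples)
        if n_fft > n_samples:
            white = np.concatenate(
                [white, rng.standard_normal((params.n_channels, n_fft - n_samples))],
                axis=-1,
            )
        spec = scipy.fft.rfft(white, axis=-1)
        freqs = scipy.fft.rfftfreq(n_fft, d=1.0 / params.srate)
        shape = np.zeros_like(freqs)
        shape[1:] = freqs[1:] ** (-params.noise_alpha / 2.0)
        x = scipy.fft.irfft(spec * shape, n=n_fft, axis=-1)[:, :n_samples]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x * (params.noise_sd / sd)


def _kernel(params: SynthParams) -> np.ndarray:
    """Raised-cosine (Hann) bump of ``kernel_dur_s`` with unit peak."""
    n = max(int(round(params.kernel_dur_s * params.srate)), 1)
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n))


def render_recording(
    events: pd.DataFrame,
    params: SynthParams,
    duration_s: float | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> Recording:
    """Render an event table into a synthetic multichannel recording.

    The signal is a superposition of (a) the syllable kernel at every onset,
    scaled by ``chunk_initial_gain`` at position-1 syllables, (b) the
    condition-dependent dependency deflection at ``dep_second`` /
    ``dep_second_violation`` onsets, and (c) 1/f noise; all channels share the
    signal via the topography weights.
    """
    if len(events) == 0:
        raise ValueError("events table is empty")
    kernel = _kernel(params) * params.kernel_amp
    unit = _kernel(params)
    last_off = float(events["onset_s"].max()) + params.kernel_dur_s
    if duration_s is None:
        duration_s = last_off + 0.5
    elif last_off > duration_s + 1e-9:
        raise ValueError(
            f"events (ending {last_off:.3f}s) overrun requested duration {duration_s:.3f}s"
        )
    n_samples = int(round(duration_s * params.srate))

    signal = np.zeros(n_samples)
    onsets = np.round(events["onset_s"].to_numpy() * params.srate).astype(int)
    positions = events["position"].to_numpy()
    roles = events["role"].to_numpy()
    conditions = events["condition"].to_numpy()
    for onset, pos, role, cond in zip(onsets, positions, roles, conditions):
        stop = min(onset + kernel.size, n_samples)
        seg = slice(onset, stop)
        gain = params.chunk_initial_gain if pos == 1 else 1.0
        signal[seg] += gain * kernel[: stop - onset]
        if role in ("dep_second", "dep_second_violation"):
            eff = params.nad_effect[cond]
            amp = eff.amp_match if role == "dep_second" else eff.amp_violation
            signal[seg] += amp * unit[: stop - onset]

    weights = params.channel_weights()
    data = np.outer(weights, signal)
    if params.noise_sd > 0:
        data = data + one_over_f_noise(params, n_samples, seed=seed)
    labels, adjacency = grid_adjacency(params.n_channels)
    return Recording(data=data, srate=params.srate, channel_labels=labels, adjacency=adjacency)
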