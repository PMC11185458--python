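"""Frequency-tagging statistics: evoked power, normalized power, ITPC.

All statistics operate on per-epoch DFT coefficients taken with a rectangular
window after per-epoch mean removal, so that responses at exact stimulation
rates fall on single frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .agdesign import TimingSpec, chunk_rate, epoch_length
from .erp import EpochSet
from .synth import Recording

__all__ = [
    "SpectralCoefficients",
    "Spectrum",
    "dft_coefficients",
    "evoked_power",
    "normalize_power",
    "normalized_power_spectrum",
    "itpc",
    "neighbor_bins",
    "target_vs_neighbors",
    "epochs_from_stream",
    "compute_spectrum",
]


@dataclass
class SpectralCoefficients:
    """Complex DFT coefficients per trial, channel and frequency."""

    X: np.ndarray  # (n_trials, n_channels, n_freqs), complex
    freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 3:
            raise ValueError("X must be trials x channels x freqs")
        if self.X.shape[2] != self.freqs.size:
            raise ValueError("frequency axis mismatch")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def theta(self) -> np.ndarray:
        """Phase angles; undefined (zero-magnitude) coefficients yield 0."""
        return np.angle(self.X)


@dataclass
class Spectrum:
    """Channel-resolved EP / normalized EP / ITPC on a common frequency grid."""

    freqs: np.ndarray
    ep: np.ndarray  # (n_channels, n_freqs)
    epn: np.ndarray
    itpc: np.ndarray
    target_bins: dict[str, int]

    def channel_average(self, which: str) -> np.ndarray:
        return getattr(self, which).mean(axis=0)


def dft_coefficients(
    epochs: EpochSet,
    fmin: float | None = None,
    fmax: float | None = None,
) -> SpectralCoefficients:
    """Rectangular-window DFT of each epoch, restricted to [fmin, fmax].

    The frequency grid is spaced at ``1 / epoch_length``. Each epoch/channel
    is mean-removed before the transform.
    """
    data = epochs.data
    if data.shape[0] < 1:
        raise ValueError("at least one epoch is required")
    n = data.shape[2]
    data = data - data.mean(axis=2, keepdims=True)
    X = np.fft.rfft(data, axis=2)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.srate)
    mask = np.ones_like(freqs, dtype=bool)
    if fmin is not None:
        mask &= freqs >= fmin - 1e-12
    if fmax is not None:
        mask &= freqs <= fmax + 1e-12
    return SpectralCoefficients(X=X[:, :, mask], freqs=freqs[mask])


def evoked_power(coeffs: SpectralCoefficients, average_channels: bool = False) -> np.ndarray:
    """EP(f) = |sum_n X_n(f)|^2 / N — power of the phase-locked response."""
    if coeffs.n_trials < 1:
        raise ValueError("at least one trial is required")
    ep = np.abs(coeffs.X.sum(axis=0)) ** 2 / coeffs.n_trials
    return ep.mean(axis=0) if average_channels else ep


def _neighbor_mask(freqs: np.ndarray, target_index: int, halfwidth: float) -> np.ndarray:
    mask = np.abs(freqs - freqs[target_index]) < halfwidth
    mask[target_index] = False
    return mask


def normalize_power(
    ep: np.ndarray,
    freqs: np.ndarray,
    f_target: float,
    halfwidth: float = 0.5,
    mode: str = "sum",
) -> np.ndarray | float:
    """Normalized power at the bin nearest ``f_target``.

    The value at the target bin is divided by the sum (``mode='sum'``, the
    primary reading) or the mean (``mode='avg'``) of the neighbouring bins
    within ``halfwidth`` Hz, excluding the target bin itself. A zero
    denominator yields ``+inf``.
    """
    ep = np.asarray(ep, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    target = int(np.argmin(np.abs(freqs - f_target)))
    mask = _neighbor_mask(freqs, target, halfwidth)
    if not mask.any():
        raise ValueError("no neighbour bins within the halfwidth window")
    neigh = ep[..., mask]
    denom = neigh.sum(axis=-1) if mode == "sum" else neigh.mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, ep[..., target] / np.where(denom > 0, denom, 1.0), np.inf)
    return out if out.ndim else float(out)


def normalized_power_spectrum(
    ep: np.ndarray, freqs: np.ndarray, halfwidth: float = 0.5, mode: str = "sum"
) -> np.ndarray:
    """Normalized power evaluated at every bin of the grid."""
    out = np.empty_like(np.asarray(ep, dtype=float))
    for i, f in enumerate(freqs):
        mask = _neighbor_mask(freqs, i, halfwidth)
        if not mask.any():
            out[..., i] = np.nan
            continue
        neigh = ep[..., mask]
        denom = neigh.sum(axis=-1) if mode == "sum" else neigh.mean(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[..., i] = np.where(
                denom > 0, ep[..., i] / np.where(denom > 0, denom, 1.0), np.inf
            )
    return out


def itpc(
    coeffs: SpectralCoefficients,
    average_channels: bool = False,
    return_excluded: bool = False,
):
    """ITPC(f) = |sum_n exp(i theta_n)| / N — phase consistency across trials.

    Trials with a zero-magnitude coefficient at a given (channel, frequency)
    have no defined phase; they are excluded from the sum and from N at that
    point, with the exclusion count available via ``return_excluded``.
    """
    if coeffs.n_trials < 1:
        raise ValueError("at least one trial is required")
    mag = np.abs(coeffs.X)
    valid = mag > 0
    unit = np.where(valid, coeffs.X / np.where(valid, mag, 1.0), 0.0)
    n_valid = valid.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(unit.sum(axis=0)) / np.maximum(n_valid, 1)
    out = np.where(n_valid > 0, out, 0.0)
    n_excluded = int(coeffs.n_trials * out.size - n_valid.sum())
    if average_channels:
        out = out.mean(axis=0)
    if return_excluded:
        return out, n_excluded
    return out


def neighbor_bins(freqs: np.ndarray, f_target: float, n_each_side: int = 2) -> np.ndarray:
    """Indices of the ``2 * n_each_side`` bins nearest the target, excluding it."""
    target = int(np.argmin(np.abs(freqs - f_target)))
    lo = np.arange(target - n_each_side, target)
    hi = np.arange(target + 1, target + n_each_side + 1)
    idx = np.concatenate([lo, hi])
    if idx.min() < 0 or idx.max() >= freqs.size:
        raise ValueError("target too close to the edge of the frequency grid")
    return idx


def target_vs_neighbors(
    target_values: np.ndarray, neighbor_values: np.ndarray
) -> tuple[float, float]:
    """Paired two-sided t test: per-subject target value vs neighbour-bin mean.

    ``target_values``: (n_subjects,); ``neighbor_values``: (n_subjects, k).
    Returns ``(t, p)``.
    """
    target_values = np.asarray(target_values, dtype=float)
    neighbor_values = np.asarray(neighbor_values, dtype=float)
    if target_values.ndim != 1 or target_values.size < 2:
        raise ValueError("at least 2 subjects are required")
    if neighbor_values.shape[0] != target_values.size:
        raise ValueError("subject axes must match")
    diffs = target_values - neighbor_values.mean(axis=1)
    if np.all(diffs == 0):
        return 0.0, 1.0
    res = scipy.stats.ttest_rel(target_values, neighbor_values.mean(axis=1))
    return float(res.statistic), float(res.pvalue)


def epochs_from_stream(
    recording: Recording,
    timing: TimingSpec,
    n_chunks: int = 8,
    n_epochs: int | None = None,
    offset_s: float = 0.0,
) -> EpochSet:
    """Cut a continuous stream recording into consecutive ``n_chunks`` epochs."""
    period = epoch_length(timing, n_chunks)
    n_samp = int(round(period * recording.srate))
    start = int(round(offset_s * recording.srate))
    max_epochs = (recording.n_samples - start) // n_samp
    if n_epochs is None:
        n_epochs = int(max_epochs)
    if n_epochs > max_epochs:
        raise ValueError(f"recording supports only {max_epochs} epochs")
    data = np.stack(
        [
            recording.data[:, start + k * n_samp : start + (k + 1) * n_samp]
            for k in range(n_epochs)
        ]
    )
    # EpochSet counts samples as round((tmax - tmin) * srate) + 1
    return EpochSet(
        data=data,
        srate=recording.srate,
        tmin=0.0,
        tmax=(n_samp - 1) / recording.srate,
    )


def compute_spectrum(
    epochs: EpochSet,
    timing: TimingSpec,
    fmin: float = 0.1,
    fmax: float = 10.0,
    halfwidth: float = 0.5,
    mode: str = "sum",
) -> Spectrum:
    """EP, normalized EP and ITPC per channel, with chunk/syllable target bins."""
    coeffs = dft_coefficients(epochs, fmin=fmin, fmax=fmax)
    ep = evoked_power(coeffs)
    epn = normalized_power_spectrum(ep, coeffs.freqs, halfwidth=halfwidth, mode=mode)
    coh = itpc(coeffs)
    f_chunk = chunk_rate(timing)
    f_syll = timing.chunk_size * f_chunk
    target_bins = {
        "chunk": int(np.argmin(np.abs(coeffs.freqs - f_chunk))),
        "syllable": int(np.argmin(np.abs(coeffs.freqs - f_syll))),
    }
    return Spectrum(freqs=coeffs.freqs, ep=ep, epn=epn, itpc=coh, target_bins=target_bins)
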