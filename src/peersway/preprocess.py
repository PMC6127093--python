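"""Epoch-domain preprocessing: re-referencing, baseline, rejection, interpolation.

The pipeline order is reference → baseline → amplitude rejection →
bad-channel interpolation.  Band-pass filtering and ocular ICA are out of
scope here: inputs are assumed to be already band-limited epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet


def average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous channel mean; idempotent."""
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def baseline_correct(epochs: EpochSet, window=(-200.0, 0.0)) -> EpochSet:
    """Subtract each trial/channel's mean over the baseline window [start, stop)."""
    mask = epochs.time_window_mask(*window)
    if not mask.any():
        raise ValueError(f"baseline window {window} outside the epoch time axis")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def reject_epochs(epochs: EpochSet, threshold: float = 100.0):
    """Flag trials whose absolute amplitude exceeds ``threshold`` µV anywhere.

    Returns ``(keep_mask, pct_rejected)``; trials are not removed (use
    :meth:`EpochSet.select` with the mask).
    """
    exceed = np.abs(epochs.data) > threshold           # trials × ch × samples
    keep = ~exceed.any(axis=(1, 2))
    pct = 100.0 * (1.0 - keep.mean()) if keep.size else 0.0
    return keep, float(pct)


def channel_rejection_rates(epochs: EpochSet, threshold: float = 100.0) -> np.ndarray:
    """Fraction of epochs in which each channel crosses the amplitude threshold."""
    exceed = (np.abs(epochs.data) > threshold).any(axis=2)  # trials × channels
    return exceed.mean(axis=0)


def detect_bad_channels(epochs: EpochSet, threshold: float = 100.0,
                        max_rate: float = 0.25) -> list[int]:
    """Channels that cross the rejection threshold in more than ``max_rate``
    of all epochs, flagged for interpolation."""
    rates = channel_rejection_rates(epochs, threshold)
    return [int(i) for i in np.flatnonzero(rates > max_rate)]


def interpolate_channel(epochs: EpochSet, bad_channel: int,
                        k_neighbors: int = 4) -> EpochSet:
    """Replace one channel by the inverse-distance-weighted mean of its
    ``k_neighbors`` nearest montage neighbors.

    Exact for spatially constant fields (weights sum to 1).  Other channels
    are untouched.
    """
    pos = np.asarray(epochs.ch_pos, dtype=float)
    n_ch = pos.shape[0]
    if n_ch - 1 < k_neighbors:
        raise ValueError(f"need at least {k_neighbors} other channels")
    if not 0 <= bad_channel < n_ch:
        raise ValueError("bad_channel out of range")
    d = np.linalg.norm(pos - pos[bad_channel], axis=1)
    d[bad_channel] = np.inf
    neighbors = np.argsort(d)[:k_neighbors]
    w = 1.0 / d[neighbors]
    w = w / w.sum()
    data = epochs.data.copy()
    data[:, bad_channel, :] = np.tensordot(w, epochs.data[:, neighbors, :], axes=(0, 1))
    return epochs.copy_with(data=data)


@dataclass
class PreprocessReport:
    """What happened in one preprocessing run."""

    n_input_trials: int
    n_kept_trials: int
    pct_rejected: float
    interpolated_channels: list[int]


def preprocess_epochs(epochs: EpochSet, threshold: float = 100.0,
               baseline=(-200.0, 0.0)) -> tuple[EpochSet, PreprocessReport]:
    """Full pipeline: average reference, baseline, rejection, interpolation."""
    out = baseline_correct(average_reference(epochs), baseline)
    keep, pct = reject_epochs(out, threshold)
    bads = detect_bad_channels(out, threshold)
    out = out.select(keep)
    for ch in bads:
        out = interpolate_channel(out, ch)
    report = PreprocessReport(
        n_input_trials=epochs.n_trials,
        n_kept_trials=int(keep.sum()),
        pct_rejected=pct,
        interpolated_channels=bads,
    )
    return out, report
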