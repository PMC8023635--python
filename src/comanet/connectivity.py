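"""Debiased weighted phase lag index (dwPLI) connectivity.

The weighted phase lag index measures phase synchronization from the
imaginary part of the cross-spectrum only, which makes it insensitive to the
instantaneous (zero-lag) correlations produced by volume conduction. The
debiased squared estimator removes the positive small-sample bias of WPLI^2;
as a consequence individual estimates can be slightly negative.

With ``I_k = Im(Z_k)`` over the ``K`` epoch-wise cross-spectral observations
of a channel pair at one frequency bin::

    dwPLI = ((sum I_k)^2 - sum I_k^2) / ((sum |I_k|)^2 - sum I_k^2)

A zero denominator (all imaginary parts zero) defines the estimate as 0.
Per-bin estimates are averaged over the bins inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .preprocess import EpochedRecording
from .spectral import BandDefinition, TOTAL_RANGE

__all__ = [
    "CrossSpectra",
    "ConnectivityMatrix",
    "epoch_cross_spectra",
    "dwpli",
    "median_connectivity",
    "band_connectivity",
]


@dataclass
class CrossSpectra:
    """Epoch-wise cross-spectral observations for all channel pairs.

    ``values`` has shape ``(n_pairs, n_epochs, n_bins)``; pairs enumerate the
    strict upper triangle in lexicographic order ``(0,1), (0,2), ...``.
    """

    values: np.ndarray
    pairs: np.ndarray  # (n_pairs, 2) channel indices, i < j
    channel_labels: list[str]
    band: BandDefinition
    freqs: np.ndarray


@dataclass
class ConnectivityMatrix:
    """Symmetric channel-by-channel dwPLI estimates for one band."""

    values: np.ndarray
    band: BandDefinition
    channel_labels: list[str]
    n_observations: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be square and symmetric")
        if np.any(v > 1 + 1e-9):
            raise ValueError("dwPLI estimates cannot exceed 1")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


def epoch_cross_spectra(ep: EpochedRecording, band: BandDefinition) -> CrossSpectra:
    """Hanning-tapered FFT cross-spectra at the band's frequency bins.

    One observation per epoch per bin: ``Z = X_a * conj(X_b)``.
    """
    if ep.n_epochs < 2:
        raise ValueError("cross-spectra require at least 2 epochs")
    if band.lo < TOTAL_RANGE[0] or band.hi > TOTAL_RANGE[1]:
        raise ValueError(f"band {band.name} outside the analysed range {TOTAL_RANGE}")
    n_samples = ep.epochs.shape[2]
    taper = _sig.windows.hann(n_samples, sym=False)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / ep.sampling_rate)
    mask = band.mask(freqs)
    if mask.sum() == 0:
        raise ValueError(f"no frequency bins inside band {band.name}")
    # X: (n_epochs, n_channels, n_bins)
    X = np.fft.rfft(ep.epochs * taper, axis=2)[:, :, mask]
    ii, jj = np.triu_indices(ep.n_channels, k=1)
    Z = X[:, ii, :] * np.conj(X[:, jj, :])  # (epochs, pairs, bins)
    return CrossSpectra(
        values=np.transpose(Z, (1, 0, 2)),
        pairs=np.column_stack([ii, jj]),
        channel_labels=list(ep.channel_labels),
        band=band,
        freqs=freqs[mask],
    )


def dwpli(cs: CrossSpectra) -> ConnectivityMatrix:
    """Debiased WPLI^2 per pair: debiased per bin, then averaged over bins."""
    K = cs.values.shape[1]
    if K < 2:
        raise ValueError("debiased WPLI requires at least 2 observations")
    imag = cs.values.imag  # (pairs, epochs, bins)
    s = imag.sum(axis=1)
    s2 = (imag**2).sum(axis=1)
    sa = np.abs(imag).sum(axis=1)
    num = s**2 - s2
    den = sa**2 - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(den == 0, 0.0, num / np.where(den == 0, 1.0, den))
    per_pair = est.mean(axis=1)

    n = len(cs.channel_labels)
    mat = np.zeros((n, n))
    mat[cs.pairs[:, 0], cs.pairs[:, 1]] = per_pair
    mat = mat + mat.T
    return ConnectivityMatrix(
        values=mat, band=cs.band, channel_labels=cs.channel_labels,
        n_observations=K,
    )


def median_connectivity(cm: ConnectivityMatrix) -> float:
    """Median dwPLI over the strict upper triangle (each pair counted once)."""
    if cm.n_channels < 2:
        raise ValueError("need at least 2 channels")
    return float(np.median(cm.upper_triangle()))


def band_connectivity(ep: EpochedRecording, band: BandDefinition) -> ConnectivityMatrix:
    """Convenience: cross-spectra then dwPLI for one band."""
    return dwpli(epoch_cross_spectra(ep, band))


def connectivity_to_csv(cm: ConnectivityMatrix, path) -> None:
    """Write the matrix with channel labels as header row and column."""
    import pandas as pd

    pd.DataFrame(cm.values, index=cm.channel_labels,
                 columns=cm.channel_labels).to_csv(path)


def connectivity_to_json(cm: ConnectivityMatrix, path) -> None:
    import json
    from pathlib import Path

    payload = {
        "band": {"name": cm.band.name, "lo": cm.band.lo, "hi": cm.band.hi},
        "channel_labels": cm.channel_labels,
        "n_observations": cm.n_observations,
        "values": cm.values.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def connectivity_from_csv(path, band: BandDefinition,
                          n_observations: int = 0) -> ConnectivityMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(df.to_numpy(), band, list(df.columns),
                              n_observations)
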