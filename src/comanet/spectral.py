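"""Power spectra and relative band power.

Spectra are Welch estimates (2-s Hamming segments, 50% overlap, 0.5 Hz
resolution) averaged within and across 10-s epochs. Relative band power for a
channel is its power integrated over a canonical band divided by power over
the full analysed range 0.5-45 Hz; the delta band is integrated from the
0.5 Hz high-pass edge rather than 0 because bins below the cutoff hold filter
roll-off, not signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import EpochedRecording

__all__ = [
    "BandDefinition",
    "Spectrum",
    "BANDS",
    "compute_psd",
    "relative_band_power",
    "mean_relative_power",
]

TOTAL_RANGE = (0.5, 45.0)


@dataclass(frozen=True)
class BandDefinition:
    """A canonical frequency band.

    The interval is half-open ``[lo, hi)`` unless ``upper_inclusive`` — used
    for the top band (alpha, 8-13 Hz) — so adjacent bands never share a bin.
    """

    name: str
    lo: float
    hi: float
    upper_inclusive: bool = False

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("band requires lo < hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        if self.upper_inclusive:
            return (freqs >= self.lo) & (freqs <= self.hi)
        return (freqs >= self.lo) & (freqs < self.hi)


BANDS = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0, upper_inclusive=True),
}


def bands_from_config(edges: dict[str, tuple[float, float]]) -> dict[str, BandDefinition]:
    """Band definitions with overridden ``{name: (lo, hi)}`` edges; the
    highest band keeps an inclusive upper edge."""
    merged = dict(BANDS)
    for name, (lo, hi) in edges.items():
        inclusive = BANDS[name].upper_inclusive if name in BANDS else False
        merged[name] = BandDefinition(name, float(lo), float(hi),
                                      upper_inclusive=inclusive)
    return merged


@dataclass
class Spectrum:
    """Per-channel power spectral density on a common frequency grid."""

    psd: np.ndarray  # (n_channels, n_freqs), uV^2/Hz
    freqs: np.ndarray  # Hz, strictly increasing
    n_epochs_used: int

    def __post_init__(self):
        self.psd = np.asarray(self.psd, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def compute_psd(ep: EpochedRecording) -> Spectrum:
    """Welch PSD per channel, averaged over epochs.

    2-s segments give 0.5 Hz resolution; the grid is clipped to the analysed
    range 0.5-45 Hz.
    """
    if ep.n_epochs < 1:
        raise ValueError("need at least one epoch")
    fs = ep.sampling_rate
    nperseg = min(2 * fs, ep.epochs.shape[2])
    freqs, psd = signal.welch(
        ep.epochs, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=nperseg // 2, axis=2,
    )
    psd = psd.mean(axis=0)  # average across epochs -> (channels, freqs)
    keep = (freqs >= TOTAL_RANGE[0]) & (freqs <= TOTAL_RANGE[1])
    return Spectrum(psd=psd[:, keep], freqs=freqs[keep], n_epochs_used=ep.n_epochs)


def _band_integral(spec: Spectrum, mask: np.ndarray) -> np.ndarray:
    if mask.sum() < 2:
        raise ValueError("band contains fewer than two frequency bins")
    return np.trapezoid(spec.psd[:, mask], spec.freqs[mask], axis=1)


def relative_band_power(spec: Spectrum, band: BandDefinition) -> np.ndarray:
    """Per-channel power in ``band`` as a fraction of total 0.5-45 Hz power."""
    if band.lo < TOTAL_RANGE[0] or band.hi > TOTAL_RANGE[1]:
        raise ValueError(f"band {band.name} exceeds the analysed range {TOTAL_RANGE}")
    total = _band_integral(spec, np.ones_like(spec.freqs, dtype=bool))
    if np.any(total <= 0):
        bad = np.flatnonzero(total <= 0).tolist()
        raise ValueError(f"zero total power on channel index(es) {bad}")
    return _band_integral(spec, band.mask(spec.freqs)) / total


def mean_relative_power(per_channel: np.ndarray) -> float:
    """Arithmetic mean over channels (the paper-style scalar power feature)."""
    per_channel = np.asarray(per_channel, dtype=float)
    if per_channel.size == 0:
        raise ValueError("no channels")
    return float(per_channel.mean())
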