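"""Synthetic EEG and synthetic cohorts with controlled structure.

The EEG generator places one source at each electrode and superimposes, per
channel: narrowband Gaussian band sources (band-pass filtered white noise,
one independent source per channel and band), an optional phase-lagged
modular coupling structure in chosen bands, a 1/f broadband background, and
zero-lag spatial mixing that emulates volume conduction.

Within a coupled band, each channel's source is::

    sqrt(c) * rotate(driver of its module, rank_in_module * lag_deg)
        + sqrt(1 - c) * independent narrowband noise

where ``rotate`` multiplies the driver's analytic signal by ``exp(-i theta)``
and takes the real part. Rotating each member by a multiple of ``lag_deg``
gives genuinely phase-lagged within-module pairs — the kind of coupling the
weighted phase lag index is designed to detect — while the zero-lag mixing
stage produces exactly the instantaneous correlations it is designed to
ignore.

The cohort generator draws clinical covariates, gives every patient a latent
alpha level, and maps a latent health score (a weighted sum of standardized
GCS and the alpha level plus Gaussian noise) through fixed cutpoints onto the
8-level GOSE outcome. Each patient's EEG is simulated with its alpha band
weight set to ``logistic(alpha level)``, so the EEG-derived mean relative
alpha power carries real prognostic signal with a tunable effect size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.signal import hilbert
from scipy.stats import norm

from .eeg_io import Montage, Recording, load_montage
from .spectral import BANDS

__all__ = [
    "Coupling",
    "EEGSimSpec",
    "CohortSimSpec",
    "simulate_eeg",
    "simulate_cohort",
    "inject_spikes",
    "split_modules",
]


@dataclass(frozen=True)
class Coupling:
    """Phase-lagged modular coupling for one band.

    ``module_assignment`` maps channel label -> module id; ``c`` is the
    fraction of within-module source variance contributed by the shared
    driver; ``lag_deg`` the phase-lag step between module members in degrees.
    """

    module_assignment: dict[str, int]
    c: float = 0.5
    lag_deg: float = 45.0

    def __post_init__(self):
        if not 0 <= self.c <= 1:
            raise ValueError("coupling fraction c must be in [0, 1]")


@dataclass(frozen=True)
class EEGSimSpec:
    """Generative settings for one synthetic resting-state EEG recording.

    Defaults emulate a healthy eyes-closed recording: 5 min (the mean usable
    length in acute clinical recordings is about 5 min), alpha-dominant band
    profile, alpha-band coupling in an anterior/posterior module pair,
    moderate volume-conduction mixing.
    """

    duration_s: float = 300.0
    sampling_rate: int = 256
    montage_ref: str = "ld1020"
    band_profiles: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.15, "theta": 0.10, "alpha": 0.35}
    )
    couplings: dict[str, Coupling] | None = None  # None -> default alpha coupling
    mixing: float = 0.2
    mixing_sigma: float = 0.5  # spatial Gaussian width, head-radius units
    noise_1f_weight: float | None = None  # None -> remainder of band weights
    seed: int = 0

    def __post_init__(self):
        total = sum(self.band_profiles.values())
        if total > 1 + 1e-9:
            raise ValueError("band_profiles weights must sum to <= 1")
        if not 0 <= self.mixing < 1:
            raise ValueError("mixing strength must be in [0, 1)")
        if self.duration_s < 10:
            raise ValueError("need at least one 10-s epoch of data")

    def background_weight(self) -> float:
        if self.noise_1f_weight is not None:
            return self.noise_1f_weight
        return max(0.0, 1.0 - sum(self.band_profiles.values()))


def split_modules(montage: Montage, labels: list[str], n_modules: int = 2) -> dict[str, int]:
    """Assign channels to ``n_modules`` spatial strips along the anterior-
    posterior axis (equal-size quantile split on the y coordinate)."""
    y = montage.positions(labels)[:, 1]
    order = np.argsort(-y)  # front to back
    assignment: dict[str, int] = {}
    sizes = np.full(n_modules, len(labels) // n_modules)
    sizes[: len(labels) % n_modules] += 1
    start = 0
    for m, size in enumerate(sizes):
        for i in order[start : start + size]:
            assignment[labels[i]] = m
        start += size
    return assignment


def _resolve_montage(spec: EEGSimSpec) -> Montage:
    return load_montage(spec.montage_ref)


def _narrowband(rng, shape, lo, hi, fs) -> np.ndarray:
    """Unit-variance band-pass filtered white noise, row-wise."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    return _standardize(x)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink_background(rng, shape, fs) -> np.ndarray:
    """White noise shaped to amplitude slope -1 (flat below 0.5 Hz)."""
    x = rng.standard_normal(shape)
    X = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    X = X / np.maximum(f, 0.5)
    return _standardize(np.fft.irfft(X, n=shape[-1], axis=-1))


def _rotate(analytic: np.ndarray, theta_rad: float) -> np.ndarray:
    return np.real(analytic * np.exp(-1j * theta_rad))


def simulate_eeg(spec: EEGSimSpec, montage: Montage | None = None) -> Recording:
    """Generate one recording; deterministic given ``spec.seed``."""
    montage = montage or _resolve_montage(spec)
    labels = list(montage.labels)
    n = len(labels)
    fs = spec.sampling_rate
    n_samples = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)

    couplings = spec.couplings
    if couplings is None:
        couplings = {"alpha": Coupling(split_modules(montage, labels, 2))}

    x = np.zeros((n, n_samples))
    for band_name in sorted(spec.band_profiles):
        weight = spec.band_profiles[band_name]
        band = BANDS[band_name]
        if weight <= 0:
            continue
        if band_name in couplings:
            src = _coupled_band_sources(
                rng, couplings[band_name], labels, n_samples, band, fs
            )
        else:
            src = _narrowband(rng, (n, n_samples), band.lo, band.hi, fs)
        x += np.sqrt(weight) * src

    bg_weight = spec.background_weight()
    if bg_weight > 0:
        x += np.sqrt(bg_weight) * _pink_background(rng, (n, n_samples), fs)

    x *= 10.0  # ~10 uV RMS, a typical scalp EEG amplitude scale

    if spec.mixing > 0:
        coords = montage.positions(labels)
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        G = np.exp(-d2 / (2 * spec.mixing_sigma**2))
        np.fill_diagonal(G, 0.0)
        G /= G.sum(axis=1, keepdims=True)
        x = (1 - spec.mixing) * x + spec.mixing * (G @ x)

    return Recording(
        signals=x, sampling_rate=fs, channel_labels=labels,
        montage_ref=montage.name,
    )


def _coupled_band_sources(rng, coupling, labels, n_samples, band, fs):
    n = len(labels)
    src = np.empty((n, n_samples))
    modules: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab not in coupling.module_assignment:
            raise ValueError(f"channel {lab!r} missing from module_assignment")
        modules.setdefault(coupling.module_assignment[lab], []).append(i)
    c = coupling.c
    for module_id in sorted(modules):
        members = modules[module_id]
        driver = _narrowband(rng, (n_samples,), band.lo, band.hi, fs)
        analytic = hilbert(driver)
        indep = _narrowband(rng, (len(members), n_samples), band.lo, band.hi, fs)
        for rank, ch in enumerate(members):
            rotated = _standardize(
                _rotate(analytic, np.deg2rad(rank * coupling.lag_deg))
            )
            src[ch] = np.sqrt(c) * rotated + np.sqrt(1 - c) * indep[rank]
    return src


def inject_spikes(
    rec: Recording,
    times_s: list[float],
    amplitude_uV: float = 500.0,
    width_s: float = 0.1,
    channels: list[str] | None = None,
) -> Recording:
    """Add Gaussian-shaped amplitude spikes (for testing artifact rejection)."""
    out = rec.signals.copy()
    t = np.arange(rec.n_samples) / rec.sampling_rate
    rows = (
        range(rec.n_channels)
        if channels is None
        else [rec.channel_labels.index(c) for c in channels]
    )
    for t0 in times_s:
        bump = amplitude_uV * np.exp(-((t - t0) ** 2) / (2 * width_s**2))
        for r in rows:
            out[r] += bump
    return Recording(out, rec.sampling_rate, list(rec.channel_labels), rec.montage_ref)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimSpec:
    """Generative settings for a synthetic patient cohort.

    ``effect_gcs`` and ``effect_alpha`` are standardized slopes of the latent
    outcome on GCS and on the latent alpha level; ``gose_cutpoints`` (7
    strictly increasing thresholds) map the latent score onto GOSE 1-8 and
    default to the octiles of the latent score's marginal distribution.
    """

    n_patients: int = 18
    effect_gcs: float = 0.7
    effect_alpha: float = 0.4
    noise_sd: float = 0.6
    gose_cutpoints: tuple[float, ...] | None = None
    p_male: float = 15 / 18  # the clinical cohort is predominantly male
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients")
        if self.gose_cutpoints is not None:
            cp = np.asarray(self.gose_cutpoints, dtype=float)
            if cp.size != 7 or np.any(np.diff(cp) <= 0):
                raise ValueError("gose_cutpoints must be 7 strictly increasing values")

    def cutpoints(self) -> np.ndarray:
        if self.gose_cutpoints is not None:
            return np.asarray(self.gose_cutpoints, dtype=float)
        sd_h = np.sqrt(self.effect_gcs**2 + self.effect_alpha**2 + self.noise_sd**2)
        return sd_h * norm.ppf(np.arange(1, 8) / 8.0)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def simulate_cohort(
    spec: CohortSimSpec, eeg_template: EEGSimSpec
) -> tuple[pd.DataFrame, list[Recording]]:
    """Draw a cohort table and one paired EEG recording per patient.

    Deterministic given ``spec.seed`` (the template's own seed is replaced by
    per-patient child seeds).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    age = rng.integers(18, 91, size=n)
    sex = np.where(rng.random(n) < spec.p_male, "male", "female")
    ct_grade = rng.integers(1, 7, size=n)
    days = rng.integers(3, 25, size=n)
    gcs = rng.integers(3, 12, size=n)
    alpha_target = rng.standard_normal(n)
    # independent per-patient slow-wave level: delta power varies on its own
    # rather than being the mirror image of alpha
    delta_target = rng.standard_normal(n)

    h = (
        spec.effect_gcs * _zscore(gcs.astype(float))
        + spec.effect_alpha * _zscore(alpha_target)
        + rng.normal(0, spec.noise_sd, size=n)
    )
    cut = spec.cutpoints()
    gose3 = 1 + (h[:, None] > cut[None, :]).sum(axis=1)
    h6 = h + rng.normal(0, 0.3, size=n)
    gose6 = 1 + (h6[:, None] > cut[None, :]).sum(axis=1)

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": pd.Categorical(sex),
            "age_years": age,
            "ct_grade": ct_grade,
            "days_since_injury": days,
            "gcs_total": gcs,
            "gose_3mo": pd.array(gose3, dtype="Int64"),
            "gose_6mo": pd.array(gose6, dtype="Int64"),
            "alpha_target": alpha_target,  # simulation ground truth
            "delta_target": delta_target,
        }
    )

    profiles = dict(eeg_template.band_profiles)
    orig_alpha = profiles.get("alpha", 0.0)
    orig_delta = profiles.get("delta", 0.0)
    # delta's base share of the non-alpha mass, perturbed per patient on the
    # logit scale by the independent slow-wave factor
    base_share = orig_delta / max(1.0 - orig_alpha, 1e-12)
    base_logit = np.log(base_share / (1.0 - base_share)) if 0 < base_share < 1 else 0.0
    recordings = []
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        w_alpha = float(1.0 / (1.0 + np.exp(-alpha_target[i])))
        mass = 1.0 - w_alpha
        share_d = float(1.0 / (1.0 + np.exp(-(base_logit + 0.8 * delta_target[i]))))
        w_delta = mass * share_d
        rest = max(1.0 - orig_alpha - orig_delta, 1e-12)
        new_profiles = {}
        for b, w in profiles.items():
            if b == "alpha":
                new_profiles[b] = w_alpha
            elif b == "delta":
                new_profiles[b] = w_delta
            else:
                new_profiles[b] = w * mass * (1.0 - share_d) / rest
        patient_spec = dataclasses.replace(
            eeg_template, band_profiles=new_profiles, seed=int(child_seeds[i])
        )
        recordings.append(simulate_eeg(patient_spec))
    return table, recordings
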