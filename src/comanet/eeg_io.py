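"""Reading and writing EEG recordings, electrode montages and cohort tables.

Recordings are plain in-memory arrays in microvolts. Clinical EEG arrives as
EDF/EDF+; reading goes through :func:`mne.io.read_raw_edf`, writing through a
minimal 16-bit EDF writer (1-second data records) so that synthetic recordings
can round-trip through the clinical format.

Two analysis montages are provided, both with electrode positions normalized
to unit head radius:

``ld1020``
    the 19 scalp electrodes of the clinical 10/20 system.
``hd91``
    a 91-channel high-density superset: the 86 scalp sites of the extended
    10-10 table plus five 10-5 sites, containing all 19 ``ld1020`` labels.
"""

from __future__ import annotations

import io
import struct
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Montage",
    "read_edf",
    "write_edf",
    "load_montage",
    "subset_channels",
    "read_cohort",
    "write_cohort",
    "table1_cohort",
    "normalize_label",
]

#: Old-nomenclature synonyms mapped onto the modern 10/20 labels.
LABEL_SYNONYMS = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

#: Mastoid/ear electrodes: read, but excluded from analysis montages.
MASTOID_LABELS = ("M1", "M2", "A1", "A2")

LD1020_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

# 10-5 sites appended to the 86 extended-10-10 scalp sites to reach 91.
_HD_EXTRA_LABELS = ["I1", "I2", "AFp9h", "AFp7h", "AFp5h"]


class FormatError(ValueError):
    """Raised for unreadable or structurally unsupported EEG files."""


class ValidationError(ValueError):
    """Raised when a table or recording violates its documented invariants."""


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    signals
        ``(n_channels, n_samples)`` array in microvolts.
    sampling_rate
        Sampling frequency in Hz.
    channel_labels
        One label per signal row; unique.
    montage_ref
        Name of the montage providing scalp coordinates (may be ``None`` for
        ad hoc layouts).
    """

    signals: np.ndarray
    sampling_rate: int
    channel_labels: list[str]
    montage_ref: str | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValidationError("signals must be a 2-D (channels x samples) array")
        if self.signals.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{self.signals.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Montage:
    """Named electrode layout with unit-head-radius scalp coordinates."""

    name: str
    labels: list[str]
    coordinates: np.ndarray  # (n, 3), each row on the unit sphere

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("montage labels must be unique")
        if self.coordinates.shape != (len(self.labels), 3):
            raise ValidationError("coordinates must be (n_labels, 3)")
        norms = np.linalg.norm(self.coordinates, axis=1)
        if np.any((norms < 0.99) | (norms > 1.01)):
            raise ValidationError("electrode coordinates must lie on the unit sphere")

    def positions(self, labels: list[str]) -> np.ndarray:
        """Coordinates for ``labels``, in that order."""
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise KeyError(f"labels not in montage {self.name!r}: {missing}")
        return self.coordinates[[index[l] for l in labels]]


def normalize_label(raw: str) -> str:
    """Normalize a clinical EDF channel label to montage conventions.

    Strips ``EEG`` prefixes and reference suffixes (``Fp1-REF`` -> ``Fp1``),
    matches case-insensitively against standard 10-10 names, and maps the old
    T3/T4/T5/T6 nomenclature to T7/T8/P7/P8.
    """
    label = raw.strip()
    if label.upper().startswith("EEG "):
        label = label[4:]
    label = label.split("-")[0].strip()
    canon = _canonical_label_map().get(label.lower(), label)
    return LABEL_SYNONYMS.get(canon, canon)


_CANONICAL_MAP: dict[str, str] | None = None


def _canonical_label_map() -> dict[str, str]:
    global _CANONICAL_MAP
    if _CANONICAL_MAP is None:
        names = list(_standard_positions().keys())
        names += list(LABEL_SYNONYMS) + list(MASTOID_LABELS)
        _CANONICAL_MAP = {n.lower(): n for n in names}
    return _CANONICAL_MAP


# ---------------------------------------------------------------------------
# Montages
# ---------------------------------------------------------------------------

_STANDARD_POSITIONS: dict[str, np.ndarray] | None = None
_MONTAGE_CACHE: dict[str, Montage] = {}


def _standard_positions() -> dict[str, np.ndarray]:
    """Standard 10-5 electrode positions, radially projected to unit radius."""
    global _STANDARD_POSITIONS
    if _STANDARD_POSITIONS is None:
        import mne

        pos: dict[str, np.ndarray] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for table in ("standard_1005", "standard_1020"):
                ch_pos = mne.channels.make_standard_montage(table).get_positions()[
                    "ch_pos"
                ]
                for name, xyz in ch_pos.items():
                    pos.setdefault(name, np.asarray(xyz))
        _STANDARD_POSITIONS = {
            name: xyz / np.linalg.norm(xyz) for name, xyz in pos.items()
        }
    return _STANDARD_POSITIONS


def _hd91_labels() -> list[str]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        extended = list(
            mne.channels.make_standard_montage("standard_1020").get_positions()[
                "ch_pos"
            ]
        )
    drop = set(LABEL_SYNONYMS) | set(MASTOID_LABELS)
    scalp = [l for l in extended if l not in drop]
    return scalp + _HD_EXTRA_LABELS


def load_montage(name: str) -> Montage:
    """Load one of the analysis montages (``ld1020`` or ``hd91``)."""
    if name in _MONTAGE_CACHE:
        return _MONTAGE_CACHE[name]
    if name == "ld1020":
        labels = list(LD1020_LABELS)
    elif name == "hd91":
        labels = _hd91_labels()
    else:
        raise KeyError(
            f"unknown montage {name!r}; available montages: 'ld1020', 'hd91'"
        )
    pos = _standard_positions()
    coords = np.array([pos[l] for l in labels])
    montage = Montage(name=name, labels=labels, coordinates=coords)
    _MONTAGE_CACHE[name] = montage
    return montage


def write_montage_csv(montage: Montage, path: str | Path) -> None:
    df = pd.DataFrame(montage.coordinates, columns=["x", "y", "z"])
    df.insert(0, "label", montage.labels)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    Channel labels are normalized to montage conventions (case-insensitive,
    old T3/T4/T5/T6 names mapped to T7/T8/P7/P8).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of types for malformed files
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    sfreqs = {int(round(raw.info["sfreq"]))}
    if len(sfreqs) != 1:
        raise FormatError("channels with mismatched sampling rates are unsupported")
    labels = [normalize_label(l) for l in raw.ch_names]
    return Recording(
        signals=raw.get_data() * 1e6,  # volts -> microvolts
        sampling_rate=int(round(raw.info["sfreq"])),
        channel_labels=labels,
    )


def _edf_str(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as a plain 16-bit EDF file with 1-second records.

    The recording length must be a whole number of seconds.
    """
    fs = rec.sampling_rate
    if rec.n_samples % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_records = rec.n_samples // fs
    nch = rec.n_channels

    def _hdr_float(v: float) -> str:
        s = f"{v:.6g}"
        return s if len(s) <= 8 else f"{v:.1e}"

    phys_max = np.maximum(np.max(np.abs(rec.signals), axis=1), 1.0)
    # keep the 8-char header fields exact by rounding the range up
    phys_max = np.array([float(_hdr_float(v)) for v in phys_max * 1.001])
    dig_min, dig_max = -32768, 32767

    buf = io.BytesIO()
    buf.write(_edf_str("0", 8))
    buf.write(_edf_str("X X X X", 80))
    buf.write(_edf_str("Startdate X X X X", 80))
    buf.write(_edf_str("01.01.00", 8))
    buf.write(_edf_str("00.00.00", 8))
    buf.write(_edf_str(256 * (1 + nch), 8))
    buf.write(_edf_str("", 44))
    buf.write(_edf_str(n_records, 8))
    buf.write(_edf_str(1, 8))
    buf.write(_edf_str(nch, 4))
    for label in rec.channel_labels:
        buf.write(_edf_str(label, 16))
    for _ in range(nch):
        buf.write(_edf_str("", 80))
    for _ in range(nch):
        buf.write(_edf_str("uV", 8))
    for v in phys_max:
        buf.write(_edf_str(_hdr_float(-v), 8))
    for v in phys_max:
        buf.write(_edf_str(_hdr_float(v), 8))
    for _ in range(nch):
        buf.write(_edf_str(dig_min, 8))
    for _ in range(nch):
        buf.write(_edf_str(dig_max, 8))
    for _ in range(nch):
        buf.write(_edf_str("", 80))
    for _ in range(nch):
        buf.write(_edf_str(fs, 8))
    for _ in range(nch):
        buf.write(_edf_str("", 32))

    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.round((rec.signals + phys_max[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    for r in range(n_records):
        chunk = digital[:, r * fs : (r + 1) * fs]
        buf.write(chunk.tobytes())

    Path(path).write_bytes(buf.getvalue())


def subset_channels(rec: Recording, labels: list[str]) -> Recording:
    """Return a recording restricted to ``labels``, in the requested order."""
    index = {l: i for i, l in enumerate(rec.channel_labels)}
    missing = [l for l in labels if l not in index]
    if missing:
        raise KeyError(f"channels not present in recording: {missing}")
    rows = [index[l] for l in labels]
    return Recording(
        signals=rec.signals[rows].copy(),
        sampling_rate=rec.sampling_rate,
        channel_labels=list(labels),
        montage_ref=rec.montage_ref,
    )


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id", "sex", "age_years", "ct_grade", "days_since_injury",
    "gcs_total", "gose_3mo", "gose_6mo",
]

_RANGES = {
    "ct_grade": (1, 6),
    "gcs_total": (3, 15),
    "gose_3mo": (1, 8),
    "gose_6mo": (1, 8),
}


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    The table holds one row per patient: sex, age, CT grade (1 = no visible
    intracranial pathology ... 6 = non-evacuated mass lesion), days since
    injury, total GCS at EEG, and GOSE outcomes at 3 and 6 months (1-8; empty
    field = missing, e.g. lost to follow-up).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"cohort file {path} is empty") from exc
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"cohort file missing columns: {missing_cols}")
    if df.empty:
        raise ValidationError("cohort table has no rows")
    return _validate_cohort(df)


def _validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate patient ids: {dup}")
    df["sex"] = df["sex"].astype(str).str.lower().astype("category")
    for col in ["age_years", "ct_grade", "days_since_injury", "gcs_total"]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    for col in ["gose_3mo", "gose_6mo"]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    for col, (lo, hi) in _RANGES.items():
        vals = df[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        if bad.any():
            rows = df.loc[bad, "id"].tolist()
            raise ValidationError(
                f"{col} out of range [{lo}, {hi}] for patient id(s) {rows}"
            )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with the documented header, empty = missing."""
    out = df.copy()
    extra = [c for c in out.columns if c not in COHORT_COLUMNS]
    out = out[COHORT_COLUMNS + extra]
    out.to_csv(path, index=False)


def table1_cohort() -> pd.DataFrame:
    """The published 18-patient cohort table shipped with the package."""
    with resources.files("comanet.data").joinpath("table1_cohort.csv").open() as f:
        return _validate_cohort(pd.read_csv(f))
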