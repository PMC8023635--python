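"""Cross-montage and cross-length reliability of EEG features.

High-density EEG is rarely feasible in acute care, so each feature is
computed twice per healthy subject — once from the full high-density montage
and once from the 19 channels of the 10/20 system, selected *before*
preprocessing so the low-density path mirrors clinical data exactly — and the
two estimates are correlated across subjects. Features whose low-density
estimates significantly track the high-density ones are considered reliable
in clinical montages. The same machinery checks feature stability between
recording lengths (e.g. the first 10 vs the first 5 minutes).

Normality gate: Shapiro-Wilk is applied to each variable; if either marginal
departs from normality (p < 0.05) a Spearman rank correlation is used,
otherwise Pearson. Selection is at raw p < 0.05, with no multiple-comparison
correction across the 8 features (a deliberate reproduction of the original
selection rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eeg_io import Montage, Recording, subset_channels
from .network_metrics import FEATURE_KEYS, extract_features
from .preprocess import preprocess

__all__ = [
    "AssociationResult",
    "paired_feature_association",
    "validate_features",
    "segment_reliability",
    "features_for_recording",
]


@dataclass
class AssociationResult:
    """Correlation between two per-subject estimates of one feature."""

    feature: str
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float
    normality_p: tuple[float, float]
    selected: bool


def paired_feature_association(
    x: np.ndarray,
    y: np.ndarray,
    alpha_level: float = 0.05,
    feature: str = "",
) -> AssociationResult:
    """Correlate paired estimates with a Shapiro-Wilk-gated method choice."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("need paired 1-D vectors of equal length >= 4")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"constant input vector; correlation undefined ({feature})")
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    if min(sw_x, sw_y) < alpha_level:
        method = "spearman"
        r, p = stats.spearmanr(x, y)
    else:
        method = "pearson"
        r, p = stats.pearsonr(x, y)
    return AssociationResult(
        feature=feature,
        method=method,
        coefficient=float(r),
        p_value=float(p),
        normality_p=(float(sw_x), float(sw_y)),
        selected=bool(p < alpha_level),
    )


def features_for_recording(
    rec: Recording,
    montage: Montage,
    seed: int = 0,
    n_runs: int = 100,
    bands: dict | None = None,
    **preprocess_kwargs,
) -> dict[str, float]:
    """Full pipeline (preprocess then the 8 features) for one recording."""
    ep = preprocess(rec, **preprocess_kwargs)
    return extract_features(ep, montage, seed=seed, n_runs=n_runs, bands=bands)


def _association_table(
    hd: list[dict[str, float]], ld: list[dict[str, float]], alpha_level: float
) -> tuple[list[AssociationResult], list[str]]:
    results = []
    for key in FEATURE_KEYS:
        res = paired_feature_association(
            np.array([f[key] for f in hd]),
            np.array([f[key] for f in ld]),
            alpha_level=alpha_level,
            feature=key,
        )
        results.append(res)
    selected = [r.feature for r in results if r.selected]
    return results, selected


def validate_features(
    recordings: list[Recording],
    hd_montage: Montage,
    ld_montage: Montage,
    seed: int = 0,
    n_runs: int = 100,
    alpha_level: float = 0.05,
) -> tuple[list[AssociationResult], list[str]]:
    """Per subject, run the pipeline on the full montage and on the channel
    subset taken *before* preprocessing; correlate each feature across paths.

    Returns all association results plus the names of selected features.
    """
    hd_feats, ld_feats = [], []
    for i, rec in enumerate(recordings):
        sub = subset_channels(rec, ld_montage.labels)
        hd_feats.append(features_for_recording(rec, hd_montage, seed=seed))
        ld_feats.append(features_for_recording(sub, ld_montage, seed=seed))
    return _association_table(hd_feats, ld_feats, alpha_level)


def segment_reliability(
    recordings: list[Recording],
    montage: Montage,
    len_a_s: float,
    len_b_s: float,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> list[AssociationResult]:
    """Correlate features computed from the first ``len_a_s`` vs the first
    ``len_b_s`` seconds of each recording."""
    feats_a, feats_b = [], []
    for rec in recordings:
        if rec.duration_s < max(len_a_s, len_b_s):
            raise ValueError("recording shorter than the requested segment")
        for length, out in ((len_a_s, feats_a), (len_b_s, feats_b)):
            n = int(round(length * rec.sampling_rate))
            cropped = Recording(
                rec.signals[:, :n], rec.sampling_rate,
                list(rec.channel_labels), rec.montage_ref,
            )
            out.append(features_for_recording(cropped, montage, seed=seed))
    results, _ = _association_table(feats_a, feats_b, alpha_level)
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results (feature, method, coefficient, p, selected)."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "method": [r.method for r in results],
            "coefficient": [r.coefficient for r in results],
            "p_value": [r.p_value for r in results],
            "selected": [r.selected for r in results],
        }
    )
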