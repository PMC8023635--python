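"""Independent brute-force reference implementations.

Everything here is written as plain scalar loops (or naive enumeration),
deliberately sharing no code with the package, so the vectorized
implementations can be checked against them on small random instances.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def dwpli_brute(observations: np.ndarray) -> np.ndarray:
    """Debiased WPLI^2 per pair from complex observations (pairs, K, bins):
    debiased per bin with scalar loops, then averaged over bins."""
    n_pairs, K, n_bins = observations.shape
    out = np.zeros(n_pairs)
    for p in range(n_pairs):
        per_bin = []
        for b in range(n_bins):
            s = s2 = sa = 0.0
            for k in range(K):
                im = observations[p, k, b].imag
                s += im
                s2 += im * im
                sa += abs(im)
            den = sa * sa - s2
            per_bin.append(0.0 if den == 0 else (s * s - s2) / den)
        out[p] = sum(per_bin) / n_bins
    return out


def modularity_brute(W: np.ndarray, membership: np.ndarray) -> float:
    n = W.shape[0]
    two_m = 0.0
    for i in range(n):
        for j in range(n):
            two_m += W[i, j]
    if two_m == 0:
        return 0.0
    strength = [sum(W[i, j] for j in range(n)) for i in range(n)]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += W[i, j] - strength[i] * strength[j] / two_m
    return q / two_m


def participation_brute(W: np.ndarray, membership: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    modules = sorted(set(int(m) for m in membership))
    out = np.zeros(n)
    for i in range(n):
        kappa = sum(W[i, j] for j in range(n))
        if kappa == 0:
            out[i] = 0.0
            continue
        acc = 0.0
        for m in modules:
            kappa_m = sum(W[i, j] for j in range(n) if membership[j] == m)
            acc += (kappa_m / kappa) ** 2
        out[i] = 1.0 - acc
    return out


def clustering_brute(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = max((W[i, j] for i in range(n) for j in range(n)), default=0.0)
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        k = sum(1 for j in range(n) if W[i, j] > 0)
        if k < 2:
            out[i] = 0.0
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += ((W[i, j] / wmax) * (W[i, h] / wmax)
                            * (W[j, h] / wmax)) ** (1.0 / 3.0)
        out[i] = acc / (k * (k - 1))
    return out


def modular_span_brute(W: np.ndarray, membership: np.ndarray,
                       coords: np.ndarray) -> float:
    modules = sorted(set(int(m) for m in membership))
    spans = []
    n = W.shape[0]
    for m in modules:
        num = den = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if membership[i] == m and membership[j] == m and W[i, j] > 0:
                    d = math.dist(coords[i], coords[j])
                    num += W[i, j] * d
                    den += W[i, j]
        if den > 0:
            spans.append(num / den)
    return sum(spans) / len(spans) if spans else 0.0


def threshold_brute(values: np.ndarray, density: float) -> set[tuple[int, int]]:
    """Retained edge set by explicit sort-and-cut (ties: lexicographic)."""
    n = values.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    k = round(density * len(pairs))
    ranked = sorted(pairs, key=lambda p: (-max(values[p], 0.0), p))
    return set(ranked[:k])


def rejection_brute(epochs: np.ndarray, labels: list[str], ptp_uV: float,
                    z_var: float) -> tuple[list[int], list[str]]:
    """Epoch/channel rejection counts by explicit scanning."""
    n_ep, n_ch, _ = epochs.shape
    bad_channels = []
    for c in range(n_ch):
        count = 0
        for e in range(n_ep):
            variances = [epochs[e, cc].var() for cc in range(n_ch)]
            mu = sum(variances) / n_ch
            sd = (sum((v - mu) ** 2 for v in variances) / n_ch) ** 0.5
            if sd > 0 and (epochs[e, c].var() - mu) / sd > z_var:
                count += 1
        if count > 0.5 * n_ep:
            bad_channels.append(labels[c])
    kept_ch = [c for c in range(n_ch) if labels[c] not in bad_channels]
    bad_epochs = []
    for e in range(n_ep):
        for c in kept_ch:
            if epochs[e, c].max() - epochs[e, c].min() > ptp_uV:
                bad_epochs.append(e)
                break
    return bad_epochs, bad_channels


def first_cca_correlation_eig(X: np.ndarray, Y: np.ndarray) -> float:
    """Largest canonical correlation via the generalized eigenvalue route."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc
    Syy = Yc.T @ Yc
    Sxy = Xc.T @ Yc
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    eig = np.linalg.eigvals(M)
    return float(np.sqrt(np.max(eig.real)))


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def partial_f_pvalue(y: np.ndarray, X_reduced: np.ndarray,
                     X_full: np.ndarray) -> float:
    """p-value of the partial F test for adding one column."""
    n = len(y)
    rss_r = _ols_rss(y, X_reduced) if X_reduced.shape[1] else float(
        ((y - y.mean()) ** 2).sum()
    )
    rss_f = _ols_rss(y, X_full)
    df2 = n - X_full.shape[1] - 1
    if df2 <= 0 or rss_f <= 0:
        return float("nan")
    f = (rss_r - rss_f) / (rss_f / df2)
    return float(stats.f.sf(f, 1, df2))


def stepwise_reference(y: np.ndarray, X: np.ndarray, names: list[str],
                       entry_p: float = 0.05,
                       removal_p: float = 0.10) -> list[str]:
    """Greedy forward/backward stepwise selection via explicit RSS-based
    partial F tests (independent of any regression library)."""
    selected: list[str] = []
    idx = {name: i for i, name in enumerate(names)}
    n = len(y)
    while True:
        changed = False
        cur = X[:, [idx[s] for s in selected]]
        if n - len(selected) - 2 >= 1:
            best = (float("inf"), None)
            for name in names:
                if name in selected:
                    continue
                full = X[:, [idx[s] for s in selected + [name]]]
                p = partial_f_pvalue(y, cur, full)
                if not math.isnan(p) and p < best[0]:
                    best = (p, name)
            if best[1] is not None and best[0] <= entry_p:
                selected.append(best[1])
                changed = True
        while selected:
            full = X[:, [idx[s] for s in selected]]
            worst = (-float("inf"), None)
            for name in selected:
                reduced = X[:, [idx[s] for s in selected if s != name]]
                p = partial_f_pvalue(y, reduced, full)
                if p > worst[0]:
                    worst = (p, name)
            if worst[0] >= removal_p:
                selected.remove(worst[1])
                changed = True
            else:
                break
        if not changed:
            return selected
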