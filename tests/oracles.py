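"""Naive, loop-based reference implementations used as independent oracles.

Every function here recomputes an estimator with direct formulas and
explicit Python loops — no vectorization, no shared code with the package —
so that agreement with the pipeline is evidence the fast path implements
the declared definition.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def naive_wpli(tf_data: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """wPLI from complex TF data (epochs, channels, samples), pair by pair."""
    n_ep, n_ch, _ = tf_data.shape
    cols = [t for t in range(tf_data.shape[2]) if valid[t]]
    out = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        for b in range(n_ch):
            if a == b:
                continue
            ims = []
            for e in range(n_ep):
                for t in cols:
                    s = tf_data[e, a, t] * np.conj(tf_data[e, b, t])
                    ims.append(s.imag)
            num = abs(sum(ims) / len(ims))
            den = sum(abs(v) for v in ims) / len(ims)
            out[a, b] = 0.0 if den == 0 else num / den
    return out


def naive_coherence(data: np.ndarray, sfreq: float, pad_ratio: int,
                    band=(1.0, 30.0), mode="full_band",
                    freq_hz: float | None = None) -> np.ndarray:
    """Magnitude-squared coherence from Hann-tapered, zero-padded epochs."""
    n_ep, n_ch, n_t = data.shape
    window = np.hanning(n_t)
    n_fft = pad_ratio * n_t
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sfreq)
    keep = [i for i, f in enumerate(freqs) if band[0] <= f <= band[1]]
    spectra = [[np.fft.rfft(data[e, c] * window, n_fft)[keep]
                for c in range(n_ch)] for e in range(n_ep)]
    kept_freqs = freqs[keep]
    out = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        for b in range(n_ch):
            if a == b:
                continue
            sxy = sum(spectra[e][a] * np.conj(spectra[e][b])
                      for e in range(n_ep)) / n_ep
            sxx = sum(np.abs(spectra[e][a]) ** 2 for e in range(n_ep)) / n_ep
            syy = sum(np.abs(spectra[e][b]) ** 2 for e in range(n_ep)) / n_ep
            coh = np.abs(sxy) ** 2 / (sxx * syy)
            coh = np.clip(coh, 0.0, 1.0)
            if mode == "full_band":
                out[a, b] = coh.mean()
            else:
                out[a, b] = coh[int(np.argmin(np.abs(kept_freqs - freq_hz)))]
    return out


def naive_mi(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Histogram MI in bits per channel pair, with explicit joint tables."""
    n_ch, n = x.shape

    def bin_index(v, lo, hi):
        if hi <= lo:
            return 0
        j = int(math.floor((v - lo) / (hi - lo) * n_bins))
        return min(max(j, 0), n_bins - 1)

    def entropy(counts):
        total = sum(counts)
        h = 0.0
        for c in counts:
            if c > 0:
                p = c / total
                h -= p * math.log2(p)
        return h

    idx = []
    for c in range(n_ch):
        lo, hi = x[c].min(), x[c].max()
        idx.append([bin_index(v, lo, hi) for v in x[c]])
    marg = [entropy([idx[c].count(j) for j in range(n_bins)])
            for c in range(n_ch)]
    out = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        for b in range(a + 1, n_ch):
            joint = [[0] * n_bins for _ in range(n_bins)]
            for t in range(n):
                joint[idx[a][t]][idx[b][t]] += 1
            hxy = entropy([joint[i][j] for i in range(n_bins)
                           for j in range(n_bins)])
            mi = max(marg[a] + marg[b] - hxy, 0.0)
            out[a, b] = out[b, a] = mi
    return out


def naive_permutation_entropy(series_list, order: int, delay: int) -> float:
    """Normalized PE of one channel from pattern counting over epochs.

    ``series_list`` is a list of 1-D epochs; ties break by occurrence order.
    """
    counts: dict[tuple, int] = {}
    for series in series_list:
        n = len(series)
        for start in range(n - (order - 1) * delay):
            window = [series[start + k * delay] for k in range(order)]
            pattern = tuple(sorted(range(order),
                                   key=lambda k: (window[k], k)))
            counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(order))


def naive_laplacian(data: np.ndarray, ch_names, adjacency) -> np.ndarray:
    """Channel minus mean of neighbors, epoch by epoch."""
    out = np.empty_like(data)
    index = {c: i for i, c in enumerate(ch_names)}
    for e in range(data.shape[0]):
        for c, name in enumerate(ch_names):
            nbrs = adjacency[name]
            acc = np.zeros(data.shape[2])
            for nb in nbrs:
                acc += data[e, index[nb]]
            out[e, c] = data[e, c] - acc / len(nbrs)
    return out


def naive_roi_means(matrix: np.ndarray, ch_names, pairs_by_roi) -> dict:
    """ROI means and the global mean over ROI values, by explicit lookup."""
    index = {c: i for i, c in enumerate(ch_names)}
    out = {}
    for roi, pairs in pairs_by_roi.items():
        vals = [matrix[index[a], index[b]] for a, b in pairs]
        out[roi] = sum(vals) / len(vals)
    out["global_mean"] = sum(out[r] for r in pairs_by_roi) / len(pairs_by_roi)
    return out


def naive_two_pass_rejection(data: np.ndarray, abs_threshold: float,
                             sd_multiplier: float, max_iter: int = 8
                             ) -> np.ndarray:
    """Kept-epoch mask under the two-pass rejection rule, recomputed naively."""
    n_ep, n_ch, _ = data.shape
    kept = [True] * n_ep
    for e in range(n_ep):
        for c in range(n_ch):
            if data[e, c].max() - data[e, c].min() > abs_threshold:
                kept[e] = False
                break
    if not any(kept):
        raise RuntimeError("empty")
    for _ in range(max_iter):
        flagged = []
        means = [np.mean([data[e, c] for e in range(n_ep) if kept[e]])
                 for c in range(n_ch)]
        peaks = [[np.max(np.abs(data[e, c] - means[c])) for c in range(n_ch)]
                 for e in range(n_ep)]
        for c in range(n_ch):
            vals = [peaks[e][c] for e in range(n_ep) if kept[e]]
            m = float(np.mean(vals))
            s = float(np.std(vals))
            if s <= 0:
                continue
            for e in range(n_ep):
                if kept[e] and peaks[e][c] > m + sd_multiplier * s:
                    flagged.append(e)
        if not flagged:
            break
        for e in flagged:
            kept[e] = False
        if not any(kept):
            raise RuntimeError("empty")
    return np.array(kept)


def naive_mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact Mann–Whitney p by enumerating all rank assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = {}
    for v in pooled:
        ranks[v] = sum(1 for w in pooled if w < v) + 1

    def u_stat(group):
        r = sum(ranks[v] for v in group)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_stat(a)
    mean_u = n1 * len(b) / 2
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in combo]
        total += 1
        if abs(u_stat(grp) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def naive_diag_lda_predict(X_train, y_train, x, positive, negative):
    """Hand-evaluated diagLinear discriminant for one held-out point."""
    pos = [X_train[i] for i in range(len(y_train)) if y_train[i] == positive]
    neg = [X_train[i] for i in range(len(y_train)) if y_train[i] == negative]
    mu_p = np.mean(pos, axis=0)
    mu_n = np.mean(neg, axis=0)
    n = len(y_train)
    ss = (sum((p - mu_p) ** 2 for p in pos)
          + sum((q - mu_n) ** 2 for q in neg))
    var = ss / (n - 2)
    prior_p = len(pos) / n
    d_p = -0.5 * np.sum((x - mu_p) ** 2 / var) + math.log(prior_p)
    d_n = -0.5 * np.sum((x - mu_n) ** 2 / var) + math.log(1 - prior_p)
    return positive if d_p - d_n > 0 else negative
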