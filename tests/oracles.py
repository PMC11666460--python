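"""Independent brute-force re-implementations used as test oracles.

Everything here is written for clarity over speed (explicit Python loops,
O(n^2) pair counts) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_zscore_rows(values):
    out = np.zeros_like(np.asarray(values, dtype=float))
    for i, row in enumerate(np.asarray(values, dtype=float)):
        sd = row.std()
        if sd > 0:
            out[i] = (row - row.mean()) / sd
    return out


def brute_population_trace(values):
    z = brute_zscore_rows(values)
    mean = z.mean(axis=0)
    sd = mean.std()
    if sd == 0:
        return np.zeros_like(mean)
    return (mean - mean.mean()) / sd


def brute_detect_bursts(trace, threshold=2.0):
    """Maximal runs with trace > threshold as (start, peak, end) triples."""
    events = []
    i = 0
    n = len(trace)
    while i < n:
        if trace[i] > threshold:
            j = i
            while j < n and trace[j] > threshold:
                j += 1
            peak = i
            for k in range(i, j):
                if trace[k] > trace[peak]:
                    peak = k
            events.append((i, peak, j))
            i = j
        else:
            i += 1
    return events


def brute_cell_participation(values, events, cell_threshold=2.0):
    z = brute_zscore_rows(values)
    out = np.zeros((z.shape[0], len(events)), dtype=bool)
    for k, (s, _, e) in enumerate(events):
        for c in range(z.shape[0]):
            out[c, k] = any(z[c, f] > cell_threshold for f in range(s, e))
    return out


def brute_ensemble_event_participation(traces: dict, events, threshold=2.0):
    out = {}
    for name, trace in traces.items():
        flags = []
        for s, _, e in events:
            flags.append(any(trace[f] > threshold for f in range(s, e)))
        out[name] = np.asarray(flags, dtype=bool)
    return out


def brute_coparticipation(flags: dict):
    names = sorted(flags)
    n = len(next(iter(flags.values())))
    independent = {}
    pairwise = {}
    for name in names:
        count = 0
        for k in range(n):
            if flags[name][k] and not any(
                flags[o][k] for o in names if o != name
            ):
                count += 1
        independent[name] = count / n
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = sum(
                1 for k in range(n) if flags[a][k] and flags[b][k]
            ) / n
    return independent, pairwise


def brute_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt(float((xm**2).sum()) * float((ym**2).sum()))
    if denom == 0:
        return np.nan
    return float((xm * ym).sum()) / denom


def brute_lagged_crosscorr(a, b, n_bin, max_lag):
    """Mean over bins of the max-over-lags Pearson correlation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    maxima = []
    for start in range(0, len(a) - n_bin + 1, n_bin):
        sa, sb = a[start:start + n_bin], b[start:start + n_bin]
        best = None
        for lag in range(-max_lag, max_lag + 1):
            if lag >= 0:
                x, y = sa[lag:], sb[:len(sb) - lag]
            else:
                x, y = sa[:len(sa) + lag], sb[-lag:]
            if len(x) < 2:
                continue
            r = brute_pearson(x, y)
            if not np.isnan(r) and (best is None or r > best):
                best = r
        if best is not None:
            maxima.append(best)
    return float(np.mean(maxima)) if maxima else np.nan


def brute_kendall_tau_b(x, y):
    """Tie-corrected Kendall's tau from explicit O(n^2) pair counts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    n0 = n * (n - 1) / 2

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return sum(c * (c - 1) / 2 for c in counts)

    denom = math.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))
    if denom == 0:
        return np.nan
    return (concordant - discordant) / denom


def brute_prominent_peaks(x, prominence):
    """Strict local maxima with prominence >= threshold (whole-trace scan)."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return []
    x = (x - lo) / (hi - lo)
    peaks = []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            # left base: lowest point between the peak and the next higher
            # sample (or the trace edge)
            left_min = x[i]
            j = i - 1
            while j >= 0 and x[j] <= x[i]:
                left_min = min(left_min, x[j])
                j -= 1
            right_min = x[i]
            j = i + 1
            while j < len(x) and x[j] <= x[i]:
                right_min = min(right_min, x[j])
                j += 1
            prom = x[i] - max(left_min, right_min)
            if prom >= prominence:
                peaks.append(i)
    return peaks


def brute_align_nearest(calcium_ts, target_ts, max_reuse=2):
    """Nearest-frame assignment with the reuse cap, O(n^2) and literal."""
    calcium_ts = np.asarray(calcium_ts, dtype=float)
    target_ts = np.asarray(target_ts, dtype=float)
    index = []
    for t in target_ts:
        d = np.abs(calcium_ts - t)
        index.append(int(np.argmin(d)))  # argmin takes earlier frame on ties
    index = np.asarray(index)
    counts = np.bincount(index, minlength=len(calcium_ts))
    while (counts > max_reuse).any():
        c = int(np.nonzero(counts > max_reuse)[0][0])
        assigned = [t for t in range(len(target_ts)) if index[t] == c]
        errs = [abs(target_ts[t] - calcium_ts[c]) for t in assigned]
        order = sorted(range(len(assigned)), key=lambda k: (errs[k], assigned[k]))
        keep = {assigned[k] for k in order[:max_reuse]}
        evict = [assigned[k] for k in order[max_reuse:]]
        evict.sort(key=lambda t: -abs(target_ts[t] - calcium_ts[c]))
        counts[c] = max_reuse
        for t in evict:
            d = np.abs(calcium_ts - target_ts[t])
            d[counts >= max_reuse] = np.inf
            j = int(np.argmin(d))
            index[t] = j
            counts[j] += 1
    return index


def brute_state_lookup(epoch_starts, epoch_s, states, t):
    """Interval-membership sleep-state lookup for one timestamp (ms)."""
    for k, start in enumerate(epoch_starts):
        if start <= t < start + epoch_s * 1000.0:
            return states[k]
    return "unknown"


def brute_hypergeom_sf(k_minus_1, N, K, n):
    """P[X >= k] for X ~ Hypergeom(N, K, n) by exact enumeration."""
    total = math.comb(N, n)
    p = 0.0
    for k in range(k_minus_1 + 1, min(K, n) + 1):
        p += math.comb(K, k) * math.comb(N - K, n - k) / total
    return p
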