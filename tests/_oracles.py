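"""Independent brute-force reference implementations used only by tests.

These are deliberately written in the most literal way possible (explicit
loops, Counter-based frequencies, itertools enumeration) and share no code
with the package, so agreement is evidence of correctness rather than of
shared bugs.
"""

from collections import Counter
from itertools import combinations
from math import comb, log2

import numpy as np


def brute_force_heterogeneity(states, min_shared=4):
    """Literal pair-enumeration version of the region heterogeneity score."""
    n_cells = states.shape[0]
    weights, dists, entropies = [], [], []
    for a, b in combinations(range(n_cells), 2):
        shared_cols = [
            j
            for j in range(states.shape[1])
            if not (np.isnan(states[a, j]) or np.isnan(states[b, j]))
        ]
        k = len(shared_cols)
        if k < min_shared:
            continue
        mismatches = sum(1 for j in shared_cols if states[a, j] != states[b, j])
        patterns = Counter(
            (int(states[a, j]), int(states[b, j])) for j in shared_cols
        )
        entropy = -sum((c / k) * log2(c / k) for c in patterns.values())
        weights.append(k)
        dists.append(mismatches / k)
        entropies.append(entropy)
    if not weights:
        return None
    w = np.array(weights, dtype=float)
    mean_d = float(np.dot(w, dists) / w.sum())
    mean_s = float(np.dot(w, entropies) / w.sum())
    return mean_d * mean_s


def brute_force_rank_sum_p(x, y, alternative="two-sided"):
    """Exhaustive mid-rank Mann-Whitney p over all C(n, n1) assignments."""
    pooled = list(x) + list(y)
    n, n1 = len(pooled), len(x)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    mu = n1 * (n - n1) / 2.0
    hits = 0
    for combo in combinations(range(n), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0
        if alternative == "greater":
            hits += u >= u_obs - 1e-9
        elif alternative == "less":
            hits += u <= u_obs + 1e-9
        else:
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
    return hits / comb(n, n1)


def rolling_median_literal(values, window, min_half):
    """Loop-written centred rolling median with symmetric edge shrink."""
    n = len(values)
    h = max(1, window // 2)
    out = []
    for i in range(n):
        hw = max(min(h, i, n - 1 - i), min(min_half, h))
        seg = values[max(0, i - hw): min(n, i + hw + 1)]
        out.append(float(np.median(seg)))
    return np.array(out)


def sliding_z_literal(values, order_by, window):
    """Loop-written sliding-window z-score over sorted records."""
    idx = np.argsort(order_by, kind="stable")
    v = np.asarray(values, float)[idx]
    n = len(v)
    h = max(1, window // 2)
    z = np.empty(n)
    for i in range(n):
        seg = v[max(0, i - h): min(n, i + h + 1)]
        sd = np.std(seg, ddof=1) if len(seg) > 1 else 0.0
        z[i] = 0.0 if sd == 0 else (v[i] - np.mean(seg)) / sd
    out = np.empty(n)
    out[idx] = z
    return out
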