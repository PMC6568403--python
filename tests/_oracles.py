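"""Independent brute-force oracles used to cross-check the package.

Deliberately naive: explicit loops, explicit distance matrices, explicit
pair tables.  Nothing here shares code with metasig's vectorized paths.
"""

from __future__ import annotations

import numpy as np

# --- k-NN / LOOCV ---------------------------------------------------------


def oracle_knn_predict(X_train, y_train, query, k, standardize=True):
    """Brute-force k-NN vote: standardize, build every distance, sort."""
    X = np.asarray(X_train, dtype=float)
    y = list(y_train)
    q = np.asarray(query, dtype=float)
    L, n = X.shape
    if standardize:
        mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        scale = np.where(sd > 0, sd, np.inf)  # constant gene contributes nothing
        Z = (X - mean[:, None]) / scale[:, None]
        zq = (q - mean) / scale
    else:
        Z, zq = X, q
    d2 = [float(((Z[:, t] - zq) ** 2).sum()) for t in range(n)]
    order = sorted(range(n), key=lambda t: (d2[t], t))
    votes = [y[t] for t in order[:k]]
    counts = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = [c for c, m in counts.items() if m == best]
    if len(winners) == 1:
        return winners[0]
    return votes[0]  # tie -> nearest neighbor's label


def oracle_loocv_fitness(X, y, k, standardize=True):
    """Brute-force LOOCV: re-derive fold statistics for every held-out sample."""
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    correct = 0
    for i in range(n):
        keep = [t for t in range(n) if t != i]
        pred = oracle_knn_predict(X[:, keep], [y[t] for t in keep], X[:, i], k, standardize)
        if pred == y[i]:
            correct += 1
    return correct / n


# --- seed-site scanning ---------------------------------------------------

_ORACLE_WC = {"AU", "UA", "GC", "CG"}
_ORACLE_GU = {"GU", "UG"}


def oracle_scan(sequence, seed, min_complementary=7, max_gu=1):
    """Enumerate every window explicitly and classify all pairs.

    Returns a list of (start, end, n_wc, n_gu) tuples; the window at
    ``start`` pairs target[start+len(seed)-1-j] with seed[j].
    """
    seq = sequence.upper().replace("T", "U")
    slen = len(seed)
    hits = []
    for start in range(len(seq) - slen + 1):
        n_wc = n_gu = 0
        for j in range(slen):
            t = seq[start + slen - 1 - j]
            s = seed[j]
            if t + s in _ORACLE_WC:
                n_wc += 1
            elif t + s in _ORACLE_GU:
                n_gu += 1
        if n_wc + min(n_gu, max_gu) >= min_complementary:
            hits.append((start, start + slen, n_wc, n_gu))
    return hits


def oracle_site_probability(seed, min_complementary=7, max_gu=1):
    """Exact probability that a uniform random window qualifies, by
    enumerating all 4^len(seed) windows."""
    from itertools import product

    slen = len(seed)
    n_hit = 0
    for window in product("ACGU", repeat=slen):
        n_wc = n_gu = 0
        for j in range(slen):
            t = window[slen - 1 - j]
            s = seed[j]
            if t + s in _ORACLE_WC:
                n_wc += 1
            elif t + s in _ORACLE_GU:
                n_gu += 1
        if n_wc + min(n_gu, max_gu) >= min_complementary:
            n_hit += 1
    return n_hit / 4**slen
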