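"""Independent reference implementations used only as test oracles.

Each function here is a deliberately plain, loop-heavy transcription of
the published definition of the quantity it computes, written without
reference to the package implementation so the two can disagree.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def tmm_reference(counts: np.ndarray, trim_m: float = 0.30,
                  trim_a: float = 0.05) -> np.ndarray:
    """Straight-line TMM: doubly trimmed, precision-weighted mean M-values."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = np.array([counts[:, j].sum() for j in range(n_samples)])

    # reference sample: 75th-percentile count fraction closest to the mean
    f75 = np.array(
        [np.percentile(counts[:, j], 75) / lib[j] for j in range(n_samples)]
    )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    logf = np.zeros(n_samples)
    for j in range(n_samples):
        m_vals, a_vals, weights = [], [], []
        for g in range(n_genes):
            y, yr = counts[g, j], counts[g, ref]
            if y > 0 and yr > 0:
                p, pr = y / lib[j], yr / lib[ref]
                m_vals.append(np.log2(p / pr))
                a_vals.append(0.5 * np.log2(p * pr))
                weights.append(
                    (lib[j] - y) / (lib[j] * y)
                    + (lib[ref] - yr) / (lib[ref] * yr)
                )
        m_vals = np.array(m_vals)
        a_vals = np.array(a_vals)
        weights = np.array(weights)
        k = len(m_vals)
        rm, ra = rankdata(m_vals), rankdata(a_vals)
        keep = np.array(
            [
                np.floor(k * trim_m) + 1 <= rm[i] <= k - np.floor(k * trim_m)
                and np.floor(k * trim_a) + 1 <= ra[i] <= k - np.floor(k * trim_a)
                for i in range(k)
            ]
        )
        if keep.any():
            w = 1.0 / np.maximum(weights[keep], 1e-12)
            logf[j] = np.sum(w * m_vals[keep]) / np.sum(w)
    logf = logf - logf.mean()
    return 2.0 ** logf


def knn_brute(train: np.ndarray, labels: np.ndarray, query: np.ndarray,
              k: int) -> str:
    """Exhaustive KNN: sort all distances, apply the stated tie-breaks."""
    dist = [
        (float(np.sqrt(((train[i] - query) ** 2).sum())), i)
        for i in range(len(train))
    ]
    dist.sort(key=lambda t: (t[0], t[1]))  # stable training order on ties
    chosen = dist[:k]
    votes: dict[str, int] = {}
    sums: dict[str, float] = {}
    for d, i in chosen:
        votes[labels[i]] = votes.get(labels[i], 0) + 1
        sums[labels[i]] = sums.get(labels[i], 0.0) + d
    best = max(votes.values())
    tied = sorted(
        [lab for lab in votes if votes[lab] == best],
        key=lambda lab: (sums[lab], lab),
    )
    return tied[0]


def silhouette_double_loop(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """s(i) = (b - a) / max(a, b) with explicit double loops."""
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            continue  # singleton convention: 0
        a = float(np.mean([dist[i, j] for j in same]))
        b = np.inf
        for c in set(labels):
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, float(np.mean([dist[i, j] for j in members])))
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out


def bh_direct(p: np.ndarray) -> np.ndarray:
    """BH adjusted value of p_(i): min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj
    return out


def welch_power(delta: float, sd: float, n1: int, n2: int,
                alpha: float = 0.05) -> float:
    """Analytic power of the two-sided Welch test at a common true sd."""
    from scipy.stats import nct, t as t_dist

    se = sd * np.sqrt(1 / n1 + 1 / n2)
    # equal variances: Welch df reduces to the Welch-Satterthwaite value
    df = (1 / n1 + 1 / n2) ** 2 / (
        (1 / n1) ** 2 / (n1 - 1) + (1 / n2) ** 2 / (n2 - 1)
    )
    nc = delta / se
    crit = t_dist.ppf(1 - alpha / 2, df)
    return float(nct.sf(crit, df, nc) + nct.cdf(-crit, df, nc))
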