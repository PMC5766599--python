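"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fitting/selection code paths:
likelihoods are maximised by coordinate-wise grid refinement, edges by a
full sort, permutation nulls with scipy.stats.rankdata, enumerations with
itertools.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from lnckit.de import nb_loglik


def grid_maximize_loglik(y, X, offsets, phi, n_sweeps=16, width0=8.0, n_grid=33):
    """Maximise the exact NB log-likelihood over beta by cyclic
    coordinate search on a shrinking grid."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    beta = np.zeros(p)
    width = width0
    for _ in range(n_sweeps):
        # repeat sweeps at this width until the search stops moving, so
        # coordinate zigzag cannot stall ahead of the width shrink
        for _pass in range(12):
            moved = False
            for j in range(p):
                deltas = np.linspace(-width, width, n_grid)
                etas = offsets + X @ beta + np.outer(deltas, X[:, j])
                lls = nb_loglik(y[None, :], np.exp(np.clip(etas, -30, 30)), phi)
                best = int(np.argmax(lls))
                if deltas[best] != 0.0:
                    beta[j] += deltas[best]
                    moved = True
            if not moved:
                break
        width *= 0.5
    ll = float(nb_loglik(y, np.exp(np.clip(offsets + X @ beta, -30, 30)), phi))
    return beta, ll


def tmm_factor_bruteforce(y, y_ref, trim_m=0.30, trim_a=0.05):
    """Direct, loop-based recomputation of the trimmed-mean-of-M formula."""
    n, n_ref = y.sum(), y_ref.sum()
    pairs = [(yi, ri) for yi, ri in zip(y, y_ref) if yi > 0 and ri > 0]
    m_vals, a_vals, w_vals = [], [], []
    for yi, ri in pairs:
        p, pr = yi / n, ri / n_ref
        m_vals.append(np.log2(p / pr))
        a_vals.append(0.5 * np.log2(p * pr))
        w_vals.append(1.0 / ((n - yi) / (n * yi) + (n_ref - ri) / (n_ref * ri)))
    m_vals, a_vals, w_vals = map(np.array, (m_vals, a_vals, w_vals))
    lo_m, hi_m = np.quantile(m_vals, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a_vals, [trim_a, 1 - trim_a])
    keep = (m_vals >= lo_m) & (m_vals <= hi_m) & (a_vals >= lo_a) & (a_vals <= hi_a)
    return 2.0 ** (np.sum(w_vals[keep] * m_vals[keep]) / np.sum(w_vals[keep]))


def signed_rank_p_enumeration(diffs):
    """Two-sided exact signed-rank p by explicit 2^n enumeration."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for mask in range(2 ** n):
        picks = [(mask >> i) & 1 for i in range(n)]
        ws.append(float(np.dot(picks, ranks)))
    ws = np.array(ws)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    return min(1.0, 2.0 * min(p_ge, p_le))


def rank_enrichment_p_enumeration(m, set_ranks):
    """One- and two-sided exact rank-sum p by enumerating all C(m, n1)
    placements of the set within ranks 1..m."""
    set_ranks = sorted(set_ranks)
    n1 = len(set_ranks)
    s_obs = sum(set_ranks)
    sums = [sum(c) for c in combinations(range(1, m + 1), n1)]
    sums = np.array(sums)
    p_le = np.mean(sums <= s_obs)
    p_ge = np.mean(sums >= s_obs)
    return float(p_le), float(min(1.0, 2.0 * min(p_le, p_ge)))


def _rank_sum_z(x, y):
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = n1 + n2
    r = rankdata(pooled)
    r1 = r[:n1].sum()
    _, cnt = np.unique(pooled, return_counts=True)
    var = n1 * n2 / 12.0 * ((n + 1) - np.sum(cnt**3 - cnt) / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return (r1 - n1 * (n + 1) / 2.0) / np.sqrt(var)


def steel_dwass_p_permutation(groups, n_resamples=100_000, seed=0):
    """Family-wise pairwise p-values by max-statistic permutation of the
    pooled observations (independent implementation)."""
    rng = np.random.default_rng(seed)
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    cuts = np.cumsum(sizes)[:-1]
    pooled = np.concatenate(groups)
    pairs = list(combinations(range(len(groups)), 2))
    q_obs = {
        (i, j): abs(_rank_sum_z(groups[i], groups[j])) * np.sqrt(2.0) for i, j in pairs
    }
    max_null = np.empty(n_resamples)
    for b in range(n_resamples):
        parts = np.split(rng.permutation(pooled), cuts)
        max_null[b] = max(abs(_rank_sum_z(parts[i], parts[j])) for i, j in pairs)
    max_null *= np.sqrt(2.0)
    return {
        pair: (1.0 + np.sum(max_null >= q - 1e-12)) / (n_resamples + 1.0)
        for pair, q in q_obs.items()
    }


def edges_bruteforce(corr_df, edge_fraction):
    """Full-sort edge selection with lexicographic tie-breaks."""
    import math

    items = [
        (l, p, corr_df.at[l, p])
        for l in corr_df.index
        for p in corr_df.columns
        if not np.isnan(corr_df.at[l, p])
    ]
    k = math.ceil(edge_fraction * len(items))
    pos = sorted(items, key=lambda t: (-t[2], t[0], t[1]))[:k]
    neg = sorted(items, key=lambda t: (t[2], t[0], t[1]))[:k]
    chosen = {}
    for l, p, r in pos:
        chosen[(l, p)] = (r, "positive")
    for l, p, r in neg:
        chosen.setdefault((l, p), (r, "negative"))
    return chosen
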