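"""Independent reference implementations used only by tests.

Each oracle is written as directly as possible (explicit loops, exhaustive
enumeration, closed forms) and never shares code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ssgsea_es_oracle(gene_ids, values, members, alpha) -> float:
    """Brute-force running-sum enrichment score for one sample.

    Orders genes by descending value with lexicographic gene-id tiebreak,
    then walks the list position by position accumulating the weighted
    in-set CDF minus the unweighted out-of-set CDF.
    """
    G = len(gene_ids)
    order = sorted(range(G), key=lambda i: (-values[i], gene_ids[i]))
    member_set = set(members)
    in_weights = []
    for pos, i in enumerate(order):
        rank_from_bottom = G - pos  # rank 1 position has weight G ** alpha
        if gene_ids[i] in member_set:
            in_weights.append((pos, float(rank_from_bottom) ** alpha))
    total_w = sum(w for _, w in in_weights)
    n_out = G - len(in_weights)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    weight_at = dict(in_weights)
    for pos, i in enumerate(order):
        if pos in weight_at:
            cum_in += weight_at[pos]
        else:
            cum_out += 1
        es += cum_in / total_w - cum_out / n_out
    return es


def efron_partial_loglik(beta, X, time, event) -> float:
    """Efron-approximation Cox partial log-likelihood, written from the
    textbook formula with explicit loops over event times."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    theta = np.exp(eta)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        sum_theta_risk = theta[R].sum()
        sum_theta_tied = theta[D].sum()
        m = len(D)
        ll += eta[D].sum()
        for ell in range(m):
            ll -= math.log(sum_theta_risk - (ell / m) * sum_theta_tied)
    return ll


def breslow_partial_loglik(beta, X, time, event) -> float:
    """Breslow-approximation Cox partial log-likelihood (full risk set for
    every tied death)."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    theta = np.exp(eta)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        ll += eta[D].sum() - len(D) * math.log(theta[R].sum())
    return ll


def grid_search_cox(X, time, event, lo=-3.0, hi=3.0, rounds=4, n_grid=31, loglik=None):
    """Coarse-to-fine grid maximization of a Cox partial likelihood (Efron
    by default) for a 2-feature design."""
    if loglik is None:
        loglik = efron_partial_loglik
    center = np.zeros(2)
    half = (hi - lo) / 2.0
    best = None
    for _ in range(rounds):
        b1s = np.linspace(center[0] - half, center[0] + half, n_grid)
        b2s = np.linspace(center[1] - half, center[1] + half, n_grid)
        best = None
        for b1 in b1s:
            for b2 in b2s:
                ll = loglik((b1, b2), X, time, event)
                if best is None or ll > best[0]:
                    best = (ll, b1, b2)
        center = np.array([best[1], best[2]])
        half = half * (2.0 / (n_grid - 1)) * 2  # shrink around the maximizer
    return center


def cindex_pairs_oracle(rs, time, event) -> float:
    """Harrell's C by O(n^2) enumeration of usable pairs."""
    n = len(rs)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable: i fails strictly earlier and i's failure is observed
            if event[i] == 1 and time[i] < time[j]:
                den += 1
                if rs[i] > rs[j]:
                    num += 1.0
                elif rs[i] == rs[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def logrank_oracle(time, event, group_a_mask):
    """Two-group log-rank chi-square by explicit O-E / variance tabulation."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n_tot = at_risk.sum()
        n_a = (at_risk & group_a_mask).sum()
        d_tot = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & group_a_mask).sum()
        e_a = d_tot * n_a / n_tot
        o_minus_e += d_a - e_a
        if n_tot > 1:
            var += d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    return o_minus_e**2 / var


def hypergeom_tail_oracle(k, N, K, n) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p for a 2x2 table by enumerating all tables with
    the observed margins and summing probabilities <= the observed one."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = math.comb(N, r1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return math.comb(c1, x) * math.comb(N - c1, r1 - x) / denom

    p_obs = prob(a)
    return sum(
        p for x in range(0, min(r1, c1) + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9)
    )


def wilcoxon_exact_oracle(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all group-A position
    choices (no ties assumed)."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)
    obs = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n_a):
        total += 1
        if abs(sum(combo) - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def uncensored_roc_oracle(rs, case_mask, threshold):
    """Sensitivity/specificity at a threshold by direct counting against the
    binary event-by-horizon label (no censoring)."""
    rs = np.asarray(rs, dtype=float)
    positive = rs >= threshold
    sens = (positive & case_mask).sum() / case_mask.sum()
    spec = (~positive & ~case_mask).sum() / (~case_mask).sum()
    return sens, spec
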