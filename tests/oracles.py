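"""Independent reference implementations used only by the tests.

These deliberately use naive loops/enumeration and stay independent of the
package code paths they check.
"""

import itertools
import math

import numpy as np


def brute_force_pairing(features, ppm_max=5.0, rt_max=3.0):
    """Naive all-pairs candidate enumeration + greedy selection.

    features: DataFrame with columns mz, rt indexed by feature id.
    Returns a set of frozensets (the selected pairs).
    """
    candidates = []
    ids = list(features.index)
    for i, j in itertools.combinations(range(len(ids)), 2):
        mz_i, mz_j = features["mz"].iloc[i], features["mz"].iloc[j]
        ppm = abs(mz_i - mz_j) / ((mz_i + mz_j) / 2) * 1e6
        dt = abs(features["rt"].iloc[i] - features["rt"].iloc[j])
        if ppm < ppm_max and 0 < dt < rt_max:
            a, b = sorted((str(ids[i]), str(ids[j])))
            candidates.append((ppm, dt, a, b))
    candidates.sort()
    used, chosen = set(), set()
    for ppm, dt, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        chosen.add(frozenset((a, b)))
    return chosen


def welch_p_two_sided(x, y):
    """Welch t-test via the closed-form statistic and Satterthwaite df."""
    from scipy.stats import t as t_dist

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2 * t_dist.sf(abs(t), df)


def wilcoxon_exact_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Requires tie-free data.  p = fraction of assignments whose rank sum
    deviates from its mean at least as much as the observed one.
    """
    x, y = list(x), list(y)
    n1, n = len(x), len(x) + len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == n, "enumeration oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    w_obs = sum(ranks[v] for v in x)
    mean_w = n1 * (n + 1) / 2
    count = total = 0
    for subset in itertools.combinations(range(1, n + 1), n1):
        total += 1
        if abs(sum(subset) - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return w_obs, count / total


def hypergeom_enumeration(n_universe, n_members, n_query, k_min):
    """P(overlap >= k_min) by enumerating all draws of n_query items."""
    universe = range(n_universe)
    members = set(range(n_members))
    hits = total = 0
    for draw in itertools.combinations(universe, n_query):
        total += 1
        if len(members & set(draw)) >= k_min:
            hits += 1
    return hits / total


def chi2_sf_even_df(x, df):
    """Closed-form chi-square upper tail for even df:
    exp(-x/2) * sum_{i<df/2} (x/2)^i / i!"""
    assert df % 2 == 0
    k = df // 2
    term, acc = 1.0, 1.0
    for i in range(1, k):
        term *= (x / 2) / i
        acc += term
    return math.exp(-x / 2) * acc


def pearson_loop(u, v):
    """Definitional product-moment correlation with explicit loops."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    num = sum((u[i] - mu) * (v[i] - mv) for i in range(n))
    du = math.sqrt(sum((u[i] - mu) ** 2 for i in range(n)))
    dv = math.sqrt(sum((v[i] - mv) ** 2 for i in range(n)))
    return num / (du * dv)
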