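"""Independent brute-force oracles, written as direct transcriptions of the
definitions and kept free of any package internals. Each oracle is the
reference a package routine is checked against; none of them import from
synprox."""

import itertools
import math

import numpy as np


def triangle_scan(hist):
    """Exhaustive Triangle threshold: mirror when the peak is nearer the
    bright end, then scan every bin after the peak for the maximum
    perpendicular distance to the peak->last-nonzero line."""
    hist = [float(v) for v in hist]
    nz = [i for i, v in enumerate(hist) if v > 0]
    assert len(nz) >= 2
    peak = max(range(len(hist)), key=lambda i: (hist[i], -i))
    if (nz[-1] - peak) < (peak - nz[0]):
        mirrored = True
        hist = hist[::-1]
        nz = [len(hist) - 1 - i for i in reversed(nz)]
        peak = len(hist) - 1 - peak
    else:
        mirrored = False
    x0, y0 = peak, hist[peak]
    x1, y1 = nz[-1], hist[nz[-1]]
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    best, best_d = None, -1.0
    for x in range(peak + 1, nz[-1] + 1):
        d = abs(dy * (x - x0) - dx * (hist[x] - y0)) / norm
        if d > best_d:
            best, best_d = x, d
    if mirrored:
        best = len(hist) - 1 - best
    return best


def poisson_pmf(k, lam):
    return math.exp(-lam) * lam ** k / math.factorial(int(k))


def saint_posterior(bait_counts, ctrl_counts, pseudocount, prior, min_fold=1.0):
    """Transcription of the two-component per-replicate posterior average."""
    lam_f = sum(ctrl_counts) / len(ctrl_counts) + pseudocount
    lam_t = max(sum(bait_counts) / len(bait_counts), min_fold * lam_f)
    ps = []
    for x in bait_counts:
        num = prior * poisson_pmf(x, lam_t)
        den = num + (1.0 - prior) * poisson_pmf(x, lam_f)
        ps.append(num / den)
    return sum(ps) / len(ps)


def fold_ratio(bait_counts, ctrl_counts, pseudocount):
    mb = sum(bait_counts) / len(bait_counts)
    mc = sum(ctrl_counts) / len(ctrl_counts)
    return (mb + pseudocount) / (mc + pseudocount)


def wilcoxon_exact_two_sided(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Assumes no zero differences and no tied absolute values."""
    diffs = list(diffs)
    n = len(diffs)
    order = sorted(range(n), key=lambda i: abs(diffs[i]))
    rank_of = {i: r + 1 for r, i in enumerate(order)}
    w_plus = sum(rank_of[i] for i in range(n) if diffs[i] > 0)
    total = n * (n + 1) // 2
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r + 1 for r, s in enumerate(signs) if s)  # subset of ranks 1..n
        if min(w, total - w) <= w_obs:
            count += 1
    return count / 2 ** n


def mannwhitney_exact_two_sided(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Assumes no ties across the pooled sample."""
    pooled = sorted(list(x) + list(y))
    n1, n2 = len(x), len(y)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(i + 1 for i in combo) - n1 * (n1 + 1) / 2
        if abs(u - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def nb_mean_mc(mu, dispersion, n=100_000, seed=12345):
    """Monte-Carlo mean of the Gamma-Poisson law (independent draw path)."""
    rng = np.random.default_rng(seed)
    if dispersion <= 0:
        x = rng.poisson(mu, n)
    else:
        lam = rng.gamma(1.0 / dispersion, mu * dispersion, n)
        x = rng.poisson(lam)
    return x.mean(), x.std(ddof=1) / math.sqrt(n)
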