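"""Brute-force reference implementations of the window statistics.

Everything here is written for clarity, not speed: explicit pair
enumeration, explicit bipartition comparison, direct two-locus arithmetic,
and constants transcribed independently from the original publications.
Used to validate the vectorized implementations in mmcscan.sumstats.
"""

import itertools
import math

import numpy as np


def pi_pairwise(x) -> float:
    """Mean pairwise differences by enumerating all haplotype pairs."""
    x = np.asarray(x)
    n = x.shape[0]
    tot = 0
    for i, j in itertools.combinations(range(n), 2):
        tot += int((x[i] != x[j]).sum())
    return tot / (n * (n - 1) / 2)


def hap_div_enum(x) -> float:
    x = np.asarray(x)
    n = x.shape[0]
    counts = {}
    for row in x:
        key = "".join(map(str, row.tolist()))
        counts[key] = counts.get(key, 0) + 1
    ssq = sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * (1 - ssq)


def _a1(n):
    return sum(1 / i for i in range(1, n))


def _a2(n):
    return sum(1 / i ** 2 for i in range(1, n))


def tajimas_d_direct(x) -> float:
    x = np.asarray(x)
    n, S = x.shape
    if S == 0:
        return math.nan
    a1, a2 = _a1(n), _a2(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_pairwise(x) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_direct(x):
    """Fu & Li (1993) D and F, outgroup known (derived singletons)."""
    x = np.asarray(x)
    n, S = x.shape
    if S == 0 or n < 3:
        return math.nan, math.nan
    eta = S
    eta_s = sum(1 for k in range(S) if int(x[:, k].sum()) == 1)
    an, bn = _a1(n), _a2(n)
    an1 = _a1(n + 1)
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vd = 1 + (an ** 2 / (bn + an ** 2)) * (cn - (n + 1) / (n - 1))
    ud = an - 1 - vd
    d = (eta - an * eta_s) / math.sqrt(ud * eta + vd * eta ** 2)
    vf = (cn + 2 * (n ** 2 + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) \
        / (an ** 2 + bn)
    uf = (1 + (n + 1) / (3 * (n - 1))
          - 4 * ((n + 1) / (n - 1) ** 2) * (an1 - 2 * n / (n + 1))) / an - vf
    f = (pi_pairwise(x) - eta_s) / math.sqrt(uf * eta + vf * eta ** 2)
    return d, f


def walls_bq_direct(x):
    """Wall's B and Q by explicit bipartition comparison."""
    x = np.asarray(x)
    n, S = x.shape
    if S < 1:
        return math.nan, math.nan
    if S < 2:
        return math.nan, 0.0

    def part(k):
        col = tuple(x[:, k].tolist())
        comp = tuple(1 - v for v in col)
        return min(col, comp)

    congruent_parts = []
    bprime = 0
    for k in range(S - 1):
        if part(k) == part(k + 1):
            bprime += 1
            congruent_parts.append(part(k))
    a = len(set(congruent_parts))
    return bprime / (S - 1), (bprime + a) / S


def ld_direct(x):
    """(ZnS, ZA, ZZ) by direct two-locus arithmetic on every pair."""
    x = np.asarray(x).astype(float)
    n, S = x.shape
    if S < 2:
        return math.nan, math.nan, math.nan

    def r2(i, j):
        pi_, pj = x[:, i].mean(), x[:, j].mean()
        pij = (x[:, i] * x[:, j]).mean()
        d = pij - pi_ * pj
        return d * d / (pi_ * (1 - pi_) * pj * (1 - pj))

    pairs = list(itertools.combinations(range(S), 2))
    zns = sum(r2(i, j) for i, j in pairs) / len(pairs)
    za = sum(r2(k, k + 1) for k in range(S - 1)) / (S - 1)
    return zns, za, za - zns


def random_matrix(rng, n_max=10, s_max=8):
    """A random segregating haplotype matrix (each column count in [1, n-1])."""
    n = int(rng.integers(4, n_max + 1))
    S = int(rng.integers(0, s_max + 1))
    cols = []
    for _ in range(S):
        while True:
            col = rng.integers(0, 2, size=n)
            if 0 < col.sum() < n:
                cols.append(col)
                break
    x = np.array(cols, dtype=np.uint8).T if S else np.zeros((n, 0), np.uint8)
    return x
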