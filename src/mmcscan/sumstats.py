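"""The 11 window summary statistics used for coalescent model choice.

SFS-based: segregating sites S, nucleotide diversity π (mean pairwise
differences per window), Tajima's D, Fu & Li's D and F (unfolded — the
simulation knows the ancestral state, so singletons are derived-count-1
sites).  Haplotype-based: haplotype diversity, Wall's B and Q.  LD-based:
Kelly's ZnS (mean r² over all site pairs), Rozas' ZA (mean r² over adjacent
pairs) and ZZ = ZA − ZnS.

Statistics that are undefined on a window (e.g. any LD statistic when S<2,
or every frequency statistic when S=0) are reported as NaN together with a
degenerate flag; the ABC layer decides how to impute them.  π and S are
reported per window, not per site.
"""

from __future__ import annotations

import numpy as np

from .engine import HaplotypeMatrix
from .params import WindowSpec

__all__ = [
    "STAT_NAMES",
    "basic_stats",
    "tajimas_d",
    "fu_li_d_f",
    "walls_b_q",
    "ld_stats",
    "window_stats",
    "compute_summary",
    "is_degenerate",
]

#: Canonical statistic order; also the fixed iteration order used when
#: pruning correlated statistics.
STAT_NAMES = [
    "S", "pi", "tajimas_d", "fu_li_d", "fu_li_f", "hap_div",
    "walls_b", "walls_q", "rozas_za", "rozas_zz", "kellys_zns",
]


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, HaplotypeMatrix):
        return m.matrix
    return np.asarray(m, dtype=np.uint8)


def basic_stats(m) -> tuple[int, float, float]:
    """(S, π, haplotype diversity).

    π is the mean number of pairwise differences: Σ_sites c(n−c)/C(n,2).
    Haplotype diversity is the sample-size-corrected probability that two
    haplotypes differ: n/(n−1)·(1 − Σ f_k²).
    """
    x = _as_matrix(m)
    n, S = x.shape
    if S == 0:
        # monomorphic data: values do not depend on n (an ms block with
        # segsites 0 carries no rows, so n may legitimately be 0 here)
        return 0, 0.0, 0.0
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    c = x.sum(axis=0, dtype=np.int64)
    pi = float((c * (n - c)).sum() * 2.0 / (n * (n - 1)))
    _, counts = np.unique(x, axis=0, return_counts=True)
    f = counts / n
    # clip float roundoff: exactly 1 when every haplotype is distinct
    hap_div = float(min(1.0, n / (n - 1) * (1.0 - (f ** 2).sum())))
    return int(S), pi, hap_div


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float((1.0 / i).sum()), float((1.0 / i ** 2).sum())


def tajimas_d(m) -> float:
    """Tajima's D from π (total pairwise differences) and S."""
    x = _as_matrix(m)
    n, S = x.shape
    if S < 1:
        return np.nan
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    _, pi, _ = basic_stats(x)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return np.nan
    return float((pi - S / a1) / np.sqrt(var))


def fu_li_d_f(m) -> tuple[float, float]:
    """Fu & Li's (1993) D and F with known ancestral state.

    η is the number of polymorphic sites (= S under infinite sites) and η_s
    the number of derived singletons.  Normalising constants follow the
    original publication.
    """
    x = _as_matrix(m)
    n, S = x.shape
    if S < 1 or n < 3:
        return np.nan, np.nan
    c = x.sum(axis=0, dtype=np.int64)
    eta = float(S)
    eta_s = float((c == 1).sum())
    an, bn = _harmonics(n)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    # D
    vd = 1.0 + (an ** 2 / (bn + an ** 2)) * (cn - (n + 1.0) / (n - 1.0))
    ud = an - 1.0 - vd
    d_den = np.sqrt(ud * eta + vd * eta ** 2)
    d = (eta - an * eta_s) / d_den if d_den > 0 else np.nan
    # F
    _, pi, _ = basic_stats(x)
    vf = (cn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) \
        / (an ** 2 + bn)
    uf = (1.0 + (n + 1.0) / (3.0 * (n - 1))
          - 4.0 * ((n + 1.0) / (n - 1.0) ** 2) * (an1 - 2.0 * n / (n + 1.0))
          ) / an - vf
    f_den = np.sqrt(uf * eta + vf * eta ** 2)
    f = (pi - eta_s) / f_den if f_den > 0 else np.nan
    return float(d), float(f)


def _bipartitions(x: np.ndarray) -> np.ndarray:
    """Canonical 0/1 encoding of each column's sample bipartition: columns
    are XORed with their first row so equal or complementary labelings map
    to the same code."""
    return np.bitwise_xor(x, x[0:1, :])


def walls_b_q(m) -> tuple[float, float]:
    """Wall's (1999) B and Q.

    An adjacent site pair is congruent when both columns induce the same
    bipartition of the sample.  B = B'/(S−1) with B' the number of congruent
    adjacent pairs; Q = (B' + A)/S with A the number of distinct bipartitions
    among congruent pairs.
    """
    x = _as_matrix(m)
    n, S = x.shape
    if S < 1:
        return np.nan, np.nan
    if S < 2:
        return np.nan, 0.0
    parts = _bipartitions(x)
    congruent = np.flatnonzero(
        (parts[:, :-1] == parts[:, 1:]).all(axis=0))
    b_prime = congruent.size
    if b_prime:
        a = np.unique(parts[:, congruent], axis=1).shape[1]
    else:
        a = 0
    return float(b_prime / (S - 1)), float((b_prime + a) / S)


def ld_stats(m) -> tuple[float, float, float]:
    """(Kelly's ZnS, Rozas' ZA, ZZ) on derived-allele r².

    r²(i,j) = D²/(p_i(1−p_i)p_j(1−p_j)) with D = p_ij − p_i p_j; ZnS averages
    all C(S,2) pairs, ZA the S−1 adjacent pairs (position order), ZZ=ZA−ZnS.
    """
    x = _as_matrix(m).astype(np.float64)
    n, S = x.shape
    if S < 2:
        return np.nan, np.nan, np.nan
    p = x.mean(axis=0)
    d = (x.T @ x) / n - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    r2 = np.clip(d ** 2 / denom, 0.0, 1.0)  # clip float roundoff at 1
    iu = np.triu_indices(S, k=1)
    zns = float(r2[iu].mean())
    za = float(np.diagonal(r2, offset=1).mean())
    return zns, za, za - zns


def window_stats(m: HaplotypeMatrix, w: WindowSpec) -> np.ndarray:
    """All 11 statistics on the window [w.start, w.end) of ``m``.

    Columns are restricted to the window and sites monomorphic within it
    dropped; π and S are per window.  Returns a vector in STAT_NAMES order
    (NaN entries mark per-statistic degeneracy).
    """
    keep = (m.positions >= w.start) & (m.positions < w.end)
    sub = HaplotypeMatrix(matrix=np.ascontiguousarray(m.matrix[:, keep]),
                          positions=m.positions[keep],
                          span=(w.start, w.end))
    return compute_summary(sub)


def compute_summary(m) -> np.ndarray:
    """Summary vector in STAT_NAMES order (NaN = degenerate statistic)."""
    S, pi, hap_div = basic_stats(m)
    td = tajimas_d(m)
    fld, flf = fu_li_d_f(m)
    wb, wq = walls_b_q(m)
    zns, za, zz = ld_stats(m)
    return np.array([S, pi, td, fld, flf, hap_div, wb, wq, za, zz, zns],
                    dtype=np.float64)


def is_degenerate(v: np.ndarray) -> bool:
    """True when any statistic in the vector is undefined."""
    return bool(np.isnan(v).any())
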