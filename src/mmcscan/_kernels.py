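"""Compiled inner loops of the forward simulator.

The population is a double-buffered, C-contiguous uint8 matrix of
``2N x cap`` derived-allele indicators, viewed both byte-wise and as uint64
words so a child haplotype is copied as a handful of word moves.  Columns at
index >= n_sites are kept zero in BOTH buffers at all times (mutations can
then claim a new column without touching the other 2N-1 rows), which is why
compaction zeroes the freed tail in the spare buffer as well.

All randomness comes from an explicit xorshift128+ state so that replicates
are bit-reproducible for a given seed, independent of global RNG state.
"""

import numpy as np
from numba import njit

U64 = np.uint64

# epoch modes
NEUTRAL = 0
SELECTION = 1
PSI = 2

# epoch exit status
DONE = 0          # ran the requested number of generations
FIXED = 1         # tracked allele reached frequency 1
LOST = 2          # tracked allele reached frequency 0
CAPACITY = 3      # site buffer full; caller must compact and resume


@njit(cache=True, inline="always")
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << U64(23)
    s1 ^= s1 >> U64(17)
    s1 ^= s0
    s1 ^= s0 >> U64(26)
    state[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def _rand_u01(state):
    return (_next_u64(state) >> U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _rand_below(state, n):
    # Lemire multiply-shift on the high 32 bits; n < 2^32
    return np.int64(((_next_u64(state) >> U64(32)) * U64(n)) >> U64(32))


@njit(cache=True)
def _poisson(state, lam):
    """Knuth sampler, chunked so the product never underflows."""
    if lam <= 0.0:
        return 0
    total = 0
    rem = lam
    while rem > 25.0:
        limit = np.exp(-25.0)
        k = 0
        p = 1.0
        while True:
            p *= _rand_u01(state)
            if p <= limit:
                break
            k += 1
        total += k
        rem -= 25.0
    limit = np.exp(-rem)
    k = 0
    p = 1.0
    while True:
        p *= _rand_u01(state)
        if p <= limit:
            break
        k += 1
    return total + k


@njit(cache=True)
def seed_state(seed):
    """Initialise a 2-word xorshift128+ state via splitmix64."""
    state = np.empty(2, dtype=np.uint64)
    z = U64(seed) + U64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = z + U64(0x9E3779B97F4A7C15)
        x = z
        x = (x ^ (x >> U64(30))) * U64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> U64(27))) * U64(0x94D049BB133111EB)
        x = x ^ (x >> U64(31))
        state[i] = x
    if state[0] == U64(0) and state[1] == U64(0):
        state[0] = U64(1)
    return state


@njit(cache=True)
def run_epoch(cur8, oth8, cur64, oth64, W, pos, n_sites,
              n_par_hap, n_child_hap, L, rho, mu,
              mode, tracked, s_coef, h_dom, psi_slots,
              max_gens, compact_every, stop_on_absorb, state,
              parent_buf, strand_buf, counts, dest, cum_fit, carriers,
              ev_child, ev_bp):
    """Run up to ``max_gens`` Wright-Fisher generations in one compiled loop.

    Returns ``(n_sites, gens_done, status, tracked)``.  On return the current
    population always lives in ``cur8``/``cur64``.
    """
    cap = 8 * W
    stride = 8 * W            # byte stride between rows
    lam_rec = rho * (L - 1.0)
    lam_mut = mu * L
    n_par_ind = n_par_hap // 2
    in_primary = True
    gens_done = 0
    status = DONE
    ev_cap = ev_child.shape[0]

    for g in range(max_gens):
        # ---- per-generation parent weighting -------------------------------
        total_fit = 0.0
        if mode == SELECTION:
            for i in range(n_par_ind):
                gcount = (cur8[2 * i * stride + tracked]
                          + cur8[(2 * i + 1) * stride + tracked])
                if gcount == 0:
                    w = 1.0
                elif gcount == 1:
                    w = 1.0 + h_dom * s_coef
                else:
                    w = 1.0 + s_coef
                total_fit += w
                cum_fit[i] = total_fit
        psi_parent = -1
        if mode == PSI:
            n_car = 0
            for i in range(n_par_ind):
                if (cur8[2 * i * stride + tracked]
                        + cur8[(2 * i + 1) * stride + tracked]) > 0:
                    carriers[n_car] = i
                    n_car += 1
            if n_car == 0:
                status = LOST
                break
            psi_parent = carriers[_rand_below(state, n_car)]

        # ---- event counts drawn first so the word-copy covers new columns --
        K = _poisson(state, n_child_hap * lam_rec)
        if K > ev_cap:
            K = ev_cap
        M = _poisson(state, n_child_hap * lam_mut)
        if n_sites + M > cap:
            status = CAPACITY
            break
        nw = (n_sites + M + 7) // 8

        # ---- reproduction --------------------------------------------------
        for j in range(n_child_hap):
            if mode == PSI and j < psi_slots:
                p = psi_parent
                row = 2 * p + _rand_below(state, 2)
            elif mode == SELECTION:
                u = _rand_u01(state) * total_fit
                lo = 0
                hi = n_par_ind - 1
                while lo < hi:
                    mid = (lo + hi) >> 1
                    if cum_fit[mid] < u:
                        lo = mid + 1
                    else:
                        hi = mid
                row = 2 * lo + _rand_below(state, 2)
            else:
                row = _rand_below(state, n_par_hap)
            parent_buf[j] = row >> 1
            strand_buf[j] = row & 1
            jb = j * W
            rb = row * W
            for k in range(nw):
                oth64[jb + k] = cur64[rb + k]

        # ---- recombination: rebuild each crossover child's gamete ----------
        for i in range(K):
            ev_child[i] = _rand_below(state, n_child_hap)
            ev_bp[i] = 1 + _rand_below(state, L - 1)
        for i in range(K):
            j = ev_child[i]
            seen = False
            for i2 in range(i):
                if ev_child[i2] == j:
                    seen = True
                    break
            if seen:
                continue
            p = parent_buf[j]
            st = strand_buf[j]
            r0 = (2 * p + st) * stride
            r1 = (2 * p + (1 - st)) * stride
            jrow = j * stride
            for k in range(n_sites):
                cnt = 0
                for i2 in range(K):
                    if ev_child[i2] == j and ev_bp[i2] <= pos[k]:
                        cnt += 1
                if cnt & 1:
                    oth8[jrow + k] = cur8[r1 + k]
                else:
                    oth8[jrow + k] = cur8[r0 + k]

        # ---- mutation (infinite sites on discrete positions) ---------------
        for _ in range(M):
            j = _rand_below(state, n_child_hap)
            while True:
                site = _rand_below(state, L)
                hit = False
                for k in range(n_sites):
                    if pos[k] == site:
                        hit = True
                        break
                if not hit:
                    break
            pos[n_sites] = site
            oth8[j * stride + n_sites] = 1
            n_sites += 1

        # ---- swap buffers ---------------------------------------------------
        t64 = cur64; cur64 = oth64; oth64 = t64
        t8 = cur8; cur8 = oth8; oth8 = t8
        in_primary = not in_primary
        gens_done = g + 1

        # ---- tracked-allele bookkeeping ------------------------------------
        if tracked >= 0 and stop_on_absorb:
            c = 0
            for j in range(n_child_hap):
                c += cur8[j * stride + tracked]
            if c == 0:
                status = LOST
                break
            if c == n_child_hap:
                status = FIXED
                break

        # ---- periodic compaction of fixed/lost columns ---------------------
        if n_sites > cap - 16 or (g % compact_every) == (compact_every - 1):
            for k in range(n_sites):
                counts[k] = 0
            for j in range(n_child_hap):
                jb = j * stride
                for k in range(n_sites):
                    counts[k] += cur8[jb + k]
            w = 0
            for k in range(n_sites):
                if (0 < counts[k] < n_child_hap) or k == tracked:
                    dest[k] = w
                    w += 1
                else:
                    dest[k] = -1
            if w < n_sites:
                if tracked >= 0:
                    tracked = dest[tracked]
                hw = 8 * ((n_sites + 7) // 8)
                newpos = w  # reuse: write pos in place (dest[k] <= k)
                for k in range(n_sites):
                    if dest[k] >= 0:
                        pos[dest[k]] = pos[k]
                for j in range(n_child_hap):
                    jb = j * stride
                    for k in range(n_sites):
                        d = dest[k]
                        if d >= 0 and d != k:
                            cur8[jb + d] = cur8[jb + k]
                    # zero freed tail in BOTH buffers: the spare buffer holds
                    # stale columns that would re-enter via future word-copies
                    for k in range(w, hw):
                        cur8[jb + k] = 0
                        oth8[jb + k] = 0
                n_sites = newpos

    # ---- make sure the population ends in the primary buffer ---------------
    if not in_primary:
        for j in range(n_child_hap):
            jb = j * W
            for k in range(W):
                oth64[jb + k] = cur64[jb + k]
    return n_sites, gens_done, status, tracked


@njit(cache=True)
def column_count(geno8, stride, col, n_hap):
    c = 0
    for j in range(n_hap):
        c += geno8[j * stride + col]
    return c
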