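"""Numba kernels: vectorized gene dropping and the BRR Gibbs sampler.

Both kernels are deterministic given their explicit inputs: the meiosis
kernel receives all random draws (parent picks, crossover counts and
positions, starting chromatids) as arrays generated by the caller from a
numpy Generator, and the Gibbs kernel seeds numba's internal RNG from an
explicit integer seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["drop_gametes", "brr_gibbs"]


@njit(cache=True)
def drop_gametes(parent_haps, parent_idx, start_chrom, cx_pos, cx_off, pos, chrom_start, out):
    """Produce gametes for a batch of meioses.

    parent_haps : (n_parents, 2, L) uint8 haplotypes
    parent_idx  : (G,) parent row per gamete
    start_chrom : (G, n_chrom) uint8, chromatid carried at the left end
    cx_pos      : flat crossover positions, blocked per (gamete, chromosome);
                  blocks need not be sorted (sorted in place here)
    cx_off      : (G*n_chrom+1,) block offsets into cx_pos
    pos         : (L,) locus positions in cM, sorted within chromosome
    chrom_start : (n_chrom+1,) locus index offsets per chromosome
    out         : (G, L) uint8, written in place

    A gamete copies the current chromatid locus-by-locus and switches
    chromatid at each crossover (no interference; positions are uniform on
    the map, counts supplied by the caller, Poisson(1) per chromosome in
    this program).
    """
    G = parent_idx.size
    n_chrom = chrom_start.size - 1
    for g in range(G):
        p = parent_idx[g]
        for c in range(n_chrom):
            lo = chrom_start[c]
            hi = chrom_start[c + 1]
            cur = start_chrom[g, c]
            k0 = cx_off[g * n_chrom + c]
            k1 = cx_off[g * n_chrom + c + 1]
            for i in range(k0 + 1, k1):  # insertion sort of the block
                v = cx_pos[i]
                j = i - 1
                while j >= k0 and cx_pos[j] > v:
                    cx_pos[j + 1] = cx_pos[j]
                    j -= 1
                cx_pos[j + 1] = v
            seg = lo
            for b in range(k0, k1):
                x = cx_pos[b]
                a, bnd = seg, hi
                while a < bnd:  # first locus with pos >= x
                    m = (a + bnd) >> 1
                    if pos[m] < x:
                        a = m + 1
                    else:
                        bnd = m
                for l in range(seg, a):
                    out[g, l] = parent_haps[p, cur, l]
                seg = a
                cur ^= 1
            for l in range(seg, hi):
                out[g, l] = parent_haps[p, cur, l]


@njit(cache=True)
def brr_gibbs(XT, y, x2, n_iter, burn_in, S_e, df_e, S_a, df_a, seed, fix_var, s2e0, s2a0):
    """Single-site Gibbs sampler for Bayesian ridge regression.

    Model: y = mu + X a + e with a_j ~ N(0, s2a) iid, flat prior on mu and
    scaled-inverse-chi2 priors on the variances (draws S/chi2_df).  Marker
    updates use residual updating, O(n) per marker.  With ``fix_var`` the
    variance components stay at (s2e0, s2a0), which makes the posterior
    mean of ``a`` the closed-form ridge solution (used as an oracle check).

    XT is the centered design transposed, C-contiguous (p, n); x2 its row
    sums of squares.  Returns posterior means (a, mu, s2e, s2a).
    """
    p, n = XT.shape
    np.random.seed(seed)
    a = np.zeros(p)
    mu = y.mean()
    e = y - mu
    s2e = s2e0
    s2a = s2a0
    a_sum = np.zeros(p)
    mu_sum = 0.0
    s2e_sum = 0.0
    s2a_sum = 0.0
    kept = 0
    for it in range(n_iter):
        em = 0.0
        for i in range(n):
            em += e[i]
        mu_new = mu + em / n + np.random.normal() * np.sqrt(s2e / n)
        d = mu_new - mu
        for i in range(n):
            e[i] -= d
        mu = mu_new
        lam = s2e / s2a
        for j in range(p):
            aj = a[j]
            rhs = x2[j] * aj
            for i in range(n):
                rhs += XT[j, i] * e[i]
            cj = x2[j] + lam
            anew = rhs / cj + np.random.normal() * np.sqrt(s2e / cj)
            d = anew - aj
            if d != 0.0:
                for i in range(n):
                    e[i] -= XT[j, i] * d
            a[j] = anew
        if not fix_var:
            ssa = 0.0
            for j in range(p):
                ssa += a[j] * a[j]
            s2a = (ssa + S_a) / np.random.chisquare(df_a + p)
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            s2e = (sse + S_e) / np.random.chisquare(df_e + n)
        if it >= burn_in:
            kept += 1
            for j in range(p):
                a_sum[j] += a[j]
            mu_sum += mu
            s2e_sum += s2e
            s2a_sum += s2a
    inv = 1.0 / kept
    return a_sum * inv, mu_sum * inv, s2e_sum * inv, s2a_sum * inv
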