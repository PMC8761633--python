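"""Jitted dynamic-programming fill for nested minimum-free-energy folding.

Energies are integers in centi-kcal/mol so that ties are exact. The fill
minimises the pair (energy, -pair_count) lexicographically; the final
lexicographic dot-bracket tie-break happens in the Python traceback.
"""
from __future__ import annotations

import numpy as np
from numba import njit

INF = 1 << 28  # sentinel; safe against int32 overflow even when summed twice


@njit(cache=True)
def fill_tables(seq, pair_idx, stack, hp_pen, bulge_pen, internal_pen,
                ml_a, ml_b, ml_c, min_hp, maxloop):
    """Fill V (i,j paired), WM (multiloop segment, >=1 branch) and the
    external suffix table Wsuf, together with pair-count companions."""
    n = seq.shape[0]
    V = np.full((n, n), INF, dtype=np.int32)
    Vp = np.zeros((n, n), dtype=np.int32)
    WM = np.full((n, n), INF, dtype=np.int32)
    WMp = np.zeros((n, n), dtype=np.int32)

    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            p = pair_idx[seq[i], seq[j]]
            if p >= 0 and d > min_hp:
                best_e = hp_pen[d - 1]
                best_p = 1
                # two-sided interior/bulge/stack extension
                for s1 in range(0, maxloop + 1):
                    k = i + 1 + s1
                    if k > j - min_hp - 2:
                        break
                    lmin = k + min_hp + 1
                    lo = j - 1 - (maxloop - s1)
                    if lo > lmin:
                        lmin = lo
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        s2 = j - 1 - l
                        if s1 == 0 and s2 == 0:
                            cost = stack[p, pair_idx[seq[k], seq[l]]]
                        elif s1 == 0 or s2 == 0:
                            cost = bulge_pen[s1 + s2]
                        else:
                            cost = internal_pen[s1 + s2]
                        e = V[k, l] + cost
                        pr = Vp[k, l] + 1
                        if e < best_e or (e == best_e and pr > best_p):
                            best_e = e
                            best_p = pr
                # multiloop closed by (i, j): >=2 inner branches
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        e = ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1]
                        pr = 1 + WMp[i + 1, k] + WMp[k + 1, j - 1]
                        if e < best_e or (e == best_e and pr > best_p):
                            best_e = e
                            best_p = pr
                V[i, j] = best_e
                Vp[i, j] = best_p
            # WM over [i, j]
            be = INF
            bp = 0
            if V[i, j] < INF:
                be = V[i, j] + ml_b
                bp = Vp[i, j]
            if WM[i + 1, j] < INF:
                e = WM[i + 1, j] + ml_c
                pr = WMp[i + 1, j]
                if e < be or (e == be and pr > bp):
                    be = e
                    bp = pr
            if WM[i, j - 1] < INF:
                e = WM[i, j - 1] + ml_c
                pr = WMp[i, j - 1]
                if e < be or (e == be and pr > bp):
                    be = e
                    bp = pr
            for k in range(i + 1, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    e = WM[i, k] + WM[k + 1, j]
                    pr = WMp[i, k] + WMp[k + 1, j]
                    if e < be or (e == be and pr > bp):
                        be = e
                        bp = pr
            if be < INF:
                WM[i, j] = be
                WMp[i, j] = bp

    Wsuf = np.zeros(n + 1, dtype=np.int32)
    Wp = np.zeros(n + 1, dtype=np.int32)
    for i in range(n - 1, -1, -1):
        be = Wsuf[i + 1]
        bp = Wp[i + 1]
        for k in range(i + min_hp + 1, n):
            if V[i, k] < INF:
                e = V[i, k] + Wsuf[k + 1]
                pr = Vp[i, k] + Wp[k + 1]
                if e < be or (e == be and pr > bp):
                    be = e
                    bp = pr
        Wsuf[i] = be
        Wp[i] = bp

    return V, Vp, WM, WMp, Wsuf, Wp
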