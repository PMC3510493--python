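"""Numba-compiled dynamic-programming kernels.

Two kernels live here:

* :func:`inside_partition` — McCaskill-style inside recursion over nested
  secondary structures (canonical pairs, min hairpin loop, bounded
  interior/bulge loops, affine multiloops, optional base-pair span limit and
  forced-unpaired constraints, both encoded in the pair-type matrix).
  Returns the full partition function Z with the open chain contributing 1.

* :func:`duplex_dp` — intermolecular hybrid-only DP: for every pair (i, j)
  of positions (sRNA index vs reversed-target index) the minimum energy of a
  duplex ending at that pair (``L``) and of an extension starting at that
  pair (``R``), with traceback predecessors/successors.  Seed anchoring and
  tie-breaking are composed on top of these tables in :mod:`srnascreen.interact`.

All energy parameters arrive as plain floats/arrays (kcal/mol); sequences as
int8 codes; pair-type matrices as int8 with -1 marking a disallowed pair.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["inside_partition", "duplex_dp", "pair_type_matrix", "cross_pair_types"]

from .energy import PAIR_TYPE


def pair_type_matrix(codes: np.ndarray, max_span: int | None,
                     unpaired: np.ndarray | None = None) -> np.ndarray:
    """Intramolecular pair-type matrix.

    ``ptype[i, j]`` (i < j) is the canonical pair type of (codes[i], codes[j])
    or -1 if the pair is non-canonical, exceeds ``max_span`` (defined as
    ``j - i``), or touches a forced-unpaired position.
    """
    n = len(codes)
    pt = PAIR_TYPE[np.asarray(codes)[:, None], np.asarray(codes)[None, :]].copy()
    idx = np.arange(n)
    span = idx[None, :] - idx[:, None]
    pt[span <= 0] = -1
    if max_span is not None:
        pt[span > max_span] = -1
    if unpaired is not None and len(unpaired):
        u = np.asarray(unpaired, dtype=np.intp)
        pt[u, :] = -1
        pt[:, u] = -1
    return pt


def cross_pair_types(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Intermolecular pair-type matrix: ``pt[i, j]`` for (a[i], b[j])."""
    return PAIR_TYPE[np.asarray(codes_a)[:, None], np.asarray(codes_b)[None, :]].copy()


@njit(cache=True)
def inside_partition(ptype, n, stack, ha, hb, ba, bb, ia, ib,
                     mla, mlb, mlc, RT, max_int, min_hairpin):
    """Inside recursion; returns Z (>= 1, open chain included)."""
    Zb = np.zeros((n, n))
    Zm1 = np.zeros((n, n))
    Zm = np.zeros((n, n))
    qc = np.exp(-mlc / RT)      # per unpaired multiloop nt
    qbr = np.exp(-mlb / RT)     # per branch
    qclose = np.exp(-(mla + mlb) / RT)   # multiloop init + closing branch

    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            pt = ptype[i, j]
            if pt >= 0 and d - 1 >= min_hairpin:
                acc = np.exp(-(ha + hb * (d - 1)) / RT)
                kmax = min(i + 1 + max_int, j - 1)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = max(k + 1, j - 1 - max_int)
                    for l in range(j - 1, lmin - 1, -1):
                        if ptype[k, l] >= 0 and Zb[k, l] > 0.0:
                            l2 = j - l - 1
                            if l1 == 0 and l2 == 0:
                                e = stack[pt, ptype[k, l]]
                            elif l1 == 0 or l2 == 0:
                                e = ba + bb * (l1 + l2)
                            else:
                                e = ia + ib * (l1 + l2)
                            acc += np.exp(-e / RT) * Zb[k, l]
                # multiloop closed by (i, j): >= 2 enclosed branches
                s = 0.0
                for h in range(i + 2, j - 1):
                    if Zm[i + 1, h - 1] > 0.0 and Zm1[h, j - 1] > 0.0:
                        s += Zm[i + 1, h - 1] * Zm1[h, j - 1]
                acc += qclose * s
                Zb[i, j] = acc
            # Zm1: exactly one branch starting at i, trailing unpaired to j
            Zm1[i, j] = Zm1[i, j - 1] * qc + Zb[i, j] * qbr
            # Zm: >= 1 branch in [i, j], leading unpaired allowed
            Zm[i, j] = Zm1[i, j] + qc * (Zm[i + 1, j] if i + 1 <= j else 0.0)

    Ze = np.zeros(n + 1)
    Ze[0] = 1.0
    for j in range(n):
        acc = Ze[j]
        for i in range(0, j):
            if Zb[i, j] > 0.0:
                acc += Ze[i] * Zb[i, j]
        Ze[j + 1] = acc
    return Ze[n]


@njit(cache=True)
def duplex_dp(ptype, stack, dinit, ba, bb, ia, ib, max_int):
    """Hybrid-only duplex DP on an (la, lb) cross pair-type matrix.

    Returns (L, predL, R, succR):
      L[i, j]    minimum energy of a duplex whose 3'-most pair is (i, j),
                 duplex initiation included;
      R[i, j]    minimum additional energy of extending 3' from pair (i, j);
      predL/succR  flat-index (k * lb + l) traceback pointers, -1 = none.
    """
    la, lb = ptype.shape
    INF = 1e30
    L = np.full((la, lb), INF)
    predL = np.full((la, lb), -1, dtype=np.int64)
    R = np.full((la, lb), INF)
    succR = np.full((la, lb), -1, dtype=np.int64)

    for i in range(la):
        for j in range(lb):
            if ptype[i, j] < 0:
                continue
            best = dinit
            bestp = -1
            kmin = max(0, i - 1 - max_int)
            lmin = max(0, j - 1 - max_int)
            for k in range(kmin, i):
                g1 = i - k - 1
                for l in range(lmin, j):
                    if ptype[k, l] < 0 or L[k, l] >= INF:
                        continue
                    g2 = j - l - 1
                    if g1 == 0 and g2 == 0:
                        e = stack[ptype[k, l], ptype[i, j]]
                    elif g1 == 0 or g2 == 0:
                        e = ba + bb * (g1 + g2)
                    else:
                        e = ia + ib * (g1 + g2)
                    cand = L[k, l] + e
                    if cand < best - 1e-12:
                        best = cand
                        bestp = k * lb + l
            L[i, j] = best
            predL[i, j] = bestp

    for i in range(la - 1, -1, -1):
        for j in range(lb - 1, -1, -1):
            if ptype[i, j] < 0:
                continue
            best = 0.0
            bestp = -1
            kmax = min(la - 1, i + 1 + max_int)
            lmax = min(lb - 1, j + 1 + max_int)
            for k in range(i + 1, kmax + 1):
                g1 = k - i - 1
                for l in range(j + 1, lmax + 1):
                    if ptype[k, l] < 0 or R[k, l] >= INF:
                        continue
                    g2 = l - j - 1
                    if g1 == 0 and g2 == 0:
                        e = stack[ptype[i, j], ptype[k, l]]
                    elif g1 == 0 or g2 == 0:
                        e = ba + bb * (g1 + g2)
                    else:
                        e = ia + ib * (g1 + g2)
                    cand = e + R[k, l]
                    if cand < best - 1e-12:
                        best = cand
                        bestp = k * lb + l
            R[i, j] = best
            succR[i, j] = bestp

    return L, predL, R, succR
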