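"""Independent brute-force oracles used by the test suite.

Everything here is written naively (explicit enumeration / plain recursion,
pure Python) and shares no code with the package's dynamic-programming
kernels, so agreement is a meaningful check.
"""

from __future__ import annotations

import math
from functools import lru_cache

from srnascreen.energy import EnergyModel, pair_type

MIN_HAIRPIN = 3


# ---------------------------------------------------------------------------
# intramolecular structures
# ---------------------------------------------------------------------------

def enumerate_structures(seq, max_span=None, forced_unpaired=frozenset()):
    """All nested structures (sets of 0-based (i, j) pairs) of ``seq``.

    Canonical pairs only, ``j - i > MIN_HAIRPIN``, optional span limit,
    optional forced-unpaired positions.  Includes the open chain.
    """
    n = len(seq)

    def pairable(i, j):
        if j - i <= MIN_HAIRPIN:
            return False
        if max_span is not None and j - i > max_span:
            return False
        if i in forced_unpaired or j in forced_unpaired:
            return False
        return pair_type(seq[i], seq[j]) >= 0

    @lru_cache(maxsize=None)
    def region(i, j):
        # structures of [i, j] inclusive
        if i > j:
            return (frozenset(),)
        out = []
        for s in region(i + 1, j):          # i unpaired
            out.append(s)
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if pairable(i, k):
                for inner in region(i + 1, k - 1):
                    for rest in region(k + 1, j):
                        out.append(inner | rest | {(i, k)})
        return tuple(out)

    return list(region(0, n - 1))


def structure_energy(seq, pairs, model: EnergyModel) -> float:
    """Loop-decomposition energy of an explicit structure (math.inf if any
    loop is outside the model's limits)."""
    if not pairs:
        return 0.0
    plist = sorted(pairs)
    total = 0.0
    for (i, j) in plist:
        children = [(k, l) for (k, l) in plist
                    if i < k < l < j and not any(
                        k2 < k and l < l2 and (k2, l2) != (i, j)
                        for (k2, l2) in plist if i < k2 < l2 < j)]
        covered = sum(l - k + 1 for (k, l) in children)
        unpaired = (j - i - 1) - covered
        if not children:
            if unpaired < model.min_hairpin:
                return math.inf
            total += model.hairpin_a + model.hairpin_b * unpaired
        elif len(children) == 1:
            (k, l) = children[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                total += model.stack[pair_type(seq[i], seq[j]),
                                     pair_type(seq[k], seq[l])]
            else:
                if l1 > model.max_interior or l2 > model.max_interior:
                    return math.inf
                if l1 == 0 or l2 == 0:
                    total += model.bulge_a + model.bulge_b * (l1 + l2)
                else:
                    total += model.interior_a + model.interior_b * (l1 + l2)
        else:
            total += model.ml_a + model.ml_b * (len(children) + 1) \
                + model.ml_c * unpaired
    return total


class EnsembleOracle:
    """Exhaustive Boltzmann ensemble of one short sequence."""

    def __init__(self, seq, model: EnergyModel, max_span=None,
                 forced_unpaired=frozenset()):
        self.seq = seq
        self.model = model
        self.structures = enumerate_structures(seq, max_span,
                                               frozenset(forced_unpaired))
        self.weights = []
        for s in self.structures:
            e = structure_energy(seq, s, model)
            self.weights.append(0.0 if math.isinf(e) else math.exp(-e / model.RT))
        self.Z = sum(self.weights)

    def pair_prob(self, i, j):
        """0-based pair probability."""
        w = sum(wt for s, wt in zip(self.structures, self.weights)
                if (i, j) in s)
        return w / self.Z

    def unpaired_probability(self, interval):
        """1-based inclusive interval, to match the package API."""
        a, b = interval
        pos = set(range(a - 1, b))
        w = 0.0
        for s, wt in zip(self.structures, self.weights):
            if all(i not in pos and j not in pos for (i, j) in s):
                w += wt
        return w / self.Z


# ---------------------------------------------------------------------------
# intermolecular duplexes
# ---------------------------------------------------------------------------

def duplex_oracle(s: str, m: str, model: EnergyModel, seed_len: int):
    """Minimum energy over all legal seed-containing duplexes of ``s`` with
    ``m`` (both 5'->3'; ``m`` is scanned antiparallel), by exhaustive
    recursion over every extension with memoization.  Returns the energy or
    None if no seed-containing duplex with energy < 0 exists.
    """
    mr = m[::-1]
    la, lb = len(s), len(mr)
    gap = model.max_interior

    def pt(i, j):
        return pair_type(s[i], mr[j])

    @lru_cache(maxsize=None)
    def ext(i, j, run, flag):
        # min additional energy continuing 3' from pair (i, j); run = length
        # of the current uninterrupted stack run (capped), flag = seed seen
        best = 0.0 if (flag or run >= seed_len) else math.inf
        for k in range(i + 1, min(la, i + 2 + gap)):
            g1 = k - i - 1
            for l in range(j + 1, min(lb, j + 2 + gap)):
                if pt(k, l) < 0:
                    continue
                g2 = l - j - 1
                if g1 == 0 and g2 == 0:
                    e = model.stack[pt(i, j), pt(k, l)]
                    nrun = min(run + 1, seed_len)
                else:
                    if g1 == 0 or g2 == 0:
                        e = model.bulge_a + model.bulge_b * (g1 + g2)
                    else:
                        e = model.interior_a + model.interior_b * (g1 + g2)
                    nrun = 1
                nflag = flag or nrun >= seed_len
                cand = e + ext(k, l, nrun, nflag)
                if cand < best:
                    best = cand
        return best

    best = math.inf
    for i in range(la):
        for j in range(lb):
            if pt(i, j) >= 0:
                cand = model.duplex_init + ext(i, j, min(1, seed_len),
                                               seed_len <= 1)
                if cand < best:
                    best = cand
    return None if (math.isinf(best) or best >= 0.0) else best
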