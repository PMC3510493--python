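"""Intermolecular hybridization with a seed constraint.

The hybrid DP finds, over all antiparallel duplexes between an sRNA and a
target region (interior/bulge loops up to ``model.max_interior`` unpaired nt
per side, no intramolecular pairs inside the site), the minimum-energy duplex
that contains at least ``SeedSpec.min_consecutive_pairs`` uninterrupted
stacked pairs.  Accessibility is charged afterwards:

    E_total = E_hybrid + ED_sRNA + ED_mRNA,

with ED = -RT ln Pu the cost of opening each partner's site
(:func:`srnascreen.thermo.opening_energy`).

Positions are 1-based on each molecule's own 5'->3' sequence; a pairing is a
list of (sRNA position, target position) with sRNA ascending and target
descending (antiparallel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import cross_pair_types, duplex_dp
from .energy import EnergyModel, encode, pair_type
from .thermo import opening_energy

__all__ = ["SeedSpec", "InteractionSite", "duplex_energy", "hybridize",
           "attach_accessibility", "scan_region", "codon_relative",
           "seed_run_length"]

_GU_TYPES = (4, 5)  # indices of GU/UG in the canonical pair order


@dataclass(frozen=True)
class SeedSpec:
    """Required stretch of consecutive intermolecular base pairs."""

    min_consecutive_pairs: int = 8
    allow_gu: bool = True   # GU pairs may participate in the seed

    def __post_init__(self):
        if self.min_consecutive_pairs < 2:
            raise ValueError("seed must require >= 2 consecutive pairs")


@dataclass
class InteractionSite:
    """A predicted sRNA-target duplex with its energy decomposition."""

    srna_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    pairing: list[tuple[int, int]]
    E_hybrid: float
    ED_srna: float = 0.0
    ED_mrna: float = 0.0
    usable: bool = True
    #: target interval in start-codon-relative coordinates (+1 = first nt of
    #: the start codon, -1 immediately 5' of it; no position 0); set by the
    #: transcript scan when the codon offset is known.
    mrna_interval_codon: tuple[int, int] | None = field(default=None)

    @property
    def E_total(self) -> float:
        return self.E_hybrid + self.ED_srna + self.ED_mrna

    def pairing_string(self) -> str:
        """Compact duplex notation: ``sRNA[a-b]:mRNA[d-c]`` pair blocks."""
        blocks = []
        run = [self.pairing[0]]
        for prev, cur in zip(self.pairing, self.pairing[1:]):
            if cur[0] == prev[0] + 1 and cur[1] == prev[1] - 1:
                run.append(cur)
            else:
                blocks.append(run)
                run = [cur]
        blocks.append(run)
        return ";".join(
            f"{r[0][0]}-{r[-1][0]}:{r[0][1]}-{r[-1][1]}" for r in blocks)


def seed_run_length(pairing: list[tuple[int, int]], allow_gu: bool = True,
                    srna: str | None = None, mrna: str | None = None) -> int:
    """Longest uninterrupted stacked run in a pairing (structural check).

    With ``allow_gu=False`` (requires the sequences) GU pairs break the run.
    """
    best = run = 0
    prev = None
    for (a, b) in pairing:
        ok = True
        if not allow_gu:
            if srna is None or mrna is None:
                raise ValueError("need sequences to exclude GU from the seed")
            ok = pair_type(srna[a - 1], mrna[b - 1]) not in _GU_TYPES
        if not ok:
            run = 0
        elif prev is not None and a == prev[0] + 1 and b == prev[1] - 1 and run:
            run += 1
        else:
            run = 1
        best = max(best, run)
        prev = (a, b)
    return best


def duplex_energy(s1: str, s2: str, pairing: list[tuple[int, int]],
                  model: EnergyModel | None = None) -> float:
    """Energy of an explicitly given duplex pairing (used as an evaluator
    and cross-check; raises on an illegal pairing)."""
    model = model or EnergyModel.default()
    if not pairing:
        raise ValueError("empty pairing")
    for (a, b) in pairing:
        if not (1 <= a <= len(s1) and 1 <= b <= len(s2)):
            raise ValueError(f"pair ({a},{b}) out of bounds")
        if pair_type(s1[a - 1], s2[b - 1]) < 0:
            raise ValueError(f"non-canonical pair {s1[a-1]}-{s2[b-1]} at ({a},{b})")
    e = model.duplex_init
    for (a1, b1), (a2, b2) in zip(pairing, pairing[1:]):
        g1, g2 = a2 - a1 - 1, b1 - b2 - 1
        if g1 < 0 or g2 < 0:
            raise ValueError("pairing not monotone antiparallel")
        if g1 == 0 and g2 == 0:
            e += model.stack_energy(pair_type(s1[a1 - 1], s2[b1 - 1]),
                                    pair_type(s1[a2 - 1], s2[b2 - 1]))
        else:
            pen = model.interior_bulge_penalty(g1, g2)
            if math.isinf(pen):
                raise ValueError(f"loop ({g1},{g2}) exceeds model limits")
            e += pen
    return e


def _traceback(i, j, predL, succR, seed_len, lb):
    path = []
    k, l = i, j
    while True:
        path.append((k, l))
        p = predL[k, l]
        if p < 0:
            break
        k, l = divmod(p, lb)
    path.reverse()
    for t in range(1, seed_len):
        path.append((i + t, j + t))
    k, l = i + seed_len - 1, j + seed_len - 1
    while True:
        p = succR[k, l]
        if p < 0:
            break
        k, l = divmod(p, lb)
        path.append((k, l))
    return path


def hybridize(srna: str, region: str, model: EnergyModel | None = None,
              seed: SeedSpec | None = None,
              exclude_region: set[int] | None = None,
              exclude_srna: set[int] | None = None) -> InteractionSite | None:
    """Minimum-E_hybrid seed-containing duplex of ``srna`` with ``region``.

    Returns None when no seed-containing duplex with E_hybrid < 0 exists.
    ``exclude_region`` / ``exclude_srna`` (1-based positions) mask
    already-claimed or inaccessible positions for the greedy multi-site
    scan.  Ties are broken by longer pairing, then smaller target start,
    then smaller sRNA start.
    """
    if not srna or not region:
        raise ValueError("both sequences must be nonempty")
    model = model or EnergyModel.default()
    seed = seed or SeedSpec()
    k = seed.min_consecutive_pairs
    sc = encode(srna)
    mrev = encode(region[::-1])
    la, lb = len(sc), len(mrev)
    pt = cross_pair_types(sc, mrev)
    if exclude_region:
        cols = np.array([lb - p for p in exclude_region], dtype=np.intp)
        pt[:, cols] = -1
    if exclude_srna:
        rows = np.array([p - 1 for p in exclude_srna], dtype=np.intp)
        pt[rows, :] = -1
    if la < k or lb < k:
        return None

    L, predL, R, succR = duplex_dp(pt, model.stack, model.duplex_init,
                                   model.bulge_a, model.bulge_b,
                                   model.interior_a, model.interior_b,
                                   model.max_interior)

    seed_ok = pt >= 0
    if not seed.allow_gu:
        seed_ok &= ~np.isin(pt, _GU_TYPES)
    valid = np.ones((la - k + 1, lb - k + 1), dtype=bool)
    seedE = np.zeros((la - k + 1, lb - k + 1))
    for t in range(k):
        valid &= seed_ok[t:la - k + 1 + t, t:lb - k + 1 + t]
    for t in range(k - 1):
        p1 = pt[t:la - k + 1 + t, t:lb - k + 1 + t]
        p2 = pt[t + 1:la - k + 2 + t, t + 1:lb - k + 2 + t]
        seedE += np.where((p1 >= 0) & (p2 >= 0),
                          model.stack[np.clip(p1, 0, 5), np.clip(p2, 0, 5)], 0.0)
    total = np.where(valid,
                     L[:la - k + 1, :lb - k + 1] + seedE
                     + R[k - 1:, k - 1:], np.inf)
    if not np.any(np.isfinite(total)):
        return None
    best = float(total.min())
    if best >= -1e-12:
        return None

    anchors = np.argwhere(total <= best + 1e-9)[:200]
    candidates = {}
    for (i, j) in anchors:
        path = _traceback(int(i), int(j), predL, succR, k, lb)
        pairing = [(a + 1, lb - b) for (a, b) in path]
        candidates[tuple(pairing)] = pairing
    def rank(p):
        return (-len(p), min(b for _, b in p), p[0][0])
    pairing = min(candidates.values(), key=rank)

    site = InteractionSite(
        srna_interval=(pairing[0][0], pairing[-1][0]),
        mrna_interval=(min(b for _, b in pairing), max(b for _, b in pairing)),
        pairing=pairing,
        E_hybrid=best,
    )
    assert seed_run_length(pairing, seed.allow_gu, srna, region) >= k
    return site


def attach_accessibility(site: InteractionSite, srna_acc, mrna_acc) -> InteractionSite:
    """Fill ED terms from accessibility providers (objects with a
    ``pu(interval)`` method: an UnpairedProfile or AccessibilityCalculator).
    A site with Pu = 0 on either side is marked unusable (infinite ED)."""
    pu_s = srna_acc.pu(site.srna_interval)
    pu_m = mrna_acc.pu(site.mrna_interval)
    model = getattr(srna_acc, "model", None) or EnergyModel.default()
    ed_s = opening_energy(pu_s, model)
    ed_m = opening_energy(pu_m, model)
    return replace(site, ED_srna=ed_s, ED_mrna=ed_m,
                   usable=math.isfinite(ed_s) and math.isfinite(ed_m))


def codon_relative(pos: int, codon_offset: int) -> int:
    """Transcript-local position -> start-codon-relative (+1 = first codon
    nt, -1 immediately 5' of it; there is no 0)."""
    return pos - codon_offset + 1 if pos >= codon_offset else pos - codon_offset


def scan_region(srna: str, region: str, model: EnergyModel | None = None,
                seed: SeedSpec | None = None, *, codon_offset: int | None = None,
                max_sites: int = 3, srna_acc=None, mrna_acc=None) -> list[InteractionSite]:
    """Greedy non-overlapping site scan of a prepared search region.

    Sites are discovered best-first by E_hybrid, claimed target positions are
    masked, accessibility is attached when calculators are provided, and the
    result is reported in ascending E_total.  ``codon_offset`` (region-local
    position of the first start-codon nt) adds start-codon-relative target
    coordinates to each site.
    """
    model = model or EnergyModel.default()
    seed = seed or SeedSpec()
    sites: list[InteractionSite] = []
    rejected: list[InteractionSite] = []
    claimed_m: set[int] = set()
    claimed_s: set[int] = set()
    with_ed = srna_acc is not None and mrna_acc is not None
    for _ in range(8 * max_sites):
        if len(sites) >= max_sites:
            break
        site = hybridize(srna, region, model, seed,
                         exclude_region=claimed_m, exclude_srna=claimed_s)
        if site is None:
            break
        if with_ed:
            site = attach_accessibility(site, srna_acc, mrna_acc)
        if codon_offset is not None:
            site.mrna_interval_codon = (
                codon_relative(site.mrna_interval[0], codon_offset),
                codon_relative(site.mrna_interval[1], codon_offset))
        if with_ed and not (site.usable and site.E_total < 0):
            # Site buried in intramolecular structure: mask the paired
            # positions of the blocking side that are themselves
            # inaccessible (per-position Pu < 0.5) and rescan; an
            # accessible sub-segment (e.g. a linker surface chained to stem
            # segments in one sprawling duplex) stays available.
            rejected.append(site)
            if site.ED_srna >= site.ED_mrna:
                pos = [a for a, _ in site.pairing]
                low = {p for p in pos if srna_acc.pu((p, p)) < 0.5}
                claimed_s.update(low or set(range(site.srna_interval[0],
                                                  site.srna_interval[1] + 1)))
            else:
                pos = [b for _, b in site.pairing]
                low = {p for p in pos if mrna_acc.pu((p, p)) < 0.5}
                claimed_m.update(low or set(range(site.mrna_interval[0],
                                                  site.mrna_interval[1] + 1)))
            continue
        claimed_m.update(range(site.mrna_interval[0], site.mrna_interval[1] + 1))
        sites.append(site)
    sites.sort(key=lambda s: (s.E_total, s.mrna_interval))
    if not sites and rejected:
        # keep the least-bad rejected site as evidence for reporting
        sites = [min(rejected, key=lambda s: (s.E_total, s.mrna_interval))]
    return sites
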