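"""Intramolecular ensemble thermodynamics.

Partition function over nested secondary structures, unpaired (accessibility)
probabilities, RNAplfold-style local-folding profiles and forced-unpaired
constraints.

Model: canonical pairs only (AU, UA, GC, CG, GU, UG), minimum hairpin loop of
3 nt, no pseudoknots, lonely pairs allowed, interior/bulge loops bounded at
``model.max_interior`` unpaired nt per side, affine multiloops, optional
base-pair span limit (a pair (i, j) is allowed when ``j - i <= max_span``).

The accessibility of an interval is the ensemble probability that every one
of its positions is unpaired,

    Pu(I) = Z(I forced unpaired) / Z,

the free-energy cost of opening it being ED = -RT ln Pu.

Coordinates in this module's public API are 1-based inclusive, matching the
rest of the package; the open chain contributes 1 to every Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from ._kernels import inside_partition, pair_type_matrix
from .energy import EnergyModel, encode

__all__ = [
    "FoldConstraint",
    "EnsembleSummary",
    "UnpairedProfile",
    "AccessibilityCalculator",
    "partition_function",
    "unpaired_probability",
    "local_accessibility_profile",
    "opening_energy",
]

# Z for a 100-nt window with the default parameters stays far below this;
# a global fold of a very long sequence could overflow float64.
_OVERFLOW_MSG = (
    "partition function overflowed float64; fold locally with a window "
    "(local_accessibility_profile / AccessibilityCalculator) instead"
)


@dataclass(frozen=True)
class FoldConstraint:
    """Positions (1-based) forced to remain unpaired."""

    forced_unpaired: frozenset[int] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "forced_unpaired",
                           frozenset(self.forced_unpaired))

    @classmethod
    def from_intervals(cls, *intervals: tuple[int, int]) -> "FoldConstraint":
        pos: set[int] = set()
        for a, b in intervals:
            pos.update(range(a, b + 1))
        return cls(frozenset(pos))

    def merged(self, other: "FoldConstraint | None") -> "FoldConstraint":
        if other is None:
            return self
        return FoldConstraint(self.forced_unpaired | other.forced_unpaired)

    def check_bounds(self, n: int) -> None:
        for p in self.forced_unpaired:
            if not 1 <= p <= n:
                raise ValueError(f"constraint position {p} outside 1..{n}")


def _run_inside(codes: np.ndarray, model: EnergyModel, max_span: int | None,
                unpaired0: np.ndarray | None,
                forbid_pair0: tuple[int, int] | None = None) -> float:
    pt = pair_type_matrix(codes, max_span, unpaired0)
    if forbid_pair0 is not None:
        pt[forbid_pair0[0], forbid_pair0[1]] = -1
    z = inside_partition(
        pt, len(codes), model.stack,
        model.hairpin_a, model.hairpin_b, model.bulge_a, model.bulge_b,
        model.interior_a, model.interior_b,
        model.ml_a, model.ml_b, model.ml_c,
        model.RT, model.max_interior, model.min_hairpin,
    )
    if not math.isfinite(z):
        raise OverflowError(_OVERFLOW_MSG)
    return z


def _constraint_array(constraint: FoldConstraint | None, n: int) -> np.ndarray | None:
    if constraint is None or not constraint.forced_unpaired:
        return None
    constraint.check_bounds(n)
    return np.array(sorted(p - 1 for p in constraint.forced_unpaired), dtype=np.intp)


class EnsembleSummary:
    """Partition function and derived probabilities for one sequence.

    Pair probabilities are computed lazily and exactly as
    ``P(i,j) = (Z - Z[pair (i,j) forbidden]) / Z`` (one inside recursion per
    queried pair), since the pipeline itself only consumes interval unpaired
    probabilities.
    """

    def __init__(self, codes: np.ndarray, model: EnergyModel,
                 max_span: int | None, unpaired0: np.ndarray | None, Z: float):
        self._codes = codes
        self._model = model
        self._max_span = max_span
        self._unpaired0 = unpaired0
        self.Z = Z
        self.length = len(codes)
        self._pp_cache: dict[tuple[int, int], float] = {}

    def pair_probability(self, i: int, j: int) -> float:
        """Probability that positions ``i < j`` (1-based) are paired."""
        if not (1 <= i < j <= self.length):
            raise ValueError("need 1 <= i < j <= length")
        key = (i, j)
        if key not in self._pp_cache:
            zf = _run_inside(self._codes, self._model, self._max_span,
                             self._unpaired0, forbid_pair0=(i - 1, j - 1))
            self._pp_cache[key] = max(0.0, (self.Z - zf) / self.Z)
        return self._pp_cache[key]

    @cached_property
    def pair_prob(self) -> dict[tuple[int, int], float]:
        """Full (i, j) -> probability map (quadratic in length; test aid)."""
        return {
            (i, j): self.pair_probability(i, j)
            for i in range(1, self.length)
            for j in range(i + 1, self.length + 1)
        }

    def unpaired_probability(self, interval: tuple[int, int]) -> float:
        a, b = interval
        if a > b:
            return 1.0
        if not (1 <= a and b <= self.length):
            raise ValueError(f"interval {interval} outside 1..{self.length}")
        extra = np.arange(a - 1, b, dtype=np.intp)
        if self._unpaired0 is not None:
            extra = np.unique(np.concatenate([self._unpaired0, extra]))
        zc = _run_inside(self._codes, self._model, self._max_span, extra)
        return min(1.0, zc / self.Z)


def partition_function(seq: str, model: EnergyModel | None = None,
                       max_span: int | None = None,
                       constraint: FoldConstraint | None = None) -> EnsembleSummary:
    """Boltzmann ensemble of one sequence (optionally span-limited/constrained)."""
    if len(seq) < 1:
        raise ValueError("sequence must have length >= 1")
    model = model or EnergyModel.default()
    codes = encode(seq)
    unp = _constraint_array(constraint, len(seq))
    z = _run_inside(codes, model, max_span, unp)
    return EnsembleSummary(codes, model, max_span, unp, z)


def unpaired_probability(seq: str, interval: tuple[int, int],
                         model: EnergyModel | None = None,
                         max_span: int | None = None,
                         constraint: FoldConstraint | None = None) -> float:
    """P(every position of ``interval`` unpaired); 1.0 for an empty interval."""
    return partition_function(seq, model, max_span, constraint).unpaired_probability(interval)


def opening_energy(pu: float, model: EnergyModel) -> float:
    """ED = -RT ln Pu (kcal/mol); ``inf`` marks an unusable (Pu <= 0) site."""
    if pu > 1.0 + 1e-12:
        raise ValueError("Pu must be <= 1")
    if pu <= 0.0:
        return math.inf
    return max(0.0, -model.RT * math.log(min(pu, 1.0)))


@dataclass
class UnpairedProfile:
    """Per-interval unpaired probabilities under the local-folding scheme."""

    window: int
    max_span: int
    probe_len: int
    Pu: dict[tuple[int, int], float] = field(default_factory=dict)

    def pu(self, interval: tuple[int, int]) -> float:
        try:
            return self.Pu[tuple(interval)]
        except KeyError:
            raise KeyError(f"interval {interval} not covered by profile") from None


class AccessibilityCalculator:
    """Window-averaged accessibility of arbitrary intervals of one sequence.

    The sequence is folded in sliding windows of ``window`` nt (base-pair
    span <= ``max_span``); Pu of an interval is the mean of the constrained
    Z ratio over all windows that fully contain it.  ``step`` thins the
    window grid (coarser averaging, same estimator); ``mode="single"`` uses
    only the window centered on the interval.  Truncated windows are used
    when the sequence is shorter than the window; nothing is ever padded.

    Unconstrained window partition functions are cached, so repeated interval
    queries (as the screen issues) cost one constrained fold per window.
    """

    def __init__(self, seq: str, model: EnergyModel | None = None,
                 window: int = 100, max_span: int = 50, step: int = 1,
                 mode: str = "averaged"):
        if window < max_span:
            raise ValueError("window must be >= max_span")
        if mode not in ("averaged", "single"):
            raise ValueError("mode must be 'averaged' or 'single'")
        self.seq = seq
        self.model = model or EnergyModel.default()
        self.window = window
        self.max_span = max_span
        self.step = max(1, int(step))
        self.mode = mode
        self._codes = encode(seq)
        self._z: dict[int, float] = {}
        self._zc: dict[tuple, float] = {}

    def _window_starts(self, a: int, b: int) -> list[int]:
        n = len(self.seq)
        if n <= self.window:
            return [1]
        lo = max(1, b - self.window + 1)
        hi = min(a, n - self.window + 1)
        if self.mode == "single":
            center = (a + b) // 2 - self.window // 2
            return [min(max(lo, center), hi)]
        starts = list(range(lo, hi + 1, self.step))
        if starts[-1] != hi:
            starts.append(hi)
        return starts

    def _fold(self, wstart: int, unp: np.ndarray | None) -> float:
        wlen = min(self.window, len(self.seq))
        codes = self._codes[wstart - 1:wstart - 1 + wlen]
        return _run_inside(codes, self.model, self.max_span, unp)

    def _pu_wide(self, a: int, b: int,
                 constraint: FoldConstraint | None) -> float:
        n = len(self.seq)
        margin = 20
        wa, wb = max(1, a - margin), min(n, b + margin)
        codes = self._codes[wa - 1:wb]
        cpos = constraint.forced_unpaired if constraint else frozenset()
        base = sorted(p - wa for p in cpos if wa <= p <= wb)
        unp = np.array(sorted(set(base) | set(range(a - wa, b - wa + 1))),
                       dtype=np.intp)
        num = _run_inside(codes, self.model, self.max_span, unp)
        den = _run_inside(codes, self.model, self.max_span,
                          np.array(base, dtype=np.intp) if base else None)
        return min(1.0, num / den)

    def pu(self, interval: tuple[int, int],
           constraint: FoldConstraint | None = None) -> float:
        a, b = interval
        if a > b:
            return 1.0
        n = len(self.seq)
        if not (1 <= a and b <= n):
            raise ValueError(f"interval {interval} outside 1..{n}")
        if b - a + 1 > min(self.window, n):
            # interval wider than the window (rare, sprawling sites): fold a
            # single locally widened window around it instead
            return self._pu_wide(a, b, constraint)
        cpos = frozenset(constraint.forced_unpaired) if constraint else frozenset()
        vals = []
        for w in self._window_starts(a, b):
            wlen = min(self.window, n)
            wset = {p - w for p in cpos if w <= p <= w + wlen - 1}
            if w not in self._z:
                self._z[w] = self._fold(w, None)
            key = (w, tuple(sorted(wset)), a - w, b - w)
            if key not in self._zc:
                unp = np.array(sorted(wset | set(range(a - w, b - w + 1))),
                               dtype=np.intp)
                self._zc[key] = self._fold(w, unp)
            denom = self._z[w]
            if wset:
                unp0 = np.array(sorted(wset), dtype=np.intp)
                denom = self._fold(w, unp0)
            vals.append(min(1.0, self._zc[key] / denom))
        return float(np.mean(vals))


def local_accessibility_profile(seq: str, model: EnergyModel | None = None,
                                window: int = 100, max_span: int = 50,
                                probe_len: int = 10) -> UnpairedProfile:
    """Pu of every ``probe_len`` interval, averaged over sliding windows.

    Windows slide by 1 nt; a sequence shorter than the window is folded as a
    single truncated window (then the profile equals the global, span-capped
    partition function's interval probabilities).
    """
    if probe_len > len(seq):
        raise ValueError("probe_len exceeds sequence length")
    if window < max_span:
        raise ValueError("window must be >= max_span")
    calc = AccessibilityCalculator(seq, model, window=window,
                                   max_span=max_span, step=1)
    prof = UnpairedProfile(window=window, max_span=max_span, probe_len=probe_len)
    for a in range(1, len(seq) - probe_len + 2):
        iv = (a, a + probe_len - 1)
        prof.Pu[iv] = calc.pu(iv)
    return prof
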