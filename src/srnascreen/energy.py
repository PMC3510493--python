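"""Nearest-neighbour energy model for folding and hybridization.

The model is deliberately self-contained: a stacking table over the six
canonical pairs (AU, UA, GC, CG, GU, UG) plus affine penalties for hairpin,
bulge, interior and multibranch loops, and a duplex initiation term for
intermolecular helices.  Parameters ship as versioned YAML
(``data/default_energy.yaml``) and any alternative table with the same schema
can be loaded with :meth:`EnergyModel.from_yaml`.

Conventions
-----------
* Energies are free energies in kcal/mol at the model temperature; negative
  is stabilising.
* ``RT = 0.0019872 * temperature`` (kcal/mol).
* A pair type is indexed 0..5 in the order AU, UA, GC, CG, GU, UG; -1 marks
  a non-canonical (disallowed) pair.
* ``stack[p1, p2]`` is the energy of pair ``p2 = (i+1, j-1)`` stacked inside
  pair ``p1 = (i, j)``.
* Hairpin loops smaller than ``min_hairpin`` and interior/bulge loops longer
  than ``max_interior`` on either side are forbidden (infinite energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

GAS_CONSTANT = 0.0019872  # kcal/mol/K

#: residue encoding used throughout the package
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: canonical pair order; index into stacking tables
PAIR_ORDER = ("AU", "UA", "GC", "CG", "GU", "UG")
PAIR_INDEX = {p: i for i, p in enumerate(PAIR_ORDER)}

# 4x4 lookup: (base_i, base_j) -> pair type or -1
PAIR_TYPE = np.full((4, 4), -1, dtype=np.int8)
for _p, _i in PAIR_INDEX.items():
    PAIR_TYPE[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string (A/C/G/U) as an int8 array."""
    try:
        return np.array([BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - guarded by seqio validation
        raise ValueError(f"non-RNA residue {exc} in sequence") from exc


@dataclass(frozen=True)
class EnergyModel:
    """Thermodynamic parameter set (see module docstring for conventions)."""

    stack: np.ndarray                 # (6, 6) kcal/mol
    hairpin_a: float
    hairpin_b: float
    bulge_a: float
    bulge_b: float
    interior_a: float
    interior_b: float
    ml_a: float
    ml_b: float
    ml_c: float
    duplex_init: float
    temperature: float
    max_interior: int = 10
    min_hairpin: int = 3
    version: int | str = "custom"
    canonical_pairs: tuple[str, ...] = PAIR_ORDER
    RT: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "RT", GAS_CONSTANT * self.temperature)
        if self.stack.shape != (6, 6):
            raise ValueError("stack table must be 6x6 over the canonical pair order")
        if np.any(self.stack > 0):
            raise ValueError("stacking energies must be <= 0")
        if self.min_hairpin < 3:
            raise ValueError("minimum hairpin loop size is 3")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModel":
        if "stack" in d:
            stack = np.asarray(d["stack"], dtype=float)
        else:
            s = d["pair_strength"]
            strengths = np.array([s[p] for p in PAIR_ORDER], dtype=float)
            stack = -(strengths[:, None] + strengths[None, :]) / 2.0
        return cls(
            stack=stack,
            hairpin_a=float(d["hairpin_a"]),
            hairpin_b=float(d["hairpin_b"]),
            bulge_a=float(d["bulge_a"]),
            bulge_b=float(d["bulge_b"]),
            interior_a=float(d["interior_a"]),
            interior_b=float(d["interior_b"]),
            ml_a=float(d["ml_a"]),
            ml_b=float(d["ml_b"]),
            ml_c=float(d["ml_c"]),
            duplex_init=float(d["duplex_init"]),
            temperature=float(d["temperature"]),
            max_interior=int(d.get("max_interior", 10)),
            min_hairpin=int(d.get("min_hairpin", 3)),
            version=d.get("version", "custom"),
        )

    @classmethod
    def from_yaml(cls, path) -> "EnergyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "EnergyModel":
        ref = resources.files("srnascreen").joinpath("data/default_energy.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    # -- loop energies -----------------------------------------------------

    def hairpin_penalty(self, size: int) -> float:
        if size < self.min_hairpin:
            return np.inf
        return self.hairpin_a + self.hairpin_b * size

    def interior_bulge_penalty(self, l1: int, l2: int) -> float:
        """Energy of an interior/bulge loop with ``l1``/``l2`` unpaired nt
        per side (not both 0 — that is a stack)."""
        if l1 == 0 and l2 == 0:
            raise ValueError("(0,0) is a stack, not a loop")
        if l1 > self.max_interior or l2 > self.max_interior:
            return np.inf
        if l1 == 0 or l2 == 0:
            return self.bulge_a + self.bulge_b * (l1 + l2)
        return self.interior_a + self.interior_b * (l1 + l2)

    def stack_energy(self, pt_outer: int, pt_inner: int) -> float:
        return float(self.stack[pt_outer, pt_inner])

    def multiloop_penalty(self, branches: int, unpaired: int) -> float:
        """Closing helix counts as one branch."""
        return self.ml_a + self.ml_b * branches + self.ml_c * unpaired

    def boltzmann(self, energy: float) -> float:
        return float(np.exp(-energy / self.RT))


def pair_type(a: str, b: str) -> int:
    """Canonical pair type index of bases ``a``,``b`` (5'/3'), or -1."""
    return int(PAIR_TYPE[BASE_INDEX[a], BASE_INDEX[b]])
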