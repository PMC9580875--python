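"""Nearest-neighbor energy model for intermolecular RNA:RNA duplexes.

Free energies are in kcal/mol at 37 degrees C.  Helices are scored by
nearest-neighbor stacking terms over Watson-Crick and G:U wobble pairs;
unpaired stretches between consecutive pairs are charged length-dependent
bulge or interior-loop penalties (with a Ninio-style asymmetry term), and
every duplex pays a single initiation cost.  Intramolecular structure of
either strand is deliberately not modeled: only the hybrid is scored.

A stack is keyed ``(p1, p2)`` where ``p1 = (a1, b1)`` is the 5' pair on the
query strand (a = query base, b = target base) and ``p2`` the next pair:

    5'-a1 a2-3'
    3'-b1 b2-5'

The table is symmetric under duplex reversal: E(p1, p2) == E(rev p2, rev p1)
with rev("AU") == "UA".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_IDX = {p: i for i, p in enumerate(PAIR_NAMES)}

#: 5x5 lookup: (query base, target base) -> pair index, -1 if unpairable.
PAIR_INDEX = np.full((5, 5), -1, dtype=np.int8)
for _p, _i in _PAIR_IDX.items():
    PAIR_INDEX[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _i

# Watson-Crick / Watson-Crick stacking free energies (Turner-style values).
_WC_STACKS = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("CG", "GC"): -2.36,
    ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26,
}

# Stacks involving at least one G:U wobble pair.
_GU_STACKS = {
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("UA", "GU"): -1.27,
    ("UA", "UG"): -1.00,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("GU", "GU"): -0.50,
    ("UG", "UG"): -0.50,
    ("GU", "UG"): 0.47,
    ("UG", "GU"): -0.30,
}


def _rev_pair(p: str) -> str:
    return p[::-1]


def _complete_stacks(base: dict) -> dict:
    """Fill in reversal-symmetric partners; error on inconsistent input."""
    out = dict(base)
    for (p1, p2), e in base.items():
        mirror = (_rev_pair(p2), _rev_pair(p1))
        if mirror in out and abs(out[mirror] - e) > 1e-9:
            raise ValueError(f"stack table not reversal-symmetric at {mirror}")
        out[mirror] = e
    return out


_DEFAULT_BULGE = (3.8, 2.8, 3.2, 3.6, 4.0, 4.4, 4.6, 4.7, 4.8, 4.9)
_DEFAULT_INTERIOR = (
    1.7, 1.8, 2.0, 2.2, 2.5, 2.6, 2.8, 2.9, 3.0,
    3.1, 3.2, 3.3, 3.4, 3.5, 3.5, 3.6, 3.6, 3.7, 3.7,
)  # total unpaired bases 2 .. 20


@dataclass(frozen=True)
class EnergyModel:
    """Parameter set for duplex scoring; all energies in kcal/mol."""

    stacks: dict = field(default_factory=lambda: _complete_stacks({**_WC_STACKS, **_GU_STACKS}))
    bulge: tuple = _DEFAULT_BULGE            # bulge length 1 .. max_loop
    interior: tuple = _DEFAULT_INTERIOR      # total interior size 2 .. 2*max_loop
    asymmetry: float = 0.48                  # Ninio penalty per bp of loop asymmetry
    asymmetry_max: float = 3.0
    init: float = 4.09                       # duplex initiation
    max_loop: int = 10                       # per-side cap on unpaired bases

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        wc = {"AU", "UA", "CG", "GC"}
        for (p1, p2), e in self.stacks.items():
            if p1 in wc and p2 in wc and e > 0:
                raise ValueError(f"WC/WC stack {p1}/{p2} must be <= 0, got {e}")
            mirror = (_rev_pair(p2), _rev_pair(p1))
            if abs(self.stacks.get(mirror, e) - e) > 1e-9:
                raise ValueError(f"stack table not symmetric under reversal at {p1}/{p2}")
        if any(v < 0 for v in self.bulge) or any(v < 0 for v in self.interior):
            raise ValueError("loop penalties must be >= 0")
        if len(self.bulge) < self.max_loop:
            raise ValueError("bulge table shorter than max_loop")
        if len(self.interior) < 2 * self.max_loop - 1:
            raise ValueError("interior table shorter than 2*max_loop")

    # -- scalar interface (used by the brute-force oracles) ----------------

    def pair_type(self, a: str, b: str) -> str | None:
        """Pair name for query base *a* opposite target base *b*, or None."""
        p = a + b
        return p if p in _PAIR_IDX else None

    def stack_energy(self, p1: str, p2: str) -> float:
        return self.stacks[(p1, p2)]

    def loop_energy(self, gi: int, gj: int) -> float:
        """Penalty for gi unpaired query bases opposite gj target bases."""
        if gi == 0 and gj == 0:
            raise ValueError("no loop between stacked pairs")
        if gi > self.max_loop or gj > self.max_loop:
            return float("inf")
        if gi == 0 or gj == 0:
            return self.bulge[max(gi, gj) - 1]
        return self.interior[gi + gj - 2] + min(
            self.asymmetry_max, self.asymmetry * abs(gi - gj)
        )

    # -- matrix interface (used by the vectorized dynamic program) ---------

    def stack_matrix(self) -> np.ndarray:
        m = np.full((6, 6), np.inf)
        for (p1, p2), e in self.stacks.items():
            m[_PAIR_IDX[p1], _PAIR_IDX[p2]] = e
        return m

    def loop_matrix(self) -> np.ndarray:
        """(max_loop+1, max_loop+1) array of loop penalties; [0,0] is inf."""
        cap = self.max_loop
        m = np.full((cap + 1, cap + 1), np.inf)
        for gi in range(cap + 1):
            for gj in range(cap + 1):
                if gi == 0 and gj == 0:
                    continue
                m[gi, gj] = self.loop_energy(gi, gj)
        return m

    def with_overrides(self, **kwargs) -> "EnergyModel":
        return replace(self, **kwargs)


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as an int8 array (unknown characters -> N)."""
    return np.array([BASE_INDEX.get(c, 4) for c in seq], dtype=np.int8)
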