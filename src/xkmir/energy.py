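"""Nearest-neighbor free-energy model for intermolecular RNA:RNA duplexes.

The packaged table (``data/turner1999_duplex.json``) carries the Turner/
Mathews 1999 37C parameters: Watson-Crick and G:U stacking terms,
length-dependent bulge and interior loop penalties with a Ninio asymmetry
correction, plus helix-end terms (terminal A:U penalty, duplex initiation).
The end terms default to "off" in scoring, matching the convention of the
hybridization tools this scanner mirrors, which report pure helix energy.

The model is deliberately duplex-only: no intramolecular pairs, no dangling
ends, no sequence-dependent interior-loop mismatch tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

PAIR_INDEX = {"CG": 0, "GC": 1, "GU": 2, "UG": 3, "AU": 4, "UA": 5}
CANONICAL_PAIRS = tuple(PAIR_INDEX)

INF = math.inf


@dataclass(frozen=True)
class EnergyTable:
    """Duplex nearest-neighbor parameter set, energies in kcal/mol."""

    stack: tuple[tuple[float, ...], ...]  # [pair1][pair2], canonical orientation
    bulge: tuple[float, ...]  # [loop length]
    internal: tuple[float, ...]  # [total loop length]
    ninio_m: float
    ninio_max: float
    terminal_au: float
    duplex_init: float
    lxc: float
    table_id: str = "turner1999"

    def stack_energy(self, p1: int, p2: int) -> float:
        """5'-a c-3' / 3'-b d-5' step with p1 = pair(a,b), p2 = pair(c,d)."""
        return self.stack[p1][p2]

    def _extrapolate(self, base: tuple[float, ...], n: int) -> float:
        if n < len(base) and math.isfinite(base[n]):
            return base[n]
        last = len(base) - 1
        return base[last] + self.lxc * math.log(n / last)

    def bulge_energy(self, n: int) -> float:
        return self._extrapolate(self.bulge, n)

    def internal_energy(self, n1: int, n2: int) -> float:
        loop = self._extrapolate(self.internal, n1 + n2)
        return loop + min(self.ninio_max, self.ninio_m * abs(n1 - n2))

    def loop_energy(self, n1: int, n2: int, p_outer: int, p_inner: int) -> float:
        """Cost of joining two consecutive pairs with n1/n2 unpaired bases
        between them on the two strands. (0, 0) is a stack; a single-base
        bulge keeps the stacking interaction of its closing pairs."""
        if n1 == 0 and n2 == 0:
            return self.stack_energy(p_outer, p_inner)
        if n1 == 0 or n2 == 0:
            n = n1 + n2
            e = self.bulge_energy(n)
            if n == 1:
                e += self.stack_energy(p_outer, p_inner)
            return e
        return self.internal_energy(n1, n2)

    def end_penalty(self, pair: int, *, apply_terminal_au: bool) -> float:
        if apply_terminal_au and pair >= PAIR_INDEX["GU"]:
            return self.terminal_au
        return 0.0


def pair_type(a: str, b: str) -> int:
    """Index of the canonical pair a:b, or -1 if a and b cannot pair."""
    return PAIR_INDEX.get(a + b, -1)


@lru_cache(maxsize=None)
def load_energy_table(name: str = "turner1999") -> EnergyTable:
    ref = resources.files("xkmir.data").joinpath(f"{name}_duplex.json")
    raw = json.loads(ref.read_text())
    pairs = raw["pairs"]
    stack = tuple(
        tuple(raw["stack"][p1][p2] for p2 in pairs) for p1 in pairs
    )

    def arr(key: str) -> tuple[float, ...]:
        return tuple(INF if v is None else v for v in raw[key])

    return EnergyTable(
        stack=stack,
        bulge=arr("bulge"),
        internal=arr("internal"),
        ninio_m=raw["ninio_m"],
        ninio_max=raw["ninio_max"],
        terminal_au=raw["terminal_au"],
        duplex_init=raw["duplex_init"],
        lxc=raw["lxc"],
        table_id=name,
    )
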