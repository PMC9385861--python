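"""Elemental formulas for dissolved organic matter mass spectrometry.

CHNOSP compositions with exact monoisotopic mass, double-bond equivalents
(DBE), elemental ratios, the modified aromaticity index (AI_mod) and van
Krevelen compound-class regions. These are the per-formula primitives that
formula assignment and the molecular descriptors build on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MolecularFormula",
    "ELEMENT_MASS",
    "ELEMENT_BOUNDS",
    "exact_mass",
    "dbe",
    "ai_mod",
    "compound_class",
    "COMPOUND_CLASSES",
    "parse_formula",
]

#: Monoisotopic masses (Da) of the light isotopes.
ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Element-count windows used for formula assignment: C1-100 H1-100 O0-70
#: N0-4 S0-2 P0-1.
ELEMENT_BOUNDS = {
    "c": (1, 100),
    "h": (1, 100),
    "n": (0, 4),
    "o": (0, 70),
    "s": (0, 2),
    "p": (0, 1),
}


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """A CHNOSP elemental composition.

    Immutable and hashable so formulas can live in sets (formula pools,
    contaminant lists, reference lists).
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"element count {name}={v!r} must be a non-negative integer")
        if self.c == 0 and self.h == 0 and self.n == 0 and self.o == 0 and self.s == 0 and self.p == 0:
            raise ValueError("empty formula (all element counts zero)")

    # -- derived quantities -------------------------------------------------

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return exact_mass(self)

    @property
    def dbe(self) -> float:
        """Double-bond equivalents: 1 + C - H/2 + (N + P)/2."""
        return 1.0 + self.c - self.h / 2.0 + (self.n + self.p) / 2.0

    @property
    def hc(self) -> float:
        return self.h / self.c if self.c else float("nan")

    @property
    def oc(self) -> float:
        return self.o / self.c if self.c else float("nan")

    @property
    def nc(self) -> float:
        return self.n / self.c if self.c else float("nan")

    @property
    def sc(self) -> float:
        return self.s / self.c if self.c else float("nan")

    @property
    def pc(self) -> float:
        return self.p / self.c if self.c else float("nan")

    @property
    def heteroelements(self) -> int:
        """Number of N + S + P atoms."""
        return self.n + self.s + self.p

    @property
    def n_atoms(self) -> int:
        return self.c + self.h + self.n + self.o + self.s + self.p

    def is_valid(self, *, o_le_c_plus_2: bool = True) -> bool:
        """Chemical validity under the assignment rules.

        Requires element counts within the CHNOSP windows, an integer,
        non-negative DBE, and (optionally) O <= C + 2.
        """
        for name, (lo, hi) in ELEMENT_BOUNDS.items():
            if not lo <= getattr(self, name) <= hi:
                return False
        d = self.dbe
        if d < 0 or abs(d - round(d)) > 1e-9:
            return False
        if o_le_c_plus_2 and self.o > self.c + 2:
            return False
        return True

    # -- formatting ---------------------------------------------------------

    def __str__(self) -> str:
        """Hill-order formula string (C, H, then alphabetical N, O, P, S)."""
        parts = []
        for sym, cnt in (("C", self.c), ("H", self.h), ("N", self.n),
                         ("O", self.o), ("P", self.p), ("S", self.s)):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)


def exact_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass of ``formula`` in Da."""
    return (formula.c * ELEMENT_MASS["C"]
            + formula.h * ELEMENT_MASS["H"]
            + formula.n * ELEMENT_MASS["N"]
            + formula.o * ELEMENT_MASS["O"]
            + formula.s * ELEMENT_MASS["S"]
            + formula.p * ELEMENT_MASS["P"])


def dbe(formula: MolecularFormula) -> float:
    """Double-bond equivalents of ``formula`` (may be negative or half-integer
    for chemically impossible compositions; callers screen with
    :meth:`MolecularFormula.is_valid`)."""
    return formula.dbe


def ai_mod(formula: MolecularFormula) -> float:
    """Modified aromaticity index.

    AI_mod = (1 + C - 0.5 O - S - 0.5 (H + N + P)) / (C - 0.5 O - N - S - P),
    treating half the oxygen as carbonyl-like. Values are clamped to 0 when
    the numerator is negative or the denominator is non-positive (no
    carbon skeleton left to be aromatic).
    """
    num = 1.0 + formula.c - 0.5 * formula.o - formula.s - 0.5 * (formula.h + formula.n + formula.p)
    den = formula.c - 0.5 * formula.o - formula.n - formula.s - formula.p
    if den <= 0 or num < 0:
        return 0.0
    return num / den


# van Krevelen compound-class regions as (O/C, H/C) predicates. The regions
# deliberately overlap in places (e.g. O/C <= 0.29 with H/C exactly 1.6);
# formulas matching zero or >= 2 regions are "unclassified".
COMPOUND_CLASSES = (
    "unsaturated_o_poor",
    "unsaturated",
    "carbohydrate_like",
    "unsaturated_hydrocarbon",
    "condensed_aromatic",
    "lignin_like",
    "tannin_like",
)

_CLASS_REGIONS = {
    "unsaturated_o_poor": lambda oc, hc: 0 < oc <= 0.29 and 1.6 <= hc <= 2.5,
    "unsaturated": lambda oc, hc: 0.29 < oc <= 0.6 and 1.5 <= hc <= 2.5,
    "carbohydrate_like": lambda oc, hc: 0.6 <= oc <= 1.2 and 1.5 <= hc <= 2.5,
    "unsaturated_hydrocarbon": lambda oc, hc: 0 < oc <= 0.29 and 1 <= hc <= 1.6,
    "condensed_aromatic": lambda oc, hc: 0 <= oc <= 0.4 and 0 <= hc <= 0.7,
    "lignin_like": lambda oc, hc: 0.29 < oc <= 0.65 and 0.7 < hc < 1.5,
    "tannin_like": lambda oc, hc: 0.65 < oc <= 1.2 and 0.5 <= hc < 1.5,
}


def class_region(name: str):
    """Return the (O/C, H/C) membership predicate of a compound class."""
    return _CLASS_REGIONS[name]


def compound_class(formula: MolecularFormula) -> str:
    """van Krevelen compound class of ``formula``.

    Returns the unique matching class, or ``"unclassified"`` when the
    (O/C, H/C) point matches no region or more than one.
    """
    oc, hc = formula.oc, formula.hc
    matches = [name for name, pred in _CLASS_REGIONS.items() if pred(oc, hc)]
    if len(matches) == 1:
        return matches[0]
    return "unclassified"


_FORMULA_RE = re.compile(r"([CHNOPS])(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-order formula string like ``"C16H32O2"``."""
    counts = {"C": 0, "H": 0, "N": 0, "O": 0, "P": 0, "S": 0}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text) or pos == 0:
        raise ValueError(f"cannot parse formula {text!r}")
    return MolecularFormula(c=counts["C"], h=counts["H"], n=counts["N"],
                            o=counts["O"], s=counts["S"], p=counts["P"])
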