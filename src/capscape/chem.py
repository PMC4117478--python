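"""Elemental-composition algebra and monoisotopic masses for cap dinucleotides.

An RNA 5' cap is an inverted nucleoside (usually a methylated guanosine)
joined to the first transcribed nucleotide through a 5'-5' triphosphate
bridge.  After enzymatic digestion the cap is released as a dinucleotide
``NpppM`` and observed in negative-mode electrospray MS as the deprotonated
anion [M-H]-.  This module provides the exact bookkeeping needed to turn a
described cap structure (bases plus base- and ribose-methylations) into an
elemental formula and a monoisotopic anion mass.

Conventions
-----------
* Monoisotopic atomic masses are frozen constants (most abundant isotope of
  each element) so downstream golden values are bit-stable.
* The [M-H]- mass is the neutral monoisotopic mass minus the proton mass
  1.00727646 Da; the electron is thereby accounted for implicitly, the
  standard negative-ESI convention.
* 7-methylguanosine-containing caps are treated as formula-neutral
  zwitterions: methylation changes the composition by CH2 only and no charge
  correction is applied.
* Only the *count* of base methyl groups affects the mass; named positions
  (N7, N2...) are not tracked because precursor-mass matching cannot
  distinguish positional isomers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "METHYLENE_MASS",
    "ElementalFormula",
    "Nucleoside",
    "CapStructure",
    "formula_of_nucleoside",
    "cap_neutral_formula",
    "anion_mass",
    "ppm_error",
    "export_constants_csv",
]

#: Monoisotopic atomic masses in Da (most abundant isotope).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.97376151,
}

#: Mass of a proton in Da, subtracted from the neutral mass to give [M-H]-.
PROTON_MASS = 1.00727646

_ELEMENTS = ("C", "H", "N", "O", "P")


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts over C, H, N, O, P with element-wise algebra.

    Counts are non-negative; subtraction that would drive any count below
    zero raises ``ValueError``.
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"element count {el}={n!r} must be a non-negative integer")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(**{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS})

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = {el: getattr(self, el) - getattr(other, el) for el in _ELEMENTS}
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"subtraction yields negative count: {counts}")
        return ElementalFormula(**counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("multiplier must be a non-negative integer")
        return ElementalFormula(**{el: getattr(self, el) * k for el in _ELEMENTS})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (dot product with the atomic-mass table)."""
        return sum(getattr(self, el) * MONOISOTOPIC_MASS[el] for el in _ELEMENTS)

    def composition(self) -> str:
        """Hill-style composition string, e.g. ``C10H13N5O5``."""
        parts = []
        for el in _ELEMENTS:
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.composition()


# Building blocks -------------------------------------------------------------

#: Formulas of the four unmodified ribonucleosides.
RIBONUCLEOSIDE: Mapping[str, ElementalFormula] = {
    "A": ElementalFormula(C=10, H=13, N=5, O=4),  # adenosine
    "C": ElementalFormula(C=9, H=13, N=3, O=5),   # cytidine
    "G": ElementalFormula(C=10, H=13, N=5, O=5),  # guanosine
    "U": ElementalFormula(C=9, H=12, N=2, O=6),   # uridine
}

#: One methyl substitution (CH2 replaces an H that stays on the group).
METHYLENE = ElementalFormula(C=1, H=2)
#: Exact monoisotopic mass shift per methyl group.
METHYLENE_MASS = METHYLENE.mass  # 14.01565006...

WATER = ElementalFormula(H=2, O=1)
#: Free triphosphate H5P3O10; two waters leave on forming the 5'-5' bridge.
TRIPHOSPHATE = ElementalFormula(H=5, O=10, P=3)

#: Default cap of base-methyl counts allowed per base: G carries up to three
#: (N7, N2, N2 — covering 7mG through the 2,2,7mG trimethylguanosine cap),
#: A up to one (N6), C and U none.
DEFAULT_BASE_METHYL_MAX: Mapping[str, int] = {"A": 1, "C": 0, "G": 3, "U": 0}

_METHYL_PREFIX = {0: "", 1: "m", 2: "2m", 3: "3m"}


@dataclass(frozen=True)
class Nucleoside:
    """A ribonucleoside with a count of base N-methyls and an optional 2'-O-methyl.

    ``mN`` / ``2mN`` / ``3mN`` denote one/two/three base methyl groups; a
    trailing ``m`` (``Nm``) denotes ribose 2'-O-methylation, so ``mAm`` is
    N6-methyl-2'-O-methyladenosine.
    """

    base: str
    base_methyls: int = 0
    ribose_methyl: bool = False

    def __post_init__(self) -> None:
        if self.base not in RIBONUCLEOSIDE:
            raise ValueError(f"unknown base {self.base!r}; expected one of A, C, G, U")
        if not isinstance(self.base_methyls, int) or self.base_methyls < 0:
            raise ValueError(f"base_methyls must be a non-negative integer, got {self.base_methyls!r}")

    @property
    def total_methyls(self) -> int:
        return self.base_methyls + int(self.ribose_methyl)

    @property
    def formula(self) -> ElementalFormula:
        return RIBONUCLEOSIDE[self.base] + self.total_methyls * METHYLENE

    @property
    def label(self) -> str:
        prefix = _METHYL_PREFIX.get(self.base_methyls, f"{self.base_methyls}m")
        return f"{prefix}{self.base}{'m' if self.ribose_methyl else ''}"


def formula_of_nucleoside(
    base: str,
    base_methyls: int = 0,
    ribose_methyl: bool = False,
    *,
    base_methyl_max: Mapping[str, int] = DEFAULT_BASE_METHYL_MAX,
) -> ElementalFormula:
    """Elemental formula of a (methylated) ribonucleoside.

    Raises ``ValueError`` for an unknown base or a base-methyl count outside
    the allowed range for that base (default: G 0-3, A 0-1, C/U 0).
    """
    nuc = Nucleoside(base, base_methyls, ribose_methyl)
    limit = base_methyl_max.get(base, 0)
    if base_methyls > limit:
        raise ValueError(f"{base_methyls} base methyls on {base} exceeds the allowed maximum {limit}")
    return nuc.formula


def _display_order(a: Nucleoside, b: Nucleoside) -> tuple[Nucleoside, Nucleoside]:
    """Order a nucleoside pair the way cap labels are conventionally written.

    The guanosine (cap) side comes first; between two guanosines the more
    base-methylated one leads (``mGpppG``), and at equal base-methylation the
    ribose-unmethylated one leads (``GpppGm``).  Pairs without G fall back to
    alphabetical base order.
    """

    def key(n: Nucleoside) -> tuple:
        return (n.base != "G", -n.base_methyls, int(n.ribose_methyl), n.base)

    return (a, b) if key(a) <= key(b) else (b, a)


@dataclass(frozen=True)
class CapStructure:
    """Two nucleosides joined 5'-5' by a triphosphate bridge.

    ``outer`` is the inverted cap nucleoside, ``inner`` the first transcribed
    nucleotide.  The mass is symmetric under swapping the two (MS cannot
    orient the dinucleotide), but cap-type classification depends on which
    side is inner.
    """

    outer: Nucleoside
    inner: Nucleoside

    @property
    def neutral_formula(self) -> ElementalFormula:
        return cap_neutral_formula(self.outer, self.inner)

    @property
    def neutral_mass(self) -> float:
        return self.neutral_formula.mass

    @property
    def anion_mass(self) -> float:
        return anion_mass(self)

    @property
    def total_methyls(self) -> int:
        return self.outer.total_methyls + self.inner.total_methyls

    @property
    def base_pair(self) -> frozenset | tuple:
        """Unordered pair of bases, e.g. ``('A', 'G')`` (sorted)."""
        return tuple(sorted((self.outer.base, self.inner.base)))

    @property
    def label(self) -> str:
        """Label in the field's notation with ``outer`` written first."""
        return f"{self.outer.label}ppp{self.inner.label}"

    @property
    def canonical_label(self) -> str:
        """Orientation-independent label (conventional display order)."""
        a, b = _display_order(self.outer, self.inner)
        return f"{a.label}ppp{b.label}"

    @property
    def dual_label(self) -> str:
        """Both orientations, mirroring ``NpppM/MpppN`` reporting."""
        a, b = _display_order(self.outer, self.inner)
        if a.label == b.label:
            return f"{a.label}ppp{b.label}"
        return f"{a.label}ppp{b.label}/{b.label}ppp{a.label}"

    @property
    def cap_type(self) -> str:
        """``type0`` if the first transcribed nucleotide lacks 2'-O-methylation."""
        return "type0" if not self.inner.ribose_methyl else "type1_or_higher"


def cap_neutral_formula(outer: Nucleoside, inner: Nucleoside) -> ElementalFormula:
    """Neutral formula of the 5'-5' dinucleotide triphosphate.

    Two nucleosides plus a triphosphate, less the two waters released when
    the bridge's phosphoester bonds form; symmetric in its arguments.
    """
    return outer.formula + inner.formula + TRIPHOSPHATE - 2 * WATER


def anion_mass(cap: CapStructure) -> float:
    """[M-H]- monoisotopic mass of the cap dinucleotide in Da."""
    return cap.neutral_formula.mass - PROTON_MASS


def ppm_error(observed: float, calculated: float) -> float:
    """Relative mass error (observed - calculated) / calculated, in ppm."""
    if calculated <= 0:
        raise ValueError(f"calculated mass must be positive, got {calculated}")
    return (observed - calculated) / calculated * 1e6


def export_constants_csv(path) -> None:
    """Write the frozen mass constants and building-block formulas to CSV."""
    rows: Iterable[tuple] = [
        ("constant", "composition", "mass_da"),
        *((f"atom_{el}", el, MONOISOTOPIC_MASS[el]) for el in _ELEMENTS),
        ("proton", "H+", PROTON_MASS),
        ("methylene", METHYLENE.composition(), METHYLENE_MASS),
        ("water", WATER.composition(), WATER.mass),
        ("triphosphate", TRIPHOSPHATE.composition(), TRIPHOSPHATE.mass),
        *(
            (f"ribonucleoside_{b}", f.composition(), f.mass)
            for b, f in sorted(RIBONUCLEOSIDE.items())
        ),
    ]
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)
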