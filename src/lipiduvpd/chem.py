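"""Elemental-formula arithmetic and glycerophospholipid construction.

Lipids are modeled compositionally: an acyl chain is a carbon count plus
unsaturation equivalents (double bonds and cyclopropane rings each remove
two hydrogens from the saturated chain, so both count toward the ``x:y``
shorthand total), optionally with located modifications. A lipid species
is a head-group class (PE, PG, PC, PA or CDL) plus its chains; an ion adds
an adduct and charge. All masses are monoisotopic, taken from the NIST
table shipped with :mod:`pyteomics`, and ion m/z values account for the
electron mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from pyteomics.mass import nist_mass as _NIST

__all__ = [
    "ElementalFormula",
    "AcylChain",
    "Modification",
    "LipidSpecies",
    "LipidIon",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "formula_mass",
    "acyl_chain_formula",
    "carboxylate_mz",
    "species_formula",
    "build_lipid_ion",
    "parse_shorthand",
    "format_shorthand",
]

ELECTRON_MASS: float = _NIST["e*"][0][0]
PROTON_MASS: float = _NIST["H"][0][0] - ELECTRON_MASS

DOUBLE_BOND = "double_bond"
CYCLOPROPANE = "cyclopropane"

GLYCEROPHOSPHOLIPID_CLASSES = ("PE", "PG", "PC", "PA")
LIPID_CLASSES = GLYCEROPHOSPHOLIPID_CLASSES + ("CDL",)


def _monoisotopic(symbol: str) -> float:
    try:
        return _NIST[symbol][0][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count map with exact monoisotopic mass.

    Supports element-wise addition and subtraction; subtraction that would
    drive any count negative raises ``ValueError`` (a fragment cannot lose
    atoms its precursor does not have).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for symbol, count in self.counts.items():
            _monoisotopic(symbol)  # validates the symbol
            if count < 0:
                raise ValueError(f"negative count for {symbol}: {count}")
            if count:
                clean[symbol] = int(count)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C7H14"`` or ``"H3PO4"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                break
            symbol, digits = match.groups()
            if not symbol:
                break
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text) or (text and not counts):
            raise ValueError(f"malformed formula string: {text!r}")
        return cls(counts)

    @property
    def mass(self) -> float:
        return sum(_monoisotopic(sym) * n for sym, n in self.counts.items())

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            new = counts.get(sym, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction would give negative count for {sym}: "
                    f"{counts.get(sym, 0)} - {n}"
                )
            counts[sym] = new
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalFormula({sym: n * k for sym, n in self.counts.items()})

    __rmul__ = __mul__

    def contains(self, other: "ElementalFormula") -> bool:
        return all(self.counts.get(sym, 0) >= n for sym, n in other.counts.items())

    def hill(self) -> str:
        """Formula in Hill order (C, H, then alphabetical)."""
        symbols = sorted(
            self.counts, key=lambda s: (s != "C", s != "H", s)
        )
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] != 1 else s for s in symbols
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def formula_mass(formula: ElementalFormula | str | Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a formula, string, or element-count map."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    elif not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    return formula.mass


# Frequently used building blocks.
F = ElementalFormula.parse
WATER = F("H2O")
GLYCEROL = F("C3H8O3")
PHOSPHORIC_ACID = F("H3PO4")
CH2 = F("CH2")
C2 = F("C2")

# Head-group residue added to phosphatidic acid via a phosphoester bond
# (condensation, -H2O): ethanolamine, glycerol, choline.
_HEADGROUP_RESIDUE = {
    "PE": F("C2H7NO"),
    "PG": F("C3H8O3"),
    "PC": F("C5H13NO"),
    "PA": None,
}


@dataclass(frozen=True)
class Modification:
    """A located acyl-chain modification, numbered from the carboxyl carbon."""

    kind: str  # DOUBLE_BOND or CYCLOPROPANE
    position: int

    def __post_init__(self) -> None:
        if self.kind not in (DOUBLE_BOND, CYCLOPROPANE):
            raise ValueError(f"unknown modification kind: {self.kind!r}")
        if self.position < 1:
            raise ValueError("modification position must be >= 1")


@dataclass(frozen=True)
class AcylChain:
    """A fatty-acyl chain: ``carbons:unsat_equiv`` plus optional located mods.

    ``unsat_equiv`` counts unsaturation equivalents: both C=C bonds and
    cyclopropane rings (a ring closes with loss of two hydrogens, exactly
    like a double bond, so PE 33:1 can stand for 16:0_17:1(cy9)).
    ``sn`` is 1, 2 or None (unknown glycerol position).
    """

    carbons: int
    unsat_equiv: int = 0
    mods: tuple[Modification, ...] = ()
    sn: int | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("acyl chain needs at least 2 carbons")
        if self.unsat_equiv < 0:
            raise ValueError("unsaturation equivalents must be >= 0")
        mods = tuple(
            m if isinstance(m, Modification) else Modification(*m) for m in self.mods
        )
        object.__setattr__(self, "mods", mods)
        if len(mods) > self.unsat_equiv:
            raise ValueError("more located modifications than unsaturation equivalents")
        for mod in mods:
            limit = self.carbons - 1 if mod.kind == DOUBLE_BOND else self.carbons - 2
            if mod.position > limit:
                raise ValueError(
                    f"{mod.kind} at position {mod.position} does not fit in a "
                    f"{self.carbons}-carbon chain"
                )
        if self.sn not in (None, 1, 2):
            raise ValueError("sn must be 1, 2 or None")

    @property
    def formula(self) -> ElementalFormula:
        """Formula of the free fatty acid CnH(2n-2y)O2."""
        return acyl_chain_formula(self.carbons, self.unsat_equiv)

    @property
    def mass(self) -> float:
        return self.formula.mass

    def label(self) -> str:
        base = f"{self.carbons}:{self.unsat_equiv}"
        for mod in self.mods:
            tag = f"Δ{mod.position}" if mod.kind == DOUBLE_BOND else f"cy{mod.position}"
            base += f"({tag})"
        return base


def acyl_chain_formula(carbons: int, unsat_equiv: int = 0) -> ElementalFormula:
    """Free fatty-acid formula CnH(2n-2y)O2 for an ``n:y`` chain."""
    hydrogens = 2 * carbons - 2 * unsat_equiv
    if hydrogens < 2:
        raise ValueError(f"chain {carbons}:{unsat_equiv} is over-unsaturated")
    return ElementalFormula({"C": carbons, "H": hydrogens, "O": 2})


def carboxylate_mz(carbons: int, unsat_equiv: int = 0) -> float:
    """m/z of the fatty-acid carboxylate anion [CnH(2n-1-2y)O2]-."""
    return acyl_chain_formula(carbons, unsat_equiv).mass - PROTON_MASS


_ID_LEVELS = ("sum_composition", "chain_composition", "sn_position", "modification_localized")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at some identification level.

    At ``sum_composition`` level only the totals are meaningful and the
    species carries a single pseudo-chain holding them; above that, chains
    are individually resolved (2 chains, or 4 for cardiolipin).
    """

    lipid_class: str
    chains: tuple[AcylChain, ...]
    id_level: str = "chain_composition"

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class: {self.lipid_class!r}")
        if self.id_level not in _ID_LEVELS:
            raise ValueError(f"unknown id level: {self.id_level!r}")
        chains = tuple(self.chains)
        object.__setattr__(self, "chains", chains)
        expected = 4 if self.lipid_class == "CDL" else 2
        if self.id_level == "sum_composition":
            if len(chains) != 1:
                raise ValueError("sum-composition species carries exactly one totals chain")
        elif len(chains) != expected:
            raise ValueError(
                f"{self.lipid_class} requires {expected} chains, got {len(chains)}"
            )

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_unsat(self) -> int:
        return sum(c.unsat_equiv for c in self.chains)

    @property
    def sum_composition(self) -> str:
        return f"{self.lipid_class} {self.total_carbons}:{self.total_unsat}"

    @property
    def formula(self) -> ElementalFormula:
        return species_formula(self)

    @property
    def monoisotopic_mass(self) -> float:
        return self.formula.mass

    def at_level(self, id_level: str) -> "LipidSpecies":
        return replace(self, id_level=id_level)


def species_formula(species: LipidSpecies) -> ElementalFormula:
    """Neutral elemental formula of a lipid species.

    Glycerophospholipids: glycerol + two esterified fatty acids (-H2O each)
    + phosphate (-H2O) + head-group residue (-H2O, except PA).
    Cardiolipin: two phosphatidic-acid moieties bridged by glycerol (-2 H2O).
    """
    if species.id_level == "sum_composition":
        # Totals chain stands in for the diacyl (or tetraacyl) sum.
        totals = species.chains[0]
        if species.lipid_class == "CDL":
            chains = _split_totals(totals, 4)
        else:
            chains = _split_totals(totals, 2)
    else:
        chains = species.chains

    def pa_formula(two_chains: Iterable[AcylChain]) -> ElementalFormula:
        out = GLYCEROL + PHOSPHORIC_ACID - WATER
        for chain in two_chains:
            out = out + chain.formula - WATER
        return out

    if species.lipid_class == "CDL":
        a, b = chains[:2], chains[2:]
        return pa_formula(a) + pa_formula(b) + GLYCEROL - 2 * WATER
    residue = _HEADGROUP_RESIDUE[species.lipid_class]
    out = pa_formula(chains)
    if residue is not None:
        out = out + residue - WATER
    return out


def _split_totals(totals: AcylChain, n: int) -> tuple[AcylChain, ...]:
    """Arbitrary chain split of a sum composition; the formula only depends
    on the totals, so any split gives the right mass."""
    carbons = [totals.carbons // n] * n
    carbons[0] += totals.carbons - sum(carbons)
    unsat = [0] * n
    unsat[0] = totals.unsat_equiv
    # keep each pseudo-chain chemically possible
    while 2 * carbons[0] - 2 * unsat[0] < 2 and unsat[0] > 0:
        unsat[0] -= 1
        unsat[1] += 1
    return tuple(AcylChain(c, u) for c, u in zip(carbons, unsat))


_ADDUCTS = {
    "+H": (PROTON_MASS, +1),
    "+Na": (_monoisotopic("Na") - ELECTRON_MASS, +1),
    "-H": (-PROTON_MASS, -1),
}


@dataclass(frozen=True)
class LipidIon:
    """A charged lipid: species + adduct (+H, +Na or -H), singly charged."""

    species: LipidSpecies
    adduct: str

    def __post_init__(self) -> None:
        if self.adduct not in _ADDUCTS:
            raise ValueError(f"unknown adduct: {self.adduct!r} (use +H, +Na or -H)")
        if self.species.lipid_class == "CDL" and self.adduct != "-H":
            raise ValueError("cardiolipin is modeled as [M-H]- only")

    @property
    def charge(self) -> int:
        return _ADDUCTS[self.adduct][1]

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @property
    def theoretical_mz(self) -> float:
        delta, charge = _ADDUCTS[self.adduct]
        return (self.species.monoisotopic_mass + delta) / abs(charge)

    def label(self) -> str:
        return f"{format_shorthand(self.species)} [{'M' + self.adduct}]{'+' if self.charge > 0 else '-'}"


def build_lipid_ion(
    lipid_class: str,
    chains: Iterable[AcylChain | tuple],
    adduct: str,
    id_level: str = "chain_composition",
) -> LipidIon:
    """Assemble a singly charged lipid ion from class, chains and adduct.

    Chains may be ``AcylChain`` objects or ``(carbons, unsat_equiv)`` tuples.
    """
    norm = tuple(
        c if isinstance(c, AcylChain) else AcylChain(*c) for c in chains
    )
    species = LipidSpecies(lipid_class, norm, id_level=id_level)
    return LipidIon(species, adduct)


# ---------------------------------------------------------------------------
# Shorthand nomenclature
#
# Grammar:   CLASS SPACE total:unsat                     (sum composition)
#          | CLASS SPACE chain (SEP chain)+              (resolved chains)
# chain:     C:U annotation*      annotation: "(ΔN)" | "(cyN)" | "(NZ)"
# SEP:       "/" (sn positions known, listed sn-1 first) or "_" (unknown)
# ---------------------------------------------------------------------------

_CHAIN_RE = re.compile(r"(\d+):(\d+)((?:\([^)]*\))*)")
_ANNOT_RE = re.compile(r"\(([^)]*)\)")


class ShorthandError(ValueError):
    """Malformed lipid shorthand; carries the offending position."""

    def __init__(self, text: str, pos: int, message: str):
        self.text, self.pos = text, pos
        super().__init__(f"{message} at position {pos} in {text!r}")


def _parse_chain(token: str, text: str, offset: int, sn: int | None) -> AcylChain:
    m = _CHAIN_RE.fullmatch(token)
    if not m:
        raise ShorthandError(text, offset, f"bad chain token {token!r}")
    carbons, unsat = int(m.group(1)), int(m.group(2))
    mods = []
    for am in _ANNOT_RE.finditer(m.group(3) or ""):
        a = am.group(1).strip()
        if a.lower().startswith("cy"):
            mods.append(Modification(CYCLOPROPANE, int(a[2:])))
        elif a.startswith(("Δ", "d", "D")):
            mods.append(Modification(DOUBLE_BOND, int(a[1:])))
        elif a.endswith(("Z", "E", "z", "e")) and a[:-1].isdigit():
            # geometry is noted in vendor names but not modeled
            mods.append(Modification(DOUBLE_BOND, int(a[:-1])))
        else:
            raise ShorthandError(text, offset, f"bad annotation {a!r}")
    try:
        return AcylChain(carbons, unsat, tuple(mods), sn=sn)
    except ValueError as exc:
        raise ShorthandError(text, offset, str(exc)) from None


def parse_shorthand(text: str) -> LipidSpecies:
    """Parse shorthand such as ``"PE 34:1"``, ``"PE 16:0/18:1"`` or
    ``"PG 17:1_19:1"``.

    A ``/`` separator records the printed order as sn-1/sn-2 (glycerol
    positions known); ``_`` leaves sn positions unknown. Located
    modifications use ``(ΔN)`` for a double bond and ``(cyN)`` for a
    cyclopropane ring, e.g. ``"PG 18:1(Δ11)_19:1(cy11)"``.
    """
    text = text.strip()
    head, sep, rest = text.partition(" ")
    if not sep or head not in LIPID_CLASSES:
        raise ShorthandError(text, 0, "expected 'CLASS chains'")
    rest = rest.strip()
    if not rest:
        raise ShorthandError(text, len(head), "missing chain description")
    if "/" in rest and "_" in rest:
        raise ShorthandError(text, len(head) + 1, "mixed '/' and '_' separators")
    sep_char = "/" if "/" in rest else "_"
    tokens = rest.split(sep_char)
    offset = len(head) + 1
    if len(tokens) == 1:
        chain = _parse_chain(tokens[0], text, offset, sn=None)
        if chain.mods:
            raise ShorthandError(text, offset, "sum composition cannot carry positions")
        return LipidSpecies(head, (chain,), id_level="sum_composition")
    sn_known = sep_char == "/" and head != "CDL" and len(tokens) == 2
    chains = []
    for i, token in enumerate(tokens):
        sn = (i + 1) if sn_known else None
        chains.append(_parse_chain(token.strip(), text, offset, sn))
        offset += len(token) + 1
    level = "sn_position" if sn_known else "chain_composition"
    if any(c.mods for c in chains):
        level = "modification_localized"
    try:
        return LipidSpecies(head, tuple(chains), id_level=level)
    except ValueError as exc:
        raise ShorthandError(text, 0, str(exc)) from None


def format_shorthand(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_shorthand`."""
    if species.id_level == "sum_composition":
        return species.sum_composition
    sep = "/" if species.id_level in ("sn_position", "modification_localized") and all(
        c.sn is not None for c in species.chains
    ) else "_"
    ordered = species.chains
    if sep == "/":
        ordered = tuple(sorted(species.chains, key=lambda c: c.sn))
    return f"{species.lipid_class} " + sep.join(c.label() for c in ordered)
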