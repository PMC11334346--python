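"""Chemical species and the degree-of-reduction calculus.

Everything downstream — reaction balancing audits, carbon/electron recovery,
the CO yield chain — rests on two primitives defined here: a molecular
formula as an element→count map, and the *degree of reduction* γ, the
per-mole count of available electrons obtained by weighting each atom with
an effective electron number (C = +4, H = +1, O = −2 by convention; Cl = 0
for the chloroethene series, so each hydrogenolysis step is electron-neutral
on the organic skeleton and the two electrons arrive with H₂).

A small registry ships the species of a CO-fed TCE-dechlorinating microcosm
(CO, CO₂, H₂, H₂O, CH₄, ethene, acetate, TCE, cDCE, VC, HCl) together with
standard Gibbs energies of formation from the CRC Handbook of Chemistry and
Physics, 84th edition, where a defensible value exists.
"""

from __future__ import annotations

import csv
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources
from pathlib import Path

__all__ = [
    "PERIODIC_SYMBOLS",
    "Phase",
    "FormulaError",
    "ElementCount",
    "parse_formula",
    "format_formula",
    "carbon_count",
    "ElectronNumberScheme",
    "DEFAULT_SCHEME",
    "degree_of_reduction",
    "Compound",
    "CompoundRegistry",
    "load_registry",
    "default_registry",
    "round_half_up",
]

#: The 118 IUPAC element symbols (validation set for formula parsing).
PERIODIC_SYMBOLS: frozenset[str] = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

PHASES = ("gas", "liquid", "aqueous")
Phase = str  # one of PHASES


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of printed tables.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    how measurement tables are typically typeset (e.g. 4.15 → 4.2, not 4.2
    vs 4.1 depending on parity).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementCount(Mapping):
    """Immutable element→count map; the atomic composition of one species.

    Counts are positive integers; symbols are validated against the periodic
    table. Hashable, so it can live inside frozen :class:`Compound` objects
    and be used as a dict key.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for sym, n in counts.items():
            if sym not in PERIODIC_SYMBOLS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            n = int(n)
            if n < 1:
                raise FormulaError(f"count for {sym} must be >= 1, got {n}")
            clean[sym] = n
        self._counts = dict(sorted(clean.items()))
        self._hash = hash(tuple(self._counts.items()))

    def __getitem__(self, sym: str) -> int:
        return self._counts[sym]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementCount):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __repr__(self) -> str:
        return f"ElementCount({self._counts!r})"

    def __add__(self, other: "ElementCount") -> "ElementCount":
        merged = dict(self._counts)
        for sym, n in other.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementCount(merged)


def parse_formula(text: str) -> ElementCount:
    """Parse a condensed molecular formula into element counts.

    The grammar is a sequence of (element symbol, optional count) pairs;
    repeated symbols accumulate, so structural spellings like ``CH3COOH``
    parse to the same composition as the Hill form ``C2H4O2``.

    Raises
    ------
    FormulaError
        On an empty string, a token that is not a periodic symbol, or
        trailing garbage.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in PERIODIC_SYMBOLS:
            # A two-letter match may hide a valid one-letter symbol, e.g. "Hc"
            # in pathological input; retry with the single capital.
            if sym[0] in PERIODIC_SYMBOLS and len(sym) == 2:
                sym, digits = sym[0], ""
                m = re.compile(rf"{sym}(\d*)").match(text, pos)
                digits = m.group(1)
            else:
                raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos += len(sym) + len(digits)
    return ElementCount(counts)


def format_formula(formula: ElementCount) -> str:
    """Write counts in Hill order (C, then H, then alphabetical)."""

    def key(sym: str) -> tuple[int, str]:
        if "C" in formula:
            return {"C": (0, ""), "H": (1, "")}.get(sym, (2, sym))
        return (2, sym)

    parts = []
    for sym in sorted(formula, key=key):
        n = formula[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def carbon_count(formula: ElementCount) -> int:
    """Number of carbon atoms (0 if carbon-free)."""
    return formula.get("C", 0)


@dataclass(frozen=True)
class ElectronNumberScheme:
    """Per-atom effective electron numbers used by the γ calculus.

    The default assigns C=+4, H=+1, O=−2 (the classical degree-of-reduction
    weights) plus Cl=0 and N=0. Cl=0 is the unique value consistent with the
    published electron recoveries of CO-fed bottles when TCE is counted as an
    electron-bearing substrate; N=0 is an extension for convenience and is
    not exercised by the shipped species set.
    """

    values: Mapping[str, Fraction] = field(
        default_factory=lambda: {
            "C": Fraction(4),
            "H": Fraction(1),
            "O": Fraction(-2),
            "Cl": Fraction(0),
            "N": Fraction(0),
        }
    )

    def __post_init__(self):
        vals = {str(k): Fraction(v) for k, v in self.values.items()}
        for required in ("C", "H", "O"):
            if required not in vals:
                raise ValueError(f"scheme must define element {required}")
        object.__setattr__(self, "values", vals)

    def gamma(self, formula: ElementCount) -> Fraction:
        missing = [sym for sym in formula if sym not in self.values]
        if missing:
            raise KeyError(
                "no effective electron number for element(s): "
                + ", ".join(sorted(missing))
            )
        return sum(
            (Fraction(n) * self.values[sym] for sym, n in formula.items()),
            Fraction(0),
        )


DEFAULT_SCHEME = ElectronNumberScheme()


def degree_of_reduction(
    formula: ElementCount, scheme: ElectronNumberScheme = DEFAULT_SCHEME
) -> Fraction:
    """Degree of reduction γ = Σ count(e) · electron_number(e), per mole.

    Examples: γ(CH₄)=8, γ(CO)=2, γ(CO₂)=0, γ(H₂)=2, γ(C₂HCl₃)=9 with Cl=0.
    Raises ``KeyError`` listing any element absent from the scheme — an
    unknown element is never silently worth zero electrons.
    """
    return scheme.gamma(formula)


@dataclass(frozen=True)
class Compound:
    """A named species: composition, phase, optional ΔfG′° and charge.

    ``formation_energy`` is the standard Gibbs energy of formation in kJ/mol
    at 298.15 K for the stated phase; ``None`` when no defensible constant is
    shipped (TCE, cDCE, VC). Elemental reference species (single-element,
    neutral, e.g. H₂) must carry ΔfG = 0 when a value is present.
    """

    name: str
    formula: ElementCount
    phase: Phase
    formation_energy: float | None = None
    charge: int = 0

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(
                f"phase must be one of {PHASES}, got {self.phase!r} for {self.name}"
            )
        if (
            self.formation_energy is not None
            and len(self.formula) == 1
            and self.charge == 0
            and self.formation_energy != 0.0
        ):
            raise ValueError(
                f"elemental reference species {self.name} must have "
                f"formation energy 0, got {self.formation_energy}"
            )

    @property
    def gamma(self) -> Fraction:
        return DEFAULT_SCHEME.gamma(self.formula)

    @property
    def carbons(self) -> int:
        return carbon_count(self.formula)

    def __str__(self) -> str:
        return self.name


#: Alternative spellings accepted when resolving species names.
ALIASES: dict[str, str] = {
    "CH3COOH": "acetate",
    "C2H4O2": "acetate",
    "acetic acid": "acetate",
    "C2H4": "ethene",
    "ethylene": "ethene",
    "methane": "CH4",
    "C2HCl3": "TCE",
    "trichloroethene": "TCE",
    "C2H2Cl2": "cDCE",
    "C2H3Cl": "VC",
    "vinyl chloride": "VC",
    "water": "H2O",
    "hydrogen": "H2",
}


class CompoundRegistry(Mapping):
    """Name → :class:`Compound` lookup with alias resolution."""

    def __init__(self, compounds: list[Compound], aliases: Mapping[str, str] | None = None):
        self._by_name = {c.name: c for c in compounds}
        self._aliases = dict(ALIASES if aliases is None else aliases)

    def __getitem__(self, name: str) -> Compound:
        key = name.strip()
        if key in self._by_name:
            return self._by_name[key]
        if key in self._aliases:
            return self._by_name[self._aliases[key]]
        raise KeyError(f"unknown species: {name!r}")

    def __contains__(self, name: object) -> bool:
        try:
            self[str(name)]
        except KeyError:
            return False
        return True

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_name)

    def __len__(self) -> int:
        return len(self._by_name)

    def formation_energies(self) -> dict[str, float]:
        """Name → ΔfG′° (kJ/mol) for every compound that carries one."""
        return {
            c.name: c.formation_energy
            for c in self._by_name.values()
            if c.formation_energy is not None
        }


def load_registry(path: str | Path) -> CompoundRegistry:
    """Load a constants table (columns name, formula, phase, dfG_kJ_per_mol,
    source) into a registry. Empty dfG cells mean "no constant shipped"."""
    compounds = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            dfg = row.get("dfG_kJ_per_mol", "").strip()
            compounds.append(
                Compound(
                    name=row["name"].strip(),
                    formula=parse_formula(row["formula"].strip()),
                    phase=row["phase"].strip(),
                    formation_energy=float(dfg) if dfg else None,
                )
            )
    return CompoundRegistry(compounds)


def default_registry() -> CompoundRegistry:
    """The packaged microcosm species set with CRC-derived constants."""
    path = resources.files("cobalance.data").joinpath("formation_energies.csv")
    with resources.as_file(path) as p:
        return load_registry(p)
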