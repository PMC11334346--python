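"""Reactions: stoichiometry, balancing audits, ΔrG′° and Hess combination.

A reaction is a signed stoichiometric map over registry compounds (negative
coefficients consumed, positive formed) with an optional standard-state
Gibbs energy ΔrG′° (kJ per mole of reaction as written, 298.15 K, gases at
1 atm, solutes at 1 M). Coefficients are exact rationals so that Hess-law
combination cancels species exactly; decimals appear only at presentation.

The packaged reaction file carries the seven-reaction ledger of a CO-fed
dechlorinating microcosm: hydrogenolysis of TCE to ethene, the biological
water-gas shift CO + H₂O → CO₂ + H₂, acetogenesis from H₂/CO₂ and directly
from CO (the Wood–Ljungdahl route), and aceticlastic plus hydrogenotrophic
plus carboxydotrophic methanogenesis. The composite rows are exact linear
combinations of the elementary ones (Hess's law), which the audit machinery
verifies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path

from .compounds import (
    Compound,
    CompoundRegistry,
    DEFAULT_SCHEME,
    ElectronNumberScheme,
    default_registry,
)

__all__ = [
    "Reaction",
    "ReactionError",
    "BalanceAudit",
    "parse_reaction",
    "load_reactions",
    "default_reactions",
    "audit_balance",
    "delta_g_standard",
    "combine_reactions",
    "MissingFormationEnergy",
]


class ReactionError(ValueError):
    """Malformed reaction text or an ill-formed stoichiometric map."""


class MissingFormationEnergy(KeyError):
    """ΔrG′° requested but a compound lacks a formation-energy constant."""


@dataclass(frozen=True, eq=False)
class Reaction:
    """Signed stoichiometric map with an optional ΔrG′° (kJ/mol)."""

    name: str
    stoich: dict[Compound, Fraction]
    delta_g_standard: float | None = None

    def __post_init__(self):
        stoich = {c: Fraction(v) for c, v in self.stoich.items()}
        if any(v == 0 for v in stoich.values()):
            raise ReactionError(f"{self.name}: zero stoichiometric coefficient")
        if not any(v < 0 for v in stoich.values()):
            raise ReactionError(f"{self.name}: no reactant (negative coefficient)")
        if not any(v > 0 for v in stoich.values()):
            raise ReactionError(f"{self.name}: no product (positive coefficient)")
        object.__setattr__(self, "stoich", stoich)

    @property
    def reactants(self) -> dict[Compound, Fraction]:
        return {c: -v for c, v in self.stoich.items() if v < 0}

    @property
    def products(self) -> dict[Compound, Fraction]:
        return {c: v for c, v in self.stoich.items() if v > 0}

    def equation(self) -> str:
        def side(terms: dict[Compound, Fraction]) -> str:
            parts = []
            for c, v in terms.items():
                coeff = "" if v == 1 else f"{v} "
                parts.append(f"{coeff}{c.name}({c.phase[0]})")
            return " + ".join(parts)

        return f"{side(self.reactants)} -> {side(self.products)}"

    def __str__(self) -> str:
        return f"{self.name}: {self.equation()}"


_SPECIES = re.compile(
    r"^\s*(?P<coeff>\d+(?:/\d+)?(?:\.\d+)?)?\s*"
    r"(?P<name>[A-Za-z][A-Za-z0-9_\- ]*?)\s*"
    r"(?:\((?P<phase>g|l|aq)\))?\s*$"
)
_PHASE_ABBREV = {"g": "gas", "l": "liquid", "aq": "aqueous"}


def _parse_side(
    text: str, registry: CompoundRegistry, rxn_name: str, sign: int
) -> dict[Compound, Fraction]:
    out: dict[Compound, Fraction] = {}
    text = text.strip()
    if not text:
        raise ReactionError(f"{rxn_name}: empty reaction side")
    for term in text.split("+"):
        m = _SPECIES.match(term)
        if not m:
            raise ReactionError(f"{rxn_name}: cannot parse term {term.strip()!r}")
        coeff = Fraction(m.group("coeff")) if m.group("coeff") else Fraction(1)
        try:
            compound = registry[m.group("name")]
        except KeyError as exc:
            raise ReactionError(f"{rxn_name}: {exc.args[0]}") from None
        phase = m.group("phase")
        if phase and _PHASE_ABBREV[phase] != compound.phase:
            raise ReactionError(
                f"{rxn_name}: phase annotation ({phase}) conflicts with "
                f"registry phase {compound.phase!r} for {compound.name}"
            )
        out[compound] = out.get(compound, Fraction(0)) + sign * coeff
    return out


def parse_reaction(
    text: str, registry: CompoundRegistry | None = None
) -> Reaction:
    """Parse ``"name: 4 CO(g) + 2 H2O(l) -> 2 CO2(g) + CH3COOH"``.

    Coefficients default to 1 and may be integers, fractions (``1/2``) or
    decimals; species are resolved against the compound registry (aliases
    included); a trailing ``; dG=<value>`` attaches a ΔrG′° ledger constant.
    """
    if registry is None:
        registry = default_registry()
    raw = text.strip()
    dg: float | None = None
    if ";" in raw:
        raw, annot = raw.split(";", 1)
        m = re.match(r"\s*dG\s*=\s*(-?\d+(?:\.\d+)?)\s*$", annot)
        if not m:
            raise ReactionError(f"bad annotation {annot.strip()!r}")
        dg = float(m.group(1))
    if ":" in raw:
        name, eq = raw.split(":", 1)
        name = name.strip()
    else:
        name, eq = "reaction", raw
    if "->" not in eq:
        raise ReactionError(f"{name}: missing '->' arrow")
    lhs, rhs = eq.split("->", 1)
    stoich = _parse_side(lhs, registry, name, -1)
    for c, v in _parse_side(rhs, registry, name, +1).items():
        stoich[c] = stoich.get(c, Fraction(0)) + v
    stoich = {c: v for c, v in stoich.items() if v != 0}
    return Reaction(name=name, stoich=stoich, delta_g_standard=dg)


def load_reactions(
    path: str | Path, registry: CompoundRegistry | None = None
) -> list[Reaction]:
    """Read a reaction file: one reaction per line, ``#`` comments allowed."""
    if registry is None:
        registry = default_registry()
    reactions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                reactions.append(parse_reaction(line, registry))
    return reactions


def default_reactions(registry: CompoundRegistry | None = None) -> list[Reaction]:
    """The packaged seven-reaction microcosm ledger."""
    path = resources.files("cobalance.data").joinpath("microcosm_reactions.txt")
    with resources.as_file(path) as p:
        return load_reactions(p, registry)


@dataclass(frozen=True)
class BalanceAudit:
    """Net product-minus-reactant deltas; all zero for a sound reaction."""

    element_delta: dict[str, Fraction]
    charge_delta: Fraction
    electron_delta: Fraction

    @property
    def balanced(self) -> bool:
        return (
            all(v == 0 for v in self.element_delta.values())
            and self.charge_delta == 0
            and self.electron_delta == 0
        )

    def failures(self) -> list[str]:
        def signed(v: Fraction) -> str:
            return f"+{v}" if v > 0 else str(v)

        msgs = [
            f"{el}: {signed(v)}"
            for el, v in sorted(self.element_delta.items())
            if v != 0
        ]
        if self.charge_delta != 0:
            msgs.append(f"charge: {signed(self.charge_delta)}")
        if self.electron_delta != 0:
            msgs.append(f"electrons: {signed(self.electron_delta)}")
        return msgs


def audit_balance(
    r: Reaction, scheme: ElectronNumberScheme = DEFAULT_SCHEME
) -> BalanceAudit:
    """Element, charge and γ-electron conservation check.

    The electron delta is Σ coeff·γ(compound): any reaction built purely
    from electron-pair transfers must conserve the degree-of-reduction sum,
    so a nonzero delta flags a typo in stoichiometry or an inconsistent
    electron-number scheme.
    """
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    electrons = Fraction(0)
    for compound, coeff in r.stoich.items():
        for sym, n in compound.formula.items():
            elements[sym] = elements.get(sym, Fraction(0)) + coeff * n
        charge += coeff * compound.charge
        electrons += coeff * scheme.gamma(compound.formula)
    return BalanceAudit(elements, charge, electrons)


def delta_g_standard(
    r: Reaction, constants: dict[str, float] | None = None
) -> float:
    """ΔrG′° = Σ coeff · ΔfG′°(compound), kJ per mole of reaction as written.

    ``constants`` maps compound names to formation energies; by default each
    compound's own ``formation_energy`` is used. A missing constant raises
    :class:`MissingFormationEnergy` naming the compound.
    """
    total = 0.0
    for compound, coeff in r.stoich.items():
        if constants is not None and compound.name in constants:
            dfg = constants[compound.name]
        else:
            dfg = compound.formation_energy
        if dfg is None:
            raise MissingFormationEnergy(
                f"no formation energy for {compound.name} (reaction {r.name})"
            )
        total += float(coeff) * dfg
    return total


def combine_reactions(
    terms: list[tuple[Fraction | int | float, Reaction]], name: str = "combined"
) -> Reaction:
    """Hess-law linear combination Σ mᵢ·reactionᵢ.

    Species whose coefficients cancel exactly are dropped. The combined
    ΔrG′° is Σ mᵢ·ΔrG′°ᵢ when every input carries one, else ``None``.
    An empty result (everything cancels) is an error.
    """
    stoich: dict[Compound, Fraction] = {}
    dgs: list[float] = []
    have_all_dg = True
    for mult, rxn in terms:
        mult = Fraction(mult) if not isinstance(mult, float) else Fraction(mult).limit_denominator(10**6)
        if mult == 0:
            raise ReactionError("zero multiplier in combination")
        for compound, coeff in rxn.stoich.items():
            stoich[compound] = stoich.get(compound, Fraction(0)) + mult * coeff
        if rxn.delta_g_standard is None:
            have_all_dg = False
        else:
            dgs.append(float(mult) * rxn.delta_g_standard)
    stoich = {c: v for c, v in stoich.items() if v != 0}
    if not stoich:
        raise ReactionError("null reaction: all species cancelled")
    dg = sum(dgs) if have_all_dg else None
    return Reaction(name=name, stoich=stoich, delta_g_standard=dg)
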