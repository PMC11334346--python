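"""Carbon- and electron-recovery statistics over per-bottle inventories.

A bottle experiment is summarised as substrate amounts consumed and product
amounts formed (µmol/bottle). Carbon recovery is the percentage of substrate
carbon found in the measured products, by convention *excluding CO₂* on
both sides (headspace CO₂ exchanges with a bicarbonate buffer and is not a
meaningful product measurement); electron recovery weights each species by
its degree of reduction γ instead of its carbon count. Residual unconsumed
substrate (nmol-scale H₂, leftover CO) is likewise excluded by default.

With every pool counted (residuals and CO₂ included) electron recovery of a
loss-free system is exactly 100 % — the conservation law the synthetic
generator is audited against.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .compounds import (
    Compound,
    CompoundRegistry,
    DEFAULT_SCHEME,
    ElectronNumberScheme,
    default_registry,
    round_half_up,
)

__all__ = [
    "BottleBalance",
    "RecoveryResult",
    "BalanceError",
    "carbon_recovery",
    "electron_recovery",
    "balance_report",
    "read_bottles_csv",
    "write_recovery_tsv",
]


class BalanceError(ValueError):
    """Ill-posed bottle inventory (negative amount, empty substrate side…)."""


def _is_co2(c: Compound) -> bool:
    return dict(c.formula) == {"C": 1, "O": 2}


@dataclass
class BottleBalance:
    """Substrates consumed and products formed for one treatment (µmol)."""

    treatment: str
    substrates: dict[Compound, float]
    products: dict[Compound, float]
    residuals: dict[Compound, float] = field(default_factory=dict)

    def __post_init__(self):
        for side in (self.substrates, self.products, self.residuals):
            for c, v in side.items():
                if v < 0:
                    raise BalanceError(
                        f"{self.treatment}: negative amount for {c.name}: {v}"
                    )
        overlap = set(self.substrates) & set(self.products)
        if overlap:
            raise BalanceError(
                f"{self.treatment}: species on both sides: "
                + ", ".join(c.name for c in overlap)
            )


@dataclass(frozen=True)
class RecoveryResult:
    """Both recovery statistics plus the underlying in/out totals."""

    treatment: str
    carbon_recovery_pct: float
    electron_recovery_pct: float
    carbon_in: float
    carbon_out: float
    electrons_in: float
    electrons_out: float


def _sides(
    b: BottleBalance, include_co2: bool, include_residuals: bool
) -> tuple[list[tuple[Compound, float]], list[tuple[Compound, float]]]:
    def keep(c: Compound) -> bool:
        return include_co2 or not _is_co2(c)

    inputs = [(c, v) for c, v in b.substrates.items() if keep(c)]
    outputs = [(c, v) for c, v in b.products.items() if keep(c)]
    if include_residuals:
        outputs += [(c, v) for c, v in b.residuals.items() if keep(c)]
    return inputs, outputs


def carbon_recovery(
    b: BottleBalance,
    include_co2: bool = False,
    include_residuals: bool = False,
) -> float:
    """Percent of substrate carbon recovered in products, 1 decimal.

    100 · Σ_products µmol·C / Σ_substrates µmol·C, CO₂ excluded from both
    sides unless ``include_co2``. Raises on zero substrate carbon.
    """
    inputs, outputs = _sides(b, include_co2, include_residuals)
    c_in = sum(v * c.carbons for c, v in inputs)
    c_out = sum(v * c.carbons for c, v in outputs)
    if c_in == 0:
        raise BalanceError(f"{b.treatment}: no substrate carbon")
    return round_half_up(100.0 * c_out / c_in, 1)


def electron_recovery(
    b: BottleBalance,
    scheme: ElectronNumberScheme = DEFAULT_SCHEME,
    include_co2: bool = False,
    include_residuals: bool = False,
) -> float:
    """Percent of substrate γ-electrons recovered in products, 1 decimal.

    Each amount is weighted by the species' degree of reduction; with the
    default scheme TCE contributes γ=9 electrons per µmol on the substrate
    side. CO₂ carries γ=0, so its inclusion flag only matters for carbon.
    """
    inputs, outputs = _sides(b, include_co2, include_residuals)
    e_in = float(sum(v * scheme.gamma(c.formula) for c, v in inputs))
    e_out = float(sum(v * scheme.gamma(c.formula) for c, v in outputs))
    if e_in == 0:
        raise BalanceError(f"{b.treatment}: no substrate electrons")
    return round_half_up(100.0 * e_out / e_in, 1)


def balance_report(
    b: BottleBalance,
    scheme: ElectronNumberScheme = DEFAULT_SCHEME,
    include_co2: bool = False,
    include_residuals: bool = False,
) -> RecoveryResult:
    """Bundle both statistics with raw in/out totals (µmol C, µmol e⁻)."""
    inputs, outputs = _sides(b, include_co2, include_residuals)
    if not b.substrates or not (b.products or (include_residuals and b.residuals)):
        raise BalanceError(f"{b.treatment}: empty bottle inventory")
    return RecoveryResult(
        treatment=b.treatment,
        carbon_recovery_pct=carbon_recovery(b, include_co2, include_residuals),
        electron_recovery_pct=electron_recovery(
            b, scheme, include_co2, include_residuals
        ),
        carbon_in=sum(v * c.carbons for c, v in inputs),
        carbon_out=sum(v * c.carbons for c, v in outputs),
        electrons_in=float(sum(v * scheme.gamma(c.formula) for c, v in inputs)),
        electrons_out=float(sum(v * scheme.gamma(c.formula) for c, v in outputs)),
    )


def read_bottles_csv(
    path: str | Path, registry: CompoundRegistry | None = None
) -> list[BottleBalance]:
    """Read bottle inventories from CSV (treatment, role, species, umol).

    ``role`` is one of substrate/product/residual; species names resolve
    against the registry (aliases accepted). Malformed rows raise
    :class:`BalanceError` with the offending line number.
    """
    if registry is None:
        registry = default_registry()
    bottles: dict[str, dict[str, dict[Compound, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"treatment", "role", "species", "umol"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise BalanceError(f"{path}: need columns {sorted(required)}")
        n = 0
        for i, row in enumerate(reader, start=2):
            n += 1
            role = row["role"].strip().lower()
            if role not in ("substrate", "product", "residual"):
                raise BalanceError(f"{path}:{i}: bad role {row['role']!r}")
            try:
                compound = registry[row["species"]]
            except KeyError as exc:
                raise BalanceError(f"{path}:{i}: {exc.args[0]}") from None
            try:
                umol = float(row["umol"])
            except ValueError:
                raise BalanceError(
                    f"{path}:{i}: bad amount {row['umol']!r}"
                ) from None
            slot = bottles.setdefault(
                row["treatment"].strip(),
                {"substrate": {}, "product": {}, "residual": {}},
            )
            slot[role][compound] = slot[role].get(compound, 0.0) + umol
    if n == 0:
        raise BalanceError(f"{path}: no records")
    return [
        BottleBalance(t, s["substrate"], s["product"], s["residual"])
        for t, s in bottles.items()
    ]


def write_recovery_tsv(results: list[RecoveryResult], path: str | Path) -> None:
    """Write a recovery table (percentages at 1 decimal, raw totals full)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "treatment",
                "carbon_recovery_pct",
                "electron_recovery_pct",
                "carbon_in_umol",
                "carbon_out_umol",
                "electrons_in_umol",
                "electrons_out_umol",
            ]
        )
        for r in results:
            w.writerow(
                [
                    r.treatment,
                    f"{r.carbon_recovery_pct:.1f}",
                    f"{r.electron_recovery_pct:.1f}",
                    repr(r.carbon_in),
                    repr(r.carbon_out),
                    repr(r.electrons_in),
                    repr(r.electrons_out),
                ]
            )
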