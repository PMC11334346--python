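"""Theoretical yield chain: CO gas dose → H₂ → dechlorination → acetate.

The reasoning chain for a CO-fed dechlorinating bottle:

1. a gas volume at lab conditions converts to moles (default molar volume
   24.5 L/mol ≈ ideal gas at 25 °C, 1 atm);
2. each CO yields at most one H₂ via the biological water-gas shift;
3. full hydrogenolysis TCE → ethene consumes 3 H₂ per TCE (one per
   chlorine removed);
4. residual H₂, if routed exclusively to acetogenesis (4 H₂ + 2 CO₂ →
   acetate), yields (H₂max − H₂dechlor)/4 acetate;
5. µmol over the liquid volume gives the predicted concentration in mM.

All functions return full-precision floats; round with
:func:`cobalance.compounds.round_half_up` for display. Results printed at
one decimal reproduce published desk arithmetic only when intermediate
values are *not* pre-rounded, so the chain keeps raw values throughout and
optionally accepts an as-printed intermediate for the dechlorination H₂
demand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compounds import round_half_up

__all__ = [
    "GasDose",
    "YieldChainResult",
    "gas_volume_to_umol",
    "max_h2_from_co",
    "h2_demand_dechlorination",
    "acetate_from_residual_h2",
    "umol_to_mM",
    "run_yield_chain",
]

#: Molar volume (L/mol) of an ideal gas at ~25 °C and 1 atm, rounded the way
#: bench calculations are customarily done.
DEFAULT_MOLAR_VOLUME = 24.5

#: H₂ consumed per TCE fully dechlorinated to ethene (one per Cl removed).
H2_PER_TCE = 3


@dataclass(frozen=True)
class GasDose:
    """A gas addition: volume in mL at the stated molar volume (L/mol)."""

    volume_ml: float
    molar_volume: float = DEFAULT_MOLAR_VOLUME

    def __post_init__(self):
        if self.volume_ml < 0:
            raise ValueError(f"negative gas volume: {self.volume_ml} mL")
        if self.molar_volume <= 0:
            raise ValueError(f"molar volume must be > 0: {self.molar_volume}")

    @property
    def umol(self) -> float:
        return gas_volume_to_umol(self)


def gas_volume_to_umol(dose: GasDose) -> float:
    """µmol of gas in a dose: 1000 · volume_mL / molar_volume_L_per_mol."""
    return 1000.0 * dose.volume_ml / dose.molar_volume


def max_h2_from_co(co_umol: float) -> float:
    """Maximum theoretical H₂ from CO oxidation, 1:1 (water-gas shift)."""
    if co_umol < 0:
        raise ValueError(f"negative CO amount: {co_umol}")
    return co_umol


def h2_demand_dechlorination(tce_umol: float, chlorines_removed: int = H2_PER_TCE) -> float:
    """H₂ (µmol) consumed dechlorinating ``tce_umol`` of TCE.

    One H₂ per chlorine removed: 3 for the full TCE → ethene sequence,
    1 for TCE → cDCE only, 2 for TCE → VC.
    """
    if tce_umol < 0:
        raise ValueError(f"negative TCE amount: {tce_umol}")
    if not 0 <= chlorines_removed <= 3:
        raise ValueError("chlorines_removed must be between 0 and 3")
    return tce_umol * chlorines_removed


def acetate_from_residual_h2(h2_max_umol: float, h2_consumed_umol: float) -> float:
    """Acetate (µmol) from residual H₂ routed to acetogenesis (4 H₂ each)."""
    if h2_consumed_umol > h2_max_umol:
        raise ValueError(
            f"H2 consumed ({h2_consumed_umol}) exceeds maximum ({h2_max_umol})"
        )
    return (h2_max_umol - h2_consumed_umol) / 4.0


def umol_to_mM(amount_umol: float, liquid_volume_ml: float) -> float:
    """µmol per bottle over liquid volume in mL equals mmol/L = mM."""
    if liquid_volume_ml <= 0:
        raise ValueError(f"liquid volume must be > 0: {liquid_volume_ml}")
    return amount_umol / liquid_volume_ml


@dataclass(frozen=True)
class YieldChainResult:
    """Full-precision intermediates of one yield-chain evaluation."""

    co_umol: float
    h2_max_umol: float
    h2_dechlor_umol: float
    h2_residual_umol: float
    acetate_umol: float
    acetate_mM: float

    def rows(self) -> list[tuple[str, float, float]]:
        """(label, display value at 1 decimal, raw value) rows."""
        fields = [
            ("CO dosed (umol)", self.co_umol),
            ("max H2 from CO (umol)", self.h2_max_umol),
            ("H2 for dechlorination (umol)", self.h2_dechlor_umol),
            ("residual H2 (umol)", self.h2_residual_umol),
            ("acetate (umol)", self.acetate_umol),
            ("acetate (mM)", self.acetate_mM),
        ]
        return [(label, round_half_up(v, 1), v) for label, v in fields]


def run_yield_chain(
    co_ml: float,
    tce_umol: float,
    liquid_volume_ml: float = 80.0,
    h2_demand_umol: float | None = None,
    molar_volume: float = DEFAULT_MOLAR_VOLUME,
) -> YieldChainResult:
    """Run the whole chain from a CO gas volume to an acetate concentration.

    ``h2_demand_umol`` overrides the computed 3·TCE demand with a stated
    intermediate (e.g. a rounded figure from a prior calculation) so that
    as-printed chains can be reproduced exactly.
    """
    co = gas_volume_to_umol(GasDose(co_ml, molar_volume))
    h2_max = max_h2_from_co(co)
    h2_dechlor = (
        h2_demand_umol
        if h2_demand_umol is not None
        else h2_demand_dechlorination(tce_umol)
    )
    acetate = acetate_from_residual_h2(h2_max, h2_dechlor)
    return YieldChainResult(
        co_umol=co,
        h2_max_umol=h2_max,
        h2_dechlor_umol=h2_dechlor,
        h2_residual_umol=h2_max - h2_dechlor,
        acetate_umol=acetate,
        acetate_mM=umol_to_mM(acetate, liquid_volume_ml),
    )
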