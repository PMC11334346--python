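"""Bookkeeping over dechlorination time series and CO dose schedules.

Chloroethene molar closure: along TCE → cDCE → VC → ethene the ethene
skeleton is conserved, so the four-species molar sum should stay at the
initial TCE amount at every timepoint; the maximum relative deviation from
that total is the standard sanity check on a measured (or simulated)
series. Dose schedules track cumulative CO additions in mL and µmol, and
fold change summarises dechlorinator growth from cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .yield_chain import GasDose, gas_volume_to_umol

__all__ = [
    "CHLOROETHENE_SPECIES",
    "TIMECOURSE_SPECIES",
    "DoseSchedule",
    "TimeCourse",
    "chloroethene_closure",
    "cumulative_dose",
    "fold_change",
]

#: The ethene-skeleton series whose molar sum is conserved by hydrogenolysis.
CHLOROETHENE_SPECIES = ("TCE", "cDCE", "VC", "ethene")

#: Canonical species axis of a bottle time course (amounts µmol/bottle).
TIMECOURSE_SPECIES = ("TCE", "cDCE", "VC", "ethene", "H2", "acetate", "CH4")


@dataclass(frozen=True)
class DoseSchedule:
    """Timed gas additions: ordered (time_days, GasDose) entries."""

    entries: tuple[tuple[float, GasDose], ...]

    def __post_init__(self):
        times = [t for t, _ in self.entries]
        if any(t < 0 for t in times):
            raise ValueError("dose times must be >= 0")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("dose times must be non-decreasing")
        object.__setattr__(self, "entries", tuple(self.entries))

    @classmethod
    def regular(
        cls, n_doses: int, volume_ml: float, interval_days: float, start: float = 0.0
    ) -> "DoseSchedule":
        """n equal doses at fixed intervals, first at ``start``."""
        return cls(
            tuple(
                (start + i * interval_days, GasDose(volume_ml))
                for i in range(n_doses)
            )
        )

    @property
    def total_ml(self) -> float:
        return sum(d.volume_ml for _, d in self.entries)


def cumulative_dose(
    ds: DoseSchedule, until: float = np.inf
) -> tuple[float, float]:
    """Total (mL, µmol) of gas dosed at times ≤ ``until``."""
    ml = 0.0
    umol = 0.0
    for t, dose in ds.entries:
        if t <= until:
            ml += dose.volume_ml
            umol += gas_volume_to_umol(dose)
    return ml, umol


@dataclass
class TimeCourse:
    """Species trajectories of one bottle: a frame with ``time_d`` plus a
    fixed, named species axis (µmol/bottle) and optional cell counts.

    H₂ is carried in µmol like everything else; use ``h2_nmol()`` for the
    nmol scale customary for trace-level dissolved-H₂ measurements.
    """

    frame: pd.DataFrame
    cell_counts: np.ndarray | None = None  # cells/mL, aligned with times

    def __post_init__(self):
        if "time_d" not in self.frame.columns:
            raise ValueError("TimeCourse frame needs a 'time_d' column")
        species = [c for c in self.frame.columns if c != "time_d"]
        unknown = set(species) - set(TIMECOURSE_SPECIES)
        if unknown:
            raise ValueError(f"unknown species column(s): {sorted(unknown)}")
        neg = [
            s for s in species if (self.frame[s].to_numpy(float) < -1e-12).any()
        ]
        if neg:
            raise ValueError(f"negative amounts in column(s): {neg}")

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_d"].to_numpy(float)

    @property
    def species(self) -> list[str]:
        return [c for c in self.frame.columns if c != "time_d"]

    def amounts(self, species: str) -> np.ndarray:
        return self.frame[species].to_numpy(float)

    def h2_nmol(self) -> np.ndarray:
        return self.amounts("H2") * 1000.0

    def to_csv(self, path: str | Path, bottle_id: str = "bottle") -> None:
        """Long-format CSV: bottle_id, time_d, species, amount, unit."""
        rows = []
        for s in self.species:
            for t, v in zip(self.times, self.amounts(s)):
                rows.append((bottle_id, t, s, v, "umol"))
        pd.DataFrame(
            rows, columns=["bottle_id", "time_d", "species", "amount", "unit"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourse":
        long = pd.read_csv(path)
        wide = long.pivot_table(
            index="time_d", columns="species", values="amount"
        ).reset_index()
        wide.columns.name = None
        cols = ["time_d"] + [s for s in TIMECOURSE_SPECIES if s in wide.columns]
        return cls(wide[cols])


def chloroethene_closure(tc: TimeCourse) -> tuple[np.ndarray, float]:
    """Per-timepoint chloroethene+ethene total and its max relative drift.

    Returns (totals µmol, max |total − total₀| / total₀). Zero drift means
    the series conserves the ethene skeleton exactly.
    """
    missing = [s for s in CHLOROETHENE_SPECIES if s not in tc.species]
    if missing:
        raise ValueError(f"closure needs species {missing}")
    if len(tc.frame) == 0:
        raise ValueError("empty time series")
    totals = sum(tc.amounts(s) for s in CHLOROETHENE_SPECIES)
    t0 = totals[0]
    if t0 == 0:
        raise ValueError("initial chloroethene total is zero")
    deviation = float(np.max(np.abs(totals - t0)) / t0)
    return totals, deviation


def fold_change(initial: float, final: float) -> float:
    """Cell-count ratio final/initial (growth fold change)."""
    if initial <= 0:
        raise ValueError(f"initial count must be > 0, got {initial}")
    return final / initial
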