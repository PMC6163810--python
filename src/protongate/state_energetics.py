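"""Protonation-state × voltage energy bookkeeping.

Quantum cluster calculations of a voltage-sensor fragment yield one energy
per (protonation state, applied voltage) pair on a small voltage grid.
This module stores such tables (energies are *relative*, in kJ/mol — the
absolute totals are meaningless), selects the minimum-energy state at each
voltage, locates the voltage at which two states' energy curves cross by
piecewise-linear interpolation, and compares decomposition terms (e.g., the
exchange–correlation part) between states.

State labels are stored verbatim; :class:`ProtonationState` provides a
canonical structured form (residue → nominal charge tag in {-, 0, +}) with
a round-tripping text label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProtonationState",
    "StateEnergyTable",
    "CrossingPoint",
    "MissingVoltageError",
    "TiedStatesError",
    "InsufficientDataError",
    "MissingTermError",
    "min_energy_state",
    "crossing_point",
    "decomposition_delta",
]

CHARGE_TAGS = ("-", "0", "+")


class MissingVoltageError(KeyError):
    """No table rows at the requested voltage."""


class TiedStatesError(ValueError):
    """Two or more states share the minimal energy at a voltage."""


class InsufficientDataError(ValueError):
    """Fewer than two common voltages for a crossing search."""


class MissingTermError(KeyError):
    """A requested decomposition term is absent from a row."""


@dataclass(frozen=True)
class ProtonationState:
    """Nominal side-chain charge assignment, e.g. Y266:-, R300:+, E183:0."""

    residue_charges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        labels = [r for r, _ in self.residue_charges]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate residue labels: {labels}")
        for r, tag in self.residue_charges:
            if tag not in CHARGE_TAGS:
                raise ValueError(f"charge tag for {r} must be one of {CHARGE_TAGS}, got {tag!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ProtonationState":
        return cls(tuple(sorted(mapping.items())))

    @classmethod
    def from_label(cls, label: str) -> "ProtonationState":
        """Parse ``"Y266:-,R300:+,E183:0"`` (order-insensitive)."""
        pairs = {}
        for part in label.split(","):
            residue, _, tag = part.strip().rpartition(":")
            if not residue:
                raise ValueError(f"malformed state label component {part!r}")
            pairs[residue] = tag
        return cls.from_mapping(pairs)

    @property
    def label(self) -> str:
        return ",".join(f"{r}:{t}" for r, t in self.residue_charges)

    def charge_of(self, residue: str) -> str:
        for r, t in self.residue_charges:
            if r == residue:
                return t
        raise KeyError(residue)

    def as_dict(self) -> dict[str, str]:
        return dict(self.residue_charges)


@dataclass(frozen=True)
class CrossingPoint:
    """Voltage (mV) where two state curves cross, and the crossing height
    (kJ/mol) above the reference state's grid minimum."""

    voltage_mv: float
    height_kj_mol: float


class StateEnergyTable:
    """Rows of (state label, voltage mV, energy kJ/mol, optional xc kJ/mol).

    (state, voltage) pairs must be unique.  Backed by a DataFrame with
    columns ``state_label``, ``voltage_mV``, ``energy_kJ_mol`` and any
    optional decomposition columns (``xc_kJ_mol`` by convention).
    """

    REQUIRED = ("state_label", "voltage_mV", "energy_kJ_mol")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["voltage_mV"] = df["voltage_mV"].astype(float)
        df["energy_kJ_mol"] = df["energy_kJ_mol"].astype(float)
        dup = df.duplicated(subset=["state_label", "voltage_mV"])
        if dup.any():
            pairs = df.loc[dup, ["state_label", "voltage_mV"]].values.tolist()
            raise ValueError(f"duplicate (state, voltage) rows: {pairs}")
        self.df = df

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float, float] | tuple[str, float, float, float]]
    ) -> "StateEnergyTable":
        rows = []
        for rec in records:
            row = {"state_label": rec[0], "voltage_mV": rec[1], "energy_kJ_mol": rec[2]}
            if len(rec) > 3:
                row["xc_kJ_mol"] = rec[3]
            rows.append(row)
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StateEnergyTable":
        return cls(pd.read_csv(path, sep=None, engine="python"))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def states(self) -> list[str]:
        return list(dict.fromkeys(self.df["state_label"]))

    @property
    def voltages(self) -> np.ndarray:
        return np.sort(self.df["voltage_mV"].unique())

    def rows_at(self, voltage: float) -> pd.DataFrame:
        rows = self.df[np.isclose(self.df["voltage_mV"], voltage)]
        if rows.empty:
            raise MissingVoltageError(f"no rows at {voltage} mV")
        return rows

    def curve(self, state: str) -> tuple[np.ndarray, np.ndarray]:
        """(voltages, energies) for one state, sorted by voltage."""
        rows = self.df[self.df["state_label"] == state].sort_values("voltage_mV")
        if rows.empty:
            raise KeyError(f"state {state!r} not in table")
        return rows["voltage_mV"].to_numpy(), rows["energy_kJ_mol"].to_numpy()

    def term(self, state: str, voltage: float, column: str) -> float:
        rows = self.rows_at(voltage)
        rows = rows[rows["state_label"] == state]
        if rows.empty:
            raise KeyError(f"state {state!r} absent at {voltage} mV")
        if column not in rows.columns:
            raise MissingTermError(f"term {column!r} not in table")
        value = rows.iloc[0][column]
        if pd.isna(value):
            raise MissingTermError(f"term {column!r} missing for ({state}, {voltage} mV)")
        return float(value)


def min_energy_state(table: StateEnergyTable, voltage: float, atol: float = 1e-9) -> str:
    """Label of the minimum-energy state at ``voltage``.

    A tie within ``atol`` kJ/mol raises :class:`TiedStatesError` listing the
    tied states; a voltage with no rows raises :class:`MissingVoltageError`.
    Invariant under adding any constant to all energies at that voltage.
    """
    rows = table.rows_at(voltage)
    energies = rows["energy_kJ_mol"].to_numpy()
    lowest = energies.min()
    tied = rows.loc[np.abs(energies - lowest) <= atol, "state_label"].tolist()
    if len(tied) > 1:
        raise TiedStatesError(f"tied minimum at {voltage} mV: {tied}")
    return tied[0]


def crossing_point(
    table: StateEnergyTable,
    state_a: str,
    state_b: str,
    reference: str | None = None,
) -> CrossingPoint | None:
    """Voltage where E_A(V) − E_B(V) changes sign, and the crossing height.

    The curves are interpolated linearly between grid voltages.  The height
    is the interpolated energy at the crossing minus the grid minimum of the
    ``reference`` state's energy (default: whichever of A/B reaches the
    lower grid minimum, which makes the default symmetric in A and B).

    Returns None when the difference never changes sign on the common grid
    (a valid no-crossing outcome); raises :class:`InsufficientDataError`
    with fewer than two common voltages.
    """
    va, ea = table.curve(state_a)
    vb, eb = table.curve(state_b)
    common = np.intersect1d(va, vb)
    if len(common) < 2:
        raise InsufficientDataError(
            f"states share only {len(common)} voltage(s); need >= 2"
        )
    ea_c = np.interp(common, va, ea)
    eb_c = np.interp(common, vb, eb)
    d = ea_c - eb_c
    v_star = None
    for i in range(len(common) - 1):
        d0, d1 = d[i], d[i + 1]
        if d0 == 0.0:
            v_star = float(common[i])
            break
        if d0 * d1 < 0:
            v_star = float(common[i] - d0 * (common[i + 1] - common[i]) / (d1 - d0))
            break
    else:
        if d[-1] == 0.0:
            v_star = float(common[-1])
    if v_star is None:
        return None
    e_star = float(np.interp(v_star, common, ea_c))
    if reference is None:
        ref_min = min(ea_c.min(), eb_c.min())
    else:
        _, er = table.curve(reference)
        ref_min = float(er.min())
    return CrossingPoint(voltage_mv=v_star, height_kj_mol=e_star - ref_min)


def decomposition_delta(
    table: StateEnergyTable,
    state_a: str,
    state_b: str,
    voltage: float,
    term: str = "xc_kJ_mol",
) -> float:
    """Difference term(A) − term(B) at one voltage, kJ/mol.

    ``term`` names a decomposition column (default the exchange–correlation
    energy).  Raises :class:`MissingTermError` if either row lacks it.
    """
    return table.term(state_a, voltage, term) - table.term(state_b, voltage, term)
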