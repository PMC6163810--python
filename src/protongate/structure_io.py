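"""Structure and charge-table I/O in a membrane coordinate frame.

Structures are read from PDB files into a flat, ordered list of atoms with
coordinates in a membrane frame: z is the membrane normal, increasing toward
the extracellular side; the frame origin defaults to the minimum z of the
selection, so slab indices downstream are reproducible without any external
membrane annotation.

Partial charges (e.g., exported from a natural-bond-orbital analysis) are
attached from a two-column table keyed by PDB atom serial.  The net charge of
a structure is always the arithmetic sum of its per-atom charges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "MembraneFrame",
    "ChargedStructure",
    "StructureError",
    "EmptyStructureError",
    "ChargeMappingError",
    "DuplicateChargeError",
    "EmptySelectionError",
    "read_structure",
    "write_structure",
    "read_charge_table",
    "attach_charges",
    "select_region",
    "parse_selection",
]


class StructureError(Exception):
    """Base class for structure-handling errors."""


class EmptyStructureError(StructureError):
    """A file parsed but contained no ATOM/HETATM records."""


class ChargeMappingError(StructureError, KeyError):
    """An atom id has no entry in the charge table."""


class DuplicateChargeError(StructureError):
    """An atom id appears more than once in the charge table."""


class EmptySelectionError(StructureError):
    """A region selection matched no atoms."""


@dataclass(frozen=True)
class Atom:
    """One atom: identity, location, and (optionally) a partial charge.

    ``atom_id`` is the PDB serial and is the key used to attach charges.
    ``position`` is in Å, in the membrane frame (z = membrane normal,
    extracellular positive).  ``partial_charge`` is in elementary-charge
    units and is None until :func:`attach_charges` has run.
    """

    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: tuple[float, float, float]
    partial_charge: float | None = None

    @property
    def z(self) -> float:
        return self.position[2]

    @property
    def is_water(self) -> bool:
        return self.residue_name in ("HOH", "WAT")


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane coordinate frame: z normal, origin at the intracellular edge.

    ``origin_z`` records the z offset applied so downstream slab partitions
    can be reconstructed; coordinates stored on atoms are already in this
    frame (the frame is metadata, not a pending transform).
    """

    origin_z: float = 0.0
    note: str = "z = membrane normal, increasing extracellular"


@dataclass(frozen=True)
class ChargedStructure:
    """An ordered collection of atoms plus the membrane-frame metadata."""

    atoms: tuple[Atom, ...]
    frame: MembraneFrame = field(default_factory=MembraneFrame)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise EmptyStructureError("structure contains no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def has_charges(self) -> bool:
        return all(a.partial_charge is not None for a in self.atoms)

    @property
    def net_charge(self) -> float:
        """Sum of partial charges, e.  Requires charges attached."""
        if not self.has_charges:
            raise StructureError("charges not attached; call attach_charges first")
        return float(sum(a.partial_charge for a in self.atoms))

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        if not self.has_charges:
            raise StructureError("charges not attached; call attach_charges first")
        return np.array([a.partial_charge for a in self.atoms], dtype=float)


def read_structure(path: str | Path) -> ChargedStructure:
    """Read a PDB file into a :class:`ChargedStructure` (charges unattached).

    All ATOM and HETATM records are kept, including waters and hydrogens.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first encountered).  Raises :class:`EmptyStructureError` on a
    file with no atoms, and lets I/O / parse errors propagate.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for residue in chain:
                # altlocs: keep the highest-occupancy conformer per atom name,
                # ties resolved to the first encountered (file order)
                best: dict[str, gemmi.Atom] = {}
                order: list[str] = []
                for a in residue:
                    if a.name not in best:
                        best[a.name] = a
                        order.append(a.name)
                    elif a.occ > best[a.name].occ:
                        best[a.name] = a
                for name in order:
                    a = best[name]
                    atoms.append(
                        Atom(
                            atom_id=a.serial,
                            name=a.name,
                            element=a.element.name,
                            residue_name=residue.name,
                            residue_number=residue.seqid.num,
                            chain_id=chain.name,
                            position=(a.pos.x, a.pos.y, a.pos.z),
                        )
                    )
        break  # first model only
    if not atoms:
        raise EmptyStructureError(f"no ATOM/HETATM records in {path}")
    logger.info("read %d atoms from %s", len(atoms), path)
    return ChargedStructure(atoms=tuple(atoms))


def write_structure(s: ChargedStructure, path: str | Path) -> None:
    """Write the structure back out as PDB (coordinates at PDB precision)."""
    import itertools

    st = gemmi.Structure()
    st.name = "protongate"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    # gemmi's add_* copy their argument, so each residue is completed first
    for (cid, num, rname), group in itertools.groupby(
        s.atoms, key=lambda a: (a.chain_id, a.residue_number, a.residue_name)
    ):
        residue = gemmi.Residue()
        residue.name = rname
        residue.seqid = gemmi.SeqId(num, " ")
        for a in group:
            residue.het_flag = "H" if a.is_water else "A"
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.serial = a.atom_id
            ga.pos = gemmi.Position(*a.position)
            ga.occ = 1.0
            residue.add_atom(ga)
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        chains[cid].add_residue(residue)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.preserve_serial = True  # serials key the charge table
    opts.ter_records = False
    Path(path).write_text(st.make_pdb_string(opts))


def read_charge_table(path: str | Path) -> dict[int, float]:
    """Read a two-column delimited charge table (atom serial, charge in e).

    Accepts comma, tab, or whitespace separation; a header line is allowed.
    Duplicate serials raise :class:`DuplicateChargeError`.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     names=["serial", "charge"])
    # tolerate a header row
    if not np.issubdtype(df["serial"].dtype, np.number):
        df = df.iloc[1:].astype({"serial": int, "charge": float})
    serials = df["serial"].astype(int)
    if serials.duplicated().any():
        dupes = sorted(serials[serials.duplicated()].unique().tolist())
        raise DuplicateChargeError(f"duplicate atom ids in charge table: {dupes}")
    return dict(zip(serials.tolist(), df["charge"].astype(float).tolist()))


def attach_charges(
    s: ChargedStructure, table: Mapping[int, float] | str | Path
) -> ChargedStructure:
    """Return a copy of ``s`` with per-atom partial charges attached.

    Every atom id must appear in the table exactly once; a missing id raises
    :class:`ChargeMappingError` naming the id.  The net charge is implied by
    the attached values (``ChargedStructure.net_charge`` recomputes the sum).
    """
    if not isinstance(table, Mapping):
        table = read_charge_table(table)
    missing = [a.atom_id for a in s.atoms if a.atom_id not in table]
    if missing:
        raise ChargeMappingError(
            f"no charge for atom id(s) {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    seen: set[int] = set()
    for a in s.atoms:
        if a.atom_id in seen:
            raise DuplicateChargeError(f"ambiguous atom id {a.atom_id} in structure")
        seen.add(a.atom_id)
    atoms = tuple(replace(a, partial_charge=float(table[a.atom_id])) for a in s.atoms)
    out = ChargedStructure(atoms=atoms, frame=s.frame)
    logger.info("attached charges; net charge = %+.6f e", out.net_charge)
    return out


def parse_selection(spec: str) -> Callable[[Atom], bool]:
    """Parse a selection string like ``"chain:A,resi:290-310"`` to a predicate.

    Supported keys: ``chain:<id>`` and ``resi:<n>`` or ``resi:<a>-<b>``
    (inclusive).  Multiple clauses are ANDed.
    """
    clauses: list[Callable[[Atom], bool]] = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(":")
        key = key.strip().lower()
        value = value.strip()
        if key == "chain":
            clauses.append(lambda a, v=value: a.chain_id == v)
        elif key == "resi":
            if "-" in value:
                lo_s, hi_s = value.split("-")
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(value)
            clauses.append(lambda a, lo=lo, hi=hi: lo <= a.residue_number <= hi)
        else:
            raise ValueError(f"unknown selection key {key!r}")
    if not clauses:
        raise ValueError(f"empty selection spec {spec!r}")
    return lambda a: all(c(a) for c in clauses)


def select_region(
    s: ChargedStructure,
    predicate: Callable[[Atom], bool] | str,
) -> ChargedStructure:
    """Return the sub-structure of atoms matching ``predicate``.

    ``predicate`` may be a callable Atom -> bool or a selection string
    understood by :func:`parse_selection`.  Atom order and frame metadata are
    preserved.  Raises :class:`EmptySelectionError` if nothing matches.
    """
    if isinstance(predicate, str):
        predicate = parse_selection(predicate)
    atoms = tuple(a for a in s.atoms if predicate(a))
    if not atoms:
        raise EmptySelectionError("selection matched no atoms")
    return ChargedStructure(atoms=atoms, frame=s.frame)
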