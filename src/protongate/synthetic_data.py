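"""Synthetic fixtures with planted, exactly recoverable truths.

Quantum-chemistry outputs (per-atom partial charges of a ~10³-atom
voltage-sensor cluster, 29-state energy tables) are not reproducible at
desk scale, so every pipeline input is emulated here with its ground truth
recorded in a manifest:

* a charged cluster (default 976 atoms: 904 protein + 24 × 3-atom waters)
  with signed partial charges summing exactly to a fixed net charge
  (default +2 e), a planted charge-weighted z centroid, and a planted
  proton-wire motif — five side-chain proxies (Tyr266, Arg300, Glu183,
  Arg303, Glu226 in minimal functional-group form) laid out so the
  hydrogen-bond graph contains exactly two residue paths R303 → E183,
  one through the tyrosine and one through the second glutamate;
* protonation-state × voltage energy tables whose two designated states
  are straight lines crossing exactly at a planted (voltage, height);
* Boltzmann gating curves and power-law conductance data with known
  parameters plus seeded noise.

A single integer seed governs each generator and identical seeds give
byte-identical files.  Motif proxies use real residue/atom names so the
site-typing rules of :mod:`protongate.proton_path` apply unchanged.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from protongate.gating_curves import (
    ConductanceDataset,
    GatingDataset,
    boltzmann_po,
)
from protongate.state_energetics import StateEnergyTable
from protongate.structure_io import Atom, ChargedStructure, MembraneFrame
from protongate.proton_path import DEFAULT_CUTOFF, DEFAULT_TRIAD_WINDOW

__all__ = [
    "FixtureManifest",
    "CLOSED_STATE_LABEL",
    "OPEN_STATE_LABEL",
    "DEFAULT_VOLTAGE_GRID",
    "gen_structure",
    "gen_structure_pair",
    "gen_energy_table",
    "gen_gating_dataset",
    "gen_conductance_dataset",
]

# nominal-charge labels of the two competing states: all-neutral (closed,
# favored under hyperpolarization) vs tyrosinate/argininium (open, 0 mV)
CLOSED_STATE_LABEL = "E183:0,R300:0,Y266:0"
OPEN_STATE_LABEL = "E183:0,R300:+,Y266:-"

DEFAULT_VOLTAGE_GRID = (-70.0, -35.0, 0.0, 35.0, 70.0)

# minimal side-chain proxies: (residue_name, residue_number, atom_name, element, x, y, z)
# Functional-group centers sit on a 2.8 Å hydrogen-bond lattice in the z=20 plane;
# extra atoms of the same residue are offset along z only, so the minimum
# inter-residue functional distance equals the in-plane spacing exactly.
_MOTIF_ATOMS: tuple[tuple[str, int, str, str, float, float, float], ...] = (
    ("TYR", 266, "OH", "O", -2.8, 0.0, 20.0),
    ("ARG", 300, "NE", "N", 0.0, 0.0, 20.0),
    ("ARG", 300, "NH1", "N", 0.0, 0.0, 20.4),
    ("ARG", 300, "NH2", "N", 0.0, 0.0, 19.6),
    ("GLU", 183, "OE1", "O", 2.8, 0.0, 20.0),
    ("GLU", 183, "OE2", "O", 2.8, 0.0, 20.4),
    ("ARG", 303, "NE", "N", -2.8, 2.8, 20.0),
    ("ARG", 303, "NH1", "N", -2.8, 2.8, 20.4),
    ("ARG", 303, "NH2", "N", -2.8, 2.8, 19.6),
    ("GLU", 226, "OE1", "O", 0.0, 2.8, 20.0),
    ("GLU", 226, "OE2", "O", 0.0, 2.8, 20.4),
)

_MOTIF_FUNCTIONAL_CENTERS = {
    "Y266": ("TYR", np.array([-2.8, 0.0, 20.0])),
    "R300": ("ARG", np.array([0.0, 0.0, 20.0])),
    "E183": ("GLU", np.array([2.8, 0.0, 20.0])),
    "R303": ("ARG", np.array([-2.8, 2.8, 20.0])),
    "E226": ("GLU", np.array([0.0, 2.8, 20.0])),
}


@dataclass
class FixtureManifest:
    """Planted ground truth for one generated fixture."""

    seed: int
    kind: str
    truths: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "kind": self.kind, "truths": self.truths}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        payload = json.loads(Path(path).read_text())
        return cls(seed=payload["seed"], kind=payload["kind"], truths=payload["truths"])


def _planted_topology() -> dict:
    """Brute-force the motif's planted triads and residue paths.

    Independent of :mod:`protongate.proton_path`: a direct double loop over
    the designed functional-group centers with the default H-bond cutoff
    and triad window.  Donor/acceptor compatibility at default protonation
    (Arg +, Glu −, Tyr 0): Tyr↔anything, Arg→Glu, Arg→Tyr; Arg–Arg and
    Glu–Glu pairs are role-incompatible.
    """
    labels = list(_MOTIF_FUNCTIONAL_CENTERS)
    kind = {lab: _MOTIF_FUNCTIONAL_CENTERS[lab][0] for lab in labels}
    pos = {lab: _MOTIF_FUNCTIONAL_CENTERS[lab][1] for lab in labels}

    def dist(a: str, b: str) -> float:
        return float(np.linalg.norm(pos[a] - pos[b]))

    def compatible(a: str, b: str) -> bool:
        pair = {kind[a], kind[b]}
        return pair != {"ARG"} and pair != {"GLU"}

    edges = {
        frozenset((a, b))
        for a, b in itertools.combinations(labels, 2)
        if compatible(a, b) and dist(a, b) <= DEFAULT_CUTOFF
    }

    triads = []
    tyrs = [l for l in labels if kind[l] == "TYR"]
    args = [l for l in labels if kind[l] == "ARG"]
    glus = [l for l in labels if kind[l] == "GLU"]
    for y in tyrs:
        for r in args:
            for e in glus:
                if max(dist(y, r), dist(r, e), dist(y, e)) <= DEFAULT_TRIAD_WINDOW:
                    triads.append(["YRE", y, r, e])
    for r1, r2 in itertools.combinations(args, 2):
        for e in glus:
            if max(dist(r1, e), dist(e, r2), dist(r1, r2)) <= DEFAULT_TRIAD_WINDOW:
                triads.append(["RER", r1, e, r2])

    # exhaustive DFS for residue-level simple paths R303 -> E183
    adjacency: dict[str, list[str]] = {l: [] for l in labels}
    for e in edges:
        a, b = sorted(e)
        adjacency[a].append(b)
        adjacency[b].append(a)

    def dfs(node: str, target: str, seen: tuple[str, ...]) -> list[list[str]]:
        if node == target:
            return [list(seen)]
        out = []
        for nxt in sorted(adjacency[node]):
            if nxt not in seen:
                out.extend(dfs(nxt, target, seen + (nxt,)))
        return out

    paths = sorted(dfs("R303", "E183", ("R303",)))
    return {
        "edges": sorted(sorted(e) for e in edges),
        "triads": sorted(triads),
        "paths_R303_to_E183": paths,
    }


def gen_structure(
    n_atoms: int = 976,
    net_charge: float = 2.0,
    planted_coc: float = 8.3,
    seed: int = 0,
    n_waters: int = 24,
) -> tuple[ChargedStructure, dict[int, float], FixtureManifest]:
    """Generate a charged cluster with planted motif, net charge, and centroid.

    Returns (structure with charges attached, charge table keyed by serial,
    manifest).  ``n_atoms`` counts everything: 11 motif side-chain atoms,
    3 atoms per water, and carbon filler.  Charges are drawn randomly and
    then two filler (or trailing) atoms are adjusted so that Σq equals
    ``net_charge`` exactly and the charge-weighted z centroid equals
    ``planted_coc`` to within 1e-6 Å on the PDB-precision coordinates.
    """
    n_motif = len(_MOTIF_ATOMS)
    n_water_atoms = 3 * n_waters
    n_filler = n_atoms - n_motif - n_water_atoms
    if n_filler < 0:
        raise ValueError(
            f"n_atoms={n_atoms} cannot hold {n_motif} motif atoms "
            f"and {n_waters} waters ({n_water_atoms} atoms)"
        )
    rng = np.random.default_rng(seed)

    records: list[tuple[str, int, str, str, str, float, float, float]] = []
    for resname, resnum, name, element, x, y, z in _MOTIF_ATOMS:
        records.append((resname, resnum, name, element, "A", x, y, z))
    # carbon filler, one pseudo-ALA residue per atom, residue numbers from 400
    for i in range(n_filler):
        x, y = rng.uniform(-15.0, 15.0, size=2)
        z = rng.uniform(0.0, 32.9)
        records.append(("ALA", 400 + i, "CB", "C", "A", x, y, z))
    # extracellular water cleft: 3-atom waters on a grid far from the motif
    for w in range(n_waters):
        gx, gy = divmod(w, 6)
        ox = 10.0 + 3.0 * gx
        oy = 10.0 + 3.0 * gy
        oz = 29.0 + 0.5 * (w % 4)
        records.append(("HOH", 901 + w, "O", "O", "W", ox, oy, oz))
        records.append(("HOH", 901 + w, "H1", "H", "W", ox + 0.6, oy, oz + 0.6))
        records.append(("HOH", 901 + w, "H2", "H", "W", ox - 0.6, oy, oz + 0.6))

    # quantize to PDB precision before planting charge constraints
    z_arr = np.array([round(r[7], 3) for r in records])
    charges = rng.normal(0.0, 0.3, size=len(records))

    # adjust the last two atoms with distinct z to hit Sum(q) and Sum(q z)
    i2 = len(records) - 1
    i1 = next(i for i in range(i2 - 1, -1, -1) if abs(z_arr[i] - z_arr[i2]) > 1e-3)
    charges[[i1, i2]] = 0.0
    s0 = charges.sum()
    s1 = float(np.dot(charges, z_arr))
    a_mat = np.array([[1.0, 1.0], [z_arr[i1], z_arr[i2]]])
    rhs = np.array([net_charge - s0, net_charge * planted_coc - s1])
    charges[[i1, i2]] = np.linalg.solve(a_mat, rhs)

    atoms = []
    table: dict[int, float] = {}
    for serial, (rec, q) in enumerate(zip(records, charges), start=1):
        resname, resnum, name, element, chain, x, y, z = rec
        atoms.append(
            Atom(
                atom_id=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_number=resnum,
                chain_id=chain,
                position=(round(x, 3), round(y, 3), round(z, 3)),
                partial_charge=float(q),
            )
        )
        table[serial] = float(q)

    structure = ChargedStructure(atoms=tuple(atoms), frame=MembraneFrame(origin_z=0.0))

    region_counts = {
        "chain:A": sum(1 for a in atoms if a.chain_id == "A"),
        "resi:290-310": sum(1 for a in atoms if 290 <= a.residue_number <= 310),
    }
    manifest = FixtureManifest(
        seed=seed,
        kind="structure",
        truths={
            "n_atoms": len(atoms),
            "n_waters": n_waters,
            "net_charge": net_charge,
            "atomwise_center_of_charge": planted_coc,
            "region_atom_counts": region_counts,
            **_planted_topology(),
        },
    )
    return structure, table, manifest


def gen_structure_pair(
    delta: float = 11.3,
    seed: int = 0,
    **kwargs,
) -> tuple[ChargedStructure, ChargedStructure, FixtureManifest]:
    """Two states related by a rigid charge translation of ``delta`` Å along z.

    State A is a generated cluster; state B is the same cluster translated
    by −delta (charges unchanged), so the center of charge of A sits
    ``delta`` Å further extracellular than B's — exactly, by translation
    equivariance.  Each state's own minimum-z-anchored slab partition
    yields slabwise centers differing by exactly ``delta`` as well.
    """
    state_a, _, manifest = gen_structure(seed=seed, **kwargs)
    moved = tuple(
        Atom(
            atom_id=a.atom_id,
            name=a.name,
            element=a.element,
            residue_name=a.residue_name,
            residue_number=a.residue_number,
            chain_id=a.chain_id,
            position=(a.position[0], a.position[1], round(a.position[2] - delta, 3)),
            partial_charge=a.partial_charge,
        )
        for a in state_a.atoms
    )
    state_b = ChargedStructure(atoms=moved, frame=state_a.frame)
    manifest.kind = "structure_pair"
    manifest.truths["displacement"] = delta
    return state_a, state_b, manifest


def gen_energy_table(
    crossing: tuple[float, float] = (-20.0, 60.0),
    voltage_grid: tuple[float, ...] = DEFAULT_VOLTAGE_GRID,
    n_extra_states: int = 3,
    seed: int = 0,
    xc_pair: tuple[float, float] = (96.0, 25.2),
) -> tuple[StateEnergyTable, FixtureManifest]:
    """Energy table whose closed/open curves cross exactly at ``crossing``.

    The closed (all-neutral) state is a line rising from 0 at the grid
    minimum voltage; the open state is a line through the crossing with a
    random negative slope.  Piecewise-linear interpolation of grid values
    then recovers the crossing voltage and its height above the closed
    minimum exactly.  ``n_extra_states`` decoys are kept strictly above
    both at every grid voltage.  ``xc_pair`` plants exchange–correlation
    decomposition values for (closed, open) at 0 mV.
    """
    v_star, height = crossing
    grid = np.asarray(sorted(voltage_grid), dtype=float)
    if not (grid[0] < v_star < grid[-1]):
        raise ValueError(f"crossing voltage {v_star} outside grid span {grid[0]}..{grid[-1]}")
    if height <= 0:
        raise ValueError(f"crossing height must be > 0, got {height}")
    rng = np.random.default_rng(seed)

    slope_closed = height / (v_star - grid[0])
    # open-state slope kept shallow enough that the open line stays above the
    # closed minimum (0) across the grid, so the closed state is the global
    # reference minimum by construction
    slope_open = -float(rng.uniform(0.2, 0.95)) * height / (grid[-1] - v_star)
    e_closed = slope_closed * (grid - grid[0])
    e_open = height + slope_open * (grid - v_star)

    records: list[tuple[str, float, float, float]] = []
    xc_closed, xc_open = xc_pair
    for v, ec, eo in zip(grid, e_closed, e_open):
        records.append((CLOSED_STATE_LABEL, float(v), float(ec),
                        xc_closed if v == 0.0 else float(rng.uniform(0.0, 120.0))))
        records.append((OPEN_STATE_LABEL, float(v), float(eo),
                        xc_open if v == 0.0 else float(rng.uniform(0.0, 120.0))))
    for k in range(n_extra_states):
        label = f"decoy{k}:+"
        offset = float(rng.uniform(5.0, 30.0))
        for v, ec, eo in zip(grid, e_closed, e_open):
            e = max(ec, eo) + offset + float(rng.uniform(0.0, 5.0))
            records.append((label, float(v), e, float(rng.uniform(0.0, 120.0))))

    table = StateEnergyTable.from_records(records)
    manifest = FixtureManifest(
        seed=seed,
        kind="energy_table",
        truths={
            "closed_state": CLOSED_STATE_LABEL,
            "open_state": OPEN_STATE_LABEL,
            "crossing_voltage_mV": v_star,
            "crossing_height_kJ_mol": height,
            "min_state_at_grid_min": CLOSED_STATE_LABEL,
            "xc_closed_kJ_mol": xc_closed,
            "xc_open_kJ_mol": xc_open,
            "xc_delta_kJ_mol": xc_closed - xc_open,
        },
    )
    return table, manifest


def gen_gating_dataset(
    q: float = 13.0,
    v_half: float = 0.0,
    noise_sd: float = 0.02,
    n_voltages: int = 41,
    t: float = 300.0,
    seed: int = 0,
) -> tuple[GatingDataset, FixtureManifest]:
    """Noisy Boltzmann gating curve with known (q, V½).

    Voltages span ±10 kBT of energy drive around the midpoint, so the curve
    runs from fully closed to fully open.  Gaussian noise of ``noise_sd``
    is added and the probabilities clipped back to [0, 1].
    """
    if n_voltages < 3:
        raise ValueError(f"need >= 3 voltages, got {n_voltages}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    from protongate.thermal_kinetics import CONSTANTS

    vkbt_mv = CONSTANTS.k_B * t / CONSTANTS.e * 1e3
    half_span = 10.0 * vkbt_mv / abs(q)
    v = np.linspace(v_half - half_span, v_half + half_span, n_voltages)
    p = boltzmann_po(v, q, v_half, t)
    if noise_sd > 0:
        p = np.clip(p + rng.normal(0.0, noise_sd, size=p.shape), 0.0, 1.0)
    data = GatingDataset(tuple(float(x) for x in v), tuple(float(x) for x in p), t)
    manifest = FixtureManifest(
        seed=seed,
        kind="gating",
        truths={"q": q, "v_half": v_half, "noise_sd": noise_sd, "temperature": t},
    )
    return data, manifest


def gen_conductance_dataset(
    slope: float = 1.0,
    n_points: int = 10,
    noise: float = 0.05,
    seed: int = 0,
    t: float = 300.0,
    c_range_mm: tuple[float, float] = (1.0, 1000.0),
) -> tuple[ConductanceDataset, FixtureManifest]:
    """Power-law conductance–concentration data with multiplicative noise.

    ln(conductance) = slope · ln(c/c_ref) + ε, ε ~ N(0, noise); the
    reference concentration is the lowest point.
    """
    if n_points < 3:
        raise ValueError(f"need >= 3 points, got {n_points}")
    rng = np.random.default_rng(seed)
    c = np.geomspace(c_range_mm[0], c_range_mm[1], n_points)
    ref = float(c.min())
    g = (c / ref) ** slope
    if noise > 0:
        g = g * np.exp(rng.normal(0.0, noise, size=g.shape))
    data = ConductanceDataset(
        tuple(float(x) for x in c), tuple(float(x) for x in g), t, ref
    )
    manifest = FixtureManifest(
        seed=seed,
        kind="conductance",
        truths={"slope": slope, "noise": noise, "reference_concentration_mm": ref},
    )
    return data, manifest
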