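"""Hydrogen-bond site graphs, Y-R-E / R-E-R triads, and proton paths.

A proton wire is a chain of hydrogen-bond donors and acceptors (side-chain
heteroatoms and water oxygens) along which a proton can hop.  The analysis
here is purely geometric/topological: sites are typed from a residue/atom
table (donor, acceptor, or both — protonation-dependent for the ionizable
side chains), edges are candidate hydrogen bonds between donor-capable and
acceptor-capable sites of different residues within a heavy-atom distance
cutoff, and candidate proton paths are residue-collapsed simple paths.

The arginine side chain is treated as amphoteric: the guanidinium NH1/NH2
nitrogens can always donate, while NE accepts when the side chain is
neutral (and donates when protonated/positive).  This is the property that
lets an arginine relay a proton even though its solution pKa suggests it is
always charged.  Water oxygens are ordinary both-role nodes, so a
water-mediated contact counts as one hop per water molecule.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from protongate.state_energetics import ProtonationState
from protongate.structure_io import Atom, ChargedStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ProtonSite",
    "Triad",
    "DEFAULT_CUTOFF",
    "DEFAULT_TRIAD_WINDOW",
    "assign_sites",
    "build_graph",
    "residue_graph",
    "find_triads",
    "enumerate_paths",
]

DEFAULT_CUTOFF = 3.5          # Å, heavy-atom H-bond distance
DEFAULT_TRIAD_WINDOW = 6.0    # Å, pairwise functional-group window

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# default nominal side-chain charges in solution; overridable per residue
DEFAULT_TAGS = {"ARG": "+", "LYS": "+", "GLU": "-", "ASP": "-", "TYR": "0", "HIS": "0"}

# functional-group atoms per residue type, used for triad distances
FUNCTIONAL_ATOMS = {
    "TYR": ("OH",),
    "ARG": ("NE", "NH1", "NH2"),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
}


@dataclass(frozen=True)
class ProtonSite:
    """One hydrogen-bond donor/acceptor site (a heavy atom)."""

    residue: str          # compact label, e.g. "Y266", "R300", "W901" for water
    residue_name: str     # 3-letter code
    atom_name: str        # e.g. OH, NE, NH1, OE2, SG, O (water)
    role: str             # "donor" | "acceptor" | "both"
    position: tuple[float, float, float]

    @property
    def key(self) -> tuple[str, str]:
        return (self.residue, self.atom_name)

    @property
    def can_donate(self) -> bool:
        return self.role in ("donor", "both")

    @property
    def can_accept(self) -> bool:
        return self.role in ("acceptor", "both")

    @property
    def is_water(self) -> bool:
        return self.residue_name in ("HOH", "WAT")


@dataclass(frozen=True)
class Triad:
    """A Y-R-E(or D) or R-E(or D)-R spatial motif with its distances."""

    pattern: str                       # "YRE", "YRD", "RER", "RDR"
    residues: tuple[str, str, str]     # labels in pattern order
    distances: tuple[float, float, float]  # pairwise, Å: (0-1, 1-2, 0-2)


def residue_label(residue_name: str, residue_number: int) -> str:
    if residue_name in ("HOH", "WAT"):
        return f"W{residue_number}"
    one = THREE_TO_ONE.get(residue_name, residue_name)
    return f"{one}{residue_number}"


def _site_roles(resname: str, tag: str) -> dict[str, str]:
    """Atom-name → role for one residue given its nominal charge tag."""
    if resname == "TYR":
        return {"OH": "acceptor" if tag == "-" else "both"}
    if resname == "ARG":
        roles = {"NH1": "donor", "NH2": "donor"}
        roles["NE"] = "acceptor" if tag == "0" else "donor"
        return roles
    if resname in ("GLU", "ASP"):
        o1, o2 = ("OE1", "OE2") if resname == "GLU" else ("OD1", "OD2")
        if tag == "0":
            # protonated carboxyl: one oxygen carries the proton (donor+acceptor)
            return {o1: "both", o2: "acceptor"}
        return {o1: "acceptor", o2: "acceptor"}
    if resname == "HIS":
        return {"ND1": "both", "NE2": "both"}
    if resname == "SER":
        return {"OG": "both"}
    if resname == "THR":
        return {"OG1": "both"}
    if resname == "CYS":
        return {"SG": "both"}
    if resname in ("HOH", "WAT"):
        return {"O": "both"}
    return {}


def assign_sites(
    s: ChargedStructure,
    protonation: ProtonationState | None = None,
) -> list[ProtonSite]:
    """Type every donor/acceptor-capable heavy atom in the structure.

    ``protonation`` overrides the default nominal charges (Arg +, Lys +,
    Glu/Asp −, Tyr 0, His 0) per residue label, switching the
    protonation-dependent roles (e.g. a neutral arginine's NE becomes an
    acceptor — the amphoteric rule).  Residues with no typed polar atoms are
    skipped; an unrecognized residue logs a warning rather than failing.
    """
    overrides = protonation.as_dict() if protonation is not None else {}
    sites: list[ProtonSite] = []
    warned: set[str] = set()
    for atom in s.atoms:
        resname = atom.residue_name
        label = residue_label(resname, atom.residue_number)
        tag = overrides.get(label, DEFAULT_TAGS.get(resname, "0"))
        roles = _site_roles(resname, tag)
        if not roles:
            if resname not in THREE_TO_ONE and resname not in ("HOH", "WAT") and resname not in warned:
                logger.warning("unknown residue %s: skipped for site typing", resname)
                warned.add(resname)
            continue
        role = roles.get(atom.name)
        if role is not None:
            sites.append(
                ProtonSite(
                    residue=label,
                    residue_name=resname,
                    atom_name=atom.name,
                    role=role,
                    position=atom.position,
                )
            )
    return sites


def build_graph(sites: list[ProtonSite], cutoff: float = DEFAULT_CUTOFF) -> nx.Graph:
    """Candidate hydrogen-bond graph over sites.

    Nodes are (residue, atom_name) keys carrying the site object; an
    undirected edge joins two sites of *different* residues when one can
    donate, the other can accept, and the heavy-atom distance is at most
    ``cutoff`` (Å).  Edges carry the distance.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    g = nx.Graph()
    for site in sites:
        g.add_node(site.key, site=site)
    pos = np.array([s.position for s in sites]) if sites else np.empty((0, 3))
    for i, j in itertools.combinations(range(len(sites)), 2):
        a, b = sites[i], sites[j]
        if a.residue == b.residue:
            continue
        if not ((a.can_donate and b.can_accept) or (b.can_donate and a.can_accept)):
            continue
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d <= cutoff:
            g.add_edge(a.key, b.key, distance=d)
    return g


def residue_graph(graph: nx.Graph) -> nx.Graph:
    """Collapse a site graph to residue level (edge iff any site pair edge)."""
    rg = nx.Graph()
    for node in graph.nodes:
        rg.add_node(node[0])
    for a, b in graph.edges:
        if a[0] != b[0]:
            rg.add_edge(a[0], b[0])
    return rg


def _functional_positions(sites: list[ProtonSite]) -> dict[str, list[np.ndarray]]:
    """Residue label → functional-group atom positions (typed residues only)."""
    out: dict[str, list[np.ndarray]] = {}
    names: dict[str, str] = {}
    for s in sites:
        fg = FUNCTIONAL_ATOMS.get(s.residue_name)
        if fg and s.atom_name in fg:
            out.setdefault(s.residue, []).append(np.asarray(s.position))
            names[s.residue] = s.residue_name
    return out, names


def find_triads(
    sites: list[ProtonSite], window: float = DEFAULT_TRIAD_WINDOW
) -> list[Triad]:
    """All Y-R-E/D and R-E/D-R triads with pairwise functional-group
    distances ≤ ``window`` (Å).

    The distance between two residues is the minimum over their
    functional-group atom pairs (hydroxyl O for Tyr, guanidinium N for Arg,
    carboxylate O for Glu/Asp).  The default 6 Å window admits the ~5 Å
    arginine-N-to-carboxylate-O separations seen in voltage-sensor and
    bacteriorhodopsin proton-wire triads.  Empty output is a valid result.
    Monotone in ``window``: enlarging it never removes a triad.
    """
    positions, resnames = _functional_positions(sites)

    def pair_distance(r1: str, r2: str) -> float:
        return min(
            float(np.linalg.norm(p1 - p2))
            for p1 in positions[r1]
            for p2 in positions[r2]
        )

    tyrs = sorted(r for r, n in resnames.items() if n == "TYR")
    args = sorted(r for r, n in resnames.items() if n == "ARG")
    acids = sorted(r for r, n in resnames.items() if n in ("GLU", "ASP"))

    triads: list[Triad] = []
    for y in tyrs:
        for r in args:
            for e in acids:
                d_yr = pair_distance(y, r)
                d_re = pair_distance(r, e)
                d_ye = pair_distance(y, e)
                if max(d_yr, d_re, d_ye) <= window:
                    pattern = "YRE" if resnames[e] == "GLU" else "YRD"
                    triads.append(Triad(pattern, (y, r, e), (d_yr, d_re, d_ye)))
    for r1, r2 in itertools.combinations(args, 2):
        for e in acids:
            d_1e = pair_distance(r1, e)
            d_e2 = pair_distance(e, r2)
            d_12 = pair_distance(r1, r2)
            if max(d_1e, d_e2, d_12) <= window:
                pattern = "RER" if resnames[e] == "GLU" else "RDR"
                triads.append(Triad(pattern, (r1, e, r2), (d_1e, d_e2, d_12)))
    return triads


def enumerate_paths(
    graph: nx.Graph,
    source_residue: str,
    target_residue: str,
    max_hops: int = 6,
) -> list[tuple[str, ...]]:
    """All residue-level simple paths source → target within ``max_hops``.

    The site graph is collapsed to residues (all sites of one residue merge
    into one path node); paths revisit no residue, have at most
    ``max_hops`` edges, and are returned in lexicographic order of their
    residue sequence.  Missing endpoints raise LookupError.
    """
    rg = residue_graph(graph)
    for endpoint in (source_residue, target_residue):
        if endpoint not in rg:
            raise LookupError(f"residue {endpoint!r} has no sites in the graph")
    paths = [
        tuple(p)
        for p in nx.all_simple_paths(rg, source_residue, target_residue, cutoff=max_hops)
    ]
    return sorted(paths)
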