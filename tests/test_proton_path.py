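import itertools

import networkx as nx
import numpy as np
import pytest

from protongate.proton_path import (
    ProtonSite,
    assign_sites,
    build_graph,
    enumerate_paths,
    find_triads,
    residue_graph,
)
from protongate.state_energetics import ProtonationState

from conftest import make_structure


def site(residue, resname, atom, role, pos):
    return ProtonSite(residue, resname, atom, role, tuple(float(x) for x in pos))


def triad_structure(y_pos, r_pos, e_pos):
    """Minimal Tyr/Arg/Glu structure with functional atoms at given points."""
    return make_structure(
        [
            (1, "OH", "O", "TYR", 266, "A", *y_pos),
            (2, "NE", "N", "ARG", 300, "A", *r_pos),
            (3, "OE1", "O", "GLU", 183, "A", *e_pos),
        ]
    )


class TestAssignSites:
    def test_typing_table_for_tyr_arg_glu(self):
        s = triad_structure((0, 0, 0), (5, 0, 0), (10, 0, 0))
        roles = {(x.residue, x.atom_name): x.role for x in assign_sites(s)}
        assert roles == {
            ("Y266", "OH"): "both",
            ("R300", "NE"): "donor",      # Arg defaults to +: NE protonated
            ("E183", "OE1"): "acceptor",  # Glu defaults to -
        }

    def test_neutral_arginine_ne_becomes_acceptor(self):
        s = make_structure([(1, "NE", "N", "ARG", 300, "A", 0, 0, 0)])
        state = ProtonationState.from_label("R300:0")
        (ne,) = assign_sites(s, protonation=state)
        assert ne.role == "acceptor"

    def test_guanidinium_amines_always_donate(self):
        s = make_structure(
            [
                (1, "NH1", "N", "ARG", 300, "A", 0, 0, 0),
                (2, "NH2", "N", "ARG", 300, "A", 1, 0, 0),
            ]
        )
        for state in (None, ProtonationState.from_label("R300:0")):
            assert all(x.role == "donor" for x in assign_sites(s, protonation=state))

    def test_neutral_glutamate_gains_a_donor_oxygen(self):
        s = make_structure(
            [
                (1, "OE1", "O", "GLU", 183, "A", 0, 0, 0),
                (2, "OE2", "O", "GLU", 183, "A", 1, 0, 0),
            ]
        )
        roles = {x.atom_name: x.role for x in assign_sites(s, ProtonationState.from_label("E183:0"))}
        assert roles == {"OE1": "both", "OE2": "acceptor"}

    def test_apolar_structure_has_no_sites(self):
        s = make_structure(
            [
                (1, "CB", "C", "ALA", 1, "A", 0, 0, 0),
                (2, "CD1", "C", "LEU", 2, "A", 1, 0, 0),
                (3, "CG1", "C", "ILE", 3, "A", 2, 0, 0),
            ]
        )
        assert assign_sites(s) == []

    def test_unknown_residue_skipped_with_warning(self, caplog):
        s = make_structure([(1, "X1", "X", "LIG", 1, "A", 0, 0, 0)])
        with caplog.at_level("WARNING"):
            assert assign_sites(s) == []
        assert "LIG" in caplog.text


class TestBuildGraph:
    def test_donor_acceptor_pair_within_cutoff(self):
        sites = [
            site("R300", "ARG", "NH1", "donor", (0, 0, 0)),
            site("E183", "GLU", "OE1", "acceptor", (2.8, 0, 0)),
        ]
        g = build_graph(sites)
        assert g.number_of_edges() == 1
        assert g.edges[("R300", "NH1"), ("E183", "OE1")]["distance"] == pytest.approx(2.8)

    def test_two_donors_make_no_edge(self):
        sites = [
            site("R300", "ARG", "NH1", "donor", (0, 0, 0)),
            site("R303", "ARG", "NH1", "donor", (2.8, 0, 0)),
        ]
        assert build_graph(sites).number_of_edges() == 0

    def test_same_residue_sites_never_bond(self):
        sites = [
            site("S1", "SER", "OG", "both", (0, 0, 0)),
            site("S1", "SER", "OG1", "both", (1.0, 0, 0)),
        ]
        assert build_graph(sites).number_of_edges() == 0

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            build_graph([], cutoff=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_cloud_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        roles = ["donor", "acceptor", "both"]
        sites = [
            site(f"R{i}", "SER", "OG", roles[int(rng.integers(3))], rng.uniform(0, 8, 3))
            for i in range(30)
        ]
        g = build_graph(sites, cutoff=3.5)
        expected = set()
        for a, b in itertools.combinations(sites, 2):
            ok_roles = (a.can_donate and b.can_accept) or (b.can_donate and a.can_accept)
            d = np.linalg.norm(np.subtract(a.position, b.position))
            if a.residue != b.residue and ok_roles and d <= 3.5:
                expected.add(frozenset((a.key, b.key)))
        assert {frozenset(e) for e in g.edges} == expected


class TestFindTriads:
    def test_planted_yre_at_five_angstroms(self):
        # pairwise Y-R = 5.0, R-E = sqrt(1+9) ~ 3.2, Y-E = 5.0 Å
        s = triad_structure((0, 0, 0), (4.0, 3.0, 0), (5.0, 0, 0))
        triads = find_triads(assign_sites(s))
        assert len(triads) == 1
        assert triads[0].pattern == "YRE"
        assert triads[0].residues == ("Y266", "R300", "E183")

    def test_one_long_distance_excludes_triad(self):
        s = triad_structure((0, 0, 0), (5.0, 0, 0), (13.0, 0, 0))  # R-E = 8 Å
        assert find_triads(assign_sites(s)) == []

    def test_rer_pattern_detected(self):
        # R300-R303 distance 8 Å > window: not a triad at default window
        s = make_structure(
            [
                (1, "NE", "N", "ARG", 300, "A", 0.0, 0, 0),
                (2, "OE1", "O", "GLU", 226, "A", 4.0, 0, 0),
                (3, "NE", "N", "ARG", 303, "A", 8.0, 0, 0),
            ]
        )
        assert find_triads(assign_sites(s)) == []
        s2 = make_structure(
            [
                (1, "NE", "N", "ARG", 300, "A", 0.0, 0, 0),
                (2, "OE1", "O", "GLU", 226, "A", 2.5, 2.5, 0),
                (3, "NE", "N", "ARG", 303, "A", 5.0, 0, 0),
            ]
        )
        triads = find_triads(assign_sites(s2))
        assert [t.pattern for t in triads] == ["RER"]
        assert triads[0].residues == ("R300", "E226", "R303")

    def test_monotone_in_window(self):
        s = triad_structure((0, 0, 0), (4.0, 3.0, 0), (5.0, 0, 0))
        sites = assign_sites(s)
        small = find_triads(sites, window=5.0)
        large = find_triads(sites, window=7.0)
        key = lambda ts: {(t.pattern, t.residues) for t in ts}
        assert key(small) <= key(large)


def brute_force_paths(graph, source, target, max_hops):
    """Exhaustive DFS over residue-level simple paths (independent oracle)."""
    rg = residue_graph(graph)
    out = []

    def dfs(node, path):
        if len(path) - 1 > max_hops:
            return
        if node == target:
            out.append(tuple(path))
            return
        for nxt in rg.neighbors(node):
            if nxt not in path:
                dfs(nxt, path + [nxt])

    dfs(source, [source])
    return sorted(out)


class TestEnumeratePaths:
    def fig6_graph(self, include_tyrosine=True):
        """The two-route topology: R303 reaches E183 through Y266 or E226."""
        sites = [
            site("R303", "ARG", "NH1", "donor", (-2.8, 2.8, 0)),
            site("R300", "ARG", "NH1", "donor", (0, 0, 0)),
            site("E183", "GLU", "OE1", "acceptor", (2.8, 0, 0)),
            site("E226", "GLU", "OE1", "acceptor", (0, 2.8, 0)),
        ]
        if include_tyrosine:
            sites.append(site("Y266", "TYR", "OH", "both", (-2.8, 0, 0)))
        return build_graph(sites)

    def test_two_paths_through_the_sensor(self):
        paths = enumerate_paths(self.fig6_graph(), "R303", "E183", max_hops=6)
        assert paths == [
            ("R303", "E226", "R300", "E183"),
            ("R303", "Y266", "R300", "E183"),
        ]

    def test_tyrosine_deletion_leaves_one_path(self):
        paths = enumerate_paths(self.fig6_graph(include_tyrosine=False), "R303", "E183", 6)
        assert paths == [("R303", "E226", "R300", "E183")]

    def test_missing_endpoint_is_lookup_error(self):
        with pytest.raises(LookupError):
            enumerate_paths(self.fig6_graph(), "R999", "E183", 6)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_dfs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        roles = ["donor", "acceptor", "both"]
        sites = [
            site(f"R{i}", "SER", "OG", roles[int(rng.integers(3))], rng.uniform(0, 6, 3))
            for i in range(n)
        ]
        g = build_graph(sites, cutoff=3.5)
        max_hops = int(rng.integers(2, 7))
        expected = brute_force_paths(g, "R0", f"R{n - 1}", max_hops)
        assert enumerate_paths(g, "R0", f"R{n - 1}", max_hops) == expected

    def test_invariant_to_insertion_order(self):
        sites = [
            site("R303", "ARG", "NH1", "donor", (-2.8, 2.8, 0)),
            site("R300", "ARG", "NH1", "donor", (0, 0, 0)),
            site("E183", "GLU", "OE1", "acceptor", (2.8, 0, 0)),
            site("E226", "GLU", "OE1", "acceptor", (0, 2.8, 0)),
            site("Y266", "TYR", "OH", "both", (-2.8, 0, 0)),
        ]
        g1 = build_graph(sites)
        g2 = build_graph(list(reversed(sites)))
        assert enumerate_paths(g1, "R303", "E183", 6) == enumerate_paths(g2, "R303", "E183", 6)

    def test_consecutive_residues_share_an_edge(self):
        g = self.fig6_graph()
        rg = residue_graph(g)
        for path in enumerate_paths(g, "R303", "E183", 6):
            for a, b in zip(path, path[1:]):
                assert rg.has_edge(a, b)

    def test_deleting_a_residue_never_adds_paths(self):
        g = self.fig6_graph()
        full = enumerate_paths(g, "R303", "E183", 6)
        g2 = g.copy()
        g2.remove_nodes_from([n for n in g.nodes if n[0] == "Y266"])
        reduced = enumerate_paths(g2, "R303", "E183", 6)
        assert set(reduced) <= set(full)
        assert len(reduced) <= len(full)
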