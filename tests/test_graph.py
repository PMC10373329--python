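"""Molecular-graph construction and vertex invariants, against brute force.

The path-count and extended-connectivity implementations are checked
against independent oracles — exhaustive simple-path enumeration and
adjacency-matrix powers — over the full atlas of small connected graphs,
and the SMILES-derived graphs are cross-checked against RDKit on the
packaged dataset.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from mcqsar import build_graph, morgan_ec, path_counts, valence_shells
from mcqsar.graph import MolecularGraph, graph_attributes, ring_codes
from mcqsar.keys import AttributeKey
from mcqsar.smiles import SmilesError

COMPOUND_1 = "COc1ccc(cc1OC)C2=C(O)C(= O)c3ccccc3O2"


def from_nx(g: nx.Graph) -> MolecularGraph:
    mg = MolecularGraph()
    order = sorted(g.nodes())
    index = {n: mg.add_vertex("C") for n in order}
    for u, v in g.edges():
        mg.add_edge(index[u], index[v], 1)
    return mg


def brute_force_paths(g: nx.Graph, start, length: int) -> int:
    """Count simple paths of exactly `length` edges by exhaustive DFS."""
    total = 0
    for target in g.nodes():
        if target == start:
            continue
        for path in nx.all_simple_paths(g, start, target, cutoff=length):
            if len(path) == length + 1:
                total += 1
    return total


class TestBuildGraph:
    def test_chain(self):
        g = build_graph("CCO")
        assert g.n_vertices == 3 and len(g.edges) == 2

    def test_benzene(self):
        g = build_graph("c1ccccc1")
        assert g.n_vertices == 6 and len(g.edges) == 6
        assert [len(r) for r in g.rings()] == [6]
        assert all(g.aromatic)

    def test_compound_1_has_22_heavy_atoms(self):
        assert build_graph(COMPOUND_1).n_vertices == 22

    def test_branching(self):
        g = build_graph("CC(C)(C)C")
        assert sorted(len(a) for a in g.adjacency) == [1, 1, 1, 1, 4]

    @pytest.mark.parametrize("bad", ["C1CC", "C(CC", "CC)C"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(SmilesError):
            build_graph(bad)


class TestMorganEC:
    def test_order_zero_is_degree(self):
        g = build_graph("CC(C)C")
        assert morgan_ec(g, 0) == [1, 3, 1, 1]

    def test_path_graph_order_one(self):
        assert morgan_ec(build_graph("CCC"), 1) == [2, 2, 2]

    def test_benzene_order_one(self):
        assert morgan_ec(build_graph("c1ccccc1"), 1) == [4] * 6

    def test_isolated_vertex(self):
        assert morgan_ec(build_graph("C"), 2) == [0]


class TestPathCounts:
    def test_benzene(self):
        g = build_graph("c1ccccc1")
        assert path_counts(g, 2) == [2] * 6
        assert path_counts(g, 3) == [2] * 6

    def test_star_centre_vs_leaf(self):
        g = build_graph("C(C)(C)C")  # K1,3 with vertex 0 at the centre
        assert path_counts(g, 2) == [0, 2, 2, 2]

    def test_single_edge(self):
        g = build_graph("CC")
        assert path_counts(g, 2) == [0, 0]
        assert path_counts(g, 3) == [0, 0]


class TestValenceShells:
    def test_benzene(self):
        g = build_graph("c1ccccc1")
        assert valence_shells(g, 2) == [2] * 6
        assert valence_shells(g, 3) == [1] * 6

    def test_path(self):
        g = build_graph("CCC")
        assert valence_shells(g, 2) == [1, 0, 1]

    def test_isolated(self):
        g = build_graph("C")
        assert valence_shells(g, 2) == [0]
        assert valence_shells(g, 3) == [0]

    def test_shells_partition_connected_graph(self, flavonols):
        for rec in list(flavonols)[::8]:
            g = build_graph(rec.smiles)
            n = g.n_vertices
            for v in range(n):
                total = sum(valence_shells(g, r)[v] for r in range(1, n))
                assert total == n - 1


class TestRingCodes:
    def test_benzene(self):
        codes = ring_codes(build_graph("c1ccccc1"))
        assert codes == {AttributeKey("RING", "6|ar=1|het=0|n=1"): 1}

    def test_morpholine(self):
        codes = ring_codes(build_graph("C1COCCN1"))
        assert codes == {AttributeKey("RING", "6|ar=0|het=1|n=1"): 1}

    def test_acyclic(self):
        assert ring_codes(build_graph("CCCC")) == {}

    def test_fused_tricycle_counts(self):
        codes = ring_codes(build_graph(COMPOUND_1))
        # two aromatic carbocycles + the heterocyclic pyranone ring
        assert codes[AttributeKey("RING", "6|ar=1|het=0|n=2")] == 1
        assert sum(1 for k in codes if "het=1" in k.payload) == 1


ATLAS = [g for g in nx.graph_atlas_g()
         if g.number_of_nodes() >= 2 and nx.is_connected(g)]


def test_path_counts_match_brute_force_on_small_graph_atlas():
    """Exhaustive oracle over every connected graph with <= 7 vertices."""
    for g in ATLAS:
        mg = from_nx(g)
        nodes = sorted(g.nodes())
        for length in (2, 3):
            ours = path_counts(mg, length)
            for i, node in enumerate(nodes):
                assert ours[i] == brute_force_paths(g, node, length), (g, node)


def test_path_counts_match_brute_force_on_eight_vertex_graphs():
    rng = np.random.default_rng(0)
    for _ in range(30):
        g = nx.gnp_random_graph(8, 0.35, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            continue
        mg = from_nx(g)
        for length in (2, 3):
            ours = path_counts(mg, length)
            for i, node in enumerate(sorted(g.nodes())):
                assert ours[i] == brute_force_paths(g, node, length)


def test_morgan_ec_matches_adjacency_power_oracle():
    """EC order k equals A^(k+1) @ 1 (degree is A @ 1)."""
    for g in ATLAS[::3]:
        mg = from_nx(g)
        a = nx.to_numpy_array(g, nodelist=sorted(g.nodes()))
        ones = np.ones(g.number_of_nodes())
        for order in (0, 1, 2):
            expected = (np.linalg.matrix_power(a, order + 1) @ ones).astype(int)
            assert morgan_ec(mg, order) == expected.tolist()


def test_total_pt2_counts_each_two_edge_path_twice():
    for g in ATLAS[::5]:
        mg = from_nx(g)
        # number of 2-edge simple paths = sum over middle vertex of C(deg, 2)
        middles = sum(d * (d - 1) // 2 for _, d in g.degree())
        assert sum(path_counts(mg, 2)) == 2 * middles


@pytest.mark.parametrize("a, b", [
    ("CCO", "OCC"),
    ("c1ccccc1", "c1ccccc1"),
    ("CC(C)C", "C(C)(C)C"),
    ("O=C1CCCC1", "C1CCCC1=O"),
])
def test_attribute_multiset_invariant_under_rewriting(a, b):
    """The same molecule written differently gives the same graph attributes."""
    assert graph_attributes(build_graph(a)) == graph_attributes(build_graph(b))


def test_benzene_attribute_symmetry():
    counts = graph_attributes(build_graph("c1ccccc1"))
    assert counts[AttributeKey("PT", "c|pta=2")] == 6
    assert counts[AttributeKey("COMBO", "c|ptdif=0")] == 6


def test_single_vertex_attributes():
    counts = graph_attributes(build_graph("C"))
    assert counts[AttributeKey("EC", "C|eca=0")] == 1
    assert not any(k.namespace == "RING" for k in counts)


def test_rdkit_agrees_on_fixture(flavonols):
    """Independent toolkit cross-check: heavy atoms and ring-bond counts."""
    from rdkit import Chem
    for rec in flavonols:
        mol = Chem.MolFromSmiles("".join(rec.smiles.split()))
        assert mol is not None, rec.id
        g = build_graph(rec.smiles)
        assert g.n_vertices == mol.GetNumHeavyAtoms(), rec.id
        assert len(g.edges) == mol.GetNumBonds(), rec.id
        assert len(g.rings()) == len(Chem.GetSSSR(mol)), rec.id
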