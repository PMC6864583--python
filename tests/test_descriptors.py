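import itertools

import numpy as np
import pandas as pd
import pytest

from mtqsar.chem_core import Atom, MolecularGraph, parse_smiles
from mtqsar.descriptors import (
    DescriptorError,
    QuadraticIndexConfig,
    compute_descriptor_matrix,
    compute_named_descriptors,
    descriptor_name,
    local_quadratic_index,
    parse_descriptor_name,
    read_descriptor_matrix,
    structure_matrix,
    total_index,
    write_descriptor_matrix,
)


def path_graph(n):
    return MolecularGraph([Atom("C")] * n, [(i, i + 1) for i in range(n - 1)], id=f"P{n}")


def random_graph(rng, n_max=8):
    """Random connected-ish simple graph for oracle checks."""
    n = int(rng.integers(2, n_max + 1))
    bonds = {(i - 1, i) for i in range(1, n)}  # spanning path keeps it connected
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.25:
            bonds.add((i, j))
    return MolecularGraph([Atom("C")] * n, bonds)


def brute_force_walks(g, k):
    """Count length-k walks between every atom pair by explicit enumeration."""
    n = g.n_atoms
    adj = [[j for i2, j in g.bonds if i2 == i] + [i2 for i2, j in g.bonds if j == i] for i in range(n)]
    W = np.zeros((n, n))
    for start in range(n):
        frontier = {start: 1}
        for _ in range(k):
            nxt = {}
            for node, cnt in frontier.items():
                for nb in adj[node]:
                    nxt[nb] = nxt.get(nb, 0) + cnt
            frontier = nxt
        for end, cnt in frontier.items():
            W[start, end] = cnt
    return W


# -- structure matrices --------------------------------------------------------


def test_p2_adjacency():
    np.testing.assert_array_equal(structure_matrix(path_graph(2), "ns", 1), [[0, 1], [1, 0]])


def test_k0_identity(benzene):
    np.testing.assert_array_equal(structure_matrix(benzene, "ns", 0), np.eye(6))
    np.testing.assert_array_equal(structure_matrix(benzene, "ss", 0), np.eye(6))


def test_stochastic_rows_sum_to_one(benzene):
    for k in range(7):
        M = structure_matrix(benzene, "ss", k)
        np.testing.assert_allclose(M.sum(axis=1), np.ones(6), atol=1e-12)


def test_negative_order_rejected(benzene):
    with pytest.raises(DescriptorError):
        structure_matrix(benzene, "ns", -1)


def test_walk_power_equals_brute_force_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(40):
        g = random_graph(rng)
        for k in range(5):
            np.testing.assert_allclose(
                structure_matrix(g, "ns", k), brute_force_walks(g, k), atol=1e-9
            )


def test_distance_semantics():
    g = path_graph(4)
    M2 = structure_matrix(g, "ns", 2, k_semantics="shortest_path_distance")
    # atoms two bonds apart: (0,2) and (1,3)
    expected = np.zeros((4, 4))
    expected[0, 2] = expected[2, 0] = expected[1, 3] = expected[3, 1] = 1
    np.testing.assert_array_equal(M2, expected)
    # ss variant row-normalises; all-zero rows stay zero
    M3 = structure_matrix(g, "ss", 3, k_semantics="shortest_path_distance")
    assert M3[1].sum() == 0  # atom 1 has nothing at distance 3
    np.testing.assert_allclose(M3[0].sum(), 1.0)


# -- local and total indices ---------------------------------------------------


def test_local_index_p2():
    g = path_graph(2)
    L = local_quadratic_index(g, "ns", 1, np.ones(2))
    np.testing.assert_allclose(L, [1, 1])
    assert total_index(L, "N1") == 2


def test_local_index_k0_squares():
    g = path_graph(3)
    x = np.array([2.0, -1.0, 3.0])
    np.testing.assert_allclose(local_quadratic_index(g, "ns", 0, x), x**2)


def test_benzene_unit_property(benzene):
    L = local_quadratic_index(benzene, "ns", 1, np.ones(6))
    np.testing.assert_allclose(L, np.full(6, 2.0))  # two neighbours each
    assert total_index(L, "N1") == 12


def test_total_index_aggregations():
    L = np.array([3.0, 4.0])
    assert total_index(L, "N1") == 7
    assert total_index(L, "N2") == 25
    assert total_index(L, "N2", n2_mode="euclidean_norm") == 5
    assert total_index(L, "RA") == 1
    assert total_index(L, "MX") == 4
    assert total_index(L, "MN") == 3
    assert total_index(L, "GM") == pytest.approx(np.sqrt(12), abs=1e-9)


def test_total_index_constant_vector():
    L = np.full(5, 2.5)
    assert total_index(L, "N1") == pytest.approx(12.5)
    assert total_index(L, "GM") == pytest.approx(2.5)
    assert total_index(L, "RA") == 0


def test_gm_sign_preservation():
    assert total_index(np.array([-2.0, 3.0]), "GM") == pytest.approx(-np.sqrt(6))
    assert total_index(np.array([-2.0, -3.0]), "GM") == pytest.approx(np.sqrt(6))
    assert total_index(np.array([0.0, 5.0]), "GM") == 0.0
    assert not np.isnan(total_index(np.array([-1.0, 2.0, -3.0]), "GM"))


def test_scaling_behaviour():
    """x → αx scales Lq and N1/GM/RA/MX/MN by α², N2 (sum of squares) by α⁴."""
    g = path_graph(5)
    rng = np.random.default_rng(3)
    x = rng.normal(size=5)
    alpha = 1.7
    for kind in ("ns", "ss"):
        for k in (1, 2, 3):
            L = local_quadratic_index(g, kind, k, x)
            L2 = local_quadratic_index(g, kind, k, alpha * x)
            np.testing.assert_allclose(L2, alpha**2 * L, rtol=1e-10)
            for agg in ("N1", "RA", "MX", "MN", "GM"):
                np.testing.assert_allclose(
                    total_index(L2, agg), alpha**2 * total_index(L, agg), rtol=1e-9
                )
            np.testing.assert_allclose(
                total_index(L2, "N2"), alpha**4 * total_index(L, "N2"), rtol=1e-9
            )


def test_permutation_invariance_of_totals():
    from mtqsar.chem_core import assign_properties

    g = parse_smiles("CC(=O)Nc1ccc(O)cc1", id="x")
    rng = np.random.default_rng(11)
    perm = list(rng.permutation(g.n_atoms))
    g2 = g.relabel(perm)
    cfg = QuadraticIndexConfig(k_max=4)
    D = compute_descriptor_matrix([g, g2], cfg, strict=True)
    np.testing.assert_allclose(D.iloc[0].values, D.iloc[1].values, rtol=1e-8, atol=1e-10)


# -- naming and matrix assembly ------------------------------------------------


def test_canonical_name_and_parse():
    assert descriptor_name("ns", 13, "VDW", "N2") == "Tnsq13(VDW)N2"
    assert descriptor_name("ss", 11, "CHR", "MN") == "Tssq11(CH)MN"
    assert parse_descriptor_name("Tnsq13(VDW)N2") == ("ns", 13, "VDW", "N2")
    assert parse_descriptor_name("Tssq11(CH)MN") == ("ss", 11, "CHR", "MN")
    with pytest.raises(DescriptorError):
        parse_descriptor_name("D[Tnsq1(M)N1]_bt")


def test_matrix_shape_and_determinism():
    g1, g2 = parse_smiles("CCO", id="a"), parse_smiles("CCN", id="b")
    cfg = QuadraticIndexConfig(k_max=1, matrix_kinds=("ns",), properties=("M",), aggregations=("N1", "MX"))
    D = compute_descriptor_matrix([g1, g2], cfg)
    assert D.shape == (2, 4)  # 2 orders × 1 property × 2 aggregations
    assert list(D.columns) == ["Tnsq0(M)N1", "Tnsq0(M)MX", "Tnsq1(M)N1", "Tnsq1(M)MX"]
    # duplicated molecule → identical descriptor row
    D2 = compute_descriptor_matrix([g1, parse_smiles("CCO", id="c")], cfg)
    np.testing.assert_array_equal(D2.iloc[0].values, D2.iloc[1].values)


def test_compute_named_matches_full_matrix(ethanol):
    cfg = QuadraticIndexConfig(k_max=3)
    D = compute_descriptor_matrix([ethanol], cfg)
    names = ["Tnsq2(M)N1", "Tssq3(CH)MN", "Tnsq1(PSA)GM"]
    got = compute_named_descriptors(ethanol, names)
    for n in names:
        assert got[n] == pytest.approx(D.iloc[0][n], rel=1e-12)


def test_matrix_round_trip(tmp_path, ethanol):
    cfg = QuadraticIndexConfig(k_max=2, properties=("M", "E"))
    D = compute_descriptor_matrix([ethanol], cfg)
    path = tmp_path / "D.csv"
    write_descriptor_matrix(D, path, cfg, {"M": "builtin-1"})
    D2 = read_descriptor_matrix(path)
    D2.index.name = None
    pd.testing.assert_frame_equal(D, D2, check_exact=False, rtol=1e-12)
    assert (tmp_path / "D.csv.json").exists()
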