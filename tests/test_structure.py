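"""Structure parsing, torsions, hydrogen bonds, secondary structure,
node features and the residue graph."""

import numpy as np
import pytest

from polysite import structure as st
from polysite import synthdata as sd
from polysite.errors import ConsistencyError, EmptyInputError

from conftest import random_rigid


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_parse_roundtrip_pdb_and_mmcif_identical(tmp_path):
    prot = sd.generate_backbone(3, "helix", seed=2)
    sd.write_pdb(prot, tmp_path / "p.pdb")
    sd.write_mmcif(prot, tmp_path / "p.cif")
    a = st.parse_structure(tmp_path / "p.pdb")
    b = st.parse_structure(tmp_path / "p.cif")
    assert len(a) == len(b) == 3
    for ra, rb in zip(a.residues, b.residues):
        assert ra.name == rb.name
        assert {x.name for x in ra.atoms} >= {"N", "CA", "C", "O"}
        for atom in ra.atoms:
            other = rb.atom(atom.name)
            assert np.allclose(atom.coords, other.coords, atol=1e-9)
            assert atom.b_factor == other.b_factor


def test_parse_water_only_file_is_empty_input(tmp_path):
    pdb = tmp_path / "w.pdb"
    pdb.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
        "END\n")
    with pytest.raises(EmptyInputError):
        st.parse_structure(pdb)


def test_parse_altloc_keeps_highest_occupancy(tmp_path):
    pdb = tmp_path / "alt.pdb"
    pdb.write_text("\n".join([
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N",
        "ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.40 10.00           C",
        "ATOM      3  CA BALA A   1       9.000   9.000   9.000  0.60 10.00           C",
        "ATOM      4  C   ALA A   1       2.004   1.423   0.000  1.00 10.00           C",
        "END", ""]))
    prot = st.parse_structure(pdb)
    assert np.allclose(prot.residues[0].coords_of("CA"), [9.0, 9.0, 9.0])


def test_parse_skips_residues_missing_ca(tmp_path):
    pdb = tmp_path / "m.pdb"
    pdb.write_text("\n".join([
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N",
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C",
        "ATOM      3  C   ALA A   1       2.004   1.423   0.000  1.00 10.00           C",
        "ATOM      4  N   GLY A   2       3.300   1.500   0.000  1.00 10.00           N",
        "ATOM      5  C   GLY A   2       5.000   2.500   0.000  1.00 10.00           C",
        "END", ""]))
    prot = st.parse_structure(pdb)
    assert len(prot) == 1
    assert prot.skipped and prot.skipped[0]["reason"] == "missing CA"


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def test_helix_torsions_recovered_to_construction_values(helix):
    tors = st.compute_torsions(helix)
    interior = slice(1, len(helix) - 1)
    assert np.abs(tors.angles[interior, 0] - (-57.0)).max() < 1e-3
    assert np.abs(tors.angles[1:-1, 1] - (-47.0)).max() < 1e-3
    omega = tors.angles[1:-1, 2]
    assert np.minimum(np.abs(omega - 180.0), np.abs(omega + 180.0)).max() < 1e-3


def test_terminal_and_glycine_torsions_undefined(helix):
    tors = st.compute_torsions(helix)
    assert not tors.defined[0, 0]  # phi at first residue
    assert not tors.defined[-1, 1] and not tors.defined[-1, 2]  # psi, omega at last
    gly = sd.generate_backbone(4, "helix", seed=0, sequence="GGGG")
    tg = st.compute_torsions(gly)
    assert not tg.defined[:, 3:].any()  # no chi atoms at all


def test_full_sidechain_chi_angles_recovered():
    prot = sd.generate_backbone(6, "helix", seed=3, sidechains="full",
                                sequence="ASKRSA")
    tors = st.compute_torsions(prot)
    # Ser: chi1 only; Lys: chi1..4; Arg: chi1..5 (built at the default rotamer)
    expected = {1: 1, 2: 4, 3: 5, 4: 1}
    for i, n_chi in expected.items():
        assert tors.defined[i, 3:3 + n_chi].all()
        assert not tors.defined[i, 3 + n_chi:].any()
        built = [sd.DEFAULT_CHI[f"chi{k + 1}"] for k in range(n_chi)]
        assert np.abs(tors.angles[i, 3:3 + n_chi] - built).max() < 1e-3


def test_cb_only_sidechains_leave_chi_undefined(helix):
    tors = st.compute_torsions(helix)
    assert not tors.defined[:, 3:].any()


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def test_helix_hbond_pattern_i_to_i_plus_4(helix, helix_featurized):
    _, hbonds, _, _ = helix_featurized
    L = len(helix)
    for i in range(5, L - 5):
        assert hbonds.bond[i - 4, i], "amide of i should bond carbonyl of i-4"
        assert tuple(hbonds.flags[i]) == (1, 1)


def test_distant_residues_have_no_hbonds():
    prot = sd.generate_backbone(2, "strand", seed=0)
    far = prot.transformed(np.eye(3), np.array([50.0, 0, 0]))
    combined = st.ProteinStructure("A", prot.residues + [
        st.Residue(2 + r.index, r.name, r.one_letter, r.atoms)
        for r in far.residues])
    hb = st.assign_hbonds(combined)
    assert not hb.bond.any()
    assert not hb.flags.any()


def test_proline_never_donates():
    prot = sd.generate_backbone(10, "helix", seed=1, sequence="AAAAAPAAAA")
    hb = st.assign_hbonds(prot)
    assert not hb.bond[:, 5].any()


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def test_helix_interior_assigned_H(helix, helix_featurized):
    _, _, ss, _ = helix_featurized
    assert all(s == "H" for s in ss[2:len(helix) - 2])


def test_two_residue_chain_never_helix():
    prot = sd.generate_backbone(2, "helix", seed=0)
    hb = st.assign_hbonds(prot)
    ss = st.assign_secondary_structure(prot, hb)
    assert set(ss) <= {"C", "S", "T", "X"}


def test_antiparallel_sheet_paired_residues_E(sheet):
    hb = st.assign_hbonds(sheet)
    ss = st.assign_secondary_structure(sheet, hb)
    n = len(sheet) // 2
    e_a = sum(1 for s in ss[:n] if s == "E")
    e_b = sum(1 for s in ss[n:] if s == "E")
    assert e_a >= 2 and e_b >= 2
    assert "H" not in ss


# ---------------------------------------------------------------------------
# per-residue features
# ---------------------------------------------------------------------------

def test_atomic_features_flags():
    prot = sd.generate_backbone(4, "helix", seed=0, sequence="GFKA")
    gly = st.residue_atomic_features(prot.residues[0])
    phe = st.residue_atomic_features(prot.residues[1])
    lys = st.residue_atomic_features(prot.residues[2])
    assert gly[2] == 0 and gly[5] == 0  # no side chain, no ring
    assert phe[5] == 1  # aromatic
    assert lys[3] == 1.0  # +1 at pH 7


def test_physchem_zscoring_properties():
    from polysite.constants import AA_ORDER, PHYSCHEM

    assert np.all(st.physchem_features("X") == 0)
    mean = np.mean([PHYSCHEM[a] for a in AA_ORDER[:20]], axis=0)
    assert np.abs(mean).max() < 1e-9
    assert st.physchem_features("I")[0] > st.physchem_features("D")[0]


# ---------------------------------------------------------------------------
# node feature matrix
# ---------------------------------------------------------------------------

def test_node_feature_block_invariants(helix, helix_featurized):
    _, _, _, feats = helix_featurized
    v = feats.values
    L = len(helix)
    assert v.shape == (L, 62)
    assert np.allclose(v[:, st.BLOCK_SS].sum(axis=1), 1.0)
    assert np.allclose(v[:, st.BLOCK_AA].sum(axis=1), 1.0)
    tor = v[:, st.BLOCK_TORSION].reshape(L, 8, 2)
    ss_cc = (tor**2).sum(axis=2)
    assert np.all((np.abs(ss_cc - 1) < 1e-9) | (np.abs(ss_cc) < 1e-9))
    pos = v[:, st.BLOCK_POSITION].ravel()
    assert np.all((pos > 0) & (pos <= 1))
    assert np.isclose(pos[0], 1.0 / L)
    assert np.all(np.isfinite(v))
    assert len(st.NodeFeatureMatrix.feature_names()) == 62


def test_node_features_length_mismatch_raises(helix, helix_featurized):
    torsions, hbonds, ss, _ = helix_featurized
    with pytest.raises(ConsistencyError):
        st.build_node_features(helix, torsions, ss[:-1], hbonds)


def test_node_features_rigid_invariance(helix, helix_featurized):
    _, _, _, feats = helix_featurized
    rng = np.random.default_rng(5)
    q, t = random_rigid(rng)
    moved = helix.transformed(q, t)
    feats2, _ = st.featurize(moved)
    assert np.abs(feats.values - feats2.values).max() < 1e-6


def test_featurization_deterministic(tmp_path, helix):
    sd.write_pdb(helix, tmp_path / "h.pdb")
    a = st.featurize(st.parse_structure(tmp_path / "h.pdb"))[0].values
    b = st.featurize(st.parse_structure(tmp_path / "h.pdb"))[0].values
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# residue graph
# ---------------------------------------------------------------------------

def _two_ca_structure(d):
    res = []
    for i, x in enumerate((0.0, d)):
        atoms = [st.Atom("N", "N", np.array([x, 1.0, 0.0])),
                 st.Atom("CA", "C", np.array([x, 0.0, 0.0])),
                 st.Atom("C", "C", np.array([x, -1.0, 0.5]))]
        res.append(st.Residue(i, "ALA", "A", atoms))
    return st.ProteinStructure("A", res)


def test_graph_cutoff_is_strict():
    assert len(st.build_graph(_two_ca_structure(7.99)).edges) == 1
    assert len(st.build_graph(_two_ca_structure(8.0)).edges) == 0


def test_graph_matches_bruteforce_on_random_coords():
    rng = np.random.default_rng(123)
    coords = rng.uniform(0, 40, (200, 3))
    res = [st.Residue(i, "GLY", "G", [st.Atom("CA", "C", c)])
           for i, c in enumerate(coords)]
    graph = st.build_graph(st.ProteinStructure("A", res))
    brute = {(i, j) for i in range(200) for j in range(i + 1, 200)
             if np.linalg.norm(coords[i] - coords[j]) < 8.0}
    assert {tuple(e) for e in graph.edges} == brute
    for (i, j), d in zip(graph.edges, graph.edge_distance):
        assert abs(d - np.linalg.norm(coords[i] - coords[j])) < 1e-6


def test_graph_distances_rigid_invariant(helix):
    g0 = st.build_graph(helix)
    rng = np.random.default_rng(9)
    q, t = random_rigid(rng)
    g1 = st.build_graph(helix.transformed(q, t))
    assert np.array_equal(g0.edges, g1.edges)
    assert np.abs(g0.edge_distance - g1.edge_distance).max() < 1e-9
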