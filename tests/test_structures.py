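"""Geometry module: ASA computation, surface and interface labeling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import biotite.structure as struc
import biotite.structure.info as struc_info

from ppisite import structures
from ppisite.structures import (
    ResidueSite,
    compute_residue_sites,
    label_interface,
    label_surface,
    load_max_asa,
    load_structure,
    read_site_table,
    write_site_table,
)

from conftest import brute_force_interface_pairs, two_sphere_exposed_areas

def _pdb_line(serial, name, res, chain, resseq, x, y, z, element, record="ATOM"):
    return (
        f"{record:<6s}{serial:>5d} {name:<4s} {res:>3s} {chain:1s}{resseq:>4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


GLY_PDB = "\n".join(
    [
        _pdb_line(1, " N", "GLY", "A", 1, 0.0, 0.6, 1.2, "N"),
        _pdb_line(2, " CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        _pdb_line(3, " C", "GLY", "A", 1, 1.3, 0.5, -0.7, "C"),
        _pdb_line(4, " O", "GLY", "A", 1, 2.2, 1.1, -0.1, "O"),
        "END",
    ]
) + "\n"


def _site(chain, num, rasa, coord, name="ALA"):
    coord = np.asarray(coord, dtype=float)
    return ResidueSite(
        chain_id=chain,
        residue_number=num,
        icode="",
        residue_name=name,
        ca_coordinates=coord,
        carbon_coordinates=coord.reshape(1, 3),
        asa=rasa * 129.0,
        rasa=rasa,
    )


def test_max_asa_table_covers_all_twenty_standard_residues():
    table = load_max_asa()
    assert len(table) == 20
    assert all(v > 0 for v in table.values())
    assert table["GLY"] == pytest.approx(104.0)
    assert table["TRP"] == pytest.approx(285.0)


def test_isolated_glycine_exceeds_tripeptide_reference_asa(tmp_path):
    # The max-ASA reference is defined in a Gly-X-Gly context; a free
    # residue has no flanking peptide occlusion, so its RASA exceeds 1.
    path = tmp_path / "gly.pdb"
    path.write_text(GLY_PDB)
    sites = compute_residue_sites(load_structure(path))
    assert len(sites) == 1
    assert sites[0].asa > 0
    assert sites[0].rasa > 1.0


def test_two_sphere_asa_matches_analytic_cap_formula():
    # Two single-atom residues: buried area is a closed-form spherical cap.
    atoms = struc.AtomArray(2)
    atoms.coord = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 4.0]])
    atoms.chain_id = np.array(["A", "A"])
    atoms.res_id = np.array([1, 2])
    atoms.res_name = np.array(["ALA", "ALA"])
    atoms.atom_name = np.array(["CA", "CA"])
    atoms.element = np.array(["C", "C"])
    atoms.hetero = np.zeros(2, bool)
    r = struc_info.vdw_radius_protor("ALA", "CA")
    sites = compute_residue_sites(atoms, sphere_points=960)
    exact1, exact2 = two_sphere_exposed_areas(r, r, d=4.0, probe=1.4)
    assert sites[0].asa == pytest.approx(exact1, rel=5e-3)
    assert sites[1].asa == pytest.approx(exact2, rel=5e-3)


def test_asa_invariant_under_translation_and_rotation(contact_fixture_pdb):
    atoms = load_structure(contact_fixture_pdb)
    base = {s.key: s.asa for s in compute_residue_sites(atoms)}

    shifted = atoms.copy()
    shifted.coord = shifted.coord + np.array([13.0, -7.0, 42.0])
    trans = {s.key: s.asa for s in compute_residue_sites(shifted)}
    for k in base:
        assert trans[k] == pytest.approx(base[k], rel=1e-6)

    rotated = atoms.copy()
    R = Rotation.from_euler("xyz", [31.0, -54.0, 112.0], degrees=True)
    rotated.coord = R.apply(rotated.coord)
    rot = {s.key: s.asa for s in compute_residue_sites(rotated)}
    # a fixed, globally oriented sphere-point set makes rotation exact only
    # up to the angular sampling error at 960 points
    for k in base:
        assert rot[k] == pytest.approx(base[k], rel=0.02)


def test_surface_threshold_is_strictly_greater_than():
    rasas = [0.16, 0.161, 0.0, 0.3, 0.1, 0.9, 0.05, 0.5, 0.15, 0.7, 0.159, 0.2]
    sites = [_site("A", i + 1, r, [i * 5.0, 0, 0]) for i, r in enumerate(rasas)]
    labeled = label_surface(sites)
    assert sum(s.is_surface for s in labeled) == 6  # exactly the six > 0.16
    by_num = {s.residue_number: s for s in labeled}
    assert not by_num[1].is_surface  # 0.16 exactly: not surface
    assert by_num[2].is_surface  # 0.161: surface
    assert all(
        (s.label == "buried") == (not s.is_surface) for s in labeled
    )


def test_far_apart_chains_have_no_interface():
    a = label_surface([_site("A", i, 0.5, [i * 3.0, 0, 0]) for i in range(5)])
    b = label_surface([_site("B", i, 0.5, [i * 3.0, 40.0, 0]) for i in range(5)])
    labeled = label_interface(a, b)
    assert all(s.label == "non_interface" for s in labeled)


def test_single_close_pair_yields_one_interface_residue_per_chain():
    a = [_site("A", i, 0.5, [i * 30.0, 0, 0]) for i in range(4)]
    b = [_site("B", i, 0.5, [i * 30.0, 20.0, 0]) for i in range(4)]
    b[2] = _site("B", 2, 0.5, [60.0, 5.0, 0])  # 5 A from A residue 2
    a, b = label_surface(a), label_surface(b)
    la = label_interface(a, b)
    lb = label_interface(b, a)
    assert [s.label for s in la].count("interface") == 1
    assert [s.label for s in lb].count("interface") == 1
    assert la[2].label == "interface" and lb[2].label == "interface"


@pytest.mark.parametrize("mode", ["ca_ca", "min_carbon"])
def test_interface_labels_agree_with_exhaustive_distance_scan(mode):
    rng = np.random.default_rng(5)
    a = label_surface(
        [_site("A", i, 0.5, c) for i, c in enumerate(rng.uniform(0, 30, (15, 3)))]
    )
    b = label_surface(
        [_site("B", i, 0.5, c) for i, c in enumerate(rng.uniform(10, 40, (15, 3)))]
    )
    labeled = label_interface(a, b, cutoff=12.0, mode=mode)
    pairs = brute_force_interface_pairs(
        [s.ca_coordinates for s in a], [s.ca_coordinates for s in b], 12.0
    )
    expected_interface = {i for i, _ in pairs}
    got = {i for i, s in enumerate(labeled) if s.label == "interface"}
    assert got == expected_interface


def test_interface_count_is_monotone_in_cutoff_and_permutation_invariant():
    rng = np.random.default_rng(11)
    a = label_surface(
        [_site("A", i, 0.5, c) for i, c in enumerate(rng.uniform(0, 25, (12, 3)))]
    )
    b = label_surface(
        [_site("B", i, 0.5, c) for i, c in enumerate(rng.uniform(5, 30, (12, 3)))]
    )
    counts = [
        sum(s.label == "interface" for s in label_interface(a, b, cutoff=c))
        for c in (4.0, 8.0, 12.0, 16.0, 25.0)
    ]
    assert counts == sorted(counts)

    perm = list(rng.permutation(len(a)))
    labels_perm = {
        s.residue_number: s.label
        for s in label_interface([a[i] for i in perm], b, cutoff=12.0)
    }
    labels_orig = {s.residue_number: s.label for s in label_interface(a, b, cutoff=12.0)}
    assert labels_perm == labels_orig


def test_buried_residues_never_become_interface():
    a = [_site("A", 1, 0.05, [0, 0, 0]), _site("A", 2, 0.5, [3, 0, 0])]
    b = [_site("B", 1, 0.5, [0, 5, 0])]
    labeled = label_interface(label_surface(a), label_surface(b))
    assert labeled[0].label == "buried"
    assert labeled[1].label == "interface"


def test_hetatm_water_is_dropped_on_load(tmp_path):
    text = GLY_PDB.replace(
        "END",
        _pdb_line(5, " O", "HOH", "A", 101, 9.0, 9.0, 9.0, "O", record="HETATM")
        + "\nEND",
    )
    path = tmp_path / "wat.pdb"
    path.write_text(text)
    atoms = load_structure(path)
    assert "HOH" not in set(atoms.res_name)


def test_site_table_round_trip(tmp_path, contact_fixture_pdb):
    atoms = load_structure(contact_fixture_pdb)
    sites = label_surface(compute_residue_sites(atoms))
    a = [s for s in sites if s.chain_id == "A"]
    b = [s for s in sites if s.chain_id == "B"]
    labeled = label_interface(a, b) + label_interface(b, a)
    path = tmp_path / "sites.tsv"
    write_site_table(labeled, path, cutoff=12.0, mode="ca_ca")
    back = read_site_table(path)
    assert len(back) == len(labeled)
    for orig, rt in zip(labeled, back):
        assert rt.key == orig.key
        assert rt.label == orig.label
        assert rt.rasa == pytest.approx(orig.rasa, abs=1e-6)
        np.testing.assert_allclose(rt.ca_coordinates, orig.ca_coordinates, atol=1e-3)
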