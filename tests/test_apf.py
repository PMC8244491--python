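import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrscreen import apf
from gpcrscreen.apf import (
    APFError,
    CHANNELS,
    N_CHANNELS,
    PropertyField,
    RigidTransform,
    apf_energy,
    assign_properties,
    build_field,
    channel_included,
    consensus,
    fields_for_ligands,
    grid_geometry,
    screen,
    superpose,
)
from gpcrscreen.ligands import Ligand, embed_3d

CH = {name: i for i, name in enumerate(CHANNELS)}


@pytest.fixture(scope="module")
def methanol():
    return embed_3d(Ligand.from_smiles("methanol", "CO"), seed=1)


@pytest.fixture(scope="module")
def benzene():
    return embed_3d(Ligand.from_smiles("benzene", "c1ccccc1"), seed=1)


# ---------------------------------------------------------------------------
# Property assignment
# ---------------------------------------------------------------------------

def test_methanol_oxygen_donor_acceptor(methanol):
    coords, props = assign_properties(methanol)
    mol = methanol.mol
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    o_row = next(i for i, a in enumerate(heavy) if a.GetSymbol() == "O")
    assert props[o_row, CH["donor"]] == 1.0
    assert props[o_row, CH["acceptor"]] == 1.0


def test_benzene_carbons_sp2_not_donor(benzene):
    _, props = assign_properties(benzene)
    assert props.shape == (6, N_CHANNELS)
    assert np.all(props[:, CH["sp2"]] == 1.0)
    assert np.all(props[:, CH["donor"]] == 0.0)
    assert np.all(props[:, CH["acceptor"]] == 0.0)


def test_properties_deterministic_reperception(small_ligands):
    actives, _ = small_ligands
    for lig in actives:
        c1, p1 = assign_properties(lig)
        c2, p2 = assign_properties(lig)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(c1, c2)
        assert np.all(p1[:, CH["size"]] > 0)  # heavy atoms have positive size
        assert set(np.unique(p1[:, CH["donor"]])) <= {0.0, 1.0}
        assert set(np.unique(p1[:, CH["sp2"]])) <= {0.0, 1.0}


def test_properties_require_conformer():
    with pytest.raises(APFError):
        assign_properties(Ligand.from_smiles("x", "CCO"))


# ---------------------------------------------------------------------------
# Field construction
# ---------------------------------------------------------------------------

def single_atom_set(pos, channel="size", value=1.0):
    props = np.zeros((1, N_CHANNELS))
    props[0, CH[channel]] = value
    return np.array([pos]), props


def test_single_atom_peak_at_atom_position():
    atom = single_atom_set([0.0, 0.0, 0.0])
    f = build_field([atom], kernel_sigma=1.0, spacing=0.5, padding=3.0)
    vals, inside = f.sample(np.array([[0.0, 0.0, 0.0]]))
    assert inside[0]
    # G(0) = 1 within grid-discretisation tolerance
    assert vals[0, CH["size"]] == pytest.approx(1.0, abs=0.02)
    assert vals[0, CH["size"]] == pytest.approx(f.grids[CH["size"]].max(), abs=0.02)


def test_two_identical_ligands_equal_single():
    atom = single_atom_set([0.2, -0.1, 0.4])
    f1 = build_field([atom])
    f2 = build_field([atom, atom], geometry=(f1.origin, f1.shape))
    np.testing.assert_allclose(f1.grids, f2.grids, atol=1e-12)


def test_field_matches_double_loop_oracle():
    coords = np.array([[0.0, 0.0, 0.0], [1.1, -0.3, 0.7]])
    props = np.zeros((2, N_CHANNELS))
    props[0] = [1, 0, 1, 0.5, 1.2, -0.3, 0.1]
    props[1] = [0, 1, 0, -0.2, 1.0, 0.9, -0.4]
    sigma, spacing = 0.8, 0.9
    f = build_field([(coords, props)], kernel_sigma=sigma, spacing=spacing,
                    padding=2.0)
    nx, ny, nz = f.shape
    for ix in range(0, nx, 2):
        for iy in range(0, ny, 2):
            for iz in range(0, nz, 2):
                node = f.origin + spacing * np.array([ix, iy, iz])
                expected = np.zeros(N_CHANNELS)
                for a in range(2):
                    delta = np.abs(node - coords[a])
                    # per-axis 3.5 sigma box window (documented truncation)
                    if np.all(delta <= 3.5 * sigma + 1e-9):
                        d2 = np.sum((node - coords[a]) ** 2)
                        expected += props[a] * math.exp(-d2 / (2 * sigma**2))
                np.testing.assert_allclose(
                    f.grids[:, ix, iy, iz], expected, atol=1e-6
                )


def test_build_field_empty_errors():
    with pytest.raises(APFError):
        build_field([])


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def test_channel_inclusion_arithmetic():
    assert channel_included(3, 4, 0.75)  # 3 >= ceil(3)
    assert not channel_included(2, 4, 0.75)
    assert not channel_included(9, 13, 0.75)  # ceil(9.75) = 10
    assert channel_included(10, 13, 0.75)


def test_consensus_masks_excluded_channels():
    a = single_atom_set([0.0, 0.0, 0.0], channel="donor")
    b = single_atom_set([0.0, 0.0, 0.0], channel="acceptor")
    geom = grid_geometry([a[0], b[0]], 0.5, 2.0)
    fa = build_field([a], geometry=geom)
    fb = build_field([b], geometry=geom)
    pharm = consensus([fa, fb, fa, fa], fraction=0.75)
    # donor present in 3/4 fields -> included; acceptor 1/4 -> excluded
    assert pharm.included[CH["donor"]]
    assert not pharm.included[CH["acceptor"]]
    assert np.all(pharm.field.grids[CH["acceptor"]] == 0.0)
    assert pharm.field.grids[CH["donor"]].max() > 0


def test_consensus_monotone_in_fraction(small_ligands):
    actives, _ = small_ligands
    fields = fields_for_ligands(actives)
    low = consensus(fields, fraction=0.5)
    high = consensus(fields, fraction=1.0)
    for i in range(N_CHANNELS):
        if high.included[i]:
            assert low.included[i]


def test_consensus_geometry_mismatch_errors():
    a = single_atom_set([0.0, 0.0, 0.0])
    f1 = build_field([a], spacing=0.5)
    f2 = build_field([a], spacing=0.4)
    with pytest.raises(APFError):
        consensus([f1, f2])


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def test_zero_field_zero_energy(toy_field):
    coords, props = single_atom_set([0.0, 0.0, 0.0])
    s = apf_energy(coords, props, toy_field)
    assert s.energy == 0.0
    assert s.score == 0.0


def test_unit_vector_at_node(toy_field):
    f = toy_field
    f.grids[CH["charge"], 4, 4, 4] = 2.5  # node at the origin
    coords, props = single_atom_set([0.0, 0.0, 0.0], channel="charge", value=1.0)
    s = apf_energy(coords, props, f)
    assert s.energy == pytest.approx(-2.5)
    assert s.score == pytest.approx(2.5)
    assert s.per_channel[CH["charge"]] == pytest.approx(-2.5)


def test_energy_against_node_sum_oracle(small_ligands):
    # place atoms exactly on grid nodes so trilinear interpolation is exact
    actives, _ = small_ligands
    coords, props = assign_properties(actives[0])
    f = build_field([(coords, props)], spacing=0.5)
    node_idx = np.array([[3, 4, 5], [6, 2, 7], [1, 1, 1]])
    node_pos = f.origin + 0.5 * node_idx
    test_props = np.ones((3, N_CHANNELS)) * 0.5
    s = apf_energy(node_pos, test_props, f)
    expected = -sum(
        0.5 * f.grids[c, i, j, k]
        for c in range(N_CHANNELS)
        for (i, j, k) in node_idx
    )
    assert s.energy == pytest.approx(expected, abs=1e-9)


def test_energy_linearity(small_ligands):
    actives, _ = small_ligands
    coords, props = assign_properties(actives[0])
    f = build_field([(coords, props)])
    n = len(coords) // 2
    whole = apf_energy(coords, props, f).energy
    part1 = apf_energy(coords[:n], props[:n], f).energy
    part2 = apf_energy(coords[n:], props[n:], f).energy
    assert whole == pytest.approx(part1 + part2, abs=1e-9)


def test_energy_translation_invariance(small_ligands):
    actives, _ = small_ligands
    coords, props = assign_properties(actives[1])
    f = build_field([(coords, props)])
    shift = np.array([5.0, -3.0, 2.0])
    f2 = PropertyField(origin=f.origin + shift, spacing=f.spacing,
                       grids=f.grids.copy(), sigma=f.sigma)
    e1 = apf_energy(coords, props, f).energy
    e2 = apf_energy(coords + shift, props, f2).energy
    assert e1 == pytest.approx(e2, abs=1e-9)


def test_energy_all_atoms_outside_errors(toy_field):
    coords, props = single_atom_set([99.0, 99.0, 99.0])
    with pytest.raises(APFError):
        apf_energy(coords, props, toy_field)


def test_per_channel_sums_to_energy(small_ligands):
    actives, _ = small_ligands
    coords, props = assign_properties(actives[2])
    f = build_field([(coords, props)])
    s = apf_energy(coords, props, f)
    assert sum(s.per_channel) == pytest.approx(s.energy, abs=1e-9)
    assert s.score == -s.energy


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def test_rigid_transform_validates_rotation():
    with pytest.raises(APFError):
        RigidTransform(np.eye(3) * 2.0, np.zeros(3))


def test_superpose_zero_restarts_is_input_pose(small_ligands):
    actives, _ = small_ligands
    coords, props = assign_properties(actives[0])
    f = build_field([(coords, props)])
    t, s = superpose((coords, props), f, n_restarts=0)
    np.testing.assert_allclose(t.apply(coords), coords)
    assert s.score == apf_energy(coords, props, f).score


def test_superpose_self_recovery(small_ligands):
    actives, _ = small_ligands
    coords, props = assign_properties(actives[0])
    f = build_field([(coords, props)])
    in_place = apf_energy(coords, props, f).score
    _, s = superpose((coords, props), f, n_restarts=4, seed=0)
    assert s.score >= 0.98 * in_place


def test_superpose_transform_recovery(small_ligands):
    actives, _ = small_ligands
    coords, props = assign_properties(actives[1])
    f = build_field([(coords, props)])
    in_place = apf_energy(coords, props, f).score
    rng = np.random.default_rng(5)
    rot = Rotation.random(random_state=rng).as_matrix()
    moved = coords @ rot.T + np.array([6.0, -4.0, 3.0])
    _, s = superpose((moved, props), f, n_restarts=32, seed=0)
    assert s.score >= 0.95 * in_place


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def test_screen_template_ranks_first(small_ligands):
    actives, decoys = small_ligands
    coords, props = assign_properties(actives[0])
    f = build_field([(coords, props)])
    table = screen([actives[0]] + list(decoys[:3]), f, seed=1, n_restarts=6)
    assert table.iloc[0]["ligand_id"] == actives[0].id


def test_screen_threshold_above_max_gives_no_hits(small_ligands):
    actives, _ = small_ligands
    coords, props = assign_properties(actives[0])
    f = build_field([(coords, props)])
    table = screen(list(actives[:2]), f, threshold=1e9, seed=0, n_restarts=2)
    assert not table["is_hit"].any()


def test_screen_deterministic_and_order_independent(small_ligands):
    actives, decoys = small_ligands
    coords, props = assign_properties(actives[0])
    f = build_field([(coords, props)])
    lib = list(actives[:2]) + list(decoys[:2])
    t1 = screen(lib, f, seed=3, n_restarts=4)
    t2 = screen(lib, f, seed=3, n_restarts=4)
    t3 = screen(lib[::-1], f, seed=3, n_restarts=4)
    assert t1.to_csv() == t2.to_csv() == t3.to_csv()


def test_screen_skips_ligands_without_conformers(small_ligands, caplog):
    actives, _ = small_ligands
    coords, props = assign_properties(actives[0])
    f = build_field([(coords, props)])
    flat = Ligand.from_smiles("flat", "CCO")
    table = screen([actives[0], flat], f, seed=0, n_restarts=2)
    assert "flat" not in set(table["ligand_id"])
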