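import numpy as np
import pytest

from auxqmmm import qmmm_coupling as qc
from auxqmmm.adft_scf import SCFSettings, run_scf
from auxqmmm.chem_model import (
    Atom,
    MolecularSystem,
    PointCharge,
    make_fixture,
    partition_by_selection,
)
from auxqmmm.mm_forcefield import FFParameters, mm_energy_gradient
from auxqmmm.units import ANGSTROM_TO_BOHR


@pytest.fixture(scope="module")
def ff():
    return FFParameters.builtin()


def mm_engine(template, part, ff):
    """MM evaluator over the capped model region (the standard QM stand-in)."""

    def engine(qm_atoms, embedding):
        model = qc._model_system(template, part, qm_atoms)
        br, g = mm_energy_gradient(model, ff)
        ef, gm, gs = qc._charge_field_interaction(model, embedding)
        return br.total + ef, g + gm, gs

    return engine


# ---------------------------------------------------------------------------
# link atoms
# ---------------------------------------------------------------------------

def test_link_atom_midpoint():
    atoms = [
        Atom("C", 6, [0, 0, 0], 12.0, mm_type="CT3"),
        Atom("C", 6, [0, 0, 2.0], 12.0, mm_type="CT3"),
    ]
    s = MolecularSystem(atoms=atoms, bonds=[(0, 1)])
    part = partition_by_selection(s, [0])
    links = qc.place_link_atoms(s, part, alpha_table={(0, 1): 0.5})
    assert np.allclose(links[0].position, [0, 0, 1.0])


def test_link_atom_cc_ratio_gives_ch_length():
    s = make_fixture("alkane", {"n_carbons": 2})
    h_of_c0 = [j for (i, j) in s.bonds if i == 0 and s.atoms[j].element == "H"]
    part = partition_by_selection(s, [0] + h_of_c0)
    links = qc.place_link_atoms(s, part)
    la = links[0]
    assert la.alpha == pytest.approx(1.090 / 1.530, abs=1e-4)
    d = np.linalg.norm(la.position - s.atoms[la.qba].position)
    assert d == pytest.approx(1.090 * ANGSTROM_TO_BOHR, abs=1e-6)


def test_link_atom_collinearity_random():
    rng = np.random.default_rng(5)
    for _ in range(10):
        rq, rm = rng.uniform(-3, 3, (2, 3))
        atoms = [
            Atom("C", 6, rq, 12.0, mm_type="CT3"),
            Atom("C", 6, rm, 12.0, mm_type="CT3"),
        ]
        s = MolecularSystem(atoms=atoms, bonds=[(0, 1)])
        part = partition_by_selection(s, [0])
        la = qc.place_link_atoms(s, part)[0]
        v1 = la.position - rq
        v2 = rm - rq
        cross = np.cross(v1, v2)
        assert np.linalg.norm(cross) <= 1e-10 * np.linalg.norm(v2)


def test_link_force_projection_limits():
    F = np.array([1.0, -2.0, 0.5])
    gq, gm = qc.project_link_forces(F, 0.999999)
    assert np.allclose(gm, F, atol=1e-5)
    gq, gm = qc.project_link_forces(F, 1e-6)
    assert np.allclose(gq, F, atol=1e-5)
    gq, gm = qc.project_link_forces(F, 0.3)
    assert np.allclose(gq + gm, F, atol=1e-14)


def test_link_alpha_range_enforced():
    with pytest.raises(ValueError):
        qc.LinkAtom(qba=0, mba=1, alpha=1.5)


# ---------------------------------------------------------------------------
# additive / subtractive identities (MM engine as the QM stand-in)
# ---------------------------------------------------------------------------

def test_same_level_oniom_collapses_to_mm(ff):
    s = make_fixture("water_droplet", {"n": 5}, seed=2)
    part = partition_by_selection(s, [0, 1, 2])
    settings = qc.QMMMSettings(qm_engine=mm_engine(s, part, ff), ff=ff)
    oni, _ = qc.subtractive_oniom(s, part, settings)
    pure, _ = mm_energy_gradient(s, ff)
    assert oni.E_total == pytest.approx(pure.total, abs=1e-12)


def test_empty_mm_region_oniom_is_model_energy(ff):
    s = make_fixture("water_droplet", {"n": 2}, seed=4)
    part = partition_by_selection(s, range(s.n_atoms))
    settings = qc.QMMMSettings(qm_engine=mm_engine(s, part, ff), ff=ff)
    oni, _ = qc.subtractive_oniom(s, part, settings)
    # E_MM(system) cancels E_MM(model) exactly
    assert oni.E_total == pytest.approx(oni.E_QM_model, abs=1e-12)


def test_additive_equals_subtractive_consistent_config(ff):
    s = make_fixture("water_droplet", {"n": 5}, seed=2)
    part = partition_by_selection(s, [0, 1, 2])
    settings = qc.QMMMSettings(qm_engine=mm_engine(s, part, ff), ff=ff)
    add, _ = qc.additive_qmmm(s, part, settings)
    oni, _ = qc.subtractive_oniom(s, part, settings)
    assert add.E_total == pytest.approx(oni.E_total, abs=1e-12)


def test_gradients_match_fd_with_link_atoms(ff):
    # ethane cut through the C-C bond exercises link placement + projection
    s = make_fixture("alkane", {"n_carbons": 2})
    rng = np.random.default_rng(7)
    s.set_positions(s.positions + 0.03 * rng.standard_normal((s.n_atoms, 3)))
    h_of_c0 = [j for (i, j) in s.bonds if i == 0 and s.atoms[j].element == "H"]
    part = partition_by_selection(s, [0] + h_of_c0)
    settings = qc.QMMMSettings(qm_engine=mm_engine(s, part, ff), ff=ff)
    for driver in (qc.additive_qmmm, qc.subtractive_oniom):
        _, g = driver(s, part, settings, compute_gradient=True)
        pos = s.positions
        h = 1e-4
        for i in [0, part.boundary_pairs[0][1], 2, 5]:
            for d in range(3):
                p = pos.copy(); p[i, d] += h
                s.set_positions(p)
                e1, _ = driver(s, part, settings)
                p = pos.copy(); p[i, d] -= h
                s.set_positions(p)
                e2, _ = driver(s, part, settings)
                s.set_positions(pos)
                fd = (e1.E_total - e2.E_total) / (2 * h)
                assert abs(fd - g[i, d]) <= 1e-6, (driver.__name__, i, d)


# ---------------------------------------------------------------------------
# additive with the real SCF engine
# ---------------------------------------------------------------------------

def test_additive_decoupled_equals_gas_phase(ff, minimal_lib):
    s = make_fixture("water_droplet", {"n": 2}, seed=9)
    part = partition_by_selection(s, [0, 1, 2])
    for i in part.mm_indices:
        s.atoms[i].mm_charge = 0.0
        s.atoms[i].lj_epsilon = 0.0
    for i in part.qm_indices:
        s.atoms[i].lj_epsilon = 0.0
    settings = qc.QMMMSettings(basis="minimal", ff=ff,
                               scf=SCFSettings(scheme="mixed", tol=1e-8))
    add, _ = qc.additive_qmmm(s, part, settings)
    gas = run_scf([s.atoms[i] for i in part.qm_indices], minimal_lib,
                  settings=SCFSettings(scheme="mixed", tol=1e-8))
    assert add.E_QM == pytest.approx(gas.E_total, abs=1e-10)
    assert add.E_QMMM == 0.0


def test_embedding_interaction_scales_like_charge_dipole(ff, water_atoms, minimal_lib):
    # a single charge at R interacts with the water dipole ~ q mu / R^2
    gas = run_scf(water_atoms, minimal_lib, settings=SCFSettings(tol=1e-9))
    de = {}
    for R in (20.0, 40.0):
        q = PointCharge(np.array([0.0, 0.0, R]), 0.5)
        emb = run_scf(water_atoms, minimal_lib, embedding=[q],
                      settings=SCFSettings(tol=1e-9))
        de[R] = emb.E_total - gas.E_total
    ratio = de[20.0] / de[40.0]
    assert 3.3 <= ratio <= 4.7  # ~ (40/20)^2 with higher-multipole corrections


def test_embedding_field_excludes_qm_and_mba(ff):
    s = make_fixture("alkane", {"n_carbons": 3})
    h_of_c0 = [j for (i, j) in s.bonds if i == 0 and s.atoms[j].element == "H"]
    part = partition_by_selection(s, [0] + h_of_c0)
    settings = qc.QMMMSettings(ff=ff)
    fieldobj = qc.build_embedding_field(s, part, settings)
    mba = part.boundary_pairs[0][1]
    assert mba in fieldobj.excluded_indices
    assert len(fieldobj.charges) == len(part.mm_indices) - 1
    qm_pos = {tuple(np.round(s.atoms[i].position, 8)) for i in part.qm_indices}
    for pc in fieldobj.charges:
        assert tuple(np.round(pc.position, 8)) not in qm_pos


# ---------------------------------------------------------------------------
# FIRES
# ---------------------------------------------------------------------------

def test_fires_no_intruder_zero():
    state = qc.FIRESState(inner_tags=[1, 2], outer_tags=[3], reference=0,
                          k_fires=0.1)
    pos = np.array([[0, 0, 0], [1.0, 0, 0], [0, 2.0, 0], [0, 0, 5.0]])
    E, g = qc.fires_energy_gradient(state, pos)
    assert E == 0.0 and np.abs(g).max() == 0.0


def test_fires_single_intruder_arithmetic():
    # R_in = 2, intruder at 1.5 -> E = 0.5 * 2 * 0.25 = 0.25
    state = qc.FIRESState(inner_tags=[1], outer_tags=[2], reference=0, k_fires=2.0)
    pos = np.array([[0, 0, 0], [0, 0, 2.0], [0, 0, 1.5]])
    E, g = qc.fires_energy_gradient(state, pos)
    assert E == pytest.approx(0.25, abs=1e-14)
    assert np.abs(g.sum(axis=0)).max() <= 1e-14


def test_fires_forces_sum_zero_random():
    rng = np.random.default_rng(12)
    state = qc.FIRESState(inner_tags=[1, 2, 3], outer_tags=[4, 5, 6, 7],
                          reference=0, k_fires=0.08)
    for _ in range(20):
        pos = rng.uniform(-3, 3, (8, 3))
        E, g = qc.fires_energy_gradient(state, pos)
        assert np.abs(g.sum(axis=0)).max() <= 1e-12
        assert E >= 0.0


def test_fires_empty_inner_rejected():
    with pytest.raises(ValueError):
        qc.FIRESState(inner_tags=[], outer_tags=[1], reference=0, k_fires=0.1)


def test_fires_md_preserves_inner_identity(ff):
    # shortened version of the droplet integrity run (the acceptance test
    # does 1,000 steps with the 21-water droplet)
    from auxqmmm.sampling import MDState, ThermostatSettings, quench, run_md
    from auxqmmm.units import KCALMOL_TO_HARTREE

    s = make_fixture("ion_droplet", {"ion": "Na", "n_waters": 10}, seed=13)
    oxy = [i for i, a in enumerate(s.atoms) if a.element == "O"]
    d = np.array([np.linalg.norm(s.atoms[i].position) for i in oxy])
    order = np.argsort(d)
    inner = [oxy[i] for i in order[:4]]
    outer = [oxy[i] for i in order[4:]]
    k = 200.0 * KCALMOL_TO_HARTREE / ANGSTROM_TO_BOHR ** 2
    state_f = qc.FIRESState(inner_tags=inner, outer_tags=outer, reference=0,
                            k_fires=k, symmetric=True, reaction="distributed")
    k_wall = 10.0 * KCALMOL_TO_HARTREE / ANGSTROM_TO_BOHR ** 2
    r_wall = float(d.max()) + 1.5 * ANGSTROM_TO_BOHR

    def engine(pos):
        s.set_positions(pos)
        br, g = mm_energy_gradient(s, ff)
        ef, gf = qc.fires_energy_gradient(state_f, pos)
        ec, gc = qc.spherical_container(pos, pos[0], r_wall, k_wall,
                                        atom_indices=oxy)
        g = g + gf + gc
        g[0] = 0.0
        return br.total + ef + ec, g

    pos0 = quench(s.positions, engine)  # start from a relaxed droplet
    st = MDState.initialize(pos0, s.masses, T=300, seed=14)
    slack = 0.5 * ANGSTROM_TO_BOHR
    depths = []

    def track(state):
        p = state.positions
        rin = max(np.linalg.norm(p[i] - p[0]) for i in inner)
        depths.append(
            max(0.0, max(rin - np.linalg.norm(p[j] - p[0]) for j in outer))
        )

    st, traj = run_md(st, engine, 300, dt_fs=0.5,
                      thermostat=ThermostatSettings("langevin", 300, 0.02, 15),
                      callback=track)
    assert max(depths) <= slack
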