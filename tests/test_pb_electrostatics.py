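"""Solver checks against closed-form electrostatics oracles.

The Born ion and two-point-charge Coulomb energies have exact analytic
expressions; the finite-difference solution must reproduce them and converge
toward them under grid refinement.  Oracle configurations use probe radius 0
so the dielectric sphere radius equals the atom radius of the closed form.
"""
import io
import math

import numpy as np
import pytest

from multipk.constants import COULOMB_KCAL
from multipk.fixtures import FixtureSpec, make_toy_peptide
from multipk.pb_electrostatics import (
    PBConfig,
    SiteEnergyTable,
    build_maps,
    coulomb_energy,
    reaction_field_energy,
    site_energy_terms,
    solve_focused,
    solve_lpb,
)
from multipk.structure_io import (
    Atom,
    Conformer,
    TitratableSite,
    assign_parameters,
    detect_sites,
    load_default_parameters,
)
from multipk.titration_core import default_microstates


def born_energy(q, radius, eps_in, eps_out):
    return COULOMB_KCAL * q * q / (2.0 * radius) * (1.0 / eps_out - 1.0 / eps_in)


def oracle_config(fine, coarse=1.0):
    return PBConfig(ionic_strength=0.0, probe_radius=0.0, grid_spacing_coarse=coarse,
                    grid_spacing_fine=fine, grid_padding=8.0, focus_margin=6.0)


SINGLE_ION = np.array([[0.0, 0.0, 0.0, 2.0, 0.0]])


def glu_fragment_conformer(table, offset=(0.0, 0.0, 0.0)):
    """A bare carboxyl model compound (the GLU side-chain fragment)."""
    coords = {"CB": (0, 1.53, 0), "CG": (0.5, 2.88, 0), "CD": (0, 4.23, 0),
              "OE1": (-0.63, 5.3, 0), "OE2": (0.93, 5.3, 0)}
    block = table.block("GLU", "neutral")
    atoms = [Atom(n, "O" if n.startswith("O") else "C",
                  np.asarray(coords[n], float) + np.asarray(offset, float),
                  "A", "GLU", 1, partial_charge=block[n][0], radius=block[n][1])
             for n in coords]
    site = TitratableSite(("A", "GLU", 1, ""), "carboxyl", 4.4,
                          default_microstates("carboxyl", 4.4, table.charge_sets("GLU")))
    return Conformer(atoms), site


class TestGridMaps:
    def test_single_atom_protein_dielectric_region(self):
        cfg = oracle_config(0.5)
        maps = build_maps(SINGLE_ION, cfg, spacing=0.5)
        eps_x = maps.eps_edges[0]
        # x-edge midpoints within 2.0 Å of the centre must be pure protein
        ox = maps.origin + np.array([0.25, 0.0, 0.0])
        nx = eps_x.shape
        xs = ox[0] + 0.5 * np.arange(nx[0])
        ys = maps.origin[1] + 0.5 * np.arange(nx[1])
        zs = maps.origin[2] + 0.5 * np.arange(nx[2])
        d = np.sqrt(xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2)
        assert np.all(eps_x[d <= 2.0 - 0.5] == cfg.eps_protein)
        assert np.all(eps_x[d >= 2.0 + 0.5] == cfg.eps_solvent)

    def test_ion_exclusion_layer(self):
        cfg = PBConfig(probe_radius=1.4, ion_exclusion=2.0, grid_padding=8.0)
        maps = build_maps(SINGLE_ION, cfg, spacing=0.5)
        xs = [maps.node_coords(d) for d in range(3)]
        d = np.sqrt(xs[0][:, None, None] ** 2 + xs[1][None, :, None] ** 2
                    + xs[2][None, None, :] ** 2)
        assert np.all(maps.kappa2bar[d <= 2.0 + 1.4 + 2.0] == 0.0)
        assert np.all(maps.kappa2bar[d > 2.0 + 1.4 + 2.0 + 0.9] > 0.0)

    def test_charge_on_node_exact(self):
        cfg = oracle_config(0.5)
        maps = build_maps(SINGLE_ION, cfg, spacing=0.5,
                          charge_overlay=[((0.0, 0.0, 0.0), 1.0)])
        # grid is centred on the atom, so the charge lands on one node
        assert maps.charge.max() == pytest.approx(1.0)
        assert np.count_nonzero(maps.charge) == 1

    def test_charge_at_cell_centre_eighths(self):
        cfg = oracle_config(0.5)
        maps = build_maps(SINGLE_ION, cfg, spacing=0.5, origin=(-5.0, -5.0, -5.0),
                          shape=(21, 21, 21), charge_overlay=[((0.25, 0.25, 0.25), 1.0)])
        vals = maps.charge[np.abs(maps.charge) > 0]
        assert len(vals) == 8
        assert np.allclose(vals, 0.125)

    def test_charge_conservation(self):
        cfg = oracle_config(0.5)
        rng = np.random.default_rng(0)
        overlay = [(tuple(rng.uniform(-1.5, 1.5, 3)), q) for q in rng.normal(0, 0.5, 12)]
        maps = build_maps(SINGLE_ION, cfg, spacing=0.5, charge_overlay=overlay)
        assert maps.charge.sum() == pytest.approx(sum(q for _, q in overlay), abs=1e-9)

    def test_charge_outside_grid_rejected(self):
        # an explicitly sized grid too small for the source must error out
        cfg = oracle_config(0.5)
        with pytest.raises(ValueError, match="padding"):
            build_maps(SINGLE_ION, cfg, spacing=0.5, origin=(-1.0, -1.0, -1.0),
                       shape=(5, 5, 5), charge_overlay=[((50.0, 0.0, 0.0), 1.0)])


class TestSolver:
    def test_zero_charge_zero_potential(self):
        cfg = oracle_config(0.5)
        maps = build_maps(SINGLE_ION, cfg, spacing=0.5)
        phi = solve_lpb(maps, cfg)
        assert np.abs(phi).max() == 0.0

    def test_two_point_charges_coulomb(self):
        cfg = oracle_config(0.4)
        field = solve_focused(np.zeros((0, 5)), [((0.0, 0.0, 0.0), 1.0)], cfg,
                              uniform_eps=78.0, with_ions=False)
        e = 1.0 * field.at(np.array([5.0, 0.0, 0.0]))[0]
        ana = coulomb_energy(1.0, 1.0, 5.0, 78.0)
        assert abs(e - ana) / abs(ana) < 0.02

    def test_born_ion_reaction_field(self):
        cfg = oracle_config(0.4)
        g = reaction_field_energy(SINGLE_ION, [((0.0, 0.0, 0.0), 1.0)], cfg)
        ana = born_energy(1.0, 2.0, 4.0, 78.0)
        assert abs(g - ana) / abs(ana) < 0.03

    def test_refinement_shrinks_oracle_gap(self):
        ana = born_energy(1.0, 2.0, 4.0, 78.0)
        errs = []
        for h in (1.0, 0.5, 0.25):
            g = reaction_field_energy(SINGLE_ION, [((0.0, 0.0, 0.0), 1.0)], oracle_config(h))
            errs.append(abs(g - ana) / abs(ana))
        assert errs[0] > errs[1] > errs[2]

    def test_nonconvergence_reported(self):
        from multipk.pb_electrostatics import PBConvergenceError

        cfg = oracle_config(0.5)
        maps = build_maps(SINGLE_ION, cfg, spacing=0.5,
                          charge_overlay=[((0.0, 0.0, 0.0), 1.0)])
        with pytest.raises(PBConvergenceError, match="residual"):
            solve_lpb(maps, cfg, max_iter=2)


@pytest.fixture(scope="module")
def table():
    return load_default_parameters()


class TestSiteEnergies:
    def test_isolated_model_compound_is_null(self, table):
        conf, site = glu_fragment_conformer(table)
        out = site_energy_terms(conf, [site], PBConfig())
        rec = out.records[0][1]  # deprotonated microstate
        assert rec.dpk_born == pytest.approx(0.0, abs=1e-9)
        assert rec.dpk_perm == pytest.approx(0.0, abs=1e-9)
        assert rec.pk_int == pytest.approx(4.4, abs=1e-9)

    def test_burial_raises_acid_pk(self, table):
        conf, site = glu_fragment_conformer(table)
        shell = [Atom("CB", "C", np.array(p, float), "A", "ALA", 2,
                      partial_charge=0.0, radius=3.0)
                 for p in [(0, 5.3, 3.6), (0, 5.3, -3.6), (3.6, 5.3, 0), (-3.4, 5.3, 0)]]
        buried = Conformer(conf.atoms + shell)
        out = site_energy_terms(buried, [site], PBConfig())
        assert out.records[0][1].dpk_born > 0.0

    def test_two_site_w_matches_coulomb_oracle(self, table):
        # near-uniform solvent dielectric: W must approach the analytic
        # Coulomb sum over the two charge-difference distributions
        cfg = PBConfig(eps_protein=77.9, eps_solvent=78.0, ionic_strength=0.0)
        conf, site = glu_fragment_conformer(table)
        lys = {"CB": (0, 1.53, 0), "CG": (0.5, 2.88, 0), "CD": (0, 4.23, 0),
               "CE": (0.5, 5.58, 0), "NZ": (0, 6.93, 0)}
        block = table.block("LYS", "neutral")
        off = np.array([5.93, -1.63, 0.0])  # NZ at 5 Å from OE2
        atoms2 = [Atom(n, "N" if n == "NZ" else "C", np.asarray(p, float) + off,
                       "B", "LYS", 1, partial_charge=block[n][0], radius=block[n][1])
                  for n, p in lys.items()]
        site2 = TitratableSite(("B", "LYS", 1, ""), "amino", 10.4,
                               default_microstates("amino", 10.4, table.charge_sets("LYS")))
        both = Conformer(conf.atoms + atoms2)
        out = site_energy_terms(both, [site, site2], cfg)
        w = out.pair_w[(0, 1)][-1, -1]
        cs_g, cs_l = table.charge_sets("GLU"), table.charge_sets("LYS")
        dq_g = {a: cs_g["charged"].get(a, 0) - cs_g["neutral"].get(a, 0) for a in cs_g["charged"]}
        dq_l = {a: cs_l["charged"].get(a, 0) - cs_l["neutral"].get(a, 0) for a in cs_l["charged"]}
        pos = {a.name + a.chain: a.coords for a in both.atoms}
        ana = sum(COULOMB_KCAL * dq_g[a] * dq_l[b]
                  / (78.0 * np.linalg.norm(pos[a + "A"] - pos[b + "B"]))
                  for a in dq_g for b in dq_l)
        assert abs(w - ana) / abs(ana) < 0.05
        assert w < 0  # acid/base pair attracts

    def test_w_symmetry_within_solver_tolerance(self, glu_lys_bridge, table):
        _, conf, _ = glu_lys_bridge
        pc = assign_parameters(conf, table)
        sites = detect_sites(pc, parameter_table=table)
        out = site_energy_terms(pc, sites, PBConfig())
        # asymmetry between the two one-sided estimates of each W entry
        assert out.asymmetry < 0.05

    def test_translation_invariance_exact_with_recentred_grid(self, table):
        conf, site = glu_fragment_conformer(table)
        moved, _ = glu_fragment_conformer(table, offset=(3.37, -1.21, 0.55))
        a = site_energy_terms(conf, [site], PBConfig())
        b = site_energy_terms(moved, [site], PBConfig())
        assert b.records[0][1].pk_int == pytest.approx(a.records[0][1].pk_int, abs=1e-9)

    def test_rotation_and_origin_shift_within_tolerance(self, table):
        conf, site = glu_fragment_conformer(table)
        shell = [Atom("CB", "C", np.array([0.0, 5.3, 3.5]), "A", "ALA", 2,
                      partial_charge=0.0, radius=3.0)]
        base = Conformer(conf.atoms + shell)
        ref = site_energy_terms(base, [site], PBConfig()).records[0][1]
        th = math.radians(30)
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        rotated = Conformer([
            Atom(a.name, a.element, rot @ a.coords, a.chain, a.resname, a.resnum,
                 partial_charge=a.partial_charge, radius=a.radius)
            for a in base.atoms])
        rec_rot = site_energy_terms(rotated, [site], PBConfig()).records[0][1]
        assert rec_rot.pk_int == pytest.approx(ref.pk_int, abs=0.05)
        shifted = site_energy_terms(base, [site],
                                    PBConfig(origin_shift=(0.31, 0.17, 0.23))).records[0][1]
        assert shifted.pk_int == pytest.approx(ref.pk_int, abs=0.05)

    def test_energy_table_tsv_roundtrip(self, glu_lys_bridge, table):
        _, conf, _ = glu_lys_bridge
        pc = assign_parameters(conf, table)
        sites = detect_sites(pc, parameter_table=table)
        out = site_energy_terms(pc, sites, PBConfig())
        back = SiteEnergyTable.from_tsv(io.StringIO(out.to_tsv()))
        assert back.site_ids == out.site_ids
        ma, mb = out.to_model(), back.to_model()
        assert np.array_equal(ma.w_dense, mb.w_dense)
        for i in range(ma.n_sites):
            assert np.array_equal(ma.pk_int[i], mb.pk_int[i])
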