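"""Partition-function and Monte Carlo titration tests.

The brute-force oracle below is an independent implementation: it loops over
all state vectors with plain ``itertools`` and accumulates Boltzmann factors
written directly in powers of ten, never touching the vectorised production
code paths.
"""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multipk.constants import LN10, kt
from multipk.fixtures import make_energy_table, random_energy_table
from multipk.titration_core import (
    MCConfig,
    StateEnergyModel,
    StateSpaceTooLarge,
    default_microstates,
    degree_of_deprotonation,
    populations_exact,
    populations_mc,
    protonated_fraction,
    state_energy,
)


def brute_force_populations(model, ph_values):
    """Independent enumeration oracle (plain loops, log10 arithmetic)."""
    kT = kt(model.temperature)
    out = [np.zeros((d, len(ph_values))) for d in model.dims]
    for ip, ph in enumerate(ph_values):
        weights = {}
        z = 0.0
        for x in itertools.product(*[range(d) for d in model.dims]):
            e = 0.0
            for i, xi in enumerate(x):
                dn = model.dn[i][xi]
                e += dn * LN10 * kT * (ph - model.pk_int[i][xi]) + model.offsets[i][xi]
            for i in range(model.n_sites):
                for j in range(i + 1, model.n_sites):
                    e += model.w_dense[i, x[i], j, x[j]]
            w = 10.0 ** (-e / (LN10 * kT))
            weights[x] = w
            z += w
        for x, w in weights.items():
            for i, xi in enumerate(x):
                out[i][xi, ip] += w / z
    return out


def hh_curve(ph, pk):
    return 1.0 / (1.0 + 10.0 ** (ph - pk))


class TestStateEnergy:
    def setup_method(self):
        self.table = make_energy_table(["carboxyl", "carboxyl"], [4.4, 4.0], {(0, 1): 1.36})
        self.model = self.table.to_model()

    def test_reference_vector_zero_any_ph(self):
        for ph in (0.0, 4.4, 7.0, 14.0):
            assert state_energy(self.model.reference_vector, self.model, ph) == 0.0

    def test_singleton_zero_at_intrinsic_pk(self):
        single = make_energy_table(["carboxyl"], [4.4]).to_model()
        assert state_energy([1], single, 4.4) == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_additivity(self):
        e_both = state_energy([1, 1], self.model, 5.0)
        e_a = state_energy([1, 0], self.model, 5.0)
        e_b = state_energy([0, 1], self.model, 5.0)
        assert e_both - e_a - e_b == pytest.approx(1.36, abs=1e-12)

    def test_invalid_index_rejected(self):
        with pytest.raises(IndexError):
            state_energy([2, 0], self.model, 7.0)


class TestExactEnumeration:
    def test_single_site_henderson_hasselbalch(self):
        model = make_energy_table(["carboxyl"], [4.4]).to_model()
        ph = np.arange(0.0, 14.01, 0.1)
        pops = populations_exact(model, ph)
        assert np.abs(protonated_fraction(pops, 0) - hh_curve(ph, 4.4)).max() < 1e-12
        at_pk = populations_exact(model, [4.4])
        assert protonated_fraction(at_pk, 0)[0] == pytest.approx(0.5, abs=1e-12)

    def test_two_acids_match_independent_brute_force(self):
        # W of 1.0 pK unit equivalent
        w = LN10 * kt(298.0)
        model = make_energy_table(["carboxyl", "carboxyl"], [4.4, 4.4], {(0, 1): w}).to_model()
        ph = np.arange(2.0, 8.01, 0.25)
        pops = populations_exact(model, ph)
        oracle = brute_force_populations(model, ph)
        for i in range(2):
            assert np.abs(pops.pops[i] - oracle[i]).max() < 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_random_systems_match_brute_force(self, seed):
        n = 2 + seed % 11  # 2..12 sites
        model = random_energy_table(n, seed).to_model()
        ph = np.array([2.0, 4.5, 7.0, 9.5, 12.0])
        pops = populations_exact(model, ph)
        oracle = brute_force_populations(model, ph)
        for i in range(n):
            assert np.abs(pops.pops[i] - oracle[i]).max() < 1e-9

    def test_his_tautomers_split_evenly(self):
        model = make_energy_table(["imidazole"], [6.4]).to_model()
        ph = np.array([4.0, 6.4, 9.0])
        pops = populations_exact(model, ph)
        prot = protonated_fraction(pops, 0)
        nd1 = pops.pops[0][1]
        ne2 = pops.pops[0][0]
        assert np.allclose(nd1, ne2, atol=1e-12)
        assert np.allclose(nd1, (1 - prot) / 2, atol=1e-12)
        # degeneracy-corrected microscopic pK puts the midpoint at pk_mod
        mid = populations_exact(model, [6.4])
        assert protonated_fraction(mid, 0)[0] == pytest.approx(0.5, abs=1e-9)

    def test_state_space_cap(self):
        model = random_energy_table(8, 0).to_model()
        with pytest.raises(StateSpaceTooLarge, match="populations_mc"):
            populations_exact(model, [7.0], cap=100)

    def test_normalisation_and_permutation(self):
        model = random_energy_table(6, 3).to_model()
        ph = np.arange(0.0, 14.01, 0.5)
        pops = populations_exact(model, ph)
        for i in range(6):
            assert np.abs(pops.pops[i].sum(axis=0) - 1.0).max() < 1e-9
        order = [5, 3, 0, 1, 4, 2]
        permuted = populations_exact(model.permuted(order), ph)
        for new_i, old_i in enumerate(order):
            assert np.abs(permuted.pops[new_i] - pops.pops[old_i]).max() < 1e-9


class TestMonteCarlo:
    def test_matches_exact_within_three_sigma(self):
        ph = np.arange(0.0, 14.01, 0.5)
        for seed in (0, 4, 7):
            model = random_energy_table(6 + seed, seed).to_model()
            exact = populations_exact(model, ph)
            mc = populations_mc(model, ph, MCConfig(sweeps=3200, burn_in=320, seed=100 + seed))
            for i in range(model.n_sites):
                z = np.abs(mc.pops[i] - exact.pops[i]) / mc.stderr[i]
                assert z.max() < 3.0

    def test_zero_interaction_matches_analytic(self):
        model = make_energy_table(["carboxyl", "amino"], [4.4, 10.4]).to_model()
        ph = np.arange(0.0, 14.01, 1.0)
        mc = populations_mc(model, ph, MCConfig(sweeps=4000, burn_in=400, seed=2))
        for i, pk in enumerate((4.4, 10.4)):
            dev = np.abs(protonated_fraction(mc, i) - hh_curve(ph, pk))
            prot_mask = model.protonated_mask(i)
            sigma = mc.stderr[i][prot_mask].sum(axis=0)
            assert (dev <= 3 * sigma + 1e-12).all()

    def test_same_seed_bitwise_identical(self):
        model = random_energy_table(5, 9).to_model()
        ph = np.arange(2.0, 12.01, 1.0)
        cfg = MCConfig(sweeps=800, burn_in=100, seed=42)
        a = populations_mc(model, ph, cfg)
        b = populations_mc(model, ph, cfg)
        for i in range(5):
            assert np.array_equal(a.pops[i], b.pops[i])
            assert np.array_equal(a.stderr[i], b.stderr[i])

    def test_diagnostics_flag_poor_mixing(self):
        model = random_energy_table(4, 1).to_model()
        mc = populations_mc(model, [7.0], MCConfig(sweeps=400, burn_in=50, seed=0,
                                                   acceptance_floor=0.999))
        assert mc.diagnostics["poor_mixing"] is True


class TestDegreeOfDeprotonation:
    def test_isolated_acid_midpoint_and_limit(self):
        model = make_energy_table(["carboxyl"], [4.4]).to_model()
        pops = populations_exact(model, np.array([0.0, 4.4]))
        theta = degree_of_deprotonation(pops, 0)
        assert theta[0] < 1e-4  # fully protonated at the acidic end
        assert theta[1] == pytest.approx(0.5, abs=1e-12)

    def test_two_site_theta_matches_brute_force(self):
        model = make_energy_table(["carboxyl", "amino"], [4.0, 10.0],
                                  {(0, 1): -1.0}).to_model()
        ph = np.arange(1.0, 13.01, 0.5)
        pops = populations_exact(model, ph)
        oracle = brute_force_populations(model, ph)
        for i in range(2):
            prot = model.protonated_mask(i)
            theta_oracle = 1.0 - oracle[i][prot].sum(axis=0)
            assert np.abs(degree_of_deprotonation(pops, i) - theta_oracle).max() < 1e-9

    def test_single_site_monotone_nondecreasing(self):
        model = make_energy_table(["amino"], [10.4]).to_model()
        pops = populations_exact(model, np.arange(0.0, 14.01, 0.1))
        theta = degree_of_deprotonation(pops, 0)
        assert (np.diff(theta) >= -1e-15).all()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 7))
def test_populations_normalised_property(seed, n):
    """Σ_α p_iα(pH) = 1 for every site and pH, whatever the couplings."""
    model = random_energy_table(n, seed).to_model()
    pops = populations_exact(model, np.array([1.0, 7.0, 13.0]))
    for i in range(n):
        assert np.abs(pops.pops[i].sum(axis=0) - 1.0).max() < 1e-9
        assert (pops.pops[i] >= 0).all()
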