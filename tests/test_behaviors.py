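"""Cell-behaviour rule tests: Monod growth, contact inhibition, mitosis
geometry, state transitions, senescence induction/clearance statistics, ECM
production/degradation and removal rules."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from woundcpm.behaviors import (background_removal, clear_senescent,
                                contact_inhibition_gate, degrade_ecm,
                                maybe_divide, monod_growth_increment,
                                myofibroblast_fate, polarize_macrophage,
                                produce_ecm, removal_probability_per_sweep,
                                secondary_senescence, activate_fibroblast,
                                senescence_gate_open, timp_inhibition,
                                update_sasp_phase)
from woundcpm.fields import ChemFields
from woundcpm.params import (ECM, FIBROBLAST, MACROPHAGE, MECH_JUXTACRINE,
                             MECH_PARACRINE, MYOFIBROBLAST, SENESCENT,
                             PRE_SENESCENT, baseline_params)

from conftest import lattice_from_grid


class TestMonodGrowth:
    def test_zero_concentration_gives_zero_increment(self, params):
        for ct in (FIBROBLAST, MYOFIBROBLAST, MACROPHAGE):
            assert monod_growth_increment(ct, 0.0, params.behavior) == 0.0

    def test_half_saturation_identity(self, params):
        b = params.behavior
        assert monod_growth_increment(FIBROBLAST, b.pdgf0, b) == \
            pytest.approx(b.gmax_f / 2)
        assert monod_growth_increment(MACROPHAGE, b.csf0, b) == \
            pytest.approx(b.gmax_m / 2)

    def test_saturation_limit(self, params):
        b = params.behavior
        assert monod_growth_increment(MYOFIBROBLAST, 1e9, b) == \
            pytest.approx(b.gmax_mf, rel=1e-6)

    def test_monotone_in_concentration(self, params):
        b = params.behavior
        incs = [monod_growth_increment(FIBROBLAST, c, b)
                for c in np.linspace(0, 1, 50)]
        assert np.all(np.diff(incs) >= 0)

    def test_errors(self, params):
        with pytest.raises(ValueError):
            monod_growth_increment(FIBROBLAST, -1.0, params.behavior)
        with pytest.raises(ValueError):
            monod_growth_increment(ECM, 1.0, params.behavior)


class TestContactInhibition:
    def test_isolated_cell_grows(self, params):
        lat = lattice_from_grid(np.pad(np.ones((2, 2), int), 2),
                                {1: FIBROBLAST}, params.energy)
        assert contact_inhibition_gate(lat, 1, params.behavior)

    def test_fully_surrounded_cell_is_arrested(self, params):
        grid = np.full((4, 4), 2, int)
        grid[1:3, 1:3] = 1
        lat = lattice_from_grid(grid, {1: FIBROBLAST, 2: MYOFIBROBLAST},
                                params.energy)
        assert not contact_inhibition_gate(lat, 1, params.behavior)

    def test_boundary_case_rs_equal_tci_grows(self, params):
        # centre pixel with exactly half its boundary on Medium
        grid = np.array([[2, 0, 2], [0, 1, 0], [2, 0, 2]])
        lat = lattice_from_grid(grid, {1: FIBROBLAST, 2: MYOFIBROBLAST},
                                params.energy)
        b = dataclasses.replace(params.behavior, t_ci=0.5)
        assert contact_inhibition_gate(lat, 1, b)   # >= convention


class TestMitosis:
    def test_below_doubling_volume_no_division(self, params, rng):
        grid = np.pad(np.ones((3, 3), int), 2)
        lat = lattice_from_grid(grid, {1: FIBROBLAST}, params.energy)
        lat.vt0[1] = 5.0    # volume 9 < 10
        assert maybe_divide(lat, 1, rng) is None

    def test_square_cell_splits_into_equal_daughters(self, params, rng):
        grid = np.pad(np.ones((4, 4), int), 3)
        lat = lattice_from_grid(grid, {1: FIBROBLAST}, params.energy)
        lat.vt0[1] = 8.0    # volume 16 >= 16
        out = maybe_divide(lat, 1, rng)
        assert out is not None
        a, b = out
        assert int(lat.volume[a]) + int(lat.volume[b]) == 16
        assert abs(int(lat.volume[a]) - int(lat.volume[b])) <= 1
        assert lat.tvol[a] == lat.tvol[b] == 8.0
        assert lat.ctype[b] == FIBROBLAST

    def test_daughters_inherit_state_flags(self, params, rng):
        grid = np.pad(np.ones((4, 4), int), 3)
        lat = lattice_from_grid(grid, {1: FIBROBLAST}, params.energy)
        lat.vt0[1] = 8.0
        lat.activated[1] = True
        _, daughter = maybe_divide(lat, 1, rng)
        assert lat.activated[daughter]

    @pytest.mark.parametrize("side", [4, 5, 6])
    def test_symmetric_cells_split_within_one_pixel(self, params, side):
        rng = np.random.default_rng(99)
        ok = 0
        n = 300
        for _ in range(n):
            grid = np.pad(np.ones((side, side), int), 2)
            lat = lattice_from_grid(grid, {1: FIBROBLAST}, params.energy)
            lat.vt0[1] = side * side / 2.0
            a, b = maybe_divide(lat, 1, rng)
            if abs(int(lat.volume[a]) - int(lat.volume[b])) <= 1:
                ok += 1
        assert ok / n >= 0.99


class TestStateTransitions:
    def test_polarization_thresholds(self, params):
        b = params.behavior
        assert not polarize_macrophage(0.0, b)             # M2
        assert not polarize_macrophage(b.inf_thr, b)       # strict inequality
        assert polarize_macrophage(2 * b.inf_thr, b)       # M1

    def test_fibroblast_activation_and_persistence(self, params):
        b = params.behavior
        assert not activate_fibroblast(False, 0.0, b)
        assert activate_fibroblast(False, b.pdgf_f * 2, b)
        assert activate_fibroblast(True, 0.0, b)           # persistent

    def test_sasp_phase_boundaries(self, params):
        t_nis = params.behavior.t_nis_days * params.units.mcs_per_day
        assert update_sasp_phase(0.0, SENESCENT, params) == "fibrogenic"
        assert update_sasp_phase(t_nis, SENESCENT, params) == "fibrolytic"
        assert update_sasp_phase(0.0, PRE_SENESCENT, params) == "fibrolytic"
        with pytest.raises(ValueError):
            update_sasp_phase(0.0, FIBROBLAST, params)

    def test_senescence_time_gate_readings(self, params):
        b = params.behavior
        t = b.t_sen_mcs
        assert not senescence_gate_open(t - 1, b)
        assert senescence_gate_open(t, b)
        flipped = dataclasses.replace(b, t_sen_mode="closed_before")
        assert senescence_gate_open(t - 1, flipped)
        assert not senescence_gate_open(t, flipped)


class TestMyofibroblastFate:
    def test_tension_release_apoptosis(self, params, rng):
        b = params.behavior
        assert myofibroblast_fate(0, 0.0, b.t_sen_mcs + 1, b, rng) == \
            "apoptosis"

    def test_inflammatory_apoptosis(self, params, rng):
        b = params.behavior
        high_ecm = int(b.ecm_thr) + 5
        assert myofibroblast_fate(high_ecm, b.inf_thr * 2,
                                  b.t_sen_mcs + 1, b, rng) == "apoptosis"

    def test_survives_with_zero_senescence_probability(self, params, rng):
        b = dataclasses.replace(params.behavior, p_snc=0.0)
        high_ecm = int(b.ecm_thr) + 5
        for _ in range(200):
            assert myofibroblast_fate(high_ecm, 0.0, b.t_sen_mcs + 1,
                                      b, rng) == "survive"

    def test_gate_closed_blocks_primary_senescence(self, params, rng):
        b = dataclasses.replace(params.behavior, p_snc=1.0)
        high_ecm = int(b.ecm_thr) + 5
        assert myofibroblast_fate(high_ecm, 0.0, 0.0, b, rng) == "survive"

    def test_senescence_fraction_matches_p_snc(self, params):
        """10^4 eligible draws senesce at P_SNC = 0.15 within 3 s.e."""
        rng = np.random.default_rng(2024)
        b = params.behavior
        assert b.p_snc == 0.15
        n = 10_000
        high_ecm = int(b.ecm_thr) + 5
        k = sum(myofibroblast_fate(high_ecm, 0.0, b.t_sen_mcs + 1, b, rng)
                == "senesce" for _ in range(n))
        se = np.sqrt(b.p_snc * (1 - b.p_snc) / n)
        assert k / n == pytest.approx(b.p_snc, abs=3 * se)


class TestSecondarySenescence:
    def test_rules(self, params):
        b = params.behavior
        assert secondary_senescence(0, 0, 1.0, 1.0, b) is None
        assert secondary_senescence(1, 0, b.snc_thr * 2, 0.0, b) == \
            MECH_JUXTACRINE
        assert secondary_senescence(1, 0, b.snc_thr, 0.0, b) is None
        assert secondary_senescence(0, 1, 0.0, b.inf_thr * 2, b) == \
            MECH_PARACRINE
        assert secondary_senescence(0, 1, 0.0, b.inf_thr, b) is None
        # juxtacrine takes priority when both routes are open
        assert secondary_senescence(1, 1, b.snc_thr * 2, b.inf_thr * 2, b) \
            == MECH_JUXTACRINE


class TestSenescentClearance:
    def test_no_trigger_survives(self, params, rng):
        assert not clear_senescent(0, 0.0, params.behavior, rng)

    def test_certain_clearance_on_contact(self, params, rng):
        b = dataclasses.replace(params.behavior, p_clear=1.0)
        assert clear_senescent(1, 0.0, b, rng)

    def test_equal_chance_of_both_triggers(self, params):
        """Macrophage-contact and inflammation-mediated removal are
        indistinguishable in rate (two-proportion z-test, alpha = 0.01)."""
        rng = np.random.default_rng(77)
        b = dataclasses.replace(params.behavior, p_clear=0.5)
        n = 10_000
        k1 = sum(clear_senescent(1, 0.0, b, rng) for _ in range(n))
        k2 = sum(clear_senescent(0, b.inf_thr * 2, b, rng) for _ in range(n))
        p1, p2 = k1 / n, k2 / n
        pool = (k1 + k2) / (2 * n)
        z = (p1 - p2) / np.sqrt(2 * pool * (1 - pool) / n)
        assert abs(z) < 2.576


class TestTimpInhibition:
    def _setup(self, params, mmp_value):
        grid = np.pad(np.ones((2, 2), int), 2)
        lat = lattice_from_grid(grid, {1: MYOFIBROBLAST}, params.energy)
        chem = ChemFields(8, 8)
        chem.mmp[:] = mmp_value
        return lat, chem

    def test_zero_stays_clamped(self, params):
        lat, chem = self._setup(params, 0.0)
        timp_inhibition(lat, chem, 1, params.behavior)
        assert np.all(chem.mmp >= 0.0)

    def test_exact_threshold_reaches_zero(self, params):
        b = params.behavior
        lat, chem = self._setup(params, b.mmp_thr)
        timp_inhibition(lat, chem, 1, b)
        r, c = 2, 2  # COM pixel of the 2x2 block at (2..3, 2..3) rounds to 3
        assert chem.mmp.min() == 0.0

    def test_subtraction_rule(self, params):
        b = params.behavior
        lat, chem = self._setup(params, 3 * b.mmp_thr)
        timp_inhibition(lat, chem, 1, b)
        assert chem.mmp.min() == pytest.approx(2 * b.mmp_thr)
        assert (chem.mmp == 3 * b.mmp_thr).sum() == 63


class TestEcmProduction:
    def _fib_lattice(self, params):
        grid = np.pad(np.ones((2, 2), int), 3)
        lat = lattice_from_grid(grid, {1: FIBROBLAST}, params.energy)
        lat.activated[1] = True
        return lat

    def test_below_pdgf_gate_produces_nothing(self, params, rng):
        lat = self._fib_lattice(params)
        assert produce_ecm(lat, 1, 0.0, params, rng) == []

    def test_fibroblast_produces_exactly_ecm_fib(self, params, rng):
        lat = self._fib_lattice(params)
        b = params.behavior
        new = produce_ecm(lat, 1, b.pdgf_f * 2, params, rng)
        assert len(new) == b.ecm_fib
        for cid in new:
            assert lat.ctype[cid] == ECM
            assert lat.volume[cid] == 1

    def test_myofibroblast_produces_double(self, params, rng):
        grid = np.pad(np.ones((2, 2), int), 3)
        lat = lattice_from_grid(grid, {1: MYOFIBROBLAST}, params.energy)
        b = params.behavior
        new = produce_ecm(lat, 1, b.pdgf_f * 2, params, rng)
        assert len(new) == b.ecm_myof == 2 * b.ecm_fib

    def test_no_adjacent_medium_produces_nothing(self, params, rng):
        grid = np.full((4, 4), 2, int)
        grid[1:3, 1:3] = 1
        lat = lattice_from_grid(grid, {1: MYOFIBROBLAST, 2: FIBROBLAST},
                                params.energy)
        assert produce_ecm(lat, 1, 1.0, params, rng) == []


class TestEcmDegradation:
    def _ecm_lattice(self, params, n=10, size=12, seed=5):
        rng = np.random.default_rng(seed)
        grid = np.zeros((size, size), int)
        types = {}
        cid = 1
        while cid <= n:
            r, c = rng.integers(size, size=2)
            if grid[r, c] == 0:
                grid[r, c] = cid
                types[cid] = ECM
                cid += 1
        return lattice_from_grid(grid, types, params.energy)

    def test_zero_mmp_removes_nothing(self, params):
        lat = self._ecm_lattice(params)
        chem = ChemFields(12, 12)
        assert degrade_ecm(lat, chem, params.behavior) == 0
        assert len(lat.alive_ids()) == 10

    def test_uniform_high_mmp_removes_all(self, params):
        lat = self._ecm_lattice(params)
        chem = ChemFields(12, 12)
        chem.mmp[:] = 2 * params.behavior.mmp_thr
        assert degrade_ecm(lat, chem, params.behavior) == 10
        assert len(lat.alive_ids()) == 0

    def test_mixed_field_matches_brute_force_scan(self, params):
        lat = self._ecm_lattice(params, n=20, size=16)
        rng = np.random.default_rng(8)
        chem = ChemFields(16, 16)
        chem.mmp[:] = rng.uniform(0, 2 * params.behavior.mmp_thr,
                                  size=(16, 16))
        expect = set()
        for cid in lat.alive_ids():
            r, c = lat.pixels_of(cid)[0]
            if chem.mmp[r, c] > params.behavior.mmp_thr:
                expect.add(int(cid))
        removed = degrade_ecm(lat, chem, params.behavior)
        assert removed == len(expect)
        assert set(lat.alive_ids()) == \
            {int(i) for i in range(1, 21)} - expect


class TestBackgroundRemoval:
    def test_no_removals_when_mu_zero_and_csf1_high(self, params, rng):
        grid = np.pad(np.ones((2, 2), int), 2)
        lat = lattice_from_grid(grid, {1: MACROPHAGE}, params.energy)
        chem = ChemFields(8, 8)
        chem.csf1[:] = params.behavior.csf1_thr * 10
        p = dataclasses.replace(
            params, behavior=dataclasses.replace(params.behavior,
                                                 mu_per_day=0.0))
        assert background_removal(lat, chem, p, rng) == []

    def test_csf1_withdrawal_removes_all_macrophages(self, params, rng):
        grid = np.zeros((12, 12), int)
        grid[1:3, 1:3] = 1
        grid[5:7, 5:7] = 2
        lat = lattice_from_grid(grid, {1: MACROPHAGE, 2: MACROPHAGE},
                                params.energy)
        chem = ChemFields(12, 12)   # CSF1 == 0 < threshold everywhere
        removed = background_removal(lat, chem, params, rng)
        assert sorted(removed) == [1, 2]

    def test_removal_fraction_matches_rate(self, params):
        """Bernoulli check: with p = 1 - exp(-mu dt) ~ 0.1, the removal
        fraction over ~2500 cell-sweeps is p within 3 s.e."""
        rng = np.random.default_rng(11)
        side, cs = 100, 2
        grid = np.zeros((side, side), int)
        types = {}
        cid = 1
        for r in range(0, side, cs * 2):
            for c in range(0, side, cs * 2):
                grid[r:r + cs, c:c + cs] = cid
                types[cid] = MACROPHAGE
                cid += 1
        lat = lattice_from_grid(grid, types, params.energy)
        n = cid - 1
        chem = ChemFields(side, side)
        chem.csf1[:] = params.behavior.csf1_thr * 10
        mu = 0.1 * params.units.mcs_per_day / params.behavior.sweep_period_mcs
        p = dataclasses.replace(
            params, behavior=dataclasses.replace(params.behavior,
                                                 mu_per_day=mu))
        p_sweep = removal_probability_per_sweep(p.behavior,
                                                p.units.mcs_per_day)
        assert p_sweep == pytest.approx(1 - np.exp(-0.1))
        removed = background_removal(lat, chem, p, rng)
        frac = len(removed) / n
        se = np.sqrt(p_sweep * (1 - p_sweep) / n)
        assert frac == pytest.approx(p_sweep, abs=3 * se)
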