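import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect, minimize_scalar

import polycg.force_field as ff
from polycg.force_field import (
    EnergyEvaluator,
    ForceFieldError,
    ForceFieldParams,
    System,
    classify_pair,
    dielectric,
    kappa_for_salt,
    mix_eps,
    paper_2024,
    phi_cp,
    phi_elec,
    phi_hp,
    phi_network,
    total_energy_forces,
)
from polycg.model_builder import build_polypr

from conftest import random_bead_model

PARAMS = ForceFieldParams()


class TestParams:
    def test_paper_preset_constants(self):
        p = paper_2024()
        assert (p.eps_hp, p.eps_rep, p.sigma) == (13.0, 10.0, 0.6)
        assert (p.dielectric_s, p.dielectric_z) == (80.0, 0.25)
        assert (p.k_network, p.rm_cp) == (8000.0, 0.45)
        assert p.eps_cp == {
            "RF": 4.30, "RY": 5.0, "RW": 6.7, "KF": 1.79, "KY": 3.13, "KW": 4.26
        }

    def test_salt_to_kappa_mapping(self):
        assert kappa_for_salt(100) == 1.0
        assert kappa_for_salt(200) == 1.5
        with pytest.raises(ForceFieldError):
            kappa_for_salt(150)

    def test_invalid_params_rejected(self):
        with pytest.raises(ForceFieldError):
            ForceFieldParams(kappa=0.0)
        with pytest.raises(ForceFieldError):
            ForceFieldParams(eps_cp={"RF": 1.0})


class TestPhiHP:
    def test_excluded_volume_vanishes_at_sigma(self):
        assert phi_hp(0.6, eps_ij=10.0) == pytest.approx(0.0, abs=1e-14)
        # and stays zero beyond sigma (eps_ij == eps_rep kills the outer branch)
        assert phi_hp(1.0, eps_ij=10.0) == pytest.approx(0.0, abs=1e-14)
        assert phi_hp(0.5, eps_ij=10.0) > 0

    def test_branch_continuity_at_sigma(self):
        for eps_ij in (0.0, 5.0, 10.0, 13.0):
            inner = PARAMS.eps_rep - eps_ij * (4.0 / 3.0 - 1.0 / 3.0)
            outer = PARAMS.eps_rep - eps_ij
            assert inner == pytest.approx(outer, abs=1e-12)
            assert phi_hp(PARAMS.sigma, eps_ij=eps_ij) == pytest.approx(
                outer, abs=1e-12
            )

    def test_derivative_continuity_at_sigma(self):
        for eps_ij in (3.0, 10.0, 13.0):
            lo = ff._phi_hp_d(PARAMS.sigma * (1 - 1e-12), eps_ij=eps_ij)[1]
            hi = ff._phi_hp_d(PARAMS.sigma * (1 + 1e-12), eps_ij=eps_ij)[1]
            # analytic limit from both sides: -8 (eps_rep - eps_ij) / sigma
            expected = -8.0 * (PARAMS.eps_rep - eps_ij) / PARAMS.sigma
            assert lo == pytest.approx(expected, abs=1e-6)
            assert hi == pytest.approx(expected, abs=1e-6)

    def test_minimum_matches_grid_oracle(self):
        # eps_i = eps_j = 1 -> eps_ij = eps_hp = 13 > eps_rep: attractive well
        eps_ij = float(mix_eps(1.0, 1.0))
        assert eps_ij == pytest.approx(13.0)
        grid = np.linspace(0.3, 2.0, 400_001)
        vals = phi_hp(grid, eps_ij=eps_ij)
        r_star = grid[np.argmin(vals)]
        res = minimize_scalar(
            lambda r: float(phi_hp(r, eps_ij=eps_ij)), bounds=(0.3, 2.0),
            method="bounded",
        )
        assert res.x == pytest.approx(r_star, abs=1e-5)
        # closed form: the inner branch minimizes at sigma*sqrt(eps_rep/eps_ij)
        assert res.x == pytest.approx(0.6 * np.sqrt(10.0 / 13.0), abs=1e-6)

    def test_r_nonpositive_is_error(self):
        with pytest.raises(ForceFieldError):
            phi_hp(0.0, eps_ij=10.0)

    @given(
        st.floats(min_value=0.05, max_value=1.0),
        st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_in_bead_exchange(self, ei, ej):
        r = 0.8
        assert phi_hp(r, ei, ej) == phi_hp(r, ej, ei)


class TestDielectric:
    def test_limits(self):
        assert dielectric(1e-8) == pytest.approx(0.0, abs=1e-12)
        assert dielectric(50.0) == pytest.approx(80.0, rel=1e-3)

    def test_monotone_increasing(self):
        # strictly increasing until float saturation at the bulk value
        r = np.linspace(1e-4, 5.0, 5000)
        eps = dielectric(r)
        assert (np.diff(eps) > 0).all()
        long_range = dielectric(np.linspace(5.0, 50.0, 100))
        assert (np.diff(long_range) >= 0).all()
        assert (eps >= 0).all() and (eps <= 80.0).all()

    def test_derivative_matches_numerical(self):
        from polycg.force_field import _dielectric_d

        for r in (0.05, 0.3, 1.0, 3.0):
            _, d = _dielectric_d(r)
            h = 1e-7
            num = (dielectric(r + h) - dielectric(r - h)) / (2 * h)
            assert d == pytest.approx(num, rel=1e-5)


class TestPhiElec:
    def test_zero_charge_gives_zero(self):
        for r in (0.1, 1.0, 10.0):
            assert phi_elec(r, 0.0, 1.0) == 0.0

    def test_higher_salt_screens_more(self):
        lo = phi_elec(1.0, 1.0, 1.0, kappa=1.0)
        hi = phi_elec(1.0, 1.0, 1.0, kappa=1.5)
        assert 0 < hi < lo

    def test_symmetry_and_sign(self):
        assert phi_elec(0.9, 1.0, -1.0) == phi_elec(0.9, -1.0, 1.0) < 0

    def test_large_r_approaches_debye_coulomb(self):
        # with eps_r -> 80 the energy approaches the plain screened Coulomb law
        r = 20.0
        expected = 138.935458 / (80.0 * r) * np.exp(-r)
        assert phi_elec(r, 1.0, 1.0) == pytest.approx(expected, rel=1e-3)


class TestPhiCP:
    @pytest.mark.parametrize(
        "key,depth",
        [("RF", 4.30), ("RY", 5.0), ("RW", 6.7), ("KF", 1.79), ("KY", 3.13), ("KW", 4.26)],
    )
    def test_minimum_location_and_depth(self, key, depth):
        res = minimize_scalar(
            lambda r: float(phi_cp(r, key)), bounds=(0.1, 3.0), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.x == pytest.approx(0.45, abs=1e-6)
        assert res.fun == pytest.approx(-depth, rel=1e-9)

    def test_unknown_pair_key(self):
        with pytest.raises(ForceFieldError):
            phi_cp(0.5, "RR")

    def test_decays_to_zero(self):
        assert phi_cp(50.0, "RF") == pytest.approx(0.0, abs=1e-9)

    def test_zero_crossing_matches_bisection_oracle(self):
        root = bisect(lambda r: float(phi_cp(r, "RF")), 0.2, 0.449, xtol=1e-12)
        # analytic root of 3u^8 = 4u^6: r = rm * sqrt(3)/2
        assert root == pytest.approx(0.45 * np.sqrt(3) / 2, abs=1e-9)
        assert phi_cp(root * 0.999, "RF") > 0 > phi_cp(root * 1.001, "RF")


class TestPhiNetwork:
    def test_zero_at_rest_length(self):
        assert phi_network(0.5, 0.5) == 0.0

    def test_direct_arithmetic(self):
        assert phi_network(0.51, 0.5) == pytest.approx(8000 * 1e-4)

    def test_symmetric_about_rest_length(self):
        for delta in (0.01, 0.1, 0.3):
            assert phi_network(0.5 + delta, 0.5) == pytest.approx(
                phi_network(0.5 - delta, 0.5)
            )


@pytest.fixture(scope="module")
def system(charged_toy):
    model, _ = charged_toy
    return System([model, build_polypr(5)], roles=["component", "polypr"])


class TestClassifyPair:
    def test_polypr_arginine_vs_aromatic_is_cation_pi(self, system):
        comp_f = int(np.flatnonzero(system.residue_names[:80] == "F")[0])
        pep_r = 80 + 1  # second polyPR bead is R
        assert system.residue_names[pep_r] == "R"
        rule = classify_pair(system, pep_r, comp_f)
        assert rule.nonbonded == "CATION_PI"
        assert classify_pair(system, comp_f, pep_r) == rule  # symmetric

    def test_polypr_proline_vs_component_is_excluded(self, system):
        pep_p = 80  # first polyPR bead is P
        rule = classify_pair(system, pep_p, 0)
        assert rule.nonbonded == "EXCLUDED"

    def test_bonded_structured_pair_is_network_only(self, system):
        model = system.models[0]
        i, j = (int(x) for x in model.bonds[0])
        rule = classify_pair(system, i, j)
        assert rule.bonded == "NETWORK"
        assert rule.nonbonded is None

    def test_polypr_backbone_neighbors_bonded(self, system):
        rule = classify_pair(system, 80, 81)
        assert rule.bonded == "BACKBONE"

    def test_intra_polypr_nonneighbors_are_hp(self, system):
        rule = classify_pair(system, 80, 83)
        assert rule.nonbonded == "HP"

    def test_invalid_pair(self, system):
        with pytest.raises(ForceFieldError):
            classify_pair(system, 0, 0)


class TestEnergyForces:
    def test_distant_neutral_beads_zero(self):
        # two neutral non-aromatic molecules far beyond the cutoff
        from polycg.model import CGModel
        from polycg.model_builder import assign_bead_properties

        mols = [
            assign_bead_properties(
                CGModel(residue_names=["G"], positions=[[4.0 * k, 0.0, 0.0]])
            )
            for k in range(2)
        ]
        e, f = total_energy_forces(mols, box=None)
        assert e == 0.0
        np.testing.assert_array_equal(f, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_forces_match_numerical_gradient(self, seed):
        model = random_bead_model(20, seed=seed)
        system = System([model])
        ev = EnergyEvaluator(system, ForceFieldParams(cutoff=None))
        pos = system.positions
        _, forces = ev.energy_forces(pos)
        h = 1e-6
        num = np.zeros_like(forces)
        for i in range(len(pos)):
            for d in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, d] += h
                pm[i, d] -= h
                num[i, d] = -(
                    ev.energy_forces(pp)[0] - ev.energy_forces(pm)[0]
                ) / (2 * h)
        rel = np.abs(forces - num).max() / np.abs(forces).max()
        assert rel < 1e-5

    def test_forces_with_cutoff_and_pbc(self):
        model = random_bead_model(15, seed=42, spread=3.0)
        system = System([model])
        ev = EnergyEvaluator(system, ForceFieldParams(cutoff=2.5))
        box = 8.0
        pos = system.positions
        _, forces = ev.energy_forces(pos, box)
        h = 1e-6
        num = np.zeros_like(forces)
        for i in range(len(pos)):
            for d in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, d] += h
                pm[i, d] -= h
                num[i, d] = -(
                    ev.energy_forces(pp, box)[0] - ev.energy_forces(pm, box)[0]
                ) / (2 * h)
        assert np.abs(forces - num).max() / np.abs(forces).max() < 1e-4

    def test_numba_and_numpy_routes_agree(self, charged_toy):
        model, _ = charged_toy
        system = System([model, build_polypr(5)])
        ev = EnergyEvaluator(system)
        e1, f1 = ev.energy_forces(system.positions, 12.0, backend="numba")
        e2, f2 = ev.energy_forces(system.positions, 12.0, backend="numpy")
        assert e1 == pytest.approx(e2, rel=1e-12)
        np.testing.assert_allclose(f1, f2, rtol=1e-10, atol=1e-10)

    def test_newtons_third_law(self):
        model = random_bead_model(30, seed=7)
        e, f = total_energy_forces([model], box=6.0)
        assert np.abs(f.sum(axis=0)).max() < 1e-9 * np.abs(f).max()

    def test_translation_invariance_across_pbc(self):
        model = random_bead_model(12, seed=3)
        system = System([model])
        ev = EnergyEvaluator(system)
        box = 7.0
        e1, f1 = ev.energy_forces(system.positions, box)
        e2, f2 = ev.energy_forces(system.positions + np.array([box, -2 * box, 5.3]), box)
        assert e2 == pytest.approx(e1, rel=1e-9)
        np.testing.assert_allclose(f1, f2, rtol=1e-7, atol=1e-9)

    def test_overlap_is_error(self):
        model = random_bead_model(3, seed=1)
        model.positions[1] = model.positions[0]
        with pytest.raises(ForceFieldError, match="overlap"):
            total_energy_forces([model])

    def test_higher_salt_lowers_like_charge_energy(self):
        # pure like-charge configuration: all-R disordered chain fragments
        from polycg.model import CGModel
        from polycg.model_builder import assign_bead_properties

        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 3, size=(8, 3))
        model = assign_bead_properties(
            CGModel(
                residue_names=["R"] * 8,
                positions=pos,
                disorder_mask=np.ones(8, dtype=bool),
            )
        )
        e100, _ = total_energy_forces(
            [model], params=ForceFieldParams(kappa=1.0, cutoff=None)
        )
        e200, _ = total_energy_forces(
            [model], params=ForceFieldParams(kappa=1.5, cutoff=None)
        )
        assert e200 <= e100
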