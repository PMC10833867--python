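"""Dielectric sigmoids, Coulomb terms, membrane energy terms, and the
weighted combination."""

import numpy as np
import pytest

from lipidfield.energy import (
    DielectricParams,
    MembraneScorer,
    TRANSFER_ONLY_WEIGHTS,
    WeightSet,
    coulomb_pair,
    excess_coulomb_pair,
    fit_weights,
    hydration_state,
    lipid_field_energy,
    mixed_dielectric,
    sigmoidal_dielectric,
    total_score,
    transfer_energy,
)
from lipidfield.fixtures import make_profile_params, synthetic_ddg_table
from lipidfield.frame import HydrationState
from lipidfield.helix import build_ideal_helix
from lipidfield.orientation import apply_orientation
from lipidfield.transfer import AtomScale

PARAMS = DielectricParams()


class TestSigmoidalDielectric:
    @pytest.mark.parametrize("core,surf", [(6.0, 80.0), (3.0, 10.0)])
    def test_contact_and_asymptote(self, core, surf):
        assert sigmoidal_dielectric(0.0, core, surf) == pytest.approx(core)
        assert sigmoidal_dielectric(50.0, core, surf) == pytest.approx(surf, abs=1e-3)

    def test_monotone_nondecreasing(self):
        r = np.linspace(0, 30, 400)
        eps = sigmoidal_dielectric(r, 6.0, 80.0)
        assert np.all(np.diff(eps) >= -1e-12)

    def test_equal_endpoints_constant(self):
        r = np.linspace(0, 20, 50)
        assert np.allclose(sigmoidal_dielectric(r, 7.0, 7.0), 7.0)


class TestMixedDielectric:
    def test_endpoints_reproduce_pure_environments(self):
        r = 3.3
        sol = sigmoidal_dielectric(r, PARAMS.eps_core_sol, PARAMS.eps_surf_sol,
                                   PARAMS.sigmoid_steepness)
        mem = sigmoidal_dielectric(r, PARAMS.eps_core_mem, PARAMS.eps_surf_mem,
                                   PARAMS.sigmoid_steepness)
        assert mixed_dielectric(r, 1.0) == pytest.approx(sol)
        assert mixed_dielectric(r, 0.0) == pytest.approx(mem)
        assert mixed_dielectric(r, 0.5) == pytest.approx(0.5 * (sol + mem))

    def test_membrane_dielectric_below_solution_everywhere(self):
        r = np.linspace(0.1, 10, 200)
        sol = sigmoidal_dielectric(r, 6.0, 80.0)
        mem = sigmoidal_dielectric(r, 3.0, 10.0)
        assert np.all(mem < sol)


class TestCoulombPair:
    def test_zero_at_cutoff(self):
        assert coulomb_pair(1.0, -1.0, 5.5, 1.0) == 0.0
        assert coulomb_pair(1.0, -1.0, 7.0, 1.0) == 0.0

    def test_hand_arithmetic_opposite_charges(self):
        # −322·(1/2.75 − 1/5.5) = −58.5454…
        expected = -322.0 * (1 / 2.75 - 1 / 5.5)
        assert coulomb_pair(1.0, -1.0, 2.75, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(-58.5454, abs=1e-3)

    def test_like_charges_positive_inside_cutoff(self):
        assert coulomb_pair(0.5, 0.5, 3.0, 4.0) > 0

    def test_contact_distance_rejected(self):
        with pytest.raises(ValueError):
            coulomb_pair(1.0, 1.0, 0.0, 1.0)


class TestExcessCoulombPair:
    def test_vanishes_in_water(self):
        r = np.linspace(0.5, 6.0, 40)
        assert np.allclose(excess_coulomb_pair(1.0, -1.0, r, 1.0), 0.0)

    def test_membrane_core_formula(self):
        r = 2.0
        mem = sigmoidal_dielectric(r, 3.0, 10.0, 1.2)
        sol = sigmoidal_dielectric(r, 6.0, 80.0, 1.2)
        expected = 322.0 * (1 / r - 1 / 5.5) * (1 / mem - 1 / sol) * (-1.0)
        assert excess_coulomb_pair(1.0, -1.0, r, 0.0) == pytest.approx(expected)

    def test_sign_structure_over_grid(self):
        r = np.linspace(0.3, 5.4, 60)
        for f in (0.0, 0.3, 0.9):
            assert np.all(excess_coulomb_pair(1.0, -1.0, r, f) <= 0)
            assert np.all(excess_coulomb_pair(1.0, 1.0, r, f) >= 0)


class TestLipidFieldEnergy:
    def test_zero_charges_zero_energy(self, walp23, profile_params):
        st = walp23.with_coords(walp23.coords, walp23.transform)
        st.charges = np.zeros_like(st.charges)
        assert lipid_field_energy(st, profile_params).sum() == 0.0

    def test_aqueous_placement_zero(self, walp23, profile_params):
        far = apply_orientation(walp23, 80.0, 0.0, 0.0)
        assert lipid_field_energy(far, profile_params).sum() == 0.0

    def test_single_atom_equals_charge_times_potential(self, profile_params):
        st = build_ideal_helix("AAA")
        st = apply_orientation(st, 5.0, 0.0, 0.0)
        per_atom = st.charges * profile_params.evaluate(st.coords[:, 2])
        total = lipid_field_energy(st, profile_params).sum()
        assert total == pytest.approx(per_atom.sum())


class TestTransferEnergy:
    def test_fully_hydrated_contributes_nothing(self, walp23, atom_scale):
        hyd = HydrationState(np.ones(walp23.n_atoms), np.zeros(walp23.n_atoms))
        assert transfer_energy(walp23, atom_scale, hyd).sum() == 0.0

    def test_fully_buried_sums_scale_values(self, walp23, atom_scale):
        hyd = HydrationState(np.zeros(walp23.n_atoms), np.zeros(walp23.n_atoms))
        expected = sum(atom_scale[t] for t in walp23.atom_types)
        assert transfer_energy(walp23, atom_scale, hyd).sum() == pytest.approx(expected)

    def test_partial_hydration_hand_value(self):
        st = build_ideal_helix("GGG")
        scale = AtomScale({t: -2.0 for t in set(st.atom_types)})
        hyd = HydrationState(np.full(st.n_atoms, 0.25), np.zeros(st.n_atoms))
        expected = -2.0 * 0.75 * st.n_atoms
        assert transfer_energy(st, scale, hyd).sum() == pytest.approx(expected)

    def test_unknown_type_rejected(self, walp23):
        with pytest.raises(KeyError):
            transfer_energy(walp23, AtomScale({"CH3": 1.0}),
                            hydration_state(walp23))


class TestTotalScore:
    def test_transfer_only_weights_ignore_lipid_profile(self, walp23, atom_scale):
        placed = apply_orientation(walp23, 0.0, 10.0, 0.0)
        profiles = [make_profile_params(psi_core=c) for c in (2.0, 20.0)]
        totals = [
            total_score(placed, TRANSFER_ONLY_WEIGHTS, p, atom_scale).total()
            for p in profiles
        ]
        assert totals[0] == pytest.approx(totals[1])
        bd = total_score(placed, TRANSFER_ONLY_WEIGHTS, profiles[0], atom_scale)
        half_transfer = 0.5 * bd.total("transfer")
        assert bd.total("combined") == pytest.approx(half_transfer)

    def test_aqueous_structure_scores_zero(self, walp23, atom_scale,
                                           profile_params):
        far = apply_orientation(walp23, 90.0, 0.0, 0.0)
        bd = total_score(far, WeightSet(), profile_params, atom_scale)
        assert bd.total("transfer") == pytest.approx(0.0, abs=1e-6)
        assert bd.total("lipid_field") == 0.0
        assert bd.total("dielec_excess") == pytest.approx(0.0, abs=1e-6)

    def test_weights_scale_linearly(self, walp23, atom_scale, profile_params):
        placed = apply_orientation(walp23, 3.0, 20.0, 40.0)
        w1 = WeightSet(0.4, 0.05, 0.004)
        w2 = WeightSet(0.8, 0.10, 0.008)
        e1 = total_score(placed, w1, profile_params, atom_scale).total()
        e2 = total_score(placed, w2, profile_params, atom_scale).total()
        assert e2 == pytest.approx(2.0 * e1)

    def test_per_residue_ledger_sums_to_totals(self, walp23, atom_scale,
                                               profile_params):
        placed = apply_orientation(walp23, 2.0, 30.0, 60.0)
        bd = total_score(placed, WeightSet(), profile_params, atom_scale)
        for term in ("transfer", "lipid_field", "dielec_excess", "combined"):
            assert getattr(bd, term).shape == (walp23.n_residues,)
        assert bd.combined.sum() == pytest.approx(bd.total("combined"))

    def test_baseline_scorer_injected(self, walp23, atom_scale, profile_params):
        bd = total_score(walp23, WeightSet(), profile_params, atom_scale,
                         baseline_scorer=lambda s: 42.0)
        assert bd.total("baseline") == pytest.approx(42.0)

    def test_scorer_cache_matches_fresh_computation(self, walp23, atom_scale,
                                                    profile_params):
        scorer = MembraneScorer(profile_params, atom_scale, WeightSet())
        for d, t, r in [(0, 0, 0), (5, 30, 45), (-12, 120, 200)]:
            placed = apply_orientation(walp23, d, t, r)
            cached = scorer(placed)
            fresh = total_score(placed, WeightSet(), profile_params,
                                atom_scale).total()
            assert cached == pytest.approx(fresh)

    def test_depth_batch_matches_per_structure_scoring(self, walp23,
                                                       atom_scale,
                                                       profile_params):
        from lipidfield.structure import rotation_zyz

        scorer = MembraneScorer(profile_params, atom_scale, WeightSet())
        depths = np.array([-20.0, 0.0, 12.0, 70.0])
        tilt, rot = 35.0, 110.0
        rotated = walp23.canonical_coords() @ rotation_zyz(tilt, rot).T
        batch = scorer.depth_batch(walp23, rotated, depths)
        singles = [scorer(apply_orientation(walp23, d, tilt, rot))
                   for d in depths]
        assert np.allclose(batch, singles)


class TestFitWeights:
    def test_recovers_generating_weights_by_correlation(self):
        terms, ddg = synthetic_ddg_table(n_points=19, seed=0)
        ws = fit_weights(terms, ddg, n_starts=8, seed=0)
        pred = terms @ ws.as_array()
        assert np.corrcoef(pred, ddg)[0, 1] >= 0.999

    def test_collapsed_bounds_return_that_point(self):
        terms, ddg = synthetic_ddg_table(seed=1)
        ws = fit_weights(terms, ddg, bounds=(0.3, 0.3))
        assert ws.as_array() == pytest.approx([0.3, 0.3, 0.3])

    def test_degenerate_inputs_rejected(self):
        terms, ddg = synthetic_ddg_table(seed=2)
        with pytest.raises(ValueError, match="constant"):
            fit_weights(terms, np.ones_like(ddg))
        with pytest.raises(ValueError, match="zero"):
            fit_weights(np.zeros_like(terms), ddg)
        with pytest.raises(ValueError, match="4"):
            fit_weights(terms[:3], ddg[:3])

    def test_weight_bounds_enforced(self):
        with pytest.raises(ValueError):
            WeightSet(1.5, 0.0, 0.0)
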