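"""Sweep placement, clash detection, cross distances, feasibility and
registration shifts, each checked against independent brute-force
oracles on synthetic fixtures."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ssbond.geom import bond_angle, dihedral
from ssbond.scan import (GridMismatchError, RigidTransform, SweepParams,
                         clash_scan, feasibility, min_cross_distances,
                         place_sulfur, registration_shift_scan, scan_pair,
                         sweep_positions)
from ssbond.structure_io import CysteineSite, StructureModel, find_cysteines
from ssbond.synth import (DimerSpec, add_clash_probe, dimer_sites,
                          engineered_separation, make_c2_dimer,
                          make_ideal_cysteine)

from conftest import (oracle_clash_mask, oracle_feasible_pairs,
                      oracle_min_cross, random_rigid)


def _random_site(rng):
    rot, trans = random_rigid(rng)
    res = make_ideal_cysteine(origin=trans, orientation=rot)
    return CysteineSite(residue=res, n_pos=res.get("N").pos,
                        ca_pos=res.get("CA").pos, cb_pos=res.get("CB").pos)


class TestPlacement:
    def test_round_trip_and_internal_coordinates(self, params):
        """Placed sulfurs reproduce χ1 to 1e-6° and the cone constants
        to 1e-9 over random site geometries."""
        rng = np.random.default_rng(123)
        worst_t, worst_b, worst_a = 0.0, 0.0, 0.0
        for _ in range(200):
            site = _random_site(rng)
            for chi1 in rng.uniform(-180.0, 180.0, size=10):
                s = place_sulfur(site, chi1, params)
                t = dihedral(site.n_pos, site.ca_pos, site.cb_pos, s)
                dt = abs(t - chi1)
                worst_t = max(worst_t, min(dt, 360.0 - dt))
                worst_b = max(worst_b, abs(np.linalg.norm(s - site.cb_pos) - params.bond_length))
                worst_a = max(worst_a, abs(bond_angle(site.ca_pos, site.cb_pos, s) - params.bond_angle))
        assert worst_t < 1e-6
        assert worst_b < 1e-9
        assert worst_a < 1e-9

    def test_full_grid_round_trip(self, engineered_dimer, params):
        _, site_a, _ = engineered_dimer
        prof = sweep_positions(site_a, params)
        for ang, pos in zip(prof.angles, prof.positions):
            t = dihedral(site_a.n_pos, site_a.ca_pos, site_a.cb_pos, pos)
            dt = abs(t - ang)
            assert min(dt, 360.0 - dt) < 1e-6

    def test_degenerate_backbone_raises(self, params):
        site = CysteineSite.__new__(CysteineSite)  # bypass sanity band
        site.residue = make_ideal_cysteine()
        site.n_pos = np.array([0.0, 0.0, -1.0])
        site.ca_pos = np.array([0.0, 0.0, 0.0])
        site.cb_pos = np.array([0.0, 0.0, 1.5])
        site.sg_pos = None
        site.is_free = True
        with pytest.raises(Exception):
            place_sulfur(site, -60.0, params)


class TestSweep:
    def test_grid_sizes(self, engineered_dimer, params):
        _, site_a, _ = engineered_dimer
        assert sweep_positions(site_a, params).n == 360
        assert sweep_positions(site_a, replace(params, step=5.0)).n == 72

    def test_positions_lie_on_cone_circle(self, engineered_dimer, params):
        """All sulfurs equidistant from the Cα-Cβ axis."""
        _, site_a, _ = engineered_dimer
        prof = sweep_positions(site_a, params)
        u = site_a.cb_pos - site_a.ca_pos
        u /= np.linalg.norm(u)
        rel = prof.positions - site_a.cb_pos
        radial = rel - np.outer(rel @ u, u)
        r = np.linalg.norm(radial, axis=1)
        assert np.abs(r - r[0]).max() < 1e-9
        assert r[0] == pytest.approx(params.cone_radius, abs=1e-9)


class TestClash:
    def test_empty_model_never_clashes(self, engineered_dimer, params):
        _, site_a, _ = engineered_dimer
        bare = StructureModel(entry_id="E", residues=[])
        prof = clash_scan(sweep_positions(site_a, params), bare, params)
        assert not prof.clash.any()

    def test_probe_arc_matches_naive_oracle(self, engineered_dimer, params):
        model, site_a, _ = engineered_dimer
        probed = add_clash_probe(model, site_a, 40.0, 10.0, params)
        prof = clash_scan(sweep_positions(site_a, params), probed, params)
        expected = oracle_clash_mask(prof.positions, probed, site_a, params)
        assert np.array_equal(prof.clash, expected)
        hit = prof.angles[prof.clash]
        assert abs(hit.min() - 30.0) <= 1.0 and abs(hit.max() - 50.0) <= 1.0

    def test_own_residue_atoms_are_exempt(self, params):
        res = make_ideal_cysteine(chi1=-60.0)
        site = find_cysteines(StructureModel(entry_id="X", residues=[res]))[0]
        prof = clash_scan(sweep_positions(site, params),
                          StructureModel(entry_id="X", residues=[res]), params)
        # CB sits well inside r_S + r_C of every cone point; exemption saves it
        assert not prof.clash.any()

    def test_deeper_overlap_requirement_never_adds_clashes(self, engineered_dimer, params):
        model, site_a, _ = engineered_dimer
        probed = add_clash_probe(model, site_a, 40.0, 30.0, params)
        base = sweep_positions(site_a, params)
        counts = []
        for ov in (0.2, 0.4, 0.6, 0.8):
            p = clash_scan(base, probed, replace(params, clash_overlap=ov))
            counts.append(int(p.clash.sum()))
        assert counts == sorted(counts, reverse=True)


class TestCrossDistances:
    def test_matches_exhaustive_oracle_exactly(self, engineered_dimer, params):
        _, site_a, site_b = engineered_dimer
        pa = sweep_positions(site_a, params)
        pb = sweep_positions(site_b, params)
        got = min_cross_distances(pa, pb)
        mins, arg = oracle_min_cross(pa.positions, pb.positions)
        assert np.abs(got.min_cross - mins).max() < 1e-12
        # argmin may legitimately flip between exactly tied partners;
        # the distance achieved at the reported partner must match
        bidx = {round(a, 9): i for i, a in enumerate(pb.angles)}
        for i in range(pa.n):
            j = bidx[round(float(got.partner_angle[i]), 9)]
            d = np.linalg.norm(pa.positions[i] - pb.positions[j])
            assert abs(d - mins[i]) < 1e-12

    def test_c2_symmetry_of_distance_matrix(self, engineered_dimer, params):
        _, site_a, site_b = engineered_dimer
        pa = sweep_positions(site_a, params)
        pb = sweep_positions(site_b, params)
        d = cdist(pa.positions, pb.positions)
        assert np.abs(d - d.T).max() < 1e-9

    def test_fine_grid_refinement_is_bounded(self, engineered_dimer, params):
        """A 0.1° partner grid lowers each per-angle minimum by less
        than the Lipschitz bound from the cone radius."""
        _, site_a, site_b = engineered_dimer
        pa = sweep_positions(site_a, params)
        pb_fine = sweep_positions(site_b, replace(params, step=0.1))
        coarse = min_cross_distances(pa, sweep_positions(site_b, params)).min_cross
        fine = cdist(pa.positions, pb_fine.positions).min(axis=1)
        assert (coarse - fine).max() < 0.06
        assert (coarse - fine).min() >= -1e-12  # refining can only lower minima

    def test_grid_mismatch_rejected(self, engineered_dimer, params):
        _, site_a, site_b = engineered_dimer
        pa = sweep_positions(site_a, params)
        pb = sweep_positions(site_b, replace(params, step=5.0))
        with pytest.raises(GridMismatchError):
            min_cross_distances(pa, pb)


class TestFeasibility:
    def test_engineered_minimum_recovered(self, engineered_dimer, params):
        model, site_a, site_b = engineered_dimer
        pa, pb, res = scan_pair(site_a, site_b, model, params)
        assert res.any_feasible
        assert res.best_pair == (-120.0, -120.0)
        assert res.best_distance == pytest.approx(2.05, abs=1e-9)
        oracle = oracle_feasible_pairs(pa.positions, pb.positions, pa.angles,
                                       pa.clash, pb.clash, params)
        assert set(res.feasible_pairs) == set(oracle)

    def test_probes_isolate_the_single_grid_pair(self, engineered_dimer, params):
        """Clash arcs leaving one clash-free angle per site reduce the
        feasible set to exactly the engineered (-120, -120) pair."""
        model, site_a, site_b = engineered_dimer
        for site in (site_a, site_b):
            model = add_clash_probe(model, site, 30.0, 149.0, params)    # [-119, 179]
            model = add_clash_probe(model, site, -150.5, 29.5, params)   # [-180, -121]
        pa, pb, res = scan_pair(site_a, site_b, model, params)
        assert list(pa.clash_free_angles()) == [-120.0]
        assert list(pb.clash_free_angles()) == [-120.0]
        assert res.feasible_pairs == ((-120.0, -120.0),)
        assert res.best_distance == pytest.approx(2.05, abs=1e-9)
        oracle = oracle_feasible_pairs(pa.positions, pb.positions, pa.angles,
                                       pa.clash, pb.clash, params)
        assert set(res.feasible_pairs) == set(oracle)

    def test_widening_tolerance_grows_feasible_set(self, engineered_dimer, params):
        model, site_a, site_b = engineered_dimer
        prev = set()
        for tol in (0.05, 0.1, 0.2, 0.4):
            _, _, res = scan_pair(site_a, site_b, model,
                                  replace(params, ss_tolerance=tol))
            cur = set(res.feasible_pairs)
            assert prev <= cur
            prev = cur

    def test_out_of_reach_dimer_is_infeasible(self, params):
        model = make_c2_dimer(DimerSpec(cb_separation=30.0))
        site_a, site_b = dimer_sites(model)
        _, _, res = scan_pair(site_a, site_b, model, params)
        assert not res.any_feasible
        assert res.best_pair is None

    def test_rigid_motion_equivariance(self, engineered_dimer, params):
        """Moving the whole model rigidly changes nothing."""
        model, site_a, site_b = engineered_dimer
        model = add_clash_probe(model, site_a, 40.0, 10.0, params)
        pa0, pb0, res0 = scan_pair(site_a, site_b, model, params)
        rng = np.random.default_rng(5)
        rot, trans = random_rigid(rng)
        t = RigidTransform(rot=rot, trans=trans)
        from ssbond.scan import _transform_model_chain, _transform_site
        moved = model
        for ch in {r.chain_id for r in model.residues}:
            moved = _transform_model_chain(moved, ch, t)
        sa = _transform_site(site_a, t)
        sb = _transform_site(site_b, t)
        pa1, pb1, res1 = scan_pair(sa, sb, moved, params)
        assert np.array_equal(pa0.clash, pa1.clash)
        assert np.array_equal(pb0.clash, pb1.clash)
        assert np.abs(pa0.min_cross - pa1.min_cross).max() < 1e-9
        assert res0.any_feasible == res1.any_feasible
        assert set(res0.feasible_pairs) == set(res1.feasible_pairs)


class TestRegistrationShift:
    def test_identity_equals_plain_feasibility(self, engineered_dimer, params):
        model, site_a, site_b = engineered_dimer
        _, _, plain = scan_pair(site_a, site_b, model, params)
        (shift,) = registration_shift_scan(site_a, site_b, model,
                                           [RigidTransform.identity()], params)
        assert shift.result.any_feasible == plain.any_feasible
        assert set(shift.result.feasible_pairs) == set(plain.feasible_pairs)
        assert shift.result.best_pair == plain.best_pair

    def test_moving_partner_away_closes_feasibility(self, engineered_dimer, params):
        model, site_a, site_b = engineered_dimer
        away = RigidTransform.translation([-10.0, 0.0, 0.0])  # B sits at -x
        (shift,) = registration_shift_scan(site_a, site_b, model, [away], params)
        assert not shift.result.any_feasible

    def test_shift_opens_engineered_feasibility(self, params):
        """Infeasible at identity (min 2.25 Å), feasible once protomer B
        slides 0.2 Å toward A; verified against the exhaustive oracle."""
        sep = engineered_separation(2.25, params)
        model = make_c2_dimer(DimerSpec(cb_separation=sep))
        site_a, site_b = dimer_sites(model)
        shifts = [RigidTransform.identity(),
                  RigidTransform.translation([0.2, 0.0, 0.0]),   # toward A
                  RigidTransform.translation([-0.2, 0.0, 0.0])]  # away
        results = registration_shift_scan(site_a, site_b, model, shifts, params)
        assert [r.result.any_feasible for r in results] == [False, True, False]
        ok = results[1]
        assert ok.result.best_distance == pytest.approx(2.05, abs=1e-9)
        from ssbond.scan import _transform_model_chain, _transform_site
        sb = _transform_site(site_b, shifts[1])
        pa = clash_scan(sweep_positions(site_a, params),
                        _transform_model_chain(model, "B", shifts[1]), params)
        pb = clash_scan(sweep_positions(sb, params),
                        _transform_model_chain(model, "B", shifts[1]), params)
        oracle = oracle_feasible_pairs(pa.positions, pb.positions, pa.angles,
                                       pa.clash, pb.clash, params)
        assert set(ok.result.feasible_pairs) == set(oracle)

    def test_achieved_chi3_reported(self, engineered_dimer, params):
        model, site_a, site_b = engineered_dimer
        (shift,) = registration_shift_scan(site_a, site_b, model,
                                           [RigidTransform.identity()], params)
        assert shift.result.any_feasible
        assert shift.best_chi3 is not None
        assert -180.0 < shift.best_chi3 <= 180.0

    def test_empty_transform_grid_rejected(self, engineered_dimer, params):
        model, site_a, site_b = engineered_dimer
        with pytest.raises(ValueError):
            registration_shift_scan(site_a, site_b, model, [], params)
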