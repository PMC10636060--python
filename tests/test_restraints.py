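"""Restraint potentials, energy combination, gradients, minimization."""

import numpy as np
import pytest

from cgrna.evalio import clash_count, kabsch_rmsd, pairs_to_matrix
from cgrna.geometry import BinSpec, CoarseStructure
from cgrna.network import GeometryPrediction
from cgrna.restraints import (EnergyWeights, MinimizeOptions,
                              RestraintConfig, _EnergyModel,
                              combine_energy, energy, generate_starts,
                              internal_energy, minimize,
                              nested_stems_from_matrix,
                              potentials_from_prediction, refine_clashes)
from cgrna.synthetic import (OracleConfig, ToySpec, helix_pair_coords,
                             make_toy_structure, oracle_prediction)


@pytest.fixture(scope="module")
def restraints(sharp_oracle):
    return potentials_from_prediction(sharp_oracle)


class TestWeights:
    def test_published_defaults(self):
        w = EnergyWeights()
        assert (w.w_dist, w.w_ori, w.w_cont, w.w_internal) == \
            (1.03, 1.0, 1.05, 0.05)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            EnergyWeights(w_dist=-1.0)

    def test_distance_term_weight(self):
        # E_dist = 1, all else 0 -> total = w1 = 1.03
        assert combine_energy(1.0, 0.0, 0.0, 0.0, 0.0, L=10) == \
            pytest.approx(1.03)

    def test_orientation_l_over_2(self):
        # L=10: E_ori = E_2D + (L/2) E_1D = 1 + 5 = 6
        assert combine_energy(0.0, 1.0, 1.0, 0.0, 0.0, L=10) == \
            pytest.approx(6.0)

    def test_all_zero(self):
        assert combine_energy(0, 0, 0, 0, 0, L=30) == 0.0


class TestSelection:
    def test_threshold_counts_bruteforce(self, sharp_oracle):
        cfg = RestraintConfig()
        rs = potentials_from_prediction(sharp_oracle, cfg)
        L = sharp_oracle.L
        pw = sharp_oracle.p_within_horizon()
        iu, ju = np.triu_indices(L, 1)
        expect_sym = int((pw[iu, ju] > 0.45).sum())
        assert len(rs.dist[0].idx_i) == expect_sym
        assert len(rs.dist[4].idx_i) == 2 * expect_sym   # both directions
        sep = ju - iu
        expect_cont = int(((sharp_oracle.contact[iu, ju] > 0.6)
                           & (sep >= 2)).sum())
        assert len(rs.contact.idx_i) == expect_cont

    def test_printed_thresholds(self):
        cfg = RestraintConfig()
        assert (cfg.dist_threshold, cfg.ori_threshold,
                cfg.contact_threshold) == (0.45, 0.65, 0.6)
        # pair probabilities [0.40, 0.50, 0.90] vs 0.45 -> 2 selected
        assert sum(p > cfg.dist_threshold
                   for p in (0.40, 0.50, 0.90)) == 2

    def test_uniform_prediction_zero_potential(self):
        L = 8
        bins = BinSpec()
        dist = np.full((5, L, L, 39), 1 / 39)
        ori2d = [np.full((L, L, 25), 1 / 25)] * 3 + \
                [np.full((L, L, 13), 1 / 13)] * 2
        ori1d = np.full((4, L, 25), 1 / 25)
        pred = GeometryPrediction(dist=dist, ori2d=ori2d, ori1d=ori1d,
                                  contact=np.zeros((L, L)))
        # force selection despite the uniform catch-all mass
        cfg = RestraintConfig(dist_threshold=0.0, ori_threshold=0.0)
        rs = potentials_from_prediction(pred, cfg)
        x = np.linspace(2.5, 39.5, 13)
        u, du = rs.dist[0].spline(np.full(len(rs.dist[0].idx_i), 10.3))
        np.testing.assert_allclose(u, 0.0, atol=1e-9)

    def test_potential_at_centers_matches_log_ratio(self, sharp_oracle):
        rs = potentials_from_prediction(sharp_oracle)
        bins = BinSpec()
        ch = rs.dist[0]
        k = 7
        centers = bins.dist_centers()
        i, j = ch.idx_i[k], ch.idx_j[k]
        p = sharp_oracle.dist[0][i, j, : 38]
        expect = -np.log((p + 1e-4) / (1 / 39 + 1e-4))
        expect -= expect[-1]
        u, _ = ch.spline(np.full(len(ch.idx_i), centers[5]))
        assert u[k] == pytest.approx(expect[5], abs=1e-9)

    def test_empty_selection_warns_not_raises(self, caplog):
        L = 6
        pred = GeometryPrediction(
            dist=np.full((5, L, L, 39), 1 / 39),
            ori2d=[np.full((L, L, 25), 1 / 25)] * 3
            + [np.full((L, L, 13), 1 / 13)] * 2,
            ori1d=np.full((4, L, 25), 1 / 25),
            contact=np.zeros((L, L)))
        cfg = RestraintConfig(dist_threshold=0.999, ori_threshold=0.999,
                              use_orientations=False)
        rs = potentials_from_prediction(pred, cfg)
        assert sum(rs.n_selected.values()) == 0


class TestDihedralPeriodicity:
    def test_value_and_slope_continuous_at_180(self, restraints):
        ch = restraints.ori2d[0]
        eps = 1e-6
        lo, dlo = ch.spline(np.full(len(ch.idx_i), -180.0 + eps))
        hi, dhi = ch.spline(np.full(len(ch.idx_i), 180.0 - eps))
        np.testing.assert_allclose(lo, hi, atol=1e-4)
        np.testing.assert_allclose(dlo, dhi, atol=1e-4)


class TestInternalEnergy:
    def test_ideal_helix_near_zero(self):
        # one continuous A-form strand from the generator's helix template
        m = 8
        coords = np.stack([helix_pair_coords(k)[0] for k in range(m)])
        helix = CoarseStructure("G" * m, coords)
        assert internal_energy(helix) / m < 1e-2

    def test_repulsion_positive_on_overlap(self, hairpin):
        c = hairpin.coords.copy()
        c[8] = c[2] + 0.5    # overlap two nucleotides
        s = CoarseStructure(hairpin.sequence, c)
        assert internal_energy(s) > internal_energy(hairpin)

    def test_rigid_motion_invariance(self, hairpin, rng):
        M = rng.normal(size=(3, 3))
        Q, R = np.linalg.qr(M)
        Q *= np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 2] *= -1
        moved = CoarseStructure(hairpin.sequence,
                                hairpin.coords @ Q.T + (3.0, -8.0, 1.0))
        assert internal_energy(moved) == pytest.approx(
            internal_energy(hairpin), rel=1e-9, abs=1e-9)


class TestEnergyGradient:
    def test_matches_central_differences(self, hairpin, restraints, rng):
        model = _EnergyModel(restraints, EnergyWeights())
        x0 = hairpin.coords.ravel() + 0.3 * rng.normal(
            size=hairpin.coords.size)
        _, g = model(x0)
        for _ in range(20):
            i = rng.integers(len(x0))
            eps = 1e-6
            xp = x0.copy()
            xp[i] += eps
            xm = x0.copy()
            xm[i] -= eps
            num = (model(xp)[0] - model(xm)[0]) / (2 * eps)
            assert abs(num - g[i]) <= 1e-3 * max(abs(num), abs(g[i]), 1.0)

    def test_nonfinite_coordinates_rejected(self, hairpin, restraints):
        bad = hairpin.coords.copy()
        bad[0, 0, 0] = np.nan
        s = CoarseStructure.__new__(CoarseStructure)
        s.sequence = hairpin.sequence
        s.coords = bad
        with pytest.raises(FloatingPointError):
            energy(s, restraints)


class TestStartsAndMinimize:
    def test_generate_starts_contract(self, hairpin_spec, hairpin_ss):
        starts = generate_starts(hairpin_spec.sequence, hairpin_ss, n=5,
                                 seed=2)
        assert len(starts) == 5
        for s in starts:
            pp = np.linalg.norm(np.diff(s.coords[:, 0], axis=0), axis=1)
            assert ((pp > 3.0) & (pp < 9.0)).all()
            assert np.isfinite(internal_energy(s))
        # distinct and seeded
        assert kabsch_rmsd(starts[0], starts[1]) > 0
        again = generate_starts(hairpin_spec.sequence, hairpin_ss, n=5,
                                seed=2)
        np.testing.assert_array_equal(starts[3].coords, again[3].coords)
        # predicted stems placed as A-form: paired C1'-C1' near 10.4
        pairs = nested_stems_from_matrix(hairpin_ss)
        for st in starts:
            for i, j in pairs:
                d = np.linalg.norm(st.coords[i, 2] - st.coords[j, 2])
                assert 8.9 <= d <= 11.9

    def test_stem_extraction_greedy_nested(self):
        m = np.zeros((10, 10))
        m[0, 9] = m[9, 0] = 0.9
        m[1, 8] = m[8, 1] = 0.8
        m[2, 7] = m[7, 2] = 0.4     # below threshold
        m[3, 9] = m[9, 3] = 0.7     # conflicts with (0,9)
        assert nested_stems_from_matrix(m) == [(0, 9), (1, 8)]

    def test_minimize_monotone_and_recovery(self, hairpin, sharp_oracle,
                                            restraints):
        d = minimize(hairpin, restraints)
        e_start = energy(hairpin, restraints)[0]
        assert d.energy <= e_start + 1e-6
        assert kabsch_rmsd(d.structure, hairpin) < 1.0
        # stored energy consistent with a recomputation
        assert d.energy == pytest.approx(
            energy(d.structure, restraints)[0], abs=1e-6)


class TestRestraintContainer:
    def test_roundtrip(self, tmp_path, hairpin, restraints):
        from cgrna.evalio import load_restraints, save_restraints
        p = tmp_path / "rs.npz"
        save_restraints(restraints, p)
        rs2 = load_restraints(p)
        assert rs2.L == restraints.L
        assert rs2.config == restraints.config
        assert rs2.n_selected == restraints.n_selected
        e1 = energy(hairpin, restraints)[0]
        e2 = energy(hairpin, rs2)[0]
        assert e2 == pytest.approx(e1, abs=1e-9)


class TestRefineClashes:
    def test_overlap_removed(self, sharp_oracle, hairpin, restraints):
        c = hairpin.coords.copy()
        c[8] = c[2] + 1.0
        clashed = CoarseStructure(hairpin.sequence, c)
        from cgrna.restraints import Decoy
        d = Decoy(structure=clashed,
                  energy=energy(clashed, restraints)[0], breakdown={})
        before = clash_count(clashed)
        assert before > 0
        refined = refine_clashes(d, restraints)
        assert clash_count(refined.structure) <= before
        assert kabsch_rmsd(refined.structure, clashed) < 2.0

    def test_clash_free_unchanged(self, hairpin, restraints):
        from cgrna.restraints import Decoy
        d = Decoy(structure=hairpin,
                  energy=energy(hairpin, restraints)[0], breakdown={})
        refined = refine_clashes(d, restraints)
        assert kabsch_rmsd(refined.structure, hairpin) < 0.1
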