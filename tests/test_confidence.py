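"""Confidence features, eRMSD estimator, OLS refit, MSA selection."""

import numpy as np
import pytest

from cgrna.confidence import (ConfidenceFeatures, EstimatorCoefficients,
                              compute_features, compute_mp, compute_prop,
                              compute_std, estimate_rmsd, refit_estimator,
                              select_msa)
from cgrna.network import GeometryPrediction
from cgrna.restraints import Decoy
from cgrna.geometry import CoarseStructure
from cgrna.synthetic import OracleConfig, oracle_prediction


def _pred_with_dist(dist, L):
    return GeometryPrediction(
        dist=dist, ori2d=[np.full((L, L, 25), 1 / 25)] * 3
        + [np.full((L, L, 13), 1 / 13)] * 2,
        ori1d=np.full((4, L, 25), 1 / 25),
        contact=np.zeros((L, L)))


class TestMp:
    def test_shared_delta_bin(self):
        """Every pair a delta in one shared bin -> mp = 1/38."""
        L = 10
        dist = np.zeros((5, L, L, 39))
        dist[..., 7] = 1.0
        mp = compute_mp(_pred_with_dist(dist, L))
        assert mp == pytest.approx(1 / 38)

    def test_uniform_with_tie_rule(self):
        """Uniform vectors: argmax ties break to class 0, one populated
        bin with mean 1/39."""
        L = 8
        dist = np.full((5, L, L, 39), 1 / 39)
        mp = compute_mp(_pred_with_dist(dist, L))
        assert mp == pytest.approx((1 / 38) * (1 / 39))

    def test_catchall_argmax_excluded(self):
        L = 6
        dist = np.zeros((5, L, L, 39))
        dist[..., 38] = 1.0            # catch-all class
        mp = compute_mp(_pred_with_dist(dist, L))
        assert mp == 0.0

    def test_matches_bruteforce(self, sharp_oracle, rng):
        pred = sharp_oracle
        L = pred.L
        pw = pred.p_within_horizon()
        iu, ju = np.triu_indices(L, 1)
        order = np.argsort(-pw[iu, ju], kind="stable")[: 15 * L]
        total = 0.0
        for k in range(38):
            vals = []
            for t in order:
                row = pred.dist[0][iu[t], ju[t]]
                if row.argmax() == k:
                    vals.append(row.max())
            if vals:
                total += np.mean(vals)
        assert compute_mp(pred) == pytest.approx(total / 38, abs=1e-9)


class TestStdProp:
    def test_uniform_vectors_zero_std(self):
        L = 8
        dist = np.full((5, L, L, 39), 1 / 39)
        assert compute_std(_pred_with_dist(dist, L)) == 0.0

    def test_bruteforce(self, sharp_oracle):
        L = sharp_oracle.L
        iu, ju = np.triu_indices(L, 1)
        stds = [sharp_oracle.dist[0][i, j].std() for i, j in zip(iu, ju)]
        assert compute_std(sharp_oracle) == pytest.approx(np.mean(stds),
                                                          abs=1e-9)
        props = [sharp_oracle.p_within_horizon()[i, j] > 0.45
                 for i, j in zip(iu, ju)]
        assert compute_prop(sharp_oracle) == pytest.approx(
            np.mean(props), abs=1e-12)


class TestFeaturesAndEstimator:
    def test_identical_decoys_zero_prmsd(self, hairpin, sharp_oracle):
        decoys = [Decoy(structure=hairpin, energy=-float(k),
                        breakdown={}) for k in range(3)]
        f = compute_features(sharp_oracle, decoys)
        assert f.pRMSD == pytest.approx(0.0, abs=1e-9)

    def test_prmsd_bruteforce_top10(self, hairpin, sharp_oracle, rng):
        from cgrna.evalio import kabsch_rmsd
        decoys = []
        for k in range(12):
            c = hairpin.coords + rng.normal(size=hairpin.coords.shape)
            decoys.append(Decoy(
                structure=CoarseStructure(hairpin.sequence, c),
                energy=float(rng.uniform(0, 10)), breakdown={}))
        f = compute_features(sharp_oracle, decoys)
        top = sorted(decoys, key=lambda d: d.energy)[:10]
        vals = [kabsch_rmsd(a.structure, b.structure)
                for i, a in enumerate(top) for b in top[i + 1:]]
        assert f.pRMSD == pytest.approx(np.mean(vals), abs=1e-9)

    def test_eq10_intercept_and_linearity(self, rng):
        z = ConfidenceFeatures(pRMSD=0, mp=0, std=0, prop=0)
        assert estimate_rmsd(z) == pytest.approx(15.2)
        one = ConfidenceFeatures(pRMSD=1, mp=0, std=0, prop=0)
        assert estimate_rmsd(one) == pytest.approx(15.84)
        c = EstimatorCoefficients()
        for _ in range(10):
            f = ConfidenceFeatures(pRMSD=float(rng.uniform(0, 20)),
                                   mp=float(rng.uniform(0, 1)),
                                   std=float(rng.uniform(0, 0.2)),
                                   prop=float(rng.uniform(0, 1)))
            expect = (0.64 * f.pRMSD - 189.43 * f.std - 4.01 * f.mp
                      - 1.06 * f.prop + 15.2)
            assert estimate_rmsd(f, c) == pytest.approx(expect, abs=1e-9)

    def test_refit_exact_recovery(self, rng):
        truth = EstimatorCoefficients(pRMSD=0.5, std=-100.0, mp=-2.0,
                                      prop=-1.5, intercept=12.0)
        samples = []
        for _ in range(20):
            f = ConfidenceFeatures(pRMSD=float(rng.uniform(0, 20)),
                                   mp=float(rng.uniform(0, 1)),
                                   std=float(rng.uniform(0, 0.2)),
                                   prop=float(rng.uniform(0, 1)))
            samples.append((f, estimate_rmsd(f, truth)))
        coef, r2 = refit_estimator(samples)
        assert coef.pRMSD == pytest.approx(0.5, abs=1e-6)
        assert coef.intercept == pytest.approx(12.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_refit_noisy_recovery(self, rng):
        truth = EstimatorCoefficients(pRMSD=0.7, std=-50.0, mp=-3.0,
                                      prop=-0.5, intercept=10.0)
        samples = []
        for _ in range(400):
            f = ConfidenceFeatures(pRMSD=float(rng.uniform(0, 20)),
                                   mp=float(rng.uniform(0, 1)),
                                   std=float(rng.uniform(0, 0.2)),
                                   prop=float(rng.uniform(0, 1)))
            samples.append((f, estimate_rmsd(f, truth)
                            + float(rng.normal(0, 0.5))))
        coef, r2 = refit_estimator(samples)
        assert coef.pRMSD == pytest.approx(0.7, abs=0.05)
        assert coef.intercept == pytest.approx(10.0, abs=1.0)

    def test_too_few_samples(self, rng):
        f = ConfidenceFeatures(pRMSD=1, mp=0.5, std=0.01, prop=0.5)
        with pytest.raises(ValueError):
            refit_estimator([(f, 5.0)] * 4)


class TestEstimatorTracksRecovery:
    """On a synthetic benchmark spanning oracle-noise levels, the refit
    eRMSD correlates positively (held-out Pearson r) with the true
    recovery RMSD of the folded models."""

    @staticmethod
    def _benchmark_specs(rng):
        """4 hairpins + 2 two-stem RNAs (the latter span the 40 A
        horizon, so the prop feature varies)."""
        out = []
        for _ in range(4):
            bp = int(rng.integers(4, 7))
            loop = int(rng.integers(4, 7))
            out.append(("G" * bp + "A" * loop + "C" * bp,
                        "(" * bp + "." * loop + ")" * bp))
        for _ in range(2):
            bp = int(rng.integers(5, 7))
            loop = int(rng.integers(4, 6))
            s1 = "G" * bp + "A" * loop + "C" * bp
            d1 = "(" * bp + "." * loop + ")" * bp
            out.append(("A" + s1 + "UUU" + s1 + "AA",
                        "." + d1 + "..." + d1 + ".."))
        return out

    def test_heldout_positive_correlation(self):
        from cgrna.evalio import kabsch_rmsd
        from cgrna.restraints import MinimizeOptions, fold
        from cgrna.synthetic import ToySpec, make_toy_structure

        rng = np.random.default_rng(17)
        opts = MinimizeOptions(maxiter=150)
        samples = []
        k = 0
        for noise in (0.0, 0.45, 0.85):
            for seq, db in self._benchmark_specs(rng):
                spec = ToySpec(seq, db, seed=300 + k)
                truth = make_toy_structure(spec)
                pred = oracle_prediction(
                    truth, OracleConfig(sigma_dist=4.0, sigma_ang=25.0,
                                        noise=noise, seed=k))
                L = len(truth)
                fr = fold(pred, spec.sequence, np.zeros((L, L)),
                          n_starts=5, seed=k, opts=opts)
                feats = compute_features(pred, fr.decoys)
                samples.append((feats,
                                kabsch_rmsd(fr.best.structure, truth)))
                k += 1
        idx = np.random.default_rng(99).permutation(len(samples))
        samples = [samples[i] for i in idx]
        half = len(samples) // 2
        coef, _ = refit_estimator(samples[:half])
        held = samples[half:]
        est = np.array([estimate_rmsd(f, coef) for f, _ in held])
        true = np.array([r for _, r in held])
        assert np.corrcoef(est, true)[0, 1] > 0


class TestSelectMsa:
    def test_single_candidate(self, sharp_oracle):
        assert select_msa(["only"], lambda _: sharp_oracle) == 0

    def test_delta_beats_uniform(self):
        L = 10
        delta = np.zeros((5, L, L, 39))
        delta[..., 5] = 1.0
        sharp = _pred_with_dist(delta, L)
        flat = _pred_with_dist(np.full((5, L, L, 39), 1 / 39), L)
        preds = {"a": flat, "b": sharp, "c": flat}
        idx = select_msa(list(preds), lambda k: preds[k])
        assert idx == 1

    def test_ranking_matches_std_order(self, hairpin):
        preds = [oracle_prediction(hairpin,
                                   OracleConfig(sigma_dist=s,
                                                sigma_ang=20.0, seed=1))
                 for s in (6.0, 1.0, 3.0)]
        idx = select_msa([0, 1, 2], lambda k: preds[k])
        stds = [compute_std(p) for p in preds]
        assert idx == int(np.argmax(stds)) == 1

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_msa([], lambda x: x)
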