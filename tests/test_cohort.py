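import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.signal import savgol_coeffs
from sklearn.metrics import adjusted_rand_score

from rarkit import (
    SubjectFeatures,
    average_actogram,
    compare_groups,
    kmeans_phenotype,
    smooth_profile,
    zscore_features,
)

from conftest import make_dm


def feats_from_matrix(X, groups=None):
    return [
        SubjectFeatures(f"s{i}", groups[i] if groups else "g", np.asarray(row, float))
        for i, row in enumerate(X)
    ]


class TestZscoreFeatures:
    def test_two_point_zscore(self):
        out = zscore_features(
            feats_from_matrix([[100, 1, 12, 5], [200, 2, 13, 6]])
        )
        assert out[0].z[0] == pytest.approx(-0.7071, abs=1e-4)
        assert out[1].z[0] == pytest.approx(0.7071, abs=1e-4)

    def test_columns_standardized(self, rng):
        out = zscore_features(feats_from_matrix(rng.normal(5, 3, (20, 4))))
        Z = np.vstack([s.z for s in out])
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_zero_variance_feature_named(self):
        with pytest.raises(ValueError, match="amplitude"):
            zscore_features(feats_from_matrix([[1, 5, 2, 3], [2, 5, 4, 1]]))

    def test_linear_acrophase_caveat(self):
        # 23.5 h and 0.5 h are 1 h apart on the clock but z-score far apart:
        # the clustering space treats acrophase linearly, by design
        out = zscore_features(
            feats_from_matrix([[1, 1, 23.5, 1], [2, 2, 0.5, 2], [3, 3, 12.0, 3]])
        )
        z_acro = [s.z[2] for s in out]
        assert abs(z_acro[0] - z_acro[1]) > 1.5


def kmeans_objective(X, labels):
    obj = 0.0
    for lab in set(labels):
        pts = X[[i for i, l in enumerate(labels) if l == lab]]
        obj += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return obj


class TestKmeansPhenotype:
    def test_separated_blobs_exact_recovery(self, rng):
        centers = np.array([[0, 0, 0, 0], [10, 10, 0, 0], [0, 0, 10, 10]], float)
        truth = np.repeat([0, 1, 2], 15)
        X = centers[truth] + rng.normal(0, 1, (45, 4))
        feats = zscore_features(feats_from_matrix(X))
        res = kmeans_phenotype(feats, k=3, replicates=50, seed=0)
        labels = [res.assignments[f"s{i}"] for i in range(45)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_matches_exhaustive_partition_oracle(self, rng):
        X = rng.normal(size=(8, 4))
        feats = zscore_features(feats_from_matrix(X))
        Z = np.vstack([s.z for s in feats])
        best = min(
            kmeans_objective(Z, labs)
            for labs in itertools.product(range(3), repeat=8)
            if len(set(labs)) == 3
        )
        res = kmeans_phenotype(feats, k=3, replicates=2000, seed=1)
        assert res.total_sum_distances == pytest.approx(best, abs=1e-9)

    def test_duplicate_points_same_centroids(self, rng):
        X = rng.normal(size=(12, 4)) + np.repeat([[0], [8], [16]], 4, axis=0)
        f1 = zscore_features(feats_from_matrix(X))
        res1 = kmeans_phenotype(f1, k=3, replicates=100, seed=3)
        X2 = np.vstack([X, X])
        f2 = [
            SubjectFeatures(f"d{i}", "g", X2[i], np.vstack([s.z for s in f1] * 2)[i])
            for i in range(24)
        ]
        res2 = kmeans_phenotype(f2, k=3, replicates=100, seed=3)
        assert np.allclose(np.sort(res1.centroids, axis=0), np.sort(res2.centroids, axis=0))

    def test_labels_ordered_by_amplitude_z(self, rng):
        X = rng.normal(0, 0.3, (15, 4)) + np.repeat([[0, 0, 0, 0], [0, 5, 0, 0], [0, 10, 0, 0]], 5, axis=0)
        feats = zscore_features(feats_from_matrix(X))
        res = kmeans_phenotype(feats, k=3, replicates=100, seed=0)
        amp_dim = 1
        by_label = {}
        for i in range(15):
            by_label.setdefault(res.assignments[f"s{i}"], []).append(feats[i].z[amp_dim])
        means = {lab: np.mean(v) for lab, v in by_label.items()}
        assert means["A"] < means["B"] < means["C"]

    def test_objective_recomputable_and_best(self, rng):
        X = rng.normal(size=(10, 4))
        feats = zscore_features(feats_from_matrix(X))
        res = kmeans_phenotype(feats, k=3, replicates=30, seed=5)
        Z = np.vstack([s.z for s in feats])
        labels = [res.assignments[f"s{i}"] for i in range(10)]
        assert res.total_sum_distances == pytest.approx(
            kmeans_objective(Z, labels), abs=1e-9
        )

    def test_k_at_least_n_rejected(self, rng):
        feats = zscore_features(feats_from_matrix(rng.normal(size=(3, 4))))
        with pytest.raises(ValueError):
            kmeans_phenotype(feats, k=3, replicates=10, seed=0)


class TestAverageActogram:
    def test_identical_days_give_single_day(self, rng):
        day = rng.integers(0, 100, 1440)
        act = average_actogram([make_dm(np.tile(day, (4, 1)))])
        assert np.allclose(act.mean_counts, day)

    def test_equal_subject_weighting(self, rng):
        p = rng.integers(0, 50, 1440).astype(float)
        q = rng.integers(0, 50, 1440).astype(float)
        dms = [make_dm(np.tile(p, (5, 1))), make_dm(np.tile(q, (2, 1)))]
        act = average_actogram(dms)
        assert np.allclose(act.mean_counts, (p + q) / 2)

    def test_30s_epochs_pair_averaged_and_loop_oracle(self, rng):
        dms = [make_dm(rng.integers(0, 80, (3, 2880)), 30) for _ in range(3)]
        act = average_actogram(dms)
        expected = np.zeros(1440)
        for m in range(1440):
            subj_means = []
            for dm in dms:
                vals = [dm.values[d, 2 * m + k] for d in range(dm.days) for k in (0, 1)]
                subj_means.append(sum(vals) / len(vals))
            expected[m] = sum(subj_means) / len(subj_means)
        assert np.allclose(act.mean_counts, expected, atol=1e-12)

    def test_mixed_epoch_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="mixed"):
            average_actogram(
                [make_dm(np.ones((1, 1440))), make_dm(np.ones((1, 2880)), 30)]
            )

    def test_grand_mean_conserved(self, rng):
        dms = [make_dm(rng.integers(0, 60, (int(rng.integers(1, 5)), 1440))) for _ in range(4)]
        act = average_actogram(dms)
        assert act.mean_counts.mean() == pytest.approx(
            np.mean([dm.values.mean() for dm in dms]), rel=1e-12
        )


class TestSmoothProfile:
    def test_constant_preserved(self):
        out = smooth_profile(np.full(1440, 7.3))
        assert np.allclose(out, 7.3, atol=1e-9)

    def test_cosine_attenuation_closed_form(self):
        W = 101
        minutes = np.arange(1440)
        f = 1 / 1440  # one cycle per day, per-minute frequency
        x = 10 + 4 * np.cos(2 * np.pi * minutes / 1440)
        out = smooth_profile(x)
        gain_ma = np.sin(np.pi * W / 1440) / (W * np.sin(np.pi / 1440))
        coeffs = savgol_coeffs(W, 2)
        k = np.arange(-(W // 2), W // 2 + 1)
        gain_sg = float(np.sum(coeffs[::-1] * np.cos(2 * np.pi * f * k)))
        fitted_amp = 2 * np.abs(np.fft.rfft(out)[1]) / 1440
        assert fitted_amp == pytest.approx(4 * gain_ma * gain_sg, rel=1e-6)
        assert out.mean() == pytest.approx(10, rel=1e-9)

    def test_circular_ramp_no_discontinuity(self):
        x = np.abs(np.arange(1440) - 720).astype(float)  # circular triangle
        out = smooth_profile(x)
        wrap_jump = abs(out[0] - out[-1])
        typical = np.median(np.abs(np.diff(out)))
        assert wrap_jump < 5 * typical + 1e-9


class TestCompareGroups:
    @staticmethod
    def toy_table():
        return pd.DataFrame(
            {
                "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                "m": [1.0, 2, 3, 4, 5, 6, 7, 8, 9],
            }
        )

    def test_textbook_f_by_hand(self):
        # group means 2,5,8; grand 5; SSB = 3*(9+0+9)=54; SSW = 6; df 2,6
        res = compare_groups(self.toy_table(), "m")
        assert res.F == pytest.approx((54 / 2) / (6 / 6))
        assert (res.df1, res.df2) == (2, 6)

    def test_tukey_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 20),
                "m": rng.normal(0, 1, 60) + np.repeat([0, 0.5, 2.0], 20),
            }
        )
        res = compare_groups(df, "m")
        sm = pairwise_tukeyhsd(df["m"], df["group"])
        assert np.allclose(sorted(res.tukey["p_adj"]), sorted(sm.pvalues), atol=1e-6)

    def test_shifted_group_flagged(self, rng):
        hits = 0
        for _ in range(25):
            df = pd.DataFrame(
                {
                    "group": np.repeat(["a", "b", "c"], 25),
                    "m": rng.normal(0, 1, 75) + np.repeat([0, 0, 3.0], 25),
                }
            )
            res = compare_groups(df, "m")
            t = res.tukey.set_index(["group1", "group2"])["p_adj"]
            involved = (t[("a", "c")] < 0.01) and (t[("b", "c")] < 0.01)
            clean = t[("a", "b")] >= 0.01
            hits += involved and clean
        assert hits >= 23

    def test_degenerate_variance_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b"], "m": [1.0, 1, 1, 1]})
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups(df, "m")
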