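"""Symptom-association PLS, loading summaries and permutation comparisons."""

import numpy as np
import pytest

from stagetraj.behavior import (PlsResult, control_correlations,
                                network_loadings, permute_group_diff,
                                pls_behavior, region_loadings,
                                score_correlations)
from stagetraj.types import ValidationError


def perfect_signal_data(rng, n=60, p=30):
    """Y depends on one X column; the rest are noise orthogonal to Y."""
    Y = rng.standard_normal((n, 3))
    X = rng.standard_normal((n, p))
    Q, _ = np.linalg.qr(Y - Y.mean(axis=0))
    X = X - Q @ (Q.T @ X)  # distractor columns carry no Y covariance
    X[:, 3] = 2.0 * Y[:, 0] + 0.01 * rng.standard_normal(n)
    return X, Y


class TestPlsBehavior:
    def test_perfect_signal_concentrates_weight(self, rng):
        X, Y = perfect_signal_data(rng)
        pls = pls_behavior(X, Y, n_perm=199, seed=0)
        cos = abs(pls.x_weights[3]) / np.linalg.norm(pls.x_weights)
        assert cos >= 0.95
        assert pls.p_perm == pytest.approx(1 / 200)

    def test_sign_convention_scores_covary_positively(self, rng):
        X, Y = perfect_signal_data(rng)
        pls = pls_behavior(X, Y, n_perm=199, seed=0)
        assert np.corrcoef(pls.x_scores, pls.y_scores)[0, 1] >= 0

    def test_invariant_to_column_order_and_y_rescaling(self, rng):
        X, Y = perfect_signal_data(rng, n=40, p=10)
        a = pls_behavior(X, Y, n_perm=99, seed=1)
        perm = rng.permutation(10)
        b = pls_behavior(X[:, perm], 5.0 * Y + 2.0, n_perm=99, seed=1)
        assert np.isclose(a.explained_variance, b.explained_variance, atol=1e-10)
        assert np.allclose(np.abs(a.x_weights[perm]), np.abs(b.x_weights),
                           atol=1e-8)

    def test_p_perm_never_zero(self, rng):
        X, Y = perfect_signal_data(rng, n=30, p=5)
        pls = pls_behavior(X, Y, n_perm=99, seed=0)
        assert pls.p_perm >= 1 / 100

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValidationError):
            pls_behavior(rng.standard_normal((5, 4)),
                         rng.standard_normal((5, 3)), n_perm=99)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValidationError):
            pls_behavior(rng.standard_normal((20, 4)), np.ones((20, 3)),
                         n_perm=99)

    def test_explained_variance_in_unit_interval(self, rng):
        X = rng.standard_normal((25, 8))
        Y = rng.standard_normal((25, 3))
        pls = pls_behavior(X, Y, n_perm=99, seed=2)
        assert 0 <= pls.explained_variance <= 1


class TestScoreCorrelations:
    def test_y_equal_to_scores_gives_r_one(self, rng):
        X, Y = perfect_signal_data(rng, n=40)
        pls = pls_behavior(X, Y, n_perm=99, seed=0)
        Y2 = np.column_stack([pls.x_scores, Y[:, 1], Y[:, 2]])
        rows = score_correlations(pls, Y2)
        assert np.isclose(rows[0]["r"], 1.0)

    def test_orthogonalized_column_gives_zero(self, rng):
        X, Y = perfect_signal_data(rng, n=40)
        pls = pls_behavior(X, Y, n_perm=99, seed=0)
        t = pls.x_scores
        y = rng.standard_normal(40)
        y -= y.mean() + 0  # center then orthogonalize against centered scores
        tc = t - t.mean()
        y = y - (y @ tc) / (tc @ tc) * tc
        rows = score_correlations(pls, np.column_stack([y, Y[:, 1], Y[:, 2]]))
        assert abs(rows[0]["r"]) < 1e-12

    def test_planted_coupling_estimated_within_band(self, rng):
        hits = 0
        for rep in range(20):
            g = np.random.default_rng(rep)
            X = g.standard_normal((60, 10))
            t = X[:, 0]
            y = 0.6 * (t - t.mean()) / t.std() + np.sqrt(1 - 0.36) * \
                g.standard_normal(60)
            Y = np.column_stack([y, g.standard_normal(60), g.standard_normal(60)])
            pls = pls_behavior(X, Y, n_perm=99, seed=rep)
            r = score_correlations(pls, Y)[0]["r"]
            hits += abs(abs(r) - 0.6) <= 0.2
        assert hits >= 18 * 0.9


def _manual_pls(loadings, perm_loadings):
    n = len(loadings)
    return PlsResult(x_weights=np.zeros(n), y_weights=np.zeros(3),
                     x_scores=np.zeros(4), y_scores=np.zeros(4),
                     x_loadings=loadings, y_loadings=np.zeros(3),
                     explained_variance=0.5, perm_null=np.zeros(9),
                     p_perm=0.5, perm_loadings=perm_loadings)


class TestNetworkLoadings:
    def test_constant_loadings_give_constant_means(self, parc):
        n_fi = 2
        load = np.full(n_fi * parc.n_labels, 0.7)
        pls = _manual_pls(load, np.zeros((20, n_fi * parc.n_labels)))
        rows = network_loadings(pls, parc, n_fi=n_fi)
        assert len(rows) == 8
        assert all(np.isclose(r["loading"], 0.7) for r in rows)

    def test_region_weighted_mean_equals_global_mean(self, parc, rng):
        n_fi = 2
        load = rng.standard_normal(n_fi * parc.n_labels)
        pls = _manual_pls(load, rng.standard_normal((20, n_fi * parc.n_labels)))
        rows = network_loadings(pls, parc, n_fi=n_fi)
        weighted = sum(r["loading"] * r["n_regions"] for r in rows) / \
            sum(r["n_regions"] for r in rows)
        assert np.isclose(weighted, load.mean(), atol=1e-10)

    def test_planted_network_mass_detected(self, parc, rng):
        n_fi = 1
        members = parc.network_members()
        load = 0.02 * rng.standard_normal(parc.n_labels)
        load[members["visual"]] += 0.5
        null = 0.02 * rng.standard_normal((199, parc.n_labels))
        rows = network_loadings(_manual_pls(load, null), parc, n_fi=n_fi)
        by_net = {r["network"]: r for r in rows}
        assert by_net["visual"]["p"] <= 0.01
        others = [r["p"] for r in rows if r["network"] != "visual"]
        assert np.median(others) > 0.05


class TestRegionLoadings:
    def test_threshold_semantics(self):
        pls = _manual_pls(np.arange(4.0), None)
        rows = region_loadings(pls, np.array([0.31, 0.29, 0.30, 1.0]),
                               n_fi=1, fraction=0.30)
        assert [r["region_index"] for r in rows] == [0, 3]

    def test_all_significant_includes_all(self):
        pls = _manual_pls(np.arange(6.0), None)
        rows = region_loadings(pls, np.ones(6), n_fi=1)
        assert len(rows) == 6

    def test_matches_counting_oracle(self, rng):
        n, n_fi = 30, 2
        pls = _manual_pls(rng.standard_normal(n * n_fi), None)
        frac = rng.random(n)
        rows = region_loadings(pls, frac, n_fi=n_fi, fraction=0.30)
        assert {r["region_index"] for r in rows} == \
            {i for i in range(n) if frac[i] > 0.30}
        by_region = pls.x_loadings.reshape(n_fi, n).mean(axis=0)
        for r in rows:
            assert np.isclose(r["loading"], by_region[r["region_index"]])


class TestPermuteGroupDiff:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(15)
        diff, p = permute_group_diff(x, x.copy(), n_perm=199, seed=0)
        assert diff == 0 and p > 0.9

    def test_three_sd_shift_significant(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 3.0
        _, p = permute_group_diff(a, b, n_perm=4999, seed=0)
        assert p <= 0.001

    def test_exhaustive_enumeration_oracle(self, rng):
        from itertools import combinations
        a = np.array([1.0, 3.0, 5.0])
        b = np.array([2.0, 4.0, 9.0])
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = sum(1 for idx in combinations(range(6), 3)
                    if abs(pooled[list(idx)].mean()
                           - np.delete(pooled, list(idx)).mean()) >= obs - 1e-12)
        exact = count / 20
        _, p = permute_group_diff(a, b, n_perm=4999, seed=1)
        assert abs(p - exact) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            permute_group_diff(np.array([]), np.array([1.0]))


class TestControlCorrelations:
    def test_planted_negative_duration_gm_slope(self, reference_cohort):
        records, _, _, _ = reference_cohort
        out = control_correlations(records, n_perm=199, seed=0)
        gm = next(r for r in out["duration_morphology"] if r["tissue"] == "gm")
        csf = next(r for r in out["duration_morphology"] if r["tissue"] == "csf")
        assert gm["r"] < 0 and gm["p"] < 0.05
        assert csf["r"] > 0

    def test_constant_morphology_reported_missing(self, reference_cohort):
        import copy
        _, patients, _, _ = reference_cohort
        pats = copy.deepcopy(patients[:20])
        for p in pats:
            p.morph = {"gm": 700.0, "wm": 500.0, "csf": 250.0}
        out = control_correlations(pats, n_perm=199, seed=0)
        assert all(np.isnan(r["r"]) for r in out["duration_morphology"])

    def test_drug_split_runs(self, reference_cohort):
        records, _, _, _ = reference_cohort
        out = control_correlations(records, n_perm=199, seed=0)
        assert len(out["drug_fi"]) == 5
        assert len(out["drug_split"]) == 5
        assert all(0 < row["p"] <= 1 for row in out["drug_split"])
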