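"""Stage discovery: windows, adjusted t-maps, affinity propagation, alignment,
Liptak-Stouffer combination and FDR, each against an independent oracle."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from stagetraj.stages import (PipelineError, StateSet, adjusted_tmap,
                              align_states, ap_cluster, build_windows, fdr_bh,
                              kmeans_check, liptak_stouffer, t_to_z)
from stagetraj.types import StatMap, SubjectRecord, ValidationError


def patients_with_durations(durations):
    return [SubjectRecord(id=f"p{i}", group="patient", age=40, sex="M",
                          tiv=1500, motion=0.1, duration_years=float(d))
            for i, d in enumerate(durations)]


class TestBuildWindows:
    def test_26_windows_for_1_to_30_years(self):
        pats = patients_with_durations(np.repeat(np.arange(1, 31), 3))
        ws = build_windows(pats, L=5, min_size=8)
        assert len(ws) == 26
        assert ws[0].duration_range == (1, 5)
        assert ws[-1].duration_range == (26, 30)

    def test_24_windows_for_L7(self):
        pats = patients_with_durations(np.repeat(np.arange(1, 31), 3))
        ws = build_windows(pats, L=7, min_size=8)
        assert len(ws) == 24  # max_duration - L + 1

    def test_degenerate_single_duration(self):
        pats = patients_with_durations([3.0] * 12)
        ws = build_windows(pats, L=5, min_size=8)
        assert [w.index for w in ws] == [1, 2, 3]
        assert all(w.n == 12 for w in ws)

    def test_subyear_durations_enter_window_one(self):
        pats = patients_with_durations([0.2] * 10 + [3.0] * 10)
        ws = build_windows(pats, L=5, min_size=8)
        assert ws[0].index == 1 and ws[0].n == 20

    def test_every_patient_covered(self):
        rng = np.random.default_rng(0)
        pats = patients_with_durations(rng.uniform(0, 30, 120))
        ws = build_windows(pats, L=5, min_size=8)
        covered = {i for w in ws for i in w.patient_ids}
        assert covered == {p.id for p in pats}

    def test_no_window_meets_minimum_errors(self):
        pats = patients_with_durations([1.0, 20.0])
        with pytest.raises(PipelineError):
            build_windows(pats, L=5, min_size=8)


class TestAdjustedTmap:
    def test_identical_groups_zero(self):
        x = np.tile(np.arange(4.0), (6, 1))
        m = adjusted_tmap(x[:3], x[3:])
        assert np.allclose(m.values, 0.0)

    def test_hand_computed_pooled_t(self):
        m = adjusted_tmap(np.array([[1.0], [2.0], [3.0]]),
                          np.array([[4.0], [5.0], [6.0]]))
        assert np.isclose(m.values[0], -3.674, atol=1e-3)
        assert m.df == 4

    def test_no_covariates_equals_textbook_pooled_t(self, rng):
        a = rng.standard_normal((9, 15))
        b = rng.standard_normal((12, 15)) + 0.4
        m = adjusted_tmap(a, b)
        t_ref = sps.ttest_ind(a, b, axis=0, equal_var=True).statistic
        assert np.allclose(m.values, t_ref, atol=1e-12)

    def test_matches_ols_contrast_oracle(self, rng):
        n_p, n_c, n_e = 14, 18, 6
        xp = rng.standard_normal((n_p, n_e)) + 0.5
        xc = rng.standard_normal((n_c, n_e))
        cp = rng.standard_normal((n_p, 3))
        cc = rng.standard_normal((n_c, 3))
        m = adjusted_tmap(xp, xc, cp, cc)
        import statsmodels.api as sm
        D = sm.add_constant(np.column_stack([
            np.concatenate([np.ones(n_p), np.zeros(n_c)]),
            np.vstack([cp, cc])]))
        y = np.vstack([xp, xc])
        for j in range(n_e):
            fit = sm.OLS(y[:, j], D).fit()
            assert np.isclose(m.values[j], fit.tvalues[1], atol=1e-10)
        assert m.df == n_p + n_c - 5

    def test_collinear_covariate_named(self, rng):
        xp = rng.standard_normal((6, 3))
        xc = rng.standard_normal((6, 3))
        # covariate identical to the group indicator
        cp, cc = np.ones((6, 1)), np.zeros((6, 1))
        with pytest.raises(ValidationError, match="badcov"):
            adjusted_tmap(xp, xc, cp, cc, cov_names=["badcov"])


def _maps(vectors, fi="falff"):
    return [StatMap(values=v, kind="z", fi=fi, subgroup=i + 1)
            for i, v in enumerate(vectors)]


class TestApCluster:
    def test_three_orthogonal_patterns_two_copies_each(self, rng):
        base = np.linalg.qr(rng.standard_normal((40, 3)))[0].T * 5
        vecs = [base[i % 3] + 1e-6 * rng.standard_normal(40) for i in range(6)]
        ss = ap_cluster(_maps(vecs))
        assert ss.n_states == 3
        groups = {}
        for w, s in ss.assignments.items():
            groups.setdefault(s, set()).add(w)
        assert sorted(map(sorted, groups.values())) == [[1, 4], [2, 5], [3, 6]]

    def test_identical_maps_single_state(self, rng):
        v = rng.standard_normal(30)
        ss = ap_cluster(_maps([v.copy() for _ in range(5)]))
        assert ss.n_states == 1

    def test_two_gaussian_clouds_match_exhaustive_exemplar_oracle(self, rng):
        centers = np.linalg.qr(rng.standard_normal((30, 2)))[0].T * 8
        vecs = [centers[i // 4] + 0.5 * rng.standard_normal(30)
                for i in range(8)]
        ss = ap_cluster(_maps(vecs))
        assert ss.n_states == 2
        X = np.vstack(vecs)
        S = np.corrcoef(X)
        # oracle: exhaustive exemplar-pair search maximizing net similarity
        best, best_pair = -np.inf, None
        for pair in itertools.combinations(range(8), 2):
            net = sum(max(S[i, e] for e in pair) for i in range(8))
            if net > best:
                best, best_pair = net, pair
        oracle_labels = [int(np.argmax([S[i, e] for e in best_pair]))
                         for i in range(8)]
        got = [ss.assignments[i + 1] for i in range(8)]
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(oracle_labels, got) == 1.0

    def test_exemplars_are_member_maps(self, rng):
        vecs = [rng.standard_normal(25) for _ in range(6)]
        ss = ap_cluster(_maps(vecs))
        X = np.vstack(vecs)
        for sid, ex in ss.exemplars.items():
            assert any(np.array_equal(ex.values, row) for row in X)
            assert ss.assignments[ex.subgroup] == sid

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValidationError):
            ap_cluster(_maps([rng.standard_normal(10)] * 2))


class TestKmeansCheck:
    def test_three_pattern_toy_ch_peaks_at_three(self, rng):
        base = np.linalg.qr(rng.standard_normal((40, 3)))[0].T * 5
        vecs = [base[i % 3] + 0.05 * rng.standard_normal(40) for i in range(9)]
        out = kmeans_check(_maps(vecs), range(2, 6), n_states_ap=3)
        assert out["ch_argmax"] == 3 and out["agrees_with_ap"]

    def test_identical_maps_indeterminate(self, rng):
        v = rng.standard_normal(20)
        out = kmeans_check(_maps([v.copy() for _ in range(6)]), range(2, 4))
        assert out["agrees_with_ap"] is None

    def test_k_out_of_range_rejected(self, rng):
        vecs = [rng.standard_normal(10) for _ in range(5)]
        with pytest.raises(ValidationError):
            kmeans_check(_maps(vecs), [5])


def _state_set(fi, assignments, exemplar_vectors):
    members = {}
    for w, s in assignments.items():
        members.setdefault(s, []).append(w)
    exemplars = {s: StatMap(values=v, kind="z", fi=fi, subgroup=members[s][0])
                 for s, v in exemplar_vectors.items()}
    return StateSet(fi=fi, assignments=assignments, exemplars=exemplars,
                    n_states=len(exemplar_vectors), ch_score=1.0,
                    members=members)


class TestAlignStates:
    def _patterns(self, rng, k, dim=40):
        return np.linalg.qr(rng.standard_normal((dim, k)))[0].T * 4

    def test_identical_state_sets_unanimous(self, rng):
        pats = self._patterns(rng, 3)
        assign = {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
        sets = [_state_set(fi, dict(assign), {s: pats[s - 1] for s in (1, 2, 3)})
                for fi in ("falff", "reho", "gfcd")]
        stages = align_states(sets)
        assert len(stages) == 3
        assert [st.member_windows for st in stages] == [[1, 2], [3, 4], [5, 6]]

    def test_permuted_state_ids_recovered(self, rng):
        pats = self._patterns(rng, 3)
        assign = {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
        perm = {1: 3, 2: 1, 3: 2}
        permuted = {w: perm[s] for w, s in assign.items()}
        sets = [
            _state_set("falff", dict(assign), {s: pats[s - 1] for s in (1, 2, 3)}),
            _state_set("reho", permuted, {perm[s]: pats[s - 1] for s in (1, 2, 3)}),
        ]
        stages = align_states(sets)
        assert [st.member_windows for st in stages] == [[1, 2], [3, 4], [5, 6]]

    def test_surplus_state_absorbed(self, rng):
        pats = self._patterns(rng, 6, dim=50)
        assign5 = {w: (w - 1) // 2 + 1 for w in range(1, 11)}  # 5 states
        sets = [_state_set(fi, dict(assign5), {s: pats[s - 1] for s in range(1, 6)})
                for fi in ("falff", "reho", "gfcd", "lfcd")]
        # sixth state: split the last state of one indicator
        assign6 = dict(assign5)
        assign6[10] = 6
        ex6 = {s: pats[s - 1] for s in range(1, 6)}
        ex6[6] = pats[4] + 0.2 * pats[5]  # resembles state 5 most
        sets.append(_state_set("lrfcd", assign6, ex6))
        stages = align_states(sets)
        assert len(stages) == 5
        assert stages[-1].member_windows == [9, 10]

    def test_alignment_idempotent(self, rng):
        pats = self._patterns(rng, 3)
        assign = {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
        sets = [_state_set(fi, dict(assign), {s: pats[s - 1] for s in (1, 2, 3)})
                for fi in ("falff", "reho")]
        first = align_states(sets)
        again = align_states(sets)
        assert [st.member_windows for st in first] == \
            [st.member_windows for st in again]


class TestLiptakStouffer:
    def test_sqrt_m_identity(self):
        maps = [StatMap(values=np.ones(5), kind="z") for _ in range(4)]
        out = liptak_stouffer(maps)
        assert np.allclose(out.values, 2.0)

    def test_two_map_hand_case(self):
        maps = [StatMap(values=np.array([2.0]), kind="z"),
                StatMap(values=np.array([-1.0]), kind="z")]
        out = liptak_stouffer(maps)
        assert np.isclose(out.values[0], 0.7071, atol=1e-4)

    def test_permutation_and_weight_scale_invariance(self, rng):
        vals = [rng.standard_normal(20) for _ in range(3)]
        maps = [StatMap(values=v, kind="z") for v in vals]
        w = np.array([1.0, 2.0, 3.0])
        a = liptak_stouffer(maps, weights=w).values
        b = liptak_stouffer(maps[::-1], weights=w[::-1]).values
        c = liptak_stouffer(maps, weights=10.0 * w).values
        assert np.allclose(a, b, atol=1e-12)
        assert np.allclose(a, c, atol=1e-12)

    def test_null_inputs_remain_standard_normal(self, rng):
        maps = [StatMap(values=rng.standard_normal(10000), kind="z")
                for _ in range(5)]
        out = liptak_stouffer(maps, weights=np.array([1, 2, 3, 4, 5.0]))
        assert sps.kstest(out.values, "norm").pvalue > 0.01

    def test_single_map_passthrough(self, rng):
        m = StatMap(values=rng.standard_normal(8), kind="z")
        out = liptak_stouffer([m])
        assert np.allclose(out.values, m.values)

    def test_t_to_z_sign_preserving_and_calibrated(self):
        t = np.array([-5.0, -1.0, 0.0, 1.0, 5.0])
        z = t_to_z(t, df=10)
        assert np.allclose(z, -z[::-1], atol=1e-12)  # odd function
        assert z[2] == 0
        # a t-quantile maps to the normal quantile of the same tail mass
        assert np.isclose(sps.norm.sf(z[4]), sps.t.sf(5.0, 10), rtol=1e-10)


class TestFdrBh:
    def test_hand_run_step_up(self):
        mask, thresh = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, True, False]
        assert thresh == 0.03

    def test_all_ones_rejects_none(self):
        mask, thresh = fdr_bh(np.ones(10), q=0.05)
        assert not mask.any() and thresh is None

    def test_all_zeros_rejects_all(self):
        mask, _ = fdr_bh(np.zeros(7), q=0.05)
        assert mask.all()

    def test_empty_input(self):
        mask, thresh = fdr_bh(np.array([]), q=0.05)
        assert mask.size == 0 and thresh is None

    def test_matches_manual_step_up_on_random_p(self, rng):
        p = rng.random(50)
        mask, _ = fdr_bh(p, q=0.1)
        order = np.argsort(p)
        m = len(p)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= 0.1 * rank / m:
                k_max = rank
        expect = np.zeros(m, dtype=bool)
        expect[order[:k_max]] = True
        assert np.array_equal(mask, expect)
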