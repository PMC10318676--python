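"""Functional indicators: spectral, rank-concordance and connectivity-count
statistics against independent brute-force oracles."""

import warnings

import numpy as np
import pytest

from stagetraj.indicators import SeriesBlock, falff, fcd, reho, compute_all
from stagetraj.types import ValidationError


def grid_coords(nx, ny, nz):
    return np.array([[i, j, k] for i in range(nx) for j in range(ny)
                     for k in range(nz)], dtype=float)


def make_block(data, tr=2.0):
    n = data.shape[0]
    side = int(np.ceil(n ** (1 / 3)))
    coords = grid_coords(side, side, side)[:n]
    return SeriesBlock(data=data, tr=tr, coords=coords)


def dense_falff_oracle(x, tr, band):
    """Direct DFT amplitude ratio, computed without the fft module."""
    n = len(x)
    t = np.arange(n)
    # explicit linear detrend by least squares
    A = np.column_stack([np.ones(n), t])
    x = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ks = np.arange(1, n // 2 + 1)
    freqs = ks / (n * tr)
    amps = np.array([abs(np.sum(x * np.exp(-2j * np.pi * k * t / n)))
                     for k in ks])
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return amps[in_band].sum() / amps.sum()


def kendall_w_oracle(series):
    """Kendall's W from first principles: average ranks, direct formula."""
    k, n = series.shape
    ranks = np.empty_like(series)
    for i in range(k):
        order = np.argsort(series[i], kind="stable")
        r = np.empty(n)
        r[order] = np.arange(1, n + 1)
        # average tied ranks
        for v in np.unique(series[i]):
            sel = series[i] == v
            r[sel] = r[sel].mean()
        ranks[i] = r
    R = ranks.sum(axis=0)
    S = np.sum((R - R.mean()) ** 2)
    return 12 * S / (k ** 2 * (n ** 3 - n))


class TestFalff:
    def test_in_band_sinusoid_dominates(self):
        t = np.arange(200) * 2.0
        x = np.cos(2 * np.pi * 0.05 * t)
        block = make_block(np.vstack([x, x]))
        assert np.all(falff(block, (0.01, 0.08)).values >= 0.95)

    def test_out_of_band_sinusoid_negligible(self):
        t = np.arange(200) * 2.0
        x = np.cos(2 * np.pi * 0.20 * t)
        block = make_block(np.vstack([x, x]))
        assert np.all(falff(block, (0.01, 0.08)).values <= 0.05)

    def test_white_noise_matches_dense_dft_oracle(self, rng):
        x = rng.standard_normal((3, 120))
        block = make_block(x)
        got = falff(block, (0.01, 0.08)).values
        expect = [dense_falff_oracle(row, 2.0, (0.01, 0.08)) for row in x]
        assert np.allclose(got, expect, atol=1e-10)

    def test_band_above_nyquist_rejected(self, rng):
        block = make_block(rng.standard_normal((2, 100)))
        with pytest.raises(ValidationError, match="Nyquist"):
            falff(block, (0.01, 0.5))

    def test_values_in_unit_interval(self, rng):
        block = make_block(rng.standard_normal((10, 100)))
        v = falff(block, (0.01, 0.08)).values
        assert np.all((v >= 0) & (v <= 1))


class TestReho:
    def test_identical_series_perfect_concordance(self, rng):
        base = rng.standard_normal(80)
        block = SeriesBlock(data=np.tile(base, (27, 1)), tr=2.0,
                            coords=grid_coords(3, 3, 3))
        w = reho(block, neighborhood=27)
        assert np.allclose(w.values, 1.0)

    def test_two_series_reversed_matches_formula(self):
        n = 10
        a = np.arange(n, dtype=float)
        b = a[::-1].copy()
        block = SeriesBlock(data=np.vstack([a, b]), tr=2.0,
                            coords=np.array([[0, 0, 0], [1, 0, 0]], float))
        got = reho(block, neighborhood=7).values
        expect = kendall_w_oracle(np.vstack([a, b]))
        assert np.allclose(got, expect, atol=1e-12)

    def test_random_neighborhood_matches_oracle(self, rng):
        block = SeriesBlock(data=rng.standard_normal((27, 60)), tr=2.0,
                            coords=grid_coords(3, 3, 3))
        got = reho(block, neighborhood=27).values[13]  # full 27-neighborhood
        expect = kendall_w_oracle(block.data)
        assert np.allclose(got, expect, atol=1e-12)

    def test_constant_series_zero_with_warning(self):
        block = SeriesBlock(data=np.ones((8, 50)), tr=2.0,
                            coords=grid_coords(2, 2, 2))
        with pytest.warns(UserWarning, match="constant"):
            w = reho(block, neighborhood=27)
        assert np.allclose(w.values, 0.0)

    def test_rank_invariance_to_monotone_rescale(self, rng):
        data = rng.standard_normal((8, 60))
        coords = grid_coords(2, 2, 2)
        a = reho(SeriesBlock(data=data, tr=2.0, coords=coords)).values
        b = reho(SeriesBlock(data=3.0 * data - 7.0, tr=2.0,
                             coords=coords)).values
        assert np.allclose(a, b, atol=1e-12)

    def test_invalid_neighborhood_rejected(self, rng):
        block = make_block(rng.standard_normal((8, 60)))
        with pytest.raises(ValidationError):
            reho(block, neighborhood=9)


class TestFcd:
    def test_complete_graph_counts(self, rng):
        shared = rng.standard_normal(200)
        gains = rng.uniform(0.5, 2.0, size=(10, 1))
        block = SeriesBlock(data=np.tile(shared, (10, 1)) * gains, tr=2.0,
                            coords=np.column_stack(
                                [np.arange(10.0), np.zeros(10), np.zeros(10)]))
        g, l, lr = fcd(block, r_threshold=0.6, lfcd_radius_mm=12.0)
        assert np.all(g.values == 9)

    def test_independent_noise_high_threshold_empty(self, rng):
        block = make_block(rng.standard_normal((12, 200)))
        g, _, _ = fcd(block, r_threshold=0.99)
        assert np.all(g.values == 0)

    def test_matches_dense_bruteforce_oracle(self, rng):
        # block design: two shared signals plus noise
        n_v, n_t = 14, 150
        s1, s2 = rng.standard_normal((2, n_t))
        data = np.empty((n_v, n_t))
        for v in range(n_v):
            base = s1 if v < 7 else s2
            data[v] = 0.8 * base + 0.6 * rng.standard_normal(n_t)
        block = make_block(data)
        g, l, lr = fcd(block, r_threshold=0.4, lfcd_radius_mm=5.0)
        xyz = block.coords_mm()
        for v in range(n_v):
            cg = cl = 0
            for u in range(n_v):
                if u == v:
                    continue
                r = np.corrcoef(data[v], data[u])[0, 1]
                if r > 0.4:
                    cg += 1
                    if np.linalg.norm(xyz[v] - xyz[u]) <= 5.0:
                        cl += 1
            assert g.values[v] == cg and l.values[v] == cl
            assert lr.values[v] == cg - cl

    def test_long_plus_local_equals_global(self, rng):
        block = make_block(rng.standard_normal((20, 100)))
        g, l, lr = fcd(block, r_threshold=0.2, lfcd_radius_mm=6.0)
        assert np.array_equal(lr.values + l.values, g.values)
        assert np.all(lr.values >= 0)

    def test_threshold_domain(self, rng):
        block = make_block(rng.standard_normal((4, 60)))
        with pytest.raises(ValidationError):
            fcd(block, r_threshold=1.0)

    def test_too_few_voxels_rejected(self, rng):
        block = SeriesBlock(data=rng.standard_normal((1, 60)), tr=2.0,
                            coords=np.zeros((1, 3)))
        with pytest.raises(ValidationError):
            fcd(block)


class TestAffineInvariance:
    def test_all_indicators_invariant_to_per_voxel_affine(self, rng):
        data = rng.standard_normal((27, 120))
        coords = grid_coords(3, 3, 3)
        a = SeriesBlock(data=data, tr=2.0, coords=coords)
        gains = rng.uniform(0.5, 3.0, size=(27, 1))
        offs = rng.normal(0, 5, size=(27, 1))
        b = SeriesBlock(data=gains * data + offs, tr=2.0, coords=coords)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fa, fb = compute_all(a), compute_all(b)
        for fi in fa:
            assert np.allclose(fa[fi].values, fb[fi].values, atol=1e-9), fi


class TestParcelShortcutAgreement:
    def test_timeseries_mode_realizes_planted_signs(self, parc):
        from stagetraj import synthetic as syn
        gt = syn.default_ground_truth(parc, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs, gt = syn.make_cohort(gt, 16, 16, parc, mode="timeseries")
        pats = [r for r in recs if r.is_patient]
        cons = [r for r in recs if not r.is_patient]
        nlab = len(pats[0].fi_data["falff"])
        for fi in gt.fi_list:
            diff = (np.mean([p.fi_data[fi] for p in pats], axis=0)
                    - np.mean([c.fi_data[fi] for c in cons], axis=0))
            effs = np.mean([gt.effect_maps[gt.stage_of(p.duration_years)][fi][:nlab]
                            for p in pats], axis=0)
            sel = np.abs(effs) > 0.2
            agree = np.mean(np.sign(diff[sel]) == np.sign(effs[sel]))
            assert agree >= 0.75, fi
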