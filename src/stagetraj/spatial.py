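"""Spatial correlation of case-control maps with molecular templates and
cortical gradients, including the demeaned gradient-ratio trajectory."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .genes import SpinNull
from .types import StatMap

log = logging.getLogger("stagetraj")

RATIO_TOL = 1e-6


def _vals(m) -> np.ndarray:
    return m.masked() if isinstance(m, StatMap) else np.asarray(m, dtype=float)


def template_correlation(maps: dict[str, StatMap | np.ndarray],
                         templates: dict[str, np.ndarray],
                         spin: SpinNull | None = None,
                         region_idx: np.ndarray | None = None) -> list[dict]:
    """Pearson r of each map against each template, with parametric p and —
    when a spin null over the same region support is supplied — a
    spatial-autocorrelation-corrected p as well.

    ``region_idx`` restricts both sides to a subset of positions (e.g. the
    spin null's analysis set). Constant templates yield missing entries.
    """
    rows = []
    for map_name, m in maps.items():
        v = _vals(m)
        if region_idx is not None:
            v = v[region_idx]
        for tname, tvec in templates.items():
            t = np.asarray(tvec, dtype=float)
            if region_idx is not None:
                t = t[region_idx]
            if t.std() == 0 or v.std() == 0:
                log.warning("constant vector for (%s, %s); entry missing",
                            map_name, tname)
                rows.append({"map": map_name, "template": tname,
                             "r": float("nan"), "p": float("nan"),
                             "p_spin": float("nan")})
                continue
            r, p = stats.pearsonr(v, t)
            p_spin = float("nan")
            if spin is not None:
                null = np.empty(spin.n_perm)
                for b in range(spin.n_perm):
                    null[b] = np.corrcoef(spin.apply(v, b), t)[0, 1]
                p_spin = float((1 + np.sum(np.abs(null) >= abs(r)))
                               / (spin.n_perm + 1))
            rows.append({"map": map_name, "template": tname, "r": float(r),
                         "p": float(p), "p_spin": p_spin})
    return rows


def gradient_profile(stage_maps: list[StatMap | np.ndarray], g1: np.ndarray,
                     g2: np.ndarray,
                     cortical_idx: np.ndarray | None = None) -> dict:
    """Per-stage correlation with two cortical gradients and their
    demeaned-ratio trajectory.

    For each stage map: r1 = corr(map, g1), r2 = corr(map, g2); both
    r-series are demeaned across stages and the per-stage ratio is
    demeaned-r1 / demeaned-r2, reported missing where the denominator's
    magnitude falls below tolerance. A linear-trend test (slope of r over
    stage order) is reported when at least 3 stages exist.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if cortical_idx is not None:
        g1, g2 = g1[cortical_idx], g2[cortical_idx]
    r1s, r2s = [], []
    for m in stage_maps:
        v = _vals(m)
        if cortical_idx is not None:
            v = v[cortical_idx]
        r1s.append(float(np.corrcoef(v, g1)[0, 1]) if v.std() > 0 else float("nan"))
        r2s.append(float(np.corrcoef(v, g2)[0, 1]) if v.std() > 0 else float("nan"))
    r1s, r2s = np.array(r1s), np.array(r2s)
    d1 = r1s - np.nanmean(r1s)
    d2 = r2s - np.nanmean(r2s)
    ratio = np.where(np.abs(d2) < RATIO_TOL, np.nan, d1 / np.where(
        np.abs(d2) < RATIO_TOL, np.nan, d2))
    out = {"r1": r1s.tolist(), "r2": r2s.tolist(),
           "r1_demeaned": d1.tolist(), "r2_demeaned": d2.tolist(),
           "ratio": [None if not np.isfinite(x) else float(x) for x in ratio]}
    n = len(stage_maps)
    if n >= 3:
        x = np.arange(1, n + 1, dtype=float)
        for name, series in (("r1", r1s), ("r2", r2s)):
            ok = np.isfinite(series)
            if ok.sum() >= 3 and np.std(series[ok]) > 0:
                res = stats.linregress(x[ok], series[ok])
                out[f"trend_{name}"] = {"slope": float(res.slope),
                                        "p": float(res.pvalue)}
            else:
                out[f"trend_{name}"] = {"slope": float("nan"), "p": float("nan")}
    return out
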