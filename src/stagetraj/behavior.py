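"""Symptom association by partial least squares regression.

For each stage, every member patient contributes a regions x indicators
feature matrix (flattened, indicator-major) as predictors and PANSS
positive / negative / general scores as responses. Only the first
covariance-maximizing component pair (PLS1) is analyzed; inference is by
subject-shuffling permutation of the response rows with the add-one
p-value rule. Loadings are summarized at network and region level against
the same permutation null. Sign convention: PLS1 is flipped so that the
neuroimaging and behavioral scores correlate non-negatively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stages import fdr_bh
from .types import Parcellation, SubjectRecord, ValidationError

log = logging.getLogger("stagetraj")

PANSS_COLS = ("positive", "negative", "general")


def standardize(M: np.ndarray, warn: str | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; zero-variance columns are zeroed (dropped from the
    fit) and reported. Returns (standardized matrix, kept-column mask)."""
    M = np.asarray(M, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    out = np.zeros_like(M)
    out[:, keep] = (M[:, keep] - mu[keep]) / sd[keep]
    if warn and not keep.all():
        log.warning("%s: dropped %d zero-variance column(s)", warn, (~keep).sum())
    return out, keep


def _pls1(Xs: np.ndarray, Ys: np.ndarray
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """First PLS component of standardized X, Y via SVD of the
    cross-covariance X'Y. Returns (x_weights, y_weights, x_scores, y_scores,
    explained fraction of Y variance)."""
    C = Xs.T @ Ys
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    wx, wy = U[:, 0], Vt[0]
    t = Xs @ wx
    u = Ys @ wy
    if np.sum(t * u) < 0:  # sign indeterminacy: make scores co-vary positively
        wx, t = -wx, -t
    tv = float(t @ t)
    if tv == 0:
        return wx, wy, t, u, 0.0
    # fraction of (standardized) Y variance captured by regression on t
    coef = Ys.T @ t / tv
    explained = float((coef ** 2).sum() * tv / (Ys ** 2).sum())
    return wx, wy, t, u, explained


@dataclass
class PlsResult:
    """First-component PLS fit with its permutation null."""

    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray  # corr(X column, x_scores)
    y_loadings: np.ndarray
    explained_variance: float
    perm_null: np.ndarray
    p_perm: float
    perm_loadings: np.ndarray | None = None
    y_names: tuple[str, ...] = PANSS_COLS

    def __post_init__(self) -> None:
        if not 0 <= self.explained_variance <= 1:
            raise ValidationError("explained variance outside [0, 1]")


def _loadings(M: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Correlation of each (standardized) column with the score vector."""
    ts = t.std(ddof=1)
    if ts == 0:
        return np.zeros(M.shape[1])
    tc = (t - t.mean()) / ts
    sd = M.std(axis=0, ddof=1)
    out = np.zeros(M.shape[1])
    ok = sd > 0
    Mc = (M[:, ok] - M[:, ok].mean(axis=0)) / sd[ok]
    out[ok] = Mc.T @ tc / (len(t) - 1)
    return out


def pls_behavior(X: np.ndarray, Y: np.ndarray, n_perm: int = 5000,
                 seed: int = 0, store_null_loadings: bool = False,
                 y_names: tuple[str, ...] = PANSS_COLS) -> PlsResult:
    """PLS1 of neuroimaging features X on behavioral scores Y.

    X, Y are column-standardized internally (within the stage subsample —
    each stage is an independent regression). The permutation null shuffles
    whole Y rows; p_perm = (1 + #{null >= observed}) / (n_perm + 1).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] < 10:
        raise ValidationError("PLS needs at least 10 subjects")
    if np.all(Y.std(axis=0) == 0):
        raise ValidationError("all behavioral columns are constant")
    Xs, _ = standardize(X, warn="pls_behavior X")
    Ys, _ = standardize(Y, warn="pls_behavior Y")
    wx, wy, t, u, ev = _pls1(Xs, Ys)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    null_load = np.empty((n_perm, X.shape[1])) if store_null_loadings else None
    n = X.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(n)
        wxp, _, tp, _, evp = _pls1(Xs, Ys[perm])
        null[b] = evp
        if null_load is not None:
            null_load[b] = _loadings(Xs, tp)
    p = (1 + np.sum(null >= ev)) / (n_perm + 1)
    return PlsResult(x_weights=wx, y_weights=wy, x_scores=t, y_scores=u,
                     x_loadings=_loadings(Xs, t), y_loadings=_loadings(Ys, t),
                     explained_variance=ev, perm_null=null, p_perm=float(p),
                     perm_loadings=null_load, y_names=tuple(y_names))


def score_correlations(pls: PlsResult, Y: np.ndarray, q: float = 0.05) -> list[dict]:
    """Pearson r of each behavioral column with the neuroimaging PLS1 scores,
    FDR-corrected across the columns."""
    Y = np.asarray(Y, dtype=float)
    out = []
    ps = []
    for j in range(Y.shape[1]):
        if Y[:, j].std() == 0 or pls.x_scores.std() == 0:
            out.append({"score": pls.y_names[j], "r": float("nan"), "p": float("nan")})
            ps.append(1.0)
            continue
        r, p = stats.pearsonr(pls.x_scores, Y[:, j])
        out.append({"score": pls.y_names[j], "r": float(r), "p": float(p)})
        ps.append(float(p))
    rej, _ = fdr_bh(np.array(ps), q=q)
    for row, sig in zip(out, rej):
        row["significant_fdr"] = bool(sig)
    return out


def network_loadings(pls: PlsResult, parc: Parcellation, n_fi: int,
                     q: float = 0.05) -> list[dict]:
    """Mean signed PLS1 loading per network with permutation significance.

    X columns are assumed indicator-major: column fi_i * n_regions + region_i.
    The null aggregates the permutation-run loadings identically; two-sided
    p with the add-one rule, FDR over the eight networks.
    """
    if pls.perm_loadings is None:
        raise ValidationError("pls was fitted without store_null_loadings=True")
    n_regions = parc.n_labels
    if len(pls.x_loadings) != n_fi * n_regions:
        raise ValidationError("loading vector length != n_fi * n_regions")
    members = parc.network_members()
    obs_by_region = pls.x_loadings.reshape(n_fi, n_regions)
    null_by_region = pls.perm_loadings.reshape(-1, n_fi, n_regions)
    rows, ps = [], []
    for net in sorted(members):
        idx = members[net]
        if idx.size == 0:
            rows.append({"network": net, "loading": float("nan"), "p": float("nan")})
            ps.append(1.0)
            continue
        obs = float(obs_by_region[:, idx].mean())
        null = null_by_region[:, :, idx].mean(axis=(1, 2))
        p = (1 + np.sum(np.abs(null) >= abs(obs))) / (len(null) + 1)
        rows.append({"network": net, "loading": obs, "p": float(p),
                     "n_regions": int(idx.size)})
        ps.append(float(p))
    rej, _ = fdr_bh(np.array(ps), q=q)
    for row, sig in zip(rows, rej):
        row["significant_fdr"] = bool(sig)
    return rows


def region_loadings(pls: PlsResult, sig_fraction: np.ndarray, n_fi: int,
                    fraction: float = 0.30) -> list[dict]:
    """Loadings (averaged across indicators) for regions where more than
    ``fraction`` of voxels carry significantly abnormal indicators.

    In parcel mode ``sig_fraction`` is 0/1 per region (significant or not);
    in voxel mode it is the per-region fraction of significant voxels.
    """
    n_regions = len(sig_fraction)
    by_region = pls.x_loadings.reshape(n_fi, n_regions).mean(axis=0)
    rows = []
    for i, frac in enumerate(np.asarray(sig_fraction, dtype=float)):
        if frac > fraction:
            rows.append({"region_index": i, "sig_fraction": float(frac),
                         "loading": float(by_region[i])})
    return rows


def permute_group_diff(values_a: np.ndarray, values_b: np.ndarray,
                       n_perm: int = 5000, seed: int = 0) -> tuple[float, float]:
    """Two-sided permutation p for a difference in means, by pooled relabeling."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return obs, 1.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:a.size].mean() - perm[a.size:].mean()
        if abs(d) >= abs(obs) - 1e-15:
            count += 1
    return obs, float((1 + count) / (n_perm + 1))


def compare_panss_between_stages(stages, patients: list[SubjectRecord],
                                 n_perm: int = 1000, seed: int = 0,
                                 q: float = 0.05) -> list[dict]:
    """All pairwise stage comparisons of PANSS scores, FDR over the family."""
    by_id = {p.id: p for p in patients}
    rows = []
    for score in PANSS_COLS:
        for i, si in enumerate(stages):
            for sj in stages[i + 1:]:
                va = np.array([by_id[x].panss[score] for x in si.patient_ids
                               if by_id[x].panss])
                vb = np.array([by_id[x].panss[score] for x in sj.patient_ids
                               if by_id[x].panss])
                diff, p = permute_group_diff(va, vb, n_perm=n_perm,
                                             seed=seed + si.id * 97 + sj.id)
                rows.append({"score": score, "stage_a": si.id, "stage_b": sj.id,
                             "diff": diff, "p": p})
    rej, _ = fdr_bh(np.array([r["p"] for r in rows]), q=q)
    for row, sig in zip(rows, rej):
        row["significant_fdr"] = bool(sig)
    return rows


def control_correlations(cohort: list[SubjectRecord], n_perm: int = 1000,
                         seed: int = 0) -> dict:
    """Confound checks: duration vs morphology, drug equivalents vs indicator
    summaries, and a high-vs-low drug median-split comparison."""
    patients = [p for p in cohort if p.is_patient]
    out: dict = {"duration_morphology": [], "drug_fi": [], "drug_split": []}
    with_morph = [p for p in patients if p.morph]
    if with_morph:
        dur = np.array([p.duration_years for p in with_morph])
        for tissue in ("gm", "wm", "csf"):
            v = np.array([p.morph[tissue] for p in with_morph])
            if v.std() == 0 or dur.std() == 0:
                out["duration_morphology"].append(
                    {"tissue": tissue, "r": float("nan"), "p": float("nan")})
                continue
            r, p = stats.pearsonr(dur, v)
            out["duration_morphology"].append(
                {"tissue": tissue, "r": float(r), "p": float(p)})
    else:
        log.warning("no morphology fields present; duration correlations skipped")
    with_drug = [p for p in patients if p.drug_equiv is not None and p.fi_data]
    if with_drug:
        drug = np.array([p.drug_equiv for p in with_drug])
        fis = sorted(with_drug[0].fi_data)
        summaries = {fi: np.array([p.fi_data[fi].mean() for p in with_drug])
                     for fi in fis}
        for fi in fis:
            r, p = stats.pearsonr(drug, summaries[fi])
            out["drug_fi"].append({"fi": fi, "r": float(r), "p": float(p)})
        median = np.median(drug)
        hi, lo = drug > median, drug <= median
        if hi.any() and lo.any():
            for fi in fis:
                diff, p = permute_group_diff(summaries[fi][hi], summaries[fi][lo],
                                             n_perm=n_perm, seed=seed)
                out["drug_split"].append({"fi": fi, "diff": diff, "p": p})
    else:
        log.warning("no drug-equivalent fields present; drug analyses skipped")
    return out


def build_feature_matrix(records: list[SubjectRecord],
                         fi_list: tuple[str, ...]) -> np.ndarray:
    """Subjects x (n_fi * n_regions) matrix, indicator-major column order."""
    return np.hstack([np.vstack([r.fi_data[fi] for r in records])
                      for fi in fi_list])


def panss_matrix(records: list[SubjectRecord]) -> np.ndarray:
    return np.array([[r.panss[c] for c in PANSS_COLS] for r in records], dtype=float)
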