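"""Duration-sliding stage discovery.

The framework substitutes overlapping disease-duration windows for
longitudinal follow-up: patients are grouped into windows of L consecutive
duration-years, each window is contrasted with all controls by a
covariate-adjusted two-sample t-test per parcel, the window t-maps of each
functional indicator are clustered by affinity propagation (cluster count
picked by the Calinski–Harabasz index), states are aligned across
indicators by spatial similarity plus temporal overlap, and each aligned
stage gets a fused z-map via the weighted Liptak–Stouffer combination with
Benjamini–Hochberg FDR thresholding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score
from statsmodels.stats.multitest import multipletests

from .types import RunConfig, StatMap, SubjectRecord, ValidationError

log = logging.getLogger("stagetraj")


class PipelineError(RuntimeError):
    pass


@dataclass
class SubgroupWindow:
    """Patients whose disease duration falls in [index, index + L - 1] years."""

    index: int
    duration_range: tuple[int, int]
    patient_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.patient_ids)


@dataclass
class StateSet:
    """Clustered representative case-control states for one indicator."""

    fi: str
    assignments: dict[int, int]  # window index -> state id
    exemplars: dict[int, StatMap]  # state id -> exemplar window t-map
    n_states: int
    ch_score: float
    members: dict[int, list[int]] = field(default_factory=dict)  # state -> windows


@dataclass
class Stage:
    """An aligned cross-indicator stage with a duration label."""

    id: int
    member_windows: list[int]
    per_fi_states: dict[str, int]
    duration_label: tuple[float, float, float] | None = None  # mean, min, max
    z_maps: dict[str, StatMap] = field(default_factory=dict)
    sig_masks: dict[str, np.ndarray] = field(default_factory=dict)
    patient_ids: list[str] = field(default_factory=list)


def build_windows(patients: list[SubjectRecord], L: int = 5,
                  min_size: int = 8) -> list[SubgroupWindow]:
    """Overlapping duration windows [k, k+L-1] for k = 1 .. max_dur - L + 1.

    Durations below 1 year enter window 1; durations beyond the last window's
    upper edge enter the last window, so every retained patient appears in at
    least one window. Windows smaller than ``min_size`` are dropped with a
    warning.
    """
    if L < 1:
        raise ValidationError("window length must be >= 1")
    durs = np.array([p.duration_years for p in patients], dtype=float)
    if durs.size == 0:
        raise PipelineError("no patients supplied")
    if np.any(durs < 0):
        raise ValidationError("negative disease duration")
    max_dur = int(np.ceil(durs.max()))
    if max_dur >= L:
        max_k = max_dur - L + 1
    else:
        # short-course cohort: every window [k, k+L-1] with k <= max duration
        # still contains patients, so keep them all
        max_k = max(1, max_dur)
    windows: list[SubgroupWindow] = []
    for k in range(1, max_k + 1):
        lo, hi = k, k + L - 1
        ids = []
        for p in patients:
            d = p.duration_years
            d_eff = max(d, 1.0)  # sub-year durations count as year 1
            if k == max_k:
                d_eff = min(d_eff, float(hi))  # clamp into the last window
            if lo <= d_eff <= hi:
                ids.append(p.id)
        if len(ids) < min_size:
            log.warning("window %d (%d-%d y) has only %d patients; dropped",
                        k, lo, hi, len(ids))
            continue
        windows.append(SubgroupWindow(index=k, duration_range=(lo, hi), patient_ids=ids))
    if not windows:
        raise PipelineError("no duration window meets the minimum subgroup size")
    return windows


def adjusted_tmap(patient_data: np.ndarray, control_data: np.ndarray,
                  patient_covs: np.ndarray | None = None,
                  control_covs: np.ndarray | None = None,
                  fi: str | None = None, subgroup: int | None = None,
                  cov_names: list[str] | None = None) -> StatMap:
    """Per-element patient-vs-control t-map adjusted for nuisance covariates.

    Fits response = intercept + group + covariates by least squares for every
    element (column) simultaneously and returns t = beta_group / SE with
    df = N - p. The group regressor codes patients 1, controls 0, so negative
    t means lower values in patients. With no covariates this reduces exactly
    to the pooled-variance two-sample t-test.
    """
    xp = np.atleast_2d(np.asarray(patient_data, dtype=float))
    xc = np.atleast_2d(np.asarray(control_data, dtype=float))
    n_p, n_c = xp.shape[0], xc.shape[0]
    y = np.vstack([xp, xc])
    group = np.concatenate([np.ones(n_p), np.zeros(n_c)])
    cols = [np.ones(n_p + n_c), group]
    names = ["intercept", "group"]
    if patient_covs is not None or control_covs is not None:
        cv = np.vstack([np.atleast_2d(patient_covs), np.atleast_2d(control_covs)])
        for j in range(cv.shape[1]):
            cols.append(cv[:, j].astype(float))
            names.append(cov_names[j] if cov_names else f"cov{j}")
    D = np.column_stack(cols)
    p = D.shape[1]
    if np.linalg.matrix_rank(D) < p:
        # identify an offending column by leave-one-out rank
        for j in range(2, p):
            if np.linalg.matrix_rank(np.delete(D, j, axis=1)) == p - 1:
                raise ValidationError(f"design matrix rank-deficient: covariate "
                                      f"{names[j]!r} is collinear")
        raise ValidationError("design matrix rank-deficient")
    dtd_inv = np.linalg.inv(D.T @ D)
    beta = dtd_inv @ D.T @ y
    resid = y - D @ beta
    df = n_p + n_c - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * dtd_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    return StatMap(values=t, kind="t", df=float(df), fi=fi, subgroup=subgroup)


def _similarity(vectors: np.ndarray) -> np.ndarray:
    """Pearson-correlation similarity between map vectors (rows)."""
    sd = vectors.std(axis=1)
    if np.any(sd == 0):
        raise ValidationError("constant map has undefined correlation similarity")
    return np.corrcoef(vectors)


def ap_cluster(maps: list[StatMap], fi: str | None = None,
               damping: float = 0.9, max_iter: int = 1000,
               convergence_iter: int = 50,
               preference_quantiles: np.ndarray | None = None,
               window_indices: list[int] | None = None) -> StateSet:
    """Affinity propagation over window t-maps with CH model selection.

    Similarity is the Pearson correlation between vectorized maps (pattern
    similarity — map amplitude scales with subgroup size and is not the
    scientific object). The preference is swept over quantiles of the
    off-diagonal similarities and the clustering maximizing the
    Calinski–Harabasz index over the map vectors is kept; exemplars are the
    affinity-propagation exemplar maps.
    """
    if len(maps) < 3:
        raise ValidationError("affinity propagation needs at least 3 maps")
    fi = fi or maps[0].fi
    if window_indices is None:
        window_indices = [m.subgroup if m.subgroup is not None else i + 1
                          for i, m in enumerate(maps)]
    X = np.vstack([m.masked() for m in maps])
    n = X.shape[0]
    # degenerate case: all maps numerically identical -> one state
    if np.allclose(X, X[0], atol=1e-12):
        sm = maps[0]
        return StateSet(fi=fi, assignments={w: 1 for w in window_indices},
                        exemplars={1: sm}, n_states=1, ch_score=float("nan"),
                        members={1: list(window_indices)})
    S = _similarity(X)
    off = S[~np.eye(n, dtype=bool)]
    if preference_quantiles is None:
        preference_quantiles = np.arange(5, 96, 10)
    prefs = np.percentile(off, preference_quantiles)
    best = None
    best_any = None
    single_state = None
    for pref in np.unique(prefs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ap = AffinityPropagation(affinity="precomputed", damping=damping,
                                     max_iter=max_iter,
                                     convergence_iter=convergence_iter,
                                     preference=pref, random_state=0)
            labels = ap.fit_predict(S)
        centers = ap.cluster_centers_indices_
        if centers is None or len(np.atleast_1d(centers)) == 0 or np.any(labels < 0):
            continue  # did not converge at this preference
        k = len(np.unique(labels))
        if k == 1:
            single_state = (labels, np.atleast_1d(centers))
            continue
        if k >= n:
            continue
        ch = calinski_harabasz_score(X, labels)
        cand = (ch, labels, np.atleast_1d(centers))
        if best_any is None or ch > best_any[0]:
            best_any = cand
        # a duration-related state needs temporal extent: partitions with a
        # singleton state (one window) are excluded from model selection
        if np.bincount(labels).min() >= 2 and (best is None or ch > best[0]):
            best = cand
    if best is None:
        best = best_any
    if best is None:
        if single_state is not None:
            labels, centers = single_state
            best = (float("nan"), labels, centers)
        else:
            raise PipelineError("affinity propagation did not converge at any "
                                "preference; consider increasing damping")
    ch, labels, centers = best
    # relabel states by ascending mean window index for stable ids
    order = np.argsort([np.mean([window_indices[i] for i in np.flatnonzero(labels == c)])
                        for c in range(len(centers))])
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    assignments = {w: remap[int(labels[i])] for i, w in enumerate(window_indices)}
    exemplars = {remap[c]: maps[centers[c]] for c in range(len(centers))}
    members: dict[int, list[int]] = {}
    for w, s in assignments.items():
        members.setdefault(s, []).append(w)
    return StateSet(fi=fi, assignments=assignments, exemplars=exemplars,
                    n_states=len(centers), ch_score=float(ch), members=members)


def kmeans_check(maps: list[StatMap], k_range: range | list[int],
                 n_states_ap: int | None = None, seed: int = 0,
                 n_restarts: int = 10) -> dict:
    """k-means sweep over candidate cluster counts as a consistency check.

    Reports per-k within-cluster variance, explained-variance fraction,
    variance gain over k-1 and the CH index, and whether the CH argmax
    agrees with the affinity-propagation state count.
    """
    X = np.vstack([m.masked() for m in maps])
    total_ss = ((X - X.mean(axis=0)) ** 2).sum()
    rows = []
    for k in k_range:
        if not 2 <= k <= X.shape[0] - 1:
            raise ValidationError(f"k={k} outside [2, n_maps-1]")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        if total_ss <= 1e-10 * X.size or len(np.unique(km.labels_)) < 2:
            rows.append({"k": k, "within_var": 0.0, "explained": float("nan"),
                         "ch": float("nan")})
            continue
        rows.append({"k": k, "within_var": float(km.inertia_),
                     "explained": float(1.0 - km.inertia_ / total_ss),
                     "ch": float(calinski_harabasz_score(X, km.labels_))})
    for i, r in enumerate(rows):
        prev = rows[i - 1]["explained"] if i else 0.0
        r["gain"] = (r["explained"] - prev) if np.isfinite(r["explained"]) else float("nan")
    chs = [r["ch"] for r in rows]
    if not any(np.isfinite(c) for c in chs):
        log.warning("identical maps: k-means agreement indeterminate")
        agrees = None
        ch_argmax = None
    else:
        ch_argmax = rows[int(np.nanargmax(chs))]["k"]
        agrees = (ch_argmax == n_states_ap) if n_states_ap is not None else None
    return {"table": rows, "ch_argmax": ch_argmax, "agrees_with_ap": agrees}


def _jaccard(a: set, b: set) -> float:
    u = a | b
    return len(a & b) / len(u) if u else 0.0


def align_states(state_sets: list[StateSet], alpha: float = 0.5,
                 window_durations: dict[int, float] | None = None) -> list[Stage]:
    """Align per-indicator states into cross-indicator stages.

    The reference is the state set whose state count equals the modal count
    (ties broken by list order). Every other set is matched to the reference
    by an optimal one-to-one assignment maximizing
    alpha * corr(exemplar maps) + (1 - alpha) * Jaccard(member windows);
    surplus states attach to the best-scoring reference state. A window's
    stage is the majority vote of its aligned labels across indicators, ties
    resolved toward the stage with the earlier mean duration. Stages are
    renumbered by ascending mean member duration.
    """
    if len(state_sets) < 2:
        raise ValidationError("alignment needs at least 2 state sets")
    counts = [s.n_states for s in state_sets]
    vals, freq = np.unique(counts, return_counts=True)
    modal = int(vals[np.argmax(freq)])
    ref = next(s for s in state_sets if s.n_states == modal)
    windows = sorted(ref.assignments.keys())

    def win_mean_dur(ws: list[int]) -> float:
        if window_durations:
            return float(np.mean([window_durations[w] for w in ws]))
        return float(np.mean(ws))

    mappings: dict[str, dict[int, int]] = {ref.fi: {s: s for s in ref.exemplars}}
    for ss in state_sets:
        if ss is ref:
            continue
        if any(len(m) == 0 for m in ss.members.values()):
            raise ValidationError(f"state set {ss.fi} has an empty state")
        ref_ids = sorted(ref.exemplars)
        oth_ids = sorted(ss.exemplars)
        score = np.zeros((len(ref_ids), len(oth_ids)))
        for i, r in enumerate(ref_ids):
            for j, o in enumerate(oth_ids):
                c = np.corrcoef(ref.exemplars[r].masked(), ss.exemplars[o].masked())[0, 1]
                jac = _jaccard(set(ref.members[r]), set(ss.members[o]))
                score[i, j] = alpha * c + (1 - alpha) * jac
        ri, oj = linear_sum_assignment(-score)
        mapping = {oth_ids[j]: ref_ids[i] for i, j in zip(ri, oj)}
        for j, o in enumerate(oth_ids):  # surplus states -> best reference state
            if o not in mapping:
                mapping[o] = ref_ids[int(np.argmax(score[:, j]))]
        mappings[ss.fi] = mapping

    stage_windows: dict[int, list[int]] = {s: [] for s in ref.exemplars}
    for w in windows:
        votes = [mappings[ss.fi][ss.assignments[w]] for ss in state_sets
                 if w in ss.assignments]
        uniq, cnt = np.unique(votes, return_counts=True)
        top = uniq[cnt == cnt.max()]
        if len(top) == 1:
            chosen = int(top[0])
        else:  # tie: earlier mean duration among candidate reference states
            chosen = int(min(top, key=lambda s: win_mean_dur(ref.members[int(s)])))
        stage_windows[chosen].append(w)

    stages = []
    for ref_state, ws in stage_windows.items():
        if not ws:
            continue
        per_fi = {}
        for ss in state_sets:
            inv_votes = [s for s, r in mappings[ss.fi].items() if r == ref_state]
            per_fi[ss.fi] = inv_votes[0] if len(inv_votes) == 1 else ref_state
        stages.append(Stage(id=ref_state, member_windows=sorted(ws),
                            per_fi_states=per_fi))
    stages.sort(key=lambda st: win_mean_dur(st.member_windows))
    for new_id, st in enumerate(stages, start=1):
        st.id = new_id
    return stages


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Sign-preserving probability transform z = Phi^-1(F_t(t; df))."""
    t = np.asarray(t, dtype=float)
    a = np.abs(t)
    p_tail = stats.t.sf(a, df)
    p_tail = np.clip(p_tail, 1e-300, None)
    return np.sign(t) * stats.norm.isf(p_tail)


def liptak_stouffer(member_maps: list[StatMap],
                    weights: np.ndarray | None = None,
                    fi: str | None = None) -> StatMap:
    """Weighted Liptak–Stouffer combination: Z = sum(w_i z_i) / sqrt(sum w_i^2).

    t-maps are first converted elementwise to z-scale through the t CDF
    (subgroup degrees of freedom differ, and the combination assumes
    z-scale inputs). The result is scale-invariant in the weights.
    """
    if not member_maps:
        raise ValidationError("no maps to combine")
    zs = []
    for m in member_maps:
        if m.kind == "t":
            zs.append(t_to_z(m.values, m.df))
        else:
            zs.append(m.values.astype(float))
    Z = np.vstack(zs)
    if len(member_maps) == 1:
        log.info("single map passed to liptak_stouffer; returned unchanged")
        return StatMap(values=Z[0], kind="z", fi=fi or member_maps[0].fi,
                       mask=member_maps[0].mask)
    if weights is None:
        weights = np.ones(len(member_maps))
    w = np.asarray(weights, dtype=float)
    combined = (w[:, None] * Z).sum(axis=0) / np.sqrt((w ** 2).sum())
    return StatMap(values=combined, kind="z", fi=fi or member_maps[0].fi,
                   mask=member_maps[0].mask)


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini–Hochberg step-up: rejection mask plus the largest rejected p."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), None
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    thresh = float(p[reject].max()) if reject.any() else None
    return reject, thresh


@dataclass
class StageDiscoveryResult:
    windows: list[SubgroupWindow]
    tmaps: dict[str, dict[int, StatMap]]  # fi -> window index -> t-map
    state_sets: dict[str, StateSet]
    stages: list[Stage]
    kmeans: dict[str, dict]


def _subject_matrix(records: list[SubjectRecord], fi: str) -> np.ndarray:
    return np.vstack([r.fi_data[fi] for r in records])


def _cov_matrix(records: list[SubjectRecord]) -> np.ndarray:
    return np.vstack([r.covariates() for r in records])


def discover_stages(patients: list[SubjectRecord], controls: list[SubjectRecord],
                    cfg: RunConfig, use_covariates: bool = True,
                    run_kmeans: bool = False) -> StageDiscoveryResult:
    """Run the full discovery chain on parcel-level cohort data.

    windows -> per-window adjusted t-maps per indicator -> affinity
    propagation states per indicator -> cross-indicator alignment ->
    per-stage Liptak–Stouffer z-maps (per indicator, weights sqrt(n_window))
    plus a cross-indicator fused map, each FDR-masked at cfg.fdr_q.
    """
    windows = build_windows(patients, L=cfg.window_length_years,
                            min_size=cfg.min_subgroup_size)
    by_id = {p.id: p for p in patients}
    ctrl_cov = _cov_matrix(controls) if use_covariates else None
    tmaps: dict[str, dict[int, StatMap]] = {fi: {} for fi in cfg.fi_list}
    for w in windows:
        pats = [by_id[i] for i in w.patient_ids]
        pat_cov = _cov_matrix(pats) if use_covariates else None
        for fi in cfg.fi_list:
            tmaps[fi][w.index] = adjusted_tmap(
                _subject_matrix(pats, fi), _subject_matrix(controls, fi),
                pat_cov, ctrl_cov, fi=fi, subgroup=w.index,
                cov_names=["age", "sex", "tiv", "motion"])
    state_sets = {}
    km = {}
    for fi in cfg.fi_list:
        maps = [tmaps[fi][w.index] for w in windows]
        state_sets[fi] = ap_cluster(maps, fi=fi, damping=cfg.ap_damping,
                                    max_iter=cfg.ap_max_iter,
                                    convergence_iter=cfg.ap_convergence_iter,
                                    window_indices=[w.index for w in windows])
        if run_kmeans:
            kmax = min(8, len(maps) - 1)
            km[fi] = kmeans_check(maps, range(2, kmax + 1),
                                  n_states_ap=state_sets[fi].n_states,
                                  seed=cfg.rng_seed)
    win_dur = {w.index: float(np.mean([by_id[i].duration_years for i in w.patient_ids]))
               for w in windows}
    stages = align_states([state_sets[fi] for fi in cfg.fi_list],
                          alpha=cfg.align_alpha, window_durations=win_dur)
    win_by_idx = {w.index: w for w in windows}
    for st in stages:
        ids = sorted({i for w in st.member_windows for i in win_by_idx[w].patient_ids})
        st.patient_ids = ids
        durs = np.array([by_id[i].duration_years for i in ids])
        st.duration_label = (float(durs.mean()), float(durs.min()), float(durs.max()))
        n_by_win = {w: win_by_idx[w].n for w in st.member_windows}
        per_fi_z: dict[str, StatMap] = {}
        for fi in cfg.fi_list:
            members = [tmaps[fi][w] for w in st.member_windows]
            wts = np.sqrt([n_by_win[w] for w in st.member_windows])
            per_fi_z[fi] = liptak_stouffer(members, weights=wts, fi=fi)
        fused = liptak_stouffer(list(per_fi_z.values()), fi="fused")
        st.z_maps = dict(per_fi_z)
        st.z_maps["fused"] = fused
        for name, zm in st.z_maps.items():
            pv = 2.0 * stats.norm.sf(np.abs(zm.values))
            st.sig_masks[name], _ = fdr_bh(pv, q=cfg.fdr_q)
    return StageDiscoveryResult(windows=windows, tmaps=tmaps, state_sets=state_sets,
                                stages=stages, kmeans=km)
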