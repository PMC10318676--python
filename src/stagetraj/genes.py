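"""Imaging-transcriptomic association with spatial-null inference.

Regional gene expression (left hemisphere) predicts a stage's case-control
z-map through PLS1. Inference respects spatial autocorrelation via a spin
test: random proper rotations of the cortical centroid sphere reassign each
cortical region to its nearest rotated neighbor, and the explained variance
is recomputed under each surrogate response. Gene weights are stabilized by
a region bootstrap: resampled refits, sign-aligned to the original weights,
give a standard error per gene and hence z = weight / SE, with
Benjamini–Hochberg FDR over two-sided normal p-values and a |z| cut for the
reported PLS1+/PLS1- lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import special_ortho_group

from .behavior import PlsResult, standardize
from .stages import fdr_bh
from .types import ExpressionMatrix, Parcellation, SchemaError, StatMap, ValidationError

log = logging.getLogger("stagetraj")


@dataclass
class SpinNull:
    """Spatial-autocorrelation-preserving label reassignments.

    ``reassignments[b, i]`` is the position (within the analysis region
    order) whose value replaces position i in surrogate b. Cortical labels
    follow the nearest rotated centroid; non-cortical labels are permuted
    uniformly among themselves.
    """

    rotations: np.ndarray  # n_perm x 3 x 3 proper rotations
    reassignments: np.ndarray  # n_perm x n_regions ints
    labels: np.ndarray  # analysis region labels, ascending
    n_perm: int
    cortical: np.ndarray | None = None  # boolean per analysis region

    def apply(self, values: np.ndarray, b: int) -> np.ndarray:
        return np.asarray(values)[self.reassignments[b]]


def build_spin(parc: Parcellation, n_perm: int = 1000, seed: int = 0,
               labels: np.ndarray | None = None) -> SpinNull:
    """Build a spin null over an analysis region set (default: left hemisphere).

    Each surrogate draws a uniform rotation R in SO(3); cortical region i is
    reassigned the value of the cortical region whose centroid is nearest
    R @ centroid_i. Subcortical regions, which have no sphere position, are
    freely permuted within themselves.
    """
    if labels is None:
        labels = parc.left_labels
    labels = np.asarray(labels, dtype=int)
    cort = np.array([parc.is_cortical[int(l)] for l in labels])
    missing = [int(l) for l, c in zip(labels, cort)
               if c and int(l) not in parc.sphere_xyz]
    if missing:
        raise SchemaError(f"cortical label(s) missing sphere coordinates: {missing}")
    xyz = np.vstack([parc.sphere_xyz[int(l)] for l in labels[cort]])
    rng = np.random.default_rng(seed)
    rots = special_ortho_group.rvs(3, size=n_perm, random_state=rng)
    rots = rots.reshape(n_perm, 3, 3)
    n = len(labels)
    cort_idx = np.flatnonzero(cort)
    sub_idx = np.flatnonzero(~cort)
    reassign = np.tile(np.arange(n), (n_perm, 1))
    for b in range(n_perm):
        rotated = xyz @ rots[b].T
        # region i takes the value of the cortical region nearest its rotated position
        d2 = ((rotated[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
        nearest = d2.argmin(axis=1)
        reassign[b, cort_idx] = cort_idx[nearest]
        if sub_idx.size:
            reassign[b, sub_idx] = rng.permutation(sub_idx)
    return SpinNull(rotations=rots, reassignments=reassign, labels=labels,
                    n_perm=n_perm, cortical=cort)


def fit_length_scale(values: np.ndarray, points: np.ndarray,
                     grid: np.ndarray | None = None) -> float:
    """Least-squares fit of a squared-exponential correlogram to the map's
    empirical distance-binned correlations."""
    values = (values - values.mean()) / values.std()
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    prod = np.outer(values, values)
    iu = np.triu_indices(len(values), k=1)
    dist, pp = d[iu], prod[iu]
    bins = np.quantile(dist, np.linspace(0, 0.6, 13))
    centers, corr = [], []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (dist >= lo) & (dist < hi)
        if sel.sum() > 10:
            centers.append(dist[sel].mean())
            corr.append(pp[sel].mean())
    centers = np.array(centers)
    corr = np.clip(np.array(corr), 1e-3, 1.0)
    if grid is None:
        grid = np.linspace(0.05, 1.5, 60)
    sse = [np.sum((np.exp(-centers ** 2 / (2 * l * l)) - corr) ** 2)
           for l in grid]
    return float(grid[int(np.argmin(sse))])


def conditional_spin_surrogates(values: np.ndarray, points: np.ndarray,
                                n_perm: int = 1000, seed: int = 0,
                                length_scale: float | None = None
                                ) -> np.ndarray:
    """Rotation surrogates by Gaussian-process conditional simulation.

    The observed map is modeled as one realization of an isotropic
    squared-exponential process on the sphere; each surrogate is that same
    realization re-evaluated at uniformly rotated coordinates, sampled from
    the exact conditional law given the observed values. Unlike
    nearest-centroid label reassignment, this preserves the map's spatial
    covariance exactly (up to kernel misfit), so the resulting permutation
    p-values are calibrated even for maps much smoother than the parcel
    spacing. The kernel length scale is fitted from the map's empirical
    correlogram when not supplied.
    """
    y = np.asarray(values, dtype=float)
    pts = np.asarray(points, dtype=float)
    if length_scale is None:
        length_scale = fit_length_scale(y, pts)
    rng = np.random.default_rng(seed)
    rots = special_ortho_group.rvs(3, size=n_perm, random_state=rng)
    rots = rots.reshape(n_perm, 3, 3)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    C = np.exp(-d2 / (2 * length_scale ** 2)) + 1e-6 * np.eye(len(pts))
    Cinv = np.linalg.inv(C)
    out = np.empty((n_perm, len(y)))
    mu, sd = y.mean(), y.std()
    ys = (y - mu) / sd
    for b in range(n_perm):
        rp = pts @ rots[b].T
        cross = np.exp(-((rp[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
                       / (2 * length_scale ** 2))
        A = cross @ Cinv
        mean = A @ ys
        cov = C - A @ cross.T
        # numerical floor: conditional covariance must stay PSD
        w, V = np.linalg.eigh((cov + cov.T) / 2)
        w = np.clip(w, 0, None)
        draw = mean + V @ (np.sqrt(w) * rng.standard_normal(len(y)))
        out[b] = mu + sd * draw
    return out


@dataclass
class GeneReport:
    gene: str
    weight: float
    boot_se: float
    z: float
    p: float
    fdr_p: float
    selected: bool
    sign: str  # PLS1+ or PLS1-
    in_reference_list: bool = False
    corr_with_map: float | None = None
    corr_fdr_p: float | None = None


def _pls1_single_response(Xs: np.ndarray, ys: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, float]:
    """PLS1 with a single standardized response: weights ∝ X'y."""
    c = Xs.T @ ys
    nrm = np.linalg.norm(c)
    if nrm == 0:
        return np.zeros_like(c), np.zeros(len(ys)), 0.0
    w = c / nrm
    t = Xs @ w
    denom = float(t @ t) * float(ys @ ys)
    ev = float((t @ ys) ** 2 / denom) if denom > 0 else 0.0
    return w, t, ev


def pls_genes(zmap: StatMap | np.ndarray, expr: ExpressionMatrix,
              spin: "SpinNull | np.ndarray", n_boot: int = 1000, seed: int = 0,
              z_threshold: float = 5.0, fdr_q: float = 0.05,
              cortical_only_boot: bool = False,
              region_labels: np.ndarray | None = None
              ) -> tuple[PlsResult, list[GeneReport]]:
    """PLS1 of regional expression (predictors) on a stage z-map (response).

    Spin p is the add-one fraction of rotated-response refits whose PLS1
    explained variance reaches the observed one; ``spin`` is either a
    label-reassignment SpinNull or a precomputed surrogate-map array
    (n_perm x n_regions, e.g. from conditional_spin_surrogates). The
    bootstrap resamples
    regions with replacement, refits, sign-aligns each draw's weights to the
    originals, and reports z = weight / bootstrap SE; genes pass selection
    when FDR-significant and |z| exceeds ``z_threshold``.
    """
    y = zmap.values if isinstance(zmap, StatMap) else np.asarray(zmap, dtype=float)
    if region_labels is not None:
        if len(region_labels) != len(y):
            raise SchemaError("region_labels length does not match map")
        if not np.array_equal(np.asarray(region_labels, int), expr.regions):
            bad = sorted(set(np.asarray(region_labels, int)) ^ set(expr.regions))
            raise SchemaError(f"region mismatch between map and expression: {bad}")
    if len(y) != expr.n_regions:
        raise SchemaError(f"map has {len(y)} regions, expression has "
                          f"{expr.n_regions}")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    Xs, _ = standardize(expr.values, warn="pls_genes expression")
    ys = (y - y.mean()) / y.std()
    w, t, ev = _pls1_single_response(Xs, ys)
    # orient PLS1 so scores track the response positively
    if float(t @ ys) < 0:
        w, t = -w, -t
    surrogates = spin if isinstance(spin, np.ndarray) else None
    n_spin = len(surrogates) if surrogates is not None else spin.n_perm
    null = np.empty(n_spin)
    for b in range(n_spin):
        yr = surrogates[b] if surrogates is not None else spin.apply(ys, b)
        yr = (yr - yr.mean()) / yr.std()
        _, _, null[b] = _pls1_single_response(Xs, yr)
    p_spin = float((1 + np.sum(null >= ev)) / (n_spin + 1))

    rng = np.random.default_rng(seed)
    n_regions = expr.n_regions
    # resampling pool: all analysis regions, or cortical regions only
    pool = np.arange(n_regions)
    if cortical_only_boot:
        if surrogates is not None or spin.cortical is None:
            raise ValidationError("cortical-only bootstrap needs a SpinNull "
                                  "with corticality flags")
        pool = np.flatnonzero(np.isin(expr.regions, spin.labels[spin.cortical]))
    boot_w = np.empty((n_boot, expr.n_genes))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.choice(pool, size=len(pool), replace=True)
        yb = y[idx]
        if yb.std() == 0:
            redraws += 1
            continue
        Xb, _ = standardize(expr.values[idx])
        ybs = (yb - yb.mean()) / yb.std()
        wb, _, _ = _pls1_single_response(Xb, ybs)
        if float(wb @ w) < 0:  # sign-align to the original weights
            wb = -wb
        boot_w[b] = wb
        b += 1
    if redraws:
        log.warning("redrew %d degenerate bootstrap draws (constant response)",
                    redraws)
    se = boot_w.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, w / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    rej, _ = fdr_bh(pvals, q=fdr_q)
    # BH-adjusted p-values for reporting
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((pvals[order] * m /
                                        np.arange(1, m + 1))[::-1])[::-1]
    adj = np.clip(adj, 0, 1)
    reports = []
    for g in range(expr.n_genes):
        selected = bool(rej[g] and abs(z[g]) > z_threshold)
        reports.append(GeneReport(
            gene=expr.genes[g], weight=float(w[g]), boot_se=float(se[g]),
            z=float(z[g]), p=float(pvals[g]), fdr_p=float(adj[g]),
            selected=selected, sign="PLS1+" if w[g] >= 0 else "PLS1-"))
    pls = PlsResult(x_weights=w, y_weights=np.ones(1), x_scores=t,
                    y_scores=ys, x_loadings=w, y_loadings=np.ones(1),
                    explained_variance=ev, perm_null=null, p_perm=p_spin,
                    y_names=("zmap",))
    return pls, reports


def top_decile_genes(reports: list[GeneReport]) -> list[str]:
    """Gene symbols in the top |z| decile — the bootstrap-ranked short list."""
    zs = np.array([abs(r.z) for r in reports])
    cut = np.quantile(zs, 0.9)
    return [r.gene for r in reports if abs(r.z) >= cut]


def overlap_reference(reports: list[GeneReport], reference: list[str],
                      expr: ExpressionMatrix | None = None,
                      case_map: np.ndarray | None = None,
                      q: float = 0.05, use_top_decile: bool = False
                      ) -> dict:
    """Intersect the selected genes with a reference list; correlate each
    overlapping gene's expression with the case-control map (FDR over the
    overlap set) and report counts split by correlation sign."""
    chosen = set(top_decile_genes(reports)) if use_top_decile else {
        r.gene for r in reports if r.selected}
    overlap = [g for g in reference if g in chosen]
    for r in reports:
        r.in_reference_list = r.gene in set(reference)
    result = {"overlap": overlap, "n_overlap": len(overlap),
              "n_selected": len(chosen), "n_reference": len(reference),
              "correlations": [], "n_positive": 0, "n_negative": 0}
    if not overlap or expr is None or case_map is None:
        return result
    gidx = {g: i for i, g in enumerate(expr.genes)}
    ps, rows = [], []
    for g in overlap:
        v = expr.values[:, gidx[g]]
        r, p = stats.pearsonr(v, case_map)
        rows.append({"gene": g, "r": float(r), "p": float(p)})
        ps.append(float(p))
    rej, _ = fdr_bh(np.array(ps), q=q)
    for row, sig in zip(rows, rej):
        row["significant_fdr"] = bool(sig)
    result["correlations"] = rows
    result["n_positive"] = sum(1 for row in rows if row["r"] > 0)
    result["n_negative"] = sum(1 for row in rows if row["r"] < 0)
    return result
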