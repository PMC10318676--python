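"""Synthetic cohorts with planted, duration-staged dysfunction.

The generator emulates the study conditions the pipeline is built for: a
patient/control cohort whose patients carry stage-specific parcel-level
dysfunction determined by disease duration, symptom scores linearly coupled
to each patient's dysfunction expression, a regions x genes expression
matrix with a planted gene subset spatially coupled to the first stage's
effect map, molecular template maps at a requested spatial correlation, and
unit-sphere centroids so spatial-autocorrelation-preserving nulls work.

Every draw flows from a single seed through named spawn keys, so multi-part
fixtures are reproducible piecewise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CONTROL,
    DEFAULT_FI_LIST,
    NETWORKS,
    PATIENT,
    ExpressionMatrix,
    Parcellation,
    SubjectRecord,
    ValidationError,
)

#: spawn keys for the per-purpose random streams
_STREAMS = {"geometry": 1, "effects": 2, "cohort": 3, "expression": 4,
            "templates": 5, "timeseries": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform points on the unit sphere (golden-angle lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def make_parcellation(n_cortical_per_hemi: int = 105,
                      n_subcortical_per_hemi: int = 18,
                      seed: int = 0) -> Parcellation:
    """A synthetic 2x(105 cortical + 18 subcortical) = 246-label parcellation.

    Left-hemisphere labels come first (ascending), mirroring an atlas whose
    metadata flags exactly half the labels L. Cortical labels get unit-sphere
    centroids; the seven cortical networks tile the sphere by latitude band
    and the subcortical labels form the eighth network.
    """
    per_hemi = n_cortical_per_hemi + n_subcortical_per_hemi
    n_total = 2 * per_hemi
    labels = np.arange(1, n_total + 1)
    cortex = _fibonacci_sphere(n_cortical_per_hemi)
    names, network, hemi, cort, xyz = {}, {}, {}, {}, {}
    cortical_nets = [n for n in NETWORKS if n != "subcortical"]
    for h_i, h in enumerate(("L", "R")):
        base = h_i * per_hemi
        order = np.argsort(cortex[:, 2])  # latitude-banded network assignment
        bands = np.array_split(order, len(cortical_nets))
        net_of = {}
        for b, net in zip(bands, cortical_nets):
            for j in b:
                net_of[j] = net
        for j in range(n_cortical_per_hemi):
            lab = int(labels[base + j])
            names[lab] = f"{h}_ctx_{j + 1}"
            network[lab] = net_of[j]
            hemi[lab] = h
            cort[lab] = True
            xyz[lab] = cortex[j].copy()
        for j in range(n_subcortical_per_hemi):
            lab = int(labels[base + n_cortical_per_hemi + j])
            names[lab] = f"{h}_sub_{j + 1}"
            network[lab] = "subcortical"
            hemi[lab] = h
            cort[lab] = False
    return Parcellation(labels=labels, names=names, network=network,
                        hemisphere=hemi, is_cortical=cort, sphere_xyz=xyz)


def _geometry(parc: Parcellation, seed: int) -> np.ndarray:
    """Unit-sphere points for every label (subcortical get interior draws)."""
    rng = _rng(seed, "geometry")
    pts = np.zeros((parc.n_labels, 3))
    for i, lab in enumerate(parc.labels):
        lab = int(lab)
        if parc.is_cortical[lab]:
            pts[i] = parc.sphere_xyz[lab]
        else:
            v = rng.normal(size=3)
            pts[i] = v / np.linalg.norm(v)
    return pts


def smooth_field(points: np.ndarray, rng: np.random.Generator,
                 length_scale: float = 0.6, n: int = 1) -> np.ndarray:
    """Draws from a Gaussian process with squared-exponential covariance on
    chordal distance — spatially autocorrelated parcel fields."""
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2 * length_scale ** 2)) + 1e-8 * np.eye(len(points))
    L = np.linalg.cholesky(cov)
    draws = (L @ rng.standard_normal((len(points), n)))
    return draws[:, 0] if n == 1 else draws.T


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic cohort."""

    n_stages_true: int
    stage_boundaries: np.ndarray  # cutpoints in years, strictly increasing
    effect_maps: dict[int, dict[str, np.ndarray]]  # stage -> fi -> d-scale map
    behavior_coupling: dict[int, dict[str, float]]  # stage -> PANSS weights
    panss_base: dict[int, dict[str, float]]
    coupled_genes: list[str]
    r_gene: float
    noise_sd: float
    rng_seed: int
    duration_max: float = 30.0
    effect_scale: float = 1.0  # data units per unit d (reference pooled SD)
    fi_list: tuple[str, ...] = DEFAULT_FI_LIST
    geometry: np.ndarray | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.stage_boundaries, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValidationError("stage boundaries must be strictly increasing")
        if not abs(self.r_gene) < 1:
            raise ValidationError("|r_gene| must be < 1")
        self.stage_boundaries = b

    def stage_of(self, duration: float) -> int:
        """1-based planted stage for a disease duration."""
        return int(np.searchsorted(self.stage_boundaries, duration,
                                   side="right")) + 1


# frozen FI-specific amplitude multipliers: each indicator expresses the
# shared stage pattern at a slightly different gain, as real indicators do
_FI_GAIN = {"falff": 1.0, "reho": 1.1, "gfcd": 0.9, "lfcd": 1.05, "lrfcd": 0.95}

# stage-wise symptom structure: positive-dominated early course, negative
# ascending to dominance, late positive rebound then negative surpassing
_PANSS_BASE = {
    1: {"positive": 18.0, "negative": 14.0, "general": 26.0},
    2: {"positive": 15.0, "negative": 18.0, "general": 28.0},
    3: {"positive": 13.0, "negative": 22.0, "general": 30.0},
    4: {"positive": 17.0, "negative": 21.0, "general": 29.0},
    5: {"positive": 12.0, "negative": 23.0, "general": 27.0},
}
_COUPLING = {
    1: {"positive": 3.0, "negative": 1.0, "general": 1.5},
    2: {"positive": 1.5, "negative": 2.5, "general": 1.5},
    3: {"positive": 1.0, "negative": 3.0, "general": 2.5},
    4: {"positive": 2.5, "negative": 2.0, "general": 1.5},
    5: {"positive": 1.0, "negative": 3.0, "general": 2.0},
}


def default_ground_truth(parc: Parcellation, seed: int = 0, n_stages: int = 5,
                         effect_d: float = 0.8, affected_fraction: float = 0.35,
                         noise_sd: float = 1.0, duration_max: float = 30.0,
                         r_gene: float = 0.7, n_coupled_genes: int = 10,
                         fi_list: tuple[str, ...] = DEFAULT_FI_LIST) -> GroundTruth:
    """Reference ground truth: equal-length stages over [0, duration_max],
    well-separated stage effect maps of amplitude ``effect_d`` on roughly
    ``affected_fraction`` of parcels, shared across indicators up to a fixed
    per-indicator gain."""
    pts = _geometry(parc, seed)
    rng = _rng(seed, "effects")
    fields = np.atleast_2d(smooth_field(pts, rng, n=n_stages))
    fields = fields - fields.mean(axis=1, keepdims=True)
    # sequential decorrelation: each stage field has the previously accepted
    # sparsified maps regressed out before its own sparsification, keeping
    # pairwise map correlations well separated
    bases: list[np.ndarray] = []
    for s in range(n_stages):
        f = fields[s].copy()
        for b in bases:
            bc = b - b.mean()
            f = f - (f @ bc) / (bc @ bc) * bc
        f = (f - f.mean()) / f.std()
        cut = np.quantile(np.abs(f), 1 - affected_fraction)
        bases.append(np.where(np.abs(f) >= cut, np.sign(f) * effect_d, 0.0))
    effect_maps: dict[int, dict[str, np.ndarray]] = {
        s: {fi: bases[s - 1] * _FI_GAIN.get(fi, 1.0) for fi in fi_list}
        for s in range(1, n_stages + 1)}
    boundaries = np.linspace(0, duration_max, n_stages + 1)[1:-1]
    # half-year offsets keep every sliding window's majority stage strict:
    # an integer boundary would split some windows exactly in half, leaving
    # their planted stage undefined
    boundaries = np.where(boundaries == np.round(boundaries),
                          boundaries - 0.5, boundaries)
    base = {s: dict(_PANSS_BASE.get(s, _PANSS_BASE[min(s, 5)]))
            for s in range(1, n_stages + 1)}
    coup = {s: dict(_COUPLING.get(s, _COUPLING[min(s, 5)]))
            for s in range(1, n_stages + 1)}
    return GroundTruth(
        n_stages_true=n_stages, stage_boundaries=boundaries,
        effect_maps=effect_maps, behavior_coupling=coup, panss_base=base,
        coupled_genes=[f"COUPLED{i + 1}" for i in range(n_coupled_genes)],
        r_gene=r_gene, noise_sd=noise_sd, rng_seed=seed,
        duration_max=duration_max, fi_list=tuple(fi_list), geometry=pts)


def null_ground_truth(parc: Parcellation, seed: int = 0,
                      **kwargs) -> GroundTruth:
    """Ground truth with every effect map zero — for calibration experiments."""
    gt = default_ground_truth(parc, seed=seed, **kwargs)
    for s in gt.effect_maps:
        for fi in gt.effect_maps[s]:
            gt.effect_maps[s][fi] = np.zeros_like(gt.effect_maps[s][fi])
    return gt


def _stratified_durations(n: int, dmax: float, rng: np.random.Generator
                          ) -> np.ndarray:
    """Marginally uniform durations over [0, dmax) with stratified (equal
    per-year-bin) coverage: the framework requires relatively uniform
    duration coverage, and stratification keeps every sliding window near
    its expected size instead of leaving chance gaps."""
    durs = (np.arange(n) + rng.uniform(0, 1, size=n)) * (dmax / n)
    return rng.permutation(durs)


def make_cohort(gt: GroundTruth, n_patients: int, n_controls: int,
                parc: Parcellation, mode: str = "parcel",
                ) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate subject records with planted stage-dependent dysfunction.

    Patient durations are uniform over [0, duration_max] (the framework
    needs relatively uniform duration coverage). In parcel mode a patient's
    FI value per parcel is control-mean + effect_d * pooled_sd + noise;
    symptom scores are an affine function of the subject's dysfunction
    expression plus noise. Returns (records, gt) with gt annotated.
    """
    if mode not in ("parcel", "timeseries"):
        raise ValidationError(f"unknown cohort mode {mode!r}")
    rng = _rng(gt.rng_seed, "cohort")
    n_parcels = parc.n_labels
    baseline = smooth_field(gt.geometry if gt.geometry is not None
                            else _geometry(parc, gt.rng_seed), rng)
    per_stage = {}  # achievability check: each stage needs >= 2 patients
    durations = _stratified_durations(n_patients, gt.duration_max, rng)
    for d in durations:
        per_stage[gt.stage_of(d)] = per_stage.get(gt.stage_of(d), 0) + 1
    for s in range(1, gt.n_stages_true + 1):
        if per_stage.get(s, 0) < 2:
            raise ValidationError(f"planted stage {s} received "
                                  f"{per_stage.get(s, 0)} patients; increase "
                                  f"n_patients")
    records: list[SubjectRecord] = []

    def _covs(g: np.random.Generator) -> dict:
        return dict(age=float(g.normal(40, 12)), sex="F" if g.random() < 0.3 else "M",
                    tiv=float(g.normal(1500, 150)),
                    motion=float(abs(g.normal(0.10, 0.05)) + 0.01))

    for i in range(n_controls):
        fi_data = {fi: baseline + rng.normal(0, gt.noise_sd, n_parcels)
                   for fi in gt.fi_list}
        records.append(SubjectRecord(id=f"hc{i + 1:03d}", group=CONTROL,
                                     fi_data=fi_data, **_covs(rng)))
    for i, d in enumerate(durations):
        s = gt.stage_of(d)
        fi_data = {}
        devs = []
        for fi in gt.fi_list:
            eff = gt.effect_maps[s][fi] * gt.effect_scale  # d-scale -> data units
            noise = rng.normal(0, gt.noise_sd, n_parcels)
            fi_data[fi] = baseline + eff + noise
            emap = gt.effect_maps[s][fi]
            norm = np.linalg.norm(emap)
            if norm > 0:
                # centered projection of this subject's deviation onto the
                # planted stage pattern (the stage-mean projection cancels)
                devs.append(float((eff + noise) @ emap) / norm
                            - norm * gt.effect_scale)
        # dysfunction expression: stage-centered pattern projection averaged
        # over indicators, ~N(0, 1/sqrt(n_fi))
        score = float(np.mean(devs)) if devs else 0.0
        base = gt.panss_base[s]
        coup = gt.behavior_coupling[s]
        panss = {}
        for k in ("positive", "negative", "general"):
            panss[k] = max(7.0, base[k] + coup[k] * score + rng.normal(0, 2.0))
        panss["total"] = panss["positive"] + panss["negative"] + panss["general"]
        morph = dict(gm=float(700 - 3.0 * d + rng.normal(0, 25)),
                     wm=float(500 + rng.normal(0, 20)),
                     csf=float(250 + 2.0 * d + rng.normal(0, 20)))
        records.append(SubjectRecord(
            id=f"sz{i + 1:03d}", group=PATIENT, duration_years=float(d),
            panss=panss, drug_equiv=float(max(25.0, rng.normal(338, 144))),
            morph=morph, fi_data=fi_data, **_covs(rng)))
    if mode == "timeseries":
        _attach_timeseries(records, gt, parc)
    return records, gt


# frozen calibration of the d -> signal mapping: the baseline mixing weight
# puts within-parcel correlations at the FCD threshold (bidirectional count
# sensitivity); planted d shifts the shared-component weight (driving
# ReHo/FCD) and the low-band power gain (driving fALFF)
_TS_MIX_BASE = 0.61
_TS_MIX_PER_D = 0.15
_TS_POWER_PER_D = 0.30


def make_series(effect_d: np.ndarray, parc_labels_of_voxel: np.ndarray,
                coords: np.ndarray, rng: np.random.Generator, n_t: int = 120,
                tr: float = 2.0):
    """Band-limited voxel time series realizing parcel effects ``effect_d``.

    Each voxel mixes a parcel-shared 0.01–0.08 Hz component with voxel
    noise; planted d raises both the shared-mixing weight (driving ReHo and
    connectivity density) and the low-band power (driving fALFF).
    """
    from .indicators import SeriesBlock

    t = np.arange(n_t) * tr
    freqs = np.fft.rfftfreq(n_t, d=tr)
    band = (freqs >= 0.01) & (freqs <= 0.08)

    def bandlimited(g, n=1):
        spec = np.zeros((n, len(freqs)), dtype=complex)
        spec[:, band] = g.standard_normal((n, band.sum())) + \
            1j * g.standard_normal((n, band.sum()))
        x = np.fft.irfft(spec, n=n_t, axis=1)
        return x / x.std(axis=1, keepdims=True)

    parcels = np.unique(parc_labels_of_voxel)
    shared = {lab: bandlimited(rng)[0] for lab in parcels}
    n_v = len(parc_labels_of_voxel)
    data = np.zeros((n_v, n_t))
    for v in range(n_v):
        lab = parc_labels_of_voxel[v]
        d = float(effect_d[lab]) if lab < len(effect_d) else 0.0
        w = np.clip(_TS_MIX_BASE + _TS_MIX_PER_D * d, 0.05, 0.95)
        amp = 1.0 + _TS_POWER_PER_D * d
        slow = bandlimited(rng)[0]
        fast = rng.standard_normal(n_t)
        fast = fast / fast.std()
        data[v] = amp * (w * shared[lab] + (1 - w) * slow) + (1 - w) * 0.8 * fast
    return SeriesBlock(data=data, tr=tr, coords=coords)


def make_toy_volume_parcellation(shape=(6, 6, 6), n_labels: int = 8) -> np.ndarray:
    """A block label volume for timeseries-mode tests."""
    vol = np.zeros(shape, dtype=int)
    xs = np.array_split(np.arange(shape[0]), min(n_labels, shape[0]))
    for i, sl in enumerate(xs):
        vol[sl, :, :] = (i % n_labels) + 1
    return vol


def _attach_timeseries(records, gt: GroundTruth, parc: Parcellation,
                       shape=(12, 5, 4), n_t: int = 120) -> None:
    """Replace parcel fi_data with values computed from synthesized series
    on a toy grid (first len(grid-labels) atlas parcels only)."""
    from .indicators import compute_all

    rng = _rng(gt.rng_seed, "timeseries")
    vol = make_toy_volume_parcellation(shape=shape, n_labels=min(8, parc.n_labels))
    coords = np.argwhere(vol > 0).astype(float)
    labv = vol[vol > 0] - 1  # 0-based parcel index per voxel
    n_lab = labv.max() + 1
    for rec in records:
        if rec.is_patient:
            s = gt.stage_of(rec.duration_years)
            eff = gt.effect_maps[s][gt.fi_list[0]][:n_lab]
        else:
            eff = np.zeros(n_lab)
        series = make_series(eff, labv, coords, rng, n_t=n_t)
        fis = compute_all(series)
        rec.fi_data = {}
        for fi, smap in fis.items():
            vals = np.zeros(n_lab)
            for lab in range(n_lab):
                vals[lab] = smap.values[labv == lab].mean()
            rec.fi_data[fi] = vals


def _coupled_vector(target: np.ndarray, noise: np.ndarray, r: float) -> np.ndarray:
    """A vector whose sample Pearson correlation with ``target`` is exactly r."""
    e = (target - target.mean()) / target.std()
    g = noise - noise.mean()
    g = g - (g @ e) / (e @ e) * e
    if g.std() == 0:
        raise ValidationError("degenerate noise field; cannot reach target r")
    g = g / g.std()
    return r * e + np.sqrt(1 - r * r) * g


def make_expression(gt: GroundTruth, parc: Parcellation, n_genes: int = 500,
                    ) -> ExpressionMatrix:
    """Left-hemisphere regions x genes matrix with the planted coupled set.

    Coupled genes hit the target correlation ``gt.r_gene`` against the
    stage-1 effect map exactly (by construction); the remaining genes are
    smooth spatially autocorrelated fields, so spin nulls are meaningful.
    """
    if n_genes < len(gt.coupled_genes):
        raise ValidationError("n_genes smaller than the planted coupled set")
    rng = _rng(gt.rng_seed, "expression")
    left = parc.left_labels
    idx = parc.index_of(left)
    pts = (gt.geometry if gt.geometry is not None else _geometry(parc, gt.rng_seed))[idx]
    target = gt.effect_maps[1][gt.fi_list[0]][idx]
    if target.std() == 0:
        target = smooth_field(pts, rng)  # null ground truth: arbitrary target
    n_coupled = len(gt.coupled_genes)
    fields = np.atleast_2d(smooth_field(pts, rng, n=n_genes))
    genes, values = [], []
    for j in range(n_genes):
        if j < n_coupled:
            v = _coupled_vector(target, fields[j], gt.r_gene)
            genes.append(gt.coupled_genes[j])
        else:
            v = (fields[j] - fields[j].mean()) / fields[j].std()
            genes.append(f"GENE{j - n_coupled + 1}")
        values.append(v + rng.normal(5.0, 0.5))  # expression-like offset
    return ExpressionMatrix(regions=left, genes=genes,
                            values=np.array(values).T)


def make_templates(gt: GroundTruth, parc: Parcellation, r: float = 0.6,
                   stage: int = 1) -> dict[str, np.ndarray]:
    """One molecular-style template correlated at ``r`` with a chosen stage
    effect map and one independent smooth template."""
    rng = _rng(gt.rng_seed, "templates")
    pts = gt.geometry if gt.geometry is not None else _geometry(parc, gt.rng_seed)
    target = gt.effect_maps[stage][gt.fi_list[0]]
    coupled = (_coupled_vector(target, smooth_field(pts, rng), r)
               if target.std() > 0 else smooth_field(pts, rng))
    independent = smooth_field(pts, rng)
    return {"dopamine_coupled": coupled, "independent": independent}


def make_gradients(gt: GroundTruth, parc: Parcellation) -> dict[str, np.ndarray]:
    """Two smooth orthogonal axis fields standing in for cortical gradients
    (principal and secondary axes of the centroid cloud)."""
    pts = gt.geometry if gt.geometry is not None else _geometry(parc, gt.rng_seed)
    return {"g1": pts[:, 2].copy(), "g2": pts[:, 0].copy()}


def planted_window_stages(gt: GroundTruth, windows, patients) -> dict[int, int]:
    """Ground-truth stage per window: the majority planted stage among its
    member patients (used to score recovery)."""
    by_id = {p.id: p for p in patients}
    out = {}
    for w in windows:
        stages = [gt.stage_of(by_id[i].duration_years) for i in w.patient_ids]
        vals, cnt = np.unique(stages, return_counts=True)
        out[w.index] = int(vals[np.argmax(cnt)])
    return out


def write_cohort(out_dir: str | Path, records: list[SubjectRecord],
                 gt: GroundTruth, parc: Parcellation,
                 expr: ExpressionMatrix | None = None,
                 templates: dict[str, np.ndarray] | None = None,
                 gradients: dict[str, np.ndarray] | None = None) -> None:
    """Write the same text formats the loaders read, plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        row = dict(id=r.id, group=r.group, age=r.age, sex=r.sex, tiv=r.tiv,
                   motion=r.motion, duration_years=r.duration_years,
                   drug_equiv=r.drug_equiv)
        for k in ("positive", "negative", "general", "total"):
            row[f"panss_{k}"] = (r.panss or {}).get(k)
        for k in ("gm", "wm", "csf"):
            row[f"{k}_volume"] = (r.morph or {}).get(k)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    fi_dir = out / "fi"
    fi_dir.mkdir(exist_ok=True)
    for fi in gt.fi_list:
        df = pd.DataFrame([r.fi_data[fi] for r in records])
        df.insert(0, "id", [r.id for r in records])
        df.to_csv(fi_dir / f"{fi}.csv", index=False)
    meta = pd.DataFrame({
        "label": parc.labels,
        "name": [parc.names[int(l)] for l in parc.labels],
        "network": [parc.network[int(l)] for l in parc.labels],
        "hemisphere": [parc.hemisphere[int(l)] for l in parc.labels],
        "is_cortical": [parc.is_cortical[int(l)] for l in parc.labels],
    })
    for ax_i, ax in enumerate("xyz"):
        meta[ax] = [parc.sphere_xyz[int(l)][ax_i] if int(l) in parc.sphere_xyz
                    else np.nan for l in parc.labels]
    meta.to_csv(out / "parcellation.csv", index=False)
    if expr is not None:
        from .io import save_expression
        save_expression(expr, out / "expression.tsv")
    for name, vecs in (("templates", templates), ("gradients", gradients)):
        if vecs is not None:
            df = pd.DataFrame({"label": parc.labels, **vecs})
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    gt_json = dict(n_stages_true=gt.n_stages_true,
                   stage_boundaries=gt.stage_boundaries.tolist(),
                   coupled_genes=gt.coupled_genes, r_gene=gt.r_gene,
                   noise_sd=gt.noise_sd, rng_seed=gt.rng_seed,
                   duration_max=gt.duration_max, fi_list=list(gt.fi_list))
    (out / "ground_truth.json").write_text(json.dumps(gt_json, indent=2))
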