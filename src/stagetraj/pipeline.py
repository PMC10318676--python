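"""End-to-end orchestration: simulate -> stages -> behavior -> genes ->
spatial, with a manifest for provenance and idempotent re-runs.

The non-progressive branch (all patients vs all controls, one window) runs
through the same association operations, so the two analyses differ only in
how subjects are grouped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (build_feature_matrix, compare_panss_between_stages,
                       control_correlations, network_loadings, panss_matrix,
                       pls_behavior, region_loadings, score_correlations)
from .genes import build_spin, overlap_reference, pls_genes
from .io import load_cohort, load_expression, load_parcel_vectors, load_parcellation
from .spatial import gradient_profile, template_correlation
from .stages import PipelineError, adjusted_tmap, discover_stages, t_to_z
from .synthetic import (default_ground_truth, make_cohort, make_expression,
                        make_gradients, make_parcellation, make_templates,
                        write_cohort)
from .types import RunConfig, StatMap

log = logging.getLogger("stagetraj")

STEPS = ("simulate", "stages", "behavior", "genes", "spatial", "nonprogressive")


def _dump_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def simulate_step(cfg: RunConfig, workdir: Path, n_patients: int = 90,
                  n_controls: int = 120) -> None:
    """Write a reference synthetic cohort into workdir/cohort."""
    parc = make_parcellation(seed=cfg.rng_seed)
    gt = default_ground_truth(parc, seed=cfg.rng_seed, fi_list=cfg.fi_list)
    records, gt = make_cohort(gt, n_patients, n_controls, parc)
    expr = make_expression(gt, parc, n_genes=200)
    templates = make_templates(gt, parc)
    gradients = make_gradients(gt, parc)
    write_cohort(workdir / "cohort", records, gt, parc, expr=expr,
                 templates=templates, gradients=gradients)
    (workdir / "cohort" / "reference_genes.txt").write_text(
        "\n".join(gt.coupled_genes) + "\n")


def run_all(cfg: RunConfig, workdir: str | Path, force: bool = False,
            n_patients: int = 90, n_controls: int = 120) -> dict:
    """Execute the full analysis in ``workdir``; returns the manifest.

    Completed steps (detected by their primary output file) are skipped
    unless ``force``. Any failure aborts with the step name and path.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(cfg), "seed": cfg.rng_seed,
                "version": __version__, "numpy": np.__version__,
                "steps": {}}
    markers = {
        "simulate": workdir / "cohort" / "subjects.csv",
        "stages": workdir / "stages" / "stages.json",
        "behavior": workdir / "behavior" / "behavior.json",
        "genes": workdir / "genes" / "gene_report.tsv",
        "spatial": workdir / "spatial" / "spatial_assoc.tsv",
        "nonprogressive": workdir / "nonprogressive" / "gene_report.tsv",
    }

    state: dict = {}
    for step in STEPS:
        t0 = time.perf_counter()
        if markers[step].exists() and not force:
            manifest["steps"][step] = {"status": "skipped"}
            log.info("step %s: output exists, skipped", step)
            continue
        try:
            _run_step(step, cfg, workdir, state, n_patients, n_controls)
        except Exception as exc:
            raise PipelineError(f"step {step!r} failed (expected output "
                                f"{markers[step]}): {exc}") from exc
        manifest["steps"][step] = {"status": "completed",
                                   "seconds": round(time.perf_counter() - t0, 3)}
    _dump_json(manifest, workdir / "manifest.json")
    return manifest


def _load_inputs(cfg: RunConfig, workdir: Path, state: dict) -> None:
    if "records" in state:
        return
    cohort_dir = workdir / "cohort"
    state["parc"] = load_parcellation(None, cohort_dir / "parcellation.csv")
    state["records"] = load_cohort(cohort_dir / "subjects.csv",
                                   cohort_dir / "fi", fi_list=cfg.fi_list)
    state["patients"] = [r for r in state["records"] if r.is_patient]
    state["controls"] = [r for r in state["records"] if not r.is_patient]
    state["expr"] = load_expression(cohort_dir / "expression.tsv")
    state["templates"] = load_parcel_vectors(cohort_dir / "templates.tsv")
    state["gradients"] = load_parcel_vectors(cohort_dir / "gradients.tsv")
    ref = cohort_dir / "reference_genes.txt"
    state["reference_genes"] = (ref.read_text().split() if ref.exists() else [])


def _stage_table(result) -> list[dict]:
    rows = []
    for st in result.stages:
        rows.append({"id": st.id, "member_windows": st.member_windows,
                     "n_patients": len(st.patient_ids),
                     "duration_mean": round(st.duration_label[0], 4),
                     "duration_min": round(st.duration_label[1], 4),
                     "duration_max": round(st.duration_label[2], 4),
                     "per_fi_states": st.per_fi_states})
    return rows


def _run_step(step: str, cfg: RunConfig, workdir: Path, state: dict,
              n_patients: int, n_controls: int) -> None:
    if step == "simulate":
        simulate_step(cfg, workdir, n_patients, n_controls)
        return
    _load_inputs(cfg, workdir, state)
    parc = state["parc"]

    if step == "stages":
        result = discover_stages(state["patients"], state["controls"], cfg)
        state["result"] = result
        out = workdir / "stages"
        out.mkdir(exist_ok=True)
        _dump_json(_stage_table(result), out / "stages.json")
        _dump_json({fi: {"n_states": ss.n_states,
                         "assignments": {str(k): v for k, v in
                                         sorted(ss.assignments.items())},
                         "ch_score": None if not np.isfinite(ss.ch_score)
                         else round(ss.ch_score, 6)}
                    for fi, ss in result.state_sets.items()},
                   out / "states.json")
        for st in result.stages:
            df = pd.DataFrame({"label": parc.labels})
            for name, zm in st.z_maps.items():
                df[f"z_{name}"] = zm.values
                df[f"sig_{name}"] = st.sig_masks[name].astype(int)
            df.to_csv(out / f"stage{st.id}_zmaps.csv", index=False)
        return

    if "result" not in state:
        state["result"] = discover_stages(state["patients"], state["controls"], cfg)
    result = state["result"]
    by_id = {p.id: p for p in state["patients"]}

    if step == "behavior":
        out = {"stages": [], "panss_comparisons": [], "controls": {}}
        n_fi = len(cfg.fi_list)
        for st in result.stages:
            members = [by_id[i] for i in st.patient_ids if by_id[i].panss]
            if len(members) < 10:
                out["stages"].append({"stage": st.id, "skipped": "too few subjects"})
                continue
            X = build_feature_matrix(members, cfg.fi_list)
            Y = panss_matrix(members)
            pls = pls_behavior(X, Y, n_perm=cfg.n_perm, seed=cfg.rng_seed,
                               store_null_loadings=True)
            nets = network_loadings(pls, parc, n_fi=n_fi, q=cfg.fdr_q)
            sig_frac = st.sig_masks["fused"].astype(float)
            regs = region_loadings(pls, sig_frac, n_fi=n_fi,
                                   fraction=cfg.voxel_abnormal_fraction)
            out["stages"].append({
                "stage": st.id, "explained_variance": round(pls.explained_variance, 6),
                "p_perm": pls.p_perm,
                "score_correlations": score_correlations(pls, Y, q=cfg.fdr_q),
                "network_loadings": nets, "n_abnormal_regions": len(regs)})
        out["panss_comparisons"] = compare_panss_between_stages(
            result.stages, state["patients"], n_perm=min(cfg.n_perm, 1000),
            seed=cfg.rng_seed, q=cfg.fdr_q)
        out["controls"] = control_correlations(state["records"],
                                               n_perm=min(cfg.n_perm, 1000),
                                               seed=cfg.rng_seed)
        _dump_json(out, workdir / "behavior" / "behavior.json")
        return

    if step == "genes":
        expr = state["expr"]
        left_idx = parc.index_of(expr.regions)
        spin = build_spin(parc, n_perm=cfg.n_perm, seed=cfg.rng_seed,
                          labels=expr.regions)
        rows = []
        summary = []
        for st in result.stages:
            zleft = st.z_maps["fused"].values[left_idx]
            pls, reports = pls_genes(zleft, expr, spin, n_boot=cfg.n_boot,
                                     seed=cfg.rng_seed,
                                     z_threshold=cfg.z_gene_threshold,
                                     fdr_q=cfg.fdr_q)
            ov = overlap_reference(reports, state["reference_genes"], expr,
                                   case_map=zleft, q=cfg.fdr_q,
                                   use_top_decile=True)
            summary.append({"stage": st.id, "p_spin": pls.p_perm,
                            "explained_variance": round(pls.explained_variance, 6),
                            "n_selected": sum(r.selected for r in reports),
                            "n_overlap_reference": ov["n_overlap"]})
            for r in reports:
                rows.append({"stage": st.id, "gene": r.gene,
                             "weight": r.weight, "z": r.z, "fdr_p": r.fdr_p,
                             "sign": r.sign, "selected": int(r.selected),
                             "in_reference": int(r.in_reference_list)})
        (workdir / "genes").mkdir(exist_ok=True)
        pd.DataFrame(rows).to_csv(workdir / "genes" / "gene_report.tsv",
                                  sep="\t", index=False, float_format="%.10g")
        _dump_json(summary, workdir / "genes" / "pls.json")
        return

    if step == "spatial":
        spin = build_spin(parc, n_perm=min(cfg.n_perm, 500), seed=cfg.rng_seed,
                          labels=parc.labels[
                              [parc.is_cortical[int(l)] for l in parc.labels]])
        cort_idx = parc.index_of(spin.labels)
        maps = {f"stage{st.id}_fused": st.z_maps["fused"] for st in result.stages}
        tcorr = template_correlation(maps, state["templates"], spin=spin,
                                     region_idx=cort_idx)
        grads = state["gradients"]
        prof = gradient_profile([st.z_maps["fused"] for st in result.stages],
                                grads["g1"], grads["g2"], cortical_idx=cort_idx)
        (workdir / "spatial").mkdir(exist_ok=True)
        pd.DataFrame(tcorr).to_csv(workdir / "spatial" / "spatial_assoc.tsv",
                                   sep="\t", index=False, float_format="%.10g")
        _dump_json(prof, workdir / "spatial" / "gradient_profile.json")
        return

    if step == "nonprogressive":
        # one-window special case: every patient against every control
        expr = state["expr"]
        left_idx = parc.index_of(expr.regions)
        pat = state["patients"]
        con = state["controls"]
        covs_p = np.vstack([p.covariates() for p in pat])
        covs_c = np.vstack([c.covariates() for c in con])
        zmaps = {}
        for fi in cfg.fi_list:
            tm = adjusted_tmap(np.vstack([p.fi_data[fi] for p in pat]),
                               np.vstack([c.fi_data[fi] for c in con]),
                               covs_p, covs_c, fi=fi)
            zmaps[fi] = StatMap(values=t_to_z(tm.values, tm.df), kind="z", fi=fi)
        fused = StatMap(values=np.mean([z.values for z in zmaps.values()], axis=0)
                        * np.sqrt(len(zmaps)), kind="z", fi="fused")
        spin = build_spin(parc, n_perm=cfg.n_perm, seed=cfg.rng_seed,
                          labels=expr.regions)
        pls, reports = pls_genes(fused.values[left_idx], expr, spin,
                                 n_boot=cfg.n_boot, seed=cfg.rng_seed,
                                 z_threshold=cfg.z_gene_threshold,
                                 fdr_q=cfg.fdr_q)
        outdir = workdir / "nonprogressive"
        outdir.mkdir(exist_ok=True)
        pd.DataFrame([{"gene": r.gene, "weight": r.weight, "z": r.z,
                       "fdr_p": r.fdr_p, "sign": r.sign,
                       "selected": int(r.selected)} for r in reports]
                     ).to_csv(outdir / "gene_report.tsv", sep="\t", index=False,
                              float_format="%.10g")
        cort_mask = [parc.is_cortical[int(l)] for l in parc.labels]
        spin_c = build_spin(parc, n_perm=min(cfg.n_perm, 500), seed=cfg.rng_seed,
                            labels=parc.labels[cort_mask])
        cort_idx = parc.index_of(spin_c.labels)
        tcorr = template_correlation({"all_patients_fused": fused},
                                     state["templates"], spin=spin_c,
                                     region_idx=cort_idx)
        pd.DataFrame(tcorr).to_csv(outdir / "spatial_assoc.tsv", sep="\t",
                                   index=False, float_format="%.10g")
        _dump_json({"p_spin": pls.p_perm,
                    "explained_variance": round(pls.explained_variance, 6),
                    "n_selected": sum(r.selected for r in reports)},
                   outdir / "pls.json")
        return
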