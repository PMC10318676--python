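"""File I/O: cohort tables, atlas volumes and metadata, expression matrices,
NIfTI statistical maps, YAML configuration.

Tabular formats are CSV/TSV (delimiter sniffed from the extension); volumes
are NIfTI-1 via nibabel, written float32. Loaders are deterministic and
order-stable: rows keep file order, parcel vectors follow ascending label.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import (
    CONTROL,
    PATIENT,
    ExpressionMatrix,
    Parcellation,
    RunConfig,
    SchemaError,
    StatMap,
    SubjectRecord,
    ValidationError,
)

log = logging.getLogger("stagetraj")

_COHORT_REQUIRED = ("id", "group", "age", "sex", "tiv", "motion")
_PANSS_COLS = ("panss_positive", "panss_negative", "panss_general", "panss_total")
_MORPH_COLS = ("gm_volume", "wm_volume", "csf_volume")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def load_cohort(subject_table: str | Path, fi_source: str | Path | None = None,
                fi_list: Sequence[str] | None = None) -> list[SubjectRecord]:
    """Load and validate subject records, optionally attaching parcel FI data.

    ``fi_source`` may be a directory of per-indicator CSVs named
    ``<fi>.csv`` with one row per subject (first column = subject id,
    remaining columns = parcel values in ascending-label order).
    """
    df = _read_table(subject_table)
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"subject table missing required column(s): {missing}")
    if "duration_years" not in df.columns and (df["group"] == PATIENT).any():
        raise SchemaError("subject table missing required column(s): ['duration_years']")
    if df["id"].astype(str).duplicated().any():
        dupes = df["id"][df["id"].astype(str).duplicated()].tolist()
        raise ValidationError(f"duplicated subject id(s): {dupes}")
    if df.empty:
        log.warning("subject table %s is empty", subject_table)
        return []

    fi_tables: dict[str, pd.DataFrame] = {}
    if fi_source is not None:
        fi_source = Path(fi_source)
        names = fi_list if fi_list is not None else sorted(
            p.stem for p in fi_source.glob("*.csv"))
        for fi in names:
            t = pd.read_csv(fi_source / f"{fi}.csv")
            fi_tables[fi] = t.set_index(t.columns[0])

    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        group = str(row["group"]).strip().lower()
        dur = row.get("duration_years")
        dur = None if dur is None or pd.isna(dur) else float(dur)
        if group == PATIENT and dur is None:
            raise ValidationError(f"patient {row['id']} has no duration_years")
        if group == CONTROL and dur is not None:
            raise ValidationError(f"control {row['id']} must not carry a duration")
        panss = None
        if all(c in df.columns for c in _PANSS_COLS) and not any(
                pd.isna(row[c]) for c in _PANSS_COLS):
            panss = {c.split("_", 1)[1]: float(row[c]) for c in _PANSS_COLS}
        morph = None
        if all(c in df.columns for c in _MORPH_COLS) and not any(
                pd.isna(row[c]) for c in _MORPH_COLS):
            morph = {c.split("_", 1)[0]: float(row[c]) for c in _MORPH_COLS}
        drug = row.get("drug_equiv")
        drug = None if drug is None or pd.isna(drug) else float(drug)
        fi_data = None
        if fi_tables:
            sid = str(row["id"])
            fi_data = {fi: t.loc[sid].to_numpy(dtype=float) for fi, t in fi_tables.items()}
        records.append(SubjectRecord(
            id=str(row["id"]), group=group, age=float(row["age"]), sex=str(row["sex"]),
            tiv=float(row["tiv"]), motion=float(row["motion"]), duration_years=dur,
            panss=panss, drug_equiv=drug, morph=morph, fi_data=fi_data))
    log.info("loaded %d subjects (%d patients)", len(records),
             sum(r.is_patient for r in records))
    return records


def load_parcellation(atlas: str | Path | None, meta: str | Path) -> Parcellation:
    """Build a Parcellation from an optional label volume plus a metadata table.

    The metadata table needs columns: label, name, network, hemisphere,
    is_cortical, x, y, z (sphere coordinates; NaN allowed for non-cortical).
    """
    mdf = _read_table(meta)
    required = ("label", "name", "network", "hemisphere", "is_cortical")
    missing = [c for c in required if c not in mdf.columns]
    if missing:
        raise SchemaError(f"atlas metadata missing column(s): {missing}")
    labels = np.sort(mdf["label"].to_numpy(dtype=int))
    label_volume = None
    if atlas is not None:
        img = nib.load(str(atlas))
        label_volume = np.asarray(img.dataobj).astype(int)
        in_vol = set(np.unique(label_volume)) - {0}
        unknown = in_vol - set(int(l) for l in labels)
        if unknown:
            raise SchemaError(f"labels present in volume but absent from metadata: "
                              f"{sorted(unknown)}")
    mdf = mdf.set_index(mdf["label"].astype(int))
    names = {int(l): str(mdf.loc[l, "name"]) for l in labels}
    network = {int(l): str(mdf.loc[l, "network"]) for l in labels}
    hemi = {int(l): str(mdf.loc[l, "hemisphere"]) for l in labels}
    cort = {int(l): bool(mdf.loc[l, "is_cortical"]) for l in labels}
    xyz = {}
    for l in labels:
        l = int(l)
        if {"x", "y", "z"} <= set(mdf.columns):
            v = mdf.loc[l, ["x", "y", "z"]].to_numpy(dtype=float)
            if np.all(np.isfinite(v)):
                n = np.linalg.norm(v)
                xyz[l] = v / n if n > 0 else v
    return Parcellation(labels=labels, names=names, network=network, hemisphere=hemi,
                        is_cortical=cort, sphere_xyz=xyz, label_volume=label_volume)


def parcel_average(values: np.ndarray | StatMap, parc: Parcellation,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Average a voxel field within each parcel; NaN where a parcel is empty.

    Returns one value per label, ascending-label order.
    """
    if isinstance(values, StatMap):
        mask = values.mask if mask is None else mask
        values = values.values
    if parc.label_volume is None:
        raise SchemaError("parcellation has no label volume; cannot parcel-average")
    vol = np.asarray(values, dtype=float)
    if vol.shape != parc.label_volume.shape:
        raise SchemaError(f"grid mismatch: data {vol.shape} vs atlas "
                          f"{parc.label_volume.shape}")
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    out = np.full(parc.n_labels, np.nan)
    lab_flat = parc.label_volume[mask]
    val_flat = vol[mask]
    for i, lab in enumerate(parc.labels):
        sel = lab_flat == lab
        if sel.any():
            out[i] = val_flat[sel].mean()
        else:
            log.warning("parcel %d has no in-mask voxels; flagged missing", lab)
    return out


def save_statmap(smap: StatMap, path: str | Path,
                 affine: np.ndarray | None = None) -> None:
    """Write a voxel StatMap as float32 NIfTI (out-of-mask voxels = NaN)."""
    data = smap.values.astype(np.float32).copy()
    data[~smap.mask] = np.nan
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_statmap(path: str | Path, kind: str = "t", fi: str | None = None,
                 df: float | None = None) -> StatMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(float)
    mask = np.isfinite(data)
    data[~mask] = 0.0
    return StatMap(values=data, kind=kind, fi=fi, df=df, mask=mask)


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a regions x genes table: first column = region label, header = genes."""
    df = _read_table(path)
    regions = df.iloc[:, 0].to_numpy(dtype=int)
    genes = [str(c) for c in df.columns[1:]]
    return ExpressionMatrix(regions=regions, genes=genes,
                            values=df.iloc[:, 1:].to_numpy(dtype=float))


def save_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.genes)
    df.insert(0, "region", expr.regions)
    df.to_csv(path, sep="\t", index=False)


def load_parcel_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Read named parcel vectors from a TSV/CSV: first column = label."""
    df = _read_table(path)
    df = df.sort_values(df.columns[0])
    return {str(c): df[c].to_numpy(dtype=float) for c in df.columns[1:]}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
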