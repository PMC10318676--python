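"""Core domain types for duration-sliding stage analysis.

All inter-module exchange happens at parcel level by default: a map is a
float vector ordered by ascending atlas label. Voxel-level maps carry a
boolean mask on the same grid. Volumes are stored float32 on disk;
statistics are computed in float64.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

PATIENT = "patient"
CONTROL = "control"

#: canonical functional-indicator names, in pipeline order
DEFAULT_FI_LIST = ("falff", "reho", "gfcd", "lfcd", "lrfcd")

#: the eight large-scale networks used for loading summaries
NETWORKS = (
    "visual",
    "sensorimotor",
    "salience",
    "dorsal_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
    "subcortical",
)


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass
class SubjectRecord:
    """One participant: group membership, duration, covariates, scores, FI data.

    ``fi_data`` maps indicator name -> parcel vector (float array ordered by
    ascending label); in volume workflows it may instead hold a path handle
    resolved by the I/O layer.
    """

    id: str
    group: str
    age: float
    sex: str
    tiv: float
    motion: float
    duration_years: float | None = None
    panss: dict[str, float] | None = None
    drug_equiv: float | None = None
    morph: dict[str, float] | None = None
    fi_data: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.group not in (PATIENT, CONTROL):
            raise ValidationError(f"subject {self.id}: unknown group {self.group!r}")
        if self.group == PATIENT:
            if self.duration_years is None:
                raise ValidationError(f"patient {self.id} has no duration_years")
            if self.duration_years < 0:
                raise ValidationError(f"patient {self.id}: negative duration")
        elif self.duration_years is not None:
            raise ValidationError(f"control {self.id} must not carry a duration")
        for name, v in (("age", self.age), ("tiv", self.tiv), ("motion", self.motion)):
            if not np.isfinite(v):
                raise ValidationError(f"subject {self.id}: non-finite covariate {name}")
        if self.panss is not None:
            tot, pos = self.panss.get("total"), self.panss.get("positive")
            if tot is not None and pos is not None and tot < pos:
                raise ValidationError(f"subject {self.id}: PANSS total < positive")

    @property
    def is_patient(self) -> bool:
        return self.group == PATIENT

    def covariates(self) -> np.ndarray:
        """Nuisance covariates (age, sex as 0/1, TIV, motion), float64."""
        sex01 = 1.0 if str(self.sex).upper().startswith("F") else 0.0
        return np.array([self.age, sex01, self.tiv, self.motion], dtype=float)


@dataclass
class Parcellation:
    """An integer-labelled brain parcellation with region metadata.

    ``labels`` are the atlas labels in ascending order; every per-parcel
    vector in the package follows this order. ``sphere_xyz`` rows are unit
    vectors for cortical labels and NaN for non-cortical ones.
    """

    labels: np.ndarray
    names: Mapping[int, str]
    network: Mapping[int, str]
    hemisphere: Mapping[int, str]
    is_cortical: Mapping[int, bool]
    sphere_xyz: Mapping[int, np.ndarray]
    label_volume: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        for lab in self.labels:
            lab = int(lab)
            for m, what in ((self.names, "name"), (self.network, "network"),
                            (self.hemisphere, "hemisphere"), (self.is_cortical, "is_cortical")):
                if lab not in m:
                    raise SchemaError(f"label {lab} missing {what} metadata")
            if self.is_cortical[lab]:
                xyz = np.asarray(self.sphere_xyz.get(lab))
                if xyz is None or xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                    raise SchemaError(f"cortical label {lab} lacks sphere coordinates")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def left_labels(self) -> np.ndarray:
        """Ascending labels flagged L — the left-hemisphere analysis set."""
        return np.array([l for l in self.labels if self.hemisphere[int(l)] == "L"], dtype=int)

    def index_of(self, labels: Sequence[int]) -> np.ndarray:
        """Positions of ``labels`` within the canonical ascending order."""
        pos = {int(l): i for i, l in enumerate(self.labels)}
        return np.array([pos[int(l)] for l in labels], dtype=int)

    def network_members(self) -> dict[str, np.ndarray]:
        """Network name -> positions of its labels in canonical order."""
        out: dict[str, list[int]] = {}
        for i, lab in enumerate(self.labels):
            out.setdefault(self.network[int(lab)], []).append(i)
        return {k: np.array(v, dtype=int) for k, v in out.items()}


@dataclass
class StatMap:
    """A statistical map over parcels or voxels (t, z or raw effect)."""

    values: np.ndarray
    kind: str  # {t, z, effect}
    fi: str | None = None
    df: float | None = None
    subgroup: int | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind == "t" and (self.df is None or self.df <= 0):
            raise ValidationError("t-map requires positive degrees of freedom")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValidationError("non-finite values inside mask")

    def masked(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class ExpressionMatrix:
    """Regional gene expression: regions (rows, left hemisphere) x genes."""

    regions: np.ndarray
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.regions = np.asarray(self.regions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.genes)):
            raise SchemaError("expression matrix shape does not match regions x genes")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("expression matrix contains missing values")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class RunConfig:
    """Tunable analysis parameters with the study defaults."""

    window_length_years: int = 5
    min_subgroup_size: int = 8
    n_perm: int = 5000
    n_boot: int = 1000
    fdr_q: float = 0.05
    z_gene_threshold: float = 5.0
    voxel_abnormal_fraction: float = 0.30
    rng_seed: int = 0
    fi_list: tuple[str, ...] = DEFAULT_FI_LIST
    fcd_r_threshold: float = 0.6
    lfcd_radius_mm: float = 12.0
    band: tuple[float, float] = (0.01, 0.08)
    align_alpha: float = 0.5
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_convergence_iter: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValidationError("fdr_q must lie in (0, 1)")
        if self.window_length_years < 1:
            raise ValidationError("window_length_years must be >= 1")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if not 0 < self.band[0] < self.band[1]:
            raise ValidationError("band must satisfy 0 < low < high")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise SchemaError(f"unknown config keys: {sorted(bad)}")
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "fi_list" in d:
            d["fi_list"] = tuple(d["fi_list"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["fi_list"] = list(self.fi_list)
        return d
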