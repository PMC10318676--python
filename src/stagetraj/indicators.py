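"""Resting-state functional indicators from 4D series.

Five per-voxel summaries of spontaneous activity are computed from a
voxels x timepoints block: fractional amplitude of low-frequency
fluctuation (fALFF), regional homogeneity (ReHo, Kendall's W over a cubic
neighborhood), and functional connectivity density at global, local and
long-range levels (suprathreshold-correlation counts).

All five are invariant to per-voxel affine rescaling of the time series:
fALFF is a ratio of spectral amplitudes of the detrended signal, ReHo is
rank-based, FCD thresholds Pearson correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import rankdata

from .types import StatMap, ValidationError


@dataclass
class SeriesBlock:
    """A block of voxel time series on a regular grid.

    ``data`` is voxels x timepoints; ``coords`` gives each voxel's integer
    grid coordinates (used for the local-FCD radius); ``voxel_size`` is the
    grid spacing in mm.
    """

    data: np.ndarray
    tr: float
    coords: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.tr <= 0:
            raise ValidationError("TR must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[0], dtype=bool)
        if self.coords.shape != (self.data.shape[0], 3):
            raise ValidationError("coords must be voxels x 3")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def coords_mm(self) -> np.ndarray:
        return self.coords * np.asarray(self.voxel_size, dtype=float)


def falff(series: SeriesBlock, band: tuple[float, float] = (0.01, 0.08)) -> StatMap:
    """Fractional amplitude of low-frequency fluctuation.

    Each series is linearly detrended; per voxel the statistic is the sum of
    square-root power over the requested band divided by the sum over the
    full positive-frequency range, so values lie in [0, 1].
    """
    low, high = band
    nyquist = 1.0 / (2.0 * series.tr)
    if not 0 < low < high <= nyquist:
        raise ValidationError(f"band {band} outside (0, Nyquist={nyquist:.4g}]")
    x = sp_signal.detrend(series.data, axis=1, type="linear")
    n = series.n_timepoints
    freqs = np.fft.rfftfreq(n, d=series.tr)
    amp = np.abs(np.fft.rfft(x, axis=1))  # sqrt of power up to a constant
    pos = freqs > 0
    in_band = pos & (freqs >= low) & (freqs <= high)
    total = amp[:, pos].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(total > 0, amp[:, in_band].sum(axis=1) / total, 0.0)
    return StatMap(values=vals, kind="effect", fi="falff", mask=series.mask)


def _kendall_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance from a K x n rank matrix."""
    k, n = ranks.shape
    r_i = ranks.sum(axis=0)
    s = np.sum((r_i - r_i.mean()) ** 2)
    denom = k * k * (n ** 3 - n) / 12.0
    return float(s / denom)


def reho(series: SeriesBlock, neighborhood: int = 27) -> StatMap:
    """Regional homogeneity: Kendall's W of each voxel and its neighbors.

    ``neighborhood`` in {7, 19, 27} selects face-, edge- or corner-connected
    cubic neighborhoods. Voxels at mask edges use whatever neighbors exist
    (K reduced); a neighborhood whose series are all constant gets W = 0
    with a warning. Ranks use the average-rank tie convention.
    """
    if neighborhood not in (7, 19, 27):
        raise ValidationError("neighborhood must be one of {7, 19, 27}")
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = abs(dx) + abs(dy) + abs(dz)
                if neighborhood == 7 and d > 1:
                    continue
                if neighborhood == 19 and d > 2:
                    continue
                offsets.append((dx, dy, dz))
    offsets = np.array(offsets, dtype=float)

    idx = {tuple(c): i for i, c in enumerate(np.asarray(series.coords, dtype=int))}
    in_mask = series.mask
    ranks = rankdata(series.data, axis=1)  # average ranks over time
    n = series.n_timepoints
    vals = np.zeros(series.n_voxels)
    warned = False
    for i, c in enumerate(series.coords):
        if not in_mask[i]:
            continue
        members = []
        for off in offsets:
            j = idx.get(tuple((c + off).astype(int)))
            if j is not None and in_mask[j]:
                members.append(j)
        block = series.data[members]
        if np.allclose(block, block[:, :1]):
            if not warned:
                warnings.warn("constant time series in ReHo neighborhood; W set to 0")
                warned = True
            vals[i] = 0.0
            continue
        vals[i] = _kendall_w(ranks[members])
    return StatMap(values=vals, kind="effect", fi="reho", mask=in_mask)


def fcd(series: SeriesBlock, r_threshold: float = 0.6,
        lfcd_radius_mm: float = 12.0) -> tuple[StatMap, StatMap, StatMap]:
    """Functional connectivity density at global, local and long-range levels.

    gFCD(v) counts in-mask voxels u != v with corr(v, u) > r_threshold;
    lFCD restricts the count to voxels within ``lfcd_radius_mm`` of v;
    lrFCD is their difference, so long_range + local = global identically.
    """
    if not -1.0 < r_threshold < 1.0:
        raise ValidationError("r_threshold must lie in (-1, 1)")
    sel = np.flatnonzero(series.mask)
    if sel.size < 2:
        raise ValidationError("FCD needs at least 2 in-mask voxels")
    x = series.data[sel]
    sd = x.std(axis=1)
    # constant series correlate with nothing
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    np.fill_diagonal(r, 0.0)
    above = r > r_threshold
    g = above.sum(axis=1).astype(float)
    xyz = series.coords_mm()[sel]
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=-1)
    near = d2 <= lfcd_radius_mm ** 2
    np.fill_diagonal(near, False)
    l = (above & near).sum(axis=1).astype(float)
    lr = g - l

    def _expand(v: np.ndarray) -> np.ndarray:
        out = np.zeros(series.n_voxels)
        out[sel] = v
        return out

    mk = lambda v, name: StatMap(values=_expand(v), kind="effect", fi=name,
                                 mask=series.mask)
    return mk(g, "gfcd"), mk(l, "lfcd"), mk(lr, "lrfcd")


def compute_all(series: SeriesBlock, band: tuple[float, float] = (0.01, 0.08),
                neighborhood: int = 27, r_threshold: float = 0.6,
                lfcd_radius_mm: float = 12.0) -> dict[str, StatMap]:
    """All five indicators for one subject, keyed by canonical FI name."""
    g, l, lr = fcd(series, r_threshold=r_threshold, lfcd_radius_mm=lfcd_radius_mm)
    return {
        "falff": falff(series, band=band),
        "reho": reho(series, neighborhood=neighborhood),
        "gfcd": g,
        "lfcd": l,
        "lrfcd": lr,
    }
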