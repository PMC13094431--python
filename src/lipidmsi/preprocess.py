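"""Spectral preprocessing: TIC normalization, baseline correction, feature
picking, cross-replicate alignment, deisotoping and interday rescaling.

The chain mirrors the standard MSI workflow: per-pixel total-ion-current
normalization (target sum 1), rolling-minimum baseline subtraction, a single
global feature list picked from the mean spectrum, greedy nearest-neighbour
alignment of replicate feature lists (tolerance in Da, matching the 0.05 Da
annotation scale), and removal of M+1 isotopologue satellites by their
+1.00336 Da spacing and lower mean intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MSIDataset

__all__ = [
    "FeatureTable",
    "AlignedFeatureSet",
    "ConsensusFeature",
    "tic_normalize",
    "baseline_correct",
    "pick_features",
    "align_features",
    "deisotope",
    "interday_rescale",
    "ISOTOPE_SPACING_DA",
]

ISOTOPE_SPACING_DA = 1.00336


@dataclass
class FeatureTable:
    """Centroided features x pixels for one replicate."""

    replicate_id: str
    polarity: str
    feature_ids: list[str]
    mz: np.ndarray
    matrix: np.ndarray  # (n_features, n_pixels)
    pixel_tic: np.ndarray | None = None  # raw per-pixel TIC, for background calls
    removed_isotopologues: list[tuple[str, str]] = field(default_factory=list)
    grid_shape: tuple[int, int] | None = None  # (height, width)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(self.feature_ids) != len(self.mz):
            raise ValueError("feature id / m/z length mismatch")
        if self.matrix.shape[0] != len(self.mz):
            raise ValueError("matrix rows inconsistent with feature list")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("feature m/z must be strictly increasing")
        if np.any(self.matrix < 0):
            raise ValueError("negative intensities")

    @property
    def n_features(self) -> int:
        return len(self.mz)

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]

    def mean_intensity(self) -> np.ndarray:
        return self.matrix.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.feature_ids)
        df.insert(0, "mz", self.mz)
        return df.reset_index(names="feature_id")


@dataclass(frozen=True)
class ConsensusFeature:
    avg_mz: float
    ppm_deviation: float
    members: dict  # replicate_id -> feature index in that replicate's table

    @property
    def n_replicates(self) -> int:
        return len(self.members)


@dataclass
class AlignedFeatureSet:
    """Consensus features grouped across replicates."""

    features: list[ConsensusFeature]
    replicate_ids: list[str]

    def covered_by_all(self) -> list[ConsensusFeature]:
        n = len(self.replicate_ids)
        return [f for f in self.features if f.n_replicates == n]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "avg_mz": [f.avg_mz for f in self.features],
            "ppm_deviation": [f.ppm_deviation for f in self.features],
            "n_replicates": [f.n_replicates for f in self.features],
        })


def tic_normalize(dataset: MSIDataset) -> MSIDataset:
    """Scale every pixel to unit total ion current.

    Zero-TIC pixels are left untouched and flagged in
    ``metadata['zero_tic_pixels']``; the raw TIC vector is kept in
    ``metadata['raw_tic']`` so later stages can call background pixels.
    Idempotent.
    """
    tic = dataset.tic()
    raw = dataset.metadata.get("raw_tic", tic)
    nz = tic > 0
    out = dataset.intensities.astype(np.float64).copy()
    out[nz] /= tic[nz, None]
    meta = dict(dataset.metadata)
    meta["raw_tic"] = np.asarray(raw, dtype=float)
    meta["zero_tic_pixels"] = np.nonzero(~nz)[0]
    return MSIDataset(
        replicate_id=dataset.replicate_id,
        polarity=dataset.polarity,
        width=dataset.width, height=dataset.height,
        mz_axis=dataset.mz_axis,
        intensities=out,
        pixel_size_um=dataset.pixel_size_um,
        metadata=meta,
    )


def baseline_correct(dataset: MSIDataset, window_da: float = 5.0) -> MSIDataset:
    """Subtract a per-pixel rolling-minimum baseline and clip at zero.

    The baseline at each axis point is the minimum intensity within
    ``window_da`` (full width) of that point; a window wider than the whole
    axis degrades to global-minimum subtraction.
    """
    if window_da <= 0:
        raise ValueError("window_da must be positive")
    mz = dataset.mz_axis
    half = window_da / 2.0
    lo = np.searchsorted(mz, mz - half, side="left")
    hi = np.searchsorted(mz, mz + half, side="right")
    X = dataset.intensities.astype(np.float64)
    baseline = np.empty_like(X)
    for i in range(len(mz)):
        baseline[:, i] = X[:, lo[i]:hi[i]].min(axis=1)
    out = np.clip(X - baseline, 0.0, None)
    return MSIDataset(
        replicate_id=dataset.replicate_id,
        polarity=dataset.polarity,
        width=dataset.width, height=dataset.height,
        mz_axis=mz,
        intensities=out,
        pixel_size_um=dataset.pixel_size_um,
        metadata=dict(dataset.metadata),
    )


def pick_features(
    dataset: MSIDataset,
    min_rel_intensity: float = 0.01,
    top_n: int = 200,
    window_da: float = 0.02,
) -> FeatureTable:
    """Pick one global feature list from the mean spectrum.

    A feature is an axis point that is the local maximum of the mean
    spectrum within ``window_da`` and reaches ``min_rel_intensity`` of the
    strongest mean peak; features are ranked by mean intensity and truncated
    to ``top_n``, then reported in m/z order.
    """
    mean = dataset.intensities.mean(axis=0, dtype=np.float64)
    if mean.max() <= 0:
        return FeatureTable(dataset.replicate_id, dataset.polarity, [],
                            np.empty(0), np.empty((0, dataset.n_pixels)),
                            pixel_tic=_raw_tic(dataset),
                            grid_shape=(dataset.height, dataset.width))
    mz = dataset.mz_axis
    lo = np.searchsorted(mz, mz - window_da, side="left")
    hi = np.searchsorted(mz, mz + window_da, side="right")
    floor = min_rel_intensity * mean.max()
    keep = []
    for i in range(len(mz)):
        if mean[i] < floor or mean[i] <= 0:
            continue
        seg = mean[lo[i]:hi[i]]
        best = seg.max()
        if mean[i] < best:
            continue
        if mean[i] == best and (lo[i] + int(np.argmax(seg))) != i:
            continue  # plateau tie: lowest m/z wins
        keep.append(i)
    keep.sort(key=lambda i: -mean[i])
    keep = sorted(keep[:top_n])
    mzs = mz[keep]
    ids = [f"F{k:04d}" for k in range(len(keep))]
    return FeatureTable(
        replicate_id=dataset.replicate_id,
        polarity=dataset.polarity,
        feature_ids=ids,
        mz=mzs,
        matrix=dataset.intensities[:, keep].T.astype(float),
        pixel_tic=_raw_tic(dataset),
        grid_shape=(dataset.height, dataset.width),
    )


def _raw_tic(dataset: MSIDataset) -> np.ndarray:
    raw = dataset.metadata.get("raw_tic")
    return np.asarray(raw, dtype=float) if raw is not None else dataset.tic()


def align_features(
    tables: list[FeatureTable], tol_da: float = 0.02,
) -> AlignedFeatureSet:
    """Greedy nearest-neighbour grouping of replicate feature lists.

    Seeded from the most intense feature downward (ties broken by lower
    m/z), each consensus feature absorbs at most one unused feature per
    replicate within ``tol_da``.  The result is independent of the input
    table order.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    pols = {t.polarity for t in tables}
    if len(pols) > 1:
        raise ValueError(f"mixed polarities {sorted(pols)} cannot be aligned")
    tables = sorted(tables, key=lambda t: t.replicate_id)
    pool = []  # (mean intensity, mz, table idx, feature idx)
    for ti, t in enumerate(tables):
        means = t.mean_intensity()
        for fi in range(t.n_features):
            pool.append((float(means[fi]), float(t.mz[fi]), ti, fi))
    pool.sort(key=lambda rec: (-rec[0], rec[1]))
    used = [np.zeros(t.n_features, dtype=bool) for t in tables]
    consensus = []
    for _, seed_mz, ti, fi in pool:
        if used[ti][fi]:
            continue
        members = {ti: fi}
        used[ti][fi] = True
        for tj, t in enumerate(tables):
            if tj == ti or t.n_features == 0:
                continue
            d = np.abs(t.mz - seed_mz)
            d[used[tj]] = np.inf
            k = int(np.argmin(d))
            if d[k] <= tol_da:
                members[tj] = k
                used[tj][k] = True
        mzs = [tables[tj].mz[fj] for tj, fj in members.items()]
        avg = float(np.mean(mzs))
        ppm = 0.0
        if len(mzs) > 1:
            ppm = float((max(mzs) - min(mzs)) / avg * 1e6)
        consensus.append(ConsensusFeature(
            avg_mz=avg, ppm_deviation=ppm,
            members={tables[tj].replicate_id: fj for tj, fj in members.items()},
        ))
    consensus.sort(key=lambda c: c.avg_mz)
    return AlignedFeatureSet(
        features=consensus,
        replicate_ids=[t.replicate_id for t in tables],
    )


def deisotope(
    table: FeatureTable,
    delta_da: float = ISOTOPE_SPACING_DA,
    tol_da: float = 0.01,
) -> FeatureTable:
    """Drop M+1 isotopologue satellites from a feature table.

    Feature B is removed when some feature A sits ``delta_da`` (within
    ``tol_da``) below it with a larger mean intensity; removals are recorded
    as ``(satellite_id, parent_id)``.  The most intense feature can never be
    removed.
    """
    means = table.mean_intensity()
    removed: list[tuple[str, str]] = []
    drop = np.zeros(table.n_features, dtype=bool)
    for b in range(table.n_features):
        gaps = table.mz[b] - table.mz[:b]
        cand = np.nonzero(np.abs(gaps - delta_da) <= tol_da)[0]
        cand = [a for a in cand if means[a] > means[b]]
        if cand:
            parent = max(cand, key=lambda a: means[a])
            drop[b] = True
            removed.append((table.feature_ids[b], table.feature_ids[parent]))
    keep = ~drop
    return FeatureTable(
        replicate_id=table.replicate_id,
        polarity=table.polarity,
        feature_ids=[fid for fid, k in zip(table.feature_ids, keep) if k],
        mz=table.mz[keep],
        matrix=table.matrix[keep],
        pixel_tic=table.pixel_tic,
        removed_isotopologues=table.removed_isotopologues + removed,
        grid_shape=table.grid_shape,
    )


def interday_rescale(
    reference: FeatureTable,
    reference_roi: np.ndarray,
    target: FeatureTable,
    target_roi: np.ndarray,
) -> tuple[float, FeatureTable]:
    """Match a target replicate's absolute intensity scale to a reference.

    ``scale`` is the ratio of mean ROI TIC (summed feature intensity) in the
    reference over the target; the target matrix is multiplied by it so
    matched-ROI mean TICs agree.
    """
    ref_tic = reference.matrix[:, np.asarray(reference_roi)].sum(axis=0).mean()
    tgt_tic = target.matrix[:, np.asarray(target_roi)].sum(axis=0).mean()
    if tgt_tic <= 0 or not math.isfinite(tgt_tic):
        raise ValueError("target ROI has zero TIC; cannot rescale")
    scale = float(ref_tic / tgt_tic)
    rescaled = FeatureTable(
        replicate_id=target.replicate_id,
        polarity=target.polarity,
        feature_ids=list(target.feature_ids),
        mz=target.mz.copy(),
        matrix=target.matrix * scale,
        pixel_tic=target.pixel_tic,
        removed_isotopologues=list(target.removed_isotopologues),
        grid_shape=target.grid_shape,
    )
    return scale, rescaled
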