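"""Tumor-seeded functional connectivity against a cortical parcellation.

Parcel mean time series are extracted with tumor voxels excluded, the seed
region's mean series is correlated with every parcel (Pearson r, Fisher
z = atanh(r), two-sided p from the t transform on T-2 df), significant
parcels are selected by Bonferroni correction, and spatial reach is
summarized as the mean Euclidean distance (world mm) between the seed
centroid and the centroids of significantly connected parcels.

Tumor seeds and their mirrored contralateral controls run through the
identical code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess_qc import BoldRun

#: Fisher z cap applied at |r| = 1 to keep arithmetic finite.
Z_CAP = float(np.arctanh(1.0 - 1e-15))


@dataclass
class SeedFcResult:
    """Per-seed connectivity profile and its scalar summaries.

    NaN entries mark parcels unusable for this subject (emptied by tumor
    exclusion or with zero-variance series); they are never selected as
    significant and are excluded from ``mean_fc``.
    """

    r_vec: np.ndarray
    z_vec: np.ndarray
    p_vec: np.ndarray
    sig_set: np.ndarray          # sorted parcel indices (0-based)
    mean_fc: float               # mean Fisher z over all usable parcels
    n_sig: int
    mean_dist_mm: float          # NaN sentinel when sig_set is empty
    alpha: float = 0.05
    n_tests: int = 0


def parcel_series(run: BoldRun, atlas, exclusion_masks=()) -> tuple[np.ndarray, np.ndarray]:
    """Mean time series per parcel, excluding any voxels under the given masks.

    Returns ``(matrix (P, T), n_voxels_used (P,))``.  Parcels emptied by the
    exclusion are flagged with a NaN row and a warning.
    """
    labels = atlas.labels
    if labels.shape != run.data.shape[:3]:
        raise ValueError("atlas grid does not match the run")
    keep = labels > 0
    for m in exclusion_masks:
        keep &= ~np.asarray(m, dtype=bool)
    P = atlas.n_parcels
    flat_labels = labels[keep]
    if flat_labels.size == 0:
        raise ValueError("exclusion removed every labeled voxel")
    counts = np.bincount(flat_labels, minlength=P + 1)[1:]
    sums = np.zeros((P, run.n_volumes))
    np.add.at(sums, flat_labels - 1, run.data[keep])
    out = np.full((P, run.n_volumes), np.nan)
    ok = counts > 0
    out[ok] = sums[ok] / counts[ok, None]
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} parcel(s) emptied by exclusion masks", stacklevel=2)
    return out, counts.astype(int)


def mask_mean_series(run: BoldRun, mask: np.ndarray) -> np.ndarray:
    """Mean series over an ROI mask (seed extraction)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return run.data[mask].mean(axis=0)


def seed_fc(seed_series: np.ndarray, parcel_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson r, Fisher z and two-sided p of the seed against each parcel.

    p comes from ``t = r sqrt((T-2)/(1-r^2))`` on T-2 df.  Zero-variance
    series yield NaN sentinels; |r| = 1 is capped at ``Z_CAP`` with p = 0.
    """
    seed_series = np.asarray(seed_series, dtype=float)
    parcel_matrix = np.atleast_2d(np.asarray(parcel_matrix, dtype=float))
    T = seed_series.size
    if parcel_matrix.shape[1] != T:
        raise ValueError("seed and parcel series lengths differ")
    if T < 4:
        raise ValueError("need at least 4 timepoints")
    s = seed_series - seed_series.mean()
    s_norm = np.linalg.norm(s)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_mat = parcel_matrix - np.nanmean(parcel_matrix, axis=1, keepdims=True)
        norms = np.sqrt(np.nansum(p_mat**2, axis=1))
    r = np.full(parcel_matrix.shape[0], np.nan)
    usable = np.isfinite(norms) & (norms > 0) & np.all(np.isfinite(parcel_matrix), axis=1)
    if s_norm == 0:
        warnings.warn("zero-variance seed series; all correlations are NaN", stacklevel=2)
        return r, r.copy(), r.copy()
    r[usable] = (p_mat[usable] @ s) / (norms[usable] * s_norm)
    r = np.clip(r, -1.0, 1.0)

    z = np.full_like(r, np.nan)
    p = np.full_like(r, np.nan)
    ok = np.isfinite(r)
    capped = ok & (np.abs(r) >= 1.0 - 1e-15)
    z[capped] = np.sign(r[capped]) * Z_CAP
    p[capped] = 0.0
    rest = ok & ~capped
    z[rest] = np.arctanh(r[rest])
    tstat = r[rest] * np.sqrt((T - 2) / (1.0 - r[rest] ** 2))
    p[rest] = 2.0 * stats.t.sf(np.abs(tstat), df=T - 2)
    return r, z, p


def select_significant(p_vec: np.ndarray, alpha: float = 0.05,
                       n_tests: int | None = None) -> np.ndarray:
    """Bonferroni parcel selection: indices with ``p < alpha / n_tests``.

    ``n_tests`` defaults to the usable (non-NaN) parcel count; a fixed
    denominator (e.g. the full atlas size) can be passed instead.  NaN
    sentinels are never selected.
    """
    p_vec = np.asarray(p_vec, dtype=float)
    usable = np.isfinite(p_vec)
    m = int(usable.sum()) if n_tests is None else int(n_tests)
    if m < 1:
        return np.array([], dtype=int)
    thr = alpha / m
    return np.flatnonzero(usable & (p_vec < thr))


def centroid(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World-mm centroid of a voxel region (mean of member voxel coordinates)."""
    ijk = np.argwhere(np.asarray(mask, dtype=bool))
    if ijk.size == 0:
        raise ValueError("empty region has no centroid")
    affine = np.asarray(affine, dtype=float)
    return (affine[:3, :3] @ ijk.T).T.mean(axis=0) + affine[:3, 3]


def mean_distance(seed_centroid: np.ndarray, parcel_centroids: np.ndarray,
                  sig_set: np.ndarray) -> float:
    """Mean Euclidean distance (mm) from the seed centroid to significant parcels.

    Returns NaN when no parcel is significant.
    """
    sig_set = np.asarray(sig_set, dtype=int)
    if sig_set.size == 0:
        return float("nan")
    d = np.linalg.norm(np.asarray(parcel_centroids)[sig_set] - np.asarray(seed_centroid), axis=1)
    return float(d.mean())


def seed_fc_result(seed_series: np.ndarray, parcel_matrix: np.ndarray,
                   seed_centroid: np.ndarray, parcel_centroids: np.ndarray,
                   alpha: float = 0.05, n_tests: int | None = None) -> SeedFcResult:
    """Full seed-connectivity profile: r/z/p, Bonferroni set, summaries."""
    r, z, p = seed_fc(seed_series, parcel_matrix)
    sig = select_significant(p, alpha=alpha, n_tests=n_tests)
    usable = np.isfinite(z)
    mean_fc = float(np.mean(z[usable])) if usable.any() else float("nan")
    return SeedFcResult(
        r_vec=r, z_vec=z, p_vec=p, sig_set=sig,
        mean_fc=mean_fc, n_sig=int(sig.size),
        mean_dist_mm=mean_distance(seed_centroid, parcel_centroids, sig),
        alpha=alpha,
        n_tests=int(np.isfinite(p).sum()) if n_tests is None else int(n_tests),
    )
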