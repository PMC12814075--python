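"""Voxel-wise local activity metrics and mirrored contralateral controls.

ALFF is the integrated periodogram power of a voxel's BOLD series within the
low-frequency band (0.01-0.1 Hz); fALFF is that power as a fraction of the
power over the full analysed band (0-0.25 Hz, DC excluded).  Both are
computed on the nuisance-regressed, smoothed but *unfiltered* run, because
band-passing first would trivialize fALFF.  ReHo (regional homogeneity) is
Kendall's coefficient of concordance of each voxel's band-passed series with
its 3x3x3 neighbourhood.  All maps are z-scored within the brain mask before
region summaries.

The contralateral mirror control of a tumor mask is its reflection across
the midsagittal plane (array x-axis flip on a midline-symmetric grid),
giving a location-matched "healthy" reference region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .preprocess_qc import BoldRun


@dataclass
class LesionSet:
    """Per-subject larger/smaller tumor masks plus mirrored controls."""

    larger_mask: np.ndarray
    smaller_mask: np.ndarray
    larger_control: np.ndarray
    smaller_control: np.ndarray
    voxel_volume_mm3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("larger_mask", "smaller_mask", "larger_control", "smaller_control"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if (self.larger_mask & self.smaller_mask).any():
            raise ValueError("tumor masks must be disjoint")
        if self.larger_mask.sum() <= self.smaller_mask.sum():
            raise ValueError("larger tumor must have strictly greater volume")

    @property
    def volumes_mm3(self) -> dict:
        return {
            "larger": float(self.larger_mask.sum() * self.voxel_volume_mm3),
            "smaller": float(self.smaller_mask.sum() * self.voxel_volume_mm3),
        }

    def mask_of(self, seed_type: str) -> np.ndarray:
        return {
            "larger": self.larger_mask,
            "smaller": self.smaller_mask,
            "larger_control": self.larger_control,
            "smaller_control": self.smaller_control,
        }[seed_type]


@dataclass
class ActivityMaps:
    """Raw and z-scored ALFF / fALFF / ReHo maps for one subject."""

    alff: np.ndarray
    falff: np.ndarray
    reho: np.ndarray
    alff_z: np.ndarray
    falff_z: np.ndarray
    reho_z: np.ndarray
    band_low: float = 0.01
    band_high: float = 0.1
    total_band_high: float = 0.25

    def zscored(self, metric: str) -> np.ndarray:
        return getattr(self, f"{metric}_z")


def _band_power(data: np.ndarray, tr: float, low: float, high: float,
                include_dc: bool = False) -> np.ndarray:
    """Integrated one-sided periodogram power over [low, high] Hz.

    Returns ``sum_k psd_k * df`` = ``(2/T^2) * sum_k |X_k|^2`` over the band
    (factor 2 for the one-sided spectrum; DC and Nyquist bins are not
    doubled).
    """
    t = data.shape[-1]
    freqs = np.fft.rfftfreq(t, tr)
    sel = (freqs >= low) & (freqs <= high)
    if not include_dc:
        sel &= freqs > 0
    if not sel.any():
        raise ValueError(f"band [{low}, {high}] Hz contains no frequency bin at T={t}, TR={tr}")
    spec = np.fft.rfft(data, axis=-1)
    power = np.abs(spec[..., sel]) ** 2
    scale = np.full(sel.sum(), 2.0)
    bf = freqs[sel]
    scale[bf == 0] = 1.0
    if t % 2 == 0:
        scale[np.isclose(bf, 0.5 / tr)] = 1.0
    return (power * scale).sum(axis=-1) / t**2


def alff(run: BoldRun, band: tuple[float, float] = (0.01, 0.1),
         brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Amplitude of low-frequency fluctuation: integrated in-band PSD per voxel."""
    low, high = band
    out = np.zeros(run.data.shape[:3])
    mask = np.ones(out.shape, bool) if brain_mask is None else np.asarray(brain_mask, bool)
    out[mask] = _band_power(run.data[mask], run.tr_seconds, low, high)
    return out


def falff(run: BoldRun, band: tuple[float, float] = (0.01, 0.1),
          total: tuple[float, float] = (0.0, 0.25),
          brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Fractional ALFF: in-band power over total-band power (DC excluded)."""
    low, high = band
    tlow, thigh = total
    if thigh > run.nyquist_hz + 1e-12:
        raise ValueError(f"total band upper {thigh} Hz exceeds Nyquist {run.nyquist_hz:.4f} Hz")
    out = np.zeros(run.data.shape[:3])
    mask = np.ones(out.shape, bool) if brain_mask is None else np.asarray(brain_mask, bool)
    num = _band_power(run.data[mask], run.tr_seconds, low, high)
    den = _band_power(run.data[mask], run.tr_seconds, tlow, thigh)
    zero = den == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} voxel(s) with zero total power; fALFF set to 0", stacklevel=2)
    vals = np.zeros_like(num)
    np.divide(num, den, out=vals, where=~zero)
    out[mask] = vals
    return out


def reho(run: BoldRun, brain_mask: np.ndarray | None = None,
         neighborhood: int = 27) -> np.ndarray:
    """Regional homogeneity: Kendall's W over 3x3x3 voxel neighbourhoods.

    W = 12 * S / (K^2 (T^3 - T)) where S is the variance of rank sums across
    time, K the number of in-mask voxels in the neighbourhood (edge voxels
    use only their in-mask neighbours), T the number of timepoints.  Average
    ranks are used for ties; no tie correction term.  Voxels with fewer than
    2 in-mask neighbours get NaN.
    """
    if neighborhood != 27:
        raise ValueError("only the 27-voxel (3x3x3) neighbourhood is supported")
    mask = np.ones(run.data.shape[:3], bool) if brain_mask is None else np.asarray(brain_mask, bool)
    t = run.n_volumes
    ranks = np.zeros(run.data.shape)
    ranks[mask] = stats.rankdata(run.data[mask], axis=-1)
    kernel = np.ones((3, 3, 3))
    k_map = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    # Rank-sum over the neighbourhood, per timepoint (out-of-mask voxels are 0).
    rank_sums = np.empty(run.data.shape)
    for j in range(t):
        rank_sums[..., j] = ndimage.correlate(ranks[..., j], kernel, mode="constant", cval=0.0)
    mean_sum = rank_sums.mean(axis=-1, keepdims=True)
    s = ((rank_sums - mean_sum) ** 2).sum(axis=-1)
    out = np.full(run.data.shape[:3], np.nan)
    valid = mask & (k_map >= 2)
    out[valid] = 12.0 * s[valid] / (k_map[valid] ** 2 * (t**3 - t))
    return out


def zscore_map(map3d: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Z-score a map within the brain mask; background is left untouched."""
    mask = np.asarray(brain_mask, bool)
    vals = np.asarray(map3d, float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite in-mask voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero in-mask SD; cannot z-score")
    out = np.array(map3d, dtype=float, copy=True)
    out[mask] = (out[mask] - vals.mean()) / sd
    return out


def mirror_mask(mask: np.ndarray, atlas=None, axis: int = 0) -> np.ndarray:
    """Reflect a mask across the midsagittal plane of its grid.

    On the midline-symmetric grids used throughout (atlas mirror plane
    between columns ``nx/2 - 1`` and ``nx/2`` for even ``nx``, through the
    central column otherwise), reflection is an index flip along ``axis``.
    The operation is an involution and preserves voxel count.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot mirror an empty mask")
    if atlas is not None and mask.shape != atlas.labels.shape:
        raise ValueError("mask grid does not match atlas grid")
    return np.flip(mask, axis=axis).copy()


def roi_summary(map3d: np.ndarray, mask: np.ndarray) -> float:
    """Mean of the (finite) map values under the mask."""
    mask = np.asarray(mask, bool)
    vals = np.asarray(map3d, float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI does not overlap the map support")
    return float(vals.mean())


def activity_maps(unfiltered: BoldRun, filtered: BoldRun, brain_mask: np.ndarray,
                  band: tuple[float, float] = (0.01, 0.1),
                  total: tuple[float, float] = (0.0, 0.25)) -> ActivityMaps:
    """Compute all three activity maps and their within-subject z-scores.

    ``unfiltered`` is the nuisance-regressed, smoothed run (feeds ALFF and
    fALFF); ``filtered`` is the band-passed run (feeds ReHo).
    """
    a = alff(unfiltered, band, brain_mask)
    f = falff(unfiltered, band, total, brain_mask)
    r = reho(filtered, brain_mask)
    return ActivityMaps(
        alff=a, falff=f, reho=r,
        alff_z=zscore_map(a, brain_mask),
        falff_z=zscore_map(f, brain_mask),
        reho_z=zscore_map(r, brain_mask),
        band_low=band[0], band_high=band[1], total_band_high=total[1],
    )
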