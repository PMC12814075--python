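"""BOLD preprocessing and quality control.

Implements the minimal resting-state pipeline applied to data that is already
in a common registered space: initial-volume trimming, nuisance regression
(6 motion parameters + white-matter + CSF), Gaussian spatial smoothing,
ideal band-pass filtering, and the motion / signal-variance / tSNR quality
gates (framewise displacement, DVARS, temporal signal-to-noise ratio).

The fixed stage order is trim -> regress -> smooth -> band-pass.  Spectral
metrics (ALFF/fALFF) are computed on the smoothed-but-unfiltered stage; see
:mod:`gliomaconn.local_activity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
CONFOUND_COLUMNS = MOTION_COLUMNS + ("wm", "csf")

#: Default motion/variance exclusion thresholds (mean FD in mm, mean DVARS
#: in native signal units).
FD_MAX_MM = 0.2
DVARS_MAX = 20.0


@dataclass
class BoldRun:
    """A 4D BOLD acquisition with voxel geometry and repetition time.

    Parameters
    ----------
    data
        Array of shape ``(x, y, z, t)`` in arbitrary signal units.
    affine
        4x4 voxel-to-world (mm) affine; must be invertible.
    tr_seconds
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[-1] < 2:
            raise ValueError("BOLD run needs at least 2 volumes")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(data=data, affine=self.affine.copy(), tr_seconds=self.tr_seconds)

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_seconds))
        return img

    @classmethod
    def from_nifti(cls, img_or_path, tr_seconds: float | None = None) -> "BoldRun":
        img = nib.load(str(img_or_path)) if not isinstance(img_or_path, nib.Nifti1Image) else img_or_path
        if tr_seconds is None:
            tr_seconds = float(img.header.get_zooms()[3])
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, tr_seconds)


@dataclass
class QcReport:
    """Motion and signal-quality summary for one subject."""

    fd_series: np.ndarray
    dvars_series: np.ndarray
    mean_fd: float
    mean_dvars: float
    tsnr_by_roi: dict = field(default_factory=dict)
    excluded: bool = False
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "mean_fd": float(self.mean_fd),
            "mean_dvars": float(self.mean_dvars),
            "tsnr_by_roi": {k: float(v) for k, v in self.tsnr_by_roi.items()},
            "excluded": bool(self.excluded),
            "reason": self.reason,
        }


class QcDecision(NamedTuple):
    excluded: bool
    reason: str


def drop_initial_volumes(run: BoldRun, k: int) -> BoldRun:
    """Discard the first ``k`` volumes (magnetic-stabilization dummies).

    The caller is responsible for trimming confound tables to match.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= run.n_volumes:
        raise ValueError(f"cannot drop {k} of {run.n_volumes} volumes")
    if k == 0:
        return run.with_data(run.data.copy())
    return run.with_data(run.data[..., k:].copy())


def framewise_displacement(motion, radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement.

    ``FD_t = sum |delta trans| + radius * sum |delta rot|`` with translations in
    mm and rotations in radians converted to arc length on a sphere of
    ``radius_mm``.  Returns a series of length ``t - 1``.
    """
    if isinstance(motion, pd.DataFrame):
        missing = [c for c in MOTION_COLUMNS if c not in motion.columns]
        if missing:
            raise ValueError(f"motion table missing columns {missing}")
        motion = motion.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must have 6 columns (3 translations mm, 3 rotations rad)")
    d = np.abs(np.diff(motion, axis=0))
    return d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)


def dvars(run: BoldRun, brain_mask: np.ndarray) -> np.ndarray:
    """Unstandardized DVARS: RMS over in-mask voxels of the temporal derivative."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != run.data.shape[:3]:
        raise ValueError("mask shape does not match run grid")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    series = run.data[brain_mask]  # (n_voxels, t)
    diffs = np.diff(series, axis=1)
    return np.sqrt(np.mean(diffs**2, axis=0))


def qc_gate(
    mean_fd: float,
    mean_dvars: float,
    fd_max: float = FD_MAX_MM,
    dvars_max: float = DVARS_MAX,
    rule: str = "and",
) -> QcDecision:
    """Decide subject inclusion from mean FD and mean DVARS.

    With ``rule="and"`` (default) a subject is excluded only when both
    thresholds are breached; a single breach is flagged as a warning.
    ``rule="or"`` excludes on either breach.
    """
    if not (np.isfinite(mean_fd) and np.isfinite(mean_dvars)):
        raise ValueError("mean_fd and mean_dvars must be finite")
    fd_bad = mean_fd > fd_max
    dv_bad = mean_dvars > dvars_max
    if rule == "and":
        excluded = fd_bad and dv_bad
    elif rule == "or":
        excluded = fd_bad or dv_bad
    else:
        raise ValueError("rule must be 'and' or 'or'")
    if excluded:
        return QcDecision(True, f"mean FD {mean_fd:.3f} > {fd_max} and mean DVARS {mean_dvars:.3f} > {dvars_max}"
                          if fd_bad and dv_bad else f"threshold breach under rule={rule}")
    if fd_bad or dv_bad:
        which = "FD" if fd_bad else "DVARS"
        warnings.warn(f"single-threshold breach ({which}) under rule='and'; subject retained", stacklevel=2)
    return QcDecision(False, "")


def regress_nuisance(run: BoldRun, confounds) -> BoldRun:
    """Per-voxel least-squares residualization on [intercept, confounds].

    Confounds are the 6 rigid-body motion parameters plus mean white-matter
    and CSF signals.  A rank-deficient design falls back to the pseudoinverse
    with a warning.
    """
    if isinstance(confounds, pd.DataFrame):
        confounds = confounds.to_numpy(dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim != 2 or confounds.shape[0] != run.n_volumes:
        raise ValueError("confound rows must equal the number of volumes")
    t = run.n_volumes
    design = np.column_stack([np.ones(t), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient confound design; using pseudoinverse", stacklevel=2)
    y = run.data.reshape(-1, t).T  # (t, n_voxels)
    beta = np.linalg.pinv(design) @ y
    resid = y - design @ beta
    return run.with_data(resid.T.reshape(run.data.shape))


def bandpass(run: BoldRun, low: float = 0.01, high: float = 0.1) -> BoldRun:
    """Ideal (FFT-mask) band-pass filter; removes DC and out-of-band power."""
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high > run.nyquist_hz + 1e-12:
        raise ValueError(f"high={high} Hz exceeds Nyquist {run.nyquist_hz:.4f} Hz")
    t = run.n_volumes
    freqs = np.fft.rfftfreq(t, run.tr_seconds)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    spec = np.fft.rfft(run.data, axis=-1)
    spec[..., ~keep] = 0
    return run.with_data(np.fft.irfft(spec, n=t, axis=-1))


def smooth(run: BoldRun, fwhm_mm: float = 5.0) -> BoldRun:
    """Volume-wise Gaussian smoothing with the kernel given in mm FWHM.

    sigma = FWHM / (2 sqrt(2 ln 2)) converted to voxels per axis; reflective
    (zero-flux) boundaries conserve the image sum.  Kernels narrower than half
    a voxel are treated as the identity.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    vox = run.voxel_size_mm
    if fwhm_mm < 0.5 * vox.min():
        return run.with_data(run.data.copy())
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vox
    out = ndimage.gaussian_filter(run.data, sigma=(*sigma_vox, 0.0), mode="reflect")
    return run.with_data(out)


def tsnr(series) -> float:
    """Temporal SNR: mean of the series divided by its (sample) SD."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("tsnr needs a 1D series of length >= 2")
    sd = series.std(ddof=1)
    if sd == 0:
        warnings.warn("zero temporal SD; tSNR is infinite", stacklevel=2)
        return float("inf")
    return float(series.mean() / sd)


def count_intersected_networks(mask: np.ndarray, atlas) -> int:
    """Number of distinct resting-state networks a region overlaps.

    ``atlas`` is a :class:`gliomaconn.synthetic_cohort.ParcelAtlas`-like object
    exposing ``labels`` and ``network_of``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != atlas.labels.shape:
        raise ValueError("mask and atlas grids differ")
    hit = atlas.labels[mask]
    hit = hit[hit > 0]
    if hit.size == 0:
        warnings.warn("mask does not overlap any labeled voxel", stacklevel=2)
        return 0
    return len({atlas.network_of[int(p)] for p in np.unique(hit)})


@dataclass
class PreprocessedRun:
    """The staged outputs of the fixed preprocessing order."""

    trimmed: BoldRun
    regressed: BoldRun
    smoothed: BoldRun          # nuisance-regressed + smoothed, unfiltered
    filtered: BoldRun          # + band-passed
    confounds: pd.DataFrame    # trimmed to match
    qc: QcReport


def preprocess(
    run: BoldRun,
    confounds: pd.DataFrame,
    brain_mask: np.ndarray,
    n_drop: int = 5,
    fwhm_mm: float = 5.0,
    band: tuple[float, float] = (0.01, 0.1),
    fd_max: float = FD_MAX_MM,
    dvars_max: float = DVARS_MAX,
    qc_rule: str = "and",
) -> PreprocessedRun:
    """Run trim -> nuisance regression -> smooth -> band-pass, with QC.

    FD is computed from the trimmed motion table and DVARS from the trimmed
    (pre-regression) run so the gates reflect the acquired data.
    """
    if len(confounds) != run.n_volumes:
        raise ValueError("confound table length must match the run")
    trimmed = drop_initial_volumes(run, n_drop)
    conf = confounds.iloc[n_drop:].reset_index(drop=True)
    fd = framewise_displacement(conf)
    dv = dvars(trimmed, brain_mask)
    decision = qc_gate(float(fd.mean()), float(dv.mean()), fd_max, dvars_max, rule=qc_rule)
    regressed = regress_nuisance(trimmed, conf)
    smoothed = smooth(regressed, fwhm_mm)
    filtered = bandpass(smoothed, *band)
    qc = QcReport(
        fd_series=fd,
        dvars_series=dv,
        mean_fd=float(fd.mean()),
        mean_dvars=float(dv.mean()),
        excluded=decision.excluded,
        reason=decision.reason,
    )
    return PreprocessedRun(trimmed, regressed, smoothed, filtered, conf, qc)
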