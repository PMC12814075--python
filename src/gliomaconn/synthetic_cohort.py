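"""Synthetic multifocal-glioma BOLD cohorts with known ground truth.

The generator emulates the study design this package analyses: each subject
carries two spatially distinct glioma lesions of common origin — a larger
one (taken as the later progression stage) and a smaller one (earlier
stage) — embedded in a midline-symmetric parcellated cortex.  Every
downstream stage (preprocessing, local activity, seed connectivity, graph
topology, paired statistics) can therefore be tested against known coupling
parameters without any data download.

Generative model
----------------
Latent signals are band-limited (0.01-0.1 Hz) Gaussian processes built in
the frequency domain, combined through a factor model:

* a global cortical factor ``g`` (variance share ``global_weight``),
* one factor per resting-state network (share ``network_weight``),
* idiosyncratic parcel noise for the remainder.

Parcel ``j`` in network ``n``:  ``x_j = sqrt(b) g + sqrt(a) f_n + sqrt(1-a-b) e_j``.
Tumor ``m`` couples to the cortex through the global factor with strength
``kappa``:  ``t_m = kappa g + sqrt(1-kappa^2) e_m``, so the expected
tumor-parcel correlation is ``kappa * sqrt(b)`` and rises monotonically
with kappa.  Voxel BOLD = 100 (baseline) + latent of the member parcel or
lesion + AR(1)+white noise, plus a small confound leak (motion drift, WM,
CSF) so nuisance regression has something real to remove.

Lesions are spheroids with jittered radii placed off-midline in the left
hemisphere; their contralateral mirror controls therefore fall in healthy
right-hemisphere cortex.  Volumes are drawn around means in the ratio of
the study cohort (78.6 : 24.9 cm^3, about 3.16 : 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .local_activity import LesionSet, mirror_mask
from .preprocess_qc import BoldRun, CONFOUND_COLUMNS, count_intersected_networks

N_NETWORKS = 7


class PlacementError(RuntimeError):
    """Raised when no admissible lesion placement is found."""


@dataclass
class ParcelAtlas:
    """A midline-symmetric cortical parcellation on a voxel grid.

    ``labels`` holds 0 for background and 1..P for parcels; parcel ``p`` in
    the left hemisphere mirrors parcel ``p + P/2`` in the right.  The mirror
    plane is the world plane x = 0, i.e. the array flip ``i -> nx - 1 - i``.
    """

    labels: np.ndarray
    affine: np.ndarray
    network_of: dict[int, int]
    parcel_centroids: np.ndarray  # (P, 3) world mm, row p-1

    @property
    def n_parcels(self) -> int:
        return int(self.labels.max())

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def mask_centroid_mm(self, mask: np.ndarray) -> np.ndarray:
        ijk = np.argwhere(mask)
        if ijk.size == 0:
            raise ValueError("empty mask has no centroid")
        return self.world_coords(ijk).mean(axis=0)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.int16), self.affine)


def _ellipsoid_mask(grid_shape: tuple[int, int, int], fraction: float = 0.45) -> np.ndarray:
    """Convex ellipsoidal 'brain' centred in the grid."""
    nx, ny, nz = grid_shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = fraction * nx, fraction * ny, fraction * nz
    return ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 + ((kk - cz) / rz) ** 2 <= 1.0


def make_atlas(n_parcels: int = 400, grid_shape: tuple[int, int, int] = (64, 76, 64),
               seed: int = 0, voxel_size_mm: float = 3.0) -> ParcelAtlas:
    """Build a mirror-symmetric parcellation with 7 network labels.

    The left half of a convex ellipsoidal brain mask is partitioned into
    ``n_parcels / 2`` Voronoi cells of k-means centres (convex, hence
    contiguous, and non-empty); the right half is the mirror image with
    labels offset by ``n_parcels / 2``.  Network ids 1..7 are assigned by
    spatial rank so paired parcels share a network.
    """
    if n_parcels % 2 != 0 or n_parcels < 2:
        raise ValueError("n_parcels must be a positive even number")
    nx = grid_shape[0]
    brain = _ellipsoid_mask(grid_shape)
    if nx % 2 == 1:  # keep the grid cleanly two-sided: blank the self-mirroring column
        brain[(nx - 1) // 2] = False
    half = brain.copy()
    half[nx // 2:] = False
    coords = np.argwhere(half)
    p_half = n_parcels // 2
    if len(coords) < 8 * p_half:
        raise ValueError(
            f"grid {grid_shape} too small for {n_parcels} parcels "
            f"({len(coords)} left-hemisphere voxels < {8 * p_half})")
    km = KMeans(n_clusters=p_half, n_init=1, max_iter=100, random_state=seed)
    left_labels = km.fit_predict(coords.astype(float)) + 1

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[tuple(coords.T)] = left_labels
    flipped = np.flip(labels, axis=0)
    labels[flipped > 0] = flipped[flipped > 0] + p_half

    # Networks by spatial (y, z) rank of left-parcel centres; mirrored pair shares.
    centers = km.cluster_centers_
    order = np.lexsort((centers[:, 2], centers[:, 1]))
    network_of: dict[int, int] = {}
    for rank, idx in enumerate(order):
        net = rank * N_NETWORKS // p_half + 1 if p_half >= N_NETWORKS else rank % N_NETWORKS + 1
        network_of[idx + 1] = net
        network_of[idx + 1 + p_half] = net

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.array(grid_shape) - 1) / 2.0
    atlas = ParcelAtlas(labels=labels, affine=affine, network_of=network_of,
                        parcel_centroids=np.zeros((n_parcels, 3)))
    cents = np.empty((n_parcels, 3))
    for p in range(1, n_parcels + 1):
        cents[p - 1] = atlas.mask_centroid_mm(labels == p)
    atlas.parcel_centroids = cents
    return atlas


@dataclass
class SimulationParams:
    """Cohort-level generator settings.

    Defaults mirror the study conditions: 24 subjects, 400 parcels, TR 1.6 s,
    500 volumes, lesion volume means in the 78.6 : 24.9 cm^3 ratio (voxel
    counts at 3 mm isotropic resolution), and a tumor-cortex coupling gap
    ``kappa_larger > kappa_smaller``.
    """

    n_subjects: int = 24
    n_parcels: int = 400
    grid_shape: tuple[int, int, int] = (64, 76, 64)
    tr_seconds: float = 1.6
    n_volumes: int = 500
    kappa_larger: float = 0.6
    kappa_smaller: float = 0.2
    vol_mean_larger: float = 2911.0   # voxels; 78.6 cm^3 at 3 mm isotropic
    vol_mean_smaller: float = 922.0   # voxels; 24.9 cm^3
    vol_cv: float = 0.35              # lognormal coefficient of variation
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0
    band: tuple[float, float] = (0.01, 0.1)
    global_weight: float = 0.1        # variance share of the global factor
    network_weight: float = 0.2       # variance share of the network factor
    baseline: float = 100.0
    confound_gain: float = 0.2
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.kappa_larger < 1 and 0 <= self.kappa_smaller < 1):
            raise ValueError("kappa values must lie in [0, 1)")
        if not self.vol_mean_larger > self.vol_mean_smaller > 0:
            raise ValueError("need vol_mean_larger > vol_mean_smaller > 0")
        if self.n_volumes <= 5:
            raise ValueError("n_volumes must exceed 5")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if not 0 < self.global_weight + self.network_weight < 1:
            raise ValueError("factor variance shares must sum inside (0, 1)")

    @classmethod
    def desk_scale(cls, **overrides) -> "SimulationParams":
        """Reduced problem size used by the replicate calibration suites:
        a 40-parcel atlas on a 24x28x20 grid with proportionally scaled
        lesion volumes (same 3.16:1 ratio)."""
        base = dict(n_parcels=40, grid_shape=(24, 28, 20),
                    vol_mean_larger=180.0, vol_mean_smaller=57.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class SubjectTruth:
    """Ground-truth record of what went into one simulated subject."""

    kappa_larger: float
    kappa_smaller: float
    volume_voxels: dict
    global_weight: float
    network_weight: float
    seed: int


@dataclass
class SubjectData:
    """Voxel-resolution simulated subject: 4D BOLD + lesions + confounds."""

    bold: BoldRun
    lesions: LesionSet
    confounds: pd.DataFrame
    truth: SubjectTruth


@dataclass
class ParcelSubject:
    """Parcel-resolution simulated subject.

    Shares the voxel path's latent model and lesion geometry, but represents
    the BOLD data directly as per-parcel and per-seed mean series (voxel
    noise enters as mask-averaged noise, sd / sqrt(n_voxels)).  Used where
    many replicate cohorts are needed.
    """

    parcel_series: np.ndarray            # (P, T); NaN rows = parcels emptied by exclusion
    seed_series: dict                    # seed_type -> (T,)
    lesions: LesionSet
    covariates: dict                     # seed_type -> {volume_mm3, tsnr, n_networks}
    seed_centroids: dict                 # seed_type -> (3,) world mm
    n_voxels_used: np.ndarray            # per parcel, after tumor exclusion
    truth: SubjectTruth


def band_limited_series(rng: np.random.Generator, n_series: int, n_volumes: int,
                        tr_seconds: float, low: float = 0.01, high: float = 0.1) -> np.ndarray:
    """Unit-variance Gaussian series with support only in [low, high] Hz."""
    freqs = np.fft.rfftfreq(n_volumes, tr_seconds)
    sel = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not sel.any():
        raise ValueError("band contains no frequency bin at this T and TR")
    coef = np.zeros((n_series, freqs.size), dtype=complex)
    coef[:, sel] = rng.standard_normal((n_series, sel.sum())) + 1j * rng.standard_normal((n_series, sel.sum()))
    x = np.fft.irfft(coef, n=n_volumes, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def ar1_noise(rng: np.random.Generator, shape: tuple, rho: float, sd: float) -> np.ndarray:
    """AR(1)+white noise along the last axis, unit marginal variance times sd."""
    w = rng.standard_normal(shape)
    if rho != 0.0:
        from scipy.signal import lfilter
        w = lfilter([1.0], [1.0, -rho], w, axis=-1) * np.sqrt(1.0 - rho**2)
    return sd * w


def _draw_volume(rng: np.random.Generator, mean: float, cv: float) -> float:
    sigma2 = np.log1p(cv**2)
    return float(rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)))


def _place_one_lesion(rng: np.random.Generator, atlas: ParcelAtlas, target_voxels: float,
                      forbidden: np.ndarray | None, max_tries: int = 200) -> np.ndarray:
    """Spheroid with jittered semi-axes, fully inside the left hemisphere."""
    nx = atlas.labels.shape[0]
    half_limit = nx // 2
    left_vox = np.argwhere(atlas.brain_mask[:half_limit])
    if len(left_vox) == 0:
        raise PlacementError("no left-hemisphere brain voxels")
    r = (3.0 * target_voxels / (4.0 * np.pi)) ** (1.0 / 3.0)
    grid = np.array(atlas.labels.shape)
    for _ in range(max_tries):
        jit = rng.uniform(0.85, 1.15, size=3)
        jit /= jit.prod() ** (1.0 / 3.0)
        radii = np.maximum(r * jit, 1.0)
        center = left_vox[rng.integers(len(left_vox))]
        if center[0] - radii[0] < 0 or center[0] + radii[0] >= half_limit:
            continue
        if np.any(center[1:] - radii[1:] < 0) or np.any(center[1:] + radii[1:] >= grid[1:]):
            continue
        lo = np.maximum(np.floor(center - radii).astype(int), 0)
        hi = np.minimum(np.ceil(center + radii).astype(int) + 1, grid)
        sub = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
        dist = sum(((sub[d] - center[d]) / radii[d]) ** 2 for d in range(3))
        mask = np.zeros(atlas.labels.shape, dtype=bool)
        mask[tuple(s for s in sub)] = dist <= 1.0
        mask &= atlas.brain_mask
        if forbidden is not None:
            mask &= ~forbidden
        if mask.sum() >= max(2, 0.5 * target_voxels):
            return mask
    raise PlacementError(f"no admissible placement for a {target_voxels:.0f}-voxel lesion")


def place_lesions(rng: np.random.Generator, atlas: ParcelAtlas,
                  params: SimulationParams, max_tries: int = 50) -> LesionSet:
    """Draw paired lesion volumes and place disjoint spheroids off-midline."""
    for _ in range(max_tries):
        v_l = _draw_volume(rng, params.vol_mean_larger, params.vol_cv)
        v_s = _draw_volume(rng, params.vol_mean_smaller, params.vol_cv)
        if not v_l > v_s:
            continue
        larger = _place_one_lesion(rng, atlas, v_l, None)
        smaller = _place_one_lesion(rng, atlas, v_s, forbidden=larger)
        if larger.sum() > smaller.sum():
            return LesionSet(
                larger_mask=larger, smaller_mask=smaller,
                larger_control=mirror_mask(larger), smaller_control=mirror_mask(smaller),
                voxel_volume_mm3=atlas.voxel_volume_mm3,
            )
    raise PlacementError("could not place a disjoint, ordered lesion pair")


def _latent_signals(rng: np.random.Generator, atlas: ParcelAtlas,
                    params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Return (parcel_latents (P,T), tumor_latents (2,T)), all unit variance."""
    P, T = atlas.n_parcels, params.n_volumes
    low, high = params.band
    g = band_limited_series(rng, 1, T, params.tr_seconds, low, high)[0]
    f = band_limited_series(rng, N_NETWORKS, T, params.tr_seconds, low, high)
    e = band_limited_series(rng, P, T, params.tr_seconds, low, high)
    b, a = params.global_weight, params.network_weight
    nets = np.array([atlas.network_of[p] - 1 for p in range(1, P + 1)])
    parcels = np.sqrt(b) * g + np.sqrt(a) * f[nets] + np.sqrt(1.0 - a - b) * e
    e_t = band_limited_series(rng, 2, T, params.tr_seconds, low, high)
    kap = np.array([params.kappa_larger, params.kappa_smaller])[:, None]
    tumors = kap * g + np.sqrt(1.0 - kap**2) * e_t
    return parcels, tumors


def _confound_table(rng: np.random.Generator, params: SimulationParams) -> pd.DataFrame:
    T = params.n_volumes
    trans = np.cumsum(rng.normal(0.0, 0.008, (T, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 0.00016, (T, 3)), axis=0)
    wm = ar1_noise(rng, (T,), params.ar1_rho, 1.0)
    csf = ar1_noise(rng, (T,), params.ar1_rho, 1.0)
    return pd.DataFrame(np.column_stack([trans, rot, wm, csf]), columns=list(CONFOUND_COLUMNS))


def subject_seed(master_seed: int, index: int) -> int:
    """Reproducible per-subject seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def simulate_subject(atlas: ParcelAtlas, params: SimulationParams, seed: int) -> SubjectData:
    """Simulate one voxel-resolution subject (4D BOLD, lesions, confounds)."""
    rng = np.random.default_rng(seed)
    lesions = place_lesions(rng, atlas, params)
    parcels, tumors = _latent_signals(rng, atlas, params)
    confounds = _confound_table(rng, params)

    shape = (*atlas.labels.shape, params.n_volumes)
    data = np.zeros(shape, dtype=np.float32)
    brain = atlas.brain_mask
    label_rows = atlas.labels[brain] - 1
    data[brain] = parcels[label_rows]
    data[lesions.larger_mask] = tumors[0]
    data[lesions.smaller_mask] = tumors[1]

    noisy = brain | lesions.larger_mask | lesions.smaller_mask
    data[noisy] += ar1_noise(rng, (int(noisy.sum()), params.n_volumes),
                             params.ar1_rho, params.noise_sd).astype(np.float32)
    # Confound leak: shared physiological + slow motion-linked drift.
    motion_drift = confounds[["trans_x", "trans_y", "trans_z"]].sum(axis=1).to_numpy()
    sd = motion_drift.std()
    drift = (motion_drift - motion_drift.mean()) / (sd if sd > 0 else 1.0)
    leak = params.confound_gain * (confounds["wm"].to_numpy() + confounds["csf"].to_numpy() + drift)
    data[noisy] += leak.astype(np.float32)
    data[noisy] += params.baseline

    affine = atlas.affine.copy()
    truth = SubjectTruth(
        kappa_larger=params.kappa_larger, kappa_smaller=params.kappa_smaller,
        volume_voxels={"larger": int(lesions.larger_mask.sum()),
                       "smaller": int(lesions.smaller_mask.sum())},
        global_weight=params.global_weight, network_weight=params.network_weight,
        seed=int(seed),
    )
    return SubjectData(bold=BoldRun(data, affine, params.tr_seconds),
                       lesions=lesions, confounds=confounds, truth=truth)


SEED_TYPES = ("larger", "smaller", "larger_control", "smaller_control")


def simulate_subject_parcel(atlas: ParcelAtlas, params: SimulationParams, seed: int) -> ParcelSubject:
    """Parcel-resolution subject: same latent model, mask-averaged noise.

    The mean series of a region with n voxels is its latent signal plus
    noise of sd ``noise_sd / sqrt(n)`` (independent voxel noise averages
    down); parcels partially covered by a tumor keep their latent mean and
    lose only voxels, exactly as tumor-excluded extraction behaves on the
    voxel path.
    """
    rng = np.random.default_rng(seed)
    lesions = place_lesions(rng, atlas, params)
    parcels, tumors = _latent_signals(rng, atlas, params)
    _ = _confound_table(rng, params)  # keep the RNG stream aligned with the voxel path
    P, T = atlas.n_parcels, params.n_volumes

    exclusion = lesions.larger_mask | lesions.smaller_mask
    counts = np.bincount(atlas.labels[atlas.brain_mask & ~exclusion].ravel(), minlength=P + 1)[1:]
    noise = ar1_noise(rng, (P + 4, T), params.ar1_rho, params.noise_sd)

    series = np.full((P, T), np.nan)
    used = counts.astype(int)
    ok = counts > 0
    series[ok] = (params.baseline + parcels[ok]
                  + noise[:P][ok] / np.sqrt(counts[ok])[:, None])

    seed_series: dict[str, np.ndarray] = {}
    covariates: dict[str, dict] = {}
    centroids: dict[str, np.ndarray] = {}
    from .preprocess_qc import tsnr as _tsnr
    for i, st in enumerate(SEED_TYPES):
        mask = lesions.mask_of(st)
        n_vox = int(mask.sum())
        if st in ("larger", "smaller"):
            latent = tumors[0] if st == "larger" else tumors[1]
        else:
            overlap = np.bincount(atlas.labels[mask].ravel(), minlength=P + 1)[1:]
            w = overlap / overlap.sum()
            latent = w @ parcels
        s = params.baseline + latent + noise[P + i] / np.sqrt(n_vox)
        seed_series[st] = s
        covariates[st] = {
            "volume_mm3": n_vox * atlas.voxel_volume_mm3,
            "tsnr": _tsnr(s),
            "n_networks": count_intersected_networks(mask, atlas),
        }
        centroids[st] = atlas.mask_centroid_mm(mask)

    truth = SubjectTruth(
        kappa_larger=params.kappa_larger, kappa_smaller=params.kappa_smaller,
        volume_voxels={"larger": int(lesions.larger_mask.sum()),
                       "smaller": int(lesions.smaller_mask.sum())},
        global_weight=params.global_weight, network_weight=params.network_weight,
        seed=int(seed),
    )
    return ParcelSubject(parcel_series=series, seed_series=seed_series, lesions=lesions,
                         covariates=covariates, seed_centroids=centroids,
                         n_voxels_used=used, truth=truth)


def simulate_cohort(params: SimulationParams, atlas: ParcelAtlas | None = None,
                    mode: str = "voxel") -> list:
    """Simulate ``params.n_subjects`` subjects with per-subject derived seeds."""
    if atlas is None:
        atlas = make_atlas(params.n_parcels, params.grid_shape, seed=params.seed,
                           voxel_size_mm=params.voxel_size_mm)
    maker = {"voxel": simulate_subject, "parcel": simulate_subject_parcel}[mode]
    return [maker(atlas, params, subject_seed(params.seed, i))
            for i in range(params.n_subjects)]


def save_subject(subject: SubjectData, atlas: ParcelAtlas, out_dir, prefix: str = "sub-01") -> None:
    """Write BOLD + masks as NIfTI, confounds as TSV, and a truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subject.bold.to_nifti().to_filename(out / f"{prefix}_bold.nii.gz")
    for st in SEED_TYPES:
        img = nib.Nifti1Image(subject.lesions.mask_of(st).astype(np.uint8), atlas.affine)
        img.to_filename(out / f"{prefix}_mask-{st}.nii.gz")
    subject.confounds.to_csv(out / f"{prefix}_confounds.tsv", sep="\t", index=False)
    (out / f"{prefix}_truth.json").write_text(json.dumps(asdict(subject.truth), indent=2))
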