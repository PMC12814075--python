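"""End-to-end cohort analysis: simulate -> metrics table -> paired statistics.

Two resolutions share all analysis code downstream of the parcel matrix:

* ``mode="voxel"`` runs the full image pipeline (trim, nuisance regression,
  smoothing, band-pass, activity maps, tumor-excluded parcel extraction);
* ``mode="parcel"`` starts from the simulator's parcel-resolution subjects
  (same latent model and lesion geometry) and therefore carries no activity
  family.  It is the resolution used for large replicate suites.

The per-subject metric rows form a long table (subject, seed_type, family,
metric, value, volume, tsnr, n_networks) consumed by
:func:`gliomaconn.paired_stats.run_cohort_stats`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import graph_topology as gt
from . import local_activity as la
from . import seed_connectivity as sc
from .paired_stats import CohortStatsReport, run_cohort_stats
from .preprocess_qc import preprocess, tsnr
from .synthetic_cohort import (SEED_TYPES, ParcelAtlas, ParcelSubject, SimulationParams,
                               SubjectData, make_atlas, simulate_cohort)


def seed_z_matrix(parcel_matrix: np.ndarray, seed_series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z weight matrix over usable parcels plus the seed as last node.

    Returns ``(z_matrix, usable_index)`` where ``usable_index`` maps matrix
    rows 0..U-1 back to parcel indices; row U is the seed node.
    """
    usable = np.flatnonzero(np.all(np.isfinite(parcel_matrix), axis=1)
                            & (np.std(parcel_matrix, axis=1) > 0))
    if usable.size == 0:
        raise ValueError("no usable parcels")
    stack = np.vstack([parcel_matrix[usable], seed_series])
    r = np.corrcoef(stack)
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z, usable


def _connectivity_topology_rows(subject_id, seed_type: str, seed_series: np.ndarray,
                                parcel_matrix: np.ndarray, seed_centroid: np.ndarray,
                                parcel_centroids: np.ndarray, covs: dict,
                                sparsity: float, alpha: float) -> list[dict]:
    fc = sc.seed_fc_result(seed_series, parcel_matrix, seed_centroid, parcel_centroids,
                           alpha=alpha)
    z, _ = seed_z_matrix(parcel_matrix, seed_series)
    fg = gt.build_graph(z, sparsity)
    seed_node = z.shape[0] - 1
    nodal = gt.nodal_metrics(fg, seed_node)
    base = dict(subject=subject_id, seed_type=seed_type, **covs)
    rows = [
        {**base, "family": "connectivity", "metric": "mean_fc", "value": fc.mean_fc},
        {**base, "family": "connectivity", "metric": "n_sig", "value": float(fc.n_sig)},
        {**base, "family": "connectivity", "metric": "mean_dist", "value": fc.mean_dist_mm},
        {**base, "family": "topology", "metric": "degree", "value": nodal["degree"]},
        {**base, "family": "topology", "metric": "betweenness", "value": nodal["betweenness"]},
        {**base, "family": "topology", "metric": "closeness", "value": nodal["closeness"]},
        {**base, "family": "topology", "metric": "clustering", "value": nodal["clustering"]},
    ]
    return rows


def analyze_subject_parcel(ps: ParcelSubject, atlas: ParcelAtlas, subject_id,
                           sparsity: float = gt.PRIMARY_SPARSITY,
                           alpha: float = 0.05) -> list[dict]:
    """Metric rows for one parcel-resolution subject (connectivity + topology)."""
    rows: list[dict] = []
    for st in SEED_TYPES:
        covs = {"volume": ps.covariates[st]["volume_mm3"],
                "tsnr": ps.covariates[st]["tsnr"],
                "n_networks": float(ps.covariates[st]["n_networks"])}
        rows += _connectivity_topology_rows(
            subject_id, st, ps.seed_series[st], ps.parcel_series,
            ps.seed_centroids[st], atlas.parcel_centroids, covs, sparsity, alpha)
    return rows


def analyze_subject_voxel(subject: SubjectData, atlas: ParcelAtlas, subject_id,
                          sparsity: float = gt.PRIMARY_SPARSITY, alpha: float = 0.05,
                          n_drop: int = 5, fwhm_mm: float = 5.0,
                          band: tuple[float, float] = (0.01, 0.1),
                          total_band: tuple[float, float] = (0.0, 0.25)) -> tuple[list[dict], dict]:
    """Full voxel pipeline for one subject.

    Returns ``(metric_rows, qc_dict)``.  Activity values are the mean
    z-scored metric within each mask; tSNR per ROI is computed on the
    trimmed (pre-regression) run, which still carries the signal baseline.
    """
    lesions = subject.lesions
    brain = atlas.brain_mask | lesions.larger_mask | lesions.smaller_mask
    pre = preprocess(subject.bold, subject.confounds, brain, n_drop=n_drop,
                     fwhm_mm=fwhm_mm, band=band)
    masks = {st: lesions.mask_of(st) for st in SEED_TYPES}
    for st, m in masks.items():
        pre.qc.tsnr_by_roi[st] = tsnr(sc.mask_mean_series(pre.trimmed, m))

    maps = la.activity_maps(pre.smoothed, pre.filtered, brain, band=band, total=total_band)
    tumor_excl = [lesions.larger_mask, lesions.smaller_mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base_matrix, _ = sc.parcel_series(pre.filtered, atlas, tumor_excl)

    rows: list[dict] = []
    for st in SEED_TYPES:
        mask = masks[st]
        if st.endswith("_control"):
            # the control's own voxels are additionally excluded from parcels
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                matrix, _ = sc.parcel_series(pre.filtered, atlas, tumor_excl + [mask])
        else:
            matrix = base_matrix
        seed_series = sc.mask_mean_series(pre.filtered, mask)
        covs = {"volume": float(mask.sum()) * atlas.voxel_volume_mm3,
                "tsnr": pre.qc.tsnr_by_roi[st],
                "n_networks": float(_n_networks(mask, atlas))}
        base = dict(subject=subject_id, seed_type=st, **covs)
        for metric, zmap in (("alff", maps.alff_z), ("falff", maps.falff_z),
                             ("reho", maps.reho_z)):
            rows.append({**base, "family": "activity", "metric": metric,
                         "value": la.roi_summary(zmap, mask)})
        rows += _connectivity_topology_rows(
            subject_id, st, seed_series, matrix, atlas.mask_centroid_mm(mask),
            atlas.parcel_centroids, covs, sparsity, alpha)
    return rows, pre.qc.to_dict()


def _n_networks(mask, atlas) -> int:
    from .preprocess_qc import count_intersected_networks
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return count_intersected_networks(mask, atlas)


def run_cohort_analysis(params: SimulationParams, atlas: ParcelAtlas | None = None,
                        mode: str = "parcel", sparsity: float = gt.PRIMARY_SPARSITY,
                        alpha: float = 0.05, fit_lmms: bool = True,
                        apply_qc_gate: bool = True) -> tuple[pd.DataFrame, CohortStatsReport]:
    """Simulate a cohort and run it through metrics and paired statistics."""
    if atlas is None:
        atlas = make_atlas(params.n_parcels, params.grid_shape, seed=params.seed,
                           voxel_size_mm=params.voxel_size_mm)
    cohort = simulate_cohort(params, atlas=atlas, mode=mode)
    rows: list[dict] = []
    for i, subj in enumerate(cohort):
        sid = f"sub-{i + 1:02d}"
        if mode == "parcel":
            rows += analyze_subject_parcel(subj, atlas, sid, sparsity=sparsity, alpha=alpha)
        else:
            srows, qc = analyze_subject_voxel(subj, atlas, sid, sparsity=sparsity, alpha=alpha)
            if apply_qc_gate and qc["excluded"]:
                warnings.warn(f"{sid} excluded by QC: {qc['reason']}")
                continue
            rows += srows
    long_df = pd.DataFrame(rows)
    report = run_cohort_stats(long_df, alpha=alpha, fit_lmms=fit_lmms)
    return long_df, report
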