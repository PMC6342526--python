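"""End-to-end composition of the analysis stages.

One call takes a configuration (and optionally pre-rendered inputs) through
simulate -> preprocess -> segment -> refine -> quantify -> stats, writing
every intermediate artifact plus the fully resolved config and seed into a
run directory so a rerun reproduces all deterministic outputs
bit-identically. Stage boundaries are plain files (TIFF / CSV / JSON), so
any stage can be fed from external data instead — e.g. per-nucleus ratio
tables can go straight into the statistics stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, dump_config
from .preprocessing import (
    generate_psf,
    merge_nuclear_channels,
    otsu_mask,
    richardson_lucy,
    smooth,
    wiener_filter,
    write_stack,
)
from .quantify import (
    ROI,
    ROISet,
    assign_domains,
    extract_nuclei,
    filter_nuclei,
    normalize_dii,
    records_to_frame,
)
from .segmentation import (
    LabelMap,
    Neighborhood,
    merge_by_depth,
    merge_by_distance,
    merge_small_to_closest,
    remove_by_intensity,
    remove_by_size,
    steepest_ascent_label,
)
from .stack import ImageStack
from .stats import group_stats, ranked_ratio_auc
from .synthetic import generate_ground_truth, render_stack

__all__ = ["segment_stack", "quantify_stack", "run_pipeline", "roiset_from_split"]

logger = logging.getLogger(__name__)


def render_psf(config: PipelineConfig):
    """Render-time blur for simulated stacks, per ``simulate.psf_mode``.

    "model" shares the optical model of the preprocess block, so the
    restoration deconvolves with the kernel that produced the blur;
    "none" disables blur; a number is an isotropic Gaussian sigma in um.
    """
    mode = config.simulate.psf_mode
    if mode == "none":
        return None
    if mode == "model":
        p = config.preprocess
        s = config.simulate
        return generate_psf(
            numerical_aperture=p.psf_na,
            excitation_nm=p.psf_excitation_nm,
            emission_nm=p.psf_emission_nm,
            spacing=tuple(float(v) for v in s.voxel_spacing),
            refractive_index=p.psf_refractive_index,
        ).kernel
    return float(mode)


def preprocess_stack(stack: ImageStack, config: PipelineConfig) -> ImageStack:
    """The pre-segmentation chain on the merged nuclear channel.

    Deconvolution (optional), Wiener denoising (optional), voxelwise
    maximum merge of the two reporters, then median/Gaussian smoothing.
    Returns the single-channel image segmentation runs on; quantification
    always uses the unprocessed reporter channels.
    """
    p = config.preprocess
    work = stack
    if p.deconvolve:
        psf = generate_psf(
            numerical_aperture=p.psf_na,
            excitation_nm=p.psf_excitation_nm,
            emission_nm=p.psf_emission_nm,
            spacing=stack.spacing,
            refractive_index=p.psf_refractive_index,
        )
        work = richardson_lucy(work, psf, n_iterations=p.rl_iterations)
    if p.wiener:
        work = wiener_filter(work, size=p.wiener_size)
    merged = merge_nuclear_channels(work, ("DII", "mDII"))
    return smooth(
        merged,
        median_iterations=p.median_iterations,
        median_radius=p.median_radius,
        gaussian_sigma=p.gaussian_sigma,
        gaussian_iterations=p.gaussian_iterations,
    )


def segment_stack(merged: ImageStack, config: PipelineConfig) -> LabelMap:
    """Otsu mask, attractor labeling, then the refinement sequence.

    Default order: distance merge -> depth merge -> small-to-closest ->
    remove by size -> remove by intensity. Any step with a zero/disabled
    threshold is a no-op.
    """
    c = config.segment
    mask = otsu_mask(merged).mask
    hood = Neighborhood(c.neighborhood_kind, c.neighborhood_radius, c.neighborhood_physical)
    lm = steepest_ascent_label(merged, mask, hood)
    if c.merge_distance_um > 0:
        lm = merge_by_distance(lm, c.merge_distance_um)
    if c.merge_depth_threshold > 0:
        lm = merge_by_depth(lm, merged, c.merge_depth_threshold, hood, c.merge_depth_mode)
    if c.small_size_threshold_um3 > 0:
        lm = merge_small_to_closest(
            lm, c.small_size_threshold_um3, c.small_max_merge_distance_um
        )
    if c.remove_min_volume_um3 > 0:
        lm = remove_by_size(lm, c.remove_min_volume_um3)
    if c.remove_min_mean_intensity > 0:
        lm = remove_by_intensity(lm, merged, c.remove_min_mean_intensity)
    return lm


def quantify_stack(
    stack: ImageStack,
    labels: LabelMap,
    config: PipelineConfig,
    roiset: ROISet | None = None,
):
    """Normalization, extraction, filtering and domain assignment."""
    q = config.quantify
    dii = np.asarray(stack.channel("DII"), dtype=float)
    mdii = np.asarray(stack.channel("mDII"), dtype=float)
    if q.background_subtract > 0:
        dii = np.maximum(dii - q.background_subtract, 0.0)
        mdii = np.maximum(mdii - q.background_subtract, 0.0)
    dii_norm, scale = normalize_dii(dii, mdii, labels)
    records = extract_nuclei(labels, dii_norm, mdii)
    records = filter_nuclei(
        records,
        min_mean_mdii=q.min_mean_mdii,
        min_volume_um3=q.min_volume_um3,
        max_volume_um3=q.max_volume_um3,
        mdii_quantile=q.mdii_quantile,
    )
    if roiset is not None:
        records = assign_domains(records, roiset)
    return records, scale


def roiset_from_split(config: PipelineConfig) -> ROISet:
    """Rectangular adaxial/abaxial ROIs matching the synthetic domain split.

    The adaxial band is y in [0, split); abaxial is the rest. Polygons are
    drawn in physical (um) coordinates, matching record centroids.
    """
    s = config.simulate
    ny, nx = s.grid_shape[1], s.grid_shape[2]
    sy, sx = s.voxel_spacing[1], s.voxel_spacing[2]
    y_ext, x_ext = ny * sy, nx * sx
    y_split = s.domain_split * y_ext
    eps = 1e-9
    ad = ROI(
        tag="adaxial",
        polygon_yx=((0, 0), (0, x_ext), (y_split - eps, x_ext), (y_split - eps, 0)),
    )
    ab = ROI(
        tag="abaxial",
        polygon_yx=((y_split, 0), (y_split, x_ext), (y_ext, x_ext), (y_ext, 0)),
    )
    return ROISet(rois=[ad, ab], note="synthetic domain split")


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    stack: ImageStack | None = None,
    roiset: ROISet | None = None,
    write_artifacts: bool = True,
):
    """Run all stages and write the run directory.

    Without an input ``stack`` a synthetic one is generated from the
    simulate block (its ground truth is saved alongside). Returns a dict
    with records (DataFrame), group stats, the AUC result, the label map
    and the ground truth (if synthetic).
    """
    out = Path(out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=logging.INFO)

    gt = None
    stage = "simulate"
    try:
        if stack is None:
            params = config.synth_params()
            gt = generate_ground_truth(params)
            stack = render_stack(gt, params, psf=render_psf(config))
            if write_artifacts:
                write_stack(stack, out / "stack.tif")
                gt.to_csv(out / "ground_truth.csv")
        if roiset is None:
            roiset = roiset_from_split(config)

        stage = "preprocess"
        merged = preprocess_stack(stack, config)

        stage = "segment"
        labels = segment_stack(merged, config)
        logger.info("segment: %d objects", labels.n_objects)

        stage = "quantify"
        records, scale = quantify_stack(stack, labels, config, roiset)
        if gt is not None and gt.calibration.any():
            # the ratio-1.0 fiducial anchors the intensity scale but is not
            # tissue: discard the record at its (known) position
            cal_centers = gt.centers[gt.calibration]
            for rec in records:
                c = np.asarray(rec.centroid)
                if np.min(np.linalg.norm(cal_centers - c, axis=1)) < 2.0:
                    rec.domain = "discarded"
        df = records_to_frame(records)

        stage = "stats"
        results = {"normalization_scale": scale}
        per_group = {}
        for dom in ("adaxial", "abaxial"):
            sub = df[df["domain"] == dom]
            if len(sub):
                gs = group_stats(sub, dom)
                per_group[dom] = {
                    "n": gs.n, "mean": gs.mean, "sd": gs.sd, "sem": gs.sem,
                }
        results["groups"] = per_group
        ad = df.loc[df["domain"] == "adaxial", "ratio"].to_numpy()
        ab = df.loc[df["domain"] == "abaxial", "ratio"].to_numpy()
        if len(ad) and len(ab):
            auc = ranked_ratio_auc(ad, ab, method=config.stats.auc_method)
            results["auc"] = auc.auc
        else:
            auc = None
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise

    if write_artifacts:
        dump_config(config, out / "config.resolved.yaml")
        df.to_csv(out / "records.csv", index=False)
        roiset.to_json(out / "rois.json")
        labels_stack = ImageStack(
            labels.labels.astype(np.uint16),
            spacing=labels.spacing,
            bit_depth=16,
            channels=("labels",),
        )
        write_stack(labels_stack, out / "labels.tif")
        with open(out / "stats.json", "w") as fh:
            json.dump(results, fh, indent=1)

    return {
        "records": df,
        "stats": results,
        "auc": auc,
        "labels": labels,
        "ground_truth": gt,
        "config": config,
    }
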