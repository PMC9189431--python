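"""End-to-end processing of one multi-channel volume under one config.

The stage order is fixed: detect nuclear centres → smooth → top-hat
background removal → marker-controlled watershed of nuclei → (optionally)
watershed of cells → measurement → inner/outer classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from embryoseg.detect import DetectionSet, detect_blobs_hessian, detect_blobs_log
from embryoseg.io_config import MultiChannelVolume, PipelineConfig
from embryoseg.measure import CellRecord, classify_inner_outer, measure_cells, records_to_frame
from embryoseg.preprocess import gaussian_smooth, tophat_background
from embryoseg.segment import LabelVolume, segment_cells, segment_nuclei

logger = logging.getLogger("embryoseg")

__all__ = ["PipelineResult", "process_volume"]


@dataclass
class PipelineResult:
    detections: DetectionSet
    nuclei: LabelVolume
    cells: LabelVolume | None
    records: list[CellRecord]

    @property
    def n_cells(self) -> int:
        """Number of segmented (non-empty) cells."""
        return len(self.nuclei.ids)

    def table(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def process_volume(
    volume: MultiChannelVolume,
    config: PipelineConfig,
    *,
    cell_stage: bool = True,
    measure_stage: bool = True,
) -> PipelineResult:
    """Run the full pipeline on one volume.

    ``cell_stage`` / ``measure_stage`` allow detection-and-nuclei-only runs
    (e.g. when benchmarking cell counts over large parameter sweeps).
    """
    nucleus = volume.nucleus

    if config.detector == "basic":
        detections = detect_blobs_log(
            nucleus, config.detector_scale_um, config.detection_threshold
        )
    else:
        detections = detect_blobs_hessian(
            nucleus, config.detector_scale_um, config.detection_threshold
        )
    logger.info("detected %d nuclear centres (%s)", len(detections), config.detector)
    if len(detections) == 0:
        raise ValueError("no nuclear centres detected; lower the detection threshold")

    smoothed = gaussian_smooth(nucleus, config.nucleus_smooth_sigma_um)
    tophat = tophat_background(smoothed, config.tophat_radius_um, config.tophat_downsize)
    nuclei = segment_nuclei(detections, tophat, config.nucleus_threshold_method)

    cells = None
    if cell_stage and volume.cell is not None:
        cell_smoothed = gaussian_smooth(volume.cell, config.cell_smooth_sigma_um)
        cells = segment_cells(
            nuclei,
            cell_smoothed,
            threshold_method=config.cell_threshold_method,
            mode=config.cell_marker_mode,
            lam=config.lambda_reg,
        )

    records: list[CellRecord] = []
    if measure_stage and len(nuclei.ids):
        records = measure_cells(
            nuclei, cells, volume, normalisation_channel=volume.normalisation_index
        )
        if records:
            classify_inner_outer(records, config.distance_threshold)
    return PipelineResult(detections=detections, nuclei=nuclei, cells=cells, records=records)
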