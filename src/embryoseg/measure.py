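"""Per-cell morphology and expression measurements; inner/outer classification.

Measurements follow the conventions of the output CSV: volumes in μm³
(voxel count x voxel volume), centroids as intensity-unweighted means of
voxel centres in μm, and *mean* intensities per region (recorded as such in
column names).  The cytoplasm of cell i is cell i minus nucleus i.

Inner/outer classification: with the embryo centroid defined as the
unweighted average of all nuclear centroids and ``D_i`` the distance of
cell i's nuclear centroid from it, cell i is *inner* iff
``D_i < D_T * D_m`` where ``D_m = max_j D_j`` and ``D_T`` (default 0.5) is
a dimensionless threshold.  The inequality is strict, so the most distant
cell is always outer.  Biologically the inner cells are inner-cell-mass
precursors and the outer cells trophectoderm precursors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu

from embryoseg.io_config import MultiChannelVolume
from embryoseg.segment import LabelVolume

logger = logging.getLogger("embryoseg")

__all__ = [
    "CellRecord",
    "measure_cells",
    "classify_inner_outer",
    "summarise_groups",
    "records_to_frame",
]


@dataclass
class CellRecord:
    """Measurements of one cell (all lengths μm, volumes μm³)."""

    cell_id: int
    nucleus_volume_um3: float
    cell_volume_um3: float | None
    volume_ratio: float | None               # cell / nucleus
    nucleus_centroid_um: np.ndarray          # (z, y, x)
    cell_centroid_um: np.ndarray | None
    nuc_mean: dict[int, float] = field(default_factory=dict)       # channel -> mean
    cyto_mean: dict[int, float] = field(default_factory=dict)
    nc_ratio: dict[int, float] = field(default_factory=dict)       # nuclear / cytoplasmic
    normalised_nuc_mean: dict[int, float] = field(default_factory=dict)
    inner_outer: str | None = None
    distance_to_centroid_um: float | None = None


def _region_means(data: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.asarray(ndimage.mean(data, labels=labels, index=ids), dtype=float)


def _centroids(labels: np.ndarray, ids: np.ndarray, spacing) -> np.ndarray:
    """Unweighted voxel-centre centroids (μm) per label id."""
    counts = np.bincount(labels.ravel(), minlength=ids.max() + 1)
    out = np.empty((len(ids), 3))
    for ax, (grid, sp) in enumerate(zip(np.indices(labels.shape, sparse=True), spacing)):
        sums = np.bincount(
            labels.ravel(),
            weights=np.broadcast_to(grid, labels.shape).ravel(),
            minlength=ids.max() + 1,
        )
        with np.errstate(invalid="ignore"):
            out[:, ax] = sums[ids] / counts[ids] * sp
    return out


def measure_cells(
    nuclei: LabelVolume,
    cells: LabelVolume | None,
    channels: MultiChannelVolume,
    normalisation_channel: int | None = None,
) -> list[CellRecord]:
    """Measure every labelled cell.

    ``cells`` may be None (nucleus-only pipelines); cytoplasmic statistics
    then stay missing.  For each expression channel the nuclear mean, the
    cytoplasmic mean (cell minus nucleus), their ratio, and — when a
    normalisation channel is configured — the nuclear mean divided by the
    nuclear mean of the normalisation channel (a depth-decay correction)
    are reported.  Cells whose cytoplasm is empty get missing cytoplasmic
    statistics and a warning.
    """
    spacing = nuclei.spacing
    voxel_vol = float(np.prod(spacing))
    nuc = nuclei.labels
    ids = nuclei.ids
    if len(ids) == 0:
        return []
    if cells is not None and cells.labels.shape != nuc.shape:
        raise ValueError("nucleus and cell label grids differ")

    nuc_counts = np.bincount(nuc.ravel(), minlength=ids.max() + 1)
    nuc_centroids = _centroids(nuc, ids, spacing)

    cell_counts = cyto = cell_centroids = None
    if cells is not None:
        cel = cells.labels
        cell_counts = np.bincount(cel.ravel(), minlength=ids.max() + 1)
        cyto = np.where(nuc == 0, cel, 0)
        cell_centroids = _centroids(cel, ids, spacing)
        cyto_counts = np.bincount(cyto.ravel(), minlength=ids.max() + 1)
        empty_cyto = [int(i) for i in ids if cell_counts[i] > 0 and cyto_counts[i] == 0]
        if empty_cyto:
            logger.warning("measure_cells: empty cytoplasm for cell(s) %s", empty_cyto)

    expr_idx = list(
        dict.fromkeys(
            [*channels.expression_indices]
            or [i for i in range(len(channels.channels))]
        )
    )
    nuc_means = {c: _region_means(channels.channels[c].data, nuc, ids) for c in expr_idx}
    cyto_means = (
        {c: _region_means(channels.channels[c].data, cyto, ids) for c in expr_idx}
        if cells is not None
        else {}
    )
    norm_means = None
    if normalisation_channel is not None:
        norm_means = _region_means(channels.channels[normalisation_channel].data, nuc, ids)

    records = []
    for k, i in enumerate(ids):
        i = int(i)
        nv = nuc_counts[i] * voxel_vol
        cv = None if cell_counts is None else cell_counts[i] * voxel_vol
        rec = CellRecord(
            cell_id=i,
            nucleus_volume_um3=nv,
            cell_volume_um3=cv,
            volume_ratio=(cv / nv) if (cv and nv > 0) else None,
            nucleus_centroid_um=nuc_centroids[k],
            cell_centroid_um=None if cell_centroids is None else cell_centroids[k],
        )
        for c in expr_idx:
            nm = float(nuc_means[c][k])
            rec.nuc_mean[c] = nm
            if cells is not None:
                cm = float(cyto_means[c][k])
                rec.cyto_mean[c] = cm
                rec.nc_ratio[c] = nm / cm if np.isfinite(cm) and cm != 0 else float("nan")
            if norm_means is not None and normalisation_channel != c:
                denom = float(norm_means[k])
                rec.normalised_nuc_mean[c] = nm / denom if denom else float("nan")
        records.append(rec)
    return records


def classify_inner_outer(
    records: list[CellRecord], distance_threshold: float = 0.5
) -> tuple[list[CellRecord], np.ndarray]:
    """Assign inner/outer classes in place; returns (records, embryo centroid).

    A single-cell embryo has ``D_m = 0`` and its cell is inner by
    convention (with a warning).
    """
    if not records:
        raise ValueError("no records to classify")
    if not (0.0 < distance_threshold < 1.0):
        raise ValueError("distance_threshold must lie in (0, 1)")
    centroids = np.stack([r.nucleus_centroid_um for r in records])
    embryo_centroid = centroids.mean(axis=0)
    d = np.linalg.norm(centroids - embryo_centroid, axis=1)
    d_m = float(d.max())
    if d_m == 0.0:
        logger.warning("classify_inner_outer: single-cell embryo, classed inner by convention")
    for rec, di in zip(records, d):
        rec.distance_to_centroid_um = float(di)
        rec.inner_outer = "inner" if (di < distance_threshold * d_m or d_m == 0.0) else "outer"
    return records, embryo_centroid


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Flatten records into the output table (one row per cell)."""
    rows = []
    for r in records:
        row = {
            "cell_id": r.cell_id,
            "nucleus_volume_um3": r.nucleus_volume_um3,
            "cell_volume_um3": r.cell_volume_um3,
            "volume_ratio": r.volume_ratio,
            "centroid_z_um": r.nucleus_centroid_um[0],
            "centroid_y_um": r.nucleus_centroid_um[1],
            "centroid_x_um": r.nucleus_centroid_um[2],
            "inner_outer": r.inner_outer,
            "distance_to_centroid_um": r.distance_to_centroid_um,
        }
        for c, v in r.nuc_mean.items():
            row[f"ch{c}_nuc_mean"] = v
        for c, v in r.cyto_mean.items():
            row[f"ch{c}_cyto_mean"] = v
        for c, v in r.nc_ratio.items():
            row[f"ch{c}_nc_ratio_mean"] = v
        for c, v in r.normalised_nuc_mean.items():
            row[f"ch{c}_nuc_mean_normalised"] = v
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=[
                "cell_id",
                "nucleus_volume_um3",
                "cell_volume_um3",
                "volume_ratio",
                "centroid_z_um",
                "centroid_y_um",
                "centroid_x_um",
                "inner_outer",
                "distance_to_centroid_um",
            ]
        )
    return pd.DataFrame(rows)


def summarise_groups(
    data: pd.DataFrame, value: str, group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group summary (median, IQR) plus pairwise two-sample Wilcoxon tests.

    The tests are two-sided Mann-Whitney U (exact where sample sizes allow
    and no ties are present, normal approximation with tie correction
    otherwise); no multiple-comparison correction is applied.  Groups with
    fewer than two observations are summarised but excluded from the
    comparisons, with a note.
    """
    groups = {k: np.asarray(v.dropna()) for k, v in data.groupby(group)[value]}
    summary = pd.DataFrame(
        [
            {
                group: k,
                "n": len(v),
                "median": np.median(v) if len(v) else np.nan,
                "q25": np.percentile(v, 25) if len(v) else np.nan,
                "q75": np.percentile(v, 75) if len(v) else np.nan,
            }
            for k, v in groups.items()
        ]
    )
    comparisons = []
    for a, b in combinations(groups, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            comparisons.append({"group_a": a, "group_b": b, "u": np.nan, "p": np.nan,
                                "note": "skipped: fewer than 2 observations"})
            continue
        res = mannwhitneyu(groups[a], groups[b], alternative="two-sided", method="auto")
        comparisons.append(
            {"group_a": a, "group_b": b, "u": float(res.statistic), "p": float(res.pvalue),
             "note": ""}
        )
    return summary, pd.DataFrame(comparisons)
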