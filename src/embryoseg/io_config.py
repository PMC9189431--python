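"""Volume containers, parameter-file handling and tabular/image I/O.

All physical quantities are expressed in micrometres.  Volumes use a fixed
(z, y, x) axis order with 0-based voxel coordinates; the voxel spacing
``(dz, dy, dx)`` may be anisotropic (confocal stacks are typically ~10x
coarser axially than laterally).
"""

from __future__ import annotations

import dataclasses
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("embryoseg")

__all__ = [
    "CalibratedVolume",
    "MultiChannelVolume",
    "PipelineConfig",
    "ConfigError",
    "read_volume",
    "write_volume",
    "write_label_volume",
    "read_label_volume",
    "write_outputs",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised for invalid, inconsistent or unknown configuration input."""


@dataclass(frozen=True)
class CalibratedVolume:
    """A single-channel 3D image with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities.
    spacing : tuple of float
        Voxel spacing ``(dz, dy, dx)`` in micrometres, all > 0.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={data.ndim}")
        if data.size == 0:
            raise ValueError("volume is empty")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be three finite positives, got {self.spacing}")
        if not np.isfinite(data).all():
            raise ValueError("volume contains non-finite intensities")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in μm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def physical_extent(self) -> tuple[float, float, float]:
        """Physical size of the volume per axis (μm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def with_data(self, data: np.ndarray) -> "CalibratedVolume":
        """Return a copy carrying the same calibration but new intensities."""
        return CalibratedVolume(data, self.spacing)


@dataclass
class MultiChannelVolume:
    """An ordered set of channels sharing one voxel grid.

    ``roles`` maps semantic roles onto channel indices: ``nucleus`` (required,
    a volumetric nuclear stain such as DAPI), ``cell`` (optional; membrane or
    volumetric cell marker), ``expression`` (list of channels to quantify) and
    ``normalisation`` (optional channel used to correct expression readouts
    for depth-dependent signal loss).
    """

    channels: list[CalibratedVolume]
    nucleus_index: int
    cell_index: int | None = None
    expression_indices: list[int] = field(default_factory=list)
    normalisation_index: int | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        ref = self.channels[0]
        for i, ch in enumerate(self.channels):
            if ch.shape != ref.shape or ch.spacing != ref.spacing:
                raise ValueError(f"channel {i} does not share the grid of channel 0")
        n = len(self.channels)
        all_idx = [self.nucleus_index, *self.expression_indices]
        if self.cell_index is not None:
            all_idx.append(self.cell_index)
        if self.normalisation_index is not None:
            all_idx.append(self.normalisation_index)
        for idx in all_idx:
            if not (0 <= int(idx) < n):
                raise ConfigError(f"channel role index {idx} out of range for {n} channels")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.channels[0].spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    @property
    def nucleus(self) -> CalibratedVolume:
        return self.channels[self.nucleus_index]

    @property
    def cell(self) -> CalibratedVolume | None:
        return None if self.cell_index is None else self.channels[self.cell_index]


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

_DETECTORS = ("basic", "advanced")
_CELL_MODES = ("membrane", "volume")


@dataclass
class PipelineConfig:
    """Every tunable of the batch pipeline, serialisable to one YAML file.

    An analysis is fully reproduced by re-running with the same parameter
    file, so serialisation must round-trip losslessly and unknown keys in a
    file are a hard error.
    """

    # channel roles (indices into the input volume's channel axis)
    nucleus_channel: int = 0
    cell_channel: int | None = None
    expression_channels: list[int] = field(default_factory=list)
    normalisation_channel: int | None = None

    # detection
    detector: str = "advanced"              # "basic" (LoG) | "advanced" (Hessian)
    detector_scale_um: float = 1.875        # blob radius (basic) / smoothing scale (advanced)
    detection_threshold: float = 5.0        # quality = detector response at the maximum

    # preprocessing
    nucleus_smooth_sigma_um: tuple[float, float, float] = (0.5, 0.3, 0.3)
    cell_smooth_sigma_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tophat_radius_um: float = 4.0
    tophat_downsize: int = 1                # block-downsample factor (x/y) before top-hat
    nucleus_threshold_method: str = "otsu"
    cell_threshold_method: str = "triangle"

    # cell segmentation
    cell_marker_mode: str = "membrane"      # "membrane" -> geodesic DT, "volume" -> Euclidean DT
    lambda_reg: float = 1.0                 # regularisation of the image-weighted metric

    # classification
    distance_threshold: float = 0.5         # D_T of the inner/outer rule

    # misc
    spacing_override_um: tuple[float, float, float] | None = None  # (dz, dy, dx)
    seed: int = 42
    output_dir: str = "embryoseg_out"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.detector not in _DETECTORS:
            raise ConfigError(f"detector must be one of {_DETECTORS}, got {self.detector!r}")
        if self.cell_marker_mode not in _CELL_MODES:
            raise ConfigError(
                f"cell_marker_mode must be one of {_CELL_MODES}, got {self.cell_marker_mode!r}"
            )
        if not (self.detector_scale_um > 0):
            raise ConfigError("detector_scale_um must be > 0")
        if not (self.tophat_radius_um > 0):
            raise ConfigError("tophat_radius_um must be > 0")
        if int(self.tophat_downsize) < 1:
            raise ConfigError("tophat_downsize must be an integer >= 1")
        if not (self.lambda_reg > 0):
            raise ConfigError("lambda_reg must be > 0")
        if not (0.0 < self.distance_threshold < 1.0):
            raise ConfigError("distance_threshold must lie in (0, 1)")
        for name in ("nucleus_smooth_sigma_um", "cell_smooth_sigma_um"):
            sig = getattr(self, name)
            if len(sig) != 3 or any(s < 0 for s in sig):
                raise ConfigError(f"{name} must be three non-negative values")
            setattr(self, name, tuple(float(s) for s in sig))
        if self.spacing_override_um is not None:
            sp = tuple(float(s) for s in self.spacing_override_um)
            if len(sp) != 3 or any(s <= 0 for s in sp):
                raise ConfigError("spacing_override_um must be three positive values")
            self.spacing_override_um = sp
        self.expression_channels = [int(i) for i in self.expression_channels]


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialise a config to a flat YAML parameter file."""
    Path(path).write_text(serialise_config(config))


def serialise_config(config: PipelineConfig) -> str:
    d = dataclasses.asdict(config)
    # tuples -> lists for YAML; parse() restores them
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return yaml.safe_dump(d, sort_keys=True, default_flow_style=None)


def parse_config(text: str) -> PipelineConfig:
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("parameter file does not contain a key/value mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown parameter(s): {sorted(unknown)}; known keys: {sorted(known)}")
    tuple_fields = {"nucleus_smooth_sigma_um", "cell_smooth_sigma_um", "spacing_override_um"}
    for k in tuple_fields & set(raw):
        if raw[k] is not None:
            raw[k] = tuple(raw[k])
    return PipelineConfig(**raw)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML parameter file; unknown keys are an error."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read parameter file {path}: {exc}") from exc
    return parse_config(text)


# ---------------------------------------------------------------------------
# Image I/O (TIFF / OME-TIFF)
# ---------------------------------------------------------------------------


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) in μm from OME or ImageJ metadata, if present."""
    if tf.ome_metadata:
        try:
            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                dx = px.get("PhysicalSizeX")
                dy = px.get("PhysicalSizeY")
                dz = px.get("PhysicalSizeZ")
                if dx and dy and dz:
                    return (float(dz), float(dy), float(dx))
        except ET.ParseError:  # pragma: no cover - malformed metadata
            pass
    if tf.imagej_metadata:
        meta = tf.imagej_metadata
        dz = meta.get("spacing")
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        if dz and res and res.value[0]:
            dx = res.value[1] / res.value[0]
            return (float(dz), float(dx), float(dx))
    return None


def read_volume(
    path: str | Path,
    *,
    nucleus_channel: int = 0,
    cell_channel: int | None = None,
    expression_channels: Sequence[int] = (),
    normalisation_channel: int | None = None,
    spacing_override: tuple[float, float, float] | None = None,
) -> MultiChannelVolume:
    """Read a TIFF/OME-TIFF stack into a role-annotated multi-channel volume.

    Spacing is taken from file metadata; an explicit ``spacing_override``
    takes precedence (a warning is logged if the two disagree).

    Raises
    ------
    IOError
        If the file cannot be read.
    ConfigError
        If a role refers to a missing channel or no spacing is available.
    ValueError
        If the data is not 3D.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            file_spacing = _spacing_from_tiff(tf)
    except (OSError, tifffile.TiffFileError, IndexError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc

    # Normalise to (C, Z, Y, X)
    axes = axes.replace("S", "C").replace("Q", "C")
    if "Z" not in axes or data.ndim < 3:
        raise ValueError(f"{path}: expected a 3D stack, got axes {axes!r} shape {data.shape}")
    if "C" not in axes:
        data = data[np.newaxis]
        axes = "C" + axes
    order = [axes.index(a) for a in "CZYX" if a in axes]
    extra = [i for i in range(data.ndim) if i not in order]
    if extra:  # drop singleton leading axes such as T
        data = data.squeeze(axis=tuple(extra))
        axes = "".join(a for a in axes if a in "CZYX")
        order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    spacing = spacing_override
    if spacing is None:
        spacing = file_spacing
        if spacing is None:
            raise ConfigError(
                f"{path}: no voxel spacing in metadata; provide spacing_override_um"
            )
    elif file_spacing is not None and not np.allclose(file_spacing, spacing):
        logger.warning(
            "%s: config spacing %s overrides file metadata spacing %s",
            path, spacing, file_spacing,
        )

    channels = [CalibratedVolume(data[c], spacing) for c in range(data.shape[0])]
    return MultiChannelVolume(
        channels,
        nucleus_index=int(nucleus_channel),
        cell_index=None if cell_channel is None else int(cell_channel),
        expression_indices=list(expression_channels),
        normalisation_index=normalisation_channel,
    )


def write_volume(path: str | Path, volume: CalibratedVolume, *, dtype=None) -> None:
    """Write a single-channel calibrated volume as OME-TIFF."""
    dz, dy, dx = volume.spacing
    data = volume.data if dtype is None else np.asarray(volume.data, dtype=dtype)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def write_label_volume(path: str | Path, labels, spacing) -> None:
    """Write an integer label volume (0 = background) as uint16 OME-TIFF."""
    arr = np.asarray(labels)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    write_volume(path, CalibratedVolume(arr.astype(np.uint16), spacing))


def read_label_volume(path: str | Path):
    """Read back a label volume written by :func:`write_label_volume`."""
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        spacing = _spacing_from_tiff(tf)
    return np.asarray(data), spacing


def write_outputs(
    outdir: str | Path,
    *,
    nucleus_labels,
    cell_labels,
    spacing,
    records: pd.DataFrame,
    config: PipelineConfig | None = None,
    embryo_id: str = "embryo",
) -> dict[str, Path]:
    """Write the per-input result set: label volumes, measurement CSV, config.

    ``records`` is the DataFrame produced by :func:`embryoseg.measure.measure_cells`
    (possibly augmented by the inner/outer classifier).  Label ids in the
    volumes and the table must agree.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    nucleus_labels = np.asarray(nucleus_labels)
    table_ids = set() if records.empty else set(records["cell_id"].astype(int))
    label_ids = set(np.unique(nucleus_labels)) - {0}
    if table_ids != {int(i) for i in label_ids}:
        raise ValueError(
            f"label/record mismatch: labels {sorted(label_ids)} vs records {sorted(table_ids)}"
        )

    paths: dict[str, Path] = {}
    paths["nucleus_labels"] = outdir / f"{embryo_id}_nuclei.ome.tif"
    write_label_volume(paths["nucleus_labels"], nucleus_labels, spacing)
    if cell_labels is not None:
        paths["cell_labels"] = outdir / f"{embryo_id}_cells.ome.tif"
        write_label_volume(paths["cell_labels"], cell_labels, spacing)

    table = records.copy()
    table.insert(0, "embryo_id", embryo_id)
    paths["measurements"] = outdir / f"{embryo_id}_measurements.csv"
    table.to_csv(paths["measurements"], index=False)

    if config is not None:
        paths["config"] = outdir / f"{embryo_id}_params.yml"
        save_config(config, paths["config"])
    return paths
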