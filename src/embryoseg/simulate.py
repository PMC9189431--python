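"""Simulated fluorescence embryos with exact ground truth.

An embryo is a set of non-overlapping, randomly oriented ellipsoidal nuclei
packed inside a sphere.  Cell bodies are carved from the Euclidean distance
map around the nuclei (a Voronoi-like partition clipped to a maximum reach),
and membranes are the shells separating neighbouring cells plus the outer
embryo boundary.  Imaging is emulated on a fine grid: a noiseless
fluorophore map is painted, attenuated exponentially with depth, convolved
with a Gaussian point-spread function, block-averaged down to the output
voxel grid and finally degraded with multiplicative gamma noise (unit mean,
fixed shape).  The fluorophore contrast is solved so the rendered volume
hits a target signal-to-noise ratio — low-SNR embryos are weakly stained
rather than spiky, which keeps the whole SNR axis physically plausible.

SNR here — and everywhere in this package — means
``(mean foreground - mean background) / std background``, with foreground
the eroded true nucleus mask and background the complement of its dilation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from embryoseg.io_config import CalibratedVolume, MultiChannelVolume
from embryoseg.segment import LabelVolume

logger = logging.getLogger("embryoseg")

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "PackingError",
    "scaled_down_params",
    "place_nuclei",
    "render_ground_truth",
    "render_image",
    "simulate_embryo",
    "measure_snr",
]


class PackingError(RuntimeError):
    """Raised when nuclei cannot be packed without overlap."""


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the embryo simulator (lengths in μm, axes (z, y, x)).

    Defaults model the acquisition the pipeline targets: ellipsoidal nuclei
    with full axes ~10.0 x 7.5 x 7.5 μm inside an embryo-sized ball, imaged
    at 0.1 x 0.1 μm laterally and 1.0 μm axially.
    """

    n_cells: int = 8
    nucleus_semi_axes_um: tuple[float, float, float] = (5.0, 3.75, 3.75)
    packing_radius_um: float = 30.0
    target_snr: float | None = 10.0
    psf_sigma_um: tuple[float, float, float] = (0.8, 0.2, 0.2)
    hires_spacing_um: tuple[float, float, float] = (0.5, 0.1, 0.1)
    output_spacing_um: tuple[float, float, float] = (1.0, 0.1, 0.1)
    output_shape: tuple[int, int, int] = (80, 800, 800)
    attenuation_per_um: float = 0.01
    amplitude: float = 100.0        # fluorophore contrast when target_snr is None
    baseline: float = 10.0
    gamma_shape: float = 25.0       # multiplicative noise shape (CV = 1/sqrt(shape))
    membrane_thickness_um: float = 0.4
    cell_reach_um: float = 3.0
    cytoplasm_fraction: float = 0.2  # diffuse cell-marker signal inside cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.target_snr is not None and not self.target_snr > 0:
            raise ValueError("target_snr must be > 0 (or None to disable noise)")
        for h, o in zip(self.hires_spacing_um, self.output_spacing_um):
            if o + 1e-12 < h:
                raise ValueError("output spacing must be >= hi-res spacing per axis")
        f = self.block_factors
        for fi, h, o in zip(f, self.hires_spacing_um, self.output_spacing_um):
            if abs(fi * h - o) > 1e-9:
                raise ValueError("output spacing must be an integer multiple of hi-res spacing")

    @property
    def block_factors(self) -> tuple[int, int, int]:
        return tuple(
            int(round(o / h)) for h, o in zip(self.hires_spacing_um, self.output_spacing_um)
        )

    @property
    def hires_shape(self) -> tuple[int, int, int]:
        return tuple(n * f for n, f in zip(self.output_shape, self.block_factors))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.output_shape, self.output_spacing_um))

    @property
    def hires_offset_um(self) -> np.ndarray:
        """Physical position of hi-res voxel (0,0,0) in output-grid coordinates.

        The output grid anchors the physical frame (out voxel i at
        ``i * spacing``); hi-res voxels are the sub-voxels of each output
        block, so hi-res voxel 0 sits *before* output voxel 0's centre.
        """
        f = np.asarray(self.block_factors, dtype=float)
        h = np.asarray(self.hires_spacing_um, dtype=float)
        return -(f - 1.0) / 2.0 * h


def scaled_down_params(
    n_cells: int = 8, target_snr: float | None = 10.0, seed: int = 0, **overrides
) -> SimulationParams:
    """Half-scale preset for routine testing and validation sweeps.

    The full-size embryos are ~100M voxels each; this preset shrinks the
    embryo geometry by 2 (nuclei of full axes 5.0 x 3.75 x 3.75 μm) and
    coarsens the lateral sampling to 0.2 μm while keeping the 1 μm axial
    spacing, giving 192 x 192 x 40 output voxels per embryo.
    """
    base = dict(
        n_cells=n_cells,
        nucleus_semi_axes_um=(2.5, 1.875, 1.875),
        packing_radius_um=15.0,
        target_snr=target_snr,
        psf_sigma_um=(0.8, 0.2, 0.2),
        hires_spacing_um=(0.5, 0.2, 0.2),
        output_spacing_um=(1.0, 0.2, 0.2),
        output_shape=(40, 192, 192),
        membrane_thickness_um=0.3,
        cell_reach_um=1.5,
        seed=seed,
    )
    base.update(overrides)
    return SimulationParams(**base)


@dataclass
class GroundTruth:
    """Simulation truth on the output grid: centroids, labels, parameters."""

    centroids_um: np.ndarray            # (n, 3) nucleus centroids, (z, y, x) μm
    nucleus_labels: LabelVolume
    cell_labels: LabelVolume
    params: SimulationParams
    # hi-res fluorophore maps kept for rendering; not part of the public contract
    _hires_nucleus: np.ndarray | None = field(default=None, repr=False)
    _hires_cell_fluor: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.centroids_um)


# ---------------------------------------------------------------------------
# Nucleus placement
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Shoemake quaternion method)."""
    u1, u2, u3 = rng.random(3)
    q = np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )
    w, x, y, z = q[3], q[0], q[1], q[2]
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _fibonacci_sphere(n: int = 200) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )


_UNIT_DIRS = _fibonacci_sphere(200)
_OVERLAP_MARGIN_UM = 0.2


@dataclass(frozen=True)
class EllipsoidPose:
    centre_um: np.ndarray   # (3,) (z, y, x)
    rotation: np.ndarray    # (3, 3), body -> world


def _surface_points(pose: EllipsoidPose, semi: np.ndarray) -> np.ndarray:
    return pose.centre_um + (_UNIT_DIRS * semi) @ pose.rotation.T


def _points_inside(points: np.ndarray, pose: EllipsoidPose, semi_inflated: np.ndarray) -> bool:
    body = (points - pose.centre_um) @ pose.rotation
    return bool((np.sum((body / semi_inflated) ** 2, axis=1) < 1.0).any())


def place_nuclei(params: SimulationParams, rng: np.random.Generator | None = None):
    """Rejection-sample non-overlapping ellipsoid poses inside the packing sphere.

    Centres are uniform in a sphere of ``packing_radius_um`` about the volume
    centre, orientations uniform on SO(3).  A candidate is accepted if its
    surface (plus a small safety margin) clears every placed nucleus and the
    whole cell (nucleus + ``cell_reach_um``) fits inside the imaged volume.
    Deterministic given the RNG state.

    Raises
    ------
    PackingError
        If the attempt cap is exhausted — the requested density is infeasible.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    semi = np.asarray(params.nucleus_semi_axes_um, dtype=float)
    semi_inflated = semi + _OVERLAP_MARGIN_UM
    extent = np.asarray(params.extent_um, dtype=float)
    centre = extent / 2.0
    margin = params.cell_reach_um

    poses: list[EllipsoidPose] = []
    surfaces: list[np.ndarray] = []
    max_attempts = 5000 * params.n_cells
    max_consecutive = 3000  # saturation: no candidate fits any more
    attempts = consecutive = 0
    while len(poses) < params.n_cells:
        if attempts >= max_attempts or consecutive >= max_consecutive:
            raise PackingError(
                f"could not place {params.n_cells} nuclei of semi-axes {tuple(semi)} μm in a "
                f"{params.packing_radius_um} μm sphere (placed {len(poses)} after "
                f"{attempts} attempts); reduce the density or enlarge the packing radius"
            )
        attempts += 1
        consecutive += 1
        # uniform point in the packing sphere
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        r = params.packing_radius_um * rng.random() ** (1.0 / 3.0)
        c = centre + v * r
        rot = _random_rotation(rng)
        cand = EllipsoidPose(c, rot)

        # containment: the rotated ellipsoid plus the cell reach must fit in the volume
        support = np.sqrt(((semi + margin) ** 2 * rot**2).sum(axis=1))
        if ((c - support) < 0).any() or ((c + support) > extent).any():
            continue

        cand_surface = _surface_points(cand, semi)
        ok = True
        for pose, surf in zip(poses, surfaces):
            gap = np.linalg.norm(pose.centre_um - c)
            if gap > 2 * semi.max() + _OVERLAP_MARGIN_UM:
                continue
            if gap < 2 * semi.min():
                ok = False
                break
            if (
                _points_inside(cand_surface, pose, semi_inflated)
                or _points_inside(surf, cand, semi_inflated)
                or _points_inside(c[np.newaxis], pose, semi_inflated)
                or _points_inside(pose.centre_um[np.newaxis], cand, semi_inflated)
            ):
                ok = False
                break
        if ok:
            poses.append(cand)
            surfaces.append(cand_surface)
            consecutive = 0
    return poses


# ---------------------------------------------------------------------------
# Ground-truth rendering
# ---------------------------------------------------------------------------


def _paint_nuclei(poses, params: SimulationParams) -> np.ndarray:
    """Voxelise the ellipsoids on the hi-res grid as labels 1..n."""
    shape = params.hires_shape
    h = np.asarray(params.hires_spacing_um, dtype=float)
    offset = params.hires_offset_um
    semi = np.asarray(params.nucleus_semi_axes_um, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    for i, pose in enumerate(poses, start=1):
        lo = np.maximum(np.floor((pose.centre_um - semi.max() - offset) / h).astype(int), 0)
        hi = np.minimum(
            np.ceil((pose.centre_um + semi.max() - offset) / h).astype(int) + 1, shape
        )
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]) * h[0] + offset[0],
            np.arange(lo[1], hi[1]) * h[1] + offset[1],
            np.arange(lo[2], hi[2]) * h[2] + offset[2],
            indexing="ij",
        )
        pts = np.stack([zz, yy, xx], axis=-1) - pose.centre_um
        body = pts @ pose.rotation
        inside = (body**2 / semi**2).sum(axis=-1) <= 1.0
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = i
    return labels


def _downsample_labels(labels: np.ndarray, factors) -> np.ndarray:
    fz, fy, fx = factors
    return labels[fz // 2::fz, fy // 2::fy, fx // 2::fx]


def render_ground_truth(poses, params: SimulationParams) -> GroundTruth:
    """Voxelise poses into nucleus/cell labels and a membrane shell.

    Cell i is the set of voxels whose nearest nucleus (by anisotropic EDT)
    is nucleus i, clipped to ``cell_reach_um`` beyond the nucleus surface;
    the membrane is the inter-cell boundary plus the outer shell of the
    configured thickness.  Labels are emitted on the output grid; centroids
    in output-grid physical coordinates.
    """
    h = np.asarray(params.hires_spacing_um, dtype=float)
    offset = params.hires_offset_um
    nuc_hi = _paint_nuclei(poses, params)

    dist, (iz, iy, ix) = ndimage.distance_transform_edt(
        nuc_hi == 0, sampling=h, return_indices=True
    )
    cells_hi = nuc_hi[iz, iy, ix]
    del iz, iy, ix
    cells_hi = np.where(dist <= params.cell_reach_um, cells_hi, 0).astype(np.int32)

    # membrane: faces between different cells + the outer shell
    membrane = (dist > params.cell_reach_um - params.membrane_thickness_um) & (
        dist <= params.cell_reach_um
    )
    for ax in range(3):
        a = np.swapaxes(cells_hi, 0, ax)
        m = np.swapaxes(membrane, 0, ax)
        diff = (a[1:] != a[:-1]) & (a[1:] > 0) & (a[:-1] > 0)
        m[1:] |= diff
        m[:-1] |= diff
    del dist

    # truth centroids from the hi-res voxelisation, in output-frame coords
    n = len(poses)
    counts = np.bincount(nuc_hi.ravel(), minlength=n + 1)[1:]
    if (counts == 0).any():
        raise PackingError("a nucleus voxelised to zero voxels; grid too coarse")
    centroids = np.stack(
        [
            (np.bincount(nuc_hi.ravel(), weights=g.ravel(), minlength=n + 1)[1:] / counts) * hh
            + off
            for g, hh, off in zip(np.indices(nuc_hi.shape, dtype=np.float32), h, offset)
        ],
        axis=1,
    )

    f = params.block_factors
    out_spacing = tuple(params.output_spacing_um)
    nuc_out = _downsample_labels(nuc_hi, f)
    cell_out = _downsample_labels(cells_hi, f)
    return GroundTruth(
        centroids_um=centroids,
        nucleus_labels=LabelVolume(nuc_out, out_spacing, kind="nucleus"),
        cell_labels=LabelVolume(cell_out, out_spacing, kind="cell"),
        params=params,
        _hires_nucleus=nuc_hi > 0,
        _hires_cell_fluor=(
            membrane.astype(np.float32)
            + params.cytoplasm_fraction * ((cells_hi > 0) & ~membrane)
        ),
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


def _block_average(data: np.ndarray, factors) -> np.ndarray:
    fz, fy, fx = factors
    nz, ny, nx = data.shape
    return (
        data.reshape(nz // fz, fz, ny // fy, fy, nx // fx, fx)
        .mean(axis=(1, 3, 5))
        .astype(np.float32)
    )


def _snr_masks(nucleus_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Foreground = eroded nucleus mask; background = complement of dilation."""
    st = np.ones((3, 3, 3), dtype=bool)
    fg = ndimage.binary_erosion(nucleus_mask, structure=st)
    if not fg.any():
        fg = nucleus_mask
    bg = ~ndimage.binary_dilation(nucleus_mask, structure=st, iterations=2)
    return fg, bg


def render_image(
    truth: GroundTruth, params: SimulationParams, rng: np.random.Generator | None = None
) -> MultiChannelVolume:
    """Render nucleus + membrane channels from a ground truth.

    Pipeline: paint fluorophore maps (baseline everywhere, fluorophore on
    the structures) → attenuate by ``exp(-attenuation * depth)`` with depth
    measured from the first z slice → Gaussian PSF blur → block-average to
    the output grid → multiplicative gamma noise of unit mean and fixed
    shape ``gamma_shape``.  The fluorophore contrast is solved so the
    rendered nucleus channel hits the target SNR exactly under that noise
    level; ``target_snr=None`` disables noise and paints ``amplitude``.
    """
    if truth._hires_nucleus is None:
        raise ValueError("ground truth lacks hi-res masks; regenerate with render_ground_truth")
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    h = np.asarray(params.hires_spacing_um, dtype=float)
    offset = params.hires_offset_um
    f = params.block_factors

    nz = params.hires_shape[0]
    depth = np.maximum(np.arange(nz) * h[0] + offset[0], 0.0)
    atten = np.exp(-params.attenuation_per_um * depth).astype(np.float32)[:, None, None]
    sig_vox = np.asarray(params.psf_sigma_um) / h

    # unit-contrast structure maps and the baseline map, rendered separately
    # (the imaging chain is linear, so contrast can be solved afterwards)
    structures = []
    for struct in (truth._hires_nucleus, truth._hires_cell_fluor):
        vol = np.asarray(struct, dtype=np.float32) * atten
        vol = ndimage.gaussian_filter(vol, sigma=sig_vox, mode="nearest")
        structures.append(_block_average(vol, f))
    base_profile = ndimage.gaussian_filter1d(
        np.broadcast_to(atten.ravel(), (nz,)).astype(np.float32), sigma=sig_vox[0],
        mode="nearest",
    )
    base_out = params.baseline * _block_average(
        np.broadcast_to(base_profile[:, None, None], params.hires_shape), f
    )

    noisy = params.target_snr is not None and np.isfinite(params.target_snr)
    if noisy:
        k = params.gamma_shape
        fg, bg = _snr_masks(truth.nucleus_labels.labels > 0)
        # background noise floor: Var(b*g) = E[b^2](1 + 1/k) - E[b]^2 over the bg region
        b = base_out[bg].astype(np.float64)
        sigma_bg = np.sqrt((b**2).mean() * (1.0 + 1.0 / k) - b.mean() ** 2)
        delta_s = float(structures[0][fg].mean() - structures[0][bg].mean())
        delta_b = float(base_out[fg].mean() - base_out[bg].mean())
        amplitude = (params.target_snr * sigma_bg - delta_b) / delta_s
        if amplitude <= 0:
            raise ValueError("non-positive contrast required; raise target_snr or baseline")
    else:
        amplitude = params.amplitude

    channels = []
    for s in structures:
        ch = base_out + np.float32(amplitude) * s
        if noisy:
            noise = rng.gamma(
                shape=params.gamma_shape, scale=1.0 / params.gamma_shape, size=ch.shape
            ).astype(np.float32)
            ch = ch * noise
        channels.append(ch)

    spacing = tuple(params.output_spacing_um)
    return MultiChannelVolume(
        [CalibratedVolume(c, spacing) for c in channels],
        nucleus_index=0,
        cell_index=1,
    )


def simulate_embryo(params: SimulationParams) -> tuple[MultiChannelVolume, GroundTruth]:
    """Place, voxelise and render one embryo; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    poses = place_nuclei(params, rng)
    truth = render_ground_truth(poses, params)
    image = render_image(truth, params, rng)
    return image, truth


def measure_snr(image: CalibratedVolume, truth: GroundTruth) -> float:
    """Measured SNR of a rendered volume against its ground-truth masks.

    This is *the* SNR definition used throughout:
    ``(mean fg - mean bg) / std bg`` with fg the eroded true nucleus mask
    and bg the complement of its dilation.  A constant image returns 0 with
    a warning.
    """
    mask = truth.nucleus_labels.labels > 0
    if not mask.any():
        raise ValueError("empty ground-truth foreground")
    fg, bg = _snr_masks(mask)
    data = image.data
    mean_fg = float(data[fg].mean())
    mean_bg = float(data[bg].mean())
    std_bg = float(data[bg].std())
    if std_bg == 0:
        if mean_fg == mean_bg:
            logger.warning("measure_snr: constant image, SNR defined as 0")
            return 0.0
        return np.inf
    return (mean_fg - mean_bg) / std_bg
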