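import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from embryoseg.detect import DetectionSet
from embryoseg.io_config import CalibratedVolume
from embryoseg.segment import (
    LabelVolume,
    _neighbour_table,
    riemannian_distance,
    segment_cells,
    segment_nuclei,
)
from embryoseg.simulate import EllipsoidPose, render_ground_truth, scaled_down_params

SPACING = (1.0, 0.2, 0.2)


def vol(data, spacing=SPACING):
    return CalibratedVolume(np.asarray(data, dtype=float), spacing)


def detections(points_um, spacing=SPACING):
    pts = np.asarray(points_um, dtype=float)
    return DetectionSet(pts, np.arange(len(pts), 0, -1, dtype=float), "basic", 1.0)


def oracle_distance(image, spacing, seed_mask, lam, mask=None):
    """Exhaustive shortest path on the explicit 26-neighbour graph."""
    shape = image.shape
    n = image.size
    steps, offsets, lengths = _neighbour_table(shape, spacing)
    flat = image.ravel().astype(float)
    allowed = np.ones(n, bool) if mask is None else mask.ravel()
    idx = np.arange(n).reshape(shape)
    rows, cols, vals = [], [], []
    for (dz, dy, dx), length in zip(steps, lengths):
        src = idx[
            max(0, -dz): shape[0] - max(0, dz),
            max(0, -dy): shape[1] - max(0, dy),
            max(0, -dx): shape[2] - max(0, dx),
        ].ravel()
        dst = src + (dz * shape[1] * shape[2] + dy * shape[2] + dx)
        ok = allowed[src] & allowed[dst]
        src, dst = src[ok], dst[ok]
        w = np.sqrt((lam * length**2 + (flat[src] - flat[dst]) ** 2) / (lam + 1.0))
        rows.append(src), cols.append(dst), vals.append(w)
    g = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    seeds = np.flatnonzero(seed_mask.ravel() & allowed)
    d = csgraph_dijkstra(g, directed=False, indices=seeds, min_only=True)
    return d.reshape(shape)


class TestSegmentNuclei:
    def test_single_seed_fills_mask_component(self):
        data = np.zeros((8, 24, 24))
        data[2:6, 8:16, 8:16] = 100.0
        seeds = detections([[4 * 1.0, 12 * 0.2, 12 * 0.2]])
        labels = segment_nuclei(seeds, vol(data), "mean")
        expect = data > data.mean()
        np.testing.assert_array_equal(labels.labels > 0, expect)
        assert set(np.unique(labels.labels)) == {0, 1}

    def test_two_seeds_split_at_nearest_seed_surface(self):
        """Two seeds in one merged blob: assignment equals the brute-force
        nearest-seed rule up to one voxel at the interface."""
        zz, yy, xx = np.indices((10, 60, 60), dtype=float)
        z, y, x = zz * SPACING[0], yy * SPACING[1], xx * SPACING[2]
        c1, c2 = np.array([5.0, 4.0, 6.0]), np.array([5.0, 8.0, 6.0])
        d1 = np.sqrt((z - c1[0]) ** 2 + (y - c1[1]) ** 2 + (x - c1[2]) ** 2)
        d2 = np.sqrt((z - c2[0]) ** 2 + (y - c2[1]) ** 2 + (x - c2[2]) ** 2)
        data = 100.0 * ((d1 < 3.0) | (d2 < 3.0))
        seeds = detections([c1, c2])
        labels = segment_nuclei(seeds, vol(data), "mean").labels
        nearest = np.where(d1 <= d2, 1, 2)
        mismatch = (labels > 0) & (labels != nearest)
        # tolerate a one-voxel-thick interface band
        interface = np.abs(d1 - d2) < max(SPACING)
        assert not (mismatch & ~interface).any()

    def test_seed_on_background_gives_empty_label(self, caplog):
        data = np.zeros((6, 20, 20))
        data[2:4, 4:10, 4:10] = 50.0
        seeds = detections([[3.0, 0.4, 0.4], [3.0, 7 * 0.2, 7 * 0.2]])
        labels = segment_nuclei(seeds, vol(data), "mean")
        assert 2 in labels.labels  # seed 2 lands in the blob
        assert 1 not in labels.labels
        assert any("empty labels" in r.message for r in caplog.records)

    def test_no_seeds_is_error(self):
        with pytest.raises(ValueError):
            segment_nuclei(
                DetectionSet(np.empty((0, 3)), np.empty(0), "basic", 1.0),
                vol(np.ones((4, 8, 8))),
                "mean",
            )


class TestRiemannianDistance:
    def test_constant_image_scales_euclidean_graph_distance(self):
        shape = (6, 10, 10)
        seed = np.zeros(shape, dtype=np.int32)
        seed[3, 5, 5] = 1
        nuclei = LabelVolume(seed, SPACING)
        channel = vol(np.full(shape, 42.0))
        for lam in (1.0, 10.0):
            d = riemannian_distance(nuclei, channel, lam)
            d_graph = oracle_distance(channel.data, SPACING, seed > 0, 1e12)
            np.testing.assert_allclose(d, np.sqrt(lam / (lam + 1)) * d_graph, rtol=1e-6)

    def test_lambda_infinity_is_euclidean_limit(self):
        """As lam -> inf the metric tends to the Euclidean graph distance,
        regardless of image content."""
        rng = np.random.default_rng(0)
        shape = (5, 8, 8)
        image = rng.random(shape) * 50
        seed = np.zeros(shape, dtype=np.int32)
        seed[2, 4, 4] = 1
        nuclei = LabelVolume(seed, SPACING)
        d = riemannian_distance(nuclei, vol(image), 1e9)
        d_graph = oracle_distance(np.zeros(shape), SPACING, seed > 0, 1e12)
        mask = d_graph > 0
        assert np.abs(d[mask] / d_graph[mask] - 1).max() < 1e-3

    def test_1d_hand_computed_path(self):
        """3 voxels, spacing 1 μm, I = (0, 10, 0), lam = 1: the distance to
        voxel 2 is d01 + d12 = 2 * sqrt((1 + 100) / 2)."""
        image = np.zeros((1, 1, 3))
        image[0, 0, 1] = 10.0
        seed = np.zeros((1, 1, 3), dtype=np.int32)
        seed[0, 0, 0] = 1
        nuclei = LabelVolume(seed, (1.0, 1.0, 1.0))
        d = riemannian_distance(nuclei, vol(image, (1.0, 1.0, 1.0)), 1.0)
        assert d[0, 0, 2] == pytest.approx(2 * np.sqrt(101 / 2), rel=1e-12)

    def test_exact_match_with_exhaustive_search(self, rng):
        """On small grids the implementation equals explicit Dijkstra on the
        full edge list, for several lam values."""
        shape = (6, 8, 7)
        image = rng.random(shape) * 30
        seed = np.zeros(shape, dtype=np.int32)
        seed[1, 2, 3] = 1
        seed[4, 6, 1] = 2
        nuclei = LabelVolume(seed, SPACING)
        for lam in (0.1, 1.0, 100.0):
            d = riemannian_distance(nuclei, vol(image), lam)
            ref = oracle_distance(image, SPACING, seed > 0, lam)
            np.testing.assert_allclose(d, ref, rtol=0, atol=1e-9)

    def test_bright_membrane_is_a_barrier(self):
        """Crossing a bright plane costs more than a Euclidean-equal path on
        the dark side."""
        shape = (3, 21, 21)
        image = np.zeros(shape)
        image[:, :14, 10] = 200.0  # wall with a gap at the bottom
        seed = np.zeros(shape, dtype=np.int32)
        seed[1, 2, 5] = 1
        nuclei = LabelVolume(seed, (1.0, 1.0, 1.0))
        d = riemannian_distance(nuclei, vol(image, (1.0, 1.0, 1.0)), 1.0)
        target = (1, 2, 15)  # directly across the wall
        euclidean = np.sqrt(10**2) * np.sqrt(1 / 2)
        assert d[target] > 1.5 * euclidean

    def test_invalid_lambda(self):
        nuclei = LabelVolume(np.ones((2, 2, 2), dtype=np.int32), SPACING)
        with pytest.raises(ValueError):
            riemannian_distance(nuclei, vol(np.zeros((2, 2, 2))), 0.0)


class TestSegmentCells:
    def _sphere_fixture(self):
        zz, yy, xx = np.indices((12, 60, 60), dtype=float)
        z, y, x = zz * SPACING[0], yy * SPACING[1], xx * SPACING[2]
        centre = np.array([6.0, 6.0, 6.0])
        r = np.sqrt((z - centre[0]) ** 2 + (y - centre[1]) ** 2 + (x - centre[2]) ** 2)
        return r, centre

    def test_volume_mode_single_nucleus_fills_sphere(self):
        r, centre = self._sphere_fixture()
        cell_marker = 100.0 * (r < 4.0)
        nuc = np.zeros(r.shape, dtype=np.int32)
        nuc[r < 1.5] = 1
        cells = segment_cells(
            LabelVolume(nuc, SPACING), vol(cell_marker), "mean", mode="volume"
        )
        np.testing.assert_array_equal(cells.labels > 0, cell_marker > cell_marker.mean())

    def test_volume_mode_two_nuclei_split_equidistant(self):
        zz, yy, xx = np.indices((12, 80, 60), dtype=float)
        z, y, x = zz * SPACING[0], yy * SPACING[1], xx * SPACING[2]
        c1, c2 = np.array([6.0, 5.0, 6.0]), np.array([6.0, 11.0, 6.0])
        d1 = np.sqrt(((z - c1[0])) ** 2 + (y - c1[1]) ** 2 + (x - c1[2]) ** 2)
        d2 = np.sqrt(((z - c2[0])) ** 2 + (y - c2[1]) ** 2 + (x - c2[2]) ** 2)
        mask_img = 100.0 * ((d1 < 4.5) | (d2 < 4.5))
        nuc = np.zeros(z.shape, dtype=np.int32)
        nuc[d1 < 1.5] = 1
        nuc[d2 < 1.5] = 2
        cells = segment_cells(LabelVolume(nuc, SPACING), vol(mask_img), "mean", "volume").labels
        # brute-force: distance to each nucleus *surface* decides the side
        from scipy import ndimage

        e1 = ndimage.distance_transform_edt(nuc != 1, sampling=SPACING)
        e2 = ndimage.distance_transform_edt(nuc != 2, sampling=SPACING)
        nearest = np.where(e1 <= e2, 1, 2)
        interface = np.abs(e1 - e2) < max(SPACING)
        mismatch = (cells > 0) & (cells != nearest) & ~interface
        assert mismatch.mean() < 1e-3

    def test_nucleus_inside_cell_and_partition(self):
        r, _ = self._sphere_fixture()
        cell_marker = 100.0 * (r < 4.0)
        nuc = np.zeros(r.shape, dtype=np.int32)
        nuc[r < 1.5] = 1
        for mode in ("volume", "membrane"):
            cells = segment_cells(LabelVolume(nuc, SPACING), vol(cell_marker), "mean", mode)
            assert ((cells.labels > 0) & (nuc > 0)).sum() == (nuc > 0).sum()
            assert set(np.unique(cells.labels)) <= {0, 1}

    def test_lambda_monotone_towards_euclidean(self):
        """Membrane-mode boundaries approach the volume-mode (EDT) boundaries
        as lam grows; at lam = 1e6 the two differ on <1% of foreground."""
        params = scaled_down_params(n_cells=2, target_snr=None, seed=0)
        c = np.asarray(params.extent_um) / 2
        poses = [
            EllipsoidPose(c + [0, -3.0, 0], np.eye(3)),
            EllipsoidPose(c + [0, 3.0, 0], np.eye(3)),
        ]
        truth = render_ground_truth(poses, params)
        from embryoseg.simulate import render_image

        image = render_image(truth, params)
        nuclei = truth.nucleus_labels
        mask = truth.cell_labels.labels > 0
        euclid = segment_cells(nuclei, image.cell, "mean", "volume", mask=mask).labels
        diffs = []
        for lam in (0.1, 10.0, 1e6):
            geo = segment_cells(nuclei, image.cell, "mean", "membrane", lam=lam, mask=mask).labels
            diffs.append((geo != euclid)[mask].mean())
        assert diffs[0] >= diffs[-1]
        assert diffs[-1] < 0.01

    def test_membrane_mode_matches_truth_voronoi(self):
        """Two-cell embryo with bright membranes: the recovered boundary sits
        within 2 lateral voxels of the ground-truth Voronoi membrane."""
        params = scaled_down_params(n_cells=2, target_snr=20.0, seed=0)
        c = np.asarray(params.extent_um) / 2
        poses = [
            EllipsoidPose(c + [0, -3.2, 0], np.eye(3)),
            EllipsoidPose(c + [0, 3.2, 0], np.eye(3)),
        ]
        truth = render_ground_truth(poses, params)
        from embryoseg.simulate import render_image

        image = render_image(truth, params)
        mask = truth.cell_labels.labels > 0
        cells = segment_cells(
            truth.nucleus_labels, image.cell, "mean", "membrane", lam=1.0, mask=mask
        ).labels
        gt = truth.cell_labels.labels
        # boundary plane is y = centre; compare label agreement off the interface
        yy = np.indices(gt.shape)[1] * params.output_spacing_um[1]
        interface = np.abs(yy - c[1]) <= 2 * params.output_spacing_um[1]
        disagree = (gt > 0) & (cells != gt) & ~interface
        assert disagree.sum() / (gt > 0).sum() < 0.02

    def test_empty_nuclei_error(self):
        with pytest.raises(ValueError):
            segment_cells(
                LabelVolume(np.zeros((2, 2, 2), dtype=np.int32), SPACING),
                vol(np.zeros((2, 2, 2))),
                "mean",
            )
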