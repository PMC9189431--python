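"""Shared helpers for the test suite."""

import numpy as np

from embryoseg.measure import CellRecord


def make_simple_records(centroids):
    return [
        CellRecord(
            cell_id=i + 1,
            nucleus_volume_um3=1.0,
            cell_volume_um3=2.0,
            volume_ratio=2.0,
            nucleus_centroid_um=np.asarray(c, dtype=float),
            cell_centroid_um=None,
        )
        for i, c in enumerate(centroids)
    ]
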