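"""Connected-cluster tables from thresholded Z-maps."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .decompose import ZMap

__all__ = ["ClusterRow", "extract_clusters", "clusters_to_frame"]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclasses.dataclass
class ClusterRow:
    """One connected supra-threshold cluster of a component's Z-map."""

    component_index: int | None
    sign: str                      # "positive" | "negative"
    peak_mm: tuple[float, float, float]
    peak_voxel: tuple[int, int, int]
    peak_abs_z: float
    size: int
    label: str = "unlabeled"


def extract_clusters(
    zmap: ZMap,
    min_size: int = 1,
    label_volume: np.ndarray | None = None,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
) -> list[ClusterRow]:
    """Connected components of surviving voxels, split by Z sign.

    26-connectivity by default (6 and 18 available).  The peak is the
    max-|Z| voxel of the cluster, mapped to world mm through ``affine``
    (identity -> voxel coordinates).  With a ``label_volume`` (integer
    grid of anatomical labels) the cluster label is the majority vote
    over its voxels.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    if label_volume is not None and label_volume.shape != zmap.values.shape:
        raise ValueError(
            f"label volume shape {label_volume.shape} does not match "
            f"Z-map shape {zmap.values.shape}"
        )
    aff = np.eye(4) if affine is None else np.asarray(affine, float)
    struct = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    rows: list[ClusterRow] = []
    for sign, m in (
        ("positive", zmap.surviving & (zmap.values > 0)),
        ("negative", zmap.surviving & (zmap.values < 0)),
    ):
        lab, n_lab = ndimage.label(m, structure=struct)
        for c in range(1, n_lab + 1):
            vox = np.argwhere(lab == c)
            if len(vox) < min_size:
                continue
            zvals = np.abs(zmap.values[tuple(vox.T)])
            peak = vox[int(np.argmax(zvals))]
            world = aff @ np.append(peak.astype(float), 1.0)
            label = "unlabeled"
            if label_volume is not None:
                vals, counts = np.unique(
                    label_volume[tuple(vox.T)].astype(int), return_counts=True
                )
                label = str(int(vals[int(np.argmax(counts))]))
            rows.append(
                ClusterRow(
                    component_index=zmap.component_index,
                    sign=sign,
                    peak_mm=tuple(np.round(world[:3], 3)),
                    peak_voxel=tuple(int(v) for v in peak),
                    peak_abs_z=float(zvals.max()),
                    size=int(len(vox)),
                    label=label,
                )
            )
    rows.sort(key=lambda r: (-r.size, -r.peak_abs_z))
    return rows


def clusters_to_frame(rows: list[ClusterRow]) -> pd.DataFrame:
    cols = [
        "component_index", "sign", "size", "peak_abs_z",
        "peak_x_mm", "peak_y_mm", "peak_z_mm", "label",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [
            {
                "component_index": r.component_index,
                "sign": r.sign,
                "size": r.size,
                "peak_abs_z": r.peak_abs_z,
                "peak_x_mm": r.peak_mm[0],
                "peak_y_mm": r.peak_mm[1],
                "peak_z_mm": r.peak_mm[2],
                "label": r.label,
            }
            for r in rows
        ]
    )[cols]
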