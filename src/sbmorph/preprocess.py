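"""Volume I/O, smoothing, masking and data-matrix assembly.

Turns a cohort of gray-matter concentration volumes into the
subjects x voxels matrix that the decomposition factors: one row per
subject (participants-table order), one column per in-mask voxel
(C-order over kept voxels, stable for the whole run).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GMVolume",
    "Mask",
    "DataMatrix",
    "FWHM_TO_SIGMA",
    "read_volume",
    "read_cohort",
    "smooth_volume",
    "make_mask",
    "assemble_matrix",
    "volumes_from_array",
]

#: FWHM = sigma * sqrt(8 ln 2) for a Gaussian kernel
FWHM_TO_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


@dataclasses.dataclass
class GMVolume:
    """One subject's gray-matter concentration map with voxel geometry."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str

    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def isotropic_voxel_mm(self, rtol: float = 1e-4) -> float:
        vs = self.voxel_sizes()
        if not np.allclose(vs, vs[0], rtol=rtol):
            raise ValueError(
                f"anisotropic voxels {vs} for subject {self.subject_id!r}; "
                "isotropic geometry required"
            )
        return float(vs[0])


@dataclasses.dataclass
class Mask:
    """Boolean analysis mask with a fixed linearization of kept voxels."""

    keep: np.ndarray               # boolean 3-D grid
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, bool)
        #: C-order flat indices of kept voxels — the column order of DataMatrix
        self.linear_index = np.flatnonzero(self.keep)

    @property
    def n_voxels(self) -> int:
        return int(self.linear_index.size)

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Masked, linearized vector of one volume."""
        return np.asarray(data).ravel()[self.linear_index]

    def scatter(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked vector back to the 3-D grid."""
        out = np.full(self.keep.size, fill, dtype=float)
        out[self.linear_index] = values
        return out.reshape(self.keep.shape)


@dataclasses.dataclass
class DataMatrix:
    """Subjects x in-mask-voxels matrix with its row/column provenance."""

    X: np.ndarray
    subject_order: list[str]
    mask: Mask

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]


def read_volume(path: str | Path, subject_id: str | None = None) -> GMVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), float)
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return GMVolume(data=data, affine=np.asarray(img.affine), subject_id=subject_id)


def _resolve_paths(
    volume_paths: dict[str, Path] | str | Path | Sequence[Path],
    ids: Sequence[str],
) -> dict[str, Path]:
    if isinstance(volume_paths, dict):
        return {k: Path(v) for k, v in volume_paths.items()}
    if isinstance(volume_paths, (str, Path)) and Path(volume_paths).is_dir():
        d = Path(volume_paths)
        out = {}
        for sid in ids:
            for suffix in (".nii.gz", ".nii"):
                p = d / f"{sid}{suffix}"
                if p.exists():
                    out[sid] = p
                    break
        return out
    return {Path(p).name.split(".")[0]: Path(p) for p in volume_paths}


def read_cohort(
    volume_paths: dict[str, Path] | str | Path | Sequence[Path],
    participants: pd.DataFrame,
) -> list[GMVolume]:
    """Load one volume per participant, in participants-table row order.

    ``volume_paths`` is a mapping ``id -> path``, a directory containing
    ``<id>.nii[.gz]`` files, or a list of paths whose stems are ids.
    """
    ids = list(participants["id"])
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids are not unique")
    mapping = _resolve_paths(volume_paths, ids)
    missing = [sid for sid in ids if sid not in mapping]
    if missing:
        raise ValueError(f"no volume found for participant(s): {missing}")
    vols = [read_volume(mapping[sid], sid) for sid in ids]
    ref = vols[0]
    for v in vols[1:]:
        if v.data.shape != ref.data.shape or not np.allclose(
            v.affine, ref.affine, atol=1e-4
        ):
            raise ValueError(
                f"geometry mismatch: subject {v.subject_id!r} has shape "
                f"{v.data.shape} vs {ref.data.shape} of {ref.subject_id!r}"
            )
        if not np.all(np.isfinite(v.data)):
            raise ValueError(f"non-finite voxel values in subject {v.subject_id!r}")
    return vols


def smooth_volume(vol: GMVolume, fwhm_mm: float) -> GMVolume:
    """Gaussian smoothing with the kernel width given as FWHM in mm.

    ``sigma_voxels = fwhm_mm / (voxel_mm * sqrt(8 ln 2))``; reflective
    boundary so constant regions and total intensity are conserved away
    from structure near the edge.  ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return GMVolume(vol.data.copy(), vol.affine.copy(), vol.subject_id)
    voxel_mm = vol.isotropic_voxel_mm()
    sigma = fwhm_mm / (voxel_mm * FWHM_TO_SIGMA)
    out = ndimage.gaussian_filter(vol.data, sigma=sigma, mode="reflect")
    return GMVolume(out, vol.affine.copy(), vol.subject_id)


def make_mask(volumes: Sequence[GMVolume], threshold: float = 0.05) -> Mask:
    """Keep voxels whose cohort-mean intensity exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not volumes:
        raise ValueError("empty cohort")
    mean = np.mean([v.data for v in volumes], axis=0)
    keep = mean > threshold
    if not keep.any():
        raise ValueError(
            f"empty mask: no voxel has cohort-mean intensity > {threshold}"
        )
    return Mask(keep=keep, affine=volumes[0].affine.copy())


def assemble_matrix(
    volumes: Sequence[GMVolume],
    mask: Mask,
    subject_order: Sequence[str] | None = None,
) -> DataMatrix:
    """Stack masked, linearized volumes into the subjects x voxels matrix."""
    by_id = {v.subject_id: v for v in volumes}
    if len(by_id) != len(volumes):
        raise ValueError("duplicate subject ids among volumes")
    order = list(subject_order) if subject_order is not None else [
        v.subject_id for v in volumes
    ]
    missing = [sid for sid in order if sid not in by_id]
    if missing:
        raise ValueError(f"subject_order names unknown subject(s): {missing}")
    ref_shape = mask.keep.shape
    rows = []
    for sid in order:
        v = by_id[sid]
        if v.data.shape != ref_shape:
            raise ValueError(
                f"mask shape {ref_shape} does not fit volume of {sid!r} "
                f"with shape {v.data.shape}"
            )
        row = mask.apply(v.data)
        if not np.all(np.isfinite(row)):
            raise ValueError(f"non-finite in-mask value for subject {sid!r}")
        rows.append(row)
    return DataMatrix(X=np.vstack(rows), subject_order=order, mask=mask)


def volumes_from_array(
    arr: np.ndarray, affine: np.ndarray, ids: Sequence[str]
) -> list[GMVolume]:
    """Wrap an ``(n, nx, ny, nz)`` array as in-memory cohort volumes."""
    if arr.shape[0] != len(ids):
        raise ValueError("one id per volume required")
    return [
        GMVolume(np.asarray(arr[i], float), np.asarray(affine), sid)
        for i, sid in enumerate(ids)
    ]
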