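"""Synthetic gray-matter cohorts with planted ground truth.

Each cohort is built as a linear mixture of ``k`` spatially independent
blob sources: subject *i*'s volume is

    V_i = baseline + sum_j A[i, j] * S_j + scanner_offset(i) + noise,

clipped at zero to emulate gray-matter concentration maps.  The mixing
matrix ``A`` (subject loadings) carries a planted group effect on one
component (a standardized mean shift of ``effect_size_d``), and the
patient group's clinical scores are constructed to correlate with that
component's loadings at a target Pearson ``score_rho``.  All planted
quantities — source maps, loadings, affected component, scores — are
returned (and optionally written) so downstream recovery can be scored
exactly.

The default design mirrors a balanced two-scanner case-control study:
50 controls and 32 patients, 8 sources, both groups represented equally
on each scanner.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Blob",
    "SourceSet",
    "CohortDesign",
    "SimulatedStudy",
    "default_blob_centers",
    "generate_sources",
    "generate_cohort",
    "mix_volumes",
    "render_volumes",
    "noise_sd_for_snr",
    "simulate_study",
    "mni_like_affine",
]

#: participants-table column order used throughout the package
PARTICIPANT_COLUMNS = [
    "id", "group", "age", "iq",
    "score_total", "score_social", "score_stereo", "scanner",
]

SCORE_COLUMNS = ["score_total", "score_social", "score_stereo"]

# ADOS-like score scales: (offset, spread) per score
_SCORE_SCALES = {
    "score_total": (12.0, 4.0),
    "score_social": (8.0, 3.0),
    "score_stereo": (4.0, 2.0),
}


def mni_like_affine(grid_shape: Sequence[int], voxel_size_mm: float) -> np.ndarray:
    """Isotropic affine centered on the grid (origin at the volume center)."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(grid_shape, float) - 1) / 2.0 * voxel_size_mm
    return aff


@dataclasses.dataclass(frozen=True)
class Blob:
    """One Gaussian-profile blob: truncated at ``radius`` (voxel units)."""

    center: tuple[float, float, float]
    radius: float
    amplitude: float = 1.0


@dataclasses.dataclass
class SourceSet:
    """``k`` spatial source maps on a common voxel grid."""

    maps: np.ndarray               # (k, nx, ny, nz)
    voxel_size_mm: float
    blobs: list[list[Blob]]        # per-source blob specification

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.maps.shape[1:])

    @property
    def affine(self) -> np.ndarray:
        return mni_like_affine(self.grid_shape, self.voxel_size_mm)


@dataclasses.dataclass
class CohortDesign:
    """Study design for a planted case-control cohort.

    ``effect_size_d`` is the standardized (Cohen's d, pooled-SD) mean
    loading difference between patients and controls on the affected
    component; ``score_rho`` is the target Pearson correlation between
    the affected component's patient loadings and the clinical scores.
    ``patient_var_mult`` multiplies the patient-group loading variance
    on the affected component to emulate the unequal variances a Welch
    design anticipates.
    """

    n_control: int = 50
    n_patient: int = 32
    affected_component: int = 6
    effect_size_d: float = 1.0
    score_rho: float = 0.45
    patient_var_mult: float = 1.5
    n_scanners: int = 2
    seed: int = 0

    def validate(self, k: int) -> None:
        if self.n_control < 1 or self.n_patient < 1:
            raise ValueError("both groups must be non-empty")
        if not (0 <= self.affected_component < k):
            raise ValueError(
                f"affected_component {self.affected_component} out of range for k={k}"
            )
        if not np.isfinite(self.effect_size_d):
            raise ValueError("effect_size_d must be finite")
        if abs(self.score_rho) > 1:
            raise ValueError(f"|score_rho| must be <= 1, got {self.score_rho}")
        if self.patient_var_mult <= 0:
            raise ValueError("patient_var_mult must be positive")
        if self.n_scanners < 1:
            raise ValueError("need at least one scanner")


def _blob_profile(grid_shape, blob: Blob) -> np.ndarray:
    """Truncated Gaussian bump, continuous at the support edge."""
    coords = np.indices(grid_shape, dtype=float)
    d2 = sum((coords[a] - blob.center[a]) ** 2 for a in range(3))
    sigma = blob.radius / 2.0
    edge = np.exp(-2.0)  # profile value at d == radius before rescaling
    prof = (np.exp(-d2 / (2.0 * sigma**2)) - edge) / (1.0 - edge)
    prof[d2 > blob.radius**2] = 0.0
    return blob.amplitude * np.clip(prof, 0.0, None)


def default_blob_centers(
    k: int, grid_shape: Sequence[int], radius: float
) -> list[tuple[float, float, float]]:
    """Deterministic max-spread placement of ``k`` disjoint blobs.

    Candidate centers sit on a lattice (spacing ~ 2*radius + 1, always
    including the feasible-box extremes); centers are picked greedily to
    maximize the minimum pairwise distance (k=2 lands on opposite
    corners) and must stay > 2*radius apart so supports cannot overlap.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    spacing = 2.0 * radius + 1.0
    axes = []
    for g in grid_shape:
        lo, hi = radius, g - 1 - radius
        if hi < lo:
            raise ValueError(f"blob radius {radius} does not fit in grid {grid_shape}")
        n = int((hi - lo) // spacing) + 1
        pos = lo + np.arange(n) * spacing
        if hi - pos[-1] > 1e-9:
            pos = np.append(pos, hi)
        axes.append(pos)
    cand = np.array(np.meshgrid(*axes, indexing="ij"), dtype=float).reshape(3, -1).T
    chosen = [0]
    while len(chosen) < k:
        d = np.min(
            np.linalg.norm(cand[:, None, :] - cand[chosen][None, :, :], axis=2), axis=1
        )
        d[chosen] = -1.0
        best = int(np.argmax(d))
        if d[best] <= 2.0 * radius:
            raise ValueError(
                f"cannot place {k} disjoint radius-{radius} blobs in grid "
                f"{grid_shape}: only {len(chosen)} fit"
            )
        chosen.append(best)
    return [tuple(cand[i]) for i in chosen]


def generate_sources(
    k: int,
    grid_shape: Sequence[int] = (24, 24, 24),
    voxel_size_mm: float = 2.0,
    blob_params: dict | list[list[Blob]] | None = None,
    seed: int = 0,
) -> SourceSet:
    """Build ``k`` blob source maps.

    ``blob_params`` is either an explicit per-source list of
    :class:`Blob` lists or a dict with keys ``radius`` (voxels; default
    scales with the grid, min(grid)/8 and at least 2), ``amplitude``
    (default 1.0) and ``jitter`` (uniform center perturbation in voxels,
    default radius/4, drawn from ``seed``).  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g < 2 for g in grid_shape):
        raise ValueError("grid_shape must be positive (each axis >= 2)")

    if isinstance(blob_params, list):
        per_source = [list(bl) for bl in blob_params]
        if len(per_source) != k:
            raise ValueError("explicit blob list must have one entry per source")
    else:
        params = dict(blob_params or {})
        radius = float(params.pop("radius", max(2.0, min(grid_shape) / 8.0)))
        amplitude = float(params.pop("amplitude", 1.0))
        jitter = float(params.pop("jitter", radius / 4.0))
        if params:
            raise ValueError(f"unknown blob_params keys: {sorted(params)}")
        rng = np.random.default_rng(seed)
        centers = default_blob_centers(k, grid_shape, radius + jitter)
        per_source = []
        for c in centers:
            off = rng.uniform(-jitter, jitter, size=3) if jitter > 0 else np.zeros(3)
            per_source.append([Blob(tuple(np.asarray(c) + off), radius, amplitude)])

    maps = np.zeros((k, *grid_shape))
    for j, blobs in enumerate(per_source):
        for b in blobs:
            if any(
                b.center[a] - b.radius < 0 or b.center[a] + b.radius > grid_shape[a] - 1
                for a in range(3)
            ):
                raise ValueError(
                    f"blob at {b.center} with radius {b.radius} extends outside "
                    f"grid {grid_shape} (source {j})"
                )
            maps[j] += _blob_profile(grid_shape, b)
    if not np.all(np.isfinite(maps)):
        raise ValueError("non-finite values in generated source maps")
    return SourceSet(maps=maps, voxel_size_mm=float(voxel_size_mm), blobs=per_source)


def generate_cohort(
    design: CohortDesign, k: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw subject loadings and a participants table for ``design``.

    Loadings are i.i.d. standard normal per component; the patient rows
    of the affected component get a ``patient_var_mult`` variance
    inflation and a mean shift of ``effect_size_d`` pooled standard
    deviations.  Clinical scores exist for patients only (controls get
    missing values) and target ``score_rho`` against the affected
    component's loadings; the scores are exactly affine in the loadings
    when ``|score_rho| == 1``.
    """
    design.validate(k)
    rng = np.random.default_rng(design.seed)
    nc, npat = design.n_control, design.n_patient
    n = nc + npat
    j = design.affected_component

    loadings = rng.standard_normal((n, k))
    pat = slice(nc, n)  # controls occupy the first nc rows
    loadings[pat, j] *= np.sqrt(design.patient_var_mult)
    pooled_sd = np.sqrt(
        ((nc - 1) * 1.0 + (npat - 1) * design.patient_var_mult) / (n - 2)
    )
    loadings[pat, j] += design.effect_size_d * pooled_sd

    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    group = ["control"] * nc + ["patient"] * npat
    age = np.round(np.clip(rng.normal(26.0, 5.0, n), 18.0, 39.0), 1)
    iq = np.round(
        np.concatenate([rng.normal(110.0, 12.0, nc), rng.normal(100.0, 15.0, npat)])
    )
    # balanced scanner assignment within each group
    scanner = np.empty(n, dtype=object)
    for rows in (range(nc), range(nc, n)):
        for pos, i in enumerate(rows):
            scanner[i] = f"scanner_{pos % design.n_scanners + 1}"

    lam = loadings[pat, j]
    z = (lam - lam.mean()) / lam.std(ddof=0) if lam.std(ddof=0) > 0 else lam * 0.0
    rho = design.score_rho
    scores = {}
    for name in SCORE_COLUMNS:
        eps = rng.standard_normal(npat)
        raw = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        offset, spread = _SCORE_SCALES[name]
        col = np.full(n, np.nan)
        col[pat] = offset + spread * raw
        scores[name] = col

    table = pd.DataFrame(
        {
            "id": ids,
            "group": group,
            "age": age,
            "iq": iq,
            **scores,
            "scanner": scanner,
        }
    )[PARTICIPANT_COLUMNS]
    return loadings, table


def noise_sd_for_snr(sources: SourceSet, snr: float) -> float:
    """Noise SD giving a global image SNR of ``snr``.

    SNR is defined as the grid-mean signal variance (sum over components
    of the squared map values, unit-variance loadings) divided by the
    noise variance.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    sig_var = float(np.mean(np.sum(sources.maps**2, axis=0)))
    return float(np.sqrt(sig_var / snr))


def mix_volumes(
    sources: SourceSet,
    loadings: np.ndarray,
    participants: pd.DataFrame | None = None,
    noise_sd: float = 0.0,
    scanner_offsets: dict[str, float] | None = None,
    baseline: float = 0.5,
    clip: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Realize subject volumes from the generative model.

    Returns an ``(n_subjects, *grid_shape)`` array.  ``scanner_offsets``
    maps scanner ids (from ``participants``) to additive intensity
    offsets applied over the whole volume.
    """
    loadings = np.asarray(loadings, float)
    if loadings.ndim != 2 or loadings.shape[1] != sources.k:
        raise ValueError(
            f"loadings must be (n_subjects, {sources.k}), got {loadings.shape}"
        )
    n = loadings.shape[0]
    offs = np.zeros(n)
    if scanner_offsets:
        if participants is None:
            raise ValueError("scanner_offsets requires a participants table")
        offs = participants["scanner"].map(lambda s: scanner_offsets.get(s, 0.0))
        offs = np.asarray(offs, float)
    flat = sources.maps.reshape(sources.k, -1)
    vols = loadings @ flat + baseline + offs[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vols = vols + rng.normal(0.0, noise_sd, size=vols.shape)
    if clip:
        np.clip(vols, 0.0, None, out=vols)
    return vols.reshape(n, *sources.grid_shape)


def render_volumes(
    sources: SourceSet,
    loadings: np.ndarray,
    participants: pd.DataFrame,
    out_dir: str | Path,
    noise_sd: float = 0.0,
    scanner_offsets: dict[str, float] | None = None,
    baseline: float = 0.5,
    clip: bool = True,
    seed: int = 0,
) -> list[Path]:
    """Write one NIfTI volume per subject; returns the paths in table order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vols = mix_volumes(
        sources, loadings, participants,
        noise_sd=noise_sd, scanner_offsets=scanner_offsets,
        baseline=baseline, clip=clip, seed=seed,
    )
    paths = []
    for i, sid in enumerate(participants["id"]):
        img = nib.Nifti1Image(vols[i].astype(np.float32), sources.affine)
        p = out_dir / f"{sid}.nii.gz"
        nib.save(img, p)
        paths.append(p)
    return paths


@dataclasses.dataclass
class SimulatedStudy:
    """A fully realized synthetic study with its planted ground truth."""

    sources: SourceSet
    loadings: np.ndarray
    participants: pd.DataFrame
    volumes: np.ndarray            # (n, *grid_shape)
    design: CohortDesign
    noise_sd: float
    baseline: float
    scanner_offsets: dict[str, float] | None

    @property
    def affine(self) -> np.ndarray:
        return self.sources.affine


def simulate_study(
    design: CohortDesign | None = None,
    k: int = 8,
    grid_shape: Sequence[int] = (24, 24, 24),
    voxel_size_mm: float = 2.0,
    blob_params: dict | None = None,
    snr: float | None = None,
    noise_sd: float | None = None,
    scanner_offsets: dict[str, float] | None = None,
    baseline: float = 0.5,
    clip: bool = True,
    out_dir: str | Path | None = None,
) -> SimulatedStudy:
    """One-call cohort simulation; optionally writes everything to disk.

    Exactly one of ``snr``/``noise_sd`` may be given (default: SNR 10).
    Seeds for sources, loadings and noise are all derived from
    ``design.seed``, so the full cohort is bit-reproducible.
    """
    design = design or CohortDesign()
    if blob_params is None:
        blob_params = {"amplitude": 0.12}
    sources = generate_sources(
        k, grid_shape, voxel_size_mm, blob_params, seed=design.seed
    )
    if snr is not None and noise_sd is not None:
        raise ValueError("give either snr or noise_sd, not both")
    if noise_sd is None:
        noise_sd = noise_sd_for_snr(sources, 10.0 if snr is None else snr)
    loadings, participants = generate_cohort(design, k)
    volumes = mix_volumes(
        sources, loadings, participants,
        noise_sd=noise_sd, scanner_offsets=scanner_offsets,
        baseline=baseline, clip=clip, seed=design.seed + 1,
    )
    study = SimulatedStudy(
        sources=sources, loadings=loadings, participants=participants,
        volumes=volumes, design=design, noise_sd=noise_sd,
        baseline=baseline, scanner_offsets=scanner_offsets,
    )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Write volumes, participants table and ground truth under ``out_dir``."""
    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(study.participants["id"]):
        img = nib.Nifti1Image(study.volumes[i].astype(np.float32), study.affine)
        nib.save(img, vol_dir / f"{sid}.nii.gz")
    study.participants.to_csv(out_dir / "participants.csv", index=False)

    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for j in range(study.sources.k):
        img = nib.Nifti1Image(study.sources.maps[j].astype(np.float32), study.affine)
        nib.save(img, truth_dir / f"source_{j:02d}.nii.gz")
    np.savetxt(
        truth_dir / "loadings.csv",
        study.loadings,
        delimiter=",",
        header=",".join(f"ic_{j:02d}" for j in range(study.sources.k)),
        comments="",
    )
    meta = {
        "k": study.sources.k,
        "grid_shape": list(study.sources.grid_shape),
        "voxel_size_mm": study.sources.voxel_size_mm,
        "affected_component": study.design.affected_component,
        "effect_size_d": study.design.effect_size_d,
        "score_rho": study.design.score_rho,
        "patient_var_mult": study.design.patient_var_mult,
        "n_control": study.design.n_control,
        "n_patient": study.design.n_patient,
        "seed": study.design.seed,
        "noise_sd": study.noise_sd,
        "baseline": study.baseline,
        "scanner_offsets": study.scanner_offsets,
    }
    (truth_dir / "truth.json").write_text(json.dumps(meta, indent=2))
    return out_dir
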