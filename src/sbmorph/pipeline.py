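"""End-to-end pipeline: volumes -> matrix -> ICA -> Z-maps -> statistics.

``run_pipeline`` executes read, smooth, mask, matrix assembly, order
selection (MDL unless overridden), ICASSO-stabilized Infomax, Z-map
export, group statistics and score correlations, writing every artifact
plus a flat key=value manifest recording the configuration, seeds and
derived quantities.  A rerun with the same configuration reproduces the
report files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from importlib.metadata import PackageNotFoundError, version as _pkg_version

from .clusters import clusters_to_frame, extract_clusters
from .decompose import decompose, estimate_order_mdl, zscale_and_threshold
from .icasso import run_icasso
from .preprocess import assemble_matrix, make_mask, read_cohort, smooth_volume
from .stats import compare_groups, confound_check, correlate_scores

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_FLOAT_FMT = "%.10g"

try:
    _version = _pkg_version("sbmorph")
except PackageNotFoundError:  # pragma: no cover - editable edge case
    _version = "unknown"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults follow the study settings: 8-mm FWHM smoothing, 20 ICASSO
    runs, |Z| > 2.5 display threshold, alpha 0.05 familywise.
    """

    volumes: str
    participants: str
    out_dir: str
    fwhm_mm: float = 8.0
    mask_threshold: float = 0.05
    k_override: int | None = None     # None -> MDL estimate
    n_icasso_runs: int = 20
    z_cut: float = 2.5
    two_sided_z: bool = True
    alpha: float = 0.05
    connectivity: int = 26
    min_cluster_size: int = 1
    base_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a flat ``key = value`` text config; kwargs take precedence."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv.pop(f.name)
            if f.name == "k_override":
                kwargs[f.name] = None if raw.lower() in ("", "none", "mdl") else int(raw)
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            elif f.type in ("bool", bool):
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw
        if kv:
            raise ValueError(f"unknown config keys: {sorted(kv)}")
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def to_items(self) -> list[tuple[str, str]]:
        out = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out.append((f.name, "mdl" if v is None else str(v)))
        return out


def _write_manifest(path: Path, items: list[tuple[str, str]]) -> None:
    path.write_text("".join(f"{k} = {v}\n" for k, v in items))


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: list[tuple[str, str]] = list(config.to_items())
    manifest.append(("sbmorph_version", _version))
    stage = "setup"

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    try:
        stage = "read_participants"
        ppath = Path(config.participants)
        if not ppath.exists():
            raise FileNotFoundError(f"participants file not found: {ppath}")
        participants = pd.read_csv(ppath)
        log(f"read {len(participants)} participants from {ppath}")

        stage = "read_cohort"
        vols = read_cohort(config.volumes, participants)
        log(f"read {len(vols)} volumes from {config.volumes}")

        stage = "smooth"
        if config.fwhm_mm > 0:
            vols = [smooth_volume(v, config.fwhm_mm) for v in vols]
        log(f"smoothed with FWHM {config.fwhm_mm} mm")

        stage = "mask"
        mask = make_mask(vols, config.mask_threshold)
        nib.save(
            nib.Nifti1Image(mask.keep.astype(np.uint8), mask.affine),
            out / "mask.nii.gz",
        )
        mask_hash = hashlib.sha256(mask.keep.tobytes()).hexdigest()[:16]
        manifest += [("n_voxels", str(mask.n_voxels)), ("mask_sha256", mask_hash)]
        log(f"mask keeps {mask.n_voxels} voxels")

        stage = "assemble_matrix"
        dm = assemble_matrix(vols, mask, list(participants["id"]))
        manifest.append(("n_subjects", str(dm.n_subjects)))

        stage = "order_estimation"
        if config.k_override is not None:
            k = int(config.k_override)
            log(f"using user-specified order k={k}")
        else:
            k = estimate_order_mdl(dm)
            log(f"MDL estimated order k={k}")
        manifest.append(("k_used", str(k)))

        stage = "ica"
        if config.n_icasso_runs >= 2:
            ica_res = run_icasso(dm, k, config.n_icasso_runs, config.base_seed)
            result = ica_res.result
            iq_df = pd.DataFrame(
                {
                    "component": np.arange(k),
                    "iq": ica_res.iq,
                    "iq_raw": ica_res.iq_raw,
                    "cluster_size": [len(c) for c in ica_res.clusters],
                }
            )
            manifest.append(("icasso_seeds", ",".join(map(str, ica_res.seeds))))
        else:
            result = decompose(dm, k, seed=config.base_seed)
            iq_df = pd.DataFrame(
                {"component": np.arange(k), "iq": np.nan, "iq_raw": np.nan,
                 "cluster_size": 1}
            )
            manifest.append(("icasso_seeds", str(config.base_seed)))
        iq_df.to_csv(out / "iq_table.csv", index=False, float_format=_FLOAT_FMT)
        log(f"decomposition done (converged={result.converged})")

        stage = "export_mixing"
        mix = pd.DataFrame(
            result.A, columns=[f"ic_{j:02d}" for j in range(k)]
        )
        mix.insert(0, "id", participants["id"].to_numpy())
        mix.to_csv(out / "mixing_matrix.csv", index=False, float_format=_FLOAT_FMT)

        stage = "zmaps"
        zmap_dir = out / "zmaps"
        zmap_dir.mkdir(exist_ok=True)
        cluster_frames = []
        for j in range(k):
            zm = zscale_and_threshold(
                result.S[j], mask, config.z_cut,
                two_sided=config.two_sided_z, component_index=j,
            )
            nib.save(
                nib.Nifti1Image(zm.values.astype(np.float32), mask.affine),
                zmap_dir / f"ic_{j:02d}_zmap.nii.gz",
            )
            nib.save(
                nib.Nifti1Image(zm.surviving.astype(np.uint8), mask.affine),
                zmap_dir / f"ic_{j:02d}_surviving.nii.gz",
            )
            rows = extract_clusters(
                zm, min_size=config.min_cluster_size,
                connectivity=config.connectivity, affine=mask.affine,
            )
            cluster_frames.append(clusters_to_frame(rows))
        pd.concat(cluster_frames, ignore_index=True).to_csv(
            out / "clusters.csv", index=False, float_format=_FLOAT_FMT
        )

        stage = "group_stats"
        comp_stats = compare_groups(result, participants["group"], config.alpha)
        comp_stats.to_csv(
            out / "component_stats.csv", index=False, float_format=_FLOAT_FMT
        )
        flagged = comp_stats.loc[comp_stats["significant"], "component"].tolist()
        manifest.append(("significant_components", ",".join(map(str, flagged))))
        log(f"group comparison flagged components: {flagged or 'none'}")

        stage = "correlations"
        corr_frames = []
        score_cols = [
            c for c in ("score_total", "score_social", "score_stereo")
            if c in participants.columns
        ]
        if flagged and score_cols:
            corr_frames.append(
                correlate_scores(
                    result, participants, flagged, score_cols, alpha=config.alpha
                )
            )
        if flagged and "iq" in participants.columns:
            for j in flagged:
                corr_frames.append(
                    confound_check(result, participants["iq"], j, name="iq")
                )
        corr = (
            pd.concat(corr_frames, ignore_index=True)
            if corr_frames
            else pd.DataFrame(
                columns=["component", "score", "r", "n", "p_raw",
                         "p_corrected", "significant", "kind"]
            )
        )
        corr.to_csv(out / "correlations.csv", index=False, float_format=_FLOAT_FMT)

        stage = "finalize"
        _write_manifest(out / "manifest.txt", manifest)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return out
    except Exception as e:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {e}\n")
        (out / "run.log").write_text("\n".join(log_lines) + f"\nFAILED at {stage}: {e}\n")
        raise PipelineError(f"pipeline stage {stage!r} failed: {e}") from e
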