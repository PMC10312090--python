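"""End-to-end pipeline: simulate -> correct -> fit -> ROI -> stats.

Each stage reads and writes ordinary NIfTI/CSV artifacts so that stages
can also be run standalone on prior outputs.  A JSON manifest records the
configuration, seeds and SHA-256 checksums of every artifact; re-running
with the same configuration and seed reproduces identical outputs.

Registration to an anatomical space and Gibbs-ringing correction are
deliberately pass-through: the pipeline assumes pre-registered,
pre-deringed input (hooks exist for supplying such volumes), since both
steps belong to external tooling.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import masks as masks_mod
from . import noise as noise_mod
from . import phantom as phantom_mod
from . import relaxometry as relax_mod
from . import stats as stats_mod
from .volume import save_echo_volume, save_labels, save_map

log = logging.getLogger("cswater")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full phantom-to-statistics run."""

    out_dir: str = "cswater_run"
    seed: int = 0
    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (1.3, 1.3, 5.0)
    snr_te1: float = 100.0          # first-echo SNR in WM (sets sigma)
    n_coils: int = 32
    lambda_laplacian: float = 100.0  # calibrated smoothing default; 0 = off
    erosion: masks_mod.ErosionSpec = field(default_factory=masks_mod.ErosionSpec)
    n_subjects: int = 60
    alpha: float = 0.05
    stages: tuple[str, ...] = ("simulate", "correct", "fit", "roi", "stats")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "erosion" in raw:
            raw["erosion"] = masks_mod.ErosionSpec(**raw["erosion"])
        for key in ("shape", "voxel_size", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "artifacts": {},
    }
    artifacts: dict[str, Path] = {}

    def record(name: str, path: Path):
        artifacts[name] = path
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    state: dict = {}
    for stage in config.stages:
        log.info("stage: %s", stage)
        try:
            if stage == "simulate":
                labels = phantom_mod.build_label_volume(
                    config.shape, config.voxel_size, seed=config.seed
                )
                truth = phantom_mod.DEFAULT_TISSUE_TRUTH
                clean = phantom_mod.forward_signal(truth, labels)
                wm_s0 = sum(truth.amplitudes[1])
                sigma = wm_s0 / config.snr_te1
                noisy = phantom_mod.add_ncchi_noise(
                    clean, noise_mod.NoiseModel(sigma, config.n_coils),
                    seed=config.seed + 1,
                )
                save_labels(labels, out / "labels.nii.gz")
                save_echo_volume(noisy, out / "echo.nii.gz")
                record("labels", out / "labels.nii.gz")
                record("echo", out / "echo.nii.gz")
                cohort = phantom_mod.simulate_cohort(
                    phantom_mod.default_cohort_spec(
                        n_subjects=config.n_subjects, seed=config.seed
                    )
                )
                cohort.to_csv(out / "cohort.csv", index=False, float_format="%.8g")
                record("cohort", out / "cohort.csv")
                state.update(labels=labels, echo=noisy, cohort=cohort, sigma=sigma)
            elif stage == "correct":
                bg = state["labels"].labels == 0
                model = noise_mod.estimate_sigma(state["echo"], bg, config.n_coils)
                table = noise_mod.build_correction_table(model)
                corrected = noise_mod.correct_magnitude(state["echo"], table)
                save_echo_volume(corrected, out / "corrected.nii.gz")
                record("corrected", out / "corrected.nii.gz")
                (out / "noise.json").write_text(
                    json.dumps({"sigma": model.sigma, "n_coils": model.n_coils})
                )
                record("noise", out / "noise.json")
                state.update(corrected=corrected, noise=model)
            elif stage == "fit":
                vol = state.get("corrected", state["echo"])
                # fit tissue voxels only; pure-CSF spaces are excluded
                # from regional WF statistics anyway
                mask = state["labels"].mask(1, 2, 3)
                fit = relax_mod.fit_volume(
                    vol,
                    mask,
                    config=relax_mod.FitConfig(
                        lambda_laplacian=config.lambda_laplacian
                    ),
                )
                for name, arr in (
                    ("mwf", fit.wf.mwf), ("iewf", fit.wf.iewf), ("csff", fit.wf.csff)
                ):
                    save_map(np.nan_to_num(arr), config.voxel_size, out / f"{name}.nii.gz")
                    record(name, out / f"{name}.nii.gz")
                save_map(fit.quality, config.voxel_size, out / "quality.nii.gz")
                record("quality", out / "quality.nii.gz")
                state["fit"] = fit
            elif stage == "roi":
                rois = masks_mod.erode_rois(state["labels"], config.erosion)
                for name, m in rois.masks.items():
                    save_map(m.astype(np.int8), config.voxel_size, out / f"roi_{name}.nii.gz")
                    record(f"roi_{name}", out / f"roi_{name}.nii.gz")
                means = masks_mod.regional_means(state["fit"].wf, rois)
                means.to_csv(out / "regional_means.csv", index=False, float_format="%.8g")
                record("regional_means", out / "regional_means.csv")
                state["rois"] = rois
            elif stage == "stats":
                summary, _ = stats_mod.analyze_cohort(state["cohort"], alpha=config.alpha)
                summary.to_csv(out / "stats_report.csv", index=False, float_format="%.8g")
                record("stats_report", out / "stats_report.csv")
            else:
                raise ValueError(f"unknown stage '{stage}'")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = "ok"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
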