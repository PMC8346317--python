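"""End-to-end orchestration: simulate, corrupt, train, denoise, evaluate,
grade, analyze, report.

Every stage that consumes randomness gets its own integer seed derived from
the global seed by a documented rule: ``numpy.random.SeedSequence(global)``
is spawned once per stage in the fixed stage order below, and each stage
seed is the first 31-bit word of its child sequence.  Re-running with the
same config therefore reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .cohort import CohortParams, cohort_to_csv, generate_cohort
from .grading import AsymmetryRule, NormalHeightTable, grade_cohort
from .metrics import (
    evaluate_harness,
    gaussian_blur_denoiser,
    identity_denoiser,
    plot_reports,
    reports_to_frame,
)
from .nn.model import DenoiserSpec, save_checkpoint
from .nn.training import TrainingConfig, train
from .noise import RicianParams, add_rician_noise
from .phantoms import phantom_bank
from .stats import build_report, plot_report

log = logging.getLogger("spinemri")

STAGES = (
    "simulate_images",
    "add_noise",
    "train",
    "denoise",
    "evaluate",
    "simulate_cohort",
    "grade",
    "analyze",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "images": {"n_images": 4, "height": 64, "width": 64, "n_structures": 5},
    "noise": {"sigma": 0.1},
    "train": {
        "depth": 3,
        "epochs": 3,
        "patch_size": 32,
        "patches_per_image": 16,
        "batch_size": 16,
        "learning_rate": 1e-3,
        "sigma_train": 0.1,
    },
    "evaluate": {"sigmas": [0.05, 0.1, 0.15]},
    "cohort": {"n_patients": 127, "target_rho_disc_facet": 0.753, "fixed_margins": True},
    "grading": {"reference_convention": "midpoint", "asymmetry_threshold": 7.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Derive one 31-bit seed per stage from the global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {
        name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(STAGES, children)
    }


def run_pipeline(config: dict | None = None, outdir="pipeline_out") -> Path:
    """Run the full demo pipeline; returns the artifact directory.

    On stage failure the exception propagates after the manifest records the
    failing stage; artifacts of completed stages are preserved.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(int(cfg["seed"]))
    cfg_blob = json.dumps(cfg, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
        "stage_seeds": seeds,
        "stages_completed": [],
        "image_hashes": {},
    }
    manifest_path = out / "manifest.json"

    def done(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("stage %s completed", stage)

    try:
        # 1. clean phantoms
        ic = cfg["images"]
        phantoms = phantom_bank(
            seeds["simulate_images"], ic["n_images"], ic["height"], ic["width"], ic["n_structures"]
        )
        (out / "images").mkdir(exist_ok=True)
        for i, img in enumerate(phantoms):
            p = out / "images" / f"clean_{i:02d}.png"
            sio.write_png(img, p)
            manifest["image_hashes"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        done("simulate_images")

        # 2. noisy versions
        sigma = float(cfg["noise"]["sigma"])
        noisy = []
        for i, img in enumerate(phantoms):
            res = add_rician_noise(img, RicianParams(sigma=sigma, seed=seeds["add_noise"] + i))
            noisy.append(res.image)
            sio.write_png(res.image, out / "images" / f"noisy_{i:02d}.png")
        done("add_noise")

        # 3. train on the clean phantoms
        tc = cfg["train"]
        tcfg = TrainingConfig(
            patch_size=tc["patch_size"],
            patches_per_image=tc["patches_per_image"],
            batch_size=tc["batch_size"],
            epochs=tc["epochs"],
            sigma_train=tc["sigma_train"],
            learning_rate=tc["learning_rate"],
            seed=seeds["train"],
        )
        result = train(None, phantoms, tcfg, spec=DenoiserSpec(depth=tc["depth"]))
        save_checkpoint(result.model, out / "model.ckpt.npz")
        pd.DataFrame({"epoch": range(1, len(result.loss_trace) + 1), "loss": result.loss_trace}).to_csv(
            out / "loss_trace.csv", index=False
        )
        done("train")

        # 4. denoise the noisy images
        for i, img in enumerate(noisy):
            sio.write_png(result.model.denoise(img), out / "images" / f"denoised_{i:02d}.png")
        done("denoise")

        # 5. metric harness
        methods = {
            "identity": identity_denoiser,
            "gaussian_blur": gaussian_blur_denoiser(1.0),
            "residual_net": result.model.denoise,
        }
        reports = evaluate_harness(methods, list(cfg["evaluate"]["sigmas"]), phantoms, seed=seeds["evaluate"])
        reports_to_frame(reports).to_csv(out / "metrics.csv", index=False)
        plot_reports(reports, out / "metrics.png")
        done("evaluate")

        # 6. cohort
        cc = cfg["cohort"]
        cohort = generate_cohort(
            CohortParams(
                n_patients=cc["n_patients"],
                target_rho_disc_facet=cc["target_rho_disc_facet"],
                fixed_margins=cc.get("fixed_margins", False),
                seed=seeds["simulate_cohort"],
            )
        )
        cohort_to_csv(cohort, out / "cohort.csv")
        done("simulate_cohort")

        # 7. grading
        gc = cfg["grading"]
        graded = grade_cohort(
            cohort,
            asymmetry_rule=AsymmetryRule(threshold_degrees=gc["asymmetry_threshold"]),
            height_table=NormalHeightTable(reference_convention=gc["reference_convention"]),
        )
        graded.to_csv(out / "cohort_graded.csv", index=False)
        done("grade")

        # 8. statistical report
        bundle = build_report(graded)
        bundle.save(out / "report")
        plot_report(bundle, out / "report")
        done("analyze")
    except Exception:
        manifest["failed_stage"] = next(
            (s for s in STAGES if s not in manifest["stages_completed"]), "unknown"
        )
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.exception("pipeline failed at stage %s", manifest["failed_stage"])
        raise
    return out
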