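"""One-command orchestration: generate -> preprocess -> correspond ->
shape space -> classify -> group statistics.

A single :class:`PipelineConfig` (YAML round-trippable) drives every
stage; every artifact is written under the output directory with the
resolved config and its hash, and a manifest lists all outputs. Runs are
deterministic given the config seed (one platform, one BLAS).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import (
    group_statistics as gs,
    particle_correspondence as pc,
    shape_space as sp,
    synthetic_cohort as sc,
    tr_classifier as tc,
    volume_preprocess as vp,
)

log = logging.getLogger("rvshape")


@dataclass
class PipelineConfig:
    cohort: sc.CohortSpec = field(default_factory=sc.CohortSpec)
    spacing: float = 1.5
    particles: int = 512
    optimizer: pc.OptimizerConfig = field(default_factory=pc.OptimizerConfig)
    pca_fraction: float = 0.99
    train_fraction: float = 0.8
    smote_k: int = 5
    lasso_repeats: int = 1000
    subset_fraction: float = 0.8
    top_modes: int = 4
    alpha_level: float = 0.05
    rotate_align: bool = False
    use_ground_truth_correspondence: bool = True
    mask_format: str = "nifti"
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.optimizer.validate()
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not 0 < self.pca_fraction <= 1:
            raise ValueError("pca_fraction must lie in (0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.particles < 1:
            raise ValueError("particles must be >= 1")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "deformation_params" in c:
                c["deformation_params"] = sc.DeformationParams(
                    **c["deformation_params"]
                )
            d["cohort"] = sc.CohortSpec(**c)
        if "optimizer" in d:
            d["optimizer"] = pc.OptimizerConfig(**d["optimizer"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _derived_seed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute every stage in order and return the run manifest."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(os.path.join(outdir, "config_resolved.yaml"))
    manifest_rows: list[dict] = []

    def record(stage: str, path: str) -> str:
        manifest_rows.append(
            {"stage": stage, "path": os.path.relpath(path, outdir),
             "config_hash": chash}
        )
        return path

    failed_marker = os.path.join(outdir, "FAILED")
    stage = "generate"
    try:
        # 1. synthetic cohort --------------------------------------------
        needs_masks = not config.use_ground_truth_correspondence
        subjects, cohort_manifest = sc.generate_cohort(
            config.cohort, with_masks=needs_masks
        )
        log.info("generate: %d subjects (seed %d)", len(subjects),
                 config.cohort.seed)
        cohort_dir = os.path.join(outdir, "cohort")
        os.makedirs(cohort_dir, exist_ok=True)
        cohort_manifest.to_csv(
            record(stage, os.path.join(cohort_dir, "manifest.csv")),
            index=False,
        )
        group3 = cohort_manifest["group"].to_numpy()
        subgroup = cohort_manifest["subgroup"].to_numpy()
        ids = list(cohort_manifest["subject_id"])

        # 2-3. preprocess + correspondence --------------------------------
        if config.use_ground_truth_correspondence:
            stage = "correspond"
            system = pc.attach_ground_truth(
                [s.shape for s in subjects], config.particles, ids
            )
            log.info("correspond: ground-truth bypass, M=%d",
                     config.particles)
        else:
            stage = "preprocess"
            masks = [s.mask for s in subjects]
            aligned, dts = vp.preprocess_cohort(
                masks, config.spacing, config.rotate_align
            )
            log.info("preprocess: %d masks -> DTs at %.2f mm", len(dts),
                     config.spacing)
            pre_dir = os.path.join(outdir, "preprocessed")
            os.makedirs(pre_dir, exist_ok=True)
            for mask, dt in zip(aligned, dts):
                mp = os.path.join(pre_dir, f"{mask.subject_id}.nii.gz")
                vp.write_mask_nifti(mask, mp)
                record(stage, mp)
                dp = os.path.join(pre_dir, f"{mask.subject_id}_dt.nii.gz")
                vp.write_dt_nifti(dt, dp)
                record(stage, dp)
            stage = "correspond"
            opt = dataclasses.replace(
                config.optimizer, M=config.particles,
                seed=_derived_seed(config.seed, "optimizer"),
            )
            system, _ = pc.optimize_particles(dts, opt)
            log.info("correspond: optimized M=%d over %d subjects",
                     config.particles, len(dts))
        part_dir = os.path.join(outdir, "particles")
        for p in pc.write_particles(system, part_dir):
            record("correspond", p)

        # 4. shape space ---------------------------------------------------
        stage = "shape_space"
        matrix = sp.ShapeMatrix.from_particles(system, group3, subgroup)
        model = sp.fit_pca(matrix)
        n99 = sp.num_modes_for_variance(model, config.pca_fraction)
        log.info("shape_space: %d modes for %.0f%% variance", n99,
                 100 * config.pca_fraction)
        sp.loadings_frame(model, matrix).to_csv(
            record(stage, os.path.join(outdir, "loadings.csv")), index=False
        )
        pd.DataFrame({"eigenvalue": model.eigenvalues}).to_csv(
            record(stage, os.path.join(outdir, "eigenvalues.csv")),
            index=False,
        )
        mode_dir = os.path.join(outdir, "modes")
        os.makedirs(mode_dir, exist_ok=True)
        for j in range(min(4, model.n_modes)):
            lo, hi = sp.mode_extremes(model, j)
            for tag, vec in (("minus", lo), ("plus", hi)):
                path = os.path.join(mode_dir,
                                    f"mode{j + 1}_{tag}2sd.particles")
                pc.write_particle_file(vec.reshape(-1, 3), path)
                record(stage, path)

        # 5. classification ------------------------------------------------
        stage = "classify"
        cohort = tc.LabeledCohort.from_loadings(model, matrix, n99)
        report = tc.classify_cohort(
            cohort, config.train_fraction, config.smote_k,
            config.lasso_repeats, config.subset_fraction, config.top_modes,
            _derived_seed(config.seed, "classifier"),
        )
        log.info("classify: acc=%.3f prec=%.3f rec=%.3f f1=%.3f",
                 report.accuracy, report.precision, report.recall, report.f1)
        rep = report.to_dict()
        rep["n_modes_99"] = n99
        with open(record(stage, os.path.join(outdir, "report.json")),
                  "w") as fh:
            json.dump(rep, fh, indent=2)
        pd.DataFrame(report.roc, columns=["fpr", "tpr"]).to_csv(
            record(stage, os.path.join(outdir, "roc.csv")), index=False
        )

        # 6. group statistics ----------------------------------------------
        stage = "group_statistics"
        contrasts = [("control", "tr"), ("healthy", "control"),
                     ("healthy", "tr")]
        for ga, gb in contrasts:
            if (group3 == ga).sum() < 2 or (group3 == gb).sum() < 2:
                continue
            sig = gs.hotelling_map(system, group3, ga, gb,
                                   config.alpha_level)
            arrows, mags = gs.mean_difference_arrows(matrix, ga, gb)
            gs.arrows_frame(arrows, mags, sig).to_csv(
                record(stage,
                       os.path.join(outdir, f"sigmap_{ga}_vs_{gb}.csv")),
                index=False,
            )
            log.info("group_statistics: %s vs %s, %d/%d significant points",
                     ga, gb, int(sig.significant.sum()), len(sig.t2))
        for sg in ("chf", "phtn"):
            in_a = (subgroup == sg) & (group3 == "tr")
            in_b = (subgroup == sg) & (group3 == "control")
            if in_a.sum() < 1 or in_b.sum() < 1:
                continue
            ldv = gs.ldv_scores(matrix, in_a, in_b)
            df = ldv.to_frame()
            df["gauss_A_mean"], df["gauss_A_sd"] = ldv.gauss_A
            df["gauss_B_mean"], df["gauss_B_sd"] = ldv.gauss_B
            df.to_csv(
                record(stage, os.path.join(outdir, f"ldv_{sg}.csv")),
                index=False,
            )
            log.info("group_statistics: LDV %s, overlap=%.2f", sg,
                     gs.overlap_fraction(ldv) if in_a.sum() > 1
                     and in_b.sum() > 1 else float("nan"))
    except Exception as exc:
        with open(failed_marker, "w") as fh:
            fh.write(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(outdir, "run_manifest.csv"), index=False)
    return {"config_hash": chash, "n_subjects": len(ids),
            "outputs": manifest_rows}
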