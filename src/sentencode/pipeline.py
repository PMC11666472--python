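"""End-to-end orchestration: design -> featurize -> simulate -> encode ->
group inference -> ROI comparison, with JSON config, fanned-out seeds, and
a content-hashed output manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import build_design
from .encoding import cross_validated_map, smooth_map
from .errors import SentencodeError
from .group import (
    AnalysisConfig,
    bootstrap_group_null,
    observed_group_map,
    permutation_maps,
    threshold_and_cluster,
)
from .roi import (
    SelectionConfig,
    build_performance_table,
    compare_models,
    make_synthetic_parcels,
)
from .simulate import (
    BetaDataset,
    Blob,
    GroundTruth,
    VoxelGrid,
    generate_dataset,
    write_dataset,
)

log = logging.getLogger("sentencode")

# Stage offsets for fanning the global seed out to per-stage seeds.
_STAGE_SEEDS = {"design": 1, "truth": 2, "simulate": 3, "group": 4}


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults mirror the study's analysis
    parameters (288-sentence design over 6 runs, 8 mm smoothing, 100
    permutations/subject, 10,000 bootstraps, P<0.005 voxelwise, q<0.05
    cluster FDR, t>2.4 / t>1.68 LOPO selection)."""

    # design
    n_target: int = 288
    n_questions: int = 36
    n_fillers: int = 72
    n_runs: int = 6
    # synthetic data
    grid_dims: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 2.5
    blobs: list[dict] = field(
        default_factory=lambda: [
            {"center": [5, 5, 5], "radius": 3.0, "model": "narrow_roles"},
            {"center": [14, 14, 14], "radius": 3.0, "model": "bag_of_nouns_cat"},
            {"center": [5, 14, 14], "radius": 3.0, "model": "broad_roles"},
        ]
    )
    signal_amplitude: float = 1.0
    noise_sd: float = 1.0
    n_participants: int = 38
    attrition_rate: float = 0.07
    substitution_rate: float = 0.23
    # encoding / group
    models: list[str] = field(default_factory=lambda: ["narrow_roles"])
    fwhm_mm: float = 8.0
    n_perm_per_subject: int = 100
    n_bootstrap: int = 10000
    voxel_p: float = 0.005
    cluster_q: float = 0.05
    connectivity: int = 18
    # roi
    t_high: float = 2.4
    t_low: float = 1.68
    roi_smoothed: bool = True
    # run
    out_dir: str = "sentencode_run"
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SentencodeError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        return dataclasses.replace(
            cfg, grid_dims=tuple(cfg.grid_dims)
        )

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence((self.seed, _STAGE_SEEDS[stage])).generate_state(1)[0]
            % (2**31)
        )

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            n_perm_per_subject=self.n_perm_per_subject,
            n_bootstrap=self.n_bootstrap,
            voxel_p=self.voxel_p,
            cluster_q=self.cluster_q,
            connectivity=self.connectivity,
            seed=self.stage_seed("group"),
            fwhm_mm=self.fwhm_mm,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order and write artifacts plus a manifest.

    Deterministic per seed: rerunning the same config reproduces
    bit-identical outputs and manifest hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "design"
    try:
        log.info("stage design: building %d-sentence stimulus set", config.n_target)
        design = build_design(
            n_target=config.n_target,
            n_questions=config.n_questions,
            n_fillers=config.n_fillers,
            seed=config.stage_seed("design"),
            n_runs=config.n_runs,
        )
        design.to_tsv(out / "design.tsv")

        stage = "simulate"
        grid = VoxelGrid.box(config.grid_dims, config.voxel_size_mm)
        prod = [s for s in design.sentences if s.trial_type == "production"]
        blobs = [
            Blob(center=tuple(b["center"]), radius=b["radius"], model=b["model"])
            for b in config.blobs
        ]
        truth = GroundTruth.plant_blobs(
            grid,
            blobs,
            prod,
            signal_amplitude=config.signal_amplitude,
            noise_sd=config.noise_sd,
            seed=config.stage_seed("truth"),
        )
        log.info("stage simulate: %d participants", config.n_participants)
        dataset = generate_dataset(
            design,
            truth,
            n_participants=config.n_participants,
            attrition_rate=config.attrition_rate,
            substitution_rate=config.substitution_rate,
            seed=config.stage_seed("simulate"),
        )
        write_dataset(dataset, out / "dataset")

        acfg = config.analysis_config()
        maps_by_model = {}
        for model in config.models:
            stage = f"encode[{model}]"
            log.info("stage encode: model %s", model)
            obs_mean, maps = observed_group_map(dataset, model, acfg)
            mdir = out / "maps" / model
            for m in maps:
                m.save(mdir)
            maps_by_model[model] = {m.participant_id: m for m in maps}

            stage = f"group[{model}]"
            log.info(
                "stage group: %d perms x %d subjects, %d bootstraps",
                acfg.n_perm_per_subject,
                config.n_participants,
                acfg.n_bootstrap,
            )
            perms = permutation_maps(dataset, model, acfg)
            null = bootstrap_group_null(perms, acfg)
            result = threshold_and_cluster(obs_mean, null, acfg)
            ctab = pd.DataFrame(
                [
                    {
                        "size": c.size,
                        "peak_x": c.peak[0],
                        "peak_y": c.peak[1],
                        "peak_z": c.peak[2],
                        "peak_value": c.peak_value,
                        "p_uncorrected": c.p_uncorrected,
                        "q_fdr": c.q_fdr,
                    }
                    for c in result.clusters
                ]
            )
            ctab.to_csv(out / f"clusters_{model}.tsv", sep="\t", index=False)
            import nibabel as nib

            nib.save(
                nib.Nifti1Image(result.thresholded_map, grid.affine),
                out / f"thresholded_{model}.nii.gz",
            )

        stage = "roi"
        log.info("stage roi: LOPO selection and model comparison")
        rois = make_synthetic_parcels(grid)
        scfg = SelectionConfig(t_high=config.t_high, t_low=config.t_low)
        table = build_performance_table(maps_by_model, rois, scfg)
        table.to_csv(out / "roi_performance.tsv", sep="\t", index=False)
        if table.empty or table["model"].nunique() < 2:
            report = {"effects": {}, "contrasts": pd.DataFrame(), "notes": [
                "model comparison skipped: fewer than 2 models with data"
            ]}
        else:
            report = compare_models(table, factors=("model", "roi", "modality"))
        report["contrasts"].to_csv(out / "roi_contrasts.tsv", sep="\t", index=False)
        (out / "roi_effects.json").write_text(
            json.dumps({"effects": report["effects"], "notes": report["notes"]}, indent=1)
        )

        stage = "manifest"
        config.to_json(out / "config.json")
        files = sorted(
            p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "seed": config.seed,
            "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_SEEDS},
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise SentencodeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
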