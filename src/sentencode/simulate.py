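"""Synthetic multi-participant beta-map datasets with planted ground truth.

The generator emulates the inputs the encoding pipeline consumes in a real
experiment: per-sentence beta images (one 3D volume per production trial)
on a small isotropic voxel grid, for ~38 participants x 6 runs x ~42
trials. Spatially contiguous "blobs" of voxels are planted whose activity
is an exact linear function of one encoding model's predictors plus
i.i.d. Gaussian noise; all other in-mask voxels carry noise only.

Per-voxel activity for a kept trial is

    beta_v(s) = signal_amplitude * w_v . x(s, model_v) + Normal(0, noise_sd)

with ``w_v`` scaled at construction so that the signal component has unit
standard deviation over the design's sentences; ``signal_amplitude /
noise_sd`` is then the per-trial SNR at planted voxels.

Imperfect task performance is emulated by per-trial attrition (erroneous
productions, dropped from analysis) and sentence substitution (acceptable
but different productions: the produced sentence is a different
lexicon-conforming sentence with the same voice).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import SentenceSpec, StimulusSet
from .errors import DatasetIOError, SentencodeError
from .features import EncodingModelSpec, build_design_matrix, get_model
from .lexicon import Lexicon, load_lexicon


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic 3D voxel grid with an analysis mask."""

    dims: tuple[int, int, int]
    voxel_size_mm: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if any(d < 8 for d in self.dims):
            raise SentencodeError("grid dims must be at least (8, 8, 8)")
        if self.mask.shape != tuple(self.dims):
            raise SentencodeError("mask shape must equal grid dims")
        if not self.mask.any():
            raise SentencodeError("mask is empty")

    @classmethod
    def box(cls, dims=(20, 20, 20), voxel_size_mm: float = 2.5) -> "VoxelGrid":
        return cls(
            dims=tuple(dims),
            voxel_size_mm=voxel_size_mm,
            mask=np.ones(dims, dtype=bool),
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())


def sphere_mask(dims, center, radius: float) -> np.ndarray:
    """Boolean mask of voxels within ``radius`` (in voxels) of ``center``."""
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius**2


@dataclass(frozen=True)
class Blob:
    """A planted spherical voxel population generating one encoding model."""

    center: tuple[int, int, int]
    radius: float
    model: str


@dataclass
class GroundTruth:
    """Per-voxel generating models and weights for a synthetic dataset.

    ``voxel_model[i,j,k]`` is the index into ``models`` of the voxel's
    generating model, or -1 for null voxels; ``weights`` maps flat voxel
    index -> weight vector over that voxel's model's predictors.
    """

    grid: VoxelGrid
    models: list[str]
    voxel_model: np.ndarray
    weights: dict[int, np.ndarray]
    signal_amplitude: float
    noise_sd: float
    blobs: list[Blob] = field(default_factory=list)

    def __post_init__(self) -> None:
        for flat, w in self.weights.items():
            m = self.voxel_model.flat[flat]
            if m < 0 and np.any(w):
                raise SentencodeError("null voxel has nonzero weights")

    def labeled_mask(self, model: str | None = None) -> np.ndarray:
        if model is None:
            return self.voxel_model >= 0
        out = np.zeros(self.grid.dims, dtype=bool)
        for i, m in enumerate(self.models):
            if m == model:
                out |= self.voxel_model == i
        return out

    @classmethod
    def plant_blobs(
        cls,
        grid: VoxelGrid,
        blobs: list[Blob],
        design_sentences: list[SentenceSpec],
        signal_amplitude: float = 1.0,
        noise_sd: float = 1.0,
        seed: int = 0,
        lexicon: Lexicon | None = None,
    ) -> "GroundTruth":
        """Plant spherical blobs and draw normalized per-voxel weights.

        Weights are drawn N(0, 1) over the blob model's predictors, then
        rescaled per voxel so the noiseless signal has unit SD over
        ``design_sentences`` (making signal_amplitude the signal SD).
        """
        rng = np.random.default_rng(seed)
        models = [b.model for b in blobs]
        voxel_model = np.full(grid.dims, -1, dtype=np.int16)
        weights: dict[int, np.ndarray] = {}
        lex = lexicon or load_lexicon()
        for bi, blob in enumerate(blobs):
            spec = get_model(blob.model, lex)
            X = build_design_matrix(design_sentences, spec).entries.astype(float)
            m = sphere_mask(grid.dims, blob.center, blob.radius) & grid.mask
            voxel_model[m] = bi
            for flat in np.flatnonzero(m.ravel()):
                for _ in range(100):
                    w = rng.standard_normal(spec.n_predictors)
                    sd = float((X @ w).std())
                    if sd > 1e-8:
                        break
                weights[int(flat)] = w / sd
        return cls(
            grid=grid,
            models=models,
            voxel_model=voxel_model,
            weights=weights,
            signal_amplitude=signal_amplitude,
            noise_sd=noise_sd,
            blobs=list(blobs),
        )


@dataclass
class RunData:
    """One run of one participant: kept sentences, their beta images, and
    the full events table (dropped trials appear with kept=False)."""

    run_id: int
    sentences: list[SentenceSpec]
    betas: np.ndarray  # (n_kept, *grid.dims)
    events: pd.DataFrame


@dataclass
class ParticipantData:
    participant_id: str
    runs: list[RunData]


@dataclass
class BetaDataset:
    grid: VoxelGrid
    participants: list[ParticipantData]
    truth: GroundTruth | None = None


def _substitute(
    s: SentenceSpec, lexicon: Lexicon, rng: np.random.Generator
) -> SentenceSpec:
    """A different lexicon-conforming sentence with the same voice."""
    nouns, verbs = list(lexicon.nouns), list(lexicon.verbs)
    while True:
        a, p = rng.choice(len(nouns), size=2, replace=False)
        v = rng.integers(len(verbs))
        cand = replace(s, agent=nouns[a], patient=nouns[p], verb=verbs[v])
        if cand.triple != s.triple:
            return cand


def generate_dataset(
    design: StimulusSet,
    truth: GroundTruth,
    n_participants: int,
    attrition_rate: float = 0.0,
    substitution_rate: float = 0.0,
    seed: int = 0,
    lexicon: Lexicon | None = None,
    min_kept_per_run: int = 2,
) -> BetaDataset:
    """Simulate per-sentence beta images for every participant and run."""
    if not (0 <= attrition_rate < 1 and 0 <= substitution_rate < 1):
        raise SentencodeError("attrition/substitution rates must be in [0, 1)")
    grid = truth.grid
    lex = lexicon or load_lexicon()
    rng = np.random.default_rng(seed)
    model_specs = {m: get_model(m, lex) for m in set(truth.models)}
    # Flat voxel indices and stacked weights per generating model.
    per_model_vox: dict[str, np.ndarray] = {}
    per_model_W: dict[str, np.ndarray] = {}
    for m in model_specs:
        vox = np.array(
            sorted(
                f
                for f in truth.weights
                if truth.models[truth.voxel_model.flat[f]] == m
            ),
            dtype=int,
        )
        per_model_vox[m] = vox
        if len(vox):
            per_model_W[m] = np.stack([truth.weights[f] for f in vox], axis=1)
    mask_flat = np.flatnonzero(grid.mask.ravel())

    participants = []
    run_ids = sorted(set(design.run_of))
    for pi in range(n_participants):
        runs = []
        for r in run_ids:
            sentences = [
                s for s in design.run(r) if s.trial_type == "production"
            ]
            produced: list[SentenceSpec] = []
            kept: list[bool] = []
            for s in sentences:
                out = s
                if substitution_rate and rng.random() < substitution_rate:
                    out = _substitute(s, lex, rng)
                produced.append(out)
                kept.append(not (attrition_rate and rng.random() < attrition_rate))
            if sum(kept) < min_kept_per_run:
                # keep at least min_kept trials so runs stay usable
                for i in rng.permutation(len(kept)):
                    if sum(kept) >= min_kept_per_run:
                        break
                    kept[i] = True
            kept_sents = [s for s, k in zip(produced, kept) if k]
            n_kept = len(kept_sents)
            betas = np.zeros((n_kept, *grid.dims))
            flat_view = betas.reshape(n_kept, -1)
            noise = rng.standard_normal((n_kept, len(mask_flat))) * truth.noise_sd
            flat_view[:, mask_flat] = noise
            for m, vox in per_model_vox.items():
                if not len(vox):
                    continue
                X = build_design_matrix(kept_sents, model_specs[m]).entries.astype(
                    float
                )
                flat_view[:, vox] += truth.signal_amplitude * (X @ per_model_W[m])
            events = pd.DataFrame(
                {
                    "trial_index": np.arange(1, len(produced) + 1),
                    "agent": [s.agent.lemma for s in produced],
                    "verb": [s.verb.lemma for s in produced],
                    "patient": [s.patient.lemma for s in produced],
                    "voice": [s.voice for s in produced],
                    "passive_order": [s.passive_order for s in produced],
                    "trial_type": [s.trial_type for s in produced],
                    "kept": kept,
                }
            )
            runs.append(
                RunData(run_id=r, sentences=kept_sents, betas=betas, events=events)
            )
        participants.append(
            ParticipantData(participant_id=f"sub-{pi + 1:02d}", runs=runs)
        )
    return BetaDataset(grid=grid, participants=participants, truth=truth)


# ---------------------------------------------------------------------------
# Disk round-trip (NIfTI volumes + events TSVs + ground-truth JSON)
# ---------------------------------------------------------------------------


def write_dataset(dataset: BetaDataset, directory: str | Path) -> None:
    """Write a dataset as NIfTI 4D stacks per run plus events TSVs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    grid = dataset.grid
    nib.save(
        nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine),
        d / "mask.nii.gz",
    )
    meta = {
        "dims": list(grid.dims),
        "voxel_size_mm": grid.voxel_size_mm,
        "participants": [p.participant_id for p in dataset.participants],
        "runs": sorted({r.run_id for p in dataset.participants for r in p.runs}),
    }
    (d / "dataset.json").write_text(json.dumps(meta, indent=1))
    for p in dataset.participants:
        pdir = d / p.participant_id
        pdir.mkdir(exist_ok=True)
        for run in p.runs:
            img = nib.Nifti1Image(
                np.moveaxis(run.betas, 0, -1).astype(np.float64), grid.affine
            )
            nib.save(img, pdir / f"run-{run.run_id}_beta.nii.gz")
            run.events.to_csv(
                pdir / f"run-{run.run_id}_events.tsv", sep="\t", index=False
            )
    if dataset.truth is not None:
        t = dataset.truth
        truth_json = {
            "models": t.models,
            "voxel_model": t.voxel_model.ravel().tolist(),
            "weights": {str(k): v.tolist() for k, v in t.weights.items()},
            "signal_amplitude": t.signal_amplitude,
            "noise_sd": t.noise_sd,
            "blobs": [
                {"center": list(b.center), "radius": b.radius, "model": b.model}
                for b in t.blobs
            ],
        }
        (d / "ground_truth.json").write_text(json.dumps(truth_json))


def read_dataset(
    directory: str | Path, lexicon: Lexicon | None = None
) -> BetaDataset:
    """Read a dataset written by :func:`write_dataset` (bit-exact images)."""
    d = Path(directory)
    lex = lexicon or load_lexicon()
    meta_path = d / "dataset.json"
    if not meta_path.exists():
        raise DatasetIOError(f"missing dataset manifest: {meta_path}")
    meta = json.loads(meta_path.read_text())
    mask_path = d / "mask.nii.gz"
    if not mask_path.exists():
        raise DatasetIOError(f"missing mask file: {mask_path}")
    mask_img = nib.load(mask_path)
    grid = VoxelGrid(
        dims=tuple(meta["dims"]),
        voxel_size_mm=float(meta["voxel_size_mm"]),
        mask=np.asarray(mask_img.dataobj).astype(bool),
    )
    from .design import StimulusSet as _SS  # noqa: F401  (lexicon reuse below)

    participants = []
    for pid in meta["participants"]:
        runs = []
        for r in meta["runs"]:
            beta_path = d / pid / f"run-{r}_beta.nii.gz"
            events_path = d / pid / f"run-{r}_events.tsv"
            if not beta_path.exists():
                raise DatasetIOError(f"missing beta image for run {r}: {beta_path}")
            if not events_path.exists():
                raise DatasetIOError(f"missing events file for run {r}: {events_path}")
            try:
                img = nib.load(beta_path)
                data = np.asarray(img.dataobj, dtype=np.float64)
            except Exception as exc:  # malformed NIfTI
                raise DatasetIOError(f"unreadable NIfTI file {beta_path}: {exc}")
            betas = np.moveaxis(data, -1, 0)
            events = pd.read_csv(events_path, sep="\t")
            kept = events[events["kept"]]
            if len(kept) != betas.shape[0]:
                raise DatasetIOError(
                    f"events/image mismatch for {pid} run {r}: "
                    f"{len(kept)} kept rows vs {betas.shape[0]} volumes"
                )
            sentences = [
                SentenceSpec(
                    agent=lex.noun(row["agent"]),
                    patient=lex.noun(row["patient"]),
                    verb=lex.verb(row["verb"]),
                    voice=row["voice"],
                    passive_order=row["passive_order"],
                    trial_type=row["trial_type"],
                )
                for _, row in kept.iterrows()
            ]
            runs.append(
                RunData(run_id=r, sentences=sentences, betas=betas, events=events)
            )
        participants.append(ParticipantData(participant_id=pid, runs=runs))
    truth = None
    truth_path = d / "ground_truth.json"
    if truth_path.exists():
        tj = json.loads(truth_path.read_text())
        truth = GroundTruth(
            grid=grid,
            models=tj["models"],
            voxel_model=np.array(tj["voxel_model"], dtype=np.int16).reshape(
                grid.dims
            ),
            weights={int(k): np.array(v) for k, v in tj["weights"].items()},
            signal_amplitude=float(tj["signal_amplitude"]),
            noise_sd=float(tj["noise_sd"]),
            blobs=[
                Blob(center=tuple(b["center"]), radius=b["radius"], model=b["model"])
                for b in tj["blobs"]
            ],
        )
    return BetaDataset(grid=grid, participants=participants, truth=truth)
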