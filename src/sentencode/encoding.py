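"""Per-voxel cross-validated encoding and the generalization statistic.

For each voxel, ordinary least squares (with intercept; minimum-norm for
rank-deficient designs) maps binary sentence predictors to single-trial
beta values on five of six runs; the held-out run's sentences are
predicted and compared to their observed values through a z-scored
squared-difference matrix:

    D[i, j] = (pred_i - obs_j)^2,  z-scored jointly over all n^2 entries,
    run score = mean(diagonal) - mean(off-diagonal).

Informative voxels have lower matched (diagonal) than mismatched
(off-diagonal) errors, so after averaging over the six leave-one-run-out
folds the score is multiplied by -1 to make informative voxels positive.
Because the z-score merely centers and rescales, the run score reduces to
(mean_diag - mean_offdiag) / SD(D); all quantities are computed from
power sums of predictions and observations, never materializing D.

Maps are computed on unsmoothed betas and smoothed afterwards (default
8 mm FWHM) with a mask-renormalized Gaussian kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import FoldError, SentencodeError
from .features import EncodingModelSpec, build_design_matrix, get_model
from .lexicon import Lexicon, load_lexicon
from .simulate import ParticipantData, VoxelGrid

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class FoldResult:
    """Held-out-run predictions/observations and per-voxel run scores."""

    run_id: int
    predictions: np.ndarray  # (n_test, n_voxels)
    observations: np.ndarray  # (n_test, n_voxels)
    run_scores: np.ndarray  # (n_voxels,) diagonal-contrast scores

    def __post_init__(self) -> None:
        if self.predictions.shape != self.observations.shape:
            raise FoldError("predictions and observations must align")
        if self.predictions.shape[0] < 2:
            raise FoldError("a fold needs at least 2 test sentences")


@dataclass
class GeneralizationMap:
    """Per-voxel cross-validated generalization score for one participant
    and one encoding model (positive = informative)."""

    data: np.ndarray  # 3D
    grid: VoxelGrid
    participant_id: str
    model_name: str
    smoothed: bool = False
    fwhm_mm: float = 0.0

    def masked_values(self) -> np.ndarray:
        return self.data[self.grid.mask]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float64), self.grid.affine)

    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{self.participant_id}_model-{self.model_name}_gen.nii.gz"
        nib.save(self.to_nifti(), path)
        return path


def fit_voxel_weights(X_train: np.ndarray, Y_train: np.ndarray) -> np.ndarray:
    """OLS weights (+ intercept) per voxel; minimum-norm when rank-deficient.

    Returns an array of shape (p + 1, n_voxels); row 0 is the intercept.
    """
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise FoldError("need at least 2 training sentences")
    if not X_train.any():
        raise SentencodeError("all-zero training design")
    Xa = np.column_stack([np.ones(X_train.shape[0]), X_train])
    # Moore-Penrose solve: identical to minimum-norm least squares but much
    # faster than LAPACK gelsd when Y has thousands of voxel columns. The
    # explicit cutoff treats numerically-zero singular values of the binary
    # design as null space (its genuine singular values are O(1)).
    return np.linalg.pinv(Xa, rcond=1e-10) @ Y_train


def predict_voxels(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    Xa = np.column_stack([np.ones(np.asarray(X).shape[0]), X])
    return Xa @ W


def _run_scores(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Vectorized diagonal-contrast score per voxel (columns).

    Implements mean(diag) - mean(offdiag) of the jointly z-scored matrix
    D[i,j] = (pred_i - obs_j)^2 via power sums: z-scoring reduces the
    contrast to (mean_diag - mean_off) / population SD of D's entries.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    n = pred.shape[0]
    if n < 2:
        raise FoldError("scoring needs at least 2 sentences")
    p2 = pred * pred
    o2 = obs * obs
    sp = [pred.sum(0), p2.sum(0), (p2 * pred).sum(0), (p2 * p2).sum(0)]
    so = [obs.sum(0), o2.sum(0), (o2 * obs).sum(0), (o2 * o2).sum(0)]
    # sum over all i,j of (p_i - o_j)^2 and ^4, from power sums
    s2 = n * sp[1] + n * so[1] - 2.0 * sp[0] * so[0]
    s4 = (
        n * sp[3]
        - 4.0 * sp[2] * so[0]
        + 6.0 * sp[1] * so[1]
        - 4.0 * sp[0] * so[2]
        + n * so[3]
    )
    n2 = float(n * n)
    mean_all = s2 / n2
    var_all = np.maximum(s4 / n2 - mean_all**2, 0.0)
    sd_all = np.sqrt(var_all)
    diag = (pred - obs) ** 2
    mean_diag = diag.mean(axis=0)
    mean_off = (s2 - diag.sum(axis=0)) / (n2 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(sd_all > 0, (mean_diag - mean_off) / sd_all, 0.0)
    # Constant predictions weight every observation equally on and off the
    # diagonal: the contrast is zero by symmetry, so return it exactly.
    const_pred = pred.max(axis=0) == pred.min(axis=0)
    if const_pred.any():
        score = np.where(const_pred, 0.0, score)
    return score


def generalization_score(
    pred: np.ndarray, obs: np.ndarray, return_flag: bool = False
):
    """Diagonal-contrast generalization score for one voxel's held-out run.

    ``D[i,j] = (pred_i - obs_j)^2`` is z-scored jointly over all n^2 entries
    (population SD); the score is mean(on-diagonal) - mean(off-diagonal).
    A degenerate matrix (all entries equal, SD = 0) scores 0; pass
    ``return_flag=True`` to also receive that degeneracy indicator.
    """
    pred = np.asarray(pred, dtype=float).reshape(-1, 1)
    obs = np.asarray(obs, dtype=float).reshape(-1, 1)
    if pred.shape != obs.shape:
        raise FoldError("pred and obs must have equal length")
    score = float(_run_scores(pred, obs)[0])
    if return_flag:
        D = (pred[:, 0][:, None] - obs[:, 0][None, :]) ** 2
        return score, bool(D.std() == 0)
    return score


def cross_validated_map(
    participant: ParticipantData,
    model: str | EncodingModelSpec,
    grid: VoxelGrid,
    lexicon: Lexicon | None = None,
) -> GeneralizationMap:
    """Leave-one-run-out cross-validated generalization map for one
    participant: per voxel, mean run score over folds, times -1."""
    lex = lexicon or load_lexicon()
    spec = model if isinstance(model, EncodingModelSpec) else get_model(model, lex)
    usable = []
    for run in participant.runs:
        if len(run.sentences) < 2:
            warnings.warn(
                f"{participant.participant_id} run {run.run_id} has fewer than "
                "2 usable sentences; dropped from folding",
                stacklevel=2,
            )
            continue
        usable.append(run)
    if len(usable) < 2:
        raise FoldError(
            f"{participant.participant_id}: need at least 2 usable runs"
        )
    mask_flat = np.flatnonzero(grid.mask.ravel())
    X_by_run = {
        r.run_id: build_design_matrix(r.sentences, spec).entries.astype(float)
        for r in usable
    }
    Y_by_run = {
        r.run_id: r.betas.reshape(r.betas.shape[0], -1)[:, mask_flat]
        for r in usable
    }
    total = np.zeros(len(mask_flat))
    for test in usable:
        train_ids = [r.run_id for r in usable if r.run_id != test.run_id]
        X_train = np.concatenate([X_by_run[i] for i in train_ids], axis=0)
        Y_train = np.concatenate([Y_by_run[i] for i in train_ids], axis=0)
        W = fit_voxel_weights(X_train, Y_train)
        pred = predict_voxels(X_by_run[test.run_id], W)
        total += _run_scores(pred, Y_by_run[test.run_id])
    mean_score = total / len(usable)
    data = np.zeros(grid.dims)
    data.ravel()[mask_flat] = -mean_score
    return GeneralizationMap(
        data=data,
        grid=grid,
        participant_id=participant.participant_id,
        model_name=spec.name,
    )


def smooth_map(gmap: GeneralizationMap, fwhm_mm: float = 8.0) -> GeneralizationMap:
    """Gaussian smoothing at the given FWHM, renormalized at mask edges.

    sigma_voxels = fwhm_mm / (voxel_size_mm * 2 * sqrt(2 ln 2)). fwhm 0 is
    the identity; a negative fwhm is an error.
    """
    if fwhm_mm < 0:
        raise SentencodeError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return GeneralizationMap(
            data=gmap.data.copy(),
            grid=gmap.grid,
            participant_id=gmap.participant_id,
            model_name=gmap.model_name,
            smoothed=True,
            fwhm_mm=0.0,
        )
    sigma = fwhm_mm / (gmap.grid.voxel_size_mm * FWHM_TO_SIGMA)
    mask = gmap.grid.mask.astype(float)
    num = gaussian_filter(gmap.data * mask, sigma=sigma, mode="constant", cval=0.0)
    den = gaussian_filter(mask, sigma=sigma, mode="constant", cval=0.0)
    out = np.zeros_like(gmap.data)
    inside = gmap.grid.mask
    out[inside] = num[inside] / den[inside]
    return GeneralizationMap(
        data=out,
        grid=gmap.grid,
        participant_id=gmap.participant_id,
        model_name=gmap.model_name,
        smoothed=True,
        fwhm_mm=fwhm_mm,
    )
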