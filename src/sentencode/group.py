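"""Group-level inference: per-participant permutation nulls, a bootstrap
group-null ensemble, voxelwise thresholding, and FDR-corrected clusters.

The null hypothesis is built nonparametrically: for each participant the
sentence -> descriptor mapping is permuted within run (preserving fold
structure) and the full cross-validated scoring pipeline is re-run
(default 100 permutations per participant). Group-average null maps are
then bootstrapped (default 10,000 draws) by picking one permutation map
per participant uniformly with replacement and averaging. Observed group
means are compared voxelwise against this ensemble (one-sided, add-one
corrected p = (r + 1) / (B + 1)); suprathreshold voxels (default
P < 0.005) are clustered, each cluster's p-value is the proportion of
bootstrap null maps whose largest suprathreshold cluster is at least as
big, and Benjamini-Hochberg FDR (default q < 0.05) is applied across
clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .encoding import GeneralizationMap, cross_validated_map, smooth_map
from .errors import SentencodeError
from .features import EncodingModelSpec
from .lexicon import Lexicon
from .simulate import BetaDataset, ParticipantData, RunData, VoxelGrid

_CONN_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class AnalysisConfig:
    """Group-inference parameters (defaults follow the study's analysis)."""

    n_perm_per_subject: int = 100
    n_bootstrap: int = 10000
    voxel_p: float = 0.005
    cluster_q: float = 0.05
    connectivity: int = 18
    seed: int = 0
    fwhm_mm: float = 8.0
    height_mode: str = "voxelwise"  # or "global": one pooled height threshold

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < 1 and 0 < self.cluster_q < 1):
            raise SentencodeError("voxel_p and cluster_q must lie in (0, 1)")
        if self.connectivity not in _CONN_RANK:
            raise SentencodeError("connectivity must be 6, 18 or 26")
        if self.height_mode not in ("voxelwise", "global"):
            raise SentencodeError("height_mode must be 'voxelwise' or 'global'")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, _CONN_RANK[self.connectivity])


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) integer coordinates
    size: int
    peak: tuple[int, int, int]
    peak_value: float
    p_uncorrected: float
    q_fdr: float = np.nan


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    thresholded_map: np.ndarray  # observed values on FDR-significant clusters
    suprathreshold: np.ndarray  # boolean, before cluster correction


@dataclass
class GroupNull:
    """Bootstrap ensemble of group-mean null maps (masked voxels x draws)."""

    values: np.ndarray  # (n_mask_voxels, n_bootstrap)
    grid: VoxelGrid

    @property
    def n_bootstrap(self) -> int:
        return self.values.shape[1]


def _permuted_participant(
    participant: ParticipantData, rng: np.random.Generator
) -> ParticipantData:
    """Shuffle the sentence -> descriptor mapping within each run."""
    runs = []
    for run in participant.runs:
        order = rng.permutation(len(run.sentences))
        runs.append(
            RunData(
                run_id=run.run_id,
                sentences=[run.sentences[i] for i in order],
                betas=run.betas,
                events=run.events,
            )
        )
    return ParticipantData(participant_id=participant.participant_id, runs=runs)


def observed_group_map(
    dataset: BetaDataset,
    model: str | EncodingModelSpec,
    config: AnalysisConfig,
    lexicon: Lexicon | None = None,
) -> tuple[np.ndarray, list[GeneralizationMap]]:
    """Smoothed per-participant maps and their voxelwise group mean."""
    maps = []
    for p in dataset.participants:
        gm = cross_validated_map(p, model, dataset.grid, lexicon=lexicon)
        maps.append(smooth_map(gm, config.fwhm_mm))
    mean = np.mean([m.data for m in maps], axis=0)
    return mean, maps


def permutation_maps(
    dataset: BetaDataset,
    model: str | EncodingModelSpec,
    config: AnalysisConfig,
    lexicon: Lexicon | None = None,
) -> dict[str, list[GeneralizationMap]]:
    """Per-participant permutation null maps under the full pipeline.

    Permutation seeds derive deterministically from
    (config.seed, participant index, permutation index).
    """
    out: dict[str, list[GeneralizationMap]] = {}
    for pi, p in enumerate(dataset.participants):
        maps = []
        for k in range(config.n_perm_per_subject):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, pi, k))
            )
            perm = _permuted_participant(p, rng)
            gm = cross_validated_map(perm, model, dataset.grid, lexicon=lexicon)
            maps.append(smooth_map(gm, config.fwhm_mm))
        out[p.participant_id] = maps
    return out


def bootstrap_group_null(
    perm_maps: dict[str, list[GeneralizationMap]] | Sequence[Sequence[GeneralizationMap]],
    config: AnalysisConfig,
) -> GroupNull:
    """Bootstrap group-average null maps from the permutation ensembles.

    Each of ``config.n_bootstrap`` draws selects one permutation map per
    participant uniformly with replacement and averages across participants.
    """
    lists = list(perm_maps.values()) if isinstance(perm_maps, dict) else list(perm_maps)
    if not lists or any(len(l) == 0 for l in lists):
        raise SentencodeError("each participant needs at least one permutation map")
    if len(lists) < 2:
        raise SentencodeError("bootstrap needs at least 2 participants")
    grid = lists[0][0].grid
    mask_flat = np.flatnonzero(grid.mask.ravel())
    stacks = [
        np.stack([m.data.ravel()[mask_flat] for m in maps]) for maps in lists
    ]
    n_sub = len(stacks)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xB007)))
    B = config.n_bootstrap
    out = np.empty((len(mask_flat), B))
    idx = np.stack(
        [rng.integers(len(stacks[s]), size=B) for s in range(n_sub)], axis=0
    )
    acc = np.zeros((B, len(mask_flat)))
    for s in range(n_sub):
        acc += stacks[s][idx[s]]
    out = (acc / n_sub).T
    return GroupNull(values=out, grid=grid)


def _suprathreshold_masks(
    observed_masked: np.ndarray, null: GroupNull, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise p-values for the observed map plus suprathreshold masks for
    the observed map and for every bootstrap null map (leave-self-out rule)."""
    values, B = null.values, null.n_bootstrap
    r = (values >= observed_masked[:, None]).sum(axis=1)
    p_vox = (r + 1) / (B + 1)
    obs_supra = p_vox < config.voxel_p
    if config.height_mode == "global":
        thresh = np.quantile(values, 1 - config.voxel_p)
        null_supra = values > thresh
        obs_supra = observed_masked > thresh
        return p_vox, obs_supra, null_supra
    # voxelwise: null map b is suprathreshold at v iff few enough other null
    # values reach it: (#{values[v,:] >= values[v,b]}) / (B + 1) < voxel_p
    from scipy.stats import rankdata

    rank_min = rankdata(values, method="min", axis=1)
    n_ge = B - rank_min + 1  # includes self
    null_supra = n_ge / (B + 1) < config.voxel_p
    return p_vox, obs_supra, null_supra


def threshold_and_cluster(
    observed: np.ndarray,
    null: GroupNull,
    config: AnalysisConfig,
) -> ClusterResult:
    """Threshold the observed group map against the bootstrap null and
    report FDR-corrected clusters.

    ``observed`` is a 3D group-mean map on the null's grid. Cluster
    p-values come from the null distribution of the maximum suprathreshold
    cluster size over bootstrap maps; BH-FDR is applied across clusters at
    ``config.cluster_q``.
    """
    grid = null.grid
    if observed.shape != grid.dims:
        raise SentencodeError("observed map and null grid shapes differ")
    mask_flat = np.flatnonzero(grid.mask.ravel())
    obs_masked = observed.ravel()[mask_flat]
    p_vox, obs_supra, null_supra = _suprathreshold_masks(obs_masked, null, config)

    structure = config.structure
    supra3d = np.zeros(grid.dims, dtype=bool)
    supra3d.ravel()[mask_flat[obs_supra]] = True

    # Null distribution of the maximum cluster size.
    B = null.n_bootstrap
    max_sizes = np.zeros(B, dtype=int)
    vol = np.zeros(grid.dims, dtype=bool)
    for b in range(B):
        cols = null_supra[:, b]
        if not cols.any():
            continue
        vol[:] = False
        vol.ravel()[mask_flat[cols]] = True
        labels, n = ndimage.label(vol, structure=structure)
        if n:
            max_sizes[b] = np.bincount(labels.ravel())[1:].max()

    labels, n_clusters = ndimage.label(supra3d, structure=structure)
    clusters: list[Cluster] = []
    if n_clusters:
        sizes = ndimage.sum_labels(
            np.ones(grid.dims), labels, index=np.arange(1, n_clusters + 1)
        ).astype(int)
        for ci in range(1, n_clusters + 1):
            coords = np.argwhere(labels == ci)
            vals = observed[tuple(coords.T)]
            peak_i = int(np.argmax(vals))
            size = int(sizes[ci - 1])
            p_unc = float(((max_sizes >= size).sum() + 1) / (B + 1))
            clusters.append(
                Cluster(
                    voxels=coords,
                    size=size,
                    peak=tuple(int(x) for x in coords[peak_i]),
                    peak_value=float(vals[peak_i]),
                    p_uncorrected=p_unc,
                )
            )
        pvals = np.array([c.p_uncorrected for c in clusters])
        reject, qvals, *_ = multipletests(
            pvals, alpha=config.cluster_q, method="fdr_bh"
        )
        for c, q in zip(clusters, qvals):
            c.q_fdr = float(q)
    else:
        reject = np.array([], dtype=bool)

    thresholded = np.zeros(grid.dims)
    for c, rej in zip(clusters, reject):
        if rej:
            thresholded[tuple(c.voxels.T)] = observed[tuple(c.voxels.T)]
    clusters.sort(key=lambda c: -c.size)
    return ClusterResult(
        clusters=clusters, thresholded_map=thresholded, suprathreshold=supra3d
    )


def null_fpr(null: GroupNull, config: AnalysisConfig) -> float:
    """Empirical voxelwise false-positive rate under the null.

    Treats each bootstrap group-null map as an observed map, computes its
    leave-self-out voxelwise p-values against the rest of the ensemble, and
    returns the overall fraction of suprathreshold (p < voxel_p) voxel-map
    pairs. For a calibrated pipeline this converges to ``config.voxel_p``.
    """
    dummy_obs = null.values[:, 0]
    _, _, null_supra = _suprathreshold_masks(dummy_obs, null, config)
    return float(null_supra.mean())


def voxelwise_pvalues(
    observed: np.ndarray, null: GroupNull
) -> np.ndarray:
    """Add-one corrected one-sided voxelwise p-map (3D; 1.0 outside mask)."""
    grid = null.grid
    mask_flat = np.flatnonzero(grid.mask.ravel())
    obs_masked = observed.ravel()[mask_flat]
    r = (null.values >= obs_masked[:, None]).sum(axis=1)
    p = (r + 1) / (null.n_bootstrap + 1)
    out = np.ones(grid.dims)
    out.ravel()[mask_flat] = p
    return out
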