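"""ROI analysis: leave-one-participant-out voxel selection, per-ROI model
performance, and mixed-effects model comparison with pairwise contrasts.

Voxels inside each ROI are selected independently for each participant
from the *other* participants' generalization maps: a one-sample t-map
(score vs. 0 across the N-1 remaining participants) is thresholded at
t > 2.4, falling back to t > 1.68 if no voxel survives. Selection for a
participant therefore never reads that participant's own data, avoiding
circular voxel selection. Each participant's model performance in an ROI
is the mean of their own map over their selected voxels.

Model comparison fits a linear mixed-effects model (participant random
effects; fitting delegated to statsmodels MixedLM) over the
participant x ROI x model x modality performance table, with
likelihood-ratio chi-square tests for fixed-effect terms, plus paired
pairwise model contrasts within each ROI x modality cell.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import GeneralizationMap
from .errors import SentencodeError
from .simulate import VoxelGrid, sphere_mask

DEFAULT_ROI_NAMES = ("LIFGtri", "LIFGoper", "LPrecentral", "LATL", "LPTL", "LTPJ")


@dataclass(frozen=True)
class ROIMask:
    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise SentencodeError(f"ROI {self.name!r} mask is empty")


@dataclass(frozen=True)
class SelectionConfig:
    """Voxel-selection thresholds for the LOPO t-map."""

    t_high: float = 2.4
    t_low: float = 1.68

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise SentencodeError("t_low must be below t_high")


def make_synthetic_parcels(
    grid: VoxelGrid,
    centers: list[tuple[int, int, int]] | None = None,
    radius: float = 3.0,
    names: tuple[str, ...] = DEFAULT_ROI_NAMES,
) -> list[ROIMask]:
    """Spherical stand-in parcels on the toy grid, named after the six
    left-hemisphere language regions the analysis targets."""
    if centers is None:
        lo = [int(round(d * 0.25)) for d in grid.dims]
        hi = [int(round(d * 0.75)) for d in grid.dims]
        corners = list(itertools.product(*zip(lo, hi)))
        centers = corners[: len(names)]
    rois = []
    for name, c in zip(names, centers):
        rois.append(
            ROIMask(name=name, mask=sphere_mask(grid.dims, c, radius) & grid.mask)
        )
    return rois


def _one_sample_t(values: np.ndarray) -> np.ndarray:
    """One-sample t (vs 0) per column; columns with zero variance get t=0."""
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def lopo_select_voxels(
    maps: dict[str, GeneralizationMap],
    roi: ROIMask,
    cfg: SelectionConfig = SelectionConfig(),
) -> dict[str, np.ndarray]:
    """Leave-one-participant-out voxel selection within one ROI.

    Returns flat voxel indices (into the 3D grid) per participant. An empty
    array (no voxels survive even ``t_low``) triggers a warning; the caller
    drops that participant's row.
    """
    pids = list(maps)
    if len(pids) < 3:
        raise SentencodeError("LOPO selection needs at least 3 participants")
    grid = next(iter(maps.values())).grid
    roi_flat = np.flatnonzero((roi.mask & grid.mask).ravel())
    data = np.stack([maps[p].data.ravel()[roi_flat] for p in pids])
    out: dict[str, np.ndarray] = {}
    for i, pid in enumerate(pids):
        rest = np.delete(data, i, axis=0)
        t = _one_sample_t(rest)
        sel = t > cfg.t_high
        if not sel.any():
            sel = t > cfg.t_low
        if not sel.any():
            warnings.warn(
                f"no voxels survive t>{cfg.t_low} in ROI {roi.name} for "
                f"held-out {pid}; row excluded",
                stacklevel=2,
            )
        out[pid] = roi_flat[sel]
    return out


def roi_model_performance(
    maps: dict[str, GeneralizationMap],
    selections: dict[str, np.ndarray],
    roi_name: str,
    model_name: str,
    modality: str = "production",
) -> pd.DataFrame:
    """Mean own-map score over each participant's selected voxels.

    Participants with empty selections are omitted.
    """
    rows = []
    for pid, vox in selections.items():
        if len(vox) == 0:
            continue
        rows.append(
            {
                "participant": pid,
                "roi": roi_name,
                "model": model_name,
                "modality": modality,
                "mean_score": float(maps[pid].data.ravel()[vox].mean()),
                "n_voxels_selected": int(len(vox)),
            }
        )
    return pd.DataFrame(rows)


def build_performance_table(
    maps_by_model: dict[str, dict[str, GeneralizationMap]],
    rois: list[ROIMask],
    cfg: SelectionConfig = SelectionConfig(),
    modality: str = "production",
) -> pd.DataFrame:
    """LOPO-select voxels per (ROI, model) and assemble the performance table."""
    tables = []
    for model_name, maps in maps_by_model.items():
        for roi in rois:
            sel = lopo_select_voxels(maps, roi, cfg)
            tables.append(
                roi_model_performance(maps, sel, roi.name, model_name, modality)
            )
    if not tables:
        return pd.DataFrame(
            columns=[
                "participant",
                "roi",
                "model",
                "modality",
                "mean_score",
                "n_voxels_selected",
            ]
        )
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# Mixed-effects comparison and pairwise contrasts
# ---------------------------------------------------------------------------


def _term_names(factors: list[str]) -> list[str]:
    terms = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            terms.append(":".join(combo))
    return terms


def compare_models(
    table: pd.DataFrame,
    factors: tuple[str, ...] = ("model", "roi", "modality"),
    re_formula: str | None = None,
) -> dict:
    """Likelihood-ratio tests for fixed effects in a participant-level mixed
    model, plus pairwise model contrasts within ROI x modality cells.

    Factors with fewer than 2 levels in the table are dropped from the
    fixed-effects structure. Singular random-effects fits fall back to a
    random intercept with a logged note. Returns a dict with ``effects``
    (term -> chi2, df, p) and ``contrasts`` (DataFrame).
    """
    import statsmodels.formula.api as smf

    table = table.copy()
    active = [f for f in factors if table[f].nunique() >= 2]
    if not active:
        raise SentencodeError("compare_models needs >= 2 levels in some factor")
    full_terms = " * ".join(f"C({f})" for f in active)
    notes: list[str] = []

    def _fit(formula: str, ref: str | None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                formula, table, groups=table["participant"], re_formula=ref
            )
            return md.fit(reml=False)

    ref = re_formula
    try:
        full = _fit(f"mean_score ~ {full_terms}", ref)
    except Exception:
        notes.append("random-effects structure simplified to random intercept")
        ref = None
        full = _fit(f"mean_score ~ {full_terms}", ref)

    effects = {}
    for term in _term_names(active):
        parts = term.split(":")
        # drop this term and every higher-order term containing it
        reduced_terms = " + ".join(
            ":".join(f"C({f})" for f in other.split(":"))
            for other in _term_names(active)
            if not set(parts) <= set(other.split(":"))
        )
        formula = f"mean_score ~ {reduced_terms}" if reduced_terms else "mean_score ~ 1"
        try:
            red = _fit(formula, ref)
            chi2 = max(2.0 * (full.llf - red.llf), 0.0)
            df = int(full.df_modelwc - red.df_modelwc)
            p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
            effects[term] = {"chi2": float(chi2), "df": df, "p": p}
        except Exception as exc:  # pragma: no cover - degenerate tables
            effects[term] = {"chi2": np.nan, "df": 0, "p": np.nan}
            notes.append(f"LRT failed for term {term}: {exc}")

    contrasts = pairwise_contrasts(table)
    return {"effects": effects, "contrasts": contrasts, "notes": notes}


def pairwise_contrasts(
    table: pd.DataFrame,
    between: str = "model",
    within: tuple[str, ...] = ("roi", "modality"),
) -> pd.DataFrame:
    """Paired t contrasts between levels of ``between`` inside each cell of
    ``within`` (degrees of freedom = paired participants - 1, uncorrected)."""
    rows = []
    within = tuple(w for w in within if w in table.columns)
    cells = table.groupby(list(within)) if within else [((), table)]
    for cell, sub in cells:
        if not isinstance(cell, tuple):
            cell = (cell,)
        levels = sorted(sub[between].unique())
        for a, b in itertools.combinations(levels, 2):
            wa = sub[sub[between] == a].set_index("participant")["mean_score"]
            wb = sub[sub[between] == b].set_index("participant")["mean_score"]
            common = wa.index.intersection(wb.index)
            if len(common) < 2:
                continue
            diff = wa[common] - wb[common]
            if np.allclose(diff.std(ddof=1), 0):
                t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0) else (np.inf, 0.0)
            else:
                t, p = stats.ttest_rel(wa[common], wb[common])
            rows.append(
                {
                    **dict(zip(within, cell)),
                    "model_a": a,
                    "model_b": b,
                    "estimate": float(diff.mean()),
                    "t": float(t),
                    "df": int(len(common) - 1),
                    "p": float(p),
                    "n": int(len(common)),
                }
            )
    return pd.DataFrame(rows)
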