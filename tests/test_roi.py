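"""ROI-analysis tests: LOPO selection semantics, performance aggregation,
mixed-model effects, and pairwise contrasts."""

import numpy as np
import pandas as pd
import pytest

from sentencode.encoding import GeneralizationMap
from sentencode.errors import SentencodeError
from sentencode.roi import (
    ROIMask,
    SelectionConfig,
    build_performance_table,
    compare_models,
    lopo_select_voxels,
    make_synthetic_parcels,
    pairwise_contrasts,
    roi_model_performance,
)
from sentencode.simulate import VoxelGrid, sphere_mask


@pytest.fixture(scope="module")
def grid():
    return VoxelGrid.box((10, 10, 10))


@pytest.fixture(scope="module")
def roi(grid):
    return ROIMask(name="A", mask=sphere_mask(grid.dims, (5, 5, 5), 3.0))


def _maps(grid, datas):
    return {
        f"sub-{i + 1:02d}": GeneralizationMap(
            data=d, grid=grid, participant_id=f"sub-{i + 1:02d}",
            model_name="narrow_roles",
        )
        for i, d in enumerate(datas)
    }


class TestSelectionConfig:
    def test_threshold_order_enforced(self):
        with pytest.raises(SentencodeError):
            SelectionConfig(t_high=1.0, t_low=2.0)


class TestLopoSelection:
    def test_forced_selection_of_consistent_subblob(self, grid, roi):
        """When all other participants carry a strong positive sub-blob, the
        held-out participant's selection is exactly that sub-blob."""
        sub = sphere_mask(grid.dims, (5, 5, 5), 1.5)
        rng = np.random.default_rng(0)
        # noise only inside the sub-blob; outside voxels are exactly 0 (zero
        # variance -> t = 0), so selection must equal the sub-blob
        datas = [
            np.where(sub, 10.0 + rng.standard_normal(grid.dims) * 0.01, 0.0)
            for _ in range(6)
        ]
        maps = _maps(grid, datas)
        sel = lopo_select_voxels(maps, roi)
        expected = set(np.flatnonzero((sub & roi.mask).ravel()).tolist())
        for pid, vox in sel.items():
            assert set(vox.tolist()) == expected

    def test_selection_independent_of_held_out_map(self, grid, roi):
        """Perturbing the held-out participant's own map leaves their
        selection unchanged (no circularity)."""
        rng = np.random.default_rng(1)
        datas = [rng.standard_normal(grid.dims) + 0.5 for _ in range(5)]
        maps = _maps(grid, datas)
        sel = lopo_select_voxels(maps, roi)
        perturbed = {k: v for k, v in maps.items()}
        perturbed["sub-01"] = GeneralizationMap(
            data=maps["sub-01"].data + 100.0,
            grid=grid,
            participant_id="sub-01",
            model_name="narrow_roles",
        )
        sel2 = lopo_select_voxels(perturbed, roi)
        np.testing.assert_array_equal(sel["sub-01"], sel2["sub-01"])
        # ... while other participants' selections do change
        assert any(
            not np.array_equal(sel[p], sel2[p]) for p in sel if p != "sub-01"
        )

    def test_fallback_engaged_iff_no_voxel_passes_t_high(self, grid, roi):
        """Construct group maps whose ROI t-values lie strictly between
        t_low and t_high: the fallback threshold must be engaged."""
        rng = np.random.default_rng(2)
        n = 10
        # mean 2 / sd ~3.16 across 9 remaining participants -> t ~ 1.9
        datas = [2.0 + rng.standard_normal(grid.dims) * 3.0 for _ in range(n)]
        maps = _maps(grid, datas)
        cfg = SelectionConfig(t_high=25.0, t_low=0.5)
        sel = lopo_select_voxels(maps, roi, cfg)
        roi_flat = np.flatnonzero((roi.mask & grid.mask).ravel())
        for i, pid in enumerate(maps):
            rest = np.stack(
                [maps[p].data.ravel()[roi_flat] for p in maps if p != pid]
            )
            t = rest.mean(0) / (rest.std(0, ddof=1) / np.sqrt(n - 1))
            assert not (t > 25.0).any()  # high threshold unreachable here
            np.testing.assert_array_equal(sel[pid], roi_flat[t > 0.5])

    def test_pure_null_selection_rate_matches_t_tail(self, grid, roi):
        """On pure-null maps the t > t_high selection rate across voxels
        matches the t-distribution tail probability."""
        from scipy import stats

        rng = np.random.default_rng(3)
        n = 12
        rates = []
        cfg = SelectionConfig(t_high=2.4, t_low=1.68)
        for _ in range(20):
            datas = [rng.standard_normal(grid.dims) for _ in range(n)]
            maps = _maps(grid, datas)
            roi_flat = np.flatnonzero((roi.mask & grid.mask).ravel())
            for pid in list(maps)[:3]:
                rest = np.stack(
                    [maps[p].data.ravel()[roi_flat] for p in maps if p != pid]
                )
                t = rest.mean(0) / (rest.std(0, ddof=1) / np.sqrt(n - 1))
                rates.append((t > 2.4).mean())
        expected = stats.t.sf(2.4, df=n - 2)
        n_obs = len(rates) * len(roi_flat)
        se = np.sqrt(expected * (1 - expected) / n_obs)
        assert np.mean(rates) == pytest.approx(expected, abs=4 * se)

    def test_too_few_participants_rejected(self, grid, roi):
        maps = _maps(grid, [np.zeros(grid.dims)] * 2)
        with pytest.raises(SentencodeError):
            lopo_select_voxels(maps, roi)


class TestPerformanceTable:
    def test_constant_map_gives_constant_mean(self, grid, roi):
        datas = [np.full(grid.dims, 0.25) for _ in range(4)]
        maps = _maps(grid, datas)
        sel = {pid: np.flatnonzero(roi.mask.ravel())[:10] for pid in maps}
        tab = roi_model_performance(maps, sel, "A", "narrow_roles")
        assert (tab["mean_score"] == 0.25).all()
        assert (tab["n_voxels_selected"] == 10).all()

    def test_empty_selection_row_omitted(self, grid, roi):
        maps = _maps(grid, [np.zeros(grid.dims)] * 3)
        sel = {
            "sub-01": np.array([], dtype=int),
            "sub-02": np.array([0, 1]),
            "sub-03": np.array([2]),
        }
        tab = roi_model_performance(maps, sel, "A", "narrow_roles")
        assert set(tab["participant"]) == {"sub-02", "sub-03"}

    def test_build_table_columns(self, grid):
        rng = np.random.default_rng(4)
        rois = make_synthetic_parcels(grid, centers=[(3, 3, 3), (7, 7, 7)],
                                      radius=2.0, names=("R1", "R2"))
        maps_by_model = {
            m: _maps(grid, [rng.standard_normal(grid.dims) + 1 for _ in range(5)])
            for m in ("narrow_roles", "bag_of_verbs")
        }
        tab = build_performance_table(maps_by_model, rois)
        assert set(tab.columns) == {
            "participant", "roi", "model", "modality",
            "mean_score", "n_voxels_selected",
        }
        assert set(tab["roi"]) == {"R1", "R2"}
        assert set(tab["model"]) == {"narrow_roles", "bag_of_verbs"}


def _synthetic_table(rng, n_sub=12, effect=0.0, interaction_roi=None):
    """Participant x ROI x model performance table with a per-participant
    random intercept and optional model effect (in a single ROI if
    ``interaction_roi`` is given)."""
    rows = []
    for i in range(n_sub):
        pid = f"sub-{i + 1:02d}"
        u = rng.standard_normal() * 0.5
        for roi_name in ("A", "B", "C"):
            for model in ("m1", "m2"):
                mu = u + rng.standard_normal() * 0.2
                if model == "m2" and (
                    interaction_roi is None or roi_name == interaction_roi
                ):
                    mu += effect
                rows.append(
                    {
                        "participant": pid,
                        "roi": roi_name,
                        "model": model,
                        "modality": "production",
                        "mean_score": mu,
                        "n_voxels_selected": 10,
                    }
                )
    return pd.DataFrame(rows)


class TestCompareModels:
    def test_true_interaction_detected(self):
        """A model effect present in only one ROI yields a model x ROI
        interaction at alpha = .05 in most seeds (effect 1 SD)."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            tab = _synthetic_table(rng, effect=0.6, interaction_roi="A")
            rep = compare_models(tab, factors=("model", "roi"))
            if rep["effects"]["model:roi"]["p"] < 0.05:
                hits += 1
        assert hits >= 9

    def test_null_type_one_error_calibrated(self):
        """Main-effect false-positive rate on exchangeable null tables is
        ~5% (checked on the cheap paired-contrast path over many seeds)."""
        rng = np.random.default_rng(0)
        fp = 0
        n = 300
        for _ in range(n):
            x = rng.standard_normal(10)
            y = x + rng.standard_normal(10) * 0.5  # paired, no true difference
            tab = pd.DataFrame(
                {
                    "participant": [f"s{i}" for i in range(10)] * 2,
                    "roi": ["A"] * 20,
                    "modality": ["production"] * 20,
                    "model": ["m1"] * 10 + ["m2"] * 10,
                    "mean_score": np.concatenate([x, y - (y.mean() - x.mean()) * 0]),
                }
            )
            # enforce exchangeability: swap labels at random per participant
            flip = rng.random(10) < 0.5
            a = tab.iloc[:10]["mean_score"].to_numpy().copy()
            b = tab.iloc[10:]["mean_score"].to_numpy().copy()
            a2 = np.where(flip, b, a)
            b2 = np.where(flip, a, b)
            tab.loc[:9, "mean_score"] = a2
            tab.loc[10:, "mean_score"] = b2
            res = pairwise_contrasts(tab)
            if res.iloc[0]["p"] < 0.05:
                fp += 1
        se = np.sqrt(0.05 * 0.95 / n)
        assert fp / n == pytest.approx(0.05, abs=4 * se)

    def test_identical_models_contrast_zero(self):
        rng = np.random.default_rng(1)
        half = _synthetic_table(rng, n_sub=6).query("model == 'm1'")
        dup = half.copy()
        dup["model"] = "m2"
        tab = pd.concat([half, dup], ignore_index=True)
        res = pairwise_contrasts(tab)
        assert (res["estimate"] == 0).all()
        assert (res["t"] == 0).all()

    def test_requires_two_levels_somewhere(self):
        rng = np.random.default_rng(2)
        tab = _synthetic_table(rng).query("model == 'm1' and roi == 'A'")
        with pytest.raises(SentencodeError):
            compare_models(tab, factors=("model", "roi"))

    def test_modality_dropped_when_single_level(self):
        rng = np.random.default_rng(3)
        tab = _synthetic_table(rng, effect=0.5)
        rep = compare_models(tab, factors=("model", "roi", "modality"))
        assert "modality" not in rep["effects"]
        assert "model" in rep["effects"]
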