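import numpy as np
import pandas as pd
import pytest

from fuzzywater.classify_stats import AD, CONTROL
from fuzzywater.loocv import (
    ParameterGrid,
    grid_search_params,
    loocv_folds,
    loocv_tune,
)
from fuzzywater.phantom import PhantomSpec, CohortSpec, generate_cohort
from fuzzywater.volume_io import read_manifest


def make_table(count_rows: dict, grid: ParameterGrid) -> pd.DataFrame:
    """Counts table with explicit per-grid-point values (dict of lists)."""
    columns = pd.MultiIndex.from_product(
        [grid.radii, grid.thresholds], names=["radius", "threshold"]
    )
    data = {sid: vals for sid, vals in count_rows.items()}
    return pd.DataFrame.from_dict(data, orient="index", dtype=float).set_axis(
        columns, axis=1
    ).rename_axis("subject_id")


class TestParameterGrid:
    def test_defaults_bracket_plausible_optima(self):
        g = ParameterGrid()
        assert g.radii[0] == 0.5 and g.radii[-1] == 1.5
        assert g.thresholds[0] == pytest.approx(0.10)
        assert g.cutoffs == "derived"

    def test_validation(self):
        with pytest.raises(ValueError, match="non-empty"):
            ParameterGrid(radii=())
        with pytest.raises(ValueError, match="ascending"):
            ParameterGrid(radii=(1.0, 0.5))
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            ParameterGrid(thresholds=(0.5, 1.5))
        with pytest.raises(ValueError):
            ParameterGrid(cutoffs=(0.0, 5.0))


class TestGridSearch:
    def test_single_point_grid_returned(self):
        grid = ParameterGrid(radii=(0.9,), thresholds=(0.3,), cutoffs=(15.0,))
        table = make_table({"a": [10], "b": [20]}, grid)
        groups = pd.Series({"a": AD, "b": CONTROL})
        params = grid_search_params(table, groups, grid)
        assert (params.gaussian_radius, params.background_threshold,
                params.region_cutoff) == (0.9, 0.3, 15.0)

    def test_separating_point_wins(self):
        grid = ParameterGrid(radii=(0.7, 1.1), thresholds=(0.3,), cutoffs=(15.0,))
        # first radius mixes the groups, second separates them
        table = make_table(
            {"a1": [20, 10], "a2": [10, 12], "c1": [12, 20], "c2": [25, 25]},
            grid,
        )
        groups = pd.Series({"a1": AD, "a2": AD, "c1": CONTROL, "c2": CONTROL})
        params = grid_search_params(table, groups, grid)
        assert params.gaussian_radius == 1.1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        grid = ParameterGrid(
            radii=(0.7, 0.9, 1.1), thresholds=(0.2, 0.3, 0.4), cutoffs="derived"
        )
        sids = [f"a{i}" for i in range(4)] + [f"c{i}" for i in range(3)]
        groups = pd.Series(
            {s: (AD if s.startswith("a") else CONTROL) for s in sids}
        )
        table = make_table(
            {s: rng.integers(5, 40, size=9).tolist() for s in sids}, grid
        )
        params = grid_search_params(table, groups, grid)

        # independent exhaustive search with the same tie policy
        best, best_j = None, -np.inf
        is_ad = np.array([groups[s] == AD for s in table.index])
        for r in grid.radii:
            for t in grid.thresholds:
                c = table[(r, t)].to_numpy()
                cutoff = (c[is_ad].mean() + c[~is_ad].mean()) / 2
                sens = 100 * (c[is_ad] <= cutoff).mean()
                spec = 100 * (c[~is_ad] > cutoff).mean()
                j = sens + spec - 100
                if j > best_j + 1e-9:
                    best_j, best = j, (r, t, cutoff)
        assert (params.gaussian_radius, params.background_threshold,
                params.region_cutoff) == pytest.approx(best)

    def test_single_class_training_rejected(self):
        grid = ParameterGrid(radii=(0.9,), thresholds=(0.3,))
        table = make_table({"a": [10], "b": [12]}, grid)
        groups = pd.Series({"a": AD, "b": AD})
        with pytest.raises(ValueError, match="both groups"):
            grid_search_params(table, groups, grid)


class TestLoocvFolds:
    grid = ParameterGrid(radii=(0.9,), thresholds=(0.3,))

    def test_each_subject_held_out_exactly_once(self):
        table = make_table(
            {"a1": [5], "a2": [7], "c1": [20], "c2": [22]}, self.grid
        )
        groups = pd.Series({"a1": AD, "a2": AD, "c1": CONTROL, "c2": CONTROL})
        cv = loocv_folds(table, groups, self.grid)
        assert sorted(f.held_out_id for f in cv.folds) == sorted(table.index)

    def test_perfect_separation_gives_perfect_oos_metrics(self):
        table = make_table(
            {"a1": [5], "a2": [6], "a3": [8], "c1": [20], "c2": [22], "c3": [24]},
            self.grid,
        )
        groups = pd.Series({s: (AD if s.startswith("a") else CONTROL)
                            for s in table.index})
        cv = loocv_folds(table, groups, self.grid)
        assert cv.oos_metrics.sensitivity == 100.0
        assert cv.oos_metrics.specificity == 100.0
        assert cv.param_sds["gaussian_radius"] == 0.0

    def test_outlier_subject_misclassified_in_own_fold_only(self):
        table = make_table(
            {"a1": [5], "a2": [6], "a3": [7], "a4": [30],
             "c1": [20], "c2": [22], "c3": [25], "c4": [28]},
            self.grid,
        )
        groups = pd.Series({s: (AD if s.startswith("a") else CONTROL)
                            for s in table.index})
        cv = loocv_folds(table, groups, self.grid)
        wrong = [f.held_out_id for f in cv.folds if f.predicted != f.true_group]
        assert wrong == ["a4"]

    def test_held_out_subject_cannot_leak_into_its_fold_params(self, rng):
        grid = ParameterGrid(radii=(0.7, 1.1), thresholds=(0.2, 0.4))
        sids = [f"a{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
        groups = pd.Series({s: (AD if s.startswith("a") else CONTROL)
                            for s in sids})
        rows = {s: rng.integers(5, 40, size=4).tolist() for s in sids}
        cv1 = loocv_folds(make_table(rows, grid), groups, grid)
        perturbed = dict(rows)
        perturbed["a1"] = [999, 999, 999, 999]
        cv2 = loocv_folds(make_table(perturbed, grid), groups, grid)
        fold1 = next(f for f in cv1.folds if f.held_out_id == "a1")
        fold2 = next(f for f in cv2.folds if f.held_out_id == "a1")
        assert fold1.params == fold2.params

    def test_too_few_subjects_rejected(self):
        table = make_table({"a1": [5], "c1": [20], "c2": [21]}, self.grid)
        groups = pd.Series({"a1": AD, "c1": CONTROL, "c2": CONTROL})
        with pytest.raises(ValueError, match="at least 2"):
            loocv_folds(table, groups, self.grid)


class TestLoocvTuneIntegration:
    def test_reproducible_end_to_end_on_tiny_phantom_cohort(self, tmp_path):
        spec = CohortSpec(
            n_ad=2, n_control=2,
            ad_spec=PhantomSpec(shape=(64, 64, 64), n_peaks_parietal=4),
            control_spec=PhantomSpec(shape=(64, 64, 64), n_peaks_parietal=10),
            master_seed=7,
        )
        generate_cohort(spec, tmp_path)
        manifest = read_manifest(tmp_path / "manifest.csv")
        grid = ParameterGrid(radii=(0.9,), thresholds=(0.3, 0.4))
        cv1 = loocv_tune(manifest, grid)
        cv2 = loocv_tune(manifest, grid)
        assert len(cv1.folds) == 4
        assert cv1.as_dict() == cv2.as_dict()
        assert cv1.final_counts is not None and cv1.ttest is not None
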