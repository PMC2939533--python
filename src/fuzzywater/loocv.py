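"""Leave-one-out cross-validated tuning of the pipeline parameters.

For every fold one subject is held out and the (smoothing radius,
background threshold, region cutoff) triple is grid-searched on the
remaining subjects to maximize Youden's index (sensitivity +
specificity - 100) of the region-count threshold classifier; the held-out
subject is then classified at the fold's parameters.  Besides per-fold
parameters and their mean +/- SD, the procedure reports out-of-sample
confusion metrics, and finally re-classifies the whole cohort at the
across-fold mean parameters (the final fixed-parameter evaluation, whose
in-sample character is inherent to that design).

The cutoff can be searched on an explicit grid or, in the default
"derived" mode, set per candidate (radius, threshold) to the midpoint
between the two training-group mean counts, which yields a continuous
critical region count.

Because the pipeline maps each subject's volume to its region count
independently of every other subject, the per-subject count table for all
grid points is computed once up front; fold-wise grid search then only
re-reads the table, which is leakage-free and fast.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .classify_stats import (
    AD,
    CONTROL,
    ConfusionMetrics,
    RegionCountClassifier,
    TTestResult,
    confusion_from_counts,
    two_sample_ttest,
)
from .pipeline import process_volume
from .preprocess import PipelineParams
from .volume_io import read_volume

_TIE_EPS = 1e-9


def _default_radii():
    return tuple(np.round(np.arange(0.5, 1.501, 0.1), 10))


def _default_thresholds():
    return tuple(np.round(np.arange(0.10, 0.501, 0.05), 10))


@dataclasses.dataclass(frozen=True)
class ParameterGrid:
    """Search space for the three pipeline parameters.

    ``cutoffs`` is either an ascending tuple of candidate cutoffs or the
    string ``"derived"`` (midpoint of the training-group mean counts).
    """

    radii: tuple = dataclasses.field(default_factory=_default_radii)
    thresholds: tuple = dataclasses.field(default_factory=_default_thresholds)
    cutoffs: tuple | str = "derived"

    def __post_init__(self):
        radii = tuple(float(r) for r in self.radii)
        thresholds = tuple(float(t) for t in self.thresholds)
        if not radii or not thresholds:
            raise ValueError("parameter grid axes must be non-empty")
        if list(radii) != sorted(radii) or list(thresholds) != sorted(thresholds):
            raise ValueError("grid axes must be sorted ascending")
        if any(r <= 0 for r in radii):
            raise ValueError("radii must be > 0")
        if any(not 0 < t < 1 for t in thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.cutoffs != "derived":
            cutoffs = tuple(float(c) for c in self.cutoffs)
            if not cutoffs or list(cutoffs) != sorted(cutoffs):
                raise ValueError("cutoffs must be non-empty and sorted ascending")
            if any(c <= 0 for c in cutoffs):
                raise ValueError("cutoffs must be > 0")
            object.__setattr__(self, "cutoffs", cutoffs)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "thresholds", thresholds)

    @classmethod
    def desk_scale(cls) -> "ParameterGrid":
        """Coarse grid used by the desk-scale synthetic validation study."""
        return cls(radii=(0.7, 0.9, 1.1), thresholds=(0.2, 0.3, 0.4))


@dataclasses.dataclass(frozen=True)
class FoldResult:
    held_out_id: str
    params: PipelineParams
    true_group: str
    predicted: str


@dataclasses.dataclass(frozen=True)
class CVResult:
    folds: tuple[FoldResult, ...]
    param_means: PipelineParams
    param_sds: dict
    oos_metrics: ConfusionMetrics
    final_metrics: ConfusionMetrics | None = None
    final_counts: dict | None = None
    ttest: TTestResult | None = None

    def as_dict(self) -> dict:
        d = {
            "folds": [
                {
                    "held_out_id": f.held_out_id,
                    "params": dataclasses.asdict(f.params),
                    "true_group": f.true_group,
                    "predicted": f.predicted,
                }
                for f in self.folds
            ],
            "param_means": dataclasses.asdict(self.param_means),
            "param_sds": dict(self.param_sds),
            "oos_metrics": self.oos_metrics.as_dict(),
        }
        if self.final_metrics is not None:
            d["final_metrics"] = self.final_metrics.as_dict()
        if self.final_counts is not None:
            d["final_counts"] = dict(self.final_counts)
        if self.ttest is not None:
            d["ttest"] = self.ttest.as_dict()
        return d


def compute_count_table(manifest: pd.DataFrame, grid: ParameterGrid, rois=None,
                        ) -> pd.DataFrame:
    """Region counts per subject for every (radius, threshold) grid point.

    Rows are subjects, columns a (radius, threshold) MultiIndex.  Each
    subject's volume is loaded once and processed independently.
    """
    columns = pd.MultiIndex.from_product(
        [grid.radii, grid.thresholds], names=["radius", "threshold"]
    )
    table = pd.DataFrame(
        index=pd.Index(manifest["subject_id"], name="subject_id"),
        columns=columns, dtype=float,
    )
    for _, row in manifest.iterrows():
        vol = read_volume(row["volume_path"])
        for radius in grid.radii:
            for threshold in grid.thresholds:
                res = process_volume(vol, radius, threshold, rois=rois)
                table.loc[row["subject_id"], (radius, threshold)] = res.count_total
    return table


def _youden(counts: np.ndarray, is_ad: np.ndarray, cutoff: float) -> float:
    pred_ad = counts <= cutoff
    sens = 100.0 * (pred_ad & is_ad).sum() / is_ad.sum()
    spec = 100.0 * (~pred_ad & ~is_ad).sum() / (~is_ad).sum()
    return sens + spec - 100.0


def _candidate_cutoffs(counts, is_ad, grid: ParameterGrid):
    if grid.cutoffs != "derived":
        return grid.cutoffs
    clf = RegionCountClassifier().fit(
        counts, np.where(is_ad, AD, CONTROL)
    )
    return (clf.cutoff_,)


def grid_search_params(table: pd.DataFrame, groups: pd.Series,
                       grid: ParameterGrid) -> PipelineParams:
    """Grid point maximizing Youden's index on the training subjects.

    Ties resolve to the smaller radius, then the smaller threshold, then
    the smaller cutoff (the iteration order, with strictly-better
    replacement).
    """
    groups = groups.loc[table.index]
    is_ad = (groups == AD).to_numpy()
    if not is_ad.any() or is_ad.all():
        raise ValueError("training set must contain both groups")
    best, best_j = None, -np.inf
    for radius in grid.radii:
        for threshold in grid.thresholds:
            counts = table[(radius, threshold)].to_numpy(dtype=float)
            for cutoff in _candidate_cutoffs(counts, is_ad, grid):
                j = _youden(counts, is_ad, cutoff)
                if j > best_j + _TIE_EPS:
                    best_j = j
                    best = PipelineParams(radius, threshold, float(cutoff))
    return best


def loocv_folds(table: pd.DataFrame, groups: pd.Series, grid: ParameterGrid,
                ) -> CVResult:
    """Leave-one-out folds over a precomputed count table."""
    groups = groups.loc[table.index]
    for g in (AD, CONTROL):
        if (groups == g).sum() < 2:
            raise ValueError("need at least 2 subjects per group for LOOCV")
    folds = []
    for held_out in table.index:
        train = table.drop(index=held_out)
        params = grid_search_params(train, groups, grid)
        count = float(table.loc[held_out, (params.gaussian_radius,
                                           params.background_threshold)])
        predicted = AD if count <= params.region_cutoff else CONTROL
        folds.append(
            FoldResult(
                held_out_id=str(held_out),
                params=params,
                true_group=str(groups.loc[held_out]),
                predicted=predicted,
            )
        )
    mats = {
        "gaussian_radius": np.array([f.params.gaussian_radius for f in folds]),
        "background_threshold": np.array(
            [f.params.background_threshold for f in folds]
        ),
        "region_cutoff": np.array([f.params.region_cutoff for f in folds]),
    }
    param_means = PipelineParams(
        **{k: float(v.mean()) for k, v in mats.items()}
    )
    param_sds = {k: float(v.std(ddof=1)) for k, v in mats.items()}
    tp = sum(1 for f in folds if f.true_group == AD and f.predicted == AD)
    fn = sum(1 for f in folds if f.true_group == AD and f.predicted == CONTROL)
    tn = sum(1 for f in folds if f.true_group == CONTROL and f.predicted == CONTROL)
    fp = sum(1 for f in folds if f.true_group == CONTROL and f.predicted == AD)
    oos = confusion_from_counts(tp, fp, tn, fn)
    return CVResult(
        folds=tuple(folds),
        param_means=param_means,
        param_sds=param_sds,
        oos_metrics=oos,
    )


def loocv_tune(manifest: pd.DataFrame, grid: ParameterGrid | None = None,
               rois=None, seed: int = 0) -> CVResult:
    """Full LOOCV study on a cohort manifest.

    Computes the per-subject count table over the grid, runs the folds,
    then re-processes every subject at the across-fold mean radius and
    threshold and classifies at the mean cutoff (final fixed-parameter
    evaluation), adding final confusion metrics and the pooled two-sample
    t-test on the final counts (controls minus AD).  The whole procedure
    is deterministic; ``seed`` is accepted for interface symmetry with the
    phantom generator.
    """
    del seed  # deterministic pipeline: nothing to seed
    grid = grid or ParameterGrid()
    groups = manifest.set_index("subject_id")["group"]
    table = compute_count_table(manifest, grid, rois=rois)
    result = loocv_folds(table, groups, grid)

    mean_p = result.param_means
    final_counts = {}
    for _, row in manifest.iterrows():
        vol = read_volume(row["volume_path"])
        res = process_volume(
            vol, mean_p.gaussian_radius, mean_p.background_threshold, rois=rois
        )
        final_counts[row["subject_id"]] = int(res.count_total)
    counts = pd.Series(final_counts)
    pred = {
        s: (AD if c <= mean_p.region_cutoff else CONTROL)
        for s, c in counts.items()
    }
    tp = sum(1 for s in counts.index if groups[s] == AD and pred[s] == AD)
    fn = sum(1 for s in counts.index if groups[s] == AD and pred[s] == CONTROL)
    tn = sum(1 for s in counts.index if groups[s] == CONTROL and pred[s] == CONTROL)
    fp = sum(1 for s in counts.index if groups[s] == CONTROL and pred[s] == AD)
    final = confusion_from_counts(tp, fp, tn, fn)
    ttest = two_sample_ttest(
        counts[groups == CONTROL].to_numpy(), counts[groups == AD].to_numpy()
    )
    return dataclasses.replace(
        result,
        final_metrics=final,
        final_counts=final_counts,
        ttest=ttest,
    )
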