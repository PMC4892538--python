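"""Scoring, F1 grid search, ROC/PR curves and stratified cross-validation.

Tremor is the positive class throughout.  Precision, recall (=
sensitivity), specificity and the F1 score ``2 p r / (p + r)`` are
computed from segment-level confusion counts; the two classifier
parameters (lower band limit, power threshold) are selected by exhaustive
grid search maximizing F1, and generalization is estimated by a
four-iteration cross-validation that holds out 20% of each patient's
tremor and no-tremor segments per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import BAND_UPPER_DEFAULT, DetectionParams
from .domfreq import df_table
from .preprocess import SegmentSet

__all__ = [
    "DEFAULT_LOWER_GRID",
    "DEFAULT_THRESH_GRID",
    "ConfusionCounts",
    "MetricSet",
    "GridResult",
    "Curves",
    "CVIteration",
    "CVResult",
    "confusion",
    "metrics",
    "grid_search",
    "optimal_by_f1",
    "curves",
    "cross_validate",
]

logger = logging.getLogger(__name__)

#: Lower band-limit search grid: 0..12 Hz in 0.05 Hz steps.
DEFAULT_LOWER_GRID = np.round(np.arange(0.0, 12.0 + 1e-9, 0.05), 10)
#: Power-threshold search grid: 0..5000 m^2/s^4 in steps of 50.
DEFAULT_THRESH_GRID = np.arange(0.0, 5000.0 + 1e-9, 50.0)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Precision / recall / specificity / F1, each in [0, 1].

    Ratios with a zero denominator are reported as 0 (and logged), which
    keeps every grid cell comparable under argmax.
    """

    precision: float
    recall: float
    specificity: float
    f1: float


def confusion(reference, predicted) -> ConfusionCounts:
    """Confusion counts with ``"tremor"`` as the positive class."""
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    if ref.shape != pred.shape:
        raise ValueError(
            f"reference and predicted lengths differ: {ref.size} vs {pred.size}"
        )
    rp = ref == "tremor"
    pp = pred == "tremor"
    return ConfusionCounts(
        tp=int(np.sum(rp & pp)),
        fp=int(np.sum(~rp & pp)),
        tn=int(np.sum(~rp & ~pp)),
        fn=int(np.sum(rp & ~pp)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """Precision, recall, specificity and F1 from confusion counts."""
    p = _ratio(c.tp, c.tp + c.fp, "precision")
    r = _ratio(c.tp, c.tp + c.fn, "recall")
    s = _ratio(c.tn, c.tn + c.fp, "specificity")
    f1 = _ratio(2 * p * r, p + r, "f1")
    return MetricSet(p, r, s, f1)


@dataclass
class GridResult:
    """Full metric surfaces over the (band_lower, threshold) grid."""

    method: str
    band_upper: float
    lower_grid: np.ndarray
    thresh_grid: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    n_segments: int = 0

    def metric_at(self, i: int, j: int) -> MetricSet:
        """MetricSet of grid cell (lower index ``i``, threshold index ``j``)."""
        return MetricSet(
            float(self.precision[i, j]), float(self.recall[i, j]),
            float(self.specificity[i, j]), float(self.f1[i, j]),
        )

    def to_frame(self) -> pd.DataFrame:
        L, T = np.meshgrid(self.lower_grid, self.thresh_grid, indexing="ij")
        return pd.DataFrame({
            "band_lower": L.ravel(),
            "threshold": T.ravel(),
            "tp": self.tp.ravel(), "fp": self.fp.ravel(),
            "tn": self.tn.ravel(), "fn": self.fn.ravel(),
            "precision": self.precision.ravel(),
            "recall": self.recall.ravel(),
            "specificity": self.specificity.ravel(),
            "f1": self.f1.ravel(),
        })


def _surfaces_from_arrays(
    freq: np.ndarray, amp: np.ndarray, y: np.ndarray,
    lower_grid: np.ndarray, thresh_grid: np.ndarray, band_upper: float,
):
    """Vectorized confusion surfaces for every grid cell.

    ``in_band`` is (L, S) and ``above`` is (T, S); the positive-prediction
    and true-positive counts per cell are then single matrix products, so a
    full 241 x 101 grid over thousands of segments is a comparison-only
    pass over cached dominant frequencies.
    """
    in_band = (freq[None, :] >= lower_grid[:, None]) & (freq[None, :] <= band_upper)
    above = amp[None, :] > thresh_grid[:, None]
    in_band_f = in_band.astype(np.float64)
    tp = in_band_f @ (above & y[None, :]).T.astype(np.float64)
    pred_pos = in_band_f @ above.T.astype(np.float64)
    n_pos = int(y.sum())
    n = y.size
    tp = np.rint(tp).astype(np.int64)
    pred_pos = np.rint(pred_pos).astype(np.int64)
    fp = pred_pos - tp
    fn = n_pos - tp
    tn = n - pred_pos - fn
    return tp, fp, tn, fn


def _metric_surfaces(tp, fp, tn, fn):
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        specificity = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return precision, recall, specificity, f1


def _labeled_arrays(segset: SegmentSet, method: str,
                    subset: set | None = None):
    table = df_table(segset, method)
    table = table[table["ref_label"].isin(["tremor", "no_tremor"])]
    if subset is not None:
        keys = list(zip(table["patient_id"], table["segment_index"]))
        table = table[[k in subset for k in keys]]
    if table.empty:
        raise ValueError("no labeled (tremor / no_tremor) segments to evaluate")
    freq = table["freq_hz"].to_numpy(float)
    amp = table["amplitude"].to_numpy(float)
    y = (table["ref_label"] == "tremor").to_numpy()
    return freq, amp, y


def grid_search(
    segset: SegmentSet,
    method: str,
    lower_grid: np.ndarray | None = None,
    thresh_grid: np.ndarray | None = None,
    band_upper: float = BAND_UPPER_DEFAULT,
    subset: set | None = None,
) -> GridResult:
    """Metric surfaces for every (band_lower, threshold) combination.

    ``subset``, if given, restricts evaluation to segments with those
    ``(patient_id, segment_index)`` keys (used by cross-validation).
    Spectra are estimated once per segment; the grid pass itself only
    compares cached dominant frequencies against the cell parameters.
    """
    lower_grid = DEFAULT_LOWER_GRID if lower_grid is None else np.asarray(lower_grid, float)
    thresh_grid = DEFAULT_THRESH_GRID if thresh_grid is None else np.asarray(thresh_grid, float)
    freq, amp, y = _labeled_arrays(segset, method, subset)
    tp, fp, tn, fn = _surfaces_from_arrays(freq, amp, y, lower_grid,
                                           thresh_grid, band_upper)
    precision, recall, specificity, f1 = _metric_surfaces(tp, fp, tn, fn)
    return GridResult(method, band_upper, lower_grid, thresh_grid,
                      tp, fp, tn, fn, precision, recall, specificity, f1,
                      n_segments=int(y.size))


@dataclass(frozen=True)
class Plateau:
    """Extent of the F1-maximizing region of the grid."""

    lower_min: float
    lower_max: float
    thresh_min: float
    thresh_max: float


def optimal_by_f1(g: GridResult) -> tuple[DetectionParams, Plateau]:
    """Argmax of the F1 surface with its tie plateau.

    Ties are reported as the full plateau extent (ranges of band_lower and
    threshold).  The selected cell is the maximum-margin one: the (lower)
    median of the thresholds represented on the plateau, then the (lower)
    median band_lower among the tied cells at that threshold.  Selecting an
    interior cell rather than a plateau edge keeps the operating point away
    from the decision boundary, so held-out segments whose dominant
    frequency or amplitude falls marginally outside the training range are
    still classified correctly.
    """
    fmax = g.f1.max()
    ii, jj = np.nonzero(np.isclose(g.f1, fmax, rtol=0, atol=1e-12))
    plateau = Plateau(
        float(g.lower_grid[ii.min()]), float(g.lower_grid[ii.max()]),
        float(g.thresh_grid[jj.min()]), float(g.thresh_grid[jj.max()]),
    )
    tie_thr = np.unique(jj)
    j = int(tie_thr[(tie_thr.size - 1) // 2])
    tie_lo = np.sort(ii[jj == j])
    i = int(tie_lo[(tie_lo.size - 1) // 2])
    params = DetectionParams(float(g.lower_grid[i]), g.band_upper,
                             float(g.thresh_grid[j]))
    return params, plateau


@dataclass
class Curves:
    """ROC / PR curve families (one curve per band_lower, swept over threshold)."""

    frame: pd.DataFrame
    roc_optimal_params: DetectionParams
    roc_optimal_point: tuple[float, float]
    pr_optimal_params: DetectionParams
    pr_optimal_point: tuple[float, float]


def curves(g: GridResult) -> Curves:
    """Threshold-swept ROC and PR curves plus the optimal operating points.

    The ROC optimum is the grid cell closest (Euclidean) to the perfect
    corner (0, 1) in (1-specificity, sensitivity); the PR optimum is the
    cell closest to (1, 1) in (recall, precision).  The two conventions may
    select different cells.
    """
    L, T = np.meshgrid(g.lower_grid, g.thresh_grid, indexing="ij")
    frame = pd.DataFrame({
        "band_lower": L.ravel(),
        "threshold": T.ravel(),
        "sensitivity": g.recall.ravel(),
        "one_minus_specificity": (1.0 - g.specificity).ravel(),
        "precision": g.precision.ravel(),
        "recall": g.recall.ravel(),
    })
    d_roc = (1.0 - g.specificity) ** 2 + (g.recall - 1.0) ** 2
    i, j = np.unravel_index(int(np.argmin(d_roc)), d_roc.shape)
    roc_params = DetectionParams(float(g.lower_grid[i]), g.band_upper,
                                 float(g.thresh_grid[j]))
    roc_point = (float(1.0 - g.specificity[i, j]), float(g.recall[i, j]))
    d_pr = (g.recall - 1.0) ** 2 + (g.precision - 1.0) ** 2
    i, j = np.unravel_index(int(np.argmin(d_pr)), d_pr.shape)
    pr_params = DetectionParams(float(g.lower_grid[i]), g.band_upper,
                                float(g.thresh_grid[j]))
    pr_point = (float(g.recall[i, j]), float(g.precision[i, j]))
    return Curves(frame, roc_params, roc_point, pr_params, pr_point)


@dataclass
class CVIteration:
    params: DetectionParams
    plateau: Plateau
    train: MetricSet
    test: MetricSet
    n_train: int
    n_test: int


@dataclass
class CVResult:
    """Per-iteration optima and held-out metrics, with cross-iteration stats."""

    method: str
    iterations: list[CVIteration] = field(default_factory=list)

    def _stat(self, attr: str, which: str = "test") -> tuple[float, float]:
        vals = np.array([getattr(getattr(it, which), attr)
                         for it in self.iterations])
        return float(vals.mean()), float(vals.std())

    @property
    def mean_test_f1(self) -> float:
        return self._stat("f1")[0]

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, it in enumerate(self.iterations):
            rows.append({
                "iteration": k + 1,
                "band_lower": it.params.band_lower,
                "threshold": it.params.power_threshold,
                "train_f1": it.train.f1,
                "test_f1": it.test.f1,
                "test_precision": it.test.precision,
                "test_recall": it.test.recall,
                "test_specificity": it.test.specificity,
                "n_train": it.n_train,
                "n_test": it.n_test,
            })
        return pd.DataFrame(rows)

    def stats(self) -> pd.DataFrame:
        rows = []
        for attr in ("f1", "precision", "recall", "specificity"):
            m, s = self._stat(attr)
            rows.append({"metric": attr, "mean": m, "std": s})
        return pd.DataFrame(rows)


def _strata(segset: SegmentSet) -> dict[tuple[str, str], list[tuple[str, int]]]:
    """Labeled segment keys grouped by (patient, class), in set order."""
    out: dict[tuple[str, str], list[tuple[str, int]]] = {}
    for s in segset:
        if s.ref_label in ("tremor", "no_tremor"):
            out.setdefault((s.patient_id, s.ref_label), []).append(s.key)
    if not out:
        raise ValueError("segment set carries no tremor / no_tremor labels")
    return out


def make_folds(
    segset: SegmentSet,
    n_blocks: int = 5,
    n_iterations: int = 4,
    min_per_stratum: int = 5,
    randomize: bool = False,
    seed: int | None = None,
) -> list[set]:
    """Held-out key sets for each CV iteration.

    Each patient's tremor and no-tremor segments are split into
    ``n_blocks`` equal contiguous blocks (or seeded-random blocks); test
    set ``i`` is block ``i`` of every stratum, so each iteration trains on
    80% and tests on 20% of both classes of every patient, and the test
    sets of the four iterations are pairwise disjoint.  Strata smaller than
    ``min_per_stratum`` stay whole in training (logged).
    """
    rng = np.random.default_rng(seed)
    test_sets: list[set] = [set() for _ in range(n_iterations)]
    for (pid, lab), keys in _strata(segset).items():
        if len(keys) < min_per_stratum:
            logger.info(
                "stratum (%s, %s) has %d segment(s) < %d; kept whole in training",
                pid, lab, len(keys), min_per_stratum,
            )
            continue
        keys = list(keys)
        if randomize:
            rng.shuffle(keys)
        blocks = np.array_split(np.arange(len(keys)), n_blocks)
        for i in range(n_iterations):
            test_sets[i].update(keys[j] for j in blocks[i])
    return test_sets


def cross_validate(
    segset: SegmentSet,
    method: str,
    lower_grid: np.ndarray | None = None,
    thresh_grid: np.ndarray | None = None,
    band_upper: float = BAND_UPPER_DEFAULT,
    n_iterations: int = 4,
    randomize: bool = False,
    seed: int | None = None,
) -> CVResult:
    """Four-iteration patient- and class-stratified cross-validation.

    Per iteration: grid search + F1 argmax on the 80% training split, then
    the held-out 20% is scored at the selected parameters.
    """
    all_keys = {s.key for s in segset
                if s.ref_label in ("tremor", "no_tremor")}
    test_sets = make_folds(segset, n_iterations=n_iterations,
                           randomize=randomize, seed=seed)
    result = CVResult(method)
    for test in test_sets:
        train = all_keys - test
        g = grid_search(segset, method, lower_grid, thresh_grid,
                        band_upper, subset=train)
        params, plateau = optimal_by_f1(g)
        train_m = _score_subset(segset, method, train, params)
        test_m = _score_subset(segset, method, test, params)
        result.iterations.append(CVIteration(
            params, plateau, train_m, test_m, len(train), len(test)))
    return result


def _score_subset(segset: SegmentSet, method: str, subset: set,
                  params: DetectionParams) -> MetricSet:
    freq, amp, y = _labeled_arrays(segset, method, subset)
    pred = ((freq >= params.band_lower) & (freq <= params.band_upper)
            & (amp > params.power_threshold))
    ref = np.where(y, "tremor", "no_tremor")
    return metrics(confusion(ref, np.where(pred, "tremor", "no_tremor")))
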