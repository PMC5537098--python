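"""PmEI: mutual-information-ranked, CV-gated greedy forward feature selection.

For one binary semantic-term annotation ``a_k`` over the cohort, the
selector:

1. discretises every (z-scored) feature column into equal-frequency bins
   and ranks all features by their plug-in mutual information with the
   labels (relevancy ``R``, in bits);
2. initialises the selected set with the top-ranked feature and measures
   the pooled fivefold cross-validated accuracy ``tau = (TP + TN) / N`` of
   a Gaussian-kernel SVM on that set;
3. walks the remaining features once, in ranking order, tentatively adding
   each one and keeping it if and only if the cross-validated accuracy
   strictly improves.

Correlated features are deliberately not penalised: every feature gets the
same chance to enter, and only its marginal effect on accuracy decides.
The number of selected features is therefore data-driven.  Selected
features finally receive a 0-5 ranking value (5 = most informative, 0 =
not selected) by linearly rescaling their relevancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .feature_bank import FeatureMatrix

DEFAULT_MI_BINS = 8
DEFAULT_CV_FOLDS = 5
SVM_C = 1.0


@dataclass
class BinaryAnnotation:
    """One semantic term's presence labels in {1, -1} over the cohort."""

    vst_name: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        bad = set(np.unique(self.labels)) - {1, -1}
        if bad:
            raise ValueError(f"labels must be in {{1, -1}}, found {sorted(bad)}")
        if not ((self.labels == 1).any() and (self.labels == -1).any()):
            raise ValueError(f"annotation {self.vst_name!r} has only one class")


@dataclass
class RelevanceRanking:
    """Feature order by non-increasing mutual information with the labels."""

    order: np.ndarray  # feature indices, best first
    relevance: np.ndarray  # R in bits, aligned with `order`

    def relevance_of(self, feature: int) -> float:
        pos = int(np.flatnonzero(self.order == feature)[0])
        return float(self.relevance[pos])


@dataclass
class SelectionStep:
    feature: int
    tau: float
    accepted: bool


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    selected: list[int]
    final_tau: float


@dataclass
class PmeiResult:
    """Per-term selection outcome used for reporting and prediction."""

    vst_name: str
    trace: SelectionTrace
    ranking: RelevanceRanking
    ranking_values: np.ndarray = field(default=None)  # len n_features, in [0, 5]


# ---------------------------------------------------------------------------
# discretisation and mutual information
# ---------------------------------------------------------------------------


def discretize(values: np.ndarray, n_bins: int = DEFAULT_MI_BINS) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` codes.

    Tied values always share the lowest code any of them would receive, so
    a constant vector yields a single code.  With all-distinct values, bin
    populations differ by at most one.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    values = np.asarray(values)
    n = values.size
    order = np.argsort(values, kind="stable")
    codes = np.empty(n, int)
    codes[order] = (np.arange(n) * n_bins) // n
    _, inverse = np.unique(values, return_inverse=True)
    min_code = np.full(inverse.max() + 1, n_bins, int)
    np.minimum.at(min_code, inverse, codes)
    return min_code[inverse]


def mutual_information(f_disc: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in mutual information in bits: H(f) + H(a) - H(f, a).

    Algebraically identical to the joint-minus-conditional-entropies form
    for the empirical distribution.
    """
    f_disc = np.asarray(f_disc)
    labels = np.asarray(labels)
    if f_disc.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {f_disc.shape} features vs {labels.shape} labels"
        )
    _, fi = np.unique(f_disc, return_inverse=True)
    _, ai = np.unique(labels, return_inverse=True)
    joint = np.zeros((fi.max() + 1, ai.max() + 1))
    np.add.at(joint, (fi, ai), 1.0)
    joint /= joint.sum()

    def h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    return h(joint.sum(axis=1)) + h(joint.sum(axis=0)) - h(joint.ravel())


def rank_features(
    matrix: FeatureMatrix, ann: BinaryAnnotation, n_bins: int = DEFAULT_MI_BINS
) -> RelevanceRanking:
    """Order features by descending relevancy; ties by ascending column index."""
    R = np.array(
        [
            mutual_information(discretize(matrix.values[:, j], n_bins), ann.labels)
            for j in range(matrix.n_features)
        ]
    )
    order = np.lexsort((np.arange(matrix.n_features), -R))
    return RelevanceRanking(order=order, relevance=R[order])


# ---------------------------------------------------------------------------
# cross-validated SVM accuracy
# ---------------------------------------------------------------------------


def _make_svm(n_features: int) -> SVC:
    # Gaussian kernel; width fixed at 1/(active feature count), untuned
    return SVC(C=SVM_C, kernel="rbf", gamma=1.0 / n_features)


def cv_accuracy(
    X: np.ndarray,
    ann: BinaryAnnotation,
    k: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
) -> float:
    """Pooled k-fold cross-validated accuracy tau = (TP + TN) / N.

    Folds are stratified by class and fully determined by ``seed``.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = ann.labels
    for cls in (1, -1):
        n_cls = int((y == cls).sum())
        if n_cls < k:
            raise ValueError(
                f"class {cls} of {ann.vst_name!r} has {n_cls} samples, fewer "
                f"than the {k} folds"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = _make_svm(X.shape[1])
        clf.fit(X[train_idx], y[train_idx])
        correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / y.size


# ---------------------------------------------------------------------------
# the selector
# ---------------------------------------------------------------------------


def pmei_select(
    matrix: FeatureMatrix,
    ann: BinaryAnnotation,
    k: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    n_bins: int = DEFAULT_MI_BINS,
    ranking: RelevanceRanking | None = None,
) -> SelectionTrace:
    """One full strict-improvement forward pass over the MI ranking.

    The first step always accepts the top-ranked feature; afterwards a
    candidate is kept iff the cross-validated accuracy strictly increases.
    Accepted features are never revisited or removed.
    """
    if ranking is None:
        ranking = rank_features(matrix, ann, n_bins)
    order = ranking.order
    selected = [int(order[0])]
    tau = cv_accuracy(matrix.values[:, selected], ann, k=k, seed=seed)
    steps = [SelectionStep(feature=int(order[0]), tau=tau, accepted=True)]
    for f in order[1:]:
        trial = selected + [int(f)]
        tau_i = cv_accuracy(matrix.values[:, trial], ann, k=k, seed=seed)
        accepted = tau_i > tau
        if accepted:
            selected = trial
            tau = tau_i
        steps.append(SelectionStep(feature=int(f), tau=tau_i, accepted=accepted))
    trace = SelectionTrace(steps=steps, selected=selected, final_tau=tau)
    _assert_monotone(trace)
    return trace


def _assert_monotone(trace: SelectionTrace) -> None:
    taus = [s.tau for s in trace.steps if s.accepted]
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise AssertionError("accepted-step accuracies are not strictly increasing")


def ranking_values(trace: SelectionTrace, ranking: RelevanceRanking) -> np.ndarray:
    """0-5 informativeness per feature: 0 for unselected features; selected
    relevancies rescaled linearly so the largest maps to 5 and the smallest
    to 1 (all 5 when the selected relevancies are equal)."""
    n = ranking.order.size
    out = np.zeros(n)
    if not trace.selected:
        return out
    rel = np.array([ranking.relevance_of(f) for f in trace.selected])
    lo, hi = rel.min(), rel.max()
    if hi - lo < 1e-12:
        scaled = np.full(rel.shape, 5.0)
    else:
        scaled = 1.0 + 4.0 * (rel - lo) / (hi - lo)
    for f, v in zip(trace.selected, scaled):
        out[f] = v
    return out


def run_pmei(
    matrix: FeatureMatrix,
    ann: BinaryAnnotation,
    k: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    n_bins: int = DEFAULT_MI_BINS,
) -> PmeiResult:
    """Rank, select and score one semantic term; convenience wrapper."""
    ranking = rank_features(matrix, ann, n_bins)
    trace = pmei_select(matrix, ann, k=k, seed=seed, n_bins=n_bins, ranking=ranking)
    values = ranking_values(trace, ranking)
    return PmeiResult(
        vst_name=ann.vst_name, trace=trace, ranking=ranking, ranking_values=values
    )
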