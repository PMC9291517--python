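"""TR-vs-control classification from PCA shape loadings.

The workflow: stratified 80/20 train/test split of the loading vectors,
Borderline-SMOTE balancing of the two minority groups (TR patients and
healthy volunteers) up to the comorbid-control count on the training side
only, stability feature selection by repeated lasso regression (the
"dominance probability" of a mode is the fraction of resampled lasso fits
in which it receives non-zero weight), then a cross-validated logistic
regression on the top four modes, evaluated with the standard confusion
metrics and a threshold-sweep ROC.

Borderline-SMOTE is implemented here directly (Borderline-SMOTE-1): a
minority sample is "borderline" when at least half but not all of its k
nearest neighbors in the whole training set belong to other classes, and
synthetic samples are convex combinations x + u (x' - x), u in (0, 1), of
a borderline sample x and one of its same-class neighbors x'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import NearestNeighbors

MAJORITY_GROUP = "control"
MINORITY_GROUPS = ("tr", "healthy")

# LassoCV settings: 3-fold CV, no intercept, tol 1e-4, a 100-point
# regularization path, 1e5 max iterations
_LASSO_KW = dict(cv=3, fit_intercept=False, tol=1e-4, alphas=100,
                 max_iter=100_000)


@dataclass
class LabeledCohort:
    """Per-subject loading vectors with binary and three-way labels."""

    s: np.ndarray                      # (K, n_modes)
    y: np.ndarray                      # 1 = patient with TR, 0 = control
    group3: np.ndarray                 # healthy / control / tr
    subgroup: np.ndarray | None = None
    subject_ids: list = field(default_factory=list)
    synthetic: np.ndarray | None = None  # True for SMOTE-generated rows

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.group3 = np.asarray(self.group3)
        if self.s.ndim != 2:
            raise ValueError("loadings must be 2-D")
        if len(self.y) != len(self.s) or len(self.group3) != len(self.s):
            raise ValueError("label arrays must match the loading rows")
        expected = (self.group3 == "tr").astype(int)
        if not np.array_equal(self.y, expected):
            raise ValueError("y must be 1 exactly for the TR group")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(len(self.s))]
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.s), dtype=bool)

    @classmethod
    def from_loadings(cls, model, matrix, n_modes: int | None = None):
        """Build from a fitted PCAModel and the labeled ShapeMatrix."""
        s = model.loadings if n_modes is None else model.loadings[:, :n_modes]
        g = matrix.group3
        if g is None:
            raise ValueError("shape matrix has no group labels")
        return cls(s, (g == "tr").astype(int), g, matrix.subgroup,
                   list(matrix.subject_ids))

    def subset(self, idx) -> "LabeledCohort":
        idx = np.asarray(idx)
        return LabeledCohort(
            self.s[idx], self.y[idx], self.group3[idx],
            None if self.subgroup is None else self.subgroup[idx],
            [self.subject_ids[i] for i in idx], self.synthetic[idx],
        )

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class LassoSelectionResult:
    dominance: np.ndarray
    n_repeats: int
    selected_modes: np.ndarray | None = None


@dataclass
class ClassificationReport:
    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc: np.ndarray          # (n, 2) columns (FPR, TPR)
    auc: float               # nan when the test set has one class
    selected_modes: np.ndarray | None = None
    dominance: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": {"TN": self.tn, "FP": self.fp, "FN": self.fn,
                          "TP": self.tp},
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "auc": None if np.isnan(self.auc) else self.auc,
            "roc": self.roc.tolist(),
            "selected_modes": None if self.selected_modes is None
            else [int(m) for m in self.selected_modes],
            "dominance": None if self.dominance is None
            else self.dominance.tolist(),
        }


# ---------------------------------------------------------------------------
# Split and balance
# ---------------------------------------------------------------------------

def split_train_test(cohort: LabeledCohort, train_fraction: float = 0.8,
                     seed: int = 0):
    """Stratified (by y) disjoint split; train size = floor(frac * K)."""
    k = len(cohort)
    if k < 5:
        raise ValueError("cohort too small to split (need >= 5 subjects)")
    n_train = int(np.floor(train_fraction * k))
    if n_train <= 0 or n_train >= k:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty side "
            f"({n_train}/{k - n_train})"
        )
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=n_train,
                                      random_state=seed)
    try:
        tr_idx, te_idx = next(splitter.split(cohort.s, cohort.y))
    except ValueError as exc:
        raise ValueError(f"stratification failed: {exc}") from None
    train, test = cohort.subset(np.sort(tr_idx)), cohort.subset(np.sort(te_idx))
    for side, name in ((train, "train"), (test, "test")):
        if len(np.unique(side.y)) < 2:
            raise ValueError(
                f"class absent from the {name} side; stratification failed "
                "at these group sizes"
            )
    return train, test


def _borderline_danger(s: np.ndarray, classes: np.ndarray, cls,
                       k_neighbors: int) -> np.ndarray:
    """Indices of minority samples in the Borderline-SMOTE-1 danger set."""
    members = np.where(classes == cls)[0]
    k = min(k_neighbors, len(s) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(s)
    _, neigh = nn.kneighbors(s[members])
    danger = []
    for row, i in zip(neigh, members):
        others = [j for j in row if j != i][:k]
        m_other = sum(classes[j] != cls for j in others)
        if k / 2 <= m_other < k:
            danger.append(i)
    return np.asarray(danger, dtype=int)


def borderline_smote(train: LabeledCohort, k_neighbors: int = 5,
                     seed: int = 0) -> LabeledCohort:
    """Upsample the minority groups to the majority (comorbid-control) count.

    Synthetic rows carry ``synthetic=True`` so tests can verify they never
    reach a test set. Already-balanced input is returned unchanged.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    counts = {g: int((train.group3 == g).sum())
              for g in np.unique(train.group3)}
    majority = counts.get(MAJORITY_GROUP, max(counts.values()))
    need = {g: majority - counts[g] for g in counts
            if g != MAJORITY_GROUP and counts[g] < majority}
    if not need:
        return train.subset(np.arange(len(train)))
    rng = np.random.default_rng(seed)
    s_new, g_new = [], []
    for cls in sorted(need):
        if counts[cls] < 2:
            raise ValueError(
                f"minority class {cls!r} has {counts[cls]} member(s); "
                "need >= 2 to interpolate"
            )
        k_eff = min(k_neighbors, counts[cls] - 1)
        if k_eff < k_neighbors:
            warnings.warn(
                f"k_neighbors clamped to {k_eff} for class {cls!r}",
                stacklevel=2,
            )
        danger = _borderline_danger(train.s, train.group3, cls, k_neighbors)
        if len(danger) == 0:
            # no borderline sample: fall back to the whole minority class
            danger = np.where(train.group3 == cls)[0]
        members = np.where(train.group3 == cls)[0]
        nn = NearestNeighbors(n_neighbors=min(k_eff + 1, len(members))).fit(
            train.s[members]
        )
        for _ in range(need[cls]):
            i = danger[rng.integers(len(danger))]
            _, neigh = nn.kneighbors(train.s[i][None, :])
            cand = [members[j] for j in neigh[0] if members[j] != i]
            j = cand[rng.integers(len(cand))]
            u = rng.uniform(0.0, 1.0)
            while u == 0.0:
                u = rng.uniform(0.0, 1.0)
            s_new.append(train.s[i] + u * (train.s[j] - train.s[i]))
            g_new.append(cls)
    g_new = np.asarray(g_new)
    s_all = np.vstack([train.s, np.asarray(s_new)])
    g_all = np.concatenate([train.group3, g_new])
    y_all = (g_all == "tr").astype(int)
    sub_all = None
    if train.subgroup is not None:
        sub_all = np.concatenate([train.subgroup,
                                  np.full(len(g_new), "none")])
    ids = list(train.subject_ids) + [
        f"synth{i:03d}" for i in range(len(g_new))
    ]
    synth = np.concatenate([train.synthetic,
                            np.ones(len(g_new), dtype=bool)])
    return LabeledCohort(s_all, y_all, g_all, sub_all, ids, synth)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def lasso_dominance(train: LabeledCohort, n_repeats: int = 1000,
                    subset_fraction: float = 0.8,
                    seed: int = 0) -> LassoSelectionResult:
    """Dominance probability of each mode over repeated subset lasso fits.

    Each repeat draws a random subset (without replacement, redrawn until
    both classes are present), fits an L1 linear regression of y on the
    loadings with 3-fold CV over the regularization path and no
    intercept, and counts which modes receive non-zero weight.
    """
    rng = np.random.default_rng(seed)
    n, p = train.s.shape
    n_sub = max(2, int(np.floor(subset_fraction * n)))
    const = train.s.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant mode(s) excluded from selection",
            stacklevel=2,
        )
    cols = np.where(~const)[0]
    counts = np.zeros(p)
    # interceptless model: center the 0/1 labels so the fit is not forced
    # to absorb the class mean through the penalized weights
    y = train.y.astype(float) - train.y.mean()
    for _ in range(n_repeats):
        for _ in range(100):
            idx = rng.choice(n, size=n_sub, replace=False)
            if len(np.unique(train.y[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class subset")
        model = LassoCV(random_state=int(rng.integers(2 ** 31)), **_LASSO_KW)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(train.s[np.ix_(idx, cols)], y[idx])
        counts[cols[np.abs(model.coef_) > 1e-10]] += 1
    return LassoSelectionResult(counts / n_repeats, n_repeats)


def select_top_modes(result: LassoSelectionResult, n: int = 4) -> np.ndarray:
    """Indices of the n most dominant modes; ties break toward the lower
    mode index."""
    dom = result.dominance
    nonzero = int((dom > 0).sum())
    if nonzero < n:
        avail = np.where(dom > 0)[0]
        raise ValueError(
            f"only {nonzero} modes have non-zero dominance "
            f"(modes {avail.tolist()}); cannot select {n}"
        )
    order = np.lexsort((np.arange(len(dom)), -dom))
    selected = np.sort(order[:n])
    result.selected_modes = selected
    return selected


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def fit_classifier(train: LabeledCohort, modes, seed: int = 0):
    """Cross-validated logistic regression on the selected modes
    (lbfgs, ROC-AUC model selection, 3-fold CV)."""
    modes = np.asarray(modes, dtype=int)
    if modes.size == 0:
        raise ValueError("no modes selected")
    if len(np.unique(train.y)) < 2:
        raise ValueError("training data contains a single class")
    # ROC-AUC is invariant to the coefficient scale, so CV ties are common;
    # a descending C grid breaks them toward the weakest regularization
    clf = LogisticRegressionCV(
        cv=3, solver="lbfgs", scoring="roc_auc", max_iter=100_000,
        Cs=np.logspace(4, -4, 10), random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(train.s[:, modes], train.y)
    clf._rvshape_modes = modes
    return clf


def evaluate(classifier, test: LabeledCohort,
             selection: LassoSelectionResult | None = None
             ) -> ClassificationReport:
    """Confusion counts at threshold 0.5, the four printed metrics,
    threshold-sweep ROC and trapezoid AUC."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    modes = getattr(classifier, "_rvshape_modes", None)
    x = test.s if modes is None else test.s[:, modes]
    prob = classifier.predict_proba(x)[:, 1]
    pred = (prob >= 0.5).astype(int)
    y = test.y
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = (tn + tp) / (tn + tp + fn + fp)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * recall * precision / (recall + precision)
          if (recall + precision) > 0 else 0.0)
    if len(np.unique(y)) < 2:
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
        auc = float("nan")
    else:
        fpr, tpr, _ = roc_curve(y, prob)
        roc = np.column_stack([fpr, tpr])
        auc = float(np.trapezoid(tpr, fpr))
    return ClassificationReport(
        tn, fp, fn, tp, accuracy, precision, recall, f1, roc, auc,
        None if selection is None else selection.selected_modes,
        None if selection is None else selection.dominance,
    )


def classify_cohort(cohort: LabeledCohort, train_fraction: float = 0.8,
                    smote_k: int = 5, n_repeats: int = 1000,
                    subset_fraction: float = 0.8, top_modes: int = 4,
                    seed: int = 0) -> ClassificationReport:
    """End-to-end: split -> SMOTE -> lasso dominance -> top modes ->
    logistic regression -> test-set report."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]
    train, test = split_train_test(cohort, train_fraction, seeds[0])
    balanced = borderline_smote(train, smote_k, seeds[1])
    selection = lasso_dominance(balanced, n_repeats, subset_fraction,
                                seeds[2])
    modes = select_top_modes(selection, top_modes)
    clf = fit_classifier(balanced, modes, seeds[3])
    return evaluate(clf, test, selection)
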