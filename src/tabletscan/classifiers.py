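"""Four classifiers for coating level: NTC, PLS-DA, SVM, CNN.

Class scheme: 1 = uncoated, 2 = slightly, 3 = moderately, 4 = fully
coated.  Class 0 is a rejection label — a tablet not strictly predicted
into any class by a discriminant model (PLS-DA by default) is assigned
class 0 and counts as misclassified downstream.

NTC (numerical threshold classification) is the univariate method: one
summed channel intensity per tablet, three ordered thresholds, class by
interval.  Coating darkens the blue channel, so class 1 owns the highest
intensities and class 4 the lowest.  The fitting rule minimizes training
misclassifications exactly (dynamic program over cut positions in the
sorted intensities); among minimizers, each threshold is placed at the
midpoint of the adjacent classes' nearest opposing values, i.e. the
maximum-margin cut.

PLS-DA is PLS2 regression of one-hot class indicators on the flattened
crop vectors (mean-centering only, no scaling), with the number of latent
variables chosen by venetian-blinds cross-validation; predictions pass
through a strictness rule that can emit class 0.  The SVM is a standard
RBF one-vs-one multiclass machine on features scaled to [0, 1] by /255,
optionally restricted to a single color channel's columns.  The CNN wraps
:mod:`tabletscan.cnn`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC

from .cnn import CnnSpec, SmallCnn, iteration_cap, iterations_per_epoch
from .core import TabletImage

__all__ = [
    "ThresholdModel",
    "fit_ntc",
    "predict_ntc",
    "PlsdaModel",
    "fit_plsda",
    "venetian_blinds_folds",
    "predict_strict",
    "SvmModel",
    "fit_svm",
    "CnnModel",
    "fit_cnn",
    "CnnSpec",
    "iteration_cap",
    "iterations_per_epoch",
]

_CLASSES = (1, 2, 3, 4)


# ---------------------------------------------------------------------------
# NTC

@dataclass(frozen=True)
class ThresholdModel:
    """Three ordered thresholds t1 > t2 > t3 on a summed channel intensity.

    Intensities above t1 are class 1, (t2, t1] class 2, (t3, t2] class 3,
    and everything at or below t3 class 4: prediction is piecewise
    constant and monotone non-increasing in the summed intensity.  A value
    exactly on a threshold goes to the lower-intensity (higher) class.
    """

    channel: str
    thresholds: tuple[float, float, float]
    fitted_on: str = ""
    train_errors: int = 0

    def __post_init__(self) -> None:
        t1, t2, t3 = self.thresholds
        if not (t1 > t2 > t3):
            raise ValueError(f"thresholds must be strictly ordered, got {self.thresholds}")


def fit_ntc(
    values: Sequence[tuple[float, int]],
    channel: str = "B",
    fitted_on: str = "",
) -> ThresholdModel:
    """Fit the three NTC thresholds by exact training-error minimization.

    ``values`` is a sequence of (summed intensity, true class) pairs and
    must contain at least one example of each class 1-4.  The search space
    is the cut positions in the descending-sorted intensities; a dynamic
    program finds the error-minimizing triple of cuts in O(n) after the
    sort, with ties broken toward the widest total margin and then toward
    the lowest cut positions, so the fit is deterministic.  Thresholds are
    midpoints of the straddling values (extreme cuts fall 1 unit outside
    the data range).
    """
    s = np.asarray([v[0] for v in values], dtype=float)
    y = np.asarray([v[1] for v in values], dtype=int)
    if s.size == 0:
        raise ValueError("no training values")
    for k in _CLASSES:
        if not np.any(y == k):
            raise ValueError(f"class {k} has no training examples")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    n = s.size

    # prefix[k][i] = count of class k among the first i sorted samples
    prefix = {k: np.concatenate([[0], np.cumsum(y_sorted == k)]) for k in _CLASSES}

    # Margin width of a cut at position c (between index c-1 and c).
    big = (s_sorted[0] - s_sorted[-1]) + 4.0  # beats any interior gap
    gap = np.empty(n + 1)
    gap[0] = gap[n] = big
    gap[1:n] = s_sorted[:-1] - s_sorted[1:]

    # f(c1,c2,c3) = correct count = g1(c1) + g2(c2) + g3(c3) + |class4|
    g1 = prefix[1] - prefix[2]
    g2 = prefix[2] - prefix[3]
    g3 = prefix[3] - prefix[4]

    def scan(values_g: np.ndarray, base_score: np.ndarray, base_gap: np.ndarray):
        """Best (score, margin) over cuts <= j, lexicographic, ties -> low cut."""
        score = base_score + values_g
        margin = base_gap + gap
        best_score = np.empty(n + 1)
        best_margin = np.empty(n + 1)
        best_cut = np.empty(n + 1, dtype=int)
        bs, bm, bc = -np.inf, -np.inf, 0
        for j in range(n + 1):
            if score[j] > bs or (score[j] == bs and margin[j] > bm):
                bs, bm, bc = score[j], margin[j], j
            best_score[j], best_margin[j], best_cut[j] = bs, bm, bc
        return best_score, best_margin, best_cut

    zeros = np.zeros(n + 1)
    s1, m1, c1_at = scan(g1, zeros, zeros)
    s2, m2, c2_at = scan(g2, s1, m1)
    s3, m3, c3_at = scan(g3, s2, m2)

    c3 = int(np.lexsort((np.arange(n + 1), -m3, -s3))[0])
    c2 = int(c2_at[c3])
    c1 = int(c1_at[c2])
    correct = int(s3[c3] + prefix[4][n])

    def cut_to_threshold(c: int) -> float:
        if c == 0:
            return s_sorted[0] + 1.0
        if c == n:
            return s_sorted[-1] - 1.0
        return float((s_sorted[c - 1] + s_sorted[c]) / 2.0)

    t = [cut_to_threshold(c) for c in (c1, c2, c3)]
    # Equal cuts (an empty predicted interval) give equal thresholds; nudge
    # them apart so the model keeps its strict ordering.
    eps = max(1e-9, 1e-12 * max(abs(t[0]), 1.0))
    for i in (1, 2):
        if t[i] >= t[i - 1]:
            t[i] = t[i - 1] - eps
    return ThresholdModel(
        channel=channel,
        thresholds=(t[0], t[1], t[2]),
        fitted_on=fitted_on,
        train_errors=n - correct,
    )


def predict_ntc(model: ThresholdModel, s: float | np.ndarray) -> int | np.ndarray:
    """Interval prediction: s > t1 -> 1; t2 < s <= t1 -> 2; t3 < s <= t2 -> 3;
    s <= t3 -> 4."""
    t1, t2, t3 = model.thresholds
    arr = np.asarray(s, dtype=float)
    out = np.full(arr.shape, 4, dtype=int)
    out[arr > t3] = 3
    out[arr > t2] = 2
    out[arr > t1] = 1
    if np.isscalar(s) or arr.ndim == 0:
        return int(out)
    return out


# ---------------------------------------------------------------------------
# strictness rule (class 0)

def predict_strict(
    scores: np.ndarray, rule: str = "unique_above_cut", cut: float = 0.5
) -> np.ndarray:
    """Map per-class score vectors to classes {0..4}.

    ``unique_above_cut`` (default): class k iff score_k > cut and every
    other score <= cut, else 0 — the rejection convention for tablets not
    strictly predicted into any single class.  ``argmax_above_cut``: the
    argmax class if its score clears the cut, else 0.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[1] != 4:
        raise ValueError(f"expected 4 per-class scores, got {S.shape[1]}")
    above = S > cut
    arg = S.argmax(axis=1)
    if rule == "unique_above_cut":
        pred = np.where(above.sum(axis=1) == 1, above.argmax(axis=1) + 1, 0)
    elif rule == "argmax_above_cut":
        pred = np.where(above[np.arange(len(S)), arg], arg + 1, 0)
    else:
        raise ValueError(f"unknown strictness rule {rule!r}")
    if np.asarray(scores).ndim == 1:
        return np.asarray(int(pred[0]))
    return pred


# ---------------------------------------------------------------------------
# PLS-DA

def venetian_blinds_folds(n: int, k: int) -> np.ndarray:
    """Fold index per sample: sample i belongs to fold i mod k."""
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    return np.arange(n) % k


@dataclass
class PlsdaModel:
    pls: PLSRegression
    n_components: int
    rule: str
    cut: float
    cv_misclassifications: dict[int, int] = field(default_factory=dict)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.pls.predict(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_strict(self.predict_scores(X), rule=self.rule, cut=self.cut)


def _one_hot(y: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(y), 4))
    for j, k in enumerate(_CLASSES):
        Y[y == k, j] = 1.0
    return Y


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components_grid: Sequence[int] | None = None,
    cv_folds: int = 10,
    rule: str = "unique_above_cut",
    cut: float = 0.5,
) -> PlsdaModel:
    """One-hot PLS2 regression classifier with venetian-blinds model selection.

    For each candidate latent-variable count the data are split into
    ``cv_folds`` venetian-blinds folds (sample i -> fold i mod k), the
    model refit on the complement and the held-out samples classified via
    the strictness rule; the component count with the fewest total CV
    misclassifications wins (ties to the smaller count).  The returned
    model is refit on all data.  Mean-centering only — no variance
    scaling.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("X is degenerate: every feature has zero variance")
    n, p = X.shape
    max_comp = min(p, n - max(2, n // cv_folds) - 1, 10)
    if n_components_grid is None:
        n_components_grid = range(1, max(2, max_comp + 1))
    folds = venetian_blinds_folds(n, cv_folds)
    Y = _one_hot(y)

    cv_err: dict[int, int] = {}
    for ncomp in n_components_grid:
        errors = 0
        ok = True
        for f in range(cv_folds):
            tr, te = folds != f, folds == f
            try:
                pls = PLSRegression(n_components=ncomp, scale=False)
                pls.fit(X[tr], Y[tr])
            except Exception:
                ok = False
                break
            pred = predict_strict(np.asarray(pls.predict(X[te])), rule=rule, cut=cut)
            errors += int((pred != y[te]).sum())
        if ok:
            cv_err[ncomp] = errors
    if not cv_err:
        raise ValueError("no candidate component count could be fit")
    best = min(cv_err, key=lambda c: (cv_err[c], c))
    pls = PLSRegression(n_components=best, scale=False)
    pls.fit(X, Y)
    return PlsdaModel(pls=pls, n_components=best, rule=rule, cut=cut,
                      cv_misclassifications=cv_err)


# ---------------------------------------------------------------------------
# SVM

@dataclass
class SvmModel:
    svc: SVC
    columns: np.ndarray | None  # feature-column subset, None = all
    scale: float = 255.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.columns is not None:
            X = X[:, self.columns]
        return self.svc.predict(X / self.scale).astype(int)


def channel_columns(n_features: int, channel: str) -> np.ndarray:
    """Column indices of one color plane in a planar R,G,B flattened vector."""
    if n_features % 3:
        raise ValueError(f"feature count {n_features} is not divisible by 3")
    plane = {"R": 0, "G": 1, "B": 2}[channel]
    npx = n_features // 3
    return np.arange(plane * npx, (plane + 1) * npx)


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    channel_subset: str | None = None,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> SvmModel:
    """One-vs-one multiclass SVM on /255-scaled features.

    ``channel_subset`` restricts the model to one color channel's columns
    (e.g. ``"B"`` for a blue-only machine), cutting the feature count to a
    third.  Kernel and regularization are the host library's defaults
    unless overridden.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("X is degenerate: every feature has zero variance")
    cols = channel_columns(X.shape[1], channel_subset) if channel_subset else None
    Xs = X[:, cols] if cols is not None else X
    svc = SVC(kernel=kernel, C=C, gamma=gamma, decision_function_shape="ovo")
    svc.fit(Xs / 255.0, y)
    return SvmModel(svc=svc, columns=cols)


# ---------------------------------------------------------------------------
# CNN

@dataclass
class CnnModel:
    net: SmallCnn
    classes_: np.ndarray
    spec: CnnSpec
    in_shape: tuple[int, int, int]
    log: list[dict] = field(default_factory=list)

    def predict(self, images: Sequence[TabletImage | np.ndarray]) -> np.ndarray:
        x = _stack_images(images, self.in_shape)
        logits = self.net.predict_logits(x)
        return self.classes_[logits.argmax(axis=1)]


def _stack_images(
    images: Sequence[TabletImage | np.ndarray], expect: tuple[int, int, int] | None = None
) -> np.ndarray:
    arrs = []
    for img in images:
        a = img.pixels if isinstance(img, TabletImage) else np.asarray(img)
        arrs.append(a)
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"images must share one canonical size, got {sorted(shapes)}")
    # Center to [-0.5, 0.5]: zero-mean-ish inputs keep ReLU units alive and
    # decorrelate the gradient signs across weights.
    x = np.stack(arrs).astype(np.float64) / 255.0 - 0.5
    x = x.transpose(0, 3, 1, 2)  # NHWC -> NCHW
    if expect is not None and x.shape[1:] != expect:
        raise ValueError(f"image shape {x.shape[1:]} != model input {expect}")
    return x


def fit_cnn(
    images: Sequence[TabletImage | np.ndarray],
    y: np.ndarray,
    spec: CnnSpec | None = None,
) -> CnnModel:
    """Train the small conv net on canonical-size crops.

    When ``spec.train_per_class`` is set, exactly that many images are
    drawn per class (seeded); classes with fewer images raise, so
    scaled-down runs must lower the quota explicitly (or pass ``None`` to
    train on everything).  Shuffling, batching and initialization all
    derive from ``spec.seed``, making the fit reproducible.
    """
    spec = spec or CnnSpec()
    y = np.asarray(y, dtype=int)
    if len(images) != len(y):
        raise ValueError("images and labels are misaligned")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    rng = np.random.default_rng(spec.seed)

    idx = np.arange(len(y))
    if spec.train_per_class is not None:
        chosen = []
        for k in classes:
            members = idx[y == k]
            if members.size < spec.train_per_class:
                raise ValueError(
                    f"class {k} has {members.size} images, fewer than "
                    f"train_per_class={spec.train_per_class}; lower the quota"
                )
            chosen.append(rng.choice(members, size=spec.train_per_class,
                                     replace=False))
        idx = np.sort(np.concatenate(chosen))

    x = _stack_images([images[i] for i in idx])
    y_sub = y[idx]
    class_to_pos = {k: j for j, k in enumerate(classes)}
    y_idx = np.array([class_to_pos[k] for k in y_sub])

    net = SmallCnn(in_shape=x.shape[1:], n_classes=classes.size, spec=spec, rng=rng)
    log = net.fit(x, y_idx, rng)
    return CnnModel(net=net, classes_=classes, spec=spec, in_shape=x.shape[1:],
                    log=log)
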