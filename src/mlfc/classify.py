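"""Connectome-based classification with in-fold feature selection.

Two feature routes over the connectivity graphs are supported:

* ``edge``   - vectorized edge weights (N(N-1)/2 per single-layer graph),
  ranked in-fold by a greedy max-relevance/min-redundancy (mRMR) rule on
  quantile-discretized mutual information, top-k selected;
* ``tensor`` - the graph treated as a 2-D tensor and projected through
  tensor subspace analysis (TSA): supervised row/column bases U (N x d1)
  and V (N x d2) learned by an alternating generalized eigenproblem,
  features = vec(U' W V), d1*d2 per graph;
* ``mpc``    - per-node multilayer participation coefficients.

Classification is SVM with an RBF kernel under leave-one-out or
stratified 5-fold cross-validation. Every data-dependent step (scaling,
ranking, TSA fitting) is fitted inside each training fold only, so
held-out subjects never influence feature selection.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Literal, Sequence

import numpy as np
import scipy.linalg
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

Scheme = Literal["loocv", "5fold"]
Route = Literal["edge", "tensor", "mpc"]


# --------------------------------------------------------------------------
# mutual-information feature ranking (mRMR)
# --------------------------------------------------------------------------


def _discretize(x: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Quantile-discretize a 1-D feature; returns codes and code count."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    codes = np.searchsorted(edges, x, side="right")
    return codes, edges.size + 1


def _mi(a: np.ndarray, na: int, b: np.ndarray, nb: int) -> float:
    """Mutual information (nats) between two discrete code vectors."""
    c = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    c /= c.sum()
    pa = c.sum(axis=1, keepdims=True)
    pb = c.sum(axis=0, keepdims=True)
    nz = c > 0
    return float((c[nz] * np.log(c[nz] / (pa @ pb)[nz])).sum())


def rank_features_mi(
    X: np.ndarray, y: np.ndarray, k: int = 15, bins: int = 8
) -> list[int]:
    """Greedy mRMR ranking of feature columns.

    The first pick maximizes MI(feature; label); each subsequent pick
    maximizes MI(feature; label) minus the mean MI with already-picked
    features. MI is estimated on quantile-discretized features
    (``bins`` bins). Constant features have MI 0 and are never an error.
    Ties resolve to the lowest column index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, F = X.shape
    if k > F:
        raise ValueError(f"k={k} exceeds the {F} available features")
    ycodes, ny = np.unique(y, return_inverse=True)[1], np.unique(y).size
    codes = np.empty((F, n), dtype=np.intp)
    ncodes = np.empty(F, dtype=np.intp)
    for f in range(F):
        codes[f], ncodes[f] = _discretize(X[:, f], bins)
    rel = np.array([_mi(codes[f], ncodes[f], ycodes, ny) for f in range(F)])

    picked = [int(np.argmax(rel))]
    red_sum = np.zeros(F)
    for _ in range(1, k):
        last = picked[-1]
        for f in range(F):
            red_sum[f] += _mi(codes[f], ncodes[f], codes[last], ncodes[last])
        score = rel - red_sum / len(picked)
        score[picked] = -np.inf
        picked.append(int(np.argmax(score)))
    return picked


def consensus_features(
    per_fold_rankings: Sequence[Sequence[Hashable]], m: int = 15
) -> list[tuple[Hashable, int]]:
    """The ``m`` features most frequently present in the folds' top-k
    lists, with their fold counts.

    Ties are broken by mean within-fold rank, then by feature id.
    """
    freq: Counter = Counter()
    rank_sum: dict[Hashable, float] = {}
    for ranking in per_fold_rankings:
        for r, fid in enumerate(ranking):
            freq[fid] += 1
            rank_sum[fid] = rank_sum.get(fid, 0.0) + r
    if m > len(freq):
        warnings.warn(
            f"requested {m} consensus features but only {len(freq)} distinct "
            "features were ever selected; returning all",
            stacklevel=2,
        )
        m = len(freq)
    ordered = sorted(
        freq, key=lambda fid: (-freq[fid], rank_sum[fid] / freq[fid], repr(fid))
    )
    return [(fid, freq[fid]) for fid in ordered[:m]]


# --------------------------------------------------------------------------
# tensor subspace analysis
# --------------------------------------------------------------------------


class TSAProjector:
    """Supervised bilinear projection of square connectivity matrices.

    Learns bases U (N x d1) and V (N x d2) by alternating generalized
    eigenproblems that keep same-class graphs close in the projected
    space (within-class affinity 1, between-class 0), then orthonormalizes
    each basis. Features are vec(U' W V): d1*d2 per graph.
    """

    def __init__(self, d1: int = 6, d2: int = 6, n_iter: int = 5, ridge: float = 1e-8):
        self.d1, self.d2, self.n_iter, self.ridge = d1, d2, n_iter, ridge
        self.U: np.ndarray | None = None
        self.V: np.ndarray | None = None

    @staticmethod
    def _solve(Ms: np.ndarray, S: np.ndarray, Dd: np.ndarray, d: int, ridge: float) -> np.ndarray:
        # Ms: n x N x d stack of projected graphs; minimize the within-class
        # scatter tr(U' A U) against the weighted energy tr(U' B U)
        B = np.einsum("i,iab,icb->ac", Dd, Ms, Ms)
        cross = np.einsum("ij,iab,jcb->ac", S, Ms, Ms)
        A = 2.0 * (B - cross)
        B = B + ridge * (np.trace(B) / B.shape[0] + 1.0) * np.eye(B.shape[0])
        w, vecs = scipy.linalg.eigh(A, B)
        U = vecs[:, :d]
        q, _ = np.linalg.qr(U)
        return q

    def fit(self, graphs: Sequence[np.ndarray], y: np.ndarray) -> "TSAProjector":
        X = np.stack([np.asarray(g, dtype=float) for g in graphs])
        n, N, N2 = X.shape
        if N != N2:
            raise ValueError("graphs must be square")
        if self.d1 > N or self.d2 > N:
            raise ValueError(f"d1/d2 ({self.d1},{self.d2}) exceed matrix side {N}")
        y = np.asarray(y)
        S = (y[:, None] == y[None, :]).astype(float)
        np.fill_diagonal(S, 0.0)
        Dd = S.sum(axis=1)
        V = np.eye(N)[:, : self.d2]
        U = np.eye(N)[:, : self.d1]
        for _ in range(self.n_iter):
            U = self._solve(X @ V, S, Dd, self.d1, self.ridge)
            V = self._solve(np.transpose(X, (0, 2, 1)) @ U, S, Dd, self.d2, self.ridge)
        self.U, self.V = U, V
        return self

    def transform(self, graphs: Sequence[np.ndarray]) -> np.ndarray:
        if self.U is None:
            raise RuntimeError("projector not fitted")
        X = np.stack([np.asarray(g, dtype=float) for g in graphs])
        return (self.U.T @ X @ self.V).reshape(len(graphs), -1)


# --------------------------------------------------------------------------
# metrics and cross-validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    accuracy: float


def metrics(tp: int, fn: int, tn: int, fp: int) -> ClassMetrics:
    """Sensitivity, specificity, accuracy from confusion counts.

    Positives are the patient group. An empty class yields NaN for the
    affected metric, with a warning, rather than a silent 0.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    if tp + fn == 0:
        warnings.warn("no positive cases: sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative cases: specificity undefined", stacklevel=2)
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    return ClassMetrics(sens, spec, (tp + tn) / total)


@dataclass
class FeatureMatrix:
    """Subjects x features with identifiable feature ids."""

    X: np.ndarray
    feature_ids: list
    y: np.ndarray


def edge_feature_matrix(
    matrices: Sequence[np.ndarray], y: np.ndarray, mode_label: str = ""
) -> FeatureMatrix:
    """Vectorize per-subject symmetric graphs into upper-triangle edge
    features with (mode, roi_i, roi_j) ids."""
    W0 = np.asarray(matrices[0])
    n = W0.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    X = np.stack([np.asarray(W)[iu, ju] for W in matrices])
    ids = [(mode_label, int(i), int(j)) for i, j in zip(iu, ju)]
    return FeatureMatrix(X=X, feature_ids=ids, y=np.asarray(y))


def multilayer_edge_feature_matrix(
    per_subject_layers: Sequence[Sequence], y: np.ndarray
) -> FeatureMatrix:
    """Concatenate the edge features of every layer (28 * N(N-1)/2)."""
    blocks = []
    ids: list = []
    n_layers = len(per_subject_layers[0])
    for li in range(n_layers):
        fm = edge_feature_matrix(
            [subj[li].W for subj in per_subject_layers],
            y,
            mode_label=per_subject_layers[0][li].mode.label,
        )
        blocks.append(fm.X)
        ids.extend(fm.feature_ids)
    return FeatureMatrix(X=np.hstack(blocks), feature_ids=ids, y=np.asarray(y))


@dataclass
class CVResult:
    scheme: str
    route: str
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_sd: float | None
    specificity_sd: float | None
    accuracy_sd: float | None
    consensus_features: list
    fold_rankings: list
    confusion: tuple[int, int, int, int]  # tp, fn, tn, fp
    y_true: np.ndarray
    y_pred: np.ndarray


def run_fold(
    features: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    route: Route,
    *,
    k_rank: int = 15,
    d1: int = 6,
    d2: int = 6,
    C: float = 1.0,
) -> tuple[list[int] | None, np.ndarray]:
    """Fit one fold (scaling + selection/extraction + SVM on the training
    subjects only) and predict the held-out subjects.

    Returns (selected feature indices or None for the tensor route,
    predicted labels). Held-out labels are never read.
    """
    ytr = y[train_idx]
    if np.unique(ytr).size < 2:
        raise ValueError("a class is absent from a training fold; resample folds")
    if route in ("edge", "mpc"):
        Xtr, Xte = features[train_idx], features[test_idx]
        scaler = StandardScaler().fit(Xtr)
        Xtr = scaler.transform(Xtr)
        Xte = scaler.transform(Xte)
        k = min(k_rank, Xtr.shape[1])
        sel = rank_features_mi(Xtr, ytr, k=k)
        clf = SVC(C=C, kernel="rbf", gamma="scale").fit(Xtr[:, sel], ytr)
        return sel, clf.predict(Xte[:, sel])
    if route == "tensor":
        proj = TSAProjector(d1=d1, d2=d2).fit(features[train_idx], ytr)
        Ftr = proj.transform(features[train_idx])
        Fte = proj.transform(features[test_idx])
        scaler = StandardScaler().fit(Ftr)
        clf = SVC(C=C, kernel="rbf", gamma="scale").fit(scaler.transform(Ftr), ytr)
        return None, clf.predict(scaler.transform(Fte))
    raise ValueError(f"unknown route {route!r}")


def crossvalidate(
    features: np.ndarray | FeatureMatrix,
    y: np.ndarray | None = None,
    scheme: Scheme = "5fold",
    route: Route = "edge",
    *,
    feature_ids: Sequence | None = None,
    k_rank: int = 15,
    m_consensus: int = 15,
    d1: int = 6,
    d2: int = 6,
    C: float = 1.0,
    seed: int = 0,
    positive_label: int = 2,
) -> CVResult:
    """Cross-validated SVM-RBF classification with in-fold selection.

    ``features`` is subjects x features for the edge and mpc routes or a
    subjects x N x N graph stack for the tensor route (a
    :class:`FeatureMatrix` carries its own labels and ids). LOOCV pools
    the confusion matrix; 5-fold (stratified, seeded) reports the mean
    and sd of per-fold metrics. Consensus feature identities are returned
    for the selection-based routes.
    """
    if isinstance(features, FeatureMatrix):
        feature_ids = features.feature_ids
        y = features.y
        features = features.X
    if y is None:
        raise ValueError("labels y are required")
    y = np.asarray(y)
    features = np.asarray(features, dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary classification requires exactly 2 classes")
    if min(np.bincount(np.searchsorted(classes, y))) < 2:
        raise ValueError("need >= 2 subjects per class")

    if scheme == "loocv":
        splitter = LeaveOneOut()
        splits = list(splitter.split(features, y))
    elif scheme == "5fold":
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        splits = list(splitter.split(features, y))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    y_pred = np.empty_like(y)
    fold_rankings: list = []
    fold_metrics: list[ClassMetrics] = []
    for train_idx, test_idx in splits:
        sel, pred = run_fold(
            features, y, train_idx, test_idx, route, k_rank=k_rank, d1=d1, d2=d2, C=C
        )
        y_pred[test_idx] = pred
        if sel is not None:
            ids = [feature_ids[s] if feature_ids is not None else s for s in sel]
            fold_rankings.append(ids)
        if scheme == "5fold":
            cm = _confusion(y[test_idx], pred, positive_label)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold_metrics.append(metrics(*cm))

    tp, fn, tn, fp = _confusion(y, y_pred, positive_label)
    pooled = metrics(tp, fn, tn, fp)
    consensus = consensus_features(fold_rankings, m_consensus) if fold_rankings else []

    if scheme == "loocv":
        sens, spec, acc = pooled.sensitivity, pooled.specificity, pooled.accuracy
        sds = (None, None, None)
    else:
        arr = np.array([[m.sensitivity, m.specificity, m.accuracy] for m in fold_metrics])
        sens, spec, acc = np.nanmean(arr, axis=0)
        sds = tuple(np.nanstd(arr, axis=0, ddof=1))
    return CVResult(
        scheme=scheme,
        route=route,
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float(acc),
        sensitivity_sd=sds[0],
        specificity_sd=sds[1],
        accuracy_sd=sds[2],
        consensus_features=consensus,
        fold_rankings=fold_rankings,
        confusion=(tp, fn, tn, fp),
        y_true=y,
        y_pred=y_pred,
    )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive_label) -> tuple[int, int, int, int]:
    pos = y_true == positive_label
    tp = int(np.sum(pos & (y_pred == positive_label)))
    fn = int(np.sum(pos & (y_pred != positive_label)))
    tn = int(np.sum(~pos & (y_pred != positive_label)))
    fp = int(np.sum(~pos & (y_pred == positive_label)))
    return tp, fn, tn, fp
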