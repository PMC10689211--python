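"""Injection-state decoding from session feature vectors.

Pipeline: session feature matrix -> per-feature z-scoring -> PCA ->
one-way ANOVA across states on each principal-component score ->
the k components with the smallest p-values feed a Gaussian (RBF) kernel
multi-class SVM (one-vs-one).  Reported accuracies come from
leave-one-session-out cross-validation; standardisation, PCA, component
selection and the SVM are re-fit on each training fold so no information
leaks from the held-out session (a single global PCA, closer to a
fit-once reading of the pipeline, is available behind ``global_pca=True``).

Pairwise contrasts: drug-vs-saline pools PCP and ketamine sessions into
one class; PCP-vs-ketamine restricts to those two states.  Cross-subject
transfer fits the full pipeline on one subject's sessions (including the
standardisation statistics) and applies it unchanged to the other.

Feature importance: each feature's weight is the Euclidean norm of its
loading entries across the selected components; the top-10 list mirrors
how feature relevance is ranked from PC loadings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f_oneway
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FEATURE_KEYS, SessionFeatures, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Assembled sessions-by-features matrix with labels."""

    X: np.ndarray
    feature_names: tuple
    states: np.ndarray
    subjects: np.ndarray
    session_ids: np.ndarray
    n_dropped: int = 0

    @property
    def n_sessions(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[mask], feature_names=self.feature_names,
            states=self.states[mask], subjects=self.subjects[mask],
            session_ids=self.session_ids[mask], n_dropped=self.n_dropped,
        )


@dataclass
class DecoderResult:
    class_labels: tuple
    confusion: np.ndarray  # rows = true class, cols = predicted
    accuracy: float
    pairwise: dict = field(default_factory=dict)
    selected_pcs: tuple = ()
    pc_pvalues: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None
    loadings: np.ndarray | None = None  # components x features
    top_features: list = field(default_factory=list)
    n_sessions: int = 0


def assemble(features: list[SessionFeatures]) -> FeatureMatrix:
    """Build the feature matrix; incomplete sessions are dropped (logged).

    Raises on duplicate session ids and on any state left with fewer than
    two complete sessions.
    """
    ids = [f.session_id for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate session_id in feature list")
    kept = [f for f in features if f.is_complete()]
    n_dropped = len(features) - len(kept)
    if n_dropped:
        logger.info("dropped %d incomplete session(s)", n_dropped)
    states = np.array([f.state for f in kept])
    for state in sorted(set(f.state for f in features)):
        if np.sum(states == state) < 2:
            raise InsufficientDataError(
                f"state {state!r} has fewer than 2 complete sessions"
            )
    X = np.array([[f.features[k] for k in FEATURE_KEYS] for f in kept])
    return FeatureMatrix(
        X=X,
        feature_names=tuple(FEATURE_KEYS),
        states=states,
        subjects=np.array([f.subject for f in kept]),
        session_ids=np.array([f.session_id for f in kept]),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# PCA + ANOVA selection


def _safe_scaler(X: np.ndarray) -> StandardScaler:
    scaler = StandardScaler().fit(X)
    scaler.scale_[scaler.scale_ == 0] = 1.0
    return scaler


def _fix_signs(pca: PCA) -> None:
    """Deterministic sign convention: the largest-|loading| entry of each
    component is made positive."""
    for i, comp in enumerate(pca.components_):
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            pca.components_[i] = -comp

def pca_transform(X: np.ndarray, standardize: bool = True):
    """(scores, loadings, explained variance ratio) of a feature matrix.

    Features are z-scored first by default (units are incommensurable:
    ms, deg, deg/s, deg^2 ...), making this a correlation-mode PCA.
    Components are ordered by decreasing variance with a deterministic
    sign convention; keeping all components reconstructs the standardized
    matrix to float precision.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    if standardize:
        X = _safe_scaler(X).transform(X)
    pca = PCA(svd_solver="full").fit(X)
    _fix_signs(pca)
    scores = X @ pca.components_.T
    return scores, pca.components_, pca.explained_variance_ratio_


def anova_select(scores: np.ndarray, labels: np.ndarray, k: int = 3):
    """Indices of the k PCs with smallest one-way-ANOVA p across states.

    Ties break toward the lower component index.  Components with no
    variance get p = 1.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    if k > scores.shape[1]:
        raise ValueError(f"k={k} exceeds number of components {scores.shape[1]}")
    classes = np.unique(labels)
    if len(classes) < 2 or any(np.sum(labels == c) < 2 for c in classes):
        raise InsufficientDataError("need >= 2 classes with >= 2 sessions each")
    if k == 0:
        return (), np.ones(scores.shape[1])
    groups = [scores[labels == c] for c in classes]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings -> p=nan
        p = f_oneway(*groups, axis=0).pvalue
    p = np.where(np.isfinite(p), p, 1.0)
    order = np.lexsort((np.arange(len(p)), p))
    return tuple(int(i) for i in order[:k]), p


# ---------------------------------------------------------------------------
# SVM decoding


def _make_svm(c: float = 1.0) -> SVC:
    # one-vs-one Gaussian-kernel SVM; gamma="scale" is the
    # 1/(n_features * variance) kernel-width analogue
    return SVC(C=c, kernel="rbf", gamma="scale", decision_function_shape="ovo")


def _fit_fold(X_train, y_train, k, svm_c):
    scaler = _safe_scaler(X_train)
    Xs = scaler.transform(X_train)
    pca = PCA(svd_solver="full").fit(Xs)
    _fix_signs(pca)
    scores = Xs @ pca.components_.T
    k_eff = min(k, scores.shape[1])
    sel, _ = anova_select(scores, y_train, k_eff)
    svm = _make_svm(svm_c).fit(scores[:, sel], y_train)
    return scaler, pca, sel, svm


def _predict_fold(model, X_test):
    scaler, pca, sel, svm = model
    scores = scaler.transform(np.atleast_2d(X_test)) @ pca.components_.T
    return svm.predict(scores[:, sel])


def _loocv_predictions(fm: FeatureMatrix, k: int, svm_c: float, global_pca: bool):
    y = fm.states
    preds = np.empty(fm.n_sessions, dtype=y.dtype)
    if global_pca:
        scaler = _safe_scaler(fm.X)
        pca = PCA(svd_solver="full").fit(scaler.transform(fm.X))
        _fix_signs(pca)
        all_scores = scaler.transform(fm.X) @ pca.components_.T
        sel, _ = anova_select(all_scores, y, min(k, all_scores.shape[1]))
    for i in range(fm.n_sessions):
        train = np.ones(fm.n_sessions, dtype=bool)
        train[i] = False
        if len(np.unique(y[train])) < len(np.unique(y)):
            warnings.warn(f"fold {i}: a class is absent from training, skipped")
            preds[i] = ""
            continue
        if global_pca:
            svm = _make_svm(svm_c).fit(all_scores[train][:, sel], y[train])
            preds[i] = svm.predict(all_scores[i : i + 1, sel])[0]
        else:
            model = _fit_fold(fm.X[train], y[train], k, svm_c)
            preds[i] = _predict_fold(model, fm.X[i])[0]
    return preds


def _confusion(y_true, y_pred, classes):
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        if p in index:
            mat[index[t], index[p]] += 1
    return mat


def loocv_accuracy(
    fm: FeatureMatrix, k: int = 3, svm_c: float = 1.0, global_pca: bool = False
) -> DecoderResult:
    """Leave-one-session-out decoding of the injection state.

    Every fold re-fits standardisation, PCA, ANOVA selection and the SVM
    on the training sessions only.  The result also carries the full-data
    PCA/selection/loadings (for reporting) and the two pairwise contrasts:
    drug (PCP+ketamine pooled) vs saline, and PCP vs ketamine.
    """
    if fm.n_sessions < 6:
        raise InsufficientDataError("need at least 6 sessions for LOOCV")
    classes = tuple(sorted(np.unique(fm.states)))
    preds = _loocv_predictions(fm, k, svm_c, global_pca)
    conf = _confusion(fm.states, preds, classes)
    acc = float(np.trace(conf) / conf.sum())

    pairwise = {}
    if set(classes) == {"saline", "pcp", "ketamine"}:
        pooled = FeatureMatrix(
            X=fm.X, feature_names=fm.feature_names,
            states=np.where(fm.states == "saline", "saline", "drug"),
            subjects=fm.subjects, session_ids=fm.session_ids,
        )
        p1 = _loocv_predictions(pooled, k, svm_c, global_pca)
        pairwise["drug_vs_saline"] = float(np.mean(p1 == pooled.states))
        two = fm.subset(np.isin(fm.states, ("pcp", "ketamine")))
        p2 = _loocv_predictions(two, k, svm_c, global_pca)
        pairwise["pcp_vs_ketamine"] = float(np.mean(p2 == two.states))

    scores, loadings, evr = pca_transform(fm.X)
    sel, pvals = anova_select(scores, fm.states, min(k, scores.shape[1]))
    top = rank_loadings(loadings, sel, fm.feature_names, n=10)
    return DecoderResult(
        class_labels=classes, confusion=conf, accuracy=acc, pairwise=pairwise,
        selected_pcs=sel, pc_pvalues=pvals, explained_variance_ratio=evr,
        loadings=loadings, top_features=top, n_sessions=fm.n_sessions,
    )


def cross_subject_accuracy(
    fm: FeatureMatrix,
    train_subject: str,
    k: int = 3,
    svm_c: float = 1.0,
    shared_space: bool = True,
) -> float:
    """Train on one subject's sessions, test on the other(s).

    With ``shared_space=True`` (default) the standardisation and PCA are
    fit on the pooled, unlabeled feature matrix of both subjects, so the
    inter-individual baseline variance collapses onto its own component;
    the supervised steps (ANOVA component selection and the SVM) see only
    the training subject's sessions and labels.  ``shared_space=False``
    fits everything, including the scaling statistics, on the training
    subject alone — a stricter transfer that large baseline offsets (e.g.
    the subjects' very different free-viewing amplitudes) can defeat.
    """
    subjects = np.unique(fm.subjects)
    if len(subjects) < 2:
        raise InsufficientDataError("cross-subject transfer needs two subjects")
    if train_subject not in subjects:
        raise ValueError(f"unknown subject {train_subject!r}")
    train = fm.subjects == train_subject
    for mask, side in ((train, "train"), (~train, "test")):
        if len(np.unique(fm.states[mask])) < len(np.unique(fm.states)):
            raise InsufficientDataError(f"{side} subject lacks some state")
    if shared_space:
        scaler = _safe_scaler(fm.X)
        pca = PCA(svd_solver="full").fit(scaler.transform(fm.X))
        _fix_signs(pca)
        scores = scaler.transform(fm.X) @ pca.components_.T
        sel, _ = anova_select(
            scores[train], fm.states[train], min(k, scores.shape[1])
        )
        svm = _make_svm(svm_c).fit(scores[train][:, sel], fm.states[train])
        preds = svm.predict(scores[~train][:, sel])
    else:
        model = _fit_fold(fm.X[train], fm.states[train], k, svm_c)
        preds = _predict_fold(model, fm.X[~train])
    return float(np.mean(preds == fm.states[~train]))


def rank_loadings(
    loadings: np.ndarray, selected: tuple, feature_names: tuple, n: int = 10
) -> list:
    """Top-n features by Euclidean norm of loadings on the selected PCs.

    Ties (including the all-zero degenerate case) break alphabetically.
    """
    loadings = np.atleast_2d(loadings)
    if n > len(feature_names):
        warnings.warn("n exceeds feature count; clipping")
        n = len(feature_names)
    if len(selected) == 0:
        weights = np.zeros(len(feature_names))
    else:
        weights = np.linalg.norm(loadings[list(selected), :], axis=0)
    order = sorted(
        range(len(feature_names)), key=lambda i: (-weights[i], feature_names[i])
    )
    return [(feature_names[i], float(weights[i])) for i in order[:n]]
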