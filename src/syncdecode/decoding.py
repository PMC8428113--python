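"""Decoders: cross-subject connectivity MVPA, within-subject power MVPA,
temporal-PCA decoding, encoding-to-maintenance generalization, and the
behavioral support-vector regression.

All classifiers are support vector machines (scikit-learn): a linear kernel
with cost C = 1 for the connectivity features, an RBF kernel with
gamma = 1 / (n_features * var(X)) (sklearn's ``gamma="scale"``) for power
and temporal patterns.  Multiclass handling is one-vs-one voting with ties
broken toward the lowest class index (sklearn's convention).  Features are
standardized with training-side statistics before every fit because C = 1
is scale-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

__all__ = [
    "DecoderSpec",
    "DecodingResult",
    "BehaviorPrediction",
    "cross_subject_decode",
    "power_pattern_decode",
    "temporal_pca_decode",
    "cross_phase_generalize",
    "behavioral_svr",
]

N_CLASSES = 6


@dataclass(frozen=True)
class DecoderSpec:
    """SVM configuration shared by all decoding analyses."""

    kernel: str = "linear"
    C: float = 1.0
    gamma: str = "scale"  # 1 / (n_features * var(X))
    split_scheme: str = "row"  # "row" (stratified rows) | "subject"
    train_fraction: float = 0.75
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.split_scheme not in ("row", "subject"):
            raise ValueError("split_scheme must be 'row' or 'subject'")

    def make_svc(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                   decision_function_shape="ovo")


@dataclass
class DecodingResult:
    """Mean accuracy over repeats/folds plus full bookkeeping."""

    accuracy: float
    per_repeat: np.ndarray
    confusion: np.ndarray  # summed over repeats, (n_classes, n_classes)
    n_train: int
    n_test: int
    test_id: tuple = ()

    def validate(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy out of [0, 1]")


def _fit_pipeline(spec: DecoderSpec):
    return make_pipeline(StandardScaler(), spec.make_svc())


def make_splits(
    X: np.ndarray,
    y: np.ndarray,
    spec: DecoderSpec,
    subjects: np.ndarray | None = None,
    n_splits: int | None = None,
) -> list:
    """Materialize the seeded train/test splits a decoder spec would use."""
    n = n_splits if n_splits is not None else spec.n_repeats
    if spec.split_scheme == "subject":
        if subjects is None:
            raise ValueError("subject-level splits need a subjects array")
        splitter = GroupShuffleSplit(
            n_splits=n, train_size=spec.train_fraction, random_state=spec.seed % (2**32)
        )
        return list(splitter.split(X, y, groups=subjects))
    splitter = StratifiedShuffleSplit(
        n_splits=n, train_size=spec.train_fraction, random_state=spec.seed % (2**32)
    )
    return list(splitter.split(X, y))


def accuracy_over_splits(
    X: np.ndarray,
    y: np.ndarray,
    splits: list,
    spec: DecoderSpec,
    train_labels: np.ndarray | None = None,
) -> float:
    """Mean held-out accuracy over pre-materialized splits (no confusion
    bookkeeping).  ``train_labels`` substitutes the training-side labels
    (permutation nulls); test labels stay true.  Standardization uses
    training-side statistics, matching the full decoder."""
    ysrc = train_labels if train_labels is not None else y
    accs = []
    for tr, te in splits:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = spec.make_svc()
        clf.fit((X[tr] - mu) / sd, ysrc[tr])
        accs.append(np.mean(clf.predict((X[te] - mu) / sd) == y[te]))
    return float(np.mean(accs))


def cross_subject_decode(
    X: np.ndarray,
    y: np.ndarray,
    spec: DecoderSpec,
    subjects: np.ndarray | None = None,
    test_id: tuple = (),
    permuted_train_labels: np.ndarray | None = None,
) -> DecodingResult:
    """Pooled cross-subject decoding with repeated 75/25 splits.

    Rows are subject x condition x subsample feature vectors from every
    subject merged together.  For each of ``n_repeats`` seeded splits a
    linear SVM is fit on the training side and scored on the held-out side;
    accuracy is averaged over repeats and the confusion matrices are summed.

    ``split_scheme="row"`` draws class-stratified row splits (the default:
    408 rows -> 306 train / 102 test); ``"subject"`` holds out whole
    subjects via group splits.  ``permuted_train_labels``, if given, replaces
    the *training-side* labels in every split (used to build permutation
    nulls); test labels stay true.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if spec.split_scheme == "subject":
        if subjects is None:
            raise ValueError("subject-level splits need a subjects array")
        splitter = GroupShuffleSplit(
            n_splits=spec.n_repeats, train_size=spec.train_fraction,
            random_state=spec.seed % (2**32),
        )
        split_iter = splitter.split(X, y, groups=subjects)
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=spec.n_repeats, train_size=spec.train_fraction,
            random_state=spec.seed % (2**32),
        )
        split_iter = splitter.split(X, y)

    y_train_source = permuted_train_labels if permuted_train_labels is not None else y
    accs = np.empty(spec.n_repeats)
    conf = np.zeros((classes.size, classes.size), dtype=int)
    n_train = n_test = 0
    for i, (tr, te) in enumerate(split_iter):
        ytr = y_train_source[tr]
        if np.unique(ytr).size < classes.size:
            # degenerate training side (possible under subject-level splits)
            accs[i] = np.nan
            continue
        model = _fit_pipeline(spec)
        model.fit(X[tr], ytr)
        pred = model.predict(X[te])
        accs[i] = np.mean(pred == y[te])
        conf += confusion_matrix(y[te], pred, labels=classes)
        n_train, n_test = tr.size, te.size
    result = DecodingResult(
        accuracy=float(np.nanmean(accs)),
        per_repeat=accs,
        confusion=conf,
        n_train=n_train,
        n_test=n_test,
        test_id=test_id,
    )
    result.validate()
    return result


def _subsample_folds(n_subsamples: int):
    """Each fold holds out one subsample per class."""
    return list(range(n_subsamples))


def power_pattern_decode(
    features: np.ndarray,
    spec: DecoderSpec | None = None,
    test_id: tuple = (),
    rng: np.random.Generator | None = None,
    permute_labels: bool = False,
) -> DecodingResult:
    """Within-subject power-pattern MVPA with leave-one-subsample-out CV.

    ``features`` has shape (n_subjects, n_classes, n_subsamples, H) where H
    is sub-ROIs x band bins.  Per subject, each of the 4 folds trains an RBF
    SVM on 3 subsamples of every class (18 rows for 6 classes) and tests on
    the held-out subsample (6 rows); fold accuracies are averaged within and
    then across subjects.
    """
    spec = spec or DecoderSpec(kernel="rbf")
    ns, nc, nq, H = features.shape
    per_subject = np.empty(ns)
    conf = np.zeros((nc, nc), dtype=int)
    labels = np.arange(nc)
    for s in range(ns):
        fold_accs = []
        for q in _subsample_folds(nq):
            train_mask = np.ones(nq, dtype=bool)
            train_mask[q] = False
            Xtr = features[s][:, train_mask].reshape(nc * (nq - 1), H)
            ytr = np.repeat(labels, nq - 1)
            if permute_labels:
                if rng is None:
                    raise ValueError("permute_labels requires an rng")
                ytr = rng.permutation(ytr)
            Xte = features[s][:, q].reshape(nc, H)
            yte = labels
            model = _fit_pipeline(spec)
            model.fit(Xtr, ytr)
            pred = model.predict(Xte)
            fold_accs.append(np.mean(pred == yte))
            conf += confusion_matrix(yte, pred, labels=labels)
        per_subject[s] = np.mean(fold_accs)
    result = DecodingResult(
        accuracy=float(per_subject.mean()),
        per_repeat=per_subject,
        confusion=conf,
        n_train=nc * (nq - 1),
        n_test=nc,
        test_id=test_id,
    )
    result.validate()
    return result


def temporal_pca_decode(
    epochs: np.ndarray,
    y: np.ndarray,
    sfreq: float,
    n_components: int = 100,
    folds: int = 10,
    spec: DecoderSpec | None = None,
    band: tuple[float, float] = (0.5, 12.0),
    test_id: tuple = (),
) -> DecodingResult:
    """Decode condition from single-trial time courses via temporal PCA.

    Trials are band-pass filtered (0.5-12 Hz), reduced to at most
    ``n_components`` principal components fit on the training folds only,
    and classified with an RBF SVM under stratified ``folds``-fold CV.
    """
    from scipy.signal import butter, sosfiltfilt

    spec = spec or DecoderSpec(kernel="rbf")
    X = np.asarray(epochs, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < folds:
        raise ValueError("fewer trials than folds")
    nyq = sfreq / 2.0
    sos = butter(4, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    Xf = sosfiltfilt(sos, X, axis=-1)

    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed % (2**32))
    accs = []
    conf = np.zeros((classes.size, classes.size), dtype=int)
    n_train = n_test = 0
    for tr, te in skf.split(Xf, y):
        ncomp = min(n_components, tr.size - 1, Xf.shape[1])
        pca = PCA(n_components=ncomp)
        Ztr = pca.fit_transform(Xf[tr])
        Zte = pca.transform(Xf[te])
        # no re-standardization of the PCs: gamma = 1/(H * var) sets the
        # kernel scale, and inflating low-variance components buries the
        # class structure
        model = spec.make_svc()
        model.fit(Ztr, y[tr])
        pred = model.predict(Zte)
        accs.append(np.mean(pred == y[te]))
        conf += confusion_matrix(y[te], pred, labels=classes)
        n_train, n_test = tr.size, te.size
    result = DecodingResult(
        accuracy=float(np.mean(accs)),
        per_repeat=np.asarray(accs),
        confusion=conf,
        n_train=n_train,
        n_test=n_test,
        test_id=test_id,
    )
    result.validate()
    return result


def cross_phase_generalize(
    encoding_features: np.ndarray,
    maintenance_features: np.ndarray,
    spec: DecoderSpec | None = None,
    test_id: tuple = (),
) -> DecodingResult:
    """Train on encoding connectivity patterns, test on maintenance ones.

    Both inputs have shape (n_subjects, n_classes, n_subsamples, T).  Per
    subject, fold q trains a linear SVM on the encoding rows of the other
    subsamples and tests on the maintenance rows of subsample q (4-fold,
    non-overlapping subsamples).  Above-chance accuracy indicates that the
    same connectivity code underlies encoding and maintenance.
    """
    if encoding_features.shape != maintenance_features.shape:
        raise ValueError("encoding and maintenance features must share row structure")
    spec = spec or DecoderSpec(kernel="linear")
    ns, nc, nq, T = encoding_features.shape
    labels = np.arange(nc)
    per_subject = np.empty(ns)
    conf = np.zeros((nc, nc), dtype=int)
    for s in range(ns):
        fold_accs = []
        for q in range(nq):
            train_mask = np.ones(nq, dtype=bool)
            train_mask[q] = False
            Xtr = encoding_features[s][:, train_mask].reshape(nc * (nq - 1), T)
            ytr = np.repeat(labels, nq - 1)
            Xte = maintenance_features[s][:, q].reshape(nc, T)
            model = _fit_pipeline(spec)
            model.fit(Xtr, ytr)
            pred = model.predict(Xte)
            fold_accs.append(np.mean(pred == labels))
            conf += confusion_matrix(labels, pred, labels=labels)
        per_subject[s] = np.mean(fold_accs)
    result = DecodingResult(
        accuracy=float(per_subject.mean()),
        per_repeat=per_subject,
        confusion=conf,
        n_train=nc * (nq - 1),
        n_test=nc,
        test_id=test_id,
    )
    result.validate()
    return result


@dataclass
class BehaviorPrediction:
    """Cross-validated SVR prediction of per-subject proportion correct."""

    rmse: float
    fold_rmse: np.ndarray
    n_components: list
    predictions: np.ndarray
    actual: np.ndarray
    test_id: tuple = ()


class SvrFoldCache:
    """Precomputed standardize-and-PCA fold projections for the SVR.

    The feature side of the cross-validation (training-fold standardization
    and PCA to ``pca_variance`` explained variance) depends only on the
    features, so it is computed once; permutation nulls then merely refit
    the SVR with shuffled training targets.
    """

    def __init__(
        self,
        features: np.ndarray,
        folds: int = 4,
        pca_variance: float = 0.95,
        C: float = 1.0,
        epsilon_scale: float = 0.1,
    ):
        X = np.asarray(features, dtype=float)
        ns, nq, T = X.shape
        if nq != folds:
            raise ValueError("one fold per subsample: folds must equal n_subsamples")
        self.n_subjects, self.n_subsamples = ns, nq
        self.C, self.epsilon_scale = C, epsilon_scale
        self.fold_data = []
        self.n_components: list[int] = []
        for q in range(folds):
            train_mask = np.ones(nq, dtype=bool)
            train_mask[q] = False
            Xtr = X[:, train_mask].reshape(ns * (nq - 1), T)
            scaler = StandardScaler().fit(Xtr)
            pca = PCA(n_components=pca_variance, svd_solver="full")
            Ztr = pca.fit_transform(scaler.transform(Xtr))
            Zte = pca.transform(scaler.transform(X[:, q]))
            self.fold_data.append((train_mask, Ztr, Zte))
            self.n_components.append(int(pca.n_components_))

    def predict(self, train_targets: np.ndarray) -> np.ndarray:
        """Held-out predictions (n_subjects, n_subsamples) given per-row
        training targets of shape (n_subjects, n_subsamples)."""
        ns, nq = self.n_subjects, self.n_subsamples
        preds = np.empty((ns, nq))
        for q, (train_mask, Ztr, Zte) in enumerate(self.fold_data):
            ytr = train_targets[:, train_mask].reshape(-1)
            sd = np.std(ytr)
            eps = self.epsilon_scale * (sd if sd > 0 else 1.0)
            svr = SVR(kernel="linear", C=self.C, epsilon=eps)
            svr.fit(Ztr, ytr)
            preds[:, q] = svr.predict(Zte)
        return preds

    def rmse(self, behavior: np.ndarray, permuted_behavior: np.ndarray | None = None) -> float:
        ytrue = np.repeat(np.asarray(behavior, float)[:, None], self.n_subsamples, axis=1)
        ysrc = permuted_behavior if permuted_behavior is not None else ytrue
        preds = self.predict(ysrc)
        return float(np.mean(np.sqrt(np.mean((preds - ytrue) ** 2, axis=0))))


def behavioral_svr(
    features: np.ndarray,
    behavior: np.ndarray,
    folds: int = 4,
    pca_variance: float = 0.95,
    C: float = 1.0,
    epsilon_scale: float = 0.1,
    test_id: tuple = (),
    permuted_behavior: np.ndarray | None = None,
) -> BehaviorPrediction:
    """Predict proportion correct from connectivity patterns with linear SVR.

    ``features`` has shape (n_subjects, n_subsamples, T); behavior is one
    value per subject in [0, 1], replicated across that subject's subsample
    rows.  Fold q holds out subsample q of every subject (17 test rows for
    17 subjects): the 51-row training block is standardized, reduced by PCA
    to the components explaining ``pca_variance`` of its variance, and fed
    to a linear SVR (C = 1, epsilon = ``epsilon_scale`` x SD of the training
    behavior).  Returns the RMSE averaged over the folds.

    ``permuted_behavior`` (n_subjects, n_subsamples), if given, replaces the
    training-side targets (permutation null); test targets stay true.
    """
    yb = np.asarray(behavior, dtype=float)
    if np.any((yb < 0) | (yb > 1)):
        raise ValueError("behavior must be proportions in [0, 1]")
    cache = SvrFoldCache(
        features, folds=folds, pca_variance=pca_variance, C=C,
        epsilon_scale=epsilon_scale,
    )
    ytrue = np.repeat(yb[:, None], cache.n_subsamples, axis=1)
    ysrc = permuted_behavior if permuted_behavior is not None else ytrue
    preds = cache.predict(ysrc)
    fold_rmse = np.sqrt(np.mean((preds - ytrue) ** 2, axis=0))
    return BehaviorPrediction(
        rmse=float(fold_rmse.mean()),
        fold_rmse=fold_rmse,
        n_components=cache.n_components,
        predictions=preds,
        actual=ytrue,
        test_id=test_id,
    )
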