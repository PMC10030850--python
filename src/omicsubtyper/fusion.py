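"""Two-level subgroup classifiers with decision-level fusion.

Level-0 base learners (RBF-kernel SVM, random forest, feed-forward network)
are trained on one feature set and emit class-probability matrices. Their
outputs are fused either linearly — P_L = alpha*P_SVM + beta*P_RF +
gamma*P_FFNN with the simplex weights found by grid search — or by a
stacked meta-learner (logistic regression or FFNN) trained on the
concatenated probabilities P_C, optionally with a 60/40 holdout so the
meta-learner never sees L0 training outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.svm import SVC

from .nn import MLP, one_hot
from .types import OmicMatrix

ROLES = ("P_SVM", "P_RF", "P_FFNN", "P_C", "P_L")


@dataclass
class ProbabilityMatrix:
    """samples x classes posterior matrix from a base or fused classifier."""

    sample_ids: list[str]
    classes: list[int]
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count mismatch")
        if self.role == "P_C":
            if self.values.shape[1] != 3 * len(self.classes):
                raise ValueError("P_C must have 3*K columns")
            return
        if self.values.shape[1] != len(self.classes):
            raise ValueError("column count must equal number of classes")
        if (self.values < -1e-12).any():
            raise ValueError("probabilities must be non-negative")
        sums = self.values.sum(axis=1)
        if np.abs(sums - 1).max() > 1e-9:
            raise ValueError("rows must sum to 1 within 1e-9")

    def predicted_labels(self) -> np.ndarray:
        """Row argmax as class labels; ties go to the lowest class index."""
        idx = np.argmax(self.values, axis=1)
        return np.array([self.classes[i] for i in idx])


@dataclass
class FusionWeights:
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        w = (self.alpha, self.beta, self.gamma)
        if any(v < -1e-12 for v in w):
            raise ValueError("weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass
class BaseLearnerSpec:
    """Hyperparameter search settings for one base-learner kind."""

    kind: str  # svm_rbf | random_forest | ffnn
    cv_folds: int = 5
    cv_repeats: int = 10
    svm_costs: tuple = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_factors: tuple = (0.1, 1.0, 10.0)  # multiples of the 'scale' heuristic
    rf_trees: tuple = (200, 500)
    rf_max_features: tuple = ("sqrt", "log2")
    ffnn_learning_rates: tuple = (0.1, 1e-2, 1e-3, 1e-4, 1e-5)
    ffnn_dropout: float = 0.1
    ffnn_activity_l2: float = 1e-4
    ffnn_weight_l1: float = 1e-5
    ffnn_epochs: int = 100
    ffnn_batch_size: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "random_forest", "ffnn"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if not self.ffnn_learning_rates or any(r <= 0 for r in self.ffnn_learning_rates):
            raise ValueError("learning rates must be positive and non-empty")


class FFNNClassifier:
    """One-hidden-layer softmax network with the regularization stack used
    throughout (dropout 0.1, L2 activity, L1 weight); hidden width is
    max(16, input/2) capped at 256. The learning rate is chosen from the
    grid by accuracy on an internal 10% stratified split."""

    def __init__(self, spec: BaseLearnerSpec):
        self.spec = spec
        self.classes_: np.ndarray | None = None
        self.model: MLP | None = None
        self.learning_rate_: float | None = None

    @staticmethod
    def _hidden_width(d: int) -> int:
        return min(256, max(16, d // 2))

    def _fit_once(self, x, y_idx, n_classes, lr, seed) -> MLP:
        s = self.spec
        model = MLP(
            widths=[x.shape[1], self._hidden_width(x.shape[1]), n_classes],
            output="softmax",
            dropout=s.ffnn_dropout,
            l1_weight=s.ffnn_weight_l1,
            l2_activity=s.ffnn_activity_l2,
        )
        rng = np.random.default_rng(seed)
        model.initialize(rng)
        target = one_hot(y_idx, n_classes)
        for _ in range(s.ffnn_epochs):
            model.train_epoch(x, target, s.ffnn_batch_size, lr, rng)
        return model

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        y_idx = np.searchsorted(self.classes_, y)
        n_classes = len(self.classes_)
        xt, xv, yt, yv = train_test_split(
            x, y_idx, test_size=0.1, stratify=y_idx, random_state=self.spec.seed
        )
        best_lr, best_acc = None, -1.0
        for lr in self.spec.ffnn_learning_rates:
            m = self._fit_once(xt, yt, n_classes, lr, self.spec.seed)
            acc = float((np.argmax(m.predict(xv), axis=1) == yv).mean())
            if acc > best_acc:
                best_lr, best_acc = lr, acc
        self.learning_rate_ = best_lr
        self.model = self._fit_once(x, y_idx, n_classes, best_lr, self.spec.seed)
        return self

    def predict_proba(self, x) -> np.ndarray:
        return self.model.predict(np.asarray(x, dtype=float))

    def predict(self, x) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(x), axis=1)]


def split_train_test(x: np.ndarray, y, test_fraction: float, seed: int):
    """Stratified split; every class keeps >= 1 test sample."""
    y = np.asarray(y)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        bad = classes[counts < 2]
        raise ValueError(f"classes with a single sample cannot be split: {bad.tolist()}")
    n_test = max(len(classes), int(round(len(y) * test_fraction)))
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=n_test, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def _cv_accuracy(make_model, x, y, folds, repeats, seed) -> float:
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    accs = []
    for tr, te in cv.split(x, y):
        model = make_model()
        model.fit(x[tr], y[tr])
        accs.append(float((model.predict(x[te]) == y[te]).mean()))
    return float(np.mean(accs))


def train_base(x: np.ndarray, y, spec: BaseLearnerSpec):
    """Fit one base learner; SVM/RF hyperparameters chosen by mean accuracy
    under repeated stratified CV (ties -> first grid entry)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")

    if spec.kind == "svm_rbf":
        scale = 1.0 / (x.shape[1] * x.var()) if x.var() > 0 else 1.0
        grid = [
            {"C": c, "gamma": scale * g}
            for c in spec.svm_costs
            for g in spec.svm_gamma_factors
        ]
        best, best_acc = None, -1.0
        for params in grid:
            acc = _cv_accuracy(
                lambda: SVC(kernel="rbf", random_state=spec.seed, **params),
                x, y, spec.cv_folds, spec.cv_repeats, spec.seed,
            )
            if acc > best_acc:
                best, best_acc = params, acc
        # sigmoid (Platt) calibration supplies class probabilities for the SVM
        _, counts = np.unique(y, return_counts=True)
        cal_cv = max(2, min(5, int(counts.min())))
        model = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=spec.seed, **best),
            method="sigmoid", cv=cal_cv, ensemble=False,
        )
        model.selected_params_ = best
        return model.fit(x, y)

    if spec.kind == "random_forest":
        grid = [
            {"n_estimators": t, "max_features": f}
            for t in spec.rf_trees
            for f in spec.rf_max_features
        ]
        best, best_acc = None, -1.0
        for params in grid:
            acc = _cv_accuracy(
                lambda: RandomForestClassifier(random_state=spec.seed, **params),
                x, y, spec.cv_folds, spec.cv_repeats, spec.seed,
            )
            if acc > best_acc:
                best, best_acc = params, acc
        model = RandomForestClassifier(random_state=spec.seed, **best)
        model.selected_params_ = best
        return model.fit(x, y)

    return FFNNClassifier(spec).fit(x, y)


def _proba_matrix(model, x, sample_ids, classes, role) -> ProbabilityMatrix:
    raw = model.predict_proba(np.asarray(x, dtype=float))
    # align model class order to the requested order
    model_classes = list(model.classes_)
    cols = [model_classes.index(c) for c in classes]
    return ProbabilityMatrix(
        sample_ids=list(sample_ids), classes=list(classes), values=raw[:, cols], role=role
    )


def linear_fuse(
    p_svm: ProbabilityMatrix,
    p_rf: ProbabilityMatrix,
    p_ffnn: ProbabilityMatrix,
    w: FusionWeights,
) -> ProbabilityMatrix:
    """Elementwise weighted sum of the three probability matrices."""
    _check_aligned(p_svm, p_rf, p_ffnn)
    fused = w.alpha * p_svm.values + w.beta * p_rf.values + w.gamma * p_ffnn.values
    return ProbabilityMatrix(
        sample_ids=list(p_svm.sample_ids),
        classes=list(p_svm.classes),
        values=fused,
        role="P_L",
    )


def _check_aligned(*ps: ProbabilityMatrix) -> None:
    ref = ps[0]
    for p in ps[1:]:
        if p.sample_ids != ref.sample_ids or p.classes != ref.classes:
            raise ValueError("probability matrices must share sample and class ordering")


def enumerate_weight_grid(step: float) -> list[FusionWeights]:
    """All non-negative multiples of ``step`` summing to 1, in lexicographic
    (alpha, beta, gamma) order. ``step`` must divide 1 evenly."""
    s = round(1.0 / step)
    if abs(s * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 evenly")
    grid = []
    for a, b in itertools.product(range(s + 1), repeat=2):
        c = s - a - b
        if c >= 0:
            grid.append(FusionWeights(a / s, b / s, c / s))
    return grid


def grid_search_weights(
    p_svm: ProbabilityMatrix,
    p_rf: ProbabilityMatrix,
    p_ffnn: ProbabilityMatrix,
    y,
    step: float = 0.05,
):
    """Exhaustive simplex grid search maximizing accuracy on ``y``; ties go
    to the first triple in lexicographic (alpha, beta, gamma) order."""
    _check_aligned(p_svm, p_rf, p_ffnn)
    y = np.asarray(y)
    best_w, best_acc = None, -1.0
    for w in enumerate_weight_grid(step):
        pred = linear_fuse(p_svm, p_rf, p_ffnn, w).predicted_labels()
        acc = float((pred == y).mean())
        if acc > best_acc:
            best_w, best_acc = w, acc
    return best_w, best_acc


def concat_probabilities(
    p_svm: ProbabilityMatrix, p_rf: ProbabilityMatrix, p_ffnn: ProbabilityMatrix
) -> ProbabilityMatrix:
    """Column-wise concatenation (SVM, RF, FFNN blocks) into P_C."""
    _check_aligned(p_svm, p_rf, p_ffnn)
    return ProbabilityMatrix(
        sample_ids=list(p_svm.sample_ids),
        classes=list(p_svm.classes),
        values=np.hstack([p_svm.values, p_rf.values, p_ffnn.values]),
        role="P_C",
    )


def evaluate_accuracy(pred, truth) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return float((pred == truth).mean())


def feature_level_fuse(blocks: list[OmicMatrix]):
    """Concatenate per-omic classifier feature sets over shared samples.

    Returns (sample_ids, matrix, column feature ids with omic prefixes).
    """
    if not blocks:
        raise ValueError("no blocks to fuse")
    common = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    if not common:
        raise ValueError("empty sample intersection")
    sample_ids = [s for s in blocks[0].sample_ids if s in common]
    mats, feat_ids = [], []
    for b in blocks:
        idx = [b.sample_ids.index(s) for s in sample_ids]
        mats.append(b.values[idx])
        feat_ids.extend(f"{b.kind.value}:{f}" for f in b.feature_ids)
    return sample_ids, np.hstack(mats), feat_ids


@dataclass
class FusedModel:
    """A trained L0 trio plus its decision-level fusion rule."""

    mode: str  # linear | stacked_lr | stacked_ffnn
    classes: list[int]
    svm: object
    rf: object
    ffnn: object
    weights: FusionWeights | None = None
    meta: object = None
    holdout: bool = False
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "stacked_lr", "stacked_ffnn"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")

    def base_probabilities(self, x, sample_ids=None):
        sample_ids = sample_ids or [f"s{i}" for i in range(len(x))]
        p_svm = _proba_matrix(self.svm, x, sample_ids, self.classes, "P_SVM")
        p_rf = _proba_matrix(self.rf, x, sample_ids, self.classes, "P_RF")
        p_ffnn = _proba_matrix(self.ffnn, x, sample_ids, self.classes, "P_FFNN")
        return p_svm, p_rf, p_ffnn

    def predict_proba(self, x, sample_ids=None) -> ProbabilityMatrix:
        p_svm, p_rf, p_ffnn = self.base_probabilities(x, sample_ids)
        if self.mode == "linear":
            return linear_fuse(p_svm, p_rf, p_ffnn, self.weights)
        p_c = concat_probabilities(p_svm, p_rf, p_ffnn)
        raw = self.meta.predict_proba(p_c.values)
        model_classes = list(self.meta.classes_)
        cols = [model_classes.index(c) for c in self.classes]
        return ProbabilityMatrix(
            sample_ids=list(p_c.sample_ids),
            classes=list(self.classes),
            values=raw[:, cols],
            role="P_L",
        )

    def predict(self, x, sample_ids=None) -> np.ndarray:
        return self.predict_proba(x, sample_ids).predicted_labels()


def _make_meta(learner: str, spec: BaseLearnerSpec, seed: int):
    if learner == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if learner == "ffnn":
        meta_spec = BaseLearnerSpec(kind="ffnn", seed=seed, **{
            k: getattr(spec, k) for k in (
                "ffnn_learning_rates", "ffnn_dropout", "ffnn_activity_l2",
                "ffnn_weight_l1", "ffnn_epochs", "ffnn_batch_size",
            )
        })
        return FFNNClassifier(meta_spec)
    raise ValueError(f"unknown meta learner {learner!r}")


def train_fused(
    x: np.ndarray,
    y,
    spec: BaseLearnerSpec,
    mode: str = "linear",
    holdout: bool = False,
    holdout_fractions: tuple[float, float] = (0.6, 0.4),
    weight_step: float = 0.05,
    seed: int = 0,
    feature_ids: list[str] | None = None,
) -> FusedModel:
    """Train the three L0 learners and the L1 fusion on one feature set.

    Without holdout, L0 and the fusion rule are fit on the same full training
    set; with holdout, L0 uses the first fraction and the fusion rule is fit
    on L0's probability outputs for the second. Both partitions must contain
    every class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())

    if holdout:
        f0, f1 = holdout_fractions
        if abs(f0 + f1 - 1.0) > 1e-9:
            raise ValueError("holdout fractions must sum to 1")
        idx0, idx1 = split_train_test(x, y, test_fraction=f1, seed=seed)
        x0, y0, x1, y1 = x[idx0], y[idx0], x[idx1], y[idx1]
        for part, name in ((y0, "L0"), (y1, "L1")):
            if sorted(np.unique(part).tolist()) != classes:
                raise ValueError(f"{name} partition is missing a class")
    else:
        x0, y0, x1, y1 = x, y, x, y

    def spec_for(kind):
        d = {k: getattr(spec, k) for k in spec.__dataclass_fields__ if k != "kind"}
        return BaseLearnerSpec(kind=kind, **d)

    svm = train_base(x0, y0, spec_for("svm_rbf"))
    rf = train_base(x0, y0, spec_for("random_forest"))
    ffnn = train_base(x0, y0, spec_for("ffnn"))

    ids1 = [f"s{i}" for i in range(len(x1))]
    p_svm = _proba_matrix(svm, x1, ids1, classes, "P_SVM")
    p_rf = _proba_matrix(rf, x1, ids1, classes, "P_RF")
    p_ffnn = _proba_matrix(ffnn, x1, ids1, classes, "P_FFNN")

    model = FusedModel(
        mode=mode, classes=classes, svm=svm, rf=rf, ffnn=ffnn, holdout=holdout,
        feature_ids=list(feature_ids) if feature_ids else [],
    )
    if mode == "linear":
        model.weights, _ = grid_search_weights(p_svm, p_rf, p_ffnn, y1, step=weight_step)
    else:
        learner = "logistic_regression" if mode == "stacked_lr" else "ffnn"
        p_c = concat_probabilities(p_svm, p_rf, p_ffnn)
        model.meta = _make_meta(learner, spec, seed).fit(p_c.values, y1)
    return model


@dataclass
class ModelVariant:
    """One trained fused model plus the preprocessing schema it expects."""

    name: str
    omic_kinds: list
    feature_ids: dict  # kind -> ordered feature ids
    minmax: dict  # kind -> MinMaxStats or None
    model: FusedModel


class ModelBundle:
    """Trained variants keyed by feature schema, with single-omic routing."""

    def __init__(self):
        self.variants: dict[str, ModelVariant] = {}

    def add(self, variant: ModelVariant) -> None:
        self.variants[variant.name] = variant

    def _assemble(self, variant: ModelVariant, omics: dict) -> tuple[np.ndarray, list[str]]:
        blocks = None
        sample_ids = None
        cols = []
        for kind in variant.omic_kinds:
            m = omics[kind]
            missing = [f for f in variant.feature_ids[kind] if f not in m.feature_ids]
            if missing:
                raise ValueError(
                    f"schema mismatch for {variant.name}: sample matrix lacks "
                    f"features {missing[:5]}"
                )
            fidx = [m.feature_ids.index(f) for f in variant.feature_ids[kind]]
            vals = m.values[:, fidx]
            stats = variant.minmax.get(kind)
            if stats is not None:
                vals = stats.transform(vals)
            if sample_ids is None:
                sample_ids = list(m.sample_ids)
            elif list(m.sample_ids) != sample_ids:
                raise ValueError("omic matrices must share sample ordering")
            cols.append(vals)
        return np.hstack(cols), sample_ids

    def predict_new(self, omics: dict):
        """Predict labels for new samples from whichever omics are available.

        ``omics`` maps OmicKind -> OmicMatrix. The variant whose schema is
        covered by the provided omics and uses the most of them wins;
        no match -> error listing the trained schemas.
        """
        usable = [
            v for v in self.variants.values() if set(v.omic_kinds).issubset(omics.keys())
        ]
        if not usable:
            schemas = {
                name: [k.value for k in v.omic_kinds] for name, v in self.variants.items()
            }
            raise ValueError(f"no trained variant matches available omics; trained: {schemas}")
        variant = max(usable, key=lambda v: len(v.omic_kinds))
        x, sample_ids = self._assemble(variant, omics)
        proba = variant.model.predict_proba(x, sample_ids)
        return proba.predicted_labels(), proba
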