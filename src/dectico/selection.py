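"""Dynamic feature selection over a descending ladder with SVM training.

The core recursion: starting from the full feature set S_0, each round k
re-fits kernel PLS on the matrix restricted to the surviving features
S_{k-1}, re-estimates per-feature weights, keeps the top n_k features
(S_k), trains an SVM on the restricted matrix, and records its
leave-one-out cross-validation accuracy a_k.  The optimal classifier is
the round with maximal a_k; ties go to the smaller feature set.  The
non-dynamic ("static") baseline ranks features once, on the full matrix,
and merely truncates that single ranking at every rung.

Feature selection is performed on the full training set; LOOCV evaluates
classifier training only, so the recorded accuracies carry the usual
selection optimism and should be read as in-sample model-selection
scores, not unbiased generalization estimates.  A nested variant
(selection re-run inside every LOOCV fold) is available via
``loocv_nested=True`` for honest error estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.svm import SVC

from .features import FeatureMatrix, build_feature_matrix
from .kpls import KernelSpec, feature_weights, fit_kpls, select_top
from .seq_io import SampleManifest, read_manifest

__all__ = [
    "SelectionLadder",
    "ClassifierSpec",
    "SelectionRound",
    "SelectionResult",
    "DectICO",
    "DectICOResults",
    "FinalModel",
    "loocv_accuracy",
    "dectico_select",
    "static_select",
    "pick_optimal",
    "train_final",
    "default_ladder",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionLadder:
    """Strictly descending feature-set sizes n_0 > n_1 > ... > n_N.

    n_0 must equal the full feature dimension of the matrix being
    selected from; the remaining sizes drive the recursion rounds.
    """

    sizes: tuple[int, ...]

    def __post_init__(self):
        if not self.sizes:
            raise ValueError("ladder must contain at least one size")
        if any(s < 1 for s in self.sizes):
            raise ValueError("ladder sizes must be positive")
        if any(a <= b for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError(f"ladder must be strictly descending, got {self.sizes}")

    def __len__(self) -> int:
        return len(self.sizes)


def default_ladder(n_features: int) -> SelectionLadder:
    """Geometric halving from the full dimension down to max(10, n_0/2^10)."""
    floor = max(10, n_features // 2 ** 10)
    sizes = [n_features]
    while sizes[-1] // 2 >= floor and sizes[-1] // 2 < sizes[-1]:
        sizes.append(sizes[-1] // 2)
    return SelectionLadder(tuple(sizes))


@dataclass(frozen=True)
class ClassifierSpec:
    """SVM configuration: kernel, regularization C, and kernel width."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: Union[float, str] = "scale"

    def __post_init__(self):
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"SVM kernel must be 'rbf' or 'linear', got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")

    def make(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)


@dataclass
class SelectionRound:
    """One rung of the ladder: the surviving feature set, its LOOCV
    accuracy, and the classifier trained on it."""

    k: int
    selected: list[str]
    accuracy: float
    classifier: Optional[SVC] = None

    @property
    def n_features(self) -> int:
        return len(self.selected)


def _fit_svm_fold(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Fit an SVM on one training fold; a single-class fold degenerates
    to majority-class prediction (logged, not an error)."""
    classes = np.unique(y)
    if classes.size < 2:
        majority = classes[0]
        logger.warning("training fold contains one class; predicting %d", majority)
        return ("majority", int(majority))
    clf = spec.make()
    clf.fit(X, y)
    return ("svm", clf)


def loocv_accuracy(F: FeatureMatrix, spec: ClassifierSpec) -> float:
    """Leave-one-out cross-validation accuracy of an SVM on F.

    Each sample is predicted by a classifier trained on the other N-1;
    deterministic for fixed inputs.
    """
    if F.labels is None:
        raise ValueError("LOOCV requires labels")
    X, y = F.values, F.labels
    N = X.shape[0]
    if N < 2:
        raise ValueError("LOOCV requires at least 2 samples")
    correct = 0
    idx = np.arange(N)
    for i in range(N):
        mask = idx != i
        kind, model = _fit_svm_fold(X[mask], y[mask], spec)
        if kind == "majority":
            pred = model
        else:
            pred = int(model.predict(X[i : i + 1])[0])
        correct += int(pred == y[i])
    return correct / N


@dataclass
class FinalModel:
    """A trained SVM plus everything needed to featurize new samples
    identically: feature names in order, extraction settings, and the
    raw support data for exact JSON round-trips."""

    feature_names: list[str]
    svm_spec: ClassifierSpec
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma_value: float
    classes: tuple[int, int]  # (negative, positive) as stored by libsvm
    extraction: dict = field(default_factory=dict)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {X.shape[1]}"
            )
        if self.svm_spec.kernel == "linear":
            K = X @ self.support_vectors.T
        else:
            sq = (
                (X ** 2).sum(1)[:, None]
                - 2 * X @ self.support_vectors.T
                + (self.support_vectors ** 2).sum(1)[None, :]
            )
            K = np.exp(-self.gamma_value * np.maximum(sq, 0))
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        neg, pos = self.classes
        return np.where(d > 0, pos, neg).astype(np.int64)

    def to_dict(self) -> dict:
        return {
            "schema": "dectico-model-v1",
            "feature_names": self.feature_names,
            "svm": {
                "kernel": self.svm_spec.kernel,
                "C": self.svm_spec.C,
                "gamma": self.svm_spec.gamma,
                "gamma_value": self.gamma_value,
                "support_vectors": self.support_vectors,
                "dual_coef": self.dual_coef,
                "intercept": self.intercept,
                "classes": list(self.classes),
            },
            "extraction": self.extraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FinalModel":
        svm = d["svm"]
        return cls(
            feature_names=list(d["feature_names"]),
            svm_spec=ClassifierSpec(
                kernel=svm["kernel"], C=svm["C"], gamma=svm["gamma"]
            ),
            support_vectors=np.asarray(svm["support_vectors"], dtype=np.float64),
            dual_coef=np.asarray(svm["dual_coef"], dtype=np.float64),
            intercept=float(svm["intercept"]),
            gamma_value=float(svm["gamma_value"]),
            classes=tuple(int(c) for c in svm["classes"]),
            extraction=dict(d.get("extraction", {})),
        )


def train_final(
    F: FeatureMatrix, spec: ClassifierSpec, extraction: Optional[dict] = None
) -> FinalModel:
    """Train the final SVM on a (restricted) feature matrix and package it
    with the feature list and extraction settings for prediction."""
    if F.labels is None or np.unique(F.labels).size < 2:
        raise ValueError("final training requires both classes present")
    clf = spec.make()
    clf.fit(F.values, F.labels)
    gamma_value = clf._gamma if spec.kernel == "rbf" else 0.0
    return FinalModel(
        feature_names=list(F.feature_names),
        svm_spec=spec,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        gamma_value=float(gamma_value),
        classes=(int(clf.classes_[0]), int(clf.classes_[1])),
        extraction=dict(extraction or {}),
    )


def pick_optimal(rounds: Sequence[SelectionRound]) -> int:
    """Index of the optimal round: maximal LOOCV accuracy; among ties,
    the minimal number of feature components."""
    if not rounds:
        raise ValueError("no rounds to pick from")
    return max(
        range(len(rounds)),
        key=lambda i: (rounds[i].accuracy, -rounds[i].n_features),
    )


class DectICO:
    """Dynamic feature-selection classifier over a descending ladder.

    Parameters
    ----------
    feature_matrix
        Labeled samples x features matrix (labels in {+1, -1}).
    ladder
        Descending feature-set sizes; ``sizes[0]`` must equal the full
        feature dimension.  Defaults to geometric halving.
    mode
        ``"dynamic"`` (re-rank on the surviving set every round) or
        ``"static"`` (rank once on the full matrix).
    classifier, kernel, n_components
        SVM spec, KPLS kernel spec, and number of KPLS components
        (default ``min(5, N-1)``).

    Examples
    --------
    >>> model = DectICO(fm, ladder=SelectionLadder((852, 100, 20)))
    >>> res = model.fit()
    >>> res.optimal_round.accuracy
    """

    def __init__(
        self,
        feature_matrix: FeatureMatrix,
        ladder: Optional[SelectionLadder] = None,
        mode: str = "dynamic",
        classifier: Optional[ClassifierSpec] = None,
        kernel: Optional[KernelSpec] = None,
        n_components: Optional[int] = None,
        extraction: Optional[dict] = None,
    ):
        if feature_matrix.labels is None:
            raise ValueError("DectICO requires a labeled feature matrix")
        if np.unique(feature_matrix.labels).size < 2:
            raise ValueError("both classes must be present")
        if mode not in ("dynamic", "static"):
            raise ValueError(f"mode must be 'dynamic' or 'static', got {mode!r}")
        if ladder is None:
            ladder = default_ladder(feature_matrix.n_features)
        if isinstance(ladder, (tuple, list)):
            ladder = SelectionLadder(tuple(ladder))
        if ladder.sizes[0] != feature_matrix.n_features:
            raise ValueError(
                f"ladder head {ladder.sizes[0]} must equal the feature dimension "
                f"{feature_matrix.n_features}"
            )
        self.feature_matrix = feature_matrix
        self.ladder = ladder
        self.mode = mode
        self.classifier = classifier or ClassifierSpec()
        self.kernel = kernel or KernelSpec()
        self.n_components = n_components
        self.extraction = dict(extraction or {})

    @classmethod
    def from_manifest(
        cls,
        manifest: Union[str, SampleManifest],
        k: int,
        feature: str = "ico",
        normalize: bool = True,
        pseudocount: float = 0.0,
        positive_label: Optional[str] = None,
        **kwargs,
    ) -> "DectICO":
        """Build the model directly from a labeled sample manifest,
        extracting the feature matrix with the given settings."""
        if not isinstance(manifest, SampleManifest):
            manifest = read_manifest(manifest)
        fm = build_feature_matrix(
            manifest,
            k=k,
            feature=feature,
            normalize=normalize,
            pseudocount=pseudocount,
            positive_label=positive_label,
        )
        extraction = {
            "k": k,
            "feature": feature,
            "normalize": normalize,
            "pseudocount": pseudocount,
            "positive_label": positive_label,
        }
        return cls(fm, extraction=extraction, **kwargs)

    def fit(self) -> "DectICOResults":
        """Run the selection recursion and return the fitted results."""
        F0 = self.feature_matrix
        rounds: list[SelectionRound] = []

        a0 = loocv_accuracy(F0, self.classifier)
        rounds.append(
            SelectionRound(k=0, selected=list(F0.feature_names), accuracy=a0)
        )

        if self.mode == "static":
            model0 = fit_kpls(F0, self.n_components, self.kernel)
            global_weights = feature_weights(model0, F0)

        current = F0
        for k, n_k in enumerate(self.ladder.sizes[1:], start=1):
            if self.mode == "dynamic":
                kmod = fit_kpls(current, self.n_components, self.kernel)
                w = feature_weights(kmod, current)
                S_k = select_top(w, n_k)
            else:
                S_k = select_top(global_weights, n_k)
            current = F0.restrict(S_k)
            a_k = loocv_accuracy(current, self.classifier)
            rounds.append(SelectionRound(k=k, selected=S_k, accuracy=a_k))
            logger.info("round %d: n=%d LOOCV accuracy %.4f", k, n_k, a_k)

        opt = pick_optimal(rounds)
        F_opt = F0.restrict(rounds[opt].selected)
        final = train_final(F_opt, self.classifier, extraction=self.extraction)
        return DectICOResults(
            model=self,
            rounds=rounds,
            optimal_round_index=opt,
            final_model=final,
        )


@dataclass
class DectICOResults:
    """Fitted selection results: per-round feature sets and LOOCV
    accuracies, the optimal round, and the final trained classifier."""

    model: DectICO
    rounds: list[SelectionRound]
    optimal_round_index: int
    final_model: FinalModel

    @property
    def mode(self) -> str:
        return self.model.mode

    @property
    def optimal_round(self) -> SelectionRound:
        return self.rounds[self.optimal_round_index]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.rounds])

    @property
    def best_accuracy(self) -> float:
        return self.optimal_round.accuracy

    def summary(self) -> str:
        lines = [
            "DectICO selection results",
            "=" * 48,
            f"mode:            {self.mode}",
            f"samples:         {self.model.feature_matrix.n_samples}",
            f"full dimension:  {self.model.feature_matrix.n_features}",
            f"ladder:          {' > '.join(str(s) for s in self.model.ladder.sizes)}",
            "-" * 48,
            f"{'round':>5} {'n_features':>10} {'LOOCV acc':>10}",
        ]
        for i, r in enumerate(self.rounds):
            mark = "  <- optimal" if i == self.optimal_round_index else ""
            lines.append(f"{r.k:>5} {r.n_features:>10} {r.accuracy:>10.4f}{mark}")
        lines.append("=" * 48)
        return "\n".join(lines)

    def predict(self, data) -> "np.ndarray":
        """Predict {+1,-1} labels for a FeatureMatrix or raw array whose
        columns cover the optimal round's selected features."""
        if isinstance(data, FeatureMatrix):
            data = data.restrict(self.final_model.feature_names).values
        return self.final_model.predict(np.asarray(data, dtype=np.float64))

    def predict_manifest(self, manifest: Union[str, SampleManifest]):
        """Featurize unlabeled samples with the stored extraction settings
        and classify them; returns (sample_ids, labels, decision values)."""
        from .features import build_feature_matrix

        if not isinstance(manifest, SampleManifest):
            manifest = read_manifest(manifest)
        ext = self.final_model.extraction
        if not ext:
            raise ValueError(
                "results carry no extraction settings; predict from a "
                "FeatureMatrix instead"
            )
        if len(manifest) == 0:
            return [], np.zeros(0, dtype=np.int64), np.zeros(0)
        fm = build_feature_matrix(
            manifest,
            k=ext["k"],
            feature=ext["feature"],
            normalize=ext["normalize"],
            pseudocount=ext.get("pseudocount", 0.0),
        )
        X = fm.restrict(self.final_model.feature_names).values
        return (
            fm.sample_ids,
            self.final_model.predict(X),
            self.final_model.decision_function(X),
        )


# --- functional wrappers (tool-style surface over the model objects) --------


def dectico_select(
    F0: FeatureMatrix,
    ladder: SelectionLadder,
    cls: Optional[ClassifierSpec] = None,
    kspec: Optional[KernelSpec] = None,
    n_components: Optional[int] = None,
) -> DectICOResults:
    """Dynamic ladder selection; see :class:`DectICO`."""
    return DectICO(
        F0, ladder=ladder, mode="dynamic", classifier=cls, kernel=kspec,
        n_components=n_components,
    ).fit()


def static_select(
    F0: FeatureMatrix,
    ladder: SelectionLadder,
    cls: Optional[ClassifierSpec] = None,
    kspec: Optional[KernelSpec] = None,
    n_components: Optional[int] = None,
) -> DectICOResults:
    """Non-dynamic baseline: one ranking, truncated at every rung."""
    return DectICO(
        F0, ladder=ladder, mode="static", classifier=cls, kernel=kspec,
        n_components=n_components,
    ).fit()


SelectionResult = DectICOResults
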