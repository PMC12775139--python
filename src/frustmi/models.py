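"""Frustration-state and motor-imagery classifier bank.

Each classifier is an FBCSP transform followed by either an RBF-kernel SVM
(probabilities via Platt scaling) or a shrinkage-regularized LDA; the backend
is chosen per classifier by an inner stratified 5-fold comparison on the
training data only (``backend="auto"``), mirroring per-subject calibration.

The bank holds the 3-class frustration decoder plus four MI decoders: one per
frustration state (M_low, M_mid, M_high), one pooled over all induced-state
data (the state-agnostic baseline) and one trained only on calibration-stage
data recorded before any state induction.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .fbcsp import CSPBankModel, FilterBankSpec, band_window_covariances, fit_fbcsp, transform
from .preprocess import WindowSet

__all__ = [
    "ModelConfig",
    "PipelineClassifier",
    "ClassifierBank",
    "select_backend",
    "train_state_classifier",
    "train_mi_bank",
]

STATE_ORDER = ["low", "mid", "high"]
MI_ORDER = ["left", "right"]


@dataclass(frozen=True)
class ModelConfig:
    """Configuration shared by all classifiers in a bank.

    ``seed`` is required; every stochastic step (backend selection folds,
    SVM probability calibration, pooled-data subsampling) derives from it.
    """

    seed: int
    backend: str = "auto"  # "auto" | "svm" | "lda"
    svm_c: float = 1.0
    n_pairs: int = 2
    k_select: int = 4
    bank: FilterBankSpec = field(default_factory=FilterBankSpec)
    pool_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.backend not in ("auto", "svm", "lda"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if not (0 < self.pool_fraction <= 1):
            raise ValueError("pool_fraction must be in (0, 1]")


class PlattSVM:
    """RBF-kernel SVM with sigmoid (Platt) probability calibration.

    Calibration folds adapt to the smallest class so tiny strata stay
    trainable; pairwise coupling handles the 3-class case.
    """

    def __init__(self, c: float, seed: int):
        self.c = c
        self.seed = seed
        self._model = None

    def fit(self, x, y):
        counts = np.bincount(np.unique(y, return_inverse=True)[1])
        cv = int(min(5, counts.min()))
        if cv < 2:
            raise ValueError("PlattSVM needs at least 2 samples per class")
        svc = SVC(C=self.c, kernel="rbf", gamma="scale", random_state=self.seed)
        self._model = CalibratedClassifierCV(svc, method="sigmoid", cv=cv, ensemble=False)
        self._model.fit(x, y)
        return self

    @property
    def classes_(self):
        return self._model.classes_

    def predict_proba(self, x):
        return self._model.predict_proba(x)

    def predict(self, x):
        return self._model.predict(x)


def _make_backend(tag: str, cfg: ModelConfig):
    if tag == "svm":
        return PlattSVM(cfg.svm_c, cfg.seed)
    if tag == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    raise ValueError(f"unknown backend {tag!r}")


def select_backend(features: np.ndarray, labels: np.ndarray, cfg: ModelConfig) -> str:
    """Choose SVM or LDA by inner stratified 5-fold accuracy; ties go to SVM.

    Operates on the training data only — never on held-out windows.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("backend selection needs at least two classes")
    n_splits = min(5, np.bincount(np.unique(labels, return_inverse=True)[1]).min())
    if n_splits < 2:
        raise ValueError("too few samples per class for backend selection")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
    scores = {}
    for tag in ("svm", "lda"):
        accs = []
        for tr, te in skf.split(features, labels):
            clf = _make_backend(tag, cfg)
            clf.fit(features[tr], labels[tr])
            accs.append(np.mean(clf.predict(features[te]) == labels[te]))
        scores[tag] = np.mean(accs)
    return "svm" if scores["svm"] >= scores["lda"] else "lda"


@dataclass
class PipelineClassifier:
    """A fitted FBCSP transform plus probability-calibrated backend."""

    csp: CSPBankModel
    clf: object
    backend: str
    classes: list[str]

    def predict_proba(
        self, windows: np.ndarray | None = None, covs: np.ndarray | None = None
    ) -> np.ndarray:
        """Class probabilities, columns in ``self.classes`` order; every row
        is a valid distribution."""
        feats = transform(self.csp, windows, covs=covs)
        raw = self.clf.predict_proba(feats)
        cols = [list(self.clf.classes_).index(c) for c in self.classes]
        proba = raw[:, cols]
        return proba / proba.sum(axis=1, keepdims=True)

    def predict(self, windows: np.ndarray | None = None, covs: np.ndarray | None = None) -> np.ndarray:
        proba = self.predict_proba(windows, covs=covs)
        return np.asarray(self.classes, dtype=object)[np.argmax(proba, axis=1)]


def _fit_pipeline(
    windows: np.ndarray | None,
    labels: np.ndarray,
    cfg: ModelConfig,
    rate: float,
    classes: list[str],
    covs: np.ndarray | None = None,
) -> PipelineClassifier:
    csp = fit_fbcsp(
        windows,
        labels,
        bank=cfg.bank,
        n_pairs=cfg.n_pairs,
        k_select=cfg.k_select,
        rate=rate,
        classes=classes,
        covs=covs,
    )
    feats = transform(csp, windows, covs=covs)
    tag = cfg.backend if cfg.backend != "auto" else select_backend(feats, labels, cfg)
    clf = _make_backend(tag, cfg)
    clf.fit(feats, labels)
    return PipelineClassifier(csp=csp, clf=clf, backend=tag, classes=classes)


def train_state_classifier(
    windows: WindowSet,
    cfg: ModelConfig,
    covs: np.ndarray | None = None,
) -> PipelineClassifier:
    """Train the 3-class frustration-state decoder on induced-state windows.

    Raises if any of low/mid/high is absent from the labels.
    """
    labels = np.asarray(windows.state_label)
    missing = [s for s in STATE_ORDER if s not in set(labels)]
    if missing:
        raise ValueError(f"state classifier training data lacks labels {missing}")
    return _fit_pipeline(windows.windows, labels, cfg, windows.rate, STATE_ORDER, covs=covs)


@dataclass
class ClassifierBank:
    """The full decoder bank used by the fusion strategies."""

    state_clf: PipelineClassifier
    mi_by_state: dict[str, PipelineClassifier]  # keys: low / mid / high
    mi_all: PipelineClassifier  # pooled induced-state data (baseline 3-1)
    mi_calibration: PipelineClassifier | None = None  # calibration-only (baseline 3-2)

    def mi_models(self) -> list[PipelineClassifier]:
        """State-specific MI models indexed 0 (low), 1 (mid), 2 (high)."""
        return [self.mi_by_state[s] for s in STATE_ORDER]

    def save(self, path) -> None:
        """Serialize into the internal bundle (pickle payload in HDF5)."""
        payload = np.frombuffer(pickle.dumps(self), dtype=np.uint8)
        with h5py.File(path, "w") as f:
            f.create_dataset("classifier_bank_pickle", data=payload)

    @classmethod
    def load(cls, path) -> "ClassifierBank":
        """Reload a bank written by :meth:`save` (trusted files only)."""
        with h5py.File(path, "r") as f:
            payload = f["classifier_bank_pickle"][()]
        bank = pickle.loads(payload.tobytes())
        if not isinstance(bank, cls):
            raise TypeError("bundle does not contain a ClassifierBank")
        return bank


def train_mi_bank(
    stage2_windows: WindowSet,
    cfg: ModelConfig,
    stage1_windows: WindowSet | None = None,
    covs2: np.ndarray | None = None,
    covs1: np.ndarray | None = None,
) -> ClassifierBank:
    """Train the state decoder and the MI classifier bank.

    Each state-specific MI model sees only windows of its own state; the
    pooled model sees all induced-state windows (optionally subsampled at
    ``cfg.pool_fraction``); the calibration model, when stage-1 windows are
    given, sees only those.
    """
    rate = stage2_windows.rate
    if covs2 is None:
        covs2 = band_window_covariances(stage2_windows.windows, cfg.bank, rate)
    states = np.asarray(stage2_windows.state_label)
    mi = np.asarray(stage2_windows.mi_label)

    state_clf = train_state_classifier(stage2_windows, cfg, covs=covs2)

    mi_by_state: dict[str, PipelineClassifier] = {}
    for s in STATE_ORDER:
        mask = states == s
        present = set(mi[mask])
        if set(MI_ORDER) - present:
            raise ValueError(
                f"state stratum {s!r} lacks MI classes {sorted(set(MI_ORDER) - present)}"
            )
        mi_by_state[s] = _fit_pipeline(
            None, mi[mask], cfg, rate, MI_ORDER, covs=covs2[mask]
        )

    idx = np.arange(len(stage2_windows))
    if cfg.pool_fraction < 1.0:
        rng = np.random.default_rng(cfg.seed)
        keep = max(2, int(round(cfg.pool_fraction * len(idx))))
        idx = np.sort(rng.choice(idx, size=keep, replace=False))
    mi_all = _fit_pipeline(None, mi[idx], cfg, rate, MI_ORDER, covs=covs2[idx])

    mi_calibration = None
    if stage1_windows is not None and len(stage1_windows):
        if covs1 is None:
            covs1 = band_window_covariances(stage1_windows.windows, cfg.bank, rate)
        mi_calibration = _fit_pipeline(
            None, np.asarray(stage1_windows.mi_label), cfg, rate, MI_ORDER, covs=covs1
        )

    return ClassifierBank(
        state_clf=state_clf,
        mi_by_state=mi_by_state,
        mi_all=mi_all,
        mi_calibration=mi_calibration,
    )
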