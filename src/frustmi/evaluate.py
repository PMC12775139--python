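"""Evaluation: leakage-guarded cross-validation, classification metrics,
band-wise spectral statistics, cohort aggregation and the per-subject
experiment driver.

The central discipline is the leakage guard: folds are stratified partitions
of *trials*, never of windows, so heavily overlapping sliding windows from
one trial can never straddle the train/test boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .fbcsp import band_window_covariances
from .models import (
    MI_ORDER,
    STATE_ORDER,
    ClassifierBank,
    ModelConfig,
    PipelineClassifier,
    _fit_pipeline,
    train_mi_bank,
)
from .fusion import decide_batch
from .preprocess import WindowSet

__all__ = [
    "CANONICAL_BANDS",
    "CVReport",
    "BandStats",
    "SubjectResult",
    "stratified_trial_folds",
    "crossval",
    "confusion_percent",
    "confusion_metrics",
    "band_psd_ttest",
    "evoked_spectrum",
    "aggregate_cohort",
    "paired_tests",
    "rm_anova",
    "separability_metrics",
    "score_resilience",
    "shuffle_trial_labels",
    "evaluate_subject",
]

# Canonical EEG band edges in Hz
CANONICAL_BANDS = {
    "Delta": (1.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 12.0),
    "Beta": (12.0, 30.0),
    "Gamma": (30.0, 45.0),
}


# ---------------------------------------------------------------------------
# Cross-validation with leakage guard
# ---------------------------------------------------------------------------

def stratified_trial_folds(
    trial_ids: np.ndarray,
    trial_labels: dict[str, str],
    k: int,
    seed: int,
) -> dict[str, int]:
    """Assign each trial to one of ``k`` folds, stratified by trial label.

    Within each class, trials are shuffled with ``seed`` and dealt
    round-robin, so class counts differ by at most one trial across folds.
    """
    unique_trials = sorted(set(map(str, trial_ids)))
    if len(unique_trials) < k:
        raise ValueError(f"only {len(unique_trials)} trials for {k} folds")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    by_label: dict[str, list[str]] = {}
    for t in unique_trials:
        by_label.setdefault(str(trial_labels[t]), []).append(t)
    offset = 0
    for label in sorted(by_label):
        trials = by_label[label]
        rng.shuffle(trials)
        for i, t in enumerate(trials):
            assignment[t] = (i + offset) % k
        offset += len(trials)  # stagger classes across folds
    return assignment


@dataclass
class CVReport:
    """Cross-validation result with full fold bookkeeping."""

    fold_accuracy: list[float]
    per_class: pd.DataFrame  # precision/recall per class
    confusion: np.ndarray  # pooled counts over test folds
    classes: list[str]
    fold_of_trial: dict[str, int]
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy))

    def to_dict(self) -> dict:
        return {
            "fold_accuracy": list(map(float, self.fold_accuracy)),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "classes": self.classes,
            "confusion_counts": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(),
            "seed": self.seed,
        }


def _task_labels(windows: WindowSet, task: str) -> tuple[np.ndarray, list[str]]:
    if task == "mi":
        return np.asarray(windows.mi_label), MI_ORDER
    if task == "state":
        return np.asarray(windows.state_label), STATE_ORDER
    raise ValueError(f"unknown task {task!r}")


def crossval(
    windows: WindowSet,
    cfg: ModelConfig,
    task: str = "mi",
    k: int = 5,
    seed: int | None = None,
    covs: np.ndarray | None = None,
    guard: bool = True,
    pipeline_factory=None,
) -> CVReport:
    """Leakage-guarded stratified k-fold cross-validation.

    Folds partition trials; every window inherits its trial's fold.  For each
    fold the full pipeline (FBCSP fit, feature selection, backend choice,
    classifier training) is fitted on training-fold windows only, and
    accuracy is counted over test-fold windows.

    ``guard=False`` splits windows directly, ignoring trial identity — it
    exists solely so tests can demonstrate how optimistic an unguarded split
    is, and should never be used for reporting.

    ``pipeline_factory(cfg)`` may supply a custom estimator exposing
    ``fit(windows, labels, covs=...)`` and ``predict(windows, covs=...)``.
    """
    seed = cfg.seed if seed is None else seed
    labels, classes = _task_labels(windows, task)
    present = set(labels)
    if set(classes) - present:
        raise ValueError(f"labels missing classes {sorted(set(classes) - present)}")
    trial_ids = np.asarray([str(t) for t in windows.trial_id])

    if guard:
        trial_label = {}
        for t, lab in zip(trial_ids, labels):
            if trial_label.setdefault(t, lab) != lab:
                raise ValueError(f"trial {t} carries conflicting labels")
        fold_of_trial = stratified_trial_folds(trial_ids, trial_label, k, seed)
        fold_of_window = np.array([fold_of_trial[t] for t in trial_ids])
    else:
        rng = np.random.default_rng(seed)
        fold_of_window = np.empty(len(windows), dtype=int)
        for c in classes:
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            fold_of_window[idx] = np.arange(len(idx)) % k
        fold_of_trial = {}

    if covs is None and pipeline_factory is None:
        covs = band_window_covariances(windows.windows, cfg.bank, windows.rate)

    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    for fold in range(k):
        tr = fold_of_window != fold
        te = ~tr
        if pipeline_factory is None:
            clf = _fit_pipeline(
                None, labels[tr], cfg, windows.rate, classes, covs=covs[tr]
            )
            pred = clf.predict(covs=covs[te])
        else:
            est = pipeline_factory(cfg)
            est.fit(windows.windows[tr], labels[tr])
            pred = est.predict(windows.windows[te])
        fold_acc.append(float(np.mean(pred == labels[te])))
        for t, p in zip(labels[te], pred):
            confusion[cls_index[t], cls_index[p]] += 1

    per_class = confusion_metrics(confusion, classes=classes)
    return CVReport(
        fold_accuracy=fold_acc,
        per_class=per_class,
        confusion=confusion,
        classes=list(classes),
        fold_of_trial=fold_of_trial,
        seed=seed,
    )


def shuffle_trial_labels(windows: WindowSet, task: str, seed: int) -> WindowSet:
    """Permute labels at the *trial* level (all windows of a trial move
    together), preserving the leakage-guard semantics for null calibration."""
    labels, _ = _task_labels(windows, task)
    trial_ids = np.asarray([str(t) for t in windows.trial_id])
    uniq = sorted(set(trial_ids))
    trial_label = {t: labels[trial_ids == t][0] for t in uniq}
    rng = np.random.default_rng(seed)
    permuted = rng.permutation([trial_label[t] for t in uniq])
    new_map = dict(zip(uniq, permuted))
    new_labels = np.array([new_map[t] for t in trial_ids], dtype=object)
    out = windows.subset(np.arange(len(windows)))
    if task == "mi":
        out.mi_label = new_labels
    else:
        out.state_label = new_labels
    return out


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

def confusion_percent(cm_counts: np.ndarray) -> np.ndarray:
    """Row-normalize a count matrix to percentages (rows sum to 100)."""
    cm = np.asarray(cm_counts, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("confusion matrix has an empty row")
    return 100.0 * cm / sums


def confusion_metrics(
    cm: np.ndarray,
    classes: list[str] | None = None,
    priors: np.ndarray | str = "equal",
) -> pd.DataFrame:
    """Per-class precision and recall from a confusion matrix.

    Accepts raw counts or row-normalized percentages (rows are normalized
    internally either way).  Recall of class c is the diagonal of the
    row-normalized matrix; precision is the prior-weighted column share of
    the diagonal (equal priors by default, matching a cohort-averaged
    row-normalized matrix).  A class never predicted gets
    ``precision_defined = False`` instead of a propagating NaN.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    n = cm.shape[0]
    classes = classes or [f"class{i}" for i in range(n)]
    rows = confusion_percent(cm)
    if isinstance(priors, str):
        if priors != "equal":
            raise ValueError("priors must be 'equal' or a vector")
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(priors, dtype=float)
        w = w / w.sum()
    weighted = rows * w[:, None]
    col_sums = weighted.sum(axis=0)
    recall = np.diag(rows)
    precision = np.full(n, np.nan)
    defined = col_sums > 0
    precision[defined] = 100.0 * np.diag(weighted)[defined] / col_sums[defined]
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "precision_defined": defined,
        },
        index=pd.Index(classes, name="class"),
    )


# ---------------------------------------------------------------------------
# Spectral statistics
# ---------------------------------------------------------------------------

def _welch_psd(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD, 1 s Hann segments, 50% overlap, along the last axis."""
    nperseg = min(int(rate), x.shape[-1])
    return signal.welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )


def band_power(windows: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    """Integrated Welch PSD over a band, averaged over channels, per window."""
    freqs, psd = _welch_psd(np.asarray(windows, dtype=float), rate)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} outside resolved frequencies")
    power = np.trapezoid(psd[..., sel], freqs[sel], axis=-1)
    return power.mean(axis=1) if power.ndim == 2 else power


@dataclass
class BandStats:
    """Per-band two-sample statistics between two window groups."""

    table: pd.DataFrame  # index band; columns t, p, mean_a, mean_b

    def t(self, band: str) -> float:
        return float(self.table.loc[band, "t"])

    def p(self, band: str) -> float:
        return float(self.table.loc[band, "p"])


def band_psd_ttest(
    windows_a: np.ndarray | WindowSet,
    windows_b: np.ndarray | WindowSet,
    rate: float | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandStats:
    """Independent two-sample t-test on per-window band power, per band.

    Sign convention ``t = (mean_A - mean_B)/se``: group A weaker than B
    gives a negative t.  Pooled-variance (Student) t, matching the textbook
    formula.
    """
    if isinstance(windows_a, WindowSet):
        rate = windows_a.rate
        windows_a = windows_a.windows
    if isinstance(windows_b, WindowSet):
        windows_b = windows_b.windows
    if rate is None:
        raise ValueError("rate required with raw arrays")
    if len(windows_a) < 2 or len(windows_b) < 2:
        raise ValueError("need at least 2 windows per group")
    bands = bands or CANONICAL_BANDS
    rows = []
    for name, band in bands.items():
        pa = band_power(windows_a, rate, band)
        pb = band_power(windows_b, rate, band)
        t, p = stats.ttest_ind(pa, pb, equal_var=True)
        rows.append({"band": name, "t": float(t), "p": float(p),
                     "mean_a": float(pa.mean()), "mean_b": float(pb.mean())})
    return BandStats(pd.DataFrame(rows).set_index("band"))


def evoked_spectrum(records, channel: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and standard deviation of per-record Welch spectra in dB.

    Returns ``(freqs, mean_db, std_db)`` across records for one channel.
    """
    spectra = []
    freqs = None
    for rec in records:
        idx = rec.channel_index(channel)
        f, psd = _welch_psd(rec.data[idx], rec.rate)
        freqs = f
        spectra.append(10.0 * np.log10(np.maximum(psd, 1e-300)))
    spectra = np.asarray(spectra)
    return freqs, spectra.mean(axis=0), spectra.std(axis=0)


# ---------------------------------------------------------------------------
# Cohort aggregation and inferential statistics
# ---------------------------------------------------------------------------

def aggregate_cohort(values) -> tuple[float, float]:
    """Arithmetic mean and population (÷n) standard deviation of per-subject
    values; report to two decimals."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty cohort")
    return float(values.mean()), float(values.std())


@dataclass
class PairedTestResult:
    t_stat: float
    t_p: float
    wilcoxon_stat: float
    wilcoxon_p: float
    degenerate: bool = False
    note: str = ""


def paired_tests(acc_a, acc_b) -> PairedTestResult:
    """Two-sided paired t-test and Wilcoxon signed-rank test.

    Degenerate cases are flagged rather than NaN'd: identical vectors give
    (t=0, p=1); a constant non-zero shift gives p=0 for the t-test (zero
    variance of the differences) and the Wilcoxon p from the sign pattern.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise ValueError("paired vectors must have equal length >= 5")
    d = a - b
    if np.allclose(d, 0):
        return PairedTestResult(0.0, 1.0, 0.0, 1.0, True, "all differences zero")
    if np.allclose(d, d[0]):
        # constant non-zero shift: t-statistic diverges
        t_stat = np.inf if d[0] > 0 else -np.inf
        w_stat, w_p = stats.wilcoxon(a, b)
        return PairedTestResult(float(t_stat), 0.0, float(w_stat), float(w_p),
                                True, "zero-variance differences")
    t_stat, t_p = stats.ttest_rel(a, b)
    w_stat, w_p = stats.wilcoxon(a, b)
    return PairedTestResult(float(t_stat), float(t_p), float(w_stat), float(w_p))


def rm_anova(ratings: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """One-way repeated-measures ANOVA over a complete subjects x conditions
    matrix; returns ``(F, p)``.  Identical columns give ``(0, 1)``."""
    from statsmodels.stats.anova import AnovaRM

    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("ratings must be a (subjects x conditions) matrix, >=2 each")
    if not np.all(np.isfinite(mat)):
        raise ValueError("ratings contain missing cells; no imputation is done")
    cond_means = mat.mean(axis=0)
    # condition sum of squares = 0 -> F = 0 exactly (avoids 0/0 downstream)
    if np.allclose(cond_means - cond_means.mean(), 0):
        return 0.0, 1.0
    n_sub, n_cond = mat.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_sub), n_cond),
            "condition": np.tile(np.arange(n_cond), n_sub),
            "value": mat.ravel(),
        }
    )
    res = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


def separability_metrics(
    embedding: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    cv: int = 5,
) -> dict:
    """Cluster separability of a labelled 2-D (or n-D) embedding.

    Returns pairwise centroid Euclidean distances, Fisher's discriminant
    ratio (between-class to within-class variance, trace form) and the
    cross-validated accuracy of a linear probe.  Zero within-class spread is
    flagged ``separated`` with an infinite ratio.
    """
    x = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("need at least two points per class")
    centroids = {c: x[labels == c].mean(axis=0) for c in classes}
    distances = {
        f"{a}-{b}": float(np.linalg.norm(centroids[a] - centroids[b]))
        for i, a in enumerate(classes)
        for b in classes[i + 1 :]
    }
    grand = x.mean(axis=0)
    n = len(x)
    between = sum(counts[c] * np.sum((centroids[c] - grand) ** 2) for c in classes) / n
    within = sum(np.sum((x[labels == c] - centroids[c]) ** 2) for c in classes) / n
    if within == 0:
        fisher, separated = np.inf, True
    else:
        fisher, separated = float(between / within), False

    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    n_splits = min(cv, min(counts.values()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    probe = LogisticRegression(max_iter=1000)
    acc = float(np.mean(cross_val_score(probe, x, labels, cv=skf)))
    return {
        "centroid_distances": distances,
        "fisher_ratio": fisher,
        "separated": separated,
        "probe_accuracy": acc,
    }


RESILIENCE_HIGH_RANGE = (146, 175)


def score_resilience(items) -> tuple[int, str]:
    """Score a 25-item, 7-point resilience scale.

    The score is the plain sum; 146-175 classifies as "high" resilience,
    anything lower as "general".
    """
    items = list(items)
    if len(items) != 25:
        raise ValueError(f"expected 25 items, got {len(items)}")
    for v in items:
        if int(v) != v or not (1 <= int(v) <= 7):
            raise ValueError(f"item {v!r} outside 1..7")
    score = int(sum(int(v) for v in items))
    lo, hi = RESILIENCE_HIGH_RANGE
    return score, ("high" if lo <= score <= hi else "general")


# ---------------------------------------------------------------------------
# Per-subject experiment driver
# ---------------------------------------------------------------------------

@dataclass
class SubjectResult:
    """All per-subject quantities the cohort tables report."""

    subject_id: str
    pbci: CVReport
    mi_per_state: dict[str, float]  # own-state accuracy of the state model
    mi_pooled_per_state: dict[str, float]  # own-state accuracy of the pooled model
    method_accuracy: dict[str, float]  # keys "1", "2", "3-1", "3-2"

    def to_row(self) -> dict:
        row = {"subject": self.subject_id, "pbci_accuracy": 100 * self.pbci.mean_accuracy}
        for s in STATE_ORDER:
            row[f"mi_{s}"] = 100 * self.mi_per_state[s]
            row[f"mi_pooled_{s}"] = 100 * self.mi_pooled_per_state[s]
        for m, acc in self.method_accuracy.items():
            row[f"method_{m}"] = 100 * acc
        return row


def evaluate_subject(
    stage2: WindowSet,
    stage1: WindowSet | None,
    cfg: ModelConfig,
    k: int = 5,
    seed: int | None = None,
) -> SubjectResult:
    """Run the full within-subject experiment.

    Per fold of a (state x MI)-stratified trial partition: the complete bank
    (state decoder, per-state MI models, pooled and calibration baselines) is
    trained on training-fold windows and every fusion method is scored on
    test-fold windows.  The 3-class frustration decoder is cross-validated on
    the same windows.  Accuracies are window-level fractions.
    """
    seed = cfg.seed if seed is None else seed
    covs2 = band_window_covariances(stage2.windows, cfg.bank, stage2.rate)
    covs1 = None
    if stage1 is not None and len(stage1):
        covs1 = band_window_covariances(stage1.windows, cfg.bank, stage1.rate)

    pbci = crossval(stage2, cfg, task="state", k=k, seed=seed, covs=covs2)

    trial_ids = np.asarray([str(t) for t in stage2.trial_id])
    states = np.asarray(stage2.state_label)
    mi_true = np.asarray(stage2.mi_label)
    joint = {t: f"{s}|{m}" for t, s, m in zip(trial_ids, states, mi_true)}
    fold_of_trial = stratified_trial_folds(trial_ids, joint, k, seed)
    fold_of_window = np.array([fold_of_trial[t] for t in trial_ids])
    method_hits = {m: 0 for m in ("1", "2", "3-1", "3-2")}
    state_hits = {s: 0 for s in STATE_ORDER}
    pooled_hits = {s: 0 for s in STATE_ORDER}
    state_totals = {s: 0 for s in STATE_ORDER}
    total = 0
    for fold in range(k):
        tr = fold_of_window != fold
        te = ~tr
        bank = train_mi_bank(
            stage2.subset(tr), cfg, stage1_windows=stage1,
            covs2=covs2[tr], covs1=covs1,
        )
        n_te = int(te.sum())
        total += n_te
        for m in method_hits:
            if m == "3-2" and bank.mi_calibration is None:
                continue
            dec = decide_batch(bank, m, covs=covs2[te])
            method_hits[m] += int(np.sum(dec["y_hat"].values == mi_true[te]))
        # own-state comparison: the matching state model vs the pooled model
        for s in STATE_ORDER:
            m_te = te & (states == s)
            if not m_te.any():
                continue
            state_totals[s] += int(m_te.sum())
            pred_s = bank.mi_by_state[s].predict(covs=covs2[m_te])
            pred_all = bank.mi_all.predict(covs=covs2[m_te])
            state_hits[s] += int(np.sum(pred_s == mi_true[m_te]))
            pooled_hits[s] += int(np.sum(pred_all == mi_true[m_te]))

    method_accuracy = {m: method_hits[m] / total for m in method_hits}
    if stage1 is None or not len(stage1):
        method_accuracy.pop("3-2")
    return SubjectResult(
        subject_id=str(stage2.subject_id[0]) if len(stage2) else "",
        pbci=pbci,
        mi_per_state={s: state_hits[s] / max(state_totals[s], 1) for s in STATE_ORDER},
        mi_pooled_per_state={s: pooled_hits[s] / max(state_totals[s], 1) for s in STATE_ORDER},
        method_accuracy=method_accuracy,
    )
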