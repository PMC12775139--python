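"""Filter-bank common spatial patterns (FBCSP) with mutual-information
feature selection.

CSP finds spatial filters ``w`` extremizing the variance ratio between two
classes by solving the generalized eigenproblem

    Sigma_A w = lambda (Sigma_A + Sigma_B) w

on shrinkage-regularized, trace-normalized average class covariances.  The
filter bank applies CSP per frequency band; each window is summarized by
normalized log-variance features of the projected signals, and the most
label-informative features are kept by a plug-in mutual-information ranking
(MIBIF) with CSP pair completion.  Three-class problems (the frustration
decoder) use one-vs-rest CSP per class with features concatenated before
selection.

Because ``var(w^T X) = w^T Sigma w`` for mean-removed windows, both fitting
and feature extraction can run entirely on per-window covariance matrices;
the band filtering then has to touch the raw signal only once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import linalg, signal

__all__ = [
    "FilterBankSpec",
    "CSPBankModel",
    "fit_csp_pair",
    "csp_log_variance",
    "fit_fbcsp",
    "transform",
    "band_window_covariances",
    "mutual_information_rank",
]


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered list of (low_hz, high_hz) bands.

    The default is the canonical nine-band layout: 4 Hz bands from 4 to
    40 Hz (4-8, 8-12, ..., 36-40).
    """

    bands: tuple[tuple[float, float], ...] = tuple(
        (lo, lo + 4.0) for lo in np.arange(4.0, 40.0, 4.0)
    )

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("filter bank must contain at least one band")
        for lo, hi in self.bands:
            if not (0 < lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")

    def __len__(self) -> int:
        return len(self.bands)


def _window_covariances(windows: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance of each mean-removed window."""
    x = windows - windows.mean(axis=-1, keepdims=True)
    covs = np.einsum("nct,ndt->ncd", x, x) / x.shape[-1]
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("degenerate (zero-variance) window encountered")
    return covs / traces[:, None, None]


def band_window_covariances(
    windows: np.ndarray,
    bank: FilterBankSpec,
    rate: float,
    order: int = 4,
) -> np.ndarray:
    """Per-window, per-band covariance tensor, shape (n, n_bands, C, C).

    Each band is isolated with a zero-phase Butterworth bandpass (the same
    family the preprocessing stage uses); covariances are trace-normalized,
    which leaves both CSP fitting and the normalized log-variance features
    unchanged while removing per-window amplitude scale.
    """
    windows = np.asarray(windows, dtype=float)
    n, n_chan, _ = windows.shape
    out = np.empty((n, len(bank), n_chan, n_chan))
    for b, (lo, hi) in enumerate(bank.bands):
        sos = signal.butter(order, (lo, hi), btype="bandpass", fs=rate, output="sos")
        filt = signal.sosfiltfilt(sos, windows, axis=-1)
        out[:, b] = _window_covariances(filt)
    return out


def _ledoit_wolf_intensity(covs: np.ndarray, mean_cov: np.ndarray) -> float:
    """Ledoit-Wolf-style shrinkage intensity toward the scaled identity.

    Treats each window covariance as one observation of the class covariance
    and balances their dispersion around the mean against the mean's distance
    from its isotropic projection.
    """
    c = mean_cov.shape[0]
    mu = np.trace(mean_cov) / c
    d2 = np.sum((mean_cov - mu * np.eye(c)) ** 2)
    if d2 <= 0:
        return 1.0
    n = len(covs)
    b2 = np.sum((covs - mean_cov) ** 2) / n**2
    return float(min(1.0, b2 / d2))


def _class_covariance(covs: np.ndarray, shrinkage: float | None = None) -> tuple[np.ndarray, float]:
    mean_cov = covs.mean(axis=0)
    alpha = _ledoit_wolf_intensity(covs, mean_cov) if shrinkage is None else shrinkage
    c = mean_cov.shape[0]
    mu = np.trace(mean_cov) / c
    return (1 - alpha) * mean_cov + alpha * mu * np.eye(c), alpha


def fit_csp_pair(
    windows_a: np.ndarray | None,
    windows_b: np.ndarray | None,
    n_pairs: int,
    covs_a: np.ndarray | None = None,
    covs_b: np.ndarray | None = None,
    shrinkage: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one two-class CSP problem.

    Parameters may be raw windows (n, C, T) or precomputed trace-normalized
    covariances (n, C, C).  Returns ``(W, eigenvalues)`` where ``W`` is
    (C, 2*n_pairs): the first ``n_pairs`` columns belong to the largest
    eigenvalues (descending), the last ``n_pairs`` to the smallest
    (ascending); column ``j`` pairs with column ``j + n_pairs``.  Columns
    satisfy ``w^T (Sigma_A + Sigma_B) w = 1``.  ``eigenvalues`` is the full
    spectrum, descending.
    """
    if covs_a is None:
        covs_a = _window_covariances(np.asarray(windows_a, dtype=float))
    if covs_b is None:
        covs_b = _window_covariances(np.asarray(windows_b, dtype=float))
    if len(covs_a) < 2 or len(covs_b) < 2:
        raise ValueError("need at least 2 windows per class")
    n_chan = covs_a.shape[1]
    if 2 * n_pairs > n_chan:
        raise ValueError(f"2*n_pairs={2 * n_pairs} exceeds channel count {n_chan}")
    sa, _ = _class_covariance(covs_a, shrinkage)
    sb, _ = _class_covariance(covs_b, shrinkage)
    composite = sa + sb
    # conditioning check: eigh would fail or return garbage on singular B
    if np.linalg.cond(composite) > 1e12:
        raise np.linalg.LinAlgError(
            "composite covariance is rank-deficient after regularization; "
            "increase the shrinkage intensity"
        )
    eigvals, eigvecs = linalg.eigh(sa, composite)  # ascending
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]  # descending
    cols = list(range(n_pairs)) + list(range(n_chan - 1, n_chan - n_pairs - 1, -1))
    w = eigvecs[:, cols]
    return w, eigvals


def csp_log_variance(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Normalized log-variance features of one window under filters ``w``.

    ``f_j = log( var(w_j^T X) / sum_k var(w_k^T X) )``, so that
    ``sum_j exp(f_j) = 1`` and the features are invariant to a global
    rescaling of the window.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != w.shape[0]:
        raise ValueError(f"window has {x.shape[0]} channels, filters expect {w.shape[0]}")
    proj = w.T @ (x - x.mean(axis=-1, keepdims=True))
    var = proj.var(axis=-1)
    if np.any(var <= 0):
        raise ValueError("zero-variance projection: degenerate window")
    return np.log(var / var.sum())


def _log_variance_from_covs(covs: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized log-variance features from (n, C, C) covariances."""
    var = np.einsum("cj,ncd,dj->nj", w, covs, w)
    if np.any(var <= 0):
        raise ValueError("zero-variance projection: degenerate window")
    return np.log(var / var.sum(axis=1, keepdims=True))


def _discretize_quantile(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def plugin_mutual_information(x_binned: np.ndarray, y_codes: np.ndarray) -> float:
    """Plug-in MI (nats) between two discrete sequences, by direct counting."""
    xs = np.unique(x_binned)
    ys = np.unique(y_codes)
    n = len(x_binned)
    mi = 0.0
    for xv in xs:
        px = np.mean(x_binned == xv)
        for yv in ys:
            pxy = np.mean((x_binned == xv) & (y_codes == yv))
            if pxy > 0:
                py = np.mean(y_codes == yv)
                mi += pxy * np.log(pxy / (px * py))
    return float(mi)


def mutual_information_rank(features: np.ndarray, labels: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Column indices ordered by decreasing plug-in MI with the label.

    Features are discretized into ``n_bins`` quantile bins.  Ties are broken
    by the lower feature index (stable sort on negated MI).
    """
    _, y_codes = np.unique(labels, return_inverse=True)
    mis = np.array([
        plugin_mutual_information(_discretize_quantile(features[:, j], n_bins), y_codes)
        for j in range(features.shape[1])
    ])
    return np.argsort(-mis, kind="stable")


@dataclass
class CSPBankModel:
    """Fitted FBCSP transform: per-(problem, band) spatial filters plus the
    selected feature indices.

    ``problems`` is ``[(class, "rest")]`` per class for one-vs-rest multiclass
    fits, or a single pair for binary fits.  ``filters`` has shape
    (n_problems, n_bands, C, 2m).  Feature column layout before selection:
    problem-major, then band, then filter, i.e. column
    ``(p * n_bands + b) * 2m + j``.
    """

    bank: FilterBankSpec
    classes: list[str]
    problems: list[tuple[str, str]]
    filters: np.ndarray
    n_pairs: int
    selected: np.ndarray
    rate: float
    n_channels: int
    shrinkage: float | None = None

    @property
    def n_features_total(self) -> int:
        return len(self.problems) * len(self.bank) * 2 * self.n_pairs

    def _all_features(self, covs: np.ndarray) -> np.ndarray:
        n = covs.shape[0]
        feats = np.empty((n, self.n_features_total))
        width = 2 * self.n_pairs
        for p in range(len(self.problems)):
            for b in range(len(self.bank)):
                col = (p * len(self.bank) + b) * width
                feats[:, col : col + width] = _log_variance_from_covs(
                    covs[:, b], self.filters[p, b]
                )
        return feats

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("filters", data=self.filters)
            f.create_dataset("selected", data=self.selected)
            f.create_dataset("bands", data=np.asarray(self.bank.bands))
            str_dt = h5py.string_dtype("utf-8")
            f.create_dataset("classes", data=np.asarray(self.classes, dtype=object), dtype=str_dt)
            f.create_dataset(
                "problems",
                data=np.asarray([list(p) for p in self.problems], dtype=object),
                dtype=str_dt,
            )
            f.attrs["n_pairs"] = self.n_pairs
            f.attrs["rate"] = self.rate
            f.attrs["n_channels"] = self.n_channels
            f.attrs["shrinkage"] = -1.0 if self.shrinkage is None else self.shrinkage

    @classmethod
    def load(cls, path) -> "CSPBankModel":
        with h5py.File(path, "r") as f:
            dec = lambda s: s.decode() if isinstance(s, bytes) else s
            shr = float(f.attrs["shrinkage"])
            return cls(
                bank=FilterBankSpec(tuple(map(tuple, f["bands"][()]))),
                classes=[dec(s) for s in f["classes"][()]],
                problems=[tuple(dec(x) for x in row) for row in f["problems"][()]],
                filters=f["filters"][()],
                n_pairs=int(f.attrs["n_pairs"]),
                selected=f["selected"][()],
                rate=float(f.attrs["rate"]),
                n_channels=int(f.attrs["n_channels"]),
                shrinkage=None if shr < 0 else shr,
            )


def _pair_complete(selected: np.ndarray, n_pairs: int) -> np.ndarray:
    """Close a set of feature indices under CSP pair completion."""
    width = 2 * n_pairs
    out = set()
    for idx in selected:
        base, j = divmod(int(idx), width)
        out.add(base * width + j)
        out.add(base * width + (j + n_pairs) % width)
    return np.array(sorted(out), dtype=int)


def fit_fbcsp(
    windows: np.ndarray,
    labels: np.ndarray,
    bank: FilterBankSpec | None = None,
    n_pairs: int = 2,
    k_select: int = 4,
    rate: float = 1000.0,
    classes: list[str] | None = None,
    covs: np.ndarray | None = None,
    shrinkage: float | None = None,
) -> CSPBankModel:
    """Fit the full FBCSP transform on labelled windows.

    Binary problems fit one CSP per band; problems with more classes fit
    one-vs-rest CSP per class, concatenating features before selection.
    The top ``k_select`` features by plug-in mutual information are kept and
    then closed under pair completion.

    ``covs`` may carry precomputed output of :func:`band_window_covariances`
    to avoid re-filtering (e.g. inside cross-validation).
    """
    labels = np.asarray(labels)
    bank = bank or FilterBankSpec()
    if classes is None:
        classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if covs is None:
        covs = band_window_covariances(np.asarray(windows, dtype=float), bank, rate)
    n_chan = covs.shape[2]

    if len(classes) == 2:
        problems = [(classes[0], classes[1])]
    else:
        problems = [(c, "rest") for c in classes]

    filters = np.empty((len(problems), len(bank), n_chan, 2 * n_pairs))
    for p, (pos, neg) in enumerate(problems):
        mask_a = labels == pos
        mask_b = ~mask_a if neg == "rest" else labels == neg
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            raise ValueError(f"problem {pos!r} vs {neg!r} lacks windows")
        for b in range(len(bank)):
            w, _ = fit_csp_pair(
                None, None, n_pairs,
                covs_a=covs[mask_a, b], covs_b=covs[mask_b, b],
                shrinkage=shrinkage,
            )
            filters[p, b] = w

    model = CSPBankModel(
        bank=bank,
        classes=list(classes),
        problems=problems,
        filters=filters,
        n_pairs=n_pairs,
        selected=np.arange(0),
        rate=rate,
        n_channels=n_chan,
        shrinkage=shrinkage,
    )
    feats = model._all_features(covs)
    if k_select > feats.shape[1]:
        raise ValueError(
            f"k_select={k_select} exceeds {feats.shape[1]} available features"
        )
    order = mutual_information_rank(feats, labels)
    model.selected = _pair_complete(order[:k_select], n_pairs)
    return model


def transform(
    model: CSPBankModel,
    windows: np.ndarray | None,
    covs: np.ndarray | None = None,
) -> np.ndarray:
    """Apply a fitted FBCSP transform; rows = windows, columns = selected
    features.  Deterministic: identical input gives identical output."""
    if covs is None:
        windows = np.asarray(windows, dtype=float)
        if windows.shape[1] != model.n_channels:
            raise ValueError(
                f"windows have {windows.shape[1]} channels, model expects "
                f"{model.n_channels}"
            )
        covs = band_window_covariances(windows, model.bank, model.rate)
    feats = model._all_features(covs)[:, model.selected]
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite features produced")
    return feats
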