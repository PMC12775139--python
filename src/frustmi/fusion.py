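"""Decision strategies combining the frustration decoder with the MI bank.

Three strategies turn a window into a left/right command:

* **Hard switching (method 1)** — pick the most probable frustration state
  ``s = argmax(p_f)`` and commit fully to that state's MI model:
  ``y = argmax(M_s(X))``.
* **Probabilistic fusion (method 2)** — weight every state-specific MI
  output by its state probability: ``p_final = sum_i p_i * M_i(X)``,
  ``y = argmax(p_final)``.
* **State-agnostic baseline (method 3)** — ignore the state decoder and use
  a single pooled MI model; variant ``3-1`` is trained on all induced-state
  data, variant ``3-2`` only on calibration-stage data.

Ties are deterministic: the lowest state index wins for states, "left" for
MI classes (both realized by first-maximum argmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import MI_ORDER, STATE_ORDER, ClassifierBank

__all__ = [
    "FusionDecision",
    "fuse_hard",
    "fuse_soft",
    "method1_hard_switch",
    "method2_soft_fusion",
    "method3_baseline",
    "decide_batch",
    "trial_majority_vote",
]

METHODS = ("1", "2", "3-1", "3-2")


@dataclass
class FusionDecision:
    """Full per-window decision trace."""

    p_f: np.ndarray  # (3,) state probabilities, low/mid/high
    per_state_mi: np.ndarray  # (3, 2) MI probabilities per state model
    p_final: np.ndarray  # (2,) fused/selected MI probabilities
    s_hat: int | str  # selected state index, or "n/a" for method 3
    y_hat: str  # "left" | "right"
    method: str


def _check_probs(p_f: np.ndarray, per_state_mi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p_f = np.asarray(p_f, dtype=float)
    q = np.asarray(per_state_mi, dtype=float)
    if p_f.shape != (3,):
        raise ValueError("p_f must have shape (3,)")
    if q.shape != (3, 2):
        raise ValueError("per_state_mi must have shape (3, 2)")
    if abs(p_f.sum() - 1) > 1e-6 or np.any(p_f < -1e-12):
        raise ValueError("p_f is not a probability vector")
    return p_f, q


def fuse_hard(p_f: np.ndarray, per_state_mi: np.ndarray) -> FusionDecision:
    """Pure hard-switching rule on given probabilities (method 1)."""
    p_f, q = _check_probs(p_f, per_state_mi)
    s_hat = int(np.argmax(p_f))  # first max -> lowest-index tie-break
    p_final = q[s_hat]
    y_hat = MI_ORDER[int(np.argmax(p_final))]
    return FusionDecision(p_f, q, p_final, s_hat, y_hat, "1")


def fuse_soft(p_f: np.ndarray, per_state_mi: np.ndarray) -> FusionDecision:
    """Pure probabilistic-fusion rule on given probabilities (method 2)."""
    p_f, q = _check_probs(p_f, per_state_mi)
    p_final = p_f @ q  # sum_i p_i * q_i
    y_hat = MI_ORDER[int(np.argmax(p_final))]
    return FusionDecision(p_f, q, p_final, "n/a", y_hat, "2")


def _window_probs(bank: ClassifierBank, x: np.ndarray):
    x = np.asarray(x, dtype=float)[None]
    p_f = bank.state_clf.predict_proba(x)[0]
    q = np.stack([m.predict_proba(x)[0] for m in bank.mi_models()])
    return p_f, q


def method1_hard_switch(x: np.ndarray, bank: ClassifierBank) -> FusionDecision:
    """Apply hard switching to one window (channels x samples)."""
    p_f, q = _window_probs(bank, x)
    return fuse_hard(p_f, q)


def method2_soft_fusion(x: np.ndarray, bank: ClassifierBank) -> FusionDecision:
    """Apply probabilistic fusion to one window."""
    p_f, q = _window_probs(bank, x)
    return fuse_soft(p_f, q)


def method3_baseline(x: np.ndarray, bank: ClassifierBank, variant: str = "3-1") -> FusionDecision:
    """Apply a state-agnostic baseline model to one window."""
    model = _baseline_model(bank, variant)
    x = np.asarray(x, dtype=float)[None]
    p_final = model.predict_proba(x)[0]
    y_hat = MI_ORDER[int(np.argmax(p_final))]
    return FusionDecision(
        np.full(3, np.nan), np.full((3, 2), np.nan), p_final, "n/a", y_hat, variant
    )


def _baseline_model(bank: ClassifierBank, variant: str):
    if variant == "3-1":
        return bank.mi_all
    if variant == "3-2":
        if bank.mi_calibration is None:
            raise ValueError("bank has no calibration-stage model (variant 3-2)")
        return bank.mi_calibration
    raise ValueError(f"unknown method-3 variant {variant!r}")


def decide_batch(
    bank: ClassifierBank,
    method: str,
    windows: np.ndarray | None = None,
    covs: np.ndarray | None = None,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Decide every window under one method; returns one row per window.

    Columns: subject, trial, window, p0..p2, per-state MI probabilities,
    fused probabilities, s_hat and y_hat.  ``meta`` (optional) supplies the
    subject/trial identifiers.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if method in ("1", "2"):
        p_f = bank.state_clf.predict_proba(windows, covs=covs)
        q = np.stack(
            [m.predict_proba(windows, covs=covs) for m in bank.mi_models()], axis=1
        )  # (n, 3, 2)
        if method == "1":
            s_hat = np.argmax(p_f, axis=1)
            p_final = q[np.arange(len(q)), s_hat]
            s_col = s_hat.astype(object)
        else:
            p_final = np.einsum("ns,nsc->nc", p_f, q)
            s_col = np.full(len(q), "n/a", dtype=object)
    else:
        model = _baseline_model(bank, method)
        p_final = model.predict_proba(windows, covs=covs)
        n = len(p_final)
        p_f = np.full((n, 3), np.nan)
        q = np.full((n, 3, 2), np.nan)
        s_col = np.full(n, "n/a", dtype=object)

    y_hat = np.asarray(MI_ORDER, dtype=object)[np.argmax(p_final, axis=1)]
    n = len(p_final)
    out = pd.DataFrame(
        {
            "subject": meta["subject"].values if meta is not None else [""] * n,
            "trial": meta["trial"].values if meta is not None else [""] * n,
            "window": meta["window"].values if meta is not None else np.arange(n),
        }
    )
    for i in range(3):
        out[f"p{i}"] = p_f[:, i]
    for i, s in enumerate(STATE_ORDER):
        out[f"q{i}L"] = q[:, i, 0]
        out[f"q{i}R"] = q[:, i, 1]
    out["pfL"] = p_final[:, 0]
    out["pfR"] = p_final[:, 1]
    out["s_hat"] = s_col
    out["y_hat"] = y_hat
    out["method"] = method
    return out


def trial_majority_vote(decisions: pd.DataFrame) -> pd.Series:
    """Optional trial-level aggregation: majority vote over a trial's window
    decisions; ties go to "left"."""

    def vote(group: pd.Series) -> str:
        counts = group.value_counts()
        left = counts.get("left", 0)
        right = counts.get("right", 0)
        return "left" if left >= right else "right"

    return decisions.groupby("trial")["y_hat"].apply(vote)
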