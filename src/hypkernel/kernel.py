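"""Kernel-based prediction of categorization behavior and AUROC scoring.

The predictive method: embed a stimulus and every hypothesized
configuration in the canonical AU space; score each category by the
kernel similarity (cosine by default) between the stimulus and that
category's configurations, taking the best-matching configuration when a
category has several; turn scores into category probabilities with a
softmax; and quantify predictive performance per participant and category
with the one-vs-rest area under the ROC curve (AUROC).

AUROC is rank-based, so the softmax inverse temperature ``beta`` affects
probability calibration only, never the headline metric.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .au_space import AU_COLUMNS, N_AUS
from .models import HypothesisModel

__all__ = [
    "KERNELS",
    "cosine_similarity",
    "category_scores",
    "predict",
    "predict_trial",
    "auroc_ovr",
    "UndefinedAUROCError",
    "evaluate_model",
    "evaluate_models",
    "au_matrix",
]


def _cosine_kernel(S: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows of S (N,P) and C (k,P).

    Zero-norm rows have similarity 0 to everything (an expressionless face
    is equally unlike every configuration).
    """
    sn = np.linalg.norm(S, axis=1, keepdims=True)
    cn = np.linalg.norm(C, axis=1, keepdims=True)
    out = (S @ C.T) / np.where(sn == 0, 1.0, sn) / np.where(cn == 0, 1.0, cn).T
    out[(sn == 0).ravel(), :] = 0.0
    out[:, (cn == 0).ravel()] = 0.0
    return out


def _dot_kernel(S: np.ndarray, C: np.ndarray) -> np.ndarray:
    return S @ C.T


def _neg_euclidean_kernel(S: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(S**2, axis=1, keepdims=True)
        + np.sum(C**2, axis=1)
        - 2.0 * (S @ C.T)
    )
    return -np.sqrt(np.maximum(d2, 0.0))


#: Pluggable stimulus×configuration similarity kernels.
KERNELS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "cosine": _cosine_kernel,
    "dot": _dot_kernel,
    "neg_euclidean": _neg_euclidean_kernel,
}


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine of the angle between two nonnegative AU vectors, in [0, 1].

    Defined as 0 if either vector has zero norm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(_cosine_kernel(u[None, :], v[None, :])[0, 0])


def category_scores(
    S: np.ndarray,
    model: HypothesisModel,
    kernel: str = "cosine",
) -> tuple[np.ndarray, list[str]]:
    """Per-trial, per-category similarity scores (N, Q).

    A category with several configurations scores each stimulus with the
    configuration most similar to it (max rule).
    """
    if not model.covered_categories:
        raise ValueError(f"model {model.name!r} covers no categories")
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[1] != N_AUS:
        raise ValueError(f"stimulus matrix must have {N_AUS} columns")
    kfun = KERNELS[kernel]
    cats = list(model.covered_categories)
    out = np.empty((S.shape[0], len(cats)))
    for q, cat in enumerate(cats):
        out[:, q] = kfun(S, model.configs[cat]).max(axis=1)
    return out, cats


def _softmax(scores: np.ndarray, beta: float) -> np.ndarray:
    z = beta * scores
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict(
    S: np.ndarray,
    model: HypothesisModel,
    beta: float = 1.0,
    kernel: str = "cosine",
) -> tuple[np.ndarray, list[str]]:
    """Probabilistic category predictions for a stimulus matrix.

    Returns an (N, Q) row-stochastic matrix (softmax of ``beta`` × the
    per-category scores) and the category order of its columns.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    scores, cats = category_scores(S, model, kernel=kernel)
    return _softmax(scores, beta), cats


def predict_trial(
    s: Sequence[float] | Mapping[str, float],
    model: HypothesisModel,
    beta: float = 1.0,
    kernel: str = "cosine",
) -> dict[str, float]:
    """Category probabilities for one stimulus, keyed by category."""
    if isinstance(s, Mapping):
        from .au_space import embed

        s = embed(s)
    P, cats = predict(np.asarray(s, dtype=float)[None, :], model, beta, kernel)
    return dict(zip(cats, P[0]))


class UndefinedAUROCError(ValueError):
    """AUROC is undefined when the labels contain a single class."""


def auroc_ovr(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """One-vs-rest AUROC: P(random positive outranks random negative).

    Ties count one half (Mann–Whitney convention).  Requires at least one
    positive and one negative label; a single-class column raises
    :class:`UndefinedAUROCError` rather than silently returning 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUROCError(
            f"need both classes, got {n_pos} positives / {n_neg} negatives"
        )
    r = rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def au_matrix(trials: pd.DataFrame) -> np.ndarray:
    """Stimulus matrix (N, 33) from a trial table; absent AU columns are 0."""
    out = np.zeros((len(trials), N_AUS))
    for j, col in enumerate(AU_COLUMNS):
        if col in trials.columns:
            out[:, j] = trials[col].to_numpy(dtype=float)
    return out


def evaluate_model(
    trials: pd.DataFrame,
    model: HypothesisModel,
    beta: float = 1.0,
    kernel: str = "cosine",
) -> pd.DataFrame:
    """Score a model against behavior: one AUROC per participant × category.

    Trials whose response falls outside the model's covered categories are
    filtered out first (models covering a category subset are tested only on
    the categorizations they cover; "other" responses must already have been
    excluded upstream).  Cells where a participant used (or avoided) a
    category on every trial have no one-vs-rest contrast; they are recorded
    with ``auroc`` NaN and skipped by downstream averages.

    Ranking uses the softmax probability column for the category, so a
    binary (two-category) model scores identically for both classes (the
    columns are complements).  For two categories the ranking is exactly
    independent of ``beta``; with more categories ``beta`` re-weights how
    competing categories discount a score, a small calibration effect.

    Returns a tidy frame: participant, culture, model, category, auroc,
    n_pos, n_neg.
    """
    covered = set(model.covered_categories)
    mask = trials["response"].isin(covered)
    sub = trials.loc[mask]
    if len(sub) == 0:
        raise ValueError(
            f"no trials left after restricting to categories covered by {model.name!r}"
        )
    P, cats = predict(au_matrix(sub), model, beta=beta, kernel=kernel)
    resp = sub["response"].to_numpy()
    part = sub["participant_id"].to_numpy()
    cult = sub["culture"].to_numpy()
    records: list[tuple] = []
    for pid in pd.unique(part):
        idx = np.flatnonzero(part == pid)
        culture = cult[idx[0]]
        for q, cat in enumerate(cats):
            y = resp[idx] == cat
            n_pos = int(y.sum())
            n_neg = int(y.size - n_pos)
            if n_pos == 0 or n_neg == 0:
                records.append((pid, culture, model.name, cat, np.nan, n_pos, n_neg))
                continue
            records.append(
                (pid, culture, model.name, cat, auroc_ovr(P[idx, q], y), n_pos, n_neg)
            )
    return pd.DataFrame(
        records,
        columns=["participant", "culture", "model", "category", "auroc", "n_pos", "n_neg"],
    )


def evaluate_models(
    trials: pd.DataFrame,
    models: Sequence[HypothesisModel],
    beta: float = 1.0,
    kernel: str = "cosine",
) -> pd.DataFrame:
    """Concatenated :func:`evaluate_model` tables for several models."""
    return pd.concat(
        [evaluate_model(trials, m, beta=beta, kernel=kernel) for m in models],
        ignore_index=True,
    )
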