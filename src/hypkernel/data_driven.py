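"""Data-driven model estimation from categorization behavior.

Instead of a published hypothesis, a model can be estimated from the data
itself: for each participant, category and AU, compute the point-biserial
Pearson correlation between the AU amplitude and the binary indicator of
that category being chosen; mark the (category, AU) cell significant at
an uncorrected two-sided α.  Per-participant binary matrices are
aggregated across participants either by proportion weighting (an AU
significant in 90% of participants gets weight 0.9) or by strict majority
(>50%, yielding a binary model).  Leave-one-participant-out evaluation
fits on N−1 participants and scores the aggregate on the left-out one,
so the estimated model is never evaluated on its own training data.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .au_space import CANONICAL_ORDER
from .kernel import au_matrix, evaluate_model
from .models import HypothesisModel

__all__ = [
    "point_biserial_matrix",
    "fit_participant",
    "aggregate",
    "to_model",
    "lopo_evaluate",
]


def point_biserial_matrix(
    trials: pd.DataFrame, categories: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p per (category × AU), vectorized.

    r is the correlation between each AU amplitude column and the binary
    chose-this-category indicator; p comes from the t transform with n−2
    degrees of freedom.  Constant amplitude columns or single-class
    categories yield NaN r (undefined, excluded downstream).
    """
    X = au_matrix(trials)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need >=3 trials to correlate, got {n}")
    resp = trials["response"].to_numpy()
    Y = np.stack([(resp == c).astype(float) for c in categories], axis=1)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    denom = np.outer(sy, sx)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc.T @ Xc) / denom
    r[denom == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    cols = list(CANONICAL_ORDER)
    return (
        pd.DataFrame(r, index=list(categories), columns=cols),
        pd.DataFrame(p, index=list(categories), columns=cols),
    )


def fit_participant(
    trials: pd.DataFrame,
    categories: Sequence[str],
    alpha: float = 0.05,
    sign_rule: str = "positive",
) -> pd.DataFrame:
    """Binary (category × 33 AU) significance matrix for one participant.

    A cell is 1 iff the point-biserial correlation is significant at the
    uncorrected two-sided ``alpha`` and its sign satisfies ``sign_rule``:
    ``"positive"`` (default — a significantly *negative* correlation should
    not add an AU to a category's template) or ``"any"``.  Categories the
    participant never (or always) chose have an all-zero row; undefined
    correlations count as not significant.
    """
    if sign_rule not in ("positive", "any"):
        raise ValueError(f"sign_rule must be 'positive' or 'any', got {sign_rule!r}")
    r, p = point_biserial_matrix(trials, categories)
    sig = (p < alpha).fillna(False)
    if sign_rule == "positive":
        sig &= r > 0
    sig[r.isna()] = False
    return sig.astype(int)


def aggregate(
    matrices: Sequence[pd.DataFrame],
    mode: str = "weighted",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Combine per-participant binary matrices across participants.

    ``weighted``: each cell's value is the proportion of participants for
    whom it was significant (AUs significant in no participant stay 0 and
    are excluded from configurations downstream).  ``majority``: binary at
    a strict ``> threshold`` rule (default 0.5, i.e. >50% of participants).
    """
    if len(matrices) == 0:
        raise ValueError("no matrices to aggregate")
    shapes = {m.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"inhomogeneous matrix shapes: {shapes}")
    prop = sum(m.astype(float) for m in matrices) / len(matrices)
    if mode == "weighted":
        return prop
    if mode == "majority":
        return (prop > threshold).astype(int)
    raise ValueError(f"mode must be 'weighted' or 'majority', got {mode!r}")


def to_model(
    weights: pd.DataFrame,
    name: str = "data_driven",
    task: str = "basic6",
) -> HypothesisModel:
    """Wrap an aggregated (category × AU) matrix as a hypothesis model.

    Each category becomes a single configuration whose coordinates are the
    aggregated weights (continuous coordinates interact with the cosine
    kernel directly).  All-zero categories are left uncovered.
    """
    configs = {
        str(cat): weights.loc[cat].to_numpy(dtype=float)[None, :]
        for cat in weights.index
        if weights.loc[cat].to_numpy(dtype=float).any()
    }
    if not configs:
        raise ValueError("aggregated matrix has no nonzero category")
    return HypothesisModel(name=name, task=task, configs=configs)


def lopo_evaluate(
    trials: pd.DataFrame,
    categories: Sequence[str],
    alpha: float = 0.05,
    beta: float = 1.0,
    sign_rule: str = "positive",
    name: str = "data_driven",
    task: str = "basic6",
    kernel: str = "cosine",
) -> pd.DataFrame:
    """Leave-one-participant-out evaluation of the data-driven model.

    For each of the N participants: fit the binary matrix on each of the
    other N−1 participants, aggregate with proportion weighting, wrap as a
    single-configuration-per-category model, and evaluate it on the
    left-out participant's trials.  Folds whose aggregate covers no
    category are skipped (recorded as missing participants in the output).
    Deterministic: no randomness is involved.
    """
    parts = list(pd.unique(trials["participant_id"]))
    if len(parts) < 3:
        raise ValueError(f"need >=3 participants for leave-one-out, got {len(parts)}")
    fits = {
        pid: fit_participant(
            trials.loc[trials["participant_id"] == pid], categories, alpha, sign_rule
        )
        for pid in parts
    }
    frames = []
    for pid in parts:
        others = [fits[q] for q in parts if q != pid]
        weights = aggregate(others, mode="weighted")
        try:
            model = to_model(weights, name=name, task=task)
        except ValueError:
            continue
        held_out = trials.loc[trials["participant_id"] == pid]
        try:
            frames.append(evaluate_model(held_out, model, beta=beta, kernel=kernel))
        except ValueError:
            continue
    if not frames:
        raise ValueError("no evaluable leave-one-out fold")
    return pd.concat(frames, ignore_index=True)
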