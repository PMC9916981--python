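"""Noise-ceiling estimation for categorical responses.

No model that sees only the stimulus can predict labels better than the
true conditional label distribution given that stimulus.  When different
participants label repeats of the same AU pattern inconsistently, that
inconsistency bounds achievable performance below 1.  The plug-in ceiling
scores the empirical conditional distribution (estimated from all
observations sharing a stimulus) with the same one-vs-rest AUROC used for
the models; a leave-one-participant-out mode estimates the conditional
from the other participants only, giving a conservative variant.

Stimuli observed only once contribute their own label as "distribution",
which inflates the plug-in ceiling; the estimate reports the singleton
fraction (with a warning above 50%) and supports restricting to stimuli
with a minimum number of observations.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .au_space import AU_COLUMNS
from .kernel import UndefinedAUROCError, auroc_ovr

__all__ = [
    "stimulus_key",
    "assign_keys",
    "optimal_predictions",
    "NoiseCeilingEstimate",
    "estimate_ceiling",
]


def stimulus_key(amap: Mapping[str, float], precision: int = 6) -> str:
    """Canonical hash of an AU pattern: equal patterns ⇒ equal keys.

    The key digests the sorted multiset of (canonical label, amplitude
    rounded to ``precision`` decimals); zero amplitudes are ignored.
    """
    items = sorted(
        (label, round(float(amp), precision))
        for label, amp in amap.items()
        if round(float(amp), precision) != 0.0
    )
    payload = "|".join(f"{l}:{a:.{precision}f}" for l, a in items)
    return hashlib.blake2b(payload.encode(), digest_size=10).hexdigest()


def assign_keys(trials: pd.DataFrame, precision: int = 6) -> pd.Series:
    """Stimulus keys for every row of a trial table, from its AU columns."""
    cols = [c for c in AU_COLUMNS if c in trials.columns]
    arr = trials[cols].to_numpy(dtype=float).round(precision)
    keys = []
    for row in arr:
        nz = np.nonzero(row)[0]
        payload = "|".join(
            f"{lab}:{row[j]:.{precision}f}"
            for j, lab in ((j, _COL2LAB[cols[j]]) for j in nz)
        )
        keys.append(hashlib.blake2b(payload.encode(), digest_size=10).hexdigest())
    return pd.Series(keys, index=trials.index, name="stimulus_key")


_COL2LAB = {}


def _init_col2lab() -> None:
    from .au_space import label_from_column

    for c in AU_COLUMNS:
        _COL2LAB[c] = label_from_column(c)


_init_col2lab()


def _group_structure(keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(group index per trial, group sizes)."""
    _, inv, counts = np.unique(keys, return_inverse=True, return_counts=True)
    return inv, counts


def optimal_predictions(
    trials: pd.DataFrame,
    categories: Sequence[str],
    exclude_participant: bool = False,
) -> np.ndarray:
    """Empirical conditional label distribution per trial (N, Q).

    Each trial's prediction is the distribution of responses over all
    observations sharing its stimulus key ("other" responses must already be
    excluded).  With ``exclude_participant``, a trial's own participant is
    left out of the conditional; stimuli seen by one participant only then
    fall back to the pooled (all-observation) distribution.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    keys = (
        trials["stimulus_key"].to_numpy()
        if "stimulus_key" in trials.columns
        else assign_keys(trials).to_numpy()
    )
    cats = list(categories)
    cat_idx = pd.Categorical(trials["response"], categories=cats).codes
    if (cat_idx < 0).any():
        bad = sorted(set(trials["response"]) - set(cats))
        raise ValueError(f"responses outside the task's categories: {bad}")
    ginv, _ = _group_structure(keys)
    n_groups = ginv.max() + 1
    counts = np.zeros((n_groups, len(cats)))
    np.add.at(counts, (ginv, cat_idx), 1.0)
    if not exclude_participant:
        P = counts[ginv]
        return P / P.sum(axis=1, keepdims=True)
    # subtract each (group, participant) contribution from its own trials
    part_codes = pd.Categorical(trials["participant_id"]).codes
    pg = np.zeros((n_groups, part_codes.max() + 1, len(cats)))
    np.add.at(pg, (ginv, part_codes, cat_idx), 1.0)
    P = counts[ginv] - pg[ginv, part_codes]
    empty = P.sum(axis=1) == 0
    P[empty] = counts[ginv[empty]]
    return P / P.sum(axis=1, keepdims=True)


@dataclass
class NoiseCeilingEstimate:
    """Per-category ceiling with bootstrap uncertainty and diagnostics."""

    ceiling: dict[str, float]
    sd: dict[str, float]
    mode: str
    grouping: str
    n_boot: int
    n_unique_stimuli: int
    n_observations: int
    singleton_fraction: float
    degenerate: bool = False
    skipped_categories: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ceiling": self.ceiling,
            "sd": self.sd,
            "mode": self.mode,
            "grouping": self.grouping,
            "n_boot": self.n_boot,
            "n_unique_stimuli": self.n_unique_stimuli,
            "n_observations": self.n_observations,
            "singleton_fraction": self.singleton_fraction,
            "degenerate": self.degenerate,
            "skipped_categories": self.skipped_categories,
        }


def _ceiling_once(
    P: np.ndarray, resp: np.ndarray, cats: Sequence[str]
) -> dict[str, float]:
    out: dict[str, float] = {}
    for q, cat in enumerate(cats):
        y = resp == cat
        try:
            out[cat] = auroc_ovr(P[:, q], y)
        except UndefinedAUROCError:
            out[cat] = np.nan
    return out


def estimate_ceiling(
    trials: pd.DataFrame,
    categories: Sequence[str],
    n_boot: int = 1000,
    seed: int | None = None,
    mode: str = "plug_in",
    grouping: str = "pooled",
    min_observations: int = 1,
) -> NoiseCeilingEstimate:
    """Estimate the per-category noise ceiling of a trial table.

    The ceiling for a category is the one-vs-rest AUROC of the optimal
    (conditional-distribution) prediction column against the observed
    labels, an upper bound for any fixed stimulus-based model.  The
    bootstrap SD resamples observations with replacement within each
    stimulus-key group ("bootstrapping repeated observations") and is
    deterministic given ``seed``.

    Parameters
    ----------
    mode : ``"plug_in"`` (default, optimistic but a true upper bound) or
        ``"leave_one_participant_out"`` (conservative).
    grouping : ``"pooled"`` (one ceiling across cultures) or
        ``"per_culture"`` — with per_culture, call once per culture subset;
        this flag only names the convention in the report.
    min_observations : drop stimulus keys observed fewer times than this
        before estimating (2 restricts to repeated stimuli).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if mode not in ("plug_in", "leave_one_participant_out"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    trials = trials.copy()
    if "stimulus_key" not in trials.columns:
        trials["stimulus_key"] = assign_keys(trials)
    keys_all = trials["stimulus_key"].to_numpy()
    ginv_all, counts_all = _group_structure(keys_all)
    singleton_fraction = float((counts_all == 1).sum() / counts_all.size)
    if min_observations > 1:
        keep = counts_all[ginv_all] >= min_observations
        trials = trials.loc[keep]
        if len(trials) == 0:
            raise ValueError(
                f"no stimulus observed at least {min_observations} times"
            )
    if singleton_fraction > 0.5 and min_observations <= 1:
        warnings.warn(
            f"{singleton_fraction:.0%} of stimuli observed only once; the "
            "plug-in ceiling is inflated toward 1 (consider min_observations=2)",
            stacklevel=2,
        )
    cats = list(categories)
    exclude = mode == "leave_one_participant_out"
    P = optimal_predictions(trials, cats, exclude_participant=exclude)
    resp = trials["response"].to_numpy()
    point = _ceiling_once(P, resp, cats)

    keys = trials["stimulus_key"].to_numpy()
    ginv, counts = _group_structure(keys)
    degenerate = bool((counts == 1).all())
    order = np.argsort(ginv, kind="stable")
    bounds = np.cumsum(counts)[:-1]
    group_indices = np.split(order, bounds)
    rng = np.random.default_rng(seed)
    boot: dict[str, list[float]] = {c: [] for c in cats}
    n = len(trials)
    for _ in range(n_boot):
        take = np.empty(n, dtype=int)
        pos = 0
        for idx in group_indices:
            k = idx.size
            take[pos : pos + k] = idx[rng.integers(0, k, size=k)]
            pos += k
        bt = trials.iloc[take]
        Pb = optimal_predictions(bt, cats, exclude_participant=exclude)
        for cat, val in _ceiling_once(Pb, bt["response"].to_numpy(), cats).items():
            boot[cat].append(val)
    sd = {}
    for c, v in boot.items():
        finite = np.asarray(v, dtype=float)
        finite = finite[np.isfinite(finite)]
        sd[c] = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    skipped = [c for c in cats if np.isnan(point[c])]
    return NoiseCeilingEstimate(
        ceiling={c: float(v) for c, v in point.items()},
        sd=sd,
        mode=mode,
        grouping=grouping,
        n_boot=n_boot,
        n_unique_stimuli=int(counts.size),
        n_observations=int(n),
        singleton_fraction=singleton_fraction,
        degenerate=degenerate,
        skipped_categories=skipped,
    )
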