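"""Explanation and exploration: AU ablation, culture accents, cross-validation.

Explanation asks which AUs causally drive a model's predictive
performance: remove ("ablate") one AU at a time from a model's
configurations for one category, re-evaluate, and record the change in
AUROC.  Averaged across models, a negative change marks the AU as
performance-critical for that category, a positive change as
performance-detrimental.

Exploration turns those findings, derived separately per culture, into
optimized culture-accented models: add every performance-critical AU to a
category's configurations and remove every performance-detrimental AU.
Optimized models are evaluated on held-out participants, faces and
stimuli (the train/test split), never on the data that produced the
accents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import au_space
from .au_space import CANONICAL_ORDER, N_AUS
from .kernel import evaluate_model, evaluate_models
from .models import HypothesisModel
from .noise_ceiling import assign_keys

__all__ = [
    "ablate",
    "ablation_map",
    "derive_accents",
    "optimize_model",
    "SplitPlan",
    "split_train_test",
    "compare_cultures",
    "compare_to_chance",
    "ExplorationResult",
    "run_exploration",
]


def _au_indices(au: int | str) -> list[int]:
    """Canonical coordinate indices addressed by an AU number or label.

    A plain number addresses both laterals where lateralized; a canonical
    label like ``"12L"`` addresses that single coordinate.
    """
    if isinstance(au, str) and not str(au).isdigit():
        return [au_space.label_index(au)]
    labels = au_space.expand_number(int(au))
    return [au_space.label_index(l) for l in labels]


def ablate(model: HypothesisModel, category: str, au: int | str) -> HypothesisModel:
    """Remove one AU from every configuration of one category.

    Other categories are untouched.  Configurations emptied by the removal
    are dropped and duplicates merged.  Rejects (rather than returning the
    model unchanged) when the AU is absent from the category — an absent AU
    cannot be ablated, which is different from ablation having no effect —
    and when removal would empty the whole category.
    """
    if category not in model.configs:
        raise ValueError(f"model {model.name!r} does not cover {category!r}")
    idx = _au_indices(au)
    arr = model.configs[category]
    if not np.any(arr[:, idx] != 0):
        raise ValueError(
            f"AU {au} occurs in no configuration of {model.name!r}/{category!r}"
        )
    new = arr.copy()
    new[:, idx] = 0.0
    new = new[np.any(new != 0, axis=1)]
    if new.shape[0] == 0:
        raise ValueError(
            f"ablating AU {au} empties every configuration of "
            f"{model.name!r}/{category!r}; category not evaluable"
        )
    out = model.copy()
    out.configs[category] = new
    # re-run invariants (dedup)
    return HypothesisModel(
        name=model.name, task=model.task, configs=out.configs,
        dropped_aus=out.dropped_aus,
    )


def _present_labels(model: HypothesisModel, category: str) -> list[str]:
    arr = model.configs[category]
    return [CANONICAL_ORDER[j] for j in np.flatnonzero(np.any(arr != 0, axis=0))]


def ablation_map(
    models: Sequence[HypothesisModel],
    trials: pd.DataFrame,
    beta: float = 1.0,
    kernel: str = "cosine",
) -> pd.DataFrame:
    """Mean ΔAUROC (ablated − original) per (category × canonical AU).

    For each model, category and AU present in that category's
    configurations: Δ is the across-participant mean of
    AUROC(ablated model) − AUROC(original model) for that category.  A cell
    averages Δ over the models containing the AU; AUs in no model's
    category stay NaN (undefined, never entering averages).  Negative cells
    mark performance-critical AUs, positive cells performance-detrimental
    ones.  Per-cell evaluation errors are recorded as NaN without aborting
    the rest of the map.
    """
    categories = sorted({c for m in models for c in m.covered_categories})
    sums = pd.DataFrame(0.0, index=categories, columns=list(CANONICAL_ORDER))
    counts = pd.DataFrame(0, index=categories, columns=list(CANONICAL_ORDER))
    for model in models:
        base = evaluate_model(trials, model, beta=beta, kernel=kernel)
        base_by_cat = {
            cat: grp.set_index("participant")["auroc"]
            for cat, grp in base.groupby("category")
        }
        for cat in model.covered_categories:
            for label in _present_labels(model, cat):
                try:
                    abl = ablate(model, cat, label)
                    scores = evaluate_model(trials, abl, beta=beta, kernel=kernel)
                except ValueError:
                    continue
                cur = scores.loc[scores["category"] == cat].set_index("participant")[
                    "auroc"
                ]
                delta = (cur - base_by_cat[cat]).dropna()
                if len(delta) == 0:
                    continue
                sums.loc[cat, label] += float(delta.mean())
                counts.loc[cat, label] += 1
    out = sums / counts.replace(0, np.nan)
    return out


def derive_accents(
    maps_per_culture: Mapping[str, pd.DataFrame],
    epsilon: float = 0.0,
) -> dict[str, dict[str, dict[str, list[str]]]]:
    """Classify AUs as performance-critical/-detrimental per culture.

    ``maps_per_culture`` maps a culture label to its ablation map
    (category × canonical AU).  An AU is critical for a category when its
    mean Δ < −ε and detrimental when Δ > +ε (strict signs; ε is a dead
    zone, default 0).  Undefined (NaN) cells are ignored.  Returns
    ``{culture: {category: {"critical": [...], "detrimental": [...]}}}``;
    the two sets are disjoint by construction.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    out: dict[str, dict[str, dict[str, list[str]]]] = {}
    for culture, amap in maps_per_culture.items():
        out[culture] = {}
        for cat in amap.index:
            row = amap.loc[cat]
            critical = [l for l in amap.columns if row[l] < -epsilon]
            detrimental = [l for l in amap.columns if row[l] > epsilon]
            out[culture][cat] = {"critical": critical, "detrimental": detrimental}
    return out


def optimize_model(
    model: HypothesisModel,
    accents: Mapping[str, Mapping[str, Mapping[str, Sequence[str]]]],
    culture: str,
) -> tuple[HypothesisModel, dict[str, bool]]:
    """Build a culture-accented model from ablation-derived accents.

    Per covered category: every critical AU is added to every
    configuration and every detrimental AU removed from every one;
    duplicates are merged and emptied configurations dropped.  A category
    whose configurations would all vanish keeps its original configuration
    of largest total weight and is flagged (second return value maps
    category → flag).
    """
    if culture not in accents:
        raise ValueError(f"no accents derived for culture {culture!r}")
    flags: dict[str, bool] = {}
    configs: dict[str, np.ndarray] = {}
    for cat, arr in model.configs.items():
        acc = accents[culture].get(cat, {"critical": [], "detrimental": []})
        new = arr.copy()
        for label in acc["critical"]:
            new[:, au_space.label_index(label)] = 1.0
        for label in acc["detrimental"]:
            new[:, au_space.label_index(label)] = 0.0
        new = new[np.any(new != 0, axis=1)]
        if new.shape[0] == 0:
            best = int(np.argmax(arr.sum(axis=1)))
            new = arr[[best]]
            flags[cat] = True
        else:
            flags[cat] = False
        configs[cat] = new
    return (
        HypothesisModel(
            name=f"{model.name}[{culture}]", task=model.task, configs=configs
        ),
        flags,
    )


@dataclass
class SplitPlan:
    """Per-culture train/test partition of participants, faces and stimuli.

    Train trials are those of train participants showing train faces AND
    train stimulus keys; test trials likewise on the test side.  All other
    ("off-diagonal") trials are dropped and counted, so test stimuli
    contain AU patterns and face identities never seen in training.
    """

    train_participants: dict[str, list] = field(default_factory=dict)
    test_participants: dict[str, list] = field(default_factory=dict)
    train_faces: dict[str, list] = field(default_factory=dict)
    test_faces: dict[str, list] = field(default_factory=dict)
    train_keys: dict[str, list] = field(default_factory=dict)
    test_keys: dict[str, list] = field(default_factory=dict)
    dropped_trials: int = 0
    n_trials: int = 0
    seed: int | None = None

    def _select(self, trials: pd.DataFrame, which: str) -> pd.DataFrame:
        parts = getattr(self, f"{which}_participants")
        faces = getattr(self, f"{which}_faces")
        keys = getattr(self, f"{which}_keys")
        frames = []
        t = trials
        if "stimulus_key" not in t.columns:
            t = t.copy()
            t["stimulus_key"] = assign_keys(t)
        for culture in parts:
            sub = t.loc[
                (t["culture"] == culture)
                & t["participant_id"].isin(parts[culture])
                & t["face_id"].isin(faces[culture])
                & t["stimulus_key"].isin(keys[culture])
            ]
            frames.append(sub)
        return pd.concat(frames) if frames else t.iloc[0:0]

    def train_trials(self, trials: pd.DataFrame) -> pd.DataFrame:
        return self._select(trials, "train")

    def test_trials(self, trials: pd.DataFrame) -> pd.DataFrame:
        return self._select(trials, "test")

    def assert_disjoint(self) -> None:
        for culture in self.train_participants:
            assert not set(self.train_participants[culture]) & set(
                self.test_participants[culture]
            ), f"participant leakage in {culture}"
            assert not set(self.train_keys[culture]) & set(
                self.test_keys[culture]
            ), f"stimulus leakage in {culture}"
            assert not set(self.train_faces[culture]) & set(
                self.test_faces[culture]
            ), f"face leakage in {culture}"

    def to_dict(self) -> dict:
        return {
            "train_participants": {k: list(map(str, v)) for k, v in self.train_participants.items()},
            "test_participants": {k: list(map(str, v)) for k, v in self.test_participants.items()},
            "train_faces": {k: list(map(str, v)) for k, v in self.train_faces.items()},
            "test_faces": {k: list(map(str, v)) for k, v in self.test_faces.items()},
            "n_train_keys": {k: len(v) for k, v in self.train_keys.items()},
            "n_test_keys": {k: len(v) for k, v in self.test_keys.items()},
            "dropped_trials": self.dropped_trials,
            "dropped_fraction": self.dropped_trials / self.n_trials if self.n_trials else 0.0,
            "seed": self.seed,
        }


def split_train_test(
    trials: pd.DataFrame,
    participant_train_fraction: float = 2 / 3,
    seed: int | None = None,
) -> SplitPlan:
    """Partition trials so test data are new participants, faces and stimuli.

    Per culture, participants are randomly split at
    ``participant_train_fraction`` (default 2/3, e.g. 60 → 40 train / 20
    test), faces 50/50 and stimulus keys 50/50.  Deterministic given
    ``seed``.  The dropped (off-diagonal) trial count is recorded on the
    plan.
    """
    if not 0 < participant_train_fraction < 1:
        raise ValueError("participant_train_fraction must lie in (0, 1)")
    t = trials
    if "stimulus_key" not in t.columns:
        t = t.copy()
        t["stimulus_key"] = assign_keys(t)
    rng = np.random.default_rng(seed)
    plan = SplitPlan(seed=seed, n_trials=len(t))
    for culture, sub in t.groupby("culture", sort=True):
        parts = np.sort(sub["participant_id"].unique())
        faces = np.sort(sub["face_id"].unique())
        keys = np.sort(sub["stimulus_key"].unique())
        if len(parts) < 2 or len(faces) < 2 or len(keys) < 2:
            raise ValueError(
                f"culture {culture!r} needs >=2 participants, faces and stimuli "
                f"(got {len(parts)}, {len(faces)}, {len(keys)})"
            )
        n_train = int(round(participant_train_fraction * len(parts)))
        n_train = min(max(n_train, 1), len(parts) - 1)
        p_perm = rng.permutation(parts)
        f_perm = rng.permutation(faces)
        k_perm = rng.permutation(keys)
        plan.train_participants[culture] = sorted(p_perm[:n_train].tolist())
        plan.test_participants[culture] = sorted(p_perm[n_train:].tolist())
        nf = len(faces) // 2
        plan.train_faces[culture] = sorted(f_perm[nf:].tolist())
        plan.test_faces[culture] = sorted(f_perm[:nf].tolist())
        nk = len(keys) // 2
        plan.train_keys[culture] = sorted(k_perm[nk:].tolist())
        plan.test_keys[culture] = sorted(k_perm[:nk].tolist())
    plan.assert_disjoint()
    kept = len(plan.train_trials(t)) + len(plan.test_trials(t))
    plan.dropped_trials = len(t) - kept
    return plan


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0 if np.mean(a) == np.mean(b) else np.inf * np.sign(np.mean(a) - np.mean(b))
    return float((np.mean(a) - np.mean(b)) / pooled)


def compare_cultures(
    auroc: pd.DataFrame,
    cultures: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-sided independent t tests of per-participant AUROC across cultures.

    Per category, each participant's AUROC is first averaged over models;
    the two culture groups are then compared with a pooled-variance t test
    and Cohen's d, signed first-culture − second-culture (WE − EA when the
    table holds those labels).  No multiple-testing correction is applied
    (``corrected`` column is always False, flagging this).  Groups that are
    both constant yield NaN statistics, flagged in ``defined``.
    """
    present = list(pd.unique(auroc["culture"]))
    if cultures is None:
        cultures = ("WE", "EA") if {"WE", "EA"} <= set(present) else tuple(sorted(present)[:2])
    c1, c2 = cultures
    rows = []
    for cat, grp in auroc.groupby("category", sort=True):
        per_part = (
            grp.dropna(subset=["auroc"])
            .groupby(["participant", "culture"], sort=True)["auroc"]
            .mean()
            .reset_index()
        )
        a = per_part.loc[per_part["culture"] == c1, "auroc"].to_numpy()
        b = per_part.loc[per_part["culture"] == c2, "auroc"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >=2 participants per culture for {cat!r}")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        d = _cohens_d(a, b)
        defined = np.isfinite(t)
        rows.append((cat, c1, c2, float(t), float(p), d, len(a), len(b), bool(defined), False))
    return pd.DataFrame(
        rows,
        columns=[
            "category", "culture_1", "culture_2", "t", "p", "cohens_d",
            "n_1", "n_2", "defined", "corrected",
        ],
    )


def compare_to_chance(auroc: pd.DataFrame, chance: float = 0.5) -> pd.DataFrame:
    """One-sample two-sided t tests of per-participant AUROC against chance."""
    rows = []
    for (model, cat), grp in auroc.groupby(["model", "category"], sort=True):
        per_part = grp.dropna(subset=["auroc"]).groupby("participant")["auroc"].mean()
        vals = per_part.to_numpy()
        if len(vals) < 2:
            continue
        t, p = stats.ttest_1samp(vals, chance)
        sd = np.std(vals, ddof=1)
        d = (np.mean(vals) - chance) / sd if sd > 0 else np.nan
        rows.append((model, cat, float(np.mean(vals)), float(t), float(p), float(d), len(vals)))
    return pd.DataFrame(
        rows, columns=["model", "category", "mean_auroc", "t", "p", "cohens_d", "n"]
    )


@dataclass
class ExplorationResult:
    """Artifacts of one prediction→explanation→exploration pass."""

    plan: SplitPlan
    ablation_maps: dict[str, pd.DataFrame]
    accents: dict[str, dict[str, dict[str, list[str]]]]
    optimized_models: dict[str, list[HypothesisModel]]
    optimization_flags: dict[str, dict[str, dict[str, bool]]]
    train_auroc: pd.DataFrame
    test_auroc_original: pd.DataFrame
    test_auroc_optimized: pd.DataFrame


def run_exploration(
    trials: pd.DataFrame,
    models: Sequence[HypothesisModel],
    beta: float = 1.0,
    epsilon: float = 0.0,
    participant_train_fraction: float = 2 / 3,
    seed: int | None = None,
    kernel: str = "cosine",
) -> ExplorationResult:
    """Full cross-validated pass: predict, explain, explore.

    Prediction and explanation (ablation maps, per culture) run on train
    participants' train trials; accents are derived per culture; each model
    gets a culture-accented optimized variant; original and optimized
    models are evaluated on the held-out test trials of test participants
    (each culture's accented models on that culture's test data).  The
    split's disjointness is asserted inside the pipeline.
    """
    t = trials.copy()
    if "stimulus_key" not in t.columns:
        t["stimulus_key"] = assign_keys(t)
    plan = split_train_test(t, participant_train_fraction, seed=seed)
    plan.assert_disjoint()
    train = plan.train_trials(t)
    test = plan.test_trials(t)
    maps = {
        culture: ablation_map(
            models, train.loc[train["culture"] == culture], beta=beta, kernel=kernel
        )
        for culture in plan.train_participants
    }
    accents = derive_accents(maps, epsilon=epsilon)
    optimized: dict[str, list[HypothesisModel]] = {}
    flags: dict[str, dict[str, dict[str, bool]]] = {}
    for culture in accents:
        optimized[culture] = []
        flags[culture] = {}
        for m in models:
            om, fl = optimize_model(m, accents, culture)
            optimized[culture].append(om)
            flags[culture][m.name] = fl
    train_auroc = evaluate_models(train, models, beta=beta, kernel=kernel)
    test_original = evaluate_models(test, models, beta=beta, kernel=kernel)
    test_opt_frames = []
    for culture, oms in optimized.items():
        sub = test.loc[test["culture"] == culture]
        frame = evaluate_models(sub, oms, beta=beta, kernel=kernel)
        frame["model"] = frame["model"].str.replace(
            rf"\[{culture}\]$", "", regex=True
        )
        test_opt_frames.append(frame)
    test_optimized = pd.concat(test_opt_frames, ignore_index=True)
    return ExplorationResult(
        plan=plan,
        ablation_maps=maps,
        accents=accents,
        optimized_models=optimized,
        optimization_flags=flags,
        train_auroc=train_auroc,
        test_auroc_original=test_original,
        test_auroc_optimized=test_optimized,
    )
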