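"""Hypothesis models: AU-configuration notation, expansion, and registry.

Published AU→emotion hypotheses are written in a compact notation:

* ``+`` joins AUs that occur together: ``"6 + 12"``;
* a comma introduces optional AUs/groups: ``"1 + 15, 4, 17"`` means
  AU1+AU15, optionally with AU4 and/or AU17;
* ``(a ∨ b)`` is a mutually exclusive alternation: ``"(25 ∨ 26)"``;
* separate bullet entries are separate explicitly proposed configurations.

:func:`parse_spec` expands such a string into the full list of AU sets it
denotes (cartesian product over alternations × power set over optionals ×
union over bullets, deduplicated), and :func:`lateralize` turns an AU set
into a binary vector in the canonical 33-AU space.
"""

from __future__ import annotations

import itertools
import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import au_space
from .au_space import N_AUS, UnknownAULabelError

__all__ = [
    "ParseError",
    "parse_spec",
    "lateralize",
    "HypothesisModel",
    "load_registry",
    "task_categories",
]

_ALT_SEPS = ("∨", "|")  # plus a standalone ASCII "v", handled in tokenizer
_BULLET_RE = re.compile(r"[•\n;]+")


class ParseError(ValueError):
    """Malformed configuration expression; carries the offending position."""

    def __init__(self, message: str, text: str, pos: int):
        super().__init__(f"{message} at position {pos} in {text!r}")
        self.text = text
        self.pos = pos


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "+,()":
            tokens.append((c, i))
            i += 1
            continue
        if c in _ALT_SEPS or (c in "vV" and not text[i - 1 : i].isdigit()):
            tokens.append(("∨", i))
            i += 1
            continue
        m = re.match(r"(?:AU)?(\d+)", text[i:], flags=re.IGNORECASE)
        if m:
            tokens.append((m.group(1), i))
            i += len(m.group(0))
            continue
        raise ParseError(f"unknown token {c!r}", text, i)
    return tokens


def _parse_term(tokens: list[tuple[str, int]], i: int, text: str) -> tuple[list[int], int]:
    """term := NUMBER | '(' NUMBER ('∨' NUMBER)* ')'; returns alternatives."""
    if i >= len(tokens):
        raise ParseError("unexpected end of expression", text, len(text))
    tok, pos = tokens[i]
    if tok == "(":
        alts: list[int] = []
        i += 1
        expect_number = True
        while i < len(tokens):
            tok, pos = tokens[i]
            if tok == ")":
                if expect_number or not alts:
                    raise ParseError("empty alternation", text, pos)
                return alts, i + 1
            if expect_number:
                if not tok.isdigit():
                    raise ParseError(f"expected AU number, got {tok!r}", text, pos)
                alts.append(int(tok))
                expect_number = False
            else:
                if tok != "∨":
                    raise ParseError(f"expected '∨' or ')', got {tok!r}", text, pos)
                expect_number = True
            i += 1
        raise ParseError("unclosed '('", text, len(text))
    if tok.isdigit():
        return [int(tok)], i + 1
    raise ParseError(f"expected AU number or '(', got {tok!r}", text, pos)


def _parse_group(
    tokens: list[tuple[str, int]], i: int, text: str
) -> tuple[list[list[int]], int]:
    """group := term ('+' term)*; returns one alternative-list per term."""
    terms: list[list[int]] = []
    alts, i = _parse_term(tokens, i, text)
    terms.append(alts)
    while i < len(tokens) and tokens[i][0] == "+":
        alts, i = _parse_term(tokens, i + 1, text)
        terms.append(alts)
    return terms, i


def _parse_bullet(text: str) -> list[frozenset[int]]:
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty expression", text, 0)
    groups: list[list[list[int]]] = []
    g, i = _parse_group(tokens, 0, text)
    groups.append(g)
    while i < len(tokens):
        tok, pos = tokens[i]
        if tok != ",":
            raise ParseError(f"expected ',' between groups, got {tok!r}", text, pos)
        g, i = _parse_group(tokens, i + 1, text)
        groups.append(g)
    required, optionals = groups[0], groups[1:]
    sets: list[frozenset[int]] = []
    for include in itertools.product([False, True], repeat=len(optionals)):
        terms = list(required)
        for inc, grp in zip(include, optionals):
            if inc:
                terms.extend(grp)
        for choice in itertools.product(*terms):
            sets.append(frozenset(choice))
    return sets


def parse_spec(text: str | Sequence[str]) -> list[frozenset[int]]:
    """Expand a configuration expression into its list of AU-number sets.

    ``text`` may be a single string (bullets separated by ``•``, ``;`` or
    newlines) or a sequence of bullet strings.  The expansion is the union
    over bullets of the cartesian product over alternations times the power
    set over optional groups, with duplicates removed (first occurrence
    kept); it is independent of bullet order up to that ordering.
    """
    if isinstance(text, str):
        bullets = [b for b in _BULLET_RE.split(text) if b.strip()]
    else:
        bullets = [b for b in text if str(b).strip()]
    if not bullets:
        raise ParseError("no configurations given", str(text), 0)
    seen: dict[frozenset[int], None] = {}
    for bullet in bullets:
        for s in _parse_bullet(str(bullet)):
            seen.setdefault(s, None)
    return list(seen)


def lateralize(
    aus: Iterable[int | str],
    on_unknown: str = "error",
) -> np.ndarray:
    """Binary configuration vector for a set of AU numbers.

    Lateralized numbers set both their L and R coordinates; other numbers
    set their single coordinate.  ``on_unknown`` controls AU numbers with no
    canonical counterpart: ``"error"`` rejects (default), ``"drop"`` skips
    them with a warning (used when loading published models that reference
    AUs outside the stimulus space).
    """
    v = np.zeros(N_AUS, dtype=float)
    for au in aus:
        try:
            labels = (
                au_space.DEFAULT_SCHEME.expand_label(str(au))
                if isinstance(au, str)
                else au_space.expand_number(int(au))
            )
        except UnknownAULabelError:
            if on_unknown == "drop":
                warnings.warn(
                    f"AU{au} has no canonical counterpart; dropped", stacklevel=2
                )
                continue
            raise
        for lab in labels:
            v[au_space.label_index(lab)] = 1.0
    return v


@dataclass
class HypothesisModel:
    """A named mapping from categories to configuration vectors.

    ``configs`` maps each covered category to a (k, 33) array whose rows are
    configuration vectors: binary for theory models, weights in [0, 1] for
    data-driven models.  A model may cover only a subset of a task's
    categories.
    """

    name: str
    task: str
    configs: dict[str, np.ndarray] = field(default_factory=dict)
    #: AU numbers dropped at load time (no canonical counterpart), per category.
    dropped_aus: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for cat, arr in self.configs.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[1] != N_AUS:
                raise ValueError(
                    f"{self.name}/{cat}: configurations must have {N_AUS} columns"
                )
            if arr.shape[0] == 0:
                raise ValueError(f"{self.name}/{cat}: category has no configuration")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{self.name}/{cat}: weights must lie in [0, 1]")
            clean[cat] = _dedup_rows(arr)
        self.configs = clean

    @property
    def covered_categories(self) -> tuple[str, ...]:
        return tuple(self.configs)

    @property
    def n_configs(self) -> int:
        return sum(arr.shape[0] for arr in self.configs.values())

    def config_sets(self, category: str) -> list[set[str]]:
        """Configurations of a category as sets of canonical AU labels."""
        return [
            set(au_space.unembed(row)) for row in self.configs[category]
        ]

    def copy(self) -> "HypothesisModel":
        return HypothesisModel(
            name=self.name,
            task=self.task,
            configs={c: a.copy() for c, a in self.configs.items()},
            dropped_aus={c: list(v) for c, v in self.dropped_aus.items()},
        )

    def to_dict(self) -> dict:
        """JSON-serializable form with explicit weighted AU lists."""
        return {
            "name": self.name,
            "task": self.task,
            "categories": {
                cat: [au_space.unembed(row) for row in arr]
                for cat, arr in self.configs.items()
            },
        }

    @classmethod
    def from_dict(cls, spec: Mapping, task_whitelist: Sequence[str] | None = None,
                  on_unknown: str = "error") -> "HypothesisModel":
        """Build from the JSON model format.

        ``categories`` values are lists whose entries are either notation
        strings (parsed and expanded) or explicit configurations: a list of
        AU numbers/labels, or a mapping canonical-label → weight (bypassing
        the parser).
        """
        name, task = spec["name"], spec.get("task", "basic6")
        dropped: dict[str, list[int]] = {}
        configs: dict[str, np.ndarray] = {}
        for cat, entries in spec.get("categories", {}).items():
            if task_whitelist is not None and cat not in task_whitelist:
                raise ValueError(
                    f"model {name!r} references category {cat!r} outside the task"
                )
            rows: list[np.ndarray] = []
            for entry in entries:
                if isinstance(entry, str):
                    for au_set in parse_spec(entry):
                        rows.append(
                            _lateralize_logged(au_set, name, cat, dropped, on_unknown)
                        )
                elif isinstance(entry, Mapping):
                    rows.append(au_space.embed(entry))
                else:  # explicit AU list
                    rows.append(
                        _lateralize_logged(entry, name, cat, dropped, on_unknown)
                    )
            if rows:
                configs[cat] = np.vstack(rows)
        return cls(name=name, task=task, configs=configs, dropped_aus=dropped)


def _dedup_rows(arr: np.ndarray) -> np.ndarray:
    seen: dict[tuple, None] = {}
    for row in arr:
        seen.setdefault(tuple(row), None)
    return np.array(list(seen), dtype=float)


def _lateralize_logged(
    au_set: Iterable[int | str],
    name: str,
    cat: str,
    dropped: dict[str, list[int]],
    on_unknown: str,
) -> np.ndarray:
    au_list = list(au_set)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        v = lateralize(au_list, on_unknown=on_unknown)
    if caught:
        bad = [
            int(au)
            for au in au_list
            if not _has_canonical(au)
        ]
        dropped.setdefault(cat, [])
        for b in bad:
            if b not in dropped[cat]:
                dropped[cat].append(b)
    return v


def _has_canonical(au: int | str) -> bool:
    try:
        if isinstance(au, str):
            au_space.DEFAULT_SCHEME.expand_label(au)
        else:
            au_space.expand_number(int(au))
        return True
    except UnknownAULabelError:
        return False


def _load_task_data() -> dict:
    with resources.files("hypkernel.data").joinpath("tasks.json").open() as fh:
        return json.load(fh)["tasks"]


_TASKS = _load_task_data()


def task_categories(task: str) -> tuple[str, ...]:
    """Category vocabulary of a task (``basic6`` or ``conversational4``)."""
    try:
        return tuple(_TASKS[task]["categories"])
    except KeyError:
        raise ValueError(f"unknown task {task!r}; known: {sorted(_TASKS)}") from None


def other_label(task: str) -> str:
    return _TASKS[task]["other_label"]


def load_registry(
    task: str = "basic6",
    source: str | Path | None = None,
) -> list[HypothesisModel]:
    """Load hypothesis models for a task.

    Without ``source``, the bundled registry is used: seven published
    basic-emotion models for ``basic6``; five empty, user-fillable slots for
    ``conversational4``.  With ``source``, a user JSON file in the same
    format is read.  Models referencing categories outside the task are
    rejected.  Published AUs with no canonical counterpart are dropped and
    recorded on the model.
    """
    cats = task_categories(task)
    if source is None:
        fname = f"models_{task}.json"
        with resources.files("hypkernel.data").joinpath(fname).open() as fh:
            doc = json.load(fh)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    models = [
        HypothesisModel.from_dict(m, task_whitelist=cats, on_unknown="drop")
        for m in doc["models"]
    ]
    return models
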