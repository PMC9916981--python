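"""Canonical action-unit (AU) space and recoding of generative AU labels.

Facial-expression stimuli are generated from a vocabulary that mixes
compound AUs (e.g. ``AU1+2``), unilateral AUs (``AU12L``) and bilateral AUs
(``AU12``).  For modeling, every AU must be an independent variable, so
compounds are expanded into their constituents and bilateral AUs into
separate left/right variables.  The result is a fixed, ordered space of 33
independent AUs; stimuli and hypotheses are embedded as length-33 vectors
in this space.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CANONICAL_ORDER",
    "N_AUS",
    "LATERALIZED",
    "COMPOUNDS",
    "RecodingScheme",
    "AULabel",
    "normalize_label",
    "expand_number",
    "label_index",
    "column_name",
    "label_from_column",
    "au_columns",
    "recode",
    "embed",
    "unembed",
]


def _load_space() -> dict:
    with resources.files("hypkernel.data").joinpath("au_space.json").open() as fh:
        return json.load(fh)


_SPACE = _load_space()

#: Canonical ordered tuple of the 33 independent AU labels.
CANONICAL_ORDER: tuple[str, ...] = tuple(_SPACE["canonical_order"])
#: Dimensionality of the AU space (P).
N_AUS: int = len(CANONICAL_ORDER)
#: AU numbers that exist as separate left/right variables.
LATERALIZED: frozenset[int] = frozenset(_SPACE["lateralized"])
#: Compound AU labels and their constituent AU numbers.
COMPOUNDS: dict[str, tuple[int, ...]] = {
    k: tuple(v) for k, v in _SPACE["compounds"].items()
}

_CANONICAL_SET = frozenset(CANONICAL_ORDER)
_INDEX = {label: i for i, label in enumerate(CANONICAL_ORDER)}
_LABEL_RE = re.compile(r"^(\d+)([LR]?)$")


class UnknownAULabelError(ValueError):
    """Raised for labels outside the canonical set / recoding scheme."""


@dataclass(frozen=True)
class AULabel:
    """A single canonical AU variable; membership is checked on construction."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in _CANONICAL_SET:
            raise UnknownAULabelError(
                f"{self.name!r} is not one of the {N_AUS} canonical AU labels"
            )

    @property
    def index(self) -> int:
        return _INDEX[self.name]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class RecodingScheme:
    """Expansion rules from generative AU labels to canonical labels.

    ``compounds`` maps compound labels ("1+2") to constituent AU numbers;
    ``lateralized`` lists AU numbers that are split into L/R variables.
    Schemes are user-extensible; the default reproduces the shipped,
    versioned ``au_space.json``.
    """

    compounds: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(COMPOUNDS)
    )
    lateralized: frozenset[int] = LATERALIZED

    def expand_number(self, num: int) -> list[str]:
        """Canonical labels for a plain AU number (both sides if lateralized)."""
        if num in self.lateralized:
            labels = [f"{num}L", f"{num}R"]
        else:
            labels = [str(num)]
        for lab in labels:
            if lab not in _CANONICAL_SET:
                raise UnknownAULabelError(
                    f"AU{num} has no canonical counterpart (got {lab!r})"
                )
        return labels

    def expand_label(self, raw: str) -> list[str]:
        """All canonical labels activated by one generative label."""
        lab = normalize_label(raw)
        if lab in self.compounds:
            out: list[str] = []
            for num in self.compounds[lab]:
                out.extend(self.expand_number(num))
            return out
        if lab in _CANONICAL_SET:
            return [lab]
        m = _LABEL_RE.match(lab)
        if m and not m.group(2):
            return self.expand_number(int(m.group(1)))
        raise UnknownAULabelError(f"unrecognized AU label {raw!r}")


DEFAULT_SCHEME = RecodingScheme()


def normalize_label(raw: str) -> str:
    """Normalize a raw label: strip AU prefixes and whitespace.

    ``"AU1 + 2"`` → ``"1+2"``; ``"au12l"`` → ``"12L"``; ``"12"`` → ``"12"``.
    """
    s = str(raw).strip().upper().replace(" ", "")
    s = re.sub(r"AU", "", s)
    return s


def expand_number(num: int, scheme: RecodingScheme = DEFAULT_SCHEME) -> list[str]:
    return scheme.expand_number(num)


def label_index(label: str) -> int:
    """Position of a canonical label in the fixed order."""
    lab = normalize_label(label)
    try:
        return _INDEX[lab]
    except KeyError:
        raise UnknownAULabelError(f"{label!r} is not a canonical AU label") from None


def column_name(label: str) -> str:
    """Trial-table column name for a canonical label, e.g. ``2L`` → ``AU02L``."""
    m = _LABEL_RE.match(normalize_label(label))
    if m is None:
        raise UnknownAULabelError(f"{label!r} is not a canonical AU label")
    return f"AU{int(m.group(1)):02d}{m.group(2)}"


def label_from_column(col: str) -> str:
    """Inverse of :func:`column_name` (``AU02L`` → ``2L``)."""
    m = re.match(r"^AU(\d+)([LR]?)$", col)
    if m is None:
        raise UnknownAULabelError(f"{col!r} is not an AU column name")
    lab = f"{int(m.group(1))}{m.group(2)}"
    if lab not in _CANONICAL_SET:
        raise UnknownAULabelError(f"{col!r} does not map to a canonical AU")
    return lab


#: Trial-table column names in canonical order.
AU_COLUMNS: tuple[str, ...] = tuple(column_name(l) for l in CANONICAL_ORDER)


def au_columns() -> tuple[str, ...]:
    return AU_COLUMNS


def recode(
    raw: Mapping[str, float],
    scheme: RecodingScheme = DEFAULT_SCHEME,
    conflict: str = "max",
) -> dict[str, float]:
    """Recode a generative AU→amplitude mapping into the canonical space.

    Compounds are expanded to their constituents at the same amplitude and
    bilateral numbers to both L and R.  When two raw labels reach the same
    canonical AU, the conflict is resolved by ``conflict``: ``"max"``
    (default, preserves "active" semantics) or ``"sum"`` (sum clipped at 1).

    Raises
    ------
    UnknownAULabelError
        For labels outside the scheme.
    ValueError
        For amplitudes outside [0, 1].
    """
    if conflict not in ("max", "sum"):
        raise ValueError(f"conflict rule must be 'max' or 'sum', got {conflict!r}")
    out: dict[str, float] = {}
    for label, amp in raw.items():
        amp = float(amp)
        if not 0.0 <= amp <= 1.0:
            raise ValueError(f"amplitude {amp} for {label!r} outside [0, 1]")
        for canon in scheme.expand_label(label):
            if canon in out:
                out[canon] = (
                    max(out[canon], amp)
                    if conflict == "max"
                    else min(1.0, out[canon] + amp)
                )
            else:
                out[canon] = amp
    return out


def embed(amap: Mapping[str, float]) -> np.ndarray:
    """Embed a canonical AU→amplitude mapping as a length-33 vector.

    Absent AUs are 0; ordering follows :data:`CANONICAL_ORDER`.
    """
    v = np.zeros(N_AUS, dtype=float)
    for label, amp in amap.items():
        v[label_index(label)] = float(amp)
    return v


def unembed(vector: Iterable[float]) -> dict[str, float]:
    """Inverse of :func:`embed`: nonzero coordinates as a canonical map."""
    v = np.asarray(list(vector), dtype=float)
    if v.shape != (N_AUS,):
        raise ValueError(f"expected a length-{N_AUS} vector, got shape {v.shape}")
    return {CANONICAL_ORDER[i]: float(v[i]) for i in np.nonzero(v)[0]}
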