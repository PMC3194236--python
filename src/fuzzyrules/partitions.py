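"""Fixed antecedent fuzzy-set vocabulary over the unit interval.

The antecedent vocabulary used throughout this package consists of 15 fixed
fuzzy sets: four homogeneous triangular (Ruspini) partitions of [0, 1] with
granularities 2, 3, 4 and 5 — fourteen triangular membership functions in
total — plus one "don't care" (DC) set whose membership is identically 1.
Using several granularities side by side lets short rules choose the coarsest
linguistic term that discriminates, which keeps rule bases legible; none of
the sets is ever tuned.

Labels follow the convention ``S`` (small), ``MS`` (relatively small),
``M`` (medium), ``ML`` (relatively large), ``L`` (large), suffixed with the
granularity, e.g. ``MS5`` is the second of five terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "MembershipFunction",
    "Vocabulary",
    "build_partition",
    "build_vocabulary",
    "VALID_GRANULARITIES",
    "DC_LABEL",
    "LINGUISTIC_TERMS",
]

VALID_GRANULARITIES = (2, 3, 4, 5)
DC_LABEL = "DC"

_PARTITION_TAGS = {
    2: ("S", "L"),
    3: ("S", "M", "L"),
    4: ("S", "MS", "ML", "L"),
    5: ("S", "MS", "M", "ML", "L"),
}

#: Plain-language rendering of each linguistic tag.
LINGUISTIC_TERMS = {
    "S": "small",
    "MS": "relatively small",
    "M": "medium",
    "ML": "relatively large",
    "L": "large",
}


@dataclass(frozen=True)
class MembershipFunction:
    """One antecedent fuzzy set: a triangular function or the DC set.

    Parameters
    ----------
    label
        Short linguistic tag, e.g. ``"MS4"`` or ``"DC"``.
    kind
        ``"triangular"`` or ``"dont_care"``.
    left, peak, right
        Breakpoints in [0, 1]; ignored for the DC set.
    granularity
        Number of sets in the partition this function belongs to
        (2–5), or ``None`` for DC.
    """

    label: str
    kind: str
    left: float = 0.0
    peak: float = 0.0
    right: float = 1.0
    granularity: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("triangular", "dont_care"):
            raise ValueError(f"unknown membership kind {self.kind!r}")
        if self.kind == "triangular":
            if not (0.0 <= self.left <= self.peak <= self.right <= 1.0):
                raise ValueError(
                    f"breakpoints must satisfy 0 <= left <= peak <= right <= 1, "
                    f"got ({self.left}, {self.peak}, {self.right})"
                )

    @property
    def is_dont_care(self) -> bool:
        return self.kind == "dont_care"

    @property
    def term(self) -> str:
        """Plain-language term, e.g. ``"relatively small"`` for MS tags."""
        if self.is_dont_care:
            return "don't care"
        tag = self.label.rstrip("0123456789")
        return LINGUISTIC_TERMS[tag]

    def membership(self, x):
        """Membership degree of ``x`` (scalar or array) in this set.

        ``x`` must lie in [0, 1]; NaN entries denote missing measurements
        and evaluate to 1 (a missing value imposes no constraint, so the
        product compatibility stays defined).
        """
        arr = np.asarray(x, dtype=float)
        finite = ~np.isnan(arr)
        if np.any((arr[finite] < 0.0) | (arr[finite] > 1.0)):
            raise ValueError(
                "membership input outside [0, 1]; normalize data first"
            )
        if self.is_dont_care:
            out = np.ones_like(arr)
            return float(out) if np.isscalar(x) else out

        out = np.zeros_like(arr)
        left, peak, right = self.left, self.peak, self.right
        if peak > left:
            rising = finite & (arr >= left) & (arr < peak)
            out[rising] = (arr[rising] - left) / (peak - left)
        if right > peak:
            falling = finite & (arr > peak) & (arr <= right)
            out[falling] = (right - arr[falling]) / (right - peak)
        out[finite & (arr == peak)] = 1.0
        out[~finite] = 1.0
        return float(out) if np.isscalar(x) else out

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "kind": self.kind,
            "left": self.left,
            "peak": self.peak,
            "right": self.right,
            "granularity": self.granularity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipFunction":
        return cls(**d)


def build_partition(k: int) -> list[MembershipFunction]:
    """Build the homogeneous Ruspini partition of [0, 1] at granularity ``k``.

    The ``k`` triangular functions have peaks at ``i/(k-1)``; each interior
    function's support spans its two neighbouring peaks, and the boundary
    functions are half-triangles clipped to [0, 1]. Memberships sum to 1 at
    every point of the interval.
    """
    if k not in VALID_GRANULARITIES:
        raise ValueError(f"granularity must be one of {VALID_GRANULARITIES}, got {k}")
    step = 1.0 / (k - 1)
    out = []
    for i, tag in enumerate(_PARTITION_TAGS[k]):
        peak = i * step
        out.append(
            MembershipFunction(
                label=f"{tag}{k}",
                kind="triangular",
                left=max(0.0, peak - step),
                peak=peak,
                right=min(1.0, peak + step),
                granularity=k,
            )
        )
    return out


@dataclass(frozen=True)
class Vocabulary:
    """Ordered, indexed collection of the 15 antecedent fuzzy sets.

    Index 0 is the DC set; indices 1–14 are the triangular sets of the
    granularity-2 through granularity-5 partitions, small to large within
    each partition. Serialized rule bases refer to these indices, so the
    ordering is part of the on-disk contract.
    """

    functions: tuple[MembershipFunction, ...]

    DC_INDEX = 0

    def __post_init__(self) -> None:
        n_dc = sum(f.is_dont_care for f in self.functions)
        if n_dc != 1 or not self.functions[0].is_dont_care:
            raise ValueError("vocabulary must hold exactly one DC set at index 0")

    def __len__(self) -> int:
        return len(self.functions)

    def __getitem__(self, i: int) -> MembershipFunction:
        return self.functions[i]

    def __iter__(self) -> Iterator[MembershipFunction]:
        return iter(self.functions)

    def index_of(self, label: str) -> int:
        for i, f in enumerate(self.functions):
            if f.label == label:
                return i
        raise KeyError(f"no membership function labelled {label!r}")

    @property
    def non_dc_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.functions) if not f.is_dont_care]

    def membership_matrix(self, x: Sequence[float] | np.ndarray) -> np.ndarray:
        """Memberships of the values ``x`` in every set: shape (len(x), 15)."""
        arr = np.asarray(x, dtype=float)
        return np.column_stack([f.membership(arr) for f in self.functions])

    def to_json(self) -> str:
        payload = [
            {"index": i, **f.to_dict()} for i, f in enumerate(self.functions)
        ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        payload = json.loads(text)
        payload.sort(key=lambda d: d["index"])
        fns = tuple(
            MembershipFunction.from_dict({k: v for k, v in d.items() if k != "index"})
            for d in payload
        )
        return cls(functions=fns)


def build_vocabulary() -> Vocabulary:
    """The fixed 15-set vocabulary: DC plus the four partitions (k = 2..5)."""
    fns = [MembershipFunction(label=DC_LABEL, kind="dont_care")]
    for k in VALID_GRANULARITIES:
        fns.extend(build_partition(k))
    return Vocabulary(functions=tuple(fns))
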