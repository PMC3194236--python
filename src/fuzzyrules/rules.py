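"""Heuristic induction of short weighted fuzzy rules from training data.

A candidate rule has the form

    If x_i is A_i and ... then Class c with CF,

where each antecedent slot holds one of the 15 vocabulary sets (the DC set
imposing no constraint). For an antecedent A and a pattern x the
*compatibility* is the product of per-feature memberships. The *confidence*
of "A ⇒ class h" is the class-h share of the antecedent's total
compatibility mass over the training set; the *support* is that class mass
divided by the number of training patterns m. The consequent is the class of
maximum confidence, and for two-class problems the rule weight (certainty
factor) is the difference of the two class confidences — 1 when the
antecedent's subspace is pure, 0 when it is uninformative.

Candidate generation enumerates every antecedent touching at most
``max_rule_length`` features (all non-DC label assignments over every
feature subset of that size), drops antecedents that cover no pattern, have
tied confidences or zero weight, filters by minimum confidence and support,
and keeps the top Q/2 rules per consequent class under a pre-screening
criterion (confidence, support, or their product).
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .partitions import Vocabulary

__all__ = [
    "Antecedent",
    "CandidateRule",
    "CandidatePool",
    "EmptySubspaceError",
    "EmptyPoolError",
    "compatibility",
    "confidence",
    "support",
    "consequent",
    "rule_weight",
    "enumerate_candidates",
    "SCREENING_CRITERIA",
]

logger = logging.getLogger(__name__)

CLASSES = (1, -1)
SCREENING_CRITERIA = ("confidence", "support", "product")


class EmptySubspaceError(ValueError):
    """The antecedent covers no training pattern; no rule can be induced."""


class EmptyPoolError(ValueError):
    """No candidate rule survived pre-screening for either class."""


@dataclass(frozen=True)
class Antecedent:
    """Vocabulary indices per feature; the DC index (0) means unconstrained."""

    conditions: tuple[int, ...]

    @property
    def length(self) -> int:
        """Number of non-DC conditions (DC slots do not count)."""
        return sum(1 for c in self.conditions if c != Vocabulary.DC_INDEX)

    @property
    def active_features(self) -> tuple[int, ...]:
        return tuple(
            i for i, c in enumerate(self.conditions) if c != Vocabulary.DC_INDEX
        )


@dataclass(frozen=True)
class CandidateRule:
    antecedent: Antecedent
    consequent_class: int
    confidence: float
    support: float
    weight: float

    @property
    def length(self) -> int:
        return self.antecedent.length

    def to_dict(self) -> dict:
        return {
            "antecedent": list(self.antecedent.conditions),
            "consequent_class": self.consequent_class,
            "confidence": self.confidence,
            "support": self.support,
            "weight": self.weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateRule":
        return cls(
            antecedent=Antecedent(conditions=tuple(d["antecedent"])),
            consequent_class=int(d["consequent_class"]),
            confidence=float(d["confidence"]),
            support=float(d["support"]),
            weight=float(d["weight"]),
        )


@dataclass
class CandidatePool:
    """The pre-screened candidate rules, balanced across consequent classes."""

    rules: list[CandidateRule]
    criterion: str
    min_confidence: float
    min_support: float
    q_requested: int
    shortfall: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def by_class(self, c: int) -> list[CandidateRule]:
        return [r for r in self.rules if r.consequent_class == c]

    def to_json(self) -> str:
        return json.dumps(
            {
                "criterion": self.criterion,
                "min_confidence": self.min_confidence,
                "min_support": self.min_support,
                "q_requested": self.q_requested,
                "shortfall": {str(k): v for k, v in self.shortfall.items()},
                "rules": [r.to_dict() for r in self.rules],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CandidatePool":
        d = json.loads(text)
        return cls(
            rules=[CandidateRule.from_dict(r) for r in d["rules"]],
            criterion=d["criterion"],
            min_confidence=d["min_confidence"],
            min_support=d["min_support"],
            q_requested=d["q_requested"],
            shortfall={int(k): v for k, v in d["shortfall"].items()},
        )


def _pattern_matrix(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def compatibility(a: Antecedent, x, v: Vocabulary):
    """Product of per-feature memberships of pattern(s) ``x`` with ``a``.

    ``x`` may be one pattern (1-D) or a stack of patterns (2-D); DC slots
    contribute a factor of 1, as do missing (NaN) measurements.
    """
    X = _pattern_matrix(x)
    if X.shape[1] != len(a.conditions):
        raise ValueError(
            f"pattern has {X.shape[1]} features, antecedent expects "
            f"{len(a.conditions)}"
        )
    comp = np.ones(X.shape[0])
    for feat, cond in enumerate(a.conditions):
        if cond != Vocabulary.DC_INDEX:
            comp *= v[cond].membership(X[:, feat])
    return float(comp[0]) if np.asarray(x).ndim == 1 else comp


def _class_masses(
    a: Antecedent, data: ExpressionDataset, v: Vocabulary
) -> tuple[float, float]:
    comp = compatibility(a, data.values, v)
    return (
        float(comp[data.labels == 1].sum()),
        float(comp[data.labels == -1].sum()),
    )


def confidence(a: Antecedent, h: int, data: ExpressionDataset, v: Vocabulary) -> float:
    """Class-h share of the antecedent's compatibility mass."""
    pos, neg = _class_masses(a, data, v)
    total = pos + neg
    if total == 0.0:
        raise EmptySubspaceError("antecedent covers no training pattern")
    return (pos if h == 1 else neg) / total


def support(a: Antecedent, h: int, data: ExpressionDataset, v: Vocabulary) -> float:
    """Class-h compatibility mass divided by the number of training patterns."""
    pos, neg = _class_masses(a, data, v)
    return (pos if h == 1 else neg) / data.m


def consequent(a: Antecedent, data: ExpressionDataset, v: Vocabulary) -> int | None:
    """Class of maximum confidence; None if uncovered or exactly tied.

    Maximizing support gives the same answer (shared denominator), so a
    tie in confidence is also a tie in support and yields no rule.
    """
    pos, neg = _class_masses(a, data, v)
    if pos + neg == 0.0 or pos == neg:
        return None
    return 1 if pos > neg else -1


def rule_weight(a: Antecedent, c: int, data: ExpressionDataset, v: Vocabulary) -> float:
    """Certainty factor for binary problems: winning minus losing confidence."""
    conf_c = confidence(a, c, data, v)
    return conf_c - (1.0 - conf_c)


def _criterion_value(criterion: str, conf: np.ndarray, supp: np.ndarray) -> np.ndarray:
    if criterion == "confidence":
        return conf
    if criterion == "support":
        return supp
    if criterion == "product":
        return conf * supp
    raise ValueError(
        f"criterion must be one of {SCREENING_CRITERIA}, got {criterion!r}"
    )


def enumerate_candidates(
    data: ExpressionDataset,
    v: Vocabulary,
    max_rule_length: int = 3,
    min_confidence: float = 0.6,
    min_support: float = 0.05,
    q: int = 300,
    criterion: str = "product",
) -> CandidatePool:
    """Enumerate, score and pre-screen short candidate rules.

    All antecedents with 1..max_rule_length non-DC conditions over the
    dataset's features are scored in one vectorized pass per feature
    subset. Survivors of the confidence/support thresholds are grouped by
    consequent class, sorted by the pre-screening criterion (descending)
    and the top q/2 per class returned; per-class shortfalls are allowed
    and recorded.
    """
    if q % len(CLASSES) != 0:
        raise ValueError(f"q must be divisible by {len(CLASSES)}")
    if max_rule_length < 1:
        raise ValueError("max_rule_length must be >= 1")
    if criterion not in SCREENING_CRITERIA:
        raise ValueError(
            f"criterion must be one of {SCREENING_CRITERIA}, got {criterion!r}"
        )
    data.require_both_classes()

    m, n = data.values.shape
    non_dc = v.non_dc_indices
    k = len(non_dc)
    # per-feature membership of every pattern in every non-DC set: (m, k)
    mu = [v.membership_matrix(data.values[:, f])[:, non_dc] for f in range(n)]
    is_pos = data.labels == 1

    found: dict[int, list[tuple[float, tuple[int, ...], float, float, float]]] = {
        1: [],
        -1: [],
    }
    for length in range(1, min(max_rule_length, n) + 1):
        label_shape = (k,) * length
        for feats in itertools.combinations(range(n), length):
            comp = mu[feats[0]]
            for f in feats[1:]:
                comp = comp[:, :, None] * mu[f][:, None, :]
                comp = comp.reshape(m, -1)
            pos_mass = comp[is_pos].sum(axis=0)
            tot_mass = comp.sum(axis=0)
            neg_mass = tot_mass - pos_mass
            covered = tot_mass > 0.0
            win_pos = pos_mass > neg_mass
            win_mass = np.where(win_pos, pos_mass, neg_mass)
            with np.errstate(invalid="ignore", divide="ignore"):
                conf = np.where(covered, win_mass / np.where(covered, tot_mass, 1.0), 0.0)
            supp = win_mass / m
            cf = 2.0 * conf - 1.0
            keep = (
                covered
                & (pos_mass != neg_mass)
                & (conf >= min_confidence)
                & (supp >= min_support)
                & (cf > 0.0)
            )
            if not keep.any():
                continue
            score = _criterion_value(criterion, conf, supp)
            for flat in np.flatnonzero(keep):
                combo = np.unravel_index(flat, label_shape)
                conditions = [0] * n
                for f, lab in zip(feats, combo):
                    conditions[f] = non_dc[lab]
                found[1 if win_pos[flat] else -1].append(
                    (
                        float(score[flat]),
                        tuple(conditions),
                        float(conf[flat]),
                        float(supp[flat]),
                        float(cf[flat]),
                    )
                )

    per_class = q // len(CLASSES)
    rules: list[CandidateRule] = []
    shortfall: dict[int, int] = {}
    for c in CLASSES:
        group = sorted(found[c], key=lambda t: (-t[0], t[1]))
        if len(group) < per_class:
            shortfall[c] = per_class - len(group)
            warnings.warn(
                f"class {c}: only {len(group)} candidate rules survive "
                f"pre-screening (requested {per_class})",
                stacklevel=2,
            )
        for score_val, conditions, conf_val, supp_val, cf_val in group[:per_class]:
            rules.append(
                CandidateRule(
                    antecedent=Antecedent(conditions=conditions),
                    consequent_class=c,
                    confidence=conf_val,
                    support=supp_val,
                    weight=cf_val,
                )
            )
    if not rules:
        raise EmptyPoolError(
            f"no candidate rule passed min_confidence={min_confidence}, "
            f"min_support={min_support} for either class"
        )
    logger.info(
        "candidate pool: %d rules (%d requested), shortfall %s",
        len(rules),
        q,
        shortfall or "none",
    )
    return CandidatePool(
        rules=rules,
        criterion=criterion,
        min_confidence=min_confidence,
        min_support=min_support,
        q_requested=q,
        shortfall=shortfall,
    )
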