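"""Single-winner fuzzy classification and linguistic rule rendering.

A rule base S classifies a pattern x by the single winner rule: the rule
maximizing compatibility(x) × CF. The prediction is the winner's consequent
class; when no rule has a positive score the pattern is rejected, and a
rejection counts as a misclassification when scoring. Ties between rules of
the same class resolve to the lowest rule index; an exact tie across classes
is rejected (the conservative convention for winner-take-all inference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset
from .partitions import Vocabulary, build_vocabulary
from .rules import CandidateRule, compatibility

__all__ = ["RuleBase", "Prediction", "classify", "evaluate", "render_rules",
           "score_matrix", "DEFAULT_CLASS_NAMES"]

REJECT = "reject"
DEFAULT_CLASS_NAMES = {1: "Cancer", -1: "Normal"}


@dataclass
class RuleBase:
    """A concrete classifier: selected rules plus the vocabulary and features."""

    rules: list[CandidateRule]
    vocabulary: Vocabulary
    feature_names: list[str]
    class_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        n = len(self.feature_names)
        for r in self.rules:
            if len(r.antecedent.conditions) != n:
                raise ValueError(
                    "rule antecedent length does not match feature count"
                )
        if self.class_names is None:
            self.class_names = dict(DEFAULT_CLASS_NAMES)

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def total_length(self) -> int:
        """Total number of antecedent conditions across rules (NOA)."""
        return sum(r.length for r in self.rules)

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "class_names": {str(k): v for k, v in self.class_names.items()},
                "rules": [r.to_dict() for r in self.rules],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RuleBase":
        d = json.loads(text)
        return cls(
            rules=[CandidateRule.from_dict(r) for r in d["rules"]],
            vocabulary=build_vocabulary(),
            feature_names=d["feature_names"],
            class_names={int(k): v for k, v in d["class_names"].items()},
        )


@dataclass(frozen=True)
class Prediction:
    label: int | str  # 1, -1, or "reject"
    winner_rule_index: int | None
    winner_score: float


def score_matrix(S: RuleBase, X: np.ndarray) -> np.ndarray:
    """Compatibility × CF of every pattern (rows) with every rule (columns)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], len(S.rules)))
    for j, r in enumerate(S.rules):
        out[:, j] = compatibility(r.antecedent, X, S.vocabulary) * r.weight
    return out


def _resolve(S: RuleBase, scores: np.ndarray) -> Prediction:
    best = scores.max() if scores.size else 0.0
    if best <= 0.0:
        return Prediction(label=REJECT, winner_rule_index=None, winner_score=0.0)
    at_max = np.flatnonzero(scores == best)
    classes = {S.rules[j].consequent_class for j in at_max}
    if len(classes) > 1:
        return Prediction(label=REJECT, winner_rule_index=None, winner_score=float(best))
    w = int(at_max[0])
    return Prediction(
        label=S.rules[w].consequent_class,
        winner_rule_index=w,
        winner_score=float(best),
    )


def classify(S: RuleBase, x) -> Prediction:
    """Classify one pattern by the single winner rule."""
    if not S.rules:
        raise ValueError("empty rule base")
    scores = score_matrix(S, x)[0]
    return _resolve(S, scores)


def evaluate(S: RuleBase, data: ExpressionDataset) -> tuple[int, float]:
    """Number of correctly classified patterns (NCCP) and accuracy.

    Rejected patterns count as errors; accuracy = NCCP / m.
    """
    if data.m == 0:
        raise ValueError("empty dataset")
    scores = score_matrix(S, data.values)
    nccp = 0
    for p in range(data.m):
        pred = _resolve(S, scores[p])
        if pred.label == data.labels[p]:
            nccp += 1
    return nccp, nccp / data.m


def render_rules(S: RuleBase) -> str:
    """Render rules as sentences plus a grid with "–" for don't-care slots.

    Each sentence follows the template
    ``If the feature F is “large” and ..., then the sample is Cancer with
    CF=99.99%.``; only non-DC conditions appear, and an all-DC rule is
    flagged as unconditional.
    """
    sentences = []
    for i, r in enumerate(S.rules, start=1):
        conds = [
            f"the feature {S.feature_names[f]} is "
            f"“{S.vocabulary[c].term}”"
            for f, c in zip(range(len(S.feature_names)), r.antecedent.conditions)
            if c != Vocabulary.DC_INDEX
        ]
        cls = S.class_names[r.consequent_class]
        cf_pct = f"{r.weight * 100:.2f}%"
        if conds:
            sentences.append(
                f"Rule {i}: If {' and '.join(conds)}, "
                f"then the sample is {cls} with CF={cf_pct}."
            )
        else:
            sentences.append(
                f"Rule {i}: (no antecedent conditions) "
                f"then the sample is {cls} with CF={cf_pct}."
            )

    # Table-style grid over the features any rule actually uses
    used = sorted(
        {f for r in S.rules for f in r.antecedent.active_features}
    )
    header = [""] + [S.feature_names[f] for f in used] + ["CF", "Class"]
    grid_rows = [header]
    for i, r in enumerate(S.rules, start=1):
        cells = [f"Rule {i}"]
        for f in used:
            c = r.antecedent.conditions[f]
            cells.append("–" if c == Vocabulary.DC_INDEX else S.vocabulary[c].label)
        cells.append(f"{r.weight:.4f}")
        cells.append(S.class_names[r.consequent_class])
        grid_rows.append(cells)
    widths = [max(len(row[j]) for row in grid_rows) for j in range(len(header))]
    grid = "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in grid_rows
    )
    return "\n".join(sentences) + "\n\n" + grid + "\n"
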