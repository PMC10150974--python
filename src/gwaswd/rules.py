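"""Human-readable decision rules from a trained random forest.

The best-performing tree (highest validation accuracy; ties favour the
tree with fewer leaves, then the lower tree index) is unrolled into one
rule per root-to-leaf path.  On one-hot genotype features a split at
0.5 reads naturally as a genotype statement: indicator = 1 renders as
``rs705904 = CC`` and indicator = 0 as ``rs2075650 != AA``.  The rule
set is mutually exclusive and exhaustive by construction, so applying
it reproduces the source tree's predictions exactly.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .models import RandomForestVoteClassifier

__all__ = ["Condition", "Rule", "RuleSet", "extract_rules", "apply_rules"]


@dataclasses.dataclass(frozen=True)
class Condition:
    feature: str  # one-hot feature name, e.g. "rs705904_CC"
    value: int  # 0 or 1

    def render(self) -> str:
        snp, _, genotype = self.feature.rpartition("_")
        op = "=" if self.value == 1 else "!="
        return f"{snp} {op} {genotype}"


@dataclasses.dataclass
class Rule:
    conditions: tuple[Condition, ...]
    predicted_class: int
    support: int  # training samples reaching the leaf
    confidence: float  # leaf purity

    def matches(self, sample: dict) -> bool:
        for c in self.conditions:
            if c.feature not in sample:
                raise KeyError(f"sample lacks feature {c.feature}")
            if int(sample[c.feature]) != c.value:
                return False
        return True

    def render(self, class_names: dict[int, str] | None = None) -> str:
        cls = (class_names or {}).get(self.predicted_class, str(self.predicted_class))
        if self.conditions:
            body = " AND ".join(c.render() for c in self.conditions)
        else:
            body = "TRUE"
        return (f"IF {body} THEN {cls} "
                f"[support={self.support}, confidence={self.confidence:.3f}]")


@dataclasses.dataclass
class RuleSet:
    rules: list[Rule]
    source_tree: int
    tree_accuracy: float
    feature_names: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_tree": self.source_tree,
                "tree_accuracy": self.tree_accuracy,
                "rules": [
                    {
                        "conditions": [dataclasses.asdict(c) for c in r.conditions],
                        "predicted_class": r.predicted_class,
                        "support": r.support,
                        "confidence": r.confidence,
                    }
                    for r in self.rules
                ],
            },
            indent=2,
        )

    def render(self, class_names: dict[int, str] | None = None) -> str:
        return "\n".join(r.render(class_names) for r in self.rules)


def _tree_rules(tree, feature_names, classes, control_class) -> list[Rule]:
    t = tree.tree_
    rules: list[Rule] = []

    def walk(node: int, conditions: tuple[Condition, ...]):
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0]
            # sklearn >= 1.3 stores fractions when trained with bootstrap
            order = np.argsort(counts)[::-1]
            if len(order) > 1 and counts[order[0]] == counts[order[1]]:
                tied = [classes[i] for i in order[:2]]
                pred = control_class if control_class in tied else min(tied)
            else:
                pred = classes[order[0]]
            # weighted count = bootstrap-weighted training rows at the leaf
            support = int(round(t.weighted_n_node_samples[node]))
            conf = float(counts.max() / counts.sum()) if counts.sum() else 0.0
            rules.append(Rule(conditions, int(pred), support, conf))
            return
        f = feature_names[t.feature[node]]
        # binary indicators: x <= 0.5 is the "= 0" branch
        walk(t.children_left[node], conditions + (Condition(f, 0),))
        walk(t.children_right[node], conditions + (Condition(f, 1),))

    walk(0, ())
    return rules


def extract_rules(
    rf: RandomForestVoteClassifier, X_val: np.ndarray, y_val: np.ndarray,
    feature_names: list[str],
) -> RuleSet:
    """Unroll the forest's best tree (by validation accuracy) into rules."""
    if not hasattr(rf, "forest_"):
        raise ValueError("untrained model")
    if len(np.asarray(y_val)) == 0:
        raise ValueError("validation set is empty")
    X_val = np.asarray(X_val)
    y_val = np.asarray(y_val)
    control = int(rf.classes_[0])

    classes_lookup = rf.forest_.classes_
    best, best_key = None, None
    for i, tree in enumerate(rf.forest_.estimators_):
        pred = classes_lookup.take(tree.predict(X_val).astype(int))
        acc = float((pred == y_val).mean())
        key = (-acc, tree.tree_.n_leaves, i)  # ties: fewer leaves, lower index
        if best_key is None or key < best_key:
            best, best_key = i, key
    tree = rf.forest_.estimators_[best]
    classes = rf.forest_.classes_.astype(int)
    rules = _tree_rules(tree, feature_names, classes, control)
    return RuleSet(rules, best, -best_key[0], list(feature_names))


def apply_rules(ruleset: RuleSet, sample) -> tuple[int, int]:
    """Classify one encoded sample; returns (predicted class, rule index).

    ``sample`` is a mapping feature name -> 0/1 (or an array aligned with
    the rule set's feature names).  Exactly one rule matches.
    """
    if not isinstance(sample, dict):
        arr = np.asarray(sample).ravel()
        sample = dict(zip(ruleset.feature_names, arr))
    matches = [i for i, r in enumerate(ruleset.rules) if r.matches(sample)]
    if len(matches) != 1:
        raise AssertionError(
            f"{len(matches)} rules matched; rule set must be a partition"
        )
    i = matches[0]
    return ruleset.rules[i].predicted_class, i
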