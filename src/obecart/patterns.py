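"""Rule extraction and subgroup comparison for fitted ordinal trees.

Every leaf of a fitted tree corresponds to a *pattern*: the conjunction
of conditions on its root-to-leaf path, together with the class
distribution and support of the training rows that satisfied it.
Patterns partition the feature space, so they read directly as employee
subgroups ("month = 3 AND disciplinary_failure = no AND age > 35 ...").

The intervention-guidance workflow built on top:

1. rank patterns by their probability of reaching at least a target
   class (the high-risk subgroups);
2. for a chosen pattern, find the *complementary subgroup* -- same path
   but with the final condition negated, i.e. the sibling branch;
3. test whether a subgroup's class distribution differs significantly
   from a reference (the complementary subgroup or the full dataset)
   with a goodness-of-fit test.

The comparison uses Pearson's chi-square when all expected counts are at
least 5 and a seeded Monte-Carlo multinomial p-value otherwise, which
keeps the test valid at the small supports typical of deep-tree leaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .core import (
    NUMERIC,
    ClassDistribution,
    ClassSpec,
    OrdinalTreeModel,
    TreeNode,
    ValidationError,
)


@dataclass(frozen=True)
class Condition:
    """One atomic condition: feature <relation> value, relation in {<=, >, =, !=}."""

    feature: str
    relation: str
    value: float | str

    def __str__(self) -> str:
        v = f"{self.value:g}" if isinstance(self.value, float) else self.value
        return f"{self.feature} {self.relation} {v}"

    def negated(self) -> "Condition":
        flip = {"<=": ">", ">": "<=", "=": "!=", "!=": "="}
        return Condition(self.feature, flip[self.relation], self.value)


@dataclass(frozen=True)
class Pattern:
    """A root-to-leaf condition conjunction with its leaf statistics.

    ``leaf_id`` encodes the path from the root as a string of L/R steps
    ("" for the root itself), which identifies the node unambiguously.
    """

    conditions: tuple[Condition, ...]
    distribution: ClassDistribution
    support: int
    leaf_id: str


@dataclass(frozen=True)
class SubgroupComparison:
    pattern: Pattern | None
    reference: ClassDistribution
    p_value: float
    statistic: float
    test: str


def _edge_condition(node: TreeNode, left: bool) -> Condition:
    if node.kind == NUMERIC:
        rel = "<=" if left else ">"
        return Condition(node.feature, rel, float(node.threshold))
    rel = "=" if left else "!="
    return Condition(node.feature, rel, str(node.category))


def extract_patterns(model: OrdinalTreeModel) -> list[Pattern]:
    """One pattern per leaf, in left-to-right tree order.

    The patterns partition the feature space and their supports sum to
    the training size.
    """
    out: list[Pattern] = []
    stack: list[tuple[TreeNode, tuple[Condition, ...], str]] = [
        (model.root, (), "")
    ]
    while stack:
        node, conds, path = stack.pop()
        if node.is_leaf:
            out.append(Pattern(conds, node.distribution, node.support, path))
            continue
        stack.append(
            (node.right, conds + (_edge_condition(node, False),), path + "R")
        )
        stack.append(
            (node.left, conds + (_edge_condition(node, True),), path + "L")
        )
    return out


def node_by_path(model: OrdinalTreeModel, path: str) -> TreeNode:
    node = model.root
    for step in path:
        if node.is_leaf:
            raise ValidationError(f"path {path!r} descends past a leaf")
        node = node.left if step == "L" else node.right
    return node


def probability_at_least(dist: ClassDistribution, target_class: int) -> float:
    """P(class >= target_class) under a distribution."""
    return float(dist.probs[target_class - 1 :].sum())


def find_high_risk_subgroups(
    model: OrdinalTreeModel, target_class: int, min_support: int = 1
) -> list[Pattern]:
    """Leaf patterns with support >= min_support, ranked by descending
    P(class >= target_class); ties break by larger support, then by path
    id for determinism."""
    n = model.class_spec.n
    if not (1 <= target_class <= n):
        raise ValidationError(f"target_class {target_class} outside 1..{n}")
    pats = [p for p in extract_patterns(model) if p.support >= min_support]
    return sorted(
        pats,
        key=lambda p: (
            -probability_at_least(p.distribution, target_class),
            -p.support,
            p.leaf_id,
        ),
    )


def complementary_subgroup(model: OrdinalTreeModel, pattern: Pattern) -> Pattern:
    """The sibling subgroup: same path, final condition negated.

    When the sibling is itself a leaf the result is that leaf's exact
    pattern.  When the sibling is a subtree, the result aggregates the
    whole subtree: its distribution/support are the sibling node's (the
    weighted mean of its leaves) under the negated final condition.
    """
    if not pattern.leaf_id:
        raise ValidationError("the root pattern has no complementary subgroup")
    parent = node_by_path(model, pattern.leaf_id[:-1])
    went_left = pattern.leaf_id[-1] == "L"
    sibling = parent.right if went_left else parent.left
    sib_path = pattern.leaf_id[:-1] + ("R" if went_left else "L")
    conds = pattern.conditions[:-1] + (_edge_condition(parent, not went_left),)
    return Pattern(conds, sibling.distribution, sibling.support, sib_path)


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------


def _chi2_stat(counts: np.ndarray, expected: np.ndarray) -> float:
    """Pearson chi-square; a zero-expected cell with observations -> inf."""
    stat = 0.0
    for o, e in zip(counts, expected):
        if e == 0:
            if o > 0:
                return float("inf")
            continue
        stat += (o - e) ** 2 / e
    return float(stat)


def compare_distributions(
    a: ClassDistribution,
    b: ClassDistribution,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> SubgroupComparison:
    """Goodness-of-fit test of subgroup *a*'s counts against reference *b*.

    Pearson's chi-square when every expected count is >= 5; otherwise a
    seeded Monte-Carlo multinomial p-value
    ``(1 + #{simulated stat >= observed}) / (n_resamples + 1)``, which
    also covers references putting zero mass on observed categories.
    """
    if a.support < 1:
        raise ValidationError("subgroup must have support >= 1")
    counts = a.counts().astype(float)
    expected = b.probs * a.support
    if np.all(expected >= 5):
        res = stats.chisquare(counts, expected)
        return SubgroupComparison(
            None, b, float(res.pvalue), float(res.statistic), "chi2"
        )
    rng = np.random.default_rng(seed)
    obs = _chi2_stat(counts, expected)
    sims = rng.multinomial(a.support, b.probs, size=n_resamples).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (sims - expected) ** 2 / expected
    terms[:, expected == 0] = 0.0  # simulated counts are 0 there by construction
    sim_stats = terms.sum(axis=1)
    n_ge = int((sim_stats >= obs - 1e-12).sum())
    p = (1 + n_ge) / (n_resamples + 1)
    return SubgroupComparison(None, b, float(p), float(obs), "chi2-monte-carlo")


# ---------------------------------------------------------------------------
# feature influence and rendering
# ---------------------------------------------------------------------------


def feature_influence(model: OrdinalTreeModel) -> dict[str, dict]:
    """Depth-of-first-use and support-weighted total gain per feature.

    ``min_depth`` (0 = root) orders features by how early the tree relies
    on them; ``total_gain`` sums gain x (node support / training size)
    over all nodes splitting on the feature.
    """
    total = model.root.support
    out: dict[str, dict] = {}
    stack = [(model.root, 0)]
    while stack:
        node, depth = stack.pop()
        if node.is_leaf:
            continue
        rec = out.setdefault(
            node.feature, {"min_depth": depth, "total_gain": 0.0, "n_splits": 0}
        )
        rec["min_depth"] = min(rec["min_depth"], depth)
        rec["total_gain"] += (node.gain or 0.0) * node.support / total
        rec["n_splits"] += 1
        stack.append((node.left, depth + 1))
        stack.append((node.right, depth + 1))
    return out


def render_pattern(pattern: Pattern, class_spec: ClassSpec) -> str:
    """Human-readable one-liner: conditions, distribution in %, support."""
    conds = " AND ".join(str(c) for c in pattern.conditions) or "<all rows>"
    dist = ", ".join(f"{100 * p:.0f}%" for p in pattern.distribution.probs)
    return f"{conds} -> ({dist}), support {pattern.support}"


def write_patterns_jsonl(
    path: str | Path,
    patterns: list[Pattern],
    comparisons: dict[str, SubgroupComparison] | None = None,
) -> None:
    """Patterns as JSON Lines; optional per-pattern comparison p-values."""
    comparisons = comparisons or {}
    with open(path, "w") as fh:
        for p in patterns:
            doc = {
                "conditions": [
                    {"feature": c.feature, "relation": c.relation, "value": c.value}
                    for c in p.conditions
                ],
                "distribution": [float(x) for x in p.distribution.probs],
                "support": p.support,
                "leaf_id": p.leaf_id,
            }
            cmp = comparisons.get(p.leaf_id)
            if cmp is not None:
                doc["p_value"] = cmp.p_value
                doc["test"] = cmp.test
            fh.write(json.dumps(doc) + "\n")
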