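"""Ordinal CART induction driven by objective-based information gain.

The gain of a binary partition of a node's data D into (D_1, D_2) is::

    OBIG(c_s, D) = OBE(c_s, D) - sum_r (|D_r|/|D|) * OBE(c_s, D_r)

with the *same* selected class s in the parent and child terms, which
makes the gain non-negative (the fixed-weight OBE is concave in the
probability vector).  The tree greedily picks, over all features and all
candidate binary conditions, the split with the highest OBIG.

Candidate conditions follow standard CART practice: numeric features are
split at midpoints between consecutive distinct sorted values
("value <= t" routes left), categorical features one-category-vs-rest
("value = category" routes left).  The gain-ratio variant OBIGR (gain
over the split information of the full N_k-way partition) is exposed for
completeness but is not used by the binary CART path, where N_k = 2
makes the correction largely moot.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


import numpy as np
from scipy.special import xlogy

from .core import (
    CATEGORICAL,
    NUMERIC,
    ClassDistribution,
    OrdinalDataset,
    OrdinalTreeModel,
    TreeNode,
    ValidationError,
)
from .entropy import (
    SelectedClassStatistic,
    class_weights,
    obe_weighted,
    selected_class,
)

#: absolute tolerance when comparing gains, to keep tie-breaking immune to
#: float summation order
GAIN_TOL = 1e-12

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class SplitCandidate:
    """One candidate binary condition with its supports and (optional) gain."""

    feature: str
    kind: str
    threshold: float | None = None
    category: str | None = None
    gain: float | None = None
    left_support: int = 0
    right_support: int = 0


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration for :func:`fit`.

    alpha
        OBE normalization factor (> 0).  Default 2, the value used in the
        worked weight examples; tune per problem via grid search.
    statistic
        Selected-class statistic (kind + scope), default c_max: the tree
        then prioritizes isolating the highest ordinal class.
    max_depth / min_samples_split / min_samples_leaf / min_gain
        Standard CART stopping rules.  Defaults (unlimited depth, split
        down to 2 samples, leaves of 1, any positive gain) grow the full
        tree; no pruning is applied.
    seed
        Recorded for provenance.  Induction itself is deterministic:
        equal-gain ties break to the lowest schema feature index, then the
        smallest threshold / lexicographically first category.
    uniform_weights
        Debug hook: replace the OBE weights by the uniform vector 1/n,
        which makes the split ordering identical to classical
        Shannon-entropy CART.
    """

    alpha: float = 2.0
    statistic: SelectedClassStatistic = field(
        default_factory=lambda: SelectedClassStatistic("max")
    )
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    min_gain: float = 0.0
    seed: int = 0
    uniform_weights: bool = False

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValidationError("alpha must be > 0")
        if self.min_samples_split < 2:
            raise ValidationError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValidationError("min_samples_leaf must be >= 1")
        if self.min_gain < 0:
            raise ValidationError("min_gain must be >= 0")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValidationError("max_depth must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["statistic"] = {"kind": self.statistic.kind, "scope": self.statistic.scope}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        stat = d.pop("statistic", {"kind": "max", "scope": None})
        if isinstance(stat, str):
            stat = {"kind": stat, "scope": None}
        return cls(
            statistic=SelectedClassStatistic(stat["kind"], stat.get("scope")), **d
        )


# ---------------------------------------------------------------------------
# candidate enumeration and public gain functions
# ---------------------------------------------------------------------------


def enumerate_splits(data: OrdinalDataset, feature: str) -> list[SplitCandidate]:
    """All valid binary split candidates of *data* over one feature.

    Numeric: one threshold per midpoint between consecutive distinct
    sorted values.  Categorical: one candidate per observed category
    (category vs rest).  Candidates with an empty child are excluded, so a
    single-valued feature yields an empty list.  Gains are left unscored.
    """
    f = data.feature(feature)
    col = data.X[feature].to_numpy()
    out: list[SplitCandidate] = []
    if f.kind == NUMERIC:
        vals = np.sort(np.unique(col.astype(float)))
        for lo, hi in zip(vals[:-1], vals[1:]):
            t = (lo + hi) / 2.0
            left = int((col.astype(float) <= t).sum())
            out.append(
                SplitCandidate(feature, NUMERIC, threshold=float(t),
                               left_support=left, right_support=data.T - left)
            )
    else:
        for cat in sorted(set(col.astype(str))):
            left = int((col.astype(str) == cat).sum())
            if left == 0 or left == data.T:
                continue
            out.append(
                SplitCandidate(feature, CATEGORICAL, category=cat,
                               left_support=left, right_support=data.T - left)
            )
    return out


def split_masks(data: OrdinalDataset, split: SplitCandidate) -> np.ndarray:
    """Boolean mask of rows routed left by *split* (condition true)."""
    col = data.X[split.feature].to_numpy()
    if split.kind == NUMERIC:
        return col.astype(float) <= split.threshold
    return col.astype(str) == split.category


def obig(
    parent: OrdinalDataset, split: SplitCandidate, s: int, alpha: float
) -> float:
    """Objective-based information gain of a binary split.

    The selected class *s* is held fixed across the parent and child
    terms, so the result is >= 0 up to float rounding.
    """
    mask = split_masks(parent, split)
    n_left = int(mask.sum())
    if n_left == 0 or n_left == parent.T:
        raise ValidationError(
            f"split {split.feature!r} produces an empty child"
        )
    n = parent.class_spec.n
    w = class_weights(n, s, alpha).weights
    y0 = parent.y - 1
    parent_counts = np.bincount(y0, minlength=n)
    left_counts = np.bincount(y0[mask], minlength=n)
    right_counts = parent_counts - left_counts
    g = obe_weighted(parent_counts / parent.T, w)
    for c in (left_counts, right_counts):
        m = c.sum()
        g -= (m / parent.T) * obe_weighted(c / m, w)
    return float(g)


def obigr(parent: OrdinalDataset, feature: str, s: int, alpha: float) -> float:
    """OBIG ratio of the full N_k-way partition over a feature.

    The multiway gain is divided by the split information
    H_k(D) = -sum_r (|D_r|/|D|) log2(|D_r|/|D|).  A single-valued feature
    has zero split information and raises.
    """
    f = parent.feature(feature)
    col = parent.X[feature].to_numpy()
    keys = col.astype(float) if f.kind == NUMERIC else col.astype(str)
    values, inv = np.unique(keys, return_inverse=True)
    if len(values) < 2:
        raise ValidationError(
            f"feature {feature!r} has a single value: zero split information"
        )
    n = parent.class_spec.n
    w = class_weights(n, s, alpha).weights
    y0 = parent.y - 1
    g = obe_weighted(np.bincount(y0, minlength=n) / parent.T, w)
    h_k = 0.0
    for r in range(len(values)):
        sel = inv == r
        m = int(sel.sum())
        frac = m / parent.T
        g -= frac * obe_weighted(np.bincount(y0[sel], minlength=n) / m, w)
        h_k -= frac * np.log2(frac)
    return float(g / h_k)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _obe_rows(counts: np.ndarray, sizes: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized OBE for a stack of count vectors (one row per candidate)."""
    p = counts / sizes[:, None]
    return -(w * xlogy(p, p)).sum(axis=1) / _LN2


class _Columns:
    """Training-time columnar view: numeric floats, categoricals as codes."""

    def __init__(self, data: OrdinalDataset):
        self.features = data.schema
        self.values: dict[str, np.ndarray] = {}
        self.categories: dict[str, list[str]] = {}
        for f in data.schema:
            col = data.X[f.name].to_numpy()
            if f.kind == NUMERIC:
                self.values[f.name] = col.astype(float)
            else:
                cats = sorted(set(col.astype(str)))  # lexicographic candidate order
                lut = {c: i for i, c in enumerate(cats)}
                self.categories[f.name] = cats
                self.values[f.name] = np.array(
                    [lut[v] for v in col.astype(str)], dtype=np.int64
                )


def _best_split_numeric(
    v: np.ndarray, y0: np.ndarray, n: int, w: np.ndarray,
    parent_obe: float, msl: int,
) -> tuple[float, float] | None:
    """Best (gain, threshold) for one numeric feature at one node."""
    m = len(v)
    order = np.argsort(v, kind="stable")
    sv = v[order]
    boundaries = np.nonzero(sv[:-1] < sv[1:])[0]
    if len(boundaries) == 0:
        return None
    onehot = np.zeros((m, n))
    onehot[np.arange(m), y0[order]] = 1.0
    csum = onehot.cumsum(axis=0)
    left_counts = csum[boundaries]
    left_sizes = boundaries + 1
    right_sizes = m - left_sizes
    ok = (left_sizes >= msl) & (right_sizes >= msl)
    if not ok.any():
        return None
    left_counts = left_counts[ok]
    left_sizes = left_sizes[ok]
    right_sizes = right_sizes[ok]
    thresholds = (sv[boundaries[ok]] + sv[boundaries[ok] + 1]) / 2.0
    total = csum[-1]
    gains = (
        parent_obe
        - (left_sizes / m) * _obe_rows(left_counts, left_sizes, w)
        - (right_sizes / m) * _obe_rows(total - left_counts, right_sizes, w)
    )
    best = float(gains.max())
    j = int(np.argmax(gains >= best - GAIN_TOL))  # smallest qualifying threshold
    return float(gains[j]), float(thresholds[j])


def _best_split_categorical(
    codes: np.ndarray, y0: np.ndarray, n: int, n_cats: int, w: np.ndarray,
    parent_obe: float, msl: int,
) -> tuple[float, int] | None:
    """Best (gain, category code) for one categorical feature at one node."""
    m = len(codes)
    counts = np.zeros((n_cats, n))
    np.add.at(counts, (codes, y0), 1.0)
    sizes = counts.sum(axis=1)
    ok = (sizes >= msl) & (m - sizes >= msl)
    if not ok.any():
        return None
    cat_idx = np.nonzero(ok)[0]
    left_counts = counts[ok]
    left_sizes = sizes[ok]
    right_sizes = m - left_sizes
    total = counts.sum(axis=0)
    gains = (
        parent_obe
        - (left_sizes / m) * _obe_rows(left_counts, left_sizes, w)
        - (right_sizes / m) * _obe_rows(total - left_counts, right_sizes, w)
    )
    best = float(gains.max())
    j = int(np.argmax(gains >= best - GAIN_TOL))  # lexicographically first
    return float(gains[j]), int(cat_idx[j])


def fit(data: OrdinalDataset, config: TrainConfig | None = None) -> OrdinalTreeModel:
    """Grow an ordinal CART on *data* by recursive binary OBIG splitting.

    At each node the selected class is resolved per the configured
    statistic (for scope ``per_node`` the mode is recomputed on the node's
    own distribution and used in both parent and child terms of that
    node's gains), every candidate split over every feature is scored, and
    the maximizer taken.  Recursion stops at purity, the depth/size
    limits, or when the best gain does not exceed ``min_gain``.
    """
    config = config or TrainConfig()
    if data.T < 1:
        raise ValidationError("cannot fit a tree on an empty dataset")
    n = data.class_spec.n
    cols = _Columns(data)
    y0 = data.y - 1

    if config.uniform_weights:
        global_w = np.full(n, 1.0 / n)
        s_global = None
    else:
        s_global = _resolve_selected(
            np.bincount(y0, minlength=n), n, config.statistic, at_node=False
        )
        global_w = None

    def build(idx: np.ndarray, depth: int) -> tuple[TreeNode, tuple | None]:
        """One node; returns (node, (left_idx, right_idx) or None for a leaf)."""
        counts = np.bincount(y0[idx], minlength=n)
        support = len(idx)
        dist = ClassDistribution.from_counts(counts)
        leaf = TreeNode(dist, support, predicted=_predicted_class(counts))
        if (
            support < config.min_samples_split
            or (config.max_depth is not None and depth >= config.max_depth)
            or int((counts > 0).sum()) <= 1
        ):
            return leaf, None

        if config.uniform_weights:
            w = global_w
        else:
            if config.statistic.kind == "mode" and config.statistic.scope == "per_node":
                s = _resolve_selected(counts, n, config.statistic, at_node=True)
            else:
                s = s_global
            w = class_weights(n, s, config.alpha).weights

        parent_obe = obe_weighted(counts / support, w)
        yy = y0[idx]
        best_gain = -np.inf
        best: tuple | None = None  # (feature, kind, threshold-or-code)
        for f in cols.features:
            v = cols.values[f.name][idx]
            if f.kind == NUMERIC:
                res = _best_split_numeric(
                    v, yy, n, w, parent_obe, config.min_samples_leaf
                )
                if res is not None and res[0] > best_gain + GAIN_TOL:
                    best_gain = res[0]
                    best = (f.name, NUMERIC, res[1])
            else:
                res = _best_split_categorical(
                    v, yy, n, len(cols.categories[f.name]), w,
                    parent_obe, config.min_samples_leaf,
                )
                if res is not None and res[0] > best_gain + GAIN_TOL:
                    best_gain = res[0]
                    best = (f.name, CATEGORICAL, res[1])

        if best is None or best_gain <= config.min_gain + GAIN_TOL:
            return leaf, None

        name, kind, cond = best
        v = cols.values[name][idx]
        mask = (v <= cond) if kind == NUMERIC else (v == cond)
        node = TreeNode(
            dist,
            support,
            feature=name,
            kind=kind,
            threshold=float(cond) if kind == NUMERIC else None,
            category=cols.categories[name][cond] if kind == CATEGORICAL else None,
            gain=float(best_gain),
        )
        return node, (idx[mask], idx[~mask])

    # explicit stack: keeps deep trees clear of the interpreter recursion limit
    root, children = build(np.arange(data.T), 0)
    stack: list[tuple[TreeNode, str, np.ndarray, int]] = []
    if children is not None:
        stack += [(root, "left", children[0], 1), (root, "right", children[1], 1)]
    while stack:
        parent, side, idx, depth = stack.pop()
        node, children = build(idx, depth)
        setattr(parent, side, node)
        if children is not None:
            # a split node must not remain childless if we stop here
            stack += [
                (node, "left", children[0], depth + 1),
                (node, "right", children[1], depth + 1),
            ]
    return OrdinalTreeModel(root, config.to_dict(), data.class_spec, data.schema)


def _resolve_selected(
    counts: np.ndarray, n: int, stat: SelectedClassStatistic, at_node: bool
) -> int:
    del at_node  # mode resolution is identical; scope decides *which* counts
    return selected_class(
        ClassDistribution.from_counts(counts), n, stat
    )


def _predicted_class(counts: np.ndarray) -> int:
    """Argmax class of a count vector; ties break toward the higher class."""
    rev = counts[::-1]
    return len(counts) - int(np.argmax(rev))


# ---------------------------------------------------------------------------
# prediction and structure
# ---------------------------------------------------------------------------


def predict(model: OrdinalTreeModel, row) -> tuple[int, ClassDistribution]:
    """Route one row (mapping feature name -> value) to its leaf.

    Returns the leaf's predicted class index and class distribution.  A
    category unseen in training simply fails the equality condition and is
    routed to the right ("condition false") branch.
    """
    node = model.root
    while not node.is_leaf:
        try:
            val = row[node.feature]
        except (KeyError, IndexError):
            raise ValidationError(f"row is missing feature {node.feature!r}") from None
        if node.kind == NUMERIC:
            try:
                go_left = float(val) <= node.threshold
            except (TypeError, ValueError):
                raise ValidationError(
                    f"feature {node.feature!r}: cannot parse {val!r} as numeric"
                ) from None
        else:
            go_left = str(val) == node.category
        node = node.left if go_left else node.right
    return node.predicted, node.distribution


def predict_dataset(
    model: OrdinalTreeModel, data: OrdinalDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction: (class indices, T x n probability matrix)."""
    model_feats = {f.name for f in model.schema}
    data_feats = {f.name for f in data.schema}
    if not model_feats <= data_feats:
        raise ValidationError(
            f"dataset lacks model features {sorted(model_feats - data_feats)}"
        )
    T = data.T
    classes = np.zeros(T, dtype=np.int64)
    probs = np.zeros((T, model.class_spec.n))
    cols = {f.name: data.X[f.name].to_numpy() for f in model.schema}

    stack = [(model.root, np.arange(T))]
    while stack:
        node, idx = stack.pop()
        if len(idx) == 0:
            continue
        if node.is_leaf:
            classes[idx] = node.predicted
            probs[idx] = node.distribution.probs
            continue
        col = cols[node.feature][idx]
        if node.kind == NUMERIC:
            mask = col.astype(float) <= node.threshold
        else:
            mask = col.astype(str) == node.category
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return classes, probs


def tree_stats(model: OrdinalTreeModel) -> tuple[int, int, int]:
    """(leaf count, node count, depth); depth 0 for a single-leaf tree."""
    leaves = nodes = depth = 0
    stack = [(model.root, 0)]
    while stack:
        node, d = stack.pop()
        nodes += 1
        depth = max(depth, d)
        if node.is_leaf:
            leaves += 1
        else:
            stack.append((node.left, d + 1))
            stack.append((node.right, d + 1))
    return leaves, nodes, depth
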