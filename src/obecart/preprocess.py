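"""Target categorization, stratified holdout split and SMOTE balancing.

The default pipeline mirrors common practice for imbalanced ordinal
outcomes: bin a non-negative numeric target (absence hours) into ordered
classes using the 8-hour day / 40-hour week convention, split train/test
while preserving per-class proportions, then oversample the training
minorities with SMOTE until every class matches the majority count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    NUMERIC,
    OrdinalDataset,
    ValidationError,
)


@dataclass(frozen=True)
class HoursBinning:
    """Ordered boundaries mapping non-negative hours to class indices.

    With the default ``(0, 8, 40)`` and four classes:

    =============  =====  ============
    hours y        class  meaning
    =============  =====  ============
    y = 0            1    not absent
    0 < y < 8        2    hours
    8 <= y < 40      3    days
    y >= 40          4    weeks
    =============  =====  ============

    The first boundary is compared strictly (``y > b0`` leaves class 1,
    which is the point mass at zero absence); the rest inclusively
    (``y >= b_j``).  Every non-negative value maps to exactly one class.
    """

    boundaries: tuple[float, ...] = (0.0, 8.0, 40.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "boundaries", tuple(float(b) for b in self.boundaries)
        )
        if len(self.boundaries) < 1:
            raise ValidationError("binning needs at least one boundary")
        if any(a >= b for a, b in zip(self.boundaries, self.boundaries[1:])):
            raise ValidationError("binning boundaries must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) + 1


def categorize_hours(y: float, binning: HoursBinning = HoursBinning()) -> int:
    """Class index (1-based) of a non-negative hours value."""
    y = float(y)
    if y < 0:
        raise ValidationError(f"hours must be non-negative, got {y}")
    b = binning.boundaries
    cls = 1 + int(y > b[0])
    for bj in b[1:]:
        cls += int(y >= bj)
    return min(cls, binning.n_classes)


def stratified_split(
    data: OrdinalDataset, test_fraction: float, seed: int
) -> tuple[OrdinalDataset, OrdinalDataset]:
    """Distribution-preserving holdout split.

    Per-class test counts follow largest-remainder rounding of
    ``test_fraction * n_c`` (overall test size = ``round(fraction * T)``),
    so train and test class proportions differ from the parent's by at
    most one sample per class.  Selection within each class is a seeded
    shuffle; the two parts are disjoint and their union is the input.
    """
    if not (0 <= test_fraction < 1):
        raise ValidationError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = data.class_spec.n
    T = data.T
    total_test = int(np.floor(test_fraction * T + 0.5))
    counts = data.class_counts()
    quotas = test_fraction * counts
    base = np.floor(quotas).astype(int)
    remainders = quotas - base
    leftover = total_test - int(base.sum())
    # assign leftovers by descending remainder (ties: lower class first),
    # never exceeding a class's population
    order = sorted(range(n), key=lambda i: (-remainders[i], i))
    while leftover > 0:
        progressed = False
        for i in order:
            if leftover == 0:
                break
            if base[i] < counts[i]:
                base[i] += 1
                leftover -= 1
                progressed = True
        if not progressed:
            break

    test_idx: list[int] = []
    for i in range(n):
        members = np.nonzero(data.y == i + 1)[0]
        perm = rng.permutation(len(members))
        test_idx.extend(members[perm[: base[i]]].tolist())
    test_mask = np.zeros(T, dtype=bool)
    test_mask[test_idx] = True
    train = data.subset(np.nonzero(~test_mask)[0])
    test = data.subset(np.nonzero(test_mask)[0])
    return train, test


def smote_balance(
    data: OrdinalDataset,
    k: int = 5,
    seed: int = 0,
    categorical_strategy: str = "seed",
    duplicate_singletons: bool = False,
) -> OrdinalDataset:
    """Oversample every minority class up to the majority count (SMOTE).

    Synthetic rows interpolate numeric features uniformly on the segment
    between a minority sample and one of its *k* nearest minority
    neighbors; neighbor search uses Euclidean distance on numeric features
    z-scored within the minority class, so large-scale features (daily
    workload ~1e5) cannot dominate small ones (BMI ~1e1).  Categorical
    features are copied from the seed sample (``categorical_strategy=
    "seed"``) or set to the majority vote among the k neighbors
    (``"vote"``, SMOTE-NC style; ties fall back to the seed value).
    Original rows are retained unchanged and an already-balanced dataset
    is returned with zero synthetic rows.

    A class with a single member cannot be interpolated; this raises
    unless ``duplicate_singletons`` is set, in which case the row is
    duplicated verbatim.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if categorical_strategy not in ("seed", "vote"):
        raise ValidationError("categorical_strategy must be 'seed' or 'vote'")
    rng = np.random.default_rng(seed)
    n = data.class_spec.n
    counts = data.class_counts()
    present = counts > 0
    majority = int(counts.max())

    num_cols = [f.name for f in data.schema if f.kind == NUMERIC]
    cat_cols = [f.name for f in data.schema if f.kind != NUMERIC]
    Xnum_all = data.X[num_cols].to_numpy(dtype=float) if num_cols else None

    new_rows: list[dict] = []
    new_y: list[int] = []
    for c in range(1, n + 1):
        n_c = int(counts[c - 1])
        deficit = majority - n_c
        if not present[c - 1] or deficit == 0:
            continue
        idx_c = np.nonzero(data.y == c)[0]
        if n_c == 1:
            if not duplicate_singletons:
                raise ValidationError(
                    f"class {data.class_spec.labels[c - 1]!r} has a single "
                    "member and cannot be interpolated; pass "
                    "duplicate_singletons=True to fall back to duplication"
                )
            row = data.X.iloc[idx_c[0]].to_dict()
            for _ in range(deficit):
                new_rows.append(dict(row))
                new_y.append(c)
            continue

        k_eff = min(k, n_c - 1)
        if Xnum_all is not None:
            sub = Xnum_all[idx_c]
            mu = sub.mean(axis=0)
            sd = sub.std(axis=0)
            sd[sd == 0] = 1.0
            z = (sub - mu) / sd
            d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
            np.fill_diagonal(d2, np.inf)
            neighbors = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]
        else:
            neighbors = np.array(
                [[j for j in range(n_c) if j != i][:k_eff] for i in range(n_c)]
            )

        seeds = rng.integers(0, n_c, size=deficit)
        picks = rng.integers(0, k_eff, size=deficit)
        gaps = rng.random(deficit)
        for s_i, p_i, u in zip(seeds, picks, gaps):
            nb = int(neighbors[s_i, p_i])
            row: dict = {}
            if Xnum_all is not None:
                a = Xnum_all[idx_c[s_i]]
                b = Xnum_all[idx_c[nb]]
                interp = a + u * (b - a)
                row.update(dict(zip(num_cols, interp)))
            for col in cat_cols:
                if categorical_strategy == "seed":
                    row[col] = data.X[col].iloc[idx_c[s_i]]
                else:
                    vals = [data.X[col].iloc[idx_c[j]] for j in neighbors[s_i]]
                    uniq, cnts = np.unique(vals, return_counts=True)
                    top = cnts.max()
                    winners = set(uniq[cnts == top])
                    seed_val = data.X[col].iloc[idx_c[s_i]]
                    row[col] = seed_val if len(winners) > 1 else next(iter(winners))
            new_rows.append(row)
            new_y.append(c)

    if not new_rows:
        return OrdinalDataset(
            data.schema, data.X.copy().reset_index(drop=True),
            data.y.copy(), data.class_spec,
        )
    add = pd.DataFrame(new_rows)[list(data.X.columns)]
    X = pd.concat([data.X, add], ignore_index=True)
    y = np.concatenate([data.y, np.asarray(new_y, dtype=np.int64)])
    return OrdinalDataset(data.schema, X, y, data.class_spec)
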