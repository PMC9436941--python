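"""Classification tree with entropy impurity and information-gain splits.

A deliberately small, from-scratch CART-style learner over mixed
numeric/categorical covariate tables:

* numeric candidates are midpoints between consecutive distinct sorted
  values;
* categorical candidates are all binary partitions of the observed levels
  (exhaustive up to ``max_exhaustive_levels``; above that, levels are
  ordered by the within-level frequency of the parent's majority class and
  only prefix partitions are scored — the classical CART heuristic);
* pre-pruning only (max depth, min samples to split, min samples per leaf,
  minimum gain); no cost-complexity pruning, no surrogate splits.

Tie-breaking is fully deterministic: equal-gain splits prefer the
lexicographically smallest variable name, then the smallest threshold
(numeric) or the lexicographically smallest left-category tuple
(categorical).  Rows with a missing split value are sent to the larger
child during fitting; prediction on a record that lacks a split covariate
raises :class:`MissingCovariateError`.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Any, Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SplitRule",
    "TreeNode",
    "TreeParams",
    "MissingCovariateError",
    "entropy",
    "gini",
    "information_gain",
    "best_split",
    "fit_tree",
    "predict_tree",
    "variable_importance",
    "tree_to_dict",
    "tree_from_dict",
    "save_tree",
    "load_tree",
]

_GAIN_TOL = 1e-12


class MissingCovariateError(KeyError):
    def __init__(self, variable: str):
        self.variable = variable
        super().__init__(f"record is missing covariate {variable!r} required by a split")


# ---------------------------------------------------------------------------
# impurity
# ---------------------------------------------------------------------------

def entropy(class_counts: Mapping[Any, int]) -> float:
    """Shannon entropy in bits of a label-count mapping; 0*log 0 := 0."""
    counts = [c for c in class_counts.values() if c > 0]
    if any(c < 0 for c in class_counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("entropy of empty counts is undefined")
    return -sum((c / total) * math.log2(c / total) for c in counts)


def gini(class_counts: Mapping[Any, int]) -> float:
    counts = [c for c in class_counts.values() if c > 0]
    total = sum(counts)
    if total == 0:
        raise ValueError("gini of empty counts is undefined")
    return 1.0 - sum((c / total) ** 2 for c in counts)


def information_gain(
    parent_counts: Mapping[Any, int],
    left_counts: Mapping[Any, int],
    right_counts: Mapping[Any, int],
) -> float:
    """H(parent) - weighted mean of child entropies, in bits."""
    labels = set(parent_counts) | set(left_counts) | set(right_counts)
    for lab in labels:
        if parent_counts.get(lab, 0) != left_counts.get(lab, 0) + right_counts.get(lab, 0):
            raise ValueError(f"child counts do not sum to parent for label {lab!r}")
    n_l = sum(left_counts.values())
    n_r = sum(right_counts.values())
    if n_l == 0 or n_r == 0:
        raise ValueError("both children must be non-empty")
    n = n_l + n_r
    return entropy(parent_counts) - (
        n_l * entropy(left_counts) + n_r * entropy(right_counts)
    ) / n


def _impurity_rows(count_matrix: np.ndarray, impurity: str) -> np.ndarray:
    """Vectorized impurity of each row of an (m, k) count matrix."""
    totals = count_matrix.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, count_matrix / np.where(totals == 0, 1, totals), 0.0)
    if impurity == "entropy":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -term.sum(axis=1)
    if impurity == "gini":
        return 1.0 - (p**2).sum(axis=1)
    raise ValueError(f"unknown impurity {impurity!r}")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitRule:
    """A binary routing rule on one covariate."""

    variable: str
    kind: str  # "numeric_threshold" | "categorical_subset"
    threshold: Optional[float] = None
    left_categories: Optional[FrozenSet[str]] = None

    def goes_left(self, value: Any) -> bool:
        if self.kind == "numeric_threshold":
            return float(value) <= self.threshold
        return str(value) in self.left_categories

    def describe(self) -> str:
        if self.kind == "numeric_threshold":
            return f"{self.variable} <= {self.threshold:g}"
        cats = ", ".join(sorted(self.left_categories))
        return f"{self.variable} in {{{cats}}}"


@dataclass
class TreeParams:
    """Pre-pruning hyperparameters (rpart-flavoured defaults)."""

    max_depth: int = 5
    min_samples_split: int = 20
    min_samples_leaf: int = 7
    min_gain: float = 0.0
    impurity: str = "entropy"
    seed: int = 0
    max_exhaustive_levels: int = 12

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_gain < 0:
            raise ValueError("min_gain must be >= 0")
        if self.impurity not in ("entropy", "gini"):
            raise ValueError("impurity must be 'entropy' or 'gini'")


@dataclass
class TreeNode:
    node_id: int
    depth: int
    class_counts: Dict[Any, int]
    split: Optional[SplitRule] = None
    gain: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def prediction(self, label_order: Optional[Sequence[Any]] = None) -> Any:
        """Majority label; ties broken by ``label_order`` position, else by str."""
        if label_order is not None:
            pos = {lab: i for i, lab in enumerate(label_order)}
            key = lambda lab: (-self.class_counts[lab], pos.get(lab, len(pos)), str(lab))
        else:
            key = lambda lab: (-self.class_counts[lab], str(lab))
        return min(self.class_counts, key=key)


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def _is_numeric_column(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col)


def _encode_labels(labels: Sequence[Any]) -> Tuple[np.ndarray, List[Any]]:
    classes = sorted(set(labels), key=str)
    index = {lab: i for i, lab in enumerate(classes)}
    return np.array([index[lab] for lab in labels], dtype=np.intp), classes


def _counts_dict(vec: np.ndarray, classes: List[Any]) -> Dict[Any, int]:
    return {lab: int(vec[i]) for i, lab in enumerate(classes)}


@dataclass(frozen=True)
class _Candidate:
    gain: float
    rule: SplitRule
    tie_key: Tuple

    def beats(self, other: Optional["_Candidate"]) -> bool:
        if other is None:
            return True
        if self.gain > other.gain + _GAIN_TOL:
            return True
        if self.gain < other.gain - _GAIN_TOL:
            return False
        return self.tie_key < other.tie_key


def _numeric_candidates(
    variable: str,
    values: np.ndarray,
    y: np.ndarray,
    k: int,
    params: TreeParams,
    parent_impurity: float,
) -> Optional[_Candidate]:
    n = len(values)
    order = np.argsort(values, kind="stable")
    vs = values[order]
    ys = y[order]
    boundaries = np.nonzero(vs[:-1] < vs[1:])[0]
    if len(boundaries) == 0:
        return None
    onehot = np.zeros((n, k))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    left = cum[boundaries]
    total = cum[-1]
    right = total[None, :] - left
    n_left = boundaries + 1
    n_right = n - n_left
    ok = (n_left >= params.min_samples_leaf) & (n_right >= params.min_samples_leaf)
    if not ok.any():
        return None
    h_left = _impurity_rows(left, params.impurity)
    h_right = _impurity_rows(right, params.impurity)
    gains = parent_impurity - (n_left * h_left + n_right * h_right) / n
    # information gain is mathematically >= 0; clamp float dust
    gains = np.where(ok, np.maximum(gains, 0.0), -np.inf)
    # ties resolve toward the smallest threshold (lowest boundary index)
    top = gains[int(np.argmax(gains))]
    best = int(np.nonzero(gains >= top - _GAIN_TOL)[0][0])
    b = boundaries[best]
    threshold = (vs[b] + vs[b + 1]) / 2.0
    rule = SplitRule(variable=variable, kind="numeric_threshold", threshold=float(threshold))
    return _Candidate(gain=float(gains[best]), rule=rule, tie_key=(variable, 0, float(threshold)))


def _categorical_candidates(
    variable: str,
    values: np.ndarray,
    y: np.ndarray,
    k: int,
    params: TreeParams,
    parent_impurity: float,
) -> Optional[_Candidate]:
    levels, level_idx = np.unique(values.astype(str), return_inverse=True)
    n_levels = len(levels)
    if n_levels < 2:
        return None
    n = len(values)
    # (levels, classes) count matrix
    m = np.zeros((n_levels, k))
    np.add.at(m, (level_idx, y), 1.0)
    total = m.sum(axis=0)

    subsets: List[FrozenSet[str]]
    if n_levels <= params.max_exhaustive_levels:
        # enumerate each partition once: level 0 pinned to the left side
        subsets = []
        rest = list(range(1, n_levels))
        for mask in range(0, 1 << (n_levels - 1)):
            members = [0] + [rest[i] for i in range(n_levels - 1) if mask >> i & 1]
            if len(members) == n_levels:
                continue
            subsets.append(frozenset(levels[i] for i in members))
    else:
        # order levels by within-level share of the parent majority class
        maj = int(np.argmax(total))
        with np.errstate(divide="ignore", invalid="ignore"):
            share = m[:, maj] / np.where(m.sum(axis=1) == 0, 1, m.sum(axis=1))
        order = sorted(range(n_levels), key=lambda i: (-share[i], levels[i]))
        subsets = [
            frozenset(levels[i] for i in order[:j]) for j in range(1, n_levels)
        ]

    best: Optional[_Candidate] = None
    level_rows = {lvl: m[i] for i, lvl in enumerate(levels)}
    for left_set in subsets:
        left = np.sum([level_rows[lvl] for lvl in left_set], axis=0)
        right = total - left
        n_l, n_r = left.sum(), right.sum()
        if n_l < params.min_samples_leaf or n_r < params.min_samples_leaf:
            continue
        h_l = _impurity_rows(left[None, :], params.impurity)[0]
        h_r = _impurity_rows(right[None, :], params.impurity)[0]
        g = max(parent_impurity - (n_l * h_l + n_r * h_r) / n, 0.0)
        rule = SplitRule(variable=variable, kind="categorical_subset", left_categories=left_set)
        cand = _Candidate(
            gain=float(g), rule=rule, tie_key=(variable, 1, tuple(sorted(left_set)))
        )
        if cand.beats(best):
            best = cand
    return best


def best_split(
    table: pd.DataFrame, labels: Sequence[Any], params: Optional[TreeParams] = None
) -> Optional[Tuple[SplitRule, float]]:
    """Maximal-information-gain admissible split of ``table`` w.r.t. ``labels``.

    Returns ``None`` when the node is pure, too small, offers no admissible
    split, or the best gain falls below ``params.min_gain``.  Rows with a
    missing value in a column are ignored while scoring that column.
    """
    if params is None:
        params = TreeParams()
    if table.shape[1] == 0:
        raise ValueError("table has no covariate columns")
    n = len(table)
    if n != len(labels):
        raise ValueError("table and labels length mismatch")
    if n < params.min_samples_split:
        return None
    y, classes = _encode_labels(labels)
    k = len(classes)
    if k == 1:
        return None
    parent_counts = np.bincount(y, minlength=k).astype(float)
    parent_impurity = _impurity_rows(parent_counts[None, :], params.impurity)[0]

    best: Optional[_Candidate] = None
    for col in sorted(table.columns):
        series = table[col]
        missing = series.isna().to_numpy()
        v = series.to_numpy()[~missing]
        yy = y[~missing]
        if len(v) < 2 * params.min_samples_leaf:
            continue
        if _is_numeric_column(series):
            cand = _numeric_candidates(
                col, v.astype(float), yy, k, params, parent_impurity
            )
        else:
            cand = _categorical_candidates(col, v, yy, k, params, parent_impurity)
        if cand is not None and cand.beats(best):
            best = cand
    if best is None or best.gain < params.min_gain:
        return None
    return best.rule, best.gain


# ---------------------------------------------------------------------------
# fitting / prediction
# ---------------------------------------------------------------------------

def _route_mask(rule: SplitRule, series: pd.Series) -> Tuple[np.ndarray, np.ndarray]:
    """(left_mask, right_mask); missing rows go to the larger non-missing child."""
    missing = series.isna().to_numpy()
    vals = series.to_numpy()
    left = np.zeros(len(series), dtype=bool)
    if rule.kind == "numeric_threshold":
        with np.errstate(invalid="ignore"):
            left[~missing] = vals[~missing].astype(float) <= rule.threshold
    else:
        left[~missing] = np.isin(vals[~missing].astype(str), list(rule.left_categories))
    right = ~left & ~missing
    if missing.any():
        if left.sum() >= right.sum():
            left |= missing
        else:
            right |= missing
    return left, right


def fit_tree(
    table: pd.DataFrame, labels: Sequence[Any], params: Optional[TreeParams] = None
) -> TreeNode:
    """Greedy recursive partitioning; deterministic for fixed input order."""
    if params is None:
        params = TreeParams()
    if len(table) == 0:
        raise ValueError("cannot fit a tree on an empty table")
    if len(table) != len(labels):
        raise ValueError("table and labels length mismatch")
    labels = list(labels)
    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node_labels = [labels[i] for i in idx]
        counts: Dict[Any, int] = {}
        for lab in node_labels:
            counts[lab] = counts.get(lab, 0) + 1
        node = TreeNode(node_id=counter[0], depth=depth, class_counts=dict(counts))
        counter[0] += 1
        if depth >= params.max_depth or len(counts) == 1:
            return node
        sub = table.iloc[idx]
        found = best_split(sub, node_labels, params)
        if found is None:
            return node
        rule, gain = found
        left_mask, right_mask = _route_mask(rule, sub[rule.variable])
        if left_mask.sum() == 0 or right_mask.sum() == 0:
            return node
        node.split = rule
        node.gain = float(gain)
        node.left = build(idx[left_mask], depth + 1)
        node.right = build(idx[right_mask], depth + 1)
        return node

    return build(np.arange(len(table)), 0)


def predict_tree(
    root: TreeNode,
    record: Mapping[str, Any],
    label_order: Optional[Sequence[Any]] = None,
) -> Any:
    """Route a covariate mapping down the tree and return the leaf majority.

    ``record`` may be any mapping (including a pandas row); a missing or NaN
    split covariate raises :class:`MissingCovariateError`.
    """
    node = root
    while not node.is_leaf:
        rule = node.split
        if rule.variable not in record:
            raise MissingCovariateError(rule.variable)
        value = record[rule.variable]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingCovariateError(rule.variable)
        # categorical levels unseen at fit time simply fail the left-membership
        # test and route right
        node = node.left if rule.goes_left(value) else node.right
    return node.prediction(label_order)


def variable_importance(root: TreeNode) -> List[Tuple[str, float]]:
    """Sum of n*gain per split variable, scaled so the max is 100."""
    raw: Dict[str, float] = {}

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        raw[node.split.variable] = raw.get(node.split.variable, 0.0) + node.n * node.gain
        walk(node.left)
        walk(node.right)

    walk(root)
    if not raw:
        return []
    top = max(raw.values())
    scaled = {v: (100.0 * s / top if top > 0 else 0.0) for v, s in raw.items()}
    return sorted(scaled.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _label_str(label: Any) -> str:
    # str-valued enums serialize by value so files stay loader-agnostic
    if isinstance(label, enum.Enum):
        return str(label.value)
    return str(label)


def tree_to_dict(root: TreeNode) -> Dict[str, Any]:
    nodes: List[Dict[str, Any]] = []

    def walk(node: TreeNode) -> int:
        entry: Dict[str, Any] = {
            "node_id": node.node_id,
            "depth": node.depth,
            "class_counts": {
                _label_str(k): v
                for k, v in sorted(node.class_counts.items(), key=lambda kv: _label_str(kv[0]))
            },
        }
        pos = len(nodes)
        nodes.append(entry)
        if not node.is_leaf:
            rule = node.split
            entry["split"] = {
                "variable": rule.variable,
                "kind": rule.kind,
                "threshold": rule.threshold,
                "left_categories": sorted(rule.left_categories) if rule.left_categories else None,
            }
            entry["gain"] = node.gain
            entry["left"] = walk(node.left)
            entry["right"] = walk(node.right)
        return pos

    walk(root)
    return {"format": "egfr-selector-tree", "version": 1, "nodes": nodes}


def tree_from_dict(data: Mapping[str, Any], label_decoder=None) -> TreeNode:
    nodes = data["nodes"]

    def build(pos: int) -> TreeNode:
        entry = nodes[pos]
        counts = {
            (label_decoder(k) if label_decoder else k): int(v)
            for k, v in entry["class_counts"].items()
        }
        node = TreeNode(
            node_id=int(entry["node_id"]), depth=int(entry["depth"]), class_counts=counts
        )
        if "split" in entry:
            s = entry["split"]
            node.split = SplitRule(
                variable=s["variable"],
                kind=s["kind"],
                threshold=s["threshold"],
                left_categories=frozenset(s["left_categories"]) if s["left_categories"] else None,
            )
            node.gain = float(entry["gain"])
            node.left = build(entry["left"])
            node.right = build(entry["right"])
        return node

    return build(0)


def save_tree(root: TreeNode, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(root), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_tree(path, label_decoder=None) -> TreeNode:
    with open(path) as fh:
        return tree_from_dict(json.load(fh), label_decoder=label_decoder)
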