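"""CART descriptor: surrogate-split importance, segments, and profiles.

The descriptor re-classifies ``(variables, predicted label)`` pairs with a
binary CART tree (Gini impurity by default).  Continuous variables split on
thresholds (``value <= t`` goes left); discrete variables split on code
subsets.  Beyond prediction, the tree is mined for three descriptive
artifacts:

* **variable importance** — ``M(x)`` sums, over all internal nodes, the
  impurity improvement of ``x``'s split where ``x`` is the primary splitter
  and the improvement of its best surrogate split elsewhere; ``VI(x) =
  M(x) / max_x M(x)`` rescales the top variable to 1.  Surrogates let a
  variable masked by a slightly better competitor surface with a nonzero
  importance even if it never appears as a primary splitter.
* **segments** — each leaf is a patient segment; its root-to-leaf path
  conditions (simplified to the tightest bound per variable) characterize
  the group.
* **profiles** — per-variable subset means, min-max scaled against the full
  cohort's range, for radial-diagram style comparison.

Improvements are parent-weighted impurity decreases
``dI = (n_t / n) * [i(t) - p_L i(t_L) - p_R i(t_R)]``.  Ties between
candidate splits are broken by lower variable index, then lower threshold
(or lexicographically smaller code subset), which makes fitted trees
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dataset import PatientTable
from .exceptions import ContractError, ParameterError
from .schema import VariableSchema

__all__ = [
    "Split",
    "Surrogate",
    "TreeNode",
    "DescriptorTree",
    "VariableImportance",
    "Segment",
    "fit_tree",
    "surrogate_splits",
    "variable_importance",
    "extract_segments",
    "profile_group",
    "tree_to_text",
    "tree_to_json",
]

_EPS = 1e-12  # improvement ties below this are resolved by the tie-break key
_MAX_EXHAUSTIVE_CODES = 10  # exact subset search up to this many codes per node


@dataclass(frozen=True)
class Split:
    """A binary split: threshold test (continuous) or code-subset test."""

    var_index: int
    variable: str
    kind: str  # "continuous" | "discrete"
    threshold: Optional[float] = None
    left_codes: Optional[frozenset] = None

    def goes_left(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "continuous":
            return np.asarray(values) <= self.threshold
        codes = np.asarray(values).astype(np.int64)
        return np.isin(codes, sorted(self.left_codes))

    def sort_key(self) -> tuple:
        if self.kind == "continuous":
            return (self.var_index, (float(self.threshold),))
        return (self.var_index, tuple(sorted(self.left_codes)))

    def describe(self) -> str:
        if self.kind == "continuous":
            return f"{self.variable} <= {self.threshold:g}"
        return f"{self.variable} in {sorted(self.left_codes)}"


@dataclass(frozen=True)
class Surrogate:
    """A surrogate split mimicking the primary partition at a node."""

    split: Split
    association: float  # lambda: relative gain in agreement over the majority rule
    agreement: float  # fraction of node rows sent to the same side
    reversed: bool  # True when the split's left side matches the primary's right
    improvement: float  # the surrogate split's own parent-weighted Gini decrease


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n: int
    class_counts: Tuple[int, int]  # (n_survived(+1), n_dead(-1))
    impurity: float
    prediction: int  # +1 / -1, majority class (ties -> +1)
    split: Optional[Split] = None
    improvement: float = 0.0
    surrogates: List[Surrogate] = field(default_factory=list)
    left: Optional[int] = None
    right: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class DescriptorTree:
    """A fitted binary descriptor tree."""

    nodes: List[TreeNode]
    feature_names: List[str]
    feature_kinds: List[str]
    code_universe: Dict[str, list]  # observed codes per discrete variable at the root
    n_root: int
    criterion: str = "gini"

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    @property
    def n_leaves(self) -> int:
        return sum(1 for nd in self.nodes if nd.is_leaf)

    @property
    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes)

    def internal_nodes(self) -> List[TreeNode]:
        return [nd for nd in self.nodes if not nd.is_leaf]

    def apply(self, X: pd.DataFrame) -> np.ndarray:
        """Leaf node id for every row of ``X``."""
        out = np.empty(len(X), dtype=np.int64)
        cols = {name: X[name].to_numpy() for name in self.feature_names}
        idx = np.arange(len(X))
        stack = [(0, idx)]
        while stack:
            node_id, rows = stack.pop()
            node = self.nodes[node_id]
            if node.is_leaf:
                out[rows] = node_id
                continue
            mask = node.split.goes_left(cols[node.split.variable][rows])
            stack.append((node.left, rows[mask]))
            stack.append((node.right, rows[~mask]))
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        leaf_ids = self.apply(X)
        pred = np.array([self.nodes[i].prediction for i in leaf_ids], dtype=np.int64)
        return pred


@dataclass
class VariableImportance:
    """Raw importances ``M`` and their max-normalized form ``VI``."""

    M: Dict[str, float]
    VI: Dict[str, float]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"variable": list(self.M), "M": list(self.M.values()),
                           "VI": [self.VI[v] for v in self.M]})
        return df.sort_values("VI", ascending=False, kind="stable").reset_index(drop=True)


@dataclass
class Segment:
    """One leaf of the descriptor tree, read as a patient group."""

    leaf_id: int
    path_conditions: List[Tuple[str, str, object]]  # (variable, relation, value)
    class_label: str  # "survived" | "dead"
    purity: float
    member_ids: np.ndarray
    profile: Dict[str, float]

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def describe(self) -> str:
        conds = " and ".join(
            f"{v} {rel} {val:g}" if rel in ("<=", ">") else f"{v} {rel} {val}"
            for v, rel, val in self.path_conditions
        ) or "(all rows)"
        return f"[leaf {self.leaf_id}] {self.class_label} (n={self.size}, purity={self.purity:.2f}): {conds}"


# ---------------------------------------------------------------------------
# impurity and split search


def _impurity(n_pos: float, n_neg: float, criterion: str) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    p = n_pos / n
    if criterion == "gini":
        return 1.0 - p * p - (1.0 - p) * (1.0 - p)
    if criterion == "entropy":
        out = 0.0
        for q in (p, 1.0 - p):
            if q > 0:
                out -= q * np.log2(q)
        return out
    raise ParameterError(f"unknown criterion {criterion!r}")


def _weighted_decrease(n_root: int, n_pos: int, n_neg: int,
                       lp: float, ln_: float, criterion: str) -> float:
    """Parent-weighted impurity decrease of a (left_pos, left_neg) partition."""
    nt = n_pos + n_neg
    nl = lp + ln_
    nr = nt - nl
    if nl == 0 or nr == 0:
        return -np.inf
    parent = _impurity(n_pos, n_neg, criterion)
    child = (nl / nt) * _impurity(lp, ln_, criterion) + \
            (nr / nt) * _impurity(n_pos - lp, n_neg - ln_, criterion)
    return (nt / n_root) * (parent - child)


def _continuous_candidates(values: np.ndarray, y: np.ndarray, n_root: int,
                           min_leaf: int, criterion: str, var_index: int,
                           name: str):
    """Best threshold split of one continuous variable, or None."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    pos = (y[order] == 1).astype(np.int64)
    nt = len(v)
    n_pos = int(pos.sum())
    n_neg = nt - n_pos
    cum_pos = np.cumsum(pos)
    best = None
    for i in range(nt - 1):
        if v[i] == v[i + 1]:
            continue
        nl = i + 1
        if nl < min_leaf or nt - nl < min_leaf:
            continue
        gain = _weighted_decrease(n_root, n_pos, n_neg, int(cum_pos[i]), nl - int(cum_pos[i]), criterion)
        thr = 0.5 * (v[i] + v[i + 1])
        cand = (gain, Split(var_index, name, "continuous", threshold=float(thr)))
        if best is None or _better(cand, best):
            best = cand
    return best


def _canonical_left(codes_subset: frozenset, present: Sequence) -> frozenset:
    """Canonicalize a subset split: the left side contains the smallest code."""
    lo = min(present)
    if lo in codes_subset:
        return codes_subset
    return frozenset(present) - codes_subset


def _discrete_candidates(values: np.ndarray, y: np.ndarray, n_root: int,
                         min_leaf: int, criterion: str, var_index: int,
                         name: str):
    """Best code-subset split of one discrete variable, or None.

    Exact subset enumeration when few codes are present; otherwise the
    classic CART shortcut of scanning prefixes of codes ordered by
    positive-class proportion (optimal for binary Gini).
    """
    codes = values.astype(np.int64)
    present = np.unique(codes)
    if len(present) < 2:
        return None
    per_pos = np.array([int(np.sum((codes == c) & (y == 1))) for c in present])
    per_tot = np.array([int(np.sum(codes == c)) for c in present])
    n_pos = int(per_pos.sum())
    n_neg = int(per_tot.sum()) - n_pos
    nt = len(codes)

    best = None
    if len(present) <= _MAX_EXHAUSTIVE_CODES:
        m = len(present)
        # enumerate subsets that contain present[0] (canonical side); skip full set
        for bits in range(1 << (m - 1)):
            mask = [True] + [(bits >> b) & 1 == 1 for b in range(m - 1)]
            if all(mask):
                continue
            lp = int(per_pos[mask].sum())
            lt = int(per_tot[mask].sum())
            if lt < min_leaf or nt - lt < min_leaf:
                continue
            gain = _weighted_decrease(n_root, n_pos, n_neg, lp, lt - lp, criterion)
            left = frozenset(int(c) for c, mm in zip(present, mask) if mm)
            cand = (gain, Split(var_index, name, "discrete", left_codes=left))
            if best is None or _better(cand, best):
                best = cand
    else:
        frac = per_pos / per_tot
        order = np.lexsort((present, frac))  # by positive fraction, ties by code
        for r in range(1, len(present)):
            sel = order[:r]
            lt = int(per_tot[sel].sum())
            if lt < min_leaf or nt - lt < min_leaf:
                continue
            lp = int(per_pos[sel].sum())
            gain = _weighted_decrease(n_root, n_pos, n_neg, lp, lt - lp, criterion)
            left = _canonical_left(frozenset(int(present[i]) for i in sel), [int(c) for c in present])
            cand = (gain, Split(var_index, name, "discrete", left_codes=left))
            if best is None or _better(cand, best):
                best = cand
    return best


def _better(cand, incumbent) -> bool:
    """Strictly better by improvement, else by the deterministic tie-break."""
    gain_c, split_c = cand
    gain_i, split_i = incumbent
    if gain_c > gain_i + _EPS:
        return True
    if gain_c < gain_i - _EPS:
        return False
    return split_c.sort_key() < split_i.sort_key()


def _best_split(cols: Dict[str, np.ndarray], kinds: List[str], names: List[str],
                rows: np.ndarray, y: np.ndarray, n_root: int, min_leaf: int,
                criterion: str):
    best = None
    ysub = y[rows]
    for j, name in enumerate(names):
        v = cols[name][rows]
        if kinds[j] == "continuous":
            cand = _continuous_candidates(v, ysub, n_root, min_leaf, criterion, j, name)
        else:
            cand = _discrete_candidates(v, ysub, n_root, min_leaf, criterion, j, name)
        if cand is not None and cand[0] > _EPS and (best is None or _better(cand, best)):
            best = cand
    return best


# ---------------------------------------------------------------------------
# surrogate search


def _best_agreement_continuous(values: np.ndarray, target_left: np.ndarray,
                               var_index: int, name: str):
    """Threshold maximizing agreement with the primary partition (both orientations)."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    t = target_left[order].astype(np.int64)
    nt = len(v)
    n_left = int(t.sum())
    cum = np.cumsum(t)
    best = None
    for i in range(nt - 1):
        if v[i] == v[i + 1]:
            continue
        nl = i + 1
        same = int(cum[i]) + (nt - nl) - (n_left - int(cum[i]))  # left&left + right&right
        agree, rev = (same, False) if same >= nt - same else (nt - same, True)
        split = Split(var_index, name, "continuous", threshold=float(0.5 * (v[i] + v[i + 1])))
        cand = (agree, split, rev)
        if best is None or _agree_better(cand, best):
            best = cand
    return best


def _best_agreement_discrete(values: np.ndarray, target_left: np.ndarray,
                             var_index: int, name: str):
    codes = values.astype(np.int64)
    present = np.unique(codes)
    if len(present) < 2:
        return None
    nt = len(codes)
    in_left = np.array([int(np.sum((codes == c) & target_left)) for c in present])
    tot = np.array([int(np.sum(codes == c)) for c in present])
    n_left = int(target_left.sum())
    best = None
    if len(present) <= _MAX_EXHAUSTIVE_CODES:
        m = len(present)
        for bits in range(1 << (m - 1)):
            mask = [True] + [(bits >> b) & 1 == 1 for b in range(m - 1)]
            if all(mask):
                continue
            lt = int(tot[mask].sum())
            ll = int(in_left[mask].sum())
            same = ll + (nt - lt) - (n_left - ll)
            agree, rev = (same, False) if same >= nt - same else (nt - same, True)
            left = frozenset(int(c) for c, mm in zip(present, mask) if mm)
            cand = (agree, Split(var_index, name, "discrete", left_codes=left), rev)
            if best is None or _agree_better(cand, best):
                best = cand
    else:
        # greedy: send each code to the side it mostly belongs to; scan by
        # per-code left-fraction prefixes for a deterministic near-optimum
        frac = in_left / tot
        order = np.lexsort((present, -frac))
        for r in range(1, len(present)):
            sel = order[:r]
            lt = int(tot[sel].sum())
            ll = int(in_left[sel].sum())
            same = ll + (nt - lt) - (n_left - ll)
            agree, rev = (same, False) if same >= nt - same else (nt - same, True)
            left = _canonical_left(frozenset(int(present[i]) for i in sel), [int(c) for c in present])
            cand = (agree, Split(var_index, name, "discrete", left_codes=left), rev)
            if best is None or _agree_better(cand, best):
                best = cand
    return best


def _agree_better(cand, incumbent) -> bool:
    if cand[0] != incumbent[0]:
        return cand[0] > incumbent[0]
    return cand[1].sort_key() < incumbent[1].sort_key()


def surrogate_splits(
    cols: Dict[str, np.ndarray],
    kinds: List[str],
    names: List[str],
    rows: np.ndarray,
    y: np.ndarray,
    primary: Split,
    n_root: int,
    criterion: str = "gini",
    n_surrogates: int = 5,
) -> List[Surrogate]:
    """Surrogate splits for one internal node.

    For every non-primary variable, the split that best reproduces the
    primary's left/right partition (in either orientation) is scored by the
    CART association measure ``lambda = (agree - maj) / (nt - maj)``, where
    ``maj`` is the count achieved by always choosing the primary's majority
    side.  Only surrogates that strictly beat the majority rule are kept,
    ranked by association (ties by variable index), at most ``n_surrogates``.
    Each carries its own parent-weighted impurity decrease on the node.
    """
    target_left = primary.goes_left(cols[primary.variable][rows])
    nt = len(rows)
    n_left = int(target_left.sum())
    maj = max(n_left, nt - n_left)
    if maj == nt:
        return []
    ysub = y[rows]
    n_pos = int(np.sum(ysub == 1))
    n_neg = nt - n_pos

    out: List[Surrogate] = []
    for j, name in enumerate(names):
        if j == primary.var_index:
            continue
        v = cols[name][rows]
        if kinds[j] == "continuous":
            cand = _best_agreement_continuous(v, target_left, j, name)
        else:
            cand = _best_agreement_discrete(v, target_left, j, name)
        if cand is None:
            continue
        agree, split, rev = cand
        if agree <= maj:
            continue
        left = split.goes_left(v)
        lp = int(np.sum(left & (ysub == 1)))
        lt = int(left.sum())
        gain = _weighted_decrease(n_root, n_pos, n_neg, lp, lt - lp, criterion)
        out.append(
            Surrogate(
                split=split,
                association=(agree - maj) / (nt - maj),
                agreement=agree / nt,
                reversed=rev,
                improvement=max(0.0, gain),
            )
        )
    out.sort(key=lambda s: (-s.association, s.split.var_index))
    return out[:n_surrogates]


# ---------------------------------------------------------------------------
# fitting


def _resolve_inputs(data: Union[PatientTable, pd.DataFrame],
                    schema: Optional[Sequence[VariableSchema]]):
    if isinstance(data, PatientTable):
        X = data.X
        schema = schema if schema is not None else data.schema
    else:
        X = data
    names = list(X.columns)
    if schema:
        kinds_by_name = {v.name: v.kind for v in schema}
        kinds = [kinds_by_name.get(nm, "continuous") for nm in names]
    else:
        # without a schema, integer columns are treated as discrete codes
        kinds = ["discrete" if pd.api.types.is_integer_dtype(X[nm]) else "continuous" for nm in names]
    return X, names, kinds


def fit_tree(
    data: Union[PatientTable, pd.DataFrame],
    labels: np.ndarray,
    max_depth: int = 6,
    min_leaf: int = 20,
    criterion: str = "gini",
    n_surrogates: int = 5,
    schema: Optional[Sequence[VariableSchema]] = None,
) -> DescriptorTree:
    """Fit a binary CART tree on fully labeled rows.

    Splitting stops at ``max_depth``, when a child would fall below
    ``min_leaf`` rows, when a node is pure, or when no split improves
    impurity.  Equal-improvement splits are resolved by lower variable
    index, then lower threshold / lexicographically smaller code subset.
    """
    X, names, kinds = _resolve_inputs(data, schema)
    y = np.asarray(labels, dtype=np.int64)
    if len(X) != len(y):
        raise ContractError("data and labels must have equal length")
    if np.any(y == 0):
        raise ContractError("descriptor input must be fully labeled (found 0 labels)")
    if max_depth < 0 or min_leaf < 1:
        raise ParameterError("max_depth must be >= 0 and min_leaf >= 1")

    cols = {nm: X[nm].to_numpy() for nm in names}
    n_root = len(y)
    code_universe = {
        nm: sorted(int(c) for c in np.unique(cols[nm]))
        for nm, kd in zip(names, kinds) if kd == "discrete"
    }

    nodes: List[TreeNode] = []

    def grow(rows: np.ndarray, depth: int) -> int:
        node_id = len(nodes)
        ysub = y[rows]
        n_pos = int(np.sum(ysub == 1))
        n_neg = len(rows) - n_pos
        node = TreeNode(
            node_id=node_id,
            depth=depth,
            n=len(rows),
            class_counts=(n_pos, n_neg),
            impurity=_impurity(n_pos, n_neg, criterion),
            prediction=1 if n_pos >= n_neg else -1,
        )
        nodes.append(node)
        if depth >= max_depth or n_pos == 0 or n_neg == 0 or len(rows) < 2 * min_leaf:
            return node_id
        best = _best_split(cols, kinds, names, rows, y, n_root, min_leaf, criterion)
        if best is None:
            return node_id
        gain, split = best
        node.split = split
        node.improvement = gain
        node.surrogates = surrogate_splits(
            cols, kinds, names, rows, y, split, n_root, criterion, n_surrogates
        )
        mask = split.goes_left(cols[split.variable][rows])
        node.left = grow(rows[mask], depth + 1)
        node.right = grow(rows[~mask], depth + 1)
        return node_id

    grow(np.arange(n_root), 0)
    return DescriptorTree(
        nodes=nodes,
        feature_names=names,
        feature_kinds=kinds,
        code_universe=code_universe,
        n_root=n_root,
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# descriptive artifacts


def variable_importance(tree: DescriptorTree) -> VariableImportance:
    """Surrogate-split importance, max-normalized.

    At each internal node, the primary variable collects the node's primary
    improvement; every surrogate variable collects its surrogate split's own
    improvement.  A depth-0 tree yields all-zero importances (VI defined as
    0 everywhere).
    """
    M = {nm: 0.0 for nm in tree.feature_names}
    for node in tree.internal_nodes():
        M[node.split.variable] += node.improvement
        for sur in node.surrogates:
            M[sur.split.variable] += sur.improvement
    top = max(M.values()) if M else 0.0
    if top > 0:
        VI = {nm: val / top for nm, val in M.items()}
    else:
        VI = {nm: 0.0 for nm in M}
    return VariableImportance(M=M, VI=VI)


def _simplify_path(conditions: List[Tuple[Split, bool]],
                   code_universe: Dict[str, list]) -> List[Tuple[str, str, object]]:
    """Keep the tightest bound per variable along a root-to-leaf path."""
    lower: Dict[str, float] = {}
    upper: Dict[str, float] = {}
    allowed: Dict[str, set] = {}
    order: List[str] = []
    for split, went_left in conditions:
        nm = split.variable
        if nm not in order:
            order.append(nm)
        if split.kind == "continuous":
            if went_left:
                upper[nm] = min(upper.get(nm, np.inf), split.threshold)
            else:
                lower[nm] = max(lower.get(nm, -np.inf), split.threshold)
        else:
            side = set(split.left_codes) if went_left else set(code_universe[nm]) - set(split.left_codes)
            allowed[nm] = allowed.get(nm, set(code_universe[nm])) & side
    out: List[Tuple[str, str, object]] = []
    for nm in order:
        if nm in lower:
            out.append((nm, ">", float(lower[nm])))
        if nm in upper:
            out.append((nm, "<=", float(upper[nm])))
        if nm in allowed:
            out.append((nm, "in", sorted(allowed[nm])))
    return out


def extract_segments(
    tree: DescriptorTree,
    table: Union[PatientTable, pd.DataFrame],
    labels: np.ndarray,
) -> List[Segment]:
    """One :class:`Segment` per leaf; segments partition the rows.

    ``labels`` must be the vector the tree was fitted on; purity is computed
    from it within each leaf, and profiles are scaled against the full
    table's per-variable ranges.
    """
    X = table.X if isinstance(table, PatientTable) else table
    ids = table.ids if isinstance(table, PatientTable) else np.arange(len(X))
    y = np.asarray(labels, dtype=np.int64)
    leaf_of = tree.apply(X)

    # path conditions per leaf
    paths: Dict[int, List[Tuple[Split, bool]]] = {}

    def walk(node_id: int, acc: List[Tuple[Split, bool]]):
        node = tree.nodes[node_id]
        if node.is_leaf:
            paths[node_id] = list(acc)
            return
        walk(node.left, acc + [(node.split, True)])
        walk(node.right, acc + [(node.split, False)])

    walk(0, [])

    segments: List[Segment] = []
    for leaf_id in sorted(paths):
        rows = np.flatnonzero(leaf_of == leaf_id)
        node = tree.nodes[leaf_id]
        ysub = y[rows]
        n_pos = int(np.sum(ysub == 1))
        n_dom = max(n_pos, len(rows) - n_pos)
        segments.append(
            Segment(
                leaf_id=leaf_id,
                path_conditions=_simplify_path(paths[leaf_id], tree.code_universe),
                class_label="survived" if node.prediction == 1 else "dead",
                purity=n_dom / len(rows) if len(rows) else 1.0,
                member_ids=np.asarray(ids)[rows],
                profile=profile_group(X, rows) if len(rows) else {},
            )
        )
    return segments


def profile_group(table: Union[PatientTable, pd.DataFrame], row_subset: np.ndarray) -> Dict[str, float]:
    """Per-variable subset means, min-max scaled by the full table's range.

    Discrete variables use their numeric codes.  A zero-range variable maps
    to 0.5 by convention.  Raises on an empty subset.
    """
    X = table.X if isinstance(table, PatientTable) else table
    rows = np.asarray(row_subset)
    if rows.size == 0:
        raise ContractError("profile_group requires a non-empty row subset")
    out: Dict[str, float] = {}
    for nm in X.columns:
        col = X[nm].to_numpy(dtype=np.float64)
        lo, hi = float(np.min(col)), float(np.max(col))
        m = float(np.mean(col[rows]))
        out[nm] = 0.5 if hi == lo else (m - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# export


def tree_to_text(tree: DescriptorTree) -> str:
    """Indented text rendering of the tree."""
    lines: List[str] = []

    def emit(node_id: int, indent: int, prefix: str):
        node = tree.nodes[node_id]
        pad = "  " * indent
        counts = f"[survived={node.class_counts[0]}, dead={node.class_counts[1]}]"
        if node.is_leaf:
            label = "survived" if node.prediction == 1 else "dead"
            lines.append(f"{pad}{prefix}leaf {node.node_id}: {label} {counts}")
        else:
            lines.append(f"{pad}{prefix}node {node.node_id}: {node.split.describe()} "
                         f"{counts} dI={node.improvement:.4f}")
            emit(node.left, indent + 1, "yes: ")
            emit(node.right, indent + 1, "no:  ")

    emit(0, 0, "")
    return "\n".join(lines)


def tree_to_json(tree: DescriptorTree) -> dict:
    """JSON-serializable dict of nodes, splits, counts and surrogates."""

    def split_dict(s: Split) -> dict:
        d = {"variable": s.variable, "kind": s.kind}
        if s.kind == "continuous":
            d["threshold"] = s.threshold
        else:
            d["left_codes"] = sorted(s.left_codes)
        return d

    nodes = []
    for node in tree.nodes:
        d: dict = {
            "node_id": node.node_id,
            "depth": node.depth,
            "n": node.n,
            "class_counts": {"survived": node.class_counts[0], "dead": node.class_counts[1]},
            "prediction": node.prediction,
        }
        if not node.is_leaf:
            d["split"] = split_dict(node.split)
            d["improvement"] = node.improvement
            d["children"] = [node.left, node.right]
            d["surrogates"] = [
                {
                    **split_dict(s.split),
                    "association": s.association,
                    "agreement": s.agreement,
                    "reversed": s.reversed,
                    "improvement": s.improvement,
                }
                for s in node.surrogates
            ]
        nodes.append(d)
    return {"n_root": tree.n_root, "criterion": tree.criterion, "nodes": nodes}
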