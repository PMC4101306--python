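"""AUC scoring, pluggable predictive models, and the CV experiment harness.

The harness mirrors the registry experiment design: draw disjoint data
groups without replacement, balance the classes by undersampling
(equipoise), run k-fold cross-validation within each group over a
hyperparameter grid per model, and report the best grid point's mean
validation AUC per group plus the across-group average.

Models plug in through a minimal transductive interface —
``score(train, test) -> scores`` — so graph-SSL (which needs the test rows
in its graph) and ordinary inductive classifiers share one harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cotrain import MemberConfig, SSLMember, cotrain, final_scores
from .dataset import PatientTable, encode
from .exceptions import ContractError, ParameterError
from .graph import build_graph, solve_ssl

__all__ = [
    "auc",
    "ExperimentPlan",
    "ModelSpec",
    "SSLModel",
    "CoTrainingModel",
    "SklearnModel",
    "ConstantModel",
    "run_experiment",
    "default_model_specs",
]

#: hyperparameter grids of the graph-SSL models
K_GRID = (3, 7, 15, 20, 30)
MU_GRID = (0.0001, 0.01, 1.0, 100.0, 1000.0)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 1/2).

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n_pos = int(pos.sum())
    n_neg = int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("AUC is undefined with a single class")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# model interface


class SSLModel:
    """Single graph-SSL classifier used transductively."""

    def __init__(self, k: int = 7, mu: float = 1.0):
        self.k = k
        self.mu = mu

    def score(self, train: PatientTable, test: PatientTable) -> np.ndarray:
        combined = _stack(train, test, unlabel_test=True)
        graph = build_graph(encode(combined), k=min(self.k, combined.n - 1))
        sol = solve_ssl(graph, combined.y.astype(float), mu=self.mu)
        return sol.f[train.n:]


class CoTrainingModel:
    """SSL co-training ensemble used transductively."""

    def __init__(self, members: Sequence[MemberConfig] = None, rule: str = "unanimity",
                 max_iter: int = 20, tau: float = 0.0):
        from .cotrain import DEFAULT_MEMBERS

        self.members = tuple(members) if members else DEFAULT_MEMBERS
        self.rule = rule
        self.max_iter = max_iter
        self.tau = tau

    def score(self, train: PatientTable, test: PatientTable) -> np.ndarray:
        combined = _stack(train, test, unlabel_test=True)
        configs = [
            MemberConfig(m.member_id, k=min(m.k, combined.n - 1), mu=m.mu,
                         feature_subset=m.feature_subset)
            for m in self.members
        ]
        member_objs = [SSLMember(cfg, combined) for cfg in configs]
        state = cotrain(combined, member_objs, rule=self.rule,
                        max_iter=self.max_iter, tau=self.tau)
        return final_scores(state, member_objs)[train.n:]


class SklearnModel:
    """Adapter for inductive scikit-learn style estimators (baselines)."""

    def __init__(self, factory: Callable):
        self.factory = factory

    def score(self, train: PatientTable, test: PatientTable) -> np.ndarray:
        labeled = np.flatnonzero(train.y != 0)
        combined = _stack(train, test, unlabel_test=True)
        Z = encode(combined).Z
        Z_train, Z_test = Z[: train.n], Z[train.n:]
        est = self.factory()
        est.fit(Z_train[labeled], train.y[labeled])
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(Z_test), dtype=np.float64)
        proba = est.predict_proba(Z_test)
        pos_col = list(est.classes_).index(1)
        return np.asarray(proba[:, pos_col], dtype=np.float64)


class ConstantModel:
    """Scores every row identically; AUC is 0.5 by construction."""

    def score(self, train: PatientTable, test: PatientTable) -> np.ndarray:
        return np.zeros(test.n)


def _stack(train: PatientTable, test: PatientTable, unlabel_test: bool) -> PatientTable:
    X = pd.concat([train.X, test.X], ignore_index=True)
    y = np.concatenate([train.y, np.zeros(test.n, dtype=np.int64) if unlabel_test else test.y])
    ids = np.arange(train.n + test.n)
    return PatientTable(X=X, y=y, ids=ids, schema=train.schema)


# ---------------------------------------------------------------------------
# experiment harness


@dataclass
class ExperimentPlan:
    """Group/fold layout and sizes of one comparison experiment.

    The registry-scale defaults are 40,000 training and 10,000 test points
    per draw, ten groups and five folds; scale ``group_size`` down for
    desk-size runs.
    """

    group_size: int = 5000
    n_groups: int = 10
    n_folds: int = 5
    seed: int = 0


@dataclass
class ModelSpec:
    """A named model with its hyperparameter grid."""

    name: str
    factory: Callable[..., object]  # factory(**grid_point) -> model with .score
    grid: List[dict] = field(default_factory=lambda: [{}])


def default_model_specs() -> List[ModelSpec]:
    """SSL and SSL co-training over the standard (k, mu) grids."""
    ssl_grid = [{"k": k, "mu": mu} for k in K_GRID for mu in MU_GRID]
    co_grid = [
        {"members": (MemberConfig("m1", k=k1, mu=mu1), MemberConfig("m2", k=k2, mu=mu2))}
        for (k1, mu1), (k2, mu2) in [((7, 1.0), (15, 0.01)), ((3, 1.0), (20, 0.01))]
    ]
    return [
        ModelSpec("SSL", SSLModel, ssl_grid),
        ModelSpec("SSL Co-training", CoTrainingModel, co_grid),
    ]


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> List[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::n_folds] for i in range(n_folds)]


def run_experiment(
    plan: ExperimentPlan,
    specs: Sequence[ModelSpec],
    table: PatientTable,
) -> pd.DataFrame:
    """Per-group best-grid-point mean CV AUC for each model, plus the average.

    Each group is an equipoised draw (without replacement across groups) of
    labeled rows; within a group, every grid point is scored by ``n_folds``
    cross-validation — the validation fold is stripped of labels, the model
    scores it transductively, and AUC is taken against the held-out labels.
    The returned frame has one row per model, one column per group and an
    ``Avg`` column.
    """
    if plan.n_groups < 1 or plan.n_folds < 2:
        raise ParameterError("need n_groups >= 1 and n_folds >= 2")
    rng = np.random.default_rng(plan.seed)
    labeled = np.flatnonzero(table.y != 0)
    if plan.group_size * plan.n_groups > len(labeled):
        raise ParameterError(
            f"plan needs {plan.group_size * plan.n_groups} labeled rows, table has {len(labeled)}"
        )
    pool = rng.permutation(labeled)

    results: Dict[str, list] = {spec.name: [] for spec in specs}
    for g in range(plan.n_groups):
        rows = pool[g * plan.group_size: (g + 1) * plan.group_size]
        group = table.subset(np.sort(rows))
        group = _equipoise_labeled(group, rng)
        folds = _fold_indices(group.n, plan.n_folds, rng)
        for spec in specs:
            best = -np.inf
            for point in spec.grid:
                model = spec.factory(**point)
                fold_aucs = []
                for f in range(plan.n_folds):
                    val_idx = folds[f]
                    trn_idx = np.concatenate([folds[j] for j in range(plan.n_folds) if j != f])
                    trn = group.subset(trn_idx)
                    val = group.subset(val_idx)
                    scores = model.score(trn, val)
                    fold_aucs.append(auc(scores, val.y))
                best = max(best, float(np.mean(fold_aucs)))
            results[spec.name].append(best)

    frame = pd.DataFrame(results).T
    frame.columns = [str(g + 1) for g in range(plan.n_groups)]
    frame["Avg"] = frame.mean(axis=1)
    frame.index.name = "model"
    return frame


def cotraining_benchmark(
    n: int = 600,
    seeds: Sequence[int] = tuple(range(10)),
    members: Sequence[MemberConfig] = None,
    label_fraction: float = 0.2,
    max_iter: int = 10,
) -> pd.DataFrame:
    """Co-training vs. single-member AUC on planted-signal synthetic cohorts.

    For each seed: draw a cohort with the default planted mechanism (five
    informative variables of sixteen), balance the labeled classes by
    undersampling, run co-training, and score the originally unlabeled rows
    against the generator's ground truth.  Each single member is scored from
    its own solve on the initial labels.  Returns one row per seed with
    columns ``cotraining`` and one per member id.
    """
    from .cotrain import DEFAULT_MEMBERS
    from .synthetic import GeneratorSpec, generate, make_equipoise

    members = tuple(members) if members else DEFAULT_MEMBERS
    rows = []
    for seed in seeds:
        table, truth = generate(GeneratorSpec(n=n, seed=seed, label_fraction=label_fraction))
        eq = make_equipoise(table, seed=seed)
        truth_eq = truth.set_index("id").loc[eq.ids].reset_index()
        unl = ~truth_eq["observed"].to_numpy()
        y_true = truth_eq["true_label"].to_numpy()
        member_objs = [SSLMember(cfg, eq) for cfg in members]
        state = cotrain(eq, member_objs, max_iter=max_iter)
        row = {"seed": seed,
               "cotraining": auc(final_scores(state, member_objs)[unl], y_true[unl])}
        for cfg, mob in zip(members, member_objs):
            row[cfg.member_id] = auc(mob.solve(eq.y.astype(float)).f[unl], y_true[unl])
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")


def _equipoise_labeled(table: PatientTable, rng: np.random.Generator) -> PatientTable:
    pos = np.flatnonzero(table.y == 1)
    neg = np.flatnonzero(table.y == -1)
    if len(pos) == 0 or len(neg) == 0:
        raise ContractError("group contains a single class; cannot equipoise")
    m = min(len(pos), len(neg))
    keep = np.sort(np.concatenate([
        rng.choice(pos, size=m, replace=False) if len(pos) > m else pos,
        rng.choice(neg, size=m, replace=False) if len(neg) > m else neg,
    ]))
    return table.subset(keep)
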