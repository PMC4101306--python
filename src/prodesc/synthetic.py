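"""Synthetic survivability cohorts with a planted label mechanism.

The generator emulates the 16-variable breast-cancer registry schema
(11 discrete variables with their declared cardinalities, 5 continuous
variables at their declared moments, truncated below at the admissible
range) and plants a linear-latent survival mechanism:

    score_i = sum_v beta_v * z_iv + noise,    label_i = sign(score_i - q),

where ``z_iv`` is the sample-standardized value of variable ``v`` (discrete
variables contribute through their ordinal codes) and the cut ``q`` is the
score quantile that realizes the requested positive-class prior.  A chosen
fraction of rows keeps its label; the rest are marked unlabeled, with the
ground truth preserved in a sidecar frame so tests can score predictions.

Default effect sizes concentrate on the five variables reported as
top-tier prognostic markers (lymph node involvement, stage, site-specific
surgery, number of positive nodes, tumor size), with negative sign: worse
pathology lowers the survival score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .dataset import PatientTable
from .exceptions import ContractError, ParameterError
from .schema import VariableSchema, default_schema, validate_schema

__all__ = ["GeneratorSpec", "generate", "make_equipoise", "generate_blobs", "generate_two_dead_subgroups"]

#: default planted effects: the top-tier prognostic markers, bad prognosis
#: pushing the survival score down.  Magnitudes give a latent signal-to-noise
#: of about 3.3 : 0.25 in variance, i.e. a strongly learnable mechanism.
DEFAULT_BETA: Dict[str, float] = {
    "lymph_node_involvement": -1.0,
    "num_positive_nodes": -0.9,
    "stage": -0.8,
    "tumor_size": -0.7,
    "site_specific_surgery": -0.6,
}

#: positive-class prior of the full registry (128,469 survived of 162,500)
DEFAULT_IMBALANCE = 128469 / 162500


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic cohort draw."""

    n: int = 2000
    schema: Sequence[VariableSchema] = field(default_factory=default_schema)
    beta: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    noise_sd: float = 0.5
    label_fraction: float = 0.2
    imbalance: float = DEFAULT_IMBALANCE
    seed: int = 0

    def __post_init__(self) -> None:
        validate_schema(list(self.schema))
        if self.n < 2:
            raise ParameterError("n must be at least 2")
        if not 0 < self.label_fraction <= 1:
            raise ParameterError(f"label_fraction must be in (0, 1], got {self.label_fraction}")
        if not 0 < self.imbalance < 1:
            raise ParameterError(f"imbalance must be in (0, 1), got {self.imbalance}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        unknown = set(self.beta) - {v.name for v in self.schema}
        if unknown:
            raise ParameterError(f"beta refers to unknown variables: {sorted(unknown)}")


def _draw_discrete(rng: np.random.Generator, card: int, n: int) -> np.ndarray:
    """Ordinal codes 1..card with mildly skewed masses (geometric decay 0.85)."""
    w = 0.85 ** np.arange(card)
    p = w / w.sum()
    return rng.choice(np.arange(1, card + 1), size=n, p=p)


def _draw_continuous(rng: np.random.Generator, var: VariableSchema, n: int) -> np.ndarray:
    mean = var.mean if var.mean is not None else 0.0
    sd = var.sd if var.sd is not None else 1.0
    lo, hi = var.declared_range if var.declared_range is not None else (None, None)
    a = -np.inf if lo is None else (lo - mean) / sd
    b = np.inf if hi is None else (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate(spec: GeneratorSpec):
    """Draw a cohort; returns ``(PatientTable, ground_truth DataFrame)``.

    The sidecar frame carries, per row: id, latent score, true label and
    whether the label is observed in the table.  Same spec (incl. seed)
    yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    schema = list(spec.schema)
    cols: Dict[str, np.ndarray] = {}
    for var in schema:
        if var.kind == "discrete":
            cols[var.name] = _draw_discrete(rng, var.cardinality, spec.n)
        else:
            cols[var.name] = _draw_continuous(rng, var, spec.n)
    X = pd.DataFrame(cols, columns=[v.name for v in schema])

    score = np.zeros(spec.n)
    for name, b in spec.beta.items():
        x = X[name].to_numpy(dtype=np.float64)
        sd = np.std(x, ddof=1)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        score += b * z
    score += rng.normal(0.0, spec.noise_sd, size=spec.n)

    cut = np.quantile(score, 1.0 - spec.imbalance)
    true_y = np.where(score >= cut, 1, -1).astype(np.int64)

    n_labeled = int(round(spec.label_fraction * spec.n))
    n_labeled = max(1, min(spec.n, n_labeled))
    labeled_rows = rng.choice(spec.n, size=n_labeled, replace=False)
    y = np.zeros(spec.n, dtype=np.int64)
    y[labeled_rows] = true_y[labeled_rows]

    ids = np.arange(spec.n)
    table = PatientTable(X=X, y=y, ids=ids, schema=schema)
    truth = pd.DataFrame(
        {
            "id": ids,
            "latent_score": score,
            "true_label": true_y,
            "observed": y != 0,
        }
    )
    return table, truth


def make_equipoise(table: PatientTable, seed: int = 0) -> PatientTable:
    """Balance the labeled classes by undersampling the majority class.

    Majority-class labeled rows are dropped without replacement until both
    classes match the minority count; unlabeled rows are kept untouched.
    """
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(table.y == 1)
    neg = np.flatnonzero(table.y == -1)
    if len(pos) == 0 or len(neg) == 0:
        raise ContractError("equipoise requires both classes among the labeled rows")
    m = min(len(pos), len(neg))
    keep_pos = rng.choice(pos, size=m, replace=False) if len(pos) > m else pos
    keep_neg = rng.choice(neg, size=m, replace=False) if len(neg) > m else neg
    unlabeled = np.flatnonzero(table.y == 0)
    keep = np.sort(np.concatenate([keep_pos, keep_neg, unlabeled]))
    return table.subset(keep)


# ---------------------------------------------------------------------------
# special-purpose cohorts for exercising individual stages


def generate_blobs(
    n: int = 200,
    separation_sd: float = 4.0,
    label_fraction: float = 0.05,
    seed: int = 0,
):
    """Two spherical Gaussian classes in two continuous variables.

    Centers sit ``separation_sd`` standard deviations apart, so the classes
    are essentially separable — a clean benchmark for the label-propagation
    and co-training loop.  Returns ``(PatientTable, true_labels)``.
    """
    rng = np.random.default_rng(seed)
    schema = [
        VariableSchema("v1", "continuous"),
        VariableSchema("v2", "continuous"),
    ]
    half = n // 2
    true_y = np.array([1] * half + [-1] * (n - half), dtype=np.int64)
    centers = np.where(true_y[:, None] == 1, separation_sd / 2.0, -separation_sd / 2.0)
    pts = centers + rng.normal(size=(n, 2))
    n_labeled = max(2, int(round(label_fraction * n)))
    # ensure both classes appear among the labels
    labeled = np.concatenate(
        [
            rng.choice(np.flatnonzero(true_y == 1), size=max(1, n_labeled // 2), replace=False),
            rng.choice(np.flatnonzero(true_y == -1), size=max(1, n_labeled - n_labeled // 2), replace=False),
        ]
    )
    y = np.zeros(n, dtype=np.int64)
    y[labeled] = true_y[labeled]
    table = PatientTable(
        X=pd.DataFrame(pts, columns=["v1", "v2"]),
        y=y,
        ids=np.arange(n),
        schema=schema,
    )
    return table, true_y


def generate_two_dead_subgroups(n: int = 600, seed: int = 0, dead_fraction: float = 0.4):
    """Cohort whose dead class splits into two planted mechanisms.

    Subgroup A dies with a very high number of primary tumors; subgroup B
    dies with few primaries but a late stage and a large tumor.  Survivors
    have low primaries, early stage and small tumors.  All rows are labeled.
    Returns ``(PatientTable, labels, subgroup)`` with ``subgroup`` in
    ``{"survived", "dead_high_primaries", "dead_late_stage"}``.
    """
    rng = np.random.default_rng(seed)
    schema = list(default_schema())
    n_dead = int(round(dead_fraction * n))
    n_a = n_dead // 2
    n_b = n_dead - n_a
    n_s = n - n_dead
    subgroup = np.array(
        ["survived"] * n_s + ["dead_high_primaries"] * n_a + ["dead_late_stage"] * n_b
    )
    perm = rng.permutation(n)
    subgroup = subgroup[perm]

    cols: Dict[str, np.ndarray] = {}
    for var in schema:
        if var.kind == "discrete":
            cols[var.name] = _draw_discrete(rng, var.cardinality, n)
        else:
            cols[var.name] = _draw_continuous(rng, var, n)

    is_s = subgroup == "survived"
    is_a = subgroup == "dead_high_primaries"
    is_b = subgroup == "dead_late_stage"

    # survivors: benign profile
    cols["num_primaries"][is_s] = np.clip(rng.normal(0.8, 0.5, is_s.sum()), 0, 2.4)
    cols["stage"][is_s] = rng.choice([1, 2, 3, 4], size=is_s.sum())
    cols["tumor_size"][is_s] = np.clip(rng.normal(60, 30, is_s.sum()), 1, None)
    # subgroup A: many primary tumors, otherwise benign-looking
    cols["num_primaries"][is_a] = np.clip(rng.normal(5.0, 0.6, is_a.sum()), 3.6, 6)
    cols["stage"][is_a] = rng.choice([1, 2, 3, 4], size=is_a.sum())
    cols["tumor_size"][is_a] = np.clip(rng.normal(60, 30, is_a.sum()), 1, None)
    # subgroup B: late stage and large tumor, few primaries
    cols["num_primaries"][is_b] = np.clip(rng.normal(0.8, 0.5, is_b.sum()), 0, 2.4)
    cols["stage"][is_b] = rng.choice([8, 9, 10], size=is_b.sum())
    cols["tumor_size"][is_b] = np.clip(rng.normal(600, 150, is_b.sum()), 300, None)

    labels = np.where(is_s, 1, -1).astype(np.int64)
    X = pd.DataFrame(cols, columns=[v.name for v in schema])
    table = PatientTable(X=X, y=labels.copy(), ids=np.arange(n), schema=schema)
    return table, labels, subgroup
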