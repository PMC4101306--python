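# prodesc — a coupled predictor–descriptor for cancer survivability

`prodesc` predicts binary five-year survivability for cohorts of cancer
patients and then *explains* the prediction: which prognostic variables drove
it, and which patient subgroups share a common prognostic pattern.  It is
aimed at biostatisticians working with registry-style tabular data (for
instance SEER-like breast-cancer extracts with 16 mixed-type prognostic
variables) where labeled outcomes are scarce but unlabeled patient records
are plentiful.

The package couples two modules:

**The predictor** is a graph-based semi-supervised co-training ensemble.
Patients are nodes of a similarity graph with Gaussian edge weights between
symmetrized k-nearest neighbors in the encoded feature space,

    w_ij = exp( −‖x_i − x_j‖² / α² )   if i ~ j,   else 0.

Given labels y ∈ {−1, 0, +1}ⁿ (0 = unlabeled), each member classifier solves
the regularized label-propagation problem

    min_f (f − y)ᵀ(f − y) + μ fᵀ L f,     L = D − W,

whose closed form is **f = (I + μL)⁻¹ y**.  Members with different
hyperparameters (k, μ) vote on the unlabeled points; unanimous predictions
become *pseudo-labels* that enlarge the labeled set, and the loop repeats
until a fixed point.  The growing labeled set is what lifts the ensemble
above any single member.

**The descriptor** re-classifies the `(variables, predicted label)` pairs
with a binary CART tree (Gini impurity) and post-processes it into:

* **variable importance** — M(x) = Σ_{t∈T} ΔI(s̃_x, t), the sum over tree
  nodes of the impurity improvements of x as a primary *or surrogate*
  splitter, normalized to VI(x) = M(x)/max_x M(x) so the top variable scores
  1.  Surrogate splits let a variable masked by a slightly better competitor
  surface with nonzero importance even if it never splits a node itself;
* **segments** — each leaf is a patient group characterized by its
  root-to-leaf path conditions;
* **profiles** — per-variable group means scaled to [0, 1] against the
  cohort range, for radial-diagram comparison of segments.

Because real registry data is access-restricted, the package ships a
synthetic-cohort generator that reproduces the 16-variable schema (declared
cardinalities and moments) with a planted linear-latent survival mechanism,
so every stage is testable end to end.

## Worked example

```python
import numpy as np
from prodesc import (GeneratorSpec, generate, make_equipoise, MemberConfig,
                     SSLMember, cotrain, final_scores, auc)
from prodesc.tree import fit_tree, variable_importance, extract_segments

table, truth = generate(GeneratorSpec(n=600, seed=7, label_fraction=0.2))
table = make_equipoise(table, seed=7)              # balance the labeled classes

members = [SSLMember(MemberConfig("m1", k=7,  mu=1.0), table),
           SSLMember(MemberConfig("m2", k=15, mu=0.01), table)]
state = cotrain(table, members, max_iter=10)
print("iterations:", state.iteration,
      "| still unlabeled:", int((state.y_current == 0).sum()))

scores = final_scores(state, members)
tr = truth.set_index("id").loc[table.ids].reset_index()
unl = ~tr["observed"].to_numpy()
print("AUC on unlabeled rows: %.3f" % auc(scores[unl], tr["true_label"].to_numpy()[unl]))

labels = state.y_current.copy()
labels[labels == 0] = np.sign(scores[labels == 0])
desc = table.subset(np.flatnonzero(labels != 0))
tree = fit_tree(desc, labels[labels != 0], max_depth=6, min_leaf=20)
print(variable_importance(tree).frame().head(5).round(3).to_string(index=False))
```

prints

```
iterations: 7 | still unlabeled: 6
AUC on unlabeled rows: 0.722
          variable     M    VI
num_positive_nodes 0.120 1.000
 histological_type 0.051 0.429
        tumor_size 0.030 0.252
     behavior_code 0.027 0.224
      primary_site 0.026 0.216
```

The co-training loop pseudo-labeled all but 6 of the unlabeled rows in 7
iterations; the averaged member scores rank the held-out rows with AUC 0.72
against the generator's ground truth; and the descriptor ranks
`num_positive_nodes` — one of the five planted markers — as the most
important variable (VI = 1 by construction of the normalization).
`extract_segments(tree, desc, ...)` then lists one patient segment per leaf
with its simplified path conditions, class, size and purity.

## Command line

```bash
prodesc generate --n 2000 --seed 0 --out cohort.csv --truth-out truth.csv
prodesc predict cohort.csv --out predictions.csv
prodesc describe labeled.csv --out-dir descriptor/
prodesc pipeline config.yaml --out-dir run1/
prodesc experiment --n 4000 --group-size 300 --n-groups 3 --out aucs.csv
```

`pipeline` runs predictor → descriptor from a single YAML config and writes
predictions, variable importances, segments, profiles, the tree (text +
JSON) and the co-training history.  `experiment` mirrors the grouped
cross-validation comparison design: per group, every grid point
(k ∈ {3,7,15,20,30}, μ ∈ {0.0001,0.01,1,100,1000}) is scored by k-fold CV
and the best mean validation AUC is reported.

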