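"""End-to-end predictor -> descriptor pipeline with artifact export.

Given a config (YAML file or dict) naming either an input CSV or a
synthetic-generator spec, the pipeline

1. runs SSL co-training to label the unlabeled rows,
2. resolves any rows the ensemble never agreed on by the sign of the final
   averaged score (exact zeros are dropped from the descriptor input),
3. fits the descriptor tree on all rows (original labels where given,
   predicted labels elsewhere),
4. writes predictions, variable importances, segments, group profiles and
   the co-training history to the output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .cotrain import MemberConfig, SSLMember, cotrain, final_scores, history_frame
from .dataset import PatientTable, read_patient_table, write_patient_table
from .exceptions import ContractError, ParameterError
from .schema import default_schema, load_schema
from .synthetic import GeneratorSpec, generate
from .tree import (
    extract_segments,
    fit_tree,
    profile_group,
    tree_to_json,
    tree_to_text,
    variable_importance,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config"]

DEFAULT_CONFIG = {
    "predictor": {
        "members": [
            {"member_id": "m1", "k": 7, "mu": 1.0},
            {"member_id": "m2", "k": 15, "mu": 0.01},
        ],
        "rule": "unanimity",
        "max_iter": 20,
        "tau": 0.0,
    },
    "descriptor": {"max_depth": 6, "min_leaf": 20},
}


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError(f"{path}: config must be a mapping")
    return cfg


def _resolve_table(cfg: dict) -> PatientTable:
    inp = cfg.get("input", {})
    if "csv" in inp:
        schema = load_schema(inp["schema"]) if "schema" in inp else default_schema()
        return read_patient_table(
            inp["csv"], schema,
            label_column=inp.get("label_column", "survivability"),
            id_column=inp.get("id_column"),
        )
    if "generator" in inp:
        gen = dict(inp["generator"])
        table, _ = generate(GeneratorSpec(**gen))
        return table
    raise ParameterError("config must name input.csv or input.generator")


def _member_configs(cfg: dict) -> list[MemberConfig]:
    out = []
    for m in cfg["members"]:
        subset = tuple(m["feature_subset"]) if m.get("feature_subset") else None
        out.append(MemberConfig(m["member_id"], k=int(m["k"]), mu=float(m["mu"]),
                                feature_subset=subset))
    return out


def run_pipeline(config: Union[dict, str, Path], output_dir: Optional[Union[str, Path]] = None) -> dict:
    """Run predictor then descriptor; returns a dict of artifact paths.

    Stage failures propagate as exceptions after a log line naming the
    stage, so CLI wrappers can exit nonzero with a meaningful message.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    pred_cfg = {**DEFAULT_CONFIG["predictor"], **cfg.get("predictor", {})}
    desc_cfg = {**DEFAULT_CONFIG["descriptor"], **cfg.get("descriptor", {})}
    outdir = Path(output_dir or cfg.get("output_dir", "prodesc_output"))
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("pipeline config: %s", json.dumps({"predictor": pred_cfg, "descriptor": desc_cfg}))

    stage = "input"
    try:
        table = _resolve_table(cfg)
        logger.info("input: n=%d (labeled %d, unlabeled %d)", table.n, table.nl, table.nu)

        stage = "predictor"
        members = _member_configs(pred_cfg)
        member_objs = [SSLMember(m, table) for m in members]
        state = cotrain(table, member_objs, rule=pred_cfg["rule"],
                        max_iter=int(pred_cfg["max_iter"]), tau=float(pred_cfg["tau"]))
        scores = final_scores(state, member_objs)
        logger.info("predictor: %d iterations, %d rows still unlabeled (%s)",
                    state.iteration, int(np.sum(state.y_current == 0)), state.stop_reason)

        stage = "descriptor"
        labels = state.y_current.copy()
        undecided = labels == 0
        labels[undecided] = np.sign(scores[undecided]).astype(np.int64)
        keep = labels != 0
        if not np.all(keep):
            logger.warning("descriptor: dropping %d rows with zero score", int(np.sum(~keep)))
        desc_table = table.subset(np.flatnonzero(keep))
        desc_labels = labels[keep]
        tree = fit_tree(desc_table, desc_labels,
                        max_depth=int(desc_cfg["max_depth"]),
                        min_leaf=int(desc_cfg["min_leaf"]))
        vi = variable_importance(tree)
        segments = extract_segments(tree, desc_table, desc_labels)

        stage = "export"
        artifacts = {}

        pred_df = pd.DataFrame({
            "id": table.ids,
            "y_input": table.y,
            "y_final": labels,
            "pseudo": state.pseudo_mask,
            "score": scores,
        })
        artifacts["predictions"] = str(outdir / "predictions.csv")
        pred_df.to_csv(artifacts["predictions"], index=False)

        artifacts["variable_importance"] = str(outdir / "variable_importance.csv")
        vi.frame().to_csv(artifacts["variable_importance"], index=False)

        seg_rows = []
        for s in segments:
            seg_rows.append({
                "leaf_id": s.leaf_id,
                "class_label": s.class_label,
                "size": s.size,
                "purity": s.purity,
                "conditions": "; ".join(
                    f"{v} {rel} {val}" for v, rel, val in s.path_conditions
                ),
            })
        artifacts["segments"] = str(outdir / "segments.csv")
        pd.DataFrame(seg_rows).to_csv(artifacts["segments"], index=False)
        artifacts["segments_json"] = str(outdir / "segments.json")
        with open(artifacts["segments_json"], "w") as fh:
            json.dump(
                [
                    {**row, "member_ids": [int(i) for i in s.member_ids],
                     "profile": s.profile}
                    for row, s in zip(seg_rows, segments)
                ],
                fh, indent=2,
            )

        # group profiles: overall, survived, dead, and one per segment
        prof_rows = {"overall": profile_group(desc_table, np.arange(desc_table.n))}
        for lbl, nm in ((1, "survived"), (-1, "dead")):
            rows = np.flatnonzero(desc_labels == lbl)
            if rows.size:
                prof_rows[nm] = profile_group(desc_table, rows)
        for s in segments:
            rows = np.flatnonzero(np.isin(desc_table.ids, s.member_ids))
            prof_rows[f"segment_{s.leaf_id}"] = profile_group(desc_table, rows)
        artifacts["profiles"] = str(outdir / "profiles.csv")
        pd.DataFrame(prof_rows).T.rename_axis("group").to_csv(artifacts["profiles"])

        artifacts["tree_text"] = str(outdir / "tree.txt")
        Path(artifacts["tree_text"]).write_text(tree_to_text(tree) + "\n")
        artifacts["tree_json"] = str(outdir / "tree.json")
        with open(artifacts["tree_json"], "w") as fh:
            json.dump(tree_to_json(tree), fh, indent=2)

        artifacts["history"] = str(outdir / "cotrain_history.csv")
        history_frame(state).to_csv(artifacts["history"], index=False)

        artifacts["labeled_table"] = str(outdir / "labeled_table.csv")
        labeled_out = PatientTable(X=desc_table.X, y=desc_labels,
                                   ids=desc_table.ids, schema=desc_table.schema)
        write_patient_table(labeled_out, artifacts["labeled_table"])
    except Exception:
        logger.error("pipeline failed in stage %r", stage)
        raise

    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return artifacts
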