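"""End-to-end procedure: best-match labeling, split, training and dispatch.

Stages
------
1. :func:`assign_best_equation` labels each patient with the candidate
   equation whose estimate deviates least from the measured GFR (both on
   the 1.73 m^2-normalized scale).
2. :func:`split_cohort` partitions the cohort into train/test by a seeded
   uniform permutation (train size = floor(n * fraction)).
3. :func:`train_selector` fits the classification tree on the training
   rows over a configurable covariate list.
4. :func:`dispatch_estimate` routes a record down the tree and evaluates
   the predicted equation.
5. :func:`run_pipeline` orchestrates everything from a config mapping and
   writes all artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cart, evaluation
from .cohort import (
    DEFAULT_TREE_COVARIATES,
    add_derived_columns,
    frame_to_records,
    read_cohort,
    record_covariate_row,
    write_cohort,
)
from .equations import (
    CANDIDATE_EQUATIONS,
    EgfrValue,
    EquationId,
    MissingInputError,
    PatientRecord,
    estimate_egfr,
)

__all__ = [
    "LabeledCohort",
    "ConfigError",
    "assign_best_equation",
    "split_cohort",
    "label_cohort",
    "train_selector",
    "dispatch_estimate",
    "run_pipeline",
]

log = logging.getLogger("egfr_selector")


class ConfigError(ValueError):
    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key {key!r}: {message}")


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def _deviation(egfr: float, sgfr_norm: float, mode: str) -> float:
    if mode == "absolute":
        return abs(egfr - sgfr_norm)
    if mode == "relative":
        return abs(egfr - sgfr_norm) / sgfr_norm
    raise ValueError(f"deviation mode must be 'absolute' or 'relative', got {mode!r}")


def assign_best_equation(
    record: PatientRecord,
    *,
    deviation: str = "absolute",
    cg_numerator: str = "weight",
) -> EquationId:
    """Candidate equation with the smallest deviation from measured GFR.

    Deviations are compared on the normalized scale; exact ties resolve by
    the fixed candidate priority order (BIS-2, CKD-EPI(CysC),
    CKD-EPI(Cr-CysC), Ruijin).
    """
    sgfr_norm = record.sgfr_norm
    if sgfr_norm is None:
        raise MissingInputError("sgfr_abs")
    best_eq: Optional[EquationId] = None
    best_dev = np.inf
    for eq in CANDIDATE_EQUATIONS:
        v = estimate_egfr(eq, record, cg_numerator=cg_numerator).value
        d = _deviation(v, sgfr_norm, deviation)
        if d < best_dev:
            best_eq, best_dev = eq, d
    return best_eq


def split_cohort(cohort, train_fraction: float, seed: int) -> np.ndarray:
    """Seeded train/test assignment array of ``"train"``/``"test"``.

    ``cohort`` may be an integer row count or any sized object.  Train size
    is floor(n * train_fraction); membership comes from a uniform random
    permutation, deterministic per seed.
    """
    n = cohort if isinstance(cohort, int) else len(cohort)
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction!r}")
    if n < 2:
        raise ValueError(f"need at least 2 rows to split, got {n}")
    n_train = int(np.floor(n * train_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out = np.full(n, "test", dtype=object)
    out[perm[:n_train]] = "train"
    return out


@dataclass
class LabeledCohort:
    """Cohort frame with derived columns, per-row best-match label and
    train/test assignment; ``records`` caches PatientRecord views."""

    frame: pd.DataFrame
    records: List[PatientRecord] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            self.records = frame_to_records(self.frame)

    @property
    def labels(self) -> List[EquationId]:
        return [EquationId(v) for v in self.frame["label"]]

    def subset_mask(self, subset: str) -> np.ndarray:
        if subset == "total":
            return np.ones(len(self.frame), dtype=bool)
        if subset in ("train", "test"):
            return (self.frame["split"] == subset).to_numpy()
        raise ValueError(f"subset must be train/test/total, got {subset!r}")

    def with_predictions(self, tree: cart.TreeNode) -> "LabeledCohort":
        preds = []
        for rec in self.records:
            preds.append(
                cart.predict_tree(
                    tree, record_covariate_row(rec), label_order=CANDIDATE_EQUATIONS
                ).value
            )
        frame = self.frame.copy()
        frame["predicted"] = preds
        return LabeledCohort(frame=frame, records=self.records)

    def iter_records(self, subset: str = "total") -> Iterator[Tuple[PatientRecord, EquationId]]:
        """Yield (record, predicted equation) over one split; requires
        ``with_predictions`` to have been applied."""
        if "predicted" not in self.frame.columns:
            raise ValueError("cohort carries no predictions; call with_predictions")
        mask = self.subset_mask(subset)
        for keep, rec, pred in zip(mask, self.records, self.frame["predicted"]):
            if keep:
                yield rec, EquationId(pred)


def label_cohort(
    frame: pd.DataFrame,
    *,
    train_fraction: float = 0.7,
    seed: int = 0,
    deviation: str = "absolute",
    cg_numerator: str = "weight",
    split: bool = True,
) -> LabeledCohort:
    """Derive BSA/BMI/normalized GFR, assign best-match labels and
    (optionally) the train/test split."""
    derived = add_derived_columns(frame)
    records = frame_to_records(frame)
    labels = [
        assign_best_equation(rec, deviation=deviation, cg_numerator=cg_numerator).value
        for rec in records
    ]
    derived["label"] = labels
    if split:
        derived["split"] = split_cohort(len(derived), train_fraction, seed)
    return LabeledCohort(frame=derived, records=records)


# ---------------------------------------------------------------------------
# training / dispatch
# ---------------------------------------------------------------------------

def train_selector(
    cohort: LabeledCohort,
    params: Optional[cart.TreeParams] = None,
    covariates: Sequence[str] = DEFAULT_TREE_COVARIATES,
) -> cart.TreeNode:
    """Fit the selector tree on the cohort's training rows."""
    mask = cohort.subset_mask("train") if "split" in cohort.frame.columns else np.ones(
        len(cohort.frame), dtype=bool
    )
    if mask.sum() == 0:
        raise ValueError("empty training set")
    missing = [c for c in covariates if c not in cohort.frame.columns]
    if missing:
        raise ValueError(f"covariates not present in cohort: {missing}")
    table = cohort.frame.loc[mask, list(covariates)]
    labels = [EquationId(v) for v in cohort.frame.loc[mask, "label"]]
    return cart.fit_tree(table, labels, params)


def dispatch_estimate(
    tree: cart.TreeNode,
    record: PatientRecord,
    *,
    cg_numerator: str = "weight",
) -> EgfrValue:
    """Estimate GFR with the equation the tree predicts for this record."""
    eq = cart.predict_tree(
        tree, record_covariate_row(record), label_order=CANDIDATE_EQUATIONS
    )
    return estimate_egfr(eq, record, cg_numerator=cg_numerator)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_TREE_PARAM_KEYS = {
    "max_depth",
    "min_samples_split",
    "min_samples_leaf",
    "min_gain",
    "impurity",
    "seed",
    "max_exhaustive_levels",
}


def _tree_params(config: Mapping[str, Any]) -> cart.TreeParams:
    block = config.get("tree", {}) or {}
    if not isinstance(block, Mapping):
        raise ConfigError("tree", "must be a mapping of tree parameters")
    unknown = set(block) - _TREE_PARAM_KEYS
    if unknown:
        raise ConfigError("tree", f"unknown parameter(s) {sorted(unknown)}")
    try:
        return cart.TreeParams(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError("tree", str(exc)) from exc


def run_pipeline(config: Mapping[str, Any], outdir=None) -> Dict[str, Any]:
    """Run labeling, split, training and evaluation from a config mapping.

    Config keys: ``seed`` (required), exactly one of ``input`` (cohort CSV
    path) or ``synthetic`` (generator overrides, at least ``n``), and
    optionally ``train_fraction``, ``deviation``, ``cg_numerator``,
    ``tree`` (TreeParams fields), ``covariates``, ``eval_subset``,
    ``outdir`` and ``plots``.

    Writes ``labeled_cohort.csv``, ``tree.json``, ``importance.csv``,
    ``metrics.csv``, ``bland_altman.csv`` and ``run_summary.json`` to the
    output directory, and returns the in-memory artifacts.
    """
    if "seed" not in config:
        raise ConfigError("seed", "required")
    seed = int(config["seed"])
    has_input = bool(config.get("input"))
    has_synth = config.get("synthetic") is not None
    if has_input == has_synth:
        raise ConfigError("input", "provide exactly one of 'input' or 'synthetic'")

    if outdir is None:
        outdir = config.get("outdir")
    if outdir is None:
        raise ConfigError("outdir", "required (or pass outdir=)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if has_input:
        path = Path(config["input"])
        if not path.exists():
            raise ConfigError("input", f"cohort file not found: {path}")
        frame = read_cohort(path)
        log.info("loaded cohort %s: %d rows", path, len(frame))
    else:
        from .synthetic import SyntheticConfig, generate_cohort

        block = dict(config["synthetic"])
        block.setdefault("seed", seed)
        try:
            synth_cfg = SyntheticConfig(**block)
        except (TypeError, ValueError) as exc:
            raise ConfigError("synthetic", str(exc)) from exc
        frame, _hidden = generate_cohort(synth_cfg)
        log.info("generated synthetic cohort: %d rows", len(frame))

    train_fraction = float(config.get("train_fraction", 0.7))
    deviation = str(config.get("deviation", "absolute"))
    cg_numerator = str(config.get("cg_numerator", "weight"))
    covariates = list(config.get("covariates", DEFAULT_TREE_COVARIATES))
    eval_subset = str(config.get("eval_subset", "test"))
    params = _tree_params(config)

    labeled = label_cohort(
        frame,
        train_fraction=train_fraction,
        seed=seed,
        deviation=deviation,
        cg_numerator=cg_numerator,
    )
    n_train = int((labeled.frame["split"] == "train").sum())
    log.info(
        "labeled cohort: %d rows (%d train / %d test)",
        len(labeled.frame),
        n_train,
        len(labeled.frame) - n_train,
    )

    tree = train_selector(labeled, params, covariates)
    importance = cart.variable_importance(tree)
    log.info("fitted tree: %d-variable importance table", len(importance))

    labeled = labeled.with_predictions(tree)
    report = evaluation.comparison_report(
        labeled, subset=eval_subset, cg_numerator=cg_numerator
    )
    pairs = evaluation.bland_altman_pairs(
        labeled, subset=eval_subset, cg_numerator=cg_numerator
    )
    log.info("evaluation on %s split: %d method rows", eval_subset, len(report))

    write_cohort(labeled.frame, outdir / "labeled_cohort.csv")
    cart.save_tree(tree, outdir / "tree.json")
    pd.DataFrame(importance, columns=["variable", "importance"]).to_csv(
        outdir / "importance.csv", index=False
    )
    report.to_csv(outdir / "metrics.csv", index=False)
    pairs.to_csv(outdir / "bland_altman.csv", index=False)
    summary = {
        "seed": seed,
        "n": len(labeled.frame),
        "n_train": n_train,
        "n_test": len(labeled.frame) - n_train,
        "eval_subset": eval_subset,
        "covariates": covariates,
        "root_split": tree.split.describe() if tree.split else None,
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if config.get("plots"):
        evaluation.plot_deviation_box(pairs, outdir / "deviation_box.png")
        evaluation.plot_bland_altman(
            pairs, evaluation.DISPATCH_METHOD, outdir / "bland_altman_tree.png"
        )

    return {
        "labeled": labeled,
        "tree": tree,
        "importance": importance,
        "metrics": report,
        "bland_altman": pairs,
        "summary": summary,
    }
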