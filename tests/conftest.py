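from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pytest

from egfr_selector import pipeline
from egfr_selector.equations import PatientRecord
from egfr_selector.synthetic import SyntheticConfig, generate_cohort


def make_record(**overrides) -> PatientRecord:
    """A valid male CKD-ish record; override any field."""
    base = dict(
        patient_id="p1",
        age=60.0,
        sex="male",
        height=170.0,
        weight=70.0,
        scr=2.0,
        scr_unit="mg/dL",
        cysc=2.0,
        bun=17.0,
        alb=35.0,
        sgfr_abs=30.0,
        covariates={},
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record() -> PatientRecord:
    return make_record()


def random_record(rng: np.random.Generator) -> PatientRecord:
    """Random valid biomarker/demographic draw for oracle sweeps."""
    return make_record(
        age=float(rng.uniform(18, 95)),
        sex=rng.choice(["male", "female"]),
        height=float(rng.uniform(145, 195)),
        weight=float(rng.uniform(40, 110)),
        scr=float(rng.uniform(0.4, 12.0)),
        scr_unit="mg/dL",
        cysc=float(rng.uniform(0.4, 8.0)),
        bun=float(rng.uniform(3.0, 40.0)),
        alb=float(rng.uniform(20.0, 50.0)),
        sgfr_abs=float(rng.uniform(3.0, 110.0)),
    )


@dataclass
class PlantedRun:
    seed: int
    recovery: float
    root_variable: str
    test_accuracy: float
    dispatch_mae: float
    candidate_maes: Dict[str, float]
    importance: List


@pytest.fixture(scope="session")
def planted_runs() -> List[PlantedRun]:
    """Default planted cohorts (n=2000) over 10 seeds with the full
    label -> split -> fit -> dispatch pipeline; shared across tests because
    this is the expensive part of the suite."""
    from egfr_selector import cart, evaluation

    runs = []
    for seed in range(10):
        frame, hidden = generate_cohort(SyntheticConfig(n=2000, seed=seed))
        labeled = pipeline.label_cohort(frame, seed=seed)
        recovery = float(
            (labeled.frame["label"].to_numpy() == hidden.to_numpy()).mean()
        )
        tree = pipeline.train_selector(labeled)
        root = tree.split.variable if tree.split is not None else ""
        lp = labeled.with_predictions(tree)
        mask = lp.subset_mask("test")
        acc = float(
            (lp.frame.loc[mask, "predicted"] == lp.frame.loc[mask, "label"]).mean()
        )
        report = evaluation.comparison_report(lp, subset="test")
        by_method = dict(zip(report["method"], report["mae"]))
        runs.append(
            PlantedRun(
                seed=seed,
                recovery=recovery,
                root_variable=root,
                test_accuracy=acc,
                dispatch_mae=by_method["decision_tree"],
                candidate_maes={
                    m: by_method[m]
                    for m in ("bis2", "ckd_epi_cysc", "ckd_epi_cr_cysc", "ruijin")
                },
                importance=cart.variable_importance(tree),
            )
        )
    return runs


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-row default synthetic cohort for cheap smoke tests."""
    frame, hidden = generate_cohort(SyntheticConfig(n=120, seed=42))
    return frame, hidden
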