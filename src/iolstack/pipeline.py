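"""End-to-end orchestration: simulate -> split -> optimize -> train -> evaluate.

``run_pipeline`` drives every stage from a single config mapping and
writes the standard artifacts (constants.json, pred.csv, report.json).
Each stage logs its seed so a run is reproducible from the log alone.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import biometry_io as bio
from .constants_opt import optimize_all
from .evaluation import (
    MethodErrors,
    compare_paired,
    proportion_chi2,
    subgroup_by_axial,
    summarize_errors,
)
from .formulas import FORMULAS, mean_offset_correct, predict_cohort
from .records import Cohort
from .stacker import (
    DEFAULT_GRIDS,
    FeatureSet,
    MODEL_KINDS,
    predict_stacker,
    select_base_formula,
    select_feature_subset,
    train_stacker,
)
from .synthetic import SyntheticConfig, generate_cohort, split_patientwise

log = logging.getLogger(__name__)

#: Reduced hyperparameter grids for routine runs; the full defaults stay
#: available via grids="full".
FAST_GRIDS = {
    "svr": {"C": [1.0, 10.0], "epsilon": [0.1], "gamma": [0.1, 1.0]},
    "rfr": {"n_estimators": [100], "max_depth": [None, 8]},
    "gbr": {"learning_rate": [0.1], "n_estimators": [100, 300], "max_depth": [2, 3]},
}

#: Default feature combination: raw optics-relevant biometry plus the
#: base formula's prediction. The exhaustive subset search scores this
#: set within CV noise of its winner on the default generative model.
DEFAULT_FEATURES = (
    "axial_length",
    "corneal_radius",
    "acd",
    "lens_thickness",
    "iol_power",
    "formula_prediction",
)

DEFAULT_CONFIG: dict = {
    "cohort_csv": None,  # path, or None to simulate
    "simulate": {},  # SyntheticConfig field overrides
    "n_test": 500,
    "seed": 0,
    "formulas": list(FORMULAS),
    "model_kinds": list(MODEL_KINDS),
    "select_base_formula": True,
    "subset_search": False,  # exhaustive subset search (slow); else DEFAULT_FEATURES
    "features": list(DEFAULT_FEATURES),
    "grids": "fast",  # "fast" | "full" | explicit mapping
    "nn_repeats": 30,
    "cv_folds": 5,
    "reference": "srkt",  # reference method for paired tests / chi-squared
    "within_threshold": 0.5,
    "out_dir": None,
    "external_predictions": None,  # CSV with eye_id,method,predicted_se over train+test
}


def _grids(cfg) -> Mapping[str, dict]:
    g = cfg["grids"]
    if g == "fast":
        return FAST_GRIDS
    if g == "full":
        return DEFAULT_GRIDS
    return g


def run_pipeline(config: Optional[Mapping] = None) -> dict:
    """Run the full study pipeline; returns the evaluation report.

    Stages and their artifacts (written when ``out_dir`` is set):
    cohort simulation or loading; patient-wise split with fellow-eye
    exclusion; per-lens constant optimization (constants.json); formula
    predictions on the test set; optional offset-corrected external
    predictions; base-formula and feature selection; stacker training for
    each model kind; prediction (pred.csv); and the statistics battery
    (report.json). Any stage failure propagates with the stage named.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    report: dict = {"config": {k: v for k, v in cfg.items() if k != "out_dir"}, "stages": []}
    out_dir = Path(cfg["out_dir"]) if cfg["out_dir"] else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("pipeline stage: %s (seed %d)", name, seed)
        report["stages"].append(name)

    try:
        stage("cohort")
        if cfg["cohort_csv"]:
            cohort = bio.read_cohort(cfg["cohort_csv"])
        else:
            sim = SyntheticConfig(**{"seed": seed, **cfg["simulate"]})
            cohort = generate_cohort(sim)
        stage("split")
        train, test = split_patientwise(cohort, int(cfg["n_test"]), seed=seed)
        report["n_train"], report["n_test"] = len(train), len(test)

        stage("optimize_constants")
        constants = optimize_all(train, formulas=cfg["formulas"])
        if out_dir:
            bio.write_constants(constants, out_dir / "constants.json")

        train_frame, test_frame = train.to_frame(), test.to_frame()
        obs_test = test_frame["postop_se"].to_numpy()
        eye_ids = test_frame["eye_id"].tolist()
        predictions: dict[str, np.ndarray] = {}

        stage("formula_predictions")
        for fid in cfg["formulas"]:
            predictions[fid] = predict_cohort(fid, test_frame, constants)

        if cfg["external_predictions"]:
            stage("external_offset_correction")
            ext = bio.read_predictions(cfg["external_predictions"])
            for method, grp in ext.groupby("method"):
                by_eye = dict(zip(grp["eye_id"], grp["predicted_se"]))
                tr_ids = train_frame["eye_id"]
                tr_mask = tr_ids.isin(by_eye).to_numpy()
                tr_pred = np.array([by_eye[e] for e in tr_ids[tr_mask]])
                tr_obs = train_frame.loc[tr_mask, "postop_se"].to_numpy()
                te_pred = np.array([by_eye[e] for e in eye_ids if e in by_eye])
                if len(te_pred) != len(eye_ids):
                    raise ValueError(f"external method {method!r} does not cover all test eyes")
                predictions[str(method)] = mean_offset_correct(te_pred, tr_pred, tr_obs)

        stage("select_base_formula")
        if cfg["select_base_formula"]:
            base, importances = select_base_formula(train_frame, constants, seed=seed)
            report["base_formula"] = {"selected": base, "importances": importances}
        else:
            base = cfg["reference"]
            report["base_formula"] = {"selected": base, "importances": None}

        stage("select_features")
        if cfg["subset_search"]:
            sel = select_feature_subset(
                train_frame, constants, base, cv_folds=int(cfg["cv_folds"]), seed=seed
            )
            features = sel.selected
            report["feature_selection"] = {
                "selected": list(sel.selected),
                "importances": sel.importances,
            }
        else:
            features = tuple(cfg["features"])
            report["feature_selection"] = {"selected": list(features), "importances": None}
        fs = FeatureSet(features, base_formula=base)

        stage("train_stackers")
        grids = _grids(cfg)
        models = {}
        for kind in cfg["model_kinds"]:
            models[kind] = train_stacker(
                kind,
                train_frame,
                constants,
                fs,
                grid=grids.get(kind) if kind != "nn" else None,
                cv_folds=int(cfg["cv_folds"]),
                seed=seed,
                n_repeats=int(cfg["nn_repeats"]),
            )
            predictions[kind] = predict_stacker(models[kind], test_frame, constants)
        report["hyperparameters"] = {k: m.hyperparams for k, m in models.items()}

        stage("evaluate")
        methods = [
            MethodErrors(name, eye_ids, predictions[name] - obs_test) for name in predictions
        ]
        report["methods"] = {m.method: summarize_errors(m) for m in methods}
        ref = cfg["reference"]
        report["tests"] = compare_paired(methods, reference=ref)
        thr = float(cfg["within_threshold"])
        n = len(eye_ids)
        k_ref = int((np.abs(predictions[ref] - obs_test) < thr).sum())
        report["chi2"] = [
            {
                "a": m.method,
                "b": ref,
                "threshold": thr,
                "k_a": int((np.abs(m.errors) < thr).sum()),
                "k_b": k_ref,
                "n": n,
                "p": proportion_chi2(int((np.abs(m.errors) < thr).sum()), n, k_ref, n),
            }
            for m in methods
            if m.method != ref
        ]
        report["subgroups"] = subgroup_by_axial(
            test_frame["axial_length"].to_numpy(), methods, reference=ref
        )

        if out_dir:
            stage("write_artifacts")
            rows = []
            for m in methods:
                pred = predictions[m.method]
                for e, p, err in zip(eye_ids, pred, m.errors):
                    rows.append({"eye_id": e, "method": m.method, "predicted_se": p, "error": err})
            bio.write_predictions(pd.DataFrame(rows), out_dir / "pred.csv")
            bio.write_report(report, out_dir / "report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {report['stages'][-1]!r}: {exc}") from exc
    return report
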