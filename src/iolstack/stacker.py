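"""Stacked machine-learning prediction of postoperative refraction.

The stacking idea: a classic vergence formula already encodes the
optics, so its predicted refraction is fed to a tabular regressor as one
feature among the raw biometry. The regressor then learns only the
formula's systematic residual structure, which needs far less data than
learning the optics from scratch.

Pipeline pieces, each exposed separately:

* feature assembly (candidate features include each eye's optimized lens
  constant and the base formula's predicted refraction),
* standardization to zero mean / unit SD using training statistics only,
* base-formula choice by gradient-boosting feature importance,
* feature-subset choice by exhaustive cross-validated MAE search,
* grid-search-tuned support-vector / random-forest / gradient-boosting
  regressors, and a seed-averaged ensemble of small neural networks
  (refraction prediction needs few inputs, so two modest hidden layers
  suffice; averaging over repeats removes initialization jitter).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, cross_val_score
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .formulas import FORMULAS, MissingConstantError, predict_cohort
from .records import Cohort

CANDIDATE_FEATURES = (
    "age",
    "axial_length",
    "corneal_radius",
    "acd",
    "lens_thickness",
    "wtw",
    "iol_constant",
    "iol_power",
    "formula_prediction",
)

#: Which optimized constant stands in as the per-lens "IOL constant" feature.
_CONSTANT_KEY = {"srkt": "A", "holladay1": "SF", "hofferq": "pACD", "haigis": "a0"}

MODEL_KINDS = ("svr", "rfr", "gbr", "nn")

DEFAULT_GRIDS = {
    "svr": {"C": [0.1, 1.0, 10.0, 100.0], "epsilon": [0.01, 0.1], "gamma": [0.01, 0.1, 1.0]},
    "rfr": {"n_estimators": [100, 300], "max_depth": [None, 4, 8]},
    "gbr": {"learning_rate": [0.01, 0.1], "n_estimators": [100, 500], "max_depth": [2, 3, 4]},
}

#: Fast gradient-boosting settings used for feature scoring/selection.
SELECTOR_PARAMS = dict(n_estimators=100, max_depth=3, learning_rate=0.1)


@dataclass(frozen=True)
class FeatureSet:
    selected: tuple[str, ...]
    base_formula: str = "srkt"

    def __post_init__(self):
        bad = [f for f in self.selected if f not in CANDIDATE_FEATURES]
        if bad:
            raise ValueError(f"unknown feature(s): {bad}")
        if self.base_formula not in FORMULAS:
            raise ValueError(f"base_formula must be one of {FORMULAS}")


@dataclass
class StandardizationStats:
    """Training-set feature means and population SDs (divide-by-n convention)."""

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "StandardizationStats":
        if len(X) < 2:
            raise ValueError("need at least 2 rows to standardize")
        sd = X.std(ddof=0)
        flat = sd[sd <= 0]
        if len(flat):
            raise ValueError(f"zero-variance feature(s): {list(flat.index)}")
        return cls(mean=X.mean(), sd=sd)

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.mean.index] - self.mean) / self.sd

    def invert(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z * self.sd + self.mean


fit_standardizer = StandardizationStats.fit


def apply_standardizer(stats: StandardizationStats, X: pd.DataFrame) -> pd.DataFrame:
    return stats.apply(X)


def _frame(cohort) -> pd.DataFrame:
    return cohort.to_frame() if isinstance(cohort, Cohort) else cohort


def assemble_features(
    cohort,
    constants: Mapping[str, Mapping[str, float]],
    fs: FeatureSet,
    require_target: bool = True,
) -> tuple[pd.DataFrame, Optional[np.ndarray]]:
    """One feature row per eye, plus the observed-refraction target.

    ``formula_prediction`` is the base formula's prediction with the
    optimized constants; ``iol_constant`` is the base formula's constant
    for the eye's lens model (a0 for the Haigis triple). The target is
    None when ``require_target=False`` and any eye lacks an observation.
    """
    frame = _frame(cohort)
    cols: dict[str, np.ndarray] = {}
    for name in fs.selected:
        if name == "formula_prediction":
            cols[name] = predict_cohort(fs.base_formula, frame, constants)
        elif name == "iol_constant":
            key = _CONSTANT_KEY[fs.base_formula]
            vals = np.empty(len(frame))
            for i, model in enumerate(frame["iol_model"]):
                try:
                    vals[i] = constants[model][key]
                except KeyError:
                    raise MissingConstantError(
                        f"no optimized {key!r} for lens model {model!r} "
                        f"(eye {frame['eye_id'].iloc[i]})"
                    ) from None
            cols[name] = vals
        else:
            cols[name] = frame[name].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=frame.index)

    y = None
    se = frame["postop_se"]
    if se.notna().all():
        y = se.to_numpy(dtype=float)
    elif require_target:
        missing = frame.loc[se.isna(), "eye_id"].tolist()
        raise ValueError(f"eyes without observed postop_se in training mode: {missing[:5]}")
    return X, y


@dataclass
class FeatureSelectionReport:
    importances: dict[str, float]
    subset_scores: dict[tuple[str, ...], float]
    selected: tuple[str, ...]
    base_formula: str
    cv_folds: int


@dataclass
class TrainedStacker:
    model_kind: str
    members: list
    hyperparams: dict
    stats: StandardizationStats
    feature_set: FeatureSet
    cv_folds: int = 5
    seeds: tuple[int, ...] = (0,)
    cv_mae: Optional[float] = None

    def predict_standardized(self, Z: pd.DataFrame) -> np.ndarray:
        preds = np.stack([m.predict(Z.to_numpy()) for m in self.members])
        return preds.mean(axis=0)


def _selector(seed: int, params: Optional[dict] = None) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(random_state=seed, **(params or SELECTOR_PARAMS))


def select_base_formula(
    train,
    constants: Mapping[str, Mapping[str, float]],
    seed: int = 0,
    extra_candidates: Sequence[str] = tuple(f for f in CANDIDATE_FEATURES if f != "formula_prediction"),
) -> tuple[str, dict[str, float]]:
    """Pick the vergence formula whose prediction the stacker should consume.

    Fits the gradient-boosting selector on all candidate features plus
    all four formulas' predictions at once and returns the formula whose
    prediction column carries the largest importance (ties break to the
    canonical formula order, SRK/T first). Also returns the full
    importance map for reporting.
    """
    frame = _frame(train)
    X_parts = {}
    for name in extra_candidates:
        if name == "iol_constant":
            continue  # constant is formula-specific; excluded from the shoot-out
        X_parts[name] = frame[name].to_numpy(dtype=float)
    for fid in FORMULAS:
        X_parts[f"pred_{fid}"] = predict_cohort(fid, frame, constants)
    X = pd.DataFrame(X_parts, index=frame.index)
    y = frame["postop_se"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("base-formula selection requires observed postop_se on every eye")
    model = _selector(seed).fit(X.to_numpy(), y)
    importances = dict(zip(X.columns, (float(v) for v in model.feature_importances_)))
    best = max(FORMULAS, key=lambda fid: (importances[f"pred_{fid}"], -FORMULAS.index(fid)))
    return best, importances


def select_feature_subset(
    train,
    constants: Mapping[str, Mapping[str, float]],
    base_formula: str,
    candidates: Sequence[str] = CANDIDATE_FEATURES,
    cv_folds: int = 5,
    seed: int = 0,
    selector_params: Optional[dict] = None,
) -> FeatureSelectionReport:
    """Exhaustive feature-subset search by cross-validated MAE.

    Every non-empty subset of ``candidates`` is scored with a
    ``cv_folds``-fold cross-validated gradient-boosting regressor (the
    fast selector, fixed seed); the subset with the lowest mean absolute
    error wins, ties broken toward fewer features then candidate order.
    The report also carries the selector's feature importances on the
    full candidate set.
    """
    frame = _frame(train)
    if len(frame) < cv_folds * 10:
        raise ValueError(f"need >= {cv_folds * 10} training eyes for {cv_folds}-fold selection")
    fs_all = FeatureSet(tuple(candidates), base_formula)
    X_all, y = assemble_features(frame, constants, fs_all)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    imp_model = _selector(seed, selector_params).fit(X_all.to_numpy(), y)
    importances = dict(zip(X_all.columns, (float(v) for v in imp_model.feature_importances_)))

    scores: dict[tuple[str, ...], float] = {}
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            mae = -cross_val_score(
                _selector(seed, selector_params),
                X_all[list(subset)].to_numpy(),
                y,
                cv=cv,
                scoring="neg_mean_absolute_error",
            ).mean()
            scores[subset] = float(mae)

    order = {f: i for i, f in enumerate(candidates)}
    best = min(scores, key=lambda s: (scores[s], len(s), tuple(order[f] for f in s)))
    return FeatureSelectionReport(
        importances=importances,
        subset_scores=scores,
        selected=best,
        base_formula=base_formula,
        cv_folds=cv_folds,
    )


def _base_estimator(kind: str, seed: int):
    if kind == "svr":
        return SVR(kernel="rbf")
    if kind == "rfr":
        return RandomForestRegressor(random_state=seed)
    if kind == "gbr":
        return GradientBoostingRegressor(random_state=seed)
    raise ValueError(f"unknown model kind {kind!r} (nn has its own fitter)")


def fit_regressor(
    kind: str,
    Z: pd.DataFrame,
    y: np.ndarray,
    grid: Optional[dict] = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[object, dict, float]:
    """Exhaustive grid search by cross-validated MAE, then refit on all rows.

    ``Z`` must already be standardized. Returns (fitted estimator, chosen
    hyperparameters, winning CV MAE).
    """
    grid = DEFAULT_GRIDS[kind] if grid is None else grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _base_estimator(kind, seed),
        grid,
        scoring="neg_mean_absolute_error",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(Z.to_numpy(), np.asarray(y, dtype=float))
    return search.best_estimator_, dict(search.best_params_), float(-search.best_score_)


def _make_nn(seed: int, hidden=(16, 8), max_iter=200) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        max_iter=max_iter,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=10,
        random_state=seed,
    )


def fit_nn_ensemble(
    Z: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 30,
    seeds: Optional[Sequence[int]] = None,
    hidden: tuple[int, ...] = (16, 8),
    max_iter: int = 200,
) -> tuple[list, dict]:
    """Train ``n_repeats`` networks differing only by seed; prediction = mean.

    A member whose training diverges (non-finite in-sample prediction) is
    retrained once with a displaced seed, then an error is raised.
    """
    seeds = list(range(n_repeats)) if seeds is None else list(seeds)
    if len(seeds) != n_repeats:
        raise ValueError("len(seeds) must equal n_repeats")
    Zv = Z.to_numpy()
    yv = np.asarray(y, dtype=float)
    members = []
    for s in seeds:
        net = _make_nn(s, hidden, max_iter).fit(Zv, yv)
        if not np.isfinite(net.predict(Zv)).all():
            net = _make_nn(s + 100003, hidden, max_iter).fit(Zv, yv)
            if not np.isfinite(net.predict(Zv)).all():
                raise RuntimeError(f"neural-network member (seed {s}) diverged twice")
        members.append(net)
    params = dict(hidden_layer_sizes=hidden, max_iter=max_iter, n_repeats=n_repeats)
    return members, params


def train_stacker(
    kind: str,
    train,
    constants: Mapping[str, Mapping[str, float]],
    fs: FeatureSet,
    grid: Optional[dict] = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_repeats: int = 30,
    nn_hidden: tuple[int, ...] = (16, 8),
) -> TrainedStacker:
    """Assemble + standardize + fit one model kind; the one-call training API."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}")
    X, y = assemble_features(train, constants, fs)
    stats = StandardizationStats.fit(X)
    Z = stats.apply(X)
    if kind == "nn":
        seeds = tuple(range(seed, seed + n_repeats))
        members, params = fit_nn_ensemble(Z, y, n_repeats=n_repeats, seeds=seeds, hidden=nn_hidden)
        cv_mae = None
    else:
        est, params, cv_mae = fit_regressor(kind, Z, y, grid=grid, cv_folds=cv_folds, seed=seed)
        members, seeds = [est], (seed,)
    return TrainedStacker(
        model_kind=kind,
        members=members,
        hyperparams=params,
        stats=stats,
        feature_set=fs,
        cv_folds=cv_folds,
        seeds=tuple(seeds),
        cv_mae=cv_mae,
    )


def predict_stacker(
    model: TrainedStacker,
    cohort,
    constants: Mapping[str, Mapping[str, float]],
) -> np.ndarray:
    """Predict postoperative refraction (diopters) for every eye in ``cohort``."""
    frame = _frame(cohort)
    if frame.empty:
        return np.empty(0)
    X, _ = assemble_features(frame, constants, model.feature_set, require_target=False)
    return model.predict_standardized(model.stats.apply(X))
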