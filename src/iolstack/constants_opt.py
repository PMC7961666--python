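"""Per-lens constant personalization on a training cohort.

Scalar constants (SRK/T A, Holladay surgeon factor, Hoffer Q pACD) are
chosen so that the mean signed prediction error (predicted - observed)
on the training eyes is zero; because every ELP model is monotone
increasing in its constant and predicted refraction is monotone
increasing in ELP at fixed implant power, the mean error is strictly
monotone in the constant and a bracketing root method converges to
machine precision.

The Haigis triple (a0, a1, a2) follows the original two-stage recipe:
back-solve each training eye's effective lens position from its observed
refraction by inverting the vergence chain (a quadratic in the ELP),
then ordinary-least-squares regress the back-solved positions on
(1, ACD, AL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .formulas import (
    OpticsError,
    back_solve_elp,
    corneal_power,
    engine_for,
    predict_refraction,
)
from .records import Cohort

log = logging.getLogger(__name__)

CONSTANT_FIELD = {"srkt": "A", "holladay1": "SF", "hofferq": "pACD"}

#: Default search brackets per scalar constant, in the constant's units.
DEFAULT_BRACKETS = {"srkt": (112.0, 126.0), "holladay1": (-2.0, 6.0), "hofferq": (2.0, 9.0)}


@dataclass
class OptimizationResult:
    iol_model: str
    formula_id: str
    constants: dict[str, float]
    n_train: int
    residual_mean_error: float
    iterations: int = 0
    n_dropped: int = 0
    residual_sd: Optional[float] = None


def _as_frame(train) -> pd.DataFrame:
    frame = train.to_frame() if isinstance(train, Cohort) else train.copy()
    if frame["postop_se"].isna().any():
        raise ValueError("training cohort contains eyes without observed postop_se")
    return frame


def _mean_error(formula_id: str, frame: pd.DataFrame, constants: Mapping[str, float]) -> float:
    pred = predict_refraction(
        formula_id,
        frame["axial_length"].to_numpy(),
        frame["corneal_radius"].to_numpy(),
        frame["acd"].to_numpy(),
        frame["iol_power"].to_numpy(),
        constants,
    )
    return float(np.mean(np.asarray(pred) - frame["postop_se"].to_numpy()))


def optimize_scalar_constant(
    formula_id: str,
    train,
    bracket: Optional[tuple[float, float]] = None,
    iol_model: str = "*",
    tol: float = 1e-9,
) -> OptimizationResult:
    """Zero the mean signed prediction error over a single constant.

    ``train`` is a Cohort or DataFrame whose rows all use the constant
    being fitted (callers optimizing per lens model pass one model's
    eyes). The bracket is expanded by up to +/-10 units when the mean
    error does not change sign inside it.
    """
    if formula_id not in CONSTANT_FIELD:
        raise ValueError(f"{formula_id!r} has no scalar constant (use fit_haigis_constants)")
    frame = _as_frame(train)
    if frame.empty:
        raise ValueError("empty training cohort")
    name = CONSTANT_FIELD[formula_id]
    lo, hi = bracket if bracket is not None else DEFAULT_BRACKETS[formula_id]

    evals = {"n": 0}

    def f(c: float) -> float:
        evals["n"] += 1
        try:
            return _mean_error(formula_id, frame, {name: c})
        except OpticsError as exc:
            # A constant so low that some eye's ELP collapses to <= 0 drives
            # predictions arbitrarily myopic; one so high that the ELP
            # reaches the retina drives them hyperopic. Map infeasibility
            # to a large value of the matching sign so bracketing proceeds.
            return -1e6 if "positive" in str(exc) else 1e6

    f_lo, f_hi = f(lo), f(hi)
    expand = 0.5
    # Mean error increases in the constant (a larger constant places the
    # lens deeper, predicting a more hyperopic outcome at fixed power), so
    # a missing sign change means the root lies below lo or above hi.
    while f_lo * f_hi > 0 and (hi - lo) < 40.0:
        if f_lo > 0:
            lo -= expand
        else:
            hi += expand
        expand *= 2.0
        f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"no sign change for {name} in [{lo}, {hi}]: mean errors {f_lo:+.4f}, {f_hi:+.4f}"
        )
    c_star, res = optimize.brentq(f, lo, hi, xtol=tol, full_output=True)
    resid = f(c_star)
    return OptimizationResult(
        iol_model=iol_model,
        formula_id=formula_id,
        constants={name: float(c_star)},
        n_train=len(frame),
        residual_mean_error=resid,
        iterations=res.iterations,
    )


def fit_haigis_constants(
    train,
    iol_model: str = "*",
    min_eyes: int = 30,
    strict: bool = False,
) -> OptimizationResult:
    """Fit (a0, a1, a2) by ELP back-solve plus ordinary least squares.

    Eyes whose observed refraction admits no physical lens position are
    dropped with a logged count; more than 10% failures raises in strict
    mode. Raises on a rank-deficient design (e.g. constant ACD).
    """
    frame = _as_frame(train)
    if len(frame) < min_eyes:
        raise ValueError(f"need >= {min_eyes} eyes with observed refraction, got {len(frame)}")
    engine = engine_for("haigis")
    al = frame["axial_length"].to_numpy()
    acd = frame["acd"].to_numpy()
    K = np.asarray(corneal_power(frame["corneal_radius"].to_numpy(), engine.k_numerator))
    P = frame["iol_power"].to_numpy()
    obs = frame["postop_se"].to_numpy()

    d = np.full(len(frame), np.nan)
    for i in range(len(frame)):
        try:
            d[i] = back_solve_elp(al[i], K[i], P[i], obs[i])
        except OpticsError:
            pass
    ok = np.isfinite(d)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("haigis back-solve failed for %d of %d eyes", n_dropped, len(frame))
        if strict and n_dropped > 0.1 * len(frame):
            raise RuntimeError(f"back-solve failed for {n_dropped}/{len(frame)} eyes (strict mode)")
    if ok.sum() < min_eyes:
        raise ValueError("too few back-solvable eyes for regression")

    X = np.column_stack([np.ones(ok.sum()), acd[ok], al[ok]])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError("rank-deficient design matrix for Haigis regression")
    coef, _, _, _ = np.linalg.lstsq(X, d[ok], rcond=None)
    resid = d[ok] - X @ coef
    a0, a1, a2 = (float(c) for c in coef)
    mean_err = _mean_error("haigis", frame.loc[ok], {"a0": a0, "a1": a1, "a2": a2})
    return OptimizationResult(
        iol_model=iol_model,
        formula_id="haigis",
        constants={"a0": a0, "a1": a1, "a2": a2},
        n_train=int(ok.sum()),
        residual_mean_error=mean_err,
        n_dropped=n_dropped,
        residual_sd=float(np.std(resid)),
    )


def optimize_all(
    train,
    formulas=("srkt", "holladay1", "hofferq", "haigis"),
    per_model: bool = True,
    min_haigis_eyes: int = 30,
) -> dict[str, dict[str, float]]:
    """Optimize every requested formula's constants, per lens model.

    Returns the constants-JSON mapping ``{iol_model: {"A": ..., ...}}``.
    With ``per_model=False`` a single pooled entry keyed ``"*"`` is fitted.
    """
    frame = _as_frame(train)
    groups = frame.groupby("iol_model", sort=True) if per_model else [("*", frame)]
    out: dict[str, dict[str, float]] = {}
    for model, grp in groups:
        entry: dict[str, float] = {}
        for fid in formulas:
            if fid == "haigis":
                if len(grp) >= min_haigis_eyes:
                    entry.update(fit_haigis_constants(grp, iol_model=model).constants)
                else:
                    log.warning("skipping haigis for %s: only %d eyes", model, len(grp))
            else:
                entry.update(optimize_scalar_constant(fid, grp, iol_model=model).constants)
        out[str(model)] = entry
    return out
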