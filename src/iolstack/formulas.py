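"""Thin-lens vergence optics for intraocular-lens power calculation.

The four classic vergence formulas — SRK/T, Holladay 1, Hoffer Q and
Haigis — share one optical chain and differ only in conventions: the
keratometric index used to turn corneal radius into corneal power, an
axial-length adjustment, and above all the effective lens position (ELP)
model that each formula's lens constant calibrates.

The chain propagates vergence from the spectacle plane (vertex distance
``V``) through the cornea (power ``K``) to the IOL plane at depth ``d``
and requires the image to land on the retina at the optical axial length:

    z_ret = 1000 n / (AL_opt - d)        # vergence needed behind the IOL
    z_in  = z_ret - P                    # vergence incident on the IOL
    f_iol = 1000 n / z_in
    f_c   = f_iol + d                    # focal distance from the cornea
    V_c   = 1000 n / f_c                 # vergence incident on the cornea
    z     = V_c - K                      # residual refraction at the cornea
    REF   = z / (1 + (V/1000) z)         # referred to the spectacle plane

with ``n`` the aqueous/vitreous index 1.336 and all distances in mm,
powers in diopters. Every formula-specific prediction composes this
chain with its own ``K``, ``AL_opt`` and ``d``; the chain is also
invertible in closed form for the implant power (``solve_iol_power``)
and, as a quadratic, for the lens position (see constant optimization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

FORMULAS = ("srkt", "holladay1", "hofferq", "haigis")

N_AQUEOUS = 1.336
VERTEX_MM = 12.0

#: Keratometric numerator (diopter*mm): corneal power = numerator / radius.
#: SRK/T and Hoffer Q use the 1.3375 keratometric index (337.5); Holladay 1
#: uses net corneal power at index 4/3 (1000/3); Haigis uses 1.3315 (331.5).
K_NUMERATOR = {
    "srkt": 337.5,
    "holladay1": 1000.0 / 3.0,
    "hofferq": 337.5,
    "haigis": 331.5,
}

ArrayLike = Union[float, Sequence[float], np.ndarray]


class OpticsError(ValueError):
    """Unphysical optical configuration (singular vergence, ELP beyond retina...)."""


class MissingConstantError(KeyError):
    """A formula's lens constant is absent for the requested lens model."""


def corneal_power(r: ArrayLike, numerator: float = 337.5) -> np.ndarray | float:
    """Corneal power in diopters from radius ``r`` (mm): ``numerator / r``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise OpticsError("corneal radius must be positive")
    out = numerator / r
    return out if out.ndim else float(out)


def optical_axial_length(formula_id: str, al: ArrayLike) -> np.ndarray | float:
    """Measured axial length -> the optical axial length each formula uses.

    SRK/T applies its retinal-thickness correction; Holladay 1 adds a
    fixed 0.2 mm; Hoffer Q and Haigis use the measured length unchanged.
    """
    al = np.asarray(al, dtype=float)
    if formula_id == "srkt":
        out = al + 0.65696 - 0.02029 * al
    elif formula_id == "holladay1":
        out = al + 0.2
    elif formula_id in ("hofferq", "haigis"):
        out = al + 0.0
    else:
        raise ValueError(f"unknown formula {formula_id!r}")
    return out if out.ndim else float(out)


def vergence_chain(
    K: ArrayLike,
    d: ArrayLike,
    al_opt: ArrayLike,
    P: ArrayLike,
    n: float = N_AQUEOUS,
    V: float = VERTEX_MM,
) -> np.ndarray | float:
    """Predicted spectacle-plane spherical equivalent of the implanted eye.

    ``d`` is the effective lens position including any formula-specific
    shift. Raises :class:`OpticsError` when ``d >= al_opt`` or a vergence
    singularity is hit within machine tolerance.
    """
    K, d, al_opt, P = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (K, d, al_opt, P))
    )
    if np.any(d >= al_opt):
        raise OpticsError("effective lens position at or beyond the retina (d >= AL)")
    if np.any(d <= 0):
        raise OpticsError("effective lens position must be positive")
    z_ret = 1000.0 * n / (al_opt - d)
    z_in = z_ret - P
    if np.any(np.abs(z_in) < 1e-9):
        raise OpticsError("unphysical configuration: zero vergence at the IOL plane")
    f_iol = 1000.0 * n / z_in
    f_c = f_iol + d
    if np.any(np.abs(f_c) < 1e-12):
        raise OpticsError("unphysical configuration: zero corneal focal distance")
    v_c = 1000.0 * n / f_c
    z = v_c - K
    denom = 1.0 + (V / 1000.0) * z
    if np.any(np.abs(denom) < 1e-9):
        raise OpticsError("unphysical configuration: spectacle-plane singularity")
    out = z / denom
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# ELP models


def elp_srkt(al: ArrayLike, r: ArrayLike, A: float) -> np.ndarray | float:
    """SRK/T effective lens position from axial length, radius and A constant.

    Uses the corrected published form: corneal-width regression on a
    length capped by the quadratic LCOR branch above 24.2 mm, corneal
    height by the sagitta relation (square root clamped at zero for very
    steep corneas), and the A-constant-derived ACD offset.
    """
    al, r = np.broadcast_arrays(np.asarray(al, float), np.asarray(r, float))
    K = 337.5 / r
    lcor = np.where(al <= 24.2, al, -3.446 + 1.715 * al - 0.0237 * al**2)
    cw = -5.41 + 0.58412 * lcor + 0.098 * K
    h = r - np.sqrt(np.maximum(0.0, r**2 - cw**2 / 4.0))
    acd_const = 0.62467 * A - 68.747
    out = h + acd_const - 3.336
    return out if out.ndim else float(out)


def elp_holladay1(al: ArrayLike, r: ArrayLike, SF: float) -> np.ndarray | float:
    """Holladay 1 ELP: anatomical ACD from the capped corneal width plus the surgeon factor."""
    al, r = np.broadcast_arrays(np.asarray(al, float), np.asarray(r, float))
    ag = np.minimum(12.5 * al / 23.45, 13.5)
    out = 0.56 + r - np.sqrt(np.maximum(0.0, r**2 - ag**2 / 4.0)) + SF
    return out if out.ndim else float(out)


def elp_hofferq(al: ArrayLike, K: ArrayLike, pACD: float) -> np.ndarray | float:
    """Hoffer Q ELP; tangent arguments in degrees, axial length clamped to [18.5, 31]."""
    al, K = np.broadcast_arrays(np.asarray(al, float), np.asarray(K, float))
    alc = np.clip(al, 18.5, 31.0)
    m = np.where(alc <= 23.0, 1.0, -1.0)
    g = np.where(alc <= 23.0, 28.0, 23.5)
    tan = lambda deg: np.tan(np.radians(deg))
    out = (
        pACD
        + 0.3 * (alc - 23.5)
        + tan(K) ** 2
        + 0.1 * m * (23.5 - alc) ** 2 * tan(0.1 * (g - alc) ** 2)
        - 0.99166
    )
    return out if out.ndim else float(out)


def elp_haigis(acd: ArrayLike, al: ArrayLike, a0: float, a1: float, a2: float) -> np.ndarray | float:
    """Haigis ELP: the linear predictor a0 + a1*ACD + a2*AL."""
    acd, al = np.broadcast_arrays(np.asarray(acd, float), np.asarray(al, float))
    out = a0 + a1 * acd + a2 * al
    return out if out.ndim else float(out)


def haigis_defaults_from_a(A: float) -> tuple[float, float, float]:
    """Standard Haigis triple initialization from an SRK/T A constant."""
    return (0.62467 * A - 72.434, 0.4, 0.1)


# --------------------------------------------------------------------------
# Formula engines


@dataclass(frozen=True)
class FormulaEngine:
    """One formula's optical conventions, bundled.

    ``elp_shift`` is added to the ELP inside the vergence chain only
    (Hoffer Q's +0.05 mm); the ELP model output itself is what constant
    optimization regresses on.
    """

    formula_id: str
    n_aqueous: float = N_AQUEOUS
    k_numerator: float = 337.5
    vertex_mm: float = VERTEX_MM
    elp_shift: float = 0.0

    def corneal_power(self, r: ArrayLike) -> np.ndarray | float:
        return corneal_power(r, self.k_numerator)

    def optical_al(self, al: ArrayLike) -> np.ndarray | float:
        return optical_axial_length(self.formula_id, al)

    def elp(self, al: ArrayLike, r: ArrayLike, acd: ArrayLike, constants: Mapping[str, float]):
        fid = self.formula_id
        try:
            if fid == "srkt":
                return elp_srkt(al, r, constants["A"])
            if fid == "holladay1":
                return elp_holladay1(al, r, constants["SF"])
            if fid == "hofferq":
                K = corneal_power(r, 337.5)
                return elp_hofferq(al, K, constants["pACD"])
            if fid == "haigis":
                return elp_haigis(acd, al, constants["a0"], constants["a1"], constants["a2"])
        except KeyError as exc:
            raise MissingConstantError(
                f"formula {fid!r} requires constant {exc.args[0]!r}"
            ) from None
        raise ValueError(f"unknown formula {fid!r}")


def engine_for(formula_id: str, vertex_mm: float = VERTEX_MM) -> FormulaEngine:
    if formula_id not in FORMULAS:
        raise ValueError(f"unknown formula {formula_id!r}; expected one of {FORMULAS}")
    return FormulaEngine(
        formula_id=formula_id,
        k_numerator=K_NUMERATOR[formula_id],
        vertex_mm=vertex_mm,
        elp_shift=0.05 if formula_id == "hofferq" else 0.0,
    )


def _constants_for(engine: FormulaEngine, constants: Mapping, iol_model: Optional[str]) -> Mapping[str, float]:
    # constants may be flat {"A": ...} or per-model {"YP2.2": {"A": ...}}
    if iol_model is not None:
        try:
            entry = constants[iol_model]
        except KeyError:
            raise MissingConstantError(
                f"no constants for lens model {iol_model!r} (formula {engine.formula_id!r})"
            ) from None
        return entry
    return constants


def predict_refraction(
    engine: FormulaEngine | str,
    al: ArrayLike,
    r: ArrayLike,
    acd: ArrayLike,
    P: ArrayLike,
    constants: Mapping,
    iol_model: Optional[str] = None,
) -> np.ndarray | float:
    """Predicted postoperative spherical equivalent for one formula.

    ``constants`` is either a flat mapping of the formula's constant(s)
    or a per-lens-model mapping, in which case ``iol_model`` selects the
    entry.
    """
    if isinstance(engine, str):
        engine = engine_for(engine)
    entry = _constants_for(engine, constants, iol_model)
    K = engine.corneal_power(r)
    al_opt = engine.optical_al(al)
    d = engine.elp(al, r, acd, entry)
    return vergence_chain(K, np.asarray(d) + engine.elp_shift, al_opt, P, engine.n_aqueous, engine.vertex_mm)


def solve_iol_power(
    engine: FormulaEngine | str,
    al: ArrayLike,
    r: ArrayLike,
    acd: ArrayLike,
    target: ArrayLike,
    constants: Mapping,
    iol_model: Optional[str] = None,
) -> np.ndarray | float:
    """Implant power achieving ``target`` refraction — exact closed-form inverse.

    Round-trip through :func:`predict_refraction` returns ``target`` to
    1e-9 D. Raises :class:`OpticsError` when the target is unreachable
    (corneal focal point in front of the lens plane).
    """
    if isinstance(engine, str):
        engine = engine_for(engine)
    entry = _constants_for(engine, constants, iol_model)
    al = np.asarray(al, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.any(np.abs(target) >= 25.0):
        raise OpticsError("target refraction out of physically sensible range (|t| < 25 D)")
    K = np.asarray(engine.corneal_power(r), dtype=float)
    al_opt = np.asarray(engine.optical_al(al), dtype=float)
    d = np.asarray(engine.elp(al, r, acd, entry), dtype=float) + engine.elp_shift
    n, V = engine.n_aqueous, engine.vertex_mm
    z = target / (1.0 - (V / 1000.0) * target)
    v_c = z + K
    if np.any(np.abs(v_c) < 1e-12):
        raise OpticsError("unphysical configuration: zero vergence at the cornea")
    f_c = 1000.0 * n / v_c
    if np.any(f_c <= d):
        raise OpticsError("target unreachable: corneal focal distance at or before the IOL plane")
    P = 1000.0 * n / (al_opt - d) - 1000.0 * n / (f_c - d)
    return P if P.ndim else float(P)


def back_solve_elp(
    al_opt: ArrayLike,
    K: ArrayLike,
    P: ArrayLike,
    obs_ref: ArrayLike,
    n: float = N_AQUEOUS,
    V: float = VERTEX_MM,
) -> np.ndarray | float:
    """Effective lens position consistent with an observed refraction.

    Inverts the vergence chain for ``d``: the chain reduces to the
    quadratic ``d^2 - (AL + f_c) d + AL f_c - 1000 n (f_c - AL)/P = 0``
    with ``f_c`` the corneal focal distance implied by the observed
    refraction. Returns the root in ``(0, AL)``, preferring the anterior
    (smaller) one when both qualify — the physiologic lens plane sits a
    few mm behind the cornea. Raises :class:`OpticsError` on complex
    roots or no root in range.
    """
    al_opt, K, P, obs_ref = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (al_opt, K, P, obs_ref))
    )
    scalar = al_opt.ndim == 0
    al_opt, K, P, obs_ref = (np.atleast_1d(x) for x in (al_opt, K, P, obs_ref))
    if np.any(np.abs(P) < 1e-9):
        raise OpticsError("cannot back-solve ELP at zero implant power")
    z = obs_ref / (1.0 - (V / 1000.0) * obs_ref)
    v_c = z + K
    f_c = 1000.0 * n / v_c
    b = -(al_opt + f_c)
    c = al_opt * f_c - 1000.0 * n * (f_c - al_opt) / P
    disc = b * b - 4.0 * c
    if np.any(disc < 0):
        raise OpticsError("no physical ELP: complex roots of the vergence quadratic")
    sq = np.sqrt(disc)
    lo = (-b - sq) / 2.0
    hi = (-b + sq) / 2.0
    lo_ok = (lo > 0) & (lo < al_opt)
    hi_ok = (hi > 0) & (hi < al_opt)
    if np.any(~lo_ok & ~hi_ok):
        raise OpticsError("no physical ELP: no root in (0, AL)")
    out = np.where(lo_ok, lo, hi)
    return float(out[0]) if scalar else out


def mean_offset_correct(
    test_pred: ArrayLike,
    train_pred: ArrayLike,
    train_obs: ArrayLike,
) -> np.ndarray:
    """Subtract the training mean prediction error from test predictions.

    The offset is ``mean(train_pred - train_obs)`` (error = predicted -
    observed); applying the correction to the training predictions
    themselves zeroes their mean error exactly. This is the standard
    constant-free personalization for externally computed predictions.
    """
    train_pred = np.asarray(train_pred, dtype=float)
    train_obs = np.asarray(train_obs, dtype=float)
    if train_pred.size == 0:
        raise ValueError("mean-offset correction requires a non-empty training set")
    if train_pred.shape != train_obs.shape:
        raise ValueError("train_pred and train_obs must have equal length")
    offset = float(np.mean(train_pred - train_obs))
    return np.asarray(test_pred, dtype=float) - offset


def predict_cohort(
    formula_id: str,
    frame,
    constants: Mapping[str, Mapping[str, float]],
) -> np.ndarray:
    """Vectorized per-formula prediction over a cohort DataFrame.

    ``constants`` is per-lens-model; rows are grouped by ``iol_model`` so
    each group is evaluated in one array call.
    """
    engine = engine_for(formula_id)
    out = np.empty(len(frame), dtype=float)
    for model, grp in frame.groupby("iol_model", sort=False):
        idx = frame.index.get_indexer(grp.index)
        out[idx] = np.asarray(
            predict_refraction(
                engine,
                grp["axial_length"].to_numpy(),
                grp["corneal_radius"].to_numpy(),
                grp["acd"].to_numpy(),
                grp["iol_power"].to_numpy(),
                constants,
                iol_model=model,
            )
        )
    return out
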