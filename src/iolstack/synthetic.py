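"""Synthetic biometry cohorts with a known optical ground truth.

Real per-eye biometry with observed surgical outcomes is rarely
shareable, so every downstream stage here is exercised on simulated
cohorts whose generative model is known exactly:

1. Biometry (axial length, corneal radius, ACD, lens thickness, WTW) is
   drawn from a truncated multivariate normal with configurable
   marginals and correlations. Defaults reproduce the marginal
   means/SDs of a large East-Asian cataract-surgery cohort
   (AL 24.02 +/- 1.57 mm, r 7.63 +/- 0.27 mm, ACD 3.10 +/- 0.41 mm,
   LT 4.57 +/- 0.43 mm, WTW 11.74 +/- 0.41 mm).
2. The true effective lens position is Haigis-style linear in ACD and
   AL — d* = a0* + a1*ACD + a2*AL — plus a per-lens-model shift and
   Gaussian ELP noise. Because the truth is Haigis-shaped, fixed-ELP
   formulas like SRK/T are deliberately mis-specified, leaving a
   realistic accuracy gap for data-driven predictors to close.
3. The implanted power targets a draw from the surgeon's target
   refraction through the exact truth vergence chain (Haigis
   conventions), rounded to the commercial half-diopter step; the
   observed postoperative spherical equivalent is the chain refraction
   at the rounded power plus measurement/healing noise.
4. A configurable fraction of patients contributes both eyes; fellow
   eyes share a patient-level latent biometry component, producing the
   strong inter-eye correlation that makes fellow-eye exclusion matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .formulas import (
    corneal_power,
    elp_srkt,
    engine_for,
    optical_axial_length,
    vergence_chain,
)
from .records import Cohort

BIOMETRY_VARS = ("axial_length", "corneal_radius", "acd", "lens_thickness", "wtw")

#: Training-cohort marginals: mean, sd, (lower, upper) truncation.
DEFAULT_MARGINALS = {
    "axial_length": (24.02, 1.57, (20.0, 32.0)),
    "corneal_radius": (7.63, 0.27, (6.5, 9.0)),
    "acd": (3.10, 0.41, (1.8, 4.8)),
    "lens_thickness": (4.57, 0.43, (3.0, 6.2)),
    "wtw": (11.74, 0.41, (10.2, 13.3)),
}

#: Physiologically signed correlations (longer eyes: deeper chambers,
#: wider corneas; deeper chambers: thinner lenses). Real joint structure
#: is facility-specific; these are stipulated, not estimated.
DEFAULT_CORRELATIONS = {
    ("axial_length", "acd"): 0.4,
    ("acd", "lens_thickness"): -0.4,
    ("axial_length", "wtw"): 0.3,
}

DEFAULT_IOL_MODELS = {
    # label -> (sampling weight, true ELP shift in mm)
    "LENS-A": (0.5, 0.0),
    "LENS-B": (0.3, 0.15),
    "LENS-C": (0.2, -0.15),
}


def correlation_matrix(corr: dict[tuple[str, str], float] | np.ndarray) -> np.ndarray:
    if isinstance(corr, np.ndarray):
        return corr
    k = len(BIOMETRY_VARS)
    mat = np.eye(k)
    idx = {v: i for i, v in enumerate(BIOMETRY_VARS)}
    for (a, b), rho in corr.items():
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = rho
    return mat


@dataclass
class SyntheticConfig:
    n_patients: int = 2010
    bilateral_fraction: float = 0.657  # ~3331 eyes from 2010 patients
    seed: int = 0
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    truth_formula: str = "haigis"  # "haigis" (default) or "srkt" ground truth
    truth_constants: tuple[float, float, float] = (-1.72, 0.277, 0.260)
    truth_a_constant: float = 119.2  # used when truth_formula == "srkt"
    elp_noise_sd: float = 0.1  # mm
    refraction_noise_sd: float = 0.25  # D
    target_refraction: tuple[float, float] = (-0.3, 0.3)  # mean, sd (D)
    target_bounds: tuple[float, float] = (-3.5, 0.5)
    power_step: float = 0.5  # commercial IOL labeling increment
    iol_models: dict = field(default_factory=lambda: dict(DEFAULT_IOL_MODELS))
    fellow_eye_rho: float = 0.7  # share of biometry variance at patient level
    age_mean: float = 72.0
    age_sd: float = 9.0
    age_bounds: tuple[float, float] = (40.0, 95.0)

    def validate(self) -> None:
        mat = correlation_matrix(self.correlations)
        if not np.allclose(mat, mat.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(mat).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        for name, (mu, sd, (lo, hi)) in self.marginals.items():
            if sd <= 0:
                raise ValueError(f"sd for {name} must be positive")
            if not lo < mu < hi:
                raise ValueError(f"mean of {name} outside its truncation bounds")
        if self.power_step <= 0:
            raise ValueError("power_step must be positive")
        if self.truth_formula not in ("haigis", "srkt"):
            raise ValueError("truth_formula must be 'haigis' or 'srkt'")
        if not 0.0 <= self.bilateral_fraction <= 1.0:
            raise ValueError("bilateral_fraction must lie in [0, 1]")
        if not 0.0 <= self.fellow_eye_rho <= 1.0:
            raise ValueError("fellow_eye_rho must lie in [0, 1]")


def _truncated_mvn_pair(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    n_patients: int,
) -> np.ndarray:
    """Correlated biometry draws for both potential eyes of each patient.

    Returns shape (2 * n_patients, k): rows [0, n) are first eyes, rows
    [n, 2n) fellow eyes. Fellow eyes mix a shared patient-level draw with
    an eye-level draw, both carrying the full cross-variable correlation,
    so each eye keeps the target marginal law while fellow eyes correlate
    at ``fellow_eye_rho``. Truncation is enforced by resampling
    out-of-bounds eyes; the bounds sit several SDs out, so acceptance is
    high.
    """
    mat = correlation_matrix(cfg.correlations)
    chol = np.linalg.cholesky(mat)
    k = len(BIOMETRY_VARS)
    mus = np.array([cfg.marginals[v][0] for v in BIOMETRY_VARS])
    sds = np.array([cfg.marginals[v][1] for v in BIOMETRY_VARS])
    los = np.array([cfg.marginals[v][2][0] for v in BIOMETRY_VARS])
    his = np.array([cfg.marginals[v][2][1] for v in BIOMETRY_VARS])

    def draw_std(n: int) -> np.ndarray:
        return rng.standard_normal((n, k)) @ chol.T

    rho = cfg.fellow_eye_rho
    z_pat = draw_std(n_patients)
    eye1 = np.sqrt(rho) * z_pat + np.sqrt(1 - rho) * draw_std(n_patients)
    eye2 = np.sqrt(rho) * z_pat + np.sqrt(1 - rho) * draw_std(n_patients)

    vals1, vals2 = mus + sds * eye1, mus + sds * eye2
    for vals in (vals1, vals2):
        for _ in range(1000):
            bad = np.any((vals < los) | (vals > his), axis=1)
            if not bad.any():
                break
            vals[bad] = mus + sds * draw_std(int(bad.sum()))
        else:
            raise RuntimeError("truncation rejection sampling did not converge")
    return np.vstack([vals1, vals2])


def generate_cohort(cfg: Optional[SyntheticConfig] = None, **overrides) -> Cohort:
    """Draw a cohort from the generative model described in the module docstring.

    Deterministic given ``cfg.seed``. Keyword overrides are applied to a
    copy of ``cfg`` (or of the defaults when ``cfg`` is None).
    """
    cfg = replace(cfg or SyntheticConfig(), **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_patients
    bilateral = rng.random(n) < cfg.bilateral_fraction
    vals = _truncated_mvn_pair(rng, cfg, n)
    vals1, vals2 = vals[:n], vals[n:]

    ages = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    lo, hi = cfg.age_bounds
    for _ in range(100):
        bad = (ages < lo) | (ages > hi)
        if not bad.any():
            break
        ages[bad] = rng.normal(cfg.age_mean, cfg.age_sd, size=int(bad.sum()))

    labels = list(cfg.iol_models)
    weights = np.array([cfg.iol_models[m][0] for m in labels], dtype=float)
    weights = weights / weights.sum()
    shifts = {m: cfg.iol_models[m][1] for m in labels}

    a0, a1, a2 = cfg.truth_constants
    engine = engine_for(cfg.truth_formula)

    first_eye = rng.integers(0, 2, size=n)  # which laterality the first eye gets
    rows = []
    for i in range(n):
        pid = f"P{i:05d}"
        eyes = [(vals1[i], "right" if first_eye[i] else "left")]
        if bilateral[i]:
            eyes.append((vals2[i], "left" if first_eye[i] else "right"))
        for biom, lat in eyes:
            al, r, acd, lt, wtw = biom
            model = labels[rng.choice(len(labels), p=weights)]
            if cfg.truth_formula == "srkt":
                d_true = float(elp_srkt(al, r, cfg.truth_a_constant)) + shifts[model]
            else:
                d_true = a0 + a1 * acd + a2 * al + shifts[model]
            if cfg.elp_noise_sd > 0:
                d_true += rng.normal(0.0, cfg.elp_noise_sd)
            target = np.clip(
                rng.normal(*cfg.target_refraction), *cfg.target_bounds
            )
            K = corneal_power(r, engine.k_numerator)
            al_opt = float(optical_axial_length(cfg.truth_formula, al))
            p_exact = _power_for_target(K, d_true, al_opt, target)
            p_round = np.round(p_exact / cfg.power_step) * cfg.power_step
            se = vergence_chain(K, d_true, al_opt, p_round)
            if cfg.refraction_noise_sd > 0:
                se += rng.normal(0.0, cfg.refraction_noise_sd)
            rows.append(
                dict(
                    patient_id=pid,
                    eye_id=f"{pid}-{lat[0].upper()}",
                    laterality=lat,
                    age=round(float(ages[i]), 1),
                    axial_length=float(al),
                    corneal_radius=float(r),
                    acd=float(acd),
                    lens_thickness=float(lt),
                    wtw=float(wtw),
                    iol_model=model,
                    iol_power=float(p_round),
                    postop_se=float(se),
                )
            )
    frame = pd.DataFrame(rows)
    return Cohort.from_frame(frame, provenance=f"synthetic seed={cfg.seed} n_patients={n}")


def _power_for_target(K: float, d: float, al: float, target: float) -> float:
    """Closed-form truth-model inverse (Haigis conventions, known true ELP)."""
    n, V = 1.336, 12.0
    z = target / (1.0 - (V / 1000.0) * target)
    f_c = 1000.0 * n / (z + K)
    return 1000.0 * n / (al - d) - 1000.0 * n / (f_c - d)


def true_elp(cfg: SyntheticConfig, acd, al, iol_model=None):
    """Noise-free ground-truth ELP for generated biometry (diagnostic helper)."""
    a0, a1, a2 = cfg.truth_constants
    shift = cfg.iol_models[iol_model][1] if iol_model is not None else 0.0
    return a0 + a1 * np.asarray(acd) + a2 * np.asarray(al) + shift


def split_patientwise(cohort: Cohort, n_test: int, seed: int = 0, allow_empty_train: bool = False):
    """Patient-level train/test split with fellow-eye exclusion.

    Picks ``n_test`` distinct patients, keeps exactly one eye per test
    patient (random choice for bilateral patients) and discards their
    fellow eyes entirely; every remaining patient's eye(s) go to
    training. No patient appears on both sides.
    """
    rng = np.random.default_rng(seed)
    patients = cohort.patient_ids
    if n_test > len(patients):
        raise ValueError(f"n_test={n_test} exceeds patient count {len(patients)}")
    if n_test == len(patients) and not allow_empty_train:
        raise ValueError("n_test equals patient count; pass allow_empty_train=True to permit")
    test_patients = set(rng.choice(patients, size=n_test, replace=False).tolist())

    by_patient: dict[str, list] = {}
    for rec in cohort:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    train_recs, test_recs = [], []
    for pid in patients:
        recs = by_patient[pid]
        if pid in test_patients:
            keep = recs[int(rng.integers(0, len(recs)))] if len(recs) > 1 else recs[0]
            test_recs.append(keep)  # fellow eye discarded
        else:
            train_recs.extend(recs)
    return (
        Cohort(train_recs, provenance=f"{cohort.provenance} [train]"),
        Cohort(test_recs, provenance=f"{cohort.provenance} [test n={n_test}]"),
    )
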