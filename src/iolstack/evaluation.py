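"""Accuracy metrics and the paired statistical-comparison battery.

Prediction error is signed, error = predicted − observed spherical
equivalent (diopters). Methods are compared on the same eyes (paired
design): a Friedman test over absolute errors asks whether the methods
differ at all; each method is then compared with a designated reference
by Wilcoxon signed-rank or paired t (a Shapiro–Wilk normality gate
decides which), with Bonferroni multiplication over the pairwise
comparisons performed. Proportions of eyes within an absolute-error
threshold are compared with Pearson chi-squared WITHOUT continuity
correction — with Yates' correction the test is conservative for these
sample sizes and does not match standard printed values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

WITHIN_THRESHOLDS = (0.25, 0.5, 1.0)

#: Axial-length subgroup bins (mm): short, middle, long. Left-closed.
AXIAL_BINS = ((0.0, 22.0), (22.0, 24.0), (24.0, float("inf")))
AXIAL_BIN_NAMES = ("short", "middle", "long")


@dataclass
class MethodErrors:
    """One method's signed per-eye errors, aligned by eye_id across methods."""

    method: str
    eye_ids: list[str]
    errors: np.ndarray

    def __post_init__(self):
        self.errors = np.asarray(self.errors, dtype=float)
        if len(self.eye_ids) != len(self.errors):
            raise ValueError("eye_ids and errors must have equal length")


def summarize_errors(errors) -> dict:
    """MAE, median AE, SD of signed error, and strict within-threshold counts.

    The within counts use strict ``<`` (an error of exactly 0.5 D is not
    "less than 0.5 D").
    """
    e = errors.errors if isinstance(errors, MethodErrors) else np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    ae = np.abs(e)
    return {
        "n": int(e.size),
        "mae": float(ae.mean()),
        "medae": float(np.median(ae)),
        "mean_error": float(e.mean()),
        "sd": float(e.std(ddof=1)) if e.size > 1 else 0.0,
        "within": {str(t): int((ae < t).sum()) for t in WITHIN_THRESHOLDS},
    }


def _friedman_abs(columns: Sequence[np.ndarray]) -> tuple[float, float]:
    cols = [np.abs(np.asarray(c, dtype=float)) for c in columns]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        return 0.0, 1.0  # identical columns: no evidence of any difference
    if len(cols) == 2:
        # Friedman needs >= 3 groups; for two paired groups it reduces to
        # the sign test on the per-eye differences
        diff = cols[0] - cols[1]
        nz = diff[diff != 0]
        if nz.size == 0:
            return 0.0, 1.0
        k = int((nz > 0).sum())
        res = stats.binomtest(k, nz.size, 0.5)
        return float(k), float(res.pvalue)
    stat, p = stats.friedmanchisquare(*cols)
    if not np.isfinite(stat):  # full ties in every block
        return 0.0, 1.0
    return float(stat), float(p)


def compare_paired(
    methods: Sequence[MethodErrors],
    reference: Optional[str] = None,
    alpha: float = 0.05,
    normality_gate: str = "per-group",
) -> dict:
    """Friedman omnibus plus reference-vs-each pairwise tests on absolute errors.

    ``reference`` defaults to the first method. The pairwise test is the
    paired t unless the Shapiro–Wilk test rejects normality at 0.05 —
    applied to each group's absolute errors (``per-group``, default) or
    to the paired differences (``differences``). Adjusted p-values are
    Bonferroni: ``min(1, raw * n_comparisons)``. Pairwise results are
    reported even when the Friedman p exceeds ``alpha``, flagged via
    ``friedman_significant``.
    """
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    n = len(methods[0].errors)
    for m in methods:
        if len(m.errors) != n or m.eye_ids != methods[0].eye_ids:
            raise ValueError(f"method {m.method!r} is not paired with {methods[0].method!r}")
    ref_name = reference or methods[0].method
    by_name = {m.method: m for m in methods}
    if ref_name not in by_name:
        raise ValueError(f"reference {ref_name!r} not among methods")

    fr_stat, fr_p = _friedman_abs([m.errors for m in methods])
    others = [m for m in methods if m.method != ref_name]
    n_comp = len(others)
    ref_abs = np.abs(by_name[ref_name].errors)

    pairwise = []
    for m in others:
        a = np.abs(m.errors)
        diff = a - ref_abs
        if normality_gate == "differences":
            normal = _shapiro_ok(diff)
        else:
            normal = _shapiro_ok(a) and _shapiro_ok(ref_abs)
        if normal:
            test = "paired-t"
            if np.allclose(diff, 0.0):
                raw = 1.0
            else:
                raw = float(stats.ttest_rel(a, ref_abs).pvalue)
        else:
            test = "wilcoxon"
            raw = 1.0 if np.allclose(diff, 0.0) else float(_wilcoxon_p(diff))
        pairwise.append(
            {
                "a": m.method,
                "b": ref_name,
                "test": test,
                "raw_p": raw,
                "adj_p": float(min(1.0, raw * n_comp)),
            }
        )
    return {
        "friedman": {"stat": fr_stat, "p": fr_p},
        "friedman_significant": bool(fr_p < alpha),
        "reference": ref_name,
        "n_comparisons": n_comp,
        "pairwise": pairwise,
    }


def _shapiro_ok(x: np.ndarray, alpha: float = 0.05) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.allclose(x, x[0]):
        return True  # too few / degenerate: cannot reject normality
    return stats.shapiro(x).pvalue >= alpha


def _wilcoxon_p(diff: np.ndarray) -> float:
    d = diff[diff != 0.0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    return stats.wilcoxon(d, method=method).pvalue


def proportion_chi2(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Pearson chi-squared p for two proportions, no continuity correction."""
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n or n <= 0:
            raise ValueError(f"invalid count {k}/{n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate 2x2 table: a zero margin")
    if k1 * n2 == k2 * n1:
        return 1.0  # identical proportions
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def subgroup_by_axial(
    axial_lengths: Sequence[float],
    methods: Sequence[MethodErrors],
    reference: Optional[str] = None,
) -> dict:
    """Per-axial-length-bin summaries and paired comparisons.

    Bins: short [0, 22), middle [22, 24), long [24, inf) mm. An empty bin
    is reported with n = 0 and no tests.
    """
    al = np.asarray(axial_lengths, dtype=float)
    if any(len(m.errors) != al.size for m in methods):
        raise ValueError("axial lengths not aligned with method errors")
    out = {}
    for name, (lo, hi) in zip(AXIAL_BIN_NAMES, AXIAL_BINS):
        mask = (al >= lo) & (al < hi)
        n_bin = int(mask.sum())
        entry: dict = {"n": n_bin, "bounds_mm": [lo, hi]}
        if n_bin > 0:
            sub = [
                MethodErrors(
                    m.method,
                    [e for e, keep in zip(m.eye_ids, mask) if keep],
                    m.errors[mask],
                )
                for m in methods
            ]
            entry["methods"] = {m.method: summarize_errors(m) for m in sub}
            if n_bin >= 5 and len(methods) >= 2:
                entry["tests"] = compare_paired(sub, reference=reference)
        out[name] = entry
    return out
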