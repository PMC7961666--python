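# Methods

## The optical model

Every prediction in this package runs through one thin-lens vergence
chain (see the README for the equations). An eye is reduced to two
refracting planes — cornea and IOL — separated by the effective lens
position (ELP) `d`, with the image constrained to land at the optical
axial length. Refraction is referred to the spectacle plane at a 12 mm
vertex distance (configurable on the engine); the outcome variable
throughout is the subjective spherical equivalent in diopters.

The four formulas are the chain plus conventions:

| formula    | corneal power | optical axial length        | ELP model |
|------------|---------------|-----------------------------|-----------|
| SRK/T      | 337.5 / r     | AL + 0.65696 − 0.02029·AL   | corneal-height sagitta + A-constant offset, long-eye LCOR quadratic above 24.2 mm |
| Holladay 1 | (1000/3) / r  | AL + 0.2                    | capped corneal width sagitta + surgeon factor |
| Hoffer Q   | 337.5 / r     | AL                          | pACD + tangent terms (degrees), AL clamped to [18.5, 31]; +0.05 mm shift inside the chain |
| Haigis     | 331.5 / r     | AL                          | a0 + a1·ACD + a2·AL |

The keratometric numerators are the single largest interoperability
pitfall between published implementations and are frozen per formula as
above. Square roots in the sagitta terms are clamped at zero for very
steep corneas. The SRK/T long-eye branch has a genuine 0.0105 mm ELP
step at AL = 24.2 mm; it is the published behaviour and is reproduced,
not smoothed.

Two exact inverses of the chain are used: the closed form for implant
power given a target refraction, and the ELP quadratic
`d² − (L + f_c)·d + L·f_c − 1000·n·(f_c − L)/P = 0` given an observed
refraction. The quadratic's root in `(0, L)` is taken, preferring the
anterior root when both qualify (physiologic pseudophakic lens planes
sit 2–8 mm behind the cornea). A complex-root or out-of-range case is a
reportable "no physical ELP" error; it arises for strongly hyperopic
observations at high implant power.

Note one sign fact the code relies on: at fixed implant power,
predicted refraction is monotone *increasing* in ELP (a deeper lens
predicts a more hyperopic outcome), and therefore increasing in every
scalar lens constant. This matches the clinical rule of thumb that
raising an A constant raises the recommended power for the same target.

## Constant personalization

Scalar constants (A, surgeon factor, pACD) solve
`mean(predicted − observed) = 0` on the training eyes of one lens model
by Brent's method; by the monotonicity above the root is unique, and
the residual mean error on success is below 1e−6 D by construction. The
initial brackets (A ∈ [112, 126], SF ∈ [−2, 6], pACD ∈ [2, 9]) are
auto-expanded by up to ±10 units; a constant that drives any eye's ELP
non-positive (or past the retina) is treated as an infeasible extreme
of the matching sign so bracketing can proceed. An alternative
MAE-minimizing objective is not offered: zero mean error is the
standard personalization convention and is what the mean-offset
correction for external predictions implicitly assumes.

The Haigis triple is fitted by the original two-stage recipe: back-solve
each eye's ELP from its observed refraction under Haigis conventions,
then ordinary least squares of `d` on `(1, ACD, AL)`. Eyes whose
back-solve fails are dropped and counted (typically <0.1% on synthetic
cohorts; >10% raises in strict mode). At least 30 eyes are required per
lens model; with fewer, the model is skipped with a warning. The
Haigis-from-A initialization `a0 = 0.62467·A − 72.434, a1 = 0.4,
a2 = 0.1` is provided for lenses with only an A constant.

Mean-offset correction (for externally computed predictions that cannot
be re-derived, e.g. from a web calculator) subtracts the training-set
mean signed error from test predictions; applied to the training set
itself the mean error is exactly zero.

## The synthetic cohort

The generator emulates a large East-Asian cataract-surgery population:
biometry is a truncated multivariate normal with marginals AL
24.02 ± 1.57 mm, r 7.63 ± 0.27 mm, ACD 3.10 ± 0.41 mm, LT 4.57 ± 0.43 mm,
WTW 11.74 ± 0.41 mm; implanted powers then centre near 19.6 D and
observed refractions near −0.2 D, matching that population's headline
summaries. No joint-distribution data are available for such cohorts,
so the correlations are stipulated, physiologically signed values
(AL–ACD 0.4, ACD–LT −0.4, AL–WTW 0.3, others 0), configurable but not
estimated. Age is N(72, 9) truncated to [40, 95] and is a candidate
feature only — it does not enter the optical truth.

The ground truth is Haigis-style by default: true ELP
`d* = −1.72 + 0.277·ACD + 0.260·AL` plus a per-lens-model shift (three
synthetic lens labels at 0/+0.15/−0.15 mm, weights 0.5/0.3/0.2) and
N(0, 0.1 mm) ELP noise. The implanted power targets a draw from
N(−0.3, 0.3) D truncated to [−3.5, 0.5], solved exactly through the
truth chain and rounded to the commercial 0.5 D step; the observed
refraction is the chain value at the rounded power plus N(0, 0.25 D)
noise covering measurement and healing variability. Because the truth
is Haigis-shaped, fixed-ELP formulas such as SRK/T are deliberately
mis-specified, which is precisely the residual structure a stacked
learner can exploit; a `truth_formula="srkt"` variant (A = 119.2)
exists for recovery experiments where the fitted formula is correctly
specified. With both noise terms at zero the generative loop closes
exactly: the truth constants reproduce every observed refraction to
machine precision, which the tests assert.

Defaults are 2010 patients with 65.7% contributing both eyes (≈3331
eyes); fellow eyes share 70% of their biometry variance at the patient
level. The patient-wise split keeps one eye per test patient and
discards the fellow eye entirely, so no patient spans both sets — at
500 test patients the default cohort leaves ≈2500 training eyes, and
the study-scale runs in `scripts/acceptance.py` use 2210 patients so
that ≈2830 remain.

What passing tests on this cohort do *not* show: robustness to
keratoconus, post-refractive corneas, silicone-oil eyes or other
excluded pathologies; to device-specific measurement bias; or to real
joint biometry structure beyond the stipulated correlations. The
generator is a controlled instrument, not a patient-data substitute.

## The stacked predictor

Candidate features are age, AL, r, ACD, LT, WTW, the eye's optimized
lens constant, implant power, and the base formula's predicted
refraction. The constant feature uses the base formula's own constant
(a0 for Haigis, as its only per-model additive term). Features are
standardized to mean 0 / SD 1 with the population-SD convention
(divide by n), using training statistics only; the target stays in
diopters.

The base formula is chosen by gradient-boosting feature importance in a
shoot-out containing all four formulas' predictions (ties break to the
canonical order, SRK/T first). Feature subsets are scored by 5-fold
cross-validated MAE with a fast gradient-boosting selector
(100 trees, depth 3, learning rate 0.1), exhaustively over all subsets
of the supplied candidates; ties prefer fewer features. Exhaustive
search over all nine candidates costs 511 × 5 fits (minutes at cohort
scale), so the routine pipeline default instead uses a fixed
optics-relevant set — AL, r, ACD, LT, implant power, and the base
formula prediction — and exposes `subset_search: true` for a full run.
On this generative model the exhaustive search ranks that set within
cross-validation noise (≈0.001 D) of its winner, which differs only in
swapping lens thickness for white-to-white; subsets without the formula
prediction score clearly worse.

Model kinds and default grids (cross-validated grid search on MAE,
5 folds, fixed fold seed):

- `svr`: radial-basis SVR, C ∈ {0.1, 1, 10, 100}, ε ∈ {0.01, 0.1}, γ ∈ {0.01, 0.1, 1};
- `rfr`: random forest, 100/300 trees, depth {∞, 4, 8};
- `gbr`: gradient boosting, learning rate {0.01, 0.1}, 100/500 trees, depth {2, 3, 4};
- `nn`: an ensemble of 30 fully connected networks (hidden layers
  16 and 8, rectifier activations, linear output, squared-error loss,
  adaptive-moment optimizer, up to 200 epochs with early stopping on a
  10% validation split) differing only by seed; the prediction is the
  member mean. Averaging removes initialization jitter — disjoint
  10-member averages fluctuate across seeds at roughly 1/√10 of a
  single network, which the tests verify. Refraction prediction has few
  inputs and smooth structure, so a small network suffices.

A reduced grid set (`grids="fast"`) covering the same families is used
by the routine pipeline and the reproduction script; the full grids
remain available via `grids="full"`. All fits are deterministic given
data, grid and seeds.

## Evaluation conventions

Prediction error is predicted − observed, signed. Summaries report MAE,
median AE, SD of signed error, and counts within 0.25/0.5/1.0 D using
strict `<`. Methods are compared on identical eyes: a Friedman omnibus
on absolute errors (reduced to the exact sign test when only two
methods are present, since Friedman needs three groups), then each
method against a designated reference with paired t or Wilcoxon
signed-rank — Wilcoxon when Shapiro–Wilk rejects normality at 0.05 in
either group's absolute errors (a `differences` gate variant is a flag;
the granularity is a convention, not a derivable fact). Wilcoxon uses
the exact null for n ≤ 25 and matches brute-force sign-flip enumeration,
which the tests verify. Bonferroni adjustment multiplies by the number
of pairwise comparisons actually performed, capped at 1; raw and
adjusted values are both reported so either presentation is
recoverable. Pairwise results are reported even when the omnibus is
non-significant, flagged accordingly.

Two-proportion comparisons use Pearson chi-squared *without* continuity
correction — the convention pinned by the reference worked examples
(406/500 vs 422, 412, 414 of 500 giving p = 0.1800, 0.6229, 0.5102).
Axial-length subgroups are [0, 22), [22, 24), [24, ∞) mm, left-closed.

## Numerical choices and degenerate inputs

- All computation in double precision; units are mm, diopters, years.
- Vergence singularities (zero vergence at a plane, ELP at/beyond the
  retina, spectacle-plane pole) raise typed errors rather than NaN.
- Record validation is total: NaN and non-numeric values are reported
  as bound violations, never as exceptions mid-pipeline.
- Identical method columns short-circuit the Friedman test to
  statistic 0, p 1 (rank ties make the generic statistic undefined).
- A rank-deficient Haigis design (e.g. ACD collinear with AL) raises;
  a zero-variance feature column refuses to standardize.
- Cohort CSVs are comma-separated, UTF-8, with a mandatory header and
  an empty cell for a missing observed refraction; no unit or format
  autodetection anywhere.

## Problem sizes used in tests and reproduction

Unit and property tests run on cohorts of 100–700 patients; the
reproduction script and acceptance tests use study-scale runs (~2830
training eyes, 500 test eyes, three seeds) with the fast grids and the
30-member neural ensemble. These sizes were chosen so the full suite
and the script each complete in a few minutes on one CPU while keeping
every estimate's sampling error well inside the asserted tolerances.

## Known limitations

- The Barrett Universal II formula is not implemented (unpublished);
  externally computed predictions can be ingested and offset-corrected
  instead.
- No toric/cylinder handling; outcomes are spherical equivalents.
- No axial-length modification rules (e.g. Wang–Koch) and no transfer
  of constants between formulas beyond the documented Haigis-from-A
  initialization.
- The synthetic generator's correlations and per-lens shifts are
  stipulated; conclusions about real cohorts require real data.
- Serialized stacker models are Python pickles and are not portable
  across library versions.
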