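"""Discriminative- and predictive-validity statistics.

Implements the analysis conventions of the reference protocol:

* side asymmetry summarised by the **Difference Index**
  ``DI(%) = 100 * (symptomatic - asymptomatic) / asymptomatic``;
* paired side comparisons gated by a Shapiro–Wilk test on the paired
  differences — paired Student's *t* when normality is not rejected at
  α = 0.05, Wilcoxon signed-rank otherwise — with **Hedge's g**
  (pooled-SD standardised mean difference with small-sample correction)
  as the effect size;
* group-versus-subgroup bivariate comparisons (independent *t* /
  chi-squared without continuity correction);
* biomarker–clinical association matrices using Pearson correlation when
  both marginals pass Shapiro–Wilk, Spearman otherwise, with coefficient
  magnitudes classified on the conventional negligible / low / moderate /
  high / very-high bands.

Hypothesis tests are delegated to :mod:`scipy.stats`; the effect-size
and index formulas, test gating and report assembly are defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InvalidParameterError, SchemaError
from .geometry import PLANES

PAIRED_T = "paired_t"
WILCOXON = "wilcoxon"
PEARSON = "pearson"
SPEARMAN = "spearman"

#: half-open |r| bands; boundary values go to the upper category
_STRENGTH_BANDS = [(0.3, "negligible"), (0.5, "low"), (0.7, "moderate"),
                   (0.9, "high"), (1.0 + 1e-12, "very_high")]

#: |g| magnitude bands
_MAGNITUDE_BANDS = [(0.2, "negligible"), (0.5, "small"), (0.8, "medium"),
                    (np.inf, "large")]

MUB_NAMES = ("thickness", "echogenicity", "homogeneity")

#: per-side clinical variables: column stem -> unit suffix
PAIRED_CLINICAL_VARS = {"soleus_lunge": "cm", "gastroc_lunge": "cm",
                        "plantarflexion": "nm", "dorsiflexion": "nm"}

#: pain / function variables correlated against both Sympt and DI biomarkers
FUNCTION_VARS = ("visa_total", "visa_q1", "visa_q2", "visa_q3", "visa_q4",
                 "visa_q5", "visa_q6", "visa_q7", "visa_q8", "lefs")


def difference_index(symptomatic: float, asymptomatic: float) -> float:
    """Relative side difference in percent (asymptomatic side as reference)."""
    if asymptomatic == 0:
        raise DegenerateDataError("difference index undefined for a zero "
                                  "asymptomatic reference value")
    return 100.0 * (symptomatic - asymptomatic) / asymptomatic


def difference_index_series(symptomatic, asymptomatic) -> np.ndarray:
    """Vectorised per-subject DI; zero references yield NaN."""
    s = np.asarray(symptomatic, dtype=float)
    a = np.asarray(asymptomatic, dtype=float)
    return np.where(a == 0, np.nan, 100.0 * (s - a) / np.where(a == 0, 1.0, a))


def classify_correlation(r: float) -> str:
    """Strength label of a correlation coefficient magnitude."""
    if not np.isfinite(r) or abs(r) > 1:
        raise InvalidParameterError(f"|r| must be <= 1, got {r!r}")
    for upper, label in _STRENGTH_BANDS:
        if abs(r) < upper:
            return label
    return "very_high"  # pragma: no cover


def effect_magnitude(g: float) -> str:
    """Conventional |g| magnitude band (>0.2 small, >0.5 medium, >0.8 large)."""
    for upper, label in _MAGNITUDE_BANDS:
        if abs(g) <= upper:
            return label
    return "large"  # pragma: no cover


def hedges_g(mean1: float, sd1: float, mean2: float, sd2: float,
             n1: int, n2: int) -> float:
    """Hedge's g for (group2 - group1), pooled SD, small-sample corrected.

    ``g = (mean2 - mean1) / SD_pooled * J`` with
    ``SD_pooled = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2))``
    (which reduces to ``sqrt((sd1^2 + sd2^2)/2)`` for equal n) and the
    correction ``J = 1 - 3 / (4 (n1+n2-2) - 1)``.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise InvalidParameterError("standard deviations must be non-negative")
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    if pooled == 0:
        raise DegenerateDataError("pooled standard deviation is zero")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    return float((mean2 - mean1) / pooled * j)


@dataclass(frozen=True)
class PairedComparisonResult:
    """One side-comparison row (means, SDs, DI, g, gated test, p)."""

    variable: str
    n: int
    mean_asympt: float
    sd_asympt: float
    mean_sympt: float
    sd_sympt: float
    di_percent: float            # from group means (primary)
    di_percent_subject: float    # mean of per-subject DIs (variant)
    hedges_g: float
    magnitude: str
    test_used: str
    p_value: float
    shapiro_p: float


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def paired_compare(x_sympt, x_asympt, variable: str = "",
                   alpha: float = 0.05) -> PairedComparisonResult:
    """Compare the symptomatic against the asymptomatic side.

    Shapiro–Wilk on the paired differences selects the paired *t*-test
    (p >= alpha) or the Wilcoxon signed-rank test (p < alpha;
    zero differences dropped, mid-rank ties).
    """
    s, a = _pairwise_complete(x_sympt, x_asympt)
    n = s.size
    if n < 3:
        raise InvalidParameterError(f"need >= 3 complete pairs, got {n}")
    d = s - a
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= alpha:
        test_used, p = PAIRED_T, float(stats.ttest_rel(s, a).pvalue)
    else:
        test_used = WILCOXON
        p = float(stats.wilcoxon(d, zero_method="wilcox", correction=False).pvalue)
    mean_a, sd_a = float(a.mean()), float(a.std(ddof=1))
    mean_s, sd_s = float(s.mean()), float(s.std(ddof=1))
    g = hedges_g(mean_a, sd_a, mean_s, sd_s, n, n)
    di_subject = difference_index_series(s, a)
    return PairedComparisonResult(
        variable=variable, n=n,
        mean_asympt=mean_a, sd_asympt=sd_a, mean_sympt=mean_s, sd_sympt=sd_s,
        di_percent=difference_index(mean_s, mean_a),
        di_percent_subject=float(np.nanmean(di_subject)),
        hedges_g=g, magnitude=effect_magnitude(g),
        test_used=test_used, p_value=p, shapiro_p=sw_p)


def group_compare(group_values, subgroup_values, kind: str = "continuous"
                  ) -> tuple[float, float]:
    """Group-versus-subgroup bivariate comparison -> (statistic, p).

    ``continuous``: independent two-sample Student's *t* (equal
    variances).  ``categorical``: Pearson chi-squared without continuity
    correction on an r x c count table passed as
    ``(group_counts, subgroup_counts)``.
    """
    if kind == "continuous":
        g = np.asarray(group_values, dtype=float)
        s = np.asarray(subgroup_values, dtype=float)
        g, s = g[np.isfinite(g)], s[np.isfinite(s)]
        if g.size < 2 or s.size < 2:
            raise InvalidParameterError("each group needs >= 2 observations")
        res = stats.ttest_ind(g, s, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if kind == "categorical":
        table = np.asarray([group_values, subgroup_values], dtype=float)
        if table.min() < 0 or table.sum() == 0:
            raise InvalidParameterError("count table must be non-negative, non-empty")
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    raise InvalidParameterError(f"unknown comparison kind {kind!r}")


@dataclass(frozen=True)
class CorrelationResult:
    """One association cell of the report."""

    x_name: str
    y_name: str
    r: float
    method: str
    p_value: float
    n_pairs: int
    strength: str
    significant: bool


def correlate(x, y, x_name: str = "x", y_name: str = "y",
              normality: bool | None = None,
              alpha: float = 0.05) -> CorrelationResult:
    """Association between two vectors after pairwise deletion.

    Pearson when both marginals pass Shapiro–Wilk at ``alpha`` (or when
    ``normality=True`` is asserted by the caller), Spearman otherwise.
    """
    xs, ys = _pairwise_complete(x, y)
    n = xs.size
    if n < 3:
        raise InvalidParameterError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateDataError("zero variance in one of the vectors")
    if normality is None:
        normality = (stats.shapiro(xs).pvalue >= alpha
                     and stats.shapiro(ys).pvalue >= alpha)
    if normality:
        method, res = PEARSON, stats.pearsonr(xs, ys)
    else:
        method, res = SPEARMAN, stats.spearmanr(xs, ys)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(x_name=x_name, y_name=y_name, r=r, method=method,
                             p_value=p, n_pairs=n,
                             strength=classify_correlation(r),
                             significant=bool(p < alpha))


def _placeholder_cell(x_name: str, y_name: str, n: int) -> CorrelationResult:
    return CorrelationResult(x_name=x_name, y_name=y_name, r=float("nan"),
                             method="none", p_value=float("nan"), n_pairs=n,
                             strength="undefined", significant=False)


@dataclass
class ValidityReport:
    """Assembled discriminative + predictive validity tables."""

    group_rows: pd.DataFrame
    paired_rows: pd.DataFrame
    sympt_block: pd.DataFrame
    di_block: pd.DataFrame
    n_significant: int
    n_significant_nonnegligible: int
    alpha: float
    notes: list = field(default_factory=list)


def mub_column(mub: str, plane: str, side: str) -> str:
    return f"{mub}_{plane}_{side}"


def required_mub_columns() -> list[str]:
    return [mub_column(m, p, s) for p in PLANES for m in MUB_NAMES
            for s in ("asympt", "sympt")]


def _safe_correlate(x, y, x_name, y_name, alpha) -> CorrelationResult:
    try:
        return correlate(x, y, x_name, y_name, alpha=alpha)
    except (InvalidParameterError, DegenerateDataError):
        xs, ys = (np.asarray(v, dtype=float) for v in (x, y))
        n = int((np.isfinite(xs) & np.isfinite(ys)).sum())
        return _placeholder_cell(x_name, y_name, n)


def build_report(cohort: pd.DataFrame, alpha: float = 0.05,
                 bh_correction: bool = False) -> ValidityReport:
    """Build the full validity report from a wide per-subject table.

    Expects the six biomarkers per side (columns
    ``{thickness|echogenicity|homogeneity}_{plane}_{asympt|sympt}``),
    the per-side clinical measures and the questionnaire columns as
    produced by the pipeline join.  Missing clinical values are handled
    by pairwise deletion; an entirely missing column yields a placeholder
    row rather than an error.

    ``bh_correction=True`` re-flags significance of the correlation
    cells with Benjamini–Hochberg-adjusted p-values (raw p-values are
    reported unchanged).
    """
    missing = [c for c in required_mub_columns() if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table lacks biomarker columns: {missing}")

    # -- group vs subgroup rows ------------------------------------------
    group_rows = []
    if "in_subgroup" in cohort.columns:
        sub = cohort["in_subgroup"].astype(bool)
        for var in FUNCTION_VARS:
            if var not in cohort.columns or var == "lefs":
                continue
            try:
                t, p = group_compare(cohort[var], cohort.loc[sub, var])
                group_rows.append({"variable": var, "statistic": t, "p_value": p,
                                   "n_group": int(cohort[var].notna().sum()),
                                   "n_subgroup": int(cohort.loc[sub, var].notna().sum())})
            except (InvalidParameterError, DegenerateDataError):
                continue

    # -- paired side comparisons -----------------------------------------
    paired = []
    targets = [(f"{stem}_{unit}", f"{stem}_sympt_{unit}", f"{stem}_asympt_{unit}")
               for stem, unit in PAIRED_CLINICAL_VARS.items()]
    targets += [(mub_column(m, p, "group"), mub_column(m, p, "sympt"),
                 mub_column(m, p, "asympt")) for p in PLANES for m in MUB_NAMES]
    for label, sc, ac in targets:
        label = label.replace("_group", "")
        if sc not in cohort.columns or ac not in cohort.columns:
            continue
        try:
            res = paired_compare(cohort[sc], cohort[ac], variable=label, alpha=alpha)
            paired.append(vars(res))
        except (InvalidParameterError, DegenerateDataError):
            paired.append({"variable": label,
                           "n": int((cohort[sc].notna() & cohort[ac].notna()).sum())})

    # -- correlation blocks ----------------------------------------------
    mubs = [(m, p) for p in PLANES for m in MUB_NAMES]
    sympt_cells: list[CorrelationResult] = []
    di_cells: list[CorrelationResult] = []
    di_of = {}
    for m, p in mubs:
        di_of[(m, p)] = difference_index_series(
            cohort[mub_column(m, p, "sympt")], cohort[mub_column(m, p, "asympt")])

    for m, p in mubs:
        mub_s = cohort[mub_column(m, p, "sympt")]
        mub_di = di_of[(m, p)]
        mlabel = f"{m}_{p}"
        for stem, unit in PAIRED_CLINICAL_VARS.items():
            sc, ac = f"{stem}_sympt_{unit}", f"{stem}_asympt_{unit}"
            if sc in cohort.columns and ac in cohort.columns:
                sympt_cells.append(_safe_correlate(
                    cohort[sc], mub_s, f"{stem}_sympt", mlabel + "_sympt", alpha))
                di_cells.append(_safe_correlate(
                    difference_index_series(cohort[sc], cohort[ac]), mub_di,
                    f"{stem}_di", mlabel + "_di", alpha))
        for var in FUNCTION_VARS:
            if var in cohort.columns:
                sympt_cells.append(_safe_correlate(
                    cohort[var], mub_s, var, mlabel + "_sympt", alpha))
                di_cells.append(_safe_correlate(
                    cohort[var], mub_di, var, mlabel + "_di", alpha))

    sympt_block = pd.DataFrame([vars(c) for c in sympt_cells])
    di_block = pd.DataFrame([vars(c) for c in di_cells])

    if bh_correction:
        for block in (sympt_block, di_block):
            valid = block["p_value"].notna()
            if valid.any():
                adj = stats.false_discovery_control(
                    block.loc[valid, "p_value"].to_numpy(), method="bh")
                block.loc[valid, "significant"] = adj < alpha

    all_cells = pd.concat([sympt_block, di_block], ignore_index=True)
    n_sig = int(all_cells["significant"].sum())
    n_sig_nn = int((all_cells["significant"]
                    & (all_cells["strength"] != "negligible")).sum())

    notes = ["group-vs-subgroup t-tests treat an overlapping subset as "
             "independent groups, mirroring the reference protocol"]
    return ValidityReport(group_rows=pd.DataFrame(group_rows),
                          paired_rows=pd.DataFrame(paired),
                          sympt_block=sympt_block, di_block=di_block,
                          n_significant=n_sig,
                          n_significant_nonnegligible=n_sig_nn,
                          alpha=alpha, notes=notes)
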