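"""Agreement and association statistics between two paired measurement series.

Implements the method-comparison toolkit of a dietary validation study:
Bland-Altman analysis with +/- 2 SD limits of agreement and a
difference-on-average regression for proportional bias, paired location
tests (paired t or Wilcoxon signed ranks), correlations (Pearson or
Spearman), and a normality-based rule for choosing the parametric or
non-parametric family.  Every reported statistic records which family
produced it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedSeries:
    """Per-participant pairs (a_i, b_i) of one variable measured twice."""

    name: str
    units: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be 1-d arrays of equal length")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError(f"{self.name}: missing values inside pairs are not allowed")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return int(self.a.size)

    def swapped(self) -> "PairedSeries":
        return PairedSeries(self.name, self.units, self.b, self.a)


@dataclass(frozen=True)
class BlandAltmanResult:
    variable: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_half_width: float   # 2 x sd_diff
    loa_lower: float
    loa_upper: float
    slope: float            # difference-on-average regression
    intercept: float
    r: float
    p: float
    mean_diff_pct: float    # mean_diff as % of the reference mean
    reference: str


def bland_altman(series: PairedSeries, reference: str = "mean_of_both") -> BlandAltmanResult:
    """Bland-Altman agreement analysis of a paired series.

    Differences are ``a - b``; limits of agreement are the mean difference
    +/- 2 SD (n-1 denominator).  Proportional bias is assessed by ordinary
    least squares of the difference on the pair average, with Pearson r and
    its two-sided p.  The percentage mean difference is taken relative to
    the mean of ``b`` (``reference='series_b'``, e.g. TEE as the criterion
    measure) or of the pooled average (``'mean_of_both'``).
    """
    if series.n < 3:
        raise ValueError(f"{series.name}: Bland-Altman requires n >= 3")
    diff = series.a - series.b
    avg = (series.a + series.b) / 2.0
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if np.ptp(avg) == 0:
        logger.warning("%s: zero variance of averages; regression undefined", series.name)
        slope = intercept = r = p = float("nan")
    else:
        res = stats.linregress(avg, diff)
        slope, intercept = float(res.slope), float(res.intercept)
        r, p = float(res.rvalue), float(res.pvalue)
    ref_mean = float(series.b.mean()) if reference == "series_b" else float(avg.mean())
    pct = 100.0 * mean_diff / ref_mean if ref_mean != 0 else float("nan")
    return BlandAltmanResult(
        variable=series.name, n=series.n, mean_diff=mean_diff, sd_diff=sd_diff,
        loa_half_width=2.0 * sd_diff, loa_lower=mean_diff - 2.0 * sd_diff,
        loa_upper=mean_diff + 2.0 * sd_diff, slope=slope, intercept=intercept,
        r=r, p=p, mean_diff_pct=pct, reference=reference,
    )


def paired_location_test(series: PairedSeries, family: str,
                         wilcoxon_exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided paired test of equal location: ``'t'`` or ``'wilcoxon'``.

    The Wilcoxon test drops zero differences, mid-ranks ties, and uses the
    exact signed-rank distribution up to ``wilcoxon_exact_max_n`` non-zero
    untied differences, the normal approximation (no continuity correction)
    above.  All differences zero returns p = 1 by convention.
    """
    if series.n < 3:
        raise ValueError(f"{series.name}: paired test requires n >= 3")
    d = series.a - series.b
    if np.all(d == 0):
        logger.info("%s: all differences zero; p = 1 by convention", series.name)
        return 0.0, 1.0
    if family == "t":
        res = stats.ttest_rel(series.a, series.b)
        return float(res.statistic), float(res.pvalue)
    if family == "wilcoxon":
        nz = d[d != 0]
        if nz.size < 5:
            raise ValueError(f"{series.name}: Wilcoxon requires >= 5 non-zero differences")
        has_ties = np.unique(np.abs(nz)).size < nz.size
        method = "exact" if (nz.size <= wilcoxon_exact_max_n and not has_ties) else "approx"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test family {family!r}")


def paired_correlation(series: PairedSeries, family: str) -> tuple[float, float]:
    """Correlation between the two members: ``'pearson'`` or ``'spearman'``."""
    if series.n < 3:
        raise ValueError(f"{series.name}: correlation requires n >= 3")
    if series.a.std() == 0 or series.b.std() == 0:
        logger.warning("%s: zero variance; correlation undefined", series.name)
        return float("nan"), float("nan")
    if family == "pearson":
        r, p = stats.pearsonr(series.a, series.b)
    elif family == "spearman":
        r, p = stats.spearmanr(series.a, series.b)
    else:
        raise ValueError(f"unknown correlation family {family!r}")
    return float(r), float(p)


def choose_family(differences, alpha: float = 0.05) -> str:
    """'parametric' or 'nonparametric' by Shapiro-Wilk on the differences.

    The parametric family (paired t / Pearson) is kept unless normality is
    rejected at ``alpha``; a per-variable override in the analysis config
    takes precedence over this rule.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("family choice requires n >= 3")
    if np.ptp(d) == 0:
        return "parametric"
    _, p = stats.shapiro(d)
    return "parametric" if p >= alpha else "nonparametric"


def summarize_validation(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    variables: list[str],
    label_a: str = "A",
    label_b: str = "B",
    family_overrides: dict[str, str] | None = None,
    units: dict[str, str] | None = None,
    reference: str = "mean_of_both",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-variable comparison table plus Bland-Altman plot data.

    ``cohort_a``/``cohort_b`` are indexed by participant_id (or carry a
    ``participant_id`` column) with one column per variable; participants
    missing from either side are dropped with a logged count.  Returns a
    tidy summary (means, SDs, chosen family, location-test p, correlation,
    Bland-Altman fields) and, per variable, the per-participant
    (average, difference) coordinates.
    """
    family_overrides = family_overrides or {}
    units = units or {}
    a = cohort_a.set_index("participant_id") if "participant_id" in cohort_a else cohort_a
    b = cohort_b.set_index("participant_id") if "participant_id" in cohort_b else cohort_b
    common = a.index.intersection(b.index)
    dropped = (len(a) - len(common)) + (len(b) - len(common))
    if dropped:
        logger.info("summarize_validation: dropped %d unmatched participant rows", dropped)
    a, b = a.loc[common], b.loc[common]

    rows, plots = [], {}
    for var in variables:
        series = PairedSeries(var, units.get(var, ""), a[var].to_numpy(float),
                              b[var].to_numpy(float))
        d = series.a - series.b
        family = family_overrides.get(var) or choose_family(d, alpha)
        if family == "parametric":
            test_name, corr_name = "paired_t", "pearson"
        else:
            test_name, corr_name = "wilcoxon", "spearman"
        try:
            stat, p = paired_location_test(series, "t" if family == "parametric"
                                           else "wilcoxon")
        except ValueError as exc:  # e.g. too few non-zero differences
            logger.warning("%s: location test unavailable (%s)", var, exc)
            stat = p = float("nan")
        r, rp = paired_correlation(series, corr_name)
        ba = bland_altman(series, reference=reference)
        rows.append({
            "variable": var, "units": series.units, "n": series.n,
            f"mean_{label_a}": series.a.mean(), f"sd_{label_a}": series.a.std(ddof=1),
            f"mean_{label_b}": series.b.mean(), f"sd_{label_b}": series.b.std(ddof=1),
            "family": family, "location_test": test_name,
            "test_statistic": stat, "test_p": p,
            "correlation": corr_name, "r": r, "r_p": rp,
            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
            "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
            "loa_half_width": ba.loa_half_width,
            "ba_slope": ba.slope, "ba_intercept": ba.intercept,
            "ba_r": ba.r, "ba_p": ba.p, "mean_diff_pct": ba.mean_diff_pct,
        })
        plots[var] = pd.DataFrame({
            "participant_id": common, "average": (series.a + series.b) / 2.0,
            "difference": d,
        })
    return pd.DataFrame(rows), plots
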