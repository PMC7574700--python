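"""Group statistics mirroring a standard small-cohort bone study pipeline.

* single-pass 2-SD outlier removal per parameter,
* normality (Lilliefors-style Kolmogorov-Smirnov against a normal with the
  sample mean and SD) and Levene homogeneity screening feeding a decision
  rule between Student t, Welch t and the exact Mann-Whitney U test,
* signed percent differences referenced to the control group,
* Pearson correlation with two-sided p via the t transform,
* pure forward stepwise OLS with partial-F entry testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "StepwiseModel",
    "remove_outliers",
    "compare_groups",
    "pearson_r",
    "r_squared",
    "forward_stepwise",
    "significance_stars",
]


@dataclass
class GroupSample:
    parameter: str
    group: str
    values: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.ids is None:
            self.ids = [str(i) for i in range(self.values.size)]
        if self.values.size != len(self.ids):
            raise ValueError("values and ids must align")


@dataclass
class ComparisonResult:
    parameter: str
    mean_control: float
    sd_control: float
    n_control: int
    mean_t2d: float
    sd_t2d: float
    n_t2d: int
    test: str  # 'student_t' | 'welch_t' | 'mann_whitney_u'
    p_value: float
    percent_difference: float  # (control - T2D) / control * 100, signed
    stars: str
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class StepwiseModel:
    response: str
    entered: list[str]
    coefficients: dict
    r_squared: float
    entry_p_values: list[float]
    skipped: list[str] = field(default_factory=list)


def significance_stars(p: float) -> str:
    """Stars at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def remove_outliers(
    values: np.ndarray, ids: list[str] | None = None, k: float = 2.0
) -> tuple[np.ndarray, list[str]]:
    """Single-pass removal of points beyond ``k`` SDs of the sample mean.

    Mean and SD are computed once on the full input (sample SD, ddof=1);
    removal is not iterated.  A zero-SD sample removes nothing.
    """
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    if ids is None:
        ids = [str(i) for i in range(values.size)]
    sd = float(values.std(ddof=1))
    if sd == 0:
        return values, []
    keep = np.abs(values - values.mean()) <= k * sd
    removed = [i for i, ok in zip(ids, keep) if not ok]
    return values[keep], removed


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney U p-value (permutation-exact for ties)."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    return float(res.pvalue)


def compare_groups(
    a: GroupSample,
    b: GroupSample,
    alpha: float = 0.05,
    outlier_k: float | None = 2.0,
) -> ComparisonResult:
    """Compare control vs T2D for one parameter with test auto-selection.

    Both groups are screened for normality (Lilliefors KS) and the pair for
    variance homogeneity (Levene).  Both normal and homogeneous -> Student
    t; both normal but heteroscedastic -> Welch t; otherwise the exact
    Mann-Whitney U.  The percent difference is control-referenced and
    signed: positive when the T2D mean is lower.
    """
    def screen(sample: GroupSample):
        # the 2-SD screen needs n >= 3; tiny groups pass through as-is
        if outlier_k and sample.values.size >= 3:
            return remove_outliers(sample.values, sample.ids, k=outlier_k)
        return sample.values, []

    x, removed_a = screen(a)
    y, removed_b = screen(b)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group after outlier removal")

    def normal_ok(v: np.ndarray) -> bool:
        # normality is untestable below n = 4; fall back to the
        # distribution-free branch rather than assume it
        if v.size < 4 or v.std(ddof=1) == 0:
            return False
        return lilliefors(v, dist="norm")[1] > alpha

    norm = normal_ok(x) and normal_ok(y)
    if norm:
        _, p_lev = sps.levene(x, y)
        if p_lev > alpha:
            test, p = "student_t", float(sps.ttest_ind(x, y, equal_var=True).pvalue)
        else:
            test, p = "welch_t", float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        test, p = "mann_whitney_u", _mann_whitney_exact(x, y)

    mc, mt = float(x.mean()), float(y.mean())
    pct = (mc - mt) / mc * 100.0 if mc != 0 else np.nan
    return ComparisonResult(
        parameter=a.parameter,
        mean_control=mc,
        sd_control=float(x.std(ddof=1)),
        n_control=int(x.size),
        mean_t2d=mt,
        sd_t2d=float(y.std(ddof=1)),
        n_t2d=int(y.size),
        test=test,
        p_value=p,
        percent_difference=float(pct),
        stars=significance_stars(p),
        removed_ids=removed_a + removed_b,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with two-sided p via the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def r_squared(r: float) -> float:
    """Variance fraction explained by a correlation."""
    return r * r


def forward_stepwise(
    y: np.ndarray,
    candidates: dict,
    alpha_enter: float = 0.05,
    cond_max: float = 1e8,
) -> StepwiseModel:
    """Pure forward stepwise OLS.

    At each step the candidate with the smallest partial-F entry p-value
    below ``alpha_enter`` (given the current model) joins; the loop stops
    when no candidate qualifies.  Near-collinear candidates (design matrix
    condition number above ``cond_max``) are skipped with a note.  There is
    no removal step.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    names = list(candidates)
    cols = {k: np.asarray(v, float) for k, v in candidates.items()}
    for k, v in cols.items():
        if v.size != y.size:
            raise ValueError(f"candidate {k!r} length mismatch")

    entered: list[str] = []
    entry_ps: list[float] = []
    skipped: list[str] = []
    while True:
        best = None
        for name in names:
            if name in entered or name in skipped:
                continue
            X = np.column_stack([cols[n] for n in entered + [name]])
            Xc = sm.add_constant(X)
            if np.linalg.cond(Xc) > cond_max:
                skipped.append(name)
                continue
            full = sm.OLS(y, Xc).fit()
            # partial F for the newest column == squared t, same p
            p_enter = float(full.pvalues[-1])
            if p_enter < alpha_enter and (best is None or p_enter < best[1]):
                best = (name, p_enter)
        if best is None:
            break
        entered.append(best[0])
        entry_ps.append(best[1])

    if entered:
        import statsmodels.api as sm2

        X = sm2.add_constant(np.column_stack([cols[n] for n in entered]))
        fit = sm2.OLS(y, X).fit()
        coef = {"const": float(fit.params[0])}
        coef.update({n: float(c) for n, c in zip(entered, fit.params[1:])})
        r2 = float(fit.rsquared)
    else:
        coef, r2 = {}, 0.0
    return StepwiseModel(
        response="y",
        entered=entered,
        coefficients=coef,
        r_squared=r2,
        entry_p_values=entry_ps,
        skipped=skipped,
    )
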