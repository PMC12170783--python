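"""Matched group comparisons and hypothesis tests for cohort BAI analyses.

Group effects on BAI are confounded by demographics (the exposed group is
typically younger). Adjustment follows the matched-design recipe:

1. a propensity score — the probability of group membership given the
   confounders (age, sex, education, race) — is estimated by logistic
   regression;
2. *full matching* partitions all subjects into subclasses, each containing
   at least one member of both groups, chosen to minimize within-subclass
   propensity spread (computed exactly by dynamic programming over the
   sorted scores); every subject receives a weight — 1 for the smaller
   (focal) group, treated:control-ratio-proportional for the other group,
   rescaled so each group's weights sum to its sample size;
3. the weights enter a weighted least-squares regression of the outcome on
   the group indicator, with cluster-robust (by subclass) covariance and a
   small-sample HC1-type correction; inference uses a t distribution with
   (number of subclasses − 1) degrees of freedom.

Balance is audited with standardized mean differences (|SMD| < 0.1 is the
conventional balance criterion). Plain paired/Welch t-tests, Spearman
correlation, the Bonferroni threshold (α/m) and the least-squares trend
line with its 95% confidence band round out the toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import ValidationError

DEFAULT_CONFOUNDERS = ("age", "sex", "education", "race")
PROPENSITY_CLIP = 1e-6


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    name: str


@dataclass
class MatchResult:
    """Full-matching subclass assignment and weights."""

    subclass: np.ndarray        # subclass id per included subject
    weights: np.ndarray         # ≥ 0, group sums equal group sizes
    scores: np.ndarray          # propensity scores in (0,1)
    treated: np.ndarray         # boolean, True = focal (smaller) group
    index: np.ndarray           # row labels of the cohort table
    reference_group: str = ""

    @property
    def n_subclasses(self) -> int:
        return len(np.unique(self.subclass))

    def composition(self) -> pd.DataFrame:
        df = pd.DataFrame({"subclass": self.subclass, "treated": self.treated})
        return df.groupby("subclass")["treated"].agg(n_treated="sum", n_total="count")


@dataclass
class EffectEstimate:
    """Covariate-adjusted group contrast on an outcome (years for BAI)."""

    effect: float               # adjusted mean difference (group − reference)
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    adjusted_means: dict = field(default_factory=dict)
    reference_group: str = ""


# ---------------------------------------------------------------------------
# propensity scores
# ---------------------------------------------------------------------------

def _design_matrix(cohort: pd.DataFrame, confounders) -> pd.DataFrame:
    cols = []
    for c in confounders:
        if c not in cohort.columns:
            raise ValidationError(f"confounder {c!r} missing from cohort table")
        col = cohort[c]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float).rename(c))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            cols.append(dummies.astype(float))
    return pd.concat(cols, axis=1)


def estimate_propensity(
    cohort: pd.DataFrame,
    treated_label: str,
    group_col: str = "group",
    confounders=DEFAULT_CONFOUNDERS,
) -> pd.Series:
    """Propensity of membership in ``treated_label`` given the confounders.

    Rows with missing confounders are excluded (logged via warning); the
    returned Series covers the remaining rows, strictly inside (0, 1).
    Perfect separation triggers a penalized (L2) refit.
    """
    import statsmodels.api as sm

    levels = cohort[group_col].unique()
    if len(levels) != 2:
        raise ValidationError(f"propensity model needs exactly two groups, got {list(levels)}")
    confounders = [c for c in confounders if c in cohort.columns]
    complete = cohort[list(confounders)].notna().all(axis=1)
    if (~complete).any():
        warnings.warn(f"excluding {int((~complete).sum())} rows with missing confounders",
                      stacklevel=2)
    data = cohort.loc[complete]
    X = _design_matrix(data, confounders)
    y = (data[group_col] == treated_label).astype(float).to_numpy()
    # standardize so a penalized fallback treats covariates on equal footing
    Xv = X.to_numpy()
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    Xz = (Xv - mu) / np.where(sd == 0, 1.0, sd)
    Xc = sm.add_constant(Xz, has_constant="add")
    scores = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(fit.params)) and fit.mle_retvals.get("converged", False):
            scores = fit.predict(Xc)
    except Exception:
        scores = None
    if scores is None or np.any(~np.isfinite(scores)):
        from sklearn.linear_model import LogisticRegression

        warnings.warn("propensity logit did not converge; penalized refit", stacklevel=2)
        lr = LogisticRegression(C=1.0, max_iter=2000)
        lr.fit(Xz, y)
        scores = lr.predict_proba(Xz)[:, 1]
    scores = np.clip(scores, PROPENSITY_CLIP, 1 - PROPENSITY_CLIP)
    return pd.Series(scores, index=data.index, name="propensity")


# ---------------------------------------------------------------------------
# full matching
# ---------------------------------------------------------------------------

def full_match(scores, treated, reference_group: str = "") -> MatchResult:
    """Optimal 1-D full matching on propensity scores.

    Subjects are sorted by score; subclasses are contiguous blocks containing
    at least one member of each group, chosen by dynamic programming to
    minimize the total within-subclass score spread. Spread is measured on
    the logit (linear-predictor) scale, the standard matching distance — on
    the probability scale, scores saturating near 0/1 would look spuriously
    close. The smaller (focal) group gets unit weights; the other group's
    weights are proportional to the focal:other ratio of their subclass and
    rescaled to sum to that group's sample size.
    """
    scores = np.asarray(pd.Series(scores), dtype=float)
    index = (
        pd.Series(scores).index.to_numpy()
        if hasattr(scores, "index")
        else np.arange(len(scores))
    )
    if hasattr(treated, "to_numpy"):
        treated = treated.to_numpy()
    treated = np.asarray(treated, dtype=bool)
    n = len(scores)
    if n != len(treated):
        raise ValidationError("scores and group indicator must align")
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise ValidationError("propensity scores must lie strictly in (0, 1)")
    n_t, n_c = int(treated.sum()), int((~treated).sum())
    if n_t < 1 or n_c < 1:
        raise ValidationError("both groups must be non-empty")
    focal = treated if n_t <= n_c else ~treated

    logit = np.log(scores / (1.0 - scores))
    order = np.argsort(logit, kind="stable")
    s = logit[order]
    f = focal[order]

    # DP over block boundaries; block (j, i] must contain both groups
    INF = np.inf
    cost = np.full(n + 1, INF)
    back = np.zeros(n + 1, dtype=int)
    cost[0] = 0.0
    cf = np.concatenate([[0], np.cumsum(f)])         # focal counts prefix
    for i in range(1, n + 1):
        for j in range(i - 1, -1, -1):
            kf = cf[i] - cf[j]
            ko = (i - j) - kf
            if kf >= 1 and ko >= 1 and cost[j] < INF:
                c = cost[j] + (s[i - 1] - s[j])
                if c < cost[i]:
                    cost[i] = c
                    back[i] = j
            # once both groups could never be completed by extending j down, stop
            if j == 0:
                break
        if not np.isfinite(cost[i]) and i == n:
            raise ValidationError("full matching infeasible (a group is empty)")
    if not np.isfinite(cost[n]):
        raise ValidationError("full matching infeasible")

    subclass_sorted = np.empty(n, dtype=int)
    i, sc = n, 0
    bounds = []
    while i > 0:
        j = back[i]
        bounds.append((j, i))
        i = j
    for sc, (j, i) in enumerate(reversed(bounds)):
        subclass_sorted[j:i] = sc

    subclass = np.empty(n, dtype=int)
    subclass[order] = subclass_sorted

    weights = np.zeros(n)
    weights[focal] = 1.0
    other = ~focal
    for scid in np.unique(subclass):
        in_sc = subclass == scid
        kf = int((in_sc & focal).sum())
        ko = int((in_sc & other).sum())
        weights[in_sc & other] = kf / ko
    # rescale the non-focal group so its weights sum to its sample size
    tot = weights[other].sum()
    weights[other] *= other.sum() / tot
    return MatchResult(
        subclass=subclass,
        weights=weights,
        scores=scores,
        treated=treated,
        index=index,
        reference_group=reference_group,
    )


def balance_table(
    cohort: pd.DataFrame,
    treated,
    weights=None,
    covariates=DEFAULT_CONFOUNDERS,
) -> pd.Series:
    """Standardized mean differences per covariate (indicator-coded).

    SMD = (weighted mean in treated − weighted mean in other) / pooled
    *unweighted* SD. Zero pooled SD yields SMD 0.
    """
    if hasattr(treated, "to_numpy"):
        treated = treated.to_numpy()
    treated = np.asarray(treated, dtype=bool)
    w = np.ones(len(cohort)) if weights is None else np.asarray(weights, dtype=float)
    X = _design_matrix(cohort, [c for c in covariates if c in cohort.columns])
    out = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        m1 = np.average(v[treated], weights=w[treated])
        m0 = np.average(v[~treated], weights=w[~treated])
        sd = np.sqrt((v[treated].std(ddof=1) ** 2 + v[~treated].std(ddof=1) ** 2) / 2)
        out[col] = 0.0 if sd == 0 else (m1 - m0) / sd
    return pd.Series(out, name="smd")


def adjusted_effect(
    outcome,
    treated,
    match: MatchResult,
    reference_group: str | None = None,
) -> EffectEstimate:
    """Weighted regression of the outcome on the group indicator.

    Uses the full-matching weights, cluster-robust covariance at the
    subclass level with an HC1-type small-sample factor, and a t reference
    distribution with (n_subclasses − 1) degrees of freedom.
    """
    import statsmodels.api as sm

    y = np.asarray(pd.Series(outcome), dtype=float)
    if hasattr(treated, "to_numpy"):
        treated = treated.to_numpy()
    t = np.asarray(treated, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("outcomes must be finite")
    G = match.n_subclasses
    if G < 2:
        raise ValidationError("cluster-robust inference needs at least 2 subclasses")
    X = sm.add_constant(t)
    fit = sm.WLS(y, X, weights=match.weights).fit(
        cov_type="cluster", cov_kwds={"groups": match.subclass, "use_correction": True}
    )
    effect = float(fit.params[1])
    se = float(fit.bse[1])
    df = G - 1
    scale = max(1.0, float(np.abs(y).max()))
    if se <= 1e-12 * scale:  # numerically exact fit (e.g. constant outcome)
        tstat = 0.0 if abs(effect) <= 1e-12 * scale else np.inf
    else:
        tstat = effect / se
    p = float(2 * sstats.t.sf(abs(tstat), df))
    ref_mean = float(np.average(y[t == 0], weights=match.weights[t == 0]))
    ref = reference_group if reference_group is not None else match.reference_group
    return EffectEstimate(
        effect=effect,
        se=se,
        ci_low=effect - 1.96 * se,
        ci_high=effect + 1.96 * se,
        p_value=p,
        df=df,
        adjusted_means={"reference": ref_mean, "group": ref_mean + effect},
        reference_group=ref,
    )


# ---------------------------------------------------------------------------
# plain tests
# ---------------------------------------------------------------------------

def paired_ttest(x_pre, x_post) -> TestResult:
    """Two-sided paired t-test (related samples)."""
    a = np.asarray(x_pre, dtype=float)
    b = np.asarray(x_post, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("paired test needs equal-length samples of n ≥ 2")
    d = b - a
    if np.all(d == 0):
        return TestResult(statistic=0.0, df=a.size - 1, p_value=1.0, name="paired_t")
    if d.std(ddof=1) == 0:
        raise ValidationError("degenerate paired test: differences have zero variance")
    res = sstats.ttest_rel(b, a)
    return TestResult(statistic=float(res.statistic), df=float(a.size - 1),
                      p_value=float(res.pvalue), name="paired_t")


def welch_ttest(x, y) -> TestResult:
    """Two-sided independent-samples t-test with Welch–Satterthwaite df."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("independent test needs n ≥ 2 per sample")
    res = sstats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        raise ValidationError("degenerate test: both samples have zero variance")
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return TestResult(statistic=float(res.statistic), df=float(df),
                      p_value=float(res.pvalue), name="welch_t")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValidationError("Spearman correlation needs n ≥ 4 aligned samples")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("Spearman correlation undefined for constant input")
    rho, p = sstats.spearmanr(a, b)
    return float(rho), float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold α/m."""
    if not 0 < alpha < 1 or m < 1:
        raise ValidationError("need alpha in (0,1) and m ≥ 1")
    return alpha / m


def significance_label(p: float, alpha: float = 0.05, m: int = 50) -> str:
    """Label a p-value against the Bonferroni threshold.

    Below α/m is "significant"; between α/m and α is "trend-level";
    otherwise "ns".
    """
    thr = bonferroni_threshold(alpha, m)
    if p < thr:
        return "significant"
    if p < alpha:
        return "trend-level"
    return "ns"


# ---------------------------------------------------------------------------
# trend line
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    slope: float
    intercept: float
    slope_se: float
    slope_ci: tuple
    p_value: float
    _model: object = None

    def band(self, x_grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fitted mean and pointwise 95% CI of the mean response."""
        import statsmodels.api as sm

        Xg = sm.add_constant(np.asarray(x_grid, dtype=float))
        pred = self._model.get_prediction(Xg)
        frame = pred.summary_frame(alpha=0.05)
        return (frame["mean"].to_numpy(), frame["mean_ci_lower"].to_numpy(),
                frame["mean_ci_upper"].to_numpy())


def linear_trend(x, y) -> TrendFit:
    """Ordinary least-squares trend of y on x with 95% CI."""
    import statsmodels.api as sm

    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size < 3:
        raise ValidationError("trend fit needs n ≥ 3")
    if np.all(a == a[0]):
        raise ValidationError("trend fit singular: constant predictor")
    X = sm.add_constant(a)
    fit = sm.OLS(b, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        p_value=float(fit.pvalues[1]),
        _model=fit,
    )
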