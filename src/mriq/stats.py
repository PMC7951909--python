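"""Frequentist and Bayesian inference for ROI quality metrics.

Four families of analysis:

* paired t tests (left vs right caudate SNR, slab vs whole-brain) with
  both the classical two-sided p and a default JZS Bayes factor,
* ordinary least-squares regressions of image quality on scan time,
  Bonferroni-adjusted across the model family,
* random-intercept linear mixed models for age effects — a null model
  (database intercepts only) against a full model adding age as a
  continuous fixed effect, compared by a 1-df likelihood-ratio test
  and a BIC-approximation Bayes factor exp((BIC_null - BIC_full)/2),
* a uniform age-interval resampling loop for databases that report
  age ranges instead of point ages.

The JZS (Jeffreys-Zellner-Siow) Bayes factor places a Cauchy(0, r)
prior on the standardised effect size (default scale r = sqrt(2)/2,
the convention of the R ``BayesFactor`` package) which is equivalent
to an inverse-gamma(1/2, r^2/2) mixing prior on g:

    BF10 = Int_0^inf (1+Ng)^(-1/2) (1 + t^2/((1+Ng) nu))^(-(nu+1)/2) pi(g) dg
           -----------------------------------------------------------------
                          (1 + t^2/nu)^(-(nu+1)/2)

with nu the degrees of freedom and N the effective sample size (n for
a one-sample/paired test, n1*n2/(n1+n2) for two independent groups).
The integral is evaluated by adaptive quadrature in log space to a
relative tolerance of 1e-6.

Mixed models are fitted by maximum likelihood (never REML): the LRT
compares models that differ in their fixed effects, which is only
valid under ML.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "DEFAULT_PRIOR_SCALE",
    "ModelComparison",
    "RegressionResult",
    "ResampleSummary",
    "StatsError",
    "TTestResult",
    "bf_evidence_label",
    "fit_lmm_age",
    "jzs_bf_ttest",
    "paired_ttest",
    "reliability_bf_anova",
    "resample_age_analysis",
    "sample_interval_ages",
    "scan_time_regression",
    "slab_vs_wholebrain_test",
]

#: default Cauchy prior scale on effect size ("medium", sqrt(2)/2)
DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


class StatsError(ValueError):
    """An inference routine's preconditions are violated."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    bf10: float
    paired: bool
    n: int

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def evidence(self) -> str:
        return bf_evidence_label(self.bf10)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2_adj: float
    f_stat: float
    df_model: float
    df_resid: float
    p: float
    bonferroni_alpha: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < self.bonferroni_alpha


@dataclass(frozen=True)
class ModelComparison:
    """Null (random intercept only) vs full (plus fixed age effect)."""

    response: str
    loglik_null: float
    loglik_full: float
    chi2: float
    lrt_df: int
    p_lrt: float
    bic_null: float
    bic_full: float
    bf10_bic: float
    fixed_effect_estimate: float
    fixed_effect_se: float
    n_obs: int
    n_groups: int
    fit_warnings: tuple[str, ...] = ()

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.fixed_effect_se
        return (self.fixed_effect_estimate - half, self.fixed_effect_estimate + half)

    @property
    def evidence(self) -> str:
        return bf_evidence_label(self.bf10_bic)


@dataclass(frozen=True)
class ResampleSummary:
    n_iter: int
    mean_p: float
    mean_bf: float
    p_values: np.ndarray = field(repr=False)
    bf_values: np.ndarray = field(repr=False)
    slopes: np.ndarray = field(repr=False)


def bf_evidence_label(bf10: float) -> str:
    """Jeffreys-style evidence category at thresholds 3, 10, 30, 100."""
    if bf10 <= 0 or not math.isfinite(math.log(bf10) if bf10 > 0 else math.inf):
        raise StatsError(f"Bayes factor must be finite and positive, got {bf10}")
    favored = "H1" if bf10 >= 1 else "H0"
    b = bf10 if bf10 >= 1 else 1.0 / bf10
    if b < 3:
        strength = "anecdotal"
    elif b < 10:
        strength = "moderate"
    elif b < 30:
        strength = "strong"
    elif b < 100:
        strength = "very strong"
    else:
        strength = "extreme"
    return f"{strength} evidence for {favored}"


def _jzs_bf10(t: float, n_eff: float, df: float, r: float) -> float:
    """JZS Bayes factor by adaptive quadrature on the g-mixture integral."""
    if not math.isfinite(t):
        raise StatsError(f"t statistic must be finite, got {t}")
    if n_eff <= 0 or df <= 0 or r <= 0:
        raise StatsError(f"need n_eff, df, r > 0 (got {n_eff}, {df}, {r})")
    nu = float(df)
    t2 = t * t
    log_prior_const = math.log(r) - 0.5 * math.log(2.0 * math.pi)

    def log_integrand(g: float) -> float:
        # marginal likelihood ratio vs the null, times the InvGamma(1/2, r^2/2)
        # prior density on g; the null's (1+t^2/nu) factor is folded in so the
        # integrand stays O(1) for large |t|
        return (
            -0.5 * math.log1p(n_eff * g)
            + 0.5 * (nu + 1.0) * (math.log1p(t2 / nu) - math.log1p(t2 / ((1.0 + n_eff * g) * nu)))
            + log_prior_const
            - 1.5 * math.log(g)
            - r * r / (2.0 * g)
        )

    value, abserr = scipy.integrate.quad(
        lambda g: math.exp(log_integrand(g)), 0.0, np.inf, epsabs=0.0, epsrel=1e-8, limit=400
    )
    if not math.isfinite(value) or value <= 0 or abserr > 1e-6 * value:
        raise StatsError(
            f"JZS quadrature did not converge (t={t}, n_eff={n_eff}, df={df}): "
            f"value={value}, abserr={abserr}"
        )
    return float(value)


def jzs_bf_ttest(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE) -> float:
    """Default JZS Bayes factor for a one-sample/paired t statistic.

    BF10 > 1 favours the effect, BF10 < 1 favours the null.
    """
    if n < 2:
        raise StatsError(f"need n >= 2, got {n}")
    return _jzs_bf10(t, n_eff=float(n), df=float(n - 1), r=r)


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise StatsError(f"{name} must be 1-D")
    if np.isnan(arr).any():
        raise StatsError(f"{name} contains missing values; complete pairs are required")
    return arr


def paired_ttest(x, y, r: float = DEFAULT_PRIOR_SCALE) -> TTestResult:
    """Two-sided paired t test with JZS Bayes factor.

    Identical samples (all differences zero) return t = 0, p = 1: there
    is exactly no evidence of a difference.  A nonzero constant
    difference (zero variance, nonzero mean) leaves t undefined and
    raises instead.
    """
    x, y = _as_array(x, "x"), _as_array(y, "y")
    if x.size != y.size:
        raise StatsError(f"paired samples must have equal length, got {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise StatsError(f"need at least 2 pairs, got {n}")
    d = x - y
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, bf10=jzs_bf_ttest(0.0, n, r), paired=True, n=n)
        raise StatsError(
            "differences have zero variance with a nonzero mean; the t statistic is undefined"
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), n - 1))
    return TTestResult(t=t, df=n - 1, p=p, bf10=jzs_bf_ttest(t, n, r), paired=True, n=n)


def scan_time_regression(
    data: pd.DataFrame,
    response: str,
    predictor: str = "scan_time_s",
    family_alpha: float = 0.05,
    n_models: int = 2,
) -> RegressionResult:
    """OLS of an image-quality response on scan time.

    Rows with missing scan time are excluded.  The Bonferroni-adjusted
    per-test threshold is ``family_alpha / n_models`` (0.05 over the two
    scan-time models gives 0.025).
    """
    if response not in data.columns or predictor not in data.columns:
        raise StatsError(f"data must contain columns {predictor!r} and {response!r}")
    sub = data[[predictor, response]].dropna()
    if len(sub) < 3:
        raise StatsError(f"need >= 3 records with nonmissing {predictor}, got {len(sub)}")
    x = sub[predictor].to_numpy(dtype=np.float64)
    y = sub[response].to_numpy(dtype=np.float64)
    if np.ptp(x) == 0:
        raise StatsError(f"all {predictor} values are equal; the slope is not identifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2_adj=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        df_model=float(model.df_model),
        df_resid=float(model.df_resid),
        p=float(model.f_pvalue),
        bonferroni_alpha=family_alpha / n_models,
        n=len(sub),
    )


def _validate_age_frame(data: pd.DataFrame, response: str, group: str, age: str) -> pd.DataFrame:
    for col in (group, age, response):
        if col not in data.columns:
            raise StatsError(f"data must contain column {col!r}")
    sub = data[[group, age, response]].copy()
    n_missing = int(sub[age].isna().sum())
    if n_missing:
        raise StatsError(
            f"{n_missing} rows carry no point age; resolve interval ages with "
            "sample_interval_ages (or resample_age_analysis) first"
        )
    if sub[response].isna().any():
        raise StatsError(f"response {response!r} contains missing values")
    if sub[group].nunique() < 2:
        raise StatsError("need at least 2 databases for a random-intercept model")
    return sub


def fit_lmm_age(
    data: pd.DataFrame,
    response: str = "snr_normalized",
    group: str = "database",
    age: str = "age",
) -> ModelComparison:
    """Compare random-intercept models without and with a fixed age effect.

    Both models are fitted by maximum likelihood; the LRT statistic is
    2*(llf_full - llf_null) on 1 df, and the Bayes factor is the BIC
    approximation exp((BIC_null - BIC_full)/2).  Age enters centred (the
    slope is unchanged; the intercept becomes the mean-age response).
    A constant age column makes the effect unidentifiable: the full
    model degenerates to the null (chi2 = 0, p = 1).
    """
    sub = _validate_age_frame(data, response, group, age)
    y = sub[response].to_numpy(dtype=np.float64)
    ages = sub[age].to_numpy(dtype=np.float64)
    groups = sub[group].to_numpy()
    n = y.size
    n_groups = int(sub[group].nunique())

    fit_warnings: list[str] = []
    if np.ptp(ages) == 0.0:
        fit_warnings.append("age column is constant; the age effect is not identifiable")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            null_fit = MixedLM(y, np.ones((n, 1)), groups=groups).fit(reml=False)
        fit_warnings.extend(str(w.message) for w in caught)
        llf = float(null_fit.llf)
        bic = -2.0 * llf + 3.0 * math.log(n)
        return ModelComparison(
            response=response, loglik_null=llf, loglik_full=llf,
            chi2=0.0, lrt_df=1, p_lrt=1.0, bic_null=bic, bic_full=bic + math.log(n),
            bf10_bic=math.exp(-0.5 * math.log(n)),
            fixed_effect_estimate=0.0, fixed_effect_se=math.nan,
            n_obs=n, n_groups=n_groups, fit_warnings=tuple(fit_warnings),
        )

    centred = ages - ages.mean()
    exog_null = np.ones((n, 1))
    exog_full = np.column_stack([np.ones(n), centred])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        warnings.simplefilter("always", UserWarning)
        null_fit = MixedLM(y, exog_null, groups=groups).fit(reml=False)
        full_fit = MixedLM(y, exog_full, groups=groups).fit(reml=False)
    fit_warnings.extend(str(w.message) for w in caught)

    llf_null, llf_full = float(null_fit.llf), float(full_fit.llf)
    chi2 = 2.0 * (llf_full - llf_null)
    if chi2 < 0:
        # optimizer noise on nested fits; a material violation is a bug
        if chi2 < -1e-6 * max(1.0, abs(llf_null)):
            raise StatsError(f"nested LRT statistic is negative ({chi2}); fits did not converge")
        chi2 = 0.0
    p_lrt = float(scipy.stats.chi2.sf(chi2, 1))
    # parameters: fixed effects + random-intercept variance + residual variance
    bic_null = -2.0 * llf_null + 3.0 * math.log(n)
    bic_full = -2.0 * llf_full + 4.0 * math.log(n)
    return ModelComparison(
        response=response,
        loglik_null=llf_null, loglik_full=llf_full,
        chi2=chi2, lrt_df=1, p_lrt=p_lrt,
        bic_null=bic_null, bic_full=bic_full,
        bf10_bic=float(np.exp(0.5 * (bic_null - bic_full))),
        fixed_effect_estimate=float(full_fit.fe_params[1]),
        fixed_effect_se=float(full_fit.bse_fe[1]),
        n_obs=n, n_groups=n_groups, fit_warnings=tuple(fit_warnings),
    )


def sample_interval_ages(data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Replace interval ages by uniform draws within [age_min, age_max].

    Rows with a point age are untouched; rows with neither a point age
    nor an interval keep a missing age.
    """
    out = data.copy()
    if "age_min" not in out.columns or "age_max" not in out.columns:
        return out
    mask = out["age"].isna() & out["age_min"].notna() & out["age_max"].notna()
    if not mask.any():
        return out
    lo = out.loc[mask, "age_min"].to_numpy(dtype=np.float64)
    hi = out.loc[mask, "age_max"].to_numpy(dtype=np.float64)
    if (lo > hi).any():
        raise StatsError("age_min > age_max in interval rows")
    out.loc[mask, "age"] = lo + (hi - lo) * rng.random(lo.size)
    return out


def resample_age_analysis(
    data: pd.DataFrame,
    response: str = "snr_normalized",
    n_iter: int = 1000,
    seed: int = 0,
    group: str = "database",
) -> ResampleSummary:
    """Repeat uniform age sampling + LMM comparison and average.

    Requires at least one interval-age row — with point ages only,
    :func:`fit_lmm_age` answers the question in one fit.
    """
    if "age_min" not in data.columns or "age_max" not in data.columns:
        raise StatsError("no age_min/age_max columns; use fit_lmm_age for point-age data")
    mask = data["age"].isna() & data["age_min"].notna() & data["age_max"].notna()
    if not mask.any():
        raise StatsError("no interval ages present; use fit_lmm_age directly")
    rng = np.random.default_rng(seed)
    ps, bfs, slopes = [], [], []
    for i in range(n_iter):
        try:
            resolved = sample_interval_ages(data, rng)
            comp = fit_lmm_age(resolved, response=response, group=group)
        except Exception as exc:  # annotate with the iteration index
            raise StatsError(f"age-resampling iteration {i} failed: {exc}") from exc
        ps.append(comp.p_lrt)
        bfs.append(comp.bf10_bic)
        slopes.append(comp.fixed_effect_estimate)
    return ResampleSummary(
        n_iter=n_iter,
        mean_p=float(np.mean(ps)),
        mean_bf=float(np.mean(bfs)),
        p_values=np.asarray(ps),
        bf_values=np.asarray(bfs),
        slopes=np.asarray(slopes),
    )


def slab_vs_wholebrain_test(
    slab: Mapping[str, float] | pd.Series,
    wholebrain: Mapping[str, float] | pd.Series,
    r: float = DEFAULT_PRIOR_SCALE,
) -> TTestResult:
    """Paired test of slab minus whole-brain metrics keyed by subject.

    Subjects present on only one side are dropped with a warning;
    fewer than two complete pairs is an error.
    """
    s = pd.Series(dict(slab) if not isinstance(slab, pd.Series) else slab, dtype=np.float64)
    w = pd.Series(dict(wholebrain) if not isinstance(wholebrain, pd.Series) else wholebrain, dtype=np.float64)
    common = s.index.intersection(w.index)
    dropped = sorted(set(s.index).symmetric_difference(w.index))
    if dropped:
        warnings.warn(f"dropping unpaired subjects: {dropped}", stacklevel=2)
    if len(common) < 2:
        raise StatsError(f"need >= 2 complete slab/whole-brain pairs, got {len(common)}")
    return paired_ttest(s.loc[common].to_numpy(), w.loc[common].to_numpy(), r=r)


def reliability_bf_anova(
    sample1: Sequence[float],
    sample2: Sequence[float],
    r: float = DEFAULT_PRIOR_SCALE,
) -> TTestResult:
    """Two-group Bayesian comparison of repeated quality samples.

    A one-way ANOVA with two levels is the square of an independent
    two-group t test, so the Bayes factor is the JZS BF of that t with
    effective sample size n1*n2/(n1+n2) and n1+n2-2 degrees of freedom.
    BF10 < 1 is evidence the two samples share one distribution.
    """
    a, b = _as_array(sample1, "sample1"), _as_array(sample2, "sample2")
    if a.size < 2 or b.size < 2:
        raise StatsError(f"both groups need n >= 2, got {a.size} and {b.size}")
    t_res = scipy.stats.ttest_ind(a, b, equal_var=True)
    t = float(t_res.statistic)
    df = a.size + b.size - 2
    if not math.isfinite(t):
        raise StatsError("two-sample t statistic is undefined (zero pooled variance)")
    n_eff = a.size * b.size / (a.size + b.size)
    bf10 = _jzs_bf10(t, n_eff=n_eff, df=float(df), r=r)
    return TTestResult(t=t, df=df, p=float(t_res.pvalue), bf10=bf10, paired=False, n=a.size + b.size)
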