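"""Longitudinal cohort statistics.

The centrepiece is a ledger of linear mixed-effects (LME) models for a
longitudinal response (e.g. the per-FOV vasomotion peak) with mouse and
FOV/vessel random effects and amyloid coverage, age, genotype and
age × genotype fixed effects, compared by AIC/BIC. Model specifications
use the lme4-style formula notation, e.g.::

    log10(Vasomotion) ~ Abeta + Age * Genotype + (1|Mouse) + (1|FOV)
    log10(Vasomotion) ~ Abeta + (1|Mouse) + (Age||FOV)

``(Age||FOV)`` denotes an uncorrelated random intercept + slope on age.
Fits are maximum likelihood (not REML) so information criteria are
comparable across different fixed-effect sets, with

    AIC = −2·loglik + 2k,   BIC = −2·loglik + k·log(n),

k counted identically across models as n_fixed + n_variance_params + 1
(residual). Fixed-effect inference is Wald-z; the reported total R² is
the conditional R² (fixed + random variance over total).

Secondary tests mirror the study's remaining statistics: Mann–Whitney U
(exact for small samples), Spearman rank correlation (exact permutation
p for n ≤ 9), two-way ANOVA with Šídák-corrected pre-selected
comparisons, two-way random-effects single-measure absolute-agreement
ICC, and unweighted Cohen's kappa.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "ModelSpec",
    "LMEResults",
    "VasomotionLME",
    "fit_lme",
    "model_ledger",
    "check_heteroskedasticity",
    "mann_whitney",
    "spearman",
    "anova2_sidak",
    "sidak_adjust",
    "icc_two_raters",
    "cohen_kappa",
    "MannWhitneyResult",
    "SpearmanResult",
    "Anova2Result",
    "AgreementResult",
]

# canonical column names behind the Table-1-style formula vocabulary
_NAME_MAP = {
    "vasomotion": "vasomotion_peak",
    "abeta": "abeta_coverage",
    "age": "age",
    "genotype": "genotype",
    "mouse": "mouse_id",
    "fov": "fov_id",
    "vessel": "vessel_id",
    "diameter": "normalized_diameter",
    "pulsatility": "pulsatility_auc",
}


def _canon(name: str) -> str:
    key = name.strip().lower()
    return _NAME_MAP.get(key, key)


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification of the ledger.

    ``fixed_terms`` is an ordered tuple drawn from
    {"abeta", "age", "genotype", "age_x_genotype"} (the interaction
    requires both mains); ``random_terms`` maps each grouping column to
    "intercept" or "intercept_slope_age" (uncorrelated). ``transform``
    is "identity" or "log10".
    """

    response: str = "vasomotion_peak"
    transform: str = "log10"
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[tuple[str, str], ...] = (
        ("mouse_id", "intercept"),
        ("fov_id", "intercept"),
    )
    name: str = ""

    def __post_init__(self) -> None:
        allowed = {"abeta", "age", "genotype", "age_x_genotype"}
        bad = set(self.fixed_terms) - allowed
        if bad:
            raise ValueError(f"unknown fixed terms: {sorted(bad)}")
        if "age_x_genotype" in self.fixed_terms and not (
            "age" in self.fixed_terms and "genotype" in self.fixed_terms
        ):
            raise ValueError("age_x_genotype requires both main effects")
        if self.transform not in ("identity", "log10"):
            raise ValueError(f"unknown transform {self.transform!r}")
        for _, kind in self.random_terms:
            if kind not in ("intercept", "intercept_slope_age"):
                raise ValueError(f"unknown random term kind {kind!r}")
        if not self.random_terms:
            raise ValueError("at least one random grouping factor is required")

    @classmethod
    def from_formula(cls, formula: str, name: str = "") -> "ModelSpec":
        """Parse an lme4-style ledger formula.

        Accepts e.g. ``log10(Vasomotion) ~ Abeta + Age × Genotype +
        (1|Mouse) + (1|FOV)`` or ``... + (Age||FOV)``; ``*``, ``×`` and
        ``x`` all denote the interaction-with-mains shorthand.
        """
        lhs, rhs = formula.split("~", 1)
        lhs = lhs.strip()
        m = re.fullmatch(r"log10\s*\(\s*(\w+)\s*\)", lhs, flags=re.IGNORECASE)
        if m:
            response, transform = _canon(m.group(1)), "log10"
        else:
            response, transform = _canon(lhs), "identity"

        random: list[tuple[str, str]] = []

        def _grab_random(match: re.Match) -> str:
            inner = match.group(1)
            if "||" in inner:
                slope, group = inner.split("||")
                if slope.strip().lower() != "age":
                    raise ValueError(f"unsupported random slope {slope!r}")
                random.append((_canon(group), "intercept_slope_age"))
            else:
                left, group = inner.split("|")
                if left.strip() != "1":
                    raise ValueError(f"unsupported random term ({inner})")
                random.append((_canon(group), "intercept"))
            return ""

        rest = re.sub(r"\(([^)]*)\)", _grab_random, rhs)
        fixed: list[str] = []
        for term in rest.split("+"):
            term = term.strip()
            if not term or term == "1":
                continue
            parts = re.split(r"\s*(?:[*×:]|\bx\b)\s*", term)
            if len(parts) == 2:
                names = sorted(p.strip().lower() for p in parts)
                if names != ["age", "genotype"]:
                    raise ValueError(f"unsupported interaction {term!r}")
                for p in ("age", "genotype"):
                    if p not in fixed:
                        fixed.append(p)
                fixed.append("age_x_genotype")
            else:
                key = term.lower()
                if key not in ("abeta", "age", "genotype"):
                    raise ValueError(f"unknown fixed term {term!r}")
                if key not in fixed:
                    fixed.append(key)
        return cls(
            response=response,
            transform=transform,
            fixed_terms=tuple(fixed),
            random_terms=tuple(random),
            name=name or formula.strip(),
        )

    @property
    def fixed_formula(self) -> str:
        terms = []
        for t in self.fixed_terms:
            if t == "abeta":
                terms.append("abeta_coverage")
            elif t == "age":
                terms.append("age")
            elif t == "genotype":
                terms.append("C(genotype, Treatment('WT'))")
            elif t == "age_x_genotype":
                terms.append("age:C(genotype, Treatment('WT'))")
        rhs = " + ".join(terms) if terms else "1"
        return f"_y ~ {rhs}"


@dataclass
class LMEResults:
    """Results of one maximum-likelihood mixed-model fit.

    ``fixed`` is a DataFrame indexed by term with columns estimate,
    ci_low, ci_high, p (Wald z). ``converged`` is False when the
    optimizer failed or the fit was singular — such fits are flagged,
    never dropped.
    """

    spec: ModelSpec
    fixed: pd.DataFrame
    log_likelihood: float
    aic: float
    bic: float
    total_r2: float
    n_obs: int
    n_params: int
    variance_components: dict[str, float] = field(default_factory=dict)
    residual_variance: float = np.nan
    converged: bool = True

    def summary(self) -> str:
        lines = [
            f"Mixed model: {self.spec.name or self.spec.fixed_formula}",
            f"  n = {self.n_obs}, k = {self.n_params}, "
            f"loglik = {self.log_likelihood:.2f}, AIC = {self.aic:.1f}, "
            f"BIC = {self.bic:.1f}, total R2 = {self.total_r2:.2f}"
            + ("" if self.converged else "  [NOT CONVERGED]"),
            "  Fixed effects (Wald 95% CI):",
        ]
        for term, row in self.fixed.iterrows():
            lines.append(
                f"    {term:<28} {row.estimate: .3e}  "
                f"[{row.ci_low: .3e}, {row.ci_high: .3e}]  p = {row.p:.2e}"
            )
        for k, v in self.variance_components.items():
            lines.append(f"  var({k}) = {v:.4g}")
        lines.append(f"  var(residual) = {self.residual_variance:.4g}")
        return "\n".join(lines)


class VasomotionLME:
    """A longitudinal mixed model built from a cohort table.

    statsmodels-style front end: construct from a long-format
    DataFrame (one row per FOV/vessel per session) and a
    :class:`ModelSpec` or ledger formula, then :meth:`fit` to obtain
    :class:`LMEResults`.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.data = self._prepare(data, spec)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "VasomotionLME":
        return cls(data, ModelSpec.from_formula(formula))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec) -> "VasomotionLME":
        return cls(data, spec)

    @staticmethod
    def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
        df = data.copy()
        if spec.response not in df.columns:
            raise ValueError(f"response column {spec.response!r} missing")
        y = df[spec.response].astype(float)
        if spec.transform == "log10":
            if (y <= 0).any():
                raise ValueError("log10 transform requires a positive response")
            y = np.log10(y)
        if not np.isfinite(y).all():
            raise ValueError("response is not finite after transform")
        df["_y"] = y
        for col, _ in spec.random_terms:
            if col not in df.columns:
                raise ValueError(f"grouping column {col!r} missing")
            if df[col].nunique() < 2:
                raise ValueError(f"grouping factor {col!r} needs >= 2 levels")
        return df

    def fit(self) -> LMEResults:
        """Maximum-likelihood fit with Wald fixed-effect inference."""
        spec, df = self.spec, self.data
        groups_col, groups_kind = spec.random_terms[0]
        re_formula = "1"
        if groups_kind == "intercept_slope_age":
            # uncorrelated intercept + slope for the top grouping factor
            re_formula = "1"
            vc_extra = {f"{groups_col}_age_slope": "0 + age"}
        else:
            vc_extra = {}
        vc: dict[str, str] = dict(vc_extra)
        for col, kind in spec.random_terms[1:]:
            vc[f"{col}_intercept"] = f"0 + C({col})"
            if kind == "intercept_slope_age":
                vc[f"{col}_age_slope"] = f"0 + C({col}):age"

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                spec.fixed_formula,
                df,
                groups=df[groups_col],
                re_formula=re_formula,
                vc_formula=vc or None,
            )
            try:
                res = model.fit(reml=False, method="lbfgs", maxiter=200)
                if not res.converged:
                    res = model.fit(reml=False, method="powell", maxiter=500)
                converged = bool(res.converged)
            except Exception:
                res, converged = None, False

        if res is None:
            nan = float("nan")
            empty = pd.DataFrame(columns=["estimate", "ci_low", "ci_high", "p"])
            return LMEResults(
                spec=spec, fixed=empty, log_likelihood=nan, aic=nan, bic=nan,
                total_r2=nan, n_obs=len(df), n_params=0, converged=False,
            )

        k_fe = len(res.fe_params)
        fe = res.fe_params
        bse = res.bse.iloc[:k_fe]
        z = fe / bse
        pvals = 2.0 * sps.norm.sf(np.abs(z))
        ci_low = fe - 1.959963984540054 * bse
        ci_high = fe + 1.959963984540054 * bse
        fixed = pd.DataFrame(
            {"estimate": fe, "ci_low": ci_low, "ci_high": ci_high, "p": pvals}
        )

        # variance parameters, all in response units
        n_re_cov = res.cov_re.shape[0] * (res.cov_re.shape[0] + 1) // 2
        vcomp_names = list(model.exog_vc.names) if vc else []
        n_vc = len(vcomp_names)
        k = k_fe + n_re_cov + n_vc + 1
        n = int(res.nobs)
        llf = float(res.llf)
        aic = -2.0 * llf + 2.0 * k
        bic = -2.0 * llf + k * math.log(n)

        var_components: dict[str, float] = {}
        re_var = float(np.diag(res.cov_re).sum()) if res.cov_re.size else 0.0
        var_components[f"{groups_col}_intercept"] = (
            float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
        )
        for name, v in zip(vcomp_names, np.atleast_1d(res.vcomp)):
            var_components[name] = float(v)
        resid_var = float(res.scale)

        # conditional R^2: fixed + random variance over total; slope terms
        # contribute sigma_slope^2 * mean(age^2)
        fitted_fixed = np.asarray(model.exog) @ np.asarray(fe)
        var_f = float(np.var(fitted_fixed))
        var_r = re_var
        for name, v in var_components.items():
            if name.endswith("_age_slope"):
                var_r += float(v) * float(np.mean(df["age"] ** 2))
            elif name.endswith("_intercept") and name != f"{groups_col}_intercept":
                var_r += float(v)
        total_r2 = (var_f + var_r) / (var_f + var_r + resid_var)

        return LMEResults(
            spec=spec,
            fixed=fixed,
            log_likelihood=llf,
            aic=aic,
            bic=bic,
            total_r2=total_r2,
            n_obs=n,
            n_params=k,
            variance_components=var_components,
            residual_variance=resid_var,
            converged=converged,
        )


def fit_lme(table: pd.DataFrame, spec: ModelSpec | str) -> LMEResults:
    """Fit one ledger model to a long-format cohort table."""
    if isinstance(spec, str):
        spec = ModelSpec.from_formula(spec)
    return VasomotionLME(table, spec).fit()


def model_ledger(
    table: pd.DataFrame, specs: list[ModelSpec | str]
) -> tuple[pd.DataFrame, list[LMEResults]]:
    """Fit a family of mixed models and rank them by information criteria.

    Returns (ledger table, results). One row per model with loglik,
    AIC, BIC, total R² and the fixed-effect estimates; the best model
    (lowest AIC, ties broken by lowest BIC) is flagged in ``selected``.
    Non-converged fits are retained with ``converged`` False.
    """
    resolved = [ModelSpec.from_formula(s) if isinstance(s, str) else s for s in specs]
    responses = {(s.response, s.transform) for s in resolved}
    if len(responses) > 1:
        raise ValueError("all ledger models must share response and transform")
    results = [fit_lme(table, s) for s in resolved]
    rows = []
    for r in results:
        row = {
            "model": r.spec.name or r.spec.fixed_formula,
            "loglik": r.log_likelihood,
            "aic": r.aic,
            "bic": r.bic,
            "total_r2": r.total_r2,
            "k": r.n_params,
            "converged": r.converged,
        }
        for term, fe in r.fixed.iterrows():
            row[f"est[{term}]"] = fe.estimate
            row[f"p[{term}]"] = fe.p
        rows.append(row)
    ledger = pd.DataFrame(rows)
    ok = ledger["converged"] & np.isfinite(ledger["aic"])
    ledger["selected"] = False
    if ok.any():
        cand = ledger[ok].sort_values(["aic", "bic"], kind="mergesort")
        ledger.loc[cand.index[0], "selected"] = True
    return ledger, results


def check_heteroskedasticity(
    table: pd.DataFrame, response: str, predictors: list[str]
) -> tuple[float, float]:
    """Breusch–Pagan LM statistic and p-value on OLS residuals.

    A significant result motivates a log transform of the response
    before mixed-model fitting.
    """
    X = sm.add_constant(table[predictors].astype(float))
    resid = sm.OLS(table[response].astype(float), X).fit().resid
    lm, lm_p, _, _ = het_breuschpagan(resid, X)
    return float(lm), float(lm_p)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@dataclass
class MannWhitneyResult:
    u: float
    z: float
    p: float
    method: str  # "exact" or "normal"
    flag: str = ""


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x over y with tie correction via midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return r1 - x.size * (x.size + 1) / 2.0


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Reports the tie-corrected normal-approximation Z in all cases. The
    p-value is exact (enumeration of all group-label assignments of the
    pooled sample, two-sided as P(|U − mn/2| ≥ |u − mn/2|)) when both
    samples have n ≤ 8, else the normal approximation 2(1 − Φ(|Z|)).
    When every value is tied across both groups, p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(
            u=n1 * n2 / 2.0, z=0.0, p=1.0, method="degenerate",
            flag="all values tied across both groups",
        )
    u = _mw_u(x, y)
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (u - mean_u) / math.sqrt(var_u) if var_u > 0 else 0.0

    if n1 <= 8 and n2 <= 8:
        stat_obs = abs(u - mean_u)
        count = total = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            u_perm = _mw_u(pooled[sel], pooled[~sel])
            total += 1
            if abs(u_perm - mean_u) >= stat_obs - 1e-12:
                count += 1
        return MannWhitneyResult(u=u, z=z, p=count / total, method="exact")
    p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(u=u, z=z, p=min(1.0, p), method="normal")


@dataclass
class SpearmanResult:
    rho: float
    p: float
    method: str  # "exact" or "t"
    flag: str = ""


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is exact by full permutation of one variable's ranks
    for n ≤ 9, otherwise the two-sided t-approximation with
    t = ρ√((n−2)/(1−ρ²)). Zero rank variance in either variable leaves
    ρ undefined (NaN) with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need paired samples with n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.var(rx) == 0 or np.var(ry) == 0:
        return SpearmanResult(
            rho=np.nan, p=np.nan, method="degenerate",
            flag="zero rank variance in one variable",
        )
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 9:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float((rx_c**2).sum() * (ry_c**2).sum()))
        obs = abs(float(rx_c @ ry_c))
        count = total = 0
        for perm in itertools.permutations(range(n)):
            s = abs(float(rx_c @ ry_c[list(perm)]))
            total += 1
            if s >= obs - 1e-9 * denom:
                count += 1
        return SpearmanResult(rho=rho, p=count / total, method="exact")
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho=rho, p=min(1.0, p), method="t")


# ---------------------------------------------------------------------------
# two-way ANOVA with Šídák-corrected pre-selected comparisons
# ---------------------------------------------------------------------------

def sidak_adjust(p: float, m: int) -> float:
    """Šídák adjustment for m pre-selected comparisons, clipped to [0, 1]."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return float(np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0))


@dataclass
class Anova2Result:
    anova_table: pd.DataFrame  # F and p for main effects (+ interaction)
    pairwise: pd.DataFrame  # raw and Šídák-adjusted Welch-t p per pair
    flag: str = ""


def anova2_sidak(
    values,
    factor_a,
    factor_b,
    preselected: list[tuple[tuple, tuple]] | None = None,
) -> Anova2Result:
    """Two-way ANOVA (Type-II SS) with Šídák-corrected planned comparisons.

    Fits ``value ~ A * B`` by OLS and reports Type-II F tests for both
    main effects and the interaction. Each pre-selected comparison is a
    pair of (a, b) cells tested with a Welch t-test; adjusted
    p = 1 − (1 − p)^m with m the number of planned pairs. When a cell
    of the layout is empty the interaction cannot be estimated: main
    effects are reported from the additive model with a flag.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "A": np.asarray(factor_a), "B": np.asarray(factor_b)}
    )
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = df.groupby(["A", "B"], observed=True).size()
    full_grid = df["A"].nunique() * df["B"].nunique()
    flag = ""
    formula = "value ~ C(A) * C(B)"
    if len(cells) < full_grid:
        flag = "empty cell: interaction not estimable, additive model reported"
        formula = "value ~ C(A) + C(B)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(formula, data=df).fit()
        table = anova_lm(fit, typ=2)

    pairs = preselected or []
    rows = []
    m = len(pairs)
    for (a1, b1), (a2, b2) in pairs:
        g1 = df.loc[(df["A"] == a1) & (df["B"] == b1), "value"]
        g2 = df.loc[(df["A"] == a2) & (df["B"] == b2), "value"]
        if g1.empty or g2.empty:
            raise ValueError(f"pre-selected pair ({a1},{b1}) vs ({a2},{b2}) names an empty cell")
        t, p = sps.ttest_ind(g1, g2, equal_var=False)
        rows.append(
            {"cell_1": f"{a1}/{b1}", "cell_2": f"{a2}/{b2}",
             "t": float(t), "p_raw": float(p), "p_sidak": sidak_adjust(float(p), m)}
        )
    pairwise = pd.DataFrame(rows)
    return Anova2Result(anova_table=table, pairwise=pairwise, flag=flag)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    value: float
    flag: str = ""


def icc_two_raters(scores: np.ndarray) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``scores`` is an (n items × 2 raters) array. From the two-way mean
    squares (rows = items, columns = raters):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).

    Zero between-item variance leaves the coefficient undefined.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2:
        raise ValueError("scores must be (n items x 2 raters)")
    n, k = s.shape
    if n < 3:
        raise ValueError("need at least 3 items")
    grand = s.mean()
    row_means = s.mean(axis=1)
    col_means = s.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((s - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    total_ss = ssr + ssc + sse
    if denom <= 1e-12 * max(total_ss, 1e-300) or total_ss == 0:
        return AgreementResult(
            value=np.nan, flag="zero between-item and residual variance"
        )
    return AgreementResult(value=float((msr - mse) / denom))


def cohen_kappa(ratings: np.ndarray, categories=None) -> AgreementResult:
    """Unweighted Cohen's kappa for two categorical raters.

    κ = (p_o − p_e) / (1 − p_e) from the confusion matrix over the
    shared category set. When both raters always assign the same single
    category (p_e = 1), κ is defined as 1 with a flag.
    """
    r = np.asarray(ratings)
    if r.ndim != 2 or r.shape[1] != 2:
        raise ValueError("ratings must be (n items x 2 raters)")
    if r.shape[0] < 1:
        raise ValueError("need at least 1 item")
    cats = np.asarray(categories) if categories is not None else np.unique(r)
    index = {c: i for i, c in enumerate(cats.tolist())}
    conf = np.zeros((len(cats), len(cats)))
    for a, b in r:
        conf[index[a], index[b]] += 1
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        return AgreementResult(value=1.0, flag="both raters constant: p_e = 1")
    return AgreementResult(value=float((p_o - p_e) / (1.0 - p_e)))
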