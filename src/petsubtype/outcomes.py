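"""Baseline characterization and longitudinal outcomes of subtypes.

Covers the statistical toolbox used to compare subtypes: composite-score
arithmetic (memory-minus-executive difference), volumetric ratios, A/T/N
biomarker classification, omnibus group tests with FDR-corrected post
hocs, progression-event extraction from CDR visits, Kaplan-Meier curves,
Cox proportional-hazards regression, and linear mixed models of
domain-specific cognitive decline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

# A/T/N positivity thresholds (amyloid PET SUVR and CSF immunoassay, pg/ml)
AV45_POSITIVE_SUVR = 1.11      # inclusive: suvr >= threshold is A+
CSF_ABETA_POSITIVE = 880.0     # strict: abeta < threshold is A+
CSF_PTAU_POSITIVE = 19.2       # strict: ptau > threshold is T+
CSF_TTAU_POSITIVE = 242.0      # strict: ttau > threshold is N+


class EligibilityError(ValueError):
    pass


class NonConvergenceError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# baseline arithmetic


def adni_diff(mem: float, ef: float) -> float:
    """Memory-minus-executive composite difference.

    Positive values mean the executive deficit exceeds the memory
    deficit; negative values the reverse.
    """
    if not (np.isfinite(mem) and np.isfinite(ef)):
        raise ValueError("composite scores must be finite")
    return float(mem - ef)


def hv_ctv_ratio(hv: float | np.ndarray, ctv: float | np.ndarray) -> float | np.ndarray:
    """Hippocampus-to-cortex volume ratio, scaled by 1000 to match the
    magnitude convention of the emulated tables. Group summaries should
    average per-subject ratios, not take the ratio of group means."""
    hv = np.asarray(hv, dtype=float)
    ctv = np.asarray(ctv, dtype=float)
    if np.any(ctv <= 0):
        raise ValueError("ctv must be positive")
    out = 1000.0 * hv / ctv
    return float(out) if out.ndim == 0 else out


@dataclass
class ATNProfile:
    A: str  # '+', '-', 'unknown'
    T: str
    N: str
    av45_suvr: float | None
    csf_abeta: float | None
    csf_ptau: float | None
    csf_ttau: float | None


def atn_classify(av45_suvr: float | None = None, csf_abeta: float | None = None,
                 csf_ptau: float | None = None, csf_ttau: float | None = None) -> ATNProfile:
    """A/T/N biomarker classification.

    Amyloid PET takes precedence for A; CSF amyloid is the fallback when
    PET is unavailable. Boundary conventions: A+ is inclusive at the PET
    threshold; the three CSF thresholds are strict.
    """
    def missing(v):
        return v is None or (isinstance(v, float) and np.isnan(v))

    if missing(av45_suvr) and missing(csf_abeta):
        raise ValueError("need at least one amyloid input (PET SUVR or CSF abeta)")
    if not missing(av45_suvr):
        a = "+" if av45_suvr >= AV45_POSITIVE_SUVR else "-"
    else:
        a = "+" if csf_abeta < CSF_ABETA_POSITIVE else "-"
    t = "unknown" if missing(csf_ptau) else ("+" if csf_ptau > CSF_PTAU_POSITIVE else "-")
    n = "unknown" if missing(csf_ttau) else ("+" if csf_ttau > CSF_TTAU_POSITIVE else "-")
    return ATNProfile(A=a, T=t, N=n, av45_suvr=av45_suvr, csf_abeta=csf_abeta,
                      csf_ptau=csf_ptau, csf_ttau=csf_ttau)


# ----------------------------------------------------------------------
# group tests


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupTestResult:
    global_p: float
    global_stat: float
    pairwise: pd.DataFrame | None  # g1, g2, stat, p_raw, p_fdr (None if global ns)
    n_used: int
    n_dropped: int


def group_test_continuous(values, group, covariates: pd.DataFrame | None = None,
                          alpha: float = 0.05) -> GroupTestResult:
    """Omnibus F test on a group factor (ANOVA/ANCOVA) with FDR post hocs.

    Fits a linear model of ``values`` on the group factor plus optional
    covariates and tests the group factor; pairwise two-sample t tests
    (BH-adjusted) are run only when the omnibus p is below ``alpha``.
    Rows with missing values are dropped listwise and counted.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": pd.Categorical(group)})
    rhs = ["C(g)"]
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True)
        for c in cov.columns:
            v = cov[c]
            if v.dtype == object or str(v.dtype) == "category":
                v = pd.factorize(v)[0].astype(float)
            df[f"cov_{c}"] = np.asarray(v, dtype=float)
            rhs.append(f"cov_{c}")
    n0 = len(df)
    df = df.dropna().reset_index(drop=True)
    counts = df["g"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 observations each")

    model = smf.ols("y ~ " + " + ".join(rhs), data=df)
    try:
        fit = model.fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError(f"design error: {exc}") from exc
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("design is rank deficient (covariate collinear with group?)")
    anova = sm.stats.anova_lm(fit, typ=2)
    global_p = float(anova.loc["C(g)", "PR(>F)"])
    global_f = float(anova.loc["C(g)", "F"])

    pairwise = None
    if global_p < alpha:
        rows = []
        for g1, g2 in combinations(sorted(df["g"].cat.categories), 2):
            a = df.loc[df["g"] == g1, "y"]
            b = df.loc[df["g"] == g2, "y"]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append((g1, g2, float(t), float(p)))
        pairwise = pd.DataFrame(rows, columns=["g1", "g2", "stat", "p_raw"])
        pairwise["p_fdr"] = fdr_bh(pairwise["p_raw"])
    return GroupTestResult(global_p=global_p, global_stat=global_f,
                           pairwise=pairwise, n_used=len(df), n_dropped=n0 - len(df))


def group_test_categorical(counts: pd.DataFrame | np.ndarray,
                           alpha: float = 0.05) -> GroupTestResult:
    """Pearson chi-square (no continuity correction) on a 2 x k count table
    with BH-adjusted pairwise 2 x 2 proportion tests."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k table of counts")
    if np.any(table < 0) or np.any(table.sum(axis=0) <= 0):
        raise ValueError("counts must be non-negative with positive column sums")
    if table.sum() == 0:
        raise ValueError("empty table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.all(np.abs(table - expected) < 1e-12):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    col_names = (list(counts.columns) if isinstance(counts, pd.DataFrame)
                 else list(range(table.shape[1])))
    pairwise = None
    if p < alpha and table.shape[1] > 2:
        rows = []
        for i, j in combinations(range(table.shape[1]), 2):
            sub = table[:, [i, j]]
            c2, pp, _, _ = stats.chi2_contingency(sub, correction=False)
            rows.append((col_names[i], col_names[j], float(c2), float(pp)))
        pairwise = pd.DataFrame(rows, columns=["g1", "g2", "stat", "p_raw"])
        pairwise["p_fdr"] = fdr_bh(pairwise["p_raw"])
    return GroupTestResult(global_p=float(p), global_stat=float(chi2),
                           pairwise=pairwise, n_used=int(table.sum()), n_dropped=0)


# ----------------------------------------------------------------------
# survival


def progression_event(visits: pd.DataFrame) -> tuple[float, bool]:
    """(time in months, event observed) for one subject's CDR visits.

    The event is the first visit with CDR >= 1; otherwise the subject is
    censored at the last visit. Baseline CDR must be 0.5.
    """
    v = visits.sort_values("month")
    if v["month"].duplicated().any() or not (np.diff(v["month"]) > 0).all():
        raise ValueError("visit months must be strictly increasing")
    if int(v["month"].iloc[0]) != 0:
        raise EligibilityError("month 0 visit required")
    if v["cdr"].iloc[0] != 0.5:
        raise EligibilityError("baseline CDR must be 0.5 for progression analysis")
    if len(v) < 2:
        raise EligibilityError("need at least one follow-up visit")
    hit = v[v["cdr"] >= 1.0]
    if len(hit):
        return float(hit["month"].iloc[0]), True
    return float(v["month"].iloc[-1]), False


def progression_table(visits: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject survival records joined with subtype and covariates."""
    rows = []
    for sid, sub in visits.groupby("subject_id"):
        time, event = progression_event(sub)
        if time <= 0:
            continue  # event at baseline: not at risk
        rows.append(dict(subject_id=sid, time=time, event=event))
    rec = pd.DataFrame(rows)
    keep = [c for c in ("subject_id", "subtype", "true_subtype", "age", "gender",
                        "education") if c in cohort.columns]
    return rec.merge(cohort[keep], on="subject_id", how="left")


def kaplan_meier(records: pd.DataFrame, by: str | None = None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, optionally per group.

    Returns ``{group: DataFrame(time, survival, at_risk)}`` with a
    right-continuous non-increasing step function starting at S(0) = 1.
    """
    from lifelines import KaplanMeierFitter

    groups = {"all": records} if by is None else dict(tuple(records.groupby(by)))
    out = {}
    for name, sub in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[str(name)] = sf
    return out


@dataclass
class CoxResults:
    summary: pd.DataFrame   # term, coef, hr, se, ci_low, ci_high, p
    reference: str
    ties: str
    model: object           # fitted statsmodels PHRegResults

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.set_index("term").loc[term, "hr"])


def cox_ph(records: pd.DataFrame, group: str = "subtype",
           reference: str = "no_hypometabolism",
           covariates: tuple[str, ...] = ("age", "gender", "education"),
           ties: str = "breslow") -> CoxResults:
    """Cox proportional-hazards fit of progression risk by subtype.

    Subtype enters as a factor against ``reference``; hazard ratios are
    ``exp(coef)`` with Wald confidence intervals. Ties are handled by the
    Breslow method by default (Efron behind the flag).
    """
    from statsmodels.duration.hazard_regression import PHReg

    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    df = records.copy().reset_index(drop=True)
    if (df["time"] <= 0).any():
        raise ValueError("all survival times must be positive")
    levels = [lv for lv in df[group].dropna().unique()]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from {group!r}")
    others = sorted(lv for lv in levels if lv != reference)
    for lv in levels:
        if not df.loc[df[group] == lv, "event"].any():
            raise NonConvergenceError(f"group {lv!r} has no events; HR not estimable")

    X = pd.DataFrame(index=df.index)
    for lv in others:
        X[f"{group}[{lv}]"] = (df[group] == lv).astype(float)
    for c in covariates:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            v = pd.factorize(v)[0].astype(float)
        X[c] = np.asarray(v, dtype=float)

    model = PHReg(np.asarray(df["time"], dtype=float), X.to_numpy(),
                  status=np.asarray(df["event"], dtype=int), ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(disp=False)
    params = np.asarray(fit.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 15):
        raise NonConvergenceError(
            "partial likelihood did not converge (possible complete separation); "
            f"coefficients: {dict(zip(X.columns, np.round(params, 2)))}")
    se = np.asarray(fit.bse, dtype=float)
    z = params / se
    summary = pd.DataFrame({
        "term": list(X.columns),
        "coef": params,
        "hr": np.exp(params),
        "se": se,
        "ci_low": np.exp(params - 1.959963984540054 * se),
        "ci_high": np.exp(params + 1.959963984540054 * se),
        "p": 2.0 * stats.norm.sf(np.abs(z)),
    })
    return CoxResults(summary=summary, reference=reference, ties=ties, model=fit)


# ----------------------------------------------------------------------
# mixed models


@dataclass
class LMMResults:
    fixed_effects: pd.DataFrame   # term, estimate, se, z, p
    interaction_terms: list[str]
    converged: bool
    random_structure: str         # 'intercept+slope' or 'intercept'
    model: object

    def interaction(self, level: str) -> pd.Series:
        t = [x for x in self.interaction_terms if f"[T.{level}]" in x]
        if not t:
            raise KeyError(level)
        return self.fixed_effects.set_index("term").loc[t[0]]


def lmm_trajectories(visits: pd.DataFrame, cohort: pd.DataFrame, domain: str,
                     group: str = "subtype", reference: str = "no_hypometabolism",
                     covariates: tuple[str, ...] = ("age", "gender", "education")
                     ) -> LMMResults:
    """Linear mixed model of a cognitive domain over follow-up months.

    Fixed effects: month, subtype, subtype x month interaction (the
    quantity of interest: differential decline vs the reference subtype)
    plus covariates. Random effects: per-subject intercept and slope;
    when that covariance is singular the model falls back to a random
    intercept with a warning. Wald z tests are reported.
    """
    import statsmodels.formula.api as smf

    df = visits.merge(cohort, on="subject_id", how="inner", suffixes=("", "_bl"))
    if group not in df.columns:
        raise ValueError(f"column {group!r} missing after join")
    df = df.dropna(subset=[domain, "month", group]).reset_index(drop=True)
    per_subj = df.groupby("subject_id").size()
    if (per_subj >= 2).mean() < 0.8:
        raise ValueError("need >= 2 visits for at least 80% of subjects")

    terms = [f"C({group}, Treatment('{reference}'))", "month",
             f"month:C({group}, Treatment('{reference}'))"]
    for c in covariates:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            df[f"{c}_num"] = pd.factorize(v)[0].astype(float)
            terms.append(f"{c}_num")
        else:
            terms.append(c)
    formula = f"{domain} ~ " + " + ".join(terms)

    def _fit(re_formula):
        model = smf.mixedlm(formula, df, groups=df["subject_id"], re_formula=re_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True, method=["lbfgs", "powell"])

    random_structure = "intercept+slope"
    fit = _fit("~month")
    cov_re = np.asarray(fit.cov_re, dtype=float)
    singular = (not fit.converged) or np.linalg.matrix_rank(cov_re) < cov_re.shape[0] \
        or np.any(np.diag(cov_re) < 1e-10)
    if singular:
        warnings.warn("random intercept+slope covariance is singular; "
                      "falling back to random intercept only", stacklevel=2)
        random_structure = "intercept"
        fit = _fit("~1")

    fe = fit.fe_params
    se = fit.bse_fe
    z = fe / se
    table = pd.DataFrame({
        "term": fe.index,
        "estimate": fe.to_numpy(),
        "se": se.to_numpy(),
        "z": z.to_numpy(),
        "p": 2.0 * stats.norm.sf(np.abs(z.to_numpy())),
    })
    inter = [t for t in fe.index if t.startswith("month:C(")]
    return LMMResults(fixed_effects=table, interaction_terms=inter,
                      converged=bool(fit.converged), random_structure=random_structure,
                      model=fit)
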