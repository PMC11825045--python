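"""Outcome statistics: group comparisons, unadjusted odds ratios, the
hypoxemia-stratified safe-upper-limit procedure, and survival stratified
by the derived limits.

The safe-upper-limit procedure tests, one-sided, whether the exposure
(MP or MP/IBW) is stochastically greater among nonsurvivors (Mann-Whitney
U). Only when that test rejects at level alpha is a limit reported, taken
as the survivors' (1 - alpha)·100th percentile with linear interpolation
between order statistics. A non-significant stratum legitimately returns
no limit — as observed for severe hypoxemia, where mortality is driven by
the underlying pathology rather than the delivered mechanical power.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 8  # per arm; above this the normal approximation is used


@dataclass
class ComparisonResult:
    var_kind: str  # "nonsymmetric" | "symmetric" | "categorical"
    statistic: float
    p_value: float
    summary_dead: str
    summary_alive: str


@dataclass
class SafeLimitResult:
    stratum: str
    variable: str
    window_h: int
    alpha: float
    p_value: float
    limit: float | None
    n_survivors: int
    n_nonsurvivors: int

    def as_dict(self) -> dict:
        return asdict(self)


def _summarize(x: np.ndarray, kind: str) -> str:
    if kind == "symmetric":
        return f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f})"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def compare_groups(values_dead, values_alive, var_kind: str = "nonsymmetric") -> ComparisonResult:
    """Two-sided comparison between mortality groups.

    nonsymmetric  -> Mann-Whitney U (medians/IQR summaries)
    symmetric     -> Welch t-test (mean/SD summaries)
    categorical   -> chi-square on the level × outcome contingency table
    """
    dead = np.asarray(values_dead)
    alive = np.asarray(values_alive)
    if len(dead) < 2 or len(alive) < 2:
        raise ValueError("need at least 2 observations per arm")
    if var_kind == "nonsymmetric":
        stat, p = sps.mannwhitneyu(dead, alive, alternative="two-sided")
        return ComparisonResult(var_kind, float(stat), float(p),
                                _summarize(dead.astype(float), var_kind),
                                _summarize(alive.astype(float), var_kind))
    if var_kind == "symmetric":
        stat, p = sps.ttest_ind(dead, alive, equal_var=False)
        return ComparisonResult(var_kind, float(stat), float(p),
                                _summarize(dead.astype(float), var_kind),
                                _summarize(alive.astype(float), var_kind))
    if var_kind == "categorical":
        levels = sorted(set(dead) | set(alive))
        table = np.array([
            [np.sum(dead == lv) for lv in levels],
            [np.sum(alive == lv) for lv in levels],
        ])
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return ComparisonResult(var_kind, float(stat), float(p),
                                str(dict(zip(levels, table[0]))),
                                str(dict(zip(levels, table[1]))))
    raise ValueError(f"unknown var_kind {var_kind!r}")


@dataclass
class OddsRatioResult:
    or_per_unit: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    separation: bool = False


def unadjusted_or(exposure, outcome) -> OddsRatioResult:
    """Odds ratio per unit of a continuous exposure for a binary outcome.

    Exponentiated slope of a single-predictor logistic regression with a
    Wald 95% CI. Complete (or quasi-complete) separation is flagged and no
    estimate is returned.
    """
    import statsmodels.api as sm

    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    # separation screen: exposure ranges of the two classes do not overlap
    if x[y == 1].min() > x[y == 0].max() or x[y == 0].min() > x[y == 1].max():
        return OddsRatioResult(None, None, None, None, separation=True)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except Exception:
            return OddsRatioResult(None, None, None, None, separation=True)
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        return OddsRatioResult(None, None, None, None, separation=True)
    beta, se = fit.params[1], fit.bse[1]
    return OddsRatioResult(
        or_per_unit=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(fit.pvalues[1]),
    )


def _exact_mw_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided Mann-Whitney p-value by enumeration.

    P(U >= U_obs) over all C(n+m, n) assignments of the pooled values to
    the first arm, under the null of exchangeability. Ties are handled
    exactly: each tied pair contributes 1/2 to U.
    """
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(first_idx: tuple[int, ...]) -> float:
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(first_idx)] = True
        a, b = pooled[mask], pooled[~mask]
        diff = a[:, None] - b[None, :]
        return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))

    u_obs = u_stat(tuple(range(n)))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if u_stat(idx) >= u_obs - 1e-12:
            count += 1
    return count / total


def mw_one_sided_greater(greater_arm, other_arm) -> float:
    """One-sided Mann-Whitney p for H1: ``greater_arm`` stochastically greater.

    Exact enumeration when both arms have ≤ 8 observations (exact even under
    ties); otherwise the normal approximation with tie correction.
    """
    x = np.asarray(greater_arm, dtype=float)
    y = np.asarray(other_arm, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both arms must be non-empty")
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _exact_mw_greater(x, y)
    _, p = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(p)


def safe_upper_limit(
    survivor_values,
    nonsurvivor_values,
    alpha: float = 0.05,
    stratum: str = "all",
    variable: str = "mp_ibw",
    window_h: int = 48,
) -> SafeLimitResult:
    """Rank-test-gated survivor-percentile threshold.

    If the one-sided Mann-Whitney test (nonsurvivors greater) rejects at
    ``alpha``, the limit is the (1 - alpha)·100th percentile of the
    survivor values (linear interpolation); otherwise no limit is reported.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    surv = np.asarray(survivor_values, dtype=float)
    nonsurv = np.asarray(nonsurvivor_values, dtype=float)
    p = mw_one_sided_greater(nonsurv, surv)
    limit = float(np.percentile(surv, 100 * (1 - alpha))) if p < alpha else None
    return SafeLimitResult(
        stratum=stratum, variable=variable, window_h=window_h, alpha=alpha,
        p_value=p, limit=limit, n_survivors=len(surv), n_nonsurvivors=len(nonsurv),
    )


def limits_by_stratum(
    twa_features: pd.DataFrame,
    admissions: pd.DataFrame,
    alpha: float = 0.05,
    variables: tuple[str, ...] = ("twa_mp", "twa_mp_ibw"),
    windows_h: tuple[int, ...] = (24, 48),
) -> list[SafeLimitResult]:
    """One SafeLimitResult per stratum × variable × window, plus pooled "all".

    ``twa_features`` is the per-admission per-window aggregate table;
    ``admissions`` must carry ``admission_id``, ``icu_mortality`` and
    ``hypoxemia_group``. Strata with fewer than 2 admissions in either
    mortality arm are skipped with a warning.
    """
    merged = twa_features.merge(
        admissions[["admission_id", "icu_mortality", "hypoxemia_group"]],
        on="admission_id",
    )
    results = []
    strata = ["all", *[g for g in merged["hypoxemia_group"].dropna().unique()]]
    for stratum in strata:
        sub = merged if stratum == "all" else merged[merged["hypoxemia_group"] == stratum]
        for wh in windows_h:
            subw = sub[sub["window_h"] == wh]
            for var in variables:
                vals = subw[[var, "icu_mortality"]].dropna()
                surv = vals.loc[vals["icu_mortality"] == 0, var].to_numpy()
                nonsurv = vals.loc[vals["icu_mortality"] == 1, var].to_numpy()
                if len(surv) < 2 or len(nonsurv) < 2:
                    warnings.warn(
                        f"stratum {stratum!r} ({var}, {wh} h): <2 per arm, skipped",
                        stacklevel=2,
                    )
                    continue
                results.append(
                    safe_upper_limit(surv, nonsurv, alpha, stratum=stratum,
                                     variable=var, window_h=wh)
                )
    return results


def to_absolute_mp(limit_per_kg: float, ibw_kg: float) -> float:
    """Convert a per-kg MP limit (J/min/kg) to absolute J/min at a given IBW,
    reported to 2 decimals."""
    if limit_per_kg < 0 or ibw_kg < 0:
        raise ValueError("inputs must be non-negative")
    return round(limit_per_kg * ibw_kg, 2)


@dataclass
class SurvivalReport:
    stratum: str
    hazard_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    km: pd.DataFrame | None  # columns: time, survival, group
    degenerate: bool = False
    note: str = ""


def survival_by_limit(
    twa_features: pd.DataFrame,
    admissions: pd.DataFrame,
    limits: list[SafeLimitResult],
    covariates: list[str] | None = None,
    variable: str = "twa_mp_ibw",
    window_h: int = 48,
    horizon_days: float = 90.0,
) -> list[SurvivalReport]:
    """Cox PH fit on the above/below-limit indicator per stratum, with
    optional covariate adjustment, plus Kaplan-Meier curves to 90 days.

    ``admissions`` must carry ``followup_days`` and ``event`` (1 = died).
    Strata without a present limit are omitted with a note. Follow-up is
    administratively censored at ``horizon_days``.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter

    covariates = covariates or []
    feats = twa_features[twa_features["window_h"] == window_h]
    merged = feats.merge(admissions, on="admission_id")
    reports = []
    for res in limits:
        if res.variable != variable or res.window_h != window_h:
            continue
        if res.limit is None:
            reports.append(SurvivalReport(res.stratum, None, None, None, None,
                                          None, note="no limit identified"))
            continue
        sub = merged if res.stratum == "all" else merged[
            merged["hypoxemia_group"] == res.stratum
        ]
        df = sub[[variable, "followup_days", "event", *covariates]].dropna().copy()
        df["above_limit"] = (df[variable] > res.limit).astype(int)
        over = df["followup_days"] > horizon_days
        df.loc[over, "event"] = 0
        df.loc[over, "followup_days"] = horizon_days
        df = df.drop(columns=[variable])

        km_parts = []
        kmf = KaplanMeierFitter()
        for g, gdf in df.groupby("above_limit"):
            kmf.fit(gdf["followup_days"], gdf["event"], label=str(g))
            part = kmf.survival_function_.reset_index()
            part.columns = ["time", "survival"]
            part["group"] = "above" if g else "below"
            km_parts.append(part)
        km = pd.concat(km_parts, ignore_index=True)

        if df["above_limit"].nunique() < 2 or df["event"].sum() == 0:
            reports.append(SurvivalReport(res.stratum, None, None, None, None,
                                          km, degenerate=True,
                                          note="degenerate grouping or no events"))
            continue
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="followup_days", event_col="event")
            row = cph.summary.loc["above_limit"]
            reports.append(SurvivalReport(
                res.stratum,
                float(row["exp(coef)"]),
                float(row["exp(coef) lower 95%"]),
                float(row["exp(coef) upper 95%"]),
                float(row["p"]),
                km,
            ))
        except Exception as exc:  # noqa: BLE001 - degenerate fits surface as a flag
            reports.append(SurvivalReport(res.stratum, None, None, None, None,
                                          km, degenerate=True, note=str(exc)))
    return reports
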