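"""Univariate case/control statistics and percentile-threshold odds ratios.

The battery applied per score and per cohort: two-sample
Kolmogorov-Smirnov on score distributions, Mann-Whitney for group
location shifts, Fisher's exact test for 2x2 contingency tables, a
Pearson correlation screen of scores against clinical covariates, and
logistic-regression odds ratios for samples above a score percentile
versus everyone below, optionally adjusted for age, sex, and BMI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Continuous Table-1-style covariates with their units.
CONTINUOUS_COVARIATES = {
    "age": "years",
    "bmi": "kg/m^2",
    "total_chol": "mmol/L",
    "hdl": "mmol/L",
    "ldl": "mmol/L",
    "triglycerides": "mmol/L",
    "glycaemia": "mmol/L",
    "pas": "mmHg",
    "pad": "mmHg",
}
BINARY_COVARIATES = ("sex", "diabetes", "hypertension", "hypercholesterolemia")

#: Ordinal smoking encoding used by the correlation screen (switchable).
SMOKING_ORDINAL = {"no": 0.0, "former": 1.0, "yes": 2.0}


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    test: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class PercentileORResult:
    """Adjusted odds ratio for scoring above the q-th percentile.

    The reference group is every sample scoring at or below the cut.  The
    CI is Wald on the log-odds scale, hence asymmetric on the OR scale.
    """

    pgs_id: str
    q: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_above: int
    n_below: int
    n_analyzed: int
    adjusted_for: list[str] = field(default_factory=list)
    separation: bool = False
    separation_direction: int = 0

    def to_row(self) -> dict:
        return {
            "pgs_id": self.pgs_id,
            "q": self.q,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_above": self.n_above,
            "n_below": self.n_below,
            "adjusted_for": ",".join(self.adjusted_for),
            "separation": self.separation,
        }


def _check_groups(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return a, b


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test on score distributions.

    Uses the exact null distribution when ``n_a * n_b <= 10_000`` and the
    asymptotic Kolmogorov distribution otherwise.
    """
    a, b = _check_groups(a, b)
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=a.size,
        n_b=b.size,
        test="ks",
    )


def mann_whitney(a, b) -> TestResult:
    """Mann-Whitney U (midrank ties, two-sided normal approximation with
    tie and continuity correction). Statistic is U for group ``a``."""
    a, b = _check_groups(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        test="mann_whitney",
    )


def fisher_exact(table) -> TestResult:
    """Fisher's exact test, two-sided by the probability-mass rule.

    The two-sided p-value sums hypergeometric probabilities of all tables
    with the observed margins no more probable than the observed one; the
    statistic is the sample cross-product odds ratio (ad/bc).
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("a margin of the 2x2 table is zero")
    res = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(table[0].sum()),
        n_b=int(table[1].sum()),
        test="fisher",
    )


def encode_covariate(cohort: pd.DataFrame, name: str) -> pd.Series:
    """Numeric encoding of a cohort covariate.

    Binary yes/no and M/F columns map to 0/1; smoking maps to the ordered
    scale no=0, former=1, yes=2; continuous columns pass through as float.
    """
    col = cohort[name]
    if name == "sex":
        return col.map({"F": 0.0, "M": 1.0})
    if name == "smoking":
        return col.map(SMOKING_ORDINAL)
    if name == "status":
        return col.map({"control": 0.0, "case": 1.0})
    if col.dtype == object:
        return col.map({"no": 0.0, "yes": 1.0})
    return col.astype(float)


def correlation_screen(
    scores: np.ndarray,
    cohort: pd.DataFrame,
    threshold: float = 0.75,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r of a score against each covariate, flagging |r| > threshold.

    Computed on pairwise-complete observations; covariates with fewer than
    3 paired values or zero variance get ``r = NaN``.  The flag uses a
    strict inequality on |r|.
    """
    if covariates is None:
        covariates = [
            c
            for c in (*CONTINUOUS_COVARIATES, *BINARY_COVARIATES, "smoking")
            if c in cohort.columns
        ]
    scores = np.asarray(scores, dtype=float)
    rows = []
    for name in covariates:
        x = encode_covariate(cohort, name).to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(scores))
        r = np.nan
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(scores[ok]) > 0:
            r = float(stats.pearsonr(scores[ok], x[ok]).statistic)
        rows.append(
            {
                "covariate": name,
                "r": r,
                "n": int(ok.sum()),
                "flagged": bool(not np.isnan(r) and abs(r) > threshold),
            }
        )
    return pd.DataFrame(rows)


def percentile_or(
    scores: np.ndarray,
    cohort: pd.DataFrame,
    q: float = 0.8,
    adjust: list[str] | None = None,
    pgs_id: str = "",
) -> PercentileORResult:
    """Odds ratio of case status above vs below a score percentile.

    Fits ``status ~ 1(percentile > q) + adjust`` by maximum-likelihood
    logistic regression; OR and 95% CI are Wald on the log scale.  The
    default adjustment set in the pipeline is age, sex, and BMI.  Missing
    covariates are handled complete-case with the analyzed n logged.
    Complete separation of the indicator is flagged and the OR reported as
    non-estimable (inf or 0 by direction) rather than fitted.
    """
    from pgseval.scoring import score_percentiles

    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    adjust = list(adjust or [])
    scores = np.asarray(scores, dtype=float)
    pct = score_percentiles(scores)
    indicator = (pct > q).astype(float)
    status = encode_covariate(cohort, "status").to_numpy(dtype=float)

    cols = {name: encode_covariate(cohort, name).to_numpy(dtype=float) for name in adjust}
    ok = ~np.isnan(status) & ~np.isnan(scores)
    for x in cols.values():
        ok &= ~np.isnan(x)
    if ok.sum() < len(status):
        logger.info(
            "percentile_or: complete-case analysis on %d/%d samples",
            ok.sum(), len(status),
        )
    y = status[ok]
    ind = indicator[ok]
    n_above = int(ind.sum())
    n_below = int((1 - ind).sum())

    # 2x2 sanity check for separation of the threshold indicator
    cells = np.array(
        [
            [np.sum((ind == 1) & (y == 1)), np.sum((ind == 1) & (y == 0))],
            [np.sum((ind == 0) & (y == 1)), np.sum((ind == 0) & (y == 0))],
        ]
    )
    if np.any(cells == 0):
        direction = 1 if (cells[0, 1] == 0 or cells[1, 0] == 0) else -1
        logger.warning(
            "WARN percentile_or: complete separation at q=%g (cells %s)",
            q, cells.tolist(),
        )
        return PercentileORResult(
            pgs_id=pgs_id, q=q,
            odds_ratio=np.inf if direction > 0 else 0.0,
            ci_low=np.nan, ci_high=np.nan,
            n_above=n_above, n_below=n_below, n_analyzed=int(ok.sum()),
            adjusted_for=adjust, separation=True,
            separation_direction=direction,
        )

    X = np.column_stack([np.ones(ok.sum()), ind] + [cols[c][ok] for c in adjust])
    model = sm.Logit(y, X)
    fit = model.fit(disp=0, maxiter=100, method="newton", tol=1e-10)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"percentile_or: IRLS did not converge at q={q}; "
            f"params={fit.params.tolist()}"
        )
    beta = fit.params[1]
    se = np.sqrt(fit.cov_params()[1, 1])
    return PercentileORResult(
        pgs_id=pgs_id, q=q,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        n_above=n_above, n_below=n_below, n_analyzed=int(ok.sum()),
        adjusted_for=adjust,
    )


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Case/control summary table with per-variable tests.

    Continuous variables: mean (SD) per group and a Mann-Whitney p-value.
    Binary variables: yes-counts per group and a Fisher exact p-value.
    Smoking: current-vs-never and former-vs-never Fisher tests with
    never-smokers as the reference level.  Reports the analyzed n per
    variable so per-column missingness is visible.
    """
    is_case = cohort["status"] == "case"
    cases = cohort[is_case]
    controls = cohort[~is_case]
    rows = []

    for name, unit in CONTINUOUS_COVARIATES.items():
        if name not in cohort.columns:
            continue
        a = cases[name].dropna().to_numpy(dtype=float)
        b = controls[name].dropna().to_numpy(dtype=float)
        res = mann_whitney(a, b) if a.size and b.size else None
        rows.append(
            {
                "variable": name,
                "unit": unit,
                "cases": f"{a.mean():.2f} (±{a.std(ddof=1):.2f})",
                "controls": f"{b.mean():.2f} (±{b.std(ddof=1):.2f})",
                "p_value": res.p_value if res else np.nan,
                "test": "mann_whitney",
                "n_analyzed": a.size + b.size,
            }
        )

    for name in BINARY_COVARIATES:
        if name not in cohort.columns:
            continue
        enc_case = encode_covariate(cases, name).dropna()
        enc_ctrl = encode_covariate(controls, name).dropna()
        table = np.array(
            [
                [(enc_case == 1).sum(), (enc_case == 0).sum()],
                [(enc_ctrl == 1).sum(), (enc_ctrl == 0).sum()],
            ]
        )
        p = np.nan
        if not (np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0)):
            p = fisher_exact(table).p_value
        level = "M" if name == "sex" else "yes"
        rows.append(
            {
                "variable": f"{name}={level}",
                "unit": "",
                "cases": str(int(table[0, 0])),
                "controls": str(int(table[1, 0])),
                "p_value": p,
                "test": "fisher",
                "n_analyzed": int(table.sum()),
            }
        )

    if "smoking" in cohort.columns:
        for level in ("yes", "former"):
            table = np.array(
                [
                    [
                        (cases["smoking"] == level).sum(),
                        (controls["smoking"] == level).sum(),
                    ],
                    [
                        (cases["smoking"] == "no").sum(),
                        (controls["smoking"] == "no").sum(),
                    ],
                ]
            )
            p = np.nan
            if not (
                np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0)
            ):
                p = fisher_exact(table).p_value
            rows.append(
                {
                    "variable": f"smoking={level} vs no",
                    "unit": "",
                    "cases": str(int(table[0, 0])),
                    "controls": str(int(table[0, 1])),
                    "p_value": p,
                    "test": "fisher",
                    "n_analyzed": int(table.sum()),
                }
            )

    return pd.DataFrame(rows)
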