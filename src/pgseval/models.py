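"""Predictive-model protocol: split, CV, Boruta, logistic models, DeLong.

The evaluation pipeline mirrors a common clinical-risk workflow: an 80/20
stratified split, logistic models fitted on the training side with a
10-fold cross-validation repeated 10 times for internal sanity, covariate
selection by the Boruta shadow-feature algorithm, and discrimination
measured on the held-out 20% as the area under the ROC curve with a
DeLong-variance confidence interval.  Nested models (covariates-only vs
covariates+PGS) are compared on the same test samples with DeLong's
paired test for correlated AUCs.

The AUC here is the Mann-Whitney formulation (probability that a random
case outscores a random control, half-credit for ties); its variance and
the paired-test covariance come from per-sample placement values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Protocol parameters for the three-model evaluation suite."""

    features: list[str]
    outcome: str = "status"
    seed: int = 0
    split_fraction: float = 0.8
    cv_folds: int = 10
    cv_repeats: int = 10
    boruta_iterations: int = 50
    boruta_alpha: float = 0.05
    select_features: bool = True

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("features must be non-empty")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (coefficients, Wald covariance)."""

    params: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool
    separation: bool
    feature_names: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted case probability for a design matrix (no intercept
        column; it is prepended internally)."""
        Xc = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        return 1.0 / (1.0 + np.exp(-Xc @ self.params))


@dataclass
class BorutaResult:
    decisions: dict[str, str]          # feature -> confirmed/rejected/tentative
    hit_counts: dict[str, int]
    n_iterations: int

    @property
    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "confirmed"]


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    roc_points: np.ndarray             # (fpr, tpr) staircase
    n_cases: int
    n_controls: int
    variance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    z_statistic: float
    p_value: float


@dataclass
class ModelComparison:
    """Per-PGS row of the three-model suite."""

    pgs_id: str
    model: str                         # covariates / pgs_only / combined
    features: list[str]
    test_auc: RocResult
    cv_auc_mean: float
    delong_vs_covariates: DeLongResult | None = None
    test_probs: np.ndarray | None = None


@dataclass
class EvaluationResult:
    """Assembled output of the model suite: one ModelComparison per
    (PGS, model) plus the shared split and selected covariates."""

    comparisons: list[ModelComparison]
    train_ids: list[str]
    test_ids: list[str]
    selected_covariates: list[str]
    boruta: BorutaResult | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "pgs_id": c.pgs_id,
                    "model": c.model,
                    "features": ",".join(c.features),
                    "test_auc": c.test_auc.auc,
                    "ci_low": c.test_auc.ci_low,
                    "ci_high": c.test_auc.ci_high,
                    "cv_auc_mean": c.cv_auc_mean,
                    "delong_p_vs_covariates": (
                        c.delong_vs_covariates.p_value
                        if c.delong_vs_covariates
                        else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Split


def stratified_split(
    cohort: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic stratified train/test split on case/control status.

    Case and control proportions are preserved within one sample.  Returns
    (train sample_ids, test sample_ids).
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for status in ("case", "control"):
        ids = cohort.loc[cohort["status"] == status, "sample_id"].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"need at least 2 {status}s to split")
        perm = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return train, test


# ---------------------------------------------------------------------------
# Logistic regression


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    maxiter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS).

    ``X`` has no intercept column (prepended internally).  Constant
    columns and rank deficiency raise with the offending column names;
    quasi-separation (diverging coefficients) is flagged, not raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const:
        raise ValueError(f"constant feature column(s): {const}")
    Xc = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(f"rank-deficient design matrix; columns {names}")

    with np.errstate(all="ignore"):
        try:
            fit = sm.Logit(y, Xc).fit(
                disp=0, maxiter=maxiter, method="newton", tol=1e-10,
                warn_convergence=False,
            )
        except np.linalg.LinAlgError:
            # singular Hessian under (quasi-)separation; a gradient method
            # still yields finite, flaggable estimates
            fit = sm.Logit(y, Xc).fit(
                disp=0, maxiter=200, method="bfgs", warn_convergence=False
            )
    params = np.asarray(fit.params)
    separation = bool(np.any(np.abs(params[1:]) > 30))
    converged = bool(fit.mle_retvals.get("converged", True))
    if separation:
        logger.warning("WARN fit_logistic: separation suspected (|beta| > 30)")
    if not converged and not separation:
        raise RuntimeError(
            f"logistic fit did not converge after {maxiter} iterations"
        )
    return LogisticFit(
        params=params,
        cov=np.asarray(fit.cov_params()),
        llf=float(fit.llf),
        converged=converged,
        separation=separation,
        feature_names=["intercept"] + list(names),
    )


# ---------------------------------------------------------------------------
# Boruta shadow-feature selection


def boruta_select(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_iterations: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 5,
    feature_names: list[str] | None = None,
) -> BorutaResult:
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends a row-shuffled shadow copy of every feature,
    fits a random-forest importance learner, and records a *hit* for each
    real feature whose importance exceeds the best shadow importance.
    After ``n_iterations``, each feature is tested two-sided against the
    Binomial(n, 1/2) null with Holm step-down at level ``alpha``:
    significantly more hits than chance confirms it, significantly fewer
    rejects it, anything else stays tentative.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    if n_iterations < 20:
        raise ValueError("n_iterations must be >= 20")
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    rng = np.random.default_rng(seed)
    y = np.asarray(y)

    hits = np.zeros(X.shape[1], dtype=int)
    for it in range(n_iterations):
        shadow = X.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        Xa = np.hstack([X, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(Xa, y)
        imp = forest.feature_importances_
        best_shadow = imp[X.shape[1]:].max()
        hits += imp[: X.shape[1]] > best_shadow

    # two-sided binomial tests with Holm step-down
    p_greater = stats.binom.sf(hits - 1, n_iterations, 0.5)
    p_less = stats.binom.cdf(hits, n_iterations, 0.5)
    p_two = np.minimum(1.0, 2 * np.minimum(p_greater, p_less))
    order = np.argsort(p_two)
    decisions = {name: "tentative" for name in names}
    m = len(names)
    for rank, j in enumerate(order):
        if p_two[j] >= alpha / (m - rank):
            break
        side = "confirmed" if p_greater[j] <= p_less[j] else "rejected"
        decisions[names[j]] = side
    return BorutaResult(
        decisions=decisions,
        hit_counts={name: int(h) for name, h in zip(names, hits)},
        n_iterations=n_iterations,
    )


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[
    np.ndarray, np.ndarray, float
]:
    """Midrank placement values and the AUC they average to.

    ``v10[i]`` is the fraction of controls the i-th case outscores (ties
    half-credit); ``v01[j]`` the fraction of cases the j-th control is
    outscored by.  ``mean(v10) = mean(v01) = AUC``.
    """
    m, n = len(cases), len(controls)
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)  # midranks
    rank_cases = stats.rankdata(cases)
    rank_controls = stats.rankdata(controls)
    v10 = (ranks[:m] - rank_cases) / n
    v01 = 1.0 - (ranks[m:] - rank_controls) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def roc_auc(outcome: np.ndarray, score: np.ndarray) -> RocResult:
    """AUC with a DeLong-variance 95% CI and the ROC staircase.

    ``outcome`` is binary (1 = case).  The AUC equals normalized
    Mann-Whitney U with half-credit for ties; the variance is DeLong's
    placement-value estimator and the CI is Wald, clipped to [0, 1].
    """
    outcome = np.asarray(outcome)
    score = np.asarray(score, dtype=float)
    cases = score[outcome == 1]
    controls = score[outcome == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    v10, v01, auc = _placements(cases, controls)
    var = 0.0
    if cases.size > 1:
        var += np.var(v10, ddof=1) / cases.size
    if controls.size > 1:
        var += np.var(v01, ddof=1) / controls.size
    half = 1.96 * np.sqrt(var)
    fpr, tpr, _ = roc_curve(outcome, score)
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        roc_points=np.column_stack([fpr, tpr]),
        n_cases=int(cases.size),
        n_controls=int(controls.size),
        variance=float(var),
    )


def delong_paired_test(
    outcome: np.ndarray, score_a: np.ndarray, score_b: np.ndarray
) -> DeLongResult:
    """DeLong's paired test for two correlated AUCs on the same samples.

    Placement values per sample per score give a 2x2 covariance of the AUC
    estimates; ``z = (auc_a - auc_b) / sqrt(var_a + var_b - 2 cov)`` with a
    two-sided normal p-value.  Identical scores (zero variance of the
    difference) return z = 0, p = 1 by convention.
    """
    outcome = np.asarray(outcome)
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if not (len(a) == len(b) == len(outcome)):
        raise ValueError("scores must be paired on the same samples")
    is_case = outcome == 1
    if is_case.all() or (~is_case).all():
        raise ValueError("need both cases and controls")
    v10a, v01a, auc_a = _placements(a[is_case], a[~is_case])
    v10b, v01b, auc_b = _placements(b[is_case], b[~is_case])
    m, n = int(is_case.sum()), int((~is_case).sum())
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        return DeLongResult(auc_a, auc_b, delta, 0.0, 1.0)
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, delta, float(z), float(p))


# ---------------------------------------------------------------------------
# Model suite


def _cv_auc(
    X: np.ndarray, y: np.ndarray, folds: int, repeats: int, seed: int
) -> float:
    """Mean held-fold AUC over repeated stratified k-fold CV."""
    aucs = []
    for rep in range(repeats):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=seed + rep
        )
        for tr, va in splitter.split(X, y):
            if len(np.unique(y[va])) < 2:
                continue
            try:
                fit = fit_logistic(X[tr], y[tr])
            except (ValueError, RuntimeError):
                continue
            aucs.append(roc_auc(y[va], fit.predict(X[va])).auc)
    return float(np.mean(aucs)) if aucs else np.nan


def evaluate_model_suite(
    cohort: pd.DataFrame,
    scores: dict[str, np.ndarray],
    spec: ModelSpec,
) -> EvaluationResult:
    """Run the three-model comparison for every PGS.

    Per score: (i) a covariates-only model on the Boruta-selected (or
    spec-listed) covariates, (ii) a PGS-only model, (iii) the combined
    covariates+PGS model — each trained on the stratified 80% split with
    repeated CV logged for internal sanity, and scored on the held-out
    20% (test AUC with DeLong CI).  Models (i) and (iii) are compared
    with DeLong's paired test on the shared test samples.

    ``scores`` maps pgs_id to per-sample standardized scores aligned with
    ``cohort`` rows.
    """
    from pgseval.cohort_stats import encode_covariate

    cohort = cohort.reset_index(drop=True)
    y_all = encode_covariate(cohort, "status").to_numpy(dtype=float)
    cov_mat = np.column_stack(
        [encode_covariate(cohort, c).to_numpy(dtype=float) for c in spec.features]
    )
    ok = ~np.isnan(y_all) & ~np.isnan(cov_mat).any(axis=1)
    for s in scores.values():
        ok &= ~np.isnan(np.asarray(s, dtype=float))
    cohort = cohort.loc[ok].reset_index(drop=True)
    y_all = y_all[ok]
    scores = {k: np.asarray(v, dtype=float)[ok] for k, v in scores.items()}

    train_ids, test_ids = stratified_split(
        cohort, fraction=spec.split_fraction, seed=spec.seed
    )
    id_pos = {sid: i for i, sid in enumerate(cohort["sample_id"])}
    tr = np.array([id_pos[s] for s in train_ids])
    te = np.array([id_pos[s] for s in test_ids])

    cov_frame = pd.DataFrame(
        {c: encode_covariate(cohort, c).to_numpy(dtype=float) for c in spec.features}
    )
    selected = list(spec.features)
    boruta = None
    if spec.select_features and len(spec.features) >= 2:
        boruta = boruta_select(
            cov_frame.iloc[tr],
            y_all[tr],
            n_iterations=spec.boruta_iterations,
            alpha=spec.boruta_alpha,
            seed=spec.seed + 1,
        )
        if boruta.confirmed:
            selected = boruta.confirmed
        else:
            logger.warning(
                "WARN evaluate_model_suite: Boruta confirmed no covariates; "
                "using the full covariate list"
            )

    X_cov = cov_frame[selected].to_numpy(dtype=float)
    y_tr, y_te = y_all[tr], y_all[te]

    fit_cov = fit_logistic(X_cov[tr], y_tr, feature_names=selected)
    probs_cov_te = fit_cov.predict(X_cov[te])
    roc_cov = roc_auc(y_te, probs_cov_te)
    cv_cov = _cv_auc(
        X_cov[tr], y_tr, spec.cv_folds, spec.cv_repeats, spec.seed + 2
    )

    comparisons: list[ModelComparison] = []
    for pgs_id, z in scores.items():
        comparisons.append(
            ModelComparison(
                pgs_id=pgs_id,
                model="covariates",
                features=selected,
                test_auc=roc_cov,
                cv_auc_mean=cv_cov,
                test_probs=probs_cov_te,
            )
        )
        X_pgs = z[:, None]
        fit_pgs = fit_logistic(X_pgs[tr], y_tr, feature_names=[pgs_id])
        probs_pgs = fit_pgs.predict(X_pgs[te])
        comparisons.append(
            ModelComparison(
                pgs_id=pgs_id,
                model="pgs_only",
                features=[pgs_id],
                test_auc=roc_auc(y_te, probs_pgs),
                cv_auc_mean=_cv_auc(
                    X_pgs[tr], y_tr, spec.cv_folds, spec.cv_repeats,
                    spec.seed + 3,
                ),
                test_probs=probs_pgs,
            )
        )
        X_comb = np.column_stack([X_cov, z])
        fit_comb = fit_logistic(
            X_comb[tr], y_tr, feature_names=selected + [pgs_id]
        )
        probs_comb = fit_comb.predict(X_comb[te])
        comparisons.append(
            ModelComparison(
                pgs_id=pgs_id,
                model="combined",
                features=selected + [pgs_id],
                test_auc=roc_auc(y_te, probs_comb),
                cv_auc_mean=_cv_auc(
                    X_comb[tr], y_tr, spec.cv_folds, spec.cv_repeats,
                    spec.seed + 4,
                ),
                delong_vs_covariates=delong_paired_test(
                    y_te, probs_comb, probs_cov_te
                ),
                test_probs=probs_comb,
            )
        )

    return EvaluationResult(
        comparisons=comparisons,
        train_ids=train_ids,
        test_ids=test_ids,
        selected_covariates=selected,
        boruta=boruta,
    )
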