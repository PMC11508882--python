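"""Score analyses stratified by population subgroup.

Given per-sample scores for one or more PGS and per-sample group labels
(geographic macro-area, sex, case/control status), these operations build
the three Kolmogorov-Smirnov matrices — all unordered area pairs,
female-vs-male within each area, cases-vs-controls within each area —
plus per-area AUCs.  Raw p-values are reported by default; optional
Bonferroni or Benjamini-Hochberg adjustment is available and clearly
labelled in the output.

Groups below the minimum size (2 per side) are skipped with a warning
rather than failing the whole matrix.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from pgseval.cohort_stats import ks_two_sample
from pgseval.models import RocResult, roc_auc

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 2


def _adjust(frame: pd.DataFrame, method: str | None) -> pd.DataFrame:
    if method is None:
        return frame
    mapping = {"bonferroni": "bonferroni", "bh": "fdr_bh"}
    ok = frame["p_value"].notna()
    adjusted = frame["p_value"].copy()
    if ok.sum():
        adjusted.loc[ok] = multipletests(
            frame.loc[ok, "p_value"], method=mapping[method]
        )[1]
    frame = frame.copy()
    frame[f"p_{method}"] = adjusted
    return frame


def pairwise_area_ks(
    scores: dict[str, np.ndarray],
    areas: np.ndarray,
    adjust_method: str | None = None,
) -> pd.DataFrame:
    """KS test for every unordered area pair and every PGS.

    Returns a long table (pair x pgs_id) with statistic, raw p-value, and
    the two group sizes; C(k, 2) pairs for k areas with >= 2 samples.
    """
    areas = np.asarray(areas)
    labels = [
        a for a in pd.unique(areas) if (areas == a).sum() >= MIN_GROUP_SIZE
    ]
    skipped = set(pd.unique(areas)) - set(labels)
    for a in skipped:
        logger.warning("WARN pairwise_area_ks: singleton area %r skipped", a)
    if len(labels) < 2:
        raise ValueError("need at least 2 areas with >= 2 samples")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        ia, ib = areas == a, areas == b
        for pgs_id, s in scores.items():
            s = np.asarray(s, dtype=float)
            res = ks_two_sample(s[ia], s[ib])
            rows.append(
                {
                    "comparison": f"{a} vs. {b}",
                    "pgs_id": pgs_id,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                }
            )
    return _adjust(pd.DataFrame(rows), adjust_method)


def _within_area_ks(
    scores: dict[str, np.ndarray],
    group_a: np.ndarray,
    group_b: np.ndarray,
    areas: np.ndarray,
    label: str,
    adjust_method: str | None,
) -> pd.DataFrame:
    rows = []
    for area in pd.unique(areas):
        in_area = areas == area
        ia = in_area & group_a
        ib = in_area & group_b
        if ia.sum() < MIN_GROUP_SIZE or ib.sum() < MIN_GROUP_SIZE:
            logger.warning(
                "WARN %s: area %r skipped (%d vs %d samples)",
                label, area, ia.sum(), ib.sum(),
            )
            continue
        for pgs_id, s in scores.items():
            s = np.asarray(s, dtype=float)
            res = ks_two_sample(s[ia], s[ib])
            rows.append(
                {
                    "area": area,
                    "pgs_id": pgs_id,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                }
            )
    return _adjust(pd.DataFrame(rows), adjust_method)


def sex_within_area_ks(
    scores: dict[str, np.ndarray],
    sex: np.ndarray,
    areas: np.ndarray,
    adjust_method: str | None = None,
) -> pd.DataFrame:
    """Female-vs-male KS per area per PGS (n_a = females, n_b = males)."""
    sex = np.asarray(sex)
    return _within_area_ks(
        scores, sex == "F", sex == "M", np.asarray(areas),
        "sex_within_area_ks", adjust_method,
    )


def case_control_within_area(
    scores: dict[str, np.ndarray],
    status: np.ndarray,
    areas: np.ndarray,
    adjust_method: str | None = None,
) -> pd.DataFrame:
    """Cases-vs-controls KS per area per PGS (n_a = cases, n_b = controls)."""
    status = np.asarray(status)
    return _within_area_ks(
        scores, status == "case", status == "control", np.asarray(areas),
        "case_control_within_area", adjust_method,
    )


def auc_by_area(
    scores: dict[str, np.ndarray],
    status: np.ndarray,
    areas: np.ndarray,
) -> pd.DataFrame:
    """Per-area, per-PGS AUC with DeLong CI; single-class areas skipped.

    Small areas yield wide CIs — the CI width shrinks with area size under
    a fixed generative model.
    """
    status = np.asarray(status)
    areas = np.asarray(areas)
    rows = []
    for area in pd.unique(areas):
        in_area = areas == area
        y = (status[in_area] == "case").astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            logger.warning(
                "WARN auc_by_area: area %r skipped (single class)", area
            )
            continue
        for pgs_id, s in scores.items():
            roc: RocResult = roc_auc(y, np.asarray(s, dtype=float)[in_area])
            rows.append(
                {
                    "area": area,
                    "pgs_id": pgs_id,
                    "auc": roc.auc,
                    "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high,
                    "n_cases": roc.n_cases,
                    "n_controls": roc.n_controls,
                }
            )
    return pd.DataFrame(rows)
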