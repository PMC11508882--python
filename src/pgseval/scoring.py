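"""Per-sample polygenic score computation, standardization, percentiles.

A polygenic score is the weighted sum of effect-allele dosages over the
harmonized variants: ``score_j = sum_i w_i * d*_ij`` where ``d*`` is the
orientation-resolved dosage (ALT dosage ``d`` when the effect allele is
ALT, ``2 - d`` when it is REF).  Standardized scores use the sample
(n - 1) standard deviation over a declared reference set, a convention
that matters for any odds-ratio-per-SD reporting.  Percentiles are
empirical ``rank / n`` with ties sharing their maximum rank, so "above
the q-th percentile" means ``percentile > q``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from pgseval.pgs_io import GenotypeMatrix, HarmonizationReport, MatchTable


@dataclass
class ScoreResult:
    """Raw, standardized, and percentile scores for one PGS."""

    pgs_id: str
    sample_ids: list[str]
    raw: np.ndarray
    z: np.ndarray
    percentile: np.ndarray
    report: HarmonizationReport | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "pgs_id": self.pgs_id,
                "raw": self.raw,
                "z": self.z,
                "percentile": self.percentile,
            }
        )


def compute_prs(
    match: MatchTable,
    geno: GenotypeMatrix,
    missing_policy: Literal["mean_impute", "omit"] = "mean_impute",
) -> np.ndarray:
    """Weighted effect-allele dosage sum per sample.

    Missing dosages are replaced by the variant's sample-mean effect dosage
    (``mean_impute``, keeps scores comparable across samples with unequal
    missingness) or their term is omitted (``omit``).
    """
    if len(match) == 0:
        raise ValueError("empty match table: score undefined")
    d = geno.dosage[:, match.geno_index].astype(float)
    # orientation transform: effect-allele dosage
    d = np.where(match.effect_is_alt[None, :], d, 2.0 - d)
    if np.any(np.isnan(d)):
        if missing_policy == "mean_impute":
            col_mean = np.nanmean(
                np.where(np.isnan(d).all(axis=0), 0.0, d), axis=0
            )
            col_mean = np.nan_to_num(col_mean)
            d = np.where(np.isnan(d), col_mean[None, :], d)
        elif missing_policy == "omit":
            d = np.nan_to_num(d, nan=0.0)
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return d @ match.weight


def standardize_scores(
    raw: np.ndarray, reference: np.ndarray | Sequence[int] | None = None
) -> np.ndarray:
    """Center and scale by the reference subset's mean and sample SD.

    ``reference`` is an index or boolean mask into ``raw`` (default: all
    samples).  Raises on fewer than two reference samples or zero variance.
    """
    raw = np.asarray(raw, dtype=float)
    ref = raw if reference is None else raw[np.asarray(reference)]
    if ref.size < 2:
        raise ValueError("reference set must contain at least 2 samples")
    mu = ref.mean()
    sd = ref.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("reference scores have zero variance")
    return (raw - mu) / sd


def score_percentiles(raw: np.ndarray) -> np.ndarray:
    """Empirical percentile ``rank / n`` with max-rank ties, in (0, 1]."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("no samples")
    return rankdata(raw, method="max") / raw.size


def score_samples(
    pgs_id: str,
    match: MatchTable,
    geno: GenotypeMatrix,
    report: HarmonizationReport | None = None,
    missing_policy: Literal["mean_impute", "omit"] = "mean_impute",
    reference: np.ndarray | None = None,
) -> ScoreResult:
    """Convenience chain: raw scores, z-standardization, percentiles."""
    raw = compute_prs(match, geno, missing_policy=missing_policy)
    return ScoreResult(
        pgs_id=pgs_id,
        sample_ids=list(geno.sample_ids),
        raw=raw,
        z=standardize_scores(raw, reference),
        percentile=score_percentiles(raw),
        report=report,
    )
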