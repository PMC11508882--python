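"""Structured-population cohort simulator with known ground truth.

Genotypes follow the Balding-Nichols model: each variant has an ancestral
allele frequency ``p`` drawn uniformly, and each population subgroup
("macro-area") draws its own frequency from
``Beta(p (1 - F) / F, (1 - p)(1 - F) / F)`` where ``F`` is the area's
divergence parameter (an F_ST); genotypes are then Hardy-Weinberg
``Binomial(2, p_area)`` draws.  Disease status comes from a logistic
liability: ``logit P(case) = b0 + log(or_per_sd) * z_true + sum_c b_c *
(c - mean_c)`` where ``z_true`` is the standardized true polygenic score
and ``c`` ranges over clinical covariates; cases and controls are then
sampled to a target case fraction, emulating a balanced case-control
design.

Scoring-file emission subsamples the causal variants at configured
coverage, perturbs weights, strand-complements a fraction of records, and
plants a few irreconcilable-allele records, so that harmonization has
real work to do.  Every generated quantity (true weights, per-area
frequencies, liability) is kept in a :class:`TruthRecord` for recovery
tests.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pgseval.pgs_io import (
    GenotypeMatrix,
    ScoreVariant,
    ScoringFile,
    write_scoring_file,
)
from pgseval.scoring import standardize_scores

_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default macro-area sample sizes (the four-area structured design).
DEFAULT_AREAS = {"North": 2030, "Center": 420, "South": 744, "Sardinia": 68}

#: Default per-area divergence from the common ancestral pool.  Within-
#: peninsula differentiation is small; the island is more diverged.
DEFAULT_FST = {"North": 0.002, "Center": 0.003, "South": 0.005, "Sardinia": 0.015}

#: Covariate generative distributions: mean, sd (continuous), or
#: category probabilities.  Loosely shaped like an early-onset MI cohort;
#: scaffolding, not claims about any real population.
COVARIATE_DISTRIBUTIONS = {
    "age": (40.0, 4.9),
    "bmi": (26.0, 3.8),
    "total_chol": (5.5, 1.2),
    "hdl": (1.2, 0.3),
    "ldl": (3.5, 1.2),
    "triglycerides": (1.7, 1.0),
    "glycaemia": (5.5, 1.5),
    "pas": (128.0, 18.0),
    "pad": (82.0, 13.0),
}
SMOKING_PROBS = {"yes": 0.30, "no": 0.25, "former": 0.45}
P_MALE = 0.885

#: Default liability coefficients (per unit of the *centered* covariate).
DEFAULT_COVARIATE_EFFECTS = {
    "bmi": 0.08,
    "hdl": -0.9,
    "ldl": 0.35,
    "triglycerides": 0.25,
    "glycaemia": 0.15,
    "smoking": 0.35,
    "diabetes": 1.2,
    "hypertension": 0.7,
}

#: Default emitted scoring files: (pgs_id, n_variants, target coverage,
#: strand-flip fraction, mismatch fraction, identifier dialect).
DEFAULT_SCORE_SPECS = (
    ("PGSSIM001", 27, 0.815, 0.10, 0.00, "rsid"),
    ("PGSSIM002", 164, 0.774, 0.10, 0.02, "chrpos"),
    ("PGSSIM003", 300, 0.974, 0.15, 0.01, "chrpos"),
    ("PGSSIM004", 400, 0.995, 0.10, 0.00, "chrpos"),
    ("PGSSIM005", 450, 0.995, 0.05, 0.01, "rsid"),
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_samples: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_AREAS)
    )
    fst: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FST))
    n_variants: int = 1000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    causal_fraction: float = 0.2
    or_per_sd: float = 2.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    beta0: float = 0.0
    case_fraction: float = 0.5
    missing_rate: float = 0.0
    n_low_rsq: int = 10
    n_pcs: int = 4
    score_specs: tuple = DEFAULT_SCORE_SPECS
    weight_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_samples.values()):
            raise ValueError("n_samples: counts must be positive")
        # areas without an explicit divergence get a small default
        for area in self.n_samples:
            self.fst.setdefault(area, 0.01)
        for area, f in self.fst.items():
            if not 0 < f < 1:
                raise ValueError(f"fst[{area!r}]={f} must be in (0, 1)")
        if self.or_per_sd <= 0:
            raise ValueError("or_per_sd must be > 0")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0 < lo < hi < 1:
            raise ValueError("ancestral_freq_range must satisfy 0 < low < high < 1")

    @property
    def areas(self) -> list[str]:
        return list(self.n_samples)

    def to_json(self) -> str:
        d = asdict(self)
        d["score_specs"] = [list(s) for s in self.score_specs]
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class TruthRecord:
    """Everything the generator knows that the pipeline must recover."""

    weights: np.ndarray                 # per-variant true weight (0 = null)
    ancestral_freq: np.ndarray
    area_freq: dict[str, np.ndarray]
    beta0: float
    beta_g: float                       # log(or_per_sd)
    covariate_effects: dict[str, float]
    liability: np.ndarray | None = None      # realized logit per emitted sample
    true_raw: np.ndarray | None = None       # raw true score per emitted sample
    true_z: np.ndarray | None = None
    kept_index: np.ndarray | None = None     # emitted rows -> simulated rows

    def to_json_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "ancestral_freq": self.ancestral_freq.tolist(),
            "area_freq": {k: v.tolist() for k, v in self.area_freq.items()},
            "beta0": self.beta0,
            "beta_g": self.beta_g,
            "covariate_effects": self.covariate_effects,
            "liability": None if self.liability is None else self.liability.tolist(),
            "true_z": None if self.true_z is None else self.true_z.tolist(),
        }


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent deterministic streams fanned out from the run seed
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, TruthRecord, np.ndarray]:
    """Draw Balding-Nichols structured genotypes.

    Returns the genotype matrix (integer dosages stored as float), the
    truth record (true weights and per-area frequencies), and the
    per-sample area labels, ordered area-block-wise.
    """
    rng = _rng(config.seed, 1)
    m = config.n_variants
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=m)

    # transition-biased substitution spectrum (~70% A<->G / C<->T), so
    # strand-ambiguous A/T and C/G pairs occur at a realistic ~15% rate
    transitions = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    transversions = [
        ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"),
        ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
    ]
    pairs = np.array(transitions + transversions)
    probs = np.r_[np.full(4, 0.70 / 4), np.full(8, 0.30 / 8)]
    drawn = pairs[rng.choice(len(pairs), p=probs, size=m)]
    ref, alt = drawn[:, 0], drawn[:, 1]

    area_freq: dict[str, np.ndarray] = {}
    blocks = []
    labels = []
    for area, n in config.n_samples.items():
        f = config.fst[area]
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_area = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        area_freq[area] = p_area
        blocks.append(rng.binomial(2, p_area, size=(n, m)).astype(float))
        labels.extend([area] * n)
    dosage = np.vstack(blocks)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    # causal variants are kept off strand-ambiguous sites so the true score
    # is exactly representable by a scoring file under the drop policy
    unambiguous = np.flatnonzero(
        ~np.isin(
            np.char.add(ref, alt), ["AT", "TA", "CG", "GC"]
        )
    )
    n_causal = max(1, int(round(config.causal_fraction * m)))
    n_causal = min(n_causal, len(unambiguous))
    causal = rng.choice(unambiguous, size=n_causal, replace=False)
    weights = np.zeros(m)
    weights[causal] = rng.normal(0.0, 1.0, size=n_causal)

    meta = pd.DataFrame(
        {
            "id": [f"rs{900000 + i}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "ref_allele": ref,
            "alt_allele": alt,
            "rsq": np.round(rng.uniform(0.61, 1.0, size=m), 4),
        }
    )
    meta["call_rate"] = 1.0 - np.isnan(dosage).mean(axis=0)
    geno = GenotypeMatrix(
        sample_ids=[f"S{i:05d}" for i in range(dosage.shape[0])],
        variant_meta=meta,
        dosage=dosage,
    )
    truth = TruthRecord(
        weights=weights,
        ancestral_freq=p_anc,
        area_freq=area_freq,
        beta0=config.beta0,
        beta_g=float(np.log(config.or_per_sd)),
        covariate_effects=dict(config.covariate_effects),
    )
    return geno, truth, np.asarray(labels)


def true_scores(geno: GenotypeMatrix, truth: TruthRecord) -> np.ndarray:
    """Raw true polygenic score of every sample (missing dosages as 0)."""
    d = np.nan_to_num(geno.dosage, nan=0.0)
    return d @ truth.weights


def simulate_phenotypes(
    geno: GenotypeMatrix,
    truth: TruthRecord,
    config: SimulationConfig,
    areas: np.ndarray,
) -> pd.DataFrame:
    """Draw covariates and case/control status from the liability model.

    Returns the emitted cohort table (one row per kept sample, balanced to
    ``case_fraction``).  The kept-row index into the genotype matrix is
    recorded in ``truth.kept_index``; restrict the genotypes with
    ``geno.take_samples``-style indexing before downstream use.
    Raises when the requested case fraction is unattainable at the
    realized population prevalence (advising a ``beta0`` adjustment).
    """
    rng = _rng(config.seed, 2)
    n = geno.n_samples
    cols: dict[str, np.ndarray] = {}
    for name, (mu, sd) in COVARIATE_DISTRIBUTIONS.items():
        cols[name] = rng.normal(mu, sd, size=n)
    cols["triglycerides"] = np.clip(cols["triglycerides"], 0.3, None)
    cols["glycaemia"] = np.clip(cols["glycaemia"], 2.5, None)
    sex = np.where(rng.random(n) < P_MALE, "M", "F")
    smoking = rng.choice(
        list(SMOKING_PROBS), p=list(SMOKING_PROBS.values()), size=n
    )
    # comorbidities linked to age and BMI
    logit_dia = -7.0 + 0.05 * (cols["age"] - 40) + 0.12 * (cols["bmi"] - 26)
    diabetes = rng.random(n) < 1 / (1 + np.exp(-logit_dia))
    logit_hyp = -2.2 + 0.05 * (cols["age"] - 40) + 0.10 * (cols["bmi"] - 26)
    hypertension = rng.random(n) < 1 / (1 + np.exp(-logit_hyp))
    hyperchol = cols["total_chol"] > 6.2

    raw = true_scores(geno, truth)
    z = standardize_scores(raw)
    encoded = dict(
        cols,
        smoking=np.vectorize(
            {"no": 0.0, "former": 1.0, "yes": 2.0}.get
        )(smoking).astype(float),
        diabetes=diabetes.astype(float),
        hypertension=hypertension.astype(float),
        sex=(sex == "M").astype(float),
    )
    logit = np.full(n, config.beta0) + truth.beta_g * z
    for name, beta in config.covariate_effects.items():
        x = encoded[name]
        logit += beta * (x - x.mean())
    prob = 1 / (1 + np.exp(-logit))
    status = rng.random(n) < prob

    n_cases, n_controls = int(status.sum()), int((~status).sum())
    cf = config.case_fraction
    n_emit = int(min(n_cases / cf, n_controls / (1 - cf)))
    if n_emit < 0.5 * n or n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"case_fraction {cf} unattainable: realized prevalence "
            f"{n_cases / n:.3f}; adjust beta0 (currently {config.beta0})"
        )
    want_cases = int(round(cf * n_emit))
    case_idx = rng.permutation(np.flatnonzero(status))[:want_cases]
    ctrl_idx = rng.permutation(np.flatnonzero(~status))[: n_emit - want_cases]
    kept = np.sort(np.concatenate([case_idx, ctrl_idx]))

    cohort = pd.DataFrame(
        {
            "sample_id": np.asarray(geno.sample_ids)[kept],
            "status": np.where(status[kept], "case", "control"),
            "age": np.round(cols["age"][kept], 1),
            "sex": sex[kept],
            "bmi": np.round(cols["bmi"][kept], 2),
            "total_chol": np.round(cols["total_chol"][kept], 2),
            "hdl": np.round(np.clip(cols["hdl"][kept], 0.3, None), 2),
            "ldl": np.round(np.clip(cols["ldl"][kept], 0.5, None), 2),
            "triglycerides": np.round(cols["triglycerides"][kept], 2),
            "glycaemia": np.round(cols["glycaemia"][kept], 2),
            "diabetes": np.where(diabetes[kept], "yes", "no"),
            "hypertension": np.where(hypertension[kept], "yes", "no"),
            "hypercholesterolemia": np.where(hyperchol[kept], "yes", "no"),
            "smoking": smoking[kept],
            "pas": np.round(cols["pas"][kept], 0),
            "pad": np.round(cols["pad"][kept], 0),
            "macro_area": np.asarray(areas)[kept],
        }
    )
    if config.n_pcs > 0:
        cohort = pd.concat([cohort, _principal_components(geno, kept, config.n_pcs)], axis=1)

    truth.liability = logit[kept]
    truth.true_raw = raw[kept]
    truth.true_z = z[kept]
    truth.kept_index = kept
    return cohort


def _principal_components(
    geno: GenotypeMatrix, kept: np.ndarray, n_pcs: int
) -> pd.DataFrame:
    """First genetic PCs of the emitted samples (covariate plumbing only)."""
    d = np.nan_to_num(geno.dosage[kept], nan=0.0)
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    d = d / np.where(sd > 0, sd, 1.0)
    k = min(n_pcs, min(d.shape) - 1)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    return pd.DataFrame(
        {f"pc{i + 1}": np.round(pcs[:, i], 6) for i in range(k)}
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Genotypes + phenotypes, restricted to the emitted cohort rows."""
    geno, truth, areas = simulate_genotypes(config)
    cohort = simulate_phenotypes(geno, truth, config, areas)
    kept = truth.kept_index
    geno_kept = GenotypeMatrix(
        sample_ids=list(np.asarray(geno.sample_ids)[kept]),
        variant_meta=geno.variant_meta,
        dosage=geno.dosage[kept],
    )
    return geno_kept, cohort, truth


# ---------------------------------------------------------------------------
# Scoring-file emission


def _is_ambiguous_pair(a: str, b: str) -> bool:
    return {a, b} in _AMBIGUOUS_PAIRS


def simulate_scoring_files(
    config: SimulationConfig,
    truth: TruthRecord,
    geno: GenotypeMatrix,
) -> list[ScoringFile]:
    """Emit partially overlapping scoring files of very different sizes.

    Each file targets a harmonization coverage: matched rows are sampled
    from the genotype panel (causal variants first, so signal is carried),
    a configured fraction of them is written strand-complemented, a few
    rows get deliberately irreconcilable alleles, and the remainder are
    absent positions.  Weights are the true weights plus Gaussian noise.
    """
    rng = _rng(config.seed, 3)
    meta = geno.variant_meta
    ref = meta["ref_allele"].to_numpy(dtype=str)
    alt = meta["alt_allele"].to_numpy(dtype=str)
    pos = meta["pos"].to_numpy()
    unambiguous = np.array(
        [not _is_ambiguous_pair(r, a) for r, a in zip(ref, alt)]
    )
    causal = np.flatnonzero((truth.weights != 0) & unambiguous)
    null_pool = np.flatnonzero((truth.weights == 0) & unambiguous)
    max_pos = int(pos.max())

    files: list[ScoringFile] = []
    for pgs_id, n_var, coverage, flip_frac, mism_frac, dialect in config.score_specs:
        n_matched = int(round(coverage * n_var))
        # cap at the matchable panel; the shortfall becomes absent rows
        n_matched = min(n_matched, len(causal) + len(null_pool))
        n_mismatch = min(
            int(round(mism_frac * n_var)), n_var - n_matched
        )
        n_absent = n_var - n_matched - n_mismatch
        n_from_causal = min(len(causal), n_matched)
        chosen = list(rng.choice(causal, size=n_from_causal, replace=False))
        if n_matched > n_from_causal:
            chosen += list(
                rng.choice(
                    null_pool, size=n_matched - n_from_causal, replace=False
                )
            )
        variants: list[ScoreVariant] = []
        flip_mask = rng.random(n_matched) < flip_frac
        for k, j in enumerate(chosen):
            effect, other = alt[j], ref[j]
            if flip_mask[k]:
                effect = effect.translate(_COMPLEMENT)
                other = other.translate(_COMPLEMENT)
            w = truth.weights[j] + rng.normal(0, config.weight_noise_sd)
            ident = (
                meta["id"].iloc[j]
                if dialect == "rsid"
                else f"1:{int(pos[j])}"
            )
            variants.append(
                ScoreVariant(
                    identifier=ident,
                    chrom="1",
                    pos=int(pos[j]),
                    effect_allele=effect,
                    other_allele=other,
                    weight=float(w),
                )
            )
        # deliberately irreconcilable alleles at genotyped positions
        # (kept off the matched positions so no row triple repeats)
        candidates = np.setdiff1d(np.flatnonzero(unambiguous), np.asarray(chosen))
        n_mismatch = min(n_mismatch, len(candidates))
        mism_pool = rng.choice(candidates, size=n_mismatch, replace=False)
        for j in mism_pool:
            present = {ref[j], alt[j], ref[j].translate(_COMPLEMENT),
                       alt[j].translate(_COMPLEMENT)}
            wrong = [b for b in "ACGT" if b not in present]
            if len(wrong) < 2:
                wrong = (wrong + [b for b in "ACGT" if b != ref[j]])[:2]
            variants.append(
                ScoreVariant(
                    identifier=f"1:{int(pos[j])}:bad",
                    chrom="1",
                    pos=int(pos[j]),
                    effect_allele=wrong[0],
                    other_allele=wrong[1],
                    weight=float(rng.normal(0, config.weight_noise_sd)),
                )
            )
        # positions never genotyped
        for k in range(n_absent):
            p_abs = max_pos + 100 * (k + 1) + 1
            variants.append(
                ScoreVariant(
                    identifier=f"2:{p_abs}",
                    chrom="2",
                    pos=p_abs,
                    effect_allele="A",
                    other_allele="G",
                    weight=float(rng.normal(0, config.weight_noise_sd)),
                )
            )
        files.append(
            ScoringFile(
                pgs_id=pgs_id,
                trait_label="simulated coronary artery disease risk",
                variants=variants,
                declared_n_variants=len(variants),
                metadata={"genome_build": "simulated", "dialect": dialect},
            )
        )
    return files


def simulate_structure_score(
    truth: TruthRecord,
    geno: GenotypeMatrix,
    area_a: str,
    area_b: str,
    n_variants: int = 100,
    pgs_id: str = "PGSSIM_STRUCT",
) -> ScoringFile:
    """A non-causal, frequency-divergent score.

    Selects the ``n_variants`` null (zero true weight) variants with the
    largest allele-frequency divergence between two areas and aligns the
    weight signs with the divergence — the drift-confounded construction
    that makes a score's distribution differ between subgroups even when
    it carries no disease signal.
    """
    meta = geno.variant_meta
    ref = meta["ref_allele"].to_numpy(dtype=str)
    alt = meta["alt_allele"].to_numpy(dtype=str)
    unambiguous = np.array(
        [not _is_ambiguous_pair(r, a) for r, a in zip(ref, alt)]
    )
    null_pool = np.flatnonzero((truth.weights == 0) & unambiguous)
    div = truth.area_freq[area_a] - truth.area_freq[area_b]
    order = null_pool[np.argsort(-np.abs(div[null_pool]))]
    chosen = order[:n_variants]
    variants = [
        ScoreVariant(
            identifier=f"1:{int(meta['pos'].iloc[j])}",
            chrom="1",
            pos=int(meta["pos"].iloc[j]),
            effect_allele=alt[j],
            other_allele=ref[j],
            weight=float(np.sign(div[j]) or 1.0),
        )
        for j in chosen
    ]
    return ScoringFile(
        pgs_id=pgs_id,
        trait_label="structure-confounded null score",
        variants=variants,
        declared_n_variants=len(variants),
    )


# ---------------------------------------------------------------------------
# Fixture emission


def _write_vcf(
    path: Path,
    geno: GenotypeMatrix,
    rng: np.random.Generator,
    n_low_rsq: int,
) -> None:
    """Plain-text VCF with DS+GT per sample and an Rsq INFO field.

    ``n_low_rsq`` decoy variants with Rsq < 0.6 and random dosages are
    appended so the imputation-quality filter has something to remove.
    """
    meta = geno.variant_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=Rsq,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write("##contig=<ID=1>\n##contig=<ID=2>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )

        def row(chrom, p, vid, r, a, rsq, dosages):
            fields = []
            for d in dosages:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    k = int(round(d))
                    gt = ("0/0", "0/1", "1/1")[k] if d == k and 0 <= k <= 2 else "./."
                    fields.append(f"{gt}:{d:g}")
            fh.write(
                f"{chrom}\t{p}\t{vid}\t{r}\t{a}\t.\tPASS\tRsq={rsq:g}\t"
                "GT:DS\t" + "\t".join(fields) + "\n"
            )

        for j in range(geno.n_variants):
            row(
                meta["chrom"].iloc[j],
                int(meta["pos"].iloc[j]),
                meta["id"].iloc[j],
                meta["ref_allele"].iloc[j],
                meta["alt_allele"].iloc[j],
                float(meta["rsq"].iloc[j]),
                geno.dosage[:, j],
            )
        max_pos = int(meta["pos"].max())
        for k in range(n_low_rsq):
            row(
                "1",
                max_pos + 7 * (k + 1),
                f"lowRsq{k}",
                "A",
                "C",
                float(np.round(rng.uniform(0.2, 0.59), 4)),
                rng.binomial(2, 0.5, size=geno.n_samples).astype(float),
            )


def write_fixture_set(
    outdir: str | Path, config: SimulationConfig
) -> dict[str, str]:
    """Emit a full fixture set: VCF, scoring files, covariate TSV, truth
    JSON, and a manifest recording the seed and config hash.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno, cohort, truth = simulate_cohort(config)

    vcf_path = outdir / "cohort.vcf"
    _write_vcf(vcf_path, geno, _rng(config.seed, 4), config.n_low_rsq)

    cov_path = outdir / "covariates.tsv"
    cohort.to_csv(cov_path, sep="\t", index=False)

    score_paths = []
    for score in simulate_scoring_files(config, truth, geno):
        sp = outdir / f"{score.pgs_id}.txt"
        write_scoring_file(score, sp, dialect="chrpos")
        score_paths.append(sp.name)

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.to_json_dict(), fh)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.to_json()),
        "files": {
            "vcf": vcf_path.name,
            "covariates": cov_path.name,
            "scoring_files": score_paths,
            "truth": truth_path.name,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
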