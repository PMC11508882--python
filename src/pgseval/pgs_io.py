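"""Reading, writing, and allele harmonization of scoring files and genotypes.

Scoring files follow the PGS Catalog dialect: ``#key=value`` metadata lines,
then a tab-separated table with at least an effect-allele column and an
effect-weight column, keyed either by rsID or by chromosome/position.
Genotypes come from VCF with per-sample dosages (``DS``, preferred) or hard
genotypes (``GT``), and an optional per-variant imputation-quality ``Rsq``
INFO field.

Harmonization reconciles each scoring-file variant with the cohort's
ref/alt alleles at the same (chrom, pos): a *direct* match when the score's
{effect, other} alleles equal {ref, alt}, a *flip* match when their strand
complements do, a drop for strand-ambiguous (A/T, C/G) pairs, a *mismatch*
when the alleles are irreconcilable, and *absent* when the position is not
genotyped.  The outcome is a match table that records, per matched variant,
which genotype column it scores, its weight, and whether the effect allele
is the VCF ALT allele (score the ALT dosage ``d``) or the REF allele
(score ``2 - d``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Column aliases accepted for each logical scoring-file field.
_COLUMN_ALIASES = {
    "identifier": ("rsID", "rsid", "variant_id", "ID"),
    "chrom": ("chr_name", "chrom", "chromosome", "chr"),
    "pos": ("chr_position", "pos", "position", "chr_pos"),
    "effect_allele": ("effect_allele", "A1", "allele1"),
    "other_allele": ("other_allele", "reference_allele", "A2", "allele2"),
    "weight": ("effect_weight", "weight", "beta"),
}


class ScoringFileFormatError(ValueError):
    """A scoring file violates the catalog dialect."""


@dataclass(frozen=True)
class ScoreVariant:
    """One weighted variant of a polygenic score.

    ``identifier`` is an rsID or a ``chr:pos`` label; ``weight`` is the
    per-effect-allele-copy effect weight (dimensionless).  ``other_allele``
    may be ``None`` in single-allele dialects.
    """

    identifier: str
    chrom: str | None
    pos: int | None
    effect_allele: str
    other_allele: str | None
    weight: float

    def __post_init__(self) -> None:
        if not self.effect_allele or set(self.effect_allele) - VALID_BASES:
            raise ValueError(
                f"effect allele {self.effect_allele!r} is not an ACGT string"
            )
        if self.other_allele is not None and (
            not self.other_allele or set(self.other_allele) - VALID_BASES
        ):
            raise ValueError(
                f"other allele {self.other_allele!r} is not an ACGT string"
            )
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"position {self.pos} must be >= 1 (1-based)")
        if not np.isfinite(self.weight):
            raise ValueError(f"weight {self.weight!r} is not finite")

    def complemented(self) -> "ScoreVariant":
        """Return the variant with both alleles strand-complemented."""
        return ScoreVariant(
            identifier=self.identifier,
            chrom=self.chrom,
            pos=self.pos,
            effect_allele=self.effect_allele.translate(_COMPLEMENT),
            other_allele=(
                None
                if self.other_allele is None
                else self.other_allele.translate(_COMPLEMENT)
            ),
            weight=self.weight,
        )


@dataclass
class ScoringFile:
    """An ordered collection of score variants plus catalog metadata."""

    pgs_id: str
    trait_label: str
    variants: list[ScoreVariant]
    declared_n_variants: int | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.declared_n_variants is not None
            and self.declared_n_variants != len(self.variants)
        ):
            raise ScoringFileFormatError(
                f"{self.pgs_id}: header declares {self.declared_n_variants} "
                f"variants but {len(self.variants)} rows are present"
            )
        keyed = [
            (v.chrom, v.pos, v.effect_allele)
            for v in self.variants
            if v.chrom is not None and v.pos is not None
        ]
        if len(keyed) != len(set(keyed)):
            raise ScoringFileFormatError(
                f"{self.pgs_id}: duplicate (chrom, pos, effect_allele) rows"
            )

    def __len__(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "identifier": [v.identifier for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "weight": [v.weight for v in self.variants],
            }
        )


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-allele dosage matrix with variant metadata.

    ``dosage`` holds ALT-allele dosages in [0, 2] with ``NaN`` for missing
    calls.  ``variant_meta`` is a DataFrame with one row per column of
    ``dosage``: chrom, pos, ref_allele, alt_allele, rsq, call_rate, and an
    optional id column.
    """

    sample_ids: list[str]
    variant_meta: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("sample IDs are not unique")
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variant_meta):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_meta)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_meta)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Sub-matrix restricted to the given variant columns."""
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            variant_meta=self.variant_meta.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )


@dataclass
class HarmonizationReport:
    """Per-score accounting of how scoring-file variants matched genotypes.

    The five counts partition ``n_score_variants``; ``coverage`` is the
    matched fraction (direct + flip) / total.
    """

    pgs_id: str
    n_score_variants: int
    n_matched_direct: int
    n_matched_flip: int
    n_ambiguous_dropped: int
    n_mismatch_dropped: int
    n_absent: int

    def __post_init__(self) -> None:
        parts = (
            self.n_matched_direct
            + self.n_matched_flip
            + self.n_ambiguous_dropped
            + self.n_mismatch_dropped
            + self.n_absent
        )
        if min(
            self.n_matched_direct, self.n_matched_flip,
            self.n_ambiguous_dropped, self.n_mismatch_dropped, self.n_absent,
        ) < 0 or parts != self.n_score_variants:
            raise ValueError(
                f"harmonization counts do not partition {self.n_score_variants}"
            )

    @property
    def n_matched(self) -> int:
        return self.n_matched_direct + self.n_matched_flip

    @property
    def coverage(self) -> float:
        if self.n_score_variants == 0:
            return 0.0
        return self.n_matched / self.n_score_variants

    def to_row(self) -> dict:
        return {
            "pgs_id": self.pgs_id,
            "n_score_variants": self.n_score_variants,
            "n_matched_direct": self.n_matched_direct,
            "n_matched_flip": self.n_matched_flip,
            "n_ambiguous_dropped": self.n_ambiguous_dropped,
            "n_mismatch_dropped": self.n_mismatch_dropped,
            "n_absent": self.n_absent,
            "coverage": self.coverage,
        }

    def __str__(self) -> str:  # human-readable one-liner
        return (
            f"{self.pgs_id}: {self.n_score_variants} variants | "
            f"direct {self.n_matched_direct}, flip {self.n_matched_flip}, "
            f"ambiguous {self.n_ambiguous_dropped}, "
            f"mismatch {self.n_mismatch_dropped}, absent {self.n_absent} | "
            f"coverage {self.coverage:.1%}"
        )


@dataclass
class MatchTable:
    """Matched score variants resolved against genotype columns.

    ``geno_index[i]`` is the genotype column scored by weight ``weight[i]``;
    ``effect_is_alt[i]`` selects the dosage transform (ALT dosage ``d`` when
    True, ``2 - d`` when False).
    """

    geno_index: np.ndarray
    weight: np.ndarray
    effect_is_alt: np.ndarray

    def __post_init__(self) -> None:
        if not (
            len(self.geno_index) == len(self.weight) == len(self.effect_is_alt)
        ):
            raise ValueError("match table columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.geno_index)


def write_harmonization_reports(
    reports: Sequence[HarmonizationReport], path: str | Path
) -> None:
    """Write one TSV row per score, mirroring the report fields."""
    pd.DataFrame([r.to_row() for r in reports]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Scoring-file I/O


def _resolve_columns(header: Sequence[str]) -> dict[str, str]:
    resolved = {}
    for logical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in header:
                resolved[logical] = alias
                break
    return resolved


def read_scoring_file(path: str | Path) -> ScoringFile:
    """Parse a PGS Catalog-dialect scoring file.

    ``#``-prefixed lines are ``key=value`` metadata; the first non-comment
    line is a column header.  Both rsID-keyed and chr/pos-keyed dialects are
    recognized and unknown columns are ignored.  Raises
    :class:`ScoringFileFormatError` when the effect-allele or effect-weight
    column is missing, when a weight fails to parse (the row index is
    reported), or when a declared ``variants_number`` disagrees with the
    actual row count.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            if header is None:
                header = line.split("\t")
                if len(header) == 1:  # tolerate whitespace-delimited fixtures
                    header = line.split()
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            rows.append(fields)
    if header is None:
        raise ScoringFileFormatError(f"{path}: no header row found")

    cols = _resolve_columns(header)
    if "effect_allele" not in cols:
        raise ScoringFileFormatError(f"{path}: no effect-allele column")
    if "weight" not in cols:
        raise ScoringFileFormatError(f"{path}: no effect-weight column")
    idx = {name: header.index(col) for name, col in cols.items()}

    variants: list[ScoreVariant] = []
    for i, fields in enumerate(rows):
        def get(name: str) -> str | None:
            j = idx.get(name)
            if j is None or j >= len(fields):
                return None
            value = fields[j].strip()
            return value or None

        raw_weight = get("weight")
        try:
            weight = float(raw_weight)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ScoringFileFormatError(
                f"{path}: row {i + 1}: non-numeric effect weight {raw_weight!r}"
            ) from None
        chrom = get("chrom")
        raw_pos = get("pos")
        pos = int(raw_pos) if raw_pos is not None else None
        identifier = get("identifier") or (
            f"{chrom}:{pos}" if chrom is not None and pos is not None else f"row{i + 1}"
        )
        variants.append(
            ScoreVariant(
                identifier=identifier,
                chrom=chrom,
                pos=pos,
                effect_allele=(get("effect_allele") or "").upper(),
                other_allele=(
                    get("other_allele").upper() if get("other_allele") else None
                ),
                weight=weight,
            )
        )

    declared = None
    if "variants_number" in metadata:
        declared = int(metadata["variants_number"])
    pgs_id = metadata.get("pgs_id", path.stem)
    trait = metadata.get("trait_reported", metadata.get("trait_mapped", ""))
    return ScoringFile(
        pgs_id=pgs_id,
        trait_label=trait,
        variants=variants,
        declared_n_variants=declared,
        metadata=metadata,
    )


def write_scoring_file(
    score: ScoringFile,
    path: str | Path,
    dialect: Literal["chrpos", "rsid"] = "chrpos",
) -> None:
    """Write a scoring file in the catalog dialect read by
    :func:`read_scoring_file`.

    ``chrpos`` emits chromosome/position columns alongside the identifier;
    ``rsid`` emits only the identifier column (position-free dialect).
    """
    with open(path, "w") as fh:
        fh.write(f"#pgs_id={score.pgs_id}\n")
        if score.trait_label:
            fh.write(f"#trait_reported={score.trait_label}\n")
        fh.write(f"#variants_number={len(score.variants)}\n")
        for key, value in score.metadata.items():
            if key in ("pgs_id", "trait_reported", "variants_number"):
                continue
            fh.write(f"#{key}={value}\n")
        if dialect == "chrpos":
            fh.write(
                "rsID\tchr_name\tchr_position\teffect_allele\tother_allele"
                "\teffect_weight\n"
            )
            for v in score.variants:
                fh.write(
                    f"{v.identifier}\t{v.chrom or ''}\t{v.pos or ''}\t"
                    f"{v.effect_allele}\t{v.other_allele or ''}\t"
                    f"{v.weight!r}\n"
                )
        else:
            fh.write("rsID\teffect_allele\tother_allele\teffect_weight\n")
            for v in score.variants:
                fh.write(
                    f"{v.identifier}\t{v.effect_allele}\t"
                    f"{v.other_allele or ''}\t{v.weight!r}\n"
                )


# ---------------------------------------------------------------------------
# Genotype I/O and QC


def read_genotypes(
    path: str | Path,
    rsq_min: float = 0.6,
    rsq_field: str = "Rsq",
) -> GenotypeMatrix:
    """Load a VCF into a dosage matrix, filtering on imputation quality.

    Per-sample ``DS`` dosages are preferred; ``GT`` is converted to an
    ALT-allele count otherwise.  Variants with ``Rsq < rsq_min`` (taken from
    INFO; absent Rsq passes) and multi-allelic records are excluded, with
    the excluded counts logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    meta_rows = []
    dosage_cols = []
    n_multi = n_lowrsq = 0
    saw_fields = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        rsq = rec.INFO.get(rsq_field)
        if rsq is not None and float(rsq) < rsq_min:
            n_lowrsq += 1
            continue
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            saw_fields.add("DS")
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gts = rec.genotype.array()  # rows: [allele_a, allele_b, phased]
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            col = alleles.sum(axis=1)
            if not np.all(np.isnan(col)):
                saw_fields.add("GT")
        dosage_cols.append(col)
        meta_rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref_allele": rec.REF.upper(),
                "alt_allele": rec.ALT[0].upper(),
                "rsq": float(rsq) if rsq is not None else 1.0,
            }
        )
    if dosage_cols and not saw_fields:
        raise ValueError(f"{path}: records carry neither DS nor GT fields")
    if n_multi:
        logger.info("%s: excluded %d multi-allelic records", path, n_multi)
    if n_lowrsq:
        logger.info(
            "%s: excluded %d variants with Rsq < %g", path, n_lowrsq, rsq_min
        )

    dosage = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(samples), 0))
    )
    meta = pd.DataFrame(
        meta_rows,
        columns=["id", "chrom", "pos", "ref_allele", "alt_allele", "rsq"],
    )
    meta["call_rate"] = (
        1.0 - np.isnan(dosage).mean(axis=0)
        if dosage.shape[1]
        else np.array([])
    )
    return GenotypeMatrix(sample_ids=samples, variant_meta=meta, dosage=dosage)


def variant_qc(
    geno: GenotypeMatrix, call_rate_min: float = 0.95
) -> GenotypeMatrix:
    """Drop variants whose call rate falls below ``call_rate_min``."""
    if not 0 <= call_rate_min <= 1:
        raise ValueError("call_rate_min must be in [0, 1]")
    call_rate = 1.0 - np.isnan(geno.dosage).mean(axis=0)
    keep = np.flatnonzero(call_rate >= call_rate_min)
    n_removed = geno.n_variants - len(keep)
    if n_removed:
        logger.warning(
            "WARN variant_qc: removed %d/%d variants with call rate < %g",
            n_removed, geno.n_variants, call_rate_min,
        )
    if len(keep) == 0:
        logger.warning("WARN variant_qc: no variants passed the call-rate filter")
    return geno.take_variants(keep)


# ---------------------------------------------------------------------------
# Harmonization


def _is_ambiguous(effect: str, other: str | None) -> bool:
    # A/T and C/G pairs cannot be assigned a strand from alleles alone.
    if other is None:
        return False
    return {effect, other} in ({"A", "T"}, {"C", "G"})


def harmonize(
    score: ScoringFile,
    geno: GenotypeMatrix,
    ambiguous_policy: Literal["drop", "keep"] = "drop",
) -> tuple[MatchTable, HarmonizationReport]:
    """Reconcile scoring-file alleles with genotype ref/alt at (chrom, pos).

    Returns the match table and a report whose five counts (direct, flip,
    ambiguous-dropped, mismatch, absent) partition the score's variants.
    Under ``ambiguous_policy='keep'``, strand-ambiguous pairs are matched
    as-written (direct-orientation reading) instead of dropped.
    Raises ``ValueError`` on duplicate genotype positions, naming the first.
    """
    meta = geno.variant_meta
    keys = list(zip(meta["chrom"].astype(str), meta["pos"].astype(int)))
    lookup: dict[tuple[str, int], int] = {}
    for j, key in enumerate(keys):
        if key in lookup:
            raise ValueError(
                f"duplicate genotype position {key[0]}:{key[1]}"
            )
        lookup[key] = j

    ref = meta["ref_allele"].astype(str).str.upper().to_numpy()
    alt = meta["alt_allele"].astype(str).str.upper().to_numpy()

    idx_list: list[int] = []
    weight_list: list[float] = []
    orient_list: list[bool] = []
    n_direct = n_flip = n_ambig = n_mismatch = n_absent = 0

    for v in score.variants:
        if v.chrom is None or v.pos is None:
            n_absent += 1
            continue
        j = lookup.get((str(v.chrom), int(v.pos)))
        if j is None:
            n_absent += 1
            continue
        if _is_ambiguous(v.effect_allele, v.other_allele) and (
            ambiguous_policy == "drop"
        ):
            n_ambig += 1
            continue
        orientation = _orient(v.effect_allele, v.other_allele, ref[j], alt[j])
        if orientation is None:
            flipped = v.complemented()
            orientation = _orient(
                flipped.effect_allele, flipped.other_allele, ref[j], alt[j]
            )
            if orientation is None:
                n_mismatch += 1
                continue
            n_flip += 1
        else:
            n_direct += 1
        idx_list.append(j)
        weight_list.append(v.weight)
        orient_list.append(orientation)

    table = MatchTable(
        geno_index=np.asarray(idx_list, dtype=int),
        weight=np.asarray(weight_list, dtype=float),
        effect_is_alt=np.asarray(orient_list, dtype=bool),
    )
    report = HarmonizationReport(
        pgs_id=score.pgs_id,
        n_score_variants=len(score.variants),
        n_matched_direct=n_direct,
        n_matched_flip=n_flip,
        n_ambiguous_dropped=n_ambig,
        n_mismatch_dropped=n_mismatch,
        n_absent=n_absent,
    )
    return table, report


def _orient(
    effect: str, other: str | None, ref: str, alt: str
) -> bool | None:
    """Direct-orientation reading: True if effect==ALT, False if effect==REF,
    None if the alleles do not reconcile without a strand flip."""
    if other is not None:
        if effect == alt and other == ref:
            return True
        if effect == ref and other == alt:
            return False
        return None
    if effect == alt:
        return True
    if effect == ref:
        return False
    return None
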