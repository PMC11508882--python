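"""Scoring-file parsing, VCF loading, QC, and allele harmonization."""

import numpy as np
import pytest

from pgseval.pgs_io import (
    GenotypeMatrix,
    HarmonizationReport,
    ScoringFile,
    ScoringFileFormatError,
    ScoreVariant,
    harmonize,
    read_genotypes,
    read_scoring_file,
    variant_qc,
    write_scoring_file,
)

import pandas as pd


def make_geno(ref_alt, chrom="1", start_pos=100, dosage=None, n_samples=3):
    """Genotype matrix with one variant per (ref, alt) pair."""
    m = len(ref_alt)
    if dosage is None:
        dosage = np.tile([0.0, 1.0, 2.0], (m, 1)).T[:n_samples]
    meta = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(m)],
            "chrom": chrom,
            "pos": [start_pos + 100 * i for i in range(m)],
            "ref_allele": [r for r, _ in ref_alt],
            "alt_allele": [a for _, a in ref_alt],
            "rsq": 1.0,
        }
    )
    meta["call_rate"] = 1.0 - np.isnan(dosage).mean(axis=0)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(dosage.shape[0])],
        variant_meta=meta,
        dosage=np.asarray(dosage, dtype=float),
    )


# ---------------------------------------------------------------------------
# Scoring-file I/O


def test_read_scoring_file_parses_rows(tmp_path):
    path = tmp_path / "score.txt"
    path.write_text(
        "#pgs_id=PGSTEST\n"
        "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
        "rs1\t1\t100\tA\tG\t0.1\n"
        "rs2\t1\t200\tC\tA\t-0.2\n"
    )
    score = read_scoring_file(path)
    assert score.pgs_id == "PGSTEST"
    assert len(score) == 2
    assert [v.weight for v in score.variants] == [0.1, -0.2]
    assert score.variants[0].pos == 100
    assert score.variants[1].effect_allele == "C"


def test_declared_count_mismatch_is_an_error(tmp_path):
    path = tmp_path / "bad.txt"
    rows = "".join(f"rs{i}\tA\tG\t0.1\n" for i in range(26))
    path.write_text(
        "#variants_number=27\n"
        "rsID\teffect_allele\tother_allele\teffect_weight\n" + rows
    )
    with pytest.raises(ScoringFileFormatError, match="27.*26"):
        read_scoring_file(path)


@pytest.mark.parametrize(
    "header",
    [
        "rsID\tother_allele\teffect_weight",   # no effect allele
        "rsID\teffect_allele\tother_allele",   # no weight
    ],
)
def test_missing_mandatory_column_is_an_error(tmp_path, header):
    path = tmp_path / "bad.txt"
    path.write_text(header + "\nrs1\tA\tG\n")
    with pytest.raises(ScoringFileFormatError):
        read_scoring_file(path)


def test_non_numeric_weight_reports_row(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text(
        "rsID\teffect_allele\teffect_weight\nrs1\tA\t0.2\nrs2\tG\toops\n"
    )
    with pytest.raises(ScoringFileFormatError, match="row 2"):
        read_scoring_file(path)


@pytest.mark.parametrize("dialect", ["chrpos", "rsid"])
def test_write_read_round_trip(tmp_path, score_files, dialect):
    """write ∘ read is the identity on simulator-emitted scoring files."""
    score = score_files[1]
    path = tmp_path / "rt.txt"
    write_scoring_file(score, path, dialect=dialect)
    back = read_scoring_file(path)
    assert back.pgs_id == score.pgs_id
    assert len(back) == len(score)
    for orig, rec in zip(score.variants, back.variants):
        assert rec.identifier == orig.identifier
        assert rec.effect_allele == orig.effect_allele
        assert rec.other_allele == orig.other_allele
        assert rec.weight == orig.weight
        if dialect == "chrpos":
            assert (rec.chrom, rec.pos) == (orig.chrom, orig.pos)


def test_score_variant_validation():
    with pytest.raises(ValueError):
        ScoreVariant("rs1", "1", 100, "N", "G", 0.1)
    with pytest.raises(ValueError):
        ScoreVariant("rs1", "1", 0, "A", "G", 0.1)
    with pytest.raises(ValueError):
        ScoreVariant("rs1", "1", 100, "A", "G", float("nan"))


# ---------------------------------------------------------------------------
# VCF loading


def write_vcf(path, records, samples=("s0", "s1", "s2"), fmt="GT"):
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=Rsq,Number=1,Type=Float,Description="q">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="d">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    lines += records
    path.write_text("\n".join(lines) + "\n")
    return path


def test_gt_converted_to_alt_dosage(tmp_path):
    path = write_vcf(
        tmp_path / "t.vcf",
        [
            "1\t100\tv1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t./.",
        ],
    )
    geno = read_genotypes(path, rsq_min=0.0)
    np.testing.assert_array_equal(geno.dosage[:, 0], [0, 1, 2])
    np.testing.assert_array_equal(geno.dosage[:2, 1], [2, 0])
    assert np.isnan(geno.dosage[2, 1])


def test_low_rsq_variant_excluded(tmp_path):
    path = write_vcf(
        tmp_path / "t.vcf",
        [
            "1\t100\tv1\tG\tA\t.\tPASS\tRsq=0.5\tGT\t0/0\t0/1\t1/1",
            "1\t200\tv2\tC\tT\t.\tPASS\tRsq=0.9\tGT\t0/0\t0/1\t1/1",
        ],
    )
    geno = read_genotypes(path, rsq_min=0.6)
    assert geno.n_variants == 1
    assert geno.variant_meta["pos"].tolist() == [200]


def test_multiallelic_records_excluded(tmp_path):
    path = write_vcf(
        tmp_path / "t.vcf",
        [
            "1\t100\tv1\tG\tA,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2",
            "1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
        ],
    )
    geno = read_genotypes(path, rsq_min=0.0)
    assert geno.n_variants == 1


def test_ds_preferred_over_gt(tmp_path):
    path = write_vcf(
        tmp_path / "t.vcf",
        ["1\t100\tv1\tG\tA\t.\tPASS\t.\tGT:DS\t0/0:0.12\t0/1:1.02\t1/1:1.9"],
    )
    geno = read_genotypes(path, rsq_min=0.0)
    np.testing.assert_allclose(geno.dosage[:, 0], [0.12, 1.02, 1.9])


def test_vcf_without_samples_is_an_error(tmp_path):
    path = write_vcf(tmp_path / "t.vcf", [], samples=())
    with pytest.raises(Exception):
        read_genotypes(path)


def test_variant_qc_matches_brute_force(rng):
    n, m = 40, 30
    dosage = rng.integers(0, 3, size=(n, m)).astype(float)
    mask = rng.random((n, m)) < 0.08
    dosage[mask] = np.nan
    geno = make_geno([("G", "A")] * m, dosage=dosage)
    out = variant_qc(geno, call_rate_min=0.95)
    expected_removed = sum(
        np.isnan(dosage[:, j]).mean() > 0.05 for j in range(m)
    )
    assert geno.n_variants - out.n_variants == expected_removed
    # identity when every call is present
    full = make_geno([("G", "A")] * 3, dosage=np.ones((n, 3)))
    assert variant_qc(full, 0.95).n_variants == 3


# ---------------------------------------------------------------------------
# Harmonization


def score_of(effect, other, pos=100, weight=0.5):
    return ScoringFile(
        pgs_id="T",
        trait_label="",
        variants=[ScoreVariant("v", "1", pos, effect, other, weight)],
    )


def test_harmonize_allele_truth_table():
    """Enumerate every ordered (effect, other) pair against ref=G/alt=A."""
    geno = make_geno([("G", "A")])
    bases = "ACGT"
    # hand-built expectations for ref=G, alt=A:
    #   direct: effect/other in {A/G (effect=ALT), G/A (effect=REF)}
    #   flip (complement to T/C space): T/C -> A/G, C/T -> G/A
    #   ambiguous pairs A/T, T/A, C/G, G/C -> dropped
    #   everything else -> mismatch
    expected = {
        ("A", "G"): ("direct", True),
        ("G", "A"): ("direct", False),
        ("T", "C"): ("flip", True),
        ("C", "T"): ("flip", False),
        ("A", "T"): ("ambiguous", None),
        ("T", "A"): ("ambiguous", None),
        ("C", "G"): ("ambiguous", None),
        ("G", "C"): ("ambiguous", None),
    }
    for effect in bases:
        for other in bases:
            if effect == other:
                continue
            kind, orient = expected.get((effect, other), ("mismatch", None))
            table, report = harmonize(score_of(effect, other), geno)
            counts = {
                "direct": report.n_matched_direct,
                "flip": report.n_matched_flip,
                "ambiguous": report.n_ambiguous_dropped,
                "mismatch": report.n_mismatch_dropped,
            }
            assert counts[kind] == 1, (effect, other)
            assert sum(counts.values()) == 1
            if orient is not None:
                assert bool(table.effect_is_alt[0]) is orient, (effect, other)


def test_harmonize_counts_partition(score_files, sim_cohort):
    geno, _, _ = sim_cohort
    for score in score_files:
        _, rep = harmonize(score, geno)
        total = (
            rep.n_matched_direct + rep.n_matched_flip + rep.n_ambiguous_dropped
            + rep.n_mismatch_dropped + rep.n_absent
        )
        assert total == rep.n_score_variants == len(score)
        assert 0.0 <= rep.coverage <= 1.0


def test_harmonize_coverage_arithmetic():
    geno = make_geno([("G", "A")] * 98)
    variants = [
        ScoreVariant(f"v{i}", "1", 100 + 100 * i, "A", "G", 0.1)
        for i in range(100)  # last 2 positions are absent from the panel
    ]
    _, rep = harmonize(
        ScoringFile(pgs_id="T", trait_label="", variants=variants), geno
    )
    assert rep.n_matched_direct == 98
    assert rep.n_absent == 2
    assert rep.coverage == pytest.approx(0.98)


def test_strand_flip_invariance(score_files, sim_cohort):
    """Complementing every record leaves the resolved match table unchanged."""
    geno, _, _ = sim_cohort
    for score in score_files[:2]:
        flipped = ScoringFile(
            pgs_id=score.pgs_id,
            trait_label=score.trait_label,
            variants=[v.complemented() for v in score.variants],
        )
        t1, r1 = harmonize(score, geno)
        t2, r2 = harmonize(flipped, geno)
        np.testing.assert_array_equal(t1.geno_index, t2.geno_index)
        np.testing.assert_array_equal(t1.weight, t2.weight)
        np.testing.assert_array_equal(t1.effect_is_alt, t2.effect_is_alt)
        assert r1.n_matched == r2.n_matched
        assert r1.n_ambiguous_dropped == r2.n_ambiguous_dropped


def test_ambiguous_keep_policy_matches_direct():
    geno = make_geno([("A", "T")])
    table, rep = harmonize(score_of("T", "A"), geno, ambiguous_policy="keep")
    assert rep.n_matched_direct == 1
    assert bool(table.effect_is_alt[0]) is True


def test_duplicate_genotype_position_is_an_error():
    geno = make_geno([("G", "A"), ("C", "T")])
    geno.variant_meta.loc[1, "pos"] = geno.variant_meta.loc[0, "pos"]
    with pytest.raises(ValueError, match="duplicate genotype position"):
        harmonize(score_of("A", "G"), geno)


def test_harmonization_report_partition_enforced():
    with pytest.raises(ValueError, match="partition"):
        HarmonizationReport("X", 10, 5, 2, 1, 1, 2)
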