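"""Genome model, annotation, cohort IO and copy-number arithmetic."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from mtmosaic import core_io
from mtmosaic.core_io import (
    CohortData,
    CoverageSummary,
    MtGenome,
    VariantRecord,
    annotate_variant,
    interval_contains,
    load_cohort,
    mtdna_copy_number,
    translate_codon,
    write_vcf,
)


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

def _oracle_consequence(genome, feat, pos, alt):
    """Independent oracle: mutate the sequence, re-translate the whole CDS
    with Biopython's vertebrate-mitochondrial table and diff the proteins."""
    seq = list(genome.sequence)
    seq[pos - 1] = alt
    mutated = MtGenome("".join(seq), genome.features, dloop=genome.dloop,
                       origin=genome.origin)
    old = str(Seq(genome.coding_sequence(feat)).translate(table=2))
    new = str(Seq(mutated.coding_sequence(feat)).translate(table=2))
    if new == old:
        return "synonymous"
    if "*" in new[:-1] and "*" not in old[:-1]:
        return "truncating"
    return "missense"


def test_annotation_agrees_with_translation_oracle(toy_genome):
    """Consequence calls match brute-force re-translation at every CDS
    position x every alternate base."""
    for feat in toy_genome.cds_features():
        for pos in range(feat.start, feat.end + 1):
            ref = toy_genome.base(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = annotate_variant(
                    VariantRecord(pos, ref, alt, "SNV"), toy_genome
                )
                assert v.consequence == _oracle_consequence(
                    toy_genome, feat, pos, alt
                ), (feat.name, pos, ref, alt)


def test_stop_gain_is_truncating(toy_genome):
    """Forcing a stop codon inside a CDS yields a truncating call."""
    feat = toy_genome.cds_features()[0]  # '+' strand gene
    found = False
    for pos in range(feat.start, feat.end - 3):
        codon, offset, positions = toy_genome.codon_at(feat, pos)
        for alt in "ACGT":
            if alt == toy_genome.base(pos):
                continue
            new = codon[:offset] + alt + codon[offset + 1:]
            if new in core_io.MT_CODON_TABLE.stop_codons:
                v = annotate_variant(
                    VariantRecord(pos, toy_genome.base(pos), alt, "SNV"),
                    toy_genome,
                )
                assert v.consequence == "truncating"
                found = True
    assert found, "toy genome offers no stop-gain opportunity"


def test_strand_class_follows_mutated_pyrimidine(toy_genome):
    """Pyrimidine reference base -> light strand; purine -> heavy."""
    for pos in (1, 10, 500, 1500):
        ref = toy_genome.base(pos)
        alt = "A" if ref != "A" else "G"
        v = annotate_variant(VariantRecord(pos, ref, alt, "SNV"), toy_genome)
        assert v.strand_class == ("light" if ref in "CT" else "heavy")


def test_frameshift_indel_is_truncating(toy_genome):
    feat = toy_genome.cds_features()[0]
    pos = feat.start + 4
    ref = toy_genome.base(pos)
    v = annotate_variant(
        VariantRecord(pos, ref, ref + "AT", "insertion"), toy_genome
    )
    assert v.consequence == "truncating"
    v3 = annotate_variant(
        VariantRecord(pos, ref, ref + "ATA", "insertion"), toy_genome
    )
    assert v3.consequence == "missense"  # in-frame


def test_reference_mismatch_raises(toy_genome):
    pos = 100
    wrong = "A" if toy_genome.base(pos) != "A" else "C"
    with pytest.raises(ValueError, match=str(pos)):
        annotate_variant(VariantRecord(pos, wrong, "G", "SNV"), toy_genome)


def test_incomplete_stop_codons_translate_as_stop():
    assert translate_codon("TA") == "*"
    assert translate_codon("T") == "*"
    assert translate_codon("AGA") == "*"  # vertebrate mito stop


def test_wrapping_intervals():
    """Features and regions wrapping the coordinate origin resolve like the
    replication origin m.16,197-191 does on the real genome."""
    assert interval_contains((16197, 191), 16500, 16569)
    assert interval_contains((16197, 191), 50, 16569)
    assert not interval_contains((16197, 191), 8000, 16569)


def test_region_flags(toy_genome):
    L = len(toy_genome)
    pos_in_origin = L - 10  # origin wraps (L-40, 15)
    ref = toy_genome.base(pos_in_origin)
    alt = "A" if ref != "A" else "C"
    v = annotate_variant(
        VariantRecord(pos_in_origin, ref, alt, "SNV"), toy_genome
    )
    assert v.in_origin and v.in_dloop


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mt, n, expected",
    [(375, 1, 750.0), (6931, 18.48, 750.1), (100, 100, 2.0)],
)
def test_mtdna_copy_number(mt, n, expected):
    assert mtdna_copy_number(CoverageSummary(mt, n)) == pytest.approx(
        expected, abs=0.05
    )


@given(mt=st.floats(0.1, 1e5), n=st.floats(0.1, 1e3),
       scale=st.floats(0.1, 10))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_copy_number_scaling(mt, n, scale):
    """Linear in mtDNA coverage, inverse in nuclear coverage."""
    base = mtdna_copy_number(CoverageSummary(mt, n))
    assert mtdna_copy_number(CoverageSummary(mt * scale, n)) == pytest.approx(
        base * scale, rel=1e-9
    )
    assert mtdna_copy_number(CoverageSummary(mt, n * scale)) == pytest.approx(
        base / scale, rel=1e-9
    )


def test_copy_number_rejects_nonpositive():
    with pytest.raises(ValueError):
        mtdna_copy_number(CoverageSummary(0, 10))


# ---------------------------------------------------------------------------
# cohort IO
# ---------------------------------------------------------------------------

def test_cohort_roundtrip_bitwise(small_cohort, tmp_path):
    """Write-then-read reproduces the VAF matrix exactly."""
    cohort, _, _ = small_cohort
    cohort.write(tmp_path)
    again = CohortData.read(tmp_path)
    assert cohort.vaf_matrix().equals(again.vaf_matrix())
    assert again.clone_ids == cohort.clone_ids
    assert set(again.phylogenies) == set(cohort.phylogenies)


def test_vcf_roundtrip(small_cohort, toy_genome, tmp_path):
    """A VCF written with AD fields reloads with identical VAFs."""
    cohort, _, _ = small_cohort
    vcf_path = tmp_path / "cohort.vcf"
    write_vcf(cohort, toy_genome, vcf_path)
    meta_path = tmp_path / "meta.tsv"
    cohort.metadata_frame().to_csv(meta_path, sep="\t", index=False)
    again = load_cohort([vcf_path], meta_path)
    orig = cohort.variants.copy()
    orig["vaf_ad"] = orig["alt_count"] / orig["depth"]
    merged = orig.merge(
        again.variants, on=["clone_id", "position", "alt"],
        suffixes=("", "_vcf"),
    )
    assert len(merged) == len(orig)
    assert np.allclose(merged["vaf_ad"], merged["vaf_vcf"], atol=1e-12)


def test_clonality_filter_excludes_and_logs(tmp_path, caplog):
    meta = pd.DataFrame([
        {"clone_id": "a", "donor_id": "d", "tissue": "colon",
         "donor_age": 50, "mean_coverage_nuclear": 30,
         "mean_coverage_mt": 5000, "nuclear_clonality_vaf": 0.45},
        {"clone_id": "b", "donor_id": "d", "tissue": "colon",
         "donor_age": 50, "mean_coverage_nuclear": 30,
         "mean_coverage_mt": 5000, "nuclear_clonality_vaf": 0.30},
    ])
    meta_path = tmp_path / "meta.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    variants = pd.DataFrame(
        [{"clone_id": "a", "position": 5, "ref": "A", "alt": "G",
          "variant_type": "SNV", "vaf": 0.5, "alt_count": 50, "depth": 100}]
    )
    vpath = tmp_path / "v.tsv"
    variants.to_csv(vpath, sep="\t", index=False)
    import logging
    with caplog.at_level(logging.WARNING, logger="mtmosaic.core_io"):
        cohort = load_cohort([vpath], meta_path)
    assert cohort.clone_ids == ["a"]
    assert cohort.excluded_clones == ["b"]
    assert any("excluded" in rec.message for rec in caplog.records)


def test_missing_metadata_column_is_fatal(tmp_path):
    pd.DataFrame([{"clone_id": "a"}]).to_csv(
        tmp_path / "meta.tsv", sep="\t", index=False
    )
    with pytest.raises(ValueError, match="metadata missing"):
        load_cohort([], tmp_path / "meta.tsv")


def test_unknown_clone_in_variants_is_fatal(tmp_path):
    meta = pd.DataFrame([
        {"clone_id": "a", "donor_id": "d", "tissue": "colon",
         "donor_age": 50, "mean_coverage_nuclear": 30,
         "mean_coverage_mt": 5000, "nuclear_clonality_vaf": 0.45},
    ])
    meta.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"clone_id": "ghost", "position": 5, "ref": "A", "alt": "G",
          "variant_type": "SNV", "vaf": 0.5, "alt_count": 5, "depth": 10}]
    ).to_csv(tmp_path / "v.tsv", sep="\t", index=False)
    with pytest.raises(ValueError, match="ghost"):
        load_cohort([tmp_path / "v.tsv"], tmp_path / "meta.tsv")
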