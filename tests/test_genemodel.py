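"""Gene structure, region classification and codon-effect annotation."""

from __future__ import annotations

import textwrap

import pytest
from Bio.Seq import Seq

from linumpool import datasets
from linumpool.genemodel import (
    GeneModel,
    GeneModelError,
    GeneReference,
    GenomicSite,
    ReferenceMismatchError,
    classify_location,
    codon_effect,
    load_gene_models,
)

# Standard genetic code, written out as an independent oracle.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def test_translation_agrees_with_standard_code_for_all_64_codons():
    for codon, aa in _CODON_TABLE.items():
        assert str(Seq(codon).translate()) == aa


# ---------------------------------------------------------------------------
# fixtures and loading
# ---------------------------------------------------------------------------

EXPECTED_STRUCTURE = {
    # gene_id: (exons, gene length, coding length, protein residues)
    "SAD1": (3, 2665, 1191, 396),
    "SAD2": (3, 2592, 1191, 396),
    "FAD2A": (1, 1137, 1137, 378),
    "FAD2B": (1, 1149, 1149, 382),
    "FAD3A": (6, 3280, 1179, 392),
    "FAD3B": (6, 3002, 1176, 391),
}


def test_fixture_models_reproduce_published_gene_structures(by_id):
    assert set(by_id) == set(EXPECTED_STRUCTURE)
    for gene_id, (n_exons, length, coding, protein) in EXPECTED_STRUCTURE.items():
        model = by_id[gene_id]
        assert len(model.exons) == n_exons
        assert model.gene_length == length
        assert model.coding_length == coding
        assert model.protein_length == protein


def _write_gff(tmp_path, body: str):
    path = tmp_path / "toy.gff3"
    path.write_text("##gff-version 3\n" + textwrap.dedent(body))
    return path


def test_load_enforces_reading_frame(tmp_path):
    good = _write_gff(
        tmp_path,
        """\
        chr1\ttoy\tgene\t10\t25\t.\t+\t.\tID=TOY1
        chr1\ttoy\texon\t10\t12\t.\t+\t.\tID=TOY1.e1;Parent=TOY1
        chr1\ttoy\texon\t20\t25\t.\t+\t.\tID=TOY1.e2;Parent=TOY1
        """,
    )
    (model,) = load_gene_models(good)
    assert model.spliced_length == 9

    bad = _write_gff(
        tmp_path,
        """\
        chr1\ttoy\tgene\t10\t25\t.\t+\t.\tID=TOY2
        chr1\ttoy\texon\t10\t12\t.\t+\t.\tID=TOY2.e1;Parent=TOY2
        chr1\ttoy\texon\t20\t24\t.\t+\t.\tID=TOY2.e2;Parent=TOY2
        """,
    )
    with pytest.raises(GeneModelError, match="multiple of 3"):
        load_gene_models(bad)


def test_load_rejects_malformed_gff3(tmp_path):
    path = tmp_path / "broken.gff3"
    path.write_text("##gff-version 3\nnot a gff line at all\n")
    with pytest.raises(ValueError, match="broken.gff3"):
        load_gene_models(path)


def test_exon_count_enforced_for_canonical_genes():
    with pytest.raises(GeneModelError, match="expected 6 exon"):
        GeneModel(
            gene_id="FAD3A", chromosome_id="chrX", strand="+",
            gene_start=1, gene_end=60, exons=((1, 30), (41, 61 - 27 - 1 + 26)),
        )


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

def test_exonic_position_is_exon(by_id):
    sad1 = by_id["SAD1"]
    start, end = sad1.exons[0]
    assert classify_location((start + end) // 2, sad1) == "exon"


def test_minus_strand_upstream_is_above_gene_end(by_id):
    fad3a = by_id["FAD3A"]
    assert fad3a.strand == "-"
    assert classify_location(fad3a.gene_end + 100, fad3a) == "upstream"
    assert classify_location(fad3a.gene_start - 100, fad3a) == "downstream"


def test_sad1_intron_sites_match_reported_labels(by_id):
    # the two tabulated SAD1 intron sites fall between exons 1 and 2
    sad1 = by_id["SAD1"]
    for pos in (2258938, 2258980):
        assert classify_location(pos, sad1) == "intron"
        assert sad1.exons[0][1] < pos < sad1.exons[1][0]


def test_all_reference_table_location_labels_reproduced(by_id):
    table = datasets.load_table1()
    for row in table.itertuples():
        site = GenomicSite(row.chromosome, row.position, row.ref_allele, row.alt_allele)
        assert classify_location(site, by_id[row.gene]) == row.location, (
            f"{row.gene}:{row.position}"
        )


def test_classification_partitions_flank_window(by_id):
    sad1 = by_id["SAD1"]
    labels = {"upstream", "exon", "intron", "downstream", "intergenic"}
    for pos in range(sad1.gene_start - sad1.flank_bp - 3,
                     sad1.gene_end + sad1.flank_bp + 4, 7):
        assert classify_location(pos, sad1) in labels
    # closed boundaries at the gene ends (both are exon edges in the fixture)
    assert classify_location(sad1.gene_start, sad1) == "exon"
    assert classify_location(sad1.gene_end, sad1) == "exon"
    assert classify_location(sad1.gene_start - 1, sad1) == "upstream"
    assert classify_location(sad1.gene_end + 1, sad1) == "downstream"
    assert classify_location(sad1.gene_start - sad1.flank_bp - 1, sad1) == "intergenic"
    assert classify_location(sad1.gene_end + sad1.flank_bp + 1, sad1) == "intergenic"


def test_other_chromosome_is_intergenic(by_id):
    site = GenomicSite("CP000000.1", 2258000, "A", "C")
    assert classify_location(site, by_id["SAD1"]) == "intergenic"


# ---------------------------------------------------------------------------
# codon effects
# ---------------------------------------------------------------------------

def _toy_gene():
    """Plus-strand single-exon gene: ATG GGT CAT TGG ATC TAA at 101..118."""
    model = GeneModel(
        gene_id="TOY", chromosome_id="chrT", strand="+",
        gene_start=101, gene_end=118, exons=((101, 118),),
    )
    seq = "ATGGGTCATTGGATCTAA"
    reference = GeneReference("TOY", "chrT", 101, seq)
    return model, reference


@pytest.mark.parametrize(
    "position, ref, alt, effect, ref_aa, alt_aa",
    [
        (104, "G", "A", "missense", "G", "S"),  # GGT->AGT glycine to serine
        (107, "C", "T", "missense", "H", "Y"),  # CAT->TAT histidine to tyrosine
        (112, "G", "A", "nonsense", "W", "*"),  # TGG->TGA tryptophan to stop
        (114, "T", "G", "missense", "I", "S"),  # ATC->AGC isoleucine to serine
        (106, "T", "C", "silent", "G", "G"),    # GGT->GGC
    ],
)
def test_codon_effect_single_base_substitutions(position, ref, alt, effect, ref_aa, alt_aa):
    model, reference = _toy_gene()
    out = codon_effect(GenomicSite("chrT", position, ref, alt), model, reference)
    assert out.effect == effect
    assert out.ref_aa == ref_aa
    assert out.alt_aa == alt_aa


@pytest.mark.parametrize(
    "gene, site, effect, ref_aa, alt_aa",
    [
        ("FAD3A", datasets.KEY_FAD3A_NONSENSE, "nonsense", "W", "*"),
        ("FAD3A", datasets.ALT_FAD3A_NONSENSE, "nonsense", "R", "*"),
        ("FAD3A", GenomicSite("CP027631.1", 16092575, "C", "T"), "missense", "A", "T"),
        ("FAD3A", GenomicSite("CP027631.1", 16092294, "T", "C"), "silent", "P", "P"),
        ("FAD3B", datasets.KEY_FAD3B_MISSENSE, "missense", "H", "Y"),
        ("FAD3B", GenomicSite("CP027622.1", 1035674, "T", "G"), "missense", "I", "S"),
        ("FAD3B", GenomicSite("CP027622.1", 1035480, "A", "G"), "silent", "P", "P"),
        ("FAD2A", GenomicSite("CP027619.1", 5296364, "G", "A"), "silent", "L", "L"),
        ("FAD2A", GenomicSite("CP027619.1", 5296658, "C", "T"), "silent", "G", "G"),
        ("SAD2", GenomicSite("CP027621.1", 17365164, "T", "C"), "silent", "L", "L"),
    ],
)
def test_fixture_key_variants_reproduce_reported_effects(
    by_id, references, gene, site, effect, ref_aa, alt_aa
):
    out = codon_effect(site, by_id[gene], references[gene])
    assert out.effect == effect
    assert (out.ref_aa, out.alt_aa) == (ref_aa, alt_aa)


def test_key_fad3b_codon_is_cat_to_tat(by_id, references):
    out = codon_effect(datasets.KEY_FAD3B_MISSENSE, by_id["FAD3B"], references["FAD3B"])
    assert (out.ref_codon, out.alt_codon) == ("CAT", "TAT")


def test_reference_mismatch_raises():
    model, reference = _toy_gene()
    with pytest.raises(ReferenceMismatchError):
        codon_effect(GenomicSite("chrT", 104, "C", "A"), model, reference)


def test_indel_and_noncoding_effects():
    model, reference = _toy_gene()
    ref_flank = GeneReference("TOY", "chrT", 95, "ACACAC" + reference.sequence)
    # exonic 1-bp insertion -> frameshift; 3-bp -> in-frame
    assert codon_effect(
        GenomicSite("chrT", 104, "G", "GA"), model, ref_flank
    ).effect == "indel_frameshift"
    assert codon_effect(
        GenomicSite("chrT", 104, "G", "GAAA"), model, ref_flank
    ).effect == "indel_inframe"
    # non-exonic substitution -> noncoding
    assert codon_effect(
        GenomicSite("chrT", 97, "A", "G"), model, ref_flank
    ).effect == "noncoding"


def test_multibase_substitution_spanning_codons():
    model, reference = _toy_gene()
    # TC at 106..107 -> AG: codon 2 GGT->GGA (silent), codon 3 CAT->GAT (H->D)
    out = codon_effect(GenomicSite("chrT", 106, "TC", "AG"), model, reference)
    assert out.effect == "missense"
    assert (out.ref_aa, out.alt_aa, out.aa_position) == ("H", "D", 3)


def test_strand_invariance_of_codon_effects():
    model, reference = _toy_gene()
    span_start, span_end = 101, 118
    mirror_model = GeneModel(
        gene_id="TOYREV", chromosome_id="chrT", strand="-",
        gene_start=span_start, gene_end=span_end, exons=((span_start, span_end),),
    )
    mirror_ref = GeneReference(
        "TOYREV", "chrT", span_start,
        str(Seq(reference.sequence).reverse_complement()),
    )
    for position, ref, alt in [(104, "G", "A"), (107, "C", "T"), (112, "G", "A")]:
        direct = codon_effect(GenomicSite("chrT", position, ref, alt), model, reference)
        mirror_pos = span_start + span_end - position
        flipped = codon_effect(
            GenomicSite(
                "chrT", mirror_pos,
                str(Seq(ref).reverse_complement()),
                str(Seq(alt).reverse_complement()),
            ),
            mirror_model, mirror_ref,
        )
        assert (direct.effect, direct.ref_aa, direct.alt_aa) == (
            flipped.effect, flipped.ref_aa, flipped.alt_aa
        )
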