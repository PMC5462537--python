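import numpy as np
import pandas as pd
import pytest
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

import poolmap as pm
from poolmap.datasets import frameshift_deletion_example, two_exon_locus_example
from poolmap.genome import make_two_exon_gene, reverse_complement

NT = "ACGT"


# ------------------------------------------------------------------ SNVs

def _gene_for_codon(codon, strand="+"):
    """Two-exon gene whose second codon is `codon`, split mid-CDS."""
    cds = "ATG" + codon + "GGCTAA"
    gene, locus = make_two_exon_gene("g", "chrT", strand, 101, cds,
                                     utr5=10, utr3=10, intron_length=50,
                                     cds_split=5)
    return gene


def _oracle_class(codon, alt_codon):
    """Independent classification straight from the standard codon table."""
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    ref_stop, alt_stop = codon in stops, alt_codon in stops
    if ref_stop and alt_stop:
        return "synonymous"
    if ref_stop:
        return "stop_loss"
    if alt_stop:
        return "nonsense"
    return "synonymous" if table[codon] == table[alt_codon] else "missense"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_all_codon_substitutions_match_codon_table_oracle(strand):
    """Exhaustive 64 codons x 9 substitutions, through the full genomic
    machinery (coordinates, strand, splicing) vs direct codon-table lookup."""
    for b1 in NT:
        for b2 in NT:
            for b3 in NT:
                codon = b1 + b2 + b3
                gene = _gene_for_codon(codon, strand)
                for within in range(3):
                    for alt in NT:
                        if alt == codon[within]:
                            continue
                        cds_idx = 3 + within  # second codon of the CDS
                        pos = _cds_to_genomic(gene, cds_idx)
                        ref_g = gene.genomic_ref_base(pos)
                        alt_g = alt if strand == "+" else reverse_complement(alt)
                        eff = pm.classify_variant_effect(
                            gene, pm.Variant("chrT", pos, ref_g, alt_g))
                        alt_codon = codon[:within] + alt + codon[within + 1:]
                        assert eff.effect == _oracle_class(codon, alt_codon), (
                            codon, within, alt, strand)


def _cds_to_genomic(gene, cds_idx):
    offset = 0
    for s, e in gene.cds_segments():
        if offset <= cds_idx <= offset + (e - s):
            return s + (cds_idx - offset) if gene.strand == "+" else e - (cds_idx - offset)
        offset += e - s + 1
    raise AssertionError("cds_idx out of range")


def test_known_codon_changes():
    # GCT -> GCC : synonymous (Ala->Ala); TAC -> TAA : nonsense (Tyr->stop)
    gene = _gene_for_codon("GCT")
    pos = _cds_to_genomic(gene, 5)
    eff = pm.classify_variant_effect(gene, pm.Variant("chrT", pos, "T", "C"))
    assert eff.effect == "synonymous" and eff.aa_ref == "A"
    gene = _gene_for_codon("TAC")
    pos = _cds_to_genomic(gene, 5)
    eff = pm.classify_variant_effect(gene, pm.Variant("chrT", pos, "C", "A"))
    assert eff.effect == "nonsense" and eff.aa_alt == "*"
    assert eff.aa_change == "p.Y2*"


def test_reverse_strand_gene_matches_forward_construction():
    """A gene built on the minus strand classifies identically to the same
    CDS built forward: strand handling is symmetric."""
    locus_f = two_exon_locus_example(seed=5, strand="+")
    locus_r = two_exon_locus_example(seed=5, strand="-")
    for locus in (locus_f, locus_r):
        effects = [pm.classify_variant_effect(locus.gene, v)
                   for v in locus.variants if locus.gene.contains(v.pos)]
        assert sorted(e.effect for e in effects) == ["missense", "missense", "synonymous"]


def test_ref_mismatch_is_a_data_integrity_error():
    gene = _gene_for_codon("AAA")
    pos = _cds_to_genomic(gene, 3)
    wrong_ref = "C" if gene.genomic_ref_base(pos) != "C" else "G"
    with pytest.raises(pm.ReferenceMismatchError):
        pm.classify_variant_effect(gene, pm.Variant("chrT", pos, wrong_ref, "T"))


def test_splice_site_window_is_two_bp():
    gene = _gene_for_codon("AAA")
    (s1, e1), (s2, e2) = gene.exons
    for pos, expected in [(e1 + 1, "splice_site"), (e1 + 2, "splice_site"),
                          (e1 + 3, "noncoding"), (s2 - 1, "splice_site"),
                          (s2 - 3, "noncoding")]:
        eff = pm.classify_variant_effect(gene, pm.Variant("chrT", pos, "A", "C"))
        assert eff.effect == expected, pos


# ------------------------------------------------------------------ indels

def test_fh436_style_8bp_deletion_is_frameshift():
    """An 8 bp deletion at CDS nucleotide 4 of exon 1 breaks the frame."""
    locus, deletion = frameshift_deletion_example()
    eff = pm.classify_variant_effect(locus.gene, deletion,
                                     contig_seq=locus.sequence)
    assert eff.effect == "frameshift"
    assert deletion.indel_length == 8


def test_inframe_deletion_never_frameshift():
    locus = two_exon_locus_example()
    gene = locus.gene
    seq = locus.sequence
    for ndel in (3, 6, 9):  # length mod 3 == 0: in-frame by definition
        anchor = gene.cds_start + 3
        ref = seq[anchor - 1 : anchor + ndel]
        eff = pm.classify_variant_effect(
            gene, pm.Variant(gene.chrom, anchor, ref, ref[0]), contig_seq=seq)
        assert eff.effect == "in_frame_indel"


def test_intronic_and_junction_indels():
    locus = two_exon_locus_example()
    gene, seq = locus.gene, locus.sequence
    e1_end = gene.exons[0][1]
    # deletion spanning the exon1/intron junction
    ref = seq[e1_end - 3 : e1_end + 4]
    with pytest.warns(UserWarning, match="junction"):
        eff = pm.classify_variant_effect(
            gene, pm.Variant(gene.chrom, e1_end - 2, ref, ref[0]))
    assert eff.effect == "splice_site"
    # deep intronic deletion
    mid = (gene.exons[0][1] + gene.exons[1][0]) // 2
    ref = seq[mid - 1 : mid + 4]
    eff = pm.classify_variant_effect(
        gene, pm.Variant(gene.chrom, mid, ref, ref[0]))
    assert eff.effect == "noncoding"


def test_indel_left_alignment_against_contig():
    from poolmap.annotate import left_align_indel
    #        123456789
    seq = "GGAAAATCG"
    # deleting one A of the run, right-anchored: normalises to pos 2
    v = pm.Variant("c", 5, "AA", "A")
    assert left_align_indel(v, seq) == pm.Variant("c", 2, "GA", "G")


# ------------------------------------------------------------------ screening

def test_interval_screen_counts_planted_missense(example_locus):
    interval = pm.LinkageInterval(example_locus.contig, 1,
                                  example_locus.contig_length, 1.0, 0)
    report = pm.screen_interval_candidates(
        interval, example_locus.variants, [example_locus.gene],
        contig_sequences={example_locus.contig: example_locus.sequence})
    assert report.tallies.get("missense") == 2
    assert report.tallies.get("synonymous") == 1
    assert report.tallies.get("noncoding") == 2
    # ranking: missense first, severity non-decreasing
    sev = [e.severity for e in report.effects]
    assert sev == sorted(sev)
    assert report.effects[0].effect == "missense"


def test_variants_outside_interval_are_excluded(example_locus):
    interval = pm.LinkageInterval(example_locus.contig, 1, 10, 1.0, 0)
    report = pm.screen_interval_candidates(interval, example_locus.variants,
                                           [example_locus.gene])
    assert report.effects == []


def test_single_missense_variant_report():
    locus = two_exon_locus_example(seed=9)
    v = next(v for v, c in locus.expected_effects.items() if c == "missense")
    interval = pm.LinkageInterval(locus.contig, v.pos - 5, v.pos + 5, 1.0, 0)
    report = pm.screen_interval_candidates(interval, locus.variants, [locus.gene])
    assert len(report.effects) == 1
    assert report.effects[0].effect == "missense"


# ------------------------------------------------------------------ expression

def _expr(genes, mut, wt):
    df = pd.DataFrame({"gene_id": genes, "mut_count": mut, "wt_count": wt})
    return pm.ExpressionTable(df, int(sum(mut)) or 1, int(sum(wt)) or 1)


def test_equal_expression_yields_no_flags():
    t = _expr(["a", "b", "c"], [100, 200, 300], [100, 200, 300])
    out = pm.expression_screen(t, ["a", "b", "c"])
    assert not out["flagged"].any()


def test_planted_reduced_gene_is_flagged():
    # fold 0.2 at mean 500 against a stable background: ample binomial power
    rng = np.random.default_rng(0)
    bg_mut = rng.poisson(300, 20)
    bg_wt = rng.poisson(300, 20)
    genes = [f"g{i}" for i in range(20)] + ["planted"]
    t = _expr(genes, list(bg_mut) + [int(rng.poisson(100))],
              list(bg_wt) + [int(rng.poisson(500))])
    out = pm.expression_screen(t, genes).set_index("gene_id")
    assert bool(out.at["planted", "flagged"])
    assert out.at["planted", "fold_change"] < 0.5


def test_increased_expression_is_not_flagged():
    t = _expr(["up", "bg"], [1000, 300], [500, 300])
    out = pm.expression_screen(t, ["up", "bg"]).set_index("gene_id")
    assert not out.at["up", "flagged"]  # direction rule: reduced only


def test_absent_gene_is_skipped_with_warning(caplog):
    t = _expr(["a"], [10], [10])
    with caplog.at_level("WARNING"):
        out = pm.expression_screen(t, ["a", "ghost"])
    assert "ghost" in caplog.text
    assert list(out["gene_id"]) == ["a"]


def test_expression_screen_estimator(small_cross):
    _, expression, truth = small_cross
    scr = pm.ExpressionScreen().fit(expression)
    assert truth.planted_gene in scr.flagged_


# ------------------------------------------------------------------ severity

def test_severity_ranking_is_total_and_deterministic():
    order = pm.SEVERITY_ORDER
    assert len(set(order.values())) == len(order)
    assert order["nonsense"] < order["missense"] < order["splice_site"]
    assert order["frameshift"] < order["missense"]
    assert order["missense"] < order["synonymous"]
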