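"""Programmatically generated example data.

No sequencing reads or variant calls are distributed with this package; the
worked-example locus here is *synthetic*, built at call time from a seeded
RNG. It emulates the situation at a mapped connexin-like locus: a small
contig carrying one two-exon gene, with two missense lesions planted in the
coding sequence plus synonymous and intergenic decoy variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .genome import GeneModel, NUCLEOTIDES, make_two_exon_gene, random_cds
from .annotate import Variant


@dataclass
class ExampleLocus:
    """A synthetic annotated locus with planted variants and their truth."""

    contig: str
    contig_length: int
    sequence: str
    gene: GeneModel
    variants: list[Variant]
    expected_effects: dict[Variant, str]


def _snv_with_effect(gene: GeneModel, cds_idx: int, wanted: str) -> Variant | None:
    """Find an alt base at spliced-CDS position cds_idx giving the wanted class."""
    codon_i, within = divmod(cds_idx, 3)
    codon = gene.cds_sequence[3 * codon_i : 3 * codon_i + 3]
    aa_ref = str(Seq(codon).translate())
    for alt in NUCLEOTIDES:
        if alt == codon[within]:
            continue
        mutated = codon[:within] + alt + codon[within + 1 :]
        aa_alt = str(Seq(mutated).translate())
        if wanted == "missense" and aa_alt not in (aa_ref, "*") and aa_ref != "*":
            break
        if wanted == "synonymous" and aa_alt == aa_ref:
            break
        if wanted == "nonsense" and aa_alt == "*" and aa_ref != "*":
            break
    else:
        return None
    # map spliced-CDS coordinate back to the genome
    offset = 0
    for s, e in gene.cds_segments():
        if offset <= cds_idx <= offset + (e - s):
            pos = s + (cds_idx - offset) if gene.strand == "+" else e - (cds_idx - offset)
            break
        offset += e - s + 1
    ref_g = gene.genomic_ref_base(pos)
    alt_g = alt if gene.strand == "+" else str(Seq(alt).reverse_complement())
    return Variant(gene.chrom, pos, ref_g, alt_g)


def two_exon_locus_example(seed: int = 2017, strand: str = "+") -> ExampleLocus:
    """Synthetic two-exon connexin-like locus with planted lesions.

    Plants exactly two missense SNVs in the gene's CDS (the mapped-locus
    situation this pipeline is built to triage), one synonymous coding decoy
    and two intergenic decoys. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    contig = "chrM5"
    contig_length = 8000
    bases = list(NUCLEOTIDES)
    seq = list(rng.choice(bases, size=contig_length))
    cds = random_cds(rng, 120)  # 360 nt coding sequence
    gene, locus_seq = make_two_exon_gene(
        "cx34like", contig, strand, 2001, cds, intron_length=600, rng=rng
    )
    seq[2000 : 2000 + len(locus_seq)] = list(locus_seq)
    sequence = "".join(seq)

    variants: list[Variant] = []
    expected: dict[Variant, str] = {}
    # two missense lesions at well-separated codons, one per exon
    for cds_idx in (30, 250):
        v = _snv_with_effect(gene, cds_idx, "missense")
        assert v is not None
        variants.append(v)
        expected[v] = "missense"
    syn = _snv_with_effect(gene, 92, "synonymous") or _snv_with_effect(gene, 95, "synonymous")
    if syn is not None:
        variants.append(syn)
        expected[syn] = "synonymous"
    for pos in (500, 7500):  # intergenic decoys
        ref = sequence[pos - 1]
        alt = next(b for b in NUCLEOTIDES if b != ref)
        v = Variant(contig, pos, ref, alt)
        variants.append(v)
        expected[v] = "noncoding"
    variants.sort(key=lambda v: v.pos)
    return ExampleLocus(contig, contig_length, sequence, gene, variants, expected)


def frameshift_deletion_example(locus: ExampleLocus | None = None) -> tuple[ExampleLocus, Variant]:
    """An engineered-style 8 bp frame-shifting deletion at CDS nucleotide 4.

    Mirrors the classic validation allele design: an 8 bp deletion starting
    at the fourth coding nucleotide of exon 1 (8 mod 3 != 0, so the reading
    frame is broken immediately after the start codon).
    """
    if locus is None:
        locus = two_exon_locus_example()
    gene = locus.gene
    segs = gene.cds_segments()
    first_s, first_e = segs[0]
    if gene.strand == "+":
        anchor = first_s + 2  # CDS nt 3; deletes nts 4..11
        ref = locus.sequence[anchor - 1 : anchor + 8]
        alt = ref[0]
    else:
        # CDS nt k sits at genomic first_e - k + 1; deleting nts 4..11 removes
        # genomic [first_e-10, first_e-3], anchored one base to the left
        anchor = first_e - 11
        ref = locus.sequence[anchor - 1 : anchor + 8]
        alt = ref[0]
    return locus, Variant(gene.chrom, anchor, ref, alt)
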