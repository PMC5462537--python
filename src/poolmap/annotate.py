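"""Candidate-lesion triage inside a mapped interval.

ENU mutagenesis produces mostly single-nucleotide lesions, so the screen
looks for coding changes — missense, nonsense, frameshift — among variants
in the linked interval, and for interval genes whose pooled expression is
significantly reduced in mutants (a signature of nonsense-mediated decay or
a regulatory lesion).

Coding consequences are computed against single-transcript gene models:
genomic position -> spliced CDS coordinate (strand-aware), codon
substitution, translation with the standard nuclear code. Intronic
positions within 2 bp of an exon boundary are splice-site; indels changing
the CDS length by a non-multiple of 3 are frameshifts.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from scipy.stats import binomtest
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, reverse_complement
from .linkage import LinkageInterval
from .simulate import ExpressionTable

logger = logging.getLogger(__name__)

#: total severity order used to rank candidates (lower = more severe)
SEVERITY_ORDER = {
    "nonsense": 0,
    "frameshift": 1,
    "stop_loss": 2,
    "missense": 3,
    "in_frame_indel": 4,
    "splice_site": 5,
    "synonymous": 6,
    "noncoding": 7,
}


class ReferenceMismatchError(ValueError):
    """Variant ref allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class Variant:
    """A VCF-style variant: 1-based pos, explicit ref/alt allele strings."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


@dataclass
class VariantEffect:
    """Classification of one variant against one gene model."""

    variant: Variant
    gene_id: str | None
    effect: str
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_pos: int | None = None  # 1-based residue number
    aa_ref: str | None = None
    aa_alt: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.effect not in SEVERITY_ORDER:
            raise ValueError(f"unknown effect class {self.effect!r}")
        if self.effect == "missense" and self.aa_ref is not None:
            assert self.aa_ref != self.aa_alt and "*" not in (self.aa_alt or "")
        if self.effect == "nonsense":
            assert self.aa_alt == "*"
        if self.effect == "frameshift":
            assert self.variant.indel_length % 3 != 0

    @property
    def severity(self) -> int:
        return SEVERITY_ORDER[self.effect]

    @property
    def aa_change(self) -> str | None:
        if self.aa_ref is None:
            return None
        return f"p.{self.aa_ref}{self.aa_pos}{self.aa_alt}"


def left_align_indel(variant: Variant, contig_seq: str | None) -> Variant:
    """Left-normalise an indel against a contig sequence (1-based coords).

    Shifts the event left while the flanking base matches the trailing base
    of the longer allele, the standard VCF normalisation. Returns the
    variant unchanged when no sequence is available or it is an SNV.
    """
    if contig_seq is None or variant.is_snv:
        return variant
    ref, alt, pos = variant.ref.upper(), variant.alt.upper(), variant.pos
    # only simple anchored indels are shifted
    if not (ref[0] == alt[0] and (len(ref) == 1 or len(alt) == 1)):
        return variant
    while pos > 1 and ref[-1] == alt[-1]:
        prev = contig_seq[pos - 2].upper()
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return Variant(variant.chrom, pos, ref, alt)


def classify_variant_effect(
    gene: GeneModel, variant: Variant, contig_seq: str | None = None
) -> VariantEffect:
    """Classify the coding consequence of a variant on one gene model.

    The variant must lie on the gene's chromosome; for positions inside the
    CDS the ref allele is checked against the gene's spliced CDS sequence
    and a mismatch raises :class:`ReferenceMismatchError`.
    """
    if variant.chrom != gene.chrom:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} not on gene chromosome {gene.chrom}"
        )
    if not variant.is_snv:
        return _classify_indel(gene, left_align_indel(variant, contig_seq))

    pos = variant.pos
    cds_idx = gene.genomic_to_cds(pos)
    if cds_idx is None:
        d = gene.splice_distance(pos)
        if d is not None and d <= 2:
            return VariantEffect(variant, gene.gene_id, "splice_site")
        return VariantEffect(variant, gene.gene_id, "noncoding")

    expected = gene.genomic_ref_base(pos)
    if expected != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} ref {variant.ref!r} != reference {expected!r}"
        )
    # move to coding strand
    alt_cds = variant.alt.upper() if gene.strand == "+" else reverse_complement(
        variant.alt.upper()
    )
    codon_i = cds_idx // 3
    within = cds_idx % 3
    codon_ref = gene.cds_sequence[3 * codon_i : 3 * codon_i + 3]
    codon_alt = codon_ref[:within] + alt_cds + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())

    common = dict(codon_ref=codon_ref, codon_alt=codon_alt,
                  aa_pos=codon_i + 1, aa_ref=aa_ref, aa_alt=aa_alt)
    if aa_alt == aa_ref:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    elif aa_ref == "*":
        effect = "stop_loss"
    else:
        effect = "missense"
    note = ""
    if codon_i == 0 and effect == "missense":
        note = "start_codon_loss"  # ranked with missense severity
        logger.info("%s: start-codon loss at %s:%d", gene.gene_id,
                    variant.chrom, variant.pos)
    return VariantEffect(variant, gene.gene_id, effect, note=note, **common)


def _classify_indel(gene: GeneModel, variant: Variant) -> VariantEffect:
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if len(ref) > len(alt):  # deletion: bases after the anchor are removed
        span = (variant.pos + 1, variant.pos + len(ref) - 1)
    else:  # insertion after the anchor base
        span = (variant.pos, variant.pos + 1)
    span_positions = list(range(span[0], span[1] + 1))
    in_cds = [p for p in span_positions if gene.genomic_to_cds(p) is not None]
    intronic = [p for p in span_positions if gene.contains(p) and not gene.in_exon(p)]
    if in_cds:
        if intronic and len(ref) > len(alt):
            warnings.warn(
                f"{variant.chrom}:{variant.pos}: indel spans an exon/intron "
                "junction; classified as splice_site"
            )
            return VariantEffect(variant, gene.gene_id, "splice_site")
        effect = "frameshift" if variant.indel_length % 3 else "in_frame_indel"
        return VariantEffect(variant, gene.gene_id, effect)
    dists = [gene.splice_distance(p) for p in span_positions]
    if any(d is not None and d <= 2 for d in dists):
        return VariantEffect(variant, gene.gene_id, "splice_site")
    return VariantEffect(variant, gene.gene_id, "noncoding")


class VariantEffectClassifier(BaseEstimator):
    """Predict coding consequences of variants against a set of gene models.

    ``predict(variants)`` returns one :class:`VariantEffect` per variant,
    classified against the first gene model whose span contains it (gene
    models rarely overlap in this setting); variants outside every gene are
    ``noncoding`` with ``gene_id=None``.
    """

    def __init__(self, gene_models: list[GeneModel] | None = None,
                 contig_sequences: dict[str, str] | None = None):
        self.gene_models = gene_models
        self.contig_sequences = contig_sequences

    def fit(self, X=None, y=None) -> "VariantEffectClassifier":
        self.genes_ = list(self.gene_models or [])
        return self

    def predict(self, variants: list[Variant]) -> list[VariantEffect]:
        if not hasattr(self, "genes_"):
            self.fit()
        seqs = self.contig_sequences or {}
        out = []
        for v in variants:
            gene = next(
                (g for g in self.genes_ if g.chrom == v.chrom and g.contains(v.pos)),
                None,
            )
            if gene is None:
                out.append(VariantEffect(v, None, "noncoding"))
            else:
                out.append(classify_variant_effect(gene, v, seqs.get(v.chrom)))
        return out


@dataclass
class CandidateReport:
    """Triage of a mapped interval: ranked coding candidates + expression hits."""

    interval: LinkageInterval
    effects: list[VariantEffect]
    tallies: dict[str, int]
    reduced_genes: pd.DataFrame

    def effects_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": e.variant.chrom, "pos": e.variant.pos,
                "ref": e.variant.ref, "alt": e.variant.alt,
                "gene_id": e.gene_id or ".", "effect": e.effect,
                "codon_change": (f"{e.codon_ref}>{e.codon_alt}" if e.codon_ref else "."),
                "aa_change": e.aa_change or ".", "note": e.note or ".",
            }
            for e in self.effects
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "gene_id", "effect",
                           "codon_change", "aa_change", "note"],
        )


def screen_interval_candidates(
    interval: LinkageInterval,
    variants: list[Variant],
    gene_models: list[GeneModel],
    expression: ExpressionTable | None = None,
    contig_sequences: dict[str, str] | None = None,
    alpha: float = 0.05,
    min_fold: float = 0.5,
) -> CandidateReport:
    """Classify every variant inside the interval and rank by severity.

    Severity order: nonsense/frameshift > stop-loss > missense >
    in-frame indel > splice > synonymous/noncoding; ties broken by genomic
    coordinate (stable, deterministic). When an expression table is given,
    interval genes are screened for significantly reduced expression.
    """
    inside = [v for v in variants if interval.contains(v.chrom, v.pos)]
    interval_genes = [
        g for g in gene_models
        if g.chrom == interval.chrom and g.start <= interval.end_bp
        and g.end >= interval.start_bp
    ]
    if not interval_genes:
        logger.warning("no gene models overlap the interval; "
                       "variants will be noncoding only")
    clf = VariantEffectClassifier(interval_genes, contig_sequences).fit()
    effects = clf.predict(inside)
    effects.sort(key=lambda e: (e.severity, e.variant.pos))
    tallies = dict(Counter(e.effect for e in effects))
    if expression is not None:
        reduced = expression_screen(
            expression, [g.gene_id for g in interval_genes],
            alpha=alpha, min_fold=min_fold,
        )
    else:
        reduced = _empty_expression_frame()
    logger.info("interval screen: %d variants, tallies %s, %d reduced-expression gene(s)",
                len(inside), tallies, int(reduced["flagged"].sum()) if len(reduced) else 0)
    return CandidateReport(interval, effects, tallies, reduced)


def _empty_expression_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene_id", "mut_count", "wt_count", "fold_change",
                 "pvalue", "padj", "flagged"]
    )


def expression_screen(
    expression: ExpressionTable,
    gene_ids: list[str],
    alpha: float = 0.05,
    min_fold: float = 0.5,
) -> pd.DataFrame:
    """Flag interval genes whose mutant-pool expression is reduced.

    For each gene the mutant/wildtype fold change is computed on
    library-size-normalised counts, and the mutant count is tested with a
    two-sided binomial test against its expectation under equal expression
    (success probability ``mut_lib / (mut_lib + wt_lib)`` of the pooled
    total). P-values are Benjamini-Hochberg adjusted across tested genes; a
    gene is flagged when fold change <= ``min_fold`` and adjusted p <=
    ``alpha`` (reduced direction only).
    """
    counts = expression.counts.set_index("gene_id")
    ml, wl = expression.mut_library_size, expression.wt_library_size
    p0 = ml / (ml + wl)
    rows = []
    for gid in gene_ids:
        if gid not in counts.index:
            logger.warning("gene %s absent from expression table; skipped", gid)
            continue
        m = int(counts.at[gid, "mut_count"])
        w = int(counts.at[gid, "wt_count"])
        total = m + w
        if total == 0:
            logger.warning("gene %s has zero counts in both pools; skipped", gid)
            continue
        mut_norm = m / ml
        wt_norm = w / wl
        fold = mut_norm / wt_norm if wt_norm > 0 else float("inf")
        pval = binomtest(m, total, p0, alternative="two-sided").pvalue
        rows.append({"gene_id": gid, "mut_count": m, "wt_count": w,
                     "fold_change": fold, "pvalue": pval})
    if not rows:
        return _empty_expression_frame()
    df = pd.DataFrame(rows)
    df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    df["flagged"] = (df["fold_change"] <= min_fold) & (df["padj"] <= alpha)
    return df


class ExpressionScreen(BaseEstimator):
    """Estimator wrapper for the reduced-expression screen.

    ``fit(expression, gene_ids)`` exposes ``results_`` (the full test table)
    and ``flagged_`` (gene ids called reduced).
    """

    def __init__(self, alpha: float = 0.05, min_fold: float = 0.5):
        self.alpha = alpha
        self.min_fold = min_fold

    def fit(self, X: ExpressionTable, y: list[str] | None = None) -> "ExpressionScreen":
        gene_ids = y if y is not None else list(X.counts["gene_id"])
        self.results_ = expression_screen(X, gene_ids, alpha=self.alpha,
                                          min_fold=self.min_fold)
        self.flagged_ = list(self.results_.loc[self.results_["flagged"], "gene_id"]) \
            if len(self.results_) else []
        return self
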