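"""Genome and gene models used throughout the mapping pipeline.

A :class:`GenomeModel` is the minimal description of a mapping genome: a set
of chromosomes with physical and genetic lengths, a panel of strain-diagnostic
biallelic SNP markers, and optionally gene models for candidate annotation.
Coordinates are 1-based inclusive throughout (VCF/GFF3 convention); BED output
converts to 0-based half-open at write time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical length in bp and genetic length in cM.

    The genetic map is assumed uniform (constant cM/Mb within a chromosome),
    so genomic position ``p`` maps to ``p / length_bp * genetic_length_cm``
    centimorgans.
    """

    name: str
    length_bp: int
    genetic_length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ConfigurationError(f"chromosome {self.name}: length_bp must be > 0")
        if self.genetic_length_cm < 0:
            raise ConfigurationError(
                f"chromosome {self.name}: genetic_length_cm must be >= 0"
            )

    def bp_to_cm(self, pos_bp) -> np.ndarray:
        return np.asarray(pos_bp, dtype=float) / self.length_bp * self.genetic_length_cm


@dataclass
class GeneModel:
    """A single-transcript protein-coding gene model.

    Parameters
    ----------
    gene_id : str
        Identifier used in reports and expression tables.
    chrom : str
    strand : str
        ``"+"`` or ``"-"``.
    exons : list of (start, end)
        1-based inclusive genomic intervals, sorted by genomic coordinate,
        non-overlapping.
    cds_start, cds_end : int
        Genomic span of the coding sequence (1-based inclusive,
        ``cds_start <= cds_end`` regardless of strand).
    cds_sequence : str
        Spliced coding sequence, 5'->3' on the coding strand. Expected to
        start with ATG, end with a stop codon and have length divisible by 3;
        violations warn rather than fail (real annotations are imperfect).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        if any(s > e for s, e in self.exons):
            raise ValueError(f"{self.gene_id}: exon start > end")
        if sorted(self.exons) != self.exons:
            raise ValueError(f"{self.gene_id}: exons must be sorted by coordinate")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap")
        cds = self.cds_sequence.upper()
        if len(cds) % 3 != 0:
            warnings.warn(f"{self.gene_id}: CDS length {len(cds)} not divisible by 3")
        elif cds:
            if not cds.startswith("ATG"):
                warnings.warn(f"{self.gene_id}: CDS does not start with ATG")
            if cds[-3:] not in STOP_CODONS:
                warnings.warn(f"{self.gene_id}: CDS does not end with a stop codon")
        self.cds_sequence = cds

    # -- coordinate machinery -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def cds_segments(self) -> list[tuple[int, int]]:
        """Genomic CDS intervals in transcription (5'->3') order."""
        segs = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                segs.append((s2, e2))
        if self.strand == "-":
            segs = segs[::-1]
        return segs

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to a 0-based spliced-CDS coordinate.

        Returns ``None`` for positions outside the CDS (UTR, intron,
        intergenic).
        """
        offset = 0
        for s, e in self.cds_segments():
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None

    def genomic_ref_base(self, pos: int) -> str | None:
        """Reference base (genome forward strand) at a CDS position."""
        idx = self.genomic_to_cds(pos)
        if idx is None:
            return None
        base = self.cds_sequence[idx]
        return base if self.strand == "+" else reverse_complement(base)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def splice_distance(self, pos: int) -> int | None:
        """Distance (bp) into the nearest intron from an exon boundary.

        Returns ``None`` if ``pos`` is not intronic; otherwise the 1-based
        offset from the closest flanking exon edge (1 and 2 are the canonical
        splice dinucleotide positions).
        """
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < pos < s2:
                return min(pos - e1, s2 - pos)
        return None


@dataclass
class GenomeModel:
    """Chromosomes + marker panel + gene models.

    ``markers`` is a DataFrame with columns ``chrom, pos, ref, alt`` sorted by
    (chromosome order, position), positions strictly increasing within a
    chromosome.
    """

    chromosomes: list[Chromosome]
    markers: pd.DataFrame
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        by_name = {c.name: c for c in self.chromosomes}
        m = self.markers
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(m.columns):
            raise ConfigurationError(f"markers need columns {sorted(required)}")
        for chrom, grp in m.groupby("chrom", sort=False):
            if chrom not in by_name:
                raise ConfigurationError(f"marker chromosome {chrom!r} not in genome")
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ConfigurationError(f"{chrom}: marker positions must strictly increase")
            if pos[0] < 1 or pos[-1] > by_name[chrom].length_bp:
                raise ConfigurationError(f"{chrom}: marker position off chromosome")
        bad = ~(m["ref"].isin(NUCLEOTIDES) & m["alt"].isin(NUCLEOTIDES))
        if bad.any():
            raise ConfigurationError("marker alleles must be single nucleotides A/C/G/T")
        for g in self.genes:
            if g.chrom not in by_name:
                raise ConfigurationError(f"gene {g.gene_id}: chromosome {g.chrom} not in genome")
            if g.end > by_name[g.chrom].length_bp:
                raise ConfigurationError(f"gene {g.gene_id}: exons extend past chromosome end")

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def make_two_exon_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    cds_sequence: str,
    *,
    utr5: int = 50,
    utr3: int = 100,
    intron_length: int = 800,
    cds_split: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GeneModel, str]:
    """Build a two-exon gene model, returning (gene, genomic locus sequence).

    The returned sequence covers ``start .. gene.end`` on the genome forward
    strand, so it can be embedded in a synthetic contig for FASTA fixtures.
    UTRs are filled with random (or ``N``) sequence.
    """
    cds = cds_sequence.upper()
    if cds_split is None:
        cds_split = len(cds) // 2
    if not 0 < cds_split < len(cds):
        raise ValueError("cds_split must fall strictly inside the CDS")

    def _fill(n: int) -> str:
        if rng is None:
            return "N" * n
        return "".join(rng.choice(list(NUCLEOTIDES), size=n))

    part1, part2 = cds[:cds_split], cds[cds_split:]
    if strand == "+":
        exon1_seq = _fill(utr5) + part1
        exon2_seq = part2 + _fill(utr3)
    else:
        # genomic left-to-right: exon1 holds the 3' end of the transcript
        exon1_seq = _fill(utr3) + reverse_complement(part2)
        exon2_seq = reverse_complement(part1) + _fill(utr5)
    intron_seq = _fill(intron_length)
    e1 = (start, start + len(exon1_seq) - 1)
    e2 = (e1[1] + intron_length + 1, e1[1] + intron_length + len(exon2_seq))
    if strand == "+":
        cds_start = e1[0] + utr5
        cds_end = e2[0] + len(part2) - 1
    else:
        cds_start = e1[0] + utr3
        cds_end = e2[0] + len(part1) - 1
    gene = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=[e1, e2],
        cds_start=cds_start,
        cds_end=cds_end,
        cds_sequence=cds,
    )
    return gene, exon1_seq + intron_seq + exon2_seq


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random open reading frame: ATG + (n_codons-2) non-stop codons + TAA."""
    if n_codons < 2:
        raise ValueError("need at least start and stop codons")
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(rng.choice(list(NUCLEOTIDES), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def simulate_genome(
    n_chrom: int = 25,
    markers_per_chrom: int = 200,
    genes_per_chrom: int = 2,
    seed: int = 0,
    *,
    chrom_length_bp: int = 55_000_000,
    genetic_length_cm: float = 100.0,
) -> GenomeModel:
    """Simulate a zebrafish-like mapping genome.

    Defaults mirror a 25-chromosome genome with a roughly uniform genetic map
    (~100 cM per chromosome). Marker positions are drawn uniformly then
    sorted; every gene is a two-exon gene placed away from chromosome ends.
    Deterministic for a fixed seed.
    """
    if n_chrom < 1 or markers_per_chrom < 1:
        raise ConfigurationError("n_chrom and markers_per_chrom must be >= 1")
    if genes_per_chrom < 0:
        raise ConfigurationError("genes_per_chrom must be >= 0")
    rng = np.random.default_rng(seed)
    chroms, rows, genes = [], [], []
    for i in range(n_chrom):
        name = f"chr{i + 1}"
        chroms.append(Chromosome(name, chrom_length_bp, genetic_length_cm))
        pos = np.sort(
            rng.choice(
                np.arange(1, chrom_length_bp + 1, 1000), size=markers_per_chrom, replace=False
            )
        )
        ref = rng.choice(list(NUCLEOTIDES), size=markers_per_chrom)
        # alt differs from ref: shift by 1-3 in nucleotide order
        shift = rng.integers(1, 4, size=markers_per_chrom)
        order = {b: k for k, b in enumerate(NUCLEOTIDES)}
        alt = [NUCLEOTIDES[(order[r] + s) % 4] for r, s in zip(ref, shift)]
        rows.append(pd.DataFrame({"chrom": name, "pos": pos, "ref": ref, "alt": alt}))
        for j in range(genes_per_chrom):
            cds = random_cds(rng, int(rng.integers(100, 300)))
            start = int(rng.uniform(0.05, 0.9) * chrom_length_bp)
            strand = "+" if rng.random() < 0.5 else "-"
            gene, _ = make_two_exon_gene(
                f"{name}.g{j + 1}", name, strand, start, cds,
                intron_length=int(rng.integers(200, 2000)), rng=rng,
            )
            genes.append(gene)
    markers = pd.concat(rows, ignore_index=True)
    return GenomeModel(chromosomes=chroms, markers=markers, genes=genes)
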