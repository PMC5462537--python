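"""File formats: VCF 4.2 / TSV marker tables, GFF3 + FASTA gene models,
profile TSV, interval BED, expression TSV, truth sidecar.

Conventions: VCF/GFF3/report coordinates are 1-based inclusive; BED is
0-based half-open. The marker VCF carries two samples, ``MUT`` and ``WT``,
with per-sample allelic depths (``FORMAT AD:DP``).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .genome import GeneModel
from .linkage import LinkageInterval
from .markers import MARKER_COLUMNS
from .simulate import ExpressionTable

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------------
# marker count tables: VCF and TSV dialects
# --------------------------------------------------------------------------

def write_counts_vcf(table: pd.DataFrame, path: str | Path,
                     contig_lengths: dict[str, int] | None = None) -> None:
    """Write a marker count table as VCF 4.2 with samples MUT and WT."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths (ref,alt)">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    contigs = contig_lengths or {}
    for chrom in table["chrom"].unique():
        length = contigs.get(chrom)
        if length:
            header.add_line(f"##contig=<ID={chrom},length={length}>")
        else:
            header.add_line(f"##contig=<ID={chrom}>")
    header.add_sample("MUT")
    header.add_sample("WT")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in table.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom, start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            rec.samples["MUT"]["AD"] = (int(row.mut_ref), int(row.mut_alt))
            rec.samples["MUT"]["DP"] = int(row.mut_ref + row.mut_alt)
            rec.samples["WT"]["AD"] = (int(row.wt_ref), int(row.wt_alt))
            rec.samples["WT"]["DP"] = int(row.wt_ref + row.wt_alt)
            vcf.write(rec)


def read_counts_vcf(path: str | Path, multiallelic: str = "skip") -> pd.DataFrame:
    """Read a two-sample (MUT, WT) VCF with AD into a marker count table.

    Multiallelic records are skipped (logged) by default; ``multiallelic=
    "split"`` decomposes them into one row per alt allele (ref counts
    repeated). Missing AD raises :class:`FormatError` naming the record.
    Unsorted input is sorted with a warning.
    """
    if multiallelic not in ("skip", "split"):
        raise ValueError("multiallelic must be 'skip' or 'split'")
    rows = []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if "MUT" not in samples or "WT" not in samples:
            raise FormatError(f"{path}: VCF must contain samples MUT and WT")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                if multiallelic == "skip" or not alts:
                    n_multi += 1
                    continue
            for ai, alt in enumerate(alts):
                try:
                    mut_ad = rec.samples["MUT"]["AD"]
                    wt_ad = rec.samples["WT"]["AD"]
                except KeyError as exc:
                    raise FormatError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks AD"
                    ) from exc
                if mut_ad is None or wt_ad is None or mut_ad[0] is None:
                    raise FormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks AD")
                rows.append(
                    (rec.chrom, rec.pos, rec.ref, alt,
                     int(mut_ad[0]), int(mut_ad[1 + ai]),
                     int(wt_ad[0]), int(wt_ad[1 + ai]))
                )
                if multiallelic == "skip":
                    break
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    if not df.empty:
        chrom_order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
        key = df["chrom"].map(chrom_order)
        if not (key.is_monotonic_increasing and
                df.groupby("chrom", sort=False)["pos"].is_monotonic_increasing.all()):
            warnings.warn(f"{path}: records unsorted; sorting")
            df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def write_counts_tsv(table: pd.DataFrame, path: str | Path,
                     header_meta: dict | None = None) -> None:
    """TSV dialect of the marker count table, with ``#key=value`` headers."""
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"#{k}={v}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


# --------------------------------------------------------------------------
# profile, interval, expression, truth
# --------------------------------------------------------------------------

def write_profile_tsv(profile: pd.DataFrame, path: str | Path,
                      header_meta: dict | None = None) -> None:
    cols = ["chrom", "pos", "raw_freq", "folded_freq", "window_freq"]
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"#{k}={v}\n")
        profile[cols].to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_interval_bed(interval: LinkageInterval, path: str | Path,
                       name: str = "linkage_interval") -> None:
    chrom, start, end = interval.to_bed_fields()
    with open(path, "w") as fh:
        fh.write(f"{chrom}\t{start}\t{end}\t{name}\t"
                 f"{interval.peak_window_freq:.4f}\n")


def read_interval_bed(path: str | Path) -> LinkageInterval:
    line = Path(path).read_text().strip().splitlines()[0]
    chrom, start, end, _name, score = line.split("\t")
    return LinkageInterval(chrom, int(start) + 1, int(end),
                           float(score), n_markers_in_interval=0)


def write_expression_tsv(expr: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#mut_library_size={expr.mut_library_size}\n")
        fh.write(f"#wt_library_size={expr.wt_library_size}\n")
        expr.counts.to_csv(fh, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> ExpressionTable:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k] = v
    counts = pd.read_csv(path, sep="\t", comment="#")
    try:
        ml = int(meta["mut_library_size"])
        wl = int(meta["wt_library_size"])
    except KeyError:
        ml = int(counts["mut_count"].sum()) or 1
        wl = int(counts["wt_count"].sum()) or 1
        logger.info("%s: no library-size headers; using column totals", path)
    return ExpressionTable(counts=counts, mut_library_size=ml, wt_library_size=wl)


# --------------------------------------------------------------------------
# gene models: GFF3 + FASTA
# --------------------------------------------------------------------------

def write_gene_models_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write single-transcript gene models (gene/mRNA/exon/CDS) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid, tid = g.gene_id, f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tpoolmap\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={gid}\n")
            fh.write(f"{g.chrom}\tpoolmap\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={tid};Parent={gid}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tpoolmap\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={tid}.exon{i};Parent={tid}\n")
            # CDS pieces with phase, in genomic order
            segs = g.cds_segments()
            ordered = segs if g.strand == "+" else segs[::-1]
            phases = _cds_phases(segs)
            if g.strand == "-":
                phases = phases[::-1]
            for (s, e), ph in zip(ordered, phases):
                fh.write(f"{g.chrom}\tpoolmap\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\t"
                         f"ID={tid}.cds;Parent={tid}\n")


def _cds_phases(segs_tx_order: list[tuple[int, int]]) -> list[int]:
    phases, consumed = [], 0
    for s, e in segs_tx_order:
        phases.append((3 - consumed % 3) % 3)
        consumed += e - s + 1
    return phases


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_models(gff3_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Build :class:`GeneModel` objects from a GFF3 and its genome FASTA.

    Uses the first mRNA of each gene (multi-isoform resolution is out of
    scope); the spliced CDS is assembled strand-aware from the FASTA.
    """
    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    fasta = Fasta(str(fasta_path), rebuild=False)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = sorted((f.start, f.end) for f in db.children(parent, featuretype="exon"))
        cds_feats = sorted((f.start, f.end) for f in db.children(parent, featuretype="CDS"))
        if not exons or not cds_feats:
            logger.warning("gene %s lacks exon/CDS features; skipped", gene.id)
            continue
        cds_start = min(s for s, _ in cds_feats)
        cds_end = max(e for _, e in cds_feats)
        pieces = [str(fasta[gene.seqid][s - 1 : e]) for s, e in cds_feats]
        spliced = "".join(pieces).upper()
        if gene.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            exons=exons, cds_start=cds_start, cds_end=cds_end,
            cds_sequence=spliced,
        ))
    return genes
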