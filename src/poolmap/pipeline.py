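"""Pipeline orchestration: simulate -> discover -> map -> annotate.

:class:`PipelineConfig` collects every stage's parameters (defaults match
the individual modules), round-trips through YAML, and :func:`run_pipeline`
executes the stages, writing all artifacts plus a run manifest (config
hash, seed, package versions) so identical config+seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import CandidateReport, Variant, screen_interval_candidates
from .genome import ConfigurationError, simulate_genome
from .io import (
    read_counts_tsv,
    read_counts_vcf,
    read_expression_tsv,
    read_gene_models,
    write_counts_tsv,
    write_counts_vcf,
    write_expression_tsv,
    write_interval_bed,
    write_profile_tsv,
)
from .linkage import LinkageScanner
from .markers import MarkerSelector
from .simulate import CrossConfig, simulate_cross

logger = logging.getLogger(__name__)


@dataclass
class GenomeConfig:
    n_chrom: int = 25
    markers_per_chrom: int = 200
    genes_per_chrom: int = 2
    chrom_length_bp: int = 55_000_000
    genetic_length_cm: float = 100.0


@dataclass
class MarkerFilterConfig:
    min_depth: int = 20
    wt_af_min: float = 0.2
    wt_af_max: float = 0.8
    min_mut_depth: int | None = None


@dataclass
class MappingConfig:
    window_size: int = 50
    peak_threshold: float = 0.98
    threshold_mode: str = "relative"
    statistic: str = "folded"
    alignment: str = "centered"


@dataclass
class AnnotationConfig:
    alpha: float = 0.05
    min_fold: float = 0.5


@dataclass
class PipelineConfig:
    """Full pipeline configuration (simulation mode or file mode)."""

    seed: int = 0
    mode: str = "simulate"  # "simulate" or "files"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    cross: CrossConfig = field(default_factory=CrossConfig)
    marker_filter: MarkerFilterConfig = field(default_factory=MarkerFilterConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    # file-mode inputs
    counts_vcf: str | None = None
    counts_tsv: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    expression_tsv: str | None = None
    make_plot: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "genome": GenomeConfig, "cross": CrossConfig,
            "marker_filter": MarkerFilterConfig, "mapping": MappingConfig,
            "annotation": AnnotationConfig,
        }
        kwargs = {}
        for k, v in d.items():
            if k in sub and isinstance(v, dict):
                if k == "cross" and isinstance(v.get("causative"), list):
                    v = {**v, "causative": tuple(v["causative"])}
                kwargs[k] = sub[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> CandidateReport:
    """Run the full analysis; artifacts land in ``outdir``.

    Returns the :class:`CandidateReport`. Simulation mode generates the
    inputs from the planted cross; file mode reads a counts VCF/TSV plus
    optional GFF3+FASTA and expression TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        if config.mode == "simulate":
            stage = "simulate"
            config.cross.seed = config.seed
            genome = simulate_genome(
                config.genome.n_chrom, config.genome.markers_per_chrom,
                config.genome.genes_per_chrom, seed=config.seed,
                chrom_length_bp=config.genome.chrom_length_bp,
                genetic_length_cm=config.genome.genetic_length_cm,
            )
            table, expression, truth = simulate_cross(genome, config.cross)
            genes = genome.genes
            contig_lengths = {c.name: c.length_bp for c in genome.chromosomes}
            write_counts_vcf(table, outdir / "markers.vcf", contig_lengths)
            write_counts_tsv(table, outdir / "markers.tsv",
                             {"seed": config.seed, "mode": "simulate"})
            write_expression_tsv(expression, outdir / "expression.tsv")
            (outdir / "truth.json").write_text(truth.to_json())
        else:
            stage = "load"
            if config.counts_vcf:
                table = read_counts_vcf(config.counts_vcf)
            elif config.counts_tsv:
                table = read_counts_tsv(config.counts_tsv)
            else:
                raise ConfigurationError("file mode requires counts_vcf or counts_tsv")
            truth = None
            genes = []
            if config.gff3:
                if not config.fasta:
                    raise ConfigurationError("gff3 given without fasta")
                genes = read_gene_models(config.gff3, config.fasta)
            expression = (read_expression_tsv(config.expression_tsv)
                          if config.expression_tsv else None)

        stage = "discover"
        selector = MarkerSelector(**dataclasses.asdict(config.marker_filter))
        retained = selector.fit(table).transform(table)
        write_counts_tsv(
            retained, outdir / "mapping_markers.tsv",
            {"n_input": len(table), "n_retained": len(retained),
             **{f"filter.{k}": v for k, v in selector.get_params().items()}},
        )

        stage = "map"
        scanner = LinkageScanner(
            window_size=config.mapping.window_size,
            peak_threshold=config.mapping.peak_threshold,
            threshold_mode=config.mapping.threshold_mode,
            statistic=config.mapping.statistic,
            alignment=config.mapping.alignment,
        ).fit(retained)
        write_profile_tsv(scanner.profile_, outdir / "profile.tsv",
                          {"window_size": config.mapping.window_size})
        if scanner.interval_ is not None:
            write_interval_bed(scanner.interval_, outdir / "interval.bed")
        if config.make_plot:
            from .plotting import plot_genome_scan
            plot_genome_scan(scanner.profile_, outdir / "genome_scan.png",
                             scanner.interval_)

        stage = "annotate"
        if scanner.interval_ is None:
            raise ConfigurationError("no linkage detected; nothing to annotate")
        variants = [
            Variant(r.chrom, int(r.pos), r.ref, r.alt)
            for r in retained.itertuples(index=False)
            if scanner.interval_.contains(r.chrom, int(r.pos))
        ]
        report = screen_interval_candidates(
            scanner.interval_, variants, genes, expression,
            alpha=config.annotation.alpha, min_fold=config.annotation.min_fold,
        )
        report.effects_frame().to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        if len(report.reduced_genes):
            report.reduced_genes.to_csv(outdir / "expression_screen.tsv",
                                        sep="\t", index=False, float_format="%.6g")

        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "window_size": config.mapping.window_size,
            "n_mutant_pool": config.cross.n_mutant_pool,
            "n_wildtype_pool": config.cross.n_wildtype_pool,
            "n_markers_input": int(len(table)),
            "n_markers_retained": int(len(retained)),
            "marker_rejections": selector.rejection_tally_,
            "linkage_status": scanner.status_,
            "interval": dataclasses.asdict(scanner.interval_),
            "effect_tallies": report.tallies,
            "versions": {
                "poolmap": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return report
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise
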