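"""Simulate a recessive F2 mapping cross with pooled sequencing readout.

The mapped generation is an incross of two heterozygous carriers. Both
parents are F1 hybrids between the mutagenesis background (carrying the
causative lesion) and the mapping background, so every marker in the panel is
heterozygous in both parents and segregates 0.5/0.5 in gametes. By
convention the ``ref`` allele of every marker is the mapping-strain allele
(the reference genome background) and the ``alt`` allele is the
mutagenesis-strain allele that rides on the lesion-bearing haplotype; at a
fully linked marker the mutant pool is therefore homozygous ``alt``.

Meiosis is modelled per gamete and chromosome as a Poisson number of
crossovers with mean equal to the genetic length in Morgans, breakpoints
uniform on the genetic map, no interference and no obligate chiasma. The
genetic map is uniform (constant cM/Mb) within a chromosome.

Individuals are phenotyped at the causative locus: homozygous carriers go to
the mutant pool, the remaining genotype classes (1 +/+ : 2 +/- by
segregation) feed the wildtype-sibling pool. Pooled sequencing draws a
Poisson read depth per marker per pool and samples alleles binomially from
the pool allele frequency with a symmetric per-base error rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ConfigurationError, GenomeModel

logger = logging.getLogger(__name__)


@dataclass
class CrossConfig:
    """Parameters of the simulated mapping cross.

    Attributes
    ----------
    n_mutant_pool : int
        Number of phenotypically mutant (-/-) larvae pooled (default 108).
    n_wildtype_pool : int
        Number of wildtype siblings (+/+ and +/-) pooled (default 108).
    causative : (chrom, pos) or None
        Planted lesion position. ``None`` draws a marker position in the
        central 60% of a random chromosome, so the lesion coincides with a
        marker and stays clear of window-undefined chromosome ends.
    mean_depth : float
        Expected reads per marker per pool (Poisson).
    seq_error_rate : float
        Symmetric per-base sequencing error probability.
    phenotyping_error_rate : float
        Probability that a pooled "mutant" larva is actually a misphenotyped
        non-mutant sibling. Nonzero values cap the mapping peak below 1.
    expression_fold : float
        Fold change applied to the planted reduced-expression gene in the
        mutant pool.
    planted_gene_mean : float
        Baseline expected count of the planted gene.
    expression_mean_log, expression_sigma_log : float
        Lognormal parameters for the other genes' expected counts.
    expression_dispersion : float or None
        If set, per-gene counts are negative binomial with this dispersion
        (variance = mu + dispersion * mu^2); Poisson otherwise.
    seed : int
    """

    n_mutant_pool: int = 108
    n_wildtype_pool: int = 108
    causative: tuple[str, int] | None = None
    mean_depth: float = 50.0
    seq_error_rate: float = 0.005
    phenotyping_error_rate: float = 0.0
    expression_fold: float = 0.2
    planted_gene_mean: float = 500.0
    expression_mean_log: float = 5.0
    expression_sigma_log: float = 1.0
    expression_dispersion: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_mutant_pool < 1 or self.n_wildtype_pool < 1:
            raise ConfigurationError("pool sizes must be >= 1")
        if not 0 <= self.seq_error_rate < 0.5:
            raise ConfigurationError("seq_error_rate must be in [0, 0.5)")
        if not 0 <= self.phenotyping_error_rate < 1:
            raise ConfigurationError("phenotyping_error_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        if not 0 < self.expression_fold:
            raise ConfigurationError("expression_fold must be > 0")


@dataclass
class ExpressionTable:
    """Per-gene pooled RNA-seq counts for the two pools."""

    counts: pd.DataFrame  # columns: gene_id, mut_count, wt_count
    mut_library_size: int
    wt_library_size: int

    def __post_init__(self) -> None:
        if (self.counts[["mut_count", "wt_count"]] < 0).any().any():
            raise ValueError("expression counts must be >= 0")
        if self.mut_library_size <= 0 or self.wt_library_size <= 0:
            raise ValueError("library sizes must be > 0")


@dataclass
class CrossTruth:
    """Ground truth of a simulated cross, for parameter-recovery tests."""

    causative: tuple[str, int]
    causative_marker_index: int | None
    seed: int
    n_mutant_pool: int
    n_wildtype_pool: int
    # haplotype dosage of the mutagenesis-background (alt) allele, one row
    # per pooled individual, one column per marker (0/1/2)
    mut_pool_diplotypes: np.ndarray = field(repr=False)
    wt_pool_diplotypes: np.ndarray = field(repr=False)
    mut_pool_true_alt: np.ndarray = field(repr=False)
    wt_pool_true_alt: np.ndarray = field(repr=False)
    planted_gene: str | None = None
    expression_fold: float = 1.0
    n_misphenotyped: int = 0

    def to_json(self) -> str:
        d = {
            "causative": list(self.causative),
            "causative_marker_index": self.causative_marker_index,
            "seed": self.seed,
            "n_mutant_pool": self.n_mutant_pool,
            "n_wildtype_pool": self.n_wildtype_pool,
            "planted_gene": self.planted_gene,
            "expression_fold": self.expression_fold,
            "n_misphenotyped": self.n_misphenotyped,
            "mut_pool_true_alt": self.mut_pool_true_alt.tolist(),
            "wt_pool_true_alt": self.wt_pool_true_alt.tolist(),
        }
        return json.dumps(d, indent=1)


def _gamete_alleles(
    rng: np.random.Generator, gpos_cm: np.ndarray, length_cm: float, n: int
) -> np.ndarray:
    """Sample n gametes of an F1 heterozygote at the given map positions.

    Returns an (n, len(gpos_cm)) array of 0/1 haplotype labels, where 1 is
    the mutagenesis-background haplotype. Crossover counts are Poisson with
    mean length_cm/100, breakpoints uniform on the genetic map.
    """
    start = rng.integers(0, 2, size=n)
    out = np.empty((n, gpos_cm.size), dtype=np.int8)
    if length_cm == 0:
        out[:] = start[:, None]
        return out
    counts = rng.poisson(length_cm / 100.0, size=n)
    for k in np.unique(counts):
        idx = np.flatnonzero(counts == k)
        if k == 0:
            out[idx] = start[idx, None]
            continue
        bp = np.sort(rng.uniform(0.0, length_cm, size=(idx.size, k)), axis=1)
        ncross = (bp[:, :, None] <= gpos_cm[None, None, :]).sum(axis=1)
        out[idx] = (start[idx, None] + ncross) % 2
    return out


def _sample_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float | None
) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mu)
    # NB with variance mu + dispersion*mu^2, gamma-Poisson mixture
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mu / shape))


def simulate_cross(
    genome: GenomeModel, config: CrossConfig
) -> tuple[pd.DataFrame, ExpressionTable, CrossTruth]:
    """Simulate the cross and pooled readout.

    Returns
    -------
    markers : DataFrame
        Columns ``chrom, pos, ref, alt, mut_ref, mut_alt, wt_ref, wt_alt``.
    expression : ExpressionTable
    truth : CrossTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = genome.markers.reset_index(drop=True)
    chrom_names = genome.chromosome_names

    # --- causative locus ---------------------------------------------------
    if config.causative is None:
        c_chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        chrom_markers = markers[markers["chrom"] == c_chrom]
        if chrom_markers.empty:
            raise ConfigurationError(f"no markers on chromosome {c_chrom}")
        L = genome.chromosome(c_chrom).length_bp
        central = chrom_markers[
            (chrom_markers["pos"] >= 0.2 * L) & (chrom_markers["pos"] <= 0.8 * L)
        ]
        pick = central if not central.empty else chrom_markers
        c_pos = int(pick["pos"].iloc[int(rng.integers(len(pick)))])
        causative = (c_chrom, c_pos)
    else:
        causative = (str(config.causative[0]), int(config.causative[1]))
        c_chrom, c_pos = causative
        if c_chrom not in chrom_names:
            raise ConfigurationError(f"causative chromosome {c_chrom!r} not in genome")
        if not 1 <= c_pos <= genome.chromosome(c_chrom).length_bp:
            raise ConfigurationError("causative position off chromosome")
        if markers[markers["chrom"] == c_chrom].empty:
            raise ConfigurationError(f"no markers on causative chromosome {c_chrom}")

    hit = markers[(markers["chrom"] == c_chrom) & (markers["pos"] == c_pos)]
    causative_marker_index = int(hit.index[0]) if len(hit) else None

    # --- per-chromosome map positions (causative inserted on its chrom) ----
    chrom_layout: list[tuple[str, np.ndarray, np.ndarray, float, int | None]] = []
    # (name, marker column indices, gpos incl causative, length_cm, causative slot)
    col0 = 0
    for c in genome.chromosomes:
        grp = markers[markers["chrom"] == c.name]
        cols = np.arange(col0, col0 + len(grp))
        col0 += len(grp)
        pos = grp["pos"].to_numpy(dtype=float)
        c_slot = None
        if c.name == c_chrom:
            insert_at = int(np.searchsorted(pos, c_pos))
            if causative_marker_index is not None:
                c_slot = int(np.searchsorted(pos, c_pos))
                gpos = c.bp_to_cm(pos)
            else:
                pos = np.insert(pos, insert_at, float(c_pos))
                c_slot = insert_at
                gpos = c.bp_to_cm(pos)
        else:
            gpos = c.bp_to_cm(pos)
        chrom_layout.append((c.name, cols, gpos, c.genetic_length_cm, c_slot))

    n_markers = len(markers)
    n_mut, n_wt = config.n_mutant_pool, config.n_wildtype_pool
    # pre-draw which mutant-pool slots are misphenotyped siblings
    contaminated = rng.random(n_mut) < config.phenotyping_error_rate
    n_clean = int(n_mut - contaminated.sum())
    n_sibs_needed = n_wt + int(contaminated.sum())

    clean_rows: list[np.ndarray] = []
    sib_rows: list[np.ndarray] = []
    batch = 256
    guard = 0
    while len(clean_rows) < n_clean or len(sib_rows) < n_sibs_needed:
        guard += 1
        if guard > 2000:  # ~500k individuals; only reachable on degenerate configs
            raise RuntimeError("failed to fill pools; check cross configuration")
        dosage = np.empty((batch, n_markers), dtype=np.int8)
        caus_dosage = np.zeros(batch, dtype=np.int8)
        for name, cols, gpos, length_cm, c_slot in chrom_layout:
            g1 = _gamete_alleles(rng, gpos, length_cm, batch)
            g2 = _gamete_alleles(rng, gpos, length_cm, batch)
            d = g1 + g2
            if c_slot is not None and cols.size and causative_marker_index is None:
                caus_dosage = d[:, c_slot]
                d = np.delete(d, c_slot, axis=1)
            elif c_slot is not None:
                caus_dosage = d[:, c_slot]
            if cols.size:
                dosage[:, cols] = d
        is_mut = caus_dosage == 2
        for i in range(batch):
            if is_mut[i]:
                if len(clean_rows) < n_clean:
                    clean_rows.append(dosage[i])
            else:
                if len(sib_rows) < n_sibs_needed:
                    sib_rows.append(dosage[i])
        # (extras discarded; loop exits when both pools are full)

    sib_rows_arr = np.array(sib_rows, dtype=np.int8)
    wt_pool = sib_rows_arr[:n_wt]
    mis = sib_rows_arr[n_wt:]
    mut_list: list[np.ndarray] = []
    ci, mi = 0, 0
    for slot in range(n_mut):
        if contaminated[slot]:
            mut_list.append(mis[mi]); mi += 1
        else:
            mut_list.append(clean_rows[ci]); ci += 1
    mut_pool = np.array(mut_list, dtype=np.int8)

    mut_true_alt = mut_pool.sum(axis=0).astype(np.int64)
    wt_true_alt = wt_pool.sum(axis=0).astype(np.int64)

    # --- pooled read sampling ----------------------------------------------
    e = config.seq_error_rate
    out = markers.copy()
    for pool, true_alt, n_pool in (
        ("mut", mut_true_alt, n_mut),
        ("wt", wt_true_alt, n_wt),
    ):
        q = true_alt / (2.0 * n_pool)
        p = q * (1 - e) + (1 - q) * e
        depth = rng.poisson(config.mean_depth, size=n_markers)
        alt_reads = rng.binomial(depth, p)
        out[f"{pool}_ref"] = depth - alt_reads
        out[f"{pool}_alt"] = alt_reads

    # --- expression --------------------------------------------------------
    gene_ids = [g.gene_id for g in genome.genes]
    planted = None
    if genome.genes:
        on_chrom = [g for g in genome.genes if g.chrom == c_chrom]
        if on_chrom:
            planted = min(on_chrom, key=lambda g: abs((g.start + g.end) // 2 - c_pos)).gene_id
    base = rng.lognormal(config.expression_mean_log, config.expression_sigma_log, len(gene_ids))
    if planted is not None:
        base[gene_ids.index(planted)] = config.planted_gene_mean
    mut_mu = base.copy()
    if planted is not None:
        mut_mu[gene_ids.index(planted)] = config.planted_gene_mean * config.expression_fold
    mut_counts = _sample_counts(rng, mut_mu, config.expression_dispersion)
    wt_counts = _sample_counts(rng, base, config.expression_dispersion)
    expr_df = pd.DataFrame(
        {"gene_id": gene_ids, "mut_count": mut_counts.astype(np.int64),
         "wt_count": wt_counts.astype(np.int64)}
    )
    expression = ExpressionTable(
        counts=expr_df,
        mut_library_size=int(max(mut_counts.sum(), 1)),
        wt_library_size=int(max(wt_counts.sum(), 1)),
    )

    truth = CrossTruth(
        causative=causative,
        causative_marker_index=causative_marker_index,
        seed=config.seed,
        n_mutant_pool=n_mut,
        n_wildtype_pool=n_wt,
        mut_pool_diplotypes=mut_pool,
        wt_pool_diplotypes=wt_pool,
        mut_pool_true_alt=mut_true_alt,
        wt_pool_true_alt=wt_true_alt,
        planted_gene=planted,
        expression_fold=config.expression_fold,
        n_misphenotyped=int(contaminated.sum()),
    )
    logger.info(
        "simulated cross: causative=%s:%d, %d markers, %d+%d pooled larvae",
        causative[0], causative[1], n_markers, n_mut, n_wt,
    )
    return out, expression, truth
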