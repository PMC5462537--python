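import numpy as np
import pandas as pd
import pytest

import poolmap as pm


@pytest.fixture(scope="session")
def small_genome() -> pm.GenomeModel:
    """3 chromosomes x 60 markers, a couple of genes, 40 Mb / 100 cM each."""
    return pm.simulate_genome(3, 60, 2, seed=11, chrom_length_bp=40_000_000)


@pytest.fixture(scope="session")
def small_cross(small_genome):
    cfg = pm.CrossConfig(seed=7, seq_error_rate=0.0)
    table, expression, truth = pm.simulate_cross(small_genome, cfg)
    return table, expression, truth


@pytest.fixture()
def marker_row():
    def make(chrom="chr1", pos=100, ref="A", alt="G",
             mut=(10, 40), wt=(25, 25)):
        return pd.DataFrame(
            [{"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
              "mut_ref": mut[0], "mut_alt": mut[1],
              "wt_ref": wt[0], "wt_alt": wt[1]}]
        )
    return make


@pytest.fixture(scope="session")
def example_locus():
    from poolmap.datasets import two_exon_locus_example
    return two_exon_locus_example()


def profile_from_folded(folded, chrom="chr1"):
    """Build a marker table whose folded mutant frequencies equal `folded`.

    Uses depth-1000 read counts so alt/(alt+ref) is exact to float precision
    for the rational frequencies used in tests.
    """
    folded = np.asarray(folded, dtype=float)
    depth = 1000
    alt = np.round(folded * depth).astype(int)
    return pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, folded.size + 1) * 1000,
        "ref": "A", "alt": "G",
        "mut_ref": depth - alt, "mut_alt": alt,
        "wt_ref": depth // 2, "wt_alt": depth // 2,
    })
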