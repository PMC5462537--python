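import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import poolmap as pm
from conftest import profile_from_folded


# ---------------------------------------------------------------- frequencies

@pytest.mark.parametrize("ref, alt, expected", [
    (0, 10, 1.0), (12, 0, 0.0), (1, 3, 0.75),
])
def test_mutant_allele_frequency(ref, alt, expected):
    assert pm.mutant_allele_frequency(ref, alt) == expected


def test_zero_depth_marker_is_no_data_not_error():
    assert np.isnan(pm.mutant_allele_frequency(0, 0))
    table = profile_from_folded([0.9, 0.9, 0.9])
    table.loc[1, ["mut_ref", "mut_alt"]] = 0
    prof = pm.sliding_window_profile(table, window_size=3)
    assert prof["no_data"].tolist() == [False, True, False]
    assert prof["window_freq"].isna().all()  # only 2 usable markers < window


@pytest.mark.parametrize("raw, folded", [
    (0.5, 0.5), (0.1, 0.9), (1.0, 1.0), (0.0, 1.0), (0.75, 0.75),
])
def test_fold_frequency(raw, folded):
    assert pm.fold_frequency(raw) == pytest.approx(folded)


# ---------------------------------------------------------------- windows

def test_constant_profile_windows_are_constant():
    prof = pm.sliding_window_profile(profile_from_folded([0.5] * 60), window_size=50)
    defined = prof["window_freq"].dropna()
    assert len(defined) == 11  # 60 - 50 + 1 centered placements
    assert (defined == 0.5).all()


def test_window_means_of_consecutive_triples():
    prof = pm.sliding_window_profile(
        profile_from_folded([1, 1, 1, 0.5, 0.5]), window_size=3
    )
    w = prof["window_freq"]
    assert np.isnan(w.iloc[0]) and np.isnan(w.iloc[4])
    assert w.iloc[1:4].tolist() == pytest.approx([1.0, 5 / 6, 2 / 3])


def naive_window_means(vals, w, alignment="centered"):
    """Brute-force O(n*w) re-computation of every window mean."""
    out = np.full(len(vals), np.nan)
    for i in range(len(vals)):
        if alignment == "centered":
            lo, hi = i - (w - 1) // 2, i + w // 2
        else:
            lo, hi = i - w + 1, i
        if lo < 0 or hi >= len(vals):
            continue
        out[i] = np.mean(vals[lo : hi + 1])
    return out


@pytest.mark.parametrize("w", [1, 2, 3, 7, 50])
@pytest.mark.parametrize("alignment", ["centered", "trailing"])
def test_window_equals_naive_oracle(w, alignment):
    rng = np.random.default_rng(100 + w)
    vals = 0.5 + 0.5 * rng.random(73)
    prof = pm.sliding_window_profile(profile_from_folded(vals), window_size=w,
                                     alignment=alignment)
    expected = naive_window_means(prof["folded_freq"].to_numpy(), w, alignment)
    np.testing.assert_allclose(prof["window_freq"], expected, rtol=1e-12)


def test_windows_never_span_chromosome_boundaries():
    a = profile_from_folded([1.0] * 10, chrom="chr1")
    b = profile_from_folded([0.5] * 10, chrom="chr2")
    prof = pm.sliding_window_profile(pd.concat([a, b], ignore_index=True),
                                     window_size=5)
    chr1 = prof[prof["chrom"] == "chr1"]["window_freq"].dropna()
    chr2 = prof[prof["chrom"] == "chr2"]["window_freq"].dropna()
    assert (chr1 == 1.0).all() and (chr2 == 0.5).all()  # no mixing across the edge


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    vals=st.lists(st.floats(0.5, 1.0), min_size=1, max_size=60),
    w=st.sampled_from([1, 2, 3, 7, 50]),
)
def test_window_bounded_by_its_inputs(vals, w):
    prof = pm.sliding_window_profile(profile_from_folded(vals), window_size=w)
    folded = prof["folded_freq"].to_numpy()
    for i, wv in enumerate(prof["window_freq"]):
        if np.isnan(wv):
            continue
        lo, hi = i - (w - 1) // 2, i + w // 2
        seg = folded[lo : hi + 1]
        assert seg.min() - 1e-9 <= wv <= seg.max() + 1e-9


# ---------------------------------------------------------------- interval call

def test_plateau_interval_matches_bruteforce_argmax_expansion():
    vals = np.full(300, 0.55)
    vals[120:181] = 1.0
    prof = pm.sliding_window_profile(profile_from_folded(vals), window_size=3)
    res = pm.find_linkage_region(prof, peak_threshold=0.98, threshold_mode="absolute")
    # brute-force oracle: argmax then expand while >= 0.98
    w = prof["window_freq"].to_numpy()
    k = int(np.nanargmax(w))
    lo = k
    while lo > 0 and w[lo - 1] >= 0.98:
        lo -= 1
    hi = k
    while hi < len(w) - 1 and w[hi + 1] >= 0.98:
        hi += 1
    assert res.interval.start_bp == prof.at[lo, "pos"]
    assert res.interval.end_bp == prof.at[hi, "pos"]
    assert res.interval.peak_window_freq == 1.0


def test_flat_profile_reports_no_linkage():
    prof = pm.sliding_window_profile(profile_from_folded([0.55] * 80), window_size=5)
    res = pm.find_linkage_region(prof)
    assert res.status == "no_linkage"
    assert res.interval is None


def test_tied_peaks_prefer_longest_run_then_lowest_coordinate():
    a = profile_from_folded([0.5] * 10 + [1.0] * 2 + [0.5] * 10, chrom="chr1")
    b = profile_from_folded([0.5] * 8 + [1.0] * 6 + [0.5] * 8, chrom="chr2")
    prof = pm.sliding_window_profile(pd.concat([a, b], ignore_index=True),
                                     window_size=1)
    res = pm.find_linkage_region(prof)
    assert res.interval.chrom == "chr2"  # longer tied plateau wins


def test_chromosome_summary_is_ranked(small_cross):
    table, _, truth = small_cross
    sc = pm.LinkageScanner(window_size=15).fit(pm.select_mapping_markers(table))
    s = sc.chrom_summary_
    assert list(s["max_window_freq"]) == sorted(s["max_window_freq"], reverse=True)
    assert s["chrom"].iloc[0] == truth.causative[0]


def test_scanner_recovers_planted_locus(small_cross):
    table, _, truth = small_cross
    sc = pm.LinkageScanner(window_size=15).fit(pm.select_mapping_markers(table))
    assert sc.status_ == "ok"
    assert sc.interval_.contains(*truth.causative)
    assert sc.interval_.peak_window_freq == sc.profile_["window_freq"].max()


def test_recombination_suppressed_cross_peaks_at_exactly_one():
    g = pm.GenomeModel(
        chromosomes=[pm.Chromosome("chr1", 10_000_000, 0.0),
                     pm.Chromosome("chr2", 10_000_000, 100.0)],
        markers=pd.DataFrame({
            "chrom": ["chr1"] * 10 + ["chr2"] * 10,
            "pos": list(range(100_000, 1_100_000, 100_000)) * 2,
            "ref": "A", "alt": "G",
        }),
    )
    cfg = pm.CrossConfig(causative=("chr1", 500_000), seq_error_rate=0.0, seed=2)
    table, _, _ = pm.simulate_cross(g, cfg)
    sc = pm.LinkageScanner(window_size=5).fit(table)
    assert sc.interval_.peak_window_freq == 1.0
    assert sc.interval_.chrom == "chr1"


def test_unlinked_background_folded_frequency_stays_low(small_genome):
    """Folded binomial baseline: unlinked markers average < 0.60, so the
    homozygosity peak is detectable against the background."""
    vals = []
    for seed in range(30):
        cfg = pm.CrossConfig(causative=("chr1", 20_000_000), seed=seed)
        table, _, _ = pm.simulate_cross(small_genome, cfg)
        off = table[table["chrom"] != "chr1"]
        vals.append(pm.fold_frequency(
            pm.mutant_allele_frequency(off["mut_ref"], off["mut_alt"])
        ).mean())
    assert np.nanmean(vals) < 0.60


def test_profile_requires_defined_windows():
    prof = pm.sliding_window_profile(profile_from_folded([0.9] * 3), window_size=50)
    with pytest.raises(ValueError):
        pm.find_linkage_region(prof)


def test_bed_conversion_is_half_open():
    iv = pm.LinkageInterval("chr5", 100, 200, 0.99, 10)
    assert iv.to_bed_fields() == ("chr5", 99, 200)
    assert iv.length_bp == 101
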