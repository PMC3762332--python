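"""Peak filtering, summit methylation, and central-CpG k-mer enrichment."""

from collections import Counter
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from mcpgbind import chip_methylome as cm
from mcpgbind.chip_methylome import MethylomeRecord, Peak


# ---------------------------------------------------------------------------
# peaks: construction, filtering, BED round-trip
# ---------------------------------------------------------------------------

def test_peak_invariants():
    with pytest.raises(ValueError):
        Peak("chr1", 100, 100, 100)
    with pytest.raises(ValueError):
        Peak("chr1", 100, 200, 250)


def test_filter_strictly_shorter():
    peaks = [Peak("chr1", 0, L, L // 2) for L in (152, 300, 371, 6062)]
    kept = cm.filter_peaks(peaks, max_length=371)
    assert [p.length for p in kept] == [152, 300]


def test_filter_quantile_one_keeps_all():
    peaks = [Peak("chr1", 0, L, L // 2) for L in (100, 200, 300)]
    assert len(cm.filter_peaks(peaks, quantile=1.0)) == 3


def test_filter_quantile_matches_sorted_percentile():
    rng = np.random.default_rng(0)
    lengths = rng.integers(150, 1000, size=1000)
    peaks = [Peak("chr1", 0, int(L), int(L) // 2) for L in lengths]
    kept = cm.filter_peaks(peaks, quantile=0.95)
    # independent sort-based quantile (linear interpolation)
    s = np.sort(lengths)
    rank = 0.95 * (len(s) - 1)
    lo, hi = int(np.floor(rank)), int(np.ceil(rank))
    cutoff = s[lo] + (rank - lo) * (s[hi] - s[lo])
    assert {p.length for p in kept} == {int(L) for L in lengths if L < cutoff}


def test_bed_roundtrip(tmp_path):
    peaks = [Peak("chr1", 100, 300, 200), Peak("chr2", 0, 50, 10)]
    path = tmp_path / "peaks.bed"
    cm.write_peaks_bed(path, peaks)
    assert cm.read_peaks_bed(path) == peaks
    cm.write_peaks_bed(tmp_path / "again.bed", cm.read_peaks_bed(path))
    assert (tmp_path / "again.bed").read_text() == path.read_text()


# ---------------------------------------------------------------------------
# summit methylation and categorization
# ---------------------------------------------------------------------------

def methylome_at(counts: dict[int, tuple[int, int]]):
    return {("chr1", pos): MethylomeRecord("chr1", pos, k, n)
            for pos, (k, n) in counts.items()}


def test_summit_methylation_pools_read_counts():
    peak = Peak("chr1", 100, 300, 200)
    meth = methylome_at({190: (9, 10), 210: (7, 10)})
    assert cm.summit_methylation(peak, meth) == pytest.approx(16 / 20)


def test_summit_without_cpgs_is_undefined():
    peak = Peak("chr1", 100, 300, 200)
    assert cm.summit_methylation(peak, methylome_at({500: (5, 10)})) is None


def test_pooled_vs_unweighted_mean():
    peak = Peak("chr1", 100, 300, 200)
    meth = methylome_at({195: (1, 10), 205: (90, 100)})
    assert cm.summit_methylation(peak, meth, pooled=True) == pytest.approx(91 / 110)
    assert cm.summit_methylation(peak, meth, pooled=False) == pytest.approx(
        (0.1 + 0.9) / 2)


def test_categorize_counting_and_boundaries():
    frac = cm.categorize_methylation([0.9, 0.85, 0.1, 0.5])
    assert frac == {"high": 0.5, "low": 0.25, "mid": 0.25}
    assert cm.categorize_methylation([1.0, 1.0]) == {
        "high": 1.0, "low": 0.0, "mid": 0.0}
    # the M = 0.8 boundary counts as high, M = 0.2 as mid
    assert cm.categorize_methylation([0.8])["high"] == 1.0
    assert cm.categorize_methylation([0.2])["mid"] == 1.0


def test_categorize_fractions_sum_to_one_uniform_levels():
    rng = np.random.default_rng(4)
    levels = rng.uniform(0, 1, 10_000).tolist()
    frac = cm.categorize_methylation(levels)
    assert frac["high"] + frac["low"] + frac["mid"] == pytest.approx(1.0)
    se = np.sqrt(0.2 * 0.8 / 10_000)
    assert frac["high"] == pytest.approx(0.2, abs=2 * se)
    assert frac["low"] == pytest.approx(0.2, abs=2 * se)


# ---------------------------------------------------------------------------
# foreground/background sequence extraction
# ---------------------------------------------------------------------------

def test_fg_bg_coordinates():
    genome = {"chr1": "A" * 1000}
    peaks = [Peak("chr1", 100, 300, 200)]
    fg, bg = cm.build_fg_bg(peaks, genome)
    assert len(fg[0]) == 2 * 60 + 1  # [140, 261)
    assert len(bg[0]) == (300 - 100) + 2 * 50  # [50, 350)


def test_fg_clipped_at_chromosome_start():
    genome = {"chr1": "A" * 1000}
    peaks = [Peak("chr1", 0, 200, 20)]
    fg, _ = cm.build_fg_bg(peaks, genome)
    assert len(fg[0]) == 81  # [0, 81)


def test_fg_length_constant_for_interior_summits():
    rng = np.random.default_rng(1)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
    peaks = [Peak("chr1", s, s + 200, s + 100)
             for s in rng.integers(100, 4500, size=20)]
    fg, _ = cm.build_fg_bg(peaks, genome)
    assert {len(s) for s in fg} == {121}


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

def test_single_central_cg_window():
    counts, total = cm.count_central_cpg_kmers(["AAACGCTT"])
    assert total == 1
    assert counts == Counter({cm.canonical_kmer("AACGCT"): 1})


def test_no_cg_no_counts():
    counts, total = cm.count_central_cpg_kmers(["AAAAAAAA"])
    assert total == 0 and not counts


def test_ambiguous_bases_skipped():
    counts, _ = cm.count_central_cpg_kmers(["AANCGCTT"])
    assert not counts


def naive_central_cg_scan(seqs, k=6):
    """Position-by-position scan, canonicalizing by explicit complement map."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts: Counter = Counter()
    for seq in seqs:
        for i in range(len(seq)):
            w = seq[i:i + k]
            if len(w) < k or any(b not in comp for b in w):
                continue
            if w[k // 2 - 1] == "C" and w[k // 2] == "G":
                rc = "".join(comp[b] for b in reversed(w))
                counts[min(w, rc)] += 1
    return counts


def test_kmer_counts_match_naive_scan():
    rng = np.random.default_rng(4)
    seqs = ["".join(rng.choice(list("ACGTN"), rng.integers(10, 80),
                               p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            for _ in range(100)]
    counts, total = cm.count_central_cpg_kmers(seqs)
    expected = naive_central_cg_scan(seqs)
    assert counts == expected
    assert total == sum(expected.values())


def test_rc_collapse_switch():
    counts, _ = cm.count_central_cpg_kmers(["AAACGCTT"], collapse_rc=False)
    assert counts == Counter({"AACGCT": 1})


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def exact_hypergeom_upper_tail(observed, population, successes, draws):
    """Exact-fraction enumeration of P(X >= observed)."""
    total = comb(population, draws)
    p = Fraction(0)
    for x in range(observed, min(successes, draws) + 1):
        p += Fraction(comb(successes, x) * comb(population - successes,
                                                draws - x), total)
    return float(p)


def test_enrichment_p_matches_exact_sum():
    fg = Counter({"AACGCT": 60})
    bg = Counter({"AACGCT": 600})
    res = cm.kmer_enrichment(fg, 100, bg, 10_000)[0]
    assert res.p_raw == pytest.approx(
        exact_hypergeom_upper_tail(60, 10_000, 600, 100), rel=1e-9)
    assert res.p_adj == pytest.approx(min(1.0, res.p_raw * 256))


def test_equal_proportions_are_not_significant():
    fg = Counter({"AACGCT": 30})
    bg = Counter({"AACGCT": 3000})
    res = cm.kmer_enrichment(fg, 100, bg, 10_000)[0]
    assert res.p_raw > 0.4


def test_bonferroni_clips_at_one():
    fg = Counter({"AACGCT": 1})
    bg = Counter({"AACGCT": 500})
    res = cm.kmer_enrichment(fg, 10, bg, 10_000)[0]
    assert res.p_adj <= 1.0


def test_fg_exceeding_bg_is_inconsistent():
    with pytest.raises(ValueError):
        cm.kmer_enrichment(Counter({"AACGCT": 5}), 10,
                           Counter({"AACGCT": 2}), 100)


def test_enrichment_oracle_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(50):
        bg_total = int(rng.integers(20, 2000))
        bg_count = int(rng.integers(0, bg_total + 1))
        fg_total = int(rng.integers(1, bg_total + 1))
        hi = min(fg_total, bg_count)
        fg_count = int(rng.integers(0, hi + 1))
        res = cm.kmer_enrichment(Counter({"AACGCT": fg_count}), fg_total,
                                 Counter({"AACGCT": bg_count}), bg_total)[0]
        assert res.p_raw == pytest.approx(
            exact_hypergeom_upper_tail(fg_count, bg_total, bg_count, fg_total),
            rel=1e-9, abs=1e-300)


# ---------------------------------------------------------------------------
# consensus from significant k-mers
# ---------------------------------------------------------------------------

def make_result(kmer, p_adj):
    return cm.EnrichmentResult(kmer=kmer, fg_count=10, fg_total=100,
                               bg_count=20, bg_total=1000,
                               p_raw=p_adj / 256, p_adj=p_adj)


def test_no_significant_kmers_yields_no_consensus():
    assert cm.methylated_consensus_in_vivo([]) is None


def test_single_significant_kmer_is_its_own_consensus():
    cons = cm.methylated_consensus_in_vivo([make_result("CCCGCC", 1e-5)])
    assert cons.iupac == "CCCGCC"


def test_two_disjoint_kmers_deterministic_tiebreak():
    sig = [make_result("AACGAA", 1e-5), make_result("TTCGTT", 1e-5)]
    cons_a = cm.methylated_consensus_in_vivo(sig)
    cons_b = cm.methylated_consensus_in_vivo(list(reversed(sig)))
    assert cons_a.iupac == cons_b.iupac == "AACGAA"  # lexicographic tie-break
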