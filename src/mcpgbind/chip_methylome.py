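"""ChIP-seq x methylome integration and central-CpG k-mer enrichment.

Given TF binding peaks/summits (from a peak caller) and a base-resolution
bisulfite methylome, this module: filters peaks by length, pools CpG read
counts around each summit into a methylation level M, splits summits into
high (M >= 0.8) / low (M < 0.2) / intermediate strata, and tests every
possible 6-mer with CG at its central two positions for enrichment in the
highly methylated summit windows (foreground, summit +/-60 bp) relative to
the extended peaks (background, peaks +/-50 bp), with a hypergeometric
upper tail and Bonferroni correction.  Significant k-mers feed the
consensus machinery to yield the in vivo methylated binding motif.

Coordinates are 0-based half-open throughout (BED convention); methylome
positions refer to the plus-strand C of each CpG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from mcpgbind.consensus import CenteredKmer, Consensus, consensus_report

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak with its summit (position of maximal signal)."""

    chrom: str
    start: int
    end: int
    summit: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.start}-{self.end}")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit outside peak")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MethylomeRecord:
    """Read counts at one CpG (position of the plus-strand C)."""

    chrom: str
    pos: int
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_meth <= self.n_total or self.n_total <= 0:
            raise ValueError("need 0 <= n_meth <= n_total, n_total > 0")

    @property
    def level(self) -> float:
        return self.n_meth / self.n_total


@dataclass(frozen=True)
class EnrichmentResult:
    """One central-CpG k-mer with its foreground/background test."""

    kmer: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    p_raw: float
    p_adj: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peaks_bed(path) -> list[Peak]:
    """BED with the summit offset (relative to start) in column 4."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            summit = start + int(fields[3]) if len(fields) > 3 else (start + end) // 2
            peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit))
    return peaks


def write_peaks_bed(path, peaks: list[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.summit - p.start}\n")


def read_methylome_tsv(path) -> dict[tuple[str, int], MethylomeRecord]:
    """Methylome table (chrom, pos, strand, n_meth, n_total), tab-delimited."""
    df = pd.read_csv(path, sep="\t")
    index: dict[tuple[str, int], MethylomeRecord] = {}
    for rec in df.itertuples(index=False):
        r = MethylomeRecord(chrom=str(rec.chrom), pos=int(rec.pos),
                            n_meth=int(rec.n_meth), n_total=int(rec.n_total))
        index[(r.chrom, r.pos)] = r
    return index


# ---------------------------------------------------------------------------
# Peak filtering and summit methylation
# ---------------------------------------------------------------------------

def filter_peaks(peaks: list[Peak], max_length: float | None = None,
                 quantile: float | None = None) -> list[Peak]:
    """Keep peaks strictly shorter than a length cutoff.

    Give either an absolute ``max_length`` in bp or a ``quantile`` q, in
    which case the cutoff is the q-quantile of the observed lengths (so
    q = 0.95 keeps the ~95% shortest peaks).
    """
    if (max_length is None) == (quantile is None):
        raise ValueError("give exactly one of max_length / quantile")
    if not peaks:
        logger.warning("empty peak list")
        return []
    lengths = np.array([p.length for p in peaks])
    if quantile is not None:
        if quantile >= 1.0:
            return list(peaks)
        max_length = float(np.quantile(lengths, quantile))
    return [p for p in peaks if p.length < max_length]


def summit_methylation(peak: Peak,
                       methylome: dict[tuple[str, int], MethylomeRecord],
                       half_window: int = 60,
                       pooled: bool = True) -> float | None:
    """Methylation level of the summit +/-half_window region.

    Pools read counts over all covered CpGs in the closed window
    [summit - hw, summit + hw] (coverage-weighted); ``pooled=False`` takes
    the unweighted mean of per-CpG levels instead.  Returns None when the
    window contains no covered CpG.
    """
    lo, hi = peak.summit - half_window, peak.summit + half_window
    records = [
        methylome[(peak.chrom, pos)]
        for pos in range(lo, hi + 1)
        if (peak.chrom, pos) in methylome
    ]
    if not records:
        return None
    if pooled:
        return sum(r.n_meth for r in records) / sum(r.n_total for r in records)
    return float(np.mean([r.level for r in records]))


def categorize_methylation(levels: list[float], high: float = 0.8,
                           low: float = 0.2) -> dict[str, float]:
    """Fractions of levels in the high (M >= high), low (M < low) and
    intermediate strata; the three fractions sum to 1."""
    if not levels:
        raise ValueError("no methylation levels")
    arr = np.asarray(levels, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("levels must be in [0, 1]")
    n = arr.size
    n_high = int((arr >= high).sum())
    n_low = int((arr < low).sum())
    return {
        "high": n_high / n,
        "low": n_low / n,
        "mid": (n - n_high - n_low) / n,
    }


# ---------------------------------------------------------------------------
# Sequence extraction and k-mer counting
# ---------------------------------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Clip to chromosome bounds and return the uppercased sequence.

    ``genome`` is any mapping from chromosome name to sequence string
    (a plain dict, or a pyfaidx.Fasta via ``str(genome[chrom][...])``).
    """
    seq = genome[chrom]
    length = len(seq)
    lo, hi = max(0, start), min(length, end)
    if (lo, hi) != (start, end):
        logger.warning("interval %s:%d-%d clipped to %d-%d",
                       chrom, start, end, lo, hi)
    return str(seq[lo:hi]).upper()


def build_fg_bg(peaks: list[Peak], genome, summit_half: int = 60,
                peak_extend: int = 50) -> tuple[list[str], list[str]]:
    """Foreground (summit +/-summit_half) and background (peak +/-peak_extend)
    sequences; the foreground windows are contained in the background."""
    fg = [
        _fetch(genome, p.chrom, p.summit - summit_half, p.summit + summit_half + 1)
        for p in peaks
    ]
    bg = [
        _fetch(genome, p.chrom, p.start - peak_extend, p.end + peak_extend)
        for p in peaks
    ]
    return fg, bg


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    return min(kmer, revcomp(kmer))


def count_central_cpg_kmers(sequences: list[str], k: int = 6,
                            collapse_rc: bool = True) -> tuple[Counter, int]:
    """Count k-mer windows whose central two bases are CG.

    Scans every offset of every sequence; with ``collapse_rc`` a k-mer and
    its reverse complement are pooled under the lexicographically smaller
    key.  Because CG is its own reverse complement, every central-CpG
    window on the reverse strand is the reverse complement of a forward-
    strand window at the same locus, so a single forward scan with
    canonical pooling captures both strands without double-counting any
    physical site (double counting would square the enrichment p-values).
    Windows containing ambiguous bases are skipped.  Returns
    (counts, total windows counted).
    """
    if k % 2 != 0:
        raise ValueError("k must be even")
    mid = k // 2 - 1
    counts: Counter = Counter()
    total = 0
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if window[mid:mid + 2] != "CG":
                continue
            if any(b not in "ACGT" for b in window):
                continue
            counts[canonical_kmer(window) if collapse_rc else window] += 1
            total += 1
    return counts, total


def kmer_enrichment(fg_counts: Counter, fg_total: int, bg_counts: Counter,
                    bg_total: int, k: int = 6, alpha: float = 0.01,
                    n_tests: int | None = None,
                    fg_subset_of_bg: bool = True) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every observed central-CpG k-mer.

    For each k-mer, p_raw = P(X >= fg_count) drawing fg_total windows from
    a population of bg_total windows containing bg_count occurrences;
    Bonferroni multiplies by the a-priori family size, all 4^(k-2)
    possible central-CpG k-mers (256 for k = 6), unless ``n_tests``
    overrides it.  Results are sorted by adjusted p.
    """
    if n_tests is None:
        n_tests = 4 ** (k - 2)
    results = []
    for kmer, fg_count in fg_counts.items():
        bg_count = bg_counts.get(kmer, 0)
        if fg_subset_of_bg and fg_count > bg_count:
            raise ValueError(
                f"{kmer}: fg count {fg_count} exceeds bg count {bg_count} "
                "but foreground is configured as a subset of background"
            )
        p_raw = float(stats.hypergeom.sf(fg_count - 1, bg_total, bg_count,
                                         fg_total))
        results.append(
            EnrichmentResult(
                kmer=kmer, fg_count=fg_count, fg_total=fg_total,
                bg_count=bg_count, bg_total=bg_total, p_raw=p_raw,
                p_adj=min(1.0, p_raw * n_tests),
            )
        )
    return sorted(results, key=lambda r: (r.p_adj, r.p_raw, r.kmer))


def significant_kmers(results: list[EnrichmentResult],
                      alpha: float = 0.01) -> list[EnrichmentResult]:
    return [r for r in results if r.p_adj < alpha]


def methylated_consensus_in_vivo(sig: list[EnrichmentResult],
                                 min_similarity: float = 0.75
                                 ) -> Consensus | None:
    """Cluster significant k-mers and return the largest-group consensus.

    Returns None when no k-mer is significant (a no-consensus outcome, not
    an error).
    """
    if not sig:
        return None
    kmers = [CenteredKmer(kmer=r.kmer) for r in sig]
    return consensus_report(kmers, min_similarity=min_similarity)[0]


def enrich_high_m_summits(peaks: list[Peak], genome,
                          methylome: dict[tuple[str, int], MethylomeRecord],
                          summit_half: int = 60, peak_extend: int = 50,
                          m_high: float = 0.8, k: int = 6,
                          alpha: float = 0.01,
                          length_quantile: float | None = 0.95
                          ) -> list[EnrichmentResult]:
    """Full in vivo pipeline: filter peaks, stratify by summit methylation,
    count central-CpG k-mers in high-M foreground vs all-peak background,
    and test enrichment."""
    if length_quantile is not None:
        peaks = filter_peaks(peaks, quantile=length_quantile)
    levels = [summit_methylation(p, methylome, half_window=summit_half)
              for p in peaks]
    high_peaks = [p for p, m in zip(peaks, levels)
                  if m is not None and m >= m_high]
    fg_seqs, _ = build_fg_bg(high_peaks, genome, summit_half=summit_half)
    _, bg_seqs = build_fg_bg(peaks, genome, peak_extend=peak_extend)
    fg_counts, fg_total = count_central_cpg_kmers(fg_seqs, k=k)
    bg_counts, bg_total = count_central_cpg_kmers(bg_seqs, k=k)
    return kmer_enrichment(fg_counts, fg_total, bg_counts, bg_total,
                           k=k, alpha=alpha)


def write_enrichment_tsv(path, results: list[EnrichmentResult]) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t",
                                                       index=False)
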