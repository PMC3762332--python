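"""mCpG-centered consensus-motif derivation.

Bound motif sequences are aligned on the methylated CpG (the conserved,
binding-determining position), reduced to k-mers with the CpG at the two
central positions (k = 6 by default), hierarchically clustered on flank
similarity, and each cluster is summarized as a position-weight matrix and
an IUPAC degenerate string.  A TF bound to a single motif keeps that motif
as its consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: smallest IUPAC degenerate code for each base subset
IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class MotifSeq:
    """A probed DNA motif with one annotated CpG position."""

    motif_id: str
    sequence: str
    cpg_offset: int  # 0-based index of the C of the CpG
    methylated: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set(BASES):
            raise ValueError(f"{self.motif_id}: non-ACGT bases in sequence")
        if seq[self.cpg_offset:self.cpg_offset + 2] != "CG":
            raise ValueError(
                f"{self.motif_id}: no CpG at offset {self.cpg_offset}"
            )


@dataclass(frozen=True)
class CenteredKmer:
    """A k-mer whose central two positions are the (methylated) CpG."""

    kmer: str
    motif_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.kmer)
        if k % 2 != 0:
            raise ValueError("centered k-mer length must be even")
        mid = k // 2 - 1
        if self.kmer[mid:mid + 2] != "CG":
            raise ValueError(f"{self.kmer}: central two bases must be CG")

    @property
    def flanks(self) -> str:
        """Non-CpG positions, left flank then right flank."""
        k = len(self.kmer)
        mid = k // 2 - 1
        return self.kmer[:mid] + self.kmer[mid + 2:]


@dataclass
class Consensus:
    """PWM + IUPAC summary of a cluster of centered k-mers."""

    pwm: np.ndarray  # positions x 4 (A,C,G,T) frequencies, rows sum to 1
    iupac: str
    members: list[CenteredKmer] = field(default_factory=list)


def extract_centered_kmers(motifs: list[MotifSeq], k: int = 6) -> list[CenteredKmer]:
    """One centered k-mer per motif CpG; motifs with short flanks are skipped.

    The CpG occupies the central two positions, leaving k/2 - 1 flank bases
    on each side.
    """
    if k % 2 != 0 or k < 4:
        raise ValueError("k must be an even integer >= 4")
    flank = k // 2 - 1
    out: list[CenteredKmer] = []
    for motif in motifs:
        start = motif.cpg_offset - flank
        end = motif.cpg_offset + 2 + flank
        if start < 0 or end > len(motif.sequence):
            logger.warning(
                "motif %s: CpG too close to sequence end for k=%d; skipped",
                motif.motif_id, k,
            )
            continue
        out.append(
            CenteredKmer(kmer=motif.sequence[start:end],
                         motif_ids=(motif.motif_id,))
        )
    return out


def flank_distance(a: CenteredKmer, b: CenteredKmer) -> float:
    """Fraction of mismatching flank positions (central CG excluded)."""
    fa, fb = a.flanks, b.flanks
    if len(fa) != len(fb):
        raise ValueError("k-mers of different length")
    return sum(x != y for x, y in zip(fa, fb)) / len(fa)


def cluster_kmers(kmers: list[CenteredKmer], min_similarity: float = 0.75,
                  linkage: str = "average") -> list[list[CenteredKmer]]:
    """Agglomerative clustering of centered k-mers on flank similarity.

    Distance is the mismatching-flank fraction; clusters are merged
    greedily by smallest average inter-cluster distance until the best
    remaining merge would join groups at average similarity below
    ``min_similarity``.  Flank distances are quantized (multiples of
    1/(k-2)), so ties are common; they are broken deterministically by the
    lexicographically smallest member pair, and the input order never
    matters because k-mers are sorted first.
    """
    if linkage != "average":
        raise ValueError(f"unsupported linkage {linkage!r}")
    if not kmers:
        raise ValueError("need at least one k-mer")
    kmers = sorted(kmers, key=lambda km: km.kmer)
    n = len(kmers)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = flank_distance(kmers[i], kmers[j])
    threshold = 1.0 - min_similarity
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        # candidate merges ranked by (average distance, merged-member kmers):
        # the kmer tuple makes tie-breaking explicit and order-independent
        best: tuple[float, tuple[str, ...], int, int] | None = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = float(np.mean(dist[np.ix_(clusters[a], clusters[b])]))
                key = tuple(sorted(kmers[i].kmer
                                   for i in clusters[a] + clusters[b]))
                if best is None or (round(avg, 9), key) < (round(best[0], 9),
                                                           best[1]):
                    best = (avg, key, a, b)
        avg, _, a, b = best
        if avg > threshold + 1e-12:
            break
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
    groups = [[kmers[i] for i in members] for members in clusters]
    # largest group first; ties broken by lexicographically smallest member
    return sorted(groups, key=lambda g: (-len(g), g[0].kmer))


def derive_consensus(group: list[CenteredKmer],
                     iupac_threshold: float = 0.25) -> Consensus:
    """PWM and IUPAC consensus of one k-mer group.

    Each position's IUPAC letter is the smallest degenerate code covering
    every base whose frequency reaches ``iupac_threshold``; the central two
    positions are always C and G by construction.
    """
    if not group:
        raise ValueError("empty group")
    k = len(group[0].kmer)
    pwm = np.zeros((k, 4))
    for kmer in group:
        if len(kmer.kmer) != k:
            raise ValueError("mixed k-mer lengths in group")
        for pos, base in enumerate(kmer.kmer):
            pwm[pos, BASES.index(base)] += 1
    pwm /= len(group)
    letters = []
    for pos in range(k):
        included = frozenset(
            BASES[b] for b in range(4) if pwm[pos, b] >= iupac_threshold
        )
        if not included:  # all below threshold: fall back to the max base
            included = frozenset(BASES[int(np.argmax(pwm[pos]))])
        letters.append(IUPAC_CODES[included])
    return Consensus(pwm=pwm, iupac="".join(letters), members=list(group))


def consensus_report(kmers: list[CenteredKmer], min_similarity: float = 0.75,
                     linkage: str = "average",
                     iupac_threshold: float = 0.25) -> list[Consensus]:
    """Cluster and summarize; consensuses ordered largest group first."""
    groups = cluster_kmers(kmers, min_similarity=min_similarity, linkage=linkage)
    return [derive_consensus(g, iupac_threshold=iupac_threshold) for g in groups]


def write_pwm(path, consensus: Consensus) -> None:
    """Tab-delimited PWM: one row per position, columns A, C, G, T."""
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tT\n")
        for pos, row in enumerate(consensus.pwm):
            fh.write(f"{pos}\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
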