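"""ChIP-bisulfite methylation comparison.

Summarizes per-read methylation calls (Sanger bisulfite clones or reads)
at each CpG of a region and tests, site by site, whether immunoprecipitated
(ChIP'ed) DNA is more methylated than the genomic input.  The null level at
each site is the input sample's observed methylated fraction, and the test
is the exact binomial upper tail P(X >= chip_k | chip_n, p0) — one-sided
for the directional claim that a methyl-preferring TF pulls down the
methylated fraction of its targets; consensus-embedded and neighboring
CpGs are both reported so the contrast (consensus up, neighbors flat) is
computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# call codes in the read x CpG matrix
METH, UNMETH, MISSING = 1, 0, -1


@dataclass
class BisulfiteReadSet:
    """Per-read methylation calls over the ordered CpGs of one region.

    ``calls`` is an int matrix (reads x CpGs) with 1 = methylated,
    0 = unmethylated, -1 = missing.
    """

    region_id: str
    cpg_positions: tuple[int, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[1] != len(self.cpg_positions):
            raise ValueError("calls must be reads x len(cpg_positions)")
        if np.any(np.diff(self.cpg_positions) <= 0):
            raise ValueError("CpG positions must be strictly increasing")
        if np.any((self.calls != METH) & (self.calls != UNMETH)
                  & (self.calls != MISSING)):
            raise ValueError("calls must be 1 (M), 0 (U) or -1 (missing)")
        if self.calls.shape[0] and np.any((self.calls == MISSING).all(axis=1)):
            raise ValueError("a read has no non-missing call")


@dataclass(frozen=True)
class SiteComparison:
    """Input-vs-ChIP methylation test at one CpG site."""

    position: int
    input_level: float
    chip_k: int
    chip_n: int
    delta: float  # chip level - input level
    p: float
    in_consensus: bool
    degenerate_null: bool = False  # input level exactly 0 or 1


def site_methylation_level(calls: np.ndarray) -> tuple[int, int, float] | None:
    """(methylated k, informative n, level k/n) at one site; None if all
    calls are missing."""
    calls = np.asarray(calls)
    informative = calls != MISSING
    n = int(informative.sum())
    if n == 0:
        return None
    k = int((calls[informative] == METH).sum())
    return k, n, k / n


def region_methylation_profile(readset: BisulfiteReadSet) -> dict:
    """Ordered per-site levels plus the pooled region mean.

    The region mean pools all informative calls (methylated calls over
    total calls), so deeply covered sites weigh more.
    """
    per_site = {}
    total_k = total_n = 0
    for j, pos in enumerate(readset.cpg_positions):
        res = site_methylation_level(readset.calls[:, j])
        if res is None:
            continue
        k, n, level = res
        per_site[pos] = level
        total_k += k
        total_n += n
    return {
        "per_site": per_site,
        "region_mean": total_k / total_n if total_n else None,
    }


def compare_methylation(input_set: BisulfiteReadSet,
                        chip_set: BisulfiteReadSet,
                        consensus_sites: set[int] = frozenset(),
                        alternative: str = "greater") -> list[SiteComparison]:
    """Exact binomial test of ChIP vs input methylation at shared CpGs.

    At each site, the input's observed methylated fraction is the plug-in
    null p0 and the ChIP calls give (k, n); ``alternative='greater'``
    reports P(X >= k | n, p0).  Sites where the input level is exactly 0
    or 1 are still tested (degenerate binomial) but flagged.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    input_pos = {p: j for j, p in enumerate(input_set.cpg_positions)}
    chip_pos = {p: j for j, p in enumerate(chip_set.cpg_positions)}
    out: list[SiteComparison] = []
    for pos in sorted(set(input_pos) & set(chip_pos)):
        in_res = site_methylation_level(input_set.calls[:, input_pos[pos]])
        chip_res = site_methylation_level(chip_set.calls[:, chip_pos[pos]])
        if in_res is None or chip_res is None:
            continue
        _, _, p0 = in_res
        k, n, chip_level = chip_res
        p = float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)
        out.append(
            SiteComparison(
                position=pos,
                input_level=p0,
                chip_k=k,
                chip_n=n,
                delta=chip_level - p0,
                p=max(p, np.nextafter(0, 1)),
                in_consensus=pos in consensus_sites,
                degenerate_null=p0 in (0.0, 1.0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O: per-read call-matrix TSV (read_id, then one column per CpG position)
# ---------------------------------------------------------------------------

_CODE = {"M": METH, "U": UNMETH, ".": MISSING}
_CHAR = {v: k for k, v in _CODE.items()}


def read_call_matrix(path, region_id: str | None = None) -> BisulfiteReadSet:
    """Read a call matrix with header ``read_id <pos> <pos> ...`` and
    values M / U / . per cell."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    positions = tuple(int(c) for c in df.columns[1:])
    calls = np.array(
        [[_CODE[v] for v in row] for row in df.iloc[:, 1:].to_numpy()],
        dtype=np.int8,
    ).reshape(len(df), len(positions))
    return BisulfiteReadSet(
        region_id=region_id or str(getattr(path, "stem", path)),
        cpg_positions=positions,
        calls=calls,
    )


def write_call_matrix(path, readset: BisulfiteReadSet) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\t" + "\t".join(map(str, readset.cpg_positions)) + "\n")
        for i, row in enumerate(readset.calls):
            fh.write(f"read{i}\t" + "\t".join(_CHAR[int(v)] for v in row) + "\n")


def write_comparison_tsv(path, comparisons: list[SiteComparison]) -> None:
    pd.DataFrame([c.__dict__ for c in comparisons]).to_csv(path, sep="\t",
                                                           index=False)
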