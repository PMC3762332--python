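"""Protein-DNA interaction (PDI) integration and summary statistics.

Joins the methylated-motif hit table from the competition assay with a
prior unmethylated-motif hit table over the same proteins and motifs, and
classifies every interaction as methylated-only, unmethylated-only, or
methylation-indifferent.  Also provides the screen-level summaries
(per-motif binder counts, hit-protein fraction, EMSA-implied false-positive
rate), hypergeometric annotation enrichment, and the motif-saturation curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from mcpgbind.microarray import HitTable


class Category(str, Enum):
    METH_ONLY = "METH_ONLY"
    UNMETH_ONLY = "UNMETH_ONLY"
    BOTH = "BOTH"
    NONE = "NONE"


@dataclass(frozen=True)
class PDIRecord:
    """One (protein, motif) interaction with its methylation-dependence."""

    protein_id: str
    motif_id: str
    z_meth: float | None
    z_unmeth: float | None
    category: Category


@dataclass(frozen=True)
class AnnotationSet:
    """A functional annotation (e.g. oncogene/tumor suppressor) on the array."""

    name: str
    members: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        if len(self.members) > self.universe_size:
            raise ValueError("annotation larger than its universe")


class ReconciliationError(ValueError):
    """The two hit tables disagree on identifier universes."""


def classify_pdis(meth_hits: HitTable, unmeth_hits: HitTable) -> list[PDIRecord]:
    """Classify every (protein, motif) pair with at least one hit.

    Both tables must cover the same protein and motif universes; a pair is
    METH_ONLY / UNMETH_ONLY / BOTH according to which assays called it.
    """
    for kind, a, b in (
        ("protein", set(meth_hits.proteins), set(unmeth_hits.proteins)),
        ("motif", set(meth_hits.motifs), set(unmeth_hits.motifs)),
    ):
        if a != b:
            raise ReconciliationError(
                f"{kind} universes differ; offenders: {sorted(a ^ b)}"
            )
    records: list[PDIRecord] = []
    for protein_id in meth_hits.proteins:
        for motif_id in meth_hits.motifs:
            m = meth_hits.is_hit(protein_id, motif_id)
            u = unmeth_hits.is_hit(protein_id, motif_id)
            if not (m or u):
                continue
            category = Category.BOTH if (m and u) else (
                Category.METH_ONLY if m else Category.UNMETH_ONLY
            )
            zm = meth_hits.z_scores.get((protein_id, motif_id))
            zu = unmeth_hits.z_scores.get((protein_id, motif_id))
            records.append(
                PDIRecord(
                    protein_id=protein_id,
                    motif_id=motif_id,
                    z_meth=float(np.min(zm)) if zm is not None else None,
                    z_unmeth=float(np.min(zu)) if zu is not None else None,
                    category=category,
                )
            )
    return records


def category_counts(records: list[PDIRecord]) -> dict[Category, int]:
    counts = {c: 0 for c in (Category.METH_ONLY, Category.UNMETH_ONLY, Category.BOTH)}
    for rec in records:
        counts[rec.category] += 1
    return counts


def category_percentages(n_meth_only: int, n_unmeth_only: int,
                         n_both: int) -> dict[str, int]:
    """Integer percentages of each PDI category out of their total.

    Rounded to the nearest percent; with counts (321, 97, 17) this prints
    the 74 / 22 / 4 split.
    """
    total = n_meth_only + n_unmeth_only + n_both
    if total == 0:
        raise ValueError("no PDIs to summarize")
    return {
        "meth_only_pct": round(100 * n_meth_only / total),
        "unmeth_only_pct": round(100 * n_unmeth_only / total),
        "both_pct": round(100 * n_both / total),
    }


def summarize_binding(hits: HitTable, universe_size: int | None = None) -> dict:
    """Screen-level binding summary over a hit matrix.

    Returns per-motif binder counts, per-protein motif counts, their
    medians, the percentage of motifs with >= 1 binder, and (when
    ``universe_size`` is given) the percentage of arrayed proteins that hit
    at least one motif.
    """
    m = hits.hits
    binders_per_motif = m.sum(axis=0)
    motifs_per_protein = m.sum(axis=1)
    bound_motifs = binders_per_motif[binders_per_motif > 0]
    n_motifs = m.shape[1]
    hit_proteins = int((motifs_per_protein > 0).sum())
    summary = {
        "n_motifs": n_motifs,
        "n_motifs_with_binder": int(bound_motifs.size),
        "pct_motifs_with_binder": (
            round(100 * bound_motifs.size / n_motifs) if n_motifs else None
        ),
        "median_binders_per_bound_motif": (
            float(bound_motifs.median()) if bound_motifs.size else None
        ),
        "binders_per_motif": binders_per_motif.to_dict(),
        "motifs_per_protein": motifs_per_protein.to_dict(),
        "n_hit_proteins": hit_proteins,
    }
    if universe_size is not None:
        summary["pct_hit_proteins"] = round(100 * hit_proteins / universe_size)
    return summary


def false_positive_rate(n_confirmed: int, n_tested: int) -> int:
    """Orthogonal-validation-implied false-positive percentage.

    When ``n_confirmed`` of ``n_tested`` hits are confirmed by an
    independent assay, the implied FP rate is the unconfirmed fraction,
    rounded to the nearest percent (8 of 11 -> 27).
    """
    if not 0 <= n_confirmed <= n_tested or n_tested == 0:
        raise ValueError("need 0 <= n_confirmed <= n_tested, n_tested > 0")
    return round(100 * (n_tested - n_confirmed) / n_tested)


def annotation_enrichment(hit_proteins: set[str],
                          annotation: AnnotationSet) -> float:
    """Upper-tail hypergeometric enrichment p-value.

    P(X >= overlap) drawing |hit_proteins| proteins without replacement
    from a universe of ``annotation.universe_size`` containing
    |annotation.members| annotated ones.
    """
    n_draws = len(hit_proteins)
    overlap = len(hit_proteins & annotation.members)
    if overlap > n_draws:
        raise ValueError("overlap exceeds number of draws")
    return float(
        stats.hypergeom.sf(
            overlap - 1, annotation.universe_size, len(annotation.members), n_draws
        )
    )


def saturation_curve(hits: HitTable, n_grid: list[int], n_draws: int = 200,
                     seed: int = 0) -> pd.DataFrame:
    """Unique hit proteins discovered as a function of motifs assayed.

    For each subset size n, averages over ``n_draws`` uniformly sampled
    motif subsets the number of proteins hitting at least one chosen motif.
    Returns a frame with columns (n_motifs, mean_unique_proteins, mc_se).
    """
    rng = np.random.default_rng(seed)
    m = hits.hits.to_numpy(dtype=bool)
    n_motifs = m.shape[1]
    rows = []
    for n in n_grid:
        if n > n_motifs:
            raise ValueError(f"subset size {n} exceeds motif count {n_motifs}")
        if n == 0:
            rows.append({"n_motifs": 0, "mean_unique_proteins": 0.0, "mc_se": 0.0})
            continue
        counts = np.empty(n_draws)
        for i in range(n_draws):
            cols = rng.choice(n_motifs, size=n, replace=False)
            counts[i] = int(m[:, cols].any(axis=1).sum())
        rows.append(
            {
                "n_motifs": n,
                "mean_unique_proteins": float(counts.mean()),
                "mc_se": float(counts.std(ddof=1) / np.sqrt(n_draws))
                if n_draws > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def saturation_expectation(hits: HitTable, n: int) -> float:
    """Closed-form E[unique hit proteins] over uniform motif subsets of size n.

    E = sum_p (1 - C(M - m_p, n) / C(M, n)) with m_p the motifs hit by
    protein p and M the total motif count.
    """
    from math import comb

    m = hits.hits.to_numpy(dtype=bool)
    n_motifs = m.shape[1]
    total = comb(n_motifs, n)
    expectation = 0.0
    for hits_p in m.sum(axis=1):
        expectation += 1.0 - comb(n_motifs - int(hits_p), n) / total if (
            n_motifs - int(hits_p) >= n
        ) else 1.0
    return expectation
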