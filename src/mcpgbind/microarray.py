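"""Protein-microarray competition-assay analysis.

A labeled, methylated DNA motif is probed against a protein array in the
presence of excess unlabeled, unmethylated competitor; binding signal that
survives the competition indicates methylation-preferring binding.  Each
protein is printed in duplicate spots and every motif assay is run on two
replicate arrays, so a protein contributes four spots per motif.

The processing chain mirrors standard array practice:

1. raw intensity ``R = F/B`` per spot (foreground over background median);
2. local normalization ``R' = R / median(R over a w x w window)`` to remove
   spatial trends (default window 9 x 9);
3. background-noise estimation from the *mirrored shadow*: sub-unity R'
   values are reflected around 1 to build a symmetric noise distribution N
   whose spread calibrates the Z-score;
4. ``Z = (R' - mean(N)) / std(N)`` per spot;
5. a protein is a hit for a motif only when **all four** of its spots reach
   the Z cutoff (default 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OK = "ok"
EXCLUDED = "excluded"

#: header columns required in a GenePix-results-style spot table
REQUIRED_COLUMNS = ("Block", "Row", "Column", "Name", "F_Median", "B_Median", "Flag")


class SpotTableFormatError(ValueError):
    """The spot table is missing a required column or malformed."""


class SpotValueError(ValueError):
    """A spot row carries an impossible value (e.g. B <= 0 on an ok spot)."""


class ArrayStructureError(ValueError):
    """Grid layout violation: duplicate cell, wrong spot multiplicity, ..."""


class DegenerateNoiseError(ValueError):
    """Too few sub-unity R' values to estimate the noise distribution."""


class UndefinedCorrelationError(ValueError):
    """Fewer than 3 jointly observed cells between replicate grids."""


@dataclass(frozen=True)
class SpotMeasurement:
    """One printed protein spot on one array scan."""

    array_id: str
    grid_pos: tuple[int, int]  # (row, column), 0-based
    protein_id: str
    F: float  # foreground median signal
    B: float  # background median signal
    flag: str = OK

    def __post_init__(self) -> None:
        if self.flag == OK and self.B <= 0:
            raise SpotValueError(
                f"spot {self.protein_id}@{self.grid_pos}: B={self.B} must be > 0"
            )


@dataclass
class ArrayGrid:
    """Spatial matrix of per-spot values with a protein -> positions map.

    ``values`` uses NaN for missing (flagged/excluded) cells; missing cells
    never enter window medians, noise estimation or hit calling.
    """

    array_id: str
    values: np.ndarray  # 2-D float, NaN = missing
    protein_map: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def protein_values(self, protein_id: str) -> np.ndarray:
        """Values at the spots of one protein, in printed order."""
        pos = self.protein_map[protein_id]
        return np.array([self.values[r, c] for r, c in pos], dtype=float)


@dataclass(frozen=True)
class NoiseModel:
    """Mirrored-shadow background noise distribution.

    Built from the shadow set N1 = {R' < 1} and its reflection
    N2 = {2 - x : x in N1}; N = N1 u N2 is symmetric about 1 by
    construction, so ``mean`` equals 1 up to floating point.
    """

    mean: float
    sd: float
    n_shadow: int


@dataclass
class HitTable:
    """Per-(protein, motif) hit calls with the underlying four Z-scores."""

    hits: pd.DataFrame  # bool matrix, index=protein_id, columns=motif_id
    z_scores: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return list(self.hits.index)

    @property
    def motifs(self) -> list[str]:
        return list(self.hits.columns)

    def is_hit(self, protein_id: str, motif_id: str) -> bool:
        return bool(self.hits.at[protein_id, motif_id])

    def hit_proteins(self) -> set[str]:
        """Proteins with at least one positive motif."""
        any_hit = self.hits.any(axis=1)
        return set(any_hit.index[any_hit])

    @staticmethod
    def merge(tables: list["HitTable"]) -> "HitTable":
        """Column-wise union of single-motif (or disjoint-motif) tables."""
        hits = pd.concat([t.hits for t in tables], axis=1).fillna(False)
        z: dict[tuple[str, str], np.ndarray] = {}
        for t in tables:
            z.update(t.z_scores)
        return HitTable(hits=hits.astype(bool), z_scores=z)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spot_table(path, dialect: str = "genepix") -> list[SpotMeasurement]:
    """Read a tab-delimited GenePix-results-style spot table.

    Required columns: Block, Row, Column, Name, F_Median, B_Median, Flag.
    Row/Column are 1-based within a block; blocks are stacked vertically to
    form the global grid.  Flag values of ``ok`` / ``0`` mark good spots,
    anything else marks the spot excluded.
    """
    if dialect != "genepix":
        raise SpotTableFormatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SpotTableFormatError(f"missing required column {col!r}")
    rows_per_block = int(df["Row"].max())
    array_id = str(getattr(path, "stem", path))
    spots: list[SpotMeasurement] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        flag = _parse_flag(rec.Flag)
        r = (int(rec.Block) - 1) * rows_per_block + int(rec.Row) - 1
        c = int(rec.Column) - 1
        try:
            spots.append(
                SpotMeasurement(
                    array_id=array_id,
                    grid_pos=(r, c),
                    protein_id=str(rec.Name),
                    F=float(rec.F_Median),
                    B=float(rec.B_Median),
                    flag=flag,
                )
            )
        except SpotValueError as exc:
            raise SpotValueError(f"row {i + 2}: {exc}") from exc
    return spots


def _parse_flag(raw) -> str:
    if isinstance(raw, str):
        return OK if raw.strip().lower() in ("ok", "0", "good") else EXCLUDED
    return OK if float(raw) >= 0 else EXCLUDED


def write_intensity_table(path, raw: ArrayGrid, normalized: ArrayGrid,
                          z: ArrayGrid) -> None:
    """Per-array TSV of (protein_id, spot, R, R_prime, Z)."""
    rows = []
    for protein_id, positions in raw.protein_map.items():
        for spot_idx, (r, c) in enumerate(positions):
            rows.append(
                {
                    "protein_id": protein_id,
                    "spot": spot_idx,
                    "R": raw.values[r, c],
                    "R_prime": normalized.values[r, c],
                    "Z": z.values[r, c],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Processing chain
# ---------------------------------------------------------------------------

def compute_raw_intensity(spots: list[SpotMeasurement]) -> ArrayGrid:
    """Place raw intensities R = F/B on the grid; excluded spots become NaN."""
    if not spots:
        raise ArrayStructureError("no spots")
    n_rows = max(s.grid_pos[0] for s in spots) + 1
    n_cols = max(s.grid_pos[1] for s in spots) + 1
    values = np.full((n_rows, n_cols), np.nan)
    occupied = np.zeros((n_rows, n_cols), dtype=bool)
    protein_map: dict[str, list[tuple[int, int]]] = {}
    for s in spots:
        r, c = s.grid_pos
        if occupied[r, c]:
            raise ArrayStructureError(f"duplicate grid position {(r, c)}")
        occupied[r, c] = True
        if s.flag == OK:
            values[r, c] = s.F / s.B
        protein_map.setdefault(s.protein_id, []).append((r, c))
    return ArrayGrid(array_id=spots[0].array_id, values=values,
                     protein_map=protein_map)


def local_normalize(grid: ArrayGrid, window: int = 9) -> ArrayGrid:
    """Divide each cell by the median of its w x w neighborhood.

    The window is centered on the cell (center included) and truncated at
    the grid borders; missing cells are skipped in the median and stay
    missing in the output.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    v = grid.values
    n_rows, n_cols = v.shape
    half = window // 2
    out = np.full_like(v, np.nan)
    for r in range(n_rows):
        r0, r1 = max(0, r - half), min(n_rows, r + half + 1)
        for c in range(n_cols):
            if np.isnan(v[r, c]):
                continue
            c0, c1 = max(0, c - half), min(n_cols, c + half + 1)
            block = v[r0:r1, c0:c1]
            med = np.nanmedian(block)
            if np.isnan(med):  # unreachable while center is non-missing
                logger.warning("all-missing window at (%d, %d)", r, c)
                continue
            out[r, c] = v[r, c] / med
    return ArrayGrid(array_id=grid.array_id, values=out,
                     protein_map=grid.protein_map)


def estimate_noise(grid: ArrayGrid, min_shadow: int = 10) -> NoiseModel:
    """Estimate the background-noise spread from the mirrored shadow.

    Takes the sub-unity normalized intensities N1 = {R' < 1}, reflects them
    around 1 (N2 = 2 - N1) and returns the mean and population SD of
    N = N1 u N2.
    """
    r_prime = grid.values[~np.isnan(grid.values)]
    n1 = r_prime[r_prime < 1.0]
    if n1.size < min_shadow:
        raise DegenerateNoiseError(
            f"only {n1.size} R' values below 1 (need >= {min_shadow}); "
            "array noise is uninterpretable"
        )
    n = np.concatenate([n1, 2.0 - n1])
    return NoiseModel(mean=float(np.mean(n)), sd=float(np.std(n)),
                      n_shadow=int(n1.size))


def compute_zscores(grid: ArrayGrid, noise: NoiseModel) -> ArrayGrid:
    """Standardize normalized intensities: Z = (R' - mean(N)) / std(N)."""
    if not noise.sd > 0:
        raise ValueError("noise SD must be positive")
    z = (grid.values - noise.mean) / noise.sd
    return ArrayGrid(array_id=grid.array_id, values=z,
                     protein_map=grid.protein_map)


def process_array(spots: list[SpotMeasurement], window: int = 9,
                  min_shadow: int = 10) -> tuple[ArrayGrid, NoiseModel]:
    """Full single-array chain: R -> R' -> noise -> Z.  Returns (Z, noise)."""
    raw = compute_raw_intensity(spots)
    norm = local_normalize(raw, window=window)
    noise = estimate_noise(norm, min_shadow=min_shadow)
    return compute_zscores(norm, noise), noise


def call_hits(z_arrays: tuple[ArrayGrid, ArrayGrid], motif_id: str,
              cutoff: float = 3.0) -> HitTable:
    """Call hits for one motif from two replicate Z grids.

    A protein is positive only when all four spots (2 spots x 2 replicate
    arrays) have Z >= cutoff.  Proteins with any missing spot are never hits.
    """
    z_a, z_b = z_arrays
    if z_a.protein_map.keys() != z_b.protein_map.keys():
        raise ArrayStructureError("replicate arrays disagree on proteins")
    hit = {}
    z_scores: dict[tuple[str, str], np.ndarray] = {}
    for protein_id in z_a.protein_map:
        za = z_a.protein_values(protein_id)
        zb = z_b.protein_values(protein_id)
        if za.size != 2 or zb.size != 2:
            raise ArrayStructureError(
                f"protein {protein_id} has {za.size}/{zb.size} spots; "
                "expected 2 per array"
            )
        four = np.concatenate([za, zb])
        z_scores[(protein_id, motif_id)] = four
        if np.isnan(four).any():
            logger.info("protein %s has missing spots; not a hit", protein_id)
            hit[protein_id] = False
        else:
            hit[protein_id] = bool(np.all(four >= cutoff))
    hits = pd.DataFrame({motif_id: pd.Series(hit, dtype=bool)})
    return HitTable(hits=hits, z_scores=z_scores)


def replicate_correlation(grid_a: ArrayGrid, grid_b: ArrayGrid) -> float:
    """Pearson correlation of two replicate grids over joint non-missing cells."""
    if grid_a.shape != grid_b.shape:
        raise ArrayStructureError("replicate grids have different layouts")
    a, b = grid_a.values.ravel(), grid_b.values.ravel()
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise UndefinedCorrelationError(
            f"only {int(ok.sum())} jointly observed cells (need >= 3)"
        )
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
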