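"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes — planted binders over multiplicative array noise, summits with
stratified methylation and a planted central-CpG 6-mer, 1:1 Langmuir
sensorgrams from known rates, Bernoulli bisulfite calls — and emits a
machine-readable truth object so recovery can be scored.  All generators
are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mcpgbind.bisulfite import METH, MISSING, UNMETH, BisulfiteReadSet
from mcpgbind.chip_methylome import MethylomeRecord, Peak
from mcpgbind.kinetics import Sensorgram, model_association, model_dissociation
from mcpgbind.microarray import OK, SpotMeasurement

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Protein microarray
# ---------------------------------------------------------------------------

@dataclass
class SyntheticArrayData:
    spots_a: list[SpotMeasurement]
    spots_b: list[SpotMeasurement]
    planted: list[str]  # protein_ids of true binders


def gen_microarray(n_proteins: int = 1536, n_binders: int = 10,
                   effect_sd_multiple: float = 6.0, noise_sd: float = 0.1,
                   n_cols: int = 64, seed: int = 0) -> SyntheticArrayData:
    """Two replicate arrays with duplicate spots and planted binders.

    Background normalized intensity is multiplicative log-normal noise
    (symmetric on the log scale around R' = 1, log-SD = ``noise_sd``) on
    top of a smooth spatial trend that local normalization must remove;
    planted binders are elevated by ``effect_sd_multiple * noise_sd`` on
    all four of their spots.  Background medians B vary log-normally
    around 500 fluorescence units.
    """
    if n_binders > n_proteins:
        raise ValueError("more binders than proteins")
    rng = np.random.default_rng(seed)
    planted_idx = rng.choice(n_proteins, size=n_binders, replace=False)
    planted = sorted(f"P{i:05d}" for i in planted_idx)
    n_cells = 2 * n_proteins
    n_rows = -(-n_cells // n_cols)

    def make_array(array_id: str) -> list[SpotMeasurement]:
        spots = []
        for p in range(n_proteins):
            protein_id = f"P{p:05d}"
            for cell in (p, p + n_proteins):
                r, c = divmod(cell, n_cols)
                trend = np.exp(
                    0.2 * np.sin(2 * np.pi * r / n_rows)
                    * np.cos(2 * np.pi * c / n_cols)
                )
                r_prime = float(np.exp(rng.normal(0.0, noise_sd)))
                if protein_id in planted:
                    r_prime += effect_sd_multiple * noise_sd
                B = float(rng.lognormal(np.log(500.0), 0.2))
                spots.append(
                    SpotMeasurement(
                        array_id=array_id, grid_pos=(r, c),
                        protein_id=protein_id,
                        F=B * r_prime * trend, B=B, flag=OK,
                    )
                )
        return spots

    return SyntheticArrayData(
        spots_a=make_array("rep_a"),
        spots_b=make_array("rep_b"),
        planted=planted,
    )


def write_spot_table(path, spots: list[SpotMeasurement],
                     n_rows_per_block: int | None = None) -> None:
    """Write spots as a single-block GenePix-results-style TSV."""
    with open(path, "w") as fh:
        fh.write("Block\tRow\tColumn\tName\tF_Median\tB_Median\tFlag\n")
        for s in spots:
            r, c = s.grid_pos
            fh.write(
                f"1\t{r + 1}\t{c + 1}\t{s.protein_id}\t{s.F:.4f}\t"
                f"{s.B:.4f}\t{s.flag}\n"
            )


# ---------------------------------------------------------------------------
# ChIP-seq peaks + methylome with a planted central-CpG k-mer
# ---------------------------------------------------------------------------

@dataclass
class SyntheticChipData:
    genome: dict[str, str]
    peaks: list[Peak]
    methylome: dict[tuple[str, int], MethylomeRecord]
    summit_m: list[float]  # true M assigned to each summit, peak order
    strata: list[str]  # "high" / "mid" / "low" per summit
    planted_kmer: str
    fold: float


def gen_peaks_methylome(n_summits: int = 400, frac_high_m: float = 0.48,
                        frac_low_m: float = 0.38,
                        planted_kmer: str = "CCCGCC", fold: float = 5.0,
                        summit_half: int = 60, mean_coverage: int = 30,
                        seed: int = 0) -> SyntheticChipData:
    """Random genome with binding peaks, stratified summit methylation and
    a planted k-mer enriched in highly methylated summit windows.

    Summits draw true methylation from high (U(0.85, 0.99)),
    low (U(0.01, 0.15)) or intermediate (U(0.3, 0.7)) strata at the given
    fractions.  In each high-M foreground window the planted k-mer is
    inserted so its occurrence rate reaches ``fold`` times the uniform
    background rate; ``fold = 1`` plants nothing (null genome).  CpG read
    counts are Poisson-coverage binomial draws at each CG dinucleotide,
    using the summit's true M inside foreground windows and a uniform
    level elsewhere.
    """
    if frac_high_m + frac_low_m > 1:
        raise ValueError("stratum fractions exceed 1")
    mid = len(planted_kmer) // 2 - 1
    if planted_kmer[mid:mid + 2] != "CG":
        raise ValueError("planted k-mer must have CG at its center")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    margin, min_len, max_len = 200, 200, 350

    genome_parts: list[np.ndarray] = []
    peaks: list[Peak] = []
    cursor = 0
    for _ in range(n_summits):
        gap = margin + int(rng.integers(0, 100))
        length = int(rng.integers(min_len, max_len + 1))
        start = cursor + gap
        wobble = int(rng.integers(-(length // 5), length // 5 + 1))
        summit = start + length // 2 + wobble
        genome_parts.append(rng.choice(4, size=gap + length))
        peaks.append(Peak(chrom=chrom, start=start, end=start + length,
                          summit=summit))
        cursor = start + length
    genome_parts.append(rng.choice(4, size=margin))
    seq = np.concatenate(genome_parts).astype(np.int8)

    # stratified summit methylation
    strata_pool = (["high"] * round(frac_high_m * n_summits)
                   + ["low"] * round(frac_low_m * n_summits))
    strata_pool += ["mid"] * (n_summits - len(strata_pool))
    strata = list(rng.permutation(strata_pool))
    bounds = {"high": (0.85, 0.99), "low": (0.01, 0.15), "mid": (0.3, 0.7)}
    summit_m = [float(rng.uniform(*bounds[s])) for s in strata]

    # plant the k-mer in high-M foreground windows at fold x background rate
    k = len(planted_kmer)
    kmer_codes = np.array(["ACGT".index(b) for b in planted_kmer], dtype=np.int8)
    window_len = 2 * summit_half + 1
    n_offsets = window_len - k + 1
    base_rate = n_offsets * 2 / 4 ** k  # expected copies per window, both strands
    lam = max(fold - 1.0, 0.0) * base_rate
    for peak, stratum in zip(peaks, strata):
        if stratum != "high" or lam == 0:
            continue
        for _ in range(rng.poisson(lam)):
            off = int(rng.integers(0, n_offsets))
            pos = peak.summit - summit_half + off
            seq[pos:pos + k] = kmer_codes

    genome = {chrom: "".join(BASES[seq])}

    # methylome over every CG dinucleotide
    fg_level: dict[int, float] = {}
    for peak, m in zip(peaks, summit_m):
        for pos in range(peak.summit - summit_half, peak.summit + summit_half + 1):
            fg_level[pos] = m
    cg_positions = np.flatnonzero((seq[:-1] == 1) & (seq[1:] == 2))
    methylome: dict[tuple[str, int], MethylomeRecord] = {}
    for pos in cg_positions:
        pos = int(pos)
        level = fg_level.get(pos, float(rng.uniform(0, 1)))
        n_total = int(rng.poisson(mean_coverage)) + 1
        n_meth = int(rng.binomial(n_total, level))
        methylome[(chrom, pos)] = MethylomeRecord(
            chrom=chrom, pos=pos, n_meth=n_meth, n_total=n_total
        )

    return SyntheticChipData(
        genome=genome, peaks=peaks, methylome=methylome,
        summit_m=summit_m, strata=strata,
        planted_kmer=planted_kmer, fold=fold,
    )


def write_genome_fasta(path, genome: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_methylome_tsv(path,
                        methylome: dict[tuple[str, int], MethylomeRecord]
                        ) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tn_meth\tn_total\n")
        for (chrom, pos), rec in sorted(methylome.items()):
            fh.write(f"{chrom}\t{pos}\t+\t{rec.n_meth}\t{rec.n_total}\n")


# ---------------------------------------------------------------------------
# OIRD sensorgrams
# ---------------------------------------------------------------------------

def gen_sensorgram(k_on: float, k_off: float, concentration: float,
                   s_max: float = 1.0, noise_frac: float = 0.0,
                   dt: float = 10.0, seed: int = 0,
                   t_assoc: float | None = None,
                   t_dissoc: float | None = None) -> Sensorgram:
    """A 1:1 Langmuir sensorgram sampled every ``dt`` seconds.

    Phase durations default to ~5 characteristic times of each phase
    (bounded to [100 s, 5000 s]) so both curves are informative at the
    10 s sampling interval; noise is multiplicative Gaussian with
    fractional SD ``noise_frac``.
    """
    if k_on <= 0 or k_off <= 0 or concentration <= 0:
        raise ValueError("rates and concentration must be positive")
    rng = np.random.default_rng(seed)
    k_obs = k_on * concentration + k_off
    if t_assoc is None:
        t_assoc = float(np.clip(np.ceil(5.0 / k_obs / dt) * dt, 100.0, 5000.0))
    if t_dissoc is None:
        t_dissoc = float(np.clip(np.ceil(5.0 / k_off / dt) * dt, 100.0, 5000.0))
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    assoc = times < t_assoc
    signals = np.empty_like(times)
    signals[assoc] = model_association(times[assoc], k_on, k_off,
                                       concentration, s_max)
    s_wash = float(model_association(t_assoc, k_on, k_off, concentration, s_max))
    signals[~assoc] = model_dissociation(times[~assoc] - t_assoc, s_wash, k_off)
    if noise_frac > 0:
        signals = signals * (1.0 + noise_frac * rng.normal(size=signals.shape))
    return Sensorgram(times=times, signals=signals,
                      concentration=concentration, t_wash=t_assoc)


def write_sensorgram_tsv(path, data: Sensorgram) -> None:
    with open(path, "w") as fh:
        fh.write(f"# concentration_M={data.concentration}\t"
                 f"t_wash_s={data.t_wash}\n")
        fh.write("time_s\tsignal\tphase\n")
        for t, s in zip(data.times, data.signals):
            phase = "association" if t < data.t_wash else "dissociation"
            fh.write(f"{t:.1f}\t{s:.8g}\t{phase}\n")


# ---------------------------------------------------------------------------
# Bisulfite read sets
# ---------------------------------------------------------------------------

def gen_bisulfite(input_levels: dict[int, float],
                  chip_levels: dict[int, float], coverage: int = 20,
                  missing_rate: float = 0.0, seed: int = 0,
                  region_id: str = "region") -> tuple[BisulfiteReadSet,
                                                      BisulfiteReadSet]:
    """Input and ChIP read sets with Bernoulli calls at the stated levels.

    Both sets share CpG positions (the union of the two level maps);
    ``missing_rate`` drops individual calls to missing, never a whole read.
    """
    rng = np.random.default_rng(seed)
    positions = tuple(sorted(set(input_levels) | set(chip_levels)))

    def make(levels: dict[int, float], label: str) -> BisulfiteReadSet:
        calls = np.empty((coverage, len(positions)), dtype=np.int8)
        for j, pos in enumerate(positions):
            p = levels.get(pos, 0.5)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"level {p} at {pos} outside [0, 1]")
            calls[:, j] = np.where(rng.random(coverage) < p, METH, UNMETH)
        if missing_rate > 0:
            drop = rng.random(calls.shape) < missing_rate
            # a read must keep at least one informative call
            all_dropped = drop.all(axis=1)
            drop[all_dropped, 0] = False
            calls[drop] = MISSING
        return BisulfiteReadSet(region_id=f"{region_id}_{label}",
                                cpg_positions=positions, calls=calls)

    return make(input_levels, "input"), make(chip_levels, "chip")
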