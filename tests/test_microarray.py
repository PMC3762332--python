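"""Microarray normalization, noise estimation, Z-scores and hit calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcpgbind import microarray as ma


def grid_from_values(values, protein_map=None):
    return ma.ArrayGrid(array_id="test", values=np.asarray(values, dtype=float),
                        protein_map=protein_map or {})


# ---------------------------------------------------------------------------
# spot-table parsing and raw intensity
# ---------------------------------------------------------------------------

def write_table(path, rows, header="Block\tRow\tColumn\tName\tF_Median\tB_Median\tFlag"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def test_read_spot_table_parses_rows(tmp_path):
    p = tmp_path / "a.tsv"
    write_table(p, [
        "1\t1\t1\tP1\t2000\t500\tok",
        "1\t1\t2\tP1\t1000\t500\tok",
        "1\t2\t1\tP2\t500\t500\tok",
        "1\t2\t2\tP2\t500\t500\tok",
    ])
    spots = ma.read_spot_table(p)
    assert len(spots) == 4
    assert spots[0].grid_pos == (0, 0) and spots[0].F == 2000
    grid = ma.compute_raw_intensity(spots)
    assert grid.values[0, 0] == 4.0  # F/B = 2000/500
    assert grid.values[1, 0] == 1.0  # F == B


def test_read_spot_table_missing_column(tmp_path):
    p = tmp_path / "bad.tsv"
    write_table(p, ["1\t1\t1\tP1\t2000\tok"],
                header="Block\tRow\tColumn\tName\tF_Median\tFlag")
    with pytest.raises(ma.SpotTableFormatError, match="B_Median"):
        ma.read_spot_table(p)


def test_read_spot_table_nonpositive_background(tmp_path):
    p = tmp_path / "bad.tsv"
    write_table(p, ["1\t1\t1\tP1\t2000\t0\tok"])
    with pytest.raises(ma.SpotValueError, match="row 2"):
        ma.read_spot_table(p)


def test_excluded_spot_becomes_missing():
    spots = [
        ma.SpotMeasurement("a", (0, 0), "P1", F=100, B=50, flag=ma.EXCLUDED),
        ma.SpotMeasurement("a", (0, 1), "P1", F=100, B=50),
    ]
    grid = ma.compute_raw_intensity(spots)
    assert np.isnan(grid.values[0, 0]) and grid.values[0, 1] == 2.0


def test_duplicate_grid_position_rejected():
    spots = [
        ma.SpotMeasurement("a", (0, 0), "P1", F=100, B=50),
        ma.SpotMeasurement("a", (0, 0), "P2", F=100, B=50),
    ]
    with pytest.raises(ma.ArrayStructureError):
        ma.compute_raw_intensity(spots)


# ---------------------------------------------------------------------------
# local normalization
# ---------------------------------------------------------------------------

def brute_force_window_median(values, r, c, window):
    """Independent truncated-window median: explicit loops + manual median."""
    half = window // 2
    vals = []
    for i in range(r - half, r + half + 1):
        for j in range(c - half, c + half + 1):
            if 0 <= i < values.shape[0] and 0 <= j < values.shape[1]:
                if not math.isnan(values[i, j]):
                    vals.append(values[i, j])
    vals.sort()
    n = len(vals)
    return vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2


def test_constant_grid_normalizes_to_one():
    grid = grid_from_values(np.full((9, 9), 4.0))
    out = ma.local_normalize(grid, window=9)
    assert np.allclose(out.values, 1.0)


def test_single_spike_survives_median():
    values = np.ones((9, 9))
    values[4, 4] = 10.0
    out = ma.local_normalize(grid_from_values(values), window=9)
    assert out.values[4, 4] == 10.0  # median of 81 values with one spike is 1


@pytest.mark.parametrize("window", [3, 5, 9])
@pytest.mark.parametrize("shape", [(5, 5), (7, 12), (12, 12)])
def test_window_median_matches_brute_force(window, shape):
    rng = np.random.default_rng(shape[0] * 100 + window)
    values = rng.lognormal(0, 0.5, size=shape)
    values[rng.random(shape) < 0.1] = np.nan  # sprinkle missing cells
    out = ma.local_normalize(grid_from_values(values), window=window)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if math.isnan(values[r, c]):
                assert math.isnan(out.values[r, c])
            else:
                expected = values[r, c] / brute_force_window_median(
                    values, r, c, window)
                assert out.values[r, c] == pytest.approx(expected)


def test_even_or_tiny_window_rejected():
    grid = grid_from_values(np.ones((5, 5)))
    for w in (1, 4):
        with pytest.raises(ValueError):
            ma.local_normalize(grid, window=w)


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def test_noise_hand_computed_example():
    # N1 = {0.8, 0.9, 0.95}; N = N1 u (2 - N1) has mean 1 and population SD
    # sqrt(2 * (0.04 + 0.01 + 0.0025) / 6)
    grid = grid_from_values([[0.8, 0.9, 0.95, 1.3, 5.0]])
    noise = ma.estimate_noise(grid, min_shadow=3)
    assert noise.mean == pytest.approx(1.0)
    assert noise.n_shadow == 3
    assert noise.sd == pytest.approx(math.sqrt(0.105 / 6), rel=1e-12)


def test_all_above_one_is_degenerate():
    grid = grid_from_values(np.full((5, 5), 1.5))
    with pytest.raises(ma.DegenerateNoiseError):
        ma.estimate_noise(grid)


def test_mirrored_sd_recovers_gaussian_sd():
    rng = np.random.default_rng(42)
    grid = grid_from_values(rng.normal(1.0, 0.1, size=(100, 100)))
    noise = ma.estimate_noise(grid)
    assert noise.sd == pytest.approx(0.1, rel=0.03)


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(0.01, 3.0), min_size=20, max_size=200))
def test_constructed_noise_mean_is_one(values):
    grid = grid_from_values([values])
    try:
        noise = ma.estimate_noise(grid)
    except ma.DegenerateNoiseError:
        return
    assert noise.mean == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Z-scores and hit calling
# ---------------------------------------------------------------------------

def test_zscore_centering_and_scaling():
    noise = ma.NoiseModel(mean=1.0, sd=0.1323, n_shadow=100)
    grid = grid_from_values([[1.0, 1.0 + 3 * 0.1323, 1.3969]])
    z = ma.compute_zscores(grid, noise)
    assert z.values[0, 0] == 0.0
    assert z.values[0, 1] == pytest.approx(3.0)
    assert z.values[0, 2] == pytest.approx(3.0, rel=1e-3)


def test_zscores_invariant_under_global_intensity_scaling():
    rng = np.random.default_rng(7)
    spots = [
        ma.SpotMeasurement("a", (i, j), f"P{i}_{j}",
                           F=float(rng.uniform(400, 900)),
                           B=float(rng.uniform(300, 600)))
        for i in range(12) for j in range(12)
    ]
    scaled = [
        ma.SpotMeasurement(s.array_id, s.grid_pos, s.protein_id,
                           F=7.5 * s.F, B=7.5 * s.B)
        for s in spots
    ]
    z1, _ = ma.process_array(spots, window=5)
    z2, _ = ma.process_array(scaled, window=5)
    assert np.allclose(z1.values, z2.values)


@pytest.mark.parametrize("four_z, expect_hit", [
    ((3.2, 4.0, 3.1, 5.0), True),  # all four spots at or above the cutoff
    ((3.2, 4.0, 2.9, 5.0), False),  # one spot below the cutoff
    ((3.0, 3.0, 3.0, 3.0), True),  # cutoff is inclusive
])
def test_all_four_spots_rule(four_z, expect_hit):
    pm = {"P1": [(0, 0), (0, 1)]}
    za = grid_from_values([[four_z[0], four_z[1]]], pm)
    zb = grid_from_values([[four_z[2], four_z[3]]], pm)
    table = ma.call_hits((za, zb), "M1")
    assert table.is_hit("P1", "M1") is expect_hit


def test_missing_spot_blocks_hit():
    pm = {"P1": [(0, 0), (0, 1)]}
    za = grid_from_values([[5.0, np.nan]], pm)
    zb = grid_from_values([[5.0, 5.0]], pm)
    assert not ma.call_hits((za, zb), "M1").is_hit("P1", "M1")


def test_empty_protein_map_gives_empty_table():
    za = grid_from_values([[1.0]], {})
    table = ma.call_hits((za, za), "M1")
    assert table.hits.empty or not table.hits.any().any()


def test_wrong_spot_multiplicity_rejected():
    pm = {"P1": [(0, 0)]}
    za = grid_from_values([[5.0]], pm)
    with pytest.raises(ma.ArrayStructureError):
        ma.call_hits((za, za), "M1")


# ---------------------------------------------------------------------------
# replicate correlation
# ---------------------------------------------------------------------------

def test_correlation_identity_and_affine_invariance():
    rng = np.random.default_rng(0)
    a = grid_from_values(rng.normal(1, 0.2, (10, 10)))
    b = grid_from_values(2 * a.values + 1)
    assert ma.replicate_correlation(a, a) == pytest.approx(1.0)
    assert ma.replicate_correlation(a, b) == pytest.approx(1.0)


def test_correlation_null_for_independent_noise():
    rng = np.random.default_rng(3)
    a = grid_from_values(rng.normal(1, 0.1, (25, 40)))
    b = grid_from_values(rng.normal(1, 0.1, (25, 40)))
    assert abs(ma.replicate_correlation(a, b)) < 0.1


def test_correlation_needs_three_joint_cells():
    a = grid_from_values([[1.0, np.nan, 2.0]])
    b = grid_from_values([[1.0, 1.0, np.nan]])
    with pytest.raises(ma.UndefinedCorrelationError):
        ma.replicate_correlation(a, b)
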