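"""FGR/BGR, robust background, SSMD* and gene aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

import mirescreen as ms

from _oracle import naive_scores
from conftest import make_norm, tiny_library, tiny_sheet

SQRT2 = math.sqrt(2.0)


@pytest.fixture()
def three_arm_norm():
    """4 constructs, one replicate, hand-set log2 values."""
    library = tiny_library(4, seed=1)
    sheet = tiny_sheet(replicates=("R1",))
    return library, sheet


def test_log_ratios_direct_subtraction(three_arm_norm):
    library, sheet = three_arm_norm
    norm = make_norm(
        {
            "scr_p00_R1_Day0": [8.0, 8.0, 8.0, 7.0],
            "scr_p00_R1_Day14": [8.0, 8.0, 9.0, 7.0],
            "scr_p00_R1_Day14Dox": [5.0, 8.0, 9.0, 7.0],
        },
        library,
        sheet,
    )
    ratios = ms.compute_log_ratios(norm)
    assert ratios["fgr_R1"].tolist() == [-3.0, 0.0, 0.0, 0.0]
    assert ratios["bgr_R1"].tolist() == [0.0, 0.0, -1.0, 0.0]
    assert not ratios["fallback_R1"].any()


def test_log_ratios_day14_fallback(three_arm_norm):
    """With Day14 masked, FGR falls back to Day14Dox - Day0 and is flagged;
    BGR is missing for that replicate."""
    library, sheet = three_arm_norm
    cid = library["construct_id"].iloc[0]
    norm = make_norm(
        {
            "scr_p00_R1_Day0": [8.0, 8.0, 8.0, 8.0],
            "scr_p00_R1_Day14": [6.0, 8.0, 8.0, 8.0],
            "scr_p00_R1_Day14Dox": [5.0, 8.0, 8.0, 8.0],
        },
        library,
        sheet,
        mask_out=[(cid, "scr_p00_R1_Day14")],
    )
    ratios = ms.compute_log_ratios(norm)
    assert ratios.loc[cid, "fgr_R1"] == -3.0
    assert np.isnan(ratios.loc[cid, "bgr_R1"])
    assert bool(ratios.loc[cid, "fallback_R1"])
    assert not ratios["fallback_R1"].drop(cid).any()


def test_log_ratios_missing_dox_unscored(three_arm_norm):
    library, sheet = three_arm_norm
    cid = library["construct_id"].iloc[1]
    norm = make_norm(
        {
            "scr_p00_R1_Day0": [8.0] * 4,
            "scr_p00_R1_Day14": [8.0] * 4,
            "scr_p00_R1_Day14Dox": [8.0] * 4,
        },
        library,
        sheet,
        mask_out=[(cid, "scr_p00_R1_Day14Dox")],
    )
    ratios = ms.compute_log_ratios(norm)
    assert np.isnan(ratios.loc[cid, "fgr_R1"])


def test_background_stats_hand_computed():
    """Pooled BGR [-1, 0, 0, 1, 3]: median 0, MAD = 1.4826 x median([1,0,0,1,3])."""
    ratios = pd.DataFrame({"bgr_R1": [-1.0, 0.0, 0.0, 1.0, 3.0]})
    median_bgr, mad = ms.background_stats(ratios)
    assert median_bgr == 0.0
    assert mad == pytest.approx(1.4826)


def test_background_stats_pools_both_replicates():
    ratios = pd.DataFrame({"bgr_R1": [1.0, 2.0], "bgr_R2": [3.0, np.nan]})
    median_bgr, mad = ms.background_stats(ratios)
    assert median_bgr == 2.0
    assert mad == pytest.approx(1.4826 * 1.0)


def test_background_stats_symmetric_median_zero():
    ratios = pd.DataFrame({"bgr_R1": [-2.0, -1.0, 1.0, 2.0]})
    median_bgr, _ = ms.background_stats(ratios)
    assert median_bgr == 0.0


def test_background_stats_degenerate_errors():
    with pytest.raises(ValueError, match="no finite"):
        ms.background_stats(pd.DataFrame({"bgr_R1": [np.nan]}))
    with pytest.raises(ValueError, match="MAD = 0"):
        ms.background_stats(pd.DataFrame({"bgr_R1": [2.0, 2.0, 2.0]}))


def test_ssmd_star_centering_and_conventions():
    assert ms.ssmd_star(0.7, 0.7, 2.0) == 0.0
    divide = ms.ssmd_star(-3.0, 0.0, 1.4826, convention="divide")
    assert divide == pytest.approx(-3.0 / (SQRT2 * 1.4826))
    assert divide == pytest.approx(-1.4308, abs=2e-4)
    multiply = ms.ssmd_star(-3.0, 0.0, 1.4826, convention="multiply")
    assert multiply == pytest.approx(-2.8616, abs=4e-4)
    assert multiply == pytest.approx(2 * divide)
    with pytest.raises(ValueError):
        ms.ssmd_star(1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        ms.ssmd_star(1.0, 0.0, 1.0, convention="other")


def test_ssmd_star_strictly_increasing_in_fgr():
    fgr = np.linspace(-5, 5, 21)
    out = ms.ssmd_star(fgr, 0.3, 0.9)
    assert (np.diff(out) > 0).all()


def test_avssmd_replicate_handling():
    assert ms.avssmd(-1.2, -1.8) == (pytest.approx(-1.5), 2)
    assert ms.avssmd(-1.2, None) == (pytest.approx(-1.2), 1)
    value, used = ms.avssmd(None, float("nan"))
    assert math.isnan(value) and used == 0


def test_protease_aggregate_mean_and_reduction():
    library = pd.concat(
        [tiny_library(3, gene="GeneA", seed=1), tiny_library(5, gene="GeneB", seed=2)],
        ignore_index=True,
    )
    mire = pd.DataFrame(
        {
            "avssmd": [-4.0, -2.0, 0.0, 1.0, np.nan, np.nan, np.nan, np.nan],
            "replicates_used": [2, 2, 1, 1, 0, 0, 0, 0],
        },
        index=pd.Index(library["construct_id"], name="construct_id"),
    )
    genes = ms.protease_aggregate(mire, library)
    assert genes.loc["GeneA", "avssmd_protease"] == pytest.approx(-2.0)
    assert genes.loc["GeneB", "avssmd_protease"] == pytest.approx(1.0)
    assert genes.loc["GeneB", "n_scored"] == 1


def test_protease_aggregate_excludes_controls(small_screen, small_scored):
    library = small_screen[0]
    mire, _ = small_scored
    genes = ms.protease_aggregate(mire, library)
    assert "" not in genes.index
    assert set(genes.index) <= set(library["target_gene"])


def _random_norm(rng, n_constructs=60, n_pools=2, missing=0.1):
    per_pool = n_constructs // (4 * n_pools)
    libs = []
    for p in range(n_pools):
        libs.append(tiny_library(per_pool * 4, gene=f"G{p}", pool=p, seed=int(rng.integers(1e6))))
        for i, g in enumerate(np.array_split(np.arange(per_pool * 4), 4)):
            libs[-1].loc[g, "target_gene"] = f"G{p}x{i}"
    library = pd.concat(libs, ignore_index=True)
    library["construct_id"] = [f"c{i:03d}" for i in range(len(library))]
    rows = []
    for p in range(n_pools):
        s = tiny_sheet(replicates=("R1", "R2"), pool=p, screen_id="scr")
        s["barcode"] = [f"bc{p}{i}" for i in range(len(s))]
        rows.append(s)
    sheet = pd.concat(rows, ignore_index=True)
    index = pd.Index(library["construct_id"], name="construct_id")
    values = pd.DataFrame(np.nan, index=index, columns=sheet["sample_id"])
    mask = pd.DataFrame(False, index=index, columns=sheet["sample_id"])
    pools = library.set_index("construct_id")["pool_id"]
    for _, s in sheet.iterrows():
        in_pool = (pools == s["pool_id"]).to_numpy()
        vals = rng.normal(10, 2, size=in_pool.sum())
        values.loc[in_pool, s["sample_id"]] = vals
        keep = rng.random(in_pool.sum()) > missing
        mask.loc[in_pool, s["sample_id"]] = keep
    return ms.NormalizedMatrix(
        values=values, mask=mask, pseudocount=1.0, scale=1e6, library=library, sheet=sheet
    )


@pytest.mark.parametrize("convention", ["divide", "multiply"])
@pytest.mark.parametrize("seed", [0, 1])
def test_oracle_equivalence_random_tables(seed, convention):
    """The vectorized pipeline matches a brute-force loop implementation of
    the scoring formulas on randomized masked tables."""
    rng = np.random.default_rng(seed)
    norm = _random_norm(rng)
    mire, stats = ms.score_constructs(norm, convention=convention)
    stats.sd_avssmd = ms.sd_cutoff(mire)
    naive_c, naive_s, naive_g = naive_scores(norm, convention=convention)
    assert stats.median_bgr == pytest.approx(naive_s["median_bgr"], abs=1e-9)
    assert stats.mad == pytest.approx(naive_s["mad"], abs=1e-9)
    assert stats.n_constructs_scored == naive_s["n_constructs_scored"]
    assert stats.sd_avssmd == pytest.approx(naive_s["sd_avssmd"], abs=1e-9)
    for cid, rec in naive_c.items():
        for col in ("fgr_R1", "fgr_R2", "bgr_R1", "bgr_R2", "ssmd_R1", "ssmd_R2", "avssmd"):
            got = mire.loc[cid, col]
            want = rec[col]
            if want is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)
        assert mire.loc[cid, "replicates_used"] == rec["replicates_used"]
    genes = ms.protease_aggregate(mire, norm.library)
    assert set(genes.index) == set(naive_g)
    for g, want in naive_g.items():
        assert genes.loc[g, "avssmd_protease"] == pytest.approx(want, abs=1e-9)


def test_location_shift_covariance():
    """Adding c to every Day14 value shifts FGR and BGR by -c but leaves
    SSMD* exactly unchanged."""
    rng = np.random.default_rng(4)
    norm = _random_norm(rng, missing=0.0)
    mire, _ = ms.score_constructs(norm)
    shifted_values = norm.values.copy()
    day14 = norm.sheet.loc[
        (norm.sheet["timepoint"] == "Day14") & (~norm.sheet["dox"]), "sample_id"
    ]
    for sid in day14:
        shifted_values[sid] = shifted_values[sid] + 2.5
    shifted = ms.NormalizedMatrix(
        values=shifted_values, mask=norm.mask, pseudocount=1.0, scale=1e6,
        library=norm.library, sheet=norm.sheet,
    )
    mire2, _ = ms.score_constructs(shifted)
    for rep in ("R1", "R2"):
        np.testing.assert_allclose(
            mire2[f"fgr_{rep}"], mire[f"fgr_{rep}"] - 2.5, atol=1e-12
        )
        np.testing.assert_allclose(
            mire2[f"ssmd_{rep}"], mire[f"ssmd_{rep}"], atol=1e-9
        )


def test_sign_convention_depletion_negative(small_screen, small_scored):
    """Constructs depleted under doxycycline score negative."""
    library, sheet, matrix, truth, labels = small_screen
    mire, _ = small_scored
    depleted = set(
        truth.effects[truth.effects < 0].index
    ) & set(mire[mire["replicates_used"] >= 1].index)
    assert depleted
    assert (mire.loc[sorted(depleted), "avssmd"] < 0).all()


def test_null_calibration_median_near_zero():
    """Across seeded null screens the median AvSSMD* stays within +/-0.2."""
    medians = []
    for seed in range(6):
        cfg = ms.SimConfig(
            n_genes=40, guides_per_gene=(5, 5), n_pools=1, depth=400_000,
            depletion_control_effect=0.0, seed=100 + seed,
        )
        lib = ms.build_library(cfg)
        sheet = ms.build_sample_sheet(cfg, "null")
        matrix, _ = ms.simulate_counts(lib, sheet, cfg)
        mire, _ = ms.score_constructs(ms.normalize_pool(matrix))
        medians.append(float(mire["avssmd"].median()))
    assert all(abs(m) <= 0.2 for m in medians)
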