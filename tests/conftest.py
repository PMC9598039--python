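from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import mirescreen as ms


@pytest.fixture(scope="session")
def small_config():
    return ms.SimConfig(
        n_genes=20,
        guides_per_gene=(4, 5),
        n_pools=2,
        depth=200_000,
        representation=1000,
        baseline_dispersion=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    """A small simulated screen with 20% of genes planted at e = -4."""
    library = ms.build_library(small_config)
    effect_map, labels = ms.plant_effects(library, frac_depleted=0.2, effect=-4.0, seed=11)
    cfg = replace(small_config, effect_map=effect_map)
    sheet = ms.build_sample_sheet(cfg, "scrA")
    matrix, truth = ms.simulate_counts(library, sheet, cfg)
    return library, sheet, matrix, truth, labels


@pytest.fixture(scope="session")
def small_normalized(small_screen):
    library, sheet, matrix, truth, labels = small_screen
    norm = ms.normalize_pool(matrix)
    return ms.trim_extremes(norm, matrix)


@pytest.fixture(scope="session")
def small_scored(small_normalized):
    mire, stats = ms.score_constructs(small_normalized)
    stats.sd_avssmd = ms.sd_cutoff(mire)
    return mire, stats


def make_norm(values_by_sample, library, sheet, mask_out=()):
    """Assemble a NormalizedMatrix directly from per-sample value lists.

    ``values_by_sample`` maps sample_id -> list of values aligned with the
    library rows (NaN allowed); cells listed in ``mask_out`` as
    (construct_id, sample_id) are additionally trimmed.
    """
    index = pd.Index(library["construct_id"], name="construct_id")
    values = pd.DataFrame(
        {sid: pd.Series(vals, index=index, dtype=float) for sid, vals in values_by_sample.items()}
    )
    mask = values.notna()
    for cid, sid in mask_out:
        mask.loc[cid, sid] = False
    return ms.NormalizedMatrix(
        values=values, mask=mask, pseudocount=1.0, scale=1e6, library=library, sheet=sheet
    )


def tiny_library(n_constructs=4, gene="GeneA", pool=0, guide_len=22, seed=0):
    """One-gene library of n target constructs (no controls)."""
    rng = np.random.default_rng(seed)
    guides = []
    seen = set()
    while len(guides) < n_constructs:
        g = "".join("ACGT"[i] for i in rng.integers(0, 4, guide_len))
        if g not in seen:
            seen.add(g)
            guides.append(g)
    return pd.DataFrame(
        {
            "construct_id": [f"{gene}.{i + 1}" for i in range(n_constructs)],
            "guide_seq": guides,
            "target_gene": gene,
            "pool_id": pool,
            "role": "target",
        }
    )


def tiny_sheet(replicates=("R1",), pool=0, screen_id="scr", with_dox=True):
    rows = []
    arms = [("Day0", False), ("Day14", False)] + ([("Day14", True)] if with_dox else [])
    barcodes = iter(
        ["ACGTACGTAC", "TGCATGCATG", "GGAACCTTGG", "CCTTGGAACC", "ATATCGCGAT", "GCGCATATCG"]
    )
    for rep in replicates:
        for timepoint, dox in arms:
            label = ms.simulate.arm_label(timepoint, dox)
            rows.append(
                (f"{screen_id}_p{pool:02d}_{rep}_{label}", screen_id, pool, rep, timepoint, dox, next(barcodes))
            )
    return pd.DataFrame(rows, columns=ms.simulate.SHEET_COLUMNS)
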