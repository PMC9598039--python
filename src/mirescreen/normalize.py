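"""Pool-based normalization, log2 transform, outlier trimming and screen QC.

Each sequencing sample holds one construct pool, so normalization happens
strictly within (pool, sample): raw counts are scaled to a common library
size (counts-per-million by default), a pseudocount is added after scaling to
preserve exact depth invariance, and values move to log2. Trimming masks
low-coverage and extreme cells instead of deleting them, so missingness can
propagate into the scoring fallbacks. QC reproduces the screen's replicate
correlation checks (Day14 vs Day0 within replicates, Day14 across replicates)
and the behavior of the spiked-in stability/depletion controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import (
    CountMatrix,
    ROLE_DEPLETION,
    ROLE_STABILITY,
    arm_label,
)

logger = logging.getLogger("mirescreen.normalize")


@dataclass
class NormalizedMatrix:
    """Log2 pool-normalized abundances plus a retained/trimmed mask.

    ``values`` and ``mask`` share the CountMatrix shape; a cell is usable
    exactly where ``mask`` is True. The pseudocount and scale that produced
    the values are recorded for provenance.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    pseudocount: float
    scale: float
    library: pd.DataFrame
    sheet: pd.DataFrame

    def retained(self, sample_id: str) -> pd.Series:
        """Values of one sample where the mask retains them."""
        return self.values.loc[self.mask[sample_id], sample_id]


def normalize_pool(
    matrix: CountMatrix,
    pseudocount: float = 1.0,
    scale: float = 1e6,
) -> NormalizedMatrix:
    """value = log2(count / pool_total * scale + pseudocount), per sample.

    Because each sample contains a single pool, the pool total is the sample
    total. Samples with zero total are fully masked (warned), as are cells
    outside a sample's pool.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = matrix.counts
    values = pd.DataFrame(np.nan, index=counts.index, columns=counts.columns)
    mask = pd.DataFrame(False, index=counts.index, columns=counts.columns)
    for sample in counts.columns:
        col = counts[sample]
        defined = col.notna()
        total = col[defined].sum()
        if total == 0:
            logger.warning("sample %s has zero total counts; all cells masked", sample)
            continue
        with np.errstate(divide="ignore"):
            vals = np.log2(col[defined] / total * scale + pseudocount)
        values.loc[defined, sample] = vals
        mask.loc[defined, sample] = np.isfinite(vals)
    return NormalizedMatrix(
        values=values,
        mask=mask,
        pseudocount=pseudocount,
        scale=scale,
        library=matrix.library,
        sheet=matrix.sheet,
    )


def trim_extremes(
    norm: NormalizedMatrix,
    matrix: CountMatrix,
    min_day0_count: int = 30,
    ratio_cap: float = 8.0,
) -> NormalizedMatrix:
    """Mask under-represented and extreme observations.

    A construct whose raw Day0 count falls below ``min_day0_count`` in a
    replicate is masked across that whole (pool, replicate); any Day14 cell
    whose log2 change against its replicate's Day0 exceeds ``ratio_cap`` in
    magnitude is masked individually. Masks only ever grow.
    """
    if min_day0_count < 0 or ratio_cap < 0:
        raise ValueError("trim thresholds must be >= 0")
    mask = norm.mask.copy()
    sheet = norm.sheet
    for (screen, pool, rep), grp in sheet.groupby(["screen_id", "pool_id", "replicate"]):
        day0_rows = grp[grp["timepoint"] == "Day0"]
        if day0_rows.empty:
            continue
        day0_id = day0_rows.iloc[0]["sample_id"]
        day0_counts = matrix.counts[day0_id]
        low = day0_counts.notna() & (day0_counts < min_day0_count)
        day0_vals = norm.values[day0_id]
        for sid in grp["sample_id"]:
            mask.loc[low, sid] = False
            if sid != day0_id and np.isfinite(ratio_cap):
                delta = (norm.values[sid] - day0_vals).abs()
                mask.loc[delta > ratio_cap, sid] = False
    n_new = int((norm.mask & ~mask).to_numpy().sum())
    if mask.to_numpy().sum() == 0:
        logger.warning("trimming masked every cell; check thresholds")
    logger.info(
        "trimming masked %d cells (min_day0_count=%s, ratio_cap=%s)",
        n_new,
        min_day0_count,
        ratio_cap,
    )
    return NormalizedMatrix(
        values=norm.values,
        mask=mask,
        pseudocount=norm.pseudocount,
        scale=norm.scale,
        library=norm.library,
        sheet=norm.sheet,
    )


def _pooled_pair(
    norm: NormalizedMatrix, pairs: list[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate co-retained values over a list of sample pairs."""
    xs, ys = [], []
    for sa, sb in pairs:
        keep = norm.mask[sa] & norm.mask[sb]
        xs.append(norm.values.loc[keep, sa].to_numpy())
        ys.append(norm.values.loc[keep, sb].to_numpy())
    if not xs:
        return np.array([]), np.array([])
    return np.concatenate(xs), np.concatenate(ys)


def qc_correlations(norm: NormalizedMatrix) -> pd.DataFrame:
    """Pearson correlations of normalized, trimmed log2 values per screen:
    Day14 vs Day0 within each replicate and Day14 between replicates, pooled
    over all pools of the screen. Pairs with fewer than 3 co-retained
    constructs are reported undefined (NaN)."""
    sheet = norm.sheet
    records = []
    for screen, scr in sheet.groupby("screen_id"):
        by_key = {
            (r["pool_id"], r["replicate"], arm_label(r["timepoint"], r["dox"])): r["sample_id"]
            for _, r in scr.iterrows()
        }
        pools = sorted(scr["pool_id"].unique())
        reps = sorted(scr["replicate"].unique())
        comparisons: list[tuple[str, list[tuple[str, str]]]] = []
        for rep in reps:
            pairs = [
                (by_key[(p, rep, "Day14")], by_key[(p, rep, "Day0")])
                for p in pools
                if (p, rep, "Day14") in by_key and (p, rep, "Day0") in by_key
            ]
            comparisons.append((f"Day14_vs_Day0_{rep}", pairs))
        if len(reps) >= 2:
            r1, r2 = reps[0], reps[1]
            pairs = [
                (by_key[(p, r1, "Day14")], by_key[(p, r2, "Day14")])
                for p in pools
                if (p, r1, "Day14") in by_key and (p, r2, "Day14") in by_key
            ]
            comparisons.append((f"Day14_{r1}_vs_{r2}", pairs))
        for name, pairs in comparisons:
            x, y = _pooled_pair(norm, pairs)
            if len(x) < 3:
                records.append((screen, name, np.nan, np.nan, len(x)))
                continue
            r, p = sps.pearsonr(x, y)
            records.append((screen, name, r, p, len(x)))
    return pd.DataFrame(
        records, columns=["screen_id", "comparison", "pearson_r", "p_value", "n_constructs"]
    )


def qc_controls(
    mire_scores: pd.DataFrame,
    library: pd.DataFrame,
    sd_avssmd: float,
) -> pd.DataFrame:
    """Control-construct behavior against the +/-1 SD_AvSSMD* band.

    Depletion controls (essential-gene hairpins) are expected below -1 SD;
    stability controls (luciferase hairpins) within +/-1 SD. Returns counts
    and fractions per control class.
    """
    roles = library.set_index("construct_id")["role"]
    scored = mire_scores[mire_scores["replicates_used"] >= 1]
    if not (roles.isin([ROLE_DEPLETION, ROLE_STABILITY])).any():
        logger.warning("library contains no control constructs; empty QC report")
        return pd.DataFrame(
            columns=["control_class", "criterion", "n_pass", "n_scored", "fraction"]
        )
    dep = scored.loc[scored.index.map(roles) == ROLE_DEPLETION, "avssmd"]
    stab = scored.loc[scored.index.map(roles) == ROLE_STABILITY, "avssmd"]
    n_dep_pass = int((dep < -sd_avssmd).sum())
    n_stab_pass = int((stab.abs() <= sd_avssmd).sum())
    return pd.DataFrame(
        [
            (
                "depletion_control",
                "AvSSMD* < -1 SD",
                n_dep_pass,
                len(dep),
                n_dep_pass / len(dep) if len(dep) else np.nan,
            ),
            (
                "stability_control",
                "|AvSSMD*| <= 1 SD",
                n_stab_pass,
                len(stab),
                n_stab_pass / len(stab) if len(stab) else np.nan,
            ),
        ],
        columns=["control_class", "criterion", "n_pass", "n_scored", "fraction"],
    )
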