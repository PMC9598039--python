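"""Robust SSMD*-based effect scoring of a competitive-growth screen.

For each construct and replicate on the log2 scale:

    FGR = value(Day14 + Dox) - value(Day14)        foreground ratio
    BGR = value(Day0)        - value(Day14)        background ratio

The background distribution over every construct in both replicates gives
the screen's robust null: medianBGR and MAD = 1.4826 * median(|BGR -
medianBGR|). Each replicate's effect score is then the robust strictly
standardized mean difference

    SSMD* = (FGR - medianBGR) / (sqrt(2) * MAD)

(the sqrt(2) accounting for the variance of a difference of two measurements;
the alternative convention multiplying by sqrt(2), exactly 2x larger, is
available via ``convention="multiply"`` and yields identical hit sets since
the SD cutoff scales along). AvSSMD* averages the available replicate scores,
keeping a single replicate when the other is missing. If a replicate's
untreated Day14 sample was trimmed away, the fallback FGR = value(Day14Dox) -
value(Day0) is used and flagged, with BGR missing for that replicate.
Gene-level AvSSMD*/Protease is the unweighted mean over a gene's scored
constructs; controls carry no target gene and never aggregate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix
from .simulate import ROLE_TARGET, arm_label

logger = logging.getLogger("mirescreen.scoring")

MAD_CONSISTENCY = 1.4826  # Gaussian-consistency factor for the MAD
SQRT2 = math.sqrt(2.0)

CONVENTIONS = ("divide", "multiply")


@dataclass
class ScreenStats:
    """Screen-level background and variability statistics."""

    median_bgr: float
    mad: float
    n_constructs_scored: int
    sd_avssmd: float | None = None
    convention: str = "divide"
    controls_in_background: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("median_bgr", self.median_bgr),
                ("mad", self.mad),
                ("sd_avssmd", self.sd_avssmd if self.sd_avssmd is not None else np.nan),
                ("n_constructs_scored", self.n_constructs_scored),
                ("convention", self.convention),
                ("controls_in_background", self.controls_in_background),
            ],
            columns=["statistic", "value"],
        )


def compute_log_ratios(norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-construct, per-replicate FGR and BGR from masked log2 values.

    Returns one row per construct with columns ``fgr_<rep>``, ``bgr_<rep>``
    and ``fallback_<rep>``; missing observations propagate as NaN. A replicate
    without a usable Day14Dox value is unscored in that replicate.
    """
    sheet = norm.sheet
    reps = sorted(sheet["replicate"].unique())
    index = norm.values.index
    out = pd.DataFrame(index=index)
    for rep in reps:
        fgr = pd.Series(np.nan, index=index)
        bgr = pd.Series(np.nan, index=index)
        fallback = pd.Series(False, index=index)
        sub = sheet[sheet["replicate"] == rep]
        for pool, grp in sub.groupby("pool_id"):
            ids = {
                arm_label(r["timepoint"], r["dox"]): r["sample_id"] for _, r in grp.iterrows()
            }

            def masked(arm: str) -> pd.Series:
                if arm not in ids:
                    return pd.Series(np.nan, index=index)
                sid = ids[arm]
                return norm.values[sid].where(norm.mask[sid])

            v_dox = masked("Day14Dox")
            v_d14 = masked("Day14")
            v_d0 = masked("Day0")
            primary = v_dox.notna() & v_d14.notna()
            fgr[primary] = v_dox[primary] - v_d14[primary]
            bgr_ok = v_d0.notna() & v_d14.notna()
            bgr[bgr_ok] = v_d0[bgr_ok] - v_d14[bgr_ok]
            fb = v_dox.notna() & ~v_d14.notna() & v_d0.notna()
            fgr[fb] = v_dox[fb] - v_d0[fb]
            fallback[fb] = True
        out[f"fgr_{rep}"] = fgr
        out[f"bgr_{rep}"] = bgr
        out[f"fallback_{rep}"] = fallback
    out.index.name = "construct_id"
    return out


def background_stats(ratios: pd.DataFrame) -> tuple[float, float]:
    """Pooled robust background: median of all finite BGR values over every
    construct and both replicates, and the Gaussian-consistent MAD about it.
    """
    bgr_cols = [c for c in ratios.columns if c.startswith("bgr_")]
    pooled = ratios[bgr_cols].to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no finite background ratios: cannot estimate screen background")
    median_bgr = float(np.median(pooled))
    mad = MAD_CONSISTENCY * float(np.median(np.abs(pooled - median_bgr)))
    if mad == 0:
        raise ValueError(
            "degenerate background (MAD = 0): review trimming thresholds and "
            "sequencing depth before scoring"
        )
    return median_bgr, mad


def ssmd_star(
    fgr,
    median_bgr: float,
    mad: float,
    convention: str = "divide",
):
    """Robust SSMD* of a foreground ratio against the screen background.

    ``convention="divide"`` computes (FGR - medianBGR) / (sqrt(2) * MAD);
    ``"multiply"`` the literal left-to-right reading, exactly 2x larger.
    Strictly increasing in FGR and zero iff FGR equals the background median.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    if mad <= 0:
        raise ValueError("MAD must be > 0 for SSMD* computation")
    centered = (np.asarray(fgr, dtype=float) - median_bgr) / mad
    out = centered / SQRT2 if convention == "divide" else centered * SQRT2
    if np.ndim(fgr) == 0:
        return float(out)
    return out


def avssmd(ssmd_r1: float | None, ssmd_r2: float | None) -> tuple[float, int]:
    """Average the available replicate scores; a lone replicate is kept.

    Returns (AvSSMD*, replicates_used); both missing gives (nan, 0).
    """
    vals = [v for v in (ssmd_r1, ssmd_r2) if v is not None and np.isfinite(v)]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def score_constructs(
    norm: NormalizedMatrix,
    convention: str = "divide",
    controls_in_background: bool = True,
) -> tuple[pd.DataFrame, ScreenStats]:
    """Full per-construct scoring of one screen.

    Computes FGR/BGR per replicate, the pooled background statistics
    (optionally excluding spiked-in controls), per-replicate SSMD* and
    AvSSMD*. Rows with ``replicates_used == 0`` are present but unscored.
    """
    ratios = compute_log_ratios(norm)
    reps = sorted({c.split("_", 1)[1] for c in ratios.columns if c.startswith("fgr_")})
    if controls_in_background:
        bg_source = ratios
    else:
        roles = norm.library.set_index("construct_id")["role"]
        bg_source = ratios[ratios.index.map(roles) == ROLE_TARGET]
    median_bgr, mad = background_stats(bg_source)

    table = ratios.copy()
    for rep in reps:
        table[f"ssmd_{rep}"] = ssmd_star(
            table[f"fgr_{rep}"].to_numpy(), median_bgr, mad, convention
        )
    ssmd_cols = [f"ssmd_{rep}" for rep in reps]
    table["avssmd"] = table[ssmd_cols].mean(axis=1, skipna=True)
    table["replicates_used"] = table[ssmd_cols].notna().sum(axis=1)
    table["fallback_used"] = table[[f"fallback_{rep}" for rep in reps]].any(axis=1)
    n_scored = int((table["replicates_used"] >= 1).sum())
    stats = ScreenStats(
        median_bgr=median_bgr,
        mad=mad,
        n_constructs_scored=n_scored,
        convention=convention,
        controls_in_background=controls_in_background,
    )
    logger.info(
        "scored %d constructs (medianBGR=%.4f, MAD=%.4f, convention=%s)",
        n_scored,
        median_bgr,
        mad,
        convention,
    )
    return table, stats


def protease_aggregate(
    mire_scores: pd.DataFrame, library: pd.DataFrame
) -> pd.DataFrame:
    """Gene-level AvSSMD*/Protease: unweighted mean of the scored constructs
    per target gene. Genes without a scored construct are absent; controls
    (no target gene) never contribute."""
    genes = library.set_index("construct_id")["target_gene"]
    roles = library.set_index("construct_id")["role"]
    scored = mire_scores[
        (mire_scores["replicates_used"] >= 1)
        & (mire_scores.index.map(roles) == ROLE_TARGET)
    ]
    grouped = scored.groupby(scored.index.map(genes))["avssmd"]
    out = pd.DataFrame(
        {"avssmd_protease": grouped.mean(), "n_scored": grouped.size()}
    )
    out.index.name = "gene"
    return out
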