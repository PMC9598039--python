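"""Hit selection and cross-screen accounting.

Two sequential filters mirror the screen's selection procedure. The first is
purely statistical: the standard deviation of all constructs' AvSSMD* in a
screen (SD_AvSSMD*) defines the band of intrinsic variability, and a gene is
a hit when at least ``min_frequency`` (default 2) of its constructs score
strictly outside +/-1 SD in either direction. The second filter requires the
target mRNA to be expressed above a per-cell-line threshold in every
configured expression table; genes absent from a table fail. Cross-screen
accounting partitions the union of hits into Venn regions and classifies
each gene as depletion (negative gene score wherever it is a hit), mixed
(negative in some screens, positive in others) or enrichment-only, the last
being flagged and excluded from the final reported list.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("mirescreen.hits")


def sd_cutoff(mire_scores: pd.DataFrame) -> float:
    """Sample standard deviation (n-1 denominator) of all scored constructs'
    AvSSMD* values; the +/-1 SD band is the screen's outlier cutoff."""
    vals = mire_scores["avssmd"].dropna()
    if len(vals) < 2:
        raise ValueError("need at least 2 scored constructs for SD_AvSSMD*")
    sd = float(vals.std(ddof=1))
    if sd == 0:
        logger.warning("degenerate SD_AvSSMD* = 0 (all scores identical)")
    return sd


def call_hits(
    gene_scores: pd.DataFrame,
    mire_scores: pd.DataFrame,
    library: pd.DataFrame,
    sd: float,
    min_frequency: int = 2,
) -> pd.DataFrame:
    """First selection filter.

    ``frequency`` counts a gene's scored constructs with |AvSSMD*| strictly
    greater than the cutoff (either sign); a hit needs ``frequency >=
    min_frequency``. Direction comes from the sign of the gene-level score
    (negative = depletion, positive = enrichment; zero left undefined).
    """
    if sd <= 0:
        raise ValueError("sd must be > 0 to call hits")
    genes = library.set_index("construct_id")["target_gene"]
    scored = mire_scores[mire_scores["replicates_used"] >= 1]
    outlier = scored["avssmd"].abs() > sd
    freq = outlier.groupby(scored.index.map(genes)).sum()
    out = gene_scores.copy()
    out["frequency"] = freq.reindex(out.index).fillna(0).astype(int)
    out["hit"] = out["frequency"] >= min_frequency
    direction = np.where(
        out["avssmd_protease"] < 0,
        "depletion",
        np.where(out["avssmd_protease"] > 0, "enrichment", "undefined"),
    )
    out["direction"] = direction
    n_undef = int((out["direction"] == "undefined").sum())
    if n_undef:
        logger.warning("%d genes with AvSSMD*/Protease exactly 0: direction undefined", n_undef)
    return out


def expression_filter(
    hits: pd.DataFrame,
    expression: Mapping[str, tuple[pd.Series, float]],
) -> pd.DataFrame:
    """Second selection filter: retain a gene only if its expression is
    strictly above threshold in every configured cell-line table. Genes
    missing from any table are excluded (absence of evidence of expression).

    ``expression`` maps a cell-line name to (gene -> value series, threshold).
    """
    if not expression:
        raise ValueError("expression filtering requested but no expression tables configured")
    keep = pd.Series(True, index=hits.index)
    for name, (table, threshold) in expression.items():
        present = hits.index.isin(table.index)
        above = pd.Series(False, index=hits.index)
        idx = hits.index[present]
        above.loc[idx] = table.reindex(idx).to_numpy() > threshold
        dropped = hits.index[keep & ~above]
        if len(dropped):
            logger.info(
                "expression filter (%s > %g): excluding %d genes (%d absent from table)",
                name,
                threshold,
                len(dropped),
                int((~present).sum()),
            )
        keep &= above
    return hits[keep]


@dataclass
class CrossScreenSummary:
    """Union, Venn partition and direction classes of hits across screens."""

    screens: list[str]
    hit_sets: dict[str, set[str]]
    union: set[str]
    #: exclusive Venn regions: frozenset of screens -> genes hit in exactly those
    regions: dict[frozenset, set] = field(default_factory=dict)
    #: per union gene: class in {depletion, mixed, enrichment}; enrichment-only
    #: genes are excluded from the reported list
    classes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def region_size(self, *screens: str) -> int:
        return len(self.regions.get(frozenset(screens), set()))

    def intersection(self, *screens: str) -> set[str]:
        sets = [self.hit_sets[s] for s in screens]
        return set.intersection(*sets) if sets else set()

    def regions_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.regions, key=lambda k: (len(k), sorted(k))):
            rows.append(("+".join(sorted(key)), len(self.regions[key])))
        rows.append(("union", len(self.union)))
        return pd.DataFrame(rows, columns=["region", "n_genes"])


def cross_screen(hits_by_screen: Mapping[str, pd.DataFrame]) -> CrossScreenSummary:
    """Partition hits across screens and classify their direction.

    A gene is *depletion* when its gene score is negative in every screen
    where it is a hit, *mixed* when hit with negative score in at least one
    screen and positive in another, *enrichment* when positive wherever hit.
    The reported list excludes enrichment-only genes.
    """
    if not hits_by_screen:
        raise ValueError("cross_screen needs at least one screen")
    screens = list(hits_by_screen)
    hit_sets = {
        s: set(df.index[df["hit"]]) for s, df in hits_by_screen.items()
    }
    union = set().union(*hit_sets.values())
    regions: dict[frozenset, set] = {}
    for r in range(1, len(screens) + 1):
        for combo in itertools.combinations(screens, r):
            inside = set.intersection(*(hit_sets[s] for s in combo))
            outside = set().union(*(hit_sets[s] for s in screens if s not in combo), set())
            regions[frozenset(combo)] = inside - outside
    rows = []
    for gene in sorted(union):
        signs = [
            np.sign(hits_by_screen[s].loc[gene, "avssmd_protease"])
            for s in screens
            if gene in hit_sets[s]
        ]
        if all(v < 0 for v in signs):
            cls = "depletion"
        elif any(v < 0 for v in signs) and any(v > 0 for v in signs):
            cls = "mixed"
        else:
            cls = "enrichment"
        rows.append((gene, cls, cls != "enrichment"))
    classes = pd.DataFrame(rows, columns=["gene", "class", "reported"]).set_index("gene")
    n_excl = int((~classes["reported"]).sum()) if len(classes) else 0
    if n_excl:
        logger.info("excluding %d enrichment-only genes from the reported list", n_excl)
    return CrossScreenSummary(
        screens=screens, hit_sets=hit_sets, union=union, regions=regions, classes=classes
    )


def dual_flashlight_table(hit_table: pd.DataFrame) -> pd.DataFrame:
    """One row per gene with its AvSSMD*/Protease, outlier frequency and hit
    flag — the tabular form of a dual-flashlight plot. Sorted by score then
    gene name for deterministic output."""
    cols = ["avssmd_protease", "n_scored", "frequency", "hit", "direction"]
    out = hit_table[cols].copy()
    return out.sort_values(["avssmd_protease", out.index.name or "gene"], kind="stable")


def heatmap_table(
    summary: CrossScreenSummary,
    hits_by_screen: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-screen score grid of the reported (non-enrichment) cross-screen
    genes. Cells of screens where a gene is not a hit are marked "ns"; rows
    are ordered by the minimum score across screens, then name."""
    genes = [g for g in summary.classes.index if summary.classes.loc[g, "reported"]]
    records = []
    for gene in genes:
        row: dict[str, object] = {"gene": gene, "class": summary.classes.loc[gene, "class"]}
        scores = []
        for s in summary.screens:
            df = hits_by_screen[s]
            if gene in summary.hit_sets[s]:
                val = float(df.loc[gene, "avssmd_protease"])
                row[f"{s}_score"] = val
                row[f"{s}_status"] = "hit"
                row[f"{s}_frequency"] = int(df.loc[gene, "frequency"])
                scores.append(val)
            else:
                row[f"{s}_score"] = np.nan
                row[f"{s}_status"] = "ns"
                row[f"{s}_frequency"] = (
                    int(df.loc[gene, "frequency"]) if gene in df.index else 0
                )
        row["_order"] = min(scores) if scores else np.inf
        records.append(row)
    if not records:
        return pd.DataFrame(columns=["gene", "class"]).set_index("gene")
    out = pd.DataFrame(records).sort_values(["_order", "gene"], kind="stable")
    return out.drop(columns="_order").set_index("gene")
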