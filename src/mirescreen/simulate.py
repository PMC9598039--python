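"""Synthetic pooled miR-E dropout screens.

Generates construct libraries, sample sheets, ground-truth fitness effects,
count matrices and raw reads with the statistical structure of a pooled
competitive-growth RNAi screen: a degradome-scale library (hundreds of target
genes, 4-7 hairpins each) split into pools of roughly 300 constructs, four
spiked-in controls per pool (two neutral stability controls targeting
luciferases, two depletion controls targeting the essential gene Rpa3), two
biological replicates from independent transductions, and three arms per
screen (Day0, Day14 untreated, Day14 + doxycycline).

The growth model is exponential in log2 units over the screen window: a clone
carrying construct *i* with fitness effect ``e_i`` (total log2 fold-change
under full knockdown) has Day14 abundance ``a_i * 2**(e_i * k)`` where ``k``
is 1 with doxycycline, the promoter leakiness ``lambda`` without, and 0 at
Day0. Sequencing is multinomial at the configured depth per sample.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("mirescreen.simulate")

NUCLEOTIDES = np.array(list("ACGT"))

LIBRARY_COLUMNS = ["construct_id", "guide_seq", "target_gene", "pool_id", "role"]
SHEET_COLUMNS = [
    "sample_id",
    "screen_id",
    "pool_id",
    "replicate",
    "timepoint",
    "dox",
    "barcode",
]

ROLE_TARGET = "target"
ROLE_STABILITY = "stability_control"
ROLE_DEPLETION = "depletion_control"

#: control constructs spiked into every pool, (name, role)
CONTROL_TEMPLATE = [
    ("shRenilla", ROLE_STABILITY),
    ("shLuciferase", ROLE_STABILITY),
    ("shRpa3-218", ROLE_DEPLETION),
    ("shRpa3-457", ROLE_DEPLETION),
]


@dataclass
class ReadLayout:
    """Structure of a screen amplicon read.

    Default layout: inline sample barcode, the constant 5' miR-E flank, the
    22-nt guide, then the loop flank. All matching downstream is fixed-offset
    (substitutions only), so the layout fully determines where the guide sits.
    """

    barcode_len: int = 10
    guide_len: int = 22
    flank5: str = "TGCTGTTGACAGTGAGCG"
    flank3: str = "TAGTGAAGCCACAGATGTA"
    quality_char: str = "I"

    @property
    def guide_offset(self) -> int:
        return self.barcode_len + len(self.flank5)

    @property
    def read_len(self) -> int:
        return self.guide_offset + self.guide_len + len(self.flank3)


@dataclass
class SimConfig:
    """Parameters of a simulated screen.

    ``representation`` is the average number of independently transduced cells
    per construct at Day0 (the screen was run at 1,000x). ``depth`` is reads
    per sequencing sample. ``baseline_dispersion`` is the log-normal sigma of
    Day0 clone abundances. ``leakiness`` is the fraction of the knockdown
    effect expressed without doxycycline. ``effect_map`` holds per-construct
    log2 fitness effects over the screen window; constructs absent from it are
    neutral. Depletion controls always receive ``depletion_control_effect``.
    """

    n_genes: int = 658
    guides_per_gene: tuple[int, int] = (4, 7)
    n_pools: int = 16
    representation: float = 1000.0
    depth: int = 1_000_000
    baseline_dispersion: float = 0.5
    leakiness: float = 0.0
    growth_days: float = 14.0
    guide_len: int = 22
    barcode_len: int = 10
    effect_map: Mapping[str, float] | None = None
    depletion_control_effect: float = -6.0
    overdispersion: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.guides_per_gene
        if not (1 <= lo <= hi <= 20):
            raise ValueError("guides_per_gene range must lie within [1, 20]")
        if self.n_pools < 1:
            raise ValueError("n_pools must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.representation <= 0:
            raise ValueError("representation must be > 0")
        if not 0.0 <= self.leakiness <= 1.0:
            raise ValueError("leakiness must lie in [0, 1]")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion concentration must be > 0")


@dataclass
class CountMatrix:
    """Raw read counts (NOR) per construct x sample.

    ``counts`` is a wide frame indexed by construct_id with one column per
    sample_id. Cells are defined (non-NaN) exactly where the construct belongs
    to the sample's pool; zeros are legitimate observations.
    """

    counts: pd.DataFrame
    library: pd.DataFrame
    sheet: pd.DataFrame

    def validate(self) -> None:
        if not self.counts.index.equals(pd.Index(self.library["construct_id"])):
            raise ValueError("count matrix rows must match the library constructs")
        pool_of_sample = self.sheet.set_index("sample_id")["pool_id"]
        pools = self.library.set_index("construct_id")["pool_id"]
        for sample in self.counts.columns:
            col = self.counts[sample]
            in_pool = pools == pool_of_sample[sample]
            defined = col.notna()
            if not defined.equals(in_pool):
                raise ValueError(
                    f"sample {sample}: counts must be defined exactly for its pool"
                )
            vals = col[defined]
            if (vals < 0).any() or (vals != np.floor(vals)).any():
                raise ValueError(f"sample {sample}: counts must be nonnegative integers")


@dataclass
class SimTruth:
    """Planted ground truth of a simulated screen."""

    effects: pd.Series  # construct_id -> log2 effect under full induction
    gene_labels: pd.DataFrame  # gene, label in {depletion, enrichment, neutral}
    abundances: pd.DataFrame  # latent expected clone abundance per sample


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """Draw n distinct k-mers uniformly without replacement."""
    if n > 4**k:
        raise ValueError(f"cannot draw {n} distinct {k}-mers: only 4^{k} exist")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(max(n - len(out), 16), k))
        for row in block:
            s = "".join(NUCLEOTIDES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_library(config: SimConfig) -> pd.DataFrame:
    """Build a construct library per the pooled-screen design.

    Genes get a uniform number of guides in ``guides_per_gene`` and are
    assigned greedily to the least-filled pool (largest genes first), so pool
    sizes differ by at most the maximum guide count. Every pool additionally
    carries the four controls. Deterministic for a given config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.guides_per_gene
    n_guides = rng.integers(lo, hi + 1, size=config.n_genes)
    n_constructs = int(n_guides.sum()) + 4 * config.n_pools
    if n_constructs > 4**config.guide_len:
        raise ValueError(
            f"infeasible config: {n_constructs} unique guides requested but only "
            f"4^{config.guide_len} exist"
        )
    genes = [f"Prot{i + 1:04d}" for i in range(config.n_genes)]

    # largest-first greedy balancing keeps pool sizes within max(guides) of each other
    order = sorted(range(config.n_genes), key=lambda i: (-n_guides[i], i))
    pool_sizes = np.zeros(config.n_pools, dtype=int)
    gene_pool = np.empty(config.n_genes, dtype=int)
    for i in order:
        p = int(np.argmin(pool_sizes))
        gene_pool[i] = p
        pool_sizes[p] += n_guides[i]

    guides = _random_kmers(rng, n_constructs, config.guide_len)
    rows = []
    g = 0
    for i, gene in enumerate(genes):
        for j in range(n_guides[i]):
            rows.append((f"{gene}.{j + 1}", guides[g], gene, int(gene_pool[i]), ROLE_TARGET))
            g += 1
    for pool in range(config.n_pools):
        for name, role in CONTROL_TEMPLATE:
            rows.append((f"{name}.p{pool:02d}", guides[g], "", pool, role))
            g += 1
    library = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
    library = library.sort_values(["pool_id", "construct_id"], kind="stable")
    library = library.reset_index(drop=True)
    validate_library(library)
    return library


def validate_library(library: pd.DataFrame) -> None:
    missing = [c for c in LIBRARY_COLUMNS if c not in library.columns]
    if missing:
        raise ValueError(f"library table missing columns: {missing}")
    if library["construct_id"].duplicated().any():
        raise ValueError("construct_id values must be unique")
    if library["guide_seq"].duplicated().any():
        raise ValueError("guide sequences must be unique")
    bad_roles = set(library["role"]) - {ROLE_TARGET, ROLE_STABILITY, ROLE_DEPLETION}
    if bad_roles:
        raise ValueError(f"unknown construct roles: {sorted(bad_roles)}")
    targets = library[library["role"] == ROLE_TARGET]
    pools_per_gene = targets.groupby("target_gene")["pool_id"].nunique()
    if (pools_per_gene > 1).any():
        raise ValueError("all constructs of a gene must sit in the same pool")


def validate_sheet(sheet: pd.DataFrame) -> None:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample_id values must be unique")
    key = sheet[["screen_id", "pool_id", "replicate", "timepoint", "dox"]]
    if key.duplicated().any():
        raise ValueError("(screen, pool, replicate, timepoint, dox) must be unique")
    day0 = sheet[sheet["timepoint"] == "Day0"]
    if day0["dox"].any():
        raise ValueError("Day0 samples cannot be doxycycline treated")


def arm_label(timepoint: str, dox: bool) -> str:
    if timepoint == "Day0":
        return "Day0"
    return "Day14Dox" if dox else "Day14"


def build_sample_sheet(
    config: SimConfig,
    screen_id: str = "screen1",
    replicates: tuple[str, ...] = ("R1", "R2"),
) -> pd.DataFrame:
    """Sample sheet for one screen: every pool x replicate x arm, with random
    sample barcodes at pairwise Hamming distance >= 3 (safe for 1-mismatch
    demultiplexing)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    arms = [("Day0", False), ("Day14", False), ("Day14", True)]
    n_samples = config.n_pools * len(replicates) * len(arms)
    barcodes: list[str] = []
    while len(barcodes) < n_samples:
        cand = "".join(NUCLEOTIDES[rng.integers(0, 4, size=config.barcode_len)])
        if all(_hamming(cand, b) >= 3 for b in barcodes):
            barcodes.append(cand)
    rows = []
    i = 0
    for pool in range(config.n_pools):
        for rep in replicates:
            for timepoint, dox in arms:
                label = arm_label(timepoint, dox)
                rows.append(
                    (
                        f"{screen_id}_p{pool:02d}_{rep}_{label}",
                        screen_id,
                        pool,
                        rep,
                        timepoint,
                        dox,
                        barcodes[i],
                    )
                )
                i += 1
    sheet = pd.DataFrame(rows, columns=SHEET_COLUMNS)
    validate_sheet(sheet)
    return sheet


def plant_effects(
    library: pd.DataFrame,
    frac_depleted: float = 0.1,
    effect: float = -4.0,
    frac_enriched: float = 0.0,
    enrich_effect: float = 2.0,
    seed: int = 0,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Assign fitness effects to a random subset of target genes.

    All constructs of a planted gene share the gene's effect (a shared biology
    across hairpins); remaining genes are neutral. Returns the per-construct
    effect map and the per-gene truth labels.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(set(library.loc[library["role"] == ROLE_TARGET, "target_gene"]))
    n_dep = int(round(frac_depleted * len(genes)))
    n_enr = int(round(frac_enriched * len(genes)))
    chosen = rng.permutation(len(genes))[: n_dep + n_enr]
    depleted = {genes[i] for i in chosen[:n_dep]}
    enriched = {genes[i] for i in chosen[n_dep:]}
    effect_map: dict[str, float] = {}
    for _, row in library.iterrows():
        if row["target_gene"] in depleted:
            effect_map[row["construct_id"]] = effect
        elif row["target_gene"] in enriched:
            effect_map[row["construct_id"]] = enrich_effect
    labels = pd.DataFrame(
        {
            "gene": genes,
            "label": [
                "depletion" if g in depleted else "enrichment" if g in enriched else "neutral"
                for g in genes
            ],
        }
    )
    return effect_map, labels


def _effects_series(library: pd.DataFrame, config: SimConfig) -> pd.Series:
    effects = pd.Series(0.0, index=pd.Index(library["construct_id"], name="construct_id"))
    effects[library.set_index("construct_id")["role"] == ROLE_DEPLETION] = (
        config.depletion_control_effect
    )
    if config.effect_map:
        unknown = set(config.effect_map) - set(effects.index)
        if unknown:
            raise ValueError(f"effect_map names unknown constructs: {sorted(unknown)[:5]}")
        for cid, e in config.effect_map.items():
            effects[cid] = e
    return effects


def simulate_counts(
    library: pd.DataFrame,
    sheet: pd.DataFrame,
    config: SimConfig,
) -> tuple[CountMatrix, SimTruth]:
    """Simulate the screen readout.

    Per replicate, Day0 clone abundances are drawn independently as
    ``representation * LogNormal(0, baseline_dispersion)`` (independent
    transductions); Day14 abundances follow the exponential growth law; each
    sample is a multinomial draw of ``depth`` reads over its pool's relative
    abundances (optionally Dirichlet-overdispersed).
    """
    config.validate()
    validate_library(library)
    validate_sheet(sheet)
    lib_pools = set(library["pool_id"])
    if not lib_pools <= set(sheet["pool_id"]):
        raise ValueError("sample sheet does not cover all library pools")
    rng = np.random.default_rng(config.seed + 2)
    effects = _effects_series(library, config)
    cid_index = pd.Index(library["construct_id"], name="construct_id")
    pools = library.set_index("construct_id")["pool_id"]

    # baselines first, in a fixed order, so they do not depend on the effect map
    replicates = sorted(sheet["replicate"].unique())
    baseline = pd.DataFrame(
        {
            rep: config.representation
            * rng.lognormal(0.0, config.baseline_dispersion, size=len(cid_index))
            for rep in replicates
        },
        index=cid_index,
    )

    counts = pd.DataFrame(np.nan, index=cid_index, columns=sheet["sample_id"])
    abundances = pd.DataFrame(np.nan, index=cid_index, columns=sheet["sample_id"])
    for _, s in sheet.iterrows():
        mask = pools == s["pool_id"]
        a = baseline.loc[mask, s["replicate"]].to_numpy()
        if s["timepoint"] == "Day0":
            k = 0.0
        else:
            k = 1.0 if s["dox"] else config.leakiness
        ab = a * np.power(2.0, effects[mask].to_numpy() * k)
        p = ab / ab.sum()
        if config.overdispersion is not None:
            p = rng.dirichlet(p * config.overdispersion)
        draw = rng.multinomial(config.depth, p)
        counts.loc[mask, s["sample_id"]] = draw
        abundances.loc[mask, s["sample_id"]] = ab

    genes = sorted(set(library.loc[library["role"] == ROLE_TARGET, "target_gene"]))
    gene_effects = effects[library.set_index("construct_id")["role"] == ROLE_TARGET]
    gene_of = library.set_index("construct_id")["target_gene"]
    labels = []
    for g in genes:
        e = gene_effects[gene_of[gene_effects.index] == g]
        nonzero = e[e != 0]
        if nonzero.empty:
            labels.append("neutral")
        elif (nonzero < 0).all():
            labels.append("depletion")
        elif (nonzero > 0).all():
            labels.append("enrichment")
        else:
            labels.append("mixed")
    truth = SimTruth(
        effects=effects,
        gene_labels=pd.DataFrame({"gene": genes, "label": labels}),
        abundances=abundances,
    )
    matrix = CountMatrix(counts=counts, library=library, sheet=sheet)
    return matrix, truth


def write_fastq(
    matrix: CountMatrix,
    path,
    layout: ReadLayout | None = None,
) -> int:
    """Emit exactly the recorded reads: for construct *i* in sample *s*,
    ``counts[i, s]`` identical records ``barcode + flank5 + guide + flank3``
    at constant quality. Returns the number of records written.

    Demultiplexing the output at zero mismatches recovers the matrix exactly.
    """
    layout = layout or ReadLayout()
    sheet = matrix.sheet
    if sheet["barcode"].duplicated().any():
        raise ValueError("duplicate sample barcodes within one FASTQ output")
    lib = matrix.library.set_index("construct_id")
    n = 0
    with open(path, "w") as fh:
        for _, s in sheet.iterrows():
            col = matrix.counts[s["sample_id"]]
            col = col[col.notna() & (col > 0)]
            for cid, c in col.items():
                seq = s["barcode"] + layout.flank5 + lib.loc[cid, "guide_seq"] + layout.flank3
                qual = layout.quality_char * len(seq)
                block = f"@{s['sample_id']}:{cid}\n{seq}\n+\n{qual}\n" * int(c)
                fh.write(block)
                n += int(c)
    return n


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["guides_per_gene"] = list(config.guides_per_gene)
    if config.effect_map is not None:
        d["effect_map"] = dict(config.effect_map)
    return d
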