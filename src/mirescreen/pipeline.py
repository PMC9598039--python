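"""End-to-end orchestration: one config file drives simulate (or load) ->
normalize -> trim -> score -> call-hits -> cross-screen, with a JSON run
manifest recording every effective parameter and per-stage row counts.

Every ambiguity of the scoring procedure is a named config key (sqrt(2)
convention, control inclusion in the background, trimming thresholds,
strictness of the outlier inequality is always strict). Reruns with the same
config and seed are byte-identical. Logging goes to standard error; machine
outputs only ever go to files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .hits import (
    call_hits,
    cross_screen,
    dual_flashlight_table,
    expression_filter,
    heatmap_table,
    sd_cutoff,
)
from .normalize import normalize_pool, qc_controls, qc_correlations, trim_extremes
from .quantify import demux_and_count, read_counts, write_counts
from .scoring import protease_aggregate, score_constructs
from .simulate import (
    CountMatrix,
    SimConfig,
    build_library,
    build_sample_sheet,
    plant_effects,
    simulate_counts,
    write_fastq,
)

logger = logging.getLogger("mirescreen.pipeline")

FLOAT_FMT = "%.10g"

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_genes": 300,
        "guides_per_gene": [5, 5],
        "n_pools": 5,
        "representation": 1000,
        "depth": 3_000_000,
        "baseline_dispersion": 0.5,
        "depletion_control_effect": -6.0,
        "fastq_roundtrip": False,
        "screens": [
            {
                "screen_id": "screen1",
                "leakiness": 0.0,
                "frac_depleted": 0.1,
                "effect": -4.0,
                "frac_enriched": 0.0,
                "enrich_effect": 2.0,
            }
        ],
    },
    "normalization": {"pseudocount": 1.0, "scale": 1_000_000.0},
    "trimming": {"min_day0_count": 30, "ratio_cap": 8.0},
    "scoring": {"convention": "divide", "controls_in_background": True},
    "hits": {"min_frequency": 2},
    "expression": {"enabled": False, "tables": {}},
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Read a YAML config and fill in every default, so the manifest shows
    the complete effective parameter set."""
    user: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _merge(default: Mapping[str, Any], user: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, val in default.items():
        if key in user and isinstance(val, Mapping) and isinstance(user[key], Mapping):
            out[key] = _merge(val, user[key])
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = json.loads(json.dumps(val))  # deep copy of plain data
    for key in user:
        if key not in default:
            out[key] = user[key]
    return out


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def _load_expression(cfg: Mapping[str, Any], base: Path) -> dict[str, tuple[pd.Series, float]]:
    tables: dict[str, tuple[pd.Series, float]] = {}
    for name, spec in cfg.get("tables", {}).items():
        if "path" not in spec or "threshold" not in spec:
            raise ValueError(f"expression table {name!r} needs both 'path' and 'threshold'")
        path = Path(spec["path"])
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise FileNotFoundError(f"expression table {name!r} missing: {path}")
        df = pd.read_csv(path, sep="\t")
        series = df.set_index(df.columns[0])[df.columns[1]]
        tables[name] = (series, float(spec["threshold"]))
    return tables


def run_pipeline(
    config: Mapping[str, Any] | str | Path | None,
    outdir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run every stage, write all outputs under ``outdir`` and return the
    manifest (also written as manifest.json)."""
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
        base = Path(config).parent if config is not None else Path(".")
    else:
        cfg = _merge(DEFAULT_CONFIG, config)
        base = Path(".")
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expr_cfg = cfg["expression"]
    expression = None
    if expr_cfg.get("enabled"):
        expression = _load_expression(expr_cfg, base)
        if not expression:
            raise ValueError(
                "expression filter enabled but no expression tables configured"
            )

    manifest: dict[str, Any] = {
        "package": "mirescreen",
        "version": __version__,
        "seed": cfg["seed"],
        "parameters": cfg,
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, rows: int, **extra: Any) -> None:
        manifest["stages"].append({"stage": stage, "rows": int(rows), **extra})
        logger.info("[%s] %d rows %s", stage, rows, extra if extra else "")

    # ---- stage 1: obtain counts per screen -------------------------------
    screens: dict[str, CountMatrix] = {}
    sim = cfg.get("simulate")
    if sim:
        sim_common = {
            k: sim[k]
            for k in (
                "n_genes",
                "guides_per_gene",
                "n_pools",
                "representation",
                "depth",
                "baseline_dispersion",
                "depletion_control_effect",
            )
        }
        sim_common["guides_per_gene"] = tuple(sim_common["guides_per_gene"])
        lib_config = SimConfig(seed=cfg["seed"], **sim_common)
        library = build_library(lib_config)
        _write(library, outdir / "library.tsv", index=False)
        manifest["outputs"]["library"] = "library.tsv"
        record("build_library", len(library))
        sheets = []
        for i, scr in enumerate(sim["screens"]):
            sid = scr["screen_id"]
            scr_seed = cfg["seed"] + 101 * (i + 1)
            effect_map, labels = plant_effects(
                library,
                frac_depleted=scr.get("frac_depleted", 0.0),
                effect=scr.get("effect", -4.0),
                frac_enriched=scr.get("frac_enriched", 0.0),
                enrich_effect=scr.get("enrich_effect", 2.0),
                seed=scr_seed,
            )
            scr_config = SimConfig(
                seed=scr_seed,
                leakiness=scr.get("leakiness", 0.0),
                effect_map=effect_map,
                **sim_common,
            )
            sheet = build_sample_sheet(scr_config, screen_id=sid)
            matrix, truth = simulate_counts(library, sheet, scr_config)
            screens[sid] = matrix
            sheets.append(sheet)
            _write(truth.gene_labels, outdir / f"truth_{sid}.tsv", index=False)
            write_counts(matrix, outdir / f"counts_{sid}.tsv")
            manifest["outputs"][f"counts_{sid}"] = f"counts_{sid}.tsv"
            record("simulate_counts", matrix.counts.shape[0], screen=sid)
            if sim.get("fastq_roundtrip"):
                fq = outdir / f"reads_{sid}.fastq"
                write_fastq(matrix, fq)
                matrix2, stats = demux_and_count(fq, library, sheet, 0, 0)
                if not matrix2.counts.equals(matrix.counts):
                    raise RuntimeError(f"FASTQ round trip mismatch in screen {sid}")
                stats.to_frame().to_csv(
                    outdir / f"demux_stats_{sid}.tsv", sep="\t", index=False
                )
                record("fastq_roundtrip", stats.total, screen=sid)
        _write(pd.concat(sheets, ignore_index=True), outdir / "samples.tsv", index=False)
        manifest["outputs"]["samples"] = "samples.tsv"
    else:
        inputs = cfg.get("inputs")
        if not inputs:
            raise ValueError("config must provide either 'simulate' or 'inputs'")
        for key in ("library", "samples", "counts"):
            if key not in inputs:
                raise ValueError(f"inputs section is missing {key!r}")
        library = pd.read_csv(Path(inputs["library"]), sep="\t")
        all_sheets = pd.read_csv(Path(inputs["samples"]), sep="\t")
        for sid, cpath in inputs["counts"].items():
            sheet = all_sheets[all_sheets["screen_id"] == sid].reset_index(drop=True)
            screens[sid] = read_counts(Path(cpath), library=library, sheet=sheet)
            record("load_counts", screens[sid].counts.shape[0], screen=sid)

    # ---- stages 2-5 per screen ------------------------------------------
    norm_cfg, trim_cfg = cfg["normalization"], cfg["trimming"]
    score_cfg, hit_cfg = cfg["scoring"], cfg["hits"]
    hits_by_screen: dict[str, pd.DataFrame] = {}
    qc_frames = []
    for sid, matrix in screens.items():
        norm = normalize_pool(
            matrix, pseudocount=norm_cfg["pseudocount"], scale=norm_cfg["scale"]
        )
        norm = trim_extremes(
            norm,
            matrix,
            min_day0_count=trim_cfg["min_day0_count"],
            ratio_cap=float(trim_cfg["ratio_cap"]),
        )
        _write(norm.values, outdir / f"normalized_{sid}.tsv")
        _write(norm.mask, outdir / f"mask_{sid}.tsv")
        record("normalize_trim", int(norm.mask.to_numpy().sum()), screen=sid)

        qc_frames.append(qc_correlations(norm))

        mire, stats = score_constructs(
            norm,
            convention=score_cfg["convention"],
            controls_in_background=score_cfg["controls_in_background"],
        )
        stats.sd_avssmd = sd_cutoff(mire)
        _write(mire, outdir / f"mire_scores_{sid}.tsv")
        stats.to_frame().to_csv(outdir / f"screen_stats_{sid}.tsv", sep="\t", index=False)
        record("score", stats.n_constructs_scored, screen=sid)

        qc_ctrl = qc_controls(mire, matrix.library, stats.sd_avssmd)
        qc_ctrl.insert(0, "screen_id", sid)
        qc_ctrl.to_csv(outdir / f"qc_controls_{sid}.tsv", sep="\t", index=False)

        gene_scores = protease_aggregate(mire, matrix.library)
        hit_table = call_hits(
            gene_scores,
            mire,
            matrix.library,
            sd=stats.sd_avssmd,
            min_frequency=hit_cfg["min_frequency"],
        )
        _write(dual_flashlight_table(hit_table), outdir / f"dual_flashlight_{sid}.tsv")
        _write(hit_table, outdir / f"hits_{sid}.tsv")
        manifest["outputs"][f"hits_{sid}"] = f"hits_{sid}.tsv"
        record("call_hits", int(hit_table["hit"].sum()), screen=sid)
        hits_by_screen[sid] = hit_table

    qc = pd.concat(qc_frames, ignore_index=True)
    qc.to_csv(outdir / "qc_correlations.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    manifest["outputs"]["qc_correlations"] = "qc_correlations.tsv"

    # ---- stage 6: cross-screen accounting --------------------------------
    summary = cross_screen(hits_by_screen)
    summary.regions_frame().to_csv(outdir / "venn_regions.tsv", sep="\t", index=False)
    _write(summary.classes, outdir / "cross_screen_classes.tsv")
    record("cross_screen", len(summary.union))

    filtered_by_screen = hits_by_screen
    if expression is not None:
        filtered_by_screen = {}
        for sid, table in hits_by_screen.items():
            passing = expression_filter(table[table["hit"]], expression)
            filtered_by_screen[sid] = table.assign(
                hit=table.index.isin(passing.index)
            )
            _write(filtered_by_screen[sid], outdir / f"hits_filtered_{sid}.tsv")
            record("expression_filter", int(filtered_by_screen[sid]["hit"].sum()), screen=sid)
        summary_f = cross_screen(filtered_by_screen)
        heat = heatmap_table(summary_f, filtered_by_screen)
    else:
        heat = heatmap_table(summary, hits_by_screen)
    _write(heat, outdir / "heatmap.tsv")
    manifest["outputs"]["heatmap"] = "heatmap.tsv"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def report(run_dir: str | Path) -> pd.DataFrame:
    """Summarize a completed run: per screen, genes with at least one scored
    construct, first-filter hits, expression-filtered hits (when computed),
    plus union and all-screen intersection sizes."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}: incomplete run")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    rows = []
    screen_ids = sorted(
        p.name[len("hits_") : -len(".tsv")]
        for p in run_dir.glob("hits_*.tsv")
        if not p.name.startswith("hits_filtered_")
    )
    for sid in screen_ids:
        hits = pd.read_csv(run_dir / f"hits_{sid}.tsv", sep="\t", index_col="gene")
        row = {
            "screen_id": sid,
            "genes_scored": len(hits),
            "first_filter_hits": int(hits["hit"].sum()),
        }
        filt = run_dir / f"hits_filtered_{sid}.tsv"
        if filt.exists():
            fhits = pd.read_csv(filt, sep="\t", index_col="gene")
            row["second_filter_hits"] = int(fhits["hit"].sum())
        rows.append(row)
    summary = pd.DataFrame(rows)
    regions = pd.read_csv(run_dir / "venn_regions.tsv", sep="\t")
    union = int(regions.loc[regions["region"] == "union", "n_genes"].iloc[0])
    triple = regions[regions["region"].str.count("\\+") == len(screen_ids) - 1]
    summary.attrs["union_hits"] = union
    summary.attrs["all_screen_intersection"] = (
        int(triple["n_genes"].iloc[0]) if len(screen_ids) > 1 and len(triple) else union
    )
    logger.info("report: union=%d", union)
    return summary
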