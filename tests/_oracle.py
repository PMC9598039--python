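"""Independent brute-force reimplementation of the scoring procedure.

Used as the oracle against the vectorized pipeline: plain Python loops and
the statistics module only, no shared code paths with the package beyond the
input containers.
"""

import math
import statistics


def naive_scores(norm, convention="divide", controls_in_background=True):
    """Score a NormalizedMatrix by direct per-construct loops.

    Returns (per_construct: dict, stats: dict, per_gene: dict). Scores follow
    FGR = Dox - Day14, BGR = Day0 - Day14 (fallback FGR = Dox - Day0 when
    Day14 is missing), medianBGR/MAD pooled over all constructs and both
    replicates, SSMD* = (FGR - medianBGR) / (sqrt(2) * MAD) (or * sqrt(2)),
    AvSSMD* the mean of the available replicates, gene scores the unweighted
    mean of scored constructs.
    """
    sheet = norm.sheet
    lib = norm.library.set_index("construct_id")
    reps = sorted(set(sheet["replicate"]))

    sample_of = {}
    for _, row in sheet.iterrows():
        arm = "Day0" if row["timepoint"] == "Day0" else ("Day14Dox" if row["dox"] else "Day14")
        sample_of[(row["pool_id"], row["replicate"], arm)] = row["sample_id"]

    def value(cid, pool, rep, arm):
        sid = sample_of.get((pool, rep, arm))
        if sid is None:
            return None
        if not bool(norm.mask.loc[cid, sid]):
            return None
        v = float(norm.values.loc[cid, sid])
        return v if math.isfinite(v) else None

    per_construct = {}
    all_bgr = []
    for cid in norm.values.index:
        pool = lib.loc[cid, "pool_id"]
        rec = {}
        for rep in reps:
            v_dox = value(cid, pool, rep, "Day14Dox")
            v_d14 = value(cid, pool, rep, "Day14")
            v_d0 = value(cid, pool, rep, "Day0")
            fgr = bgr = None
            fallback = False
            if v_dox is not None and v_d14 is not None:
                fgr = v_dox - v_d14
            elif v_dox is not None and v_d0 is not None:
                fgr = v_dox - v_d0
                fallback = True
            if v_d0 is not None and v_d14 is not None:
                bgr = v_d0 - v_d14
            rec[f"fgr_{rep}"] = fgr
            rec[f"bgr_{rep}"] = bgr
            rec[f"fallback_{rep}"] = fallback
            if bgr is not None and (
                controls_in_background or lib.loc[cid, "role"] == "target"
            ):
                all_bgr.append(bgr)
        per_construct[cid] = rec

    median_bgr = statistics.median(all_bgr)
    mad = 1.4826 * statistics.median(abs(b - median_bgr) for b in all_bgr)
    for cid, rec in per_construct.items():
        ssmds = []
        for rep in reps:
            fgr = rec[f"fgr_{rep}"]
            if fgr is None:
                rec[f"ssmd_{rep}"] = None
                continue
            s = (fgr - median_bgr) / mad
            s = s / math.sqrt(2) if convention == "divide" else s * math.sqrt(2)
            rec[f"ssmd_{rep}"] = s
            ssmds.append(s)
        rec["avssmd"] = sum(ssmds) / len(ssmds) if ssmds else None
        rec["replicates_used"] = len(ssmds)

    per_gene = {}
    for cid, rec in per_construct.items():
        gene = lib.loc[cid, "target_gene"]
        if lib.loc[cid, "role"] != "target" or rec["avssmd"] is None:
            continue
        per_gene.setdefault(gene, []).append(rec["avssmd"])
    per_gene = {g: sum(v) / len(v) for g, v in per_gene.items()}

    scored = [r["avssmd"] for r in per_construct.values() if r["avssmd"] is not None]
    mean = sum(scored) / len(scored)
    sd = math.sqrt(sum((x - mean) ** 2 for x in scored) / (len(scored) - 1))
    stats = {
        "median_bgr": median_bgr,
        "mad": mad,
        "n_constructs_scored": len(scored),
        "sd_avssmd": sd,
    }
    return per_construct, stats, per_gene
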