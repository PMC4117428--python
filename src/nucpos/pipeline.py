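"""End-to-end orchestration of the two headline analyses.

``run_pipeline`` executes the enabled stages in dependency order:

1. ``simulate`` — synthetic genome with planted nucleosomes; a normal
   condition (all classes at the normal density, MNase-like unpaired reads)
   and an apoptotic condition (GC-dependent depletion, paired 120 bp reads).
2. ``patterns`` — 5'-anchored dinucleotide profiles and dyad offsets for
   both conditions.
3. ``periodicity`` — dominant periods of the AA+TT / GG+CC tracks and their
   phase lag.
4. ``occupancy`` — TSS occupancy matrices, K-means promoter groups, group
   composition, per-condition promoter counts and a bootstrap group z-score.
5. ``predict`` — {AA,TT,AT} / {GG,CC,GC} pattern training and dyad
   prediction on truth-centered evaluation windows, with precision vs the
   analytic random baseline.
6. ``curvature`` — mean wedge-model curvature tracks around true dyads.

Every output is stamped with the config hash and seed; per-stage seeds are
derived deterministically from the global seed by hashing the stage name, so
toggling one stage never reshuffles another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .config import APOPTOTIC_PROTOCOL, RunConfig, _to_plain
from .curvature import WedgeTable, mean_curvature_track
from .occupancy import (
    bootstrap_group_z,
    cluster_promoters,
    dyad_counts_around_tss,
    dyads_from_reads,
    group_nucleotide_profile,
    promoter_nucleosome_counts,
)
from .patterns import (
    recenter_reads,
    dinucleotide_profile,
    estimate_dyad_offset,
    extract_aligned_windows,
)
from .periodicity import dominant_period, profile_lag
from .predict import PatternSet, evaluate_precision, predict_dyads
from .simulate import (
    apply_apoptotic_depletion,
    build_synthetic_genome,
    simulate_protocol_reads,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "patterns", "periodicity", "occupancy", "predict",
               "curvature"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_to_plain(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise RuntimeError(
            f"stage {stage!r}: missing upstream output {key!r} "
            f"(enable the producing stage or provide it via config paths)")
    return state[key]


def _stage_simulate(cfg: RunConfig, state: dict, outdir: Path) -> dict:
    seed = stage_seed(cfg.seed, "simulate")
    normal_density = max(c.nucleosome_density for c in cfg.classes)
    normal_classes = tuple(
        dataclasses.replace(c, nucleosome_density=normal_density)
        for c in cfg.classes
    )
    genome, tss, truth = build_synthetic_genome(
        normal_classes, cfg.signal, seed=seed, flank=cfg.flank_bp)
    truth_apo = apply_apoptotic_depletion(
        truth, genome, cfg.retention_gc_rich, seed=stage_seed(cfg.seed, "deplete"))
    reads = simulate_protocol_reads(
        genome, truth, cfg.protocol, seed=stage_seed(cfg.seed, "reads_normal"))
    reads_apo = simulate_protocol_reads(
        genome, truth_apo, APOPTOTIC_PROTOCOL,
        seed=stage_seed(cfg.seed, "reads_apoptotic"))
    gio.write_genome_fasta(genome, outdir / "genome.fa")
    gio.write_tss_table(tss, outdir / "tss.tsv")
    gio.write_truth_table(truth_apo, outdir / "truth.tsv")
    gio.write_reads_bed(reads, outdir / "reads_normal.bed")
    gio.write_reads_bed(reads_apo, outdir / "reads_apoptotic.bed")
    state.update(genome=genome, tss=tss, truth=truth, truth_apoptotic=truth_apo,
                 reads_normal=reads, reads_apoptotic=reads_apo)
    return {
        "n_nucleosomes": int(len(truth)),
        "n_retained_apoptotic": int(truth_apo["retained_in_apoptosis"].sum()),
        "n_reads_normal": int(len(reads)),
        "n_reads_apoptotic": int(len(reads_apo)),
    }


def _load_external(cfg: RunConfig, state: dict) -> None:
    if "genome" not in state and cfg.genome_fasta:
        state["genome"] = gio.load_genome_fasta(cfg.genome_fasta)
    if "tss" not in state and cfg.tss_tsv:
        state["tss"] = gio.load_tss_table(cfg.tss_tsv)
    if "reads_normal" not in state and cfg.reads_bed:
        state["reads_normal"] = gio.load_reads_bed(cfg.reads_bed,
                                                   strict=cfg.strict)


def _stage_patterns(cfg: RunConfig, state: dict, outdir: Path) -> dict:
    genome = _require(state, "genome", "patterns")
    out = {}
    for cond in ("normal", "apoptotic"):
        key = f"reads_{cond}"
        if key not in state:
            continue
        reads = state[key]
        windows = extract_aligned_windows(reads, genome, 147)
        profile = dinucleotide_profile(windows)
        profile.to_tsv(outdir / f"profile_{cond}.tsv")
        offset, curve = estimate_dyad_offset(reads, genome)
        curve.to_csv(outdir / f"dyad_offset_{cond}.tsv", sep="\t", index=False)
        centered = dinucleotide_profile(extract_aligned_windows(
            recenter_reads(reads, offset), genome, 147))
        centered.to_tsv(outdir / f"profile_centered_{cond}.tsv")
        state[f"windows_{cond}"] = windows
        state[f"profile_{cond}"] = profile
        state[f"profile_centered_{cond}"] = centered
        state[f"dyad_offset_{cond}"] = offset
        out[cond] = {"n_windows": int(windows.shape[0]),
                     "dyad_offset": int(offset)}
    if not out:
        raise RuntimeError("stage 'patterns': no read set available")
    return out


def _stage_periodicity(cfg: RunConfig, state: dict, outdir: Path) -> dict:
    out = {}
    seed = stage_seed(cfg.seed, "periodicity")
    for cond in ("normal", "apoptotic"):
        # dyad-centered profiles: the frame in which the periodic signal is
        # symmetric, so the detrended spectrum isolates the helical repeat
        prof = state.get(f"profile_centered_{cond}",
                         state.get(f"profile_{cond}"))
        if prof is None:
            continue
        aatt = prof.track({"AA", "TT"})
        ggcc = prof.track({"GG", "CC"})
        sp = dominant_period(aatt, detrend="linear", seed=seed)
        sp.to_frame().to_csv(outdir / f"spectrum_aatt_{cond}.tsv", sep="\t",
                             index=False)
        lag, curve = profile_lag(aatt, ggcc, max_lag=cfg.max_lag)
        curve.to_csv(outdir / f"lag_aatt_ggcc_{cond}.tsv", sep="\t",
                     index=False)
        out[cond] = {
            "dominant_period_aatt": round(float(sp.dominant_period), 3),
            "significant": bool(sp.significant),
            "lag_aatt_ggcc": int(lag),
        }
    if not out:
        raise RuntimeError("stage 'periodicity': no profiles available")
    return out


def _stage_occupancy(cfg: RunConfig, state: dict, outdir: Path) -> dict:
    genome = _require(state, "genome", "occupancy")
    tss = _require(state, "tss", "occupancy")
    out: dict = {}
    mats = {}
    for cond in ("normal", "apoptotic"):
        key = f"reads_{cond}"
        if key not in state:
            continue
        offset = state.get(f"dyad_offset_{cond}", 147 // 2)
        dyads = dyads_from_reads(state[key], offset)
        mats[cond] = dyad_counts_around_tss(
            dyads, tss, cfg.flank_bp, cfg.smooth_bp, genome.chrom_sizes)
        state[f"occupancy_{cond}"] = mats[cond]
        mats[cond].to_frame().to_csv(outdir / f"occupancy_{cond}.tsv",
                                     sep="\t")
    if not mats:
        raise RuntimeError("stage 'occupancy': no read set available")
    cond = "apoptotic" if "apoptotic" in mats else "normal"
    groups = cluster_promoters(mats[cond], cfg.kmeans_k,
                               seed=stage_seed(cfg.seed, "occupancy"))
    state["groups"] = groups
    groups.labels.to_csv(outdir / "promoter_groups.tsv", sep="\t")
    comp = group_nucleotide_profile(genome, tss, groups, cfg.flank_bp)
    for g, d in comp.items():
        groups.group_gc[g] = d["mean_gc"]
    out["groups"] = {
        "sizes": groups.sizes,
        "mean_gc": {g: round(d["mean_gc"], 4) for g, d in comp.items()},
    }
    if len(mats) == 2 and groups.sizes.get(2):
        # contrast: depleted-group per-promoter counts, apoptotic vs normal
        ids = groups.ids_in_group(2)
        idx = [mats["normal"].promoter_ids.index(p) for p in ids]
        a = mats["apoptotic"].totals[idx]
        b = mats["normal"].totals[idx]
        if len(ids) >= 2:
            boot = bootstrap_group_z(a, b, seed=stage_seed(cfg.seed, "boot"))
            out["depleted_group_z"] = round(boot["z"], 2)
    if cfg.gene_sets_tsv:
        gs = pd.read_csv(cfg.gene_sets_tsv, sep="\t")
        rows = {}
        for cond2, mat in mats.items():
            counts = promoter_nucleosome_counts(
                dyads_from_reads(state[f"reads_{cond2}"],
                                 state.get(f"dyad_offset_{cond2}", 73)),
                tss, cfg.flank_bp, gs)
            rows[cond2] = counts["sets"]
        out["gene_sets"] = rows
        pd.DataFrame(rows).to_json(outdir / "gene_set_counts.json")
    if cfg.make_figures:
        _plot_occupancy(mats, groups, cfg, outdir)
    return out


def _stage_predict(cfg: RunConfig, state: dict, outdir: Path) -> dict:
    genome = _require(state, "genome", "predict")
    profile = _require(state, "profile_normal", "predict")
    truth = _require(state, "truth", "predict")
    rng = np.random.default_rng(stage_seed(cfg.seed, "predict"))
    ps_at = PatternSet.train(profile, ["AA", "TT", "AT"], "{AA,TT,AT}")
    ps_gc = PatternSet.train(profile, ["GG", "CC", "GC"], "{GG,CC,GC}")
    half = 313 // 2
    pick = truth.sample(min(cfg.n_eval_windows, len(truth)),
                        random_state=int(rng.integers(2**31)))
    windows = []
    for rec in pick.itertuples(index=False):
        seq = genome.sequences[rec.chrom]
        lo = rec.dyad_pos - half
        if lo < 0 or lo + 313 > len(seq):
            continue
        windows.append(seq[lo:lo + 313])
    from .alphabet import encode
    mat = np.vstack([encode(w) for w in windows])
    result = predict_dyads(mat, [ps_at, ps_gc], cfg.tolerances)
    table = evaluate_precision(result)
    table.to_csv(outdir / "prediction_precision.tsv", sep="\t", index=False)
    preds = result.table
    bed = pd.DataFrame({
        "chrom": "eval", "start": preds["dyad_combined"] - 73,
        "end": preds["dyad_combined"] + 74,
        "name": [f"w{i}" for i in range(len(preds))],
        "score": (np.nanmax(preds[[f"peak_{ps_at.name}",
                                   f"peak_{ps_gc.name}"]].to_numpy(), axis=1)
                  * 1000).round().astype(int),
        "strand": "+",
    })
    bed.to_csv(outdir / "predictions.bed", sep="\t", header=False, index=False)
    state["prediction_result"] = result
    state["precision_table"] = table
    return {
        "n_windows": int(len(preds)),
        "precision": {
            int(r["tolerance"]): {
                "combined": round(float(r["hit_combined"]), 4),
                "union": round(float(r.get("hit_union", np.nan)), 4),
                "both": round(float(r.get("hit_both", np.nan)), 4),
                "random_baseline": round(float(r["random_baseline"]), 4),
            }
            for _, r in table.iterrows()
        },
    }


def _stage_curvature(cfg: RunConfig, state: dict, outdir: Path) -> dict:
    genome = _require(state, "genome", "curvature")
    truth = _require(state, "truth", "curvature")
    rng = np.random.default_rng(stage_seed(cfg.seed, "curvature"))
    table = WedgeTable.default()
    pick = truth.sample(min(cfg.n_eval_windows, len(truth)),
                        random_state=int(rng.integers(2**31)))
    from .alphabet import encode
    half = 147 // 2
    wins = []
    for rec in pick.itertuples(index=False):
        seq = genome.sequences[rec.chrom]
        lo = rec.dyad_pos - half
        if lo >= 0 and lo + 147 <= len(seq):
            wins.append(encode(seq[lo:lo + 147]))
    track = mean_curvature_track(np.vstack(wins), 11, table)
    df = pd.DataFrame({"position_from_dyad": np.arange(147) - half,
                       "mean_curvature_deg": track})
    df.to_csv(outdir / "curvature_around_dyad.tsv", sep="\t", index=False)
    finite = df.dropna()
    peak = finite.loc[finite["mean_curvature_deg"].idxmax()]
    return {"n_windows": len(wins),
            "peak_position": int(peak["position_from_dyad"]),
            "peak_curvature_deg": round(float(peak["mean_curvature_deg"]), 3)}


def _plot_occupancy(mats, groups, cfg: RunConfig, outdir: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - plotting is best-effort
        logger.warning("matplotlib unavailable; skipping figures")
        return
    fig, ax = plt.subplots(figsize=(7, 4))
    for cond, mat in mats.items():
        pos = mat.positions
        for g in sorted(groups.sizes):
            ids = set(groups.ids_in_group(g))
            rows = [i for i, p in enumerate(mat.promoter_ids) if p in ids]
            if not rows:
                continue
            ax.plot(pos, mat.smoothed[rows].mean(axis=0),
                    label=f"{cond} group {g}")
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("mean dyad count (smoothed)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "occupancy_groups.png", dpi=120)
    plt.close(fig)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "patterns": _stage_patterns,
    "periodicity": _stage_periodicity,
    "occupancy": _stage_occupancy,
    "predict": _stage_predict,
    "curvature": _stage_curvature,
}


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages; returns (and writes) the summary bundle.

    The machine-readable summary (``summary.json``) is stamped with the
    config hash and global seed; identical config + seed give byte-identical
    summaries. Stages run in dependency order; a stage whose upstream output
    is missing fails with the stage name.
    """
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    _load_external(cfg, state)
    summary: dict = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
    }
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        t0 = time.monotonic()
        logger.info("stage %s: start", stage)
        summary["stages"][stage] = _STAGE_FNS[stage](cfg, state, outdir)
        logger.info("stage %s: done in %.1fs", stage, time.monotonic() - t0)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    return summary
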