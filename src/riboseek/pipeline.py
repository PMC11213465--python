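"""Stage orchestration: run configured analysis stages and assemble a report.

The pipeline is a thin layer over the library modules.  Stages run in
dependency order; a failing stage is recorded (with its error) and its
dependents are skipped, while independent stages still run.  All numeric
output is a pure function of the inputs and the configured seeds, so a
rerun on unchanged inputs reproduces the report body exactly (timestamps
excluded).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import dynamics as dyn
from . import localization as loc
from . import motifs as mot
from . import polysome as poly
from . import screen as scr
from . import stalling as stl

log = logging.getLogger("riboseek")

__all__ = ["load_config", "run_pipeline", "run_stage"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


# -- individual stages ------------------------------------------------------


def _stage_screen(blk: dict) -> dict:
    expr_a = scr.ExpressionMatrix.from_tsv(blk["expr"], blk["meta"])
    expr_b = scr.ExpressionMatrix.from_tsv(blk["expr_b"], blk["meta_b"])
    with open(blk["annotation"]) as fh:
        annotation = {line.split("\t")[0].strip() for line in fh if line.strip()}
    omap = scr.OrthologMap.from_tsv(blk["orthologs"])
    report, validated = scr.run_screen(
        expr_a,
        blk.get("target_tissue", "heart"),
        annotation,
        omap,
        expr_b,
        fold=float(blk.get("fold", 5.0)),
        floor=float(blk.get("floor", 0.5)),
    )
    return {"funnel": report.to_dict(), "validated": validated}


def _stage_polysome(blk: dict) -> dict:
    table = pd.read_csv(blk["table"], sep="\t")
    calls = poly.classify_table(
        table,
        detect=float(blk.get("detect", 1.0)),
        pseudocount=float(blk.get("pseudocount", 0.5)),
    )
    ranked = poly.rank_associated(calls)
    ranked_strength = poly.rank_associated(calls, by="strength")
    return {
        "calls": [asdict(c) for c in calls],
        "n_associated": sum(c.call == "associated" for c in calls),
        "ranking_by_level": [c.transcript_id for c in ranked],
        "ranking_by_strength": [c.transcript_id for c in ranked_strength],
    }


def _stage_localize(blk: dict) -> dict:
    df = pd.read_csv(blk["fish"], sep="\t")
    cells = [
        loc.CellSpotCounts(str(r.cell_id), int(r.nuclear_spots),
                           int(r.cytoplasmic_spots))
        for r in df.itertuples()
    ]
    res = loc.fish_localization(cells, min_cells=int(blk.get("min_cells", 100)))
    return res.to_dict()


def _stage_motifs(blk: dict) -> dict:
    rec_a = next(SeqIO.parse(blk["promoter_a"], "fasta"))
    rec_b = next(SeqIO.parse(blk["promoter_b"], "fasta"))
    seq_a, seq_b = str(rec_a.seq), str(rec_b.seq)
    windows = mot.conserved_window_detect(
        seq_a,
        seq_b,
        window_len=int(blk.get("window", 50)),
        identity_min=float(blk.get("identity", 70.0)),
    )
    pwms = [mot.read_pwm(p) for p in blk["pwm"]]
    p_thr = float(blk.get("p", 1e-4))
    hits_a, hits_b, pairs = [], [], []
    for pwm in pwms:
        hits_a += mot.scan_sequence(pwm, seq_a, p_thr, sequence_id=rec_a.id)
        hits_b += mot.scan_sequence(pwm, seq_b, p_thr, sequence_id=rec_b.id)
    pairs = mot.cross_species_site_pairs(hits_a, hits_b, windows)
    return {
        "windows": [asdict(w) for w in windows],
        "n_hits_a": len(hits_a),
        "n_hits_b": len(hits_b),
        "pairs": [
            {"motif": p.motif, "start_a": p.hit_a.start, "start_b": p.hit_b.start,
             "window": [p.window.start, p.window.end]}
            for p in pairs
        ],
    }


def _stage_dynamics(blk: dict) -> dict:
    ribo = dyn.read_timecourse_tsv(blk["table"], blk.get("ribo_series", "ribo"))
    rna = dyn.read_timecourse_tsv(blk["table"], blk.get("rna_series", "rna"))
    call = dyn.translational_shift(ribo, rna)
    return {
        "ribo_peak": call.ribo_peak_label,
        "rna_peak": call.rna_peak_label,
        "lag_hours": call.lag_hours,
    }


def _stage_stalls(blk: dict) -> dict:
    starts = {}
    with open(blk["starts"]) as fh:
        for line in fh:
            tx, s = line.split()
            starts[tx] = int(s)
    tracks = dyn.read_bedgraph(blk["coverage"], starts)
    out = {}
    for tr in tracks:
        peaks, ratio = dyn.stall_peak_detect(
            tr,
            flank=int(blk.get("flank", 25)),
            z_min=float(blk.get("z", 5.0)),
        )
        out[tr.transcript_id] = {
            "peaks": [asdict(p) for p in peaks],
            "start_proximal_ratio": None if np.isnan(ratio) else ratio,
        }
    return out


def _stage_stalling(blk: dict) -> dict:
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(blk["proteins"], "fasta")}
    groups = {}
    with open(blk["groups"]) as fh:
        for line in fh:
            if line.strip():
                pid, g = line.split()
                groups[pid] = g
    motifs = (
        stl.StallingMotifSet.from_file(blk["motifs"])
        if blk.get("motifs")
        else stl.EXAMPLE_STALLING_MOTIFS
    )
    rng = np.random.default_rng(int(blk.get("seed", 0)))
    stats = stl.run_enrichment(
        seqs, groups, blk.get("test_group", "upregulated"), motifs, rng=rng
    )
    return stats.to_dict()


def _stage_interactome(blk: dict) -> dict:
    sets = []
    for path in blk["sets"]:
        with open(path) as fh:
            ids = frozenset(line.strip() for line in fh if line.strip())
        sets.append(stl.InteractorSet(Path(path).stem, ids))
    return {"shared": sorted(stl.intersect_interactomes(sets))}


_STAGES = {
    "screen": _stage_screen,
    "polysome": _stage_polysome,
    "localize": _stage_localize,
    "motifs": _stage_motifs,
    "dynamics": _stage_dynamics,
    "stalls": _stage_stalls,
    "stalling": _stage_stalling,
    "interactome": _stage_interactome,
}


def run_stage(name: str, blk: dict) -> dict:
    return _STAGES[name](blk)


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Run every configured stage, isolating failures, and return the report."""
    report: dict = {"stages": {}, "seeds": {}, "timestamp": time.time()}
    for name in _STAGES:
        blk = cfg.get(name)
        if not blk:
            report["stages"][name] = {"status": "skipped", "reason": "not configured"}
            continue
        try:
            log.info("stage %s: running", name)
            result = run_stage(name, blk)
            report["stages"][name] = {"status": "ok", "result": result}
            if "seed" in blk:
                report["seeds"][name] = blk["seed"]
        except Exception as exc:  # stage isolation: record, keep going
            log.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        body = {k: v for k, v in report.items() if k != "timestamp"}
        with open(out / "report.json", "w") as fh:
            json.dump(body, fh, indent=2, default=float)
    return report
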