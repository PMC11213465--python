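"""Synthetic-data generators with known ground truth for every pipeline stage.

Every generator is a pure function of a :class:`SimulationConfig` (seed
included): the same configuration reproduces every file bit-for-bit.  The
global seed expands into independent per-generator substreams so individual
stages can be regenerated without touching the others.

What is emulated, and the defaults:

* multi-organ FPKM matrices for two species with planted target-specific
  genes (multiplicative lognormal noise, sigma 0.3 in log2 units) and
  annotation / ortholog tables whose dropout reproduces the screening-funnel
  structure 96 -> 26 -> 8 -> 5;
* polysome-fraction tables where 4 of 5 candidates carry polysome signal,
  plus a polysome-heavy housekeeping control and a free-only control;
* FISH spot counts with cytoplasmic spots binomial at a true fraction;
* TSS-anchored promoter pairs with conserved blocks and planted PWM sites;
* ribosome-protected vs total-RNA time courses with planted peak timing, and
  footprint coverage tracks with planted stall pile-ups;
* a proteome with group-dependent planted stalling-motif rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import PWM, build_pwm
from .screen import ExpressionMatrix, OrthologMap

__all__ = [
    "SimulationConfig",
    "example_pwms",
    "generate_expression",
    "generate_polysome",
    "generate_fish",
    "generate_promoters",
    "generate_dynamics_and_coverage",
    "generate_proteome",
    "generate_interactomes",
    "generate_all",
]

_SUBSTREAMS = {
    "expression": 1,
    "polysome": 2,
    "fish": 3,
    "promoters": 4,
    "dynamics": 5,
    "proteome": 6,
    "interactome": 7,
}


@dataclass
class SimulationConfig:
    seed: int = 0

    # expression screen (species A = "human"-like, species B = "mouse"-like)
    n_background: int = 400
    n_planted: int = 96
    true_fold: float = 50.0  # demo-funnel default: far above the 5x rule
    sigma: float = 0.3  # lognormal noise, log2 units
    tissues: tuple[str, ...] = ("heart", "brain", "liver", "kidney")
    n_replicates: int = 2
    target_tissue: str = "heart"
    other_mean_fpkm: float = 5.0
    n_annotated: int = 26  # planted genes present in the annotation table
    n_orthologous: int = 8  # annotated planted genes with a species-B ortholog
    n_cross_specific: int = 5  # orthologs planted target-specific in species B

    # polysome profiling
    candidate_polysome_levels: tuple[float, ...] = (8.0, 3.0, 2.0, 1.5, 0.0)
    candidate_free_levels: tuple[float, ...] = (2.0, 1.5, 1.0, 0.8, 5.0)
    polysome_sigma: float = 0.05

    # FISH
    fish_true_cyto: float = 0.6
    fish_n_cells: int = 100
    fish_spots_per_cell: int = 50

    # promoters: [TSS-2000, TSS+200), two conserved blocks near the TSS
    promoter_len: int = 2200
    conserved_blocks: tuple[tuple[int, int], ...] = ((1700, 1780), (1960, 2040))
    block_mismatch_rate: float = 0.02

    # dynamics time course
    timepoints: tuple[tuple[str, float], ...] = (
        ("sham", 0.0), ("3 h", 3.0), ("2 d", 48.0), ("2 w", 336.0), ("4 w", 672.0)
    )
    rna_means: tuple[float, ...] = (1.0, 2.0, 10.0, 4.0, 2.0)  # peaks at 2 d
    ribo_means: tuple[float, ...] = (1.0, 1.5, 3.0, 10.0, 5.0)  # peaks at 2 w
    tc_sigma: float = 0.1
    n_tc_replicates: int = 3

    # footprint coverage
    coverage_len: int = 2000
    coverage_lambda: float = 20.0
    start_codon: int = 100
    stall_positions: tuple[int, ...] = (600, 1200)
    stall_fold: float = 10.0

    # proteome
    n_per_group: int = 200
    protein_len: int = 400
    rest_motif_rate: float = 2.0
    group_rate_ratio: float = 2.0

    # interactome
    shared_protein: str = "DRG1"
    interactome_sizes: tuple[int, ...] = (30, 25, 20)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SUBSTREAMS[stream]])


def _lognoise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise, sigma in log2 units."""
    return 2.0 ** rng.normal(0.0, sigma, shape)


# -- expression -------------------------------------------------------------


def _species_matrix(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    species: str,
    gene_means: pd.DataFrame,
) -> ExpressionMatrix:
    samples, meta = [], []
    cols = {}
    for tissue in cfg.tissues:
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{species}_{tissue}_{rep}"
            samples.append(sid)
            meta.append({"sample_id": sid, "species": species,
                         "tissue": tissue, "replicate": rep})
            noise = _lognoise(rng, cfg.sigma, len(gene_means))
            cols[sid] = gene_means[tissue].to_numpy() * noise
    values = pd.DataFrame(cols, index=gene_means.index)
    meta_df = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionMatrix(values, meta_df)


def generate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, set[str], OrthologMap, dict]:
    """Two-species expression matrices plus annotation/ortholog tables and truth.

    Planted genes have target-tissue mean = true_fold x the (shared) mean of
    every other tissue; background genes share one mean across tissues.
    Annotation and ortholog dropout follow the configured funnel structure,
    and the species-B partners of the orthologous planted genes split into
    cross-species-specific and non-specific genes.
    """
    if not (cfg.n_cross_specific <= cfg.n_orthologous <= cfg.n_annotated
            <= cfg.n_planted):
        raise ValueError("funnel structure must nest: cross <= orth <= ann <= planted")
    rng = cfg.rng("expression")
    others = [t for t in cfg.tissues if t != cfg.target_tissue]
    if not others:
        raise ValueError("need at least one non-target tissue")

    planted = [f"GA{i:04d}" for i in range(cfg.n_planted)]
    background = [f"BG{i:04d}" for i in range(cfg.n_background)]
    rows = {}
    for g in planted:
        base = cfg.other_mean_fpkm
        rows[g] = {t: base for t in others} | {
            cfg.target_tissue: cfg.true_fold * base
        }
    for g in background:
        base = float(cfg.other_mean_fpkm * _lognoise(rng, 0.5, ()))
        rows[g] = {t: base for t in cfg.tissues}
    means_a = pd.DataFrame(rows).T.loc[planted + background]
    expr_a = _species_matrix(cfg, rng, "speciesA", means_a)

    annotated_planted = planted[: cfg.n_annotated]
    annotation = set(annotated_planted) | set(background)

    orth_planted = annotated_planted[: cfg.n_orthologous]
    partners = {g: g.replace("GA", "MB") for g in orth_planted}
    bg_pairs = [(g, g.replace("BG", "MG")) for g in background]
    omap = OrthologMap([(g, partners[g]) for g in orth_planted] + bg_pairs)

    cross_specific = orth_planted[: cfg.n_cross_specific]
    rows_b = {}
    for g in orth_planted:
        base = cfg.other_mean_fpkm
        if g in cross_specific:
            rows_b[partners[g]] = {t: base for t in others} | {
                cfg.target_tissue: cfg.true_fold * base
            }
        else:
            rows_b[partners[g]] = {t: base for t in cfg.tissues}
    for g, p in bg_pairs:
        base = float(cfg.other_mean_fpkm * _lognoise(rng, 0.5, ()))
        rows_b[p] = {t: base for t in cfg.tissues}
    means_b = pd.DataFrame(rows_b).T
    expr_b = _species_matrix(cfg, rng, "speciesB", means_b)

    truth = {
        "planted_specific_a": planted,
        "annotated_planted": annotated_planted,
        "orthologous_planted": orth_planted,
        "cross_species_specific": cross_specific,
        "expected_funnel": {
            "specificity_out": cfg.n_planted,
            "annotation_excluded": cfg.n_planted - cfg.n_annotated,
            "ortholog_excluded": cfg.n_annotated - cfg.n_orthologous,
            "cross_species_excluded": cfg.n_orthologous - cfg.n_cross_specific,
            "final": cfg.n_cross_specific,
        },
    }
    return expr_a, expr_b, annotation, omap, truth


# -- polysome ---------------------------------------------------------------


def generate_polysome(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Long-format fraction table for 5 candidates plus two controls."""
    rng = cfg.rng("polysome")
    rows = []
    truth_assoc = []
    fractions = ("free", "40S", "60S", "monosome", "polysome")

    def emit(tid: str, levels: dict[str, float]) -> None:
        for fr in fractions:
            lvl = levels.get(fr, 0.0)
            if lvl > 0:
                lvl = float(lvl * _lognoise(rng, cfg.polysome_sigma, ()))
            rows.append({"transcript_id": tid, "fraction": fr, "level": lvl})

    for i, (poly, free) in enumerate(
        zip(cfg.candidate_polysome_levels, cfg.candidate_free_levels), start=1
    ):
        tid = f"CAND{i}"
        emit(tid, {"free": free, "40S": poly * 0.2, "60S": poly * 0.2,
                   "monosome": poly * 0.4, "polysome": poly})
        if poly >= 1.0:
            truth_assoc.append(tid)
    emit("HOUSEKEEPING", {"free": 2.0, "40S": 3.0, "60S": 3.0,
                          "monosome": 10.0, "polysome": 40.0})
    emit("FREE_ONLY", {"free": 10.0})
    truth = {
        "candidates": [f"CAND{i+1}" for i in
                       range(len(cfg.candidate_polysome_levels))],
        "associated": truth_assoc,
        "strongest": "CAND1",
        "free_only": ["FREE_ONLY"],
    }
    return pd.DataFrame(rows), truth


# -- FISH -------------------------------------------------------------------


def generate_fish(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Per-cell spot counts: total ~ Poisson(spots/cell), cytoplasmic ~ binomial."""
    rng = cfg.rng("fish")
    rows = []
    for i in range(cfg.fish_n_cells):
        total = int(rng.poisson(cfg.fish_spots_per_cell))
        cyto = int(rng.binomial(total, cfg.fish_true_cyto)) if total else 0
        rows.append({"cell_id": f"cell{i:03d}",
                     "nuclear_spots": total - cyto,
                     "cytoplasmic_spots": cyto})
    return pd.DataFrame(rows), {"true_cytoplasmic_fraction": cfg.fish_true_cyto}


# -- promoters --------------------------------------------------------------


def example_pwms() -> list[PWM]:
    """Two demonstration PWMs built from consensus strings.

    A MEF2-like A/T-rich site and an NFAT-like GGAA-core site; each position
    puts ~0.82 probability on the consensus base.
    """
    def from_consensus(name: str, consensus: str) -> PWM:
        counts = np.zeros((len(consensus), 4))
        for i, b in enumerate(consensus):
            counts[i, "ACGT".index(b)] = 17.0
            counts[i, [j for j in range(4) if j != "ACGT".index(b)]] = 1.0
        return build_pwm(counts, pseudocount=0.25, name=name)

    return [
        from_consensus("MEF2_like", "CTAAAAATAG"),
        from_consensus("NFAT_like", "TGGAAAAT"),
    ]


def generate_promoters(cfg: SimulationConfig) -> tuple[str, str, list[dict], dict]:
    """Two TSS-anchored promoters with conserved blocks and planted motif sites.

    Backgrounds are independent uniform-base sequences; each conserved block
    is copied from species A to B with the configured mismatch rate; motif
    consensus instances are planted at the same TSS-relative offset in both
    species inside the blocks (overwriting any mismatches).
    """
    rng = cfg.rng("promoters")
    bases = np.array(list("ACGT"))
    a = rng.choice(bases, cfg.promoter_len)
    b = rng.choice(bases, cfg.promoter_len)
    for s, e in cfg.conserved_blocks:
        block = a[s:e].copy()
        mm = rng.random(e - s) < cfg.block_mismatch_rate
        for i in np.nonzero(mm)[0]:
            block[i] = rng.choice([x for x in "ACGT" if x != block[i]])
        b[s:e] = block

    pwms = example_pwms()
    planted = []
    for pwm, (s, e) in zip(pwms, cfg.conserved_blocks):
        consensus = "".join("ACGT"[i] for i in np.argmax(pwm.probabilities, axis=1))
        offset = s + 10
        if offset + len(consensus) > e:
            raise ValueError("planted motif does not fit inside its block")
        inst = np.array(list(consensus))
        a[offset : offset + len(inst)] = inst
        b[offset : offset + len(inst)] = inst
        planted.append({"motif": pwm.name, "start": offset,
                        "end": offset + len(inst), "strand": "+"})
    truth = {
        "conserved_blocks": [list(bl) for bl in cfg.conserved_blocks],
        "planted_motifs": planted,
        "tss_offset": cfg.promoter_len - 200,
    }
    return "".join(a), "".join(b), planted, truth


# -- dynamics + coverage ----------------------------------------------------


def generate_dynamics_and_coverage(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, dict]:
    """Time-course table, planted-stall coverage track, flat control track, truth."""
    rng = cfg.rng("dynamics")
    rows = []
    for series, means in (("ribo", cfg.ribo_means), ("rna", cfg.rna_means)):
        for (label, hours), mean in zip(cfg.timepoints, means):
            for rep in range(1, cfg.n_tc_replicates + 1):
                rows.append({
                    "series": series, "timepoint_label": label, "hours": hours,
                    "replicate": rep,
                    "level": float(mean * _lognoise(rng, cfg.tc_sigma, ())),
                })
    tc = pd.DataFrame(rows)

    cov = rng.poisson(cfg.coverage_lambda, cfg.coverage_len).astype(int)
    for pos in cfg.stall_positions:
        cov[pos] = int(rng.poisson(cfg.stall_fold * cfg.coverage_lambda))
    flat = np.full(cfg.coverage_len, int(cfg.coverage_lambda))

    labels = [lb for lb, _ in cfg.timepoints]
    hours = [h for _, h in cfg.timepoints]
    truth = {
        "rna_peak": labels[int(np.argmax(cfg.rna_means))],
        "ribo_peak": labels[int(np.argmax(cfg.ribo_means))],
        "lag_hours": hours[int(np.argmax(cfg.ribo_means))]
        - hours[int(np.argmax(cfg.rna_means))],
        "stall_positions": list(cfg.stall_positions),
        "start_codon": cfg.start_codon,
    }
    return tc, cov, flat, truth


# -- proteome ---------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_proteome(
    cfg: SimulationConfig, motif_catalog: dict[str, tuple[str, ...]] | None = None
) -> tuple[dict[str, str], dict[str, str], dict]:
    """Random proteome with group-dependent planted stalling-motif rates.

    The test group ("upregulated") receives planted motif occurrences at
    ``group_rate_ratio`` times the rest rate (Poisson counts; motif and
    position uniform; overlaps allowed).
    """
    from .stalling import EXAMPLE_STALLING_MOTIFS

    catalog = (
        motif_catalog
        if motif_catalog is not None
        else EXAMPLE_STALLING_MOTIFS.categories
    )
    all_motifs = [m for ms in catalog.values() for m in ms]
    rng = cfg.rng("proteome")
    sequences: dict[str, str] = {}
    groups: dict[str, str] = {}
    for label, rate, prefix in (
        ("upregulated", cfg.rest_motif_rate * cfg.group_rate_ratio, "UP"),
        ("rest", cfg.rest_motif_rate, "RP"),
    ):
        for i in range(cfg.n_per_group):
            seq = rng.choice(_AA, cfg.protein_len)
            for _ in range(int(rng.poisson(rate))):
                m = all_motifs[int(rng.integers(len(all_motifs)))]
                pos = int(rng.integers(cfg.protein_len - len(m) + 1))
                seq[pos : pos + len(m)] = list(m)
            pid = f"{prefix}{i:04d}"
            sequences[pid] = "".join(seq)
            groups[pid] = label
    truth = {
        "group_rate": cfg.rest_motif_rate * cfg.group_rate_ratio,
        "rest_rate": cfg.rest_motif_rate,
    }
    return sequences, groups, truth


def generate_interactomes(cfg: SimulationConfig) -> tuple[list[dict], dict]:
    """Three pull-down interactor sets sharing exactly one protein."""
    rng = cfg.rng("interactome")
    sets = []
    for i, size in enumerate(cfg.interactome_sizes, start=1):
        ids = {f"X{i}_{j:03d}" for j in range(size - 1)}  # experiment-private ids
        sets.append({"experiment": f"pulldown{i}",
                     "proteins": sorted(ids | {cfg.shared_protein})})
    return sets, {"shared": [cfg.shared_protein]}


# -- orchestration ----------------------------------------------------------


def generate_all(cfg: SimulationConfig, out_dir) -> dict:
    """Emit every fixture file the pipeline consumes, plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"config": asdict(cfg)}

    expr_a, expr_b, annotation, omap, t = generate_expression(cfg)
    expr_a.to_tsv(out / "expr_a.tsv", out / "expr_a.meta.tsv")
    expr_b.to_tsv(out / "expr_b.tsv", out / "expr_b.meta.tsv")
    (out / "annotation.tsv").write_text("".join(f"{g}\n" for g in sorted(annotation)))
    with open(out / "orthologs.tsv", "w") as fh:
        for a, b in omap.pairs:
            fh.write(f"{a}\t{b}\n")
    truth["expression"] = t

    poly, t = generate_polysome(cfg)
    poly.to_csv(out / "polysome.tsv", sep="\t", index=False)
    truth["polysome"] = t

    fish, t = generate_fish(cfg)
    fish.to_csv(out / "fish.tsv", sep="\t", index=False)
    truth["fish"] = t

    prom_a, prom_b, planted, t = generate_promoters(cfg)
    (out / "promoter_a.fa").write_text(f">promA TSS={t['tss_offset']}\n{prom_a}\n")
    (out / "promoter_b.fa").write_text(f">promB TSS={t['tss_offset']}\n{prom_b}\n")
    with open(out / "planted_motifs.bed", "w") as fh:
        for p in planted:
            fh.write(f"promoter\t{p['start']}\t{p['end']}\t{p['motif']}\t0\t+\n")
    for pwm in example_pwms():
        with open(out / f"{pwm.name}.mat", "w") as fh:
            fh.write(f">{pwm.name}\n")
            for row in pwm.probabilities:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    truth["promoters"] = t

    tc, cov, flat, t = generate_dynamics_and_coverage(cfg)
    tc.to_csv(out / "timecourse.tsv", sep="\t", index=False)
    with open(out / "coverage.bedgraph", "w") as fh:
        for tid, track in (("TX1", cov), ("FLAT", flat)):
            for pos, v in enumerate(track):
                fh.write(f"{tid}\t{pos}\t{pos + 1}\t{int(v)}\n")
    with open(out / "start_codons.tsv", "w") as fh:
        fh.write(f"TX1\t{cfg.start_codon}\nFLAT\t{cfg.start_codon}\n")
    truth["dynamics"] = t

    seqs, groups, t = generate_proteome(cfg)
    with open(out / "proteins.fa", "w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n{seq}\n")
    with open(out / "groups.tsv", "w") as fh:
        for pid, g in groups.items():
            fh.write(f"{pid}\t{g}\n")
    truth["proteome"] = t

    isets, t = generate_interactomes(cfg)
    for s in isets:
        with open(out / f"{s['experiment']}.tsv", "w") as fh:
            fh.write("".join(f"{p}\n" for p in s["proteins"]))
    truth["interactome"] = t

    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
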