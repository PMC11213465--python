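"""Seeded end-to-end validation experiments on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage, and measures recovery of the planted ground truth.  These are the
computations behind the package's reported operating characteristics
(screen sensitivity, localization accuracy, stall-site recovery, enrichment
power and calibration); the problem sizes are the generator defaults.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps

from .dynamics import CoverageTrack, stall_peak_detect
from .localization import CellSpotCounts, fish_localization
from .motifs import PWM, score_pvalue
from .polysome import classify_table
from .screen import run_screen
from .simulate import SimulationConfig, generate_expression, generate_fish, \
    generate_polysome, generate_proteome
from .stalling import EXAMPLE_STALLING_MOTIFS, run_enrichment

__all__ = [
    "funnel_fixture_counts",
    "screen_recovery",
    "localization_recovery",
    "stall_recovery",
    "enrichment_power",
    "enrichment_null_calibration",
    "pwm_null_max_error",
]


def funnel_fixture_counts(seed: int) -> dict:
    """Screen + polysome classification on the demo funnel fixture."""
    cfg = SimulationConfig(seed=seed)
    expr_a, expr_b, ann, omap, truth = generate_expression(cfg)
    report, validated = run_screen(expr_a, cfg.target_tissue, ann, omap, expr_b)
    table, ptruth = generate_polysome(cfg)
    calls = {c.transcript_id: c for c in classify_table(table)}
    n_assoc = sum(
        calls[t].call == "associated" for t in ptruth["candidates"]
    )
    return {
        "initial": report.stage("annotation").n_in,
        "annotation_excluded": report.stage("annotation").n_excluded,
        "ortholog_excluded": report.stage("ortholog").n_excluded,
        "cross_species_excluded": report.stage("cross_species").n_excluded,
        "final": report.n_final,
        "candidates_associated": n_assoc,
        "n_candidates": len(ptruth["candidates"]),
    }


def screen_recovery(
    seed: int,
    n_replicates: int = 20,
    true_fold: float = 10.0,
    sigma: float = 0.3,
    n_planted: int = 50,
    n_background: int = 450,
) -> dict:
    """Planted-gene recovery of the 5x screen over seeded replicates.

    Sensitivity = recovered planted genes / planted genes; false-discovery
    proportion = non-planted calls / all calls; both pooled over replicates.
    """
    tp = fp = fn = 0
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    for s in seeds:
        cfg = SimulationConfig(
            seed=int(s), true_fold=true_fold, sigma=sigma,
            n_planted=n_planted, n_background=n_background,
            n_annotated=n_planted, n_orthologous=n_planted,
            n_cross_specific=n_planted,
        )
        expr_a, _, _, _, truth = generate_expression(cfg)
        from .screen import compute_specificity

        calls = compute_specificity(expr_a, cfg.target_tissue, fold=5.0,
                                    floor=0.5)
        called = {c.gene_id for c in calls if c.passes_fold}
        planted = set(truth["planted_specific_a"])
        tp += len(called & planted)
        fp += len(called - planted)
        fn += len(planted - called)
    sensitivity = tp / (tp + fn)
    fdp = fp / max(tp + fp, 1)
    return {"sensitivity": sensitivity, "fdp": fdp,
            "n_planted_total": tp + fn}


def localization_recovery(seed: int, true_fraction: float = 0.6) -> dict:
    """FISH recovery of a planted cytoplasmic fraction (percent scale)."""
    cfg = SimulationConfig(seed=seed, fish_true_cyto=true_fraction)
    df, truth = generate_fish(cfg)
    cells = [
        CellSpotCounts(str(r.cell_id), int(r.nuclear_spots),
                       int(r.cytoplasmic_spots))
        for r in df.itertuples()
    ]
    res = fish_localization(cells)
    return {
        "percent_cytoplasmic": res.percent_cytoplasmic,
        "true_percent": 100.0 * truth["true_cytoplasmic_fraction"],
        "error": abs(res.percent_cytoplasmic
                     - 100.0 * truth["true_cytoplasmic_fraction"]),
    }


def stall_recovery(seed: int, n_tracks: int = 20) -> dict:
    """Planted stall pile-up recovery (within 1 nt) and flat-track specificity."""
    recovered = total = 0
    flat_false = 0
    seeds = np.random.SeedSequence(seed).generate_state(n_tracks) % (2**31)
    for s in seeds:
        cfg = SimulationConfig(seed=int(s))
        rng = cfg.rng("dynamics")
        cov = rng.poisson(cfg.coverage_lambda, cfg.coverage_len).astype(int)
        for pos in cfg.stall_positions:
            cov[pos] = int(rng.poisson(cfg.stall_fold * cfg.coverage_lambda))
        track = CoverageTrack("tx", cov, cfg.start_codon)
        peaks, _ = stall_peak_detect(track, flank=25, z_min=5.0)
        hits = {p.position for p in peaks}
        for pos in cfg.stall_positions:
            total += 1
            if any(abs(h - pos) <= 1 for h in hits):
                recovered += 1
        flat = CoverageTrack("flat",
                             np.full(cfg.coverage_len,
                                     int(cfg.coverage_lambda)),
                             cfg.start_codon)
        fpeaks, _ = stall_peak_detect(flat, flank=25, z_min=5.0)
        flat_false += len(fpeaks)
    return {"recovery_rate": recovered / total, "n_planted": total,
            "flat_false_peaks": flat_false}


def enrichment_power(
    seed: int, n_sims: int = 50, rate_ratio: float = 2.0, n_per_group: int = 200
) -> dict:
    """Fraction of simulations with one-sided count p < 0.01 at a planted
    rate difference."""
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    n_sig = 0
    for s in seeds:
        cfg = SimulationConfig(seed=int(s), group_rate_ratio=rate_ratio,
                               n_per_group=n_per_group)
        seqs, groups, _ = generate_proteome(cfg)
        res = run_enrichment(seqs, groups, "upregulated",
                             EXAMPLE_STALLING_MOTIFS,
                             rng=np.random.default_rng(int(s)))
        if res.mann_whitney.p_greater < 0.01:
            n_sig += 1
    return {"power": n_sig / n_sims, "n_sims": n_sims}


def enrichment_null_calibration(
    seed: int, n_reps: int = 200, n_per_group: int = 200
) -> dict:
    """KS distance of the one-sided count p from uniform under equal rates."""
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    pvals = []
    for s in seeds:
        cfg = SimulationConfig(seed=int(s), group_rate_ratio=1.0,
                               n_per_group=n_per_group)
        seqs, groups, _ = generate_proteome(cfg)
        res = run_enrichment(seqs, groups, "upregulated",
                             EXAMPLE_STALLING_MOTIFS,
                             rng=np.random.default_rng(int(s)))
        pvals.append(res.mann_whitney.p_greater)
    ks = sps.kstest(pvals, "uniform").statistic
    return {"ks_statistic": float(ks), "n_reps": n_reps}


def pwm_null_max_error(seed: int, widths: tuple[int, ...] = (2, 3, 4, 5, 6),
                       per_width: int = 3) -> dict:
    """Max |DP p-value - exhaustive enumeration| over random test PWMs."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for w in widths:
        for _ in range(per_width):
            pwm = PWM(rng.dirichlet(np.ones(4) * 2.0, size=w))
            words = np.array(list(itertools.product(range(4), repeat=w)))
            lo = pwm.log_odds
            enum_scores = lo[np.arange(w)[None, :], words].sum(axis=1)
            enum_probs = pwm.background[words].prod(axis=1)
            scores, _ = pwm.score_distribution()
            probes = np.concatenate([scores, scores + 1e-6, scores - 1e-6])
            for s in probes:
                exact = float(enum_probs[enum_scores >= s - 1e-9].sum())
                err = abs(score_pvalue(pwm, float(s)) - exact)
                max_err = max(max_err, err)
    return {"max_abs_error": max_err}
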