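# Methods

This document records the statistical model behind each `riboseek`
procedure, the default parameters and their rationale, the scope of the
synthetic-data generators, and numerical choices. It makes no empirical
claims beyond what the test suite and `scripts/acceptance.py` compute.

## 1. Tissue-specificity screen (`riboseek.screen`)

**Rule.** For target tissue *T* and fold threshold *f* (default 5), gene
*g* passes when

```
min_{s in samples(T)} FPKM(g, s)  >=  f * max_{s not in samples(T)} FPKM(g, s)
```

All FPKM values are floored at 0.5 before the comparison. The floor keeps
the ratio defined and damps noise amplification near zero; with the floor
applied the denominator is always positive. The comparison is inclusive
(`>=`), so a gene exactly at the fold passes.

**Funnel.** The screen is a sequence of filters whose bookkeeping is
validated: each stage's `n_in` must equal the previous stage's `n_out`,
and `n_in = n_excluded + n_out`. Stages: specificity → annotation overlap
removal → ortholog requirement → cross-species specificity (the ortholog
must itself pass the specificity rule in the second species; a gene whose
ortholog is absent from the second panel is recorded as `absent` and
excluded). When a gene has several ortholog partners, validation in *any*
partner suffices.

## 2. Polysome association (`riboseek.polysome`)

A transcript is *associated* when its polysome-fraction level is at or
above a detection threshold (default 1.0, i.e. detectable signal in the
polysome fraction). Association strength is

```
strength = log2((polysome + c) / (free + c)),  c = 0.5
```

The pseudocount bounds the statistic when either fraction is near zero.
Fraction profiles over (free, 40S, 60S, monosome, polysome) are expressed
as percentages and compared with the total-variation distance
`TV(a, b) = (1/2) * sum_i |a_i - b_i| / 100`, which lies in [0, 1].

## 3. Localization (`riboseek.localization`)

**FISH.** Each cell contributes `100 * cyto / (cyto + nuc)` percent
cytoplasmic; the summary is the *median* across cells (robust to a few
high-count cells), with the pooled-spot percentage reported alongside.
Cells with zero spots are excluded and counted in a QC flag; fewer than
`min_cells` (default 100) usable cells is also flagged.

**Fractionation qPCR.** With amplification efficiency *E* (default 2.0
= perfect doubling), ΔCt = target Ct − reference Ct per compartment, the
cytoplasm:nucleus ratio is `r = E^(ΔCt_nuc − ΔCt_cyto)` and percent
cytoplasmic is `100 r / (1 + r)`. QC is control-based: a designated
nuclear control that measures > 50 % cytoplasmic (or a cytosolic control
< 50 %) fails the run, flagging fraction cross-contamination.

## 4. PWM scanning and conservation (`riboseek.motifs`)

**Scoring.** PWMs are probability matrices (width × 4, A/C/G/T). Windows
are scored by the sum of per-position log2-odds against the background
(default uniform). Windows containing any non-ACGT character are skipped.
Both strands are scanned; a reverse-strand hit at offset *i* of the
reverse complement maps to forward coordinates `start = L − i − w`.

**Exact null.** The null distribution of the score under the background is
computed by dynamic programming over positions:

- width ≤ 8: a sparse dictionary over attainable scores, keys rounded to
  10 decimals to merge floating-point aliases of the same sum. This is
  exact; `pwm_null_max_error` in `riboseek.experiments` measures the
  maximum deviation from brute-force enumeration of all 4^w windows.
- width > 8: scores binned at 0.01 bits, which bounds the accumulated
  score error at 0.005·w bits while keeping the table small.

The p-value of score *s* is the null probability of scores ≥ s − 1e-9; the
epsilon protects `searchsorted` from excluding the probe's own mass at
exact ties. The default scan threshold is p ≤ 1e-4, the conventional
per-window threshold for promoter scans.

**Conserved windows.** Two same-length, TSS-anchored promoter sequences
are compared by ungapped sliding-window identity (window 50 nt, threshold
70 %). Per-position match indicators are convolved with a length-50 box
kernel; runs of qualifying windows are merged into maximal spans with the
identity recomputed over the merged span. The ungapped model is
appropriate for short, anchored promoter stretches; it will miss
conservation displaced by indels (see Limitations).

**Cross-species site pairs.** Hits with the same motif name, each inside
the same conserved window, whose intervals overlap by ≥ 1 nt, form a
conserved site pair.

## 5. Dynamics and stall calling (`riboseek.dynamics`)

**Peaks and lag.** A time-course peak is the argmax of the per-timepoint
replicate means; ties resolve to the earliest timepoint (a later equal
value is not additional evidence of a later response). The translational
lag is `ribo_peak_hours − rna_peak_hours`; both series must share the
timepoint grid.

**Stall caller.** For each position *i* in a coverage track, the local
background is the window of ± `flank` (default 25 nt) positions *excluding
i itself* (including it would let a strong pile-up inflate its own
background). The statistic is

```
z_i = (count_i − median(window)) / max(MAD(window), mad_floor)
```

with `mad_floor = 1.0` so that perfectly flat or near-constant coverage
(MAD = 0) cannot produce infinite z; a flat track yields no calls.
Positions with z ≥ `z_min` (default 5) are candidate stalls; candidates
within 3 nt are merged keeping the maximum. The start-proximal ratio is
the mean coverage of the first 150 nt (50 codons) after the start codon
divided by the mean of the remainder.

## 6. Enrichment statistics (`riboseek.stalling`)

**Mann–Whitney U.** Ranks are midranks. When n + m ≤ 12 and there are no
ties, p-values are computed by exact enumeration of all C(n+m, n) group
assignments; otherwise a tie-corrected normal approximation with ±0.5
continuity correction is used. A degenerate comparison (zero variance,
e.g. all counts equal) is flagged and reported as p = 1. The identity
`U_group + U_rest = n·m` is property-tested.

**Category test.** Motif-category presence per protein forms a
2 × (K+1) contingency table. The chi-square statistic is computed after
dropping all-zero columns; when any expected cell is < 5 the p-value is
replaced by a seeded Monte-Carlo estimate using `scipy.stats.random_table`
with `p = (1 + #{stat_sim ≥ stat_obs}) / (1 + n_mc)`, `n_mc = 10000`.

**Example motif set.** `EXAMPLE_STALLING_MOTIFS` (poly-proline,
poly-lysine, acidic, arginine-rich tripeptides) is a synthetic,
non-canonical demonstration set; users should supply curated motifs for
real analyses.

## 7. Synthetic generators (`riboseek.simulate`)

All randomness flows from `SimulationConfig.seed` through
`numpy.random.default_rng([seed, substream])`, one substream per data
type, so changing one fixture does not perturb the others.

**Noise model.** Multiplicative lognormal noise expressed in log2 units:
a level μ is observed as `μ · 2^N(0, σ)` with σ = 0.3. On this scale a
planted fold-*F* gene passes the fold-*f* screen when the worst-case
noise excursion stays under `log2(F/f)`; σ is stated in the same base as
the screening rule, keeping the margin interpretable.

**Expression panel.** Tissues heart/brain/liver/kidney × 2 replicates;
400 background genes (not tissue-specific) plus 96 planted heart-specific
genes, of which 26 are annotation-free, 8 have orthologs, and 5 are
cross-species specific — the demo funnel therefore excludes 70/18/3 by
construction. The demo fixture plants fold 50: the log2 margin to the 5×
threshold is log2(10) ≈ 3.3, more than 7 noise standard deviations even
after combining min/max over 8 samples, so the planted counts are
recovered deterministically for any seed. Operating characteristics are
measured separately at the harder planted fold 10
(`experiments.screen_recovery`: 50 planted + 450 background genes × 20
seeded replicates, pooled sensitivity and false-discovery proportion).

**Other fixtures.** Polysome: five candidate profiles spanning
associated/non-associated plus controls. FISH: 100 cells, ~50 spots each,
true cytoplasmic fraction 0.6. Promoters: 2200 nt with two conserved
blocks (2 % mismatch) carrying planted motif sites. Time course:
sham/3 h/2 d/2 w/4 w with the RNA mean peaking at 2 d (48 h) and the
ribosome-footprint mean at 2 w (336 h), so the planted lag is +288 h.
Coverage: Poisson(20) over 2000 nt with 10× pile-ups planted at two
positions. Proteome: 200 proteins per group, 400 aa, background stalling-
motif rate 2 per protein, rate ratio 2 in the test group.

## 8. Numerical and implementation choices

- Exact-DP width cutoff 8 (≤ 65 536 windows) balances exactness against
  dictionary size; the binned DP above that uses 0.01-bit bins.
- Mann–Whitney exact cutoff n + m ≤ 12 (≤ 924 assignments) keeps exact
  enumeration trivially fast where the normal approximation is worst.
- Replicate seeds are derived via `SeedSequence.generate_state` reduced
  mod 2^31 so they remain valid 32-bit seeds.
- Problem sizes in the validation experiments: 20 screen replicates,
  20 coverage tracks, 50 power simulations, 200 null-calibration
  replicates, 15 PWM-null test matrices (widths 2–6 × 3).

## 9. Limitations

- The specificity rule is a deterministic threshold, not a statistical
  test; it reports no uncertainty and its operating characteristics depend
  on the assumed noise scale.
- Conserved-window detection is ungapped and anchored; indels between
  promoters shift the frame and suppress detection.
- The stall caller models only local pile-ups; broad elongation slowdowns
  and codon-level periodicity are out of scope.
- Generators use independent lognormal noise per sample; real RNA-seq
  exhibits overdispersion structure and sample correlation not modeled
  here. Generator defaults describe the synthetic study design, not any
  particular real dataset.
- The normal Mann–Whitney approximation is used whenever samples exceed
  the exact cutoff or contain ties; for very small tied samples its
  accuracy is the usual textbook caveat.
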