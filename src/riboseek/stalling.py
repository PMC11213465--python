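"""Interactome intersection and ribosome-stalling-motif enrichment statistics.

Protein interactor sets from independent pull-down designs are intersected
to find shared candidates.  Protein sequences are then scored for
occurrences of short amino-acid motifs associated with ribosome stalling
(for example poly-proline runs), organised in K categories, and a test group
of proteins (e.g. proteins upregulated during hypertrophy) is compared with
the remaining proteins two ways:

* categories: a 2 x (K+1) contingency table of how many categories each
  protein hits (0..K), tested by chi-square, with a seeded Monte-Carlo
  fallback conditioned on the table margins when expected cells are small;
* counts: total motif occurrences per protein, tested by Mann-Whitney U
  with midranks for ties — exact null by full enumeration of group
  assignments for small tie-free samples, tie-corrected normal approximation
  with continuity correction otherwise.

The catalogue of stalling motifs is user-supplied configuration; the
EXAMPLE_STALLING_MOTIFS set shipped here is a synthetic 4-category example
for testing and demonstration only, not a canonical catalogue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "InteractorSet",
    "StallingMotifSet",
    "MotifCountResult",
    "MannWhitneyResult",
    "CategoryEnrichment",
    "EnrichmentStats",
    "EXAMPLE_STALLING_MOTIFS",
    "intersect_interactomes",
    "count_stalling_motifs",
    "enrichment_categories",
    "enrichment_counts",
    "run_enrichment",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class InteractorSet:
    experiment: str
    proteins: frozenset[str]


@dataclass
class StallingMotifSet:
    """Named categories of fixed amino-acid motifs."""

    categories: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("at least one category required")
        for cat, motifs in self.categories.items():
            if not motifs:
                raise ValueError(f"category {cat!r} has no motifs")
            for m in motifs:
                if not m or any(a not in AA_ALPHABET for a in m):
                    raise ValueError(f"invalid motif {m!r} in category {cat!r}")

    @property
    def k(self) -> int:
        return len(self.categories)

    @classmethod
    def from_file(cls, path) -> "StallingMotifSet":
        """Load a YAML/JSON mapping of category -> list of motifs."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls({str(c): tuple(ms) for c, ms in data.items()})


#: synthetic example catalogue (testing/demo only; NOT a canonical motif set)
EXAMPLE_STALLING_MOTIFS = StallingMotifSet(
    {
        "poly-proline": ("PPP", "PPG"),
        "poly-lysine": ("KKK",),
        "acidic": ("DDD", "EEE", "DED"),
        "arginine-rich": ("RRR", "RKR"),
    }
)


@dataclass(frozen=True)
class MotifCountResult:
    protein_id: str
    total_occurrences: int
    categories_present: int


def intersect_interactomes(sets: list[InteractorSet]) -> set[str]:
    """Proteins shared by every interactor set (order-independent)."""
    if len(sets) < 2:
        raise ValueError("need >= 2 interactor sets")
    shared = set(sets[0].proteins)
    for s in sets[1:]:
        shared &= s.proteins
    return shared


def _count_overlapping(seq: str, motif: str) -> int:
    n, i = 0, seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


def count_stalling_motifs(
    sequence: str, motifs: StallingMotifSet, protein_id: str = ""
) -> MotifCountResult:
    """Count motif occurrences (overlapping offsets all count) per category.

    X in the sequence never matches any motif; an empty sequence yields zeros.
    """
    seq = sequence.upper()
    total = 0
    present = 0
    for cat_motifs in motifs.categories.values():
        cat_n = sum(_count_overlapping(seq, m) for m in cat_motifs)
        total += cat_n
        if cat_n:
            present += 1
    return MotifCountResult(protein_id, total, present)


# -- Mann-Whitney U ---------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u_group: float
    u_rest: float
    n_group: int
    n_rest: int
    p_less: float  # P(group stochastically smaller)
    p_greater: float  # P(group stochastically larger)
    p_two_sided: float
    method: str  # "exact" | "normal"
    z: float | None = None
    degenerate: bool = False


def enrichment_counts(
    group_totals: list[float], rest_totals: list[float]
) -> MannWhitneyResult:
    """Mann-Whitney U comparing per-protein motif totals, group vs rest.

    U is computed from midrank sums.  With n+m <= 12 and no ties the exact
    null is obtained by enumerating all C(n+m, n) group assignments;
    otherwise a tie-corrected normal approximation with continuity
    correction is used.  All-tied input is degenerate (p = 1, flagged).
    """
    x = np.asarray(group_totals, dtype=float)
    y = np.asarray(rest_totals, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r_group = ranks[:n].sum()
    u_group = r_group - n * (n + 1) / 2.0
    u_rest = n * m - u_group

    ties = np.unique(pooled, return_counts=True)[1]
    has_ties = (ties > 1).any()

    if n + m <= 12 and not has_ties:
        # exact: enumerate group assignments over the distinct ranks
        idx = range(n + m)
        count_le = count_ge = 0
        total = comb(n + m, n)
        for grp in combinations(idx, n):
            # ranks are the distinct integers 1..N under exchangeability
            u = sum(g + 1 for g in grp) - n * (n + 1) / 2.0
            if u <= u_group + 1e-9:
                count_le += 1
            if u >= u_group - 1e-9:
                count_ge += 1
        p_less = count_le / total
        p_greater = count_ge / total
        p_two = min(1.0, 2.0 * min(p_less, p_greater))
        return MannWhitneyResult(u_group, u_rest, n, m, p_less, p_greater,
                                 p_two, "exact")

    mu = n * m / 2.0
    N = n + m
    tie_term = ((ties**3 - ties).sum()) / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(u_group, u_rest, n, m, 1.0, 1.0, 1.0,
                                 "normal", z=0.0, degenerate=True)
    sd = sqrt(var)
    z_greater = (u_group - mu - 0.5) / sd
    z_less = (u_group - mu + 0.5) / sd
    p_greater = float(stats.norm.sf(z_greater))
    p_less = float(stats.norm.cdf(z_less))
    p_two = min(1.0, 2.0 * min(p_less, p_greater))
    return MannWhitneyResult(u_group, u_rest, n, m, p_less, p_greater, p_two,
                             "normal", z=z_greater)


# -- category contingency ---------------------------------------------------


@dataclass
class CategoryEnrichment:
    table: np.ndarray  # 2 x (K+1): rows group/rest, cols categories_present 0..K
    proportions: np.ndarray  # row-normalized
    chi2: float
    dof: int
    p_value: float
    method: str  # "chi2" | "monte-carlo"
    n_mc: int = 0


def _chi2_stat(table: np.ndarray) -> tuple[float, int]:
    t = table[:, table.sum(axis=0) > 0].astype(float)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    expected = np.outer(r, c) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, dof


def enrichment_categories(
    group: list[MotifCountResult],
    rest: list[MotifCountResult],
    k: int,
    rng: np.random.Generator | None = None,
    n_mc: int = 10000,
) -> CategoryEnrichment:
    """Compare the 0..K categories-present distribution, group vs rest.

    Chi-square on the 2 x (K+1) table (all-zero columns dropped for the
    statistic).  When any expected cell is below 5 the p-value is instead
    computed by seeded Monte-Carlo resampling of tables with the observed
    margins (Patefield sampling).
    """
    if not group or not rest:
        raise ValueError("both groups must be nonempty")
    table = np.zeros((2, k + 1), dtype=int)
    for r in group:
        table[0, r.categories_present] += 1
    for r in rest:
        table[1, r.categories_present] += 1
    proportions = table / table.sum(axis=1, keepdims=True)

    stat, dof = _chi2_stat(table)
    nz = table[:, table.sum(axis=0) > 0].astype(float)
    expected = np.outer(nz.sum(axis=1), nz.sum(axis=0)) / nz.sum()

    if dof == 0 or stat == 0.0:
        return CategoryEnrichment(table, proportions, stat, dof, 1.0, "chi2")

    if (expected >= 5).all():
        # standard asymptotic chi-square; cross-checks scipy's Pearson test
        p = float(stats.chi2.sf(stat, dof))
        return CategoryEnrichment(table, proportions, stat, dof, p, "chi2")

    rng = np.random.default_rng() if rng is None else rng
    dist = stats.random_table(nz.sum(axis=1), nz.sum(axis=0))
    samples = dist.rvs(n_mc, random_state=rng)
    exceed = 0
    for t in samples:
        s, _ = _chi2_stat(np.asarray(t))
        if s >= stat - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_mc)
    return CategoryEnrichment(table, proportions, stat, dof, float(p),
                              "monte-carlo", n_mc=n_mc)


# -- composition ------------------------------------------------------------


@dataclass
class EnrichmentStats:
    counts: list[MotifCountResult]
    group_ids: list[str]
    rest_ids: list[str]
    categories: CategoryEnrichment
    mann_whitney: MannWhitneyResult
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_group": len(self.group_ids),
            "n_rest": len(self.rest_ids),
            "category_table": self.categories.table.tolist(),
            "category_proportions": self.categories.proportions.tolist(),
            "chi2": self.categories.chi2,
            "chi2_dof": self.categories.dof,
            "chi2_p": self.categories.p_value,
            "chi2_method": self.categories.method,
            "u_group": self.mann_whitney.u_group,
            "u_rest": self.mann_whitney.u_rest,
            "mw_p_greater": self.mann_whitney.p_greater,
            "mw_p_less": self.mann_whitney.p_less,
            "mw_p_two_sided": self.mann_whitney.p_two_sided,
            "mw_method": self.mann_whitney.method,
            "flags": self.flags,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_enrichment(
    sequences: dict[str, str],
    groups: dict[str, str],
    test_group: str,
    motifs: StallingMotifSet,
    rng: np.random.Generator | None = None,
) -> EnrichmentStats:
    """Count stalling motifs per protein and test the group-vs-rest contrast.

    The same machinery serves both the upregulated-vs-remaining contrast and
    any named gene-set contrast: ``test_group`` selects which label forms
    the test group; all other labelled proteins form the rest.  Proteins
    labelled but absent from the sequence collection are dropped with a flag.
    """
    labels = set(groups.values())
    if test_group not in labels:
        raise ValueError(f"unknown test group {test_group!r}")
    if len(labels) < 2:
        raise ValueError("need >= 2 group labels")
    dropped = sorted(p for p in groups if p not in sequences)
    counts = {
        pid: count_stalling_motifs(sequences[pid], motifs, pid)
        for pid in groups
        if pid in sequences
    }
    group_ids = sorted(p for p, g in groups.items() if g == test_group and p in counts)
    rest_ids = sorted(p for p, g in groups.items() if g != test_group and p in counts)
    grp = [counts[p] for p in group_ids]
    rst = [counts[p] for p in rest_ids]
    cat = enrichment_categories(grp, rst, motifs.k, rng=rng)
    mw = enrichment_counts(
        [c.total_occurrences for c in grp], [c.total_occurrences for c in rst]
    )
    flags = {"dropped_proteins": dropped}
    if all(c.total_occurrences == 0 for c in counts.values()):
        flags["all_zero_counts"] = True
    return EnrichmentStats(list(counts.values()), group_ids, rest_ids, cat, mw, flags)
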