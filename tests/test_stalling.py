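"""Interactome intersection, motif counting and enrichment statistics."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from riboseek.stalling import (
    EXAMPLE_STALLING_MOTIFS,
    InteractorSet,
    MotifCountResult,
    StallingMotifSet,
    count_stalling_motifs,
    enrichment_categories,
    enrichment_counts,
    intersect_interactomes,
    run_enrichment,
)


class TestIntersection:
    def test_single_shared_protein(self):
        sets = [
            InteractorSet("a", frozenset({"A", "B", "DRG1"})),
            InteractorSet("b", frozenset({"C", "DRG1"})),
            InteractorSet("c", frozenset({"D", "DRG1", "E"})),
        ]
        assert intersect_interactomes(sets) == {"DRG1"}

    def test_disjoint_sets_empty(self):
        sets = [InteractorSet("a", frozenset({"A"})),
                InteractorSet("b", frozenset({"B"}))]
        assert intersect_interactomes(sets) == set()

    def test_idempotence(self):
        s = InteractorSet("a", frozenset({"A", "B"}))
        assert intersect_interactomes([s, s]) == {"A", "B"}

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            intersect_interactomes([InteractorSet("a", frozenset())])


class TestMotifCounting:
    def test_overlapping_occurrences(self):
        ms = StallingMotifSet({"polyP": ("PPP",)})
        r = count_stalling_motifs("APPPPK", ms)
        assert r.total_occurrences == 2 and r.categories_present == 1

    def test_two_categories(self):
        ms = StallingMotifSet({"polyP": ("PPP",), "polyK": ("KKK",)})
        r = count_stalling_motifs("PPPKKK", ms)
        assert r.total_occurrences == 2 and r.categories_present == 2

    def test_empty_sequence(self):
        r = count_stalling_motifs("", EXAMPLE_STALLING_MOTIFS)
        assert r.total_occurrences == 0 and r.categories_present == 0

    def test_x_never_matches(self):
        ms = StallingMotifSet({"polyP": ("PPP",)})
        assert count_stalling_motifs("PPXPP", ms).total_occurrences == 0

    def test_concatenation_superadditive(self, rng):
        ms = EXAMPLE_STALLING_MOTIFS
        aa = list("ACDEFGHIKLMNPQRSTVWYPPPKKK")
        for _ in range(20):
            s1 = "".join(rng.choice(aa, 30))
            s2 = "".join(rng.choice(aa, 30))
            c12 = count_stalling_motifs(s1 + s2, ms).total_occurrences
            c1 = count_stalling_motifs(s1, ms).total_occurrences
            c2 = count_stalling_motifs(s2, ms).total_occurrences
            assert c12 >= c1 + c2


def exact_mw_oracle(x, y):
    """Enumerate all C(n+m, n) assignments of pooled values to the group."""
    pooled = sorted(x + y)
    n = len(x)
    obs_u = sum(sum(1 for v in y if v < g) for g in x)
    count_le = count_ge = 0
    for grp_idx in itertools.combinations(range(len(pooled)), n):
        grp = [pooled[i] for i in grp_idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(grp_idx)]
        u = sum(sum(1 for v in rest if v < g) for g in grp)
        count_le += u <= obs_u
        count_ge += u >= obs_u
    total = comb(len(pooled), n)
    return count_le / total, count_ge / total


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = enrichment_counts([1, 2, 3], [4, 5, 6])
        assert res.u_group == 0
        assert res.method == "exact"
        assert res.p_less == pytest.approx(0.05)
        oracle_le, _ = exact_mw_oracle([1, 2, 3], [4, 5, 6])
        assert res.p_less == pytest.approx(oracle_le)

    def test_all_ties_degenerate(self):
        res = enrichment_counts([2, 2, 2], [2, 2, 2, 2])
        assert res.u_group == pytest.approx(3 * 4 / 2)
        assert res.degenerate and res.p_two_sided == 1.0

    def test_u_identity_on_random_inputs(self, rng):
        for _ in range(200):
            n, m = rng.integers(2, 30, 2)
            x = rng.poisson(3, n).tolist()
            y = rng.poisson(3, m).tolist()
            res = enrichment_counts(x, y)
            assert res.u_group + res.u_rest == pytest.approx(n * m)

    def test_exact_path_matches_enumeration_oracle(self, rng):
        """Tie-free small samples: implementation vs independent enumeration."""
        for _ in range(10):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 12 - n + 1))
            pool = rng.choice(1000, n + m, replace=False).astype(float)
            x, y = pool[:n].tolist(), pool[n:].tolist()
            res = enrichment_counts(x, y)
            assert res.method == "exact"
            le, ge = exact_mw_oracle(x, y)
            assert res.p_less == pytest.approx(le, abs=1e-12)
            assert res.p_greater == pytest.approx(ge, abs=1e-12)

    def test_exact_path_matches_scipy(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 12 - n + 1))
            pool = rng.choice(1000, n + m, replace=False).astype(float)
            x, y = pool[:n].tolist(), pool[n:].tolist()
            res = enrichment_counts(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="greater", method="exact")
            assert res.u_group == pytest.approx(ref.statistic)
            assert res.p_greater == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_path_close_to_scipy_corrected(self, rng):
        x = rng.poisson(4, 60).tolist()
        y = rng.poisson(3, 80).tolist()
        res = enrichment_counts(x, y)
        assert res.method == "normal"
        ref = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert res.p_greater == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            enrichment_counts([], [1.0])


def counts_from(cats):
    return [MotifCountResult(f"p{i}", c, c) for i, c in enumerate(cats)]


def enumerate_2x2_pvalue(table):
    """Exhaustive conditional null over all 2x2 tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def chi2(t):
        t = np.asarray(t, float)
        e = np.outer(t.sum(1), t.sum(0)) / t.sum()
        return ((t - e) ** 2 / e).sum()

    obs = chi2(table)
    p = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        t = [[aa, r1 - aa], [c1 - aa, r2 - (c1 - aa)]]
        prob = sps.hypergeom.pmf(aa, n, c1, r1)
        if chi2(t) >= obs - 1e-12:
            p += prob
    return p


class TestCategoryEnrichment:
    def test_identical_distributions_null(self):
        g = counts_from([0, 1, 2, 3] * 10)
        res = enrichment_categories(g, list(g), k=4)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2_statistic(self):
        g = counts_from([0] * 10)
        r = counts_from([1] * 10)
        res = enrichment_categories(g, r, k=1)
        assert res.chi2 == pytest.approx(20.0)

    def test_label_swap_invariance(self, rng):
        g = counts_from(rng.integers(0, 5, 40))
        r = counts_from(rng.integers(0, 5, 60))
        a = enrichment_categories(g, r, k=4, rng=np.random.default_rng(0))
        b = enrichment_categories(r, g, k=4, rng=np.random.default_rng(0))
        assert a.chi2 == pytest.approx(b.chi2)

    def test_monte_carlo_close_to_exhaustive(self):
        g = counts_from([0] * 6 + [1] * 2)
        r = counts_from([0] * 2 + [1] * 5)
        res = enrichment_categories(g, r, k=1, rng=np.random.default_rng(7),
                                    n_mc=20000)
        assert res.method == "monte-carlo"
        exact = enumerate_2x2_pvalue(np.asarray(res.table))
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enrichment_categories([], counts_from([1]), k=1)


class TestRunEnrichment:
    def test_motif_free_proteome_flagged(self):
        seqs = {f"p{i}": "AGAGAGAGAG" for i in range(10)}
        groups = {f"p{i}": ("upregulated" if i < 5 else "rest") for i in range(10)}
        res = run_enrichment(seqs, groups, "upregulated", EXAMPLE_STALLING_MOTIFS)
        assert res.flags.get("all_zero_counts")
        assert res.mann_whitney.degenerate

    def test_planted_difference_detected(self, rng):
        from riboseek.simulate import SimulationConfig, generate_proteome

        cfg = SimulationConfig(seed=5, n_per_group=100, protein_len=300)
        seqs, groups, _ = generate_proteome(cfg)
        res = run_enrichment(seqs, groups, "upregulated",
                             EXAMPLE_STALLING_MOTIFS,
                             rng=np.random.default_rng(5))
        assert res.mann_whitney.p_greater < 0.01

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            run_enrichment({"p": "PPP"}, {"p": "a"}, "b", EXAMPLE_STALLING_MOTIFS)

    def test_missing_proteins_dropped_with_flag(self):
        seqs = {"p0": "PPPP", "p1": "KKKK"}
        groups = {"p0": "g", "p1": "r", "p2": "r"}
        res = run_enrichment(seqs, groups, "g", EXAMPLE_STALLING_MOTIFS)
        assert res.flags["dropped_proteins"] == ["p2"]
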