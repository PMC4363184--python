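"""Distances, NJ trees, relative-rate test, Tajima's D, duplication z-score."""

import math

import numpy as np
import pytest

from plantmapk.core_io import AlignmentMatrix, ProteinRecord, read_newick
from plantmapk.evolution import (
    AnalysisError,
    assign_group_by_tree,
    duplication_zscore,
    nj_tree,
    overall_mean_distance,
    pdistance_matrix,
    relative_rate_test,
    tajima_d,
    tajima_d_from_counts,
)
from plantmapk.synthetic import make_polymorphism_alignment, make_triplet_alignment

AA = "ACDEFGHIKLMNPQRSTVWY"


def aln(rows: dict[str, str]) -> AlignmentMatrix:
    return AlignmentMatrix([ProteinRecord(id=k, sequence=v) for k, v in rows.items()])


# ---------------------------------------------------------------------------
# independent literal re-implementation of the Tajima 1989 statistic,
# kept deliberately separate from the package's version


def oracle_tajima_d(m, n, S, pi_per_site):
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / (i * i) for i in range(1, m))
    b1 = (m + 1.0) / (3.0 * (m - 1.0))
    b2 = 2.0 * (m * m + m + 3.0) / (9.0 * m * (m - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2.0) / (a1 * m) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    khat = pi_per_site * n
    return (khat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = pdistance_matrix(aln({"a": "TEY", "b": "TEY"}))
        assert dm.pair("a", "b") == 0.0

    def test_one_in_three(self):
        dm = pdistance_matrix(aln({"a": "TEY", "b": "TDY"}))
        assert dm.pair("a", "b") == pytest.approx(1 / 3)

    def test_matches_naive_recount(self, rng):
        rows = {f"s{i}": "".join(rng.choice(list(AA + "-"), size=60, p=[0.045] * 20 + [0.1]))
                for i in range(10)}
        alignment = aln(rows)
        dm = pdistance_matrix(alignment, coverage_cutoff=0.0)
        labels = alignment.labels
        for i in range(10):
            for j in range(i + 1, 10):
                a, b = rows[labels[i]], rows[labels[j]]
                comp = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
                expected = sum(x != y for x, y in comp) / len(comp)
                assert dm.d[i, j] == pytest.approx(expected)

    def test_cutoff_one_equals_complete_deletion(self, rng):
        rows = {"a": "TE-AC", "b": "TDYAC", "c": "TEYAC"}
        full = pdistance_matrix(aln(rows), coverage_cutoff=1.0)
        assert full.sites_used == 4  # gap column dropped entirely
        loose = pdistance_matrix(aln(rows), coverage_cutoff=0.0)
        assert loose.sites_used == 5

    def test_incomparable_pair_raises(self):
        with pytest.raises(AnalysisError, match="no comparable sites"):
            pdistance_matrix(aln({"a": "A--", "b": "-CC", "c": "ACC"}),
                             coverage_cutoff=0.0)


class TestMeanDistance:
    def test_identical_sequences(self):
        s = overall_mean_distance(aln({"a": "TEYTEY", "b": "TEYTEY"}),
                                  replicates=20, seed=0)
        assert s.mean == 0.0 and s.se == 0.0

    def test_two_sequences_mean_is_their_distance(self):
        s = overall_mean_distance(aln({"a": "TEY", "b": "TDY"}), replicates=50, seed=0)
        assert s.mean == pytest.approx(1 / 3)

    def test_se_shrinks_with_sites(self, rng):
        def random_aln(n_sites):
            return aln({f"s{i}": "".join(rng.choice(list(AA), size=n_sites))
                        for i in range(4)})

        se_small = overall_mean_distance(random_aln(100), replicates=100, seed=1).se
        se_large = overall_mean_distance(random_aln(10_000), replicates=100, seed=1).se
        assert se_large < se_small / 3  # ~ 1/sqrt(100) expected


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        import numpy as np
        from plantmapk.evolution import PDistanceMatrix

        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(PDistanceMatrix(labels=["a", "b", "c"], d=d, sites_used=0))
        tips = {t.name: t for t in tree.tips()}
        dm = tree.tip_tip_distances()
        assert dm["a", "b"] == pytest.approx(0.3, abs=1e-9)
        assert dm["a", "c"] == pytest.approx(0.5, abs=1e-9)
        assert dm["b", "c"] == pytest.approx(0.6, abs=1e-9)

    def test_additive_four_taxon_recovery(self):
        from plantmapk.evolution import PDistanceMatrix

        # ((a:2,b:3):3,(c:4,d:5):2) -> additive distances
        d = np.array([
            [0, 5, 9, 10],
            [5, 0, 10, 11],
            [9, 10, 0, 9],
            [10, 11, 9, 0],
        ], dtype=float)
        tree = nj_tree(PDistanceMatrix(labels=list("abcd"), d=d, sites_used=0))
        dm = tree.tip_tip_distances()
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                assert dm[x, y] == pytest.approx(d[i, j], abs=1e-9)
        # topology: a,b are sisters
        lca = tree.lowest_common_ancestor(["a", "b"])
        assert {t.name for t in lca.tips()} <= {"a", "b", "c", "d"}
        assert {t.name for t in lca.tips()} == {"a", "b"} or \
               {t.name for t in lca.tips()} == {"c", "d"}

    def test_ultrametric_clock_tree_recovery(self):
        from plantmapk.evolution import PDistanceMatrix

        tree0 = read_newick("((a:1,b:1):2,(c:2,d:2):1);")
        labels = ["a", "b", "c", "d"]
        dm0 = tree0.tip_tip_distances()
        d = np.array([[dm0[x, y] for y in labels] for x in labels])
        tree = nj_tree(PDistanceMatrix(labels=labels, d=d, sites_used=0))
        dm = tree.tip_tip_distances()
        for x in labels:
            for y in labels:
                assert dm[x, y] == pytest.approx(dm0[x, y], abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        from plantmapk.evolution import PDistanceMatrix

        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(AnalysisError, match="symmetric"):
            nj_tree(PDistanceMatrix(labels=list("abc"), d=d, sites_used=0))


class TestTreeGroupAssignment:
    def make_clustered_tree(self):
        # two tight reference clades far apart, one query grafted in each
        return read_newick(
            "(((d1:0.1,d2:0.1):0.05,q_d:0.1):2.0,"
            "((a1:0.1,a2:0.1):0.05,q_a:0.1):2.0,a3:2.2);"
        )

    def test_query_inherits_adjacent_clade_group(self):
        tree = self.make_clustered_tree()
        refs = {"d1": "D", "d2": "D", "a1": "A", "a2": "A", "a3": "A"}
        out = assign_group_by_tree(tree, refs, k=3)
        assert out["q_d"] == "D" and out["q_a"] == "A"

    def test_equidistant_query_unresolved(self):
        tree = read_newick("((a1:1,b1:1):1,(a2:1,b2:1):1,q:1.5);")
        out = assign_group_by_tree(tree, {"a1": "A", "b1": "B", "a2": "A", "b2": "B"},
                                   k=4)
        assert out["q"] == "unresolved"

    def test_no_references_rejected(self):
        with pytest.raises(AnalysisError):
            assign_group_by_tree(read_newick("(a:1,b:1);"), {})

    def test_six_planted_clades_recovered(self, rng):
        # six groups; within-clade distance << between-clade
        parts = []
        refs = {}
        queries = []
        for gi, g in enumerate("ABCDEF"):
            leaves = []
            for i in range(3):
                name = f"{g}ref{i}"
                refs[name] = g
                leaves.append(f"{name}:0.05")
            qname = f"{g}query"
            queries.append((qname, g))
            leaves.append(f"{qname}:0.05")
            parts.append("(" + ",".join(leaves) + f"):{3 + gi}")
        tree = read_newick("(" + ",".join(parts) + ");")
        out = assign_group_by_tree(tree, refs, k=3)
        assert all(out[q] == g for q, g in queries)


class TestRelativeRate:
    def test_worked_example_one(self, rng):
        alignment = make_triplet_alignment(157, 64, 13, 5, 70, rng)
        res = relative_rate_test(*alignment.records)
        assert (res.n_identical, res.n_divergent_all) == (157, 64)
        assert (res.mA, res.mB, res.mC) == (13, 5, 70)
        assert round(res.x2, 2) == 3.56
        assert res.p == pytest.approx(0.05935, abs=1e-4)

    def test_worked_example_two(self, rng):
        alignment = make_triplet_alignment(150, 44, 8, 0, 47, rng)
        res = relative_rate_test(*alignment.records)
        assert round(res.x2, 2) == 8.00
        assert res.p == pytest.approx(0.00468, abs=1e-4)

    def test_equal_rates_give_null(self, rng):
        alignment = make_triplet_alignment(0, 0, 6, 6, 0, rng)
        res = relative_rate_test(*alignment.records)
        assert res.x2 == 0.0 and res.p == 1.0

    def test_swap_symmetry(self, rng):
        alignment = make_triplet_alignment(30, 10, 9, 4, 7, rng)
        a, b, c = alignment.records
        r1 = relative_rate_test(a, b, c)
        r2 = relative_rate_test(b, a, c)
        assert (r1.mA, r1.mB) == (r2.mB, r2.mA)
        assert r1.x2 == r2.x2 and r1.p == r2.p

    def test_gapped_columns_eliminated(self):
        res = relative_rate_test("TE-A", "TD-A", "TE-A")
        assert res.n_identical == 2 and res.mB == 1

    def test_p_matches_scipy_chi2(self, rng):
        from scipy.stats import chi2

        alignment = make_triplet_alignment(50, 20, 11, 3, 9, rng)
        res = relative_rate_test(*alignment.records)
        assert res.p == pytest.approx(chi2.sf(res.x2, df=1), abs=1e-12)


class TestTajimaD:
    def test_table_intermediates_and_headline(self):
        res = tajima_d_from_counts(m=594, n=322, S=320, pi=0.377879)
        assert res.ps == pytest.approx(0.993789, abs=5e-7)
        assert res.theta == pytest.approx(0.142719, abs=5e-7)
        assert res.D == pytest.approx(4.904140, abs=0.01)

    def test_equilibrium_input_gives_zero(self):
        m, n, S = 10, 200, 40
        a1 = sum(1.0 / i for i in range(1, m))
        pi = (S / a1) / n  # numerator pi*n - S/a1 vanishes exactly
        res = tajima_d_from_counts(m, n, S, pi)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_no_segregating_sites_flagged_not_raised(self):
        res = tajima_d_from_counts(m=6, n=100, S=0, pi=0.0)
        assert res.D is None

    def test_alignment_equals_counts_route(self, rng):
        alignment, S, pi = make_polymorphism_alignment(8, 120, 25, 0.08, rng)
        from_aln = tajima_d(alignment, coverage_cutoff=0.95)
        from_counts = tajima_d_from_counts(8, 120, S, pi)
        assert from_aln.S == S
        assert from_aln.pi == pytest.approx(pi, abs=1e-12)
        assert from_aln.D == pytest.approx(from_counts.D, abs=1e-12)

    def test_matches_independent_oracle_on_random_alignments(self, rng):
        for _ in range(50):
            m = int(rng.integers(4, 12))
            n = int(rng.integers(30, 120))
            S = int(rng.integers(1, min(n, 30)))
            from plantmapk.synthetic import polymorphism_pi_range

            lo, hi = polymorphism_pi_range(m, S, n)
            pi = float(rng.uniform(lo, hi))
            alignment, S_real, pi_real = make_polymorphism_alignment(m, n, S, pi, rng)
            res = tajima_d(alignment, coverage_cutoff=0.95)
            assert res.D == pytest.approx(oracle_tajima_d(m, n, S_real, pi_real),
                                          abs=1e-9)

    def test_small_m_rejected(self):
        with pytest.raises(AnalysisError):
            tajima_d_from_counts(m=3, n=10, S=2, pi=0.1)


class TestDuplicationZ:
    def random_proteome(self, rng, n=6, length=250):
        return [ProteinRecord(id=f"p{i}", sequence="".join(
            rng.choice(list(AA), size=length))) for i in range(n)]

    def test_exact_copy_flagged_duplicated(self, rng):
        proteome = self.random_proteome(rng)
        copy = ProteinRecord(id="dup", sequence=proteome[0].sequence)
        res = duplication_zscore(copy, proteome + [copy], n_null=60, seed=42)
        assert res.z >= 4 and res.verdict == "duplicated"
        assert res.best_partner == "p0"

    def test_unrelated_gene_mostly_below_threshold(self, rng):
        hits = 0
        trials = 10
        for t in range(trials):
            proteome = self.random_proteome(rng, n=5, length=200)
            gene = ProteinRecord(id="g", sequence="".join(
                rng.choice(list(AA), size=200)))
            res = duplication_zscore(gene, proteome + [gene], n_null=40, seed=100 + t)
            hits += res.z < 4
        assert hits >= int(0.95 * trials) - 1  # allow one excursion at small n

    def test_singleton_proteome_rejected(self, rng):
        gene = self.random_proteome(rng, n=1)[0]
        with pytest.raises(AnalysisError):
            duplication_zscore(gene, [gene], n_null=10, seed=0)

    def test_degenerate_null_rejected(self):
        gene = ProteinRecord(id="g", sequence="AAAAAAAAAA")
        partner = ProteinRecord(id="h", sequence="AAAAAAAAAA")
        with pytest.raises(AnalysisError, match="degenerate null"):
            duplication_zscore(gene, [gene, partner], n_null=10, seed=0)
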