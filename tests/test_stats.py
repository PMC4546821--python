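"""Z-score over-representation analysis against independent oracles."""

import itertools
import math
import random

import pytest

from pathviz import (
    CriterionCounts,
    count_criterion,
    import_data,
    rank_pathways,
    write_results_tsv,
    zscore,
)
from pathviz.stats import StatisticsError


def hypergeom_mean_var(N, R, n):
    """Exact mean/variance of the hit count by direct enumeration of the
    hypergeometric pmf (math.comb only; independent of the implementation)."""
    denom = math.comb(N, n)
    mean = var = 0.0
    for r in range(max(0, n - (N - R)), min(n, R) + 1):
        p = math.comb(R, r) * math.comb(N - R, n - r) / denom
        mean += r * p
    for r in range(max(0, n - (N - R)), min(n, R) + 1):
        p = math.comb(R, r) * math.comb(N - R, n - r) / denom
        var += (r - mean) ** 2 * p
    return mean, var


class TestZScore:
    def test_zero_when_observed_equals_expected(self):
        assert zscore(CriterionCounts(N=100, R=50, n=10, r=5)) == 0.0

    def test_matches_subset_enumeration_oracle(self):
        # brute force: every 4-subset of 20 genes of which 5 are hits
        N, R, n = 20, 5, 4
        hits = set(range(R))
        counts = [len(hits & set(s)) for s in itertools.combinations(range(N), n)]
        mean = sum(counts) / len(counts)
        var = sum((c - mean) ** 2 for c in counts) / len(counts)
        expected = (3 - mean) / math.sqrt(var)
        got = zscore(CriterionCounts(N=N, R=R, n=n, r=3))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_pmf_oracle_on_small_grid(self):
        for N in (2, 5, 9, 14):
            for R in range(N + 1):
                for n in range(N + 1):
                    for r in range(max(0, n - (N - R)), min(n, R) + 1):
                        z = zscore(CriterionCounts(N=N, R=R, n=n, r=r))
                        mean, var = hypergeom_mean_var(N, R, n)
                        if var <= 1e-12:
                            assert math.isnan(z)
                        else:
                            assert z == pytest.approx((r - mean) / math.sqrt(var), rel=1e-9)

    def test_undefined_cases(self):
        assert math.isnan(zscore(CriterionCounts(N=10, R=5, n=0, r=0)))
        assert math.isnan(zscore(CriterionCounts(N=10, R=0, n=3, r=0)))
        assert math.isnan(zscore(CriterionCounts(N=10, R=10, n=3, r=3)))
        assert math.isnan(zscore(CriterionCounts(N=10, R=5, n=10, r=5)))

    def test_sign_property(self):
        rng = random.Random(77)
        for _ in range(200):
            N = rng.randrange(2, 200)
            R = rng.randrange(1, N)
            n = rng.randrange(1, N)
            r = rng.randrange(max(0, n - (N - R)), min(n, R) + 1)
            z = zscore(CriterionCounts(N=N, R=R, n=n, r=r))
            if math.isnan(z):
                continue
            expected_r = n * R / N
            assert (z > 0) == (r > expected_r)
            assert (z == 0) == (r == expected_r)

    def test_invalid_counts_rejected(self):
        with pytest.raises(StatisticsError):
            CriterionCounts(N=10, R=5, n=12, r=3)
        with pytest.raises(StatisticsError):
            CriterionCounts(N=10, R=2, n=5, r=4)


class TestCounting:
    def test_counts_match_generator_truth(self, bundle, bundle_table, bundle_store, bundle_docs):
        for doc, _src in bundle_docs:
            c = count_criterion(doc, bundle_table, bundle_store, bundle.truth["criterion"])
            truth = bundle.truth["pathways"][doc.name]
            assert (c.N, c.R, c.n, c.r) == (
                bundle.truth["N"],
                bundle.truth["R"],
                truth["n"],
                truth["r"],
            )

    def test_empty_pathway(self, bundle, bundle_table, bundle_store):
        from pathviz import create_pathway

        c = count_criterion(
            create_pathway("empty"), bundle_table, bundle_store,
            bundle.truth["criterion"], unify_code="En",
        )
        assert (c.n, c.r) == (0, 0)
        assert c.N == bundle.truth["N"]

    def test_tautology_counts_everything(self, bundle_table, bundle_store, bundle_docs):
        doc, _ = bundle_docs[0]
        c = count_criterion(doc, bundle_table, bundle_store, "1 = 1")
        assert c.R == c.N and c.r == c.n

    def test_absent_criterion_column_rejected(self, bundle_table, bundle_store, bundle_docs):
        with pytest.raises(StatisticsError):
            count_criterion(bundle_docs[0][0], bundle_table, bundle_store, "[nope] < 1")


class TestRanking:
    def test_enriched_pathway_ranks_first(self, bundle, bundle_table, bundle_store, bundle_docs):
        ranked = rank_pathways(bundle_docs, bundle_table, bundle_store, bundle.truth["criterion"])
        assert ranked.scores[0].name == bundle.truth["enriched_pathway"]
        assert ranked.scores[0].z > 0
        zs = [s.z for s in ranked.scores if s.z_defined]
        assert zs == sorted(zs, reverse=True)

    def test_identical_pathways_tie_break_by_name(self, bundle_table, bundle_store, bundle_docs):
        import copy

        doc_b = copy.deepcopy(bundle_docs[0][0])
        doc_b.name = "A-clone"
        ranked = rank_pathways(
            [(bundle_docs[0][0], "x"), (doc_b, "y")],
            bundle_table, bundle_store, "[P.Value_d1] < 0.05",
        )
        assert ranked.scores[0].z == ranked.scores[1].z
        assert [s.name for s in ranked.scores] == sorted(s.name for s in ranked.scores)

    def test_singleton_collection(self, bundle_table, bundle_store, bundle_docs):
        ranked = rank_pathways(bundle_docs[:1], bundle_table, bundle_store, "[P.Value_d1] < 0.05")
        assert len(ranked.scores) == 1

    def test_empty_collection_rejected(self, bundle_table, bundle_store):
        with pytest.raises(StatisticsError):
            rank_pathways([], bundle_table, bundle_store, "[P.Value_d1] < 0.05")

    def test_permutation_invariance(self, tmp_path, bundle, bundle_store, bundle_docs):
        lines = bundle.data_path.read_text().splitlines()
        header, rows = lines[0], lines[1:]
        random.Random(3).shuffle(rows)
        shuffled = tmp_path / "shuffled.tsv"
        shuffled.write_text("\n".join([header] + rows) + "\n")
        t1 = import_data(bundle.data_path, "GeneID", "SystemCode")
        t2 = import_data(shuffled, "GeneID", "SystemCode")
        r1 = rank_pathways(bundle_docs, t1, bundle_store, bundle.truth["criterion"])
        r2 = rank_pathways(bundle_docs, t2, bundle_store, bundle.truth["criterion"])
        assert [(s.name, s.z) for s in r1.scores] == [(s.name, s.z) for s in r2.scores]

    def test_results_tsv_stable_columns(self, tmp_path, bundle, bundle_table, bundle_store, bundle_docs):
        ranked = rank_pathways(bundle_docs, bundle_table, bundle_store, bundle.truth["criterion"])
        out = tmp_path / "results.tsv"
        write_results_tsv(ranked, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "pathway\tfile\tn\tr\tN\tR\tz"
        assert len(lines) == 1 + len(bundle_docs)
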