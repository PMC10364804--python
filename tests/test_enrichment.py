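"""The Poisson enrichment statistic, exclusion rule, corrections, reports."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import genecontext as gc
from conftest import make_neighborhood


class TestExpectedLambda:
    def test_formula(self):
        assert gc.expected_lambda(10, 10.0, 50, 10_000) == pytest.approx(0.5)

    def test_absent_domain_has_zero_expectation(self):
        assert gc.expected_lambda(5, 8.0, 0, 1000) == 0.0

    def test_whole_database_saturation(self):
        assert gc.expected_lambda(1, 1.0, 1000, 1000) == 1.0

    @pytest.mark.parametrize(
        "args", [(1, 1.0, 5, 0), (0, 1.0, 1, 10), (1, 1.0, 11, 10), (1, 0.0, 1, 10)]
    )
    def test_precondition_violations(self, args):
        with pytest.raises(gc.ParameterError):
            gc.expected_lambda(*args)


class TestPoissonPscore:
    def test_zero_occurrences_always_certain(self):
        for lam in (0.0, 0.3, 7.0, 1e3):
            assert gc.poisson_pscore(0, lam) == 1.0

    def test_closed_forms(self):
        assert gc.poisson_pscore(1, 0.5) == pytest.approx(1 - math.exp(-0.5), abs=1e-15)
        assert gc.poisson_pscore(2, 1.0) == pytest.approx(1 - 2 * math.exp(-1), abs=1e-15)

    def test_finite_at_extreme_arguments(self):
        assert math.isfinite(gc.poisson_pscore(10_000, 1e3))
        p = gc.poisson_pscore(2_000, 1e3)
        assert 0 < p < 1e-100  # far tail resolved, no cancellation to 0 or negative

    def test_negative_inputs_rejected(self):
        with pytest.raises(gc.ParameterError):
            gc.poisson_pscore(-1, 1.0)
        with pytest.raises(gc.ParameterError):
            gc.poisson_pscore(1, -0.5)

    @given(st.integers(0, 200), st.floats(0.01, 100))
    def test_monotone_decreasing_in_k(self, k, lam):
        assert gc.poisson_pscore(k + 1, lam) <= gc.poisson_pscore(k, lam) + 1e-15

    @given(st.integers(0, 200), st.floats(0.01, 50), st.floats(0.01, 50))
    def test_monotone_increasing_in_lambda(self, k, lam_a, lam_b):
        lo, hi = sorted([lam_a, lam_b])
        assert gc.poisson_pscore(k, lo) <= gc.poisson_pscore(k, hi) + 1e-15


class TestCounting:
    def test_counts_per_gene_presence_summed_over_neighborhoods(self):
        nbs = [
            make_neighborhood("n1", [], counts={"PF00009": 3, "PF00002": 1}),
            make_neighborhood("n2", [], counts={"PF00002": 2}),
        ]
        k, presence = gc.count_in_neighborhoods(nbs, "PF00009")
        assert (k, presence) == (3, 0.5)

    def test_absent_domain(self):
        nbs = [make_neighborhood("n1", ["PF00001"])]
        assert gc.count_in_neighborhoods(nbs, "PF00042") == (0, 0.0)

    def test_ubiquitous_domain(self):
        nbs = [make_neighborhood(f"n{i}", ["PF00007"]) for i in range(4)]
        assert gc.count_in_neighborhoods(nbs, "PF00007") == (4, 1.0)


class TestCorrections:
    def test_bonferroni_multiplies_by_m(self):
        assert gc.correct_pvalues([0.01, 0.02, 0.03], "bonferroni") == pytest.approx(
            [0.03, 0.06, 0.09]
        )

    def test_benjamini_hochberg_step_up(self):
        assert gc.correct_pvalues([0.01, 0.02, 0.03], "benjamini_hochberg") == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_none_is_identity(self):
        p = [0.4, 0.01, 1.0]
        assert gc.correct_pvalues(p, "none") == p

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(gc.ParameterError):
            gc.correct_pvalues([0.1, 1.5], "bonferroni")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_hand_coded_oracles(self, p):
        m = len(p)
        bonf = [min(1.0, m * x) for x in p]
        order = np.argsort(p, kind="stable")
        bh = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            val = min(prev, p[i] * m / (rank_from_top + 1))
            bh[i] = val
            prev = val
        assert gc.correct_pvalues(p, "bonferroni") == pytest.approx(bonf, abs=1e-12)
        assert gc.correct_pvalues(p, "benjamini_hochberg") == pytest.approx(
            list(bh), abs=1e-12
        )


class TestEnrich:
    def test_planted_partner_is_top_hit(self, small_planted_db):
        spec, db, _ = small_planted_db
        res = gc.resolve_query(db, gc.QuerySpec(pfam_id=spec.query_domain))
        nbs = gc.extract_all(db, res.genes)
        rows = gc.enrich(db, nbs, query_domain=spec.query_domain)
        partner = spec.planted_partners[0][0]
        non_query = [r for r in rows if not r.is_query]
        assert non_query and non_query[0].domain == partner
        assert non_query[0].p_score < 1e-5
        assert non_query[0].presence_fraction >= 0.5

    def test_query_row_flagged_and_saturated(self, small_planted_db):
        spec, db, _ = small_planted_db
        res = gc.resolve_query(db, gc.QuerySpec(pfam_id=spec.query_domain))
        nbs = gc.extract_all(db, res.genes)
        rows = gc.enrich(db, nbs, query_domain=spec.query_domain)
        q = [r for r in rows if r.is_query]
        assert len(q) == 1 and q[0].domain == spec.query_domain
        assert q[0].k >= len(nbs)
        assert q[0].presence_fraction == 1.0

    def test_underrepresented_domains_excluded(self, small_planted_db):
        spec, db, _ = small_planted_db
        res = gc.resolve_query(db, gc.QuerySpec(pfam_id=spec.query_domain))
        nbs = gc.extract_all(db, res.genes)
        stats = gc.compute_candidate_stats(db, nbs, query_domain=spec.query_domain)
        assert (stats["k"] < stats["lam"]).any(), "fixture must offer excludable domains"
        loose = gc.EnrichmentParams(pscore_cutoff=1.0, min_presence_fraction=0.0)
        retained = {r.domain for r in gc.enrich(db, nbs, loose)}
        for r in stats.itertuples(index=False):
            assert (r.domain in retained) == (r.k >= r.lam)

    def test_bonferroni_never_below_raw_pscore(self, small_planted_db):
        spec, db, _ = small_planted_db
        res = gc.resolve_query(db, gc.QuerySpec(pfam_id=spec.query_domain))
        nbs = gc.extract_all(db, res.genes)
        params = gc.EnrichmentParams(
            correction="bonferroni", pscore_cutoff=1.0, min_presence_fraction=0.0
        )
        rows = gc.enrich(db, nbs, params)
        assert rows
        for r in rows:
            assert r.p_corrected >= r.p_score - 1e-18

    def test_output_sorted_with_deterministic_ties(self, small_planted_db):
        spec, db, _ = small_planted_db
        res = gc.resolve_query(db, gc.QuerySpec(pfam_id=spec.query_domain))
        nbs = gc.extract_all(db, res.genes)
        rows = gc.enrich(db, nbs, gc.EnrichmentParams(pscore_cutoff=1.0, min_presence_fraction=0.0))
        keys = [(r.p_score, -r.k, r.domain) for r in rows]
        assert keys == sorted(keys)

    def test_pipeline_deterministic(self, small_planted_db):
        spec, db, _ = small_planted_db
        res = gc.resolve_query(db, gc.QuerySpec(pfam_id=spec.query_domain))
        nbs = gc.extract_all(db, res.genes)
        frame_a = gc.rows_to_frame(gc.enrich(db, nbs, query_domain=spec.query_domain))
        frame_b = gc.rows_to_frame(gc.enrich(db, nbs, query_domain=spec.query_domain))
        assert frame_a.to_csv() == frame_b.to_csv()


class TestTaxonomyReport:
    def test_per_gene_lineages_and_counts(self, toy_db):
        genes, _ = toy_db.genes_with_domain("PF00001")
        per_gene, per_rank = gc.taxonomy_report(toy_db, genes)
        assert list(per_gene["gene_id"]) == ["g1", "g3"]
        assert set(per_gene["genus"]) == {"Escherichia", "Salmonella"}
        genus_counts = per_rank[per_rank["rank"] == "genus"]
        assert dict(zip(genus_counts["name"], genus_counts["n_genomes"])) == {
            "Escherichia": 1,
            "Salmonella": 1,
        }
        # per-rank counts sum to the number of distinct query genomes
        for rank in ("phylum", "genus"):
            total = per_rank[per_rank["rank"] == rank]["n_genomes"].sum()
            assert total == per_gene["genome_id"].nunique()

    def test_taxonomy_less_genome_uses_sentinel(self, toy_paths):
        db = gc.load_database(toy_paths[0])  # no taxonomy file at all
        genes, _ = db.genes_with_domain("PF00001")
        per_gene, _ = gc.taxonomy_report(db, genes)
        assert set(per_gene["genus"]) == {gc.MISSING_RANK}
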