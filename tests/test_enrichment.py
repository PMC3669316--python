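import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathflux.enrichment import (
    RankedList,
    _es_from_hit_ranks,
    _scan_es,
    build_catalog,
    enrichment_score,
    heatmap_table,
    permutation_significance,
    snr_rank,
)
from pathflux.io import ExpressionStudy
from pathflux.simulate import SimulationConfig, simulate_expression


def brute_force_es(scores, is_hit, p):
    """Independent oracle: explicit walk over every prefix sum.

    Positive extremum wins an exact magnitude tie, matching the documented
    convention.
    """
    n = len(scores)
    n_hit = sum(is_hit)
    w = [abs(s) ** p if h else 0.0 for s, h in zip(scores, is_hit)]
    total = sum(w)
    if total == 0:
        w = [1.0 if h else 0.0 for h in is_hit]
        total = float(n_hit)
    run = 0.0
    best_top, best_bot = -np.inf, np.inf
    for i in range(n):
        run += w[i] / total if is_hit[i] else -1.0 / (n - n_hit)
        best_top = max(best_top, run)
        best_bot = min(best_bot, run)
    return best_top if best_top >= -best_bot - 1e-12 else best_bot


class TestSnrRank:
    def test_identical_classes_score_zero(self, small_study):
        scores, _ = snr_rank(small_study)
        assert scores["PS01"] == 0.0

    def test_sd_floor_hand_example(self, small_study):
        # treat {2,2,2}, ctrl {1,1,1}: raw sds 0 floored to 0.2*|mu| -> 1/(0.4+0.2)
        scores, audit = snr_rank(small_study)
        assert scores["PS00"] == pytest.approx(1.0 / 0.6)
        assert audit.loc["PS00", "sd_treat"] == pytest.approx(0.4)
        assert audit.loc["PS00", "sd_ctrl"] == pytest.approx(0.2)

    def test_label_swap_negates_every_score(self, small_study):
        fwd, _ = snr_rank(small_study)
        rev, _ = snr_rank(small_study.with_swapped_labels())
        assert np.array_equal(fwd.to_numpy(), -rev.to_numpy())

    def test_single_sample_class_is_error(self):
        values = pd.DataFrame(np.arange(8.0).reshape(2, 4), columns=list("abcd"))
        labels = pd.Series(["T", "C", "C", "C"], index=list("abcd"))
        study = ExpressionStudy.__new__(ExpressionStudy)  # bypass 2-per-class check
        study.values, study.labels, study.classes = values, labels, ("T", "C")
        with pytest.raises(ValueError, match="need >= 2"):
            snr_rank(study)

    def test_ranked_list_strictly_ordered_with_id_tiebreak(self):
        ranked = RankedList.from_scores({"b": 1.0, "a": 1.0, "c": 2.0})
        assert ranked.ids == ("c", "a", "b")


class TestBuildCatalog:
    NATIVE = {"A": {"x", "y"}, "B": {"y", "z"}, "C": {"z", "w"}}

    def test_merge_is_set_union(self):
        cat = build_catalog(self.NATIVE, merges={"AB": ["A", "B"]})
        assert cat.sets["AB"] == frozenset({"x", "y", "z"})
        assert cat.flags["AB"] == "merged"
        assert cat.provenance["AB"] == ("A", "B")

    def test_single_member_merge_is_identity(self):
        cat = build_catalog(self.NATIVE, merges={"justA": ["A"]})
        assert cat.sets["justA"] == cat.sets["A"]

    def test_inclusion_exclusion_on_three_pathway_fixture(self):
        # two shared members (y in A&B, z in B&C) drop out of the union size
        cat = build_catalog(self.NATIVE, all_union="ALL")
        total = sum(len(s) for s in self.NATIVE.values())
        assert len(cat.sets["ALL"]) == total - 2
        assert cat.sets["ALL"] == cat.native_union()

    def test_unknown_merge_member_named_in_error(self):
        with pytest.raises(ValueError, match="NOPE"):
            build_catalog(self.NATIVE, merges={"bad": ["A", "NOPE"]})


class TestEnrichmentScore:
    def _ranked(self, scores):
        return RankedList.from_scores({f"e{i}": s for i, s in enumerate(scores)})

    def test_singleton_at_top_unweighted_is_plus_one(self):
        ranked = self._ranked([4.0, 3.0, 2.0, 1.0])
        es, profile, edge = enrichment_score(ranked, {"e0"}, p=0.0)
        assert es == pytest.approx(1.0)
        assert edge == ("e0",)

    def test_singleton_at_bottom_unweighted_is_minus_one(self):
        ranked = self._ranked([4.0, 3.0, 2.0, 1.0])
        es, profile, edge = enrichment_score(ranked, {"e3"}, p=0.0)
        assert es == pytest.approx(-1.0)
        assert edge == ("e3",)

    def test_profile_ends_at_zero(self):
        rng = np.random.default_rng(3)
        ranked = self._ranked(sorted(rng.normal(size=30), reverse=True))
        _, profile, _ = enrichment_score(ranked, {"e2", "e11", "e29"}, p=1.0)
        assert profile[-1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_set_is_error(self):
        ranked = self._ranked([2.0, 1.0])
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked, {"nope"}, p=1.0)

    def test_full_list_set_is_error(self):
        ranked = self._ranked([2.0, 1.0])
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, {"e0", "e1"}, p=1.0)

    def test_leading_edge_members_precede_extremum(self):
        rng = np.random.default_rng(9)
        scores = sorted(rng.normal(size=40), reverse=True)
        ranked = self._ranked(scores)
        members = {"e0", "e3", "e5", "e30"}
        es, profile, edge = enrichment_score(ranked, members, p=1.0)
        assert es > 0
        assert set(edge) <= members
        assert "e30" not in edge

    @settings(max_examples=500, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        p=st.sampled_from([0.0, 1.0, 2.0]),
        k=st.integers(1, 10),
        n=st.integers(5, 60),
    )
    def test_scan_matches_bruteforce(self, seed, p, k, n):
        k = min(k, n - 1)
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        is_hit = np.zeros(n, dtype=bool)
        is_hit[rng.choice(n, size=k, replace=False)] = True
        es, _, _ = _scan_es(scores, is_hit, p)
        assert es == pytest.approx(brute_force_es(scores, is_hit, p), abs=1e-12)
        assert -1.0 <= es <= 1.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), p=st.sampled_from([0.0, 1.0]), k=st.integers(1, 8))
    def test_hit_rank_formula_matches_scan(self, seed, p, k):
        n = 40
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        pos = np.sort(rng.choice(n, size=k, replace=False))
        is_hit = np.zeros(n, dtype=bool)
        is_hit[pos] = True
        es_scan, _, _ = _scan_es(scores, is_hit, p)
        es_fast = _es_from_hit_ranks(
            pos[:, None].astype(float), (np.abs(scores[pos]) ** p)[:, None], n
        )
        assert es_fast[0] == pytest.approx(es_scan, abs=1e-12)


@pytest.fixture(scope="module")
def planted_run():
    from pathflux.simulate import PlantedEffect

    cfg = SimulationConfig(
        seed=11, n_genes=600, n_pathways=12, pathway_size=12, n_samples_per_class=4,
        planted_pathways=(PlantedEffect("PATHWAY_003", 2.0, 1),),
    )
    study, emap, catalog, _ = simulate_expression(cfg)
    run = permutation_significance(study, emap, catalog, n_perm=200, seed=5)
    return study, emap, catalog, run


class TestPermutationSignificance:
    def test_result_contracts(self, planted_run):
        _, _, _, run = planted_run
        for r in run.results:
            assert 0.0 < r.p <= 1.0
            assert 0.0 <= r.q <= 1.0
            assert -1.0 <= r.es <= 1.0
            if np.isfinite(r.nes) and r.es != 0:
                assert np.sign(r.nes) == np.sign(r.es)
        nes = [r.nes for r in run.results]
        assert nes == sorted(nes, reverse=True)

    def test_q_monotone_within_sign_stratum(self, planted_run):
        _, _, _, run = planted_run
        for sign in (1, -1):
            stratum = sorted(
                (r for r in run.results if np.isfinite(r.nes) and np.sign(r.nes) == sign),
                key=lambda r: -abs(r.nes),
            )
            qs = [r.q for r in stratum]
            assert qs == sorted(qs)

    def test_planted_pathway_is_most_enriched(self, planted_run):
        _, _, _, run = planted_run
        top = max(run.results, key=lambda r: abs(r.nes))
        assert top.pathway == "PATHWAY_003"
        assert top.p == min(r.p for r in run.results)

    def test_small_classes_fall_back_to_set_scheme(self):
        cfg = SimulationConfig(seed=2, n_genes=300, n_pathways=8, pathway_size=10,
                               n_samples_per_class=3)
        study, emap, catalog, _ = simulate_expression(cfg)
        run = permutation_significance(study, emap, catalog, scheme="phenotype",
                                       n_perm=100, seed=0)
        assert run.metadata["scheme"] == "set"
        forced = permutation_significance(study, emap, catalog, scheme="phenotype",
                                          n_perm=100, seed=0, allow_small_phenotype=True)
        assert forced.metadata["scheme"] == "phenotype"

    def test_label_swap_negates_es_exactly(self, planted_run):
        study, emap, catalog, run = planted_run
        swapped = permutation_significance(
            study.with_swapped_labels(), emap, catalog, n_perm=200, seed=5
        )
        fwd = {r.pathway: r.es for r in run.results}
        rev = {r.pathway: r.es for r in swapped.results}
        assert set(fwd) == set(rev)
        for name in fwd:
            assert rev[name] == pytest.approx(-fwd[name], abs=1e-12)

    def test_too_few_permutations_rejected(self, planted_run):
        study, emap, catalog, _ = planted_run
        with pytest.raises(ValueError, match="n_perm"):
            permutation_significance(study, emap, catalog, n_perm=50)

    def test_size_filters_recorded_as_skips(self, planted_run):
        from pathflux.enrichment import PathwayCatalog

        study, emap, catalog, _ = planted_run
        tiny = frozenset(list(catalog.sets["PATHWAY_001"])[:3])
        mixed = PathwayCatalog(sets={**catalog.sets, "TINY": tiny})
        run = permutation_significance(study, emap, mixed, n_perm=100, seed=1)
        assert "TINY" in run.skipped and "min_size" in run.skipped["TINY"]
        assert all(r.pathway != "TINY" for r in run.results)
        with pytest.raises(ValueError, match="no pathway passed"):
            permutation_significance(study, emap, catalog, n_perm=100, seed=1, min_size=13)


class TestHeatmapTable:
    def test_rows_sorted_and_provenance_filled(self, planted_run):
        study, emap, catalog, _ = planted_run
        table = heatmap_table(study, emap, catalog, "PATHWAY_003")
        assert list(table.columns) == ["ec", "snr", "probeset", "gene_symbol"]
        assert (table["snr"].to_numpy()[:-1] >= table["snr"].to_numpy()[1:]).all()
        assert (table["probeset"] != "").all()
        assert (table["gene_symbol"] != "").all()

    def test_sort_matches_independent_full_sort(self, planted_run):
        from pathflux.annotation import collapse_scores, resolve_enzymes

        study, emap, catalog, _ = planted_run
        table = heatmap_table(study, emap, catalog, "PATHWAY_003")
        scores, _ = snr_rank(study)
        mapping, _ = resolve_enzymes(emap, study.values.index)
        members = catalog.sets["PATHWAY_003"]
        sub = {ps: frozenset(e for e in ecs if e in members) for ps, ecs in mapping.items()}
        collapsed = collapse_scores(scores.to_dict(), {k: v for k, v in sub.items() if v}, "max_abs")
        oracle = sorted(collapsed.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        assert list(table["ec"]) == [ec for ec, _ in oracle]

    def test_max_abs_rule_on_isozyme_pair(self, tiny_emap):
        # isozymes GENE_A/GENE_B share one EC; scores +0.3 and -1.1 -> -1.1
        from pathflux.annotation import collapse_scores

        mapping = {"PS_A1": frozenset({"2.7.1.1"}), "PS_B1": frozenset({"2.7.1.1"})}
        out = collapse_scores({"PS_A1": 0.3, "PS_B1": -1.1}, mapping, "max_abs")
        assert out.scores["2.7.1.1"] == -1.1

    def test_unknown_pathway_is_keyerror(self, planted_run):
        study, emap, catalog, _ = planted_run
        with pytest.raises(KeyError):
            heatmap_table(study, emap, catalog, "NOT_A_PATHWAY")
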