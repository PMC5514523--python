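"""Leave-one-out drivers, AUC estimators, baselines and stratification."""

import numpy as np
import pytest

from signprop import (
    AssociationSet,
    GeneNetwork,
    Ontology,
    PredictionRecord,
    PropagationConfig,
    SignGeneSet,
    SignPanel,
    auc_from_ranks,
    best_sign_upper_bound,
    build_sign_gene_sets,
    direct_oligogenic_predictions,
    filter_censored,
    fpr_at_rank,
    loo_disease_predictions,
    loo_sign_predictions,
    propagate_annotations,
    random_baseline,
    restrict_to_network,
    select_panel,
    stratify,
    summarize,
    topk_curve,
)
from signprop.evaluate import read_records, write_records
from signprop.io import DiseaseMeta

from oracles import trapezoid_roc_auc


def _rec(rank, m, unit="S", gene="g", censored=False, kind="sign", ctx=(), method="rwr"):
    return PredictionRecord(
        unit=unit, unit_kind=kind, test_gene=gene, method=method, rank=rank,
        censored=censored, M=m, seed_size=0, disease_context=frozenset(ctx),
    )


def _panel(genes_by_term, diseases=None):
    sets = {}
    for t, gs in genes_by_term.items():
        sets[t] = SignGeneSet(
            term=t,
            genes=set(gs),
            source_diseases={g: set(diseases.get(g, {"D"})) if diseases else {"D"} for g in gs},
        )
    return SignPanel(sets=sets, min_genes=2)


# ---------------------------------------------------------------------------
# AUC / top-k / FPR


class TestAucFromRanks:
    def test_perfect_and_worst_predictions(self):
        assert auc_from_ranks([_rec(1, 100)]) == 1.0
        assert auc_from_ranks([_rec(100, 100)]) == 0.0

    def test_two_extremes_average_to_half(self):
        assert auc_from_ranks([_rec(1, 50), _rec(50, 50)]) == 0.5

    def test_matches_trapezoid_roc_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            pools = rng.integers(5, 10_000, size=n)
            ranks = [int(rng.integers(1, m + 1)) for m in pools]
            records = [_rec(r, int(m)) for r, m in zip(ranks, pools)]
            want = trapezoid_roc_auc(list(zip(ranks, (int(m) for m in pools))))
            assert auc_from_ranks(records) == pytest.approx(want, abs=1e-12)

    def test_rejects_empty_censored_and_degenerate_pools(self):
        with pytest.raises(ValueError):
            auc_from_ranks([])
        with pytest.raises(ValueError):
            auc_from_ranks([_rec(1, 100, censored=True)])
        with pytest.raises(ValueError):
            auc_from_ranks([_rec(1, 1)])

    def test_filter_censored_counts(self):
        records = [_rec(1, 10), _rec(5, 10, censored=True)]
        kept, n = filter_censored(records)
        assert len(kept) == 1 and n == 1


class TestTopkCurve:
    def test_counting_within_threshold(self):
        records = [_rec(1, 5000), _rec(5, 5000), _rec(2000, 5000)]
        curve = topk_curve(records, k_max=100)
        assert curve[100] == pytest.approx(2 / 3)
        assert curve[1] == pytest.approx(1 / 3)

    def test_all_censored_is_flat_zero(self):
        records = [_rec(10, 100, censored=True)] * 3
        curve = topk_curve(records, k_max=50)
        assert set(curve.values()) == {0.0}

    def test_censored_records_only_enter_denominator(self):
        base = [_rec(1, 100), _rec(2, 100)]
        with_cens = base + [_rec(100, 100, censored=True)]
        assert topk_curve(base, 10)[10] == pytest.approx(1.0)
        assert topk_curve(with_cens, 10)[10] == pytest.approx(2 / 3)

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(1)
        records = [_rec(int(r), 2000) for r in rng.integers(1, 2000, size=200)]
        curve = topk_curve(records, k_max=500)
        vals = [curve[k] for k in sorted(curve)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_kmax_rejected(self):
        with pytest.raises(ValueError):
            topk_curve([_rec(1, 10)], k_max=0)


class TestFprAtRank:
    def test_values(self):
        assert fpr_at_rank(100, 13435) == pytest.approx(0.00744, abs=5e-5)
        assert fpr_at_rank(5, 5) == 1.0
        assert fpr_at_rank(1, 2) == 0.5

    def test_threshold_beyond_pool_rejected(self):
        with pytest.raises(ValueError):
            fpr_at_rank(6, 5)


# ---------------------------------------------------------------------------
# Leave-one-out drivers


class TestLooSignPredictions:
    def test_one_record_per_pair_with_full_seed(self, small_dataset):
        panel = _panel({"S": sorted(small_dataset.network.nodes)[:25]})
        records = loo_sign_predictions(panel, small_dataset.network)
        assert len(records) == 25
        assert all(r.seed_size == 24 for r in records)
        assert all(r.M == small_dataset.network.n_nodes - 24 for r in records)

    def test_disjoint_sets_and_shared_genes_count_independently(self, small_dataset):
        nodes = sorted(small_dataset.network.nodes)
        panel = _panel({"S1": nodes[:3], "S2": nodes[3:6]})
        assert len(loo_sign_predictions(panel, small_dataset.network)) == 6
        overlap = _panel({"S1": nodes[:3], "S2": nodes[2:5]})
        records = loo_sign_predictions(overlap, small_dataset.network)
        assert len(records) == 6
        assert sum(1 for r in records if r.test_gene == nodes[2]) == 2

    def test_diamond_ranks_are_iterations_with_censoring(self, small_dataset):
        nodes = sorted(small_dataset.network.nodes)
        panel = _panel({"S": nodes[:5]})
        records = loo_sign_predictions(
            panel, small_dataset.network, method="diamond", diamond_max_iter=5
        )
        assert len(records) == 5
        for r in records:
            assert r.censored or r.rank <= 5

    def test_rwr_and_diamond_share_pair_keys(self, small_dataset):
        nodes = sorted(small_dataset.network.nodes)
        panel = _panel({"S": nodes[:4]})
        r1 = loo_sign_predictions(panel, small_dataset.network, method="rwr")
        r2 = loo_sign_predictions(
            panel, small_dataset.network, method="diamond", diamond_max_iter=3
        )
        assert {(r.unit, r.test_gene) for r in r1} == {(r.unit, r.test_gene) for r in r2}

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            loo_sign_predictions(_panel({"S": ["a", "b"]}), small_dataset.network, method="pagerank")


class TestLooDiseasePredictions:
    def _world(self):
        # net: D1 = {g1, g2}; D2 = {g2, g3}; D3 = {g4} shares sign T2 with D2
        net = GeneNetwork.from_edges(
            [("g1", "g2"), ("g2", "g3"), ("g3", "g4"), ("g4", "g5"), ("g5", "g1")]
        )
        onto = Ontology({"root": set(), "T1": {"root"}, "T2": {"root"}})
        assoc = AssociationSet(
            disease_genes={"D1": {"g1", "g2"}, "D2": {"g2", "g3"}, "D3": {"g4"}},
            disease_signs={
                "D1": {"T1": "typical"},
                "D2": {"T1": "typical", "T2": "typical"},
                "D3": {"T2": "typical"},
            },
        )
        expanded = propagate_annotations(assoc, onto)
        return net, onto, assoc, expanded

    def test_seed_weight_is_max_inverse_term_size(self):
        net, onto, assoc, expanded = self._world()
        # terms (expanded): T1 -> {g1,g2,g3} (n=3), T2 -> {g2,g3,g4} (n=3),
        # root -> {g1..g4} (n=4).  Predicting g1 of D1: seed gene g2 sits in
        # T1 (1/2), T2 (1/2) and root (1/3) -> weight 1/2; g4 only via root
        # of D1? D1 is annotated T1+root only, so g4 enters via root at 1/3.
        from signprop.evaluate import term_gene_index

        tg = term_gene_index(expanded, assoc, net)
        assert tg["T1"] == {"g1", "g2", "g3"}
        assert tg["T2"] == {"g2", "g3", "g4"}
        assert tg["root"] == {"g1", "g2", "g3", "g4"}
        records = loo_disease_predictions(assoc, onto, expanded, net)
        rec = [r for r in records if r.unit == "D1" and r.test_gene == "g1"]
        assert len(rec) == 1
        # seed = all of T1 and root genes minus g1
        assert rec[0].seed_size == 3

    def test_monogenic_disease_seed_excludes_own_gene(self):
        net, onto, assoc, expanded = self._world()
        records = loo_disease_predictions(assoc, onto, expanded, net)
        rec = [r for r in records if r.unit == "D3"][0]
        # D3's only gene is held out; seed comes from sign-sharing diseases
        assert rec.test_gene == "g4"
        assert rec.seed_size > 0

    def test_pair_without_shared_sign_information_skipped(self, caplog):
        net = GeneNetwork.from_edges([("g1", "g2")])
        onto = Ontology({"root": set(), "T": {"root"}})
        assoc = AssociationSet(
            disease_genes={"D": {"g1"}}, disease_signs={"D": {"T": "typical"}}
        )
        expanded = propagate_annotations(assoc, onto)
        with caplog.at_level("WARNING"):
            records = loo_disease_predictions(assoc, onto, expanded, net)
        assert records == []
        assert any("empty seed" in r.message for r in caplog.records)


class TestDirectOligogenic:
    def test_counts_by_disease_size(self, triangle):
        assoc = AssociationSet(
            disease_genes={"tri": {"A", "B", "C"}, "pair": {"A", "B"}, "mono": {"C"}}
        )
        records = direct_oligogenic_predictions(assoc, triangle)
        by_unit = {}
        for r in records:
            by_unit.setdefault(r.unit, []).append(r)
        assert len(by_unit["tri"]) == 3
        assert all(r.seed_size == 2 for r in by_unit["tri"])
        assert len(by_unit["pair"]) == 2
        assert all(r.seed_size == 1 for r in by_unit["pair"])
        assert "mono" not in by_unit


# ---------------------------------------------------------------------------
# Baseline / upper bound


class TestRandomBaseline:
    def test_single_set_record_count_and_determinism(self, small_dataset):
        net = small_dataset.network
        s1 = random_baseline(net, n_sets=2, size_range=(25, 30), rng_seed=3)
        s2 = random_baseline(net, n_sets=2, size_range=(25, 30), rng_seed=3)
        assert s1.n_pairs == s2.n_pairs
        assert s1.auc == s2.auc
        assert len(s1.per_set_auc) == 2

    def test_small_network_rejected(self, triangle):
        with pytest.raises(ValueError):
            random_baseline(triangle, n_sets=1)


class TestBestSignUpperBound:
    def test_minimum_rank_kept_per_disease_gene_pair(self):
        records = [
            _rec(15, 1000, unit="S1", gene="MMAA", ctx={"D"}),
            _rec(604, 1000, unit="S2", gene="MMAA", ctx={"D"}),
            _rec(7, 1000, unit="S1", gene="OTHER", ctx={"D"}),
        ]
        summary = best_sign_upper_bound(records)
        assert summary.n_pairs == 2
        kept = {r for r in [15, 7]}
        assert summary.auc == pytest.approx(
            auc_from_ranks([_rec(r, 1000) for r in kept])
        )

    def test_dominates_any_single_sign_restriction(self, small_dataset):
        rng = np.random.default_rng(2)
        records = []
        for sign in ["S1", "S2", "S3"]:
            for i in range(20):
                records.append(
                    _rec(int(rng.integers(1, 500)), 500, unit=sign,
                         gene=f"g{i}", ctx={f"D{i}"})
                )
        bound = best_sign_upper_bound(records).auc
        for sign in ["S1", "S2", "S3"]:
            sub = [r for r in records if r.unit == sign]
            assert bound >= auc_from_ranks(sub) - 1e-12


# ---------------------------------------------------------------------------
# Stratification


class TestStratify:
    def _world(self, triangle):
        assoc = AssociationSet(
            disease_genes={"Dmono": {"A"}, "Doligo": {"B", "C"}},
            disease_signs={},
            disease_meta={
                "Dmono": DiseaseMeta(inheritance="AD",
                                     onset=frozenset({"neonatal", "infantile"}),
                                     progression="slow"),
                "Doligo": DiseaseMeta(inheritance="AR",
                                      onset=frozenset({"adult"}),
                                      progression="progressive"),
            },
            gene_functions={"A": {"FN:metab"}},
        )
        records = [
            _rec(1, 100, unit="S", gene="A", ctx={"Dmono"}),
            _rec(50, 100, unit="S", gene="B", ctx={"Doligo"}),
            _rec(10, 100, unit="S", gene="C", ctx={"Dmono", "Doligo"}),
        ]
        return assoc, records

    def test_ploidy_groups_with_multi_membership(self, triangle):
        assoc, records = self._world(triangle)
        out = {s.group: s for s in stratify(records, assoc, "ploidy", net=triangle)}
        assert out["monogenic"].n_pairs == 2
        assert out["oligogenic"].n_pairs == 2
        # multiset union exceeds the record count
        assert out["monogenic"].n_pairs + out["oligogenic"].n_pairs > len(records)

    def test_multivalued_onset_counts_in_each_group(self, triangle):
        assoc, records = self._world(triangle)
        out = {s.group: s for s in stratify(records, assoc, "onset")}
        assert out["neonatal"].n_pairs == 2
        assert out["infantile"].n_pairs == 2
        assert out["adult"].n_pairs == 2

    def test_mono_only_filter(self, triangle):
        assoc, records = self._world(triangle)
        out = stratify(records, assoc, "inheritance", net=triangle, mono_only=True)
        total = sum(s.n_pairs for s in out)
        # the pure-oligogenic record is excluded; the overlap pair stays
        assert total == 3  # ranks 1 and 10, with ctx {Dmono,Doligo} in AD+AR

    def test_gene_function_and_unknown_fallback(self, triangle):
        assoc, records = self._world(triangle)
        out = {s.group: s for s in stratify(records, assoc, "gene_function")}
        assert out["FN:metab"].n_pairs == 1
        assert out["unknown"].n_pairs == 2

    def test_sign_class_multi_membership(self):
        onto = Ontology(
            {"root": set(), "C1": {"root"}, "C2": {"root"}, "S": {"C1", "C2"}}
        )
        records = [_rec(1, 100, unit="S", gene="A", ctx={"D"})]
        assoc = AssociationSet(disease_genes={"D": {"A"}})
        out = {s.group: s for s in stratify(records, assoc, "sign_class", onto=onto)}
        assert set(out) == {"C1", "C2"}

    def test_frequency_uses_expanded_annotations(self, chain_ontology):
        assoc = AssociationSet(
            disease_genes={"D": {"A"}},
            disease_signs={"D": {"C": "hallmark"}},
        )
        expanded = propagate_annotations(assoc, chain_ontology)
        records = [_rec(1, 100, unit="B", gene="A", ctx={"D"})]
        out = {
            s.group: s
            for s in stratify(records, assoc, "frequency", expanded=expanded)
        }
        assert set(out) == {"hallmark"}

    def test_groups_are_subsets_of_input(self, triangle):
        assoc, records = self._world(triangle)
        for factor in ["ploidy", "inheritance", "onset", "progression"]:
            out = stratify(records, assoc, factor, net=triangle)
            assert sum(s.n_pairs for s in out) >= len(records)

    def test_unknown_factor_rejected(self, triangle):
        assoc, records = self._world(triangle)
        with pytest.raises(ValueError):
            stratify(records, assoc, "zodiac")


# ---------------------------------------------------------------------------
# Records round-trip


class TestRecordsRoundTrip:
    def test_write_read_identity(self, tmp_path):
        records = [
            _rec(3, 50, unit="S1", gene="g1", ctx={"D1", "D2"}),
            _rec(10, 50, unit="S2", gene="g2", censored=True, method="diamond"),
        ]
        path = tmp_path / "records.tsv"
        write_records(records, path)
        assert read_records(path) == records

    def test_summarize_reports_censoring(self):
        records = [_rec(1, 100), _rec(50, 100, censored=True)]
        s = summarize(records, k_max=10)
        assert s.n_pairs == 2 and s.n_censored == 1
        assert s.auc == 1.0
        assert s.topk[10] == pytest.approx(0.5)
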