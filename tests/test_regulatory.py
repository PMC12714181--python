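from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from degnet.diffexpr import DEGSets, call_degs
from degnet.errors import ValidationError
from degnet.io_formats import GeneSet, GeneSetCollection, TFPrior
from degnet.meta import run_meta_contrast
from degnet.regulatory import (
    build_rescue_network,
    build_tf_network,
    classify_rescue,
    ora_enrichment,
    rank_tfs,
)
from degnet.synthetic import generate_cohorts, generate_tf_prior, split_by_cohort


def _common(up, down):
    return DEGSets(up=frozenset(up), down=frozenset(down))


class TestBuildTFNetwork:
    def test_cebpb_dusp1_edge_with_directions(self):
        prior = TFPrior(frozenset({("CEBPB", "DUSP1"), ("CEBPB", "XYZ")}))
        net = build_tf_network(_common({"CEBPB"}, {"DUSP1"}), prior, tf_universe={"CEBPB"})
        assert ("CEBPB", "DUSP1") in net.edges
        assert ("CEBPB", "XYZ") not in net.edges  # XYZ not a DEG
        assert net.nodes["CEBPB"] == ("tf", "up")
        assert net.nodes["DUSP1"] == ("target", "down")

    def test_tf_not_deg_excluded_unless_relaxed(self):
        prior = TFPrior(frozenset({("TF1", "DUSP1")}))
        common = _common(set(), {"DUSP1"})
        net = build_tf_network(common, prior, tf_universe={"TF1"})
        assert not net.edges
        relaxed = build_tf_network(common, prior, tf_universe={"TF1"}, require_tf_deg=False)
        assert ("TF1", "DUSP1") in relaxed.edges
        assert relaxed.nodes["TF1"] == ("tf", None)

    def test_recovers_planted_regulon(self, small_config):
        matrix, metadata, truth = generate_cohorts(small_config)
        report = run_meta_contrast(split_by_cohort(matrix, metadata), metadata)
        prior = TFPrior(truth.regulon)
        net = build_tf_network(report, prior, tf_universe={truth.hub_tf})
        recovered_degs = report.common_up | report.common_down
        expected = {
            (tf, t) for tf, t in truth.regulon if t in recovered_degs and tf in recovered_degs
        }
        assert net.edges == frozenset(expected)

    def test_empty_prior_rejected(self):
        with pytest.raises(ValidationError):
            build_tf_network(_common({"A"}, set()), TFPrior(frozenset()), tf_universe=set())


class TestRankTFs:
    def test_degree_sort_with_lexicographic_ties(self):
        edges = {("A", f"t{i}") for i in range(3)}
        edges |= {("B", f"t{i}") for i in range(5)}
        edges |= {("C", f"u{i}") for i in range(3)}
        prior = TFPrior(frozenset(edges))
        degs = {f"t{i}" for i in range(5)} | {f"u{i}" for i in range(3)} | {"A", "B", "C"}
        net = build_tf_network(_common(degs, set()), prior, tf_universe={"A", "B", "C"})
        assert [tf for tf, _ in rank_tfs(net)] == ["B", "A", "C"]

    def test_empty_network_gives_empty_ranking(self):
        prior = TFPrior(frozenset({("A", "B")}))
        net = build_tf_network(_common(set(), set()), prior, tf_universe={"A"})
        assert rank_tfs(net) == []

    def test_planted_hub_ranks_first(self, small_config):
        matrix, metadata, truth = generate_cohorts(small_config)
        report = run_meta_contrast(split_by_cohort(matrix, metadata), metadata)
        prior = generate_tf_prior(small_config, truth, n_decoys=5, max_decoy_size=5)
        net = build_tf_network(report, prior, tf_universe=prior.tfs)
        ranking = rank_tfs(net)
        assert ranking[0][0] == truth.hub_tf


def _de_row(gene, lfc, padj):
    return {"gene": gene, "base_mean": 1.0, "log2fc": lfc, "p": padj, "padj": padj}


class TestClassifyRescue:
    CASES = {  # (tumor_state, kd_state) -> class; states: sig-up, sig-down, ns
        ("up", "up"): "none",
        ("up", "down"): "tumor_up_rescued",
        ("up", "ns"): "none",
        ("down", "up"): "tumor_down_rescued",
        ("down", "down"): "none",
        ("down", "ns"): "none",
        ("ns", "up"): "none",
        ("ns", "down"): "none",
        ("ns", "ns"): "none",
    }
    STATES = {"up": (2.0, 0.001), "down": (-2.0, 0.001), "ns": (0.1, 0.8)}

    def test_matches_enumeration_oracle(self):
        tumor_rows, kd_rows, expected = [], [], {}
        for i, ((ts, ks), cls) in enumerate(self.CASES.items()):
            gene = f"g{i}"
            tumor_rows.append(_de_row(gene, *self.STATES[ts]))
            kd_rows.append(_de_row(gene, *self.STATES[ks]))
            expected[gene] = cls
        table = classify_rescue(pd.DataFrame(tumor_rows), pd.DataFrame(kd_rows))
        got = dict(zip(table["gene"], table["rescue_class"]))
        assert got == expected

    def test_dusp1_like_pattern_is_tumor_down_rescued(self):
        tumor = pd.DataFrame([_de_row("DUSP1", -1.5, 1e-4)])
        kd = pd.DataFrame([_de_row("DUSP1", 1.0, 1e-3)])
        table = classify_rescue(tumor, kd)
        assert table["rescue_class"].iloc[0] == "tumor_down_rescued"

    def test_insignificant_knockdown_gates_to_none(self):
        tumor = pd.DataFrame([_de_row("g", 2.0, 1e-4)])
        kd = pd.DataFrame([_de_row("g", -2.0, 0.2)])
        assert classify_rescue(tumor, kd)["rescue_class"].iloc[0] == "none"

    def test_antisymmetry_under_contrast_swap(self):
        rng = np.random.default_rng(4)
        rows_a = [_de_row(f"g{i}", rng.normal(0, 2), rng.uniform(0, 0.1)) for i in range(50)]
        rows_b = [_de_row(f"g{i}", rng.normal(0, 2), rng.uniform(0, 0.1)) for i in range(50)]
        fwd = classify_rescue(pd.DataFrame(rows_a), pd.DataFrame(rows_b))
        rev = classify_rescue(pd.DataFrame(rows_b), pd.DataFrame(rows_a))
        swap = {"tumor_up_rescued": "tumor_down_rescued", "tumor_down_rescued": "tumor_up_rescued", "none": "none"}
        assert list(rev["rescue_class"]) == [swap[c] for c in fwd["rescue_class"]]

    def test_only_shared_genes_kept(self):
        tumor = pd.DataFrame([_de_row("a", 2, 0.01), _de_row("b", 2, 0.01)])
        kd = pd.DataFrame([_de_row("b", -2, 0.01), _de_row("c", -2, 0.01)])
        table = classify_rescue(tumor, kd)
        assert list(table["gene"]) == ["b"]


class TestORA:
    def _annotation(self, sets):
        return GeneSetCollection(
            [GeneSet(f"T{i}", f"term {i}", frozenset(m)) for i, m in enumerate(sets)]
        )

    def test_closed_form_full_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        result = ora_enrichment(term, universe, self._annotation([term]))
        assert result["p"].iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        result = ora_enrichment(
            {"g0", "g1"}, universe, self._annotation([{"g10", "g11"}])
        )
        assert result["p"].iloc[0] == pytest.approx(1.0)

    def test_query_equals_universe_saturates(self):
        universe = {f"g{i}" for i in range(10)}
        result = ora_enrichment(universe, universe, self._annotation([{"g0", "g1", "g2"}]))
        assert result["overlap"].iloc[0] == 3
        assert result["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exact_tail_summation_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            N = int(rng.integers(20, 200))
            universe = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            term = set(rng.choice(sorted(universe), size=K, replace=False))
            query = set(rng.choice(sorted(universe), size=n, replace=False))
            k = len(term & query)
            result = ora_enrichment(query, universe, self._annotation([term]))
            exact = sum(
                Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
                for i in range(k, min(K, n) + 1)
            )
            assert abs(result["p"].iloc[0] - float(exact)) < 1e-10

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            ora_enrichment({"a"}, set(), self._annotation([{"a"}]))


class TestRescueNetwork:
    def _rescue_table(self, classes):
        rows = []
        for gene, cls in classes.items():
            lfc = 2.0 if cls == "tumor_up_rescued" else -2.0
            rows.append(
                {
                    "gene": gene,
                    "tumor_log2fc": lfc,
                    "tumor_padj": 0.01,
                    "kd_log2fc": -lfc,
                    "kd_padj": 0.01,
                    "rescue_class": cls,
                }
            )
        return pd.DataFrame(rows)

    def test_majority_coloring_and_gate(self):
        classes = {f"u{i}": "tumor_up_rescued" for i in range(3)}
        classes["d0"] = "tumor_down_rescued"
        for i in range(40):
            classes[f"n{i}"] = "none"
        table = self._rescue_table(classes)
        annotation = GeneSetCollection(
            [
                GeneSet("HIT", "contains rescue genes", frozenset({"u0", "u1", "u2", "d0"})),
                GeneSet("MISS", "background", frozenset({f"n{i}" for i in range(10)})),
            ]
        )
        edges, colors, enrichment = build_rescue_network(table, annotation, alpha=0.05)
        assert colors["HIT"] == "tumor_up_rescued"
        assert "MISS" not in colors
        assert {g for g, t in edges if t == "HIT"} == {"u0", "u1", "u2", "d0"}

    def test_tie_is_mixed(self):
        classes = {"u0": "tumor_up_rescued", "d0": "tumor_down_rescued"}
        for i in range(40):
            classes[f"n{i}"] = "none"
        annotation = GeneSetCollection([GeneSet("HIT", "tied", frozenset({"u0", "d0"}))])
        _, colors, _ = build_rescue_network(self._rescue_table(classes), annotation)
        assert colors["HIT"] == "mixed"

    def test_planted_reversal_term_ranks_first(self, small_config):
        from degnet.synthetic import generate_annotation

        _, _, truth = generate_cohorts(small_config)
        classes = {g: ("tumor_up_rescued" if lfc < 0 else "tumor_down_rescued")
                   for g, lfc in truth.reversal_genes.items()}
        for g in truth.gene_ids:
            classes.setdefault(g, "none")
        annotation = generate_annotation(small_config, truth)
        _, _, enrichment = build_rescue_network(self._rescue_table(classes), annotation)
        assert enrichment["term_id"].iloc[0] == "REVERSAL"

    def test_empty_rescue_set_gives_empty_network(self):
        table = self._rescue_table({"g0": "none"})
        annotation = GeneSetCollection([GeneSet("T", "t", frozenset({"g0"}))])
        edges, colors, enrichment = build_rescue_network(table, annotation)
        assert edges == [] and colors == {} and enrichment.empty
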