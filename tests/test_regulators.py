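"""Regulator overlap, screening, chromosome tabulation and enrichment."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from coexmod import (
    chromosome_distribution,
    count_regulators_per_gene,
    hypergeometric_enrichment,
    module_coverage,
    mutual_de_genes,
    mutual_targets,
    top_regulators,
)
from coexmod.datatypes import RegulatorMap

from conftest import brute_hypergeom_tail


def _map(**entries):
    rmap = RegulatorMap()
    for name, (typ, targets) in entries.items():
        rmap.add(name, typ, targets)
    return rmap


class TestCounts:
    def test_counts_per_gene(self):
        rmap = _map(
            A=("TF", ["g1", "g2"]),
            B=("TF", ["g1"]),
            C=("TF", ["g1"]),
            m1=("miRNA", ["g1"]),
        )
        counts = count_regulators_per_gene(rmap, ["g1", "g2", "g3"])
        by_gene = counts.set_index("gene")
        assert by_gene.loc["g1"].tolist() == [3, 1]
        assert by_gene.loc["g2"].tolist() == [1, 0]
        assert by_gene.loc["g3"].tolist() == [0, 0]

    def test_empty_map_all_zeros(self):
        counts = count_regulators_per_gene(RegulatorMap(), ["a", "b"])
        assert (counts[["n_tf", "n_mirna"]].to_numpy() == 0).all()

    def test_most_module_genes_multi_tf_regulated(self):
        # six TFs each covering 89% of an 84-gene module leave almost no
        # gene with fewer than two regulators
        from coexmod import generate_regulator_map
        from coexmod.synthetic import SyntheticConfig

        module = [f"M{i:02d}" for i in range(84)]
        rmap = generate_regulator_map(SyntheticConfig(seed=11), module)
        counts = count_regulators_per_gene(rmap, module)
        assert (counts["n_tf"] > 1).sum() >= 70


class TestTopRegulators:
    def test_single_total_regulator_full_coverage(self):
        rmap = _map(A=("TF", ["g1", "g2", "g3"]))
        assert top_regulators(rmap, ["g1", "g2", "g3"], k=1).coverage == 1.0

    def test_ties_broken_lexicographically(self):
        rmap = _map(B=("TF", ["g1"]), A=("TF", ["g2"]))
        table = top_regulators(rmap, ["g1", "g2"], k=2).table
        assert table["regulator"].tolist() == ["A", "B"]

    def test_k_below_one_is_error(self):
        with pytest.raises(ValueError):
            top_regulators(_map(A=("TF", ["g"])), ["g"], k=0)


class TestMutualTargets:
    def test_disjoint_sets_zero_triple(self):
        rmap = _map(A=("TF", ["a"]), B=("TF", ["b"]), C=("TF", ["c"]))
        regions = mutual_targets(rmap, ["A", "B", "C"])
        assert regions[frozenset("ABC")] == 0
        assert regions[frozenset(["A"])] == 1

    def test_identical_sets_full_triple(self):
        genes = [f"g{i}" for i in range(35)]
        rmap = _map(A=("TF", genes), B=("TF", genes), C=("TF", genes))
        regions = mutual_targets(rmap, ["A", "B", "C"])
        assert regions[frozenset("ABC")] == 35
        assert sum(regions.values()) == 35

    def test_regions_match_brute_force_membership(self, rng):
        universe = [f"g{i:02d}" for i in range(40)]
        sets = {
            name: ("TF", list(rng.choice(universe, size=rng.integers(5, 25),
                                         replace=False)))
            for name in "ABC"
        }
        rmap = _map(**sets)
        regions = mutual_targets(rmap, ["A", "B", "C"])
        # brute force: classify every gene by its exact membership pattern
        expected: dict[frozenset, int] = {k: 0 for k in regions}
        for g in universe:
            members = frozenset(n for n in "ABC" if g in set(sets[n][1]))
            if members:
                expected[members] += 1
        assert regions == expected
        union = set().union(*(set(s[1]) for s in sets.values()))
        assert sum(regions.values()) == len(union)

    def test_absent_regulator_is_error(self):
        rmap = _map(A=("TF", ["g"]), B=("TF", ["g"]))
        with pytest.raises(ValueError, match="GHOST"):
            mutual_targets(rmap, ["A", "GHOST"])

    def test_needs_two_to_four_regulators(self):
        rmap = _map(A=("TF", ["g"]))
        with pytest.raises(ValueError):
            mutual_targets(rmap, ["A"])


class TestCoverage:
    def test_superset_full_coverage(self):
        row = module_coverage(["a", "b", "c", "x"], ["a", "b", "c"], "ovarian")
        assert row.coverage == 1.0
        assert row.pct == 100

    def test_disjoint_zero(self):
        row = module_coverage(["x", "y"], ["a", "b"], "breast")
        assert row.coverage == 0.0

    def test_half_coverage_like_the_ovarian_screen(self):
        module = [f"m{i:02d}" for i in range(84)]
        degs = module[:42] + ["other1", "other2"]
        row = module_coverage(degs, module, "ovarian")
        assert row.pct == 50
        assert row.n_module_de == 42

    def test_monotone_in_deg_set(self, rng):
        module = [f"m{i:02d}" for i in range(30)]
        degs: set[str] = set()
        last = -1.0
        for g in rng.permutation(module):
            degs.add(str(g))
            cov = module_coverage(degs, module, "c").coverage
            assert cov >= last
            last = cov


class TestMutualDEGenes:
    # the recurrent-gene table from the multi-tumor screen, used as fixture
    TABLE1 = {
        "BUB1": [("colorectal", "up", 12.11), ("cervical", "up", 2.68),
                 ("leukemia", "up", 25.34), ("ovarian", "up", 2.38)],
        "GATM": [("cervical", "down", 3.15), ("leukemia", "down", 2.43),
                 ("ovarian", "down", 2.48), ("thyroid", "down", 3.01)],
        "PLCE1": [("colorectal", "down", 5.47), ("ovarian", "down", 4.55),
                  ("leukemia", "up", 3.44)],
        "PTGER3": [("cervical", "down", 2.26), ("leukemia", "up", 2.95),
                   ("ovarian", "down", 4.99)],
        "NEGR1": [("ovarian", "down", 17.44), ("leukemia", "up", 3.18),
                  ("thyroid", "down", 2.06)],
        "SH3RF2": [("colorectal", "down", 2.54), ("lung", "down", 2.10),
                   ("ovarian", "down", 2.89)],
    }

    def _condition_tables(self, extra_rows=()):
        conditions: dict[str, list] = {}
        for gene, rows in self.TABLE1.items():
            for cond, direction, fc in rows:
                conditions.setdefault(cond, []).append((gene, direction, fc))
        for cond, gene, direction, fc in extra_rows:
            conditions.setdefault(cond, []).append((gene, direction, fc))
        return {
            cond: pd.DataFrame(rows, columns=["gene", "direction", "fc"])
            for cond, rows in conditions.items()
        }

    def test_reconstructs_fixture_rows_exactly(self):
        module = list(self.TABLE1) + ["UNSEEN1", "UNSEEN2"]
        out = mutual_de_genes(self._condition_tables(), module,
                              min_conditions=3)
        assert sorted(out["gene"].unique()) == sorted(self.TABLE1)
        for gene, rows in self.TABLE1.items():
            got = out[out["gene"] == gene]
            expected = sorted((c, d, f) for c, d, f in rows)
            assert list(map(tuple, got[["condition", "direction", "fc"]]
                            .to_numpy())) == expected

    def test_gene_in_two_conditions_excluded(self):
        tables = self._condition_tables(
            extra_rows=[("ovarian", "RARE1", "up", 3.0),
                        ("lung", "RARE1", "down", 2.0)]
        )
        out = mutual_de_genes(tables, list(self.TABLE1) + ["RARE1"])
        assert "RARE1" not in set(out["gene"])

    def test_three_conditions_included(self):
        tables = self._condition_tables(
            extra_rows=[("ovarian", "TRIO", "up", 3.0),
                        ("lung", "TRIO", "up", 2.0),
                        ("thyroid", "TRIO", "down", 2.2)]
        )
        out = mutual_de_genes(tables, list(self.TABLE1) + ["TRIO"])
        assert (out["gene"] == "TRIO").sum() == 3

    def test_accepts_log2fc_tables(self):
        tables = {
            "c1": pd.DataFrame({"gene": ["A"], "log2fc": [2.0]}),
            "c2": pd.DataFrame({"gene": ["A"], "log2fc": [-1.0]}),
            "c3": pd.DataFrame({"gene": ["A"], "log2fc": [1.5]}),
        }
        out = mutual_de_genes(tables, ["A"])
        assert len(out) == 3
        assert set(out["direction"]) == {"up", "down"}
        assert (out["fc"] >= 1).all()  # magnitudes, direction carried apart

    def test_needs_three_conditions(self):
        with pytest.raises(ValueError, match="3 conditions"):
            mutual_de_genes({"a": pd.DataFrame(), "b": pd.DataFrame()}, ["g"])


class TestChromosomes:
    def test_single_chromosome(self):
        counts, un = chromosome_distribution({"a": "1", "b": "1"}, ["a", "b"])
        assert counts.to_dict() == {"1": 2}
        assert un == []

    def test_unannotated_reported_separately(self):
        counts, un = chromosome_distribution({"a": "3"}, ["a", "mystery"])
        assert counts.sum() == 1
        assert un == ["mystery"]

    def test_random_annotation_matches_brute_tally(self, rng):
        genes = [f"g{i:02d}" for i in range(50)]
        chroms = [str(int(c)) for c in rng.integers(1, 23, size=50)]
        ann = dict(zip(genes, chroms))
        counts, _ = chromosome_distribution(ann, genes)
        for c in set(chroms):
            assert counts[c] == chroms.count(c)
        assert counts.sum() == 50

    def test_no_annotated_gene_is_error(self):
        with pytest.raises(ValueError, match="annotation"):
            chromosome_distribution({"x": "1"}, ["a", "b"])


class TestEnrichment:
    def test_zero_overlap_p_is_one(self):
        universe = [f"u{i}" for i in range(20)]
        sets = [("s", "d", universe[:4])]
        out = hypergeometric_enrichment(universe[10:15], sets, universe)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_worked_example_p_0032(self):
        # N=20, K=4, n=5, overlap=3: (C(4,3)C(16,2)+C(4,4)C(16,1))/C(20,5)
        universe = [f"u{i:02d}" for i in range(20)]
        sets = [("s", "d", universe[:4])]
        query = universe[:3] + universe[10:12]
        out = hypergeometric_enrichment(query, sets, universe)
        assert out["p"].iloc[0] == pytest.approx(496 / 15504, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(0.0320, abs=5e-5)

    def test_matches_full_enumeration_small_universe(self, rng):
        for trial in range(8):
            N = int(rng.integers(6, 13))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"u{i:02d}" for i in range(N)]
            members = universe[:K]
            query = list(rng.choice(universe, size=n, replace=False))
            out = hypergeometric_enrichment(query, [("s", "d", members)],
                                            universe)
            k = len(set(query) & set(members))
            assert out["p"].iloc[0] == pytest.approx(
                brute_hypergeom_tail(N, K, n, k), abs=1e-12
            )

    def test_invariant_to_gene_relabeling(self, rng):
        universe = [f"u{i:02d}" for i in range(30)]
        members = universe[:10]
        query = universe[5:14]
        p1 = hypergeometric_enrichment(query, [("s", "d", members)],
                                       universe)["p"].iloc[0]
        mapping = {g: f"zz_{g}" for g in universe}
        p2 = hypergeometric_enrichment(
            [mapping[g] for g in query],
            [("s", "d", [mapping[g] for g in members])],
            [mapping[g] for g in universe],
        )["p"].iloc[0]
        assert p1 == p2

    def test_bh_and_significance_flag(self):
        universe = [f"u{i:02d}" for i in range(40)]
        sets = [
            ("hit", "d", universe[:10]),
            ("miss", "d", universe[30:]),
        ]
        out = hypergeometric_enrichment(universe[:10], sets, universe)
        out = out.set_index("set")
        assert bool(out.loc["hit", "significant"])
        assert not bool(out.loc["miss", "significant"])

    def test_query_outside_universe_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeometric_enrichment(["alien"], [("s", "d", ["a"])], ["a"])

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrichment([], [("s", "d", ["a"])], [])
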