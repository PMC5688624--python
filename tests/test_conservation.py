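"""Cross-species integration: profiles, normalization, clustering, Venn."""

import itertools

import numpy as np
import pandas as pd
import pytest

from irkit import conservation as C
from irkit.quantify import GeneIR


def gene_ir(gid, ratio, fpkm=10.0):
    return GeneIR(
        gene_id=gid, fpkm=fpkm, gene_ir_ratio=ratio,
        retained_intron_ids=[], n_retained=int(ratio > 0),
        is_expressed=fpkm >= 1, is_ir_gene=fpkm >= 1 and ratio > 0,
    )


class TestProfileMatrix:
    def test_disjoint_genes_give_half_missing_rows(self):
        irs = {
            "sp1": {"a": gene_ir("a", 0.3)},
            "sp2": {"b": gene_ir("b", 0.5)},
        }
        rows = [("og1", "sp1", "a"), ("og2", "sp2", "b")]
        mat = C.build_profile_matrix(irs, rows)
        assert mat.shape == (2, 2)
        assert mat.isna().sum().sum() == 2

    def test_many_to_many_collapses_by_max(self):
        irs = {"sp1": {"a": gene_ir("a", 0.2), "b": gene_ir("b", 0.6)}}
        rows = [("og1", "sp1", "a"), ("og1", "sp1", "b")]
        mat = C.build_profile_matrix(irs, rows)
        assert mat.loc["og1", "sp1"] == 0.6

    def test_row_count_equals_observed_groups(self):
        irs = {
            "sp1": {f"g{i}": gene_ir(f"g{i}", 0.1 * i) for i in range(5)},
            "sp2": {f"h{i}": gene_ir(f"h{i}", 0.1) for i in range(5)},
        }
        rows = [(f"og{i}", "sp1", f"g{i}") for i in range(5)] + [
            (f"og{i}", "sp2", f"h{i}") for i in range(5)
        ]
        mat = C.build_profile_matrix(irs, rows)
        assert mat.shape[0] == 5


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 3.0, 2.0], "b": [1.0, 3.0, 2.0]})
        out = C.quantile_normalize(m)
        assert np.allclose(out, m)

    def test_hand_computed_reference(self):
        # sorted columns: a -> [2,3,5], b -> [1,2,4]; reference = means
        m = pd.DataFrame({"a": [5.0, 2.0, 3.0], "b": [4.0, 1.0, 2.0]})
        out = C.quantile_normalize(m)
        assert np.allclose(out["a"], [4.5, 1.5, 2.5])
        assert np.allclose(out["b"], [4.5, 1.5, 2.5])

    def test_column_means_equal_after(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(0, 1, (50, 4)))
        out = C.quantile_normalize(m)
        means = out.mean()
        assert np.allclose(means, means.iloc[0])

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.uniform(0, 1, (30, 3)))
        once = C.quantile_normalize(m)
        twice = C.quantile_normalize(once)
        assert np.allclose(once, twice)

    def test_missing_values_stay_missing(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [2.0, 1.0, 3.0]})
        out = C.quantile_normalize(m)
        assert np.isnan(out.loc[1, "a"])
        assert out.notna().sum().sum() == 5


class TestKmeans:
    def test_separated_blobs_fully_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.05, (30, 4))
        b = rng.normal(1, 0.05, (30, 4))
        m = pd.DataFrame(np.vstack([a, b]))
        labels = C.kmeans_rows(m, k=2, seed=1)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_rows_gives_singletons(self):
        m = pd.DataFrame(np.eye(5))
        labels = C.kmeans_rows(m, k=5, seed=0)
        assert labels.nunique() == 5

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.uniform(0, 1, (40, 3)))
        l1 = C.kmeans_rows(m, k=4, seed=7)
        l2 = C.kmeans_rows(m, k=4, seed=7)
        assert (l1 == l2).all()

    def test_rows_with_missing_dropped(self):
        m = pd.DataFrame({"a": [0.1, np.nan, 0.3, 0.0], "b": [0.2, 0.1, 0.4, 0.1]})
        labels = C.kmeans_rows(m, k=2, seed=0)
        assert len(labels) == 3


class TestHcluster:
    def test_identical_columns_merge_at_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 40)
        m = pd.DataFrame({"a": x, "b": x, "c": rng.uniform(0, 1, 40)})
        z, newick, order = C.hcluster_species(m)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert newick.endswith(";") and "a" in newick

    def test_anticorrelated_columns_merge_at_two(self):
        x = np.linspace(0, 1, 20)
        m = pd.DataFrame({"a": x, "b": -x})
        z, _, _ = C.hcluster_species(m)
        assert z[-1, 2] == pytest.approx(2.0, abs=1e-9)

    def test_four_column_toy_matches_bruteforce_average_linkage(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.uniform(0, 1, (25, 4)), columns=list("abcd"))
        z, _, _ = C.hcluster_species(m)
        # independent oracle: greedy average-linkage on the distance matrix
        d = (1 - m.corr()).to_numpy()
        clusters = {i: [i] for i in range(4)}
        heights = []
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(sorted(clusters), 2):
                dist = np.mean(
                    [d[p, q] for p in clusters[i] for q in clusters[j]]
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
            dist, i, j = best
            heights.append(dist)
            new_key = max(clusters) + 1
            clusters[new_key] = clusters.pop(i) + clusters.pop(j)
        assert np.allclose(sorted(z[:, 2]), sorted(heights), atol=1e-9)


class TestVenn:
    def rows(self, species, n):
        return [
            (f"og{g}", sp, f"{sp}_g{g}") for g in range(n) for sp in species
        ]

    def test_disjoint_sets_only_singletons(self):
        rows = self.rows(["s1", "s2"], 4)
        sets = {"s1": {"s1_g0", "s1_g1"}, "s2": {"s2_g2", "s2_g3"}}
        venn = C.venn_counts(sets, rows)
        assert venn["regions"][frozenset(["s1"])] == 2
        assert venn["regions"][frozenset(["s2"])] == 2
        assert venn["regions"][frozenset(["s1", "s2"])] == 0

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(11)
        species = ["s1", "s2", "s3"]
        rows = self.rows(species, 30)
        sets = {
            sp: {f"{sp}_g{g}" for g in rng.choice(30, 12, replace=False)}
            for sp in species
        }
        venn = C.venn_counts(sets, rows)
        assert sum(venn["regions"].values()) == venn["union"]

    def test_invariant_to_species_ordering(self):
        rows = self.rows(["s1", "s2", "s3"], 10)
        sets = {
            "s1": {f"s1_g{g}" for g in range(6)},
            "s2": {f"s2_g{g}" for g in range(3, 9)},
            "s3": {f"s3_g{g}" for g in range(2, 7)},
        }
        v1 = C.venn_counts(sets, rows)
        v2 = C.venn_counts(dict(reversed(list(sets.items()))), rows)
        assert v1["regions"] == v2["regions"]

    def test_planted_core_recovered_through_estimator(self):
        from irkit import quantify
        from irkit import simulate as sim

        cfgs = [sim.SimConfig(n_genes=150, rng_seed=40 + s) for s in range(5)]
        sims, rows, core = sim.simulate_species_panel(
            cfgs, n_conserved_core=25
        )
        ir_sets = {}
        for s in sims:
            fpkm = sim.estimate_fpkm_from_coverage(
                s.annotation, s.coverage, s.config.coverage_per_fpkm
            )
            _, gene_irs = quantify.quantify_annotation(
                s.annotation, s.coverage, s.junctions, fpkm=fpkm
            )
            ir_sets[s.name] = {
                g for g, gi in gene_irs.items() if gi.is_ir_gene
            }
        venn = C.venn_counts(ir_sets, rows)
        assert venn["all"] == 25


class TestComplexityCorrelation:
    def test_published_table_gives_minus_095(self):
        r = C.correlate_ir_complexity(C.published_species_summaries())
        assert r == -0.95

    def test_perfect_linear_pair_gives_plus_one(self):
        summaries = [
            C.SpeciesSummary(f"s{i}", 1000 * (i + 1), None, 10.0 * (i + 1))
            for i in range(4)
        ]
        assert C.correlate_ir_complexity(summaries) == 1.0

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(8)
        x = rng.integers(5000, 30000, 5)
        y = rng.uniform(1, 50, 5)
        summaries = [
            C.SpeciesSummary(f"s{i}", int(x[i]), None, float(y[i]))
            for i in range(5)
        ]
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r = cov / (x.std() * y.std())
        assert C.correlate_ir_complexity(summaries) == pytest.approx(
            round(r, 2)
        )

    def test_affine_rescaling_invariance(self):
        base = [
            C.SpeciesSummary(f"s{i}", n, None, f)
            for i, (n, f) in enumerate(
                [(20296, 17.4), (22547, 13.6), (19856, 18.6), (15508, 40.8)]
            )
        ]
        scaled = [
            C.SpeciesSummary(s.species, s.n_pc_genes * 3 + 100, None,
                             s.fraction_ir_genes)
            for s in base
        ]
        assert C.correlate_ir_complexity(base) == C.correlate_ir_complexity(
            scaled
        )

    def test_fraction_must_be_percentage(self):
        with pytest.raises(ValueError):
            C.SpeciesSummary("x", 100, None, 150.0)

    def test_needs_three_species(self):
        with pytest.raises(ValueError):
            C.correlate_ir_complexity(C.published_species_summaries()[:2])
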