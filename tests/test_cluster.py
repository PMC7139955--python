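import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from immunosig import ExpressionMatrix, simulate_expression
from immunosig.cluster import (
    Dendrogram,
    ImmunomeModel,
    Merge,
    correlation_distance,
    extract_modules,
    from_newick,
    hierarchical_cluster,
    partition_samples,
    select_focus_set,
    to_newick,
)
from immunosig.preprocess import center_genes

from _oracles import brute_force_centroid_merges


def log2m(values, genes, samples=None):
    df = pd.DataFrame(
        values, index=genes, columns=samples or [f"s{j}" for j in range(len(values[0]))]
    )
    return ExpressionMatrix(df, scale="log2")


def merge_record(d: Dendrogram):
    """(left leaf set, right leaf set, height) per merge, for oracle
    comparison."""
    sets = d.leaf_sets()
    return [
        (frozenset(sets[m.left]), frozenset(sets[m.right]), m.height)
        for m in d.merges
    ]


class TestCorrelationDistance:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        assert correlation_distance(x, x) == pytest.approx(0.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0])
        assert correlation_distance(x, -x) == pytest.approx(2.0)

    def test_hand_computed_pearson(self):
        # r((1,2,3),(1,2,4)) = 0.981980506...
        d = correlation_distance(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert d == pytest.approx(1 - 0.9819805060619656, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_distance(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))


class TestHierarchicalCluster:
    def test_identical_profiles_merge_first_at_zero(self):
        m = log2m(
            [[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 2, 2]], ["gA", "gB", "gC"]
        )
        d = hierarchical_cluster(m, axis="genes")
        first = d.merges[0]
        sets = d.leaf_sets()
        assert sets[3] == frozenset({"gA", "gB"})
        assert first.height == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        """Merge-for-merge equality with an O(n^3) full-rescan oracle on
        small random matrices."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        profiles = rng.normal(size=(n, 6))
        labels = [f"g{i}" for i in range(n)]
        m = log2m(profiles, labels)
        d = hierarchical_cluster(m, axis="genes")
        ours = merge_record(d)
        oracle = brute_force_centroid_merges(profiles, labels)
        assert len(ours) == len(oracle)
        for (l1, r1, h1), (l2, r2, h2) in zip(ours, oracle):
            assert {l1, r1} == {l2, r2}
            assert h1 == pytest.approx(h2, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        profiles = rng.normal(size=(6, 8))
        labels = [f"g{i}" for i in range(6)]
        m1 = log2m(profiles, labels)
        perm = [3, 1, 5, 0, 4, 2]
        m2 = log2m(profiles[perm], [labels[i] for i in perm])
        rec1 = [
            ({l, r}, round(h, 10)) for l, r, h in merge_record(hierarchical_cluster(m1))
        ]
        rec2 = [
            ({l, r}, round(h, 10)) for l, r, h in merge_record(hierarchical_cluster(m2))
        ]
        assert rec1 == rec2

    def test_constant_profile_named_in_error(self):
        m = log2m([[1, 1, 1], [1, 2, 3]], ["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(m, axis="genes")

    def test_sample_axis_clusters_columns(self):
        rng = np.random.default_rng(6)
        m = log2m(rng.normal(size=(5, 4)), [f"g{i}" for i in range(5)])
        d = hierarchical_cluster(m, axis="samples")
        assert d.axis == "samples"
        assert set(d.leaves) == {"s0", "s1", "s2", "s3"}


class TestCut:
    def fixture(self):
        return Dendrogram(
            leaves=["a", "b", "c", "d"],
            merges=[Merge(0, 1, 0.1), Merge(2, 3, 0.2), Merge(4, 5, 0.9)],
        )

    def test_height_zero_gives_singletons(self):
        clusters = self.fixture().cut(height=0.0)
        assert clusters == [["a"], ["b"], ["c"], ["d"]]

    def test_height_above_max_gives_one_cluster(self):
        assert self.fixture().cut(height=1.0) == [["a", "b", "c", "d"]]

    def test_k_cut(self):
        assert self.fixture().cut(k=2) == [["a", "b"], ["c", "d"]]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            self.fixture().cut(k=5)

    def test_exactly_one_criterion_required(self):
        with pytest.raises(ValueError):
            self.fixture().cut()


class TestModuleExtraction:
    def test_planted_modules_recovered_exactly(self, planted_config):
        cohort = simulate_expression(planted_config(seed=1))
        m = center_genes(cohort.truth["log2"])
        d = hierarchical_cluster(m, axis="genes")
        modules, unassigned = extract_modules(d, height=0.5, min_size=3)
        truth = cohort.truth["membership"]
        pred = {g: i for i, mod in enumerate(modules) for g in mod.genes}
        genes = sorted(truth)
        ari = adjusted_rand_score(
            [truth[g] for g in genes], [pred.get(g, -1) for g in genes]
        )
        assert ari == pytest.approx(1.0)
        assert sorted(len(mod.genes) for mod in modules) == [5, 6, 10]

    def test_min_size_sends_small_clusters_to_unassigned(self):
        d = Dendrogram(
            leaves=["a", "b", "c"], merges=[Merge(0, 1, 0.1), Merge(3, 2, 0.9)]
        )
        modules, unassigned = extract_modules(d, height=0.5, min_size=2)
        assert [m.genes for m in modules] == [["a", "b"]]
        assert unassigned == ["c"]


class TestFocusSet:
    def make_modules(self):
        from immunosig.cluster import GeneModule

        return [
            GeneModule("m1", ["g1", "g2"], dominant_classes=["T.cells.CD8"]),
            GeneModule("m2", ["g3"], dominant_classes=["Neutrophils"]),
        ]

    def immunome(self):
        return ImmunomeModel(
            {
                "g1": {"T.cells.CD8"},
                "g2": {"T.cells.CD8"},
                "g3": {"Neutrophils"},
            }
        )

    def test_all_classes_returns_all_module_genes(self):
        out = select_focus_set(
            self.make_modules(), self.immunome(), ["T.cells.CD8", "Neutrophils"]
        )
        assert out == ["g1", "g2", "g3"]

    def test_class_filter_selects_tagged_modules(self):
        out = select_focus_set(self.make_modules(), self.immunome(), ["T.cells.CD8"])
        assert out == ["g1", "g2"]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            select_focus_set(self.make_modules(), self.immunome(), ["Made.Up"])

    def test_empty_result_rejected(self):
        from immunosig.cluster import GeneModule

        mods = [GeneModule("m1", ["g1"], dominant_classes=["T.cells.CD8"])]
        with pytest.raises(ValueError, match="no module"):
            select_focus_set(mods, self.immunome(), ["Neutrophils"])


class TestPartitionSamples:
    def test_active_silent_recovery(self):
        from immunosig import SimulationConfig

        cfg = SimulationConfig(
            seed=1, n_types=1, samples_per_type=300, active_fraction=0.4
        )
        cohort = simulate_expression(cfg)
        log2 = cohort.truth["log2"]
        focus = [g for g in cohort.truth["membership"]]
        centered = center_genes(log2.subset_genes(focus))
        d = hierarchical_cluster(centered, axis="samples")
        labels = partition_samples(d, log2, focus)
        truth = cohort.truth["active"].map({True: "active", False: "silent"})
        accuracy = (labels == truth).mean()
        assert accuracy >= 0.95

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(5, 1, size=(6, 12))
        vals[:, 6:] += 2.0
        genes = [f"g{i}" for i in range(6)]
        m1 = log2m(vals, genes)
        perm = list(np.random.default_rng(0).permutation(12))
        m2 = ExpressionMatrix(
            m1.values.iloc[:, perm].copy(), scale="log2"
        )
        d1 = hierarchical_cluster(center_genes(m1), axis="samples")
        d2 = hierarchical_cluster(center_genes(m2), axis="samples")
        p1 = partition_samples(d1, m1, genes).sort_index()
        p2 = partition_samples(d2, m2, genes).sort_index()
        assert (p1 == p2).all()

    def test_degenerate_single_group_all_active(self):
        from immunosig import SimulationConfig

        cfg = SimulationConfig(
            seed=3, n_types=1, samples_per_type=80, active_fraction=1.0
        )
        cohort = simulate_expression(cfg)
        log2 = cohort.truth["log2"]
        focus = list(cohort.truth["membership"])
        d = hierarchical_cluster(center_genes(log2.subset_genes(focus)), axis="samples")
        labels = partition_samples(d, log2, focus)
        assert set(labels) == {"active"}


class TestNewickRoundTrip:
    def test_topology_and_heights_preserved(self, planted_config):
        cohort = simulate_expression(planted_config(seed=2))
        d = hierarchical_cluster(center_genes(cohort.truth["log2"]), axis="genes")
        d2 = from_newick(to_newick(d), axis="genes")
        assert set(d.leaf_sets().values()) == set(d2.leaf_sets().values())
        h1 = sorted(round(m.height, 6) for m in d.merges)
        h2 = sorted(round(m.height, 6) for m in d2.merges)
        assert h1 == h2

    def test_small_tree_exact(self):
        d = Dendrogram(
            leaves=["a", "b", "c"], merges=[Merge(0, 1, 0.25), Merge(3, 2, 1.5)]
        )
        d2 = from_newick(to_newick(d))
        assert set(d2.leaf_sets().values()) == set(d.leaf_sets().values())
        assert [m.height for m in d2.merges] == pytest.approx([0.25, 1.5])
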