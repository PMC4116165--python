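"""Correlation distances, UPGMA linkage (against a brute-force oracle),
tree cutting, gene grouping and representative selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from nemagrn import clustering as cl
from nemagrn import synthetic_data as sd
from nemagrn.quantification import StandardizedProfile


def upgma_bruteforce(D):
    """O(n^3) UPGMA oracle: average distances recomputed from the original
    matrix at every merge; lowest-index pair breaks ties.  Returns the full
    cophenetic matrix (height at which each pair first joins)."""
    D = np.asarray(D, float)
    n = len(D)
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        for x in clusters[a]:
            for y in clusters[b]:
                coph[x, y] = coph[y, x] = d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph


def profiles_from_rows(rows, genes=None, stages=None):
    out = []
    for k, row in enumerate(rows):
        v = np.asarray(row, float)
        v = v / v.max() if v.max() > 0 else v
        out.append(StandardizedProfile(genes[k] if genes else f"g{k}",
                                       stages[k] if stages else 72.0, v))
    return out


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        v = sd.make_template("endodermal").values
        D = cl.correlation_distance(np.vstack([v, v]))
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        x = np.linspace(0, 1, 100)
        D = cl.correlation_distance(np.vstack([x, -x]))
        assert D[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_covariance_oracle(self, rng):
        X = rng.uniform(0, 1, (5, 100))
        D = cl.correlation_distance(X)
        for i in range(5):
            for j in range(5):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(D[i, j] - (1 - r)) < 1e-12

    def test_constant_profile_rejected_with_name(self):
        profs = profiles_from_rows([np.ones(100) * 0.5,
                                    sd.make_template("oral").values],
                                   genes=["flatgene", "okgene"])
        profs[0] = StandardizedProfile("flatgene", 72.0, np.ones(100))
        with pytest.raises(cl.ClusteringError, match="flatgene"):
            cl.correlation_distance(profs)


class TestAverageLinkage:
    def test_hand_computed_three_points(self):
        D = np.array([[0.0, 0.1, 0.5],
                      [0.1, 0.0, 0.5],
                      [0.5, 0.5, 0.0]])
        Z = cl.average_linkage(D)
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.5)

    def test_duplicate_points_merge_first_at_zero(self):
        D = np.array([[0.0, 0.0, 0.9],
                      [0.0, 0.0, 0.9],
                      [0.9, 0.9, 0.0]])
        Z = cl.average_linkage(D)
        assert Z[0, 2] == 0.0

    def test_matches_bruteforce_oracle_random_instances(self):
        """Exact cophenetic agreement with the O(n^3) oracle on 100 random
        instances with up to 8 leaves."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            M = rng.uniform(0.05, 1.5, (n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            Z = cl.average_linkage(D)
            coph = squareform(cophenet(Z))
            np.testing.assert_allclose(coph, upgma_bruteforce(D), rtol=1e-10)

    def test_invariant_to_input_ordering(self, rng):
        n = 7
        M = rng.uniform(0.1, 1.0, (n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        base = squareform(cophenet(cl.average_linkage(D)))
        for _ in range(5):
            perm = rng.permutation(n)
            Dp = D[np.ix_(perm, perm)]
            coph = squareform(cophenet(cl.average_linkage(Dp)))
            np.testing.assert_allclose(coph, base[np.ix_(perm, perm)], rtol=1e-10)


class TestCutTree:
    def test_trivial_cuts(self, rng):
        M = rng.uniform(0.1, 1.0, (6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = cl.average_linkage(D)
        assert len(np.unique(cl.cut_tree(Z, 10.0))) == 1
        assert len(np.unique(cl.cut_tree(Z, 0.0))) == 6

    def test_within_cluster_merges_below_height(self, rng):
        M = rng.uniform(0.1, 1.0, (8, 8))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = cl.average_linkage(D)
        h = float(np.median(Z[:, 2]))
        labels = cl.cut_tree(Z, h)
        coph = squareform(cophenet(Z))
        for lab in np.unique(labels):
            members = np.where(labels == lab)[0]
            for i in members:
                for j in members:
                    assert coph[i, j] <= h + 1e-12

    def test_three_synthetic_clusters_at_default_cut(self):
        """Endodermal / oral / border shapes separate into 3 clusters at the
        0.6 correlation-distance cut."""
        rng = np.random.default_rng(5)
        profs = []
        for kind, count in (("endodermal", 10), ("oral", 7), ("border", 2)):
            t = sd.make_template(kind)
            profs += [sd.sample_profile(t, 0.05, rng, gene=kind) for _ in range(count)]
        result = cl.cluster_profiles(profs, cut_height=0.6)
        labels = result["labels"]
        assert len(np.unique(labels)) == 3
        # each kind lands in a single cluster
        for kind, count in (("endodermal", 10), ("oral", 7), ("border", 2)):
            sub = [lab for lab, p in zip(labels, profs) if p.gene == kind]
            assert len(set(sub)) == 1


class TestNewick:
    def test_export_parses_and_is_ultrametric(self, rng):
        import io
        from Bio import Phylo
        M = rng.uniform(0.1, 1.0, (5, 5))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = cl.average_linkage(D)
        names = [f"leaf{i}" for i in range(5)]
        tree = Phylo.read(io.StringIO(cl.to_newick(Z, names)), "newick")
        depths = tree.depths()
        leaf_depths = [d for cl_, d in depths.items() if cl_.name in names]
        assert len(leaf_depths) == 5
        root_height = Z[-1, 2] / 2
        np.testing.assert_allclose(leaf_depths, root_height, rtol=1e-6)


class TestGeneGroups:
    @pytest.fixture
    def engineered_meta(self):
        rows = [
            # group 1: present at cleavage
            ("matA", "cleavage", 1), ("matA", "gastrula", 1), ("matA", "planula", 1),
            # group 2: gastrula + planula endoderm
            ("endo1", "gastrula", 1), ("endo1", "planula", 1),
            # group 3: gastrula + planula oral
            ("oral1", "gastrula", 2), ("oral1", "planula", 2),
            ("oral2", "gastrula", 2), ("oral2", "planula", 2), ("oral2", "blastula", 2),
            # group 4: absent at gastrula
            ("late1", "planula", 3),
        ]
        meta = pd.DataFrame(rows, columns=["gene", "stage", "cluster"])
        domains = {1: "endoderm", 2: "oral", 3: "oral"}
        return meta, domains

    def test_four_groups_recovered(self, engineered_meta):
        meta, domains = engineered_meta
        table = cl.build_gene_groups(meta, domains)
        got = dict(zip(table["gene"], table["group"]))
        assert got == {"matA": 1, "endo1": 2, "oral1": 3, "oral2": 3, "late1": 4}

    def test_cleavage_gene_is_group_one(self, engineered_meta):
        meta, domains = engineered_meta
        table = cl.build_gene_groups(meta, domains)
        assert table.loc[table["gene"] == "matA", "group"].item() == 1

    def test_absent_at_gastrula_is_group_four(self, engineered_meta):
        meta, domains = engineered_meta
        table = cl.build_gene_groups(meta, domains)
        assert table.loc[table["gene"] == "late1", "group"].item() == 4

    def test_conflicting_planula_clusters_majority_and_tie(self):
        meta = pd.DataFrame([
            ("g", "gastrula", 1), ("g", "planula", 1), ("g", "planula", 1),
            ("g", "planula", 2),
            ("t", "gastrula", 1), ("t", "planula", 1), ("t", "planula", 2),
        ], columns=["gene", "stage", "cluster"])
        domains = {1: "endoderm", 2: "oral"}
        table = cl.build_gene_groups(meta, domains).set_index("gene")
        assert table.loc["g", "group"] == 2  # majority endoderm
        assert table.loc["g", "status"] == "conflict"
        assert table.loc["t", "status"] == "unresolved"

    def test_representative_selection(self):
        table = pd.DataFrame({
            "gene": ["a", "b", "c", "d", "e"],
            "group": [1, 1, 2, 2, 2],
            "n_profiles": [5, 2, 3, 3, 1],
        })
        reps = cl.select_representatives(table)
        assert reps == {1: "a", 2: "c"}  # max count; tie broken lexicographically

    def test_stage_assignment_from_hours(self):
        assert cl.assign_stage(5) == "cleavage"
        assert cl.assign_stage(15) == "blastula"
        assert cl.assign_stage(24) == "gastrula"
        assert cl.assign_stage(72) == "planula"
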