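"""Phylogenetics: GTR+Gamma distances, NJ, bootstrap, divergence dating."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from mitomethyl import phylo, synthetic


# ---------------------------------------------------------------------------
# brute-force topology oracle (exhaustive search over unrooted topologies)
# ---------------------------------------------------------------------------


def enumerate_topologies(labels):
    """All unrooted binary topologies as (edges, nodes) adjacency structures.

    Leaves are label strings; internal nodes are integers. Built by
    sequential insertion of each new leaf into every existing edge.
    """
    a, b, c, *rest = labels
    base_edges = [(a, 0), (b, 0), (c, 0)]
    trees = [(base_edges, 1)]
    for leaf in rest:
        nxt_trees = []
        for edges, n_int in trees:
            for i, (u, v) in enumerate(edges):
                new = n_int
                new_edges = edges[:i] + edges[i + 1:] + [
                    (u, new), (v, new), (leaf, new)
                ]
                nxt_trees.append((new_edges, n_int + 1))
        trees = nxt_trees
    return trees


def topology_splits(edges, labels):
    splits = set()
    for i, (u, v) in enumerate(edges):
        adj = {}
        for j, (x, y) in enumerate(edges):
            if j == i:
                continue
            adj.setdefault(x, []).append(y)
            adj.setdefault(y, []).append(x)
        seen, stack = {u}, [u]
        while stack:
            node = stack.pop()
            for nb in adj.get(node, []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(x for x in seen if isinstance(x, str))
        other = frozenset(labels) - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


def best_topology_by_least_squares(labels, d):
    """Fit branch lengths of every topology by OLS on path distances; return
    the splits of the topology with the smallest residual."""
    pairs = list(itertools.combinations(range(len(labels)), 2))
    best = None
    for edges, _ in enumerate_topologies(labels):
        adj = {}
        for k, (x, y) in enumerate(edges):
            adj.setdefault(x, []).append((y, k))
            adj.setdefault(y, []).append((x, k))

        def path_edges(src, dst):
            stack = [(src, None, [])]
            visited = {src}
            while stack:
                node, _, path = stack.pop()
                if node == dst:
                    return path
                for nb, k in adj[node]:
                    if nb not in visited:
                        visited.add(nb)
                        stack.append((nb, node, path + [k]))
            raise RuntimeError("disconnected topology")

        A = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, (i, j) in enumerate(pairs):
            for k in path_edges(labels[i], labels[j]):
                A[r, k] = 1.0
            y[r] = d[i, j]
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ x - y) ** 2).sum())
        if best is None or resid < best[0]:
            best = (resid, topology_splits(edges, labels))
    return best


def additive_matrix_from_tree(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return d


# ---------------------------------------------------------------------------
# model and distances
# ---------------------------------------------------------------------------


class TestGtrModel:
    def test_rate_matrix_properties(self):
        m = phylo.GtrModel(
            (1.2, 4.0, 0.8, 1.1, 5.0, 1.0), (0.31, 0.26, 0.12, 0.31), 0.3734, 5
        )
        q = m.rate_matrix()
        pi = np.asarray(m.base_freqs)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T)  # reversibility
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)

    def test_gamma_discretisation_mean_one(self):
        rates = phylo.discrete_gamma_rates(0.3734, 5)
        assert rates.shape == (5,)
        assert rates.mean() == pytest.approx(1.0)
        assert (np.diff(rates) > 0).all()
        assert rates[0] < 0.05  # strong rate variation at shape 0.3734

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            phylo.GtrModel(base_freqs=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ValueError):
            phylo.GtrModel(exchangeabilities=(1, 1, 1, 1, 1))

    def test_transition_matrices_are_stochastic(self):
        m = phylo.GtrModel((2.0, 1.0, 3.0, 0.5, 4.0, 1.0), (0.4, 0.2, 0.2, 0.2), 0.5, 4)
        eig = phylo.EigenGtr(m)
        for t in (0.0, 0.01, 0.5, 3.0):
            p = eig.prob(t)
            assert np.all(p >= 0)
            assert np.allclose(p.sum(axis=2), 1.0)


class TestDistances:
    def jc_counts(self, p, n=12000):
        counts = np.full((4, 4), p * n / 12)
        np.fill_diagonal(counts, (1 - p) * n / 4)
        return counts

    def test_identical_sequences_zero_distance(self):
        aln = {"A": "ACGTACGT" * 20, "B": "ACGTACGT" * 20}
        _, d = phylo.pairwise_distances(aln, phylo.GtrModel.jc())
        assert d[0, 1] == 0.0

    @pytest.mark.parametrize("p", [0.05, 0.3, 0.5])
    def test_jc_limit_matches_closed_form(self, p):
        """Under equal rates and frequencies (no +Gamma) the ML distance
        must equal the analytic Jukes-Cantor correction to 1e-9."""
        eig = phylo.EigenGtr(phylo.GtrModel.jc())
        d = phylo.ml_distance(self.jc_counts(p), eig)
        expected = -0.75 * np.log(1 - 4 * p / 3)
        assert abs(d - expected) < 1e-9

    def test_gtr_reduces_to_jc_on_uniform_parameters(self):
        rng = np.random.default_rng(5)
        aln, _ = synthetic.gen_clock_alignment(
            "((A:2.0,B:2.0):2.0,(C:2.0,D:2.0):2.0);",
            phylo.GtrModel.jc(),
            rate=0.03,
            n_sites=4000,
            seed=31,
        )
        labels, d_gtr = phylo.pairwise_distances(aln, phylo.GtrModel.jc())
        for i, j in itertools.combinations(range(4), 2):
            p = np.mean(
                [a != b for a, b in zip(aln[labels[i]], aln[labels[j]])]
            )
            assert abs(d_gtr[i, j] - (-0.75 * np.log(1 - 4 * p / 3))) < 1e-9

    def test_simulated_distance_within_three_se(self):
        aln, _ = synthetic.gen_clock_alignment(
            "(A:5.0,B:5.0);", phylo.GtrModel.jc(), rate=0.01, n_sites=16000, seed=41
        )
        _, d = phylo.pairwise_distances(aln, phylo.GtrModel.jc())
        p = np.mean([a != b for a, b in zip(aln["A"], aln["B"])])
        se = np.sqrt(p * (1 - p) / 16000) / (1 - 4 * p / 3)
        assert abs(d[0, 1] - 0.1) < 3 * se

    def test_saturated_pair_returns_inf(self):
        counts = np.full((4, 4), 100.0)  # random association: saturation
        eig = phylo.EigenGtr(phylo.GtrModel.jc())
        with pytest.warns(UserWarning, match="saturated"):
            assert np.isinf(phylo.ml_distance(counts, eig))

    def test_estimate_gtr_params_recovers_frequencies(self):
        aln = {"A": "AAAACCCCGGTT", "B": "AAAACCCCGGTT"}
        m = phylo.estimate_gtr_params(aln, gamma_shape=None)
        assert np.allclose(m.base_freqs, (4 / 12, 4 / 12, 2 / 12, 2 / 12))


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        labels = ["A", "B", "C", "D"]
        nwk = "((A:1.0,B:2.0):1.0,C:3.0,D:4.0);"
        d = additive_matrix_from_tree(nwk, labels)
        tree = phylo.nj_tree(labels, d)
        # topology vs exhaustive least-squares search
        resid, oracle_splits = best_topology_by_least_squares(labels, d)
        assert resid < 1e-20
        assert phylo.bipartitions(tree) == oracle_splits
        # branch lengths: recovered path distances reproduce the input matrix
        assert np.allclose(
            additive_matrix_from_tree(tree.as_string(schema="newick"), labels), d
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_five_taxon_random_additive_exact(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCDE")
        b = rng.uniform(0.5, 4.0, size=7)
        nwk = (
            f"((A:{b[0]},B:{b[1]}):{b[4]},(C:{b[2]},D:{b[3]}):{b[5]},E:{b[6]});"
        )
        d = additive_matrix_from_tree(nwk, labels)
        tree = phylo.nj_tree(labels, d)
        resid, oracle_splits = best_topology_by_least_squares(labels, d)
        assert resid < 1e-18
        assert phylo.bipartitions(tree) == oracle_splits
        assert np.allclose(
            additive_matrix_from_tree(tree.as_string(schema="newick"), labels), d
        )

    def test_three_taxa_star_exact_lengths(self):
        labels = ["A", "B", "C"]
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = phylo.nj_tree(labels, d)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_matches_dendropy_on_random_matrices(self):
        """Independent cross-check: same splits as dendropy's NJ on noisy
        (non-additive) random distance matrices."""
        import csv
        import io

        rng = np.random.default_rng(3)
        labels = list("ABCDEF")
        for _ in range(3):
            base = additive_matrix_from_tree(
                "(((A:1.0,B:1.4):0.8,(C:0.9,D:1.1):0.7):0.5,E:2.0,F:2.2);", labels
            )
            d = base + rng.uniform(0, 0.05, base.shape)
            d = 0.5 * (d + d.T)
            np.fill_diagonal(d, 0.0)
            buf = io.StringIO()
            w = csv.writer(buf)
            w.writerow([""] + labels)
            for i, lab in enumerate(labels):
                w.writerow([lab] + [f"{x:.12f}" for x in d[i]])
            buf.seek(0)
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
            ref = pdm.nj_tree()
            assert phylo.bipartitions(phylo.nj_tree(labels, d)) == phylo.bipartitions(ref)

    def test_nan_matrix_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            phylo.nj_tree(["A", "B", "C"], d)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


CLEAN_TREE = "((((mus:1.82,spretus:1.82):2.06,dunni:3.88):2.56,pahari:6.44):3.56,rat:10.0);"


@pytest.fixture(scope="module")
def clean_alignment():
    model = phylo.GtrModel(
        (1.2, 4.0, 0.8, 1.1, 5.0, 1.0), (0.31, 0.26, 0.12, 0.31), 0.3734, 5
    )
    aln, ages = synthetic.gen_clock_alignment(
        CLEAN_TREE, model, rate=0.01, n_sites=16300, seed=97
    )
    return aln, ages, model


class TestBootstrap:
    def test_clean_data_full_support(self, clean_alignment):
        aln, _, model = clean_alignment
        tree, support = phylo.bootstrap_support(aln, model, n_reps=200, seed=1)
        assert len(support) == 2  # 5 taxa -> 2 internal edges
        assert all(v == 100.0 for v in support.values())

    def test_zero_reps_empty_support(self, clean_alignment):
        aln, _, model = clean_alignment
        _, support = phylo.bootstrap_support(aln, model, n_reps=0, seed=1)
        assert support == {}

    def test_fixed_seed_reproducible(self, clean_alignment):
        aln, _, model = clean_alignment
        _, s1 = phylo.bootstrap_support(aln, model, n_reps=50, seed=11)
        _, s2 = phylo.bootstrap_support(aln, model, n_reps=50, seed=11)
        assert s1 == s2

    def test_independent_seeds_converge(self):
        """Supports from two independent seeds agree within 2 points at
        1000 replicates (smaller alignment keeps this quick)."""
        model = phylo.GtrModel.jc(gamma_shape=None)
        aln, _ = synthetic.gen_clock_alignment(
            "(((A:1.0,B:1.0):0.6,C:1.6):0.6,D:2.2);", model,
            rate=0.03, n_sites=1500, seed=55,
        )
        _, s1 = phylo.bootstrap_support(aln, model, n_reps=1000, seed=1)
        _, s2 = phylo.bootstrap_support(aln, model, n_reps=1000, seed=2)
        for split, pct in s1.items():
            assert abs(pct - s2[split]) <= 2.0


# ---------------------------------------------------------------------------
# divergence dating
# ---------------------------------------------------------------------------


class TestDivergenceTimes:
    def test_ultrametric_input_heights_exact(self):
        tree = dendropy.Tree.get(data=CLEAN_TREE, schema="newick")
        df = phylo.divergence_times(tree, "rat").set_index("clade")
        assert df.loc["mus;spretus", "rel_height"] == pytest.approx(1.82)
        assert df.loc["dunni;mus;spretus", "rel_height"] == pytest.approx(3.88)
        assert df.loc["dunni;mus;pahari;spretus", "rel_height"] == pytest.approx(6.44)
        # calibration midpoint anchors the root at 10 Mya
        root = df[df["is_calibration"]]
        assert root["age_mya"].iloc[0] == pytest.approx(10.0)
        assert root["age_lo_mya"].iloc[0] == pytest.approx(8.0)
        assert root["age_hi_mya"].iloc[0] == pytest.approx(12.0)

    def test_branch_scale_invariance(self):
        t1 = dendropy.Tree.get(data=CLEAN_TREE, schema="newick")
        scaled = CLEAN_TREE
        for a, b in [("1.82", "5.46"), ("2.06", "6.18"), ("3.88", "11.64"),
                     ("2.56", "7.68"), ("6.44", "19.32"), ("3.56", "10.68"),
                     ("10.0", "30.0")]:
            scaled = scaled.replace(a, b)
        t2 = dendropy.Tree.get(data=scaled, schema="newick")
        a1 = phylo.divergence_times(t1, "rat").set_index("clade")["age_mya"]
        a2 = phylo.divergence_times(t2, "rat").set_index("clade")["age_mya"]
        assert np.allclose(a1, a2)

    def test_ages_decrease_root_to_tips(self, clean_alignment):
        aln, _, model = clean_alignment
        labels, d = phylo.pairwise_distances(aln, model)
        df = phylo.divergence_times(phylo.nj_tree(labels, d), "rat")
        df = df.sort_values("age_mya", ascending=False).reset_index(drop=True)
        sizes = df["clade"].str.count(";")
        assert (np.diff(sizes) <= 0).all()

    def test_missing_outgroup_rejected(self):
        tree = dendropy.Tree.get(data=CLEAN_TREE, schema="newick")
        with pytest.raises(ValueError, match="outgroup"):
            phylo.divergence_times(tree, "hamster")

    def test_clock_simulation_recovers_true_ages(self, clean_alignment):
        """dist -> nj -> dates on a 16.3 kb GTR+Gamma clock simulation
        recovers the planted ages (1.82, 3.88, 6.44, 10 Mya) within 10%."""
        aln, true_ages, model = clean_alignment
        labels, d = phylo.pairwise_distances(aln, model)
        tree = phylo.nj_tree(labels, d)
        df = phylo.divergence_times(tree, "rat", calibration=(8.0, 12.0))
        got = df.set_index("clade")["age_mya"]
        for clade, age in true_ages.items():
            key = ";".join(clade)
            assert abs(got[key] / age - 1) < 0.10, (key, got[key], age)
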