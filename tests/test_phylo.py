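import math

import dendropy
import numpy as np
import pytest

from htrscan.msa_positionmap import Alignment
from htrscan.phylo import (
    DistanceMatrix,
    bootstrap_support,
    find_anchored_clade,
    neighbor_joining,
    protein_distance,
    read_newick,
    tree_bipartitions,
    write_newick,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _aln(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Alignment(ids, rows)


class TestProteinDistance:
    def test_identical_rows_have_zero_distance(self):
        dm = protein_distance(_aln(["ARTK", "ARTK"]))
        assert dm.d[0, 1] == 0.0

    def test_poisson_closed_form(self):
        rows = ["A" * 9 + "C", "A" * 9 + "D"]  # p = 0.1
        dm = protein_distance(_aln(rows), model="poisson")
        assert dm.d[0, 1] == pytest.approx(-math.log(0.9), abs=1e-9)
        assert dm.d[0, 1] == pytest.approx(0.10536, abs=1e-4)

    def test_gamma_converges_to_poisson(self):
        rows = ["A" * 7 + "CDE", "A" * 7 + "DEF"]
        p_pois = protein_distance(_aln(rows), "poisson").d[0, 1]
        p_gam = protein_distance(_aln(rows), "gamma", alpha=1e6).d[0, 1]
        assert abs(p_gam - p_pois) < 1e-5

    def test_pairwise_deletion_skips_gapped_columns(self):
        rows = ["AR-K", "ARTK", "WRTK"]
        dm = protein_distance(_aln(rows))
        assert dm.d[0, 1] == 0.0  # only 3 comparable columns, all equal
        assert dm.d[0, 2] > 0

    def test_saturated_pair_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            protein_distance(_aln(["AAAA", "CCCC"]))

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            protein_distance(_aln(["AA--", "--CC"]))


def _random_additive_tree(n_taxa, rng):
    from htrscan.synthetic_data import random_tree

    tree = random_tree(n_taxa, rng, mean_branch=0.4)
    # strictly positive branch lengths keep the matrix uniquely additive
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) + 0.05
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    d = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
    return tree, DistanceMatrix(ids, d)


def _topology_equal(t1, t2):
    b1 = set(tree_bipartitions(t1))
    b2 = set(tree_bipartitions(t2))
    return b1 == b2


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_additive_eight_taxon_matrix_recovered_exactly(self):
        rng = np.random.default_rng(11)
        true_tree, dm = _random_additive_tree(8, rng)
        est = neighbor_joining(dm)
        assert _topology_equal(true_tree, est)
        # total length preserved to 1e-9
        total_true = sum(e.length or 0.0 for e in true_tree.preorder_edge_iter())
        total_est = sum(e.length or 0.0 for e in est.preorder_edge_iter())
        assert total_est == pytest.approx(total_true, abs=1e-9)

    def test_ultrametric_quartet_matches_least_squares_oracle(self):
        # ((a,b),(c,d)) ultrametric: within-pair 0.2, across 1.0
        d = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        ids = ["a", "b", "c", "d"]
        tree = neighbor_joining(DistanceMatrix(ids, d))
        # brute-force: the best-fitting quartet is ab|cd
        best = _best_quartet_by_least_squares(ids, d)
        got = next(iter(tree_bipartitions(tree)))
        assert {frozenset(best[0]), frozenset(best[1])} == {got, frozenset(ids) - got}

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(21)
        _, dm = _random_additive_tree(7, rng)
        t1 = neighbor_joining(dm)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix([dm.ids[i] for i in perm], dm.d[np.ix_(perm, perm)])
        t2 = neighbor_joining(dm2)
        assert _topology_equal(t1, t2)

    def test_agrees_with_scikit_bio(self):
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(33)
        _, dm = _random_additive_tree(6, rng)
        ours = neighbor_joining(dm)
        sk_tree = skbio_nj(SkbioDM(dm.d, ids=dm.ids))
        sk_dendropy = dendropy.Tree.get(
            data=str(sk_tree.write(io.StringIO()).getvalue()), schema="newick"
        )
        assert _topology_equal(ours, sk_dendropy)


def _best_quartet_by_least_squares(ids, d):
    import itertools

    def fit(split):
        (a, b), (c, d2) = split
        # path-length parameterization; crude least squares on 5 edges
        ia, ib, ic, id_ = (ids.index(x) for x in (a, b, c, d2))
        best = None
        for m in np.linspace(0, 1, 21):
            for ea in np.linspace(0, 1, 21):
                eb = d[ia, ib] - ea
                for ec in np.linspace(0, 1, 21):
                    ed = d[ic, id_] - ec
                    resid = 0.0
                    for (i, x), (j, y) in itertools.product(
                        ((ia, ea), (ib, eb)), ((ic, ec), (id_, ed))
                    ):
                        resid += (d[i, j] - (x + y + m)) ** 2
                    if best is None or resid < best:
                        best = resid
        return best

    splits = [
        ((ids[0], ids[1]), (ids[2], ids[3])),
        ((ids[0], ids[2]), (ids[1], ids[3])),
        ((ids[0], ids[3]), (ids[1], ids[2])),
    ]
    return min(splits, key=fit)


def _two_clade_alignment(rng, n_per_clade=4, n_cols=100, n_diag=20):
    base = rng.choice(list(AA), size=n_cols)
    rows, ids = [], []
    diag_cols = rng.choice(n_cols, size=n_diag, replace=False)
    alt = {c: ("W" if base[c] != "W" else "Y") for c in diag_cols}
    for k in range(n_per_clade):
        row = base.copy()
        noise = rng.integers(0, n_cols)
        row[noise] = "H" if row[noise] != "H" else "Q"
        ids.append(f"cen{k}" if k else "anchor")
        rows.append("".join(row))
    for k in range(n_per_clade):
        row = base.copy()
        for c in diag_cols:
            row[c] = alt[c]
        noise = rng.integers(0, n_cols)
        row[noise] = "N" if row[noise] != "N" else "S"
        ids.append(f"h3_{k}")
        rows.append("".join(row))
    return Alignment(ids, rows)


class TestBootstrap:
    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(2)
        aln = _two_clade_alignment(rng)
        b1 = bootstrap_support(aln, 50, seed=9)
        b2 = bootstrap_support(aln, 50, seed=9)
        assert b1.supports == b2.supports

    def test_two_clade_support_high(self):
        rng = np.random.default_rng(3)
        aln = _two_clade_alignment(rng)
        boot = bootstrap_support(aln, 200, seed=4)
        clade = frozenset(i for i in aln.seq_ids if i.startswith(("cen", "anchor")))
        comp = frozenset(aln.seq_ids) - clade
        support = boot.supports.get(clade, boot.supports.get(comp))
        assert support is not None and support >= 95
        assert all(0 <= s <= 100 for s in boot.supports.values())

    def test_supports_converge_between_500_and_1000_replicates(self):
        rng = np.random.default_rng(6)
        aln = _two_clade_alignment(rng)
        b500 = bootstrap_support(aln, 500, seed=13)
        b1000 = bootstrap_support(aln, 1000, seed=13)
        for key, s500 in b500.supports.items():
            assert abs(b1000.supports[key] - s500) <= 5

    def test_identical_sequences_give_no_supported_edges(self):
        aln = _aln(["ARTKQT"] * 5)
        boot = bootstrap_support(aln, 20, seed=1)
        assert boot.supports == {}

    def test_replicate_count_validated(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            bootstrap_support(_two_clade_alignment(rng), 0, seed=1)


class TestAnchoredClade:
    def _supported_tree(self):
        nwk = "((anchor:0.1,cen1:0.1,cen2:0.1)98:0.3,((h1:0.1,h2:0.1)40:0.1,h3:0.2)30:0.3,h4:0.4);"
        return dendropy.Tree.get(data=nwk, schema="newick", suppress_internal_node_taxa=True)

    def test_returns_supported_anchor_clade(self):
        tree = self._supported_tree()
        assert find_anchored_clade(tree, ["anchor"], 70) == {"anchor", "cen1", "cen2"}

    def test_all_supports_below_threshold_gives_empty(self):
        tree = self._supported_tree()
        assert find_anchored_clade(tree, ["anchor"], 99) == set()

    def test_anchor_with_only_whole_tree_clade_gives_empty(self):
        nwk = "((h1:0.1,h2:0.1)95:0.2,(h3:0.1,h4:0.1)95:0.2,anchor:0.5);"
        tree = dendropy.Tree.get(data=nwk, schema="newick", suppress_internal_node_taxa=True)
        assert find_anchored_clade(tree, ["anchor"], 70) == set()

    def test_missing_anchor_named_in_error(self):
        with pytest.raises(ValueError, match="ghost"):
            find_anchored_clade(self._supported_tree(), ["ghost"], 70)


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self, tmp_path):
        rng = np.random.default_rng(17)
        aln = _two_clade_alignment(rng)
        boot = bootstrap_support(aln, 100, seed=3)
        path = tmp_path / "t.nwk"
        write_newick(boot.tree, path)
        back = read_newick(path)
        assert _topology_equal(boot.tree, back)
        orig = sorted(
            round(e.length, 6) for e in boot.tree.preorder_edge_iter() if e.length is not None
        )
        rt = sorted(round(e.length, 6) for e in back.preorder_edge_iter() if e.length is not None)
        assert rt == orig
        back_supports = sorted(
            float(n.label) for n in back.preorder_node_iter() if n.label and not n.is_leaf()
        )
        assert back_supports == sorted(boot.supports.values())
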