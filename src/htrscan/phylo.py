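"""Distance-based phylogenetics: corrected protein distances, neighbor
joining, column-resampling bootstrap, and anchored clade search.

Distances use pairwise deletion and either a Poisson correction
(d = -ln(1 - p)) or a gamma correction (d = alpha * ((1-p)^(-1/alpha) - 1),
alpha default 1.0) of the proportion of differing sites p. Trees are
dendropy objects; bootstrap supports are stored as internal-node labels so
the newick dialect ``(A:0.1,B:0.2)95:0.05`` round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

_SATURATION = 1.0 - 1e-9


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")


def _row_arrays(alignment) -> np.ndarray:
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows]
    return np.vstack(rows)


def protein_distance(alignment, model: str = "poisson", alpha: float = 1.0) -> DistanceMatrix:
    """Pairwise corrected distances with pairwise deletion.

    Columns gapped in either member of a pair are skipped for that pair
    only. Saturated pairs (p at or beyond the correction's domain) raise,
    as do pairs with no comparable columns.
    """
    if len(alignment.rows) < 2:
        raise ValueError("need >= 2 rows")
    if model not in ("poisson", "gamma"):
        raise ValueError(f"unknown distance model {model!r}")
    mat = _row_arrays(alignment)
    gaps = mat == b"-"
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = ~(gaps[i] | gaps[j])
            compared = int(keep.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.seq_ids[i]!r} and {alignment.seq_ids[j]!r}"
                )
            p = float((mat[i, keep] != mat[j, keep]).sum()) / compared
            if p >= _SATURATION:
                raise ValueError(
                    f"saturated pair: {alignment.seq_ids[i]!r} vs {alignment.seq_ids[j]!r} (p = {p:.3f})"
                )
            if model == "poisson":
                dist = -np.log(1.0 - p)
            else:
                dist = alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(alignment.seq_ids), d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Join ties are broken by the smallest (i, j) index pair in node-creation
    order; negative branch lengths are clamped to zero with the deficit
    moved to the sibling branch. Additive matrices are recovered exactly
    (topology and branch lengths). The returned tree is unrooted with a
    trifurcating seed node.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    ns = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=ns)

    nodes: list[dendropy.Node] = []
    for label in dm.ids:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)
    # active entries: (creation_order, node); distances in a dict-of-dict on ids
    active = list(range(n))
    dist = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n) if i < j}
    next_id = n

    def get_d(a: int, b: int) -> float:
        return 0.0 if a == b else dist[(min(a, b), max(a, b))]

    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {a: sum(get_d(a, b) for b in active) for a in active}
        best = None
        best_pair = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * get_d(a, b) - r[a] - r[b]
                if best is None or q < best - 1e-12:
                    best = q
                    best_pair = (a, b)
        a, b = best_pair
        dab = get_d(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0.0:
            lb += -la  # move the deficit to the sibling
            la = 0.0
        if lb < 0.0:
            la += -lb
            lb = 0.0
        parent = dendropy.Node()
        parent.add_child(node_of[a])
        node_of[a].edge.length = la
        parent.add_child(node_of[b])
        node_of[b].edge.length = lb
        node_of[next_id] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (get_d(a, c) + get_d(b, c) - dab)
            dist[(min(next_id, c), max(next_id, c))] = duc
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (get_d(a, b) + get_d(a, c) - get_d(b, c))
    lb = 0.5 * (get_d(a, b) + get_d(b, c) - get_d(a, c))
    lc = 0.5 * (get_d(a, c) + get_d(b, c) - get_d(a, b))
    root = tree.seed_node
    for x, lx in ((a, la), (b, lb), (c, lc)):
        root.add_child(node_of[x])
        node_of[x].edge.length = max(lx, 0.0)
    tree.is_rooted = False
    return tree


def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def tree_bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial bipartitions as (canonical smaller-side-or-child) leafsets.

    Keyed by the side NOT containing the alphabetically first taxon, so two
    trees over the same taxa index bipartitions identically.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(all_leaves)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            continue
        key = side if anchor not in side else all_leaves - side
        out[key] = node
    return out


@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_skipped: int

    @property
    def skip_rate(self) -> float:
        return self.n_skipped / self.n_replicates if self.n_replicates else 0.0


def bootstrap_support(
    alignment,
    n_replicates: int,
    seed: int,
    model: str = "poisson",
    alpha: float = 1.0,
) -> BootstrapResult:
    """NJ tree with column-resampling bootstrap supports.

    Columns are resampled with replacement per replicate; replicates whose
    distance computation saturates (or loses all comparable columns for a
    pair) are skipped and counted. Support = 100 x bipartition frequency
    over successful replicates, written onto internal-node labels of the
    full-alignment tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(alignment.rows) < 4:
        raise ValueError("bootstrap needs >= 4 rows")
    rng = np.random.default_rng(seed)
    base = neighbor_joining(protein_distance(alignment, model, alpha))
    # zero-length internal edges are unresolved (e.g. identical sequences):
    # they carry no supportable bipartition
    bips = {
        key: node
        for key, node in tree_bipartitions(base).items()
        if node.edge.length is not None and node.edge.length > 0.0
    }
    counts = {key: 0 for key in bips}
    ncol = alignment.column_count
    mat = _row_arrays(alignment)
    skipped = 0
    successes = 0
    ids = list(alignment.seq_ids)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row) for row in mat[:, cols].astype("U1")]
        rep = type(alignment)(ids, rep_rows)
        try:
            rep_tree = neighbor_joining(protein_distance(rep, model, alpha))
        except ValueError:
            skipped += 1
            continue
        successes += 1
        rep_bips = tree_bipartitions(rep_tree)
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    supports: dict[frozenset[str], float] = {}
    for key, node in bips.items():
        sup = 100.0 * counts[key] / successes if successes else 0.0
        supports[key] = sup
        node.label = f"{sup:g}"
    return BootstrapResult(base, supports, n_replicates, skipped)


def supported_clades(tree: dendropy.Tree) -> list[tuple[frozenset[str], float]]:
    """(leafset, support) for every internal clade of the midpoint-rooted
    tree that carries a bootstrap support.

    NJ trees are unrooted; which groups appear as subtrees depends on the
    arbitrary seed-node placement, so clades are read off the
    midpoint-rooted topology (the field's standard display rooting).
    Supports are properties of bipartitions and therefore rooting-
    invariant; they are looked up by bipartition key, never carried
    through the rerooting. The whole-tree leaf set is never yielded.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(all_leaves)
    supports: dict[frozenset[str], float] = {}
    for key, node in tree_bipartitions(tree).items():
        sup = _node_support(node)
        if sup is not None:
            supports[key] = sup
    rooted = tree.clone(depth=1)
    try:
        rooted.reroot_at_midpoint(update_bipartitions=False)
    except (AssertionError, ValueError):  # degenerate lengths; keep rooting
        pass
    out = []
    for node in rooted.preorder_node_iter():
        if node is rooted.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if len(side) <= 1 or len(side) >= len(all_leaves):
            continue
        key = side if anchor not in side else all_leaves - side
        if key in supports:
            out.append((side, supports[key]))
    return out


def find_anchored_clade(
    tree: dendropy.Tree, anchor_ids: list[str], min_support: float
) -> set[str]:
    """Smallest supported clade containing every anchor.

    Clades are subtrees of the midpoint-rooted tree (see
    ``supported_clades``); the whole-tree "clade" is excluded, and leaf
    edges carry no support. Returns the clade's leaf set, or an empty set
    when none qualifies.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for a in anchor_ids:
        if a not in leaves:
            raise ValueError(f"anchor {a!r} missing from tree")
    anchors = set(anchor_ids)
    best: frozenset[str] | None = None
    for side, support in supported_clades(tree):
        if support < min_support:
            continue
        if anchors <= side and len(side) < len(leaves):
            if best is None or (len(side), sorted(side)) < (len(best), sorted(best)):
                best = side
    return set(best) if best is not None else set()


def _node_support(node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(as_newick(tree) + "\n")


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    ).strip()


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", suppress_internal_node_taxa=True)
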