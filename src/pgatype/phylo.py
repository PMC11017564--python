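"""Per-enzyme alignments, p-distances, neighbor-joining and bootstrap.

Tree inference here is deliberately distance-based: progressive profile
alignment (UPGMA guide tree), pairwise-deletion p-distance and Saitou-Nei
neighbor joining with column-resampling bootstrap.  Distance NJ is exact
on additive matrices and reproducible bit-for-bit, which is what the
downstream diversity summaries need; likelihood inference is out of scope.

Newick serialisation is delegated to dendropy; bootstrap supports travel
as internal-node labels.
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage

from .align import DEFAULT_SCHEME, ScoringScheme, _fill_global, _load_matrix, _traceback_ops, align_pair
from .errors import PgatypeError, ValidationError


@dataclasses.dataclass
class MSA:
    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValidationError("labels/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_fasta(self) -> str:
        return "".join(f">{l}\n{r}\n" for l, r in zip(self.labels, self.rows))


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(columns, 26) residue counts; gaps contribute nothing."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    counts = np.zeros((arr.shape[1], 26))
    for r in range(arr.shape[0]):
        idx = arr[r] - 65
        ok = (idx >= 0) & (idx < 26)
        np.add.at(counts, (np.nonzero(ok)[0], idx[ok]), 1.0)
    return counts


def _align_profiles(rows_a: list[str], rows_b: list[str], scheme: ScoringScheme):
    """Profile-profile global alignment; column score is the summed
    substitution score over all residue pairs across the two profiles."""
    mat = _load_matrix(scheme.matrix).astype(float)
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    S = ca @ mat @ cb.T
    # gap penalties scale with the number of cross-profile sequence pairs so
    # the DP objective tracks the sum-of-pairs score of the merged alignment
    npairs = float(len(rows_a) * len(rows_b))
    go, ge = scheme.gap_open * npairs, scheme.gap_extend * npairs
    M, X, Y = _fill_global(S, go, ge)
    ops = _traceback_ops(M, X, Y, go, ge)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("M", "Y"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def build_msa(seqs: dict[str, str], scheme: ScoringScheme = DEFAULT_SCHEME) -> MSA:
    """Progressive multiple alignment.

    Pairwise global identities give a distance matrix, average-linkage
    (UPGMA) gives the guide tree, and profiles are merged bottom-up with
    the same affine-gap recurrence used for pairwise alignment.
    """
    labels = list(seqs)
    if len(labels) < 2:
        raise PgatypeError("build_msa needs at least 2 sequences")
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[labels[i]], seqs[labels[j]]
            ident = 1.0 if a == b else align_pair(a, b, scheme).identity
            dist[i, j] = dist[j, i] = 1.0 - ident
    condensed = dist[np.triu_indices(n, k=1)]
    merges = linkage(condensed, method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[labels[i]]]) for i in range(n)
    }
    for step, (a, b, _d, _cnt) in enumerate(merges):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        new_a, new_b = _align_profiles(rows_a, rows_b, scheme)
        clusters[n + step] = (idx_a + idx_b, new_a + new_b)
    (order, rows), = clusters.values()
    # restore input order
    by_index = dict(zip(order, rows))
    return MSA(labels=labels, rows=[by_index[i] for i in range(n)])


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape mismatch")
        if np.abs(v - v.T).max(initial=0.0) > 1e-9:
            raise ValidationError("distance matrix asymmetric beyond 1e-9")
        self.values = v

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            lines.append(label + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def pdistance_matrix(msa: MSA) -> DistanceMatrix:
    """Pairwise-deletion p-distance: mismatches / columns where neither
    row is gapped."""
    arr = np.frombuffer("".join(msa.rows).encode(), dtype=np.uint8).reshape(
        len(msa.rows), -1
    )
    gap = arr == ord("-")
    n = len(msa.rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            total = int(both.sum())
            if total == 0:
                raise PgatypeError(
                    f"no comparable columns between {msa.labels[i]} and {msa.labels[j]}"
                )
            mism = int((arr[i][both] != arr[j][both]).sum())
            out[i, j] = out[j, i] = mism / total
    return DistanceMatrix(list(msa.labels), out)


@dataclasses.dataclass
class PhyloTree:
    """Unrooted tree (stored with a trifurcating root), branch lengths >= 0.

    ``clamped`` records raw negative NJ branch estimates that were clamped
    to zero; ``supports`` maps internal splits to bootstrap percentages.
    """

    tree: dendropy.Tree
    clamped: list[float] = dataclasses.field(default_factory=list)
    supports: dict[frozenset, float] = dataclasses.field(default_factory=dict)

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        out = cls(tree=tree)
        out.supports = {
            split: float(sup) for split, sup in _read_support_labels(tree).items()
        }
        return out

    def path_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.distance(ta, tb)


def _leafset(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def nontrivial_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Internal splits as normalised leaf-label sets (side excluding the
    alphabetically first leaf)."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = _leafset(node)
        side = below if anchor not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def _read_support_labels(tree: dendropy.Tree) -> dict[frozenset, float]:
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if not all_leaves:
        return {}
    anchor = min(all_leaves)
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf() or node.label is None:
            continue
        below = _leafset(node)
        side = below if anchor not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = float(node.label)
    return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaks.

    Candidate pairs are scanned in stable node order (input label order,
    then creation order), keeping the first strict minimum of the
    Q-criterion.  Negative branch estimates are clamped to zero with the
    raw value retained in ``clamped``.
    """
    labels = dm.labels
    n = len(labels)
    if n < 2:
        raise PgatypeError("neighbor_joining needs at least 2 taxa")
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    clamped: list[float] = []

    def make_leaf(label):
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        return node

    def set_len(node, value):
        if value < -1e-12:
            clamped.append(float(value))
            value = 0.0
        node.edge.length = max(float(value), 0.0)

    nodes = [make_leaf(l) for l in labels]
    D = dm.values.copy()
    active = list(range(n))

    if n == 2:
        root = dendropy.Node()
        for node, ln in zip(nodes, (D[0, 1] / 2.0, D[0, 1] / 2.0)):
            root.add_child(node)
            set_len(node, ln)
        tree.seed_node = root
        tree.update_taxon_namespace()
        return PhyloTree(tree=tree, clamped=clamped)

    next_id = n
    Dfull = np.zeros((n + max(n - 3, 0), n + max(n - 3, 0)))
    Dfull[:n, :n] = D
    while len(active) > 3:
        r = len(active)
        sub = Dfull[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        best = None
        for ai in range(r):
            for bj in range(ai + 1, r):
                q = (r - 2) * sub[ai, bj] - rowsum[ai] - rowsum[bj]
                if best is None or q < best[0] - 1e-15:
                    best = (q, ai, bj)
        _q, ai, bj = best
        i, j = active[ai], active[bj]
        dij = Dfull[i, j]
        li = dij / 2.0 + (rowsum[ai] - rowsum[bj]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        set_len(nodes[i], li)
        parent.add_child(nodes[j])
        set_len(nodes[j], lj)
        nodes.append(parent)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            Dfull[u, k] = Dfull[k, u] = 0.5 * (Dfull[i, k] + Dfull[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    root = dendropy.Node()
    a, b, c = active
    la = 0.5 * (Dfull[a, b] + Dfull[a, c] - Dfull[b, c])
    lb = 0.5 * (Dfull[a, b] + Dfull[b, c] - Dfull[a, c])
    lc = 0.5 * (Dfull[a, c] + Dfull[b, c] - Dfull[a, b])
    for k, ln in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[k])
        set_len(nodes[k], ln)
    tree.seed_node = root
    tree.update_taxon_namespace()
    tree.update_bipartitions(suppress_unifurcations=False)
    return PhyloTree(tree=tree, clamped=clamped)


def bootstrap_support(
    msa: MSA, replicates: int, seed: int, scheme: ScoringScheme = DEFAULT_SCHEME
) -> PhyloTree:
    """Column-resampling bootstrap on the NJ tree of an alignment.

    Support of each internal split of the full-data tree = percentage of
    replicate NJ trees containing it; supports are written onto the
    internal node labels so they survive Newick round-trips.
    """
    if replicates < 1:
        raise PgatypeError("replicates must be >= 1")
    full = neighbor_joining(pdistance_matrix(msa))
    target_splits = nontrivial_splits(full.tree)
    hits = {s: 0 for s in target_splits}
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    ncol = msa.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep = neighbor_joining(pdistance_matrix(MSA(list(msa.labels), rows)))
        rep_splits = nontrivial_splits(rep.tree)
        for s in target_splits:
            if s in rep_splits:
                hits[s] += 1
    full.supports = {s: 100.0 * h / replicates for s, h in hits.items()}
    all_leaves = frozenset(full.leaf_labels())
    anchor = min(all_leaves)
    for node in full.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = _leafset(node)
        side = below if anchor not in below else all_leaves - below
        if side in full.supports:
            node.label = f"{full.supports[side]:g}"
    return full


def count_variants(seqs: dict[str, str]) -> int:
    """Number of distinct sequences (haplotypes) in a panel."""
    if not seqs:
        raise PgatypeError("count_variants needs at least 1 sequence")
    return len(set(seqs.values()))
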