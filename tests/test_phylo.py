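"""Progressive MSA, p-distances, neighbor joining and bootstrap."""

import itertools
import random

import dendropy
import numpy as np
import pytest

from pgatype.errors import PgatypeError, ValidationError
from pgatype.phylo import (
    MSA,
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    build_msa,
    count_variants,
    neighbor_joining,
    nontrivial_splits,
    pdistance_matrix,
)
from pgatype.align import DEFAULT_SCHEME
from pgatype.simulate import random_protein, _rng


# ---------------------------------------------------------------------- MSA

def test_identical_pair_aligns_gap_free():
    msa = build_msa({"a": "MKVLACDEFG", "b": "MKVLACDEFG"})
    assert msa.rows[0] == msa.rows[1] == "MKVLACDEFG"


def test_truncated_sequence_gets_one_terminal_gap():
    msa = build_msa({"a": "ACDE", "b": "ACDE", "c": "ACD"})
    by_label = dict(zip(msa.labels, msa.rows))
    assert by_label["a"] == "ACDE" and by_label["b"] == "ACDE"
    assert by_label["c"] == "ACD-"


def _sp_score(rows, scheme=DEFAULT_SCHEME):
    """Sum-of-pairs score of an MSA under the package's gap convention."""
    mat = scheme.score_matrix()
    total = 0
    for ra, rb in itertools.combinations(rows, 2):
        prev = "M"
        for x, y in zip(ra, rb):
            if x == "-" and y == "-":
                continue
            if x != "-" and y != "-":
                total += mat[ord(x) - 65, ord(y) - 65]
                prev = "M"
            elif y == "-":
                total += scheme.gap_extend if prev == "X" else scheme.gap_open
                prev = "X"
            else:
                total += scheme.gap_extend if prev == "Y" else scheme.gap_open
                prev = "Y"
    return total


def _star_alignment(seqs, scheme=DEFAULT_SCHEME):
    """Naive star alignment around the centroid (the sequence with the
    highest summed pairwise score), merged by centroid coordinates."""
    from pgatype.align import align_pair

    labels = list(seqs)
    sums = {
        a: sum(align_pair(seqs[a], seqs[b], scheme).score for b in labels if b != a)
        for a in labels
    }
    center = max(labels, key=lambda l: (sums[l], l))
    others = [l for l in labels if l != center]
    aligned = {}
    # collect per-pair alignments, then thread onto common centroid columns
    pair_alns = {o: align_pair(seqs[center], seqs[o], scheme) for o in others}
    # insertion counts relative to centroid positions (gaps in centroid)
    max_ins = [0] * (len(seqs[center]) + 1)
    for res in pair_alns.values():
        pos = 0
        run = 0
        for c in res.aligned_a:
            if c == "-":
                run += 1
            else:
                max_ins[pos] = max(max_ins[pos], run)
                run = 0
                pos += 1
        max_ins[pos] = max(max_ins[pos], run)

    def thread(aligned_center, aligned_other):
        out = []
        pos = 0
        run = []
        for x, y in zip(aligned_center, aligned_other):
            if x == "-":
                run.append(y)
            else:
                out.append("-" * (max_ins[pos] - len(run)) + "".join(run))
                run = []
                out.append(y)
                pos += 1
        out.append("-" * (max_ins[pos] - len(run)) + "".join(run))
        return "".join(out)

    rows = {}
    # centroid row: no gaps of its own beyond the shared insertion columns
    center_row = []
    for pos, ch in enumerate(seqs[center]):
        center_row.append("-" * max_ins[pos])
        center_row.append(ch)
    center_row.append("-" * max_ins[len(seqs[center])])
    rows[center] = "".join(center_row)
    for o in others:
        rows[o] = thread(pair_alns[o].aligned_a, pair_alns[o].aligned_b)
    return [rows[l] for l in labels]


def test_progressive_alignment_beats_star_oracle_on_homolog_triples():
    """On triples of point-mutated homologs (the package's use case) the
    progressive alignment scores at least as well as a naive star
    alignment around the centroid."""
    from pgatype.simulate import random_protein, _rng

    for t in range(25):
        base = random_protein(30, _rng(70, t))
        seqs = {}
        for k, name in enumerate("abc"):
            s = list(base)
            rng = random.Random(t * 3 + k)
            for pos in rng.sample(range(30), 4):
                s[pos] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
            seqs[name] = "".join(s)
        msa = build_msa(seqs)
        star_rows = _star_alignment(seqs)
        assert len({len(r) for r in star_rows}) == 1
        assert _sp_score(msa.rows) >= _sp_score(star_rows)


def test_msa_structurally_valid_on_arbitrary_triples():
    rng = random.Random(13)
    for _ in range(25):
        seqs = {
            name: "".join(rng.choice("ACDE") for _ in range(rng.randint(2, 6)))
            for name in ("a", "b", "c")
        }
        msa = build_msa(seqs)
        assert len({len(r) for r in msa.rows}) == 1
        for label, row in zip(msa.labels, msa.rows):
            assert row.replace("-", "") == seqs[label]
        # no column is entirely gaps
        for col in zip(*msa.rows):
            assert set(col) != {"-"}


def test_single_sequence_rejected():
    with pytest.raises(PgatypeError):
        build_msa({"a": "ACDE"})


# ----------------------------------------------------------------- distances

def test_pdistance_trivial_and_counting_oracle():
    msa = MSA(["a", "b"], ["ACDE", "ACDA"])
    assert pdistance_matrix(msa).values[0, 1] == 0.25
    msa2 = MSA(["a", "b"], ["ACDE", "ACDE"])
    assert pdistance_matrix(msa2).values[0, 1] == 0.0
    rng = random.Random(3)
    rows = []
    for _ in range(4):
        rows.append("".join(rng.choice("ACDE-") for _ in range(40)))
    rows = [r if r.replace("-", "") else "A" * 40 for r in rows]
    try:
        dm = pdistance_matrix(MSA(list("wxyz"), rows))
    except PgatypeError:
        return  # a fully-gapped pair is a legal error path
    for i in range(4):
        for j in range(4):
            comparable = [
                (x, y) for x, y in zip(rows[i], rows[j]) if x != "-" and y != "-"
            ]
            expect = sum(1 for x, y in comparable if x != y) / len(comparable) if comparable else 0
            assert dm.values[i, j] == pytest.approx(expect)


def test_pdistance_zero_comparable_columns_names_pair():
    msa = MSA(["left", "right"], ["AC--", "--DE"])
    with pytest.raises(PgatypeError, match="left.*right"):
        pdistance_matrix(msa)


def test_asymmetric_matrix_rejected():
    vals = np.array([[0.0, 0.1], [0.2, 0.0]])
    with pytest.raises(ValidationError):
        DistanceMatrix(["a", "b"], vals)


# ------------------------------------------------------------------------ NJ

def test_three_taxon_closed_form():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]))
    tree = neighbor_joining(dm)
    root = tree.tree.seed_node
    lengths = {ch.taxon.label: ch.edge.length for ch in root.child_nodes()}
    assert lengths["A"] == pytest.approx(0.1, abs=1e-9)
    assert lengths["B"] == pytest.approx(0.1, abs=1e-9)
    assert lengths["C"] == pytest.approx(0.3, abs=1e-9)


def test_two_taxon_degenerate_tree():
    dm = DistanceMatrix(["A", "B"], np.array([[0, 0.3], [0.3, 0]]))
    tree = neighbor_joining(dm)
    assert tree.path_distance("A", "B") == pytest.approx(0.3, abs=1e-12)


def random_additive_tree(n_leaves, rng):
    """Test-side oracle: random topology with known branch lengths, plus
    its exact leaf-to-leaf path-distance matrix."""
    taxa = [f"T{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    # start from a 3-leaf star, attach remaining leaves to random edges
    root = tree.seed_node
    leaves = []
    for t in taxa[:3]:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(t)
        node.edge.length = rng.uniform(0.05, 0.5)
        root.add_child(node)
        leaves.append(node)
    for t in taxa[3:]:
        edges = [n.edge for n in tree.preorder_node_iter() if n.parent_node is not None]
        edge = rng.choice(edges)
        child = edge.head_node
        parent = edge.tail_node
        split = dendropy.Node()
        old_len = child.edge.length
        f = rng.uniform(0.25, 0.75)
        parent.remove_child(child)
        parent.add_child(split)
        split.edge.length = old_len * f
        split.add_child(child)
        child.edge.length = old_len * (1 - f)
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(t)
        leaf.edge.length = rng.uniform(0.05, 0.5)
        split.add_child(leaf)
    tree.update_taxon_namespace()
    pdm = tree.phylogenetic_distance_matrix()
    mat = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
                mat[i, j] = mat[j, i] = d
    return taxa, tree, mat


@pytest.mark.parametrize("n_leaves", [4, 6, 8])
def test_nj_recovers_additive_trees(n_leaves):
    rng = random.Random(100 + n_leaves)
    for _ in range(10):
        taxa, true_tree, mat = random_additive_tree(n_leaves, rng)
        est = neighbor_joining(DistanceMatrix(taxa, mat))
        assert nontrivial_splits(est.tree) == nontrivial_splits(true_tree)
        pdm = est.tree.phylogenetic_distance_matrix()
        tns = est.tree.taxon_namespace
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    d = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
                    assert d == pytest.approx(mat[i, j], abs=1e-9)


def test_negative_branch_estimates_are_clamped():
    # a triangle-inequality violation forces a negative branch estimate
    labels = list("ABC")
    m = np.array(
        [
            [0.0, 0.1, 0.4],
            [0.1, 0.0, 0.2],
            [0.4, 0.2, 0.0],
        ]
    )
    tree = neighbor_joining(DistanceMatrix(labels, m))
    lengths = [
        n.edge.length for n in tree.tree.preorder_node_iter() if n.parent_node is not None
    ]
    assert all(l >= 0 for l in lengths)
    assert tree.clamped  # the raw negative estimate is retained


# ------------------------------------------------------------------ bootstrap

def _diagnostic_msa(n_cols=200):
    """4 taxa, conflict-free signal grouping (a,b) vs (c,d)."""
    rows = {"a": [], "b": [], "c": [], "d": []}
    for k in range(n_cols):
        if k % 2 == 0:
            rows["a"].append("A"); rows["b"].append("A")
            rows["c"].append("C"); rows["d"].append("C")
        else:
            for t in rows:
                rows[t].append("G")
    return MSA(list(rows), ["".join(v) for v in rows.values()])


def test_conflict_free_bootstrap_gives_full_support():
    msa = _diagnostic_msa()
    tree = bootstrap_support(msa, replicates=200, seed=11)
    assert tree.supports and all(s == 100.0 for s in tree.supports.values())


def test_bootstrap_reproducible_for_same_seed():
    msa = _diagnostic_msa(80)
    t1 = bootstrap_support(msa, replicates=300, seed=42)
    t2 = bootstrap_support(msa, replicates=300, seed=42)
    assert t1.supports == t2.supports
    assert t1.to_newick() == t2.to_newick()


def test_planted_conflict_support_matches_direct_simulation():
    """3:1 column conflict: bootstrap support of the majority split should
    match the multinomial expectation simulated independently."""
    n_ab, n_ac, n_const = 120, 40, 40
    rows = {"a": [], "b": [], "c": [], "d": []}
    for _ in range(n_ab):  # supports ab|cd
        rows["a"].append("A"); rows["b"].append("A"); rows["c"].append("C"); rows["d"].append("C")
    for _ in range(n_ac):  # supports ac|bd
        rows["a"].append("A"); rows["c"].append("A"); rows["b"].append("C"); rows["d"].append("C")
    for _ in range(n_const):
        for t in rows:
            rows[t].append("G")
    msa = MSA(list(rows), ["".join(v) for v in rows.values()])
    tree = bootstrap_support(msa, replicates=1000, seed=42)
    support = tree.supports[frozenset({"c", "d"})]
    # independent oracle: resample column categories, majority wins
    rng = np.random.default_rng(7)
    ncol = n_ab + n_ac + n_const
    p = np.array([n_ab, n_ac, n_const]) / ncol
    draws = rng.multinomial(ncol, p, size=20000)
    wins = (draws[:, 0] > draws[:, 1]).mean() + 0.5 * (draws[:, 0] == draws[:, 1]).mean()
    assert support == pytest.approx(100 * wins, abs=5)


def test_bad_replicate_count_rejected():
    with pytest.raises(PgatypeError):
        bootstrap_support(_diagnostic_msa(10), replicates=0, seed=1)


# -------------------------------------------------------------------- newick

def test_newick_round_trip_preserves_everything():
    msa = _diagnostic_msa(60)
    tree = bootstrap_support(msa, replicates=50, seed=3)
    text = tree.to_newick()
    back = PhyloTree.from_newick(text)
    assert nontrivial_splits(back.tree) == nontrivial_splits(tree.tree)
    assert back.supports == tree.supports
    for a, b in itertools.combinations("abcd", 2):
        assert back.path_distance(a, b) == pytest.approx(tree.path_distance(a, b), abs=1e-9)


def test_count_variants():
    assert count_variants({f"s{i}": "MKV" for i in range(5)}) == 1
    assert count_variants({"a": "A", "b": "A", "c": "B", "d": "C"}) == 3
    k = 7
    seqs = {}
    for i in range(20):
        seqs[f"s{i}"] = random_protein(30, _rng(60, i % k))
    assert count_variants(seqs) == k
    with pytest.raises(PgatypeError):
        count_variants({})
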