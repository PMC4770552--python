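"""Distance policies, NJ exactness on additive matrices, bootstrap, newick."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import random_additive_tree, tree_path_distances
from nirktools.phylogeny import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    to_newick,
)
from nirktools.sequence_io import Alignment


def test_identical_rows_give_zero_distances():
    aln = Alignment(["a", "b", "c"], ["ACDE", "ACDE", "ACDE"])
    dm = distance_matrix(aln)
    assert np.all(dm.matrix == 0)


def test_complete_deletion_drops_gapped_column():
    aln = Alignment(["a", "b"], ["AC-D", "AAAD"])
    dm = distance_matrix(aln, "count_differences", "complete")
    assert dm.matrix[0, 1] == 1  # column 3 removed, only column 2 differs
    dmp = distance_matrix(aln, "p_distance", "complete")
    assert dmp.matrix[0, 1] == pytest.approx(1 / 3)


def test_pairwise_deletion_uses_per_pair_columns():
    aln = Alignment(["a", "b", "c"], ["AC-D", "AAAD", "A-AD"])
    dm = distance_matrix(aln, "count_differences", "pairwise")
    assert dm.matrix[0, 1] == 1  # 3 shared columns, 1 differs
    assert dm.matrix[0, 2] == 0  # shared columns: 1 and 4, both equal


def test_all_gapped_columns_rejected():
    aln = Alignment(["a", "b"], ["A-", "-A"])
    with pytest.raises(ValueError, match="complete deletion"):
        distance_matrix(aln)


def test_random_alignment_distances_match_recount():
    rng = np.random.default_rng(4)
    rows = ["".join(rng.choice(list("ACDE-"), size=40)) for _ in range(4)]
    aln = Alignment(list("abcd"), rows)
    dm = distance_matrix(aln, "count_differences", "complete")
    keep = [k for k in range(40) if all(r[k] != "-" for r in rows)]
    for i in range(4):
        for j in range(4):
            expected = sum(rows[i][k] != rows[j][k] for k in keep)
            assert dm.matrix[i, j] == expected


def test_nj_four_taxon_closed_form():
    ids = list("ABCD")
    D = np.array(
        [[0, 3, 4, 5], [3, 0, 5, 6], [4, 5, 0, 5], [5, 6, 5, 0]], dtype=float
    )
    tree = neighbor_joining(DistanceMatrix(ids, D))
    assert tree.bipartitions() == {frozenset("AB")}
    dists = tree_path_distances(tree)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            assert dists[frozenset((a, b))] == pytest.approx(D[ids.index(a), ids.index(b)])


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(list("ABC"), D))
    lengths = {c.label: ln for c, ln in tree.root.children}
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0), "C": pytest.approx(2.0)}


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


@pytest.mark.parametrize("n", [4, 6, 8, 10])
def test_nj_exact_recovery_on_random_additive_matrices(n):
    for trial in range(5):
        rng = np.random.default_rng(100 * n + trial)
        ids, D, true_splits = random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(ids, D))
        assert tree.bipartitions() == true_splits
        dists = tree_path_distances(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert dists[frozenset((ids[i], ids[j]))] == pytest.approx(
                    D[i, j], abs=1e-9
                )


def test_negative_branch_clamped_non_negative():
    # non-additive matrix known to produce a negative NJ branch estimate
    D = np.array(
        [
            [0, 1, 6, 6],
            [1, 0, 6, 6],
            [6, 6, 0, 1],
            [6, 6, 1, 0],
        ],
        dtype=float,
    )
    D[0, 1] = D[1, 0] = 5.9  # perturb to break additivity
    tree = neighbor_joining(DistanceMatrix(list("ABCD"), D))

    def walk(node):
        for child, ln in node.children:
            assert ln >= 0
            walk(child)

    walk(tree.root)


def test_bootstrap_full_support_for_clean_split():
    aln = Alignment(
        list("ABCD"),
        ["AAAAAAAA", "AAAAAAAA", "TTTTTTTT", "TTTTTTTT"],
    )
    tree = bootstrap_support(aln, replicates=50, seed=0)

    def supports(node, acc):
        if node.support is not None:
            acc.append(node.support)
        for child, _ in node.children:
            supports(child, acc)
        return acc

    vals = supports(tree.root, [])
    assert vals and all(v == pytest.approx(100.0) for v in vals)


def test_bootstrap_deterministic_under_seed(clean_set):
    records, _, ref = clean_set
    from nirktools.reference_mapping import map_to_reference, stack_alignment

    maps = [map_to_reference(r, ref) for r in records[:8]]
    aln = stack_alignment(records[:8], maps)
    t1 = bootstrap_support(aln, replicates=30, seed=42)
    t2 = bootstrap_support(aln, replicates=30, seed=42)
    assert to_newick(t1) == to_newick(t2)


def test_clade_separating_edge_gets_high_bootstrap_support():
    """On clean generated clade structure the I/II split is strongly supported."""
    from nirktools.reference_mapping import map_to_reference, stack_alignment
    from nirktools.synthetic_data import SequenceGenConfig, generate_nirk_set

    records, truth, ref = generate_nirk_set(
        SequenceGenConfig(seed=21, fraction_with_heme_ext=0, fraction_with_cupredoxin_ext=0)
    )
    maps = [map_to_reference(r, ref) for r in records]
    tree = bootstrap_support(stack_alignment(records, maps), replicates=100, seed=0)
    taxa = frozenset(truth.id)
    clade2 = frozenset(truth.loc[truth.clade == "II", "id"])
    target = min(clade2, taxa - clade2, key=lambda s: (len(s), sorted(s)))
    assert target in tree.bipartitions()

    found = []

    def walk(node):
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if 1 < len(below) < len(taxa) - 1:
            if min(below, taxa - below, key=lambda s: (len(s), sorted(s))) == target:
                found.append(node.support)
        return below

    for child, _ in tree.root.children:
        walk(child)
    assert found and found[0] >= 95.0


def test_newick_round_trip_topology_and_lengths():
    rng = np.random.default_rng(17)
    ids, D, true_splits = random_additive_tree(rng, 7)
    tree = neighbor_joining(DistanceMatrix(ids, D))
    nwk = to_newick(tree)
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == set(ids)
    # unrooted bipartitions must survive the round trip
    parsed.encode_bipartitions()
    got = set()
    taxa = frozenset(ids)
    for bp in parsed.bipartition_encoding:
        side = frozenset(t.label for t in bp.leafset_taxa(parsed.taxon_namespace))
        if 1 < len(side) < len(ids) - 1:
            got.add(min(side, taxa - side, key=lambda s: (len(s), sorted(s))))
    assert got == true_splits
    # branch lengths preserved: compare leaf path distances
    pdm = parsed.phylogenetic_distance_matrix()
    for t1 in parsed.taxon_namespace:
        for t2 in parsed.taxon_namespace:
            if t1.label < t2.label:
                i, j = ids.index(t1.label), ids.index(t2.label)
                assert pdm.patristic_distance(t1, t2) == pytest.approx(D[i, j], abs=1e-6)


def test_newick_three_taxon_star_shape():
    D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(list("ABC"), D))
    assert to_newick(tree) == "(A:1,B:1,C:1);"


def test_nj_topology_agrees_with_skbio_on_noisy_matrix():
    """Independent cross-check against scikit-bio's NJ on a non-additive matrix."""
    import io

    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(23)
    ids, D, _ = random_additive_tree(rng, 6)
    noise = rng.uniform(0, 0.02, size=D.shape)
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0)
    Dn = D + noise
    ours = neighbor_joining(DistanceMatrix(ids, Dn))
    sk_tree = sk_nj(SkDM(Dn, ids))
    sk_newick = io.StringIO()
    sk_tree.write(sk_newick)
    parsed = dendropy.Tree.get(data=sk_newick.getvalue(), schema="newick")
    parsed.encode_bipartitions()
    taxa = frozenset(ids)
    sk_splits = set()
    for bp in parsed.bipartition_encoding:
        side = frozenset(t.label for t in bp.leafset_taxa(parsed.taxon_namespace))
        if 1 < len(side) < len(ids) - 1:
            sk_splits.add(min(side, taxa - side, key=lambda s: (len(s), sorted(s))))
    assert ours.bipartitions() == sk_splits
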