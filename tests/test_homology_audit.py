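from functools import lru_cache

import numpy as np
import pytest

from shadowfold.homology_audit import (LABEL_PAIR, LABEL_ROOT, LABEL_UNPAIRED,
                                       max_noncrossing_pairs, mean_min_ted,
                                       structure_to_tree, tree_edit_distance)
from shadowfold.structure_io import RnaRecord, parse_dotbracket
from shadowfold.synthetic_families import FamilySpec, generate_corpus


def _rec(db: str, id="x") -> RnaRecord:
    return RnaRecord(id, "f", "A" * len(db), parse_dotbracket(db))


# --- independent oracle: naive recursive forest edit distance -----------------

def _to_nested(tree):
    """Rebuild nested-tuple form (label, children...) from postorder arrays."""
    stack = []
    for k in range(len(tree)):
        children = []
        while stack and stack[-1][1] >= tree.lml[k]:
            children.append(stack.pop())
        stack.extend([])
        node = ((int(tree.labels[k]), tuple(n for n, _ in reversed(children))),
                int(tree.lml[k]))
        stack.append(node)
    assert len(stack) == 1
    return stack[0][0]


@lru_cache(maxsize=None)
def _forest_dist(f1: tuple, f2: tuple) -> int:
    if not f1 and not f2:
        return 0
    if not f1:
        return sum(_size(t) for t in f2)
    if not f2:
        return sum(_size(t) for t in f1)
    (l1, c1), r1 = f1[-1], f1[:-1]
    (l2, c2), r2 = f2[-1], f2[:-1]
    delete = _forest_dist(r1 + c1, f2) + 1
    insert = _forest_dist(f1, r2 + c2) + 1
    match = (_forest_dist(c1, c2) + _forest_dist(r1, r2) +
             (0 if l1 == l2 else 1))
    return min(delete, insert, match)


def _size(t) -> int:
    return 1 + sum(_size(c) for c in t[1])


class TestTreeConstruction:
    def test_unpaired_molecule(self):
        t = structure_to_tree(_rec("...."))
        assert len(t) == 5  # 4 leaves + root
        assert list(t.labels).count(LABEL_UNPAIRED) == 4
        assert t.labels[-1] == LABEL_ROOT

    def test_hairpin_example(self):
        t = structure_to_tree(_rec("...(((....)))."))
        # 8 unpaired leaves + 3 pair nodes + root
        assert len(t) == 12
        assert list(t.labels).count(LABEL_PAIR) == 3

    def test_node_count_invariant(self, tiny_corpus):
        for rec in tiny_corpus[:8]:
            t = structure_to_tree(rec)
            unpaired = len(rec) - 2 * len(rec.pairs)
            assert len(t) == len(rec.pairs) + unpaired + 1

    def test_identical_structures_identical_trees(self):
        a = structure_to_tree(_rec("..((...))"))
        b = structure_to_tree(_rec("..((...))"))
        assert (a.labels == b.labels).all() and (a.lml == b.lml).all()

    def test_crossing_pairs_removed_maximally(self):
        # (1,10) and (2,9) cross (5,14): keep the larger nested subset
        pairs = frozenset({(1, 10), (2, 9), (5, 14)})
        kept = max_noncrossing_pairs(pairs, 14)
        assert kept == frozenset({(1, 10), (2, 9)})


class TestTreeEditDistance:
    def test_identical_is_zero(self, tiny_corpus):
        for rec in tiny_corpus[:4]:
            t = structure_to_tree(rec)
            assert tree_edit_distance(t, t) == 0.0

    def test_root_vs_n_nodes(self):
        a = structure_to_tree(RnaRecord("a", "f", "A" * 10, frozenset()))
        b = structure_to_tree(RnaRecord("b", "f", "A" * 4, frozenset()))
        # 10 leaves+root vs 4 leaves+root: delete 6 leaves
        assert tree_edit_distance(a, b) == 6.0

    @pytest.mark.parametrize("db1,db2", [
        ("((..))", "(....)"),
        ("(((...)))", "((....))"),
        ("..((...))..", "((.....))"),
        ("(....)(....)", "((........))"),
    ])
    def test_matches_naive_recursion(self, db1, db2):
        t1, t2 = structure_to_tree(_rec(db1)), structure_to_tree(_rec(db2))
        expected = _forest_dist((_to_nested(t1),), (_to_nested(t2),))
        assert tree_edit_distance(t1, t2) == expected

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(17)
        recs = generate_corpus(
            [FamilySpec(f"f{k}", 2, 30, structure_seed=100 + k)
             for k in range(6)], seed=1)
        trees = [structure_to_tree(r) for r in recs]
        for _ in range(100):
            a, b, c = rng.choice(len(trees), size=3, replace=False)
            dab = tree_edit_distance(trees[a], trees[b])
            dba = tree_edit_distance(trees[b], trees[a])
            assert dab == dba
            dac = tree_edit_distance(trees[a], trees[c])
            dcb = tree_edit_distance(trees[c], trees[b])
            assert dab <= dac + dcb + 1e-9


class TestMeanMinTed:
    def test_zero_when_test_subset_of_train(self, tiny_corpus):
        mean, _ = mean_min_ted(tiny_corpus[:4], tiny_corpus)
        assert mean == 0.0

    def test_singletons(self):
        a, b = _rec("((..))", "a"), _rec("(....)", "b")
        mean, detail = mean_min_ted([a], [b])
        assert mean == tree_edit_distance(structure_to_tree(a),
                                          structure_to_tree(b))
        assert detail.nearest_train_id.iloc[0] == "b"

    def test_family_splits_score_higher_than_intra_splits(self, tiny_corpus):
        famA = [r for r in tiny_corpus if r.family == "famA"]
        famB = [r for r in tiny_corpus if r.family == "famB"]
        intra, _ = mean_min_ted(famA[:4], famA[4:])
        inter, _ = mean_min_ted(famA[:4], famB)
        assert intra == 0.0  # identical conserved structures leak
        assert inter > 10 * max(intra, 1e-9)

    def test_empty_side_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match="nonempty"):
            mean_min_ted([], tiny_corpus)

    def test_subsampling_is_seeded(self, tiny_corpus):
        a = mean_min_ted(tiny_corpus, tiny_corpus, max_test=4, max_train=6,
                         seed=3)
        b = mean_min_ted(tiny_corpus, tiny_corpus, max_test=4, max_train=6,
                         seed=3)
        assert a[0] == b[0]
        assert a[1].equals(b[1])
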