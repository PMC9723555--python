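import itertools

import numpy as np
import pandas as pd
import pytest

from spuritax import (
    DistanceSpec,
    ValidationError,
    cv_report,
    distance_matrix,
    effective_richness,
    generalized_unifrac,
    median_within_group_distance,
    parse_newick,
    richness,
    richness_cv,
    richness_iqr,
    shannon_effective,
    unweighted_unifrac,
)


def one_sample(counts, name="s1"):
    return pd.DataFrame({name: counts}, index=[f"t{i}" for i in range(len(counts))], dtype=float)


# ---------------------------------------------------------------------------
# independent UniFrac oracles working from leaf sets, not postorder masses


def branch_leaf_sets(tree):
    """(length, leaf set) for every non-root branch."""
    out = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            leaves = frozenset([node.name])
        else:
            leaves = frozenset(t.name for t in node.tips())
        out.append((node.length or 0.0, leaves))
    return out


def oracle_unweighted(tree, present_a, present_b):
    unique = union = 0.0
    for length, leaves in branch_leaf_sets(tree):
        in_a = bool(leaves & present_a)
        in_b = bool(leaves & present_b)
        if in_a or in_b:
            union += length
        if in_a != in_b:
            unique += length
    return unique / union


def oracle_weighted_normalized(tree, prop_a, prop_b):
    """Weighted-normalized UniFrac: sum L|pA-pB| / sum L(pA+pB)."""
    num = den = 0.0
    for length, leaves in branch_leaf_sets(tree):
        pa = sum(prop_a.get(t, 0.0) for t in leaves)
        pb = sum(prop_b.get(t, 0.0) for t in leaves)
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    return num / den


def all_tree_shapes(n_leaves):
    """All unlabeled rooted bifurcating shapes with exactly n leaves,
    as nested tuples."""
    if n_leaves == 1:
        return [None]
    shapes = []
    seen = set()
    for k in range(1, n_leaves // 2 + 1):
        for left in all_tree_shapes(k):
            for right in all_tree_shapes(n_leaves - k):
                key = tuple(sorted([repr(left), repr(right)]))
                if key not in seen:
                    seen.add(key)
                    shapes.append((left, right))
    return shapes


def shape_to_newick(shape, labels, lengths):
    """Materialize a shape with the given leaf labels and branch lengths."""
    labels = iter(labels)
    lengths = iter(lengths)

    def build(node):
        if node is None:
            return f"{next(labels)}:{next(lengths)}"
        left = build(node[0])
        right = build(node[1])
        return f"({left},{right}):{next(lengths)}"

    text = build(shape)
    # strip the root's own branch length; a rooted tree has no stem
    return text.rsplit(":", 1)[0] + ";"


class TestAlphaDiversity:
    def test_richness_counts_nonzero(self):
        assert richness(one_sample([5, 0, 1]), "s1") == 2

    def test_richness_allows_empty_sample(self):
        assert richness(one_sample([0, 0]), "s1") == 0

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValidationError):
            richness(one_sample([1]), "s9")

    def test_emr_counts_taxa_above_quarter_percent(self):
        # 1000 reads as [600, 300, 97, 2, 1] -> proportions 60/30/9.7/0.2/0.1%
        assert effective_richness(one_sample([600, 300, 97, 2, 1]), "s1") == 3

    def test_emr_scale_invariant(self):
        table = one_sample([600, 300, 97, 2, 1])
        assert effective_richness(table * 1000, "s1") == effective_richness(table, "s1")

    def test_emr_equals_rescaled_count_rule(self):
        """EMR equals the count after rescaling the sample to 1000 reads and
        dropping taxa below 2.5 rescaled counts (ties removed)."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 5000, size=rng.integers(2, 40)).astype(float)
            if counts.sum() == 0:
                counts[0] = 1
            table = one_sample(counts)
            rescaled = counts / counts.sum() * 1000.0
            assert effective_richness(table, "s1") == int((rescaled > 2.5).sum())

    def test_shannon_effective_uniform_is_k(self):
        assert shannon_effective(one_sample([7, 7, 7, 7]), "s1") == pytest.approx(4.0)

    def test_shannon_effective_single_taxon_is_one(self):
        assert shannon_effective(one_sample([123]), "s1") == pytest.approx(1.0)

    def test_shannon_effective_closed_form(self):
        # proportions [0.5, 0.25, 0.25] -> exp(1.5 ln 2)
        got = shannon_effective(one_sample([2, 1, 1]), "s1")
        assert got == pytest.approx(np.exp(1.5 * np.log(2)))


class TestReproStats:
    def test_iqr_examples(self):
        assert richness_iqr([3, 3, 3]) == 0.0
        assert richness_iqr([1, 2, 3, 4, 5]) == 2.0
        assert richness_iqr([10, 10, 100]) == 45.0  # type-7: Q1=10, Q3=55

    def test_iqr_needs_two_values(self):
        with pytest.raises(ValidationError):
            richness_iqr([5])

    def test_cv_examples(self):
        assert richness_cv([10, 10, 10]) == 0.0
        assert richness_cv([8, 10, 12]) == pytest.approx(20.0)

    def test_cv_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            richness_cv([0, 0])

    def test_cv_report_within_and_across_runs(self):
        meta = pd.DataFrame(
            {
                "run_id": ["r1", "r1", "r2", "r2"],
                "replicate_group": ["g"] * 4,
                "subject_id": ["g"] * 4,
                "category": [""] * 4,
                "timepoint": [0, 1, 0, 1],
            },
            index=["a", "b", "c", "d"],
        )
        rich = pd.Series([8, 12, 10, 10], index=["a", "b", "c", "d"])
        report = cv_report(rich, meta)
        within = report[report["scope"] == "within_run"].set_index("run_id")["cv"]
        assert within["r1"] == pytest.approx(richness_cv([8, 12]))
        assert within["r2"] == 0.0
        across = report[report["scope"] == "across_runs"]["cv"].iloc[0]
        assert across == 0.0  # per-run means are both 10


class TestUniFracExamples:
    def test_identical_presence_zero(self):
        tree = parse_newick("(A:1,B:1);")
        table = pd.DataFrame({"s1": [3.0, 1.0], "s2": [1.0, 3.0]}, index=["A", "B"])
        assert unweighted_unifrac(tree, table, "s1", "s2") == 0.0

    def test_disjoint_samples_distance_one(self):
        tree = parse_newick("(A:1,B:1);")
        table = pd.DataFrame({"s1": [5.0, 0.0], "s2": [0.0, 7.0]}, index=["A", "B"])
        assert unweighted_unifrac(tree, table, "s1", "s2") == 1.0
        for alpha in (0.0, 0.25, 0.5, 1.0):
            assert generalized_unifrac(tree, table, "s1", "s2", alpha) == 1.0

    def test_shared_and_unique_branch(self):
        tree = parse_newick("(A:1,B:1);")
        table = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 0.0]}, index=["A", "B"])
        assert unweighted_unifrac(tree, table, "s1", "s2") == 0.5

    def test_identical_proportions_zero_generalized(self):
        tree = parse_newick("((A:1,B:2):0.5,C:1);")
        table = pd.DataFrame({"s1": [2.0, 1.0, 1.0], "s2": [4.0, 2.0, 2.0]}, index=list("ABC"))
        assert generalized_unifrac(tree, table, "s1", "s2") == pytest.approx(0.0)

    def test_taxon_missing_from_tree_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        table = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["Z"])
        with pytest.raises(ValidationError):
            unweighted_unifrac(tree, table, "s1", "s2")

    def test_abundance_perturbation_leaves_unweighted_invariant(self):
        tree = parse_newick("((A:1,B:2):0.5,(C:1,D:3):0.2);")
        base = pd.DataFrame(
            {"s1": [5.0, 0.0, 2.0, 0.0], "s2": [1.0, 4.0, 0.0, 9.0]}, index=list("ABCD")
        )
        d0 = unweighted_unifrac(tree, base, "s1", "s2")
        perturbed = base * np.array([[3.0, 7.0], [1.0, 1.0], [10.0, 2.0], [1.0, 0.5]])
        assert unweighted_unifrac(tree, perturbed, "s1", "s2") == pytest.approx(d0)


class TestUniFracOracles:
    def test_unweighted_matches_oracle_on_all_shapes(self):
        """Exhaustive check against a leaf-set branch-enumeration oracle over
        every rooted bifurcating shape with 2-6 leaves and every pair of
        non-empty presence sets."""
        rng = np.random.default_rng(2024)
        for n in range(2, 7):
            for shape in all_tree_shapes(n):
                labels = [chr(65 + i) for i in range(n)]
                lengths = np.round(rng.uniform(0.1, 2.0, size=2 * n), 3)
                tree = parse_newick(shape_to_newick(shape, labels, lengths))
                subsets = [
                    frozenset(c)
                    for r in range(1, n + 1)
                    for c in itertools.combinations(labels, r)
                ]
                # one column per presence set; the public distance_matrix
                # covers every pair of subsets in one call
                table = pd.DataFrame(
                    {
                        f"p{k}": [1.0 if t in s else 0.0 for t in labels]
                        for k, s in enumerate(subsets)
                    },
                    index=labels,
                )
                dm = distance_matrix(tree, table, DistanceSpec("unweighted_unifrac"))
                for i, sa in enumerate(subsets):
                    for j, sb in enumerate(subsets[: i + 1]):
                        want = oracle_unweighted(tree, sa, sb) if sa != sb else 0.0
                        assert dm.iloc[i, j] == pytest.approx(want, abs=1e-12)

    def test_generalized_alpha_one_matches_weighted_normalized_oracle(self):
        rng = np.random.default_rng(7)
        shapes = all_tree_shapes(6)
        for trial in range(100):
            shape = shapes[trial % len(shapes)]
            labels = [f"L{i}" for i in range(6)]
            lengths = rng.uniform(0.05, 3.0, size=12)
            tree = parse_newick(shape_to_newick(shape, labels, lengths))
            counts = rng.integers(0, 50, size=(6, 2)).astype(float)
            counts[rng.integers(6), 0] += 1  # keep both samples non-empty
            counts[rng.integers(6), 1] += 1
            table = pd.DataFrame(counts, index=labels, columns=["s1", "s2"])
            props = table / table.sum(axis=0)
            got = generalized_unifrac(tree, table, "s1", "s2", alpha=1.0)
            want = oracle_weighted_normalized(
                tree, props["s1"].to_dict(), props["s2"].to_dict()
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_symmetry_range_and_zero_diagonal(self, mock_study):
        table = mock_study.table.iloc[:, :3]
        tree = mock_study.tree
        for spec in (DistanceSpec("unweighted_unifrac"), DistanceSpec("generalized_unifrac", 0.5)):
            dm = distance_matrix(tree, table, spec)
            assert np.allclose(dm.to_numpy(), dm.to_numpy().T)
            assert np.allclose(np.diag(dm.to_numpy()), 0.0)
            assert (dm.to_numpy() >= 0).all() and (dm.to_numpy() <= 1).all()


class TestDistanceMatrix:
    def test_duplicated_sample_distance_zero(self):
        tree = parse_newick("(A:1,B:1);")
        table = pd.DataFrame({"s1": [2.0, 1.0], "s2": [2.0, 1.0]}, index=["A", "B"])
        dm = distance_matrix(tree, table, DistanceSpec("generalized_unifrac", 0.5))
        assert dm.loc["s1", "s2"] == pytest.approx(0.0)

    def test_matrix_matches_pairwise_calls(self):
        tree = parse_newick("((A:1,B:2):0.5,C:1);")
        table = pd.DataFrame(
            {"x": [3.0, 1.0, 0.0], "y": [0.0, 2.0, 2.0], "z": [1.0, 1.0, 1.0]},
            index=list("ABC"),
        )
        dm = distance_matrix(tree, table, DistanceSpec("unweighted_unifrac"))
        for a, b in itertools.combinations(table.columns, 2):
            assert dm.loc[a, b] == pytest.approx(unweighted_unifrac(tree, table, a, b))

    def test_median_within_group(self):
        tree = parse_newick("(A:1,B:1);")
        table = pd.DataFrame(
            {"s1": [1.0, 0.0], "s2": [0.0, 1.0], "s3": [1.0, 1.0]}, index=["A", "B"]
        )
        meta = pd.DataFrame(
            {
                "run_id": [""] * 3,
                "subject_id": ["u", "u", "u"],
                "replicate_group": [""] * 3,
                "category": [""] * 3,
                "timepoint": [0, 1, 2],
            },
            index=["s1", "s2", "s3"],
        )
        dm = distance_matrix(tree, table, DistanceSpec("unweighted_unifrac"))
        med = median_within_group_distance(dm, meta, by="subject_id")
        assert med["u"] == pytest.approx(np.median([1.0, 0.5, 0.5]))
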