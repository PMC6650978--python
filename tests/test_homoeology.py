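import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyfam.homoeology import (
    HomoeologGroup,
    assign_homoeolog_groups,
    compare_group_structures,
    greedy_cluster,
    pairwise_identity,
    summarize_groups,
)
from polyfam.models import ChromosomeId, PolyfamError


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDEFG", "ACDEFG") == 1.0

    def test_single_substitution(self):
        assert pairwise_identity("AAAA", "AAAT") == pytest.approx(0.75)

    def test_truncation_counts_against_identity(self):
        rng = np.random.default_rng(1)
        full = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        mutated = list(full)
        for pos in [5, 25, 45, 65, 85]:
            mutated[pos] = "W" if mutated[pos] != "W" else "Y"
        truncated = "".join(mutated)[:90]
        assert pairwise_identity(full, truncated) == pytest.approx(0.85)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "AA")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.text(alphabet="ACDEFG", min_size=1, max_size=40),
        b=st.text(alphabet="ACDEFG", min_size=1, max_size=40),
    )
    def test_symmetric_and_bounded(self, a, b):
        x = pairwise_identity(a, b)
        assert 0.0 <= x <= 1.0
        assert x == pytest.approx(pairwise_identity(b, a))


class TestGreedyCluster:
    def test_single_sequence(self):
        clusters = greedy_cluster({"a": "ACDEFGHIKL"})
        assert len(clusters) == 1
        assert clusters[0].representative == "a"

    def test_three_similar_one_diverged(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))

        def mutate(s, n):
            out = list(s)
            for pos in rng.choice(len(s), size=n, replace=False):
                alternatives = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c != out[pos]]
                out[pos] = alternatives[rng.integers(len(alternatives))]
            return "".join(out)

        seqs = {
            "s1": base,
            "s2": mutate(base, 5),
            "s3": mutate(base, 5),
            "s4": mutate(base, 30),
        }
        clusters = greedy_cluster(seqs, threshold=0.90)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 3]

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            greedy_cluster({"a": "AC"}, threshold=0.0)

    def test_partition_invariant(self, small_sim):
        _cfg, _assembly, genes, truth = small_sim
        seqs = {g.gene_id: g.protein for g in genes if g.gene_id in set(truth.family_members)}
        clusters = greedy_cluster(seqs)
        seen = [m for c in clusters for m in c.members]
        assert sorted(seen) == sorted(seqs)

    def test_matches_independent_first_fit_oracle(self):
        rng = np.random.default_rng(3)
        seqs = {}
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        for i in range(10):
            out = list(base)
            n = int(rng.integers(0, 25))
            for pos in rng.choice(len(base), size=n, replace=False):
                alternatives = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c != out[pos]]
                out[pos] = alternatives[rng.integers(len(alternatives))]
            seqs[f"q{i}"] = "".join(out)
        # oracle: explicit re-statement of the greedy rule from the all-pairs
        # identity matrix
        order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
        oracle_clusters = []
        for sid in order:
            for cl in oracle_clusters:
                if pairwise_identity(seqs[sid], seqs[cl[0]]) >= 0.90:
                    cl.append(sid)
                    break
            else:
                oracle_clusters.append([sid])
        clusters = greedy_cluster(seqs, threshold=0.90)
        assert [c.members for c in clusters] == oracle_clusters


def loc(number, sub, start=0, end=1000):
    return (ChromosomeId(number, sub), (start, end))


class TestAssignGroups:
    def _cluster(self, members):
        from polyfam.homoeology import SequenceCluster

        return SequenceCluster(
            cluster_id=0,
            representative=members[0],
            members=list(members),
            identity_to_rep={m: 1.0 for m in members},
        )

    def test_triplet_on_homoeologous_chromosomes(self):
        locations = {"a": loc(3, "A"), "b": loc(3, "B"), "d": loc(3, "D")}
        groups = assign_homoeolog_groups([self._cluster(["a", "b", "d"])], locations)
        assert len(groups) == 1
        assert groups[0].kind == "triplet"
        assert groups[0].chromosome_number == 3

    def test_non_homoeologous_pair_becomes_singlets(self):
        locations = {"a": loc(2, "A"), "b": loc(5, "D")}
        groups = assign_homoeolog_groups([self._cluster(["a", "b"])], locations)
        assert sorted(g.kind for g in groups) == ["singlet", "singlet"]

    def test_same_subgenome_pair_becomes_singlets(self):
        locations = {"a": loc(2, "A"), "b": loc(2, "A")}
        groups = assign_homoeolog_groups([self._cluster(["a", "b"])], locations)
        assert sorted(g.kind for g in groups) == ["singlet", "singlet"]

    def test_singleton_cluster(self):
        groups = assign_homoeolog_groups([self._cluster(["a"])], {"a": loc(1, "A")})
        assert groups[0].kind == "singlet"

    def test_large_cluster_partitioned_by_chromosome_number(self):
        locations = {
            "a": loc(3, "A"), "b": loc(3, "B"), "d": loc(3, "D"),
            "x": loc(5, "B"), "y": loc(5, "D"),
            "z": loc(7, "A"),
        }
        groups = assign_homoeolog_groups(
            [self._cluster(["a", "b", "d", "x", "y", "z"])], locations
        )
        kinds = sorted(g.kind for g in groups)
        assert kinds == ["probable_pair", "probable_triplet", "singlet"]

    def test_missing_location_is_error(self):
        with pytest.raises(PolyfamError):
            assign_homoeolog_groups([self._cluster(["a", "b"])], {"a": loc(1, "A")})


class TestSummarize:
    def test_paper_scale_bookkeeping(self):
        groups = []
        for i in range(8):
            groups.append(
                HomoeologGroup(f"t{i}", "triplet", 1,
                               [(f"t{i}a", "A"), (f"t{i}b", "B"), (f"t{i}d", "D")])
            )
        for i in range(11):
            groups.append(
                HomoeologGroup(f"p{i}", "pair", 2, [(f"p{i}a", "A"), (f"p{i}b", "B")])
            )
        s = summarize_groups(groups, total_genes=92)
        assert (s.n_triplets, s.n_pairs) == (8, 11)
        assert s.grouped_members == 46
        assert s.singlets == 46

    def test_null_case(self):
        s = summarize_groups([], total_genes=10)
        assert s.grouped_members == 0 and s.singlets == 10

    def test_exhaustive_case(self):
        groups = [
            HomoeologGroup("t", "triplet", 1, [("a", "A"), ("b", "B"), ("d", "D")]),
            HomoeologGroup("p", "pair", 2, [("x", "A"), ("y", "D")]),
        ]
        s = summarize_groups(groups, total_genes=5)
        assert s.grouped_members == 5 and s.singlets == 0

    def test_double_counting_is_error(self):
        groups = [
            HomoeologGroup("p1", "pair", 1, [("a", "A"), ("b", "B")]),
            HomoeologGroup("p2", "pair", 1, [("a", "A"), ("c", "D")]),
        ]
        with pytest.raises(PolyfamError):
            summarize_groups(groups, total_genes=5)


class TestCompareStructures:
    def test_intron_gain_is_divergent(self):
        g = HomoeologGroup("g", "triplet", 3, [("a", "A"), ("b", "B"), ("d", "D")])
        classes = {"a": "TypeIa_nonconserved", "b": "TypeIb", "d": "TypeIb"}
        divergent, _cls, _notes = compare_group_structures(g, classes)
        assert divergent

    def test_all_intronless_is_concordant(self):
        g = HomoeologGroup("g", "triplet", 3, [("a", "A"), ("b", "B"), ("d", "D")])
        divergent, _cls, _notes = compare_group_structures(
            g, {"a": "TypeIb", "b": "TypeIb", "d": "TypeIb"}
        )
        assert not divergent

    def test_positional_divergence_reported_in_notes(self):
        g = HomoeologGroup("g", "pair", 3, [("a", "A"), ("b", "B")])
        divergent, _cls, notes = compare_group_structures(
            g, {"a": "TypeIa_conserved", "b": "TypeIa_nonconserved"}
        )
        assert not divergent
        assert "positional" in notes

    def test_recovers_planted_divergent_triplet(self, small_sim):
        _cfg, _assembly, _genes, truth = small_sim
        flags = []
        for group in truth.homoeolog_groups:
            g = HomoeologGroup(
                group["group_id"], group["kind"], group["chromosome_number"],
                [(m["gene_id"], m["subgenome"]) for m in group["members"]],
            )
            divergent, _c, _n = compare_group_structures(g, truth.structural_class)
            flags.append(divergent)
        assert any(flags)  # the generator plants one intron-gain triplet
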