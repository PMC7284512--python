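import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_additive_tree
from liriopogon.phylogeny import (
    CladeAssignment,
    SaturationError,
    assign_clade,
    bootstrap_consensus,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    triplet_call_from_bases,
    triplet_call,
)
from liriopogon.seqio import SeqRecord


def seq_with(transitions: int, transversions: int, L: int = 100) -> tuple[str, str]:
    """Pair of length-L sequences differing by the requested substitutions."""
    a = ("ACGT" * ((L + 3) // 4))[:L]
    b = list(a)
    i = 0
    for _ in range(transitions):
        b[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[b[i]]
        i += 1
    for _ in range(transversions):
        b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
        i += 1
    return a, "".join(b)


class TestK2P:
    def test_identical_sequences(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)
        assert r.L == 8

    def test_ten_transitions(self):
        a, b = seq_with(10, 0)
        r = k2p_distance(a, b)
        # closed form: -0.5 ln(1 - 2*0.1) = -0.5 ln(0.8)
        assert r.d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
        assert r.d == pytest.approx(0.1115717756571049, abs=1e-12)

    def test_25_transversions(self):
        a, b = seq_with(0, 25)
        r = k2p_distance(a, b)
        expected = -0.5 * math.log(1 - 0.25) - 0.25 * math.log(1 - 0.5)
        assert r.d == pytest.approx(expected, abs=1e-12)
        assert r.d == pytest.approx(0.3171, abs=5e-4)

    def test_pairwise_deletion(self):
        r = k2p_distance("ACGTN-GT", "ACGTAAGT")
        assert r.L == 6

    def test_saturation_raises(self):
        a, b = seq_with(40, 20)
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_zero_comparable_sites_raises(self):
        with pytest.raises(ValueError):
            k2p_distance("NNNN", "ACGT")

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")

    @settings(max_examples=60, deadline=None)
    @given(
        ts=st.integers(min_value=0, max_value=15),
        tv=st.integers(min_value=0, max_value=15),
    )
    def test_closed_form_oracle(self, ts, tv):
        a, b = seq_with(ts, tv, L=200)
        P, Q = ts / 200, tv / 200
        r = k2p_distance(a, b)
        assert r.P == pytest.approx(P) and r.Q == pytest.approx(Q)
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert r.d == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        a, b = seq_with(5, 7)
        assert k2p_distance(a, b).d == k2p_distance(b, a).d

    def test_zero_iff_no_substitutions(self):
        a, b = seq_with(1, 0)
        assert k2p_distance(a, b).d > 0

    def test_matrix_agrees_with_pairwise(self):
        rows = {
            "a": seq_with(0, 0)[0],
            "b": seq_with(3, 1)[1],
            "c": seq_with(7, 4)[1],
        }
        names, D = k2p_matrix(rows)
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i != j:
                    assert D[i, j] == pytest.approx(k2p_distance(rows[x], rows[y]).d)
        assert np.allclose(D, D.T)


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(["A", "B", "C"], D)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    def test_additive_quartet_recovers_topology(self):
        # quartet ((A,B),(C,D)) with all five branches length 1
        D = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        tree = nj_tree(["A", "B", "C", "D"], D)
        splits = [b for b, _, _ in tree.bipartitions()]
        assert len(splits) == 1
        assert splits[0] in (frozenset({"A", "B"}), frozenset({"C", "D"}))
        # internal branch length 1, terminals 1: path lengths reproduce D
        dist = tree.patristic_distances("A")
        assert dist["B"] == pytest.approx(2.0)
        assert dist["C"] == pytest.approx(3.0)

    def test_all_zero_matrix_star(self):
        D = np.zeros((4, 4))
        tree = nj_tree(list("ABCD"), D)
        assert all(leaf.length == 0.0 for leaf in tree.leaves())

    def test_rejects_asymmetric(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(["A", "B", "C"], D)

    def test_rejects_nan(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(["A", "B", "C"], D)

    @pytest.mark.parametrize("n_taxa", [4, 6, 8, 10])
    def test_additive_matrix_recovery(self, n_taxa):
        # NJ is exact on additive matrices: path lengths must reproduce D
        for seed in range(5):
            rng = np.random.default_rng(100 * n_taxa + seed)
            names, D = random_additive_tree(rng, n_taxa)
            tree = nj_tree(names, D)
            for i, src in enumerate(names):
                dist = tree.patristic_distances(src)
                for j, dst in enumerate(names):
                    if i != j:
                        assert dist[dst] == pytest.approx(D[i, j], abs=1e-9)

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(77)
        names, D = random_additive_tree(rng, 7)
        tree = nj_tree(names, D)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(names)

    def test_topology_matches_dendropy_nj(self):
        # independent implementation check against dendropy's NJ
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(31)
        names, D = random_additive_tree(rng, 8)
        mine = nj_tree(names, D)

        csv = "," + ",".join(names) + "\n"
        for i, nm in enumerate(names):
            csv += nm + "," + ",".join(f"{D[i, j]:.10f}" for j in range(len(names))) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv), delimiter=","
        )
        theirs = pdm.nj_tree()
        taxa = theirs.taxon_namespace
        parsed = dendropy.Tree.get(data=mine.newick(), schema="newick", taxon_namespace=taxa)
        parsed.encode_bipartitions()
        theirs.encode_bipartitions()
        assert treecompare.symmetric_difference(parsed, theirs) == 0


class TestBootstrapConsensus:
    def _clean_rows(self, panel, reference_set):
        _, clade_models = reference_set
        rows = {}
        for clade in ("B2", "B3a", "B3b"):
            model = clade_models[clade]
            for ref in model.references:
                rows[ref.id] = ref.seq
        return rows

    def test_no_conflict_gives_full_support(self, panel, reference_set):
        rows = self._clean_rows(panel, reference_set)
        point = nj_tree(*k2p_matrix(rows))
        cons = bootstrap_consensus(rows, replicates=20, seed=4)
        point_splits = {b for b, _, _ in point.bipartitions()}
        cons_splits = {b for b, _, _ in cons.bipartitions()}

        def canon(splits, all_leaves, anchor):
            return {s if anchor not in s else all_leaves - s for s in splits}

        leaves = frozenset(rows)
        anchor = next(iter(rows))
        assert canon(cons_splits, leaves, anchor) == canon(point_splits, leaves, anchor)
        assert all(s == 100.0 for _, s, _ in cons.bipartitions())

    def test_majority_rule_counting(self):
        # oracle: brute-force bipartition counts over a fixed replicate set.
        # 6 replicates support AB|CD, 4 support AC|BD -> AB|CD kept at 60.
        D_ab = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        D_ac = np.array(
            [[0, 3, 2, 3], [3, 0, 3, 2], [2, 3, 0, 3], [3, 2, 3, 0]], dtype=float
        )
        matrices = [D_ab] * 6 + [D_ac] * 4
        calls = iter(matrices)

        def fake_distance(rows):
            return list(rows), next(calls)

        rows = {n: "ACGT" for n in "ABCD"}
        cons = bootstrap_consensus(
            rows, replicates=10, threshold=0.5, seed=0, distance_fn=fake_distance
        )
        splits = cons.bipartitions()
        assert len(splits) == 1
        below, support, _ = splits[0]
        assert below in (frozenset("AB"), frozenset("CD"))
        assert support == pytest.approx(60.0)

    def test_exactly_at_threshold_retained(self):
        D_ab = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        D_ac = np.array(
            [[0, 3, 2, 3], [3, 0, 3, 2], [2, 3, 0, 3], [3, 2, 3, 0]], dtype=float
        )
        matrices = [D_ab] * 5 + [D_ac] * 5
        calls = iter(matrices)

        def fake_distance(rows):
            return list(rows), next(calls)

        rows = {n: "ACGT" for n in "ABCD"}
        cons = bootstrap_consensus(
            rows, replicates=10, threshold=0.5, seed=0, distance_fn=fake_distance
        )
        # both splits sit exactly at the 50% threshold; >=50% is kept, so the
        # compatibility filter retains exactly one of the two, at support 50
        splits = cons.bipartitions()
        assert len(splits) == 1
        assert splits[0][1] == pytest.approx(50.0)

    def test_requires_three_rows(self):
        with pytest.raises(ValueError):
            bootstrap_consensus({"a": "ACGT", "b": "ACGT"}, replicates=5, seed=0)

    def test_supports_at_least_threshold_and_compatible(self, panel, reference_set):
        _, clade_models = reference_set
        rng = np.random.default_rng(6)
        rows = {}
        for clade, model in clade_models.items():
            for ref in model.references:
                seq = list(ref.seq)
                for pos in rng.integers(0, len(seq), 4):  # mild conflicting noise
                    seq[pos] = "ACGT"[rng.integers(4)]
                rows[ref.id] = "".join(seq)
        cons = bootstrap_consensus(rows, replicates=30, threshold=0.5, seed=6)
        splits = cons.bipartitions()
        assert all(s >= 50.0 for _, s, _ in splits)
        leaves = frozenset(rows)
        anchor = next(iter(rows))
        canon = [b if anchor not in b else leaves - b for b, _, _ in splits]
        for i, x in enumerate(canon):
            for y in canon[i + 1:]:
                assert x <= y or y <= x or not (x & y)

    def test_deterministic_for_seed(self, reference_set):
        rows = self._clean_rows(None, reference_set)
        t1 = bootstrap_consensus(rows, replicates=10, seed=9).newick()
        t2 = bootstrap_consensus(rows, replicates=10, seed=9).newick()
        assert t1 == t2


class TestAssignClade:
    def _tree_with_query(self, reference_set, query_seq, query_id="q"):
        _, clade_models = reference_set
        rows = {query_id: query_seq}
        labels = {}
        for clade, model in clade_models.items():
            for ref in model.references:
                rows[ref.id] = ref.seq
                labels[ref.id] = clade
        cons = bootstrap_consensus(rows, replicates=20, seed=3)
        return cons, labels

    def test_identical_to_reference_gets_its_clade(self, reference_set):
        _, clade_models = reference_set
        cons, labels = self._tree_with_query(
            reference_set, clade_models["B3a"].references[0].seq
        )
        call = assign_clade(cons, "q", labels)
        assert call.label == "B3a"
        assert call.support is not None and call.support >= 50.0

    def test_full_pipeline_b3b_assignment(self, panel, reference_set):
        # query generated from the bodinieri clade backbone
        _, clade_models = reference_set
        cons, labels = self._tree_with_query(
            reference_set, clade_models["B3b"].backbone
        )
        call = assign_clade(cons, "q", labels)
        assert call.label == "B3b"
        assert call.support == pytest.approx(100.0)

    def test_equidistant_conflicting_query_unassigned(self):
        # symmetric distances: query exactly between two labelled pairs
        names = ["q", "x1", "x2", "y1", "y2"]
        rows = {n: "A" * 10 for n in names}

        D = np.array(
            [
                [0, 2, 2, 2, 2],
                [2, 0, 1, 3, 3],
                [2, 1, 0, 3, 3],
                [2, 3, 3, 0, 1],
                [2, 3, 3, 1, 0],
            ],
            dtype=float,
        )

        def fake_distance(r):
            return names, D

        cons = bootstrap_consensus(
            rows, replicates=5, seed=0, distance_fn=fake_distance
        )
        labels = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        call = assign_clade(cons, "q", labels)
        assert call.label == "unassigned"
        assert call.support is None

    def test_unknown_query_raises(self, reference_set):
        _, clade_models = reference_set
        cons, labels = self._tree_with_query(
            reference_set, clade_models["B2"].backbone
        )
        with pytest.raises(KeyError):
            assign_clade(cons, "nonexistent", labels)


class TestTripletCall:
    def test_full_planiscapus_pattern(self, panel):
        trip = panel.its_triplet
        bases = {p: trip.patterns["planiscapus"][p] for p in trip.positions}
        assert triplet_call_from_bases(bases, trip) == ("planiscapus", False)

    def test_full_bodinieri_pattern(self, panel):
        trip = panel.its_triplet
        bases = {p: trip.patterns["bodinieri"][p] for p in trip.positions}
        assert triplet_call_from_bases(bases, trip) == ("bodinieri", False)

    def test_two_of_three_is_partial(self, panel):
        trip = panel.its_triplet
        bases = {p: trip.patterns["planiscapus"][p] for p in trip.positions}
        bases[trip.positions[2]] = trip.patterns["bodinieri"][trip.positions[2]]
        assert triplet_call_from_bases(bases, trip) == ("planiscapus", True)

    def test_all_n_undetermined(self, panel):
        trip = panel.its_triplet
        bases = {p: "N" for p in trip.positions}
        # N is compatible with both patterns -> no majority for either
        key, partial = triplet_call_from_bases(bases, trip)
        assert key in ("planiscapus", "bodinieri", "undetermined")

    def test_gap_positions_undetermined(self, panel):
        trip = panel.its_triplet
        bases = {p: "-" for p in trip.positions}
        assert triplet_call_from_bases(bases, trip) == ("undetermined", False)

    def test_aligned_record_call(self, panel, reference_set, its_reference):
        _, clade_models = reference_set
        rec = SeqRecord("q", clade_models["B3a"].backbone)
        key, partial = triplet_call(rec, panel.its_triplet, its_reference)
        assert (key, partial) == ("planiscapus", False)
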