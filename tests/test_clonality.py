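"""Heterozygous-locus similarity, threshold calibration, clone clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import clonekit as ck
from clonekit.errors import CalibrationError


def matrix_from_lists(calls, sample_ids=None):
    arr = np.array(calls, dtype=np.int16)
    n = arr.shape[0]
    return ck.GenotypeMatrix(
        sample_ids or [f"S{i}" for i in range(n)],
        [f"L{j}" for j in range(arr.shape[1])],
        arr,
    )


MISS = (0, 0)


class TestHetSimilarity:
    def test_self_similarity_is_100(self):
        m = matrix_from_lists([[(1, 2), (1, 1)], [(1, 1), (1, 1)]])
        sim = ck.het_similarity("S0", "S0", m)
        assert sim.sim_percent == 100.0

    def test_hand_counted_three_of_four(self):
        # A het at 4 loci, B matches 3; B het at the same 4 loci, matches 3
        a = [(1, 2), (1, 2), (1, 2), (1, 2), (1, 1)]
        b = [(1, 2), (1, 2), (1, 2), (1, 3), (1, 1)]
        sim = ck.het_similarity("S0", "S1", matrix_from_lists([a, b]))
        assert sim.sim_percent == pytest.approx(75.0)
        assert sim.a_to_b == pytest.approx(75.0)
        assert sim.b_to_a == pytest.approx(75.0)
        assert sim.n_het_compared == 4

    def test_asymmetric_directions_are_averaged(self):
        # A het at 2 loci (B matches 1 -> 50 %); B het at 1 locus (A matches -> 100 %)
        a = [(1, 2), (1, 2), (1, 1)]
        b = [(1, 2), (1, 1), (1, 1)]
        sim = ck.het_similarity("S0", "S1", matrix_from_lists([a, b]))
        assert sorted([sim.a_to_b, sim.b_to_a]) == [50.0, 100.0]
        assert sim.sim_percent == pytest.approx(75.0)

    def test_no_het_either_side_is_incomparable(self):
        m = matrix_from_lists([[(1, 1), (2, 2)], [(1, 1), (2, 2)]])
        sim = ck.het_similarity("S0", "S1", m)
        assert sim.sim_percent is None

    def test_missing_loci_excluded_from_comparison(self):
        a = [(1, 2), (1, 2)]
        b = [(1, 2), MISS]
        sim = ck.het_similarity("S0", "S1", matrix_from_lists([a, b]))
        assert sim.a_to_b == pytest.approx(100.0)

    def test_duplicate_libraries_with_one_percent_dropout(self):
        # two libraries of one genotype, het loci independently dropped to
        # hom with p=0.01: similarity should sit near 99 %
        rng = np.random.default_rng(42)
        n_loci = 500
        sims = []
        for _ in range(20):
            calls_a, calls_b = [], []
            for _ in range(n_loci):
                for calls in (calls_a, calls_b):
                    calls.append((1, 1) if rng.random() < 0.01 else (1, 2))
            m = matrix_from_lists([calls_a, calls_b])
            sims.append(ck.het_similarity("S0", "S1", m).sim_percent)
        assert np.mean(sims) == pytest.approx(99.0, abs=0.3)
        assert min(sims) > 97.0


class TestPairwiseTable:
    def test_identical_samples_all_100(self):
        row = [(1, 2), (1, 1), (2, 2)]
        table = ck.pairwise_het_similarities(matrix_from_lists([row, row, row]))
        assert (table.frame["sim_percent"] == 100.0).all()

    def test_pair_count(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(1, 3, size=(6, 30, 2)).astype(np.int16)
        table = ck.pairwise_het_similarities(matrix_from_lists(calls))
        assert len(table) == 15

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(1, 3, size=(4, 40, 2)).astype(np.int16)
        ids = [f"S{i}" for i in range(4)]
        m1 = matrix_from_lists(calls, ids)
        perm = [2, 0, 3, 1]
        m2 = matrix_from_lists(calls[perm], [ids[i] for i in perm])
        t1 = ck.pairwise_het_similarities(m1).frame.sort_values(
            ["sample_a", "sample_b"]).reset_index(drop=True)
        t2 = ck.pairwise_het_similarities(m2).frame.sort_values(
            ["sample_a", "sample_b"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)


def table_from_values(pairs_and_values):
    rows = []
    for (a, b), v in pairs_and_values.items():
        rows.append({"sample_a": a, "sample_b": b, "sim_percent": v,
                     "n_het_compared": 100, "a_to_b": v, "b_to_a": v,
                     "reliable": True})
    return ck.SimilarityTable(pd.DataFrame(rows), min_overlap=20)


def full_table(values_by_pair):
    return table_from_values(values_by_pair)


class TestCalibrateThreshold:
    def test_widest_gap_below_duplicates(self):
        values = {("a", "b"): 10, ("a", "c"): 12, ("b", "c"): 15,
                  ("d", "e"): 96, ("d", "f"): 98, ("e", "f"): 100}
        cal = ck.calibrate_threshold(full_table(values),
                                     duplicates=[("d", "f"), ("e", "f")])
        assert cal.gap == (15.0, 96.0)
        assert cal.threshold_percent == pytest.approx(55.5)
        assert not cal.used_default

    def test_no_wide_gap_falls_back_to_default(self):
        values = {("a", "b"): 96, ("a", "c"): 97, ("b", "c"): 98}
        with pytest.warns(UserWarning, match="default threshold"):
            cal = ck.calibrate_threshold(full_table(values),
                                         duplicates=[("a", "b")])
        assert cal.threshold_percent == 85.0
        assert cal.used_default

    def test_no_duplicates_falls_back_to_default(self):
        values = {("a", "b"): 10, ("a", "c"): 95, ("b", "c"): 96}
        with pytest.warns(UserWarning):
            cal = ck.calibrate_threshold(full_table(values))
        assert cal.threshold_percent == 85.0
        assert not cal.duplicate_pairs_validated

    def test_duplicate_below_threshold_fails_calibration(self):
        values = {("a", "b"): 40, ("a", "c"): 95, ("b", "c"): 96}
        with pytest.raises(CalibrationError, match="contamination"), \
                pytest.warns(UserWarning):
            ck.calibrate_threshold(full_table(values), duplicates=[("a", "b")])


def union_find_components(samples, edges):
    parent = {s: s for s in samples}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for s in samples:
        comps.setdefault(find(s), set()).add(s)
    return sorted(frozenset(c) for c in comps.values())


class TestAssignClones:
    def test_all_similar_is_one_clone(self):
        values = {(f"S{i}", f"S{j}"): 99.0
                  for i in range(5) for j in range(i + 1, 5)}
        asg = ck.assign_clones(full_table(values), 85.0)
        assert asg.n_clones == 1
        assert set(asg.clone_of.values()) == {"S0"}

    def test_all_dissimilar_is_singletons(self):
        values = {(f"S{i}", f"S{j}"): 40.0
                  for i in range(5) for j in range(i + 1, 5)}
        asg = ck.assign_clones(full_table(values), 85.0)
        assert asg.n_clones == 5

    def test_transitivity_violation_reported_not_split(self):
        values = {("a", "b"): 90, ("b", "c"): 90, ("a", "c"): 70}
        asg = ck.assign_clones(full_table(values), 85.0)
        assert asg.n_clones == 1
        assert asg.transitivity_violations == [("a", "c", 70.0)]

    @given(data=st.data())
    def test_matches_union_find_oracle(self, data):
        n = data.draw(st.integers(2, 8))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        samples = [f"S{i}" for i in range(n)]
        values = {
            (samples[i], samples[j]): float(rng.choice([20, 50, 84, 86, 99]))
            for i in range(n) for j in range(i + 1, n)
        }
        threshold = 85.0
        asg = ck.assign_clones(full_table(values), threshold)
        edges = [pair for pair, v in values.items() if v >= threshold]
        expected = union_find_components(samples, edges)
        got = sorted(frozenset(m) for m in asg.clone_members.values())
        assert got == expected
        # clone ids are the smallest member
        for cid, members in asg.clone_members.items():
            assert cid == min(members)

    @given(data=st.data())
    def test_raising_threshold_never_merges(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        samples = [f"S{i}" for i in range(6)]
        values = {
            (samples[i], samples[j]): float(rng.uniform(0, 100))
            for i in range(6) for j in range(i + 1, 6)
        }
        t1 = data.draw(st.floats(10, 80))
        t2 = t1 + data.draw(st.floats(1, 19))
        low = ck.assign_clones(full_table(values), t1)
        high = ck.assign_clones(full_table(values), t2)
        assert high.n_clones >= low.n_clones
        for members in high.clone_members.values():
            root = low.clone_of[members[0]]
            assert all(low.clone_of[s] == root for s in members)


class TestSimulatedContrast:
    def test_sibs_sit_below_gap_below_duplicates(self, default_dataset):
        """Sexual full sibs share far fewer het loci than duplicate libraries:
        mean(sib) < gap.low < gap.high < min(duplicate)."""
        ds = default_dataset
        sib_samples = sorted(
            s for s, t in ds.truth.taxon_of.items() if t == "Taxon_B_diploid"
        )
        m = ds.genotypes.select_samples(sib_samples)
        m = ck.filter_loci_by_missingness(m, 0.0)
        table = ck.pairwise_het_similarities(m)
        dups = [p for p in ck.duplicate_pairs(ds.metadata)
                if p[0] in sib_samples and p[1] in sib_samples]
        cal = ck.calibrate_threshold(table, dups)
        dup_vals = [table.pair(*p)["sim_percent"] for p in dups]
        clone_of = ds.truth.clone_of
        sib_vals = [
            row["sim_percent"]
            for _, row in table.defined().iterrows()
            if clone_of[row["sample_a"]] != clone_of[row["sample_b"]]
        ]
        assert cal.gap is not None
        # duplicates are the only same-clone pairs in this taxon, so the gap
        # closes exactly at the duplicate floor
        assert np.mean(sib_vals) < cal.gap[0] < cal.gap[1] <= min(dup_vals)

    def test_perfect_clone_recovery_on_default_simulation(self, default_dataset):
        """Pairwise precision and recall of clone co-membership equal 1.0
        against simulation truth under the reference conditions."""
        ds = default_dataset
        m = ck.filter_loci_by_missingness(ds.genotypes, 0.30)
        dm = ck.p_distance_matrix(m)
        groups = ck.partition_samples(
            dm, ck.simulate.SCENARIO_PARTITION_SIMILARITY
        )
        predicted = {}
        for group in groups:
            sub = ck.filter_loci_by_missingness(
                ds.genotypes.select_samples(group), 0.0)
            table = ck.pairwise_het_similarities(sub)
            dups = [p for p in ck.duplicate_pairs(ds.metadata)
                    if p[0] in group and p[1] in group]
            cal = ck.calibrate_threshold(table, dups)
            asg = ck.assign_clones(table, cal.threshold_percent, cal)
            predicted.update({s: f"g{groups.index(group)}:{c}"
                              for s, c in asg.clone_of.items()})
        truth = ds.truth.clone_of
        samples = sorted(predicted)
        tp = fp = fn = 0
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                same_pred = predicted[a] == predicted[b]
                same_true = truth[a] == truth[b]
                tp += same_pred and same_true
                fp += same_pred and not same_true
                fn += same_true and not same_pred
        assert fp == 0 and fn == 0 and tp > 0
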