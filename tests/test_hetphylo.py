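import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mengen.hetphylo import (
    GERMLINE,
    UnanalyzablePatientError,
    build_tree,
    discovery_curve,
    driver_vs_passenger_overlap,
    expected_clonal_af,
    mutation_detection_power,
    pairwise_shared_fraction,
    partition_mutations,
    per_patient_average,
    powered_set,
    presence_matrix,
)

from _oracles import discovery_curve_enumeration, least_squares_quartet
from conftest import make_meta, make_mutation


def keyset(*positions):
    return {("1", p, "C", "T") for p in positions}


class TestPartition:
    def test_identical_samples_all_ubiquitous(self):
        part = partition_mutations({"A": keyset(1, 2, 3), "B": keyset(1, 2, 3)}, "P")
        assert (part.n_ubiquitous, part.n_shared, part.n_private) == (3, 0, 0)

    def test_disjoint_samples_all_private(self):
        part = partition_mutations({"A": keyset(1, 2), "B": keyset(3, 4)}, "P")
        assert (part.n_ubiquitous, part.n_shared, part.n_private) == (0, 0, 4)

    def test_mutation_in_two_of_three_is_shared(self):
        part = partition_mutations(
            {"A": keyset(1, 9), "B": keyset(2, 9), "C": keyset(3)}, "P"
        )
        assert part.n_shared == 1
        assert part.n_private == 3

    def test_single_sample_unanalyzable(self):
        with pytest.raises(UnanalyzablePatientError):
            partition_mutations({"A": keyset(1)}, "P")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sets(st.integers(0, 12)), min_size=2, max_size=5
        )
    )
    def test_categories_partition_all_events(self, sets):
        samples = {f"S{i}": keyset(*s) for i, s in enumerate(sets)}
        part = partition_mutations(samples, "P")
        total = len(set().union(*(keyset(*s) for s in sets)))
        assert part.n_total == total

    def test_scna_analog_identical_profiles_share_fully(self):
        # arm-call vectors in place of mutation keys
        arms = {("22q", "loss"), ("1p", "loss")}
        assert pairwise_shared_fraction(arms, set(arms)) == 1.0


class TestPairwiseSharedFraction:
    def test_identical(self):
        assert pairwise_shared_fraction(keyset(1, 2), keyset(1, 2)) == 1.0

    def test_disjoint(self):
        assert pairwise_shared_fraction(keyset(1), keyset(2)) == 0.0

    def test_jaccard_arithmetic(self):
        a, b = keyset(*range(10)), keyset(*range(5, 15))
        assert pairwise_shared_fraction(a, b) == pytest.approx(5 / 15)

    def test_per_sample_denominator_variant(self):
        a, b = keyset(*range(10)), keyset(*range(5, 15))
        assert pairwise_shared_fraction(a, b, "per_sample") == pytest.approx(0.5)

    def test_patient_average_over_pairs(self):
        samples = {"A": keyset(1, 2), "B": keyset(1, 2), "C": keyset(3)}
        # pairs: (A,B)=1, (A,C)=0, (B,C)=0
        assert per_patient_average(samples) == pytest.approx(1 / 3)


class TestDiscoveryCurve:
    def test_identical_samples_flat_at_one(self):
        curve = discovery_curve({"A": keyset(1, 2), "B": keyset(1, 2)})
        assert curve == [1.0, 1.0]

    def test_fully_private_equal_halves(self):
        curve = discovery_curve({"A": keyset(1, 2), "B": keyset(3, 4)})
        assert curve == pytest.approx([0.5, 1.0])

    def test_matches_subset_enumeration_for_toy_patient(self, rng):
        sets = [set(rng.choice(20, size=rng.integers(3, 9), replace=False))
                for _ in range(4)]
        samples = {f"S{i}": keyset(*s) for i, s in enumerate(sets)}
        expected = discovery_curve_enumeration([keyset(*s) for s in sets])
        assert discovery_curve(samples) == pytest.approx(expected)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 15)), min_size=2, max_size=5).filter(
        lambda s: any(s)
    ))
    def test_monotone_and_complete(self, sets):
        samples = {f"S{i}": keyset(*s) for i, s in enumerate(sets)}
        curve = discovery_curve(samples)
        assert all(b >= a - 1e-12 for a, b in zip(curve, curve[1:]))
        assert curve[-1] == pytest.approx(1.0)


class TestDetectionPower:
    def test_deep_coverage_near_certain(self):
        assert mutation_detection_power(100, 0.25) >= 0.9999

    def test_shallow_coverage_hopeless(self):
        assert mutation_detection_power(3, 0.05) < 0.001

    def test_clonal_af_closed_form(self):
        assert expected_clonal_af(1.0, 2, 1) == pytest.approx(0.5)

    def test_powered_set_all_pass_at_depth(self):
        pres = presence_matrix({"A": keyset(1, 2), "B": keyset(2, 3)})
        metas = {s: make_meta(sample_id=s, purity=0.9, mean_coverage=100.0)
                 for s in ("A", "B")}
        assert set(powered_set(pres, metas)) == set(pres.columns)

    def test_powered_set_site_depth_exclusion(self):
        pres = presence_matrix({"A": keyset(1, 2), "B": keyset(2, 3)})
        metas = {s: make_meta(sample_id=s, purity=0.9, mean_coverage=100.0)
                 for s in ("A", "B")}
        weak = ("1", 1, "C", "T")
        kept = powered_set(pres, metas, site_depths={weak: {"B": 4.0}})
        assert weak not in kept
        assert len(kept) == len(pres.columns) - 1

    def test_missing_metadata_is_actionable(self):
        pres = presence_matrix({"A": keyset(1), "B": keyset(1)})
        with pytest.raises(KeyError, match="metadata"):
            powered_set(pres, {"A": make_meta(sample_id="A")})


class TestBuildTree:
    @staticmethod
    def _tree(samples, chronology=None):
        return build_tree(presence_matrix(samples), "P", chronology=chronology)

    def test_dominant_overlap_forms_sister_pair(self):
        shared = set(range(9))
        samples = {
            "A": keyset(*shared, 100),
            "B": keyset(*shared, 200),
            "C": keyset(0, 300, 301, 302, 303, 304, 305, 306, 307),
        }
        t = self._tree(samples)
        d = t.tip_distances
        assert d.loc["A", "B"] < d.loc["A", "C"]
        assert d.loc["A", "B"] < d.loc["B", "C"]

    def test_identical_samples_zero_length_cherry(self):
        t = self._tree({"A": keyset(1, 2), "B": keyset(1, 2)})
        assert t.tip_distances.loc["A", "B"] == pytest.approx(0.0)

    def test_input_order_invariance(self):
        samples = {
            "A": keyset(1, 2, 3), "B": keyset(1, 2, 4), "C": keyset(7, 8, 9),
        }
        t1 = self._tree(dict(samples))
        t2 = self._tree(dict(reversed(list(samples.items()))))
        assert t1.newick == t2.newick

    def test_germline_outgroup_present(self):
        t = self._tree({"A": keyset(1), "B": keyset(2)})
        assert GERMLINE in t.newick

    def test_nj_matches_least_squares_quartet_oracle(self, rng):
        # quartets built from a true cherry structure (trunk + two sibling
        # pairs with private mutations), so the Jaccard distances are close
        # to additive and both methods must recover the same split
        for _ in range(20):
            trunk = set(rng.choice(200, size=int(rng.integers(8, 15)), replace=False))
            pool = [int(x) for x in range(200, 400)]
            rng.shuffle(pool)
            it = iter(pool)
            branch1 = {next(it) for _ in range(int(rng.integers(4, 10)))}
            branch2 = {next(it) for _ in range(int(rng.integers(4, 10)))}
            sets = []
            for branch in (branch1, branch1, branch2, branch2):
                private = {next(it) for _ in range(int(rng.integers(1, 6)))}
                sets.append(trunk | branch | private)
            order = rng.permutation(4)
            sets = [sets[i] for i in order]
            ids = ["S1", "S2", "S3", "S4"]
            samples = {i: keyset(*s) for i, s in zip(ids, sets)}
            dist = [[0.0] * 4 for _ in range(4)]
            for i, j in itertools.combinations(range(4), 2):
                d = 1 - pairwise_shared_fraction(samples[ids[i]], samples[ids[j]])
                dist[i][j] = dist[j][i] = d
            split = least_squares_quartet(dist)
            t = self._tree(samples)
            dm = t.tip_distances
            (a, b), (c, d_) = split
            # the oracle's sister pairs are mutually closest in the NJ tree
            within = dm.loc[ids[a], ids[b]] + dm.loc[ids[c], ids[d_]]
            across = min(
                dm.loc[ids[a], ids[c]] + dm.loc[ids[b], ids[d_]],
                dm.loc[ids[a], ids[d_]] + dm.loc[ids[b], ids[c]],
            )
            assert within <= across + 1e-9


class TestClassifyTopology:
    def test_perfect_ladder_is_linear(self):
        # nested sets: each resection adds private mutations to the last
        samples = {
            "S1": keyset(*range(10)),
            "S2": keyset(*range(20)),
            "S3": keyset(*range(30)),
            "S4": keyset(*range(40)),
        }
        t = build_tree(presence_matrix(samples), "P",
                       chronology=["S1", "S2", "S3", "S4"])
        assert t.adjacency_score == 1.0
        assert t.topology_call == "linear"

    def test_shuffled_cherries_are_branched(self):
        # chronology S1..S4 but lineage cherries pair (S1,S3) and (S2,S4)
        trunk = set(range(10))
        branch_a, branch_b = set(range(100, 115)), set(range(200, 215))
        samples = {
            "S1": keyset(*(trunk | branch_a)),
            "S2": keyset(*(trunk | branch_b)),
            "S3": keyset(*(trunk | branch_a | {116, 117})),
            "S4": keyset(*(trunk | branch_b | {216, 217})),
        }
        t = build_tree(presence_matrix(samples), "P",
                       chronology=["S1", "S2", "S3", "S4"])
        assert t.adjacency_score < 0.5
        assert t.topology_call == "branched"

    def test_two_sample_series_trivially_linear(self):
        t = build_tree(presence_matrix({"S1": keyset(1, 2), "S2": keyset(1, 3)}),
                       "P", chronology=["S1", "S2"])
        assert t.topology_call == "linear"


class TestDriverVsPassengerOverlap:
    @staticmethod
    def _pair(shared_genes, private_a_genes, private_b_genes):
        pos = itertools.count(1)
        a, b = [], []
        for g in shared_genes:
            p = next(pos)
            a.append(make_mutation(gene=g, pos=p))
            b.append(make_mutation(gene=g, pos=p, sample_id="S2"))
        for g in private_a_genes:
            a.append(make_mutation(gene=g, pos=next(pos)))
        for g in private_b_genes:
            b.append(make_mutation(gene=g, pos=next(pos), sample_id="S2"))
        return a, b

    def test_all_shared_gives_p_one(self):
        pair = self._pair(["NF2", "G1", "G2"], [], [])
        counts, p = driver_vs_passenger_overlap([pair], ["NF2"])
        assert counts == (1, 0, 2, 0)
        assert p == 1.0

    def test_published_counts_reproduce_significance(self):
        pairs = []
        pairs.append(self._pair(["NF2"] * 0 + [f"D{i}" for i in range(21)]
                                + [f"P{i}" for i in range(18)],
                                [f"Q{i}" for i in range(43)], []))
        pairs.append(self._pair([], ["D99"], []))  # the one unshared driver
        drivers = [f"D{i}" for i in range(21)] + ["D99"]
        counts, p = driver_vs_passenger_overlap(pairs, drivers)
        assert counts == (21, 1, 18, 43)
        assert p < 0.001

    def test_empty_driver_list_rejected(self):
        with pytest.raises(ValueError):
            driver_vs_passenger_overlap([], [])
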