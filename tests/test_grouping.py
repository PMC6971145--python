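"""Locus inference and allele-group clustering thresholds."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bfbl.distances import DistanceMatrix
from bfbl.grouping import GroupingConfig, assign_locus, cluster, pair_zone


def _dm(labels, pairs, domains=None):
    n = len(labels)
    M = np.zeros((n, n), dtype=int)
    for (a, b), v in pairs.items():
        i, j = labels.index(a), labels.index(b)
        M[i, j] = M[j, i] = v
    doms = None
    if domains is not None:
        doms = {}
        for key in ("alpha1", "alpha2"):
            Dk = np.zeros((n, n), dtype=int)
            for (a, b), v in domains[key].items():
                i, j = labels.index(a), labels.index(b)
                Dk[i, j] = Dk[j, i] = v
            doms[key] = Dk
    return DistanceMatrix(tuple(labels), M, "aa", 90, None, doms)


class TestPairZone:
    @pytest.mark.parametrize(
        "total,expect",
        [(0, "variant"), (4, "variant"), (5, "review"), (9, "review"), (10, "beyond")],
    )
    def test_blb_thresholds(self, total, expect):
        assert pair_zone(total, None, "BLB") == expect

    @pytest.mark.parametrize(
        "domains,expect",
        [
            ((4, 3), "variant"),  # the known seven-difference pair groups
            ((4, 4), "variant"),
            ((5, 2), "review"),  # per-domain cutoff exceeded
            ((4, 5), "review"),  # total cutoff exceeded
            ((9, 9), "review"),
            ((10, 0), "beyond"),
        ],
    )
    def test_bf_conjunction_rule(self, domains, expect):
        assert pair_zone(sum(domains), domains, "BF") == expect

    def test_bf_requires_domain_split(self):
        with pytest.raises(Exception):
            pair_zone(3, None, "BF")


class TestCluster:
    def test_identical_classes_single_group(self):
        dm = _dm(["a", "b"], {("a", "b"): 0})
        groups = cluster(["a", "b"], dm, "BLB1")
        assert len(groups) == 1 and groups[0].members == ("a", "b")

    def test_far_classes_split(self):
        dm = _dm(["a", "b"], {("a", "b"): 25})
        assert len(cluster(["a", "b"], dm, "BLB1")) == 2

    def test_chain_within_cutoff_not_chained(self):
        doms = {
            "alpha1": {("a", "b"): 2, ("b", "c"): 2, ("a", "c"): 4},
            "alpha2": {("a", "b"): 2, ("b", "c"): 2, ("a", "c"): 4},
        }
        dm = _dm(["a", "b", "c"], {("a", "b"): 4, ("b", "c"): 4, ("a", "c"): 8}, doms)
        groups = cluster(["a", "b", "c"], dm, "BF2")
        assert len(groups) == 1 and not groups[0].chained

    def test_chain_beyond_cutoff_flagged(self):
        doms = {
            "alpha1": {("a", "b"): 2, ("b", "c"): 2, ("a", "c"): 6},
            "alpha2": {("a", "b"): 2, ("b", "c"): 2, ("a", "c"): 6},
        }
        dm = _dm(["a", "b", "c"], {("a", "b"): 4, ("b", "c"): 4, ("a", "c"): 12}, doms)
        groups = cluster(["a", "b", "c"], dm, "BF2")
        assert len(groups) == 1 and groups[0].chained

    def test_review_zone_recorded_never_merged(self):
        dm = _dm(["a", "b"], {("a", "b"): 6})
        groups = cluster(["a", "b"], dm, "BLB2")
        assert len(groups) == 2
        assert all(("a", "b", 6) in g.review_edges for g in groups)

    def test_exactly_five_is_review_not_variant(self):
        dm = _dm(["a", "b"], {("a", "b"): 5})
        groups = cluster(["a", "b"], dm, "BLB2")
        assert len(groups) == 2

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(2)
        labels = [f"c{i}" for i in range(7)]
        for _ in range(10):
            n = len(labels)
            M = np.zeros((n, n), dtype=int)
            for i, j in itertools.combinations(range(n), 2):
                M[i, j] = M[j, i] = int(rng.choice([0, 2, 4, 6, 15, 30]))
            dm = DistanceMatrix(tuple(labels), M, "aa", 90)
            groups = cluster(labels, dm, "BLB1")
            # brute-force transitive closure over <=4 edges
            reach = {l: {l} for l in labels}
            changed = True
            while changed:
                changed = False
                for i, j in itertools.combinations(range(n), 2):
                    if M[i, j] <= 4 and reach[labels[i]] != reach[labels[j]]:
                        merged = reach[labels[i]] | reach[labels[j]]
                        for m in merged:
                            reach[m] = merged
                        changed = True
            expect = {frozenset(v) for v in reach.values()}
            assert {frozenset(g.members) for g in groups} == expect

    @given(st.permutations(["a", "b", "c", "d", "e"]))
    def test_order_invariant_and_idempotent(self, order):
        dm = _dm(
            ["a", "b", "c", "d", "e"],
            {
                ("a", "b"): 2,
                ("a", "c"): 3,
                ("b", "c"): 4,
                ("d", "e"): 1,
                ("a", "d"): 20,
                ("a", "e"): 20,
                ("b", "d"): 21,
                ("b", "e"): 21,
                ("c", "d"): 22,
                ("c", "e"): 22,
            },
        )
        baseline = cluster(["a", "b", "c", "d", "e"], dm, "BLB1")
        permuted = cluster(list(order), dm, "BLB1")
        assert permuted == baseline
        again = cluster([m for g in permuted for m in g.members], dm, "BLB1")
        assert again == baseline


class TestAssignLocus:
    refs = [
        ("r_bf1", "BF1", "A" * 90),
        ("r_bf2", "BF2", "C" * 90),
    ]

    def test_identical_to_reference(self):
        a = assign_locus("q", "A" * 90, self.refs)
        assert a.locus == "BF1" and not a.ambiguous and a.nearest_reference == "r_bf1"
        assert a.margin == 90

    def test_margin_below_tau_is_ambiguous(self):
        query = "A" * 46 + "C" * 44  # 44 vs 46 differences: margin 2 < 5
        a = assign_locus("q", query, self.refs)
        assert a.ambiguous

    def test_attested_both_loci_is_ambiguous_even_when_anchored(self):
        a = assign_locus(
            "q", "A" * 90, self.refs, anchored_claim="BLB1", attested_loci=("BLB1", "BLB2")
        )
        assert a.anchored and a.ambiguous

    def test_anchored_claim_overrides_inference(self):
        a = assign_locus("q", "C" * 90, self.refs, anchored_claim="BF1")
        assert a.locus == "BF1" and a.anchored and not a.ambiguous

    def test_no_references_is_an_error(self):
        with pytest.raises(Exception):
            assign_locus("q", "A" * 90, [])

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            GroupingConfig(review_lo=4)
        with pytest.raises(ValueError):
            GroupingConfig(review_hi=10)


class TestPipelineLocusResolution:
    def test_cross_locus_shared_class_routes_to_ambiguous(self):
        from bfbl import AMBIGUOUS_BLB, SynthConfig, curate, generate

        gen = generate(SynthConfig(seed=6, cross_locus_shares=1, pcr_error_rate=0.0))
        shared = set(gen.truth[gen.truth.locus == AMBIGUOUS_BLB].seq_id)
        assert shared, "generator planted no share"
        result = curate(gen.records, gen.evidence)
        for cls in result.classes.values():
            if set(cls.member_ids) & shared:
                assert cls.locus == AMBIGUOUS_BLB
                entry = result.registry.lookup(cls.digest)
                assert entry is not None and entry.name.f1 >= 101
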