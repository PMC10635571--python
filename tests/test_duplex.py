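"""Duplex-group clustering, connection score and filtering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lhclip.extract import Arm, ChimeraRecord, FragmentIndex, SCOPE_INTRA
from lhclip.duplex import (
    DuplexGroup,
    call_duplex_groups,
    cluster_duplex_groups,
    connection_score,
    compute_arm_coverage,
    filter_groups,
    score_groups,
)
from conftest import simulate_bundle


def chim(read_id, a_start, a_end, b_start, b_end, gene="G"):
    return ChimeraRecord(
        read_id,
        Arm("chr1", a_start, a_end, "+"),
        Arm("chr1", b_start, b_end, "+"),
        "chimeric_alignment",
        gene5=gene,
        gene3=gene,
    )


class TestConnectionScore:
    def test_worked_value(self):
        assert connection_score(20, 100, 400) == pytest.approx(0.1)

    @pytest.mark.parametrize("c", [1, 7, 250.5])
    def test_identity_case(self, c):
        assert connection_score(c, c, c) == pytest.approx(1.0)

    def test_zero_numerator_and_zero_coverage(self):
        assert connection_score(0, 50, 50) == 0.0
        assert connection_score(5, 0, 50) == 0.0

    def test_negative_input_is_domain_error(self):
        with pytest.raises(ValueError):
            connection_score(-1, 10, 10)

    @given(
        a=st.floats(0.1, 1e3), ca=st.floats(0.1, 1e3), cb=st.floats(0.1, 1e3),
        lam=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scaling_algebra(self, a, ca, cb, lam):
        """Common scaling of all three coverages leaves the score unchanged;
        scaling the numerator alone scales the score linearly."""
        base = connection_score(a, ca, cb)
        assert connection_score(lam * a, lam * ca, lam * cb) == pytest.approx(base)
        assert connection_score(lam * a, ca, cb) == pytest.approx(lam * base)


class TestClustering:
    def test_identical_termini_pair_is_rejected(self):
        groups = cluster_duplex_groups(
            [chim("r1", 100, 130, 300, 330), chim("r2", 100, 130, 300, 330)]
        )
        assert groups == []

    def test_three_mutually_overlapping_chimeras_form_one_group(self):
        chims = [
            chim("r1", 100, 130, 300, 330),
            chim("r2", 105, 135, 305, 335),
            chim("r3", 110, 140, 310, 340),
        ]
        groups = cluster_duplex_groups(chims)
        assert len(groups) == 1
        assert groups[0].n_members == 3
        assert groups[0].n_unique_termini == 3
        # consensus arms are member unions
        assert (groups[0].arm_a.start, groups[0].arm_a.end) == (100, 140)
        assert (groups[0].arm_b.start, groups[0].arm_b.end) == (300, 340)

    def test_left_arm_only_overlap_does_not_join(self):
        groups = cluster_duplex_groups(
            [chim("r1", 100, 130, 300, 330), chim("r2", 105, 135, 400, 430)]
        )
        assert groups == []  # singles with <2 distinct termini are dropped

    def test_arms_matched_by_genomic_order(self):
        # second chimera given with arms swapped in read order
        a = chim("r1", 100, 130, 300, 330)
        b = ChimeraRecord("r2", Arm("chr1", 305, 335, "+"),
                          Arm("chr1", 105, 135, "+"),
                          "chimeric_alignment", gene5="G", gene3="G")
        groups = cluster_duplex_groups([a, b])
        assert len(groups) == 1 and groups[0].n_members == 2

    def test_overlapping_arm_chimeras_are_excluded_as_artifacts(self):
        groups = cluster_duplex_groups(
            [chim("r1", 100, 200, 150, 250), chim("r2", 100, 200, 150, 250)]
        )
        assert groups == []

    def test_non_intra_input_rejected(self):
        c = ChimeraRecord("r1", Arm("chr1", 1, 30, "+"), Arm("chr1", 100, 130, "+"),
                          "chimeric_alignment", gene5="G1", gene3="G2")
        with pytest.raises(ValueError):
            cluster_duplex_groups([c])


def bruteforce_partition(chims):
    """Independent oracle: explicit graph over all pairs, networkx components."""
    import networkx as nx

    def arms(c):
        a, b = sorted((c.arm5, c.arm3), key=lambda x: (x.start, x.end))
        return None if b.start < a.end else (a, b)

    nodes = [(c, arms(c)) for c in chims]
    nodes = [(c, ab) for c, ab in nodes if ab is not None]
    g = nx.Graph()
    g.add_nodes_from(c.read_id for c, _ in nodes)
    for (c1, (a1, b1)), (c2, (a2, b2)) in itertools.combinations(nodes, 2):
        if c1.gene5 != c2.gene5:
            continue
        if a1.start < a2.end and a2.start < a1.end and b1.start < b2.end and b2.start < b1.end:
            g.add_edge(c1.read_id, c2.read_id)
    return {frozenset(comp) for comp in nx.connected_components(g)}


def random_instance(rng, n_max=50):
    n = int(rng.integers(2, n_max + 1))
    chims = []
    for i in range(n):
        gene = f"G{rng.integers(2)}"
        a = int(rng.integers(0, 500))
        al = int(rng.integers(15, 40))
        b = int(rng.integers(a + al + 1, a + al + 500))
        bl = int(rng.integers(15, 40))
        chims.append(chim(f"r{i:03d}", a, a + al, b, b + bl, gene=gene))
    return chims


def test_clustering_matches_bruteforce_components():
    """Implementation partition == networkx components on random instances."""
    rng = np.random.default_rng(99)
    for _ in range(100):
        chims = random_instance(rng)
        expected = {
            comp for comp in bruteforce_partition(chims) if len(comp) >= 2
        }
        got = {}
        for g in cluster_duplex_groups(chims):
            got.setdefault(frozenset(g.member_ids), None)
        # oracle components of size>=2 may still fail the distinct-termini
        # rule; compare after applying it
        def termini(c):
            a, b = sorted((c.arm5, c.arm3), key=lambda x: (x.start, x.end))
            return (a.start, a.end, b.start, b.end)

        by_id = {c.read_id: c for c in chims}
        expected_kept = {
            comp for comp in expected
            if len({termini(by_id[r]) for r in comp}) >= 2
        }
        assert set(got) == expected_kept


class TestScoringAndFiltering:
    def make_group(self, score):
        g = DuplexGroup("G", Arm("chr1", 0, 30, "+"), Arm("chr1", 100, 130, "+"),
                        ("r1", "r2"), 2)
        g.score = score
        return g

    def test_cutoff_is_strict(self):
        groups = [self.make_group(s) for s in (0.01, 0.0101, 0.009, 0.5)]
        kept = filter_groups(groups, cutoff=0.01)
        assert [g.score for g in kept] == [0.0101, 0.5]

    def test_empty_input(self):
        assert filter_groups([]) == []

    def test_arm_coverage_counts_overlapping_fragments(self):
        idx = FragmentIndex()
        idx.add("chr1", "+", [(100, 150)])
        idx.add("chr1", "+", [(140, 190)])
        idx.add("chr1", "+", [(500, 550)])       # elsewhere
        idx.add("chr1", "-", [(100, 150)])       # wrong strand
        arm = Arm("chr1", 120, 160, "+")
        assert compute_arm_coverage(arm, idx) == 2.0
        # monotone: adding a read never decreases coverage
        idx.add("chr1", "+", [(130, 135)])
        assert compute_arm_coverage(arm, idx) == 3.0

    def test_group_score_uses_member_count_as_numerator(self):
        chims = [chim("r1", 100, 130, 300, 330), chim("r2", 105, 135, 305, 335)]
        idx = FragmentIndex()
        for c in chims:
            idx.add("chr1", "+", [(c.arm5.start, c.arm5.end)])
            idx.add("chr1", "+", [(c.arm3.start, c.arm3.end)])
        (g,) = score_groups(cluster_duplex_groups(chims), idx)
        assert g.coverage_ab == 2.0
        assert g.coverage_a == 2.0 and g.coverage_b == 2.0
        assert g.score == pytest.approx(1.0)


def test_planted_duplex_recovery_on_simulated_data(tmp_path):
    """Planted duplexes recovered; no reported group breaks the termini rule."""
    _, _, truth, res = simulate_bundle(
        tmp_path, seed=29, n_duplexes=20, n_support=5,
        background_ligation_rate=0.05, duplicate_rate=0.05, low_mapq_rate=0.02,
    )
    groups = call_duplex_groups(res.by_scope(SCOPE_INTRA), res.coverage, cutoff=0.01)
    assert all(g.n_unique_termini >= 2 for g in groups)
    dup = truth[truth.mechanism == "planted_duplex"]
    members = [set(g.member_ids) for g in groups]
    recovered = sum(
        1
        for _, grp in dup.groupby("key")
        if any(len(set(grp.read_id) & m) >= 2 for m in members)
    )
    assert recovered / dup.key.nunique() >= 0.9
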