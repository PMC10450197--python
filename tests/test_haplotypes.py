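"""Haplotype normalisation, collapse, MJ networks, transmission clock."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_rotations, revcomp
from plasmidnet.haplotypes import (
    _kruskal_mst,
    align_members,
    canonical_rotation,
    collapse_haplotypes,
    filter_msa_members,
    hamming,
    median_joining_network,
    prepare_members,
    transmission_window,
    write_haplotype_table,
    write_network,
    write_nexus_haplotypes,
)
from plasmidnet.simulate import gen_haplotype_population, random_sequence

dna = st.text(alphabet="ACGT", min_size=4, max_size=40)


class TestCanonicalRotation:
    def test_gtac_enumerated(self):
        assert canonical_rotation("GTAC") == min(brute_rotations("GTAC"))
        assert canonical_rotation("GTAC") == "ACGT"

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(dna, st.integers(min_value=0, max_value=39))
    def test_orbit_invariance(self, seq, rot):
        r = rot % len(seq)
        rotated = seq[r:] + seq[:r]
        assert canonical_rotation(seq) == canonical_rotation(rotated)
        assert canonical_rotation(seq) == canonical_rotation(revcomp(seq))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(dna)
    def test_matches_brute_enumeration(self, seq):
        assert canonical_rotation(seq) == min(brute_rotations(seq))


class TestPrepareMembers:
    def test_exact_dtr_kept_and_trimmed(self, rng):
        circle = random_sequence(rng, 400)
        member = circle + circle[:12]
        out = prepare_members({"m": member})
        assert len(out) == 1
        assert len(out[0].canonical_seq) == 400
        assert out[0].canonical_seq == canonical_rotation(circle)

    def test_mismatched_dtr_dropped(self, rng):
        circle = random_sequence(rng, 400)
        tail = list(circle[:12])
        tail[5] = {"A": "C"}.get(tail[5], "A")
        out = prepare_members({"m": circle + "".join(tail)})
        assert out == []

    def test_no_dtr_dropped(self, rng):
        assert prepare_members({"m": random_sequence(rng, 400)}) == []


class TestAlignAndFilter:
    def test_identical_members_all_kept(self, rng):
        s = random_sequence(rng, 300)
        msa, ref = align_members({"a": s, "b": s, "c": s})
        assert set(filter_msa_members(msa, ref)) == {"a", "b", "c"}

    def test_long_deletion_removed(self, rng):
        s = random_sequence(rng, 300)
        deleted = s[:100] + s[103:]  # 3-bp deletion
        msa, ref = align_members({"ref": s, "alt": s, "del3": deleted},
                                 reference_id="ref")
        kept = filter_msa_members(msa, ref)
        assert "del3" not in kept and {"ref", "alt"} <= set(kept)

    def test_two_separate_single_base_indels_kept(self, rng):
        s = random_sequence(rng, 300)
        indel = s[:80] + s[81:200] + "A" + s[200:]  # 1-bp del + 1-bp ins
        msa, ref = align_members({"ref": s, "i": indel}, reference_id="ref")
        assert set(filter_msa_members(msa, ref)) == {"ref", "i"}


class TestCollapseHaplotypes:
    def test_identical_rows_one_haplotype(self):
        table = collapse_haplotypes({f"m{i}": "ACGTACGT" for i in range(10)})
        assert len(table.haplotypes) == 1
        assert len(table.haplotypes[0].member_ids) == 10

    def test_snp_splits(self):
        table = collapse_haplotypes({"a": "ACGT", "b": "ACGA"})
        assert len(table.haplotypes) == 2
        assert hamming(table.haplotypes[0].signature,
                       table.haplotypes[1].signature) == 1

    def test_single_base_gap_counts(self):
        table = collapse_haplotypes({"a": "AC-T", "b": "ACGT"})
        assert len(table.haplotypes) == 2
        assert hamming(table.haplotypes[0].signature,
                       table.haplotypes[1].signature) == 1

    def test_within_haplotype_identity_is_total(self, rng):
        pop = gen_haplotype_population(
            11, ancestor_len=600, mutation_tree=((0, 2), (1, 1)),
            members_per_hap=4)
        msa, ref = align_members(prepare_members(pop.members))
        table = collapse_haplotypes(filter_msa_members(msa, ref))
        for h in table.haplotypes:
            truths = {pop.truth["assignment"][m] for m in h.member_ids}
            assert len(truths) == 1  # no mixing across planted haplotypes
        assert len(table.haplotypes) == 3


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        net = median_joining_network({"A": "AAA", "B": "TTT"})
        assert net.edges == [("A", "B", 3)]

    def test_single_haplotype(self):
        net = median_joining_network({"A": "ACGT"})
        assert net.edges == [] and set(net.vectors) == {"A"}

    def test_three_star_matches_enumerated_optimum(self):
        bg = "A" * 10
        haps = {"A": "C" + bg[1:], "B": bg[:1] + "C" + bg[2:],
                "C": bg[:2] + "C" + bg[3:]}
        net = median_joining_network(haps)
        medians = [n for n in net.vectors if n not in net.observed]
        assert len(medians) == 1 and net.vectors[medians[0]] == bg
        assert sorted(w for *_, w in net.edges) == [1, 1, 1]

    def test_weight_bound_and_reachability(self):
        """Network weight never exceeds the observed-only MST; all
        observed haplotypes stay reachable (random sets, <=5 haps,
        <=12 columns)."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            cols = int(rng.integers(3, 13))
            vecs = {}
            while len(vecs) < n:
                v = "".join(rng.choice(list("ACGT"), cols))
                if v not in vecs.values():
                    vecs[f"H{len(vecs)}"] = v
            net = median_joining_network(dict(vecs))
            total = sum(w for *_, w in net.edges)
            mst = sum(w for *_, w in _kruskal_mst(dict(vecs)))
            assert total <= mst
            assert nx.is_connected(net.graph())
            assert all(w >= 1 for *_, w in net.edges)

    def test_planted_tree_recovered_as_paths(self):
        """Every planted parent-child edge appears as a network path of
        exactly the planted mutation count."""
        pop = gen_haplotype_population(
            3, ancestor_len=800,
            mutation_tree=((0, 1), (0, 1), (1, 2)), members_per_hap=3)
        msa, ref = align_members(prepare_members(pop.members))
        table = collapse_haplotypes(filter_msa_members(msa, ref))
        net = median_joining_network(table)
        g = net.graph()
        idx2id = {pop.truth["assignment"][h.member_ids[0]]: h.hap_id
                  for h in table.haplotypes}
        for parent, child, n_mut in pop.truth["edges"]:
            d = nx.dijkstra_path_length(g, idx2id[parent], idx2id[child],
                                        weight="weight")
            assert d == n_mut


class TestTransmissionWindow:
    def test_zero_mutation_window_rounds_to_ten_years(self):
        lo, hi = transmission_window(0, 5600)
        assert lo == 0.0 and hi == 10.0

    def test_point_estimate(self):
        lo, hi = transmission_window(2, 5600)
        lam = 30.0 * 5600 / 1_670_000
        assert lo == hi == pytest.approx(2 / lam)
        assert hi == pytest.approx(19.88, abs=0.01)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            transmission_window(0, 0)


def test_clonal_set_collapses_to_one_haplotype():
    """Rotations and strand flips of one circle are one haplotype."""
    pop = gen_haplotype_population(9, ancestor_len=500, mutation_tree=(),
                                   members_per_hap=6)
    norm = prepare_members(pop.members)
    assert len(norm) == 6
    assert len({m.canonical_seq for m in norm}) == 1
    msa, ref = align_members(norm)
    table = collapse_haplotypes(msa)
    assert len(table.haplotypes) == 1


def test_output_writers(tmp_path):
    pop = gen_haplotype_population(2, ancestor_len=300,
                                   mutation_tree=((0, 2),), members_per_hap=2)
    msa, ref = align_members(prepare_members(pop.members))
    table = collapse_haplotypes(msa)
    net = median_joining_network(table)
    write_haplotype_table(table, tmp_path / "h.tsv")
    write_network(net, tmp_path / "e.tsv", tmp_path / "n.graphml")
    write_nexus_haplotypes(table, tmp_path / "h.nex")
    assert (tmp_path / "h.tsv").read_text().startswith("hap_id")
    assert nx.read_graphml(tmp_path / "n.graphml").number_of_nodes() == 2
    assert (tmp_path / "h.nex").read_text().startswith("#NEXUS")
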