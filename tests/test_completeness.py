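"""DTR detection, circular paths, copy numbers, completeness fractions."""

import numpy as np
import pytest

from oracles import brute_dtr, revcomp
from plasmidnet.completeness import (
    FWD,
    REV,
    AssemblyGraph,
    CircularPath,
    best_hit_anchors,
    confirm_circular_by_reads,
    dtr_completeness,
    estimate_completeness,
    find_dtr,
    map_read,
    node_copy_number,
    path_copy_numbers,
    read_fastg,
    shortest_circular_path,
    validate_path_with_pairs,
    write_fastg,
)
from plasmidnet.simulate import gen_assembly_fixture, random_sequence


class TestFindDTR:
    def test_planted_terminal_repeat(self, rng):
        x = random_sequence(rng, 15)
        core = random_sequence(rng, 500)
        res = find_dtr(x + core + x)
        assert res.found and res.length == 15 and res.n_mismatch == 0

    def test_planted_repeat_with_one_mismatch(self, rng):
        x = random_sequence(rng, 20)
        y = list(x)
        y[7] = {"A": "C"}.get(y[7], "A")
        res = find_dtr(x + random_sequence(rng, 400) + "".join(y))
        assert res.found and res.length == 20 and res.n_mismatch == 1

    def test_agrees_with_brute_force_scan(self):
        """100 random 300-bp cases against the all-length oracle."""
        r = np.random.default_rng(42)
        for case in range(100):
            seq = random_sequence(r, 300)
            if case % 3 == 0:  # plant a repeat in a third of the cases
                L = int(r.integers(10, 40))
                seq = seq[:L] + seq[L:-L] + seq[:L]
            mine = find_dtr(seq)
            oracle = brute_dtr(seq)
            assert (mine.found, mine.length, mine.n_mismatch) == oracle

    def test_circular_round_trip(self):
        """Linearised circles with a 15-bp duplicated terminus."""
        r = np.random.default_rng(7)
        for _ in range(20):
            circle = random_sequence(r, 400)
            linear = circle + circle[:15]
            res = find_dtr(linear, max_mismatch=0)
            assert res.found and res.length == 15

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_dtr("ACGTACGTACGTACG")


class TestConfirmCircularByReads:
    @pytest.fixture
    def circular(self, rng):
        circle = random_sequence(rng, 3000)
        linear = circle + circle[:15]
        dtr = find_dtr(linear)
        return circle, linear, dtr

    @staticmethod
    def junction_pairs(circle, read_len=100):
        pairs = []
        for off in (25, 40, 55):
            pairs.append((circle[-read_len - off : -off],
                          circle[off : off + read_len]))
        return pairs

    def test_junction_pairs_confirm(self, circular):
        circle, linear, dtr = circular
        assert confirm_circular_by_reads(linear, dtr,
                                         self.junction_pairs(circle))

    def test_interior_reads_do_not_confirm(self, circular):
        circle, linear, dtr = circular
        pairs = [(circle[1000:1100], circle[1300:1400])]
        assert not confirm_circular_by_reads(linear, dtr, pairs)

    def test_low_coverage_mate_fails_filter(self, circular, rng):
        """A mate with a 15% unaligned overhang is below 90% coverage."""
        circle, linear, dtr = circular
        good_right = circle[-130:-30]
        bad_left = random_sequence(rng, 15) + circle[30:115]  # 85% aligns
        cov, _, _ = map_read(bad_left, circle)
        assert cov < 0.90
        assert not confirm_circular_by_reads(linear, dtr,
                                             [(bad_left, good_right)])

    def test_no_reads_warns_false(self, circular):
        _, linear, dtr = circular
        with pytest.warns(UserWarning):
            assert confirm_circular_by_reads(linear, dtr, []) is False


def _simple_graph(rng, lens):
    g = AssemblyGraph()
    for i, L in enumerate(lens):
        g.add_node(f"n{i}", random_sequence(rng, L), 10.0)
    return g


class TestShortestCircularPath:
    def test_self_loop_single_node(self, rng):
        g = _simple_graph(rng, [1000])
        g.add_edge(("n0", FWD), ("n0", FWD))
        path = shortest_circular_path(g, [("n0", FWD)])
        assert path.steps == [("n0", FWD)] and path.total_len == 1000

    def test_dead_end_anchor_returns_none(self, rng):
        g = _simple_graph(rng, [1000, 1000])
        g.add_edge(("n0", FWD), ("n1", FWD))  # no way back
        assert shortest_circular_path(g, [("n0", FWD)]) is None

    def test_picks_shorter_of_two_cycles(self, rng):
        """Anchor n0: cycle via n1 (9 kb total) vs via n2+n3 (14 kb)."""
        g = _simple_graph(rng, [4000, 5000, 4000, 6000])
        g.add_edge(("n0", FWD), ("n1", FWD))
        g.add_edge(("n1", FWD), ("n0", FWD))
        g.add_edge(("n0", FWD), ("n2", FWD))
        g.add_edge(("n2", FWD), ("n3", FWD))
        g.add_edge(("n3", FWD), ("n0", FWD))
        path = shortest_circular_path(g, [("n0", FWD)])
        assert [s[0] for s in path.steps] == ["n0", "n1"]
        assert path.total_len == 9000

    def test_unknown_anchor_rejected(self, rng):
        g = _simple_graph(rng, [1000])
        with pytest.raises(ValueError):
            shortest_circular_path(g, ["ghost"])


class TestNodeCopyNumber:
    def _path_graph(self, rng, abunds, with_neighbors=()):
        g = AssemblyGraph()
        for i, a in enumerate(abunds):
            g.add_node(f"n{i}", random_sequence(rng, 500), a)
        for i in range(len(abunds)):
            g.add_edge((f"n{i}", FWD), (f"n{(i + 1) % len(abunds)}", FWD))
        for name, a, attach in with_neighbors:
            g.add_node(name, random_sequence(rng, 500), a)
            g.add_edge((attach, FWD), (name, FWD))
        return g

    def test_isolated_node_c_equals_one(self, rng):
        g = self._path_graph(rng, [10.0])
        path = CircularPath(steps=[("n0", FWD)], total_len=500)
        c, multi = node_copy_number(path, 0, g, abase=10.0)
        assert c == 1.0 and not multi

    def test_printed_formula_arithmetic(self, rng):
        """A=30, Ap=8, Af=12, Abase=10 -> C = (30-8)/10 = 2.2, multi."""
        g = AssemblyGraph()
        g.add_node("n0", random_sequence(rng, 500), 30.0)
        g.add_node("prev", random_sequence(rng, 500), 5.0)
        g.add_node("nxt", random_sequence(rng, 500), 5.0)
        g.add_node("off_p", random_sequence(rng, 500), 8.0)
        g.add_node("off_f", random_sequence(rng, 500), 12.0)
        g.add_edge(("prev", FWD), ("n0", FWD))
        g.add_edge(("n0", FWD), ("nxt", FWD))
        g.add_edge(("nxt", FWD), ("prev", FWD))
        g.add_edge(("off_p", FWD), ("n0", FWD))
        g.add_edge(("n0", FWD), ("off_f", FWD))
        path = CircularPath(steps=[("prev", FWD), ("n0", FWD), ("nxt", FWD)],
                            total_len=1500)
        c, multi = node_copy_number(path, 1, g, abase=10.0)
        assert c == pytest.approx(2.2) and multi

    def test_opposite_orientation_needs_2_8(self, rng):
        g = AssemblyGraph()
        g.add_node("n0", random_sequence(rng, 500), 22.0)
        g.add_node("n1", random_sequence(rng, 500), 10.0)
        g.add_edge(("n0", FWD), ("n1", FWD))
        g.add_edge(("n1", FWD), ("n0", REV))
        g.add_edge(("n0", REV), ("n1", REV))
        g.add_edge(("n1", REV), ("n0", FWD))
        path = CircularPath(
            steps=[("n0", FWD), ("n1", FWD), ("n0", REV), ("n1", REV)],
            total_len=2000)
        c, multi = node_copy_number(path, 0, g, abase=10.0)
        assert c == pytest.approx(2.2)
        assert not multi  # both orientations present: needs C > 2.8

    def test_zero_abase_rejected(self, rng):
        g = self._path_graph(rng, [10.0])
        path = CircularPath(steps=[("n0", FWD)], total_len=500)
        with pytest.raises(ValueError):
            node_copy_number(path, 0, g, abase=0.0)

    def test_multiplicity_classification_under_noise(self):
        """Planted multiplicities {1,2,3} with +-10% abundance noise:
        the 1.8 threshold classifies >= 95% of nodes correctly."""
        correct = total = 0
        for seed in range(10):
            fx = gen_assembly_fixture(
                seed, plasmid_len=9000, n_nodes=6,
                copy_plan=[1, 1, 2, 1, 3, 1], coverage=30.0,
                abundance_noise=0.10)
            path = shortest_circular_path(fx.graph, fx.truth["anchors"])
            assert path is not None
            mult = {nid: fx.truth["copy_plan"][i]
                    for i, nid in enumerate(sorted(
                        fx.graph.seqs, key=lambda n: int(n.split("_")[1])))}
            for i, (nid, _) in enumerate(path.steps):
                c, multi = node_copy_number(path, i, fx.graph, abase=30.0)
                total += 1
                correct += (multi == (mult[nid] >= 2))
        assert correct / total >= 0.95


class TestValidatePath:
    def test_uniform_junction_pairs_validate(self):
        fx = gen_assembly_fixture(3, plasmid_len=8000, n_nodes=5)
        path = shortest_circular_path(fx.graph, fx.truth["anchors"])
        assert validate_path_with_pairs(path, fx.graph, fx.read_pairs)

    def test_missing_junction_fails(self):
        fx = gen_assembly_fixture(3, plasmid_len=8000, n_nodes=5)
        path = shortest_circular_path(fx.graph, fx.truth["anchors"])
        order = fx.truth["order"]
        # drop every pair spanning the junction after the first node
        first, second = order[0], order[1]
        kept = [
            (m1, m2) for m1, m2 in fx.read_pairs
            if not ((map_read(m1, fx.graph.seqs[first])[0] >= 0.9
                     and map_read(m2, fx.graph.seqs[second])[0] >= 0.9)
                    or (map_read(m2, fx.graph.seqs[first])[0] >= 0.9
                        and map_read(m1, fx.graph.seqs[second])[0] >= 0.9))
        ]
        assert not validate_path_with_pairs(path, fx.graph, kept)

    def test_multicopy_node_needs_both_sides(self):
        """A twice-traversed node loses validation when pairs spanning
        one of its junctions are removed."""
        fx = gen_assembly_fixture(5, plasmid_len=9000, n_nodes=4,
                                  copy_plan=[1, 2, 1, 1])
        path = shortest_circular_path(fx.graph, fx.truth["anchors"])
        order = fx.truth["order"]
        multi = [n for n in set(order) if order.count(n) == 2][0]
        idx = order.index(multi)
        downstream = order[(idx + 1) % len(order)]
        kept = [
            (m1, m2) for m1, m2 in fx.read_pairs
            if not ((map_read(m1, fx.graph.seqs[multi])[0] >= 0.9
                     and map_read(m2, fx.graph.seqs[downstream])[0] >= 0.9)
                    or (map_read(m2, fx.graph.seqs[multi])[0] >= 0.9
                        and map_read(m1, fx.graph.seqs[downstream])[0] >= 0.9))
        ]
        assert validate_path_with_pairs(path, fx.graph, fx.read_pairs)
        assert not validate_path_with_pairs(path, fx.graph, kept)


class TestEstimateCompleteness:
    def test_single_node_full_coverage(self, rng):
        g = _simple_graph(rng, [2000])
        g.add_edge(("n0", FWD), ("n0", FWD))
        path = shortest_circular_path(g, [("n0", FWD)])
        res = estimate_completeness("p", 2000, path, [("n0", FWD)], g)
        assert res.fraction == 1.0 and res.is_compls

    def test_gap_interpretation_arithmetic(self, rng):
        """8 kb PLS + 2 kb of off-PLS path nodes -> 0.8."""
        g = _simple_graph(rng, [8000, 2000])
        g.add_edge(("n0", FWD), ("n1", FWD))
        g.add_edge(("n1", FWD), ("n0", FWD))
        path = shortest_circular_path(g, [("n0", FWD)])
        res = estimate_completeness("p", 8000, path, [("n0", FWD)], g)
        assert res.fraction == pytest.approx(0.8) and res.is_compls

    def test_below_threshold_not_compls(self, rng):
        g = _simple_graph(rng, [5500, 4500])
        g.add_edge(("n0", FWD), ("n1", FWD))
        g.add_edge(("n1", FWD), ("n0", FWD))
        path = shortest_circular_path(g, [("n0", FWD)])
        res = estimate_completeness("p", 5500, path, [("n0", FWD)], g)
        assert res.fraction == 0.55 and not res.is_compls

    def test_all_nodes_mode_is_the_literal_reading(self, rng):
        g = _simple_graph(rng, [2000])
        g.add_edge(("n0", FWD), ("n0", FWD))
        path = shortest_circular_path(g, [("n0", FWD)])
        res = estimate_completeness("p", 2000, path, [("n0", FWD)], g,
                                    lg_mode="all_nodes")
        assert res.fraction == pytest.approx(0.5)

    def test_dtr_route_is_complete(self):
        res = dtr_completeness("p")
        assert res.fraction == 1.0 and res.method == "dtr_circular"
        assert res.is_compls

    @pytest.mark.parametrize("frac", [0.5, 0.7, 0.9, 1.0])
    def test_planted_fraction_recovery(self, frac):
        for seed in (1, 2, 3):
            fx = gen_assembly_fixture(seed, plasmid_len=8000, n_nodes=5,
                                      fraction_observed=frac)
            anchors = best_hit_anchors(fx.pls_seq, fx.graph)
            path = shortest_circular_path(fx.graph, anchors)
            assert validate_path_with_pairs(path, fx.graph, fx.read_pairs)
            res = estimate_completeness("p", len(fx.pls_seq), path,
                                        anchors, fx.graph)
            assert res.fraction == pytest.approx(fx.truth["fraction"], abs=1e-9)
            assert res.fraction == pytest.approx(frac, abs=0.02)


def test_fastg_round_trip(tmp_path):
    fx = gen_assembly_fixture(11, plasmid_len=6000, n_nodes=4,
                              abundance_noise=0.05)
    p = tmp_path / "assembly.fastg"
    write_fastg(fx.graph, p)
    back = read_fastg(p)
    assert back.seqs == fx.graph.seqs
    for nid, a in fx.graph.abundances.items():
        assert back.abundances[nid] == pytest.approx(a, rel=1e-4)
    assert back.edges == fx.graph.edges
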