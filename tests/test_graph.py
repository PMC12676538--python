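"""Splice-graph construction, pruning rules and phasing extraction."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from conftest import make_fragment
from umiasm.graph import (EmptyLocusError, IRParams, SINK, SOURCE,
                          build_graph, extract_phasing_paths,
                          full_ir_removal_set, isolated_removal_set,
                          partial_ir_removal_set, prune,
                          prune_full_intron_retention,
                          prune_isolated_vertices,
                          prune_partial_intron_retention)
from umiasm.loci import Locus
from umiasm.simulate import (PRUNING_DEMO, GraphFixtureError,
                             make_graph_fixture, random_splice_graph)


def _locus(frags, strand="+"):
    return Locus("chr1", strand, min(f.start for f in frags),
                 max(f.end for f in frags), list(frags))


class TestImmediatelyJoint:
    def test_abutting_true_gap_false(self):
        g = make_graph_fixture(
            "graph c +\nvertex a 10 20\nvertex b 20 35\nvertex c 40 50\n"
            "edge s a 1\nedge a b 1\nedge b c 1\nedge c t 1\n")
        assert g.immediately_joint(0, 1) is True
        assert g.immediately_joint(1, 2) is False

    def test_overlap_raises(self):
        from umiasm.graph import SpliceGraph
        g = SpliceGraph("c", "+")
        g.add_vertex(0, 10, 20)
        g.add_vertex(1, 19, 35)
        with pytest.raises(ValueError):
            g.immediately_joint(0, 1)


class TestBuildGraph:
    def test_single_exon_coverage(self):
        # ten unspliced 100 bp fragments tiling a 300 bp exon
        starts = [0, 20, 40, 60, 80, 100, 120, 140, 160, 200]
        frags = [make_fragment(blocks=((s, s + 100),), key=s) for s in starts]
        g = build_graph(_locus(frags))
        assert g.n_vertices == 1
        assert g.interval(0) == (0, 300)
        assert g.wv(0) == pytest.approx(10 * 100 / 300)
        assert g.has_edge(SOURCE, 0) and g.has_edge(0, SINK)

    def test_shared_donor_two_out_edges(self):
        a = [make_fragment(blocks=((0, 100), (200, 300)), key=("a", i))
             for i in range(4)]
        b = [make_fragment(blocks=((0, 100), (400, 500)), key=("b", i))
             for i in range(7)]
        g = build_graph(_locus(a + b))
        donor = next(v for v in g.vertices() if g.interval(v) == (0, 100))
        outs = [u for u in g.out_neighbors(donor) if u != SINK]
        assert len(outs) == 2
        weights = sorted(g.we(donor, u) for u in outs)
        assert weights == [4, 7]

    def test_coverage_gap_splits_vertices(self):
        frags = [make_fragment(blocks=((0, 100),), key=1),
                 make_fragment(blocks=((150, 250),), key=2)]
        g = build_graph(_locus(frags))
        assert g.n_vertices == 2
        assert not g.has_edge(0, 1)  # nothing bridges the gap

    def test_read_through_edge_counts_bridging_fragments(self):
        spliced = [make_fragment(blocks=((0, 100), (200, 300)), key=("s", i))
                   for i in range(3)]
        bridging = [make_fragment(blocks=((80, 220),), junctions=(),
                                  key=("b", i)) for i in range(2)]
        g = build_graph(_locus(spliced + bridging))
        # splice sites at 100 and 200 cut the bridged region into vertices
        v100 = next(v for v in g.vertices() if g.interval(v)[0] == 100)
        v200 = next(v for v in g.vertices() if g.interval(v)[0] == 200)
        assert g.we(v100, v200) == 2

    def test_umi_support_counts_fragments_once_per_vertex(self):
        frags = [make_fragment(blocks=((0, 100), (200, 300)), key=i,
                               umi=f"U{i}") for i in range(3)]
        frags += [make_fragment(blocks=((0, 100),), key=("i", 0))]
        g = build_graph(_locus(frags))
        assert g.wm(0) == 3 and g.wm(1) == 3

    def test_empty_locus_raises(self):
        with pytest.raises(EmptyLocusError):
            build_graph(Locus("chr1", "+", 0, 100, []))

    def test_construction_is_order_independent(self):
        rng = np.random.default_rng(0)
        frags = [make_fragment(blocks=((s, s + 80), (s + 200, s + 280)),
                               key=("x", s), umi="U" if s % 2 else None)
                 for s in rng.integers(0, 100, size=15)]
        g1 = build_graph(_locus(sorted(frags, key=lambda f: f.start)))
        g2 = build_graph(_locus(frags[::-1]))
        assert g1.to_text() == g2.to_text()


class TestFixtureFormat:
    def test_demo_round_trips(self):
        g = make_graph_fixture(PRUNING_DEMO)
        assert make_graph_fixture(g.to_text()).to_text() == g.to_text()

    def test_empty_description_errors(self):
        with pytest.raises(GraphFixtureError):
            make_graph_fixture("")

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(GraphFixtureError, match="line 2"):
            make_graph_fixture("graph c +\nvertex broken\n")


class TestPruningDemo:
    """Worked example: one graph exhibiting all three artifact classes."""

    def test_cascade_removes_exactly_the_three_artifacts(self):
        g = make_graph_fixture(PRUNING_DEMO)
        prune(g, IRParams())
        assert sorted(g.labels.values()) == ["v1", "v2", "v4", "v6", "v8"]

    def test_full_ir_detects_v3_only(self):
        g = make_graph_fixture(PRUNING_DEMO)
        doomed = full_ir_removal_set(g, IRParams())
        assert {g.labels[v] for v in doomed} == {"v3"}

    def test_partial_ir_detects_v5_only(self):
        g = make_graph_fixture(PRUNING_DEMO)
        prune_full_intron_retention(g, IRParams())
        doomed = partial_ir_removal_set(g, IRParams())
        assert {g.labels[v] for v in doomed} == {"v5"}

    def test_isolated_detects_v7_only(self):
        g = make_graph_fixture(PRUNING_DEMO)
        doomed = isolated_removal_set(g, IRParams())
        assert {g.labels[v] for v in doomed} == {"v7"}

    def test_umi_support_blocks_full_ir_removal(self):
        g = make_graph_fixture(PRUNING_DEMO.replace(
            "vertex v3 400 700   wv=1.5  wm=0",
            "vertex v3 400 700   wv=1.5  wm=2"))
        assert full_ir_removal_set(g, IRParams(a4=1)) == set()

    def test_spliced_first_exon_not_a_partial_ir_candidate(self):
        g = make_graph_fixture(PRUNING_DEMO)
        v1 = next(v for v, lab in g.labels.items() if lab == "v1")
        prune(g, IRParams())
        assert v1 in g.vertices()

    def test_isolated_vertex_at_threshold_kept(self):
        g = make_graph_fixture(PRUNING_DEMO.replace(
            "vertex v7 1200 1300 wv=6.0  wm=0",
            "vertex v7 1200 1300 wv=6.0  wm=2"))
        assert isolated_removal_set(g, IRParams(single_exon_min_umi=2)) == set()

    def test_weights_conserved_for_untouched_vertices(self):
        g = make_graph_fixture(PRUNING_DEMO)
        before = {g.labels[v]: (g.interval(v), g.wv(v), g.wm(v))
                  for v in g.vertices()}
        edges_before = {(g.labels.get(u, u), g.labels.get(v, v)): g.we(u, v)
                        for u, v in g.edges()}
        prune(g, IRParams())
        for v in g.vertices():
            assert before[g.labels[v]] == (g.interval(v), g.wv(v), g.wm(v))
        for u, v in g.edges():
            key = (g.labels.get(u, u), g.labels.get(v, v))
            assert edges_before[key] == g.we(u, v)


class TestPruningProperties:
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_splice_graph(rng)
        p = IRParams()
        assert full_ir_removal_set(g, p) == oracles.brute_full_ir(g, p)
        assert partial_ir_removal_set(g, p) == oracles.brute_partial_ir(g, p)
        assert isolated_removal_set(g, p) == oracles.brute_isolated(g, p)

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_full_ir_monotone_in_thresholds(self, seed, lo, hi):
        lo, hi = sorted((lo, hi))
        rng = np.random.default_rng(seed)
        g = random_splice_graph(rng)
        small = full_ir_removal_set(g, IRParams(a1=lo, a2=lo, a3=lo, a5=1e9))
        big = full_ir_removal_set(g, IRParams(a1=hi, a2=hi, a3=hi, a5=1e9))
        assert small <= big

    @given(st.integers(0, 2**31 - 1))
    def test_pruning_preserves_acyclicity_and_st(self, seed):
        rng = np.random.default_rng(seed)
        g = random_splice_graph(rng)
        prune(g, IRParams())
        import networkx as nx
        assert nx.is_directed_acyclic_graph(g._g)
        assert SOURCE in g._g and SINK in g._g


class TestPhasingExtraction:
    def _demo_locus_and_graph(self):
        spliced = [make_fragment(blocks=((0, 100), (200, 300)), key=("s", i),
                                 umi=f"U{i}") for i in range(8)]
        retained = [make_fragment(blocks=((80, 220),), junctions=(),
                                  key=("r", i)) for i in range(1)]
        locus = _locus(spliced + retained)
        g = build_graph(locus)
        return locus, g

    def test_fragment_over_removed_vertex_dropped(self):
        locus, g = self._demo_locus_and_graph()
        # removing the retained-intron vertex orphans the bridging fragment
        mid = next(v for v in g.vertices() if g.interval(v) == (100, 200))
        g.remove_vertex(mid)
        paths = extract_phasing_paths(locus, g)
        assert all((100, 200) not in
                   [g.interval(v) for v in p.vertices] for p in paths)
        total = sum(p.multiplicity for p in paths)
        assert total == 8  # only the spliced fragments survive

    def test_identical_fragments_aggregate(self):
        frags = [make_fragment(blocks=((0, 100), (200, 300)), key=("a", i))
                 for i in range(2)]
        locus = _locus(frags)
        g = build_graph(locus)
        (path,) = extract_phasing_paths(locus, g)
        assert path.multiplicity == 2 and len(path.vertices) == 2

    def test_single_vertex_fragment_contributes_path(self):
        frags = [make_fragment(blocks=((0, 100), (200, 300)), key="spliced"),
                 make_fragment(blocks=((10, 90),), key="inside", umi="U")]
        locus = _locus(frags)
        g = build_graph(locus)
        paths = extract_phasing_paths(locus, g)
        singles = [p for p in paths if len(p.vertices) == 1]
        assert len(singles) == 1 and singles[0].umi_multiplicity == 1

    def test_mate_gap_splits_phasing(self):
        # blocks far apart with no junction recorded: two separate chains
        tiling = [make_fragment(blocks=((s, s + 120),), key=("t", s))
                  for s in range(0, 500, 60)]
        gapped = make_fragment(blocks=((0, 100), (300, 400)), junctions=(),
                               key="gap")
        locus = _locus(tiling + [gapped])
        g = build_graph(locus)
        paths = extract_phasing_paths(locus, g)
        assert sum(p.multiplicity for p in paths) > len(tiling)
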