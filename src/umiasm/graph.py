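"""Weighted splice graph: construction, intron-retention pruning, phasing.

A locus is summarised by a weighted DAG. Splice sites observed in any
fragment's junctions cut the locus into non-overlapping intervals; every
maximal covered interval between cuts becomes a vertex (a partial or full
exon). Vertex weight ``w_v`` is the mean per-base read coverage over the
interval, ``w_m`` counts distinct UMI fragments with at least one aligned
base in it, and edge weight ``w_e`` counts fragments connecting two vertices
by a splice junction or by reading through the shared boundary. A source
``s`` is attached to every vertex with no other in-edge and a sink ``t`` to
every vertex with no other out-edge, so every vertex lies on an s-t path.

Internal reads contaminate intronic sequence, so before decomposition three
rule-based pruning passes remove (1) fully retained introns skipped by a
high-weight junction, (2) partially retained introns masquerading as
alternative first/last exons, and (3) isolated vertices, unless they carry
the UMI support a real single-exon transcript would have.
"""
from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .loci import Locus
from .reads import Fragment, UMI

SOURCE = "s"
SINK = "t"


class EmptyLocusError(ValueError):
    """Raised when asked to build a graph for a locus with no fragments."""


@dataclass
class IRParams:
    """Thresholds of the intron-retention pruning rules.

    A full retention candidate ``v`` (single in/out edge, not adjacent to s/t,
    immediately joint to both neighbours, skipped by edge (v-, v+)) is removed
    when [w_v(v) <= a1*skip or w_e(v-,v) <= a2*skip or w_e(v,v+) <= a3*skip]
    and w_m(v) <= a4, or -- the PCR-amplified intron-lariat case -- when
    w_v(v) >= a5 * max(w_e(v-,v), w_e(v,v+)). A partial retention candidate
    adjacent to s (resp. t) is removed when [w_v(v) <= b1*w' or
    w_e(v,v+) <= b2*w'] and w_m(v) <= b3, where w' is the heaviest competing
    in-edge (resp. out-edge) of its neighbour. Isolated vertices survive only
    with w_m >= single_exon_min_umi.
    """

    a1: float = 0.25
    a2: float = 0.25
    a3: float = 0.25
    a4: float = 1.0
    a5: float = 5.0
    b1: float = 0.2
    b2: float = 0.2
    b3: int = 1
    single_exon_min_umi: int = 2

    def __post_init__(self) -> None:
        vals = (self.a1, self.a2, self.a3, self.a4, self.a5,
                self.b1, self.b2, self.b3, self.single_exon_min_umi)
        if any(v < 0 for v in vals):
            raise ValueError("pruning thresholds must be non-negative")


@dataclass(frozen=True)
class PhasingPath:
    """An ordered vertex chain co-observed within single fragments."""

    vertices: tuple[int, ...]
    multiplicity: int
    umi_multiplicity: int = 0


class SpliceGraph:
    """Weighted splice DAG of one locus, with source/sink bookkeeping."""

    def __init__(self, chrom: str, strand: str):
        self.chrom = chrom
        self.strand = strand
        self._g = nx.DiGraph()
        self._g.add_node(SOURCE)
        self._g.add_node(SINK)
        self._ival: dict[int, tuple[int, int]] = {}
        self._wv: dict[int, float] = {}
        self._wm: dict[int, int] = {}
        self.labels: dict[int, str] = {}

    # -- construction ------------------------------------------------------
    def add_vertex(self, vid: int, start: int, end: int,
                   wv: float = 0.0, wm: int = 0, label: str | None = None) -> None:
        if start >= end:
            raise ValueError("empty vertex interval")
        self._ival[vid] = (start, end)
        self._wv[vid] = float(wv)
        self._wm[vid] = int(wm)
        self._g.add_node(vid)
        if label is not None:
            self.labels[vid] = label

    def add_edge(self, u, v, weight: float) -> None:
        self._g.add_edge(u, v, weight=float(weight))

    def remove_vertex(self, vid: int) -> None:
        self._g.remove_node(vid)  # incident edges go with it
        del self._ival[vid], self._wv[vid], self._wm[vid]
        self.labels.pop(vid, None)

    # -- accessors ---------------------------------------------------------
    def vertices(self) -> list[int]:
        return sorted(self._ival)

    @property
    def n_vertices(self) -> int:
        return len(self._ival)

    def interval(self, vid: int) -> tuple[int, int]:
        return self._ival[vid]

    def wv(self, vid: int) -> float:
        return self._wv[vid]

    def wm(self, vid: int) -> int:
        return self._wm[vid]

    def has_edge(self, u, v) -> bool:
        return self._g.has_edge(u, v)

    def we(self, u, v) -> float:
        return self._g[u][v]["weight"]

    def edges(self) -> list[tuple]:
        def key(e):
            u, v = e
            return (u == SINK, self._ival.get(u, (-1, -1)),
                    v == SINK, self._ival.get(v, (-1, -1)))
        return sorted(self._g.edges(), key=key)

    def in_neighbors(self, vid) -> list:
        ins = list(self._g.predecessors(vid))
        return sorted(ins, key=lambda u: (u != SOURCE, self._ival.get(u, (0, 0))))

    def out_neighbors(self, vid) -> list:
        outs = list(self._g.successors(vid))
        return sorted(outs, key=lambda u: (u == SINK, self._ival.get(u, (0, 0))))

    def immediately_joint(self, u: int, v: int) -> bool:
        """True iff vertex ``u`` abuts ``v`` exactly (u_r == v_l)."""
        (ul, ur), (vl, vr) = self._ival[u], self._ival[v]
        if ur > vl:
            raise ValueError("vertices overlap; construction invariant violated")
        return ur == vl

    def copy(self) -> "SpliceGraph":
        g = SpliceGraph(self.chrom, self.strand)
        g._g = self._g.copy()
        g._ival = dict(self._ival)
        g._wv = dict(self._wv)
        g._wm = dict(self._wm)
        g.labels = dict(self.labels)
        return g

    def validate(self) -> None:
        """Assert the structural invariants; used by tests and fixtures."""
        if not nx.is_directed_acyclic_graph(self._g):
            raise AssertionError("splice graph is cyclic")
        ivals = sorted(self._ival.values())
        for (al, ar), (bl, br) in zip(ivals, ivals[1:]):
            if ar > bl:
                raise AssertionError("vertex intervals overlap")
        for u, v in self._g.edges():
            if u == SINK or v == SOURCE:
                raise AssertionError("edge into source or out of sink")
            if u != SOURCE and v != SINK and self._ival[u][0] >= self._ival[v][0]:
                raise AssertionError("edge against genomic coordinate order")
        for vid in self._ival:
            if not nx.has_path(self._g, SOURCE, vid) or \
                    not nx.has_path(self._g, vid, SINK):
                raise AssertionError(f"vertex {vid} not on any s-t path")

    def to_text(self) -> str:
        """Serialize to the plain-text fixture format (see ``parse_graph``)."""
        lines = [f"graph {self.chrom} {self.strand}"]
        for vid in self.vertices():
            s, e = self._ival[vid]
            name = self.labels.get(vid, str(vid))
            lines.append(f"vertex {name} {s} {e} wv={self._wv[vid]:g} "
                         f"wm={self._wm[vid]}")
        names = {vid: self.labels.get(vid, str(vid)) for vid in self._ival}
        names[SOURCE] = SOURCE
        names[SINK] = SINK
        for u, v in self.edges():
            lines.append(f"edge {names[u]} {names[v]} {self.we(u, v):g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# construction from fragments
# ---------------------------------------------------------------------------

def build_graph(locus: Locus) -> SpliceGraph:
    """Build the weighted splice graph of a locus from all its fragments."""
    frags = locus.fragments
    if not frags:
        raise EmptyLocusError(f"locus {locus.chrom}:{locus.span} has no fragments")
    off = min(f.start for f in frags)
    hi = max(f.end for f in frags)
    cov = np.zeros(hi - off, dtype=np.int64)
    junction_tally: Counter = Counter()
    for f in frags:
        for b0, b1 in f.blocks:
            cov[b0 - off:b1 - off] += 1
        for j in f.junctions:
            junction_tally[j] += 1

    sites = sorted({p for j in junction_tally for p in j if off < p < hi})

    # vertices: maximal covered runs, split further at splice sites
    covered = cov > 0
    edges_of_cov = np.flatnonzero(np.diff(np.concatenate(
        ([False], covered, [False])).astype(np.int8)))
    runs = [(int(a) + off, int(b) + off)
            for a, b in zip(edges_of_cov[::2], edges_of_cov[1::2])]
    intervals: list[tuple[int, int]] = []
    for a, b in runs:
        cuts = [a] + [p for p in sites if a < p < b] + [b]
        intervals.extend(zip(cuts, cuts[1:]))

    g = SpliceGraph(locus.chrom, locus.strand)
    starts = [iv[0] for iv in intervals]
    start_of: dict[int, int] = {}
    end_of: dict[int, int] = {}
    for vid, (a, b) in enumerate(intervals):
        wv = float(cov[a - off:b - off].sum()) / (b - a)
        g.add_vertex(vid, a, b, wv=wv, wm=0)
        start_of[a] = vid
        end_of[b] = vid

    # UMI support
    for f in frags:
        if f.read_type != UMI:
            continue
        for vid in _overlapped_vertices(starts, intervals, f):
            g._wm[vid] += 1

    edge_tally: Counter = Counter()
    first_at: Counter = Counter()
    last_at: Counter = Counter()
    for f in frags:
        vids = _overlapped_vertices(starts, intervals, f)
        first_at[vids[0]] += 1
        last_at[vids[-1]] += 1
        for b0, b1 in f.blocks:  # read-through support at interior boundaries
            i = bisect_right(starts, b0) - 1
            while i + 1 < len(intervals) and intervals[i + 1][0] < b1:
                boundary = intervals[i][1]
                if b0 < boundary < b1 and intervals[i + 1][0] == boundary:
                    edge_tally[(i, i + 1)] += 1
                i += 1
    for (js, je), n in junction_tally.items():
        u = end_of.get(js)
        v = start_of.get(je)
        if u is not None and v is not None:
            edge_tally[(u, v)] += n
    for (u, v), n in sorted(edge_tally.items()):
        g.add_edge(u, v, n)

    for vid in g.vertices():
        if g._g.in_degree(vid) == 0:
            g.add_edge(SOURCE, vid, first_at[vid])
        if g._g.out_degree(vid) == 0:
            g.add_edge(vid, SINK, last_at[vid])
    return g


def _overlapped_vertices(starts: list[int], intervals: list[tuple[int, int]],
                         f: Fragment) -> list[int]:
    """Indices of vertices overlapped by >=1 aligned base of ``f``."""
    vids: list[int] = []
    for b0, b1 in f.blocks:
        i = max(bisect_right(starts, b0) - 1, 0)
        while i < len(intervals) and intervals[i][0] < b1:
            if intervals[i][1] > b0 and (not vids or vids[-1] != i):
                vids.append(i)
            i += 1
    return vids


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _real_ins(g: SpliceGraph, v: int) -> list[int]:
    return [u for u in g.in_neighbors(v) if u != SOURCE]


def _real_outs(g: SpliceGraph, v: int) -> list[int]:
    return [u for u in g.out_neighbors(v) if u != SINK]


def full_ir_removal_set(g: SpliceGraph, p: IRParams) -> set[int]:
    """Vertices condemned as full intron retentions, judged on ``g`` as-is."""
    out: set[int] = set()
    for v in g.vertices():
        ins = g.in_neighbors(v)
        outs = g.out_neighbors(v)
        if len(ins) != 1 or len(outs) != 1:
            continue
        vm, vp = ins[0], outs[0]
        if vm == SOURCE or vp == SINK:  # adjacent to s or t
            continue
        if not (g.immediately_joint(vm, v) and g.immediately_joint(v, vp)):
            continue
        if not g.has_edge(vm, vp):
            continue
        skip = g.we(vm, vp)
        w_in, w_out = g.we(vm, v), g.we(v, vp)
        low = (g.wv(v) <= p.a1 * skip or w_in <= p.a2 * skip
               or w_out <= p.a3 * skip) and g.wm(v) <= p.a4
        lariat = g.wv(v) >= p.a5 * max(w_in, w_out)
        if low or lariat:
            out.add(v)
    return out


def partial_ir_removal_set(g: SpliceGraph, p: IRParams) -> set[int]:
    """Vertices condemned as partial intron retentions (both graph sides)."""
    out: set[int] = set()
    for v in g.vertices():
        ins = g.in_neighbors(v)
        outs = g.out_neighbors(v)
        if len(ins) != 1 or len(outs) != 1:
            continue
        vm, vp = ins[0], outs[0]
        # start side: false alternative first exon
        if vm == SOURCE and vp != SINK and g.immediately_joint(v, vp):
            competing = _real_ins(g, vp)
            if len(competing) >= 2:
                w_prime = max(g.we(u, vp) for u in competing)
                if (g.wv(v) <= p.b1 * w_prime or g.we(v, vp) <= p.b2 * w_prime) \
                        and g.wm(v) <= p.b3:
                    out.add(v)
        # end side: mirror image, false alternative last exon
        if vp == SINK and vm != SOURCE and g.immediately_joint(vm, v):
            competing = _real_outs(g, vm)
            if len(competing) >= 2:
                w_prime = max(g.we(vm, u) for u in competing)
                if (g.wv(v) <= p.b1 * w_prime or g.we(vm, v) <= p.b2 * w_prime) \
                        and g.wm(v) <= p.b3:
                    out.add(v)
    return out


def isolated_removal_set(g: SpliceGraph, p: IRParams) -> set[int]:
    """Isolated vertices (neighbours only s and t) lacking single-exon UMI support."""
    out: set[int] = set()
    for v in g.vertices():
        nbrs = set(g.in_neighbors(v)) | set(g.out_neighbors(v))
        if nbrs <= {SOURCE, SINK} and g.wm(v) < p.single_exon_min_umi:
            out.add(v)
    return out


def _prune_to_fixpoint(g: SpliceGraph, p: IRParams, removal_set_fn) -> SpliceGraph:
    # candidates are judged against the pass-start state and removed together;
    # passes repeat until nothing changes
    while True:
        doomed = removal_set_fn(g, p)
        if not doomed:
            return g
        for v in sorted(doomed):
            g.remove_vertex(v)


def prune_full_intron_retention(g: SpliceGraph, p: IRParams) -> SpliceGraph:
    return _prune_to_fixpoint(g, p, full_ir_removal_set)


def prune_partial_intron_retention(g: SpliceGraph, p: IRParams) -> SpliceGraph:
    return _prune_to_fixpoint(g, p, partial_ir_removal_set)


def prune_isolated_vertices(g: SpliceGraph, p: IRParams) -> SpliceGraph:
    return _prune_to_fixpoint(g, p, isolated_removal_set)


def prune(g: SpliceGraph, p: IRParams) -> SpliceGraph:
    """Full pruning cascade: full IR, then partial IR, then isolated vertices."""
    prune_full_intron_retention(g, p)
    prune_partial_intron_retention(g, p)
    prune_isolated_vertices(g, p)
    return g


# ---------------------------------------------------------------------------
# phasing extraction
# ---------------------------------------------------------------------------

def _fragment_segments(g: SpliceGraph, f: Fragment) -> list[tuple[int, ...]] | None:
    """Vertex chains co-observed in ``f`` against the (pruned) graph.

    Returns one chain per contiguously sequenced stretch (mate insert gaps
    split chains), or None when the fragment touches pruned-away sequence or
    contradicts a surviving edge.
    """
    ivals = [g.interval(v) for v in g.vertices()]
    vids = g.vertices()
    starts = [iv[0] for iv in ivals]
    junctions = set(f.junctions)

    per_block: list[list[int]] = []
    for b0, b1 in f.blocks:
        got: list[int] = []
        covered_to = b0
        i = max(bisect_right(starts, b0) - 1, 0)
        while i < len(ivals) and ivals[i][0] < b1:
            a, b = ivals[i]
            if b > b0:
                if max(a, b0) != covered_to:
                    return None  # aligned base in a removed region
                got.append(vids[i])
                covered_to = min(b, b1)
            i += 1
        if covered_to != b1 or not got:
            return None
        per_block.append(got)

    segments: list[list[int]] = [per_block[0]]
    for (pb0, pb1), (b0, b1), chunk in zip(f.blocks, f.blocks[1:], per_block[1:]):
        if (pb1, b0) in junctions:
            if not g.has_edge(segments[-1][-1], chunk[0]):
                return None  # junction contradicts the surviving graph
            segments[-1].extend(chunk)
        else:
            segments.append(chunk)  # unsequenced mate insert: phase breaks
    for seg in segments:
        for u, v in zip(seg, seg[1:]):
            if not g.has_edge(u, v):
                return None
    return [tuple(seg) for seg in segments]


def extract_phasing_paths(locus: Locus, g: SpliceGraph) -> list[PhasingPath]:
    """Collapse fragments into phasing paths over the pruned graph.

    Fragments overlapping removed vertices or contradicting surviving edges
    are dropped; identical vertex chains aggregate their multiplicities.
    """
    tally: Counter = Counter()
    umi_tally: Counter = Counter()
    for f in locus.fragments:
        segments = _fragment_segments(g, f)
        if segments is None:
            continue
        for seg in segments:
            tally[seg] += 1
            if f.read_type == UMI:
                umi_tally[seg] += 1
    paths = [PhasingPath(seg, n, umi_tally[seg]) for seg, n in tally.items()]
    paths.sort(key=lambda p: (g.interval(p.vertices[0]), p.vertices))
    return paths
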