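"""Independent brute-force evaluators of the pruning rules.

These re-derive each rule directly from raw adjacency maps, independently of
the SpliceGraph helpers the implementation uses, so they can arbitrate the
pruning operations on randomized graphs.
"""
from umiasm.graph import SINK, SOURCE, SpliceGraph


def _raw(g: SpliceGraph):
    ins: dict = {v: [] for v in g.vertices()}
    outs: dict = {v: [] for v in g.vertices()}
    we: dict = {}
    for u, v in g.edges():
        we[(u, v)] = g.we(u, v)
        if v in ins:
            ins[v].append(u)
        if u in outs:
            outs[u].append(v)
    return ins, outs, we


def brute_full_ir(g: SpliceGraph, p) -> set:
    ins, outs, we = _raw(g)
    doomed = set()
    for v in g.vertices():
        if len(ins[v]) != 1 or len(outs[v]) != 1:
            continue
        vm, vp = ins[v][0], outs[v][0]
        if vm == SOURCE or vp == SINK:
            continue
        if g.interval(vm)[1] != g.interval(v)[0]:
            continue
        if g.interval(v)[1] != g.interval(vp)[0]:
            continue
        if (vm, vp) not in we:
            continue
        skip = we[(vm, vp)]
        low = (g.wv(v) <= p.a1 * skip or we[(vm, v)] <= p.a2 * skip
               or we[(v, vp)] <= p.a3 * skip)
        if (low and g.wm(v) <= p.a4) or \
                g.wv(v) >= p.a5 * max(we[(vm, v)], we[(v, vp)]):
            doomed.add(v)
    return doomed


def brute_partial_ir(g: SpliceGraph, p) -> set:
    ins, outs, we = _raw(g)
    doomed = set()
    for v in g.vertices():
        if len(ins[v]) != 1 or len(outs[v]) != 1:
            continue
        vm, vp = ins[v][0], outs[v][0]
        if vm == SOURCE and vp != SINK and \
                g.interval(v)[1] == g.interval(vp)[0]:
            others = [u for u in ins[vp] if u != SOURCE]
            if len(others) >= 2:
                w = max(we[(u, vp)] for u in others)
                if (g.wv(v) <= p.b1 * w or we[(v, vp)] <= p.b2 * w) \
                        and g.wm(v) <= p.b3:
                    doomed.add(v)
        if vp == SINK and vm != SOURCE and \
                g.interval(vm)[1] == g.interval(v)[0]:
            others = [u for u in outs[vm] if u != SINK]
            if len(others) >= 2:
                w = max(we[(vm, u)] for u in others)
                if (g.wv(v) <= p.b1 * w or we[(vm, v)] <= p.b2 * w) \
                        and g.wm(v) <= p.b3:
                    doomed.add(v)
    return doomed


def brute_isolated(g: SpliceGraph, p) -> set:
    ins, outs, _ = _raw(g)
    return {v for v in g.vertices()
            if set(ins[v]) <= {SOURCE} and set(outs[v]) <= {SINK}
            and g.wm(v) < p.single_exon_min_umi}
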