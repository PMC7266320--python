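"""Splice-graph construction from spliced alignments.

The graph is built in three steps:

* **split** — infer covered exon regions from aligned blocks, detect splice
  junctions from split alignments, and cut regions at every internal donor
  or acceptor so that alternative linkages become node boundaries;
* **merge** — re-join adjacent regions separated by a short uncovered gap
  (or a moderate gap when both sides are deeply covered), unless a splice
  site lies between them;
* **connect** — add a directed edge for every pair of nodes bridged by a
  read alignment (weight = supporting read count), augment edges from mate
  pairs straddling uncovered gaps, and collect known paths (node triples
  witnessed by a single read or pair) for later tie-breaking.

Each weakly connected component is one gene locus and is emitted as its own
:class:`SpliceGraph` (a DAG: edges always point downstream in genomic
coordinates).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment_io import Fragment, ReadAlignment
from .config import GraphConfig

logger = logging.getLogger(__name__)


@dataclass
class ExonRegion:
    """Maximal genomic interval with >=1x read coverage."""

    chrom: str
    start: int
    end: int
    depth: np.ndarray  # per-base depth over [start, end)

    @property
    def coverage(self) -> float:
        return float(self.depth.mean())


@dataclass(frozen=True)
class SpliceJunction:
    """Donor/acceptor pair (1-based, as conventionally reported).

    ``donor`` is the last genomic base of the upstream exon block and
    ``acceptor`` the first base of the downstream block; the excised intron
    is (donor, acceptor) exclusive.
    """

    chrom: str
    donor: int
    acceptor: int
    support: int = 1

    @property
    def donor_boundary(self) -> int:
        """0-based cut position just after the donor base."""
        return self.donor

    @property
    def acceptor_boundary(self) -> int:
        """0-based cut position just before the acceptor base."""
        return self.acceptor - 1


@dataclass
class GraphNode:
    id: int
    chrom: str
    start: int
    end: int
    coverage: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GraphEdge:
    from_node: int
    to_node: int
    weight: float
    kind: str = "crossing"  # crossing | junction | pair_augmented


@dataclass
class SpliceGraph:
    """One gene locus: weighted DAG over sub-exonic nodes plus known paths."""

    chrom: str
    nodes: list[GraphNode]
    edges: list[GraphEdge]
    known_paths: set[tuple[int, int, int]] = field(default_factory=set)

    def node_by_id(self) -> dict[int, GraphNode]:
        return {n.id: n for n in self.nodes}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, start=n.start, end=n.end, coverage=n.coverage)
        for e in self.edges:
            g.add_edge(e.from_node, e.to_node, weight=e.weight, kind=e.kind)
        return g

    @property
    def start(self) -> int:
        return min(n.start for n in self.nodes)


def infer_exon_regions(alignments: list[ReadAlignment]) -> list[ExonRegion]:
    """Union aligned blocks into maximal covered regions with depth profiles."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for aln in alignments:
        for b in aln.blocks:
            by_chrom[b.chrom].append((b.start, b.end))
    regions: list[ExonRegion] = []
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = [m[0] for m in merged]
        depths = [np.zeros(m[1] - m[0], dtype=np.int64) for m in merged]
        for s, e in ivals:
            idx = bisect_right(starts, s) - 1
            depths[idx][s - starts[idx]: e - starts[idx]] += 1
        for (s, e), d in zip(merged, depths):
            regions.append(ExonRegion(chrom, s, e, d))
    return regions


def detect_junctions(
    alignments: list[ReadAlignment], min_support: int = 1
) -> list[SpliceJunction]:
    """Call one junction per distinct gap between consecutive blocks."""
    counts: Counter[tuple[str, int, int]] = Counter()
    for aln in alignments:
        for left, right in zip(aln.blocks, aln.blocks[1:]):
            # donor = last base of upstream block (1-based == 0-based end),
            # acceptor = first base of downstream block (1-based)
            counts[(aln.chrom, left.end, right.start + 1)] += 1
    return [
        SpliceJunction(chrom, donor, acceptor, n)
        for (chrom, donor, acceptor), n in sorted(counts.items())
        if n >= min_support
    ]


def split_regions(
    regions: list[ExonRegion], junctions: list[SpliceJunction]
) -> list[GraphNode]:
    """Cut each region at every donor/acceptor strictly inside it."""
    cuts_by_chrom: dict[str, set[int]] = defaultdict(set)
    for j in junctions:
        cuts_by_chrom[j.chrom].add(j.donor_boundary)
        cuts_by_chrom[j.chrom].add(j.acceptor_boundary)
    placed: set[tuple[str, int]] = set()
    nodes: list[GraphNode] = []
    nid = 0
    for region in regions:
        inside = sorted(
            c for c in cuts_by_chrom.get(region.chrom, ())
            if region.start < c < region.end
        )
        placed.update((region.chrom, c) for c in inside)
        placed.update(
            (region.chrom, c)
            for c in cuts_by_chrom.get(region.chrom, ())
            if c in (region.start, region.end)
        )
        bounds = [region.start] + inside + [region.end]
        for s, e in zip(bounds, bounds[1:]):
            cov = float(region.depth[s - region.start: e - region.start].mean())
            nodes.append(GraphNode(nid, region.chrom, s, e, cov))
            nid += 1
    stray = sum(
        1
        for chrom, cs in cuts_by_chrom.items()
        for c in cs
        if (chrom, c) not in placed
    )
    if stray:
        logger.warning("%d junction boundaries fall outside all covered regions", stray)
    return nodes


def merge_regions(
    nodes: list[GraphNode],
    junctions: list[SpliceJunction],
    small_gap: int = 10,
    moderate_gap: int = 50,
    high_cov: float = 20.0,
) -> list[GraphNode]:
    """Re-join adjacent nodes across small uncovered gaps.

    Two neighbours merge when the gap is at most ``small_gap``, or at most
    ``moderate_gap`` with both coverages >= ``high_cov`` — but never when a
    splice donor or acceptor boundary lies in ``[left.end, right.start]``
    (the splice event means the gap really is intronic in some transcript).
    Merging cascades left to right; coverage is length-weighted-averaged.
    """
    bounds_by_chrom: dict[str, list[int]] = defaultdict(list)
    for j in junctions:
        bounds_by_chrom[j.chrom].append(j.donor_boundary)
        bounds_by_chrom[j.chrom].append(j.acceptor_boundary)
    for chrom in bounds_by_chrom:
        bounds_by_chrom[chrom].sort()

    def blocked(chrom: str, lo: int, hi: int) -> bool:
        bs = bounds_by_chrom.get(chrom, [])
        return bisect_right(bs, hi) > bisect_left(bs, lo)

    out: list[GraphNode] = []
    for nd in nodes:
        if out and out[-1].chrom == nd.chrom:
            left = out[-1]
            gap = nd.start - left.end
            mergeable = gap <= small_gap or (
                gap <= moderate_gap
                and left.coverage >= high_cov
                and nd.coverage >= high_cov
            )
            if mergeable and not blocked(nd.chrom, left.end, nd.start):
                # gap counts as zero depth: coverage is covered-base mass
                # over the merged span
                mass = left.coverage * len(left) + nd.coverage * len(nd)
                cov = mass / (nd.end - left.start)
                out[-1] = GraphNode(left.id, left.chrom, left.start, nd.end, cov)
                continue
        out.append(GraphNode(nd.id, nd.chrom, nd.start, nd.end, nd.coverage))
    for i, nd in enumerate(out):
        nd.id = i
    return out


class _NodeIndex:
    """Locate the nodes overlapping a genomic interval (per chromosome)."""

    def __init__(self, nodes: list[GraphNode]):
        self.by_chrom: dict[str, tuple[list[int], list[GraphNode]]] = {}
        grouped: dict[str, list[GraphNode]] = defaultdict(list)
        for n in nodes:
            grouped[n.chrom].append(n)
        for chrom, ns in grouped.items():
            ns.sort(key=lambda n: n.start)
            self.by_chrom[chrom] = ([n.start for n in ns], ns)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GraphNode]:
        if chrom not in self.by_chrom:
            return []
        starts, ns = self.by_chrom[chrom]
        i = bisect_right(starts, start) - 1
        hits: list[GraphNode] = []
        if i >= 0 and ns[i].end > start:
            hits.append(ns[i])
        i += 1
        while i < len(ns) and ns[i].start < end:
            hits.append(ns[i])
            i += 1
        return hits

    def rank(self, chrom: str, node_id: int) -> int:
        _, ns = self.by_chrom[chrom]
        for r, n in enumerate(ns):
            if n.id == node_id:
                return r
        raise KeyError(node_id)


def _alignment_chain(aln: ReadAlignment, index: _NodeIndex) -> list[int]:
    """Ordered node ids touched (>=1 base overlap) by one alignment."""
    chain: list[int] = []
    for b in aln.blocks:
        for n in index.overlapping(b.chrom, b.start, b.end):
            if not chain or chain[-1] != n.id:
                chain.append(n.id)
    return chain


def _fragment_chain(frag: Fragment, index: _NodeIndex) -> list[int] | None:
    """Combined node chain of a mate pair, or None if the pair cannot be
    joined (an intervening node exists, or a mate touches no node)."""
    c1 = _alignment_chain(frag.first, index)
    c2 = _alignment_chain(frag.second, index)
    if not c1 or not c2:
        return None
    if c1[-1] == c2[0]:
        return c1 + c2[1:]
    chrom = frag.first.chrom
    r1, r2 = index.rank(chrom, c1[-1]), index.rank(chrom, c2[0])
    if r2 == r1 + 1:  # adjacent: no intervening node
        return c1 + c2
    return None


def build_edges(
    nodes: list[GraphNode],
    alignments: list[ReadAlignment],
    fragments: list[Fragment] | None = None,
) -> list[GraphEdge]:
    """Weighted directed edges from crossing reads plus pair augmentation.

    A pair-augmented edge joins the node holding a fragment's first-mate end
    to the node holding its second-mate start, only when no other node lies
    strictly between them and no read already crosses the two nodes.
    """
    index = _NodeIndex(nodes)
    pos = {n.id: n for n in nodes}
    counts: Counter[tuple[int, int]] = Counter()
    orphan_blocks = 0
    for aln in alignments:
        chain = _alignment_chain(aln, index)
        if not chain:
            orphan_blocks += 1
            continue
        for u, v in zip(chain, chain[1:]):
            counts[(u, v)] += 1
    if orphan_blocks:
        logger.warning("%d alignments overlap no node", orphan_blocks)
    edges: dict[tuple[int, int], GraphEdge] = {}
    for (u, v), w in counts.items():
        kind = "crossing" if pos[u].end == pos[v].start else "junction"
        edges[(u, v)] = GraphEdge(u, v, float(w), kind)
    if fragments:
        aug: Counter[tuple[int, int]] = Counter()
        for frag in fragments:
            if frag.second is None:
                continue
            c1 = _alignment_chain(frag.first, index)
            c2 = _alignment_chain(frag.second, index)
            if not c1 or not c2 or c1[-1] == c2[0]:
                continue
            u, v = c1[-1], c2[0]
            chrom = frag.first.chrom
            if index.rank(chrom, v) == index.rank(chrom, u) + 1 and (u, v) not in edges:
                aug[(u, v)] += 1
        for (u, v), w in aug.items():
            edges[(u, v)] = GraphEdge(u, v, float(w), "pair_augmented")
    return sorted(edges.values(), key=lambda e: (e.from_node, e.to_node))


def collect_known_paths(
    nodes: list[GraphNode],
    alignments: list[ReadAlignment],
    fragments: list[Fragment] | None = None,
) -> set[tuple[int, int, int]]:
    """Node triples directly witnessed by one read or one joined mate pair.

    Longer chains contribute every sliding window of width 3; triples are
    stored (not longer tuples) — sufficient to break decomposition ties
    while keeping memory linear.
    """
    index = _NodeIndex(nodes)
    triples: set[tuple[int, int, int]] = set()

    def windows(chain: list[int]) -> None:
        for i in range(len(chain) - 2):
            triples.add((chain[i], chain[i + 1], chain[i + 2]))

    for aln in alignments:
        windows(_alignment_chain(aln, index))
    for frag in fragments or []:
        if frag.second is None:
            continue
        chain = _fragment_chain(frag, index)
        if chain:
            windows(chain)
    return triples


def build_splice_graph(
    alignments: list[ReadAlignment],
    fragments: list[Fragment] | None = None,
    config: GraphConfig | None = None,
) -> list[SpliceGraph]:
    """Run split, merge and connect; return one graph per gene locus.

    Loci are the weakly connected components of the full per-chromosome
    graph, ordered by chromosome then genomic start.
    """
    config = config or GraphConfig()
    alignments = sorted(alignments, key=lambda a: (a.chrom, a.start))
    regions = infer_exon_regions(alignments)
    junctions = detect_junctions(alignments, config.min_junction_support)
    nodes = split_regions(regions, junctions)
    nodes = merge_regions(
        nodes, junctions, config.small_gap, config.moderate_gap, config.high_cov
    )
    edges = build_edges(nodes, alignments, fragments)
    known = collect_known_paths(nodes, alignments, fragments)

    g = nx.DiGraph()
    g.add_nodes_from(n.id for n in nodes)
    g.add_edges_from((e.from_node, e.to_node) for e in edges)
    by_id = {n.id: n for n in nodes}
    graphs: list[SpliceGraph] = []
    for comp in nx.weakly_connected_components(g):
        comp_nodes = sorted((by_id[i] for i in comp), key=lambda n: (n.chrom, n.start))
        comp_edges = [e for e in edges if e.from_node in comp]
        comp_known = {t for t in known if t[0] in comp}
        sg = SpliceGraph(comp_nodes[0].chrom, comp_nodes, comp_edges, comp_known)
        if not nx.is_directed_acyclic_graph(sg.to_networkx()):
            logger.error("cyclic component at %s:%d skipped", sg.chrom, sg.start)
            continue
        graphs.append(sg)
    graphs.sort(key=lambda sg: (sg.chrom, sg.start))
    return graphs


def dump_graph_tables(graph: SpliceGraph, prefix: str) -> None:
    """Debug dump: tab-separated node/edge/known-path tables (0-based coords)."""
    with open(f"{prefix}.nodes.tsv", "w") as fh:
        fh.write("id\tchrom\tstart\tend\tcoverage\n")
        for n in graph.nodes:
            fh.write(f"{n.id}\t{n.chrom}\t{n.start}\t{n.end}\t{n.coverage:.3f}\n")
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("from\tto\tweight\tkind\n")
        for e in graph.edges:
            fh.write(f"{e.from_node}\t{e.to_node}\t{e.weight:g}\t{e.kind}\n")
    with open(f"{prefix}.paths.tsv", "w") as fh:
        fh.write("n1\tn2\tn3\n")
        for t in sorted(graph.known_paths):
            fh.write(f"{t[0]}\t{t[1]}\t{t[2]}\n")
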