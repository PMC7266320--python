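"""Sparse flow decomposition of splice graphs.

Globally we want the minimum number of weighted source-to-sink paths whose
superposition reproduces every edge weight — an intractable combinatorial
problem (2^(mn) support patterns per node alone).  Instead the graph is
decomposed node by node in topological order.  At each internal node v with
in-edge weights w_i and out-edge weights w_j we seek the sparsest
nonnegative matrix f with row sums w_i and column sums w_j.  The L1 norm of
f is constant (it equals the total weight), so plain L1 relaxation is
useless; we minimise instead the randomly reweighted L1 norm
``sum_ij f_ij * r_ij`` with r_ij > 0 drawn i.i.d., which is an LP whose
optimum sits at a vertex of the transportation polytope — typically a very
sparse one.  Several reweighting draws are taken and the sparsest
thresholded solution kept; ties are broken in favour of solutions covering
known paths, then deterministically.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .config import FlowConfig
from .splice_graph import SpliceGraph

logger = logging.getLogger(__name__)

SOURCE = "__source__"
SINK = "__sink__"


@dataclass
class LocalProblem:
    """Edge-weight constraints at one node: row/column sums for the flow."""

    node: object
    in_weights: np.ndarray
    out_weights: np.ndarray
    known_pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.in_weights = np.asarray(self.in_weights, dtype=float)
        self.out_weights = np.asarray(self.out_weights, dtype=float)
        if self.in_weights.ndim != 1 or self.out_weights.ndim != 1:
            raise ValueError("weights must be 1-D")
        if len(self.in_weights) < 1 or len(self.out_weights) < 1:
            raise ValueError("need at least one in- and one out-edge")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.in_weights), len(self.out_weights)


@dataclass
class FlowMatrix:
    """A feasible local flow assignment f_ij between in- and out-edges."""

    values: np.ndarray

    def support(self, eps: float = 1e-9) -> set[tuple[int, int]]:
        m, n = self.values.shape
        return {(i, j) for i in range(m) for j in range(n) if self.values[i, j] > eps}

    def support_size(self, eps: float = 1e-9) -> int:
        return int((self.values > eps).sum())


@dataclass
class Transcript:
    """A recovered source-to-sink path with its flow weight."""

    chrom: str
    node_path: tuple[int, ...]
    weight: float
    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


def balance_node(
    in_weights: np.ndarray, out_weights: np.ndarray, tol: float = 0.2
) -> tuple[np.ndarray, np.ndarray, str | None]:
    """Reconcile in/out weight sums before the LP (which needs equality).

    Read-count noise makes the two sums differ; within relative tolerance
    ``tol`` the smaller side is scaled up, beyond it an auxiliary sentinel
    entry carrying the surplus is appended to the smaller side.  Returns
    (in', out', aux) with aux in {None, 'in', 'out'} naming the side that
    received a sentinel entry (always the last entry of that side).
    """
    win = np.asarray(in_weights, dtype=float).copy()
    wout = np.asarray(out_weights, dtype=float).copy()
    si, so = win.sum(), wout.sum()
    if si == so:
        return win, wout, None
    if abs(si - so) / max(si, so) <= tol:
        if si < so:
            win *= so / si
        else:
            wout *= si / so
        return win, wout, None
    if si < so:
        return np.append(win, so - si), wout, "in"
    return win, np.append(wout, si - so), "out"


def _solve_reweighted_lp(
    r: np.ndarray, win: np.ndarray, wout: np.ndarray
) -> np.ndarray | None:
    """min <r, f> s.t. row sums = win, col sums = wout, f >= 0."""
    m, n = len(win), len(wout)
    a_eq = np.zeros((m + n, m * n))
    for i in range(m):
        a_eq[i, i * n:(i + 1) * n] = 1.0
    for j in range(n):
        a_eq[m + j, j::n] = 1.0
    b_eq = np.concatenate([win, wout])
    res = linprog(r.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        return None
    return res.x.reshape(m, n)


def _threshold_and_restore(
    f: np.ndarray,
    win: np.ndarray,
    wout: np.ndarray,
    abs_eps: float,
    rel_eps: float,
) -> np.ndarray:
    """Zero small entries, then restore exact marginals.

    The largest entry of each row and column is never zeroed (every marginal
    must stay representable).  Marginals are restored by iterative
    proportional fitting on the surviving support; if that fails to converge
    the solution is returned with only numerically-zero entries removed.
    """
    thr = max(abs_eps, rel_eps * win.sum())
    guard = np.zeros_like(f, dtype=bool)
    guard[np.arange(f.shape[0]), f.argmax(axis=1)] = True
    guard[f.argmax(axis=0), np.arange(f.shape[1])] = True
    g = f.copy()
    g[(g < thr) & ~guard] = 0.0
    if (g > 0).sum() == (f > abs_eps).sum():  # nothing newly zeroed
        g = f.copy()
        g[g <= abs_eps] = 0.0
        return g
    for _ in range(500):
        rs = g.sum(axis=1)
        np.divide(win, rs, out=rs, where=rs > 0)
        g *= rs[:, None]
        cs = g.sum(axis=0)
        np.divide(wout, cs, out=cs, where=cs > 0)
        g *= cs[None, :]
        if (
            np.abs(g.sum(axis=1) - win).max() <= 1e-9 * max(win.sum(), 1.0)
            and np.abs(g.sum(axis=0) - wout).max() <= 1e-9 * max(wout.sum(), 1.0)
        ):
            break
    rel = max(
        np.abs(g.sum(axis=1) - win).max() / max(win.max(), 1e-12),
        np.abs(g.sum(axis=0) - wout).max() / max(wout.max(), 1e-12),
    )
    if rel > 1e-6:
        g = f.copy()
        g[g <= abs_eps] = 0.0
    return g


def _product_flow(win: np.ndarray, wout: np.ndarray) -> np.ndarray:
    return np.outer(win, wout) / win.sum()


def _greedy_match_flow(win: np.ndarray, wout: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Deterministic sparse candidate by marginal matching.

    Repeatedly pairs an in-weight with an equal out-weight when one exists
    (such a pair can always be realised by a single flow), otherwise routes
    the largest remaining in-weight to the largest remaining out-weight.
    Always feasible with support <= m + n - 1, and recovers the sparsest
    vertex whenever the true paths leave matching residual marginals.
    """
    m, n = len(win), len(wout)
    f = np.zeros((m, n))
    rows = {i: float(w) for i, w in enumerate(win)}
    cols = {j: float(w) for j, w in enumerate(wout)}
    scale = max(win.sum(), 1.0)
    while rows and cols:
        pair = None
        for i, wi in rows.items():
            for j, wj in cols.items():
                if abs(wi - wj) <= rtol * scale and (pair is None or wi > pair[2]):
                    pair = (i, j, wi)
        if pair is not None:
            i, j, w = pair
            f[i, j] += w
            del rows[i], cols[j]
            continue
        i = max(rows, key=rows.get)
        j = max(cols, key=cols.get)
        t = min(rows[i], cols[j])
        f[i, j] += t
        rows[i] -= t
        cols[j] -= t
        if rows[i] <= rtol * scale:
            del rows[i]
        if j in cols and cols[j] <= rtol * scale:
            del cols[j]
    return f


def apply_known_paths(
    candidates: list[FlowMatrix], known_pairs: set[tuple[int, int]]
) -> FlowMatrix:
    """Among equally sparse candidates, prefer the one covering the most
    known (in-edge, out-edge) pairs; fall back to a deterministic order."""
    if not candidates:
        raise ValueError("no candidates")

    def key(c: FlowMatrix):
        sup = tuple(sorted(c.support()))
        covered = sum(1 for p in known_pairs if p in c.support())
        return (-covered, sup)

    return min(candidates, key=key)


def local_decompose(
    problem: LocalProblem,
    trials: int = 5,
    seed: int = 0,
    rel_eps: float = 0.01,
    abs_eps: float = 1e-6,
) -> FlowMatrix:
    """Sparsest local flow via repeated randomly-reweighted LP.

    Each trial draws r_ij ~ Uniform(0.5, 1.5) and solves the reweighted LP;
    entries are thresholded and marginals restored, and the candidate with
    the smallest support wins.  Two deterministic candidates join the
    portfolio: a marginal-matching assignment (pairs equal in/out weights
    first), and — when known paths touch the node — one extra LP trial with
    r discounted on the known pairs so the witnessed pairing is always
    represented.  Requires a balanced problem.
    """
    win, wout = problem.in_weights, problem.out_weights
    if not np.isclose(win.sum(), wout.sum(), rtol=1e-6):
        raise ValueError("unbalanced local problem; run balance_node first")
    m, n = problem.shape
    if m == 1 or n == 1:
        # constraints force the (unique) product solution
        return FlowMatrix(_product_flow(win, wout))

    rng = np.random.default_rng(seed)
    reweights = [rng.uniform(0.5, 1.5, size=(m, n)) for _ in range(trials)]
    if problem.known_pairs:
        r_known = np.ones((m, n))
        for i, j in problem.known_pairs:
            r_known[i, j] = 0.6
        reweights.append(r_known)

    candidates: list[FlowMatrix] = []
    for r in reweights:
        f = _solve_reweighted_lp(r, win, wout)
        if f is None:
            continue
        g = _threshold_and_restore(f, win, wout, abs_eps, rel_eps)
        candidates.append(FlowMatrix(g))
    if not candidates:
        logger.warning("all reweighted LPs infeasible at node %s; "
                       "falling back to product flow", problem.node)
        candidates.append(FlowMatrix(_product_flow(win, wout)))
    candidates.append(FlowMatrix(_greedy_match_flow(win, wout)))
    best = min(c.support_size() for c in candidates)
    sparsest = [c for c in candidates if c.support_size() == best]
    return apply_known_paths(sparsest, problem.known_pairs)


def brute_force_min_support(
    problem: LocalProblem,
) -> tuple[int, list[FlowMatrix]]:
    """Exhaustive minimal-support oracle for tiny problems (m*n <= 12).

    Enumerates support sets in increasing size; a set is feasible when a
    nonnegative flow restricted to it meets the marginals (checked by LP).
    Returns the minimum feasible support size and all witnesses of that size.
    """
    m, n = problem.shape
    if m * n > 12:
        raise ValueError("problem too large for brute force (m*n > 12)")
    win, wout = problem.in_weights, problem.out_weights
    if not np.isclose(win.sum(), wout.sum(), rtol=1e-6):
        raise ValueError("unbalanced problem")
    cells = [(i, j) for i in range(m) for j in range(n)]
    for size in range(max(m, n), m * n + 1):
        witnesses: list[FlowMatrix] = []
        seen: set[frozenset] = set()
        for combo in itertools.combinations(cells, size):
            rows = {i for i, _ in combo}
            cols = {j for _, j in combo}
            if len(rows) < m or len(cols) < n:
                continue
            a_eq = np.zeros((m + n, size))
            for k, (i, j) in enumerate(combo):
                a_eq[i, k] = 1.0
                a_eq[m + j, k] = 1.0
            b_eq = np.concatenate([win, wout])
            res = linprog(
                np.zeros(size), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs"
            )
            if not res.success:
                continue
            f = np.zeros((m, n))
            for k, (i, j) in enumerate(combo):
                f[i, j] = res.x[k]
            sup = frozenset((i, j) for i, j in zip(*np.nonzero(f > 1e-9)))
            if len(sup) == size and sup not in seen:
                seen.add(sup)
                witnesses.append(FlowMatrix(f))
        if witnesses:
            return size, witnesses
    raise RuntimeError("no feasible support found")  # pragma: no cover


def augment_source_sink(g: nx.DiGraph) -> nx.DiGraph:
    """Add sentinel source/sink nodes with flow-balancing edge weights.

    Nodes without in-edges get a source edge weighted by their out-sum (and
    symmetrically for sinks); isolated nodes get both, weighted by their
    coverage so the node itself carries flow.
    """
    if g.number_of_nodes() == 0:
        return g
    g = g.copy()
    for v in [v for v in g.nodes if v not in (SOURCE, SINK)]:
        din = sum(d["weight"] for _, _, d in g.in_edges(v, data=True))
        dout = sum(d["weight"] for _, _, d in g.out_edges(v, data=True))
        if din == 0 and dout == 0:
            w = max(g.nodes[v].get("coverage", 1.0), 1e-9)
            g.add_edge(SOURCE, v, weight=w, kind="sentinel")
            g.add_edge(v, SINK, weight=w, kind="sentinel")
        elif din == 0:
            g.add_edge(SOURCE, v, weight=dout, kind="sentinel")
        elif dout == 0:
            g.add_edge(v, SINK, weight=din, kind="sentinel")
    return g


def _merge_exons(
    path: tuple[int, ...], by_id: dict[int, "object"]
) -> list[tuple[int, int]]:
    exons: list[list[int]] = []
    for nid in path:
        n = by_id[nid]
        if exons and exons[-1][1] == n.start:
            exons[-1][1] = n.end
        else:
            exons.append([n.start, n.end])
    return [(s, e) for s, e in exons]


def decompose_graph(
    graph: SpliceGraph, config: FlowConfig | None = None
) -> list[Transcript]:
    """Decompose one locus graph into transcripts with flow weights.

    Internal nodes are visited in genomic (hence topological) order.  Each
    carries a set of *live* in-flows, every one remembering the full node
    path from the source; the local decomposition pairs live in-flows with
    out-edges and forwards the extended paths downstream.  Flows reaching
    the sink are emitted as transcripts; paths shorter than ``min_tx_len``
    bases or lighter than ``min_tx_weight`` reads are dropped.
    """
    config = config or FlowConfig()
    if not graph.nodes:
        return []
    by_id = graph.node_by_id()
    g = augment_source_sink(graph.to_networkx())
    order = [n.id for n in sorted(graph.nodes, key=lambda n: (n.start, n.end))]

    # live flows: (path_prefix excluding current head, head, weight)
    live: dict[object, list[tuple[tuple[int, ...], float]]] = {v: [] for v in order}
    live[SINK] = []
    for _, v, d in g.out_edges(SOURCE, data=True):
        live[v].append(((), d["weight"]))

    finished: list[tuple[tuple[int, ...], float]] = []
    rng = np.random.default_rng(config.seed)
    for count, v in enumerate(order):
        inflows = live.pop(v)
        outs = [(x, d["weight"]) for _, x, d in g.out_edges(v, data=True)]
        if not inflows:
            continue
        if not outs:  # unreachable given augmentation, but keep safe
            continue
        win = np.array([w for _, w in inflows], dtype=float)
        wout = np.array([w for _, w in outs], dtype=float)
        win_b, wout_b, aux = balance_node(win, wout, config.balance_tol)
        prefixes = [p for p, _ in inflows]
        targets = [x for x, _ in outs]
        if aux == "in":
            prefixes.append(())
        elif aux == "out":
            targets.append(SINK)
        # known-path triples (u, v, x): pair live flows whose last node is u
        # with out-edges toward x
        known_pairs: set[tuple[int, int]] = set()
        for (u, vv, x) in graph.known_paths:
            if vv != v:
                continue
            for i, p in enumerate(prefixes):
                if p and p[-1] == u:
                    for j, t in enumerate(targets):
                        if t == x:
                            known_pairs.add((i, j))
        problem = LocalProblem(v, win_b, wout_b, known_pairs)
        node_seed = int(rng.integers(0, 2**31 - 1))
        flow = local_decompose(
            problem, config.trials, node_seed, config.rel_eps, config.abs_eps
        )
        for i, j in sorted(flow.support()):
            w = float(flow.values[i, j])
            new_path = prefixes[i] + (v,)
            tgt = targets[j]
            if tgt == SINK:
                finished.append((new_path, w))
            else:
                live[tgt].append((new_path, w))

    transcripts: list[Transcript] = []
    for path, w in finished:
        exons = _merge_exons(path, by_id)
        t = Transcript(graph.chrom, path, w, exons)
        if t.length < config.min_tx_len or t.weight < config.min_tx_weight:
            continue
        transcripts.append(t)
    transcripts.sort(key=lambda t: (t.exons[0][0], t.node_path))
    return transcripts


def greedy_path_decomposition(
    graph: SpliceGraph, eps: float = 1e-9
) -> list[tuple[tuple[int, ...], float]]:
    """Baseline: repeatedly extract the heaviest source-to-sink path.

    The heaviest path maximises total edge weight (DAG dynamic programme);
    its flow is the bottleneck edge weight, which is subtracted before the
    next round.  Serves as the comparison point showing why greedy traversal
    mis-assembles graphs that sparse decomposition resolves exactly.
    """
    g = augment_source_sink(graph.to_networkx())
    paths: list[tuple[tuple[int, ...], float]] = []
    while True:
        topo = list(nx.topological_sort(g))
        best: dict[object, tuple[float, tuple]] = {SOURCE: (0.0, (SOURCE,))}
        for v in topo:
            if v not in best:
                continue
            score, path = best[v]
            for _, x, d in g.out_edges(v, data=True):
                cand = (score + d["weight"], path + (x,))
                if x not in best or cand[0] > best[x][0]:
                    best[x] = cand
        if SINK not in best:
            break
        _, path = best[SINK]
        flow = min(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        if flow <= eps:
            break
        real = tuple(v for v in path if v not in (SOURCE, SINK))
        paths.append((real, flow))
        for u, v in zip(path, path[1:]):
            g[u][v]["weight"] -= flow
            if g[u][v]["weight"] <= eps:
                g.remove_edge(u, v)
        if g.number_of_edges() == 0:
            break
    return paths
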