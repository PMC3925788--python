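"""Contig graph construction, depth classification, and master-circle walks.

A plant mitochondrial assembly is naturally a graph: contigs are nodes with
a 5' and a 3' end, scaffold links join ends, and repeat contigs sit at the
junction of several loops. The conventional single-sequence representation
("master circle") is a closed walk through this graph that uses every
contig at least once, re-using repeat contigs as needed.

"Use all contigs at least once" is formalised here as a *minimum-length*
closed covering walk with a deterministic lexicographic tie-break, found by
depth-first search with memoised dead ends — adequate because organellar
contig graphs have tens of nodes. Contigs whose read depth falls below a
fraction of the mitochondrial median are classified as nuclear-encoded
copies beforehand; GC content is recorded but deliberately not used (true
nuclear copies of mitochondrial sequence have indistinguishable GC).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .core import revcomp

ENDS = ("5'", "3'")


@dataclass(frozen=True)
class Contig:
    id: str
    length: int
    mean_depth: float
    gc: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.id}: length must be positive")
        if self.mean_depth < 0:
            raise ValueError(f"{self.id}: depth must be >= 0")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.id}: gc must be in [0, 1]")


@dataclass
class ContigGraph:
    """Contigs joined end-to-end by oriented scaffold edges."""

    nodes: dict[str, Contig] = field(default_factory=dict)
    # canonical edge key -> summed support
    edges: dict[tuple[str, str, str, str], int] = field(default_factory=dict)

    @staticmethod
    def _canonical(a: str, ea: str, b: str, eb: str) -> tuple[str, str, str, str]:
        return (a, ea, b, eb) if (a, ea) <= (b, eb) else (b, eb, a, ea)

    def add_edge(self, a: str, ea: str, b: str, eb: str, support: int = 1) -> None:
        for cid, end in ((a, ea), (b, eb)):
            if cid not in self.nodes:
                raise ValueError(f"link references unknown contig {cid!r}")
            if end not in ENDS:
                raise ValueError(f"contig end must be 5' or 3', got {end!r}")
        key = self._canonical(a, ea, b, eb)
        self.edges[key] = self.edges.get(key, 0) + support

    def edges_at(self, cid: str, end: str) -> list[tuple[str, str]]:
        """(other_contig, other_end) over edges incident to (cid, end)."""
        out = []
        for a, ea, b, eb in self.edges:
            if (a, ea) == (cid, end):
                out.append((b, eb))
            if (b, eb) == (cid, end) and (a, ea) != (b, eb):
                out.append((a, ea))
        return out

    def n_edges(self) -> int:
        return len(self.edges)

    def components(self) -> list[set[str]]:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, _, b, _ in self.edges:
            g.add_edge(a, b)
        return [set(c) for c in nx.connected_components(g)]


@dataclass
class MasterCircleWalk:
    """A closed walk (contig, orientation) using every contig >= once."""

    steps: list[tuple[str, str]]
    closed: bool = True

    def __len__(self) -> int:
        return len(self.steps)


class NoMasterCircleError(RuntimeError):
    """No closed covering walk exists; carries the connected components."""

    def __init__(self, message: str, components: list[set[str]]):
        super().__init__(message)
        self.components = components


# ---------------------------------------------------------------------------
# depth classification
# ---------------------------------------------------------------------------

def classify_contigs(
    contigs: list[Contig], depth_ratio_threshold: float = 0.10
) -> dict[str, str]:
    """Split contigs into mitochondrial vs nuclear-copy by relative depth.

    The mitochondrial reference depth is the median over the retained set,
    computed iteratively: start from all contigs, drop those below
    ``threshold x median``, recompute the median once, and classify against
    it. A contig is a nuclear copy iff its depth is *strictly less than*
    ``threshold x reference``; a contig at exactly the threshold stays
    mitochondrial.
    """
    if not contigs:
        raise ValueError("need at least one contig")
    depths = sorted(c.mean_depth for c in contigs)
    ref = _median(depths)
    kept = [c.mean_depth for c in contigs
            if c.mean_depth >= depth_ratio_threshold * ref]
    if not kept:
        raise ValueError("all contigs fell below the depth threshold; "
                         "reference depth is degenerate")
    ref = _median(sorted(kept))
    out = {
        c.id: ("nuclear_copy" if c.mean_depth < depth_ratio_threshold * ref else "mito")
        for c in contigs
    }
    if all(v == "nuclear_copy" for v in out.values()):
        raise ValueError("all contigs classified nuclear_copy; degenerate reference")
    return out


def _median(sorted_vals: list[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])


# ---------------------------------------------------------------------------
# graph construction and degree profile
# ---------------------------------------------------------------------------

def build_graph(
    contigs: list[Contig],
    links: list[tuple[str, str, str, str, int]],
) -> ContigGraph:
    """Build the oriented contig graph from link records.

    Duplicate links (same contig-end pair in either order) collapse into a
    single edge with summed support. A link naming an unknown contig raises
    with the offending record.
    """
    graph = ContigGraph(nodes={c.id: c for c in contigs})
    for rec in links:
        a, ea, b, eb, support = rec
        try:
            graph.add_edge(a, ea, b, eb, int(support))
        except ValueError as exc:
            raise ValueError(f"bad link record {rec!r}: {exc}") from exc
    return graph


def degree_profile(graph: ContigGraph) -> dict[int, int]:
    """Tally contigs by the maximum edge multiplicity over their two ends.

    Class 1 contigs have single 5' and 3' edges (simple path members);
    class 2 contigs sit at the junction of two loops; and so on.
    """
    per_end: Counter = Counter()
    for a, ea, b, eb in graph.edges:
        per_end[(a, ea)] += 1
        if (a, ea) != (b, eb):
            per_end[(b, eb)] += 1
    profile: Counter = Counter()
    for cid in graph.nodes:
        profile[max(per_end[(cid, "5'")], per_end[(cid, "3'")])] += 1
    return dict(profile)


# ---------------------------------------------------------------------------
# master-circle traversal
# ---------------------------------------------------------------------------

def _out_end(orientation: str) -> str:
    return "3'" if orientation == "+" else "5'"


def _successors(graph: ContigGraph, step: tuple[str, str]) -> list[tuple[str, str]]:
    cid, ori = step
    nxt = []
    for b, eb in graph.edges_at(cid, _out_end(ori)):
        nxt.append((b, "+" if eb == "5'" else "-"))
    return sorted(set(nxt))


def _closes(graph: ContigGraph, last: tuple[str, str], first: tuple[str, str]) -> bool:
    return first in _successors(graph, last)


def traverse_master_circle(
    graph: ContigGraph, max_steps: int | None = None
) -> MasterCircleWalk:
    """Find the minimum-length closed walk covering every contig.

    Search is depth-first with backtracking and memoised dead ends, anchored
    at the lexicographically smallest contig id in '+' orientation (every
    closed covering walk can be rotated/reflected into that form, so the
    anchor loses no generality). Among minimal walks the lexicographically
    smallest step sequence is returned, making the traversal deterministic.

    Raises :class:`NoMasterCircleError` when the graph is disconnected or
    no closed covering walk exists within ``max_steps`` (default ``2n + 4``)
    — the graph may then represent independent subgenomic circles, reported
    as its connected components.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    comps = graph.components()
    if len(comps) > 1:
        raise NoMasterCircleError(
            f"contig graph is disconnected ({len(comps)} components); "
            "independent subgenomic circles?", comps)
    n = len(graph.nodes)
    if max_steps is None:
        max_steps = 2 * n + 4
    anchor = (min(graph.nodes), "+")
    for limit in range(n, max_steps + 1):
        walk = _search(graph, anchor, limit, find_all=False)
        if walk:
            return MasterCircleWalk(steps=walk[0], closed=True)
    raise NoMasterCircleError(
        f"no closed covering walk within {max_steps} steps", comps)


def _search(graph: ContigGraph, anchor, limit: int, find_all: bool,
            cap: int | None = None):
    """All closed covering walks of exactly ``limit`` steps from ``anchor``
    (or just the first, lexicographically smallest, when not ``find_all``)."""
    n = len(graph.nodes)
    results: list[list[tuple[str, str]]] = []
    dead: set = set()

    def dfs(walk: list, covered: frozenset) -> bool:
        remaining = limit - len(walk)
        if remaining == 0:
            if len(covered) == n and _closes(graph, walk[-1], anchor):
                results.append(list(walk))
                return not find_all
            return False
        if n - len(covered) > remaining:
            return False
        state = (walk[-1], covered, remaining)
        if not find_all and state in dead:
            return False
        for nxt in _successors(graph, walk[-1]):
            walk.append(nxt)
            done = dfs(walk, covered | {nxt[0]})
            walk.pop()
            if done:
                return True
            if find_all and cap is not None and len(results) >= cap:
                return True
        if not find_all:
            dead.add(state)
        return False

    dfs([anchor], frozenset({anchor[0]}))
    return results


def count_configurations(graph: ContigGraph, cap: int = 1000) -> tuple[int, bool]:
    """Count distinct minimal closed covering walks up to rotation/reflection.

    Returns ``(count, capped)``; ``capped`` is True when enumeration stopped
    early at ``cap``, meaning "at least cap" configurations exist.
    """
    n = len(graph.nodes)
    anchor = (min(graph.nodes), "+")
    walks: list = []
    for limit in range(n, 2 * n + 5):
        walks = _search(graph, anchor, limit, find_all=True, cap=10 * cap)
        if walks:
            break
    classes: set[tuple] = set()
    for walk in walks:
        classes.add(_canonical_class(walk))
        if len(classes) >= cap:
            return cap, True
    return len(classes), False


def _canonical_class(walk: list[tuple[str, str]]) -> tuple:
    """Canonical form of a closed walk under rotation and reflection."""
    k = len(walk)
    flip = {"+": "-", "-": "+"}
    reflected = [(cid, flip[ori]) for cid, ori in reversed(walk)]
    forms = []
    for seq in (walk, reflected):
        for r in range(k):
            forms.append(tuple(seq[r:] + seq[:r]))
    return min(forms)


# ---------------------------------------------------------------------------
# independent walk validation and stitching
# ---------------------------------------------------------------------------

def validate_walk(graph: ContigGraph, walk: MasterCircleWalk) -> bool:
    """Edge-consistency + coverage check, sharing no code with the search.

    Every consecutive step pair (and last -> first for closed walks) must
    be joined by an edge whose ends match the two orientations, and every
    graph node must appear at least once.
    """
    steps = walk.steps
    if not steps:
        return False
    if {cid for cid, _ in steps} != set(graph.nodes):
        return False
    pairs = list(zip(steps, steps[1:]))
    if walk.closed:
        pairs.append((steps[-1], steps[0]))
    for (a, oa), (b, ob) in pairs:
        end_a = "3'" if oa == "+" else "5'"
        end_b = "5'" if ob == "+" else "3'"
        key1 = (a, end_a, b, end_b)
        key2 = (b, end_b, a, end_a)
        if key1 not in graph.edges and key2 not in graph.edges:
            return False
    return True


def stitch_walk(walk: MasterCircleWalk, sequences: dict[str, str]) -> str:
    """Concatenate contig sequences along the walk (reverse-complementing
    '-' steps). Assumes contigs tile without overlap, as the simulator
    produces."""
    parts = []
    for cid, ori in walk.steps:
        seq = sequences[cid]
        parts.append(seq if ori == "+" else revcomp(seq))
    return "".join(parts)


def equal_up_to_rotation_and_strand(a: str, b: str) -> bool:
    """True iff circular sequence b is a rotation of a or of revcomp(a)."""
    if len(a) != len(b):
        return False
    return b in a + a or b in revcomp(a) + revcomp(a)
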