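"""Isoform collapse, in-paralog detection, and BDBH / Markov clustering.

The similarity graph produced by the alignment layer is clustered with one of
two algorithms.  BDBH seeds candidate clusters with the sequences of a chosen
reference accession and grows them by bidirectional best hits, so genes absent
from the reference are never clustered.  The OMCL-style route symmetrizes the
graph, normalizes edge weights per accession pair (so closely related
accessions do not dominate), and runs Markov clustering (alternating expansion
and inflation of a column-stochastic matrix); with no cluster-size restriction
every node, including singletons, ends up in exactly one cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np


@dataclass
class Edge:
    """Directed similarity edge with its merged-alignment evidence."""

    weight: float  # capped -log10(evalue), in [0, 300]
    bitscore: float
    evalue: float
    identity: float
    coverage: float
    covered_bp: int
    strand: str


class SimilarityGraph:
    """Directed weighted graph over sequences with a per-accession best-hit index.

    Nodes carry accession labels and lengths; there are no self-edges.  For
    every (node, target accession) pair the best outgoing edge is indexed,
    ranked by bitscore, then lower evalue, then lexicographic target id.
    """

    def __init__(self, min_identity: float = 95.0, min_coverage: float = 50.0):
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self.accession_of: dict[str, str] = {}
        self.length_of: dict[str, int] = {}
        self.accessions: list[str] = []
        self.edges: dict[tuple[str, str], Edge] = {}
        self._best: dict[tuple[str, str], str] = {}
        self._out: dict[str, list[str]] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, seq_id: str, accession: str, length: int) -> None:
        if seq_id not in self.accession_of:
            self.accession_of[seq_id] = accession
            self.length_of[seq_id] = length
            self._out[seq_id] = []
            if accession not in self.accessions:
                self.accessions.append(accession)

    def add_edge(self, q_id: str, s_id: str, edge: Edge) -> None:
        if q_id == s_id:
            return
        if q_id not in self.accession_of or s_id not in self.accession_of:
            raise KeyError(f"edge endpoints must be added as nodes first: {q_id}->{s_id}")
        self.edges[(q_id, s_id)] = edge
        self._out[q_id].append(s_id)
        acc = self.accession_of[s_id]
        cur = self._best.get((q_id, acc))
        if cur is None:
            self._best[(q_id, acc)] = s_id
            return
        cur_edge = self.edges[(q_id, cur)]
        new_key = (edge.bitscore, -edge.evalue)
        cur_key = (cur_edge.bitscore, -cur_edge.evalue)
        # higher bitscore, then lower evalue, then lexicographically lower id
        if new_key > cur_key or (new_key == cur_key and s_id < cur):
            self._best[(q_id, acc)] = s_id

    # -- queries ----------------------------------------------------------
    def nodes(self) -> list[str]:
        return list(self.accession_of)

    def best_hit(self, seq_id: str, accession: str) -> Optional[str]:
        """Best-scoring target of ``seq_id`` within ``accession`` (never itself)."""
        return self._best.get((seq_id, accession))

    def out_neighbors(self, seq_id: str) -> list[str]:
        return self._out[seq_id]

    def weight(self, q: str, s: str) -> float:
        edge = self.edges.get((q, s))
        return edge.weight if edge is not None else 0.0


@dataclass
class Cluster:
    """A group of non-redundant sequences plus the isoforms collapsed onto them."""

    cluster_id: str
    members: list[str]
    per_accession: dict[str, int]
    occupancy: int
    single_copy: bool
    isoforms: dict[str, list[str]] = field(default_factory=dict)  # member -> dropped ids

    def all_sequences(self) -> list[str]:
        out = list(self.members)
        for extras in self.isoforms.values():
            out.extend(extras)
        return out


@dataclass
class RedundancyMap:
    """Mapping of every sequence to its redundancy-group representative."""

    representative: dict[str, str]
    dropped: set[str]

    def rep(self, seq_id: str) -> str:
        return self.representative.get(seq_id, seq_id)


def _make_cluster(
    cluster_id: str,
    members: list[str],
    accession_of: dict[str, str],
    redundancy: Optional[RedundancyMap],
) -> Cluster:
    per_acc: dict[str, int] = {}
    isoforms: dict[str, list[str]] = {}
    if redundancy is not None:
        member_set = set(members)
        for dropped, rep in redundancy.representative.items():
            if dropped in redundancy.dropped and rep in member_set:
                isoforms.setdefault(rep, []).append(dropped)
        for v in isoforms.values():
            v.sort()
    for m in members:
        acc = accession_of[m]
        per_acc[acc] = per_acc.get(acc, 0) + 1
    return Cluster(
        cluster_id=cluster_id,
        members=sorted(members),
        per_accession=per_acc,
        occupancy=len(per_acc),
        single_copy=all(v <= 1 for v in per_acc.values()),
        isoforms=isoforms,
    )


# ---------------------------------------------------------------------------
# isoform collapse
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def collapse_isoforms(
    graph: SimilarityGraph,
    seqs=None,
    min_overlap: int = 40,
    min_identity: float = 95.0,
) -> RedundancyMap:
    """Collapse redundant within-accession isoforms onto their longest member.

    Two sequences of the same accession are redundant when their merged
    alignment spans at least ``min_overlap`` bp at ``min_identity`` or better
    and passes the graph's coverage threshold (computed over the shorter
    sequence, so a fully contained fragment always qualifies on coverage).
    Redundancy groups are transitive closures; the longest member (ties broken
    by lexicographic id) represents the group.
    """
    uf = _UnionFind()
    for (q, s), edge in graph.edges.items():
        if graph.accession_of[q] != graph.accession_of[s]:
            continue
        if (
            edge.covered_bp >= min_overlap
            and edge.identity >= min_identity
            and edge.coverage >= graph.min_coverage
        ):
            uf.union(q, s)
    groups: dict[str, list[str]] = {}
    for node in uf.parent:
        groups.setdefault(uf.find(node), []).append(node)
    representative: dict[str, str] = {}
    dropped: set[str] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        rep = min(members, key=lambda m: (-graph.length_of[m], m))
        for m in members:
            representative[m] = rep
            if m != rep:
                dropped.add(m)
    for node in graph.nodes():
        representative.setdefault(node, node)
    return RedundancyMap(representative=representative, dropped=dropped)


# ---------------------------------------------------------------------------
# in-paralogs
# ---------------------------------------------------------------------------

def detect_inparalogs(graph: SimilarityGraph) -> dict[str, set[str]]:
    """Same-accession reciprocal best hits that beat all cross-accession hits.

    A pair (x, y) within one accession is an in-paralog pair when each is the
    other's best hit inside the accession and each of those edges scores at
    least as high as any cross-accession hit of either sequence.
    """
    result: dict[str, set[str]] = {node: set() for node in graph.nodes()}

    def best_cross_key(x: str) -> Optional[tuple]:
        acc = graph.accession_of[x]
        keys = []
        for other in graph.accessions:
            if other == acc:
                continue
            hit = graph.best_hit(x, other)
            if hit is not None:
                e = graph.edges[(x, hit)]
                keys.append((e.bitscore, -e.evalue))
        return max(keys) if keys else None

    for x in graph.nodes():
        acc = graph.accession_of[x]
        y = graph.best_hit(x, acc)
        if y is None or graph.best_hit(y, acc) != x:
            continue
        key_xy = graph.edges[(x, y)]
        key_yx = graph.edges[(y, x)]
        ok = True
        for node, edge in ((x, key_xy), (y, key_yx)):
            cross = best_cross_key(node)
            if cross is not None and (edge.bitscore, -edge.evalue) < cross:
                ok = False
                break
        if ok:
            result[x].add(y)
            result[y].add(x)
    return result


# ---------------------------------------------------------------------------
# BDBH
# ---------------------------------------------------------------------------

def cluster_bdbh(
    graph: SimilarityGraph,
    reference: str,
    redundancy: Optional[RedundancyMap] = None,
    inparalogs: Optional[dict[str, set[str]]] = None,
) -> list[Cluster]:
    """Seed one candidate cluster per non-redundant reference sequence.

    For every other accession (in input order) the sequence forming a
    bidirectional best hit with the seed is added; in-paralogs of added
    members join their representative's cluster.  Clusters are disjoint;
    contested in-paralogs go to the cluster with the highest-weight edge
    (ties: lower evalue, then lexicographic seed id).  Genes absent from the
    reference remain unclustered.
    """
    if reference not in graph.accessions:
        raise KeyError(f"unknown reference accession {reference!r}")
    if inparalogs is None:
        inparalogs = detect_inparalogs(graph)
    dropped = redundancy.dropped if redundancy is not None else set()

    seeds = sorted(
        n
        for n in graph.nodes()
        if graph.accession_of[n] == reference and n not in dropped
    )
    claimed: set[str] = set()
    memberships: dict[str, list[str]] = {}
    for seed in seeds:
        members = [seed]
        claimed.add(seed)
        for acc in graph.accessions:
            if acc == reference:
                continue
            cand = graph.best_hit(seed, acc)
            if cand is None or cand in dropped or cand in claimed:
                continue
            back = graph.best_hit(cand, reference)
            if back != seed:
                continue
            members.append(cand)
            claimed.add(cand)
        memberships[seed] = members

    # attach in-paralogs deterministically: strongest supporting edge wins
    requests = []  # (bitscore, -evalue, seed, member, paralog)
    for seed, members in memberships.items():
        for m in members:
            for p in inparalogs.get(m, ()):  # same accession by construction
                if p in dropped or p in claimed:
                    continue
                e = graph.edges[(m, p)]
                requests.append((e.bitscore, -e.evalue, seed, m, p))
    for bitscore, neg_ev, seed, m, p in sorted(
        requests, key=lambda r: (-r[0], -r[1], r[2])
    ):
        if p not in claimed:
            memberships[seed].append(p)
            claimed.add(p)

    clusters = []
    for i, seed in enumerate(sorted(memberships)):
        clusters.append(
            _make_cluster(
                f"bdbh{i + 1:05d}", memberships[seed], graph.accession_of, redundancy
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# OMCL-style Markov clustering
# ---------------------------------------------------------------------------

def _mcl(matrix: np.ndarray, inflation: float, max_iter: int, prune_below: float,
         tol: float) -> tuple[np.ndarray, bool]:
    m = matrix / matrix.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated[inflated < prune_below] = 0.0
        colsums = inflated.sum(axis=0, keepdims=True)
        colsums[colsums == 0.0] = 1.0
        inflated /= colsums
        change = np.abs(inflated - m).max()
        m = inflated
        if change < tol:
            return m, True
    return m, False


def cluster_omcl(
    graph: SimilarityGraph,
    inflation: float = 1.5,
    max_iter: int = 100,
    prune_below: float = 1e-5,
    tol: float = 1e-6,
    normalize_accession_pairs: bool = True,
    redundancy: Optional[RedundancyMap] = None,
) -> list[Cluster]:
    """Markov clustering of the symmetrized similarity graph.

    Directed weights are symmetrized as the mean of both directions (a missing
    reciprocal contributes 0 rather than vetoing the pair, since truncated
    transcripts often align with adequate coverage in one direction only).
    Weights are then normalized by the mean weight of their accession pair,
    self-loops set to each node's maximum incident weight, and the resulting
    column-stochastic matrix iterated through expansion/inflation until
    convergence.  Clusters are the connected components of the converged
    attractor structure; singletons are emitted as clusters of size one.
    """
    dropped = redundancy.dropped if redundancy is not None else set()
    nodes = sorted(n for n in graph.nodes() if n not in dropped)
    if not nodes:
        raise ValueError("graph has no nodes to cluster")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for (q, s), edge in graph.edges.items():
        if q in dropped or s in dropped:
            continue
        i, j = idx[q], idx[s]
        w[i, j] = edge.weight
    sym = (w + w.T) / 2.0
    present = sym > 0.0

    if normalize_accession_pairs:
        acc_idx = {a: k for k, a in enumerate(graph.accessions)}
        acc_of = np.array([acc_idx[graph.accession_of[node]] for node in nodes])
        n_acc = len(graph.accessions)
        sums = np.zeros((n_acc, n_acc))
        counts = np.zeros((n_acc, n_acc))
        ii, jj = np.nonzero(np.triu(present, k=1))
        for i, j in zip(ii, jj):
            a, b = sorted((acc_of[i], acc_of[j]))
            sums[a, b] += sym[i, j]
            counts[a, b] += 1
        for i, j in zip(*np.nonzero(present)):
            a, b = sorted((acc_of[i], acc_of[j]))
            if counts[a, b] > 0 and sums[a, b] > 0:
                sym[i, j] /= sums[a, b] / counts[a, b]

    loops = sym.max(axis=0)
    loops[loops == 0.0] = 1.0
    np.fill_diagonal(sym, loops)

    converged_m, ok = _mcl(sym, inflation, max_iter, prune_below, tol)
    if not ok:
        warnings.warn("Markov clustering did not converge; using current partition")

    structure = nx.Graph()
    structure.add_nodes_from(range(n))
    ii, jj = np.nonzero(converged_m > prune_below)
    structure.add_edges_from((i, j) for i, j in zip(ii, jj) if i != j)

    components = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(structure)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return [
        _make_cluster(f"omcl{i + 1:05d}", comp, graph.accession_of, redundancy)
        for i, comp in enumerate(components)
    ]
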