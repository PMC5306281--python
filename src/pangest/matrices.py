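"""Pan-genome matrices, occupancy classes, ANI matrices and derived reports.

A pan-genome matrix (PM) counts, for every accession (row) and sequence
cluster (column), how many sequences of that accession fell in the cluster.
Occupancy — the number of accessions represented in a cluster — drives the
classification into core (all N accessions), soft-core (nearly all, by
default at least the nearest integer to 0.95 N), shell, and cloud (at most 2
accessions) classes.  Average nucleotide identity (ANI) between two
accessions is the mean identity of the merged alignments of their
co-clustered sequences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .clustering import Cluster
from .pairwise import PairwiseHit, group_hsps_by_pair, local_align, merge_all_pairs, merge_hsps
from .seqio import AccessionSet, SequenceRecord

OCCUPANCY_CLASSES = ("core", "soft-core", "shell", "cloud")


@dataclass
class PangenomeMatrix:
    """Accessions x clusters occurrence-count matrix."""

    accessions: list[str]
    cluster_ids: list[str]
    counts: np.ndarray  # shape (n_accessions, n_clusters), non-negative ints

    @property
    def occupancy(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\t" + "\t".join(self.cluster_ids) + "\n")
            for i, acc in enumerate(self.accessions):
                fh.write(acc + "\t" + "\t".join(str(v) for v in self.counts[i]) + "\n")


@dataclass
class ANIMatrix:
    """Symmetric accession x accession average nucleotide identity matrix."""

    accessions: list[str]
    values: np.ndarray  # percent, diagonal 100, NaN when never co-clustered
    n_pairs_used: np.ndarray

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.accessions)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.accessions[i], self.accessions[j]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\t" + "\t".join(self.accessions) + "\n")
            for i, acc in enumerate(self.accessions):
                fh.write(
                    acc
                    + "\t"
                    + "\t".join(f"{v:.4f}" for v in self.values[i])
                    + "\n"
                )


def build_pangenome_matrix(
    clusters: Iterable[Cluster],
    accessions: list[str],
    seqs: Optional[AccessionSet] = None,
    include_isoforms: bool = True,
) -> PangenomeMatrix:
    """Count cluster membership per accession.

    Collapsed isoforms are mapped to their representative's cluster (disable
    with ``include_isoforms=False``).  Column order follows the cluster list.
    """
    clusters = list(clusters)
    acc_index = {a: i for i, a in enumerate(accessions)}
    acc_of = {rec.seq_id: rec.accession for rec in seqs} if seqs is not None else None
    counts = np.zeros((len(accessions), len(clusters)), dtype=int)
    for j, cluster in enumerate(clusters):
        for acc, k in cluster.per_accession.items():
            if acc not in acc_index:
                raise KeyError(f"cluster member accession {acc!r} not in accession list")
            counts[acc_index[acc], j] += k
        if include_isoforms:
            for rep, extras in cluster.isoforms.items():
                for iso in extras:
                    if acc_of is None:
                        raise ValueError("seqs required to place isoforms")
                    acc = acc_of[iso]
                    if acc not in acc_index:
                        raise KeyError(f"isoform accession {acc!r} not in accession list")
                    counts[acc_index[acc], j] += 1
    return PangenomeMatrix(
        accessions=list(accessions),
        cluster_ids=[c.cluster_id for c in clusters],
        counts=counts,
    )


def soft_core_min_occupancy(n_accessions: int, soft_fraction: float = 0.95) -> int:
    """Lowest occupancy admitted to the soft-core (nearest integer to f*N)."""
    return int(math.floor(soft_fraction * n_accessions + 0.5))


def classify_occupancy(
    pm: PangenomeMatrix,
    soft_fraction: float = 0.95,
    cloud_max: int = 2,
) -> dict[str, str]:
    """Label every cluster core / soft-core / shell / cloud by occupancy.

    Core requires all N accessions; the soft-core admits clusters missing
    from a small fraction of accessions (occupancy at least the nearest
    integer to ``soft_fraction * N`` — absence from one of 16 or 19 inputs);
    cloud clusters appear in at most ``cloud_max`` accessions; shell is the
    remainder.  If the soft band dips into the cloud band the soft label wins.
    """
    n = len(pm.accessions)
    if n < 3:
        raise ValueError("occupancy classification needs at least 3 accessions")
    soft_min = soft_core_min_occupancy(n, soft_fraction)
    if soft_min <= cloud_max:
        warnings.warn("soft-core threshold overlaps the cloud band; soft-core wins")
    labels: dict[str, str] = {}
    for cid, occ in zip(pm.cluster_ids, pm.occupancy):
        if occ == n:
            labels[cid] = "core"
        elif occ >= soft_min:
            labels[cid] = "soft-core"
        elif occ <= cloud_max:
            labels[cid] = "cloud"
        else:
            labels[cid] = "shell"
    return labels


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

def compute_ani(
    clusters: Iterable[Cluster],
    hits,
    seqs: AccessionSet,
    cluster_filter: str = "all",
    min_occupancy: Optional[int] = None,
) -> ANIMatrix:
    """Average nucleotide identity per accession pair from co-clustered hits.

    For each accession pair (A, B) the identities of all merged pairwise
    hits between A-sequences and B-sequences lying in the same cluster are
    averaged; both hit directions of a sequence pair count as one alignment
    (their identities are averaged first).  ``cluster_filter`` restricts the
    clusters considered: ``all``, ``core``, ``single_copy`` or
    ``min_occupancy`` (with ``min_occupancy=k``).
    """
    clusters = list(clusters)
    n_total = len(seqs.accessions)
    if cluster_filter == "all":
        kept = clusters
    elif cluster_filter == "core":
        kept = [c for c in clusters if c.occupancy == n_total]
    elif cluster_filter == "single_copy":
        kept = [c for c in clusters if c.single_copy]
    elif cluster_filter == "min_occupancy":
        if min_occupancy is None:
            raise ValueError("min_occupancy filter requires a k value")
        kept = [c for c in clusters if c.occupancy >= min_occupancy]
    else:
        raise ValueError(f"unknown cluster filter {cluster_filter!r}")
    if not kept:
        raise ValueError("cluster filter left no clusters")

    if isinstance(hits, dict):
        merged: dict[tuple[str, str], PairwiseHit] = hits
    else:
        merged = merge_all_pairs(hits, seqs)

    acc_of = {rec.seq_id: rec.accession for rec in seqs}
    acc_index = {a: i for i, a in enumerate(seqs.accessions)}
    n = len(seqs.accessions)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for cluster in kept:
        members = cluster.members
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                a, b = members[x], members[y]
                ai, bi = acc_index[acc_of[a]], acc_index[acc_of[b]]
                if ai == bi:
                    continue
                idents = [
                    merged[key].identity
                    for key in ((a, b), (b, a))
                    if key in merged
                ]
                if not idents:
                    continue
                ident = sum(idents) / len(idents)
                sums[ai, bi] += ident
                sums[bi, ai] += ident
                counts[ai, bi] += 1
                counts[bi, ai] += 1

    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(values, 100.0)
    ani = ANIMatrix(
        accessions=list(seqs.accessions), values=values, n_pairs_used=counts
    )
    if ani.missing_pairs():
        warnings.warn(
            f"{len(ani.missing_pairs())} accession pairs were never co-clustered"
        )
    return ani


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Newick string from a scipy linkage matrix.

    Branch lengths are half the merge-height differences, so the cophenetic
    distance between two leaves equals their merge height.
    """
    tree = hierarchy.to_tree(link)

    def recurse(node, parent_height: float) -> str:
        length = (parent_height - node.dist) / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    left = recurse(tree.left, tree.dist)
    right = recurse(tree.right, tree.dist)
    return f"({left},{right});"


def ani_dendrogram(
    ani: ANIMatrix,
    method: str = "euclidean_columns",
    linkage: str = "complete",
) -> str:
    """Hierarchical clustering of the ANI matrix, returned as Newick.

    ``distance_direct`` uses d = 100 - ANI; ``euclidean_columns`` the
    Euclidean distance between ANI column vectors (with the diagonal at 100).
    """
    if ani.missing_pairs():
        raise ValueError(f"ANI matrix has missing values: {ani.missing_pairs()}")
    if method == "distance_direct":
        dist = 100.0 - ani.values
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
    elif method == "euclidean_columns":
        condensed = pdist(ani.values.T, metric="euclidean")
    else:
        raise ValueError(f"unknown method {method!r}")
    if linkage not in ("complete", "average"):
        raise ValueError(f"unknown linkage {linkage!r}")
    link = hierarchy.linkage(condensed, method=linkage)
    return _linkage_to_newick(link, ani.accessions)


# ---------------------------------------------------------------------------
# non-redundant matrix and reference comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Reference-CDS comparison mirroring recall/precision bookkeeping."""

    total_references: int
    matched_references: int
    total_clusters: int
    matching_clusters: int
    recall: float
    precision: float
    clusters_per_matched_reference: float
    nr_pan_size: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "nr_clusters\tmatching_clusters\tmatched_references\ttotal_references\t"
                "clusters_per_cds\trecall\tprecision\tpan_size\n"
            )
            fh.write(
                f"{self.total_clusters}\t{self.matching_clusters}\t"
                f"{self.matched_references}\t{self.total_references}\t"
                f"{self.clusters_per_matched_reference:.2f}\t{self.recall:.2f}\t"
                f"{self.precision:.2f}\t{self.nr_pan_size}\n"
            )


@dataclass
class NRResult:
    pm: PangenomeMatrix
    column_map: dict[str, str]  # original cluster id -> NR column id
    representatives: dict[str, str]  # NR column id -> representative seq_id
    report: Optional[ComparisonReport] = None


def _pair_matches(
    a: SequenceRecord | tuple[str, str],
    b: SequenceRecord | tuple[str, str],
    min_identity: float,
    min_coverage: float,
) -> bool:
    """Merged shortest-mode alignment of two sequences passes both thresholds."""
    a_id, a_nt = (a.seq_id, a.nt) if isinstance(a, SequenceRecord) else a
    b_id, b_nt = (b.seq_id, b.nt) if isinstance(b, SequenceRecord) else b
    hsps = local_align(a_nt, b_nt, q_id=a_id, s_id=b_id)
    if not hsps:
        return False
    hit = merge_hsps(hsps, len(a_nt), len(b_nt), mode="shortest")
    return hit.identity >= min_identity and hit.coverage >= min_coverage


def make_nr_matrix(
    pm: PangenomeMatrix,
    clusters: Iterable[Cluster],
    seqs: AccessionSet,
    min_identity: float = 95.0,
    min_coverage: float = 50.0,
    reference_cds: Optional[dict[str, str]] = None,
) -> NRResult:
    """Collapse clusters with mutually matching representatives; optionally
    compare the non-redundant clusters against a reference CDS set.

    Representatives (longest member) are considered in descending length
    order; a cluster joins the first accepted non-redundant column whose
    representative it matches at the identity/coverage thresholds, else it
    founds a new column.  The reference comparison reports recall (matched
    references / total references), precision (matching clusters / total
    clusters) and the clusters-per-matched-reference ratio.
    """
    clusters = list(clusters)
    index = seqs.by_id()
    cluster_by_id = {c.cluster_id: c for c in clusters}
    reps = {
        c.cluster_id: max(c.members, key=lambda m: (index[m].length, m))
        for c in clusters
    }
    order = sorted(clusters, key=lambda c: (-index[reps[c.cluster_id]].length, c.cluster_id))

    accepted: list[str] = []  # NR column ids == founding cluster ids
    column_map: dict[str, str] = {}
    for cluster in order:
        rep = index[reps[cluster.cluster_id]]
        target = None
        for nr_id in accepted:
            nr_rep = index[reps[nr_id]]
            if _pair_matches(rep, nr_rep, min_identity, min_coverage):
                target = nr_id
                break
        if target is None:
            accepted.append(cluster.cluster_id)
            column_map[cluster.cluster_id] = cluster.cluster_id
        else:
            column_map[cluster.cluster_id] = target

    old_col = {cid: j for j, cid in enumerate(pm.cluster_ids)}
    counts = np.zeros((len(pm.accessions), len(accepted)), dtype=int)
    for cid, nr_id in column_map.items():
        if cid in old_col:
            counts[:, accepted.index(nr_id)] += pm.counts[:, old_col[cid]]
    nr_pm = PangenomeMatrix(
        accessions=list(pm.accessions), cluster_ids=list(accepted), counts=counts
    )

    report = None
    if reference_cds is not None:
        if not reference_cds:
            raise ValueError("empty reference CDS set")
        matched_refs: set[str] = set()
        matching_clusters = 0
        for nr_id in accepted:
            rep = index[reps[nr_id]]
            hit_any = False
            for ref_id, ref_nt in reference_cds.items():
                if _pair_matches(rep, (ref_id, ref_nt), min_identity, min_coverage):
                    matched_refs.add(ref_id)
                    hit_any = True
            if hit_any:
                matching_clusters += 1
        n_ref = len(reference_cds)
        report = ComparisonReport(
            total_references=n_ref,
            matched_references=len(matched_refs),
            total_clusters=len(accepted),
            matching_clusters=matching_clusters,
            recall=len(matched_refs) / n_ref,
            precision=matching_clusters / len(accepted) if accepted else 0.0,
            clusters_per_matched_reference=(
                matching_clusters / len(matched_refs) if matched_refs else 0.0
            ),
            nr_pan_size=len(accepted),
        )
    return NRResult(
        pm=nr_pm,
        column_map=column_map,
        representatives={nr_id: reps[nr_id] for nr_id in accepted},
        report=report,
    )


def find_accessory(
    pm: PangenomeMatrix,
    include: set[str],
    exclude: set[str],
    min_occupancy: int = 3,
) -> list[str]:
    """Clusters present in every ``include`` accession, absent from every
    ``exclude`` accession, with occupancy at least ``min_occupancy``."""
    if include & exclude:
        raise ValueError("include and exclude sets overlap")
    unknown = (include | exclude) - set(pm.accessions)
    if unknown:
        raise KeyError(f"unknown accessions: {sorted(unknown)}")
    acc_index = {a: i for i, a in enumerate(pm.accessions)}
    occ = pm.occupancy
    out = []
    for j, cid in enumerate(pm.cluster_ids):
        col = pm.counts[:, j]
        if occ[j] < min_occupancy:
            continue
        if any(col[acc_index[a]] == 0 for a in include):
            continue
        if any(col[acc_index[a]] > 0 for a in exclude):
            continue
        out.append(cid)
    return out
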