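"""Codon-level conservation (NG86 dN/dS), occupancy summaries, tree distances.

Pairwise dN/dS follows the Nei–Gojobori counting method: synonymous and
non-synonymous site counts are derived per codon from the standard genetic
code (averaged over the two sequences), multiple-hit codons are averaged over
all minimal mutational pathways with pathways through stop codons excluded,
and the raw proportions are corrected with the Jukes–Cantor formula
``d = -(3/4) ln(1 - 4p/3)``.  omega = dN/dS is undefined when dS == 0, and an
estimate with p >= 3/4 is flagged unusable rather than returned as a number.

Tree comparison uses unrooted split semantics: the symmetric
(Robinson–Foulds) distance counts splits present in exactly one tree, and the
branch score sums squared branch-length differences over all splits (absent
splits contribute length zero).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .seqio import SequenceRecord

_STOPS = set(standard_dna_table.stop_codons)
_CODE = dict(standard_dna_table.forward_table)
_CODE.update({c: "*" for c in _STOPS})
_BASES = "ACGT"


def _translate_codon(codon: str) -> Optional[str]:
    return _CODE.get(codon)


def _syn_fraction(codon: str) -> float:
    """Fraction of the 9 single-nucleotide changes that are synonymous.

    Changes producing stop codons count as non-synonymous, so per-codon
    synonymous + non-synonymous sites always sum to 3.
    """
    aa = _CODE[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODE[alt] == aa and _CODE[alt] != "*":
                syn += 1
    return syn / 3.0


_SYN_SITES = {
    codon: _syn_fraction(codon)
    for codon in ("".join(c) for c in itertools.product(_BASES, repeat=3))
    if codon not in _STOPS
}


# ---------------------------------------------------------------------------
# codon alignment (center-star over peptides)
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gapped codon rows of equal length; gaps occupy whole codons."""

    seq_ids: list[str]
    rows: list[str]
    excluded: list[str]

    def codons(self, i: int) -> list[str]:
        row = self.rows[i]
        return [row[j : j + 3] for j in range(0, len(row), 3)]


def _peptide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _gapped_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def align_codons(cds_members: Iterable[SequenceRecord]) -> CodonAlignment:
    """Center-star global peptide alignment, back-translated codon-wise.

    The longest peptide is the alignment center; every other member is
    aligned to it globally (BLOSUM62, affine gaps) and the pairwise
    alignments are merged on center coordinates.  Rows cover the coding part
    only (the terminal stop codon is not aligned).  Members with internal
    stop codons or lengths not divisible by 3 are excluded with a warning.
    """
    usable: list[tuple[SequenceRecord, str]] = []
    excluded: list[str] = []
    for rec in cds_members:
        if rec.length % 3 != 0:
            warnings.warn(f"{rec.seq_id}: length not divisible by 3; excluded")
            excluded.append(rec.seq_id)
            continue
        pep = str(Seq(rec.nt).translate())
        if pep.endswith("*"):
            pep = pep[:-1]
        if "*" in pep:
            warnings.warn(f"{rec.seq_id}: internal stop codon; excluded")
            excluded.append(rec.seq_id)
            continue
        if rec.peptide is not None and rec.peptide.rstrip("*") != pep:
            warnings.warn(f"{rec.seq_id}: stored peptide disagrees with translation")
        usable.append((rec, pep))
    if len(usable) < 2:
        raise ValueError("codon alignment needs at least 2 usable members")

    center_i = max(range(len(usable)), key=lambda i: (len(usable[i][1]), usable[i][0].seq_id))
    center_rec, center_pep = usable[center_i]
    others = [usable[i] for i in range(len(usable)) if i != center_i]

    aligner = _peptide_aligner()
    # per pairwise alignment: insertions relative to center, and residue map
    pair_data = []
    max_ins = [0] * (len(center_pep) + 1)  # insertions before center pos j (j==L: trailing)
    for rec, pep in others:
        aln = aligner.align(center_pep, pep)[0]
        g_center, g_other = _gapped_rows(aln)
        ins = [0] * (len(center_pep) + 1)
        cells: list[list[str]] = [[] for _ in range(len(center_pep) + 1)]
        aligned: list[str] = []
        cpos = 0
        for cc, oc in zip(g_center, g_other):
            if cc == "-":
                ins[cpos] += 1
                cells[cpos].append(oc)
            else:
                aligned.append(oc)
                cpos += 1
        pair_data.append((rec, pep, ins, cells, aligned))
        for j in range(len(ins)):
            max_ins[j] = max(max_ins[j], ins[j])

    def build_pep_row(ins_cells: Optional[list[list[str]]], aligned: Optional[list[str]]) -> str:
        out = []
        for j in range(len(center_pep) + 1):
            chunk = ins_cells[j] if ins_cells is not None else []
            out.append("".join(chunk) + "-" * (max_ins[j] - len(chunk)))
            if j < len(center_pep):
                if aligned is None:
                    out.append(center_pep[j])
                else:
                    out.append(aligned[j])
        return "".join(out)

    pep_rows = [build_pep_row(None, None)]
    seq_ids = [center_rec.seq_id]
    nts = [center_rec.nt]
    for rec, pep, ins, cells, aligned in pair_data:
        pep_rows.append(build_pep_row(cells, aligned))
        seq_ids.append(rec.seq_id)
        nts.append(rec.nt)

    codon_rows = []
    for pep_row, nt in zip(pep_rows, nts):
        codons = []
        pos = 0
        for ch in pep_row:
            if ch == "-":
                codons.append("---")
            else:
                codons.append(nt[pos : pos + 3])
                pos += 3
        codon_rows.append("".join(codons))

    lengths = {len(r) for r in codon_rows}
    assert len(lengths) == 1, "codon rows must have equal length"
    return CodonAlignment(seq_ids=seq_ids, rows=codon_rows, excluded=excluded)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

@dataclass
class DnDsEstimate:
    dN: float
    dS: float
    omega: Optional[float]
    n_codons_used: int
    usable: bool = True
    s_sites: float = 0.0
    n_sites: float = 0.0


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/non-synonymous change counts averaged over minimal pathways.

    Pathways passing through stop codons are excluded; if every pathway is
    blocked, all pathways are averaged instead (degenerate but finite).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> Optional[tuple[float, float]]:
        syn = nonsyn = 0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                return None
            if _CODE[cur] == _CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return float(syn), float(nonsyn)

    valid = []
    fallback = []
    for order in itertools.permutations(diff_positions):
        res = walk(order)
        if res is not None:
            valid.append(res)
        else:
            # count the path anyway for the all-blocked fallback
            syn = nonsyn = 0
            cur = codon_a
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if _CODE[cur] == _CODE[nxt] and _CODE[nxt] != "*":
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            fallback.append((float(syn), float(nonsyn)))
    paths = valid if valid else fallback
    syn = sum(p[0] for p in paths) / len(paths)
    nonsyn = sum(p[1] for p in paths) / len(paths)
    return syn, nonsyn


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_ng86(row_a: str, row_b: str) -> DnDsEstimate:
    """NG86 dN/dS for two equal-length aligned codon rows.

    Codons containing gaps, Ns or stop codons in either row are skipped
    pairwise.  Site counts are averaged over the two sequences; change counts
    average all valid minimal mutational pathways.
    """
    if len(row_a) != len(row_b) or len(row_a) % 3 != 0:
        raise ValueError("rows must be equal length and divisible by 3")
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    used = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        used += 1
        s_sites_a += _SYN_SITES[ca]
        s_sites_b += _SYN_SITES[cb]
        syn, nonsyn = _pathway_counts(ca, cb)
        sd += syn
        nd += nonsyn
    if used == 0:
        return DnDsEstimate(0.0, 0.0, None, 0, usable=False)
    s_sites = (s_sites_a + s_sites_b) / 2.0
    n_sites = 3.0 * used - s_sites
    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    if p_s >= 0.75 or p_n >= 0.75:
        return DnDsEstimate(
            math.nan, math.nan, None, used, usable=False, s_sites=s_sites, n_sites=n_sites
        )
    d_s = jukes_cantor(p_s)
    d_n = jukes_cantor(p_n)
    omega = d_n / d_s if d_s > 0.0 else None
    return DnDsEstimate(d_n, d_s, omega, used, usable=True, s_sites=s_sites, n_sites=n_sites)


@dataclass
class ClusterOmega:
    """Cluster-level dN/dS summary over all member pairs."""

    n_pairs: int
    n_defined: int
    mean_dn: float
    mean_ds: float
    mean_omega: Optional[float]
    excluded: bool
    classification: Optional[str]  # purifying | positive | None


def cluster_omega(aln: CodonAlignment, max_omega: float = 1.5) -> ClusterOmega:
    """Mean pairwise omega of a cluster, with the poor-alignment exclusion.

    Pairs whose omega is undefined (dS == 0) are left out of the mean rather
    than capped.  A cluster whose mean omega exceeds ``max_omega`` is flagged
    excluded (poorly aligned); below 1 it is classified as purifying, above 1
    as positive selection.
    """
    omegas, dns, dss = [], [], []
    n_pairs = 0
    for i in range(len(aln.rows)):
        for j in range(i + 1, len(aln.rows)):
            n_pairs += 1
            est = pairwise_ng86(aln.rows[i], aln.rows[j])
            if not est.usable:
                continue
            dns.append(est.dN)
            dss.append(est.dS)
            if est.omega is not None:
                omegas.append(est.omega)
    if not omegas:
        return ClusterOmega(
            n_pairs=n_pairs,
            n_defined=0,
            mean_dn=float(np.mean(dns)) if dns else math.nan,
            mean_ds=float(np.mean(dss)) if dss else math.nan,
            mean_omega=None,
            excluded=False,
            classification=None,
        )
    mean_omega = float(np.mean(omegas))
    if mean_omega > max_omega:
        classification = None
        excluded = True
    else:
        excluded = False
        classification = (
            "purifying" if mean_omega < 1.0 else "positive" if mean_omega > 1.0 else None
        )
    return ClusterOmega(
        n_pairs=n_pairs,
        n_defined=len(omegas),
        mean_dn=float(np.mean(dns)),
        mean_ds=float(np.mean(dss)),
        mean_omega=mean_omega,
        excluded=excluded,
        classification=classification,
    )


# ---------------------------------------------------------------------------
# notched box statistics
# ---------------------------------------------------------------------------

@dataclass
class BoxStats:
    """Five-number summary with notch bounds median +- 1.58 IQR / sqrt(n)."""

    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def notch_half_width(self) -> float:
        return 1.58 * self.iqr / math.sqrt(self.n)

    @property
    def notch_low(self) -> float:
        return self.median - self.notch_half_width

    @property
    def notch_high(self) -> float:
        return self.median + self.notch_half_width


def box_stats(values: Iterable[float]) -> BoxStats:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("box_stats needs at least one value")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return BoxStats(n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3))


def notches_overlap(a: BoxStats, b: BoxStats) -> bool:
    return not (a.notch_high < b.notch_low or b.notch_high < a.notch_low)


def stratify_by_occupancy(
    values: dict[str, float],
    occupancy: dict[str, int],
) -> dict[int, BoxStats]:
    """Notched box statistics per occupancy level.

    Non-overlapping notches between two levels are the significance criterion
    for a difference in medians.
    """
    per_level: dict[int, list[float]] = {}
    for key, value in values.items():
        per_level.setdefault(occupancy[key], []).append(value)
    return {level: box_stats(vals) for level, vals in sorted(per_level.items())}


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

def _as_tree(t) -> dendropy.Tree:
    if isinstance(t, dendropy.Tree):
        return t
    return dendropy.Tree.get(data=t, schema="newick")


def _split_lengths(tree: dendropy.Tree) -> tuple[dict[frozenset, float], frozenset]:
    """Canonical split -> total branch length, over all edges (unrooted).

    A split is represented by the side not containing the lexicographically
    smallest taxon; the two root edges of a rooted binary tree map to the
    same split and their lengths are summed.
    """
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(leaves)
    lengths: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if anchor not in below else leaves - below
        if not side or len(side) == len(leaves):
            continue
        lengths[side] = lengths.get(side, 0.0) + (node.edge.length or 0.0)
    return lengths, leaves


def tree_distance(t1, t2) -> dict[str, float]:
    """Symmetric (Robinson–Foulds) and branch score distances of two trees.

    Requires identical leaf sets (apply :func:`prune_to_common` first).  The
    symmetric distance counts non-trivial splits present in exactly one tree;
    the branch score is the sum over all splits of squared branch-length
    differences (absent splits contribute length 0), reported together with
    its square root.
    """
    tree1, tree2 = _as_tree(t1), _as_tree(t2)
    lengths1, leaves1 = _split_lengths(tree1)
    lengths2, leaves2 = _split_lengths(tree2)
    if leaves1 != leaves2:
        raise ValueError("trees have different leaf sets; prune_to_common first")
    n = len(leaves1)
    nontrivial1 = {s for s in lengths1 if 2 <= len(s) <= n - 2}
    nontrivial2 = {s for s in lengths2 if 2 <= len(s) <= n - 2}
    symmetric = len(nontrivial1 ^ nontrivial2)
    score = 0.0
    for split in set(lengths1) | set(lengths2):
        score += (lengths1.get(split, 0.0) - lengths2.get(split, 0.0)) ** 2
    return {
        "symmetric": symmetric,
        "branch_score": score,
        "branch_score_sqrt": math.sqrt(score),
    }


def prune_to_common(t1, t2) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Restrict both trees to their shared leaves.

    Degree-2 internal nodes created by pruning are suppressed with branch
    lengths summed.  Requires at least 3 shared leaves.
    """
    tree1, tree2 = _as_tree(t1).clone(depth=1), _as_tree(t2).clone(depth=1)
    leaves1 = {l.taxon.label for l in tree1.leaf_node_iter()}
    leaves2 = {l.taxon.label for l in tree2.leaf_node_iter()}
    common = leaves1 & leaves2
    if len(common) < 3:
        raise ValueError(f"only {len(common)} shared leaves; need at least 3")
    for tree, own in ((tree1, leaves1), (tree2, leaves2)):
        drop = own - common
        if drop:
            tree.prune_taxa_with_labels(sorted(drop))
    return tree1, tree2
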